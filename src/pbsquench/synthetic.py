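"""Synthetic phycobilisome-like networks and carotenoid parameter samplers.

The toy antenna emulates the topology that matters for quenching kinetics —
a tri-cylindrical allophycocyanin core with six radiating phycocyanin rods
and four OCP-bound canthaxanthins attached to core ApcA bilins — on idealized
cylinder lattices.  It is a geometry surrogate: distance scales and class
topology are realistic, disk symmetry and true per-disk pigment counts are
not.  Carotenoid S₁ energies and CAN–ApcA couplings are drawn from truncated
normal distributions centered on the QM/MM ensemble means (2.00 eV; 54 and
27 cm⁻¹).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
from scipy import stats

from .constants import ev_to_wavenumber
from .couplings import CouplingRuleSet, build_coupling_matrix
from .errors import ConfigurationError
from .network import Pigment, PigmentClass, PigmentNetwork, SiteProperties

#: Default CAN S₁ intrinsic decay rate (ps⁻¹): a ~4 ps carotenoid S₁ lifetime.
DEFAULT_CAN_DECAY_PS1 = 0.25

#: Default per-class site-energy scheme (cm⁻¹), intrinsic bilin decay
#: 1/1600 ps⁻¹ (≈1.6 ns fluorescence lifetime), bilin TDM 7 D scale.
#: Rod bilins absorb near 620 nm; ApcA/ApcB emit at 660 nm and the terminal
#: ApcD/ApcE states at 680 nm.  CAN entries are placeholders overwritten by
#: the per-run sampler.
DEFAULT_SCHEME: dict[PigmentClass, SiteProperties] = {
    PigmentClass.ROD_PCB: SiteProperties(16130.0, 1.0 / 1600.0, 7.0, "pcb"),
    PigmentClass.APCA_PCB: SiteProperties(1e7 / 660.0, 1.0 / 1600.0, 7.0, "pcb"),
    PigmentClass.APCB_PCB: SiteProperties(1e7 / 660.0, 1.0 / 1600.0, 7.0, "pcb"),
    PigmentClass.APCD_PCB: SiteProperties(1e7 / 680.0, 1.0 / 1600.0, 7.0, "pcb"),
    PigmentClass.APCE_PCB: SiteProperties(1e7 / 680.0, 1.0 / 1600.0, 7.0, "pcb"),
    PigmentClass.CAN: SiteProperties(
        ev_to_wavenumber(2.00) - 1400.0, DEFAULT_CAN_DECAY_PS1, 7.0, "can"
    ),
}


@dataclass
class ToyPBSConfig:
    """Geometry and composition of the synthetic antenna."""

    n_rods: int = 6
    pigments_per_rod: int = 6
    core_cylinders: int = 3
    pigments_per_cylinder: int = 12
    nn_distance: float = 25.0  # Å, nearest-neighbour bilin spacing
    n_can: int = 4
    #: optional explicit CAN → (ApcA₁ id, ApcA₂ id) assignment; by default the
    #: carotenoids are attached to consecutive core ApcA pigments
    can_attachment: dict[str, tuple[str, str]] | None = None
    jitter_deg: float = 8.0  # TDM orientation jitter
    seed: int = 2024

    def __post_init__(self) -> None:
        for name in ("n_rods", "pigments_per_rod", "core_cylinders",
                     "pigments_per_cylinder", "n_can"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be ≥ 0")
        if self.nn_distance <= 5.0:
            raise ConfigurationError("nn_distance must exceed 5 Å")
        if self.core_cylinders > 0 and self.pigments_per_cylinder < 1:
            raise ConfigurationError("core cylinders need ≥ 1 pigment each")


@dataclass
class CanParameterSpec:
    """Distributions of the sampled carotenoid parameters.

    ``e_s1_mean`` is the mean vertical S₀–S₁ (absorption-maximum) energy of
    CAN from the QM/MM ensemble; the 0-0 site energy used for detailed
    balance is ``e_s1 − e00_shift_cm1`` (one vibronic quantum below the
    vertical energy by default).  Coupling means are the CAN–ApcA₁ and
    CAN–ApcA₂ ensemble means.
    """

    e_s1_mean: float = 2.00  # eV
    e_s1_sd: float = 0.07  # eV
    coupling_means: tuple[float, float] = (54.0, 27.0)  # cm⁻¹
    coupling_sds: tuple[float, float] | None = None  # default 40% of the means
    distribution: str = "truncated_normal"
    e00_shift_cm1: float = 1400.0
    empirical_samples: np.ndarray | None = None  # (n, 3) for empirical mode

    def __post_init__(self) -> None:
        if self.e_s1_mean <= 0 or any(m <= 0 for m in self.coupling_means):
            raise ConfigurationError("means must be positive")
        if self.coupling_sds is None:
            self.coupling_sds = tuple(0.4 * m for m in self.coupling_means)
        if self.e_s1_sd < 0 or any(s < 0 for s in self.coupling_sds):
            raise ConfigurationError("standard deviations must be ≥ 0")
        if self.distribution not in ("truncated_normal", "empirical_samples"):
            raise ConfigurationError(
                f"unknown distribution {self.distribution!r}"
            )
        if self.distribution == "empirical_samples":
            if self.empirical_samples is None or len(self.empirical_samples) == 0:
                raise ConfigurationError(
                    "empirical_samples mode requires a non-empty sample table"
                )
            self.empirical_samples = np.atleast_2d(
                np.asarray(self.empirical_samples, float)
            )


def _truncated_normal(
    mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Normal(mean, sd) truncated to positive support."""
    if sd == 0.0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def sample_can_parameters(
    spec: CanParameterSpec, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw n independent (E_S1 eV, V₁ cm⁻¹, V₂ cm⁻¹) parameter sets."""
    if n < 1:
        raise ValueError("n must be ≥ 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if spec.distribution == "empirical_samples":
        idx = rng.integers(len(spec.empirical_samples), size=n)
        draws = spec.empirical_samples[idx]
    else:
        draws = np.column_stack(
            [
                _truncated_normal(spec.e_s1_mean, spec.e_s1_sd, n, rng),
                _truncated_normal(
                    spec.coupling_means[0], spec.coupling_sds[0], n, rng
                ),
                _truncated_normal(
                    spec.coupling_means[1], spec.coupling_sds[1], n, rng
                ),
            ]
        )
    if np.any(draws <= 0):
        raise ConfigurationError("sampler produced a non-positive draw")
    return draws


def make_can_sampler(spec: CanParameterSpec, attachment: dict[str, tuple[str, str]]):
    """Per-CAN sampler closure for :func:`pbsquench.dynamics.run_ensemble`.

    ``attachment`` maps each CAN id to its (ApcA₁ id, ApcA₂ id) partners.
    The returned callable draws one parameter set for the named CAN; the
    sampled vertical energy is converted to the 0-0 scale via
    ``e00_shift_cm1``.
    """

    def sampler(rng: np.random.Generator, can_id: str) -> dict:
        e_s1, v1, v2 = sample_can_parameters(spec, 1, rng)[0]
        e00 = ev_to_wavenumber(float(e_s1)) - spec.e00_shift_cm1
        a1, a2 = attachment[can_id]
        return {
            "e00_cm1": e00,
            "couplings": {(can_id, a1): float(v1), (can_id, a2): float(v2)},
        }

    return sampler


def _ring_positions(
    axis_yz: tuple[float, float], n_rings: int, per_ring: int, spacing: float
) -> np.ndarray:
    """Pigment positions of one core cylinder: stacked rings along x."""
    radius = spacing / (2.0 * np.sin(np.pi / per_ring)) if per_ring > 1 else 0.0
    pos = []
    x0 = -0.5 * (n_rings - 1) * spacing
    for r in range(n_rings):
        for k in range(per_ring):
            phi = 2.0 * np.pi * k / per_ring + (np.pi / per_ring) * (r % 2)
            pos.append(
                [
                    x0 + r * spacing,
                    axis_yz[0] + radius * np.cos(phi),
                    axis_yz[1] + radius * np.sin(phi),
                ]
            )
    return np.array(pos)


def _jittered_unit(base: np.ndarray, rng: np.random.Generator, deg: float) -> np.ndarray:
    v = base + np.deg2rad(deg) * rng.standard_normal(3)
    return v / np.linalg.norm(v)


def make_toy_pbs(
    config: ToyPBSConfig,
    spec: CanParameterSpec | None = None,
    scheme: dict[PigmentClass, SiteProperties] | None = None,
) -> PigmentNetwork:
    """Build the synthetic antenna network with couplings assembled.

    Bilin–bilin couplings use the point-dipole approximation over the
    generated geometry; the whitelisted CAN–ApcA couplings are seeded at the
    distribution means of ``spec`` (per-run resampling happens in
    :func:`pbsquench.dynamics.run_ensemble`).  The CAN attachment map and the
    sampler spec are stored in the network metadata.
    """
    spec = spec or CanParameterSpec()
    scheme = scheme or DEFAULT_SCHEME
    rng = np.random.default_rng(config.seed)
    pigments: list[Pigment] = []

    # --- tri-cylindrical core: rings of 6 stacked along x ------------------
    # cylinder axes spaced so the closest inter-cylinder bilin pair sits at
    # roughly the nearest-neighbour distance (no artificially hot contacts)
    per_ring = min(6, config.pigments_per_cylinder)
    axes = [(0.0, 0.0), (75.0, 0.0), (37.5, 63.0)][: config.core_cylinders]
    core_indices: list[int] = []
    core_base_tdms: list[np.ndarray] = []  # un-jittered: keeps geometry seed-free
    apca_ids: list[str] = []
    for c, axis_yz in enumerate(axes):
        n_rings = max(1, int(np.ceil(config.pigments_per_cylinder / per_ring)))
        pos = _ring_positions(axis_yz, n_rings, per_ring, config.nn_distance)
        pos = pos[: config.pigments_per_cylinder]
        for k, p in enumerate(pos):
            # alternate ApcA/ApcB; the two lowest-energy terminal emitters
            # (ApcD, ApcE) sit in the first (bottom) cylinder
            if c == 0 and k == 0:
                cls = PigmentClass.APCD_PCB
            elif c == 0 and k == 1:
                cls = PigmentClass.APCE_PCB
            else:
                cls = PigmentClass.APCA_PCB if k % 2 == 0 else PigmentClass.APCB_PCB
            tangent = np.array(
                [0.0, -(p[2] - axis_yz[1]), p[1] - axis_yz[0]]
            )
            if np.linalg.norm(tangent) < 1e-9:
                tangent = np.array([1.0, 0.0, 0.0])
            tangent /= np.linalg.norm(tangent)
            # tilt out of the disc plane so rod (axis-aligned) and core
            # dipoles are never mutually orthogonal
            tangent = tangent + np.array([0.8, 0.0, 0.0])
            tangent /= np.linalg.norm(tangent)
            core_base_tdms.append(tangent)
            pid = f"core{c}_{k}"
            pigments.append(
                Pigment(
                    id=pid,
                    pigment_class=cls,
                    position=p,
                    tdm_direction=_jittered_unit(tangent, rng, config.jitter_deg),
                )
            )
            core_indices.append(len(pigments) - 1)
            if cls is PigmentClass.APCA_PCB:
                apca_ids.append(pid)

    # --- six rods radiating in the y-z plane -------------------------------
    # each rod is anchored one nearest-neighbour spacing outside the core
    # pigment that lies farthest along its direction, so every rod has a
    # genuine ~nn_distance contact with the core
    center = np.array([0.0, 37.5, 21.0])
    core_pos = np.array([p.position for p in pigments]) if pigments else None
    placed_rod_points: list[np.ndarray] = []
    for r in range(config.n_rods):
        ang = 2.0 * np.pi * r / max(config.n_rods, 1)
        direction = np.array([0.0, np.cos(ang), np.sin(ang)])
        if core_pos is not None:
            proj = (core_pos - center) @ direction
            # dock among the outermost core pigments at the one whose dipole
            # is best aligned with the rod for efficient transfer, skipping
            # anchors whose rod line would clash with an already-placed rod
            candidates = np.nonzero(proj >= proj.max() - 15.0)[0]
            align = np.array(
                [abs(direction @ core_base_tdms[i]) for i in candidates]
            )
            anchor = None
            for ci in candidates[np.argsort(-align)]:
                line = core_pos[ci] + direction * config.nn_distance * (
                    1 + np.arange(config.pigments_per_rod)[:, None]
                )
                clash = any(
                    np.min(np.linalg.norm(line - q, axis=1)) < 0.6 * config.nn_distance
                    for q in placed_rod_points
                )
                if not clash:
                    anchor = core_pos[ci]
                    break
            if anchor is None:
                raise ConfigurationError(
                    f"cannot place rod {r} without clashing with another rod"
                )
        else:
            anchor = center
        for k in range(config.pigments_per_rod):
            p = anchor + direction * ((k + 1) * config.nn_distance)
            tdm = direction  # head-to-tail chain (κ ≈ −2): efficient 1D transport
            pigments.append(
                Pigment(
                    id=f"rod{r}_{k}",
                    pigment_class=PigmentClass.ROD_PCB,
                    position=p,
                    tdm_direction=_jittered_unit(tdm, rng, config.jitter_deg),
                )
            )
            placed_rod_points.append(p)

    # --- carotenoids attached to core ApcA pigments ------------------------
    by_id = {p.id: p for p in pigments}
    if config.can_attachment is not None:
        if len(config.can_attachment) != config.n_can:
            raise ConfigurationError(
                f"can_attachment lists {len(config.can_attachment)} CAN, "
                f"config asks for {config.n_can}"
            )
        for can_id, pair in config.can_attachment.items():
            for pid in pair:
                target = by_id.get(pid)
                if target is None:
                    raise ConfigurationError(
                        f"CAN attachment target {pid!r} does not exist"
                    )
                if target.pigment_class in (
                    PigmentClass.ROD_PCB, PigmentClass.CAN
                ):
                    raise ConfigurationError(
                        f"CAN {can_id} attached to {pid!r} "
                        f"({target.pigment_class.value}): CAN binds core bilins"
                    )
        assignments = {k: tuple(v) for k, v in config.can_attachment.items()}
    else:
        if config.n_can > 0 and len(apca_ids) < 2 * config.n_can:
            raise ConfigurationError(
                f"need ≥ {2 * config.n_can} ApcA pigments for "
                f"{config.n_can} CAN, have {len(apca_ids)}"
            )
        assignments = {
            f"can{q}": (apca_ids[2 * q], apca_ids[2 * q + 1])
            for q in range(config.n_can)
        }
    attachment: dict[str, tuple[str, str]] = {}
    for can_id, (a1, a2) in assignments.items():
        host = by_id[a1]
        outward = host.position - np.array([0.0, *np.mean(axes, axis=0)])
        outward[0] = 0.0
        if np.linalg.norm(outward) < 1e-9:
            outward = np.array([0.0, 1.0, 0.0])
        outward /= np.linalg.norm(outward)
        pigments.append(
            Pigment(
                id=can_id,
                pigment_class=PigmentClass.CAN,
                position=host.position + 12.0 * outward,
                tdm_direction=_jittered_unit(np.array([1.0, 0.0, 0.0]), rng,
                                             config.jitter_deg),
            )
        )
        attachment[can_id] = (a1, a2)

    from .network import assign_site_properties

    pigments = assign_site_properties(pigments, scheme)
    # override CAN 0-0 energy with the spec mean (resampled per run later)
    for p in pigments:
        if p.pigment_class is PigmentClass.CAN:
            p.site_energy = ev_to_wavenumber(spec.e_s1_mean) - spec.e00_shift_cm1

    pos = np.array([p.position for p in pigments])
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    if d.min() <= 5.0:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise ConfigurationError(
            f"generated geometry has pigments {pigments[i].id!r} and "
            f"{pigments[j].id!r} only {d.min():.2f} Å apart (≤ 5 Å)"
        )

    whitelist = tuple(
        (can_id, pcb_id)
        for can_id, pair in attachment.items()
        for pcb_id in pair
    )
    rules = CouplingRuleSet(can_pcb_whitelist=whitelist)
    sampled = {}
    for can_id, (a1, a2) in attachment.items():
        sampled[(can_id, a1)] = spec.coupling_means[0]
        sampled[(can_id, a2)] = spec.coupling_means[1]
    network = PigmentNetwork(
        pigments=pigments,
        metadata={
            "generator": "make_toy_pbs",
            "seed": config.seed,
            "n_rods": config.n_rods,
            "pigments_per_rod": config.pigments_per_rod,
            "core_cylinders": config.core_cylinders,
            "pigments_per_cylinder": config.pigments_per_cylinder,
            "n_can": config.n_can,
            "can_attachment": attachment,
        },
    )
    return build_coupling_matrix(network, rules, sampled=sampled)


# --------------------------------------------------------------------------
# mmCIF fixture writer (synthetic stand-in for a deposited structure)
# --------------------------------------------------------------------------

_FIXTURE_CODES = {"bilin": "CYC", "can": "CAN"}


def make_fixture_structure(
    path: str | Path, n_bilin: int = 3, n_can: int = 1
) -> Path:
    """Write a minimal synthetic mmCIF with known cofactor content.

    Each cofactor carries ten "conjugated" atoms (C1..C10) laid out along a
    known axis, so extraction tests have planted ground truth: bilins
    (ligand code CYC) along x on chain B, carotenoids (CAN) along y on
    chain Q.  The file round-trips through gemmi.
    """
    st = gemmi.Structure()
    st.name = "synthetic quenching fixture"
    model = gemmi.Model("1")

    def add_chain(name: str, code: str, count: int, axis: np.ndarray,
                  origin: np.ndarray) -> None:
        chain = gemmi.Chain(name)
        for r in range(count):
            res = gemmi.Residue()
            res.name = code
            res.seqid = gemmi.SeqId(r + 1, " ")
            res.het_flag = "H"
            base = origin + 40.0 * r * np.array([0.0, 0.0, 1.0])
            for a in range(10):
                atom = gemmi.Atom()
                atom.name = f"C{a + 1}"
                atom.element = gemmi.Element("C")
                p = base + 1.4 * a * axis
                atom.pos = gemmi.Position(*p)
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)

    if n_bilin > 0:
        add_chain("B", _FIXTURE_CODES["bilin"], n_bilin,
                  np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 0.0]))
    if n_can > 0:
        add_chain("Q", _FIXTURE_CODES["can"], n_can,
                  np.array([0.0, 1.0, 0.0]), np.array([30.0, 0.0, 0.0]))
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    st.make_mmcif_document().write_file(str(path))
    return path


def fixture_extraction_config() -> dict:
    """Extraction rules matching :func:`make_fixture_structure` output."""
    from .network import CofactorRule

    atoms = tuple(f"C{i + 1}" for i in range(10))
    return {
        _FIXTURE_CODES["bilin"]: CofactorRule(PigmentClass.APCA_PCB, atoms),
        _FIXTURE_CODES["can"]: CofactorRule(PigmentClass.CAN, atoms),
    }
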