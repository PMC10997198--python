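"""Pigment network model.

Domain types for chromophore sites (phycocyanobilins and the OCP-bound
canthaxanthin) and the coupled network they form, plus extraction of pigment
geometry and transition-dipole axes from PDB/mmCIF structure files.

Positions are in Å, site energies in cm⁻¹ (0-0 transition), transition-dipole
magnitudes in debye and decay rates in ps⁻¹.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from .constants import DEBYE_PER_E_ANGSTROM
from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    MissingAtomsError,
    NoPigmentsFoundError,
    StructureFormatError,
)


class PigmentClass(enum.Enum):
    """Spectroscopic class of a chromophore site.

    Rod phycocyanobilins absorb highest; allophycocyanin-family core bilins
    (ApcA/ApcB) emit near 660 nm; the terminal emitters (ApcD/ApcE) carry the
    lowest-energy ~680 nm states; CAN is the canthaxanthin S₁ quencher.
    """

    ROD_PCB = "ROD_PCB"
    APCA_PCB = "APCA_PCB"
    APCB_PCB = "APCB_PCB"
    APCD_PCB = "APCD_PCB"
    APCE_PCB = "APCE_PCB"
    CAN = "CAN"

    @property
    def is_bilin(self) -> bool:
        return self is not PigmentClass.CAN


@dataclass
class Pigment:
    """One chromophore site.

    ``site_energy``, ``decay_rate``, ``tdm_magnitude`` and ``lineshape_id``
    may be ``None`` until :func:`assign_site_properties` fills them from a
    per-class scheme.
    """

    id: str
    pigment_class: PigmentClass
    position: np.ndarray
    tdm_direction: np.ndarray
    tdm_magnitude: float | None = None  # debye
    site_energy: float | None = None  # cm⁻¹, 0-0
    decay_rate: float | None = None  # ps⁻¹
    lineshape_id: str | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.tdm_direction = np.asarray(self.tdm_direction, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"pigment {self.id}: position must be a 3-vector")
        norm = float(np.linalg.norm(self.tdm_direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(
                f"pigment {self.id}: |tdm_direction| = {norm!r}, expected unit"
            )
        if self.site_energy is not None and self.site_energy <= 0:
            raise ValueError(f"pigment {self.id}: site_energy must be > 0")
        if self.tdm_magnitude is not None and self.tdm_magnitude < 0:
            raise ValueError(f"pigment {self.id}: tdm_magnitude must be ≥ 0")
        if self.decay_rate is not None and self.decay_rate < 0:
            raise ValueError(f"pigment {self.id}: decay_rate must be ≥ 0")


@dataclass
class TransitionChargeSet:
    """Atomic transition charges of one electronic transition.

    Charges are in units of elementary charge e and sum to ~0 (a
    dipole-allowed transition carries no monopole); coordinates are in Å.
    """

    pigment_id: str
    atom_positions: np.ndarray  # (n, 3) Å
    charges: np.ndarray  # (n,) e
    charge_sum_tol: float = 1e-3

    def __post_init__(self) -> None:
        self.atom_positions = np.atleast_2d(np.asarray(self.atom_positions, float))
        self.charges = np.atleast_1d(np.asarray(self.charges, float))
        if self.atom_positions.shape != (self.charges.size, 3):
            raise ValueError(
                f"{self.pigment_id}: {self.atom_positions.shape[0]} positions "
                f"vs {self.charges.size} charges"
            )
        total = float(self.charges.sum())
        if abs(total) > self.charge_sum_tol:
            raise ValueError(
                f"{self.pigment_id}: transition charges sum to {total:.2e} e "
                f"(tolerance {self.charge_sum_tol:.0e} e)"
            )

    def dipole_debye(self) -> float:
        """|Σᵢ qᵢ rᵢ| in debye (origin-independent since Σq≈0)."""
        mu = self.charges @ self.atom_positions  # e·Å
        return float(np.linalg.norm(mu)) * DEBYE_PER_E_ANGSTROM

    def check_dipole(self, declared_debye: float, rel_tol: float = 0.05) -> None:
        """Validate the summed dipole against a declared TDM magnitude."""
        mu = self.dipole_debye()
        if declared_debye <= 0:
            raise ValueError("declared TDM must be positive")
        if abs(mu - declared_debye) > rel_tol * declared_debye:
            raise ValueError(
                f"{self.pigment_id}: charge dipole {mu:.3f} D deviates from "
                f"declared {declared_debye:.3f} D by more than {rel_tol:.0%}"
            )


@dataclass
class PigmentNetwork:
    """Pigments plus their symmetric electronic-coupling matrix (cm⁻¹)."""

    pigments: list[Pigment]
    couplings: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.pigments)
        if self.couplings is None:
            self.couplings = np.zeros((n, n))
        self.couplings = np.asarray(self.couplings, dtype=float)
        if self.couplings.shape != (n, n):
            raise ValueError(
                f"coupling matrix {self.couplings.shape} for {n} pigments"
            )
        if np.any(np.abs(np.diag(self.couplings)) > 0):
            raise ValueError("coupling diagonal must be exactly zero")
        if not np.allclose(self.couplings, self.couplings.T, atol=1e-9):
            raise ValueError("coupling matrix must be symmetric")

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.pigments]

    def index_of(self, pigment_id: str) -> int:
        for i, p in enumerate(self.pigments):
            if p.id == pigment_id:
                return i
        raise KeyError(pigment_id)

    def indices_of_class(self, cls: PigmentClass) -> np.ndarray:
        return np.array(
            [i for i, p in enumerate(self.pigments) if p.pigment_class is cls],
            dtype=int,
        )

    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.pigments])

    def to_frame(self) -> pd.DataFrame:
        """Pigment table with the canonical CSV schema."""
        rows = []
        for p in self.pigments:
            rows.append(
                {
                    "id": p.id,
                    "class": p.pigment_class.value,
                    "x": p.position[0],
                    "y": p.position[1],
                    "z": p.position[2],
                    "ux": p.tdm_direction[0],
                    "uy": p.tdm_direction[1],
                    "uz": p.tdm_direction[2],
                    "tdm_D": p.tdm_magnitude,
                    "E_cm1": p.site_energy,
                    "kdecay_ps1": p.decay_rate,
                }
            )
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def compute_tdm_axis(atom_positions: Sequence[Sequence[float]]) -> np.ndarray:
    """Principal geometric axis of a set of atoms.

    Returns the eigenvector of the largest eigenvalue of the centered
    second-moment matrix, as a unit vector with a fixed sign convention
    (the component of largest absolute value is positive).  Serves as the
    orientation of a conjugated system's transition dipole.
    """
    pts = np.atleast_2d(np.asarray(atom_positions, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegenerateGeometryError(
            f"need ≥ 3 points with 3 coordinates, got shape {pts.shape}"
        )
    centered = pts - pts.mean(axis=0)
    moment = centered.T @ centered
    evals, evecs = np.linalg.eigh(moment)
    if evals[-1] <= 1e-12:
        raise DegenerateGeometryError("points have zero spatial extent")
    axis = evecs[:, -1]
    k = int(np.argmax(np.abs(axis)))
    if axis[k] < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


@dataclass(frozen=True)
class CofactorRule:
    """Extraction rule for one ligand code."""

    pigment_class: PigmentClass
    conjugated_atoms: tuple[str, ...]
    #: optional chain-id → class override (e.g. rod vs core bilins of one code)
    chain_classes: Mapping[str, PigmentClass] | None = None


def _class_for(rule: CofactorRule, chain: str) -> PigmentClass:
    if rule.chain_classes and chain in rule.chain_classes:
        return rule.chain_classes[chain]
    return rule.pigment_class


def read_structure(
    path: str | Path,
    extraction_config: Mapping[str, CofactorRule],
) -> list[Pigment]:
    """Extract pigments from a PDB or mmCIF file.

    ``extraction_config`` maps ligand three-letter codes (phycocyanobilin
    dialects vary across entries; canthaxanthin is "CAN") to a
    :class:`CofactorRule` naming the pigment class and the conjugated atoms.
    One :class:`Pigment` is produced per matched cofactor: its position is the
    centroid of the conjugated atoms and its dipole axis the principal
    geometric axis of those atoms.  Site properties are left unassigned.
    Output order is deterministic: chain name, then residue number.
    """
    path = Path(path)
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(structure) == 0:
        raise StructureFormatError(f"{path}: no models in structure")

    hits: list[tuple[str, int, gemmi.Residue]] = []
    model = structure[0]
    for chain in model:
        for residue in chain:
            if residue.name in extraction_config:
                hits.append((chain.name, residue.seqid.num, residue))
    if not hits:
        raise NoPigmentsFoundError(
            f"{path}: no pigments found (no residue matched codes "
            f"{sorted(extraction_config)})"
        )
    hits.sort(key=lambda t: (t[0], t[1]))

    pigments: list[Pigment] = []
    for chain_name, seqnum, residue in hits:
        rule = extraction_config[residue.name]
        coords = {atom.name: np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                  for atom in residue}
        missing = [a for a in rule.conjugated_atoms if a not in coords]
        if missing:
            raise MissingAtomsError(
                f"{path}: cofactor {residue.name} {chain_name}{seqnum} is "
                f"missing atoms {missing}"
            )
        pts = np.array([coords[a] for a in rule.conjugated_atoms])
        pigments.append(
            Pigment(
                id=f"{chain_name}{seqnum}_{residue.name}",
                pigment_class=_class_for(rule, chain_name),
                position=pts.mean(axis=0),
                tdm_direction=compute_tdm_axis(pts),
            )
        )
    return pigments


@dataclass(frozen=True)
class SiteProperties:
    """Per-class spectroscopic parameters."""

    site_energy: float  # cm⁻¹
    decay_rate: float  # ps⁻¹
    tdm_magnitude: float  # debye
    lineshape_id: str


def assign_site_properties(
    pigments: Sequence[Pigment],
    scheme: Mapping[PigmentClass, SiteProperties],
) -> list[Pigment]:
    """Fill site energy, decay rate, TDM magnitude and lineshape per class.

    Returns new Pigment objects; geometry is never altered.  Idempotent.
    """
    missing = {p.pigment_class for p in pigments} - set(scheme)
    if missing:
        names = sorted(c.value for c in missing)
        raise ConfigurationError(f"scheme lacks entries for classes {names}")
    out = []
    for p in pigments:
        props = scheme[p.pigment_class]
        out.append(
            replace(
                p,
                site_energy=props.site_energy,
                decay_rate=props.decay_rate,
                tdm_magnitude=props.tdm_magnitude,
                lineshape_id=props.lineshape_id,
            )
        )
    return out
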