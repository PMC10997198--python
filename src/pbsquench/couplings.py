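"""Electronic coupling calculators.

Two routes to the excitonic coupling V (cm⁻¹) between pigments:

* TrEsp — Coulomb sum over atomic transition charges,
  V = K · Σᵢ Σⱼ qᵢqⱼ / rᵢⱼ, used for the short CAN–bilin contacts where a
  point dipole is not justified;
* point-dipole approximation (PDA) — V = s·C·κ·μ₁μ₂/R³ with the orientation
  factor κ = û₁·û₂ − 3(û₁·R̂)(û₂·R̂), used for the bilin–bilin network.

Assembly rules restrict CAN couplings to a whitelist of nearest partners;
all other CAN entries are exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .constants import (
    PDA_WAVENUMBER_ANGSTROM3_PER_DEBYE2,
    TRESP_COULOMB_WAVENUMBER_ANGSTROM,
)
from .errors import CoincidentAtomsError, ConfigurationError
from .network import Pigment, PigmentClass, PigmentNetwork, TransitionChargeSet


def tresp_coupling(a: TransitionChargeSet, b: TransitionChargeSet) -> float:
    """TrEsp coupling in cm⁻¹ from two transition-charge sets (q in e, r in Å)."""
    diff = a.atom_positions[:, None, :] - b.atom_positions[None, :, :]
    r = np.sqrt((diff**2).sum(axis=2))
    zero = np.argwhere(r == 0.0)
    if zero.size:
        i, j = zero[0]
        raise CoincidentAtomsError(
            f"atoms {a.pigment_id}[{i}] and {b.pigment_id}[{j}] coincide"
        )
    return TRESP_COULOMB_WAVENUMBER_ANGSTROM * float(
        (np.outer(a.charges, b.charges) / r).sum()
    )


def orientation_factor(u_a: np.ndarray, u_b: np.ndarray, r_hat: np.ndarray) -> float:
    """Dipole orientation factor κ = û_a·û_b − 3(û_a·R̂)(û_b·R̂), in [−2, 2]."""
    return float(u_a @ u_b - 3.0 * (u_a @ r_hat) * (u_b @ r_hat))


def point_dipole_coupling(a: Pigment, b: Pigment, screening: float = 1.0) -> float:
    """Point-dipole coupling in cm⁻¹ between two pigments (μ in D, R in Å)."""
    if a.tdm_magnitude is None or b.tdm_magnitude is None:
        raise ConfigurationError(
            f"point-dipole coupling needs assigned TDM magnitudes "
            f"({a.id}, {b.id})"
        )
    rvec = b.position - a.position
    r = float(np.linalg.norm(rvec))
    if r == 0.0:
        raise CoincidentAtomsError(f"pigments {a.id} and {b.id} coincide")
    kappa = orientation_factor(a.tdm_direction, b.tdm_direction, rvec / r)
    return (
        screening
        * PDA_WAVENUMBER_ANGSTROM3_PER_DEBYE2
        * kappa
        * a.tdm_magnitude
        * b.tdm_magnitude
        / r**3
    )


def tdm_fold_change(mu: float, mu_ref: float, base: float = 10.0) -> float:
    """log(μ/μ_ref): the fold-change metric for per-residue TDM perturbation.

    Base 10 by default; pass ``base=math.e`` for natural log.
    """
    if mu <= 0 or mu_ref <= 0:
        raise ValueError(f"TDM magnitudes must be positive (got {mu}, {mu_ref})")
    return math.log(mu / mu_ref, base)


class CanPcbMethod:
    TRESP = "tresp"
    SAMPLED = "sampled"


@dataclass
class CouplingRuleSet:
    """How each pigment-class pair acquires its coupling.

    Bilin–bilin couplings always use the PDA; CAN–bilin couplings are either
    computed by TrEsp from supplied transition charges or injected as sampled
    values, and only for whitelisted (CAN id, bilin id) pairs — every other
    CAN coupling is exactly zero.
    """

    can_pcb_method: str = CanPcbMethod.SAMPLED
    can_pcb_whitelist: tuple[tuple[str, str], ...] = ()
    screening_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.screening_factor <= 0:
            raise ConfigurationError(
                f"screening_factor must be > 0, got {self.screening_factor}"
            )
        if self.can_pcb_method not in (CanPcbMethod.TRESP, CanPcbMethod.SAMPLED):
            raise ConfigurationError(
                f"unknown can_pcb_method {self.can_pcb_method!r}"
            )
        self.can_pcb_whitelist = tuple(
            (str(a), str(b)) for a, b in self.can_pcb_whitelist
        )


def build_coupling_matrix(
    network: PigmentNetwork,
    rules: CouplingRuleSet,
    charges: Mapping[str, TransitionChargeSet] | None = None,
    sampled: Mapping[tuple[str, str], float] | None = None,
) -> PigmentNetwork:
    """Assemble the full symmetric coupling matrix for a pigment network.

    Returns a new network with the couplings filled; pigments are shared.
    """
    ids = network.ids
    id_set = set(ids)
    for can_id, pcb_id in rules.can_pcb_whitelist:
        for pid in (can_id, pcb_id):
            if pid not in id_set:
                raise ConfigurationError(
                    f"whitelist references unknown pigment {pid!r}"
                )
    n = len(ids)
    V = np.zeros((n, n))
    pigments = network.pigments
    for i in range(n):
        for j in range(i + 1, n):
            a, b = pigments[i], pigments[j]
            a_can = a.pigment_class is PigmentClass.CAN
            b_can = b.pigment_class is PigmentClass.CAN
            if a_can and b_can:
                continue  # CAN–CAN transfer is not modelled
            if not a_can and not b_can:
                V[i, j] = point_dipole_coupling(a, b, rules.screening_factor)
                continue
            can, pcb = (a, b) if a_can else (b, a)
            pair = (can.id, pcb.id)
            if pair not in rules.can_pcb_whitelist:
                continue  # neglected: exactly zero
            if rules.can_pcb_method == CanPcbMethod.TRESP:
                if charges is None or can.id not in charges or pcb.id not in charges:
                    raise ConfigurationError(
                        f"TrEsp mode: missing transition charges for pair {pair}"
                    )
                V[i, j] = tresp_coupling(charges[can.id], charges[pcb.id])
            else:
                if sampled is None or pair not in sampled:
                    raise ConfigurationError(
                        f"sampled mode: no coupling value supplied for pair {pair}"
                    )
                V[i, j] = sampled[pair]
    V = V + V.T
    return PigmentNetwork(
        pigments=list(pigments), couplings=V, metadata=dict(network.metadata)
    )


def load_transition_charges(
    path: str | Path, pigment_id: str, charge_sum_tol: float = 1e-3
) -> TransitionChargeSet:
    """Read a transition-charge table (columns: atom, x, y, z, q).

    Whitespace- or comma-separated text with a header line.
    """
    df = pd.read_csv(path, sep=r"[,\s]+", engine="python", comment="#")
    needed = {"atom", "x", "y", "z", "q"}
    cols = {c.lower(): c for c in df.columns}
    if not needed <= set(cols):
        raise ConfigurationError(
            f"{path}: expected columns {sorted(needed)}, found {list(df.columns)}"
        )
    return TransitionChargeSet(
        pigment_id=pigment_id,
        atom_positions=df[[cols["x"], cols["y"], cols["z"]]].to_numpy(float),
        charges=df[cols["q"]].to_numpy(float),
        charge_sum_tol=charge_sum_tol,
    )


def coupling_matrix_to_csv(network: PigmentNetwork, path: str | Path) -> None:
    """Write the coupling matrix as a labeled CSV."""
    pd.DataFrame(network.couplings, index=network.ids, columns=network.ids).to_csv(path)


def coupling_matrix_from_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
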