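"""Förster hopping kinetics.

Pairwise transfer rates follow k_AB = 1.18 · V_AB² · J with V in cm⁻¹ and the
spectral overlap J of normalized donor-emission and acceptor-absorption
profiles in cm, giving k in ps⁻¹.  The downhill direction (higher → lower 0-0
site energy) is computed from the overlap; the uphill rate is obtained from
detailed balance, k_up = k_down·exp(−Δε/k_BT), so every pair is exactly
Boltzmann-balanced and a closed network relaxes to the Boltzmann distribution
over site energies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .constants import FORSTER_PREFACTOR, KB_WAVENUMBER_PER_K
from .errors import ConfigurationError
from .network import PigmentNetwork
from .spectra import LineShape, mirror_emission, spectral_overlap


def forster_rate(coupling: float, overlap: float) -> float:
    """Förster transfer rate in ps⁻¹: k = 1.18·V²·J (V in cm⁻¹, J in cm)."""
    if overlap < 0:
        raise ValueError(f"spectral overlap must be ≥ 0, got {overlap}")
    return FORSTER_PREFACTOR * coupling * coupling * overlap


def detailed_balance_pair(
    k_downhill: float, delta_e: float, temperature: float
) -> float:
    """Uphill rate from the downhill rate: k_up = k_down·exp(−Δε/k_BT).

    ``delta_e`` is the (non-negative) 0-0 energy gap in cm⁻¹.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    if delta_e < 0:
        raise ValueError(f"delta_e must be ≥ 0, got {delta_e}")
    return k_downhill * math.exp(-delta_e / (KB_WAVENUMBER_PER_K * temperature))


@dataclass
class RateMatrix:
    """First-order kinetic matrix over a pigment network.

    ``transfer[i, j]`` is the hop rate i→j in ps⁻¹ (zero diagonal);
    ``decay[i]`` the intrinsic depopulation rate of pigment i.
    """

    transfer: np.ndarray
    decay: np.ndarray
    labels: list[str]
    temperature: float = 300.0

    def __post_init__(self) -> None:
        self.transfer = np.asarray(self.transfer, dtype=float)
        self.decay = np.asarray(self.decay, dtype=float)
        n = len(self.labels)
        if self.transfer.shape != (n, n):
            raise ValueError(
                f"transfer matrix {self.transfer.shape} for {n} labels"
            )
        if self.decay.shape != (n,):
            raise ValueError(f"decay vector {self.decay.shape} for {n} labels")
        if np.any(self.transfer < 0) or np.any(self.decay < 0):
            raise ValueError("rates must be non-negative")
        if np.any(np.diag(self.transfer) != 0):
            raise ValueError("transfer diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def exit_rates(self) -> np.ndarray:
        """Total exit rate per pigment (decay + all hops out), ps⁻¹."""
        return self.decay + self.transfer.sum(axis=1)

    def generator(self) -> np.ndarray:
        """Master-equation generator K with dp/dt = K·p (columns = sources)."""
        K = self.transfer.T.copy()
        np.fill_diagonal(K, -self.exit_rates())
        return K

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.transfer, index=self.labels, columns=self.labels)
        df["__decay__"] = self.decay
        df.to_csv(path)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": self.labels,
            "temperature_K": self.temperature,
            "transfer_ps1": self.transfer.tolist(),
            "decay_ps1": self.decay.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_csv(
        cls, path: str | Path, temperature: float = 300.0
    ) -> "RateMatrix":
        df = pd.read_csv(path, index_col=0)
        decay = df.pop("__decay__").to_numpy(float)
        return cls(
            transfer=df.to_numpy(float),
            decay=decay,
            labels=[str(x) for x in df.index],
            temperature=temperature,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RateMatrix":
        payload = json.loads(Path(path).read_text())
        return cls(
            transfer=np.array(payload["transfer_ps1"]),
            decay=np.array(payload["decay_ps1"]),
            labels=list(payload["labels"]),
            temperature=float(payload["temperature_K"]),
        )


def pair_rates(
    e_donor: float,
    e_acceptor: float,
    coupling: float,
    donor_abs: LineShape,
    acceptor_abs: LineShape,
    temperature: float,
) -> tuple[float, float]:
    """Forward (donor→acceptor) and backward rates for one coupled pair.

    Both lineshapes are absorption templates; each is anchored at its
    pigment's 0-0 site energy, the downhill donor's emission is the mirror
    image of its absorption, and the uphill direction comes from detailed
    balance on the 0-0 gap.
    """
    if e_donor >= e_acceptor:
        down_em = mirror_emission(donor_abs.with_e00(e_donor))
        up_abs = acceptor_abs.with_e00(e_acceptor)
        k_down = forster_rate(coupling, spectral_overlap(down_em, up_abs))
        k_up = detailed_balance_pair(k_down, e_donor - e_acceptor, temperature)
        return k_down, k_up
    k_back, k_fwd = pair_rates(
        e_acceptor, e_donor, coupling, acceptor_abs, donor_abs, temperature
    )
    return k_fwd, k_back


def build_rate_matrix(
    network: PigmentNetwork,
    lineshapes: Mapping[str, LineShape],
    temperature: float = 300.0,
) -> RateMatrix:
    """Assemble the full transfer + decay rate matrix for a coupled network.

    Every pigment must carry a site energy, decay rate and lineshape id;
    uncoupled pairs get zero rate both ways.
    """
    for p in network.pigments:
        if p.site_energy is None or p.decay_rate is None:
            raise ConfigurationError(
                f"pigment {p.id}: site energy / decay rate not assigned"
            )
        if p.lineshape_id is None or p.lineshape_id not in lineshapes:
            raise ConfigurationError(
                f"pigment {p.id}: lineshape {p.lineshape_id!r} not available"
            )
    n = len(network.pigments)
    transfer = np.zeros((n, n))
    V = network.couplings
    for i in range(n):
        pi = network.pigments[i]
        for j in range(i + 1, n):
            if V[i, j] == 0.0:
                continue
            pj = network.pigments[j]
            k_ij, k_ji = pair_rates(
                pi.site_energy,
                pj.site_energy,
                V[i, j],
                lineshapes[pi.lineshape_id],
                lineshapes[pj.lineshape_id],
                temperature,
            )
            transfer[i, j] = k_ij
            transfer[j, i] = k_ji
    decay = np.array([p.decay_rate for p in network.pigments])
    return RateMatrix(
        transfer=transfer,
        decay=decay,
        labels=network.ids,
        temperature=temperature,
    )
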