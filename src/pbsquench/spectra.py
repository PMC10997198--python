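"""Parametric lineshapes and spectral overlap integrals.

A :class:`LineShape` is a sum of Gaussian vibronic components on a wavenumber
grid, normalized to unit area, so the overlap integral J of a donor emission
with an acceptor absorption carries units of cm.  Emission is constructed
from absorption by mirror reflection about the 0-0 energy.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from functools import lru_cache
from pathlib import Path

import numpy as np

from .errors import ConfigurationError


class ShapeKind(enum.Enum):
    ABSORPTION = "absorption"
    EMISSION = "emission"


@dataclass(frozen=True)
class LineShape:
    """Normalized vibronic band built from Gaussian components.

    ``components`` is a tuple of ``(offset, weight, sigma)`` triples, offset
    ≥ 0 in cm⁻¹ relative to the 0-0 energy ``e00``: absorption components sit
    at ``e00 + offset``, emission components at ``e00 - offset`` (mirror
    image).  ``grid`` is ``(min, max, step)`` in cm⁻¹; if omitted it is chosen
    to cover every component of both kinds to ±6σ.
    """

    kind: ShapeKind
    e00: float  # cm⁻¹
    components: tuple[tuple[float, float, float], ...]
    grid: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not self.components:
            raise ConfigurationError("lineshape needs at least one component")
        for off, w, sig in self.components:
            if off < 0:
                raise ConfigurationError(f"component offset {off} < 0")
            if w <= 0:
                raise ConfigurationError(f"component weight {w} ≤ 0")
            if sig <= 0:
                raise ConfigurationError(f"component width {sig} ≤ 0")
        if self.grid is None:
            lo, hi, step = self._auto_grid()
            object.__setattr__(self, "grid", (lo, hi, step))
        else:
            lo, hi, step = self.grid
            if step <= 0 or hi <= lo:
                raise ConfigurationError(f"invalid grid {self.grid}")
            self._check_coverage()

    def _auto_grid(self, step: float = 1.0) -> tuple[float, float, float]:
        span = max(off + 6.0 * sig for off, _, sig in self.components)
        lo = float(np.floor(self.e00 - span))
        hi = float(np.ceil(self.e00 + span))
        return lo, hi, step

    def _check_coverage(self) -> None:
        lo, hi, _ = self.grid
        for off, _, sig in self.components:
            center = self.e00 + off if self.kind is ShapeKind.ABSORPTION else self.e00 - off
            need_lo, need_hi = center - 5.0 * sig, center + 5.0 * sig
            if need_lo < lo or need_hi > hi:
                raise ConfigurationError(
                    f"grid [{lo}, {hi}] too narrow: component at {center} cm⁻¹ "
                    f"(σ={sig}) needs [{need_lo}, {need_hi}]"
                )

    def with_e00(self, e00: float) -> "LineShape":
        """Same band translated to a new 0-0 energy (grid moves with it)."""
        lo, hi, step = self.grid
        shift = e00 - self.e00
        return replace(self, e00=e00, grid=(lo + shift, hi + shift, step))

    def axis(self) -> np.ndarray:
        lo, hi, step = self.grid
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)


def evaluate(shape: LineShape) -> tuple[np.ndarray, np.ndarray]:
    """Sample a lineshape on its grid, normalized to unit trapezoidal area.

    Returns ``(nu, f)`` with ``nu`` in cm⁻¹ and ``f`` in cm (density per
    wavenumber).
    """
    nu = shape.axis()
    sign = 1.0 if shape.kind is ShapeKind.ABSORPTION else -1.0
    f = np.zeros_like(nu)
    for off, w, sig in shape.components:
        center = shape.e00 + sign * off
        f += w * np.exp(-0.5 * ((nu - center) / sig) ** 2) / (sig * np.sqrt(2 * np.pi))
    area = np.trapezoid(f, nu)
    return nu, f / area


def mirror_emission(absorption: LineShape) -> LineShape:
    """Emission lineshape as the mirror image of an absorption lineshape.

    The 0-0 energy and vibronic structure are preserved; offsets are applied
    below the 0-0 instead of above.
    """
    if absorption.kind is not ShapeKind.ABSORPTION:
        raise ConfigurationError("mirror_emission expects an ABSORPTION lineshape")
    return replace(absorption, kind=ShapeKind.EMISSION)


@lru_cache(maxsize=4096)
def spectral_overlap(donor_emission: LineShape, acceptor_absorption: LineShape) -> float:
    """Overlap integral J = ∫ f_D(ν) a_A(ν) dν of normalized spectra, in cm.

    Both profiles are normalized over their own grid; the product is
    integrated by the trapezoidal rule over the grid intersection.  Disjoint
    grids are an error (distinct from a genuinely vanishing overlap).
    """
    if donor_emission.kind is not ShapeKind.EMISSION:
        raise ConfigurationError("donor lineshape must be EMISSION")
    if acceptor_absorption.kind is not ShapeKind.ABSORPTION:
        raise ConfigurationError("acceptor lineshape must be ABSORPTION")
    d_lo, d_hi, d_step = donor_emission.grid
    a_lo, a_hi, a_step = acceptor_absorption.grid
    if abs(d_step - a_step) > 1e-12:
        raise ConfigurationError(
            f"grids have different steps ({d_step} vs {a_step} cm⁻¹)"
        )
    lo, hi = max(d_lo, a_lo), min(d_hi, a_hi)
    if hi <= lo:
        raise ConfigurationError(
            f"lineshape grids are disjoint ([{d_lo},{d_hi}] vs [{a_lo},{a_hi}])"
        )
    nu_d, f_d = evaluate(donor_emission)
    nu_a, f_a = evaluate(acceptor_absorption)
    # interpolate onto the common window (grids may be offset by < step)
    nu = np.arange(lo, hi + 0.5 * d_step, d_step)
    fd = np.interp(nu, nu_d, f_d, left=0.0, right=0.0)
    fa = np.interp(nu, nu_a, f_a, left=0.0, right=0.0)
    return float(np.trapezoid(fd * fa, nu))


def load_tabulated(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a two-column (wavenumber, intensity) text spectrum, normalized.

    Returned as arrays; parametric operations require :class:`LineShape`, so
    tabulated spectra serve direct overlap computation only.
    """
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ConfigurationError(f"{path}: expected two columns (wavenumber, intensity)")
    nu, f = data[:, 0], data[:, 1]
    if np.any(np.diff(nu) <= 0):
        order = np.argsort(nu)
        nu, f = nu[order], f[order]
    area = np.trapezoid(f, nu)
    if area <= 0:
        raise ConfigurationError(f"{path}: non-positive spectrum area")
    return nu, f / area
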