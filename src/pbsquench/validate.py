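"""Self-validation: fast internal consistency checks.

Each check recomputes one of the package's structural guarantees against an
independent route (analytic formula, eigen/matrix-exponential oracle, brute
force) at a reduced problem size and reports pass/fail with the seeds used.
Run via ``pbsquench validate`` or :func:`run_all`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants, couplings, kinetics
from .dynamics import gillespie_run, master_equation_survival
from .kinetics import RateMatrix, detailed_balance_pair, forster_rate
from .network import Pigment, PigmentClass, TransitionChargeSet


@dataclass
class CheckResult:
    name: str
    passed: bool
    detail: str
    seed: int | None = None


def check_forster_constant() -> CheckResult:
    k = forster_rate(1.0, 1.0)
    ok = k == constants.FORSTER_PREFACTOR == 1.18
    return CheckResult(
        "forster_constant", ok, f"k(V=1 cm⁻¹, J=1 cm) = {k} ps⁻¹"
    )


def check_tresp_pda_limit(separation: float = 50.0) -> CheckResult:
    """Two ±0.1e discretized dipoles (1 Å extent) vs the analytic point dipole."""
    q = 0.1
    d = 1.0
    a = TransitionChargeSet(
        "dipA", [[-d / 2, 0, 0], [d / 2, 0, 0]], [-q, q]
    )
    b = TransitionChargeSet(
        "dipB", [[-d / 2, 0, separation], [d / 2, 0, separation]], [-q, q]
    )
    v_tresp = couplings.tresp_coupling(a, b)
    mu = q * d * constants.DEBYE_PER_E_ANGSTROM
    pa = Pigment("a", PigmentClass.APCA_PCB, [0, 0, 0], [1, 0, 0], tdm_magnitude=mu)
    pb = Pigment("b", PigmentClass.APCA_PCB, [0, 0, separation], [1, 0, 0],
                 tdm_magnitude=mu)
    v_pda = couplings.point_dipole_coupling(pa, pb)
    rel = abs(v_tresp - v_pda) / abs(v_pda)
    return CheckResult(
        "tresp_pda_limit",
        rel < 0.01,
        f"TrEsp {v_tresp:.6f} vs PDA {v_pda:.6f} cm⁻¹ (rel err {rel:.2e})",
    )


def check_detailed_balance_equilibrium(seed: int = 7) -> CheckResult:
    """Closed 4-pigment network must relax to Boltzmann site-energy weights."""
    rng = np.random.default_rng(seed)
    energies = np.array([15000.0, 15200.0, 15400.0, 15800.0])
    temperature = 300.0
    n = 4
    transfer = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            hi, lo = (i, j) if energies[i] >= energies[j] else (j, i)
            k_down = float(rng.uniform(0.05, 1.0))
            transfer[hi, lo] = k_down
            transfer[lo, hi] = detailed_balance_pair(
                k_down, energies[hi] - energies[lo], temperature
            )
    rates = RateMatrix(transfer, np.zeros(n), [f"p{i}" for i in range(n)],
                       temperature)
    from .dynamics import master_equation_solve

    p = master_equation_solve(rates, np.array([1.0, 0, 0, 0]), [2.0e4])[0]
    beta = 1.0 / (constants.KB_WAVENUMBER_PER_K * temperature)
    boltz = np.exp(-beta * (energies - energies.min()))
    boltz /= boltz.sum()
    rel = float(np.max(np.abs(p - boltz) / boltz))
    return CheckResult(
        "detailed_balance_equilibrium",
        rel < 1e-6,
        f"max relative deviation from Boltzmann = {rel:.2e}",
        seed=seed,
    )


def check_gillespie_vs_master_equation(
    n_runs: int = 2000, seed: int = 11
) -> CheckResult:
    """Stochastic survival vs master equation on a random 5-pigment network."""
    rng = np.random.default_rng(seed)
    n = 5
    transfer = rng.uniform(0.0, 0.5, (n, n))
    np.fill_diagonal(transfer, 0.0)
    decay = rng.uniform(0.02, 0.2, n)
    rates = RateMatrix(transfer, decay, [f"p{i}" for i in range(n)])
    times = np.linspace(1.0, 30.0, 8)
    p0 = np.zeros(n)
    p0[0] = 1.0
    s_exact = master_equation_survival(rates, p0, times)
    decays = np.array(
        [gillespie_run(rates, 0, seed * 100003 + r).decay_time
         for r in range(n_runs)]
    )
    s_mc = (decays[None, :] > times[:, None]).mean(axis=1)
    sigma = np.sqrt(np.maximum(s_exact * (1 - s_exact), 1e-12) / n_runs)
    z = np.abs(s_mc - s_exact) / sigma
    return CheckResult(
        "gillespie_vs_master_equation",
        bool(np.all(z < 4.0)),
        f"max |z| over {times.size} checkpoints = {z.max():.2f} "
        f"({n_runs} trajectories)",
        seed=seed,
    )


def run_all() -> list[CheckResult]:
    return [
        check_forster_constant(),
        check_tresp_pda_limit(),
        check_detailed_balance_equilibrium(),
        check_gillespie_vs_master_equation(),
    ]
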