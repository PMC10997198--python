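"""Stochastic exciton dynamics and the master-equation oracle.

A single excitation performs a continuous-time Markov jump process on the
pigment network (Gillespie algorithm): from pigment i with total exit rate
Λᵢ the waiting time is Exponential(Λᵢ) and the channel — a hop or the
intrinsic decay — is chosen with probability proportional to its rate.
Ensembles of trajectories with per-run resampled carotenoid parameters give
the quenched fluorescence decay; the master equation dp/dt = K·p provides an
independent deterministic check.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .errors import ConfigurationError, NonTerminatingStateError
from .kinetics import RateMatrix, build_rate_matrix
from .network import PigmentClass, PigmentNetwork
from .spectra import LineShape


@dataclass
class Trajectory:
    """One stochastic exciton path: hops, decay time and terminal channel."""

    hops: list[tuple[float, int]]  # (time ps, pigment index), first is (0, start)
    decay_time: float
    terminal_index: int
    rng_seed: int

    def __post_init__(self) -> None:
        times = [t for t, _ in self.hops]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("hop times must be strictly increasing")
        if self.decay_time < times[-1]:
            raise ValueError("decay_time precedes the last hop")
        if self.terminal_index != self.hops[-1][1]:
            raise ValueError("terminal pigment must equal last occupied pigment")

    @property
    def n_hops(self) -> int:
        return len(self.hops) - 1


@dataclass
class DecayEnsemble:
    """A collection of trajectories plus the per-run sampled parameters."""

    trajectories: list[Trajectory]
    terminal_classes: list[PigmentClass]
    sampled_parameters: list[dict] = field(default_factory=list)
    config_hash: str = ""

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise ValueError("ensemble must contain at least one trajectory")
        if len(self.terminal_classes) != len(self.trajectories):
            raise ValueError("one terminal class per trajectory required")

    @property
    def decay_times(self) -> np.ndarray:
        return np.array([t.decay_time for t in self.trajectories])

    def write_decay_times_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "run": np.arange(len(self.trajectories)),
                "decay_time_ps": self.decay_times,
                "terminal_class": [c.value for c in self.terminal_classes],
                "rng_seed": [t.rng_seed for t in self.trajectories],
            }
        ).to_csv(path, index=False)


def _check_terminating(rates: RateMatrix, start_index: int) -> None:
    """Every pigment reachable from the start must have a positive exit rate."""
    exits = rates.exit_rates()
    n = rates.n
    seen = np.zeros(n, dtype=bool)
    stack = [start_index]
    seen[start_index] = True
    while stack:
        i = stack.pop()
        if exits[i] <= 0.0:
            raise NonTerminatingStateError(
                f"pigment {rates.labels[i]!r} is reachable but has zero exit rate"
            )
        for j in np.nonzero(rates.transfer[i] > 0)[0]:
            if not seen[j]:
                seen[j] = True
                stack.append(int(j))


def gillespie_run(
    rates: RateMatrix, start_index: int, seed: int
) -> Trajectory:
    """Simulate one exciton trajectory until its decay event.

    Exact stochastic simulation: exponential waiting times with the total
    exit rate, channel choice proportional to rates.  Bit-reproducible for a
    given seed.
    """
    n = rates.n
    if not 0 <= start_index < n:
        raise ValueError(f"start_index {start_index} out of range 0..{n - 1}")
    _check_terminating(rates, start_index)
    rng = np.random.default_rng(seed)
    # channel table per pigment: cumulative [decay, hop→0, ..., hop→n-1]
    channels = np.concatenate(
        [rates.decay[:, None], rates.transfer], axis=1
    ).cumsum(axis=1)
    exits = channels[:, -1]
    t = 0.0
    i = start_index
    hops: list[tuple[float, int]] = [(0.0, i)]
    while True:
        lam = exits[i]
        t += rng.exponential(1.0 / lam)
        u = rng.random() * lam
        ch = int(np.searchsorted(channels[i], u, side="right"))
        if ch == 0:
            return Trajectory(
                hops=hops, decay_time=t, terminal_index=i, rng_seed=seed
            )
        i = ch - 1
        hops.append((t, i))


def _run_seed(master_seed: int, run_index: int, stream: int) -> int:
    """Counter-based per-run seed derivation; independent, replayable."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(run_index, stream))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


CanSampler = Callable[[np.random.Generator, str], dict]
"""Draws one carotenoid parameter set for the named CAN pigment: a mapping
with keys ``e00_cm1`` (0-0 energy, cm⁻¹) and ``couplings``
({(can_id, pcb_id): cm⁻¹} for its whitelisted partners)."""


def run_ensemble(
    base_network: PigmentNetwork,
    can_sampler: CanSampler | None,
    lineshapes: Mapping[str, LineShape],
    n_runs: int,
    master_seed: int,
    temperature: float = 300.0,
) -> DecayEnsemble:
    """Ensemble of quenched-decay simulations with resampled CAN parameters.

    For each run the carotenoid S₁ energies and whitelisted couplings are
    drawn independently per CAN, the rate matrix is rebuilt, the exciton is
    started on a uniformly random rod bilin, and one Gillespie trajectory is
    generated with a per-run seed derived from ``master_seed``.

    The bilin–bilin block of the rate matrix does not depend on the sampled
    parameters and is computed once; only the CAN rows are rebuilt per run.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be ≥ 1")
    rod_idx = base_network.indices_of_class(PigmentClass.ROD_PCB)
    if rod_idx.size == 0:
        raise ConfigurationError("network has no ROD_PCB pigment to start from")
    can_idx = base_network.indices_of_class(PigmentClass.CAN)
    if can_idx.size > 0 and can_sampler is None:
        raise ConfigurationError("network contains CAN pigments but no sampler")

    base_rates = build_rate_matrix(base_network, lineshapes, temperature)
    id_to_index = {pid: k for k, pid in enumerate(base_network.ids)}

    trajectories: list[Trajectory] = []
    terminal_classes: list[PigmentClass] = []
    sampled_parameters: list[dict] = []
    from .kinetics import pair_rates  # local import avoids cycle at module load

    for run in range(n_runs):
        par_rng = np.random.default_rng(_run_seed(master_seed, run, 0))
        rates = base_rates
        record: dict = {"run": run, "can": []}
        if can_idx.size > 0:
            transfer = base_rates.transfer.copy()
            decay = base_rates.decay
            for ci in can_idx:
                can = base_network.pigments[ci]
                draw = can_sampler(par_rng, can.id)
                e_can = float(draw["e00_cm1"])
                if e_can <= 0:
                    raise ConfigurationError(
                        f"sampler returned non-physical CAN energy {e_can}"
                    )
                record["can"].append(
                    {"id": can.id, "e00_cm1": e_can,
                     "couplings_cm1": {f"{a}|{b}": v
                                       for (a, b), v in draw["couplings"].items()}}
                )
                transfer[ci, :] = 0.0
                transfer[:, ci] = 0.0
                for (can_id, pcb_id), v in draw["couplings"].items():
                    if can_id != can.id:
                        raise ConfigurationError(
                            f"sampler for {can.id} returned coupling for {can_id}"
                        )
                    pj = id_to_index[pcb_id]
                    pcb = base_network.pigments[pj]
                    k_cp, k_pc = pair_rates(
                        e_can,
                        pcb.site_energy,
                        float(v),
                        lineshapes[can.lineshape_id],
                        lineshapes[pcb.lineshape_id],
                        temperature,
                    )
                    transfer[ci, pj] = k_cp
                    transfer[pj, ci] = k_pc
            rates = RateMatrix(
                transfer=transfer,
                decay=decay,
                labels=base_rates.labels,
                temperature=temperature,
            )
        start = int(rod_idx[par_rng.integers(rod_idx.size)])
        traj = gillespie_run(rates, start, _run_seed(master_seed, run, 1))
        record["start_index"] = start
        trajectories.append(traj)
        terminal_classes.append(
            base_network.pigments[traj.terminal_index].pigment_class
        )
        sampled_parameters.append(record)

    digest = hashlib.sha256(
        json.dumps(
            {
                "master_seed": master_seed,
                "n_runs": n_runs,
                "temperature": temperature,
                "network": base_network.metadata,
            },
            sort_keys=True,
            default=str,
        ).encode()
    ).hexdigest()[:16]
    return DecayEnsemble(
        trajectories=trajectories,
        terminal_classes=terminal_classes,
        sampled_parameters=sampled_parameters,
        config_hash=digest,
    )


def survival_curve(
    ensemble: DecayEnsemble, time_grid: Sequence[float]
) -> np.ndarray:
    """Empirical survival P(t): fraction of trajectories alive past t."""
    grid = np.asarray(time_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("time grid must be non-empty")
    times = ensemble.decay_times
    return (times[None, :] > grid[:, None]).mean(axis=1)


@dataclass(frozen=True)
class LifetimeEstimate:
    """Mean excited-state lifetime with standard error and an exponential fit."""

    mean: float  # ps
    se: float  # ps
    n: int
    exp_fit: float  # ps, single-exponential (MLE = mean for exact decay times)


def mean_lifetime(ensemble: DecayEnsemble) -> LifetimeEstimate:
    """Arithmetic-mean decay time (= area under the empirical survival curve).

    The maximum-likelihood single-exponential time constant for fully
    observed decay times coincides with the mean; it is reported separately
    so censored or re-binned variants can diverge from it.
    """
    times = ensemble.decay_times
    n = times.size
    mean = float(times.mean())
    se = float(times.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return LifetimeEstimate(mean=mean, se=se, n=n, exp_fit=mean)


def quench_fraction(ensemble: DecayEnsemble) -> float:
    """Fraction of excitons whose terminal decay occurred on a carotenoid."""
    flags = [c is PigmentClass.CAN for c in ensemble.terminal_classes]
    return float(np.mean(flags))


def master_equation_solve(
    rates: RateMatrix, p0: Sequence[float], times: Sequence[float]
) -> np.ndarray:
    """Populations p(t) of dp/dt = K·p on a time grid (rows = times).

    Matrix-exponential propagation for networks up to 200 pigments, an
    implicit stiff ODE solver above that.
    """
    p0 = np.asarray(p0, dtype=float)
    times = np.asarray(times, dtype=float)
    if p0.shape != (rates.n,):
        raise ValueError(f"p0 has shape {p0.shape}, expected ({rates.n},)")
    if np.any(p0 < 0) or abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("p0 must be a probability vector")
    K = rates.generator()
    if rates.n <= 200:
        out = np.empty((times.size, rates.n))
        order = np.argsort(times)
        t_prev, p = 0.0, p0.copy()
        for idx in order:
            dt = times[idx] - t_prev
            if dt < 0:
                raise ValueError("times must be non-negative")
            if dt > 0:
                p = expm(K * dt) @ p
                t_prev = times[idx]
            out[idx] = p
        return out
    from scipy.integrate import solve_ivp

    sol = solve_ivp(
        lambda _, p: K @ p,
        (0.0, float(times.max())),
        p0,
        t_eval=times,
        method="Radau",
        rtol=1e-10,
        atol=1e-12,
    )
    return sol.y.T


def master_equation_survival(
    rates: RateMatrix, p0: Sequence[float], times: Sequence[float]
) -> np.ndarray:
    """Deterministic survival probability Σᵢ pᵢ(t)."""
    return master_equation_solve(rates, p0, times).sum(axis=1)


def master_equation_mean_lifetime(rates: RateMatrix, p0: Sequence[float]) -> float:
    """Mean decay time ∫S(t)dt = Σᵢ[(−K)⁻¹p0]ᵢ (requires a decaying network)."""
    K = rates.generator()
    occ = np.linalg.solve(-K, np.asarray(p0, dtype=float))
    return float(occ.sum())


def master_equation_channel_fractions(
    rates: RateMatrix, p0: Sequence[float]
) -> np.ndarray:
    """Probability of terminating through each pigment's decay channel.

    Time-integrated flux decayᵢ·∫pᵢ(t)dt; sums to 1 for a decaying network.
    """
    K = rates.generator()
    occ = np.linalg.solve(-K, np.asarray(p0, dtype=float))
    return rates.decay * occ
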