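"""End-to-end pipelines: extract → couple → rate → simulate → report."""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .couplings import (
    CanPcbMethod,
    build_coupling_matrix,
    coupling_matrix_to_csv,
    load_transition_charges,
)
from .dynamics import (
    DecayEnsemble,
    LifetimeEstimate,
    mean_lifetime,
    quench_fraction,
    run_ensemble,
    survival_curve,
)
from .errors import ConfigurationError
from .kinetics import build_rate_matrix
from .network import (
    PigmentClass,
    PigmentNetwork,
    assign_site_properties,
    read_structure,
)
from .synthetic import make_can_sampler, make_toy_pbs


def build_network(config: RunConfig) -> PigmentNetwork:
    """Materialize the pigment network a configuration describes.

    Toy input generates geometry, classes and couplings in one step; a
    structure file goes through extraction, per-class property assignment
    and coupling assembly (TrEsp from charge tables, or sampler means for
    the whitelisted carotenoid pairs).
    """
    if config.input_kind == "toy":
        return make_toy_pbs(config.toy, config.can_sampler, config.scheme)
    pigments = read_structure(config.structure_path, config.extraction)
    pigments = assign_site_properties(pigments, config.scheme)
    network = PigmentNetwork(
        pigments=pigments,
        metadata={"structure": str(config.structure_path)},
    )
    charges = None
    sampled = None
    if config.coupling.can_pcb_method == CanPcbMethod.TRESP:
        charges = {
            pid: load_transition_charges(path, pid)
            for pid, path in config.charge_tables.items()
        }
    else:
        # mean couplings from the sampler spec: (ApcA1, ApcA2) per CAN, in
        # whitelist order
        sampled = {}
        seen: dict[str, int] = {}
        for can_id, pcb_id in config.coupling.can_pcb_whitelist:
            k = seen.get(can_id, 0)
            means = config.can_sampler.coupling_means
            sampled[(can_id, pcb_id)] = means[min(k, len(means) - 1)]
            seen[can_id] = k + 1
    return build_coupling_matrix(network, config.coupling, charges, sampled)


def attachment_map(config: RunConfig, network: PigmentNetwork) -> dict:
    """CAN id → (partner₁, partner₂) from metadata or the coupling whitelist."""
    att = network.metadata.get("can_attachment")
    if att:
        return {k: tuple(v) for k, v in att.items()}
    grouped: dict[str, list[str]] = {}
    for can_id, pcb_id in config.coupling.can_pcb_whitelist:
        grouped.setdefault(can_id, []).append(pcb_id)
    bad = {k: v for k, v in grouped.items() if len(v) != 2}
    if bad:
        raise ConfigurationError(
            f"each CAN needs exactly two whitelisted partners, got {bad}"
        )
    return {k: (v[0], v[1]) for k, v in grouped.items()}


@dataclass
class SimulationResult:
    network: PigmentNetwork
    ensemble: DecayEnsemble
    lifetime: LifetimeEstimate
    quench_fraction: float
    time_grid: np.ndarray
    survival: np.ndarray
    output_dir: Path


def simulate(config: RunConfig, plot: bool = False) -> SimulationResult:
    """Run the full quenching simulation and write the output bundle."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    network = build_network(config)
    network.write_csv(outdir / "pigments.csv")
    coupling_matrix_to_csv(network, outdir / "couplings.csv")

    lineshapes = config.lineshapes()
    sim = config.simulation
    rates_mean = build_rate_matrix(network, lineshapes, sim.temperature_K)
    rates_mean.to_json(outdir / "rate_matrix_mean.json")
    rates_mean.to_csv(outdir / "rate_matrix_mean.csv")

    has_can = any(
        p.pigment_class is PigmentClass.CAN for p in network.pigments
    )
    sampler = (
        make_can_sampler(config.can_sampler, attachment_map(config, network))
        if has_can
        else None
    )
    ensemble = run_ensemble(
        network,
        sampler,
        lineshapes,
        n_runs=sim.n_runs,
        master_seed=sim.master_seed,
        temperature=sim.temperature_K,
    )
    ensemble.config_hash = chash
    ensemble.write_decay_times_csv(outdir / "decay_times.csv")

    t0, t1, dt = sim.time_grid_ps
    grid = np.arange(t0, t1 + 0.5 * dt, dt)
    surv = survival_curve(ensemble, grid)
    n = len(ensemble.trajectories)
    half_width = 1.96 * np.sqrt(np.maximum(surv * (1 - surv), 0.0) / n)
    pd.DataFrame(
        {
            "t_ps": grid,
            "P": surv,
            "CI_low": np.clip(surv - half_width, 0, 1),
            "CI_high": np.clip(surv + half_width, 0, 1),
        }
    ).to_csv(outdir / "survival.csv", index=False)

    life = mean_lifetime(ensemble)
    qf = quench_fraction(ensemble)
    manifest = {
        "config_hash": chash,
        "package_version": __version__,
        "python": platform.python_version(),
        "config": config.to_dict(),
        "n_pigments": len(network.pigments),
        "seeds": [t.rng_seed for t in ensemble.trajectories],
        "sampled_parameters": ensemble.sampled_parameters,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    summary = {
        "config_hash": chash,
        "mean_lifetime_ps": life.mean,
        "lifetime_se_ps": life.se,
        "exp_fit_lifetime_ps": life.exp_fit,
        "n_runs": life.n,
        "quench_fraction": qf,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))

    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(grid, surv, lw=1.5)
        ax.fill_between(grid, surv - half_width, surv + half_width, alpha=0.3)
        ax.set_xlabel("time (ps)")
        ax.set_ylabel("excited-state survival P(t)")
        ax.set_yscale("log")
        ax.set_ylim(max(1e-3, surv[surv > 0].min() if np.any(surv > 0) else 1e-3), 1.1)
        fig.tight_layout()
        fig.savefig(outdir / "survival.png", dpi=150)
        plt.close(fig)

    return SimulationResult(
        network=network,
        ensemble=ensemble,
        lifetime=life,
        quench_fraction=qf,
        time_grid=grid,
        survival=surv,
        output_dir=outdir,
    )
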