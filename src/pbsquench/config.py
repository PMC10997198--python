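"""Run configuration: a single YAML file drives the whole pipeline.

Every defaulted field is echoed back into the resolved configuration so the
run manifest records the complete parameter set, not just the user-supplied
subset.  Validation is collected and reported in one aggregated error.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .couplings import CanPcbMethod, CouplingRuleSet
from .errors import ConfigurationError
from .network import CofactorRule, PigmentClass, SiteProperties
from .spectra import LineShape, ShapeKind
from .synthetic import DEFAULT_SCHEME, CanParameterSpec, ToyPBSConfig

#: Default lineshape templates (offset cm⁻¹, weight, σ cm⁻¹ per component).
#: "pcb": bilin absorption, a 0-0 band with one vibronic satellite.
#: "can": surrogate carotenoid S₁ band — the true band shape is not measured
#: for canthaxanthin, so a generic keto-carotenoid vibronic progression
#: (0-0 plus satellites at ~1400 and ~2800 cm⁻¹) stands in.
DEFAULT_LINESHAPES: dict[str, tuple[tuple[float, float, float], ...]] = {
    "pcb": ((0.0, 1.0, 450.0), (1300.0, 0.4, 450.0)),
    "can": ((0.0, 1.0, 600.0), (1400.0, 0.7, 600.0), (2800.0, 0.3, 600.0)),
}


@dataclass
class SimulationBlock:
    n_runs: int = 100
    master_seed: int = 1
    temperature_K: float = 300.0
    time_grid_ps: tuple[float, float, float] = (0.0, 2000.0, 5.0)  # start, stop, step


@dataclass
class RunConfig:
    """Fully resolved pipeline configuration."""

    input_kind: str  # "toy" | "structure"
    structure_path: str | None
    extraction: dict[str, CofactorRule] | None
    toy: ToyPBSConfig
    scheme: dict[PigmentClass, SiteProperties]
    lineshape_components: dict[str, tuple[tuple[float, float, float], ...]]
    coupling: CouplingRuleSet
    #: pigment id → transition-charge table path (TrEsp mode only)
    charge_tables: dict[str, str]
    can_sampler: CanParameterSpec
    simulation: SimulationBlock
    output_dir: str = "pbsquench_out"

    def lineshapes(self) -> dict[str, LineShape]:
        """Absorption templates keyed by lineshape id, anchored at a nominal
        0-0 (re-anchored per pigment when rates are built)."""
        return {
            name: LineShape(ShapeKind.ABSORPTION, 15000.0, comps)
            for name, comps in self.lineshape_components.items()
        }

    def to_dict(self) -> dict:
        d: dict[str, Any] = {
            "input_kind": self.input_kind,
            "structure_path": self.structure_path,
            "extraction": None
            if self.extraction is None
            else {
                code: {
                    "class": rule.pigment_class.value,
                    "atoms": list(rule.conjugated_atoms),
                    "chain_classes": None
                    if rule.chain_classes is None
                    else {k: v.value for k, v in rule.chain_classes.items()},
                }
                for code, rule in self.extraction.items()
            },
            "toy": asdict(self.toy),
            "scheme": {
                cls.value: asdict(props) for cls, props in self.scheme.items()
            },
            "lineshapes": {
                k: [list(c) for c in v]
                for k, v in self.lineshape_components.items()
            },
            "coupling": {
                "can_pcb_method": self.coupling.can_pcb_method,
                "can_pcb_whitelist": [list(p) for p in self.coupling.can_pcb_whitelist],
                "screening_factor": self.coupling.screening_factor,
                "charge_tables": dict(self.charge_tables),
            },
            "can_sampler": {
                "e_s1_mean_ev": self.can_sampler.e_s1_mean,
                "e_s1_sd_ev": self.can_sampler.e_s1_sd,
                "coupling_means_cm1": list(self.can_sampler.coupling_means),
                "coupling_sds_cm1": list(self.can_sampler.coupling_sds),
                "distribution": self.can_sampler.distribution,
                "e00_shift_cm1": self.can_sampler.e00_shift_cm1,
            },
            "simulation": asdict(self.simulation),
            "output_dir": self.output_dir,
        }
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _parse_class(name: str, errors: list[str], where: str) -> PigmentClass | None:
    try:
        return PigmentClass(name)
    except ValueError:
        errors.append(f"{where}: unknown pigment class {name!r} "
                      f"(valid: {[c.value for c in PigmentClass]})")
        return None


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    errors: list[str] = []

    inp = raw.get("input", {}) or {}
    input_kind = inp.get("kind", "toy")
    if input_kind not in ("toy", "structure"):
        errors.append(f"input.kind must be 'toy' or 'structure', got {input_kind!r}")
    structure_path = inp.get("structure")
    if input_kind == "structure" and not structure_path:
        errors.append("input.kind is 'structure' but input.structure is missing")

    extraction = None
    if "extraction" in raw and raw["extraction"]:
        extraction = {}
        for code, entry in raw["extraction"].items():
            cls = _parse_class(entry.get("class", ""), errors, f"extraction.{code}")
            atoms = entry.get("atoms", [])
            if not atoms:
                errors.append(f"extraction.{code}: 'atoms' list is empty")
            chain_classes = None
            if entry.get("chain_classes"):
                chain_classes = {}
                for ch, cname in entry["chain_classes"].items():
                    c2 = _parse_class(cname, errors, f"extraction.{code}.chain_classes")
                    if c2:
                        chain_classes[str(ch)] = c2
            if cls:
                extraction[str(code)] = CofactorRule(
                    cls, tuple(atoms), chain_classes
                )
    elif input_kind == "structure":
        errors.append("structure input requires an 'extraction' section")

    toy_kwargs = dict(raw.get("toy", {}) or {})
    if "can_attachment" in toy_kwargs and toy_kwargs["can_attachment"]:
        toy_kwargs["can_attachment"] = {
            str(k): tuple(v) for k, v in toy_kwargs["can_attachment"].items()
        }
    try:
        toy = ToyPBSConfig(**toy_kwargs)
    except (TypeError, ConfigurationError) as exc:
        errors.append(f"toy: {exc}")
        toy = ToyPBSConfig()

    scheme: dict[PigmentClass, SiteProperties] = dict(DEFAULT_SCHEME)
    for cname, entry in (raw.get("scheme", {}) or {}).items():
        cls = _parse_class(cname, errors, "scheme")
        if cls is None:
            continue
        base = scheme.get(cls)
        try:
            scheme[cls] = SiteProperties(
                site_energy=float(entry.get("site_energy_cm1", base.site_energy)),
                decay_rate=float(entry.get("decay_ps1", base.decay_rate)),
                tdm_magnitude=float(entry.get("tdm_debye", base.tdm_magnitude)),
                lineshape_id=str(entry.get("lineshape", base.lineshape_id)),
            )
        except (TypeError, ValueError) as exc:
            errors.append(f"scheme.{cname}: {exc}")

    lineshape_components = {
        k: tuple(tuple(float(x) for x in c) for c in v)
        for k, v in (raw.get("lineshapes", {}) or {}).items()
    }
    for name, comps in DEFAULT_LINESHAPES.items():
        lineshape_components.setdefault(name, comps)
    for cls, props in scheme.items():
        if props.lineshape_id not in lineshape_components:
            errors.append(
                f"scheme.{cls.value}: lineshape {props.lineshape_id!r} undefined"
            )

    coup = raw.get("coupling", {}) or {}
    try:
        coupling = CouplingRuleSet(
            can_pcb_method=coup.get("can_pcb_method", CanPcbMethod.SAMPLED),
            can_pcb_whitelist=tuple(
                tuple(p) for p in coup.get("can_pcb_whitelist", [])
            ),
            screening_factor=float(coup.get("screening_factor", 1.0)),
        )
    except ConfigurationError as exc:
        errors.append(f"coupling: {exc}")
        coupling = CouplingRuleSet()
    charge_tables = {
        str(k): str(v) for k, v in (coup.get("charge_tables", {}) or {}).items()
    }
    if coupling.can_pcb_method == CanPcbMethod.TRESP:
        listed = set(charge_tables)
        for pair in coupling.can_pcb_whitelist:
            for pid in pair:
                if pid not in listed:
                    errors.append(
                        f"coupling: TrEsp mode needs a charge table for {pid!r}"
                    )

    samp = raw.get("can_sampler", {}) or {}
    try:
        can_sampler = CanParameterSpec(
            e_s1_mean=float(samp.get("e_s1_mean_ev", 2.00)),
            e_s1_sd=float(samp.get("e_s1_sd_ev", 0.07)),
            coupling_means=tuple(samp.get("coupling_means_cm1", (54.0, 27.0))),
            coupling_sds=(
                tuple(samp["coupling_sds_cm1"])
                if "coupling_sds_cm1" in samp
                else None
            ),
            distribution=samp.get("distribution", "truncated_normal"),
            e00_shift_cm1=float(samp.get("e00_shift_cm1", 1400.0)),
        )
    except ConfigurationError as exc:
        errors.append(f"can_sampler: {exc}")
        can_sampler = CanParameterSpec()

    sim = raw.get("simulation", {}) or {}
    try:
        simulation = SimulationBlock(
            n_runs=int(sim.get("n_runs", 100)),
            master_seed=int(sim.get("master_seed", 1)),
            temperature_K=float(sim.get("temperature_K", 300.0)),
            time_grid_ps=tuple(sim.get("time_grid_ps", (0.0, 2000.0, 5.0))),
        )
        if simulation.n_runs < 1:
            errors.append("simulation.n_runs must be ≥ 1")
        if simulation.temperature_K <= 0:
            errors.append("simulation.temperature_K must be > 0")
    except (TypeError, ValueError) as exc:
        errors.append(f"simulation: {exc}")
        simulation = SimulationBlock()

    if errors:
        bullet = "\n  - ".join(errors)
        raise ConfigurationError(f"invalid configuration {path}:\n  - {bullet}")

    return RunConfig(
        input_kind=input_kind,
        structure_path=structure_path,
        extraction=extraction,
        toy=toy,
        scheme=scheme,
        lineshape_components=lineshape_components,
        coupling=coupling,
        charge_tables=charge_tables,
        can_sampler=can_sampler,
        simulation=simulation,
        output_dir=str(raw.get("output", "pbsquench_out")),
    )
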