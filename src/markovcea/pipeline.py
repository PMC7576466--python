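"""Run configuration and end-to-end pipeline orchestration.

A :class:`RunConfig` (usually loaded from YAML) selects one of three modes:

``passthrough``
    drive the Markov engine directly with the packaged reference inputs
    (the headline reproduction path; no patient-level data needed);
``synthetic``
    generate a synthetic cohort, compute effectiveness statistics, cost the
    resource use, estimate the Markov inputs from the cohort, then run the
    engine and the sweeps;
``patient_data``
    as ``synthetic`` but reading cohort tables written by
    :func:`markovcea.cohort.write_cohort` from disk.

Every stage's outputs are written as delimited text under the run
directory, alongside a machine-readable ``summary.json`` and a ``run_log``
echoing the full effective configuration, so a run can be re-created from
its log alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, defaults
from .cohort import CohortConfig, generate_cohort, read_cohort, write_cohort
from .costing import UnitCosts, patient_perspective_costs
from .effectiveness import mean_change_ci
from .lifetable import LifeTable, load_life_table
from .markov import EconConfig
from .model import MarkovCohortModel
from .sensitivity import SweepSpec, one_way_sweep, threshold_verdict

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

MODES = ("passthrough", "synthetic", "patient_data")

#: Default sensitivity sweeps: intervention baseline-stage utility and the
#: per-state health-care costs of both arms, ±5% in 0.5% steps.
DEFAULT_SWEEPS = (
    SweepSpec("intervention.utility_baseline"),
    SweepSpec("both.state_costs"),
)


@dataclass
class RunConfig:
    """Complete, reproducible description of one pipeline run."""

    mode: str = "passthrough"
    seed: int = 0
    perspective: str = "healthcare"
    wtp: float = defaults.DEFAULT_WTP
    cohort: CohortConfig | None = None  # defaults to the packaged cohort config
    unit_costs: UnitCosts = field(default_factory=UnitCosts)
    econ: EconConfig = field(default_factory=EconConfig)
    sweeps: tuple = DEFAULT_SWEEPS
    life_table_path: str | None = None  # None -> packaged synthetic table
    cohort_path: str | None = None  # required for patient_data mode

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "patient_data" and not self.cohort_path:
            raise ValueError("patient_data mode requires cohort_path")


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML document.

    Recognized top-level keys: mode, seed, perspective, wtp,
    life_table_path, cohort_path, cohort (n_intervention/n_comparator),
    econ (EconConfig fields), unit_costs (UnitCosts fields), sweeps (list
    of SweepSpec fields).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    kwargs = {
        k: doc[k]
        for k in ("mode", "seed", "perspective", "wtp", "life_table_path", "cohort_path")
        if k in doc
    }
    if "econ" in doc:
        kwargs["econ"] = EconConfig(**doc["econ"])
    if "unit_costs" in doc:
        kwargs["unit_costs"] = UnitCosts(**doc["unit_costs"])
    if "cohort" in doc:
        c = doc["cohort"]
        kwargs["cohort"] = defaults.default_cohort_config(
            n_intervention=c.get("n_intervention", 98),
            n_comparator=c.get("n_comparator", 100),
            seed=doc.get("seed", 0),
        )
    if "sweeps" in doc:
        kwargs["sweeps"] = tuple(
            SweepSpec(
                parameter_path=s["parameter_path"],
                relative_range=tuple(s.get("relative_range", (-0.05, 0.05))),
                n_points=s.get("n_points", 11),
                wtp=s.get("wtp", doc.get("wtp", defaults.DEFAULT_WTP)),
            )
            for s in doc["sweeps"]
        )
    return RunConfig(**kwargs)


def _effectiveness_report(patients) -> pd.DataFrame:
    rows = []
    for arm in ("intervention", "comparator"):
        arm_p = [p for p in patients if p.arm == arm]
        for instrument in ("barthel", "iadl", "gds"):
            pre = [p.score(instrument, 0) for p in arm_p]
            post = [p.score(instrument, 1) for p in arm_p]
            s = mean_change_ci(pre, post, instrument=instrument)
            rows.append(
                {
                    "arm": arm,
                    "instrument": instrument,
                    "n": s.n,
                    "mean_change": s.mean_change,
                    "ci_low": s.ci_low,
                    "ci_high": s.ci_high,
                    "p_value": s.p_value,
                    "level": s.level,
                }
            )
    return pd.DataFrame(rows)


def _cost_report(patients, unit_costs: UnitCosts) -> pd.DataFrame:
    rows = []
    for p in patients:
        for perspective in ("healthcare", "societal"):
            c = patient_perspective_costs(p, unit_costs, perspective)
            rows.append(
                {
                    "patient_id": p.id,
                    "arm": p.arm,
                    "perspective": perspective,
                    "contact_cost": c.contact_cost,
                    "hospital_cost": c.hospital_cost,
                    "time_cost": c.time_cost,
                    "travel_cost": c.travel_cost,
                    "total": c.total,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the configured stages and write all artifacts to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    life_table = (
        load_life_table(config.life_table_path)
        if config.life_table_path
        else LifeTable.packaged_synthetic()
    )

    stage = "setup"
    try:
        patients = None
        if config.mode == "synthetic":
            stage = "cohort generation"
            cohort_cfg = config.cohort or defaults.default_cohort_config(seed=config.seed)
            if config.cohort is None:
                cohort_cfg = dataclasses.replace(cohort_cfg, seed=config.seed)
            patients = generate_cohort(cohort_cfg)
            write_cohort(patients, outdir / "cohort")
        elif config.mode == "patient_data":
            stage = "cohort loading"
            patients = read_cohort(config.cohort_path)

        if patients is not None:
            stage = "effectiveness"
            _effectiveness_report(patients).to_csv(outdir / "effectiveness.csv", index=False)
            stage = "costing"
            _cost_report(patients, config.unit_costs).to_csv(outdir / "costs.csv", index=False)
            stage = "markov"
            model = MarkovCohortModel.from_cohort(
                patients,
                unit_costs=config.unit_costs,
                perspective=config.perspective,
                econ=config.econ,
                life_table=life_table,
            )
        else:
            stage = "markov"
            model = MarkovCohortModel.from_reference_inputs(
                perspective=config.perspective, econ=config.econ, life_table=life_table
            )

        results = model.fit(wtp=config.wtp)
        results.trace_intervention.trace.to_csv(outdir / "trace_intervention.csv", index=False)
        results.trace_comparator.trace.to_csv(outdir / "trace_comparator.csv", index=False)

        stage = "sensitivity"
        sweep_summaries = []
        for i, spec in enumerate(config.sweeps):
            sweep = one_way_sweep(model, spec)
            name = spec.parameter_path.replace(".", "_")
            sweep.grid.to_csv(outdir / f"sweep_{i}_{name}.csv", index=False)
            sweep_summaries.append(
                {
                    "parameter_path": spec.parameter_path,
                    "max_icer": sweep.max_icer,
                    "all_below_wtp": sweep.all_below_wtp,
                    "verdict_at_wtp": threshold_verdict(sweep),
                }
            )

        stage = "reporting"
        summary = {
            "mode": config.mode,
            "perspective": config.perspective,
            "seed": config.seed,
            "wtp": config.wtp,
            "qalys_intervention": results.cea.qalys_intervention,
            "qalys_comparator": results.cea.qalys_comparator,
            "costs_intervention": results.cea.costs_intervention,
            "costs_comparator": results.cea.costs_comparator,
            "delta_cost": results.delta_cost,
            "delta_effect": results.delta_effect,
            "icer": results.icer,
            "dominance": results.dominance,
            "nmb": results.nmb(),
            "sweeps": sweep_summaries,
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        (outdir / "summary.txt").write_text(results.summary() + "\n")

        run_log = {
            "markovcea_version": __version__,
            "config": _config_to_dict(config),
        }
        (outdir / "run_log.yaml").write_text(
            yaml.safe_dump(run_log, sort_keys=True, default_flow_style=False)
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outdir


def _config_to_dict(config: RunConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple, set)):
            return [convert(v) for v in obj]
        return obj

    return convert(
        {
            "mode": config.mode,
            "seed": config.seed,
            "perspective": config.perspective,
            "wtp": config.wtp,
            "life_table_path": config.life_table_path,
            "cohort_path": config.cohort_path,
            "unit_costs": config.unit_costs,
            "econ": config.econ,
            "sweeps": list(config.sweeps),
            "cohort": config.cohort,
        }
    )
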