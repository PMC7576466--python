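"""Model/Results interface for the cost-utility analysis.

:class:`MarkovCohortModel` bundles the two arm parameterizations, the
economic settings and a life table; ``fit()`` runs the cohort model for
both arms and returns :class:`CEAResults` with the incremental economics,
per-cycle traces, a ``summary()`` table, and hooks for sensitivity
analysis and plotting.

Constructors
------------
``MarkovCohortModel(intervention, comparator, econ, life_table)``
    direct parameterization.
``MarkovCohortModel.from_reference_inputs(...)``
    the packaged published input block (pass-through mode — the headline
    reproduction path when no patient-level data exist).
``MarkovCohortModel.from_cohort(patients, ...)``
    estimates transition probabilities, utilities and state costs from a
    patient-level cohort (synthetic or loaded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import defaults
from .cohort import Patient
from .costing import UnitCosts, state_conditional_costs
from .effectiveness import (
    UtilityMap,
    classify_transition,
    estimate_transition_probs,
    map_barthel_to_utility,
)
from .lifetable import LifeTable
from .markov import (
    CEAResult,
    EconConfig,
    MarkovArm,
    MarkovTrace,
    ProgramCosts,
    compare_arms,
    nmb,
    run_arm,
)

__all__ = ["MarkovCohortModel", "CEAResults"]


class MarkovCohortModel:
    """Three-state Markov cohort cost-utility model of two study arms."""

    def __init__(
        self,
        intervention: MarkovArm,
        comparator: MarkovArm,
        econ: EconConfig | None = None,
        life_table: LifeTable | None = None,
        perspective: str = "healthcare",
    ) -> None:
        self.intervention = intervention
        self.comparator = comparator
        self.econ = econ or EconConfig()
        self.life_table = life_table or LifeTable.packaged_synthetic()
        self.perspective = perspective

    # ------------------------------------------------------------ builders
    @classmethod
    def from_reference_inputs(
        cls,
        perspective: str = "healthcare",
        econ: EconConfig | None = None,
        life_table: LifeTable | None = None,
    ) -> "MarkovCohortModel":
        """Model driven directly by the packaged published input block."""
        arms = defaults.default_markov_arms(perspective)
        return cls(arms["intervention"], arms["comparator"], econ, life_table, perspective)

    @classmethod
    def from_cohort(
        cls,
        patients: list[Patient],
        instrument: str = "barthel",
        worsening_threshold: float = 0.0,
        utility_map: UtilityMap | None = None,
        unit_costs: UnitCosts | None = None,
        program: ProgramCosts | None = None,
        perspective: str = "healthcare",
        econ: EconConfig | None = None,
        life_table: LifeTable | None = None,
    ) -> "MarkovCohortModel":
        """Estimate the arm parameterizations from patient-level data.

        Incidence/recovery come from the worsened fraction per arm; state
        utilities from the mean follow-up Barthel score within each stage
        stratum mapped through ``utility_map``; state costs from the mean
        annualized per-patient costs within each stratum.  An empty
        deteriorated (or baseline) stratum falls back on the other
        stratum's values.
        """
        utility_map = utility_map or UtilityMap()
        unit_costs = unit_costs or UnitCosts()
        program = program or ProgramCosts(
            defaults.MARKOV_REFERENCE_INPUTS["intervention"]["one_off"],
            defaults.MARKOV_REFERENCE_INPUTS["intervention"]["recurring"],
        )
        arms = {}
        for arm_name in ("intervention", "comparator"):
            arm_patients = [p for p in patients if p.arm == arm_name]
            if not arm_patients:
                raise ValueError(f"no patients in arm {arm_name!r}")
            trans = estimate_transition_probs(arm_patients, instrument, worsening_threshold)
            classification = {
                p.id: classify_transition(p, instrument, worsening_threshold)
                for p in arm_patients
            }
            # utilities: mean follow-up Barthel within each stratum
            final_scores = {"baseline": [], "deteriorated": []}
            for p in arm_patients:
                state = "deteriorated" if classification[p.id] == "worsened" else "baseline"
                final_scores[state].append(p.score("barthel", 1))
            utilities = {}
            for state, vals in final_scores.items():
                if utility_map.mode == "direct":
                    utilities[state] = map_barthel_to_utility(0, utility_map, state=state)
                elif vals:
                    utilities[state] = map_barthel_to_utility(
                        float(np.mean(vals)), utility_map, state=state
                    )
                else:
                    utilities[state] = None
            costs = state_conditional_costs(arm_patients, classification, unit_costs, perspective)
            # fall back across strata when one is empty
            u_b = utilities["baseline"] if utilities["baseline"] is not None else utilities["deteriorated"]
            u_d = utilities["deteriorated"] if utilities["deteriorated"] is not None else utilities["baseline"]
            c_b = costs["baseline"]["mean_cost"]
            c_d = costs["deteriorated"]["mean_cost"]
            c_b = c_b if c_b is not None else c_d
            c_d = c_d if c_d is not None else c_b
            arms[arm_name] = MarkovArm(
                name=arm_name,
                incidence=trans.incidence,
                recovery=trans.recovery,
                utility_baseline=u_b,
                utility_deteriorated=u_d,
                cost_baseline=c_b or 0.0,
                cost_deteriorated=c_d or 0.0,
                program=program if arm_name == "intervention" else ProgramCosts(),
            )
        return cls(arms["intervention"], arms["comparator"], econ, life_table, perspective)

    # ---------------------------------------------------------------- fit
    def fit(self, wtp: float = defaults.DEFAULT_WTP) -> "CEAResults":
        """Run both arms and return the incremental cost-utility results."""
        trace_int = run_arm(self.intervention, self.econ, self.life_table)
        trace_comp = run_arm(self.comparator, self.econ, self.life_table)
        cea = compare_arms(trace_int, trace_comp, wtp=wtp)
        return CEAResults(model=self, cea=cea, trace_intervention=trace_int,
                          trace_comparator=trace_comp, wtp=wtp)

    def replace_param(self, path: str, value: float) -> "MarkovCohortModel":
        """A copy of the model with one arm parameter replaced.

        ``path`` is ``'<arm>.<field>'`` with arm in {intervention,
        comparator} and field a numeric :class:`MarkovArm` attribute.
        """
        arm_name, _, attr = path.partition(".")
        if arm_name not in ("intervention", "comparator") or not attr:
            raise ValueError(f"cannot resolve parameter path {path!r}")
        arm = getattr(self, arm_name)
        if not hasattr(arm, attr):
            raise ValueError(f"cannot resolve parameter path {path!r}")
        new_arm = arm.replace(**{attr: value})
        kwargs = {"intervention": self.intervention, "comparator": self.comparator}
        kwargs[arm_name] = new_arm
        return MarkovCohortModel(kwargs["intervention"], kwargs["comparator"],
                                 self.econ, self.life_table, self.perspective)


@dataclass
class CEAResults:
    """Fitted cost-utility results for an intervention/comparator pair."""

    model: MarkovCohortModel
    cea: CEAResult
    trace_intervention: MarkovTrace
    trace_comparator: MarkovTrace
    wtp: float

    # convenience accessors -------------------------------------------------
    @property
    def delta_cost(self) -> float:
        return self.cea.delta_cost

    @property
    def delta_effect(self) -> float:
        return self.cea.delta_effect

    @property
    def icer(self) -> float | None:
        return self.cea.icer

    @property
    def dominance(self) -> str:
        return self.cea.dominance

    def nmb(self, wtp: float | None = None) -> float:
        return nmb(self.delta_cost, self.delta_effect, self.wtp if wtp is None else wtp)

    def to_frame(self) -> pd.DataFrame:
        """Per-arm totals and incremental results as a tidy frame."""
        rows = [
            {"quantity": "discounted QALYs", "intervention": self.cea.qalys_intervention,
             "comparator": self.cea.qalys_comparator, "incremental": self.delta_effect},
            {"quantity": "discounted costs (EUR)", "intervention": self.cea.costs_intervention,
             "comparator": self.cea.costs_comparator, "incremental": self.delta_cost},
        ]
        return pd.DataFrame(rows).set_index("quantity")

    def summary(self) -> str:
        """Human-readable summary table (EUR to 2 decimals, QALYs to 3)."""
        e = self.model.econ
        icer_txt = "undefined" if self.icer is None else f"{self.icer:,.2f} EUR/QALY"
        lines = [
            "      Markov Cohort Cost-Utility Results",
            "=" * 56,
            f"Perspective:        {self.model.perspective}",
            f"Horizon:            {e.horizon} annual cycles",
            f"Discounting:        {e.discount_effects:.1%} effects / {e.discount_costs:.1%} costs",
            f"Entry profile:      age {e.start_age}, {e.sex_mix:.0%} female",
            "-" * 56,
            f"{'':22s}{'Intervention':>16s}{'Comparator':>16s}",
            f"{'Discounted QALYs':22s}{self.cea.qalys_intervention:>16.3f}"
            f"{self.cea.qalys_comparator:>16.3f}",
            f"{'Discounted costs (EUR)':22s}{self.cea.costs_intervention:>16.2f}"
            f"{self.cea.costs_comparator:>16.2f}",
            "-" * 56,
            f"Incremental effect: {self.delta_effect:.3f} QALYs",
            f"Incremental cost:   {self.delta_cost:,.2f} EUR",
            f"ICER:               {icer_txt}",
            f"Dominance class:    {self.dominance}",
            f"NMB @ {self.wtp:,.0f} EUR/QALY: {self.nmb():,.2f} EUR",
            "=" * 56,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        icer_txt = "undefined" if self.icer is None else f"{self.icer:.2f}"
        return (f"<CEAResults ΔC={self.delta_cost:.2f} ΔE={self.delta_effect:.4f} "
                f"ICER={icer_txt}>")
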