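"""Three-state Markov cohort engine for cost-utility analysis.

States are *baseline disease stage*, *deteriorated disease stage*, and
*dead*.  Each cycle (1 year) a cohort member may die with an age- and
sex-specific probability scaled by a state-specific mortality relative risk,
otherwise move baseline→deteriorated with probability ``incidence`` or
deteriorated→baseline with probability ``recovery``.  Utilities (QALY
weights) and annual state costs accrue on end-of-cycle occupancy and are
discounted; an optional half-cycle correction averages start- and
end-of-cycle occupancy instead.

Transition ordering: death competes first, then stage transitions among
survivors.  The mortality relative risk acts on the hazard scale,
``p = 1 - (1 - qx)**rr``, which keeps probabilities valid for any rr > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lifetable import LifeTable

__all__ = [
    "ProgramCosts",
    "MarkovArm",
    "EconConfig",
    "MarkovTrace",
    "CEAResult",
    "annual_death_prob",
    "run_arm",
    "compare_arms",
    "nmb",
    "icer",
    "closed_form_dly",
]


@dataclass(frozen=True)
class ProgramCosts:
    """Intervention programme costs in euros.

    ``one_off_per_patient`` is charged once at model start (undiscounted);
    ``recurring_per_patient_year`` is charged each cycle to the fraction of
    the cohort still alive.
    """

    one_off_per_patient: float = 0.0
    recurring_per_patient_year: float = 0.0

    def __post_init__(self) -> None:
        for name in ("one_off_per_patient", "recurring_per_patient_year"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class MarkovArm:
    """Full economic parameterization of one study arm.

    Parameters
    ----------
    incidence, recovery : float
        Per-cycle probabilities of baseline→deteriorated and
        deteriorated→baseline transitions among survivors.
    rr_baseline, rr_deteriorated : float
        Mortality relative risks applied on the hazard scale.
    utility_baseline, utility_deteriorated : float
        QALY weights in [0, 1].
    cost_baseline, cost_deteriorated : float
        Annual state costs in € per patient-year (perspective-specific).
    program : ProgramCosts
        One-off and recurring intervention costs (zero for a comparator).
    """

    name: str
    incidence: float
    recovery: float
    utility_baseline: float
    utility_deteriorated: float
    cost_baseline: float
    cost_deteriorated: float
    rr_baseline: float = 1.005
    rr_deteriorated: float = 1.005
    program: ProgramCosts = field(default_factory=ProgramCosts)

    def __post_init__(self) -> None:
        for name in ("incidence", "recovery", "utility_baseline", "utility_deteriorated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("rr_baseline", "rr_deteriorated"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("cost_baseline", "cost_deteriorated"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **kw) -> "MarkovArm":
        return replace(self, **kw)


@dataclass(frozen=True)
class EconConfig:
    """Economic evaluation settings.

    Discount rates default to 3% for both effects and costs; the horizon is
    40 annual cycles; the cohort enters 100% in the baseline stage at
    ``start_age`` with a fraction ``sex_mix`` female.
    """

    discount_effects: float = 0.03
    discount_costs: float = 0.03
    horizon: int = 40
    start_age: int = 84
    sex_mix: float = 0.65
    start_state: float = 1.0
    half_cycle_correction: bool = False
    cycle_length: float = 1.0  # years; fixed at 1

    def __post_init__(self) -> None:
        if self.discount_effects < 0 or self.discount_costs < 0:
            raise ValueError("discount rates must be >= 0")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1 cycle")
        if not 0.0 <= self.sex_mix <= 1.0:
            raise ValueError("sex_mix must be in [0, 1]")
        if not 0.0 <= self.start_state <= 1.0:
            raise ValueError("start_state must be in [0, 1]")
        if self.cycle_length != 1.0:
            raise ValueError("cycle_length is fixed at 1 year")


@dataclass
class MarkovTrace:
    """Per-cycle state occupancy and cumulative discounted rewards."""

    arm: str
    trace: pd.DataFrame  # cycle, baseline, deteriorated, dead, disc_qaly, disc_cost
    total_qalys: float
    total_costs: float
    life_years: float


@dataclass
class CEAResult:
    """Incremental cost-effectiveness comparison of two arms."""

    qalys_intervention: float
    qalys_comparator: float
    costs_intervention: float
    costs_comparator: float
    delta_cost: float
    delta_effect: float
    icer: float | None
    dominance: str  # 'icer', 'dominant', 'dominated', 'undefined'
    wtp: float
    nmb: float
    label: str = "base case"


def annual_death_prob(age: float, sex: str, life_table: LifeTable, rr: float = 1.0) -> float:
    """Hazard-scaled annual death probability ``1 - (1 - qx)**rr``.

    Ages beyond the table clamp to the terminal row, where qx = 1.
    """
    if rr <= 0:
        raise ValueError(f"rr must be > 0, got {rr}")
    qx = life_table.qx(age, sex)
    if rr == 1.0:
        return qx
    return 1.0 - (1.0 - qx) ** rr


def _run_one_sex(arm: MarkovArm, econ: EconConfig, life_table: LifeTable, sex: str) -> pd.DataFrame:
    """Cohort trace for a single sex; columns per cycle 0..horizon."""
    T = econ.horizon
    occ = np.zeros((T + 1, 3))  # baseline, deteriorated, dead
    occ[0, 0] = econ.start_state
    occ[0, 1] = 1.0 - econ.start_state
    for t in range(1, T + 1):
        age = econ.start_age + (t - 1)  # age during cycle t
        pd_b = annual_death_prob(age, sex, life_table, arm.rr_baseline)
        pd_d = annual_death_prob(age, sex, life_table, arm.rr_deteriorated)
        b, d, z = occ[t - 1]
        b_surv = b * (1.0 - pd_b)
        d_surv = d * (1.0 - pd_d)
        occ[t, 0] = b_surv * (1.0 - arm.incidence) + d_surv * arm.recovery
        occ[t, 1] = b_surv * arm.incidence + d_surv * (1.0 - arm.recovery)
        occ[t, 2] = z + b * pd_b + d * pd_d
    return pd.DataFrame(occ, columns=["baseline", "deteriorated", "dead"])


def run_arm(arm: MarkovArm, econ: EconConfig, life_table: LifeTable) -> MarkovTrace:
    """Run the cohort model for one arm and accumulate discounted rewards.

    Rewards accrue on end-of-cycle occupancy discounted by ``(1+r)**-t`` for
    cycles t = 1..horizon (with the half-cycle correction, on the average of
    start- and end-of-cycle occupancy).  The one-off programme cost is
    charged undiscounted at t = 0; the recurring cost is charged per cycle
    to the alive fraction and discounted like state costs.
    """
    if econ.start_age > life_table.max_age:
        raise ValueError(
            f"start_age {econ.start_age} exceeds life-table max age {life_table.max_age}"
        )
    parts = []
    weights = []
    if econ.sex_mix > 0:
        parts.append(_run_one_sex(arm, econ, life_table, "F"))
        weights.append(econ.sex_mix)
    if econ.sex_mix < 1:
        parts.append(_run_one_sex(arm, econ, life_table, "M"))
        weights.append(1.0 - econ.sex_mix)
    occ = sum(w * p.to_numpy() for w, p in zip(weights, parts))

    T = econ.horizon
    t = np.arange(T + 1)
    ve = (1.0 + econ.discount_effects) ** (-t.astype(float))
    vc = (1.0 + econ.discount_costs) ** (-t.astype(float))

    if econ.half_cycle_correction:
        reward_occ = np.vstack([occ[0], 0.5 * (occ[:-1] + occ[1:])])
    else:
        reward_occ = occ  # end-of-cycle occupancy; row 0 earns nothing

    alive = reward_occ[:, 0] + reward_occ[:, 1]
    qaly_cycle = reward_occ[:, 0] * arm.utility_baseline + reward_occ[:, 1] * arm.utility_deteriorated
    cost_cycle = (
        reward_occ[:, 0] * arm.cost_baseline
        + reward_occ[:, 1] * arm.cost_deteriorated
        + alive * arm.program.recurring_per_patient_year
    )
    qaly_cycle = qaly_cycle * ve
    cost_cycle = cost_cycle * vc
    ly_cycle = alive * ve
    # cycle 0 accrues no per-cycle rewards; only the one-off cost
    qaly_cycle[0] = cost_cycle[0] = ly_cycle[0] = 0.0
    cost_cycle[0] += arm.program.one_off_per_patient

    df = pd.DataFrame(occ, columns=["baseline", "deteriorated", "dead"])
    df.insert(0, "cycle", t)
    df["disc_qaly"] = np.cumsum(qaly_cycle)
    df["disc_cost"] = np.cumsum(cost_cycle)
    df["disc_life_years"] = np.cumsum(ly_cycle)
    return MarkovTrace(
        arm=arm.name,
        trace=df,
        total_qalys=float(df["disc_qaly"].iloc[-1]),
        total_costs=float(df["disc_cost"].iloc[-1]),
        life_years=float(df["disc_life_years"].iloc[-1]),
    )


def nmb(delta_cost: float, delta_effect: float, wtp: float) -> float:
    """Net monetary benefit ``wtp * delta_effect - delta_cost``."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return wtp * delta_effect - delta_cost


def icer(delta_cost: float, delta_effect: float) -> float | None:
    """ΔCost/ΔEffect, or None when ΔEffect is zero (ratio undefined)."""
    if delta_effect == 0:
        return None
    return delta_cost / delta_effect


def compare_arms(
    trace_int: MarkovTrace,
    trace_comp: MarkovTrace,
    wtp: float = 15000.0,
    label: str = "base case",
) -> CEAResult:
    """Incremental analysis of intervention vs comparator traces.

    Dominance classes follow the cost-effectiveness plane quadrants:
    cheaper and more effective → *dominant*; costlier and less effective →
    *dominated*; otherwise the ICER is reported.  ΔEffect = 0 leaves the
    ICER undefined (NMB is still defined).
    """
    dc = trace_int.total_costs - trace_comp.total_costs
    de = trace_int.total_qalys - trace_comp.total_qalys
    if de == 0:
        dom, ratio = "undefined", None
    elif de > 0 and dc <= 0:
        dom, ratio = "dominant", icer(dc, de)
    elif de < 0 and dc >= 0:
        dom, ratio = "dominated", icer(dc, de)
    else:
        dom, ratio = "icer", icer(dc, de)
    return CEAResult(
        qalys_intervention=trace_int.total_qalys,
        qalys_comparator=trace_comp.total_qalys,
        costs_intervention=trace_int.total_costs,
        costs_comparator=trace_comp.total_costs,
        delta_cost=dc,
        delta_effect=de,
        icer=ratio,
        dominance=dom,
        wtp=wtp,
        nmb=nmb(dc, de, wtp),
        label=label,
    )


def closed_form_dly(survival_per_cycle: float, discount: float, horizon: int) -> float:
    """Discounted life-years under constant per-cycle survival.

    Equals ``sum_{t=1..T} (s*v)**t`` with ``v = 1/(1+discount)``; the
    geometric closed form ``s*v*(1-(s*v)**T)/(1-s*v)`` is used, with the
    ``s*v = 1`` case handled as the limit T.
    """
    if not 0.0 <= survival_per_cycle <= 1.0:
        raise ValueError("survival must be in [0, 1]")
    sv = survival_per_cycle / (1.0 + discount)
    if math.isclose(sv, 1.0, rel_tol=0, abs_tol=1e-15):
        return float(horizon)
    return sv * (1.0 - sv**horizon) / (1.0 - sv)
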