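"""Monetization of resource use under health-care and societal perspectives.

Professional contact time is costed at average hourly wages (2016 euros,
with employer social-security contributions), hospital stays at a national
cost per bed-day, and patient/caregiver time at the minimum
inter-professional wage.  All costs are homogenized to € per patient-year.

The health-care perspective covers professional contacts and hospital bed
days.  The societal perspective additionally monetizes, for intervention
patients, the time they spend operating the telehealth platform, and, for
comparator patients, the travel time and out-of-pocket travel cost of
attended out-of-home contacts (the intervention is assumed to avoid these).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import AdmissionRecord, ContactRecord, Patient
from .markov import ProgramCosts

__all__ = [
    "UnitCosts",
    "ProgramCosts",
    "PerspectiveCosts",
    "contact_cost",
    "hospital_cost",
    "citizen_time_cost",
    "annualize",
    "patient_perspective_costs",
    "state_conditional_costs",
    "arm_program_costs",
]

PERSPECTIVES = ("healthcare", "societal")

#: Assumed contact durations in hours by setting; the source resource-use
#: data count contacts but not minutes, so these ship as documented
#: assumptions and are fully configurable.
DEFAULT_CONTACT_DURATIONS = {
    "out_of_home": 0.33,
    "home_visit": 0.75,
    "telephone": 0.17,
    "writing": 0.08,
    "other": 0.25,
}

#: Wage class used for each professional category. Specialists are costed
#: at the physician wage and "other health care provider" at the nurse wage
#: (no separate wages are available); volunteer care is unmonetized.
WAGE_CLASS = {
    "GP": "physician",
    "specialist": "physician",
    "nurse": "nurse",
    "other_health": "nurse",
    "social_worker": "social",
    "volunteer": None,
}


@dataclass(frozen=True)
class UnitCosts:
    """Unit costs in 2016 euros.

    Wages are € per hour of professional time; ``wage_citizen`` prices
    patient and informal-caregiver time at the 2016 minimum
    inter-professional wage.  ``bed_day`` is the national cost per hospital
    bed-day.
    """

    wage_physician: float = 29.23
    wage_nurse: float = 20.79
    wage_social: float = 18.19
    wage_citizen: float = 6.07
    bed_day: float = 733.56
    currency_year: int = 2016
    contact_duration_defaults: dict = field(
        default_factory=lambda: dict(DEFAULT_CONTACT_DURATIONS)
    )
    travel_time_per_contact: float = 0.5  # hours, comparator out-of-home contacts
    travel_cost_per_contact: float = 0.0  # € out-of-pocket per such contact
    platform_hours_per_year: float = 47.5  # intervention patients' device time

    def __post_init__(self) -> None:
        for name in (
            "wage_physician",
            "wage_nurse",
            "wage_social",
            "wage_citizen",
            "bed_day",
            "travel_time_per_contact",
            "travel_cost_per_contact",
            "platform_hours_per_year",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def wage_for(self, professional: str) -> float:
        if professional not in WAGE_CLASS:
            raise ValueError(
                f"unknown professional class {professional!r}; "
                f"known: {sorted(WAGE_CLASS)}"
            )
        klass = WAGE_CLASS[professional]
        if klass is None:
            return 0.0
        return getattr(self, f"wage_{klass}")

    def scaled(self, k: float) -> "UnitCosts":
        """All monetary unit costs multiplied by ``k`` (currency rescaling)."""
        return UnitCosts(
            wage_physician=self.wage_physician * k,
            wage_nurse=self.wage_nurse * k,
            wage_social=self.wage_social * k,
            wage_citizen=self.wage_citizen * k,
            bed_day=self.bed_day * k,
            currency_year=self.currency_year,
            contact_duration_defaults=dict(self.contact_duration_defaults),
            travel_time_per_contact=self.travel_time_per_contact,
            travel_cost_per_contact=self.travel_cost_per_contact * k,
            platform_hours_per_year=self.platform_hours_per_year,
        )


@dataclass
class PerspectiveCosts:
    """Per-patient annualized cost breakdown under one perspective."""

    perspective: str
    contact_cost: float
    hospital_cost: float
    time_cost: float
    travel_cost: float

    @property
    def total(self) -> float:
        base = self.contact_cost + self.hospital_cost
        if self.perspective == "healthcare":
            return base
        return base + self.time_cost + self.travel_cost


def contact_cost(record: ContactRecord, unit_costs: UnitCosts) -> float:
    """Cost of one professional contact: duration × hourly wage.

    Volunteer contacts cost 0.  Duration comes from the record if present,
    otherwise from the per-setting defaults.
    """
    wage = unit_costs.wage_for(record.professional)
    duration = record.duration
    if duration is None:
        if record.setting not in unit_costs.contact_duration_defaults:
            raise ValueError(
                f"no duration on record and no default for setting {record.setting!r}"
            )
        duration = unit_costs.contact_duration_defaults[record.setting]
    return duration * wage


def hospital_cost(bed_days: float, unit_costs: UnitCosts) -> float:
    """Bed days × cost per bed-day."""
    if bed_days < 0:
        raise ValueError(f"bed_days must be >= 0, got {bed_days}")
    return bed_days * unit_costs.bed_day


def citizen_time_cost(hours: float, unit_costs: UnitCosts) -> float:
    """Patient/caregiver hours × the citizen hourly wage."""
    if hours < 0:
        raise ValueError(f"hours must be >= 0, got {hours}")
    return hours * unit_costs.wage_citizen


def annualize(amount: float, followup_months: float) -> float:
    """Homogenize an observed amount to € per patient-year (× 12/months)."""
    if followup_months <= 0:
        raise ValueError(f"followup_months must be > 0, got {followup_months}")
    return amount * 12.0 / followup_months


def patient_perspective_costs(
    patient: Patient,
    unit_costs: UnitCosts,
    perspective: str = "healthcare",
) -> PerspectiveCosts:
    """Annualized per-patient costs under the requested perspective.

    Health-care perspective: professional contacts plus hospital bed days.
    Societal perspective adds citizen-time terms: platform-usage time for
    intervention patients; travel time and cost of attended out-of-home
    contacts for comparator patients.
    """
    if perspective not in PERSPECTIVES:
        raise ValueError(
            f"unknown perspective {perspective!r}; expected one of {PERSPECTIVES}"
        )
    c_contacts = sum(contact_cost(r, unit_costs) for r in patient.contacts)
    bed_days = sum(a.bed_days for a in patient.admissions)
    c_hospital = hospital_cost(bed_days, unit_costs)

    time_cost = travel_cost = 0.0
    if perspective == "societal":
        if patient.arm == "intervention":
            # platform usage time is already a per-year quantity
            time_cost = citizen_time_cost(
                unit_costs.platform_hours_per_year
                * patient.followup_months
                / 12.0,
                unit_costs,
            )
        else:
            n_out = sum(1 for r in patient.contacts if r.setting == "out_of_home")
            time_cost = citizen_time_cost(
                n_out * unit_costs.travel_time_per_contact, unit_costs
            )
            travel_cost = n_out * unit_costs.travel_cost_per_contact

    m = patient.followup_months
    return PerspectiveCosts(
        perspective=perspective,
        contact_cost=annualize(c_contacts, m),
        hospital_cost=annualize(c_hospital, m),
        time_cost=annualize(time_cost, m),
        travel_cost=annualize(travel_cost, m),
    )


def state_conditional_costs(
    cohort_arm: list[Patient],
    classification: dict,
    unit_costs: UnitCosts,
    perspective: str = "healthcare",
) -> dict:
    """Mean annualized per-patient cost within each disease-stage stratum.

    ``classification`` maps patient id → 'worsened' / 'stable_or_improved'
    (see :func:`markovcea.effectiveness.classify_transition`).  Patients in
    the stable-or-improved stratum inform the baseline-stage cost; worsened
    patients inform the deteriorated-stage cost.  An empty stratum is
    reported as None with n = 0.
    """
    strata = {"baseline": [], "deteriorated": []}
    for p in cohort_arm:
        label = classification.get(p.id)
        if label is None:
            continue
        state = "deteriorated" if label == "worsened" else "baseline"
        strata[state].append(patient_perspective_costs(p, unit_costs, perspective).total)
    out = {}
    for state, values in strata.items():
        out[state] = {
            "mean_cost": float(np.mean(values)) if values else None,
            "n": len(values),
        }
    return out


def arm_program_costs(program: ProgramCosts, arm: str) -> tuple[float, float]:
    """(one-off, recurring) programme costs: configured for the intervention
    arm, (0, 0) for the comparator."""
    if arm == "intervention":
        return (program.one_off_per_patient, program.recurring_per_patient_year)
    return (0.0, 0.0)
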