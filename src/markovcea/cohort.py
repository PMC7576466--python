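"""Synthetic two-arm patient cohorts for integrated-care evaluations.

Generates patient-level data with the statistical structure the downstream
analysis assumes: demographics, comorbidity flags, baseline and follow-up
functional scores (Barthel 0–100 in steps of 5, IADL 0–8, GDS 0–15),
professional-contact records, and hospital admissions.  Every quantity is
driven by a :class:`CohortConfig`; the packaged defaults describe a frail,
multimorbid domiciliary-care population followed for 8 months.

Randomness uses a single seed split per patient by counter
(``SeedSequence((seed, index))``), so adding a patient never perturbs
earlier patients and identical (config, seed) pairs yield bit-identical
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SCORE_GRIDS",
    "ARMS",
    "PROFESSIONALS",
    "SETTINGS",
    "ContactMix",
    "HospitalizationParams",
    "ArmParams",
    "CohortConfig",
    "ContactRecord",
    "AdmissionRecord",
    "Patient",
    "generate_cohort",
    "sample_score_trajectory",
    "charlson_score",
    "write_cohort",
    "read_cohort",
    "DEFAULT_CHARLSON_WEIGHTS",
]

ARMS = ("intervention", "comparator")
PROFESSIONALS = ("GP", "specialist", "nurse", "other_health", "social_worker", "volunteer")
SETTINGS = ("out_of_home", "home_visit", "telephone", "writing", "other")

#: (min, max, step) of each instrument.
SCORE_GRIDS = {
    "barthel": (0, 100, 5),
    "iadl": (0, 8, 1),
    "gds": (0, 15, 1),
}

#: Standard Charlson Comorbidity Index weights (original 1987 weighting).
DEFAULT_CHARLSON_WEIGHTS = {
    "myocardial_infarction": 1,
    "congestive_heart_failure": 1,
    "peripheral_vascular_disease": 1,
    "cerebrovascular_disease": 1,
    "dementia": 1,
    "chronic_pulmonary_disease": 1,
    "rheumatic_disease": 1,
    "peptic_ulcer_disease": 1,
    "mild_liver_disease": 1,
    "diabetes_without_complication": 1,
    "diabetes_with_complication": 2,
    "hemiplegia_or_paraplegia": 2,
    "renal_disease": 2,
    "malignancy": 2,
    "moderate_severe_liver_disease": 3,
    "metastatic_solid_tumor": 6,
}


def _check_prob(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {value}")


def _check_sd(value: float, name: str) -> None:
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value}")


@dataclass(frozen=True)
class ContactMix:
    """Distribution of contacts over professional, setting and anticipation.

    The three margins are sampled independently; ``joint()`` exposes the
    implied product distribution over professional × setting × planned,
    which sums to 1.
    """

    professional: dict
    setting: dict
    planned_fraction: float

    def __post_init__(self) -> None:
        for name, margin, domain in (
            ("professional", self.professional, PROFESSIONALS),
            ("setting", self.setting, SETTINGS),
        ):
            unknown = set(margin) - set(domain)
            if unknown:
                raise ValueError(f"contact_mix.{name} has unknown keys {sorted(unknown)}")
            for k, v in margin.items():
                _check_prob(v, f"contact_mix.{name}[{k}]")
            if abs(sum(margin.values()) - 1.0) > 1e-6:
                raise ValueError(f"contact_mix.{name} must sum to 1")
        _check_prob(self.planned_fraction, "contact_mix.planned_fraction")

    def joint(self) -> dict:
        out = {}
        for prof, pp in self.professional.items():
            for setting, ps in self.setting.items():
                for planned, pl in ((True, self.planned_fraction), (False, 1 - self.planned_fraction)):
                    out[(prof, setting, planned)] = pp * ps * pl
        return out


@dataclass(frozen=True)
class HospitalizationParams:
    admission_prob: float = 0.0  # P(at least one admission over follow-up)
    mean_admissions: float = 0.0  # unconditional mean admissions per patient
    los_mean: float = 0.0  # per-admission length of stay, days
    los_sd: float = 0.0
    planned_fraction: float = 0.3
    readmission_prob: float = 0.2

    def __post_init__(self) -> None:
        _check_prob(self.admission_prob, "hospitalization.admission_prob")
        _check_prob(self.planned_fraction, "hospitalization.planned_fraction")
        _check_prob(self.readmission_prob, "hospitalization.readmission_prob")
        if self.mean_admissions < 0:
            raise ValueError("hospitalization.mean_admissions must be >= 0")
        if self.los_mean < 0:
            raise ValueError("hospitalization.los_mean must be >= 0")
        _check_sd(self.los_sd, "hospitalization.los_sd")


@dataclass(frozen=True)
class ArmParams:
    """Generative parameters for one study arm."""

    age_mean: float
    age_sd: float
    female_fraction: float
    comorbidity_prevalences: dict
    score_baseline: dict  # instrument -> (mean, sd)
    score_change: dict  # instrument -> (mean, sd)
    contact_rate: float  # expected contacts per patient-year
    contact_mix: ContactMix
    hospitalization: HospitalizationParams

    def __post_init__(self) -> None:
        _check_sd(self.age_sd, "age_sd")
        _check_prob(self.female_fraction, "female_fraction")
        for name, p in self.comorbidity_prevalences.items():
            _check_prob(p, f"comorbidity_prevalences[{name}]")
        for d, label in ((self.score_baseline, "score_baseline"), (self.score_change, "score_change")):
            unknown = set(d) - set(SCORE_GRIDS)
            if unknown:
                raise ValueError(f"{label} has unknown instruments {sorted(unknown)}")
            missing = set(SCORE_GRIDS) - set(d)
            if missing:
                raise ValueError(f"{label} missing instruments {sorted(missing)}")
            for instr, (mean, sd) in d.items():
                _check_sd(sd, f"{label}[{instr}].sd")
        if self.contact_rate < 0:
            raise ValueError("contact_rate must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Full two-arm generative configuration."""

    n_per_arm: dict  # arm -> count
    arms: dict  # arm -> ArmParams
    seed: int = 0
    followup_months: float = 8.0

    def __post_init__(self) -> None:
        for arm in ARMS:
            if arm not in self.n_per_arm:
                raise ValueError(f"n_per_arm missing arm {arm!r}")
            if arm not in self.arms:
                raise ValueError(f"arms missing arm {arm!r}")
            if self.n_per_arm[arm] < 1:
                raise ValueError(f"n_per_arm[{arm}] must be >= 1")
        if self.followup_months <= 0:
            raise ValueError("followup_months must be > 0")


@dataclass
class ContactRecord:
    professional: str
    setting: str
    planned: bool
    duration: float | None = None  # hours; None defers to costing defaults

    def __post_init__(self) -> None:
        if self.professional not in PROFESSIONALS:
            raise ValueError(f"unknown professional {self.professional!r}")
        if self.setting not in SETTINGS:
            raise ValueError(f"unknown setting {self.setting!r}")
        if self.duration is not None and self.duration <= 0:
            raise ValueError("contact duration must be > 0")


@dataclass
class AdmissionRecord:
    planned: bool
    bed_days: float
    readmission_within_30d: bool = False

    def __post_init__(self) -> None:
        if self.bed_days < 0:
            raise ValueError("bed_days must be >= 0")


@dataclass
class Patient:
    id: str
    arm: str
    age: float
    sex: str
    comorbidities: set
    barthel_0: int
    barthel_1: int
    iadl_0: int
    iadl_1: int
    gds_0: int
    gds_1: int
    contacts: list = field(default_factory=list)
    admissions: list = field(default_factory=list)
    followup_months: float = 8.0

    def score(self, instrument: str, timepoint: int) -> int:
        return getattr(self, f"{instrument}_{timepoint}")


def _round_to_grid(value: float, instrument: str) -> int:
    lo, hi, step = SCORE_GRIDS[instrument]
    snapped = round(value / step) * step
    return int(np.clip(snapped, lo, hi))


def sample_score_trajectory(
    baseline_params: tuple,
    change_params: tuple,
    instrument: str,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Sample (baseline, final) scores for one instrument.

    Baseline and change are Gaussian draws; both scores are snapped to the
    instrument grid and clipped to its range, so extremes saturate at the
    scale limits rather than erroring.
    """
    b_mean, b_sd = baseline_params
    c_mean, c_sd = change_params
    baseline = _round_to_grid(rng.normal(b_mean, b_sd) if b_sd > 0 else b_mean, instrument)
    change = rng.normal(c_mean, c_sd) if c_sd > 0 else c_mean
    final = _round_to_grid(baseline + change, instrument)
    return baseline, final


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a lognormal with the given mean/sd."""
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _generate_patient(
    pid: str, arm: str, params: ArmParams, followup_months: float, seed_key: tuple
) -> Patient:
    rng = np.random.default_rng(np.random.SeedSequence(seed_key))
    age = float(np.clip(rng.normal(params.age_mean, params.age_sd), 60.0, 105.0))
    sex = "F" if rng.random() < params.female_fraction else "M"
    comorbidities = {
        name for name, prev in sorted(params.comorbidity_prevalences.items())
        if rng.random() < prev
    }
    scores = {}
    for instr in SCORE_GRIDS:
        b, f = sample_score_trajectory(
            params.score_baseline[instr], params.score_change[instr], instr, rng
        )
        scores[f"{instr}_0"], scores[f"{instr}_1"] = b, f

    n_contacts = int(rng.poisson(params.contact_rate * followup_months / 12.0))
    contacts = []
    if n_contacts:
        profs = list(params.contact_mix.professional)
        p_prof = np.array([params.contact_mix.professional[p] for p in profs])
        settings = list(params.contact_mix.setting)
        p_set = np.array([params.contact_mix.setting[s] for s in settings])
        prof_idx = rng.choice(len(profs), size=n_contacts, p=p_prof / p_prof.sum())
        set_idx = rng.choice(len(settings), size=n_contacts, p=p_set / p_set.sum())
        planned = rng.random(n_contacts) < params.contact_mix.planned_fraction
        contacts = [
            ContactRecord(
                professional=profs[i], setting=settings[j], planned=bool(k)
            )
            for i, j, k in zip(prof_idx, set_idx, planned)
        ]

    admissions = []
    h = params.hospitalization
    if h.admission_prob > 0 and rng.random() < h.admission_prob:
        # conditional count: 1 + Poisson excess so the unconditional mean
        # matches mean_admissions
        excess = max(h.mean_admissions / h.admission_prob - 1.0, 0.0)
        n_adm = 1 + rng.poisson(excess)
        for _ in range(n_adm):
            if h.los_mean > 0 and h.los_sd > 0:
                mu, sigma = _lognormal_params(h.los_mean, h.los_sd)
                bed_days = float(rng.lognormal(mu, sigma))
            else:
                bed_days = h.los_mean
            admissions.append(
                AdmissionRecord(
                    planned=bool(rng.random() < h.planned_fraction),
                    bed_days=round(bed_days, 2),
                    readmission_within_30d=bool(rng.random() < h.readmission_prob),
                )
            )

    return Patient(
        id=pid,
        arm=arm,
        age=round(age, 1),
        sex=sex,
        comorbidities=comorbidities,
        contacts=contacts,
        admissions=admissions,
        followup_months=followup_months,
        **scores,
    )


def generate_cohort(config: CohortConfig) -> list[Patient]:
    """Generate the full two-arm cohort, deterministically given the seed."""
    patients = []
    counter = 0
    for arm in ARMS:
        params = config.arms[arm]
        for i in range(config.n_per_arm[arm]):
            pid = f"{arm[:3]}-{i + 1:04d}"
            patients.append(
                _generate_patient(
                    pid, arm, params, config.followup_months,
                    (config.seed, counter),
                )
            )
            counter += 1
    return patients


def charlson_score(comorbidities: set, weights: dict | None = None) -> int:
    """Sum of Charlson weights over the present comorbidity flags."""
    weights = DEFAULT_CHARLSON_WEIGHTS if weights is None else weights
    unknown = set(comorbidities) - set(weights)
    if unknown:
        raise ValueError(f"comorbidity flag(s) without weight: {sorted(unknown)}")
    return int(sum(weights[c] for c in comorbidities))


# --------------------------------------------------------------------- I/O

def write_cohort(patients: list[Patient], directory: str | Path) -> dict:
    """Write patients plus long-format contact/admission tables as CSV.

    Returns the mapping of table name → path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    prows, crows, arows = [], [], []
    for p in patients:
        row = {k: v for k, v in asdict(p).items() if k not in ("comorbidities", "contacts", "admissions")}
        row["comorbidities"] = ";".join(sorted(p.comorbidities))
        prows.append(row)
        for c in p.contacts:
            crows.append({"patient_id": p.id, **asdict(c)})
        for a in p.admissions:
            arows.append({"patient_id": p.id, **asdict(a)})
    paths = {
        "patients": directory / "patients.csv",
        "contacts": directory / "contacts.csv",
        "admissions": directory / "admissions.csv",
    }
    pd.DataFrame(prows).to_csv(paths["patients"], index=False)
    pd.DataFrame(crows, columns=["patient_id", "professional", "setting", "planned", "duration"]).to_csv(
        paths["contacts"], index=False
    )
    pd.DataFrame(
        arows, columns=["patient_id", "planned", "bed_days", "readmission_within_30d"]
    ).to_csv(paths["admissions"], index=False)
    return paths


def read_cohort(directory: str | Path) -> list[Patient]:
    """Read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    pdf = pd.read_csv(directory / "patients.csv")
    cdf = pd.read_csv(directory / "contacts.csv")
    adf = pd.read_csv(directory / "admissions.csv")
    contacts_by, admissions_by = {}, {}
    for _, r in cdf.iterrows():
        dur = None if pd.isna(r["duration"]) else float(r["duration"])
        contacts_by.setdefault(r["patient_id"], []).append(
            ContactRecord(r["professional"], r["setting"], bool(r["planned"]), dur)
        )
    for _, r in adf.iterrows():
        admissions_by.setdefault(r["patient_id"], []).append(
            AdmissionRecord(bool(r["planned"]), float(r["bed_days"]), bool(r["readmission_within_30d"]))
        )
    patients = []
    for _, r in pdf.iterrows():
        com = r["comorbidities"]
        comorbidities = set() if pd.isna(com) or com == "" else set(str(com).split(";"))
        patients.append(
            Patient(
                id=r["id"],
                arm=r["arm"],
                age=float(r["age"]),
                sex=r["sex"],
                comorbidities=comorbidities,
                barthel_0=int(r["barthel_0"]),
                barthel_1=int(r["barthel_1"]),
                iadl_0=int(r["iadl_0"]),
                iadl_1=int(r["iadl_1"]),
                gds_0=int(r["gds_0"]),
                gds_1=int(r["gds_1"]),
                contacts=contacts_by.get(r["id"], []),
                admissions=admissions_by.get(r["id"], []),
                followup_months=float(r["followup_months"]),
            )
        )
    return patients
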