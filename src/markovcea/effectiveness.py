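"""Clinical-effectiveness statistics and Markov-input estimation.

Covers the statistics used in the trial analysis — paired-differences t
confidence intervals for score changes, chi-square comparisons of
categorical baseline characteristics, t / Mann-Whitney group comparisons
with a Kolmogorov-Smirnov normality gate — and the bridge from patient-level
outcomes to the Markov model: classifying each patient as worsened vs
stable-or-improved, estimating the per-cycle incidence/recovery
probabilities, and mapping Barthel scores to utilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import Patient

__all__ = [
    "ChangeSummary",
    "TransitionEstimates",
    "UtilityMap",
    "mean_change_ci",
    "compare_groups_categorical",
    "compare_groups_continuous",
    "classify_transition",
    "estimate_transition_probs",
    "map_barthel_to_utility",
]


@dataclass
class ChangeSummary:
    """Paired mean-change summary for one instrument."""

    instrument: str
    n: int
    mean_change: float
    ci_low: float
    ci_high: float
    p_value: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not self.ci_low <= self.mean_change <= self.ci_high:
            raise ValueError("confidence interval must bracket the point estimate")


@dataclass
class TransitionEstimates:
    """Worsened/recovered fractions of an arm, used as per-cycle probabilities."""

    incidence: float
    recovery: float
    n: int
    worsening_threshold: float = 0.0
    n_excluded: int = 0


@dataclass
class UtilityMap:
    """Barthel→utility mapping.

    ``affine`` mode computes ``u = a + b*score`` clipped to [0, 1] (the
    default identity-like map is a=0, b=0.01 so Barthel 100 → utility 1).
    ``direct`` mode ignores the score and returns pre-specified state
    utilities, the route used when utilities are supplied externally.
    """

    mode: str = "affine"
    a: float = 0.0
    b: float = 0.01
    direct: dict = field(default_factory=dict)  # state -> utility

    def __post_init__(self) -> None:
        if self.mode not in ("affine", "direct"):
            raise ValueError(f"unknown utility map mode {self.mode!r}")
        for state, u in self.direct.items():
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"direct utility for {state!r} outside [0, 1]")


def mean_change_ci(pre, post, level: float = 0.95, instrument: str = "") -> ChangeSummary:
    """Mean follow-up change with CI and p from the paired t procedure.

    Zero-variance differences get the conventional degenerate answer:
    CI collapses to the mean, p = 1 when the mean is 0 and p = 0 otherwise.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    n = pre.size
    if n < 2:
        raise ValueError("need at least 2 paired observations for a CI")
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    diff = post - pre
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        return ChangeSummary(instrument, n, mean, mean, mean,
                             1.0 if mean == 0.0 else 0.0, level)
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
    tstat = mean / se
    p = 2.0 * stats.t.sf(abs(tstat), df=n - 1)
    return ChangeSummary(instrument, n, mean, mean - tcrit * se, mean + tcrit * se,
                         float(p), level)


def compare_groups_categorical(counts, correction: bool = False):
    """Chi-square test on a contingency table of counts.

    No continuity correction by default.  Returns (statistic, p_value,
    expected) where ``expected`` carries the expected-count diagnostics.
    Tables with a zero row or column margin are rejected.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.min() < 0:
        raise ValueError("counts must be a 2-D nonnegative table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a row or column margin is zero")
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue), res.expected_freq


def _ks_normal_p(x: np.ndarray) -> float:
    """One-sample KS test against a normal with the sample's moments."""
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0  # constant sample: treat as non-normal
    return float(stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def compare_groups_continuous(a, b, method: str = "auto"):
    """Two-sided comparison of two independent samples.

    ``method='t'`` runs Student's t test, ``'mann_whitney'`` the
    Mann-Whitney U test (exact when feasible, midranks under ties),
    ``'auto'`` gates on Kolmogorov-Smirnov normality of both samples at
    α = .05, choosing t when both pass.  Identical degenerate samples
    return (0, 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if method not in ("t", "mann_whitney", "auto"):
        raise ValueError(f"unknown method {method!r}")
    if np.concatenate([a, b]).std() == 0:
        stat = 0.0 if method != "mann_whitney" else a.size * b.size / 2.0
        return stat, 1.0
    if method == "auto":
        method = "t" if (_ks_normal_p(a) > 0.05 and _ks_normal_p(b) > 0.05) else "mann_whitney"
    if method == "t":
        res = stats.ttest_ind(a, b)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def classify_transition(patient: Patient, instrument: str = "barthel",
                        worsening_threshold: float = 0.0) -> str:
    """'worsened' iff the follow-up change is strictly below −threshold.

    A decline equal to the threshold therefore still counts as
    stable-or-improved (strict inequality).
    """
    baseline = patient.score(instrument, 0)
    final = patient.score(instrument, 1)
    if baseline is None or final is None:
        raise ValueError(f"patient {patient.id}: missing {instrument} score")
    return "worsened" if (final - baseline) < -worsening_threshold else "stable_or_improved"


def estimate_transition_probs(
    cohort_arm: list[Patient],
    instrument: str = "barthel",
    worsening_threshold: float = 0.0,
) -> TransitionEstimates:
    """Worsened fraction of an arm → incidence; recovery = 1 − incidence.

    Patients with a missing follow-up score are excluded and counted in
    ``n_excluded``.
    """
    labels = []
    excluded = 0
    for p in cohort_arm:
        try:
            labels.append(classify_transition(p, instrument, worsening_threshold))
        except ValueError:
            excluded += 1
    if not labels:
        raise ValueError("no classifiable patients in arm")
    n = len(labels)
    worsened = sum(1 for l in labels if l == "worsened")
    inc = worsened / n
    return TransitionEstimates(
        incidence=inc, recovery=1.0 - inc, n=n,
        worsening_threshold=worsening_threshold, n_excluded=excluded,
    )


def map_barthel_to_utility(score: float, utility_map: UtilityMap, state: str = "baseline") -> float:
    """Map a Barthel score (0–100) to a utility in [0, 1]."""
    if not 0.0 <= score <= 100.0:
        raise ValueError(f"Barthel score must be in [0, 100], got {score}")
    if utility_map.mode == "direct":
        if state not in utility_map.direct:
            raise ValueError(f"no direct utility configured for state {state!r}")
        return utility_map.direct[state]
    return float(np.clip(utility_map.a + utility_map.b * score, 0.0, 1.0))
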