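"""Chance bounds, accuracy summaries and the Welch two-sample test.

The chance level of a k-class classifier over finitely many trials is
summarized by the adjusted-Wald (Agresti-Coull) upper confidence limit
for a binomial with success probability 1/k: random classification can
exceed 1/k substantially when trial counts are small, so observed
accuracies are compared against this bound rather than against 1/k.

Subject-level accuracy summaries use the population (divisor-n)
standard deviation.  The Welch t statistic compares two summarized
groups with unequal variances; its effective degrees of freedom follow
the Welch-Satterthwaite equation with sample-variance (n-1) weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import norm


@dataclass(frozen=True)
class ChanceBound:
    """Upper confidence limit (%) on a random classifier's accuracy."""

    n_per_class: int
    n_classes: int
    alpha: float
    bound: float  # %


@dataclass(frozen=True)
class WelchResult:
    """Welch's t statistic with Welch-Satterthwaite degrees of freedom."""

    t: float
    df: float
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int


def chance_upper_bound(n_per_class: int, n_classes: int,
                       alpha: float) -> ChanceBound:
    """Adjusted-Wald upper limit for random k-class accuracy, in percent.

    With n = n_per_class * n_classes balanced trials and z the upper
    1 - alpha/2 normal quantile: ñ = n + z², p̃ = (n/k + z²/2)/ñ and the
    bound is p̃ + z·sqrt(p̃(1-p̃)/ñ).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be at least 1")
    if n_classes < 2:
        raise ValueError("n_classes must be at least 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    n = n_per_class * n_classes
    z = norm.ppf(1 - alpha / 2)
    n_adj = n + z * z
    p_adj = (n / n_classes + z * z / 2) / n_adj
    bound = p_adj + z * np.sqrt(p_adj * (1 - p_adj) / n_adj)
    return ChanceBound(n_per_class=n_per_class, n_classes=n_classes,
                       alpha=alpha, bound=100.0 * float(bound))


def summarize_accuracies(values) -> tuple[float, float]:
    """Mean and population (divisor-n) standard deviation of accuracies."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("empty accuracy list")
    return float(values.mean()), float(values.std(ddof=0))


def welch_t(mean1: float, sd1: float, n1: int,
            mean2: float, sd2: float, n2: int) -> WelchResult:
    """Welch's t from group summaries.

    t = (mean1 - mean2) / sqrt(sd1²/n1 + sd2²/n2); degrees of freedom
    follow Welch-Satterthwaite with n_i - 1 in the denominator weights.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValueError("standard deviations must be >= 0 and not both zero")
    v1 = sd1 * sd1 / n1
    v2 = sd2 * sd2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    return WelchResult(t=float(t), df=float(df), mean1=mean1, sd1=sd1, n1=n1,
                       mean2=mean2, sd2=sd2, n2=n2)


def accuracy_change(primary_mean: float, secondary_mean: float) -> float:
    """Accuracy difference (primary - secondary), percentage points."""
    for v in (primary_mean, secondary_mean):
        if not 0 <= v <= 100:
            raise ValueError("accuracies must lie in [0, 100]")
    return primary_mean - secondary_mean


def count_above(values, threshold: float) -> int:
    """Number of accuracies strictly greater than ``threshold``."""
    if not 0 <= threshold <= 100:
        raise ValueError("threshold must lie in [0, 100]")
    return int(sum(float(v) > threshold for v in values))


def load_accuracy_table(which: str = "per_subject") -> pd.DataFrame:
    """Packaged per-subject accuracy tables.

    ``per_subject``: frequency couple, offline mean ± SD and online
    accuracy for all 20 subjects.  ``frequency_check``: the 8 subjects
    who repeated the offline session with the unselected (secondary)
    frequency couple.
    """
    names = {"per_subject": "table3.csv", "frequency_check": "table2.csv"}
    if which not in names:
        raise ValueError(f"unknown table {which!r}; choose from {sorted(names)}")
    with resources.files("vibci.data").joinpath(names[which]).open() as fh:
        return pd.read_csv(fh)
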