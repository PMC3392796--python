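"""Nonparametric cohort comparison and biomarker-profile banding.

Group comparisons follow the classical slide-cytometry screening scheme:
Mann-Whitney U for the two-cohort contrast, Kruskal-Wallis across control
and the disease subgroups, and — when the omnibus test is significant —
pairwise Mann-Whitney post hocs at a Bonferroni-adjusted level
(0.05 / 3 comparisons -> 0.017).  Profile banding colour-codes each subject
per marker against the control mean + 1 SD / + 2 SD boundaries.

Test machinery is scipy.stats; this module fixes the conventions (two-sided
throughout, exact Mann-Whitney enumeration for small tie-free samples, tie
corrections elsewhere, sample SD for bands).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

HIGH_ALPHA = 0.001  # "highly significant" level

#: Total observations at or below which the exact Mann-Whitney null is used
#: (tie-free data only); above it, the tie- and continuity-corrected normal
#: approximation.
EXACT_LIMIT = 12


@dataclass(frozen=True)
class TestResult:
    marker: str
    comparison: str
    test: str  # "mann-whitney" | "kruskal-wallis"
    statistic: float
    p_value: float
    adjusted_alpha: float
    significant: bool
    highly_significant: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def _result(marker, comparison, test, statistic, p, alpha) -> TestResult:
    return TestResult(
        marker=marker,
        comparison=comparison,
        test=test,
        statistic=float(statistic),
        p_value=float(p),
        adjusted_alpha=float(alpha),
        significant=bool(p <= alpha),
        highly_significant=bool(p <= HIGH_ALPHA),
    )


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    marker: str = "",
    comparison: str = "",
    method: str = "auto",
) -> TestResult:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    ``method="auto"`` uses the exact permutation null when the pooled sample
    has at most :data:`EXACT_LIMIT` observations and no ties, otherwise the
    normal approximation with tie and continuity corrections.  The statistic
    reported is U for the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if method == "auto":
        pooled = np.concatenate([a, b])
        tie_free = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (len(pooled) <= EXACT_LIMIT and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return _result(marker, comparison, "mann-whitney", res.statistic, res.pvalue, alpha)


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    marker: str = "",
    comparison: str = "",
) -> TestResult:
    """Kruskal-Wallis H with tie correction; p from chi-square with k-1 df.

    A fully tied sample (all observations equal) carries no rank information:
    H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("all groups must be nonempty")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return _result(marker, comparison, "kruskal-wallis", 0.0, 1.0, alpha)
    res = sps.kruskal(*arrays)
    return _result(marker, comparison, "kruskal-wallis", res.statistic, res.pvalue, alpha)


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-comparison level alpha / m."""
    if m < 1:
        raise ValueError(f"number of comparisons must be >= 1, got {m}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return alpha / m


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (midranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    return float(sps.spearmanr(x, y).statistic)


def profile_bands(control_values: pd.DataFrame) -> pd.DataFrame:
    """Per-marker banding boundaries from the control cohort.

    For each marker (column) of the control matrix: boundaries at
    mean + 1 SD and mean + 2 SD (sample SD, n-1).  Zero-variance markers are
    flagged degenerate — both boundaries collapse onto the mean, so any
    larger value lands in the top band.
    """
    if len(control_values) < 2:
        raise ValueError("need at least 2 control subjects per marker")
    mean = control_values.mean(axis=0)
    sd = control_values.std(axis=0, ddof=1)
    degenerate = sd == 0.0
    if degenerate.any():
        warnings.warn(
            f"zero control variance for markers {list(sd.index[degenerate])}; "
            "bands are degenerate",
            UserWarning,
            stacklevel=2,
        )
    return pd.DataFrame(
        {
            "mean": mean,
            "sd": sd,
            "upper1": mean + sd,
            "upper2": mean + 2.0 * sd,
            "degenerate": degenerate,
        }
    )


def assign_bands(values: pd.DataFrame, bands: pd.DataFrame) -> pd.DataFrame:
    """Band every subject x marker value: 0 (<= mean+1SD), 1 (<= mean+2SD),
    2 (> mean+2SD)."""
    out = pd.DataFrame(0, index=values.index, columns=values.columns, dtype=int)
    for marker in values.columns:
        v = values[marker]
        out[marker] = np.where(v > bands.loc[marker, "upper2"], 2,
                               np.where(v > bands.loc[marker, "upper1"], 1, 0))
    return out


def compare_cohorts(
    dataset,
    alpha: float = 0.05,
    control: str = "control",
) -> pd.DataFrame:
    """Full marker-wise comparison table for a cohort dataset.

    Per marker: Mann-Whitney control vs pooled disease; Kruskal-Wallis across
    all cohorts present; and, when the omnibus test reaches ``alpha``,
    pairwise Mann-Whitney post hocs at the Bonferroni level alpha / 3.
    """
    cohorts = [c for c in pd.unique(dataset.labels) if c != control]
    if not cohorts:
        raise ValueError("dataset contains only the control cohort")
    post_alpha = bonferroni(alpha, 3)
    rows = []
    for marker in dataset.markers:
        ctrl = dataset.cohort_values(marker, control)
        disease = np.concatenate([dataset.cohort_values(marker, c) for c in cohorts])
        rows.append(mann_whitney(ctrl, disease, alpha, marker, f"{control} vs disease"))
        groups = [ctrl] + [dataset.cohort_values(marker, c) for c in cohorts]
        kw = kruskal_wallis(groups, alpha, marker, " | ".join([control] + cohorts))
        rows.append(kw)
        if kw.significant:
            pairs = list(itertools.combinations([control] + cohorts, 2))
            for g1, g2 in pairs:
                rows.append(
                    mann_whitney(
                        dataset.cohort_values(marker, g1),
                        dataset.cohort_values(marker, g2),
                        post_alpha,
                        marker,
                        f"{g1} vs {g2}",
                    )
                )
    return pd.DataFrame([r.__dict__ for r in rows])
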