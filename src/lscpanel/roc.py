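"""ROC analysis: curves, AUC, DeLong/bootstrap confidence intervals,
sensitivity at fixed specificity, and discriminability bands.

Operating points come from a full threshold sweep (one point per distinct
score; tied scores form diagonal segments) and AUC is the trapezoidal area,
which equals the pairwise Mann-Whitney probability that a random positive
outscores a random negative with ties counted half.  The 95% CI uses the
DeLong placement-variance estimator by default, with a stratified
percentile bootstrap as the alternative (and as the automatic fallback when
perfect separation makes the DeLong variance degenerate).

Bands follow the screening convention: AUC > 0.85 highly discriminative,
AUC < 0.55 nondiscriminative, intermediate between.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

HIGH_BAND = 0.85
LOW_BAND = 0.55


@dataclass
class ROCCurve:
    """Ordered ROC operating points with trapezoid AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    ci95: tuple[float, float] | None = None


def roc_from_scores(scores, labels, pos_label=1) -> ROCCurve:
    """Threshold-sweep ROC of decision scores (higher score = positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == pos_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(pos.astype(int), scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc, n_pos=n_pos, n_neg=n_neg)


def sensitivity_at_specificity(
    curve: ROCCurve,
    target_specificity: float = 0.90,
    method: str = "interpolated",
) -> float:
    """Sensitivity where specificity equals the target.

    ``"interpolated"`` reads the curve's upper envelope linearly between
    adjacent operating points; ``"step"`` is the conservative step-function
    value (the best sensitivity actually attainable at specificity >=
    target).  Printed operating points in the literature may follow either
    convention, so both are exposed.
    """
    if not 0.0 < target_specificity < 1.0:
        raise ValueError(f"target specificity must be in (0, 1), got {target_specificity}")
    if method not in ("interpolated", "step"):
        raise ValueError(f"unknown method {method!r}")
    target_fpr = 1.0 - target_specificity
    if len(curve.fpr) <= 2:
        warnings.warn(
            "degenerate ROC curve (single segment); returning diagonal value",
            UserWarning,
            stacklevel=2,
        )
    if method == "step":
        ok = curve.fpr <= target_fpr
        return float(curve.tpr[ok].max()) if ok.any() else 0.0
    # upper envelope: max tpr at each distinct fpr (fpr is nondecreasing,
    # so equal values are contiguous), then linear interpolation
    fpr_u, idx = np.unique(curve.fpr, return_index=True)
    tpr_env = np.maximum.reduceat(curve.tpr, idx)
    return float(np.interp(target_fpr, fpr_u, tpr_env))


def _delong_variance(scores, pos_mask):
    """DeLong placement values and AUC variance estimate."""
    x = scores[pos_mask]
    y = scores[~pos_mask]
    m, n = len(x), len(y)
    # midrank placements via pooled ranking
    all_s = np.concatenate([x, y])
    r_all = rankdata(all_s)
    r_x = rankdata(x)
    r_y = rankdata(y)
    v10 = (r_all[:m] - r_x) / n  # P(Y < x_i) + 0.5 P(Y = x_i)
    v01 = 1.0 - (r_all[m:] - r_y) / m
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def auc_ci(
    scores,
    labels,
    method: str = "delong",
    seed: int | None = None,
    n_boot: int = 2000,
    pos_label=1,
) -> tuple[float, float]:
    """95% confidence interval for the AUC, clipped to [0, 1].

    ``"delong"`` is the analytic placement-variance interval; ``"bootstrap"``
    is a class-stratified percentile bootstrap.  Perfect separation gives a
    zero DeLong variance, in which case the bootstrap fallback is used with
    a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos_mask = labels == pos_label
    if pos_mask.sum() < 2 or (~pos_mask).sum() < 2:
        raise ValueError("need at least 2 samples per class")
    if method == "delong":
        auc, var = _delong_variance(scores, pos_mask)
        if var <= 0.0:
            warnings.warn(
                "degenerate DeLong variance (AUC at 0 or 1); bootstrap fallback",
                UserWarning,
                stacklevel=2,
            )
            return auc_ci(scores, labels, method="bootstrap", seed=seed,
                          n_boot=n_boot, pos_label=pos_label)
        half = norm.ppf(0.975) * np.sqrt(var)
        return (float(np.clip(auc - half, 0.0, 1.0)), float(np.clip(auc + half, 0.0, 1.0)))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        x = scores[pos_mask]
        y = scores[~pos_mask]
        m, n = len(x), len(y)
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            xb = x[rng.integers(0, m, m)]
            yb = y[rng.integers(0, n, n)]
            r = rankdata(np.concatenate([xb, yb]))
            aucs[b] = (r[:m].sum() - m * (m + 1) / 2) / (m * n)
        lo, hi = np.percentile(aucs, [2.5, 97.5])
        return (float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0)))
    raise ValueError(f"unknown CI method {method!r}")


def classify_auc_band(auc: float) -> str:
    """Discriminability band: > 0.85 highly discriminative, < 0.55
    nondiscriminative, intermediate otherwise (both boundaries inclusive of
    the intermediate band)."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC {auc} outside [0, 1]")
    if auc > HIGH_BAND:
        return "highly_discriminative"
    if auc < LOW_BAND:
        return "nondiscriminative"
    return "intermediate"


def plot_roc(curve: ROCCurve, path=None, label: str | None = None):
    """Plot a single ROC curve; writes to ``path`` if given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve.fpr, curve.tpr, drawstyle="default",
            label=label or f"AUC = {curve.auc:.3f}")
    ax.plot([0, 1], [0, 1], ls=":", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
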