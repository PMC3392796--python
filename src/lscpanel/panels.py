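"""Exhaustive in-silico search over small marker panels.

Every unordered marker subset up to size three is scored, per cohort
contrast and per parameter track (corrected MFI or affected area — the two
tracks are never mixed in one feature matrix), by repeated cross-validated
linear discrimination; the ROC is computed on the out-of-fold discriminant
scores so ranking reflects generalization rather than resubstitution fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .discriminant import CVReport, cross_validate
from .markers import CohortDataset
from .roc import ROCCurve, auc_ci, classify_auc_band, roc_from_scores, sensitivity_at_specificity

MAX_PANEL_SIZE = 3

#: contrast name -> cohorts on the positive (disease) side
CONTRASTS = {
    "control-vs-ra": ("RA(+)", "RA(++)"),
    "control-vs-ra+": ("RA(+)",),
    "control-vs-ra++": ("RA(++)",),
}

RANK_CRITERIA = ("auc", "sens_at_90_spec", "lr_plus")


@dataclass
class PanelResult:
    panel: tuple[str, ...]
    contrast: str
    parameter: str
    cv: CVReport
    roc: ROCCurve
    auc: float
    ci95: tuple[float, float]
    sens_at_90_spec: float
    sens_at_90_spec_step: float
    lr_plus: float
    band: str


def enumerate_panels(
    markers: Sequence[str],
    max_size: int,
    min_size: int = 1,
) -> list[tuple[str, ...]]:
    """All unordered marker subsets of sizes ``min_size..max_size`` in
    deterministic lexicographic order."""
    if len(set(markers)) != len(markers):
        raise ValueError("markers must be distinct")
    if not 1 <= min_size <= max_size:
        raise ValueError(f"invalid size range [{min_size}, {max_size}]")
    if max_size > MAX_PANEL_SIZE:
        raise ValueError(f"max_size must be <= {MAX_PANEL_SIZE}, got {max_size}")
    if max_size > len(markers):
        raise ValueError(f"max_size {max_size} exceeds the {len(markers)} available markers")
    ordered = sorted(markers)
    out: list[tuple[str, ...]] = []
    for size in range(min_size, max_size + 1):
        out.extend(combinations(ordered, size))
    return out


def _contrast_subset(dataset: CohortDataset, contrast: str, control: str = "control"):
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; choose from {sorted(CONTRASTS)}")
    disease = CONTRASTS[contrast]
    keep = dataset.labels.isin((control,) + disease)
    labels = dataset.labels.loc[keep]
    y = labels.isin(disease).to_numpy(dtype=int)
    if y.sum() == 0 or (y == 0).sum() == 0:
        raise ValueError(f"contrast {contrast!r}: a group is empty")
    return dataset.values.loc[keep], y


def evaluate_panel(
    panel: Sequence[str],
    dataset: CohortDataset,
    contrast: str = "control-vs-ra",
    k: int = 10,
    reps: int = 10,
    seed: int = 0,
    target_specificity: float = 0.90,
    ci_method: str = "delong",
) -> PanelResult:
    """Cross-validated discrimination metrics for one marker panel.

    The ROC is computed on each patient's out-of-fold decision score
    averaged over repetitions, so AUC, sensitivity-at-specificity and the
    pooled confusion counts all describe the same held-out surface.
    """
    panel = tuple(panel)
    missing = [m for m in panel if m not in dataset.values.columns]
    if missing:
        raise KeyError(f"markers not in dataset: {missing}")
    values, y = _contrast_subset(dataset, contrast)
    X = values.loc[:, list(panel)].to_numpy(dtype=float)
    cv = cross_validate(X, y, k=k, reps=reps, seed=seed)
    scores = cv.mean_scores
    curve = roc_from_scores(scores, y, pos_label=1)
    ci = auc_ci(scores, y, method=ci_method, seed=seed, pos_label=1)
    curve.ci95 = ci
    return PanelResult(
        panel=panel,
        contrast=contrast,
        parameter=dataset.parameter,
        cv=cv,
        roc=curve,
        auc=curve.auc,
        ci95=ci,
        sens_at_90_spec=sensitivity_at_specificity(curve, target_specificity),
        sens_at_90_spec_step=sensitivity_at_specificity(curve, target_specificity, "step"),
        lr_plus=cv.lr_plus,
        band=classify_auc_band(curve.auc),
    )


def rank_panels(results: Iterable[PanelResult], criterion: str = "auc") -> list[PanelResult]:
    """Stable descending sort by the chosen criterion; ties broken by
    smaller panel, then lexicographically."""
    results = list(results)
    if not results:
        raise ValueError("no panel results to rank")
    if criterion not in RANK_CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {RANK_CRITERIA}")
    contrasts = {r.contrast for r in results}
    parameters = {r.parameter for r in results}
    if len(contrasts) > 1 or len(parameters) > 1:
        raise ValueError(
            f"cannot rank across mixed contrasts {contrasts} or parameters {parameters}"
        )
    return sorted(results, key=lambda r: (-getattr(r, criterion), len(r.panel), r.panel))


def search_panels(
    dataset: CohortDataset,
    contrast: str = "control-vs-ra",
    max_size: int = 2,
    min_size: int = 1,
    k: int = 10,
    reps: int = 10,
    seed: int = 0,
    criterion: str = "auc",
    target_specificity: float = 0.90,
    ci_method: str = "delong",
) -> list[PanelResult]:
    """Evaluate and rank every panel up to ``max_size`` markers.

    One seed drives all evaluations so panels are compared on identical
    fold assignments.
    """
    panels = enumerate_panels(dataset.markers, max_size=max_size, min_size=min_size)
    results = [
        evaluate_panel(
            p, dataset, contrast, k=k, reps=reps, seed=seed,
            target_specificity=target_specificity, ci_method=ci_method,
        )
        for p in panels
    ]
    return rank_panels(results, criterion=criterion)


def results_frame(results: Sequence[PanelResult]) -> pd.DataFrame:
    """Flatten panel results into a tidy table for reporting."""
    rows = []
    for r in results:
        rows.append(
            {
                "panel": "+".join(r.panel),
                "size": len(r.panel),
                "contrast": r.contrast,
                "parameter": r.parameter,
                "auc": r.auc,
                "ci_low": r.ci95[0],
                "ci_high": r.ci95[1],
                "sens_at_90_spec": r.sens_at_90_spec,
                "sens_at_90_spec_step": r.sens_at_90_spec_step,
                "sensitivity": r.cv.sensitivity,
                "specificity": r.cv.specificity,
                "lr_plus": r.lr_plus if np.isfinite(r.lr_plus) else np.inf,
                "band": r.band,
                "tp": r.cv.tp,
                "fp": r.cv.fp,
                "tn": r.cv.tn,
                "fn": r.cv.fn,
            }
        )
    return pd.DataFrame(rows)
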