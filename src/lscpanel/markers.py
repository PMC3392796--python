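"""Per-section statistics: background-corrected MFI and affected area.

Two numbers summarize each stained section, both calibrated against the
patient's matched negative-control (isotype) section:

* **corrected MFI** — the median integral fluorescence over all tissue
  phantoms, minus the same median on the negative control.  May be negative
  when the control outshines the stain; it is reported as-is.
* **affected area** — the percentage of tissue phantoms whose MaxPixel
  exceeds the autofluorescence cutoff.  The cutoff is set per patient and
  dye on the negative control as the smallest observed MaxPixel value that
  leaves strictly fewer than ``max_fpr`` (default 5%) of the calibration
  events above it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DyeThreshold:
    """Autofluorescence cutoff calibrated on one negative-control section."""

    patient_id: str
    marker: str
    cutoff: float
    n_calibration: int
    exceedance: float  # achieved fraction of calibration events above cutoff


@dataclass(frozen=True)
class SectionSummary:
    patient_id: str
    marker: str
    mfi_raw: float
    mfi_negctrl: float
    mfi_corrected: float
    affected_area: float  # percent of tissue phantoms, 0..100
    n_phantoms: int
    threshold: DyeThreshold


def calibrate_threshold(negctrl: pd.DataFrame, max_fpr: float = 0.05) -> DyeThreshold:
    """Set the autofluorescence cutoff from a negative-control phantom table.

    The cutoff is the smallest *observed* MaxPixel value ``t`` such that the
    fraction of calibration phantoms with MaxPixel strictly greater than
    ``t`` is strictly below ``max_fpr``.  Choosing from observed values with
    a strict comparison guarantees the "< max_fpr positive events" contract
    on the calibration set itself, deterministically.
    """
    if not 0.0 < max_fpr < 1.0:
        raise ValueError(f"max_fpr must be in (0, 1), got {max_fpr}")
    if len(negctrl) == 0:
        raise ValueError("empty negative-control table")
    values = np.sort(negctrl["maxpixel"].to_numpy(dtype=float))
    n = len(values)
    candidates = np.unique(values)
    # fraction strictly above each candidate
    above = (n - np.searchsorted(values, candidates, side="right")) / n
    idx = int(np.argmax(above < max_fpr))  # candidates ascending -> first hit is smallest
    cutoff = float(candidates[idx])
    patient = str(negctrl["patient_id"].iloc[0]) if "patient_id" in negctrl else ""
    marker = str(negctrl["marker"].iloc[0]) if "marker" in negctrl else ""
    return DyeThreshold(
        patient_id=patient,
        marker=marker,
        cutoff=cutoff,
        n_calibration=n,
        exceedance=float(above[idx]),
    )


def mfi(table: pd.DataFrame) -> float:
    """Median integral fluorescence over the section's phantoms."""
    if len(table) == 0:
        raise ValueError("empty phantom table")
    return float(np.median(table["integral"].to_numpy(dtype=float)))


def affected_area(table: pd.DataFrame, cutoff: float) -> float:
    """Percent of phantoms whose MaxPixel strictly exceeds ``cutoff``."""
    if len(table) == 0:
        raise ValueError("empty phantom table")
    return 100.0 * float(np.mean(table["maxpixel"].to_numpy(dtype=float) > cutoff))


def summarize_section(
    marker_table: pd.DataFrame,
    negctrl_table: pd.DataFrame,
    max_fpr: float = 0.05,
) -> SectionSummary:
    """Corrected MFI and affected area for one section against its matched
    negative control.  Both tables must belong to the same patient."""
    if len(marker_table) == 0 or len(negctrl_table) == 0:
        raise ValueError("empty phantom table")
    p_marker = set(marker_table["patient_id"].unique())
    p_ctrl = set(negctrl_table["patient_id"].unique())
    if p_marker != p_ctrl:
        raise ValueError(f"patient mismatch: marker section {p_marker} vs control {p_ctrl}")
    threshold = calibrate_threshold(negctrl_table, max_fpr=max_fpr)
    mfi_raw = mfi(marker_table)
    mfi_neg = mfi(negctrl_table)
    return SectionSummary(
        patient_id=str(marker_table["patient_id"].iloc[0]),
        marker=str(marker_table["marker"].iloc[0]),
        mfi_raw=mfi_raw,
        mfi_negctrl=mfi_neg,
        mfi_corrected=mfi_raw - mfi_neg,
        affected_area=affected_area(marker_table, threshold.cutoff),
        n_phantoms=len(marker_table),
        threshold=threshold,
    )


def summarize_study(tables: pd.DataFrame, max_fpr: float = 0.05) -> pd.DataFrame:
    """Summarize every (patient, marker) section pair in a concatenated
    phantom table, returning one tidy row per section."""
    rows = []
    for (patient, marker), grp in tables.groupby(["patient_id", "marker"], sort=True):
        stained = grp.loc[~grp["is_negctrl"]]
        control = grp.loc[grp["is_negctrl"]]
        if len(stained) == 0 or len(control) == 0:
            raise ValueError(f"patient {patient}, marker {marker}: missing section or control")
        s = summarize_section(stained, control, max_fpr=max_fpr)
        rows.append(
            {
                "patient_id": s.patient_id,
                "marker": s.marker,
                "mfi_raw": s.mfi_raw,
                "mfi_negctrl": s.mfi_negctrl,
                "mfi_corrected": s.mfi_corrected,
                "affected_area": s.affected_area,
                "n_phantoms": s.n_phantoms,
                "cutoff": s.threshold.cutoff,
                "exceedance": s.threshold.exceedance,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CohortDataset:
    """Patients x markers value matrix for one parameter, with cohort labels.

    ``values`` is indexed by patient id with one column per marker; ``labels``
    is a patient-indexed Series of cohort names.
    """

    parameter: str
    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("marker names must be unique")
        missing = self.values.index.difference(self.labels.index)
        if len(missing):
            raise ValueError(f"patients without cohort label: {list(missing)}")
        self.labels = self.labels.loc[self.values.index]

    @property
    def markers(self) -> list[str]:
        return list(self.values.columns)

    def cohort_values(self, marker: str, cohort: str) -> np.ndarray:
        return self.values.loc[self.labels == cohort, marker].to_numpy(dtype=float)


def build_dataset(
    summaries: pd.DataFrame,
    metadata: pd.DataFrame,
    parameter: str = "mfi_corrected",
) -> CohortDataset:
    """Pivot tidy section summaries into a patients x markers matrix."""
    if parameter not in summaries.columns:
        raise ValueError(f"unknown parameter {parameter!r}")
    values = summaries.pivot(index="patient_id", columns="marker", values=parameter)
    if values.isna().any().any():
        raise ValueError("missing sections: patients x markers matrix has holes")
    labels = metadata.set_index("patient_id")["cohort"]
    return CohortDataset(parameter=parameter, values=values, labels=labels)
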