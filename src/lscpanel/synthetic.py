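"""Synthetic slide-cytometry cohorts: phantom event tables and tissue scans.

The generator emulates the statistical structure a slide-based cytometer
produces after phantom (grid-tile) contouring of a stained tissue section:
per-event MaxPixel and integral fluorescence over a log-normal
autofluorescent background, with a cohort- and marker-dependent fraction of
events carrying positive signal from a heavier-tailed, shifted log-normal.
Each patient gets one marker section and one matched negative-control
section per marker; negative controls share the patient's background
parameters (an idealized isotype control, with an optional jitter).

The default design mirrors a synovial-tissue biomarker study: 14 controls
and 17 rheumatoid-arthritis patients split into 12 with mild current-activity
synovitis (``RA(+)``) and 5 with high activity (``RA(++)``), screened with
nine surface markers.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CONTROL = "control"
RA_MILD = "RA(+)"
RA_HIGH = "RA(++)"
COHORTS = (CONTROL, RA_MILD, RA_HIGH)

DEFAULT_MARKERS = (
    "CD4",
    "CD11b",
    "CD29",
    "CD38",
    "CD64",
    "CD90",
    "CD271",
    "CD304",
    "HLA-DR",
)

#: Columns of the on-disk phantom table format, in order.
TABLE_COLUMNS = (
    "patient_id",
    "marker",
    "is_negctrl",
    "phantom_id",
    "row",
    "col",
    "scatter",
    "integral",
    "maxpixel",
)


@dataclass(frozen=True)
class CohortDesign:
    """Parameters of a synthetic three-cohort biomarker study.

    ``positive_fraction[cohort][marker]`` is the expected fraction of tissue
    phantoms carrying positive marker signal; ``positive_shift`` is the
    log-intensity offset of that signal above the autofluorescent background.
    ``patient_log_sd`` spreads the per-patient background level and
    ``fraction_jitter_sd`` spreads each patient's positive fraction
    (log-normal multiplier), so that cohorts overlap the way real patient
    cohorts do rather than separating perfectly at large event counts.
    """

    n_control: int = 14
    n_ra_mild: int = 12
    n_ra_high: int = 5
    markers: Sequence[str] = DEFAULT_MARKERS
    phantoms_per_section: int = 5000
    background_log_mean: float = 5.0
    background_log_sd: float = 0.4
    positive_sd_scale: float = 1.5
    patient_log_sd: float = 0.10
    fraction_jitter_sd: float = 0.8
    area_factor_log_mean: float = math.log(40.0)
    area_factor_log_sd: float = 0.3
    negctrl_jitter_sd: float = 0.0
    positive_fraction: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    positive_shift: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_control", "n_ra_mild", "phantoms_per_section"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_ra_high < 0:
            raise ValueError("n_ra_high must be >= 0")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker names must be unique")
        for cohort, per_marker in self.positive_fraction.items():
            if cohort not in COHORTS:
                raise ValueError(f"unknown cohort {cohort!r} in positive_fraction")
            for marker, frac in per_marker.items():
                if not 0.0 <= frac <= 1.0:
                    raise ValueError(
                        f"positive_fraction[{cohort!r}][{marker!r}] = {frac} not in [0, 1]"
                    )
        for cohort in self.positive_shift:
            if cohort not in COHORTS:
                raise ValueError(f"unknown cohort {cohort!r} in positive_shift")

    def fraction_for(self, cohort: str, marker: str) -> float:
        if cohort not in COHORTS:
            raise ValueError(f"unknown cohort {cohort!r}")
        if marker not in self.markers:
            raise ValueError(f"unknown marker {marker!r}")
        return float(self.positive_fraction.get(cohort, {}).get(marker, 0.0))

    def shift_for(self, cohort: str, marker: str) -> float:
        if cohort not in COHORTS:
            raise ValueError(f"unknown cohort {cohort!r}")
        if marker not in self.markers:
            raise ValueError(f"unknown marker {marker!r}")
        return float(self.positive_shift.get(cohort, {}).get(marker, 0.0))

    def patient_ids(self) -> "pd.DataFrame":
        """Metadata table: one row per patient with its cohort label."""
        rows = (
            [(f"C{i + 1:02d}", CONTROL) for i in range(self.n_control)]
            + [(f"R{i + 1:02d}", RA_MILD) for i in range(self.n_ra_mild)]
            + [(f"H{i + 1:02d}", RA_HIGH) for i in range(self.n_ra_high)]
        )
        return pd.DataFrame(rows, columns=["patient_id", "cohort"])


@dataclass
class ScanImage:
    """A two-channel tissue scan: one scatter and one fluorescence channel."""

    scatter: np.ndarray
    fluorescence: np.ndarray
    pixel_size_um: float = 1.0
    patient_id: str = ""
    marker: str = ""
    negative_control: bool = False

    def __post_init__(self) -> None:
        if self.scatter.shape != self.fluorescence.shape:
            raise ValueError("scatter and fluorescence channels must share a shape")
        if self.scatter.ndim != 2:
            raise ValueError("channels must be 2-D pixel grids")
        if (self.scatter < 0).any() or (self.fluorescence < 0).any():
            raise ValueError("intensities must be nonnegative")


def default_design(seed: int = 0, **overrides) -> CohortDesign:
    """The study-shaped default design.

    Effect pattern over the nine markers: CD4 and CD271 carry no cohort
    effect; CD29, CD90 and HLA-DR respond preferentially in RA(+); CD11b,
    CD38 and CD304 preferentially in RA(++); CD64 and HLA-DR respond in both
    RA subgroups.  Controls keep a small nonspecific positive fraction.
    """
    base = 0.05
    frac = {
        CONTROL: {m: base for m in DEFAULT_MARKERS},
        RA_MILD: {
            "CD4": base,
            "CD271": base,
            "CD11b": 0.10,
            "CD38": 0.08,
            "CD304": 0.08,
            "CD29": 0.20,
            "CD90": 0.22,
            "CD64": 0.18,
            "HLA-DR": 0.25,
        },
        RA_HIGH: {
            "CD4": base,
            "CD271": base,
            "CD11b": 0.30,
            "CD38": 0.22,
            "CD304": 0.25,
            "CD29": 0.10,
            "CD90": 0.10,
            "CD64": 0.35,
            "HLA-DR": 0.18,
        },
    }
    shift = {c: {m: 1.2 for m in DEFAULT_MARKERS} for c in COHORTS}
    params = dict(positive_fraction=frac, positive_shift=shift, seed=seed)
    params.update(overrides)
    return CohortDesign(**params)


def _entropy(*parts) -> list[int]:
    """Stable integer entropy stream from mixed str/int parts."""
    out = []
    for p in parts:
        if isinstance(p, str):
            out.append(zlib.crc32(p.encode("utf-8")))
        else:
            out.append(int(p) & 0xFFFFFFFF)
    return out


def _patient_background(design: CohortDesign, patient_id: str) -> float:
    """Per-patient background log-mean, shared by all of the patient's sections."""
    rng = np.random.default_rng(np.random.SeedSequence(_entropy(design.seed, patient_id, 0xBAC)))
    return design.background_log_mean + rng.normal(0.0, design.patient_log_sd)


def _patient_fraction(design: CohortDesign, patient_id: str, cohort: str, marker: str) -> float:
    """Patient-level effective positive fraction (log-normal jitter, clipped)."""
    nominal = design.fraction_for(cohort, marker)
    if nominal == 0.0 or design.fraction_jitter_sd == 0.0:
        return nominal
    rng = np.random.default_rng(
        np.random.SeedSequence(_entropy(design.seed, patient_id, marker, 0xF8AC))
    )
    return float(np.clip(nominal * rng.lognormal(0.0, design.fraction_jitter_sd), 0.0, 1.0))


def generate_phantom_table(
    design: CohortDesign,
    patient_id: str,
    marker: str,
    cohort: str,
    negative_control: bool = False,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw one section's phantom event table.

    Every event is tissue (scatter high).  MaxPixel is log-normal background,
    or background shifted by the cohort/marker signal with the patient's
    effective positive fraction; negative controls have zero positive
    fraction.  Integral fluorescence is MaxPixel times a log-normal
    area factor >= 1, so ``integral >= maxpixel`` always holds.

    Returns a DataFrame with the columns in :data:`TABLE_COLUMNS` plus a
    ground-truth ``is_positive`` column (not part of the on-disk format).
    """
    frac = 0.0 if negative_control else _patient_fraction(design, patient_id, cohort, marker)
    shift = design.shift_for(cohort, marker)
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(
        np.random.SeedSequence(_entropy(seed, patient_id, marker, int(negative_control)))
    )
    n = design.phantoms_per_section
    mu = _patient_background(design, patient_id)
    if negative_control and design.negctrl_jitter_sd > 0.0:
        mu += rng.normal(0.0, design.negctrl_jitter_sd)
    is_positive = rng.random(n) < frac
    log_max = rng.normal(mu, design.background_log_sd, n)
    pos_sd = design.background_log_sd * design.positive_sd_scale
    log_max_pos = rng.normal(mu + shift, pos_sd, n)
    log_max = np.where(is_positive, log_max_pos, log_max)
    maxpixel = np.exp(log_max)
    area_factor = 1.0 + rng.lognormal(design.area_factor_log_mean, design.area_factor_log_sd, n)
    integral = maxpixel * area_factor
    scatter = np.clip(rng.normal(1000.0, 50.0, n), 1.0, None)
    side = max(1, math.isqrt(n - 1) + 1)
    idx = np.arange(n)
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "marker": marker,
            "is_negctrl": bool(negative_control),
            "phantom_id": idx,
            "row": idx // side,
            "col": idx % side,
            "scatter": scatter,
            "integral": integral,
            "maxpixel": maxpixel,
            "is_positive": is_positive,
        }
    )


def generate_scan(
    design: CohortDesign,
    patient_id: str,
    marker: str,
    cohort: str = CONTROL,
    seed: int | None = None,
    shape: tuple[int, int] = (400, 400),
    tissue_fraction: float = 0.6,
    n_foci: int = 30,
    focus_radius: int = 3,
) -> ScanImage:
    """Render a synthetic two-channel scan: a connected tissue blob with
    autofluorescent background and clustered bright foci.

    The tissue is a centred disk covering ``tissue_fraction`` of the frame
    (fraction 1.0 fills the whole frame); scatter is high inside the blob and
    near zero outside.  Fluorescence inside the tissue is log-normal
    background; each focus adds a small bright disk whose intensity sits at
    the cohort/marker signal level.
    """
    if not 0.0 < tissue_fraction <= 1.0:
        raise ValueError(f"tissue_fraction must be in (0, 1], got {tissue_fraction}")
    design.fraction_for(cohort, marker)  # validates names
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(
        np.random.SeedSequence(_entropy(seed, patient_id, marker, 0x5CA7))
    )
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    if tissue_fraction >= 1.0:
        mask = np.ones(shape, dtype=bool)
    else:
        radius = math.sqrt(tissue_fraction * rows * cols / math.pi)
        mask = (yy - rows / 2.0) ** 2 + (xx - cols / 2.0) ** 2 <= radius**2

    scatter = np.abs(rng.normal(0.0, 3.0, shape))
    scatter[mask] = np.clip(rng.normal(1000.0, 50.0, int(mask.sum())), 1.0, None)

    mu = _patient_background(design, patient_id)
    fluor = np.abs(rng.normal(0.0, 1.0, shape))
    fluor[mask] = np.exp(rng.normal(mu, design.background_log_sd, int(mask.sum())))

    shift = design.shift_for(cohort, marker)
    ty, tx = np.nonzero(mask)
    for _ in range(n_foci):
        k = rng.integers(len(ty))
        cy, cx = ty[k], tx[k]
        peak = math.exp(mu + max(shift, 1.0) + rng.normal(0.0, 0.2))
        spot = (yy - cy) ** 2 + (xx - cx) ** 2 <= focus_radius**2
        fluor[spot & mask] += peak
    return ScanImage(
        scatter=scatter,
        fluorescence=fluor,
        patient_id=patient_id,
        marker=marker,
    )


def generate_study(design: CohortDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the whole study: per patient and marker, one marker section
    and one matched negative-control section.

    Returns ``(tables, metadata)``: all phantom tables concatenated, and the
    patient metadata with cohort labels.  Total sections =
    patients x markers x 2.
    """
    metadata = design.patient_ids()
    frames = []
    for patient_id, cohort in metadata.itertuples(index=False):
        for marker in design.markers:
            for negctrl in (False, True):
                frames.append(
                    generate_phantom_table(
                        design,
                        patient_id,
                        marker,
                        cohort=cohort,
                        negative_control=negctrl,
                        seed=design.seed,
                    )
                )
    tables = pd.concat(frames, ignore_index=True)
    return tables, metadata
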