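"""Plain-text I/O for every pipeline artifact.

All intermediate artifacts are tabular text (CSV with fixed, documented
headers) or JSON/YAML, so each stage can be run, inspected and tested in
isolation — the analysis deliberately keeps the seams between simulation,
quantification, statistics and classification explicit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import TABLE_COLUMNS, CohortDesign

def write_table(table: pd.DataFrame, path) -> None:
    """Write a phantom table (the documented 9-column format; any extra
    in-memory columns such as ground-truth flags are dropped)."""
    # default float repr round-trips exactly, keeping disk and in-memory paths identical
    table.loc[:, list(TABLE_COLUMNS)].to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, float_precision="round_trip")
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: phantom table missing columns {sorted(missing)}")
    return table


def write_frame(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_frame(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def design_to_dict(design: CohortDesign) -> dict:
    d = dataclasses.asdict(design)
    d["markers"] = list(design.markers)
    d["positive_fraction"] = {c: dict(m) for c, m in design.positive_fraction.items()}
    d["positive_shift"] = {c: dict(m) for c, m in design.positive_shift.items()}
    return d


def design_from_dict(d: dict) -> CohortDesign:
    d = dict(d)
    if "markers" in d:
        d["markers"] = tuple(d["markers"])
    return CohortDesign(**d)


def load_design(path) -> CohortDesign:
    with open(path) as fh:
        return design_from_dict(yaml.safe_load(fh))


def save_design(design: CohortDesign, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design_to_dict(design), fh, sort_keys=True)


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_scan_tiff(image, path) -> None:
    """Two-page TIFF: page 0 scatter, page 1 fluorescence."""
    import tifffile

    tifffile.imwrite(path, np.stack([image.scatter, image.fluorescence]).astype(np.float32))


def read_scan_tiff(path, patient_id: str = "", marker: str = "", negative_control: bool = False):
    import tifffile

    from .synthetic import ScanImage

    pages = np.asarray(tifffile.imread(path), dtype=float)
    if pages.ndim != 3 or pages.shape[0] < 2:
        raise ValueError(f"{path}: expected a 2-page (scatter, fluorescence) TIFF")
    return ScanImage(
        scatter=pages[0],
        fluorescence=pages[1],
        patient_id=patient_id,
        marker=marker,
        negative_control=negative_control,
    )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
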