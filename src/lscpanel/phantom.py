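"""Phantom contouring of scan images and scatter-based tissue gating.

A *phantom* here is a fixed-size square grid tile — a virtual, non-cell-based
analysis unit carrying the tile's integral fluorescence, its brightest pixel
(MaxPixel), and its brightest scatter pixel.  Tissue/background separation is
done on the scatter channel: tiles whose scatter maximum exceeds a cutoff are
tissue; the cutoff is either fixed or an automatic two-class (Otsu) split of
the scatter-maximum histogram.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .synthetic import ScanImage


def tile_phantoms(image: ScanImage, tile_edge: int = 20) -> pd.DataFrame:
    """Partition a scan into non-overlapping square tiles, row-major.

    Partial tiles at the right/bottom edges are dropped, so every phantom has
    the same pixel area.  Per tile: ``integral`` (fluorescence pixel sum),
    ``maxpixel`` (fluorescence maximum) and ``scatter`` (scatter maximum).

    Raises ``ValueError`` if ``tile_edge`` exceeds both image dimensions.
    """
    if tile_edge < 1:
        raise ValueError(f"tile_edge must be >= 1, got {tile_edge}")
    rows, cols = image.scatter.shape
    if tile_edge > rows and tile_edge > cols:
        raise ValueError(f"tile_edge {tile_edge} exceeds both image dimensions {rows}x{cols}")
    nr, nc = rows // tile_edge, cols // tile_edge
    fl = image.fluorescence[: nr * tile_edge, : nc * tile_edge]
    sc = image.scatter[: nr * tile_edge, : nc * tile_edge]
    fl = fl.reshape(nr, tile_edge, nc, tile_edge).swapaxes(1, 2)
    sc = sc.reshape(nr, tile_edge, nc, tile_edge).swapaxes(1, 2)
    integral = fl.sum(axis=(2, 3), dtype=float).ravel()
    maxpixel = fl.max(axis=(2, 3)).ravel().astype(float) if fl.size else np.empty(0)
    scatter = sc.max(axis=(2, 3)).ravel().astype(float) if sc.size else np.empty(0)
    rr, cc = np.divmod(np.arange(nr * nc), max(nc, 1))
    table = pd.DataFrame(
        {
            "patient_id": image.patient_id,
            "marker": image.marker,
            "is_negctrl": image.negative_control,
            "phantom_id": np.arange(nr * nc),
            "row": rr,
            "col": cc,
            "scatter": scatter,
            "integral": integral,
            "maxpixel": maxpixel,
        }
    )
    table.attrs["tile_edge"] = tile_edge
    table.attrs["tile_area"] = tile_edge * tile_edge
    return table


def mask_tissue(table: pd.DataFrame, rule: float | str = "auto") -> pd.DataFrame:
    """Retain exactly the phantoms whose scatter maximum exceeds a cutoff.

    ``rule`` is either a fixed scatter value or ``"auto"`` for a two-class
    Otsu split of the scatter-maximum histogram.  The resolved cutoff is
    stored in ``result.attrs["scatter_cutoff"]`` and reused on re-application,
    which makes the operation idempotent under the automatic rule as well.

    An empty result is returned with a ``UserWarning`` (section unusable),
    never silently.
    """
    if "scatter" not in table.columns:
        raise ValueError("phantom table has no scatter column")
    if isinstance(rule, str):
        if rule != "auto":
            raise ValueError(f"unknown tissue rule {rule!r}")
        if "scatter_cutoff" in table.attrs:
            cutoff = float(table.attrs["scatter_cutoff"])
        else:
            values = table["scatter"].to_numpy(dtype=float)
            if len(values) == 0:
                cutoff = 0.0
            elif np.ptp(values) == 0:
                cutoff = float(values[0]) - 1.0  # constant scatter: keep everything
            else:
                cutoff = float(threshold_otsu(values))
    else:
        cutoff = float(rule)
    out = table.loc[table["scatter"] > cutoff].copy()
    out.attrs.update(table.attrs)
    out.attrs["scatter_cutoff"] = cutoff
    if len(out) == 0:
        warnings.warn(
            f"no phantom exceeds the scatter cutoff {cutoff:g}; section unusable",
            UserWarning,
            stacklevel=2,
        )
    return out
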