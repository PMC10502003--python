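"""Segmentation-quality metrics: DSC, RVD, ASSD and MSSD.

Overlap metrics (Dice, relative volume difference) are voxel-count based.
Surface distances are computed between mask *boundaries* — the foreground
voxels having at least one background 6-neighbour, with out-of-grid
counting as background — using the exact Euclidean distance transform with
anisotropic sampling, so all distances are in millimetres regardless of
voxel shape.

ASSD averages the nearest boundary-to-boundary distances taken in both
directions; MSSD is the maximum of those distances, i.e. the Hausdorff
distance between the two boundaries.

Degenerate masks never crash the pipeline: a catastrophically empty
prediction must remain rankable as an outlier, so exactly-one-side-empty
pairs get DSC 0, RVD 1 (prediction empty; undefined and NaN when the
reference is empty) and surface distances capped at the image physical
diagonal, all flagged via ``surface_defined``/``rvd_defined``.  Two empty
masks agree perfectly (DSC 1, distances 0), also flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import BinaryMask, check_same_geometry

__all__ = [
    "MetricRecord",
    "METRIC_NAMES",
    "CSV_COLUMNS",
    "dice",
    "rvd",
    "rvd_signed",
    "boundary_voxels",
    "boundary_mask",
    "assd",
    "mssd",
    "surface_distances",
    "evaluate",
    "records_to_frame",
    "write_metrics_csv",
    "read_metrics_csv",
]

#: Metric short names in their canonical order.
METRIC_NAMES = ("dsc", "rvd", "assd", "mssd")

#: Fixed column layout of the on-disk metric table.
CSV_COLUMNS = ("organ", "image_id", "source_id", "dsc", "rvd",
               "assd_mm", "mssd_mm", "surface_defined")

_STRUCT_6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass(frozen=True)
class MetricRecord:
    """All four metrics of one (image, source) pair.

    ``surface_defined`` is False iff a degenerate-mask fallback was applied
    to the surface distances; ``rvd_defined`` is False iff RVD is undefined
    (empty reference with non-empty prediction, reported as NaN).
    """

    organ: str
    image_id: str
    source_id: str
    dsc: float
    rvd: float
    assd_mm: float
    mssd_mm: float
    surface_defined: bool = True
    rvd_defined: bool = True

    def loss(self, metric: str) -> float:
        """The loss form of a metric: Dice loss 1−DSC for ``dsc``, the
        metric itself otherwise (all are minimised)."""
        if metric == "dsc":
            return 1.0 - self.dsc
        return getattr(self, metric if metric == "rvd" else f"{metric}_mm")


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|), in [0, 1].

    Symmetric.  Both-empty masks return 1.0 (perfect-agreement limit).
    """
    check_same_geometry(a, b)
    na, nb = a.volume_voxels, b.volume_voxels
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a.voxels & b.voxels))
    return 2.0 * inter / (na + nb)


def rvd(pred: BinaryMask, ref: BinaryMask) -> float:
    """Absolute relative volume difference | |pred| − |ref| | / |ref|.

    Ignores overlap entirely.  Both empty → 0.0; empty reference with a
    non-empty prediction is undefined → NaN.
    """
    check_same_geometry(pred, ref)
    vp, vr = pred.volume_voxels, ref.volume_voxels
    if vr == 0:
        return 0.0 if vp == 0 else math.nan
    return abs(vp - vr) / vr


def rvd_signed(pred: BinaryMask, ref: BinaryMask) -> float:
    """Signed variant (|pred| − |ref|) / |ref|; positive = over-segmentation."""
    check_same_geometry(pred, ref)
    vp, vr = pred.volume_voxels, ref.volume_voxels
    if vr == 0:
        return 0.0 if vp == 0 else math.nan
    return (vp - vr) / vr


def boundary_mask(mask: BinaryMask) -> np.ndarray:
    """Boolean array marking the boundary: foreground voxels with at least
    one background 6-neighbour, the grid border counting as background."""
    fg = mask.voxels
    interior = ndimage.binary_erosion(fg, structure=_STRUCT_6, border_value=0)
    return fg & ~interior


def boundary_voxels(mask: BinaryMask) -> np.ndarray:
    """Boundary voxel coordinates, shape (n, 3).  Empty mask → (0, 3)."""
    return np.argwhere(boundary_mask(mask))


def _crop_slices(union: np.ndarray) -> tuple[slice, slice, slice]:
    # 1-voxel pad keeps the out-of-grid-is-background convention intact:
    # boundary status is computed on the full grid before cropping.
    idx = np.argwhere(union)
    lo = np.maximum(idx.min(axis=0) - 1, 0)
    hi = np.minimum(idx.max(axis=0) + 2, union.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))  # type: ignore[return-value]


def surface_distances(pred: BinaryMask, ref: BinaryMask) -> np.ndarray:
    """The pooled multiset of directed nearest boundary distances (both
    directions), in mm.  Raises on empty input masks."""
    check_same_geometry(pred, ref)
    if pred.is_empty() or ref.is_empty():
        raise ValueError("surface distances require two non-empty masks")
    bnd_p, bnd_r = boundary_mask(pred), boundary_mask(ref)
    # Distances only involve boundary voxels; crop to their joint bounding
    # box so the distance transforms run on a small grid.  Exact: every
    # nearest boundary voxel lies inside the box.
    sl = _crop_slices(bnd_p | bnd_r)
    bnd_p, bnd_r = bnd_p[sl], bnd_r[sl]
    dt_r = ndimage.distance_transform_edt(~bnd_r, sampling=pred.spacing)
    dt_p = ndimage.distance_transform_edt(~bnd_p, sampling=pred.spacing)
    return np.concatenate([dt_r[bnd_p], dt_p[bnd_r]])


def _degenerate_distance(pred: BinaryMask, ref: BinaryMask) -> float | None:
    """None when both masks are non-empty; the degenerate fallback value
    otherwise (0 for both-empty, the physical diagonal for one-empty)."""
    ep, er = pred.is_empty(), ref.is_empty()
    if not ep and not er:
        return None
    return 0.0 if (ep and er) else pred.physical_diagonal_mm


def assd(pred: BinaryMask, ref: BinaryMask) -> float:
    """Average symmetric surface distance in mm (mean over the union of
    both directed nearest-distance multisets).  Symmetric."""
    cap = _degenerate_distance(pred, ref)
    if cap is not None:
        return cap
    return float(surface_distances(pred, ref).mean())


def mssd(pred: BinaryMask, ref: BinaryMask) -> float:
    """Maximum symmetric surface distance in mm — the Hausdorff distance
    between the two boundaries.  Symmetric."""
    cap = _degenerate_distance(pred, ref)
    if cap is not None:
        return cap
    return float(surface_distances(pred, ref).max())


def evaluate(pred: BinaryMask, ref: BinaryMask, *, organ: str = "",
             image_id: str = "", source_id: str = "",
             include_surface: bool = True) -> MetricRecord:
    """Compute all four metrics of a (prediction, reference) pair.

    ``include_surface=False`` skips the distance transforms (the dominant
    cost) and reports NaN surface distances with ``surface_defined=False``;
    useful for overlap-only experiments such as Dice-vs-ensemble-size
    curves.
    """
    check_same_geometry(pred, ref)
    d = dice(pred, ref)
    ep, er = pred.is_empty(), ref.is_empty()
    r = rvd(pred, ref)
    rvd_ok = not math.isnan(r)
    if not include_surface:
        return MetricRecord(organ, image_id, source_id, d, r,
                            math.nan, math.nan, False, rvd_ok)
    cap = _degenerate_distance(pred, ref)
    if cap is not None:
        return MetricRecord(organ, image_id, source_id, d, r, cap, cap,
                            surface_defined=False, rvd_defined=rvd_ok)
    dists = surface_distances(pred, ref)
    return MetricRecord(organ, image_id, source_id, d, r,
                        float(dists.mean()), float(dists.max()),
                        surface_defined=not (ep or er), rvd_defined=rvd_ok)


def records_to_frame(records: Iterable[MetricRecord]) -> pd.DataFrame:
    """Stack records into the fixed-column metric table."""
    rows = [{c: getattr(r, c) for c in CSV_COLUMNS} for r in records]
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def write_metrics_csv(records: Iterable[MetricRecord] | pd.DataFrame,
                      path: str | Path) -> None:
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metric table {path} missing columns {sorted(missing)}")
    return df
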