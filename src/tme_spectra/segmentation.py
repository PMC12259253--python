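"""Nuclear segmentation and per-cell quantification.

Mirrors a classical IMC quantification stage: nuclei are detected on the
summed DNA channels (Gaussian smoothing, threshold, connected components),
every nucleus is expanded by a fixed Euclidean radius (default 3 px) into a
cell object, and overlap between neighbouring expansions is resolved at the
perpendicular bisector between nuclei — i.e. the locus at the median of the
two nucleus distances — implemented as nearest-centroid (Voronoi) assignment.
Mean raw intensity per channel over each cell mask yields the cell table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import gaussian, threshold_otsu

from .core_data import CellTable, MultichannelImage

__all__ = ["SegmentationParams", "LabelMask", "detect_nuclei", "expand_to_cells", "quantify_cells"]

#: 4-connectivity structuring element (no diagonal bridges between nuclei)
_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class SegmentationParams:
    """Parameters of the nuclear-detection + expansion stage.

    ``nucleus_threshold=None`` selects Otsu's threshold on the smoothed DNA
    image (keeps the pipeline headless); pass an absolute value to override.
    """

    dna_channels: tuple[str, ...] = ("DNA", "H3")
    smoothing_sigma_px: float = 1.0
    nucleus_threshold: float | None = None
    min_nucleus_area_px: int = 4
    expansion_radius_px: int = 3

    def __post_init__(self) -> None:
        if self.expansion_radius_px < 0:
            raise ValueError("expansion_radius_px must be >= 0")
        if self.min_nucleus_area_px < 1:
            raise ValueError("min_nucleus_area_px must be >= 1")


@dataclass
class LabelMask:
    """H x W integer label image (0 = background) plus nucleus centroids."""

    labels: np.ndarray
    centroids: dict[int, tuple[float, float]] = field(default_factory=dict)  # label -> (y, x)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))


def detect_nuclei(image: MultichannelImage, params: SegmentationParams) -> LabelMask:
    """Detect nuclei on the summed DNA channels.

    Smooth, threshold (Otsu by default), label 4-connected components, drop
    components below the minimum area. An image with no suprathreshold pixel
    yields an empty mask with a warning rather than an error.
    """
    dna = np.zeros(image.shape_yx, dtype=np.float64)
    for name in params.dna_channels:
        dna += image.channel(name)
    if params.smoothing_sigma_px > 0:
        dna = gaussian(dna, sigma=params.smoothing_sigma_px, preserve_range=True)

    thr = params.nucleus_threshold
    if thr is None:
        if np.ptp(dna) == 0:
            thr = np.inf  # flat image: nothing to segment
        else:
            thr = float(threshold_otsu(dna))
    fg = dna > thr
    if not fg.any():
        warnings.warn("no pixel above nucleus threshold; empty mask", stacklevel=2)
        return LabelMask(labels=np.zeros(image.shape_yx, dtype=np.int32))

    labels, n = ndimage.label(fg, structure=_STRUCTURE_4)
    if params.min_nucleus_area_px > 1 and n:
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas < params.min_nucleus_area_px)
        small = small[small > 0]
        if small.size:
            labels[np.isin(labels, small)] = 0
            labels, n = _relabel_sequential(labels)
    centroids = _centroids(labels, n)
    return LabelMask(labels=labels.astype(np.int32), centroids=centroids)


def _relabel_sequential(labels: np.ndarray) -> tuple[np.ndarray, int]:
    vals = np.unique(labels)
    vals = vals[vals > 0]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[vals] = np.arange(1, len(vals) + 1, dtype=np.int32)
    return lut[labels], len(vals)


def _centroids(labels: np.ndarray, n: int) -> dict[int, tuple[float, float]]:
    if n == 0:
        return {}
    cy = ndimage.mean(np.indices(labels.shape)[0], labels, index=np.arange(1, n + 1))
    cx = ndimage.mean(np.indices(labels.shape)[1], labels, index=np.arange(1, n + 1))
    return {k + 1: (float(cy[k]), float(cx[k])) for k in range(n)}


def expand_to_cells(nuclei: LabelMask, params: SegmentationParams) -> LabelMask:
    """Expand each nucleus by ``expansion_radius_px`` (Euclidean) into a cell.

    Membership: a background pixel joins a cell iff it lies within the radius
    of some nucleus pixel. Contested pixels (reachable from several nuclei)
    are assigned to the nucleus with the nearest centroid, which places the
    inter-cell boundary on the perpendicular bisector between the two nuclei;
    exact centroid-distance ties go to the lowest label. Nucleus pixels keep
    their labels, so expansion never merges, splits, or deletes a label.
    """
    labels = nuclei.labels
    n = nuclei.n_labels
    if n == 0 or params.expansion_radius_px == 0:
        return LabelMask(labels=labels.copy(), centroids=dict(nuclei.centroids))

    dist = ndimage.distance_transform_edt(labels == 0)
    in_range = (dist <= params.expansion_radius_px) & (labels == 0)

    centroids = nuclei.centroids or _centroids(labels, n)
    order = sorted(centroids)  # ascending label; ties resolved to lowest label
    pts = np.array([centroids[k] for k in order], dtype=float)
    lab_of = np.array(order, dtype=np.int32)
    tree = cKDTree(pts)

    ys, xs = np.nonzero(in_range)
    if ys.size:
        q = np.stack([ys, xs], axis=1).astype(float)
        k = min(4, len(pts))
        d, idx = tree.query(q, k=k)
        if k == 1:
            d, idx = d[:, None], idx[:, None]
        # among equidistant nearest centroids take the lowest label
        best = np.where(np.isclose(d, d[:, :1], rtol=0.0, atol=1e-9), lab_of[idx], np.iinfo(np.int32).max).min(axis=1)
        out = labels.copy()
        out[ys, xs] = best.astype(np.int32)
    else:
        out = labels.copy()
    return LabelMask(labels=out, centroids=dict(centroids))


def quantify_cells(
    mask: LabelMask,
    image: MultichannelImage,
    markers: Sequence[str] | None = None,
) -> CellTable:
    """One row per cell: centroid, area, and mean raw intensity per channel."""
    labels = mask.labels
    if labels.shape != image.shape_yx:
        raise ValueError(f"mask shape {labels.shape} != image shape {image.shape_yx}")
    markers = list(markers or image.channel_names)
    n = mask.n_labels
    if n == 0:
        return CellTable.empty(markers)

    flat = labels.ravel()
    counts = np.bincount(flat, minlength=n + 1)[1:].astype(float)
    yy, xx = np.indices(labels.shape)
    cy = np.bincount(flat, weights=yy.ravel(), minlength=n + 1)[1:] / counts
    cx = np.bincount(flat, weights=xx.ravel(), minlength=n + 1)[1:] / counts

    means = {}
    for name in markers:
        ch = image.channel(name).ravel()
        means[name] = np.bincount(flat, weights=ch, minlength=n + 1)[1:] / counts

    df = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1, dtype=np.int64),
            "case_id": image.case_id,
            "roi_id": image.roi_id,
            "x_px": cx,
            "y_px": cy,
            "area_px": counts.astype(np.int64),
            "population": "unassigned",
            "cluster": pd.array([pd.NA] * n, dtype="Int64"),
        }
    )
    for name in markers:
        df[name] = means[name]
    return CellTable(df, markers)
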