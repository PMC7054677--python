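"""Nucleus and plaque segmentation.

Nuclei: Gaussian blur of the DAPI channel (sigma 0.72 um) -> Otsu
binarisation -> Euclidean distance map -> watershed split of touching
objects.  Plaques: Gaussian blur of the 4G8 channel (sigma 7.2 um) -> Otsu
-> 8-connected components; only objects strictly above 720 um^2 count as
plaques.

The Otsu threshold is computed here by exhaustive search over candidate
thresholds maximising the between-class variance, with ties resolved to the
lowest threshold; pixels strictly above the threshold are foreground.  This
convention is shared by the per-cell marker-positivity classifier in
:mod:`plaquekit.cell_quant`.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .imgio import MultichannelSection

__all__ = [
    "SegmentationParams",
    "LabelMask",
    "otsu_threshold",
    "otsu_from_histogram",
    "segment_nuclei",
    "segment_plaques",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Physical-unit segmentation parameters.

    sigma_nucleus_um : Gaussian blur scale for DAPI (default 0.72 um).
    sigma_plaque_um  : Gaussian blur scale for 4G8 (default 7.2 um).
    min_plaque_area_um2 : minimum plaque area, strict ``>`` (default 720 um^2).
    n_bins : histogram resolution for image-level Otsu.
    """

    sigma_nucleus_um: float = 0.72
    sigma_plaque_um: float = 7.2
    min_plaque_area_um2: float = 720.0
    n_bins: int = 256

    def __post_init__(self) -> None:
        if min(self.sigma_nucleus_um, self.sigma_plaque_um, self.min_plaque_area_um2) <= 0:
            raise ValueError("segmentation parameters must be strictly positive")


@dataclass
class LabelMask:
    """Integer-labelled segmentation with per-region physical measurements.

    ``labels`` holds 0 for background and 1..K for regions, numbered by
    raster order of each region's first pixel.  ``regions`` is a DataFrame
    with ``label``, ``area_um2``, ``centroid_x_um``, ``centroid_y_um`` and
    bounding box columns.
    """

    labels: np.ndarray
    pixel_size_um: float

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())

    @cached_property
    def regions(self) -> pd.DataFrame:
        k = self.n_regions
        if k == 0:
            return pd.DataFrame(
                columns=[
                    "label", "area_um2", "centroid_x_um", "centroid_y_um",
                    "bbox_min_row", "bbox_min_col", "bbox_max_row", "bbox_max_col",
                ]
            )
        idx = np.arange(1, k + 1)
        counts = ndi.sum_labels(np.ones_like(self.labels), self.labels, idx)
        centroids = ndi.center_of_mass(np.ones_like(self.labels), self.labels, idx)
        rows = np.array([c[0] for c in centroids])
        cols = np.array([c[1] for c in centroids])
        objs = ndi.find_objects(self.labels)
        bbox = np.array(
            [(s[0].start, s[1].start, s[0].stop, s[1].stop) for s in objs if s is not None]
        )
        return pd.DataFrame(
            {
                "label": idx,
                "area_um2": counts * self.pixel_size_um**2,
                "centroid_x_um": cols * self.pixel_size_um,
                "centroid_y_um": rows * self.pixel_size_um,
                "bbox_min_row": bbox[:, 0],
                "bbox_min_col": bbox[:, 1],
                "bbox_max_row": bbox[:, 2],
                "bbox_max_col": bbox[:, 3],
            }
        )

    def to_tiff(self, path: str | Path) -> Path:
        """Export the label grid as a 16-bit single-channel TIFF."""
        path = Path(path)
        if self.n_regions > np.iinfo(np.uint16).max:
            raise ValueError("more than 65535 regions; cannot export as 16-bit")
        tifffile.imwrite(path, self.labels.astype(np.uint16))
        return path


def otsu_from_histogram(counts: np.ndarray, values: np.ndarray) -> float:
    """Otsu threshold for a discrete intensity histogram.

    Exhaustively evaluates every bin value ``t`` as a candidate threshold
    (classes: ``value <= t`` vs ``value > t``) and returns the ``t``
    maximising the between-class variance ``w0*w1*(mu0-mu1)^2``; ties
    resolve to the lowest threshold.  If all mass sits in one bin the bin's
    value is returned (foreground then empty under the strict-``>`` rule).
    """
    counts = np.asarray(counts, dtype=float)
    values = np.asarray(values, dtype=float)
    if counts.shape != values.shape or counts.ndim != 1:
        raise ValueError("counts and values must be 1D and of equal length")
    keep = counts > 0
    if not np.any(keep):
        raise ValueError("empty histogram: no nonempty bin")
    counts, values = counts[keep], values[keep]
    order = np.argsort(values, kind="stable")
    counts, values = counts[order], values[order]
    if len(values) == 1:
        return float(values[0])

    total = counts.sum()
    w0 = np.cumsum(counts) / total            # mass at value <= t, per candidate t
    mu_cum = np.cumsum(counts * values) / total
    mu_tot = mu_cum[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / w0
        mu1 = (mu_tot - mu_cum) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between = np.where(w1 <= 0, 0.0, var_between)
    # ties resolve to the lowest threshold; a relative tolerance keeps the
    # rule stable when mathematically equal variances round differently
    vmax = float(var_between.max())
    best = int(np.flatnonzero(var_between >= vmax - 1e-12 * max(vmax, 1e-300))[0])
    return float(values[best])


def otsu_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Histogram-based Otsu threshold for an intensity image.

    The image is binned into ``n_bins`` equal-width bins between its minimum
    and maximum; candidate thresholds are the bin centres.  A constant image
    returns its constant value (empty foreground).
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    lo, hi = float(image.min()), float(image.max())
    if lo == hi:
        return lo
    counts, edges = np.histogram(image, bins=n_bins, range=(lo, hi))
    centres = 0.5 * (edges[:-1] + edges[1:])
    return otsu_from_histogram(counts, centres)


def _relabel_raster_order(labels: np.ndarray) -> np.ndarray:
    """Renumber regions 1..K by raster order of each region's first pixel."""
    flat = labels.ravel()
    uniq, first_idx = np.unique(flat, return_index=True)
    fg = uniq > 0
    uniq, first_idx = uniq[fg], first_idx[fg]
    if uniq.size == 0:
        return labels
    order = np.argsort(first_idx, kind="stable")
    mapping = np.zeros(int(flat.max()) + 1, dtype=labels.dtype)
    mapping[uniq[order]] = np.arange(1, uniq.size + 1, dtype=labels.dtype)
    return mapping[labels]


def _blur(image: np.ndarray, sigma_um: float, pixel_size_um: float) -> np.ndarray:
    return ndi.gaussian_filter(image, sigma=sigma_um / pixel_size_um, mode="reflect")


def segment_nuclei(
    section: MultichannelSection,
    params: SegmentationParams = SegmentationParams(),
    channel: str = "DAPI",
) -> LabelMask:
    """Segment nuclei: blur -> Otsu -> EDT -> watershed split.

    Touching nuclei merged by the blur/threshold are separated by a
    watershed on the negated Euclidean distance map, seeded at distance-map
    local maxima with a minimum seed separation of ``2 * sigma_nucleus_um``.
    Any foreground component left without a seed keeps one seed at its
    distance maximum, so the watershed can only split components, never
    merge them.
    """
    img = section.channel(channel)
    px = section.pixel_size_um
    blurred = _blur(img, params.sigma_nucleus_um, px)
    thr = otsu_threshold(blurred, params.n_bins)
    binary = blurred > thr
    if not binary.any():
        return LabelMask(np.zeros(img.shape, dtype=np.int32), px)

    distance = ndi.distance_transform_edt(binary)
    min_sep = max(1, int(round(2.0 * params.sigma_nucleus_um / px)))
    peaks = peak_local_max(
        distance, min_distance=min_sep, labels=binary, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i

    # guarantee every connected component owns at least one marker
    comps, n_comp = ndi.label(binary, structure=np.ones((3, 3), dtype=int))
    seeded = np.unique(comps[markers > 0])
    next_id = len(peaks) + 1
    for comp_id in range(1, n_comp + 1):
        if comp_id not in seeded:
            inside = comps == comp_id
            flat = np.where(inside.ravel(), distance.ravel(), -1.0)
            r, c = np.unravel_index(int(np.argmax(flat)), img.shape)
            markers[r, c] = next_id
            next_id += 1

    labels = watershed(-distance, markers=markers, mask=binary, connectivity=2)
    return LabelMask(_relabel_raster_order(labels.astype(np.int32)), px)


def segment_plaques(
    section: MultichannelSection,
    params: SegmentationParams = SegmentationParams(),
    channel: str = "4G8",
) -> LabelMask:
    """Segment plaques: blur -> Otsu -> 8-connected components -> area filter.

    Components with area <= ``min_plaque_area_um2`` are discarded (the size
    rule is a strict ``>``); survivors are renumbered in raster order.
    """
    img = section.channel(channel)
    px = section.pixel_size_um
    blurred = _blur(img, params.sigma_plaque_um, px)
    thr = otsu_threshold(blurred, params.n_bins)
    binary = blurred > thr
    labels, n = ndi.label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return LabelMask(np.zeros(img.shape, dtype=np.int32), px)
    counts = ndi.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    areas = counts * px**2
    keep = np.flatnonzero(areas > params.min_plaque_area_um2) + 1
    mapping = np.zeros(n + 1, dtype=np.int32)
    mapping[keep] = np.arange(1, len(keep) + 1)
    return LabelMask(_relabel_raster_order(mapping[labels]), px)
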