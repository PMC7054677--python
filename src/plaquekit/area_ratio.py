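"""Stained-area-fraction analysis: BACE1/4G8 ratio and pFTAA area fraction.

Workflow: each image is reduced to a contrast-stretched greyscale grid; one
fixed threshold per channel is fitted for the whole run from the pooled
pixel mean and SD of all images of that channel (threshold = mean + k*SD,
k = 2 by default); the stained fraction of an image is the proportion of
pixels strictly above the threshold.  Image quality control compares each
image's summary features (per-channel mean and variance) against (i) all
other images of the same animal and (ii) all other images of the same
experimental group; an image outside the inclusive mean +/- 2*SD band of
either comparison set, on any feature, is excluded from downstream
analysis.  Per image the BACE1 stained fraction is normalised to the 4G8
stained fraction of the same image, the per-animal median ratio is taken,
and groups are compared on animal values.

The greyscale conversion here is lossless (linear percentile stretch); no
compressed intermediate is written.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage.draw import polygon2mask

from .imgio import MultichannelSection

__all__ = [
    "FixedThreshold",
    "to_greyscale_contrast",
    "fit_fixed_threshold",
    "fit_fixed_threshold_from_stats",
    "stained_fraction",
    "stained_fraction_from_histogram",
    "qc_filter",
    "bace1_4g8_ratio",
    "pftaa_area_fraction",
]

log = logging.getLogger(__name__)

DISPLAY_MAX = 255.0
STRETCH_PCT = (0.35, 99.65)


@dataclass(frozen=True)
class FixedThreshold:
    """One run-wide analysis threshold with its provenance statistics.

    threshold = pooled_mean + k * pooled_sd over every pixel of every image
    of ``channel`` in the run.
    """

    channel: str
    threshold: float
    pooled_mean: float
    pooled_sd: float
    k: float


def to_greyscale_contrast(
    section: MultichannelSection | np.ndarray,
    channel: str | None = None,
) -> np.ndarray:
    """Contrast-stretched greyscale conversion of one channel.

    Linear stretch mapping the 0.35th/99.65th intensity percentiles to
    [0, 255], clipped; a deterministic, lossless realisation of batch
    "contrast-optimised greyscale" conversion.  A constant image cannot be
    stretched and is returned unchanged (with a warning).
    """
    img = section.channel(channel) if isinstance(section, MultichannelSection) else np.asarray(section, dtype=float)
    lo, hi = np.percentile(img, STRETCH_PCT)
    if hi <= lo:
        warnings.warn("constant image: contrast stretch skipped", stacklevel=2)
        return img.astype(float).copy()
    return np.clip((img - lo) / (hi - lo) * DISPLAY_MAX, 0.0, DISPLAY_MAX)


def fit_fixed_threshold(
    images: Iterable[np.ndarray], channel: str = "", k: float = 2.0
) -> FixedThreshold:
    """Fit the run-wide fixed threshold from all images of one channel.

    Pools every pixel of every image; threshold = pooled mean + k * SD
    (population SD over the pooled pixels).
    """
    n = 0
    s = 0.0
    ss = 0.0
    for img in images:
        a = np.asarray(img, dtype=float)
        n += a.size
        s += float(a.sum())
        ss += float(np.square(a).sum())
    if n == 0:
        raise ValueError("no images supplied")
    return fit_fixed_threshold_from_stats(n, s, ss, channel=channel, k=k)


def fit_fixed_threshold_from_stats(
    n_pixels: int, pixel_sum: float, pixel_sumsq: float, channel: str = "", k: float = 2.0
) -> FixedThreshold:
    """Fixed threshold from streamed pixel moments (sum and sum of squares)."""
    mean = pixel_sum / n_pixels
    var = max(pixel_sumsq / n_pixels - mean**2, 0.0)
    sd = float(np.sqrt(var))
    return FixedThreshold(channel, mean + k * sd, mean, sd, k)


def stained_fraction(image: np.ndarray, threshold: float) -> float:
    """Fraction of pixels strictly above the threshold, in [0, 1]."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    image = np.asarray(image)
    return float(np.count_nonzero(image > threshold)) / image.size


def stained_fraction_from_histogram(
    counts: np.ndarray, bin_values: np.ndarray, threshold: float
) -> float:
    """Stained fraction from a discrete intensity histogram.

    Mirrors the histogram-extraction route of the original workflow: counts
    whose bin value lies strictly above the threshold are stained.
    """
    counts = np.asarray(counts, dtype=float)
    bin_values = np.asarray(bin_values, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty histogram")
    return float(counts[bin_values > threshold].sum() / total)


def _band_flags(
    values: np.ndarray, groups: pd.Series, n_sd: float, min_set: int
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out mean +/- n_sd*SD band check within comparison sets.

    Returns (flagged, checked): ``flagged[i]`` True when value i lies
    strictly outside the inclusive band of the *other* members of its set;
    ``checked[i]`` False when the set of others has fewer than ``min_set``
    members (QC skipped for that set).
    """
    flagged = np.zeros(len(values), dtype=bool)
    checked = np.zeros(len(values), dtype=bool)
    for _, idx in groups.groupby(groups).groups.items():
        pos = groups.index.get_indexer(idx)
        v = values[pos]
        m = len(v)
        if m - 1 < min_set:
            continue
        s, ss = v.sum(), np.square(v).sum()
        loo_mean = (s - v) / (m - 1)
        with np.errstate(invalid="ignore"):
            loo_var = np.maximum((ss - v**2) / (m - 1) - loo_mean**2, 0.0)
            # unbiased (ddof=1) SD of the m-1 others
            loo_sd = np.sqrt(loo_var * (m - 1) / max(m - 2, 1))
        checked[pos] = True
        flagged[pos] = np.abs(v - loo_mean) > n_sd * loo_sd
    return flagged, checked


def qc_filter(
    features: pd.DataFrame,
    feature_cols: Sequence[str],
    animal_col: str = "animal_id",
    group_col: str = "group",
    n_sd: float = 2.0,
    min_set: int = 3,
) -> pd.DataFrame:
    """Cross-comparison image QC with an inclusive mean +/- ``n_sd``*SD band.

    Each image's features are compared against (i) the other images of the
    same animal and (ii) the other images of the same experimental group
    (leave-one-out statistics, so an extreme image cannot mask itself).  An
    image is excluded when any feature lies outside the band in either
    comparison; a value exactly on the band boundary is retained.
    Comparison sets smaller than ``min_set`` are skipped.

    Returns ``features`` extended with ``excluded`` and ``exclusion_basis``
    ("same-animal", "same-group", "both" or "").
    """
    out = features.reset_index(drop=True).copy()
    animal_hit = np.zeros(len(out), dtype=bool)
    group_hit = np.zeros(len(out), dtype=bool)
    for col in feature_cols:
        v = out[col].to_numpy(dtype=float)
        fa, _ = _band_flags(v, out[animal_col], n_sd, min_set)
        fg, _ = _band_flags(v, out[group_col], n_sd, min_set)
        animal_hit |= fa
        group_hit |= fg
    out["excluded"] = animal_hit | group_hit
    basis = np.select(
        [animal_hit & group_hit, animal_hit, group_hit],
        ["both", "same-animal", "same-group"],
        default="",
    )
    out["exclusion_basis"] = basis
    n_exc = int(out["excluded"].sum())
    if n_exc:
        log.info("QC excluded %d/%d images (%.1f%%)", n_exc, len(out), 100 * n_exc / len(out))
    return out


def bace1_4g8_ratio(
    fractions: pd.DataFrame,
    bace1_col: str = "frac_BACE1",
    g8_col: str = "frac_4G8",
    animal_col: str = "animal_id",
    group_col: str = "group",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-image BACE1/4G8 stained-fraction ratio and per-animal medians.

    ``fractions`` holds one row per QC-passing image with the two stained
    fractions.  Images with a zero 4G8 fraction are dropped with a warning;
    animals left without images are dropped.  Returns (per-image table with
    ``ratio`` column, per-animal medians table).
    """
    df = fractions.copy()
    zero = df[g8_col] <= 0
    if zero.any():
        log.warning("dropping %d image(s) with zero 4G8 stained fraction", int(zero.sum()))
        df = df[~zero]
    df["ratio"] = df[bace1_col] / df[g8_col]
    animals = (
        df.groupby([group_col, animal_col], sort=True)["ratio"].median().reset_index()
    )
    return df, animals


def pftaa_area_fraction(
    section: MultichannelSection | np.ndarray,
    roi_polygon_um: np.ndarray,
    threshold: float,
    channel: str = "pFTAA",
    pixel_size_um: float | None = None,
) -> float:
    """Percent area of an ROI polygon above a shared threshold.

    The polygon is given as (x, y) vertices in um; the same threshold is
    applied to every section of a run.  Returns
    100 * (pixels above threshold inside ROI) / (pixels inside ROI).
    """
    if isinstance(section, MultichannelSection):
        img = section.channel(channel)
        px = section.pixel_size_um
    else:
        img = np.asarray(section, dtype=float)
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required with a bare array")
        px = pixel_size_um
    poly = np.asarray(roi_polygon_um, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise ValueError("ROI polygon needs >= 3 (x, y) vertices")
    # polygon2mask expects (row, col) vertices
    mask = polygon2mask(img.shape, poly[:, ::-1] / px)
    n_roi = int(mask.sum())
    if n_roi == 0:
        raise ValueError("ROI contains no pixels")
    return 100.0 * float(np.count_nonzero(img[mask] > threshold)) / n_roi
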