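"""Per-cell quantification of plaque-associated microglia.

The mean intensity over each segmented nuclear region measures a cell's
marker expression (Iba1, Clec7a, 4G8, ...).  Cells are called
Iba1-positive/-negative by Otsu's method on the per-cell expression values
of one image, and only Iba1-positive cells enter downstream analyses.  Each
cell gets its Euclidean distance from the nucleus centre of mass to the
nearest plaque border (0 inside a plaque) and the area of that nearest
plaque; cells within the association radius (default 30 um, inclusive) of a
plaque border count as plaque-associated.

Radial intensity profiles are computed per channel around the nucleus
centre of mass, optionally normalised by their own integral; profiles and
intensity histograms are pooled hierarchically: median over the images of
one animal, then mean +/- SEM over the animals of one group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .imgio import MultichannelSection
from .segmentation import LabelMask, otsu_from_histogram

__all__ = [
    "AssociationParams",
    "RadialProfile",
    "BinnedHistogram",
    "NO_PLAQUE",
    "measure_expression",
    "classify_positive",
    "nearest_plaque_metrics",
    "plaque_associated_summary",
    "radial_profile",
    "intensity_histogram",
    "pool_scalar",
    "pool_curves",
]

#: Sentinel distance for cells in an image containing no plaque.
NO_PLAQUE = np.inf


@dataclass(frozen=True)
class AssociationParams:
    """association_radius_um: inclusive plaque-border distance defining
    plaque-associated cells (default 30 um)."""

    association_radius_um: float = 30.0

    def __post_init__(self) -> None:
        if self.association_radius_um <= 0:
            raise ValueError("association_radius_um must be > 0")


@dataclass
class RadialProfile:
    """Radial mean-intensity curve around one centre.

    ``values[i]`` is the mean intensity over pixels whose centre distance r
    satisfies ``i*dr <= r < (i+1)*dr``; bins containing no pixel are NaN.
    When ``normalised`` the curve integrates to 1: sum(values * dr) == 1
    over the non-NaN bins.
    """

    channel: str
    dr_um: float
    values: np.ndarray
    normalised: bool = False

    @property
    def bin_centres_um(self) -> np.ndarray:
        return (np.arange(len(self.values)) + 0.5) * self.dr_um

    def normalise(self) -> "RadialProfile":
        integral = np.nansum(self.values) * self.dr_um
        if integral <= 0:
            raise ValueError("cannot normalise an all-zero profile")
        return RadialProfile(self.channel, self.dr_um, self.values / integral, True)


@dataclass
class BinnedHistogram:
    """Frequency histogram over fixed intensity bin edges.

    When ``normalised`` it is a density: sum(values * bin_width) == 1.
    """

    bin_edges: np.ndarray
    values: np.ndarray
    normalised: bool = False

    def normalise(self) -> "BinnedHistogram":
        widths = np.diff(self.bin_edges)
        integral = float(np.sum(self.values * widths))
        if integral <= 0:
            raise ValueError("cannot normalise an empty histogram")
        return BinnedHistogram(self.bin_edges, self.values / integral, True)


def measure_expression(
    nuclei: LabelMask,
    section: MultichannelSection,
    channels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean intensity of each channel over each labelled nuclear region.

    Returns one row per nucleus with ``cell_id`` (= nucleus label), the
    centroid in um and one ``mean_<channel>`` column per channel.
    """
    if nuclei.labels.shape != section.shape:
        raise ValueError(
            f"label grid {nuclei.labels.shape} does not match section {section.shape}"
        )
    channels = list(channels) if channels is not None else sorted(section.channels)
    regions = nuclei.regions
    out = pd.DataFrame(
        {
            "cell_id": regions["label"].to_numpy(dtype=int),
            "centroid_x_um": regions["centroid_x_um"].to_numpy(),
            "centroid_y_um": regions["centroid_y_um"].to_numpy(),
        }
    )
    idx = out["cell_id"].to_numpy()
    for ch in channels:
        img = section.channel(ch)
        means = (
            ndi.mean(img, labels=nuclei.labels, index=idx) if len(idx) else np.array([])
        )
        out[f"mean_{ch}"] = means
    return out


def classify_positive(values: Sequence[float]) -> np.ndarray:
    """Otsu split of per-cell expression values into negative/positive.

    The threshold is the exhaustive between-class-variance maximiser over
    the distinct observed values; cells strictly above it are positive.
    Degenerate input (all values identical, or empty) yields all-negative:
    no cell exceeds a threshold it does not strictly exceed.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return np.zeros(0, dtype=bool)
    uniq, counts = np.unique(values, return_counts=True)
    if uniq.size == 1:
        return np.zeros(values.size, dtype=bool)
    thr = otsu_from_histogram(counts.astype(float), uniq)
    return values > thr


def _border_pixels(plaques: LabelMask) -> tuple[np.ndarray, np.ndarray]:
    """Plaque border pixels: foreground with >= 1 background 4-neighbour.

    Returns (coords_rc, labels_at_border).
    """
    mask = plaques.labels > 0
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    interior = ndi.binary_erosion(mask, structure=cross, border_value=0)
    border = mask & ~interior
    rc = np.argwhere(border)
    return rc, plaques.labels[border]


def nearest_plaque_metrics(
    cells: pd.DataFrame,
    plaques: LabelMask,
    params: AssociationParams = AssociationParams(),
) -> pd.DataFrame:
    """Attach nearest-plaque distance, area and the association flag.

    Distance is measured from the nucleus centre of mass to the nearest
    plaque border pixel centre, in um; cells whose centroid falls inside a
    plaque get distance 0.  With no plaque in the image the distance is the
    ``NO_PLAQUE`` sentinel (inf), the nearest area is NaN and association is
    False.
    """
    cells = cells.copy()
    n = len(cells)
    px = plaques.pixel_size_um
    if plaques.n_regions == 0:
        cells["dist_to_plaque_border_um"] = np.full(n, NO_PLAQUE)
        cells["nearest_plaque_label"] = 0
        cells["nearest_plaque_area_um2"] = np.nan
        cells["plaque_associated"] = False
        return cells

    rc, border_labels = _border_pixels(plaques)
    tree = cKDTree(rc[:, ::-1] * px)  # (x, y) um
    pts = cells[["centroid_x_um", "centroid_y_um"]].to_numpy()
    dist, nearest_idx = tree.query(pts) if n else (np.array([]), np.array([], dtype=int))
    nearest_label = border_labels[nearest_idx] if n else np.array([], dtype=int)

    if n:
        rows = np.clip(np.round(pts[:, 1] / px).astype(int), 0, plaques.labels.shape[0] - 1)
        cols = np.clip(np.round(pts[:, 0] / px).astype(int), 0, plaques.labels.shape[1] - 1)
        inside_label = plaques.labels[rows, cols]
        inside = inside_label > 0
        dist = np.where(inside, 0.0, dist)
        nearest_label = np.where(inside, inside_label, nearest_label)

    areas = plaques.regions.set_index("label")["area_um2"]
    cells["dist_to_plaque_border_um"] = dist
    cells["nearest_plaque_label"] = nearest_label
    cells["nearest_plaque_area_um2"] = areas.reindex(nearest_label).to_numpy()
    cells["plaque_associated"] = dist <= params.association_radius_um
    return cells


def plaque_associated_summary(cells: pd.DataFrame, plaques: LabelMask) -> dict:
    """Per-image summary of Iba1-positive plaque-associated microglia.

    ``n_associated`` counts positive associated cells; the normalised count
    divides each cell by the area of its nearest plaque (cells per um^2 of
    plaque) and sums.  Undefined (None values) when the image has no plaque.
    """
    if plaques.n_regions == 0:
        return {"n_plaques": 0, "n_associated": None, "normalised_count_per_um2": None}
    sel = cells[(cells.get("iba1_positive", True) == True) & cells["plaque_associated"]]
    return {
        "n_plaques": plaques.n_regions,
        "n_associated": int(len(sel)),
        "normalised_count_per_um2": float((1.0 / sel["nearest_plaque_area_um2"]).sum()),
    }


def radial_profile(
    section: MultichannelSection,
    channel: str,
    centre_um: tuple[float, float],
    r_max_um: float = 20.0,
    dr_um: float = 0.5,
    normalised: bool = False,
) -> RadialProfile:
    """Mean intensity in concentric annuli around ``centre_um`` (x, y).

    Bin i covers radii [i*dr, (i+1)*dr); the bin value is the mean over the
    pixels whose centre falls in the annulus, NaN where the annulus contains
    no pixel (entirely outside the image).
    """
    if r_max_um <= 0 or dr_um <= 0:
        raise ValueError("r_max_um and dr_um must be > 0")
    img = section.channel(channel)
    px = section.pixel_size_um
    cx, cy = centre_um
    h, w = img.shape
    if not (0 <= cx <= (w - 1) * px and 0 <= cy <= (h - 1) * px):
        raise ValueError(f"centre {centre_um} outside image bounds")

    n_bins = int(math.ceil(r_max_um / dr_um))
    # restrict to the bounding window of the largest annulus
    r_px = r_max_um / px
    r0 = max(0, int(math.floor(cy / px - r_px)))
    r1 = min(h, int(math.ceil(cy / px + r_px)) + 1)
    c0 = max(0, int(math.floor(cx / px - r_px)))
    c1 = min(w, int(math.ceil(cx / px + r_px)) + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    radii = np.hypot(xx * px - cx, yy * px - cy)
    inside = radii < n_bins * dr_um
    bins = (radii[inside] / dr_um).astype(int)
    vals = img[r0:r1, c0:c1][inside]

    sums = np.bincount(bins, weights=vals, minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    prof = RadialProfile(channel, dr_um, means[:n_bins])
    return prof.normalise() if normalised else prof


def intensity_histogram(
    values: Sequence[float],
    bin_edges: np.ndarray,
    normalised: bool = False,
) -> BinnedHistogram:
    """Image-wise histogram of per-cell intensities over fixed bin edges."""
    counts, _ = np.histogram(np.asarray(values, dtype=float), bins=bin_edges)
    hist = BinnedHistogram(np.asarray(bin_edges, dtype=float), counts.astype(float))
    return hist.normalise() if normalised else hist


def pool_scalar(
    images: pd.DataFrame,
    value_cols: Sequence[str],
    animal_col: str = "animal_id",
    group_col: str = "group",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hierarchical pooling of per-image scalars.

    Animal value = median over that animal's images (NaN rows ignored);
    group value = mean over animals with SEM = sd/sqrt(n_animals), sd the
    n-1 sample standard deviation.  Returns (animals, groups) tables.
    Order-invariant: rows are sorted on the grouping keys.
    """
    value_cols = list(value_cols)
    animals = (
        images.groupby([group_col, animal_col], sort=True)[value_cols]
        .median()
        .reset_index()
    )
    grouped = animals.groupby(group_col, sort=True)[value_cols]
    mean = grouped.mean()
    sem = grouped.std(ddof=1) / np.sqrt(grouped.count())
    n = grouped.count()
    groups = mean.add_suffix("_mean").join(sem.add_suffix("_sem")).join(
        n.add_suffix("_n")
    ).reset_index()
    return animals, groups


def pool_curves(
    curves: pd.DataFrame,
    animal_col: str = "animal_id",
    group_col: str = "group",
    bin_col: str = "bin",
    value_col: str = "value",
) -> pd.DataFrame:
    """Element-wise hierarchical pooling of per-image curves.

    ``curves`` is long-format with one row per (image, bin).  Per animal the
    median over images is taken bin-wise, then per group the mean and SEM
    over animals.  Returns long-format (group, bin, mean, sem, n_animals).
    """
    animal = (
        curves.groupby([group_col, animal_col, bin_col], sort=True)[value_col]
        .median()
        .reset_index()
    )
    g = animal.groupby([group_col, bin_col], sort=True)[value_col]
    out = g.mean().rename("mean").to_frame()
    out["sem"] = g.std(ddof=1) / np.sqrt(g.count())
    out["n_animals"] = g.count()
    return out.reset_index()
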