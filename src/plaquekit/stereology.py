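"""Design-based stereological estimators.

Two estimators mirror standard Stereo Investigator readouts:

* Cavalieri point counting for percent area covered — counting frames are
  placed on a systematic grid with one uniform random offset (systematic
  uniform random sampling, SURS); within each frame a point lattice with a
  random sub-offset is laid down, and the area fraction is the proportion
  of ROI-hitting points that also hit the structure.  Default design for
  plaque burden: 90 x 90 um frame, 450 x 450 um grid, 10 um point spacing.

* An optical-fractionator-style density estimator for cell counts — cells
  are counted inside SURS-placed counting frames under the unbiased
  counting-frame rule (inclusion on the left/bottom edges, exclusion on the
  right/top "forbidden" edges); the estimated population is the raw count
  divided by the areal sampling fraction (frame area / grid area), and the
  density divides by ROI area times a user-defined section thickness.
  Default design for cortical astrocytes: 75 x 75 um frame, 500 x 500 um
  grid.

The z-dimension collapses to the user-defined section thickness: inputs
here are 2D coordinates, exactly as in the published readout where the
estimated population and the measured volume are divided.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

__all__ = [
    "SamplingDesign",
    "PLAQUE_DESIGN",
    "CELL_DESIGN",
    "StereologyEstimate",
    "cavalieri_area_fraction",
    "fractionator_density",
]


@dataclass(frozen=True)
class SamplingDesign:
    """Systematic sampling design in physical units (um).

    counting_frame_um : (width, height) of each counting frame.
    grid_um           : (x, y) placement period of the frames.
    point_spacing_um  : Cavalieri point lattice spacing within frames.
    section_thickness_um : thickness entering the volume term of the
        fractionator density (user-defined; the cut thickness is a study
        input, not derivable from the image).
    """

    counting_frame_um: tuple[float, float] = (90.0, 90.0)
    grid_um: tuple[float, float] = (450.0, 450.0)
    point_spacing_um: float = 10.0
    section_thickness_um: float = 40.0

    def __post_init__(self) -> None:
        fw, fh = self.counting_frame_um
        gx, gy = self.grid_um
        if fw > gx or fh > gy:
            raise ValueError("counting frame must fit inside the placement grid")
        if min(fw, fh, gx, gy, self.point_spacing_um, self.section_thickness_um) <= 0:
            raise ValueError("design lengths must be strictly positive")


PLAQUE_DESIGN = SamplingDesign((90.0, 90.0), (450.0, 450.0), 10.0)
CELL_DESIGN = SamplingDesign((75.0, 75.0), (500.0, 500.0), 10.0)


@dataclass
class StereologyEstimate:
    """estimate: the quantity (percent area, or cells/um^3); counts and the
    sampled-support sizes back it for auditability."""

    estimate: float
    n_hits: int
    n_sampled: int
    per_frame_counts: list[int]
    between_frame_cv: float


def _frame_origins(lo: float, hi: float, frame: float, period: float, offset: float) -> np.ndarray:
    """Origins of the lattice {offset + k*period} whose frame [o, o+frame)
    intersects the window [lo, hi)."""
    k0 = int(np.ceil((lo - frame - offset) / period))
    k1 = int(np.floor((hi - offset) / period))
    origins = offset + period * np.arange(k0, k1 + 1)
    return origins[(origins + frame > lo) & (origins < hi)]


def cavalieri_area_fraction(
    mask: np.ndarray,
    roi: np.ndarray,
    pixel_size_um: float,
    design: SamplingDesign = PLAQUE_DESIGN,
    seed: int | np.random.Generator = 0,
) -> StereologyEstimate:
    """Percent of ROI area covered by ``mask``, by SURS point counting.

    ``mask`` and ``roi`` are boolean grids on the same image frame.  Points
    falling outside the image or off the ROI do not enter the denominator.
    Raises if no point hits the ROI.
    """
    mask = np.asarray(mask, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if mask.shape != roi.shape:
        raise ValueError("mask and ROI must share the image frame")
    rng = seed if hasattr(seed, "uniform") else np.random.default_rng(seed)
    h, w = mask.shape
    wx, wy = w * pixel_size_um, h * pixel_size_um
    fw, fh = design.counting_frame_um
    gx, gy = design.grid_um
    sp = design.point_spacing_um

    off_x, off_y = rng.uniform(0, gx), rng.uniform(0, gy)
    sub_x, sub_y = rng.uniform(0, sp), rng.uniform(0, sp)
    ox = _frame_origins(0.0, wx, fw, gx, off_x)
    oy = _frame_origins(0.0, wy, fh, gy, off_y)

    n_in_frame_x = int(np.ceil(fw / sp))
    n_in_frame_y = int(np.ceil(fh / sp))
    lx = sub_x + sp * np.arange(n_in_frame_x)
    ly = sub_y + sp * np.arange(n_in_frame_y)
    lx = lx[lx < fw]
    ly = ly[ly < fh]
    px_x = (ox[:, None] + lx[None, :]).ravel()
    px_y = (oy[:, None] + ly[None, :]).ravel()
    px_x = px_x[(px_x >= 0) & (px_x < wx)]
    px_y = px_y[(px_y >= 0) & (px_y < wy)]

    xs, ys = np.meshgrid(px_x, px_y)
    cols = np.floor(xs.ravel() / pixel_size_um).astype(int)
    rows = np.floor(ys.ravel() / pixel_size_um).astype(int)
    ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    rows, cols = rows[ok], cols[ok]
    on_roi = roi[rows, cols]
    n_roi = int(on_roi.sum())
    if n_roi == 0:
        raise ValueError("ROI too small: no sampling point hit it")
    hits = int((mask[rows, cols] & on_roi).sum())
    return StereologyEstimate(
        estimate=100.0 * hits / n_roi,
        n_hits=hits,
        n_sampled=n_roi,
        per_frame_counts=[],
        between_frame_cv=float("nan"),
    )


def fractionator_density(
    cells_um: np.ndarray,
    roi_um: tuple[float, float, float, float],
    design: SamplingDesign = CELL_DESIGN,
    seed: int | np.random.Generator = 0,
) -> StereologyEstimate:
    """Cells per unit volume from counts in SURS counting frames.

    ``cells_um`` is an (N, 2) array of (x, y) positions; ``roi_um`` is the
    rectangle (xmin, ymin, xmax, ymax) containing them.  A cell at position
    (x, y) is counted by the frame with origin (x0, y0) iff
    ``x0 <= x < x0 + w`` and ``y0 <= y < y0 + h`` — the left/bottom edges
    include, the right/top forbidden edges exclude, so no cell can be
    counted twice by adjacent frames.  Every frame of the offset lattice
    that can intersect the ROI is used, which makes the count an unbiased
    fraction (frame area / grid area) of the true population.

    density = count * (grid area / frame area) / (ROI area * thickness).
    """
    cells = np.asarray(cells_um, dtype=float).reshape(-1, 2)
    xmin, ymin, xmax, ymax = roi_um
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("empty ROI rectangle")
    rng = seed if hasattr(seed, "uniform") else np.random.default_rng(seed)
    fw, fh = design.counting_frame_um
    gx, gy = design.grid_um

    ox = _frame_origins(xmin, xmax, fw, gx, xmin + rng.uniform(0, gx))
    oy = _frame_origins(ymin, ymax, fh, gy, ymin + rng.uniform(0, gy))
    if len(ox) == 0 or len(oy) == 0:
        raise ValueError("no counting frame lands in the ROI")

    counts = []
    total = 0
    for y0 in oy:
        in_y = (cells[:, 1] >= y0) & (cells[:, 1] < y0 + fh)
        for x0 in ox:
            c = int(np.count_nonzero(in_y & (cells[:, 0] >= x0) & (cells[:, 0] < x0 + fw)))
            counts.append(c)
            total += c

    asf = (fw * fh) / (gx * gy)  # areal sampling fraction
    est_population = total / asf
    volume = (xmax - xmin) * (ymax - ymin) * design.section_thickness_um
    arr = np.asarray(counts, dtype=float)
    cv = float(arr.std(ddof=1) / arr.mean()) if len(arr) > 1 and arr.mean() > 0 else float("nan")
    return StereologyEstimate(
        estimate=est_population / volume,
        n_hits=total,
        n_sampled=len(counts),
        per_frame_counts=counts,
        between_frame_cv=cv,
    )
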