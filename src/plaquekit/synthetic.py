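"""Ground-truthed synthetic sections and cohorts.

Renders multichannel fluorescence fields with the statistical structure the
analysis assumes, so every pipeline stage is testable against a known
truth:

* plaques — a homogeneous Poisson process of blurred bright discs with
  log-normally distributed areas; a configurable fraction (default 0.25,
  matching the observed compact/total plaque ratio) carries a dense
  "compact" core sub-disc, which doubles as the Congo-Red-like truth mask;
* nuclei — soft discs in DAPI; microglial nuclei cluster near plaques
  (density multiplier within the association radius of plaque borders);
* Iba1 — an isotropic exponentially decaying halo around each microglial
  nucleus (cell body fading out by roughly 6 um);
* 4G8 — the plaque signal plus one intracellular uptake blob per
  plaque-associated microglial cell, offset ~4 um from the nucleus centre;
* Clec7a — bimodal nuclear-region expression (activated microglia near
  plaques draw from a high mode);
* BACE1 — an annular rim of signal along plaque borders, with identical
  per-plaque amplitude in every group (a built-in null for the BACE1/4G8
  ratio);
* noise — Poisson photon noise on signal plus background, then Gaussian
  read noise, clipped at zero.  Ground truth is recorded before noise.

Cohorts assign each group a multiplicative effect on plaque count
intensity (defaults: female/male = 2.0 for the sex comparison; an
IL12p40-knockout male runs at 0.42 of the male control, i.e. a 58%
reduction in deposited area).  Generation is deterministic given the seed;
per-image seeds derive from (group, animal, image) indices so adding
images never perturbs existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imgio import MultichannelSection, write_section

__all__ = [
    "SceneParams",
    "CohortParams",
    "SectionTruth",
    "generate_section",
    "iter_cohort",
    "generate_cohort",
]

ALL_CHANNELS = ("DAPI", "4G8", "Iba1", "Clec7a", "BACE1")


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic imaged field (physical units: um, mm^2).

    The defaults define the package's reference study conditions; group
    effects act on ``plaque_density_per_mm2`` through the cohort
    multipliers.
    """

    size_px: int = 512
    pixel_size_um: float = 0.72

    # plaques; defaults give ~4% male burden from many moderate-size
    # deposits, so an imaged field at study age virtually never lacks a
    # plaque (the histogram stays bimodal, as the thresholding assumes)
    plaque_density_per_mm2: float = 60.0
    plaque_area_median_um2: float = 600.0
    plaque_area_sigma: float = 0.5          # log-normal sigma of area
    plaque_amplitude: float = 200.0
    plaque_render_blur_um: float = 1.5
    compact_fraction: float = 0.25
    core_radius_fraction: float = 0.4
    core_amplitude_factor: float = 2.0

    # nuclei
    nucleus_radius_um: float = 3.0
    nucleus_radius_sd_um: float = 0.3
    dapi_amplitude: float = 120.0
    dapi_render_blur_um: float = 0.7
    other_cell_density_per_mm2: float = 150.0
    min_nucleus_separation_um: float = 0.0

    # microglia
    microglia_density_per_mm2: float = 60.0
    cluster_multiplier: float = 4.0
    association_radius_um: float = 30.0
    iba1_amplitude: float = 120.0
    iba1_decay_um: float = 2.5              # halo ~gone by 6 um
    g8_blob_amplitude: float = 250.0
    g8_blob_offset_um: float = 4.0
    g8_blob_sigma_um: float = 1.5

    # Clec7a bimodality
    activated_fraction_near: float = 0.7
    activated_fraction_far: float = 0.05
    clec7a_high: float = 150.0
    clec7a_low: float = 30.0
    clec7a_sigma: float = 0.25              # log-normal sigma of expression

    # BACE1 rim
    bace1_amplitude: float = 150.0
    bace1_rim_sigma_um: float = 1.5

    # camera
    background: float = 10.0
    read_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.size_px < 16 or self.pixel_size_um <= 0:
            raise ValueError("invalid image geometry")
        for name in (
            "plaque_density_per_mm2", "plaque_area_median_um2", "plaque_area_sigma",
            "microglia_density_per_mm2", "other_cell_density_per_mm2",
            "nucleus_radius_um", "iba1_decay_um", "g8_blob_sigma_um",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.compact_fraction <= 1:
            raise ValueError("compact_fraction must lie in [0, 1]")
        for name in ("activated_fraction_near", "activated_fraction_far"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def field_um(self) -> float:
        return self.size_px * self.pixel_size_um

    @property
    def field_mm2(self) -> float:
        return (self.field_um / 1000.0) ** 2


@dataclass(frozen=True)
class CohortParams:
    """Cohort layout: per-group plaque-burden multipliers, animals, images.

    Defaults mirror the reference comparison: a 2x female excess in plaque
    burden, 8 animals per group, 30 images per animal (10 serial sections x
    3 regions).
    """

    groups: Mapping[str, float] = field(
        default_factory=lambda: {"male": 1.0, "female": 2.0}
    )
    animals_per_group: int = 8
    images_per_animal: int = 30
    sections_per_animal: int = 10

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.groups.values()):
            raise ValueError("group multipliers must be > 0")
        if self.animals_per_group < 1 or self.images_per_animal < 1:
            raise ValueError("need >= 1 animal and >= 1 image")


#: Multiplier reproducing the knockout effect: a 58% reduction in covered area.
KO_MULTIPLIER = 0.42


@dataclass
class SectionTruth:
    """Hidden truth of one generated section (recorded before noise).

    ``compact_mask`` is the full extent of compact (Congo-Red-like)
    plaques, so compact-mask area / total plaque area estimates the
    compact fraction; the brighter core sub-discs are a rendering detail
    recorded per plaque as ``core_area_um2``.
    """

    plaque_labels: np.ndarray
    compact_mask: np.ndarray
    plaques: pd.DataFrame        # label, area_um2, compact, x_um, y_um
    cells: pd.DataFrame          # x_um, y_um, radius_um, is_microglia, activated,
                                 # dist_to_border_um, associated, clec7a, has_blob
    burden_fraction: float
    seed: int

    def summary(self) -> dict:
        mg = self.cells[self.cells["is_microglia"]]
        assoc = mg[mg["associated"]]
        return {
            "n_plaques": int(len(self.plaques)),
            "plaque_area_um2": float(self.plaques["area_um2"].sum()),
            "burden_fraction": self.burden_fraction,
            "compact_area_um2": float(
                self.plaques.loc[self.plaques["compact"], "area_um2"].sum()
            )
            if len(self.plaques)
            else 0.0,
            "n_microglia": int(len(mg)),
            "n_associated": int(len(assoc)),
            "activated_fraction": float(assoc["activated"].mean()) if len(assoc) else np.nan,
        }


def _disc_patch(shape, cy, cx, radius_px, value=1.0):
    """Additive soft disc footprint returned as (slices, patch)."""
    r = int(np.ceil(radius_px)) + 1
    r0, r1 = max(0, int(cy) - r), min(shape[0], int(cy) + r + 1)
    c0, c1 = max(0, int(cx) - r), min(shape[1], int(cx) + r + 1)
    if r0 >= r1 or c0 >= c1:
        return None, None
    yy, xx = np.mgrid[r0:r1, c0:c1]
    patch = (np.hypot(yy - cy, xx - cx) <= radius_px) * value
    return (slice(r0, r1), slice(c0, c1)), patch


def _sample_positions(rng, n, field_um, min_sep_um=0.0, max_tries=200):
    """Uniform positions, optionally with a hard minimum separation."""
    if min_sep_um <= 0 or n == 0:
        return rng.uniform(0, field_um, size=(n, 2))
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n and tries < max_tries * n:
        cand = rng.uniform(0, field_um, size=2)
        if all(np.hypot(*(cand - p)) >= min_sep_um for p in pts):
            pts.append(cand)
        tries += 1
    return np.array(pts) if pts else np.zeros((0, 2))


def generate_section(
    scene: SceneParams,
    seed: int | np.random.SeedSequence = 0,
    channels: Sequence[str] = ALL_CHANNELS,
    animal_id: str = "animal0",
    group: str = "group0",
    section_index: int = 1,
    region_index: int = 1,
    burden_multiplier: float = 1.0,
) -> tuple[MultichannelSection, SectionTruth]:
    """Render one section and its ground truth.

    ``channels`` restricts rendering (e.g. ``("4G8",)`` for burden-only
    studies); the truth is complete either way.  Deterministic given the
    seed.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    n = scene.size_px
    px = scene.pixel_size_um
    field_um = scene.field_um
    shape = (n, n)
    channels = tuple(channels)
    unknown = set(channels) - set(ALL_CHANNELS)
    if unknown:
        raise ValueError(f"unknown channel(s) {sorted(unknown)}")

    # ---- plaques -------------------------------------------------------
    lam = scene.plaque_density_per_mm2 * burden_multiplier * scene.field_mm2
    n_plaques = int(rng.poisson(lam))
    centres = rng.uniform(0, field_um, size=(n_plaques, 2))
    areas = scene.plaque_area_median_um2 * np.exp(
        rng.normal(0.0, scene.plaque_area_sigma, size=n_plaques)
    )
    radii = np.sqrt(areas / np.pi)
    compact = rng.uniform(size=n_plaques) < scene.compact_fraction

    plaque_labels = np.zeros(shape, dtype=np.int32)
    compact_mask = np.zeros(shape, dtype=bool)
    g8 = np.zeros(shape)
    rows = []
    for i in range(n_plaques):
        cx, cy = centres[i] / px
        sl, patch = _disc_patch(shape, cy, cx, radii[i] / px)
        if sl is None:
            continue
        plaque_labels[sl][patch > 0] = i + 1
        g8[sl] += patch * scene.plaque_amplitude
        core_area = 0.0
        if compact[i]:
            compact_mask[sl] |= patch > 0
            slc, cpatch = _disc_patch(
                shape, cy, cx, scene.core_radius_fraction * radii[i] / px
            )
            if slc is not None:
                g8[slc] += cpatch * scene.plaque_amplitude * (
                    scene.core_amplitude_factor - 1.0
                )
                core_area = float((cpatch > 0).sum()) * px**2
        rows.append(
            {
                "label": i + 1,
                "x_um": centres[i, 0],
                "y_um": centres[i, 1],
                "radius_um": radii[i],
                "area_um2": float((plaque_labels == i + 1).sum()) * px**2,
                "compact": bool(compact[i]),
                "core_area_um2": core_area,
            }
        )
    plaques_df = pd.DataFrame(
        rows,
        columns=[
            "label", "x_um", "y_um", "radius_um", "area_um2", "compact", "core_area_um2",
        ],
    )
    plaque_mask = plaque_labels > 0
    burden_fraction = float(plaque_mask.mean())

    # distance (um) from any pixel to the nearest plaque pixel (0 inside)
    if plaque_mask.any():
        dist_to_plaque = ndi.distance_transform_edt(~plaque_mask) * px
    else:
        dist_to_plaque = np.full(shape, np.inf)

    # ---- cells ---------------------------------------------------------
    def density_at(points_um: np.ndarray) -> np.ndarray:
        cols = np.clip((points_um[:, 0] / px).astype(int), 0, n - 1)
        rows_ = np.clip((points_um[:, 1] / px).astype(int), 0, n - 1)
        near = dist_to_plaque[rows_, cols] <= scene.association_radius_um
        return np.where(near, scene.cluster_multiplier, 1.0)

    d_max = scene.cluster_multiplier
    n_cand = int(rng.poisson(scene.microglia_density_per_mm2 * d_max * scene.field_mm2))
    cand = _sample_positions(rng, n_cand, field_um, scene.min_nucleus_separation_um)
    if len(cand):
        accept = rng.uniform(size=len(cand)) < density_at(cand) / d_max
        mg_pos = cand[accept]
    else:
        mg_pos = np.zeros((0, 2))
    n_other = int(rng.poisson(scene.other_cell_density_per_mm2 * scene.field_mm2))
    other_pos = _sample_positions(rng, n_other, field_um, scene.min_nucleus_separation_um)

    pos = np.vstack([mg_pos, other_pos])
    is_mg = np.r_[np.ones(len(mg_pos), bool), np.zeros(len(other_pos), bool)]
    radii_n = np.clip(
        rng.normal(scene.nucleus_radius_um, scene.nucleus_radius_sd_um, len(pos)),
        0.5 * scene.nucleus_radius_um,
        None,
    )
    if len(pos):
        cols = np.clip((pos[:, 0] / px).astype(int), 0, n - 1)
        rows_ = np.clip((pos[:, 1] / px).astype(int), 0, n - 1)
        dist_border = dist_to_plaque[rows_, cols]
    else:
        dist_border = np.zeros(0)
    associated = is_mg & (dist_border <= scene.association_radius_um)
    p_act = np.where(associated, scene.activated_fraction_near, scene.activated_fraction_far)
    activated = is_mg & (rng.uniform(size=len(pos)) < p_act)
    clec7a_mode = np.where(activated, scene.clec7a_high, scene.clec7a_low)
    clec7a_expr = clec7a_mode * np.exp(rng.normal(0, scene.clec7a_sigma, len(pos)))
    clec7a_expr = np.where(is_mg, clec7a_expr, 0.0)
    blob_angle = rng.uniform(0, 2 * np.pi, len(pos))

    cells_df = pd.DataFrame(
        {
            "x_um": pos[:, 0] if len(pos) else np.zeros(0),
            "y_um": pos[:, 1] if len(pos) else np.zeros(0),
            "radius_um": radii_n,
            "is_microglia": is_mg,
            "activated": activated,
            "dist_to_border_um": dist_border,
            "associated": associated,
            "clec7a": clec7a_expr,
            "has_blob": associated,
        }
    )

    # ---- render --------------------------------------------------------
    out: dict[str, np.ndarray] = {}
    if "DAPI" in channels:
        dapi = np.zeros(shape)
        for i in range(len(pos)):
            sl, patch = _disc_patch(
                shape, pos[i, 1] / px, pos[i, 0] / px, radii_n[i] / px,
                scene.dapi_amplitude,
            )
            if sl is not None:
                dapi[sl] += patch
        out["DAPI"] = ndi.gaussian_filter(dapi, scene.dapi_render_blur_um / px)

    if "Iba1" in channels:
        iba1 = np.zeros(shape)
        halo_r = 6.0 * scene.iba1_decay_um
        for i in np.flatnonzero(is_mg):
            r = int(np.ceil(halo_r / px))
            cy, cx = pos[i, 1] / px, pos[i, 0] / px
            r0, r1 = max(0, int(cy) - r), min(n, int(cy) + r + 1)
            c0, c1 = max(0, int(cx) - r), min(n, int(cx) + r + 1)
            if r0 >= r1 or c0 >= c1:
                continue
            yy, xx = np.mgrid[r0:r1, c0:c1]
            rad = np.hypot(yy - cy, xx - cx) * px
            iba1[r0:r1, c0:c1] += scene.iba1_amplitude * np.exp(-rad / scene.iba1_decay_um)
        out["Iba1"] = iba1

    if "Clec7a" in channels:
        clec = np.zeros(shape)
        for i in np.flatnonzero(is_mg):
            sl, patch = _disc_patch(
                shape, pos[i, 1] / px, pos[i, 0] / px, radii_n[i] / px, clec7a_expr[i]
            )
            if sl is not None:
                clec[sl] += patch
        out["Clec7a"] = ndi.gaussian_filter(clec, scene.dapi_render_blur_um / px)

    if "4G8" in channels:
        g8_cells = np.zeros(shape)
        for i in np.flatnonzero(associated):
            bx = pos[i, 0] + scene.g8_blob_offset_um * np.cos(blob_angle[i])
            by = pos[i, 1] + scene.g8_blob_offset_um * np.sin(blob_angle[i])
            r = int(np.ceil(4 * scene.g8_blob_sigma_um / px))
            cy, cx = by / px, bx / px
            r0, r1 = max(0, int(cy) - r), min(n, int(cy) + r + 1)
            c0, c1 = max(0, int(cx) - r), min(n, int(cx) + r + 1)
            if r0 >= r1 or c0 >= c1:
                continue
            yy, xx = np.mgrid[r0:r1, c0:c1]
            rad2 = ((yy - cy) ** 2 + (xx - cx) ** 2) * px**2
            g8_cells[r0:r1, c0:c1] += scene.g8_blob_amplitude * np.exp(
                -rad2 / (2 * scene.g8_blob_sigma_um**2)
            )
        out["4G8"] = ndi.gaussian_filter(g8, scene.plaque_render_blur_um / px) + g8_cells

    if "BACE1" in channels:
        if plaque_mask.any():
            d_border = dist_to_plaque + ndi.distance_transform_edt(plaque_mask) * px
            bace1 = scene.bace1_amplitude * np.exp(
                -(d_border**2) / (2 * scene.bace1_rim_sigma_um**2)
            )
        else:
            bace1 = np.zeros(shape)
        out["BACE1"] = bace1

    # ---- noise ---------------------------------------------------------
    noisy = {}
    for name in channels:
        img = out[name] + scene.background
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
        img += rng.normal(0, scene.read_noise_sd, shape)
        noisy[name] = np.clip(img, 0, None)

    # truth-only generation (empty channel tuple) skips the section object
    section = (
        MultichannelSection(
            channels=noisy,
            pixel_size_um=px,
            animal_id=animal_id,
            group=group,
            section_index=section_index,
            region_index=region_index,
        )
        if channels
        else None
    )
    truth = SectionTruth(
        plaque_labels=plaque_labels,
        compact_mask=compact_mask,
        plaques=plaques_df,
        cells=cells_df,
        burden_fraction=burden_fraction,
        seed=int(ss.entropy) if isinstance(ss.entropy, int) else 0,
    )
    return section, truth


def iter_cohort(
    cohort: CohortParams,
    scene: SceneParams,
    seed: int = 0,
    channels: Sequence[str] = ALL_CHANNELS,
) -> Iterator[tuple[MultichannelSection, SectionTruth]]:
    """Stream (section, truth) pairs for a whole cohort, one at a time.

    Per-image seeds derive from (group index, animal index, image index)
    via spawn keys, so the stream is order-stable and extensible.
    """
    regions = max(1, cohort.images_per_animal // cohort.sections_per_animal)
    for gi, (gname, mult) in enumerate(cohort.groups.items()):
        for ai in range(cohort.animals_per_group):
            animal = f"{gname}_a{ai + 1}"
            for ii in range(cohort.images_per_animal):
                ss = np.random.SeedSequence(entropy=seed, spawn_key=(gi, ai, ii))
                yield generate_section(
                    scene,
                    seed=ss,
                    channels=channels,
                    animal_id=animal,
                    group=gname,
                    section_index=ii // regions + 1,
                    region_index=ii % regions + 1,
                    burden_multiplier=mult,
                )


def generate_cohort(
    cohort: CohortParams,
    scene: SceneParams,
    outdir: str | Path,
    seed: int = 0,
    channels: Sequence[str] = ALL_CHANNELS,
) -> pd.DataFrame:
    """Write a cohort to disk: one TIFF folder per animal plus truth tables.

    Emits ``<outdir>/<animal>/<image_id>.tiff``, a per-image truth summary
    ``truth_images.csv`` and a ``manifest.json`` (all parameters + seed)
    sufficient to regenerate the cohort bit-identically.  Returns the truth
    summary table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for section, truth in iter_cohort(cohort, scene, seed, channels):
        adir = outdir / section.animal_id
        adir.mkdir(exist_ok=True)
        write_section(section, adir / f"{section.image_id}.tiff")
        rows.append(
            {
                "image_id": section.image_id,
                "animal_id": section.animal_id,
                "group": section.group,
                "section_index": section.section_index,
                "region_index": section.region_index,
                **truth.summary(),
            }
        )
    truth_df = pd.DataFrame(rows)
    truth_df.to_csv(outdir / "truth_images.csv", index=False)
    manifest = {
        "seed": seed,
        "channels": list(channels),
        "scene": asdict(scene),
        "cohort": {
            "groups": dict(cohort.groups),
            "animals_per_group": cohort.animals_per_group,
            "images_per_animal": cohort.images_per_animal,
            "sections_per_animal": cohort.sections_per_animal,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return truth_df
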