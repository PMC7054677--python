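"""Config-driven end-to-end runs.

``run(config)`` executes simulate/load -> segment -> per-cell quantify ->
area-ratio QC -> stereology -> hierarchical pooling -> group statistics and
writes one CSV per result level plus a JSON run summary and a log.  Stages
communicate only through tables, and every exclusion (QC, plaque-free
image, empty animal) is logged with its reason.

Metrics are reported per group as mean +/- SEM with n = animals (never
n = images): image values are pooled to animal medians first.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

from . import area_ratio as ar
from . import cell_quant as cq
from . import stats as st
from . import stereology as stereo
from .imgio import MultichannelSection, read_section, write_result_tables
from .segmentation import SegmentationParams, segment_nuclei, segment_plaques
from .synthetic import ALL_CHANNELS, CohortParams, SceneParams, SectionTruth, iter_cohort

__all__ = ["RunConfig", "run", "load_config"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully serialisable run description.

    Either ``input_dir`` points at a cohort written by
    :func:`plaquekit.synthetic.generate_cohort` (TIFFs + manifest), or
    ``simulate`` is True and the cohort is generated in memory from
    ``cohort``/``scene``.
    """

    outdir: str = "results"
    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None
    channels: tuple[str, ...] = ALL_CHANNELS
    cohort: CohortParams = field(default_factory=CohortParams)
    scene: SceneParams = field(default_factory=SceneParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    association: cq.AssociationParams = field(default_factory=cq.AssociationParams)
    profile_r_max_um: float = 20.0
    profile_dr_um: float = 0.5
    profile_channels: tuple[str, ...] = ("Iba1", "4G8")
    histogram_bins: int = 20
    histogram_range: tuple[float, float] = (0.0, 300.0)
    ratio_k: float = 2.0
    qc_n_sd: float = 2.0
    stereology_design: stereo.SamplingDesign = field(
        default_factory=lambda: stereo.SamplingDesign((90.0, 90.0), (90.0, 90.0), 10.0)
    )
    run_stereology: bool = True
    alpha: float = 0.05

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["groups"] = dict(self.cohort.groups)
        return d


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file of nested parameter blocks."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(raw)
    for key, cls in (
        ("cohort", CohortParams),
        ("scene", SceneParams),
        ("segmentation", SegmentationParams),
        ("association", cq.AssociationParams),
    ):
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = cls(**kwargs[key])
    if "stereology_design" in kwargs and isinstance(kwargs["stereology_design"], dict):
        sd = kwargs["stereology_design"]
        kwargs["stereology_design"] = stereo.SamplingDesign(
            tuple(sd.get("counting_frame_um", (90.0, 90.0))),
            tuple(sd.get("grid_um", (90.0, 90.0))),
            sd.get("point_spacing_um", 10.0),
            sd.get("section_thickness_um", 40.0),
        )
    for key in ("channels", "profile_channels"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if "histogram_range" in kwargs:
        kwargs["histogram_range"] = tuple(kwargs["histogram_range"])
    return RunConfig(**kwargs)


def _iter_input(config: RunConfig) -> Iterator[tuple[MultichannelSection, SectionTruth | None]]:
    if config.simulate:
        yield from iter_cohort(config.cohort, config.scene, config.seed, config.channels)
    else:
        root = Path(config.input_dir)
        manifest = root / "manifest.json"
        if not manifest.exists():
            raise FileNotFoundError(f"no manifest.json under {root}")
        meta = json.loads(manifest.read_text())
        paths = sorted(root.glob("*/*.tif*"))
        if not paths:
            raise FileNotFoundError(f"no TIFF sections under {root}")
        for p in paths:
            yield read_section(p), None


def _quantify_image(section: MultichannelSection, config: RunConfig, img_seed):
    """All per-image measurements; returns (image_row, cells, profiles, hist)."""
    row: dict = {
        "image_id": section.image_id,
        "animal_id": section.animal_id,
        "group": section.group,
    }
    have = set(section.channels)
    px = section.pixel_size_um

    plaques = None
    if "4G8" in have:
        plaques = segment_plaques(section, config.segmentation)
        plaque_mask = plaques.labels > 0
        row["n_plaques"] = plaques.n_regions
        row["burden_pct"] = 100.0 * float(plaque_mask.mean())
        if config.run_stereology:
            try:
                est = stereo.cavalieri_area_fraction(
                    plaque_mask,
                    np.ones_like(plaque_mask),
                    px,
                    config.stereology_design,
                    seed=np.random.default_rng(img_seed),
                )
                row["cavalieri_burden_pct"] = est.estimate
                row["cavalieri_points"] = est.n_sampled
            except ValueError as exc:
                log.warning("%s: Cavalieri skipped (%s)", section.image_id, exc)

    cells = None
    profiles_long: list[dict] = []
    hist_row = None
    if "DAPI" in have:
        nuclei = segment_nuclei(section, config.segmentation)
        row["n_nuclei"] = nuclei.n_regions
        cells = cq.measure_expression(nuclei, section)
        if "Iba1" in have and len(cells):
            cells["iba1_positive"] = cq.classify_positive(cells["mean_Iba1"].to_numpy())
        else:
            cells["iba1_positive"] = False
        if plaques is not None:
            cells = cq.nearest_plaque_metrics(cells, plaques, config.association)
            summ = cq.plaque_associated_summary(cells, plaques)
            if summ["n_associated"] is None:
                log.info("%s: no plaque; association summary undefined", section.image_id)
            else:
                row["n_associated"] = summ["n_associated"]
                row["normalised_count_per_um2"] = summ["normalised_count_per_um2"]

            assoc = cells[cells["iba1_positive"] & cells["plaque_associated"]]
            prof_channels = [c for c in config.profile_channels if c in have]
            for ch in prof_channels:
                acc = []
                for _, cell in assoc.iterrows():
                    prof = cq.radial_profile(
                        section, ch,
                        (cell["centroid_x_um"], cell["centroid_y_um"]),
                        config.profile_r_max_um, config.profile_dr_um,
                    )
                    acc.append(prof.values)
                if acc:
                    mean_curve = np.nanmean(np.vstack(acc), axis=0)
                    integral = np.nansum(mean_curve) * config.profile_dr_um
                    if integral > 0:
                        mean_curve = mean_curve / integral
                        for b, v in enumerate(mean_curve):
                            if np.isfinite(v):
                                profiles_long.append(
                                    {
                                        "image_id": section.image_id,
                                        "animal_id": section.animal_id,
                                        "group": section.group,
                                        "channel": ch,
                                        "bin_centre_um": (b + 0.5) * config.profile_dr_um,
                                        "value": float(v),
                                    }
                                )
            if "Clec7a" in have and len(assoc):
                edges = np.linspace(*config.histogram_range, config.histogram_bins + 1)
                vals = assoc["mean_Clec7a"].to_numpy()
                if len(vals) and np.histogram(vals, bins=edges)[0].sum() > 0:
                    hist = cq.intensity_histogram(vals, edges, normalised=True)
                    hist_row = {
                        "image_id": section.image_id,
                        "animal_id": section.animal_id,
                        "group": section.group,
                        "edges": edges,
                        "values": hist.values,
                    }
        if cells is not None and len(cells):
            cells.insert(0, "image_id", section.image_id)
            cells.insert(1, "animal_id", section.animal_id)
            cells.insert(2, "group", section.group)

    # area-ratio stage inputs: contrast greyscale stats + 256-level histograms
    ratio_chans = [c for c in ("BACE1", "4G8") if c in have]
    grey_stats = {}
    for ch in ratio_chans:
        grey = ar.to_greyscale_contrast(section, ch)
        counts, _ = np.histogram(grey, bins=256, range=(0.0, 256.0))
        grey_stats[ch] = {
            "n": grey.size,
            "sum": float(grey.sum()),
            "sumsq": float(np.square(grey).sum()),
            "hist": counts,
            "mean": float(grey.mean()),
            "var": float(grey.var()),
        }
    return row, cells, profiles_long, hist_row, grey_stats


def _stats_rows(animals: pd.DataFrame, metrics: Sequence[str], alpha: float) -> list[dict]:
    rows = []
    groups = sorted(animals["group"].unique())
    for metric in metrics:
        by_group = {
            g: animals.loc[animals["group"] == g, metric].dropna().to_numpy()
            for g in groups
        }
        by_group = {g: v for g, v in by_group.items() if len(v) >= 2}
        if len(by_group) < 2:
            continue
        if len(by_group) == 2:
            (ga, va), (gb, vb) = by_group.items()
            try:
                res = st.unpaired_t_test(va, vb, names=(ga, gb))
            except ValueError as exc:
                log.warning("t-test on %s failed: %s", metric, exc)
                continue
            rows.append(
                {
                    "metric": metric, "test": res.test, "groups": f"{ga} vs {gb}",
                    "n": f"{len(va)},{len(vb)}",
                    "means": f"{va.mean():.6g},{vb.mean():.6g}",
                    "sems": f"{res.groups[0].sem:.6g},{res.groups[1].sem:.6g}",
                    "statistic": res.statistic, "df": res.df,
                    "p": res.p_value, "p_adj": res.p_value, "stars": res.stars,
                }
            )
        else:
            res = st.anova_tukey(by_group)
            rows.append(
                {
                    "metric": metric, "test": "anova", "groups": "all",
                    "n": ",".join(str(len(v)) for v in by_group.values()),
                    "means": ",".join(f"{v.mean():.6g}" for v in by_group.values()),
                    "sems": "", "statistic": res.statistic, "df": res.df,
                    "p": res.p_value, "p_adj": res.p_value, "stars": res.stars,
                }
            )
            for pw in res.pairwise:
                rows.append(
                    {
                        "metric": metric, "test": "tukey",
                        "groups": f"{pw.group_a} vs {pw.group_b}", "n": "",
                        "means": "", "sems": "", "statistic": pw.mean_diff,
                        "df": res.df, "p": pw.p_adj, "p_adj": pw.p_adj,
                        "stars": pw.stars,
                    }
                )
    return rows


def _per_bin_tests(curves: pd.DataFrame, bin_col: str, label: str) -> list[dict]:
    """Two-group per-bin t-tests with Bonferroni over the tested bins."""
    rows: list[dict] = []
    groups = sorted(curves["group"].unique())
    if len(groups) != 2:
        return rows
    ga, gb = groups
    animal = (
        curves.groupby(["group", "animal_id", bin_col], sort=True)["value"]
        .median()
        .reset_index()
    )
    raw = []
    for b, sub in animal.groupby(bin_col, sort=True):
        va = sub.loc[sub["group"] == ga, "value"].to_numpy()
        vb = sub.loc[sub["group"] == gb, "value"].to_numpy()
        if len(va) >= 2 and len(vb) >= 2:
            try:
                res = st.unpaired_t_test(va, vb, names=(ga, gb))
                raw.append((b, res))
            except ValueError:
                continue
    if not raw:
        return rows
    adj = st.bonferroni_per_bin([r.p_value for _, r in raw])
    for (b, res), p_adj in zip(raw, adj):
        rows.append(
            {
                "metric": f"{label}@{b}", "test": res.test, "groups": f"{ga} vs {gb}",
                "n": f"{res.groups[0].n},{res.groups[1].n}",
                "means": f"{res.groups[0].mean:.6g},{res.groups[1].mean:.6g}",
                "sems": f"{res.groups[0].sem:.6g},{res.groups[1].sem:.6g}",
                "statistic": res.statistic, "df": res.df,
                "p": res.p_value, "p_adj": float(p_adj),
                "stars": st.significance_stars(float(p_adj)),
            }
        )
    return rows


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the result tables in memory.

    Writes cells.csv, images.csv, animals.csv, groups.csv, qc.csv,
    ratios.csv, profiles.csv, histograms.csv, stats.csv and
    run_summary.json under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root_log = logging.getLogger("plaquekit")
    root_log.addHandler(handler)
    root_log.setLevel(logging.INFO)

    image_rows: list[dict] = []
    all_cells: list[pd.DataFrame] = []
    prof_rows: list[dict] = []
    hist_rows: list[dict] = []
    grey_acc: dict[str, dict] = {}
    try:
        for i, (section, _truth) in enumerate(_iter_input(config)):
            img_seed = np.random.SeedSequence(entropy=config.seed, spawn_key=(7001, i))
            row, cells, profs, hist_row, grey = _quantify_image(section, config, img_seed)
            image_rows.append(row)
            if cells is not None and len(cells):
                all_cells.append(cells)
            prof_rows.extend(profs)
            if hist_row is not None:
                hist_rows.append(hist_row)
            for ch, s in grey.items():
                acc = grey_acc.setdefault(
                    ch, {"n": 0, "sum": 0.0, "sumsq": 0.0, "images": []}
                )
                acc["n"] += s["n"]
                acc["sum"] += s["sum"]
                acc["sumsq"] += s["sumsq"]
                acc["images"].append(
                    {
                        "image_id": section.image_id,
                        "animal_id": section.animal_id,
                        "group": section.group,
                        "mean": s["mean"],
                        "var": s["var"],
                        "hist": s["hist"],
                    }
                )
    except Exception:
        log.exception("stage 'quantify' failed; partial outputs not written")
        root_log.removeHandler(handler)
        raise

    images = pd.DataFrame(image_rows)
    tables: dict[str, pd.DataFrame] = {"image": images}
    if all_cells:
        tables["cell"] = pd.concat(all_cells, ignore_index=True)

    # ---- BACE1/4G8 ratio with QC --------------------------------------
    qc_df = pd.DataFrame()
    ratios_img = pd.DataFrame()
    thresholds: dict[str, ar.FixedThreshold] = {}
    if set(grey_acc) >= {"BACE1", "4G8"}:
        feats = None
        for ch, acc in grey_acc.items():
            thresholds[ch] = ar.fit_fixed_threshold_from_stats(
                acc["n"], acc["sum"], acc["sumsq"], channel=ch, k=config.ratio_k
            )
            df = pd.DataFrame(
                [
                    {
                        "image_id": im["image_id"],
                        "animal_id": im["animal_id"],
                        "group": im["group"],
                        f"mean_{ch}": im["mean"],
                        f"var_{ch}": im["var"],
                    }
                    for im in acc["images"]
                ]
            )
            feats = df if feats is None else feats.merge(
                df, on=["image_id", "animal_id", "group"]
            )
        feat_cols = [c for c in feats.columns if c.startswith(("mean_", "var_"))]
        qc_df = ar.qc_filter(feats, feat_cols, n_sd=config.qc_n_sd)
        kept = set(qc_df.loc[~qc_df["excluded"], "image_id"])
        log.info("QC retained %d/%d images for the ratio stage", len(kept), len(qc_df))

        bins = np.arange(256) + 0.5
        frac_rows = []
        for im_b, im_g in zip(grey_acc["BACE1"]["images"], grey_acc["4G8"]["images"]):
            if im_b["image_id"] not in kept:
                continue
            frac_rows.append(
                {
                    "image_id": im_b["image_id"],
                    "animal_id": im_b["animal_id"],
                    "group": im_b["group"],
                    "frac_BACE1": ar.stained_fraction_from_histogram(
                        im_b["hist"], bins, thresholds["BACE1"].threshold
                    ),
                    "frac_4G8": ar.stained_fraction_from_histogram(
                        im_g["hist"], bins, thresholds["4G8"].threshold
                    ),
                }
            )
        if frac_rows:
            ratios_img, ratio_animals = ar.bace1_4g8_ratio(pd.DataFrame(frac_rows))
            tables["ratio"] = ratios_img
            images = images.merge(
                ratios_img[["image_id", "ratio"]], on="image_id", how="left"
            )
            tables["image"] = images
    if len(qc_df):
        tables["qc"] = qc_df.drop(columns=[], errors="ignore")

    # ---- pooling -------------------------------------------------------
    metric_cols = [
        c
        for c in (
            "n_plaques", "burden_pct", "cavalieri_burden_pct", "n_nuclei",
            "n_associated", "normalised_count_per_um2", "ratio",
        )
        if c in images.columns
    ]
    animals, groups = cq.pool_scalar(images, metric_cols)
    tables["animal"] = animals
    tables["group"] = groups
    if "cavalieri_burden_pct" in images.columns:
        tables["stereology"] = images[
            ["image_id", "animal_id", "group", "cavalieri_burden_pct", "cavalieri_points"]
        ]

    profiles = pd.DataFrame(prof_rows)
    if len(profiles):
        pooled_prof = []
        for ch, sub in profiles.groupby("channel"):
            p = cq.pool_curves(sub, bin_col="bin_centre_um")
            p.insert(0, "channel", ch)
            pooled_prof.append(p)
        tables["profile"] = profiles
        tables["profile_pooled"] = pd.concat(pooled_prof, ignore_index=True)

    if hist_rows:
        hist_long = pd.DataFrame(
            [
                {
                    "image_id": h["image_id"],
                    "animal_id": h["animal_id"],
                    "group": h["group"],
                    "bin_centre": 0.5 * (h["edges"][b] + h["edges"][b + 1]),
                    "value": float(h["values"][b]),
                }
                for h in hist_rows
                for b in range(len(h["values"]))
            ]
        )
        tables["histogram"] = hist_long
        tables["histogram_pooled"] = cq.pool_curves(hist_long, bin_col="bin_centre")

    # ---- statistics ----------------------------------------------------
    stat_rows = _stats_rows(animals, metric_cols, config.alpha)
    if len(profiles):
        for ch, sub in profiles.groupby("channel"):
            stat_rows.extend(_per_bin_tests(sub, "bin_centre_um", f"profile_{ch}"))
    if hist_rows:
        stat_rows.extend(_per_bin_tests(tables["histogram"], "bin_centre", "clec7a_hist"))
    tables["stat"] = pd.DataFrame(stat_rows)

    written = write_result_tables(tables, outdir)
    summary = {
        "config": config.to_dict(),
        "n_images": int(len(images)),
        "n_animals": int(len(animals)),
        "groups": {
            g: {
                m: (None if not np.isfinite(v) else round(float(v), 10))
                for m in metric_cols
                for v in [
                    groups.loc[groups["group"] == g, f"{m}_mean"].iloc[0]
                ]
            }
            for g in groups["group"]
        },
        "thresholds": {
            ch: {"threshold": t.threshold, "mean": t.pooled_mean, "sd": t.pooled_sd, "k": t.k}
            for ch, t in thresholds.items()
        },
        "qc_excluded": int(qc_df["excluded"].sum()) if len(qc_df) else 0,
        "tables": {k: str(p) for k, p in written.items()},
    }
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    root_log.removeHandler(handler)
    handler.close()
    return tables
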