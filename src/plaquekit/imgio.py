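"""Data model and I/O for multichannel fluorescence sections.

A :class:`MultichannelSection` is the per-image unit of the whole pipeline:
one imaged field with named channels (DAPI, 4G8, Iba1, Clec7a, BACE1, ...),
a physical pixel size in micrometres and provenance metadata (animal, group,
section and region indices).  Confocal z-stacks are ordered lists of such
planes (:class:`SectionStack`) and are reduced to a single plane by maximum
projection before quantification.

Physical convention used throughout the package: the pixel at array position
``(row, col)`` has its centre at ``(x, y) = (col * pixel_size_um,
row * pixel_size_um)``.  All physical parameters (blur sigmas, radii, areas)
are converted to pixel units at run time, so the pipeline is
resolution-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "MultichannelSection",
    "SectionStack",
    "read_section",
    "write_section",
    "max_projection",
    "write_result_tables",
]


@dataclass
class MultichannelSection:
    """One imaged field: named 2D intensity grids plus physical metadata.

    Parameters
    ----------
    channels
        Mapping from channel name (e.g. ``"DAPI"``) to a 2D float array of
        nonnegative intensities.  All grids must share one shape.
    pixel_size_um
        Physical edge length of one pixel in micrometres; must be > 0.
    animal_id, group
        Provenance: opaque animal identifier and experimental group label
        (e.g. ``"male_wt"``).
    section_index, region_index
        1-based serial section and imaged region counters.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    animal_id: str = "animal0"
    group: str = "group0"
    section_index: int = 1
    region_index: int = 1

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not self.channels:
            raise ValueError("section must contain at least one channel")
        shapes = {name: np.asarray(grid).shape for name, grid in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(len(s) != 2 for s in shapes.values()):
            raise ValueError(f"channel grids must be 2D, got shapes {shapes}")
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channel grids differ in shape: {shapes}")
        for name, grid in self.channels.items():
            arr = np.asarray(grid, dtype=float)
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} contains negative intensities")
            self.channels[name] = arr
        if self.section_index < 1 or self.region_index < 1:
            raise ValueError("section_index and region_index are 1-based (>= 1)")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"missing channel {name!r}; available: {sorted(self.channels)}"
            ) from None

    @property
    def image_id(self) -> str:
        return f"{self.animal_id}_s{self.section_index}_r{self.region_index}"


@dataclass
class SectionStack:
    """Ordered confocal z-stack of dimension-identical planes."""

    planes: Sequence[MultichannelSection]
    z_step_um: float = 1.0

    def __post_init__(self) -> None:
        if len(self.planes) < 1:
            raise ValueError("stack must contain at least one plane")
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be > 0")
        first = self.planes[0]
        for p in self.planes[1:]:
            if p.shape != first.shape or set(p.channels) != set(first.channels):
                raise ValueError("all planes must share shape and channel names")


def max_projection(stack: SectionStack) -> MultichannelSection:
    """Per-channel maximum over z; metadata copied from the first plane.

    Quantification operates on maximum projections of confocal stacks, so
    this is the canonical stack -> section reduction.  Idempotent for
    single-plane stacks.
    """
    first = stack.planes[0]
    projected = {
        name: np.max(np.stack([p.channels[name] for p in stack.planes]), axis=0)
        for name in first.channels
    }
    return replace(first, channels=projected)


def write_section(section: MultichannelSection, path: str | Path) -> Path:
    """Write a section as a multi-page float32 TIFF (one page per channel).

    Channel names, pixel size and provenance go into the ImageDescription
    tag as JSON so :func:`read_section` can round-trip without sidecars.
    """
    path = Path(path)
    names = sorted(section.channels)
    data = np.stack([section.channels[n].astype(np.float32) for n in names])
    meta = {
        "channels": names,
        "pixel_size_um": section.pixel_size_um,
        "animal_id": section.animal_id,
        "group": section.group,
        "section_index": section.section_index,
        "region_index": section.region_index,
    }
    tifffile.imwrite(path, data, description=json.dumps(meta))
    return path


def read_section(
    path: str | Path,
    channel_map: Sequence[str] | None = None,
    pixel_size_um: float | None = None,
    **provenance,
) -> MultichannelSection:
    """Read a multichannel TIFF into a validated :class:`MultichannelSection`.

    ``channel_map`` names each plane in order; it may be omitted for files
    written by :func:`write_section`, whose tags carry the names.  A declared
    channel with no corresponding plane is an error, as is a missing pixel
    size (required metadata when absent from the file tags).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected a 2D or 3D (channel, y, x) TIFF, got shape {data.shape}")

    names = list(channel_map) if channel_map is not None else meta.get("channels")
    if names is None:
        raise ValueError("channel_map required: file carries no channel names")
    if len(names) > data.shape[0]:
        missing = names[data.shape[0]:]
        raise ValueError(f"missing channel(s) {missing}: file has {data.shape[0]} plane(s)")
    if len(names) < data.shape[0]:
        raise ValueError(
            f"channel_map names {len(names)} plane(s) but file has {data.shape[0]}"
        )

    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if px is None:
        raise ValueError("pixel_size_um required: not present in file metadata")

    fields = {
        k: provenance.get(k, meta.get(k, d))
        for k, d in (
            ("animal_id", "animal0"),
            ("group", "group0"),
            ("section_index", 1),
            ("region_index", 1),
        )
    }
    channels = {n: data[i].astype(float) for i, n in enumerate(names)}
    return MultichannelSection(channels=channels, pixel_size_um=float(px), **fields)


_LEVELS = ("cell", "image", "animal", "group", "stat", "ratio", "profile", "histogram")


def write_result_tables(tables: Mapping[str, pd.DataFrame], outdir: str | Path) -> dict[str, Path]:
    """Write one CSV per result level (cells.csv, images.csv, ...) plus extras.

    Keys in ``tables`` matching a level name are written as ``<level>s.csv``;
    any other key is written verbatim as ``<key>.csv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for key, df in tables.items():
        fname = f"{key}s.csv" if key in _LEVELS else f"{key}.csv"
        p = outdir / fname
        df.to_csv(p, index=False)
        written[key] = p
    return written
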