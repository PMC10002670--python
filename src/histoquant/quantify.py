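"""Regional stain-load quantification with object splitting.

"Load" is the percentage of segmented (stained) pixel area within a region's
pixel area.  Connected stained objects are split across the atlas regions they
overlap: each region receives exactly its own pixel share, and the object
increments the object count of every region it touches.  Hemisphere masks
exclude pixels from both numerator and denominator; per-brain loads are pooled
pixel sums over the sections kept after damage triage.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from skimage import measure

from .atlas import BACKGROUND_ID, UNMAPPED, CustomHierarchy
from .registration import AtlasMap

STAINS = ("NeuN", "GFAP", "Iba1", "AB1-42", "thionine", "other")


@dataclass(frozen=True)
class SegmentationImage:
    """Binary label/background segmentation of one section."""

    pixels: np.ndarray  # bool, True = stained ("label" class)
    stain: str = "other"

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError("segmentation must be 2D")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 255))) and not np.all(np.isin(vals, (0, 1))):
                raise ValueError("segmentation must be binary (0/255 or bool)")
            arr = arr > 0
        object.__setattr__(self, "pixels", arr)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class RegionStats:
    """Pixel tallies for one region on one section (or pooled per brain)."""

    region_id: int
    region_area_px: int = 0
    stained_px: int = 0
    n_objects: int = 0

    @property
    def load_pct(self) -> Optional[float]:
        if self.region_area_px == 0:
            return None
        return 100.0 * self.stained_px / self.region_area_px


@dataclass
class LoadReport:
    """Per-section and pooled region stats for one (brain, stain)."""

    brain_id: str
    stain: str
    per_section: dict[str, list[RegionStats]] = field(default_factory=dict)
    excluded_sections: list[str] = field(default_factory=list)

    def pooled(self) -> dict[int, RegionStats]:
        return brain_load(self.per_section, self.excluded_sections)


def label_objects(seg: SegmentationImage, connectivity: int = 2) -> np.ndarray:
    """Connected components of stained pixels; 8-connectivity by default."""
    return measure.label(seg.pixels, connectivity=connectivity)


def regional_counts(
    seg: SegmentationImage,
    amap: AtlasMap,
    mask: Optional[np.ndarray],
    hierarchy: CustomHierarchy,
    connectivity: int = 2,
) -> list[RegionStats]:
    """Per-region areas, stained pixels and split-object counts for a section.

    Only pixels with ``mask`` true and a nonzero atlas ID contribute.  Pixels
    whose label has no selected ancestor are tallied under the reserved
    :data:`histoquant.atlas.UNMAPPED` row.
    """
    if mask is None:
        mask = np.ones(seg.pixels.shape, dtype=bool)
    if seg.pixels.shape != amap.region_ids.shape or mask.shape != seg.pixels.shape:
        raise ValueError(
            f"dim mismatch: seg {seg.pixels.shape}, map {amap.region_ids.shape}, "
            f"mask {mask.shape}"
        )
    lut = hierarchy.lookup_table(max_label=int(amap.region_ids.max(initial=0)))
    custom = lut[amap.region_ids]
    valid = mask & (amap.region_ids != BACKGROUND_ID)

    stats: dict[int, RegionStats] = {}
    region_vals, region_areas = np.unique(custom[valid], return_counts=True)
    for rid, area in zip(region_vals, region_areas):
        stats[int(rid)] = RegionStats(region_id=int(rid), region_area_px=int(area))

    stained = valid & seg.pixels
    if stained.any():
        sv, sc = np.unique(custom[stained], return_counts=True)
        for rid, cnt in zip(sv, sc):
            stats[int(rid)].stained_px = int(cnt)
        objects = label_objects(seg, connectivity=connectivity)
        # object splitting: an object touching k regions counts once in each
        pairs = np.unique(
            np.column_stack([objects[stained], custom[stained]]), axis=0
        )
        for _, rid in pairs:
            stats[int(rid)].n_objects += 1
    return [stats[rid] for rid in sorted(stats)]


def brain_load(
    per_section: Mapping[str, Sequence[RegionStats]],
    excluded_sections: Iterable[str] = (),
) -> dict[int, RegionStats]:
    """Pool section stats into per-brain region stats over kept sections.

    Pooled load is pixel-sum based: 100 · Σ stained / Σ area, the only
    definition consistent with "% stained area per region area" at brain
    level.  Regions absent from every kept section keep area 0 (load None).
    """
    excluded = set(excluded_sections)
    pooled: dict[int, RegionStats] = {}
    for section_id, stats in per_section.items():
        if section_id in excluded:
            continue
        for st in stats:
            agg = pooled.setdefault(st.region_id, RegionStats(region_id=st.region_id))
            agg.region_area_px += st.region_area_px
            agg.stained_px += st.stained_px
            agg.n_objects += st.n_objects
    return dict(sorted(pooled.items()))


def mean_of_section_loads(
    per_section: Mapping[str, Sequence[RegionStats]],
    excluded_sections: Iterable[str] = (),
) -> dict[int, float]:
    """Sensitivity-analysis variant: unweighted mean of per-section loads."""
    excluded = set(excluded_sections)
    vals: dict[int, list[float]] = {}
    for section_id, stats in per_section.items():
        if section_id in excluded:
            continue
        for st in stats:
            if st.load_pct is not None:
                vals.setdefault(st.region_id, []).append(st.load_pct)
    return {rid: sum(v) / len(v) for rid, v in sorted(vals.items())}


def load_difference(
    loads_linear: Mapping[int, float], loads_nonlinear: Mapping[int, float]
) -> dict[int, float]:
    """Per-region (nonlinear − linear) load difference for one animal."""
    if set(loads_linear) != set(loads_nonlinear):
        raise ValueError("linear and nonlinear reports cover different regions")
    return {rid: loads_nonlinear[rid] - loads_linear[rid] for rid in sorted(loads_linear)}


def summarize_differences(
    per_animal: Sequence[Mapping[int, float]],
) -> dict[int, tuple[float, Optional[float], int]]:
    """Mean ± SEM of per-region differences across animals."""
    keys = set()
    for d in per_animal:
        keys |= set(d)
    out = {}
    for rid in sorted(keys):
        vals = [d[rid] for d in per_animal if rid in d]
        n = len(vals)
        mean = sum(vals) / n
        sem = None
        if n >= 2:
            var = sum((v - mean) ** 2 for v in vals) / (n - 1)
            sem = (var / n) ** 0.5
        out[rid] = (mean, sem, n)
    return out


# ---------------------------------------------------------------------------
# I/O


def read_segmentation_png(path: str | Path, stain: str = "other") -> SegmentationImage:
    """Read an 8-bit indexed PNG (0 = background, nonzero = label)."""
    from PIL import Image

    with Image.open(path) as img:
        arr = np.asarray(img)
    if arr.ndim == 3:  # indexed PNGs may decode to RGB; any nonzero channel = label
        arr = arr.max(axis=2)
    return SegmentationImage(pixels=arr > 0, stain=stain)


def write_segmentation_png(seg: SegmentationImage, path: str | Path) -> None:
    from PIL import Image

    arr = np.where(seg.pixels, 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path, format="PNG")


def write_load_report(report: LoadReport, path: str | Path) -> None:
    """TSV rows per section plus pooled rows with section id ``__pooled__``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["brain", "stain", "section", "region_id", "area_px", "stained_px", "n_objects", "load_pct"]
        )
        for section_id in report.per_section:
            for st in report.per_section[section_id]:
                writer.writerow(
                    [
                        report.brain_id,
                        report.stain,
                        section_id,
                        st.region_id,
                        st.region_area_px,
                        st.stained_px,
                        st.n_objects,
                        "" if st.load_pct is None else repr(st.load_pct),
                    ]
                )
        for st in report.pooled().values():
            writer.writerow(
                [
                    report.brain_id,
                    report.stain,
                    "__pooled__",
                    st.region_id,
                    st.region_area_px,
                    st.stained_px,
                    st.n_objects,
                    "" if st.load_pct is None else repr(st.load_pct),
                ]
            )
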