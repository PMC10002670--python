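"""Seeded synthetic fixtures with exact ground truth for every pipeline input.

Generates: nested-box labeled atlas volumes with a 3-level ontology, sectioned
"brains" whose segmentation objects have known size and anatomical location
(so true regional loads are exact by construction), simulated raters with
known per-label probabilities, and gene-expression matrices whose genes fall
into known null / load-driven / age-driven classes.

All randomness flows through ``numpy`` PCG64 generators seeded as
``default_rng([seed, component_offset])``, so a fixed seed reproduces every
artifact bit-exactly across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .atlas import (
    AtlasVolume,
    CustomHierarchy,
    Ontology,
    build_ontology,
    collapse_to_custom,
    export_custom_hierarchy,
    write_label_volume,
    write_ontology,
)
from .qc import MarkerPoint, MarkerSet
from .quantify import SegmentationImage, write_segmentation_png
from .registration import (
    AtlasMap,
    LinearAnchoring,
    SectionRecord,
    slice_atlas,
    write_registration,
)

# fixed child-seed offsets per component
_SEED_ATLAS = 11
_SEED_BRAIN = 23
_SEED_RATERS = 37
_SEED_EXPR = 53

#: Section thickness used throughout the sectioning model (µm).
SECTION_THICKNESS_UM = 40.0


def section_spacing_um(thickness_um: float, interval: int) -> float:
    """Inter-section spacing of a 1-in-``interval`` sampling of serial sections."""
    if thickness_um <= 0 or interval <= 0:
        raise ValueError("thickness and interval must be positive")
    return thickness_um * interval


# ---------------------------------------------------------------------------
# atlas


@dataclass(frozen=True)
class SynthAtlasSpec:
    shape: tuple[int, int, int] = (24, 24, 12)
    n_major: int = 3  # level-2 slabs along x
    n_sub: int = 2  # leaves per slab along y
    margin: int = 2  # background shell around the "brain"
    voxel_size_um: float = 25.0

    def __post_init__(self) -> None:
        nx, ny, nz = self.shape
        if nx - 2 * self.margin < self.n_major or ny - 2 * self.margin < self.n_sub:
            raise ValueError("atlas shape too small for the requested region layout")


ROOT_ID = 1
_MAJOR_BASE = 2
_LEAF_BASE = 100


def make_synthetic_atlas(
    spec: SynthAtlasSpec = SynthAtlasSpec(), seed: int = 0
) -> tuple[AtlasVolume, Ontology]:
    """Nested-box atlas: root → n_major slabs → n_major·n_sub leaf boxes.

    Leaves tile the interior "brain" box exactly; everything else is 0.
    Slab and leaf boundaries are jittered by the seeded generator.
    """
    rng = np.random.default_rng([seed, _SEED_ATLAS])
    nx, ny, nz = spec.shape
    m = spec.margin
    labels = np.zeros(spec.shape, dtype=np.int32)

    def cuts(lo: int, hi: int, k: int) -> list[int]:
        # k segments between lo and hi, each of length >= 1, jittered
        base = np.linspace(lo, hi, k + 1).round().astype(int)
        for i in range(1, k):
            wiggle = int(rng.integers(-1, 2))
            base[i] = min(max(base[i] + wiggle, base[i - 1] + 1), hi - (k - i))
        return list(base)

    records: list[tuple[int, str, Optional[int]]] = [(ROOT_ID, "brain", None)]
    xcuts = cuts(m, nx - m, spec.n_major)
    leaf_id = _LEAF_BASE
    for i in range(spec.n_major):
        major_id = _MAJOR_BASE + i
        records.append((major_id, f"slab_{i}", ROOT_ID))
        ycuts = cuts(m, ny - m, spec.n_sub)
        for j in range(spec.n_sub):
            records.append((leaf_id, f"slab_{i}_part_{j}", major_id))
            labels[
                xcuts[i] : xcuts[i + 1], ycuts[j] : ycuts[j + 1], m : nz - m
            ] = leaf_id
            leaf_id += 1
    volume = AtlasVolume(labels=labels, voxel_size_um=spec.voxel_size_um)
    return volume, build_ontology(records)


def leaf_hierarchy(ontology: Ontology, volume: AtlasVolume) -> CustomHierarchy:
    """Identity hierarchy: every leaf label selected as its own region."""
    leaves = sorted(int(i) for i in volume.region_ids())
    return collapse_to_custom(ontology, leaves, volume)


# ---------------------------------------------------------------------------
# brain (sections + segmentations + ground truth)


@dataclass(frozen=True)
class SynthBrainSpec:
    n_sections: int = 3
    sampling_interval: int = 24
    thickness_um: float = SECTION_THICKNESS_UM
    objects_per_section: int = 4
    object_shape: tuple[int, int] = (2, 3)  # (height, width) pixel blocks
    deform: bool = False
    deform_shift: tuple[float, float] = (2.0, 0.0)


@dataclass
class SectionTruth:
    """Exact pixel bookkeeping for one section, by construction."""

    region_area_px: dict[int, int]
    stained_px: dict[int, int]
    n_objects: dict[int, int]

    def load_pct(self, region_id: int) -> Optional[float]:
        area = self.region_area_px.get(region_id, 0)
        if area == 0:
            return None
        return 100.0 * self.stained_px.get(region_id, 0) / area


@dataclass
class SyntheticBrain:
    brain_id: str
    sections: list[SectionRecord]
    atlas_maps: dict[str, AtlasMap]
    segmentations: dict[str, SegmentationImage]
    truth: dict[str, SectionTruth]
    hierarchy: CustomHierarchy

    def write(self, outdir: str | Path, volume: AtlasVolume, ontology: Ontology) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_label_volume(volume, outdir / "atlas.raw")
        write_ontology(ontology, outdir / "ontology.csv")
        export_custom_hierarchy(self.hierarchy, outdir / "hierarchy.txt")
        write_registration(self.sections, outdir / "registration.json", name=self.brain_id)
        for rec in self.sections:
            write_segmentation_png(self.segmentations[rec.filename], outdir / rec.filename)
        truth_payload = {
            sid: {
                "region_area_px": {str(k): v for k, v in t.region_area_px.items()},
                "stained_px": {str(k): v for k, v in t.stained_px.items()},
                "n_objects": {str(k): v for k, v in t.n_objects.items()},
            }
            for sid, t in self.truth.items()
        }
        (outdir / "ground_truth.json").write_text(json.dumps(truth_payload, indent=1))


def _axis_aligned_anchoring(volume: AtlasVolume, z: int) -> LinearAnchoring:
    nx, ny, _ = volume.shape
    return LinearAnchoring(
        o=np.array([-0.5, -0.5, float(z)]),
        u=np.array([float(nx), 0.0, 0.0]),
        v=np.array([0.0, float(ny), 0.0]),
    )


def _placeable(region_mask: np.ndarray, occupied: np.ndarray, oh: int, ow: int) -> np.ndarray:
    """Top-left corners where an oh×ow block fits wholly in region, off occupied."""
    free = (region_mask & ~occupied).astype(np.int64)
    h, w = free.shape
    if h < oh or w < ow:
        return np.zeros((h, w), dtype=bool)
    # integral image: blocksum(y, x) = sum of free[y:y+oh, x:x+ow]
    s = np.zeros((h + 1, w + 1), dtype=np.int64)
    s[1:, 1:] = free.cumsum(axis=0).cumsum(axis=1)
    block = (
        s[oh:, ow:] - s[:-oh, ow:] - s[oh:, :-ow] + s[:-oh, :-ow]
    )
    valid = np.zeros((h, w), dtype=bool)
    valid[: h - oh + 1, : w - ow + 1] = block == oh * ow
    return valid


def make_synthetic_brain(
    volume: AtlasVolume,
    ontology: Ontology,
    spec: SynthBrainSpec = SynthBrainSpec(),
    seed: int = 0,
    brain_id: str = "synth",
    stain: str = "other",
) -> SyntheticBrain:
    """Sections + segmentations with objects of known size and location.

    Every object is an axis-aligned pixel block placed wholly inside one leaf
    region (and not touching any other object, 8-connectivity), so per-region
    stained pixels, object counts and loads are exact arithmetic on the
    placements.  Regional areas are counted on the emitted atlas map.
    """
    rng = np.random.default_rng([seed, _SEED_BRAIN])
    hierarchy = leaf_hierarchy(ontology, volume)
    tissue_z = np.where(volume.labels.any(axis=(0, 1)))[0]
    if len(tissue_z) == 0:
        raise ValueError("atlas volume contains no tissue")
    zs = np.unique(
        np.linspace(tissue_z[0], tissue_z[-1], spec.n_sections).round().astype(int)
    )
    oh, ow = spec.object_shape

    sections: list[SectionRecord] = []
    atlas_maps: dict[str, AtlasMap] = {}
    segmentations: dict[str, SegmentationImage] = {}
    truth: dict[str, SectionTruth] = {}
    for snum, z in enumerate(zs):
        anchoring = _axis_aligned_anchoring(volume, int(z))
        nx, ny, _ = volume.shape
        amap = slice_atlas(volume, anchoring, width=nx, height=ny)
        filename = f"{brain_id}_s{snum:03d}.png"
        rec = SectionRecord(
            filename=filename, nr=snum * spec.sampling_interval,
            width=nx, height=ny, anchoring=anchoring,
        )
        lut = hierarchy.lookup_table(max_label=int(amap.region_ids.max(initial=0)))
        custom = lut[amap.region_ids]
        region_ids = [int(r) for r in np.unique(custom) if r > 0]
        area = {r: int((custom == r).sum()) for r in region_ids}
        stained = {r: 0 for r in region_ids}
        n_objects = {r: 0 for r in region_ids}

        seg = np.zeros(amap.region_ids.shape, dtype=bool)
        occupied = np.zeros_like(seg)  # objects plus 1-px halo, keeps objects apart
        for _ in range(spec.objects_per_section):
            candidates = [r for r in region_ids if area[r] >= oh * ow]
            rng.shuffle(candidates)
            placed = False
            for r in candidates:
                valid = _placeable(custom == r, occupied, oh, ow)
                idx = np.argwhere(valid)
                if len(idx) == 0:
                    continue
                yy, xx = idx[int(rng.integers(len(idx)))]
                seg[yy : yy + oh, xx : xx + ow] = True
                occupied[
                    max(0, yy - 1) : yy + oh + 1, max(0, xx - 1) : xx + ow + 1
                ] = True
                stained[r] += oh * ow
                n_objects[r] += 1
                placed = True
                break
            if not placed:
                break  # sections can saturate; truth stays exact
        atlas_maps[filename] = amap
        segmentations[filename] = SegmentationImage(pixels=seg, stain=stain)
        truth[filename] = SectionTruth(
            region_area_px=area, stained_px=stained, n_objects=n_objects
        )
        sections.append(rec)
    return SyntheticBrain(
        brain_id=brain_id,
        sections=sections,
        atlas_maps=atlas_maps,
        segmentations=segmentations,
        truth=truth,
        hierarchy=hierarchy,
    )


# ---------------------------------------------------------------------------
# raters


@dataclass(frozen=True)
class RaterSpec:
    n_raters: int = 3
    p_correct: float = 0.8  # P(accurate | verifiable marker)
    p_uncertain: float = 0.1
    p_damage: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_correct", "p_uncertain", "p_damage"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_uncertain + self.p_damage > 1:
            raise ValueError("p_uncertain + p_damage must be <= 1")


def make_synthetic_raters(
    amap: AtlasMap,
    grid_points: Sequence[tuple[float, float]],
    spec: RaterSpec = RaterSpec(),
    seed: int = 0,
    section_id: str = "s000",
) -> list[MarkerSet]:
    """Simulated rater markups with known per-label probabilities.

    Each on-tissue grid marker is damage with ``p_damage``, else uncertain
    with ``p_uncertain``, else accurate with ``p_correct`` (inaccurate
    otherwise); the generative accuracy is therefore exactly ``p_correct``.
    """
    rng = np.random.default_rng([seed, _SEED_RATERS])
    out = []
    for r in range(spec.n_raters):
        points = []
        for x, y in grid_points:
            ix, iy = int(np.floor(x + 0.5)), int(np.floor(y + 0.5))
            region = int(amap.region_ids[iy, ix]) if (
                0 <= iy < amap.height and 0 <= ix < amap.width
            ) else 0
            if region == 0:
                points.append(MarkerPoint(x=x, y=y, label="none", region_id=0))
                continue
            roll = rng.random()
            if roll < spec.p_damage:
                label = "damage"
            elif roll < spec.p_damage + spec.p_uncertain:
                label = "uncertain"
            elif rng.random() < spec.p_correct:
                label = "accurate"
            else:
                label = "inaccurate"
            points.append(MarkerPoint(x=x, y=y, label=label, region_id=region))
        out.append(MarkerSet(section_id=section_id, rater_id=f"rater_{r}", points=points))
    return out


# ---------------------------------------------------------------------------
# expression


@dataclass(frozen=True)
class SynthExprSpec:
    n_null: int = 40
    n_load_driven: int = 30  # true age-independent correlates
    n_age_driven: int = 30  # true age-dependent correlates
    load_effect: float = 1.0  # slope on within-age-standardized load, in SD units
    age_effect: float = 2.0  # expression shift between age groups, in SD units
    noise_sd: float = 1.0


def make_synthetic_expression(
    loads: Sequence[float],
    ages: Sequence,
    spec: SynthExprSpec = SynthExprSpec(),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """(normalized matrix, raw-count matrix, truth categories) per gene.

    Three generative classes matching the downstream categories:

    * null genes — pure noise (ns);
    * load-driven genes — expression follows the within-age-group centered
      load, with an age offset chosen to cancel the pooled load covariance,
      so the association survives age adjustment but not the pooled test
      (age_independent);
    * age-driven genes — expression shifts with age only, conditionally
      independent of load within groups (age_dependent).
    """
    rng = np.random.default_rng([seed, _SEED_EXPR])
    load = np.asarray(loads, dtype=float)
    age = np.asarray(ages)
    n = load.size
    if age.shape != load.shape:
        raise ValueError("loads and ages must have equal length")
    groups = pd.unique(age)
    centered = load.copy()
    for grp in groups:
        members = age == grp
        centered[members] -= load[members].mean()
    sd_w = centered.std()
    if sd_w == 0:
        raise ValueError("loads have no within-group variation")
    xc = centered / sd_w
    z = (age == groups[-1]).astype(float)
    z = z - z.mean()

    cov_load_xc = float(np.mean((load - load.mean()) * xc))
    cov_load_z = float(np.mean((load - load.mean()) * z))

    rows, names, cats = [], [], []

    def add(name: str, values: np.ndarray, cat: str) -> None:
        names.append(name)
        rows.append(values)
        cats.append(cat)

    for i in range(spec.n_null):
        add(f"null_{i:04d}", rng.normal(0, spec.noise_sd, n), "ns")
    for i in range(spec.n_load_driven):
        b = spec.load_effect
        # cancel the pooled covariance through an opposing age offset
        c = -b * cov_load_xc / cov_load_z if cov_load_z != 0 else 0.0
        vals = b * xc + c * z + rng.normal(0, spec.noise_sd, n)
        add(f"loadgene_{i:04d}", vals, "age_independent")
    for i in range(spec.n_age_driven):
        vals = spec.age_effect * z + rng.normal(0, spec.noise_sd, n)
        add(f"agegene_{i:04d}", vals, "age_dependent")

    norm = pd.DataFrame(
        np.vstack(rows), index=names, columns=[f"sample_{j:03d}" for j in range(n)]
    )
    counts = pd.DataFrame(
        rng.poisson(np.exp2(norm.to_numpy() + 5.0)), index=norm.index, columns=norm.columns
    )
    truth = pd.Series(cats, index=names, name="true_category")
    return norm, counts, truth
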