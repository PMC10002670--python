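"""Grid-sampled quality control of atlas registration and section integrity.

Markers placed on a systematic grid are labeled by raters; per-region scores:

    accuracy    = accurate / (accurate + inaccurate)      (undefined when the
                  denominator is zero, i.e. nothing could be verified)
    uncertainty = uncertain / (accurate + inaccurate + uncertain)
    damage      = damage markers / total markers on the section

Sections with damage strictly greater than 30% are excluded from analysis.
Scores are aggregated over (rater, brain) assessments as mean ± SEM, with
undefined accuracies excluded from the accuracy mean and its n.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import FormatError, GeometryError
from .registration import LinearAnchoring

import numpy as np

MARKER_LABELS = ("accurate", "inaccurate", "uncertain", "damage", "none")

#: Grid spacings in atlas voxels used for the two assessments.
ACCURACY_GRID_SPACING_VOXELS = 15.0
DAMAGE_GRID_SPACING_VOXELS = 5.0

#: Sections with damage fraction strictly above this are excluded.
DAMAGE_THRESHOLD = 0.30


@dataclass(frozen=True)
class GridSpec:
    """Systematic sampling grid in section-pixel units."""

    spacing_px: float
    origin_offset_px: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.spacing_px < 1:
            raise ValueError("spacing_px must be >= 1")

    def offset(self) -> tuple[float, float]:
        """Deterministic default origin: half a spacing in from the corner."""
        if self.origin_offset_px is not None:
            return self.origin_offset_px
        half = math.floor(self.spacing_px / 2)
        return (half, half)


@dataclass(frozen=True)
class MarkerPoint:
    x: float
    y: float
    label: str
    region_id: int

    def __post_init__(self) -> None:
        if self.label not in MARKER_LABELS:
            raise FormatError(f"unknown marker label {self.label!r}")


@dataclass
class MarkerSet:
    """All markers of one rater on one section."""

    section_id: str
    rater_id: str
    points: list[MarkerPoint] = field(default_factory=list)


@dataclass(frozen=True)
class QCCounts:
    n_accurate: int = 0
    n_inaccurate: int = 0
    n_uncertain: int = 0
    n_damage: int = 0

    def __post_init__(self) -> None:
        for name in ("n_accurate", "n_inaccurate", "n_uncertain", "n_damage"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_accurate + self.n_inaccurate + self.n_uncertain + self.n_damage


@dataclass(frozen=True)
class ScoreAssessment:
    """One (region, rater, brain) assessment; accuracy may be undefined."""

    region_id: int
    rater_id: str
    brain_id: str
    accuracy: Optional[float]
    uncertainty: float


@dataclass(frozen=True)
class RegionAggregate:
    region_id: int
    accuracy_mean: Optional[float]
    accuracy_sem: Optional[float]
    n_assessments: int
    uncertainty_mean: Optional[float]
    uncertainty_sem: Optional[float]
    n_uncertainty: int


def generate_grid(width: int, height: int, spec: GridSpec) -> list[tuple[float, float]]:
    """Grid points ``(ox + i*s, oy + j*s)`` strictly inside the image, row-major."""
    if width < 1 or height < 1:
        raise ValueError("image dims must be >= 1")
    ox, oy = spec.offset()
    s = spec.spacing_px
    points = []
    y = oy
    while y < height:
        x = ox
        while x < width:
            points.append((x, y))
            x += s
        y += s
    return points


def voxel_spacing_to_pixels(
    spacing_voxels: float, anchoring: LinearAnchoring, width: int
) -> float:
    """Convert an atlas-voxel grid spacing to section pixels via |u|."""
    ulen = float(np.linalg.norm(anchoring.u))
    if ulen == 0:
        raise GeometryError("anchoring u has zero length")
    return spacing_voxels * width / ulen


def counts_from_markers(points: Iterable[MarkerPoint]) -> QCCounts:
    tally = {lbl: 0 for lbl in MARKER_LABELS}
    for p in points:
        tally[p.label] += 1
    return QCCounts(
        n_accurate=tally["accurate"],
        n_inaccurate=tally["inaccurate"],
        n_uncertain=tally["uncertain"],
        n_damage=tally["damage"],
    )


def score_damage(markers: MarkerSet) -> Optional[float]:
    """Damage markers / total markers on the section; None when no markers."""
    n_total = len(markers.points)
    if n_total == 0:
        return None
    n_damage = sum(1 for p in markers.points if p.label == "damage")
    return n_damage / n_total


def filter_damaged_sections(
    damage_by_section: Sequence[tuple[str, float]],
    threshold: float = DAMAGE_THRESHOLD,
) -> tuple[list[str], list[str]]:
    """Split section IDs into (kept, excluded); excluded iff damage > threshold.

    The comparison is strict: a section at exactly the threshold is kept.
    Input order is preserved in both lists.
    """
    kept, excluded = [], []
    for section_id, frac in damage_by_section:
        if frac > threshold:
            excluded.append(section_id)
        else:
            kept.append(section_id)
    return kept, excluded


def score_region(counts: QCCounts) -> tuple[Optional[float], Optional[float]]:
    """(accuracy, uncertainty) from marker counts.

    Accuracy is None when no marker could be verified (accurate + inaccurate
    = 0); uncertainty is None only for all-zero counts.
    """
    verified = counts.n_accurate + counts.n_inaccurate
    assessed = verified + counts.n_uncertain
    accuracy = counts.n_accurate / verified if verified > 0 else None
    uncertainty = counts.n_uncertain / assessed if assessed > 0 else None
    return accuracy, uncertainty


def score_marker_set(markers: MarkerSet, brain_id: str = "") -> list[ScoreAssessment]:
    """Per-region assessments from one rater's markers on one section."""
    by_region: dict[int, list[MarkerPoint]] = {}
    for p in markers.points:
        if p.label in ("accurate", "inaccurate", "uncertain"):
            by_region.setdefault(p.region_id, []).append(p)
    out = []
    for region_id in sorted(by_region):
        accuracy, uncertainty = score_region(counts_from_markers(by_region[region_id]))
        out.append(
            ScoreAssessment(
                region_id=region_id,
                rater_id=markers.rater_id,
                brain_id=brain_id or markers.section_id,
                accuracy=accuracy,
                uncertainty=uncertainty if uncertainty is not None else 0.0,
            )
        )
    return out


def _mean_sem(values: Sequence[float]) -> tuple[Optional[float], Optional[float], int]:
    n = len(values)
    if n == 0:
        return None, None, 0
    mean = sum(values) / n
    if n < 2:
        return mean, None, n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var) / math.sqrt(n), n


def aggregate_scores(assessments: Sequence[ScoreAssessment]) -> dict[int, RegionAggregate]:
    """Aggregate per-(rater, brain) assessments into per-region mean ± SEM.

    Undefined accuracies are excluded from the accuracy mean and its
    ``n_assessments``; SEM uses the n−1 sample SD and is None for n < 2.
    """
    by_region: dict[int, list[ScoreAssessment]] = {}
    for a in assessments:
        by_region.setdefault(a.region_id, []).append(a)
    out = {}
    for region_id, items in sorted(by_region.items()):
        acc_vals = [a.accuracy for a in items if a.accuracy is not None]
        unc_vals = [a.uncertainty for a in items]
        acc_mean, acc_sem, n_acc = _mean_sem(acc_vals)
        unc_mean, unc_sem, n_unc = _mean_sem(unc_vals)
        out[region_id] = RegionAggregate(
            region_id=region_id,
            accuracy_mean=acc_mean,
            accuracy_sem=acc_sem,
            n_assessments=n_acc,
            uncertainty_mean=unc_mean,
            uncertainty_sem=unc_sem,
            n_uncertainty=n_unc,
        )
    return out


def pooled_region_scores(
    marker_sets: Sequence[MarkerSet],
) -> dict[int, tuple[Optional[float], Optional[float]]]:
    """Alternative pooled-count scoring: sum counts across raters first."""
    by_region: dict[int, list[MarkerPoint]] = {}
    for ms in marker_sets:
        for p in ms.points:
            by_region.setdefault(p.region_id, []).append(p)
    return {
        region_id: score_region(counts_from_markers(pts))
        for region_id, pts in sorted(by_region.items())
    }


# ---------------------------------------------------------------------------
# marker and report I/O

_MARKER_FIELDS = ["section_id", "rater_id", "x", "y", "label", "region_id"]


def write_marker_file(marker_sets: Sequence[MarkerSet], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_MARKER_FIELDS)
        for ms in marker_sets:
            for p in ms.points:
                writer.writerow([ms.section_id, ms.rater_id, p.x, p.y, p.label, p.region_id])


def read_marker_file(path: str | Path) -> list[MarkerSet]:
    """Read marker TSV; markers grouped by (section_id, rater_id) in file order."""
    sets: dict[tuple[str, str], MarkerSet] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            return []
        if header != _MARKER_FIELDS:
            raise FormatError(f"marker file header must be {_MARKER_FIELDS}")
        for row in reader:
            if not row:
                continue
            section_id, rater_id, x, y, label, region_id = row
            if label not in MARKER_LABELS:
                raise FormatError(f"unknown marker label {label!r}")
            key = (section_id, rater_id)
            if key not in sets:
                sets[key] = MarkerSet(section_id=section_id, rater_id=rater_id)
            sets[key].points.append(
                MarkerPoint(x=float(x), y=float(y), label=label, region_id=int(region_id))
            )
    return list(sets.values())


def write_qc_report(aggregates: dict[int, RegionAggregate], path: str | Path) -> None:
    def fmt(v: Optional[float]) -> str:
        return "" if v is None else repr(v)

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            [
                "region_id",
                "accuracy_mean",
                "accuracy_sem",
                "n_assessments",
                "uncertainty_mean",
                "uncertainty_sem",
                "n_uncertainty",
            ]
        )
        for region_id in sorted(aggregates):
            agg = aggregates[region_id]
            writer.writerow(
                [
                    region_id,
                    fmt(agg.accuracy_mean),
                    fmt(agg.accuracy_sem),
                    agg.n_assessments,
                    fmt(agg.uncertainty_mean),
                    fmt(agg.uncertainty_sem),
                    agg.n_uncertainty,
                ]
            )
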