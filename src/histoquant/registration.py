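"""Section-to-atlas registration: oblique plane slicing and anchor-point warping.

A section image is placed in atlas voxel space by nine numbers ``(o, u, v)``:
``o`` is the atlas-space position of the image's top-left corner, ``u`` spans
the image width and ``v`` the image height.  Pixel ``(x, y)`` of a
``width×height`` image samples the atlas at

    p = o + ((x + 0.5) / width) * u + ((y + 0.5) / height) * v

with nearest-voxel lookup (ties round half-up per axis); points outside the
volume map to 0.  Nonlinear refinement is expressed as anchor-point pairs in
section-pixel coordinates and realized as a piecewise-linear (Delaunay)
displacement field that is exact at every anchor, zero at the image frame
where no anchor reaches, and applied by inverse (backward) nearest-neighbor
warping so region IDs stay categorical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import Delaunay, QhullError

from .atlas import AtlasVolume
from .errors import FormatError, GeometryError

#: Per-stain downscale factors applied before registration, then a further
#: global factor to meet registration-image size limits.
STAIN_SCALE_FACTORS = {
    "AB1-42": 0.20,
    "GFAP": 0.40,
    "Iba1": 0.40,
    "NeuN": 0.40,
    "thionine": 0.35,
}
GLOBAL_SCALE_FACTOR = 0.50

_PARALLEL_EPS = 1e-12


@dataclass(frozen=True)
class LinearAnchoring:
    """Plane geometry of one section in atlas voxel space."""

    o: np.ndarray
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        for name in ("o", "u", "v"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.shape != (3,):
                raise GeometryError(f"{name} must be a 3-vector")
            object.__setattr__(self, name, vec)
        if np.linalg.norm(self.u) == 0 or np.linalg.norm(self.v) == 0:
            raise GeometryError("u and v must be nonzero")
        if np.linalg.norm(np.cross(self.u, self.v)) <= _PARALLEL_EPS:
            raise GeometryError("u and v must not be parallel")

    @classmethod
    def from_flat(cls, values: Sequence[float]) -> "LinearAnchoring":
        vals = list(values)
        if len(vals) != 9:
            raise FormatError(f"anchoring must have 9 numbers, got {len(vals)}")
        return cls(o=np.array(vals[0:3]), u=np.array(vals[3:6]), v=np.array(vals[6:9]))

    def to_flat(self) -> list[float]:
        return [float(x) for x in (*self.o, *self.u, *self.v)]


@dataclass(frozen=True)
class AtlasMap:
    """Per-pixel region-ID image; ``region_ids[y, x]`` is pixel ``(x, y)``."""

    region_ids: np.ndarray
    width: int
    height: int
    provenance: str = "linear"

    def __post_init__(self) -> None:
        arr = np.asarray(self.region_ids)
        if arr.shape != (self.height, self.width):
            raise ValueError(f"region_ids shape {arr.shape} != (height, width)")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("region_ids must be integer")
        object.__setattr__(self, "region_ids", arr)


@dataclass(frozen=True)
class DeformationSpec:
    """Anchor pairs ``((sx, sy), (tx, ty))`` in section-pixel coordinates."""

    anchors: tuple[tuple[tuple[float, float], tuple[float, float]], ...]
    width: int
    height: int

    def __post_init__(self) -> None:
        anchors = tuple(
            ((float(sx), float(sy)), (float(tx), float(ty)))
            for (sx, sy), (tx, ty) in self.anchors
        )
        object.__setattr__(self, "anchors", anchors)
        targets = [t for _, t in anchors]
        if len(set(targets)) != len(targets):
            raise ValueError("duplicate target anchor points")
        # only targets are bounded: a source may point outside the frame when
        # the section content was displaced past the image edge
        for _, (tx, ty) in anchors:
            if not (0 <= tx <= self.width and 0 <= ty <= self.height):
                raise ValueError(
                    f"target anchor ({tx}, {ty}) outside [0,{self.width}]x[0,{self.height}]"
                )


class DeformationField:
    """Continuous target→source displacement field over a section image.

    ``displacement`` holds the field sampled at integer pixel coordinates,
    shape ``(height, width, 2)`` with ``[..., 0]`` the x-component.
    """

    def __init__(self, width: int, height: int, interpolator=None):
        self.width = int(width)
        self.height = int(height)
        self._interp = interpolator
        self._grid: Optional[np.ndarray] = None

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Displacement at arbitrary ``(x, y)`` points, shape ``(n, 2)``."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self._interp is None:
            return np.zeros((pts.shape[0], 2))
        out = self._interp(pts)
        return np.nan_to_num(out, nan=0.0)

    @property
    def displacement(self) -> np.ndarray:
        if self._grid is None:
            xs, ys = np.meshgrid(np.arange(self.width), np.arange(self.height))
            pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
            self._grid = self.sample(pts).reshape(self.height, self.width, 2)
        return self._grid


def slice_atlas(
    volume: AtlasVolume, anchoring: LinearAnchoring, width: int, height: int
) -> AtlasMap:
    """Sample the atlas along the anchored plane into a per-pixel region map."""
    if width < 1 or height < 1:
        raise ValueError("width and height must be >= 1")
    xs = (np.arange(width) + 0.5) / width
    ys = (np.arange(height) + 0.5) / height
    # p[y, x, :] = o + xs[x]*u + ys[y]*v
    p = (
        anchoring.o[None, None, :]
        + xs[None, :, None] * anchoring.u[None, None, :]
        + ys[:, None, None] * anchoring.v[None, None, :]
    )
    idx = np.floor(p + 0.5).astype(np.int64)  # round half-up per axis
    nx, ny, nz = volume.shape
    inb = (
        (idx[..., 0] >= 0)
        & (idx[..., 0] < nx)
        & (idx[..., 1] >= 0)
        & (idx[..., 1] < ny)
        & (idx[..., 2] >= 0)
        & (idx[..., 2] < nz)
    )
    out = np.zeros((height, width), dtype=volume.labels.dtype)
    if inb.any():
        ii = idx[inb]
        out[inb] = volume.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
    return AtlasMap(region_ids=out, width=width, height=height, provenance="linear")


def _frame_points(width: float, height: float) -> np.ndarray:
    w, h = float(width), float(height)
    return np.array(
        [
            (0, 0), (w, 0), (0, h), (w, h),
            (w / 2, 0), (0, h / 2), (w, h / 2), (w / 2, h),
        ]
    )


def build_deformation(spec: DeformationSpec) -> DeformationField:
    """Triangulated piecewise-linear field from anchor pairs.

    The target anchor set is augmented with zero-displacement points at the
    four image corners and edge midpoints, but only where those frame points
    are not already covered by the anchors' convex hull — so a set of anchors
    spanning the whole frame (e.g. all four corners translated uniformly)
    reproduces the exact affine field with no spurious pinning.
    """
    if not spec.anchors:
        return DeformationField(spec.width, spec.height, None)
    targets = np.array([t for _, t in spec.anchors], dtype=float)
    disp = np.array(
        [(sx - tx, sy - ty) for (sx, sy), (tx, ty) in spec.anchors], dtype=float
    )
    frame = _frame_points(spec.width, spec.height)
    keep = np.ones(len(frame), dtype=bool)
    # drop frame points coincident with a target anchor
    for i, fp in enumerate(frame):
        if np.any(np.linalg.norm(targets - fp, axis=1) < 1e-9):
            keep[i] = False
    # drop frame points inside/on the anchors' convex hull
    if len(targets) >= 3:
        try:
            tri = Delaunay(targets)
            covered = tri.find_simplex(frame) >= 0
            keep &= ~covered
        except QhullError:
            pass  # degenerate anchor layout: keep the frame
    pts = np.vstack([targets, frame[keep]])
    vals = np.vstack([disp, np.zeros((int(keep.sum()), 2))])
    if len(pts) < 3:
        raise GeometryError("not enough points to triangulate a deformation field")
    interp = LinearNDInterpolator(pts, vals, fill_value=0.0)
    return DeformationField(spec.width, spec.height, interp)


def warp_atlas_map(amap: AtlasMap, dfield: DeformationField) -> AtlasMap:
    """Backward-warp a region map: output (x,y) reads the input at (x,y)+d(x,y)."""
    if (amap.width, amap.height) != (dfield.width, dfield.height):
        raise ValueError("atlas map and deformation field dims disagree")
    disp = dfield.displacement
    xs, ys = np.meshgrid(np.arange(amap.width), np.arange(amap.height))
    sx = np.floor(xs + disp[..., 0] + 0.5).astype(np.int64)
    sy = np.floor(ys + disp[..., 1] + 0.5).astype(np.int64)
    inb = (sx >= 0) & (sx < amap.width) & (sy >= 0) & (sy < amap.height)
    out = np.zeros_like(amap.region_ids)
    out[inb] = amap.region_ids[sy[inb], sx[inb]]
    return AtlasMap(
        region_ids=out, width=amap.width, height=amap.height, provenance="nonlinear"
    )


# ---------------------------------------------------------------------------
# registration descriptor I/O


@dataclass
class SectionRecord:
    """One section's registration payload."""

    filename: str
    nr: int
    width: int
    height: int
    anchoring: LinearAnchoring
    deformation: Optional[DeformationSpec] = None
    metadata: dict = field(default_factory=dict)


def read_registration(path: str | Path) -> list[SectionRecord]:
    """Read the registration JSON dialect.

    Layout: ``{"name", "target", "slices": [{"filename", "nr", "width",
    "height", "anchoring": [ox,oy,oz,ux,uy,uz,vx,vy,vz], "markers":
    [[tx,ty,sx,sy], ...]}]}``; ``markers`` optional (absent means linear only).
    """
    payload = json.loads(Path(path).read_text())
    if "slices" not in payload:
        raise FormatError("registration file has no 'slices' array")
    records = []
    for sl in payload["slices"]:
        if "anchoring" not in sl:
            raise FormatError(f"slice {sl.get('filename')!r} has no anchoring")
        anchoring = LinearAnchoring.from_flat(sl["anchoring"])
        width, height = int(sl["width"]), int(sl["height"])
        deformation = None
        if "markers" in sl:
            anchors = tuple(
                ((float(sx), float(sy)), (float(tx), float(ty)))
                for tx, ty, sx, sy in sl["markers"]
            )
            deformation = DeformationSpec(anchors=anchors, width=width, height=height)
        records.append(
            SectionRecord(
                filename=str(sl.get("filename", "")),
                nr=int(sl.get("nr", 0)),
                width=width,
                height=height,
                anchoring=anchoring,
                deformation=deformation,
                metadata={
                    k: v
                    for k, v in sl.items()
                    if k not in ("filename", "nr", "width", "height", "anchoring", "markers")
                },
            )
        )
    return records


def write_registration(
    records: Sequence[SectionRecord],
    path: str | Path,
    name: str = "series",
    target: str = "atlas",
) -> None:
    slices = []
    for rec in records:
        sl: dict = {
            "filename": rec.filename,
            "nr": rec.nr,
            "width": rec.width,
            "height": rec.height,
            "anchoring": rec.anchoring.to_flat(),
        }
        sl.update(rec.metadata)
        if rec.deformation is not None:
            sl["markers"] = [
                [tx, ty, sx, sy] for (sx, sy), (tx, ty) in rec.deformation.anchors
            ]
        slices.append(sl)
    Path(path).write_text(json.dumps({"name": name, "target": target, "slices": slices}, indent=1))


def atlas_map_for_section(volume: AtlasVolume, rec: SectionRecord) -> AtlasMap:
    """Full registration chain for one section: slice, then warp if refined."""
    amap = slice_atlas(volume, rec.anchoring, rec.width, rec.height)
    if rec.deformation is not None:
        amap = warp_atlas_map(amap, build_deformation(rec.deformation))
    return amap


# ---------------------------------------------------------------------------
# preprocessing


def preprocessed_dims(width: int, height: int, stain: str) -> tuple[int, int]:
    """Image dims after the per-stain downscale and the global resize."""
    factor = STAIN_SCALE_FACTORS.get(stain, 1.0) * GLOBAL_SCALE_FACTOR
    return max(1, round(width * factor)), max(1, round(height * factor))


def downscale_nearest(image: np.ndarray, factor: float) -> np.ndarray:
    """Nearest-neighbor downscale sampling at output pixel centers."""
    if not (0 < factor <= 1):
        raise ValueError("factor must be in (0, 1]")
    h, w = image.shape[:2]
    wp, hp = max(1, round(w * factor)), max(1, round(h * factor))
    src_x = np.minimum((np.floor((np.arange(wp) + 0.5) * w / wp)).astype(int), w - 1)
    src_y = np.minimum((np.floor((np.arange(hp) + 0.5) * h / hp)).astype(int), h - 1)
    return image[np.ix_(src_y, src_x)]


# ---------------------------------------------------------------------------
# atlas map export


def write_atlas_map(amap: AtlasMap, path: str | Path) -> None:
    """Write a region map as raw int32 plus a JSON sidecar."""
    path = Path(path)
    amap.region_ids.astype("<i4").tofile(path)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(
            {"width": amap.width, "height": amap.height, "provenance": amap.provenance}
        )
    )


def read_atlas_map(path: str | Path) -> AtlasMap:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.fromfile(path, dtype="<i4").reshape(meta["height"], meta["width"])
    return AtlasMap(
        region_ids=data,
        width=meta["width"],
        height=meta["height"],
        provenance=meta.get("provenance", "linear"),
    )
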