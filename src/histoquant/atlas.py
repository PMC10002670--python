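"""Labeled atlas volumes, region ontologies, custom hierarchies and hemisphere masks.

The atlas volume is a 3D grid of non-negative integer region IDs where 0 is
background (outside the brain).  The ontology is a rooted tree over region IDs.
A :class:`CustomHierarchy` collapses fine-grained atlas labels onto a
user-selected set of ontology nodes ("intermediate hierarchy"): every atlas
label maps to its nearest selected ancestor-or-self, or to :data:`UNMAPPED`.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import FormatError, StructureError

#: Sentinel custom ID for atlas labels with no selected ancestor.
UNMAPPED = -1

#: Background label; never mapped and never part of any region tally.
BACKGROUND_ID = 0

#: Default medio-lateral axis of a raw volume (explicit, never inferred).
DEFAULT_ML_AXIS = 0

_SIDES = ("left", "right", "both")


@dataclass(frozen=True)
class AtlasVolume:
    """A labeled 3D reference volume.

    Parameters
    ----------
    labels
        3D integer array of region IDs, ``labels >= 0``.
    voxel_size_um
        Isotropic voxel size in micrometres.
    background_id
        Fixed at 0 by convention.
    """

    labels: np.ndarray
    voxel_size_um: float
    background_id: int = BACKGROUND_ID

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise StructureError(f"labels must be 3D, got ndim={arr.ndim}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError(f"labels must be an integer array, got {arr.dtype}")
        if arr.size and arr.min() < 0:
            raise StructureError("negative region IDs are not allowed")
        if self.voxel_size_um <= 0:
            raise StructureError("voxel_size_um must be positive")
        object.__setattr__(self, "labels", arr)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    def region_ids(self) -> np.ndarray:
        """Sorted array of nonzero IDs present in the volume."""
        ids = np.unique(self.labels)
        return ids[ids != self.background_id]


class Ontology:
    """A rooted region tree with ancestor/descendant queries.

    Construct via :func:`build_ontology`; direct construction assumes the
    records already form a valid tree.
    """

    def __init__(self, records: Sequence[tuple[int, str, Optional[int]]]):
        self._name: dict[int, str] = {}
        self._parent: dict[int, Optional[int]] = {}
        self._children: dict[int, list[int]] = {}
        roots = []
        for rid, name, parent in records:
            rid = int(rid)
            if rid in self._name:
                raise StructureError(f"duplicate ontology ID {rid}")
            if not name:
                raise StructureError(f"ontology node {rid} has an empty name")
            self._name[rid] = str(name)
            self._parent[rid] = None if parent is None else int(parent)
            self._children.setdefault(rid, [])
            if parent is None:
                roots.append(rid)
        if len(roots) != 1:
            raise StructureError(f"ontology must have exactly one root, found {len(roots)}")
        self._root = roots[0]
        for rid, parent in self._parent.items():
            if parent is None:
                continue
            if parent not in self._name:
                raise StructureError(f"node {rid} references unknown parent {parent}")
            self._children[parent].append(rid)
        # cycle check: every node must reach the root
        for rid in self._name:
            seen = set()
            cur: Optional[int] = rid
            while cur is not None:
                if cur in seen:
                    raise StructureError(f"cycle detected through ontology node {cur}")
                seen.add(cur)
                cur = self._parent[cur]
            if self._root not in seen:
                raise StructureError(f"node {rid} is not connected to the root")

    @property
    def root(self) -> int:
        return self._root

    def __contains__(self, rid: int) -> bool:
        return rid in self._name

    def __len__(self) -> int:
        return len(self._name)

    def ids(self) -> list[int]:
        return list(self._name)

    def name(self, rid: int) -> str:
        return self._name[rid]

    def parent(self, rid: int) -> Optional[int]:
        return self._parent[rid]

    def ancestors(self, rid: int) -> list[int]:
        """Ancestors of ``rid`` from parent up to the root (exclusive of self)."""
        out = []
        cur = self._parent[rid]
        while cur is not None:
            out.append(cur)
            cur = self._parent[cur]
        return out

    def children(self, rid: int) -> list[int]:
        return list(self._children[rid])

    def descendants(self, rid: int) -> list[int]:
        out = []
        stack = list(self._children[rid])
        while stack:
            cur = stack.pop()
            out.append(cur)
            stack.extend(self._children[cur])
        return out

    def is_ancestor(self, a: int, b: int) -> bool:
        """True if ``a`` is a strict ancestor of ``b``."""
        return a in self.ancestors(b)

    def breadth_first(self) -> list[int]:
        order = []
        q = deque([self._root])
        while q:
            cur = q.popleft()
            order.append(cur)
            q.extend(self._children[cur])
        return order


def build_ontology(records: Sequence[tuple[int, str, Optional[int]]]) -> Ontology:
    """Validate ``(id, name, parent_id)`` records into an :class:`Ontology`."""
    if not records:
        raise StructureError("ontology records are empty")
    return Ontology(records)


def read_ontology(path: str | Path) -> Ontology:
    """Read an ontology from CSV (``id,name,parent_id``) or a JSON tree."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        tree = json.loads(path.read_text())
        records: list[tuple[int, str, Optional[int]]] = []

        def walk(node: Mapping, parent: Optional[int]) -> None:
            records.append((int(node["id"]), str(node["name"]), parent))
            for child in node.get("children", []):
                walk(child, int(node["id"]))

        walk(tree, None)
        return build_ontology(records)
    records = []
    with open(path, newline="") as fh:
        import csv

        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"id", "name", "parent_id"} <= set(reader.fieldnames):
            raise FormatError("ontology CSV must have header id,name,parent_id")
        for row in reader:
            parent = row["parent_id"].strip()
            records.append((int(row["id"]), row["name"], int(parent) if parent else None))
    return build_ontology(records)


def write_ontology(onto: Ontology, path: str | Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "name", "parent_id"])
        for rid in onto.breadth_first():
            parent = onto.parent(rid)
            writer.writerow([rid, onto.name(rid), "" if parent is None else parent])


@dataclass
class CustomHierarchy:
    """Mapping from every atlas label to a selected "intermediate" region.

    ``leaf_map`` is total over the nonzero labels of the volume it was built
    from; labels with no selected ancestor map to :data:`UNMAPPED`.
    """

    selected_ids: list[int]
    leaf_map: dict[int, int]
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, custom in self.leaf_map.items():
            if custom != UNMAPPED and custom not in self.selected_ids:
                raise StructureError(f"label {label} maps to unselected ID {custom}")

    def map_label(self, label: int) -> int:
        """Custom ID for an atlas label (background maps to itself)."""
        if label == BACKGROUND_ID:
            return BACKGROUND_ID
        return self.leaf_map.get(label, UNMAPPED)

    def unmapped_labels(self) -> list[int]:
        return sorted(k for k, v in self.leaf_map.items() if v == UNMAPPED)

    def members(self, custom_id: int) -> list[int]:
        return sorted(k for k, v in self.leaf_map.items() if v == custom_id)

    def lookup_table(self, max_label: Optional[int] = None) -> np.ndarray:
        """Dense LUT from raw label to custom ID, for vectorized relabeling."""
        if max_label is None:
            max_label = max(self.leaf_map, default=0)
        lut = np.full(max_label + 1, UNMAPPED, dtype=np.int64)
        lut[BACKGROUND_ID] = BACKGROUND_ID
        for label, custom in self.leaf_map.items():
            if label <= max_label:
                lut[label] = custom
        return lut


def collapse_to_custom(
    ontology: Ontology, selected_ids: Sequence[int], volume: AtlasVolume
) -> CustomHierarchy:
    """Collapse every nonzero volume label onto its nearest selected ancestor-or-self.

    When both a node and its descendant are selected, the nearest (deepest)
    selected ancestor wins.  Labels with no selected ancestor map to
    :data:`UNMAPPED` and are reported via
    :meth:`CustomHierarchy.unmapped_labels`.
    """
    if not selected_ids:
        raise ValueError("selection is empty")
    selected = [int(s) for s in selected_ids]
    for sid in selected:
        if sid not in ontology:
            raise ValueError(f"selected ID {sid} not in ontology")
    sel_set = set(selected)
    leaf_map: dict[int, int] = {}
    for label in volume.region_ids():
        label = int(label)
        if label not in ontology:
            raise StructureError(f"volume label {label} not present in ontology")
        target = UNMAPPED
        cur: Optional[int] = label
        while cur is not None:
            if cur in sel_set:
                target = cur
                break
            cur = ontology.parent(cur)
        leaf_map[label] = target
    names = {sid: ontology.name(sid) for sid in selected}
    return CustomHierarchy(selected_ids=selected, leaf_map=leaf_map, names=names)


def export_custom_hierarchy(hierarchy: CustomHierarchy, path: str | Path) -> None:
    """Write the hierarchy as TSV: ``custom_name<TAB>custom_id<TAB>member_ids``.

    ``member_ids`` is semicolon-separated; UNMAPPED labels appear on a row with
    ``custom_id`` −1.
    """
    lines = ["custom_name\tcustom_id\tmember_ids"]
    for cid in hierarchy.selected_ids:
        members = ";".join(str(m) for m in hierarchy.members(cid))
        lines.append(f"{hierarchy.names.get(cid, str(cid))}\t{cid}\t{members}")
    unmapped = hierarchy.unmapped_labels()
    if unmapped:
        lines.append(f"UNMAPPED\t{UNMAPPED}\t" + ";".join(str(m) for m in unmapped))
    Path(path).write_text("\n".join(lines) + "\n")


def read_custom_hierarchy(path: str | Path) -> CustomHierarchy:
    """Inverse of :func:`export_custom_hierarchy`."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != ["custom_name", "custom_id", "member_ids"]:
        raise FormatError("custom hierarchy TXT must start with the TSV header")
    selected: list[int] = []
    leaf_map: dict[int, int] = {}
    names: dict[int, str] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"malformed hierarchy row: {line!r}")
        name, cid_s, members_s = parts
        cid = int(cid_s)
        members = [int(m) for m in members_s.split(";") if m]
        if cid != UNMAPPED:
            selected.append(cid)
            names[cid] = name
        for m in members:
            leaf_map[m] = cid
    return CustomHierarchy(selected_ids=selected, leaf_map=leaf_map, names=names)


@dataclass(frozen=True)
class HemisphereMask:
    """Boolean voxel mask selecting one hemisphere (or both)."""

    side: str
    midline_voxel: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.side not in _SIDES:
            raise ValueError(f"side must be one of {_SIDES}, got {self.side!r}")


def make_hemisphere_mask(
    volume: AtlasVolume, side: str, midline_voxel: float, ml_axis: int = DEFAULT_ML_AXIS
) -> HemisphereMask:
    """Build a hemisphere mask along the medio-lateral axis.

    Half-open convention: ``left`` is coordinate < midline, ``right`` is
    coordinate >= midline, so left and right always partition the volume.
    """
    if side not in _SIDES:
        raise ValueError(f"side must be one of {_SIDES}, got {side!r}")
    extent = volume.shape[ml_axis]
    if not (0 <= midline_voxel <= extent):
        raise ValueError(f"midline_voxel {midline_voxel} outside [0, {extent}]")
    if side == "both":
        mask = np.ones(volume.shape, dtype=bool)
    else:
        coords = np.arange(extent, dtype=float)
        onside = coords < midline_voxel if side == "left" else coords >= midline_voxel
        shape = [1, 1, 1]
        shape[ml_axis] = extent
        mask = np.broadcast_to(onside.reshape(shape), volume.shape).copy()
    return HemisphereMask(side=side, midline_voxel=float(midline_voxel), mask=mask)


# ---------------------------------------------------------------------------
# volume I/O


def read_label_volume(path: str | Path, voxel_size_um: Optional[float] = None) -> AtlasVolume:
    """Read a labeled volume from NIfTI or raw int32 + JSON sidecar.

    NIfTI files must hold integer data (floats with fractional parts are a
    format error).  Raw volumes are little-endian int32 with a sidecar
    ``<path>.json`` carrying ``{"shape", "voxel_size_um", "axis_order"}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if not np.issubdtype(data.dtype, np.integer):
            if not np.all(np.isfinite(data)) or not np.array_equal(data, np.round(data)):
                raise FormatError("volume data is not castable to integers without loss")
            data = data.astype(np.int64)
        if voxel_size_um is None:
            voxel_size_um = float(img.header.get_zooms()[0]) * 1000.0
        return AtlasVolume(labels=data.astype(np.int32), voxel_size_um=voxel_size_um)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar for raw volume: {sidecar}")
    meta = json.loads(sidecar.read_text())
    shape = tuple(int(s) for s in meta["shape"])
    data = np.fromfile(path, dtype="<i4")
    if data.size != int(np.prod(shape)):
        raise FormatError(f"raw volume size {data.size} does not match shape {shape}")
    if voxel_size_um is None:
        voxel_size_um = float(meta["voxel_size_um"])
    return AtlasVolume(labels=data.reshape(shape).astype(np.int32), voxel_size_um=voxel_size_um)


def write_label_volume(volume: AtlasVolume, path: str | Path) -> None:
    """Write a volume in the format implied by the file extension."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        import nibabel as nib

        zoom_mm = volume.voxel_size_um / 1000.0
        img = nib.Nifti1Image(volume.labels.astype(np.int32), np.diag([zoom_mm] * 3 + [1.0]))
        nib.save(img, str(path))
        return
    volume.labels.astype("<i4").tofile(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "shape": list(volume.shape),
                "voxel_size_um": volume.voxel_size_um,
                "axis_order": "xyz",
            }
        )
    )


def validate_volume_against_ontology(volume: AtlasVolume, ontology: Ontology) -> None:
    """Raise if any nonzero volume label is missing from the ontology."""
    missing = [int(i) for i in volume.region_ids() if int(i) not in ontology]
    if missing:
        raise StructureError(f"volume labels missing from ontology: {missing}")
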