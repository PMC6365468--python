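"""Volume and graph I/O with explicit voxel-spacing metadata.

Axis order is fixed as (z, y, x) — slice index first, matching the page
order of a TIFF stack.  Spacing is isotropic and carried in μm; NIfTI
headers record it in mm per that format's convention.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from angiotomo.graph import Branch, Node, VascularGraph

__all__ = [
    "Volume",
    "read_volume",
    "write_volume",
    "export_graph",
    "load_graph_json",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}


@dataclass
class Volume:
    """A 3D scalar grid with isotropic voxel spacing in μm."""

    data: np.ndarray
    spacing_um: float
    origin_um: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("every volume axis must have length >= 1")
        self.spacing_um = float(self.spacing_um)
        if not self.spacing_um > 0:
            raise ValueError("spacing_um must be positive")
        self.origin_um = np.asarray(self.origin_um, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_to_um(self, idx: np.ndarray) -> np.ndarray:
        """Voxel indices (z, y, x) → physical coordinates in μm."""
        return np.asarray(idx, dtype=float) * self.spacing_um + self.origin_um

    def um_to_voxel(self, pos_um: np.ndarray) -> np.ndarray:
        """Physical coordinates in μm → fractional voxel indices (z, y, x)."""
        return (np.asarray(pos_um, dtype=float) - self.origin_um) / self.spacing_um


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_volume(path: str | Path, spacing_override: float | None = None) -> Volume:
    """Read a volume from a multi-page TIFF, a directory of 2D TIFF slices
    (lexicographic order), or a NIfTI file.

    Spacing comes from file metadata when present, else from
    ``spacing_override``; with neither, this is an error.  Intensities are
    preserved without rescaling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        return _read_slice_dir(path, spacing_override)
    if _is_nifti(path):
        return _read_nifti(path, spacing_override)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        return _read_tiff(path, spacing_override)
    raise ValueError(f"unsupported volume format: {path.name}")


def _resolve_spacing(meta_um: float | None, override: float | None, what: str) -> float:
    if meta_um is not None:
        return float(meta_um)
    if override is not None:
        if not override > 0:
            raise ValueError("spacing_override must be positive")
        return float(override)
    raise ValueError(f"{what} carries no spacing metadata and no spacing_override was given")


def _tiff_spacing(tf: tifffile.TiffFile) -> float | None:
    meta = tf.shaped_metadata
    if meta:
        spacing = meta[0].get("spacing_um")
        if spacing is not None:
            return float(spacing)
    return None


def _read_tiff(path: Path, spacing_override: float | None) -> Volume:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        spacing = _tiff_spacing(tf)
    if data.ndim == 2:
        data = data[None]
    return Volume(data, _resolve_spacing(spacing, spacing_override, str(path)))


def _read_slice_dir(path: Path, spacing_override: float | None) -> Volume:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _TIFF_SUFFIXES)
    if not files:
        raise ValueError(f"no TIFF slices found in {path}")
    slices = []
    spacing = None
    for f in files:
        with tifffile.TiffFile(f) as tf:
            arr = tf.asarray()
            if spacing is None:
                spacing = _tiff_spacing(tf)
        if arr.ndim != 2:
            raise ValueError(f"slice {f.name} is not 2D")
        if slices and arr.shape != slices[0].shape:
            raise ValueError(
                f"slice {f.name} has shape {arr.shape}, expected {slices[0].shape}"
            )
        slices.append(arr)
    return Volume(np.stack(slices, axis=0), _resolve_spacing(spacing, spacing_override, str(path)))


def _read_nifti(path: Path, spacing_override: float | None) -> Volume:
    img = nib.load(str(path))
    # on-disk NIfTI axes are (x, y, z); flip to our (z, y, x) convention
    data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    spacing = None
    if all(z > 0 for z in zooms):
        if max(zooms) - min(zooms) > 1e-6 * max(zooms):
            raise ValueError(f"anisotropic NIfTI voxels {zooms} are not supported")
        spacing = float(zooms[0]) * 1000.0  # mm → μm
    return Volume(data, _resolve_spacing(spacing, spacing_override, str(path)))


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a volume to .tif/.tiff (multi-page) or .nii/.nii.gz, recording
    the voxel spacing in the file metadata.  Round-trips are lossless for
    integer and floating dtypes."""
    path = Path(path)
    if not path.parent.exists():
        raise ValueError(f"parent directory {path.parent} does not exist")
    if _is_nifti(path):
        mm = vol.spacing_um / 1000.0
        affine = np.diag([mm, mm, mm, 1.0])
        img = nib.Nifti1Image(np.transpose(vol.data, (2, 1, 0)), affine)
        img.header.set_zooms((mm, mm, mm))
        nib.save(img, str(path))
        return path
    if path.suffix.lower() in _TIFF_SUFFIXES:
        # photometric forced grayscale: a (3,N,N) or (4,N,N) stack must not
        # be reinterpreted as RGB(A) planes
        tifffile.imwrite(path, vol.data, photometric="minisblack",
                         metadata={"spacing_um": vol.spacing_um})
        return path
    raise ValueError(f"unsupported volume format: {path.name}")


# ---------------------------------------------------------------------------
# graph export

def export_graph(graph: VascularGraph, path: str | Path, format: str = "json") -> Path:
    """Export a vascular graph as JSON (full topology), SWC (tree components;
    cycle-closing branches listed in trailing comments), or CSV (one row per
    branch)."""
    path = Path(path)
    graph.validate()
    if format == "json":
        _export_json(graph, path)
    elif format == "swc":
        _export_swc(graph, path)
    elif format == "csv":
        _export_csv(graph, path)
    else:
        raise ValueError(f"unknown graph format {format!r}; expected json, swc or csv")
    return path


def _export_json(graph: VascularGraph, path: Path) -> None:
    doc = {
        "spacing_um": graph.spacing_um,
        "provenance": graph.provenance,
        "nodes": [
            {
                "id": n.id,
                "position_um": [float(v) for v in n.position_um],
                "kind": n.kind,
                "degree": int(n.degree),
            }
            for n in graph.nodes
        ],
        "branches": [
            {
                "id": b.id,
                "node_a": b.node_a,
                "node_b": b.node_b,
                "path": b.path.tolist(),
                "length_um": float(b.length_um),
                "diameter_um": float(b.diameter_um),
            }
            for b in graph.branches
        ],
    }
    path.write_text(json.dumps(doc, indent=1))


def load_graph_json(path: str | Path) -> VascularGraph:
    doc = json.loads(Path(path).read_text())
    nodes = [
        Node(d["id"], np.array(d["position_um"]), d["kind"], d["degree"])
        for d in doc["nodes"]
    ]
    branches = [
        Branch(
            d["id"], d["node_a"], d["node_b"],
            np.array(d["path"], dtype=np.int64).reshape(-1, 3),
            d["length_um"], d["diameter_um"],
        )
        for d in doc["branches"]
    ]
    return VascularGraph(nodes, branches, doc["spacing_um"], doc.get("provenance", {}))


def _export_csv(graph: VascularGraph, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "n_points", "length_um", "diameter_um", "node_a", "node_b"])
        for b in graph.branches:
            w.writerow([b.id, len(b.path), f"{b.length_um:.6g}", f"{b.diameter_um:.6g}",
                        b.node_a, b.node_b])


def _export_swc(graph: VascularGraph, path: Path) -> None:
    """SWC with one point per centerline sample (id type x y z radius parent).

    Coordinates in μm, (x, y, z) order per the SWC convention.  Each tree
    component is rooted at its lowest-id node; branches that would close a
    cycle are not emitted as points and are listed in trailing comments.
    """
    spacing = graph.spacing_um
    adjacency: dict[int, list[Branch]] = {n.id: [] for n in graph.nodes}
    for b in graph.branches:
        adjacency[b.node_a].append(b)
        if b.node_b != b.node_a:
            adjacency[b.node_b].append(b)

    lines: list[str] = ["# id type x y z radius parent"]
    skipped: list[int] = []
    visited_nodes: set[int] = set()
    visited_branches: set[int] = set()
    node_point: dict[int, int] = {}
    next_id = 1

    def emit(pos_um: np.ndarray, radius: float, parent: int) -> int:
        nonlocal next_id
        pid = next_id
        next_id += 1
        x, y, z = pos_um[2], pos_um[1], pos_um[0]
        lines.append(f"{pid} 2 {x:.3f} {y:.3f} {z:.3f} {radius:.3f} {parent}")
        return pid

    for root in sorted(adjacency):
        if root in visited_nodes:
            continue
        node = graph.node_by_id(root)
        node_point[root] = emit(node.position_um, 0.0, -1)
        visited_nodes.add(root)
        stack = [root]
        while stack:
            nid = stack.pop()
            for b in sorted(adjacency[nid], key=lambda b: b.id):
                if b.id in visited_branches:
                    continue
                visited_branches.add(b.id)
                other = b.node_b if b.node_a == nid else b.node_a
                if other in visited_nodes:
                    skipped.append(b.id)  # would close a cycle
                    continue
                # orient the path from this node outwards
                pts = b.path if b.node_a == nid else b.path[::-1]
                parent = node_point[nid]
                radius = b.diameter_um / 2.0
                for vox in pts[1:]:
                    parent = emit(np.asarray(vox, dtype=float) * spacing, radius, parent)
                node_point[other] = parent
                visited_nodes.add(other)
                stack.append(other)
    for bid in skipped:
        lines.append(f"# non-tree branch (cycle): id {bid}")
    path.write_text("\n".join(lines) + "\n")
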