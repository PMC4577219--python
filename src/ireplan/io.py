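"""Volume and scene I/O: NIfTI, MetaImage, and JSON/YAML scene documents.

Label volumes are written as small integers with a JSON sidecar recording
the label-code <-> tissue-name mapping.  MetaImage support is a minimal
uncompressed reader/writer (header + raw appended data), enough for
round-tripping volumes with spacing and origin.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .scene import (
    LABELS,
    Electrode,
    ElectrodeArray,
    Scene,
    TissueLabelMap,
    VoxelGrid,
)

__all__ = [
    "save_volume",
    "load_volume",
    "save_label_map",
    "load_label_map",
    "scene_to_dict",
    "scene_from_dict",
    "save_scene",
    "load_scene",
]


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.spacing
    aff[:3, 3] = np.asarray(grid.origin) + 0.5 * np.asarray(grid.spacing)
    return aff


def save_volume(array: np.ndarray, grid: VoxelGrid, path: str | Path) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or MetaImage (.mha)."""
    path = Path(path)
    if path.suffix == ".mha":
        _write_mha(array, grid, path)
        return
    img = nib.Nifti1Image(np.asarray(array), _affine(grid))
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    path = Path(path)
    if path.suffix == ".mha":
        return _read_mha(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) - 0.5 * z for o, z in zip(img.affine[:3, 3], zooms))
    grid = VoxelGrid(shape=data.shape[:3], spacing=zooms, origin=origin)
    return data, grid


_MHA_TYPES = {
    "MET_UCHAR": np.uint8,
    "MET_USHORT": np.uint16,
    "MET_SHORT": np.int16,
    "MET_INT": np.int32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_NP_TO_MHA = {np.dtype(v): k for k, v in _MHA_TYPES.items()}


def _write_mha(array: np.ndarray, grid: VoxelGrid, path: Path) -> None:
    array = np.asarray(array)
    if array.dtype not in _NP_TO_MHA:
        array = array.astype(np.float64)
    # MetaImage stores fastest-varying axis first
    header = "\n".join(
        [
            "ObjectType = Image",
            "NDims = 3",
            "BinaryData = True",
            "BinaryDataByteOrderMSB = False",
            "CompressedData = False",
            "TransformMatrix = 1 0 0 0 1 0 0 0 1",
            f"Offset = {grid.origin[0]} {grid.origin[1]} {grid.origin[2]}",
            f"ElementSpacing = {grid.spacing[0]} {grid.spacing[1]} {grid.spacing[2]}",
            f"DimSize = {array.shape[0]} {array.shape[1]} {array.shape[2]}",
            f"ElementType = {_NP_TO_MHA[array.dtype]}",
            "ElementDataFile = LOCAL",
            "",
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.asfortranarray(array).tobytes(order="F"))


def _read_mha(path: Path) -> tuple[np.ndarray, VoxelGrid]:
    raw = path.read_bytes()
    end = raw.index(b"ElementDataFile")
    nl = raw.index(b"\n", end)
    header = raw[: nl].decode("ascii")
    fields = {}
    for line in header.splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            fields[k.strip()] = v.strip()
    shape = tuple(int(x) for x in fields["DimSize"].split())
    spacing = tuple(float(x) for x in fields["ElementSpacing"].split())
    origin = tuple(float(x) for x in fields.get("Offset", "0 0 0").split())
    dtype = _MHA_TYPES[fields["ElementType"]]
    data = np.frombuffer(raw[nl + 1 :], dtype=dtype)
    array = data.reshape(shape, order="F")
    return array.copy(), VoxelGrid(shape=shape, spacing=spacing, origin=origin)


def save_label_map(label_map: TissueLabelMap, path: str | Path) -> None:
    """Write labels plus a JSON sidecar with the code->name mapping."""
    path = Path(path)
    save_volume(label_map.labels, label_map.grid, path)
    sidecar = {
        "labels": {str(code): name for name, code in sorted(LABELS.items(), key=lambda x: x[1])},
        "electrode_ids_file": None,
    }
    stem = path.name.split(".")[0]
    if label_map.electrode_ids.any():
        ids_path = path.with_name(stem + "_electrode_ids" + path.name[len(stem):])
        save_volume(label_map.electrode_ids, label_map.grid, ids_path)
        sidecar["electrode_ids_file"] = ids_path.name
    path.with_name(stem + "_labels.json").write_text(json.dumps(sidecar, indent=2))


def load_label_map(path: str | Path) -> TissueLabelMap:
    path = Path(path)
    labels, grid = load_volume(path)
    stem = path.name.split(".")[0]
    sidecar_path = path.with_name(stem + "_labels.json")
    electrode_ids = None
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        if sidecar.get("electrode_ids_file"):
            electrode_ids, _ = load_volume(path.with_name(sidecar["electrode_ids_file"]))
    return TissueLabelMap(grid, labels.astype(np.uint8), electrode_ids)


# ---------------------------------------------------------------------------
# scene documents
# ---------------------------------------------------------------------------


def scene_to_dict(scene: Scene) -> dict:
    return {
        "schema_version": 1,
        "grid": {
            "shape": list(scene.grid.shape),
            "spacing_mm": list(scene.grid.spacing),
            "origin_mm": list(scene.grid.origin),
        },
        "electrodes": [
            {
                "index": e.index,
                "tip_mm": list(e.tip),
                "axis": list(e.axis),
                "radius_mm": e.radius,
                "exposure_length_mm": e.exposure_length,
                "insulated_length_mm": e.insulated_length,
            }
            for e in scene.electrodes
        ],
    }


def scene_from_dict(d: dict, label_map: TissueLabelMap) -> Scene:
    g = d["grid"]
    grid = VoxelGrid(
        shape=tuple(g["shape"]), spacing=tuple(g["spacing_mm"]), origin=tuple(g["origin_mm"])
    )
    if grid.shape != label_map.grid.shape:
        raise ValueError("scene document grid does not match the label volume")
    electrodes = ElectrodeArray(
        [
            Electrode(
                tip=tuple(e["tip_mm"]),
                axis=tuple(e["axis"]),
                index=int(e["index"]),
                radius=float(e["radius_mm"]),
                exposure_length=float(e["exposure_length_mm"]),
                insulated_length=float(e["insulated_length_mm"]),
            )
            for e in d["electrodes"]
        ]
    )
    return Scene(grid=grid, label_map=label_map, electrodes=electrodes)


def save_scene(scene: Scene, out_dir: str | Path, volume_format: str = ".nii.gz") -> Path:
    """Write a scene directory: labels volume, sidecar, scene.json, protocol.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_label_map(scene.label_map, out / f"labels{volume_format}")
    (out / "scene.json").write_text(json.dumps(scene_to_dict(scene), indent=2))
    if scene.protocol is not None:
        scene.protocol.save(out / "protocol.csv")
    return out


def load_scene(in_dir: str | Path) -> Scene:
    in_dir = Path(in_dir)
    candidates = sorted(
        p for p in in_dir.iterdir()
        if p.name.startswith("labels") and "electrode" not in p.name and "json" not in p.name
    )
    if not candidates:
        raise FileNotFoundError(f"no labels volume in {in_dir}")
    label_map = load_label_map(candidates[0])
    scene = scene_from_dict(json.loads((in_dir / "scene.json").read_text()), label_map)
    protocol_path = in_dir / "protocol.csv"
    if protocol_path.exists():
        from .sequence import load_protocol

        scene.protocol = load_protocol(protocol_path)
    return scene
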