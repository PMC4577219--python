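"""Voxelized scene construction: grids, tissue labels, electrodes.

Conventions
-----------
* Coordinates are physical millimetres, right-handed, origin at the grid
  corner; voxel indices are 0-based and a voxel's sample point is its
  center, ``origin + (index + 0.5) * spacing``.
* A voxel belongs to a shape iff its center does (center-point test).
* Volumes are reported in cm^3 (1 cm^3 = 1000 mm^3).
* Electrode active tips are flat-capped cylinders; the physical conical
  tip is sub-voxel at the default spacing and ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LABELS",
    "LABEL_NAMES",
    "VoxelGrid",
    "TissueLabelMap",
    "Electrode",
    "ElectrodeArray",
    "Scene",
    "build_grid",
    "rasterize_ellipsoid",
    "rasterize_capsule",
    "place_electrode",
    "pairwise_geometry",
    "synthetic_case",
    "ellipsoid_volume",
    "safety_margin_volume",
    "cylinder_hot_zone_volume",
    "TABLE_TIP_DISTANCES_MM",
]

#: label codes; values are stable across releases (serialized to disk)
LABELS = {
    "background": 0,
    "liver": 1,
    "tumor": 2,
    "vessel": 3,
    "electrode_active": 4,
    "electrode_insulated": 5,
}
LABEL_NAMES = {v: k for k, v in LABELS.items()}

#: reference pairwise tip distances (mm) of the four-needle case, keyed by
#: unordered electrode index pair
TABLE_TIP_DISTANCES_MM = {
    (1, 2): 18.0,
    (1, 3): 14.0,
    (1, 4): 12.0,
    (2, 3): 15.0,
    (2, 4): 12.0,
    (3, 4): 17.0,
}


@dataclass(frozen=True)
class VoxelGrid:
    """Regular cell-centered voxel grid in physical mm coordinates."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(n < 2 for n in self.shape):
            raise ValueError(f"shape components must be >= 2, got {self.shape}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size of the grid box, mm."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def axis_centers(self, axis: int) -> np.ndarray:
        """Center coordinates of all voxels along one axis, mm."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def contains_point(self, p: Sequence[float]) -> bool:
        lo = np.asarray(self.origin)
        hi = lo + np.asarray(self.extent)
        p = np.asarray(p, float)
        return bool(np.all(p >= lo) and np.all(p <= hi))


@dataclass
class TissueLabelMap:
    """Per-voxel tissue labels plus per-voxel electrode ownership.

    ``labels`` holds one code from :data:`LABELS` per voxel.
    ``electrode_ids`` is 0 where no electrode occupies the voxel and the
    (1-based) electrode index on electrode voxels.
    """

    grid: VoxelGrid
    labels: np.ndarray
    electrode_ids: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels array shape must match grid shape")
        if self.electrode_ids is None:
            self.electrode_ids = np.zeros(self.grid.shape, dtype=np.uint16)
        else:
            self.electrode_ids = np.asarray(self.electrode_ids, dtype=np.uint16)
            if self.electrode_ids.shape != self.grid.shape:
                raise ValueError("electrode_ids shape must match grid shape")

    @classmethod
    def filled(cls, grid: VoxelGrid, label: str = "background") -> "TissueLabelMap":
        return cls(grid, np.full(grid.shape, LABELS[label], dtype=np.uint8))

    def mask(self, label: str) -> np.ndarray:
        return self.labels == LABELS[label]

    def volume_cm3(self, label: str) -> float:
        """Labeled volume: voxel count times voxel volume, in cm^3."""
        return float(np.count_nonzero(self.mask(label))) * self.grid.voxel_volume_mm3 / 1000.0

    def label_counts(self) -> dict[str, int]:
        out = {}
        for name, code in LABELS.items():
            out[name] = int(np.count_nonzero(self.labels == code))
        return out

    def copy(self) -> "TissueLabelMap":
        return TissueLabelMap(self.grid, self.labels.copy(), self.electrode_ids.copy())


@dataclass(frozen=True)
class Electrode:
    """Needle electrode: conductive exposed tip plus insulated shaft.

    ``axis`` is the unit insertion direction (entry point toward tip); the
    active segment runs from the tip backwards along ``axis`` for
    ``exposure_length``, followed by ``insulated_length`` of shaft.
    """

    tip: tuple[float, float, float]
    axis: tuple[float, float, float]
    index: int
    radius: float = 0.5
    exposure_length: float = 20.0
    insulated_length: float = 40.0

    def __post_init__(self) -> None:
        a = np.asarray(self.axis, float)
        if abs(np.linalg.norm(a) - 1.0) > 1e-9:
            raise ValueError(f"electrode axis must have unit norm, got |a|={np.linalg.norm(a)}")
        if self.exposure_length <= 0:
            raise ValueError("exposure_length must be positive")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.insulated_length < 0:
            raise ValueError("insulated_length must be >= 0")
        object.__setattr__(self, "tip", tuple(float(x) for x in self.tip))
        object.__setattr__(self, "axis", tuple(float(x) for x in self.axis))


@dataclass
class ElectrodeArray:
    """Ordered set of electrodes with unique 1-based contiguous indices."""

    electrodes: list[Electrode] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = sorted(e.index for e in self.electrodes)
        if idx and idx != list(range(1, len(idx) + 1)):
            raise ValueError(f"electrode indices must be 1..n without gaps, got {idx}")

    def __len__(self) -> int:
        return len(self.electrodes)

    def __iter__(self):
        return iter(self.electrodes)

    def get(self, index: int) -> Electrode:
        for e in self.electrodes:
            if e.index == index:
                return e
        raise KeyError(f"no electrode with index {index}")


@dataclass
class Scene:
    """Geometric world consumed by the solvers."""

    grid: VoxelGrid
    label_map: TissueLabelMap
    electrodes: ElectrodeArray
    protocol: object | None = None  # sequence.Protocol, optional


# ---------------------------------------------------------------------------
# grid / rasterization
# ---------------------------------------------------------------------------


def build_grid(
    extent: Sequence[float],
    spacing: Sequence[float] | float,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> VoxelGrid:
    """Build a voxel grid covering ``extent`` mm at ``spacing`` mm.

    The voxel count per axis is ``ceil(extent / spacing)``, so the grid box
    is at least as large as the requested extent.
    """
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    extent = tuple(float(e) for e in extent)
    spacing = tuple(float(s) for s in spacing)
    if any(e <= 0 for e in extent) or any(s <= 0 for s in spacing):
        raise ValueError(f"extent and spacing must be positive, got {extent}, {spacing}")
    shape = tuple(int(np.ceil(e / s - 1e-12)) for e, s in zip(extent, spacing))
    return VoxelGrid(shape=shape, spacing=spacing, origin=tuple(origin))


def _center_grids(grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = grid.axis_centers(0)[:, None, None]
    y = grid.axis_centers(1)[None, :, None]
    z = grid.axis_centers(2)[None, None, :]
    return x, y, z


def rasterize_ellipsoid(
    label_map: TissueLabelMap,
    center: Sequence[float],
    semi_axes: Sequence[float],
    label: str,
) -> TissueLabelMap:
    """Label all voxels whose centers lie inside the ellipsoid (in place)."""
    center = np.asarray(center, float)
    semi = np.asarray(semi_axes, float)
    if np.any(semi <= 0):
        raise ValueError(f"semi-axes must be positive, got {semi_axes}")
    x, y, z = _center_grids(label_map.grid)
    r2 = (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    )
    inside = r2 <= 1.0
    if not inside.any():
        warnings.warn("ellipsoid does not cover any voxel center; no voxels labeled")
        return label_map
    label_map.labels[inside] = LABELS[label]
    return label_map


def _segment_distance(grid: VoxelGrid, p0: np.ndarray, p1: np.ndarray, caps: str):
    """Per-voxel (radial distance, axial parameter) relative to segment p0-p1."""
    x, y, z = _center_grids(grid)
    d = p1 - p0
    L = np.linalg.norm(d)
    u = d / L
    rx, ry, rz = x - p0[0], y - p0[1], z - p0[2]
    t = rx * u[0] + ry * u[1] + rz * u[2]
    if caps == "round":
        tc = np.clip(t, 0.0, L)
    else:
        tc = t
    px = rx - tc * u[0]
    py = ry - tc * u[1]
    pz = rz - tc * u[2]
    radial = np.sqrt(px**2 + py**2 + pz**2)
    return radial, t, L


def _capsule_mask(
    grid: VoxelGrid,
    p0: Sequence[float],
    p1: Sequence[float],
    radius: float,
    caps: str = "flat",
    thin_guarantee: bool = True,
) -> np.ndarray:
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    if np.allclose(p0, p1):
        raise ValueError("degenerate segment: p0 == p1")
    if radius <= 0:
        raise ValueError("radius must be positive")
    radial, t, L = _segment_distance(grid, p0, p1, caps)
    if caps == "round":
        mask = radial <= radius
    else:
        mask = (radial <= radius) & (t >= 0.0) & (t <= L)
    if thin_guarantee:
        # voxels traversed by the axis are always included, so structures
        # thinner than the spacing never vanish
        spacing = np.asarray(grid.spacing)
        origin = np.asarray(grid.origin)
        n_steps = max(2, int(np.ceil(L / (spacing.min() / 2.0))) + 1)
        pts = p0[None, :] + np.linspace(0.0, 1.0, n_steps)[:, None] * (p1 - p0)[None, :]
        idx = np.floor((pts - origin) / spacing).astype(int)
        ok = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
        idx = idx[ok]
        if len(idx):
            mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return mask


def rasterize_capsule(
    label_map: TissueLabelMap,
    p0: Sequence[float],
    p1: Sequence[float],
    radius: float,
    label: str,
    caps: str = "flat",
) -> TissueLabelMap:
    """Label a finite cylinder along segment ``p0``-``p1`` (in place).

    ``caps="flat"`` gives a flat-ended cylinder (used for electrodes);
    ``caps="round"`` adds hemispherical end caps.  Voxels containing the
    axis itself are always labeled even when ``radius`` is below half the
    voxel spacing (thin-structure guarantee).
    """
    mask = _capsule_mask(label_map.grid, p0, p1, radius, caps)
    if not mask.any():
        warnings.warn("capsule does not cover any voxel center; no voxels labeled")
        return label_map
    label_map.labels[mask] = LABELS[label]
    return label_map


def place_electrode(label_map: TissueLabelMap, electrode: Electrode) -> TissueLabelMap:
    """Stamp an electrode into the label map (electrode overrides tissue).

    The active segment runs from the tip backwards along the axis for
    ``exposure_length`` and is labeled ``electrode_active``; the following
    ``insulated_length`` of shaft is labeled ``electrode_insulated``.  The
    shaft may leave the grid; the active segment may not.
    """
    grid = label_map.grid
    tip = np.asarray(electrode.tip, float)
    axis = np.asarray(electrode.axis, float)
    back = tip - electrode.exposure_length * axis
    if not (grid.contains_point(tip) and grid.contains_point(back)):
        raise ValueError(
            f"electrode {electrode.index}: active segment extends outside the grid"
        )
    active = _capsule_mask(grid, back, tip, electrode.radius, caps="flat")
    label_map.labels[active] = LABELS["electrode_active"]
    label_map.electrode_ids[active] = electrode.index
    if electrode.insulated_length > 0:
        shaft_end = back - electrode.insulated_length * axis
        # clip the shaft to the grid box so partial insertion is allowed
        shaft_end = np.clip(
            shaft_end,
            np.asarray(grid.origin),
            np.asarray(grid.origin) + np.asarray(grid.extent),
        )
        if not np.allclose(shaft_end, back):
            insul = _capsule_mask(grid, shaft_end, back, electrode.radius, caps="flat")
            insul &= ~active
            label_map.labels[insul] = LABELS["electrode_insulated"]
            label_map.electrode_ids[insul] = electrode.index
    return label_map


# ---------------------------------------------------------------------------
# electrode geometry
# ---------------------------------------------------------------------------


def pairwise_geometry(array: ElectrodeArray) -> pd.DataFrame:
    """Tip distance (mm) and axis angle (degrees) for every unordered pair.

    The angle is ``arccos(|a_i . a_j|)`` so antiparallel axes count as
    parallel (needles have no preferred direction).
    """
    if len(array) < 2:
        raise ValueError("need at least 2 electrodes")
    rows = []
    electrodes = sorted(array.electrodes, key=lambda e: e.index)
    for i, ei in enumerate(electrodes):
        for ej in electrodes[i + 1 :]:
            d = float(np.linalg.norm(np.subtract(ei.tip, ej.tip)))
            cosang = abs(float(np.dot(ei.axis, ej.axis)))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            rows.append(
                {"pair_a": ei.index, "pair_b": ej.index, "distance_mm": d, "angle_deg": ang}
            )
    return pd.DataFrame(rows)


def _embed_tips(distances: dict[tuple[int, int], float]) -> np.ndarray:
    """Embed n points in 3-D from their pairwise distance table (classical MDS)."""
    n = max(max(p) for p in distances)
    D2 = np.zeros((n, n))
    for (i, j), d in distances.items():
        D2[i - 1, j - 1] = D2[j - 1, i - 1] = d * d
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    w, V = np.linalg.eigh(B)
    w = np.clip(w, 0.0, None)
    X = (V * np.sqrt(w))[:, ::-1][:, :3]
    return X


# ---------------------------------------------------------------------------
# synthetic case
# ---------------------------------------------------------------------------


def synthetic_case(
    spacing: float = 1.0,
    seed: int = 0,
    extent: Sequence[float] = (80.0, 80.0, 80.0),
    tumor_diameters: Sequence[float] = (14.0, 9.0, 15.0),
    vessel_radius: float = 4.0,
    electrode_radius: float = 0.5,
    exposure_length: float = 20.0,
    jitter_mm: float = 0.2,
    with_protocol: bool = True,
) -> Scene:
    """Build the synthetic four-needle liver case.

    The scene contains a liver background, an ellipsoidal tumor with the
    given diameters, a cylindrical vessel tangent to the tumor, and four
    parallel needle electrodes whose pairwise tip distances reproduce the
    reference table (18, 14, 12, 15, 12, 17 mm) to within the jitter.
    Deterministic for a fixed ``seed`` and ``spacing``.
    """
    rng = np.random.default_rng(seed)
    grid = build_grid(extent, spacing)
    label_map = TissueLabelMap.filled(grid, "liver")

    center = np.asarray(grid.origin) + np.asarray(grid.extent) / 2.0

    # tumor at the domain center
    semi = np.asarray(tumor_diameters, float) / 2.0
    rasterize_ellipsoid(label_map, center, semi, "tumor")

    # vessel tangent to the tumor along +x, running the full y extent
    vx = center[0] + semi[0] + vessel_radius
    p0 = (vx, grid.origin[1], center[2])
    p1 = (vx, grid.origin[1] + grid.extent[1], center[2])
    rasterize_capsule(label_map, p0, p1, vessel_radius, "vessel", caps="flat")

    # four parallel needles along +z; tip xy offsets and depths from the
    # exact 3-D embedding of the reference distance table
    tips3 = _embed_tips(TABLE_TIP_DISTANCES_MM)
    tips3 = tips3 - tips3.mean(axis=0)
    if jitter_mm > 0:
        tips3 = tips3 + rng.uniform(-jitter_mm, jitter_mm, size=tips3.shape) / np.sqrt(3.0)
    electrodes = []
    for i, (dx, dy, dz) in enumerate(tips3, start=1):
        tip = (center[0] + dx, center[1] + dy, center[2] + semi[2] + dz)
        electrodes.append(
            Electrode(
                tip=tip,
                axis=(0.0, 0.0, 1.0),
                index=i,
                radius=electrode_radius,
                exposure_length=exposure_length,
            )
        )
    array = ElectrodeArray(electrodes)
    for e in array:
        place_electrode(label_map, e)

    protocol = None
    if with_protocol:
        from .sequence import table3_protocol

        protocol = table3_protocol()
    return Scene(grid=grid, label_map=label_map, electrodes=array, protocol=protocol)


# ---------------------------------------------------------------------------
# closed-form geometry
# ---------------------------------------------------------------------------


def ellipsoid_volume(semi_axes: Sequence[float]) -> float:
    """Ellipsoid volume 4/3 pi a b c, semi-axes in mm, result in cm^3."""
    a, b, c = (float(s) for s in semi_axes)
    if min(a, b, c) <= 0:
        raise ValueError(f"semi-axes must be positive, got {semi_axes}")
    return 4.0 / 3.0 * np.pi * a * b * c / 1000.0


def safety_margin_volume(tumor_diameters: Sequence[float], margin: float) -> float:
    """Volume of the tumor ellipsoid grown by a uniform margin, cm^3.

    Semi-axes become ``diameter/2 + margin`` (mm).
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    semi = [d / 2.0 + margin for d in tumor_diameters]
    return ellipsoid_volume(semi)


def cylinder_hot_zone_volume(n: int, radius: float, height: float) -> float:
    """Total volume of n cylinders of given radius/height (mm), cm^3."""
    if n < 0 or radius <= 0 or height <= 0:
        if n == 0:
            return 0.0
        raise ValueError("inputs must be positive")
    return n * np.pi * radius**2 * height / 1000.0
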