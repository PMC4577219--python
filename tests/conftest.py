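import numpy as np
import pytest

from ireplan.materials import (
    BloodProperties,
    MaterialTable,
    TissueMaterial,
    default_material_table,
)
from ireplan.scene import (
    LABELS,
    Electrode,
    ElectrodeArray,
    Scene,
    TissueLabelMap,
    VoxelGrid,
)


@pytest.fixture(scope="session")
def materials():
    return default_material_table()


def make_uniform_material_table(sigma: float = 0.2, **overrides) -> MaterialTable:
    """Material table where every tissue has the same constant conductivity
    (electroporation disabled via equal sigma0/sigma_f)."""
    base = dict(
        sigma0=sigma,
        sigma_f=sigma,
        E_rev=1e9,
        E_irr=1e9,
        alphaT=0.015,
        k=0.52,
        rho=1079.0,
        c=3540.0,
        perfusion=0.018,
        metabolic_q=10740.0,
    )
    base.update(overrides)
    tissues = {name: TissueMaterial(name=name, **base) for name in ("liver", "tumor", "vessel")}
    tissues["electrode"] = TissueMaterial(
        name="electrode", sigma0=1e6, sigma_f=1e6, E_rev=1e9, E_irr=1e9,
        alphaT=0.0, k=15.0, rho=6000.0, c=500.0, perfusion=0.0, metabolic_q=0.0,
    )
    return MaterialTable(tissues=tissues, blood=BloodProperties())


def make_plate_scene(nx=12, ny=6, nz=6, spacing=1.0) -> Scene:
    """Slab with full-face plate electrodes on the two x faces.

    Effective plate gap (between the Dirichlet voxel centers) is
    ``(nx - 1) * spacing`` mm.
    """
    grid = VoxelGrid(shape=(nx, ny, nz), spacing=(spacing,) * 3)
    lm = TissueLabelMap.filled(grid, "liver")
    lm.labels[0, :, :] = LABELS["electrode_active"]
    lm.labels[-1, :, :] = LABELS["electrode_active"]
    lm.electrode_ids[0, :, :] = 1
    lm.electrode_ids[-1, :, :] = 2
    # electrode objects are geometric stand-ins; the solver reads the labels
    arr = ElectrodeArray(
        [
            Electrode(tip=(0.5, ny / 2, nz / 2), axis=(1, 0, 0), index=1,
                      exposure_length=ny * spacing),
            Electrode(tip=(nx - 0.5, ny / 2, nz / 2), axis=(1, 0, 0), index=2,
                      exposure_length=ny * spacing),
        ]
    )
    return Scene(grid=grid, label_map=lm, electrodes=arr)


def make_needle_scene(
    extent=(40.0, 40.0, 20.0),
    spacing=1.0,
    separation=15.0,
    radius=0.5,
    n_electrodes=2,
) -> Scene:
    """Parallel needles spanning the full z extent (quasi-2D two-wire setup)."""
    from ireplan.scene import build_grid, place_electrode

    grid = build_grid(extent, spacing)
    lm = TissueLabelMap.filled(grid, "liver")
    cx, cy = extent[0] / 2, extent[1] / 2
    xs = np.linspace(cx - separation / 2, cx + separation / 2, 2)
    if n_electrodes > 2:
        xs = np.concatenate([xs, [cx + separation * 1.5]])
    electrodes = []
    for i, x in enumerate(xs[:n_electrodes], start=1):
        e = Electrode(
            tip=(float(x), cy, extent[2]),
            axis=(0.0, 0.0, 1.0),
            index=i,
            radius=radius,
            exposure_length=extent[2],
            insulated_length=0.0,
        )
        place_electrode(lm, e)
        electrodes.append(e)
    return Scene(grid=grid, label_map=lm, electrodes=ElectrodeArray(electrodes))
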