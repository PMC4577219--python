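"""Transient bioheat solve with duty-cycle Joule heating and damage accounting.

The temperature field follows the perfused-tissue heat equation

    rho c dT/dt = div(k grad T) - w_b rho_b c_b (T - T_b) + q''' + Q

advanced by backward (implicit) Euler on the same 7-point stencil as the
electric solver.  The Joule source of the currently delivered train is
scaled by the pulse duty cycle.  Thermal damage accumulates in the
first-order Arrhenius integral Omega; Omega = 1 corresponds to a 63%
damage probability.

Deliberately absent (matching the modeled physics): boiling/enthalpy cap at
100 degC (temperatures above it are reported with a warning), perfusion
shutdown in damaged tissue, and convective cooling inside the vessel lumen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .efield import FieldSolution, SolverError
from .materials import ArrheniusParams, MaterialTable
from .scene import LABELS, Scene
from .sequence import Protocol, ProtocolRun, duty_cycle

__all__ = [
    "ThermalParams",
    "ThermalState",
    "ThermalModel",
    "ThermalRun",
    "heat_source",
    "arrhenius_update",
    "damage_probability",
    "exceedance_volume",
    "run_thermal",
]

CELSIUS = 273.15


@dataclass(frozen=True)
class ThermalParams:
    """Settings of the transient thermal run."""

    dt: float = 1.0  # s
    T_init: float = 310.0  # K
    boundary_T: float = 310.0  # K (fixed on the outer faces)
    duty: float | None = None  # None: per-train width*rate
    couple_sigma_T: bool = False  # rescale Joule source by (1 + alphaT dT)
    boundary: str = "dirichlet"  # dirichlet | neumann
    inter_train_gap: float = 0.0  # s of source-off time between trains

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duty is not None and not (0 < self.duty < 1):
            raise ValueError("duty must be in (0, 1)")
        if self.boundary not in ("dirichlet", "neumann"):
            raise ValueError("boundary must be 'dirichlet' or 'neumann'")


@dataclass
class ThermalState:
    """Temperature and accumulated damage at one instant."""

    T: np.ndarray  # K
    omega: np.ndarray  # dimensionless Arrhenius integral
    t: float  # s elapsed

    def copy(self) -> "ThermalState":
        return ThermalState(self.T.copy(), self.omega.copy(), self.t)


def heat_source(
    sol: FieldSolution,
    duty: float,
    state: ThermalState | None = None,
    materials: MaterialTable | None = None,
    scene: Scene | None = None,
    T_init: float = 310.0,
) -> np.ndarray:
    """Duty-cycle-averaged volumetric heating Q = duty * sigma |E|^2, W/m^3.

    When ``state`` is given (temperature coupling on), the conductivity is
    first rescaled by the material thermal coefficient
    ``1 + alphaT (T - T_init)``.
    """
    if not 0 <= duty < 1:
        raise ValueError("duty must be in [0, 1)")
    q = sol.joule
    if state is not None:
        if materials is None or scene is None:
            raise ValueError("temperature coupling requires materials and scene")
        alpha = np.zeros(q.shape)
        for name in ("background", "liver", "tumor", "vessel"):
            m = materials.material_for(name)
            alpha[scene.label_map.labels == LABELS[name]] = m.alphaT
        q = q * np.maximum(1.0 + alpha * (state.T - T_init), 0.0)
    return duty * q


def arrhenius_update(
    omega: np.ndarray,
    T: np.ndarray,
    dt: float,
    ap: ArrheniusParams,
) -> np.ndarray:
    """Accumulate the damage integral: Omega += zeta exp(-Ea/(R T)) dt."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    with np.errstate(divide="ignore"):
        expo = np.log(ap.zeta) - ap.Ea / (ap.R * np.asarray(T, float))
    return omega + np.exp(expo) * dt


def damage_probability(omega: np.ndarray | float) -> np.ndarray | float:
    """Thermal damage probability 1 - exp(-Omega)."""
    om = np.asarray(omega, float)
    if np.any(om < 0):
        raise ValueError("omega must be >= 0")
    out = 1.0 - np.exp(-om)
    return float(out) if out.ndim == 0 else out


def exceedance_volume(
    values: np.ndarray,
    level: float,
    voxel_volume_mm3: float,
    mask: np.ndarray | None = None,
) -> float:
    """Volume (cm^3) where ``values`` exceeds ``level`` (within a mask)."""
    sel = values > level if mask is None else (values > level) & mask
    return float(np.count_nonzero(sel)) * voxel_volume_mm3 / 1000.0


class ThermalModel:
    """Implicit-Euler stepper for the perfused heat equation on a scene.

    The linear system ``(rho c / dt + w rho_b c_b - div k grad) T = rhs``
    has constant coefficients, so the matrix is assembled once; steps are
    conjugate-gradient solves warm-started from the previous temperature.
    """

    def __init__(self, scene: Scene, materials: MaterialTable, params: ThermalParams):
        self.scene = scene
        self.materials = materials
        self.params = params
        grid = scene.grid
        labels = scene.label_map.labels
        shape = grid.shape
        self.spacing_m = tuple(s * 1e-3 for s in grid.spacing)
        self.voxvol_m3 = float(np.prod(self.spacing_m))

        self.rho_c = np.empty(shape)
        self.k = np.empty(shape)
        self.perf_sink = np.empty(shape)  # w_b rho_b c_b, W/(m^3 K)
        self.q_met = np.empty(shape)
        b = materials.blood
        for name, code in LABELS.items():
            mask = labels == code
            if not mask.any():
                continue
            m = materials.material_for(name)
            self.rho_c[mask] = m.rho * m.c
            self.k[mask] = m.k
            self.perf_sink[mask] = m.perfusion * b.rho_b * b.c_b
            self.q_met[mask] = m.metabolic_q
        self.T_b = b.T_b
        self._assemble()
        self._warned_boiling = False

    def _assemble(self) -> None:
        shape = self.scene.grid.shape
        N = int(np.prod(shape))
        idx = np.arange(N).reshape(shape)
        dt = self.params.dt
        rows, cols, vals = [], [], []
        diag = self.voxvol_m3 * (self.rho_c.ravel() / dt + self.perf_sink.ravel())
        for ax in range(3):
            sl0 = [slice(None)] * 3
            sl1 = [slice(None)] * 3
            sl0[ax] = slice(0, -1)
            sl1[ax] = slice(1, None)
            k0 = self.k[tuple(sl0)]
            k1 = self.k[tuple(sl1)]
            kf = 2.0 * k0 * k1 / (k0 + k1)
            h = self.spacing_m[ax]
            g = (kf * self.voxvol_m3 / h**2).ravel()
            i0 = idx[tuple(sl0)].ravel()
            i1 = idx[tuple(sl1)].ravel()
            rows += [i0, i1]
            cols += [i1, i0]
            vals += [-g, -g]
            np.add.at(diag, i0, g)
            np.add.at(diag, i1, g)
            if self.params.boundary == "dirichlet":
                # ghost-cell Dirichlet on both outer faces of this axis
                for face_sl in (0, -1):
                    sl = [slice(None)] * 3
                    sl[ax] = face_sl
                    ib = idx[tuple(sl)].ravel()
                    kb = self.k[tuple(sl)].ravel()
                    gb = 2.0 * kb * self.voxvol_m3 / h**2
                    np.add.at(diag, ib, gb)
                    if not hasattr(self, "_bdry_rhs"):
                        self._bdry_rhs = np.zeros(N)
                    self._bdry_rhs[ib] += gb * self.params.boundary_T
        if self.params.boundary == "neumann":
            self._bdry_rhs = np.zeros(N)
        rows.append(np.arange(N))
        cols.append(np.arange(N))
        vals.append(diag)
        self.A = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(N, N)
        )
        self._diag = self.A.diagonal()
        self._M = spla.LinearOperator((N, N), matvec=lambda v: v / self._diag)

    def initial_state(self) -> ThermalState:
        shape = self.scene.grid.shape
        return ThermalState(
            T=np.full(shape, self.params.T_init), omega=np.zeros(shape), t=0.0
        )

    def step(self, state: ThermalState, source: np.ndarray, rtol: float = 1e-9) -> ThermalState:
        """Advance one implicit-Euler step with the given source (W/m^3)."""
        dt = self.params.dt
        rhs = (
            self.voxvol_m3
            * (self.rho_c.ravel() / dt * state.T.ravel()
               + self.perf_sink.ravel() * self.T_b
               + self.q_met.ravel()
               + source.ravel())
            + self._bdry_rhs
        )
        x, info = spla.cg(
            self.A, rhs, x0=state.T.ravel(), rtol=rtol, maxiter=5000, M=self._M
        )
        if info != 0:
            raise SolverError(f"thermal CG failed to converge (info={info})")
        if not np.all(np.isfinite(x)):
            raise SolverError("non-finite temperatures in thermal step")
        T = x.reshape(state.T.shape)
        if not self._warned_boiling and np.any(T > 100.0 + CELSIUS):
            self._warned_boiling = True
            warnings.warn(
                "temperatures above 100 degC: the model has no boiling term; "
                "values above boiling are reported as-is"
            )
        omega = arrhenius_update(state.omega, T, dt, self.materials.arrhenius)
        return ThermalState(T=T, omega=omega, t=state.t + dt)


@dataclass
class ThermalRun:
    """Trajectory summaries of a protocol-driven thermal simulation."""

    final: ThermalState
    T_peak: np.ndarray  # K, voxelwise maximum over the whole timeline
    times: np.ndarray  # s
    max_T: np.ndarray  # K
    vol_T50_cm3: np.ndarray
    vol_T70_cm3: np.ndarray
    vol_T100_cm3: np.ndarray
    vol_omega1_cm3: np.ndarray
    snapshots: list[ThermalState] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_s": self.times,
                "max_T_K": self.max_T,
                "vol_T_gt_50C_cm3": self.vol_T50_cm3,
                "vol_T_gt_70C_cm3": self.vol_T70_cm3,
                "vol_T_gt_100C_cm3": self.vol_T100_cm3,
                "vol_omega_ge_1_cm3": self.vol_omega1_cm3,
            }
        )


def run_thermal(
    scene: Scene,
    materials: MaterialTable,
    run: ProtocolRun,
    params: ThermalParams | None = None,
    keep_snapshots: bool = False,
    tissue_only: bool = True,
) -> ThermalRun:
    """Simulate the protocol timeline train by train.

    During train i the source is the duty-scaled Joule map of that train's
    field solution, held for ``n_pulses / rate`` seconds; an optional
    source-off gap separates trains.  Exceedance volumes are evaluated in
    tissue voxels (electrodes excluded) unless ``tissue_only`` is False.
    """
    params = params or ThermalParams()
    model = ThermalModel(scene, materials, params)
    state = model.initial_state()
    voxvol = scene.grid.voxel_volume_mm3
    labels = scene.label_map.labels
    if tissue_only:
        mask = (labels != LABELS["electrode_active"]) & (labels != LABELS["electrode_insulated"])
    else:
        mask = np.ones(labels.shape, bool)

    times = [0.0]
    max_T = [float(state.T.max())]
    v50, v70, v100, vom = [0.0], [0.0], [0.0], [0.0]
    snapshots: list[ThermalState] = []
    T_peak = state.T.copy()

    def record(st: ThermalState) -> None:
        np.maximum(T_peak, st.T, out=T_peak)
        times.append(st.t)
        max_T.append(float(st.T.max()))
        v50.append(exceedance_volume(st.T, 50.0 + CELSIUS, voxvol, mask))
        v70.append(exceedance_volume(st.T, 70.0 + CELSIUS, voxvol, mask))
        v100.append(exceedance_volume(st.T, 100.0 + CELSIUS, voxvol, mask))
        vom.append(float(np.count_nonzero((st.omega >= 1.0) & mask)) * voxvol / 1000.0)

    for res in run.results:
        t = res.train
        if res.solution is None:
            raise ValueError(
                f"train {t.index} has no stored field solution; "
                "run the protocol with keep_solutions=True"
            )
        duty = params.duty if params.duty is not None else duty_cycle(t.pulse_width, t.rate)
        if params.couple_sigma_T:
            src = None  # rebuilt each step from the current temperature
        else:
            src = heat_source(res.solution, duty)
        n_steps = max(1, int(round(t.duration / params.dt)))
        for _ in range(n_steps):
            if params.couple_sigma_T:
                src = heat_source(
                    res.solution, duty, state=state, materials=materials,
                    scene=scene, T_init=params.T_init,
                )
            state = model.step(state, src)
            record(state)
        if params.inter_train_gap > 0:
            zero = np.zeros(scene.grid.shape)
            for _ in range(max(1, int(round(params.inter_train_gap / params.dt)))):
                state = model.step(state, zero)
                record(state)
        if keep_snapshots:
            snapshots.append(state.copy())

    return ThermalRun(
        final=state,
        T_peak=T_peak,
        times=np.asarray(times),
        max_T=np.asarray(max_T),
        vol_T50_cm3=np.asarray(v50),
        vol_T70_cm3=np.asarray(v70),
        vol_T100_cm3=np.asarray(v100),
        vol_omega1_cm3=np.asarray(vom),
        snapshots=snapshots,
    )
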