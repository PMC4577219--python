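"""Pulse protocols, combined-maximum fields, coverage and power bookkeeping.

A protocol is an ordered list of pulse trains, each delivered to one
electrode pair at a fixed voltage.  The stationary field is solved once
per train (first pulse of the train); coverage of the target is evaluated
on the voxelwise maximum of |E| over all trains delivered so far.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from io import StringIO
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .efield import BoundaryAssignment, FieldSolution, solve_pair
from .materials import MaterialTable
from .scene import LABELS, Scene

__all__ = [
    "PulseTrain",
    "Protocol",
    "CoverageCurve",
    "ProtocolRun",
    "load_protocol",
    "table3_protocol",
    "total_pulses",
    "run_protocol",
    "coverage_curve",
    "lesion_volume",
    "duty_cycle",
    "peak_power",
    "average_power",
    "recommended_voltage",
    "DEFAULT_THRESHOLDS_VCM",
]

#: default IRE thresholds per tissue, V/cm
DEFAULT_THRESHOLDS_VCM = {"liver": 700.0, "tumor": 800.0}

#: default coverage threshold grid, V/cm
DEFAULT_THRESHOLD_GRID = np.arange(0.0, 1501.0, 25.0)

PROTOCOL_COLUMNS = ["train", "pair_a", "pair_b", "voltage_V", "n_pulses", "width_us", "rate_Hz"]


@dataclass(frozen=True)
class PulseTrain:
    """One contiguous train of identical pulses to a single electrode pair."""

    index: int
    pair: tuple[int, int]
    voltage: float  # V
    n_pulses: int
    pulse_width: float = 90e-6  # s
    rate: float = 1.0  # Hz
    measured_current: float | None = None  # A
    phase: str = "treatment"  # test | treatment | additional

    def __post_init__(self) -> None:
        if self.voltage <= 0:
            raise ValueError(f"train {self.index}: voltage must be positive")
        if self.n_pulses <= 0:
            raise ValueError(f"train {self.index}: n_pulses must be positive")
        if self.pulse_width * self.rate >= 1:
            raise ValueError(f"train {self.index}: duty cycle must be < 1")

    @property
    def duration(self) -> float:
        """Train duration in seconds at the nominal rate."""
        return self.n_pulses / self.rate


@dataclass
class Protocol:
    """Ordered delivery schedule."""

    trains: list[PulseTrain] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [t.index for t in self.trains]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("train indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.trains)

    def __iter__(self):
        return iter(self.trains)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "train": [t.index for t in self.trains],
                "pair_a": [t.pair[0] for t in self.trains],
                "pair_b": [t.pair[1] for t in self.trains],
                "voltage_V": [t.voltage for t in self.trains],
                "n_pulses": [t.n_pulses for t in self.trains],
                "width_us": [t.pulse_width * 1e6 for t in self.trains],
                "rate_Hz": [t.rate for t in self.trains],
                "measured_current_A": [t.measured_current for t in self.trains],
                "phase": [t.phase for t in self.trains],
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _protocol_from_frame(df: pd.DataFrame, source: str) -> Protocol:
    missing = [c for c in PROTOCOL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing protocol columns {missing}")
    trains = []
    for pos, row in df.iterrows():
        try:
            measured = row.get("measured_current_A")
            measured = None if measured is None or pd.isna(measured) else float(measured)
            trains.append(
                PulseTrain(
                    index=int(row["train"]),
                    pair=(int(row["pair_a"]), int(row["pair_b"])),
                    voltage=float(row["voltage_V"]),
                    n_pulses=int(row["n_pulses"]),
                    pulse_width=float(row["width_us"]) * 1e-6,
                    rate=float(row["rate_Hz"]),
                    measured_current=measured,
                    phase=str(row.get("phase", "treatment")),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{source}: bad protocol entry in row {pos}: {exc}") from exc
    if not trains:
        raise ValueError(f"{source}: protocol has no trains")
    return Protocol(trains)


def load_protocol(path: str | Path) -> Protocol:
    """Load a protocol from a CSV file (see PROTOCOL_COLUMNS for the header)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty protocol file") from exc
    return _protocol_from_frame(df, str(path))


def table3_protocol() -> Protocol:
    """The 18-train reference protocol shipped with the package.

    Six 20-pulse test trains, six 70-pulse treatment trains and six
    20-pulse additional trains, with the delivered voltages and the
    generator-measured currents.
    """
    text = resources.files("ireplan.data").joinpath("protocol_table3.csv").read_text()
    return _protocol_from_frame(pd.read_csv(StringIO(text)), "protocol_table3.csv")


def table3_frame() -> pd.DataFrame:
    """The reference protocol table verbatim, including the published
    computed-current column (used for comparison statistics)."""
    text = resources.files("ireplan.data").joinpath("protocol_table3.csv").read_text()
    return pd.read_csv(StringIO(text))


def total_pulses(p: Protocol) -> int:
    """Total number of delivered pulses across all trains."""
    return int(sum(t.n_pulses for t in p.trains))


# ---------------------------------------------------------------------------
# running a protocol
# ---------------------------------------------------------------------------


@dataclass
class TrainResult:
    """Per-train bookkeeping after the field solve."""

    train: PulseTrain
    current: float  # A, predicted
    current_flux: float  # A, flux estimator
    measured_current: float | None
    solution: FieldSolution | None = None


@dataclass
class ProtocolRun:
    """Outcome of running a full protocol on a scene."""

    scene: Scene
    protocol: Protocol
    results: list[TrainResult]
    E_max: np.ndarray  # V/cm, combined max over all trains
    E_max_after: list[np.ndarray] | None = None  # per-train combined field

    def currents_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "train": [r.train.index for r in self.results],
                "pair_a": [r.train.pair[0] for r in self.results],
                "pair_b": [r.train.pair[1] for r in self.results],
                "voltage_V": [r.train.voltage for r in self.results],
                "computed_current_A": [r.current for r in self.results],
                "measured_current_A": [r.measured_current for r in self.results],
            }
        )


def run_protocol(
    scene: Scene,
    materials: MaterialTable,
    protocol: Protocol,
    n_iter: int = 6,
    sigma_E_enabled: bool = True,
    keep_solutions: bool = True,
    keep_combined_trajectory: bool = False,
    cache_pairs: bool = True,
    rtol: float = 1e-8,
    progress: Callable[[str], None] | None = None,
) -> ProtocolRun:
    """Solve every train and combine fields by voxelwise maximum.

    The combined field accumulates each train's exposure field (the
    maximum field each voxel experienced while the conductivity evolved),
    so threshold coverage is consistent with the electroporated state.
    Trains repeating an already-solved (pair, voltage) combination reuse
    the cached solution (each train is solved independently of pulse
    history, so the stationary solution is identical).
    """
    cache: dict[tuple[tuple[int, int], float], FieldSolution] = {}
    E_max = np.zeros(scene.grid.shape)
    results: list[TrainResult] = []
    trajectory: list[np.ndarray] = [] if keep_combined_trajectory else None
    for t in protocol:
        key = (tuple(sorted(t.pair)), float(t.voltage))
        sol = cache.get(key) if cache_pairs else None
        if sol is None:
            if progress:
                progress(f"solving train {t.index}: pair {t.pair} at {t.voltage:.0f} V")
            try:
                sol = solve_pair(
                    scene,
                    materials,
                    BoundaryAssignment(pair=t.pair, voltage=t.voltage),
                    n_iter=n_iter,
                    sigma_E_enabled=sigma_E_enabled,
                    rtol=rtol,
                )
            except Exception as exc:
                raise RuntimeError(f"train {t.index} (pair {t.pair}) failed: {exc}") from exc
            if cache_pairs:
                cache[key] = sol
        np.maximum(E_max, sol.E_exposure, out=E_max)
        results.append(
            TrainResult(
                train=t,
                current=sol.current,
                current_flux=sol.current_flux,
                measured_current=t.measured_current,
                solution=sol if keep_solutions else None,
            )
        )
        if keep_combined_trajectory:
            trajectory.append(E_max.copy())
    return ProtocolRun(
        scene=scene,
        protocol=protocol,
        results=results,
        E_max=E_max,
        E_max_after=trajectory,
    )


# ---------------------------------------------------------------------------
# coverage / lesion volumes
# ---------------------------------------------------------------------------


@dataclass
class CoverageCurve:
    """Covered volume (cm^3) as a function of field threshold (V/cm)."""

    thresholds: np.ndarray
    volume_cm3: np.ndarray
    mask_volume_cm3: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold_Vcm": self.thresholds, "volume_cm3": self.volume_cm3})

    def fraction_at(self, threshold: float) -> float:
        i = int(np.searchsorted(self.thresholds, threshold))
        if i >= len(self.thresholds) or self.thresholds[i] != threshold:
            raise ValueError(f"threshold {threshold} not on the curve grid")
        return float(self.volume_cm3[i] / self.mask_volume_cm3)


def coverage_curve(
    E_max: np.ndarray,
    mask: np.ndarray,
    voxel_volume_mm3: float,
    thresholds: Sequence[float] | None = None,
) -> CoverageCurve:
    """Volume (cm^3) with combined field >= threshold, within a tissue mask."""
    if not mask.any():
        raise ValueError("coverage mask is empty")
    thr = np.asarray(DEFAULT_THRESHOLD_GRID if thresholds is None else thresholds, float)
    vals = np.sort(E_max[mask])
    n = len(vals)
    counts = n - np.searchsorted(vals, thr, side="left")
    vol = counts * voxel_volume_mm3 / 1000.0
    return CoverageCurve(
        thresholds=thr, volume_cm3=vol, mask_volume_cm3=n * voxel_volume_mm3 / 1000.0
    )


def coverage_fraction(E_max: np.ndarray, mask: np.ndarray, threshold: float) -> float:
    """Fraction of mask voxels with combined field >= threshold."""
    if not mask.any():
        raise ValueError("coverage mask is empty")
    return float(np.count_nonzero(E_max[mask] >= threshold)) / int(mask.sum())


def lesion_volume(
    E_max: np.ndarray,
    scene: Scene,
    thresholds: dict[str, float] | None = None,
) -> dict[str, float]:
    """Predicted ablation volume per tissue plus total, in cm^3.

    Each tissue's volume counts voxels of that label at or above its own
    IRE threshold.  Electrode and vessel voxels are not ablation volume.
    """
    thresholds = dict(DEFAULT_THRESHOLDS_VCM if thresholds is None else thresholds)
    if any(v <= 0 for v in thresholds.values()):
        raise ValueError("thresholds must be positive")
    voxvol = scene.grid.voxel_volume_mm3 / 1000.0
    out: dict[str, float] = {}
    total = 0.0
    for tissue, thr in thresholds.items():
        mask = scene.label_map.labels == LABELS[tissue]
        vol = float(np.count_nonzero(E_max[mask] >= thr)) * voxvol
        out[tissue] = vol
        total += vol
    out["total"] = total
    return out


# ---------------------------------------------------------------------------
# power / duty bookkeeping
# ---------------------------------------------------------------------------


def duty_cycle(width: float, rate: float) -> float:
    """Fraction of time the pulse is on: width (s) times rate (Hz)."""
    if width < 0 or rate < 0:
        raise ValueError("width and rate must be non-negative")
    d = width * rate
    if d >= 1:
        raise ValueError(f"duty cycle must be < 1, got {d}")
    return d


def peak_power(voltage: float, current: float) -> float:
    """Instantaneous power during the pulse, W."""
    if voltage < 0 or current < 0:
        raise ValueError("voltage and current must be non-negative")
    return voltage * current


def average_power(peak: float, duty: float) -> float:
    """Time-averaged power: peak times duty cycle, W."""
    if not 0 <= duty <= 1:
        raise ValueError("duty must be in [0, 1]")
    return peak * duty


def recommended_voltage(distance_cm: float, ratio_V_per_cm: float = 1500.0) -> float:
    """Manufacturer dosing rule: applied voltage = distance x ratio.

    Warns when the electrode distance exceeds the recommended 2.2 cm
    maximum spacing.
    """
    if distance_cm <= 0:
        raise ValueError("distance must be positive")
    if distance_cm > 2.2:
        warnings.warn(
            f"electrode distance {distance_cm} cm exceeds the recommended 2.2 cm maximum"
        )
    return distance_cm * ratio_V_per_cm
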