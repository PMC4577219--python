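"""Summary statistics and run reports.

Compares predicted currents against generator measurements, computes the
headline bookkeeping quantities (lesion volumes, coverage fractions,
power budget, damage volumes) and serializes them deterministically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMA_VERSION",
    "percent_error",
    "current_rmse",
    "current_comparison",
    "build_report",
    "save_report",
    "load_report",
]

SCHEMA_VERSION = 1


def percent_error(measured: float, computed: float) -> float:
    """Signed percent error 100 (computed - measured) / measured.

    Note the asymmetry: swapping the arguments changes the denominator,
    so this is not symmetric under exchange.
    """
    if measured <= 0:
        raise ValueError("measured current must be positive")
    return 100.0 * (computed - measured) / measured


def current_rmse(measured, computed) -> float:
    """Root-mean-square difference between paired current columns, A."""
    m = np.asarray(measured, float)
    c = np.asarray(computed, float)
    ok = np.isfinite(m) & np.isfinite(c)
    if not ok.any():
        raise ValueError("no rows with both measured and computed currents")
    d = c[ok] - m[ok]
    return float(np.sqrt(np.mean(d * d)))


def current_comparison(df: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-train comparison table plus overall RMSE.

    ``df`` needs columns ``train``, ``measured_current_A`` and
    ``computed_current_A`` (extra columns are carried through).  Percent
    errors are rounded to integers for display, matching the published
    table precision; the unrounded value is kept in ``error_pct_exact``.
    """
    need = {"train", "measured_current_A", "computed_current_A"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = df.copy()
    out["error_pct_exact"] = [
        percent_error(m, c)
        for m, c in zip(out["measured_current_A"], out["computed_current_A"])
    ]
    out["error_pct"] = np.round(out["error_pct_exact"]).astype(int)
    rmse = current_rmse(out["measured_current_A"], out["computed_current_A"])
    return out, rmse


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def build_report(
    protocol=None,
    lesion=None,
    tumor_coverage: dict[str, float] | None = None,
    exceedance: dict[str, float] | None = None,
    currents: pd.DataFrame | None = None,
    safety_margin_cm3: float | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Assemble the run report as a deterministic JSON-serializable dict.

    Every section is optional; a protocol-only report (pulse/duty/power
    bookkeeping) is valid.  Includes a provenance block with a hash of the
    configuration, the seed and package versions; no timestamps, so a
    rerun with identical inputs is byte-identical.
    """
    from . import __version__
    from .sequence import average_power, duty_cycle, peak_power, total_pulses

    report: dict = {"schema_version": SCHEMA_VERSION}

    if protocol is not None:
        widths = {t.pulse_width for t in protocol}
        rates = {t.rate for t in protocol}
        width = max(widths)
        rate = max(rates)
        duty = duty_cycle(width, rate)
        vmax = max(t.voltage for t in protocol)
        imax = max((t.measured_current or 0.0) for t in protocol)
        peak = peak_power(vmax, imax) if imax > 0 else None
        report["protocol"] = {
            "n_trains": len(protocol),
            "total_pulses": total_pulses(protocol),
            "pulse_width_us": width * 1e6,
            "rate_Hz": rate,
            "duty_cycle": duty,
            "duty_cycle_pct": 100.0 * duty,
            "max_voltage_V": vmax,
            "max_measured_current_A": imax if imax > 0 else None,
            "peak_power_W": peak,
            "average_power_W": average_power(peak, duty) if peak else None,
        }

    if lesion is not None:
        report["lesion_volume_cm3"] = dict(lesion)
    if tumor_coverage is not None:
        for v in tumor_coverage.values():
            if not 0 <= v <= 1:
                raise ValueError("coverage fractions must be in [0, 1]")
        report["tumor_coverage_fraction"] = dict(tumor_coverage)
    if exceedance is not None:
        report["exceedance_volume_cm3"] = dict(exceedance)
    if safety_margin_cm3 is not None:
        report["safety_margin_ellipsoid_cm3"] = safety_margin_cm3

    if currents is not None:
        table, rmse = current_comparison(currents)
        report["current_comparison"] = {
            "rmse_A": rmse,
            "trains": [
                {
                    "train": int(r["train"]),
                    "measured_A": round(float(r["measured_current_A"]), 1),
                    "computed_A": round(float(r["computed_current_A"]), 1),
                    "error_pct": int(r["error_pct"]),
                }
                for _, r in table.iterrows()
                if np.isfinite(r["measured_current_A"])
            ],
        }

    cfg_json = json.dumps(config or {}, sort_keys=True)
    report["provenance"] = {
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "seed": seed,
        "ireplan_version": __version__,
    }
    return _round_floats(report)


def report_text(report: dict) -> str:
    """Human-readable rendering of a report dict."""
    lines = [f"ireplan run report (schema v{report['schema_version']})", ""]
    p = report.get("protocol")
    if p:
        lines += [
            f"protocol: {p['n_trains']} trains, {p['total_pulses']} pulses",
            f"  duty cycle {p['duty_cycle_pct']:.4f} %",
        ]
        if p.get("peak_power_W"):
            lines += [
                f"  peak power {p['peak_power_W'] / 1e3:.1f} kW, "
                f"average {p['average_power_W']:.2f} W",
            ]
    if "lesion_volume_cm3" in report:
        vols = ", ".join(f"{k} {v:.2f}" for k, v in report["lesion_volume_cm3"].items())
        lines.append(f"lesion volume [cm^3]: {vols}")
    if "tumor_coverage_fraction" in report:
        cov = ", ".join(
            f"{k}: {100 * v:.1f} %" for k, v in report["tumor_coverage_fraction"].items()
        )
        lines.append(f"tumor coverage: {cov}")
    if "exceedance_volume_cm3" in report:
        exc = ", ".join(f"{k} {v:.2f}" for k, v in report["exceedance_volume_cm3"].items())
        lines.append(f"exceedance volumes [cm^3]: {exc}")
    if "current_comparison" in report:
        lines.append(f"current RMSE: {report['current_comparison']['rmse_A']:.2f} A")
    return "\n".join(lines) + "\n"


def validate_report(report: dict) -> None:
    if report.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported report schema: {report.get('schema_version')!r}"
        )
    if "provenance" not in report:
        raise ValueError("report missing provenance block")


def save_report(report: dict, path: str | Path) -> None:
    validate_report(report)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def load_report(path: str | Path) -> dict:
    report = json.loads(Path(path).read_text())
    validate_report(report)
    return report
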