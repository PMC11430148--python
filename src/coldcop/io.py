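"""Readers and writers for the plain-text interchange formats.

All tables are UTF-8, tab-delimited with one header row; acquisition
schemes and run provenance are JSON with a versioned ``format_version``
field.  Readers validate and reject malformed input (naming columns and
line numbers) rather than coercing it — no silent NaN propagation.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .dosy import Condition, DecaySeries, DiffusionPeak, GradientScheme, PeakList
from .screens import AssignmentTable, ScreenResult

__all__ = [
    "InputFormatError",
    "read_peaklist",
    "write_peaklist",
    "read_decay_table",
    "write_decay_table",
    "read_scheme",
    "write_scheme",
    "read_assignments",
    "write_assignments",
    "write_cluster_report",
    "write_screen_result",
    "read_screen_result",
]

FORMAT_VERSION = 1

PEAKLIST_COLUMNS = ["peak_id", "shift_ppm", "D_m2s", "sigma_D_m2s", "I0", "flags"]

#: Accepted gradient units and their factor into T/m.
GRADIENT_UNITS = {"T/m": 1.0, "G/cm": 0.01}


class InputFormatError(ValueError):
    """A malformed input file (maps to exit code 2 at the CLI)."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing required column(s) {missing}")


def _numeric_column(df: pd.DataFrame, col: str, path) -> pd.Series:
    values = pd.to_numeric(df[col], errors="coerce")
    bad = values.isna() & df[col].notna() | df[col].isna()
    if bad.any():
        # +2: header row and 1-based numbering
        lines = [int(i) + 2 for i in df.index[bad]]
        raise InputFormatError(
            f"{path}: non-numeric value in column {col!r} at line(s) {lines}"
        )
    return values


def read_peaklist(path: str | Path, condition: Condition | str) -> PeakList:
    """Read a fitted peak list TSV (columns: peak_id, shift_ppm, D_m2s,
    sigma_D_m2s, I0, flags)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"peak_id": str, "flags": str})
    _require_columns(df, PEAKLIST_COLUMNS[:5], path)
    for col in ("shift_ppm", "D_m2s", "sigma_D_m2s", "I0"):
        _numeric_column(df, col, path)
    peaks = []
    for _, row in df.iterrows():
        flags = row.get("flags")
        flags = () if pd.isna(flags) or flags == "" else tuple(str(flags).split(";"))
        peaks.append(
            DiffusionPeak(
                peak_id=str(row["peak_id"]),
                shift_ppm=float(row["shift_ppm"]),
                d=float(row["D_m2s"]),
                sigma_d=float(row["sigma_D_m2s"]),
                i0=float(row["I0"]),
                flags=flags,
            )
        )
    try:
        return PeakList(condition=Condition(condition), peaks=tuple(peaks))
    except ValueError as exc:
        raise InputFormatError(f"{path}: {exc}") from exc


def write_peaklist(peaklist: PeakList, path: str | Path) -> None:
    """Write a peak list TSV (D in m^2/s, scientific notation, 8 sig. digits)."""
    rows = [
        {
            "peak_id": p.peak_id,
            "shift_ppm": f"{p.shift_ppm:.4f}",
            "D_m2s": f"{p.d:.8e}",
            "sigma_D_m2s": f"{p.sigma_d:.8e}",
            "I0": f"{p.i0:.8e}",
            "flags": ";".join(p.flags),
        }
        for p in peaklist.peaks
    ]
    pd.DataFrame(rows, columns=PEAKLIST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_scheme(path: str | Path) -> GradientScheme:
    """Read an acquisition-scheme JSON (gamma, delta_s, big_delta_s,
    gradients, gradient_unit); gradients are converted into T/m."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    for key in ("delta_s", "big_delta_s", "gradients"):
        if key not in payload:
            raise InputFormatError(f"{path}: missing scheme field {key!r}")
    unit = payload.get("gradient_unit", "T/m")
    if unit not in GRADIENT_UNITS:
        raise InputFormatError(
            f"{path}: unknown gradient_unit {unit!r}; expected one of "
            f"{sorted(GRADIENT_UNITS)}"
        )
    factor = GRADIENT_UNITS[unit]
    try:
        return GradientScheme(
            gradients=tuple(factor * float(g) for g in payload["gradients"]),
            delta=float(payload["delta_s"]),
            big_delta=float(payload["big_delta_s"]),
            gamma=float(payload.get("gamma", 2.675e8)),
            timing_correction=float(payload.get("timing_correction_s", 0.0)),
        )
    except ValueError as exc:
        raise InputFormatError(f"{path}: invalid scheme: {exc}") from exc


def write_scheme(scheme: GradientScheme, path: str | Path) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "gamma": scheme.gamma,
        "delta_s": scheme.delta,
        "big_delta_s": scheme.big_delta,
        "gradients": list(scheme.gradients),
        "gradient_unit": "T/m",
        "timing_correction_s": scheme.timing_correction,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def read_decay_table(
    path: str | Path, scheme_path: str | Path
) -> tuple[list[DecaySeries], GradientScheme]:
    """Read a decay CSV (peak_id, shift_ppm, I_1..I_n) and its scheme JSON.

    The intensity column count must equal the scheme's gradient count.
    """
    scheme = read_scheme(scheme_path)
    path = Path(path)
    df = pd.read_csv(path, dtype={"peak_id": str})
    _require_columns(df, ["peak_id", "shift_ppm"], path)
    icols = [c for c in df.columns if c.startswith("I_")]
    if len(icols) != scheme.n_gradients:
        raise InputFormatError(
            f"{path}: {len(icols)} intensity columns but the scheme has "
            f"{scheme.n_gradients} gradients"
        )
    icols = sorted(icols, key=lambda c: int(c.split("_")[1]))
    _numeric_column(df, "shift_ppm", path)
    for col in icols:
        _numeric_column(df, col, path)
    series = []
    for _, row in df.iterrows():
        try:
            series.append(
                DecaySeries(
                    peak_id=str(row["peak_id"]),
                    shift_ppm=float(row["shift_ppm"]),
                    intensities=tuple(float(row[c]) for c in icols),
                )
            )
        except ValueError as exc:
            raise InputFormatError(f"{path}: {exc}") from exc
    return series, scheme


def write_decay_table(series: list[DecaySeries], path: str | Path) -> None:
    """Write decay series as CSV with columns peak_id, shift_ppm, I_1..I_n."""
    if not series:
        raise ValueError("cannot write an empty decay table")
    n = len(series[0].intensities)
    rows = []
    for s in series:
        if len(s.intensities) != n:
            raise ValueError("all decay series must have the same length")
        row = {"peak_id": s.peak_id, "shift_ppm": f"{s.shift_ppm:.4f}"}
        row.update({f"I_{k + 1}": f"{v:.8e}" for k, v in enumerate(s.intensities)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_assignments(path: str | Path) -> AssignmentTable:
    """Read an assignment TSV (compound, shift_ppm; one row per resonance)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"compound": str})
    _require_columns(df, ["compound", "shift_ppm"], path)
    _numeric_column(df, "shift_ppm", path)
    mapping: dict[str, list[float]] = {}
    for _, row in df.iterrows():
        mapping.setdefault(str(row["compound"]), []).append(float(row["shift_ppm"]))
    return AssignmentTable.from_dict(mapping)


def write_assignments(table: AssignmentTable, path: str | Path) -> None:
    rows = [
        {"compound": name, "shift_ppm": f"{s:.4f}"}
        for name, shifts in table.entries
        for s in shifts
    ]
    pd.DataFrame(rows, columns=["compound", "shift_ppm"]).to_csv(
        path, sep="\t", index=False
    )


def write_cluster_report(result: ScreenResult, path: str | Path) -> None:
    """Write the cluster-level TSV report of a screen run."""
    rows = result.hit_table()
    df = pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "n_members",
            "mean_ppm_list",
            "r",
            "se_r",
            "z",
            "q",
            "label",
            "member_peak_ids",
        ],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_screen_result(result: ScreenResult, path: str | Path) -> None:
    Path(path).write_text(result.to_json(), encoding="utf-8")


def read_screen_result(path: str | Path) -> ScreenResult:
    return ScreenResult.from_json(Path(path).read_text(encoding="utf-8"))
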