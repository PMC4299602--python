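"""Delimited-text readers/writers, flat-file configuration and run reports.

Everything is tab-separated UTF-8 text with a header row: cell-cycle
record tables (one row per tracked cell), long-format traces, flow event
tables and competition series.  Times are minutes from movie start
(0-based); volumes are in the arbitrary units declared by the producing
config.  Every pipeline run can emit a JSON provenance record (config +
seed + package version) next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .simkit import RECORD_COLUMNS, TRACE_COLUMNS, SimConfig
from .size_control import expected_false_positives

__all__ = [
    "SchemaError",
    "read_records",
    "write_records",
    "read_traces",
    "write_traces",
    "read_events",
    "write_events",
    "read_competition",
    "write_competition",
    "read_config",
    "write_config",
    "sim_config_from_file",
    "provenance_record",
    "write_report",
]

PathLike = Union[str, Path]

EVENT_COLUMNS = ["plate", "well", "area", "width", "fsc", "ssc"]
COMPETITION_COLUMNS = ["day", "frequency", "dilution_factor"]


class SchemaError(ValueError):
    pass


def _check_columns(df: pd.DataFrame, required: list[str], path: PathLike) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


# ---------------------------------------------------------------------------
# Cell-cycle records


def write_records(records: pd.DataFrame, path: PathLike) -> None:
    records.to_csv(path, sep="\t", index=False, columns=RECORD_COLUMNS)


def read_records(path: PathLike) -> pd.DataFrame:
    """Read a cell-cycle record table, validating schema and volumes.

    Malformed rows (non-positive volumes, reversed landmark times) are
    reported with their file line numbers.
    """
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, RECORD_COLUMNS, path)
    df["censored"] = df["censored"].astype(bool)
    bad_lines = []
    for col in ("birth_volume", "budding_volume", "division_volume"):
        vals = df[col].to_numpy(float)
        bad = np.nonzero(np.isfinite(vals) & (vals <= 0))[0]
        bad_lines.extend(int(i) + 2 for i in bad)  # +2: header line and 1-based
    uncens = ~df["censored"]
    order = df["birth_time"] < df["budding_time"]
    order &= df["budding_time"] < df["division_time"]
    bad_lines.extend(int(i) + 2 for i in np.nonzero((uncens & ~order).to_numpy())[0])
    if bad_lines:
        raise SchemaError(f"{path}: malformed row(s) at line(s) {sorted(set(bad_lines))}")
    return df


# ---------------------------------------------------------------------------
# Traces / events / competition series


def write_traces(traces: pd.DataFrame, path: PathLike) -> None:
    traces.to_csv(path, sep="\t", index=False, columns=TRACE_COLUMNS)


def read_traces(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, TRACE_COLUMNS, path)
    return df


def write_events(events: pd.DataFrame, path: PathLike) -> None:
    cols = [c for c in events.columns if c in EVENT_COLUMNS + ["label"]]
    events.to_csv(path, sep="\t", index=False, columns=cols)


def read_events(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, ["area", "width"], path)
    if not np.isfinite(df[["area", "width"]].to_numpy(float)).all():
        raise SchemaError(f"{path}: non-finite fluorescence channel values")
    return df


def write_competition(series: pd.DataFrame, path: PathLike) -> None:
    series.to_csv(path, sep="\t", index=False, columns=COMPETITION_COLUMNS)


def read_competition(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, COMPETITION_COLUMNS, path)
    return df


# ---------------------------------------------------------------------------
# Flat key-value configuration


def read_config(path: PathLike) -> dict[str, str]:
    """Parse a flat ``key = value`` text file (``#`` comments allowed)."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SchemaError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key in out:
            raise SchemaError(f"{path}:{lineno}: duplicate key {key!r}")
        out[key] = value
    return out


def write_config(config: SimConfig, path: PathLike) -> None:
    lines = [f"{f.name} = {getattr(config, f.name)}" for f in dataclasses.fields(config)]
    Path(path).write_text("\n".join(lines) + "\n")


def sim_config_from_file(path: PathLike, **overrides) -> SimConfig:
    """Build a :class:`SimConfig` from a flat config file.

    Unknown keys are rejected rather than ignored, so typos surface
    immediately.
    """
    raw = read_config(path)
    fields = {f.name: f for f in dataclasses.fields(SimConfig)}
    unknown = sorted(set(raw) - set(fields))
    if unknown:
        raise SchemaError(f"{path}: unknown configuration key(s) {unknown}")
    kwargs: dict = {}
    for key, text in raw.items():
        if text == "None":
            kwargs[key] = None
        elif key in ("control_mode", "strain_id"):
            kwargs[key] = text
        elif key in ("seed", "n_founders", "max_cells"):
            kwargs[key] = int(text)
        else:
            kwargs[key] = float(text)
    kwargs.update(overrides)
    return SimConfig(**kwargs)


# ---------------------------------------------------------------------------
# Provenance and reports


def provenance_record(config, seed: int, extra: dict | None = None) -> dict:
    from . import __version__

    cfg = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config)
    rec = {"package": "sizescreen", "version": __version__, "seed": seed, "config": cfg}
    if extra:
        rec.update(extra)
    return rec


def write_report(
    classifications: pd.DataFrame,
    out_dir: PathLike,
    alpha: float = 0.001,
    provenance: dict | None = None,
) -> Path:
    """Write the screen report: a tidy classification table, a JSON
    machine-readable summary and a short human-readable text summary.

    The summary includes the expected number of false non-normal calls,
    ``alpha * n_strains * n_responses`` — the screen's false-positive
    control (no per-strain multiple-testing correction is applied).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table_path = out / "classification.tsv"
    classifications.to_csv(table_path, sep="\t", index=False)

    n = len(classifications)
    counts = (
        classifications["regulator_label"].value_counts().to_dict()
        if "regulator_label" in classifications and n
        else {}
    )
    summary = {
        "n_strains": n,
        "alpha": alpha,
        "expected_false_positives": expected_false_positives(alpha, n),
        "regulator_counts": counts,
    }
    if provenance:
        summary["provenance"] = provenance
    (out / "report.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")

    lines = [
        f"strains classified: {n}",
        f"significance level per response: {alpha}",
        f"expected false non-normal calls: {summary['expected_false_positives']:.3g}",
    ]
    for label, cnt in sorted(counts.items()):
        lines.append(f"  {label}: {cnt}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return table_path
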