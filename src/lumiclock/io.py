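"""CSV/TSV input-output contracts for the pipeline.

Plate-format luminescence CSV: one row per (time, well) with columns
time_h, well_id, condition, counts. Flux CSV: one row per measurement cycle
with columns well_id, cycle_index, phase, ocr, ecar and an optional group
column. All tabular outputs are TSV with a header comment carrying the
package version.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

import lumiclock
from lumiclock.normalization import NormalizedTrace
from lumiclock.respirometry import RespirometryTrace
from lumiclock.rhythmometry import JtkResult
from lumiclock.signal_model import LuminescenceTrace

__all__ = [
    "read_luminescence_csv",
    "write_luminescence_csv",
    "write_normalized_csv",
    "read_respirometry_csv",
    "write_respirometry_csv",
    "jtk_results_table",
    "write_tsv",
]

LUMI_COLUMNS = ("time_h", "well_id", "condition", "counts")
FLUX_COLUMNS = ("well_id", "cycle_index", "phase", "ocr", "ecar")


def read_luminescence_csv(path: str | Path) -> list[LuminescenceTrace]:
    """Read a plate-format luminescence CSV into per-well traces.

    Every well must sit on the same uniform time grid; a well with missing or
    extra timepoints is rejected naming the well.
    """
    df = pd.read_csv(path)
    missing = set(LUMI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    traces = []
    ref_times = None
    for well_id, sub in df.groupby("well_id", sort=True):
        sub = sub.sort_values("time_h")
        times = sub["time_h"].to_numpy(dtype=float)
        if ref_times is None:
            ref_times = times
        elif times.shape != ref_times.shape or not np.allclose(times, ref_times):
            raise ValueError(
                f"{path}: well {well_id!r} is not on the plate's common time grid "
                f"({times.size} rows vs {ref_times.size})"
            )
        conditions = sub["condition"].unique()
        if len(conditions) != 1:
            raise ValueError(f"{path}: well {well_id!r} has multiple condition labels")
        try:
            traces.append(
                LuminescenceTrace(
                    times_h=times,
                    values=sub["counts"].to_numpy(dtype=float),
                    well_id=str(well_id),
                    condition=str(conditions[0]),
                )
            )
        except ValueError as err:
            raise ValueError(f"{path}: well {well_id!r}: {err}") from err
    if not traces:
        raise ValueError(f"{path}: no wells found")
    return traces


def write_luminescence_csv(
    traces: Sequence[LuminescenceTrace],
    path: str | Path,
    truth_sidecar: str | Path | None = None,
) -> None:
    """Write traces in plate format; optionally a JSON ground-truth sidecar."""
    frames = [
        pd.DataFrame(
            {
                "time_h": t.times_h,
                "well_id": t.well_id,
                "condition": t.condition,
                "counts": t.values,
            }
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    if truth_sidecar is not None:
        truth = {
            t.well_id: {"clock": asdict(t.truth[0]), "magnitude": asdict(t.truth[1])}
            for t in traces
            if t.truth is not None
        }
        Path(truth_sidecar).write_text(json.dumps(truth, indent=2, sort_keys=True))


def write_normalized_csv(traces: Sequence[NormalizedTrace], path: str | Path) -> None:
    """Write normalized traces in plate layout with a mode column."""
    frames = [
        pd.DataFrame(
            {
                "time_h": t.times_h,
                "well_id": t.source_well,
                "condition": t.condition,
                "value": t.values,
                "mode": t.mode,
            }
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_normalized_csv(path: str | Path) -> list[NormalizedTrace]:
    df = pd.read_csv(path)
    missing = {"time_h", "well_id", "condition", "value", "mode"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for well_id, sub in df.groupby("well_id", sort=True):
        sub = sub.sort_values("time_h")
        out.append(
            NormalizedTrace(
                times_h=sub["time_h"].to_numpy(dtype=float),
                values=sub["value"].to_numpy(dtype=float),
                mode=str(sub["mode"].iloc[0]),
                source_well=str(well_id),
                condition=str(sub["condition"].iloc[0]),
            )
        )
    return out


def read_respirometry_csv(path: str | Path) -> list[RespirometryTrace]:
    """Read a flux CSV (one row per measurement cycle) into per-well traces."""
    df = pd.read_csv(path)
    missing = set(FLUX_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if "group" not in df.columns:
        df = df.assign(group="all")
    traces = []
    for well_id, sub in df.groupby("well_id", sort=True):
        sub = sub.sort_values("cycle_index")
        traces.append(
            RespirometryTrace(
                well_id=str(well_id),
                cycles=sub[["cycle_index", "phase", "ocr", "ecar"]].reset_index(drop=True),
                group=str(sub["group"].iloc[0]),
            )
        )
    return traces


def write_respirometry_csv(traces: Sequence[RespirometryTrace], path: str | Path) -> None:
    frames = []
    for t in traces:
        sub = t.cycles.copy()
        sub.insert(0, "well_id", t.well_id)
        sub["group"] = t.group
        frames.append(sub)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def jtk_results_table(results: Iterable[JtkResult]) -> pd.DataFrame:
    """Per-well rhythmicity table (one row per scanned trace)."""
    rows = []
    for r in results:
        rows.append(
            {
                "well_id": r.well_id,
                "condition": r.condition,
                "period_h": r.best_period_h,
                "phase_h": r.best_phase_h,
                "S": r.S,
                "tau": r.tau,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "amplitude": r.amplitude,
                "is_constant": r.is_constant,
            }
        )
    return pd.DataFrame(rows)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV with a version header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# lumiclock {lumiclock.__version__}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
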