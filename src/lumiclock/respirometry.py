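"""Mitochondrial stress-test metrics from phase-labelled OCR/ECAR traces.

A mito stress test measures oxygen consumption rate (OCR, pmol O2/min) and
extracellular acidification rate (ECAR, mpH/min) over repeated cycles while
injecting oligomycin (ATP-synthase inhibitor), FCCP (uncoupler) and
rotenone/antimycin A (complex I/III inhibitors). The canonical partition:

    non_mito_ocr      = OCR(rot_aa)
    basal_respiration = OCR(baseline) - non_mito_ocr
    atp_linked        = OCR(baseline) - OCR(oligomycin)
    max_respiration   = OCR(fccp) - non_mito_ocr
    spare_capacity    = max_respiration - basal_respiration
    basal_glycolysis  = ECAR(baseline)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PHASE_ORDER",
    "RespirometryTrace",
    "MitoStressMetrics",
    "phase_summary",
    "compute_metrics",
    "summarize_plate",
]

PHASE_ORDER = ("baseline", "oligomycin", "fccp", "rot_aa")

# Instrument-vendor report convention: which cycle represents each phase.
VENDOR_SUMMARIZERS = {"baseline": "last", "oligomycin": "min", "fccp": "max", "rot_aa": "min"}

_SUMMARIZERS = {
    "last": lambda x: float(x[-1]),
    "first": lambda x: float(x[0]),
    "min": lambda x: float(np.min(x)),
    "max": lambda x: float(np.max(x)),
    "mean": lambda x: float(np.mean(x)),
}


@dataclass(frozen=True)
class RespirometryTrace:
    """One well's stress-test trace: ordered measurement cycles with injection phase."""

    well_id: str
    cycles: pd.DataFrame  # columns: cycle_index, phase, ocr, ecar
    group: str = "control"

    def __post_init__(self):
        required = {"cycle_index", "phase", "ocr", "ecar"}
        missing = required - set(self.cycles.columns)
        if missing:
            raise ValueError(f"cycles table missing columns: {sorted(missing)}")
        phases = list(dict.fromkeys(self.cycles["phase"]))
        unknown = set(phases) - set(PHASE_ORDER)
        if unknown:
            raise ValueError(f"unknown phase label(s): {sorted(unknown)}")
        if phases != [p for p in PHASE_ORDER if p in phases]:
            raise ValueError(
                f"phases must appear in canonical injection order {PHASE_ORDER}, got {phases}"
            )


def phase_summary(
    trace: RespirometryTrace, phase: str, summarizer: str = "mean", signal: str = "ocr"
) -> float:
    """Summarize one phase's cycles with last/first/min/max/mean."""
    if phase not in PHASE_ORDER:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASE_ORDER}")
    if summarizer not in _SUMMARIZERS:
        raise ValueError(f"unknown summarizer {summarizer!r}")
    sub = trace.cycles.loc[trace.cycles["phase"] == phase]
    if sub.empty:
        raise ValueError(f"well {trace.well_id}: phase {phase!r} absent from trace")
    return _SUMMARIZERS[summarizer](sub[signal].to_numpy(dtype=float))


@dataclass(frozen=True)
class MitoStressMetrics:
    """Derived stress-test metrics, in the units of the input trace."""

    well_id: str
    non_mito_ocr: float
    basal_respiration: float
    atp_linked: float
    max_respiration: float
    spare_capacity: float
    basal_glycolysis: float
    group: str = "control"
    negative_flag: bool = False  # noise can make difference metrics negative


def compute_metrics(trace: RespirometryTrace, summarizer: str = "vendor") -> MitoStressMetrics:
    """Compute the stress-test partition for one well.

    ``summarizer="vendor"`` follows the instrument report convention (baseline:
    last cycle, oligomycin: min, FCCP: max, rot/AA: min); ``"mean"`` averages
    every phase's cycles. Basal glycolysis is always the mean baseline ECAR.
    """
    missing = [p for p in PHASE_ORDER if p not in set(trace.cycles["phase"])]
    if missing:
        raise ValueError(f"well {trace.well_id}: missing phase(s) {missing}")
    if summarizer == "vendor":
        summ = {p: phase_summary(trace, p, VENDOR_SUMMARIZERS[p]) for p in PHASE_ORDER}
    elif summarizer == "mean":
        summ = {p: phase_summary(trace, p, "mean") for p in PHASE_ORDER}
    else:
        raise ValueError(f"summarizer must be 'vendor' or 'mean', got {summarizer!r}")

    non_mito = summ["rot_aa"]
    basal = summ["baseline"] - non_mito
    atp_linked = summ["baseline"] - summ["oligomycin"]
    max_resp = summ["fccp"] - non_mito
    spare = max_resp - basal
    basal_glyc = phase_summary(trace, "baseline", "mean", signal="ecar")
    negative = min(basal, atp_linked, max_resp, spare) < 0
    if negative:
        warnings.warn(
            f"well {trace.well_id}: negative stress-test metric (noise); returned as-is",
            stacklevel=2,
        )
    return MitoStressMetrics(
        well_id=trace.well_id,
        non_mito_ocr=non_mito,
        basal_respiration=basal,
        atp_linked=atp_linked,
        max_respiration=max_resp,
        spare_capacity=spare,
        basal_glycolysis=basal_glyc,
        group=trace.group,
        negative_flag=bool(negative),
    )


METRIC_COLUMNS = (
    "non_mito_ocr",
    "basal_respiration",
    "atp_linked",
    "max_respiration",
    "spare_capacity",
    "basal_glycolysis",
)


def metrics_table(metrics: Iterable[MitoStressMetrics]) -> pd.DataFrame:
    """Per-well metric table (one row per well)."""
    rows = [
        {"well_id": m.well_id, "group": m.group, **{c: getattr(m, c) for c in METRIC_COLUMNS}}
        for m in metrics
    ]
    return pd.DataFrame(rows)


def summarize_plate(
    traces: Sequence[RespirometryTrace], summarizer: str = "vendor"
) -> pd.DataFrame:
    """Per-group mean, SEM (= SD/sqrt(n), ddof=1) and n of every metric.

    Metrics are computed per well first, then averaged within groups, matching
    replicate-level reporting.
    """
    per_well = metrics_table(compute_metrics(t, summarizer) for t in traces)
    if per_well.empty:
        raise ValueError("no wells to summarize")
    out = []
    for group, sub in per_well.groupby("group", sort=True):
        n = len(sub)
        row: dict[str, object] = {"group": group, "n": n}
        for c in METRIC_COLUMNS:
            x = sub[c].to_numpy(dtype=float)
            row[f"{c}_mean"] = float(np.mean(x))
            row[f"{c}_sem"] = float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out.append(row)
    return pd.DataFrame(out)
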