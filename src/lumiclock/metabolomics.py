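"""Metabolite peak-table normalization, QC filtering and phenotype classification.

Peak areas from LC-HRMS are normalized per sample by the matched internal
standard's area (correcting extraction loss and ion suppression) and by the
plate's protein amount, filtered by the stability of a quality-control sample
run at the beginning and end of the sequence (two-point relative SD), min-max
scaled per metabolite across cell lines for heatmap display, and summarized
into a metabolic phenotype call from relative pyruvate and lactate levels:

    low pyruvate,  low lactate   -> hypometabolic
    high pyruvate, high lactate  -> hypermetabolic
    low pyruvate,  high lactate  -> glycolytic
    high pyruvate, low lactate   -> oxphos
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PeakTable",
    "PhenotypeCall",
    "normalize_areas",
    "qc_rsd_filter",
    "two_point_rsd",
    "minmax_scale",
    "classify_phenotype",
]


@dataclass(frozen=True)
class PeakTable:
    """Samples x metabolites peak areas with internal-standard and protein normalizers.

    ``samples``: one row per sample with sample_id, line_id, is_qc,
    qc_position (begin/end/none), protein_amount.
    ``areas``: integrated peak areas, index sample_id, columns metabolites.
    ``is_areas``: internal-standard areas, index sample_id, columns IS ids.
    ``is_map``: metabolite -> internal-standard id (shared ISs allowed; a
    metabolite without a matched standard must be mapped to the designated
    nearest-retention-time standard in this table — the mapping is supplied,
    not inferred).
    """

    samples: pd.DataFrame
    areas: pd.DataFrame
    is_areas: pd.DataFrame
    is_map: pd.Series

    def __post_init__(self):
        required = {"sample_id", "line_id", "is_qc", "qc_position", "protein_amount"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"samples table missing columns: {sorted(missing)}")
        if not self.areas.index.equals(self.is_areas.index):
            raise ValueError("areas and is_areas must share the same sample index")
        unmapped = [m for m in self.areas.columns if m not in self.is_map.index]
        if unmapped:
            raise ValueError(f"metabolites without internal-standard mapping: {unmapped}")
        bad_is = set(self.is_map.loc[list(self.areas.columns)]) - set(self.is_areas.columns)
        if bad_is:
            raise ValueError(f"internal standards absent from is_areas: {sorted(bad_is)}")
        if (self.areas.to_numpy(dtype=float) < 0).any():
            raise ValueError("peak areas must be >= 0")


def normalize_areas(table: PeakTable) -> pd.DataFrame:
    """intensity = area / internal-standard area / protein amount, per sample.

    Samples with a nonpositive internal-standard area or protein amount are
    excluded from the output (with a warning naming them).
    """
    protein = table.samples.set_index("sample_id")["protein_amount"].reindex(table.areas.index)
    is_cols = table.is_map.loc[list(table.areas.columns)]
    is_matrix = table.is_areas[list(is_cols)].to_numpy(dtype=float)
    bad = (
        (is_matrix <= 0).any(axis=1)
        | ~np.isfinite(protein.to_numpy(dtype=float))
        | (protein.to_numpy(dtype=float) <= 0)
    )
    if bad.any():
        dropped = list(table.areas.index[bad])
        warnings.warn(
            f"excluding sample(s) with nonpositive internal standard or protein: {dropped}",
            stacklevel=2,
        )
    keep = ~bad
    intens = (
        table.areas.to_numpy(dtype=float)[keep]
        / is_matrix[keep]
        / protein.to_numpy(dtype=float)[keep, None]
    )
    return pd.DataFrame(intens, index=table.areas.index[keep], columns=table.areas.columns)


def two_point_rsd(x1: float, x2: float) -> float:
    """Relative SD (%) of two measurements: SD = |x1 - x2| / sqrt(2) (n-1 convention)."""
    mean = (x1 + x2) / 2.0
    if mean == 0:
        return float("inf")
    return abs(x1 - x2) / np.sqrt(2.0) / mean * 100.0


def qc_rsd_filter(
    table: PeakTable,
    threshold_pct: float = 25.0,
    intensities: pd.DataFrame | None = None,
) -> tuple[list[str], pd.Series]:
    """Retain metabolites whose begin/end QC relative SD is below the threshold.

    Returns (retained metabolite names, per-metabolite RSD%). Requires exactly
    one begin-QC and one end-QC sample; if either is missing the filter is
    skipped with a warning and every metabolite is retained.
    """
    if intensities is None:
        intensities = normalize_areas(table)
    qc = table.samples.loc[table.samples["is_qc"].astype(bool)]
    begin = qc.loc[qc["qc_position"] == "begin", "sample_id"].tolist()
    end = qc.loc[qc["qc_position"] == "end", "sample_id"].tolist()
    if len(begin) != 1 or len(end) != 1:
        warnings.warn(
            "QC filter skipped: need exactly one begin and one end QC sample "
            f"(found {len(begin)} begin, {len(end)} end)",
            stacklevel=2,
        )
        rsd = pd.Series(np.nan, index=intensities.columns, name="rsd_pct")
        return list(intensities.columns), rsd
    x1 = intensities.loc[begin[0]]
    x2 = intensities.loc[end[0]]
    rsd = pd.Series(
        [two_point_rsd(float(a), float(b)) for a, b in zip(x1, x2)],
        index=intensities.columns,
        name="rsd_pct",
    )
    retained = [m for m in intensities.columns if rsd[m] < threshold_pct]
    return retained, rsd


def minmax_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-metabolite (x - min) / (max - min) across cell lines, into [0, 1].

    A metabolite constant across lines carries no contrast and is emitted as
    missing (NaN) rather than an arbitrary constant color.
    """
    if len(matrix.index) < 2:
        raise ValueError("min-max scaling needs at least 2 lines")
    x = matrix.to_numpy(dtype=float)
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    rng = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (x - lo) / rng
    scaled[:, rng == 0] = np.nan
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)


@dataclass(frozen=True)
class PhenotypeCall:
    line_id: str
    pyruvate_level: float
    lactate_level: float
    call: str  # hypometabolic | hypermetabolic | glycolytic | oxphos | ambiguous


def classify_phenotype(pyruvate: pd.Series, lactate: pd.Series) -> list[PhenotypeCall]:
    """Quadrant phenotype calls from pyruvate/lactate dichotomized at the panel median.

    The split is rank-based, so calls are invariant to min-max scaling. A line
    sitting exactly on a median is flagged ``ambiguous`` rather than silently
    assigned.
    """
    if not pyruvate.index.equals(lactate.index):
        raise ValueError("pyruvate and lactate must be indexed by the same lines")
    if pyruvate.isna().any() or lactate.isna().any():
        raise ValueError("pyruvate and lactate must be present for all lines")
    pyr_med = float(pyruvate.median())
    lac_med = float(lactate.median())
    calls = []
    for line in pyruvate.index:
        p, l = float(pyruvate[line]), float(lactate[line])
        if p == pyr_med or l == lac_med:
            call = "ambiguous"
        elif p < pyr_med and l < lac_med:
            call = "hypometabolic"
        elif p > pyr_med and l > lac_med:
            call = "hypermetabolic"
        elif p < pyr_med and l > lac_med:
            call = "glycolytic"
        else:
            call = "oxphos"
        calls.append(PhenotypeCall(line_id=str(line), pyruvate_level=p, lactate_level=l, call=call))
    return calls
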