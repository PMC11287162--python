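"""Rolling-mean normalization of luminescence traces.

Two ratio modes decompose the reporter signal:

* self-normalization — divide each timepoint by the trace's own 24-h rolling
  mean; cancels slowly varying multiplicative components (the ATP-dependent
  signal magnitude) and isolates the circadian transcriptional oscillation;
* control normalization — divide by the 24-h rolling mean of the averaged
  control-condition trace of the same experiment; preserves between-condition
  magnitude differences.

Plus the two grid utilities: trimming the initial burn-in (with T0 relabelled
to the first retained timepoint) and binning to coarser sampling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from lumiclock.signal_model import LuminescenceTrace, validate_uniform_grid

__all__ = [
    "NormalizedTrace",
    "rolling_mean",
    "rolling_mean_24h",
    "self_normalize",
    "control_normalize",
    "trim_initial",
    "bin_to_hours",
]


@dataclass(frozen=True)
class NormalizedTrace:
    """Dimensionless ratio trace with provenance of the normalization."""

    times_h: np.ndarray
    values: np.ndarray
    mode: str  # "self" or "control"
    source_well: str
    condition: str = "control"
    window_h: float = 24.0
    align: str = "centered"
    source_step_h: float | None = None  # sampling step at normalization time

    def __post_init__(self):
        object.__setattr__(self, "times_h", np.asarray(self.times_h, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.mode not in ("self", "control"):
            raise ValueError(f"mode must be 'self' or 'control', got {self.mode!r}")
        validate_uniform_grid(self.times_h)

    @property
    def step_h(self) -> float:
        return float(self.times_h[1] - self.times_h[0])


def rolling_mean(
    trace: LuminescenceTrace | NormalizedTrace, window_h: float = 24.0, align: str = "centered"
) -> np.ndarray:
    """Per-timepoint rolling average of a trace.

    ``align="centered"`` uses every sample within +/- window_h/2 of the
    timepoint (truncated at the edges, so the first/last half-window use
    partial windows); ``align="trailing"`` uses the samples within the
    preceding window_h (inclusive of the current point).
    """
    step = validate_uniform_grid(trace.times_h)
    if window_h > trace.times_h[-1] - trace.times_h[0]:
        raise ValueError(
            f"window ({window_h} h) longer than trace span "
            f"({trace.times_h[-1] - trace.times_h[0]:g} h)"
        )
    s = pd.Series(trace.values)
    if align == "centered":
        half = int(round((window_h / 2.0) / step))
        out = s.rolling(window=2 * half + 1, center=True, min_periods=1).mean()
    elif align == "trailing":
        n = int(round(window_h / step)) + 1
        out = s.rolling(window=n, min_periods=1).mean()
    else:
        raise ValueError(f"align must be 'centered' or 'trailing', got {align!r}")
    return out.to_numpy()


def rolling_mean_24h(trace, window_h: float = 24.0, align: str = "centered") -> np.ndarray:
    """Alias for :func:`rolling_mean` at the conventional 24-h window."""
    return rolling_mean(trace, window_h=window_h, align=align)


def self_normalize(
    trace: LuminescenceTrace, window_h: float = 24.0, align: str = "centered"
) -> NormalizedTrace:
    """Divide each timepoint by the trace's own rolling mean.

    Exactly invariant to rescaling the raw counts; the long-run mean of the
    output is ~1 and the residual oscillation reflects circadian transcription
    alone.
    """
    if np.any(trace.values <= 0):
        raise ValueError(
            f"well {trace.well_id}: nonpositive counts; self-normalization needs positive "
            "values (handle offsets upstream rather than silently shifting)"
        )
    denom = rolling_mean(trace, window_h=window_h, align=align)
    return NormalizedTrace(
        times_h=trace.times_h,
        values=trace.values / denom,
        mode="self",
        source_well=trace.well_id,
        condition=trace.condition,
        window_h=window_h,
        align=align,
        source_step_h=trace.step_h,
    )


def control_normalize(
    trace: LuminescenceTrace,
    control_traces: Sequence[LuminescenceTrace],
    window_h: float = 24.0,
    align: str = "centered",
) -> NormalizedTrace:
    """Divide each timepoint by the rolling mean of the experiment's control signal.

    Control wells are averaged first (the control condition of an experiment is
    a single reference signal), then rolling-averaged. Magnitude differences
    between conditions are preserved in the output.
    """
    if len(control_traces) == 0:
        raise ValueError("control_traces must be nonempty")
    for ct in control_traces:
        if ct.times_h.shape != trace.times_h.shape or not np.allclose(
            ct.times_h, trace.times_h
        ):
            raise ValueError(
                f"control well {ct.well_id} grid does not match well {trace.well_id}"
            )
    mean_control = np.mean([ct.values for ct in control_traces], axis=0)
    if np.any(mean_control <= 0):
        raise ValueError("mean control trace has nonpositive values")
    ref = dataclasses.replace(trace, values=mean_control, truth=None)
    denom = rolling_mean(ref, window_h=window_h, align=align)
    return NormalizedTrace(
        times_h=trace.times_h,
        values=trace.values / denom,
        mode="control",
        source_well=trace.well_id,
        condition=trace.condition,
        window_h=window_h,
        align=align,
        source_step_h=trace.step_h,
    )


def trim_initial(trace, burn_in_h: float = 12.0):
    """Drop the first ``burn_in_h`` hours and relabel the first retained point t=0.

    Works on raw or normalized traces; returns the same type.
    """
    t = trace.times_h
    if burn_in_h >= t[-1] - t[0]:
        raise ValueError(f"burn_in ({burn_in_h} h) >= trace span ({t[-1] - t[0]:g} h)")
    keep = t >= t[0] + burn_in_h - 1e-9
    new_t = t[keep] - t[keep][0]
    return dataclasses.replace(trace, times_h=new_t, values=trace.values[keep])


def bin_to_hours(trace, bin_h: float = 1.0):
    """Average consecutive samples into bins of width ``bin_h``.

    ``bin_h`` must be an integer multiple of the sampling step; timestamps are
    placed at bin centers (mean of the bin's timepoints). A trailing
    incomplete bin is dropped. Returns the same trace type.
    """
    step = validate_uniform_grid(trace.times_h)
    ratio = bin_h / step
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-6:
        raise ValueError(f"bin_h ({bin_h} h) is not a multiple of the sampling step ({step:g} h)")
    if k == 1:
        return trace
    n_bins = trace.times_h.size // k
    if n_bins < 2:
        raise ValueError("binning would leave fewer than two points")
    t = trace.times_h[: n_bins * k].reshape(n_bins, k).mean(axis=1)
    v = trace.values[: n_bins * k].reshape(n_bins, k).mean(axis=1)
    return dataclasses.replace(trace, times_h=t, values=v)
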