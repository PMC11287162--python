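"""Synthetic generators for luminescence traces, stress-test traces and cell-line panels.

The conceptual model: the photon count of a circadian luciferase reporter is
the product of an ATP-dependent signal magnitude (baseline level, slow
substrate/ATP drift, drug multiplier) and a damped-cosine circadian
component, with multiplicative measurement noise:

    L(t) = b * mult * exp(-kappa*t) * [1 + a * exp(-lambda*t) * cos(2*pi*(t - phi)/tau)] * exp(sigma*Z_t)

optionally followed by Poisson photon counting. Every simulated object
carries its ground-truth parameters so each downstream analysis stage can be
run as a recovery test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from lumiclock._seeding import derive_seed
from lumiclock.respirometry import PHASE_ORDER, RespirometryTrace

__all__ = [
    "ClockParams",
    "MagnitudeParams",
    "NoiseParams",
    "LuminescenceTrace",
    "PanelSpec",
    "PanelSim",
    "default_times",
    "simulate_trace",
    "simulate_condition_plate",
    "simulate_mito_stress",
    "simulate_panel",
]


@dataclass(frozen=True)
class ClockParams:
    """Circadian component: relative amplitude a, period tau (h), phase phi (h),
    exponential damping lambda (1/h)."""

    rel_amplitude: float = 0.3
    period_h: float = 24.0
    phase_h: float = 0.0
    damping_per_h: float = 0.005

    def __post_init__(self):
        if not 0.0 <= self.rel_amplitude < 1.0:
            raise ValueError(
                f"rel_amplitude must be in [0, 1) to keep the signal positive, "
                f"got {self.rel_amplitude}"
            )
        if self.period_h <= 0:
            raise ValueError("period_h must be positive")
        if self.damping_per_h < 0:
            raise ValueError("damping_per_h must be >= 0")


@dataclass(frozen=True)
class MagnitudeParams:
    """ATP-dependent signal level: baseline counts b, slow exponential drift
    kappa (1/h) and a condition (drug) multiplier on the magnitude."""

    baseline_counts: float = 1000.0
    drift_per_h: float = 0.005
    condition_multiplier: float = 1.0

    def __post_init__(self):
        if self.baseline_counts <= 0:
            raise ValueError("baseline_counts must be positive")
        if self.condition_multiplier <= 0:
            raise ValueError("condition_multiplier must be positive")


@dataclass(frozen=True)
class NoiseParams:
    """Multiplicative lognormal noise (sigma of log), optional Poisson counting."""

    lognormal_sigma: float = 0.0
    poisson_counting: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.lognormal_sigma < 0:
            raise ValueError("lognormal_sigma must be >= 0")


@dataclass(frozen=True)
class LuminescenceTrace:
    """Uniformly sampled per-well reporter counts with condition metadata."""

    times_h: np.ndarray
    values: np.ndarray
    well_id: str = "W01"
    condition: str = "control"
    truth: tuple[ClockParams, MagnitudeParams] | None = None

    def __post_init__(self):
        object.__setattr__(self, "times_h", np.asarray(self.times_h, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times_h.ndim != 1 or self.times_h.shape != self.values.shape:
            raise ValueError("times_h and values must be 1-D arrays of equal length")
        validate_uniform_grid(self.times_h)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"well {self.well_id}: non-finite values")

    @property
    def step_h(self) -> float:
        return float(self.times_h[1] - self.times_h[0])

    @property
    def span_h(self) -> float:
        return float(self.times_h[-1] - self.times_h[0])


def validate_uniform_grid(times: np.ndarray) -> float:
    """Return the grid step, raising if the grid is not strictly increasing and uniform."""
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise ValueError("time grid needs at least two points")
    steps = np.diff(times)
    if np.any(steps <= 0):
        raise ValueError("time grid must be strictly increasing")
    step = steps[0]
    if not np.allclose(steps, step, rtol=1e-6, atol=1e-9 * max(step, 1.0)):
        raise ValueError("time grid must be uniform (constant sampling interval)")
    return float(step)


def default_times(total_h: float = 84.0, step_min: float = 10.0) -> np.ndarray:
    """Default LumiCycle-like grid: 10-min sampling over 84 h (both endpoints).

    84 h = 12-h burn-in plus a 72-h analysis window.
    """
    step_h = step_min / 60.0
    n = int(round(total_h / step_h)) + 1
    return np.arange(n) * step_h


def clock_component(clock: ClockParams, times: np.ndarray) -> np.ndarray:
    """Damped-cosine circadian factor 1 + a*exp(-lambda t)*cos(2 pi (t-phi)/tau)."""
    t = np.asarray(times, dtype=float)
    osc = clock.rel_amplitude * np.exp(-clock.damping_per_h * t) * np.cos(
        2.0 * np.pi * (t - clock.phase_h) / clock.period_h
    )
    return 1.0 + osc


def magnitude_component(mag: MagnitudeParams, times: np.ndarray) -> np.ndarray:
    """ATP-dependent magnitude factor b*mult*exp(-kappa t)."""
    t = np.asarray(times, dtype=float)
    return mag.baseline_counts * mag.condition_multiplier * np.exp(-mag.drift_per_h * t)


def simulate_trace(
    clock: ClockParams,
    mag: MagnitudeParams,
    noise: NoiseParams,
    times: np.ndarray | None = None,
    well_id: str = "W01",
    condition: str = "control",
) -> LuminescenceTrace:
    """Simulate one luminescence trace from the multiplicative model.

    Deterministic given ``noise.seed``. The ground-truth (clock, magnitude)
    parameters are attached to the returned trace.
    """
    if times is None:
        times = default_times()
    times = np.asarray(times, dtype=float)
    validate_uniform_grid(times)
    values = magnitude_component(mag, times) * clock_component(clock, times)
    rng = np.random.default_rng(noise.seed)
    if noise.lognormal_sigma > 0:
        values = values * np.exp(noise.lognormal_sigma * rng.standard_normal(times.size))
    if noise.poisson_counting:
        values = rng.poisson(values).astype(float)
    return LuminescenceTrace(
        times_h=times, values=values, well_id=well_id, condition=condition, truth=(clock, mag)
    )


@dataclass(frozen=True)
class Condition:
    """One plate condition: magnitude multiplier acts on the ATP-dependent level,
    amplitude multiplier on the clock's relative amplitude."""

    label: str
    condition_multiplier: float = 1.0
    amplitude_multiplier: float = 1.0


def simulate_condition_plate(
    n_wells_per_condition: int,
    conditions: Sequence[Condition | tuple],
    clock: ClockParams | None = None,
    mag: MagnitudeParams | None = None,
    noise: NoiseParams | None = None,
    times: np.ndarray | None = None,
    control_label: str = "control",
) -> list[LuminescenceTrace]:
    """Simulate a multi-well plate with shared clock/magnitude parameters.

    One condition must carry ``control_label`` and act as the untreated
    reference (both multipliers 1). Each well gets an independent noise
    stream derived from the root seed, the condition label and the well
    index, so streams are stable under adding wells or conditions.
    """
    clock = clock or ClockParams()
    mag = mag or MagnitudeParams()
    noise = noise or NoiseParams()
    conds = [c if isinstance(c, Condition) else Condition(*c) for c in conditions]
    labels = [c.label for c in conds]
    if control_label not in labels:
        raise ValueError(f"no condition labelled {control_label!r} among {labels}")
    ctrl = conds[labels.index(control_label)]
    if ctrl.condition_multiplier != 1.0 or ctrl.amplitude_multiplier != 1.0:
        raise ValueError("control condition must have both multipliers equal to 1")
    if n_wells_per_condition < 1:
        raise ValueError("n_wells_per_condition must be >= 1")

    traces = []
    for cond in conds:
        cond_clock = replace(clock, rel_amplitude=clock.rel_amplitude * cond.amplitude_multiplier)
        cond_mag = replace(
            mag, condition_multiplier=mag.condition_multiplier * cond.condition_multiplier
        )
        for k in range(n_wells_per_condition):
            well_id = f"{cond.label}_w{k + 1:02d}"
            well_noise = replace(noise, seed=derive_seed(noise.seed, "plate", cond.label, k))
            traces.append(
                simulate_trace(
                    cond_clock, cond_mag, well_noise, times, well_id=well_id, condition=cond.label
                )
            )
    return traces


def simulate_mito_stress(
    phase_levels: Mapping[str, tuple[float, float]],
    n_cycles_per_phase: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    well_id: str = "W01",
    group: str = "control",
) -> RespirometryTrace:
    """Simulate one well of a four-phase mitochondrial stress test.

    ``phase_levels`` maps each of baseline, oligomycin, fccp, rot_aa to the
    (OCR mean, ECAR mean) of that injection phase. Cycles get iid additive
    Gaussian noise with SD ``noise_sd`` on both channels.
    """
    missing = [p for p in PHASE_ORDER if p not in phase_levels]
    if missing:
        raise ValueError(f"missing injection phase(s): {missing}")
    if n_cycles_per_phase < 1:
        raise ValueError("n_cycles_per_phase must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for phase in PHASE_ORDER:
        ocr_mean, ecar_mean = phase_levels[phase]
        for _ in range(n_cycles_per_phase):
            idx += 1
            rows.append(
                {
                    "cycle_index": idx,
                    "phase": phase,
                    "ocr": ocr_mean + noise_sd * rng.standard_normal(),
                    "ecar": ecar_mean + noise_sd * rng.standard_normal(),
                }
            )
    return RespirometryTrace(well_id=well_id, cycles=pd.DataFrame(rows), group=group)


@dataclass(frozen=True)
class PanelSpec:
    """Cell-line panel where a latent metabolic activity m drives ATP production
    and basal glycolysis positively and clock amplitude negatively:

        atp        = atp_baseline + atp_coupling * m + noise
        glycolysis = glycolysis_baseline + glycolysis_coupling * m + noise
        amplitude  = max(0, amplitude_intercept - amplitude_slope * m + noise)

    Defaults emulate a patient-derived melanoma panel: OCR-scale ATP-linked
    respiration (tens of pmol O2/min), ECAR-scale glycolysis (tens of mpH/min)
    and self-normalized clock amplitudes of 0.1-0.4.
    """

    n_lines: int = 12
    activity_mean: float = 0.0
    activity_sd: float = 1.0
    atp_baseline: float = 60.0
    atp_coupling: float = 25.0
    glycolysis_baseline: float = 30.0
    glycolysis_coupling: float = 12.0
    amplitude_intercept: float = 0.25
    amplitude_slope: float = 0.08
    atp_noise_sd: float = 5.0
    glycolysis_noise_sd: float = 3.0
    amplitude_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_lines < 3:
            raise ValueError("n_lines must be >= 3")
        if self.activity_sd <= 0:
            raise ValueError("activity_sd must be positive")


@dataclass(frozen=True)
class PanelSim:
    """Simulated panel: truth table (one row per line) and optional traces."""

    panel: pd.DataFrame
    traces: dict[str, LuminescenceTrace] = field(default_factory=dict)


def simulate_panel(
    spec: PanelSpec,
    with_traces: bool = False,
    times: np.ndarray | None = None,
    trace_sigma: float = 0.05,
) -> PanelSim:
    """Simulate a cell-line panel; optionally a luminescence trace per line.

    The returned table has columns line_id, metabolic_activity, atp_linked,
    basal_glycolysis, amplitude (ground truth of the line's oscillation depth).
    Metabolic rates are clipped at 0.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.activity_mean + spec.activity_sd * rng.standard_normal(spec.n_lines)
    atp = spec.atp_baseline + spec.atp_coupling * m + spec.atp_noise_sd * rng.standard_normal(
        spec.n_lines
    )
    glyc = (
        spec.glycolysis_baseline
        + spec.glycolysis_coupling * m
        + spec.glycolysis_noise_sd * rng.standard_normal(spec.n_lines)
    )
    amp = (
        spec.amplitude_intercept
        - spec.amplitude_slope * m
        + spec.amplitude_noise_sd * rng.standard_normal(spec.n_lines)
    )
    panel = pd.DataFrame(
        {
            "line_id": [f"L{k + 1:03d}" for k in range(spec.n_lines)],
            "metabolic_activity": m,
            "atp_linked": np.clip(atp, 0.0, None),
            "basal_glycolysis": np.clip(glyc, 0.0, None),
            "amplitude": np.clip(amp, 0.0, None),
        }
    )
    traces: dict[str, LuminescenceTrace] = {}
    if with_traces:
        for _, row in panel.iterrows():
            a = min(float(row["amplitude"]), 0.95)
            clock = ClockParams(rel_amplitude=a)
            mag = MagnitudeParams()
            noise = NoiseParams(
                lognormal_sigma=trace_sigma, seed=derive_seed(spec.seed, "panel", row["line_id"])
            )
            traces[row["line_id"]] = simulate_trace(
                clock, mag, noise, times, well_id=str(row["line_id"]), condition="panel"
            )
    return PanelSim(panel=panel, traces=traces)
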