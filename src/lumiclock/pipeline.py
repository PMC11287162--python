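"""End-to-end orchestration: simulation -> normalization -> rhythmometry ->
respirometry -> panel statistics, under one config and one root seed.

All randomness derives from the single config seed via stable per-stage /
per-well hashing, so two runs with the same config produce byte-identical
outputs and adding a well never perturbs another well's noise stream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

import lumiclock
from lumiclock._seeding import derive_seed
from lumiclock.config import AnalysisConfig, RunManifest
from lumiclock.io import jtk_results_table, write_tsv
from lumiclock.normalization import (
    NormalizedTrace,
    bin_to_hours,
    control_normalize,
    self_normalize,
    trim_initial,
)
from lumiclock.panel_stats import PanelAnalysis, run_panel_analysis
from lumiclock.respirometry import RespirometryTrace, metrics_table, summarize_plate, compute_metrics
from lumiclock.rhythmometry import JtkGrid, JtkResult, classify_rhythmic, jtk_scan
from lumiclock.signal_model import (
    ClockParams,
    Condition,
    LuminescenceTrace,
    MagnitudeParams,
    NoiseParams,
    PanelSpec,
    simulate_condition_plate,
    simulate_mito_stress,
    simulate_panel,
)

__all__ = ["PlateAnalysis", "RunResult", "analyze_plate", "run_end_to_end", "default_scenario"]

# Illustrative default scenario: a magnitude-doubling OxPhos enhancer and a
# clock-dampening control compound (the study reports no numeric drug effect
# sizes, so these are round numbers exercising both arms of the decomposition).
DEFAULT_CONDITIONS = (
    Condition("DMSO", 1.0, 1.0),
    Condition("BEZ", 2.0, 1.0),
    Condition("DMF", 1.0, 0.4),
)
DEFAULT_MITO_LEVELS = {
    "baseline": (100.0, 30.0),
    "oligomycin": (40.0, 45.0),
    "fccp": (150.0, 50.0),
    "rot_aa": (20.0, 25.0),
}
DEFAULT_MITO_OCR_MULT = {"DMSO": 1.0, "BEZ": 1.5, "DMF": 1.1}


def crop_window(trace, window_h: float):
    """Keep only timepoints within [t0, t0 + window_h]."""
    keep = trace.times_h <= trace.times_h[0] + window_h + 1e-9
    return dataclasses.replace(trace, times_h=trace.times_h[keep], values=trace.values[keep])


def _grid(config: AnalysisConfig) -> JtkGrid:
    step = config.period_step_h if config.period_step_h is not None else config.bin_h
    periods = tuple(np.arange(config.period_min_h, config.period_max_h + step / 2, step))
    return JtkGrid(periods_h=periods, phase_step_h=step)


@dataclass
class PlateAnalysis:
    """Per-well rhythmicity and per-condition summaries for one plate."""

    jtk: pd.DataFrame
    condition_summary: pd.DataFrame
    self_normalized: list[NormalizedTrace] = field(default_factory=list)
    control_normalized: list[NormalizedTrace] = field(default_factory=list)


def analyze_plate(
    traces: Sequence[LuminescenceTrace], config: AnalysisConfig | None = None
) -> PlateAnalysis:
    """Trim, normalize (both modes), bin, scan and summarize one plate.

    The per-condition summary reports the mean/SEM of the self-normalized JTK
    amplitude (circadian component) and the mean control-normalized level
    (ATP-dependent magnitude relative to the control condition).
    """
    config = config or AnalysisConfig()
    trimmed = [crop_window(trim_initial(t, config.burn_in_h), config.window_h) for t in traces]
    controls = [t for t in trimmed if t.condition == config.control_label]
    if not controls:
        raise ValueError(f"no wells with control label {config.control_label!r}")
    selfn = [
        self_normalize(t, window_h=config.rolling_window_h, align=config.rolling_align)
        for t in trimmed
    ]
    ctrln = [
        control_normalize(t, controls, window_h=config.rolling_window_h, align=config.rolling_align)
        for t in trimmed
    ]
    selfn_binned = [bin_to_hours(t, config.bin_h) for t in selfn]
    grid = _grid(config)
    results: list[JtkResult] = [
        jtk_scan(t, grid=grid, null_method=config.null_method, n_perm=config.n_perm)
        for t in selfn_binned
    ]
    jtk = jtk_results_table(results)
    jtk["rhythmic"] = [classify_rhythmic(r, config.alpha) for r in results]

    level = pd.DataFrame(
        {
            "well_id": [t.source_well for t in ctrln],
            "condition": [t.condition for t in ctrln],
            "control_norm_level": [float(np.mean(t.values)) for t in ctrln],
        }
    )
    merged = jtk.merge(level, on=["well_id", "condition"])
    rows = []
    for cond, sub in merged.groupby("condition", sort=True):
        n = len(sub)
        amp = sub["amplitude"].to_numpy(dtype=float)
        lev = sub["control_norm_level"].to_numpy(dtype=float)
        rows.append(
            {
                "condition": cond,
                "n": n,
                "amplitude_mean": float(amp.mean()),
                "amplitude_sem": float(amp.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
                "control_norm_level_mean": float(lev.mean()),
                "control_norm_level_sem": float(lev.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
            }
        )
    return PlateAnalysis(
        jtk=merged,
        condition_summary=pd.DataFrame(rows),
        self_normalized=selfn_binned,
        control_normalized=[bin_to_hours(t, config.bin_h) for t in ctrln],
    )


def default_scenario(
    config: AnalysisConfig,
) -> tuple[list[LuminescenceTrace], list[RespirometryTrace], PanelSpec]:
    """Simulated inputs for a full run, all seeded from the config seed."""
    plate = simulate_condition_plate(
        n_wells_per_condition=config.n_wells_per_condition,
        conditions=DEFAULT_CONDITIONS,
        clock=ClockParams(rel_amplitude=0.3),
        mag=MagnitudeParams(baseline_counts=1000.0),
        noise=NoiseParams(lognormal_sigma=0.05, seed=derive_seed(config.seed, "luminescence")),
        control_label=config.control_label,
    )
    flux = []
    for cond, mult in DEFAULT_MITO_OCR_MULT.items():
        levels = {
            p: (ocr * mult, ecar) for p, (ocr, ecar) in DEFAULT_MITO_LEVELS.items()
        }
        for k in range(6):
            flux.append(
                simulate_mito_stress(
                    levels,
                    n_cycles_per_phase=3,
                    noise_sd=5.0,
                    seed=derive_seed(config.seed, "mito", cond, k),
                    well_id=f"{cond}_m{k + 1:02d}",
                    group=cond,
                )
            )
    panel_spec = PanelSpec(seed=derive_seed(config.seed, "panel"))
    return plate, flux, panel_spec


def analyze_panel(panel_spec: PanelSpec, config: AnalysisConfig) -> tuple[PanelAnalysis, pd.DataFrame]:
    """Simulate a cell-line panel, score each line's trace, run the association analysis."""
    sim = simulate_panel(panel_spec, with_traces=True)
    grid = _grid(config)
    rows = []
    for line_id, trace in sim.traces.items():
        t = crop_window(trim_initial(trace, config.burn_in_h), config.window_h)
        nt = bin_to_hours(
            self_normalize(t, window_h=config.rolling_window_h, align=config.rolling_align),
            config.bin_h,
        )
        res = jtk_scan(nt, grid=grid, null_method=config.null_method, n_perm=config.n_perm)
        rows.append(
            {
                "line_id": line_id,
                "amplitude": res.amplitude,
                "period_h": res.best_period_h,
                "p_adj": res.p_adj,
                "rhythmic": classify_rhythmic(res, config.alpha),
            }
        )
    records = pd.DataFrame(rows).merge(
        sim.panel[["line_id", "atp_linked", "basal_glycolysis"]], on="line_id"
    )
    analysis = run_panel_analysis(records, z_threshold=config.z_threshold)
    truth = sim.panel.rename(columns={"amplitude": "amplitude_truth"})
    return analysis, truth


@dataclass
class RunResult:
    """Bundle of every stage's outputs plus the run manifest."""

    config: AnalysisConfig
    plate: PlateAnalysis
    mito_per_well: pd.DataFrame
    mito_summary: pd.DataFrame
    panel: PanelAnalysis
    panel_truth: pd.DataFrame
    manifest: RunManifest

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_tsv(self.plate.jtk, out / "plate_jtk.tsv")
        write_tsv(self.plate.condition_summary, out / "plate_condition_summary.tsv")
        write_tsv(self.mito_per_well, out / "mito_per_well.tsv")
        write_tsv(self.mito_summary, out / "mito_summary.tsv")
        write_tsv(self.panel.records, out / "panel_records.tsv")
        regressions = {
            label: {
                "slope": r.slope,
                "intercept": r.intercept,
                "r_squared": r.r_squared,
                "p_value": r.p_value,
                "n": r.n,
            }
            for label, r in self.panel.regressions.items()
        }
        (out / "panel_regressions.json").write_text(
            json.dumps(regressions, indent=2, sort_keys=True)
        )
        self.manifest.write(out / "manifest.json")


def run_end_to_end(
    config: AnalysisConfig | None = None,
    luminescence: Sequence[LuminescenceTrace] | None = None,
    flux: Sequence[RespirometryTrace] | None = None,
    panel_spec: PanelSpec | None = None,
) -> RunResult:
    """Run the full pipeline; stages without supplied inputs are simulated."""
    config = config or AnalysisConfig()
    sim_plate, sim_flux, sim_panel = default_scenario(config)
    luminescence = list(luminescence) if luminescence is not None else sim_plate
    flux = list(flux) if flux is not None else sim_flux
    panel_spec = panel_spec or sim_panel

    plate = analyze_plate(luminescence, config)
    per_well = metrics_table(compute_metrics(t, config.summarizer) for t in flux)
    mito_summary = summarize_plate(flux, summarizer=config.summarizer)
    panel, panel_truth = analyze_panel(panel_spec, config)

    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.seed,
        package_version=lumiclock.__version__,
        record_counts={
            "luminescence_wells": len(luminescence),
            "flux_wells": len(flux),
            "panel_lines": len(panel.records),
            "panel_excluded": int(panel.records["excluded"].sum()),
        },
    )
    return RunResult(
        config=config,
        plate=plate,
        mito_per_well=per_well,
        mito_summary=mito_summary,
        panel=panel,
        panel_truth=panel_truth,
        manifest=manifest,
    )
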