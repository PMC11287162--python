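"""Panel-level association analysis and the study's statistical procedures.

Cell-line panels joining circadian amplitude with metabolic metrics are
analyzed with: exclusion of arrhythmic lines, exclusion of extreme-amplitude
outliers (Z-score > 2), simple OLS regressions (amplitude ~ ATP production,
amplitude ~ basal glycolysis, ATP ~ glycolysis) with R^2 and two-sided t
p-values, one-way ANOVA, Holm-Sidak step-down adjustment, the
Benjamini-Krieger-Yekutieli two-stage step-up FDR procedure, and
comparative-Ct qPCR expression (2^-dCt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegressionResult",
    "AnovaResult",
    "MultipleComparisonResult",
    "PanelAnalysis",
    "zscore_exclude",
    "linreg",
    "anova_oneway",
    "holm_sidak",
    "bky_two_stage",
    "ddct_expression",
    "run_panel_analysis",
]


def zscore_exclude(
    amplitudes: np.ndarray, threshold: float = 2.0, method: str = "leave_in"
) -> np.ndarray:
    """Flag high-amplitude outliers: Z_i > threshold (one-sided high).

    ``leave_in`` computes each point's Z from the full panel's mean and SD
    (ddof=1); note a single extreme point inflates the SD and can mask itself.
    ``leave_one_out`` recomputes mean/SD without the point under test, which
    avoids that self-masking.
    """
    x = np.asarray(amplitudes, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 values for Z-score exclusion")
    if method == "leave_in":
        sd = x.std(ddof=1)
        if sd == 0:
            return np.zeros(n, dtype=bool)
        z = (x - x.mean()) / sd
        return z > threshold
    if method == "leave_one_out":
        flags = np.zeros(n, dtype=bool)
        for i in range(n):
            rest = np.delete(x, i)
            sd = rest.std(ddof=1)
            if sd > 0:
                flags[i] = (x[i] - rest.mean()) / sd > threshold
            else:
                flags[i] = x[i] > rest.mean()  # infinite Z
        return flags
    raise ValueError(f"method must be 'leave_in' or 'leave_one_out', got {method!r}")


@dataclass(frozen=True)
class RegressionResult:
    """Simple OLS y = intercept + slope*x with two-sided t test on the slope."""

    slope: float
    intercept: float
    r_squared: float
    t_stat: float
    p_value: float
    n: int
    label: str = ""


def linreg(x: np.ndarray, y: np.ndarray, label: str = "") -> RegressionResult:
    """Closed-form simple linear regression (p from t with n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("var(x) = 0: regression undefined")
    res = stats.linregress(x, y)
    t = res.slope / res.stderr if res.stderr > 0 else np.inf * np.sign(res.slope)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        t_stat=float(t),
        p_value=float(res.pvalue),
        n=int(x.size),
        label=label,
    )


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p_value: float
    degenerate: bool = False  # zero within- and between-group variance


def anova_oneway(*groups: np.ndarray) -> AnovaResult:
    """One-way ANOVA across >= 2 groups (each n >= 2)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return AnovaResult(F=float("nan"), p_value=float("nan"), degenerate=True)
    within_var = sum(float(np.var(a, ddof=1)) for a in arrs)
    if within_var == 0:
        # identical values within groups but different means: infinitely strong signal
        return AnovaResult(F=float("inf"), p_value=0.0)
    F, p = stats.f_oneway(*arrs)
    return AnovaResult(F=float(F), p_value=float(p))


@dataclass(frozen=True)
class MultipleComparisonResult:
    raw_p: np.ndarray
    procedure: str  # holm_sidak | bky_two_stage
    q_or_alpha: float
    reject: np.ndarray
    adjusted_p: np.ndarray | None = None  # holm_sidak only


def holm_sidak(raw_p: np.ndarray, alpha: float = 0.05) -> MultipleComparisonResult:
    """Holm-Sidak step-down adjustment: adj_(i) = 1 - (1 - p_(i))^(m-i+1), running max."""
    p = np.asarray(raw_p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    with np.errstate(divide="ignore"):  # p = 1 hits log1p(-1) inside statsmodels
        reject, adj, _, _ = multipletests(p, alpha=alpha, method="holm-sidak")
    return MultipleComparisonResult(
        raw_p=p, procedure="holm_sidak", q_or_alpha=alpha, reject=reject, adjusted_p=adj
    )


def bky_two_stage(raw_p: np.ndarray, q: float = 0.05) -> MultipleComparisonResult:
    """Benjamini-Krieger-Yekutieli two-stage linear step-up FDR procedure.

    Stage 1: Benjamini-Hochberg at q' = q/(1+q), giving r1 rejections. If
    r1 = 0 reject nothing; if r1 = m reject everything; otherwise stage 2 is
    BH at level q' * m / (m - r1) (m - r1 estimates the number of true nulls).
    """
    p = np.asarray(raw_p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    q1 = q / (1.0 + q)
    r1 = int(_bh_reject(p, q1).sum())
    if r1 == 0:
        reject = np.zeros(m, dtype=bool)
    elif r1 == m:
        reject = np.ones(m, dtype=bool)
    else:
        reject = _bh_reject(p, q1 * m / (m - r1))
    return MultipleComparisonResult(
        raw_p=p, procedure="bky_two_stage", q_or_alpha=q, reject=reject
    )


def _bh_reject(p: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg linear step-up rejection set at level q."""
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = q * (np.arange(1, m + 1) / m)
    below = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))
        reject[order[: k + 1]] = True
    return reject


def ddct_expression(ct_target: float, ct_reference: float) -> float:
    """Comparative-Ct relative expression: 2^-(Ct_target - Ct_reference)."""
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    if not (np.all(np.isfinite(ct_target)) and np.all(np.isfinite(ct_reference))):
        raise ValueError("Ct values must be finite")
    out = 2.0 ** (-(ct_target - ct_reference))
    return float(out) if out.ndim == 0 else out


REGRESSION_PAIRS = (
    ("amplitude", "atp_linked", "amplitude~atp"),
    ("amplitude", "basal_glycolysis", "amplitude~glycolysis"),
    ("atp_linked", "basal_glycolysis", "atp~glycolysis"),
)


@dataclass(frozen=True)
class PanelAnalysis:
    """Exclusion-annotated panel and the three pairwise regressions."""

    records: pd.DataFrame
    amplitude_vs_atp: RegressionResult
    amplitude_vs_glycolysis: RegressionResult
    atp_vs_glycolysis: RegressionResult

    @property
    def regressions(self) -> dict[str, RegressionResult]:
        return {
            r.label: r
            for r in (self.amplitude_vs_atp, self.amplitude_vs_glycolysis, self.atp_vs_glycolysis)
        }


def run_panel_analysis(
    records: pd.DataFrame, z_threshold: float = 2.0, z_method: str = "leave_in"
) -> PanelAnalysis:
    """Apply the panel exclusion rules, then fit the three regressions on survivors.

    ``records`` needs columns line_id, amplitude, atp_linked, basal_glycolysis
    and rhythmic (boolean; callers typically derive it from the JTK adjusted
    p). Arrhythmic lines are excluded first; then amplitude outliers
    (Z > ``z_threshold``) among the rhythmic subset. The regressions are fit
    on x = metabolic metric, y = amplitude (and ATP ~ glycolysis).
    """
    required = {"line_id", "amplitude", "atp_linked", "basal_glycolysis", "rhythmic"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    out = records.copy().reset_index(drop=True)
    out["excluded"] = False
    out["exclusion_reason"] = "none"

    arrhythmic = ~out["rhythmic"].astype(bool)
    out.loc[arrhythmic, "excluded"] = True
    out.loc[arrhythmic, "exclusion_reason"] = "arrhythmic"

    rhythmic_idx = out.index[~arrhythmic]
    if len(rhythmic_idx) >= 3:
        flags = zscore_exclude(
            out.loc[rhythmic_idx, "amplitude"].to_numpy(), threshold=z_threshold, method=z_method
        )
        outlier_idx = rhythmic_idx[flags]
        out.loc[outlier_idx, "excluded"] = True
        out.loc[outlier_idx, "exclusion_reason"] = "amplitude_outlier"

    kept = out.loc[~out["excluded"]]
    if len(kept) < 3:
        raise ValueError(
            f"only {len(kept)} lines survive exclusion; need >= 3 for the regressions"
        )
    fits = {}
    for ycol, xcol, label in REGRESSION_PAIRS:
        fits[label] = linreg(kept[xcol].to_numpy(), kept[ycol].to_numpy(), label=label)
    return PanelAnalysis(
        records=out,
        amplitude_vs_atp=fits["amplitude~atp"],
        amplitude_vs_glycolysis=fits["amplitude~glycolysis"],
        atp_vs_glycolysis=fits["atp~glycolysis"],
    )
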