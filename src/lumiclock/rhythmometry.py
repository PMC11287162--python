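"""JTK-style nonparametric rhythm detection.

A trace is scored against cosine reference waveforms over a period x phase
grid with Kendall's S: concordant pairs count +1, discordant -1, pairs tied
in either series 0. Because S is a rank statistic, its null distribution
under exchangeability depends only on the series length and the reference's
tie structure, so null tables are computed once per (n, tie pattern) — by
exact enumeration for short series, by seeded Monte-Carlo permutation for
longer ones, or by a tie-corrected normal approximation — and cached.

The scan reports the reference with the smallest raw p (ties broken by
larger |tau|, then smaller period, then smaller phase), a Bonferroni
adjustment over the grid, and a fixed-period cosinor amplitude. For
self-normalized traces the cosinor amplitude is corrected for the known
frequency response of the rolling-mean normalization (a 24-h window
attenuates periods above 24 h and inflates those below), calibrated
numerically on the trace's own grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import islice, permutations
from typing import Sequence

import numpy as np
from scipy import stats

from lumiclock.normalization import NormalizedTrace, rolling_mean

__all__ = [
    "ReferenceWaveform",
    "JtkGrid",
    "JtkResult",
    "make_reference",
    "kendall_S",
    "null_distribution",
    "jtk_scan",
    "estimate_amplitude",
    "cosinor_fit",
    "classify_rhythmic",
]

_MAX_ENUMERATE_N = 10
_REF_DECIMALS = 9  # rounding so symmetric cosine values tie exactly

_PAIR_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}
_NULL_CACHE: dict[tuple, "SNull"] = {}
_CONTEXT_CACHE: dict[tuple, "_ScanContext"] = {}


def _pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _PAIR_CACHE:
        _PAIR_CACHE[n] = np.triu_indices(n, k=1)
    return _PAIR_CACHE[n]


def _pair_signs(x: np.ndarray) -> np.ndarray:
    """sign(x_j - x_i) over all pairs i<j, int8."""
    i, j = _pairs(x.size)
    return np.sign(x[j] - x[i]).astype(np.int8)


def _tie_signature(x: np.ndarray) -> tuple[int, ...]:
    """Multiset of tie-group sizes; determines a rank pattern up to relabeling."""
    _, counts = np.unique(x, return_counts=True)
    return tuple(sorted(int(c) for c in counts))


def _tie_pair_count(sig: Sequence[int]) -> int:
    return sum(t * (t - 1) // 2 for t in sig)


@dataclass(frozen=True)
class ReferenceWaveform:
    """Cosine reference evaluated on the analysis grid, with its rank/tie pattern."""

    period_h: float
    phase_h: float
    values: np.ndarray
    rank_pattern: np.ndarray
    tie_sizes: tuple[int, ...]


def make_reference(times_h: np.ndarray, period_h: float, phase_h: float) -> ReferenceWaveform:
    """Cosine peaking at ``phase_h`` with period ``period_h`` on the given grid.

    Values are rounded so that timepoints symmetric about the peak tie exactly.
    """
    t = np.asarray(times_h, dtype=float)
    vals = np.round(np.cos(2.0 * np.pi * (t - phase_h) / period_h), _REF_DECIMALS)
    ranks = stats.rankdata(vals)
    return ReferenceWaveform(
        period_h=float(period_h),
        phase_h=float(phase_h),
        values=vals,
        rank_pattern=ranks,
        tie_sizes=_tie_signature(vals),
    )


def kendall_S(data: np.ndarray, ref: ReferenceWaveform | np.ndarray) -> tuple[int, float]:
    """Kendall score S and tie-corrected tau (tau-b) of data against a reference.

    S = sum over pairs i<j of sign(data_j - data_i) * sign(ref_j - ref_i);
    pairs tied in either series contribute 0. tau = S normalized by the
    tie-corrected pair count sqrt((n0 - T_data)(n0 - T_ref)).
    """
    ref_vals = ref.values if isinstance(ref, ReferenceWaveform) else np.asarray(ref, dtype=float)
    data = np.asarray(data, dtype=float)
    if data.shape != ref_vals.shape:
        raise ValueError(f"length mismatch: data {data.shape} vs reference {ref_vals.shape}")
    n = data.size
    if n < 4:
        raise ValueError("need at least 4 points")
    if np.all(data == data[0]):
        raise ValueError("constant data: tau undefined (trace is arrhythmic)")
    d = _pair_signs(data)
    r = _pair_signs(ref_vals)
    S = int(np.dot(d.astype(np.int64), r.astype(np.int64)))
    n0 = n * (n - 1) // 2
    t_data = _tie_pair_count(_tie_signature(data))
    t_ref = _tie_pair_count(_tie_signature(ref_vals))
    tau = S / math.sqrt((n0 - t_data) * (n0 - t_ref))
    return S, tau


# ---------------------------------------------------------------------------
# Null distribution of S under exchangeability of the data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SNull:
    """Two-sided null of the Kendall score for one (n, reference tie pattern).

    Exactly one of (support, probs), abs_draws_sorted, or sd is populated,
    for the enumerate, permutation, and normal methods respectively.
    """

    method: str
    n: int
    tie_sizes: tuple[int, ...]
    support: np.ndarray | None = None
    probs: np.ndarray | None = None
    abs_draws_sorted: np.ndarray | None = None
    sd: float | None = None

    def p_values(self, S: np.ndarray) -> np.ndarray:
        """Two-sided p: Pr(|S_null| >= |S_obs|), vectorized."""
        s = np.abs(np.atleast_1d(np.asarray(S, dtype=float)))
        if self.method == "enumerate":
            a = np.abs(self.support)
            p = np.array([self.probs[a >= v - 0.5].sum() for v in s])
        elif self.method == "permutation":
            draws = self.abs_draws_sorted
            n_ge = draws.size - np.searchsorted(draws, s - 0.5, side="left")
            p = (1.0 + n_ge) / (draws.size + 1.0)
        elif self.method == "normal":
            if self.sd == 0:
                p = np.ones_like(s)
            else:
                z = np.maximum(s - 1.0, 0.0) / self.sd  # continuity correction
                p = 2.0 * stats.norm.sf(z)
        else:  # pragma: no cover
            raise ValueError(self.method)
        return np.minimum(p, 1.0)

    def p_value(self, S: float) -> float:
        return float(self.p_values(np.array([S]))[0])


def _normal_sd(n: int, ref_sig: Sequence[int], data_sig: Sequence[int] = ()) -> float:
    """Tie-corrected SD of S under random permutation (exact variance)."""

    def v0(sizes):
        return sum(t * (t - 1) * (2 * t + 5) for t in sizes)

    def v1(sizes):
        return sum(t * (t - 1) for t in sizes)

    def v2(sizes):
        return sum(t * (t - 1) * (t - 2) for t in sizes)

    var = (n * (n - 1) * (2 * n + 5) - v0(ref_sig) - v0(data_sig)) / 18.0
    if data_sig and n > 2:
        var += v2(data_sig) * v2(ref_sig) / (9.0 * n * (n - 1) * (n - 2))
        var += v1(data_sig) * v1(ref_sig) / (2.0 * n * (n - 1))
    return math.sqrt(max(var, 0.0))


def _representative_pattern(n: int, sig: Sequence[int]) -> np.ndarray:
    """A reference vector with the given tie-group sizes (canonical relabeling)."""
    out = np.repeat(np.arange(len(sig), dtype=float), list(sig))
    if out.size != n:  # pragma: no cover - internal consistency
        raise ValueError("tie signature does not sum to n")
    return out


def _simulate_null_draws(
    n: int, ref_sign_rows: np.ndarray, n_perm: int, seed: int
) -> np.ndarray:
    """(n_perm, u) Kendall scores of random permutations against u reference patterns.

    Assumes tie-free data (random permutations of 0..n-1); shared draws across
    the u patterns.
    """
    rng = np.random.default_rng(seed)
    i, j = _pairs(n)
    Rf = ref_sign_rows.astype(np.float32).T  # (P, u)
    out = np.empty((n_perm, ref_sign_rows.shape[0]), dtype=np.int32)
    base = np.arange(n)
    chunk = max(64, int(4_000_000 // max(i.size, 1)))
    pos = 0
    while pos < n_perm:
        b = min(chunk, n_perm - pos)
        X = rng.permuted(np.tile(base, (b, 1)), axis=1)
        D = np.sign(X[:, j] - X[:, i]).astype(np.float32)
        out[pos : pos + b] = np.rint(D @ Rf).astype(np.int32)
        pos += b
    return out


def _enumerate_support(n: int, ref_sign: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of S over all n! orderings of tie-free data."""
    if n > _MAX_ENUMERATE_N:
        raise ValueError(
            f"exact enumeration limited to n <= {_MAX_ENUMERATE_N} (factorial blowup), got {n}"
        )
    i, j = _pairs(n)
    counts: dict[int, int] = {}
    it = permutations(range(n))
    rf = ref_sign.astype(np.float32)
    while True:
        chunk = list(islice(it, 40320))
        if not chunk:
            break
        X = np.asarray(chunk, dtype=np.int16)
        D = np.sign(X[:, j] - X[:, i]).astype(np.float32)
        S = np.rint(D @ rf).astype(np.int64)
        vals, cnts = np.unique(S, return_counts=True)
        for v, c in zip(vals, cnts):
            counts[int(v)] = counts.get(int(v), 0) + int(c)
    total = math.factorial(n)
    support = np.array(sorted(counts), dtype=np.int64)
    probs = np.array([counts[int(v)] for v in support], dtype=float) / total
    return support, probs


def null_distribution(
    n: int,
    rank_pattern: ReferenceWaveform | np.ndarray | Sequence[float],
    method: str = "auto",
    n_perm: int = 20_000,
    seed: int = 0,
) -> SNull:
    """Null distribution of S against a given reference pattern, tie-free data.

    ``method``: "enumerate" (exact, n <= 10), "permutation" (seeded Monte
    Carlo), "normal" (tie-corrected variance), or "auto" (enumerate if
    n <= 10 else permutation). Results are cached by (n, tie pattern, method).
    """
    if isinstance(rank_pattern, ReferenceWaveform):
        ref_vals = rank_pattern.values
    else:
        ref_vals = np.asarray(rank_pattern, dtype=float)
    if ref_vals.size != n:
        raise ValueError(f"rank_pattern length {ref_vals.size} != n {n}")
    if method == "auto":
        method = "enumerate" if n <= _MAX_ENUMERATE_N else "permutation"
    sig = _tie_signature(ref_vals)
    key = (n, sig, method, n_perm if method == "permutation" else None,
           seed if method == "permutation" else None)
    if key in _NULL_CACHE:
        return _NULL_CACHE[key]
    rep = _representative_pattern(n, sig)
    ref_sign = _pair_signs(rep)
    if method == "enumerate":
        support, probs = _enumerate_support(n, ref_sign)
        null = SNull(method="enumerate", n=n, tie_sizes=sig, support=support, probs=probs)
    elif method == "permutation":
        draws = _simulate_null_draws(n, ref_sign[None, :], n_perm, seed)[:, 0]
        null = SNull(
            method="permutation",
            n=n,
            tie_sizes=sig,
            abs_draws_sorted=np.sort(np.abs(draws)),
        )
    elif method == "normal":
        null = SNull(method="normal", n=n, tie_sizes=sig, sd=_normal_sd(n, sig))
    else:
        raise ValueError(f"unknown null method {method!r}")
    _NULL_CACHE[key] = null
    return null


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JtkGrid:
    """Period/phase grid of reference waveforms.

    By default periods run 20-28 h in steps of the trace's sampling interval,
    and phases cover [0, period) at the same resolution.
    """

    periods_h: tuple[float, ...] = ()
    phase_step_h: float | None = None

    def resolve(self, step_h: float) -> tuple[np.ndarray, float]:
        if self.periods_h:
            periods = np.asarray(self.periods_h, dtype=float)
        else:
            periods = np.arange(20.0, 28.0 + step_h / 2, step_h)
        if np.any(periods <= 0):
            raise ValueError("periods must be positive")
        phase_step = self.phase_step_h if self.phase_step_h is not None else step_h
        if phase_step <= 0:
            raise ValueError("phase_step_h must be positive")
        return periods, float(phase_step)


@dataclass(frozen=True)
class JtkResult:
    """Outcome of a period/phase scan for one trace."""

    best_period_h: float
    best_phase_h: float
    S: int
    tau: float
    p_raw: float
    p_adj: float
    amplitude: float
    n_alternatives: int
    well_id: str = ""
    condition: str = ""
    span_warning: bool = False
    is_constant: bool = False


class _ScanContext:
    """Reference waveforms, sign matrix and null tables for one (grid, time base)."""

    def __init__(self, times: np.ndarray, periods: np.ndarray, phase_step: float):
        self.times = times
        n = times.size
        refs: list[ReferenceWaveform] = []
        for period in periods:
            for phase in np.arange(0.0, period - 1e-9, phase_step):
                refs.append(make_reference(times, period, phase))
        self.refs = refs
        self.periods = np.array([r.period_h for r in refs])
        self.phases = np.array([r.phase_h for r in refs])
        self.sign_matrix = np.stack([_pair_signs(r.values) for r in refs]).astype(np.float32)
        n0 = n * (n - 1) // 2
        self.ref_pair_counts = np.array(
            [n0 - _tie_pair_count(r.tie_sizes) for r in refs], dtype=float
        )
        sigs = [r.tie_sizes for r in refs]
        self.unique_sigs = sorted(set(sigs))
        self.sig_index = np.array([self.unique_sigs.index(s) for s in sigs])
        self._nulls: dict[tuple, list[SNull]] = {}

    def nulls(self, method: str, n_perm: int, seed: int) -> list[SNull]:
        n = self.times.size
        if method == "auto":
            method = "enumerate" if n <= _MAX_ENUMERATE_N else "permutation"
        key = (method, n_perm, seed)
        if key in self._nulls:
            return self._nulls[key]
        if method == "permutation":
            # joint draws across all unique tie patterns (shared permutations)
            reps = np.stack(
                [_pair_signs(_representative_pattern(n, s)) for s in self.unique_sigs]
            )
            draws = _simulate_null_draws(n, reps, n_perm, seed)
            out = [
                SNull(
                    method="permutation",
                    n=n,
                    tie_sizes=s,
                    abs_draws_sorted=np.sort(np.abs(draws[:, k])),
                )
                for k, s in enumerate(self.unique_sigs)
            ]
        else:
            rep = _representative_pattern
            out = [
                null_distribution(n, rep(n, s), method=method, n_perm=n_perm, seed=seed)
                for s in self.unique_sigs
            ]
        self._nulls[key] = out
        return out


def _scan_context(times: np.ndarray, grid: JtkGrid) -> _ScanContext:
    step = float(times[1] - times[0])
    periods, phase_step = grid.resolve(step)
    key = (
        times.size,
        round(step, 9),
        round(float(times[0]), 9),
        tuple(np.round(periods, 9)),
        round(phase_step, 9),
    )
    if key not in _CONTEXT_CACHE:
        _CONTEXT_CACHE[key] = _ScanContext(times, periods, phase_step)
    return _CONTEXT_CACHE[key]


def jtk_scan(
    trace: NormalizedTrace,
    grid: JtkGrid | None = None,
    null_method: str = "auto",
    n_perm: int = 20_000,
    null_seed: int = 0,
    amplitude_correction: bool = True,
) -> JtkResult:
    """Scan a (normalized, binned) trace over the period/phase reference grid.

    Selects the reference with minimal raw p (ties: larger |tau|, then smaller
    period, then smaller phase); ``p_adj`` is Bonferroni over all scanned
    (period, phase) pairs. The amplitude is a fixed-period cosinor fit; for
    self-normalized traces it is corrected for the rolling-window gain (see
    :func:`self_normalization_gain`).

    If the data contain ties (rare for binned photon counts), the
    tie-corrected normal null is used in place of enumeration/permutation,
    whose cached tables assume tie-free data.
    """
    times = np.asarray(trace.times_h, dtype=float)
    values = np.asarray(trace.values, dtype=float)
    n = values.size
    well = getattr(trace, "source_well", getattr(trace, "well_id", ""))
    condition = getattr(trace, "condition", "")
    grid = grid or JtkGrid()
    ctx = _scan_context(times, grid)
    span = times[-1] - times[0]
    span_warning = span < 2.0 * float(np.max(ctx.periods))

    if np.all(values == values[0]):
        return JtkResult(
            best_period_h=float("nan"),
            best_phase_h=float("nan"),
            S=0,
            tau=float("nan"),
            p_raw=1.0,
            p_adj=1.0,
            amplitude=0.0,
            n_alternatives=len(ctx.refs),
            well_id=well,
            condition=condition,
            span_warning=span_warning,
            is_constant=True,
        )

    data_sig = _tie_signature(values)
    data_has_ties = any(t > 1 for t in data_sig)
    method = null_method
    if method == "auto":
        method = "enumerate" if n <= _MAX_ENUMERATE_N else "permutation"
    if data_has_ties and method in ("enumerate", "permutation"):
        method = "normal"

    d = _pair_signs(values).astype(np.float32)
    S_all = np.rint(ctx.sign_matrix @ d).astype(np.int64)
    n0 = n * (n - 1) // 2
    t_data = _tie_pair_count(data_sig)
    tau_all = S_all / np.sqrt((n0 - t_data) * ctx.ref_pair_counts)

    if method == "normal" and data_has_ties:
        p_all = np.empty(len(ctx.refs))
        for k, sig in enumerate(ctx.unique_sigs):
            mask = ctx.sig_index == k
            sd = _normal_sd(n, sig, data_sig)
            nd = SNull(method="normal", n=n, tie_sizes=sig, sd=sd)
            p_all[mask] = nd.p_values(S_all[mask])
    else:
        nulls = ctx.nulls(method, n_perm, null_seed)
        p_all = np.empty(len(ctx.refs))
        for k, nd in enumerate(nulls):
            mask = ctx.sig_index == k
            p_all[mask] = nd.p_values(S_all[mask])

    order = np.lexsort((ctx.phases, ctx.periods, -np.abs(tau_all), p_all))
    best = int(order[0])
    n_alt = len(ctx.refs)
    best_period = float(ctx.periods[best])
    best_phase = float(ctx.phases[best])

    # The rank test reports the grid period; the amplitude fit refines the
    # period within one grid step (SSE-optimal) so grid truncation does not
    # bias the cosinor amplitude.
    step = float(times[1] - times[0])
    fit_period = _refine_period(times, values, best_period, step)
    fit = cosinor_fit(times, values, fit_period)
    amplitude = fit.amplitude
    if (
        amplitude_correction
        and getattr(trace, "mode", None) == "self"
        and getattr(trace, "align", "centered") == "centered"
    ):
        gain = self_normalization_gain(
            times,
            fit_period,
            fit.phase_h,
            window_h=getattr(trace, "window_h", 24.0),
            source_step_h=getattr(trace, "source_step_h", None),
        )
        if gain > 0.2:
            amplitude = amplitude / gain

    return JtkResult(
        best_period_h=best_period,
        best_phase_h=best_phase,
        S=int(S_all[best]),
        tau=float(tau_all[best]),
        p_raw=float(p_all[best]),
        p_adj=float(min(1.0, p_all[best] * n_alt)),
        amplitude=float(amplitude),
        n_alternatives=n_alt,
        well_id=well,
        condition=condition,
        span_warning=span_warning,
    )


def _refine_period(
    times: np.ndarray, values: np.ndarray, period: float, step: float
) -> float:
    """Period minimizing the cosinor SSE within one grid step of the scan period."""
    from scipy.optimize import minimize_scalar

    def sse(p: float) -> float:
        w = 2.0 * np.pi / p
        X = np.column_stack([np.ones_like(times), np.cos(w * times), np.sin(w * times)])
        _, res, rank, _ = np.linalg.lstsq(X, values, rcond=None)
        if rank < 3 or res.size == 0:
            return float("inf")
        return float(res[0])

    out = minimize_scalar(sse, bounds=(period - step, period + step), method="bounded")
    return float(out.x) if np.isfinite(out.fun) else period


@dataclass(frozen=True)
class CosinorFit:
    mesor: float
    amplitude: float
    phase_h: float
    period_h: float


def cosinor_fit(times: np.ndarray, values: np.ndarray, period_h: float) -> CosinorFit:
    """Least-squares fit of v(t) = m + A*cos(2*pi*(t - phi)/period), A >= 0."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 points for a cosinor fit")
    span = t[-1] - t[0]
    if span < period_h / 2:
        raise ValueError(
            f"span ({span:g} h) too short relative to period ({period_h:g} h): singular design"
        )
    w = 2.0 * np.pi / period_h
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    beta, _, rank, _ = np.linalg.lstsq(X, v, rcond=None)
    if rank < 3:
        raise ValueError("singular cosinor design matrix")
    m, b, c = beta
    A = float(np.hypot(b, c))
    phase = float((np.arctan2(c, b) / w) % period_h)
    return CosinorFit(mesor=float(m), amplitude=A, phase_h=phase, period_h=float(period_h))


def estimate_amplitude(
    trace: NormalizedTrace | np.ndarray,
    period_h: float,
    phase_h: float | None = None,
    values: np.ndarray | None = None,
) -> float:
    """Cosinor amplitude of a trace at a fixed period (phase fitted freely).

    Accepts a trace object or (times, values) arrays. ``phase_h`` is accepted
    for interface symmetry with the scan but the least-squares fit determines
    the phase; the returned amplitude is nonnegative with sign absorbed into
    the phase.
    """
    if values is None:
        times, vals = trace.times_h, trace.values
    else:
        times, vals = np.asarray(trace, dtype=float), values
    return cosinor_fit(times, vals, period_h).amplitude


def self_normalization_gain(
    times: np.ndarray,
    period_h: float,
    phase_h: float,
    window_h: float = 24.0,
    source_step_h: float | None = None,
    probe_amplitude: float = 0.2,
) -> float:
    """Amplitude gain of self-normalization for a cosine of the given period.

    Dividing by a W-hour rolling mean multiplies the oscillatory component by
    approximately 1 - sinc(W/period) (the moving-average frequency response):
    ~1 at period = W, >1 for shorter periods, <1 for longer ones, with extra
    attenuation from the truncated windows at the trace edges. The gain is
    measured numerically by pushing a unit-mesor probe cosine through the same
    pipeline the data saw: rolling-mean division on the original sampling grid
    (``source_step_h``, reconstructed from the bin centers), then binning back
    to ``times`` and refitting the amplitude.
    """
    t = np.asarray(times, dtype=float)
    step = float(t[1] - t[0])
    if source_step_h is None or source_step_h >= step - 1e-9:
        fine, k = t, 1
    else:
        k = int(round(step / source_step_h))
        start = t[0] - (k - 1) / 2.0 * source_step_h
        fine = start + np.arange(t.size * k) * source_step_h
    w = 2.0 * np.pi / period_h
    probe = 1.0 + probe_amplitude * np.cos(w * (fine - phase_h))
    carrier = NormalizedTrace(
        times_h=fine, values=probe, mode="self", source_well="_probe", window_h=window_h
    )
    denom = rolling_mean(carrier, window_h=window_h, align="centered")
    ratio = (probe / denom).reshape(t.size, k).mean(axis=1)
    fitted = cosinor_fit(t, ratio, period_h).amplitude
    return fitted / probe_amplitude


def classify_rhythmic(result: JtkResult, alpha: float = 0.05) -> bool:
    """A trace is rhythmic iff its grid-adjusted p falls below alpha."""
    if result.is_constant:
        return False
    return bool(result.p_adj < alpha)
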