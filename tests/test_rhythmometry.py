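"""Tests of the JTK-style rank scoring, null distributions and the scan."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from lumiclock.normalization import NormalizedTrace, bin_to_hours, self_normalize, trim_initial
from lumiclock.rhythmometry import (
    JtkGrid,
    classify_rhythmic,
    cosinor_fit,
    estimate_amplitude,
    jtk_scan,
    kendall_S,
    make_reference,
    null_distribution,
)
from lumiclock.signal_model import (
    ClockParams,
    MagnitudeParams,
    NoiseParams,
    default_times,
    simulate_trace,
)


def brute_force_S(data, ref):
    n = len(data)
    return sum(
        np.sign(data[j] - data[i]) * np.sign(ref[j] - ref[i])
        for i in range(n)
        for j in range(i + 1, n)
    )


def norm_trace(values, step_h=1.0, mode="self"):
    return NormalizedTrace(
        times_h=np.arange(len(values)) * step_h, values=np.asarray(values, float),
        mode=mode, source_well="w",
    )


class TestKendallS:
    def test_perfect_concordance_and_discordance(self):
        ref = make_reference(np.arange(24.0), 24.0, 0.0)
        S, tau = kendall_S(ref.values, ref)
        assert tau == pytest.approx(1.0)
        S, tau = kendall_S(-ref.values, ref)
        assert tau == pytest.approx(-1.0)

    @pytest.mark.parametrize("n", [5, 8])
    @pytest.mark.parametrize("tied", [False, True])
    def test_matches_exhaustive_pair_oracle(self, rng, n, tied):
        for _ in range(25):
            data = rng.integers(0, 4, size=n).astype(float) if tied else rng.standard_normal(n)
            ref = rng.integers(0, 3, size=n).astype(float)
            if np.all(data == data[0]) or np.all(ref == ref[0]):
                continue
            S, tau = kendall_S(data, ref)
            assert S == brute_force_S(data, ref)
            expected_tau = stats.kendalltau(data, ref).statistic
            assert tau == pytest.approx(expected_tau, rel=1e-12)

    def test_invariant_under_monotone_transforms(self, rng):
        ref = make_reference(np.arange(20.0), 24.0, 3.0)
        data = rng.standard_normal(20)
        S0, tau0 = kendall_S(data, ref)
        for f in (np.exp, lambda x: 5 * x + 2, lambda x: x**3):
            S, tau = kendall_S(f(data), ref)
            assert (S, tau) == (S0, tau0)

    def test_time_reversal_leaves_p_invariant(self, rng):
        t = np.arange(16.0)
        ref = make_reference(t, 24.0, 0.0)
        data = rng.standard_normal(16)
        S_fwd, _ = kendall_S(data, ref)
        rev = make_reference(t, 24.0, 0.0).values[::-1]
        S_rev, _ = kendall_S(data[::-1], rev)
        null = null_distribution(16, ref, method="normal")
        assert null.p_value(S_fwd) == null.p_value(S_rev)

    def test_constant_data_rejected(self):
        ref = make_reference(np.arange(10.0), 24.0, 0.0)
        with pytest.raises(ValueError, match="constant"):
            kendall_S(np.ones(10), ref)

    def test_length_mismatch_rejected(self):
        ref = make_reference(np.arange(10.0), 24.0, 0.0)
        with pytest.raises(ValueError, match="length"):
            kendall_S(np.arange(8.0), ref)


class TestNullDistribution:
    def test_n3_tie_free_exact(self):
        null = null_distribution(3, np.array([1.0, 2.0, 3.0]), method="enumerate")
        np.testing.assert_array_equal(null.support, [-3, -1, 1, 3])
        np.testing.assert_allclose(null.probs, [1 / 6, 2 / 6, 2 / 6, 1 / 6])

    @pytest.mark.parametrize("method", ["enumerate", "permutation"])
    def test_probabilities_sum_to_one(self, method):
        ref = make_reference(np.arange(6.0), 24.0, 0.0)
        null = null_distribution(6, ref, method=method, n_perm=2000)
        if method == "enumerate":
            assert null.probs.sum() == pytest.approx(1.0)
        else:
            assert null.abs_draws_sorted.size == 2000

    @pytest.mark.parametrize("period,phase", [(24.0, 0.0), (20.0, 3.0)])
    def test_enumeration_matches_brute_force_oracle(self, period, phase):
        # independent oracle: loop over all n! orderings with the naive pair count
        n = 6
        ref = make_reference(np.arange(float(n)), period, phase)
        counts = {}
        for perm in itertools.permutations(range(n)):
            S = brute_force_S(np.array(perm, float), ref.values)
            counts[S] = counts.get(S, 0) + 1
        total = math.factorial(n)
        null = null_distribution(n, ref, method="enumerate")
        assert list(null.support) == sorted(counts)
        np.testing.assert_allclose(
            null.probs, [counts[s] / total for s in sorted(counts)], rtol=1e-12
        )

    def test_permutation_estimate_agrees_with_enumeration(self):
        n = 6
        ref = make_reference(np.arange(float(n)), 26.0, 1.0)
        exact = null_distribution(n, ref, method="enumerate")
        mc = null_distribution(n, ref, method="permutation", n_perm=100_000, seed=11)
        draws = mc.abs_draws_sorted
        for s, p_exact in zip(exact.support, exact.probs):
            p_hat = np.mean(np.abs(draws) == abs(s)) if s >= 0 else None
        # compare atom frequencies on |S|: each within 3 SE of the exact mass
        abs_support = np.unique(np.abs(exact.support))
        for v in abs_support:
            mass = exact.probs[np.abs(exact.support) == v].sum()
            freq = np.mean(draws == v)
            se = math.sqrt(mass * (1 - mass) / draws.size)
            assert abs(freq - mass) <= 3 * se + 1e-12

    def test_normal_sd_matches_exact_variance(self):
        ref = make_reference(np.arange(8.0), 24.0, 2.0)
        exact = null_distribution(8, ref, method="enumerate")
        var_exact = np.sum(exact.probs * exact.support.astype(float) ** 2)
        normal = null_distribution(8, ref, method="normal")
        assert normal.sd == pytest.approx(math.sqrt(var_exact), rel=1e-12)

    def test_enumerate_beyond_limit_rejected(self):
        with pytest.raises(ValueError, match="enumeration"):
            null_distribution(12, np.arange(12.0), method="enumerate")

    def test_two_sided_definition(self):
        null = null_distribution(3, np.array([1.0, 2.0, 3.0]), method="enumerate")
        assert null.p_value(3) == pytest.approx(2 / 6)  # P(|S| >= 3)
        assert null.p_value(1) == pytest.approx(1.0)


class TestJtkScan:
    def make_cosine_trace(self, a=0.3, tau=24.0, phase=0.0, n=72):
        t = np.arange(float(n))
        return norm_trace(1 + a * np.cos(2 * np.pi * (t - phase) / tau))

    def test_noise_free_cosine_recovers_period(self):
        res = jtk_scan(self.make_cosine_trace(tau=24.0))
        assert abs(res.best_period_h - 24.0) <= 1.0
        assert res.p_adj < 1e-4
        assert classify_rhythmic(res)

    def test_constant_trace_flagged_arrhythmic(self):
        res = jtk_scan(norm_trace(np.ones(72)))
        assert res.is_constant
        assert math.isnan(res.best_period_h)
        assert not classify_rhythmic(res)

    def test_tie_break_prefers_smaller_period(self):
        # grid with duplicated period entries exercises deterministic tie-breaking
        res = jtk_scan(self.make_cosine_trace(tau=24.0), grid=JtkGrid(periods_h=(24.0, 24.0)))
        assert res.best_period_h == 24.0

    def test_short_span_sets_warning(self):
        res = jtk_scan(self.make_cosine_trace(n=40), null_method="normal")
        assert res.span_warning

    def test_bonferroni_adjustment(self):
        res = jtk_scan(self.make_cosine_trace(a=0.05), null_method="normal")
        assert res.p_adj == pytest.approx(min(1.0, res.p_raw * res.n_alternatives))
        assert res.n_alternatives == sum(int(p) for p in range(20, 29))

    def test_amplitude_rescaling_invariance(self):
        # rank statistics and the cosinor ratio both ignore raw-count scale
        t = default_times(84.0, 10.0)
        tr = simulate_trace(
            ClockParams(0.25, 24.0, 2.0, 0.0),
            MagnitudeParams(1000.0),
            NoiseParams(0.05, seed=4),
            t,
        )
        import dataclasses

        res1 = jtk_scan(bin_to_hours(self_normalize(trim_initial(tr, 12.0)), 1.0))
        scaled = dataclasses.replace(tr, values=1e3 * tr.values)
        res2 = jtk_scan(bin_to_hours(self_normalize(trim_initial(scaled, 12.0)), 1.0))
        assert res1.amplitude == pytest.approx(res2.amplitude, rel=1e-12)
        assert res1.p_raw == res2.p_raw


class TestAmplitude:
    def test_exact_cosine_amplitude(self):
        t = np.arange(72.0)
        v = 1 + 0.3 * np.cos(2 * np.pi * t / 24)
        assert estimate_amplitude(t, 24.0, values=v) == pytest.approx(0.3, rel=1e-12)

    def test_constant_input_gives_zero(self):
        t = np.arange(72.0)
        assert estimate_amplitude(t, 24.0, values=np.ones(72)) == pytest.approx(0.0, abs=1e-12)

    def test_phase_and_mesor_recovered(self):
        t = np.arange(96.0)
        v = 2.5 + 0.4 * np.cos(2 * np.pi * (t - 7.0) / 24)
        fit = cosinor_fit(t, v, 24.0)
        assert fit.mesor == pytest.approx(2.5, rel=1e-9)
        assert fit.phase_h == pytest.approx(7.0, abs=1e-6)

    def test_short_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            cosinor_fit(np.arange(8.0), np.ones(8), 24.0)

    def test_noisy_amplitude_recovery(self):
        # a = 0.2, sigma = 0.05: mean recovered amplitude within 10% of truth
        t = default_times(84.0, 10.0)
        amps = []
        for seed in range(25):
            tr = simulate_trace(
                ClockParams(0.2, 24.0, 3.0, 0.0),
                MagnitudeParams(1000.0),
                NoiseParams(0.05, seed=seed),
                t,
            )
            nt = bin_to_hours(self_normalize(trim_initial(tr, 12.0)), 1.0)
            amps.append(jtk_scan(nt).amplitude)
        assert 0.18 <= np.mean(amps) <= 0.22


class TestClassify:
    def test_boundaries(self):
        res = jtk_scan(norm_trace(1 + 0.3 * np.cos(2 * np.pi * np.arange(72.0) / 24)))
        assert classify_rhythmic(res, alpha=0.05)
        assert not classify_rhythmic(res, alpha=0.0)
        import dataclasses

        weak = dataclasses.replace(res, p_adj=1.0)
        assert not classify_rhythmic(weak)


@given(st.integers(min_value=0, max_value=500))
def test_p_uniformity_spot_check(seed):
    """Single-reference p of pure noise is rarely extreme (sanity, not calibration)."""
    r = np.random.default_rng(seed)
    ref = make_reference(np.arange(30.0), 24.0, 0.0)
    S, _ = kendall_S(r.standard_normal(30), ref)
    p = null_distribution(30, ref, method="normal").p_value(S)
    assert 0.0 < p <= 1.0
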