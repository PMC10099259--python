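"""Agreement statistics against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from solegrf.metrics import (
    CrossingError,
    bland_altman,
    evaluate_testset,
    midstance_crossing_time,
    midstance_timing_error,
    peak_values,
    pearson_per_axis,
    rmse_per_axis,
    timing_error_percent,
)
from solegrf.preprocess import StanceSegment


def brute_pearson(x, y):
    """Textbook covariance / sd formula, no shared code."""
    mx, my = sum(x) / len(x), sum(y) / len(y)
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / (vx**0.5 * vy**0.5)


def brute_bland_altman(est, mea):
    """Direct-formula Bland-Altman, including both CI families."""
    d = [a - b for a, b in zip(est, mea)]
    n = len(d)
    bias = sum(d) / n
    sd = (sum((x - bias) ** 2 for x in d) / (n - 1)) ** 0.5
    t = stats.t.ppf(0.975, n - 1)
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    return {
        "bias": bias,
        "sd": sd,
        "loa": loa,
        "bias_ci": (bias - t * sd / n**0.5, bias + t * sd / n**0.5),
        "lloa_ci": (loa[0] - t * sd * (3 / n) ** 0.5, loa[0] + t * sd * (3 / n) ** 0.5),
        "uloa_ci": (loa[1] - t * sd * (3 / n) ** 0.5, loa[1] + t * sd * (3 / n) ** 0.5),
    }


class TestPearsonRmse:
    def test_perfect_and_shifted(self):
        x = [np.vstack([np.arange(10.0), np.arange(10.0), np.arange(10.0)])]
        y = [x[0] + 10.0]
        assert np.allclose(pearson_per_axis(y, x), 1.0)
        assert np.allclose(rmse_per_axis(y, x), 10.0)
        assert np.allclose(rmse_per_axis(x, x), 0.0)

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = rng.integers(5, 1000)
            p = [rng.normal(size=(3, n))]
            m = [rng.normal(size=(3, n))]
            rs = pearson_per_axis(p, m)
            es = rmse_per_axis(p, m)
            for axis in range(3):
                assert rs[axis] == pytest.approx(
                    brute_pearson(list(p[0][axis]), list(m[0][axis])), abs=1e-12
                )
                brute_rmse = (
                    sum((a - b) ** 2 for a, b in zip(p[0][axis], m[0][axis])) / n
                ) ** 0.5
                assert es[axis] == pytest.approx(brute_rmse, abs=1e-12)

    def test_zero_variance_rejected(self):
        const = [np.zeros((3, 10))]
        with pytest.raises(ValueError, match="zero variance"):
            pearson_per_axis(const, [np.random.default_rng(0).normal(size=(3, 10))])

    def test_pooling_concatenates_segments(self):
        rng = np.random.default_rng(3)
        p = [rng.normal(size=(3, 7)), rng.normal(size=(3, 5))]
        m = [rng.normal(size=(3, 7)), rng.normal(size=(3, 5))]
        pooled = pearson_per_axis(p, m)
        concat = pearson_per_axis(
            [np.concatenate(p, axis=1)], [np.concatenate(m, axis=1)]
        )
        assert np.allclose(pooled, concat)


class TestMidstanceCrossing:
    def test_constructed_series(self):
        assert midstance_crossing_time(np.array([-1.0, -1.0, 1.0, 1.0]), 200.0) == pytest.approx(0.0075)

    def test_no_crossing_raises(self):
        with pytest.raises(CrossingError):
            midstance_crossing_time(np.array([1.0, 2.0, 3.0]), 200.0)

    def test_spurious_early_flips_ignored(self):
        """Noise flips before the braking minimum do not count."""
        ap = np.array([0.1, -0.1, 0.1, -5.0, -3.0, -1.0, 2.0, 4.0])
        t = midstance_crossing_time(ap, 200.0)
        assert t > 5 / 200.0

    def test_synthetic_waveform_crossing(self, reference_subject):
        """AP template with crossing phase 0.5 over a 0.6 s stance
        crosses at 0.300 s."""
        from solegrf.synthgait import ap_grf_waveform

        t = np.arange(0, 0.6, 1 / 200.0)
        ap = ap_grf_waveform(t / 0.6, reference_subject)
        assert midstance_crossing_time(ap, 200.0) == pytest.approx(0.300, abs=0.005)


class TestTimingError:
    def test_identical_series_equal_class(self):
        ap = np.array([-1.0, -0.5, 0.5, 1.0])
        signed, abs_err, label = midstance_timing_error(ap, ap, 200.0)
        assert signed == 0.0 and abs_err == 0.0 and label == "equal"

    def test_shifted_measurement_classified_earlier(self):
        pred = np.array([-1.0] * 5 + [-0.5, 0.5] + [1.0] * 8)
        meas = np.roll(pred, 3)
        meas[:3] = -1.0
        signed, _, label = midstance_timing_error(pred, meas, 200.0)
        assert signed == pytest.approx(-0.015)
        assert label == "earlier"

    @given(shift=st.integers(min_value=-4, max_value=4))
    @settings(max_examples=20, deadline=None)
    def test_antisymmetry(self, shift):
        base = np.concatenate([-np.linspace(3, 0.2, 10), np.linspace(0.2, 3, 10)])
        n = len(base)
        # time-shift with edge clamping: keeps a single clean crossing
        other = np.interp(np.arange(n) - shift, np.arange(n), base)
        s1, a1, l1 = midstance_timing_error(base, other, 200.0)
        s2, a2, l2 = midstance_timing_error(other, base, 200.0)
        assert s1 == pytest.approx(-s2, abs=1e-12)
        assert a1 == pytest.approx(a2)
        flip = {"earlier": "later", "later": "earlier", "equal": "equal"}
        assert l2 == flip[l1]

    def test_percent_arithmetic(self):
        assert timing_error_percent(0.059, 0.59, 0.6) == pytest.approx((6.0, 10.0))
        assert timing_error_percent(0.0, 0.59, 0.6) == (0.0, 0.0)
        pct_cycle, pct_stance = timing_error_percent(0.0550, 0.59, 0.6)
        assert pct_stance == pytest.approx(9.32, abs=0.01)
        assert pct_cycle == pytest.approx(pct_stance * 0.6)  # identity

    def test_percent_rejects_bad_stance(self):
        with pytest.raises(ValueError):
            timing_error_percent(0.05, 0.0)


class TestPeaks:
    def test_maxima_extracted(self):
        targets = np.array(
            [[0.0, 700.0, 650.0, 0.0], [-50.0, -10.0, 80.0, 20.0], [1.0, 5.0, 3.0, 0.0]]
        )
        assert peak_values(targets) == (700.0, 80.0, 5.0)

    def test_all_negative_ap_rejected(self):
        targets = np.zeros((3, 5))
        targets[1] = -1.0
        with pytest.raises(ValueError, match="propulsive"):
            peak_values(targets)


class TestBlandAltman:
    def test_worked_example(self):
        """Five pairs with differences (2, -1, 3, -2, 5): bias 1.4,
        sd 2.881, LoA (-4.247, 7.047)."""
        res = bland_altman([12, 19, 33, 38, 55], [10, 20, 30, 40, 50])
        assert res.bias == pytest.approx(1.4)
        assert res.sd_diff == pytest.approx(2.8809721, abs=1e-6)
        assert res.lloa == pytest.approx(-4.2467, abs=1e-3)
        assert res.uloa == pytest.approx(7.0467, abs=1e-3)

    def test_identical_pairs(self):
        res = bland_altman([5.0] * 5, [5.0] * 5)
        assert res.bias == 0.0 and res.sd_diff == 0.0
        assert res.lloa == 0.0 and res.uloa == 0.0

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            n = int(rng.integers(2, 1000))
            est = rng.normal(50, 20, n)
            mea = rng.normal(50, 20, n)
            res = bland_altman(est, mea)
            ref = brute_bland_altman(list(est), list(mea))
            assert res.bias == pytest.approx(ref["bias"], abs=1e-12)
            assert res.sd_diff == pytest.approx(ref["sd"], abs=1e-12)
            assert res.lloa == pytest.approx(ref["loa"][0], abs=1e-12)
            assert res.uloa == pytest.approx(ref["loa"][1], abs=1e-12)
            assert res.bias_ci == pytest.approx(ref["bias_ci"], abs=1e-12)
            assert res.lloa_ci == pytest.approx(ref["lloa_ci"], abs=1e-12)
            assert res.uloa_ci == pytest.approx(ref["uloa_ci"], abs=1e-12)

    @given(scale=st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, scale):
        est = [12.0, 19.0, 33.0, 38.0, 55.0]
        mea = [10.0, 20.0, 30.0, 40.0, 50.0]
        a = bland_altman(est, mea)
        b = bland_altman([scale * x for x in est], [scale * x for x in mea])
        assert b.bias == pytest.approx(scale * a.bias, rel=1e-9)
        assert b.sd_diff == pytest.approx(scale * a.sd_diff, rel=1e-9)
        assert b.uloa == pytest.approx(scale * a.uloa, rel=1e-9)

    def test_bias_ci_nested_in_loa(self):
        # nesting requires t(n-1, 0.975)/sqrt(n) < 1.96, true from n = 4
        rng = np.random.default_rng(31)
        for _ in range(50):
            n = int(rng.integers(4, 200))
            est = rng.normal(0, 5, n)
            mea = rng.normal(0, 5, n)
            res = bland_altman(est, mea)
            if res.sd_diff > 0:
                assert res.lloa < res.bias_ci[0]
                assert res.bias_ci[1] < res.uloa

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class _VerbatimModel:
    """Outputs the measured targets: the perfect estimator."""

    def __init__(self, segments):
        self._lookup = {s.inputs.tobytes(): s.targets for s in segments}

    def predict(self, inputs):
        return self._lookup[np.asarray(inputs).tobytes()]


def _toy_segments():
    rng = np.random.default_rng(6)
    segments = []
    for i, group in enumerate(["similar", "different", "different", "similar"]):
        T = 90 + 10 * i
        t = np.arange(T) / 200.0
        vertical = 700 * np.sin(np.pi * t / t[-1]) + rng.normal(0, 1, T)
        ap = -120 * np.sin(2 * np.pi * t / t[-1]) + rng.normal(0, 1, T)
        ml = 30 * np.sin(np.pi * t / t[-1]) + rng.normal(0, 1, T)
        lc = np.abs(rng.normal(100, 30, (3, T)))
        inputs = np.vstack([lc, lc.sum(axis=0, keepdims=True)])
        segments.append(
            StanceSegment(f"S{i}", "t0", 200.0, inputs, np.vstack([vertical, ap, ml]),
                          timing_group=group)
        )
    return segments


class TestEvaluateTestset:
    def test_verbatim_model_is_perfect(self):
        segs = _toy_segments()
        report = evaluate_testset(_VerbatimModel(segs), segs)
        for m in report.axis_metrics:
            assert m.pearson_r == pytest.approx(1.0)
            assert m.rmse == pytest.approx(0.0, abs=1e-9)
        assert report.timing.mean_abs_error == 0.0
        assert report.timing.n_equal == len(segs)
        for ba in report.bland_altman_peaks.values():
            assert ba.bias == pytest.approx(0.0, abs=1e-9)

    def test_subgroup_counts_sum_to_total(self):
        segs = _toy_segments()
        report = evaluate_testset(_VerbatimModel(segs), segs)
        assert report.n_trials == len(segs)
        assert sum(s.n_trials for s in report.subgroups.values()) == len(segs)
        assert set(report.subgroups) == {"similar", "different"}

    def test_empty_testset_rejected(self):
        with pytest.raises(ValueError):
            evaluate_testset(_VerbatimModel([]), [])
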