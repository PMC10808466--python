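"""Calibration: 4PL fitting, inversion, flat-field mask, error propagation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import barriersense as bs
from barriersense.errors import (
    DegeneratePixelError,
    InvalidInputError,
    NonConvergenceError,
    OutOfRangeError,
)
from barriersense.synthetic_chip import NoiseModel, generate_calibration_dataset

from conftest import make_frame


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def bisect_invert(curve, f, lo=1e-12, hi=1e6, tol=1e-13):
    """Invert the 4PL by bisection on eval_4pl, independent of invert_4pl."""
    increasing = bs.eval_4pl(curve, hi) > bs.eval_4pl(curve, lo)
    for _ in range(200):
        mid = np.sqrt(lo * hi)  # bisect in log space
        if (bs.eval_4pl(curve, mid) < f) == increasing:
            lo = mid
        else:
            hi = mid
        if hi / lo - 1 < tol:
            break
    return np.sqrt(lo * hi)


def grid_search_4pl(x, y, a_grid, b_grid, c_grid, d_grid):
    """Exhaustive least-squares over a parameter grid; returns (ssr, params)."""
    best = (np.inf, None)
    x = np.asarray(x)
    y = np.asarray(y)
    for a in a_grid:
        for b in b_grid:
            for c in c_grid:
                for d in d_grid:
                    pred = d + (a - d) / (1.0 + (x / c) ** b)
                    ssr = float(np.sum((y - pred) ** 2))
                    if ssr < best[0]:
                        best = (ssr, (a, b, c, d))
    return best


# ---------------------------------------------------------------------------
# eval / invert
# ---------------------------------------------------------------------------


class TestEval4PL:
    def test_worked_arithmetic(self, simple_curve):
        # F(1.5) = 5 + 200/(1+3) = 155 for a=5, b=1, c=0.5, d=205
        assert bs.eval_4pl(simple_curve, 1.5) == pytest.approx(155.0, abs=1e-12)

    def test_midpoint_and_zero_limits(self, truth_curve):
        c = truth_curve
        assert bs.eval_4pl(c, c.c) == pytest.approx((c.a + c.d) / 2)
        assert bs.eval_4pl(c, 0.0) == c.a

    def test_zero_limit_negative_slope_gives_other_asymptote(self):
        dec = bs.CalibrationCurve("cyan", a=5.0, b=-1.2, c=0.5, d=220.0)
        assert bs.eval_4pl(dec, 0.0) == dec.d

    def test_negative_concentration_rejected(self, truth_curve):
        with pytest.raises(InvalidInputError):
            bs.eval_4pl(truth_curve, -0.1)

    def test_vectorized_matches_scalar(self, truth_curve):
        xs = np.array([0.0, 0.1, 0.5, 2.0])
        vec = bs.eval_4pl(truth_curve, xs)
        assert vec == pytest.approx([bs.eval_4pl(truth_curve, float(x)) for x in xs])


class TestInvert4PL:
    def test_worked_arithmetic_against_bisection(self, simple_curve):
        assert bs.invert_4pl(simple_curve, 155.0) == pytest.approx(1.5, rel=1e-9)
        assert bs.invert_4pl(simple_curve, 155.0) == pytest.approx(
            bisect_invert(simple_curve, 155.0), rel=1e-9
        )

    def test_midpoint_inverts_to_c(self, truth_curve):
        c = truth_curve
        assert bs.invert_4pl(c, (c.a + c.d) / 2) == pytest.approx(c.c, rel=1e-12)

    def test_near_lower_asymptote_goes_to_zero(self, truth_curve):
        x = bs.invert_4pl(truth_curve, truth_curve.a + 1e-9)
        assert 0 < x < 1e-6

    @pytest.mark.parametrize("f,asym", [(4.9, "lower"), (5.0, "lower"),
                                        (220.0, "upper"), (300.0, "upper")])
    def test_out_of_range_names_violated_asymptote(self, truth_curve, f, asym):
        with pytest.raises(OutOfRangeError) as exc:
            bs.invert_4pl(truth_curve, f)
        assert exc.value.asymptote == asym

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.0, 50.0),
        span=st.floats(10.0, 250.0),
        b=st.floats(0.3, 4.0),
        c=st.floats(1e-3, 10.0),
        sign=st.sampled_from([1.0, -1.0]),
        logx=st.floats(-2.0, 2.0),
    )
    def test_round_trip_identity(self, a, span, b, c, sign, logx):
        """invert(eval(x)) == x to 1e-9 relative for x in [c/100, 100c]."""
        curve = bs.CalibrationCurve("ch", a=a, b=sign * b, c=c, d=a + span)
        x = c * 10.0**logx
        assert bs.invert_4pl(curve, bs.eval_4pl(curve, x)) == pytest.approx(x, rel=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        b=st.floats(0.3, 4.0).flatmap(lambda v: st.sampled_from([v, -v])),
        d=st.floats(60.0, 250.0),
    )
    def test_strict_monotonicity(self, b, d):
        curve = bs.CalibrationCurve("ch", a=5.0, b=b, c=0.5, d=d)
        xs = np.logspace(-3, 2, 50)
        ys = bs.eval_4pl(curve, xs)
        diffs = np.diff(ys)
        assert np.all(diffs > 0) or np.all(diffs < 0)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class TestFit4PL:
    def test_noiseless_exact_recovery(self, truth_curve):
        ds = generate_calibration_dataset(
            truth_curve, np.logspace(-3, 0.7, 8), 1, NoiseModel(gaussian_sigma=0, seed=0)
        )
        fit = bs.fit_4pl(ds, "cyan")
        for p in "abcd":
            assert getattr(fit, p) == pytest.approx(getattr(truth_curve, p), rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_recovery_decreasing_curve(self):
        truth = bs.CalibrationCurve("amber", a=230.0, b=0.8, c=0.2, d=12.0)
        ds = generate_calibration_dataset(
            truth, np.logspace(-3, 1, 9), 1, NoiseModel(gaussian_sigma=0, seed=0)
        )
        fit = bs.fit_4pl(ds)
        for p in "abcd":
            assert getattr(fit, p) == pytest.approx(getattr(truth, p), rel=1e-6)

    def test_noisy_fit_beats_grid_oracle_and_recovers_c(self, truth_curve):
        ds = generate_calibration_dataset(
            truth_curve, np.logspace(-3, 0.7, 8), 3, NoiseModel(gaussian_sigma=2, seed=42)
        )
        fit = bs.fit_4pl(ds)
        assert fit.c == pytest.approx(0.5, rel=0.10)
        x = np.array(ds.concentrations)
        y = np.array(ds.intensities)
        ssr_grid, params = grid_search_4pl(
            x, y,
            a_grid=np.linspace(0, 15, 7),
            b_grid=np.linspace(0.8, 1.6, 9),
            c_grid=np.logspace(-1, 0, 21),
            d_grid=np.linspace(210, 230, 9),
        )
        ssr_fit = float(np.sum((y - bs.eval_4pl(fit, x)) ** 2))
        assert ssr_fit <= ssr_grid + 1e-9
        assert params[2] == pytest.approx(fit.c, rel=0.15)

    def test_c_recovered_within_10pct_in_95pct_of_trials(self, truth_curve):
        conc = np.logspace(-3, 0.7, 8)
        hits = 0
        for seed in range(100):
            ds = generate_calibration_dataset(
                truth_curve, conc, 3, NoiseModel(gaussian_sigma=2, seed=seed)
            )
            fit = bs.fit_4pl(ds)
            hits += abs(fit.c - truth_curve.c) / truth_curve.c <= 0.10
        assert hits >= 95

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(InvalidInputError):
            bs.CalibrationDataset([0.1, 0.2, 0.3, 0.4], [10, 20, 30, 40])

    def test_flat_intensities_fail_to_converge(self):
        ds = bs.CalibrationDataset([0.1, 0.2, 0.4, 0.8, 1.6], [50.0] * 5)
        with pytest.raises(NonConvergenceError):
            bs.fit_4pl(ds)

    def test_ci_brackets_point_estimates(self, truth_curve):
        ds = generate_calibration_dataset(
            truth_curve, np.logspace(-3, 0.7, 8), 3, NoiseModel(gaussian_sigma=2, seed=5)
        )
        fit = bs.fit_4pl(ds)
        for p in "abcd":
            lo, hi = fit.param_ci95[p]
            assert lo <= getattr(fit, p) <= hi
        assert 0.0 <= fit.r_squared <= 1.0
        assert fit.se_regression > 0


# ---------------------------------------------------------------------------
# illumination mask
# ---------------------------------------------------------------------------


class TestIlluminationMask:
    def test_uniform_frames_give_unit_mask(self):
        frames = [make_frame(np.full((4, 5), 100.0)) for _ in range(3)]
        mask = bs.estimate_illumination_mask(frames)
        assert mask.multipliers == pytest.approx(np.ones((4, 5)))

    def test_gradient_multipliers_match_direct_arithmetic(self):
        # pixel means [50, 100, 150], global mean 100 -> [2, 1, 2/3]
        frames = [make_frame([[50.0, 100.0, 150.0]]) for _ in range(3)]
        mask = bs.estimate_illumination_mask(frames)
        assert mask.multipliers == pytest.approx(np.array([[2.0, 1.0, 2.0 / 3.0]]))

    def test_zero_pixel_raises_with_coordinates(self):
        arr = np.full((3, 3), 10.0)
        arr[1, 2] = 0.0
        with pytest.raises(DegeneratePixelError) as exc:
            bs.estimate_illumination_mask([make_frame(arr)] * 3)
        assert (1, 2) in exc.value.pixels

    def test_fewer_than_three_frames_rejected(self):
        frames = [make_frame(np.full((2, 2), 9.0))] * 2
        with pytest.raises(InvalidInputError):
            bs.estimate_illumination_mask(frames)

    def test_correction_flattens_calibration_image(self):
        rng = np.random.default_rng(0)
        field = 1.0 + 0.4 * rng.random((20, 30))
        frames = [make_frame(80.0 * field) for _ in range(3)]
        mask = bs.estimate_illumination_mask(frames)
        corrected = bs.apply_mask(frames[0], mask)
        cv = corrected.pixels.std() / corrected.pixels.mean()
        assert cv < 1e-9

    def test_mask_estimation_is_idempotent(self):
        rng = np.random.default_rng(1)
        field = 1.0 + 0.4 * rng.random((20, 30))
        frames = [make_frame(70.0 * field) for _ in range(3)]
        mask = bs.estimate_illumination_mask(frames)
        corrected = [bs.apply_mask(f, mask) for f in frames]
        remask = bs.estimate_illumination_mask(corrected)
        assert remask.multipliers == pytest.approx(np.ones((20, 30)), abs=1e-12)

    def test_apply_mask_examples(self):
        frame = make_frame([[50.0, 100.0, 150.0]])
        mask = bs.IlluminationMask(np.array([[2.0, 1.0, 2.0 / 3.0]]))
        assert bs.apply_mask(frame, mask).pixels == pytest.approx(np.full((1, 3), 100.0))
        ones = bs.IlluminationMask(np.ones((1, 3)))
        assert bs.apply_mask(frame, ones).pixels == pytest.approx(frame.pixels)
        zero = make_frame(np.zeros((1, 3)))
        assert bs.apply_mask(zero, mask).pixels == pytest.approx(np.zeros((1, 3)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            bs.apply_mask(make_frame(np.ones((2, 2))), bs.IlluminationMask(np.ones((3, 3))))


# ---------------------------------------------------------------------------
# error propagation and sensitivity region
# ---------------------------------------------------------------------------


class TestConcentrationError:
    def test_zero_se_gives_zero_error(self, truth_curve):
        curve = bs.CalibrationCurve("c", a=5, b=1.2, c=0.5, d=220, se_regression=0.0)
        err = bs.concentration_error(curve, 100.0)
        assert err.value == 0.0 and not err.one_sided

    def test_half_width_matches_bisection_oracle(self):
        curve = bs.CalibrationCurve("c", a=5, b=1.0, c=0.5, d=205, se_regression=4.0)
        err = bs.concentration_error(curve, 155.0)
        lo = bisect_invert(curve, 151.0)
        hi = bisect_invert(curve, 159.0)
        assert err.value == pytest.approx((hi - lo) / 2, rel=1e-6)
        assert not err.one_sided

    def test_one_sided_near_asymptote_is_flagged(self):
        curve = bs.CalibrationCurve("c", a=5, b=1.0, c=0.5, d=205, se_regression=4.0)
        err = bs.concentration_error(curve, 7.0)  # f - se would fall below a
        assert err.one_sided and err.value > 0

    def test_neither_side_invertible_raises(self):
        curve = bs.CalibrationCurve("c", a=5, b=1.0, c=0.5, d=205, se_regression=400.0)
        with pytest.raises(OutOfRangeError):
            bs.concentration_error(curve, 100.0)


class TestSensitivityRegion:
    @staticmethod
    def _fitted(truth, sigma, seed):
        ds = generate_calibration_dataset(
            truth, np.logspace(-4, 0.7, 10), 3, NoiseModel(gaussian_sigma=sigma, seed=seed)
        )
        return bs.fit_4pl(ds)

    def test_region_brackets_steep_portion(self, truth_curve):
        fit = self._fitted(truth_curve, 2.0, 3)
        region = bs.sensitivity_region(fit)
        assert 0 < region.lower < fit.c < region.upper
        # agrees with the bisection oracle applied to the CI edges
        a_hi = fit.param_ci95["a"][1]
        d_lo = fit.param_ci95["d"][0]
        assert region.lower == pytest.approx(bisect_invert(fit, a_hi), rel=1e-6)
        assert region.upper == pytest.approx(bisect_invert(fit, d_lo), rel=1e-6)
        assert region.lower_err > 0 and region.upper_err > 0

    def test_decreasing_curve_region_still_ordered(self):
        truth = bs.CalibrationCurve("amber", a=230.0, b=0.9, c=0.3, d=10.0)
        fit = self._fitted(truth, 2.0, 11)
        region = bs.sensitivity_region(fit)
        assert 0 < region.lower < region.upper

    def test_zero_width_ci_is_unbounded(self):
        # exactly zero-width CIs put the edges on the asymptotes, where the
        # inversion limits are 0 and infinity: reported as out-of-range
        curve = bs.CalibrationCurve(
            "c", a=5.0, b=1.2, c=0.5, d=220.0, se_regression=0.0,
            param_ci95={"a": (5.0, 5.0), "b": (1.2, 1.2),
                        "c": (0.5, 0.5), "d": (220.0, 220.0)},
        )
        with pytest.raises(OutOfRangeError):
            bs.sensitivity_region(curve)
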