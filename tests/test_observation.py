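"""Tests of arrest detection, duration correction and survival-curve building."""

from __future__ import annotations

import numpy as np
import pytest

from flowbond import (
    BondLaw,
    NonspecificModel,
    SurvivalCurve,
    Trajectory,
    binding_frequency,
    build_survival,
    correct_duration,
    detect_arrests,
    extrapolate_true_count,
    fit_bond_law,
    fit_grid,
    mean_off_rate,
    peak_velocity,
    sample_duration,
    specific_fraction,
    specific_survival_pipeline,
    subtract_nonspecific,
    survival,
)
from flowbond.hydrodynamics import ChamberGeometry
from flowbond.synthetic_data import default_ground_truth, generate_arrests

U_P = 22.5  # um/s at G = 18.5
FRAME = 0.02  # s


def make_track(stop_windows, total=4.0, u_p=U_P, noise=0.0, seed=0):
    """Bead moving at u_p except inside the given (start, end) stop windows."""
    t = np.arange(0.0, total, FRAME)
    moving = np.ones_like(t, dtype=bool)
    for t0, t1 in stop_windows:
        moving &= ~((t >= t0) & (t < t1))
    x = np.concatenate(([0.0], np.cumsum(np.where(moving[:-1], u_p * FRAME, 0.0))))
    if noise:
        x = x + np.random.default_rng(seed).normal(0.0, noise, size=x.shape)
    return Trajectory("b0", t, x)


class TestDetectArrests:
    def test_constant_velocity_has_no_events(self):
        assert detect_arrests(make_track([]), u_p=U_P) == []

    def test_single_full_stop_detected_and_corrected(self):
        events = detect_arrests(make_track([(1.5, 2.5)]), u_p=U_P)
        assert len(events) == 1
        ev = events[0]
        assert not ev.censored
        # window truncation removes (window - 2*threshold/u_p) from the
        # apparent span; the correction restores the true 1.0-s duration
        assert ev.corrected_duration == pytest.approx(1.0, abs=2 * FRAME)

    def test_subwindow_pause_is_invisible(self):
        assert detect_arrests(make_track([(1.5, 1.6)]), u_p=U_P) == []

    def test_two_separated_stops_are_distinct(self):
        events = detect_arrests(make_track([(0.8, 1.6), (2.4, 3.2)]), u_p=U_P)
        assert len(events) == 2
        assert events[0].start_time < events[1].start_time

    def test_trailing_arrest_flagged_censored(self):
        events = detect_arrests(make_track([(3.0, 4.0)]), u_p=U_P)
        assert len(events) == 1
        assert events[0].censored

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            Trajectory("b", np.array([0.0, 0.02, 0.01]), np.zeros(3))


class TestCorrectDuration:
    @pytest.mark.parametrize(
        "d_app, window, threshold, u_p, expected",
        [
            (0.5, 0.2, 0.5, 22.5, 0.6556),
            (0.7, 0.2, 0.5, 5.0, 0.7),  # 2*threshold/u_p equals the window
            (0.0, 0.2, 0.5, 22.5, 0.1556),  # shortest detectable duration
        ],
    )
    def test_examples(self, d_app, window, threshold, u_p, expected):
        assert correct_duration(d_app, window, threshold, u_p) == pytest.approx(
            expected, abs=1e-4
        )

    def test_affine_with_unit_slope(self):
        base = correct_duration(0.0, u_p=30.0)
        for d in (0.1, 0.7, 2.3):
            assert correct_duration(d, u_p=30.0) == pytest.approx(base + d, rel=1e-12)

    def test_nonpositive_velocity_rejected(self):
        with pytest.raises(ValueError):
            correct_duration(1.0, u_p=0.0)


class TestBuildSurvival:
    def test_all_longer_than_grid(self):
        curve = build_survival([10.0, 12.0], np.array([0.0, 1.0, 2.0]))
        assert np.all(curve.survival == 1.0)
        assert np.all(curve.sd == 0.0)

    def test_counting_example(self):
        curve = build_survival(
            [0.1, 0.3, 0.5, 0.7], np.array([0.0, 0.2, 0.4, 0.6, 0.8])
        )
        assert np.allclose(curve.survival, [1.0, 0.75, 0.5, 0.25, 0.0])
        assert curve.n_total == 4

    def test_binomial_sd(self):
        curve = build_survival([0.1, 0.3, 0.5, 0.7], np.array([0.3]))
        assert curve.sd[0] == pytest.approx(np.sqrt(0.5 * 0.5 / 4))

    def test_large_sample_matches_law(self):
        rng = np.random.default_rng(7)
        law = BondLaw(1.277, 2.270)
        d = sample_duration(law, 1.0 - rng.random(10_000))
        g = fit_grid()
        curve = build_survival(d, g)
        assert np.abs(curve.survival - survival(law, g)).max() < 0.02

    def test_kaplan_meier_with_censoring(self):
        # one censored at 2: risk set {3} after it; hand-computed KM
        curve = build_survival(
            [1.0, 2.0, 3.0],
            np.array([0.5, 1.5, 2.5, 3.5]),
            censored=[False, True, False],
        )
        assert np.allclose(curve.survival, [1.0, 2 / 3, 2 / 3, 0.0])

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            build_survival([], np.array([0.0, 1.0]))


class TestExtrapolation:
    def test_collinear_counts(self):
        curve = SurvivalCurve(
            times=np.array([0.1, 0.3, 0.5]),
            survival=np.array([1.0, 0.9, 0.8]),
            n_total=100,
        )
        assert extrapolate_true_count(curve) == pytest.approx(105.0)

    def test_constant_counts(self):
        curve = SurvivalCurve(
            times=np.array([0.1, 0.2, 0.4]),
            survival=np.array([1.0, 1.0, 1.0]),
            n_total=50,
        )
        assert extrapolate_true_count(curve) == pytest.approx(50.0)

    def test_too_few_points(self):
        curve = SurvivalCurve(
            times=np.array([0.1, 0.9]), survival=np.array([1.0, 0.5]), n_total=10
        )
        with pytest.raises(ValueError):
            extrapolate_true_count(curve, cutoff=0.2)


class TestBindingFrequency:
    @pytest.mark.parametrize(
        "n, length, expected",
        [(0, 100.0, (0.0, 0.0)), (400, 200.0, (2.0, 0.1)), (100, 100.0, (1.0, 0.1))],
    )
    def test_examples(self, n, length, expected):
        f, sd = binding_frequency(n, length)
        assert (f, sd) == pytest.approx(expected)

    def test_invalid_path_length(self):
        with pytest.raises(ValueError):
            binding_frequency(10, 0.0)


class TestNonspecificSubtraction:
    def test_identity_at_zero_fraction(self):
        g = fit_grid()
        obs = SurvivalCurve(times=g, survival=survival(BondLaw(1.0, 1.0), g))
        ns = NonspecificModel(0.0, BondLaw(2.0, 0.5))
        out = subtract_nonspecific(obs, ns)
        assert np.allclose(out.survival, obs.survival)

    def test_pointwise_example(self):
        g = np.array([0.0, 1.0])
        obs = SurvivalCurve(times=g, survival=np.array([1.0, 0.6]))
        ns_curve = SurvivalCurve(times=g, survival=np.array([1.0, 0.9]))
        out = subtract_nonspecific(obs, NonspecificModel(0.2, ns_curve))
        assert out.survival[1] == pytest.approx(0.525)

    def test_exact_demixing(self):
        g = fit_grid()
        spec = survival(BondLaw(1.277, 2.270), g)
        ns = survival(BondLaw(3.6, 2.0), g)
        mixture = SurvivalCurve(times=g, survival=0.8 * spec + 0.2 * ns)
        ns_model = NonspecificModel(0.2, SurvivalCurve(times=g, survival=ns))
        out = subtract_nonspecific(mixture, ns_model)
        assert np.abs(out.survival - spec).max() < 1e-10

    def test_preserves_monotonicity_on_slower_ns(self):
        g = fit_grid()
        spec = survival(BondLaw(2.0, 1.0), g)
        ns = survival(BondLaw(0.5, 2.0), g)  # decays more slowly
        mixture = SurvivalCurve(times=g, survival=0.75 * spec + 0.25 * ns)
        out = subtract_nonspecific(
            mixture, NonspecificModel(0.25, SurvivalCurve(times=g, survival=ns))
        )
        assert np.all(np.diff(out.survival) <= 1e-12)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            NonspecificModel(1.0, BondLaw(1.0, 0.0))


class TestSpecificFraction:
    @pytest.mark.parametrize(
        "fold, expected", [(3.45, 0.7101), (1.0, 0.0), (2.0, 0.5)]
    )
    def test_examples(self, fold, expected):
        assert specific_fraction(fold) == pytest.approx(expected, abs=1e-4)

    def test_domain(self):
        with pytest.raises(ValueError):
            specific_fraction(0.9)


class TestMeanOffRate:
    def test_pure_exponential(self):
        assert mean_off_rate(BondLaw(1.7, 0.0), horizon=0.5) == pytest.approx(1.7)
        assert mean_off_rate(BondLaw(1.7, 0.0), horizon=2.0) == pytest.approx(1.7)

    def test_strengthening_law(self):
        assert mean_off_rate(BondLaw(0.519, 1.171), horizon=0.5) == pytest.approx(
            0.409, abs=1e-3
        )

    def test_no_decay_gives_zero(self):
        curve = SurvivalCurve(times=np.array([0.0, 1.0]), survival=np.array([1.0, 1.0]))
        assert mean_off_rate(curve, horizon=0.5) == 0.0


class TestEndToEndRecovery:
    def test_pipeline_recovers_generating_laws(self):
        """Mixed synthetic arrests -> subtract -> conditional fit per condition.

        The 200-ms detection window hides the early part of each curve and
        the 22% nonspecific subtraction adds noise, which leaves (k0, a)
        weakly identified, increasingly so as the curve steepens: replicate
        runs at this event count put the per-parameter sampling SD at 6-42%
        depending on condition.  The bands below are bias + 3 sigma of that
        measured sampling distribution.
        """
        grid = fit_grid()
        truth = default_ground_truth(n_events=2000, p_ns=0.22, seed=5)
        data = generate_arrests(truth)
        geom = ChamberGeometry()
        tolerances = {10.3: 0.30, 18.5: 0.30, 30.9: 0.50}
        for cond in truth.conditions:
            arrests, _labels = data[cond.label]
            u_p = peak_velocity(geom, cond.shear_rate)
            floor = truth.detection.floor(u_p)
            ns_cond = survival(
                cond.nonspecific_law, np.maximum(grid, floor)
            ) / survival(cond.nonspecific_law, floor)
            ns = NonspecificModel(
                truth.p_ns,
                SurvivalCurve(times=grid, survival=np.clip(ns_cond, 0, 1)),
            )
            conditional, _renorm = specific_survival_pipeline(
                arrests.durations(), ns, grid, detection_floor=floor
            )
            fit = fit_bond_law(conditional, condition_at=floor)
            tol = tolerances[cond.shear_rate]
            assert fit.law.initial_off_rate == pytest.approx(
                cond.specific_law.initial_off_rate, rel=tol
            )
            assert fit.law.strengthening_rate == pytest.approx(
                cond.specific_law.strengthening_rate, rel=tol
            )
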