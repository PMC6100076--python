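import math

import numpy as np
import pandas as pd
import pytest

import oracles
from hsvr_qsar.svr_engine import MemberSVR
from hsvr_qsar.validation import (
    CriteriaThresholds,
    MetricReport,
    basic_metrics,
    check_criteria,
    combine_rm2,
    determination_coefficient,
    evaluate_predictions,
    external_metrics,
    origin_stats,
    residual_analysis,
    roy_metrics,
    y_scramble,
)


def random_pair(rng, n=10):
    y = rng.normal(size=n)
    yhat = y + rng.normal(scale=0.5, size=n)
    return y, yhat


class TestBasicMetrics:
    def test_perfect_prediction(self):
        y = np.array([0.3, 1.2, -0.5, 2.0])
        rep = basic_metrics(y, y.copy())
        assert rep.r2 == pytest.approx(1.0)
        assert rep.rmse == 0.0 and rep.mae == 0.0 and rep.delta_max == 0.0

    def test_direct_arithmetic(self):
        rep = basic_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert np.allclose(rep.residuals, [0.0, 0.0, -1.0])
        assert rep.mae == pytest.approx(1.0 / 3.0)
        assert rep.rmse == pytest.approx(1.0 / math.sqrt(3.0))
        assert rep.delta_max == pytest.approx(1.0)

    def test_rmse_at_least_mae(self, rng):
        for _ in range(20):
            y, yhat = random_pair(rng)
            rep = basic_metrics(y, yhat)
            assert rep.rmse >= rep.mae >= 0.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            basic_metrics([1.0, 2.0], [1.0, 2.0, 3.0])


class TestOriginAndRoy:
    def test_identity_gives_unit_slope(self):
        y = [1.0, 2.0, 3.0, 4.0]
        ro2, ro2p, k = origin_stats(y, y)
        assert (ro2, ro2p, k) == pytest.approx((1.0, 1.0, 1.0))

    def test_doubling_forces_slope_two(self):
        y = np.array([1.0, 2.0, 3.0])
        _, _, k = origin_stats(y, 2.0 * y)
        assert k == pytest.approx(2.0)

    def test_swap_symmetry(self, rng):
        """Swapping observed and predicted exchanges the two
        through-origin coefficients."""
        y, yhat = random_pair(rng, n=8)
        ro2, ro2p, _ = origin_stats(y, yhat)
        ro2_s, ro2p_s, _ = origin_stats(yhat, y)
        assert ro2 == pytest.approx(ro2p_s, abs=1e-12)
        assert ro2p == pytest.approx(ro2_s, abs=1e-12)

    @pytest.mark.parametrize(
        "rm2, rm2_prime, expected_mean, expected_delta",
        [
            (0.90, 0.85, 0.88, 0.05),  # training-context worked example
            (0.72, 0.60, 0.66, 0.12),  # test-context worked example
            (0.5, 0.5, 0.50, 0.00),
        ],
    )
    def test_rm2_combinations(self, rm2, rm2_prime, expected_mean, expected_delta):
        mean, delta = combine_rm2(rm2, rm2_prime)
        assert round(mean, 2) == pytest.approx(expected_mean)
        assert round(delta, 2) == pytest.approx(expected_delta)

    def test_rm2_never_exceeds_r2(self, rng):
        """The modified coefficients carry a multiplier <= 1 in both
        variants."""
        for variant in ("sqrt", "printed"):
            for _ in range(20):
                y, yhat = random_pair(rng)
                r2 = determination_coefficient(np.asarray(y), np.asarray(yhat))
                ro2, ro2p, _ = origin_stats(y, yhat)
                rm2, rm2p, _, _ = roy_metrics(r2, ro2, ro2p, variant=variant)
                if r2 > 0:
                    assert rm2 <= r2 + 1e-12 and rm2p <= r2 + 1e-12


class TestExternalMetrics:
    def test_perfect_agreement(self, rng):
        y = rng.normal(size=10)
        out = external_metrics(y, y.copy(), rng.normal(size=20))
        assert out == pytest.approx((1.0, 1.0, 1.0, 1.0))

    def test_mean_prediction_zeroes_qf2(self, rng):
        y = rng.normal(size=12)
        const = np.full(12, y.mean())
        _, qf2, _, _ = external_metrics(y, const, rng.normal(size=20))
        assert qf2 == pytest.approx(0.0, abs=1e-12)

    def test_ccc_strictly_below_one_under_scaling(self, rng):
        y = rng.normal(size=15) + 1.0
        base = oracles.ccc(list(y), list(y))
        assert base == pytest.approx(1.0)
        for c in (0.5, 0.9, 1.1, 2.0):
            _, _, _, scaled = external_metrics(y, c * y, rng.normal(size=10))
            assert scaled < 1.0


class TestOracleEquivalence:
    def test_all_coefficients_match_brute_force(self, rng):
        """Dual-route check: every statistic agrees with an independent
        loop-based implementation of the printed formulas to 1e-12."""
        for _ in range(100):
            n_ext, n_tr = int(rng.integers(5, 30)), int(rng.integers(5, 40))
            y = rng.normal(size=n_ext)
            yhat = y + rng.normal(scale=rng.uniform(0.05, 1.0), size=n_ext)
            ytr = rng.normal(size=n_tr)
            rep = evaluate_predictions(y, yhat, context="external", observed_train=ytr)

            yl, pl, tl = list(y), list(yhat), list(ytr)
            assert rep.r2 == pytest.approx(oracles.det_coeff(yl, pl), abs=1e-12)
            assert rep.rmse == pytest.approx(oracles.rmse(yl, pl), abs=1e-12)
            assert rep.mae == pytest.approx(oracles.mae(yl, pl), abs=1e-12)
            assert rep.s == pytest.approx(oracles.residual_sd(yl, pl), abs=1e-12)
            assert rep.delta_max == pytest.approx(oracles.max_abs_residual(yl, pl), abs=1e-12)
            o_ro2, o_ro2p, o_k = oracles.origin_stats(yl, pl)
            assert rep.ro2 == pytest.approx(o_ro2, abs=1e-12)
            assert rep.ro2_prime == pytest.approx(o_ro2p, abs=1e-12)
            assert rep.k == pytest.approx(o_k, abs=1e-12)
            assert rep.rm2 == pytest.approx(oracles.roy_rm2(rep.r2, rep.ro2), abs=1e-12)
            assert rep.qf1 == pytest.approx(oracles.qf1(yl, pl, tl), abs=1e-12)
            assert rep.qf2 == pytest.approx(oracles.qf2(yl, pl), abs=1e-12)
            assert rep.qf3 == pytest.approx(oracles.qf3(yl, pl, tl), abs=1e-12)
            assert rep.ccc == pytest.approx(oracles.ccc(yl, pl), abs=1e-12)

    def test_printed_eq4_centers_on_predicted_mean(self, rng):
        y, yhat = random_pair(rng, n=12)
        alt = determination_coefficient(np.asarray(y), np.asarray(yhat), center="predicted")
        assert alt == pytest.approx(
            oracles.det_coeff(list(y), list(yhat), center_observed=False), abs=1e-12
        )


def _report(context="training", **overrides) -> MetricReport:
    base = dict(
        context=context,
        n=50,
        r2=0.96,
        residuals=np.zeros(2),
        rmse=0.1,
        mae=0.06,
        s=0.1,
        delta_max=0.45,
        mean_residual=-0.02,
        q2_cv=0.94,
        ro2=0.95,
        ro2_prime=0.94,
        k=1.03,
        rm2=0.90,
        rm2_prime=0.85,
        rm2_mean=0.88,
        delta_rm2=0.05,
    )
    base.update(overrides)
    return MetricReport(**base)


class TestCriteria:
    def test_published_column_pattern(self):
        """The printed training/test validation columns reproduce the
        published pass / not-applicable pattern."""
        train = _report()
        test = _report(
            context="external", n=13, r2=0.83, q2_cv=float("nan"),
            ro2=0.77, ro2_prime=0.52, k=1.05, rm2=0.72, rm2_prime=0.60,
            rm2_mean=0.66, delta_rm2=0.12, qf1=0.80, qf2=0.80, qf3=0.80, ccc=0.87,
        )
        verdict = check_criteria(train, test)
        assert verdict.overall_pass
        assert verdict.statuses["ccc_floor"] == ("not_applicable", "pass")
        assert verdict.statuses["r2_q2cv_gap"] == ("pass", "not_applicable")
        for name, (tr, te) in verdict.statuses.items():
            if name == "ccc_floor":
                continue
            assert tr == "pass"
            if name != "r2_q2cv_gap":
                assert te == "pass"

    def test_slope_outside_band_fails(self):
        verdict = check_criteria(_report(k=1.20), None)
        assert verdict.statuses["origin_regression"][0] == "fail"
        assert not verdict.overall_pass

    def test_monotone_in_each_coefficient(self):
        """Improving any single coefficient never flips pass to fail."""
        base = _report()
        verdict0 = check_criteria(base, None)
        assert verdict0.overall_pass
        for field, better in [
            ("r2", 0.97), ("q2_cv", 0.95), ("ro2", 0.955), ("rm2", 0.92),
            ("rm2_mean", 0.90),
        ]:
            verdict = check_criteria(_report(**{field: better}), None)
            assert verdict.overall_pass, field

    def test_nan_inputs_become_not_applicable(self):
        verdict = check_criteria(_report(ro2=float("nan")), None)
        assert verdict.statuses["origin_regression"][0] == "not_applicable"
        assert verdict.statuses["origin_symmetry"][0] == "not_applicable"

    def test_thresholds_are_strict_inequalities_where_printed(self):
        # delta_rm2 exactly at 0.20 fails the "< 0.20" requirement
        verdict = check_criteria(_report(delta_rm2=0.20), None)
        assert verdict.statuses["rm2_mean_and_delta"][0] == "fail"


class TestScrambleAndResiduals:
    def test_identity_permutation_recovers_unscrambled_r2(self, toy_table):
        X, y = toy_table
        model = MemberSVR(C=10.0, gamma=0.5, epsilon=0.01)
        model.fit(X, y)
        r2 = determination_coefficient(y.to_numpy(), model.predict(X))
        report = y_scramble(
            X, y,
            model_factory=lambda: MemberSVR(C=10.0, gamma=0.5, epsilon=0.01),
            scrambles=1,
            seed=0,
            _permutations=[np.arange(len(y))],
        )
        assert report.rs2_values[0] == pytest.approx(r2, abs=1e-12)

    def test_strong_signal_has_chance_correlation_gap(self, toy_table):
        """Scrambled refits lose the signal: mean rs^2 collapses while
        the unscrambled fit stays strong."""
        X, y = toy_table
        factory = lambda: MemberSVR(C=10.0, gamma=0.5, epsilon=0.01)
        model = factory().fit(X, y)
        r2 = determination_coefficient(y.to_numpy(), model.predict(X))
        report = y_scramble(X, y, model_factory=factory, scrambles=10, seed=3)
        assert r2 > 0.8
        assert report.mean_rs2 < r2 - 0.4
        assert report.count == 10
        assert report.mean_rs2 == pytest.approx(np.mean(report.rs2_values))

    def test_constant_bias_shows_in_mean_residual(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        table, mean_res = residual_analysis(y, y - 0.25)
        assert mean_res == pytest.approx(0.25)
        assert np.allclose(table["residual"], 0.25)
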