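import numpy as np
import pytest

from th17translate.io_formats import ValidationError
from th17translate.pharmacodynamics import (
    efficacy_profile,
    exposure_at,
    exposure_response_points,
    fit_hill,
    inhibition_at,
    percent_inhibition,
)
from th17translate.synthetic_data import GeneratorConfig, HillTruth, gen_pd_table

from .conftest import make_pd_table


def hill(c, i_max, ec50, h):
    return i_max * c**h / (ec50**h + c**h)


class TestPercentInhibition:
    def test_treated_equals_negative_control_is_100(self):
        t = make_pd_table({"e": {"negative_control": 10, "positive_control": 110, "treated:d": 10}})
        assert percent_inhibition(t, "e", "treated:d").percent_inhibition == pytest.approx(100.0)

    def test_treated_equals_positive_control_is_0(self):
        t = make_pd_table({"e": {"negative_control": 10, "positive_control": 110, "treated:d": 110}})
        assert percent_inhibition(t, "e", "treated:d").percent_inhibition == pytest.approx(0.0)

    def test_midpoint_is_50(self):
        t = make_pd_table({"e": {"negative_control": 10, "positive_control": 110, "treated:d": 60}})
        res = percent_inhibition(t, "e", "treated:d")
        assert res.percent_inhibition == pytest.approx(50.0)
        assert res.K1 == pytest.approx(100.0)
        assert res.Y == pytest.approx(50.0)

    def test_overshoot_beyond_100_representable(self):
        t = make_pd_table({"e": {"negative_control": 10, "positive_control": 110, "treated:d": 0}})
        assert percent_inhibition(t, "e", "treated:d").percent_inhibition == pytest.approx(110.0)

    def test_k1_zero_rejected(self):
        t = make_pd_table({"e": {"negative_control": 10, "positive_control": 10, "treated:d": 5}})
        with pytest.raises(ValidationError):
            percent_inhibition(t, "e", "treated:d")

    def test_missing_group_rejected(self):
        t = make_pd_table({"e": {"negative_control": 10, "positive_control": 110}})
        with pytest.raises(ValidationError):
            percent_inhibition(t, "e", "treated:nope")

    def test_affine_invariance(self):
        base = {"negative_control": 10.0, "positive_control": 110.0, "treated:d": 35.0}
        t1 = make_pd_table({"e": base})
        a, b = 3.7, 12.0
        t2 = make_pd_table({"e": {g: a * v + b for g, v in base.items()}})
        r1 = percent_inhibition(t1, "e", "treated:d").percent_inhibition
        r2 = percent_inhibition(t2, "e", "treated:d").percent_inhibition
        assert r1 == pytest.approx(r2, abs=1e-9)


class TestFitHill:
    def test_noise_free_recovery(self):
        c = np.array([10, 30, 60, 120, 240, 480, 1000, 2000], dtype=float)
        y = hill(c, 100, 120, 1.5)
        fit = fit_hill(list(zip(c, y)))
        assert fit.ec50 == pytest.approx(120, rel=1e-6)
        assert fit.h == pytest.approx(1.5, rel=1e-6)

    @pytest.mark.parametrize("ec50", [10.0, 120.0, 1000.0])
    @pytest.mark.parametrize("h", [0.5, 1.0, 2.0])
    def test_grid_recovery(self, ec50, h):
        c = ec50 * np.logspace(-1.5, 1.5, 9)
        y = hill(c, 100, ec50, h)
        fit = fit_hill(list(zip(c, y)))
        assert fit.ec50 == pytest.approx(ec50, rel=1e-6)
        assert fit.h == pytest.approx(h, rel=1e-6)

    def test_noisy_median_recovery(self):
        c = np.array([10, 30, 60, 120, 240, 480, 1000, 2000], dtype=float)
        truth = hill(c, 100, 120, 1.5)
        rng = np.random.default_rng(19)
        estimates = []
        for _ in range(100):
            y = truth + rng.normal(0, 5, size=len(c))
            estimates.append(fit_hill(list(zip(c, y))).ec50)
        assert np.median(estimates) == pytest.approx(120, rel=0.10)

    def test_free_imax(self):
        c = np.array([10, 30, 100, 300, 1000], dtype=float)
        y = hill(c, 80, 100, 1.0)
        fit = fit_hill(list(zip(c, y)), fix_imax=False)
        assert fit.i_max == pytest.approx(80, rel=1e-4)
        assert fit.ec50 == pytest.approx(100, rel=1e-4)

    def test_single_exposure_rejected(self):
        with pytest.raises(ValidationError):
            fit_hill([(100.0, 10.0), (100.0, 12.0)])

    def test_all_equal_inhibitions_rejected(self):
        with pytest.raises(ValidationError):
            fit_hill([(10.0, 50.0), (100.0, 50.0), (1000.0, 50.0)])

    def test_fitted_curve_monotone(self):
        c = np.array([10, 50, 120, 500, 2000], dtype=float)
        y = hill(c, 100, 120, 1.5)
        fit = fit_hill(list(zip(c, y)))
        grid = np.logspace(0, 4, 50)
        preds = [inhibition_at(fit, g) for g in grid]
        assert all(a <= b + 1e-12 for a, b in zip(preds, preds[1:]))


class TestInverse:
    @pytest.fixture
    def fit(self):
        c = np.array([10, 30, 60, 120, 240, 480, 1000, 2000], dtype=float)
        return fit_hill(list(zip(c, hill(c, 100, 120, 1.5))))

    def test_ec50_gives_half_max(self, fit):
        assert inhibition_at(fit, fit.ec50) == pytest.approx(fit.i_max / 2)

    def test_inverse_identity(self, fit):
        for c in (5.0, 120.0, 777.0):
            assert exposure_at(fit, inhibition_at(fit, c)) == pytest.approx(c, abs=1e-9, rel=1e-9)

    def test_inverse_out_of_range_rejected(self, fit):
        with pytest.raises(ValidationError):
            exposure_at(fit, 100.0)
        with pytest.raises(ValidationError):
            exposure_at(fit, 0.0)

    def test_left_shifted_pair_closed_form(self):
        # two curves, EC50 ratio 1:5 with h = 1.5; evaluate curve B at
        # curve A's 90%-inhibition exposure and compare with the closed form
        h, ec50_a, ec50_b = 1.5, 100.0, 500.0
        c = np.logspace(0.5, 4, 10)
        fit_a = fit_hill(list(zip(c, hill(c, 100, ec50_a, h))))
        fit_b = fit_hill(list(zip(c, hill(c, 100, ec50_b, h))))
        c90 = exposure_at(fit_a, 90.0)
        expected = hill(ec50_a * 9 ** (1 / h), 100, ec50_b, h)  # closed-form oracle
        assert c90 == pytest.approx(ec50_a * 9 ** (1 / h), rel=1e-6)
        assert inhibition_at(fit_b, c90) == pytest.approx(expected, rel=1e-6)


class TestEfficacyProfile:
    def test_matrix_shape(self):
        cfg = GeneratorConfig(seed=3)
        table, _ = gen_pd_table(cfg)
        profile = efficacy_profile(table)
        assert profile.raw.shape == (len(cfg.pd_endpoints), len(cfg.pd_doses))

    def test_treatment_identical_to_positive_control_all_zero(self):
        t = make_pd_table(
            {
                "e1": {"negative_control": 10, "positive_control": 110, "treated:d": 110},
                "e2": {"negative_control": 5, "positive_control": 25, "treated:d": 25},
            }
        )
        profile = efficacy_profile(t)
        assert np.allclose(profile.raw.to_numpy(), 0.0)

    def test_display_floors_negative_raw_kept(self):
        t = make_pd_table({"e": {"negative_control": 10, "positive_control": 110, "treated:d": 150}})
        profile = efficacy_profile(t)
        assert profile.raw.loc["e", "treated:d"] == pytest.approx(-40.0)
        assert profile.display.loc["e", "treated:d"] == 0.0

    def test_planted_profile_ordering(self):
        # strong IL-17, moderate IL-22, untouched Th2 endpoint
        cfg = GeneratorConfig(
            seed=5,
            pd_endpoints=("IL-17", "IL-22", "eosinophils"),
            pd_hill_truth={"IL-17": HillTruth(ec50=120.0, h=1.5), "IL-22": HillTruth(ec50=600.0, h=1.5)},
        )
        table, truth = gen_pd_table(cfg)
        profile = efficacy_profile(table)
        for dose in cfg.pd_doses:
            col = f"treated:{dose}"
            assert profile.raw.loc["IL-17", col] > profile.raw.loc["IL-22", col]
            assert profile.raw.loc["IL-22", col] > profile.raw.loc["eosinophils", col] - 1e-9

    def test_per_cell_errors_do_not_kill_run(self):
        t = make_pd_table(
            {
                "ok": {"negative_control": 10, "positive_control": 110, "treated:d": 60},
                "flat": {"negative_control": 10, "positive_control": 10, "treated:d": 10},
            }
        )
        profile = efficacy_profile(t)
        assert profile.raw.loc["ok", "treated:d"] == pytest.approx(50.0)
        assert np.isnan(profile.raw.loc["flat", "treated:d"])
        assert len(profile.errors) == 1


class TestExposureResponseIntegration:
    def test_zero_noise_recovers_truth_curve(self):
        cfg = GeneratorConfig(seed=7, pd_noise_sd=0.0)
        table, truth = gen_pd_table(cfg)
        points = exposure_response_points(table, "IL-17")
        for c, inh in points:
            assert inh == pytest.approx(truth["hill"]["IL-17"].inhibition(c), abs=1e-9)
        fit = fit_hill(points)
        assert fit.ec50 == pytest.approx(120.0, rel=1e-5)
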