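import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import chromaqbd as cq
from chromaqbd import CMADefinition, MCConfig
from chromaqbd.design_space import GradientProgram, _point_rng
from chromaqbd.simulate import default_bbd_specs


@pytest.fixture(scope="module")
def cma_fits(bbd_table, separation_cmas):
    return cq.fit_cma_surfaces(bbd_table, separation_cmas)


class TestGrid:
    def test_default_knowledge_space_grid_has_4851_points(self):
        grid = cq.make_grid(default_bbd_specs())
        assert len(grid) == 21 * 21 * 11

    def test_two_level_grid_is_just_endpoints(self):
        spec = cq.FactorSpec("x", "X", 3.0, 5.0, grid_levels=2)
        assert cq.make_grid([spec])["X"].tolist() == [3.0, 5.0]

    def test_grid_spacing_even_and_inclusive(self):
        spec = cq.FactorSpec("acn", "A", 37.0, 41.0, grid_levels=21)
        levels = np.unique(cq.make_grid([spec])["A"])
        assert levels[0] == 37.0 and levels[-1] == 41.0
        assert np.allclose(np.diff(levels), 0.2)


class TestEvaluateCMA:
    def test_row_arithmetic_on_measured_times(self, bbd_table, screening_table):
        s1 = CMADefinition("s1", "t_b_imp2", "t_e_bup")
        run5 = bbd_table.data.loc[5]
        assert cq.evaluate_cma(run5, s1) == pytest.approx(0.13)
        run1 = screening_table.data.loc[1]
        assert cq.evaluate_cma(run1, s1) == pytest.approx(-0.08)  # overlapping peaks

    def test_equal_times_satisfy_zero_threshold(self):
        s = cq.evaluate_cma({"a": 5.0, "b": 5.0}, CMADefinition("s", "a", "b"))
        assert s == 0.0 and s >= 0.0

    def test_missing_response_reported(self):
        with pytest.raises(KeyError, match="s1"):
            cq.evaluate_cma({"a": 1.0}, CMADefinition("s1", "a", "b"))

    def test_parse_cli_syntax(self):
        cma = CMADefinition.parse("s1:t_b_imp2-t_e_bup>=0.1")
        assert cma == CMADefinition("s1", "t_b_imp2", "t_e_bup", 0.1)


class TestMCProbability:
    def test_degenerate_fit_gives_exact_probability_one(self, bbd_table):
        fit = cq.fit_ols(bbd_table, "t_e_bup", "quadratic")
        sure = dataclasses.replace(
            fit, cov_beta=np.zeros_like(fit.cov_beta), sigma2=0.0
        )
        shifted = dataclasses.replace(sure, beta=sure.beta + np.eye(10)[0] * 100)
        cmas = [CMADefinition("gap", "hi", "lo")]
        pi = cq.mc_predictive_probability(
            {"hi": shifted, "lo": sure}, cmas, [0.0, 0.0, 0.0], MCConfig(iterations=500, seed=0)
        )
        assert pi == 1.0

    def test_matches_gaussian_closed_form_in_fixed_sigma_limit(self, cma_fits):
        """With sigma fixed, the sampled criterion is exactly normal; pi must
        agree with Phi(mu/sd) within Monte Carlo error."""
        fit = cma_fits["s1"]
        cma = [CMADefinition("s1", "t_b_imp2", "t_e_bup")]
        config = MCConfig(
            iterations=40000, seed=4, sample_sigma=False, include_observation_noise=True
        )
        for point in ([-0.75, 0.0, 0.5], [1.0, -1.0, 0.0], [0.3, 0.8, -0.4]):
            mean, var_mean, var_new = fit.predict_mean(point)
            expected = stats.norm.cdf(mean / np.sqrt(var_new))
            pi = cq.mc_predictive_probability({"s1": fit}, cma, point, config)
            tol = 3.0 * np.sqrt(expected * (1 - expected) / config.iterations) + 1e-3
            assert pi == pytest.approx(expected, abs=tol)

    def test_reproducible_under_fixed_seed(self, cma_fits, separation_cmas):
        cfg = MCConfig(iterations=2000, seed=9)
        a = cq.mc_predictive_probability(cma_fits, separation_cmas, [0.1, 0.2, 0.3], cfg)
        b = cq.mc_predictive_probability(cma_fits, separation_cmas, [0.1, 0.2, 0.3], cfg)
        assert a == b

    def test_raising_minuend_intercept_never_lowers_pi(self, cma_fits, separation_cmas):
        cfg = MCConfig(iterations=3000, seed=2)
        fits_hi = dict(cma_fits)
        boosted = dataclasses.replace(
            cma_fits["s1"], beta=cma_fits["s1"].beta + np.eye(10)[0] * 0.5
        )
        fits_hi["s1"] = boosted
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.uniform(-1, 1, 3)
            lo = cq.mc_predictive_probability(cma_fits, separation_cmas, x, cfg)
            hi = cq.mc_predictive_probability(fits_hi, separation_cmas, x, cfg)
            assert hi >= lo

    def test_difference_mode_uses_response_models(self, bbd_table, separation_cmas):
        fits = {
            nm: cq.fit_ols(bbd_table, nm, "quadratic")
            for nm in bbd_table.response_names
        }
        cfg = MCConfig(iterations=2000, seed=5, cma_mode="difference")
        pi = cq.mc_predictive_probability(fits, separation_cmas, [-0.75, 0, 0.5], cfg)
        assert 0.0 < pi < 1.0
        joint = dataclasses.replace(cfg, joint_across_responses=True)
        pj = cq.mc_predictive_probability(fits, separation_cmas, [-0.75, 0, 0.5], joint)
        # restoring the within-run error correlation tightens the criterion
        assert pj > pi

    def test_missing_models_reported(self, separation_cmas):
        with pytest.raises(KeyError, match="t_b_imp2"):
            cq.mc_predictive_probability({}, separation_cmas, [0, 0, 0], MCConfig(iterations=100))

    def test_tiny_iteration_count_warns(self):
        with pytest.warns(UserWarning, match="Monte Carlo"):
            MCConfig(iterations=10)


@pytest.fixture(scope="module")
def small_result(cma_fits, separation_cmas):
    specs = [dataclasses.replace(s, grid_levels=5) for s in default_bbd_specs()]
    return cq.compute_design_space(
        cma_fits,
        separation_cmas,
        specs,
        config=MCConfig(iterations=1500, seed=3),
        working_point=[37.5, 45.0, 10.0],
    )


class TestDesignSpace:
    def test_zero_threshold_accepts_everything(self, small_result):
        relaxed = dataclasses.replace(small_result, threshold_pi=0.0)
        assert relaxed.mask.all()

    def test_masks_nest_with_threshold(self, small_result):
        strict = dataclasses.replace(small_result, threshold_pi=0.95)
        loose = dataclasses.replace(small_result, threshold_pi=0.85)
        assert np.all(strict.mask <= loose.mask)

    def test_pi_independent_of_grid_order(self, cma_fits, separation_cmas):
        spec = [dataclasses.replace(s, grid_levels=3) for s in default_bbd_specs()]
        cfg = MCConfig(iterations=1000, seed=6)
        full = cq.compute_design_space(cma_fits, separation_cmas, spec, config=cfg)
        again = cq.compute_design_space(cma_fits, separation_cmas, spec, config=cfg)
        assert np.array_equal(full.pi, again.pi)

    def test_summary_reports_bounding_box_and_working_point(self, small_result):
        summary = small_result.summary()
        assert summary["n_grid"] == 125
        assert set(summary["bounding_box"]) == {"A", "B", "C"}
        assert summary["working_point_in_ds"] is True

    def test_empty_design_space_is_reported_not_raised(self, cma_fits, separation_cmas):
        hopeless = {
            "s1": dataclasses.replace(
                cma_fits["s1"], beta=cma_fits["s1"].beta - np.eye(10)[0] * 50
            ),
            "s2": cma_fits["s2"],
        }
        spec = [dataclasses.replace(s, grid_levels=2) for s in default_bbd_specs()]
        res = cq.compute_design_space(
            hopeless, separation_cmas, spec, config=MCConfig(iterations=500, seed=1)
        )
        assert res.summary()["n_in_ds"] == 0

    def test_slice_restricts_full_mask(self, small_result):
        sub = cq.slice_2d(small_result, "C", small_result.grid["C"].iloc[0])
        keep = np.isclose(small_result.grid["C"], small_result.grid["C"].iloc[0])
        assert len(sub.grid) == 25
        assert np.array_equal(sub.pi, small_result.pi[keep])
        assert np.array_equal(sub.mask, small_result.mask[keep])

    def test_slices_restack_to_full_result(self, small_result):
        pieces = [
            cq.slice_2d(small_result, "C", lv).pi
            for lv in np.unique(small_result.grid["C"])
        ]
        restacked = np.concatenate(pieces)
        assert sorted(restacked.tolist()) == sorted(small_result.pi.tolist())

    def test_off_grid_slice_value_snaps_with_warning(self, small_result):
        with pytest.warns(UserWarning, match="grid level"):
            sub = cq.slice_2d(small_result, "C", 8.1)
        assert len(sub.grid) == 25


class TestGradientProgram:
    def test_working_point_program_breakpoints(self):
        program = cq.working_point_to_gradient_program([37.5, 45.0, 10.0])
        assert program.timetable == (
            (0.0, 37.5),
            (10.0, 37.5),
            (17.0, 70.0),
            (21.0, 37.5),
            (23.0, 37.5),
        )
        assert program.total_time == 23.0

    def test_ramp_midpoint_is_composition_midpoint(self):
        program = cq.working_point_to_gradient_program([37.5, 45.0, 10.0])
        assert program.percent_at(13.5) == pytest.approx((37.5 + 70.0) / 2)

    def test_flat_program_when_start_equals_final(self):
        program = cq.working_point_to_gradient_program([50.0, 45.0, 10.0], final_pct=50.0)
        assert {pct for _, pct in program.timetable} == {50.0}

    def test_start_after_end_rejected(self):
        with pytest.raises(ValueError, match="precede"):
            cq.working_point_to_gradient_program([37.5, 45.0, 18.0])

    def test_invalid_timetables_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            GradientProgram(((0.0, 10.0), (0.0, 20.0)))
        with pytest.raises(ValueError, match="0, 100"):
            GradientProgram(((0.0, 10.0), (1.0, 120.0)))


def test_point_rng_streams_differ_by_index():
    a = _point_rng(7, 0).standard_normal(4)
    b = _point_rng(7, 1).standard_normal(4)
    c = _point_rng(7, 0).standard_normal(4)
    assert not np.allclose(a, b)
    assert np.allclose(a, c)
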