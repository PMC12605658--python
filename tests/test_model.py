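"""Design construction, carry-forward, mixed-model fitting and term selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cetraj.errors import CohortIntegrityError, SpecificationError
from cetraj.model import (
    PiecewiseLinearMixedModel,
    backward_select,
    build_design,
    carry_forward_covariates,
    fit_discontinuity_variant,
    fit_piecewise_lmm,
    time_columns,
)
from conftest import make_matched_table

ZERO_G = np.zeros((3, 3))


class TestDesignAlgebra:
    @given(st.lists(st.floats(-20, 20, allow_nan=False), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_piecewise_identities_exact(self, ts):
        t = np.array(ts)
        cols = time_columns(t, 1.0, 0.0, terms=("post2",), discontinuity=True)
        assert (cols["pre_time"] + cols["post_time"] == t).all()
        assert (cols["pre_time"] * cols["post_time"] == 0.0).all()
        assert ((cols["disc"] == 1.0) == (t >= 0)).all()
        assert (cols["post2"] == cols["post_time"] ** 2).all()

    def test_piecewise_split_examples(self):
        cols = time_columns(np.array([-3.0, 0.0, 5.0]), 0.0, 0.0, terms=("post2",))
        assert cols["pre_time"].tolist() == [-3.0, 0.0, 0.0]
        assert cols["post_time"].tolist() == [0.0, 0.0, 5.0]
        assert cols["post2"].tolist() == [0.0, 0.0, 25.0]

    def test_control_rows_have_zero_group_interactions(self):
        d = make_matched_table(coef={"const": 1.0})
        design, meta = build_design(d, "memory_z", terms=("post2",), discontinuity=True)
        ctl = design[design["group"] == 0]
        for col in ("group_pre", "group_post", "group_post2", "group_disc"):
            assert (ctl[col] == 0.0).all()

    def test_design_is_deterministic(self):
        d = make_matched_table(coef={"const": 0.5, "post_time": -0.02}, noise_sd=0.1, seed=5)
        a, _ = build_design(d, "memory_z", terms=("pre2", "post2"))
        b, _ = build_design(d.copy(), "memory_z", terms=("pre2", "post2"))
        assert a.to_csv() == b.to_csv()

    def test_unknown_term_rejected(self):
        d = make_matched_table(coef={"const": 1.0})
        with pytest.raises(SpecificationError):
            build_design(d, "memory_z", terms=("post4",))


class TestCarryForward:
    def _one(self, pairs, pid="p"):
        rows = []
        for i, (t, wealth) in enumerate(pairs):
            rows.append(dict(participant_id=pid, t=t, wave=i + 1, age=60.0 + t, wealth_z=wealth))
        return pd.DataFrame(rows)

    def test_frozen_at_origin_value(self):
        d = self._one([(-4, 1.0), (-2, 1.2), (0, 1.4), (2, 1.9)])
        out = carry_forward_covariates(d, columns=("wealth_z",))
        assert out["wealth_z"].tolist() == [1.0, 1.2, 1.4, 1.4]

    def test_frozen_at_last_pre_value_when_no_origin_row(self):
        d = self._one([(-4, 1.0), (-2, 1.2), (2, 1.9), (4, 2.5)])
        out = carry_forward_covariates(d, columns=("wealth_z",))
        assert out["wealth_z"].tolist() == [1.0, 1.2, 1.2, 1.2]

    def test_constant_covariate_unchanged(self):
        d = self._one([(-2, 0.7), (0, 0.7), (2, 0.7)])
        out = carry_forward_covariates(d, columns=("wealth_z",))
        assert out["wealth_z"].tolist() == [0.7, 0.7, 0.7]

    def test_pre_window_gap_filled_by_locf(self):
        d = self._one([(-4, 1.0), (-2, np.nan), (0, np.nan), (2, 9.9)])
        out = carry_forward_covariates(d, columns=("wealth_z",))
        assert out["wealth_z"].tolist() == [1.0, 1.0, 1.0, 1.0]

    def test_no_pre_origin_observation_errors_unless_fallback(self):
        d = self._one([(2, 1.9), (4, 2.5)])
        with pytest.raises(CohortIntegrityError, match="no observation at or before"):
            carry_forward_covariates(d, columns=("wealth_z",))
        out = carry_forward_covariates(d, columns=("wealth_z",), baseline_fallback=True)
        assert out["wealth_z"].tolist() == [1.9, 1.9]


class TestFitting:
    COEF = {
        "const": 0.4,
        "pre_time": -0.01,
        "post_time": -0.03,
        "group": 0.05,
        "group_pre": 0.004,
        "group_post": -0.012,
        "aget0": -0.02,
        "aget0_pre": 0.001,
        "aget0_post": -0.002,
        "wealth_z": 0.03,
        "cesd": -0.01,
        "female": 0.08,
    }

    def test_noise_free_interpolation_recovers_coefficients(self):
        """Exact data from known coefficients is reproduced to 1e-8."""
        d = make_matched_table(coef=self.COEF, n_per_cell=3)
        m = fit_piecewise_lmm(d, "memory_z", variance_components=(ZERO_G, 1.0))
        for name, value in self.COEF.items():
            assert m.fit_.params[name] == pytest.approx(value, abs=1e-8)

    def test_gls_matches_brute_force_oracle(self):
        """Fixed effects at known variance components equal dense-matrix GLS."""
        G = np.array([[0.4, 0.01, 0.02], [0.01, 0.01, 0.002], [0.02, 0.002, 0.02]])
        sigma2 = 0.3
        rng = np.random.default_rng(8)
        d = make_matched_table(coef=self.COEF, n_per_cell=3, noise_sd=0.0)
        # add correlated person noise consistent with (G, sigma2)
        design, meta = build_design(d, "memory_z")
        y = d["memory_z"].to_numpy().copy()
        for pid, idx in d.groupby("participant_id").groups.items():
            Z = design.loc[idx, ["const", "pre_time", "post_time"]].to_numpy()
            b = rng.multivariate_normal(np.zeros(3), G)
            y[np.asarray(idx)] += Z @ b + rng.normal(0, np.sqrt(sigma2), len(idx))
        d = d.assign(memory_z=y)

        m = fit_piecewise_lmm(d, "memory_z", variance_components=(G, sigma2))

        # oracle: dense per-person V, normal equations via explicit inverses
        design, meta = build_design(d, "memory_z")
        X = design[meta["columns"]].to_numpy()
        yv = design["memory_z"].to_numpy()
        A = np.zeros((X.shape[1], X.shape[1]))
        c = np.zeros(X.shape[1])
        for pid, idx in design.groupby("participant_id").groups.items():
            idx = np.asarray(idx)
            Z = design.loc[idx, ["const", "pre_time", "post_time"]].to_numpy()
            Vi = Z @ G @ Z.T + sigma2 * np.eye(len(idx))
            Wi = np.linalg.inv(Vi)
            A += X[idx].T @ Wi @ X[idx]
            c += X[idx].T @ Wi @ yv[idx]
        beta = np.linalg.solve(A, c)
        assert np.max(np.abs(m.fit_.params.to_numpy() - beta)) < 1e-6

    def test_ml_solution_is_gls_at_fitted_components(self, matched_axes):
        """The ML fixed effects satisfy the GLS normal equations at the fitted (G, s2)."""
        m = fit_piecewise_lmm(matched_axes, "memory_z")
        gls = fit_piecewise_lmm(
            matched_axes, "memory_z",
            variance_components=(m.fit_.re_cov.to_numpy(), m.fit_.resid_var),
        )
        assert np.max(np.abs(m.fit_.params.to_numpy() - gls.fit_.params.to_numpy())) < 2e-3

    def test_random_effect_correlations_bounded(self, fitted_small):
        rho = fitted_small.fit_.rho.to_numpy()
        assert np.all(np.abs(rho[np.isfinite(rho)]) <= 1.0 + 1e-12)
        g = fitted_small.fit_.re_cov.to_numpy()
        assert np.linalg.eigvalsh(g).min() > -1e-10

    def test_practice_effect_coefficient_recovered(self):
        """A known assessment-round (practice) effect is recovered exactly."""
        d = make_matched_table(coef=self.COEF, n_per_cell=3)
        rounds = d["assessment_round"].to_numpy() - 1.0
        d = d.assign(memory_z=d["memory_z"] + 0.04 * rounds)
        m = PiecewiseLinearMixedModel(
            outcome="memory_z", practice_effect=True, variance_components=(ZERO_G, 1.0)
        ).fit(d)
        assert m.fit_.params["assessment_round"] == pytest.approx(0.04, abs=1e-8)

    def test_degenerate_outcome_rejected(self):
        d = make_matched_table(coef={})
        with pytest.raises(SpecificationError):
            fit_piecewise_lmm(d, "memory_z")


class TestSelectionAndStep:
    def test_no_candidates_returns_base_model(self, matched_axes):
        model, trail = backward_select(matched_axes, "memory_z", candidates=())
        assert model.fit_.terms == []
        assert trail == []

    def test_strong_quadratic_retained_weak_dropped(self):
        rng_coef = dict(TestFitting.COEF)
        rng_coef["post2"] = -0.02  # strong curvature
        d = make_matched_table(coef=rng_coef, n_per_cell=4, noise_sd=0.3, seed=2)
        model, trail = backward_select(d, "memory_z", candidates=("post2",), variance_components=(ZERO_G, 0.09))
        assert "post2" in model.fit_.terms
        d0 = make_matched_table(coef=TestFitting.COEF, n_per_cell=4, noise_sd=0.3, seed=2)
        model0, trail0 = backward_select(d0, "memory_z", candidates=("post2",), variance_components=(ZERO_G, 0.09))
        assert model0.fit_.terms == []
        assert trail0[-1]["action"] == "drop"

    def test_hierarchy_cubic_tested_before_quadratic(self):
        d = make_matched_table(coef=TestFitting.COEF, n_per_cell=3, noise_sd=0.3, seed=4)
        model, trail = backward_select(
            d, "memory_z", candidates=("post2", "post3"), variance_components=(ZERO_G, 0.09)
        )
        first_tested = trail[0]["term"]
        assert first_tested == "post3"

    def test_likelihood_non_decrease_for_nested_models(self, matched_axes):
        base = fit_piecewise_lmm(matched_axes, "memory_z")
        bigger = fit_piecewise_lmm(matched_axes, "memory_z", terms=("post2",))
        assert bigger.fit_.llf >= base.fit_.llf - 1e-6

    def test_noise_free_step_recovered_exactly(self):
        coef = dict(TestFitting.COEF)
        coef["disc"] = -0.05
        coef["group_disc"] = 0.5
        d = make_matched_table(coef=coef, n_per_cell=3)
        m = fit_discontinuity_variant(d, "memory_z", variance_components=(ZERO_G, 1.0))
        assert m.fit_.params["group_disc"] == pytest.approx(0.5, abs=1e-8)
        assert m.fit_.params["disc"] == pytest.approx(-0.05, abs=1e-8)

    def test_step_model_requires_post_origin_rows(self):
        d = make_matched_table(coef={"const": 1.0}, t_grid=(-6, -4, -2))
        with pytest.raises(SpecificationError, match="t >= 0"):
            fit_discontinuity_variant(d, "memory_z", variance_components=(ZERO_G, 1.0))
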