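"""Trade-off fits, deviation decomposition, residualization, influence,
and seed-level screens."""

import warnings

import numpy as np
import pandas as pd
import pytest

from seedpareto.simulate import scenario_preset, generate_study
from seedpareto.tradeoff import (
    cooks_influence,
    deviation_decomposition,
    fit_tradeoff,
    residualize_on_mass,
    screen_seed_outcomes,
)

from conftest import make_lines
from _oracles import oracle_cooks, oracle_glmm_loglik, oracle_two_stage_slope


class TestFitTradeoff:
    def test_exact_linear_data_recovers_slope(self):
        pf = [0.1, 0.3, 0.5, 0.2, 0.4, 0.6]
        y = [2 + 3 * x for x in pf]
        lines = make_lines("AAABBB", pf, y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_tradeoff(lines)
        assert fit.slope == pytest.approx(3.0, abs=1e-8)
        assert fit.df == 1 and fit.p_value <= 0.05

    def test_constant_predictor_rejected(self):
        lines = make_lines("AABB", [0.3] * 4, [2.0, 2.1, 2.2, 2.3])
        with pytest.raises(ValueError, match="variance"):
            fit_tradeoff(lines)

    def test_mixed_fit_on_noisy_data(self, rng):
        truth = scenario_preset("tradeoff_only", rng_seed=77)
        records, _, _ = generate_study(truth, make_climate=False)
        from seedpareto.records import summarize_lines

        fit = fit_tradeoff(summarize_lines(records))
        assert fit.method == "mixed"
        assert fit.slope > 0 and 0 < fit.p_value < 1


class TestDeviation:
    def test_centering_identity(self):
        lines = make_lines("AABB", [0.1, 0.5, 0.2, 0.8], [2.0, 3.0, 1.0, 4.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cent, _fit = deviation_decomposition(lines)
        for pop in ("A", "B"):
            d = cent[cent["population_id"] == pop]
            assert d["dev_mean_sqrt_emergence"].sum() == pytest.approx(0.0, abs=1e-12)
            assert d["dev_persistence_fraction"].sum() == pytest.approx(0.0, abs=1e-12)

    def test_simpson_fixture_flips_sign(self):
        # pooled slope negative, within-population slope exactly +1
        lines = make_lines(
            "AABB", [0.0, 0.2, 0.8, 1.0], [1.0, 1.2, 0.1, 0.3]
        )
        pooled = np.polyfit(lines["persistence_fraction"], lines["mean_sqrt_emergence"], 1)[0]
        assert pooled < 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _cent, fit = deviation_decomposition(lines)
        assert fit.slope == pytest.approx(1.0, abs=1e-8)

    def test_single_population_equals_centered_ols(self, rng):
        pf = rng.random(12)
        y = 2 + 0.8 * pf + rng.normal(0, 0.1, 12)
        lines = make_lines("A" * 12, list(pf), list(y))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _c, fit = deviation_decomposition(lines)
        beta = np.polyfit(pf - pf.mean(), y - y.mean(), 1)[0]
        assert fit.slope == pytest.approx(beta, abs=1e-6)

    def test_per_population_shift_invariance(self, rng):
        pf = list(rng.random(10))
        y = list(2 + 0.5 * np.array(pf) + rng.normal(0, 0.2, 10))
        pops = "AAAAABBBBB"
        lines = make_lines(pops, pf, y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, fit0 = deviation_decomposition(lines)
        shifted = lines.copy()
        shifted.loc[shifted["population_id"] == "A", "mean_sqrt_emergence"] += 5.0
        shifted.loc[shifted["population_id"] == "B", "persistence_fraction"] += 0.25
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, fit1 = deviation_decomposition(shifted)
        assert fit1.slope == pytest.approx(fit0.slope, abs=1e-8)

    def test_single_line_population_excluded(self):
        lines = make_lines("AAAB", [0.1, 0.5, 0.3, 0.4], [2.0, 3.0, 2.5, 2.8])
        with pytest.warns(UserWarning, match="single-line"):
            cent, _ = deviation_decomposition(lines)
        assert set(cent["population_id"]) == {"A"}


class TestResidualize:
    def test_orthogonal_mass_leaves_slope_unchanged(self):
        # mass exactly uncorrelated with emergence time
        pf = [0.1, 0.2, 0.3, 0.4]
        y = [2.0, 2.5, 3.0, 3.5]
        mass = [5.0, 6.0, 6.0, 5.0]  # cov(mass, y) = 0
        assert np.cov(mass, y, ddof=1)[0, 1] == pytest.approx(0.0, abs=1e-12)
        lines = make_lines("AABB", pf, y, mass)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = fit_tradeoff(lines)
            res = residualize_on_mass(lines)
        assert res.slope == pytest.approx(raw.slope, abs=1e-8)

    def test_emergence_linear_in_mass_gives_zero_slope(self):
        mass = [4.0, 5.0, 6.0, 7.0]
        y = [1 + 0.5 * m for m in mass]
        lines = make_lines("AABB", [0.1, 0.4, 0.2, 0.6], y, mass)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = residualize_on_mass(lines)
        assert res.slope == pytest.approx(0.0, abs=1e-8)

    def test_matches_two_stage_oracle_on_random_fixtures(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 20))
            pf = rng.random(n)
            mass = rng.uniform(3, 8, n)
            y = 2 + 0.6 * pf - 0.1 * mass + rng.normal(0, 0.2, n)
            lines = make_lines("A" * n, list(pf), list(y), list(mass))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = residualize_on_mass(lines)
            ref = oracle_two_stage_slope(pf, mass, y)
            assert fit.slope == pytest.approx(ref, abs=1e-8)

    def test_constant_mass_rejected(self):
        lines = make_lines("AABB", [0.1, 0.4, 0.2, 0.6], [2, 3, 2, 3], [5.0] * 4)
        with pytest.raises(ValueError, match="mass"):
            residualize_on_mass(lines)


class TestCooks:
    def test_point_on_fitted_surface_has_zero_distance(self):
        # cluster exactly collinear; extreme point exactly on the same line
        lines = make_lines(
            "A" * 6,
            [0.10, 0.12, 0.08, 0.11, 0.09, 0.90],
            [2.0, 2.1, 1.9, 2.05, 1.95, 6.0],  # y = 1.5 + 5x for every point
        )
        cd = cooks_influence(lines)
        assert cd["cooks_d"].iloc[5] == pytest.approx(0.0, abs=1e-8)

    def test_matches_leave_one_out_oracle(self, rng):
        for _ in range(50):
            # every population gets >= 3 lines: a singleton population's dummy
            # makes its line an exact-leverage-1 point, where the leave-one-out
            # refit is rank-deficient and Cook's D undefined
            sizes = rng.integers(3, 9, size=3)
            n = int(sizes.sum())
            pops = np.repeat(["A", "B", "C"], sizes)
            pf = rng.random(n)
            y = 2 + pf + rng.normal(0, 0.3, n)
            lines = make_lines(list(pops), list(pf), list(y))
            cd = cooks_influence(lines)
            dummies = pd.get_dummies(pd.Series(pops), dtype=float).to_numpy()
            X = np.column_stack([dummies, pf])
            ref = oracle_cooks(X, y)
            assert np.max(np.abs(cd["cooks_d"].to_numpy() - ref)) < 1e-8

    def test_high_leverage_outlier_flagged_at_default_threshold(self):
        lines = make_lines(
            "A" * 6,
            [0.10, 0.12, 0.08, 0.11, 0.09, 0.90],
            [2.0, 2.1, 1.9, 2.05, 1.95, 5.5],  # off the cluster line
        )
        cd = cooks_influence(lines)
        assert cd["cooks_d"].iloc[5] > 7
        assert bool(cd["influential"].iloc[5])

    def test_rank_deficiency_rejected(self):
        lines = make_lines("AB", [0.1, 0.2], [2.0, 2.2])
        with pytest.raises(ValueError, match="rank"):
            cooks_influence(lines)


class TestGlmm:
    def test_loglik_matches_quadrature_oracle(self, rng):
        from seedpareto._glmm import _nll_and_grad, fit_logistic_glmm

        n_groups, per = 12, 8
        groups = np.repeat(np.arange(n_groups), per)
        X = np.column_stack([np.ones(n_groups * per), rng.normal(size=n_groups * per)])
        u = rng.normal(0, 0.8, n_groups)
        from scipy.special import expit

        y = (rng.random(n_groups * per) < expit(0.3 + 0.5 * X[:, 1] + u[groups])).astype(float)
        beta = np.array([0.25, 0.55])
        sigma = 0.7
        z, w = np.polynomial.hermite.hermgauss(25)
        logw = np.log(w) - 0.5 * np.log(np.pi)
        starts = np.flatnonzero(np.r_[True, groups[1:] != groups[:-1]])
        nll, _ = _nll_and_grad(np.r_[beta, np.log(sigma)], y, X, starts, z, logw)
        ref = oracle_glmm_loglik(y, X, groups, beta, sigma)
        assert -nll == pytest.approx(ref, abs=1e-6)
        # and the ML fit cannot be worse than the true parameters
        fit = fit_logistic_glmm(y, X, groups)
        assert fit.loglik >= ref - 1e-6

    def test_gradient_matches_finite_differences(self, rng):
        from seedpareto._glmm import _nll_and_grad

        groups = np.repeat(np.arange(6), 5)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        y = (rng.random(30) < 0.5).astype(float)
        z, w = np.polynomial.hermite.hermgauss(25)
        logw = np.log(w) - 0.5 * np.log(np.pi)
        starts = np.flatnonzero(np.r_[True, groups[1:] != groups[:-1]])
        theta = np.array([0.2, -0.3, np.log(0.6)])
        nll, grad = _nll_and_grad(theta, y, X, starts, z, logw)
        for k in range(3):
            e = np.zeros(3)
            e[k] = 1e-6
            num = (
                _nll_and_grad(theta + e, y, X, starts, z, logw)[0]
                - _nll_and_grad(theta - e, y, X, starts, z, logw)[0]
            ) / 2e-6
            assert grad[k] == pytest.approx(num, rel=1e-4, abs=1e-6)


@pytest.fixture(scope="module")
def screen_frame():
    truth = scenario_preset("tradeoff_only", rng_seed=5)
    records, _, _ = generate_study(truth, make_climate=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return records, screen_seed_outcomes(records)


class TestScreens:

    def test_one_row_per_response_and_term(self, screen_frame):
        _, scr = screen_frame
        assert len(scr) == 16
        assert set(scr["response"]) == {"emergence_time", "persistence", "emergence", "mortality"}
        assert (scr.groupby(["response", "term"]).size() == 1).all()
        binom = scr[scr["model_family"] == "binomial-logit"]
        assert (binom["statistic"] >= 0).all()
        assert scr["p_value"].between(0, 1).all()

    def test_mass_effects_detected_with_correct_direction(self, screen_frame):
        _, scr = screen_frame
        mass = scr.set_index(["response", "term"])
        assert mass.loc[("emergence_time", "seed_mass"), "p_value"] < 0.05
        assert mass.loc[("emergence_time", "seed_mass"), "direction_note"] == "decrease"
        assert mass.loc[("emergence", "seed_mass"), "p_value"] < 0.05
        assert mass.loc[("emergence", "seed_mass"), "direction_note"] == "increase"

    def test_lrt_equals_twice_loglik_difference(self, screen_frame):
        import patsy

        from seedpareto._glmm import fit_logistic_glmm

        records, scr = screen_frame
        df = records.copy()
        df["mass_c"] = df["seed_mass_mg"] - df["seed_mass_mg"].mean()
        df["y"] = (df["fate"] == "persistent").astype(float)
        full = patsy.dmatrix("C(population_id) + C(treatment) + mass_c", df)
        red = patsy.dmatrix("C(treatment) + mass_c", df)
        g = df["maternal_line_id"].to_numpy()
        ll_full = fit_logistic_glmm(df["y"].to_numpy(), np.asarray(full), g).loglik
        ll_red = fit_logistic_glmm(df["y"].to_numpy(), np.asarray(red), g).loglik
        expected = 2.0 * (ll_full - ll_red)
        got = scr.set_index(["response", "term"]).loc[("persistence", "population"), "statistic"]
        assert got == pytest.approx(expected, abs=1e-4)

    def test_null_treatment_term_rejection_rate_is_nominal(self):
        # no treatment effect in the generator: the persistence/emergence
        # treatment terms should reject at roughly the nominal level
        rej = 0
        n_rep = 24
        small = scenario_preset(
            "tradeoff_only", treatment_preset="none", n_pops=4, n_lines_per_pop=8
        )
        pvals = []
        for r in range(n_rep):
            records, _, _ = generate_study(small.replace(rng_seed=1000 + r), make_climate=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scr = screen_seed_outcomes(records)
            p = scr.set_index(["response", "term"]).loc[("persistence", "treatment"), "p_value"]
            pvals.append(float(p))
            rej += p < 0.05
        # 99% binomial bound at n=24, p=0.05: at most 5 rejections
        assert rej <= 5
        assert 0.25 < np.mean(pvals) < 0.75
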