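"""Multilevel REML meta-analysis, heterogeneity, Wald and sign tests."""

import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest

import phenolink as pl
from phenolink.meta import (
    adjusted_threshold,
    binomial_sign_test,
    compare_phylo_models,
    fit_multilevel_meta,
    heterogeneity_stats,
    moderator_model,
    pagels_lambda,
    wald_test,
)


def toy_records(effects, se, **cols):
    k = len(effects)
    base = {
        "study_id": [f"s{i}" for i in range(k)],
        "species": ["sp"] * k,
        "location_id": ["l"] * k,
        "effect": effects,
        "se": [se] * k if np.isscalar(se) else se,
    }
    base.update(cols)
    return pd.DataFrame(base)


class TestClosedForm:
    def test_equal_variance_single_component(self):
        """REML with equal known v: tau2 = sample variance - v, mu = mean."""
        rec = toy_records([0.0, 1.0, 2.0], 0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_multilevel_meta(rec)
        assert m.tau2_study == pytest.approx(0.75, abs=1e-8)
        assert m.beta[0] == pytest.approx(1.0, abs=1e-8)
        assert m.se[0] == pytest.approx(np.sqrt((0.75 + 0.25) / 3), abs=1e-8)

    def test_matches_metafor(self, tmp_path):
        """Independent oracle: metafor's rma.mv on the same records."""
        tree = pl.simulate_tree(8, 2)
        rec = pl.simulate_effect_records(
            24, tree, mu=-0.3, tau2_study=0.06, tau2_location=0.02,
            n_locations=8, seed=3,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_multilevel_meta(rec)
        csv = tmp_path / "rec.csv"
        rec.to_csv(csv, index=False)
        script = (
            "library(metafor); d <- read.csv('%s'); d$vi <- d$se^2; "
            "fit <- rma.mv(effect, vi, random = list(~1|study_id, ~1|location_id,"
            " ~1|species), data=d, method='REML'); "
            "cat(sprintf('%%.8f %%.8f %%.8f', coef(fit), fit$se, fit$sigma2[1]))"
            % csv
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        ).stdout.split()
        mu_r, se_r, tau_r = map(float, out[-3:])
        assert m.beta[0] == pytest.approx(mu_r, abs=1e-5)
        assert m.se[0] == pytest.approx(se_r, abs=1e-5)
        assert m.tau2_study == pytest.approx(tau_r, abs=1e-5)


class TestPagelsLambda:
    @pytest.mark.parametrize(
        "s2p,s2n,want", [(0.3, 0.1, 0.75), (0.0, 0.5, 0.0), (0.0, 0.0, 0.0)]
    )
    def test_values(self, s2p, s2n, want):
        assert pagels_lambda(s2p, s2n) == pytest.approx(want)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pagels_lambda(-0.1, 0.2)


class TestHeterogeneity:
    def test_equal_weight_identity(self):
        rec = toy_records([0.0, 1.0, 2.0], 0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_multilevel_meta(rec)
        i2, q, df, p = heterogeneity_stats(rec, m)
        # typical sampling variance is 0.25 and tau2 is 0.75
        assert i2 == pytest.approx(0.75, abs=1e-6)
        assert q == pytest.approx(8.0, abs=1e-8)
        assert df == 2
        assert p == pytest.approx(np.exp(-4.0), abs=1e-8)

    def test_zero_tau_gives_zero_i2(self):
        rec = toy_records([1.0, 1.0, 1.0, 1.0], 0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_multilevel_meta(rec)
        assert m.tau2_study == 0.0
        assert m.i2 == 0.0

    def test_bounds_on_simulated_fits(self):
        tree = pl.simulate_tree(10, 4)
        rec = pl.simulate_effect_records(30, tree, tau2_study=0.1, seed=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_multilevel_meta(rec)
        assert 0.0 <= m.i2 <= 1.0
        assert 0.0 <= m.lambda_ <= 1.0


class TestWald:
    def test_single_coefficient(self):
        rec = toy_records([0.0, 1.0, 2.0, 1.0], 0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_multilevel_meta(rec)
        m.beta = np.array([2.0])
        m.cov_beta = np.array([[1.0]])
        w = wald_test(m, ["intercept"])
        assert w.chi2 == pytest.approx(4.0)
        assert w.df == 1
        assert w.p == pytest.approx(0.0455, abs=1e-4)

    def test_zero_coefficient(self):
        rec = toy_records([0.0, 1.0, 2.0, 1.0], 0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_multilevel_meta(rec)
        m.beta = np.array([0.0])
        m.cov_beta = np.array([[1.0]])
        w = wald_test(m, ["intercept"])
        assert w.chi2 == 0.0 and w.p == 1.0

    def test_joint_matches_quadratic_form(self):
        tree = pl.simulate_tree(6, 1)
        rng = np.random.default_rng(5)
        rec = pl.simulate_effect_records(40, tree, seed=5)
        rec["abs_latitude"] = rng.uniform(0, 70, 40)
        rec["generation_time"] = rng.uniform(1, 20, 40)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_multilevel_meta(
                rec, moderators=("abs_latitude", "generation_time")
            )
        w = wald_test(m, ["abs_latitude", "generation_time"])
        idx = [m.terms.index("abs_latitude"), m.terms.index("generation_time")]
        g = m.beta[idx]
        C = m.cov_beta[np.ix_(idx, idx)]
        assert w.chi2 == pytest.approx(float(g @ np.linalg.inv(C) @ g), abs=1e-10)
        assert w.df == 2


class TestComparePhylo:
    def test_identity_kernel_tiebreak(self):
        """With A = I the likelihoods tie on a ridge; the extra component
        costs 2 AIC and the non-phylo model wins."""
        tree = pl.simulate_tree(12, 9)
        rec = pl.simulate_effect_records(12, tree, tau2_study=0.08, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comp = compare_phylo_models(rec, np.eye(12))
        assert not comp.phylo_chosen
        assert comp.aic_with - comp.aic_without == pytest.approx(2.0, abs=0.05)

    def test_phylo_detected_when_strong(self):
        tree = pl.simulate_tree(40, 3)
        A = pl.correlation_matrix(tree)
        chosen = 0
        for s in range(20):
            rec = pl.simulate_effect_records(
                100, tree, tau2_study=0.02, sigma2_p=0.08, sigma2_n=0.0, seed=s
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                comp = compare_phylo_models(rec, A)
            chosen += comp.phylo_chosen
        assert chosen >= 14  # majority, at lambda_true = 1 and sigma2 = 0.08


class TestModerators:
    def test_latitude_slope_recovery(self):
        """Recovers a -0.015 per-degree latitude slope on the climate-trait
        path (the magnitude reported for phenological sensitivity)."""
        tree = pl.simulate_tree(30, 6)
        slopes = []
        for s in range(20):
            rng = np.random.default_rng(200 + s)
            rec = pl.simulate_effect_records(150, tree, mu=-0.37,
                                             tau2_study=0.04, seed=300 + s)
            lat = rng.uniform(0, 70, 150)
            rec["abs_latitude"] = lat
            rec["generation_time"] = rng.uniform(1, 20, 150)
            rec["diet"] = np.tile(["herbivore", "carnivore", "omnivore"], 50)
            rec["migratory_mode"] = np.tile(["resident", "migrant"], 75)
            rec["effect"] = rec["effect"] - 0.015 * (lat - lat.mean())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m, block = moderator_model(rec)
            slopes.append(m.coef("abs_latitude"))
            assert block.df == len(m.moderator_terms)
        assert np.mean(slopes) == pytest.approx(-0.015, abs=0.005)

    def test_null_moderators_type_one(self):
        tree = pl.simulate_tree(20, 8)
        rejections = 0
        n_rep = 60
        for s in range(n_rep):
            rng = np.random.default_rng(700 + s)
            rec = pl.simulate_effect_records(60, tree, tau2_study=0.05, seed=900 + s)
            rec["abs_latitude"] = rng.uniform(0, 70, 60)
            rec["generation_time"] = rng.uniform(1, 20, 60)
            rec["diet"] = np.tile(["herbivore", "carnivore", "omnivore"], 20)
            rec["migratory_mode"] = np.tile(["resident", "migrant"], 30)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, block = moderator_model(rec)
            rejections += block.p < 0.05
        assert 0.0 <= rejections / n_rep <= 0.15

    def test_adjusted_threshold(self):
        assert adjusted_threshold(0.05, 5) == pytest.approx(0.01)


class TestBinomialSignTest:
    def test_paper_worked_example(self):
        values = np.concatenate([np.ones(55), -np.ones(38)])
        res = binomial_sign_test(values)
        assert res.n == 93 and res.n_nonnegative == 55
        assert res.proportion == pytest.approx(0.59, abs=0.005)
        assert res.p_one_sided == pytest.approx(0.048, abs=5e-4)

    def test_extreme_case(self):
        res = binomial_sign_test(np.ones(10))
        assert res.p_one_sided == pytest.approx(2**-10)

    def test_exact_tail_sum(self):
        from scipy.stats import binom

        res = binomial_sign_test(np.concatenate([np.ones(50), -np.ones(50)]))
        assert res.p_one_sided == pytest.approx(binom.sf(49, 100, 0.5), abs=1e-12)

    def test_zero_counts_as_nonnegative(self):
        res = binomial_sign_test(np.array([0.0, -1.0, 1.0, 0.0]))
        assert res.n_nonnegative == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            binomial_sign_test(np.array([]))
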