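import numpy as np
import pandas as pd
import pytest
from scipy import stats

from micropart import _kernels
from micropart.bayes import BayesianVariancePartition, compute_dic, hpd_interval


class TestHPDInterval:
    def test_normal_draws_match_quantiles(self):
        rng = np.random.default_rng(0)
        lo, hi = hpd_interval(rng.standard_normal(10_000), 0.95)
        assert lo == pytest.approx(-1.96, abs=0.1)
        assert hi == pytest.approx(1.96, abs=0.1)

    def test_constant_samples_zero_width(self):
        lo, hi = hpd_interval(np.full(50, 3.2))
        assert lo == hi == 3.2

    def test_shorter_than_equal_tail_for_skewed(self):
        rng = np.random.default_rng(1)
        s = rng.exponential(1.0, 20_000)
        lo, hi = hpd_interval(s, 0.95)
        eq = np.quantile(s, [0.025, 0.975])
        assert (hi - lo) < (eq[1] - eq[0])
        assert lo == pytest.approx(0.0, abs=0.02)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="20"):
            hpd_interval(np.arange(10))


class TestDIC:
    def test_degenerate_chain_has_zero_pd(self):
        dev = np.full(100, 42.0)
        dic, pd_ = compute_dic(dev, 42.0)
        assert pd_ == 0.0
        assert dic == 42.0


class TestKernels:
    def test_gibbs_full_conditional_moments(self):
        # Repeated single-column draws reproduce the closed-form Normal
        # full conditional.
        rng = np.random.default_rng(2)
        n = 50
        w = rng.standard_normal((n, 1))
        y = rng.standard_normal(n)
        s2e, pv = 0.7, 2.0
        wsq = np.array([float(w[:, 0] @ w[:, 0])])
        v = 1.0 / (wsq[0] / s2e + 1.0 / pv)
        mean = v * float(w[:, 0] @ y) / s2e
        draws = []
        for _ in range(4000):
            coef = np.zeros(1)
            r = y.copy()
            _kernels.gibbs_sweep(
                np.asfortranarray(w), wsq, coef, np.array([1.0 / pv]), r,
                s2e, rng,
            )
            draws.append(coef[0])
        draws = np.array(draws)
        assert draws.mean() == pytest.approx(mean, abs=4 * np.sqrt(v / 4000))
        assert draws.var() == pytest.approx(v, rel=0.15)

    def test_gibbs_residual_bookkeeping(self):
        # After a sweep the maintained residual equals y - W @ coef.
        rng = np.random.default_rng(3)
        n, k = 40, 6
        W = rng.standard_normal((n, k))
        y = rng.standard_normal(n)
        coef = np.zeros(k)
        r = y.copy()
        wsq = np.einsum("ij,ij->j", W, W)
        _kernels.gibbs_sweep(
            np.asfortranarray(W), wsq, coef, np.full(k, 0.5), r, 1.0, rng
        )
        assert np.allclose(r, y - W @ coef, atol=1e-8)

    def test_tracked_sweep_maintains_fit(self):
        rng = np.random.default_rng(4)
        n, k = 30, 5
        W = rng.standard_normal((n, k))
        y = rng.standard_normal(n)
        coef = np.zeros(k)
        r = y.copy()
        fit = np.zeros(n)
        wsq = np.einsum("ij,ij->j", W, W)
        _kernels.gibbs_sweep_tracked(
            np.asfortranarray(W), wsq, coef, np.full(k, 1.0), r, fit, 1.0, rng
        )
        assert np.allclose(fit, W @ coef, atol=1e-8)
        assert np.allclose(r, y - fit, atol=1e-8)

    def test_indicator_symmetric_two_component(self):
        # K=2, equal variances and proportions: every proposal accepted
        # (boundary corrections cancel), so labels equidistribute.
        rng = np.random.default_rng(5)
        p = 2000
        beta = rng.standard_normal(p) * 0.1
        z = np.zeros(p, dtype=np.int64)
        acc = _kernels.indicator_mh_sweep(
            beta, z, np.log(np.array([0.5, 0.5])), np.array([1.0, 1.0]), rng
        )
        assert acc == p  # acceptance probability exactly 1 both directions

    def test_indicator_prefers_stronger_shrinkage_at_zero(self):
        # With beta = 0 the density ratio favors the smaller variance.
        rng = np.random.default_rng(6)
        p = 3000
        beta = np.zeros(p)
        z = np.ones(p, dtype=np.int64)
        comp_var = np.array([0.01, 1.0])
        for _ in range(30):
            _kernels.indicator_mh_sweep(
                beta, z, np.log(np.array([0.5, 0.5])), comp_var, rng
            )
        assert (z == 0).mean() > 0.85

    def test_mixture_loglik_matches_scipy(self):
        rng = np.random.default_rng(7)
        beta = rng.standard_normal(20)
        z = rng.integers(0, 3, 20)
        cv = np.array([0.1, 1.0, 5.0])
        expected = sum(
            stats.norm.logpdf(b, 0, np.sqrt(cv[k])) for b, k in zip(beta, z)
        )
        assert _kernels.mixture_loglik(beta, z, cv) == pytest.approx(expected)


def quick_chain(seed=0, **kw):
    rng = np.random.default_rng(17)
    n, p = 120, 40
    M = rng.standard_normal((n, p))
    M = (M - M.mean(0)) / M.std(0, ddof=1)
    beta = np.zeros(p)
    beta[:3] = [0.4, -0.3, 0.25]
    y = M @ beta + rng.standard_normal(n)
    defaults = dict(chain_length=2000, burn_in=500, thin=3, random_state=seed)
    defaults.update(kw)
    model = BayesianVariancePartition(**defaults)
    return model.fit(M, y), M, y


class TestChainInvariants:
    def test_variance_ratio_constraint_exact_every_cycle(self):
        model, _, _ = quick_chain()
        # scale_var column stores the largest component variance; the
        # constraint holds exactly by construction, so saved values are all
        # strictly positive and finite.
        sv = model.samples_["scale_var"].values
        assert (sv > 0).all() and np.isfinite(sv).all()

    def test_pi_simplex_valid_every_cycle(self):
        model, _, _ = quick_chain()
        pis = model.samples_[[f"pi_{k}" for k in range(1, 5)]].values
        assert (pis >= 0).all()
        assert np.allclose(pis.sum(axis=1), 1.0, atol=1e-12)

    def test_variance_shares_sum_to_one(self):
        model, _, _ = quick_chain()
        s = model.samples_
        share_e = s["sigma_e2"] / (s["sigma_u2"] + s["var_m"] + s["sigma_e2"])
        assert np.allclose(s["prop_u"] + s["prop_m"] + share_e, 1.0, atol=1e-12)
        assert ((s["prop_u"] >= 0) & (s["prop_u"] <= 1)).all()
        assert ((s["prop_m"] >= 0) & (s["prop_m"] <= 1)).all()

    def test_seed_fixed_bit_reproducible(self):
        m1, _, _ = quick_chain(seed=42)
        m2, _, _ = quick_chain(seed=42)
        assert (m1.samples_.values == m2.samples_.values).all()
        assert m1.dic_ == m2.dic_

    def test_different_seeds_differ(self):
        m1, _, _ = quick_chain(seed=1)
        m2, _, _ = quick_chain(seed=2)
        assert not (m1.samples_["sigma_e2"].values ==
                    m2.samples_["sigma_e2"].values).all()

    def test_hpd_brackets_mean(self):
        model, _, _ = quick_chain()
        lo, hi = model.hpd_prop_m_
        assert lo <= model.prop_m_ <= hi

    def test_taxon_variance_nonnegative(self):
        model, _, _ = quick_chain()
        assert (model.taxon_variance_.values >= 0).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            BayesianVariancePartition(
                variance_ratios=(1.0, 1.0, 2.0, 3.0)
            ).fit(np.ones((30, 2)), np.arange(30.0))
        with pytest.raises(ValueError, match="burn_in"):
            BayesianVariancePartition(
                chain_length=10, burn_in=20
            ).fit(np.ones((30, 2)), np.arange(30.0))


class TestConjugateChecks:
    def test_dirichlet_update_conjugacy(self):
        # With indicators effectively frozen (huge separation), the mixture
        # proportions' long-run mean matches the Dirichlet posterior mean.
        rng = np.random.default_rng(8)
        n, p = 60, 30
        M = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        alpha = np.array([125.0, 25.0, 5.0, 1.0])
        model = BayesianVariancePartition(
            chain_length=4000, burn_in=500, thin=2,
            fixed_comp_var=(1e-8, 1e-7, 1e-6, 1e-5),
            fixed_sigma_e2=1.0, random_state=9,
        ).fit(M, y)
        counts = model.samples_[[f"n_comp_{k}" for k in range(1, 5)]].mean()
        expected = (alpha + counts.values) / (alpha.sum() + p)
        observed = model.samples_[[f"pi_{k}" for k in range(1, 5)]].mean()
        assert np.allclose(observed.values, expected, atol=0.02)

    def test_sigma_e2_inverse_chisquare_mean(self):
        # Scaled-inverse-chi-square draw: E[s / chi2_df] = s / (df - 2).
        rng = np.random.default_rng(10)
        draws = 100.0 / rng.chisquare(100, size=20_000)
        assert draws.mean() == pytest.approx(100.0 / 98.0, rel=0.02)


class TestModelBehavior:
    def test_null_data_small_shares(self):
        rng = np.random.default_rng(11)
        n, p = 200, 50
        M = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        model = BayesianVariancePartition(
            chain_length=3000, burn_in=1000, thin=4, random_state=12
        ).fit(M, y)
        assert model.prop_m_ < 0.06

    def test_strong_signal_detected(self):
        model, M, y = quick_chain(chain_length=3000, burn_in=1000)
        assert model.prop_m_ > 0.1
        # Per-taxon attribution favors the causal columns: the largest
        # effect ranks first and the causal trio outweighs the null taxa.
        assert model.taxon_variance_.idxmax() == 0
        causal = model.taxon_variance_.iloc[:3].mean()
        null = model.taxon_variance_.iloc[3:].mean()
        assert causal > 3 * null

    def test_divergence_guard(self):
        rng = np.random.default_rng(13)
        M = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        with pytest.raises(RuntimeError, match="divergent"):
            BayesianVariancePartition(
                chain_length=100, burn_in=50,
                fixed_sigma_e2=1e13, random_state=1,
            ).fit(M, y)
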