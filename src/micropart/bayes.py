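"""Bayesian variance partitioning of a quantitative trait into host-genetic
and microbiome components.

The model is

    y | gamma, u, beta, sigma_e2 ~ N(X gamma + Z u + M beta, I sigma_e2)

with a flat prior on the fixed effects ``gamma``, a polygenic effect
``u ~ N(0, A sigma_u2)`` (pedigree or genomic relationship matrix A, flat
prior on sigma_u2), and a K-component scale-mixture-of-normals prior on the
taxon effects ``beta`` in the BayesR tradition: each beta_i belongs to an
unknown component z_i with variance comp_var[z_i], the component variances
are locked at fixed ratios (1:10:100:1000 by default, strongest to mildest
shrinkage) with a single free scale, and the mixture proportions pi carry a
sparsity-inducing Dirichlet prior (most prior mass on the
strongest-shrinkage component).

Posterior computation is a single Markov chain mixing Gibbs updates (gamma,
u, beta, pi, sigma_e2, sigma_u2) with Metropolis-Hastings updates (the
component indicators z, and the constrained component-variance scale, moved
on a log-normal proposal). The polygenic term is reparameterized through a
Cholesky factor L of A (u = L a with a ~ N(0, sigma_u2 I)), so no solves
against A appear inside the chain and the quadratic form u'A^-1 u reduces
to a'a.

The explained-variance shares reported are
``prop_u = sigma_u2 / T`` and ``prop_m = var(M beta) / T`` with
``T = sigma_u2 + var(M beta) + sigma_e2``, where var(M beta) is the sample
variance (n-1 divisor) of the fitted microbiome contribution, recomputed in
every cycle of the chain so its full posterior is available.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import _kernels
from .containers import FixedDesign, MicrobiotaMatrix, RelationshipMatrix, RunConfig

__all__ = [
    "BayesianVariancePartition",
    "run_mcmc",
    "hpd_interval",
    "compute_dic",
]

logger = logging.getLogger(__name__)


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` samples."""
    s = np.sort(np.asarray(samples, dtype=float))
    n = s.shape[0]
    if n < 20:
        raise ValueError(f"need at least 20 samples for an HPD interval, got {n}")
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(s[0]), float(s[-1])
    widths = s[k - 1 :] - s[: n - k + 1]
    j = int(np.argmin(widths))
    return float(s[j]), float(s[j + k - 1])


def compute_dic(deviances: np.ndarray, deviance_at_mean: float) -> tuple[float, float]:
    """DIC = mean deviance + pD, with pD = mean deviance - deviance at the
    posterior mean. Returns (dic, p_d)."""
    d_bar = float(np.mean(deviances))
    p_d = d_bar - float(deviance_at_mean)
    return d_bar + p_d, p_d


def _as_matrix(M) -> tuple[np.ndarray, pd.Index | None]:
    if isinstance(M, MicrobiotaMatrix):
        return M.M, M.taxon_ids
    if isinstance(M, pd.DataFrame):
        return M.values.astype(float), M.columns
    return np.asarray(M, dtype=float), None


class BayesianVariancePartition(BaseEstimator):
    """MCMC estimator of host-genetic and microbiome variance shares.

    Parameters
    ----------
    n_components : int
        Number of mixture components K for the taxon-effect prior (the
        two- and four-component variants are the scientifically interesting
        settings).
    variance_ratios : tuple of float
        Relative component variances from strongest to mildest shrinkage,
        strictly increasing; component k has variance ``scale * ratio[k]``
        with a single free scale sampled by MH.
    dirichlet_alpha : tuple of float
        Dirichlet prior counts for the mixture proportions, aligned with
        ``variance_ratios`` (most mass on the strongest-shrinkage class for
        a sparse model).
    chain_length, burn_in, thin : int
        Chain protocol; every ``thin``-th post-burn-in cycle is saved.
    step_sd : float
        Initial log-scale proposal SD of the constrained variance move;
        auto-tuned toward 20-50% acceptance during burn-in only.
    fixed_sigma_e2, fixed_comp_var, fixed_pi : optional
        Freeze the corresponding parameters (used for conjugate/enumeration
        validation and for degenerate designs); ``None`` means "sample it".
    random_state : int
        Seed for the single chain; a fixed seed gives a bit-identical chain.

    Attributes
    ----------
    prop_u_, prop_m_ : float
        Posterior mean explained-variance shares of host genetics and the
        microbiome.
    hpd_prop_u_, hpd_prop_m_ : (float, float)
        95% highest-posterior-density intervals of the shares.
    var_m_mean_, hpd_var_m_ : posterior mean / HPD of var(M beta).
    pi_mean_ : ndarray, posterior mean mixture proportions.
    taxon_variance_ : Series, posterior mean per-taxon contribution
        var(m_i beta_i).
    dic_, p_d_ : deviance information criterion and effective parameters.
    samples_ : DataFrame of saved scalar samples.
    trace_ : DataFrame logged every ``trace_every`` cycles (convergence
        inspection).
    """

    def __init__(
        self,
        n_components: int = 4,
        variance_ratios: tuple = (1.0, 10.0, 100.0, 1000.0),
        dirichlet_alpha: tuple = (125.0, 25.0, 5.0, 1.0),
        chain_length: int = 100_000,
        burn_in: int = 10_000,
        thin: int = 20,
        step_sd: float = 0.1,
        hpd_mass: float = 0.95,
        fixed_sigma_e2: float | None = None,
        fixed_comp_var: tuple | None = None,
        fixed_pi: tuple | None = None,
        trace_every: int = 1000,
        save_z: bool = False,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.variance_ratios = variance_ratios
        self.dirichlet_alpha = dirichlet_alpha
        self.chain_length = chain_length
        self.burn_in = burn_in
        self.thin = thin
        self.step_sd = step_sd
        self.hpd_mass = hpd_mass
        self.fixed_sigma_e2 = fixed_sigma_e2
        self.fixed_comp_var = fixed_comp_var
        self.fixed_pi = fixed_pi
        self.trace_every = trace_every
        self.save_z = save_z
        self.random_state = random_state

    # -- validation helpers -------------------------------------------------

    def _validate(self):
        K = self.n_components
        ratios = np.asarray(self.variance_ratios, dtype=float)
        alpha = np.asarray(self.dirichlet_alpha, dtype=float)
        if K < 1:
            raise ValueError("n_components must be >= 1")
        if ratios.shape[0] < K or alpha.shape[0] < K:
            raise ValueError(
                "variance_ratios and dirichlet_alpha must provide at least "
                "n_components entries"
            )
        ratios, alpha = ratios[:K], alpha[:K]
        if np.any(ratios <= 0) or (K > 1 and np.any(np.diff(ratios) <= 0)):
            raise ValueError("variance_ratios must be positive and strictly increasing")
        if np.any(alpha <= 0):
            raise ValueError("dirichlet_alpha must be positive")
        if self.chain_length <= self.burn_in:
            raise ValueError("chain_length must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        return ratios, alpha

    # -- fitting ------------------------------------------------------------

    def fit(self, M, y, X=None, relationship=None):
        """Run the chain.

        Parameters
        ----------
        M : MicrobiotaMatrix, DataFrame or ndarray (n x p)
            Transformed taxon design matrix.
        y : array-like (n,)
            Phenotype (e.g. methane production, l/day).
        X : FixedDesign, ndarray or None
            Fixed-effect design (fitted inside the model, flat priors).
        relationship : RelationshipMatrix, ndarray or None
            Covariance structure of the polygenic term; ``None`` drops the
            polygenic effect from the model.
        """
        ratios, alpha = self._validate()
        K = self.n_components
        rng = np.random.default_rng(self.random_state)

        Mmat, taxon_ids = _as_matrix(M)
        y = np.asarray(y, dtype=float).ravel()
        n, p = Mmat.shape
        if y.shape[0] != n:
            raise ValueError("y length does not match M rows")
        if n <= 2:
            raise ValueError("need more than 2 observations")

        if X is None:
            Xmat = np.empty((n, 0))
        elif isinstance(X, FixedDesign):
            Xmat = X.X
        else:
            Xmat = np.atleast_2d(np.asarray(X, dtype=float))
            if Xmat.shape[0] != n:
                Xmat = Xmat.T
        if Xmat.shape[0] != n:
            raise ValueError("X rows do not match y")

        if relationship is None:
            L = None
        else:
            if isinstance(relationship, RelationshipMatrix):
                A = relationship.values
            else:
                A = np.asarray(relationship, dtype=float)
            if A.shape != (n, n):
                raise ValueError("relationship matrix shape does not match y")
            L = RelationshipMatrix(A, pd.RangeIndex(n), "genomic_G").cholesky_factor()

        # Fortran order for fast column access in the kernels.
        Mf = np.asfortranarray(Mmat)
        Xf = np.asfortranarray(Xmat)
        Lf = np.asfortranarray(L) if L is not None else None
        msq = np.einsum("ij,ij->j", Mmat, Mmat)
        xsq = np.einsum("ij,ij->j", Xmat, Xmat)
        lsq = np.einsum("ij,ij->j", L, L) if L is not None else None
        col_var = Mmat.var(axis=0, ddof=1) if n > 1 else np.zeros(p)

        vary = float(np.var(y, ddof=1))
        # Initialization: OLS fixed effects, null polygenic effects, ridge
        # taxon effects, all taxa in the strongest-shrinkage class, variances
        # split from var(y). Starting beta at exactly zero is hazardous: the
        # constrained-variance move would see a zero likelihood gradient and
        # can crash the mixture scale to its floor before beta grows, a
        # near-absorbing state; the ridge start puts data-driven effect
        # sizes into the very first scale update.
        gamma = (
            np.linalg.lstsq(Xmat, y, rcond=None)[0]
            if Xmat.shape[1]
            else np.empty(0)
        )
        y_c = y - Xmat @ gamma if Xmat.shape[1] else y
        msq0 = np.einsum("ij,ij->j", Mmat, Mmat)
        beta = (Mmat.T @ y_c) / (msq0 + 2.0 * n)
        a = np.zeros(n) if L is not None else None
        z = np.zeros(p, dtype=np.int64)
        pi = (
            np.asarray(self.fixed_pi, dtype=float)[:K]
            if self.fixed_pi is not None
            else alpha / alpha.sum()
        )
        sigma_e2 = (
            float(self.fixed_sigma_e2)
            if self.fixed_sigma_e2 is not None
            else max(vary / 2.0, 1e-12)
        )
        sigma_u2 = max(vary / 4.0, 1e-12)
        if self.fixed_comp_var is not None:
            comp_var = np.asarray(self.fixed_comp_var, dtype=float)[:K].copy()
        else:
            # Start the strongest-shrinkage variance at the mean squared
            # ridge effect: the first Gibbs sweeps then preserve the
            # data-driven effect sizes instead of annihilating them, and the
            # scale move adapts downward as the mixture takes over.
            v1 = max(float(np.mean(beta**2)), vary * 1e-9, 1e-12)
            comp_var = v1 * ratios

        fit_m = Mmat @ beta
        fit_u = np.zeros(n)
        r = y_c - fit_m

        n_save = (self.chain_length - self.burn_in + self.thin - 1) // self.thin
        cols = [
            "sigma_u2", "sigma_e2", "var_m", "prop_u", "prop_m",
            "scale_var", "scale_var_min",
        ]
        saved = np.zeros((n_save, len(cols)))
        saved_pi = np.zeros((n_save, K))
        saved_z = np.zeros((n_save, K))
        deviances = np.zeros(n_save)
        taxon_acc = np.zeros(p)
        beta_acc = np.zeros(p)
        beta2_acc = np.zeros(p)
        fitted_acc = np.zeros(n)
        sigma_e2_acc = 0.0
        z_samples = np.zeros((n_save, p), dtype=np.int8) if self.save_z else None

        step_sd = float(self.step_sd)
        z_prop = z_acc = 0
        var_prop = var_acc = 0
        var_prop_window = var_acc_window = 0
        trace_rows = []
        isave = 0

        log_pi = np.log(np.maximum(pi, 1e-300))
        for it in range(self.chain_length):
            if Xmat.shape[1]:
                _kernels.gibbs_sweep(Xf, xsq, gamma, np.zeros(Xmat.shape[1]), r,
                                     sigma_e2, rng)
            if L is not None:
                inv_u = np.full(n, 1.0 / sigma_u2)
                _kernels.gibbs_sweep_tracked(Lf, lsq, a, inv_u, r, fit_u,
                                             sigma_e2, rng)
            inv_b = 1.0 / comp_var[z]
            _kernels.gibbs_sweep_tracked(Mf, msq, beta, inv_b, r, fit_m,
                                         sigma_e2, rng)
            if K > 1:
                z_acc += _kernels.indicator_mh_sweep(beta, z, log_pi, comp_var, rng)
                z_prop += p
            if K > 1 and self.fixed_pi is None:
                counts = np.bincount(z, minlength=K).astype(float)
                pi = rng.dirichlet(alpha + counts)
                log_pi = np.log(np.maximum(pi, 1e-300))
            if self.fixed_sigma_e2 is None:
                sigma_e2 = max(float(r @ r) / rng.chisquare(n - 2), 1e-12)
            if L is not None:
                sigma_u2 = max(float(a @ a) / rng.chisquare(n - 2), 1e-12)
            if self.fixed_comp_var is None:
                lv0 = np.log(comp_var[0])
                lv = lv0 + step_sd * rng.normal()
                prop = np.exp(lv) * ratios
                # Log-normal random-walk proposal under the uniform prior on
                # the variance scale: acceptance is the beta-likelihood
                # ratio times the Jacobian exp(lv - lv0). Without the
                # Jacobian the implied prior is flat in log sigma^2, which
                # is improper at 0 and lets the scale collapse.
                delta = (
                    _kernels.mixture_loglik(beta, z, prop)
                    - _kernels.mixture_loglik(beta, z, comp_var)
                    + (lv - lv0)
                )
                var_prop += 1
                var_prop_window += 1
                if np.log(rng.random()) < delta and prop[0] > 1e-14:
                    comp_var = prop
                    var_acc += 1
                    var_acc_window += 1
                # Auto-tune the proposal during burn-in only, so the
                # post-burn-in kernel is fixed and valid.
                if it < self.burn_in and var_prop_window == 100:
                    rate = var_acc_window / 100.0
                    if rate < 0.2:
                        step_sd *= 0.7
                    elif rate > 0.5:
                        step_sd *= 1.4
                    var_prop_window = var_acc_window = 0

            if sigma_e2 > 1e12 or sigma_u2 > 1e12 or comp_var[-1] > 1e12:
                raise RuntimeError(
                    f"divergent chain at iteration {it}: sigma_e2={sigma_e2:.3g}, "
                    f"sigma_u2={sigma_u2:.3g}, comp_var_max={comp_var[-1]:.3g}"
                )

            var_m = float(np.var(fit_m, ddof=1))
            var_u = sigma_u2 if L is not None else 0.0
            total = var_u + var_m + sigma_e2

            if self.trace_every and it % self.trace_every == 0:
                trace_rows.append(
                    (it, var_u, sigma_e2, var_m, comp_var[-1], *pi)
                )

            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                saved[isave] = (
                    var_u, sigma_e2, var_m, var_u / total, var_m / total,
                    comp_var[-1], comp_var[0],
                )
                saved_pi[isave] = pi
                saved_z[isave] = np.bincount(z, minlength=K)
                rss = float(r @ r)
                deviances[isave] = n * np.log(2.0 * np.pi * sigma_e2) + rss / sigma_e2
                taxon_acc += beta * beta * col_var
                beta_acc += beta
                beta2_acc += beta * beta
                if z_samples is not None:
                    z_samples[isave] = z
                fitted_acc += y - r
                sigma_e2_acc += sigma_e2
                isave += 1

        # -- posterior summaries -------------------------------------------
        self.samples_ = pd.DataFrame(saved[:isave], columns=cols)
        for k in range(K):
            self.samples_[f"pi_{k + 1}"] = saved_pi[:isave, k]
            self.samples_[f"n_comp_{k + 1}"] = saved_z[:isave, k]
        self.n_saved_ = isave
        self.prop_u_ = float(self.samples_["prop_u"].mean())
        self.prop_m_ = float(self.samples_["prop_m"].mean())
        self.var_u_mean_ = float(self.samples_["sigma_u2"].mean())
        self.var_m_mean_ = float(self.samples_["var_m"].mean())
        self.sigma_e2_mean_ = sigma_e2_acc / isave
        self.hpd_prop_u_ = hpd_interval(self.samples_["prop_u"], self.hpd_mass)
        self.hpd_prop_m_ = hpd_interval(self.samples_["prop_m"], self.hpd_mass)
        self.hpd_var_m_ = hpd_interval(self.samples_["var_m"], self.hpd_mass)
        self.pi_mean_ = saved_pi[:isave].mean(axis=0)
        self.taxon_variance_ = pd.Series(
            taxon_acc / isave,
            index=taxon_ids if taxon_ids is not None else pd.RangeIndex(p),
            name="var_contribution",
        )
        fitted_mean = fitted_acc / isave
        dev_at_mean = n * np.log(2.0 * np.pi * self.sigma_e2_mean_) + float(
            ((y - fitted_mean) ** 2).sum()
        ) / self.sigma_e2_mean_
        self.dic_, self.p_d_ = compute_dic(deviances[:isave], dev_at_mean)
        self.deviances_ = deviances[:isave]
        self.beta_mean_ = beta_acc / isave
        self.beta_var_ = beta2_acc / isave - self.beta_mean_**2
        self.z_samples_ = z_samples[:isave] if z_samples is not None else None
        self.z_accept_rate_ = z_acc / z_prop if z_prop else np.nan
        self.var_accept_rate_ = var_acc / var_prop if var_prop else np.nan
        self.step_sd_final_ = step_sd
        self.trace_ = pd.DataFrame(
            trace_rows,
            columns=["iteration", "var_u", "sigma_e2", "var_m", "comp_var_max"]
            + [f"pi_{k + 1}" for k in range(K)],
        )
        return self

    # -- reporting ----------------------------------------------------------

    def summary(self) -> pd.DataFrame:
        """One-row-per-quantity posterior summary table."""
        rows = [
            ("prop_host_genetics", self.prop_u_, *self.hpd_prop_u_),
            ("prop_microbiome", self.prop_m_, *self.hpd_prop_m_),
            ("var_u", self.var_u_mean_, *hpd_interval(self.samples_["sigma_u2"])),
            ("var_m", self.var_m_mean_, *self.hpd_var_m_),
            ("sigma_e2", self.sigma_e2_mean_, *hpd_interval(self.samples_["sigma_e2"])),
            ("dic", self.dic_, np.nan, np.nan),
        ]
        return pd.DataFrame(
            rows, columns=["quantity", "posterior_mean", "hpd_low", "hpd_high"]
        )


def run_mcmc(
    y,
    X,
    relationship,
    M,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> BayesianVariancePartition:
    """Functional entry point: fit :class:`BayesianVariancePartition` under a
    :class:`RunConfig` and return the fitted estimator."""
    config = config or RunConfig()
    model = BayesianVariancePartition(
        n_components=config.n_components,
        variance_ratios=config.variance_ratios,
        dirichlet_alpha=config.dirichlet_alpha,
        chain_length=config.chain_length,
        burn_in=config.burn_in,
        thin=config.thin,
        step_sd=config.step_sd,
        random_state=config.seed if seed is None else seed,
    )
    return model.fit(M, y, X=X, relationship=relationship)
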