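"""REML variance components for microbial traits and single-SNP mixed-model
association.

Heritability of a (pre-corrected) microbial trait is estimated under

    y = 1 mu + u + e,   u ~ N(0, G sigma_g2),   e ~ N(0, I sigma_e2)

by restricted maximum likelihood. One eigendecomposition of the genomic
relationship matrix G diagonalizes the covariance for every variance ratio
lambda = sigma_g2 / sigma_e2, so the restricted likelihood is maximized by a
cheap 1-D search; the heritability h2 = sigma_g2 / (sigma_g2 + sigma_e2) and
its standard error follow from the observed information by the delta method.

Association scans fit ``y = 1 mu + s g + u + e`` one SNP at a time with the
variance components fixed at their null-model REML estimates (the
EMMAX/P3D strategy), i.e. generalized least squares with covariance
``sigma_g2 G + sigma_e2 I``; the cached eigendecomposition makes the
per-SNP fit a pair of weighted inner products.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .containers import RelationshipMatrix

__all__ = [
    "GenomicREML",
    "reml_single",
    "h2_scan",
    "gwas_scan",
    "benjamini_yekutieli",
]

logger = logging.getLogger(__name__)


def _eig(G) -> tuple[np.ndarray, np.ndarray]:
    vals = G.values if isinstance(G, RelationshipMatrix) else np.asarray(G, float)
    d, U = np.linalg.eigh(vals)
    return np.maximum(d, 0.0), U


class GenomicREML(BaseEstimator):
    """Single-variance-component REML with an eigendecomposed covariance.

    Parameters
    ----------
    log_lambda_bounds : tuple
        Search range for log10 of the variance ratio
        ``lambda = sigma_g2 / sigma_e2``.

    Attributes
    ----------
    sigma_g2_, sigma_e2_ : float
        REML variance components.
    h2_ : float
        Genomic heritability ``sigma_g2 / (sigma_g2 + sigma_e2)``,
        clipped to [0, 1].
    se_h2_ : float
        Delta-method standard error from the observed information.
    p_value_ : float
        One-sided Wald test of h2 > 0 (variance ratios are non-negative).
    loglik_ : float
        Restricted log-likelihood at the optimum.
    converged_ : bool
        False when the optimum sits on the search boundary.
    """

    def __init__(self, log_lambda_bounds: tuple = (-6.0, 6.0)):
        self.log_lambda_bounds = log_lambda_bounds

    # Restricted log-likelihood profiled over sigma_e2 and the mean.
    @staticmethod
    def _profile_reml(lam, d, yt, xt):
        w = 1.0 / (lam * d + 1.0)
        xwx = float((xt * xt * w).sum())
        xwy = float((xt * yt * w).sum())
        mu = xwy / xwx
        res = yt - mu * xt
        rss = float((res * res * w).sum())
        n = yt.shape[0]
        df = n - 1
        sigma_e2 = rss / df
        ll = -0.5 * (
            df * np.log(sigma_e2)
            + np.log(lam * d + 1.0).sum()
            + np.log(xwx)
            + df
        )
        return ll, mu, sigma_e2

    def restricted_loglik(self, lam: float) -> float:
        """Profiled restricted log-likelihood at variance ratio ``lam``
        (available after :meth:`fit`; used for grid cross-checks)."""
        return self._profile_reml(lam, self._d, self._yt, self._xt)[0]

    def fit(self, G, y):
        y = np.asarray(y, dtype=float).ravel()
        d, U = _eig(G)
        if d.shape[0] != y.shape[0]:
            raise ValueError("G dimension does not match y")
        self._d = d
        self._yt = U.T @ y
        self._xt = U.T @ np.ones_like(y)
        self._U = U

        lo, hi = self.log_lambda_bounds
        res = optimize.minimize_scalar(
            lambda t: -self._profile_reml(10.0**t, d, self._yt, self._xt)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        t_opt = float(res.x)
        lam = 10.0**t_opt
        ll, mu, sigma_e2 = self._profile_reml(lam, d, self._yt, self._xt)
        # A boundary optimum (lambda at either end) means h2 -> 0 or 1.
        self.converged_ = bool(res.success) and (lo + 0.05 < t_opt < hi - 0.05)
        self.mu_ = mu
        self.sigma_e2_ = sigma_e2
        self.sigma_g2_ = lam * sigma_e2
        if t_opt <= lo + 0.05:
            self.sigma_g2_ = 0.0
        self.loglik_ = ll
        total = self.sigma_g2_ + self.sigma_e2_
        self.h2_ = float(np.clip(self.sigma_g2_ / total, 0.0, 1.0))
        self.se_h2_ = self._se_h2()
        if self.se_h2_ > 0:
            self.p_value_ = float(stats.norm.sf(self.h2_ / self.se_h2_))
        else:
            self.p_value_ = 1.0 if self.h2_ == 0 else 0.0
        return self

    def _reml_ll_varcomp(self, sigma_g2, sigma_e2):
        """Unprofiled restricted log-likelihood in the variance components."""
        v = sigma_g2 * self._d + sigma_e2
        if np.any(v <= 0):
            return -np.inf
        w = 1.0 / v
        xwx = float((self._xt * self._xt * w).sum())
        xwy = float((self._xt * self._yt * w).sum())
        mu = xwy / xwx
        res = self._yt - mu * self._xt
        rss = float((res * res * w).sum())
        return -0.5 * (np.log(v).sum() + np.log(xwx) + rss)

    def _se_h2(self) -> float:
        """Delta-method SE of h2 from a numerical observed information."""
        sg, se = max(self.sigma_g2_, 1e-8), self.sigma_e2_
        h = np.array([max(1e-5, 1e-4 * sg), max(1e-5, 1e-4 * se)])
        f = self._reml_ll_varcomp
        H = np.zeros((2, 2))
        pts = [sg, se]

        def at(dg, de):
            return f(pts[0] + dg, pts[1] + de)

        H[0, 0] = (at(h[0], 0) - 2 * at(0, 0) + at(-h[0], 0)) / h[0] ** 2
        H[1, 1] = (at(0, h[1]) - 2 * at(0, 0) + at(0, -h[1])) / h[1] ** 2
        H[0, 1] = H[1, 0] = (
            at(h[0], h[1]) - at(h[0], -h[1]) - at(-h[0], h[1]) + at(-h[0], -h[1])
        ) / (4 * h[0] * h[1])
        info = -H
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return float("nan")
        if np.any(np.diag(cov) < 0):
            return float("nan")
        total = sg + se
        grad = np.array([se, -sg]) / total**2
        var = float(grad @ cov @ grad)
        return float(np.sqrt(var)) if var > 0 else 0.0


def reml_single(y, G) -> GenomicREML:
    """Fit :class:`GenomicREML` for one trait and return the fitted model."""
    return GenomicREML().fit(G, y)


def h2_scan(traits: pd.DataFrame, G, fdr_method: str = "BY") -> pd.DataFrame:
    """REML heritability for each trait column, with FDR adjustment.

    Traits are assumed pre-corrected for fixed effects and transformed
    upstream. Constant traits are skipped with a warning. Returns a
    DataFrame with one row per trait (estimate, se, statistic, p_value,
    p_adjusted, method).
    """
    d, U = _eig(G)
    rows = []
    for name in traits.columns:
        yv = traits[name].values.astype(float)
        if np.var(yv) == 0:
            logger.warning("trait %r is constant; skipped", name)
            continue
        model = GenomicREML()
        # Reuse the shared eigendecomposition.
        model._d = d
        model._yt = U.T @ yv
        model._xt = U.T @ np.ones_like(yv)
        lo, hi = model.log_lambda_bounds
        res = optimize.minimize_scalar(
            lambda t: -model._profile_reml(10.0**t, d, model._yt, model._xt)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        lam = 10.0 ** float(res.x)
        ll, mu, sigma_e2 = model._profile_reml(lam, d, model._yt, model._xt)
        model.converged_ = bool(res.success) and (lo + 0.05 < res.x < hi - 0.05)
        model.mu_, model.sigma_e2_, model.loglik_ = mu, sigma_e2, ll
        model.sigma_g2_ = 0.0 if res.x <= lo + 0.05 else lam * sigma_e2
        total = model.sigma_g2_ + model.sigma_e2_
        model.h2_ = float(np.clip(model.sigma_g2_ / total, 0, 1))
        model.se_h2_ = model._se_h2()
        p = (
            float(stats.norm.sf(model.h2_ / model.se_h2_))
            if model.se_h2_ and model.se_h2_ > 0
            else (1.0 if model.h2_ == 0 else 0.0)
        )
        rows.append(
            {
                "id": name,
                "estimate": model.h2_,
                "se": model.se_h2_,
                "statistic": model.h2_ / model.se_h2_ if model.se_h2_ else np.nan,
                "p_value": p,
                "sigma_g2": model.sigma_g2_,
                "sigma_e2": model.sigma_e2_,
                "converged": model.converged_,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        if fdr_method == "BY":
            out["p_adjusted"] = benjamini_yekutieli(out["p_value"].values)
        else:
            out["p_adjusted"] = np.minimum(out["p_value"] * len(out), 1.0)
        out["method"] = fdr_method
    return out


def benjamini_yekutieli(pvalues) -> np.ndarray:
    """Benjamini-Yekutieli FDR-adjusted p-values (valid under arbitrary
    dependence): the step-up adjustment with the harmonic-number inflation
    ``c(m) = sum_{k<=m} 1/k``."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, alpha=0.05, method="fdr_by")[1]


def gwas_scan(
    y,
    G,
    geno: pd.DataFrame,
    per_snp_reml: bool = False,
) -> pd.DataFrame:
    """Single-SNP mixed linear model scan.

    For each SNP s the model ``y = 1 mu + s g + u + e`` is fitted by
    generalized least squares with covariance ``sigma_g2 G + sigma_e2 I``.
    By default the variance components come from one null-model REML fit
    and are reused for every SNP (P3D/EMMAX); ``per_snp_reml`` re-estimates
    them per SNP (slow, exact). The t statistic ``g / SE`` is referred to a
    t distribution with n - 2 degrees of freedom, and Bonferroni adjustment
    multiplies p by the number of SNPs tested.

    Monomorphic SNPs (collinear with the intercept) are skipped.
    """
    y = np.asarray(y, dtype=float).ravel()
    d, U = _eig(G)
    n = y.shape[0]
    S = geno.values.astype(float)
    if S.shape[0] != n:
        raise ValueError("genotype rows do not match y")

    poly = S.std(axis=0) > 0
    if (~poly).any():
        logger.warning("%d monomorphic SNPs skipped", int((~poly).sum()))

    # Null-model variance components (shared eigendecomposition).
    null = GenomicREML()
    null._d, null._yt, null._xt = d, U.T @ y, U.T @ np.ones(n)
    lo, hi = null.log_lambda_bounds
    res = optimize.minimize_scalar(
        lambda t: -null._profile_reml(10.0**t, d, null._yt, null._xt)[0],
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-8},
    )
    lam0 = 10.0 ** float(res.x)
    _, _, sigma_e2 = null._profile_reml(lam0, d, null._yt, null._xt)
    sigma_g2 = lam0 * sigma_e2

    yt = U.T @ y
    ot = U.T @ np.ones(n)
    St = U.T @ S[:, poly]
    ids = list(geno.columns[poly])

    if per_snp_reml:
        effects, ses = np.zeros(St.shape[1]), np.zeros(St.shape[1])
        for j in range(St.shape[1]):
            sg, se2 = _per_snp_components(d, yt, ot, St[:, j])
            g, sg_se = _gls_snp(d, yt, ot, St[:, j], sg, se2)
            effects[j], ses[j] = g, sg_se
    else:
        w = 1.0 / (sigma_g2 * d + sigma_e2)
        a11 = float((ot * ot * w).sum())
        a12 = (ot[:, None] * St * w[:, None]).sum(axis=0)
        a22 = (St * St * w[:, None]).sum(axis=0)
        b1 = float((ot * yt * w).sum())
        b2 = (St * yt[:, None] * w[:, None]).sum(axis=0)
        det = a11 * a22 - a12**2
        effects = (a11 * b2 - a12 * b1) / det
        ses = np.sqrt(a11 / det)

    tstat = effects / ses
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    out = pd.DataFrame(
        {
            "id": ids,
            "estimate": effects,
            "se": ses,
            "statistic": tstat,
            "p_value": pvals,
            "p_adjusted": np.minimum(pvals * len(ids), 1.0),
            "method": "bonferroni",
        }
    )
    return out


def _per_snp_components(d, yt, ot, st):
    """Exact per-SNP REML: profile over lambda with the SNP in the mean."""
    X = np.column_stack([ot, st])

    def nll(t):
        lam = 10.0**t
        w = 1.0 / (lam * d + 1.0)
        XtWX = X.T @ (X * w[:, None])
        XtWy = X.T @ (yt * w)
        bh = np.linalg.solve(XtWX, XtWy)
        res = yt - X @ bh
        rss = float((res * res * w).sum())
        n, c = yt.shape[0], 2
        sigma_e2 = rss / (n - c)
        sign, logdet = np.linalg.slogdet(XtWX)
        return 0.5 * (
            (n - c) * np.log(sigma_e2)
            + np.log(lam * d + 1.0).sum()
            + logdet
            + (n - c)
        )

    res = optimize.minimize_scalar(nll, bounds=(-6, 6), method="bounded")
    lam = 10.0 ** float(res.x)
    w = 1.0 / (lam * d + 1.0)
    XtWX = X.T @ (X * w[:, None])
    XtWy = X.T @ (yt * w)
    bh = np.linalg.solve(XtWX, XtWy)
    rss = float((((yt - X @ bh) ** 2) * w).sum())
    sigma_e2 = rss / (yt.shape[0] - 2)
    return lam * sigma_e2, sigma_e2


def _gls_snp(d, yt, ot, st, sigma_g2, sigma_e2):
    w = 1.0 / (sigma_g2 * d + sigma_e2)
    X = np.column_stack([ot, st])
    XtWX = X.T @ (X * w[:, None])
    XtWy = X.T @ (yt * w)
    cov = np.linalg.inv(XtWX)
    bh = cov @ XtWy
    return float(bh[1]), float(np.sqrt(cov[1, 1]))
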