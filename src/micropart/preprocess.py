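"""SNP quality control, OTU filtering/transforms, and fixed-effect designs.

Two transformation paths produce the microbiome design matrix M:

* ``log_std`` — add a small pseudo-count, natural-log, then z-score each
  taxon column (mean 0, variance 1, n-1 divisor);
* ``clr`` — per-sample centered log-ratio after additive zero replacement,
  removing compositional closure (each row sums to 0).

Fixed effects follow the dairy-trait convention: intercept, herd and parity
dummies (reference level dropped), days in milk, and a Wilmink exponential
term ``exp(-k * DIM)`` capturing early-lactation nonlinearity.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from skbio.stats.composition import clr as _skbio_clr

from .containers import FixedDesign, MicrobiotaMatrix, OTUTable

__all__ = [
    "SNPQC",
    "PrevalenceFilter",
    "LogStandardizer",
    "CLRTransformer",
    "snp_qc",
    "otu_prevalence_filter",
    "log_standardize",
    "clr_transform",
    "nest_by_instrument",
    "collapse_to_genus",
    "build_fixed_design",
    "precorrect_phenotype",
    "hwe_test",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Hardy-Weinberg test
# ---------------------------------------------------------------------------

def _hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value (two-sided, by probability mass).

    Enumerates the conditional distribution of the heterozygote count given
    the minor-allele count, summing probabilities no larger than that of the
    observed configuration.
    """
    from scipy.special import gammaln

    n = n_het + n_hom1 + n_hom2
    n_rare = n_het + 2 * min(n_hom1, n_hom2)
    # Heterozygote count has the parity of the rare-allele count;
    # log P(h) ∝ h log 2 - log h! - log rare_hom! - log common_hom!
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(rare_hom + 1)
        - gammaln(common_hom + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[hets == n_het][0]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Hardy-Weinberg equilibrium p-value for one SNP.

    Uses the exact conditional test when any HWE-expected genotype count is
    below 5, otherwise a 1-df chi-square goodness-of-fit test.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    p = (2 * n_hom_alt + n_het) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    if exp.min() < 5:
        return _hwe_exact_p(n_het, n_hom_ref, n_hom_alt)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# SNP quality control
# ---------------------------------------------------------------------------

class SNPQC(BaseEstimator, TransformerMixin):
    """Genotype quality control in the conventional filter order.

    Filters are applied sequentially: individual call rate, SNP call rate,
    Hardy-Weinberg deviation, minor allele frequency. Remaining missing
    genotypes are imputed to the (post-QC) SNP mean.

    Parameters
    ----------
    ind_call_min, snp_call_min : float
        Minimum call rates for individuals (default 0.99) and SNPs (0.98).
    hwe_p_min : float
        SNPs with HWE p below this (default 1e-8) are removed.
    maf_min : float
        Minimum minor allele frequency (default 0.02).

    Attributes
    ----------
    kept_individuals_, kept_snps_ : Index
        Surviving row/column labels.
    attrition_ : dict
        Removal counts per filter.
    """

    def __init__(
        self,
        ind_call_min: float = 0.99,
        snp_call_min: float = 0.98,
        hwe_p_min: float = 1e-8,
        maf_min: float = 0.02,
        impute: bool = True,
    ):
        self.ind_call_min = ind_call_min
        self.snp_call_min = snp_call_min
        self.hwe_p_min = hwe_p_min
        self.maf_min = maf_min
        self.impute = impute

    def fit(self, geno: pd.DataFrame, y=None):
        X = geno.values.astype(float)
        valid = ~np.isnan(X)
        bad_codes = valid & ~np.isin(X, (0.0, 1.0, 2.0))
        if bad_codes.any():
            raise ValueError("genotype codes must be 0/1/2 or missing")
        attrition: dict[str, int] = {}

        ind_ok = valid.mean(axis=1) >= self.ind_call_min
        attrition["individual_call_rate"] = int((~ind_ok).sum())
        X, valid = X[ind_ok], valid[ind_ok]

        snp_ok = valid.mean(axis=0) >= self.snp_call_min
        attrition["snp_call_rate"] = int((~snp_ok).sum())
        X, valid = X[:, snp_ok], valid[:, snp_ok]
        snps = geno.columns[snp_ok]

        hwe_p = np.array(
            [
                hwe_test(
                    int((X[valid[:, j], j] == 0).sum()),
                    int((X[valid[:, j], j] == 1).sum()),
                    int((X[valid[:, j], j] == 2).sum()),
                )
                for j in range(X.shape[1])
            ]
        )
        hwe_ok = hwe_p >= self.hwe_p_min
        attrition["hwe"] = int((~hwe_ok).sum())
        X, valid, snps = X[:, hwe_ok], valid[:, hwe_ok], snps[hwe_ok]

        with np.errstate(invalid="ignore"):
            freq = np.nansum(np.where(valid, X, np.nan), axis=0) / (
                2.0 * valid.sum(axis=0)
            )
        maf = np.minimum(freq, 1.0 - freq)
        maf_ok = maf >= self.maf_min
        attrition["maf"] = int((~maf_ok).sum())
        snps = snps[maf_ok]

        self.kept_individuals_ = geno.index[ind_ok]
        self.kept_snps_ = snps
        self.attrition_ = attrition
        if len(snps) == 0:
            raise ValueError(
                f"all SNPs removed by QC; per-filter attrition: {attrition}"
            )
        logger.info("SNP QC attrition: %s", attrition)
        return self

    def transform(self, geno: pd.DataFrame) -> pd.DataFrame:
        out = geno.loc[self.kept_individuals_, self.kept_snps_].astype(float)
        if self.impute and out.isna().any().any():
            out = out.fillna(out.mean(axis=0))
        return out


def snp_qc(geno: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Apply :class:`SNPQC` and return the filtered, imputed genotype table."""
    qc = SNPQC(**kwargs)
    return qc.fit(geno).transform(geno)


# ---------------------------------------------------------------------------
# OTU filtering and transforms
# ---------------------------------------------------------------------------

class PrevalenceFilter(BaseEstimator, TransformerMixin):
    """Keep taxa present (count > 0) in at least ``min_prevalence`` of samples.

    The boundary is inclusive: with 4 samples and min_prevalence 0.5, a
    taxon present in exactly 2 is retained.
    """

    def __init__(self, min_prevalence: float = 0.5):
        self.min_prevalence = min_prevalence

    def fit(self, counts: pd.DataFrame, y=None):
        n = counts.shape[0]
        threshold = int(np.ceil(self.min_prevalence * n))
        prev = (counts.values > 0).sum(axis=0)
        self.kept_ = counts.columns[prev >= threshold]
        if len(self.kept_) == 0:
            raise ValueError(
                f"no taxa pass the {self.min_prevalence:.0%} prevalence filter"
            )
        return self

    def transform(self, counts: pd.DataFrame) -> pd.DataFrame:
        return counts.loc[:, self.kept_]


def otu_prevalence_filter(otu: OTUTable, min_prevalence: float = 0.5) -> OTUTable:
    filt = PrevalenceFilter(min_prevalence).fit(otu.counts)
    return otu.subset_taxa(filt.kept_)


class LogStandardizer(BaseEstimator, TransformerMixin):
    """``ln(count + pseudo)`` followed by per-column z-scoring (n-1 divisor)."""

    def __init__(self, pseudo: float = 0.001):
        self.pseudo = pseudo

    def fit(self, counts: pd.DataFrame, y=None):
        L = np.log(counts.values.astype(float) + self.pseudo)
        self.mean_ = L.mean(axis=0)
        self.scale_ = L.std(axis=0, ddof=1)
        degenerate = self.scale_ <= 1e-12 * np.maximum(np.abs(self.mean_), 1.0)
        if np.any(degenerate):
            bad = list(counts.columns[degenerate][:5])
            raise ValueError(f"zero-variance taxa cannot be standardized: {bad}")
        return self

    def transform(self, counts: pd.DataFrame) -> pd.DataFrame:
        L = np.log(counts.values.astype(float) + self.pseudo)
        Z = (L - self.mean_) / self.scale_
        return pd.DataFrame(Z, index=counts.index, columns=counts.columns)


def log_standardize(
    otu: OTUTable,
    pseudo: float = 0.001,
    per_instrument: bool = False,
) -> MicrobiotaMatrix:
    """Log-standardized design matrix M.

    With ``per_instrument`` the z-scoring is computed within each sequencing
    instrument group, absorbing additive instrument offsets into the
    transform instead of the fixed effects.
    """
    counts = otu.counts
    if per_instrument:
        if otu.instrument is None:
            raise ValueError("per_instrument requires instrument labels")
        Z = pd.DataFrame(
            np.nan, index=counts.index, columns=counts.columns, dtype=float
        )
        for _, members in counts.groupby(otu.instrument):
            Z.loc[members.index] = LogStandardizer(pseudo).fit_transform(members)
    else:
        Z = LogStandardizer(pseudo).fit_transform(counts)
    return MicrobiotaMatrix(
        Z.values, counts.columns, counts.index, "log_std", otu.instrument
    )


class CLRTransformer(BaseEstimator, TransformerMixin):
    """Per-sample centered log-ratio with additive zero replacement.

    Zeros are replaced by ``zero_replacement`` (default 0.5 counts) before
    the log-ratio; each output row sums to zero. Optionally z-scores columns
    afterwards (off by default, so the compositional geometry is untouched).
    """

    def __init__(self, zero_replacement: float = 0.5, standardize: bool = False):
        self.zero_replacement = zero_replacement
        self.standardize = standardize

    def fit(self, counts: pd.DataFrame, y=None):
        return self

    def transform(self, counts: pd.DataFrame) -> pd.DataFrame:
        X = counts.values.astype(float)
        if (X.sum(axis=1) == 0).any():
            bad = list(counts.index[X.sum(axis=1) == 0][:5])
            raise ValueError(f"all-zero samples cannot be CLR-transformed: {bad}")
        X = np.where(X == 0, self.zero_replacement, X)
        Z = _skbio_clr(X)
        if self.standardize:
            Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)
        return pd.DataFrame(Z, index=counts.index, columns=counts.columns)


def nest_by_instrument(M: MicrobiotaMatrix) -> MicrobiotaMatrix:
    """Expand the taxon design to per-instrument effects.

    Each taxon column becomes one column per sequencing-instrument group
    (the column masked to that group's samples, zero elsewhere), the
    alternative reading of "effects within instrument" to the default
    shared-effects + instrument-dummy model.
    """
    if M.instrument is None:
        raise ValueError("nesting requires instrument labels")
    groups = pd.unique(M.instrument)
    blocks, names = [], []
    instr = M.instrument.values
    for g in groups:
        mask = (instr == g).astype(float)[:, None]
        blocks.append(M.M * mask)
        names.extend([f"{t}@{g}" for t in M.taxon_ids])
    return MicrobiotaMatrix(
        np.hstack(blocks), pd.Index(names), M.sample_ids, M.transform,
        M.instrument,
    )


def clr_transform(
    otu: OTUTable, zero_replacement: float = 0.5, standardize: bool = False
) -> MicrobiotaMatrix:
    Z = CLRTransformer(zero_replacement, standardize).fit_transform(otu.counts)
    return MicrobiotaMatrix(
        Z.values, otu.counts.columns, otu.counts.index, "clr", otu.instrument
    )


# ---------------------------------------------------------------------------
# Taxonomic collapsing
# ---------------------------------------------------------------------------

_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


def _collapse_label(lineage: str) -> str:
    """Lineage string truncated at genus; unclassified-at-genus OTUs group by
    their deepest assigned rank."""
    parts = [p.strip() for p in str(lineage).split(";")]
    kept: list[str] = []
    for part in parts:
        prefix = part[:3] if part[:3] in _RANK_PREFIXES else None
        name = part[3:] if prefix else part
        if prefix == "s__":
            break
        if name == "":
            break
        kept.append(part)
        if prefix == "g__":
            break
    return ";".join(kept) if kept else "unclassified"


def collapse_to_genus(otu: OTUTable) -> OTUTable:
    """Sum OTU counts within genus-level lineage groups."""
    if otu.taxonomy is None:
        raise ValueError("collapse_to_genus requires a taxonomy column")
    labels = otu.taxonomy.map(_collapse_label)
    collapsed = otu.counts.T.groupby(labels.values).sum().T
    collapsed = collapsed.sort_index(axis=1)
    tax = pd.Series(collapsed.columns, index=collapsed.columns)
    return OTUTable(collapsed, tax, otu.instrument)


# ---------------------------------------------------------------------------
# Fixed-effect design and phenotype pre-correction
# ---------------------------------------------------------------------------

def build_fixed_design(
    pheno: pd.DataFrame,
    wilmink_k: float = 0.05,
    instrument: pd.Series | None = None,
) -> FixedDesign:
    """Fixed-effect design: intercept, herd/parity dummies, DIM, Wilmink term.

    Parameters
    ----------
    pheno : DataFrame
        Must provide ``herd``, ``parity`` and ``dim`` columns, indexed by
        animal ID.
    wilmink_k : float
        Rate of the Wilmink lactation-curve term ``exp(-k * DIM)``; the
        classical constant 0.05 by default.
    instrument : Series, optional
        If given, a reference-coded instrument dummy block is appended
        (sequencing-batch adjustment).
    """
    n = pheno.shape[0]
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]

    factors = {"herd": pheno["herd"], "parity": pheno["parity"]}
    if instrument is not None:
        factors["instrument"] = instrument.reindex(pheno.index)
    for fname, fac in factors.items():
        levels = pd.unique(fac)
        if len(levels) < 2:
            logger.warning("factor %r has a single level; dummy block omitted", fname)
            continue
        dummies = pd.get_dummies(
            pd.Categorical(fac), prefix=fname, drop_first=True, dtype=float
        )
        cols.extend(dummies.values.T)
        names.extend(dummies.columns)

    dim = pheno["dim"].astype(float).values
    cols.append(dim)
    names.append("dim")
    cols.append(np.exp(-wilmink_k * dim))
    names.append("wilmink")

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # Identify an offending column for the error message.
        keep = [0]
        collinear = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
                keep.append(j)
            else:
                collinear.append(names[j])
        raise ValueError(f"fixed design is rank deficient; collinear: {collinear}")
    return FixedDesign(X, names, pheno.index)


def precorrect_phenotype(y: np.ndarray | pd.Series, design: FixedDesign) -> np.ndarray:
    """Residual of y on the fixed design (least squares), orthogonal to X."""
    yv = np.asarray(y, dtype=float)
    X = design.X
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed design is rank deficient")
    gamma_hat, *_ = np.linalg.lstsq(X, yv, rcond=None)
    return yv - X @ gamma_hat
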