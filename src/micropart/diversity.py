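"""Community summaries used as quantitative traits: Bray-Curtis PCoA
(between-animal beta diversity), Chao1 richness (within-animal alpha
diversity), and PCA on CLR-transformed abundances (Aitchison geometry).

The ordination axes and richness values produced here feed the REML
heritability scan and the single-SNP association scan as response traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .containers import MicrobiotaMatrix, OTUTable

__all__ = [
    "OrdinationResult",
    "bray_curtis",
    "pcoa",
    "chao1",
    "chao1_per_sample",
    "pca_clr",
]

logger = logging.getLogger(__name__)


@dataclass
class OrdinationResult:
    """Sample scores on ordination axes with per-axis explained variance."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray
    method: str  # "pcoa_braycurtis" | "pca_clr" | "pcoa"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.explained_fraction) > 1e-12):
            raise ValueError("explained fractions must be non-increasing")


def bray_curtis(otu: OTUTable | pd.DataFrame, relative: bool = False) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples.

    ``D_jk = 1 - 2 sum_i min(c_ij, c_ik) / (sum_i c_ij + sum_i c_ik)``,
    computed on raw filtered counts by default (``relative`` switches to
    per-sample relative abundances first).
    """
    counts = otu.counts if isinstance(otu, OTUTable) else otu
    X = counts.values.astype(float)
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        bad = list(counts.index[totals == 0][:5])
        raise ValueError(f"all-zero samples have undefined dissimilarity: {bad}")
    if relative:
        X = X / totals[:, None]
    dm = beta_diversity("braycurtis", X, ids=[str(i) for i in counts.index])
    return pd.DataFrame(dm.data, index=counts.index, columns=counts.index)


def pcoa(D: pd.DataFrame | np.ndarray, n_axes: int = 2) -> OrdinationResult:
    """Classical scaling (principal coordinate analysis) of a dissimilarity
    matrix: double-center -D^2/2, eigendecompose, keep the leading
    non-negative eigenvalues. Negative eigenvalues (non-Euclidean input) are
    dropped; their mass is logged."""
    if isinstance(D, pd.DataFrame):
        ids, Dv = D.index, D.values
    else:
        Dv = np.asarray(D, dtype=float)
        ids = pd.RangeIndex(Dv.shape[0])
    dm = DistanceMatrix(Dv, ids=[str(i) for i in ids])
    res = _skbio_pcoa(dm, method="eigh")
    eig = res.eigvals.values
    neg_mass = -eig[eig < 0].sum()
    if neg_mass > 0:
        logger.info(
            "dropping negative PCoA eigenvalue mass %.3g (%.2f%% of total magnitude)",
            neg_mass, 100 * neg_mass / np.abs(eig).sum(),
        )
    pos = eig > 1e-12
    n_pos = int(pos.sum())
    if n_axes > n_pos:
        logger.warning(
            "requested %d axes but only %d positive eigenvalues; truncating",
            n_axes, n_pos,
        )
        n_axes = n_pos
    order = np.argsort(eig)[::-1][:n_axes]
    coords = pd.DataFrame(
        res.samples.values[:, order],
        index=ids,
        columns=[f"PCoA{k + 1}" for k in range(n_axes)],
    )
    lam = eig[order]
    return OrdinationResult(coords, lam, lam / eig[pos].sum(), "pcoa_braycurtis")


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness:
    ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))`` with F1/F2 the singleton and
    doubleton counts. Defined on integer counts only."""
    c = np.asarray(counts)
    if not np.all(np.equal(np.mod(c, 1), 0)):
        raise ValueError("Chao1 is defined on integer counts")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    return float(_skbio_chao1(c.astype(int), bias_corrected=True))


def chao1_per_sample(otu: OTUTable | pd.DataFrame) -> pd.Series:
    """Chao1 richness for every sample in the table."""
    counts = otu.counts if isinstance(otu, OTUTable) else otu
    vals = [chao1(row) for row in counts.values]
    return pd.Series(vals, index=counts.index, name="chao1")


def pca_clr(M: MicrobiotaMatrix | pd.DataFrame, n_axes: int = 2) -> OrdinationResult:
    """PCA of CLR-transformed abundances (Euclidean/Aitchison distances).

    Column-centers the CLR matrix and eigendecomposes its covariance;
    scores equal classical scaling of the Euclidean distance matrix up to
    sign."""
    if isinstance(M, MicrobiotaMatrix):
        if M.transform != "clr":
            raise ValueError("pca_clr expects a CLR-transformed matrix")
        X, ids = M.M, M.sample_ids
    else:
        X, ids = M.values.astype(float), M.index
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    Xc = X - X.mean(axis=0)
    # SVD of the centered matrix: eigenvalues of the covariance are s^2/(n-1).
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    lam = s**2 / (n - 1)
    pos = lam > 1e-12
    n_axes = min(n_axes, int(pos.sum()))
    scores = U[:, :n_axes] * s[:n_axes]
    coords = pd.DataFrame(
        scores, index=ids, columns=[f"PC{k + 1}" for k in range(n_axes)]
    )
    return OrdinationResult(
        coords, lam[:n_axes], lam[:n_axes] / lam.sum(), "pca_clr"
    )
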