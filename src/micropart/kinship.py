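"""Additive relationship matrices: pedigree-based A and SNP-based genomic G.

The pedigree matrix uses the classic tabular (recursive) method; the genomic
matrix uses the Yang et al. SNP-by-SNP standardized estimator, including its
distinct own-relationship (diagonal) form.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import RelationshipMatrix

__all__ = ["pedigree_A", "grm_yang", "sort_pedigree"]

logger = logging.getLogger(__name__)

UNKNOWN = "0"


def sort_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    """Topologically sort a pedigree so parents precede offspring.

    Parameters
    ----------
    ped : DataFrame
        Columns ``animal``, ``sire``, ``dam``; the string ``"0"`` (or NaN)
        denotes an unknown parent. Parents referenced but never listed as
        animals are auto-added as founders (with a warning).

    Raises
    ------
    ValueError
        If an animal is its own ancestor (pedigree cycle).
    """
    ped = ped.copy()
    for col in ("animal", "sire", "dam"):
        ped[col] = ped[col].fillna(UNKNOWN).astype(str)
    animals = set(ped["animal"])
    referenced = (set(ped["sire"]) | set(ped["dam"])) - {UNKNOWN}
    orphans = sorted(referenced - animals)
    if orphans:
        logger.warning(
            "%d parents not listed as animals; added as founders: %s",
            len(orphans),
            orphans[:5],
        )
        ped = pd.concat(
            [
                pd.DataFrame(
                    {"animal": orphans, "sire": UNKNOWN, "dam": UNKNOWN}
                ),
                ped,
            ],
            ignore_index=True,
        )
    if ped["animal"].duplicated().any():
        dup = ped.loc[ped["animal"].duplicated(), "animal"].iloc[0]
        raise ValueError(f"duplicate animal in pedigree: {dup}")

    # Kahn's algorithm over parent -> offspring edges.
    parents = {
        row.animal: [p for p in (row.sire, row.dam) if p != UNKNOWN]
        for row in ped.itertuples()
    }
    children: dict[str, list[str]] = {a: [] for a in parents}
    indeg = {a: len(ps) for a, ps in parents.items()}
    for a, ps in parents.items():
        for p in ps:
            children[p].append(a)
    queue = sorted(a for a, d in indeg.items() if d == 0)
    order: list[str] = []
    while queue:
        a = queue.pop(0)
        order.append(a)
        ready = []
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
        queue.extend(sorted(ready))
        queue.sort()
    if len(order) != len(parents):
        cyc = sorted(set(parents) - set(order))
        raise ValueError(f"pedigree contains a cycle involving: {cyc[:5]}")
    return ped.set_index("animal").loc[order].reset_index()


def pedigree_A(ped: pd.DataFrame) -> RelationshipMatrix:
    """Numerator relationship matrix A by the tabular method.

    With animals ordered parents-first, ``A_ii = 1 + 0.5 * A[sire, dam]``
    (the inbreeding term) and ``A_ij = 0.5 * (A[j, sire_i] + A[j, dam_i])``
    for j < i; an unknown parent contributes 0.
    """
    ped = sort_pedigree(ped)
    animals = list(ped["animal"])
    idx = {a: i for i, a in enumerate(animals)}
    n = len(animals)
    A = np.zeros((n, n))
    sires = [idx.get(s, -1) if s != UNKNOWN else -1 for s in ped["sire"]]
    dams = [idx.get(d, -1) if d != UNKNOWN else -1 for d in ped["dam"]]
    for i in range(n):
        s, d = sires[i], dams[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        for j in range(i):
            val = 0.0
            if s >= 0:
                val += 0.5 * A[j, s]
            if d >= 0:
                val += 0.5 * A[j, d]
            A[i, j] = A[j, i] = val
    return RelationshipMatrix(A, pd.Index(animals), "pedigree_A")


def grm_yang(
    geno: pd.DataFrame,
    freqs: pd.Series | None = None,
    regularize: bool = False,
) -> RelationshipMatrix:
    """Genomic relationship matrix, Yang et al. standardized-SNP estimator.

    Off-diagonals average ``(x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))``
    over SNPs; diagonals use the estimator's own-relationship form
    ``1 + (x² - (1 + 2p) x + 2p²) / (2 p (1 - p))`` averaged over SNPs.

    Parameters
    ----------
    geno : DataFrame
        Animals x SNPs allele counts in {0, 1, 2}; no missing values (QC and
        imputation happen upstream).
    freqs : Series, optional
        External per-SNP allele frequencies; by default estimated from the
        sample itself.
    regularize : bool
        If True and the minimum eigenvalue is below 1e-8, add 1e-6 to the
        diagonal (logged) so the matrix can serve as a REML covariance.
    """
    X = np.asarray(geno.values, dtype=float)
    if np.isnan(X).any():
        raise ValueError("genotypes contain missing values; run QC/imputation first")
    n, m = X.shape
    if freqs is None:
        p = X.mean(axis=0) / 2.0
    else:
        p = np.asarray(freqs.reindex(geno.columns).values, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        bad = list(geno.columns[(p <= 0) | (p >= 1)][:5])
        raise ValueError(f"monomorphic SNPs reached GRM construction: {bad}")
    het = 2.0 * p * (1.0 - p)
    W = (X - 2.0 * p) / np.sqrt(het)
    G = (W @ W.T) / m
    # Replace the diagonal with the estimator's own-relationship form.
    diag = 1.0 + ((X * X - (1.0 + 2.0 * p) * X + 2.0 * p * p) / het).mean(axis=1)
    np.fill_diagonal(G, diag)
    G = 0.5 * (G + G.T)
    if regularize:
        w = np.linalg.eigvalsh(G)
        if w.min() < 1e-8:
            logger.info(
                "GRM min eigenvalue %.3g < 1e-8; adding 1e-6 ridge", w.min()
            )
            G = G + 1e-6 * np.eye(n)
    return RelationshipMatrix(G, geno.index, "genomic_G")
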