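"""Core in-memory containers shared across the pipeline.

The package is deliberately pandas/numpy-centric: tabular data live in
DataFrames indexed by animal/sample ID, dense numeric designs in ndarrays.
The small dataclasses here add just enough structure (IDs, labels,
transform provenance) to keep the pipeline stages honest about alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OTUTable",
    "MicrobiotaMatrix",
    "RelationshipMatrix",
    "FixedDesign",
    "RunConfig",
]


@dataclass
class OTUTable:
    """Sample x taxon count table with taxonomy and instrument labels.

    Parameters
    ----------
    counts : DataFrame
        Non-negative counts, rows indexed by sample (animal) ID, columns by
        taxon (OTU) ID.
    taxonomy : Series, optional
        Lineage strings (e.g. ``"k__Bacteria;p__Firmicutes;...;g__Prevotella"``)
        indexed by taxon ID.
    instrument : Series, optional
        Sequencing-instrument label per sample (e.g. HiSeq / MiSeq halves of
        a run), indexed by sample ID.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None
    instrument: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("OTU counts must be non-negative")
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(self.counts.columns)
        if self.instrument is not None:
            self.instrument = self.instrument.reindex(self.counts.index)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def taxon_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_taxa(self, taxa) -> "OTUTable":
        tax = self.taxonomy.loc[taxa] if self.taxonomy is not None else None
        return OTUTable(self.counts.loc[:, taxa], tax, self.instrument)

    def subset_samples(self, samples) -> "OTUTable":
        instr = (
            self.instrument.loc[samples] if self.instrument is not None else None
        )
        return OTUTable(self.counts.loc[samples], self.taxonomy, instr)

    def copy(self) -> "OTUTable":
        return OTUTable(
            self.counts.copy(),
            None if self.taxonomy is None else self.taxonomy.copy(),
            None if self.instrument is None else self.instrument.copy(),
        )


@dataclass
class MicrobiotaMatrix:
    """Transformed abundance design matrix M (animals x taxa).

    ``transform`` records which path produced it: ``log_std`` (log of
    count + pseudo-count, column z-scored) or ``clr`` (per-sample centered
    log-ratio).
    """

    M: np.ndarray
    taxon_ids: pd.Index
    sample_ids: pd.Index
    transform: str
    instrument: pd.Series | None = None

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError("M shape does not match sample/taxon IDs")
        if self.transform not in ("log_std", "clr", "raw"):
            raise ValueError(f"unknown transform tag: {self.transform!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.M.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.M, index=self.sample_ids, columns=self.taxon_ids)


@dataclass
class RelationshipMatrix:
    """Additive-relationship covariance structure (pedigree A or genomic G)."""

    values: np.ndarray
    ids: pd.Index
    kind: str  # "pedigree_A" | "genomic_G"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = pd.Index(self.ids)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape does not match IDs")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")
        if self.kind not in ("pedigree_A", "genomic_G"):
            raise ValueError(f"unknown relationship kind: {self.kind!r}")

    @property
    def n(self) -> int:
        return len(self.ids)

    def align(self, ids) -> "RelationshipMatrix":
        """Subset/reorder to the given IDs (all must be present)."""
        ids = pd.Index(ids)
        pos = self.ids.get_indexer(ids)
        if (pos < 0).any():
            missing = list(ids[pos < 0][:5])
            raise KeyError(f"IDs absent from relationship matrix: {missing}")
        return RelationshipMatrix(self.values[np.ix_(pos, pos)], ids, self.kind)

    def cholesky_factor(self, jitter: float = 1e-8) -> np.ndarray:
        """A factor L with L L' = values.

        Tries a plain Cholesky, escalating a small diagonal ridge when the
        matrix is numerically semi-definite (a genomic matrix with fewer
        SNPs than animals, duplicated animals, ...); as a last resort uses
        the eigendecomposition square root with negative eigenvalues
        clipped to zero. Any factor with L L' = values serves equally well
        as a sampling/reparameterization basis.
        """
        scale = max(float(np.mean(np.diag(self.values))), 1.0)
        for j in (0.0, jitter, jitter * 1e2, jitter * 1e4):
            try:
                return np.linalg.cholesky(
                    self.values + j * scale * np.eye(self.n)
                )
            except np.linalg.LinAlgError:
                continue
        # The standardized-SNP genomic estimator is mildly indefinite when
        # markers are few; clip small negative eigenvalues, refuse large ones.
        d, U = np.linalg.eigh(self.values)
        if d.min() < -0.05 * scale:
            raise np.linalg.LinAlgError(
                f"matrix is not PSD (min eigenvalue {d.min():.3g})"
            )
        return U * np.sqrt(np.clip(d, 0.0, None))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class FixedDesign:
    """Fixed-effect design matrix X with named columns.

    Always contains an intercept column of ones; factor blocks are
    reference-coded (first level dropped).
    """

    X: np.ndarray
    column_names: list[str]
    sample_ids: pd.Index | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.column_names):
            raise ValueError("X shape does not match column names")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.sample_ids, columns=self.column_names)


@dataclass
class RunConfig:
    """Chain protocol and prior settings for the mixture-model run.

    Defaults follow the standard protocol for this model family: a single
    100k-iteration chain, 10k burn-in, every 20th post-burn-in sample saved;
    a four-component scale mixture whose variances are locked at ratios
    1:10:100:1000 (strongest to mildest shrinkage) with a sparsity-inducing
    Dirichlet(125, 25, 5, 1) prior on the mixture proportions.
    """

    chain_length: int = 100_000
    burn_in: int = 10_000
    thin: int = 20
    n_components: int = 4
    dirichlet_alpha: tuple[float, ...] = (125.0, 25.0, 5.0, 1.0)
    variance_ratios: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0)
    seed: int = 0
    transform: str = "log_std"
    prevalence_min: float = 0.5
    pseudo_count: float = 0.001
    step_sd: float = 0.1

    def __post_init__(self) -> None:
        self.dirichlet_alpha = tuple(float(a) for a in self.dirichlet_alpha)
        self.variance_ratios = tuple(float(r) for r in self.variance_ratios)
        if self.chain_length <= self.burn_in:
            raise ValueError("chain_length must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if len(self.dirichlet_alpha) != self.n_components:
            raise ValueError("dirichlet_alpha length must equal n_components")
        if len(self.variance_ratios) != self.n_components:
            raise ValueError("variance_ratios length must equal n_components")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ValueError("dirichlet_alpha entries must be positive")
        if any(np.diff(self.variance_ratios) <= 0):
            raise ValueError("variance_ratios must be strictly increasing")
        if self.transform not in ("log_std", "clr"):
            raise ValueError("transform must be 'log_std' or 'clr'")
        if not 0.0 <= self.prevalence_min <= 1.0:
            raise ValueError("prevalence_min must lie in [0, 1]")
        if self.pseudo_count <= 0:
            raise ValueError("pseudo_count must be positive")

    def to_dict(self) -> dict:
        return {
            "chain_length": self.chain_length,
            "burn_in": self.burn_in,
            "thin": self.thin,
            "n_components": self.n_components,
            "dirichlet_alpha": list(self.dirichlet_alpha),
            "variance_ratios": list(self.variance_ratios),
            "seed": self.seed,
            "transform": self.transform,
            "prevalence_min": self.prevalence_min,
            "pseudo_count": self.pseudo_count,
            "step_sd": self.step_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("dirichlet_alpha", "variance_ratios"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)
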