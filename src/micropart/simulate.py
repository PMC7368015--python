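"""Synthetic herd-scale data with recorded ground truth.

The generator emulates the structure of a ~750-cow methane study: half-sib
sire families genotyped at SNP-chip scale (gene-dropping through a shallow
pedigree), zero-inflated overdispersed OTU count tables in which a subset of
taxa is heritable, herd/parity/lactation fixed effects, and a phenotype
drawn exactly from the analysis model

    y = X gamma + Z u + M beta + e,

with u multivariate normal on a relationship matrix and beta drawn from a
K-component scale mixture whose component variances obey the configured
1:10:100:1000 ratios. Every dataset is reproducible from (scenario, seed)
and ships its :class:`TruthRecord` so recovery tests can compare posterior
summaries against the generating values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FixedDesign, MicrobiotaMatrix, OTUTable, RelationshipMatrix
from .kinship import grm_yang
from .preprocess import build_fixed_design, log_standardize, otu_prevalence_filter

__all__ = [
    "TruthRecord",
    "sim_genotypes",
    "sim_otu_counts",
    "sim_phenotype",
    "make_scenario",
    "SCENARIOS",
]


@dataclass
class TruthRecord:
    """Generating values of one synthetic phenotype dataset."""

    sigma_u2: float
    sigma_e2: float
    beta_true: np.ndarray
    z_true: np.ndarray
    pi_true: np.ndarray
    gamma_true: np.ndarray
    h2_target: float
    microbiability_target: float
    otu_h2: np.ndarray = field(default_factory=lambda: np.empty(0))
    realized_prop_u: float = float("nan")
    realized_prop_m: float = float("nan")
    total_var: float = float("nan")

    def __post_init__(self) -> None:
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        self.z_true = np.asarray(self.z_true, dtype=int)
        self.pi_true = np.asarray(self.pi_true, dtype=float)
        self.gamma_true = np.asarray(self.gamma_true, dtype=float)
        self.otu_h2 = np.asarray(self.otu_h2, dtype=float)
        if not np.isclose(self.pi_true.sum(), 1.0):
            raise ValueError("pi_true must sum to 1")
        if self.sigma_u2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variances must be non-negative")
        if self.beta_true.shape != self.z_true.shape:
            raise ValueError("beta_true and z_true must have equal length")

    def to_json(self, path) -> None:
        d = asdict(self)
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()}
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Genotypes and pedigree
# ---------------------------------------------------------------------------

def sim_genotypes(
    n: int,
    m: int,
    maf_range: tuple = (0.05, 0.5),
    n_families: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Founder genotypes at Hardy-Weinberg proportions plus Mendelian
    gene-dropping through half-sib sire families.

    With ``n_families = 0`` every animal is an unrelated founder. Otherwise
    the first ``n_families`` animals are founder sires, roughly half the
    remainder founder dams, and the rest offspring assigned round-robin to
    sires (several offspring per sire: paternal half-sib structure; dams are
    reused cyclically, so full sibs arise when offspring outnumber dams).

    Returns (genotype DataFrame animals x SNPs in {0,1,2}, pedigree
    DataFrame with columns animal/sire/dam, "0" = unknown).
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if n_families > n:
        raise ValueError("n_families cannot exceed n")
    rng = np.random.default_rng(seed)
    ids = [f"A{i + 1:05d}" for i in range(n)]
    freqs = rng.uniform(lo, hi, size=m)
    snp_ids = [f"SNP{j + 1:05d}" for j in range(m)]

    if n_families <= 0 or n < n_families + 3:
        geno = rng.binomial(2, freqs, size=(n, m))
        ped = pd.DataFrame({"animal": ids, "sire": "0", "dam": "0"})
        return (
            pd.DataFrame(geno, index=pd.Index(ids, name="animal"), columns=snp_ids),
            ped,
        )

    n_sires = n_families
    remaining = n - n_sires
    n_dams = max(1, remaining // 2)
    n_off = remaining - n_dams
    n_founders = n_sires + n_dams

    geno = np.zeros((n, m), dtype=np.int64)
    geno[:n_founders] = rng.binomial(2, freqs, size=(n_founders, m))
    sire_idx = [i % n_sires for i in range(n_off)]
    dam_idx = [n_sires + (i % n_dams) for i in range(n_off)]
    for k in range(n_off):
        i = n_founders + k
        # Each parent transmits one allele: Bernoulli(parent genotype / 2).
        geno[i] = rng.binomial(1, geno[sire_idx[k]] / 2.0) + rng.binomial(
            1, geno[dam_idx[k]] / 2.0
        )

    ped = pd.DataFrame(
        {
            "animal": ids,
            "sire": ["0"] * n_founders + [ids[s] for s in sire_idx],
            "dam": ["0"] * n_founders + [ids[d] for d in dam_idx],
        }
    )
    return (
        pd.DataFrame(geno, index=pd.Index(ids, name="animal"), columns=snp_ids),
        ped,
    )


# ---------------------------------------------------------------------------
# OTU counts
# ---------------------------------------------------------------------------

_PHYLA = [
    ("k__Bacteria", "p__Bacteroidetes", "c__Bacteroidia", "o__Bacteroidales",
     "f__Prevotellaceae"),
    ("k__Bacteria", "p__Firmicutes", "c__Clostridia", "o__Clostridiales",
     "f__Lachnospiraceae"),
    ("k__Bacteria", "p__Actinobacteria", "c__Coriobacteriia",
     "o__Coriobacteriales", "f__Coriobacteriaceae"),
    ("k__Archaea", "p__Euryarchaeota", "c__Methanobacteria",
     "o__Methanobacteriales", "f__Methanobacteriaceae"),
]


def _taxonomy_strings(p: int) -> list[str]:
    """Plausible lineage strings; consecutive OTU pairs share a genus so
    genus-level collapsing is exercised."""
    out = []
    for j in range(p):
        lineage = _PHYLA[j % len(_PHYLA)]
        genus = f"g__Genus{j // 2 + 1:03d}"
        out.append(";".join(lineage) + ";" + genus)
    return out


def sim_otu_counts(
    n: int,
    p: int,
    heritable_fraction: float = 0.2,
    otu_h2: float = 0.25,
    zero_inflation: float = 0.1,
    instrument_split: float = 0.5,
    genetic_values: RelationshipMatrix | np.ndarray | None = None,
    seed: int = 0,
    nb_size: float = 10.0,
    latent_sd: float = 1.0,
    instrument_sd: float = 0.3,
    sample_ids=None,
) -> tuple[OTUTable, pd.DataFrame]:
    """Zero-inflated negative-binomial OTU counts with a heritable subset.

    For a heritable taxon the log-abundance latent is
    ``sqrt(h2) * g + sqrt(1 - h2) * eps`` with g a unit-variance polygenic
    value drawn on the supplied relationship structure; the latent is
    exponentiated to a negative-binomial mean (overdispersion ``1/nb_size``)
    and structural zeros are injected independently at rate
    ``zero_inflation``. Samples split into two sequencing-instrument halves
    with an additive per-taxon offset on the log scale.

    Returns (OTUTable, per-taxon truth DataFrame with columns ``heritable``
    and ``h2``).
    """
    for name, v in (("heritable_fraction", heritable_fraction),
                    ("zero_inflation", zero_inflation),
                    ("instrument_split", instrument_split)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if not 0.0 <= otu_h2 < 1.0:
        raise ValueError("otu_h2 must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = [f"A{i + 1:05d}" for i in range(n)]
    sample_ids = pd.Index(sample_ids, name="animal")

    L = None
    if genetic_values is not None:
        if isinstance(genetic_values, RelationshipMatrix):
            L = genetic_values.align(sample_ids).cholesky_factor() \
                if not genetic_values.ids.equals(sample_ids) \
                else genetic_values.cholesky_factor()
        else:
            A = np.asarray(genetic_values, dtype=float)
            L = RelationshipMatrix(A, sample_ids, "genomic_G").cholesky_factor()

    n_her = int(round(heritable_fraction * p)) if L is not None else 0
    heritable = np.zeros(p, dtype=bool)
    heritable[:n_her] = True
    h2_vec = np.where(heritable, otu_h2, 0.0)

    base = rng.normal(np.log(50.0), 1.0, size=p)
    counts = np.zeros((n, p), dtype=np.int64)
    n_first = int(round(instrument_split * n))
    instrument = np.array(["HiSeq"] * n_first + ["MiSeq"] * (n - n_first))
    instr_offset = rng.normal(0.0, instrument_sd, size=p)

    for j in range(p):
        if heritable[j]:
            g = L @ rng.standard_normal(n)
            g = g / max(g.std(ddof=1), 1e-12)
            latent = np.sqrt(h2_vec[j]) * g + np.sqrt(1 - h2_vec[j]) * \
                rng.standard_normal(n)
        else:
            latent = rng.standard_normal(n)
        logmu = base[j] + latent_sd * latent
        logmu = logmu + np.where(instrument == "MiSeq", instr_offset[j], 0.0)
        mu = np.exp(np.clip(logmu, -20, 20))
        # Negative binomial via the gamma-Poisson mixture.
        lam = rng.gamma(nb_size, mu / nb_size)
        counts[:, j] = rng.poisson(lam)
    if zero_inflation > 0:
        counts[rng.random((n, p)) < zero_inflation] = 0

    taxon_ids = [f"OTU{j + 1:05d}" for j in range(p)]
    table = OTUTable(
        pd.DataFrame(counts, index=sample_ids, columns=taxon_ids),
        taxonomy=pd.Series(_taxonomy_strings(p), index=taxon_ids),
        instrument=pd.Series(instrument, index=sample_ids),
    )
    truth = pd.DataFrame(
        {"heritable": heritable, "h2": h2_vec}, index=pd.Index(taxon_ids)
    )
    return table, truth


# ---------------------------------------------------------------------------
# Phenotype
# ---------------------------------------------------------------------------

def sim_covariates(n: int, seed: int = 0, n_herds: int = 6, n_parities: int = 4,
                   sample_ids=None) -> pd.DataFrame:
    """Herd (6 levels), parity (4 levels, geometric frequencies) and days in
    milk (uniform on 1..350) for each animal."""
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = [f"A{i + 1:05d}" for i in range(n)]
    parity_probs = 0.5 ** np.arange(n_parities)
    parity_probs = parity_probs / parity_probs.sum()
    return pd.DataFrame(
        {
            "herd": rng.integers(1, n_herds + 1, size=n),
            "parity": rng.choice(np.arange(1, n_parities + 1), size=n,
                                 p=parity_probs),
            "dim": rng.integers(1, 351, size=n),
        },
        index=pd.Index(sample_ids, name="animal"),
    )


def sim_phenotype(
    X: FixedDesign | None,
    relationship: RelationshipMatrix | np.ndarray | None,
    M: MicrobiotaMatrix | np.ndarray,
    h2_target: float = 0.25,
    microbiability_target: float = 0.07,
    pi_true=(0.85, 0.10, 0.04, 0.01),
    variance_ratios=(1.0, 10.0, 100.0, 1000.0),
    total_var: float = 1.0,
    seed: int = 0,
    gamma_true: np.ndarray | None = None,
) -> tuple[np.ndarray, TruthRecord]:
    """Phenotype drawn exactly from the analysis model.

    ``sigma_u2 = h2_target * total_var``; taxon effects come from the
    mixture ``z ~ cat(pi_true)``, ``beta_i ~ N(0, v_{z_i})`` with component
    variances proportional to ``variance_ratios`` and scaled so the
    expected var(M beta) equals ``microbiability_target * total_var``;
    ``sigma_e2`` absorbs the remainder. Realized variance shares (which
    fluctuate around the targets) are recorded in the returned
    :class:`TruthRecord`.
    """
    if h2_target + microbiability_target >= 1.0:
        raise ValueError("variance-share targets must sum to < 1")
    rng = np.random.default_rng(seed)
    Mmat = M.M if isinstance(M, MicrobiotaMatrix) else np.asarray(M, dtype=float)
    n, p = Mmat.shape
    pi_true = np.asarray(pi_true, dtype=float)
    ratios = np.asarray(variance_ratios, dtype=float)

    u = np.zeros(n)
    sigma_u2 = h2_target * total_var
    if relationship is not None and sigma_u2 > 0:
        A = relationship.values if isinstance(relationship, RelationshipMatrix) \
            else np.asarray(relationship, dtype=float)
        try:
            L = RelationshipMatrix(
                A, pd.RangeIndex(n), "genomic_G"
            ).cholesky_factor()
        except np.linalg.LinAlgError as err:
            raise ValueError(f"relationship matrix not PSD: {err}") from err
        u = np.sqrt(sigma_u2) * (L @ rng.standard_normal(n))
    else:
        sigma_u2 = 0.0

    z = rng.choice(len(pi_true), size=p, p=pi_true)
    col_var = Mmat.var(axis=0, ddof=1)
    mean_ratio = float((pi_true * ratios).sum())
    if microbiability_target > 0 and col_var.sum() > 0:
        scale = microbiability_target * total_var / (col_var.sum() * mean_ratio)
        comp_var = scale * ratios
        beta = rng.standard_normal(p) * np.sqrt(comp_var[z])
    else:
        beta = np.zeros(p)

    sigma_e2 = max(total_var * (1.0 - h2_target - microbiability_target), 0.0)
    e = rng.standard_normal(n) * np.sqrt(sigma_e2)

    if X is not None:
        Xmat = X.X if isinstance(X, FixedDesign) else np.asarray(X, dtype=float)
        if gamma_true is None:
            k = Xmat.shape[1]
            sd = np.sqrt(total_var)
            gamma_true = rng.normal(0.0, 0.5 * sd, size=k)
            names = X.column_names if isinstance(X, FixedDesign) else [""] * k
            for j, nm in enumerate(names):
                if nm == "intercept":
                    gamma_true[j] = 10.0 * sd
                elif nm == "dim":
                    gamma_true[j] = 0.5 * sd / 100.0
                elif nm == "wilmink":
                    gamma_true[j] = -2.0 * sd
        fixed_part = Xmat @ gamma_true
    else:
        gamma_true = np.empty(0)
        fixed_part = 0.0

    mb = Mmat @ beta
    y = fixed_part + u + mb + e

    denom = (
        np.var(u, ddof=1) + np.var(mb, ddof=1) + np.var(e, ddof=1)
        if n > 1
        else np.nan
    )
    truth = TruthRecord(
        sigma_u2=sigma_u2,
        sigma_e2=sigma_e2,
        beta_true=beta,
        z_true=z,
        pi_true=pi_true,
        gamma_true=np.asarray(gamma_true, dtype=float),
        h2_target=h2_target,
        microbiability_target=microbiability_target,
        realized_prop_u=float(np.var(u, ddof=1) / denom),
        realized_prop_m=float(np.var(mb, ddof=1) / denom),
        total_var=total_var,
    )
    return y, truth


# ---------------------------------------------------------------------------
# Scenario writer
# ---------------------------------------------------------------------------

SCENARIOS: dict[str, dict] = {
    "study": dict(n=750, m_snps=5000, p_otus=500, n_families=50,
                       h2=0.25, microbiability=0.07),
    "tiny": dict(n=60, m_snps=200, p_otus=40, n_families=6,
                 h2=0.25, microbiability=0.07),
    # Null calibration runs at the full study scale: variance-share
    # posteriors under flat priors are weakly identified at small n, so a
    # meaningful null check needs the same design as the signal scenarios.
    "null": dict(n=750, m_snps=5000, p_otus=500, n_families=50,
                 h2=0.0, microbiability=0.0),
}


def make_scenario(name: str, seed: int, outdir) -> dict[str, Path]:
    """Simulate a named scenario and write every input file plus the truth
    JSON to ``outdir``. Deterministic given (name, seed)."""
    from . import io as io_formats  # local import to avoid a cycle

    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    cfg = SCENARIOS[name]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = cfg["n"]

    geno, ped = sim_genotypes(n, cfg["m_snps"], (0.05, 0.5), cfg["n_families"],
                              seed=seed)
    # SNPs drifted to fixation during gene-dropping carry no relationship
    # information; exclude them from the simulation-side genomic matrix.
    poly = geno.loc[:, geno.std(axis=0) > 0]
    G = grm_yang(poly)
    otu, otu_truth = sim_otu_counts(
        n, cfg["p_otus"], genetic_values=G, seed=seed + 1,
        sample_ids=geno.index,
    )
    covars = sim_covariates(n, seed=seed + 2, sample_ids=geno.index)
    design = build_fixed_design(covars)
    filtered = otu_prevalence_filter(otu)
    M = log_standardize(filtered)
    y, truth = sim_phenotype(
        design, G, M,
        h2_target=cfg["h2"], microbiability_target=cfg["microbiability"],
        seed=seed + 3,
    )
    pheno = covars.copy()
    pheno.insert(0, "methane", y)

    paths = {
        "phenotype": outdir / "phenotype.tsv",
        "genotypes": outdir / "genotypes.tsv",
        "pedigree": outdir / "pedigree.csv",
        "otu": outdir / "otu_counts.tsv",
        "taxonomy": outdir / "otu_taxonomy.tsv",
        "truth": outdir / "truth.json",
        "otu_truth": outdir / "otu_truth.tsv",
    }
    io_formats.write_phenotype(pheno, paths["phenotype"])
    io_formats.write_genotypes_tsv(geno, paths["genotypes"])
    io_formats.write_pedigree(ped, paths["pedigree"])
    io_formats.write_otu_table(otu, paths["otu"], paths["taxonomy"])
    truth.to_json(paths["truth"])
    otu_truth.to_csv(paths["otu_truth"], sep="\t")
    return paths
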