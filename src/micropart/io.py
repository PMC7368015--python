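"""Reading and writing the pipeline's table dialects.

TSV is the primary dialect throughout: phenotype tables, "ID + 0/1/2
matrix" genotype tables, pedigree CSV (animal,sire,dam with 0 = unknown),
OTU count tables with a per-sample instrument column and a sidecar taxonomy
table. PLINK .ped/.map text genotypes are supported as an alternative
genotype dialect. Loaders canonicalize row order (sorted by ID) so results
are insensitive to input row order, and ``load_tables`` aligns every table
on the shared animal IDs, reporting and dropping orphans.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import OTUTable, RunConfig

__all__ = [
    "load_tables",
    "read_phenotype",
    "write_phenotype",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_plink",
    "write_plink",
    "read_pedigree",
    "write_pedigree",
    "read_otu_table",
    "write_otu_table",
    "read_relationship_tsv",
    "write_relationship_tsv",
    "write_matrix_h5",
    "read_matrix_h5",
    "write_results",
    "read_results",
    "load_config",
    "save_config",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A required column or code is missing/invalid in an input file."""


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")


# -- phenotype ---------------------------------------------------------------

def read_phenotype(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"animal": str})
    _require_columns(df, ["animal", "methane", "herd", "parity", "dim"], path)
    return df.set_index("animal").sort_index()


def write_phenotype(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="animal")


# -- genotypes ---------------------------------------------------------------

def read_genotypes_tsv(path) -> pd.DataFrame:
    """Plain matrix dialect: first column ``animal``, remaining columns SNP
    IDs with allele counts 0/1/2 (``NA`` = missing)."""
    df = pd.read_csv(path, sep="\t", dtype={"animal": str})
    _require_columns(df, ["animal"], path)
    df = df.set_index("animal").sort_index()
    vals = df.values.astype(float)
    valid = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
    if not valid.all():
        raise FormatError(f"{path}: genotype codes outside {{0,1,2,NA}}")
    return df.astype(float)


def write_genotypes_tsv(geno: pd.DataFrame, path) -> None:
    out = geno.copy()
    out.to_csv(path, sep="\t", index=True, index_label="animal", na_rep="NA")


def read_plink(ped_path, map_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PLINK text .ped/.map pair -> (allele-count matrix, SNP map).

    Counts copies of the alphabetically later allele at each SNP (a
    deterministic convention; flip downstream if an external allele
    reference is available). ``0`` alleles denote missing genotypes.
    """
    snp_map = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos"], dtype={"snp": str},
    )
    rows, ids = [], []
    for line in Path(ped_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * len(snp_map):
            raise FormatError(
                f"{ped_path}: expected {6 + 2 * len(snp_map)} fields, "
                f"got {len(parts)}"
            )
        ids.append(parts[1])
        rows.append(parts[6:])
    alleles = np.array(rows).reshape(len(rows), len(snp_map), 2)
    counts = np.full((len(rows), len(snp_map)), np.nan)
    for j in range(len(snp_map)):
        obs = np.unique(alleles[:, j, :])
        obs = sorted(a for a in obs if a != "0")
        if not obs:
            continue
        counted = obs[-1]  # alphabetically later allele
        missing = (alleles[:, j, :] == "0").any(axis=1)
        counts[:, j] = (alleles[:, j, :] == counted).sum(axis=1).astype(float)
        counts[missing, j] = np.nan
    geno = pd.DataFrame(
        counts, index=pd.Index(ids, name="animal"), columns=snp_map["snp"]
    ).sort_index()
    return geno, snp_map


def write_plink(geno: pd.DataFrame, ped_path, map_path,
                snp_map: pd.DataFrame | None = None) -> None:
    """Write the 0/1/2 matrix as PLINK text using A (uncounted) / B
    (counted) pseudo-alleles, missing as 0 0."""
    m = geno.shape[1]
    if snp_map is None:
        snp_map = pd.DataFrame(
            {"chrom": 1, "snp": geno.columns, "cm": 0,
             "pos": np.arange(1, m + 1) * 1000}
        )
    snp_map.to_csv(map_path, sep="\t", header=False, index=False)
    code = {0.0: "A A", 1.0: "A B", 2.0: "B B"}
    with open(ped_path, "w") as fh:
        for animal, row in geno.iterrows():
            fields = [str(animal), str(animal), "0", "0", "0", "-9"]
            for v in row.values:
                fields.append(code.get(float(v), "0 0") if not np.isnan(v)
                              else "0 0")
            fh.write(" ".join(fields) + "\n")


# -- pedigree ----------------------------------------------------------------

def read_pedigree(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["animal", "sire", "dam"], path)
    return df[["animal", "sire", "dam"]].fillna("0")


def write_pedigree(ped: pd.DataFrame, path) -> None:
    ped[["animal", "sire", "dam"]].to_csv(path, index=False)


# -- OTU table ---------------------------------------------------------------

def read_otu_table(path, taxonomy_path=None) -> OTUTable:
    """Count table: first column ``animal``, optional ``instrument`` column,
    remaining columns taxon counts. Taxonomy sidecar: columns ``taxon``,
    ``taxonomy``."""
    df = pd.read_csv(path, sep="\t", dtype={"animal": str})
    _require_columns(df, ["animal"], path)
    df = df.set_index("animal").sort_index()
    instrument = None
    if "instrument" in df.columns:
        instrument = df.pop("instrument").astype(str)
    counts = df.astype(np.int64)
    taxonomy = None
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str)
        _require_columns(tax, ["taxon", "taxonomy"], taxonomy_path)
        taxonomy = tax.set_index("taxon")["taxonomy"]
    return OTUTable(counts, taxonomy, instrument)


def write_otu_table(otu: OTUTable, path, taxonomy_path=None) -> None:
    df = otu.counts.copy()
    if otu.instrument is not None:
        df.insert(0, "instrument", otu.instrument)
    df.to_csv(path, sep="\t", index=True, index_label="animal")
    if taxonomy_path is not None and otu.taxonomy is not None:
        otu.taxonomy.rename("taxonomy").to_csv(
            taxonomy_path, sep="\t", index=True, index_label="taxon"
        )


# -- relationship matrices ---------------------------------------------------

def read_relationship_tsv(path, kind: str):
    from .containers import RelationshipMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return RelationshipMatrix(df.values, df.index, kind)


def write_relationship_tsv(rel, path) -> None:
    rel.to_frame().to_csv(path, sep="\t", index=True, index_label="id")


def write_matrix_h5(values: np.ndarray, ids, path, name: str = "matrix",
                    attrs: dict | None = None) -> None:
    """Binary HDF5 dump of a labelled numeric matrix (large-p alternative
    to TSV for relationship matrices, transformed abundance matrices and
    saved chains)."""
    import h5py

    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset(name, data=np.asarray(values, dtype=float),
                               compression="gzip")
        fh.create_dataset(
            "ids", data=np.array([str(i) for i in ids], dtype="S")
        )
        for k, v in (attrs or {}).items():
            ds.attrs[k] = v


def read_matrix_h5(path, name: str = "matrix"):
    import h5py

    with h5py.File(path, "r") as fh:
        values = fh[name][...]
        ids = [s.decode() for s in fh["ids"][...]]
        attrs = dict(fh[name].attrs)
    return values, pd.Index(ids), attrs


# -- scan results / summaries ------------------------------------------------

def write_results(result, path) -> None:
    """Write a scan result (DataFrame) or a fitted mixture model's summary
    to TSV with full-precision floats, rereadable by :func:`read_results`."""
    if hasattr(result, "summary") and not isinstance(result, pd.DataFrame):
        result = result.summary()
    result.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- run configuration -------------------------------------------------------

def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


# -- joint loader ------------------------------------------------------------

def load_tables(
    phenotype_path=None,
    genotype_path=None,
    pedigree_path=None,
    otu_path=None,
    taxonomy_path=None,
    plink_prefix=None,
) -> dict:
    """Load any subset of the input tables and align them on shared animal
    IDs (sorted). Unmatched IDs are reported and dropped; zero overlap is
    fatal. The pedigree is *not* restricted to the overlap (ancestors stay)."""
    out: dict = {}
    id_sets = []
    if phenotype_path is not None:
        out["phenotype"] = read_phenotype(phenotype_path)
        id_sets.append(set(out["phenotype"].index))
    if plink_prefix is not None:
        out["genotypes"], out["snp_map"] = read_plink(
            f"{plink_prefix}.ped", f"{plink_prefix}.map"
        )
        id_sets.append(set(out["genotypes"].index))
    elif genotype_path is not None:
        out["genotypes"] = read_genotypes_tsv(genotype_path)
        id_sets.append(set(out["genotypes"].index))
    if otu_path is not None:
        out["otu"] = read_otu_table(otu_path, taxonomy_path)
        id_sets.append(set(out["otu"].sample_ids))
    if pedigree_path is not None:
        out["pedigree"] = read_pedigree(pedigree_path)

    if id_sets:
        shared = sorted(set.intersection(*id_sets))
        if not shared:
            raise FormatError("no animal IDs shared across the input tables")
        union = set.union(*id_sets)
        orphans = sorted(union - set(shared))
        if orphans:
            logger.warning(
                "%d animal IDs not present in every table were dropped: %s%s",
                len(orphans), orphans[:10], "..." if len(orphans) > 10 else "",
            )
        if "phenotype" in out:
            out["phenotype"] = out["phenotype"].loc[shared]
        if "genotypes" in out:
            out["genotypes"] = out["genotypes"].loc[shared]
        if "otu" in out:
            out["otu"] = out["otu"].subset_samples(shared)
        out["ids"] = pd.Index(shared, name="animal")
    return out
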