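import numpy as np
import pandas as pd
import pytest

from micropart import kinship, simulate
from micropart.containers import OTUTable


@pytest.fixture(scope="session")
def small_panel():
    """Unrelated genotype panel (n=200, m=2000) with its genomic matrix."""
    geno, ped = simulate.sim_genotypes(200, 2000, (0.05, 0.5), 0, seed=101)
    G = kinship.grm_yang(geno)
    return geno, ped, G


@pytest.fixture(scope="session")
def family_panel():
    """Half-sib family structure (n=500, m=2000) with its genomic matrix."""
    geno, ped = simulate.sim_genotypes(500, 2000, (0.05, 0.5), 25, seed=202)
    G = kinship.grm_yang(geno)
    return geno, ped, G


@pytest.fixture(scope="session")
def tiny_scenario(tmp_path_factory):
    """The tiny on-disk scenario (n=60), shared across IO tests."""
    outdir = tmp_path_factory.mktemp("tiny_scenario")
    paths = simulate.make_scenario("tiny", seed=7, outdir=outdir)
    return paths


@pytest.fixture
def toy_otu():
    """4 samples x 5 taxa with taxonomy, instrument labels and zeros."""
    counts = pd.DataFrame(
        [
            [5, 0, 3, 1, 10],
            [2, 8, 0, 1, 4],
            [0, 1, 6, 2, 0],
            [7, 0, 0, 3, 2],
        ],
        index=pd.Index(["c1", "c2", "c3", "c4"], name="animal"),
        columns=["t1", "t2", "t3", "t4", "t5"],
    )
    tax = pd.Series(
        [
            "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__Blautia",
            "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__Blautia",
            "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Prevotellaceae;g__Prevotella",
            "k__Archaea;p__Euryarchaeota;c__Methanobacteria;o__Methanobacteriales",
            "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales",
        ],
        index=counts.columns,
    )
    instr = pd.Series(["HiSeq", "HiSeq", "MiSeq", "MiSeq"], index=counts.index)
    return OTUTable(counts, tax, instr)
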