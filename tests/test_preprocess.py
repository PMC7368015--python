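import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from micropart.containers import OTUTable
from micropart.preprocess import (
    CLRTransformer,
    LogStandardizer,
    SNPQC,
    build_fixed_design,
    clr_transform,
    collapse_to_genus,
    hwe_test,
    log_standardize,
    otu_prevalence_filter,
    precorrect_phenotype,
    snp_qc,
)


class TestHWE:
    def test_perfect_proportions_retained(self):
        # (AA=25, Aa=50, aa=25) is exact HWE at p=0.5.
        assert hwe_test(25, 50, 25) > 0.9

    def test_strong_deviation_detected(self):
        # All heterozygotes at n=200: wildly non-HWE.
        assert hwe_test(0, 200, 0) < 1e-8

    def test_exact_matches_enumeration_small(self):
        # Independent check: direct enumeration of the conditional
        # distribution of heterozygote counts at tiny n.
        from math import comb

        n_het, n_hom1, n_hom2 = 2, 3, 1
        n = n_het + n_hom1 + n_hom2
        n_rare = n_het + 2 * min(n_hom1, n_hom2)
        probs = {}
        for h in range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2):
            rare = (n_rare - h) // 2
            common = n - h - rare
            from math import factorial

            probs[h] = 2.0**h / (
                factorial(h) * factorial(rare) * factorial(common)
            )
        total = sum(probs.values())
        obs = probs[n_het] / total
        expected = sum(v / total for v in probs.values() if v / total <= obs + 1e-12)
        assert hwe_test(n_hom1, n_het, n_hom2) == pytest.approx(expected, rel=1e-9)


class TestSNPQC:
    def test_monomorphic_removed_by_maf(self):
        geno = pd.DataFrame(
            {"mono": [0] * 100, "ok": [0, 1, 2] * 33 + [1]},
            index=[f"a{i}" for i in range(100)],
        )
        out = snp_qc(geno)
        assert list(out.columns) == ["ok"]

    def test_engineered_failures_match_brute_force(self):
        # Enough clean background SNPs that one missing genotype does not
        # push an individual below the 99% call-rate threshold.
        rng = np.random.default_rng(9)
        n, m_bg = 200, 150
        geno = pd.DataFrame(
            rng.binomial(2, 0.3, size=(n, m_bg)).astype(float),
            columns=[f"s{i}" for i in range(m_bg)],
            index=[f"a{i}" for i in range(n)],
        )
        geno["low_maf"] = rng.binomial(2, 0.005, size=n).astype(float)
        bad_call = rng.binomial(2, 0.3, size=n).astype(float)
        bad_call[: int(0.05 * n)] = np.nan
        geno["low_call"] = bad_call
        out = snp_qc(geno)
        # Brute-force recount of the two engineered failures.
        assert "low_call" not in out.columns
        assert "low_maf" not in out.columns
        kept_bg = [
            c for c in geno.columns[:m_bg]
            if min(geno[c].mean() / 2, 1 - geno[c].mean() / 2) >= 0.02
            and hwe_test(
                int((geno[c] == 0).sum()),
                int((geno[c] == 1).sum()),
                int((geno[c] == 2).sum()),
            ) >= 1e-8
        ]
        assert list(out.columns) == kept_bg

    def test_individual_call_rate_filter(self):
        rng = np.random.default_rng(10)
        X = rng.binomial(2, 0.4, size=(50, 100)).astype(float)
        X[0, :50] = np.nan  # 50% call rate individual
        geno = pd.DataFrame(X, index=[f"a{i}" for i in range(50)])
        qc = SNPQC().fit(geno)
        assert "a0" not in qc.kept_individuals_
        assert qc.attrition_["individual_call_rate"] == 1

    def test_imputation_fills_missing_with_mean(self):
        rng = np.random.default_rng(11)
        X = rng.binomial(2, 0.4, size=(100, 20)).astype(float)
        X[rng.random(X.shape) < 0.02] = np.nan
        geno = pd.DataFrame(X, index=[f"a{i}" for i in range(100)])
        out = snp_qc(geno, ind_call_min=0.0, snp_call_min=0.0)
        assert not out.isna().any().any()
        # Imputed entries equal the observed SNP mean.
        j = np.argwhere(np.isnan(X))[0]
        col = geno.columns[j[1]]
        assert out.loc[f"a{j[0]}", col] == pytest.approx(
            geno[col].mean(), abs=1e-12
        )

    def test_all_removed_is_fatal(self):
        geno = pd.DataFrame({"mono": [0.0] * 20})
        with pytest.raises(ValueError, match="attrition"):
            snp_qc(geno)


class TestPrevalenceFilter:
    def test_boundary_inclusive(self):
        counts = pd.DataFrame(
            {"half": [1, 2, 0, 0], "quarter": [3, 0, 0, 0]},
            index=list("abcd"),
        )
        out = otu_prevalence_filter(
            OTUTable(counts), min_prevalence=0.5
        )
        assert list(out.taxon_ids) == ["half"]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.poisson(0.8, size=(20, 50)),
            columns=[f"t{i}" for i in range(50)],
        )
        out = otu_prevalence_filter(OTUTable(counts), 0.5)
        expected = [
            c for c in counts.columns if (counts[c] > 0).sum() >= 10
        ]
        assert list(out.taxon_ids) == expected


class TestLogStandardize:
    def test_zero_count_closed_form(self):
        # ln(0 + 0.001) = -6.9078 before standardization.
        assert np.log(0.001) == pytest.approx(-6.9078, abs=1e-4)

    def test_columns_standardized(self, toy_otu):
        M = log_standardize(toy_otu)
        assert np.allclose(M.M.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(M.M.var(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_matches_hand_zscore(self):
        counts = pd.DataFrame(
            [[1, 10, 0], [2, 20, 5], [3, 30, 1], [4, 40, 2], [5, 50, 3]],
            index=list("abcde"),
        )
        M = log_standardize(OTUTable(counts)).M
        L = np.log(counts.values + 0.001)
        expected = (L - L.mean(0)) / L.std(0, ddof=1)
        assert np.allclose(M, expected, atol=1e-12)

    def test_zero_variance_column_errors(self):
        counts = pd.DataFrame({"const": [2, 2, 2], "ok": [1, 2, 3]})
        with pytest.raises(ValueError, match="const"):
            log_standardize(OTUTable(counts))

    def test_commutes_with_sample_reordering(self, toy_otu):
        M1 = log_standardize(otu_prevalence_filter(toy_otu)).to_frame()
        shuffled = toy_otu.subset_samples(["c3", "c1", "c4", "c2"])
        M2 = log_standardize(otu_prevalence_filter(shuffled)).to_frame()
        assert np.allclose(M1.loc[M2.index].values, M2.values, atol=1e-12)

    def test_per_instrument_centers_within_group(self):
        rng = np.random.default_rng(13)
        counts = pd.DataFrame(
            rng.poisson(20, size=(8, 4)) + np.arange(8)[:, None],
            index=[f"c{i}" for i in range(8)],
        )
        instr = pd.Series(["HiSeq"] * 4 + ["MiSeq"] * 4, index=counts.index)
        table = OTUTable(counts, instrument=instr)
        M = log_standardize(table, per_instrument=True).to_frame()
        for group in ("HiSeq", "MiSeq"):
            rows = instr[instr == group].index
            assert np.allclose(M.loc[rows].mean(axis=0), 0.0, atol=1e-10)


class TestCLR:
    def test_uniform_composition_maps_to_zero(self):
        counts = pd.DataFrame([[1, 1, 1, 1]])
        Z = CLRTransformer().fit_transform(counts)
        assert np.allclose(Z.values, 0.0, atol=1e-12)

    def test_two_part_closed_form(self):
        counts = pd.DataFrame([[2, 8]])
        Z = CLRTransformer().fit_transform(counts)
        assert Z.values[0, 0] == pytest.approx(-0.6931, abs=1e-4)
        assert Z.values[0, 1] == pytest.approx(0.6931, abs=1e-4)

    def test_rows_sum_to_zero(self, toy_otu):
        M = clr_transform(toy_otu)
        assert np.allclose(M.M.sum(axis=1), 0.0, atol=1e-10)

    def test_all_zero_sample_errors(self):
        counts = pd.DataFrame([[0, 0], [1, 2]], index=["z", "ok"])
        with pytest.raises(ValueError, match="all-zero"):
            clr_transform(OTUTable(counts))

    @given(
        st.lists(
            st.integers(min_value=1, max_value=1000), min_size=3, max_size=8
        ),
        st.integers(min_value=2, max_value=7),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance_on_zero_free_samples(self, row, factor):
        counts = pd.DataFrame([row])
        scaled = pd.DataFrame([[factor * v for v in row]])
        z1 = CLRTransformer().fit_transform(counts).values
        z2 = CLRTransformer().fit_transform(scaled).values
        assert np.allclose(z1, z2, atol=1e-10)


class TestNestByInstrument:
    def test_columns_doubled_and_masked(self):
        rng = np.random.default_rng(14)
        counts = pd.DataFrame(
            rng.poisson(20, size=(6, 3)) + 1, index=[f"c{i}" for i in range(6)]
        )
        instr = pd.Series(["HiSeq"] * 3 + ["MiSeq"] * 3, index=counts.index)
        from micropart.preprocess import log_standardize, nest_by_instrument

        M = log_standardize(OTUTable(counts, instrument=instr))
        nested = nest_by_instrument(M)
        assert nested.M.shape == (6, 6)
        # HiSeq block is zero on MiSeq rows and vice versa; the two blocks
        # sum back to the shared design.
        assert np.allclose(nested.M[3:, :3], 0.0)
        assert np.allclose(nested.M[:3, 3:], 0.0)
        assert np.allclose(nested.M[:, :3] + nested.M[:, 3:], M.M)

    def test_requires_instrument_labels(self):
        rng = np.random.default_rng(15)
        counts = pd.DataFrame(rng.poisson(20, size=(4, 2)) + 1)
        from micropart.preprocess import log_standardize, nest_by_instrument

        M = log_standardize(OTUTable(counts))
        with pytest.raises(ValueError, match="instrument"):
            nest_by_instrument(M)


class TestCollapseToGenus:
    def test_same_genus_summed(self, toy_otu):
        out = collapse_to_genus(toy_otu)
        blautia = [c for c in out.taxon_ids if "Blautia" in c]
        assert len(blautia) == 1
        expected = toy_otu.counts[["t1", "t2"]].sum(axis=1)
        assert (out.counts[blautia[0]] == expected).all()

    def test_matches_brute_force_groupby(self, toy_otu):
        out = collapse_to_genus(toy_otu)
        # Unclassified-at-genus rows group by their deepest assigned rank.
        assert out.n_taxa == 4  # Blautia, Prevotella, o__Methanobacteriales, o__Clostridiales
        assert out.counts.values.sum() == toy_otu.counts.values.sum()

    def test_all_distinct_genera_preserves_counts(self):
        counts = pd.DataFrame([[1, 2], [3, 4]], columns=["a", "b"])
        tax = pd.Series(
            ["k__B;p__X;c__C;o__O;f__F;g__G1", "k__B;p__X;c__C;o__O;f__F;g__G2"],
            index=["a", "b"],
        )
        out = collapse_to_genus(OTUTable(counts, tax))
        assert out.n_taxa == 2
        assert sorted(out.counts.sum()) == sorted(counts.sum())

    def test_missing_taxonomy_errors(self):
        with pytest.raises(ValueError, match="taxonomy"):
            collapse_to_genus(OTUTable(pd.DataFrame([[1]])))


class TestFixedDesign:
    def make_pheno(self, n=240, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "herd": rng.integers(1, 7, n),
                "parity": rng.integers(1, 5, n),
                "dim": rng.integers(1, 351, n),
            },
            index=[f"a{i}" for i in range(n)],
        )

    def test_column_count_six_herds_four_parities(self):
        design = build_fixed_design(self.make_pheno())
        # intercept + 5 herd + 3 parity + dim + wilmink = 11
        assert design.k == 11

    def test_wilmink_term_monotone_decreasing(self):
        pheno = self.make_pheno()
        design = build_fixed_design(pheno)
        j = design.column_names.index("wilmink")
        w = design.X[:, j]
        order = np.argsort(pheno["dim"].values)
        assert (np.diff(w[order]) <= 1e-12).all()
        # At DIM=0 the term would equal exp(0) = 1.
        assert np.exp(-0.05 * 0) == 1.0

    def test_single_level_factor_omitted(self):
        pheno = self.make_pheno()
        pheno["herd"] = 1
        design = build_fixed_design(pheno)
        assert not any(c.startswith("herd") for c in design.column_names)

    def test_permutation_invariance_of_fit(self):
        rng = np.random.default_rng(2)
        pheno = self.make_pheno()
        y = rng.standard_normal(len(pheno))
        d1 = build_fixed_design(pheno)
        g1, *_ = np.linalg.lstsq(d1.X, y, rcond=None)
        perm = rng.permutation(len(pheno))
        d2 = build_fixed_design(pheno.iloc[perm])
        g2, *_ = np.linalg.lstsq(d2.X, y[perm], rcond=None)
        assert np.allclose(g1, g2, atol=1e-8)


class TestPrecorrect:
    def test_exact_fit_gives_zero(self):
        design = build_fixed_design(
            TestFixedDesign().make_pheno(n=100, seed=1)
        )
        c = np.arange(design.k, dtype=float)
        y = design.X @ c
        resid = precorrect_phenotype(y, design)
        assert np.allclose(resid, 0.0, atol=1e-8)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(8)
        design = build_fixed_design(
            TestFixedDesign().make_pheno(n=150, seed=3)
        )
        y = rng.standard_normal(150)
        resid = precorrect_phenotype(y, design)
        assert np.max(np.abs(resid @ design.X)) < 1e-6

    def test_orthogonal_input_unchanged(self):
        rng = np.random.default_rng(12)
        design = build_fixed_design(
            TestFixedDesign().make_pheno(n=100, seed=4)
        )
        y = rng.standard_normal(100)
        resid = precorrect_phenotype(y, design)
        again = precorrect_phenotype(resid, design)
        assert np.allclose(resid, again, atol=1e-8)
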