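"""cis metQTL, conditional EWAS, expression links and summaries."""

import numpy as np
import pandas as pd
import pytest

from lipidewas.ewas import prepare_trait
from lipidewas.integrate import (
    cis_expression_association,
    cis_met_qtl,
    classify_genetic_regulation,
    conditional_ewas,
    distance_summaries,
    expression_trait_association,
    set_overlap_enrichment,
)
from lipidewas.qc import MethylationMatrix


def covariate_frame(rng, samples):
    n = len(samples)
    return pd.DataFrame(
        {
            "age": rng.normal(50, 8, n),
            "sex": rng.integers(0, 2, n),
            "bmi": rng.normal(45, 4, n),
            "batch": np.where(rng.random(n) < 0.5, "A", "B"),
        },
        index=samples,
    )


def matrix(meth, positions, samples):
    meth = pd.DataFrame(meth, columns=samples)
    meth.index = [f"chr1:{p}" for p in positions]
    cov = pd.DataFrame(25.0, index=meth.index, columns=samples)
    posf = pd.DataFrame({"chrom": "chr1", "pos": positions}, index=meth.index)
    return MethylationMatrix(meth, cov, posf)


class TestCisMetQtl:
    def _setup(self, rng, n=200, cpg_pos=(500_000,), snp_pos=(510_000,), gamma=0.0):
        samples = pd.Index([f"S{i:03d}" for i in range(n)], name="sample")
        dosages = pd.DataFrame(
            rng.binomial(2, 0.3, (len(snp_pos), n)),
            index=[f"snp{j}" for j in range(len(snp_pos))],
            columns=samples,
        )
        snp_info = pd.DataFrame(
            {"chrom": "chr1", "pos": snp_pos, "maf": 0.3}, index=dosages.index
        )
        meth = np.clip(
            0.4
            + gamma * dosages.iloc[0].to_numpy() / 2.0
            + rng.normal(0, 0.05, (len(cpg_pos), n)),
            0.01, 0.99,
        )
        mat = matrix(meth, list(cpg_pos), samples)
        return mat, dosages, snp_info, covariate_frame(rng, samples)

    def test_window_boundary_inclusive(self, rng):
        mat, dos, info, cov = self._setup(
            rng, cpg_pos=(500_000,), snp_pos=(750_000, 750_001)
        )
        res = cis_met_qtl(mat, dos, info, cov, window=250_000)
        assert set(res["snp_id"]) == {"snp0"}  # 250,001 bp away excluded

    def test_planted_slope_sign_recovered(self, rng):
        mat, dos, info, cov = self._setup(rng, n=500, gamma=0.3)
        res = cis_met_qtl(mat, dos, info, cov)
        assert res.iloc[0]["slope"] > 0
        assert res.iloc[0]["p"] < 1e-6

    def test_constant_dosage_skipped(self, rng):
        mat, dos, info, cov = self._setup(rng)
        dos.iloc[0, :] = 2
        res = cis_met_qtl(mat, dos, info, cov)
        assert res.empty

    def test_matches_ols_oracle(self, rng):
        import statsmodels.api as sm
        from lipidewas.ewas import build_design

        mat, dos, info, cov = self._setup(rng, n=80, gamma=0.2)
        res = cis_met_qtl(mat, dos, info, cov)
        D = np.column_stack([np.ones(80), build_design(cov).to_numpy(), dos.iloc[0]])
        fit = sm.OLS(mat.meth.iloc[0].to_numpy(), D).fit()
        assert res.iloc[0]["slope"] == pytest.approx(fit.params[-1], abs=1e-10)
        assert res.iloc[0]["p"] == pytest.approx(fit.pvalues[-1], abs=1e-10)

    def test_slope_bias_small(self, rng):
        biases = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            mat, dos, info, cov = self._setup(r, n=500, gamma=0.2)
            res = cis_met_qtl(mat, dos, info, cov)
            biases.append(res.iloc[0]["slope"] - 0.1)  # gamma/2 per allele
        assert abs(np.mean(biases)) < 0.01  # < 10% of the planted 0.1


class TestClassifyGeneticRegulation:
    def test_printed_fold_changes(self):
        # group-level folds recomputed from the printed count pairs
        from lipidewas.regions import fisher_enrichment

        assert fisher_enrichment(362, 567, 22101, 50759).fold == 1.5
        assert fisher_enrichment(63, 68, 22101, 50759).fold == 2.1

    def test_element_flags_and_zero_group(self):
        qtls = pd.DataFrame(
            {"cpg_id": ["chr1:100"], "snp_id": ["s"], "q": [0.01]}
        )
        assignment = pd.Series(["E1", "E2", None])
        ids = pd.Series(["chr1:100", "chr1:200", "chr1:300"])
        flags, enrich = classify_genetic_regulation(
            qtls, assignment, ids,
            groups={"with_qtl": {"E1"}, "without": {"E2"}},
            background={"E1", "E2"},
        )
        assert flags["E1"] and not flags["E2"]
        assert enrich["with_qtl"].proportion_fg == 1.0
        assert enrich["without"].proportion_fg == 0.0
        assert enrich["without"].fold == 0.0


class TestConditionalEwas:
    def _setup(self, rng, n=500, snp_driven=False):
        samples = pd.Index([f"S{i:03d}" for i in range(n)], name="sample")
        dosage = pd.Series(rng.binomial(2, 0.3, n).astype(float), index=samples)
        cov = covariate_frame(rng, samples)
        if snp_driven:
            # methylation fully SNP-driven; trait linked only through the SNP
            latent = 0.3 + 0.15 * dosage.to_numpy()
            trait_raw = dosage.to_numpy() + rng.normal(0, 0.5, n)
        else:
            latent = np.full(n, 0.4)
            trait_raw = rng.normal(0, 1, n)
        meth = np.clip(latent + rng.normal(0, 0.03, n), 0.01, 0.99)
        mat = matrix(meth[None, :], [1000], samples)
        trait = prepare_trait(pd.Series(trait_raw, index=samples))
        return mat, trait, cov, dosage

    def test_independent_dosage_leaves_z_unchanged(self, rng):
        mat, trait, cov, dosage = self._setup(rng)
        res = conditional_ewas(mat, trait, cov, dosage)
        row = res.iloc[0]
        assert abs(row["z_conditional"] - row["z_marginal"]) < 0.2

    def test_snp_mediated_association_nulls_out(self, rng):
        mat, trait, cov, dosage = self._setup(rng, snp_driven=True)
        res = conditional_ewas(mat, trait, cov, dosage)
        row = res.iloc[0]
        assert row["p_marginal"] < 1e-8
        assert row["p_conditional"] > 0.01
        assert row["attenuation"] > 1.0

    def test_constant_dosage_raises(self, rng):
        mat, trait, cov, dosage = self._setup(rng)
        with pytest.raises(ValueError, match="constant dosage"):
            conditional_ewas(mat, trait, cov, dosage * 0 + 1)


class TestCisExpression:
    def _setup(self, rng, n=100, gene_offset=5_000, delta=0.0):
        samples = pd.Index([f"S{i:03d}" for i in range(n)], name="sample")
        meth = np.clip(rng.uniform(0.2, 0.8, (1, n)), 0.01, 0.99)
        mat = matrix(meth, [500_000], samples)
        expr = 8.0 + delta * meth[0] + rng.normal(0, 0.5, n)
        expression = pd.DataFrame(expr[None, :], index=["g1"], columns=samples)
        genes = pd.DataFrame(
            {"chrom": "chr1", "start": [500_000 + gene_offset],
             "end": [500_000 + gene_offset + 10_000], "gene_id": ["g1"]}
        )
        return mat, expression, genes, covariate_frame(rng, samples)

    def test_identical_fit_and_null_lrt_zero(self, rng):
        mat, expression, genes, cov = self._setup(rng)
        expression.loc["g1"] = 5.0  # constant expression -> skipped
        res = cis_expression_association(mat, expression, genes, cov)
        assert res.empty

    def test_lrt_matches_two_fit_oracle(self, rng):
        import statsmodels.api as sm
        from lipidewas.ewas import build_design

        mat, expression, genes, cov = self._setup(rng, delta=2.0)
        res = cis_expression_association(mat, expression, genes, cov)
        D = np.column_stack([np.ones(100), build_design(cov).to_numpy()])
        y = mat.meth.iloc[0].to_numpy()
        e = expression.iloc[0].to_numpy()
        full = sm.OLS(y, np.column_stack([D, e])).fit()
        null = sm.OLS(y, D).fit()
        assert res.iloc[0]["lrt"] == pytest.approx(2 * (full.llf - null.llf), abs=1e-8)

    def test_window_boundary_exclusive_beyond_1mb(self, rng):
        mat, expression, genes, cov = self._setup(rng, gene_offset=1_000_001)
        res = cis_expression_association(mat, expression, genes, cov)
        assert res.empty
        mat, expression, genes, cov = self._setup(rng, gene_offset=999_000)
        res = cis_expression_association(mat, expression, genes, cov)
        assert len(res) == 1


class TestExpressionTrait:
    def test_planted_link_recovered_and_null_uniformish(self, rng):
        n = 300
        samples = pd.Index([f"S{i:03d}" for i in range(n)], name="sample")
        cov = covariate_frame(rng, samples)
        trait = prepare_trait(pd.Series(rng.normal(size=n), index=samples))
        t = trait.values.to_numpy()
        expr = np.vstack([
            8 + 0.8 * t + rng.normal(0, 1, n),   # planted
            rng.normal(8, 1, (20, n)),           # null genes
        ])
        expression = pd.DataFrame(
            expr, index=[f"g{i}" for i in range(21)], columns=samples
        )
        res = expression_trait_association(expression, trait, cov)
        assert res.iloc[0]["p"] < 1e-10
        assert res.iloc[0]["direction"] == 1.0
        assert (res.iloc[1:]["p"] < 0.05).sum() <= 4

    def test_constant_trait_raises(self, rng):
        n = 50
        samples = pd.Index([f"S{i:03d}" for i in range(n)], name="sample")
        cov = covariate_frame(rng, samples)
        trait = prepare_trait(pd.Series(rng.normal(size=n), index=samples))
        trait.values[:] = 0.0
        expression = pd.DataFrame(rng.normal(8, 1, (3, n)), columns=samples)
        with pytest.raises(ValueError, match="constant trait"):
            expression_trait_association(expression, trait, cov)


class TestSummaries:
    def test_single_gene_both_distances_equal(self):
        assocs = pd.DataFrame(
            {"cpg_id": ["chr1:5000"], "gene_id": ["g1"], "p": [1e-6], "q": [0.01]}
        )
        assignment = pd.Series(["E1"])
        ids = pd.Series(["chr1:5000"])
        elements = pd.DataFrame(
            [{"chrom": "chr1", "start": 4000, "end": 6000, "element_id": "E1",
              "class": "LMR", "specificity": "shared", "tss": -1,
              "tss_strand": ".", "bivalent": False}]
        )
        genes = pd.DataFrame(
            {"chrom": "chr1", "start": [15_000], "end": [20_000], "gene_id": ["g1"]}
        )
        table, summary = distance_summaries(assocs, assignment, ids, elements, genes)
        assert table.iloc[0]["dist_most_correlated"] == pytest.approx(10_000)
        assert table.iloc[0]["dist_most_proximal"] == pytest.approx(10_000)
        assert summary["n_multi_gene"] == 0

    def test_long_range_gene_dominates(self):
        assocs = pd.DataFrame(
            {
                "cpg_id": ["chr1:5000", "chr1:5000"],
                "gene_id": ["far", "near"],
                "p": [1e-9, 1e-3],
                "q": [0.001, 0.05],
            }
        )
        assignment = pd.Series(["E1"])
        ids = pd.Series(["chr1:5000"])
        elements = pd.DataFrame(
            [{"chrom": "chr1", "start": 4000, "end": 6000, "element_id": "E1",
              "class": "LMR", "specificity": "shared", "tss": -1,
              "tss_strand": ".", "bivalent": False}]
        )
        genes = pd.DataFrame(
            {"chrom": "chr1", "start": [500_000, 10_000],
             "end": [510_000, 15_000], "gene_id": ["far", "near"]}
        )
        table, summary = distance_summaries(assocs, assignment, ids, elements, genes)
        row = table.iloc[0]
        assert row["most_correlated_gene"] == "far"
        assert row["dist_most_correlated"] > row["dist_most_proximal"]
        assert summary["frac_multi_gene"] == 1.0


class TestSetOverlap:
    def test_printed_fold(self):
        universe = {f"u{i}" for i in range(15_815)}
        catalog = {f"u{i}" for i in range(692)}
        hits = {f"u{i}" for i in range(6)} | {f"u{i}" for i in range(10_000, 10_014)}
        res = set_overlap_enrichment(hits, catalog, universe)
        assert res.fold == 6.9
        assert res.p < 0.001

    def test_empty_hits_raises(self):
        with pytest.raises(ValueError):
            set_overlap_enrichment(set(), {"a"}, {"a", "b"})

    def test_hits_equal_universe_fold_one(self):
        universe = {f"u{i}" for i in range(100)}
        catalog = {f"u{i}" for i in range(20)}
        res = set_overlap_enrichment(universe, catalog, universe)
        assert res.fold == 1.0
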