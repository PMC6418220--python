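"""Synthetic-cohort generator: geometry, densities, determinism, truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidewas.simulate import (
    SimulationConfig,
    SyntheticTruth,
    generate_cohort,
    generate_cpgs,
    generate_elements,
    generate_study,
    simulate_genotypes,
    simulate_phenotypes,
    read_cohort,
    write_cohort,
)

from conftest import small_config


class TestElements:
    def test_counts_and_disjointness(self):
        cfg = small_config(n_elements_lmr=10, n_elements_umr=10)
        el = generate_elements(cfg)
        assert len(el) == 20
        assert (el["class"] == "UMR").sum() == 10
        assert (el["tss"] >= 0).sum() == 10  # only UMRs carry a TSS
        sorted_el = el.sort_values("start")
        assert (sorted_el["start"].to_numpy()[1:] >= sorted_el["end"].to_numpy()[:-1]).all()
        assert (el["start"] < el["end"]).all()

    def test_tss_at_midpoint(self):
        el = generate_elements(small_config())
        umr = el[el["class"] == "UMR"]
        assert (umr["tss"] == (umr["start"] + umr["end"]) // 2).all()

    def test_deterministic_under_seed(self):
        a = generate_elements(small_config(seed=9))
        b = generate_elements(small_config(seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_chromosome_too_short(self):
        cfg = small_config(chrom_length=10_000, n_elements_umr=50)
        with pytest.raises(ValueError, match="too short"):
            generate_elements(cfg)


class TestCpGs:
    def test_densities_match_configured_means(self):
        # 7 CpGs per enhancer, 37 per promoter on average
        cfg = SimulationConfig(seed=3, n_elements_lmr=300, n_elements_umr=300)
        el = generate_elements(cfg)
        cpgs = generate_cpgs(el, cfg)
        pos = cpgs["pos"].to_numpy()
        for cls, mean in (("LMR", 7.0), ("UMR", 37.0)):
            sub = el[el["class"] == cls]
            n_in = sum(
                ((pos >= s) & (pos < e)).sum() for s, e in zip(sub["start"], sub["end"])
            )
            per_element = n_in / len(sub)
            # Poisson sampling: SE of the mean ~ sqrt(mean/300)
            assert per_element == pytest.approx(mean, rel=0.05)

    def test_sorted_unique(self, small_cohort):
        pos = small_cohort.cpgs["pos"].to_numpy()
        assert (np.diff(pos) > 0).all()

    def test_zero_background_keeps_all_inside(self):
        cfg = small_config(background_cpg_frac=0.0)
        el = generate_elements(cfg)
        cpgs = generate_cpgs(el, cfg)
        pos = cpgs["pos"].to_numpy()
        starts = el["start"].to_numpy()
        ends = el["end"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(el) - 1)])
        assert inside.all()


class TestPhenotypes:
    def test_cell_proportions_simplex_and_reproducible(self):
        cfg = small_config()
        a = simulate_phenotypes(cfg, 200)
        b = simulate_phenotypes(cfg, 200)
        pd.testing.assert_frame_equal(a, b)
        cells = a[[c for c in a.columns if c.startswith("cell_")]].to_numpy()
        np.testing.assert_allclose(cells.sum(axis=1), 1.0, atol=1e-12)

    def test_tg_lognormal_support(self):
        pheno = simulate_phenotypes(small_config(), 1000)
        assert (pheno["TG"] > 0).all()
        assert stats.skew(pheno["TG"]) > 0.5  # right-skewed

    def test_zero_trait_correlation_recovered(self):
        pheno = simulate_phenotypes(small_config(trait_corr=0.0), 2000)
        corr = pheno[["TG", "HDL", "LDL", "TC"]].corr().to_numpy()
        off = corr[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 3 / np.sqrt(2000)

    def test_rejects_tiny_n(self):
        with pytest.raises(ValueError):
            simulate_phenotypes(small_config(), 1)


class TestGenotypes:
    def test_reproducible_and_polymorphic(self):
        cfg = small_config()
        d1, i1 = simulate_genotypes(cfg, 100)
        d2, i2 = simulate_genotypes(cfg, 100)
        pd.testing.assert_frame_equal(d1, d2)
        assert (d1.std(axis=1) > 0).all()

    def test_allele_frequency_matches_maf(self):
        cfg = small_config(n_snps=200)
        dos, info = simulate_genotypes(cfg, 2000)
        freq = dos.mean(axis=1) / 2.0
        resid = freq.to_numpy() - info["maf"].to_numpy()
        se = np.sqrt(info["maf"] * (1 - info["maf"]) / (2 * 2000))
        assert np.mean(np.abs(resid) < 3 * se) > 0.95


class TestMethylationCounts:
    def test_counts_are_consistent(self, small_cohort):
        c = small_cohort.counts
        assert (c.meth_fwd.to_numpy() <= c.total_fwd.to_numpy()).all()
        assert (c.meth_rev.to_numpy() <= c.total_rev.to_numpy()).all()
        assert (c.total_fwd.to_numpy() >= 0).all()

    def test_null_model_matches_baseline(self):
        # with no overdispersion/noise/effects, pooled proportions track
        # the latent methylation within binomial error
        cfg = small_config(
            beta_dispersion=0.0, sample_noise_sd=0.0,
            frac_lipid_cpgs=0.0, frac_metqtl_cpgs=0.0, n_samples=100,
        )
        coh = generate_cohort(cfg)
        total = coh.counts.total_fwd + coh.counts.total_rev
        meth = coh.counts.meth_fwd + coh.counts.meth_rev
        pooled = meth.sum(axis=1) / total.sum(axis=1)
        latent = coh.latent_meth.mean(axis=1)
        resid = pooled - latent
        assert np.nanmedian(np.abs(resid)) < 0.01

    def test_planted_effect_sign_recovered(self):
        cfg = small_config(seed=12, n_samples=500, effect_size_logit=0.5)
        coh = generate_cohort(cfg)
        total = coh.counts.total_fwd + coh.counts.total_rev
        meth = coh.counts.meth_fwd + coh.counts.meth_rev
        ok_signs = 0
        checked = 0
        for cpg, rec in list(coh.truth.lipid.items())[:20]:
            m = (meth.loc[cpg] / total.loc[cpg].replace(0, np.nan)).astype(float)
            trait = coh.phenotypes[rec["trait"]]
            rho = stats.spearmanr(m, trait, nan_policy="omit").statistic
            checked += 1
            if np.sign(rho) == np.sign(rec["beta"]):
                ok_signs += 1
        assert checked > 0 and ok_signs / checked >= 0.9

    def test_zero_coverage_is_missing_not_error(self):
        cfg = small_config(coverage_dispersion=3.0)  # heavy-tailed coverage -> zeros
        coh = generate_cohort(cfg)
        total = (coh.counts.total_fwd + coh.counts.total_rev).to_numpy()
        assert (total == 0).any()


class TestTruthAndStudy:
    def test_truth_registry_roundtrip(self, small_cohort, tmp_path):
        path = tmp_path / "truth.json"
        small_cohort.truth.to_json(path)
        back = SyntheticTruth.from_json(path)
        assert back.lipid == small_cohort.truth.lipid
        assert back.metqtl == small_cohort.truth.metqtl
        assert back.expr == small_cohort.truth.expr

    def test_truth_references_valid_ids(self, small_cohort):
        small_cohort.truth.validate(
            small_cohort.cpgs["cpg_id"],
            small_cohort.genotypes.index,
            small_cohort.genes["gene_id"],
        )

    def test_cohort_write_read_roundtrip(self, small_cohort, tmp_path):
        write_cohort(small_cohort, tmp_path)
        back = read_cohort(tmp_path)
        np.testing.assert_array_equal(
            back.counts.meth_fwd.to_numpy(), small_cohort.counts.meth_fwd.to_numpy()
        )
        assert back.truth.lipid == small_cohort.truth.lipid
        assert set(back.array_mask) == set(small_cohort.array_mask)

    def test_replication_cohort_silences_specific_effects(self):
        cfg = small_config(seed=8)
        disc, repl = generate_study(cfg)
        assert not disc.phenotypes.index.equals(repl.phenotypes.index)
        pd.testing.assert_frame_equal(disc.elements, repl.elements)
        assert repl.truth is disc.truth

    def test_byte_identical_outputs_under_seed(self, tmp_path):
        cfg = small_config(seed=17)
        for d in ("a", "b"):
            write_cohort(generate_cohort(cfg), tmp_path / d)
        for name in ("cpg_counts.tsv", "elements.bed", "phenotypes.tsv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
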