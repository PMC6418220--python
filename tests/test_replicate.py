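"""Region-level replication classes, rate contrasts and fine-mapping."""

import numpy as np
import pandas as pd
import pytest

from lipidewas.replicate import (
    fine_map_contrast,
    rate_contrast_counts,
    replicate_regions,
    replication_rate_contrast,
)


def records(rows):
    return pd.DataFrame(
        rows,
        columns=["element_id", "trait", "cpg_id", "chrom", "pos",
                 "direction", "p_corrected"],
    )


def disc_ten_regions():
    rows = []
    for i in range(10):
        rows.append([f"E{i}", "TG", f"chr1:{100 + i * 10}", "chr1", 100 + i * 10, 1.0, 1e-6])
    return records(rows)


class TestReplicateRegions:
    def test_same_direction_replication(self):
        disc = disc_ten_regions()
        # one replication CpG per region; only E0's passes 0.05/100
        rows = [["E0", "TG", "chr1:100", "chr1", 100, 1.0, 1e-6]]
        for i in range(1, 10):
            for j in range(11):
                rows.append([f"E{i}", "TG", f"chr1:{100 + i * 10 + j}", "chr1",
                             100 + i * 10 + j, 1.0, 0.5])
        out = replicate_regions(disc, records(rows))
        assert out.loc[out["element_id"] == "E0", "class"].iloc[0] == "replicated_same_direction"
        assert (out.loc[out["element_id"] != "E0", "class"] == "not_replicated").all()

    def test_opposite_direction_replication(self):
        disc = disc_ten_regions()
        rows = [["E0", "TG", "chr1:100", "chr1", 100, -1.0, 1e-6]]
        for i in range(1, 10):
            rows.append([f"E{i}", "TG", f"chr1:{100 + i * 10}", "chr1", 100 + i * 10, 1.0, 0.5])
        out = replicate_regions(disc, records(rows))
        assert out.loc[out["element_id"] == "E0", "class"].iloc[0] == "replicated_opposite_direction"

    def test_untestable_region(self):
        disc = disc_ten_regions()
        repl = records([["E1", "TG", "chr1:110", "chr1", 110, 1.0, 0.5]])
        out = replicate_regions(disc, repl)
        assert out.loc[out["element_id"] == "E0", "class"].iloc[0] == "untestable"
        assert out.loc[out["element_id"] == "E0", "n_testable"].iloc[0] == 0

    def test_classes_partition_testable(self):
        rng = np.random.default_rng(1)
        disc_rows, repl_rows = [], []
        for i in range(30):
            disc_rows.append([f"E{i}", "TG", f"chr1:{i * 100}", "chr1", i * 100,
                              rng.choice([-1.0, 1.0]), 10 ** -rng.uniform(1, 8)])
            for j in range(rng.integers(0, 4)):
                repl_rows.append([f"E{i}", "TG", f"chr1:{i * 100 + j + 1}", "chr1",
                                  i * 100 + j + 1, rng.choice([-1.0, 1.0]),
                                  10 ** -rng.uniform(0, 6)])
        out = replicate_regions(records(disc_rows), records(repl_rows))
        counts = out["class"].value_counts()
        testable = (out["class"] != "untestable").sum()
        assert (
            counts.get("replicated_same_direction", 0)
            + counts.get("replicated_opposite_direction", 0)
            + counts.get("not_replicated", 0)
            == testable
        )

    def test_tightening_alpha_is_monotone(self):
        rng = np.random.default_rng(2)
        disc_rows, repl_rows = [], []
        for i in range(20):
            disc_rows.append([f"E{i}", "TG", f"chr1:{i * 100}", "chr1", i * 100, 1.0, 1e-5])
            repl_rows.append([f"E{i}", "TG", f"chr1:{i * 100 + 1}", "chr1", i * 100 + 1,
                              1.0, 10 ** -rng.uniform(0, 6)])
        disc, repl = records(disc_rows), records(repl_rows)
        loose = replicate_regions(disc, repl, alpha=0.05)
        tight = replicate_regions(disc, repl, alpha=0.005)
        was = set(loose.loc[loose["class"].str.startswith("replicated"), "element_id"])
        now = set(tight.loc[tight["class"].str.startswith("replicated"), "element_id"])
        assert now <= was

    def test_empty_discovery_raises(self):
        empty = records([])
        empty["element_id"] = pd.Series(dtype=object)
        with pytest.raises(ValueError):
            replicate_regions(empty, disc_ten_regions())


class TestRateContrast:
    def test_printed_rates_reproduce(self):
        res = rate_contrast_counts(46, 340, 12, 225)
        assert res["rate_a_pct"] == 14
        assert res["rate_b_pct"] == 5
        assert res["binomial_p"] < 0.05

    def test_two_fold_ratio(self):
        res = rate_contrast_counts(17, 46, 5, 28)
        assert res["ratio"] >= 2.0

    def test_identical_rates_ratio_one(self):
        res = rate_contrast_counts(10, 100, 5, 50)
        assert res["ratio"] == 1.0

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            rate_contrast_counts(5, 0, 1, 10)

    def test_outcome_wrapper_counts_same_direction(self):
        out = pd.DataFrame(
            {
                "element_id": ["A", "B", "C", "D"],
                "trait": "TG",
                "class": ["replicated_same_direction", "not_replicated",
                          "replicated_opposite_direction", "untestable"],
            }
        )
        res = replication_rate_contrast(out, {"A", "B"}, {"C", "D"})
        assert res["k_a"] == 1 and res["n_a"] == 2
        assert res["k_b"] == 0 and res["n_b"] == 1
        res2 = replication_rate_contrast(out, {"A", "B"}, {"C", "D"}, include_opposite=True)
        assert res2["k_b"] == 1


class TestFineMapping:
    def _elements(self):
        return pd.DataFrame(
            [
                {"chrom": "chr1", "start": 0, "end": 1000, "element_id": "L1",
                 "class": "LMR", "specificity": "shared", "tss": -1,
                 "tss_strand": ".", "bivalent": False},
                {"chrom": "chr1", "start": 2000, "end": 4000, "element_id": "U1",
                 "class": "UMR", "specificity": "shared", "tss": 3000,
                 "tss_strand": "+", "bivalent": False},
            ]
        )

    def test_refined_when_other_cpg_stronger(self):
        disc = records([
            ["L1", "TG", "chr1:500", "chr1", 500, 1.0, 1e-4],   # overlaps array CpG
            ["L1", "TG", "chr1:510", "chr1", 510, 1.0, 1e-6],   # stronger elsewhere
        ])
        repl = records([["L1", "TG", "chr1:500", "chr1", 500, 1.0, 1e-5]])
        out = fine_map_contrast(disc, repl, self._elements())
        row = out.iloc[0]
        assert row["status"] == "evaluated"
        assert row["refined"]
        assert row["best_other_band"] == "midpoint"  # 510 -> +1% from midpoint

    def test_single_cpg_region_skipped(self):
        disc = records([["L1", "TG", "chr1:500", "chr1", 500, 1.0, 1e-6]])
        repl = records([["L1", "TG", "chr1:500", "chr1", 500, 1.0, 1e-5]])
        out = fine_map_contrast(disc, repl, self._elements())
        assert out.iloc[0]["status"] == "skipped_single_cpg"

    def test_umr_bimodal_band(self):
        # percent distance of 2400 in [2000,4000) = (2400-3000)/2000*100 = -30
        disc = records([
            ["U1", "TG", "chr1:3000", "chr1", 3000, 1.0, 1e-3],
            ["U1", "TG", "chr1:2400", "chr1", 2400, 1.0, 1e-6],
        ])
        repl = records([["U1", "TG", "chr1:3000", "chr1", 3000, 1.0, 1e-5]])
        out = fine_map_contrast(disc, repl, self._elements())
        row = out.iloc[0]
        assert row["refined"]
        assert row["best_other_band"] == "bimodal"
        assert row["best_other_pos_pct"] == pytest.approx(-30.0)

    def test_no_overlap_skipped(self):
        disc = records([
            ["L1", "TG", "chr1:400", "chr1", 400, 1.0, 1e-4],
            ["L1", "TG", "chr1:510", "chr1", 510, 1.0, 1e-6],
        ])
        repl = records([["L1", "TG", "chr1:900", "chr1", 900, 1.0, 1e-5]])
        out = fine_map_contrast(disc, repl, self._elements())
        assert out.iloc[0]["status"] == "skipped_no_overlap"
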