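"""Region-level replication across cohorts/tissues and fine-mapping contrast.

A discovery region (regulatory element harboring significant CpGs for a
trait) replicates when at least one CpG of the region passes the
per-trait Bonferroni cutoff in the replication cohort; the direction of
the region is the sign of its top (smallest-p) CpG, and replication is
classed same-direction or opposite-direction accordingly.  Regions with
no testable replication CpG are 'untestable'.  The fine-mapping contrast
asks whether, within a replicated region, some sequencing-resolution CpG
not overlapping the replication top CpG carries a stronger association —
the added value of dense profiling over sparse arrays.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from lipidewas.adjust import bonferroni_threshold
from lipidewas.regions import percent_distance, round_half_up

__all__ = ["replicate_regions", "replication_rate_contrast", "rate_contrast_counts", "fine_map_contrast"]


def _top_record(records: pd.DataFrame, p_col: str) -> pd.Series:
    """Smallest p, ties broken by leftmost genomic coordinate."""
    sub = records.sort_values([p_col, "pos"], kind="mergesort")
    return sub.iloc[0]


def replicate_regions(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    alpha: float = 0.05,
    p_col: str = "p_corrected",
    repl_p_col: str | None = None,
    denominator: str = "global",
) -> pd.DataFrame:
    """Classify each discovery (region, trait) pair by replication outcome.

    ``discovery`` and ``replication`` are association tables with
    element_id, trait, cpg_id, pos, direction and a p column.  The
    Bonferroni denominator is, per trait, the number of replication
    tests across all candidate regions (``denominator='global'``, the
    default) or within each region (``'per_region'``).
    """
    if denominator not in ("global", "per_region"):
        raise ValueError("denominator must be 'global' or 'per_region'")
    if repl_p_col is None:
        repl_p_col = p_col
    disc = discovery[discovery["element_id"].notna()]
    if disc.empty:
        raise ValueError("no discovery CpGs annotated to regions")
    repl = replication[replication["element_id"].notna() & replication[repl_p_col].notna()]

    candidate_regions = disc[["element_id", "trait"]].drop_duplicates()
    repl_in_candidates = repl.merge(candidate_regions, on=["element_id", "trait"])
    n_tests_per_trait = repl_in_candidates.groupby("trait").size().to_dict()

    outcomes = []
    for (eid, trait), group in disc.groupby(["element_id", "trait"], sort=True):
        if group[p_col].notna().sum() == 0:
            continue
        top_d = _top_record(group[group[p_col].notna()], p_col)
        r = repl[(repl["element_id"] == eid) & (repl["trait"] == trait)]
        rec = {
            "element_id": eid,
            "trait": trait,
            "disc_top_cpg": top_d["cpg_id"],
            "disc_top_p": top_d[p_col],
            "disc_direction": top_d["direction"],
            "n_testable": int(len(r)),
            "repl_top_cpg": None,
            "repl_top_p": np.nan,
            "repl_direction": np.nan,
        }
        if len(r) == 0:
            rec["class"] = "untestable"
        else:
            n_tests = (
                n_tests_per_trait[trait] if denominator == "global" else len(r)
            )
            cutoff = bonferroni_threshold(n_tests, alpha)
            top_r = _top_record(r, repl_p_col)
            rec["repl_top_cpg"] = top_r["cpg_id"]
            rec["repl_top_p"] = top_r[repl_p_col]
            rec["repl_direction"] = top_r["direction"]
            passing = r[r[repl_p_col] <= cutoff]
            same = passing[passing["direction"] == top_d["direction"]]
            opposite = passing[passing["direction"] == -top_d["direction"]]
            if len(same):
                rec["class"] = "replicated_same_direction"
            elif len(opposite):
                rec["class"] = "replicated_opposite_direction"
            else:
                rec["class"] = "not_replicated"
        outcomes.append(rec)
    return pd.DataFrame(outcomes)


def rate_contrast_counts(k_a: int, n_a: int, k_b: int, n_b: int) -> dict:
    """Replication-rate contrast from raw counts.

    Rates are reported as nearest-integer percents, the ratio of rates
    half-up to one decimal, and group B's count is tested against group
    A's rate with an exact binomial test (two-sided).
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("empty group in rate contrast")
    from scipy import stats

    rate_a, rate_b = k_a / n_a, k_b / n_b
    return {
        "rate_a": rate_a,
        "rate_b": rate_b,
        "rate_a_pct": int(round(rate_a * 100)),
        "rate_b_pct": int(round(rate_b * 100)),
        "ratio": round_half_up(rate_a / rate_b) if rate_b > 0 else None,
        "binomial_p": float(stats.binomtest(k_b, n_b, rate_a).pvalue),
    }


def replication_rate_contrast(
    outcomes: pd.DataFrame,
    group_a: set,
    group_b: set,
    include_opposite: bool = False,
) -> dict:
    """Contrast replication rates between two region groups.

    Groups are element-id sets (e.g. tissue-shared vs adipose-specific).
    A (region, trait) outcome counts as replicated when classed
    same-direction (optionally also opposite-direction).  Denominators
    count testable outcomes (untestable regions excluded).
    """
    classes = ["replicated_same_direction"]
    if include_opposite:
        classes.append("replicated_opposite_direction")
    testable = outcomes[outcomes["class"] != "untestable"]
    in_a = testable[testable["element_id"].isin(group_a)]
    in_b = testable[testable["element_id"].isin(group_b)]
    if len(in_a) == 0 or len(in_b) == 0:
        raise ValueError("empty group in rate contrast")
    k_a = int(in_a["class"].isin(classes).sum())
    k_b = int(in_b["class"].isin(classes).sum())
    out = rate_contrast_counts(k_a, len(in_a), k_b, len(in_b))
    out.update({"k_a": k_a, "n_a": len(in_a), "k_b": k_b, "n_b": len(in_b)})
    return out


def fine_map_contrast(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    elements: pd.DataFrame,
    p_col: str = "p_corrected",
    repl_p_col: str | None = None,
    lmr_mid_band: float = 20.0,
    umr_band: tuple[float, float] = (20.0, 45.0),
) -> pd.DataFrame:
    """Fine-mapping verdict per (region, trait).

    Evaluable regions have >= 2 discovery CpGs of which one coincides
    with the replication top CpG position; the verdict is 'refined' when
    some non-overlapping discovery CpG has a smaller p.  Each evaluated
    CpG is also classed into positional bands: LMR midpoint band
    |pct| <= ``lmr_mid_band``; UMR bimodal band ``umr_band[0]`` <=
    |pct| <= ``umr_band[1]``.  Regions failing the precondition are
    returned with a status explaining the skip.
    """
    if repl_p_col is None:
        repl_p_col = p_col
    emap = elements.set_index("element_id")
    disc = discovery[discovery["element_id"].notna() & discovery[p_col].notna()]
    repl = replication[replication["element_id"].notna() & replication[repl_p_col].notna()]
    rows = []
    for (eid, trait), group in disc.groupby(["element_id", "trait"], sort=True):
        row = {"element_id": eid, "trait": trait, "n_discovery_cpgs": len(group)}
        r = repl[(repl["element_id"] == eid) & (repl["trait"] == trait)]
        if len(group) < 2:
            row["status"] = "skipped_single_cpg"
            rows.append(row)
            continue
        if len(r) == 0:
            row["status"] = "skipped_untestable"
            rows.append(row)
            continue
        top_r = _top_record(r, repl_p_col)
        overlap = group[group["pos"] == top_r["pos"]]
        if overlap.empty:
            row["status"] = "skipped_no_overlap"
            rows.append(row)
            continue
        p_overlap = float(overlap[p_col].min())
        others = group[group["pos"] != top_r["pos"]]
        p_best_other = float(others[p_col].min())
        el = emap.loc[eid]
        best_other = _top_record(others, p_col)
        orient = el["class"] == "UMR"
        pct = percent_distance(int(best_other["pos"]), el, orient_by_tss=orient)
        if el["class"] == "LMR":
            band = "midpoint" if abs(pct) <= lmr_mid_band else "outside"
        else:
            band = "bimodal" if umr_band[0] <= abs(pct) <= umr_band[1] else "outside"
        row.update(
            {
                "status": "evaluated",
                "overlap_cpg": overlap.sort_values(p_col).iloc[0]["cpg_id"],
                "overlap_p": p_overlap,
                "best_other_cpg": best_other["cpg_id"],
                "best_other_p": p_best_other,
                "refined": bool(p_best_other < p_overlap),
                "best_other_pos_pct": pct,
                "best_other_band": band,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
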