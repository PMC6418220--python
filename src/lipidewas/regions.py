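"""CpG-to-element annotation, positional statistics and enrichment tests.

Regulatory elements are disjoint half-open intervals classed as LMR
(putative enhancer) or UMR (putative promoter).  The positional
statistic of a CpG inside its element is the signed percent distance
from the element midpoint, (pos - midpoint) / length * 100, optionally
sign-flipped for minus-strand TSSs so that positive values point into
the gene body.  Enrichment contrasts are two-sided Fisher exact tests
on 2x2 count tables with the fold change reported as the ratio of
proportions rounded half-up to one decimal (the convention of printed
fold-change tables).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "annotate_cpgs",
    "percent_distance",
    "positional_profile",
    "PositionalProfile",
    "EnrichmentResult",
    "fisher_enrichment",
    "array_mask_comparison",
    "plot_positional_profile",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (2.45 -> 2.5), matching printed tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _check_disjoint(elements: pd.DataFrame) -> None:
    for chrom, sub in elements.groupby("chrom"):
        sub = sub.sort_values("start")
        overlap = sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]
        if overlap.any():
            i = int(np.flatnonzero(overlap)[0])
            a, b = sub.iloc[i], sub.iloc[i + 1]
            if a["class"] == b["class"]:
                raise ValueError(
                    f"overlapping {a['class']} elements {a['element_id']} and "
                    f"{b['element_id']} on {chrom}: annotation is ambiguous"
                )


def annotate_cpgs(cpgs: pd.DataFrame, elements: pd.DataFrame) -> pd.Series:
    """Assign each CpG to its containing element (half-open intervals).

    Returns a Series of element ids indexed like ``cpgs``; CpGs outside
    all elements get None (background).  Same-class overlapping elements
    raise; on a cross-class overlap the earlier-starting element wins
    (deterministic, documented).
    """
    _check_disjoint(elements)
    owner = pd.Series([None] * len(cpgs), index=cpgs.index, dtype=object)
    for chrom, sub in elements.groupby("chrom"):
        on = cpgs["chrom"] == chrom
        if not on.any():
            continue
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        ids = sub["element_id"].to_numpy()
        pos = cpgs.loc[on, "pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        vals = np.where(inside, ids[np.clip(idx, 0, len(ids) - 1)], None)
        owner.loc[on] = vals
    return owner


def percent_distance(pos: int, element, orient_by_tss: bool = False) -> float:
    """Signed percent distance of a position from the element midpoint.

    midpoint = (start + end) / 2 taken real-valued (keeps the statistic
    exactly antisymmetric for odd lengths); result = (pos - midpoint) /
    length * 100, sign flipped when orienting by a minus-strand TSS.
    """
    start, end = int(element["start"]), int(element["end"])
    length = end - start
    if length <= 0:
        raise ValueError("zero-length element")
    midpoint = (start + end) / 2.0
    pct = (pos - midpoint) / length * 100.0
    if orient_by_tss and element.get("tss_strand") == "-":
        pct = -pct
    return pct


@dataclass
class PositionalProfile:
    """Signed percent-distance values and their histogram per element class."""

    lmr_pct: np.ndarray
    umr_pct: np.ndarray
    bins: np.ndarray
    lmr_hist: np.ndarray
    umr_hist: np.ndarray
    n_lmr_elements: int
    n_umr_elements: int


def positional_profile(
    cpgs: pd.DataFrame,
    elements: pd.DataFrame,
    assignment: pd.Series | None = None,
    subset: set | None = None,
    umr_tss_window: int = 1500,
    n_bins: int = 20,
) -> PositionalProfile:
    """Percent-distance profile of CpGs within LMRs and qualifying UMRs.

    The LMR profile covers all LMRs; the UMR profile is restricted to
    promoters whose annotated TSS lies inside the element and within
    +/- ``umr_tss_window`` bp of the element midpoint, and that are not
    flagged bivalent; UMR distances are TSS-strand oriented.  ``subset``
    optionally restricts to a CpG-id subset (e.g. significant CpGs).
    """
    if assignment is None:
        assignment = annotate_cpgs(cpgs, elements)
    emap = elements.set_index("element_id")
    lmr_vals: list[float] = []
    umr_vals: list[float] = []
    used_lmr: set = set()
    used_umr: set = set()
    for (idx, cpg), eid in zip(cpgs.iterrows(), assignment):
        if eid is None:
            continue
        if subset is not None and cpg["cpg_id"] not in subset:
            continue
        el = emap.loc[eid]
        if el["class"] == "LMR":
            lmr_vals.append(percent_distance(cpg["pos"], el))
            used_lmr.add(eid)
        else:
            tss = int(el.get("tss", -1))
            if tss < 0 or not (el["start"] <= tss < el["end"]):
                continue
            if bool(el.get("bivalent", False)):
                continue
            midpoint = (el["start"] + el["end"]) / 2.0
            if abs(tss - midpoint) > umr_tss_window:
                continue
            umr_vals.append(percent_distance(cpg["pos"], el, orient_by_tss=True))
            used_umr.add(eid)
    bins = np.linspace(-50.0, 50.0, n_bins + 1)
    lmr_pct = np.asarray(lmr_vals)
    umr_pct = np.asarray(umr_vals)
    return PositionalProfile(
        lmr_pct=lmr_pct,
        umr_pct=umr_pct,
        bins=bins,
        lmr_hist=np.histogram(lmr_pct, bins=bins)[0],
        umr_hist=np.histogram(umr_pct, bins=bins)[0],
        n_lmr_elements=len(used_lmr),
        n_umr_elements=len(used_umr),
    )


@dataclass
class EnrichmentResult:
    """2x2 enrichment contrast: a/b hits in the foreground, c/d in background."""

    a: int
    b: int
    c: int
    d: int
    proportion_fg: float
    proportion_bg: float
    fold: float | None
    p: float
    degenerate: bool = False


def fisher_enrichment(a: int, b: int, c: int, d: int) -> EnrichmentResult:
    """Fold change (a/b)/(c/d), half-up to 1 decimal, with Fisher two-sided p.

    The Fisher table is [[a, b-a], [c, d-c]]; the two-sided p-value sums
    hypergeometric outcomes at most as probable as the observed table.
    Degenerate margins (no hits anywhere, or hits everywhere) give p = 1
    by convention with a flag.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0:
            raise ValueError(f"negative count {name}={v}")
    if b <= 0 or d <= 0:
        raise ValueError("group totals b and d must be positive")
    if a > b or c > d:
        raise ValueError("hits exceed group totals")
    prop_fg = a / b
    prop_bg = c / d
    fold = round_half_up(prop_fg / prop_bg) if c > 0 else None
    degenerate = (a == 0 and c == 0) or (a == b and c == d)
    if degenerate:
        p = 1.0
    else:
        p = float(stats.fisher_exact([[a, b - a], [c, d - c]], alternative="two-sided")[1])
    return EnrichmentResult(
        a=a, b=b, c=c, d=d,
        proportion_fg=prop_fg, proportion_bg=prop_bg,
        fold=fold, p=p, degenerate=degenerate,
    )


def array_mask_comparison(
    cpgs: pd.DataFrame,
    mask: set | pd.Index,
    elements: pd.DataFrame,
    assignment: pd.Series | None = None,
) -> dict:
    """Fraction of element-resident CpGs captured by an array-like mask.

    Returns per-class capture fractions plus the positional profile of
    the masked CpGs (the array's view of the elements).
    """
    if assignment is None:
        assignment = annotate_cpgs(cpgs, elements)
    mask = set(mask)
    emap = elements.set_index("element_id")["class"]
    out: dict = {}
    owner_class = assignment.map(lambda e: emap[e] if e is not None else None)
    for cls in ("LMR", "UMR"):
        resident = cpgs.loc[(owner_class == cls).to_numpy(), "cpg_id"]
        captured = sum(c in mask for c in resident)
        out[cls] = {
            "n_resident": int(len(resident)),
            "n_captured": int(captured),
            "fraction": captured / len(resident) if len(resident) else float("nan"),
        }
    out["profile_masked"] = positional_profile(cpgs, elements, assignment, subset=mask)
    return out


def plot_positional_profile(profile: PositionalProfile, path=None, title: str = ""):
    """Density plot of percent-distance trends (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=False)
    for ax, vals, label in (
        (axes[0], profile.lmr_pct, "LMR (putative enhancers)"),
        (axes[1], profile.umr_pct, "UMR (putative promoters)"),
    ):
        if len(vals):
            ax.hist(vals, bins=profile.bins, density=True, alpha=0.7)
        ax.set_xlabel("% distance from element midpoint")
        ax.set_title(label, fontsize=9)
    axes[0].set_ylabel("density")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
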