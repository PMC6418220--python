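"""Strand merging and site-level QC of per-CpG bisulfite read counts.

Methylation at a CpG is measured on both strands of the symmetric CpG
dyad.  The two strands are merged by pooling counts — the methylation
value is (meth_fwd + meth_rev) / (total_fwd + total_rev), never an
average of per-strand ratios — after discarding entries where the two
strands disagree by more than a configurable proportion (default 20%),
which flags mapping artefacts and unannotated variants.  Site filters
then require a minimum read depth per entry (default 5 reads, inclusive)
and, per CpG, coverage in a minimum number of individuals with a strictly
greater than 10% fraction of covered individuals showing intermediate
(0 < m < 1) methylation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StrandCountMatrix",
    "MethylationMatrix",
    "merge_strands",
    "apply_min_coverage",
    "filter_sites",
    "classify_baseline_state",
    "apply_exclusion_mask",
]


@dataclass
class StrandCountMatrix:
    """Per-CpG, per-sample, per-strand methylated/total read counts.

    All four frames share the same index (CpG ids, ordered by genomic
    position) and columns (sample ids).  ``positions`` carries the
    genomic location of each CpG (columns: chrom, pos).
    """

    meth_fwd: pd.DataFrame
    total_fwd: pd.DataFrame
    meth_rev: pd.DataFrame
    total_rev: pd.DataFrame
    positions: pd.DataFrame

    def __post_init__(self) -> None:
        for name in ("meth_fwd", "total_fwd", "meth_rev", "total_rev"):
            frame = getattr(self, name)
            if (frame.to_numpy() < 0).any():
                raise ValueError(f"negative read counts in {name}")
        if (self.meth_fwd.to_numpy() > self.total_fwd.to_numpy()).any():
            raise ValueError("meth_fwd exceeds total_fwd")
        if (self.meth_rev.to_numpy() > self.total_rev.to_numpy()).any():
            raise ValueError("meth_rev exceeds total_rev")

    @property
    def cpg_ids(self) -> pd.Index:
        return self.meth_fwd.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.meth_fwd.columns


@dataclass
class MethylationMatrix:
    """Merged methylation proportions and coverages after strand merging.

    ``meth`` holds the methylation proportion m in [0, 1] (NaN where the
    entry is missing), ``cov`` the pooled read coverage (0 where missing).
    m is defined only where cov > 0 and equals pooled-meth / pooled-total
    exactly.
    """

    meth: pd.DataFrame
    cov: pd.DataFrame
    positions: pd.DataFrame

    @property
    def cpg_ids(self) -> pd.Index:
        return self.meth.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.meth.columns

    def copy(self) -> "MethylationMatrix":
        return MethylationMatrix(self.meth.copy(), self.cov.copy(), self.positions.copy())


def merge_strands(counts: StrandCountMatrix, max_strand_diff: float = 0.20) -> MethylationMatrix:
    """Pool forward/reverse counts into methylation proportions.

    Entries where both strands have coverage and the per-strand
    methylation proportions differ by more than ``max_strand_diff`` are
    set missing; the strand test is skipped when either strand has zero
    coverage.
    """
    mf = counts.meth_fwd.to_numpy(dtype=float)
    tf = counts.total_fwd.to_numpy(dtype=float)
    mr = counts.meth_rev.to_numpy(dtype=float)
    tr = counts.total_rev.to_numpy(dtype=float)

    total = tf + tr
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(total > 0, (mf + mr) / np.where(total > 0, total, 1.0), np.nan)
        pf = np.where(tf > 0, mf / np.where(tf > 0, tf, 1.0), np.nan)
        pr = np.where(tr > 0, mr / np.where(tr > 0, tr, 1.0), np.nan)

    both = (tf > 0) & (tr > 0)
    discordant = both & (np.abs(pf - pr) > max_strand_diff)
    m[discordant] = np.nan
    cov = np.where(discordant, 0.0, total)
    m[cov == 0] = np.nan

    meth = pd.DataFrame(m, index=counts.cpg_ids, columns=counts.sample_ids)
    coverage = pd.DataFrame(cov, index=counts.cpg_ids, columns=counts.sample_ids)
    return MethylationMatrix(meth, coverage, counts.positions.copy())


def apply_min_coverage(mat: MethylationMatrix, min_reads: int = 5) -> MethylationMatrix:
    """Set entries with coverage below ``min_reads`` missing (inclusive keep)."""
    if min_reads < 0:
        raise ValueError("min_reads must be non-negative")
    out = mat.copy()
    low = out.cov.to_numpy() < min_reads
    meth = out.meth.to_numpy()
    cov = out.cov.to_numpy()
    meth[low] = np.nan
    cov[low] = 0.0
    out.meth = pd.DataFrame(meth, index=mat.cpg_ids, columns=mat.sample_ids)
    out.cov = pd.DataFrame(cov, index=mat.cpg_ids, columns=mat.sample_ids)
    return out


def filter_sites(
    mat: MethylationMatrix,
    min_individuals: int,
    min_variable_frac: float = 0.10,
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Keep CpGs covered in enough individuals with enough variable entries.

    A CpG passes when it is covered (cov > 0) in at least
    ``min_individuals`` samples AND the fraction of covered samples with
    0 < m < 1 is strictly greater than ``min_variable_frac``.  Returns
    the filtered matrix and a per-CpG QC report with pass flags and an
    exclusion reason.
    """
    if min_individuals <= 0 or min_variable_frac < 0:
        raise ValueError("thresholds must be positive")
    n_samples = len(mat.sample_ids)
    if min_individuals > n_samples:
        raise ValueError(
            f"min_individuals={min_individuals} exceeds cohort size {n_samples}"
        )

    cov = mat.cov.to_numpy()
    meth = mat.meth.to_numpy()
    covered = cov > 0
    n_covered = covered.sum(axis=1)
    variable = covered & (meth > 0) & (meth < 1)
    n_variable = variable.sum(axis=1)

    pass_coverage = n_covered >= min_individuals
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_variable = np.where(n_covered > 0, n_variable / np.maximum(n_covered, 1), 0.0)
    pass_variable = frac_variable > min_variable_frac
    keep = pass_coverage & pass_variable

    reason = np.full(len(mat.cpg_ids), "", dtype=object)
    reason[~pass_coverage] = "coverage"
    reason[pass_coverage & ~pass_variable] = "invariant"

    report = pd.DataFrame(
        {
            "n_covered": n_covered,
            "n_variable": n_variable,
            "frac_variable": frac_variable,
            "pass_coverage": pass_coverage,
            "pass_variable": pass_variable,
            "pass": keep,
            "reason": reason,
        },
        index=mat.cpg_ids,
    )

    kept = MethylationMatrix(
        mat.meth.loc[keep], mat.cov.loc[keep], mat.positions.loc[keep]
    )
    return kept, report


def classify_baseline_state(
    mat: MethylationMatrix, hypo_cutoff: float = 0.20, hyper_cutoff: float = 0.80
) -> pd.Series:
    """Label CpGs hypo / intermediate / hyper by mean methylation.

    Mean is over covered samples; CpGs with no covered sample get NaN.
    """
    mean_m = mat.meth.mean(axis=1, skipna=True)
    label = pd.Series(pd.NA, index=mat.cpg_ids, dtype=object)
    label[mean_m < hypo_cutoff] = "hypo"
    label[mean_m > hyper_cutoff] = "hyper"
    label[(mean_m >= hypo_cutoff) & (mean_m <= hyper_cutoff)] = "intermediate"
    return label


def apply_exclusion_mask(mat: MethylationMatrix, exclude: pd.DataFrame) -> MethylationMatrix:
    """Drop CpGs overlapping user-supplied exclusion intervals (BED-like).

    ``exclude`` needs chrom/start/end columns, half-open coordinates.
    Represents external masks (dbSNP positions, blacklisted regions)
    which are inputs, not computed here.
    """
    pos = mat.positions
    drop = np.zeros(len(pos), dtype=bool)
    for chrom, sub in exclude.groupby("chrom"):
        on_chrom = (pos["chrom"] == chrom).to_numpy()
        if not on_chrom.any():
            continue
        p = pos.loc[on_chrom, "pos"].to_numpy()
        starts = np.sort(sub["start"].to_numpy())
        ends = sub["end"].to_numpy()[np.argsort(sub["start"].to_numpy())]
        idx = np.searchsorted(starts, p, side="right") - 1
        inside = (idx >= 0) & (p < ends[np.clip(idx, 0, len(ends) - 1)])
        drop[np.flatnonzero(on_chrom)[inside]] = True
    keep = ~drop
    return MethylationMatrix(mat.meth.loc[keep], mat.cov.loc[keep], mat.positions.loc[keep])
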