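"""Synthetic study generator with planted effects and known ground truth.

Emulates the data structure of a targeted bisulfite-sequencing lipid
EWAS on one toy chromosome: hypomethylated regulatory footprints (LMR
"enhancers", shorter and sparser; UMR "promoters", longer and denser,
each carrying a TSS), CpGs inside and outside elements, per-strand
beta-binomial read counts whose latent methylation logit carries planted
lipid-trait and SNP-dosage effects, correlated lipid phenotypes with
covariates, Hardy-Weinberg genotype dosages, an expression matrix with
genes linked to element CpGs at short and long range, and an array-like
CpG subsampling mask mimicking sparse microarray designs.

All randomness flows from one root seed through named substreams, so a
fixed (seed, config) pair reproduces the cohort byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from lipidewas.qc import StrandCountMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "Cohort",
    "generate_elements",
    "generate_cpgs",
    "simulate_phenotypes",
    "simulate_genotypes",
    "simulate_methylation_counts",
    "simulate_expression",
    "generate_cohort",
    "generate_study",
    "write_cohort",
    "read_cohort",
]

TRAITS = ("TG", "HDL", "LDL", "TC")

# substream labels -> fixed child indices of the root SeedSequence
_STREAMS = {
    "elements": 0,
    "cpgs": 1,
    "phenotypes": 2,
    "genotypes": 3,
    "methylation": 4,
    "expression": 5,
    "mask": 6,
    "replication": 7,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the structure of the emulated study: ~200 samples,
    33x mean coverage, 7 CpGs per LMR and 37 per UMR, 60% female, a
    two-level capture-panel batch, 1% of CpGs carrying a lipid effect.
    ``beta_dispersion`` is the beta-binomial overdispersion rho in
    [0, 1); the default 0.02 induces the mild test-statistic inflation
    the empirical-null correction is designed to remove.
    """

    n_samples: int = 200
    n_elements_lmr: int = 400
    n_elements_umr: int = 400
    mean_cpgs_per_lmr: float = 7.0
    mean_cpgs_per_umr: float = 37.0
    lmr_length_mean: float = 600.0
    umr_length_mean: float = 2200.0
    chrom: str = "chr1"
    chrom_length: int = 10_000_000
    frac_adipose_specific: float = 0.4
    frac_bivalent_umr: float = 0.05
    background_cpg_frac: float = 0.10
    coverage_mean: float = 33.0
    coverage_dispersion: float = 0.3
    beta_dispersion: float = 0.02
    sample_noise_sd: float = 0.10
    frac_lipid_cpgs: float = 0.01
    effect_size_logit: float = 0.30
    n_snps: int = 300
    maf_low: float = 0.05
    maf_high: float = 0.5
    frac_metqtl_cpgs: float = 0.02
    snp_effect_logit: float = 0.5
    metqtl_max_dist: int = 50_000
    n_genes: int = 120
    frac_expr_linked: float = 0.003
    expr_effect: float = 15.0
    expr_noise_sd: float = 1.0
    array_mask_frac_lmr: float = 0.06
    array_mask_frac_umr: float = 0.19
    trait_corr: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "frac_adipose_specific": self.frac_adipose_specific,
            "frac_bivalent_umr": self.frac_bivalent_umr,
            "background_cpg_frac": self.background_cpg_frac,
            "frac_lipid_cpgs": self.frac_lipid_cpgs,
            "frac_metqtl_cpgs": self.frac_metqtl_cpgs,
            "frac_expr_linked": self.frac_expr_linked,
            "array_mask_frac_lmr": self.array_mask_frac_lmr,
            "array_mask_frac_umr": self.array_mask_frac_umr,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if not 0.0 <= self.beta_dispersion < 1.0:
            raise ValueError("beta_dispersion must lie in [0, 1)")
        for name in ("n_samples", "n_elements_lmr", "n_elements_umr", "chrom_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.coverage_mean < 5:
            raise ValueError("coverage_mean must be at least 5 reads")
        if not 0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("MAF range must satisfy 0 < low <= high <= 0.5")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream of the root seed (stable across runs)."""
        root = np.random.SeedSequence(self.seed)
        children = root.spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS[stream]])


@dataclass
class SyntheticTruth:
    """Registry of planted effects, keyed by CpG / gene id.

    lipid: cpg -> {trait, beta}           (logit units per SD of trait)
    metqtl: cpg -> {snp, gamma}           (logit units per alternate allele)
    expr: gene -> {cpg, delta, distance}  (expression units per unit methylation)
    """

    lipid: dict = field(default_factory=dict)
    metqtl: dict = field(default_factory=dict)
    expr: dict = field(default_factory=dict)

    def validate(self, cpg_ids, snp_ids, gene_ids) -> None:
        cpgs, snps, genes = set(cpg_ids), set(snp_ids), set(gene_ids)
        for cpg, rec in self.lipid.items():
            if cpg not in cpgs:
                raise ValueError(f"lipid registry references unknown CpG {cpg}")
            if not np.isfinite(rec["beta"]) or rec["beta"] == 0:
                raise ValueError(f"non-finite/zero lipid effect at {cpg}")
        for cpg, rec in self.metqtl.items():
            if cpg not in cpgs or rec["snp"] not in snps:
                raise ValueError(f"metqtl registry references unknown id at {cpg}")
            if not np.isfinite(rec["gamma"]) or rec["gamma"] == 0:
                raise ValueError(f"non-finite/zero metQTL effect at {cpg}")
        for gene, rec in self.expr.items():
            if gene not in genes or rec["cpg"] not in cpgs:
                raise ValueError(f"expr registry references unknown id at {gene}")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text())
        return cls(lipid=raw["lipid"], metqtl=raw["metqtl"], expr=raw["expr"])


@dataclass
class Cohort:
    """One simulated tissue cohort plus the shared genomic scaffolding."""

    config: SimulationConfig
    elements: pd.DataFrame
    cpgs: pd.DataFrame
    phenotypes: pd.DataFrame
    genotypes: pd.DataFrame
    snp_info: pd.DataFrame
    counts: StrandCountMatrix
    truth: SyntheticTruth
    expression: pd.DataFrame | None = None
    genes: pd.DataFrame | None = None
    array_mask: pd.Index | None = None
    latent_meth: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# elements and CpGs


def generate_elements(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Place disjoint LMR/UMR intervals on the toy chromosome.

    Enhancer-like LMRs are short, promoter-like UMRs longer; each UMR
    carries a TSS at the element midpoint with a random strand, and a
    small fraction of UMRs is flagged bivalent (excluded from oriented
    positional profiles downstream).  Raises if the chromosome cannot
    hold all elements.
    """
    config.validate()
    if rng is None:
        rng = config.rng("elements")
    n_lmr, n_umr = config.n_elements_lmr, config.n_elements_umr
    lengths_lmr = np.maximum(
        200, rng.normal(config.lmr_length_mean, config.lmr_length_mean / 5, n_lmr)
    ).astype(int)
    lengths_umr = np.maximum(
        800, rng.normal(config.umr_length_mean, config.umr_length_mean / 5, n_umr)
    ).astype(int)
    classes = np.array(["LMR"] * n_lmr + ["UMR"] * n_umr, dtype=object)
    lengths = np.concatenate([lengths_lmr, lengths_umr])
    order = rng.permutation(len(lengths))
    classes, lengths = classes[order], lengths[order]

    total = int(lengths.sum())
    free = config.chrom_length - total
    if free < len(lengths) + 1:
        raise ValueError(
            f"chromosome of {config.chrom_length} bp too short for "
            f"{len(lengths)} elements totalling {total} bp"
        )
    gaps = np.floor(rng.dirichlet(np.ones(len(lengths) + 1)) * free).astype(int)
    starts = np.cumsum(gaps[:-1] + np.concatenate([[0], lengths[:-1]]))
    ends = starts + lengths

    specific = rng.random(len(lengths)) < config.frac_adipose_specific
    tss = np.where(classes == "UMR", (starts + ends) // 2, -1)
    tss_strand = np.where(
        classes == "UMR", np.where(rng.random(len(lengths)) < 0.5, "+", "-"), "."
    )
    bivalent = (classes == "UMR") & (rng.random(len(lengths)) < config.frac_bivalent_umr)

    counters = {"LMR": 0, "UMR": 0}
    ids = []
    for cls in classes:
        counters[cls] += 1
        ids.append(f"{cls}_{counters[cls]:04d}")

    elements = pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": starts,
            "end": ends,
            "element_id": ids,
            "class": classes,
            "specificity": np.where(specific, "adipose_specific", "shared"),
            "tss": tss,
            "tss_strand": tss_strand,
            "bivalent": bivalent,
        }
    ).sort_values("start", ignore_index=True)
    return elements


def generate_cpgs(
    elements: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample CpG positions inside elements plus a background fraction.

    Per-element CpG counts are Poisson around the configured class
    densities (7/LMR, 37/UMR); background CpGs are uniform on the
    chromosome outside all elements.  Positions are sorted and unique.
    """
    if rng is None:
        rng = config.rng("cpgs")
    means = np.where(
        elements["class"].to_numpy() == "LMR",
        config.mean_cpgs_per_lmr,
        config.mean_cpgs_per_umr,
    )
    counts = rng.poisson(means)
    positions = []
    for (start, end), n in zip(
        elements[["start", "end"]].itertuples(index=False), counts
    ):
        if n > 0:
            positions.append(rng.integers(start, end, size=n))
    inside = np.unique(np.concatenate(positions)) if positions else np.array([], dtype=int)

    n_background = int(
        round(len(inside) * config.background_cpg_frac / max(1e-12, 1 - config.background_cpg_frac))
    ) if config.background_cpg_frac > 0 else 0
    background = np.array([], dtype=int)
    if n_background > 0:
        starts = elements["start"].to_numpy()
        ends = elements["end"].to_numpy()
        draws = rng.integers(0, config.chrom_length, size=4 * n_background + 16)
        idx = np.searchsorted(starts, draws, side="right") - 1
        in_element = (idx >= 0) & (draws < ends[np.clip(idx, 0, len(ends) - 1)])
        background = np.unique(draws[~in_element])[:n_background]

    pos = np.unique(np.concatenate([inside, background]))
    cpgs = pd.DataFrame({"chrom": config.chrom, "pos": pos})
    cpgs["cpg_id"] = [f"{config.chrom}:{p}" for p in pos]
    return cpgs


# ---------------------------------------------------------------------------
# phenotypes and genotypes


def simulate_phenotypes(
    config: SimulationConfig,
    n: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Correlated lipid traits plus covariates for n samples.

    TG is log-normal (right-skewed, positive); HDL-C, LDL-C and TC are
    normal on plausible mmol/L scales; a latent exchangeable-correlation
    Gaussian couples the four traits with correlation ``trait_corr``.
    Covariates: age, sex (Bernoulli 0.6 female), BMI in the severely
    obese range, a two-level capture-panel batch, and Dirichlet(5,3,2,1,1)
    cell proportions summing to one.
    """
    if n is None:
        n = config.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    if rng is None:
        rng = config.rng("phenotypes")
    r = config.trait_corr
    corr = np.full((4, 4), r)
    np.fill_diagonal(corr, 1.0)
    z = rng.multivariate_normal(np.zeros(4), corr, size=n, method="cholesky")

    tg = np.exp(np.log(1.5) + 0.45 * z[:, 0])
    hdl = np.maximum(0.3, 1.30 + 0.35 * z[:, 1])
    ldl = np.maximum(0.5, 3.00 + 0.90 * z[:, 2])
    tc = np.maximum(1.0, 5.00 + 1.00 * z[:, 3])

    cells = rng.dirichlet([5.0, 3.0, 2.0, 1.0, 1.0], size=n)
    pheno = pd.DataFrame(
        {
            "TG": tg,
            "HDL": hdl,
            "LDL": ldl,
            "TC": tc,
            "age": np.clip(rng.normal(45.0, 10.0, n), 18, 75),
            "sex": (rng.random(n) < 0.6).astype(int),  # 1 = female
            "bmi": np.maximum(40.0, rng.normal(47.0, 5.0, n)),
            "batch": np.where(rng.random(n) < 113 / 205, "MetV1", "MetV2"),
        },
        index=pd.Index([f"S{i:04d}" for i in range(n)], name="sample"),
    )
    for k in range(cells.shape[1]):
        pheno[f"cell_{k}"] = cells[:, k]
    return pheno


def simulate_genotypes(
    config: SimulationConfig,
    n: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Biallelic dosages under Hardy-Weinberg at uniform MAF.

    Returns (dosages: snp x sample int frame, snp_info: chrom/pos/maf).
    Monomorphic draws are excluded.
    """
    if n is None:
        n = config.n_samples
    if rng is None:
        rng = config.rng("genotypes")
    pos = np.sort(rng.choice(config.chrom_length, size=config.n_snps, replace=False))
    maf = rng.uniform(config.maf_low, config.maf_high, size=config.n_snps)
    dosage = rng.binomial(2, maf[:, None], size=(config.n_snps, n))
    poly = dosage.std(axis=1) > 0
    pos, maf, dosage = pos[poly], maf[poly], dosage[poly]
    snp_ids = [f"snp_{config.chrom}_{p}" for p in pos]
    samples = pd.Index([f"S{i:04d}" for i in range(n)], name="sample")
    dosages = pd.DataFrame(dosage, index=pd.Index(snp_ids, name="snp_id"), columns=samples)
    snp_info = pd.DataFrame(
        {"chrom": config.chrom, "pos": pos, "maf": maf},
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return dosages, snp_info


# ---------------------------------------------------------------------------
# methylation counts


def _assign_effects(
    cpgs: pd.DataFrame,
    elements: pd.DataFrame,
    snp_info: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SyntheticTruth:
    """Choose which CpGs carry lipid and metQTL effects.

    Lipid effects are planted element-wise (whole elements become
    lipid-linked, echoing region-level signal): elements are drawn at
    random and all their CpGs receive the same trait/sign until the
    configured fraction of CpGs is reached.  metQTL CpGs are drawn
    uniformly from element CpGs with a polymorphic SNP within
    ``metqtl_max_dist``.
    """
    starts = elements["start"].to_numpy()
    ends = elements["end"].to_numpy()
    pos = cpgs["pos"].to_numpy()
    idx = np.searchsorted(starts, pos, side="right") - 1
    inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
    owner = np.where(inside, elements["element_id"].to_numpy()[np.clip(idx, 0, len(ends) - 1)], None)

    truth = SyntheticTruth()
    target = int(round(config.frac_lipid_cpgs * len(cpgs)))
    element_order = rng.permutation(elements["element_id"].to_numpy())
    planted = 0
    for eid in element_order:
        if planted >= target:
            break
        members = cpgs["cpg_id"].to_numpy()[owner == eid]
        if len(members) == 0:
            continue
        trait = TRAITS[rng.integers(len(TRAITS))]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        for cpg in members:
            truth.lipid[cpg] = {"trait": trait, "beta": sign * config.effect_size_logit}
        planted += len(members)

    n_qtl = int(round(config.frac_metqtl_cpgs * len(cpgs)))
    snp_pos = snp_info["pos"].to_numpy()
    snp_ids = snp_info.index.to_numpy()
    candidates = np.flatnonzero(inside)
    rng.shuffle(candidates)
    for i in candidates:
        if len(truth.metqtl) >= n_qtl:
            break
        cpg = cpgs["cpg_id"].iat[i]
        d = np.abs(snp_pos - pos[i])
        j = int(np.argmin(d))
        if d[j] <= config.metqtl_max_dist:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            truth.metqtl[cpg] = {"snp": str(snp_ids[j]), "gamma": sign * config.snp_effect_logit}
    return truth


def _baseline_logits(
    cpgs: pd.DataFrame, elements: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-CpG baseline methylation logit by genomic context.

    UMR promoters are unmethylated (mean ~5%), LMR enhancers lowly
    methylated (~25%), background CpGs mostly methylated (~85%) —
    reproducing the hypomethylated-footprint geometry of regulatory
    elements on an otherwise methylated genome.
    """
    starts = elements["start"].to_numpy()
    ends = elements["end"].to_numpy()
    classes = elements["class"].to_numpy()
    pos = cpgs["pos"].to_numpy()
    idx = np.searchsorted(starts, pos, side="right") - 1
    inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
    cls = np.where(inside, classes[np.clip(idx, 0, len(classes) - 1)], "background")
    centre = np.select(
        [cls == "UMR", cls == "LMR"], [logit(0.05), logit(0.25)], default=logit(0.85)
    )
    return centre + rng.normal(0.0, 0.8, size=len(cpgs))


def simulate_methylation_counts(
    cpgs: pd.DataFrame,
    phenotypes: pd.DataFrame,
    genotypes: pd.DataFrame,
    truth: SyntheticTruth,
    config: SimulationConfig,
    baseline_logit: np.ndarray,
    rng: np.random.Generator | None = None,
    active_cpgs: set | None = None,
) -> tuple[StrandCountMatrix, pd.DataFrame]:
    """Draw per-strand beta-binomial counts from the planted latent model.

    Latent logit(pi_ij) = alpha_i + beta_i * trait_j(std) +
    gamma_i * dosage_ij + eps_ij; the proportion is drawn beta-binomial
    with overdispersion rho = ``beta_dispersion`` on a negative-binomial
    total split binomially between strands.  ``active_cpgs`` restricts
    which planted effects are switched on (used for the tissue-specific
    replication cohort); None means all.

    Returns (counts, latent methylation proportions frame).
    """
    if rng is None:
        rng = config.rng("methylation")
    n_cpg = len(cpgs)
    samples = phenotypes.index
    n = len(samples)

    eta = np.tile(baseline_logit[:, None], (1, n))
    traits_std = {
        t: (phenotypes[t] - phenotypes[t].mean()) / phenotypes[t].std(ddof=0) for t in TRAITS
    }
    cpg_index = pd.Index(cpgs["cpg_id"])
    for cpg, rec in truth.lipid.items():
        if active_cpgs is not None and cpg not in active_cpgs:
            continue
        i = cpg_index.get_loc(cpg)
        eta[i] += rec["beta"] * traits_std[rec["trait"]].to_numpy()
    for cpg, rec in truth.metqtl.items():
        if active_cpgs is not None and cpg not in active_cpgs:
            continue
        i = cpg_index.get_loc(cpg)
        eta[i] += rec["gamma"] * genotypes.loc[rec["snp"], samples].to_numpy(dtype=float)
    if config.sample_noise_sd > 0:
        eta += rng.normal(0.0, config.sample_noise_sd, size=eta.shape)

    pi = expit(eta)
    rho = config.beta_dispersion
    if rho > 0:
        conc = (1.0 - rho) / rho
        a = np.maximum(pi * conc, 1e-8)
        b = np.maximum((1.0 - pi) * conc, 1e-8)
        p = rng.beta(a, b)
    else:
        p = pi

    k = 1.0 / config.coverage_dispersion  # NB shape: var = mu + mu^2/k
    total = rng.negative_binomial(k, k / (k + config.coverage_mean), size=(n_cpg, n))
    t_fwd = rng.binomial(total, 0.5)
    t_rev = total - t_fwd
    m_fwd = rng.binomial(t_fwd, p)
    m_rev = rng.binomial(t_rev, p)

    def frame(a):
        return pd.DataFrame(a, index=cpg_index, columns=samples)

    counts = StrandCountMatrix(
        meth_fwd=frame(m_fwd),
        total_fwd=frame(t_fwd),
        meth_rev=frame(m_rev),
        total_rev=frame(t_rev),
        positions=cpgs.set_index("cpg_id")[["chrom", "pos"]],
    )
    return counts, frame(pi)


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    cpgs: pd.DataFrame,
    elements: pd.DataFrame,
    latent_meth: pd.DataFrame,
    config: SimulationConfig,
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene expression with planted methylation links at mixed ranges.

    Unlinked genes are noise around a baseline.  Linked genes are placed
    so that about half sit proximal (<100 kb) and half long-range
    (200-800 kb) from their linked CpG — expression then equals
    baseline + delta * latent methylation + Gaussian noise.  Updates
    ``truth.expr`` in place and returns (expression frame, genes BED
    frame with transcribed start/end).
    """
    if rng is None:
        rng = config.rng("expression")
    n_genes = config.n_genes
    samples = latent_meth.columns
    gene_len = np.maximum(2_000, rng.normal(20_000, 8_000, n_genes)).astype(int)
    gene_start = rng.integers(0, config.chrom_length - gene_len.max(), size=n_genes)
    gene_ids = [f"gene_{i:04d}" for i in range(n_genes)]

    n_linked = min(n_genes, int(round(config.frac_expr_linked * len(cpgs))))
    # linked CpGs drawn from inside elements, preferring lipid CpGs with
    # high inter-individual variability (the expression dissection
    # targets variable CpGs in lipid-linked regions; links planted at
    # invariant sites would be unrecoverable from count noise)
    starts = elements["start"].to_numpy()
    ends = elements["end"].to_numpy()
    pos = cpgs["pos"].to_numpy()
    idx = np.searchsorted(starts, pos, side="right") - 1
    inside = np.flatnonzero((idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)]))
    is_lipid = cpgs["cpg_id"].isin(truth.lipid).to_numpy()
    lat_sd = latent_meth.std(axis=1).to_numpy()
    lipid_rows = np.flatnonzero(is_lipid)
    other_rows = np.setdiff1d(inside, lipid_rows)
    pool = np.concatenate([
        lipid_rows[np.argsort(-lat_sd[lipid_rows], kind="stable")],
        other_rows[np.argsort(-lat_sd[other_rows], kind="stable")],
    ])
    linked_cpg_rows = pool[:n_linked]

    expr = rng.normal(8.0, 1.0, size=(n_genes, 1)) + rng.normal(
        0.0, config.expr_noise_sd, size=(n_genes, len(samples))
    )
    for g, row in enumerate(linked_cpg_rows):
        cpg_pos = pos[row]
        cpg = cpgs["cpg_id"].iat[row]
        long_range = rng.random() < 0.5
        offset = (
            int(rng.integers(200_000, 800_000)) if long_range else int(rng.integers(5_000, 100_000))
        )
        sign = 1 if rng.random() < 0.5 else -1
        start = int(np.clip(cpg_pos + sign * offset, 0, config.chrom_length - gene_len[g] - 1))
        gene_start[g] = start
        delta = config.expr_effect * (1.0 if rng.random() < 0.5 else -1.0)
        m = latent_meth.loc[cpg].to_numpy()
        expr[g] += delta * m
        edge = max(abs(start - cpg_pos), abs(start + gene_len[g] - cpg_pos))
        truth.expr[gene_ids[g]] = {"cpg": cpg, "delta": delta, "distance": int(edge)}

    genes = pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": gene_start,
            "end": gene_start + gene_len,
            "gene_id": gene_ids,
        }
    )
    expression = pd.DataFrame(
        expr, index=pd.Index(gene_ids, name="gene_id"), columns=samples
    )
    return expression, genes


# ---------------------------------------------------------------------------
# cohort assembly


def _array_mask(
    cpgs: pd.DataFrame, elements: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.Index:
    """Array-like CpG subsample: sparse in LMRs, denser in UMRs."""
    starts = elements["start"].to_numpy()
    ends = elements["end"].to_numpy()
    classes = elements["class"].to_numpy()
    pos = cpgs["pos"].to_numpy()
    idx = np.searchsorted(starts, pos, side="right") - 1
    inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
    cls = np.where(inside, classes[np.clip(idx, 0, len(classes) - 1)], "background")
    p = np.select(
        [cls == "LMR", cls == "UMR"],
        [config.array_mask_frac_lmr, config.array_mask_frac_umr],
        default=0.02,
    )
    chosen = rng.random(len(cpgs)) < p
    return pd.Index(cpgs["cpg_id"].to_numpy()[chosen])


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate the full discovery (adipose-like) cohort."""
    config.validate()
    elements = generate_elements(config)
    cpgs = generate_cpgs(elements, config)
    phenotypes = simulate_phenotypes(config)
    genotypes, snp_info = simulate_genotypes(config)
    rng_m = config.rng("methylation")
    truth = _assign_effects(cpgs, elements, snp_info, config, rng_m)
    baseline = _baseline_logits(cpgs, elements, config, rng_m)
    counts, latent = simulate_methylation_counts(
        cpgs, phenotypes, genotypes, truth, config, baseline, rng=rng_m
    )
    expression, genes = simulate_expression(cpgs, elements, latent, config, truth)
    mask = _array_mask(cpgs, elements, config, config.rng("mask"))
    truth.validate(cpgs["cpg_id"], genotypes.index, genes["gene_id"])
    return Cohort(
        config=config,
        elements=elements,
        cpgs=cpgs,
        phenotypes=phenotypes,
        genotypes=genotypes,
        snp_info=snp_info,
        counts=counts,
        truth=truth,
        expression=expression,
        genes=genes,
        array_mask=mask,
        latent_meth=latent,
    )


def generate_study(config: SimulationConfig) -> tuple[Cohort, Cohort]:
    """Discovery plus a second-tissue replication cohort.

    The replication cohort shares the genomic scaffolding (elements,
    CpG catalog, SNP panel, truth registry) but has independent samples,
    and only effects at CpGs inside tissue-shared elements are active —
    adipose-specific effects are silent in the second tissue, so shared
    regions replicate and specific regions do not (beyond noise).
    """
    discovery = generate_cohort(config)
    rng = config.rng("replication")
    elements = discovery.elements
    shared_ids = set(elements.loc[elements["specificity"] == "shared", "element_id"])
    starts = elements["start"].to_numpy()
    ends = elements["end"].to_numpy()
    eids = elements["element_id"].to_numpy()
    pos = discovery.cpgs["pos"].to_numpy()
    idx = np.searchsorted(starts, pos, side="right") - 1
    inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
    owner = np.where(inside, eids[np.clip(idx, 0, len(eids) - 1)], None)
    active = {
        cpg
        for cpg, o in zip(discovery.cpgs["cpg_id"], owner)
        if o is not None and o in shared_ids
    }

    pheno = simulate_phenotypes(config, rng=rng)
    pheno.index = pd.Index([f"R{i:04d}" for i in range(len(pheno))], name="sample")
    maf = discovery.snp_info["maf"].to_numpy()
    geno_r = rng.binomial(2, maf[:, None], size=(len(maf), len(pheno)))
    genotypes = pd.DataFrame(geno_r, index=discovery.genotypes.index, columns=pheno.index)
    baseline = _baseline_logits(discovery.cpgs, elements, config, rng)
    counts, latent = simulate_methylation_counts(
        discovery.cpgs, pheno, genotypes, discovery.truth, config, baseline,
        rng=rng, active_cpgs=active,
    )
    replication = Cohort(
        config=config,
        elements=elements,
        cpgs=discovery.cpgs,
        phenotypes=pheno,
        genotypes=genotypes,
        snp_info=discovery.snp_info,
        counts=counts,
        truth=discovery.truth,
        array_mask=discovery.array_mask,
        latent_meth=latent,
    )
    return discovery, replication


# ---------------------------------------------------------------------------
# file round-trip


def write_cohort(cohort: Cohort, outdir) -> dict[str, str]:
    """Write the cohort as plain-text files (TSV/BED/JSON).

    cpg_counts.tsv is long-format (chrom, pos, sample, strand,
    meth_reads, total_reads); elements.bed is BED6 plus class,
    specificity, tss, tss_strand, bivalent columns.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    c = cohort.counts
    longs = []
    for strand, meth, tot in (("+", c.meth_fwd, c.total_fwd), ("-", c.meth_rev, c.total_rev)):
        df = meth.stack().rename("meth_reads").to_frame()
        df["total_reads"] = tot.stack()
        df = df.reset_index().rename(columns={"level_0": "cpg_id", "level_1": "sample"})
        df.columns = ["cpg_id", "sample", "meth_reads", "total_reads"]
        df["strand"] = strand
        longs.append(df)
    long = pd.concat(longs, ignore_index=True)
    posmap = c.positions
    long["chrom"] = posmap.loc[long["cpg_id"], "chrom"].to_numpy()
    long["pos"] = posmap.loc[long["cpg_id"], "pos"].to_numpy()
    long = long[["chrom", "pos", "sample", "strand", "meth_reads", "total_reads"]]
    long = long.sort_values(["pos", "sample", "strand"], ignore_index=True)
    path = outdir / "cpg_counts.tsv"
    long.to_csv(path, sep="\t", index=False)
    files["cpg_counts"] = str(path)

    bed = cohort.elements.copy()
    bed["score"] = 0
    bed["strand"] = "."
    bed = bed[
        ["chrom", "start", "end", "element_id", "score", "strand",
         "class", "specificity", "tss", "tss_strand", "bivalent"]
    ]
    path = outdir / "elements.bed"
    bed.to_csv(path, sep="\t", index=False, header=False)
    files["elements"] = str(path)

    path = outdir / "phenotypes.tsv"
    cohort.phenotypes.to_csv(path, sep="\t")
    files["phenotypes"] = str(path)

    path = outdir / "genotypes.tsv"
    geno = cohort.snp_info.join(cohort.genotypes)
    geno.to_csv(path, sep="\t")
    files["genotypes"] = str(path)

    if cohort.expression is not None:
        path = outdir / "expression.tsv"
        cohort.expression.to_csv(path, sep="\t")
        files["expression"] = str(path)
        path = outdir / "genes.bed"
        cohort.genes[["chrom", "start", "end", "gene_id"]].to_csv(
            path, sep="\t", index=False, header=False
        )
        files["genes"] = str(path)

    path = outdir / "truth.json"
    cohort.truth.to_json(path)
    files["truth"] = str(path)

    if cohort.array_mask is not None:
        path = outdir / "array_mask.txt"
        path.write_text("\n".join(cohort.array_mask) + "\n")
        files["array_mask"] = str(path)
    return files


def read_counts(path) -> StrandCountMatrix:
    """Read a long-format cpg_counts.tsv back into a StrandCountMatrix."""
    long = pd.read_csv(path, sep="\t")
    long["cpg_id"] = long["chrom"].astype(str) + ":" + long["pos"].astype(str)
    order = long.drop_duplicates("cpg_id").sort_values(["chrom", "pos"])
    cpg_index = pd.Index(order["cpg_id"])
    frames = {}
    for strand, label in (("+", "fwd"), ("-", "rev")):
        sub = long[long["strand"] == strand]
        frames[f"meth_{label}"] = (
            sub.pivot(index="cpg_id", columns="sample", values="meth_reads")
            .reindex(cpg_index)
            .fillna(0)
            .astype(int)
        )
        frames[f"total_{label}"] = (
            sub.pivot(index="cpg_id", columns="sample", values="total_reads")
            .reindex(cpg_index)
            .fillna(0)
            .astype(int)
        )
    positions = order.set_index("cpg_id")[["chrom", "pos"]]
    return StrandCountMatrix(
        meth_fwd=frames["meth_fwd"],
        total_fwd=frames["total_fwd"],
        meth_rev=frames["meth_rev"],
        total_rev=frames["total_rev"],
        positions=positions,
    )


ELEMENT_BED_COLUMNS = [
    "chrom", "start", "end", "element_id", "score", "strand",
    "class", "specificity", "tss", "tss_strand", "bivalent",
]


def read_elements(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, names=ELEMENT_BED_COLUMNS)
    bed["bivalent"] = bed["bivalent"].astype(bool)
    return bed.drop(columns=["score", "strand"])


def read_cohort(outdir) -> Cohort:
    """Read back a cohort written by :func:`write_cohort`.

    The returned cohort carries no latent methylation (it is not an
    output file); config is a default placeholder.
    """
    outdir = Path(outdir)
    counts = read_counts(outdir / "cpg_counts.tsv")
    elements = read_elements(outdir / "elements.bed")
    phenotypes = pd.read_csv(outdir / "phenotypes.tsv", sep="\t", index_col=0)
    geno = pd.read_csv(outdir / "genotypes.tsv", sep="\t", index_col=0)
    snp_info = geno[["chrom", "pos", "maf"]]
    genotypes = geno.drop(columns=["chrom", "pos", "maf"])
    cpgs = counts.positions.reset_index()[["chrom", "pos", "cpg_id"]]
    expression = genes = None
    if (outdir / "expression.tsv").exists():
        expression = pd.read_csv(outdir / "expression.tsv", sep="\t", index_col=0)
        genes = pd.read_csv(
            outdir / "genes.bed", sep="\t", header=None,
            names=["chrom", "start", "end", "gene_id"],
        )
    truth = SyntheticTruth.from_json(outdir / "truth.json")
    mask = None
    if (outdir / "array_mask.txt").exists():
        mask = pd.Index((outdir / "array_mask.txt").read_text().split())
    return Cohort(
        config=SimulationConfig(),
        elements=elements,
        cpgs=cpgs,
        phenotypes=phenotypes,
        genotypes=genotypes,
        snp_info=snp_info,
        counts=counts,
        truth=truth,
        expression=expression,
        genes=genes,
        array_mask=mask,
    )
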