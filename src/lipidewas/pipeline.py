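"""Staged pipeline: simulate -> qc -> ewas -> adjust -> annotate ->
replicate -> integrate -> report, with a YAML config, one root seed and
a reproducible run manifest.

Each stage reads its inputs from the run directory and writes plain-text
outputs there; a missing upstream file raises a PipelineError naming the
stage that should have produced it.  The manifest records package
version, seed, per-stage record counts and SHA-256 hashes of outputs, so
identical (seed, config) runs are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lipidewas import __version__, adjust, ewas, integrate, qc, regions, replicate, simulate

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "STAGES"]

log = logging.getLogger("lipidewas")

STAGES = (
    "simulate", "qc", "ewas", "adjust", "annotate", "replicate", "integrate", "report",
)

TRAIT_TRANSFORMS = {"TG": "log", "HDL": "identity", "LDL": "identity", "TC": "identity"}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration (YAML-serializable)."""

    outdir: str = "results/run"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    # QC thresholds
    max_strand_diff: float = 0.20
    min_reads: int = 5
    min_individuals: int = 100
    min_variable_frac: float = 0.10
    # inference thresholds
    fdr: float = 0.10
    alpha: float = 0.05
    # windows
    qtl_window: int = 250_000
    expr_window: int = 1_000_000
    umr_tss_window: int = 1500
    sim: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)

    def validate(self) -> None:
        if not 0 < self.max_strand_diff <= 1:
            raise ValueError("max_strand_diff outside (0, 1]")
        if not 0 < self.fdr < 1 or not 0 < self.alpha < 1:
            raise ValueError("fdr and alpha must lie in (0, 1)")
        if self.min_reads < 1 or self.min_individuals < 1:
            raise ValueError("count thresholds must be positive")
        if self.qtl_window <= 0 or self.expr_window <= 0:
            raise ValueError("cis windows must be positive")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.sim.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        cfg = cls(**raw)
        cfg.sim = simulate.SimulationConfig(**sim_raw)
        if "seed" in raw:
            cfg.sim.seed = cfg.seed
        return cfg

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _need(path: Path, producer: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing input {path.name}: run the '{producer}' stage first"
        )
    return path


def _write_matrix(mat: qc.MethylationMatrix, outdir: Path, prefix: str) -> None:
    mat.meth.to_csv(outdir / f"{prefix}_m.tsv", sep="\t")
    mat.cov.to_csv(outdir / f"{prefix}_cov.tsv", sep="\t")
    mat.positions.to_csv(outdir / f"{prefix}_positions.tsv", sep="\t")


def _read_matrix(outdir: Path, prefix: str, producer: str) -> qc.MethylationMatrix:
    meth = pd.read_csv(_need(outdir / f"{prefix}_m.tsv", producer), sep="\t", index_col=0)
    cov = pd.read_csv(outdir / f"{prefix}_cov.tsv", sep="\t", index_col=0)
    pos = pd.read_csv(outdir / f"{prefix}_positions.tsv", sep="\t", index_col=0)
    return qc.MethylationMatrix(meth, cov, pos)


def _prepare_traits(pheno: pd.DataFrame) -> dict[str, ewas.TraitVector]:
    return {
        t: ewas.prepare_trait(pheno[t], TRAIT_TRANSFORMS[t]) for t in simulate.TRAITS
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages in order and return the run manifest."""
    config.validate()
    config.sim.seed = config.seed
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "files": {},
    }

    def record(stage: str, counts: dict, files: list[Path]) -> None:
        manifest["stages"][stage] = {"status": "run", "counts": counts}
        for f in files:
            manifest["files"][str(f.relative_to(outdir))] = _sha256(f)
        log.info("[%s] done: %s", stage, counts)

    for stage in STAGES:
        if not config.stages.get(stage, True):
            manifest["stages"][stage] = {"status": "skipped"}
            log.info("[%s] skipped", stage)
            continue

        if stage == "simulate":
            disc, repl = simulate.generate_study(config.sim)
            files = []
            for name, cohort in (("discovery", disc), ("replication", repl)):
                written = simulate.write_cohort(cohort, outdir / name)
                files.extend(Path(p) for p in written.values())
            record(stage, {"cpgs": len(disc.cpgs), "samples": len(disc.phenotypes)}, files)

        elif stage == "qc":
            counts_out = {}
            files = []
            for name in ("discovery", "replication"):
                cdir = outdir / name
                counts = simulate.read_counts(_need(cdir / "cpg_counts.tsv", "simulate"))
                mat = qc.merge_strands(counts, config.max_strand_diff)
                mat = qc.apply_min_coverage(mat, config.min_reads)
                mat, report = qc.filter_sites(
                    mat, config.min_individuals, config.min_variable_frac
                )
                _write_matrix(mat, cdir, "methylation")
                report.to_csv(cdir / "site_qc.tsv", sep="\t")
                counts_out[name] = int(len(mat.cpg_ids))
                files += [cdir / "methylation_m.tsv", cdir / "site_qc.tsv"]
            record(stage, counts_out, files)

        elif stage == "ewas":
            counts_out = {}
            files = []
            for name in ("discovery", "replication"):
                cdir = outdir / name
                mat = _read_matrix(cdir, "methylation", "qc")
                pheno = pd.read_csv(
                    _need(cdir / "phenotypes.tsv", "simulate"), sep="\t", index_col=0
                )
                records = ewas.run_ewas(mat, _prepare_traits(pheno), pheno)
                records.to_csv(cdir / "ewas.tsv", sep="\t", index=False)
                counts_out[name] = int(len(records))
                files.append(cdir / "ewas.tsv")
            record(stage, counts_out, files)

        elif stage == "adjust":
            counts_out = {}
            files = []
            for name in ("discovery", "replication"):
                cdir = outdir / name
                records = pd.read_csv(_need(cdir / "ewas.tsv", "ewas"), sep="\t")
                adjusted, summary = adjust.adjust_associations(records, (0.05, config.fdr))
                adjusted.to_csv(cdir / "ewas_adjusted.tsv", sep="\t", index=False)
                (cdir / "null_fit.json").write_text(json.dumps(summary, indent=1, default=float))
                counts_out[name] = {
                    t: round(s["lambda_raw"], 3) for t, s in summary.items()
                }
                files += [cdir / "ewas_adjusted.tsv", cdir / "null_fit.json"]
            record(stage, counts_out, files)

        elif stage == "annotate":
            cdir = outdir / "discovery"
            elements = simulate.read_elements(_need(outdir / "discovery" / "elements.bed", "simulate"))
            files = []
            for name in ("discovery", "replication"):
                cdir = outdir / name
                adjusted = pd.read_csv(_need(cdir / "ewas_adjusted.tsv", "adjust"), sep="\t")
                cpgs = adjusted[["cpg_id", "chrom", "pos"]].drop_duplicates("cpg_id").reset_index(drop=True)
                owner = regions.annotate_cpgs(cpgs, elements)
                owner_map = pd.Series(owner.values, index=cpgs["cpg_id"].values)
                adjusted["element_id"] = adjusted["cpg_id"].map(owner_map)
                adjusted.to_csv(cdir / "ewas_annotated.tsv", sep="\t", index=False)
                files.append(cdir / "ewas_annotated.tsv")
            # positional profile and enrichment on discovery lipid-CpGs
            adjusted = pd.read_csv(outdir / "discovery" / "ewas_annotated.tsv", sep="\t")
            cpgs = adjusted[["cpg_id", "chrom", "pos"]].drop_duplicates("cpg_id").reset_index(drop=True)
            owner = regions.annotate_cpgs(cpgs, elements)
            lipid_cpgs = set(adjusted.loc[adjusted["q"] <= config.fdr, "cpg_id"])
            prof_all = regions.positional_profile(cpgs, elements, owner, umr_tss_window=config.umr_tss_window)
            prof_sig = regions.positional_profile(cpgs, elements, owner, subset=lipid_cpgs, umr_tss_window=config.umr_tss_window)
            prof = pd.DataFrame(
                {
                    "bin_left": prof_all.bins[:-1],
                    "bin_right": prof_all.bins[1:],
                    "lmr_all": prof_all.lmr_hist,
                    "umr_all": prof_all.umr_hist,
                    "lmr_lipid": prof_sig.lmr_hist,
                    "umr_lipid": prof_sig.umr_hist,
                }
            )
            prof.to_csv(outdir / "positional_profile.tsv", sep="\t", index=False)
            emap = elements.set_index("element_id")["class"]
            owner_class = pd.Series(owner.values, index=cpgs["cpg_id"].values).map(
                lambda e: emap[e] if pd.notna(e) and e is not None else "background"
            )
            enr_rows = []
            for cls in ("LMR", "UMR"):
                fg_ids = [c for c in lipid_cpgs if owner_class.get(c) == cls]
                enr = regions.fisher_enrichment(
                    len(fg_ids), max(len(lipid_cpgs), 1),
                    int((owner_class == cls).sum()), len(cpgs),
                )
                enr_rows.append(
                    {"class": cls, "a": enr.a, "b": enr.b, "c": enr.c, "d": enr.d,
                     "prop_fg": enr.proportion_fg, "prop_bg": enr.proportion_bg,
                     "fold": enr.fold, "p": enr.p}
                )
            pd.DataFrame(enr_rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            files += [outdir / "positional_profile.tsv", outdir / "enrichment.tsv"]
            record(stage, {"lipid_cpgs": len(lipid_cpgs)}, files)

        elif stage == "replicate":
            disc = pd.read_csv(_need(outdir / "discovery" / "ewas_annotated.tsv", "annotate"), sep="\t")
            repl = pd.read_csv(_need(outdir / "replication" / "ewas_annotated.tsv", "annotate"), sep="\t")
            elements = simulate.read_elements(outdir / "discovery" / "elements.bed")
            lipid = disc[(disc["q"] <= config.fdr) & disc["element_id"].notna()]
            lipid_regions = lipid[["element_id", "trait"]].drop_duplicates()
            disc_in = disc.merge(lipid_regions, on=["element_id", "trait"])
            outcomes = replicate.replicate_regions(disc_in, repl, alpha=config.alpha)
            outcomes.to_csv(outdir / "replication.tsv", sep="\t", index=False)
            fm = replicate.fine_map_contrast(disc_in, repl, elements)
            fm.to_csv(outdir / "fine_mapping.tsv", sep="\t", index=False)
            spec_map = elements.set_index("element_id")["specificity"]
            shared = set(elements.loc[elements["specificity"] == "shared", "element_id"])
            specific = set(elements.loc[elements["specificity"] == "adipose_specific", "element_id"])
            contrast = {}
            try:
                contrast = replicate.replication_rate_contrast(outcomes, shared, specific)
            except ValueError as exc:
                contrast = {"error": str(exc)}
            (outdir / "replication_contrast.json").write_text(json.dumps(contrast, indent=1, default=float))
            record(
                stage,
                {"regions": int(len(outcomes)),
                 "replicated": int((outcomes["class"] == "replicated_same_direction").sum()) if len(outcomes) else 0},
                [outdir / "replication.tsv", outdir / "fine_mapping.tsv", outdir / "replication_contrast.json"],
            )

        elif stage == "integrate":
            cdir = outdir / "discovery"
            mat = _read_matrix(cdir, "methylation", "qc")
            pheno = pd.read_csv(cdir / "phenotypes.tsv", sep="\t", index_col=0)
            geno = pd.read_csv(_need(cdir / "genotypes.tsv", "simulate"), sep="\t", index_col=0)
            snp_info = geno[["chrom", "pos", "maf"]]
            dosages = geno.drop(columns=["chrom", "pos", "maf"])
            elements = simulate.read_elements(cdir / "elements.bed")
            adjusted = pd.read_csv(_need(cdir / "ewas_annotated.tsv", "annotate"), sep="\t")
            cpgs = adjusted[["cpg_id", "chrom", "pos"]].drop_duplicates("cpg_id").reset_index(drop=True)
            owner = regions.annotate_cpgs(cpgs, elements)
            owner_map = pd.Series(owner.values, index=cpgs["cpg_id"].values)
            in_element = owner_map.dropna().index

            sub = qc.MethylationMatrix(
                mat.meth.loc[mat.cpg_ids.isin(in_element)],
                mat.cov.loc[mat.cpg_ids.isin(in_element)],
                mat.positions.loc[mat.cpg_ids.isin(in_element)],
            )
            qtls = integrate.cis_met_qtl(
                sub, dosages, snp_info, pheno, window=config.qtl_window, fdr=config.fdr
            )
            qtls.to_csv(cdir / "metqtl.tsv", sep="\t", index=False)

            lipid_elements = set(
                adjusted.loc[(adjusted["q"] <= config.fdr) & adjusted["element_id"].notna(), "element_id"]
            )
            shared = set(elements.loc[elements["specificity"] == "shared", "element_id"])
            groups = {
                "all_lipid_linked": lipid_elements,
                "adipose_specific": lipid_elements - shared,
                "tissue_shared": lipid_elements & shared,
            }
            background = set(elements["element_id"])
            flags, enrich = integrate.classify_genetic_regulation(
                qtls, owner, cpgs["cpg_id"], groups, background, fdr=config.fdr
            )
            report_rows = [
                {"group": name, "n": r.b, "n_regulated": r.a, "proportion": r.proportion_fg,
                 "fold": r.fold, "p": r.p}
                for name, r in enrich.items()
            ]
            pd.DataFrame(report_rows).to_csv(cdir / "genetic_regulation_report.tsv", sep="\t", index=False)

            expr_files = []
            if (cdir / "expression.tsv").exists():
                expression = pd.read_csv(cdir / "expression.tsv", sep="\t", index_col=0)
                genes = pd.read_csv(
                    cdir / "genes.bed", sep="\t", header=None,
                    names=["chrom", "start", "end", "gene_id"],
                )
                lipid_cpg_ids = owner_map[owner_map.isin(lipid_elements)].index
                lip = qc.MethylationMatrix(
                    mat.meth.loc[mat.cpg_ids.isin(lipid_cpg_ids)],
                    mat.cov.loc[mat.cpg_ids.isin(lipid_cpg_ids)],
                    mat.positions.loc[mat.cpg_ids.isin(lipid_cpg_ids)],
                )
                if len(lip.cpg_ids):
                    expr_assoc = integrate.cis_expression_association(
                        lip, expression, genes, pheno, window=config.expr_window, fdr=config.fdr
                    )
                else:
                    expr_assoc = pd.DataFrame()
                expr_assoc.to_csv(cdir / "expr_assoc.tsv", sep="\t", index=False)
                expr_files.append(cdir / "expr_assoc.tsv")
            record(
                stage,
                {"qtl_tests": int(len(qtls)),
                 "qtl_significant": int(qtls["significant"].sum()) if len(qtls) else 0},
                [cdir / "metqtl.tsv", cdir / "genetic_regulation_report.tsv"] + expr_files,
            )

        elif stage == "report":
            manifest_path = outdir / "manifest.json"
            manifest["n_stages"] = len([s for s in manifest["stages"].values() if s["status"] == "run"]) + 1
            manifest["stages"]["report"] = {"status": "run", "counts": {}}
            manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=float))
            log.info("[report] manifest written to %s", manifest_path)

    return manifest
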