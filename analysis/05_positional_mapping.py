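"""Annotate lipid-CpGs to regulatory elements and map their positions.

Assigns every CpG to its containing element (LMR enhancer / UMR
promoter / background), contrasts lipid-CpG membership against the
background with Fisher fold changes, and computes the percent-distance-
from-midpoint profiles (UMRs restricted to TSS-anchored, non-bivalent
promoters, strand-oriented).  Also quantifies what an array-like CpG
subsample captures of each element class.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _study import RESULTS, STUDY_DIR, study_config

from lipidewas.pipeline import run_pipeline
from lipidewas.regions import annotate_cpgs, array_mask_comparison, plot_positional_profile, positional_profile
from lipidewas.simulate import read_elements


def main() -> None:
    run_pipeline(study_config(stages=["annotate"]))
    enr = pd.read_csv(STUDY_DIR / "enrichment.tsv", sep="\t")
    for _, row in enr.iterrows():
        print(f"lipid-CpGs in {row['class']}: {row['prop_fg']:.0%} vs background "
              f"{row['prop_bg']:.0%} (fold {row['fold']}, Fisher p {row['p']:.2g})")

    adj = pd.read_csv(STUDY_DIR / "discovery" / "ewas_annotated.tsv", sep="\t")
    elements = read_elements(STUDY_DIR / "discovery" / "elements.bed")
    cpgs = adj[["cpg_id", "chrom", "pos"]].drop_duplicates("cpg_id").reset_index(drop=True)
    mask = set((STUDY_DIR / "discovery" / "array_mask.txt").read_text().split())
    capture = array_mask_comparison(cpgs, mask, elements)
    for cls in ("LMR", "UMR"):
        c = capture[cls]
        print(f"array-like mask captures {c['fraction']:.0%} of {cls} CpGs "
              f"({c['n_captured']}/{c['n_resident']})")

    lipid = set(adj.loc[adj["q"] <= 0.10, "cpg_id"])
    prof = positional_profile(cpgs, elements, subset=lipid)
    fig_path = RESULTS / "positional_profile_lipid_cpgs.png"
    plot_positional_profile(prof, fig_path, title="lipid-CpG positions within elements")
    print(f"profile written to {STUDY_DIR / 'positional_profile.tsv'} and {fig_path}")


if __name__ == "__main__":
    main()
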