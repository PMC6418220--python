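"""Empirical-null recalibration and per-trait multiplicity control.

Fits the constrained three-component Gaussian mixture to each trait's
z-scores, rescales them by the estimated null bias/inflation, and
derives Storey q-values per trait.  Reports the genomic inflation
factor before and after correction and the lipid-CpG counts at FDR 10%
and 5%.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _study import STUDY_DIR, study_config

from lipidewas.pipeline import run_pipeline


def main() -> None:
    run_pipeline(study_config(stages=["adjust"]))
    summary = json.loads((STUDY_DIR / "discovery" / "null_fit.json").read_text())
    for trait, s in sorted(summary.items()):
        print(f"[{trait}] lambda {s['lambda_raw']:.2f} -> {s['lambda_corrected']:.2f} "
              f"(mu0 {s['mu0']:+.3f}, sigma0 {s['sigma0']:.3f}, pi0 {s['pi0']:.2f})")
    adj = pd.read_csv(STUDY_DIR / "discovery" / "ewas_adjusted.tsv", sep="\t")
    for level in (0.10, 0.05):
        n = adj.loc[adj["q"] <= level, "cpg_id"].nunique()
        print(f"lipid-CpGs at FDR {level:.0%}: {n}")


if __name__ == "__main__":
    main()
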