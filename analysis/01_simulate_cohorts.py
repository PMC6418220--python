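"""Generate the synthetic two-tissue study with planted ground truth.

Writes a discovery (adipose-like) and a replication (blood-like) cohort
under results/study/: regulatory elements, per-strand CpG read counts,
lipid phenotypes with covariates, genotype dosages, expression, and the
truth registry of planted CpG-lipid, SNP-CpG and CpG-expression effects.
Effects at adipose-specific elements are silent in the second tissue.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _study import STUDY_DIR, study_config

from lipidewas.pipeline import run_pipeline
from lipidewas.simulate import SyntheticTruth


def main() -> None:
    run_pipeline(study_config(stages=["simulate"]))
    truth = SyntheticTruth.from_json(STUDY_DIR / "discovery" / "truth.json")
    n_counts = sum(1 for _ in open(STUDY_DIR / "discovery" / "cpg_counts.tsv")) - 1
    print(f"study written to {STUDY_DIR}")
    print(f"planted lipid CpGs: {len(truth.lipid)}; metQTL CpGs: {len(truth.metqtl)}; "
          f"expression-linked genes: {len(truth.expr)}")
    print(f"count rows (cpg x sample x strand): {n_counts}")


if __name__ == "__main__":
    main()
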