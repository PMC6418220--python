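"""Merge strands and apply the site-level QC filters.

Pools forward/reverse counts into methylation proportions (dropping
entries whose strands disagree by >20%), requires >= 5 reads per entry
and coverage in >= 100 individuals with a strictly >10% variable
fraction, then summarizes the baseline methylation landscape (hypo /
intermediate / hyper by the 20% / 80% cutoffs).
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _study import STUDY_DIR, study_config

from lipidewas.pipeline import _read_matrix, run_pipeline
from lipidewas.qc import classify_baseline_state


def main() -> None:
    run_pipeline(study_config(stages=["qc"]))
    for name in ("discovery", "replication"):
        report = pd.read_csv(STUDY_DIR / name / "site_qc.tsv", sep="\t", index_col=0)
        mat = _read_matrix(STUDY_DIR / name, "methylation", "qc")
        states = classify_baseline_state(mat).value_counts(normalize=True)
        kept = int(report["pass"].sum())
        print(f"[{name}] {kept}/{len(report)} CpGs pass QC "
              f"(dropped: {dict(report.loc[~report['pass'], 'reason'].value_counts())})")
        print(f"[{name}] baseline states: "
              + ", ".join(f"{k} {v:.0%}" for k, v in states.items()))


if __name__ == "__main__":
    main()
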