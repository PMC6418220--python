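"""Cross-tissue replication of lipid-linked regions and fine-mapping.

Replicates each discovery (region, trait) pair in the second-tissue
cohort at the per-trait Bonferroni cutoff with direction-of-effect
classes, contrasts tissue-shared vs adipose-specific replication rates
(the tissue-shared rate should dominate: adipose-specific effects are
silent in the replication tissue by construction), and runs the
fine-mapping contrast of dense CpGs against replication top CpGs.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _study import STUDY_DIR, study_config

from lipidewas.pipeline import run_pipeline


def main() -> None:
    run_pipeline(study_config(stages=["replicate"]))
    outcomes = pd.read_csv(STUDY_DIR / "replication.tsv", sep="\t")
    print("replication outcomes:", dict(outcomes["class"].value_counts()))
    contrast = json.loads((STUDY_DIR / "replication_contrast.json").read_text())
    if "error" not in contrast:
        print(f"tissue-shared regions replicate at {contrast['rate_a_pct']}% "
              f"({contrast['k_a']}/{contrast['n_a']}) vs adipose-specific "
              f"{contrast['rate_b_pct']}% ({contrast['k_b']}/{contrast['n_b']}); "
              f"binomial p {contrast['binomial_p']:.2g}")
    fm = pd.read_csv(STUDY_DIR / "fine_mapping.tsv", sep="\t")
    ev = fm[fm["status"] == "evaluated"]
    if len(ev):
        print(f"fine-mapping: {int(ev['refined'].sum())}/{len(ev)} evaluated regions "
              "refined by a non-overlapping CpG with a stronger association")
    else:
        print("fine-mapping: no region met the evaluation preconditions at this scale")


if __name__ == "__main__":
    main()
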