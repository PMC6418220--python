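"""cis metQTL mapping, genetic-regulation classification and expression links.

Regresses element-CpG methylation on SNP dosages within +/-250 kb,
flags elements with a significant metQTL (FDR 10%) and contrasts
lipid-linked element groups against all elements (Table-style fold
changes); associates lipid-element CpG methylation with cis gene
expression (+/-1 Mb, likelihood-ratio test) and summarizes distances to
the most-correlated vs most-proximal gene.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _study import STUDY_DIR, study_config

from lipidewas.pipeline import run_pipeline


def main() -> None:
    run_pipeline(study_config(stages=["integrate"]))
    cdir = STUDY_DIR / "discovery"
    qtls = pd.read_csv(cdir / "metqtl.tsv", sep="\t")
    sig = qtls[qtls["significant"]]
    print(f"metQTL: {len(sig)}/{len(qtls)} tests significant at FDR 10%")
    if len(sig):
        print(f"median |SNP-CpG distance|: significant {sig['distance'].abs().median():.0f} bp "
              f"vs all tested {qtls['distance'].abs().median():.0f} bp")
    report = pd.read_csv(cdir / "genetic_regulation_report.tsv", sep="\t")
    for _, row in report.iterrows():
        print(f"under genetic regulation — {row['group']}: "
              f"{row['n_regulated']}/{row['n']} ({row['proportion']:.0%}), fold {row['fold']}")
    expr_path = cdir / "expr_assoc.tsv"
    if expr_path.exists():
        expr = pd.read_csv(expr_path, sep="\t")
        if len(expr):
            n_sig = int(expr["significant"].sum())
            print(f"cis expression: {n_sig}/{len(expr)} CpG-gene pairs significant at FDR 10%")


if __name__ == "__main__":
    main()
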