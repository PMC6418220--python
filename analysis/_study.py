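"""Shared configuration for the numbered analysis scripts.

One synthetic study, written under results/study/, analysed stage by
stage by the scripts 01-08.  The scale (120 samples, ~60 elements per
class, ~5k CpGs) keeps every script interactive while preserving the
statistical structure of the full-size study; the package defaults
carry the full-scale configuration used by the test suite and the
acceptance script.
"""

from pathlib import Path

from lipidewas.pipeline import PipelineConfig, STAGES
from lipidewas.simulate import SimulationConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
STUDY_DIR = RESULTS / "study"
SEED = 2024


def study_config(stages=None) -> PipelineConfig:
    cfg = PipelineConfig(outdir=str(STUDY_DIR), seed=SEED)
    cfg.sim = SimulationConfig(
        n_samples=120,
        n_elements_lmr=120,
        n_elements_umr=120,
        n_snps=200,
        n_genes=80,
        frac_lipid_cpgs=0.04,
        frac_expr_linked=0.005,
        seed=SEED,
    )
    cfg.min_individuals = 100
    if stages is not None:
        cfg.stages = {s: s in stages for s in STAGES}
    return cfg
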