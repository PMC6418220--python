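import numpy as np
import pandas as pd
import pytest

from lipidewas.qc import MethylationMatrix, StrandCountMatrix
from lipidewas.simulate import SimulationConfig, generate_cohort


def small_config(seed: int = 5, **overrides) -> SimulationConfig:
    base = dict(
        seed=seed,
        n_samples=60,
        n_elements_lmr=25,
        n_elements_umr=25,
        n_snps=60,
        n_genes=25,
        frac_lipid_cpgs=0.03,
        frac_expr_linked=0.01,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """A ~1.3k-CpG cohort reused across read-only tests."""
    return generate_cohort(small_config())


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_strand_counts(entries, samples=("s1",)):
    """Build a StrandCountMatrix from per-CpG tuples.

    ``entries`` maps cpg position -> (mf, tf, mr, tr) for a single
    sample, or a list of such tuples for several samples.
    """
    pos = sorted(entries)
    ids = [f"chr1:{p}" for p in pos]

    def grab(k):
        rows = []
        for p in pos:
            vals = entries[p]
            if isinstance(vals[0], (int, float)):
                vals = [vals]
            rows.append([v[k] for v in vals])
        return pd.DataFrame(rows, index=ids, columns=list(samples))

    positions = pd.DataFrame({"chrom": "chr1", "pos": pos}, index=ids)
    return StrandCountMatrix(grab(0), grab(1), grab(2), grab(3), positions)


def make_matrix(meth, cov, positions=None):
    meth = pd.DataFrame(meth)
    cov = pd.DataFrame(cov)
    if positions is None:
        positions = pd.DataFrame(
            {"chrom": "chr1", "pos": range(100, 100 + len(meth))}, index=meth.index
        )
    return MethylationMatrix(meth, cov, positions)
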