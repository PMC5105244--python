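import numpy as np
import pandas as pd
import pytest

from csfqtl import SimulationConfig, build_covariate_design, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One paper-scale cohort: 379 samples, causal SNP + 150 null variants."""
    return simulate_cohort(SimulationConfig(seed=11, n_null_variants=150))


@pytest.fixture(scope="session")
def default_design(default_cohort):
    _, pheno = default_cohort
    covars, names = build_covariate_design(pheno, ["age", "gender", "batch"])
    return covars, names


def make_counts_matrix(columns, ids=None):
    """Build a GenotypeMatrix from a dict/list of genotype-count columns."""
    from csfqtl import GenotypeMatrix

    counts = np.column_stack([np.asarray(c, dtype=float) for c in columns])
    n, m = counts.shape
    meta = pd.DataFrame(
        {
            "chrom": "1",
            "pos": 1000 * (np.arange(m) + 1),
            "id": ids or [f"v{j}" for j in range(m)],
            "ref": "A",
            "alt": "G",
            "counted_allele": "G",
        }
    )
    return GenotypeMatrix([f"S{i:04d}" for i in range(n)], meta, counts)
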