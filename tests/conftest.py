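import numpy as np
import pandas as pd
import pytest

from polyscore import (
    GenotypeMatrix,
    LDBlockSpec,
    make_variant_panel,
    random_architecture,
    simulate_cohort,
)


def make_panel_frame(m, chrom="1", spacing=1000, maf=0.3, seed=0,
                     alleles=("A", "G")):
    """Minimal variant-metadata frame for hand-built genotype matrices."""
    rng = np.random.default_rng(seed)
    maf_arr = np.full(m, maf, dtype=float) if np.isscalar(maf) else np.asarray(maf)
    return pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(m)],
            "chrom": chrom,
            "pos": 1 + spacing * np.arange(m),
            "a1": alleles[0],
            "a2": alleles[1],
            "maf": maf_arr,
            "info": rng.uniform(0.4, 1.0, m),
            "missing_rate": 0.0,
        }
    )


def genotypes_from_array(X, **panel_kw):
    """Wrap a raw n x m array as a GenotypeMatrix with stub metadata."""
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    return GenotypeMatrix(X, make_panel_frame(m, **panel_kw),
                          [f"s{i}" for i in range(n)])


@pytest.fixture(scope="session")
def small_spec():
    return LDBlockSpec(n_blocks=6, block_size=40, within_block_r=0.8,
                       maf_range=(0.01, 0.5), low_maf_fraction=0.2)


@pytest.fixture(scope="session")
def small_panel(small_spec):
    return make_variant_panel(small_spec, seed=101)


@pytest.fixture(scope="session")
def small_cohort(small_spec, small_panel):
    """1,500-sample cohort with 20 causal variants at h2 = 0.3."""
    arch = random_architecture(small_panel, n_causal=20, seed=202, target_h2=0.3)
    return simulate_cohort(small_spec, arch, 1500, seed=303, panel=small_panel)
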