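import numpy as np
import pytest

from mseqtl.ruv_core import RuvDesign
from mseqtl.synthetic_data import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort exercising every feature: an LD proxy pair, planted
    additive, interaction and phenotype effects, 3 unwanted factors."""
    config = CohortConfig(
        n_snps=12,
        n_genes=300,
        n_controls_genes=80,
        cis_fraction=0.7,
        ld_pairs=[(0, 1, 0.9)],
        interaction_effects=[(0.3, -0.6)],
        phenotype_effects=[0.3],
        seed=7,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def clean_design():
    """A design with pure iid noise controls and a known signal-free X."""
    rng = np.random.default_rng(11)
    n, m = 60, 500
    Y = rng.normal(size=(n, m))
    X = np.column_stack([rng.integers(0, 3, size=n).astype(float),
                         (rng.random(n) < 0.4).astype(float)])
    ctl = np.zeros(m, dtype=bool)
    ctl[:400] = True
    return RuvDesign(Y=Y, X=X, ctl=ctl, factor_names=["G", "P"])
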