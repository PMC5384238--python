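import numpy as np
import pandas as pd
import pytest

from mirpair.matrix import CountMatrix
from mirpair.simulate import SimConfig, generate_cohort


def make_count_matrix(values, groups, features=None, samples=None,
                      tumour_type="TT"):
    values = np.asarray(values)
    features = features or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=features, columns=samples)
    return CountMatrix(df, pd.Series(groups, index=samples), tumour_type)


def nb_counts(rng, mean, disp, size):
    if disp < 1e-12:
        return rng.poisson(mean, size=size)
    r = 1.0 / disp
    return rng.negative_binomial(r, r / (r + mean), size=size)


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-type cohort small enough for fast module-level tests."""
    cfg = SimConfig(n_tumour_types=4, n_genes=120, n_mirnas=40,
                    n_controls_per_type=10, n_tumours_per_type=25,
                    planted_de_fraction=0.2, n_planted_pairs=6,
                    planted_recurrence=3, seed=11)
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth
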