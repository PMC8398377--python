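import numpy as np
import pandas as pd
import pytest

import radmetab as rm


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-dose, two-timepoint cohort with planted effects."""
    spec = rm.EffectSpec(n_metabolites=120, fraction_affected=0.2,
                         sham_drift_fraction=0.05)
    cfg = rm.balanced_design(doses=(0.0, 12.5), days=(-1, 9), n_per_cell=10)
    return rm.simulate_cohort(cfg, spec, seed=11)


@pytest.fixture(scope="session")
def small_imputed(small_cohort):
    matrix, meta, annotation, truth = small_cohort
    imputed, normalized, report = rm.preprocess_pipeline(matrix, meta)
    return imputed, normalized, meta, annotation, truth


def two_class_data(rng, n_per_class=12, n_features=20, shift=0.0, shift_cols=0):
    """Gaussian two-class matrix with an optional mean shift on some columns."""
    X = rng.normal(size=(2 * n_per_class, n_features))
    X[n_per_class:, :shift_cols] += shift
    y = np.array(["a"] * n_per_class + ["b"] * n_per_class)
    return pd.DataFrame(X), y
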