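import numpy as np
import pytest

import zernmp as z

#: Fixed study seed for cohort-level fixtures (shared across test modules).
COHORT_SEED = 42


@pytest.fixture(scope="session")
def default_cohort():
    """Synthetic three-group cohort at default parameters, 30 per group."""
    manifest, maps, truths = z.make_cohort(n_per_group=30, seed=COHORT_SEED)
    return manifest, maps, truths


@pytest.fixture(scope="session")
def cohort_coefficients(default_cohort):
    """105-coefficient fits of every map in the default cohort."""
    manifest, maps, _ = default_cohort
    X = z.fit_cohort(maps)
    return X, manifest.table["group"].to_numpy(int), maps


@pytest.fixture(scope="session")
def cohort_dataset(cohort_coefficients, default_cohort):
    manifest, _, _ = default_cohort
    X, groups, _ = cohort_coefficients
    return z.LabelledDataset(X=X, groups=groups,
                             subjects=manifest.table["subject"].to_numpy())


@pytest.fixture(scope="session")
def disk81():
    return z.make_disk_grid(81)


def paired_cohort(delta: dict, seed: int, n_per_group: int = 15):
    """Two-group cohort whose groups differ only in the given parameters."""
    base = z.GroupPhantomParams(peak_amplitude=0.40,
                                peripheral_baseline=0.15, noise_sd=0.02)
    params = {1: base, 2: base.replace(**delta)}
    manifest, maps, _ = z.make_cohort(n_per_group, seed=seed, groups=(1, 2),
                                      group_params=params)
    X = z.fit_cohort(maps)
    y = (manifest.table["group"].to_numpy(int) == 2).astype(int)
    return X, y
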