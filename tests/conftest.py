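import numpy as np
import pandas as pd
import pytest

from tcellclock import clock, qc, simulate as sim


@pytest.fixture(scope="session")
def small_study():
    """24-donor study with the default planted gene panel, QC'd+normalized."""
    donors = sim.generate_cohort(16, 8, (0, 90), 2, 9, seed=42)
    panel = sim.default_gene_panel(seed=42)
    spec = sim.CellSimSpec(
        cells_per_visit=100,
        subset_composition=sim.default_subset_composition(),
        subset_age_offsets=sim.default_subset_age_offsets(),
        seed=42,
    )
    raw = sim.generate_counts(donors, panel, spec)
    filtered, _ = qc.filter_cells(raw)
    return raw, qc.log2_normalize(filtered)


@pytest.fixture(scope="session")
def clock_data():
    """Standard clock study conditions (20 donors, ~200 cells/donor)."""
    donors, specs, cellspec = sim.clock_study(seed=5)
    raw = sim.generate_counts(donors, specs, cellspec)
    filtered, _ = qc.filter_cells(raw)
    norm = qc.log2_normalize(filtered)
    X, feats, y, groups = clock.make_features(norm)
    return norm, X, feats, y, groups


def make_linear_problem(n, p, seed, n_groups=1, noise=0.5, offsets=None):
    """Simple linear regression problem for clock unit tests."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + rng.normal(0, noise, n)
    if n_groups == 1:
        groups = np.full(n, "g0")
    else:
        groups = np.array([f"g{i % n_groups}" for i in range(n)])
        if offsets is not None:
            y = y + np.array([offsets[i % n_groups] for i in range(n)])
    return X, y, groups, beta
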