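import numpy as np
import pandas as pd
import pytest

from wkgs import GenotypePanel, PhenotypeTable, SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel():
    """4 individuals x 5 markers with a missing call and a monomorphic marker."""
    calls = np.array([
        [0, 1, 2, 0, 0],
        [2, np.nan, 1, 0, 0],
        [1, 1, 0, 2, 0],
        [0, 0, 2, 2, 0],
    ], dtype=float)
    return GenotypePanel(
        individual_ids=[f"I{i}" for i in range(4)],
        marker_ids=[f"M{j}" for j in range(5)],
        calls=calls,
    )


@pytest.fixture
def dh_dataset():
    """Small doubled-haploid dataset: 50 lines, 2 environments, 120 markers."""
    cfg = SimConfig(design="dh_shared_lines", n=50, m=2, p=120, n_qtl=15,
                    h2=0.5, genetic_corr=0.8, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture
def halfsib_dataset():
    """Half-sib families disjoint across 2 environments."""
    cfg = SimConfig(design="half_sib_disjoint", n_families=8, family_size=6,
                    m=2, p=150, n_qtl=20, h2=0.4, genetic_corr=0.6,
                    frac_rare=0.88, seed=13)
    return simulate_dataset(cfg)


@pytest.fixture
def tiny_phenos():
    rows = []
    for env in ("E1", "E2"):
        for i in range(6):
            rows.append({"individual_id": f"I{i}", "environment": env,
                         "trait": "t", "value": float(i) + (env == "E2")})
    return PhenotypeTable(pd.DataFrame(rows))
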