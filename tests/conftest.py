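import numpy as np
import pandas as pd
import pytest

from mthet import (
    CohortConfig,
    GeneModel,
    ReferenceGenome,
    generate_gene_model,
    generate_reference,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def rcrs_ref() -> ReferenceGenome:
    """An rCRS-like genome: 16,569 bp, one placeholder at 3107."""
    return generate_reference(16569, {3107}, seed=11)


@pytest.fixture(scope="session")
def small_ref() -> ReferenceGenome:
    return generate_reference(300, set(), seed=7)


@pytest.fixture(scope="session")
def rcrs_genes(rcrs_ref) -> GeneModel:
    return generate_gene_model(
        rcrs_ref, 6, {"heavy": 5, "light": 1}, seed=5, min_length=300, max_length=900
    )


@pytest.fixture(scope="session")
def cohort(rcrs_ref, rcrs_genes):
    """A mid-sized default-condition cohort shared across read-only tests."""
    cfg = CohortConfig(n_samples=2000, n_sibling_pairs=100)
    return simulate_cohort(rcrs_ref, rcrs_genes, cfg, seed=17)


@pytest.fixture()
def toy_callset() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["A", "A", "B", "B", "C"],
            "pos": [100, 200, 100, 300, 400],
            "ref": ["C", "A", "C", "G", "T"],
            "alt": ["T", "G", "T", "A", "C"],
            "HL": [0.10, 0.40, 0.07, 0.96, 0.004],
            "AD": [20, 80, 14, 192, 1],
            "DP": [200, 200, 200, 200, 250],
            "filter": ["PASS", "PASS", "PASS", "PASS", "PASS"],
        }
    )


def make_samples(n, seed=0, ages=None, ch=None):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:05d}" for i in range(n)],
            "age": ages if ages is not None else rng.integers(40, 71, n),
            "sex": rng.choice(["F", "M"], n),
            "ch": ch if ch is not None else np.zeros(n, dtype=bool),
            "smoking": np.zeros(n, dtype=bool),
            "ancestry": rng.choice(["EUR", "AFR"], n, p=[0.7, 0.3]),
            "haplogroup": rng.choice(["H", "U"], n),
            "mt_contamination": np.zeros(n),
            "nuc_contamination": np.zeros(n),
            "overlapping_homoplasmies": np.zeros(n, dtype=bool),
            "haplogroup_conflict": np.zeros(n, dtype=bool),
            "pilot": np.zeros(n, dtype=bool),
            "mtcn": np.full(n, 120.0),
            "sibling_pair": np.full(n, -1),
        }
    )
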