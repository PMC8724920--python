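import numpy as np
import pandas as pd
import pytest

from hla_thresholds import synthetic


@pytest.fixture(scope="session")
def small_dataset():
    """Six alleles at reduced background size; shared across read-only tests."""
    cfg = synthetic.SyntheticConfig(n_alleles=6, rng_seed=11, n_background=2_000)
    return synthetic.generate(cfg)


@pytest.fixture(scope="session")
def default_scale_dataset():
    """Twelve alleles at the default per-allele and background sizes."""
    cfg = synthetic.SyntheticConfig(n_alleles=12, rng_seed=7)
    return synthetic.generate(cfg)


@pytest.fixture
def scored_frame():
    """Tiny hand-enumerable scored dataset for one allele (4 pos / 6 neg)."""
    return pd.DataFrame(
        {
            "sequence": [f"PEPTIDE{i:02d}"[:9] for i in range(10)],
            "allele": "HLA-A*02:01",
            "ic50_nm": [10, 20, 400, 800, 100, 900, 1500, 450, 5000, 300],
            "ba_rank": [0.1, 0.3, 2.0, 6.0, 1.0, 9.0, 15.0, 3.0, 50.0, 2.5],
            "el_score": [0.99, 0.95, 0.6, 0.2, 0.8, 0.1, 0.05, 0.5, 0.01, 0.7],
            "el_rank": [0.05, 0.1, 1.5, 4.0, 0.8, 7.0, 12.0, 2.0, 40.0, 1.2],
            "role": ["ligand"] * 4 + ["background"] * 6,
        }
    )


def random_unique_9mers(rng: np.random.Generator, n: int) -> list[str]:
    """Distinct random 9-mers for building curation fixtures."""
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    out: set[str] = set()
    while len(out) < n:
        out.add("".join(rng.choice(letters, size=9)))
    return sorted(out)
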