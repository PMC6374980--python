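import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from tractprs.config import SimulationConfig
from tractprs.simulate import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_subjects=500, n_snps=400, n_genes=60, pathway_n_genes=10, seed=11
    )
    return simulate_cohort(cfg)


def make_variants(rng: np.random.Generator, n: int, n_chrom: int = 2,
                  pos_range: int = 1_000_000) -> pd.DataFrame:
    """Random summary-statistics table for oracle tests."""
    chrom = rng.integers(1, n_chrom + 1, size=n).astype(str)
    pos = rng.integers(1, pos_range, size=n)
    return pd.DataFrame(
        {
            "id": [f"v{i}" for i in range(n)],
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "effect_allele": "G",
            "odds_ratio": np.exp(rng.normal(0, 0.1, size=n)),
            "se": np.full(n, 0.05),
            "p": rng.uniform(1e-6, 1.0, size=n),
        }
    )
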