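import numpy as np
import pandas as pd
import pytest

from tumorpool import (
    CallSet,
    SimulationConfig,
    make_truth,
    simulate_region_counts,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Desk-scale config: full structure, small counts, fast to simulate."""
    return SimulationConfig(
        n_truncal=30,
        n_shared=10,
        n_private=10,
        n_germline_het=30,
        n_germline_hom=15,
        n_genes=400,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    return make_truth(small_cfg)


@pytest.fixture(scope="session")
def small_regions(small_truth):
    return [
        simulate_region_counts(small_truth, r)
        for r in range(small_truth.config.n_regions)
    ]


def make_callset_from_detection(
    detected: np.ndarray, sample_id: str, vaf: np.ndarray | None = None
) -> CallSet:
    """Build a CallSet directly from a boolean detection vector (test helper)."""
    n = len(detected)
    if vaf is None:
        vaf = np.where(detected, 0.3, 0.0)
    depth = np.full(n, 100)
    df = pd.DataFrame(
        {
            "variant_id": [f"v{i:05d}" for i in range(n)],
            "depth": depth,
            "alt_count": (vaf * depth).round().astype(int),
            "vaf": vaf,
            "detected": detected,
            "filter_status": np.where(detected, "PASS", "NOT_DETECTED"),
        }
    )
    return CallSet(sample_id, df)
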