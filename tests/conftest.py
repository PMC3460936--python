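import numpy as np
import pytest

from regionrisk import FactorSpec, RegionRecord, RegionTable


@pytest.fixture
def simple_factors():
    return [
        FactorSpec("mortality_rate", "direct", 2, "per 100,000 women"),
        FactorSpec("uninsured_pct", "direct", 1, "%"),
        FactorSpec("median_income", "inverse", 1, "$"),
    ]


@pytest.fixture
def simple_table(simple_factors):
    """Six regions in two groups, complete values, no ties."""
    rng = np.random.default_rng(42)
    records = []
    for i in range(6):
        records.append(
            RegionRecord(
                region_id=f"R{i + 1:02d}",
                group_id="A" if i < 3 else "B",
                values={
                    "mortality_rate": float(20 + rng.uniform(0, 15)),
                    "uninsured_pct": float(rng.uniform(5, 20)),
                    "median_income": float(rng.uniform(35000, 90000)),
                },
            )
        )
    return RegionTable(records=records, factors=simple_factors)


def random_rank_table(rng, n_regions=None, n_factors=None):
    """A random table of raw values plus random factor directions/weights.

    Helper for the scoring-invariant property checks.
    """
    n_regions = n_regions or int(rng.integers(4, 16))
    n_factors = n_factors or int(rng.integers(1, 6))
    factors = [
        FactorSpec(
            name=f"f{j}",
            direction="direct" if rng.random() < 0.5 else "inverse",
            weight=int(rng.integers(1, 4)),
        )
        for j in range(n_factors)
    ]
    values = rng.normal(size=(n_regions, n_factors)).round(
        int(rng.integers(0, 3))  # coarse rounding to provoke ties
    )
    records = [
        RegionRecord(
            region_id=f"R{i:03d}",
            values={f"f{j}": float(values[i, j]) for j in range(n_factors)},
        )
        for i in range(n_regions)
    ]
    return RegionTable(records=records, factors=factors)
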