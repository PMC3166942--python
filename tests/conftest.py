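import logging

import numpy as np
import pandas as pd
import pytest


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    # warnings about dropped rows etc. are expected in many scenarios
    logging.getLogger("rowcollapse").setLevel(logging.ERROR)
    for name in ("rowcollapse.matrix_io", "rowcollapse.collapse", "rowcollapse.network",
                 "rowcollapse.evaluate", "rowcollapse.deconvolve", "rowcollapse.enrich"):
        logging.getLogger(name).setLevel(logging.ERROR)
    yield


@pytest.fixture
def small_matrix() -> pd.DataFrame:
    """Six probes over four samples, three genes of sizes 1, 2 and 3."""
    rng = np.random.default_rng(42)
    values = rng.normal(5.0, 2.0, size=(6, 4))
    return pd.DataFrame(
        values,
        index=["p1", "p2", "p3", "p4", "p5", "p6"],
        columns=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def small_groups() -> pd.Series:
    return pd.Series(
        {"p1": "gA", "p2": "gB", "p3": "gB", "p4": "gC", "p5": "gC", "p6": "gC"},
        name="gene",
    )


def random_grouped_matrix(
    seed: int,
    n_groups: int = 4,
    max_rows_per_group: int = 8,
    n_samples: int = 12,
    missing_fraction: float = 0.1,
) -> tuple[pd.DataFrame, pd.Series]:
    """Random matrix with grouped rows and scattered missing values."""
    rng = np.random.default_rng(seed)
    rows, ids, groups = [], [], {}
    for g in range(n_groups):
        for r in range(int(rng.integers(1, max_rows_per_group + 1))):
            rid = f"g{g}_r{r}"
            ids.append(rid)
            groups[rid] = f"G{g}"
            row = rng.normal(rng.uniform(-2, 6), rng.uniform(0.5, 2.0), size=n_samples)
            miss = rng.random(n_samples) < missing_fraction
            if miss.sum() > n_samples - 4:  # keep enough overlap for correlations
                miss = np.zeros(n_samples, dtype=bool)
            row[miss] = np.nan
            rows.append(row)
    matrix = pd.DataFrame(
        np.vstack(rows), index=ids, columns=[f"s{j}" for j in range(n_samples)]
    )
    return matrix, pd.Series(groups, name="group")
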