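import numpy as np
import pandas as pd
import pytest

import seedbankevo as se


@pytest.fixture(scope="session")
def small_catalog() -> se.GeneCatalog:
    """A 200-gene catalog with log-normally distributed effective lengths."""
    rng = np.random.default_rng(11)
    lengths = pd.Series(
        rng.lognormal(np.log(600), 0.5, 200),
        index=[f"g{i:03d}" for i in range(200)],
    )
    return se.GeneCatalog(lengths)


@pytest.fixture(scope="session")
def tiny_trajectories() -> se.TrajectoryMatrix:
    """Two mutations in one population over four timepoints."""
    rows = []
    freqs = {"mA": [0.10, 0.50, 0.30, 0.20], "mB": [0.05, 0.10, 0.40, 0.90]}
    for mid, fs in freqs.items():
        for j, f in enumerate(fs):
            day = 100 * (j + 1)
            depth = 200
            rows.append(
                (mid, "pop1", "WT", "1day", "gene1", "nonsynonymous",
                 day, day * 3.32, int(round(f * depth)), depth)
            )
    df = pd.DataFrame(rows, columns=se.trajectories.TRAJECTORY_COLUMNS)
    return se.TrajectoryMatrix(df)
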