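import numpy as np
import pandas as pd
import pytest

from bh3map import SimConfig, simulate_screen
from bh3map.simulate import CrisprConfig, DependencyRule, EMTConfig


@pytest.fixture(scope="session")
def default_bundle():
    """One full default synthetic cohort shared across read-only tests."""
    return simulate_screen(SimConfig(seed=11))


@pytest.fixture()
def zero_noise_config():
    """All noise terms off: downstream scores must equal the planted losses."""
    return SimConfig(
        tissues={"LUAD": 6, "BLCA": 6},
        noise_sd_viability=0.0,
        line_sd=0.0,
        crispr=None,
        seed=5,
    )


@pytest.fixture()
def small_panel():
    """Tiny hand-buildable panel: 2 lines x 8 conditions x 2 replicates."""
    rng = np.random.default_rng(7)
    rows = []
    for line in ("L1", "L2"):
        for cond in ("VEH", "A199", "W539", "A121", "A199+W539",
                     "A199+A121", "W539+A121", "TRIPLE"):
            for rep in (1, 2):
                rows.append((line, cond, rep, float(rng.uniform(1e5, 1e6))))
    return pd.DataFrame(rows, columns=["cell_line", "condition", "replicate", "signal"])


def threshold_recovery_config(seed: int) -> SimConfig:
    """Planted cutpoint study: 60 lines, one tissue, +60-point effect at
    tau = 10.0 log2 NOXA, biological noise sd 10 points."""
    return SimConfig(
        tissues={"LUAD": 60},
        base_dependency={"LUAD": {"BCL2": 0.02, "BCLXL": 0.05, "MCL1": 0.10}},
        dependency_rules=(DependencyRule("PMAIP1", "BCLXL", "above", 10.0, 60.0),),
        expr_means={"PMAIP1": 10.0},
        noise_sd_viability=0.0,
        line_sd=0.10,
        emt=None,
        crispr=None,
        seed=seed,
    )
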