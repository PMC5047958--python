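import numpy as np
import pandas as pd
import pytest

from qifcal import synthetic as syn


@pytest.fixture
def small_survival() -> pd.DataFrame:
    """Four cases, all events, marker groups interleaved in time."""
    return pd.DataFrame(
        {
            "case_id": ["a", "b", "c", "d"],
            "time_months": [1.0, 3.0, 2.0, 4.0],
            "event": [1, 1, 1, 1],
            "marker": ["low", "low", "high", "high"],
        }
    )


@pytest.fixture(scope="session")
def study():
    """One seeded two-platform study in the default regime used throughout the validation suite."""
    return syn.simulate_study(n=323, seed=7)


@pytest.fixture(scope="session")
def noisefree_platforms():
    return (
        syn.PlatformSpec("A", alpha=0.2, beta=1.1, sigma_e=0.0),
        syn.PlatformSpec("B", alpha=0.43, beta=0.95, sigma_e=0.0),
    )


def brute_force_rank_auc(risk: np.ndarray, is_case: np.ndarray) -> float:
    """Pairwise Mann-Whitney AUC with 0.5 for ties (test oracle)."""
    cases = risk[is_case]
    ctrls = risk[~is_case]
    num = 0.0
    for rc in cases:
        for rn in ctrls:
            num += 1.0 if rc > rn else (0.5 if rc == rn else 0.0)
    return num / (len(cases) * len(ctrls))
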