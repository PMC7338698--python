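import numpy as np
import pandas as pd
import pytest

from sdtmem.models import DPSDParams, MSDParams, UVSDParams

#: fixed-condition mean criteria of participant-level UVSD fits
CRITERIA = (-1.21, -0.12, 0.54, 1.08, 1.92)


@pytest.fixture(scope="session")
def criteria():
    return CRITERIA


@pytest.fixture(scope="session")
def uvsd_params():
    """Fixed-condition mean UVSD estimates (d = 1.27, sigma_o = 1.47)."""
    return UVSDParams(1.27, 1.47, CRITERIA)


@pytest.fixture(scope="session")
def dpsd_params():
    return DPSDParams(0.56, 0.26, (-1.14, -0.12, 0.50, 1.03, 2.59))


@pytest.fixture(scope="session")
def msd_params():
    return MSDParams(2.60, 0.58, (-1.25, -0.14, 0.52, 1.08, 2.20))


@pytest.fixture
def small_trials():
    """Minimal valid trial table: 2 participants x 1 condition."""
    rows = []
    rng = np.random.default_rng(7)
    for p in ("p1", "p2"):
        for status, n in (("old", 10), ("new", 10)):
            for r in rng.integers(1, 7, size=n):
                rows.append(
                    {"participant": p, "condition": "fixed", "status": status,
                     "rating": int(r)}
                )
    return pd.DataFrame(rows)
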