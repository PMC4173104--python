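import numpy as np
import pandas as pd
import pytest

from centerbench.registry_io import StratumTable, expand_stratum_table, registry_from_frame


@pytest.fixture
def table1() -> StratumTable:
    """Three-center artificial stratum table: two centers with identical
    patient-specific risks (1% / 10%) but mirrored patient mix, one center
    with uniformly worse risks (2% / 12%)."""
    df = pd.DataFrame(
        {
            "L": ["low", "high"] * 3,
            "center": ["1", "1", "2", "2", "3", "3"],
            "risk": [0.01, 0.10, 0.01, 0.10, 0.02, 0.12],
            "count": [900, 100, 100, 900, 100, 900],
        }
    )
    return StratumTable(df, pattern_cols=["L"])


@pytest.fixture
def table1_registry(table1):
    return expand_stratum_table(table1)


def make_registry(seed=0, m=4, n_c=100, beta=(0.5,), psi_sd=0.4, psi=None):
    """Simple exchangeable synthetic registry: L ~ N(0,1), logit-linear outcome."""
    from scipy.special import expit

    rng = np.random.default_rng(seed)
    p = len(beta)
    n = m * n_c
    if psi is None:
        psi = rng.normal(-1.2, psi_sd, m)
    psi = np.asarray(psi, dtype=float)
    X = rng.standard_normal((n, p))
    C = np.repeat(np.arange(m), n_c)
    y = (rng.random(n) < expit(X @ np.asarray(beta) + psi[C])).astype(int)
    cols = {f"x{j+1}": X[:, j] for j in range(p)}
    df = pd.DataFrame({"outcome": y, "center": [f"c{c:02d}" for c in C], **cols})
    return registry_from_frame(df, covariates=list(cols)), psi
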