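import numpy as np
import pandas as pd
import pytest

import commoccu as co


@pytest.fixture(scope="session")
def toy_dataset():
    return co.simulate_community(co.toy_scenario(), seed=42)


@pytest.fixture(scope="session")
def toy_tensor(toy_dataset):
    tensor, cov = toy_dataset.to_tensor()
    return tensor, cov


@pytest.fixture(scope="session")
def species_table():
    return co.load_species_table()


def make_deployments(rows):
    """rows: (station, cell, start, end) -> deployments frame."""
    return pd.DataFrame(
        [{"station_id": st, "cell_id": c, "on_trail": False,
          "active_start": pd.Timestamp(a), "active_end": pd.Timestamp(b)}
         for st, c, a, b in rows])


def make_records(rows):
    """rows: (station, species, timestamp) -> records frame."""
    return pd.DataFrame(
        [{"station_id": st, "species_code": sp,
          "timestamp": pd.Timestamp(ts), "count": 1} for st, sp, ts in rows],
        columns=["station_id", "species_code", "timestamp", "count"])


@pytest.fixture(scope="session")
def small_grid():
    cells = ("c1", "c2", "c3")
    return co.SurveyGrid(cells, {c: "A" for c in cells}, cell_area=16.0)


def enumerate_marginal_loglik(params, y, X_psi, X_p):
    """Independent oracle: likelihood by summing over all 2^J latent states."""
    from scipy.special import expit
    import itertools

    J, K = y.shape
    psi = expit(X_psi @ params[: X_psi.shape[1]])
    p = expit(X_p @ params[X_psi.shape[1]:])
    obs = ~np.isnan(y)
    total = 0.0
    for j in range(J):
        cell = 0.0
        for z in (0, 1):
            pr = psi[j] if z else 1.0 - psi[j]
            for k in range(K):
                if not obs[j, k]:
                    continue
                pd_ = p[j, k] * z
                pr *= pd_ if y[j, k] == 1 else 1.0 - pd_
            cell += pr
        total += np.log(cell)
    return total
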