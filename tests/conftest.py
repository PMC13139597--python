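import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from heatmir.simulate import SimulationConfig, simulate_dataset

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ref_config():
    return SimulationConfig(seed=11, n_farms=3, n_cows_per_farm=30, n_years=2)


@pytest.fixture(scope="session")
def ref_dataset(ref_config):
    """Moderate multi-farm dataset shared across integration tests."""
    return simulate_dataset(ref_config)


@pytest.fixture(scope="session")
def tiny_dataset():
    cfg = SimulationConfig(seed=5, n_farms=2, n_cows_per_farm=12, n_years=1)
    return simulate_dataset(cfg)


def random_pedigree(rng, n_animals):
    """Random multi-generation pedigree with unrelated mating pairs.

    Mates with a nonzero additive relationship are rejected so every animal
    is non-inbred, the regime in which the simple Henderson rules invert the
    tabular relationship matrix exactly.
    """
    rows = []
    A = np.zeros((n_animals, n_animals))
    for i in range(n_animals):
        sire = dam = 0
        if i >= 2 and rng.random() < 0.7:
            sire = int(rng.integers(0, i)) + 1
        if i >= 2 and rng.random() < 0.7:
            dam = int(rng.integers(0, i)) + 1
            if dam == sire or (sire and A[sire - 1, dam - 1] != 0.0):
                dam = 0
        for j in range(i):
            val = 0.0
            if sire:
                val += 0.5 * A[j, sire - 1]
            if dam:
                val += 0.5 * A[j, dam - 1]
            A[i, j] = A[j, i] = val
        A[i, i] = 1.0
        rows.append({"animal": i + 1, "sire": sire, "dam": dam})
    return pd.DataFrame(rows)


def tabular_a_matrix(pedigree):
    """Dense numerator relationship matrix by the tabular method (oracle)."""
    n = len(pedigree)
    idx = {a: i for i, a in enumerate(pedigree["animal"])}
    A = np.zeros((n, n))
    for i, (a, s, d) in enumerate(
        pedigree[["animal", "sire", "dam"]].itertuples(index=False)
    ):
        ps = idx.get(s) if s != 0 else None
        pd_ = idx.get(d) if d != 0 else None
        for j in range(i):
            val = 0.0
            if ps is not None:
                val += 0.5 * A[j, ps]
            if pd_ is not None:
                val += 0.5 * A[j, pd_]
            A[i, j] = A[j, i] = val
        A[i, i] = 1.0 + (0.5 * A[ps, pd_] if ps is not None and pd_ is not None
                         else 0.0)
    return A


def dense_blup_oracle(X, Z_G_pairs, y, sigma2_e):
    """Independent GLS/BLUP solution via direct dense inversion of V."""
    n = len(y)
    V = sigma2_e * np.eye(n)
    for Z, G in Z_G_pairs:
        V += Z @ G @ Z.T
    Vinv = np.linalg.inv(V)
    XtVinv = X.T @ Vinv
    b = np.linalg.solve(XtVinv @ X, XtVinv @ y)
    resid_marg = y - X @ b
    us = [G @ Z.T @ Vinv @ resid_marg for Z, G in Z_G_pairs]
    return b, us
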