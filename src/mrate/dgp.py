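"""Synthetic data-generating process for the simulation study.

Ten standard-normal covariates X1..X10 with four correlated pairs
(corr(X1,X5) = corr(X4,X9) = 0.9, corr(X2,X6) = corr(X3,X8) = 0.2, all other
pairs independent), a logistic treatment-assignment model on X1..X7 with no
intercept, and a linear-plus-quadratic outcome model with an additive unit
treatment effect and N(0,1) noise.  The true average treatment effect is
exactly 1 for every subject, while the raw difference of arm means is
confounded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import Dataset, EmptyArmError

__all__ = [
    "DGPConfig",
    "SimulatedDataset",
    "TRUE_ATE",
    "COVARIATE_NAMES",
    "correlation_matrix",
    "generate_covariates",
    "generate_treatment",
    "generate_outcome",
    "outcome_mean",
    "generate_dataset",
]

TRUE_ATE = 1.0
N_COVARIATES = 10
COVARIATE_NAMES = tuple(f"X{i}" for i in range(1, N_COVARIATES + 1))

# (i, j, r) pairs, 1-based covariate indices
_CORRELATED_PAIRS = ((1, 5, 0.9), (4, 9, 0.9), (2, 6, 0.2), (3, 8, 0.2))

# logit[P(Z=1|X)] = 0.8 X1 - 0.25 X2 + 0.6 X3 - 0.4 X4 - 0.8 X5 - 0.5 X6 + 0.7 X7
PS_COEF = np.array([0.8, -0.25, 0.6, -0.4, -0.8, -0.5, 0.7])

# E[Y|X,Z] = -3.85 + 0.3 X1 - 0.36 X2 - 0.73 X3 - 0.2 X4 + 0.71 X8 + 0.19 X9
#            + 0.26 X10 + 0.3 X1^2 - 0.36 X2^2 + Z
OUTCOME_INTERCEPT = -3.85
OUTCOME_LINEAR = {  # 1-based covariate index -> coefficient
    1: 0.3, 2: -0.36, 3: -0.73, 4: -0.2, 8: 0.71, 9: 0.19, 10: 0.26,
}
OUTCOME_QUADRATIC = {1: 0.3, 2: -0.36}


def correlation_matrix() -> np.ndarray:
    """The 10x10 population correlation matrix of the covariates."""
    R = np.eye(N_COVARIATES)
    for i, j, r in _CORRELATED_PAIRS:
        R[i - 1, j - 1] = R[j - 1, i - 1] = r
    return R


_CORR = correlation_matrix()
# The pair structure is disjoint, so each 2x2 block has eigenvalues 1 +/- r;
# the smallest eigenvalue is 1 - 0.9 = 0.1 > 0.  Checked once at import.
_min_eig = float(np.linalg.eigvalsh(_CORR).min())
if _min_eig <= 0:  # pragma: no cover - construction guarantees PD
    raise RuntimeError(f"covariate correlation matrix not PD (min eig {_min_eig})")
_CHOL = np.linalg.cholesky(_CORR)


@dataclass(frozen=True)
class DGPConfig:
    """Configuration of one synthetic dataset draw."""

    n: int
    seed: int
    p: int = N_COVARIATES

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.p != N_COVARIATES:
            raise ValueError(f"the generative model has exactly {N_COVARIATES} covariates")


class SimulatedDataset(Dataset):
    """A :class:`Dataset` drawn from the generative model; carries the truth."""

    true_ate: float = TRUE_ATE

    def __init__(self, X: pd.DataFrame, Z: np.ndarray, Y: np.ndarray) -> None:
        super().__init__(X=X, Z=Z, Y=Y)
        self.true_ate = TRUE_ATE


def generate_covariates(config: DGPConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw n rows of the correlated multivariate-normal covariates."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    W = rng.standard_normal((config.n, N_COVARIATES))
    X = W @ _CHOL.T
    return pd.DataFrame(X, columns=list(COVARIATE_NAMES))


def _linear_predictor(X: pd.DataFrame) -> np.ndarray:
    return X.iloc[:, :7].to_numpy() @ PS_COEF


def generate_treatment(X: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli treatment draws from the logistic assignment model."""
    if X.shape[1] < 7:
        raise ValueError("treatment model needs at least 7 covariate columns")
    p = expit(_linear_predictor(X))
    return rng.binomial(1, p)


def true_propensity(X: pd.DataFrame) -> np.ndarray:
    """P(Z=1|X) under the generative model (useful for diagnostics)."""
    return expit(_linear_predictor(X))


def outcome_mean(X: pd.DataFrame, Z: np.ndarray) -> np.ndarray:
    """E[Y|X,Z]; the treatment enters additively with coefficient 1."""
    mu = np.full(len(X), OUTCOME_INTERCEPT)
    for idx, coef in OUTCOME_LINEAR.items():
        mu += coef * X[f"X{idx}"].to_numpy()
    for idx, coef in OUTCOME_QUADRATIC.items():
        mu += coef * X[f"X{idx}"].to_numpy() ** 2
    return mu + np.asarray(Z)


def generate_outcome(X: pd.DataFrame, Z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return outcome_mean(X, Z) + rng.standard_normal(len(X))


def generate_dataset(config: DGPConfig) -> SimulatedDataset:
    """One seeded draw of (X, Z, Y); deterministic given ``config.seed``.

    The seed is split into independent child streams for covariates,
    treatment and noise so the three stages cannot alias.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_x, rng_z, rng_e = (np.random.default_rng(s) for s in ss.spawn(3))
    X = generate_covariates(config, rng_x)
    Z = generate_treatment(X, rng_z)
    Y = generate_outcome(X, Z, rng_e)
    ds = SimulatedDataset(X=X, Z=Z, Y=Y)
    if ds.n_treated == 0 or ds.n_control == 0:
        raise EmptyArmError(
            f"simulated dataset with n={config.n}, seed={config.seed} has an empty arm"
        )
    return ds
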