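"""Candidate propensity-score and outcome-regression models.

Two families are supported:

* parametric — maximum-likelihood logistic regression for the propensity
  score, ordinary least squares for the outcome regression (fit on the full
  sample with the treatment as a regressor);
* network — a single-hidden-layer neural network with 4 sigmoid hidden
  units (sigmoid output + cross-entropy loss for the PS, identity output +
  squared-error loss for the OR), trained full-batch by L-BFGS for at most
  100 iterations with no weight decay, deterministic given its seed.

Feature terms are strings over the covariate columns: ``"X1"`` (linear),
``"X1^2"`` (square), ``"X1*X2"`` (pairwise product).  OR models always take
the treatment as an additional input and are evaluated counterfactually at
Z=1 and Z=0 for every subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier, MLPRegressor

from .data import Dataset, EstimationError

__all__ = [
    "ModelSpec",
    "FittedCandidates",
    "ModelFitError",
    "design_matrix",
    "fit_parametric_ps",
    "fit_parametric_or",
    "fit_network",
    "predict_counterfactuals",
    "assemble_candidates",
]

# propensities are clipped strictly inside (0,1) before use in constraints/IPW
PS_CLIP = 1e-6


class ModelFitError(EstimationError):
    """A candidate model failed to fit (non-convergence, separation, ...)."""


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one candidate model.

    ``features`` is an ordered list of feature terms; OR models additionally
    receive the treatment as an input (``include_treatment``, default True
    for OR specs — the treatment is never a PS feature).
    """

    target: Literal["ps", "or"]
    form: Literal["parametric", "network"]
    features: tuple[str, ...]
    include_treatment: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.target not in ("ps", "or"):
            raise ValueError(f"target must be 'ps' or 'or', got {self.target!r}")
        if self.form not in ("parametric", "network"):
            raise ValueError(f"form must be 'parametric' or 'network', got {self.form!r}")
        if self.target == "ps" and self.include_treatment:
            raise ValueError("PS models must not include the treatment as a feature")
        object.__setattr__(self, "features", tuple(self.features))
        for term in self.features:
            if term in ("Z", "Y"):
                raise ValueError("treatment/outcome cannot appear as covariate features")


def ps_spec(features: Sequence[str], form: str = "parametric") -> ModelSpec:
    return ModelSpec(target="ps", form=form, features=tuple(features))


def or_spec(features: Sequence[str], form: str = "parametric") -> ModelSpec:
    return ModelSpec(target="or", form=form, features=tuple(features), include_treatment=True)


def _eval_term(X: pd.DataFrame, term: str) -> np.ndarray:
    if "*" in term:
        a, b = (t.strip() for t in term.split("*"))
        return X[a].to_numpy() * X[b].to_numpy()
    if term.endswith("^2"):
        return X[term[:-2].strip()].to_numpy() ** 2
    return X[term].to_numpy()


def design_matrix(X: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    """Evaluate feature terms column-wise; shape (n, len(terms))."""
    if len(terms) == 0:
        return np.empty((len(X), 0))
    return np.column_stack([_eval_term(X, t) for t in terms])


class LogisticPS:
    """MLE logistic regression propensity model (with intercept)."""

    def __init__(self, spec: ModelSpec, coef: np.ndarray, intercept: float):
        self.spec = spec
        self.coef = coef
        self.intercept = intercept

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        from scipy.special import expit

        eta = self.intercept + design_matrix(X, self.spec.features) @ self.coef
        return np.clip(expit(eta), PS_CLIP, 1 - PS_CLIP)


def fit_parametric_ps(data: Dataset, spec: ModelSpec, index: int | None = None) -> LogisticPS:
    """Fit Z ~ features by maximum likelihood (unpenalized logistic)."""
    F = design_matrix(data.X, spec.features)
    # drop constant columns so rank deficiency cannot stall the optimizer
    keep = F.std(axis=0) > 0
    # C=inf: unpenalized maximum likelihood
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(F[:, keep], data.Z)
        except ConvergenceWarning as exc:
            raise ModelFitError(
                f"PS model {index if index is not None else spec.features} did not "
                f"converge (possible perfect separation)"
            ) from exc
    if np.abs(clf.coef_).max() > 1e3:
        raise ModelFitError(
            f"PS model {index if index is not None else spec.features}: divergent "
            f"coefficients suggest perfect separation"
        )
    coef = np.zeros(F.shape[1])
    coef[keep] = clf.coef_.ravel()
    return LogisticPS(spec, coef, float(clf.intercept_[0]))


class LinearOR:
    """OLS outcome-regression model: Y ~ 1 + features (+ Z)."""

    def __init__(self, spec: ModelSpec, beta: np.ndarray):
        self.spec = spec
        self.beta = beta  # [intercept, features..., (Z)]

    def predict(self, X: pd.DataFrame, z) -> np.ndarray:
        n = len(X)
        cols = [np.ones(n), *design_matrix(X, self.spec.features).T]
        if self.spec.include_treatment:
            cols.append(np.broadcast_to(np.asarray(z, dtype=float), (n,)))
        return np.column_stack(cols) @ self.beta


def fit_parametric_or(data: Dataset, spec: ModelSpec, index: int | None = None) -> LinearOR:
    """OLS on the full sample; minimum-norm solution if rank deficient."""
    n = data.n
    cols = [np.ones(n), *design_matrix(data.X, spec.features).T]
    if spec.include_treatment:
        cols.append(data.Z.astype(float))
    D = np.column_stack(cols)
    beta, _, rank, _ = np.linalg.lstsq(D, data.Y, rcond=None)
    if rank < D.shape[1]:
        warnings.warn(
            f"OR model {index if index is not None else spec.features}: rank-deficient "
            f"design ({rank} < {D.shape[1]}); using minimum-norm solution",
            stacklevel=2,
        )
    return LinearOR(spec, beta)


class NetworkPS:
    def __init__(self, spec: ModelSpec, net: MLPClassifier):
        self.spec = spec
        self._net = net

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        p = self._net.predict_proba(design_matrix(X, self.spec.features))[:, 1]
        return np.clip(p, PS_CLIP, 1 - PS_CLIP)


class NetworkOR:
    def __init__(self, spec: ModelSpec, net: MLPRegressor):
        self.spec = spec
        self._net = net

    def predict(self, X: pd.DataFrame, z) -> np.ndarray:
        F = design_matrix(X, self.spec.features)
        zcol = np.broadcast_to(np.asarray(z, dtype=float), (len(X),))
        return self._net.predict(np.column_stack([F, zcol]))


_NET_KW = dict(
    hidden_layer_sizes=(4,),
    activation="logistic",
    solver="lbfgs",
    alpha=0.0,
    max_iter=100,
)


def fit_network(data: Dataset, spec: ModelSpec, seed: int, index: int | None = None):
    """Train the 4-hidden-unit network; deterministic given ``seed``."""
    F = design_matrix(data.X, spec.features)
    label = index if index is not None else spec.features
    with warnings.catch_warnings():
        # hitting the 100-iteration cap is expected behaviour, not a failure
        warnings.simplefilter("ignore", ConvergenceWarning)
        try:
            if spec.target == "ps":
                net = MLPClassifier(random_state=seed, **_NET_KW)
                net.fit(F, data.Z)
                fitted = NetworkPS(spec, net)
            else:
                net = MLPRegressor(random_state=seed, **_NET_KW)
                inputs = np.column_stack([F, data.Z.astype(float)])
                net.fit(inputs, data.Y)
                fitted = NetworkOR(spec, net)
        except Exception as exc:  # noqa: BLE001 - surface with model identity
            raise ModelFitError(f"network model {label} failed to train: {exc}") from exc
    if not np.all(np.isfinite(np.concatenate([w.ravel() for w in net.coefs_]))):
        raise ModelFitError(f"network model {label}: non-finite weights after training")
    return fitted


def predict_counterfactuals(fitted_or, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate an OR model at Z=1 and Z=0 for every row of ``X``."""
    return fitted_or.predict(X, 1.0), fitted_or.predict(X, 0.0)


@dataclass
class FittedCandidates:
    """All candidate predictions evaluated on one dataset.

    ``theta1[l] = mean_i pi_hat^l(X_i)`` and ``theta0 = 1 - theta1`` are the
    full-sample propensity targets; ``eta1[k]``/``eta0[k]`` are full-sample
    means of the counterfactual OR predictions.  These are the calibration
    targets of the empirical-likelihood constraints.
    """

    ps_hat: np.ndarray   # (n, n_ps), each column strictly in (0,1)
    m1_hat: np.ndarray   # (n, n_or)
    m0_hat: np.ndarray   # (n, n_or)
    theta1: np.ndarray
    theta0: np.ndarray
    eta1: np.ndarray
    eta0: np.ndarray

    @property
    def n_ps(self) -> int:
        return self.ps_hat.shape[1]

    @property
    def n_or(self) -> int:
        return self.m1_hat.shape[1]


def _fit_one(data: Dataset, spec: ModelSpec, seed: int, index: int):
    if spec.form == "network":
        return fit_network(data, spec, seed, index=index)
    if spec.target == "ps":
        return fit_parametric_ps(data, spec, index=index)
    return fit_parametric_or(data, spec, index=index)


def assemble_candidates(
    data: Dataset,
    ps_specs: Sequence[ModelSpec],
    or_specs: Sequence[ModelSpec],
    seed: int = 0,
) -> FittedCandidates:
    """Fit every candidate and evaluate it on all n subjects.

    Column order follows spec order.  Network seeds are derived
    deterministically from ``seed``, one child stream per model.
    """
    n = data.n
    n_models = len(ps_specs) + len(or_specs)
    model_seeds = np.random.SeedSequence(seed).generate_state(max(n_models, 1))
    ps_hat = np.empty((n, len(ps_specs)))
    for l, spec in enumerate(ps_specs):
        fitted = _fit_one(data, spec, int(model_seeds[l]), index=l + 1)
        ps_hat[:, l] = np.clip(fitted.predict(data.X), PS_CLIP, 1 - PS_CLIP)
    m1_hat = np.empty((n, len(or_specs)))
    m0_hat = np.empty((n, len(or_specs)))
    for k, spec in enumerate(or_specs):
        fitted = _fit_one(data, spec, int(model_seeds[len(ps_specs) + k]), index=k + 1)
        m1_hat[:, k], m0_hat[:, k] = predict_counterfactuals(fitted, data.X)
    theta1 = ps_hat.mean(axis=0)
    return FittedCandidates(
        ps_hat=ps_hat,
        m1_hat=m1_hat,
        m0_hat=m0_hat,
        theta1=theta1,
        theta0=1.0 - theta1,
        eta1=m1_hat.mean(axis=0),
        eta0=m0_hat.mean(axis=0),
    )
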