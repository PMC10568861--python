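"""Point estimators of the average treatment effect.

Three families:

* ``IPW.modelK`` — inverse probability weighting under the K-th candidate
  propensity model (self-normalized Hájek form by default);
* ``OR.modelK`` — g-computation under the K-th candidate outcome model;
* ``MR<digits>`` — the multiply robust estimator: empirical-likelihood
  calibration weights in each arm against any subset of the candidate
  models, with one binary digit per candidate (PS models left-to-right,
  then OR models).  ``MR000000`` (no constraints) reduces exactly to the
  difference of arm means.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .data import Dataset, EmptyArmError
from .el import build_constraints, el_weights
from .models import FittedCandidates

__all__ = [
    "EstimatorSpec",
    "ATEEstimate",
    "parse_estimator_name",
    "ipw_estimate",
    "or_estimate",
    "mr_estimate",
]


@dataclass(frozen=True)
class EstimatorSpec:
    name: str
    family: str  # "mr" | "ipw" | "or"
    included_ps: tuple[bool, ...]
    included_or: tuple[bool, ...]

    @property
    def ps_indices(self) -> tuple[int, ...]:
        return tuple(i for i, b in enumerate(self.included_ps) if b)

    @property
    def or_indices(self) -> tuple[int, ...]:
        return tuple(i for i, b in enumerate(self.included_or) if b)


@dataclass
class ATEEstimate:
    estimate: float
    estimator: EstimatorSpec
    diagnostics: dict = field(default_factory=dict)


def parse_estimator_name(name: str, n_ps: int, n_or: int) -> EstimatorSpec:
    """Parse 'MR010010' / 'IPW.model2' / 'OR.model1' into inclusion masks.

    MR digits map left-to-right to the PS candidates in spec order, then the
    OR candidates in spec order (six digits for the 3+3 simulation sets).
    """
    m = re.fullmatch(r"MR([01]+)", name)
    if m:
        digits = m.group(1)
        if len(digits) != n_ps + n_or:
            raise ValueError(
                f"{name!r}: expected {n_ps + n_or} digits ({n_ps} PS + {n_or} OR), "
                f"got {len(digits)}"
            )
        bits = tuple(c == "1" for c in digits)
        return EstimatorSpec(name, "mr", bits[:n_ps], bits[n_ps:])
    m = re.fullmatch(r"(IPW|OR)\.model(\d+)", name)
    if m:
        family, k = m.group(1).lower(), int(m.group(2))
        n_avail = n_ps if family == "ipw" else n_or
        if not 1 <= k <= n_avail:
            raise ValueError(f"{name!r}: model index {k} outside 1..{n_avail}")
        mask = tuple(i == k - 1 for i in range(n_avail))
        if family == "ipw":
            return EstimatorSpec(name, "ipw", mask, (False,) * n_or)
        return EstimatorSpec(name, "or", (False,) * n_ps, mask)
    raise ValueError(f"unrecognized estimator name {name!r}")


def ipw_estimate(
    data: Dataset,
    ps_hat_col: np.ndarray,
    spec: EstimatorSpec | None = None,
    hajek: bool = True,
) -> ATEEstimate:
    """IPW ATE under one fitted propensity column.

    Hájek (default): arm-wise weighted means with weights 1/pi (treated) and
    1/(1-pi) (control), each normalized to sum to one.  ``hajek=False``
    gives the unnormalized Horvitz-Thompson sum with divisor n.
    """
    data.require_both_arms()
    pi = np.asarray(ps_hat_col, dtype=float)
    Z, Y = data.Z, data.Y
    wt1 = Z / pi
    wt0 = (1 - Z) / (1 - pi)
    if hajek:
        est = (wt1 @ Y) / wt1.sum() - (wt0 @ Y) / wt0.sum()
    else:
        est = (wt1 @ Y - wt0 @ Y) / data.n
    if spec is None:
        spec = EstimatorSpec("IPW", "ipw", (), ())
    return ATEEstimate(float(est), spec)


def or_estimate(
    data: Dataset,
    m1_col: np.ndarray,
    m0_col: np.ndarray,
    spec: EstimatorSpec | None = None,
) -> ATEEstimate:
    """g-computation: average counterfactual contrast over all n subjects."""
    est = float(np.mean(np.asarray(m1_col) - np.asarray(m0_col)))
    if spec is None:
        spec = EstimatorSpec("OR", "or", (), ())
    return ATEEstimate(est, spec)


def mr_estimate(data: Dataset, fc: FittedCandidates, spec: EstimatorSpec) -> ATEEstimate:
    """Multiply robust estimate over the candidate subset selected by ``spec``.

    The two arms are calibrated independently; a convex-hull failure in
    either arm fails the whole estimate.  With no models selected the
    weights are uniform and the estimate is the raw difference of arm means.
    """
    data.require_both_arms()
    ps_idx = list(spec.ps_indices)
    or_idx = list(spec.or_indices)
    col_idx = ps_idx + [fc.n_ps + k for k in or_idx]
    diagnostics = {}
    parts = {}
    for arm in ("treated", "control"):
        cs = build_constraints(fc, data, arm)
        cs.G = cs.G[:, col_idx]
        sol = el_weights(cs)
        y_arm = data.Y[data.Z == (1 if arm == "treated" else 0)]
        parts[arm] = float(sol.weights @ y_arm)
        diagnostics[arm] = {
            "iterations": sol.iterations,
            "max_constraint_residual": sol.max_constraint_residual,
            "dropped_columns": sol.dropped_columns,
        }
    return ATEEstimate(parts["treated"] - parts["control"], spec, diagnostics)


def estimate(data: Dataset, fc: FittedCandidates, spec: EstimatorSpec, hajek: bool = True) -> ATEEstimate:
    """Dispatch on the estimator family (shared by the CLI and sim engine)."""
    if spec.family == "mr":
        return mr_estimate(data, fc, spec)
    if spec.family == "ipw":
        (l,) = spec.ps_indices
        return ipw_estimate(data, fc.ps_hat[:, l], spec, hajek=hajek)
    if spec.family == "or":
        (k,) = spec.or_indices
        return or_estimate(data, fc.m1_hat[:, k], fc.m0_hat[:, k], spec)
    raise ValueError(f"unknown estimator family {spec.family!r}")
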