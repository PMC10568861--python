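"""Nonparametric bootstrap variance and normality-based 95% CI.

Each resample draws n rows with replacement and re-runs the entire
estimation pipeline (all candidate models refit, EL weights re-solved).
The interval is centered at the original-sample point estimate:

    CI = estimate +/- 1.96 * sqrt(var_hat),
    var_hat = (B-1)^{-1} sum_b (delta_b - mean(delta))^2

over the successful resamples.  Resamples with an empty arm or a solver
failure are skipped and counted; more than 20% failures aborts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .data import Dataset, EstimationError

__all__ = ["BootstrapResult", "bootstrap_ci"]

Z975 = 1.96
MAX_FAIL_FRACTION = 0.2


@dataclass
class BootstrapResult:
    B: int
    estimates: np.ndarray  # successful resample estimates
    variance: float
    se: float
    ci_low: float
    ci_high: float
    n_failed: int
    center: float
    boot_mean: float


def bootstrap_ci(
    data: Dataset,
    estimator_fn: Callable[[Dataset, int], float],
    B: int,
    seed: int,
    point_estimate: float | None = None,
) -> BootstrapResult:
    """Bootstrap ``estimator_fn`` (a full pipeline: ``(dataset, seed) -> float``).

    ``seed`` drives both the resampling and a deterministic per-resample
    sub-seed handed to ``estimator_fn`` (networks are refit under it), so
    identical seeds give identical results.
    """
    if B < 2:
        raise ValueError(f"B must be >= 2, got {B}")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(B + 2)
    if point_estimate is None:
        point_estimate = float(estimator_fn(data, int(children[-1].generate_state(1)[0])))
    rng = np.random.default_rng(children[0])
    n = data.n
    estimates = []
    n_failed = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        sub_seed = int(children[b + 1].generate_state(1)[0])
        try:
            resampled = data.subset(idx)
            resampled.require_both_arms()
            estimates.append(float(estimator_fn(resampled, sub_seed)))
        except EstimationError:
            n_failed += 1
    if n_failed > MAX_FAIL_FRACTION * B:
        raise EstimationError(
            f"bootstrap failed on {n_failed}/{B} resamples (> {MAX_FAIL_FRACTION:.0%})"
        )
    est = np.asarray(estimates)
    boot_mean = float(est.mean())
    variance = float(est.var(ddof=1)) if len(est) > 1 else 0.0
    se = float(np.sqrt(variance))
    return BootstrapResult(
        B=B,
        estimates=est,
        variance=variance,
        se=se,
        ci_low=point_estimate - Z975 * se,
        ci_high=point_estimate + Z975 * se,
        n_failed=n_failed,
        center=point_estimate,
        boot_mean=boot_mean,
    )
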