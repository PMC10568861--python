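"""Core data container for observational ATE analyses.

A :class:`Dataset` holds the covariate matrix ``X`` (a pandas DataFrame so
feature terms can be resolved by column name), the binary treatment vector
``Z`` and the numeric outcome ``Y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Dataset", "EmptyArmError", "EstimationError"]


class EstimationError(RuntimeError):
    """Base class for estimator-level failures (a replication can recover)."""


class EmptyArmError(EstimationError):
    """Raised when the treated or control arm contains no subjects."""


@dataclass
class Dataset:
    """An observational dataset: covariates, binary treatment, outcome.

    Parameters
    ----------
    X : pandas.DataFrame, shape (n, p)
        Covariates; column names are used to resolve model feature terms.
    Z : ndarray of {0, 1}, shape (n,)
        Treatment indicator.
    Y : ndarray, shape (n,)
        Observed outcome.
    """

    X: pd.DataFrame
    Z: np.ndarray = field(repr=False)
    Y: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z)
        self.Y = np.asarray(self.Y, dtype=float)
        n = len(self.X)
        if self.Z.shape != (n,) or self.Y.shape != (n,):
            raise ValueError(
                f"shape mismatch: X has {n} rows, Z has shape {self.Z.shape}, "
                f"Y has shape {self.Y.shape}"
            )
        uniq = np.unique(self.Z)
        if not np.isin(uniq, [0, 1]).all():
            raise ValueError(f"treatment must be binary 0/1, found values {uniq}")
        self.Z = self.Z.astype(int)

    @property
    def n(self) -> int:
        return len(self.Y)

    @property
    def n_treated(self) -> int:
        return int(self.Z.sum())

    @property
    def n_control(self) -> int:
        return self.n - self.n_treated

    def require_both_arms(self) -> None:
        """Raise :class:`EmptyArmError` unless both arms are non-empty."""
        if self.n_treated == 0:
            raise EmptyArmError("treated arm is empty")
        if self.n_control == 0:
            raise EmptyArmError("control arm is empty")

    def subset(self, idx: np.ndarray) -> "Dataset":
        """Row subset (used by the bootstrap); ``idx`` may repeat rows."""
        return Dataset(
            X=self.X.iloc[idx].reset_index(drop=True),
            Z=self.Z[idx],
            Y=self.Y[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = self.X.copy()
        df["Z"] = self.Z
        df["Y"] = self.Y
        return df
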