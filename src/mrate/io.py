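"""Reading analysis tables and writing result files."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .data import Dataset
from .models import ModelSpec

__all__ = ["read_dataset", "write_dataset", "write_results", "load_model_config"]


def read_dataset(
    path,
    treatment: str = "Z",
    outcome: str = "Y",
    covariates: Sequence[str] | None = None,
    sep: str = ",",
) -> Dataset:
    """Read a delimited table into a validated :class:`Dataset`.

    Missing columns, non-binary treatment values or NA cells in the used
    columns are rejected with descriptive errors (no imputation).
    """
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: file is empty") from exc
    for col in (treatment, outcome):
        if col not in df.columns:
            raise ValueError(f"{path}: required column {col!r} not found")
    if covariates is None:
        covariates = [c for c in df.columns if c not in (treatment, outcome)]
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: covariate columns not found: {missing}")
    used = df[list(covariates) + [treatment, outcome]]
    if used.isna().any().any():
        bad = used.columns[used.isna().any()].tolist()
        raise ValueError(f"{path}: missing values in columns {bad}; complete cases required")
    z = pd.to_numeric(df[treatment], errors="raise")
    if not set(z.unique()) <= {0, 1}:
        raise ValueError(
            f"{path}: treatment column {treatment!r} must be binary 0/1, "
            f"found {sorted(z.unique())}"
        )
    X = df[list(covariates)].apply(pd.to_numeric, errors="raise")
    Y = pd.to_numeric(df[outcome], errors="raise")
    return Dataset(X=X.reset_index(drop=True), Z=z.to_numpy(), Y=Y.to_numpy())


def write_dataset(ds: Dataset, path) -> None:
    ds.to_frame().to_csv(path, index=False)


def write_results(results: pd.DataFrame, path) -> None:
    """TSV with floats at 3 decimals; full-precision sidecar JSON next to it."""
    path = Path(path)
    results.to_csv(path, sep="\t", index=False, float_format="%.3f")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(results.to_dict(orient="records"), indent=2))


def load_model_config(path) -> tuple[list[ModelSpec], list[ModelSpec]]:
    """Load candidate model lists from YAML/JSON.

    Expected shape::

        ps_models:
          - {form: parametric, features: [X1, X2, "X1^2"]}
          - {form: network, features: [X1, X2]}
        or_models:
          - {form: parametric, features: [X1, "X1*X2"], include_treatment: true}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a mapping with ps_models/or_models")

    def build(entries, target):
        specs = []
        for entry in entries or []:
            specs.append(
                ModelSpec(
                    target=target,
                    form=entry.get("form", "parametric"),
                    features=tuple(entry["features"]),
                    include_treatment=bool(entry.get("include_treatment", target == "or")),
                )
            )
        return specs

    return build(cfg.get("ps_models"), "ps"), build(cfg.get("or_models"), "or")
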