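"""Reading and writing the delimited formats used by the command line tools.

Feature tables are stored with features in rows and samples in columns
(feature IDs in the first column, sample IDs in the header); in memory the
package works with the transposed samples-by-features orientation that the
estimators expect.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .stepwise import FittedModel, INTERCEPT

__all__ = ["read_features", "read_meta", "model_to_json", "model_from_json"]


def read_features(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a features-by-samples table; returns samples-by-features."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise InvalidInputError(f"empty feature table: {path}")
    return df.T


def read_meta(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a samples-by-covariates metadata table."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise InvalidInputError(f"empty metadata table: {path}")
    return df


def model_to_json(model: FittedModel, path: str | Path) -> None:
    payload = {
        "family": model.family,
        "terms": list(model.terms),
        "term_idx": [int(j) for j in model.term_idx],
        "coefficients": model.coefficients,
        "log_likelihood": model.log_likelihood,
        "criterion_kind": model.criterion_kind,
        "criterion_value": model.criterion_value,
        "converged": model.converged,
        "n_obs": model.n_obs,
        "saturated": model.saturated,
        "scale": None if not np.isfinite(model.scale) else model.scale,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def model_from_json(path: str | Path) -> FittedModel:
    payload = json.loads(Path(path).read_text())
    if INTERCEPT not in payload.get("coefficients", {}):
        raise InvalidInputError(f"not a model file: {path}")
    return FittedModel(
        family=payload["family"],
        terms=list(payload["terms"]),
        term_idx=np.asarray(payload["term_idx"], dtype=int),
        coefficients=payload["coefficients"],
        log_likelihood=payload["log_likelihood"],
        criterion_kind=payload["criterion_kind"],
        criterion_value=payload["criterion_value"],
        converged=payload["converged"],
        n_obs=payload["n_obs"],
        saturated=payload.get("saturated", False),
        scale=payload["scale"] if payload.get("scale") is not None else float("nan"),
    )
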