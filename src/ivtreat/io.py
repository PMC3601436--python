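"""Config parsing, tabular dataset I/O and result serialization.

Datasets travel as delimited text with a header; column roles (outcome,
treatment, covariates, instruments) are declared in a YAML config, never
inferred.  Fits and effect summaries serialize to JSON, simulation tables
to CSV; every output echoes the schema version, seed and config so a run
can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import FitResult, IVDataset
from .effects import EffectSummary
from .likelihood import ExclusionTest, ProfileCurve

log = logging.getLogger("ivtreat")

SCHEMA_VERSION = 1

__all__ = [
    "RunConfig",
    "read_dataset",
    "write_dataset",
    "log_transform_outcome",
    "write_results",
    "read_results",
]


@dataclass
class RunConfig:
    """Declarative description of one analysis run."""

    outcome: str
    treatment: str
    covariates: list[str] = field(default_factory=list)
    instruments: list[str] = field(default_factory=list)
    method: str = "2sls"
    method_options: dict = field(default_factory=dict)
    prior: dict = field(default_factory=dict)
    retransform: str = "smearing"
    log_transform: bool = False
    add_intercept: bool = True
    delimiter: str | None = None
    seed: int = 0
    log_level: str = "INFO"
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self):
        if not self.outcome or not self.treatment:
            raise ValueError("config must declare exactly one outcome and one treatment column")
        roles = [
            {self.outcome},
            {self.treatment},
            set(self.covariates),
            set(self.instruments),
        ]
        seen, overlap = set(), set()
        for r in roles:
            overlap |= seen & r
            seen |= r
        if overlap:
            raise ValueError(f"columns declared in multiple roles: {sorted(overlap)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text


def log_transform_outcome(raw_cost: np.ndarray) -> np.ndarray:
    """Natural log of positive spending; zero or negative entries are
    rejected (rows with zero recorded cost are treated as impossible and
    must be excluded upstream)."""
    raw = np.asarray(raw_cost, dtype=float)
    bad = np.flatnonzero(raw <= 0)
    if bad.size:
        raise ValueError(
            f"nonpositive cost at rows {bad[:5].tolist()}: zero-cost records are "
            "considered impossible and must be excluded before log transformation"
        )
    return np.log(raw)


def read_dataset(path: str | Path, config: RunConfig) -> IVDataset:
    """Read a delimited text file into a validated IVDataset.

    Rows with missing values in any declared column are dropped with a
    logged count; non-binary treatment values raise with the offending rows
    named."""
    df = pd.read_csv(path, sep=config.delimiter, engine="python" if config.delimiter is None else "c")
    declared = [config.outcome, config.treatment] + config.covariates + config.instruments
    missing_cols = [c for c in declared if c not in df.columns]
    if missing_cols:
        raise ValueError(f"declared columns absent from {path}: {missing_cols}")
    sub = df[declared]
    keep = sub.notna().all(axis=1)
    if (~keep).any():
        log.warning("dropping %d rows with missing values", int((~keep).sum()))
    sub = sub.loc[keep]

    zraw = sub[config.treatment].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isin(zraw, (0.0, 1.0)))
    if bad.size:
        vals = zraw[bad[:5]].tolist()
        raise ValueError(
            f"treatment column {config.treatment!r} must be 0/1; rows "
            f"{sub.index[bad[:5]].tolist()} have values {vals}"
        )
    y = sub[config.outcome].to_numpy(dtype=float)
    if config.log_transform:
        y = log_transform_outcome(y)
    X = sub[config.covariates].to_numpy(dtype=float) if config.covariates else np.empty((len(sub), 0))
    if config.add_intercept:
        X = np.column_stack([np.ones(len(sub)), X])
    U = sub[config.instruments].to_numpy(dtype=float)
    return IVDataset(
        y=y,
        z=zraw,
        X=X,
        U=U,
        meta={
            "source": str(path),
            "columns": {
                "outcome": config.outcome,
                "treatment": config.treatment,
                "covariates": config.covariates,
                "instruments": config.instruments,
            },
        },
    )


def write_dataset(data: IVDataset, path: str | Path, sep: str = ",") -> None:
    """Write the dataset as delimited text with generic role-based names
    (y, z, x0..., u0...)."""
    data.to_frame().to_csv(path, sep=sep, index=False)


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="index")
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def _scalar_like(v) -> bool:
    if dataclasses.is_dataclass(v) and not isinstance(v, type):
        return all(
            isinstance(x, (int, float, bool, str, np.floating, np.integer))
            for x in dataclasses.asdict(v).values()
        )
    return isinstance(v, (int, float, bool, str, np.floating, np.integer))


def _fit_payload(result: FitResult) -> dict:
    return {
        "kind": "fit",
        "method": result.method,
        "estimates": _jsonify(result.estimates),
        "se": _jsonify(result.se),
        "vcov": _jsonify(result.vcov.to_numpy()),
        "param_names": list(result.estimates.index),
        "loglik": result.loglik,
        "converged": result.converged,
        "n_obs": result.n_obs,
        "extra": {k: _jsonify(v) for k, v in result.extra.items() if _scalar_like(v)},
    }


def write_results(
    result,
    path: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> None:
    """Serialize a result object (JSON for fits/tests/effects, CSV for
    simulation tables) with schema version, seed and config echoed."""
    path = Path(path)
    envelope = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed if seed is not None else (config.seed if config else None),
        "config": dataclasses.asdict(config) if config else None,
    }
    if isinstance(result, FitResult):
        payload = {**envelope, **_fit_payload(result)}
    elif isinstance(result, ExclusionTest):
        payload = {
            **envelope,
            "kind": "exclusion_test",
            "beta3": _jsonify(result.beta3),
            "se": _jsonify(result.se),
            "z_values": _jsonify(result.z_values),
            "wald": result.wald,
            "f_stat": result.f_stat,
            "df_num": result.df_num,
            "p_value": result.p_value,
            "p_value_f": result.p_value_f,
            "reject": result.reject,
        }
    elif isinstance(result, EffectSummary):
        payload = {**envelope, "kind": "effects", **_jsonify(dataclasses.asdict(result))}
    elif isinstance(result, ProfileCurve):
        result.to_frame().to_csv(path, index=False)
        return
    elif isinstance(result, pd.DataFrame):
        result.to_csv(path, index=False)
        return
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")
    path.write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")


def read_results(path: str | Path) -> dict:
    """Read back a JSON result file."""
    with open(path) as fh:
        return json.load(fh)
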