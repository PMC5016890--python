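"""Fit/transform scaling models over feature matrices.

Four methods share one model container and strict fit-on-train /
transform-anywhere semantics:

``gl``
    Each feature is scaled by its own fitted generalized-logistic curve,
    an approximation of the feature's CDF.  Every finite input, however
    far outside the training range, maps into the open interval (0, 1).
``minmax``
    Linear map of the training range onto [0, 1]; values outside the
    training range map outside [0, 1] (deliberately not clipped — this
    is the method's documented weakness on unseen data).
``zscore``
    Centering by the training mean, division by the training standard
    deviation (n-1 denominator).
``none``
    Identity passthrough, for benchmarking against unscaled data.

Degenerate features never raise during fitting: a constant feature is
flagged and transforms to a constant (0.5 for ``gl``, 0 otherwise), and
a feature whose median collides with an extreme has its center anchor
replaced by the 25th/75th percentile before the curve fit.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .curve import (
    ConvergenceError,
    FeatureSample,
    FitConfig,
    GLParams,
    fit_gl,
    gl_eval,
    init_params_from_anchors,
)

__all__ = [
    "SCALER_METHODS",
    "FeatureRecord",
    "ScalerModel",
    "ModelFormatError",
    "fit_scaler",
    "transform",
    "save_model",
    "load_model",
]

SCALER_METHODS = ("gl", "minmax", "zscore", "none")

MODEL_FORMAT_VERSION = 1

# Fallback reasons recorded per feature
FALLBACK_CONSTANT = "constant"          # fewer than the required distinct values
FALLBACK_DEGENERATE = "degenerate"      # anchors could not be repaired / fit failed


class ModelFormatError(ValueError):
    """Raised when a persisted model file is malformed or invalid."""


@dataclass
class FeatureRecord:
    """Per-feature scaling parameters; ``params`` keys depend on the method."""

    name: str
    fallback: str | None = None
    params: dict[str, float] | None = None


@dataclass
class ScalerModel:
    """A fitted scaling model for a whole matrix."""

    method: str
    features: list[FeatureRecord] = field(default_factory=list)
    n_train: int = 0
    version: str = __version__

    @property
    def n_features(self) -> int:
        return len(self.features)


def _coerce_matrix(data, feature_names=None) -> tuple[np.ndarray, list[str]]:
    """Validate a samples x features matrix; returns (array, names)."""
    if isinstance(data, pd.DataFrame):
        names = [str(c) for c in data.columns]
        arr = data.to_numpy(dtype=float)
    else:
        arr = np.asarray(data, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got ndim={arr.ndim}")
        names = (
            [str(n) for n in feature_names]
            if feature_names is not None
            else [f"f{j}" for j in range(arr.shape[1])]
        )
    if arr.size == 0:
        raise ValueError("empty feature matrix")
    if len(names) != arr.shape[1]:
        raise ValueError("feature_names length does not match number of columns")
    if not np.all(np.isfinite(arr)):
        i, j = np.argwhere(~np.isfinite(arr))[0]
        raise ValueError(
            f"non-finite value at row {i}, column {names[j]!r}; "
            "missing values are rejected, not imputed"
        )
    return arr, names


def _constant_fallback(name: str) -> FeatureRecord:
    warnings.warn(
        f"feature {name!r} is constant; falling back to a constant output",
        RuntimeWarning,
        stacklevel=4,
    )
    return FeatureRecord(name=name, fallback=FALLBACK_CONSTANT)


def _fit_gl_feature(col: np.ndarray, name: str, config: FitConfig) -> FeatureRecord:
    distinct = np.unique(col)
    if distinct.size < 3:
        warnings.warn(
            f"feature {name!r} has fewer than 3 distinct values; "
            "falling back to a constant 0.5 scaling",
            RuntimeWarning,
            stacklevel=3,
        )
        return FeatureRecord(name=name, fallback=FALLBACK_CONSTANT)
    sample = FeatureSample.from_values(col)
    x_min, x_med, x_max = sample.x_min, sample.x_med, sample.x_max
    center = x_med
    if center == x_min:
        center = float(np.percentile(col, 75))
    elif center == x_max:
        center = float(np.percentile(col, 25))
    if not (x_min < center < x_max):
        warnings.warn(
            f"feature {name!r} has no usable interior anchor; "
            "falling back to a constant 0.5 scaling",
            RuntimeWarning,
            stacklevel=3,
        )
        return FeatureRecord(name=name, fallback=FALLBACK_DEGENERATE)
    init = init_params_from_anchors(x_min, center, x_max, strict=False)
    try:
        params, _ = fit_gl(sample, config, init=init)
    except ConvergenceError:  # pragma: no cover - defensive
        return FeatureRecord(name=name, fallback=FALLBACK_DEGENERATE)
    return FeatureRecord(
        name=name,
        params={"Q": params.Q, "B": params.B, "M": params.M, "nu": params.nu},
    )


def fit_scaler(
    train,
    method: str,
    config: FitConfig | None = None,
    feature_names=None,
) -> ScalerModel:
    """Fit a scaling model on training data only.

    Each feature is fitted independently.  Degenerate features (constant,
    or too few distinct values for the curve fit) are flagged with a
    fallback instead of raising.
    """
    if method not in SCALER_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {SCALER_METHODS}")
    arr, names = _coerce_matrix(train, feature_names)
    if method in ("minmax", "zscore") and arr.shape[0] < 2:
        raise ValueError(f"method {method!r} requires at least 2 training samples")
    config = config or FitConfig()
    records: list[FeatureRecord] = []
    for j, name in enumerate(names):
        col = arr[:, j]
        if method == "none":
            records.append(FeatureRecord(name=name))
        elif method == "minmax":
            lo, hi = float(col.min()), float(col.max())
            if lo == hi:
                records.append(_constant_fallback(name))
            else:
                records.append(
                    FeatureRecord(name=name, params={"x_min": lo, "x_max": hi})
                )
        elif method == "zscore":
            mean = float(col.mean())
            std = float(col.std(ddof=1))
            if std == 0.0:
                records.append(_constant_fallback(name))
            else:
                records.append(
                    FeatureRecord(name=name, params={"mean": mean, "std": std})
                )
        else:  # gl
            records.append(_fit_gl_feature(col, name, config))
    return ScalerModel(method=method, features=records, n_train=int(arr.shape[0]))


def _transform_column(method: str, rec: FeatureRecord, col: np.ndarray) -> np.ndarray:
    if rec.fallback is not None:
        fill = 0.5 if method == "gl" else 0.0
        return np.full_like(col, fill)
    if method == "none":
        return col.copy()
    p = rec.params
    if method == "minmax":
        return (col - p["x_min"]) / (p["x_max"] - p["x_min"])
    if method == "zscore":
        return (col - p["mean"]) / p["std"]
    gl = GLParams(Q=p["Q"], B=p["B"], M=p["M"], nu=p["nu"])
    return np.asarray(gl_eval(gl, col))


def transform(model: ScalerModel, data):
    """Apply a fitted model to new data of the same feature layout.

    Returns the same container kind it is given (DataFrame in, DataFrame
    out; otherwise an ndarray).
    """
    is_frame = isinstance(data, pd.DataFrame)
    arr, names = _coerce_matrix(data)
    if arr.shape[1] != model.n_features:
        raise ValueError(
            f"feature count mismatch: model has {model.n_features}, data has {arr.shape[1]}"
        )
    out = np.empty_like(arr)
    for j, rec in enumerate(model.features):
        out[:, j] = _transform_column(model.method, rec, arr[:, j])
    if is_frame:
        return pd.DataFrame(out, columns=data.columns, index=data.index)
    return out


# ---------------------------------------------------------------------------
# Persistence (JSON; float round trip is exact through repr serialization)


def save_model(model: ScalerModel, path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "method": model.method,
        "n_train": model.n_train,
        "version": model.version,
        "features": [
            {"name": rec.name, "fallback": rec.fallback, "params": rec.params}
            for rec in model.features
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def _validate_record(method: str, raw: dict) -> FeatureRecord:
    for key in ("name", "fallback", "params"):
        if key not in raw:
            raise ModelFormatError(f"feature record missing key {key!r}")
    rec = FeatureRecord(name=str(raw["name"]), fallback=raw["fallback"], params=raw["params"])
    if rec.fallback is None and method != "none":
        if not isinstance(rec.params, dict):
            raise ModelFormatError(f"feature {rec.name!r} has no parameter block")
        expected = {
            "gl": {"Q", "B", "M", "nu"},
            "minmax": {"x_min", "x_max"},
            "zscore": {"mean", "std"},
        }[method]
        if set(rec.params) != expected:
            raise ModelFormatError(
                f"feature {rec.name!r}: expected parameters {sorted(expected)}, "
                f"got {sorted(rec.params)}"
            )
        if method == "gl":
            try:
                GLParams(**rec.params)
            except ValueError as exc:
                raise ModelFormatError(f"feature {rec.name!r}: {exc}") from exc
        if method == "zscore" and rec.params["std"] <= 0:
            raise ModelFormatError(f"feature {rec.name!r}: std must be positive")
        if method == "minmax" and rec.params["x_min"] >= rec.params["x_max"]:
            raise ModelFormatError(f"feature {rec.name!r}: x_min must be < x_max")
    return rec


def load_model(path) -> ScalerModel:
    try:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"not a valid model file: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model format version {payload.get('format_version')!r}; "
            f"this release reads version {MODEL_FORMAT_VERSION}"
        )
    method = payload.get("method")
    if method not in SCALER_METHODS:
        raise ModelFormatError(f"unknown scaler method {method!r}")
    raw_features = payload.get("features")
    if not isinstance(raw_features, list) or not raw_features:
        raise ModelFormatError("model file has no feature records")
    features = [_validate_record(method, raw) for raw in raw_features]
    return ScalerModel(
        method=method,
        features=features,
        n_train=int(payload.get("n_train", 0)),
        version=str(payload.get("version", "")),
    )
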