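"""Reading, validation and serialization of tubule-level datasets and fitted models.

The canonical on-disk inputs are two CSV files:

* a long-format *tubule table* with one row per segmented object
  (``subject_id,object_id,<feature_1>,...,<feature_q>``), and
* a *outcome table* with one scalar outcome per subject (``subject_id,y``).

Fitted models (CLUSSO, Full Information, naive) are stored as a single JSON
document; numeric arrays are stored as flat row-major lists with explicit
shapes so a write -> read round trip reproduces every number bit-for-bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "TubuleTable",
    "OutcomeVector",
    "ModelArchive",
    "load_paired_dataset",
    "save_model",
    "load_model",
]

_SCHEMA_VERSION = 1
_METHOD_TAGS = ("clusso", "full_info", "naive")


class DataError(ValueError):
    """Raised for malformed or inconsistent input data or model archives."""


@dataclass
class TubuleTable:
    """Ragged per-subject object-by-feature data.

    One row per object (tubule); ``subject_ids``/``object_ids`` are aligned to
    the rows of ``features`` (an ``(N, q)`` float array). Subjects are exposed
    in sorted order so every downstream per-subject vector has a deterministic
    ordering.
    """

    subject_ids: np.ndarray
    object_ids: np.ndarray
    features: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        self.object_ids = np.asarray(self.object_ids)
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[1] < 1:
            raise DataError("features must be a 2-D array with q >= 1 columns")
        n = self.features.shape[0]
        if len(self.subject_ids) != n or len(self.object_ids) != n:
            raise DataError("subject_ids/object_ids must align with feature rows")
        if len(self.feature_names) != self.features.shape[1]:
            raise DataError("feature_names length must equal number of feature columns")
        if not np.all(np.isfinite(self.features)):
            bad = np.argwhere(~np.isfinite(self.features))[0]
            raise DataError(
                f"non-finite feature value at row {bad[0]}, "
                f"column '{self.feature_names[bad[1]]}'"
            )
        keys = list(zip(self.subject_ids.tolist(), self.object_ids.tolist()))
        if len(set(keys)) != len(keys):
            raise DataError("(subject_id, object_id) pairs must be unique")

    @property
    def q(self) -> int:
        return self.features.shape[1]

    @property
    def n_objects(self) -> int:
        return self.features.shape[0]

    @property
    def subjects(self) -> np.ndarray:
        """Unique subject identifiers in sorted order."""
        return np.unique(self.subject_ids)

    def subject_row_indices(self) -> dict[Any, np.ndarray]:
        """Map each subject id to the row indices of its objects."""
        order = np.argsort(self.subject_ids, kind="stable")
        uniq, starts = np.unique(self.subject_ids[order], return_index=True)
        bounds = np.append(starts, order.size)
        return {
            s: order[bounds[i] : bounds[i + 1]] for i, s in enumerate(uniq.tolist())
        }

    def subset_subjects(self, keep) -> "TubuleTable":
        keep = set(keep)
        mask = np.fromiter(
            (s in keep for s in self.subject_ids.tolist()), bool, self.n_objects
        )
        return TubuleTable(
            self.subject_ids[mask],
            self.object_ids[mask],
            self.features[mask],
            list(self.feature_names),
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TubuleTable":
        required = {"subject_id", "object_id"}
        if not required.issubset(df.columns):
            raise DataError("tubule table requires 'subject_id' and 'object_id' columns")
        feature_names = [c for c in df.columns if c not in required]
        if not feature_names:
            raise DataError("tubule table requires at least one feature column")
        feats = np.empty((len(df), len(feature_names)), dtype=float)
        for j, c in enumerate(feature_names):
            col = pd.to_numeric(df[c], errors="coerce")
            if col.isna().any():
                row = int(np.flatnonzero(col.isna().to_numpy())[0])
                raise DataError(f"non-numeric feature value at row {row}, column '{c}'")
            feats[:, j] = col.to_numpy(dtype=float)
        return cls(
            df["subject_id"].to_numpy(),
            df["object_id"].to_numpy(),
            feats,
            feature_names,
        )

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"subject_id": self.subject_ids, "object_id": self.object_ids}
        )
        for j, name in enumerate(self.feature_names):
            out[name] = self.features[:, j]
        return out


@dataclass
class OutcomeVector:
    """Subject-level scalar outcomes, sorted by subject id."""

    subject_ids: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        self.y = np.asarray(self.y, dtype=float)
        if self.subject_ids.shape != self.y.shape or self.y.ndim != 1:
            raise DataError("subject_ids and y must be aligned 1-D arrays")
        if len(np.unique(self.subject_ids)) != len(self.subject_ids):
            raise DataError("duplicated subject_id in outcomes")
        if not np.all(np.isfinite(self.y)):
            raise DataError("non-finite outcome value")
        order = np.argsort(self.subject_ids)
        self.subject_ids = self.subject_ids[order]
        self.y = self.y[order]

    def select(self, subjects) -> np.ndarray:
        """Outcomes for the given subjects, in the given order."""
        lookup = {s: v for s, v in zip(self.subject_ids.tolist(), self.y)}
        try:
            return np.asarray([lookup[s] for s in subjects], dtype=float)
        except KeyError as exc:  # pragma: no cover - guarded by pairing
            raise DataError(f"subject {exc.args[0]!r} has no outcome") from exc


def load_paired_dataset(tubule_path, outcome_path) -> tuple[TubuleTable, OutcomeVector]:
    """Load and pair a tubule CSV and an outcome CSV on ``subject_id``.

    Subjects present in only one of the files are excluded with a warning;
    an empty intersection is fatal. Subjects are returned in sorted order.
    """
    tub_df = pd.read_csv(tubule_path)
    out_df = pd.read_csv(outcome_path)
    if not {"subject_id", "y"}.issubset(out_df.columns):
        raise DataError("outcome table requires 'subject_id' and 'y' columns")
    tubules = TubuleTable.from_dataframe(tub_df)
    ycol = pd.to_numeric(out_df["y"], errors="coerce")
    if ycol.isna().any():
        row = int(np.flatnonzero(ycol.isna().to_numpy())[0])
        raise DataError(f"non-numeric outcome value at row {row}, column 'y'")
    outcomes = OutcomeVector(out_df["subject_id"].to_numpy(), ycol.to_numpy())

    tub_subjects = set(tubules.subjects.tolist())
    out_subjects = set(outcomes.subject_ids.tolist())
    shared = tub_subjects & out_subjects
    if not shared:
        raise DataError("no subjects shared between tubule and outcome tables")
    only_tub = sorted(tub_subjects - out_subjects)
    only_out = sorted(out_subjects - tub_subjects)
    if only_tub:
        warnings.warn(
            f"excluding {len(only_tub)} subject(s) with tubules but no outcome: "
            f"{only_tub}",
            stacklevel=2,
        )
    if only_out:
        warnings.warn(
            f"excluding {len(only_out)} subject(s) with an outcome but no tubules: "
            f"{only_out}",
            stacklevel=2,
        )
    tubules = tubules.subset_subjects(shared)
    keep = np.isin(outcomes.subject_ids, sorted(shared))
    outcomes = OutcomeVector(outcomes.subject_ids[keep], outcomes.y[keep])
    return tubules, outcomes


@dataclass
class ModelArchive:
    """Everything needed to reuse a fitted model on new data.

    ``beta`` holds the raw fitted column effects used for prediction;
    ``beta_normalized`` holds the L1-normalized, thresholded vector used for
    variable selection and reporting. ``alpha`` and ``cluster_model`` are
    absent (``None``) for the naive method.
    """

    method: str
    feature_names: list[str]
    beta: np.ndarray
    beta_normalized: np.ndarray
    lam: float
    design_mean: np.ndarray
    design_scale: np.ndarray
    y_mean: float
    G: int | None = None
    alpha: np.ndarray | None = None
    cluster_model: dict | None = None
    metadata: dict = field(default_factory=dict)
    schema_version: int = _SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.method not in _METHOD_TAGS:
            raise DataError(f"unknown method tag {self.method!r}")
        self.beta = np.asarray(self.beta, dtype=float)
        self.beta_normalized = np.asarray(self.beta_normalized, dtype=float)
        self.design_mean = np.asarray(self.design_mean, dtype=float)
        self.design_scale = np.asarray(self.design_scale, dtype=float)
        if self.alpha is not None:
            self.alpha = np.asarray(self.alpha, dtype=float)
        if self.method == "naive" and self.alpha is not None:
            raise DataError("naive archives must not carry alpha")
        if self.method != "naive" and self.alpha is None:
            raise DataError(f"{self.method} archives require alpha")


def _encode(obj):
    if isinstance(obj, np.ndarray):
        return {
            "__ndarray__": obj.ravel(order="C").tolist(),
            "shape": list(obj.shape),
            "dtype": str(obj.dtype),
        }
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _decode(obj):
    if isinstance(obj, dict):
        if "__ndarray__" in obj:
            return np.asarray(obj["__ndarray__"], dtype=obj["dtype"]).reshape(
                obj["shape"]
            )
        return {k: _decode(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_decode(v) for v in obj]
    return obj


def save_model(model: ModelArchive, path) -> None:
    """Write a fitted model to a JSON archive."""
    doc = {
        "schema_version": model.schema_version,
        "method": model.method,
        "feature_names": list(model.feature_names),
        "G": model.G,
        "alpha": _encode(model.alpha) if model.alpha is not None else None,
        "beta": _encode(model.beta),
        "beta_normalized": _encode(model.beta_normalized),
        "lam": float(model.lam),
        "design_mean": _encode(model.design_mean),
        "design_scale": _encode(model.design_scale),
        "y_mean": float(model.y_mean),
        "cluster_model": _encode(model.cluster_model)
        if model.cluster_model is not None
        else None,
        "metadata": _encode(model.metadata),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> ModelArchive:
    """Read a model archive; truncated or unknown-schema files are fatal."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise DataError(f"corrupt or truncated model archive: {exc}") from exc
    if doc.get("schema_version") != _SCHEMA_VERSION:
        raise DataError(f"unsupported archive schema version {doc.get('schema_version')}")
    if doc.get("method") not in _METHOD_TAGS:
        raise DataError(f"unknown method tag {doc.get('method')!r}")
    return ModelArchive(
        method=doc["method"],
        feature_names=list(doc["feature_names"]),
        G=doc["G"],
        alpha=_decode(doc["alpha"]) if doc["alpha"] is not None else None,
        beta=_decode(doc["beta"]),
        beta_normalized=_decode(doc["beta_normalized"]),
        lam=doc["lam"],
        design_mean=_decode(doc["design_mean"]),
        design_scale=_decode(doc["design_scale"]),
        y_mean=doc["y_mean"],
        cluster_model=_decode(doc["cluster_model"])
        if doc["cluster_model"] is not None
        else None,
        metadata=_decode(doc["metadata"]),
        schema_version=doc["schema_version"],
    )
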