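"""RBF-kernel SVM coding-potential model.

The modelling surface follows the Model/Results convention:
:class:`CodingPotentialSVM` is built from a labelled feature matrix
(or directly from sequences / FASTA files) and its :meth:`fit` returns
a :class:`CodingPotentialResults` carrying the fitted SVM, the min-max
scaling parameters learned on the training data, and the metadata
needed for bit-reproducible prediction.

Conventions: lncRNA is the positive class (+1), coding the negative
class (−1); a transcript is called lncRNA iff its decision score is
positive — users never choose a cutoff.  Features are min-max scaled
to [0, 1] per feature using parameters fitted on training rows only;
features constant in training map to 0.

Default hyperparameters are cost C = 1 and kernel width
gamma = 1/1366 (one over the number of features); an optional grid
search over C in 2^-3..2^7 and gamma in 2^-9..2^1, selected by 5-fold
CV accuracy, can replace them.  Whatever is used is recorded in the
model metadata.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from . import kmer
from .errors import ModelIOError, SchemaMismatchError
from .io import read_fasta
from .orf import Sequence

POSITIVE_LABEL = "lncRNA"
NEGATIVE_LABEL = "coding"
_MODEL_FORMAT = "lncsieve-model/1"

DEFAULT_COST = 1.0
DEFAULT_GAMMA = 1.0 / kmer.N_FEATURES
COST_GRID = tuple(2.0**e for e in range(-3, 8))
GAMMA_GRID = tuple(2.0**e for e in range(-9, 2))


@dataclass(frozen=True)
class ScalingParams:
    """Per-feature minimum and maximum learned on the training set."""

    data_min: np.ndarray
    data_max: np.ndarray

    def __post_init__(self) -> None:
        if self.data_min.shape != self.data_max.shape:
            raise ValueError("min/max shapes differ")

    @property
    def n_features(self) -> int:
        return self.data_min.size

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = self.data_max - self.data_min
        span = np.where(span == 0, 1.0, span)  # constant features -> 0
        return (np.asarray(X, dtype=float) - self.data_min) / span


def _encode_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "iuf":
        y = np.sign(labels.astype(int))
        bad = ~np.isin(y, (-1, 1))
    else:
        mapping = {POSITIVE_LABEL: 1, NEGATIVE_LABEL: -1}
        y = np.array([mapping.get(str(v), 0) for v in labels])
        bad = y == 0
    if bad.any():
        raise ValueError(
            f"labels must be {POSITIVE_LABEL!r}/{NEGATIVE_LABEL!r} or ±1; "
            f"offending value: {labels[bad][0]!r}"
        )
    return y


def _coerce_features(features, ids=None) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(features, pd.DataFrame):
        ids = list(features.index.astype(str)) if ids is None else list(ids)
        X = features.to_numpy(dtype=float)
    elif features is not None and len(features) and isinstance(features[0], Sequence):
        ids = [s.id for s in features] if ids is None else list(ids)
        X = kmer.feature_frame(list(features)).to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.size == 0:
            X = X.reshape(0, kmer.N_FEATURES)
        ids = None if ids is None else list(ids)
    if X.shape[1] != kmer.N_FEATURES:
        raise SchemaMismatchError(
            f"feature vectors have length {X.shape[1]}, "
            f"schema {kmer.SCHEMA_VERSION!r} requires {kmer.N_FEATURES}"
        )
    return X, ids


class CodingPotentialSVM:
    """SVM model over the 1,366-feature transcript representation.

    Parameters
    ----------
    features : DataFrame, ndarray or list of Sequence
        Labelled training examples (rows in feature-schema order, or
        raw sequences to be featurized).
    labels : array-like
        Class labels, ``"lncRNA"``/``"coding"`` or ±1 (lncRNA positive).
    C, gamma : float
        RBF-SVM cost and kernel width; defaults 1 and 1/1366.
    seed : int
        Seed recorded in the model and driving any internal shuffling.
    class_weight : None or "balanced"
        Off by default (balanced training sets); "balanced" enables
        inverse-frequency weights.
    """

    def __init__(
        self,
        features,
        labels,
        ids=None,
        *,
        C: float = DEFAULT_COST,
        gamma: float = DEFAULT_GAMMA,
        seed: int = 0,
        class_weight: str | None = None,
    ):
        X, ids = _coerce_features(features, ids)
        y = _encode_labels(labels)
        if X.shape[0] != y.size:
            raise ValueError("features and labels disagree in length")
        counts = {v: int((y == v).sum()) for v in (-1, 1)}
        if min(counts.values()) < 2:
            raise ValueError(
                "need at least 2 examples per class "
                f"(got lncRNA={counts[1]}, coding={counts[-1]})"
            )
        if ids is not None:
            pos = {i for i, v in zip(ids, y) if v == 1}
            neg = {i for i, v in zip(ids, y) if v == -1}
            clash = pos & neg
            if clash:
                raise ValueError(f"duplicate ids across classes: {sorted(clash)[:5]}")
        self.X, self.y, self.ids = X, y, ids
        self.C, self.gamma, self.seed = float(C), float(gamma), int(seed)
        self.class_weight = class_weight

    @classmethod
    def from_sequences(cls, coding: list[Sequence], noncoding: list[Sequence], **kw):
        """Build the model from two labelled sequence sets."""
        seqs = list(noncoding) + list(coding)
        labels = [POSITIVE_LABEL] * len(noncoding) + [NEGATIVE_LABEL] * len(coding)
        return cls(seqs, labels, **kw)

    @classmethod
    def from_fasta(cls, coding_path, noncoding_path, **kw):
        """Build the model from two FASTA files (coding, noncoding)."""
        return cls.from_sequences(read_fasta(coding_path), read_fasta(noncoding_path), **kw)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, label_col: str = "label", **kw):
        """Build the model from a feature table with a label column."""
        labels = frame[label_col]
        return cls(frame.drop(columns=[label_col]), labels, **kw)

    def fit(self, grid_search: bool = False, cv: int = 5) -> "CodingPotentialResults":
        """Fit scaling and SVM; optionally grid-search (C, gamma) by CV accuracy."""
        return _fit_svm(
            self.X,
            self.y,
            C=self.C,
            gamma=self.gamma,
            class_weight=self.class_weight,
            seed=self.seed,
            grid_search=bool(grid_search),
            grid_cv=cv,
        )


def _fit_svm(
    X: np.ndarray,
    y: np.ndarray,
    *,
    C: float,
    gamma: float,
    class_weight: str | None,
    seed: int,
    grid_search: bool = False,
    grid_cv: int = 5,
) -> "CodingPotentialResults":
    """Fit min-max scaling (training rows only) then the RBF SVM.

    With ``grid_search`` the (C, gamma) pair is chosen from the spec
    grids by ``grid_cv``-fold CV accuracy on the training data before
    the final fit.
    """
    scaler = MinMaxScaler().fit(X)
    Xs = scaler.transform(X)
    if grid_search:
        search = GridSearchCV(
            SVC(kernel="rbf", class_weight=class_weight),
            {"C": list(COST_GRID), "gamma": list(GAMMA_GRID)},
            scoring="accuracy",
            cv=StratifiedKFold(grid_cv, shuffle=True, random_state=seed),
        ).fit(Xs, y)
        C, gamma = float(search.best_params_["C"]), float(search.best_params_["gamma"])
    svm = SVC(kernel="rbf", C=C, gamma=gamma, class_weight=class_weight)
    svm.fit(Xs, y)
    metadata = {
        "n_lncRNA": int((y == 1).sum()),
        "n_coding": int((y == -1).sum()),
        "C": C,
        "gamma": gamma,
        "class_weight": class_weight,
        "grid_search": grid_search,
        "seed": seed,
        "date": _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
    }
    return CodingPotentialResults(
        svm=svm,
        scaling=ScalingParams(scaler.data_min_.copy(), scaler.data_max_.copy()),
        schema_version=kmer.SCHEMA_VERSION,
        metadata=metadata,
    )


class CodingPotentialResults:
    """A fitted coding-potential model: SVM + scaling + schema + metadata."""

    def __init__(self, svm: SVC, scaling: ScalingParams, schema_version: str, metadata: dict):
        if scaling.n_features != kmer.N_FEATURES:
            raise SchemaMismatchError(
                f"scaling has {scaling.n_features} entries, expected {kmer.N_FEATURES}"
            )
        self.svm = svm
        self.scaling = scaling
        self.schema_version = schema_version
        self.metadata = dict(metadata)

    def _check_schema(self) -> None:
        if self.schema_version != kmer.SCHEMA_VERSION:
            raise SchemaMismatchError(
                f"model schema {self.schema_version!r} does not match "
                f"extractor schema {kmer.SCHEMA_VERSION!r}"
            )

    def decision_scores(self, features, ids=None) -> np.ndarray:
        """Signed margins; positive means lncRNA."""
        self._check_schema()
        X, _ = _coerce_features(features, ids)
        if X.shape[0] == 0:
            return np.empty(0)
        return self.svm.decision_function(self.scaling.transform(X))

    def predict(self, features, ids=None) -> pd.DataFrame:
        """Per-input predictions: id, label, decision score (input order kept)."""
        X, ids = _coerce_features(features, ids)
        scores = self.decision_scores(X)
        if ids is None:
            ids = [f"seq_{i}" for i in range(len(scores))]
        labels = np.where(scores > 0, POSITIVE_LABEL, NEGATIVE_LABEL)
        return pd.DataFrame({"id": ids, "label": labels, "score": scores})

    def predict_fasta(self, path) -> pd.DataFrame:
        return self.predict(read_fasta(path))

    def summary(self) -> str:
        """A human-readable description of the fitted model."""
        md = self.metadata
        sv = getattr(self.svm, "n_support_", None)
        lines = [
            "Coding-potential RBF-SVM".center(58),
            "=" * 58,
            f"{'Schema:':<24}{self.schema_version}",
            f"{'Training examples:':<24}lncRNA={md.get('n_lncRNA')}, coding={md.get('n_coding')}",
            f"{'Cost C:':<24}{md.get('C'):g}",
            f"{'Kernel width gamma:':<24}{md.get('gamma'):g}",
            f"{'Grid search:':<24}{md.get('grid_search')}",
            f"{'Class weight:':<24}{md.get('class_weight')}",
            f"{'Seed:':<24}{md.get('seed')}",
            f"{'Fitted (UTC):':<24}{md.get('date')}",
        ]
        if sv is not None:
            lines.append(f"{'Support vectors:':<24}{int(np.sum(sv))} "
                         f"(per class: {list(map(int, sv))})")
        lines.append("=" * 58)
        lines.append("Decision rule: label = lncRNA iff decision score > 0")
        return "\n".join(lines)

    def save(self, path) -> None:
        """Persist as a single versioned archive (joblib)."""
        payload = {
            "format": _MODEL_FORMAT,
            "schema_version": self.schema_version,
            "svm": self.svm,
            "data_min": self.scaling.data_min,
            "data_max": self.scaling.data_max,
            "metadata": self.metadata,
        }
        joblib.dump(payload, Path(path))


def load_model(path) -> CodingPotentialResults:
    """Load a model archive written by :meth:`CodingPotentialResults.save`.

    Corrupt or truncated files raise ModelIOError; a schema version
    different from the current extractor schema raises
    SchemaMismatchError naming both versions — never a silent
    misprediction.
    """
    try:
        payload = joblib.load(Path(path))
    except Exception as exc:  # joblib/pickle raise a zoo of error types
        raise ModelIOError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != _MODEL_FORMAT:
        raise ModelIOError(f"{path} is not a {_MODEL_FORMAT} archive")
    if payload["schema_version"] != kmer.SCHEMA_VERSION:
        raise SchemaMismatchError(
            f"model schema {payload['schema_version']!r} does not match "
            f"extractor schema {kmer.SCHEMA_VERSION!r}"
        )
    return CodingPotentialResults(
        svm=payload["svm"],
        scaling=ScalingParams(payload["data_min"], payload["data_max"]),
        schema_version=payload["schema_version"],
        metadata=payload["metadata"],
    )


def train(features, labels, ids=None, **config) -> CodingPotentialResults:
    """Functional wrapper: build and fit in one call."""
    grid_search = config.pop("grid_search", False)
    return CodingPotentialSVM(features, labels, ids, **config).fit(grid_search=grid_search)


def predict(results: CodingPotentialResults, features, ids=None) -> pd.DataFrame:
    """Functional wrapper around :meth:`CodingPotentialResults.predict`."""
    return results.predict(features, ids)
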