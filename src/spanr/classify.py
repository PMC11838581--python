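"""SPANR: an SVM deciding whether a predicted structure is consistent
with NMR data.

A structure is labeled "consistent" when its TM-score to the
experimentally determined structure exceeds 0.5 — the conventional
same-fold threshold.  Features come in three groups: the contact/distance
scores (CS-DS), the recall/precision/F metrics (RPF) and the AlphaFold
PAE summaries (PAE).  The classifier is an RBF-kernel SVM with balanced
class weights, feature standardization frozen on the training split, and
sigmoid probability calibration so that a confidence for each class can
be reported.

Also provided here: mismatch augmentation (pairing each dataset member's
NMR data with another member's prediction, doubling the dataset with
mostly poor structures), the Spearman correlation analysis between
heuristics and TM-score, and the grid search selecting the CS/DS distance
thresholds by maximizing those correlations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FEATURE_GROUPS",
    "DatasetEntry",
    "EvalReport",
    "SpanrClassifier",
    "label_entry",
    "mismatch_augment",
    "make_feature_frame",
    "train_spanr",
    "evaluate",
    "predict_confidence",
    "spearman_matrix",
    "grid_search_thresholds",
    "save_model",
    "load_model",
]

#: feature-group name -> DatasetEntry field names
FEATURE_GROUPS: dict[str, list[str]] = {
    "CS-DS": ["cs", "ds"],
    "RPF": ["recall", "precision", "f"],
    "PAE": ["mean_pae", "long_range_mean_pae"],
}

CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"

MODEL_FORMAT_VERSION = 1


@dataclass
class DatasetEntry:
    """One dataset row: scores of a predicted structure against NMR data."""

    entry_id: str
    cs: float | None = None
    ds: float | None = None
    recall: float | None = None
    precision: float | None = None
    f: float | None = None
    mean_pae: float | None = None
    long_range_mean_pae: float | None = None
    tm: float | None = None
    mismatched: bool = False
    donor_id: str | None = None


@dataclass
class EvalReport:
    """Per-class and overall identification rates, in percent."""

    neg_id_rate: float | None
    pos_id_rate: float | None
    total_accuracy: float
    balanced_accuracy: float | None


def label_entry(tm: float) -> str:
    """Classify by TM-score: consistent iff TM > 0.5 (strict)."""
    if not (0.0 <= tm <= 1.0):
        raise ValueError(f"TM-score {tm} outside [0, 1]")
    return CONSISTENT if tm > 0.5 else INCONSISTENT


def mismatch_augment(
    entries: Sequence[DatasetEntry],
    seed: int,
    rescore: Callable[[DatasetEntry, DatasetEntry], DatasetEntry] | None = None,
) -> list[DatasetEntry]:
    """Double a dataset by pairing each member with another member's
    prediction.

    For every original entry a mismatched twin is added whose predicted
    structure comes from a uniformly chosen *other* member.  Structure-
    dependent features and the TM label must be recomputed against the
    donor's prediction: supply *rescore(entry, donor)* to do so (the
    corpus-level pipeline in :mod:`spanr.synthdata` provides one);
    without it the twin carries only identity/bookkeeping fields.
    """
    n = len(entries)
    if n < 2:
        raise ValueError("mismatch augmentation needs at least 2 entries")
    rng = np.random.default_rng(seed)
    out = list(entries)
    for idx, entry in enumerate(entries):
        j = int(rng.integers(n - 1))
        if j >= idx:
            j += 1
        donor = entries[j]
        if rescore is not None:
            twin = rescore(entry, donor)
            twin = dataclasses.replace(
                twin, mismatched=True, donor_id=donor.entry_id)
        else:
            twin = DatasetEntry(
                entry_id=f"{entry.entry_id}|mm",
                mismatched=True, donor_id=donor.entry_id)
        out.append(twin)
    return out


# ----------------------------------------------------------------- estimator

class SpanrClassifier(ClassifierMixin, BaseEstimator):
    """RBF-kernel SVM with balanced class weights and calibrated confidence.

    scikit-learn estimator: ``fit(X, y)`` on a numeric feature matrix with
    string labels ("consistent"/"inconsistent"), ``predict_proba`` giving
    the calibrated class probabilities, and ``predict`` thresholding the
    consistent-class probability at 0.5.  Standardization statistics are
    estimated on the training data only.
    """

    def __init__(self, C: float = 1.0, gamma: str | float = "scale",
                 kernel: str = "rbf", random_state: int = 0,
                 feature_names: list[str] | None = None):
        self.C = C
        self.gamma = gamma
        self.kernel = kernel
        self.random_state = random_state
        self.feature_names = feature_names

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("SPANR is a binary classifier; need both classes")
        svc = SVC(C=self.C, gamma=self.gamma, kernel=self.kernel,
                  class_weight="balanced", random_state=self.random_state)
        self.pipeline_ = Pipeline([
            ("scale", StandardScaler()),
            ("svm", CalibratedClassifierCV(svc, method="sigmoid",
                                           ensemble=False)),
        ])
        self.pipeline_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        if self.feature_names is not None:
            if len(self.feature_names) != self.n_features_in_:
                raise ValueError("feature_names length does not match X")
            self.feature_names_in_ = np.asarray(self.feature_names)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict_proba(np.asarray(X, dtype=float))

    def consistent_proba(self, X) -> np.ndarray:
        """Calibrated probability of the "consistent" class."""
        proba = self.predict_proba(X)
        idx = int(np.flatnonzero(
            self.pipeline_.named_steps["svm"].classes_ == CONSISTENT)[0])
        return proba[:, idx]

    def predict(self, X):
        p = self.consistent_proba(X)
        return np.where(p >= 0.5, CONSISTENT, INCONSISTENT)


# --------------------------------------------------------------- data frames

def make_feature_frame(entries: Iterable[DatasetEntry],
                       groups: Sequence[str]) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the feature matrix and labels for the chosen groups.

    Refuses PAE features on datasets containing mismatched entries: a
    mismatched pairing has no meaningful prediction-uncertainty matrix for
    the data it was paired with.  Rows with a missing feature or label are
    dropped.
    """
    entries = list(entries)
    cols: list[str] = []
    for g in groups:
        if g not in FEATURE_GROUPS:
            raise KeyError(f"unknown feature group {g!r}")
        cols.extend(FEATURE_GROUPS[g])
    if "PAE" in groups and any(e.mismatched for e in entries):
        raise ValueError("PAE features cannot be used with mismatched entries")
    records = []
    for e in entries:
        if e.tm is None:
            continue
        row = {c: getattr(e, c) for c in cols}
        if any(v is None or not np.isfinite(v) for v in row.values()):
            continue
        row["label"] = label_entry(e.tm)
        row["entry_id"] = e.entry_id
        records.append(row)
    if not records:
        raise ValueError("no complete labeled entries for the chosen groups")
    df = pd.DataFrame.from_records(records).set_index("entry_id")
    return df[cols], df["label"]


def evaluate(model: SpanrClassifier, X, y) -> EvalReport:
    """Identification rates of *model* on a labeled test set, in percent."""
    y = np.asarray(y)
    pred = model.predict(X)
    total = 100.0 * float(np.mean(pred == y))
    rates: dict[str, float | None] = {}
    for cls in (INCONSISTENT, CONSISTENT):
        mask = y == cls
        rates[cls] = 100.0 * float(np.mean(pred[mask] == cls)) if mask.any() else None
    neg, pos = rates[INCONSISTENT], rates[CONSISTENT]
    balanced = (neg + pos) / 2.0 if (neg is not None and pos is not None) else None
    return EvalReport(neg_id_rate=neg, pos_id_rate=pos,
                      total_accuracy=total, balanced_accuracy=balanced)


def train_spanr(
    entries: Sequence[DatasetEntry],
    feature_groups: Sequence[str] = ("CS-DS",),
    split_seed: int = 0,
    train_fraction: float = 0.8,
    svm_params: Mapping | None = None,
) -> tuple[SpanrClassifier, EvalReport]:
    """Train an SVM on an 80–20 split and evaluate on the held-out 20%."""
    X, y = make_feature_frame(entries, feature_groups)
    X_train, X_test, y_train, y_test = train_test_split(
        X.values, y.values, train_size=train_fraction,
        random_state=split_seed, stratify=y.values)
    model = SpanrClassifier(feature_names=list(X.columns),
                            random_state=split_seed,
                            **dict(svm_params or {}))
    model.fit(X_train, y_train)
    return model, evaluate(model, X_test, y_test)


def predict_confidence(model: SpanrClassifier,
                       features: Mapping[str, float] | Sequence[float]) -> float:
    """Probability that one structure is consistent with its NMR data.

    *features* may be a mapping keyed by the model's feature names or a
    plain sequence in training order.
    """
    check_is_fitted(model, "pipeline_")
    if isinstance(features, Mapping):
        names = getattr(model, "feature_names_in_", None)
        if names is None:
            raise ValueError("model has no recorded feature names")
        missing = [n for n in names if n not in features]
        if missing:
            raise KeyError(f"missing feature(s): {missing}")
        vec = [features[n] for n in names]
    else:
        vec = list(features)
    return float(model.consistent_proba(np.asarray(vec, dtype=float)[None, :])[0])


# -------------------------------------------------------------- correlations

def spearman_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank correlations (average ranks for ties) between all
    columns of *table*, with p-values.

    Returns (rho, p) DataFrames; a constant column yields NaN against
    everything (undefined rank correlation), with a unit diagonal
    otherwise.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    cols = list(table.columns)
    k = len(cols)
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            xi = table.iloc[:, i].to_numpy(dtype=float)
            xj = table.iloc[:, j].to_numpy(dtype=float)
            ok = np.isfinite(xi) & np.isfinite(xj)
            if ok.sum() < 3 or np.ptp(xi[ok]) == 0 or np.ptp(xj[ok]) == 0:
                continue
            r, p = stats.spearmanr(xi[ok], xj[ok])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    return (pd.DataFrame(rho, index=cols, columns=cols),
            pd.DataFrame(pval, index=cols, columns=cols))


def grid_search_thresholds(
    corpus: Sequence,
    eps_cs_grid: Sequence[float],
    eps_d_grid: Sequence[float],
    base_params=None,
) -> dict:
    """Select (eps_cs, eps_d) maximizing rank correlation with TM-score.

    *corpus* is a sequence of ``(contacts, proposed_structure, tm)``
    triples.  For each candidate ``eps_cs`` the Spearman correlation of CS
    with TM is computed over the corpus (and for ``eps_d``, |rho| of DS
    with TM); the maximizing threshold is returned, ties broken toward the
    smaller threshold.  The full grid tables are included in the result.
    """
    import dataclasses as _dc

    from .scores import ScoringParams, contact_score, distance_score

    base = base_params or ScoringParams()
    tms = np.array([tm for (_, _, tm) in corpus], dtype=float)
    if np.ptp(tms) == 0:
        raise ValueError("degenerate corpus: constant TM-score")

    def corr(values: list[float | None]) -> float:
        arr = np.array([np.nan if v is None else v for v in values])
        ok = np.isfinite(arr)
        if ok.sum() < 3 or np.ptp(arr[ok]) == 0:
            return np.nan
        return float(stats.spearmanr(arr[ok], tms[ok]).statistic)

    cs_rows, ds_rows = [], []
    best_cs, best_cs_rho = None, -np.inf
    for eps in eps_cs_grid:
        p = _dc.replace(base, eps_cs=float(eps))
        rho = corr([contact_score(c, s, p).cs for (c, s, _) in corpus])
        cs_rows.append({"eps_cs": float(eps), "spearman_cs_tm": rho})
        if np.isfinite(rho) and rho > best_cs_rho:
            best_cs, best_cs_rho = float(eps), rho
    best_ds, best_ds_rho = None, -np.inf
    for eps in eps_d_grid:
        p = _dc.replace(base, eps_d=float(eps))
        rho = corr([distance_score(c, s, p).ds for (c, s, _) in corpus])
        ds_rows.append({"eps_d": float(eps), "spearman_ds_tm": rho})
        if np.isfinite(rho) and abs(rho) > best_ds_rho:
            best_ds, best_ds_rho = float(eps), abs(rho)
    return {
        "eps_cs": best_cs,
        "eps_d": best_ds,
        "cs_table": pd.DataFrame(cs_rows),
        "ds_table": pd.DataFrame(ds_rows),
    }


# ------------------------------------------------------------- serialization

def save_model(model: SpanrClassifier, path: str | Path) -> None:
    """Serialize a fitted model to a single versioned archive."""
    check_is_fitted(model, "pipeline_")
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model},
                path)


def load_model(path: str | Path) -> SpanrClassifier:
    payload = joblib.load(path)
    version = payload.get("format_version") if isinstance(payload, dict) else None
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model archive version {version!r}; "
            f"this build reads version {MODEL_FORMAT_VERSION}"
        )
    return payload["model"]
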