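"""The blinded index test: QDA pattern transfer with LOSO validation.

A quadratic discriminant model (one full-covariance Gaussian per class,
maximum-likelihood mean and covariance, empirical priors) is trained to
separate PD from control speakers in a chosen feature subset.  The best
subset is found by sequential (or exhaustive) search maximizing
leave-one-subject-out accuracy, and the resulting speech pattern is
transferred to a held-out cohort whose subjects are scored against a
motor-status dichotomization (UPDRS III* > 3 = motor positive).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

CONTROL, PD = "control", "PD"


@dataclass
class SubjectRecord:
    subject_id: str
    group: str                      # "PD", "control" or "heldout"
    features: dict                  # (feature_name, task) -> float (may be NaN)
    updrs3_star: int | None = None


def _design_matrix(records, feature_keys):
    X = np.full((len(records), len(feature_keys)), np.nan)
    for i, rec in enumerate(records):
        for j, key in enumerate(feature_keys):
            v = rec.features.get(key, math.nan)
            X[i, j] = v if v is not None else math.nan
    return X


class GaussianPatternClassifier(BaseEstimator, ClassifierMixin):
    """Two-class QDA with pooled-mean imputation of missing features.

    Each class is modelled as a multivariate normal fitted by maximum
    likelihood (the fixed point of EM for a single Gaussian); priors are
    the empirical class proportions.  Prediction follows the Bayes
    discriminant rule; exact ties go to the control class.

    Fitted attributes: ``means_``, ``covariances_``, ``priors_``,
    ``classes_``, ``impute_values_``.
    """

    def __init__(self, reg_covar: float = 1e-8):
        self.reg_covar = reg_covar

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        # control first so argmax tie-breaking favours control
        classes = sorted(np.unique(y), key=lambda c: (c != CONTROL, c))
        self.classes_ = np.array(classes)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.impute_values_ = np.nanmean(X, axis=0)  # training-pooled means
        if np.isnan(self.impute_values_).any():
            self.impute_values_ = np.where(np.isnan(self.impute_values_), 0.0,
                                           self.impute_values_)
        Xi = self._impute(X)
        p = Xi.shape[1]
        self.means_, self.covariances_, self.priors_ = [], [], []
        for c in self.classes_:
            Z = Xi[y == c]
            if len(Z) < 2:
                raise ValueError(f"class {c!r} needs >= 2 records")
            mu = Z.mean(axis=0)
            cov = np.cov(Z, rowvar=False, bias=True).reshape(p, p)
            cov = cov + self.reg_covar * np.eye(p)
            # escalate the ridge until the covariance is invertible
            for _ in range(8):
                try:
                    np.linalg.cholesky(cov)
                    break
                except np.linalg.LinAlgError:
                    cov = cov + max(np.trace(cov) / p, 1e-12) * 1e-3 * np.eye(p)
            else:
                raise ValueError("singular covariance after regularization")
            self.means_.append(mu)
            self.covariances_.append(cov)
            self.priors_.append(len(Z) / len(Xi))
        self.means_ = np.array(self.means_)
        self.covariances_ = np.array(self.covariances_)
        self.priors_ = np.array(self.priors_)
        return self

    def _impute(self, X):
        X = np.array(X, dtype=float)
        nan = np.isnan(X)
        if nan.any():
            X[nan] = np.take(self.impute_values_, np.where(nan)[1])
        return X

    def _log_joint(self, X):
        X = self._impute(np.atleast_2d(np.asarray(X, dtype=float)))
        out = np.zeros((len(X), len(self.classes_)))
        p = X.shape[1]
        for k in range(len(self.classes_)):
            diff = X - self.means_[k]
            cov = self.covariances_[k]
            sign, logdet = np.linalg.slogdet(cov)
            sol = np.linalg.solve(cov, diff.T).T
            maha = (diff * sol).sum(axis=1)
            out[:, k] = (np.log(self.priors_[k]) - 0.5 * logdet
                         - 0.5 * maha - 0.5 * p * np.log(2 * np.pi))
        return out

    def predict_proba(self, X):
        lj = self._log_joint(X)
        lj -= lj.max(axis=1, keepdims=True)
        w = np.exp(lj)
        return w / w.sum(axis=1, keepdims=True)

    def predict(self, X):
        lj = self._log_joint(X)
        # argmax takes the first (control) class on exact ties
        return self.classes_[np.argmax(lj, axis=1)]


def fit_qda(records, feature_keys, reg_covar: float = 1e-8):
    """Fit the per-class Gaussian model on PD/control records."""
    X = _design_matrix(records, feature_keys)
    y = np.array([r.group for r in records])
    return GaussianPatternClassifier(reg_covar=reg_covar).fit(X, y)


def classify_subject(model: GaussianPatternClassifier, record: SubjectRecord,
                     feature_keys):
    """Class label and posterior for one subject."""
    x = _design_matrix([record], feature_keys)
    label = model.predict(x)[0]
    post = model.predict_proba(x)[0]
    return label, dict(zip(model.classes_, post))


def _metrics(y_true, y_pred):
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    acc = float((y_true == y_pred).mean())
    pos = y_true == PD
    neg = ~pos
    sens = float((y_pred[pos] == PD).mean()) if pos.any() else math.nan
    spec = float((y_pred[neg] != PD).mean()) if neg.any() else math.nan
    return acc, sens, spec


def loso_accuracy(records, feature_keys):
    """Leave-one-subject-out accuracy, sensitivity, specificity.

    Each fold refits the model (including imputation values) without
    the held-out subject, so no information leaks into its prediction.
    """
    y_true, y_pred = [], []
    for i, rec in enumerate(records):
        train = records[:i] + records[i + 1:]
        model = fit_qda(train, feature_keys)
        label, _ = classify_subject(model, rec, feature_keys)
        y_true.append(rec.group)
        y_pred.append(label)
    return _metrics(y_true, y_pred)


def search_best_subset(records, candidate_keys, strategy: str = "forward"):
    """Find the feature subset maximizing LOSO accuracy.

    ``forward``: greedy sequential selection, stopping when no addition
    improves accuracy.  ``exhaustive``: all non-empty subsets (allowed
    for up to 12 candidates).  Ties prefer the smaller subset, then
    lexicographic feature order.  Returns (subset, accuracy,
    sensitivity, specificity).
    """
    candidate_keys = list(candidate_keys)
    if not candidate_keys:
        raise ValueError("need at least one candidate feature")

    def evaluate(subset):
        return loso_accuracy(records, list(subset))

    if strategy == "exhaustive":
        if len(candidate_keys) > 12:
            raise ValueError("exhaustive search limited to 12 candidates")
        best = None
        for r in range(1, len(candidate_keys) + 1):
            for combo in itertools.combinations(sorted(candidate_keys), r):
                acc, sens, spec = evaluate(combo)
                key = (-acc, len(combo), combo)
                if best is None or key < best[0]:
                    best = (key, combo, acc, sens, spec)
        _, subset, acc, sens, spec = best
        return list(subset), acc, sens, spec

    if strategy != "forward":
        raise ValueError(f"unknown strategy {strategy!r}")
    selected = []
    best_acc, best_sens, best_spec = -1.0, math.nan, math.nan
    remaining = sorted(candidate_keys)
    while remaining:
        trial = []
        for key in remaining:
            acc, sens, spec = evaluate(selected + [key])
            trial.append((-acc, key, acc, sens, spec))
        trial.sort()
        _, key, acc, sens, spec = trial[0]
        if acc > best_acc:
            selected.append(key)
            remaining.remove(key)
            best_acc, best_sens, best_spec = acc, sens, spec
        else:
            break
    if not selected:  # no single feature beat -1: take the best single
        raise RuntimeError("forward selection failed to select any feature")
    return selected, best_acc, best_sens, best_spec


@dataclass
class IndexTestResult:
    subset: list
    train_accuracy: float
    train_sensitivity: float
    train_specificity: float
    accuracy: float
    sensitivity: float
    specificity: float
    calls: list = field(default_factory=list)  # (subject_id, motor, speech)


def index_test(train_records, heldout_records, candidate_keys=None,
               strategy: str = "forward", updrs_cutoff: int = 3,
               subset=None) -> IndexTestResult:
    """Learn the PD speech pattern and transfer it to a held-out cohort.

    Held-out subjects must carry a UPDRS III* score; motor positive
    means UPDRS III* strictly greater than ``updrs_cutoff``.  Subjects
    assigned to the PD distribution are speech positives; accuracy,
    sensitivity and specificity come from the motor/speech 2x2 table.
    """
    if not heldout_records:
        raise ValueError("held-out cohort is empty")
    missing = [r.subject_id for r in heldout_records if r.updrs3_star is None]
    if missing:
        raise ValueError(f"held-out subjects missing UPDRS III*: {missing}")
    if subset is None:
        if candidate_keys is None:
            raise ValueError("need candidate_keys or an explicit subset")
        subset, tr_acc, tr_sens, tr_spec = search_best_subset(
            train_records, candidate_keys, strategy)
    else:
        tr_acc, tr_sens, tr_spec = loso_accuracy(train_records, subset)
    model = fit_qda(train_records, subset)
    y_true, y_pred, calls = [], [], []
    for rec in heldout_records:
        label, _ = classify_subject(model, rec, subset)
        motor = PD if rec.updrs3_star > updrs_cutoff else CONTROL
        y_true.append(motor)
        y_pred.append(label)
        calls.append((rec.subject_id, motor, label))
    acc, sens, spec = _metrics(y_true, y_pred)
    return IndexTestResult(list(subset), tr_acc, tr_sens, tr_spec,
                           acc, sens, spec, calls)


def records_from_frames(features_df, meta_df) -> list:
    """Build SubjectRecords from a features table and a metadata table.

    ``features_df`` has columns subject_id, task plus feature columns;
    ``meta_df`` has subject_id, group and optionally updrs3_star.
    Feature keys become ``"<name>:<task>"``.
    """
    import pandas as pd
    meta = meta_df.drop_duplicates("subject_id").set_index("subject_id")
    records = []
    for sid, sub in features_df.groupby("subject_id", sort=True):
        feats = {}
        for _, row in sub.iterrows():
            task = row["task"]
            for col in sub.columns:
                if col in ("subject_id", "task"):
                    continue
                feats[f"{col}:{task}"] = float(row[col]) if pd.notna(row[col]) else math.nan
        m = meta.loc[sid]
        updrs = m.get("updrs3_star")
        records.append(SubjectRecord(
            subject_id=str(sid), group=str(m["group"]), features=feats,
            updrs3_star=int(updrs) if pd.notna(updrs) else None))
    return records
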