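"""Polymarker classification: preprocessing, weighted linear SVM, and
permutation-tested leave-one-out evaluation.

The classifier contract mirrors a premanifest-vs-control imaging study:
feature columns are standardized, age and imaging site are regressed
out, and each column is mapped through a rank-based inverse-normal
(Blom) transform before a linear soft-margin SVM with inverse-frequency
class weights is trained.  Evaluation is leave-one-out with the F1 score
(harmonic mean of sensitivity and precision, patient class positive),
and significance comes from a label-shuffling permutation null with the
add-one empirical p-value (1 + #{null >= observed}) / (1 + n_perm).

Every preprocessing parameter is refit on the training subjects of each
fold and applied to the held-out subject through the stored reference
distribution, never touching held-out labels.  Because the preprocessing
pipeline is fully unsupervised, the per-fold transforms are identical
across label permutations and are computed once per dataset.

A statsmodels-flavoured model/results pair (:class:`PolymarkerSVM` /
:class:`PolymarkerSVMResults`) wraps these operations for interactive
use; the module-level functions are the primitive API.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.svm import SVC

try:  # low-level libsvm binding: identical optimizer, ~50x less call overhead
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
except Exception:  # pragma: no cover - fall back to the public estimator
    _libsvm = None

__all__ = [
    "FeatureMatrix",
    "PreprocessModel",
    "SVMModel",
    "ClassificationReport",
    "rank_inverse_normal",
    "fit_preprocess",
    "apply_preprocess",
    "train_weighted_svm",
    "decision_values",
    "loo_f1",
    "permutation_test",
    "hyperplane_scores",
    "external_validate",
    "PolymarkerSVM",
    "PolymarkerSVMResults",
]


FEATURE_SETS = ("rest", "ct", "scv", "polymarker")


@dataclass
class FeatureMatrix:
    """Subjects x features table for one feature set.

    ``covariates`` (optional) holds per-subject nuisance variables: an
    ``age`` column (numeric) and/or a ``site`` column (categorical).
    ``state`` flags whether preprocessing has been applied.
    """

    values: pd.DataFrame
    feature_set: str = "polymarker"
    state: str = "raw"  # "raw" | "preprocessed"
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
        if self.state == "preprocessed" and not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("non-finite values in preprocessed features")
        if self.covariates is not None:
            missing = self.values.index.difference(self.covariates.index)
            if len(missing):
                raise ValueError(f"covariates missing for subjects: {list(missing)[:5]}")

    @property
    def subjects(self) -> list:
        return list(self.values.index)

    @staticmethod
    def concat(blocks: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        """Column-concatenate feature blocks into a polymarker matrix."""
        idx = blocks[0].values.index
        for b in blocks[1:]:
            if not b.values.index.equals(idx):
                raise ValueError("feature blocks must share the same subjects in order")
        return FeatureMatrix(
            values=pd.concat([b.values for b in blocks], axis=1),
            feature_set="polymarker",
            state=blocks[0].state,
            covariates=blocks[0].covariates,
        )


# ---------------------------------------------------------------------------
# preprocessing


def rank_inverse_normal(column: Sequence[float]) -> np.ndarray:
    """Blom rank-based inverse-normal scores, Phi^-1((r - 3/8)/(n + 1/4)).

    Ties receive average ranks; the transform is strictly monotone in the
    input (up to ties).  Requires at least 3 distinct values.
    """
    x = np.asarray(column, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("rank-inverse-normal transform needs >= 3 distinct values")
    r = rankdata(x, method="average")
    return norm.ppf((r - 3.0 / 8.0) / (len(x) + 0.25))


def _covariate_design(cov: pd.DataFrame | None, site_levels: list | None = None
                      ) -> tuple[np.ndarray, list]:
    """Design matrix [1, centred age, site indicators (drop first)]."""
    n = len(cov) if cov is not None else 0
    if cov is None or cov.shape[1] == 0:
        return np.ones((n, 1)), []
    cols = [np.ones(len(cov))]
    levels = site_levels
    if "age" in cov.columns:
        cols.append(cov["age"].to_numpy(dtype=float))
    if "site" in cov.columns:
        observed = sorted(cov["site"].astype(str).unique())
        if levels is None:
            levels = observed
        else:
            unseen = set(observed) - set(levels)
            if unseen:
                raise ValueError(f"unseen imaging site(s) at apply time: {sorted(unseen)}")
        for lv in levels[1:]:
            cols.append((cov["site"].astype(str) == lv).to_numpy(dtype=float))
    return np.column_stack(cols), (levels or [])


@dataclass
class PreprocessModel:
    """Frozen preprocessing parameters fitted on one training population.

    Pipeline order: per-feature standardization -> residualization on
    (age, site indicators) -> rank-based inverse-normal transform.  For
    held-out subjects the inverse-normal step interpolates into the
    training population's reference distribution (sorted residual values
    against their Blom normal scores), clamping outside the observed
    range; held-out labels are never used.
    """

    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    beta: np.ndarray  # k x p residualization coefficients
    site_levels: list
    has_age: bool
    ref_values: list[np.ndarray]  # per feature: sorted unique residual values
    ref_scores: list[np.ndarray]  # per feature: matching normal scores
    fit_subjects: list = field(default_factory=list)

    def residualize(self, fm: FeatureMatrix) -> np.ndarray:
        """Standardize + residualize only (no inverse-normal step)."""
        X = fm.values[self.feature_names].to_numpy(dtype=float)
        Xs = (X - self.means) / self.sds
        cov = fm.covariates.loc[fm.values.index] if fm.covariates is not None else None
        if cov is not None and (self.has_age or self.site_levels):
            D, _ = _covariate_design(cov, self.site_levels or None)
        else:
            D = np.ones((len(Xs), 1))
        return Xs - D @ self.beta


def fit_preprocess(fm: FeatureMatrix, covariates: pd.DataFrame | None = None
                   ) -> PreprocessModel:
    """Fit the standardize -> residualize -> inverse-normal pipeline."""
    cov = covariates if covariates is not None else fm.covariates
    if cov is not None:
        cov = cov.loc[fm.values.index]
        if cov.isna().any().any():
            raise ValueError("covariates contain missing values")
    X = fm.values.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    if np.any(sds == 0):
        dead = [c for c, s in zip(fm.values.columns, sds) if s == 0]
        raise ValueError(f"constant feature columns: {dead}")
    Xs = (X - means) / sds
    if cov is None:
        D, site_levels = np.ones((len(Xs), 1)), []
    else:
        D, site_levels = _covariate_design(cov)
    beta, *_ = np.linalg.lstsq(D, Xs, rcond=None)
    R = Xs - D @ beta
    ref_values, ref_scores = [], []
    for j in range(R.shape[1]):
        scores = rank_inverse_normal(R[:, j])
        order = np.argsort(R[:, j], kind="mergesort")
        v, s = R[order, j], scores[order]
        uniq, first = np.unique(v, return_index=True)
        ref_values.append(uniq)
        ref_scores.append(np.array([s[v == u][0] for u in uniq]) if len(uniq) < len(v)
                          else s)
    return PreprocessModel(
        feature_names=list(fm.values.columns), means=means, sds=sds, beta=beta,
        site_levels=site_levels,
        has_age=bool(cov is not None and "age" in cov.columns),
        ref_values=ref_values, ref_scores=ref_scores,
        fit_subjects=list(fm.values.index),
    )


def apply_preprocess(model: PreprocessModel, fm: FeatureMatrix) -> FeatureMatrix:
    """Apply a fitted preprocessing model (training-population parameters)."""
    R = model.residualize(fm)
    out = np.empty_like(R)
    for j in range(R.shape[1]):
        out[:, j] = np.interp(R[:, j], model.ref_values[j], model.ref_scores[j])
    values = pd.DataFrame(out, index=fm.values.index, columns=model.feature_names)
    return FeatureMatrix(values=values, feature_set=fm.feature_set,
                         state="preprocessed", covariates=fm.covariates)


# ---------------------------------------------------------------------------
# weighted linear SVM


@dataclass
class SVMModel:
    """Linear soft-margin SVM: decision value = w . x + b."""

    w: np.ndarray
    b: float
    class_weights: dict
    C: float
    feature_names: list[str]
    positive_label: object
    negative_label: object
    meta: dict = field(default_factory=dict)


def _inverse_frequency_weights(y01: np.ndarray) -> dict[int, float]:
    """Per-class costs proportional to inverse class frequency, mean 1."""
    counts = {k: int((y01 == k).sum()) for k in (0, 1)}
    inv = {k: 1.0 / c for k, c in counts.items()}
    mean_inv = (inv[0] + inv[1]) / 2.0
    return {k: v / mean_inv for k, v in inv.items()}


def _fit_linear_hyperplane(X: np.ndarray, y01: np.ndarray, C: float,
                           cw: dict[int, float]) -> tuple[np.ndarray, float]:
    """(w, b) of the weighted linear SVM, in the dec>0 -> class 1 convention.

    Uses the low-level libsvm binding when available (the exact same
    solver SVC wraps, minus per-call validation overhead — the LOO
    permutation loops make tens of thousands of tiny fits); equivalence
    with SVC is asserted in the test suite.  The raw libsvm hyperplane
    for 0/1-encoded binary labels is oriented opposite to sklearn's
    class-1-positive convention, hence the negation.
    """
    if _libsvm is None:
        clf = SVC(kernel="linear", C=C, class_weight=cw)
        clf.fit(X, y01)
        return clf.coef_.ravel(), float(clf.intercept_[0])
    out = _libsvm.fit(
        np.ascontiguousarray(X, dtype=np.float64), y01.astype(np.float64),
        svm_type=0, kernel="linear", C=C,
        class_weight=np.array([cw[0], cw[1]], dtype=np.float64))
    support_vectors, dual_coef, intercept = out[1], out[3], out[4]
    return -(dual_coef[0] @ support_vectors), -float(intercept[0])


def _encode(labels: Sequence, positive_label) -> tuple[np.ndarray, object]:
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    if positive_label is None:
        raise ValueError("positive_label (the patient class) must be given")
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} not among {list(classes)}")
    negative = classes[classes != positive_label][0]
    return (y == positive_label).astype(int), negative


def train_weighted_svm(fm: FeatureMatrix, labels: Sequence, C: float = 1.0,
                       positive_label=None) -> SVMModel:
    """Train a linear SVM with inverse-frequency class weights (mean 1)."""
    if fm.state != "preprocessed":
        warnings.warn("training on features not flagged as preprocessed", stacklevel=2)
    X = fm.values.to_numpy(dtype=float)
    y01, negative = _encode(labels, positive_label)
    if y01.min() == y01.max():
        raise ValueError("single-class input")
    cw = _inverse_frequency_weights(y01)
    clf = SVC(kernel="linear", C=C, class_weight=cw)
    clf.fit(X, y01)
    return SVMModel(
        w=clf.coef_.ravel().copy(), b=float(clf.intercept_[0]),
        class_weights=cw, C=C, feature_names=list(fm.values.columns),
        positive_label=positive_label, negative_label=negative,
        meta={"feature_set": fm.feature_set, "n_fit": len(y01)},
    )


def decision_values(model: SVMModel, fm: FeatureMatrix) -> np.ndarray:
    X = fm.values[model.feature_names].to_numpy(dtype=float)
    return X @ model.w + model.b


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class ClassificationReport:
    """Per-subject predictions plus aggregate and permutation statistics."""

    subjects: list
    y_true: np.ndarray
    y_pred: np.ndarray
    decision: np.ndarray
    positive_label: object
    confusion: dict  # tp, fp, tn, fn
    sensitivity: float
    precision: float
    f1: float
    null_f1: np.ndarray | None = None
    n_perm: int = 0
    p_value: float | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "subjects": list(map(str, self.subjects)),
            "y_true": [int(v) for v in self.y_true],
            "y_pred": [int(v) for v in self.y_pred],
            "decision": [float(v) for v in self.decision],
            "positive_label": str(self.positive_label),
            "confusion": {k: int(v) for k, v in self.confusion.items()},
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "f1": self.f1,
            "null_f1": None if self.null_f1 is None else [float(v) for v in self.null_f1],
            "n_perm": self.n_perm,
            "p_value": self.p_value,
            "seed": self.seed,
        }


def _f1_parts(y_true01: np.ndarray, y_pred01: np.ndarray) -> tuple[dict, float, float, float]:
    tp = int(np.sum((y_true01 == 1) & (y_pred01 == 1)))
    fp = int(np.sum((y_true01 == 0) & (y_pred01 == 1)))
    tn = int(np.sum((y_true01 == 0) & (y_pred01 == 0)))
    fn = int(np.sum((y_true01 == 1) & (y_pred01 == 0)))
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    prec = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = 2 * sens * prec / (sens + prec) if (sens + prec) else 0.0
    return {"tp": tp, "fp": fp, "tn": tn, "fn": fn}, sens, prec, f1


def _fold_cache(fm: FeatureMatrix, covariates: pd.DataFrame | None,
                paper_mode: bool) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-LOO-fold (train matrix, held-out row) after fold-safe preprocessing.

    The pipeline is unsupervised, so this depends only on features and
    covariates, never labels, and can be shared across permutations.  In
    ``paper_mode`` preprocessing is fitted once on the full sample (the
    leaky variant) and folds just slice the preprocessed matrix.
    """
    n = len(fm.values)
    cov = covariates if covariates is not None else fm.covariates
    if paper_mode:
        model = fit_preprocess(fm, cov)
        Z = apply_preprocess(model, fm).values.to_numpy(dtype=float)
        mask = np.ones(n, dtype=bool)
        folds = []
        for i in range(n):
            mask[i] = False
            folds.append((Z[mask], Z[i:i + 1]))
            mask[i] = True
        return folds
    folds = []
    idx = fm.values.index
    for i in range(n):
        tr_idx = idx.delete(i)
        tr = FeatureMatrix(values=fm.values.loc[tr_idx], feature_set=fm.feature_set,
                           state=fm.state,
                           covariates=cov.loc[tr_idx] if cov is not None else None)
        te = FeatureMatrix(values=fm.values.iloc[[i]], feature_set=fm.feature_set,
                           state=fm.state,
                           covariates=cov.iloc[[i]] if cov is not None else None)
        model = fit_preprocess(tr, cov.loc[tr_idx] if cov is not None else None)
        folds.append((apply_preprocess(model, tr).values.to_numpy(dtype=float),
                      apply_preprocess(model, te).values.to_numpy(dtype=float)))
    return folds


def _loo_eval(folds: list, y01: np.ndarray, C: float,
              with_distance: bool = False) -> tuple[np.ndarray, np.ndarray | None]:
    """Predict each held-out subject from an SVM trained on the rest.

    Optionally also returns the held-out hyperplane distance
    (w.x + b)/||w|| per subject — the fold-safe classification-strength
    score (a held-out point never sits artificially on the margin, which
    training points do when features outnumber subjects).
    """
    n = len(y01)
    y_pred = np.empty(n, dtype=int)
    dist = np.empty(n) if with_distance else None
    mask = np.ones(n, dtype=bool)
    for i, (Xtr, Xte) in enumerate(folds):
        mask[i] = False
        ytr = y01[mask]
        mask[i] = True
        if ytr.min() == ytr.max():
            raise ValueError(f"fold {i}: training set contains a single class")
        w, b = _fit_linear_hyperplane(Xtr, ytr, C, _inverse_frequency_weights(ytr))
        dec = float(Xte[0] @ w + b)
        y_pred[i] = int(dec > 0)
        if with_distance:
            dist[i] = dec / float(np.linalg.norm(w))
    return y_pred, dist


def loo_f1(fm: FeatureMatrix, labels: Sequence, C: float = 1.0,
           positive_label=None, covariates: pd.DataFrame | None = None,
           paper_mode: bool = False) -> ClassificationReport:
    """Leave-one-out evaluation aggregated into one confusion matrix.

    Each fold refits preprocessing and the SVM on the n-1 training
    subjects and predicts the held-out subject; predictions are pooled
    into a single confusion matrix and F1 (patient class positive,
    defined as 0 when there are no positive predictions).  The report's
    ``decision`` holds each subject's held-out hyperplane distance, the
    fold-safe classification-strength score.
    """
    y01, _ = _encode(labels, positive_label)
    n = len(y01)
    if n < 6 or y01.sum() < 3 or (n - y01.sum()) < 3:
        raise ValueError("need n >= 6 with at least 3 subjects per class")
    folds = _fold_cache(fm, covariates, paper_mode)
    y_pred, dist = _loo_eval(folds, y01, C, with_distance=True)
    confusion, sens, prec, f1 = _f1_parts(y01, y_pred)
    return ClassificationReport(
        subjects=fm.subjects, y_true=y01, y_pred=y_pred, decision=dist,
        positive_label=positive_label, confusion=confusion,
        sensitivity=sens, precision=prec, f1=f1,
    )


def permutation_test(fm: FeatureMatrix, labels: Sequence, n_perm: int = 1000,
                     seed: int | None = None, C: float = 1.0, positive_label=None,
                     covariates: pd.DataFrame | None = None,
                     paper_mode: bool = False) -> ClassificationReport:
    """Label-shuffling permutation test of the leave-one-out F1 score.

    Labels are permuted ``n_perm`` times (class counts preserved by
    construction) and the full LOO F1 recomputed for each shuffle; the
    empirical p is the add-one rank (1 + #{null >= observed})/(1 + n_perm),
    so an observed F1 above every null gives p = 1/(n_perm + 1).
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20 gives a meaningless null; use more permutations")
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} yields a coarse empirical p", stacklevel=2)
    y01, _ = _encode(labels, positive_label)
    report = loo_f1(fm, labels, C=C, positive_label=positive_label,
                    covariates=covariates, paper_mode=paper_mode)
    folds = _fold_cache(fm, covariates, paper_mode)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        yp = rng.permutation(y01)
        while yp.min() == yp.max():  # cannot happen for 2-class data, kept for safety
            yp = rng.permutation(y01)
        pred, _ = _loo_eval(folds, yp, C)
        null[k] = _f1_parts(yp, pred)[3]
    p = (1 + int(np.sum(null >= report.f1))) / (1 + n_perm)
    report.null_f1 = null
    report.n_perm = n_perm
    report.p_value = p
    report.seed = seed
    return report


def hyperplane_scores(model: SVMModel, fm: FeatureMatrix,
                      patient_mask: Sequence[bool] | None = None) -> pd.DataFrame:
    """Signed hyperplane distances, patient-side ranks and median-split calls.

    Distance = (w.x + b)/||w||, positive on the patient side of the
    boundary.  Patients (``patient_mask``; all subjects if omitted) are
    ranked by distance toward the patient side (rank 1 = most
    patient-like) and median-split into predicted converters
    (distance >= patient median) and nonconverters.
    """
    nw = float(np.linalg.norm(model.w))
    if nw == 0:
        raise ValueError("degenerate SVM: zero weight vector")
    dist = decision_values(model, fm) / nw
    out = pd.DataFrame({"distance": dist}, index=fm.values.index)
    if patient_mask is None:
        patient_mask = np.ones(len(dist), dtype=bool)
    patient_mask = np.asarray(patient_mask, dtype=bool)
    out["is_patient"] = patient_mask
    pd_dist = out.loc[patient_mask, "distance"]
    ranks = pd_dist.rank(ascending=False, method="average")
    out["patient_rank"] = np.nan
    out.loc[patient_mask, "patient_rank"] = ranks
    med = float(pd_dist.median()) if patient_mask.any() else np.nan
    out["median_split"] = pd.NA
    out.loc[patient_mask, "median_split"] = np.where(
        out.loc[patient_mask, "distance"] >= med, "predicted_converter",
        "predicted_nonconverter")
    return out


def external_validate(train_fm: FeatureMatrix, train_labels: Sequence,
                      test_fm: FeatureMatrix, test_labels: Sequence,
                      n_perm: int = 1000, seed: int | None = None, C: float = 1.0,
                      positive_label=None) -> ClassificationReport:
    """Train on one cohort, test once on another, permute the test labels.

    Preprocessing and the SVM are fitted on the training cohort only and
    applied once to the test cohort.  The null distribution shuffles the
    TEST cohort's labels and re-scores the fixed predictions (the model
    is never retrained), and the empirical p uses the add-one formula.
    """
    missing = [c for c in train_fm.values.columns if c not in test_fm.values.columns]
    if missing:
        raise ValueError(f"test cohort missing features: {missing[:10]}")
    if n_perm < 20:
        raise ValueError("n_perm < 20 gives a meaningless null")
    y_tr, _ = _encode(train_labels, positive_label)
    y_te, _ = _encode(test_labels, positive_label)
    pm = fit_preprocess(train_fm, train_fm.covariates)
    model = train_weighted_svm(apply_preprocess(pm, train_fm), train_labels,
                               C=C, positive_label=positive_label)
    test_p = apply_preprocess(pm, FeatureMatrix(
        values=test_fm.values[train_fm.values.columns], feature_set=test_fm.feature_set,
        state=test_fm.state, covariates=test_fm.covariates))
    dec = decision_values(model, test_p)
    y_pred = (dec > 0).astype(int)
    confusion, sens, prec, f1 = _f1_parts(y_te, y_pred)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = _f1_parts(rng.permutation(y_te), y_pred)[3]
    p = (1 + int(np.sum(null >= f1))) / (1 + n_perm)
    return ClassificationReport(
        subjects=test_fm.subjects, y_true=y_te, y_pred=y_pred, decision=dec,
        positive_label=positive_label, confusion=confusion,
        sensitivity=sens, precision=prec, f1=f1,
        null_f1=null, n_perm=n_perm, p_value=p, seed=seed,
    )


# ---------------------------------------------------------------------------
# model/results surface


class PolymarkerSVM:
    """Imbalance-weighted linear SVM over an imaging feature set.

    A thin statsmodels-style model object: construct from a feature
    matrix (raw features plus age/site covariates), then :meth:`fit`
    preprocesses the full sample, trains the weighted SVM and returns a
    :class:`PolymarkerSVMResults` carrying the hyperplane, per-subject
    decision values and the evaluation methods (LOO, permutation test,
    median split).

    Parameters
    ----------
    features : FeatureMatrix or DataFrame
        Subjects x features (raw scale).
    labels : sequence
        Two-class labels aligned with the feature rows.
    positive_label : hashable
        The patient class (the F1 positive class).
    covariates : DataFrame, optional
        Per-subject ``age`` / ``site`` columns to regress out.
    C : float
        Soft-margin constant (no inner tuning loop).
    paper_mode : bool
        Fit preprocessing once on the full sample inside cross-validation
        (the leaky variant) instead of per fold.
    """

    def __init__(self, features, labels, positive_label, covariates=None,
                 C: float = 1.0, paper_mode: bool = False):
        if isinstance(features, pd.DataFrame):
            features = FeatureMatrix(values=features, covariates=covariates)
        self.features = features
        self.labels = np.asarray(labels)
        self.positive_label = positive_label
        self.covariates = covariates if covariates is not None else features.covariates
        self.C = C
        self.paper_mode = paper_mode
        _encode(labels, positive_label)  # validate early

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str,
                       feature_cols: Sequence[str], positive_label,
                       covariate_cols: Sequence[str] = (), **kwargs) -> "PolymarkerSVM":
        cov = df[list(covariate_cols)] if covariate_cols else None
        return cls(df[list(feature_cols)], df[label_col].to_numpy(),
                   positive_label, covariates=cov, **kwargs)

    def fit(self) -> "PolymarkerSVMResults":
        pm = fit_preprocess(self.features, self.covariates)
        full = apply_preprocess(pm, self.features)
        svm = train_weighted_svm(full, self.labels, C=self.C,
                                 positive_label=self.positive_label)
        return PolymarkerSVMResults(self, pm, svm, full)


class PolymarkerSVMResults:
    """Fitted polymarker SVM: hyperplane, scores, evaluation, summary."""

    def __init__(self, model: PolymarkerSVM, preprocess: PreprocessModel,
                 svm: SVMModel, preprocessed: FeatureMatrix):
        self.model = model
        self.preprocess = preprocess
        self.svm = svm
        self._preprocessed = preprocessed
        self.params = pd.Series(svm.w, index=svm.feature_names, name="weight")
        self.intercept = svm.b
        self.decision_values = pd.Series(decision_values(svm, preprocessed),
                                         index=preprocessed.values.index,
                                         name="decision")

    def predict(self, features: "FeatureMatrix | pd.DataFrame",
                covariates: pd.DataFrame | None = None):
        if isinstance(features, pd.DataFrame):
            features = FeatureMatrix(values=features, covariates=covariates)
        if features.covariates is None and self.model.covariates is not None:
            # reuse the fit covariates for subjects we already know
            cov = self.model.covariates
            missing = features.values.index.difference(cov.index)
            if len(missing):
                raise ValueError(
                    f"covariates required for new subjects: {list(missing)[:5]}")
            features = FeatureMatrix(values=features.values,
                                     feature_set=features.feature_set,
                                     state=features.state,
                                     covariates=cov.loc[features.values.index])
        z = apply_preprocess(self.preprocess, features)
        dec = decision_values(self.svm, z)
        return np.where(dec > 0, self.svm.positive_label, self.svm.negative_label)

    def loo(self) -> ClassificationReport:
        m = self.model
        return loo_f1(m.features, m.labels, C=m.C, positive_label=m.positive_label,
                      covariates=m.covariates, paper_mode=m.paper_mode)

    def permutation_test(self, n_perm: int = 1000, seed: int | None = None
                         ) -> ClassificationReport:
        m = self.model
        return permutation_test(m.features, m.labels, n_perm=n_perm, seed=seed,
                                C=m.C, positive_label=m.positive_label,
                                covariates=m.covariates, paper_mode=m.paper_mode)

    def hyperplane(self, patient_mask=None) -> pd.DataFrame:
        if patient_mask is None:
            patient_mask = self.model.labels == self.model.positive_label
        return hyperplane_scores(self.svm, self._preprocessed, patient_mask)

    def summary(self) -> str:
        m = self.model
        y01, _ = _encode(m.labels, m.positive_label)
        pred = (self.decision_values.to_numpy() > 0).astype(int)
        _, sens, prec, f1 = _f1_parts(y01, pred)
        lines = [
            "Polymarker linear SVM",
            "=" * 44,
            f"feature set:       {m.features.feature_set} "
            f"({m.features.values.shape[1]} features)",
            f"subjects:          {len(m.labels)} "
            f"({int(y01.sum())} {m.positive_label} / {int((1 - y01).sum())} other)",
            f"C:                 {m.C}",
            f"class weights:     {self.svm.class_weights}",
            f"training fit:      sens {sens:.3f}  prec {prec:.3f}  F1 {f1:.3f}",
            "(use .loo()/.permutation_test() for unbiased evaluation)",
        ]
        return "\n".join(lines)
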