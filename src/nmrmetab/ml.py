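"""Classifier-based biomarker validation.

Random forest with mean-decrease-in-accuracy (MDA) importance ranking,
soft-margin SVM with sequential-minimal-optimization-style settings
(C = 1.0, tolerance 1e-3, linear kernel by default), Monte-Carlo
cross-validated AUROC panels with per-split feature selection, and the
two stratified hold-out validation schemes (n = 9: 6 control + 3 case,
72 repeats; n = 12: 9 control + 3 case).

Forest and SVM fitting delegate to scikit-learn; the splits, balanced
subsampling, importance averaging, panel selection and scoring are owned
here.  MDA is estimated by permutation importance scored on each repeat's
held-out third, averaged over repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .univariate import welch_test


class CompositionError(ValueError):
    pass


def _as_matrix(X):
    if hasattr(X, "values") and not isinstance(X, np.ndarray):
        return np.asarray(X.values, dtype=float)
    return np.asarray(X, dtype=float)


def _binary(y) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    labels = np.unique(y)
    if labels.size != 2:
        raise ValueError("need exactly two classes")
    return (y == labels[1]).astype(int), labels


def _stratified_split(y01, train_frac, rng):
    train, test = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(y01 == cls)
        rng.shuffle(idx)
        k = max(1, int(round(train_frac * idx.size)))
        k = min(k, idx.size - 1) if idx.size > 1 else k
        train.extend(idx[:k])
        test.extend(idx[k:])
    return np.array(sorted(train)), np.array(sorted(test))


# ---------------------------------------------------------------------------
# Random forest
# ---------------------------------------------------------------------------


@dataclass
class RfResult:
    ntree: int
    mtry: int
    n_repeats: int
    oob_error: float
    accuracy: float
    sensitivity: float
    specificity: float
    mda: pd.Series  # mean decrease in accuracy per feature, descending
    per_repeat_accuracy: np.ndarray = field(default_factory=lambda: np.empty(0))

    def ranking(self) -> list:
        return list(self.mda.index)


def rf_classify(
    X,
    y,
    ntree: int = 1000,
    mtry: int = 7,
    n_repeats: int = 1000,
    train_frac: float = 2 / 3,
    rng: np.random.Generator | None = None,
    feature_names=None,
) -> RfResult:
    """Repeated-split random forest classification with MDA ranking.

    Per repeat: a stratified 2/3-1/3 train/test split, a forest of
    ``ntree`` trees with ``mtry`` candidate predictors per node, the
    out-of-bag error on the training portion, test accuracy/sensitivity/
    specificity, and permutation importance on the held-out third.  MDA is
    the importance averaged over repeats; features are ranked by it.
    """
    M = _as_matrix(X)
    y01, labels = _binary(y)
    if mtry > M.shape[1]:
        raise ValueError(f"mtry={mtry} exceeds the {M.shape[1]} available features")
    if feature_names is None:
        feature_names = (
            list(X.feature_names) if hasattr(X, "feature_names") else [f"f{j}" for j in range(M.shape[1])]
        )
    rng = np.random.default_rng(0) if rng is None else rng

    oob, acc, sens, spec = [], [], [], []
    mda_sum = np.zeros(M.shape[1])
    for _ in range(n_repeats):
        tr, te = _stratified_split(y01, train_frac, rng)
        seed = int(rng.integers(2**31 - 1))
        forest = RandomForestClassifier(
            n_estimators=ntree,
            max_features=mtry,
            oob_score=True,
            random_state=seed,
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # few-sample OOB coverage warnings
            forest.fit(M[tr], y01[tr])
        oob.append(1.0 - forest.oob_score_)
        pred = forest.predict(M[te])
        truth = y01[te]
        acc.append((pred == truth).mean())
        pos, neg = truth == 1, truth == 0
        sens.append((pred[pos] == 1).mean() if pos.any() else np.nan)
        spec.append((pred[neg] == 0).mean() if neg.any() else np.nan)
        imp = permutation_importance(
            forest, M[te], truth, n_repeats=5, random_state=seed, scoring="accuracy"
        )
        mda_sum += imp.importances_mean
    mda = pd.Series(mda_sum / n_repeats, index=feature_names).sort_values(
        ascending=False
    )
    return RfResult(
        ntree=ntree,
        mtry=mtry,
        n_repeats=n_repeats,
        oob_error=float(np.mean(oob)),
        accuracy=float(np.mean(acc)),
        sensitivity=float(np.nanmean(sens)),
        specificity=float(np.nanmean(spec)),
        mda=mda,
        per_repeat_accuracy=np.asarray(acc),
    )


def prune_redundant(result: RfResult, min_keep: int = 1) -> list:
    """Features above the plateau of the sorted-MDA curve.

    The cut point is the largest relative drop in the descending MDA
    profile (features with little or no accuracy change are redundant).
    """
    mda = result.mda.to_numpy(dtype=float)
    names = list(result.mda.index)
    if mda.size <= min_keep:
        return names
    span = mda.max() - mda.min()
    if span == 0:
        warnings.warn("all MDA values equal; no plateau detected, keeping all features")
        return names
    # shift to a positive scale and find the largest ratio drop
    shifted = mda - mda.min() + 0.01 * span
    ratio = shifted[:-1] / shifted[1:]
    cut = int(np.argmax(ratio)) + 1
    return names[: max(cut, min_keep)]


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------


@dataclass
class SvmSpec:
    """SMO-style SVM settings (linear kernel, C = 1.0 by default)."""

    kernel: str = "linear"
    c: float = 1.0
    tolerance: float = 1e-3
    epsilon: float = 1e-12
    power_beta: float = 1.0  # exponent of the negative-distance kernel

    def __post_init__(self):
        if self.kernel not in ("linear", "sigmoid", "rbf", "power"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if not self.c > 0 or not self.tolerance > 0:
            raise ValueError("C and tolerance must be > 0")


@dataclass
class SvmPrediction:
    predictions: np.ndarray
    decision_values: np.ndarray
    accuracy: float | None
    labels: np.ndarray


def _make_svc(spec: SvmSpec) -> SVC:
    if spec.kernel == "power":
        beta = spec.power_beta

        def kernel(U, V):
            # negative-distance (conditionally positive-definite) kernel
            return -(cdist(U, V) ** beta)

        return SVC(kernel=kernel, C=spec.c, tol=spec.tolerance)
    return SVC(kernel=spec.kernel, C=spec.c, tol=spec.tolerance)


def svm_classify(
    X_train, y_train, X_eval, spec: SvmSpec | None = None, y_eval=None
) -> SvmPrediction:
    """Soft-margin SVM classification of ``X_eval`` given a training set."""
    spec = SvmSpec() if spec is None else spec
    Xtr, Xev = _as_matrix(X_train), _as_matrix(X_eval)
    y01, labels = _binary(y_train)
    svc = _make_svc(spec)
    svc.fit(Xtr, y01)
    pred01 = svc.predict(Xev)
    accuracy = None
    if y_eval is not None:
        yev = (np.asarray(y_eval) == labels[1]).astype(int)
        accuracy = float((pred01 == yev).mean())
    return SvmPrediction(
        predictions=labels[pred01],
        decision_values=svc.decision_function(Xev),
        accuracy=accuracy,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validated AUROC
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    panel_size: int
    auroc: float
    ci95: tuple[float, float]
    selection_frequency: pd.Series
    n_splits: int


def auroc_mccv(
    X,
    y,
    panel_sizes,
    n_splits: int = 100,
    spec: SvmSpec | None = None,
    train_frac: float = 2 / 3,
    rng: np.random.Generator | None = None,
    feature_names=None,
) -> list[RocResult]:
    """Monte-Carlo cross-validated AUROC for biomarker panels.

    Per split: a balanced training subsample (equal class counts via
    undersampling the majority class), per-split univariate (|Welch t|)
    selection of the top ``panel_size`` features, an SVM fit, and the
    AUROC of its decision values on the remaining samples.  Reports the
    mean AUROC, the percentile 95% interval across splits, and how often
    each feature entered the panel.
    """
    spec = SvmSpec() if spec is None else spec
    M = _as_matrix(X)
    y01, _ = _binary(y)
    if feature_names is None:
        feature_names = (
            list(X.feature_names) if hasattr(X, "feature_names") else [f"f{j}" for j in range(M.shape[1])]
        )
    rng = np.random.default_rng(0) if rng is None else rng
    results = []
    for size in panel_sizes:
        if not 0 < size <= M.shape[1]:
            raise ValueError(f"panel size {size} not in 1..{M.shape[1]}")
        aurocs = []
        counts = np.zeros(M.shape[1])
        for _ in range(n_splits):
            # balanced training subsample
            per_class = min(
                int(round(train_frac * (y01 == c).sum())) for c in (0, 1)
            )
            per_class = max(per_class, 1)
            train = []
            for c in (0, 1):
                idx = np.flatnonzero(y01 == c)
                rng.shuffle(idx)
                train.extend(idx[:per_class])
            train = np.array(train)
            test = np.setdiff1d(np.arange(y01.size), train)
            if np.unique(y01[test]).size < 2:
                continue
            tstats = np.array(
                [
                    abs(
                        welch_test(
                            M[train][y01[train] == 0, j], M[train][y01[train] == 1, j]
                        ).t
                    )
                    if M[train][:, j].std() > 0
                    else 0.0
                    for j in range(M.shape[1])
                ]
            )
            panel = np.argsort(-tstats)[:size]
            counts[panel] += 1
            svc = _make_svc(spec)
            svc.fit(M[np.ix_(train, panel)], y01[train])
            scores = svc.decision_function(M[np.ix_(test, panel)])
            aurocs.append(roc_auc_score(y01[test], scores))
        aurocs = np.asarray(aurocs)
        results.append(
            RocResult(
                panel_size=size,
                auroc=float(aurocs.mean()),
                ci95=(float(np.percentile(aurocs, 2.5)), float(np.percentile(aurocs, 97.5))),
                selection_frequency=pd.Series(
                    counts / max(len(aurocs), 1), index=feature_names
                ).sort_values(ascending=False),
                n_splits=len(aurocs),
            )
        )
    return results


# ---------------------------------------------------------------------------
# Hold-out validation
# ---------------------------------------------------------------------------


@dataclass
class HoldoutScheme:
    """Stratified hold-out composition and repeat schedule."""

    name: str
    n_holdout_control: int
    n_holdout_case: int
    n_repeats: int
    n_train: int | None = None  # inner training-set size; rest is the test set


def scheme_n9(n_repeats: int = 72) -> HoldoutScheme:
    """6 control + 3 case held out; inner 19/9 train/test splits."""
    return HoldoutScheme("n9", 6, 3, n_repeats, n_train=19)


def scheme_n12(n_repeats: int = 72) -> HoldoutScheme:
    """9 control + 3 case held out; inner 2/3 train splits."""
    return HoldoutScheme("n12", 9, 3, n_repeats, n_train=None)


@dataclass
class ValidationReport:
    scheme: str
    n_repeats: int
    train_accuracy: np.ndarray
    test_accuracy: np.ndarray
    holdout_accuracy: np.ndarray
    per_class: pd.DataFrame  # mean accuracy per (partition, class)

    def summary(self) -> pd.DataFrame:
        def ms(a):
            a = np.asarray(a, dtype=float) * 100.0
            return a.mean(), a.std(ddof=1) / np.sqrt(a.size) if a.size > 1 else 0.0

        rows = []
        for part, a in (
            ("training", self.train_accuracy),
            ("test", self.test_accuracy),
            ("holdout", self.holdout_accuracy),
        ):
            mean, sem = ms(a)
            rows.append({"partition": part, "mean_pct": mean, "sem_pct": sem})
        return pd.DataFrame(rows).set_index("partition")

    @property
    def holdout_percent_correct(self) -> float:
        return float(np.mean(self.holdout_accuracy) * 100.0)


def holdout_validate(
    X,
    y,
    scheme: HoldoutScheme,
    seed: int = 0,
    spec: SvmSpec | None = None,
    classifier: str = "svm",
) -> ValidationReport:
    """Stratified hold-out validation with repeated inner splits.

    A fixed stratified hold-out set (used for prediction only) is removed
    once; per repeat, the remainder is split into training and test sets,
    a classifier is fitted on the training portion, and accuracies on all
    three partitions are recorded.  Deterministic under ``seed``.
    """
    spec = SvmSpec() if spec is None else spec
    M = _as_matrix(X)
    y01, labels = _binary(y)
    rng = np.random.default_rng(seed)
    n = y01.size
    idx_control = np.flatnonzero(y01 == 0)
    idx_case = np.flatnonzero(y01 == 1)
    if scheme.n_holdout_control > idx_control.size or scheme.n_holdout_case > idx_case.size:
        raise CompositionError("hold-out set larger than a class")
    rng.shuffle(idx_control)
    rng.shuffle(idx_case)
    holdout = np.concatenate(
        [idx_control[: scheme.n_holdout_control], idx_case[: scheme.n_holdout_case]]
    )
    rest = np.setdiff1d(np.arange(n), holdout)

    def fit_eval(tr, parts):
        if classifier == "svm":
            svc = _make_svc(spec)
            svc.fit(M[tr], y01[tr])
            return [float((svc.predict(M[p]) == y01[p]).mean()) for p in parts], [
                svc.predict(M[p]) for p in parts
            ]
        raise ValueError(f"unknown classifier {classifier!r}")

    n_train = scheme.n_train or int(round(2 * rest.size / 3))
    if not 2 <= n_train < rest.size:
        raise CompositionError("inner training-set size infeasible")

    train_acc, test_acc, hold_acc = [], [], []
    class_correct = {("training", c): [] for c in labels}
    class_correct.update({("test", c): [] for c in labels})
    class_correct.update({("holdout", c): [] for c in labels})
    for _ in range(scheme.n_repeats):
        for _attempt in range(100):
            perm = rng.permutation(rest)
            tr, te = perm[:n_train], perm[n_train:]
            if np.unique(y01[tr]).size == 2:
                break
        else:
            raise CompositionError("could not draw a two-class training split")
        (a_tr, a_te, a_ho), (p_tr, p_te, p_ho) = fit_eval(tr, [tr, te, holdout])
        train_acc.append(a_tr)
        test_acc.append(a_te)
        hold_acc.append(a_ho)
        for part, idx, pred in (
            ("training", tr, p_tr),
            ("test", te, p_te),
            ("holdout", holdout, p_ho),
        ):
            for c01, cname in enumerate(labels):
                mask = y01[idx] == c01
                if mask.any():
                    class_correct[(part, cname)].append(
                        float((pred[mask] == c01).mean())
                    )
    per_class = pd.DataFrame(
        [
            {"partition": part, "class": cname, "accuracy": float(np.mean(v))}
            for (part, cname), v in class_correct.items()
            if v
        ]
    ).set_index(["partition", "class"])
    return ValidationReport(
        scheme=scheme.name,
        n_repeats=scheme.n_repeats,
        train_accuracy=np.asarray(train_acc),
        test_accuracy=np.asarray(test_acc),
        holdout_accuracy=np.asarray(hold_acc),
        per_class=per_class,
    )
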