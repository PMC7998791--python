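"""Latent-variable analysis with the study's validation protocol.

PCA (optionally Varimax-rotated with Kaiser normalization), Hotelling-style
outlier detection, PLS-DA with VIP scores, cross-validated Q² and label
permutation testing, OPLS-DA with the S-plot, partial redundancy analysis
(P-RDA) permutation tests for covariate effects, and agglomerative
hierarchical clustering with complete linkage on Euclidean distances.

PLS fitting delegates to scikit-learn's NIPALS implementation; OPLS-DA
(orthogonal signal correction), VIP, Q², the permutation machinery and
P-RDA are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.cross_decomposition import PLSRegression


class DataError(ValueError):
    pass


def _as_matrix(X):
    if hasattr(X, "values") and not isinstance(X, np.ndarray):
        return np.asarray(X.values, dtype=float)
    return np.asarray(X, dtype=float)


def _dummy(y) -> np.ndarray:
    """0/1 dummy coding of a binary label vector (sorted label order)."""
    y = np.asarray(y)
    labels = np.unique(y)
    if labels.size != 2:
        raise DataError(f"need exactly 2 classes, got {labels.size}")
    return (y == labels[1]).astype(float)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaModel:
    scores: np.ndarray  # samples x comps
    loadings: np.ndarray  # features x comps (orthonormal before rotation)
    eigenvalues: np.ndarray
    squared_cosines: np.ndarray  # features x comps, in [0, 1]
    communalities: np.ndarray  # per feature, sum of squared cosines
    rotation: str = "none"
    feature_names: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)
    mean_: np.ndarray | None = None


def pca(X, n_comp: int = 5, feature_names=None, sample_ids=None) -> PcaModel:
    """SVD-based PCA of an already transformed/scaled matrix (max 5 comps)."""
    M = _as_matrix(X)
    n, p = M.shape
    if n_comp > min(n - 1, p):
        raise ValueError(f"n_comp={n_comp} exceeds min(n-1, p)={min(n - 1, p)}")
    mean = M.mean(axis=0)
    C = M - mean
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    scores = (U * s)[:, :n_comp]
    loadings = Vt.T[:, :n_comp]
    eig = (s[:n_comp] ** 2) / (n - 1)
    sd = C.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = loadings * np.sqrt(eig) / sd[:, None]
    corr = np.nan_to_num(corr)
    cos2 = np.clip(corr**2, 0.0, 1.0)
    if feature_names is None and hasattr(X, "feature_names"):
        feature_names = list(X.feature_names)
    if sample_ids is None and hasattr(X, "sample_ids"):
        sample_ids = list(X.sample_ids)
    return PcaModel(
        scores=scores,
        loadings=loadings,
        eigenvalues=eig,
        squared_cosines=cos2,
        communalities=cos2.sum(axis=1),
        feature_names=feature_names or [],
        sample_ids=sample_ids or [],
        mean_=mean,
    )


def factor_loadings(model: PcaModel) -> np.ndarray:
    """Loadings scaled by component size (sqrt eigenvalue); the scale on
    which varimax operates and communalities are defined."""
    if model.rotation == "none":
        return model.loadings * np.sqrt(model.eigenvalues)
    return model.loadings  # already in factor-loading scale after rotation


def varimax_rotate(model: PcaModel) -> tuple[PcaModel, np.ndarray]:
    """Varimax rotation with Kaiser normalization of the PCA loadings.

    Orthogonal rotation maximizing the varimax simplicity criterion on
    Kaiser (row-) normalized factor loadings; per-feature communalities are
    invariant.  Returns the rotated model and the rotation matrix T
    (T'T = I).  After rotation ``model.loadings`` holds rotated factor
    loadings (no longer orthonormal) and ``eigenvalues`` the column sums of
    squared rotated loadings.
    """
    from statsmodels.multivariate.factor_rotation import rotate_factors

    L = factor_loadings(model)
    if L.shape[1] < 2:
        warnings.warn("varimax needs >= 2 components; returning model unchanged")
        return model, np.eye(L.shape[1])
    h = np.sqrt((L**2).sum(axis=1))
    safe = np.where(h == 0, 1.0, h)
    Lr, T = rotate_factors(L / safe[:, None], "varimax")
    Lr = Lr * safe[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        std_scores = model.scores / np.sqrt(model.eigenvalues)
    rotated = PcaModel(
        scores=np.nan_to_num(std_scores) @ T,
        loadings=Lr,
        eigenvalues=(Lr**2).sum(axis=0),
        squared_cosines=model.squared_cosines,  # communalities invariant
        communalities=model.communalities,
        rotation="varimax+kaiser",
        feature_names=model.feature_names,
        sample_ids=model.sample_ids,
        mean_=model.mean_,
    )
    return rotated, T


def detect_outliers(model: PcaModel, n_comp: int = 2, alpha: float = 0.05):
    """Samples outside the Hotelling-T² ellipse on the first components.

    The score distance T² = sum_a t_a²/lambda_a over the first ``n_comp``
    components is compared with the F-based (1-alpha) control limit.
    """
    k = min(n_comp, model.scores.shape[1])
    n = model.scores.shape[0]
    t2 = (model.scores[:, :k] ** 2 / model.eigenvalues[:k]).sum(axis=1)
    fcrit = stats.f.ppf(1 - alpha, k, n - k)
    limit = k * (n - 1) * (n + 1) / (n * (n - k)) * fcrit
    flagged = np.flatnonzero(t2 > limit)
    ids = model.sample_ids or list(range(n))
    return [ids[i] for i in flagged]


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------


@dataclass
class PlsModel:
    n_comp: int
    scores: np.ndarray  # T
    weights: np.ndarray  # W (features x comps)
    x_loadings: np.ndarray  # P
    y_loadings: np.ndarray  # q per comp
    r2y: float
    vip: np.ndarray | None = None
    q2: float | None = None
    permutation_p: float | None = None
    cv_scheme: str | None = None
    classes: np.ndarray | None = None
    feature_names: list = field(default_factory=list)
    _sk: PLSRegression | None = None


def plsda_fit(X, y, n_comp: int = 2, feature_names=None) -> PlsModel:
    """PLS-DA: NIPALS PLS1 regression on a 0/1 dummy-coded class label."""
    M = _as_matrix(X)
    yd = _dummy(y)
    if n_comp < 1:
        raise ValueError("n_comp must be >= 1")
    pls = PLSRegression(n_components=n_comp, scale=False)
    pls.fit(M, yd)
    resid = yd - pls.predict(M).ravel()
    tss = ((yd - yd.mean()) ** 2).sum()
    r2y = 1.0 - (resid**2).sum() / tss
    if feature_names is None and hasattr(X, "feature_names"):
        feature_names = list(X.feature_names)
    model = PlsModel(
        n_comp=n_comp,
        scores=pls.x_scores_,
        weights=pls.x_weights_,
        x_loadings=pls.x_loadings_,
        y_loadings=pls.y_loadings_.ravel(),
        r2y=float(r2y),
        classes=np.unique(np.asarray(y)),
        feature_names=feature_names or [],
        _sk=pls,
    )
    model.vip = vip_scores(model)
    return model


def vip_scores(model: PlsModel) -> np.ndarray:
    """Variable importance in projection; mean of squared VIPs equals 1.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ), where
    SSY_a is the y-variance explained by component a.
    """
    W, T, q = model.weights, model.scores, model.y_loadings
    p = W.shape[0]
    ssy = (T**2).sum(axis=0) * q**2
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    return np.sqrt(p * (wn**2 @ ssy) / ssy.sum())


def _class_preserving_folds(y, n_splits, rng, max_attempts=100):
    """Index folds such that every training partition keeps both classes."""
    n = y.size
    for _ in range(max_attempts):
        perm = rng.permutation(n)
        folds = np.array_split(perm, n_splits)
        ok = all(np.unique(y[np.setdiff1d(perm, f)]).size == 2 for f in folds)
        if ok:
            return folds
    raise DataError("could not build folds with both classes in every training set")


def cross_validate_q2(
    X,
    y,
    scheme: str = "kfold10",
    n_comp: int = 2,
    n_repeats: int = 20,
    rng: np.random.Generator | None = None,
) -> float:
    """Cross-validated predictive ability Q² = 1 - PRESS/TSS.

    Schemes: ``"loo"`` (leave-one-out), ``"kfold10"`` (10-fold, the
    default), ``"split67"`` (repeated random 67/33 train/test splits,
    ``n_repeats`` times).  Held-out class dummies are predicted from models
    fit on the remaining samples.
    """
    M = _as_matrix(X)
    yd = _dummy(y)
    n = yd.size
    rng = np.random.default_rng(0) if rng is None else rng
    tss = ((yd - yd.mean()) ** 2).sum()

    def fit_predict(tr, te):
        pls = PLSRegression(n_components=min(n_comp, len(tr) - 1), scale=False)
        pls.fit(M[tr], yd[tr])
        return pls.predict(M[te]).ravel()

    if scheme == "loo":
        press = 0.0
        for i in range(n):
            tr = np.setdiff1d(np.arange(n), [i])
            if np.unique(yd[tr]).size < 2:
                raise DataError("LOO leaves a single-class training set")
            press += (fit_predict(tr, [i])[0] - yd[i]) ** 2
        return 1.0 - press / tss
    if scheme == "kfold10":
        folds = _class_preserving_folds(yd, min(10, n), rng)
        press = 0.0
        for f in folds:
            tr = np.setdiff1d(np.arange(n), f)
            press += ((fit_predict(tr, f) - yd[f]) ** 2).sum()
        return 1.0 - press / tss
    if scheme == "split67":
        q2s = []
        for _ in range(n_repeats):
            for _attempt in range(100):
                perm = rng.permutation(n)
                n_tr = int(round(2 * n / 3))
                tr, te = perm[:n_tr], perm[n_tr:]
                if np.unique(yd[tr]).size == 2 and te.size:
                    break
            else:
                raise DataError("could not draw a two-class training split")
            press = ((fit_predict(tr, te) - yd[te]) ** 2).sum()
            tss_te = ((yd[te] - yd[tr].mean()) ** 2).sum()
            q2s.append(1.0 - press / tss_te if tss_te > 0 else 0.0)
        return float(np.mean(q2s))
    raise ValueError(f"unknown scheme {scheme!r}")


def permutation_test(
    X,
    y,
    n_perm: int = 2000,
    scheme: str = "kfold10",
    n_comp: int = 2,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, np.ndarray]:
    """Label-permutation test of the cross-validated Q² statistic.

    Returns (observed Q², p, null Q² values); p uses the add-one
    convention p = (1 + #{perm >= obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(0) if rng is None else rng
    y = np.asarray(y)
    observed = cross_validate_q2(X, y, scheme=scheme, n_comp=n_comp, rng=rng)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = cross_validate_q2(
            X, rng.permutation(y), scheme=scheme, n_comp=n_comp, rng=rng
        )
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return observed, p, null


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


@dataclass
class OplsModel:
    predictive_scores: np.ndarray  # t
    predictive_weights: np.ndarray  # w
    p1: np.ndarray  # cov(t, x_j) per feature
    p_corr: np.ndarray  # corr(t, x_j) per feature
    orthogonal_scores: np.ndarray  # samples x n_orth
    orthogonal_loadings: np.ndarray
    r2y: float
    n_orth: int
    feature_names: list = field(default_factory=list)


def oplsda_fit(X, y, n_orth: int = 1, feature_names=None) -> OplsModel:
    """OPLS-DA: class-orthogonal variation is removed before the single
    predictive component (orthogonal signal correction).

    Per orthogonal component: the X-loading of the provisional predictive
    score is deflated of its y-predictive part; the remainder defines an
    orthogonal score whose contribution is subtracted from X.
    """
    M = _as_matrix(X)
    yd = _dummy(y)
    Xc = M - M.mean(axis=0)
    yc = yd - yd.mean()

    w = Xc.T @ yc
    w /= np.linalg.norm(w)
    T_orth, P_orth = [], []
    Xf = Xc.copy()
    for _ in range(n_orth):
        t = Xf @ w
        p = Xf.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break
        w_o /= norm
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf = Xf - np.outer(t_o, p_o)
        T_orth.append(t_o)
        P_orth.append(p_o)

    t = Xf @ w
    n = Xf.shape[0]
    p1 = Xf.T @ t / (n - 1)  # covariance loadings
    sd_x = Xf.std(axis=0, ddof=1)
    sd_t = t.std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_corr = p1 / (sd_x * sd_t)
    p_corr = np.clip(np.nan_to_num(p_corr), -1.0, 1.0)
    b = (t @ yc) / (t @ t)
    resid = yc - b * t
    r2y = 1.0 - (resid**2).sum() / (yc**2).sum()
    if feature_names is None and hasattr(X, "feature_names"):
        feature_names = list(X.feature_names)
    return OplsModel(
        predictive_scores=t,
        predictive_weights=w,
        p1=p1,
        p_corr=p_corr,
        orthogonal_scores=np.column_stack(T_orth) if T_orth else np.empty((n, 0)),
        orthogonal_loadings=np.column_stack(P_orth) if P_orth else np.empty((M.shape[1], 0)),
        r2y=float(r2y),
        n_orth=len(T_orth),
        feature_names=feature_names or [],
    )


def s_plot(model: OplsModel) -> pd.DataFrame:
    """S-plot coordinates: covariance p[1] vs correlation p(corr)[1].

    Discriminatory features sit at the extremes of both axes.
    """
    return pd.DataFrame(
        {"p1": model.p1, "p_corr": model.p_corr},
        index=model.feature_names or range(model.p1.size),
    )


# ---------------------------------------------------------------------------
# Partial redundancy analysis (P-RDA)
# ---------------------------------------------------------------------------


@dataclass
class RdaResult:
    tested: str
    conditioning: list
    pseudo_f: float
    p: float
    n_perm: int


def _design(col: pd.Series) -> np.ndarray:
    if col.dtype.kind in "ifu":
        return col.to_numpy(dtype=float)[:, None]
    dummies = pd.get_dummies(col, drop_first=True)
    return dummies.to_numpy(dtype=float)


def prda_permutation(
    X,
    factors: pd.DataFrame,
    tested: str,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> RdaResult:
    """Partial RDA permutation test of one factor given the others.

    Both the response matrix and the tested design are residualized on the
    conditioning factors; the pseudo-F compares constrained to residual
    variance, with significance from Freedman-Lane-style permutation of the
    reduced-model residuals.
    """
    if tested not in factors.columns:
        raise ValueError(f"tested factor {tested!r} not among factors")
    rng = np.random.default_rng(0) if rng is None else rng
    M = _as_matrix(X)
    n = M.shape[0]
    conditioning = [c for c in factors.columns if c != tested]
    Z = np.column_stack(
        [np.ones((n, 1))] + [_design(factors[c]) for c in conditioning]
    )
    T = _design(factors[tested])

    def residualize(A, B):
        beta, *_ = np.linalg.lstsq(B, A, rcond=None)
        return A - B @ beta

    Rx = residualize(M, Z)
    Rt = residualize(T, Z)
    if np.linalg.norm(Rt) < 1e-10:
        raise DataError(
            f"factor {tested!r} is confounded with the conditioning factors"
        )
    rank_z = np.linalg.matrix_rank(Z)
    df_t = np.linalg.matrix_rank(Rt)
    df_res = n - rank_z - df_t
    if df_res <= 0:
        raise DataError("no residual degrees of freedom")

    def pseudo_f(R):
        fitted = Rt @ np.linalg.lstsq(Rt, R, rcond=None)[0]
        ss_fit = (fitted**2).sum()
        ss_res = ((R - fitted) ** 2).sum()
        return (ss_fit / df_t) / (ss_res / df_res)

    observed = pseudo_f(Rx)
    count = 0
    for _ in range(n_perm):
        if pseudo_f(Rx[rng.permutation(n)]) >= observed:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return RdaResult(
        tested=tested,
        conditioning=conditioning,
        pseudo_f=float(observed),
        p=float(p),
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# Agglomerative hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass
class HcaResult:
    linkage: np.ndarray
    row_order: np.ndarray
    labels: np.ndarray | None = None
    col_linkage: np.ndarray | None = None
    col_order: np.ndarray | None = None


def ahc(
    X,
    metric: str = "euclidean",
    linkage_method: str = "complete",
    bicluster: bool = False,
    n_clusters: int | None = None,
) -> HcaResult:
    """Agglomerative clustering (maximum dissimilarity / complete linkage)."""
    M = _as_matrix(X)
    if M.shape[0] < 2:
        raise DataError("need at least 2 samples")
    Z = hierarchy.linkage(M, method=linkage_method, metric=metric)
    labels = None
    if n_clusters is not None:
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    col_Z = col_order = None
    if bicluster and M.shape[1] >= 2:
        col_Z = hierarchy.linkage(M.T, method=linkage_method, metric=metric)
        col_order = hierarchy.leaves_list(col_Z)
    return HcaResult(
        linkage=Z,
        row_order=hierarchy.leaves_list(Z),
        labels=labels,
        col_linkage=col_Z,
        col_order=col_order,
    )


def distance_matrix(X, metric: str = "euclidean") -> np.ndarray:
    return squareform(pdist(_as_matrix(X), metric=metric))


def to_newick(Z: np.ndarray, labels) -> str:
    """Serialize a scipy linkage tree to Newick (branch lengths = heights)."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
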