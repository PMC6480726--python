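"""Metabolomics statistics: transforms, univariate tests, PCA, OPLS-DA,
MCCV-SVM ROC and random-forest classification.

The canonical pipeline order is: internal-standard (or constant-sum)
normalisation → exclusion filtering → generalised-log transform → Pareto
scaling → modelling.  Feature matrices are pandas DataFrames carrying a
``state`` tag list in ``.attrs`` which the transforms update and the models
check, so an out-of-order pipeline raises instead of silently mis-scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SkPCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MVResult",
    "glog_transform",
    "pareto_scale",
    "ttest_fdr",
    "pca",
    "varimax",
    "oplsda_fit",
    "oplsda_predict",
    "cv_q2",
    "permutation_test",
    "mccv_svm_roc",
    "MCCVResult",
    "random_forest_classify",
    "exclusion_filter",
]


def _state(fm: pd.DataFrame) -> list:
    return list(fm.attrs.get("state", ["raw"]))


def _with_state(fm: pd.DataFrame, out: pd.DataFrame, tag: str) -> pd.DataFrame:
    out.attrs = dict(fm.attrs)
    out.attrs["state"] = _state(fm) + [tag]
    return out


def _require(fm: pd.DataFrame, *any_of: str, stage: str):
    st = _state(fm)
    if not any(tag in st for tag in any_of):
        raise ValueError(
            f"{stage} expects a matrix tagged with one of {any_of}; "
            f"current state: {st}")


def _forbid(fm: pd.DataFrame, tag: str, stage: str):
    if tag in _state(fm):
        raise ValueError(f"{stage}: matrix already {tag}-processed")


# ---------------------------------------------------------------------------
# transforms

def glog_transform(fm: pd.DataFrame, lam: float = None) -> pd.DataFrame:
    """Generalised logarithm g(x) = ln((x + √(x² + λ))/2), defined at 0.

    λ defaults to the square of the median within-sample noise-bucket scale
    (the smallest bucket magnitude per sample), a variance-stabilising choice
    when the true λ is unknown.
    """
    _require(fm, "tsp", "csn", "cn", stage="glog")
    _forbid(fm, "glog", "glog")
    _forbid(fm, "pareto", "glog")
    X = fm.to_numpy(dtype=float)
    if lam is None:
        lam = float(np.median(np.min(np.abs(X), axis=1)) ** 2)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    out = pd.DataFrame(np.log((X + np.sqrt(X ** 2 + lam)) / 2.0),
                       index=fm.index, columns=fm.columns)
    out = _with_state(fm, out, "glog")
    out.attrs["glog_lambda"] = lam
    return out


def pareto_scale(fm: pd.DataFrame) -> pd.DataFrame:
    """Mean-centre then divide by √(column s.d.).

    After scaling each column has mean 0 and variance equal to its original
    s.d. — "similar but not equal to unity".
    """
    _forbid(fm, "pareto", "pareto")
    if len(fm) < 2:
        raise ValueError("need at least 2 samples")
    X = fm.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    bad = sd == 0
    if bad.any():
        raise ValueError("constant column(s): "
                         + ", ".join(fm.columns[bad].astype(str)))
    out = pd.DataFrame((X - X.mean(axis=0)) / np.sqrt(sd),
                       index=fm.index, columns=fm.columns)
    return _with_state(fm, out, "pareto")


def exclusion_filter(fm: pd.DataFrame, regions, table=None):
    """Drop buckets intersecting any exclusion region; returns (matrix, log).

    With a bucket table, intersection is tested on bucket bounds; without
    one, bucket labels of the form ``low-high`` or named buckets cannot be
    located and a table is required unless ``regions`` is empty.
    """
    regions = list(regions)
    if not regions:
        out = fm.copy()
        out.attrs = dict(fm.attrs)
        return out, []
    if table is None:
        raise ValueError("a BucketTable is required to resolve bucket bounds")
    dropped = []
    for b in table.buckets:
        if b.label in fm.columns and any(
                b.low < hi and lo < b.high for lo, hi in regions):
            dropped.append(b.label)
    out = fm.drop(columns=dropped)
    out.attrs = dict(fm.attrs)
    out.attrs["state"] = _state(fm) + ["filtered"] if dropped else _state(fm)
    return out, dropped


# ---------------------------------------------------------------------------
# univariate

def ttest_fdr(fm: pd.DataFrame, groups, method: str = "BH") -> pd.DataFrame:
    """Two-sample t-tests per bucket with BH-FDR or Holm adjustment."""
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    a = fm.loc[groups == levels[0]].to_numpy(dtype=float)
    b = fm.loc[groups == levels[1]].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind(a, b, axis=0)
    p = np.where(np.isnan(p), 1.0, p)
    t = np.where(np.isnan(t), 0.0, t)
    key = {"BH": "fdr_bh", "holm": "holm"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment {method!r}")
    adj = multipletests(p, method=key)[1]
    return pd.DataFrame({"t": t, "p": p, "p_adj": np.maximum(adj, p)},
                        index=fm.columns)


# ---------------------------------------------------------------------------
# multivariate

@dataclass
class MVResult:
    """Scores/loadings container for PCA and (O)PLS-DA models."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance: np.ndarray
    R2X: float = float("nan")
    R2Y: float = float("nan")
    Q2: float = float("nan")
    p_Q2: float = float("nan")
    p_R2Y: float = float("nan")
    vip: pd.Series = None
    model: dict = field(default_factory=dict)


def varimax(loadings: np.ndarray, kaiser: bool = True, tol: float = 1e-8,
            max_iter: int = 500) -> tuple:
    """Varimax rotation (orthogonal), optionally with Kaiser row
    normalisation; returns (rotated loadings, rotation matrix)."""
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    comm = np.sqrt((L ** 2).sum(axis=1))
    if kaiser:
        comm_safe = np.where(comm == 0, 1.0, comm)
        L = L / comm_safe[:, None]
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr ** 3 - Lr @ np.diag((Lr ** 2).sum(axis=0)) / p))
        R = u @ vt
        var = s.sum()
        if var_old != 0 and (var - var_old) / var_old < tol:
            break
        var_old = var
    Lr = L @ R
    if kaiser:
        Lr = Lr * comm_safe[:, None]
    return Lr, R


def pca(fm: pd.DataFrame, variance_criterion: float = 0.8,
        rotate: str = "none") -> MVResult:
    """PCA retaining components to a cumulative-variance criterion.

    ``rotate='varimax'`` applies varimax with Kaiser normalisation to the
    retained loadings; rotation redistributes but preserves the total
    explained variance.
    """
    if not 0 < variance_criterion <= 1:
        raise ValueError("variance criterion must lie in (0, 1]")
    if len(fm) < 2:
        raise ValueError("need more than one sample")
    X = fm.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    sk = _SkPCA()
    scores = sk.fit_transform(Xc)
    evr = sk.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(evr), variance_criterion) + 1)
    k = min(k, len(evr))
    load = sk.components_[:k].T  # buckets × k
    scr = scores[:, :k]
    expl = evr[:k].copy()
    if rotate == "varimax":
        load, R = varimax(load, kaiser=True)
        scr = scr @ R
        tot = (Xc ** 2).sum()
        expl = (scr ** 2).sum(axis=0) / tot
        order = np.argsort(expl)[::-1]
        scr, load, expl = scr[:, order], load[:, order], expl[order]
    elif rotate != "none":
        raise ValueError(f"unknown rotation {rotate!r}")
    cols = [f"PC{i + 1}" for i in range(scr.shape[1])]
    return MVResult(
        scores=pd.DataFrame(scr, index=fm.index, columns=cols),
        loadings=pd.DataFrame(load, index=fm.columns, columns=cols),
        explained_variance=expl,
        R2X=float(expl.sum()))


def _encode_binary(groups) -> tuple:
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("binary class labels required")
    y = np.where(groups == levels[1], 1.0, 0.0)
    return y, levels


def _opls_decompose(X: np.ndarray, y: np.ndarray, n_orthogonal: int):
    """Orthogonal-signal-corrected PLS1 (one predictive component).

    Returns a dict of weights/loadings sufficient for prediction on new data.
    """
    W_o, P_o = [], []
    Xf = X.copy()
    w = X.T @ y
    w /= np.linalg.norm(w)
    for _ in range(n_orthogonal):
        t = Xf @ w
        p = Xf.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-12:
            break
        w_o /= nrm
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf = Xf - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
    t = Xf @ w
    p = Xf.T @ t / (t @ t)
    q = (y @ t) / (t @ t)
    return {"w": w, "p": p, "q": q, "W_o": W_o, "P_o": P_o, "t": t, "Xf": Xf}


def oplsda_fit(fm: pd.DataFrame, groups, n_orthogonal: int = 1) -> MVResult:
    """OPLS-DA: one predictive + ``n_orthogonal`` orthogonal components.

    Orthogonal components capture within-X variation uncorrelated with class;
    the predictive component carries the discrimination.  With zero
    orthogonal components the fitted Y equals the single-component PLS1
    solution.
    """
    y01, levels = _encode_binary(groups)
    if len(fm) < 4:
        raise ValueError("need n >= 4 samples")
    X = fm.to_numpy(dtype=float)
    xm, ym = X.mean(axis=0), y01.mean()
    Xc, yc = X - xm, y01 - ym
    m = _opls_decompose(Xc, yc, n_orthogonal)
    t, q, p = m["t"], m["q"], m["p"]
    yhat = t * q
    R2Y = 1.0 - ((yc - yhat) ** 2).sum() / (yc ** 2).sum()
    ssx = (Xc ** 2).sum()
    modelled = np.outer(t, p)
    T_o = []
    Xtmp = Xc.copy()
    for w_o, p_o in zip(m["W_o"], m["P_o"]):
        t_o = Xtmp @ w_o
        T_o.append(t_o)
        Xtmp = Xtmp - np.outer(t_o, p_o)
        modelled = modelled + np.outer(t_o, p_o)
    R2X = float((modelled ** 2).sum() / ssx)
    cols = ["t_pred"] + [f"t_orth{i + 1}" for i in range(len(T_o))]
    scores = pd.DataFrame(np.column_stack([t] + T_o) if T_o else t[:, None],
                          index=fm.index, columns=cols)
    loadings = pd.DataFrame(
        np.column_stack([p] + m["P_o"]) if m["P_o"] else p[:, None],
        index=fm.columns, columns=cols)
    expl = np.array([(s ** 2).sum() / ssx for s in
                     [np.outer(scores[c], loadings[c]) for c in cols]])
    # VIP over the predictive component; for a single component this reduces
    # to sqrt(p) * |w_j| / ||w||
    wn = m["w"] / np.linalg.norm(m["w"])
    vip = np.sqrt(len(fm.columns)) * np.abs(wn)
    return MVResult(
        scores=scores, loadings=loadings, explained_variance=expl,
        R2X=R2X, R2Y=float(R2Y),
        vip=pd.Series(vip, index=fm.columns),
        model={"w": m["w"], "q": q, "p": p, "W_o": m["W_o"], "P_o": m["P_o"],
               "x_mean": xm, "y_mean": ym, "levels": levels,
               "n_orthogonal": len(m["W_o"])})


def oplsda_predict(result: MVResult, fm_new: pd.DataFrame) -> np.ndarray:
    """Continuous class prediction (ŷ on the 0/1 scale) for new samples."""
    m = result.model
    X = fm_new.to_numpy(dtype=float) - m["x_mean"]
    for w_o, p_o in zip(m["W_o"], m["P_o"]):
        t_o = X @ w_o
        X = X - np.outer(t_o, p_o)
    t = X @ m["w"]
    return t * m["q"] + m["y_mean"]


def cv_q2(fm: pd.DataFrame, groups, k_folds: int = 10,
          n_orthogonal: int = 1, seed: int = 0) -> float:
    """Stratified k-fold cross-validated Q² = 1 − PRESS/TSS."""
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    y01, _ = _encode_binary(groups)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(k_folds)]
    for level in pd.unique(groups):
        idx = np.flatnonzero(groups == level)
        if len(idx) < k_folds and len(idx) < 2:
            raise ValueError("a class is too small to stratify")
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % k_folds].append(i)
    press = tss = 0.0
    for fold in folds:
        if not fold:
            continue
        test = np.array(sorted(fold))
        train = np.setdiff1d(np.arange(len(fm)), test)
        if len(pd.unique(groups[train])) < 2:
            raise ValueError("a training fold lost a class; lower k_folds")
        res = oplsda_fit(fm.iloc[train], groups[train],
                         n_orthogonal=n_orthogonal)
        yhat = oplsda_predict(res, fm.iloc[test])
        ybar = y01[train].mean()
        press += ((y01[test] - yhat) ** 2).sum()
        tss += ((y01[test] - ybar) ** 2).sum()
    return float(1.0 - press / tss)


def permutation_test(fm: pd.DataFrame, groups, B: int = 2000,
                     n_orthogonal: int = 1, k_folds: int = 10,
                     seed: int = 0) -> dict:
    """Label-permutation p-values for Q² and R²Y.

    p = (1 + #{permuted ≥ observed}) / (1 + B); the smallest attainable
    value is 1/(B+1) — e.g. 1/2001 < 5×10⁻⁴ at B = 2000.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    groups = np.asarray(groups)
    obs_q2 = cv_q2(fm, groups, k_folds=k_folds, n_orthogonal=n_orthogonal,
                   seed=seed)
    obs_r2y = oplsda_fit(fm, groups, n_orthogonal=n_orthogonal).R2Y
    rng = np.random.default_rng(seed)
    n_ge_q2 = n_ge_r2y = 0
    for _ in range(B):
        perm = rng.permutation(groups)
        try:
            q2p = cv_q2(fm, perm, k_folds=k_folds,
                        n_orthogonal=n_orthogonal, seed=seed)
        except ValueError:
            q2p = -np.inf
        r2yp = oplsda_fit(fm, perm, n_orthogonal=n_orthogonal).R2Y
        n_ge_q2 += q2p >= obs_q2
        n_ge_r2y += r2yp >= obs_r2y
    return {"Q2": obs_q2, "R2Y": obs_r2y,
            "p_Q2": (1 + n_ge_q2) / (1 + B),
            "p_R2Y": (1 + n_ge_r2y) / (1 + B)}


# ---------------------------------------------------------------------------
# classification

@dataclass
class MCCVResult:
    """Per-feature-count AUROC summary from MCCV balanced subsampling."""

    auroc: dict          # k -> (mean, lo95, hi95)
    roc_points: dict     # k -> (fpr, tpr) pooled over splits
    n_splits: int

    def mean_auroc(self, k: int) -> float:
        return self.auroc[k][0]


def mccv_svm_roc(fm: pd.DataFrame, groups, n_features_grid=(10,),
                 n_splits: int = 100, seed: int = 0,
                 train_fraction: float = 2 / 3) -> MCCVResult:
    """Monte Carlo CV with balanced subsampling and a linear-kernel SVM.

    Each split balances the classes by subsampling the larger one, holds out
    1 − ``train_fraction`` for testing, ranks features by |t| on the training
    portion only, fits a linear maximum-margin classifier on the top-k
    features, and scores the held-out samples.  AUROC is averaged over
    splits with a normal-approximation 95% interval.
    """
    if n_splits < 10:
        raise ValueError("n_splits must be >= 10")
    y01, _ = _encode_binary(groups)
    X = fm.to_numpy(dtype=float)
    idx0 = np.flatnonzero(y01 == 0)
    idx1 = np.flatnonzero(y01 == 1)
    n_bal = min(len(idx0), len(idx1))
    n_train = int(round(train_fraction * n_bal))
    if n_train < 2 or n_bal - n_train < 1:
        raise ValueError("classes too small for balanced subsampling")
    rng = np.random.default_rng(seed)
    aucs = {k: [] for k in n_features_grid}
    pooled = {k: ([], []) for k in n_features_grid}  # scores, labels
    for _ in range(n_splits):
        s0 = rng.choice(idx0, n_bal, replace=False)
        s1 = rng.choice(idx1, n_bal, replace=False)
        tr = np.concatenate((s0[:n_train], s1[:n_train]))
        te = np.concatenate((s0[n_train:], s1[n_train:]))
        t_stat, _ = stats.ttest_ind(X[tr][y01[tr] == 0],
                                    X[tr][y01[tr] == 1], axis=0)
        order = np.argsort(-np.abs(np.nan_to_num(t_stat)))
        for k in n_features_grid:
            feats = order[:k]
            clf = SVC(kernel="linear", C=1.0)
            clf.fit(X[np.ix_(tr, feats)], y01[tr])
            scores = clf.decision_function(X[np.ix_(te, feats)])
            aucs[k].append(roc_auc_score(y01[te], scores))
            pooled[k][0].extend(scores)
            pooled[k][1].extend(y01[te])
    summary, rocs = {}, {}
    for k in n_features_grid:
        a = np.asarray(aucs[k])
        half = 1.96 * a.std(ddof=1) / np.sqrt(len(a))
        summary[k] = (float(a.mean()), float(a.mean() - half),
                      float(a.mean() + half))
        fpr, tpr, _ = roc_curve(pooled[k][1], pooled[k][0])
        rocs[k] = (fpr, tpr)
    return MCCVResult(auroc=summary, roc_points=rocs, n_splits=n_splits)


def random_forest_classify(fm: pd.DataFrame, groups, n_trees: int = 500,
                           m_try: int = 7, seed: int = 0) -> dict:
    """Random forest with out-of-bag validation.

    Defaults follow the case-study settings (500 trees, 7 candidate
    variables per split).  Returns OOB accuracy, the OOB confusion counts
    and per-class accuracies.
    """
    if m_try > fm.shape[1]:
        raise ValueError("m_try exceeds the number of features")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if n_trees < 50:
        warnings.warn("OOB estimates are unstable for very few trees",
                      UserWarning)
    y, levels = _encode_binary(groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny forests: some samples never OOB
        rf = RandomForestClassifier(
            n_estimators=n_trees, max_features=m_try, oob_score=True,
            random_state=seed, bootstrap=True)
        rf.fit(fm.to_numpy(dtype=float), y)
        proba = rf.oob_decision_function_
    valid = ~np.isnan(proba[:, 0])
    pred = (proba[valid, 1] > 0.5).astype(float)
    truth = y[valid]
    conf = pd.DataFrame(
        [[(int(((truth == a) & (pred == b)).sum())) for b in (0.0, 1.0)]
         for a in (0.0, 1.0)],
        index=[f"true_{l}" for l in levels],
        columns=[f"pred_{l}" for l in levels])
    acc = float((pred == truth).mean())
    per_class = {str(levels[int(a)]): float((pred[truth == a] == a).mean())
                 for a in (0, 1)}
    return {"oob_accuracy": acc, "confusion": conf,
            "per_class_accuracy": per_class,
            "feature_importance": pd.Series(rf.feature_importances_,
                                            index=fm.columns)}
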