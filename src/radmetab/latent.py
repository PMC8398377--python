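"""Latent-variable models: PCA and a from-scratch OPLS-DA.

PCA is the unsupervised sanity check (group separation by dose and
timepoint, cohort comparability).  OPLS-DA is the supervised workhorse: a
two-class partial least squares discriminant model whose predictor
variation is split into one *predictive* component (correlated with the
class vector) and zero or more *orthogonal* components (systematic
variation uncorrelated with class).  The implementation is the standard
NIPALS-style orthogonal-projections algorithm:

1. autoscale X (mean-centre, unit variance by default) and centre the
   0/1-coded class vector ``y``;
2. repeat for each orthogonal component: compute the PLS weight
   ``w ∝ Xᵀy``, score ``t = Xw`` and loading ``p``; split ``p`` into its
   projection on ``w`` and the orthogonal remainder ``w_orth``; extract
   the orthogonal score ``t_orth = X w_orth`` and deflate
   ``X ← X − t_orth p_orthᵀ``;
3. fit the final one-component PLS on the deflated X.

By construction each orthogonal score has exactly zero covariance with the
centred class vector, and with zero orthogonal components the model *is*
one-component PLS1-DA.

Model quality is summarised by R²Y (training fit), Q² (stratified k-fold
cross-validation; 10-fold when the smaller class has ≥10 members, else
5-fold, else leave-one-out), a cross-validated ANOVA F-test on the CV
residuals, and a label-permutation test (default 100 permutations).  VIP
scores use the predictive component only; their squares average 1, so
VIP > 1 marks metabolites contributing more than average to the
discrimination.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PcaModel",
    "OplsDaModel",
    "fit_pca",
    "fit_oplsda",
    "predict_oplsda",
    "vip_scores",
    "cross_validate",
    "cv_anova",
    "permutation_test",
    "choose_n_orthogonal",
    "validate_oplsda",
]


# --------------------------------------------------------------------------- PCA

@dataclass
class PcaModel:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_fraction: np.ndarray
    scaling: str
    mean: np.ndarray
    scale: np.ndarray


def _as_frame(matrix) -> pd.DataFrame:
    """Accept an AbundanceMatrix, DataFrame or ndarray."""
    if hasattr(matrix, "data") and hasattr(matrix, "stage"):
        return matrix.data
    if isinstance(matrix, pd.DataFrame):
        return matrix
    arr = np.asarray(matrix, dtype=float)
    return pd.DataFrame(arr)


def _autoscale(X: np.ndarray, scaling: str, columns=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    if scaling == "unit_variance":
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            name = columns[zero[0]] if columns is not None else zero[0]
            raise ValueError(f"constant metabolite {name!r} cannot be unit-variance scaled")
    elif scaling == "center_only":
        sd = np.ones(X.shape[1])
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return (X - mean) / sd, mean, sd


def fit_pca(matrix, n_components: int, scaling: str = "unit_variance") -> PcaModel:
    """Principal component analysis with a fixed sign convention.

    Components are ordered by explained variance; the sign of each is fixed
    so that the largest-magnitude loading entry is positive, making score
    plots reproducible across runs and platforms.
    """
    from sklearn.decomposition import PCA

    df = _as_frame(matrix)
    X = df.to_numpy(dtype=float)
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds max rank {max_rank}")
    Xs, mean, sd = _autoscale(X, scaling, df.columns)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xs)
    loadings = pca.components_.T  # metabolites × components
    for k in range(n_components):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return PcaModel(
        scores=pd.DataFrame(scores, index=df.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=df.columns, columns=comp_names),
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        scaling=scaling, mean=mean, scale=sd,
    )


# ----------------------------------------------------------------------- OPLS-DA

@dataclass
class OplsDaModel:
    """Fitted two-class OPLS-DA model (one predictive + K orthogonal components)."""

    classes: tuple
    w_pred: np.ndarray          # predictive weight, unit norm
    p_pred: np.ndarray          # predictive X-loading
    t_pred: np.ndarray          # predictive score
    q_pred: float               # y-loading of the predictive component
    w_orth: np.ndarray          # K × m orthogonal weights
    p_orth: np.ndarray          # K × m orthogonal loadings
    t_orth: np.ndarray          # n × K orthogonal scores
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    scaling: str
    metabolite_ids: list
    sample_ids: list
    r2x: float
    r2y: float
    vip: pd.Series = field(default=None)
    q2: float | None = None
    n_folds: int | None = None
    cv_anova_F: float | None = None
    cv_anova_p: float | None = None
    permutation_p_q2: float | None = None
    permutation_p_r2y: float | None = None
    n_permutations: int | None = None

    @property
    def n_orthogonal(self) -> int:
        return self.w_orth.shape[0]

    def is_validated(self, perm_p_max: float = 0.05, q2_min: float = 0.0) -> bool:
        """Overfitting guard: permutation p below threshold and Q² above floor."""
        if self.permutation_p_q2 is None or self.q2 is None:
            return False
        return self.permutation_p_q2 < perm_p_max and self.q2 > q2_min

    def to_json(self, path) -> None:
        payload = {
            "classes": [str(c) for c in self.classes],
            "scaling": self.scaling,
            "n_orthogonal": self.n_orthogonal,
            "r2x": self.r2x, "r2y": self.r2y, "q2": self.q2,
            "n_folds": self.n_folds,
            "cv_anova_F": self.cv_anova_F, "cv_anova_p": self.cv_anova_p,
            "permutation_p_q2": self.permutation_p_q2,
            "permutation_p_r2y": self.permutation_p_r2y,
            "n_permutations": self.n_permutations,
            "metabolite_ids": list(map(str, self.metabolite_ids)),
            "w_pred": self.w_pred.tolist(),
            "p_pred": self.p_pred.tolist(),
            "t_pred": self.t_pred.tolist(),
            "q_pred": self.q_pred,
            "w_orth": self.w_orth.tolist(),
            "p_orth": self.p_orth.tolist(),
            "vip": self.vip.tolist() if self.vip is not None else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)


def _encode_labels(labels) -> tuple[np.ndarray, tuple]:
    labels = np.asarray(labels)
    classes = tuple(sorted(pd.unique(labels), key=str))
    if len(classes) != 2:
        raise ValueError(f"OPLS-DA requires exactly two classes, got {classes}")
    y = (labels == classes[1]).astype(float)
    return y, classes


def fit_oplsda(matrix, labels, n_orthogonal: int = 0,
               scaling: str = "unit_variance") -> OplsDaModel:
    """Fit an OPLS-DA model for a two-class problem.

    ``matrix`` rows are the samples of both classes (AbundanceMatrix,
    DataFrame, or array); ``labels`` is the per-row class label.  Each
    class needs at least 3 samples.  ``n_orthogonal`` beyond the rank of
    the class-orthogonal subspace raises an error.
    """
    df = _as_frame(matrix)
    y, classes = _encode_labels(labels)
    if min((y == 0).sum(), (y == 1).sum()) < 3:
        raise ValueError("each class needs at least 3 samples")
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be >= 0")

    X = df.to_numpy(dtype=float)
    Xs, x_mean, x_scale = _autoscale(X, scaling, df.columns)
    y_mean = y.mean()
    yc = y - y_mean
    ss_x_total = float((Xs ** 2).sum())

    Xd = Xs.copy()
    W_o, P_o, T_o = [], [], []
    ss_explained = 0.0
    for _ in range(n_orthogonal):
        w = Xd.T @ yc
        w_norm = np.linalg.norm(w)
        if w_norm < 1e-12:
            raise ValueError("no class-correlated variation left; reduce n_orthogonal")
        w = w / w_norm
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        wo_norm = np.linalg.norm(w_o)
        if wo_norm < 1e-10:
            raise ValueError("n_orthogonal exceeds the rank of the orthogonal subspace")
        w_o = w_o / wo_norm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        ss_explained += float((t_o @ t_o) * (p_o @ p_o))
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)

    w = Xd.T @ yc
    w_norm = np.linalg.norm(w)
    if w_norm < 1e-12:
        raise ValueError("class vector is orthogonal to X; cannot fit predictive component")
    w = w / w_norm
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))
    ss_explained += float((t @ t) * (p @ p))

    yhat_c = q * t
    r2y = 1.0 - float(((yc - yhat_c) ** 2).sum() / (yc ** 2).sum())

    m = X.shape[1]
    vip = pd.Series(np.sqrt(m) * np.abs(w), index=df.columns, name="vip")

    return OplsDaModel(
        classes=classes, w_pred=w, p_pred=p, t_pred=t, q_pred=q,
        w_orth=np.array(W_o).reshape(len(W_o), m),
        p_orth=np.array(P_o).reshape(len(P_o), m),
        t_orth=np.column_stack(T_o) if T_o else np.zeros((X.shape[0], 0)),
        x_mean=x_mean, x_scale=x_scale, y_mean=float(y_mean), scaling=scaling,
        metabolite_ids=list(df.columns), sample_ids=list(df.index),
        r2x=ss_explained / ss_x_total if ss_x_total > 0 else 0.0,
        r2y=r2y, vip=vip,
    )


def predict_oplsda(model: OplsDaModel, matrix) -> pd.Series:
    """Continuous class prediction on the 0/1 scale for new samples.

    New rows are autoscaled with the training statistics, filtered through
    the orthogonal components (their contribution is removed) and projected
    on the predictive component.  Threshold at 0.5 for a class call.
    """
    df = _as_frame(matrix)
    Xn = (df.to_numpy(dtype=float) - model.x_mean) / model.x_scale
    for k in range(model.n_orthogonal):
        t_o = Xn @ model.w_orth[k]
        Xn = Xn - np.outer(t_o, model.p_orth[k])
    t = Xn @ model.w_pred
    return pd.Series(model.q_pred * t + model.y_mean, index=df.index, name="y_pred")


def vip_scores(model: OplsDaModel) -> pd.Series:
    """Variable importance in projection from the predictive component.

    For a single predictive component VIP_j = √M · |w_j| / ‖w‖, so the mean
    of squared VIP over the M metabolites is exactly 1.
    """
    return model.vip.copy()


# ------------------------------------------------------------------ validation

def _n_folds_for(y: np.ndarray, folds) -> int:
    n_small = int(min((y == 0).sum(), (y == 1).sum()))
    if folds == "auto":
        if n_small >= 10:
            return 10
        if n_small >= 5:
            return 5
        return len(y)  # leave-one-out
    k = int(folds)
    if k > n_small and k != len(y):
        warnings.warn(f"smaller class ({n_small}) below fold count {k}; "
                      "falling back to leave-one-out")
        return len(y)
    return k


def _fold_assignment(index, y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Class-stratified fold labels, invariant to row order.

    Rows are keyed by their sample id (string order) within each class,
    shuffled with the fold seed, and dealt cyclically into folds, so the
    assignment depends only on the id set, the labels and the seed.
    """
    rng = np.random.default_rng(seed)
    fold = np.empty(len(y), dtype=int)
    ids = np.asarray([str(i) for i in index])
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y == cls)
        idx = idx[np.argsort(ids[idx])]
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % k
    return fold


def cross_validate(matrix, labels, n_orthogonal: int = 0, folds="auto",
                   seed: int = 0, scaling: str = "unit_variance",
                   ) -> tuple[float, pd.Series, int]:
    """Stratified k-fold Q² for an OPLS-DA model.

    Returns ``(q2, out_of_fold_predictions, n_folds_used)`` where
    ``q2 = 1 − PRESS/TSS``: PRESS sums squared out-of-fold errors of the
    0/1 class vector and TSS is its total centred sum of squares.
    """
    df = _as_frame(matrix)
    y, _classes = _encode_labels(labels)
    k = _n_folds_for(y, folds)
    fold = _fold_assignment(df.index, y, k, seed)

    yhat = np.empty(len(y))
    labels_arr = np.asarray(labels)
    for f in np.unique(fold):
        train = fold != f
        test = ~train
        if len(np.unique(y[train])) < 2:
            raise ValueError("a training split lost one class; too few samples")
        model = fit_oplsda(df.loc[train], labels_arr[train],
                           n_orthogonal=n_orthogonal, scaling=scaling)
        yhat[test] = predict_oplsda(model, df.loc[test]).to_numpy()

    press = float(((y - yhat) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    q2 = 1.0 - press / tss
    return q2, pd.Series(yhat, index=df.index, name="y_cv"), k


def cv_anova(yhat_cv: pd.Series, labels, n_components: int = 1) -> tuple[float, float]:
    """F-test of cross-validated residuals against the intercept-only baseline.

    SIMCA-style construction: F = ((TSS − PRESS)/d₁) / (PRESS/d₂) with
    d₁ = number of model components (predictive + orthogonal) and
    d₂ = N − 1 − d₁; p is the upper F tail.  A model no better than the
    class-mean predictor gives F ≤ 0, reported as F = 0, p = 1.  A
    zero-PRESS (perfect) model is degenerate: F is capped at 1/eps.
    """
    y, _ = _encode_labels(labels)
    yhat = np.asarray(yhat_cv, dtype=float)
    press = float(((y - yhat) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    d1 = n_components
    d2 = len(y) - 1 - n_components
    if d2 <= 0:
        raise ValueError("too few samples for CV-ANOVA degrees of freedom")
    if press == 0.0:
        f_stat = 1.0 / np.finfo(float).eps
        return f_stat, float(stats.f.sf(f_stat, d1, d2))
    f_stat = ((tss - press) / d1) / (press / d2)
    if f_stat <= 0:
        return 0.0, 1.0
    return float(f_stat), float(stats.f.sf(f_stat, d1, d2))


def permutation_test(matrix, labels, n_orthogonal: int = 0,
                     n_permutations: int = 100, seed: int = 0,
                     folds="auto", scaling: str = "unit_variance") -> dict:
    """Label-permutation null for R²Y and Q².

    The class labels are permuted, the model refit (same component count
    and fold scheme), and the add-one rule applied:
    ``p = (1 + #{permuted ≥ observed}) / (1 + n_permutations)``.  A
    permutation that reproduces the original labels still counts.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    df = _as_frame(matrix)
    labels_arr = np.asarray(labels)
    ss = np.random.SeedSequence(seed)
    fold_seed = int(ss.generate_state(1)[0] % (2 ** 31))
    rng = np.random.default_rng(ss.spawn(1)[0])

    obs_model = fit_oplsda(df, labels_arr, n_orthogonal, scaling)
    obs_q2, _, k = cross_validate(df, labels_arr, n_orthogonal, folds, fold_seed, scaling)

    null_r2y = np.empty(n_permutations)
    null_q2 = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(len(labels_arr))
        lab_b = labels_arr[perm]
        null_r2y[b] = fit_oplsda(df, lab_b, n_orthogonal, scaling).r2y
        null_q2[b], _, _ = cross_validate(df, lab_b, n_orthogonal, folds,
                                          fold_seed, scaling)
    p_r2y = (1 + int((null_r2y >= obs_model.r2y).sum())) / (1 + n_permutations)
    p_q2 = (1 + int((null_q2 >= obs_q2).sum())) / (1 + n_permutations)
    return {
        "r2y": obs_model.r2y, "q2": obs_q2, "n_folds": k,
        "p_r2y": p_r2y, "p_q2": p_q2,
        "null_r2y": null_r2y, "null_q2": null_q2,
    }


def choose_n_orthogonal(matrix, labels, k_max: int = 3, folds="auto",
                        seed: int = 0, tol: float = 0.01,
                        scaling: str = "unit_variance") -> int:
    """Greedy choice of the orthogonal component count.

    Starts at 0 and adds orthogonal components while cross-validated Q²
    improves by more than ``tol``; stops at ``k_max`` or when the
    orthogonal subspace is exhausted.
    """
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    best_q2, _, _ = cross_validate(matrix, labels, 0, folds, seed, scaling)
    chosen = 0
    for k in range(1, k_max + 1):
        try:
            q2_k, _, _ = cross_validate(matrix, labels, k, folds, seed, scaling)
        except ValueError:
            break
        if q2_k > best_q2 + tol:
            best_q2, chosen = q2_k, k
        else:
            break
    return chosen


def validate_oplsda(matrix, labels, n_orthogonal: int | str = "auto",
                    folds="auto", n_permutations: int = 100, seed: int = 0,
                    k_max: int = 3, scaling: str = "unit_variance") -> OplsDaModel:
    """Fit + cross-validate + CV-ANOVA + permutation test in one call."""
    ss = np.random.SeedSequence(seed)
    s_choice, s_cv, s_perm = [int(s.generate_state(1)[0] % (2 ** 31))
                              for s in ss.spawn(3)]
    if n_orthogonal == "auto":
        n_orthogonal = choose_n_orthogonal(matrix, labels, k_max, folds,
                                           s_choice, scaling=scaling)
    model = fit_oplsda(matrix, labels, n_orthogonal, scaling)
    q2, yhat_cv, k = cross_validate(matrix, labels, n_orthogonal, folds, s_cv, scaling)
    f_stat, p_cv = cv_anova(yhat_cv, labels, n_components=1 + n_orthogonal)
    perm = permutation_test(matrix, labels, n_orthogonal, n_permutations,
                            s_perm, folds, scaling)
    model.q2 = q2
    model.n_folds = k
    model.cv_anova_F = f_stat
    model.cv_anova_p = p_cv
    model.permutation_p_q2 = perm["p_q2"]
    model.permutation_p_r2y = perm["p_r2y"]
    model.n_permutations = n_permutations
    return model
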