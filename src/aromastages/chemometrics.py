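"""From-scratch PCA and two-class OPLS-DA with VIP scores.

OPLS-DA follows the orthogonal-signal-correction factorization: the
predictor matrix is split into one class-predictive component and
``n_ortho`` components orthogonal to the class response. Removing the
orthogonal variation first concentrates between-class variation in a
single predictive score, which is what makes the per-variable VIP
ranking interpretable.

Everything here is deterministic: no random initialization, a fixed
sign convention (the largest-magnitude element of every weight vector
is positive), and seeded, stratified cross-validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datamodel import AbundanceTable, ValidationError

__all__ = [
    "ScaledMatrix",
    "PCAModel",
    "OPLSDAModel",
    "PermutationRecord",
    "autoscale",
    "fit_pca",
    "fit_oplsda",
    "vip_scores",
    "cross_validate_q2",
    "permutation_test",
]


@dataclass
class ScaledMatrix:
    """Column-centered (and optionally scaled) data matrix.

    Modes: ``center`` (mean only), ``unit_variance`` (autoscaling,
    the default for metabolomics peak tables), ``pareto`` (sqrt-sd
    scaling, compromise between the two). Constant columns get scale 1
    and are flagged rather than dropped.
    """

    X: np.ndarray
    sample_ids: list[str]
    var_ids: list[str]
    col_means: np.ndarray
    col_scales: np.ndarray
    mode: str
    constant_mask: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_vars(self) -> int:
        return self.X.shape[1]

    def rows(self, idx: Sequence[int]) -> np.ndarray:
        return self.X[np.asarray(idx, dtype=int)]


_MODES = ("center", "unit_variance", "pareto")


def autoscale(
    table: Union[AbundanceTable, pd.DataFrame, np.ndarray],
    mode: str = "unit_variance",
) -> ScaledMatrix:
    """Center each column; scale by sd (unit_variance) or sqrt(sd) (pareto)."""
    if mode not in _MODES:
        raise ValidationError(f"unknown scaling mode {mode!r}; pick from {_MODES}")
    if isinstance(table, AbundanceTable):
        df = table.values
    elif isinstance(table, pd.DataFrame):
        df = table
    else:
        arr = np.asarray(table, dtype=float)
        df = pd.DataFrame(arr,
                          index=[f"s{i}" for i in range(arr.shape[0])],
                          columns=[f"v{j}" for j in range(arr.shape[1])])
    X = df.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("scaling needs at least 2 samples")
    means = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd: two points (0, 2) scale to (-1, 1)
    # float-tolerant constant detection: a column of repeated 4.2 can have
    # sd ~ 1e-15 from the mean subtraction alone
    constant = sd <= 100 * np.finfo(float).eps * np.maximum(1.0, np.abs(means))
    if mode == "center":
        scales = np.ones_like(sd)
    elif mode == "unit_variance":
        scales = np.where(constant, 1.0, sd)
    else:  # pareto
        scales = np.where(constant, 1.0, np.sqrt(sd))
    Xs = (X - means) / scales
    return ScaledMatrix(
        X=Xs,
        sample_ids=list(df.index.astype(str)),
        var_ids=list(df.columns.astype(str)),
        col_means=means,
        col_scales=scales,
        mode=mode,
        constant_mask=constant,
    )


@dataclass
class PCAModel:
    scores: np.ndarray            # n_samples × k
    loadings: np.ndarray          # n_vars × k, orthonormal columns
    explained_variance_ratio: np.ndarray
    sample_ids: list[str]
    var_ids: list[str]

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.loadings.T


def fit_pca(X: ScaledMatrix, n_components: int) -> PCAModel:
    """SVD-based PCA on an already-scaled matrix.

    Sign convention: the largest-|value| element of each loading vector
    is made positive, so scores are reproducible across platforms.
    """
    max_k = min(X.n_samples - 1, X.n_vars)
    if not 1 <= n_components <= max_k:
        raise ValidationError(
            f"n_components must be in [1, {max_k}], got {n_components}")
    U, s, Vt = np.linalg.svd(X.X, full_matrices=False)
    k = n_components
    loadings = Vt[:k].T
    scores = U[:, :k] * s[:k]
    total = float((X.X ** 2).sum())
    ratios = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    for a in range(k):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1.0
            scores[:, a] *= -1.0
    return PCAModel(scores=scores, loadings=loadings,
                    explained_variance_ratio=ratios,
                    sample_ids=list(X.sample_ids), var_ids=list(X.var_ids))


@dataclass
class PermutationRecord:
    """Label-permutation validation record (all values kept for plotting)."""

    n_perm: int
    r2y_observed: float
    q2_observed: float
    r2y_permuted: list[float]
    q2_permuted: list[float]
    p_value_q2: float


@dataclass
class OPLSDAModel:
    """Fitted two-class OPLS-DA with one predictive component."""

    classes: tuple          # (class_a, class_b); positive scores = class_b
    w_pred: np.ndarray      # predictive weights, unit norm
    t_pred: np.ndarray      # predictive scores
    p_pred: np.ndarray      # predictive loadings
    c_pred: float           # y-loading of the predictive score
    w_ortho: np.ndarray     # n_ortho × n_vars, unit norm rows
    t_ortho: np.ndarray     # n_samples × n_ortho
    p_ortho: np.ndarray     # n_ortho × n_vars
    y_centered: np.ndarray
    y_mean: float
    r2x: float
    r2y: float
    vip: np.ndarray
    var_ids: list[str]
    sample_ids: list[str]
    q2: Optional[float] = None
    permutation: Optional[PermutationRecord] = None

    @property
    def n_ortho(self) -> int:
        return self.w_ortho.shape[0]

    def predict_scores(self, X_new: np.ndarray) -> np.ndarray:
        """Orthogonal-filter new rows, then project on the predictive weight."""
        Xf = np.array(X_new, dtype=float, copy=True)
        for a in range(self.n_ortho):
            t_o = Xf @ self.w_ortho[a]
            Xf -= np.outer(t_o, self.p_ortho[a])
        return Xf @ self.w_pred

    def predict_y(self, X_new: np.ndarray) -> np.ndarray:
        """Predicted response on the centered 0/1 scale."""
        return self.predict_scores(X_new) * self.c_pred

    def vip_table(self) -> pd.DataFrame:
        return pd.DataFrame({"compound_id": self.var_ids, "vip": self.vip})


def _encode_y(y: Sequence) -> tuple[np.ndarray, tuple]:
    y_arr = np.asarray(y)
    classes = sorted(set(y_arr.tolist()), key=str)
    if len(classes) != 2:
        raise ValidationError(
            f"OPLS-DA needs exactly 2 classes, got {len(classes)}")
    y01 = (y_arr == classes[1]).astype(float)
    return y01, tuple(classes)


def _fix_sign(w: np.ndarray) -> float:
    """Return +1/-1 so the largest-|value| element of w becomes positive."""
    j = int(np.argmax(np.abs(w)))
    return -1.0 if w[j] < 0 else 1.0


def fit_oplsda(
    X: ScaledMatrix,
    y: Sequence,
    n_ortho: int = 1,
) -> OPLSDAModel:
    """Fit a two-class OPLS-DA (1 predictive + n_ortho orthogonal comps).

    Per orthogonal round: project the current matrix on the predictive
    weight, take the loading p of that score, remove its y-predictive
    part to get the orthogonal weight w_o ∝ p − (w'p)w, and deflate the
    matrix by t_o p_o'. The final predictive component is fit on the
    orthogonality-filtered matrix. With ``n_ortho=0`` this is exactly a
    one-component PLS1 fit.
    """
    if n_ortho < 0:
        raise ValidationError("n_ortho must be >= 0")
    y01, classes = _encode_y(y)
    if len(y01) != X.n_samples:
        raise ValidationError("y length does not match the matrix rows")
    rank = int(np.linalg.matrix_rank(X.X))
    if n_ortho >= rank:
        raise ValidationError(
            f"n_ortho={n_ortho} must be < rank(X)={rank}")
    y_mean = float(y01.mean())
    yc = y01 - y_mean
    ss_y = float(yc @ yc)
    if ss_y == 0.0:
        raise ValidationError("response has a single class")

    Xf = X.X.copy()
    ss_x_total = float((Xf ** 2).sum())

    w = Xf.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0.0:
        raise ValidationError("response is orthogonal to every predictor")
    w /= norm

    w_os, t_os, p_os = [], [], []
    ss_x_ortho = 0.0
    for _ in range(n_ortho):
        t = Xf @ w
        p = (Xf.T @ t) / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:
            raise ValidationError(
                "no orthogonal variation left; reduce n_ortho")
        w_o /= n_o
        w_o *= _fix_sign(w_o)
        t_o = Xf @ w_o
        p_o = (Xf.T @ t_o) / (t_o @ t_o)
        Xf = Xf - np.outer(t_o, p_o)
        ss_x_ortho += float((t_o @ t_o) * (p_o @ p_o))
        w_os.append(w_o)
        t_os.append(t_o)
        p_os.append(p_o)
        # re-derive the predictive direction on the filtered matrix
        w = Xf.T @ yc
        w /= np.linalg.norm(w)

    # orient the predictive component by the response: positive scores
    # mean the second class (later stage), so label swap negates scores
    t = Xf @ w
    if (t @ yc) < 0:
        w = -w
        t = -t
    p = (Xf.T @ t) / (t @ t)
    c = float((yc @ t) / (t @ t))

    ss_x_pred = float((t @ t) * (p @ p))
    r2x = (ss_x_pred + ss_x_ortho) / ss_x_total if ss_x_total > 0 else 0.0
    resid_y = yc - t * c
    r2y = 1.0 - float(resid_y @ resid_y) / ss_y

    w_ortho = np.array(w_os) if w_os else np.empty((0, X.n_vars))
    t_ortho = np.array(t_os).T if t_os else np.empty((X.n_samples, 0))
    p_ortho = np.array(p_os) if p_os else np.empty((0, X.n_vars))

    model = OPLSDAModel(
        classes=classes, w_pred=w, t_pred=t, p_pred=p, c_pred=c,
        w_ortho=w_ortho, t_ortho=t_ortho, p_ortho=p_ortho,
        y_centered=yc, y_mean=y_mean, r2x=r2x, r2y=r2y,
        vip=np.empty(0), var_ids=list(X.var_ids),
        sample_ids=list(X.sample_ids),
    )
    model.vip = vip_scores(model)
    return model


def vip_scores(model: OPLSDAModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p · Σ_a SSY_a (w_aj / ‖w_a‖)² / Σ_a SSY_a )

    summed over the model's components (predictive + orthogonal), with
    SSY_a the response sum of squares explained by component a. The
    orthogonal components explain ≈ 0 of the response by construction,
    so the ranking is driven by the predictive weights; the
    normalization guarantees mean(VIP²) = 1.
    """
    if model.w_pred.size == 0:
        raise ValidationError("model is not fitted")
    n_vars = len(model.var_ids)
    weights = [model.w_pred] + [model.w_ortho[a] for a in range(model.n_ortho)]
    scores = [model.t_pred] + [model.t_ortho[:, a] for a in range(model.n_ortho)]
    yc = model.y_centered
    ssy = []
    for t in scores:
        tt = float(t @ t)
        ssy.append((float(t @ yc) ** 2) / tt if tt > 0 else 0.0)
    total = sum(ssy)
    if total <= 0:
        raise ValidationError("model explains none of the response")
    acc = np.zeros(n_vars)
    for w, s in zip(weights, ssy):
        wn = w / np.linalg.norm(w)
        acc += s * wn ** 2
    return np.sqrt(n_vars * acc / total)


def _stratified_folds(
    y01: np.ndarray, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Deterministic stratified fold assignment (round-robin per class)."""
    rng = np.random.default_rng(seed)
    n = len(y01)
    order = rng.permutation(n)  # one global, label-independent shuffle
    # process classes by first appearance in the shuffled order so the
    # assignment depends only on the class partition, not on which class
    # is coded 0 or 1 (label swap must not change the folds)
    seen: list[float] = []
    for i in order:
        if y01[i] not in seen:
            seen.append(y01[i])
    fold_of = np.empty(n, dtype=int)
    counter = 0
    for cls in seen:
        for i in order:
            if y01[i] == cls:
                fold_of[i] = counter % n_folds
                counter += 1
    return [np.flatnonzero(fold_of == f) for f in range(n_folds)]


def cross_validate_q2(
    X: ScaledMatrix,
    y: Sequence,
    n_ortho: int = 1,
    n_folds: int = 7,
    seed: int = 0,
) -> float:
    """Cross-validated predictive ability Q² = 1 − PRESS / SS_y.

    Folds are stratified by class and deterministic under ``seed``.
    When the sample count is below twice the fold count the split falls
    back to leave-one-out. A fold whose training part loses a class is
    an error (use fewer folds).
    """
    y01, _classes = _encode_y(y)
    n = len(y01)
    if n_folds < 2:
        raise ValidationError("n_folds must be >= 2")
    if n < 2 * n_folds:
        n_folds = n  # leave-one-out
    folds = _stratified_folds(y01, n_folds, seed)
    yc = y01 - y01.mean()
    press = 0.0
    for test_idx in folds:
        if len(test_idx) == 0:
            continue
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        y_train = y01[train_mask]
        if len(set(y_train.tolist())) < 2:
            raise ValidationError(
                "a training fold lost a class; use fewer folds")
        sub = ScaledMatrix(
            X=X.X[train_mask], sample_ids=[], var_ids=list(X.var_ids),
            col_means=X.col_means, col_scales=X.col_scales,
            mode=X.mode, constant_mask=X.constant_mask,
        )
        m = fit_oplsda(sub, y_train, n_ortho=n_ortho)
        # predictions on the centered scale of the training response
        y_hat = m.predict_y(X.X[test_idx]) + m.y_mean
        press += float(((y01[test_idx] - y_hat) ** 2).sum())
    ss = float(yc @ yc)
    return 1.0 - press / ss


def permutation_test(
    X: ScaledMatrix,
    y: Sequence,
    n_ortho: int = 1,
    n_perm: int = 200,
    seed: int = 0,
    n_folds: int = 7,
) -> PermutationRecord:
    """Label-permutation validation of an OPLS-DA model.

    The class labels are shuffled ``n_perm`` times; R²Y and Q² are
    recomputed for each shuffle. The empirical p-value for Q² uses the
    add-one rule, p = (1 + #{Q²_perm ≥ Q²_obs}) / (n_perm + 1), so it
    can never be exactly zero.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    y01, _ = _encode_y(y)
    model = fit_oplsda(X, y01, n_ortho=n_ortho)
    q2_obs = cross_validate_q2(X, y01, n_ortho=n_ortho,
                               n_folds=n_folds, seed=seed)
    rng = np.random.default_rng(seed)
    r2_perm: list[float] = []
    q2_perm: list[float] = []
    for _ in range(n_perm):
        y_p = rng.permutation(y01)
        while len(set(y_p.tolist())) < 2:  # cannot happen for 2-class input
            y_p = rng.permutation(y01)
        m = fit_oplsda(X, y_p, n_ortho=n_ortho)
        r2_perm.append(m.r2y)
        q2_perm.append(cross_validate_q2(X, y_p, n_ortho=n_ortho,
                                         n_folds=n_folds, seed=seed))
    n_ge = sum(1 for q in q2_perm if q >= q2_obs)
    p_val = (1 + n_ge) / (n_perm + 1)
    return PermutationRecord(
        n_perm=n_perm, r2y_observed=model.r2y, q2_observed=q2_obs,
        r2y_permuted=r2_perm, q2_permuted=q2_perm, p_value_q2=p_val,
    )
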