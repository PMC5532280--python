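"""Orthogonal projections to latent structures discriminant analysis (OPLS-DA).

The classifier separates between-class ("predictive") from within-class
("orthogonal") variation in spectra.  For ``C`` classes the model uses
exactly ``C - 1`` predictive components and at most ``C`` orthogonal
components, fit on mean-centered data; class membership is coded as a
dummy response matrix with one column per class.

Algorithm (NIPALS family)
-------------------------
With centered ``X`` (n x m) and centered dummy ``Y`` (n x C):

1. ``W_y`` = orthonormal basis of the columns of ``X'Y`` (the predictive
   weight span).  Deflating by orthogonal components leaves ``X'Y``
   unchanged, because every orthogonal weight is constructed orthogonal to
   this span, so the basis is computed once.
2. For each orthogonal component: take the X-loading ``p`` of a NIPALS PLS
   component of the current (deflated) ``X`` against ``Y``; the orthogonal
   weight is ``w_o = p - W_y (W_y' p)``, normalized.  Scores
   ``t_o = X w_o``, loadings ``p_o = X' t_o / (t_o' t_o)``; deflate
   ``X <- X - t_o p_o'``.
3. Fit an ordinary NIPALS PLS2 model with ``C - 1`` components on the
   filtered ``X``; predictions use ``W* = W (P'W)^-1``.

Unassigned spectra are predicted by the fitted model; a spectrum is
assigned NONE (outlier, not described by the model) when its Hotelling T^2
or its distance-to-model (DModX) exceeds the F-based critical value at
``outlier_alpha``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .core import ValidationError

__all__ = [
    "OplsdaConfig",
    "ModelQuality",
    "PredictionResult",
    "HotellingEllipse",
    "OPLSDA",
    "encode_dummy",
    "fit_oplsda",
    "predict",
    "correlation_scaled_loadings",
    "q2_cross_validation",
    "hotelling_ellipse",
]

NONE_LABEL = "NONE"

_EPS = np.finfo(float).eps


@dataclass
class OplsdaConfig:
    """OPLS-DA settings.  ``n_pred`` is fixed to C - 1 by the class rule."""

    max_ortho: int | None = None  # default: C
    n_ortho: int | str = "auto"
    cv_folds: int = 7
    outlier_alpha: float = 0.05
    ortho_var_min: float = 0.01


@dataclass
class ModelQuality:
    """Explained variance and cross-validated predictive ability."""

    r2x: float
    r2y: float
    q2_cum: float
    folds: int


@dataclass
class PredictionResult:
    """Per-spectrum prediction output of :meth:`OPLSDA.predict_full`."""

    scores: np.ndarray  # (n, n_pred) predictive scores
    ortho_scores: np.ndarray  # (n, n_ortho)
    y_pred: np.ndarray  # (n, C) predicted dummy responses
    labels: np.ndarray  # class name or "NONE" per spectrum
    hotelling_t2: np.ndarray
    dmodx: np.ndarray
    outlier: np.ndarray  # bool


@dataclass
class HotellingEllipse:
    """95% (by default) confidence ellipse of a 2-D scores plot."""

    center: np.ndarray
    semi_axes: np.ndarray  # (2,) lengths, descending
    directions: np.ndarray  # (2, 2) columns = axis directions
    t2_crit: float
    t2: np.ndarray  # per-point T^2


def encode_dummy(labels: np.ndarray, class_names: tuple[str, ...] | list[str]) -> np.ndarray:
    """One-hot dummy response matrix, one column per class, row sums 1."""
    class_names = list(class_names)
    if len(class_names) < 2:
        raise ValidationError("discriminant coding requires at least 2 classes")
    index = {name: j for j, name in enumerate(class_names)}
    Y = np.zeros((len(labels), len(class_names)))
    for i, lab in enumerate(labels):
        if lab not in index:
            raise ValidationError(f"label {lab!r} not among classes {class_names}")
        Y[i, index[lab]] = 1.0
    return Y


def _nipals_component(
    X: np.ndarray, Y: np.ndarray, tol: float = 1e-13, max_iter: int = 1000
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One NIPALS PLS component of centered X against centered Y.

    Returns (w, t, p, c) with unit-norm w.  Deterministic: the score
    iteration starts from the Y column with the largest sum of squares.
    """
    u = Y[:, int(np.argmax((Y**2).sum(axis=0)))].copy()
    w = None
    for _ in range(max_iter):
        w_new = X.T @ u
        nw = np.linalg.norm(w_new)
        if nw < _EPS:
            raise ValidationError("degenerate X (no variance left for a PLS component)")
        w_new /= nw
        t = X @ w_new
        tt = t @ t
        if tt < _EPS:
            raise ValidationError("degenerate PLS score")
        c = Y.T @ t / tt
        converged = w is not None and np.linalg.norm(w_new - w) < tol
        w = w_new
        cc = c @ c
        if converged or cc < _EPS:
            break
        u = Y @ c / cc
    t = X @ w
    p = X.T @ t / (t @ t)
    c = Y.T @ t / (t @ t)
    return w, t, p, c


def _orthonormal_basis(M: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the column space of M (SVD, rank-truncated)."""
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    rank = int(np.sum(s > rtol * (s[0] if s.size else 1.0)))
    return U[:, :rank]


class OPLSDA(BaseEstimator, ClassifierMixin):
    """OPLS-DA classifier for labeled spectra.

    Parameters
    ----------
    n_ortho : int or "auto"
        Number of orthogonal components.  ``"auto"`` extracts up to
        ``max_ortho`` (default: the number of classes C), stopping early
        when a component explains less than ``ortho_var_min`` of the X
        variance or when the cross-validated Q2 decreases.
    cv_folds : int
        Folds of the deterministic interleaved cross-validation used for
        Q2(cum); quality is skipped when there are fewer samples than folds.
    outlier_alpha : float
        Significance level of the T^2 / DModX outlier (NONE) tests.
    classes : sequence of str, optional
        Explicit class order; default is the sorted unique labels.

    Fitted attributes use the trailing-underscore convention; predictive
    quantities are ``W_``, ``P_``, ``C_y_``, ``T_`` and orthogonal ones
    ``W_o_``, ``P_o_``, ``T_o_``.
    """

    def __init__(
        self,
        n_ortho: int | str = "auto",
        max_ortho: int | None = None,
        cv_folds: int = 7,
        outlier_alpha: float = 0.05,
        ortho_var_min: float = 0.01,
        classes: tuple[str, ...] | None = None,
    ):
        self.n_ortho = n_ortho
        self.max_ortho = max_ortho
        self.cv_folds = cv_folds
        self.outlier_alpha = outlier_alpha
        self.ortho_var_min = ortho_var_min
        self.classes = classes

    # ------------------------------------------------------------------
    # fitting
    # ------------------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OPLSDA":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValidationError("X must be 2-D (spectra x bands)")
        if self.classes is not None:
            classes = list(self.classes)
            unknown = set(np.unique(y)) - set(classes)
            if unknown:
                raise ValidationError(f"labels {sorted(unknown)} not in classes {classes}")
        else:
            classes = [str(c) for c in np.unique(y)]
        C = len(classes)
        if C < 2:
            raise ValidationError("OPLS-DA requires at least 2 classes")
        n, m = X.shape
        n_pred = C - 1
        if n <= C or m < C:
            raise ValidationError(
                f"need more than C={C} spectra and at least C bands, got n={n}, m={m}"
            )
        if np.allclose(X.var(axis=0), 0):
            raise ValidationError("degenerate X: zero variance in every band")

        self.classes_ = np.asarray(classes, dtype=object)
        self.n_pred_ = n_pred
        max_ortho = C if self.max_ortho is None else int(self.max_ortho)

        Yd = encode_dummy([str(v) for v in y], classes)
        self._labels_str = np.asarray([str(v) for v in y], dtype=object)

        if isinstance(self.n_ortho, str) and self.n_ortho == "auto":
            counts = self._candidate_ortho_counts(X, Yd, max_ortho)
            chosen = counts[0]
            if len(counts) > 1 and n >= self.cv_folds:
                best_q2 = -np.inf
                for k in counts:
                    q2 = self._cv_q2(X, self._labels_str, k)
                    if q2 is None or q2 < best_q2:
                        break
                    best_q2 = q2
                    chosen = k
            elif len(counts) > 1:
                chosen = counts[-1]
            n_ortho = chosen
        else:
            n_ortho = int(self.n_ortho)
            if n_ortho > max_ortho:
                raise ValidationError(f"n_ortho={n_ortho} exceeds max_ortho={max_ortho}")
        self._fit_fixed(X, Yd, n_ortho)

        # cross-validated quality (skipped on very small training sets)
        if n >= self.cv_folds:
            q2 = self._cv_q2(X, self._labels_str, self.n_ortho_)
            self.quality_ = ModelQuality(
                r2x=self.r2x_, r2y=self.r2y_, q2_cum=q2 if q2 is not None else np.nan,
                folds=self.cv_folds,
            )
        else:
            self.quality_ = None
        return self

    def _candidate_ortho_counts(self, X: np.ndarray, Yd: np.ndarray, max_ortho: int) -> list[int]:
        """Orthogonal-component counts surviving the variance rule (0..k)."""
        Xc = X - X.mean(axis=0)
        Yc = Yd - Yd.mean(axis=0)
        ssx = np.sum(Xc**2)
        Wy = _orthonormal_basis(Xc.T @ Yc)
        counts = [0]
        Xd = Xc.copy()
        for _ in range(max_ortho):
            try:
                _, _, p, _ = _nipals_component(Xd, Yc)
            except ValidationError:
                break
            w_o = p - Wy @ (Wy.T @ p)
            nw = np.linalg.norm(w_o)
            if nw < 1e-10 * max(np.linalg.norm(p), 1.0):
                break
            w_o /= nw
            t_o = Xd @ w_o
            tt = t_o @ t_o
            if tt < _EPS:
                break
            p_o = Xd.T @ t_o / tt
            if tt * (p_o @ p_o) < self.ortho_var_min * ssx:
                break
            Xd = Xd - np.outer(t_o, p_o)
            counts.append(counts[-1] + 1)
        return counts

    def _fit_fixed(self, X: np.ndarray, Yd: np.ndarray, n_ortho: int) -> None:
        """Core fit with a fixed orthogonal-component count."""
        n, m = X.shape
        C = Yd.shape[1]
        n_pred = C - 1
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Yd.mean(axis=0)
        Xc = X - self.x_mean_
        Yc = Yd - self.y_mean_
        ssx = np.sum(Xc**2)
        ssy = np.sum(Yc**2)

        Wy = _orthonormal_basis(Xc.T @ Yc)
        W_o = np.zeros((m, 0))
        P_o = np.zeros((m, 0))
        T_o = np.zeros((n, 0))
        Xd = Xc.copy()
        for _ in range(n_ortho):
            try:
                _, _, p, _ = _nipals_component(Xd, Yc)
            except ValidationError:
                break
            w_o = p - Wy @ (Wy.T @ p)
            nw = np.linalg.norm(w_o)
            if nw < 1e-10 * max(np.linalg.norm(p), 1.0):
                break
            w_o /= nw
            t_o = Xd @ w_o
            tt = t_o @ t_o
            if tt < _EPS:
                break
            p_o = Xd.T @ t_o / tt
            Xd = Xd - np.outer(t_o, p_o)
            W_o = np.hstack([W_o, w_o[:, None]])
            P_o = np.hstack([P_o, p_o[:, None]])
            T_o = np.hstack([T_o, t_o[:, None]])
        self.W_o_, self.P_o_, self.T_o_ = W_o, P_o, T_o
        self.n_ortho_ = W_o.shape[1]

        # predictive PLS2 with exactly C-1 components on the filtered X
        W = np.zeros((m, 0))
        P = np.zeros((m, 0))
        Cy = np.zeros((C, 0))
        T = np.zeros((n, 0))
        Xp = Xd.copy()
        for _ in range(n_pred):
            w, t, p, c = _nipals_component(Xp, Yc)
            Xp = Xp - np.outer(t, p)
            W = np.hstack([W, w[:, None]])
            P = np.hstack([P, p[:, None]])
            Cy = np.hstack([Cy, c[:, None]])
            T = np.hstack([T, t[:, None]])
        self.W_, self.P_, self.C_y_, self.T_ = W, P, Cy, T
        self.Wstar_ = W @ np.linalg.inv(P.T @ W)

        # training residuals and diagnostics reference quantities
        E = Xp  # = Xc - T_o P_o' - T P'
        a_tot = self.n_ortho_ + n_pred
        self.score_var_ = np.concatenate(
            [T.var(axis=0, ddof=1), T_o.var(axis=0, ddof=1)]
        )
        dof = max((n - a_tot - 1) * (m - a_tot), 1)
        self.residual_sd_ = float(np.sqrt(np.sum(E**2) / dof))
        self.n_train_ = n
        self.n_bands_ = m
        # training DModX distribution, used to calibrate the outlier cut-off
        s_obs = np.sqrt(np.sum(E**2, axis=1) / max(m - a_tot, 1))
        if self.residual_sd_ > 0:
            self.train_dmodx_ = s_obs / self.residual_sd_
        else:
            self.train_dmodx_ = np.zeros(n)

        Yhat = T @ Cy.T
        self.r2y_ = float(1.0 - np.sum((Yc - Yhat) ** 2) / ssy)
        self.r2x_ = float(1.0 - np.sum(E**2) / ssx) if ssx > 0 else 0.0

    # ------------------------------------------------------------------
    # prediction
    # ------------------------------------------------------------------

    def _filter_and_score(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Remove orthogonal variation, return (T, T_o, residual E)."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_bands_:
            raise ValidationError(
                f"band count {X.shape[1]} does not match the model's {self.n_bands_}"
            )
        Xc = X - self.x_mean_
        T_o = np.zeros((X.shape[0], self.n_ortho_))
        for j in range(self.n_ortho_):
            t_o = Xc @ self.W_o_[:, j]
            T_o[:, j] = t_o
            Xc = Xc - np.outer(t_o, self.P_o_[:, j])
        T = Xc @ self.Wstar_
        E = Xc - T @ self.P_.T
        return T, T_o, E

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Predicted dummy responses (n x C)."""
        T, _, _ = self._filter_and_score(X)
        return T @ self.C_y_.T + self.y_mean_

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Predictive scores (n x n_pred)."""
        return self._filter_and_score(X)[0]

    def t2_crit(self, alpha: float | None = None) -> float:
        a = self.n_pred_ + self.n_ortho_
        n = self.n_train_
        alpha = self.outlier_alpha if alpha is None else alpha
        if n - a <= 0:
            return np.inf
        return a * (n - 1) / (n - a) * stats.f.ppf(1 - alpha, a, n - a)

    def dmodx_crit(self, alpha: float | None = None) -> float:
        """Distance-to-model cut-off at significance ``alpha``.

        The F-based variance-ratio value is floored against the empirical
        (1 - alpha) quantile of the training DModX distribution: spectral
        residuals of real (and realistically simulated) tissue are heavier
        tailed than the iid-Gaussian F assumption, which would otherwise
        flag a large fraction of perfectly ordinary tissue pixels.
        """
        a = self.n_pred_ + self.n_ortho_
        n, m = self.n_train_, self.n_bands_
        alpha = self.outlier_alpha if alpha is None else alpha
        d1 = max(m - a, 1)
        d2 = max((n - a - 1) * (m - a), 1)
        f_crit = float(np.sqrt(stats.f.ppf(1 - alpha, d1, d2)))
        emp = float(np.quantile(self.train_dmodx_, 1 - alpha)) if self.train_dmodx_.size else 0.0
        return max(f_crit, emp)

    def predict_full(self, X: np.ndarray) -> PredictionResult:
        """Classify spectra, flagging outliers as NONE.

        A spectrum is NONE when its Hotelling T^2 over all model components
        or its distance-to-model (DModX, residual standard deviation
        relative to the training residual) exceeds its critical value.
        The two component tests are Bonferroni-split (each at
        ``outlier_alpha / 2``) so the union NONE test has overall size
        ``outlier_alpha``.
        """
        T, T_o, E = self._filter_and_score(X)
        y_pred = T @ self.C_y_.T + self.y_mean_
        idx = np.argmax(y_pred, axis=1)
        ties = (y_pred == y_pred[np.arange(len(idx)), idx][:, None]).sum(axis=1) > 1
        if ties.any():
            warnings.warn(
                f"{int(ties.sum())} spectra had tied class responses; "
                "assigned to the lower class index",
                stacklevel=2,
            )
        labels = self.classes_[idx].astype(object)

        scores_all = np.hstack([T, T_o])
        var = np.where(self.score_var_ > 0, self.score_var_, np.inf)
        t2 = np.sum(scores_all**2 / var, axis=1)
        a = self.n_pred_ + self.n_ortho_
        s_obs = np.sqrt(np.sum(E**2, axis=1) / max(self.n_bands_ - a, 1))
        dmodx = s_obs / self.residual_sd_ if self.residual_sd_ > 0 else np.where(s_obs > 0, np.inf, 0.0)
        half = self.outlier_alpha / 2.0
        outlier = (t2 > self.t2_crit(half)) | (dmodx > self.dmodx_crit(half))
        labels[outlier] = NONE_LABEL
        return PredictionResult(
            scores=T,
            ortho_scores=T_o,
            y_pred=y_pred,
            labels=np.asarray(labels, dtype=object),
            hotelling_t2=t2,
            dmodx=dmodx,
            outlier=outlier,
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Plain argmax class prediction (no outlier handling)."""
        y_pred = self.decision_function(X)
        return self.classes_[np.argmax(y_pred, axis=1)]

    # ------------------------------------------------------------------
    # quality / cross-validation
    # ------------------------------------------------------------------

    def _cv_q2(self, X: np.ndarray, labels: np.ndarray, n_ortho: int) -> float | None:
        try:
            return _q2(X, labels, list(self.classes_), self.cv_folds, n_ortho)
        except ValidationError:
            return None

    # ------------------------------------------------------------------
    # serialization (HDF5 container support)
    # ------------------------------------------------------------------

    _ARRAY_FIELDS = (
        "x_mean_", "y_mean_", "W_", "P_", "C_y_", "T_", "W_o_", "P_o_", "T_o_",
        "Wstar_", "score_var_", "train_dmodx_",
    )

    def _to_arrays(self) -> dict:
        out: dict = {k: getattr(self, k) for k in self._ARRAY_FIELDS}
        out["classes"] = np.asarray([str(c) for c in self.classes_], dtype="S")
        out["residual_sd"] = float(self.residual_sd_)
        out["n_train"] = int(self.n_train_)
        out["n_bands"] = int(self.n_bands_)
        out["n_pred"] = int(self.n_pred_)
        out["n_ortho"] = int(self.n_ortho_)
        out["outlier_alpha"] = float(self.outlier_alpha)
        out["r2x"] = float(self.r2x_)
        out["r2y"] = float(self.r2y_)
        q = getattr(self, "quality_", None)
        out["q2_cum"] = float(q.q2_cum) if q is not None else np.nan
        out["cv_folds"] = int(self.cv_folds)
        return out

    @classmethod
    def _from_arrays(cls, arrays: dict) -> "OPLSDA":
        model = cls(outlier_alpha=float(arrays["outlier_alpha"]), cv_folds=int(arrays["cv_folds"]))
        for k in cls._ARRAY_FIELDS:
            setattr(model, k, np.asarray(arrays[k]))
        model.classes_ = np.asarray([c.decode() if isinstance(c, bytes) else str(c)
                                     for c in arrays["classes"]], dtype=object)
        model.residual_sd_ = float(arrays["residual_sd"])
        model.n_train_ = int(arrays["n_train"])
        model.n_bands_ = int(arrays["n_bands"])
        model.n_pred_ = int(arrays["n_pred"])
        model.n_ortho_ = int(arrays["n_ortho"])
        model.r2x_ = float(arrays["r2x"])
        model.r2y_ = float(arrays["r2y"])
        q2 = float(arrays["q2_cum"])
        model.quality_ = ModelQuality(model.r2x_, model.r2y_, q2, int(arrays["cv_folds"]))
        return model


# ---------------------------------------------------------------------------
# module-level functional API
# ---------------------------------------------------------------------------


def fit_oplsda(
    X: np.ndarray,
    labels: np.ndarray,
    config: OplsdaConfig | None = None,
    class_names: tuple[str, ...] | None = None,
) -> OPLSDA:
    cfg = config or OplsdaConfig()
    model = OPLSDA(
        n_ortho=cfg.n_ortho,
        max_ortho=cfg.max_ortho,
        cv_folds=cfg.cv_folds,
        outlier_alpha=cfg.outlier_alpha,
        ortho_var_min=cfg.ortho_var_min,
        classes=class_names,
    )
    return model.fit(X, labels)


def predict(model: OPLSDA, X_new: np.ndarray) -> PredictionResult:
    return model.predict_full(X_new)


def correlation_scaled_loadings(model: OPLSDA, X_train: np.ndarray) -> np.ndarray:
    """p(corr): Pearson correlation of each centered band with each
    predictive score, shape (n_pred, n_bands), values in [-1, 1].

    Bands with positive p(corr) are more intensive in the classes on the
    positive side of that predictive score.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    Xc = X_train - model.x_mean_
    T = model.T_
    out = np.zeros((T.shape[1], Xc.shape[1]))
    band_sd = Xc.std(axis=0)
    zero = band_sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance bands; p(corr) set to 0", stacklevel=2)
    for k in range(T.shape[1]):
        t = T[:, k]
        t_sd = t.std()
        if t_sd == 0:
            continue
        cov = (Xc * (t - t.mean())[:, None]).mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / (band_sd * t_sd)
        r[zero] = 0.0
        out[k] = np.clip(r, -1.0, 1.0)
    return out


def _q2(
    X: np.ndarray,
    labels: np.ndarray,
    class_names: list[str],
    folds: int,
    n_ortho: int,
) -> float:
    """Q2(cum) by deterministic interleaved cross-validation."""
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    n = X.shape[0]
    if n < folds:
        raise ValidationError(f"need at least {folds} samples for {folds}-fold CV, got {n}")
    Y = encode_dummy([str(v) for v in labels], class_names)
    fold_id = np.arange(n) % folds
    press = 0.0
    for f in range(folds):
        test = fold_id == f
        train = ~test
        train_labels = labels[train]
        missing = set(class_names) - {str(v) for v in train_labels}
        if missing:
            raise ValidationError(
                f"fold {f} removes all spectra of class(es) {sorted(missing)}; "
                "cannot refit"
            )
        sub = OPLSDA(n_ortho=n_ortho, classes=tuple(class_names))
        Ytr = encode_dummy([str(v) for v in train_labels], class_names)
        sub.classes_ = np.asarray(class_names, dtype=object)
        sub.n_pred_ = len(class_names) - 1
        sub._fit_fixed(X[train], Ytr, n_ortho)
        y_hat = sub.decision_function(X[test])
        press += float(np.sum((Y[test] - y_hat) ** 2))
    ss_y = float(np.sum((Y - Y.mean(axis=0)) ** 2))
    return 1.0 - press / ss_y


def q2_cross_validation(
    X: np.ndarray,
    labels: np.ndarray,
    config: OplsdaConfig | None = None,
    class_names: tuple[str, ...] | None = None,
) -> ModelQuality:
    """Fit the model and report R2X, R2Y and cross-validated Q2(cum)."""
    model = fit_oplsda(X, labels, config=config, class_names=class_names)
    cfg = config or OplsdaConfig()
    q2 = _q2(X, np.asarray(labels), list(model.classes_), cfg.cv_folds, model.n_ortho_)
    return ModelQuality(r2x=model.r2x_, r2y=model.r2y_, q2_cum=q2, folds=cfg.cv_folds)


def hotelling_ellipse(T: np.ndarray, alpha: float = 0.05) -> HotellingEllipse:
    """Hotelling T^2 confidence ellipse for a 2-D scores plot.

    The boundary is at ``T2_crit = 2 (n-1) / (n-2) * F_(1-alpha)(2, n-2)``;
    the axes lie along the eigenvectors of the score covariance with
    semi-axis lengths ``sqrt(T2_crit * eigenvalue)``.
    """
    T = np.asarray(T, dtype=np.float64)
    if T.ndim != 2 or T.shape[1] != 2:
        raise ValidationError("hotelling_ellipse expects an (n, 2) scores matrix")
    n = T.shape[0]
    if n < 4:
        raise ValidationError("need at least 4 points for a T^2 ellipse")
    center = T.mean(axis=0)
    cov = np.cov(T, rowvar=False)
    if np.linalg.matrix_rank(cov) < 2 or np.linalg.det(cov) <= 0:
        raise ValidationError("singular score covariance; ellipse undefined")
    t2_crit = 2.0 * (n - 1) / (n - 2) * stats.f.ppf(1 - alpha, 2, n - 2)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    diff = T - center
    t2 = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)
    return HotellingEllipse(
        center=center,
        semi_axes=np.sqrt(t2_crit * evals),
        directions=evecs,
        t2_crit=float(t2_crit),
        t2=t2,
    )
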