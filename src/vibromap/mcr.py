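"""Multivariate Curve Resolution - Alternating Least Squares (MCR-ALS).

Bilinear decomposition of a mixture matrix ``D`` (pixels x bands) into
non-negative per-pixel concentrations ``C`` and pure spectral profiles
``S``: ``D ~ C @ S``.  Initial spectral profiles are picked by the
pure-pixel SIMPLISMA variant (iterative purity maximization over rows) and
the factors are refined by alternating exactly-solved non-negative least
squares.  The convergence metric is the lack of fit

    LOF% = 100 * sqrt( sum (D - C S)^2 / sum D^2 )

and iteration stops when the *relative* change in LOF between iterations
drops below ``conv_limit`` percent (default 0.1, the convention of the
canonical MCR-ALS toolbox), when the fit is numerically exact, or after
``max_iter`` iterations (default 50).  Only non-negativity constraints are applied, in
both the concentration and the spectral direction.

Each constrained subproblem is solved exactly (active-set NNLS), which
guarantees a monotonically non-increasing reconstruction error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from .core import ValidationError, VibromapError

__all__ = ["McrAlsConfig", "McrAlsResult", "MCRALS", "simplisma_init", "mcr_als_solve"]

_TINY = np.finfo(float).tiny


@dataclass
class McrAlsConfig:
    """MCR-ALS settings (defaults follow the published workflow)."""

    n_components: int = 2
    conv_limit: float = 0.1
    max_iter: int = 50
    simplisma_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValidationError("n_components must be >= 1")
        if self.conv_limit < 0 or self.max_iter < 1:
            raise ValidationError("conv_limit must be >= 0 and max_iter >= 1")


@dataclass
class McrAlsResult:
    """Resolved profiles and concentrations with the lack-of-fit history."""

    concentrations: np.ndarray  # (n_pixels, k), >= 0
    profiles: np.ndarray  # (k, n_bands), >= 0, rows unit-sum
    lof_history: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0


def simplisma_init(D: np.ndarray, k: int, alpha: float = 0.05) -> np.ndarray:
    """Select ``k`` pure rows of ``D`` by iterative purity maximization.

    The purity of row ``i`` is ``s_i / (m_i + alpha * max(m))`` where ``m``
    and ``s`` are the row mean and standard deviation; after each pick the
    purity is reweighted by the determinant of the Gram matrix of the
    noise-corrected, normalized candidate + selected rows, which deflates
    rows collinear with earlier selections.  Returns the selected rows
    normalized to unit sum.
    """
    D = np.asarray(D, dtype=np.float64)
    if D.ndim != 2:
        raise ValidationError("SIMPLISMA input must be a 2-D matrix")
    n, _ = D.shape
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} outside [1, {n}]")
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    m = D.mean(axis=1)
    s = D.std(axis=1)
    denom = m + alpha * (m.max() if m.max() > 0 else 1.0)
    if np.any(denom <= 0):
        denom = np.where(denom <= 0, np.finfo(float).eps, denom)
    purity = s / denom
    # noise-corrected length normalization (classic SIMPLISMA scaling)
    norms = np.sqrt(m**2 + (s + alpha * (m.max() if m.max() > 0 else 1.0)) ** 2)
    Y = D / norms[:, None]
    selected: list[int] = []
    for _ in range(k):
        weights = np.empty(n)
        for i in range(n):
            rows = Y[selected + [i]]
            gram = rows @ rows.T / D.shape[1]
            weights[i] = np.linalg.det(gram)
        score = purity * weights
        score[selected] = -np.inf
        best = int(np.argmax(score))
        # Y rows are length-normalized, so det(gram) is O(1) for genuinely
        # independent rows and collapses to ~0 for collinear ones
        if selected and (not np.isfinite(score[best]) or weights[best] <= 1e-10):
            raise ValidationError(
                f"SIMPLISMA found no {len(selected) + 1}-th pure direction; "
                "the data matrix is rank-deficient for the requested components"
            )
        selected.append(best)
    profiles = D[selected].astype(np.float64).copy()
    sums = profiles.sum(axis=1)
    if np.any(sums <= 0):
        raise ValidationError("selected pure rows have non-positive total intensity")
    return profiles / sums[:, None]


def _nnls_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||A X - B||_F with X >= 0, column by column (exact)."""
    X = np.empty((A.shape[1], B.shape[1]))
    for j in range(B.shape[1]):
        X[:, j], _ = nnls(A, B[:, j])
    return X


def _lof(D: np.ndarray, C: np.ndarray, S: np.ndarray) -> float:
    resid = D - C @ S
    return 100.0 * float(np.sqrt(np.sum(resid**2) / np.sum(D**2)))


class MCRALS(BaseEstimator, TransformerMixin):
    """MCR-ALS decomposition as a scikit-learn style transformer.

    ``fit(D)`` resolves the profiles; ``transform(D)`` returns non-negative
    concentrations for (possibly new) spectra against the fitted profiles.

    Attributes (after fit)
    ----------------------
    profiles_ : (k, n_bands) non-negative pure spectral profiles, unit-sum.
    concentrations_ : (n_pixels, k) non-negative concentrations.
    lof_history_ : LOF% after each completed iteration.
    converged_, n_iter_ : convergence flag and iteration count.
    """

    def __init__(
        self,
        n_components: int = 2,
        conv_limit: float = 0.1,
        max_iter: int = 50,
        simplisma_alpha: float = 0.05,
        init_profiles: np.ndarray | None = None,
    ):
        self.n_components = n_components
        self.conv_limit = conv_limit
        self.max_iter = max_iter
        self.simplisma_alpha = simplisma_alpha
        self.init_profiles = init_profiles

    def fit(self, X: np.ndarray, y: object = None) -> "MCRALS":
        D = np.asarray(X, dtype=np.float64)
        if D.ndim != 2:
            raise ValidationError("MCR-ALS input must be 2-D (pixels x bands)")
        if not np.any(D):
            raise ValidationError("MCR-ALS input is all zero")
        k = int(self.n_components)
        if k > min(D.shape):
            raise ValidationError(f"n_components={k} exceeds min(D.shape)={min(D.shape)}")
        if self.init_profiles is not None:
            S = np.asarray(self.init_profiles, dtype=np.float64).copy()
            if S.shape != (k, D.shape[1]):
                raise ValidationError(
                    f"init_profiles shape {S.shape} != ({k}, {D.shape[1]})"
                )
        else:
            S = simplisma_init(D, k, self.simplisma_alpha)
        lof_history: list[float] = []
        converged = False
        C = np.zeros((D.shape[0], k))
        for _ in range(int(self.max_iter)):
            C = _nnls_columns(S.T, D.T).T  # min ||S' C' - D'||, per pixel
            S = _nnls_columns(C, D)  # min ||C S - D||, per band
            lof = _lof(D, C, S)
            lof_history.append(lof)
            if lof < 1e-9:  # numerically exact fit
                converged = True
                break
            if len(lof_history) >= 2:
                rel = 100.0 * abs(lof_history[-2] - lof) / max(lof_history[-2], _TINY)
                if rel < self.conv_limit:
                    converged = True
                    break
        row_sums = S.sum(axis=1)
        if np.any(row_sums <= 0):
            import warnings

            warnings.warn("MCR-ALS produced an all-zero profile (rank deficiency)", stacklevel=2)
            row_sums = np.where(row_sums > 0, row_sums, 1.0)
        # fix the scale ambiguity: unit-sum profiles, compensated concentrations
        self.profiles_ = S / row_sums[:, None]
        self.concentrations_ = C * row_sums[None, :]
        self.lof_history_ = lof_history
        self.converged_ = converged
        self.n_iter_ = len(lof_history)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        D = np.asarray(X, dtype=np.float64)
        return _nnls_columns(self.profiles_.T, D.T).T

    def result(self) -> McrAlsResult:
        return McrAlsResult(
            concentrations=self.concentrations_,
            profiles=self.profiles_,
            lof_history=list(self.lof_history_),
            converged=self.converged_,
            n_iter=self.n_iter_,
        )


def mcr_als_solve(
    D: np.ndarray,
    init_profiles: np.ndarray | None = None,
    config: McrAlsConfig | None = None,
) -> McrAlsResult:
    """Functional wrapper around :class:`MCRALS`."""
    cfg = config or McrAlsConfig()
    est = MCRALS(
        n_components=cfg.n_components,
        conv_limit=cfg.conv_limit,
        max_iter=cfg.max_iter,
        simplisma_alpha=cfg.simplisma_alpha,
        init_profiles=init_profiles,
    )
    est.fit(D)
    return est.result()
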