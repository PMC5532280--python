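"""Spectral preprocessing chain for vibrational hyperspectral maps.

The chain reproduces the standard workflow for FT-IR/Raman tissue maps:

``despike -> pca_noise_filter -> trim -> asls_baseline -> savgol -> normalize_total_area``

Despiking and low-rank noise filtering emulate the instrument-side cleanup
applied to Raman maps; the remaining stages are the published chemometric
chain: asymmetric least squares (Whittaker) baseline correction, light
Savitzky-Golay smoothing (1st-order polynomial, frame 5) and total-area
normalization.  Modality presets carry the baseline smoothness values used
for the corresponding sample types:

========================  =========  ==============
preset                    lambda     trim (cm^-1)
========================  =========  ==============
``ftir``                  5 000      950-2000
``raman-dry``             10 000     630-1890
``raman-intact``          1 000 000  630-1890
========================  =========  ==============

All presets use the asymmetry p = 0.01 and Savitzky-Golay frame 5, order 1.

Each stage is exposed both as a scikit-learn style transformer operating on
a ``(n_spectra, n_bands)`` array and as an image-level function that logs
itself into the image metadata history.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy.linalg import solveh_banded
from scipy.signal import savgol_coeffs
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .core import HyperspectralImage, Spectrum, ValidationError, VibromapError

__all__ = [
    "PreprocessConfig",
    "StageError",
    "Despike",
    "PCANoiseFilter",
    "AslsBaseline",
    "SavitzkyGolay",
    "TotalAreaNormalizer",
    "despike",
    "pca_noise_filter",
    "trim",
    "asls_baseline",
    "savgol",
    "normalize_total_area",
    "preprocess",
]


class StageError(VibromapError):
    """A preprocessing stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_PRESETS: dict[str, dict[str, Any]] = {
    "ftir": {"lam": 5_000.0, "trim_lo": 950.0, "trim_hi": 2000.0, "run_despike": False},
    "raman-dry": {"lam": 10_000.0, "trim_lo": 630.0, "trim_hi": 1890.0, "run_despike": True},
    "raman-intact": {"lam": 1_000_000.0, "trim_lo": 630.0, "trim_hi": 1890.0, "run_despike": True},
}


@dataclass
class PreprocessConfig:
    """Parameters of the fixed preprocessing chain.

    ``lam`` is the AsLS smoothness penalty, ``p_asym`` the asymmetry weight
    given to points above the baseline.  ``noise_rank`` is ``None`` (off),
    a positive integer rank, or ``"auto"`` (rank explaining 99% variance).
    Boolean ``run_*`` switches let individual stages be bypassed.
    """

    lam: float = 10_000.0
    p_asym: float = 0.01
    asls_max_iter: int = 50
    asls_tol: float = 1e-6
    sg_frame: int = 5
    sg_order: int = 1
    trim_lo: float | None = None
    trim_hi: float | None = None
    despike_window: int = 5
    despike_z: float = 10.0
    noise_rank: int | str | None = None
    run_despike: bool = True
    run_trim: bool = True
    run_baseline: bool = True
    run_savgol: bool = True
    run_normalize: bool = True
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValidationError("AsLS lambda must be positive")
        if not 0 < self.p_asym < 1:
            raise ValidationError("AsLS asymmetry p must lie in (0, 1)")
        if self.sg_frame < 3 or self.sg_frame % 2 == 0:
            raise ValidationError("Savitzky-Golay frame must be odd and >= 3")
        if not 0 <= self.sg_order < self.sg_frame:
            raise ValidationError("Savitzky-Golay order must satisfy 0 <= order < frame")
        if self.trim_lo is not None and self.trim_hi is not None and self.trim_lo >= self.trim_hi:
            raise ValidationError("trim_lo must be < trim_hi")
        if self.despike_window < 3 or self.despike_window % 2 == 0:
            raise ValidationError("despike window must be odd and >= 3")

    @classmethod
    def preset(cls, name: str, **overrides: Any) -> "PreprocessConfig":
        """Named modality preset: ``ftir``, ``raman-dry`` or ``raman-intact``."""
        if name not in _PRESETS:
            raise ValidationError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
        params = dict(_PRESETS[name])
        params.update(overrides)
        return cls(**params)

    def replace(self, **changes: Any) -> "PreprocessConfig":
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# despiking
# ---------------------------------------------------------------------------


class Despike(BaseEstimator, TransformerMixin):
    """Cosmic-ray removal by modified z-score of the second difference.

    Channels whose second difference has a modified z-score (0.6745 x
    deviation from the median, scaled by the median absolute deviation)
    beyond ``z`` are replaced by the median of the surrounding ``window``,
    excluding flagged channels.  All other values pass through bit-exact.
    """

    def __init__(self, window: int = 5, z: float = 10.0):
        self.window = window
        self.z = z

    def fit(self, X: np.ndarray, y: Any = None) -> "Despike":
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if self.window % 2 == 0 or self.window < 3:
            raise ValidationError("despike window must be odd and >= 3")
        n_bands = X.shape[1]
        if self.window >= n_bands:
            raise ValidationError(
                f"despike window {self.window} must be smaller than n_bands={n_bands}"
            )
        out = X.copy()
        half = self.window // 2
        n_replaced = 0
        d2 = np.diff(X, n=2, axis=1)  # d2[:, i] involves channels i, i+1, i+2
        med = np.median(d2, axis=1, keepdims=True)
        mad = np.median(np.abs(d2 - med), axis=1, keepdims=True)
        # robust fallback for noiseless spectra where the MAD collapses
        scale = np.where(mad > 0, mad, np.mean(np.abs(d2 - med), axis=1, keepdims=True))
        scale = np.where(scale > 0, scale, 1.0)
        zscore = 0.6745 * (d2 - med) / scale
        spike = np.zeros_like(X, dtype=bool)
        spike[:, 1:-1] = np.abs(zscore) > self.z
        for i in np.flatnonzero(spike.any(axis=1)):
            for j in np.flatnonzero(spike[i]):
                lo, hi = max(0, j - half), min(n_bands, j + half + 1)
                keep = ~spike[i, lo:hi]
                if keep.any():
                    out[i, j] = np.median(X[i, lo:hi][keep])
                else:
                    out[i, j] = np.median(X[i, lo:hi])
                n_replaced += 1
        self.n_replaced_ = n_replaced
        self.spike_mask_ = spike
        return out


# ---------------------------------------------------------------------------
# PCA noise filter
# ---------------------------------------------------------------------------


class PCANoiseFilter(BaseEstimator, TransformerMixin):
    """Low-rank (multivariate) noise filter.

    The pixels-by-bands matrix is replaced by its best rank-``rank``
    approximation around the mean spectrum.  ``rank="auto"`` keeps the
    components explaining 99% of the variance.
    """

    def __init__(self, rank: int | str = "auto"):
        self.rank = rank

    def fit(self, X: np.ndarray, y: Any = None) -> "PCANoiseFilter":
        X = np.asarray(X, dtype=np.float64)
        max_rank = min(X.shape)
        if self.rank == "auto":
            pca = PCA(n_components=min(max_rank, X.shape[0] - 1) or 1, svd_solver="full")
            pca.fit(X)
            cum = np.cumsum(pca.explained_variance_ratio_)
            rank = int(np.searchsorted(cum, 0.99) + 1)
        else:
            rank = int(self.rank)
            if not 1 <= rank <= max_rank:
                raise ValidationError(f"noise-filter rank {rank} outside [1, {max_rank}]")
        self.rank_ = rank
        self._pca = PCA(n_components=rank, svd_solver="full").fit(X)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return self._pca.inverse_transform(self._pca.transform(X))


# ---------------------------------------------------------------------------
# AsLS baseline
# ---------------------------------------------------------------------------


def _whittaker_solve(y: np.ndarray, w: np.ndarray, lam: float) -> np.ndarray:
    """Solve (W + lam * D2' D2) z = W y with a banded Cholesky solve.

    D2 is the (n-2) x n second-difference matrix, so D2'D2 is pentadiagonal
    with diagonal [1, 5, 6, ..., 6, 5, 1], first off-diagonal
    [-2, -4, ..., -4, -2] and second off-diagonal 1 (n >= 8 guaranteed by
    the axis invariant).
    """
    n = y.size
    diag = np.full(n, 6.0)
    diag[[0, -1]] = 1.0
    diag[[1, -2]] = 5.0
    off1 = np.full(n - 1, -4.0)
    off1[[0, -1]] = -2.0
    ab = np.zeros((3, n))
    ab[0, 2:] = lam  # second superdiagonal
    ab[1, 1:] = lam * off1
    ab[2, :] = lam * diag + w
    return solveh_banded(ab, w * y, lower=False)


class AslsBaseline(BaseEstimator, TransformerMixin):
    """Asymmetric least squares baseline correction.

    Estimates, per spectrum, the baseline ``z`` minimizing

        sum_i w_i (y_i - z_i)^2 + lam * sum (Delta^2 z)^2

    with asymmetric weights ``w_i = p`` where ``y_i > z_i`` and ``1 - p``
    otherwise, iterated until the weights stop changing.  With the default
    p = 0.01 the baseline hugs the lower envelope of the spectrum, leaving
    the (positive) vibrational bands in the corrected signal.
    """

    def __init__(self, lam: float = 10_000.0, p: float = 0.01, max_iter: int = 50, tol: float = 1e-6):
        self.lam = lam
        self.p = p
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X: np.ndarray, y: Any = None) -> "AslsBaseline":
        return self

    def baseline(self, X: np.ndarray) -> np.ndarray:
        """Per-spectrum baselines, same shape as ``X``."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if not np.all(np.isfinite(X)):
            raise ValidationError("AsLS input must be finite")
        if not 0 < self.p < 1 or self.lam <= 0:
            raise ValidationError("AsLS requires lam > 0 and 0 < p < 1")
        Z = np.empty_like(X)
        unconverged = 0
        for i, yrow in enumerate(X):
            w = np.full(yrow.size, 0.5)
            converged = False
            for _ in range(self.max_iter):
                z = _whittaker_solve(yrow, w, self.lam)
                w_new = np.where(yrow > z, self.p, 1.0 - self.p)
                if np.max(np.abs(w_new - w)) < self.tol:
                    w = w_new
                    converged = True
                    break
                w = w_new
            Z[i] = _whittaker_solve(yrow, w, self.lam)
            if not converged:
                unconverged += 1
        self.n_unconverged_ = unconverged
        return Z

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return X - self.baseline(X)


# ---------------------------------------------------------------------------
# Savitzky-Golay
# ---------------------------------------------------------------------------


def _savgol_matrix(n: int, frame: int, order: int) -> np.ndarray:
    """Dense smoothing matrix: interior rows use the classic convolution
    coefficients; edge rows refit the polynomial on the truncated window."""
    if frame > n:
        raise ValidationError(f"Savitzky-Golay frame {frame} exceeds n_bands={n}")
    half = frame // 2
    M = np.zeros((n, n))
    interior = savgol_coeffs(frame, order, use="dot")
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        if hi - lo == frame:
            M[i, lo:hi] = interior
        else:
            offsets = np.arange(lo, hi) - i
            k = min(order, hi - lo - 1)
            A = np.vander(offsets, k + 1, increasing=True)
            # fitted value at offset 0 = first row of the pseudo-inverse
            M[i, lo:hi] = np.linalg.pinv(A)[0]
    return M


class SavitzkyGolay(BaseEstimator, TransformerMixin):
    """Savitzky-Golay smoothing (least-squares polynomial per window).

    Each point is replaced by the value, at the window center, of the
    least-squares polynomial of the given order over the frame; windows are
    truncated (and the polynomial refit) at the spectrum edges.
    """

    def __init__(self, frame: int = 5, order: int = 1):
        self.frame = frame
        self.order = order

    def fit(self, X: np.ndarray, y: Any = None) -> "SavitzkyGolay":
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if self.frame % 2 == 0 or self.frame < 3:
            raise ValidationError("Savitzky-Golay frame must be odd and >= 3")
        if not 0 <= self.order < self.frame:
            raise ValidationError("Savitzky-Golay order must satisfy 0 <= order < frame")
        M = _savgol_matrix(X.shape[1], self.frame, self.order)
        return X @ M.T


# ---------------------------------------------------------------------------
# total-area normalization
# ---------------------------------------------------------------------------


class TotalAreaNormalizer(BaseEstimator, TransformerMixin):
    """Scale each spectrum so its intensity sum equals 1.

    Spectra with non-positive total area (e.g. empty-region pixels after
    baseline correction) are flagged in ``unnormalizable_`` and returned
    unchanged; downstream model fitting excludes them.
    """

    def fit(self, X: np.ndarray, y: Any = None) -> "TotalAreaNormalizer":
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        totals = X.sum(axis=1)
        bad = totals <= 0
        out = X.copy()
        out[~bad] = X[~bad] / totals[~bad, None]
        self.unnormalizable_ = bad
        self.scale_factors_ = np.where(bad, np.nan, totals)
        return out


# ---------------------------------------------------------------------------
# image-level functional API
# ---------------------------------------------------------------------------


def _apply_matrix_stage(img: HyperspectralImage, fn, stage: str, **params: Any) -> HyperspectralImage:
    mat = fn(img.as_matrix())
    out = img.with_cube(mat.reshape(img.cube.shape))
    out.append_history(stage, **params)
    return out


def despike(img: HyperspectralImage, window: int = 5, z: float = 10.0) -> HyperspectralImage:
    t = Despike(window=window, z=z)
    out = _apply_matrix_stage(img, t.transform, "despike", window=window, z=z)
    out.metadata["n_despiked"] = int(t.n_replaced_)
    return out


def pca_noise_filter(img: HyperspectralImage, rank: int | str) -> HyperspectralImage:
    t = PCANoiseFilter(rank=rank)
    mat = img.as_matrix()
    t.fit(mat)
    out = img.with_cube(t.transform(mat).reshape(img.cube.shape))
    out.append_history("pca_noise_filter", rank=t.rank_)
    return out


def trim(img: HyperspectralImage, lo: float, hi: float) -> HyperspectralImage:
    """Restrict the axis to lo <= wavenumber <= hi (inclusive)."""
    i0, i1 = img.axis.index_range(lo, hi)
    from .core import SpectralAxis

    axis = SpectralAxis(values=img.axis.values[i0:i1], modality=img.axis.modality)
    out = HyperspectralImage(axis=axis, cube=img.cube[:, :, i0:i1], metadata=dict(img.metadata))
    out.append_history("trim", lo=lo, hi=hi)
    return out


def asls_baseline(
    spectrum: Spectrum,
    lam: float,
    p_asym: float = 0.01,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> tuple[Spectrum, Spectrum]:
    """Baseline-correct a single spectrum; returns (baseline, corrected)."""
    t = AslsBaseline(lam=lam, p=p_asym, max_iter=max_iter, tol=tol)
    z = t.baseline(spectrum.intensities[None, :])[0]
    meta = dict(spectrum.metadata)
    if t.n_unconverged_:
        meta["asls_unconverged"] = True
    baseline = Spectrum(axis=spectrum.axis, intensities=z, metadata=meta)
    corrected = Spectrum(axis=spectrum.axis, intensities=spectrum.intensities - z, metadata=meta)
    return baseline, corrected


def savgol(spectrum: Spectrum, frame: int = 5, order: int = 1) -> Spectrum:
    y = SavitzkyGolay(frame=frame, order=order).transform(spectrum.intensities[None, :])[0]
    return Spectrum(axis=spectrum.axis, intensities=y, metadata=dict(spectrum.metadata))


def normalize_total_area(spectrum: Spectrum) -> Spectrum:
    t = TotalAreaNormalizer()
    y = t.transform(spectrum.intensities[None, :])[0]
    meta = dict(spectrum.metadata)
    if t.unnormalizable_[0]:
        meta["unnormalizable"] = True
    else:
        meta["area_scale"] = float(t.scale_factors_[0])
    return Spectrum(axis=spectrum.axis, intensities=y, metadata=meta)


def preprocess(img: HyperspectralImage, config: PreprocessConfig) -> HyperspectralImage:
    """Apply the full chain in the fixed order.

    Stage order: despike -> pca_noise_filter -> trim -> asls_baseline ->
    savgol -> normalize_total_area.  Every executed stage appends a record
    to the image metadata history; empty-region pixels that cannot be
    normalized are flagged in ``metadata["unnormalizable"]`` (row-major
    boolean list).
    """
    out = img
    try:
        if config.run_despike:
            out = despike(out, window=config.despike_window, z=config.despike_z)
    except VibromapError as exc:
        raise StageError(f"stage 'despike': {exc}") from exc
    try:
        if config.noise_rank is not None and config.noise_rank != "off":
            out = pca_noise_filter(out, rank=config.noise_rank)
    except VibromapError as exc:
        raise StageError(f"stage 'pca_noise_filter': {exc}") from exc
    try:
        if config.run_trim and config.trim_lo is not None and config.trim_hi is not None:
            out = trim(out, config.trim_lo, config.trim_hi)
    except VibromapError as exc:
        raise StageError(f"stage 'trim': {exc}") from exc
    try:
        if config.run_baseline:
            t = AslsBaseline(
                lam=config.lam, p=config.p_asym, max_iter=config.asls_max_iter, tol=config.asls_tol
            )
            out = _apply_matrix_stage(
                out, t.transform, "asls_baseline", lam=config.lam, p=config.p_asym
            )
            if t.n_unconverged_:
                out.metadata["asls_unconverged_pixels"] = int(t.n_unconverged_)
    except VibromapError as exc:
        raise StageError(f"stage 'asls_baseline': {exc}") from exc
    try:
        if config.run_savgol:
            out = _apply_matrix_stage(
                out,
                SavitzkyGolay(frame=config.sg_frame, order=config.sg_order).transform,
                "savgol",
                frame=config.sg_frame,
                order=config.sg_order,
            )
    except VibromapError as exc:
        raise StageError(f"stage 'savgol': {exc}") from exc
    try:
        if config.run_normalize:
            t = TotalAreaNormalizer()
            out = _apply_matrix_stage(out, t.transform, "normalize_total_area")
            out.metadata["unnormalizable"] = t.unnormalizable_.tolist()
    except VibromapError as exc:
        raise StageError(f"stage 'normalize_total_area': {exc}") from exc
    return out
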