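"""False-color class maps and band-level diagnostic reports.

Turns per-pixel predictions back into spatial context (the false-color
maps built from predictive scores) and summarizes which spectral bands
drive the class separation, via the correlation-scaled loadings p(corr).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .core import ClassLabelMask, HyperspectralImage, ValidationError
from .opls import NONE_LABEL, PredictionResult

__all__ = [
    "BandAnnotation",
    "ClassMap",
    "DEFAULT_ANNOTATIONS",
    "DEFAULT_PALETTE",
    "build_training_set",
    "render_class_map",
    "diagnostic_band_report",
]


@dataclass
class BandAnnotation:
    """A wavenumber range with a chemical assignment label."""

    lo: float
    hi: float
    label: str

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise ValidationError("annotation requires lo < hi")

    def overlaps(self, lo: float, hi: float) -> bool:
        return self.lo <= hi and lo <= self.hi


#: the two figure-anchor assignments shipped by default; all further
#: assignments must be supplied by the user
DEFAULT_ANNOTATIONS: tuple[BandAnnotation, ...] = (
    BandAnnotation(663.0, 683.0, "-S-S- stretch (insulin-associated)"),
    BandAnnotation(1580.0, 1700.0, "amide I (protein secondary structure)"),
)

DEFAULT_PALETTE: dict[str, tuple[int, int, int]] = {
    NONE_LABEL: (0, 0, 0),
    "islet": (220, 40, 40),
    "endocrine": (220, 40, 40),
    "exocrine": (40, 80, 220),
}


@dataclass
class ClassMap:
    """Predicted class index per pixel (NONE = 0) with its palette."""

    grid: np.ndarray
    class_names: tuple[str, ...]
    palette: dict[str, tuple[int, int, int]]
    provenance: dict = field(default_factory=dict)

    def to_rgb(self) -> np.ndarray:
        rgb = np.zeros((*self.grid.shape, 3), dtype=np.uint8)
        rgb[self.grid == 0] = self.palette.get(NONE_LABEL, (0, 0, 0))
        for k, name in enumerate(self.class_names, start=1):
            rgb[self.grid == k] = self.palette[name]
        return rgb

    def save(self, png_path: str | Path, csv_path: str | Path | None = None) -> None:
        """Write the PNG render and (by default alongside) its CSV twin."""
        Image.fromarray(self.to_rgb(), mode="RGB").save(png_path)
        if csv_path is None:
            csv_path = Path(png_path).with_suffix(".csv")
        np.savetxt(csv_path, self.grid, delimiter=",", fmt="%d")


def build_training_set(
    img: HyperspectralImage, mask: ClassLabelMask
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collect labeled spectra for model fitting.

    Returns ``(X, labels, coords)`` where rows of ``X`` are the spectra of
    labeled pixels in row-major order, ``labels`` are class names and
    ``coords`` the (row, col) pixel coordinates.  Unassigned pixels and
    pixels flagged unnormalizable by preprocessing are excluded.
    """
    if (mask.n_rows, mask.n_cols) != (img.n_rows, img.n_cols):
        raise ValidationError(
            f"mask shape {(mask.n_rows, mask.n_cols)} does not match "
            f"image {(img.n_rows, img.n_cols)}"
        )
    labels_flat = mask.labels.ravel()
    selected = labels_flat > 0
    if not selected.any():
        raise ValidationError("mask labels no pixels")
    flagged = img.metadata.get("unnormalizable")
    if flagged is not None:
        flagged = np.asarray(flagged, dtype=bool).ravel()
        n_dropped = int((selected & flagged).sum())
        if n_dropped:
            warnings.warn(
                f"{n_dropped} labeled pixel(s) excluded: flagged unnormalizable",
                stacklevel=2,
            )
        selected &= ~flagged
    idx = np.flatnonzero(selected)
    present = np.unique(labels_flat[idx])
    if present.size < 2:
        raise ValidationError("training set must contain at least 2 classes")
    sub = ClassLabelMask(
        labels=np.where(selected.reshape(mask.labels.shape), mask.labels, 0),
        class_names=mask.class_names,
    )
    sub.check_fit_counts()
    X = img.as_matrix()[idx]
    labels = np.asarray([mask.class_names[k - 1] for k in labels_flat[idx]], dtype=object)
    coords = np.column_stack(np.unravel_index(idx, (img.n_rows, img.n_cols)))
    return X, labels, coords


def render_class_map(
    prediction: PredictionResult | np.ndarray,
    shape: tuple[int, int],
    class_names: tuple[str, ...],
    palette: dict[str, tuple[int, int, int]] | None = None,
    provenance: dict | None = None,
) -> ClassMap:
    """Fill the pixel grid with predicted class indices (NONE = 0)."""
    labels = prediction.labels if isinstance(prediction, PredictionResult) else np.asarray(prediction)
    n_rows, n_cols = shape
    if labels.size != n_rows * n_cols:
        raise ValidationError(
            f"prediction covers {labels.size} pixels, grid needs {n_rows * n_cols}"
        )
    if palette is None:
        palette = DEFAULT_PALETTE
    missing = [c for c in class_names if c not in palette]
    if missing:
        raise ValidationError(f"palette missing class(es) {missing}")
    index = {name: k for k, name in enumerate(class_names, start=1)}
    index[NONE_LABEL] = 0
    try:
        grid = np.asarray([index[str(v)] for v in labels], dtype=np.int64).reshape(shape)
    except KeyError as exc:
        raise ValidationError(f"predicted label {exc} not in class_names") from exc
    return ClassMap(
        grid=grid, class_names=tuple(class_names), palette=dict(palette),
        provenance=provenance or {},
    )


def diagnostic_band_report(
    axis_values: np.ndarray,
    p_corr: np.ndarray,
    annotations: tuple[BandAnnotation, ...] = DEFAULT_ANNOTATIONS,
    threshold: float = 0.5,
    positive_class: str = "+",
    negative_class: str = "-",
) -> pd.DataFrame:
    """Rank contiguous bands with |p(corr)| above ``threshold``.

    Contiguous channels above the threshold with a common sign are merged
    into ranges; ranges are ranked by peak |p(corr)| (ties broken by
    ascending wavenumber) and annotated with any overlapping assignment.
    The ``sign`` column reports in which class the band is more intensive.
    """
    axis_values = np.asarray(axis_values, dtype=np.float64)
    p = np.asarray(p_corr, dtype=np.float64)
    if p.ndim == 2:  # first predictive component by default
        p = p[0]
    if p.shape != axis_values.shape:
        raise ValidationError("p_corr length must match the axis")
    above = np.abs(p) >= threshold
    rows = []
    i = 0
    n = p.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        sign = np.sign(p[i])
        j = i
        while j + 1 < n and above[j + 1] and np.sign(p[j + 1]) == sign:
            j += 1
        seg = slice(i, j + 1)
        peak_idx = i + int(np.argmax(np.abs(p[seg])))
        lo, hi = float(axis_values[i]), float(axis_values[j])
        labels = "; ".join(a.label for a in annotations if a.overlaps(lo, hi))
        rows.append(
            {
                "lo": lo,
                "hi": hi,
                "peak_wavenumber": float(axis_values[peak_idx]),
                "peak_pcorr": float(p[peak_idx]),
                "sign": "more intensive in " + (positive_class if sign > 0 else negative_class),
                "label": labels,
            }
        )
        i = j + 1
    df = pd.DataFrame(rows, columns=["lo", "hi", "peak_wavenumber", "peak_pcorr", "sign", "label"])
    if len(df):
        df = df.sort_values(
            by=["peak_pcorr", "lo"],
            key=lambda s: -s.abs() if s.name == "peak_pcorr" else s,
        ).reset_index(drop=True)
    return df
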