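"""Core data model for vibrational hyperspectral maps.

A hyperspectral map is a spatial grid of spectra sharing a single wavenumber
axis.  Every analysis stage in this package consumes and produces the types
defined here.  Conventions:

* the canonical axis order is *ascending* wavenumber (cm^-1); files recorded
  in descending order are flipped at the I/O boundary;
* pixel coordinates are 0-based ``(row, col)``, row-major;
* intensities are stored as 64-bit floats regardless of source precision,
  because downstream baseline correction involves ill-conditioned solves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "VibromapError",
    "FormatError",
    "ValidationError",
    "ContainerError",
    "SpectralAxis",
    "Spectrum",
    "HyperspectralImage",
    "ClassLabelMask",
    "FTIR",
    "RAMAN",
]

FTIR = "ftir"
RAMAN = "raman"

#: pixel-count range of typical instrument maps; larger maps trigger a warning
_MAX_PIXELS_SILENT = 10**6


class VibromapError(Exception):
    """Base class for all package errors."""


class FormatError(VibromapError):
    """An on-disk file violates its format contract."""


class ValidationError(VibromapError):
    """An in-memory object violates a domain invariant."""


class ContainerError(VibromapError):
    """An HDF5 container is unreadable or has an unexpected schema."""


@dataclass(frozen=True)
class SpectralAxis:
    """Wavenumber axis of a spectrum or map.

    Parameters
    ----------
    values : array-like
        Wavenumbers in cm^-1, strictly increasing, all positive and finite,
        at least 8 channels.
    modality : str
        ``"ftir"`` or ``"raman"``.
    """

    values: np.ndarray
    modality: str = FTIR

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 8:
            raise ValidationError(
                f"spectral axis must be 1-D with >= 8 channels, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValidationError("spectral axis values must be positive and finite")
        if not np.all(np.diff(v) > 0):
            raise ValidationError(
                "spectral axis must be strictly increasing; flip descending axes on read"
            )
        if self.modality not in (FTIR, RAMAN):
            raise ValidationError(f"unknown modality {self.modality!r}")

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return self.modality == other.modality and np.array_equal(self.values, other.values)

    def index_range(self, lo: float, hi: float) -> tuple[int, int]:
        """Return slice bounds [i0, i1) covering lo <= v <= hi (inclusive)."""
        mask = (self.values >= lo) & (self.values <= hi)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValidationError(
                f"trim range [{lo}, {hi}] cm^-1 selects no channels on axis "
                f"[{self.values[0]:g}, {self.values[-1]:g}]"
            )
        return int(idx[0]), int(idx[-1]) + 1


@dataclass
class Spectrum:
    """A single spectrum on a shared axis."""

    axis: SpectralAxis
    intensities: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=np.float64)
        if y.shape != (len(self.axis),):
            raise ValidationError(
                f"intensities length {y.shape} does not match axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(y)):
            raise ValidationError("spectrum intensities must be finite")
        self.intensities = y


@dataclass
class HyperspectralImage:
    """A spatial grid of spectra sharing one wavenumber axis.

    ``cube`` has shape ``(n_rows, n_cols, n_bands)``.  ``metadata`` carries
    the source path and a ``history`` list of preprocessing records.
    """

    axis: SpectralAxis
    cube: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.cube, dtype=np.float64)
        if c.ndim != 3:
            raise ValidationError(f"cube must be 3-D (rows, cols, bands), got {c.ndim}-D")
        if c.shape[2] != len(self.axis):
            raise ValidationError(
                f"cube band dimension {c.shape[2]} does not match axis length {len(self.axis)}"
            )
        if c.shape[0] * c.shape[1] > _MAX_PIXELS_SILENT:
            warnings.warn(
                f"map has {c.shape[0] * c.shape[1]} pixels, beyond the expected range",
                stacklevel=2,
            )
        self.cube = c

    @property
    def n_rows(self) -> int:
        return self.cube.shape[0]

    @property
    def n_cols(self) -> int:
        return self.cube.shape[1]

    @property
    def n_bands(self) -> int:
        return self.cube.shape[2]

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    def as_matrix(self) -> np.ndarray:
        """Pixels-by-bands view (row-major pixel order)."""
        return self.cube.reshape(self.n_pixels, self.n_bands)

    def with_cube(self, cube: np.ndarray, **meta_updates: Any) -> "HyperspectralImage":
        """New image with a replaced cube and (copied) updated metadata."""
        md = dict(self.metadata)
        md.update(meta_updates)
        return HyperspectralImage(axis=self.axis, cube=cube, metadata=md)

    def append_history(self, stage: str, **params: Any) -> None:
        self.metadata.setdefault("history", []).append({"stage": stage, **params})


@dataclass
class ClassLabelMask:
    """Per-pixel expert labels: 0 = unassigned, 1..C = classes.

    Only spectra of unambiguous tissue origin are labeled; the rest of the
    map stays 0 and is later classified by the fitted model.
    """

    labels: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValidationError("mask labels must be a 2-D grid")
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.all(lab == np.floor(lab)):
                raise ValidationError("mask labels must be integers")
            lab = lab.astype(np.int64)
        self.labels = lab.astype(np.int64)
        self.class_names = tuple(self.class_names)
        c = len(self.class_names)
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) > c:
            bad = int(self.labels.max()) if self.labels.max(initial=0) > c else int(self.labels.min())
            raise ValidationError(
                f"mask value {bad} outside the valid range 0..{c} for classes {self.class_names}"
            )

    @property
    def n_rows(self) -> int:
        return self.labels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.labels.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def check_fit_counts(self, n_pred: int | None = None) -> None:
        """Validate the labeled-pixel counts required to fit a model.

        Each class must have at least ``max(3, n_pred + 2)`` labeled pixels
        and at least two classes must be present.
        """
        c = self.n_classes
        if c < 2:
            raise ValidationError("model fitting requires at least 2 classes")
        if n_pred is None:
            n_pred = c - 1
        minimum = max(3, n_pred + 2)
        counts = np.bincount(self.labels.ravel(), minlength=c + 1)
        present = [i for i in range(1, c + 1) if counts[i] > 0]
        if len(present) < 2:
            raise ValidationError("mask labels fewer than 2 classes; cannot fit")
        for i in range(1, c + 1):
            if 0 < counts[i] < minimum:
                raise ValidationError(
                    f"class {self.class_names[i - 1]!r} has {counts[i]} labeled pixels, "
                    f"fewer than the required {minimum}"
                )
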