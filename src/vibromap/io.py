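"""Readers and writers for on-disk formats.

Formats
-------
Long-format map
    Delimited text with header ``x,y,wavenumber,intensity``; one row per
    (pixel, channel).  ``x`` maps to column index, ``y`` to row index.
Wide matrix
    TSV, first column ``wavenumber``, one column per pixel named
    ``r<row>_c<col>``.
Class mask
    CSV grid of integers (0 = unassigned).
Container
    HDF5 with keys ``/axis``, ``/cube``, ``/meta`` for images and
    ``/model/*`` for fitted models; every numeric array round-trips
    bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd

from .core import (
    ClassLabelMask,
    ContainerError,
    FormatError,
    HyperspectralImage,
    SpectralAxis,
)

SCHEMA_VERSION = "1"

_LONG_COLUMNS = ("x", "y", "wavenumber", "intensity")


def _read_numeric_table(path: str | Path, delimiter: str, columns: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    for col in columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
            raise FormatError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at line {line}"
            )
        if converted.isna().any():
            line = int(converted.isna().idxmax()) + 2
            raise FormatError(f"{path}: empty cell in column {col!r} at line {line}")
        df[col] = converted.astype(np.float64)
    return df


def read_long_format_map(
    path: str | Path, delimiter: str = ",", modality: str = "ftir"
) -> HyperspectralImage:
    """Read a long-format instrument export into a hyperspectral image.

    Every pixel must carry the identical wavenumber set; the pixel grid is
    inferred from the distinct x/y values and the axis is canonicalized to
    ascending order.
    """
    df = _read_numeric_table(path, delimiter, _LONG_COLUMNS)
    xs = np.sort(df["x"].unique())
    ys = np.sort(df["y"].unique())
    wn_ref: np.ndarray | None = None
    for (y, x), grp in df.groupby(["y", "x"], sort=True):
        wn = np.sort(grp["wavenumber"].to_numpy())
        if wn_ref is None:
            wn_ref = wn
        elif wn.shape != wn_ref.shape or not np.array_equal(wn, wn_ref):
            raise FormatError(
                f"{path}: pixel (x={x:g}, y={y:g}) has a wavenumber set differing "
                f"from the first pixel ({wn.size} vs {wn_ref.size} channels)"
            )
    assert wn_ref is not None
    axis = SpectralAxis(values=wn_ref, modality=modality)
    n_rows, n_cols, n_bands = ys.size, xs.size, wn_ref.size
    if len(df) != n_rows * n_cols * n_bands:
        raise FormatError(
            f"{path}: {len(df)} rows inconsistent with a complete "
            f"{n_rows}x{n_cols}x{n_bands} grid"
        )
    x_idx = np.searchsorted(xs, df["x"].to_numpy())
    y_idx = np.searchsorted(ys, df["y"].to_numpy())
    b_idx = np.searchsorted(wn_ref, df["wavenumber"].to_numpy())
    cube = np.full((n_rows, n_cols, n_bands), np.nan)
    cube[y_idx, x_idx, b_idx] = df["intensity"].to_numpy()
    if np.isnan(cube).any():
        raise FormatError(f"{path}: duplicate or missing (pixel, wavenumber) entries")
    return HyperspectralImage(axis=axis, cube=cube, metadata={"source": str(path)})


def write_long_format_map(img: HyperspectralImage, path: str | Path, delimiter: str = ",") -> None:
    """Write the long-format twin of :func:`read_long_format_map`."""
    rows, cols = np.meshgrid(np.arange(img.n_rows), np.arange(img.n_cols), indexing="ij")
    rec = pd.DataFrame(
        {
            "x": np.repeat(cols.ravel(), img.n_bands),
            "y": np.repeat(rows.ravel(), img.n_bands),
            "wavenumber": np.tile(img.axis.values, img.n_pixels),
            "intensity": img.as_matrix().ravel(),
        }
    )
    rec.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def read_wide_matrix(path: str | Path, modality: str = "ftir") -> HyperspectralImage:
    """Read the wide TSV format (wavenumber column + one column per pixel)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.columns[0] != "wavenumber":
        raise FormatError(f"{path}: first column must be 'wavenumber', got {df.columns[0]!r}")
    coords = []
    for name in df.columns[1:]:
        try:
            r, c = name.split("_")
            coords.append((int(r[1:]), int(c[1:])))
            if not (name.startswith("r") and "_c" in name):
                raise ValueError
        except ValueError as exc:
            raise FormatError(f"{path}: pixel column {name!r} not of the form r<row>_c<col>") from exc
    wn = df["wavenumber"].to_numpy(dtype=np.float64)
    order = np.argsort(wn)
    axis = SpectralAxis(values=wn[order], modality=modality)
    n_rows = max(r for r, _ in coords) + 1
    n_cols = max(c for _, c in coords) + 1
    cube = np.full((n_rows, n_cols, len(axis)), np.nan)
    for name, (r, c) in zip(df.columns[1:], coords):
        cube[r, c, :] = df[name].to_numpy(dtype=np.float64)[order]
    if np.isnan(cube).any():
        raise FormatError(f"{path}: pixel columns do not cover the full grid")
    return HyperspectralImage(axis=axis, cube=cube, metadata={"source": str(path)})


def write_wide_matrix(img: HyperspectralImage, path: str | Path) -> None:
    data: dict[str, np.ndarray] = {"wavenumber": img.axis.values}
    for r in range(img.n_rows):
        for c in range(img.n_cols):
            data[f"r{r}_c{c}"] = img.cube[r, c, :]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_mask(path: str | Path, class_names: tuple[str, ...] | list[str]) -> ClassLabelMask:
    """Read a CSV integer grid as a class-label mask."""
    try:
        grid = np.loadtxt(path, delimiter=",", dtype=np.int64, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: mask must be a CSV grid of integers ({exc})") from exc
    return ClassLabelMask(labels=grid, class_names=tuple(class_names))


def write_mask(mask: ClassLabelMask, path: str | Path) -> None:
    np.savetxt(path, mask.labels, delimiter=",", fmt="%d")


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------


def _write_meta(grp: h5py.Group, metadata: dict[str, Any]) -> None:
    grp.create_dataset("meta", data=json.dumps(metadata, default=str))


def _read_meta(grp: h5py.Group) -> dict[str, Any]:
    if "meta" not in grp:
        return {}
    raw = grp["meta"][()]
    if isinstance(raw, bytes):
        raw = raw.decode()
    return json.loads(raw)


def save_container(obj: Any, path: str | Path) -> None:
    """Save an image, OPLS-DA model or MCR-ALS result to an HDF5 container."""
    from .mcr import McrAlsResult
    from .opls import OPLSDA

    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        if isinstance(obj, HyperspectralImage):
            f.attrs["kind"] = "image"
            ax = f.create_dataset("axis", data=obj.axis.values)
            ax.attrs["modality"] = obj.axis.modality
            f.create_dataset("cube", data=obj.cube)
            _write_meta(f, obj.metadata)
        elif isinstance(obj, OPLSDA):
            f.attrs["kind"] = "oplsda"
            g = f.create_group("model")
            for key, val in obj._to_arrays().items():
                if isinstance(val, np.ndarray):
                    g.create_dataset(key, data=val)
                else:
                    g.attrs[key] = val
        elif isinstance(obj, McrAlsResult):
            f.attrs["kind"] = "mcr"
            g = f.create_group("model")
            g.create_dataset("concentrations", data=obj.concentrations)
            g.create_dataset("profiles", data=obj.profiles)
            g.create_dataset("lof_history", data=np.asarray(obj.lof_history))
            g.attrs["converged"] = bool(obj.converged)
            g.attrs["n_iter"] = int(obj.n_iter)
        else:
            raise ContainerError(f"cannot save object of type {type(obj).__name__}")


def load_container(path: str | Path) -> Any:
    """Load whatever :func:`save_container` wrote at ``path``."""
    from .mcr import McrAlsResult
    from .opls import OPLSDA

    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ContainerError(f"{path}: not a readable HDF5 container ({exc})") from exc
    with f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ContainerError(
                f"{path}: schema version mismatch, expected {SCHEMA_VERSION!r}, found {version!r}"
            )
        kind = f.attrs.get("kind")
        if kind == "image":
            axis = SpectralAxis(values=f["axis"][()], modality=f["axis"].attrs["modality"])
            return HyperspectralImage(axis=axis, cube=f["cube"][()], metadata=_read_meta(f))
        if kind == "oplsda":
            g = f["model"]
            arrays = {k: g[k][()] for k in g if k != "meta"}
            arrays.update({k: g.attrs[k] for k in g.attrs})
            return OPLSDA._from_arrays(arrays)
        if kind == "mcr":
            g = f["model"]
            return McrAlsResult(
                concentrations=g["concentrations"][()],
                profiles=g["profiles"][()],
                lof_history=list(g["lof_history"][()]),
                converged=bool(g.attrs["converged"]),
                n_iter=int(g.attrs["n_iter"]),
            )
        raise ContainerError(f"{path}: unknown container kind {kind!r}")
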