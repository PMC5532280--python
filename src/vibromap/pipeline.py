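"""Configuration-driven end-to-end orchestration.

``run`` executes the full workflow on one map: preprocess -> collect
labeled spectra -> fit OPLS-DA -> predict the entire image -> render the
false-color class map -> band report (optionally MCR-ALS), writing every
artifact plus a reproducible run manifest (parameter log + SHA-256 output
hashes) to the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import HyperspectralImage, ValidationError, VibromapError
from .io import load_container, read_long_format_map, read_mask, read_wide_matrix, save_container
from .mapping import (
    DEFAULT_ANNOTATIONS,
    DEFAULT_PALETTE,
    build_training_set,
    diagnostic_band_report,
    render_class_map,
)
from .mcr import MCRALS
from .opls import NONE_LABEL, OPLSDA, correlation_scaled_loadings
from .preprocessing import PreprocessConfig, preprocess

__all__ = ["RunConfig", "RunManifest", "run", "load_image"]

logger = logging.getLogger("vibromap")


@dataclass
class RunConfig:
    """Validated run configuration (usually loaded from YAML)."""

    image: str
    mask: str
    class_names: tuple[str, ...]
    preset: str = "raman-dry"
    outdir: str = "vibromap-out"
    preprocessing: dict[str, Any] = field(default_factory=dict)
    opls: dict[str, Any] = field(default_factory=dict)
    mcr: dict[str, Any] = field(default_factory=dict)
    band_threshold: float = 0.5
    palette: dict[str, tuple[int, int, int]] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: run configuration must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"{path}: unknown configuration key(s) {sorted(unknown)}")
        for req in ("image", "mask", "class_names"):
            if req not in raw:
                raise ValidationError(f"{path}: missing required key {req!r}")
        raw["class_names"] = tuple(raw["class_names"])
        if raw.get("palette"):
            raw["palette"] = {k: tuple(v) for k, v in raw["palette"].items()}
        return cls(**raw)

    def validate(self) -> None:
        for path, what in ((self.image, "image"), (self.mask, "mask")):
            if not Path(path).exists():
                raise ValidationError(f"{what} file not found: {path}")
        if self.preset not in ("ftir", "raman-dry", "raman-intact"):
            raise ValidationError(f"unknown preset {self.preset!r}")
        if len(self.class_names) < 2:
            raise ValidationError("need at least 2 class names")


@dataclass
class RunManifest:
    """Reproducibility record of one run."""

    config: dict[str, Any]
    version: str
    stages: list[dict[str, Any]] = field(default_factory=list)
    output_hashes: dict[str, str] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "version": self.version,
                    "stages": self.stages,
                    "output_hashes": self.output_hashes,
                },
                fh,
                indent=2,
                default=str,
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_image(path: str | Path, modality: str = "raman") -> HyperspectralImage:
    """Load a map by extension: .h5/.hdf5 container, .tsv wide, else long CSV."""
    p = Path(path)
    if p.suffix in (".h5", ".hdf5"):
        obj = load_container(p)
        if not isinstance(obj, HyperspectralImage):
            raise ValidationError(f"{p}: container does not hold an image")
        return obj
    if p.suffix == ".tsv":
        return read_wide_matrix(p, modality=modality)
    return read_long_format_map(p, modality=modality)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run(config: RunConfig) -> RunManifest:
    """Execute the full analysis workflow described by ``config``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.__dict__.copy(), version=__version__)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    stage = "load"
    try:
        modality = "ftir" if config.preset == "ftir" else "raman"
        img = load_image(config.image, modality=modality)
        mask = read_mask(config.mask, class_names=config.class_names)
        manifest.stages.append({"stage": stage, "image": str(config.image), "mask": str(config.mask)})

        stage = "preprocess"
        pp_cfg = PreprocessConfig.preset(config.preset, **config.preprocessing)
        pre = preprocess(img, pp_cfg)
        save_container(pre, outdir / "preprocessed.h5")
        manifest.stages.append({"stage": stage, "preset": config.preset, **config.preprocessing})
        logger.info("preprocess: %s (%d pixels, %d bands)", config.preset, pre.n_pixels, pre.n_bands)

        stage = "build_training_set"
        X, labels, coords = build_training_set(pre, mask)
        manifest.stages.append({"stage": stage, "n_labeled": int(len(labels))})

        stage = "fit_oplsda"
        model = OPLSDA(classes=config.class_names, **config.opls)
        model.fit(X, labels)
        save_container(model, outdir / "model.h5")
        quality = pd.DataFrame(
            [
                {
                    "n_pred": model.n_pred_,
                    "n_ortho": model.n_ortho_,
                    "r2x": model.r2x_,
                    "r2y": model.r2y_,
                    "q2_cum": model.quality_.q2_cum if model.quality_ else float("nan"),
                    "cv_folds": model.cv_folds,
                }
            ]
        )
        _write_tsv(quality, outdir / "quality.tsv")
        manifest.stages.append(
            {"stage": stage, "n_pred": int(model.n_pred_), "n_ortho": int(model.n_ortho_)}
        )
        logger.info("fit: %d predictive + %d orthogonal components", model.n_pred_, model.n_ortho_)

        stage = "predict"
        full = model.predict_full(pre.as_matrix())
        scores = pd.DataFrame(
            {
                "row": np.repeat(np.arange(pre.n_rows), pre.n_cols),
                "col": np.tile(np.arange(pre.n_cols), pre.n_rows),
                **{f"t{k + 1}": full.scores[:, k] for k in range(model.n_pred_)},
                "hotelling_t2": full.hotelling_t2,
                "dmodx": full.dmodx,
                "label": [str(v) for v in full.labels],
            }
        )
        _write_tsv(scores, outdir / "scores.tsv")
        manifest.stages.append(
            {"stage": stage, "n_none": int(np.sum(full.labels == NONE_LABEL))}
        )

        stage = "render_class_map"
        palette = dict(DEFAULT_PALETTE)
        palette.update(config.palette or {})
        for name in config.class_names:
            # deterministic fallback color derived from the class name
            digest = hashlib.sha256(name.encode()).digest()
            palette.setdefault(name, tuple(40 + b % 200 for b in digest[:3]))
        cmap = render_class_map(
            full, (pre.n_rows, pre.n_cols), config.class_names, palette,
            provenance={"image": str(config.image)},
        )
        cmap.save(outdir / "class_map.png", outdir / "class_map.csv")
        manifest.stages.append({"stage": stage})

        stage = "diagnostic_band_report"
        pcorr = correlation_scaled_loadings(model, X)
        pcorr_df = pd.DataFrame({"wavenumber": pre.axis.values})
        for k in range(pcorr.shape[0]):
            pcorr_df[f"pcorr{k + 1}"] = pcorr[k]
        _write_tsv(pcorr_df, outdir / "pcorr.tsv")
        report = diagnostic_band_report(
            pre.axis.values,
            pcorr,
            annotations=DEFAULT_ANNOTATIONS,
            threshold=config.band_threshold,
            positive_class="positive-scored class",
            negative_class="negative-scored class",
        )
        _write_tsv(report, outdir / "band_report.tsv")
        manifest.stages.append({"stage": stage, "n_bands_reported": int(len(report))})

        if config.mcr.get("run", False):
            stage = "mcr_als"
            est = MCRALS(
                n_components=int(config.mcr.get("components", 2)),
                conv_limit=float(config.mcr.get("conv_limit", 0.1)),
                max_iter=int(config.mcr.get("max_iter", 50)),
            )
            est.fit(pre.as_matrix())
            save_container(est.result(), outdir / "mcr.h5")
            prof = pd.DataFrame({"wavenumber": pre.axis.values})
            for k in range(est.profiles_.shape[0]):
                prof[f"profile{k + 1}"] = est.profiles_[k]
            _write_tsv(prof, outdir / "mcr_profiles.tsv")
            manifest.stages.append(
                {"stage": stage, "n_iter": int(est.n_iter_), "converged": bool(est.converged_),
                 "final_lof": float(est.lof_history_[-1])}
            )
    except VibromapError as exc:
        failed_marker.write_text(f"stage '{stage}': {exc}\n")
        raise VibromapError(f"stage '{stage}': {exc}") from exc

    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest.output_hashes[f.name] = _sha256(f)
    manifest.save(outdir / "manifest.json")
    return manifest
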