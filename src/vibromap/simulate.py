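"""Ground-truthed synthetic vibrational hyperspectral tissue scenes.

The generator emulates the statistical structure of FT-IR/Raman tissue
maps that the analysis pipeline assumes: per-class spectra built from sums
of Gaussian/Lorentzian bands, smooth additive baselines with per-pixel
intensity variation, iid additive noise, sparse cosmic-ray spikes, and
spatial layouts with a compact endocrine "islet" region embedded in an
"exocrine" background plus empty (no-tissue) margins.

Within-class biological variability is modeled as per-pixel lognormal
scaling of each band amplitude, which gives the discriminant model genuine
orthogonal (within-class) variation to filter out.  Every draw is
reproducible from the scene seed (NumPy PCG64 generator).

Default band anchors follow the vibrational bands highlighted for
pancreatic tissue: an islet-characteristic -S-S- stretch near 673 cm^-1
(insulin-associated) and the amide I envelope; the amide I sub-band
centers (alpha-helix 1654 cm^-1, beta-sheet 1625 cm^-1) are generator
conventions for planting secondary-structure shifts.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core import ClassLabelMask, HyperspectralImage, SpectralAxis, ValidationError

__all__ = [
    "BandSpec",
    "SyntheticScene",
    "GroundTruth",
    "band_profile",
    "generate",
    "disease_effect",
    "islet_scene",
    "two_class_scene",
    "training_mask",
    "AMIDE_I_ALPHA",
    "AMIDE_I_BETA",
    "INSULIN_SS",
]

#: conventional sub-band centers (cm^-1) used to plant structural effects
AMIDE_I_ALPHA = 1654.0
AMIDE_I_BETA = 1625.0
INSULIN_SS = 673.0


@dataclass
class BandSpec:
    """One analytic vibrational band."""

    center: float
    fwhm: float
    amplitude: float
    shape: Literal["gaussian", "lorentzian"] = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValidationError("band fwhm must be positive")
        if self.amplitude < 0:
            raise ValidationError("band amplitude must be non-negative")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValidationError(f"unknown band shape {self.shape!r}")


def band_profile(axis: np.ndarray | SpectralAxis, bands: list[BandSpec]) -> np.ndarray:
    """Sum of analytic band shapes evaluated on the axis (exact closed form)."""
    v = axis.values if isinstance(axis, SpectralAxis) else np.asarray(axis, dtype=np.float64)
    y = np.zeros_like(v)
    for b in bands:
        if not v[0] <= b.center <= v[-1]:
            raise ValidationError(f"band center {b.center} outside axis [{v[0]}, {v[-1]}]")
        if b.shape == "gaussian":
            y = y + b.amplitude * np.exp(-4.0 * np.log(2.0) * ((v - b.center) / b.fwhm) ** 2)
        else:
            hwhm = b.fwhm / 2.0
            y = y + b.amplitude * hwhm**2 / ((v - b.center) ** 2 + hwhm**2)
    return y


@dataclass
class SyntheticScene:
    """Declarative description of a synthetic tissue map.

    ``layout`` is one of ``"islet-disc"`` (disc of the first class inside a
    background of the second, with an optional empty margin),
    ``"two-region-split"`` (left/right halves) or ``"empty-margin"``
    (single class with an empty border).
    """

    class_profiles: dict[str, list[BandSpec]]
    axis_lo: float = 630.0
    axis_hi: float = 1890.0
    spacing: float = 2.0
    modality: str = "raman"
    layout: str = "islet-disc"
    n_rows: int = 40
    n_cols: int = 40
    disc_radius: float = 10.0
    margin: int = 4
    amp_sigma: float = 0.15
    baseline_coeffs: tuple[float, ...] = (0.2, 0.1, -0.05)
    baseline_scale_sigma: float = 0.2
    noise_sd: float = 0.01
    spike_rate: float = 0.0
    spike_amplitude: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.class_profiles:
            raise ValidationError("scene needs at least one class")
        for name, bands in self.class_profiles.items():
            if not bands:
                raise ValidationError(f"class {name!r} has no bands")
        if self.layout not in ("islet-disc", "two-region-split", "empty-margin"):
            raise ValidationError(f"unknown layout {self.layout!r}")
        if self.axis_lo >= self.axis_hi or self.spacing <= 0:
            raise ValidationError("invalid axis specification")

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(self.class_profiles)

    def make_axis(self) -> SpectralAxis:
        values = np.arange(self.axis_lo, self.axis_hi + 0.5 * self.spacing, self.spacing)
        return SpectralAxis(values=values, modality=self.modality)


@dataclass
class GroundTruth:
    """Everything a test oracle needs about a generated scene."""

    mask: ClassLabelMask  # 0 = EMPTY, 1..C per scene class order
    clean: np.ndarray  # noiseless, baseline-free cube (incl. per-pixel scaling)
    baselines: np.ndarray  # planted baseline cube
    spikes: list[tuple[int, int, int]] = field(default_factory=list)  # (row, col, band)


def _layout_mask(scene: SyntheticScene) -> np.ndarray:
    """Integer region grid: 0 = empty, 1..C = class regions."""
    nr, nc = scene.n_rows, scene.n_cols
    names = scene.class_names
    grid = np.zeros((nr, nc), dtype=np.int64)
    if scene.layout == "islet-disc":
        if len(names) < 2:
            raise ValidationError("islet-disc layout needs two classes (islet, background)")
        m = scene.margin
        grid[m : nr - m, m : nc - m] = 2
        rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        cy, cx = (nr - 1) / 2.0, (nc - 1) / 2.0
        disc = (rr - cy) ** 2 + (cc - cx) ** 2 <= scene.disc_radius**2
        grid[disc & (grid == 2)] = 1
    elif scene.layout == "two-region-split":
        if len(names) < 2:
            raise ValidationError("two-region-split needs two classes")
        grid[:, : nc // 2] = 1
        grid[:, nc // 2 :] = 2
    else:  # empty-margin
        m = scene.margin
        if m >= min(nr, nc) // 2:
            raise ValidationError("margin too large for the grid")
        grid[m : nr - m, m : nc - m] = 1
    return grid


def generate(scene: SyntheticScene) -> tuple[HyperspectralImage, GroundTruth]:
    """Draw a hyperspectral image (and its ground truth) from a scene.

    Per pixel: the class bands are scaled by lognormal per-band draws
    (within-class variability), the polynomial baseline is added with a
    lognormal per-pixel scale, iid Gaussian noise is added, and cosmic-ray
    spikes are planted with probability ``spike_rate`` per spectrum.
    EMPTY pixels carry baseline + noise only.
    """
    rng = np.random.default_rng(scene.seed)
    axis = scene.make_axis()
    v = axis.values
    nr, nc, nb = scene.n_rows, scene.n_cols, len(axis)
    grid = _layout_mask(scene)
    names = scene.class_names

    # normalized axis coordinate in [-1, 1] for the polynomial baseline
    u = 2.0 * (v - v[0]) / (v[-1] - v[0]) - 1.0
    if scene.baseline_coeffs:
        base_shape = np.polynomial.polynomial.polyval(u, np.asarray(scene.baseline_coeffs))
    else:
        base_shape = np.zeros_like(v)

    clean = np.zeros((nr, nc, nb))
    baselines = np.zeros((nr, nc, nb))
    cube = np.zeros((nr, nc, nb))
    spikes: list[tuple[int, int, int]] = []
    for r in range(nr):
        for c in range(nc):
            k = grid[r, c]
            if k > 0:
                bands = scene.class_profiles[names[k - 1]]
                y = np.zeros(nb)
                for b in bands:
                    scale = rng.lognormal(mean=0.0, sigma=scene.amp_sigma) if scene.amp_sigma > 0 else 1.0
                    y += scale * band_profile(v, [b])
                clean[r, c] = y
            bl_scale = (
                rng.lognormal(mean=0.0, sigma=scene.baseline_scale_sigma)
                if scene.baseline_scale_sigma > 0
                else 1.0
            )
            baselines[r, c] = bl_scale * base_shape
            noise = rng.normal(0.0, scene.noise_sd, nb) if scene.noise_sd > 0 else 0.0
            spec = clean[r, c] + baselines[r, c] + noise
            if scene.spike_rate > 0 and rng.random() < scene.spike_rate:
                j = int(rng.integers(2, nb - 2))
                spec[j] += scene.spike_amplitude * max(np.max(np.abs(clean[r, c])), 1.0)
                spikes.append((r, c, j))
            cube[r, c] = spec

    img = HyperspectralImage(
        axis=axis, cube=cube, metadata={"source": "synthetic", "seed": scene.seed}
    )
    mask = ClassLabelMask(labels=grid, class_names=names)
    return img, GroundTruth(mask=mask, clean=clean, baselines=baselines, spikes=spikes)


def disease_effect(
    scene: SyntheticScene,
    class_name: str,
    op: Literal["shift", "scale", "add"],
    center: float | None = None,
    new_center: float | None = None,
    factor: float | None = None,
    band: BandSpec | None = None,
) -> SyntheticScene:
    """Return a new scene with one class profile modified.

    ``shift`` moves the band at ``center`` to ``new_center`` (amplitude and
    width preserved, so the profile's total area is conserved); ``scale``
    multiplies the amplitude of the band at ``center`` by ``factor``;
    ``add`` appends ``band``.  The input scene is unchanged.
    """
    if class_name not in scene.class_profiles:
        raise ValidationError(f"unknown class {class_name!r}")
    out = copy.deepcopy(scene)
    bands = out.class_profiles[class_name]
    if op == "add":
        if band is None:
            raise ValidationError("'add' requires a band")
        bands.append(band)
        return out
    if center is None:
        raise ValidationError(f"{op!r} requires the target band center")
    matches = [b for b in bands if abs(b.center - center) < 1e-9]
    if not matches:
        raise ValidationError(f"class {class_name!r} has no band at {center} cm^-1")
    target = matches[0]
    if op == "shift":
        if new_center is None:
            raise ValidationError("'shift' requires new_center")
        target.center = float(new_center)
    elif op == "scale":
        if factor is None:
            raise ValidationError("'scale' requires factor")
        target.amplitude *= float(factor)
    else:
        raise ValidationError(f"unknown effect {op!r}")
    return out


def training_mask(
    truth: GroundTruth, n_per_class: int = 120, erode: int = 2, seed: int = 0
) -> ClassLabelMask:
    """Label spectra of unambiguous origin from a scene's ground truth.

    Emulates expert labeling: each class region is eroded by ``erode``
    pixels (keeping pixels well away from region boundaries) and up to
    ``n_per_class`` pixels per class are then subsampled with a seeded
    generator.  The majority of the map stays unassigned (0).
    """
    from scipy.ndimage import binary_erosion

    rng = np.random.default_rng(seed)
    g = truth.mask.labels
    out = np.zeros_like(g)
    for k in range(1, truth.mask.n_classes + 1):
        region = g == k
        if erode > 0:
            region = binary_erosion(region, iterations=erode)
        idx = np.flatnonzero(region.ravel())
        if idx.size == 0:
            continue
        if idx.size > n_per_class:
            idx = rng.choice(idx, n_per_class, replace=False)
        out.ravel()[idx] = k
    return ClassLabelMask(labels=out, class_names=truth.mask.class_names)


# ---------------------------------------------------------------------------
# stock scenes
# ---------------------------------------------------------------------------


def _raman_islet_bands() -> list[BandSpec]:
    return [
        BandSpec(INSULIN_SS, 18.0, 0.6),  # -S-S- stretch, islet marker
        BandSpec(1004.0, 10.0, 0.9),  # phenylalanine ring breathing
        BandSpec(1260.0, 40.0, 0.5),  # amide III
        BandSpec(1445.0, 30.0, 0.8),  # CH2 deformation
        BandSpec(AMIDE_I_ALPHA, 40.0, 1.0),  # amide I, alpha-helix side
    ]


def _raman_exocrine_bands() -> list[BandSpec]:
    return [
        BandSpec(1004.0, 10.0, 0.7),
        BandSpec(1098.0, 25.0, 0.4),  # nucleic acid / C-C backbone
        BandSpec(1260.0, 40.0, 0.7),
        BandSpec(1445.0, 30.0, 1.0),
        BandSpec(1670.0, 45.0, 0.9),  # amide I, shifted envelope
    ]


def islet_scene(seed: int = 0, **overrides) -> SyntheticScene:
    """Default Raman scene: islet disc in exocrine background, empty margin."""
    params = dict(
        class_profiles={"islet": _raman_islet_bands(), "exocrine": _raman_exocrine_bands()},
        layout="islet-disc",
        n_rows=40,
        n_cols=40,
        disc_radius=9.0,
        margin=5,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticScene(**params)


def two_class_scene(seed: int = 0, **overrides) -> SyntheticScene:
    """FT-IR style two-region scene on the 950-2000 cm^-1 fingerprint axis."""
    params = dict(
        class_profiles={
            "endocrine": [
                BandSpec(1080.0, 30.0, 0.5),
                BandSpec(1545.0, 40.0, 0.7),  # amide II
                BandSpec(AMIDE_I_ALPHA, 45.0, 1.0),
            ],
            "exocrine": [
                BandSpec(1080.0, 30.0, 0.8),
                BandSpec(1545.0, 40.0, 0.6),
                BandSpec(1665.0, 45.0, 1.0),
            ],
        },
        axis_lo=950.0,
        axis_hi=2000.0,
        spacing=4.0,
        modality="ftir",
        layout="two-region-split",
        n_rows=14,
        n_cols=16,
        margin=0,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticScene(**params)
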