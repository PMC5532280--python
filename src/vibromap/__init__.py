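"""vibromap: multivariate profiling of vibrational microspectroscopy maps.

Supervised OPLS-DA classification of FT-IR/Raman hyperspectral tissue
images, spectral preprocessing (despiking, low-rank noise filtering,
asymmetric least squares baseline correction, Savitzky-Golay smoothing,
total-area normalization), MCR-ALS pure-profile resolution, false-color
class mapping, and a ground-truthed synthetic tissue-scene generator.
"""

__version__ = "0.1.0"

from .core import (
    ClassLabelMask,
    ContainerError,
    FormatError,
    HyperspectralImage,
    SpectralAxis,
    Spectrum,
    ValidationError,
    VibromapError,
)
from .mcr import MCRALS, McrAlsConfig, McrAlsResult, mcr_als_solve, simplisma_init
from .opls import (
    OPLSDA,
    HotellingEllipse,
    ModelQuality,
    OplsdaConfig,
    PredictionResult,
    correlation_scaled_loadings,
    encode_dummy,
    fit_oplsda,
    hotelling_ellipse,
    q2_cross_validation,
)
from .preprocessing import PreprocessConfig, preprocess
from .simulate import BandSpec, GroundTruth, SyntheticScene, band_profile, disease_effect, generate

__all__ = [
    "__version__",
    "SpectralAxis",
    "Spectrum",
    "HyperspectralImage",
    "ClassLabelMask",
    "VibromapError",
    "FormatError",
    "ValidationError",
    "ContainerError",
    "PreprocessConfig",
    "preprocess",
    "MCRALS",
    "McrAlsConfig",
    "McrAlsResult",
    "simplisma_init",
    "mcr_als_solve",
    "OPLSDA",
    "OplsdaConfig",
    "ModelQuality",
    "PredictionResult",
    "HotellingEllipse",
    "encode_dummy",
    "fit_oplsda",
    "correlation_scaled_loadings",
    "q2_cross_validation",
    "hotelling_ellipse",
    "BandSpec",
    "SyntheticScene",
    "GroundTruth",
    "band_profile",
    "generate",
    "disease_effect",
]
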