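"""The seven training-time augmentations for H&E tiles.

Applied jointly, in a fixed order, each with a freshly sampled parameter:
rotation (multiples of 90 degrees), mirroring, contrast, brightness, H&E
stain-space colour modulation, additive Gaussian noise, Gaussian blur.

Rasters are ``(H, W, 3)`` floats in ``[0, 1]``. Every augmentation returns a
raster in the same range; geometric augmentations are pixel permutations.

The colour augmentation works in optical density (OD) space: RGB intensity
``p`` relative to the background intensity I0 maps to ``OD = -log10(p/I0)``,
which is linear in stain concentration (Beer-Lambert). The OD vector is
projected onto a hematoxylin/eosin/residual basis, the two stain channels
are shifted by per-image scalars, and the result is mapped back to RGB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigError, ParameterError

ROTATION_ANGLES = (0, 90, 180, 270)
MIRROR_CHOICES = ("horizontal", "vertical", "none")

_LOG_EPS = 1e-6


# ------------------------------------------------------------- geometric ---

def rotate(raster: np.ndarray, angle: int) -> np.ndarray:
    """Lossless clockwise rotation by a multiple of 90 degrees."""
    if angle not in ROTATION_ANGLES:
        raise ParameterError(f"angle must be one of {ROTATION_ANGLES}, got {angle!r}")
    return np.rot90(raster, k=-(angle // 90), axes=(0, 1)).copy()


def mirror(raster: np.ndarray, axis: str) -> np.ndarray:
    """Flip left-right ("horizontal"), top-bottom ("vertical"), or not at all."""
    if axis == "none":
        return np.asarray(raster).copy()
    if axis == "horizontal":
        return np.flip(raster, axis=1).copy()
    if axis == "vertical":
        return np.flip(raster, axis=0).copy()
    raise ParameterError(f"axis must be one of {MIRROR_CHOICES}, got {axis!r}")


# ----------------------------------------------------------- photometric ---

def adjust_contrast(raster: np.ndarray, factor: float) -> np.ndarray:
    """Scale deviations from the per-image mean intensity by ``factor``."""
    if not factor > 0:
        raise ParameterError("contrast factor must be positive")
    arr = np.asarray(raster, dtype=float)
    if factor == 1.0:
        return arr.copy()
    mean = arr.mean()
    return np.clip(mean + factor * (arr - mean), 0.0, 1.0)


def adjust_brightness(raster: np.ndarray, factor: float) -> np.ndarray:
    """Multiply all pixel values by ``factor``, clipping into [0, 1]."""
    if not factor > 0:
        raise ParameterError("brightness factor must be positive")
    arr = np.asarray(raster, dtype=float)
    if factor == 1.0:
        return arr.copy()
    return np.clip(arr * factor, 0.0, 1.0)


# ------------------------------------------------------------ stain space ---

@dataclass(frozen=True)
class StainModel:
    """An RGB optical-density basis for H&E colour decomposition.

    Defaults to the Ruifrok-Johnston hematoxylin/eosin OD vectors with a
    third, orthogonal residual direction and background intensity I0 = 1 on
    the normalized scale.
    """

    hematoxylin: tuple[float, float, float] = (0.650, 0.704, 0.286)
    eosin: tuple[float, float, float] = (0.072, 0.990, 0.105)
    background: float = 1.0

    def basis(self) -> np.ndarray:
        """The 3x3 OD matrix whose columns are unit H, E and residual vectors."""
        h = np.asarray(self.hematoxylin, dtype=float)
        e = np.asarray(self.eosin, dtype=float)
        if h.shape != (3,) or e.shape != (3,):
            raise ConfigError("stain vectors must have 3 components")
        nh, ne = np.linalg.norm(h), np.linalg.norm(e)
        if nh == 0 or ne == 0:
            raise ConfigError("stain vectors must be non-zero")
        h, e = h / nh, e / ne
        r = np.cross(h, e)
        nr = np.linalg.norm(r)
        if nr < 1e-6:
            raise ConfigError("hematoxylin and eosin vectors are collinear")
        if not self.background > 0:
            raise ConfigError("background intensity I0 must be positive")
        return np.stack([h, e, r / nr], axis=1)


def rgb_to_he(raster: np.ndarray, stain: StainModel | None = None) -> np.ndarray:
    """Project a raster into stain-concentration space.

    Returns a ``(H, W, 3)`` array whose channels are hematoxylin
    concentration, eosin concentration, and the residual OD component.
    Background pixels (``p = I0``) map to concentrations ~= 0.
    """
    stain = stain or StainModel()
    basis = stain.basis()
    od = -np.log10((np.asarray(raster, dtype=float) + _LOG_EPS) / stain.background)
    return od @ np.linalg.inv(basis).T


def he_to_rgb(concentrations: np.ndarray, stain: StainModel | None = None) -> np.ndarray:
    """Invert :func:`rgb_to_he`; output clipped to [0, 1]."""
    stain = stain or StainModel()
    od = np.asarray(concentrations, dtype=float) @ stain.basis().T
    rgb = stain.background * np.power(10.0, -od) - _LOG_EPS
    return np.clip(rgb, 0.0, 1.0)


def he_color_augment(
    raster: np.ndarray,
    delta_h: float,
    delta_e: float,
    stain: StainModel | None = None,
) -> np.ndarray:
    """Shift the per-image H and E concentrations by scalar deltas.

    Deltas must lie in [-0.05, 0.05]. Concentrations are not allowed to be
    driven negative by the shift (background cannot be "un-stained" below
    blank glass): each pixel's concentration is floored at
    ``min(original, 0)``, so pixels whose projection is already slightly
    negative (non-stain colours, log-epsilon round-off) pass through
    unchanged at delta 0 and the round trip stays an identity.
    """
    for name, d in (("delta_h", delta_h), ("delta_e", delta_e)):
        if not -0.05 - 1e-12 <= d <= 0.05 + 1e-12:
            raise ParameterError(f"{name} must lie in [-0.05, 0.05], got {d}")
    conc = rgb_to_he(raster, stain)
    for channel, delta in ((0, delta_h), (1, delta_e)):
        c = conc[..., channel]
        conc[..., channel] = np.maximum(c + delta, np.minimum(c, 0.0))
    return he_to_rgb(conc, stain)


# ---------------------------------------------------------- noise & blur ---

def add_gaussian_noise(
    raster: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Add iid per-pixel-per-channel N(0, sigma^2) noise, clipped to [0, 1]."""
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    arr = np.asarray(raster, dtype=float)
    if sigma == 0:
        return arr.copy()
    return np.clip(arr + rng.normal(0.0, sigma, size=arr.shape), 0.0, 1.0)


def gaussian_blur(raster: np.ndarray, radius: float) -> np.ndarray:
    """Convolve each channel with a Gaussian of std ``radius`` pixels.

    Reflective boundaries conserve total intensity. ``radius = 0`` is the
    identity.
    """
    if radius < 0:
        raise ParameterError("radius must be >= 0")
    arr = np.asarray(raster, dtype=float)
    if radius == 0:
        return arr.copy()
    sigma = (radius, radius) + (0,) * (arr.ndim - 2)
    return np.clip(ndimage.gaussian_filter(arr, sigma=sigma, mode="reflect"), 0.0, 1.0)


# -------------------------------------------------------------- pipeline ---

@dataclass
class AugmentationConfig:
    """Sampling laws for the joint augmentation pipeline.

    Defaults follow the screening pipeline's training recipe: equiprobable
    axis-aligned rotations and mirrorings, contrast/brightness factors
    uniform in [0.7, 1.3], H&E concentration deltas uniform in
    [-0.05, 0.05], noise sigma 0.1 (normalized intensity), blur radius
    0.1 px.
    """

    rotation_angles: tuple[int, ...] = ROTATION_ANGLES
    mirror_choices: tuple[str, ...] = MIRROR_CHOICES
    contrast_range: tuple[float, float] = (0.7, 1.3)
    brightness_range: tuple[float, float] = (0.7, 1.3)
    he_delta_range: tuple[float, float] = (-0.05, 0.05)
    noise_sigma: float = 0.1
    blur_radius: float = 0.1
    stain: StainModel = field(default_factory=StainModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for angle in self.rotation_angles:
            if angle not in ROTATION_ANGLES:
                raise ConfigError(f"rotation_angles contains invalid angle {angle}")
        for choice in self.mirror_choices:
            if choice not in MIRROR_CHOICES:
                raise ConfigError(f"mirror_choices contains invalid choice {choice!r}")
        for name in ("contrast_range", "brightness_range", "he_delta_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} is not well-ordered: ({lo}, {hi})")
        if self.contrast_range[0] <= 0 or self.brightness_range[0] <= 0:
            raise ConfigError("contrast/brightness factors must be positive")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.blur_radius < 0:
            raise ConfigError("blur_radius must be >= 0")

    @classmethod
    def identity(cls) -> "AugmentationConfig":
        """A degenerate config under which :func:`augment` is the identity."""
        return cls(
            rotation_angles=(0,),
            mirror_choices=("none",),
            contrast_range=(1.0, 1.0),
            brightness_range=(1.0, 1.0),
            he_delta_range=(0.0, 0.0),
            noise_sigma=0.0,
            blur_radius=0.0,
        )


def augment(
    raster: np.ndarray,
    config: AugmentationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample one parameter per augmentation and apply all seven in order."""
    config = config or AugmentationConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    out = rotate(raster, config.rotation_angles[rng.integers(len(config.rotation_angles))])
    out = mirror(out, config.mirror_choices[rng.integers(len(config.mirror_choices))])
    out = adjust_contrast(out, rng.uniform(*config.contrast_range))
    out = adjust_brightness(out, rng.uniform(*config.brightness_range))
    delta_h = rng.uniform(*config.he_delta_range)
    delta_e = rng.uniform(*config.he_delta_range)
    if delta_h != 0.0 or delta_e != 0.0:
        out = he_color_augment(out, delta_h, delta_e, config.stain)
    out = add_gaussian_noise(out, config.noise_sigma, rng)
    out = gaussian_blur(out, config.blur_radius)
    return out
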