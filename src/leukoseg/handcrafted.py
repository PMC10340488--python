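"""Handcrafted WBC nuclei segmentation.

The pipeline exploits the staining chemistry of blood smears: leukocyte nuclei
take up basic dyes and appear purple, i.e. simultaneously high in the CMYK
Magenta channel and the HSV Saturation channel, while red cells and the
background are pink/yellow and score low on at least one of the two.  The
stages are

1. gray-world color constancy (per-channel rescaling so every channel mean
   equals the grayscale mean), which homogenizes stain and illumination
   differences between acquisition setups;
2. extraction of Magenta (CMYK) and Saturation (HSV) and their Hadamard
   (elementwise) product, which highlights nuclei and suppresses everything
   else;
3. edge-preserving bilateral smoothing of the product map;
4. global Otsu thresholding of the smoothed map;
5. morphological refinement: closing, hole filling, and an area filter that
   removes small spurious components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import closing, disk, remove_small_objects
from skimage.restoration import denoise_bilateral

from .exceptions import ConfigError, DegenerateChannelError, DimensionError, StageError

#: ITU-R BT.601 luma coefficients, the default grayscale definition.
BT601_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class SegConfig:
    """Tunable parameters of the handcrafted pipeline.

    Attributes
    ----------
    bilateral_diameter : int
        Window size of the bilateral filter, pixels (odd).
    bilateral_sigma_color : float
        Range sigma of the bilateral filter, on the [0, 1] intensity scale.
    bilateral_sigma_space : float
        Spatial sigma of the bilateral filter, pixels.
    closing_radius : int
        Radius of the disk structuring element used for morphological closing.
    min_area : int or None
        Area-filter threshold in pixels.  ``None`` means "use
        ``min_area_frac`` of the image's pixel count", which keeps behavior
        stable across image sizes.
    min_area_frac : float
        Relative area threshold used when ``min_area`` is ``None``.
    grayscale_weights : tuple of float
        Luma coefficients (wR, wG, wB); must sum to 1.
    """

    bilateral_diameter: int = 9
    bilateral_sigma_color: float = 0.1
    bilateral_sigma_space: float = 5.0
    closing_radius: int = 3
    min_area: int | None = None
    min_area_frac: float = 0.001
    grayscale_weights: tuple[float, float, float] = field(default=BT601_WEIGHTS)

    def __post_init__(self) -> None:
        for name in ("bilateral_diameter", "bilateral_sigma_color",
                     "bilateral_sigma_space", "closing_radius", "min_area_frac"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.min_area is not None and self.min_area <= 0:
            raise ConfigError(f"min_area must be > 0, got {self.min_area}")
        if abs(sum(self.grayscale_weights) - 1.0) > 1e-9:
            raise ConfigError(
                f"grayscale_weights must sum to 1, got {self.grayscale_weights}")

    def resolve_min_area(self, shape: tuple[int, int]) -> int:
        """Area threshold in pixels for an image of the given (H, W) shape."""
        if self.min_area is not None:
            return int(self.min_area)
        return max(1, int(round(self.min_area_frac * shape[0] * shape[1])))


def validate_rgb(image: np.ndarray) -> np.ndarray:
    """Check an 8-bit RGB raster and return it as uint8."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise DimensionError(f"expected (H, W, 3) RGB image, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise DimensionError("image must have height >= 1 and width >= 1")
    if arr.dtype != np.uint8:
        if np.any(arr < 0) or np.any(arr > 255):
            raise ValueError("intensities must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def color_constancy(
    image: np.ndarray,
    weights: tuple[float, float, float] = BT601_WEIGHTS,
    clip: bool = True,
) -> np.ndarray:
    """Gray-world color constancy.

    Each channel is multiplied by ``gray_mean / channel_mean`` so that, before
    clipping, every output channel mean equals the input grayscale mean.
    With ``clip=True`` (default) the result is clamped to [0, 255] and
    rounded half-up back to uint8; with ``clip=False`` the unclipped float
    array is returned (useful for checking the mean-conservation property).
    """
    arr = validate_rgb(image).astype(np.float64)
    channel_means = arr.mean(axis=(0, 1))
    for name, mean in zip("RGB", channel_means):
        if mean == 0.0:
            raise DegenerateChannelError(
                f"channel {name} has zero mean; its constancy weight is undefined")
    gray_mean = float(np.dot(weights, channel_means))
    scaled = arr * (gray_mean / channel_means)
    if not clip:
        return scaled
    return np.floor(np.clip(scaled, 0.0, 255.0) + 0.5).astype(np.uint8)


def extract_magenta(image: np.ndarray) -> np.ndarray:
    """CMYK Magenta channel via the naive device conversion (no ICC profile).

    With normalized (r, g, b): K = 1 - max(r, g, b) and
    M = (1 - g - K) / (1 - K) when K < 1, else 0 (black pixels carry no hue).
    """
    arr = validate_rgb(image).astype(np.float64) / 255.0
    k = 1.0 - arr.max(axis=2)
    denom = 1.0 - k
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(denom > 0, (1.0 - arr[..., 1] - k) / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(m, 0.0, 1.0)


def extract_saturation(image: np.ndarray) -> np.ndarray:
    """HSV Saturation: S = (max - min) / max when max > 0, else 0."""
    arr = validate_rgb(image).astype(np.float64) / 255.0
    mx = arr.max(axis=2)
    mn = arr.min(axis=2)
    s = np.where(mx > 0, (mx - mn) / np.where(mx > 0, mx, 1.0), 0.0)
    return np.clip(s, 0.0, 1.0)


def hadamard_enhance(m: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Elementwise (Hadamard) product of the Magenta and Saturation maps."""
    m = np.asarray(m, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    if m.shape != s.shape:
        raise DimensionError(f"shape mismatch: {m.shape} vs {s.shape}")
    return np.clip(m * s, 0.0, 1.0)


def bilateral_smooth(channel: np.ndarray, config: SegConfig | None = None) -> np.ndarray:
    """Edge-preserving bilateral smoothing of a [0, 1] channel map."""
    config = config or SegConfig()
    arr = np.asarray(channel, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("channel map contains NaN/Inf")
    out = denoise_bilateral(
        arr,
        win_size=int(config.bilateral_diameter),
        sigma_color=config.bilateral_sigma_color,
        sigma_spatial=config.bilateral_sigma_space,
        mode="symmetric",   # zero-padding would darken the borders
    )
    return np.clip(out, arr.min(), arr.max())


def otsu_threshold(channel: np.ndarray) -> int:
    """Otsu's threshold on the 256-bin histogram of a [0, 1] channel map.

    Returns the 8-bit bin index t* maximizing the between-class variance of
    the split {q <= t} / {q > t}; ties are broken toward the lowest t.
    """
    q = np.floor(np.clip(np.asarray(channel, dtype=np.float64), 0, 1) * 255.0 + 0.5)
    hist = np.bincount(q.astype(np.intp).ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    omega = np.cumsum(hist) / total            # class-0 weight for t = 0..255
    mu = np.cumsum(hist * np.arange(256)) / total
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = 0.0
    return int(np.argmax(sigma_b))             # argmax returns the first (lowest) maximizer


def otsu_binarize(channel: np.ndarray) -> np.ndarray:
    """Global Otsu binarization; foreground = pixels above the threshold.

    A constant input has no inter-class variance to maximize: the result is an
    all-background mask and a degenerate-histogram warning is emitted.
    """
    arr = np.asarray(channel, dtype=np.float64)
    q = np.floor(np.clip(arr, 0, 1) * 255.0 + 0.5)
    if q.min() == q.max():
        warnings.warn("degenerate histogram: constant channel map, returning empty mask",
                      stacklevel=2)
        return np.zeros(arr.shape, dtype=bool)
    t = otsu_threshold(arr)
    return q > t


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background components not connected to the image border (8-connectivity)."""
    return ndi.binary_fill_holes(mask, structure=np.ones((3, 3), dtype=bool))


def refine_mask(mask: np.ndarray, config: SegConfig | None = None) -> np.ndarray:
    """Morphological refinement: closing, hole filling, area filter.

    Closing uses a disk of ``closing_radius``; components (8-connectivity)
    with area below the resolved ``min_area`` are removed last, so every
    surviving component has area >= min_area and no interior holes.
    """
    config = config or SegConfig()
    m = np.asarray(mask, dtype=bool)
    m = closing(m, disk(config.closing_radius))
    m = fill_holes(m)
    min_area = config.resolve_min_area(m.shape)
    # components of area < min_area go; area >= min_area survives
    return remove_small_objects(m, max_size=min_area - 1, connectivity=2)


def segment_handcrafted(
    image: np.ndarray, config: SegConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Run the full handcrafted pipeline on an RGB image.

    Returns ``(mask, segmented)`` where ``mask`` is the boolean nucleus mask
    and ``segmented`` is the input image with the background zeroed.  Stage
    failures are re-raised as :class:`StageError` carrying the stage name.
    """
    config = config or SegConfig()
    image = validate_rgb(image)

    def run(stage: str, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:  # noqa: BLE001 - wrapped with stage context
            if isinstance(exc, StageError):
                raise
            raise StageError(stage, exc) from exc

    cc = run("color_constancy", color_constancy, image, config.grayscale_weights)
    m = run("extract_magenta", extract_magenta, cc)
    s = run("extract_saturation", extract_saturation, cc)
    prod = run("hadamard_enhance", hadamard_enhance, m, s)
    smooth = run("bilateral_smooth", bilateral_smooth, prod, config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        binary = run("otsu_binarize", otsu_binarize, smooth)
    mask = run("refine_mask", refine_mask, binary, config)
    segmented = image * mask[..., None].astype(np.uint8)
    return mask, segmented
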