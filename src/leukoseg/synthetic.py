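"""Synthetic test-data generators.

Two deterministic generators make every module testable without downloads:

* :func:`make_smear` draws a stained-blood-smear-like image: a pinkish
  background, disk-shaped red cells (pink: low Magenta x Saturation product),
  and irregular purple nucleus blobs (high product) whose exact union is the
  ground-truth mask.  Nucleus outlines are radial-frequency-perturbed
  ellipses, so the morphological refinement stages have real work to do.

* :func:`make_logits` samples 3-class Gaussian logit clouds with controllable
  centroid separation and spread, for the cluster-separability analysis.

Both are pure functions of their parameter structs (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import LogitSet
from .exceptions import ConfigError

PURPLE_NUCLEUS = (115, 45, 140)
PALE_NUCLEUS = (150, 110, 165)     # "hard mode": almost-translucent nuclei
PINK_RBC = (228, 160, 170)
PINK_BACKGROUND = (238, 215, 205)


@dataclass
class SmearParams:
    """Parameters of the synthetic smear generator (all intensities 0-255)."""

    image_size: int = 128
    n_nuclei: int = 2
    nucleus_radius_range: tuple[float, float] = (10.0, 18.0)
    nucleus_color: tuple[int, int, int] = PURPLE_NUCLEUS
    n_rbc: int = 12
    rbc_radius_range: tuple[float, float] = (8.0, 14.0)
    rbc_color: tuple[int, int, int] = PINK_RBC
    background_color: tuple[int, int, int] = PINK_BACKGROUND
    color_jitter_sd: float = 8.0
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for color in (self.nucleus_color, self.rbc_color, self.background_color):
            if any(not 0 <= c <= 255 for c in color):
                raise ConfigError(f"colors must be within [0, 255], got {color}")
        margin = self.nucleus_radius_range[1] * 1.3 + 2
        if self.n_nuclei > 0 and 2 * margin >= self.image_size:
            raise ConfigError(
                f"nuclei of max radius {self.nucleus_radius_range[1]} overflow a "
                f"{self.image_size}px canvas")


def hard_mode(**overrides) -> SmearParams:
    """Preset with low-saturation, almost-translucent nuclei for stress tests."""
    return SmearParams(nucleus_color=PALE_NUCLEUS, **overrides)


def _jitter(rng, color, sd) -> np.ndarray:
    return np.clip(np.asarray(color, float) + rng.normal(0, sd, 3), 0, 255)


def _blob_alpha(size: int, cy: float, cx: float, r0: float, rng) -> np.ndarray:
    """Soft coverage map of one irregular nucleus blob.

    The outline is an ellipse whose radius is modulated by a few low-order
    radial harmonics; the returned alpha is 1 inside, 0 outside, with a
    ~1-px anti-aliased boundary.
    """
    aspect = rng.uniform(0.7, 1.0)
    theta0 = rng.uniform(0, 2 * np.pi)
    amps = rng.uniform(0.03, 0.10, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    # rotate then squeeze one axis to get an ellipse
    ca, sa = np.cos(theta0), np.sin(theta0)
    u = ca * dx + sa * dy
    v = (-sa * dx + ca * dy) / aspect
    dist = np.hypot(u, v)
    ang = np.arctan2(v, u)
    radius = r0 * (1.0 + sum(a * np.cos(k * ang + p)
                             for k, a, p in zip((2, 3, 5), amps, phases)))
    return np.clip(radius + 0.5 - dist, 0.0, 1.0)


def _disk_alpha(size: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    return np.clip(r + 0.5 - np.hypot(yy - cy, xx - cx), 0.0, 1.0)


def make_smear(params: SmearParams | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Generate one synthetic smear; returns (RGB uint8 image, boolean GT mask)."""
    p = params or SmearParams()
    rng = np.random.default_rng(p.seed)
    size = p.image_size
    canvas = np.ones((size, size, 3), dtype=np.float64) * _jitter(
        rng, p.background_color, p.color_jitter_sd)

    for _ in range(p.n_rbc):
        r = rng.uniform(*p.rbc_radius_range)
        cy, cx = rng.uniform(0, size, 2)
        alpha = _disk_alpha(size, cy, cx, r)[..., None]
        # red cells have a paler center (biconcave look)
        inner = _disk_alpha(size, cy, cx, r * 0.45)[..., None]
        color = _jitter(rng, p.rbc_color, p.color_jitter_sd)
        pale = np.clip(color + 18.0, 0, 255)
        canvas = canvas * (1 - alpha) + alpha * color
        canvas = canvas * (1 - inner * 0.6) + inner * 0.6 * pale

    gt = np.zeros((size, size), dtype=bool)
    margin = p.nucleus_radius_range[1] * 1.3 + 2
    for _ in range(p.n_nuclei):
        r0 = rng.uniform(*p.nucleus_radius_range)
        cy = rng.uniform(margin, size - margin)
        cx = rng.uniform(margin, size - margin)
        alpha = _blob_alpha(size, cy, cx, r0, rng)
        color = _jitter(rng, p.nucleus_color, p.color_jitter_sd)
        canvas = canvas * (1 - alpha[..., None]) + alpha[..., None] * color
        gt |= alpha >= 0.5

    canvas = canvas + rng.normal(0.0, p.noise_sd, canvas.shape)
    image = np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8)
    return image, gt


def make_smear_batch(n: int, seed: int = 0, **overrides) -> list[tuple[np.ndarray, np.ndarray]]:
    """n independent smears with seeds derived from `seed`."""
    return [make_smear(SmearParams(seed=seed * 100003 + i, **overrides))
            for i in range(n)]


@dataclass
class LogitSimParams:
    """Parameters of the 3-class Gaussian logit-cloud generator."""

    centroids: tuple = ((6.0, 0.0, 0.0), (0.0, 6.0, 0.0), (0.0, 0.0, 6.0))
    spread_sd: float = 1.0
    n_per_class: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        cents = [tuple(c) for c in self.centroids]
        if len(cents) != 3 or len(set(cents)) != 3:
            raise ConfigError("need three distinct centroids")
        if any(len(c) != 3 for c in cents):
            raise ConfigError("centroids must be 3-vectors")
        if self.spread_sd <= 0:
            raise ConfigError(f"spread_sd must be > 0, got {self.spread_sd}")
        if self.n_per_class < 2:
            raise ConfigError("need at least 2 samples per class")


def make_logits(params: LogitSimParams | None = None) -> LogitSet:
    """Sample isotropic Gaussian logit clouds around the three class centroids."""
    p = params or LogitSimParams()
    rng = np.random.default_rng(p.seed)
    samples, labels = [], []
    for c, centroid in enumerate(p.centroids, start=1):
        samples.append(np.asarray(centroid, float)
                       + rng.normal(0.0, p.spread_sd, (p.n_per_class, 3)))
        labels.append(np.full(p.n_per_class, c))
    return LogitSet(np.vstack(samples), np.concatenate(labels))
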