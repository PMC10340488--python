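"""Ensemble mask fusion.

The handcrafted and deep-learning segmenters make largely independent false
positives, so their masks are merged by pixelwise logical AND: a pixel is
nucleus only if both methods agree.  This can only reduce false positives
(at a possible cost in recall, which is accepted by design).  An area
opening removes any small fragments the intersection leaves behind.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import remove_small_objects

from .exceptions import ConfigError, DimensionError


@dataclass
class EnsembleConfig:
    """Post-fusion area-opening threshold, pixels."""

    open_min_area: int = 0

    def __post_init__(self) -> None:
        if self.open_min_area < 0:
            raise ConfigError(f"open_min_area must be >= 0, got {self.open_min_area}")


def fuse_masks(handcrafted: np.ndarray, deep: np.ndarray,
               config: EnsembleConfig | None = None) -> np.ndarray:
    """Pixelwise AND of two masks followed by area opening.

    The output is a subset of both inputs, so against any ground truth its
    false-positive count is at most the smaller of the two inputs' counts.
    """
    config = config or EnsembleConfig()
    h = np.asarray(handcrafted, dtype=bool)
    d = np.asarray(deep, dtype=bool)
    if h.shape != d.shape:
        raise DimensionError(f"shape mismatch: {h.shape} vs {d.shape}")
    fused = h & d
    if config.open_min_area > 1:
        fused = remove_small_objects(fused, max_size=config.open_min_area - 1,
                                     connectivity=2)
    return fused
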