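"""Contrast enhancement of the minor ROI.

Combined global + local percentile contrast stretching.  The global stage
linearly maps the (low, high) percentile range of the whole image onto
[0, 255]; the local stage repeats the mapping with percentiles taken over a
sliding window centred at each pixel (edge-replicate padding).  Both clip
and round half-up onto the 8-bit grid.  A window at least as large as the
image degenerates to the global stretch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

_OUT_MAX = 255.0


@dataclass(frozen=True)
class EnhanceParams:
    global_percentiles: tuple[float, float] = (2.0, 98.0)
    local_window: int = 15
    local_percentiles: tuple[float, float] = (2.0, 98.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.global_percentiles, self.local_percentiles):
            if not (0 <= lo < hi <= 100):
                raise ValueError("percentiles must satisfy 0 <= low < high <= 100")
        if self.local_window < 3 or self.local_window % 2 == 0:
            raise ValueError("local_window must be odd and >= 3")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def global_stretch(image: np.ndarray, params: EnhanceParams | None = None) -> np.ndarray:
    """Percentile min-max stretch onto [0, 255]; constant images pass through."""
    params = params or EnhanceParams()
    image = np.asarray(image, dtype=float)
    lo, hi = np.percentile(image, params.global_percentiles)
    if hi <= lo:
        return image.copy()
    out = (image - lo) / (hi - lo) * _OUT_MAX
    return _round_half_up(np.clip(out, 0.0, _OUT_MAX))


def local_stretch(image: np.ndarray, params: EnhanceParams | None = None) -> np.ndarray:
    """Sliding-window percentile stretch; flat windows leave pixels unchanged."""
    params = params or EnhanceParams()
    image = np.asarray(image, dtype=float)
    w = params.local_window
    if w > max(image.shape):
        raise ValueError(f"local_window {w} larger than image {image.shape}")
    if w >= max(image.shape) and w >= min(image.shape):
        # window covers the whole image everywhere: global limit
        gp = EnhanceParams(global_percentiles=params.local_percentiles)
        return global_stretch(image, gp)
    plo, phi = params.local_percentiles
    lo = ndi.percentile_filter(image, percentile=plo, size=w, mode="nearest")
    hi = ndi.percentile_filter(image, percentile=phi, size=w, mode="nearest")
    span = hi - lo
    flat = span <= 0
    span = np.where(flat, 1.0, span)
    out = (image - lo) / span * _OUT_MAX
    out = np.where(flat, image, _round_half_up(np.clip(out, 0.0, _OUT_MAX)))
    return out


def enhance_roi(image: np.ndarray, params: EnhanceParams | None = None) -> np.ndarray:
    """Global stretch followed by local stretch (deterministic)."""
    params = params or EnhanceParams()
    return local_stretch(global_stretch(image, params), params)
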