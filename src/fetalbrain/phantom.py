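"""Synthetic fetal-head phantom generator.

Single-slice T2-like phantoms provide ground truth for every downstream
stage: a textured maternal-tissue band touching the image border, a dark
CSF/amniotic gap, a bright thin skull ellipse, and a speckle-textured brain
interior.  Abnormal phantoms additionally carry a lesion — a texture and
intensity change confined to the upper-right quadrant of the brain bounding
box, mimicking a focal abnormality in the region the classifier inspects.

Geometry is drawn once per seed (centres/axes jittered within +-10% of the
defaults) and shared between the two class labels, so a healthy/abnormal
pair generated from the same seed differs only inside the lesion quadrant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

HEALTHY = "healthy"
ABNORMAL = "abnormal"
LABELS = (HEALTHY, ABNORMAL)

# intensity plateaus (8-bit scale) of the four anatomical compartments
_BG = 15.0
_MATERNAL = 120.0
_GAP = 35.0
_SKULL = 225.0
_BRAIN = 140.0


@dataclass(frozen=True)
class TextureParams:
    """Per-class speckle controls for the multiplicative texture model.

    ``grain`` is the Gaussian smoothing sigma (px) of the white-noise field
    — larger grain means coarser, smoother speckle; ``amplitude`` is the
    relative modulation depth.  The lesion overrides apply inside the
    abnormal-class lesion quadrant only.
    """

    grain: float = 2.5
    amplitude: float = 0.18
    lesion_grain: float = 0.8
    lesion_amplitude: float = 0.30


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the phantom generator.

    Defaults define the study conditions for all property and acceptance
    tests: 256 px frames, mild additive noise, and a lesion whose combined
    intensity offset and speckle change is recoverable by second-order
    texture statistics.
    """

    image_size: int = 256
    noise_sigma: float = 2.0
    lesion_contrast: float = 25.0
    texture_params: TextureParams = field(default_factory=TextureParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class LabeledPhantom:
    image: np.ndarray  # uint8, (size, size)
    brain_mask: np.ndarray  # bool, ground truth: filled skull outer ellipse
    label: str


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  axes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def _speckle(rng: np.random.Generator, shape: tuple[int, int],
             grain: float, amplitude: float) -> np.ndarray:
    """Multiplicative texture field 1 + amplitude * smoothed unit noise."""
    g = ndi.gaussian_filter(rng.standard_normal(shape), grain)
    s = g.std()
    if s > 0:
        g = g / s
    return 1.0 + amplitude * g


def lesion_box(brain_mask: np.ndarray) -> tuple[int, int, int, int]:
    """Upper-right quadrant of the brain-mask bounding box, (r0, c0, h, w)."""
    rows = np.flatnonzero(brain_mask.any(axis=1))
    cols = np.flatnonzero(brain_mask.any(axis=0))
    r0, h = rows[0], rows[-1] - rows[0] + 1
    c0, w = cols[0], cols[-1] - cols[0] + 1
    return (int(r0), int(c0 + w - w // 2), int(h // 2), int(w // 2))


def generate_phantom(spec: PhantomSpec, label: str) -> LabeledPhantom:
    """Render one phantom slice with its ground-truth brain mask.

    The abnormal variant is rendered from the same random draws as the
    healthy one; the lesion (texture + contrast offset) uses a dedicated
    stream and touches only pixels in the upper-right brain quadrant.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    size = spec.image_size
    shape = (size, size)
    rng = np.random.default_rng(spec.seed)
    tp = spec.texture_params

    # jittered concentric geometry, +-10% of defaults
    jit = lambda v: v * (1.0 + 0.1 * rng.uniform(-1, 1))  # noqa: E731
    cr, cc_ = size * 0.5 + size * 0.02 * rng.uniform(-1, 1), \
        size * 0.5 + size * 0.02 * rng.uniform(-1, 1)
    brain_a, brain_b = jit(size * 0.27), jit(size * 0.21)
    skull_th = max(3.0, jit(size * 0.022))
    gap_th = jit(size * 0.055)

    skull_outer = _ellipse_mask(shape, (cr, cc_), (brain_a + skull_th, brain_b + skull_th))
    skull_inner = _ellipse_mask(shape, (cr, cc_), (brain_a, brain_b))
    gap_outer = _ellipse_mask(
        shape, (cr, cc_), (brain_a + skull_th + gap_th, brain_b + skull_th + gap_th))

    img = np.full(shape, _BG)
    maternal = ~gap_outer
    img[maternal] = _MATERNAL
    img[gap_outer] = _GAP
    img[skull_outer] = _SKULL
    img[skull_inner] = _BRAIN

    # textures: maternal band and brain interior get independent speckle
    img = np.where(maternal, img * _speckle(rng, shape, 4.0, 0.15), img)
    brain_tex = _speckle(rng, shape, tp.grain, tp.amplitude)
    img = np.where(skull_inner, _BRAIN * brain_tex, img)

    noise = rng.standard_normal(shape) * spec.noise_sigma

    brain_mask = skull_outer  # ground truth: everything inside the skull outline
    if label == ABNORMAL:
        r0, c0, h, w = lesion_box(brain_mask)
        region = np.zeros(shape, dtype=bool)
        region[r0:r0 + h, c0:c0 + w] = True
        region &= skull_inner
        lesion_rng = np.random.default_rng([spec.seed, 0x1e510])
        lesion_tex = _speckle(lesion_rng, shape, tp.lesion_grain, tp.lesion_amplitude)
        img = np.where(region, (_BRAIN + spec.lesion_contrast) * lesion_tex, img)

    img = np.clip(img + noise, 0, 255)
    image = np.rint(img).astype(np.uint8)
    return LabeledPhantom(image=image, brain_mask=brain_mask, label=label)


def generate_cohort(spec: PhantomSpec, n_per_class: int) -> list[LabeledPhantom]:
    """Balanced list of 2*n_per_class phantoms with per-item derived seeds.

    Item i of each class uses seed ``spec.seed + i`` offsets drawn through a
    SeedSequence spawn so cohorts are deterministic and items distinct.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    seeds = np.random.SeedSequence(spec.seed).generate_state(2 * n_per_class)
    out: list[LabeledPhantom] = []
    k = 0
    for label in LABELS:
        for _ in range(n_per_class):
            item_spec = replace(spec, seed=int(seeds[k] % (2**31 - 1)))
            out.append(generate_phantom(item_spec, label))
            k += 1
    return out
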