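"""Texture feature extraction: Gabor bank, 2-D DWT, GLCM and statistical
descriptors, assembled into six feature subsets.

Subset layout (lengths for the canonical 112 px ROI, G = 8 gray levels):

1. level-4 DWT band coefficients CA4 ++ CH4 ++ CV4 ++ CD4 (196),
2. smoothed Gabor magnitude images, all wavelengths x orientations
   (high-dimensional; reduced by PCA downstream),
3. GLCM + statistical descriptors of the spatial ROI (13),
4. subset 1 ++ subset 3 (209),
5. GLCM + statistical descriptors of the concatenated level-4 DWT
   coefficient grid (13),
6. subset 2 ++ subset 5 (high-dimensional; reduced by PCA downstream).

The wavelet is the discrete Meyer family (``dmey``) with periodization, so
each level halves the band sides (ceil) and four levels on 112 px give
7 x 7 bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage as ndi
from scipy.signal import fftconvolve
from skimage.filters import gabor_kernel

PCA_SUBSETS = (2, 6)  # high-dimensional subsets the pipeline must reduce

STAT_NAMES = ("mean", "variance", "std", "skewness", "entropy",
              "idm", "kurtosis", "rms", "smoothness")
GLCM_NAMES = ("contrast", "correlation", "energy", "homogeneity")


# --------------------------------------------------------------------------
# Gabor filter bank

@dataclass(frozen=True)
class GaborBankSpec:
    """Orientations 0..150 deg in 30-deg steps; wavelengths a geometric
    ladder from 4*sqrt(2) px doubling up to the image hypotenuse."""

    orientations: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)
    wavelengths: tuple[float, ...] | None = None  # None: ladder from image size
    smoothing_sigma: float = 2.0
    bandwidth: float = 1.0

    def resolve_wavelengths(self, shape: tuple[int, int]) -> tuple[float, ...]:
        if self.wavelengths is not None:
            return self.wavelengths
        hyp = float(np.hypot(*shape))
        lam, out = 4.0 * np.sqrt(2.0), []
        while lam <= hyp:
            out.append(lam)
            lam *= 2.0
        return tuple(out)


def gabor_bank(image: np.ndarray, bank: GaborBankSpec | None = None) -> np.ndarray:
    """Concatenated Gaussian-smoothed Gabor magnitude images.

    One complex filter per (wavelength, orientation) pair; the magnitude of
    the full-image response is low-pass filtered and flattened, giving a
    vector of length n_wavelengths * n_orientations * n_pixels.
    """
    bank = bank or GaborBankSpec()
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    wavelengths = bank.resolve_wavelengths(image.shape)
    if not wavelengths or not bank.orientations:
        raise ValueError("empty Gabor bank")
    chunks = []
    for lam in wavelengths:
        for theta_deg in bank.orientations:
            kernel = gabor_kernel(frequency=1.0 / lam,
                                  theta=np.deg2rad(theta_deg),
                                  bandwidth=bank.bandwidth)
            resp = fftconvolve(image, kernel, mode="same")
            mag = ndi.gaussian_filter(np.abs(resp), bank.smoothing_sigma)
            chunks.append(mag.ravel())
    return np.concatenate(chunks)


# --------------------------------------------------------------------------
# Discrete wavelet transform

@dataclass(frozen=True)
class WaveletSpec:
    basis: str = "dmey"
    levels: int = 4
    extension_mode: str = "periodization"


@dataclass
class WaveletCoefficients:
    approx: np.ndarray  # CA at the deepest level
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]  # (CH, CV, CD), deepest first
    spec: WaveletSpec


def dwt_decompose(image: np.ndarray, spec: WaveletSpec | None = None) -> WaveletCoefficients:
    spec = spec or WaveletSpec()
    image = np.asarray(image, dtype=float)
    if min(image.shape) < 2 ** spec.levels:
        raise ValueError(
            f"image sides {image.shape} too small for {spec.levels} levels")
    coeffs = pywt.wavedec2(image, spec.basis, mode=spec.extension_mode,
                           level=spec.levels)
    return WaveletCoefficients(approx=coeffs[0], details=list(coeffs[1:]),
                               spec=spec)


def dwt_reconstruct(coeffs: WaveletCoefficients) -> np.ndarray:
    return pywt.waverec2([coeffs.approx] + coeffs.details, coeffs.spec.basis,
                         mode=coeffs.spec.extension_mode)


def dwt_feature_vector(coeffs: WaveletCoefficients) -> np.ndarray:
    """Flattened CA_4 ++ CH_4 ++ CV_4 ++ CD_4, in that fixed order."""
    if coeffs.spec.levels < 4:
        raise ValueError("subset 1 requires at least 4 decomposition levels")
    ch, cv, cd = coeffs.details[0]  # deepest level is first in wavedec2 order
    return np.concatenate([coeffs.approx.ravel(), ch.ravel(),
                           cv.ravel(), cd.ravel()])


def level4_coefficient_grid(coeffs: WaveletCoefficients) -> np.ndarray:
    """Deepest-level bands tiled into one 2-D grid (CA CH / CV CD)."""
    ch, cv, cd = coeffs.details[0]
    return np.block([[coeffs.approx, ch], [cv, cd]])


# --------------------------------------------------------------------------
# GLCM

@dataclass
class GLCMatrix:
    P: np.ndarray  # (G, G) joint probabilities
    levels: int
    offset: tuple[int, int]

    @property
    def normalized(self) -> bool:
        return bool(np.isclose(self.P.sum(), 1.0))


def quantize(image: np.ndarray, levels: int) -> np.ndarray:
    """Min-max quantization to integer gray levels 0..levels-1."""
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    if hi <= lo:
        return np.zeros(image.shape, dtype=np.uint8)
    q = np.floor((image - lo) / (hi - lo) * levels)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def compute_glcm(image: np.ndarray, levels: int = 8,
                 offset: tuple[int, int] = (0, 1)) -> GLCMatrix:
    """Normalized non-symmetric co-occurrence matrix at one pixel offset.

    The image is min-max quantized to ``levels`` gray values first; counts
    are accumulated for ordered pairs (p, p+offset) inside the image.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    image = np.asarray(image)
    dr, dc = offset
    h, w = image.shape
    if abs(dr) >= h or abs(dc) >= w:
        raise ValueError(f"offset {offset} does not fit image {image.shape}")
    q = quantize(image, levels).astype(np.int64)
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    counts = np.bincount(a * levels + b,
                         minlength=levels * levels).reshape(levels, levels)
    P = counts / counts.sum()
    return GLCMatrix(P=P.astype(float), levels=levels, offset=(dr, dc))


def glcm_descriptors(glcm: GLCMatrix) -> dict[str, float]:
    """Contrast, correlation, energy, homogeneity of a normalized GLCM.

    correlation = (sum_ij i*j*P(i,j) - mu_x*mu_y) / (sigma_x*sigma_y), with
    the degenerate convention correlation = 0 when either marginal std is 0.
    """
    if not glcm.normalized:
        raise ValueError("GLCM must be normalized (sum to 1)")
    P = glcm.P
    G = glcm.levels
    i = np.arange(G)[:, None]
    j = np.arange(G)[None, :]
    diff = np.abs(i - j)
    contrast = float(np.sum(diff ** 2 * P))
    energy = float(np.sum(P ** 2))
    homogeneity = float(np.sum(P / (1.0 + diff)))
    px, py = P.sum(axis=1), P.sum(axis=0)
    mx, my = float(np.sum(np.arange(G) * px)), float(np.sum(np.arange(G) * py))
    sx = float(np.sqrt(np.sum((np.arange(G) - mx) ** 2 * px)))
    sy = float(np.sqrt(np.sum((np.arange(G) - my) ** 2 * py)))
    if sx * sy > 0:
        correlation = float((np.sum(i * j * P) - mx * my) / (sx * sy))
    else:
        correlation = 0.0
    return {"contrast": contrast, "correlation": correlation,
            "energy": energy, "homogeneity": homogeneity}


# --------------------------------------------------------------------------
# Statistical descriptors

def statistical_descriptors(sample: np.ndarray, glcm: GLCMatrix,
                            glcm_smoothness: bool = True) -> dict[str, float]:
    """Nine named statistics of a pixel sample plus GLCM-based measures.

    mean/variance/std/skewness/kurtosis/RMS are moments of the intensity
    sample (variance with the N-1 denominator; skewness and excess kurtosis
    standardized by the sample std; degenerate sigma = 0 returns 0 for
    both).  entropy (-sum P log P, natural log, 0 log 0 := 0), IDM
    (sum P/(1+(i-j)^2)) and smoothness are evaluated on the normalized GLCM;
    ``glcm_smoothness=False`` switches smoothness to the variance-based form
    1 - 1/(1+sigma^2) of the intensity sample.
    """
    a = np.asarray(sample, dtype=float).ravel()
    n = a.size
    if n < 2:
        raise ValueError("sample must have at least 2 values")
    mean = float(a.mean())
    variance = float(np.sum((a - mean) ** 2) / (n - 1))
    std = float(np.sqrt(variance))
    if std > 0:
        z = (a - mean) / std
        skewness = float(np.mean(z ** 3))
        kurtosis = float(np.mean(z ** 4) - 3.0)
    else:
        skewness = kurtosis = 0.0
    rms = float(np.sqrt(np.mean(a ** 2)))

    P = glcm.P
    nz = P[P > 0]
    entropy = float(-np.sum(nz * np.log(nz)))
    i = np.arange(glcm.levels)[:, None]
    j = np.arange(glcm.levels)[None, :]
    idm = float(np.sum(P / (1.0 + (i - j) ** 2)))
    if glcm_smoothness:
        smoothness = float(1.0 - 1.0 / (1.0 + P.sum()))
    else:
        smoothness = float(1.0 - 1.0 / (1.0 + variance))
    return {"mean": mean, "variance": variance, "std": std,
            "skewness": skewness, "entropy": entropy, "idm": idm,
            "kurtosis": kurtosis, "rms": rms, "smoothness": smoothness}


# --------------------------------------------------------------------------
# Subset assembly

@dataclass(frozen=True)
class FeatureConfig:
    glcm_levels: int = 8
    glcm_offset: tuple[int, int] = (0, 1)
    glcm_smoothness: bool = True
    gabor: GaborBankSpec = field(default_factory=GaborBankSpec)
    wavelet: WaveletSpec = field(default_factory=WaveletSpec)


def _descriptor_block(grid: np.ndarray, config: FeatureConfig
                      ) -> tuple[np.ndarray, list[str]]:
    """13 named GLCM + statistical descriptors of a 2-D grid."""
    glcm = compute_glcm(grid, levels=config.glcm_levels,
                        offset=config.glcm_offset)
    g = glcm_descriptors(glcm)
    s = statistical_descriptors(grid, glcm,
                                glcm_smoothness=config.glcm_smoothness)
    names = list(GLCM_NAMES) + list(STAT_NAMES)
    values = np.array([g[k] for k in GLCM_NAMES] + [s[k] for k in STAT_NAMES])
    return values, names


def assemble_subset(roi: np.ndarray, subset_id: int,
                    config: FeatureConfig | None = None
                    ) -> tuple[np.ndarray, list[str]]:
    """Feature vector and column names for one of the six subsets."""
    config = config or FeatureConfig()
    roi = np.asarray(roi, dtype=float)
    if subset_id == 1:
        vec = dwt_feature_vector(dwt_decompose(roi, config.wavelet))
        return vec, [f"dwt_{i:04d}" for i in range(vec.size)]
    if subset_id == 2:
        vec = gabor_bank(roi, config.gabor)
        return vec, [f"gabor_{i:06d}" for i in range(vec.size)]
    if subset_id == 3:
        vec, names = _descriptor_block(roi, config)
        return vec, [f"spatial_{n}" for n in names]
    if subset_id == 4:
        v1, n1 = assemble_subset(roi, 1, config)
        v3, n3 = assemble_subset(roi, 3, config)
        return np.concatenate([v1, v3]), n1 + n3
    if subset_id == 5:
        grid = level4_coefficient_grid(dwt_decompose(roi, config.wavelet))
        vec, names = _descriptor_block(grid, config)
        return vec, [f"dwt_{n}" for n in names]
    if subset_id == 6:
        v2, n2 = assemble_subset(roi, 2, config)
        v5, n5 = assemble_subset(roi, 5, config)
        return np.concatenate([v2, v5]), n2 + n5
    raise ValueError(f"unknown subset_id {subset_id!r} (expected 1..6)")


def feature_matrix(rois: list[np.ndarray], subset_id: int,
                   config: FeatureConfig | None = None):
    """Stack per-image subset vectors into a pandas DataFrame."""
    import pandas as pd

    config = config or FeatureConfig()
    rows, names = [], None
    for roi in rois:
        vec, names = assemble_subset(roi, subset_id, config)
        rows.append(vec)
    df = pd.DataFrame(np.vstack(rows), columns=names)
    df.attrs["subset_id"] = subset_id
    return df
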