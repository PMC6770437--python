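"""Semi-automatic fetal-brain segmentation.

Six-step chain on a single 2-D slice:

1. adaptive (local-mean) thresholding — removes CSF/amniotic fluid,
2. morphological opening (disk SE) — cuts thin maternal/skull links,
3. border clearing — drops everything connected to the image frame,
4. morphological closing (same SE) — fills small skull gaps,
5. boundary tracing into a parent/children hierarchy, rasterized as filled
   parent regions, then marker-controlled watershed on the distance
   transform (H-minima markers + imposed minima) — separates the brain
   candidate from residual attached structures,
6. area-based selection of the largest region, masking of the input
   (whole brain), and extraction of the upper-right "minor ROI".

Conventions fixed here for reproducibility: pixels outside the image are
background (border_value=0) for erosion/dilation; components use
8-connectivity; watershed ridges use 4-connectivity; ties in area are
broken toward the lowest label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology, segmentation as skseg, transform


class SegmentationError(RuntimeError):
    """Raised when a pipeline step produces an empty/invalid intermediate."""

    def __init__(self, step: str, message: str):
        super().__init__(f"[{step}] {message}")
        self.step = step


@dataclass(frozen=True)
class ThresholdParams:
    """Local-mean threshold: T(i,j) = mean over window + offset."""

    window: int = 31
    offset: float = 5.0

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")


@dataclass(frozen=True)
class StructuringElement:
    shape: str = "disk"
    radius: int = 1

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.shape not in ("disk", "square"):
            raise ValueError("shape must be 'disk' or 'square'")

    def footprint(self) -> np.ndarray:
        if self.shape == "disk":
            return morphology.disk(self.radius).astype(bool)
        return np.ones((2 * self.radius + 1,) * 2, dtype=bool)


@dataclass
class Contour:
    """Closed pixel chain with the area it encloses (px^2)."""

    points: np.ndarray  # (n, 2) row/col vertices from marching squares
    area: float
    parent: int | None = None  # index into parents for child contours


@dataclass
class BoundaryHierarchy:
    parents: list[Contour]
    children: list[Contour]
    region_image: np.ndarray  # filled parent regions (holes filled)


@dataclass
class SegmentedBrain:
    whole_brain: np.ndarray
    brain_mask: np.ndarray
    minor_roi: np.ndarray
    roi_box: tuple[int, int, int, int]  # (row, col, height, width), half-open
    intermediates: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunables of the whole chain; every default is package-chosen."""

    threshold: ThresholdParams | None = None  # None: window from image size
    se: StructuringElement = field(default_factory=StructuringElement)
    h_minima: float = 2.0
    roi_size: int = 112  # canonical minor-ROI side; 4-level DWT bands are 7x7
    roi_mode: str = "auto"
    manual_box: tuple[int, int, int, int] | None = None


def default_threshold_params(image: np.ndarray, offset_frac: float = 0.02) -> ThresholdParams:
    """Window = nearest odd to side/8; offset = 2% of the dynamic range.

    The offset floor (as if the range were one gray level) keeps flat
    images all-background, so degenerate inputs fail fast at this step.
    """
    side = min(image.shape)
    window = max(3, (side // 8) | 1)
    lo, hi = float(image.min()), float(image.max())
    return ThresholdParams(window=window, offset=offset_frac * max(hi - lo, 1.0))


def adaptive_threshold(image: np.ndarray, params: ThresholdParams) -> np.ndarray:
    """Foreground where image >= local mean + offset.

    Windows are clamped to lie fully inside the image (shifted at the
    edges, never padded), so a window as large as the image reduces to the
    global mean at every pixel.
    """
    image = np.asarray(image, dtype=float)
    if params.window > min(image.shape):
        raise ValueError(
            f"window {params.window} larger than image {image.shape}")
    w = params.window
    r = w // 2
    h_img, w_img = image.shape
    ii = np.zeros((h_img + 1, w_img + 1))
    ii[1:, 1:] = image.cumsum(axis=0).cumsum(axis=1)
    rs = np.clip(np.arange(h_img) - r, 0, h_img - w)
    cs = np.clip(np.arange(w_img) - r, 0, w_img - w)
    sums = (ii[np.ix_(rs + w, cs + w)] - ii[np.ix_(rs, cs + w)]
            - ii[np.ix_(rs + w, cs)] + ii[np.ix_(rs, cs)])
    local_mean = sums / (w * w)
    return image >= local_mean + params.offset


def morph_open(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    fp = se.footprint()
    eroded = ndi.binary_erosion(mask, structure=fp, border_value=0)
    return ndi.binary_dilation(eroded, structure=fp, border_value=0)


def morph_close(mask: np.ndarray, se: StructuringElement,
                opening_se: StructuringElement | None = None) -> np.ndarray:
    """Dilation then erosion; warns if the SE differs from the opening's."""
    if opening_se is not None and se != opening_se:
        warnings.warn(
            "closing SE differs from the opening SE of this run; the chain "
            "expects matched elements", stacklevel=2)
    fp = se.footprint()
    dilated = ndi.binary_dilation(mask, structure=fp, border_value=0)
    return ndi.binary_erosion(dilated, structure=fp, border_value=0)


def clear_border(mask: np.ndarray) -> np.ndarray:
    """Remove every 8-connected component touching an image edge."""
    labels = measure.label(mask, connectivity=2)
    border_labels = np.unique(
        np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]]))
    keep = ~np.isin(labels, border_labels[border_labels > 0])
    return mask.astype(bool) & keep


def trace_boundaries(mask: np.ndarray) -> BoundaryHierarchy:
    """Parent (outer) and child (hole) contours, each sorted by descending area.

    The region image fills every parent contour, so interior holes are
    filled; this is what the watershed step consumes.
    """
    mask = mask.astype(bool)
    labels = measure.label(mask, connectivity=2)
    parents: list[Contour] = []
    children: list[tuple[int, Contour]] = []
    region = np.zeros_like(mask)
    for prop in measure.regionprops(labels):
        comp = labels == prop.label
        filled = ndi.binary_fill_holes(comp)
        region |= filled
        outer = measure.find_contours(np.pad(filled, 1).astype(float), 0.5)
        if not outer:
            continue
        main = max(outer, key=len) - 1.0  # undo padding shift
        parents.append(Contour(points=main, area=float(filled.sum())))
        holes = measure.label(filled & ~comp, connectivity=1)
        for hp in measure.regionprops(holes):
            hole_mask = holes == hp.label
            cs = measure.find_contours(np.pad(hole_mask, 1).astype(float), 0.5)
            if cs:
                children.append(
                    (len(parents) - 1,
                     Contour(points=max(cs, key=len) - 1.0,
                             area=float(hole_mask.sum()))))
    order = np.argsort([-p.area for p in parents], kind="stable")
    remap = {old: new for new, old in enumerate(order)}
    parents = [parents[i] for i in order]
    kids = [Contour(points=c.points, area=c.area, parent=remap[pi])
            for pi, c in children]
    kids.sort(key=lambda c: -c.area)
    return BoundaryHierarchy(parents=parents, children=kids, region_image=region)


def _impose_minima(img: np.ndarray, minima: np.ndarray) -> np.ndarray:
    """Morphological-reconstruction minima imposition (imimposemin recipe)."""
    img = img - img.min()
    marker = np.full(img.shape, img.max() + 1.0)
    marker[minima] = 0.0
    mask_img = np.minimum(img + 1.0, marker)
    return morphology.reconstruction(marker, mask_img, method="erosion")


def watershed_split(mask: np.ndarray, h: float = 2.0) -> np.ndarray:
    """Marker-controlled watershed of the mask's distance transform.

    Markers are the extended minima at depth ``h`` of the negated distance
    map; they are imposed as the only regional minima before flooding, which
    suppresses over-segmentation.  Ridge pixels are labelled 0.
    """
    if h < 0:
        raise ValueError("h must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    if not mask.any():
        return labels
    d = ndi.distance_transform_edt(mask)
    inv = -d
    minima = morphology.h_minima(inv, h) if h > 0 else morphology.local_minima(inv)
    minima &= mask
    if not minima.any():  # depth larger than any basin: single region
        minima = d == d.max()
    d_new = _impose_minima(inv, minima)
    markers = measure.label(minima, connectivity=2)
    ws = skseg.watershed(d_new, markers=markers, mask=mask,
                         connectivity=1, watershed_line=True)
    # relabel contiguous from 1
    present = np.unique(ws[ws > 0])
    lut = np.zeros(int(ws.max()) + 1, dtype=np.int32)
    lut[present] = np.arange(1, len(present) + 1)
    return lut[ws]


def area_select(labels: np.ndarray) -> np.ndarray:
    """Mask of the largest-area region; ties go to the lowest label."""
    labels = np.asarray(labels)
    if labels.max() < 1:
        raise ValueError("no labelled regions to select from")
    counts = np.bincount(labels.ravel())
    counts[0] = -1
    best = int(np.argmax(counts))  # argmax returns the first (lowest) tie
    return labels == best


def region_areas_descending(labels: np.ndarray) -> list[tuple[int, int]]:
    """(label, area) pairs sorted by descending area (lowest label on ties)."""
    counts = np.bincount(np.asarray(labels).ravel())
    pairs = [(lab, int(a)) for lab, a in enumerate(counts) if lab > 0 and a > 0]
    return sorted(pairs, key=lambda p: (-p[1], p[0]))


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    return np.where(mask, image, 0)


def _bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return (int(rows[0]), int(cols[0]),
            int(rows[-1] - rows[0] + 1), int(cols[-1] - cols[0] + 1))


def upper_right_quadrant(bbox: tuple[int, int, int, int]) -> tuple[int, int, int, int]:
    r0, c0, h, w = bbox
    return (r0, c0 + w - w // 2, h // 2, w // 2)


def extract_minor_roi(brain: np.ndarray, mask: np.ndarray, mode: str = "auto",
                      box: tuple[int, int, int, int] | None = None,
                      roi_size: int = 112) -> SegmentedBrain:
    """Crop the abnormality-bearing sub-region and resize it canonically.

    ``auto`` crops the upper-right quadrant of the brain-mask bounding box;
    ``manual`` crops a user-supplied (r, c, h, w) box, standing in for the
    operator-drawn borderline of the interactive workflow.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if mode == "auto":
        roi_box = upper_right_quadrant(_bbox(mask))
    elif mode == "manual":
        if box is None:
            raise ValueError("manual mode requires a box")
        roi_box = tuple(int(v) for v in box)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    r0, c0, h, w = roi_box
    if r0 < 0 or c0 < 0 or h < 1 or w < 1 or \
            r0 + h > brain.shape[0] or c0 + w > brain.shape[1]:
        raise ValueError(f"box {roi_box} outside image {brain.shape}")
    crop = np.asarray(brain, dtype=float)[r0:r0 + h, c0:c0 + w]
    roi = transform.resize(crop, (roi_size, roi_size), order=1,
                           preserve_range=True, anti_aliasing=False)
    return SegmentedBrain(whole_brain=apply_mask(brain, mask),
                          brain_mask=mask, minor_roi=roi, roi_box=roi_box)


def segment_brain(image: np.ndarray, config: SegmentationConfig | None = None
                  ) -> SegmentedBrain:
    """Run the full six-step chain; intermediates are kept for inspection."""
    config = config or SegmentationConfig()
    image = np.asarray(image, dtype=float)
    params = config.threshold or default_threshold_params(image)
    inter: dict[str, np.ndarray] = {}

    binary = adaptive_threshold(image, params)
    inter["binary"] = binary
    if not binary.any():
        raise SegmentationError("adaptive_threshold", "empty foreground")

    opened = morph_open(binary, config.se)
    inter["open"] = opened
    if not opened.any():
        raise SegmentationError("morph_open", "empty foreground")

    cleared = clear_border(opened)
    inter["clear"] = cleared
    if not cleared.any():
        raise SegmentationError("clear_border", "empty foreground")

    closed = morph_close(cleared, config.se, opening_se=config.se)
    inter["close"] = closed
    if not closed.any():
        raise SegmentationError("morph_close", "empty foreground")

    hierarchy = trace_boundaries(closed)
    region = hierarchy.region_image
    inter["region"] = region
    if not region.any():
        raise SegmentationError("trace_boundaries", "empty region image")

    ws = watershed_split(region, h=config.h_minima)
    inter["watershed"] = ws
    if ws.max() < 1:
        raise SegmentationError("watershed_split", "no regions")

    brain_mask = area_select(ws)
    inter["abs"] = brain_mask

    seg = extract_minor_roi(image, brain_mask, mode=config.roi_mode,
                            box=config.manual_box, roi_size=config.roi_size)
    seg.intermediates.update(inter)
    return seg
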