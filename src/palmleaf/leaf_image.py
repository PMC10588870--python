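"""Leaf silhouette segmentation and calibrated measurement.

The photographic protocol places a single detached leaf on a white chart,
flattened under acrylic, photographed perpendicularly with a scale
reference in view.  Under those conditions the luminance histogram is
bimodal, so a global Otsu threshold separates the (darker) leaf from the
background; rulers and chart edges are suppressed by discarding
components that touch a border margin, and the leaf is the largest
remaining component.  Areas are pixel counts divided by ppcm², lengths
are extents divided by ppcm.

Two descriptor conventions are offered:

``axis-extent`` (default)
    L = silhouette extent along the principal axis of the second-moment
    ellipse, W = extent along the perpendicular axis.  Deterministic and
    robust for any shape.
``tip-based``
    Lobe tips are detected as local maxima of the contour's radial
    distance from the centroid; L is the largest tip-to-tip distance and
    W the widest tip span perpendicular to it.  Matches the field
    convention of measuring between leaflet apices on palmate leaves,
    and stays well-defined for leaves whose silhouette is nearly
    isotropic (where a principal axis is ill-conditioned).

Both are reported in cm.  Raster convention: row-major, origin top-left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage import measure as skmeasure
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu

__all__ = [
    "LeafImage",
    "LeafMask",
    "Descriptors",
    "SegmentationConfig",
    "NoLeafFoundError",
    "MarkerNotFoundError",
    "DegenerateMaskError",
    "read_image",
    "segment_leaf",
    "measure_area",
    "measure_descriptors",
    "calibrate_scale",
]


class NoLeafFoundError(RuntimeError):
    """No foreground component above the minimum area: no leaf found."""


class MarkerNotFoundError(RuntimeError):
    """The scale fiducial could not be detected in the search region."""


class DegenerateMaskError(RuntimeError):
    """The mask collapses to a single row or column; descriptors undefined."""


@dataclass
class LeafImage:
    """A photograph (or rendering) of one leaf plus its scale.

    ``pixels`` is a 2-D grayscale or 3-D colour raster; ``ppcm`` the
    pixels-per-centimetre calibration (> 0).
    """

    pixels: np.ndarray
    ppcm: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.size == 0 or self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be a non-empty 2-D or 3-D raster")
        if not self.ppcm > 0:
            raise ValueError("ppcm must be > 0")

    def luminance(self) -> np.ndarray:
        if self.pixels.ndim == 3:
            return rgb2gray(self.pixels[..., :3])
        return self.pixels.astype(float)


@dataclass
class LeafMask:
    """Calibrated binary leaf silhouette (foreground = leaf)."""

    mask: np.ndarray
    ppcm: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.ppcm > 0:
            raise ValueError("ppcm must be > 0")
        if self.mask.ndim != 2 or not self.mask.any():
            raise ValueError("mask must be 2-D with at least one foreground pixel")

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class Descriptors:
    """Leaf length L and width W, cm."""

    L: float
    W: float

    def __post_init__(self) -> None:
        if not (self.L > 0 and self.W > 0):
            raise ValueError("descriptors must be > 0")


@dataclass(frozen=True)
class SegmentationConfig:
    """Knobs of :func:`segment_leaf`.

    ``threshold``: fixed luminance threshold overriding Otsu (same scale
    as the luminance image).  ``border_margin_frac``: components touching
    a border band of this fraction of the smaller image side are
    discarded (rulers, chart edges, fiducials).  ``min_area_px``: below
    this the image is treated as empty.
    """

    threshold: float | None = None
    leaf_darker: bool = True
    border_margin_frac: float = 0.02
    fill_holes: bool = True
    min_area_px: int = 64


def read_image(path, ppcm: float) -> LeafImage:
    """Load a PNG/TIFF/JPEG photograph with a known scale."""
    import imageio.v3 as iio

    return LeafImage(pixels=iio.imread(path), ppcm=ppcm)


def segment_leaf(image: LeafImage, config: SegmentationConfig | None = None) -> LeafMask:
    """Extract the leaf silhouette from a bright-background photograph.

    Global threshold (Otsu on luminance unless fixed), discard components
    touching the border margin, fill interior holes, keep the largest
    connected component.

    Raises
    ------
    NoLeafFoundError
        If no component of at least ``min_area_px`` pixels survives
        (e.g. an all-white image).
    """
    cfg = config or SegmentationConfig()
    lum = image.luminance()
    if np.ptp(lum) == 0:
        raise NoLeafFoundError("no leaf found: image has no contrast")
    thresh = cfg.threshold if cfg.threshold is not None else threshold_otsu(lum)
    fg = lum < thresh if cfg.leaf_darker else lum > thresh

    eight = np.ones((3, 3), dtype=int)  # 8-connectivity keeps thin lobe tips
    labels, n = ndimage.label(fg, structure=eight)
    if n == 0:
        raise NoLeafFoundError("no leaf found: empty foreground")

    margin = max(1, int(round(cfg.border_margin_frac * min(fg.shape))))
    band = np.zeros_like(fg, dtype=bool)
    band[:margin, :] = band[-margin:, :] = True
    band[:, :margin] = band[:, -margin:] = True
    touching = np.unique(labels[band & fg])
    keep = fg & ~np.isin(labels, touching[touching > 0])
    if not keep.any():
        raise NoLeafFoundError("no leaf found: all components touch the border margin")

    if cfg.fill_holes:
        keep = ndimage.binary_fill_holes(keep)
    labels, n = ndimage.label(keep, structure=eight)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < cfg.min_area_px:
        raise NoLeafFoundError(
            f"no leaf found: largest component has {int(sizes[best - 1])} px "
            f"(minimum {cfg.min_area_px})"
        )
    return LeafMask(mask=labels == best, ppcm=image.ppcm)


def measure_area(mask: LeafMask) -> float:
    """Leaf area in cm²: foreground pixel count / ppcm²."""
    return mask.n_foreground / mask.ppcm**2


def _principal_axes(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centroid and unit major/minor axes of the foreground pixels,
    in (x=col, y=row) coordinates."""
    rows, cols = np.nonzero(mask)
    pts = np.column_stack([cols.astype(float), rows.astype(float)])
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    w, vecs = np.linalg.eigh(cov)
    major = vecs[:, int(np.argmax(w))]
    minor = np.array([-major[1], major[0]])
    return centroid, major, minor


def measure_descriptors(mask: LeafMask, method: str = "axis-extent") -> Descriptors:
    """Measure the leaf descriptors L and W (cm) from a silhouette.

    See the module docstring for the two methods.  The larger span is L
    by construction of the principal axis under ``axis-extent``; under
    ``tip-based`` L is the tip span along the principal axis whatever its
    magnitude.
    """
    rows, cols = np.nonzero(mask.mask)
    if rows.max() == rows.min() or cols.max() == cols.min():
        raise DegenerateMaskError("mask is a single row/column")
    centroid, major, minor = _principal_axes(mask.mask)

    if method == "axis-extent":
        pts = np.column_stack([cols.astype(float), rows.astype(float)]) - centroid
        span_l = np.ptp(pts @ major) + 1.0  # + 1 px for the pixel footprint
        span_w = np.ptp(pts @ minor) + 1.0
    elif method == "tip-based":
        from .synthetic import tip_spans

        tips = _detect_tips(mask.mask, centroid)
        span_l, span_w, _ = tip_spans(tips)
    else:
        raise ValueError(f"unknown descriptor method {method!r}")
    if span_l <= 0 or span_w <= 0:
        raise DegenerateMaskError("degenerate spans")
    return Descriptors(L=span_l / mask.ppcm, W=span_w / mask.ppcm)


def _detect_tips(mask: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Lobe tips: local maxima of the contour's radial distance profile.

    The profile is smoothed circularly and rotated so its global minimum
    sits at the boundary, then peaks are kept by prominence (relative to
    the radial range) and a minimum angular separation.
    Returns tip coordinates as (x=col, y=row) pairs.
    """
    contours = skmeasure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)  # (row, col)
    xy = np.column_stack([contour[:, 1], contour[:, 0]])
    r = np.hypot(*(xy - centroid).T)
    n = len(r)
    win = max(3, n // 100)
    kernel = np.ones(win) / win
    r_s = np.convolve(np.r_[r[-win:], r, r[:win]], kernel, mode="same")[win:-win]
    shift = int(np.argmin(r_s))
    rolled = np.roll(r_s, -shift)
    # genuine lobe apices rise far above the inter-lobe notches; shallow
    # bumps near the petiole attachment stay well under this cut
    prom = 0.20 * float(np.ptp(r_s))
    peaks, _ = find_peaks(rolled, prominence=prom, distance=max(5, n // 40))
    if len(peaks) < 2:
        # nearly convex silhouette: fall back to the two contour points
        # extremal along the major axis
        proj = (xy - centroid) @ _principal_axes(mask)[1]
        peaks_idx = np.array([int(np.argmin(proj)), int(np.argmax(proj))])
        return xy[peaks_idx]
    idx = (peaks + shift) % n
    # snap each smoothed peak to the raw radial maximum nearby, then
    # extrapolate past the rasterisation cut-off
    snapped = []
    for i in idx:
        nb = np.arange(i - win, i + win + 1) % n
        snapped.append(int(nb[np.argmax(r[nb])]))
    return np.array([_refine_tip(xy, i, centroid) for i in snapped])


def _refine_tip(xy: np.ndarray, i: int, centroid: np.ndarray,
                depth: float = 14.0, max_extend: float = 8.0) -> np.ndarray:
    """Sub-pixel apex of one lobe by extrapolating its width taper.

    Rasterisation truncates a tapering lobe where it becomes thinner than
    one pixel, so the extremal contour point sits short of the true apex.
    The lobe's half-width is measured in 1-px bins of distance below the
    detected peak and extrapolated linearly to zero width; the apex may
    move at most ``max_extend`` px outward (otherwise the raw peak is
    kept).
    """
    n = len(xy)
    tip = xy[i]
    u = tip - centroid
    u = u / np.linalg.norm(u)
    perp = np.array([-u[1], u[0]])
    # walk the contour both ways until `depth` px below the apex
    take = min(n // 2, int(depth * 4))
    pts = xy[np.arange(i - take, i + take + 1) % n] - tip
    d = -(pts @ u)  # distance below the apex, px
    h = pts @ perp
    sel = (d >= 0) & (d <= depth)
    if sel.sum() < 6:
        return tip
    d, h = d[sel], h[sel]
    bins = np.floor(d).astype(int)
    widths, centers = [], []
    for b in np.unique(bins):
        hb = h[bins == b]
        if hb.size >= 2:
            widths.append((hb.max() - hb.min()) / 2.0)
            centers.append(b + 0.5)
    if len(widths) < 4:
        return tip
    w = np.asarray(widths)
    c = np.asarray(centers)
    slope, intercept = np.polyfit(c, w, 1)
    if slope <= 0.02:  # not a tapering lobe
        return tip
    extend = float(intercept / slope)  # where the width profile hits zero
    if not (-1.0 <= extend <= max_extend):
        return tip
    return tip + u * max(extend, 0.0)


def calibrate_scale(
    image: LeafImage | np.ndarray,
    marker_cm: float,
    corner: str = "top-left",
    search_frac: float = 0.4,
    min_area_px: int = 25,
) -> float:
    """Pixels-per-cm from a dark square fiducial of known side length.

    Searches the given corner region for a component that is square
    (bounding-box aspect within 4:3, fill ratio ≥ 0.8) and returns
    ``sqrt(pixel area) / marker_cm``.  Supplying ``ppcm`` directly in the
    run configuration bypasses this step entirely.

    Raises
    ------
    MarkerNotFoundError
        If no square-like component is present in the region.
    """
    pixels = image.pixels if isinstance(image, LeafImage) else np.asarray(image)
    lum = rgb2gray(pixels[..., :3]) if pixels.ndim == 3 else pixels.astype(float)
    h, w = lum.shape
    rh, rw = max(1, int(h * search_frac)), max(1, int(w * search_frac))
    regions = {
        "top-left": (slice(0, rh), slice(0, rw)),
        "top-right": (slice(0, rh), slice(w - rw, w)),
        "bottom-left": (slice(h - rh, h), slice(0, rw)),
        "bottom-right": (slice(h - rh, h), slice(w - rw, w)),
    }
    try:
        window = lum[regions[corner]]
    except KeyError:
        raise ValueError(f"unknown corner {corner!r}") from None
    if np.ptp(window) == 0:
        raise MarkerNotFoundError("marker not detected: corner region is blank")
    dark = window < threshold_otsu(window)
    labels, n = ndimage.label(dark)
    best_area = 0
    for lab in range(1, n + 1):
        rr, cc = np.nonzero(labels == lab)
        area = rr.size
        if area < min_area_px:
            continue
        bh, bw = np.ptp(rr) + 1, np.ptp(cc) + 1
        aspect = bh / bw if bw else np.inf
        fill = area / (bh * bw)
        if 0.75 <= aspect <= 4 / 3 and fill >= 0.8 and area > best_area:
            best_area = area
    if best_area == 0:
        raise MarkerNotFoundError("marker not detected")
    return float(np.sqrt(best_area) / marker_cm)
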