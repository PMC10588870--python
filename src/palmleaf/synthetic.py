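"""Synthetic palmate leaves with exact ground truth.

Real cassava leaves are palmate: 3–7 lanceolate lobes radiating from the
petiole attachment point.  This module builds such silhouettes as exact
polygons (vector geometry, resolution-independent), so that every pipeline
stage — rasterisation, segmentation, area and descriptor measurement,
clustering, model fitting — can be tested against known truth without any
photographic data.

Each lobe is a lanceolate outline with half-width profile

    w(t) = lobe_width_ratio · l · sin(π t) ** shape_exponent,   t ∈ [0, 1]

along its axis (length l), tapering to a point at both ends for any
positive exponent; the exponent-0 limit is a rectangle.  Lobes are unioned
with a small circular attachment pad into a single simple polygon.  The
ground-truth area is the shoelace area of that polygon; the ground-truth
descriptors follow the tip-geometry convention of :func:`tip_spans` —
L is the largest leaflet-apex-to-apex distance and W the widest apex
span across that axis — the same convention the tip-based image
measurement uses.

Leaf *populations* (L, W, LA records without silhouettes) are sampled to
match the descriptor envelope observed for cassava: L in 6.28–29.26 cm,
W in 5.00–40.58 cm, with area following LA = a·L·W up to multiplicative
noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from matplotlib.path import Path as MplPath
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union

from .io import LeafRecord

__all__ = [
    "TABLE_L_RANGE",
    "TABLE_W_RANGE",
    "SyntheticLeafSpec",
    "GroundTruth",
    "shoelace_area",
    "polygon_moments",
    "principal_axis",
    "tip_spans",
    "generate_leaf",
    "render_leaf",
    "generate_population",
    "generate_plant_truths",
]

#: Descriptor envelope of the cassava reference dataset (cm).
TABLE_L_RANGE = (6.28, 29.26)
TABLE_W_RANGE = (5.00, 40.58)

#: Default ratio W/L used by the correlated population sampler; the
#: midpoints of the two ranges give ≈ 1.28.
DEFAULT_WL_RATIO = 1.28


@dataclass(frozen=True)
class SyntheticLeafSpec:
    """Shape parameters of one synthetic palmate leaf.

    ``n_lobes`` is 3–7 for realistic cassava leaves; a single-lobe
    override is accepted for degenerate test shapes.  ``seed`` drives the
    optional per-lobe jitter (``angle_jitter_deg``, ``ratio_jitter``);
    with zero jitter the leaf is a pure function of the spec.
    """

    n_lobes: int = 5
    central_lobe_length: float = 12.0  # cm
    lobe_length_ratios: tuple[float, ...] | None = None
    angular_spread: float = 200.0  # degrees, tip-to-tip fan opening
    lobe_width_ratio: float = 0.25  # max lobe width / lobe length
    shape_exponent: float = 1.5  # lanceolate taper; 0 = rectangle limit
    attachment_pad_fraction: float = 0.05  # pad radius / central length
    angle_jitter_deg: float = 0.0
    ratio_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_lobes == 1 or 3 <= self.n_lobes <= 7):
            raise ValueError("n_lobes must be 3..7 (or 1 for degenerate shapes)")
        if not self.central_lobe_length > 0:
            raise ValueError("central_lobe_length must be > 0")
        if not 0 < self.angular_spread < 360:
            raise ValueError("angular_spread must be in (0, 360)")
        if not self.lobe_width_ratio > 0:
            raise ValueError("lobe_width_ratio must be > 0")
        if self.shape_exponent < 0:
            raise ValueError("shape_exponent must be >= 0")

    def lobe_angles(self) -> np.ndarray:
        """Lobe axis directions, degrees clockwise from the +y (apex) axis."""
        if self.n_lobes == 1:
            return np.array([0.0])
        return np.linspace(-self.angular_spread / 2, self.angular_spread / 2, self.n_lobes)

    def default_ratios(self, angles: np.ndarray) -> np.ndarray:
        # shorter lobes toward the base, central lobe longest
        half = self.angular_spread / 2 if self.n_lobes > 1 else 1.0
        return 1.0 - 0.45 * (np.abs(angles) / half) ** 1.2


@dataclass(frozen=True)
class GroundTruth:
    """Exact geometry of one synthetic leaf (all coordinates in cm).

    ``polygon`` is the closed outline (first vertex repeated last);
    ``area`` its shoelace area; ``tips`` the lobe apex coordinates;
    ``L`` and ``W`` the tip spans of :func:`tip_spans` and ``axis`` the
    unit vector of the L direction (principal-axis silhouette extents
    for single-lobe shapes).
    """

    polygon: np.ndarray
    area: float
    L: float
    W: float
    tips: np.ndarray
    axis: np.ndarray
    spec: SyntheticLeafSpec


def shoelace_area(vertices: np.ndarray) -> float:
    """Unsigned polygon area by the shoelace formula.

    Accepts open or closed vertex lists; translation- and
    rotation-invariant by construction.
    """
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def polygon_moments(vertices: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Exact area, centroid and central second-moment (covariance) matrix
    of a simple polygon, from the standard shoelace-based integrals."""
    v = np.asarray(vertices, dtype=float)
    if not np.allclose(v[0], v[-1]):
        v = np.vstack([v, v[0]])
    x0, y0 = v[:-1, 0], v[:-1, 1]
    x1, y1 = v[1:, 0], v[1:, 1]
    cross = x0 * y1 - x1 * y0
    a = float(np.sum(cross) / 2.0)
    cx = float(np.sum((x0 + x1) * cross) / (6.0 * a))
    cy = float(np.sum((y0 + y1) * cross) / (6.0 * a))
    ixx = float(np.sum(cross * (y0**2 + y0 * y1 + y1**2)) / 12.0)  # ∫ y² dA
    iyy = float(np.sum(cross * (x0**2 + x0 * x1 + x1**2)) / 12.0)  # ∫ x² dA
    ixy = float(np.sum(cross * (x0 * y1 + 2 * x0 * y0 + 2 * x1 * y1 + x1 * y0)) / 24.0)
    # central moments, normalised to a covariance of the uniform lamina
    var_x = iyy / a - cx**2
    var_y = ixx / a - cy**2
    cov_xy = ixy / a - cx * cy
    cov = np.array([[var_x, cov_xy], [cov_xy, var_y]])
    return abs(a), np.array([cx, cy]), cov


def principal_axis(vertices: np.ndarray) -> np.ndarray:
    """Unit vector of the silhouette's major axis (largest-variance
    direction of the uniform lamina)."""
    _, _, cov = polygon_moments(vertices)
    w, vecs = np.linalg.eigh(cov)
    u = vecs[:, int(np.argmax(w))]
    # fix the sign for reproducibility; spans are sign-independent
    if u[1] < 0 or (u[1] == 0 and u[0] < 0):
        u = -u
    return u


def tip_spans(tips: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Descriptors from lobe-tip geometry, as Feret diameters.

    L is the maximum Feret diameter of the apex set (the largest
    apex-to-apex distance, whose direction defines the leaf axis) and W
    the minimum Feret width (the smallest cross-direction extent of the
    apices).  Both are continuous functions of the tip coordinates, so
    small raster-measurement noise cannot flip them between near-tied
    apex pairs — unlike conventions that pick one axis pair discretely,
    which are unstable for the nearly symmetric silhouettes common in
    palmate leaves.
    """
    tips = np.asarray(tips, dtype=float)
    diff = tips[:, None, :] - tips[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    i, j = np.unravel_index(int(np.argmax(dist)), dist.shape)
    L = float(dist[i, j])
    axis = (tips[i] - tips[j]) / L if L > 0 else np.array([0.0, 1.0])
    # minimum width by rotating calipers over hull-edge directions
    try:
        from scipy.spatial import ConvexHull

        hull = tips[ConvexHull(tips).vertices]
    except Exception:  # collinear or tiny tip sets
        perp = np.array([-axis[1], axis[0]])
        return L, float(np.ptp(tips @ perp)), axis
    W = np.inf
    m = len(hull)
    for k in range(m):
        e = hull[(k + 1) % m] - hull[k]
        norm = np.hypot(*e)
        if norm == 0:
            continue
        n_vec = np.array([-e[1], e[0]]) / norm
        W = min(W, float(np.ptp(hull @ n_vec)))
    return L, float(W), axis


def _extent_spans(vertices: np.ndarray, axis: np.ndarray) -> tuple[float, float]:
    perp = np.array([-axis[1], axis[0]])
    return float(np.ptp(vertices @ axis)), float(np.ptp(vertices @ perp))


def _lobe_polygon(length: float, angle_deg: float, width_ratio: float,
                  exponent: float, n_samples: int = 48) -> Polygon:
    theta = math.radians(angle_deg)
    d = np.array([math.sin(theta), math.cos(theta)])  # lobe axis
    p = np.array([math.cos(theta), -math.sin(theta)])  # perpendicular
    t = np.linspace(0.0, 1.0, n_samples)
    half = 0.5 * width_ratio * length * np.sin(np.pi * t) ** exponent
    center = np.outer(t * length, d)
    side_a = center + np.outer(half, p)
    side_b = center - np.outer(half, p)
    if exponent > 0:
        ring = np.vstack([side_a, side_b[::-1][1:-1]])
    else:  # rectangle limit: endpoints carry full width
        ring = np.vstack([side_a, side_b[::-1]])
    return Polygon(ring)


def generate_leaf(spec: SyntheticLeafSpec) -> GroundTruth:
    """Build one palmate leaf polygon with exact ground truth.

    Deterministic: the same spec (including its seed) always yields a
    bit-identical polygon.
    """
    rng = np.random.default_rng(spec.seed)
    angles = spec.lobe_angles()
    ratios = (
        np.asarray(spec.lobe_length_ratios, dtype=float)
        if spec.lobe_length_ratios is not None
        else spec.default_ratios(angles)
    )
    if ratios.shape != angles.shape:
        raise ValueError("lobe_length_ratios must have one entry per lobe")
    if np.any(ratios <= 0):
        raise ValueError("lobe length ratios must be > 0")
    if spec.angle_jitter_deg > 0:
        angles = angles + rng.normal(0, spec.angle_jitter_deg, angles.size)
    if spec.ratio_jitter > 0:
        ratios = ratios * (1 + rng.normal(0, spec.ratio_jitter, ratios.size))
        ratios = np.clip(ratios, 0.2, None)

    lengths = spec.central_lobe_length * ratios
    lobes = [
        _lobe_polygon(l, a, spec.lobe_width_ratio, spec.shape_exponent)
        for l, a in zip(lengths, angles)
    ]
    parts = list(lobes)
    if spec.attachment_pad_fraction > 0 and spec.n_lobes > 1:
        parts.append(Point(0.0, 0.0).buffer(
            spec.attachment_pad_fraction * spec.central_lobe_length, quad_segs=16))
    union = unary_union(parts)
    if union.geom_type == "MultiPolygon":  # pragma: no cover - guarded by pad
        union = max(union.geoms, key=lambda g: g.area)
    union = union.buffer(0)
    if union.is_empty or union.area <= 0:
        raise ValueError("spec produced a degenerate (zero-area) leaf")

    ring = np.asarray(union.exterior.coords)
    area = shoelace_area(ring)
    axis = principal_axis(ring)
    tips = np.column_stack([
        lengths * np.sin(np.radians(angles)),
        lengths * np.cos(np.radians(angles)),
    ])
    if len(tips) >= 2:
        L, W, axis = tip_spans(tips)
    else:  # degenerate single-lobe shape: use silhouette extents
        L, W = _extent_spans(ring, axis)
    return GroundTruth(polygon=ring, area=area, L=L, W=W, tips=tips, axis=axis, spec=spec)


def render_leaf(
    truth: GroundTruth,
    ppcm: float,
    canvas_px: tuple[int, int] | None = None,
    margin_cm: float = 1.5,
    fiducial_cm: float | None = None,
    fg: int = 60,
    bg: int = 255,
):
    """Rasterise a leaf polygon onto a white canvas.

    A pixel is foreground iff its centre lies inside the polygon, so the
    pixel count converges to the true area as ``ppcm`` grows (within ~2%
    at 20 px/cm for leaf-sized shapes).  Optionally draws a dark fiducial
    square of known side (``fiducial_cm``) in the top-left corner for
    scale calibration.

    Returns a :class:`palmleaf.leaf_image.LeafImage`.

    Raises
    ------
    ValueError
        If an explicit ``canvas_px`` cannot contain the polygon plus
        margins at this scale.
    """
    from .leaf_image import LeafImage  # local import to avoid a cycle

    if ppcm <= 0:
        raise ValueError("ppcm must be > 0")
    poly = np.asarray(truth.polygon, dtype=float)
    minx, miny = poly.min(axis=0)
    maxx, maxy = poly.max(axis=0)
    need_rows = int(math.ceil((maxy - miny + 2 * margin_cm) * ppcm))
    need_cols = int(math.ceil((maxx - minx + 2 * margin_cm) * ppcm))
    if canvas_px is None:
        rows, cols = need_rows, need_cols
    else:
        rows, cols = canvas_px
        if rows < need_rows or cols < need_cols:
            raise ValueError(
                f"canvas {canvas_px} too small: need at least ({need_rows}, {need_cols}) px"
            )
    # irrational sub-pixel registration phase: keeps axis-aligned polygon
    # edges from landing exactly on pixel centres (which would make the
    # boundary's in/out status numerically arbitrary)
    phase = 0.381966011 / ppcm
    x0 = minx - margin_cm - phase
    y1 = maxy + margin_cm + phase

    img = np.full((rows, cols), bg, dtype=np.uint8)
    # restrict the point-in-polygon test to the polygon's bounding box
    c_lo = max(0, int((minx - x0) * ppcm) - 2)
    c_hi = min(cols, int((maxx - x0) * ppcm) + 3)
    r_lo = max(0, int((y1 - maxy) * ppcm) - 2)
    r_hi = min(rows, int((y1 - miny) * ppcm) + 3)
    cc, rr = np.meshgrid(np.arange(c_lo, c_hi), np.arange(r_lo, r_hi))
    xs = x0 + (cc.ravel() + 0.5) / ppcm
    ys = y1 - (rr.ravel() + 0.5) / ppcm
    inside = MplPath(poly).contains_points(np.column_stack([xs, ys]))
    sub = img[r_lo:r_hi, c_lo:c_hi]
    sub[inside.reshape(sub.shape)] = fg

    if fiducial_cm is not None:
        side = int(round(fiducial_cm * ppcm))
        off = max(2, int(round(0.04 * min(rows, cols))))
        if off + side > min(rows, cols):
            raise ValueError("fiducial does not fit on the canvas")
        img[off:off + side, off:off + side] = fg
    return LeafImage(pixels=img, ppcm=float(ppcm))


def generate_population(
    n_leaves: int,
    l_range: tuple[float, float] = TABLE_L_RANGE,
    w_range: tuple[float, float] = TABLE_W_RANGE,
    slope_a: float = 0.42,
    noise_sd: float = 0.05,
    wl_ratio: float = DEFAULT_WL_RATIO,
    wl_jitter_sd: float = 0.15,
    seed: int = 0,
    plant_id: str = "synthetic-1",
) -> list[LeafRecord]:
    """Sample a leaf population with known allometry.

    L is uniform on ``l_range``; W follows W = wl_ratio · L · (1 + η),
    η ~ N(0, wl_jitter_sd), clipped into ``w_range`` (the paper-era data
    publish only marginal ranges, so the joint (L, W) distribution is a
    modelling choice).  Areas follow LA = slope_a · L · W · (1 + ε) with
    ε ~ N(0, noise_sd); noise_sd = 0 gives an exact allometry whose slope
    any sound through-origin fit must recover exactly.
    """
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    if l_range[0] >= l_range[1] or w_range[0] >= w_range[1]:
        raise ValueError("empty descriptor range")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    L = rng.uniform(*l_range, size=n_leaves)
    W = wl_ratio * L * (1 + rng.normal(0, wl_jitter_sd, n_leaves))
    W = np.clip(W, *w_range)
    eps = rng.normal(0, noise_sd, n_leaves) if noise_sd > 0 else np.zeros(n_leaves)
    eps = np.maximum(eps, -0.9)  # keep areas positive under heavy noise
    LA = slope_a * L * W * (1 + eps)
    return [
        LeafRecord(
            plant_id=plant_id,
            leaf_id=f"{plant_id}-{i:04d}",
            L=float(L[i]),
            W=float(W[i]),
            LA=float(LA[i]),
            source="synthetic",
        )
        for i in range(n_leaves)
    ]


def generate_plant_truths(
    n_leaves: int,
    central_length_range: tuple[float, float] = (6.0, 16.0),
    base_spec: SyntheticLeafSpec | None = None,
    seed: int = 0,
) -> list[GroundTruth]:
    """Silhouettes for one synthetic plant: a shared lobe architecture at
    leaf-to-leaf varying scale.

    Because only the overall size varies, the true area is exactly
    proportional to L·W across the plant — the noiseless limit of the
    allometric model, used to validate the measurement → clustering →
    prediction pipeline end to end.
    """
    base = base_spec or SyntheticLeafSpec()
    rng = np.random.default_rng(seed)
    sizes = rng.uniform(*central_length_range, size=n_leaves)
    return [generate_leaf(replace(base, central_lobe_length=float(s))) for s in sizes]
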