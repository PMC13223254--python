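"""Adaptive multiscale local mesh ternary pattern (AM-LMTP) features.

The descriptor compares *pairs of neighbours* on a circle around each pixel
(the "mesh"), rather than neighbours against the centre.  For neighbour i
of P on the circle of radius R, its mesh partner is

    beta = 1 + mod(i + P + a - 1, P)

where the order ``a`` selects how far around the circle the partner sits.
Each pairwise intensity difference is ternary-quantised against a per-pixel
adaptive threshold

    T(x, y) = alpha * sigma(x, y) + beta_offset

with sigma the local (population) standard deviation, so the dead zone
widens in strongly textured neighbourhoods and never collapses to zero in
flat ones.  The +1 and -1 codes are packed separately into 8-bit "upper"
and "lower" pattern images; three orders x two polarities give six pattern
images per scale, and 256-bin histograms at the 3x3 and 7x7 scales are
concatenated into a 6 x 512 = 3072-dimensional feature vector.

Scale handling: P = 8 neighbours at angles 2*pi*(i-1)/8 (i = 1 at angle 0,
counter-clockwise), radius R = (window-1)/2, bilinear interpolation at
non-integer positions.  Offsets within 1e-9 of an integer are snapped so
axis-aligned samples are exact pixel reads.  Features are computed only on
the valid region shared by all scales (inset R_max from every border).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ThresholdParams",
    "MeshScale",
    "PatternImage",
    "local_std_map",
    "adaptive_threshold",
    "center_bounds",
    "mesh_neighbor_index",
    "sample_neighbors",
    "ternary_encode",
    "compute_pattern_images",
    "lmtp_visualization",
    "pattern_histogram",
    "extract_features",
    "feature_names",
    "DEFAULT_SCALES",
]


@dataclass(frozen=True)
class ThresholdParams:
    """Adaptive-threshold constants: T = alpha * sigma + beta_offset.

    ``alpha`` scales with local contrast (high alpha suppresses codes in
    noisy regions); ``beta_offset`` floors the threshold so perfectly flat
    regions do not code noise.  Defaults (0.2, 5) are the operating point
    used throughout.
    """

    alpha: float = 0.2
    beta_offset: float = 5.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta_offset < 0:
            raise ValueError("alpha and beta_offset must be >= 0")


@dataclass(frozen=True)
class MeshScale:
    """One analysis scale: an odd square window and the circle inside it."""

    window: int = 3
    P: int = 8
    orders: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")

    @property
    def radius(self) -> int:
        return (self.window - 1) // 2


DEFAULT_SCALES: tuple[MeshScale, ...] = (MeshScale(3), MeshScale(7))

#: Fixed (order, polarity) layout of the six pattern images.
PATTERN_LAYOUT: tuple[tuple[int, str], ...] = (
    (1, "upper"), (1, "lower"), (2, "upper"), (2, "lower"), (3, "upper"), (3, "lower"),
)


@dataclass(frozen=True)
class PatternImage:
    """Per-pixel 8-bit mesh-pattern codes for one (order, polarity, scale)."""

    codes: np.ndarray
    order: int
    polarity: str
    scale: MeshScale

    def __post_init__(self) -> None:
        if self.codes.min() < 0 or self.codes.max() > 2 ** self.scale.P - 1:
            raise ValueError("pattern codes out of range for P-bit packing")


def local_std_map(img: np.ndarray, window: int) -> np.ndarray:
    """Population standard deviation of each fully supported window.

    Returns the valid-region map of shape (H - window + 1, W - window + 1).
    Sums are accumulated in exact integer arithmetic, so the result is
    bit-reproducible and exactly invariant to adding a constant.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    img = np.asarray(img)
    if window > min(img.shape):
        raise ValueError(f"window {window} exceeds image size {img.shape}")
    x = img.astype(np.int64)
    n = window * window
    s1 = sliding_window_view(x, (window, window)).sum(axis=(2, 3))
    s2 = sliding_window_view(x * x, (window, window)).sum(axis=(2, 3))
    var = (n * s2 - s1 * s1).astype(float) / (n * n)
    return np.sqrt(np.maximum(var, 0.0))


def adaptive_threshold(sigma, params: ThresholdParams = ThresholdParams()):
    """Per-pixel ternary dead-zone half-width T = alpha * sigma + beta_offset."""
    return params.alpha * np.asarray(sigma, dtype=float) + params.beta_offset


def center_bounds(center: float, T: float) -> tuple[float, float]:
    """Upper/lower intensity bounds around a centre pixel, clamped to [0, 255].

    Exposes the classic centre +/- T reading of the ternary threshold; the
    feature path itself thresholds mesh-pair differences, not the centre.
    """
    return (min(center + T, 255.0), max(center - T, 0.0))


def mesh_neighbor_index(i: int, P: int = 8, a: int = 1) -> int:
    """Partner index beta = 1 + mod(i + P + a - 1, P) for neighbour i (1-based)."""
    if not 1 <= i <= P:
        raise ValueError(f"neighbour index {i} outside 1..{P}")
    if a < 1:
        raise ValueError("order a must be >= 1")
    return 1 + (i + P + a - 1) % P


def _neighbor_offsets(P: int, R: float) -> list[tuple[float, float]]:
    """(dx, dy) of the P circle samples; near-integer coordinates snapped.

    dx is the column offset R*cos(theta); dy the row offset -R*sin(theta),
    so increasing i walks counter-clockwise in conventional orientation.
    """
    offs = []
    for i in range(1, P + 1):
        theta = 2.0 * math.pi * (i - 1) / P
        dx = R * math.cos(theta)
        dy = -R * math.sin(theta)
        dx = round(dx) if abs(dx - round(dx)) < 1e-9 else dx
        dy = round(dy) if abs(dy - round(dy)) < 1e-9 else dy
        offs.append((dx, dy))
    return offs


def _bilinear(img: np.ndarray, rows: np.ndarray, cols: np.ndarray,
              dy: float, dx: float) -> np.ndarray:
    """Sample img at (rows+dy, cols+dx); exact read at integer offsets.

    The four bilinear weights are constructed to sum to exactly 1.
    """
    f = img.astype(float)
    if float(dy).is_integer() and float(dx).is_integer():
        return f[rows + int(dy)][:, cols + int(dx)]
    y0, x0 = math.floor(dy), math.floor(dx)
    fy, fx = dy - y0, dx - x0
    w11 = fy * fx
    w10 = fy * (1.0 - fx)
    w01 = (1.0 - fy) * fx
    w00 = 1.0 - w11 - w10 - w01
    a = f[rows + y0][:, cols + x0]
    b = f[rows + y0][:, cols + x0 + 1]
    c = f[rows + y0 + 1][:, cols + x0]
    d = f[rows + y0 + 1][:, cols + x0 + 1]
    return w00 * a + w01 * b + w10 * c + w11 * d


def sample_neighbors(img: np.ndarray, x: int, y: int, scale: MeshScale) -> np.ndarray:
    """The P circle samples around pixel (x=col, y=row) at this scale."""
    R = scale.radius
    h, w = img.shape
    if not (R <= y < h - R and R <= x < w - R):
        raise ValueError(f"pixel ({x}, {y}) lacks radius-{R} support in {h}x{w} image")
    out = np.empty(scale.P)
    for k, (dx, dy) in enumerate(_neighbor_offsets(scale.P, R)):
        out[k] = _bilinear(img, np.array([y]), np.array([x]), dy, dx)[0, 0]
    return out


def ternary_encode(diff: float, T: float) -> int:
    """Three-way quantisation: +1 if diff >= T, -1 if diff <= -T, else 0.

    Boundaries are inclusive: a difference of exactly +/-T counts as
    significant.
    """
    if T < 0:
        raise ValueError("threshold must be >= 0")
    if diff >= T:
        return 1
    if diff <= -T:
        return -1
    return 0


def compute_pattern_images(
    img: np.ndarray,
    scale: MeshScale = MeshScale(3),
    params: ThresholdParams = ThresholdParams(),
    inset: int | None = None,
) -> list[PatternImage]:
    """All six (order x polarity) mesh-pattern images of one scale.

    ``inset`` is the border kept away from every edge (defaults to the
    scale's own radius; the multiscale extractor passes the largest radius
    so every scale shares one valid region).  The local-SD window equals the
    scale window.
    """
    img = np.asarray(img)
    h, w = img.shape
    R = scale.radius
    inset = R if inset is None else inset
    if inset < R:
        raise ValueError(f"inset {inset} smaller than scale radius {R}")
    if h < 2 * inset + 1 or w < 2 * inset + 1:
        raise ValueError(f"image {h}x{w} too small for inset {inset}")

    rows = np.arange(inset, h - inset)
    cols = np.arange(inset, w - inset)

    sd = local_std_map(img, scale.window)  # valid map at inset = R
    crop = inset - R
    if crop:
        sd = sd[crop:-crop, crop:-crop]
    T = adaptive_threshold(sd, params)

    samples = [
        _bilinear(img, rows, cols, dy, dx)
        for dx, dy in _neighbor_offsets(scale.P, R)
    ]

    out: list[PatternImage] = []
    for a in scale.orders:
        upper = np.zeros(T.shape, dtype=np.int64)
        lower = np.zeros(T.shape, dtype=np.int64)
        for i in range(1, scale.P + 1):
            beta = mesh_neighbor_index(i, scale.P, a)
            d = samples[beta - 1] - samples[i - 1]
            upper += (d >= T).astype(np.int64) << (i - 1)
            lower += (d <= -T).astype(np.int64) << (i - 1)
        out.append(PatternImage(upper.astype(np.uint8), a, "upper", scale))
        out.append(PatternImage(lower.astype(np.uint8), a, "lower", scale))
    return out


def lmtp_visualization(patterns: list[PatternImage]) -> np.ndarray:
    """Per-pixel mean of the six pattern images, rounded — for figures only."""
    shapes = {p.codes.shape for p in patterns}
    if len(shapes) != 1:
        raise ValueError(f"pattern images have mismatched shapes: {shapes}")
    stack = np.stack([p.codes.astype(float) for p in patterns])
    return np.clip(np.rint(stack.mean(axis=0)), 0, 255).astype(np.uint8)


def pattern_histogram(pattern: PatternImage, bins: int = 256,
                      normalize: bool = True) -> np.ndarray:
    """Histogram of the pattern codes; L1-normalised frequencies by default."""
    codes = pattern.codes.ravel()
    if codes.max(initial=0) >= bins:
        raise ValueError(f"code {codes.max()} does not fit in {bins} bins")
    counts = np.bincount(codes, minlength=bins).astype(float)
    if normalize:
        counts /= max(codes.size, 1)
    return counts


def extract_features(
    img: np.ndarray,
    scales: tuple[MeshScale, ...] = DEFAULT_SCALES,
    params: ThresholdParams = ThresholdParams(),
    bins: int = 256,
    normalize: bool = True,
) -> np.ndarray:
    """Concatenated multiscale mesh-pattern histogram feature vector.

    Layout: for each (order, polarity) in the fixed order
    (1,up),(1,low),(2,up),(2,low),(3,up),(3,low), the per-scale histograms
    in scale order.  Defaults give 6 x (256 + 256) = 3072 values, each
    256-bin block summing to 1.
    """
    img = np.asarray(img)
    r_max = max(s.radius for s in scales)
    if min(img.shape) < 2 * r_max + 1:
        raise ValueError(
            f"image {img.shape} smaller than the {2 * r_max + 1}x{2 * r_max + 1} support"
        )
    per_scale = {
        s.window: {
            (p.order, p.polarity): pattern_histogram(p, bins, normalize)
            for p in compute_pattern_images(img, s, params, inset=r_max)
        }
        for s in scales
    }
    blocks = [
        per_scale[s.window][(a, pol)]
        for (a, pol) in PATTERN_LAYOUT
        for s in scales
    ]
    return np.concatenate(blocks)


def feature_names(scales: tuple[MeshScale, ...] = DEFAULT_SCALES,
                  bins: int = 256) -> list[str]:
    """Column names mirroring the extract_features layout, e.g. a1_up_s3_b000."""
    names = []
    for a, pol in PATTERN_LAYOUT:
        for s in scales:
            tag = "up" if pol == "upper" else "low"
            names.extend(f"a{a}_{tag}_s{s.window}_b{b:03d}" for b in range(bins))
    return names
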