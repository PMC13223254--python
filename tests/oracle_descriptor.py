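"""Straight-line per-pixel reference implementation of the mesh ternary
descriptor, used as the independent oracle for the vectorized code path.

Everything here is deliberately scalar Python: explicit loops over pixels,
neighbours and orders, with no shared code with the package beyond the
mathematical definitions (circle sampling with snap-to-integer offsets,
bilinear weights constructed to sum to exactly one, population SD from
exact integer sums, T = alpha*sigma + beta, mesh pairing
beta = 1 + mod(i + P + a - 1, P), inclusive ternary boundaries).
"""

import math

import numpy as np


def oracle_local_sd(img, y, x, window):
    """Population SD of the window centred at (row y, col x), integer sums."""
    r = (window - 1) // 2
    vals = [int(img[yy, xx])
            for yy in range(y - r, y + r + 1)
            for xx in range(x - r, x + r + 1)]
    n = len(vals)
    s1 = sum(vals)
    s2 = sum(v * v for v in vals)
    return math.sqrt(max((n * s2 - s1 * s1) / (n * n), 0.0))


def oracle_sample(img, y, x, dy, dx):
    """Bilinear sample at (y+dy, x+dx); exact read at integer offsets."""
    if float(dy).is_integer() and float(dx).is_integer():
        return float(img[y + int(dy), x + int(dx)])
    y0, x0 = math.floor(dy), math.floor(dx)
    fy, fx = dy - y0, dx - x0
    w11 = fy * fx
    w10 = fy * (1.0 - fx)
    w01 = (1.0 - fy) * fx
    w00 = 1.0 - w11 - w10 - w01
    a = float(img[y + y0, x + x0])
    b = float(img[y + y0, x + x0 + 1])
    c = float(img[y + y0 + 1, x + x0])
    d = float(img[y + y0 + 1, x + x0 + 1])
    return w00 * a + w01 * b + w10 * c + w11 * d


def oracle_offsets(P, R):
    offs = []
    for i in range(1, P + 1):
        theta = 2.0 * math.pi * (i - 1) / P
        dx = R * math.cos(theta)
        dy = -R * math.sin(theta)
        if abs(dx - round(dx)) < 1e-9:
            dx = round(dx)
        if abs(dy - round(dy)) < 1e-9:
            dy = round(dy)
        offs.append((dx, dy))
    return offs


def oracle_pattern_images(img, window, alpha, beta_offset,
                          orders=(1, 2, 3), inset=None):
    """Dict (order, polarity) -> code image, all via per-pixel loops."""
    img = np.asarray(img)
    h, w = img.shape
    P = 8
    R = (window - 1) // 2
    inset = R if inset is None else inset
    offs = oracle_offsets(P, R)
    out = {(a, pol): np.zeros((h - 2 * inset, w - 2 * inset), dtype=np.int64)
           for a in orders for pol in ("upper", "lower")}
    for y in range(inset, h - inset):
        for x in range(inset, w - inset):
            sigma = oracle_local_sd(img, y, x, window)
            T = alpha * sigma + beta_offset
            s = [oracle_sample(img, y, x, dy, dx) for dx, dy in offs]
            for a in orders:
                up = low = 0
                for i in range(1, P + 1):
                    beta = 1 + (i + P + a - 1) % P
                    d = s[beta - 1] - s[i - 1]
                    if d >= T:
                        up |= 1 << (i - 1)
                    elif d <= -T:
                        low |= 1 << (i - 1)
                out[(a, "upper")][y - inset, x - inset] = up
                out[(a, "lower")][y - inset, x - inset] = low
    return out


def oracle_features(img, alpha=0.2, beta_offset=5.0, windows=(3, 7), bins=256):
    """Full concatenated feature vector via the per-pixel loops."""
    inset = max((w - 1) // 2 for w in windows)
    per_w = {w: oracle_pattern_images(img, w, alpha, beta_offset, inset=inset)
             for w in windows}
    layout = [(1, "upper"), (1, "lower"), (2, "upper"),
              (2, "lower"), (3, "upper"), (3, "lower")]
    blocks = []
    for key in layout:
        for w in windows:
            codes = per_w[w][key].ravel()
            hist = np.bincount(codes, minlength=bins).astype(float) / codes.size
            blocks.append(hist)
    return np.concatenate(blocks)
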