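"""Independent brute-force oracles used to cross-check the implementation.

Deliberately simple and independent of the package's computational routes:
raster rotation instead of coordinate projection, a literal z-score loop,
EM instead of differential evolution, matplotlib point-in-polygon hulls
instead of scikit-image.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def raster_rotation_width_px(
    pixels: np.ndarray, theta_deg: float, supersample: int = 4
) -> float:
    """Feret width (px) by literally rotating the raster and measuring columns.

    The raster is block-replicated ``supersample``-fold before rotation so the
    oracle's own interpolation error stays well below one pixel; the column
    extent of the rotated raster divided by the factor is the width in
    original pixels (consistent with the "+1 pixel" width convention, since
    the blocks cover the full pixel squares).
    """
    up = np.kron(pixels, np.ones((supersample, supersample), dtype=bool))
    rot = (
        ndimage.rotate(up.astype(float), theta_deg, reshape=True, order=1,
                       mode="constant", cval=0.0)
        >= 0.5
    )
    cols = np.nonzero(rot)[1]
    return float(cols.max() - cols.min() + 1) / supersample


def zscore_filter_literal(values, threshold=2.5, passes=2):
    """Straight-line transcription of the filtering rule."""
    v = list(map(float, values))
    for _ in range(passes):
        if len(v) < 3:
            break
        mean = sum(v) / len(v)
        sd = (sum((x - mean) ** 2 for x in v) / (len(v) - 1)) ** 0.5
        if sd == 0:
            break
        v = [x for x in v if abs(x - mean) / sd <= threshold]
    return np.array(v)


def em_weights(x: np.ndarray, mus, sigmas, iters=20000, tol=1e-13) -> np.ndarray:
    """EM for mixture weights with fixed normal components."""
    x = np.asarray(x, float)
    mus = np.asarray(mus, float)
    sig = np.asarray(sigmas, float)
    w = np.full(len(mus), 1.0 / len(mus))
    for _ in range(iters):
        dens = w / (sig * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x[:, None] - mus) / sig) ** 2)
        dens = np.maximum(dens, 1e-300)
        resp = dens / dens.sum(axis=1, keepdims=True)
        w_new = resp.mean(axis=0)
        if np.abs(w_new - w).max() < tol:
            return w_new
        w = w_new
    return w


def hull_solidity(pixels: np.ndarray) -> float:
    """Solidity by rasterizing the convex hull with a point-in-polygon test."""
    from matplotlib.path import Path as MplPath
    from scipy.spatial import ConvexHull

    coords = np.argwhere(pixels).astype(float)
    hull = ConvexHull(coords)
    poly = MplPath(coords[hull.vertices])
    yy, xx = np.mgrid[0 : pixels.shape[0], 0 : pixels.shape[1]]
    pts = np.stack([yy.ravel(), xx.ravel()], axis=1)
    inside = poly.contains_points(pts, radius=1e-9).reshape(pixels.shape)
    return float(pixels.sum()) / float(inside.sum())
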