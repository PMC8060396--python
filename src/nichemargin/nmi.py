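"""The Niche Margin Index: signed, standardized distance to the niche margin.

For a site with environmental-space coordinates *x* and a niche envelope,
the NMI is built in three steps: (1) the sign is positive if *x* lies inside
the envelope (outer rings minus holes) and negative otherwise; (2) the
magnitude is the minimum Euclidean distance from *x* to any boundary ring;
(3) the signed distance is divided by the maximal minimum interior distance
— the distance to the margin from the most margin-distant interior point,
found on a regular lattice of ~10,000 points — so that values are
comparable across species with different niche sizes.  NMI therefore lies
in (-inf, +1]: 0 on the margin, 1 at the deepest interior point, and
increasingly negative far outside the niche.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.optimize import brentq

from .envelope import NicheEnvelope

__all__ = [
    "NMIResult",
    "signed_margin_distance",
    "signed_margin_distances",
    "max_inner_distance",
    "nmi",
    "ellipsoid_signed_distance",
]


@dataclass
class NMIResult:
    """Per-site NMI decomposition."""

    site_id: object
    inside: bool | None
    distance: float
    denominator: float
    nmi: float
    missing: bool = False


def signed_margin_distances(points: np.ndarray, envelope: NicheEnvelope) -> np.ndarray:
    """Vectorized signed distances of an (n, 2) array of points.

    Positive inside the envelope (union of outer rings minus holes), negative
    outside, 0 exactly on a boundary ring.  Rows with non-finite coordinates
    yield NaN.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.shape[1] != 2:
        raise ValueError("points must be (n, 2) in environmental space")
    out = np.full(len(pts), np.nan)
    ok = np.all(np.isfinite(pts), axis=1)
    if not ok.any():
        return out
    geom = envelope.geometry
    boundary = envelope.boundary
    shapely.prepare(geom)
    p = shapely.points(pts[ok, 0], pts[ok, 1])
    d = shapely.distance(p, boundary)
    sign = np.where(shapely.covers(geom, p), 1.0, -1.0)
    out[ok] = sign * d
    return out


def signed_margin_distance(point, envelope: NicheEnvelope) -> float:
    """Signed distance of a single point to the envelope margin."""
    return float(signed_margin_distances(np.asarray(point, float)[None, :], envelope)[0])


def _interior_lattice(envelope: NicheEnvelope, n_points: int) -> np.ndarray:
    """Regular square lattice of ~n_points points inside the envelope."""
    geom = envelope.geometry
    area = geom.area
    if area <= 0:
        raise ValueError("zero-area envelope")
    minx, miny, maxx, maxy = geom.bounds
    s = math.sqrt(area / n_points)
    shapely.prepare(geom)
    for _ in range(30):
        xs = np.arange(minx + s / 2, maxx, s)
        ys = np.arange(miny + s / 2, maxy, s)
        XX, YY = np.meshgrid(xs, ys)
        inside = shapely.contains_xy(geom, XX.ravel(), YY.ravel())
        if inside.any():
            return np.column_stack([XX.ravel()[inside], YY.ravel()[inside]])
        s /= 2  # degenerate slivers: refine until the lattice hits the interior
    raise ValueError("could not place lattice points inside the envelope")


def max_inner_distance(envelope: NicheEnvelope, n_points: int = 10000) -> float:
    """Maximal minimum distance to the margin over a regular interior lattice.

    This approximates the margin distance of the envelope's "deepest" point
    (the Chebyshev-center depth) and serves as the NMI standardization
    denominator.  The lattice origin is deterministic (bounding-box lower
    left + half a spacing), so repeated calls are bit-identical; the result
    is cached on the envelope per ``n_points``.
    """
    cached = envelope._denominators.get(n_points)
    if cached is not None:
        return cached
    lattice = _interior_lattice(envelope, n_points)
    d = shapely.distance(
        shapely.points(lattice[:, 0], lattice[:, 1]), envelope.boundary
    )
    val = float(d.max())
    if val <= 0:
        raise ValueError("degenerate envelope: no interior depth")
    envelope._denominators[n_points] = val
    return val


def nmi(
    points: np.ndarray,
    envelope: NicheEnvelope,
    ids=None,
    n_points: int = 10000,
) -> list[NMIResult]:
    """Niche Margin Index of each site: signed margin distance / denominator.

    Values cannot exceed 1 (beyond lattice tolerance) but may fall below -1
    far outside the niche.  Missing coordinates propagate as flagged missing
    results.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    if ids is None:
        ids = np.arange(len(pts))
    denom = max_inner_distance(envelope, n_points=n_points)
    dist = signed_margin_distances(pts, envelope)
    results = []
    for i, d in enumerate(dist):
        if not np.isfinite(d):
            results.append(
                NMIResult(site_id=ids[i], inside=None, distance=np.nan,
                          denominator=denom, nmi=np.nan, missing=True)
            )
        else:
            results.append(
                NMIResult(site_id=ids[i], inside=bool(d >= 0), distance=float(d),
                          denominator=denom, nmi=float(d / denom))
            )
    return results


def ellipsoid_signed_distance(point, center, shape_matrix) -> float:
    """Signed Euclidean distance from a k-D point to an ellipsoid boundary.

    The ellipsoid is {x : (x-c)' A (x-c) <= 1}; positive inside, negative
    outside.  Solves the Lagrange condition for the closest boundary point by
    1-D root-finding in the ellipsoid's principal frame; this extends margin
    distances beyond the 2-D polygon representation when envelopes are kept
    as ellipsoids in k dimensions.
    """
    c = np.asarray(center, float)
    A = np.asarray(shape_matrix, float)
    x = np.asarray(point, float) - c
    eigvals, eigvecs = np.linalg.eigh(A)
    a = 1.0 / np.sqrt(eigvals)  # semi-axes
    y = eigvecs.T @ x  # coordinates in the principal frame
    m2 = float(np.sum((y / a) ** 2))
    if m2 < 1e-300:
        return float(a.min())  # at the center

    def g(lam: float) -> float:
        return float(np.sum((a * y) ** 2 / (lam + a**2) ** 2) - 1.0)

    # closest boundary point: y_b = a^2 y / (lam + a^2); g is decreasing in lam
    lo = -float((a**2).min()) + 1e-14
    if m2 < 1.0:
        hi = 0.0
        if g(lo) < 0:  # numerically at the center along the smallest axis
            return float(a.min() * (1 - math.sqrt(m2)))
        lam = brentq(g, lo, hi, xtol=1e-14) if g(hi) < 0 else 0.0
    else:
        hi = float(a.max() * np.linalg.norm(y)) + 1.0
        while g(hi) > 0:
            hi *= 2
        lam = brentq(g, 0.0, hi, xtol=1e-14)
    yb = a**2 * y / (lam + a**2)
    d = float(np.linalg.norm(y - yb))
    return d if m2 < 1.0 else -d
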