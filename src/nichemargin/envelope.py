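"""Delimiting the native climatic niche (NCN) as closed polygons in env-space.

Two estimators are provided:

* ``kde_envelope`` — the realized-niche estimate: a Gaussian kernel density
  is fitted to the PCA scores of the native-range pixels, and the contour of
  the highest-density region (HDR) enclosing a stated fraction of the
  estimated density mass (0.99 by default) is extracted by marching squares.
* ``mve_envelope`` — a fundamental-niche proxy: the minimum-volume enclosing
  ellipsoid of the scores after robust Mahalanobis peeling down to the
  stated fraction of points.

Both return a :class:`NicheEnvelope` whose geometry is a shapely
(Multi)Polygon in environmental-space units, so that downstream margin
distances are computed uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from scipy.stats import gaussian_kde
from shapely.geometry import MultiPolygon, Polygon
from skimage.measure import find_contours

from .climate import ClimateStack, EnvScores, EnvSpace, project

__all__ = [
    "NicheEnvelope",
    "DEFAULT_NATIVE_STATUSES",
    "range_to_scores",
    "kde_envelope",
    "mve_envelope",
]

#: IUCN-style presence codes retained as part of the native range.
DEFAULT_NATIVE_STATUSES = (
    "extant",
    "probably extant",
    "reintroduced",
    "probably extinct",
    "extinct",
)


@dataclass
class NicheEnvelope:
    """A closed niche envelope in environmental space.

    ``geometry`` is a shapely MultiPolygon (outer rings, possibly with
    holes); ``level`` is the fraction of density mass (kde) or of points
    (mve) the envelope encloses.
    """

    method: str
    level: float
    geometry: MultiPolygon
    metadata: dict = field(default_factory=dict)
    _denominators: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if isinstance(self.geometry, Polygon):
            self.geometry = MultiPolygon([self.geometry])
        if not isinstance(self.geometry, MultiPolygon):
            raise TypeError("geometry must be a (Multi)Polygon")
        if not (0 < self.level <= 1):
            raise ValueError("level must lie in (0, 1]")
        if self.geometry.area <= 0:
            raise ValueError("envelope has zero area")
        if not self.geometry.is_valid:
            self.geometry = shapely.make_valid(self.geometry)

    @property
    def boundary(self):
        return self.geometry.boundary

    @property
    def area(self) -> float:
        return self.geometry.area

    def to_geojson_dict(self) -> dict:
        meta = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.metadata.items()
        }
        return {
            "type": "FeatureCollection",
            "properties": {
                "method": self.method,
                "level": self.level,
                "coordinate_space": "environmental PCA scores (unitless)",
                **meta,
            },
            "features": [
                {
                    "type": "Feature",
                    "properties": {},
                    "geometry": shapely.geometry.mapping(poly),
                }
                for poly in self.geometry.geoms
            ],
        }

    @classmethod
    def from_geojson_dict(cls, doc: dict) -> "NicheEnvelope":
        props = dict(doc.get("properties", {}))
        polys = [shapely.geometry.shape(f["geometry"]) for f in doc["features"]]
        method = props.pop("method")
        level = props.pop("level")
        props.pop("coordinate_space", None)
        return cls(method=method, level=level, geometry=MultiPolygon(polys), metadata=props)


def range_to_scores(
    range_polygons: Iterable,
    stack: ClimateStack,
    space: EnvSpace,
    statuses: Sequence[str] = DEFAULT_NATIVE_STATUSES,
) -> EnvScores:
    """PCA scores of valid pixels whose center falls in the native range.

    ``range_polygons`` is an iterable of ``(geometry, status)`` pairs (or
    dicts with ``geometry``/``status`` keys); polygons whose status is not in
    ``statuses`` (case-insensitive) are discarded before rasterization.
    """
    keep = {s.lower() for s in statuses}
    geoms = []
    for item in range_polygons:
        if isinstance(item, dict):
            geom, status = item["geometry"], item["status"]
        else:
            geom, status = item
        if str(status).lower() in keep:
            geoms.append(geom)
    if not geoms:
        raise ValueError(
            "no range polygon with a retained presence status; "
            f"retained statuses are {sorted(keep)}"
        )
    union = shapely.union_all(geoms)
    ids = stack.valid_ids()
    lon, lat = stack.pixel_lonlat(ids)
    inside = shapely.intersects_xy(union, lon, lat)
    if not inside.any():
        raise ValueError("range smaller than one cell: no pixel center inside range")
    sub = ids[inside]
    scores_all = project(stack, space)
    sel = np.isin(scores_all.ids, sub)
    return EnvScores(ids=scores_all.ids[sel], coords=scores_all.coords[sel])


# ---------------------------------------------------------------------------
# KDE highest-density-region envelope
# ---------------------------------------------------------------------------


def _rings_to_multipolygon(rings: list[np.ndarray], min_area: float) -> MultiPolygon:
    """Assemble marching-squares rings into polygons with holes (even-odd)."""
    polys = []
    for r in rings:
        if len(r) < 4:
            continue
        p = Polygon(r)
        if not p.is_valid:
            p = p.buffer(0)
        if p.is_empty or p.area < min_area:
            continue
        polys.append(p)
    if not polys:
        raise ValueError("no contour ring found at the requested level")
    polys.sort(key=lambda p: p.area, reverse=True)
    depth = []
    for i, p in enumerate(polys):
        rep = p.representative_point()
        depth.append(sum(1 for q in polys[:i] if q.contains(rep)))
    shells = []
    for i, p in enumerate(polys):
        if depth[i] % 2 == 0:
            shells.append([p, []])
        else:
            # hole: attach to the smallest (= most recent) containing shell
            for shell in reversed(shells):
                if shell[0].contains(p.representative_point()):
                    shell[1].append(p.exterior)
                    break
    return MultiPolygon(
        [Polygon(shell.exterior, holes) for shell, holes in shells]
    )


def kde_envelope(
    scores: EnvScores | np.ndarray,
    level: float = 0.99,
    eval_grid_n: int = 500,
    bandwidth: str = "normal-reference",
    expand: float = 0.1,
    min_ring_area_frac: float = 1e-6,
    mass_tol: float = 0.01,
) -> NicheEnvelope:
    """Highest-density-region contour of a 2-D Gaussian KDE.

    The density threshold ``t`` is chosen such that the estimated mass of
    ``{density >= t}`` equals ``level``; the contour polygons at ``t`` are
    extracted by marching squares from a regular evaluation grid spanning
    the data range expanded by ``expand`` per side.  The enclosed mass is
    re-integrated over the returned polygons and must agree with ``level``
    within ``mass_tol`` (raises otherwise).

    Bandwidth: ``"normal-reference"`` uses the normal-reference full
    covariance bandwidth matrix (for d=2 this coincides with Silverman's
    factor applied to the data covariance); ``"scott"`` uses Scott's factor.
    """
    pts = scores.valid_coords() if isinstance(scores, EnvScores) else np.asarray(scores, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("kde_envelope expects 2-D scores")
    if len(pts) < 5:
        raise ValueError("need at least 5 points for a density envelope")
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1) for a density contour")
    spans = np.ptp(pts, axis=0)
    if np.any(spans == 0) or np.linalg.matrix_rank(np.cov(pts.T)) < 2:
        raise ValueError(
            "degenerate point cloud (zero bandwidth); add a small jitter to the scores"
        )
    bw = {"normal-reference": "silverman", "silverman": "silverman", "scott": "scott"}
    if bandwidth not in bw:
        raise ValueError(f"unknown bandwidth rule {bandwidth!r}")
    kde = gaussian_kde(pts.T, bw_method=bw[bandwidth])

    lo = pts.min(axis=0) - expand * spans
    hi = pts.max(axis=0) + expand * spans
    xs = np.linspace(lo[0], hi[0], eval_grid_n)
    ys = np.linspace(lo[1], hi[1], eval_grid_n)
    XX, YY = np.meshgrid(xs, ys)
    dens = kde(np.vstack([XX.ravel(), YY.ravel()])).reshape(XX.shape)

    flat = dens.ravel()
    order = np.sort(flat)[::-1]
    cum = np.cumsum(order)
    total = cum[-1]
    k = np.searchsorted(cum, level * total)
    k = min(k, len(order) - 1)
    t = order[k]
    if t <= order[-1] * (1 + 1e-12) and level < 0.999:
        raise ValueError(
            "density threshold hits the grid border; increase `expand`"
        )

    # pad with zeros so every contour closes inside the grid
    padded = np.pad(dens, 1, mode="constant", constant_values=0.0)
    dx = xs[1] - xs[0]
    dy = ys[1] - ys[0]
    rings = []
    for c in find_contours(padded, t):
        # c[:, 0] is row index into padded (y), c[:, 1] is column (x)
        x = lo[0] + (c[:, 1] - 1) * dx
        y = lo[1] + (c[:, 0] - 1) * dy
        rings.append(np.column_stack([x, y]))
    area_scale = sum(abs(_ring_area(r)) for r in rings)
    geom = _rings_to_multipolygon(rings, min_ring_area_frac * max(area_scale, 1e-300))

    shapely.prepare(geom)
    inside = shapely.contains_xy(geom, XX.ravel(), YY.ravel())
    enclosed = flat[inside].sum() / total
    if abs(enclosed - level) > mass_tol:
        raise ValueError(
            f"mass calibration failed: enclosed {enclosed:.4f} vs level {level:.4f}; "
            "increase eval_grid_n or expand"
        )
    return NicheEnvelope(
        method="kde",
        level=level,
        geometry=geom,
        metadata={
            "bandwidth_matrix": np.asarray(kde.covariance),
            "n_points": int(len(pts)),
            "eval_grid_n": int(eval_grid_n),
            "expand": float(expand),
            "density_threshold": float(t),
            "enclosed_mass": float(enclosed),
        },
    )


def _ring_area(r: np.ndarray) -> float:
    x, y = r[:, 0], r[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


# ---------------------------------------------------------------------------
# Minimum-volume ellipsoid envelope
# ---------------------------------------------------------------------------


def _mvee(points: np.ndarray, tol: float = 1e-6, max_iter: int = 100000):
    """Minimum-volume enclosing ellipsoid (Khachiyan's algorithm).

    Returns (center c, shape matrix A) with the ellipsoid
    {x : (x-c)' A (x-c) <= 1}.
    """
    P = np.asarray(points, dtype=float)
    n, d = P.shape
    Q = np.column_stack([P, np.ones(n)])  # (n, d+1)
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        V = Q.T @ (Q * u[:, None])  # (d+1, d+1)
        M = np.einsum("ij,ji->i", Q, np.linalg.solve(V, Q.T))
        j = int(np.argmax(M))
        mx = M[j]
        if mx / (d + 1) - 1.0 <= tol:
            break
        step = (mx - d - 1.0) / ((d + 1.0) * (mx - 1.0))
        u *= 1.0 - step
        u[j] += step
    c = P.T @ u
    S = P.T @ (P * u[:, None]) - np.outer(c, c)
    A = np.linalg.inv(S) / d
    return c, A


def _ellipse_polygon(center: np.ndarray, A: np.ndarray, n_vertices: int = 256) -> Polygon:
    eigvals, eigvecs = np.linalg.eigh(A)
    # circumscribe: scale so the polygon contains the ellipse, not inscribes it
    axes = 1.0 / (np.sqrt(eigvals) * np.cos(np.pi / n_vertices))
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    verts = center + (circle * axes) @ eigvecs.T
    return Polygon(verts)


def mve_envelope(
    scores: EnvScores | np.ndarray,
    level: float = 0.95,
    tol: float = 1e-6,
    n_vertices: int = 256,
) -> NicheEnvelope:
    """Minimum-volume ellipsoid enclosing a fraction ``level`` of the scores.

    The farthest point by Mahalanobis distance (mean/covariance recomputed
    after each removal) is discarded iteratively until ``ceil(level * n)``
    points remain, then the exact minimum-volume enclosing ellipsoid of the
    retained set is fitted by Khachiyan iteration and converted to an
    ``n_vertices``-gon.
    """
    pts = scores.valid_coords() if isinstance(scores, EnvScores) else np.asarray(scores, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("mve_envelope expects 2-D scores")
    if not (0 < level <= 1):
        raise ValueError("level must lie in (0, 1]")
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 points")
    keep = int(np.ceil(level * n))
    keep = max(keep, 3)
    retained = pts.copy()
    while len(retained) > keep:
        mu = retained.mean(axis=0)
        cov = np.cov(retained.T)
        if np.linalg.matrix_rank(cov) < 2:
            raise ValueError("collinear points: degenerate ellipsoid")
        diff = retained - mu
        md2 = np.einsum("ij,ij->i", diff @ np.linalg.inv(cov), diff)
        retained = np.delete(retained, int(np.argmax(md2)), axis=0)
    centered = retained - retained.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-12 * max(1.0, np.abs(centered).max())) < 2:
        raise ValueError("collinear points: degenerate ellipsoid")
    c, A = _mvee(retained, tol=tol)
    # rescale exactly so every retained point is inside (boundary inclusive):
    # the Khachiyan iteration stops within `tol`, leaving support points a
    # hair outside the raw ellipse
    diff = retained - c
    md2_max = float(np.einsum("ij,ij->i", diff @ A, diff).max())
    if md2_max > 1.0:
        A = A / md2_max
    geom = _ellipse_polygon(c, A, n_vertices)
    return NicheEnvelope(
        method="mve",
        level=level,
        geometry=MultiPolygon([geom]),
        metadata={
            "center": c,
            "shape_matrix": A,
            "n_points": int(n),
            "n_retained": int(len(retained)),
        },
    )
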