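import numpy as np
import pytest
from shapely.geometry import MultiPolygon, Point, Polygon

from nichemargin import ClimateStack, NicheEnvelope


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_stack():
    """10x10 grid, 3 correlated variables, all pixels valid."""
    rng = np.random.default_rng(7)
    nr = nc = 10
    lat = np.linspace(1, -1, nr)[:, None] * np.ones((1, nc))
    lon = np.ones((nr, 1)) * np.linspace(-1, 1, nc)[None, :]
    v0 = 10 - 5 * lat**2 + 0.1 * rng.standard_normal((nr, nc))
    v1 = 2 * lat + 0.1 * rng.standard_normal((nr, nc))
    v2 = 100 + 30 * lon + 0.5 * rng.standard_normal((nr, nc))
    return ClimateStack(
        values=np.stack([v0, v1, v2]),
        mask=np.ones((nr, nc), bool),
        extent=(-5.0, -5.0, 5.0, 5.0),
        band_names=["temp", "seasonality", "precip"],
    )


def regular_polygon_envelope(radius=1.0, center=(0.0, 0.0), n=1024, level=0.95):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    ring = np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )
    return NicheEnvelope(method="kde", level=level, geometry=MultiPolygon([Polygon(ring)]))


@pytest.fixture
def disc_envelope():
    """Unit disc approximated by a 1024-gon (vertex error < 5e-6)."""
    return regular_polygon_envelope()


@pytest.fixture
def square_envelope():
    return NicheEnvelope(
        method="kde",
        level=0.95,
        geometry=MultiPolygon([Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])]),
    )


# ---------------------------------------------------------------------------
# independent geometry oracles (pure numpy, no shapely)
# ---------------------------------------------------------------------------


def _segment_distances(p, ring):
    """Min distance from point p to each closed-ring segment, exactly."""
    a = np.asarray(ring, float)
    b = np.roll(a, -1, axis=0)
    ab = b - a
    ap = p - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.divide(np.einsum("ij,ij->i", ap, ab), np.where(denom == 0, 1, denom)), 0, 1)
    proj = a + t[:, None] * ab
    return np.linalg.norm(proj - p, axis=1)


def _ray_cast_inside(p, ring):
    """Even-odd ray casting for one closed ring."""
    x, y = p
    a = np.asarray(ring, float)
    b = np.roll(a, -1, axis=0)
    cond = (a[:, 1] > y) != (b[:, 1] > y)
    with np.errstate(divide="ignore", invalid="ignore"):
        xint = a[:, 0] + (y - a[:, 1]) * (b[:, 0] - a[:, 0]) / (b[:, 1] - a[:, 1])
    return bool(np.sum(cond & (x < xint)) % 2)


def oracle_signed_distance(point, rings):
    """Brute-force signed distance to a polygon given as a list of rings.

    rings[0] is the outer boundary, the rest are holes (even-odd rule:
    a point inside an odd number of rings is outside the niche).
    """
    p = np.asarray(point, float)
    d = min(_segment_distances(p, r).min() for r in rings)
    crossings = sum(_ray_cast_inside(p, r) for r in rings)
    return d if crossings % 2 == 1 else -d


def random_convex_polygon(rng, n_pts=12, scale=1.0):
    from scipy.spatial import ConvexHull

    pts = rng.standard_normal((n_pts, 2)) * scale + rng.uniform(-2, 2, 2)
    hull = ConvexHull(pts)
    return pts[hull.vertices]
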