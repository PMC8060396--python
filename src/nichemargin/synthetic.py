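"""Synthetic landscapes, virtual species and introduction outcomes.

Everything downstream of raw data downloads can be exercised on synthetic
inputs with known ground truth: smooth gradient-plus-noise climate fields, species
whose "native range" is exactly the set of pixels within a Mahalanobis
ellipse of a Gaussian virtual niche in environmental space (so the true
niche envelope is analytic), and Bernoulli establishment outcomes generated
from the hierarchical logistic model with known coefficients.

All randomness flows through one explicitly passed, seeded generator; the
same seed reproduces the same landscape, species and events bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit
from scipy.stats import chi2
from shapely.geometry import MultiPolygon, box

from .climate import ClimateStack, EnvSpace, EnvScores, project
from .envelope import NicheEnvelope, _ellipse_polygon
from .nmi import nmi as compute_nmi
from .establishment import FIXED_COLS, LOG_COLS, ModelData

__all__ = [
    "VirtualSpecies",
    "SimulationTruth",
    "CLIMATE_BAND_NAMES",
    "generate_climate",
    "generate_species",
    "simulate_introductions",
    "simulate_model_data",
]

#: band names mirroring the eight bioclimatic variables commonly used for
#: global invasion niche work (temperature range/seasonality/quarters,
#: precipitation quarters, aridity)
CLIMATE_BAND_NAMES = [
    "temp_range",
    "temp_seasonality",
    "temp_coldest_q",
    "temp_warmest_q",
    "prec_driest_q",
    "prec_coldest_q",
    "prec_warmest_q",
    "aridity",
]

CLIMATE_BAND_UNITS = ["degC", "degC", "degC", "degC", "mm", "mm", "mm", "index"]

# deterministic spatial gradients on normalized lon/lat in [-1, 1]
_GRADIENTS = [
    lambda x, y: -(y**2),
    lambda x, y: y,
    lambda x, y: x,
    lambda x, y: x * y,
    lambda x, y: x**2,
    lambda x, y: 0.5 * (x + y),
    lambda x, y: y**3,
    lambda x, y: (x**2) * y,
]


def gradient_field(k: int, lon_norm: np.ndarray, lat_norm: np.ndarray) -> np.ndarray:
    """The deterministic gradient component of band ``k`` (cycled)."""
    return _GRADIENTS[k % len(_GRADIENTS)](lon_norm, lat_norm)


def generate_climate(
    grid_n: tuple[int, int] | int = (60, 120),
    n_vars: int = 8,
    means: np.ndarray | None = None,
    amplitudes: np.ndarray | None = None,
    noise_sd: float | np.ndarray = 0.3,
    smooth: float = 3.0,
    mask_fraction: float = 0.0,
    extent: tuple[float, float, float, float] = (-180.0, -90.0, 180.0, 90.0),
    seed: int | np.random.Generator | None = None,
) -> ClimateStack:
    """Generate a synthetic multi-band climate grid.

    Each band is ``mean_k + amplitude_k * gradient_k(lon, lat) + noise_sd_k *
    G`` where ``gradient_k`` is a fixed low-order polynomial in normalized
    coordinates and ``G`` is a smoothed, unit-variance Gaussian random field.
    With ``noise_sd = 0`` each band equals its gradient formula exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(grid_n, (int, np.integer)):
        grid_n = (int(grid_n), int(grid_n))
    nr, nc = grid_n
    if n_vars < 2:
        raise ValueError("need at least 2 variables")
    means = np.zeros(n_vars) if means is None else np.asarray(means, float)
    amplitudes = np.ones(n_vars) if amplitudes is None else np.asarray(amplitudes, float)
    noise_sd = np.broadcast_to(np.asarray(noise_sd, float), (n_vars,))

    west, south, east, north = extent
    lon = west + (east - west) * (np.arange(nc) + 0.5) / nc
    lat = north - (north - south) * (np.arange(nr) + 0.5) / nr
    lon_n = 2 * (lon - west) / (east - west) - 1
    lat_n = 2 * (lat - south) / (north - south) - 1
    XX, YY = np.meshgrid(lon_n, lat_n)

    values = np.empty((n_vars, nr, nc))
    for k in range(n_vars):
        band = means[k] + amplitudes[k] * gradient_field(k, XX, YY)
        if noise_sd[k] > 0:
            g = gaussian_filter(rng.standard_normal((nr, nc)), sigma=smooth, mode="wrap")
            band = band + noise_sd[k] * g / g.std()
        values[k] = band
    mask = np.ones((nr, nc), dtype=bool)
    if mask_fraction > 0:
        mask &= rng.random((nr, nc)) >= mask_fraction
    if n_vars == len(CLIMATE_BAND_NAMES):
        names, units = list(CLIMATE_BAND_NAMES), list(CLIMATE_BAND_UNITS)
    else:
        names = [f"var_{k}" for k in range(n_vars)]
        units = ["unitless"] * n_vars
    return ClimateStack(values=values, mask=mask, extent=extent,
                        band_names=names, band_units=units)


@dataclass
class VirtualSpecies:
    """A species whose niche is a known Gaussian in environmental space."""

    name: str
    center: np.ndarray
    covariance: np.ndarray
    level: float
    pixel_ids: np.ndarray  # flat indices of native-range pixels
    true_envelope: NicheEnvelope = field(repr=False)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float)
        self.covariance = np.asarray(self.covariance, float)
        if len(self.pixel_ids) == 0:
            raise ValueError("virtual species with empty range")
        if np.any(np.linalg.eigvalsh(self.covariance) <= 0):
            raise ValueError("niche covariance must be positive-definite")

    def range_polygons(self, stack: ClimateStack, status: str = "extant"):
        """Native range as cell-box polygons (IUCN-style geometry + status)."""
        lon, lat = stack.pixel_lonlat(self.pixel_ids)
        dx, dy = stack.cell_size
        cells = [box(x - dx / 2, y - dy / 2, x + dx / 2, y + dy / 2) for x, y in zip(lon, lat)]
        geom = shapely.union_all(cells)
        return [(geom, status)]


def generate_species(
    stack: ClimateStack,
    space: EnvSpace,
    center,
    covariance,
    level: float = 0.99,
    name: str = "species",
) -> VirtualSpecies:
    """A virtual species occupying pixels within its niche ellipse.

    The range is the set of valid pixels whose environmental score has
    squared Mahalanobis distance to ``center`` at most the chi-square
    quantile of ``level`` (2 df); the analytic ellipse at that level is
    recorded as the true envelope.
    """
    center = np.asarray(center, float)
    cov = np.asarray(covariance, float)
    scores = project(stack, space)
    if scores.n_axes != 2:
        raise ValueError("virtual species require a 2-axis environmental space")
    diff = scores.coords - center
    md2 = np.einsum("ij,ij->i", diff @ np.linalg.inv(cov), diff)
    q = chi2.ppf(level, df=2)
    inside = md2 <= q
    ids = scores.ids[inside]
    if np.isfinite(q):
        A = np.linalg.inv(cov) / q
    else:  # level == 1: unbounded ellipse; cap at a huge quantile
        A = np.linalg.inv(cov) / chi2.ppf(1 - 1e-12, df=2)
    envelope = NicheEnvelope(
        method="analytic-ellipse",
        level=level,
        geometry=MultiPolygon([_ellipse_polygon(center, A, 256)]),
        metadata={"center": center, "shape_matrix": A},
    )
    return VirtualSpecies(
        name=name, center=center, covariance=cov, level=level,
        pixel_ids=ids, true_envelope=envelope,
    )


@dataclass
class SimulationTruth:
    """Ground-truth parameters of the generative establishment model.

    ``beta`` holds coefficients on the standardized covariate scale (the
    scale the model is fitted on).  Defaults reproduce study-like
    conditions: ~80% baseline success, a strong positive niche-margin and
    propagule-size effect, a negative range-area effect.
    """

    intercept: float = float(logit(0.8))
    beta: dict = field(default_factory=lambda: {
        "nmi": 0.31,
        "n_individuals": 0.56,
        "litters_per_year": 0.27,
        "cv_neonate_mass": 0.36,
        "range_area": -0.43,
    })
    sigma_species: float = 0.5
    sigma_family: float = 0.3
    sigma_region: float = 0.3
    missing_rate: float = 0.1
    n_regions: int = 8
    island_prob: float = 0.25
    inside_fraction: float = 0.65  # fraction of sites drawn inside the species range
    seed: int | None = None

    def beta_vector(self) -> np.ndarray:
        return np.array([self.beta.get(c, 0.0) for c in FIXED_COLS])


#: life-history columns subject to MCAR masking (missing at the species/site level)
MASKABLE_COLS = (
    "weaning_age",
    "litter_size",
    "litters_per_year",
    "cv_adult_mass",
    "cv_neonate_mass",
    "range_area",
)


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def simulate_introductions(
    species: list[VirtualSpecies],
    stack: ClimateStack,
    space: EnvSpace,
    truth: SimulationTruth,
    n_events: int = 979,
    rng: np.random.Generator | None = None,
    return_truth: bool = False,
):
    """Simulate release events with outcomes from the generative model.

    Sites are drawn across the landscape — a fraction inside the focal
    species' range (hence inside its niche), the rest anywhere — NMI is
    computed against each species' analytic true envelope, covariates are
    drawn from log-normal/normal distributions, and outcomes follow
    Bernoulli(logit^-1(linear predictor)) with the truth coefficients.
    MCAR missingness is then applied to the life-history columns.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    n_sp = len(species)
    if n_sp == 0:
        raise ValueError("need at least one species")
    fam_of_sp = np.arange(n_sp) // 4  # ~4 congeners per family
    valid_ids = stack.valid_ids()
    lon_all, lat_all = stack.pixel_lonlat(valid_ids)
    id_to_pos = {int(i): k for k, i in enumerate(valid_ids)}
    scores_all = project(stack, space)

    # species-level traits
    weaning = np.exp(rng.normal(np.log(60.0), 0.8, n_sp))
    litter = np.exp(rng.normal(np.log(3.0), 0.5, n_sp))
    litters_yr = np.clip(rng.normal(1.5, 0.6, n_sp), 0.2, None)
    cv_adult = np.clip(rng.normal(0.15, 0.05, n_sp), 0.01, None)
    cv_neo = np.clip(rng.normal(0.15, 0.05, n_sp), 0.01, None)
    range_area = np.array([len(s.pixel_ids) for s in species], float)
    range_area *= np.prod(stack.cell_size) * 111.0**2  # rough km^2 per cell

    sp_idx = rng.integers(0, n_sp, n_events)
    region = rng.integers(0, truth.n_regions, n_events)
    island = (rng.random(n_events) < truth.island_prob).astype(float)
    n_indiv = np.maximum(1, np.round(np.exp(rng.normal(np.log(20.0), 1.2, n_events)))).astype(float)
    date = rng.integers(1850, 2001, n_events).astype(float)

    site_id = np.empty(n_events, dtype=int)
    for i in range(n_events):
        sp = species[sp_idx[i]]
        if rng.random() < truth.inside_fraction:
            site_id[i] = rng.choice(sp.pixel_ids)
        else:
            site_id[i] = rng.choice(valid_ids)
    pos = np.array([id_to_pos[int(s)] for s in site_id])

    nmi_vals = np.empty(n_events)
    for k, sp in enumerate(species):
        sel = sp_idx == k
        if not sel.any():
            continue
        pts = scores_all.coords[pos[sel]]
        res = compute_nmi(pts, sp.true_envelope)
        nmi_vals[sel] = [r.nmi for r in res]

    raw = {
        "nmi": nmi_vals,
        "n_individuals": n_indiv,
        "intro_date": date,
        "range_area": range_area[sp_idx],
        "weaning_age": weaning[sp_idx],
        "litter_size": litter[sp_idx],
        "litters_per_year": litters_yr[sp_idx],
        "cv_adult_mass": cv_adult[sp_idx],
        "cv_neonate_mass": cv_neo[sp_idx],
        "island": island,
    }
    # linear predictor on the fitted (log + z-scored) covariate scale
    bvec = truth.beta_vector()
    eta = np.full(n_events, truth.intercept)
    for j, col in enumerate(FIXED_COLS):
        v = raw[col]
        if col == "island":
            eta += bvec[j] * v
            continue
        v = np.log(v) if col in LOG_COLS else v
        eta += bvec[j] * _zscore(v)
    a_sp = rng.normal(0, truth.sigma_species, n_sp)
    a_fam = rng.normal(0, truth.sigma_family, fam_of_sp.max() + 1)
    a_reg = rng.normal(0, truth.sigma_region, truth.n_regions)
    eta += a_sp[sp_idx] + a_fam[fam_of_sp[sp_idx]] + a_reg[region]
    psi = expit(eta)
    outcome = (rng.random(n_events) < psi).astype(int)

    records = pd.DataFrame(
        {
            "species": [species[k].name for k in sp_idx],
            "family": [f"family_{f}" for f in fam_of_sp[sp_idx]],
            "region": [f"region_{r}" for r in region],
            "longitude": lon_all[pos],
            "latitude": lat_all[pos],
            "outcome": outcome,
            **{c: raw[c] for c in FIXED_COLS},
        }
    )
    if truth.missing_rate > 0:
        for col in MASKABLE_COLS:
            hide = rng.random(n_events) < truth.missing_rate
            records.loc[hide, col] = np.nan
    if return_truth:
        info = {"psi": psi, "eta": eta, "a_species": a_sp, "a_family": a_fam,
                "a_region": a_reg, "beta": bvec, "intercept": truth.intercept}
        return records, info
    return records


def simulate_model_data(
    truth: SimulationTruth,
    n: int = 1000,
    n_species: int = 50,
    n_families: int = 15,
    n_regions: int = 8,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[ModelData, np.ndarray]:
    """Draw a ModelData set directly from the model, on the standardized scale.

    Continuous covariates (including the NMI column) are drawn N(0, 1) and
    re-centered to exact sample mean 0 / sd 1, so the returned truth vector
    is exactly the coefficient vector of the fitted parameterization.  Used
    for sampler-calibration studies (e.g. HPD coverage) without the
    geometry pipeline.  Returns (data, true beta vector incl. intercept as
    element 0's companion — the vector matches ``ModelData.col_names``).
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    p = len(FIXED_COLS)
    X = np.empty((n, p))
    for j, col in enumerate(FIXED_COLS):
        if col == "island":
            v = (rng.random(n) < truth.island_prob).astype(float)
            if v.std() == 0:
                v[: n // 2] = 1 - v[0]
            X[:, j] = v
        else:
            X[:, j] = _zscore(rng.standard_normal(n))
    sp = rng.integers(0, n_species, n)
    fam_of_sp = rng.integers(0, n_families, n_species)
    fam = fam_of_sp[sp]
    reg = rng.integers(0, n_regions, n)
    a_sp = rng.normal(0, truth.sigma_species, n_species)
    a_fam = rng.normal(0, truth.sigma_family, n_families)
    a_reg = rng.normal(0, truth.sigma_region, n_regions)
    bvec = truth.beta_vector()
    eta = truth.intercept + X @ bvec + a_sp[sp] + a_fam[fam] + a_reg[reg]
    y = (rng.random(n) < expit(eta)).astype(float)
    if y.min() == y.max():  # pathological draw; flip one to keep both classes
        y[0] = 1 - y[0]
    missing = np.zeros((n, p), dtype=bool)
    if missing_rate > 0:
        for col in MASKABLE_COLS:
            j = FIXED_COLS.index(col)
            missing[:, j] = rng.random(n) < missing_rate
    Xm = X.copy()
    Xm[missing] = np.nan
    data = ModelData(
        y=y,
        X=Xm,
        missing=missing,
        col_names=FIXED_COLS,
        col_means=np.zeros(p),
        col_sds=np.ones(p),
        log_flags=np.array([c in LOG_COLS for c in FIXED_COLS]),
        species_idx=sp,
        family_idx=fam,
        region_idx=reg,
        species_levels=np.array([f"sp_{i}" for i in range(n_species)]),
        family_levels=np.array([f"family_{i}" for i in range(n_families)]),
        region_levels=np.array([f"region_{i}" for i in range(n_regions)]),
    )
    return data, bvec
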