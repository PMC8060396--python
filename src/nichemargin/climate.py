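"""Reduced climatic space ("PCA-env") built from gridded climate variables.

The climatic niche of a species is quantified not in geographic space but in
an environmental space: a principal component analysis is calibrated on the
climate values of *all* pixels of the study extent (typically the globe), and
the first axes of that PCA define a low-dimensional plane onto which ranges
and introduction sites are projected.  Because the climate variables mix
units (°C, mm, dimensionless indices), the PCA is computed on centered,
unit-variance variables (correlation PCA) by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClimateStack",
    "EnvSpace",
    "EnvScores",
    "calibrate_env_space",
    "project",
    "aggregate_resolution",
]


@dataclass
class ClimateStack:
    """Co-registered multi-band climate grid with a validity mask.

    Parameters
    ----------
    values : ndarray, shape (n_bands, n_rows, n_cols)
        Band values; row 0 is the northernmost row (image convention).
    mask : ndarray of bool, shape (n_rows, n_cols)
        True where the pixel is valid (e.g. land); masked pixels are
        excluded from every downstream computation.
    extent : tuple (west, south, east, north)
        Geographic extent in decimal degrees, WGS84.
    band_names : list of str
    band_units : list of str, optional
    """

    values: np.ndarray
    mask: np.ndarray
    extent: tuple[float, float, float, float]
    band_names: list[str]
    band_units: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("values must have shape (n_bands, n_rows, n_cols)")
        if self.values.shape[0] < 2:
            raise ValueError("a ClimateStack needs at least 2 variables")
        if self.mask.shape != self.values.shape[1:]:
            raise ValueError("mask shape must match the grid shape")
        if len(self.band_names) != self.values.shape[0]:
            raise ValueError("band_names length must match the number of bands")
        if self.band_units is None:
            self.band_units = ["unknown"] * len(self.band_names)
        west, south, east, north = self.extent
        if not (east > west and north > south):
            raise ValueError("degenerate extent")

    # -- grid geometry -------------------------------------------------
    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    @property
    def cell_size(self) -> tuple[float, float]:
        """(dx, dy) in degrees."""
        west, south, east, north = self.extent
        nr, nc = self.shape
        return (east - west) / nc, (north - south) / nr

    def lon_centers(self) -> np.ndarray:
        west, _, east, _ = self.extent
        nc = self.shape[1]
        dx = (east - west) / nc
        return west + dx * (np.arange(nc) + 0.5)

    def lat_centers(self) -> np.ndarray:
        """Latitudes of row centers, row 0 = northernmost."""
        _, south, _, north = self.extent
        nr = self.shape[0]
        dy = (north - south) / nr
        return north - dy * (np.arange(nr) + 0.5)

    # -- pixel access --------------------------------------------------
    def valid_ids(self) -> np.ndarray:
        """Flat (row-major) indices of valid pixels."""
        return np.flatnonzero(self.mask.ravel())

    def table(self) -> np.ndarray:
        """Valid pixels x variables matrix."""
        flat = self.values.reshape(self.n_bands, -1)
        return flat[:, self.mask.ravel()].T

    def pixel_lonlat(self, ids: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Longitude/latitude of pixel centers for flat indices (default: valid)."""
        if ids is None:
            ids = self.valid_ids()
        nr, nc = self.shape
        rows, cols = np.divmod(np.asarray(ids), nc)
        return self.lon_centers()[cols], self.lat_centers()[rows]


@dataclass
class EnvSpace:
    """A calibrated PCA transform of the climate variables.

    `loadings` has one orthonormal column per component (variables x
    components); `variance_fraction` sums to 1 over all components.  Only the
    first `n_axes` axes are used for projection (2 by default, following the
    convention of analysing niches on the first factorial plane).
    """

    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    n_axes: int
    band_names: list[str]
    scaled: bool = True

    def __post_init__(self) -> None:
        for name in ("means", "sds", "loadings", "eigenvalues", "variance_fraction"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        p = len(self.band_names)
        if self.loadings.shape != (p, p):
            raise ValueError("loadings must be square (variables x components)")
        if not 1 <= self.n_axes <= p:
            raise ValueError("n_axes out of range")
        frac = self.variance_fraction
        if np.any(frac < -1e-9) or np.any(frac > 1 + 1e-9):
            raise ValueError("variance fractions must lie in [0, 1]")
        if np.any(np.diff(frac) > 1e-9):
            raise ValueError("variance fractions must be non-increasing")
        if abs(frac.sum() - 1.0) > 1e-9:
            raise ValueError("variance fractions must sum to 1")
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(p), atol=1e-9):
            raise ValueError("loading columns must be orthonormal")

    def to_json(self) -> str:
        doc = {
            "band_names": self.band_names,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_fraction": self.variance_fraction.tolist(),
            "n_axes": self.n_axes,
            "scaled": self.scaled,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EnvSpace":
        doc = json.loads(text)
        return cls(
            means=doc["means"],
            sds=doc["sds"],
            loadings=doc["loadings"],
            eigenvalues=doc["eigenvalues"],
            variance_fraction=doc["variance_fraction"],
            n_axes=doc["n_axes"],
            band_names=doc["band_names"],
            scaled=doc.get("scaled", True),
        )


@dataclass
class EnvScores:
    """Coordinates of sites/pixels on the retained PCA axes."""

    ids: np.ndarray
    coords: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be 2-D (n x axes)")
        if self.missing is None:
            self.missing = np.zeros(len(self.ids), dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if len(self.ids) != len(self.coords) or len(self.ids) != len(self.missing):
            raise ValueError("inconsistent lengths")
        if not np.all(np.isfinite(self.coords[~self.missing])):
            raise ValueError("non-finite coordinates in non-missing rows")

    @property
    def n_axes(self) -> int:
        return self.coords.shape[1]

    def valid_coords(self) -> np.ndarray:
        return self.coords[~self.missing]


def calibrate_env_space(stack: ClimateStack, n_axes: int = 2, scale: bool = True) -> EnvSpace:
    """Calibrate the reduced climatic space on all valid pixels.

    Centers each variable and (by default) scales it to unit variance, then
    eigendecomposes the correlation (or covariance) matrix.  Axes are ordered
    by decreasing eigenvalue and each axis' sign is fixed so that its
    largest-magnitude loading is positive, making results reproducible.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be a positive integer")
    X = stack.table()
    n, p = X.shape
    if p < n_axes:
        raise ValueError(f"need at least {n_axes} variables, got {p}")
    if n < n_axes + 1:
        raise ValueError(f"too few valid pixels ({n}) to calibrate {n_axes} axes")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        names = ", ".join(stack.band_names[i] for i in zero)
        raise ValueError(f"zero-variance variable(s): {names}")
    if scale:
        Z = (X - means) / sds
    else:
        Z = X - means
        sds = np.ones(p)
    C = (Z.T @ Z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest |loading| per axis is positive
    for j in range(p):
        k = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    total = eigvals.sum()
    return EnvSpace(
        means=means,
        sds=sds,
        loadings=eigvecs,
        eigenvalues=eigvals,
        variance_fraction=eigvals / total,
        n_axes=n_axes,
        band_names=list(stack.band_names),
        scaled=scale,
    )


def project(data, space: EnvSpace) -> EnvScores:
    """Project a ClimateStack, DataFrame or array into the calibrated space.

    score = loadings[:, :n_axes].T @ ((x - mean) / sd).  Rows containing
    non-finite climate values yield a missing score (flagged, never zeroed).
    """
    if isinstance(data, ClimateStack):
        if list(data.band_names) != list(space.band_names):
            raise ValueError(
                "variable mismatch: stack bands "
                f"{data.band_names} != calibration bands {space.band_names}"
            )
        X = data.table()
        ids = data.valid_ids()
    elif isinstance(data, pd.DataFrame):
        missing_cols = [b for b in space.band_names if b not in data.columns]
        if missing_cols:
            raise ValueError(f"missing variable column(s): {missing_cols}")
        X = data[space.band_names].to_numpy(dtype=float)
        ids = data.index.to_numpy()
    else:
        X = np.asarray(data, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(space.band_names):
            raise ValueError(
                f"expected {len(space.band_names)} variables, got {X.shape[1]}"
            )
        ids = np.arange(X.shape[0])
    bad = ~np.all(np.isfinite(X), axis=1)
    Z = (X - space.means) / space.sds
    scores = Z @ space.loadings[:, : space.n_axes]
    scores[bad] = np.nan
    return EnvScores(ids=ids, coords=scores, missing=bad)


def aggregate_resolution(stack: ClimateStack, factor: int) -> ClimateStack:
    """Aggregate the grid to a coarser resolution by block-averaging.

    Each coarse cell is the mean of its valid fine cells; partial edge
    blocks are averaged over the fine cells available.  A coarse cell is
    masked only when every contributing fine cell is masked.
    """
    if not isinstance(factor, (int, np.integer)) or factor <= 0:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return ClimateStack(
            values=stack.values.copy(),
            mask=stack.mask.copy(),
            extent=stack.extent,
            band_names=list(stack.band_names),
            band_units=list(stack.band_units),
        )
    nr, nc = stack.shape
    row_idx = np.arange(0, nr, factor)
    col_idx = np.arange(0, nc, factor)
    m = stack.mask.astype(float)
    vals = np.where(stack.mask, stack.values, 0.0)

    def block_sum(a: np.ndarray) -> np.ndarray:
        s = np.add.reduceat(a, row_idx, axis=-2)
        return np.add.reduceat(s, col_idx, axis=-1)

    counts = block_sum(m)
    sums = block_sum(vals)
    with np.errstate(invalid="ignore", divide="ignore"):
        coarse = sums / counts
    coarse_mask = counts > 0
    coarse[:, ~coarse_mask] = np.nan
    return ClimateStack(
        values=coarse,
        mask=coarse_mask,
        extent=stack.extent,
        band_names=list(stack.band_names),
        band_units=list(stack.band_units),
    )
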