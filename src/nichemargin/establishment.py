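"""Hierarchical Bayesian logistic model of establishment success.

Each introduction event i of species s has a binary outcome

    Y_i(s) ~ Bernoulli(psi_i(s))
    logit(psi_i(s)) = alpha + a_species(s) + a_family(fam(s)) + a_region(r)
                      + beta_NMI * NMI_i(s) + sum_c beta_c * Covariate_c,i(s)

with species intercepts nested within family intercepts plus a biogeographic
region intercept, all Normal(0, sigma.) with half-Cauchy priors on the
sigmas; fixed effects have Normal(0, precision 0.1) priors.  Missing
covariate cells are treated as MCAR and imputed jointly during sampling
(covariate c ~ Normal(nu_c, sigma_c), nu_c ~ Normal(0, 10), sigma_c
half-Cauchy), so the posterior propagates imputation uncertainty.

Posterior sampling uses Polya-Gamma data augmentation, which makes every
full conditional (fixed effects, random intercepts, missing cells,
imputation means) Gaussian and the variance parameters inverse-gamma via
the usual half-Cauchy parameter expansion; the result is a tuning-free
Gibbs sampler.  Effect sizes are posterior medians, confidence is the 95%
highest posterior density interval, and the directional posterior
probability P[effect > 0] is the fraction of retained draws above zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit
from scipy.stats import rankdata

from ._polyagamma import sample_pg

__all__ = [
    "LOG_COLS",
    "CONTINUOUS_COLS",
    "FIXED_COLS",
    "ModelData",
    "ModelSpec",
    "PosteriorSummary",
    "prepare_covariates",
    "fit_model",
    "posterior_probability_positive",
    "hpd_interval",
    "gelman_rubin",
    "bayesian_p_value",
    "max_tss",
    "cross_validate",
    "wilcoxon_rank_sum",
]

#: covariates natural-log-transformed before standardization (to reduce skew)
LOG_COLS = ("n_individuals", "weaning_age", "range_area", "intro_date", "litter_size")

#: continuous fixed-effect columns, z-scored on observed entries (NMI first)
CONTINUOUS_COLS = (
    "nmi",
    "n_individuals",
    "intro_date",
    "range_area",
    "weaning_age",
    "litter_size",
    "litters_per_year",
    "cv_adult_mass",
    "cv_neonate_mass",
)

#: full fixed-effect design: 9 continuous + the binary island flag
#: (mainland is the reference, so the intercept is the mainland average)
FIXED_COLS = CONTINUOUS_COLS + ("island",)


@dataclass
class ModelData:
    """Response, standardized design matrix, missingness and grouping indices."""

    y: np.ndarray
    X: np.ndarray  # (n, 10); NaN marks a missing cell
    missing: np.ndarray  # (n, 10) bool
    col_names: tuple[str, ...]
    col_means: np.ndarray
    col_sds: np.ndarray
    log_flags: np.ndarray
    species_idx: np.ndarray
    family_idx: np.ndarray
    region_idx: np.ndarray
    species_levels: np.ndarray
    family_levels: np.ndarray
    region_levels: np.ndarray

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_species(self) -> int:
        return len(self.species_levels)

    @property
    def n_families(self) -> int:
        return len(self.family_levels)

    @property
    def n_regions(self) -> int:
        return len(self.region_levels)

    def subset(self, rows: np.ndarray) -> "ModelData":
        """Row subset sharing the level sets and transform parameters."""
        return ModelData(
            y=self.y[rows],
            X=self.X[rows],
            missing=self.missing[rows],
            col_names=self.col_names,
            col_means=self.col_means,
            col_sds=self.col_sds,
            log_flags=self.log_flags,
            species_idx=self.species_idx[rows],
            family_idx=self.family_idx[rows],
            region_idx=self.region_idx[rows],
            species_levels=self.species_levels,
            family_levels=self.family_levels,
            region_levels=self.region_levels,
        )


@dataclass
class ModelSpec:
    """Priors and MCMC configuration.

    Defaults follow the reference analysis: fixed effects Normal(0,
    precision 0.1); half-Cauchy(scale 5) on random-effect and imputation
    sds; 2 chains, 5000 burn-in, 20000 further iterations thinned by 20
    (2 x 1000 = 2000 retained draws).
    """

    prior_precision: float = 0.1
    sigma_scale: float = 5.0
    nu_prior_sd: float = 10.0
    chains: int = 2
    burn_in: int = 5000
    iterations: int = 20000
    thin: int = 20
    seed: int | None = None
    pg_trunc: int = 64

    def __post_init__(self) -> None:
        if self.prior_precision <= 0 or self.sigma_scale <= 0 or self.nu_prior_sd <= 0:
            raise ValueError("prior precision/scales must be positive")
        if self.chains < 1 or self.burn_in < 0 or self.iterations < 1 or self.thin < 1:
            raise ValueError("invalid MCMC configuration")
        if self.iterations % self.thin != 0:
            raise ValueError("thin must divide iterations")

    @property
    def retained_per_chain(self) -> int:
        return self.iterations // self.thin


def prepare_covariates(records: pd.DataFrame) -> ModelData:
    """Build the standardized design matrix from raw introduction records.

    Expects columns: species, family, region, outcome, and the covariates in
    :data:`FIXED_COLS` (missing cells allowed, left masked).  The five
    covariates in :data:`LOG_COLS` are natural-log-transformed, then every
    continuous column is z-scored (sample sd) over its observed entries; the
    island flag stays binary with mainland as reference.
    """
    req = {"species", "family", "region", "outcome"}
    missing_cols = sorted(req.union(FIXED_COLS) - set(records.columns))
    if missing_cols:
        raise ValueError(f"missing column(s): {missing_cols}")
    y = records["outcome"].to_numpy()
    if not np.isin(y, [0, 1]).all():
        raise ValueError("outcome must be binary (0 = failed, 1 = established)")
    y = y.astype(float)

    fam_of = records.groupby("species")["family"].nunique()
    bad = fam_of[fam_of > 1]
    if len(bad):
        raise ValueError(f"species mapped to multiple families: {list(bad.index)}")

    n = len(records)
    p = len(FIXED_COLS)
    X = np.full((n, p), np.nan)
    log_flags = np.array([c in LOG_COLS for c in FIXED_COLS])
    means = np.zeros(p)
    sds = np.ones(p)
    for j, col in enumerate(FIXED_COLS):
        v = records[col].to_numpy(dtype=float)
        obs = np.isfinite(v)
        if col == "island":
            vals = v[obs]
            if not np.isin(vals, [0, 1]).all():
                raise ValueError("island must be binary (0 = mainland, 1 = island)")
            X[obs, j] = vals
            continue
        if col == "n_individuals" and np.any(v[obs] < 1):
            rows = records.index[obs][v[obs] < 1].tolist()
            raise ValueError(f"number of introduced individuals < 1 at record(s) {rows}")
        if log_flags[j]:
            if np.any(v[obs] <= 0):
                rows = records.index[obs][v[obs] <= 0].tolist()
                raise ValueError(f"non-positive value under log for '{col}' at record(s) {rows}")
            v = np.where(obs, np.log(np.where(obs, v, 1.0)), np.nan)
        vals = v[obs]
        if len(np.unique(vals)) < 2:
            raise ValueError(f"covariate '{col}' has fewer than 2 distinct observed values")
        m = vals.mean()
        s = vals.std(ddof=1)
        if s == 0:
            raise ValueError(f"zero-variance observed column: '{col}'")
        means[j], sds[j] = m, s
        X[obs, j] = (vals - m) / s

    sp_levels, sp_idx = np.unique(records["species"].to_numpy(), return_inverse=True)
    fam_levels, fam_idx_sp = np.unique(
        records.groupby("species", sort=True)["family"].first().to_numpy(), return_inverse=True
    )
    fam_idx = fam_idx_sp[sp_idx]
    reg_levels, reg_idx = np.unique(records["region"].to_numpy(), return_inverse=True)
    return ModelData(
        y=y,
        X=X,
        missing=~np.isfinite(X),
        col_names=FIXED_COLS,
        col_means=means,
        col_sds=sds,
        log_flags=log_flags,
        species_idx=sp_idx,
        family_idx=fam_idx,
        region_idx=reg_idx,
        species_levels=sp_levels,
        family_levels=fam_levels,
        region_levels=reg_levels,
    )


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


def _run_chain(data: ModelData, spec: ModelSpec, seed: np.random.SeedSequence, init_sd: float):
    rng = np.random.default_rng(seed)
    n, p = data.X.shape
    S, F, R = data.n_species, data.n_families, data.n_regions
    sp, fam, reg = data.species_idx, data.family_idx, data.region_idx
    y = data.y
    kappa = y - 0.5
    var0 = 1.0 / spec.prior_precision
    A2 = spec.sigma_scale**2
    nu_var0 = spec.nu_prior_sd**2

    miss = data.missing
    miss_cols = [j for j in range(p) if miss[:, j].any()]
    X = np.where(miss, 0.0, data.X)

    # overdispersed random initial values, one region of parameter space per chain
    alpha = rng.normal(0, init_sd)
    beta = rng.normal(0, init_sd, p)
    a_sp = rng.normal(0, 0.1, S)
    a_fam = rng.normal(0, 0.1, F)
    a_reg = rng.normal(0, 0.1, R)
    sig2 = {"sp": 1.0, "fam": 1.0, "reg": 1.0}
    xi = {"sp": 1.0, "fam": 1.0, "reg": 1.0}
    nu = {j: 0.0 for j in miss_cols}
    sig2_c = {j: 1.0 for j in miss_cols}
    xi_c = {j: 1.0 for j in miss_cols}

    n_keep = spec.retained_per_chain
    fixed_names = ["alpha"] + [f"beta_{c}" for c in data.col_names]
    names = (
        fixed_names
        + ["sigma_species", "sigma_family", "sigma_region"]
        + [f"nu_{data.col_names[j]}" for j in miss_cols]
        + [f"sigma_cov_{data.col_names[j]}" for j in miss_cols]
        + [f"a_species[{lv}]" for lv in data.species_levels]
        + [f"a_family[{lv}]" for lv in data.family_levels]
        + [f"a_region[{lv}]" for lv in data.region_levels]
    )
    draws = np.empty((n_keep, len(names)))
    psi_draws = np.empty((n_keep, n))
    t_obs = np.empty(n_keep)
    t_rep = np.empty(n_keep)

    prior_prec_fixed = np.full(p + 1, spec.prior_precision)
    Xd = np.empty((n, p + 1))
    Xd[:, 0] = 1.0

    eta = alpha + a_sp[sp] + a_fam[fam] + a_reg[reg] + X @ beta
    keep_i = 0
    total_iter = spec.burn_in + spec.iterations
    for it in range(total_iter):
        omega = sample_pg(rng, eta, spec.pg_trunc)

        # fixed effects (intercept + slopes) jointly
        offset = a_sp[sp] + a_fam[fam] + a_reg[reg]
        Xd[:, 1:] = X
        WX = Xd * omega[:, None]
        prec = Xd.T @ WX
        prec[np.diag_indices_from(prec)] += prior_prec_fixed
        rhs = Xd.T @ (kappa - omega * offset)
        cf = cho_factor(prec, lower=True)
        mean = cho_solve(cf, rhs)
        z = rng.standard_normal(p + 1)
        drawn = mean + cho_solve_sample(cf, z)
        alpha, beta = drawn[0], drawn[1:]
        eta = alpha + offset + X @ beta

        # random intercepts, one factor at a time
        for idx, size, key, arr in (
            (sp, S, "sp", a_sp),
            (fam, F, "fam", a_fam),
            (reg, R, "reg", a_reg),
        ):
            eta_wo = eta - arr[idx]
            prec_g = np.bincount(idx, weights=omega, minlength=size) + 1.0 / sig2[key]
            mean_g = np.bincount(idx, weights=kappa - omega * eta_wo, minlength=size) / prec_g
            new = mean_g + rng.standard_normal(size) / np.sqrt(prec_g)
            if key == "sp":
                a_sp = new
            elif key == "fam":
                a_fam = new
            else:
                a_reg = new
            eta = eta_wo + new[idx]
            # half-Cauchy sd via inverse-gamma parameter expansion
            b = 1.0 / xi[key] + 0.5 * np.sum(new**2)
            sig2[key] = b / rng.gamma(0.5 * (size + 1))
            xi[key] = (1.0 / A2 + 1.0 / sig2[key]) / rng.gamma(1.0)
            # ancillary (non-centered) rescaling: with a = s * a_tilde the
            # PG likelihood is exactly Gaussian in s, so propose from that
            # conditional and Metropolis-correct by the half-Cauchy prior
            # ratio; this breaks the funnel between the sd and the effects
            s_cur = np.sqrt(sig2[key])
            atil = new / s_cur
            w = atil[idx]
            P_s = np.sum(omega * w * w) + 1e-12
            m_s = np.sum((kappa - omega * (eta - new[idx])) * w) / P_s
            s_prop = abs(m_s + rng.standard_normal() / np.sqrt(P_s))
            log_acc = np.log1p(s_cur**2 / A2) - np.log1p(s_prop**2 / A2)
            if np.log(rng.random()) < log_acc:
                eta_base = eta - new[idx]
                new = s_prop * atil
                sig2[key] = s_prop**2
                eta = eta_base + new[idx]
                if key == "sp":
                    a_sp = new
                elif key == "fam":
                    a_fam = new
                else:
                    a_reg = new

        # missing covariate cells (MCAR Normal imputation model)
        for j in miss_cols:
            m = miss[:, j]
            bj = beta[j]
            eta_wo = eta - bj * X[:, j]
            prec_m = omega[m] * bj**2 + 1.0 / sig2_c[j]
            mean_m = (bj * (kappa[m] - omega[m] * eta_wo[m]) + nu[j] / sig2_c[j]) / prec_m
            X[m, j] = mean_m + rng.standard_normal(m.sum()) / np.sqrt(prec_m)
            eta = eta_wo + bj * X[:, j]
            # imputation-model mean and sd
            col = X[:, j]
            prec_nu = n / sig2_c[j] + 1.0 / nu_var0
            mean_nu = (col.sum() / sig2_c[j]) / prec_nu
            nu[j] = mean_nu + rng.standard_normal() / np.sqrt(prec_nu)
            b = 1.0 / xi_c[j] + 0.5 * np.sum((col - nu[j]) ** 2)
            sig2_c[j] = b / rng.gamma(0.5 * (n + 1))
            xi_c[j] = (1.0 / A2 + 1.0 / sig2_c[j]) / rng.gamma(1.0)

        if it >= spec.burn_in and (it - spec.burn_in + 1) % spec.thin == 0:
            psi = expit(eta)
            psi_c = np.clip(psi, 1e-10, 1 - 1e-10)
            draws[keep_i] = np.concatenate(
                [
                    [alpha],
                    beta,
                    np.sqrt([sig2["sp"], sig2["fam"], sig2["reg"]]),
                    [nu[j] for j in miss_cols],
                    [np.sqrt(sig2_c[j]) for j in miss_cols],
                    a_sp,
                    a_fam,
                    a_reg,
                ]
            )
            psi_draws[keep_i] = psi
            var = psi_c * (1 - psi_c)
            t_obs[keep_i] = np.sum((y - psi_c) ** 2 / var)
            y_rep = (rng.random(n) < psi).astype(float)
            t_rep[keep_i] = np.sum((y_rep - psi_c) ** 2 / var)
            keep_i += 1

    return names, draws, psi_draws, t_obs, t_rep


def cho_solve_sample(cf, z: np.ndarray) -> np.ndarray:
    """Draw N(0, Prec^-1) noise from a lower-Cholesky factorization of Prec."""
    from scipy.linalg import solve_triangular

    L, _ = cf  # Prec = L L', so L'^-1 z has covariance Prec^-1
    return solve_triangular(L, z, lower=True, trans="T")


@dataclass
class PosteriorSummary:
    """Retained posterior draws plus per-parameter summaries and diagnostics."""

    names: list[str]
    chains: np.ndarray  # (n_chains, n_draws, n_params)
    psi: np.ndarray  # (total_draws, n_obs)
    t_obs: np.ndarray
    t_rep: np.ndarray
    data: ModelData
    spec: ModelSpec
    seed: int | None
    rhat: np.ndarray = field(init=False)
    converged: bool = field(init=False)

    def __post_init__(self) -> None:
        self.rhat = np.array(
            [gelman_rubin(self.chains[:, :, j]) for j in range(self.chains.shape[2])]
        )
        finite = self.rhat[np.isfinite(self.rhat)]
        self.converged = bool(np.all(finite <= 1.1))

    @property
    def samples(self) -> np.ndarray:
        """(total_draws, n_params) pooled across chains."""
        return self.chains.reshape(-1, self.chains.shape[2])

    @property
    def max_rhat(self) -> float:
        finite = self.rhat[np.isfinite(self.rhat)]
        return float(finite.max()) if len(finite) else float("nan")

    def parameter(self, name: str) -> np.ndarray:
        return self.samples[:, self.names.index(name)]

    def median(self, name: str) -> float:
        return float(np.median(self.parameter(name)))

    def summary(self, parameters: list[str] | None = None, hpd_mass: float = 0.95) -> pd.DataFrame:
        """Effect sizes (posterior medians), HPD interval, P[effect>0], Rhat."""
        if parameters is None:
            parameters = [nm for nm in self.names if not nm.startswith("a_")]
        rows = []
        for nm in parameters:
            s = self.parameter(nm)
            lo, hi = hpd_interval(s, hpd_mass)
            rows.append(
                {
                    "parameter": nm,
                    "median": float(np.median(s)),
                    "hpd_low": lo,
                    "hpd_high": hi,
                    "p_positive": posterior_probability_positive(s),
                    "rhat": self.rhat[self.names.index(nm)],
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    # -- prediction -----------------------------------------------------
    def _median_state(self):
        med = np.median(self.samples, axis=0)
        get = dict(zip(self.names, med))
        p = len(self.data.col_names)
        beta = np.array([get[f"beta_{c}"] for c in self.data.col_names])
        a_sp = np.array([get[f"a_species[{lv}]"] for lv in self.data.species_levels])
        a_fam = np.array([get[f"a_family[{lv}]"] for lv in self.data.family_levels])
        a_reg = np.array([get[f"a_region[{lv}]"] for lv in self.data.region_levels])
        nu = np.zeros(p)
        for j, c in enumerate(self.data.col_names):
            nu[j] = get.get(f"nu_{c}", 0.0)
        return get["alpha"], beta, a_sp, a_fam, a_reg, nu

    def predict(self, newdata: ModelData) -> np.ndarray:
        """Posterior-median success probability for new rows.

        Missing covariate cells are filled with the imputation-model median
        (approximately the standardized column mean); group levels never seen
        in the fit effectively sit at the population mean (their posterior
        median is prior-centered near 0).
        """
        alpha, beta, a_sp, a_fam, a_reg, nu = self._median_state()
        X = np.where(newdata.missing, nu[None, :], newdata.X)
        eta = (
            alpha
            + a_sp[newdata.species_idx]
            + a_fam[newdata.family_idx]
            + a_reg[newdata.region_idx]
            + X @ beta
        )
        return expit(eta)

    def fitted_probabilities(self) -> np.ndarray:
        """Posterior mean of psi per observation (explanatory predictions)."""
        return self.psi.mean(axis=0)


def fit_model(data: ModelData, spec: ModelSpec | None = None) -> PosteriorSummary:
    """Sample the joint posterior and return summaries.

    Runs ``spec.chains`` Gibbs chains from overdispersed random starting
    points, discards ``burn_in`` iterations, and retains every ``thin``-th of
    the following ``iterations`` draws.  If any parameter's Gelman-Rubin
    Rhat exceeds 1.1, the result is flagged (``converged = False``) and a
    warning is issued; the result is never silently discarded.
    """
    if spec is None:
        spec = ModelSpec()
    if data.y.min() == data.y.max():
        raise ValueError("need at least one success and one failure")
    for idx, size in (
        (data.species_idx, data.n_species),
        (data.family_idx, data.n_families),
        (data.region_idx, data.n_regions),
    ):
        if idx.min() < 0 or idx.max() >= size:
            raise ValueError("grouping index out of range")
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    all_draws, all_psi, all_tobs, all_trep = [], [], [], []
    names = None
    for c, ss in enumerate(seeds):
        names, draws, psi, tobs, trep = _run_chain(data, spec, ss, init_sd=1.0 + c)
        all_draws.append(draws)
        all_psi.append(psi)
        all_tobs.append(tobs)
        all_trep.append(trep)
    fit = PosteriorSummary(
        names=names,
        chains=np.stack(all_draws),
        psi=np.concatenate(all_psi),
        t_obs=np.concatenate(all_tobs),
        t_rep=np.concatenate(all_trep),
        data=data,
        spec=spec,
        seed=spec.seed,
    )
    if not fit.converged:
        warnings.warn(
            f"chains may not have converged: max Rhat = {fit.max_rhat:.3f} > 1.1",
            RuntimeWarning,
            stacklevel=2,
        )
    return fit


# ---------------------------------------------------------------------------
# Posterior and fit diagnostics
# ---------------------------------------------------------------------------


def posterior_probability_positive(samples: np.ndarray) -> float:
    """Fraction of posterior draws above zero."""
    s = np.asarray(samples, float)
    if s.size == 0:
        raise ValueError("empty sample")
    return float(np.mean(s > 0))


def hpd_interval(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` draws."""
    if not (0 < mass < 1):
        raise ValueError("mass must lie in (0, 1)")
    s = np.sort(np.asarray(samples, float))
    n = len(s)
    if n < 20:
        raise ValueError("need at least 20 samples for an HPD interval")
    m = int(np.ceil(mass * n))
    widths = s[m - 1 :] - s[: n - m + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + m - 1])


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor (plain formula, no chain splitting)."""
    c = np.asarray(chains, float)
    if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
        raise ValueError("need (m >= 2 chains, n >= 2 draws)")
    m, n = c.shape
    chain_means = c.mean(axis=1)
    W = c.var(axis=1, ddof=1).mean()
    B = n * chain_means.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else float("inf")
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def bayesian_p_value(fit: PosteriorSummary, data: ModelData | None = None) -> float:
    """Posterior predictive check on squared standardized Pearson residuals.

    For each retained draw the discrepancy T = sum (y - psi)^2 / (psi (1 -
    psi)) is computed for the observed outcomes and for outcomes replicated
    from the same draw; the returned p is the fraction of draws where the
    replicated discrepancy exceeds the observed one.  Values near 0.5
    indicate adequate fit; values near 0 or 1 indicate misfit.
    """
    if fit.t_obs.size == 0:
        raise ValueError("fit carries no retained draws")
    return float(np.mean(fit.t_rep > fit.t_obs))


def max_tss(
    predicted_probabilities: np.ndarray,
    outcomes: np.ndarray,
    grid_step: float = 0.001,
) -> tuple[float, float]:
    """Maximum true skill statistic over a threshold grid on [0, 1].

    TSS(t) = sensitivity(t) + specificity(t) - 1 with "established"
    predicted when p >= t.  Returns (maxTSS, smallest achieving threshold).
    """
    p = np.asarray(predicted_probabilities, float)
    y = np.asarray(outcomes, float)
    if p.shape != y.shape:
        raise ValueError("shape mismatch")
    pos = y == 1
    n_pos = pos.sum()
    n_neg = (~pos).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both outcome classes")
    thresholds = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    pred = p[None, :] >= thresholds[:, None]
    sens = (pred & pos[None, :]).sum(axis=1) / n_pos
    spec = (~pred & ~pos[None, :]).sum(axis=1) / n_neg
    tss = sens + spec - 1.0
    i = int(np.argmax(tss))
    return float(tss[i]), float(thresholds[i])


def cross_validate(
    data: ModelData,
    spec: ModelSpec | None = None,
    reps: int = 10,
    train_fraction: float = 0.8,
    seed: int | None = None,
) -> list[float]:
    """Repeated split-sample internal validation.

    Each repetition draws a random split stratified by outcome (so both
    classes appear in the evaluation set), refits the model on the training
    fraction and scores the held-out events with maxTSS using
    posterior-median parameters.  Returns the list of evaluation maxTSS.
    """
    if spec is None:
        spec = ModelSpec()
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    scores = []
    for rep in range(reps):
        train = np.zeros(data.n, dtype=bool)
        for cls in (0, 1):
            rows = np.flatnonzero(data.y == cls)
            rng.shuffle(rows)
            k = int(round(train_fraction * len(rows)))
            k = min(max(k, 1), len(rows) - 1)
            train[rows[:k]] = True
        rep_spec = ModelSpec(
            **{**spec.__dict__, "seed": int(rng.integers(2**31 - 1))}
        )
        fit = fit_model(data.subset(train), rep_spec)
        p_test = fit.predict(data.subset(~train))
        tss, _ = max_tss(p_test, data.y[~train])
        scores.append(tss)
    return scores


def wilcoxon_rank_sum(
    success_values: np.ndarray,
    failure_values: np.ndarray,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test with midrank ties.

    Returns (U, p) where U is the Mann-Whitney statistic of the first
    sample.  The p-value is computed by exhaustive enumeration of rank
    assignments when both samples have at most 10 values, and otherwise by
    the normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(success_values, float)
    y = np.asarray(failure_values, float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    if n1 <= 10 and n2 <= 10:
        us = []
        base = n1 * (n1 + 1) / 2.0
        for sel in combinations(range(n1 + n2), n1):
            us.append(ranks[list(sel)].sum() - base)
        us = np.asarray(us)
        eps = 1e-9
        if alternative == "two-sided":
            p = float(np.mean(np.abs(us - mu) >= abs(u - mu) - eps))
        elif alternative == "greater":
            p = float(np.mean(us >= u - eps))
        elif alternative == "less":
            p = float(np.mean(us <= u + eps))
        else:
            raise ValueError("alternative must be two-sided/greater/less")
        return float(u), p

    # normal approximation with tie and continuity corrections
    N = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (N * (N - 1))
    var = n1 * n2 / 12.0 * (N + 1 - tie_term)
    if var == 0:
        return float(u), 1.0
    from scipy.stats import norm

    if alternative == "two-sided":
        z = (abs(u - mu) - 0.5) / np.sqrt(var)
        p = 2 * norm.sf(max(z, 0.0))
    elif alternative == "greater":
        z = (u - mu - 0.5) / np.sqrt(var)
        p = norm.sf(z)
    elif alternative == "less":
        z = (u - mu + 0.5) / np.sqrt(var)
        p = norm.cdf(z)
    else:
        raise ValueError("alternative must be two-sided/greater/less")
    return float(u), float(min(p, 1.0))
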