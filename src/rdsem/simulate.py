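"""Synthetic five-year PSUD-recovery cohorts from the two-level rDSEM process.

The generator emulates a prospective substance-use-disorder cohort: N persons
observed on a quarterly/annual schedule over five years, three continuous
outcomes driven by person-specific intercepts and linear trends plus a
stationary lag-1 VAR on the detrended residuals, demographic covariates
(age truncated at the inclusion minimum of 16, binary gender), attrition via
an empirical cluster-size law, and within-occasion item missingness with an
MAR dependence of life-satisfaction missingness on the observed
substance-use score.

Outcomes are simulated as continuous Gaussians on the downscaled (rescaled)
metric, which is the metric the model is estimated on; clipping to the raw
instrument ranges is available but off by default so parameter recovery stays
unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .dynamics import spectral_radius, stationary_cov
from .exceptions import ConfigError
from .model import ModelSpec, ParameterSet
from .panel import (DEFAULT_RESCALE_FACTORS, OUTCOMES, OUTCOME_RANGES,
                    SCHEDULES, PanelDataset)

#: Cluster-size law of the emulated cohort: share of persons by number of
#: attended occasions (out of eleven).
DEFAULT_CLUSTER_SIZE_PROBS = {5: 0.018, 6: 0.024, 7: 0.012, 8: 0.061,
                              9: 0.037, 10: 0.098, 11: 0.750}

#: Per-outcome item-missingness rates within attended occasions, derived from
#: the cohort's marginal missing fractions net of whole-occasion attrition.
#: Approximate: the generator reproduces marginal rates and the cluster-size
#: law, not the full joint pattern table.
DEFAULT_ITEM_MISSING_RATES = {"dudit_c": 0.322, "swls": 0.091, "scl90r_gsi": 0.507}


@dataclass
class GeneratingConfig:
    """True parameter values plus schedule, demographics and missingness.

    The dynamic parameters have the same meaning as :class:`ParameterSet`;
    ``missing_dependence`` is the odds multiplier on life-satisfaction
    missingness per standard deviation of the observed substance-use score
    (1.0 = independent missingness).
    """

    n_persons: int = 164
    schedule: tuple = SCHEDULES["stayer11"]
    lattice_step: int = 3
    # dynamic / structural parameters (rescaled metric)
    phi: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    sigma_u: np.ndarray = field(default_factory=lambda: np.eye(3))
    grand_intercepts: np.ndarray = field(default_factory=lambda: np.zeros(3))
    trend_means: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gamma_alpha: np.ndarray = field(default_factory=lambda: np.zeros((3, 2)))
    gamma_beta: np.ndarray = field(default_factory=lambda: np.zeros((3, 2)))
    sigma_alpha: np.ndarray = field(default_factory=lambda: 0.1 * np.eye(3))
    sigma_beta2: np.ndarray = field(default_factory=lambda: 0.01 * np.ones(3))
    # demographics
    age_mean: float = 27.1       # mean of the (truncated) age distribution
    age_sd: float = 7.1          # SD of the (truncated) age distribution
    age_min: float = 16.0
    male_prop: float = 0.622
    # drug-free-friends covariate: near-constant binary
    dff_prob: float = 0.85
    dff_nonconstant_prop: float = 0.05
    # missingness
    cluster_size_probs: dict = field(default_factory=lambda: dict(DEFAULT_CLUSTER_SIZE_PROBS))
    item_missing_rates: dict = field(default_factory=lambda: dict(DEFAULT_ITEM_MISSING_RATES))
    missing_dependence: float = 2.0
    # behaviour flags
    stationary_init: bool = True
    clip_to_ranges: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("phi", "sigma_u", "grand_intercepts", "trend_means",
                     "gamma_alpha", "gamma_beta", "sigma_alpha", "sigma_beta2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.schedule = tuple(int(m) for m in self.schedule)
        if self.n_persons < 1:
            raise ConfigError("n_persons must be positive")
        tot = sum(self.cluster_size_probs.values())
        if abs(tot - 1.0) > 1e-8:
            raise ConfigError(f"cluster_size_probs sums to {tot}, expected 1")
        if max(self.cluster_size_probs) > len(self.schedule):
            raise ConfigError("cluster size exceeds number of occasions")
        for v, r in self.item_missing_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"missing rate for {v} outside [0, 1]: {r}")
        if self.missing_dependence <= 0:
            raise ConfigError("missing_dependence must be a positive odds multiplier")
        if spectral_radius(self.phi) >= 1.0:
            raise ConfigError("phi must be stationary (spectral radius < 1)")
        for m, name in ((self.sigma_u, "sigma_u"), (self.sigma_alpha, "sigma_alpha")):
            if not np.allclose(m, m.T) or np.any(np.linalg.eigvalsh(m) <= 0):
                raise ConfigError(f"{name} must be symmetric positive definite")

    # -- views ----------------------------------------------------------
    def to_parameter_set(self) -> ParameterSet:
        return ParameterSet(
            phi=self.phi, sigma_u=self.sigma_u,
            grand_intercepts=self.grand_intercepts, trend_means=self.trend_means,
            gamma_alpha=self.gamma_alpha, gamma_beta=self.gamma_beta,
            sigma_alpha=self.sigma_alpha, sigma_beta2=self.sigma_beta2,
        )

    def lattice_months(self) -> np.ndarray:
        return np.arange(min(self.schedule), max(self.schedule) + 1, self.lattice_step)

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        d = {}
        for k, v in self.__dict__.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
            elif isinstance(v, dict):
                d[k] = {int(kk) if isinstance(kk, (int, np.integer)) else kk: float(vv)
                        for kk, vv in v.items()}
            elif isinstance(v, tuple):
                d[k] = list(v)
            else:
                d[k] = v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratingConfig":
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "GeneratingConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ----------------------------------------------------------------------
# Demographics
# ----------------------------------------------------------------------

@lru_cache(maxsize=8)
def _truncnorm_underlying(mean: float, sd: float, lower: float) -> tuple[float, float]:
    """Location/scale of the normal whose ``lower``-truncated version has the
    given mean and SD.  Reported cohort moments describe the observed
    (already truncated) ages, so naive truncation of N(mean, sd^2) would bias
    the simulated mean upward."""

    def eqs(p):
        loc, log_scale = p
        scale = float(np.exp(log_scale))
        a = (lower - loc) / scale
        d = stats.truncnorm(a, np.inf, loc=loc, scale=scale)
        return [d.mean() - mean, d.std() - sd]

    sol = optimize.root(eqs, x0=[mean - 1.0, np.log(sd * 1.1)], tol=1e-12)
    if not sol.success:
        raise ConfigError(f"cannot match truncated-age moments ({mean}, {sd}, >= {lower})")
    loc, log_scale = sol.x
    return float(loc), float(np.exp(log_scale))


def draw_ages(config: GeneratingConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    loc, scale = _truncnorm_underlying(config.age_mean, config.age_sd, config.age_min)
    a = (config.age_min - loc) / scale
    return stats.truncnorm.rvs(a, np.inf, loc=loc, scale=scale, size=n, random_state=rng)


# ----------------------------------------------------------------------
# Core operations
# ----------------------------------------------------------------------

def stationary_moments(config: GeneratingConfig) -> np.ndarray:
    """Stationary within-level covariance of the detrended residuals."""
    return stationary_cov(config.phi, config.sigma_u)


def generate_panel(config: GeneratingConfig, seed: int | None = None,
                   return_latents: bool = False):
    """Simulate a complete (pre-missingness) cohort.

    Per person: draw age and gender, then latent intercepts and trend slopes
    from the between model; simulate the residual VAR on the 3-month lattice
    (first occasion from the stationary distribution unless
    ``stationary_init`` is off, in which case the innovation distribution is
    used as a diffuse start); emit y = intercept + slope * years + residual
    at the scheduled months only.  Deterministic given the seed.

    With ``return_latents`` the true person effects and residual paths are
    returned alongside the panel (useful for oracle checks).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, p = config.n_persons, 3
    months = config.lattice_months()
    tau = months / 12.0
    sched_idx = np.array([int(np.where(months == m)[0][0]) for m in config.schedule])

    age = draw_ages(config, n, rng)
    gender = (rng.random(n) < config.male_prop).astype(float)
    age_std = (age - config.age_mean) / config.age_sd
    x = np.column_stack([gender, age_std])

    la = np.linalg.cholesky(config.sigma_alpha)
    alpha = config.grand_intercepts + x @ config.gamma_alpha.T + rng.standard_normal((n, p)) @ la.T
    beta = (config.trend_means + x @ config.gamma_beta.T
            + rng.standard_normal((n, p)) * np.sqrt(config.sigma_beta2))

    seps = stationary_moments(config)
    l0 = np.linalg.cholesky(seps if config.stationary_init else config.sigma_u)
    lu = np.linalg.cholesky(config.sigma_u)
    eps = np.empty((n, len(months), p))
    eps[:, 0, :] = rng.standard_normal((n, p)) @ l0.T
    for t in range(1, len(months)):
        eps[:, t, :] = eps[:, t - 1, :] @ config.phi.T + rng.standard_normal((n, p)) @ lu.T
    y = alpha[:, None, :] + beta[:, None, :] * tau[None, :, None] + eps

    if config.clip_to_ranges:
        for j, v in enumerate(OUTCOMES):
            lo, hi = OUTCOME_RANGES[v]
            f = DEFAULT_RESCALE_FACTORS[v]
            y[:, :, j] = np.clip(y[:, :, j], lo / f, hi / f)

    # near-constant binary time-varying covariate
    dff_base = (rng.random(n) < config.dff_prob).astype(float)
    dff = np.repeat(dff_base[:, None], len(config.schedule), axis=1)
    toggle = rng.random(n) < config.dff_nonconstant_prop
    if toggle.any():
        occ = rng.integers(0, len(config.schedule), size=int(toggle.sum()))
        dff[np.where(toggle)[0], occ] = 1.0 - dff[np.where(toggle)[0], occ]

    pids = np.arange(1, n + 1)
    rec = pd.DataFrame({
        "person_id": np.repeat(pids, len(config.schedule)),
        "month": np.tile(list(config.schedule), n),
        "dudit_c": y[:, sched_idx, 0].ravel(),
        "swls": y[:, sched_idx, 1].ravel(),
        "scl90r_gsi": y[:, sched_idx, 2].ravel(),
        "drug_free_friends": dff.ravel(),
    })
    persons = pd.DataFrame({"person_id": pids, "age": age, "gender": gender})
    panel = PanelDataset(records=rec, persons=persons, schedule=config.schedule,
                         rescaled=True)
    if return_latents:
        return panel, {"alpha": alpha, "beta": beta, "eps": eps,
                       "lattice_months": months}
    return panel


def impose_missingness(data: PanelDataset, config: GeneratingConfig,
                       seed: int | None = None) -> PanelDataset:
    """Apply attrition and item missingness to a complete panel.

    (a) each person's number of attended occasions is drawn from the
    cluster-size law and the dropped occasions (all outcomes missing) are
    chosen uniformly; (b) within attended occasions, each outcome is set
    missing at its configured rate, with the life-satisfaction missingness
    odds multiplied by ``missing_dependence`` per SD of the *observed*
    substance-use score at the same occasion (missing at random by
    construction).  An attended occasion always keeps at least one observed
    outcome, so the cluster-size law of (a) holds exactly in the output.
    Records for dropped occasions are kept as all-missing rows, so pattern
    counts stay defined over persons x occasions.
    """
    rng = np.random.default_rng((config.seed + 1) if seed is None else seed)
    n_occ = len(data.schedule)
    rec = data.records.copy()
    n = data.n_persons

    sizes = np.array(sorted(config.cluster_size_probs))
    probs = np.array([config.cluster_size_probs[s] for s in sizes])
    attend_n = rng.choice(sizes, size=n, p=probs / probs.sum())

    # map rows to (person, occasion) grid; records are sorted by person, month
    wide_ok = len(rec) == n * n_occ
    if not wide_ok:
        raise ConfigError("impose_missingness expects a complete panel (one row per "
                          "person per scheduled occasion)")
    # uniform subset of dropped occasions per person, vectorized: rank a
    # random matrix row-wise and drop the lowest-ranked occasions
    ranks = np.argsort(rng.random((n, n_occ)), axis=1).argsort(axis=1)
    miss_occ = ranks < (n_occ - attend_n)[:, None]

    out_cols = list(OUTCOMES) + ["drug_free_friends"]
    vals = {c: rec[c].to_numpy().reshape(n, n_occ) for c in out_cols}
    for c in out_cols:
        vals[c][miss_occ] = np.nan

    attended = ~miss_occ
    # independent item missingness for substance use and distress
    hits = {}
    for v in ("dudit_c", "scl90r_gsi"):
        r = config.item_missing_rates.get(v, 0.0)
        hits[v] = attended & (rng.random((n, n_occ)) < r)
    # life-satisfaction missingness depends on the substance-use score where
    # that score stays observed (missing at random by construction)
    r_swls = config.item_missing_rates.get("swls", 0.0)
    d = vals["dudit_c"]
    d_observed = attended & ~hits["dudit_c"] & ~np.isnan(d)
    z = np.zeros((n, n_occ))
    if d_observed.sum() > 1 and np.std(d[d_observed]) > 0:
        z[d_observed] = (d[d_observed] - d[d_observed].mean()) / d[d_observed].std()
    if 0.0 < r_swls < 1.0:
        logit = np.log(r_swls / (1.0 - r_swls)) + np.log(config.missing_dependence) * z
        hits["swls"] = attended & (rng.random((n, n_occ)) < 1.0 / (1.0 + np.exp(-logit)))
    else:
        hits["swls"] = attended & (np.full((n, n_occ), r_swls) > rng.random((n, n_occ)))
    # an attended occasion keeps at least one observed outcome, so the
    # cluster-size law is preserved exactly; the spared outcome is the one
    # with the lowest configured missing rate
    all3 = attended & hits["dudit_c"] & hits["scl90r_gsi"] & hits["swls"]
    if all3.any():
        spare = min(OUTCOMES, key=lambda v: config.item_missing_rates.get(v, 0.0))
        hits[spare][all3] = False
    for v in OUTCOMES:
        vals[v][hits[v]] = np.nan

    for c in out_cols:
        rec[c] = vals[c].ravel()
    return replace(data, records=rec)


def simulate_cohort(config: GeneratingConfig, seed: int | None = None) -> PanelDataset:
    """Convenience: generate a complete panel and impose missingness."""
    base = config.seed if seed is None else seed
    return impose_missingness(generate_panel(config, seed=base), config, seed=base + 1)


def default_generating_config(n_persons: int = 164, seed: int = 0,
                              schedule: str = "stayer11") -> GeneratingConfig:
    """The default study-like cohort configuration.

    Dynamic parameters are calibrated so the model-implied standardized
    (STDYX) parameters equal the published posterior means for the cohort
    (see :mod:`rdsem.calibrate`); demographics, attrition and missingness
    follow the cohort's reported baseline and cluster-size tables.
    """
    from .calibrate import calibrate_to_stdyx  # late import: avoids a cycle

    cfg = calibrate_to_stdyx()
    return replace_config(cfg, n_persons=n_persons, seed=seed,
                          schedule=SCHEDULES[schedule])


def replace_config(cfg: GeneratingConfig, **kw) -> GeneratingConfig:
    d = cfg.to_dict()
    d.update({k: (list(v) if isinstance(v, tuple) else v) for k, v in kw.items()})
    return GeneratingConfig.from_dict(d)
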