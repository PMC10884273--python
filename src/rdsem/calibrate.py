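"""Calibrate the generating process to a standardized (STDYX) parameter table.

The published estimates for the emulated cohort are standardized; the
generator needs unstandardized parameters.  ``calibrate_to_stdyx`` solves the
inverse problem deterministically: given standardized lagged coefficients,
innovation correlations, standardized innovation variances, cluster-averaged
standardized trend effects and the between-level standardized table, it
fixed-point iterates on the unstandardized (Phi, Sigma_u, trend means/
variances) until the model-implied STDYX values (computed by the same map the
reporting module uses, with the cluster average replaced by a Gauss-Hermite
expectation over the slope distribution) reproduce every target.

Scale degrees of freedom (total variance and between-person share per
outcome) are not identified by a standardized table; they are design
constants chosen from the cohort's baseline SDs and intraclass correlations.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from .dynamics import stationary_cov
from .exceptions import CalibrationError, ConfigError
from .model import LABELS
from .panel import OUTCOMES, SCHEDULES
from .simulate import GeneratingConfig

_L = [LABELS[v] for v in OUTCOMES]          # ["DUDIT", "SWLS", "SCL90R"]
_PAIRS = [(0, 1), (0, 2), (1, 2)]
_FREE_PHI = [(0, 0), (0, 1), (0, 2), (1, 1), (2, 2)]

#: Published STDYX posterior means for the emulated five-year cohort
#: (substance use, life satisfaction, psychological distress).
DEFAULT_STDYX_TARGETS = {
    "trend_std[DUDIT]": -0.135, "trend_std[SWLS]": 0.191, "trend_std[SCL90R]": -0.036,
    "phi_std[DUDIT<-DUDIT]": 0.152, "phi_std[DUDIT<-SWLS]": 0.025,
    "phi_std[DUDIT<-SCL90R]": 0.103, "phi_std[SWLS<-SWLS]": 0.320,
    "phi_std[SCL90R<-SCL90R]": 0.131,
    "innov_corr[DUDIT,SWLS]": -0.233, "innov_corr[DUDIT,SCL90R]": -0.038,
    "innov_corr[SWLS,SCL90R]": 0.095,
    "resid_var_std[DUDIT]": 0.766, "resid_var_std[SWLS]": 0.738,
    "resid_var_std[SCL90R]": 0.702,
    "gamma_std[alpha.DUDIT<-gender]": -0.028, "gamma_std[alpha.DUDIT<-age]": -0.041,
    "gamma_std[alpha.SWLS<-gender]": 0.016, "gamma_std[alpha.SWLS<-age]": -0.104,
    "gamma_std[alpha.SCL90R<-gender]": 0.032, "gamma_std[alpha.SCL90R<-age]": -0.127,
    "gamma_std[beta.DUDIT<-gender]": -0.012, "gamma_std[beta.DUDIT<-age]": -0.026,
    "gamma_std[beta.SWLS<-gender]": 0.012, "gamma_std[beta.SWLS<-age]": 0.001,
    "gamma_std[beta.SCL90R<-gender]": 0.061, "gamma_std[beta.SCL90R<-age]": -0.001,
    "between_corr[DUDIT,SWLS]": -0.432, "between_corr[DUDIT,SCL90R]": 0.201,
    "between_corr[SWLS,SCL90R]": -0.590,
    "intercept_std[alpha.DUDIT]": 2.196, "intercept_std[alpha.SWLS]": 4.001,
    "intercept_std[alpha.SCL90R]": 1.985,
}

#: Total outcome variance on the rescaled metric and between-person share,
#: chosen from the cohort's baseline SDs (SWLS 6.2/10, GSI 0.7) and ICCs.
DEFAULT_TOTAL_VAR = np.array([0.25, 0.3844, 0.49])
DEFAULT_ICC = np.array([0.29, 0.45, 0.49])

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(64)


def _gh_expect(f, mu: float, var: float) -> float:
    """E[f(beta)] for beta ~ N(mu, var) by 64-node Gauss-Hermite quadrature."""
    if var <= 0:
        return float(f(np.array([mu]))[0])
    b = mu + np.sqrt(2.0 * var) * _GH_NODES
    return float(np.sum(_GH_WEIGHTS * f(b)) / np.sqrt(np.pi))


def _slope_w_moments(mu, var, veps_v, var_tau):
    """Expectations over the slope distribution of the within total variance
    W(beta) = beta^2 Var(tau) + Veps_v: (E[W^-1/2], E[W^-1], E[beta*sqrt(Var tau)/sqrt(W)])."""
    w = lambda b: b * b * var_tau + veps_v
    e_isqrt = _gh_expect(lambda b: 1.0 / np.sqrt(w(b)), mu, var)
    e_inv = _gh_expect(lambda b: 1.0 / w(b), mu, var)
    e_trend = _gh_expect(lambda b: b * np.sqrt(var_tau) / np.sqrt(w(b)), mu, var)
    return e_isqrt, e_inv, e_trend


def _solve_slope_dist(t_target: float, m2: float, veps_v: float, var_tau: float):
    """Given E[beta^2] = m2 and the standardized-trend target, split m2 into
    (mean, variance) of the slope distribution.  Parameterized by
    mu = r sqrt(m2); the cluster-averaged standardized trend is increasing
    in r, so a bracketed root solve is exact and deterministic."""
    if m2 <= 1e-14:
        if abs(t_target) > 1e-9:
            raise CalibrationError(
                f"standardized trend {t_target} requires a trend variance share, "
                "but the scale constants leave none")
        return 0.0, 0.0

    def avg_trend(r):
        mu = r * np.sqrt(m2)
        var = (1.0 - r * r) * m2
        return _slope_w_moments(mu, var, veps_v, var_tau)[2] - t_target

    lo, hi = avg_trend(-0.999999), avg_trend(0.999999)
    if lo > 0 or hi < 0:
        raise CalibrationError(
            f"standardized trend target {t_target} unreachable with trend "
            f"variance share E[b^2]Var(tau) = {m2 * var_tau:.4f}")
    r = optimize.brentq(avg_trend, -0.999999, 0.999999, xtol=1e-13)
    return r * np.sqrt(m2), (1.0 - r * r) * m2


def calibrate_to_stdyx(targets: dict | None = None,
                       total_var=DEFAULT_TOTAL_VAR, icc=DEFAULT_ICC,
                       male_prop: float = 0.622, schedule=SCHEDULES["stayer11"],
                       lattice_step: int = 3, max_iter: int = 1000,
                       tol: float = 1e-12, check_tol: float = 5e-3) -> GeneratingConfig:
    """Solve for unstandardized generating parameters matching STDYX targets.

    Raises :class:`CalibrationError` when the targets are unattainable (e.g.
    a standardized lagged coefficient implying a non-stationary process).
    The returned config reproduces every target through
    :func:`implied_stdyx` within ``check_tol`` (typically to near machine
    precision).
    """
    tg = dict(DEFAULT_STDYX_TARGETS)
    if targets is not None:
        tg.update(targets)
    total_var = np.asarray(total_var, dtype=float)
    icc = np.asarray(icc, dtype=float)
    w_tot = (1.0 - icc) * total_var         # within total variance per outcome
    b_tot = icc * total_var                 # between intercept total variance

    months = np.arange(min(schedule), max(schedule) + 1, lattice_step)
    tau = months / 12.0
    var_tau = float(np.var(tau))

    s_v = np.array([tg[f"resid_var_std[{l}]"] for l in _L])
    t_v = np.array([tg[f"trend_std[{l}]"] for l in _L])
    if np.any(s_v <= 0) or np.any(s_v > 1):
        raise CalibrationError("standardized innovation variances must lie in (0, 1]")

    # state: slope mean/var, stationary residual variances
    veps = s_v * w_tot
    mu_b = np.zeros(3)
    vb = np.maximum((w_tot - veps) / var_tau, 0.0)
    phi = np.zeros((3, 3))
    su = np.diag(veps)

    for it in range(max_iter):
        old = np.concatenate([phi.ravel(), su.ravel(), mu_b, vb])
        mom = [_slope_w_moments(mu_b[v], vb[v], veps[v], var_tau) for v in range(3)]
        e_isqrt = np.array([m[0] for m in mom])
        e_inv = np.array([m[1] for m in mom])

        phi = np.zeros((3, 3))
        for (v, w) in _FREE_PHI:
            key = f"phi_std[{_L[v]}<-{_L[w]}]"
            phi[v, w] = tg[key] / (np.sqrt(veps[w]) * e_isqrt[v])
        su_d = s_v / e_inv
        su = np.diag(su_d)
        for (v, w) in _PAIRS:
            su[v, w] = su[w, v] = (tg[f"innov_corr[{_L[v]},{_L[w]}]"]
                                   * np.sqrt(su_d[v] * su_d[w]))
        if np.any(np.linalg.eigvalsh(su) <= 0):
            raise CalibrationError("innovation correlation targets are not positive definite")
        try:
            veps_full = stationary_cov(phi, su)
        except ConfigError as e:
            raise CalibrationError(f"targets imply a non-stationary process: {e}") from e
        veps = np.diag(veps_full)

        m2 = (w_tot - veps) / var_tau
        if np.any(m2 < -1e-10):
            raise CalibrationError(
                "stationary residual variance exceeds the within total variance; "
                "targets inconsistent with the chosen scale constants")
        m2 = np.maximum(m2, 0.0)
        for v in range(3):
            mu_b[v], vb[v] = _solve_slope_dist(t_v[v], m2[v], veps[v], var_tau)

        new = np.concatenate([phi.ravel(), su.ravel(), mu_b, vb])
        if np.max(np.abs(new - old)) < tol:
            break
    else:
        raise CalibrationError("calibration fixed point did not converge")

    # between level: direct inversion
    var_x = np.array([male_prop * (1.0 - male_prop), 1.0])
    sd_x = np.sqrt(var_x)
    gamma_alpha = np.zeros((3, 2))
    gamma_beta = np.zeros((3, 2))
    for v, l in enumerate(_L):
        for j, pred in enumerate(("gender", "age")):
            gamma_alpha[v, j] = tg[f"gamma_std[alpha.{l}<-{pred}]"] * np.sqrt(b_tot[v]) / sd_x[j]
            gamma_beta[v, j] = (tg[f"gamma_std[beta.{l}<-{pred}]"]
                                * np.sqrt(vb[v]) / sd_x[j] if vb[v] > 0 else 0.0)
    expl_a = (gamma_alpha ** 2 @ var_x)
    sig_a_d = b_tot - expl_a
    if np.any(sig_a_d <= 0):
        raise CalibrationError("between regressions explain more than the total between variance")
    sigma_alpha = np.diag(sig_a_d)
    for (v, w) in _PAIRS:
        sigma_alpha[v, w] = sigma_alpha[w, v] = (tg[f"between_corr[{_L[v]},{_L[w]}]"]
                                                 * np.sqrt(sig_a_d[v] * sig_a_d[w]))
    if np.any(np.linalg.eigvalsh(sigma_alpha) <= 0):
        raise CalibrationError("between correlation targets are not positive definite")
    expl_b = gamma_beta ** 2 @ var_x
    sigma_beta2 = np.maximum(vb - expl_b, 1e-12)

    nu_alpha = np.array([tg[f"intercept_std[alpha.{l}]"] for l in _L]) * np.sqrt(b_tot)
    xbar = np.array([male_prop, 0.0])
    nu_beta = mu_b - gamma_beta @ xbar

    cfg = GeneratingConfig(
        schedule=tuple(schedule), lattice_step=lattice_step,
        phi=phi, sigma_u=su, grand_intercepts=nu_alpha, trend_means=nu_beta,
        gamma_alpha=gamma_alpha, gamma_beta=gamma_beta,
        sigma_alpha=sigma_alpha, sigma_beta2=sigma_beta2, male_prop=male_prop,
    )
    implied = implied_stdyx(cfg)
    err = {k: abs(implied[k] - tg[k]) for k in tg if k in implied}
    worst = max(err, key=err.get)
    if err[worst] > check_tol:
        raise CalibrationError(f"calibration check failed: {worst} off by {err[worst]:.4g}")
    return cfg


def implied_stdyx(config: GeneratingConfig) -> dict:
    """Model-implied STDYX parameters of a generating configuration.

    The population counterpart of the reporting module's standardization:
    cluster averages are replaced by expectations over the (normal
    approximation of the) slope distribution.  Also reports the implied
    within/between R-squared per outcome.
    """
    months = config.lattice_months()
    tau = months / 12.0
    var_tau = float(np.var(tau))
    veps_full = stationary_cov(config.phi, config.sigma_u)
    veps = np.diag(veps_full)
    var_x = np.array([config.male_prop * (1.0 - config.male_prop), 1.0])
    sd_x = np.sqrt(var_x)
    xbar = np.array([config.male_prop, 0.0])

    mu_b = config.trend_means + config.gamma_beta @ xbar
    vb_tot = config.gamma_beta ** 2 @ var_x + config.sigma_beta2
    mom = [_slope_w_moments(mu_b[v], vb_tot[v], veps[v], var_tau) for v in range(3)]

    out = {}
    su = config.sigma_u
    for v, l in enumerate(_L):
        e_isqrt, e_inv, e_trend = mom[v]
        out[f"trend_std[{l}]"] = e_trend
        out[f"resid_var_std[{l}]"] = su[v, v] * e_inv
        out[f"r2_within[{l}]"] = 1.0 - su[v, v] * e_inv
    for (v, w) in _FREE_PHI:
        out[f"phi_std[{_L[v]}<-{_L[w]}]"] = (config.phi[v, w] * np.sqrt(veps[w])
                                             * mom[v][0])
    for (v, w) in _PAIRS:
        out[f"innov_corr[{_L[v]},{_L[w]}]"] = su[v, w] / np.sqrt(su[v, v] * su[w, w])

    b_tot = config.gamma_alpha ** 2 @ var_x + np.diag(config.sigma_alpha)
    for v, l in enumerate(_L):
        out[f"intercept_std[alpha.{l}]"] = config.grand_intercepts[v] / np.sqrt(b_tot[v])
        out[f"between_resid_var_std[alpha.{l}]"] = config.sigma_alpha[v, v] / b_tot[v]
        out[f"r2_between[alpha.{l}]"] = 1.0 - config.sigma_alpha[v, v] / b_tot[v]
        out[f"r2_between[beta.{l}]"] = (config.gamma_beta[v] ** 2 @ var_x) / vb_tot[v] \
            if vb_tot[v] > 0 else 0.0
        for j, pred in enumerate(("gender", "age")):
            out[f"gamma_std[alpha.{l}<-{pred}]"] = (config.gamma_alpha[v, j] * sd_x[j]
                                                    / np.sqrt(b_tot[v]))
            out[f"gamma_std[beta.{l}<-{pred}]"] = (config.gamma_beta[v, j] * sd_x[j]
                                                   / np.sqrt(vb_tot[v])) if vb_tot[v] > 0 else 0.0
    for (v, w) in _PAIRS:
        out[f"between_corr[{_L[v]},{_L[w]}]"] = (config.sigma_alpha[v, w]
                                                 / np.sqrt(config.sigma_alpha[v, v]
                                                           * config.sigma_alpha[w, w]))
    return out
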