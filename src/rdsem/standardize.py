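"""STDYX standardization and variance-explained (R^2) summaries.

Within-level coefficients are standardized per cluster with the
model-implied within-cluster SDs and then averaged over clusters: the
within-cluster total variance of outcome v in cluster i is

    W_vi = beta_vi^2 Var(tau) + Sigma_eps[v, v]

(trend contribution plus stationary residual variance), lagged-path
predictors carry the stationary residual SD, innovation and between-level
covariances are reported as residual correlations, and between-level
variables are standardized by their model-implied total between SDs.  The
within-level R^2 is one minus the standardized innovation variance — an
identity that holds per draw exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import stationary_cov_batched
from .exceptions import StandardizationError
from .gibbs import PosteriorDraws
from .model import LABELS, ModelSpec
from .panel import OUTCOMES, PanelDataset

_L = [LABELS[v] for v in OUTCOMES]
_PAIRS = [(0, 1), (0, 2), (1, 2)]


@dataclass
class StandardizedResults:
    """STDYX table and R^2 block with per-draw arrays retained.

    ``table`` rows: (parameter, estimate, sd, lo95, up95, credible) — the
    credible flag is True exactly when the equal-tailed 95% interval excludes
    zero.  ``per_draw`` maps each label to a (chains, draws) array so
    identities and diagnostics can be checked on the draw level.
    """

    table: pd.DataFrame
    r2: pd.DataFrame
    per_draw: dict
    chains: int

    def estimate(self, label: str) -> float:
        if label not in self.per_draw:
            raise KeyError(f"unknown standardized parameter {label!r}")
        return float(self.per_draw[label].mean())


def _collect_params(draws: PosteriorDraws):
    spec = draws.spec
    shape = next(iter(draws.params.values())).shape   # (chains, kept)
    n = shape[0] * shape[1]
    g = lambda name: draws.array(name).reshape(n)
    phi = np.zeros((n, 3, 3))
    for v, w in spec.free_lag_entries():
        phi[:, v, w] = g(f"phi[{_L[v]}<-{_L[w]}]")
    su = np.zeros((n, 3, 3))
    sa = np.zeros((n, 3, 3))
    for v in range(3):
        for w in range(v, 3):
            su[:, v, w] = su[:, w, v] = g(f"sigma_u[{_L[v]},{_L[w]}]")
            sa[:, v, w] = sa[:, w, v] = g(f"sigma_alpha[{_L[v]},{_L[w]}]")
    nu_a = np.stack([g(f"nu_alpha[{l}]") for l in _L], axis=1)
    nu_b = np.stack([g(f"nu_beta[{l}]") for l in _L], axis=1)
    ga = np.stack([np.stack([g(f"gamma_alpha[{l}<-gender]"),
                             g(f"gamma_alpha[{l}<-age]")], axis=1) for l in _L], axis=1)
    gb = np.stack([np.stack([g(f"gamma_beta[{l}<-gender]"),
                             g(f"gamma_beta[{l}<-age]")], axis=1) for l in _L], axis=1)
    sb2 = np.stack([g(f"sigma_beta2[{l}]") for l in _L], axis=1)
    return phi, su, sa, nu_a, nu_b, ga, gb, sb2, shape


def stdyx_standardize(draws: PosteriorDraws, data: PanelDataset | None = None,
                      spec: ModelSpec | None = None,
                      cluster_average: bool = True) -> StandardizedResults:
    """Standardize a fit's draws; summarize as mean/SD/95% CrI with
    credibility flags.

    ``cluster_average=True`` (default) averages cluster-wise standardized
    within-level coefficients over clusters; the alternative pools the
    within-cluster variances first.  ``data``/``spec`` default to what the
    fit stored.
    """
    spec = spec or draws.spec
    phi, su, sa, nu_a, nu_b, ga, gb, sb2, (n_chains, kept) = _collect_params(draws)
    n = phi.shape[0]
    beta = draws.beta.reshape(n, -1, 3)
    tau = draws.tau
    var_tau = float(np.var(tau))
    x = draws.x
    cov_x = np.atleast_2d(np.cov(x.T, ddof=0))
    sd_x = np.sqrt(np.diag(cov_x))

    seps = stationary_cov_batched(phi, su)
    if np.isnan(seps).any():
        raise StandardizationError("non-stationary draws encountered")
    seps_d = np.einsum("nvv->nv", seps)
    su_d = np.einsum("nvv->nv", su)
    sa_d = np.einsum("nvv->nv", sa)

    w = beta ** 2 * var_tau + seps_d[:, None, :]            # (n, N, 3)
    if np.any(w <= 0):
        raise StandardizationError("zero implied within-cluster variance")
    if cluster_average:
        inv_sqrt_w = (1.0 / np.sqrt(w)).mean(axis=1)
        inv_w = (1.0 / w).mean(axis=1)
        trend_std = (beta * np.sqrt(var_tau) / np.sqrt(w)).mean(axis=1)
    else:
        w_bar = w.mean(axis=1)
        inv_sqrt_w = 1.0 / np.sqrt(w_bar)
        inv_w = 1.0 / w_bar
        trend_std = beta.mean(axis=1) * np.sqrt(var_tau) * inv_sqrt_w

    per = {}
    for v, l in enumerate(_L):
        per[f"trend_std[{l}]"] = trend_std[:, v]
    for v, wv in spec.free_lag_entries():
        per[f"phi_std[{_L[v]}<-{_L[wv]}]"] = (phi[:, v, wv] * np.sqrt(seps_d[:, wv])
                                              * inv_sqrt_w[:, v])
    for v, wv in _PAIRS:
        per[f"innov_corr[{_L[v]},{_L[wv]}]"] = su[:, v, wv] / np.sqrt(su_d[:, v] * su_d[:, wv])
    for v, l in enumerate(_L):
        per[f"resid_var_std[{l}]"] = su_d[:, v] * inv_w[:, v]

    expl_a = np.einsum("nvj,jk,nvk->nv", ga, cov_x, ga)
    b_tot_a = expl_a + sa_d
    expl_b = np.einsum("nvj,jk,nvk->nv", gb, cov_x, gb)
    b_tot_b = expl_b + sb2
    for v, l in enumerate(_L):
        for j, pred in enumerate(("gender", "age")):
            per[f"gamma_std[alpha.{l}<-{pred}]"] = ga[:, v, j] * sd_x[j] / np.sqrt(b_tot_a[:, v])
            per[f"gamma_std[beta.{l}<-{pred}]"] = gb[:, v, j] * sd_x[j] / np.sqrt(b_tot_b[:, v])
    for v, wv in _PAIRS:
        per[f"between_corr[{_L[v]},{_L[wv]}]"] = sa[:, v, wv] / np.sqrt(sa_d[:, v] * sa_d[:, wv])
    for v, l in enumerate(_L):
        per[f"intercept_std[alpha.{l}]"] = nu_a[:, v] / np.sqrt(b_tot_a[:, v])
        per[f"intercept_std[beta.{l}]"] = nu_b[:, v] / np.sqrt(b_tot_b[:, v])
        per[f"between_resid_var_std[alpha.{l}]"] = sa_d[:, v] / b_tot_a[:, v]
        per[f"between_resid_var_std[beta.{l}]"] = sb2[:, v] / b_tot_b[:, v]

    r2_draw = {}
    for v, l in enumerate(_L):
        r2_draw[("within", l)] = 1.0 - per[f"resid_var_std[{l}]"]
        r2_draw[("between_intercept", l)] = expl_a[:, v] / b_tot_a[:, v]
        r2_draw[("between_trend", l)] = expl_b[:, v] / b_tot_b[:, v]
    for v, l in enumerate(_L):
        per[f"r2_within[{l}]"] = r2_draw[("within", l)]
        per[f"r2_between[alpha.{l}]"] = r2_draw[("between_intercept", l)]
        per[f"r2_between[beta.{l}]"] = r2_draw[("between_trend", l)]

    rows = []
    for label, arr in per.items():
        if label.startswith("r2_"):
            continue
        lo, hi = np.percentile(arr, [2.5, 97.5])
        rows.append({"parameter": label, "estimate": arr.mean(), "sd": arr.std(ddof=1),
                     "lo95": lo, "up95": hi, "credible": bool(lo > 0 or hi < 0)})
    table = pd.DataFrame(rows).set_index("parameter")

    r2_rows = []
    for (level, l), arr in r2_draw.items():
        lo, hi = np.percentile(arr, [2.5, 97.5])
        r2_rows.append({"outcome": l, "level": level, "estimate": arr.mean(),
                        "sd": arr.std(ddof=1), "lo95": lo, "up95": hi})
    r2 = pd.DataFrame(r2_rows)

    per = {k: v.reshape(n_chains, kept) for k, v in per.items()}
    return StandardizedResults(table=table, r2=r2, per_draw=per, chains=n_chains)


def r_squared(draws: PosteriorDraws, data: PanelDataset | None = None,
              spec: ModelSpec | None = None) -> pd.DataFrame:
    """Per-outcome variance explained: within level (one minus the
    standardized innovation variance) and between level (share of intercept
    and trend-slope variance explained by gender and age), with 95% CrIs."""
    return stdyx_standardize(draws, data, spec).r2
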