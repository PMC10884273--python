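"""Blocked Gibbs sampler with data augmentation for the two-level rDSEM.

Sampling scheme (one iteration):

1. missing and phantom outcome cells from their Gaussian full conditionals
   given the neighbouring occasions and the observed components of the same
   occasion — a red/black sweep over time slices (even slices are mutually
   conditionally independent given the odd ones under the lag-1 Markov
   structure, and vice versa), with cells batched by missingness pattern;
2. latent person intercepts and trend slopes jointly (conjugate normal; the
   within likelihood is quasi-differenced with a stationary first-occasion
   term, so the 6x6 posterior precision is common to all persons);
3. free lagged coefficients jointly (conjugate normal from the transition
   terms used as an independence proposal, Metropolis-corrected for the
   stationary initial density; non-stationary proposals are rejected, and the
   admissible-range regime truncates each coefficient to (-1, 1));
4. innovation covariance (inverse-Wishart proposal from the transitions,
   Metropolis-corrected for the initial density);
5. between-level regressions, intercept covariance and slope variances
   (conjugate normal / inverse-Wishart / inverse-gamma).

Chains run sequentially and are reproducible given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .dynamics import spectral_radius, stationary_cov
from .exceptions import EstimationError
from .model import LABELS, ModelSpec, PriorSpec, _mvn_logpdf, default_priors
from .panel import OUTCOMES, PanelDataset

logger = logging.getLogger("rdsem")

_L = [LABELS[v] for v in OUTCOMES]


def param_names(spec: ModelSpec) -> list[str]:
    """Canonical scalar parameter names, in stable order."""
    names = [f"phi[{_L[v]}<-{_L[w]}]" for v, w in spec.free_lag_entries()]
    names += [f"sigma_u[{_L[v]},{_L[w]}]" for v in range(3) for w in range(v, 3)]
    names += [f"nu_alpha[{l}]" for l in _L] + [f"nu_beta[{l}]" for l in _L]
    names += [f"gamma_alpha[{l}<-{p}]" for l in _L for p in ("gender", "age")]
    names += [f"gamma_beta[{l}<-{p}]" for l in _L for p in ("gender", "age")]
    names += [f"sigma_alpha[{_L[v]},{_L[w]}]" for v in range(3) for w in range(v, 3)]
    names += [f"sigma_beta2[{l}]" for l in _L]
    return names


@dataclass
class PosteriorDraws:
    """Posterior draws indexed by (chain, iteration, parameter name).

    Warmup draws are discarded before storage.  Latent person intercepts and
    slopes are kept per draw (the cluster-wise standardization averages over
    them).  ``converged`` flags whether every parameter's split-chain Rhat
    stayed below the sampler's threshold — a failed flag is a result, not an
    exception.
    """

    params: dict
    alpha: np.ndarray          # (chains, kept, N, 3)
    beta: np.ndarray           # (chains, kept, N, 3)
    warmup: int
    iterations: int
    chains: int
    seed: int
    spec: ModelSpec
    prior_regime: str
    person_ids: list
    x: np.ndarray              # (N, 2) between design (gender, age standardized)
    tau: np.ndarray            # (T,) lattice times in years
    accept: dict = field(default_factory=dict)
    converged: bool | None = None
    max_rhat: float | None = None

    def names(self) -> list[str]:
        return list(self.params)

    def array(self, name: str) -> np.ndarray:
        if name not in self.params:
            raise KeyError(f"unknown parameter {name!r}")
        return self.params[name]

    def mean(self, name: str) -> float:
        return float(self.array(name).mean())

    @property
    def n_kept(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        return self.array(name).reshape(-1)

    def to_inference_data(self):
        import arviz as az
        return az.from_dict(posterior={k: v for k, v in self.params.items()})


# ----------------------------------------------------------------------
# data preparation
# ----------------------------------------------------------------------

def _prepare_arrays(data: PanelDataset):
    if data.n_records == 0:
        raise EstimationError("empty data")
    if not data.rescaled:
        raise EstimationError("fit requires rescaled outcomes (rescale_outcomes)")
    if data.lattice_step is None:
        raise EstimationError("fit requires lattice-expanded data (expand_time_lattice)")
    months = np.array(sorted(data.schedule))
    T = len(months)
    if T < 2:
        raise EstimationError("need at least two occasions")
    per = data.persons
    N = len(per)
    rec = data.records
    if len(rec) != N * T:
        raise EstimationError("records do not form a complete person x lattice grid")
    Y = rec[list(OUTCOMES)].to_numpy().reshape(N, T, 3)
    obs = ~np.isnan(Y)
    if not obs.any(axis=(0, 1)).all():
        dead = [OUTCOMES[j] for j in range(3) if not obs[:, :, j].any()]
        raise EstimationError(f"outcomes entirely missing: {dead}")
    tau = months / 12.0
    age = per["age"].to_numpy(dtype=float)
    sd = age.std()
    x = np.column_stack([per["gender"].to_numpy(dtype=float),
                         (age - age.mean()) / (sd if sd > 0 else 1.0)])
    return Y, obs, tau, x, per["person_id"].tolist()


def _time_class(t: int, T: int) -> int:
    return 0 if t == 0 else (2 if t == T - 1 else 1)


def _build_impute_plan(obs: np.ndarray):
    """Group missing cells for the red/black sweep.

    Returns (plan, class_masks): ``plan[parity]`` is a list of
    (class, mask, person_idx, t_idx) batches, where class 0/1/2 marks
    first/interior/last occasions (they carry different conditional
    precisions) and mask is the missingness bitmask of the occasion.
    """
    N, T, p = obs.shape
    weights = 1 << np.arange(p)
    masks = ((~obs) * weights).sum(axis=2)          # (N, T)
    plan = [[], []]
    class_masks = [set(), set(), set()]
    for parity in (0, 1):
        for cls in (0, 1, 2):
            ts = np.array([t for t in range(T)
                           if t % 2 == parity and _time_class(t, T) == cls], dtype=int)
            if not len(ts):
                continue
            sub = masks[:, ts]
            for mask in np.unique(sub):
                if mask == 0:
                    continue
                pi, ti = np.nonzero(sub == mask)
                plan[parity].append((cls, int(mask), pi, ts[ti]))
                class_masks[cls].add(int(mask))
    return plan, class_masks


def _conditional_pieces(lam: np.ndarray, masks):
    """Schur pieces for sampling the missing components of a 3-vector with
    precision ``lam``, for each missingness bitmask in use."""
    sc = np.linalg.inv(lam)
    sc = 0.5 * (sc + sc.T)
    pieces = {}
    for mask in masks:
        M = np.array([j for j in range(3) if mask >> j & 1])
        O = np.array([j for j in range(3) if not mask >> j & 1], dtype=int)
        if len(O):
            k = sc[M][:, O] @ np.linalg.inv(sc[O][:, O])
            cc = sc[M][:, M] - k @ sc[M][:, O].T
        else:
            k = None
            cc = sc
        cc = 0.5 * (cc + cc.T)
        pieces[mask] = (M, O, k, np.linalg.cholesky(cc))
    return pieces, sc


# ----------------------------------------------------------------------
# sampler blocks
# ----------------------------------------------------------------------

def impute_missing_sweep(eps, plan, class_masks, phi, su_inv, seps_inv, rng):
    """One red/black Gibbs sweep over the missing residual cells, in place.

    ``eps`` is the (N, T, 3) detrended-residual array; cells listed in
    ``plan`` are redrawn from their full conditional under
    eps_t = Phi eps_{t-1} + u_t with stationary initial state.
    """
    cross = phi.T @ su_inv @ phi
    lams = [seps_inv + cross, su_inv + cross, su_inv]
    m1 = su_inv @ phi
    pieces, scs = [None] * 3, [None] * 3
    for c in range(3):
        if class_masks[c]:
            pieces[c], scs[c] = _conditional_pieces(lams[c], class_masks[c])
    for parity in (0, 1):
        entries = plan[parity]
        if not entries:
            continue
        h = np.zeros_like(eps)
        h[:, 1:] += eps[:, :-1] @ m1.T
        h[:, :-1] += eps[:, 1:] @ m1
        for cls, mask, pi, ti in entries:
            M, O, k, lcc = pieces[cls][mask]
            m = h[pi, ti] @ scs[cls]
            if len(O):
                cur = eps[pi, ti]
                mean = m[:, M] + (cur[:, O] - m[:, O]) @ k.T
            else:
                mean = m[:, M]
            draw = mean + rng.standard_normal((len(pi), len(M))) @ lcc.T
            eps[pi[:, None], ti[:, None], M[None, :]] = draw


def _draw_person_effects(Y, tau, phi, su_inv, seps_inv, q_prior, m_prior, rng):
    """Joint conjugate draw of (alpha_i, beta_i) for all persons, batched."""
    N, T, p = Y.shape
    eye = np.eye(p)
    G = np.zeros((T, p, 2 * p))
    G[0, :, :p] = eye
    G[0, :, p:] = tau[0] * eye
    G[1:, :, :p] = eye - phi
    G[1:, :, p:] = tau[1:, None, None] * eye - tau[:-1, None, None] * phi
    H = np.empty_like(G)
    H[0] = seps_inv @ G[0]
    H[1:] = np.einsum("ij,tjk->tik", su_inv, G[1:])
    P = np.einsum("tij,tik->jk", G, H) + q_prior
    r = np.empty_like(Y)
    r[:, 0, :] = Y[:, 0, :]
    r[:, 1:, :] = Y[:, 1:, :] - np.einsum("vw,ntw->ntv", phi, Y[:, :-1, :])
    b = np.einsum("nti,tij->nj", r, H) + m_prior @ q_prior
    cho = linalg.cho_factor(P, lower=True)
    mean = linalg.cho_solve(cho, b.T).T
    z = rng.standard_normal((N, 2 * p))
    noise = linalg.solve_triangular(cho[0].T, z.T, lower=False).T
    return mean + noise


def _mvn0_sum(x: np.ndarray, cov: np.ndarray) -> float:
    return float(np.sum(_mvn_logpdf(x, cov)))


def _draw_phi(eps, free, phi, su, su_inv, seps, priors: PriorSpec, rng):
    """Conjugate proposal for the free lagged coefficients + MH correction
    for the stationary initial density.  Returns (phi, seps, accepted)."""
    K = len(free)
    e0 = eps[:, :-1, :].reshape(-1, 3)
    e1 = eps[:, 1:, :].reshape(-1, 3)
    sxx = e0.T @ e0
    sxy = e0.T @ e1
    P = np.empty((K, K))
    b = np.empty(K)
    vs = [v for v, _ in free]
    ws = [w for _, w in free]
    for k in range(K):
        for l in range(K):
            P[k, l] = su_inv[vs[k], vs[l]] * sxx[ws[k], ws[l]]
        b[k] = sxy[ws[k]] @ su_inv[:, vs[k]]
    P += np.eye(K) / priors.ar_sd ** 2
    cho = linalg.cho_factor(P, lower=True)
    mean = linalg.cho_solve(cho, b)
    for _ in range(100):
        th = mean + linalg.solve_triangular(cho[0].T,
                                            rng.standard_normal(K), lower=False)
        if priors.ar_truncated and np.any(np.abs(th) >= 1.0):
            continue
        break
    else:
        return phi, seps, False
    phi_prop = np.zeros_like(phi)
    for k, (v, w) in enumerate(free):
        phi_prop[v, w] = th[k]
    if spectral_radius(phi_prop) >= 1.0 - 1e-10:
        return phi, seps, False
    seps_prop = stationary_cov(phi_prop, su)
    e_first = eps[:, 0, :]
    log_r = _mvn0_sum(e_first, seps_prop) - _mvn0_sum(e_first, seps)
    if np.log(rng.random()) < log_r:
        return phi_prop, seps_prop, True
    return phi, seps, False


def _invwishart_rvs(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Inverse-Wishart draw via the Bartlett decomposition."""
    p = scale.shape[0]
    chol_inv = np.linalg.cholesky(np.linalg.inv(scale))
    a = np.zeros((p, p))
    a[np.diag_indices(p)] = np.sqrt(rng.chisquare(df - np.arange(p)))
    a[np.tril_indices(p, -1)] = rng.standard_normal(p * (p - 1) // 2)
    l = chol_inv @ a                      # W = L L' ~ Wishart(df, scale^-1)
    w_inv = np.linalg.inv(l @ l.T)
    return 0.5 * (w_inv + w_inv.T)


def _draw_sigma_u(eps, phi, su, seps, priors: PriorSpec, rng):
    """Inverse-Wishart proposal from the transitions + MH initial correction."""
    p = eps.shape[2]
    e0 = eps[:, :-1, :].reshape(-1, p)
    resid = eps[:, 1:, :].reshape(-1, p) - e0 @ phi.T
    scatter = resid.T @ resid
    df = p + priors.iw_df_add + resid.shape[0]
    scale = priors.iw_scale * np.eye(p) + scatter
    su_prop = _invwishart_rvs(df, scale, rng)
    seps_prop = stationary_cov(phi, su_prop)
    e_first = eps[:, 0, :]
    log_r = _mvn0_sum(e_first, seps_prop) - _mvn0_sum(e_first, seps)
    if np.log(rng.random()) < log_r:
        return su_prop, seps_prop, True
    return su, seps, False


def _draw_mvreg_coefs(Yv, D, cov_inv, prior_prec, rng):
    """Coefficients C (q_out x q_des) of Y = D C' + E, E ~ N(0, cov), with
    independent N(0, 1/prior_prec) priors; returns a draw of C."""
    q_out, q_des = cov_inv.shape[0], D.shape[1]
    dtd = D.T @ D
    P = np.kron(cov_inv, dtd) + prior_prec * np.eye(q_out * q_des)
    b = (cov_inv @ Yv.T @ D).ravel()
    cho = linalg.cho_factor(P, lower=True)
    mean = linalg.cho_solve(cho, b)
    draw = mean + linalg.solve_triangular(cho[0].T,
                                          rng.standard_normal(len(b)), lower=False)
    return draw.reshape(q_out, q_des)


# ----------------------------------------------------------------------
# main entry
# ----------------------------------------------------------------------

def fit_mcmc(data: PanelDataset, spec: ModelSpec | None = None,
             priors: PriorSpec | None = None, chains: int = 2,
             iterations: int = 2000, seed: int = 0,
             warmup: int | None = None, rhat_threshold: float = 1.05,
             inner_scans: int = 8, progress: bool = False) -> PosteriorDraws:
    """Posterior sampling for the two-level rDSEM.

    ``data`` must be rescaled and lattice-expanded.  ``iterations`` is the
    total per chain; the first ``warmup`` (default: half) are discarded.
    Reproducible given ``seed``.  Convergence (split-chain Rhat below
    ``rhat_threshold`` for every parameter) is checked when at least two
    chains are run and reported on the result, with a warning — never a
    silent success — when it fails.
    """
    spec = spec or ModelSpec()
    priors = priors or default_priors()
    if chains < 1:
        raise EstimationError("need at least one chain")
    warmup = iterations // 2 if warmup is None else warmup
    if not 0 <= warmup < iterations:
        raise EstimationError("warmup must be in [0, iterations)")

    Y0, obs, tau, x, person_ids = _prepare_arrays(data)
    plan, class_masks = _build_impute_plan(obs)
    free = spec.free_lag_entries()
    names = param_names(spec)
    kept = iterations - warmup
    N, T, p = Y0.shape

    params_out = {k: np.empty((chains, kept)) for k in names}
    alpha_out = np.empty((chains, kept, N, p))
    beta_out = np.empty((chains, kept, N, p))
    accept = {"phi": 0.0, "sigma_u": 0.0}

    for c in range(chains):
        rng = np.random.default_rng([seed, c])
        state = _run_chain(Y0, obs, tau, x, plan, class_masks, free, spec,
                           priors, iterations, warmup, rng, inner_scans,
                           progress, chain_id=c)
        for k in names:
            params_out[k][c] = state["params"][k]
        alpha_out[c] = state["alpha"]
        beta_out[c] = state["beta"]
        accept["phi"] += state["accept_phi"] / chains
        accept["sigma_u"] += state["accept_su"] / chains

    draws = PosteriorDraws(
        params=params_out, alpha=alpha_out, beta=beta_out, warmup=warmup,
        iterations=iterations, chains=chains, seed=seed, spec=spec,
        prior_regime=priors.regime, person_ids=person_ids, x=x, tau=tau,
        accept=accept,
    )
    if chains >= 2 and kept >= 4:
        from .diagnostics import rhat
        rhats = [rhat(draws, k) for k in names]
        draws.max_rhat = float(np.nanmax(rhats))
        draws.converged = bool(draws.max_rhat < rhat_threshold)
        if not draws.converged:
            logger.warning("convergence flag failed: max Rhat %.3f >= %.2f",
                           draws.max_rhat, rhat_threshold)
    return draws


def _run_chain(Y0, obs, tau, x, plan, class_masks, free, spec, priors,
               iterations, warmup, rng, inner_scans, progress, chain_id):
    N, T, p = Y0.shape
    D = np.column_stack([np.ones(N), x])          # between design (1, gender, age)
    kept = iterations - warmup

    # ---- initialization (overdispersed across chains via rng) ----
    Y = Y0.copy()
    col_mean = np.nanmean(Y0.reshape(-1, p), axis=0)
    col_sd = np.nanstd(Y0.reshape(-1, p), axis=0)
    for j in range(p):
        yj = Y[:, :, j]
        pm = np.where(obs[:, :, j], yj, np.nan)
        n_obs_j = obs[:, :, j].sum(axis=1)
        person_mean = np.where(n_obs_j > 0,
                               np.nansum(pm, axis=1) / np.maximum(n_obs_j, 1),
                               col_mean[j])
        person_mean = np.where(np.isnan(person_mean), col_mean[j], person_mean)
        fill = person_mean[:, None] + 0.3 * col_sd[j] * rng.standard_normal((N, T))
        yj[~obs[:, :, j]] = fill[~obs[:, :, j]]

    X_ols = np.column_stack([np.ones(T), tau])
    pinv = np.linalg.pinv(X_ols)
    coefs = np.einsum("kt,ntj->nkj", pinv, Y)
    A = coefs[:, 0, :] + 0.1 * col_sd * rng.standard_normal((N, p))
    B = coefs[:, 1, :] + 0.05 * col_sd * rng.standard_normal((N, p))
    eps = Y - A[:, None, :] - B[:, None, :] * tau[None, :, None]

    phi = np.zeros((p, p))
    su = np.cov(eps.reshape(-1, p).T) + 1e-6 * np.eye(p)
    seps = su.copy()
    dpinv = np.linalg.pinv(D)
    Ca = (dpinv @ A).T
    Cb = (dpinv @ B).T
    ra = A - D @ Ca.T
    sa = np.cov(ra.T) + 1e-6 * np.eye(p)
    sb2 = (B - D @ Cb.T).var(axis=0) + 1e-6

    names = param_names(spec)
    out = {k: np.empty(kept) for k in names}
    alpha_store = np.empty((kept, N, p))
    beta_store = np.empty((kept, N, p))
    acc_phi = acc_su = 0
    any_missing = bool(plan[0] or plan[1])
    tau_b = tau[None, :, None]

    loc_prec = 1.0 / priors.location_sd ** 2
    iw_df0 = p + priors.iw_df_add
    iw_s0 = priors.iw_scale * np.eye(p)

    su_inv = np.linalg.inv(su)
    seps_inv = np.linalg.inv(seps)

    for it in range(iterations):
        # blocks 1-4 are scanned several times per iteration: the heavy data
        # augmentation couples the latent residual paths to the dynamic
        # parameters, and repeated scans decorrelate successive stored draws
        for _ in range(inner_scans):
            # 1. impute missing / phantom cells
            if any_missing:
                impute_missing_sweep(eps, plan, class_masks, phi, su_inv, seps_inv, rng)
                Y = np.where(obs, Y0, eps + A[:, None, :] + B[:, None, :] * tau_b)

            # 2. person effects
            q_prior = linalg.block_diag(np.linalg.inv(sa), np.diag(1.0 / sb2))
            m_prior = np.hstack([D @ Ca.T, D @ Cb.T])
            AB = _draw_person_effects(Y, tau, phi, su_inv, seps_inv, q_prior,
                                      m_prior, rng)
            A, B = AB[:, :p], AB[:, p:]
            eps = Y - A[:, None, :] - B[:, None, :] * tau_b

            # 3. lagged coefficients
            if free:
                phi, seps, ok = _draw_phi(eps, free, phi, su, su_inv, seps,
                                          priors, rng)
                acc_phi += ok

            # 4. innovation covariance
            su, seps, ok = _draw_sigma_u(eps, phi, su, seps, priors, rng)
            acc_su += ok
            su_inv = np.linalg.inv(su)
            seps_inv = np.linalg.inv(seps)

        # 5. between level
        Ca = _draw_mvreg_coefs(A, D, np.linalg.inv(sa), loc_prec, rng)
        ra = A - D @ Ca.T
        sa = _invwishart_rvs(iw_df0 + N, iw_s0 + ra.T @ ra, rng)
        for v in range(p):
            Pv = D.T @ D / sb2[v] + loc_prec * np.eye(D.shape[1])
            bv = D.T @ B[:, v] / sb2[v]
            cho = linalg.cho_factor(Pv, lower=True)
            Cb[v] = (linalg.cho_solve(cho, bv)
                     + linalg.solve_triangular(cho[0].T,
                                               rng.standard_normal(D.shape[1]),
                                               lower=False))
            rss = float(np.sum((B[:, v] - D @ Cb[v]) ** 2))
            # inverse-gamma(a, b) via 1 / gamma(a, 1/b)
            sb2[v] = 1.0 / rng.gamma(priors.ig_shape + N / 2.0,
                                     1.0 / (priors.ig_scale + rss / 2.0))

        if progress and (it + 1) % 500 == 0:
            logger.info("chain %d: %d/%d iterations", chain_id, it + 1, iterations)

        if it >= warmup:
            k = it - warmup
            for j, (v, w) in enumerate(free):
                out[f"phi[{_L[v]}<-{_L[w]}]"][k] = phi[v, w]
            for v in range(p):
                for w in range(v, p):
                    out[f"sigma_u[{_L[v]},{_L[w]}]"][k] = su[v, w]
                    out[f"sigma_alpha[{_L[v]},{_L[w]}]"][k] = sa[v, w]
            for v, l in enumerate(_L):
                out[f"nu_alpha[{l}]"][k] = Ca[v, 0]
                out[f"nu_beta[{l}]"][k] = Cb[v, 0]
                out[f"gamma_alpha[{l}<-gender]"][k] = Ca[v, 1]
                out[f"gamma_alpha[{l}<-age]"][k] = Ca[v, 2]
                out[f"gamma_beta[{l}<-gender]"][k] = Cb[v, 1]
                out[f"gamma_beta[{l}<-age]"][k] = Cb[v, 2]
                out[f"sigma_beta2[{l}]"][k] = sb2[v]
            alpha_store[k] = A
            beta_store[k] = B

    n_up = iterations * inner_scans
    return {"params": out, "alpha": alpha_store, "beta": beta_store,
            "accept_phi": acc_phi / n_up, "accept_su": acc_su / n_up}
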