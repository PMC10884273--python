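"""MCMC convergence diagnostics and prior-sensitivity comparison."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EstimationError
from .gibbs import PosteriorDraws


def _chains_array(draws, parameter=None) -> np.ndarray:
    if isinstance(draws, PosteriorDraws):
        if parameter is None:
            raise EstimationError("parameter name required")
        return draws.array(parameter)
    arr = np.asarray(draws, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr


def ess(draws, parameter: str | None = None) -> float:
    """Multi-chain autocorrelation-based effective sample size (bulk).

    Accepts a :class:`PosteriorDraws` plus a parameter name, or a raw
    (chains, draws) array.  A constant chain has no defined ESS and is
    reported as NaN.
    """
    arr = _chains_array(draws, parameter)
    if arr.size < 100:
        raise EstimationError("need at least 100 stored draws for an ESS estimate")
    if np.ptp(arr) == 0:
        return float("nan")
    import arviz as az
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(arr, method="bulk"))


def rhat(draws, parameter: str | None = None) -> float:
    """Rank-normalized split-chain potential scale reduction factor."""
    arr = _chains_array(draws, parameter)
    if arr.shape[0] < 2:
        raise EstimationError("Rhat requires at least two chains")
    import arviz as az
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(arr))


@dataclass
class PriorSensitivity:
    """Per-parameter comparison of two prior regimes on the same data/spec."""

    table: pd.DataFrame
    conservative: bool       # admissible-range |means| uniformly <= reference
    conservative_ar: bool    # same, restricted to the lagged-coefficient block
    tolerance: float


def prior_sensitivity(fit_ref: PosteriorDraws, fit_adm: PosteriorDraws,
                      tolerance: float = 0.01) -> PriorSensitivity:
    """Compare posterior means under reference vs admissible-range priors.

    Reports the per-parameter shift, sign agreement and 95% interval overlap,
    and flags the admissible-range fit as *conservative* when its posterior
    means are uniformly no larger in magnitude (within ``tolerance``).
    """
    if set(fit_ref.names()) != set(fit_adm.names()):
        raise EstimationError("fits have different parameter sets")
    if fit_ref.person_ids != fit_adm.person_ids:
        raise EstimationError("fits were produced from different data")
    rows = []
    for name in fit_ref.names():
        a, r = fit_adm.stacked(name), fit_ref.stacked(name)
        lo_a, hi_a = np.percentile(a, [2.5, 97.5])
        lo_r, hi_r = np.percentile(r, [2.5, 97.5])
        rows.append({
            "parameter": name,
            "mean_reference": r.mean(),
            "mean_admissible": a.mean(),
            "shift": a.mean() - r.mean(),
            "magnitude_change": abs(a.mean()) - abs(r.mean()),
            "sign_agreement": np.sign(a.mean()) == np.sign(r.mean()),
            "cri_overlap": max(0.0, min(hi_a, hi_r) - max(lo_a, lo_r)) > 0,
        })
    table = pd.DataFrame(rows).set_index("parameter")
    shrunk = table["magnitude_change"] <= tolerance
    ar_rows = table.index.str.startswith("phi[")
    return PriorSensitivity(
        table=table,
        conservative=bool(shrunk.all()),
        conservative_ar=bool(shrunk[ar_rows].all()) if ar_rows.any() else True,
        tolerance=tolerance,
    )
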