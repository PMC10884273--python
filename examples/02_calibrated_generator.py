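"""The calibrated synthetic-cohort generator and its oracles.

The default generating configuration is solved (deterministically) so that
the model-implied standardized (STDYX) parameters equal the published
posterior means for the cohort the generator emulates.  This script shows
the calibration residuals, the stationary residual covariance implied by the
lag-1 dynamics, and checks it against an empirical long-run simulation.
"""

import numpy as np

from rdsem import (DEFAULT_STDYX_TARGETS, default_generating_config,
                   generate_panel, implied_stdyx, stationary_moments)

cfg = default_generating_config(seed=1)
implied = implied_stdyx(cfg)

print("calibration check (model-implied STDYX vs target):")
for key in ("phi_std[DUDIT<-DUDIT]", "phi_std[SWLS<-SWLS]", "trend_std[DUDIT]",
            "innov_corr[DUDIT,SWLS]", "resid_var_std[DUDIT]"):
    print(f"  {key:28s} implied {implied[key]:+.4f}  target "
          f"{DEFAULT_STDYX_TARGETS[key]:+.4f}")
worst = max(abs(implied[k] - v) for k, v in DEFAULT_STDYX_TARGETS.items())
print(f"  worst absolute calibration error over all targets: {worst:.2e}")

print("\nunstandardized lagged-coefficient matrix (rows: DUDIT, SWLS, GSI):")
print(np.round(cfg.phi, 3))

seps = stationary_moments(cfg)
print("\nstationary residual covariance (rescaled metric):")
print(np.round(seps, 4))

# empirical check: the detrended residuals of a large simulated cohort have
# exactly this covariance (up to Monte-Carlo error)
_, lat = generate_panel(cfg, seed=2, return_latents=True)
emp = np.cov(lat["eps"].reshape(-1, 3).T)
print(f"\nmax |empirical - implied| at N=164: {np.max(np.abs(emp - seps)):.4f} "
      "(shrinks as the cohort grows)")
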