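"""Prior sensitivity: diffuse reference vs admissible-range priors.

Fits the same synthetic cohort under both regimes and compares the posterior
means.  The admissible-range priors (lagged coefficients truncated to
(-1, 1), unit-scale normals elsewhere) concentrate mass on the plausible
region and give slightly more conservative estimates, shifted toward zero.
"""

from rdsem import (default_generating_config, default_priors,
                   expand_time_lattice, fit_mcmc, prior_sensitivity,
                   simulate_cohort)

cfg = default_generating_config(n_persons=60, seed=9)
panel = expand_time_lattice(simulate_cohort(cfg))

fit_ref = fit_mcmc(panel, priors=default_priors("reference"),
                   chains=2, iterations=800, seed=9)
fit_adm = fit_mcmc(panel, priors=default_priors("admissible_range"),
                   chains=2, iterations=800, seed=9)

out = prior_sensitivity(fit_ref, fit_adm)
ar_rows = out.table[out.table.index.str.startswith("phi[")]
print(ar_rows[["mean_reference", "mean_admissible", "magnitude_change"]].round(4))
print(f"\nlagged block uniformly shrunk toward zero: {out.conservative_ar}")
# negative magnitude_change = the admissible-range estimate is smaller in
# absolute value; the sign of every effect is unchanged.
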