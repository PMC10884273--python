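# rdsem — two-level residual dynamic structural equation models

`rdsem` is a Python toolkit for analysing how substance use, satisfaction
with life, and psychological distress co-evolve over years of recovery from
polysubstance use disorder, using Bayesian two-level **residual dynamic
structural equation models** (rDSEM).  It is aimed at longitudinal
addiction/mental-health researchers with panel data that are unequally
spaced, heavily incomplete, and nested in persons.

The package covers the complete workflow:

- **Panel QC** — cluster sizes, the 2³ outcome-missingness patterns,
  intraclass correlations, and a rank-sum screen for whether an outcome's
  distribution depends on another outcome's missingness.
- **Preprocessing** — outcome rescaling (DUDIT-C ÷ 5, SWLS ÷ 10) and
  time-lattice expansion: phantom all-missing occasions are inserted so one
  lag always means one 3-month step, even across annual follow-up waves.
- **Synthetic cohorts** — a generator calibrated so that its model-implied
  standardized parameters equal the published posterior means of the
  five-year STAYER recovery cohort it emulates (the original data are not
  deposited), with the cohort's demographics, attrition law and
  missingness-dependence structure.
- **Estimation** — a blocked Gibbs sampler with data augmentation for
  missing/phantom cells and latent person effects; ESS / split-chain Rhat
  diagnostics; reference vs admissible-range prior regimes and a
  prior-sensitivity comparison.
- **Reporting** — STDYX standardization (cluster-wise, averaged over
  clusters), credibility flags, within/between R², and a parameter-recovery
  harness.

## The model

For outcome $v \in \{\text{DUDIT}, \text{SWLS}, \text{GSI}\}$ of person $i$
at lattice occasion $t$ (time $\tau_t$ in years, 3-month steps):

$$y_{vit} = \alpha_{vi} + \beta_{vi}\,\tau_t + \varepsilon_{vit}$$

$$\boldsymbol\varepsilon_{it} = \Phi\,\boldsymbol\varepsilon_{i,t-1} + \mathbf u_{it},
\qquad \mathbf u_{it} \sim N(\mathbf 0, \Sigma_u),\qquad
\boldsymbol\varepsilon_{i1} \sim N(\mathbf 0, \Sigma_\varepsilon)$$

so the lag-1 vector autoregression acts on *latent-centred, detrended
residuals* — lagged effects are not confounded with person means or growth.
$\Sigma_\varepsilon$ solves the discrete Lyapunov equation
$\Sigma_\varepsilon = \Phi \Sigma_\varepsilon \Phi' + \Sigma_u$ (stationary
start).  $\Phi$ is sparse: all three lagged residuals feed the substance-use
equation; life satisfaction and distress carry own lags only.  Lagged
effects are fixed (not person-varying).  At the between level,

$$\boldsymbol\alpha_i = \boldsymbol\nu_\alpha + \Gamma_\alpha \mathbf x_i + \mathbf a_i,
\qquad
\boldsymbol\beta_i = \boldsymbol\nu_\beta + \Gamma_\beta \mathbf x_i + \mathbf b_i,$$

with $\mathbf x_i$ = (gender, standardized age),
$\mathbf a_i \sim N(0, \Sigma_\alpha)$ unstructured and
$\mathbf b_i \sim N(0, \mathrm{diag}\,\sigma^2_\beta)$.  Missing cells —
item non-response, missed occasions, and phantom lattice rows alike — are
treated as latent and integrated over by the sampler.  See
`docs/methods.md` for priors, the sampler, and standardization conventions.

## Worked example

```python
from rdsem import (default_generating_config, simulate_cohort,
                   expand_time_lattice, fit_mcmc, stdyx_standardize,
                   credible_table)

cfg = default_generating_config(n_persons=60, seed=3)   # calibrated cohort
panel = expand_time_lattice(simulate_cohort(cfg))        # QC-ready panel
fit = fit_mcmc(panel, chains=2, iterations=800, seed=3)
print(credible_table(stdyx_standardize(fit))[0])
```

prints (abridged; `examples/03_fit_and_report.py`):

```
parameter                                 est      sd     lo95     up95  sig
phi_std[DUDIT<-DUDIT]                   0.204   0.069    0.073    0.325  ***
phi_std[DUDIT<-SCL90R]                  0.161   0.079    0.010    0.308  ***
phi_std[SWLS<-SWLS]                     0.346   0.051    0.240    0.438  ***
innov_corr[DUDIT,SWLS]                 -0.231   0.056   -0.334   -0.122  ***
resid_var_std[DUDIT]                    0.768   0.040    0.687    0.841  ***
...
R^2 (variance explained)
  within             DUDIT     0.232 [ 0.159,  0.313]
```

Reading it: `phi_std[DUDIT<-SCL90R] = 0.161` says a one-SD
higher-than-personal-norm distress residual predicts a 0.16-SD higher
substance-use residual one quarter later; `innov_corr[DUDIT,SWLS] = −0.231`
is the same-occasion innovation correlation between substance use and life
satisfaction; `resid_var_std[DUDIT] = 0.768` is the standardized innovation
variance, so the model explains 23.2% of the observation-level substance-use
variance (the `within DUDIT` R² — the two are complements by construction).
`***` marks rows whose 95% credible interval excludes zero.

The same workflow is available from the shell:

```bash
rdsem simulate -o panel.csv --n-persons 164 --seed 7
rdsem qc panel.csv --rescaled
rdsem fit --data panel.csv --chains 2 --iter 5000 --seed 7 -o draws.npz
rdsem report --draws draws.npz -o results.csv
rdsem recover --seed 7 -o recovery.json     # end-to-end recovery harness
```

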