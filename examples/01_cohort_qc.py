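"""Quality control of an unequally spaced longitudinal panel.

Simulates a study-like cohort (164 persons, 11 occasions over four years,
realistic attrition and item missingness), then runs the descriptive QC a
analyst would do before any dynamic modelling: cluster sizes, the 2^3
outcome-missingness patterns, intraclass correlations, the dependence of the
substance-use distribution on life-satisfaction missingness, and the
low-variance screen for the drug-free-friends covariate.
"""

from rdsem import (default_generating_config, distribution_by_missingness,
                   icc1, missingness_patterns, screen_low_variance_covariate,
                   simulate_cohort)

cfg = default_generating_config(n_persons=164, seed=42)
panel = simulate_cohort(cfg)

ms = missingness_patterns(panel)
print(f"persons: {panel.n_persons}, person-occasions: {panel.n_records}, "
      f"complete occasions: {ms.n_complete_occasions}")

print("\ncluster sizes (attended occasions -> % of persons):")
for k, v in sorted(ms.cluster_size_table.items()):
    print(f"  {k:3d}  {v:5.1f}%")
# ~75% of persons attend all 11 occasions; the rest mostly miss 1-3.

print("\nintraclass correlations (share of variance between persons):")
for v in ("dudit_c", "swls", "scl90r_gsi"):
    print(f"  {v:12s} ICC1 = {icc1(panel, v):.2f}")
# values around 0.3-0.5 say a two-level (hierarchical) model is needed.

dep = distribution_by_missingness(panel, target="dudit_c", indicator="swls")
print(f"\nsubstance use when SWLS is missing vs observed: "
      f"Cliff's delta {dep.cliffs_delta:+.3f}, p = {dep.p_value:.2g}")
# positive delta: drug-use scores run higher at occasions where the
# life-satisfaction score was not returned (missingness is not MCAR).

screen = screen_low_variance_covariate(panel, "drug_free_friends")
print(f"\ndrug-free friends: constant within {screen.constancy_proportion:.0%} "
      f"of persons -> recommendation: {screen.decision}")
# a binary covariate that never moves within persons cannot enter the
# within-person dynamic model.
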