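"""Missing-data and clustering diagnostics for longitudinal panels.

Covers the descriptive preprocessing of an unequally spaced cohort: cluster
sizes (occasions attended per person), the 2^3 outcome-missingness patterns,
intraclass correlations, and the dependence of one outcome's observed
distribution on another outcome's missingness (an MCAR screen).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateStratumError, EstimationError, PanelFormatError
from .panel import OUTCOMES, PanelDataset


@dataclass(frozen=True)
class MissingnessSummary:
    n_total_cells: int
    n_complete_occasions: int
    #: occasion counts keyed by the subset of outcomes missing at the occasion
    pattern_counts: dict
    #: percentage of persons by number of attended occasions
    cluster_size_table: dict

    def __post_init__(self):
        total_pat = sum(self.pattern_counts.values())
        if total_pat and total_pat * 3 != self.n_total_cells:
            raise ValueError("pattern counts inconsistent with cell count")


def missingness_patterns(data: PanelDataset) -> MissingnessSummary:
    """Tabulate outcome-missingness patterns and the cluster-size table.

    An occasion is *attended* when at least one outcome is observed; the
    cluster size of a person is their number of attended occasions.  Pattern
    counts are over all person-occasions present in the records and sum to
    persons x occasions when every person has a full schedule of records.
    """
    rec = data.records
    miss = rec[list(OUTCOMES)].isna()
    codes = miss.to_numpy() @ (1 << np.arange(3))        # bitmask per occasion
    pattern_counts = {}
    for code, n in zip(*np.unique(codes, return_counts=True)):
        key = frozenset(v for j, v in enumerate(OUTCOMES) if int(code) >> j & 1)
        pattern_counts[key] = int(n)
    n_complete = int(pattern_counts.get(frozenset(), 0))
    attended = ~miss.all(axis=1)
    sizes = attended.groupby(rec["person_id"]).sum() if len(rec) else pd.Series([], dtype=int)
    cluster_table = {}
    if len(sizes):
        counts = sizes.astype(int).value_counts().sort_index()
        cluster_table = {int(k): 100.0 * v / len(sizes) for k, v in counts.items()}
    return MissingnessSummary(
        n_total_cells=3 * len(rec),
        n_complete_occasions=n_complete,
        pattern_counts=pattern_counts,
        cluster_size_table=cluster_table,
    )


def icc1(data: PanelDataset, outcome: str) -> float:
    """One-way random-effects ANOVA intraclass correlation, ICC(1).

    The between-person share of total variance, with the unbalanced-design
    correction for the average cluster size

        n0 = (N - sum n_i^2 / N) / (k - 1),
        ICC1 = (MSB - MSW) / (MSB + (n0 - 1) MSW),

    clipped at zero.  Requires at least two persons with two or more
    observed values each.
    """
    if outcome not in OUTCOMES:
        raise PanelFormatError(f"unknown outcome {outcome!r}")
    x = data.records[["person_id", outcome]].dropna()
    if x.empty:
        raise EstimationError(f"{outcome} entirely missing")
    groups = x.groupby("person_id")[outcome]
    sizes = groups.size()
    if (sizes >= 2).sum() < 2:
        raise EstimationError("need >=2 persons with >=2 observed values")
    n_total = int(sizes.sum())
    k = len(sizes)
    grand = x[outcome].mean()
    means = groups.mean()
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float(((x[outcome] - means.loc[x["person_id"]].values) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (n_total - k)
    n0 = (n_total - float((sizes**2).sum()) / n_total) / (k - 1)
    if msw == 0.0:
        return 1.0
    icc = (msb - msw) / (msb + (n0 - 1) * msw)
    return float(np.clip(icc, 0.0, 1.0))


@dataclass(frozen=True)
class MissingnessDependence:
    """Distribution of an observed outcome stratified by another's missingness."""

    target: str
    indicator: str
    n_indicator_missing: int
    n_indicator_observed: int
    cliffs_delta: float            # P(target higher | indicator missing) - P(lower)
    smd: float                     # standardized mean difference (missing - observed)
    statistic: float               # Mann-Whitney U
    p_value: float


def distribution_by_missingness(data: PanelDataset, target: str,
                                indicator: str) -> MissingnessDependence:
    """Rank-sum comparison of observed ``target`` values by ``indicator`` missingness.

    Splits occasions where ``target`` is observed into two strata (indicator
    missing vs observed at the same occasion) and reports a Wilcoxon
    rank-sum test with Cliff's delta and a standardized mean difference —
    positive values mean ``target`` is higher when ``indicator`` is missing.
    """
    for v in (target, indicator):
        if v not in OUTCOMES:
            raise PanelFormatError(f"unknown outcome {v!r}")
    rec = data.records
    obs = rec[rec[target].notna()]
    missing_stratum = obs.loc[obs[indicator].isna(), target].to_numpy()
    observed_stratum = obs.loc[obs[indicator].notna(), target].to_numpy()
    if len(missing_stratum) == 0 or len(observed_stratum) == 0:
        raise DegenerateStratumError(
            f"no occasions with {target} observed and {indicator} "
            f"{'missing' if len(missing_stratum) == 0 else 'observed'}"
        )
    u, p = stats.mannwhitneyu(missing_stratum, observed_stratum, alternative="two-sided")
    delta = 2.0 * u / (len(missing_stratum) * len(observed_stratum)) - 1.0
    pooled = np.sqrt(0.5 * (missing_stratum.var(ddof=1) + observed_stratum.var(ddof=1)))
    smd = float((missing_stratum.mean() - observed_stratum.mean()) / pooled) if pooled > 0 else 0.0
    return MissingnessDependence(
        target=target, indicator=indicator,
        n_indicator_missing=len(missing_stratum),
        n_indicator_observed=len(observed_stratum),
        cliffs_delta=float(delta), smd=smd, statistic=float(u), p_value=float(p),
    )
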