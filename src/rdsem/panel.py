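"""Long-format longitudinal panel container, IO and preprocessing transforms.

The panel holds one record per person per measurement occasion with three
continuous outcomes — a drug-consumption score (DUDIT-C, 0-8), a satisfaction
with life sum score (SWLS, 5-35) and a psychological-distress index
(SCL-90-R GSI, 0-4) — a binary time-varying covariate (drug-free friends) and
two person-level covariates (age at baseline, gender).  Time is measured in
months since baseline; occasions follow a nominal schedule that mixes
quarterly and annual follow-ups, so a lattice-expansion step inserts phantom
(all-missing) occasions to make the spacing constant before any lag-1 model
is fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError, PanelFormatError, PanelIntegrityError, StateError

#: Outcome columns in canonical order.
OUTCOMES = ("dudit_c", "swls", "scl90r_gsi")

#: Instrument ranges on the raw (unrescaled) metric.
OUTCOME_RANGES = {"dudit_c": (0.0, 8.0), "swls": (5.0, 35.0), "scl90r_gsi": (0.0, 4.0)}

#: Default downscaling used to bring the outcomes to similar ranges.
DEFAULT_RESCALE_FACTORS = {"dudit_c": 5.0, "swls": 10.0, "scl90r_gsi": 1.0}

RECORD_COLUMNS = ["person_id", "month", "dudit_c", "swls", "scl90r_gsi", "drug_free_friends"]
PERSON_COLUMNS = ["person_id", "age", "gender"]
CSV_COLUMNS = RECORD_COLUMNS + ["age", "gender"]

#: Nominal occasion schedules (months since baseline).  ``stayer11`` is the
#: default five-year design: quarterly to two years, then annual to four
#: years; ``stayer12`` extends it with a 60-month wave.
SCHEDULES = {
    "stayer11": (0, 3, 6, 9, 12, 15, 18, 21, 24, 36, 48),
    "stayer12": (0, 3, 6, 9, 12, 15, 18, 21, 24, 36, 48, 60),
}

MIN_AGE = 16.0


@dataclass(frozen=True)
class PanelDataset:
    """Validated long-format panel.

    Attributes
    ----------
    records
        One row per (person, occasion): outcome scores and the time-varying
        covariate; missing cells are NaN.
    persons
        One row per person: ``person_id``, ``age`` (years at baseline, >= 16)
        and ``gender`` (binary code, male = 1).
    schedule
        Nominal occasion months.  After lattice expansion this is the lattice.
    rescaled
        Whether outcomes are on the downscaled metric.
    rescale_factors
        Division factors applied when ``rescaled`` is True.
    lattice_step
        Spacing in months after :func:`expand_time_lattice`; None before.
    """

    records: pd.DataFrame
    persons: pd.DataFrame
    schedule: tuple[int, ...]
    rescaled: bool = False
    rescale_factors: dict = field(default_factory=lambda: dict(DEFAULT_RESCALE_FACTORS))
    lattice_step: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "records", _normalize_records(self.records))
        object.__setattr__(self, "persons", _normalize_persons(self.persons))
        object.__setattr__(self, "schedule", tuple(int(m) for m in self.schedule))
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check all container invariants; raise on violation."""
        rec, per = self.records, self.persons
        dup = rec.duplicated(subset=["person_id", "month"])
        if dup.any():
            rows = rec.index[dup].tolist()[:5]
            raise PanelIntegrityError(f"duplicate (person_id, month) pairs at rows {rows}")
        if (rec["month"] < 0).any():
            raise PanelIntegrityError("negative month values")
        bad_month = ~rec["month"].isin(self.schedule)
        if bad_month.any():
            rows = rec.index[bad_month].tolist()[:5]
            raise PanelIntegrityError(f"months outside the schedule at rows {rows}")
        if per["person_id"].duplicated().any():
            raise PanelIntegrityError("duplicate person_id in persons table")
        unknown = ~rec["person_id"].isin(per["person_id"])
        if unknown.any():
            rows = rec.index[unknown].tolist()[:5]
            raise PanelIntegrityError(f"records for persons missing from persons table, rows {rows}")
        if (per["age"] < MIN_AGE).any():
            raise PanelIntegrityError(f"ages below the inclusion minimum of {MIN_AGE}")
        if not per["gender"].dropna().isin([0, 1]).all():
            raise PanelIntegrityError("gender must be coded 0/1")
        if not self.rescaled:
            for v, (lo, hi) in OUTCOME_RANGES.items():
                x = rec[v]
                bad = x.notna() & ((x < lo) | (x > hi))
                if bad.any():
                    rows = rec.index[bad].tolist()[:5]
                    raise PanelIntegrityError(
                        f"{v} outside instrument range [{lo}, {hi}] at rows {rows}"
                    )

    # ------------------------------------------------------------------
    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def person_ids(self) -> list:
        return self.persons["person_id"].tolist()

    def to_frame(self) -> pd.DataFrame:
        """Flat frame with person covariates repeated on every record."""
        return self.records.merge(self.persons, on="person_id", how="left")[CSV_COLUMNS]

    def equals(self, other: "PanelDataset") -> bool:
        a = self.to_frame().reset_index(drop=True)
        b = other.to_frame().reset_index(drop=True)
        return (
            a.shape == b.shape
            and self.schedule == other.schedule
            and self.rescaled == other.rescaled
            and bool(np.all((a.values == b.values) | (pd.isna(a).values & pd.isna(b).values)))
        )


def _normalize_records(rec: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in rec.columns]
    if missing:
        raise PanelFormatError(f"records missing required columns {missing}")
    rec = rec[RECORD_COLUMNS].copy()
    rec["month"] = rec["month"].astype(int)
    for c in OUTCOMES + ("drug_free_friends",):
        rec[c] = pd.to_numeric(rec[c], errors="coerce").astype(float)
    return rec.sort_values(["person_id", "month"], kind="mergesort").reset_index(drop=True)


def _normalize_persons(per: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PERSON_COLUMNS if c not in per.columns]
    if missing:
        raise PanelFormatError(f"persons missing required columns {missing}")
    per = per[PERSON_COLUMNS].copy()
    per["age"] = pd.to_numeric(per["age"], errors="coerce").astype(float)
    per["gender"] = pd.to_numeric(per["gender"], errors="coerce").astype(float)
    return per.sort_values("person_id", kind="mergesort").reset_index(drop=True)


# ----------------------------------------------------------------------
# IO
# ----------------------------------------------------------------------

def read_panel(path, schedule: tuple[int, ...] | None = None, rescaled: bool = False) -> PanelDataset:
    """Read a long-format CSV panel.

    The file must carry the columns ``person_id, month, dudit_c, swls,
    scl90r_gsi, drug_free_friends, age, gender``; missing cells are empty.
    Rows with out-of-range outcome values are rejected with row-indexed
    diagnostics.

    Parameters
    ----------
    path : str or file-like
    schedule : optional explicit occasion schedule; inferred from the
        observed months when omitted.
    rescaled : set True when the file is already on the downscaled metric.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise PanelFormatError(f"panel file missing required columns {missing}")
    persons = df[PERSON_COLUMNS].drop_duplicates(subset="person_id")
    incons = df.groupby("person_id")[["age", "gender"]].nunique(dropna=False)
    bad = incons[(incons > 1).any(axis=1)]
    if len(bad):
        raise PanelIntegrityError(
            f"inconsistent age/gender within persons {bad.index.tolist()[:5]}"
        )
    if schedule is None:
        schedule = tuple(sorted(df["month"].astype(int).unique()))
    return PanelDataset(records=df[RECORD_COLUMNS], persons=persons,
                        schedule=schedule, rescaled=rescaled)


def write_panel(data: PanelDataset, path) -> None:
    """Write the panel as long CSV with stable column order; missing = empty cell."""
    data.to_frame().to_csv(path, index=False, na_rep="")


# ----------------------------------------------------------------------
# Transforms
# ----------------------------------------------------------------------

def rescale_outcomes(data: PanelDataset, dudit_factor: float = 5.0,
                     swls_factor: float = 10.0) -> PanelDataset:
    """Downscale DUDIT-C and SWLS to ranges comparable with the GSI.

    Dividing DUDIT-C by 5 and SWLS by 10 brings all three outcomes to a
    similar numeric range, which eases MCMC convergence.  The operation is
    exactly invertible via :func:`inverse_rescale_outcomes`.
    """
    if data.rescaled:
        raise StateError("panel already rescaled")
    if dudit_factor <= 0 or swls_factor <= 0:
        raise ConfigError("rescale factors must be positive")
    factors = {"dudit_c": float(dudit_factor), "swls": float(swls_factor), "scl90r_gsi": 1.0}
    rec = data.records.copy()
    for v, f in factors.items():
        rec[v] = rec[v] / f
    return replace(data, records=rec, rescaled=True, rescale_factors=factors)


def inverse_rescale_outcomes(data: PanelDataset) -> PanelDataset:
    """Undo :func:`rescale_outcomes` exactly."""
    if not data.rescaled:
        raise StateError("panel is not rescaled")
    rec = data.records.copy()
    for v, f in data.rescale_factors.items():
        rec[v] = rec[v] * f
    return replace(data, records=rec, rescaled=False,
                   rescale_factors=dict(DEFAULT_RESCALE_FACTORS))


def expand_time_lattice(data: PanelDataset, step_months: int = 3) -> PanelDataset:
    """Insert phantom all-missing occasions so spacing is a constant step.

    For every person a record exists at every multiple of ``step_months``
    between the schedule minimum and maximum.  Inserted records have all
    outcomes (and the time-varying covariate) missing; original records are
    unchanged.  After expansion a lag-1 term always means one ``step_months``
    interval.  Idempotent.
    """
    if step_months <= 0:
        raise ConfigError("step_months must be a positive integer")
    gaps = np.diff(sorted(set(data.schedule)))
    if len(gaps) and step_months > gaps.min():
        raise ConfigError(
            f"step {step_months} exceeds the smallest schedule gap {int(gaps.min())}"
        )
    off = [m for m in data.schedule if m % step_months]
    if off:
        raise ConfigError(f"schedule months {off} not divisible by step {step_months}")
    lo, hi = min(data.schedule), max(data.schedule)
    lattice = tuple(range(lo, hi + 1, step_months))
    if tuple(sorted(data.schedule)) == lattice:
        return replace(data, schedule=lattice, lattice_step=step_months)
    pids = data.persons["person_id"]
    full = pd.MultiIndex.from_product([pids, lattice], names=["person_id", "month"])
    rec = data.records.set_index(["person_id", "month"]).reindex(full).reset_index()
    return replace(data, records=rec, schedule=lattice, lattice_step=step_months)


def dichotomize_dudit(data: PanelDataset, cutoff: float = 0.0) -> pd.Series:
    """Binary use indicator: 0 at the cutoff (score zero = no use), 1 above.

    Must be called on unrescaled scores; missing propagates.
    """
    if data.rescaled:
        raise StateError("dichotomize_dudit requires unrescaled scores")
    x = data.records["dudit_c"]
    out = (x > cutoff).astype(float)
    out[x.isna()] = np.nan
    out.name = "substance_use"
    return out


@dataclass(frozen=True)
class CovariateScreen:
    """Low-variance screening decision for a binary time-varying covariate."""

    covariate: str
    decision: str                 # "keep" | "drop"
    constancy_proportion: float   # share of persons with a time-constant value
    pooled_variance: float
    threshold: float


def screen_low_variance_covariate(data: PanelDataset, covariate: str = "drug_free_friends",
                                  threshold: float = 0.9) -> CovariateScreen:
    """Recommend dropping a binary covariate that is virtually constant.

    A covariate whose value never changes within ``threshold`` (default 90%)
    of persons carries no usable within-person variance and is recommended
    for exclusion from the dynamic model.
    """
    if covariate not in data.records.columns:
        raise PanelFormatError(f"covariate {covariate!r} not in records")
    x = data.records[[covariate, "person_id"]].dropna(subset=[covariate])
    vals = x[covariate].unique()
    if not set(vals) <= {0.0, 1.0}:
        raise PanelIntegrityError(f"{covariate} is not binary")
    per_person = x.groupby("person_id")[covariate].nunique()
    constancy = float((per_person <= 1).mean()) if len(per_person) else 1.0
    pooled_var = float(x[covariate].var(ddof=0)) if len(x) else 0.0
    decision = "drop" if constancy >= threshold else "keep"
    return CovariateScreen(covariate, decision, constancy, pooled_var, threshold)
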