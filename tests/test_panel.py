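"""Panel container, IO and preprocessing transforms."""

import numpy as np
import pandas as pd
import pytest

from rdsem import (ConfigError, PanelDataset, PanelFormatError,
                   PanelIntegrityError, StateError, dichotomize_dudit,
                   expand_time_lattice, inverse_rescale_outcomes, read_panel,
                   rescale_outcomes, screen_low_variance_covariate, write_panel)
from conftest import toy_frame


def test_read_panel_parses_toy_csv(tmp_path):
    path = tmp_path / "panel.csv"
    toy_frame().to_csv(path, index=False)
    data = read_panel(path)
    assert data.n_records == 6
    assert data.n_persons == 3
    assert data.schedule == (0, 3)
    assert np.isnan(data.records.loc[
        (data.records.person_id == "a") & (data.records.month == 3), "swls"]).all()


def test_write_read_round_trip(tmp_path, toy_panel):
    path = tmp_path / "out.csv"
    write_panel(toy_panel, path)
    back = read_panel(path)
    assert back.equals(toy_panel)
    # missing cell written as empty, not a sentinel
    raw = path.read_text()
    assert "-99" not in raw and "nan" not in raw.lower().replace("nan,", "")


def test_write_empty_dataset_header_only(tmp_path):
    data = PanelDataset(records=toy_frame().iloc[:0],
                        persons=toy_frame()[["person_id", "age", "gender"]].iloc[:0],
                        schedule=(0, 3))
    path = tmp_path / "empty.csv"
    write_panel(data, path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 1 and lines[0].startswith("person_id,month")


@pytest.mark.parametrize("column,value,err", [
    ("dudit_c", 9.0, PanelIntegrityError),     # above instrument maximum of 8
    ("swls", 2.0, PanelIntegrityError),        # below SWLS minimum of 5
    ("scl90r_gsi", 4.5, PanelIntegrityError),
])
def test_out_of_range_values_rejected_with_row(column, value, err):
    df = toy_frame()
    df.loc[2, column] = value
    with pytest.raises(err, match="rows"):
        PanelDataset(records=df, persons=df[["person_id", "age", "gender"]].drop_duplicates(),
                     schedule=(0, 3))


def test_missing_column_is_format_error(tmp_path):
    df = toy_frame().drop(columns=["swls"])
    path = tmp_path / "bad.csv"
    df.to_csv(path, index=False)
    with pytest.raises(PanelFormatError, match="swls"):
        read_panel(path)


def test_duplicate_person_month_is_integrity_error():
    df = pd.concat([toy_frame(), toy_frame().iloc[[0]]], ignore_index=True)
    with pytest.raises(PanelIntegrityError, match="duplicate"):
        PanelDataset(records=df, persons=df[["person_id", "age", "gender"]].drop_duplicates(),
                     schedule=(0, 3))


def test_age_below_inclusion_minimum_rejected():
    df = toy_frame()
    df.loc[df.person_id == "a", "age"] = 15.0
    with pytest.raises(PanelIntegrityError, match="16"):
        PanelDataset(records=df, persons=df[["person_id", "age", "gender"]].drop_duplicates(),
                     schedule=(0, 3))


class TestRescale:
    def test_division_by_default_factors(self, toy_panel):
        out = rescale_outcomes(toy_panel)
        rec = out.records
        assert rec.loc[3, "dudit_c"] == pytest.approx(8.0 / 5.0)
        assert rec.loc[4, "swls"] == pytest.approx(35.0 / 10.0)
        # GSI untouched
        assert np.allclose(rec["scl90r_gsi"], toy_panel.records["scl90r_gsi"])
        assert out.rescaled

    def test_missing_cells_stay_missing(self, toy_panel):
        out = rescale_outcomes(toy_panel)
        assert out.records["swls"].isna().sum() == 1

    def test_double_rescale_is_state_error(self, toy_panel):
        with pytest.raises(StateError):
            rescale_outcomes(rescale_outcomes(toy_panel))

    def test_inverse_round_trip_exact(self, toy_panel):
        back = inverse_rescale_outcomes(rescale_outcomes(toy_panel))
        for v in ("dudit_c", "swls", "scl90r_gsi"):
            a, b = back.records[v], toy_panel.records[v]
            assert np.allclose(a.dropna(), b.dropna())


class TestLatticeExpansion:
    STAYER11 = (0, 3, 6, 9, 12, 15, 18, 21, 24, 36, 48)

    def _panel(self, months, n_persons=2):
        rows = []
        for i in range(n_persons):
            for m in months:
                rows.append({"person_id": i, "month": m, "dudit_c": 1.0,
                             "swls": 20.0, "scl90r_gsi": 1.0, "drug_free_friends": 1})
        df = pd.DataFrame(rows)
        persons = pd.DataFrame({"person_id": range(n_persons),
                                "age": 30.0, "gender": 1})
        return PanelDataset(records=df, persons=persons, schedule=tuple(months))

    def test_default_schedule_gives_17_lattice_points(self):
        out = expand_time_lattice(self._panel(self.STAYER11))
        assert len(out.schedule) == 17          # multiples of 3 in [0, 48]
        assert out.n_records == 2 * 17
        per_person = out.records.groupby("person_id")
        # 6 phantom records per person, all outcomes missing
        phantom = per_person.apply(
            lambda g: g[list(("dudit_c", "swls", "scl90r_gsi"))].isna().all(axis=1).sum(),
            include_groups=False)
        assert (phantom == 6).all()

    def test_already_equally_spaced_is_identity(self):
        panel = self._panel((0, 3, 6, 9))
        out = expand_time_lattice(panel)
        assert out.n_records == panel.n_records
        assert out.schedule == (0, 3, 6, 9)

    def test_idempotent(self):
        once = expand_time_lattice(self._panel(self.STAYER11))
        twice = expand_time_lattice(once)
        assert twice.n_records == once.n_records

    def test_person_with_five_occasions_still_gets_full_lattice(self):
        months = (0, 12, 24, 36, 48)
        out = expand_time_lattice(self._panel(months))
        g = out.records[out.records.person_id == 0]
        assert len(g) == 17
        assert g["dudit_c"].isna().sum() == 12

    def test_step_larger_than_smallest_gap_is_config_error(self):
        with pytest.raises(ConfigError):
            expand_time_lattice(self._panel(self.STAYER11), step_months=6)

    def test_original_records_unchanged(self):
        panel = self._panel(self.STAYER11)
        out = expand_time_lattice(panel)
        kept = out.records[out.records.month.isin(self.STAYER11)]
        assert np.allclose(kept["dudit_c"], 1.0)


class TestDichotomize:
    def test_cutoff_and_missing(self, toy_panel):
        ind = dichotomize_dudit(toy_panel)
        rec = toy_panel.records
        assert ind[rec.dudit_c == 0].eq(0).all()        # score zero = no use
        assert ind[rec.dudit_c > 0].eq(1).all()
        df = toy_frame()
        df.loc[0, "dudit_c"] = np.nan
        panel = PanelDataset(records=df,
                             persons=df[["person_id", "age", "gender"]].drop_duplicates(),
                             schedule=(0, 3))
        assert dichotomize_dudit(panel).isna().sum() == 1

    def test_rescaled_data_is_state_error(self, toy_panel):
        with pytest.raises(StateError):
            dichotomize_dudit(rescale_outcomes(toy_panel))


class TestCovariateScreen:
    def _panel(self, dff_values):
        n_occ = len(dff_values[0])
        rows = []
        for i, vals in enumerate(dff_values):
            for t, v in enumerate(vals):
                rows.append({"person_id": i, "month": 3 * t, "dudit_c": 1.0,
                             "swls": 20.0, "scl90r_gsi": 1.0, "drug_free_friends": v})
        df = pd.DataFrame(rows)
        persons = pd.DataFrame({"person_id": range(len(dff_values)), "age": 30.0,
                                "gender": 0})
        return PanelDataset(records=df, persons=persons,
                            schedule=tuple(3 * t for t in range(n_occ)))

    def test_constant_covariate_dropped_with_zero_variance(self):
        out = screen_low_variance_covariate(self._panel([[1, 1, 1]] * 4))
        assert out.decision == "drop"
        assert out.pooled_variance == 0.0
        assert out.constancy_proportion == 1.0

    def test_alternating_covariate_kept(self):
        out = screen_low_variance_covariate(self._panel([[0, 1, 0, 1]] * 4))
        assert out.decision == "keep"

    def test_95_percent_constant_dropped_at_default_threshold(self):
        vals = [[1, 1, 1]] * 19 + [[0, 1, 0]]
        out = screen_low_variance_covariate(self._panel(vals))
        assert out.constancy_proportion == pytest.approx(0.95)
        assert out.decision == "drop"

    def test_unknown_covariate_is_schema_error(self, toy_panel):
        with pytest.raises(PanelFormatError):
            screen_low_variance_covariate(toy_panel, covariate="nope")
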