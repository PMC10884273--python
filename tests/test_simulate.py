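"""Synthetic-cohort generator: demographics, dynamics, attrition, missingness."""

import numpy as np
import pytest

from rdsem import (CalibrationError, ConfigError, GeneratingConfig,
                   calibrate_to_stdyx, default_generating_config,
                   distribution_by_missingness, draw_ages, generate_panel,
                   icc1, implied_stdyx, impose_missingness, missingness_patterns,
                   stationary_moments)
from rdsem.calibrate import DEFAULT_STDYX_TARGETS
from rdsem.simulate import replace_config


class TestDefaultConfig:
    def test_demographic_calibration(self, default_config):
        assert default_config.male_prop == pytest.approx(0.622)
        assert default_config.age_mean == pytest.approx(27.1)
        assert default_config.cluster_size_probs[11] == pytest.approx(0.75)
        assert default_config.n_persons == 164
        assert len(default_config.schedule) == 11

    def test_implied_stdyx_matches_targets(self, default_config):
        implied = implied_stdyx(default_config)
        for key, target in DEFAULT_STDYX_TARGETS.items():
            assert implied[key] == pytest.approx(target, abs=5e-3), key


class TestCalibration:
    def test_zero_targets_give_zero_phi_and_diagonal_innovations(self):
        targets = {k: 0.0 for k in DEFAULT_STDYX_TARGETS}
        for l in ("DUDIT", "SWLS", "SCL90R"):
            targets[f"resid_var_std[{l}]"] = 1.0
            targets[f"intercept_std[alpha.{l}]"] = 1.0
        cfg = calibrate_to_stdyx(targets)
        assert np.allclose(cfg.phi, 0.0)
        off_diag = cfg.sigma_u - np.diag(np.diag(cfg.sigma_u))
        assert np.allclose(off_diag, 0.0)

    def test_nonstationary_target_fails_with_diagnostics(self):
        with pytest.raises(CalibrationError):
            calibrate_to_stdyx({"phi_std[SWLS<-SWLS]": 1.2})

    def test_deterministic(self):
        a = calibrate_to_stdyx()
        b = calibrate_to_stdyx()
        assert np.array_equal(a.phi, b.phi)
        assert np.array_equal(a.sigma_u, b.sigma_u)


class TestStationaryMoments:
    def test_zero_phi_returns_innovation_covariance(self):
        cfg = GeneratingConfig(sigma_u=np.diag([0.2, 0.3, 0.4]))
        assert np.allclose(stationary_moments(cfg), np.diag([0.2, 0.3, 0.4]))

    def test_univariate_closed_form(self):
        # phi = 0.5, unit innovation variance: stationary variance 1/(1-0.25)
        cfg = GeneratingConfig(phi=np.diag([0.5, 0.0, 0.0]))
        assert stationary_moments(cfg)[0, 0] == pytest.approx(4.0 / 3.0)

    def test_agrees_with_scipy_lyapunov_solver(self, default_config):
        from scipy.linalg import solve_discrete_lyapunov
        got = stationary_moments(default_config)
        ref = solve_discrete_lyapunov(default_config.phi, default_config.sigma_u)
        assert np.allclose(got, ref, atol=1e-12)

    def test_matches_long_run_simulation(self, default_config):
        phi, su = default_config.phi, default_config.sigma_u
        rng = np.random.default_rng(0)
        lu = np.linalg.cholesky(su)
        n = 400_000
        eps = np.zeros((n, 3))
        z = rng.standard_normal((n, 3)) @ lu.T
        for t in range(1, n):
            eps[t] = phi @ eps[t - 1] + z[t]
        emp = np.cov(eps[1000:].T)
        assert np.allclose(emp, stationary_moments(default_config), atol=0.004)

    def test_nonstationary_refused(self):
        with pytest.raises(ConfigError):
            GeneratingConfig(phi=np.diag([1.05, 0.0, 0.0]))


class TestGeneratePanel:
    def test_same_seed_identical(self, default_config):
        a = generate_panel(default_config, seed=4)
        b = generate_panel(default_config, seed=4)
        assert a.equals(b)

    def test_structure(self, default_config):
        panel = generate_panel(default_config, seed=4)
        assert panel.n_records == 164 * 11
        assert panel.rescaled
        assert panel.records[["dudit_c", "swls", "scl90r_gsi"]].notna().all().all()

    def test_no_dynamics_gives_near_zero_icc(self):
        cfg = GeneratingConfig(
            n_persons=300, sigma_alpha=1e-8 * np.eye(3), sigma_beta2=1e-10 * np.ones(3),
            grand_intercepts=np.array([1.0, 2.0, 1.0]), seed=2)
        panel = generate_panel(cfg)
        assert icc1(panel, "dudit_c") < 0.02

    def test_detrended_residuals_match_stationary_moments(self, default_config):
        cfg = replace_config(default_config, n_persons=2000)
        panel, lat = generate_panel(cfg, seed=6, return_latents=True)
        eps = lat["eps"]                          # (N, T_lattice, 3)
        n, t, _ = eps.shape
        emp = np.cov(eps.reshape(-1, 3).T)
        seps = stationary_moments(cfg)
        assert np.allclose(emp, seps, atol=0.01)
        # lag-1 cross moments match Phi Sigma_eps
        lag = np.einsum("ntv,ntw->vw", eps[:, 1:, :], eps[:, :-1, :]) / (n * (t - 1))
        assert np.allclose(lag, cfg.phi @ seps, atol=0.01)

    def test_ages_truncated_with_target_mean(self, default_config):
        rng = np.random.default_rng(0)
        ages = draw_ages(default_config, 20000, rng)
        assert ages.min() >= 16.0
        assert ages.mean() == pytest.approx(27.1, abs=0.2)
        assert ages.std() == pytest.approx(7.1, abs=0.2)


class TestImposeMissingness:
    def test_no_missingness_configured_is_identity(self, default_config):
        cfg = replace_config(default_config, n_persons=30,
                             cluster_size_probs={11: 1.0},
                             item_missing_rates={"dudit_c": 0.0, "swls": 0.0,
                                                 "scl90r_gsi": 0.0})
        panel = generate_panel(cfg, seed=1)
        out = impose_missingness(panel, cfg, seed=2)
        assert out.equals(panel)

    def test_cluster_size_law(self, default_config):
        cfg = replace_config(default_config, n_persons=4000)
        panel = generate_panel(cfg, seed=1)
        out = impose_missingness(panel, cfg, seed=2)
        ms = missingness_patterns(out)
        # attended occasions can only shrink via item missingness of all three
        share_11 = ms.cluster_size_table.get(11, 0.0) / 100.0
        assert share_11 == pytest.approx(0.75, abs=0.03)

    def test_item_rates_close_to_configured(self, default_config):
        cfg = replace_config(default_config, n_persons=3000)
        out = impose_missingness(generate_panel(cfg, seed=3), cfg, seed=4)
        rec = out.records
        # total missing = attrition share + item rate within attended occasions
        attr = sum((11 - k) * p for k, p in cfg.cluster_size_probs.items()) / 11
        for v in ("dudit_c", "scl90r_gsi"):
            expected = attr + (1 - attr) * cfg.item_missing_rates[v]
            assert rec[v].isna().mean() == pytest.approx(expected, abs=0.02)

    def test_dudit_higher_when_swls_missing(self, default_config):
        cfg = replace_config(default_config, n_persons=2000)
        out = impose_missingness(generate_panel(cfg, seed=5), cfg, seed=6)
        rep = distribution_by_missingness(out, "dudit_c", "swls")
        assert rep.cliffs_delta > 0.05
        assert rep.p_value < 0.01

    def test_unit_dependence_multiplier_gives_no_effect(self, default_config):
        cfg = replace_config(default_config, n_persons=2000, missing_dependence=1.0)
        out = impose_missingness(generate_panel(cfg, seed=7), cfg, seed=8)
        rep = distribution_by_missingness(out, "dudit_c", "swls")
        assert abs(rep.cliffs_delta) < 0.06

    def test_bad_rate_rejected(self, default_config):
        with pytest.raises(ConfigError):
            replace_config(default_config, item_missing_rates={"swls": 1.4})


def test_config_yaml_round_trip(tmp_path, default_config):
    path = tmp_path / "cfg.yaml"
    default_config.save(path)
    back = GeneratingConfig.load(path)
    assert np.allclose(back.phi, default_config.phi)
    assert np.allclose(back.sigma_alpha, default_config.sigma_alpha)
    assert back.cluster_size_probs == default_config.cluster_size_probs
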