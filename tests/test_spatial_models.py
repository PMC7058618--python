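"""SEM/SDEM maximum likelihood: nesting, oracles, LR test, selection."""

import numpy as np
import pandas as pd
import pytest

import ahspatial as ah
from ahspatial.spatial_models import significance_stars


@pytest.fixture(scope="module")
def sem_fit(demeaned_panel, queen117):
    return ah.fit_sem(demeaned_panel, queen117)


class TestSemCore:
    def test_rho_fixed_zero_reproduces_two_way_fe_ols(self, default_panel, demeaned_panel, queen117):
        cfg, panel, _ = default_panel
        f0 = ah.fit_sem(demeaned_panel, queen117, rho_fixed=0.0)
        Xc = panel.data[list(cfg.covariate_names)].to_numpy()
        Dd = pd.get_dummies(panel.data["district_id"]).to_numpy(float)
        Dy = pd.get_dummies(panel.data["year"], drop_first=True).to_numpy(float)
        b = np.linalg.lstsq(
            np.hstack([Xc, Dd, Dy]), panel.y(), rcond=None
        )[0][: len(cfg.covariate_names)]
        assert np.allclose(
            f0.beta[list(cfg.covariate_names)].to_numpy(), b, atol=1e-8
        )

    def test_rho_estimate_near_truth_on_default_panel(self, sem_fit, default_panel):
        cfg, _, _ = default_panel
        assert sem_fit.rho == pytest.approx(cfg.rho_true, abs=0.25)
        assert sem_fit.converged

    def test_loglik_argmax_matches_dense_grid_oracle(self, queen16):
        cfg = ah.SyntheticConfig(n_districts=16, n_years=4, rho_true=0.5,
                                 beta_true=(0.01, -0.01), seed=31)
        panel, _ = ah.generate_panel(cfg, queen16)
        d = ah.within_transform(panel)
        fit = ah.fit_sem(d, queen16)
        lo, hi = fit.rho_bounds
        grid = np.arange(lo + 0.01, hi - 1e-6, 0.001)
        lls = np.array([fit.profile_loglik(r) for r in grid])
        assert abs(grid[np.argmax(lls)] - fit.rho) <= 0.001 + 1e-9

    def test_logdet_via_eigenvalues_matches_dense_determinant(self, queen117):
        Wd = queen117.dense()
        eigs = np.linalg.eigvals(Wd)
        for rho in (-0.6, -0.2, 0.3, 0.7, 0.95):
            direct = np.linalg.slogdet(np.eye(117) - rho * Wd)[1]
            via_eigs = np.log(1 - rho * eigs).sum().real
            assert via_eigs == pytest.approx(direct, abs=1e-8)

    def test_profile_loglik_continuous_on_interval(self, sem_fit):
        lo, hi = sem_fit.rho_bounds
        grid = np.linspace(lo + 0.01, hi - 0.01, 60)
        lls = np.array([sem_fit.profile_loglik(r) for r in grid])
        assert np.isfinite(lls).all()
        assert np.abs(np.diff(lls)).max() < 50  # no jumps at desk scale

    def test_filtering_identity_at_rho_zero(self, default_panel, demeaned_panel, queen117):
        # pre-filtering by B(rho0) then fitting at rho=0 equals fitting the
        # unfiltered panel at rho=rho0 (same beta)
        cfg, panel, _ = default_panel
        rho0 = 0.3
        N, T = panel.n_districts, panel.n_years
        B = np.eye(N) - rho0 * queen117.dense()
        filt = demeaned_panel.copy()
        cols = ["share_total"] + list(cfg.covariate_names)
        for col in cols:
            v = filt.data[col].to_numpy().reshape(N, T)
            filt.data[col] = (B @ v).reshape(-1)
        f_filtered = ah.fit_sem(filt, queen117, rho_fixed=0.0)
        f_direct = ah.fit_sem(demeaned_panel, queen117, rho_fixed=rho0)
        assert np.allclose(
            f_filtered.beta[list(cfg.covariate_names)],
            f_direct.beta[list(cfg.covariate_names)],
            atol=1e-8,
        )

    def test_vcov_diagonal_positive_and_bic_identity(self, sem_fit):
        assert (np.diag(sem_fit.vcov.to_numpy()) > 0).all()
        assert sem_fit.bic == pytest.approx(
            -2 * sem_fit.loglik + sem_fit.k_params * np.log(sem_fit.n_obs)
        )
        assert sem_fit.rho_bounds[0] < sem_fit.rho < sem_fit.rho_bounds[1]

    def test_untransformed_panel_rejected(self, default_panel, queen117):
        _, panel, _ = default_panel
        with pytest.raises(ValueError, match="within-transform"):
            ah.fit_sem(panel, queen117)

    def test_collinear_columns_raise(self, demeaned_panel, queen117):
        bad = demeaned_panel.copy()
        bad.data["x1_dup"] = bad.data["x1"]
        bad.covariates = bad.covariates + ["x1_dup"]
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            ah.fit_sem(bad, queen117)


class TestSdem:
    def test_zero_durbin_column_gives_sem_loglik(self, demeaned_panel, queen117):
        aug = demeaned_panel.copy()
        aug.data["zero"] = 0.0
        sem = ah.fit_sem(demeaned_panel, queen117)
        x_cols = demeaned_panel.covariates + demeaned_panel.year_dummies
        sdem = ah.fit_sdem(aug, queen117, x_cols=x_cols, durbin_columns=["zero"])
        # W @ 0 = 0: lstsq assigns it zero effect; likelihood unchanged
        assert sdem.loglik == pytest.approx(sem.loglik, abs=1e-6)

    def test_theta_centered_at_zero_under_sem_dgp(self, demeaned_panel, queen117):
        sdem = ah.fit_sdem(demeaned_panel, queen117, durbin_columns=["x1", "x2"])
        assert set(sdem.durbin_columns) == {"W_x1", "W_x2"}
        for c in sdem.durbin_columns:
            assert abs(sdem.beta[c]) < 4 * sdem.se[c]

    def test_genuine_spillover_detected(self, queen117):
        # theta = 0.5 on x1: SDEM should beat SEM decisively
        cfg = ah.SyntheticConfig(beta_true=(0.5, 0.2), sigma_eps=0.5, seed=99)
        panel, _ = ah.generate_panel(cfg, queen117)
        N, T = panel.n_districts, panel.n_years
        wx1 = (queen117.dense() @ panel.data["x1"].to_numpy().reshape(N, T)).reshape(-1)
        panel.data["share_total"] = panel.data["share_total"] + 0.5 * wx1
        d = ah.within_transform(panel)
        sem = ah.fit_sem(d, queen117)
        sdem = ah.fit_sdem(d, queen117, durbin_columns=["x1", "x2"])
        t = ah.lr_test(sdem, sem)
        assert t.p_value < 0.01
        assert sdem.beta["W_x1"] == pytest.approx(0.5, abs=0.1)

    def test_empty_durbin_rejected(self, demeaned_panel, queen117):
        with pytest.raises(ValueError, match="durbin"):
            ah.fit_sdem(demeaned_panel, queen117, durbin_columns=[])


class TestLrAndSelection:
    def test_identical_fits_give_stat_zero_p_one(self, sem_fit, demeaned_panel, queen117):
        bigger = ah.fit_sdem(demeaned_panel, queen117, durbin_columns=["x1"])
        t = ah.lr_test(bigger, sem_fit)
        assert t.df == 1 and t.stat >= 0
        import dataclasses

        same = ah.lr_test(bigger, dataclasses.replace(bigger, k_params=bigger.k_params - 1))
        assert same.stat == pytest.approx(0.0, abs=1e-12)
        assert same.p_value == pytest.approx(1.0)

    def test_df_mismatch_rejected(self, sem_fit, demeaned_panel, queen117):
        sdem = ah.fit_sdem(demeaned_panel, queen117, durbin_columns=["x1", "x2"])
        with pytest.raises(ValueError, match="df"):
            ah.lr_test(sdem, sem_fit, df=5)

    def test_non_nested_order_rejected(self, sem_fit, demeaned_panel, queen117):
        sdem = ah.fit_sdem(demeaned_panel, queen117, durbin_columns=["x1"])
        with pytest.raises(ValueError, match="more parameters"):
            ah.lr_test(sem_fit, sdem)

    def test_bic_ranking_and_tie_break(self, sem_fit, demeaned_panel, queen117):
        sdem = ah.fit_sdem(demeaned_panel, queen117, durbin_columns=["x1", "x2"])
        tab = ah.model_select([sdem, sem_fit])
        assert tab.loc[0, "bic"] <= tab.loc[1, "bic"]
        # tie: equal BICs rank the smaller model first
        import dataclasses

        clone = dataclasses.replace(sdem, bic=sem_fit.bic)
        tab2 = ah.model_select([clone, sem_fit])
        assert tab2.loc[0, "model"] == "sem"

    def test_different_samples_not_comparable(self, sem_fit, queen16):
        cfg = ah.SyntheticConfig(n_districts=16, n_years=4, beta_true=(0.01,), seed=2)
        panel, _ = ah.generate_panel(cfg, queen16)
        other = ah.fit_sem(ah.within_transform(panel), queen16)
        with pytest.raises(ValueError, match="comparable"):
            ah.model_select([sem_fit, other])


class TestStars:
    @pytest.mark.parametrize(
        "p,expected", [(0.005, "***"), (0.03, "**"), (0.049, "**"), (0.05, ""), (0.5, "")]
    )
    def test_legend_thresholds(self, p, expected):
        assert significance_stars(p) == expected
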