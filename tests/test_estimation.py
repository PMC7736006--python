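"""Likelihood machinery, fitting, bootstrap and predictive checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from piperbrain.core_model import BrainModelParams
from piperbrain.estimation import (
    BQLMethod,
    DatasetPredictor,
    FitResult,
    _condition_numbers,
    apply_bql_method,
    bootstrap,
    diagnostics,
    fit,
    neg2ll,
    ofv_drop_significant,
    vpc,
)
from piperbrain.io import MicrodialysisDataset
from piperbrain.synthetic import generate_study


@pytest.fixture(scope="module")
def prepared(small_dataset):
    return apply_bql_method(small_dataset, BQLMethod("M5"))


class TestBQLMethods:
    def test_m5_substitutes_half_lloq(self, small_dataset):
        out = apply_bql_method(small_dataset, BQLMethod("M5"))
        was_bql = small_dataset.df["BQL"] == 1
        assert was_bql.sum() > 0
        assert (out.df.loc[was_bql, "DV"] == 0.025).all()
        assert (out.df.loc[was_bql, "BQL"] == 0).all()

    def test_m3_leaves_dataset_untouched(self, small_dataset):
        out = apply_bql_method(small_dataset, BQLMethod("M3"))
        pd.testing.assert_frame_equal(out.df, small_dataset.df)

    def test_no_bql_rows_unchanged_under_both(self, small_dataset):
        df = small_dataset.df
        quiet = MicrodialysisDataset(
            df[(df.EVID == 1) | (df.BQL == 0)].reset_index(drop=True)
        )
        assert quiet.bql_fraction() == 0.0
        for m in ("M3", "M5"):
            out = apply_bql_method(quiet, BQLMethod(m))
            pd.testing.assert_frame_equal(out.df, quiet.df)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            BQLMethod("M6")

    def test_substitution_above_lloq_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="below the LLOQ"):
            apply_bql_method(small_dataset, BQLMethod("M5", substitution=0.06))

    def test_m3_censored_row_far_above_lloq_is_penalised(self, truth, plasma, prepared, small_dataset):
        # flagging a clearly-quantifiable steady-state row as BQL must cost
        # many -2LL units under M3 (the censoring probability is ~ 0)
        base = neg2ll(truth, small_dataset, plasma, BQLMethod("M3"))
        df = small_dataset.df.copy()
        md_rows = df[(df.EVID == 0) & (df.OCC == 2)]
        df.loc[md_rows["DV"].idxmax(), "BQL"] = 1
        worse = neg2ll(truth, MicrodialysisDataset(df), plasma, BQLMethod("M3"))
        assert worse > base + 5.0


class TestLikelihood:
    def test_no_iiv_additive_error_equals_gaussian_deviance(self, plasma, noise_free_params, small_design):
        from dataclasses import replace as dc_replace

        p = BrainModelParams(
            K_pb=noise_free_params.K_pb, K_bp_fd=noise_free_params.K_bp_fd,
            K_bp_md=noise_free_params.K_bp_md, T_lag_fd=noise_free_params.T_lag_fd,
            omega_tlag=0.0, sigma_add=0.05, sigma_prop=0.0,
        )
        raw = generate_study(p, plasma, dc_replace(small_design, lloq=1e-6),
                             rng=np.random.default_rng(11))
        # keep only quantified rows so the deviance is purely Gaussian
        ds = MicrodialysisDataset(
            raw.df[(raw.df.EVID == 1) | (raw.df.BQL == 0)].reset_index(drop=True)
        )
        assert ds.bql_fraction() == 0.0
        got = neg2ll(p, ds, plasma, BQLMethod("M5"))

        # closed form against the package's own predictions
        pred = DatasetPredictor(ds, plasma)
        md_integ = pred.md_cumint(p.K_pb, p.K_bp_md)
        fd_integ = pred.fd_cumint(p.K_pb, p.K_bp_fd, p.T_lag_fd)
        dev = 0.0
        for sid in pred.subject_ids:
            f = np.concatenate([
                pred.fd_predict_subject(sid, fd_integ),
                pred.md_predict_subject(sid, md_integ),
            ])
            y = np.concatenate([pred.subject_obs(sid, 1)["y"], pred.subject_obs(sid, 2)["y"]])
            dev += np.sum(np.log(2 * np.pi * 0.05**2) + (y - f) ** 2 / 0.05**2)
        assert got == pytest.approx(dev, abs=1e-8)

    def test_laplace_close_to_quadrature_oracle_single_subject(self, plasma, small_design):
        from dataclasses import replace as dc_replace

        # tame toy: moderate combined error, all rows quantified, so the
        # integrand is smooth and near-Gaussian where Laplace is accurate
        truth = BrainModelParams(K_pb=0.32, K_bp_fd=7.31, K_bp_md=4.39, T_lag_fd=2.70,
                                 omega_tlag=0.0380757, sigma_add=0.10, sigma_prop=0.10)
        d = dc_replace(small_design, n_subjects=1, lloq=1e-4)
        raw = generate_study(truth, plasma, d, rng=np.random.default_rng(42))
        ds = MicrodialysisDataset(
            raw.df[(raw.df.EVID == 1) | (raw.df.BQL == 0)].reset_index(drop=True)
        )
        got = neg2ll(truth, ds, plasma, BQLMethod("M5"))

        # oracle: direct numerical integration of the marginal likelihood
        pred = DatasetPredictor(apply_bql_method(ds, BQLMethod("M5")), plasma)
        sid = pred.subject_ids[0]
        f_md = pred.md_predict_subject(sid, pred.md_cumint(truth.K_pb, truth.K_bp_md))
        y = np.concatenate([pred.subject_obs(sid, 1)["y"], pred.subject_obs(sid, 2)["y"]])

        def lik(eta):
            lag = truth.T_lag_fd * np.exp(eta)
            f = np.concatenate([
                pred.fd_predict_subject(sid, pred.fd_cumint(truth.K_pb, truth.K_bp_fd, lag)),
                f_md,
            ])
            sd = np.sqrt(truth.sigma_add**2 + (truth.sigma_prop * f) ** 2)
            return np.prod(stats.norm.pdf(y, f, sd)) * stats.norm.pdf(
                eta, 0.0, np.sqrt(truth.omega_tlag)
            )

        marginal, _ = integrate.quad(lik, -2.0, 2.0, limit=200)
        oracle = -2.0 * np.log(marginal)
        assert got == pytest.approx(oracle, abs=0.1)
        # the explicit quadrature mode should be even closer
        gh = neg2ll(truth, ds, plasma, BQLMethod("M5"), approximation="gh")
        assert gh == pytest.approx(oracle, abs=1e-3)

    def test_combined_error_sd_arithmetic(self):
        assert np.hypot(0.03, 0.35 * 1.0) == pytest.approx(0.3513, abs=5e-5)

    def test_continuity_in_the_no_iiv_limit(self, truth, plasma, prepared):
        p0 = BrainModelParams(K_pb=truth.K_pb, K_bp_fd=truth.K_bp_fd, K_bp_md=truth.K_bp_md,
                              T_lag_fd=truth.T_lag_fd, omega_tlag=0.0,
                              sigma_add=truth.sigma_add, sigma_prop=truth.sigma_prop)
        tiny = BrainModelParams(K_pb=truth.K_pb, K_bp_fd=truth.K_bp_fd, K_bp_md=truth.K_bp_md,
                                T_lag_fd=truth.T_lag_fd, omega_tlag=1e-10,
                                sigma_add=truth.sigma_add, sigma_prop=truth.sigma_prop)
        v0 = neg2ll(p0, prepared, plasma, BQLMethod("M5"))
        v1 = neg2ll(tiny, prepared, plasma, BQLMethod("M5"))
        assert v1 == pytest.approx(v0, abs=1e-3)

    def test_fast_and_per_subject_paths_agree(self, truth, plasma, prepared):
        vf = neg2ll(truth, prepared, plasma, BQLMethod("M5"))
        vs = neg2ll(truth, prepared, plasma, BQLMethod("M5"), fast=False)
        assert vf == pytest.approx(vs, abs=0.05 * len(prepared.ids))


class TestFit:
    def test_noise_free_recovery(self, noise_free_params, plasma, small_design):
        from dataclasses import replace as dc_replace

        ds = generate_study(noise_free_params, plasma,
                            dc_replace(small_design, n_subjects=8),
                            rng=np.random.default_rng(2))
        init = BrainModelParams(K_pb=0.5, K_bp_fd=5.0, K_bp_md=5.0, T_lag_fd=2.0,
                                omega_tlag=0.0, sigma_add=0.01, sigma_prop=0.0)
        res = fit(ds, init, plasma, BQLMethod("M3"),
                  fixed={"omega_tlag": 0.0, "sigma_add": 0.01, "sigma_prop": 0.0},
                  n_starts=1, xtol=1e-7, ftol=1e-12)
        for name in ("K_pb", "K_bp_fd", "K_bp_md", "T_lag_fd"):
            assert res.theta[name] == pytest.approx(getattr(noise_free_params, name), rel=1e-3)
        assert res.ofv <= res.ofv_init

    def test_single_occasion_warns_about_identifiability(self, truth, plasma, small_design):
        ds = generate_study(truth, plasma, small_design, rng=np.random.default_rng(5))
        one_occ = MicrodialysisDataset(ds.df[(ds.df.OCC == 1)].reset_index(drop=True))
        init = truth
        with pytest.warns(UserWarning, match="identifiab"):
            fit(one_occ, init, plasma, BQLMethod("M5"), n_starts=1, maxfev=50,
                compute_diagnostics=False)


class TestBootstrap:
    def test_identical_resample_collapses_to_point_estimate(self, truth, plasma, small_dataset):
        point = fit(small_dataset, truth, plasma, BQLMethod("M5"), n_starts=1,
                    compute_diagnostics=False)
        res = bootstrap(small_dataset, 1, seed=0, init=point.params, plasma=plasma,
                        resamples=[list(small_dataset.ids)])
        for name in ("K_pb", "T_lag_fd"):
            assert res.summary.loc[name, "median"] == pytest.approx(point.theta[name], rel=1e-2)
            assert res.summary.loc[name, "ci_lo"] == res.summary.loc[name, "ci_hi"]

    def test_median_tracks_point_estimate(self, truth, plasma, small_dataset):
        point = fit(small_dataset, truth, plasma, BQLMethod("M5"), n_starts=1,
                    compute_diagnostics=False)
        res = bootstrap(small_dataset, 10, seed=1, init=point.params, plasma=plasma)
        assert res.n_failed <= 2
        assert res.summary.loc["K_pb", "median"] == pytest.approx(point.theta["K_pb"], rel=0.3)


class TestDiagnostics:
    def _fake_fit(self, ebes, omega):
        return FitResult(theta={}, omega=omega, sigma=(0.03, 0.35), ofv=0.0,
                         ebes=pd.Series(ebes), eta_shrinkage=np.nan, eps_shrinkage=np.nan,
                         condition_number=np.nan, condition_number_cov=np.nan,
                         convergence="converged", method="M5")

    def test_all_zero_ebes_give_full_shrinkage(self):
        d = diagnostics(self._fake_fit(np.zeros(10), omega=0.04))
        assert d["eta_shrinkage_pct"] == pytest.approx(100.0)

    def test_ebe_spread_equal_to_omega_gives_zero_shrinkage(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(0, 1, 2000)
        draws = (draws - draws.mean()) / draws.std(ddof=1) * 0.2
        d = diagnostics(self._fake_fit(draws, omega=0.04))
        assert d["eta_shrinkage_pct"] == pytest.approx(0.0, abs=1e-6)

    def test_omega_zero_shrinkage_undefined(self):
        d = diagnostics(self._fake_fit(np.zeros(5), omega=0.0))
        assert np.isnan(d["eta_shrinkage_pct"])

    def test_quadratic_bowl_has_unit_condition_number(self):
        cond_corr, cond_cov = _condition_numbers(lambda x: float(x @ x), np.zeros(3))
        assert cond_corr == pytest.approx(1.0, abs=1e-6)
        assert cond_cov == pytest.approx(1.0, abs=1e-6)

    def test_ofv_drop_utility(self):
        assert ofv_drop_significant(3.85)
        assert not ofv_drop_significant(3.0)


class TestVPC:
    def test_bands_collapse_without_variability(self, noise_free_params, plasma, small_design):
        ds = generate_study(noise_free_params, plasma, small_design,
                            rng=np.random.default_rng(3))
        res = FitResult(
            theta={n: getattr(noise_free_params, n)
                   for n in ("K_pb", "K_bp_fd", "K_bp_md", "T_lag_fd", "T_lag_md")},
            omega=0.0, sigma=(0.0, 0.0), ofv=0.0, ebes=pd.Series(dtype=float),
            eta_shrinkage=np.nan, eps_shrinkage=np.nan, condition_number=np.nan,
            condition_number_cov=np.nan, convergence="converged", method="M5",
        )
        out = vpc(res, ds, n_sim=100, seed=0, plasma=plasma)
        assert (out.table["sim_p5"] == out.table["sim_p95"]).all()
        assert (out.table["sim_p50_lo"] == out.table["sim_p50_hi"]).all()

    def test_self_consistency_under_the_generating_model(self, truth, plasma, small_design):
        from dataclasses import replace as dc_replace

        ds = generate_study(truth, plasma, dc_replace(small_design, n_subjects=10),
                            rng=np.random.default_rng(6))
        res = FitResult(
            theta={n: getattr(truth, n)
                   for n in ("K_pb", "K_bp_fd", "K_bp_md", "T_lag_fd", "T_lag_md")},
            omega=truth.omega_tlag, sigma=(truth.sigma_add, truth.sigma_prop),
            ofv=0.0, ebes=pd.Series(dtype=float), eta_shrinkage=np.nan,
            eps_shrinkage=np.nan, condition_number=np.nan, condition_number_cov=np.nan,
            convergence="converged", method="M5",
        )
        out = vpc(res, ds, n_sim=200, seed=1, plasma=plasma)
        inside = (
            (out.table["obs_p50"] >= out.table["sim_p50_lo"])
            & (out.table["obs_p50"] <= out.table["sim_p50_hi"])
        )
        assert inside.mean() >= 0.9
        # censoring fractions track too
        bql_inside = (
            (out.table["obs_bql_frac"] >= out.table["sim_bql_lo"])
            & (out.table["obs_bql_frac"] <= out.table["sim_bql_hi"])
        )
        assert bql_inside.mean() >= 0.8

    def test_small_nsim_warns(self, truth, plasma, small_dataset):
        res = FitResult(
            theta={n: getattr(truth, n)
                   for n in ("K_pb", "K_bp_fd", "K_bp_md", "T_lag_fd", "T_lag_md")},
            omega=truth.omega_tlag, sigma=(truth.sigma_add, truth.sigma_prop),
            ofv=0.0, ebes=pd.Series(dtype=float), eta_shrinkage=np.nan,
            eps_shrinkage=np.nan, condition_number=np.nan, condition_number_cov=np.nan,
            convergence="converged", method="M5",
        )
        with pytest.warns(UserWarning, match="unstable"):
            vpc(res, small_dataset, n_sim=20, seed=0, plasma=plasma)
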