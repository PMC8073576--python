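"""Dropout-model likelihood, fitting, moderation and contrast inference."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from prxmap.containers import ExperimentDesign, IntensityMatrix
from prxmap.dropout import (
    ModerationPrior,
    ProbabilisticDropoutModel,
    estimate_dropout_curves,
    fit_protein_model,
    missing_loglik,
    moderate_variances,
)
from prxmap.synthetic import (
    DropoutSpec,
    TruthConfig,
    generate_interactome_truth,
    simulate_lfq_experiment,
)


def _quadrature_missing_prob(mu, sigma, rho, zeta):
    """Independent oracle: integrate N(y; mu, sigma^2) Phi((rho - y)/zeta) dy."""
    f = lambda y: norm.pdf(y, mu, sigma) * norm.cdf((rho - y) / zeta)
    val, _ = quad(f, mu - 12 * sigma, mu + 12 * sigma, limit=200)
    return val


def _log2_matrix(values, samples):
    ids = [f"p{i}" for i in range(np.asarray(values).shape[0])]
    return IntensityMatrix(
        pd.DataFrame(np.asarray(values, dtype=float), index=ids, columns=samples),
        scale="log2",
    )


class TestMissingLoglik:
    def test_symmetric_point_is_half(self):
        # mu = rho with vanishing sigma and zeta -> probability 1/2
        assert np.exp(missing_loglik(20.0, 1e-9, 20.0, 1e-9)) == pytest.approx(0.5)

    def test_far_above_curve_is_negligible(self):
        assert np.exp(missing_loglik(30.0, 1.0, 20.0, 1.0)) < 1e-10

    def test_matches_quadrature_at_reference_point(self):
        got = np.exp(missing_loglik(22.0, 1.5, 20.0, 1.0))
        want = _quadrature_missing_prob(22.0, 1.5, 20.0, 1.0)
        assert got == pytest.approx(want, abs=1e-6)

    def test_matches_quadrature_on_parameter_grid(self):
        for mu in (18.0, 20.0, 23.0):
            for sigma in (0.3, 1.0, 2.5):
                for zeta in (0.5, 1.0, 2.0):
                    got = np.exp(missing_loglik(mu, sigma, 20.0, zeta))
                    want = _quadrature_missing_prob(mu, sigma, 20.0, zeta)
                    assert got == pytest.approx(want, abs=1e-6)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            missing_loglik(20.0, -1.0, 20.0, 1.0)


class TestDropoutCurves:
    def test_complete_matrix_uses_fallback(self, two_condition_design):
        rng = np.random.default_rng(0)
        m = _log2_matrix(rng.normal(25, 2, (50, 6)), two_condition_design.sample_ids)
        curves = estimate_dropout_curves(m, two_condition_design)
        assert curves["fallback"].all()
        for sid in m.sample_ids:
            assert curves.loc[sid, "rho"] == pytest.approx(
                np.quantile(m.values[sid], 0.10)
            )
            assert curves.loc[sid, "zeta"] == 1.0

    def test_recovers_generating_curve(self, two_condition_design):
        """rho/zeta estimates track the generating curve; the proxy-set
        mean carries a small upward selection bias (only observed edge
        values enter), measured at ~ +0.5*zeta."""
        cfg = TruthConfig(
            seed=9, n_background=2000, n_interactors=0, n_reverse_decoys=0,
            n_contaminants=0, baseline_mean=22.0, low_peptide_fraction=0.0,
        )
        truths = generate_interactome_truth(cfg)
        mat, _ = simulate_lfq_experiment(
            truths, two_condition_design, DropoutSpec(rho=20.0, zeta=1.0),
            noise_sd=0.5, seed=9,
        )
        curves = estimate_dropout_curves(mat, two_condition_design)
        assert not curves["fallback"].any()
        assert (curves["rho"] - 20.0).abs().max() <= 0.8
        assert (curves["zeta"] - 1.0).abs().max() <= 0.3

    def test_all_missing_sample_named_in_error(self, two_condition_design):
        vals = np.random.default_rng(1).normal(25, 2, (20, 6))
        vals[:, 2] = np.nan
        m = _log2_matrix(vals, two_condition_design.sample_ids)
        with pytest.raises(ValueError, match="PRDX1_WT_3"):
            estimate_dropout_curves(m, two_condition_design)


def _curves(sample_ids, rho=20.0, zeta=1.0):
    return pd.DataFrame(
        {"rho": rho, "zeta": zeta, "fallback": False, "n_proxy": 100},
        index=pd.Index(sample_ids, name="sample_id"),
    )


class TestProteinFit:
    def test_fully_observed_far_above_curve_gives_arithmetic_means(
        self, two_condition_design
    ):
        sids = two_condition_design.sample_ids
        y = pd.Series([30.0, 30.5, 29.8, 28.0, 28.4, 27.9], index=sids, name="p0")
        res = fit_protein_model(y, two_condition_design, _curves(sids))
        assert res.mu.loc["p0", "PRDX1:WT"] == pytest.approx(
            np.mean([30.0, 30.5, 29.8]), abs=1e-3
        )
        assert res.mu.loc["p0", "PRDX1:CPRS"] == pytest.approx(
            np.mean([28.0, 28.4, 27.9]), abs=1e-3
        )

    def test_all_missing_condition_mean_bounded_and_sign_contract(
        self, two_condition_design
    ):
        sids = two_condition_design.sample_ids
        y = pd.Series(
            [28.0, 28.5, 27.8, np.nan, np.nan, np.nan], index=sids, name="p0"
        )
        curves = _curves(sids, rho=22.0, zeta=1.0)
        res = fit_protein_model(y, two_condition_design, curves)
        mu_miss = res.mu.loc["p0", "PRDX1:CPRS"]
        assert np.isfinite(mu_miss)
        assert mu_miss <= 22.0 + 1.0
        contrast = res.contrast("PRDX1:WT", "PRDX1:CPRS")
        assert contrast.loc["p0", "delta"] > 0

    def test_translation_equivariance_without_dropout(self, two_condition_design):
        """Shifting one condition's data by +k shifts its mean by +k when
        the dropout curve is far below all values."""
        sids = two_condition_design.sample_ids
        rng = np.random.default_rng(3)
        base = rng.normal(30, 0.5, (10, 6))
        shifted = base.copy()
        shifted[:, :3] += 2.5
        curves = _curves(sids, rho=5.0)
        r0 = ProbabilisticDropoutModel(
            _log2_matrix(base, sids), two_condition_design, curves=curves
        ).fit()
        r1 = ProbabilisticDropoutModel(
            _log2_matrix(shifted, sids), two_condition_design, curves=curves
        ).fit()
        np.testing.assert_allclose(
            r1.mu["PRDX1:WT"].to_numpy(),
            r0.mu["PRDX1:WT"].to_numpy() + 2.5,
            atol=1e-6,
        )
        np.testing.assert_allclose(
            r1.mu["PRDX1:CPRS"].to_numpy(), r0.mu["PRDX1:CPRS"].to_numpy(), atol=1e-6
        )

    def test_optimum_dominates_grid_search(self, null_experiment, two_condition_design):
        """Fitted (mu, sigma) beat a grid search of the identical joint
        likelihood, recomputed from scratch, on 30 random proteins."""
        _, mat, _ = null_experiment
        res = ProbabilisticDropoutModel(mat, two_condition_design).fit(moderate=False)
        rng = np.random.default_rng(0)
        ids = rng.choice(mat.protein_ids, size=30, replace=False)
        curves = res.model.curves
        rho = curves["rho"].to_numpy()
        zeta = curves["zeta"].to_numpy()
        labels = two_condition_design.condition_labels.to_numpy()
        conditions = list(res.mu.columns)
        lo, hi = res.mu_bounds
        mu_grid = np.linspace(lo, hi, 200)
        sigma_grid = np.linspace(0.05, 10.0, 50)
        for pid in ids:
            y = mat.values.loc[pid].to_numpy()
            best = -np.inf
            for sigma in sigma_grid:
                total = _oracle_loglik_best_mu(
                    y, labels, conditions, rho, zeta, mu_grid, sigma, res
                )
                best = max(best, total)
            assert res.objective.loc[pid] >= best - 1e-6

    def test_self_contrast_rejected(self, null_experiment, two_condition_design):
        _, mat, _ = null_experiment
        res = ProbabilisticDropoutModel(mat, two_condition_design).fit()
        with pytest.raises(ValueError):
            res.contrast("PRDX1:WT", "PRDX1:WT")

    def test_identical_replicates_give_null_contrast(self, two_condition_design):
        sids = two_condition_design.sample_ids
        vals = np.tile([27.0, 27.5, 26.5, 27.0, 27.5, 26.5], (12, 1))
        vals += np.random.default_rng(0).normal(0, 0.3, (12, 1))  # per-protein offset
        m = _log2_matrix(vals, sids)
        res = ProbabilisticDropoutModel(m, two_condition_design, curves=_curves(sids, rho=5.0)).fit()
        c = res.contrast("PRDX1:WT", "PRDX1:CPRS")
        assert c["delta"].abs().max() < 1e-8
        assert (c["p"] > 0.99).all()

    def test_delta_antisymmetry(self, null_experiment, two_condition_design):
        _, mat, _ = null_experiment
        res = ProbabilisticDropoutModel(mat, two_condition_design).fit()
        ab = res.contrast("PRDX1:WT", "PRDX1:CPRS")
        ba = res.contrast("PRDX1:CPRS", "PRDX1:WT")
        np.testing.assert_allclose(
            ab["delta"].to_numpy(), -ba["delta"].to_numpy(), atol=1e-9
        )


def _oracle_loglik_best_mu(y, labels, conditions, rho, zeta, mu_grid, sigma, res):
    """Literal transcription of the joint likelihood, maximized over the
    mu grid independently per condition (valid because conditions only
    share sigma).  Pinned all-missing conditions stay at their anchor."""
    obs = ~np.isnan(y)
    total = 0.0
    for cond in conditions:
        cols = labels == cond
        yo = y[cols & obs]
        rho_c, zeta_c = rho[cols], zeta[cols]
        miss_rho = rho[cols & ~obs]
        miss_zeta = zeta[cols & ~obs]
        if len(yo) == 0:
            mu_options = np.array([(rho_c - zeta_c).mean()])
        else:
            mu_options = mu_grid
        ll = norm.logpdf(yo[None, :], mu_options[:, None], sigma).sum(axis=1)
        ll += np.sum(norm.logsf((rho[cols & obs] - yo) / zeta[cols & obs]))
        s = np.sqrt(miss_zeta**2 + sigma**2)
        ll += norm.logcdf((miss_rho[None, :] - mu_options[:, None]) / s[None, :]).sum(
            axis=1
        )
        total += ll.max()
    return total


class TestModeration:
    def test_identical_variances_collapse_to_prior(self):
        s2 = np.full(50, 0.49)
        prior, post = moderate_variances(s2, np.full(50, 4.0))
        assert np.isinf(prior.d0)
        np.testing.assert_allclose(post, 0.49, rtol=1e-9)

    def test_recovers_scaled_inverse_chisq_parameters(self):
        rng = np.random.default_rng(5)
        d0, s0sq, n = 4.0, 0.25, 2000
        s2 = s0sq * d0 / rng.chisquare(d0, n)
        prior, _ = moderate_variances(s2, np.full(n, np.inf))
        assert abs(prior.d0 - d0) <= 1.5
        assert abs(prior.s0_sq - s0sq) / s0sq <= 0.20

    def test_recovery_with_finite_sampling_df(self):
        rng = np.random.default_rng(6)
        d0, s0sq, n, df = 4.0, 0.25, 2000, 4
        sigma2 = s0sq * d0 / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(df, n) / df
        prior, _ = moderate_variances(s2, np.full(n, float(df)))
        assert abs(prior.d0 - d0) <= 1.5
        assert abs(prior.s0_sq - s0sq) / s0sq <= 0.20

    def test_single_protein_skips_moderation(self):
        prior, post = moderate_variances(np.array([0.5]), np.array([4.0]))
        assert np.isinf(prior.d0)
        np.testing.assert_allclose(post, 0.5)

    def test_posterior_interpolates_between_prior_and_estimate(self):
        prior = ModerationPrior(d0=4.0, s0_sq=0.25)
        post = prior.posterior_var(np.array([1.0]), np.array([4.0]))
        assert post[0] == pytest.approx((4 * 0.25 + 4 * 1.0) / 8)


class TestStatisticalCalibration:
    def test_type_one_error_on_pure_null(self, null_experiment, two_condition_design):
        """Fraction of raw p < 0.05 on null data stays within [0.03, 0.07]."""
        _, mat, _ = null_experiment
        res = ProbabilisticDropoutModel(mat, two_condition_design).fit()
        c = res.contrast("PRDX1:WT", "PRDX1:CPRS")
        frac = float((c["p"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_planted_effect_recovery(self, two_condition_design):
        """Mean estimated delta on 100 planted log2FC=3 proteins is close
        to the truth despite 34% dropout.  Proteins never observed in the
        depleted condition are censored at the detection limit, so their
        fold change is attenuated by construction; the unbiasedness claim
        applies to proteins with at least one observation on both sides."""
        cfg = TruthConfig(
            seed=21, n_background=500, n_interactors=100, effect_size=3.0,
            frac_cys_dependent=1.0, mechanism_mix={"SOH": 0.0, "SS": 1.0},
            frac_isoform_specific=1.0, isoforms=["PRDX1"],
            n_reverse_decoys=0, n_contaminants=0, low_peptide_fraction=0.0,
        )
        truths = generate_interactome_truth(cfg)
        mat, _ = simulate_lfq_experiment(
            truths, two_condition_design,
            DropoutSpec(target_missing_fraction=0.34), noise_sd=0.5, seed=21,
        )
        res = ProbabilisticDropoutModel(mat, two_condition_design).fit()
        c = res.contrast("PRDX1:WT", "PRDX1:CPRS")
        planted = [t.protein_id for t in truths if t.binds_isoforms]
        sub = c.loc[planted]
        both_sides = sub[(sub["n_obs_a"] > 0) & (sub["n_obs_b"] > 0)]
        assert len(both_sides) > 50
        assert both_sides["delta"].mean() == pytest.approx(3.0, abs=0.3)
        # detection-limit censoring pulls the unconditional mean down a bit
        assert sub["delta"].mean() == pytest.approx(3.0, abs=0.5)
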