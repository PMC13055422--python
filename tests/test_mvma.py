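"""Bayesian multivariate model: covariance builders, samplers, summaries."""

import numpy as np
import pandas as pd
import pytest

from mvmeta_mf import (
    EffectEstimate,
    EffectTable,
    FactorDef,
    MvmaConfig,
    StudyRecord,
    build_within_covariance,
    builtin_table1,
    convergence_report,
    exponentiate_summary,
    fit_mvma,
    model_u_as_univariate,
    posterior_correlation,
    simulate_table,
    SimParams,
)
from mvmeta_mf.mvma import _summarize, trace_series


def _study(**cells):
    return StudyRecord("s1", "s1", {k: EffectEstimate(*v) for k, v in cells.items()})


def _fake_fit(mu_draws, tau_draws=None, variant="U"):
    """Assemble a PosteriorSummary from explicit draw arrays (chain, kept, J)."""
    mu_draws = np.asarray(mu_draws, dtype=float)
    if tau_draws is None:
        tau_draws = np.full_like(mu_draws, 0.5)
    J = mu_draws.shape[2]
    cfg = MvmaConfig(variant=variant, burn_in=10, draws=mu_draws.shape[1])
    fids = [f"f{j}" for j in range(J)]
    return _summarize(fids, mu_draws, np.asarray(tau_draws), None, None, cfg,
                      variant, 0.0, "fabricated")


class TestWithinCovariance:
    def test_m0_and_u_are_diagonal(self):
        s = _study(a=(0.1, 0.2), b=(0.2, 0.3))
        for variant in ("M0", "U"):
            S = build_within_covariance(s, variant, rho_w=0.7)  # rho ignored
            assert np.allclose(S.to_numpy(), np.diag([0.04, 0.09]))

    def test_h_with_zero_rho_reduces_to_m0(self):
        s = _study(a=(0.1, 0.2), b=(0.2, 0.3), c=(0.0, 0.5))
        SH = build_within_covariance(s, "H", rho_w=0.0)
        SM = build_within_covariance(s, "M0")
        pd.testing.assert_frame_equal(SH, SM)

    def test_h_off_diagonal(self):
        s = _study(a=(0.1, 0.2), b=(0.2, 0.3))
        S = build_within_covariance(s, "H", rho_w=0.5)
        assert S.loc["a", "b"] == pytest.approx(0.03)
        assert np.all(np.linalg.eigvalsh(S.to_numpy()) > 0)

    def test_invalid_rho_rejected(self):
        s = _study(a=(0.1, 0.2), b=(0.2, 0.3))
        with pytest.raises(ValueError):
            build_within_covariance(s, "H", rho_w=1.0)


class TestConfig:
    def test_defaults_pin_published_protocol(self):
        cfg = MvmaConfig()
        assert (cfg.chains, cfg.burn_in, cfg.draws) == (3, 100_000, 100_000)

    @pytest.mark.parametrize(
        "kw",
        [
            {"variant": "X"},
            {"chains": 1},
            {"burn_in": 0},
            {"thin": 0},
            {"prior_tau_upper": -1.0},
            {"fix_rho_w": 1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            MvmaConfig(**kw)


class TestFitPreconditions:
    def test_empty_table_rejected(self, fast_cfg):
        t = EffectTable(studies=[], factors=[])
        with pytest.raises(ValueError):
            fit_mvma(t, fast_cfg)

    def test_singleton_factor_requires_filter(self, fast_cfg):
        t = EffectTable(
            studies=[_study(a=(0.5, 0.2))],
            factors=[FactorDef("a", "A", "yes vs no")],
        )
        with pytest.raises(ValueError, match="filter_factors_min_studies"):
            fit_mvma(t, fast_cfg)


class TestConjugateOracle:
    """Single factor, tau fixed at 0: the posterior is available in closed
    form (precision-weighted normal), so the samplers can be checked
    against exact moments."""

    y, s, sd0 = 0.5, 0.2, 1.0

    @property
    def _truth(self):
        prec = 1 / self.s**2 + 1 / self.sd0**2
        return (1 / self.s**2) * self.y / prec, np.sqrt(1 / prec)

    def _table(self):
        return EffectTable(
            studies=[_study(a=(self.y, self.s))],
            factors=[FactorDef("a", "A", "yes vs no")],
        )

    def test_joint_engine_matches_closed_form(self):
        cfg = MvmaConfig(variant="U", prior_mu_sd=self.sd0, fix_tau=0.0,
                         burn_in=100, draws=20_000, thin=1, seed=5)
        fit = fit_mvma(self._table(), cfg)
        mean_true, sd_true = self._truth
        mu = fit.draws["mu"][:, :, 0]
        assert mu.mean() == pytest.approx(mean_true, abs=4 * sd_true / np.sqrt(mu.size))
        assert mu.std() == pytest.approx(sd_true, rel=0.03)

    def test_univariate_engine_matches_closed_form(self):
        cfg = MvmaConfig(variant="U", prior_mu_sd=self.sd0, fix_tau=0.0,
                         burn_in=100, draws=20_000, thin=1, seed=6)
        fit = model_u_as_univariate(self._table(), cfg)
        mean_true, sd_true = self._truth
        mu = fit.draws["mu"][:, :, 0]
        assert mu.mean() == pytest.approx(mean_true, abs=4 * sd_true / np.sqrt(mu.size))
        assert mu.std() == pytest.approx(sd_true, rel=0.03)


def _dense_table(seed=42, n=10, J=2):
    params = SimParams(
        n_studies=n,
        factor_defs=tuple(FactorDef(f"f{j}", f"f{j}", "yes vs no") for j in range(J)),
        mu_true=(0.4, -0.2)[:J],
        tau_true=(0.3,) * J,
        se_range=(0.15, 0.4),
        report_prob=1.0,
        seed=seed,
    )
    return simulate_table(params)[0]


class TestReductionChain:
    """H with rho_W pinned at 0 is M0; M0 with R_B pinned to the identity
    is U.  Posterior medians agree within Monte Carlo error."""

    def _medians(self, fit):
        return fit.summary["median"].to_numpy()

    def test_h_rho0_equals_m0(self, fast_cfg):
        from dataclasses import replace

        t = _dense_table()
        h = fit_mvma(t, replace(fast_cfg, variant="H", fix_rho_w=0.0, seed=21))
        m0 = fit_mvma(t, replace(fast_cfg, variant="M0", seed=22))
        assert np.allclose(self._medians(h), self._medians(m0), atol=0.08)

    def test_m0_identity_equals_u(self, fast_cfg):
        from dataclasses import replace

        t = _dense_table()
        m0i = fit_mvma(
            t, replace(fast_cfg, variant="M0", fix_between_identity=True, seed=23)
        )
        u = fit_mvma(t, replace(fast_cfg, variant="U", seed=24))
        assert np.allclose(self._medians(m0i), self._medians(u), atol=0.08)


class TestCrossEngineAgreement:
    def test_model_u_as_univariate_matches_joint_engine(self, table1):
        """The structural definition of Model U: the independent numpy
        engine and the joint MWG engine agree within Monte Carlo error."""
        cfg = MvmaConfig(variant="U", burn_in=4000, draws=4000, thin=1, seed=31)
        joint = fit_mvma(table1, cfg)
        sep = model_u_as_univariate(table1, MvmaConfig(
            variant="U", burn_in=4000, draws=4000, thin=1, seed=32))
        for fid in table1.factor_ids:
            width = joint.cri95(fid)[1] - joint.cri95(fid)[0]
            tol = max(0.06, 0.03 * width)
            assert joint.median(fid) == pytest.approx(sep.median(fid), abs=tol), fid


class TestDeterminism:
    def test_same_seed_same_summaries(self, table1, fast_cfg):
        from dataclasses import replace

        cfg = replace(fast_cfg, variant="M0", seed=77)
        f1 = fit_mvma(table1, cfg)
        f2 = fit_mvma(table1, cfg)
        pd.testing.assert_frame_equal(f1.summary, f2.summary)
        pd.testing.assert_frame_equal(f1.correlation, f2.correlation)

    def test_different_seed_different_draws(self, table1, fast_cfg):
        from dataclasses import replace

        f1 = fit_mvma(table1, replace(fast_cfg, seed=1))
        f2 = fit_mvma(table1, replace(fast_cfg, seed=2))
        assert not np.array_equal(f1.draws["mu"], f2.draws["mu"])


class TestPosteriorCorrelation:
    def test_u_variant_is_an_error(self, table1, fast_cfg):
        fit = fit_mvma(table1, fast_cfg)
        with pytest.raises(ValueError, match="identity"):
            posterior_correlation(fit)

    def test_symmetric_unit_diagonal(self, fast_cfg):
        from dataclasses import replace

        t = _dense_table()
        fit = fit_mvma(t, replace(fast_cfg, variant="M0", seed=9))
        R = posterior_correlation(fit).to_numpy()
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)
        assert np.all(np.abs(R) <= 1.0)

    def test_recovers_sign_of_strong_positive_correlation(self):
        params = SimParams(
            n_studies=25,
            factor_defs=(
                FactorDef("f0", "f0", "yes vs no"),
                FactorDef("f1", "f1", "yes vs no"),
            ),
            mu_true=(0.0, 0.0),
            tau_true=(0.6, 0.6),
            R_B_true=((1.0, 0.8), (0.8, 1.0)),
            se_range=(0.1, 0.25),
            report_prob=1.0,
            seed=15,
        )
        t, truth = simulate_table(params)
        cfg = MvmaConfig(variant="M0", burn_in=3000, draws=3000, thin=1, seed=16)
        fit = fit_mvma(t, cfg)
        assert posterior_correlation(fit).loc["f0", "f1"] > 0.2


class TestConvergenceDiagnostics:
    def test_well_mixed_chains_pass(self):
        rng = np.random.default_rng(0)
        mu = rng.normal(0.0, 1.0, size=(3, 2000, 1))
        tau = np.abs(rng.normal(1.0, 0.2, size=(3, 2000, 1)))
        fit = _fake_fit(mu, tau)
        rep = convergence_report(fit)
        assert (rep.dropna()["rhat"] < 1.01).all()
        assert fit.converged

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(1)
        mu = rng.normal(0.0, 0.1, size=(3, 1000, 1))
        mu[0] += 10.0  # one chain stuck in a different region
        fit = _fake_fit(mu)
        assert float(fit.diagnostics.loc["mu[f0]", "rhat"]) > 1.5
        assert not fit.converged

    def test_fixture_fit_converges_at_moderate_protocol(self, table1):
        cfg = MvmaConfig(variant="U", burn_in=10_000, draws=10_000, thin=2, seed=3)
        fit = fit_mvma(table1, cfg)
        assert fit.converged
        rep = convergence_report(fit)
        assert (rep.dropna()["ess"] > 400).all()


class TestExponentiation:
    @pytest.mark.parametrize(
        "median,expect", [(0.36, 1.43), (0.0, 1.00), (0.05, 1.05)]
    )
    def test_point_values(self, median, expect):
        fit = _fake_fit(np.full((2, 100, 1), median) + 0.0)
        est = exponentiate_summary(fit, "f0")
        assert round(est.or_point, 2) == expect

    def test_quantile_monotonicity(self, table1, fast_cfg):
        fit = fit_mvma(table1, fast_cfg)
        for fid in table1.factor_ids:
            est = exponentiate_summary(fit, fid)
            assert est.or_ci95[0] < est.or_point < est.or_ci95[1]
            assert est.or_ci95[0] == pytest.approx(np.exp(fit.cri95(fid)[0]))

    def test_unknown_factor(self, table1, fast_cfg):
        fit = fit_mvma(table1, fast_cfg)
        with pytest.raises(KeyError):
            exponentiate_summary(fit, "nope")


class TestTraceSeries:
    def test_shapes_and_errors(self, table1, fast_cfg):
        fit = fit_mvma(table1, fast_cfg)
        tr = trace_series(fit, "mu[aci]")
        assert tr.shape == (fast_cfg.draws // fast_cfg.thin, fast_cfg.chains)
        with pytest.raises(KeyError):
            trace_series(fit, "mu[nope]")
        with pytest.raises(KeyError):
            trace_series(fit, "rho_w")  # not a Model H fit
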