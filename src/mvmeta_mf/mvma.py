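"""Bayesian multivariate meta-analysis of multiple factors (Models H/M0/U).

Three nested variants of one hierarchical multivariate-normal model are
offered, differing only in which correlations they admit:

* **Model H** — within-study sampling errors share a common correlation
  :math:`\\rho_W` and the study-level true effects are correlated across
  factors through a between-study correlation matrix :math:`R_B`;
* **Model M0** — within-study errors independent (:math:`\\rho_W = 0`),
  between-study correlations retained;
* **Model U** — all correlations off: each factor is an independent
  univariate normal-normal random-effects model.

Priors (configurable): :math:`\\mu_j \\sim \\mathrm{N}(0, 10^2)`,
:math:`\\tau_j \\sim \\mathrm{U}(0, 5)`, :math:`\\rho_W \\sim
\\mathrm{U}(-1, 1)` restricted to values keeping every within-study
covariance positive definite, and a flat prior over positive-definite
correlation matrices for :math:`R_B`.  Missing cells are handled by the
observed-subvector marginal likelihood, so no imputation is involved.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .effect_table import EffectTable, StudyRecord

__all__ = [
    "MvmaConfig",
    "PosteriorSummary",
    "OrEstimate",
    "full_profile",
    "test_profile",
    "build_within_covariance",
    "fit_mvma",
    "model_u_as_univariate",
    "posterior_correlation",
    "convergence_report",
    "exponentiate_summary",
]

VARIANTS = ("H", "M0", "U")


@dataclass(frozen=True)
class MvmaConfig:
    """Model variant, priors and MCMC protocol.

    The default protocol is the published one: 3 chains of 100 000
    retained updates after 100 000 burn-in each.  ``thin`` only controls
    which retained draws are stored (memory), not the kernel itself.

    The ``fix_*`` fields pin a parameter instead of sampling it; they
    exist for degenerate-limit checks and for the reduction chain
    H(rho_W=0) == M0, M0(R_B=I) == U.
    """

    variant: str = "U"
    prior_mu_sd: float = 10.0
    prior_tau_upper: float = 5.0
    chains: int = 3
    burn_in: int = 100_000
    draws: int = 100_000
    thin: int = 10
    seed: int = 0
    fix_tau: float | None = None
    fix_rho_w: float | None = None
    fix_between_identity: bool = False
    rhat_threshold: float = 1.01
    ess_threshold: float = 400.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required")
        if self.burn_in <= 0 or self.draws <= 0:
            raise ValueError("burn_in and draws must be positive")
        if self.thin < 1 or self.thin > self.draws:
            raise ValueError("thin must be in [1, draws]")
        if self.prior_mu_sd <= 0 or self.prior_tau_upper <= 0:
            raise ValueError("prior bounds must be positive")
        if self.fix_rho_w is not None and not (-1.0 < self.fix_rho_w < 1.0):
            raise ValueError("fix_rho_w must lie in (-1, 1)")
        if self.fix_tau is not None and self.fix_tau < 0:
            raise ValueError("fix_tau must be >= 0")


def full_profile(variant: str = "U", seed: int = 0, **kw) -> MvmaConfig:
    """The published protocol: 3 chains x 100k draws after 100k burn-in."""
    return MvmaConfig(variant=variant, seed=seed, **kw)


def test_profile(variant: str = "U", seed: int = 0, **kw) -> MvmaConfig:
    """A short protocol (3 x 2000/2000) for unit tests and simulations."""
    kw.setdefault("burn_in", 2000)
    kw.setdefault("draws", 2000)
    kw.setdefault("thin", 1)
    return MvmaConfig(variant=variant, seed=seed, **kw)


@dataclass(frozen=True)
class OrEstimate:
    """An exponentiated posterior summary (odds-ratio scale)."""

    factor_id: str
    variant: str
    or_point: float
    or_ci95: tuple[float, float]
    log_or_median: float
    log_or_ci95: tuple[float, float]


@dataclass
class PosteriorSummary:
    """Posterior summaries, diagnostics and stored draws for one fit.

    ``summary`` has one row per factor with the posterior median of the
    overall log OR, its 95% credible interval (2.5th/97.5th percentiles),
    the posterior median between-study SD, and split-chain Rhat / bulk
    effective sample size for the overall effect.  ``correlation`` is the
    posterior mean between-study correlation matrix (Models H/M0 only).
    """

    variant: str
    config: MvmaConfig
    summary: pd.DataFrame
    correlation: pd.DataFrame | None
    rho_w_summary: dict | None
    draws: Mapping[str, np.ndarray]
    diagnostics: pd.DataFrame
    converged: bool
    runtime_s: float
    engine: str = "mwg-numba"

    def median(self, factor_id: str) -> float:
        return float(self.summary.loc[factor_id, "median"])

    def cri95(self, factor_id: str) -> tuple[float, float]:
        row = self.summary.loc[factor_id]
        return (float(row["cri_lo"]), float(row["cri_hi"]))


def build_within_covariance(
    study: StudyRecord, variant: str, rho_w: float = 0.0
) -> pd.DataFrame:
    """Within-study sampling covariance over the study's observed factors.

    Diagonal entries are the squared SEs; under Model H the off-diagonals
    are ``rho_w * s_j * s_k``; Models M0 and U are diagonal.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    if not (-1.0 < rho_w < 1.0):
        raise ValueError(f"|rho_w| must be < 1 for positive definiteness, got {rho_w}")
    fids = list(study.estimates)
    s = np.array([study.estimates[f].se for f in fids])
    if variant == "H":
        S = rho_w * np.outer(s, s)
        np.fill_diagonal(S, s**2)
    else:
        S = np.diag(s**2)
    return pd.DataFrame(S, index=fids, columns=fids)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _check_table(table: EffectTable, config: MvmaConfig) -> None:
    if table.n_studies == 0 or table.n_factors == 0:
        raise ValueError("cannot fit an empty effect table")
    if config.fix_tau is None:
        counts = table.mask.sum(axis=0)
        thin_factors = [f for f in table.factor_ids if counts[f] < 2]
        if thin_factors:
            raise ValueError(
                "between-study SDs are unidentifiable for factors reported by "
                f"fewer than 2 studies: {thin_factors}; apply "
                "filter_factors_min_studies(table, 2) first (or fix tau)"
            )


def _rhat_ess(arr: np.ndarray) -> tuple[float, float]:
    """Split-chain rank-normalized Rhat and bulk ESS for (chain, draw)."""
    import arviz as az

    if np.allclose(arr.std(), 0.0):
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(arr)), float(az.ess(arr))


def _diagnose(
    draw_map: dict[str, np.ndarray], config: MvmaConfig
) -> tuple[pd.DataFrame, bool]:
    rows = []
    for name, arr in draw_map.items():
        rhat, ess = _rhat_ess(arr)
        rows.append({"parameter": name, "rhat": rhat, "ess": ess})
    diag = pd.DataFrame(rows).set_index("parameter")
    checked = diag.dropna()
    converged = bool(
        (checked["rhat"] < config.rhat_threshold).all()
        and (checked["ess"] > config.ess_threshold).all()
    )
    return diag, converged


def _summarize(
    factor_ids: list[str],
    mu: np.ndarray,
    tau: np.ndarray,
    rho: np.ndarray | None,
    R_mean: np.ndarray | None,
    config: MvmaConfig,
    variant: str,
    runtime_s: float,
    engine: str,
) -> PosteriorSummary:
    """Assemble a PosteriorSummary from draw arrays (chain, kept, J)."""
    J = len(factor_ids)
    rows = []
    draw_map: dict[str, np.ndarray] = {}
    for j, fid in enumerate(factor_ids):
        mj = mu[:, :, j]
        tj = tau[:, :, j]
        rhat, ess = _rhat_ess(mj)
        rows.append(
            {
                "factor": fid,
                "median": float(np.median(mj)),
                "cri_lo": float(np.percentile(mj, 2.5)),
                "cri_hi": float(np.percentile(mj, 97.5)),
                "tau_median": float(np.median(tj)),
                "rhat": rhat,
                "ess": ess,
            }
        )
        draw_map[f"mu[{fid}]"] = mj
        draw_map[f"tau[{fid}]"] = tj
    if rho is not None:
        draw_map["rho_w"] = rho
    summary = pd.DataFrame(rows).set_index("factor")
    diagnostics, converged = _diagnose(draw_map, config)
    correlation = None
    if R_mean is not None:
        correlation = pd.DataFrame(R_mean, index=factor_ids, columns=factor_ids)
    rho_summary = None
    if rho is not None:
        rho_summary = {
            "median": float(np.median(rho)),
            "cri_lo": float(np.percentile(rho, 2.5)),
            "cri_hi": float(np.percentile(rho, 97.5)),
        }
    draws = {"mu": mu, "tau": tau}
    if rho is not None:
        draws["rho_w"] = rho
    fit = PosteriorSummary(
        variant=variant,
        config=config,
        summary=summary,
        correlation=correlation,
        rho_w_summary=rho_summary,
        draws=draws,
        diagnostics=diagnostics,
        converged=converged,
        runtime_s=runtime_s,
        engine=engine,
    )
    if not converged:
        warnings.warn(
            f"Model {variant} fit did not meet the convergence gate "
            f"(Rhat < {config.rhat_threshold}, ESS > {config.ess_threshold}); "
            "inspect fit.diagnostics before use",
            stacklevel=3,
        )
    return fit


def fit_mvma(table: EffectTable, config: MvmaConfig) -> PosteriorSummary:
    """Fit the configured model variant to an effect table by MCMC.

    The likelihood uses each study's observed subvector only.  Chains are
    run sequentially with seeds derived from ``config.seed``; results are
    reproducible for a fixed seed, protocol and package version.
    """
    from .mcmc import prepare_study_data, run_mwg_chain

    _check_table(table, config)
    t0 = time.perf_counter()
    variant = config.variant
    y = table.log_or.to_numpy()
    se = table.se.to_numpy()
    data = prepare_study_data(y, se)
    J = data["J"]

    sample_corr = variant in ("H", "M0") and not config.fix_between_identity and J > 1
    sample_rho = variant == "H" and config.fix_rho_w is None
    rho_fixed = 0.0
    if variant == "H" and config.fix_rho_w is not None:
        rho_fixed = float(config.fix_rho_w)
    sample_tau = config.fix_tau is None

    kept = config.draws // config.thin
    C = config.chains
    mu_keep = np.zeros((C, kept, J))
    tau_keep = np.zeros((C, kept, J))
    rho_keep = np.zeros((C, kept))
    R_sum = np.zeros((J, J))
    acc_out = np.zeros(1)

    ss = np.random.SeedSequence(config.seed)
    chain_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(C)]
    for c in range(C):
        rng = np.random.default_rng(chain_seeds[c])
        mu_init = rng.normal(0.0, 1.0, size=J)
        if config.fix_tau is None:
            hi = min(1.5, config.prior_tau_upper * 0.9)
            tau_init = rng.uniform(min(0.2, hi / 2), hi, size=J)
        else:
            tau_init = np.full(J, float(config.fix_tau))
        run_mwg_chain(
            chain_seeds[c],
            config.burn_in,
            config.draws,
            config.thin,
            J,
            data["n_stud"],
            data["obs_ptr"],
            data["obs_idx"],
            data["y_all"],
            data["s_all"],
            config.prior_mu_sd,
            config.prior_tau_upper,
            sample_tau,
            sample_rho,
            rho_fixed,
            sample_corr,
            data["pair_j"],
            data["pair_k"],
            data["pair_ptr"],
            data["pair_stud"],
            data["fac_ptr"],
            data["fac_stud"],
            data["multi_stud"],
            mu_init,
            tau_init,
            mu_keep[c],
            tau_keep[c],
            rho_keep[c],
            R_sum,
            acc_out,
        )
    R_mean = R_sum / (C * kept) if sample_corr else None
    rho = rho_keep if variant == "H" else None
    return _summarize(
        table.factor_ids,
        mu_keep,
        tau_keep,
        rho,
        R_mean,
        config,
        variant,
        time.perf_counter() - t0,
        engine="mwg-numba",
    )


def model_u_as_univariate(table: EffectTable, config: MvmaConfig) -> PosteriorSummary:
    """Fit each factor independently (the structural definition of Model U).

    Runs the vectorized numpy normal-normal sampler — a code path fully
    independent of the joint Metropolis-within-Gibbs engine — and must
    agree with ``fit_mvma(variant='U')`` within Monte Carlo error.
    """
    from .mcmc import sample_univariate

    config = replace(config, variant="U")
    _check_table(table, config)
    t0 = time.perf_counter()
    out = sample_univariate(
        table.log_or.to_numpy(),
        table.se.to_numpy(),
        chains=config.chains,
        burn_in=config.burn_in,
        draws=config.draws,
        thin=config.thin,
        seed=config.seed,
        prior_mu_sd=config.prior_mu_sd,
        tau_upper=config.prior_tau_upper,
        fix_tau=config.fix_tau,
    )
    return _summarize(
        table.factor_ids,
        out["mu"],
        out["tau"],
        None,
        None,
        config,
        "U",
        time.perf_counter() - t0,
        engine="univariate-numpy",
    )


def posterior_correlation(fit: PosteriorSummary, variant: str | None = None) -> pd.DataFrame:
    """Posterior mean between-study correlation matrix (Models H and M0).

    For Model U the matrix is the identity by construction, so requesting
    it is an error rather than a trivial answer.
    """
    variant = variant or fit.variant
    if variant == "U" or fit.correlation is None:
        raise ValueError(
            "between-study correlations are fixed to the identity under "
            "Model U (or this fit pinned R_B); no posterior correlation exists"
        )
    return fit.correlation.copy()


def convergence_report(fit: PosteriorSummary) -> pd.DataFrame:
    """Per-parameter split-chain Rhat and effective sample size."""
    if fit.config.chains < 2:
        warnings.warn("convergence diagnostics are unreliable with a single chain")
    return fit.diagnostics.copy()


def trace_series(fit: PosteriorSummary, parameter: str) -> pd.DataFrame:
    """Stored draws of one parameter as a (draw x chain) frame for plotting.

    ``parameter`` is e.g. ``"mu[aci]"``, ``"tau[aci]"`` or ``"rho_w"``.
    """
    if parameter == "rho_w":
        if "rho_w" not in fit.draws:
            raise KeyError("this fit has no rho_w (not Model H)")
        arr = fit.draws["rho_w"]
    else:
        kind, _, rest = parameter.partition("[")
        fid = rest.rstrip("]")
        fids = list(fit.summary.index)
        if kind not in ("mu", "tau") or fid not in fids:
            raise KeyError(f"unknown parameter {parameter!r}")
        arr = fit.draws[kind][:, :, fids.index(fid)]
    return pd.DataFrame(
        arr.T, columns=[f"chain{c}" for c in range(arr.shape[0])]
    )


def exponentiate_summary(fit: PosteriorSummary, factor_id: str) -> OrEstimate:
    """Exponentiate a factor's posterior median and CrI to the OR scale.

    The exponential is monotone, so quantiles map through directly:
    the median OR is exp(median log OR) and interval ordering is
    preserved.
    """
    if factor_id not in fit.summary.index:
        raise KeyError(f"unknown factor {factor_id!r}")
    med = fit.median(factor_id)
    lo, hi = fit.cri95(factor_id)
    return OrEstimate(
        factor_id=factor_id,
        variant=fit.variant,
        or_point=float(np.exp(med)),
        or_ci95=(float(np.exp(lo)), float(np.exp(hi))),
        log_or_median=med,
        log_or_ci95=(lo, hi),
    )
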