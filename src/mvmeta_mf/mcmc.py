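"""MCMC kernels for the hierarchical multivariate meta-analysis model.

The observation model for study *i* with observed factor subset
:math:`O_i` is

.. math::

    y_i(O_i) \\mid \\mu, \\tau, R_B, \\rho_W
        \\sim \\mathrm{N}\\!\\big(\\mu(O_i),\\; S_i + \\Sigma_B(O_i)\\big),

i.e. the study-level true effects are marginalized out analytically
(observed-subvector marginal likelihood — no imputation of unreported
factors).  :math:`S_i` carries the within-study sampling covariance
(diagonal :math:`s_{ij}^2`, off-diagonals :math:`\\rho_W s_{ij} s_{ik}`
under Model H) and :math:`\\Sigma_B = D R_B D` with
:math:`D = \\mathrm{diag}(\\tau)` the between-study covariance.

Two samplers are provided:

* :func:`run_mwg_chain` — a numba-compiled Metropolis-within-Gibbs sweep
  over the joint model: exact Gibbs draw for :math:`\\mu` (its full
  conditional is multivariate normal), random-walk Metropolis for each
  :math:`\\tau_j`, for each free correlation :math:`R_{jk}` (flat prior
  over positive-definite correlation matrices, enforced by rejection,
  never projection), and for the shared :math:`\\rho_W`.
* :func:`sample_univariate` — an independent, vectorized numpy
  implementation of the per-factor univariate special case (Model U),
  used both as the fast engine for simulation studies and as a
  cross-engine consistency check on the joint sampler.

Proposal scales adapt in batches during burn-in only, so retained draws
come from fixed kernels.  All randomness is seeded and deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["prepare_study_data", "run_mwg_chain", "sample_univariate"]

_LOG_SQRT_2PI = 0.9189385332046727
_ADAPT_BATCH = 100


# ---------------------------------------------------------------------------
# low-level linear algebra (small dense matrices, success-flag Cholesky)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _chol_d(A, L, d):
    """Cholesky of the top-left d x d block of A into L; False if not PD."""
    for i in range(d):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 1e-12:
                    return False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return True


@njit(cache=True)
def _build_V(i, obs_ptr, obs_idx, s_all, tau, R, rho_w, V):
    """Marginal covariance S_i + Sigma_B restricted to study i's subset."""
    p0 = obs_ptr[i]
    d = obs_ptr[i + 1] - p0
    for a in range(d):
        ja = obs_idx[p0 + a]
        sa = s_all[p0 + a]
        V[a, a] = sa * sa + tau[ja] * tau[ja]
        for b in range(a):
            jb = obs_idx[p0 + b]
            sb = s_all[p0 + b]
            V[a, b] = rho_w * sa * sb + tau[ja] * R[ja, jb] * tau[jb]
            V[b, a] = V[a, b]
    return d


@njit(cache=True)
def _ll_from_chol(L, d, r, u):
    """Gaussian log density at residual r given the Cholesky factor of V."""
    ll = -_LOG_SQRT_2PI * d
    for a in range(d):
        s = r[a]
        for k in range(a):
            s -= L[a, k] * u[k]
        u[a] = s / L[a, a]
        ll -= np.log(L[a, a]) + 0.5 * u[a] * u[a]
    return ll


@njit(cache=True)
def _study_ll(i, obs_ptr, obs_idx, y_all, s_all, mu, tau, R, rho_w, V, L, r, u):
    d = _build_V(i, obs_ptr, obs_idx, s_all, tau, R, rho_w, V)
    if not _chol_d(V, L, d):
        return False, 0.0
    p0 = obs_ptr[i]
    for a in range(d):
        r[a] = y_all[p0 + a] - mu[obs_idx[p0 + a]]
    return True, _ll_from_chol(L, d, r, u)


@njit(cache=True)
def _gibbs_mu(J, n_stud, obs_ptr, obs_idx, y_all, chol_all, prior_prec,
              mu, P, bvec, LP, w1, w2, Vinv):
    """Exact draw from the multivariate normal full conditional of mu."""
    for a in range(J):
        bvec[a] = 0.0
        for b in range(J):
            P[a, b] = 0.0
        P[a, a] = prior_prec
    for i in range(n_stud):
        p0 = obs_ptr[i]
        d = obs_ptr[i + 1] - p0
        # invert V_i from its cached Cholesky factor, column by column
        for c in range(d):
            for a in range(d):
                s = 1.0 if a == c else 0.0
                for k in range(a):
                    s -= chol_all[i, a, k] * w1[k]
                w1[a] = s / chol_all[i, a, a]
            for a in range(d - 1, -1, -1):
                s = w1[a]
                for k in range(a + 1, d):
                    s -= chol_all[i, k, a] * w2[k]
                w2[a] = s / chol_all[i, a, a]
            for a in range(d):
                Vinv[a, c] = w2[a]
        for a in range(d):
            ja = obs_idx[p0 + a]
            for b in range(d):
                P[ja, obs_idx[p0 + b]] += Vinv[a, b]
                bvec[ja] += Vinv[a, b] * y_all[p0 + b]
    _chol_d(P, LP, J)
    # posterior mean: solve LP w1 = b, LP^T w2 = w1
    for a in range(J):
        s = bvec[a]
        for k in range(a):
            s -= LP[a, k] * w1[k]
        w1[a] = s / LP[a, a]
    for a in range(J - 1, -1, -1):
        s = w1[a]
        for k in range(a + 1, J):
            s -= LP[k, a] * w2[k]
        w2[a] = s / LP[a, a]
    # draw: mu = mean + LP^{-T} z
    for a in range(J):
        w1[a] = np.random.standard_normal()
    for a in range(J - 1, -1, -1):
        s = w1[a]
        for k in range(a + 1, J):
            s -= LP[k, a] * mu[k]
        mu[a] = w2[a] + s / LP[a, a]


@njit(cache=True)
def run_mwg_chain(seed, n_burn, n_draws, thin,
                  J, n_stud, obs_ptr, obs_idx, y_all, s_all,
                  prior_mu_sd, tau_upper,
                  sample_tau,
                  sample_rho, rho_fixed,
                  sample_corr,
                  pair_j, pair_k, pair_ptr, pair_stud,
                  fac_ptr, fac_stud, multi_stud,
                  mu_init, tau_init,
                  mu_keep, tau_keep, rho_keep, R_sum, acc_out):
    """One MCMC chain; fills the *_keep output arrays in place.

    Returns the number of retained draws (== n_draws // thin).
    """
    np.random.seed(seed)
    Dmax = 0
    for i in range(n_stud):
        d = obs_ptr[i + 1] - obs_ptr[i]
        if d > Dmax:
            Dmax = d

    mu = mu_init.copy()
    tau = tau_init.copy()
    R = np.eye(J)
    rho_w = rho_fixed

    # workspaces
    V = np.zeros((Dmax, Dmax))
    Lw = np.zeros((Dmax, Dmax))
    r = np.zeros(Dmax)
    u = np.zeros(Dmax)
    P = np.zeros((J, J))
    LP = np.zeros((J, J))
    LR = np.zeros((J, J))
    bvec = np.zeros(J)
    w1 = np.zeros(J)
    w2 = np.zeros(J)
    Vinv = np.zeros((Dmax, Dmax))
    Rprop = np.zeros((J, J))

    chol_all = np.zeros((n_stud, Dmax, Dmax))
    ll_all = np.zeros(n_stud)
    prop_chol = np.zeros((n_stud, Dmax, Dmax))
    prop_ll = np.zeros(n_stud)

    for i in range(n_stud):
        ok, ll = _study_ll(i, obs_ptr, obs_idx, y_all, s_all, mu, tau, R,
                           rho_w, V, chol_all[i], r, u)
        ll_all[i] = ll

    n_pair = len(pair_j)
    tau_step = np.full(J, 0.4)
    r_step = np.full(n_pair, 0.3)
    rho_step = 0.3
    tau_acc = np.zeros(J)
    r_acc = np.zeros(n_pair)
    rho_acc = 0.0
    prior_prec = 1.0 / (prior_mu_sd * prior_mu_sd)

    kept = 0
    n_iter = n_burn + n_draws
    for it in range(n_iter):
        # --- mu | rest: exact Gibbs (V_i do not depend on mu) -----------
        _gibbs_mu(J, n_stud, obs_ptr, obs_idx, y_all, chol_all, prior_prec,
                  mu, P, bvec, LP, w1, w2, Vinv)
        for i in range(n_stud):
            p0 = obs_ptr[i]
            d = obs_ptr[i + 1] - p0
            for a in range(d):
                r[a] = y_all[p0 + a] - mu[obs_idx[p0 + a]]
            ll_all[i] = _ll_from_chol(chol_all[i], d, r, u)

        # --- tau_j | rest: random-walk Metropolis -----------------------
        if sample_tau:
            for j in range(J):
                prop = tau[j] + tau_step[j] * np.random.standard_normal()
                if prop <= 0.0 or prop >= tau_upper:
                    continue
                old = tau[j]
                tau[j] = prop
                delta = 0.0
                ok_all = True
                for q in range(fac_ptr[j], fac_ptr[j + 1]):
                    i = fac_stud[q]
                    ok, ll = _study_ll(i, obs_ptr, obs_idx, y_all, s_all,
                                       mu, tau, R, rho_w, V, prop_chol[i], r, u)
                    if not ok:
                        ok_all = False
                        break
                    prop_ll[i] = ll
                    delta += ll - ll_all[i]
                if ok_all and np.log(np.random.random()) < delta:
                    tau_acc[j] += 1.0
                    for q in range(fac_ptr[j], fac_ptr[j + 1]):
                        i = fac_stud[q]
                        ll_all[i] = prop_ll[i]
                        d = obs_ptr[i + 1] - obs_ptr[i]
                        for a in range(d):
                            for b in range(a + 1):
                                chol_all[i, a, b] = prop_chol[i, a, b]
                else:
                    tau[j] = old

        # --- R_jk | rest: random-walk Metropolis, PD by rejection -------
        if sample_corr:
            for p in range(n_pair):
                j = pair_j[p]
                k = pair_k[p]
                prop = R[j, k] + r_step[p] * np.random.standard_normal()
                if prop <= -1.0 or prop >= 1.0:
                    continue
                for a in range(J):
                    for b in range(J):
                        Rprop[a, b] = R[a, b]
                Rprop[j, k] = prop
                Rprop[k, j] = prop
                if not _chol_d(Rprop, LR, J):
                    continue
                delta = 0.0
                ok_all = True
                for q in range(pair_ptr[p], pair_ptr[p + 1]):
                    i = pair_stud[q]
                    ok, ll = _study_ll(i, obs_ptr, obs_idx, y_all, s_all,
                                       mu, tau, Rprop, rho_w, V,
                                       prop_chol[i], r, u)
                    if not ok:
                        ok_all = False
                        break
                    prop_ll[i] = ll
                    delta += ll - ll_all[i]
                if ok_all and np.log(np.random.random()) < delta:
                    r_acc[p] += 1.0
                    R[j, k] = prop
                    R[k, j] = prop
                    for q in range(pair_ptr[p], pair_ptr[p + 1]):
                        i = pair_stud[q]
                        ll_all[i] = prop_ll[i]
                        d = obs_ptr[i + 1] - obs_ptr[i]
                        for a in range(d):
                            for b in range(a + 1):
                                chol_all[i, a, b] = prop_chol[i, a, b]

        # --- rho_w | rest: random-walk Metropolis (Model H) -------------
        if sample_rho:
            prop = rho_w + rho_step * np.random.standard_normal()
            if -1.0 < prop < 1.0:
                delta = 0.0
                ok_all = True
                for q in range(len(multi_stud)):
                    i = multi_stud[q]
                    ok, ll = _study_ll(i, obs_ptr, obs_idx, y_all, s_all,
                                       mu, tau, R, prop, V, prop_chol[i], r, u)
                    if not ok:
                        ok_all = False
                        break
                    prop_ll[i] = ll
                    delta += ll - ll_all[i]
                if ok_all and np.log(np.random.random()) < delta:
                    rho_acc += 1.0
                    rho_w = prop
                    for q in range(len(multi_stud)):
                        i = multi_stud[q]
                        ll_all[i] = prop_ll[i]
                        d = obs_ptr[i + 1] - obs_ptr[i]
                        for a in range(d):
                            for b in range(a + 1):
                                chol_all[i, a, b] = prop_chol[i, a, b]

        # --- burn-in step-size adaptation (frozen afterwards) -----------
        if it < n_burn and (it + 1) % _ADAPT_BATCH == 0:
            for j in range(J):
                rate = tau_acc[j] / _ADAPT_BATCH
                if rate > 0.5:
                    tau_step[j] *= 1.3
                elif rate < 0.2:
                    tau_step[j] /= 1.3
                tau_acc[j] = 0.0
            for p in range(n_pair):
                rate = r_acc[p] / _ADAPT_BATCH
                if rate > 0.5:
                    r_step[p] *= 1.3
                elif rate < 0.2:
                    r_step[p] /= 1.3
                r_acc[p] = 0.0
            rate = rho_acc / _ADAPT_BATCH
            if rate > 0.5:
                rho_step *= 1.3
            elif rate < 0.2:
                rho_step /= 1.3
            rho_acc = 0.0

        # --- record ------------------------------------------------------
        if it >= n_burn and (it - n_burn) % thin == 0:
            for j in range(J):
                mu_keep[kept, j] = mu[j]
                tau_keep[kept, j] = tau[j]
            rho_keep[kept] = rho_w
            for a in range(J):
                for b in range(J):
                    R_sum[a, b] += R[a, b]
            kept += 1

    acc_out[0] = rho_step
    return kept


def prepare_study_data(y: np.ndarray, se: np.ndarray):
    """Flatten a studies x factors pair of (possibly NaN) matrices.

    Returns the CSR-style arrays consumed by :func:`run_mwg_chain`:
    per-study observed factor indices, values and SEs; per-factor lists of
    reporting studies; per-pair lists of co-reporting studies; and the
    list of studies observing two or more factors.
    """
    y = np.asarray(y, dtype=float)
    se = np.asarray(se, dtype=float)
    n, J = y.shape
    mask = ~np.isnan(y)
    obs_ptr = [0]
    obs_idx: list[int] = []
    y_all: list[float] = []
    s_all: list[float] = []
    for i in range(n):
        js = np.flatnonzero(mask[i])
        obs_idx.extend(js.tolist())
        y_all.extend(y[i, js].tolist())
        s_all.extend(se[i, js].tolist())
        obs_ptr.append(len(obs_idx))
    fac_ptr = [0]
    fac_stud: list[int] = []
    for j in range(J):
        fac_stud.extend(np.flatnonzero(mask[:, j]).tolist())
        fac_ptr.append(len(fac_stud))
    pair_j: list[int] = []
    pair_k: list[int] = []
    pair_ptr = [0]
    pair_stud: list[int] = []
    for j in range(J):
        for k in range(j + 1, J):
            pair_j.append(j)
            pair_k.append(k)
            pair_stud.extend(np.flatnonzero(mask[:, j] & mask[:, k]).tolist())
            pair_ptr.append(len(pair_stud))
    multi = np.flatnonzero(mask.sum(axis=1) >= 2)
    return dict(
        J=J,
        n_stud=n,
        obs_ptr=np.array(obs_ptr, dtype=np.int64),
        obs_idx=np.array(obs_idx, dtype=np.int64),
        y_all=np.array(y_all, dtype=float),
        s_all=np.array(s_all, dtype=float),
        fac_ptr=np.array(fac_ptr, dtype=np.int64),
        fac_stud=np.array(fac_stud, dtype=np.int64),
        pair_j=np.array(pair_j, dtype=np.int64),
        pair_k=np.array(pair_k, dtype=np.int64),
        pair_ptr=np.array(pair_ptr, dtype=np.int64),
        pair_stud=np.array(pair_stud, dtype=np.int64),
        multi_stud=multi.astype(np.int64),
    )


# ---------------------------------------------------------------------------
# vectorized univariate (Model U) sampler — independent numpy code path
# ---------------------------------------------------------------------------


def sample_univariate(
    y: np.ndarray,
    se: np.ndarray,
    *,
    chains: int,
    burn_in: int,
    draws: int,
    thin: int,
    seed: int,
    prior_mu_sd: float = 10.0,
    tau_upper: float = 5.0,
    fix_tau: float | None = None,
) -> dict[str, np.ndarray]:
    """Per-factor normal-normal random-effects sampler, ignoring correlations.

    ``y``/``se`` are studies x factors matrices with NaN for unreported
    cells.  All factors and chains are advanced simultaneously (Gibbs for
    each overall effect, random-walk Metropolis for each between-study
    SD), so a full published-scale protocol runs in seconds.

    Returns a dict with ``mu`` and ``tau`` draw arrays of shape
    (chains, kept, n_factors).
    """
    y = np.asarray(y, dtype=float)
    se = np.asarray(se, dtype=float)
    n, J = y.shape
    mask = ~np.isnan(y)
    y0 = np.where(mask, y, 0.0)
    s2 = np.where(mask, se, 1.0) ** 2
    m = mask.astype(float)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    C = chains
    # overdispersed but in-support starting points
    mu = rng.normal(0.0, 1.0, size=(C, J))
    if fix_tau is None:
        tau = rng.uniform(0.2, min(1.5, tau_upper * 0.9), size=(C, J))
    else:
        tau = np.full((C, J), float(fix_tau))
    step = np.full((C, J), 0.4)
    acc = np.zeros((C, J))

    prior_prec = 1.0 / prior_mu_sd**2
    kept = draws // thin
    mu_keep = np.empty((C, kept, J))
    tau_keep = np.empty((C, kept, J))

    # data arranged as (1, n, J) for broadcasting against (C, 1, J) states
    yb = y0[None, :, :]
    s2b = s2[None, :, :]
    mb = m[None, :, :]

    def _ll(tau_cj, mu_cj):
        var = s2b + tau_cj[:, None, :] ** 2
        dev = yb - mu_cj[:, None, :]
        return -0.5 * np.sum(mb * (np.log(var) + dev**2 / var), axis=1)

    cur_ll = _ll(tau, mu)
    k_out = 0
    total = burn_in + draws
    for it in range(total):
        # Gibbs update of mu
        var = s2b + tau[:, None, :] ** 2
        prec = mb / var
        P = prec.sum(axis=1) + prior_prec
        mean = (prec * yb).sum(axis=1) / P
        mu = mean + rng.standard_normal((C, J)) / np.sqrt(P)
        cur_ll = _ll(tau, mu)
        # RW Metropolis update of tau
        if fix_tau is None:
            prop = tau + step * rng.standard_normal((C, J))
            ok = (prop > 0.0) & (prop < tau_upper)
            prop_ll = _ll(np.where(ok, prop, tau), mu)
            accept = ok & (np.log(rng.random((C, J))) < prop_ll - cur_ll)
            tau = np.where(accept, prop, tau)
            cur_ll = np.where(accept, prop_ll, cur_ll)
            acc += accept
            if it < burn_in and (it + 1) % _ADAPT_BATCH == 0:
                rate = acc / _ADAPT_BATCH
                step = step * np.where(rate > 0.5, 1.3, np.where(rate < 0.2, 1 / 1.3, 1.0))
                acc[:] = 0.0
        if it >= burn_in and (it - burn_in) % thin == 0:
            mu_keep[:, k_out, :] = mu
            tau_keep[:, k_out, :] = tau
            k_out += 1
    return {"mu": mu_keep, "tau": tau_keep}
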