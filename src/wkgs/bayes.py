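"""Gibbs samplers for single- and multi-environment Bayesian kernel models.

Single-environment (SE) model, one environment j at a time:

    y_j = 1 mu_j + g_j + b_j + e_j
    g_j ~ N(0, sigma2_g K_j),  b_j ~ N(0, sigma2_b B_j),  e_j ~ N(0, sigma2_e I)

Multi-environment (ME) model over stacked records y = (y_1, ..., y_m):

    y = mu + g + b + e
    g ~ N(0, Sigma_g),  Sigma_g[i,k] = G_env[env(i), env(k)] * K[i,k]
    b ~ N(0, Sigma_b),  Sigma_b built the same way from background blocks
    e ~ N(0, diag(sigma2_e_j))

G_env is the m x m environment genetic covariance matrix whose off-diagonals
carry the cross-environment genetic covariances that let training records in
one environment inform predictions in another.

Two ME regimes are implemented. The *kronecker* regime requires the same
individuals in every environment (replicated lines): Sigma_g = G_env (x) K,
the kernel eigenbasis decouples the latent genetic values into independent
m-dimensional draws, and G_env has a conjugate inverse-Wishart update. The
*general* regime allows disjoint individuals per environment: the Hadamard
covariance breaks conjugacy, so G_env (and, in half-sib mode, the
background covariance matrix) moves by random-scan Metropolis-within-Gibbs
on log variances and Fisher-z correlations, with per-component step sizes
adapted during burn-in toward a 20-45% acceptance rate and frozen afterwards.

Priors (proper, weakly informative, conjugate where conjugacy exists):
scaled-inverse-chi2(df 5, scale = half the phenotypic variance) for every
scalar variance; inverse-Wishart(df m + 2, scale = diag of per-environment
phenotypic variances / 2) for G_env in the kronecker regime; uniform(-1, 1)
for correlations in the general regime.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "BackgroundMatrix",
    "SEFit",
    "MEFit",
    "Chain",
    "build_background",
    "fit_se",
    "predict_se",
    "fit_me",
    "predict_cv2",
    "estimate_h2",
]

PRIOR_DF = 5.0          # scaled-inverse-chi2 df for scalar variances
JITTER = 1e-8           # ridge added to covariance diagonals before factorization
EIG_TOL = 1e-8          # relative eigenvalue cutoff for singular kernels
ADAPT_WINDOW = 50       # MH proposals per adaptation step during burn-in
ACC_LOW, ACC_HIGH = 0.20, 0.45


# ---------------------------------------------------------------------------
# Background relationship matrices


@dataclass
class BackgroundMatrix:
    """Background (non-marker) relationship over the stacked records.

    identity mode: B_jj = I, cross-environment blocks zero, and the
    cross-environment background covariances are fixed at zero during
    fitting. half_sib mode: 1 on the diagonal, 0.25 for distinct
    same-family pairs within or across environments, 0 otherwise.
    """

    full: np.ndarray
    mode: str
    record_envs: np.ndarray
    record_ids: list[str]

    def env_slice(self, env: str) -> np.ndarray:
        return np.where(self.record_envs == env)[0]


def build_background(phenos, trait: str | None = None, families: dict | None = None,
                     mode: str = "identity") -> BackgroundMatrix:
    if mode not in ("identity", "half_sib"):
        raise ValueError(f"unknown background mode {mode!r}")
    if trait is None:
        traits = phenos.traits
        if len(traits) != 1:
            raise ValueError("trait must be given for multi-trait tables")
        trait = traits[0]
    recs = phenos.for_trait(trait)
    ids = list(recs["individual_id"])
    envs = recs["environment"].to_numpy()
    n = len(ids)
    if mode == "identity":
        full = np.eye(n)
    else:
        if families is None:
            raise ValueError("half_sib mode requires a family map")
        missing = [i for i in ids if i not in families]
        if missing:
            raise ValueError(f"no family label for individuals {missing[:5]}")
        fam = np.array([families[i] for i in ids])
        full = np.where(fam[:, None] == fam[None, :], 0.25, 0.0)
        np.fill_diagonal(full, 1.0)
    return BackgroundMatrix(full=full, mode=mode, record_envs=envs, record_ids=ids)


# ---------------------------------------------------------------------------
# Fit containers


@dataclass
class Chain:
    """Named posterior traces with standard MCMC diagnostics."""

    traces: dict
    iters: int
    burnin: int
    seed: int
    thin: int = 1

    def __post_init__(self) -> None:
        lengths = {np.asarray(v).shape[0] for v in self.traces.values()}
        if len(lengths) > 1:
            raise ValueError("trace lengths differ")

    def diagnostics(self) -> pd.DataFrame:
        """Effective sample size and split-chain R-hat per scalar trace."""
        rows = []
        for name, tr in self.traces.items():
            tr = np.asarray(tr, dtype=float)
            flat = tr.reshape(tr.shape[0], -1)
            for j in range(flat.shape[1]):
                x = flat[:, j]
                label = name if flat.shape[1] == 1 else f"{name}[{j}]"
                rows.append({"parameter": label, "ess": _ess(x),
                             "rhat": _split_rhat(x)})
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (draw, parameter, value) table."""
        rows = {}
        for name, tr in self.traces.items():
            tr = np.asarray(tr, dtype=float)
            flat = tr.reshape(tr.shape[0], -1)
            for j in range(flat.shape[1]):
                label = name if flat.shape[1] == 1 else f"{name}[{j}]"
                rows[label] = flat[:, j]
        df = pd.DataFrame(rows)
        df.insert(0, "draw", np.arange(len(df)))
        return df.melt(id_vars="draw", var_name="parameter", value_name="value")


def _ess(x: np.ndarray) -> float:
    """Initial-positive-sequence autocorrelation ESS estimate."""
    n = x.size
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for t in range(1, n // 2):
        pair = acf[2 * t - 1] + acf[2 * t] if 2 * t < n else acf[2 * t - 1]
        if pair < 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))


def _split_rhat(x: np.ndarray) -> float:
    n = x.size // 2
    if n < 2:
        return np.nan
    a, b = x[:n], x[-n:]
    W = 0.5 * (a.var(ddof=1) + b.var(ddof=1))
    Bv = n * np.var([a.mean(), b.mean()], ddof=1)
    if W == 0:
        return np.nan
    return float(np.sqrt(((n - 1) / n * W + Bv / n) / W))


@dataclass
class SEFit:
    """Posterior draws for the single-environment model."""

    mu: np.ndarray
    sig2_g: np.ndarray
    sig2_b: np.ndarray
    sig2_e: np.ndarray
    g_mean: np.ndarray
    b_mean: np.ndarray
    g_draws: np.ndarray
    y: np.ndarray
    chain: Chain

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0]


@dataclass
class MEFit:
    """Posterior draws for the multi-environment model."""

    environments: list[str]
    mu: np.ndarray            # (S, m)
    G_env: np.ndarray         # (S, m, m) genetic covariance matrix draws
    B_env: np.ndarray         # (S, m, m) background variance/covariance draws
    sig2_e: np.ndarray        # (S, m)
    g_mean: np.ndarray
    b_mean: np.ndarray
    y: np.ndarray             # training phenotypes (fitted records)
    record_envs: np.ndarray   # env per fitted record
    train_mask: np.ndarray | None
    background_mode: str
    regime: str
    chain: Chain

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0]


# ---------------------------------------------------------------------------
# Shared numerics


from scipy.linalg.lapack import dpotrf as _dpotrf


def _chol(S: np.ndarray) -> np.ndarray:
    """Lower Cholesky of S + jitter*I via LAPACK, minimal overhead."""
    A = np.array(S, dtype=float, order="F")
    A.flat[:: A.shape[0] + 1] += JITTER
    c, info = _dpotrf(A, lower=1, overwrite_a=1, clean=1)
    if info != 0:
        raise np.linalg.LinAlgError(f"matrix not positive definite (info={info})")
    return c


def _scaled_inv_chi2(rng, df: float, scale_ss: float) -> float:
    """Draw sigma2 ~ ScInvChi2: (df * scale) aggregated as scale_ss / chi2_df."""
    return scale_ss / rng.chisquare(df)


def _check_finite(it: int, *values) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise FloatingPointError(f"divergent chain: non-finite draw at iteration {it}")


def _eig_psd(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition with small/negative eigenvalues clipped to zero."""
    lam, U = np.linalg.eigh(S)
    if lam.min() < -1e-6 * max(lam.max(), 1.0):
        raise ValueError("matrix is not positive semidefinite")
    lam = np.clip(lam, 0.0, None)
    lam[lam < EIG_TOL * max(lam.max(), 1.0)] = 0.0
    return lam, U


# ---------------------------------------------------------------------------
# Single-environment model


def fit_se(y, K, B=None, iters: int = 12000, burnin: int = 6000,
           seed: int = 0, thin_latent: int = 10) -> SEFit:
    """Gibbs sampler for y = 1 mu + g + b + e in one environment.

    Works in the eigenbases of K and B, so each sweep is O(n^2) regardless
    of kernel conditioning; components with zero eigenvalue are pinned at 0.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    K = np.asarray(K, dtype=float)
    B = np.eye(n) if B is None else np.asarray(B, dtype=float)
    if K.shape != (n, n) or B.shape != (n, n):
        raise ValueError("K and B must be n x n")
    if iters <= burnin:
        raise ValueError("iters must exceed burnin")
    lam_g, U = _eig_psd(K)
    lam_b, V = _eig_psd(B)
    act_g, act_b = lam_g > 0, lam_b > 0
    rng = np.random.default_rng(seed)

    vy = y.var()
    if vy == 0:
        raise ValueError("phenotype has zero variance")
    s0 = vy / 2.0  # prior scale: half the phenotypic variance
    mu = y.mean()
    sig2_g = sig2_b = sig2_e = vy / 3.0
    gam = np.zeros(n)   # g in K's eigenbasis
    dlt = np.zeros(n)   # b in B's eigenbasis

    n_keep = iters - burnin
    out = {k: np.empty(n_keep) for k in ("mu", "sig2_g", "sig2_b", "sig2_e")}
    g_sum = np.zeros(n)
    b_sum = np.zeros(n)
    g_draws = []

    for it in range(iters):
        g = U @ gam
        b = V @ dlt
        # mu | rest (flat prior)
        r = y - g - b
        mu = rng.normal(r.mean(), np.sqrt(sig2_e / n))
        # g | rest in K eigenbasis
        rt = U.T @ (y - mu - b)
        prior_v = sig2_g * lam_g
        post_v = np.where(act_g, 1.0 / (1.0 / np.where(act_g, prior_v, 1.0) + 1.0 / sig2_e), 0.0)
        post_m = post_v * rt / sig2_e
        gam = post_m + np.sqrt(post_v) * rng.standard_normal(n)
        gam[~act_g] = 0.0
        g = U @ gam
        # b | rest in B eigenbasis
        rb = V.T @ (y - mu - g)
        prior_vb = sig2_b * lam_b
        post_vb = np.where(act_b, 1.0 / (1.0 / np.where(act_b, prior_vb, 1.0) + 1.0 / sig2_e), 0.0)
        post_mb = post_vb * rb / sig2_e
        dlt = post_mb + np.sqrt(post_vb) * rng.standard_normal(n)
        dlt[~act_b] = 0.0
        b = V @ dlt
        # variances | rest (scaled-inverse-chi2 conditionals)
        ss_g = np.sum(gam[act_g] ** 2 / lam_g[act_g])
        sig2_g = _scaled_inv_chi2(rng, PRIOR_DF + act_g.sum(), PRIOR_DF * s0 + ss_g)
        ss_b = np.sum(dlt[act_b] ** 2 / lam_b[act_b])
        sig2_b = _scaled_inv_chi2(rng, PRIOR_DF + act_b.sum(), PRIOR_DF * s0 + ss_b)
        resid = y - mu - g - b
        sig2_e = _scaled_inv_chi2(rng, PRIOR_DF + n, PRIOR_DF * s0 + resid @ resid)
        _check_finite(it, mu, sig2_g, sig2_b, sig2_e)
        if it >= burnin:
            k = it - burnin
            out["mu"][k] = mu
            out["sig2_g"][k] = sig2_g
            out["sig2_b"][k] = sig2_b
            out["sig2_e"][k] = sig2_e
            g_sum += g
            b_sum += b
            if k % thin_latent == 0:
                g_draws.append(g.copy())

    chain = Chain(traces=dict(out), iters=iters, burnin=burnin, seed=seed)
    return SEFit(mu=out["mu"], sig2_g=out["sig2_g"], sig2_b=out["sig2_b"],
                 sig2_e=out["sig2_e"], g_mean=g_sum / n_keep, b_mean=b_sum / n_keep,
                 g_draws=np.array(g_draws), y=y, chain=chain)


def predict_se(fit: SEFit, K_full, B_full, train_idx, test_idx,
               thin: int = 10) -> np.ndarray:
    """Conditional-mean prediction for held-out records under the SE model.

    K_full/B_full cover train and test records; the fit supplies y_train
    and variance draws. Averages the Gaussian conditional mean over thinned
    posterior draws.
    """
    K_full = np.asarray(K_full, dtype=float)
    B_full = np.asarray(B_full, dtype=float)
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    y_tr = fit.y
    preds = np.zeros(test_idx.size)
    draws = range(0, fit.n_draws, thin)
    count = 0
    for s in draws:
        Sg = fit.sig2_g[s] * K_full
        Sb = fit.sig2_b[s] * B_full
        V_tr = Sg[np.ix_(train_idx, train_idx)] + Sb[np.ix_(train_idx, train_idx)]
        V_tr[np.diag_indices_from(V_tr)] += fit.sig2_e[s]
        C = Sg[np.ix_(test_idx, train_idx)] + Sb[np.ix_(test_idx, train_idx)]
        L = _chol(V_tr)
        alpha = sla.cho_solve((L, True), y_tr - fit.mu[s], check_finite=False)
        preds += fit.mu[s] + C @ alpha
        count += 1
    return preds / count


# ---------------------------------------------------------------------------
# Multi-environment model


def _expand_env(M: np.ndarray, env_idx: np.ndarray) -> np.ndarray:
    """Record-level expansion of an m x m environment matrix."""
    return M[np.ix_(env_idx, env_idx)]


def _records_for_me(phenos, trait, kernel_set, train_mask):
    recs = phenos.for_trait(trait) if trait else phenos.for_trait(phenos.traits[0])
    key = list(zip(recs["individual_id"], recs["environment"]))
    kkey = list(zip(kernel_set.record_ids, kernel_set.record_envs))
    if key != kkey:
        raise ValueError("phenotype records do not align with the kernel set")
    y_all = recs["value"].to_numpy()
    envs_all = recs["environment"].to_numpy()
    if train_mask is None:
        train_mask = np.ones(len(recs), dtype=bool)
    else:
        train_mask = np.asarray(train_mask, dtype=bool)
    return y_all, envs_all, train_mask


def fit_me(phenos, kernel_set, background: BackgroundMatrix,
           iters: int | None = None, burnin: int | None = None, seed: int = 0,
           regime: str = "general", trait: str | None = None,
           train_mask=None, thin_latent: int = 10) -> MEFit:
    """Fit the ME model; see the module docstring for the two regimes."""
    if regime not in ("kronecker", "general"):
        raise ValueError(f"unknown regime {regime!r}")
    if iters is None:
        iters = 20000 if regime == "kronecker" else 100000
    if burnin is None:
        burnin = iters // 2
    if iters <= burnin:
        raise ValueError("iters must exceed burnin")
    y_all, envs_all, train_mask = _records_for_me(phenos, trait, kernel_set, train_mask)
    y = y_all[train_mask]
    envs = envs_all[train_mask]
    env_levels = list(kernel_set.environments)
    K = kernel_set.full[np.ix_(np.where(train_mask)[0], np.where(train_mask)[0])]
    B = background.full[np.ix_(np.where(train_mask)[0], np.where(train_mask)[0])]
    if regime == "kronecker":
        draws = _gibbs_me_kronecker(y, envs, env_levels, K, background.mode, B,
                                    iters, burnin, seed, thin_latent)
    else:
        draws = _gibbs_me_general(y, envs, env_levels, K, background.mode, B,
                                  iters, burnin, seed, thin_latent)
    chain = Chain(traces={k: draws[k] for k in ("mu", "G_env", "B_env", "sig2_e")},
                  iters=iters, burnin=burnin, seed=seed)
    return MEFit(environments=env_levels, mu=draws["mu"], G_env=draws["G_env"],
                 B_env=draws["B_env"], sig2_e=draws["sig2_e"],
                 g_mean=draws["g_mean"], b_mean=draws["b_mean"], y=y,
                 record_envs=envs, train_mask=train_mask,
                 background_mode=background.mode, regime=regime, chain=chain)


def _prior_scales(y: np.ndarray, env_idx: np.ndarray, m: int) -> np.ndarray:
    s = np.empty(m)
    for j in range(m):
        v = y[env_idx == j].var()
        s[j] = v / 2.0 if v > 0 else 0.5
    return s


def _gibbs_me_kronecker(y, envs, env_levels, K_full, bg_mode, B_full,
                        iters, burnin, seed, thin_latent):
    """Conjugate sampler for replicated lines: Sigma_g = G_env (x) K."""
    if bg_mode != "identity":
        raise ValueError("kronecker regime supports identity background only")
    m = len(env_levels)
    env_idx = np.searchsorted(env_levels, envs)
    # consistent line sets and order across environments
    counts = np.bincount(env_idx, minlength=m)
    n = counts[0]
    if not np.all(counts == n):
        raise ValueError("kronecker regime requires identical lines per environment")
    Y = np.column_stack([y[env_idx == j] for j in range(m)])
    K = K_full[np.ix_(np.where(env_idx == 0)[0], np.where(env_idx == 0)[0])]
    lam, U = _eig_psd(K)
    act = lam > 0
    n_act = int(act.sum())
    rng = np.random.default_rng(seed)

    s0 = _prior_scales(y, env_idx, m)
    nu_iw = m + 2.0
    S_iw = np.diag(s0)
    mu = Y.mean(axis=0)
    G = np.diag(np.maximum(Y.var(axis=0) / 3.0, 1e-3))
    sig2_b = np.maximum(Y.var(axis=0) / 3.0, 1e-3)
    sig2_e = np.maximum(Y.var(axis=0) / 3.0, 1e-3)
    Gt = np.zeros((n, m))   # g in the kernel eigenbasis (rows independent)
    Bmat = np.zeros((n, m))

    n_keep = iters - burnin
    out = {"mu": np.empty((n_keep, m)), "G_env": np.empty((n_keep, m, m)),
           "B_env": np.empty((n_keep, m, m)), "sig2_e": np.empty((n_keep, m))}
    g_sum = np.zeros((n, m))
    b_sum = np.zeros((n, m))

    lam_a = lam[act]
    for it in range(iters):
        Gmat = U @ Gt
        # mu
        r = Y - Gmat - Bmat
        mu = r.mean(axis=0) + np.sqrt(sig2_e / n) * rng.standard_normal(m)
        # g: rows of U'(Y - mu - B) are independent m-variate normals
        Rt = U.T @ (Y - mu - Bmat)
        prior_prec = np.linalg.inv(G)  # (lam_i G)^{-1} = prior_prec / lam_i
        De_inv = 1.0 / sig2_e
        P = prior_prec[None, :, :] / lam_a[:, None, None] + np.diag(De_inv)[None, :, :]
        C = np.linalg.inv(P)
        mean = np.einsum("ijk,ik->ij", C, Rt[act] * De_inv[None, :])
        Lc = np.linalg.cholesky(C)
        Gt_act = mean + np.einsum("ijk,ik->ij", Lc, rng.standard_normal((n_act, m)))
        Gt = np.zeros((n, m))
        Gt[act] = Gt_act
        Gmat = U @ Gt
        # b: identity background, scalar shrinkage per cell
        Rb = Y - mu - Gmat
        post_v = 1.0 / (1.0 / sig2_b + 1.0 / sig2_e)
        Bmat = (post_v * Rb / sig2_e) + np.sqrt(post_v) * rng.standard_normal((n, m))
        # G_env: conjugate inverse-Wishart
        S_g = np.einsum("ij,ik->jk", Gt_act / lam_a[:, None], Gt_act)
        G = stats.invwishart.rvs(df=nu_iw + n_act, scale=S_iw + S_g, random_state=rng)
        G = np.atleast_2d(G)
        # background and residual variances
        for j in range(m):
            sig2_b[j] = _scaled_inv_chi2(rng, PRIOR_DF + n,
                                         PRIOR_DF * s0[j] + Bmat[:, j] @ Bmat[:, j])
            resid = Y[:, j] - mu[j] - Gmat[:, j] - Bmat[:, j]
            sig2_e[j] = _scaled_inv_chi2(rng, PRIOR_DF + n,
                                         PRIOR_DF * s0[j] + resid @ resid)
        _check_finite(it, mu, G, sig2_b, sig2_e)
        if it >= burnin:
            k = it - burnin
            out["mu"][k] = mu
            out["G_env"][k] = G
            out["B_env"][k] = np.diag(sig2_b)
            out["sig2_e"][k] = sig2_e
            g_sum += Gmat
            b_sum += Bmat

    # flatten latent means back to stacked record order (env-major)
    g_mean = np.concatenate([(g_sum / n_keep)[:, j] for j in range(m)])
    b_mean = np.concatenate([(b_sum / n_keep)[:, j] for j in range(m)])
    out["g_mean"] = g_mean
    out["b_mean"] = b_mean
    return out


class _CovState:
    """Cached factorization of a Hadamard covariance Sigma = expand(M) o R.

    Decomposing M = D C D (D = diag of per-environment sd, C the correlation
    matrix), Sigma = P (R o expand(C)) P with P the record-level sd diagonal,
    so chol(Sigma) = P chol(R o expand(C)): variance moves rescale the cached
    correlation factor and only correlation moves pay a fresh Cholesky.
    """

    def __init__(self, M, R, env_idx, m):
        self.R = R
        self.env_idx = env_idx
        self.E = np.eye(m)[env_idx]  # N x m one-hot
        self.set_matrix(M)

    def _expand(self, M):
        return (self.E @ M) @ self.E.T

    def set_matrix(self, M, L_corr=None):
        self.M = M
        v, r = _vc_from_mat(M)
        self.v, self.r = v, r
        C = M / np.outer(np.sqrt(v), np.sqrt(v))
        if L_corr is None:
            L_corr = _chol(self.R * self._expand(C))
        self.L_corr = L_corr
        self.p_sd = self.E @ np.sqrt(v)
        self.L = self.p_sd[:, None] * L_corr
        self.S = self._expand(M) * self.R
        self.logdet = 2.0 * np.sum(np.log(np.diag(self.L)))

    def chol_for(self, M_new, corr_unchanged: bool = False):
        """Cholesky of the covariance at M_new, reusing the correlation factor
        when only variances changed. Returns (L, L_corr) or None if not PD."""
        v_new, r_new = _vc_from_mat(M_new)
        p_sd = self.E @ np.sqrt(v_new)
        if corr_unchanged:
            return p_sd[:, None] * self.L_corr, self.L_corr
        C = M_new / np.outer(np.sqrt(v_new), np.sqrt(v_new))
        try:
            L_corr = _chol(self.R * self._expand(C))
        except np.linalg.LinAlgError:
            return None
        return p_sd[:, None] * L_corr, L_corr

    def loglik(self, x, L=None, logdet=None):
        L = self.L if L is None else L
        logdet = self.logdet if logdet is None else logdet
        z = sla.solve_triangular(L, x, lower=True, check_finite=False)
        return -0.5 * (logdet + z @ z)

    def sample_prior(self, rng):
        return self.L @ rng.standard_normal(self.L.shape[0])


def _cov_params(m: int) -> list[tuple]:
    """Parameter list for an m x m covariance: log variances then Fisher-z corrs."""
    params = [("logvar", j, j) for j in range(m)]
    params += [("zcorr", j, k) for j in range(m) for k in range(j + 1, m)]
    return params


def _mat_from_vc(v: np.ndarray, r: np.ndarray, m: int) -> np.ndarray | None:
    """Covariance from variances v and flat upper-triangle correlations r."""
    Rm = np.eye(m)
    idx = 0
    for j in range(m):
        for k in range(j + 1, m):
            Rm[j, k] = Rm[k, j] = r[idx]
            idx += 1
    try:
        np.linalg.cholesky(Rm + 1e-12 * np.eye(m))
    except np.linalg.LinAlgError:
        return None
    sd = np.sqrt(v)
    return Rm * np.outer(sd, sd)


def _vc_from_mat(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v = np.diag(M).copy()
    sd = np.sqrt(v)
    m = M.shape[0]
    r = np.array([M[j, k] / (sd[j] * sd[k])
                  for j in range(m) for k in range(j + 1, m)])
    return v, r


def _log_prior_cov(v: np.ndarray, r: np.ndarray, s0: np.ndarray) -> float:
    """Prior in sampling coordinates: ScInvChi2 on variances (log scale, with
    Jacobian) and uniform(-1,1) on correlations (Fisher-z scale, with Jacobian)."""
    lp = 0.0
    for j, vj in enumerate(v):
        # scaled-inv-chi2(nu, s) density at vj, plus d(sigma2)/d(log sigma2) = sigma2
        nu, s = PRIOR_DF, s0[j]
        lp += -(nu / 2 + 1) * np.log(vj) - nu * s / (2 * vj) + np.log(vj)
    lp += np.sum(np.log(1.0 - np.asarray(r) ** 2 + 1e-300))  # dz -> dr Jacobian
    return lp


def _gibbs_me_general(y, envs, env_levels, K_full, bg_mode, B_full,
                      iters, burnin, seed, thin_latent):
    """Metropolis-within-Gibbs sampler for disjoint-individual designs."""
    m = len(env_levels)
    env_idx = np.searchsorted(env_levels, envs)
    N = y.size
    rng = np.random.default_rng(seed)
    s0 = _prior_scales(y, env_idx, m)

    counts = np.bincount(env_idx, minlength=m)
    mu = np.array([y[env_idx == j].mean() for j in range(m)])
    v0 = np.array([max(y[env_idx == j].var() / 3.0, 1e-3) for j in range(m)])
    G = np.diag(v0.copy())
    sig2_e = v0.copy()
    g = np.zeros(N)
    b = np.zeros(N)
    sig2_b = v0.copy()          # identity mode
    Sb = np.diag(v0.copy())     # half_sib mode
    half_sib = bg_mode == "half_sib"

    g_state = _CovState(G, K_full, env_idx, m)
    b_state = _CovState(Sb, B_full, env_idx, m) if half_sib else None
    env_masks = [env_idx == j for j in range(m)]

    params_g = _cov_params(m)
    params_b = _cov_params(m) if half_sib else []
    steps = {("g",) + p: 0.3 for p in params_g}
    steps.update({("b",) + p: 0.3 for p in params_b})
    acc = {k: [0, 0] for k in steps}

    n_keep = iters - burnin
    out = {"mu": np.empty((n_keep, m)), "G_env": np.empty((n_keep, m, m)),
           "B_env": np.empty((n_keep, m, m)), "sig2_e": np.empty((n_keep, m))}
    g_sum = np.zeros(N)
    b_sum = np.zeros(N)
    sig2_e_rec = sig2_e[env_idx]

    def mh_update(state, latent, block, it):
        """One random-scan MH move on the covariance parameters of `state`."""
        v, r = state.v, state.r
        plist = params_g if block == "g" else params_b
        kind, j, k = plist[rng.integers(len(plist))]
        key = (block, kind, j, k)
        step = steps[key]
        v_new, r_new = v.copy(), r.copy()
        if kind == "logvar":
            v_new[j] = np.exp(np.log(v[j]) + step * rng.standard_normal())
        else:
            flat = [(a, c) for a in range(m) for c in range(a + 1, m)]
            idx = flat.index((j, k))
            z = np.arctanh(np.clip(r[idx], -0.999999, 0.999999))
            r_new[idx] = np.tanh(z + step * rng.standard_normal())
        M_new = _mat_from_vc(v_new, r_new, m)
        acc[key][1] += 1
        accepted = False
        if M_new is not None:
            pair = state.chol_for(M_new, corr_unchanged=(kind == "logvar"))
            if pair is not None:
                L_new, L_corr_new = pair
                logdet_new = 2.0 * np.sum(np.log(np.diag(L_new)))
                ll_new = state.loglik(latent, L=L_new, logdet=logdet_new)
                ll_old = state.loglik(latent)
                lp_new = _log_prior_cov(v_new, r_new, s0)
                lp_old = _log_prior_cov(v, r, s0)
                if np.log(rng.uniform()) < (ll_new + lp_new) - (ll_old + lp_old):
                    state.set_matrix(M_new, L_corr=L_corr_new)
                    acc[key][0] += 1
                    accepted = True
        # step-size adaptation, frozen after burn-in
        if it < burnin and acc[key][1] >= ADAPT_WINDOW:
            rate = acc[key][0] / acc[key][1]
            if rate > ACC_HIGH:
                steps[key] *= 1.4
            elif rate < ACC_LOW:
                steps[key] *= 0.7
            acc[key][0] = acc[key][1] = 0
        return accepted

    all_rejected_warned = False
    for it in range(iters):
        # mu
        r_vec = y - g - b
        for j in range(m):
            mu[j] = rng.normal(r_vec[env_masks[j]].mean(),
                               np.sqrt(sig2_e[j] / counts[j]))
        mu_rec = mu[env_idx]
        # g | rest via Matheron's rule: one Cholesky of Sigma_g + Sigma_e
        resid = y - mu_rec - b
        W = np.array(g_state.S, order="C")
        W.flat[:: N + 1] += sig2_e_rec
        Lw = _chol(W)
        u = g_state.sample_prior(rng)
        eps = np.sqrt(sig2_e_rec) * rng.standard_normal(N)
        rhs = resid - u - eps
        sol = sla.cho_solve((Lw, True), rhs, check_finite=False)
        g = u + g_state.S @ sol
        # b | rest
        resid_b = y - mu_rec - g
        if half_sib:
            Wb = np.array(b_state.S, order="C")
            Wb.flat[:: N + 1] += sig2_e_rec
            Lb = _chol(Wb)
            ub = b_state.sample_prior(rng)
            epsb = np.sqrt(sig2_e_rec) * rng.standard_normal(N)
            solb = sla.cho_solve((Lb, True), resid_b - ub - epsb, check_finite=False)
            b = ub + b_state.S @ solb
        else:
            post_v = 1.0 / (1.0 / sig2_b[env_idx] + 1.0 / sig2_e_rec)
            b = post_v * resid_b / sig2_e_rec + np.sqrt(post_v) * rng.standard_normal(N)
            for j in range(m):
                bj = b[env_masks[j]]
                sig2_b[j] = _scaled_inv_chi2(rng, PRIOR_DF + counts[j],
                                             PRIOR_DF * s0[j] + bj @ bj)
        # residual variances
        resid_e = y - mu_rec - g - b
        for j in range(m):
            rj = resid_e[env_masks[j]]
            sig2_e[j] = _scaled_inv_chi2(rng, PRIOR_DF + counts[j],
                                         PRIOR_DF * s0[j] + rj @ rj)
        sig2_e_rec = sig2_e[env_idx]
        # covariance-matrix moves
        mh_update(g_state, g, "g", it)
        if half_sib:
            mh_update(b_state, b, "b", it)
        _check_finite(it, mu, g_state.M, sig2_e)
        if it == burnin and not all_rejected_warned:
            dead = [k for k, (a, t) in acc.items() if t >= ADAPT_WINDOW and a == 0]
            if dead:
                log.warning("MH components with zero acceptance during adaptation: %s", dead)
                all_rejected_warned = True
        if it >= burnin:
            kidx = it - burnin
            out["mu"][kidx] = mu
            out["G_env"][kidx] = g_state.M
            out["B_env"][kidx] = b_state.M if half_sib else np.diag(sig2_b)
            out["sig2_e"][kidx] = sig2_e
            g_sum += g
            b_sum += b

    out["g_mean"] = g_sum / n_keep
    out["b_mean"] = b_sum / n_keep
    return out


def predict_cv2(fit: MEFit, kernel_set, background: BackgroundMatrix,
                train_mask, test_mask, thin: int = 10) -> np.ndarray:
    """Predict held-out records from a fit trained on ``train_mask`` records.

    For each thinned posterior draw, computes the Gaussian conditional mean
    mu_TST + Sigma_(TST,TRN) Sigma_(TRN,TRN)^-1 (y_TRN - mu_TRN) under the
    multi-environment covariance implied by that draw, then averages.
    """
    train_mask = np.asarray(train_mask, dtype=bool)
    test_mask = np.asarray(test_mask, dtype=bool)
    if np.any(train_mask & test_mask):
        raise ValueError("train and test masks overlap")
    if fit.train_mask is not None and not np.array_equal(fit.train_mask, train_mask):
        raise ValueError("fit was trained on a different train mask")
    env_levels = fit.environments
    env_idx = np.searchsorted(env_levels, kernel_set.record_envs)
    tr = np.where(train_mask)[0]
    te = np.where(test_mask)[0]
    K = kernel_set.full
    B = background.full
    y_tr = fit.y
    preds = np.zeros(te.size)
    count = 0
    for s in range(0, fit.n_draws, thin):
        Ge = _expand_env(fit.G_env[s], env_idx)
        Be = _expand_env(fit.B_env[s], env_idx)
        if fit.background_mode == "identity":
            # cross-environment background covariance fixed at zero
            Be = Be * (env_idx[:, None] == env_idx[None, :])
        Sig = Ge * K + Be * B
        V_tr = Sig[np.ix_(tr, tr)].copy()
        V_tr[np.diag_indices_from(V_tr)] += fit.sig2_e[s][env_idx[tr]]
        C = Sig[np.ix_(te, tr)]
        mu_tr = fit.mu[s][env_idx[tr]]
        mu_te = fit.mu[s][env_idx[te]]
        try:
            L = _chol(V_tr)
        except np.linalg.LinAlgError:
            V_tr[np.diag_indices_from(V_tr)] += 1e-6
            L = _chol(V_tr)
        alpha = sla.cho_solve((L, True), y_tr - mu_tr, check_finite=False)
        preds += mu_te + C @ alpha
        count += 1
    return preds / count


def estimate_h2(fit) -> np.ndarray:
    """Posterior-mean narrow-sense heritability per environment.

    sigma2_g / (sigma2_g + sigma2_b + sigma2_e), with the per-environment
    genetic variances taken from the diagonal of G_env for ME fits. Fit the
    model with the additive (linear) kernel for the GBLUP convention.
    """
    if isinstance(fit, SEFit):
        h2 = fit.sig2_g / (fit.sig2_g + fit.sig2_b + fit.sig2_e)
        return np.array([h2.mean()])
    gvar = np.einsum("sjj->sj", fit.G_env)
    bvar = np.einsum("sjj->sj", fit.B_env)
    h2 = gvar / (gvar + bvar + fit.sig2_e)
    return h2.mean(axis=0)
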