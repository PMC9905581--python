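"""Per-marker association scan with genotype main and G x E interaction effects.

Each marker is tested in the fixed-effects linear model

    value = intercept + environment + marker + marker x environment + error

on the stacked (individual, environment) records. Two p-values per marker
feed the weighted kernel: a t-test (1 df) of the marker main effect in the
full model, and a joint F-test of the m - 1 interaction terms against the
nested model without them. Both raw vectors are then Benjamini-Hochberg
adjusted, separately, matching the false-discovery-rate control the weight
formulas expect.

The scan is ordinary least squares with no kinship correction; the
downstream kernel mixed model absorbs relatedness. Fits are hand-rolled on
top of an environment-projection (within-environment centering) so that
re-running the scan inside every cross-validation partition stays cheap;
tests cross-check the p-values against statsmodels OLS/ANOVA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = ["GwasResult", "scan_marker", "fdr_adjust", "run_gwas"]

FDR_LEVEL = 0.05  # recorded level; adjusted p-values enter the weights continuously


@dataclass
class GwasResult:
    """Per-marker association summaries aligned with the panel's marker set."""

    marker_ids: list[str]
    pvalue1_raw: np.ndarray
    pvalue2_raw: np.ndarray
    pvalue1_adj: np.ndarray
    pvalue2_adj: np.ndarray
    effect: np.ndarray
    constant: np.ndarray  # markers flagged constant (p-values set to 1)
    fdr_level: float = FDR_LEVEL

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker_id": self.marker_ids,
            "beta_hat": self.effect,
            "p_main_raw": self.pvalue1_raw,
            "p_gxe_raw": self.pvalue2_raw,
            "p_main_adj": self.pvalue1_adj,
            "p_gxe_adj": self.pvalue2_adj,
        })

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _env_design(env: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum-to-zero (effects) coded environment columns and the level order.

    Effects coding makes the marker coefficient in the full model the
    environment-averaged slope, so a pure crossover interaction nulls the
    main-effect test instead of loading onto a reference environment.
    """
    levels = np.array(sorted(set(env)))
    if levels.size < 2:
        raise ValueError("scan requires at least 2 environments")
    dummies = (env[:, None] == levels[None, 1:]).astype(float)
    dummies[env == levels[0], :] = -1.0
    return dummies, levels


def scan_marker(y, env, x) -> tuple[float, float, float]:
    """Single-marker G x E scan; returns (p_main, p_gxe, effect).

    ``y`` stacked phenotypes, ``env`` environment label per record, ``x``
    marker dosages aligned to records. A constant marker yields (1, 1, 0).
    """
    y = np.asarray(y, dtype=float)
    env = np.asarray(env)
    x = np.asarray(x, dtype=float)
    dummies, _ = _env_design(env)
    if np.ptp(x) == 0:
        return 1.0, 1.0, 0.0
    p1, p2, eff = _scan_block(y, env, dummies, x[:, None])
    return float(p1[0]), float(p2[0]), float(eff[0])


def _scan_block(y, env, dummies, X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized scan of the marker columns of X (n x p)."""
    n, p = X.shape
    m1 = dummies.shape[1]          # m - 1 interaction terms per marker
    q_full = 2 + m1 + m1            # intercept + env + marker + interactions
    base = np.column_stack([np.ones(n), dummies])
    # QR of the base design reused across markers
    Qb, _ = np.linalg.qr(base)
    proj = lambda M: M - Qb @ (Qb.T @ M)
    ry = proj(y[:, None])[:, 0]
    rss_base = float(ry @ ry)
    p1 = np.ones(p)
    p2 = np.ones(p)
    eff = np.zeros(p)
    df_full = n - q_full
    df_red = n - (q_full - m1)
    for j in range(p):
        x = X[:, j]
        if np.ptp(x) == 0:
            continue
        inter = x[:, None] * dummies
        Z = np.column_stack([x, inter])           # marker block, p-part
        Rz = proj(Z)
        # reduced model: base + marker main effect
        rx = Rz[:, 0]
        sxx = float(rx @ rx)
        if sxx <= 0:
            continue
        bred = float(rx @ ry) / sxx
        rss_red = rss_base - bred * float(rx @ ry)
        # full model: solve the projected normal equations for [x, inter]
        G = Rz.T @ Rz
        c = Rz.T @ ry
        try:
            coef = np.linalg.solve(G, c)
            Ginv = np.linalg.inv(G)
            rank_def = False
        except np.linalg.LinAlgError:
            coef, *_ = np.linalg.lstsq(G, c, rcond=None)
            Ginv = np.linalg.pinv(G)
            rank_def = True
            log.warning("rank-deficient interaction design at marker %d", j)
        rss_full = rss_base - float(coef @ c)
        rss_full = max(rss_full, 0.0)
        df_j = df_full if not rank_def else n - np.linalg.matrix_rank(
            np.column_stack([base, Z]))
        sigma2 = rss_full / df_j if df_j > 0 else np.nan
        eff[j] = coef[0]
        if sigma2 > 0 and np.isfinite(sigma2):
            se = np.sqrt(sigma2 * Ginv[0, 0])
            if se > 0:
                t = coef[0] / se
                p1[j] = 2 * stats.t.sf(abs(t), df_j)
        # joint F-test of the interaction block (full vs reduced-with-main)
        # reduced model has df_red residual df; use marker-adjusted reduced RSS
        num_df = m1 if not rank_def else max(df_red - df_j, 1)
        if rss_full > 0 and df_j > 0:
            F = ((rss_red - rss_full) / num_df) / (rss_full / df_j)
            p2[j] = stats.f.sf(max(F, 0.0), num_df, df_j)
        elif rss_red > rss_full:
            p2[j] = 0.0
    return np.clip(p1, 0, 1), np.clip(p2, 0, 1), eff


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, alpha=FDR_LEVEL, method="fdr_bh")
    return adj


def run_gwas(panel, phenos, trait: str, subset=None) -> GwasResult:
    """Scan every marker for ``trait`` and FDR-adjust both p-value vectors.

    ``subset`` is an optional boolean mask over the trait's records
    (environment-major order); cross-validation passes the training mask so
    p-values never see test phenotypes.
    """
    recs = phenos.for_trait(trait)
    if subset is not None:
        subset = np.asarray(subset, dtype=bool)
        if subset.shape[0] != len(recs):
            raise ValueError("subset mask length does not match record count")
        recs = recs[subset].reset_index(drop=True)
    y = recs["value"].to_numpy()
    env = recs["environment"].to_numpy()
    X = panel.calls[panel.row_index(recs["individual_id"])]
    dummies, _ = _env_design(env)
    p1_raw, p2_raw, eff = _scan_block(y, env, dummies, X)
    constant = np.ptp(X, axis=0) == 0
    return GwasResult(
        marker_ids=list(panel.marker_ids),
        pvalue1_raw=p1_raw,
        pvalue2_raw=p2_raw,
        pvalue1_adj=fdr_adjust(p1_raw),
        pvalue2_adj=fdr_adjust(p2_raw),
        effect=eff,
        constant=constant,
    )
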