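"""Cross-validation harness: CV2 partitioning, per-partition reweighting,
bandwidth-shape (beta) selection, and model-variant comparison.

The protocol mirrors a multi-environment genomic-selection benchmark: 70% of
the data is training (TRN), 30% testing (TST), repeated 50 times, scoring
Pearson correlation (PCOR) and mean squared error (MSE) per environment.
Two holdout modes are provided: ``line`` holds out whole individuals (the
same id set missing from every environment) and ``cell`` holds out
(individual, environment) cells independently within each environment, the
classical CV2 scheme where individuals are observed in some environments
and predicted in others.

MAF, GWAS p-values, marker weights and the beta-grid choice are recomputed
inside every partition from training records only; nothing derived from
test phenotypes reaches the kernels.

Model variants: SE_GK (per-environment single-environment fits), ME_GK
(multi-environment, unweighted Gaussian kernel), and ME_WK_MAF /
ME_WK_Pvalue / ME_WK_MAF_Pvalue (multi-environment weighted kernels).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bayes, gwas, kernels
from .geno_pheno import compute_maf

log = logging.getLogger(__name__)

__all__ = ["CVPartition", "CVReport", "make_partitions", "pcor", "mse",
           "select_beta", "run_experiment", "VARIANTS"]

VARIANTS = ("SE_GK", "ME_GK", "ME_WK_MAF", "ME_WK_Pvalue", "ME_WK_MAF_Pvalue")


@dataclass
class CVPartition:
    """One TRN/TST split over a trait's records (environment-major order)."""

    replicate: int
    train_mask: np.ndarray
    test_mask: np.ndarray
    mode: str
    seed: int

    def __post_init__(self) -> None:
        if np.any(self.train_mask & self.test_mask):
            raise ValueError("train and test overlap")
        if not np.all(self.train_mask | self.test_mask):
            raise ValueError("train and test do not cover all records")


@dataclass
class CVReport:
    """Per-(variant, environment, replicate) scores plus aggregation."""

    records: pd.DataFrame
    failures: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        g = self.records.groupby(["variant", "environment"])
        out = g.agg(pcor_mean=("pcor", "mean"),
                    pcor_se=("pcor", lambda x: x.std(ddof=1) / np.sqrt(len(x))),
                    mse_mean=("mse", "mean"),
                    mse_se=("mse", lambda x: x.std(ddof=1) / np.sqrt(len(x))),
                    n_replicates=("replicate", "nunique"))
        return out.reset_index()

    def write(self, path_records, path_summary=None) -> None:
        self.records.to_csv(path_records, sep="\t", index=False)
        if path_summary is not None:
            self.summary().to_csv(path_summary, sep="\t", index=False)


def pcor(observed, predicted) -> float:
    """Sample Pearson correlation; NaN if either vector has zero variance."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.size != p.size:
        raise ValueError("length mismatch")
    if o.size < 3:
        raise ValueError("need at least 3 pairs")
    if o.std() == 0 or p.std() == 0:
        return float("nan")
    return float(np.corrcoef(o, p)[0, 1])


def mse(observed, predicted) -> float:
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.size != p.size:
        raise ValueError("length mismatch")
    return float(np.mean((o - p) ** 2))


def make_partitions(phenos, trait: str | None = None, n_reps: int = 50,
                    train_frac: float = 0.7, mode: str = "line",
                    seed: int = 0, min_test: int = 5) -> list[CVPartition]:
    """Seeded random TRN/TST splits of a trait's records."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    if mode not in ("line", "cell"):
        raise ValueError(f"unknown holdout mode {mode!r}")
    if trait is None:
        trait = phenos.traits[0]
    recs = phenos.for_trait(trait)
    n = len(recs)
    envs = recs["environment"].to_numpy()
    ids = recs["individual_id"].to_numpy()
    rng = np.random.default_rng(seed)
    parts = []
    for rep in range(n_reps):
        train = np.zeros(n, dtype=bool)
        if mode == "line":
            uniq = np.unique(ids)
            n_train = int(round(train_frac * uniq.size))
            chosen = set(rng.choice(uniq, size=n_train, replace=False))
            train = np.array([i in chosen for i in ids])
        else:
            for env in np.unique(envs):
                pos = np.where(envs == env)[0]
                n_train = int(round(train_frac * pos.size))
                chosen = rng.choice(pos, size=n_train, replace=False)
                train[chosen] = True
        test = ~train
        for env in np.unique(envs):
            if test[envs == env].sum() < min_test:
                raise ValueError(
                    f"fewer than {min_test} test records in environment {env}")
        parts.append(CVPartition(replicate=rep, train_mask=train, test_mask=test,
                                 mode=mode, seed=seed))
    return parts


def _train_hash(ids, envs, mask) -> str:
    key = ";".join(f"{i}|{e}" for i, e, m in zip(ids, envs, mask) if m)
    return hashlib.sha256(key.encode()).hexdigest()[:16]


def _compute_weights(panel, phenos, trait, train_mask, scheme, alpha, beta_val):
    """MAF/GWAS-based marker weights from training records only."""
    recs = phenos.for_trait(trait)
    train_ids = sorted(set(recs["individual_id"][train_mask]))
    maf = compute_maf(panel.subset_rows(train_ids))
    res = gwas.run_gwas(panel, phenos, trait, subset=train_mask)
    if scheme == "MAF_Pvalue":
        return kernels.weights_maf_pvalue(maf, res.pvalue1_adj, res.pvalue2_adj,
                                          alpha=alpha, beta=beta_val)
    if scheme == "MAF":
        return kernels.weights_maf(maf, alpha=alpha, beta=beta_val,
                                   pvalue1=res.pvalue1_adj, pvalue2=res.pvalue2_adj)
    if scheme == "Pvalue":
        return kernels.weights_pvalue(res.pvalue1_adj, res.pvalue2_adj)
    raise ValueError(f"unknown weighting scheme {scheme!r}")


def _pick_regime(ids, envs, mask) -> str:
    """kronecker when the training lines are identical across environments."""
    sets = {}
    for i, e, m in zip(ids, envs, mask):
        if m:
            sets.setdefault(e, set()).add(i)
    first = None
    for s in sets.values():
        if first is None:
            first = s
        elif s != first:
            return "general"
    return "kronecker"


def _fit_predict_me(panel, phenos, trait, weights, h, train_mask, test_mask,
                    background, iters, burnin, seed, thin, regime=None):
    recs = phenos.for_trait(trait)
    record_ids = list(zip(recs["individual_id"], recs["environment"]))
    kset = kernels.assemble_kernel_set(panel, {}, weights=weights, h=h,
                                       record_ids=record_ids)
    ids = recs["individual_id"].to_numpy()
    envs = recs["environment"].to_numpy()
    if regime is None:
        regime = _pick_regime(ids, envs, train_mask)
    if regime == "kronecker" and background.mode != "identity":
        regime = "general"
    fit = bayes.fit_me(phenos, kset, background, iters=iters, burnin=burnin,
                       seed=seed, regime=regime, trait=trait,
                       train_mask=train_mask, thin_latent=thin)
    pred = bayes.predict_cv2(fit, kset, background, train_mask, test_mask,
                             thin=thin)
    return pred


def _fit_predict_se(panel, phenos, trait, h, train_mask, test_mask,
                    iters, burnin, seed, thin):
    """Per-environment SE fits; returns predictions aligned to test records."""
    recs = phenos.for_trait(trait)
    envs = recs["environment"].to_numpy()
    ids = recs["individual_id"].to_numpy()
    y = recs["value"].to_numpy()
    pred = np.full(len(recs), np.nan)
    for env in np.unique(envs):
        sel = envs == env
        sel_tr = sel & train_mask
        sel_te = sel & test_mask
        env_ids = ids[sel]
        rows = panel.calls[panel.row_index(env_ids)]
        K = kernels.gaussian_kernel(rows, h=h)  # per-environment normalizer
        local = np.where(sel)[0]
        loc_tr = np.where(np.isin(local, np.where(sel_tr)[0]))[0]
        loc_te = np.where(np.isin(local, np.where(sel_te)[0]))[0]
        K_tr = K[np.ix_(loc_tr, loc_tr)]
        fit = bayes.fit_se(y[sel_tr], K_tr, None, iters=iters, burnin=burnin,
                           seed=seed)
        B_full = np.eye(K.shape[0])
        pred[sel_te] = bayes.predict_se(fit, K, B_full, loc_tr, loc_te, thin=thin)
    return pred


def select_beta(panel, phenos, trait, train_mask, beta_grid, scheme,
                alpha=1.0, h=1.0, background_mode: str = "identity",
                families: dict | None = None, iters=2000, burnin=1000,
                seed=0, inner_reps: int = 5, inner_frac: float = 0.8,
                holdout: str = "line", thin: int = 10):
    """Choose beta by inner cross-validation entirely within training records.

    The training records are re-split ``inner_reps`` times (80/20 by
    default); MAF and GWAS p-values are recomputed on each inner training
    set. Returns the grid value with the highest mean inner PCOR, ties
    broken toward the smaller beta. A single-element grid short-circuits.
    """
    beta_grid = sorted(beta_grid)
    if len(beta_grid) == 0:
        raise ValueError("beta grid is empty")
    if len(beta_grid) == 1:
        return beta_grid[0], None
    recs = phenos.for_trait(trait)
    train_idx = np.where(train_mask)[0]
    inner_phenos_df = recs.iloc[train_idx].reset_index(drop=True)
    from .geno_pheno import PhenotypeTable
    inner_phenos = PhenotypeTable(inner_phenos_df)
    inner_parts = make_partitions(inner_phenos, trait, n_reps=inner_reps,
                                  train_frac=inner_frac, mode=holdout,
                                  seed=seed, min_test=2)
    background = bayes.build_background(inner_phenos, trait, families=families,
                                        mode=background_mode)
    scores = {b: [] for b in beta_grid}
    for part in inner_parts:
        for b in beta_grid:
            try:
                w = _compute_weights(panel, inner_phenos, trait, part.train_mask,
                                     scheme, alpha, b)
                pred = _fit_predict_me(panel, inner_phenos, trait, w, h,
                                       part.train_mask, part.test_mask,
                                       background, iters, burnin, seed, thin)
                obs = inner_phenos.for_trait(trait)["value"].to_numpy()
                scores[b].append(pcor(obs[part.test_mask], pred))
            except Exception as exc:  # noqa: BLE001 - recorded, not silenced
                log.warning("inner fold failed for beta=%s: %s", b, exc)
    means = {b: (np.nanmean(v) if v else -np.inf) for b, v in scores.items()}
    return _choose_beta(means), means


def _choose_beta(means: dict) -> float:
    """Highest mean inner PCOR wins; ties go to the smaller beta."""
    return max(sorted(means), key=lambda b: (means[b], -b))


def run_experiment(panel, phenos, trait: str | None = None,
                   variants=("SE_GK", "ME_GK", "ME_WK_MAF_Pvalue"),
                   n_reps: int = 50, train_frac: float = 0.7,
                   holdout: str = "line", seed: int = 0,
                   beta_grid=kernels.DEFAULT_BETA_GRID, alpha: float = 1.0,
                   h: float = 1.0, families: dict | None = None,
                   background_mode: str = "identity",
                   iters_me: int | None = None, burnin_me: int | None = None,
                   iters_se: int = 12000, burnin_se: int = 6000,
                   inner_iters: int = 2000, inner_burnin: int = 1000,
                   inner_reps: int = 5, thin: int = 10) -> CVReport:
    """Full benchmark: partition, reweight, fit, predict and score."""
    bad = [v for v in variants if v not in VARIANTS]
    if bad:
        raise ValueError(f"unknown variants {bad}; choose from {VARIANTS}")
    if trait is None:
        trait = phenos.traits[0]
    recs = phenos.for_trait(trait)
    y = recs["value"].to_numpy()
    envs = recs["environment"].to_numpy()
    ids = recs["individual_id"].to_numpy()
    background = bayes.build_background(phenos, trait, families=families,
                                        mode=background_mode)
    parts = make_partitions(phenos, trait, n_reps=n_reps,
                            train_frac=train_frac, mode=holdout, seed=seed)
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s) % (2 ** 31) for s in ss.generate_state(n_reps)]
    rows = []
    failures = []
    scheme_of = {"ME_WK_MAF": "MAF", "ME_WK_Pvalue": "Pvalue",
                 "ME_WK_MAF_Pvalue": "MAF_Pvalue"}
    default_iters = {"kronecker": (20000, 10000), "general": (100000, 50000)}
    regime = _pick_regime(ids, envs, np.ones(len(ids), dtype=bool))
    if background_mode != "identity":
        regime = "general"
    it_me = iters_me if iters_me is not None else default_iters[regime][0]
    bi_me = burnin_me if burnin_me is not None else default_iters[regime][1]

    for part, rseed in zip(parts, rep_seeds):
        thash = _train_hash(ids, envs, part.train_mask)
        for variant in variants:
            try:
                chosen_beta = np.nan
                if variant == "SE_GK":
                    pred = _fit_predict_se(panel, phenos, trait, h,
                                           part.train_mask, part.test_mask,
                                           iters_se, burnin_se, rseed, thin)
                else:
                    weights = None
                    if variant in scheme_of:
                        scheme = scheme_of[variant]
                        if scheme in ("MAF", "MAF_Pvalue"):
                            chosen_beta, _ = select_beta(
                                panel, phenos, trait, part.train_mask,
                                beta_grid, scheme, alpha=alpha, h=h,
                                background_mode=background_mode,
                                families=families,
                                iters=inner_iters, burnin=inner_burnin,
                                seed=rseed, inner_reps=inner_reps,
                                holdout=holdout, thin=thin)
                        else:
                            chosen_beta = np.nan
                        weights = _compute_weights(
                            panel, phenos, trait, part.train_mask, scheme,
                            alpha, chosen_beta if scheme != "Pvalue" else 25)
                    pred = _fit_predict_me(panel, phenos, trait, weights, h,
                                           part.train_mask, part.test_mask,
                                           background, it_me, bi_me, rseed,
                                           thin)
                for env in np.unique(envs):
                    sel = (envs == env) & part.test_mask
                    if variant == "SE_GK":
                        pred_env = pred[sel]
                    else:
                        te = np.where(part.test_mask)[0]
                        pred_env = pred[np.isin(te, np.where(sel)[0])]
                    rows.append({
                        "variant": variant, "environment": env,
                        "replicate": part.replicate,
                        "pcor": pcor(y[sel], pred_env),
                        "mse": mse(y[sel], pred_env),
                        "beta": chosen_beta, "train_hash": thash,
                    })
            except Exception as exc:  # noqa: BLE001
                log.warning("replicate %d variant %s failed: %s",
                            part.replicate, variant, exc)
                failures.append({"replicate": part.replicate,
                                 "variant": variant, "error": str(exc)})
    report = CVReport(records=pd.DataFrame(rows), failures=failures)
    if failures:
        log.warning("%d replicate-variant runs failed and were excluded",
                    len(failures))
    return report
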