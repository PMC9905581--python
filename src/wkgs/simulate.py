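"""Synthetic genotype/phenotype generators matching the models' assumptions.

Two designs are emulated:

* ``dh_shared_lines`` — a doubled-haploid population: fully homozygous lines
  (dosages 0/2) genotyped once and phenotyped in every environment, with a
  bimodal MAF spectrum (a rare-variant mass below 0.2 plus a common mass
  near 0.4-0.5; default 64% of markers below MAF 0.2, as in a wheat DH
  panel).
* ``half_sib_disjoint`` — open-pollinated half-sib families: each family has
  a common parent, offspring share one parental gamete, individuals are
  disjoint across environments but families span them, and the MAF spectrum
  is rare-allele-heavy (default 88% below 0.2, as in a conifer panel).

Phenotypes follow y = mu + g + b + e: QTL effects are drawn with a
configurable cross-environment correlation (shared-plus-specific
decomposition), the residual variance is set per environment to hit the
target heritability, and an optional family-level background effect adds
variance sigma2_b. Markers are independent (no linkage disequilibrium).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno_pheno import GenotypePanel, PhenotypeTable

__all__ = ["SimConfig", "SimTruth", "simulate_genotypes", "simulate_phenotypes",
           "subsample_families", "simulate_dataset"]


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    design: str = "dh_shared_lines"   # or "half_sib_disjoint"
    n: int = 242                      # individuals (lines, or per environment)
    m: int = 3                        # environments
    p: int = 1000                     # markers
    frac_rare: float = 0.64           # target fraction of markers with MAF < 0.2
    n_qtl: int = 50
    h2: float | tuple = 0.5           # per-environment heritability target
    genetic_corr: float | np.ndarray = 0.8
    n_families: int = 25              # half-sib design only
    family_size: int = 10             # offspring per family per environment
    sigma2_b: float = 0.0             # family background variance (phenotype scale)
    rare_effect_coupling: float = 1.0 # kappa in effect ~ [2f(1-f)]^(-kappa/2);
                                      # 1 = equal variance per QTL (inverse
                                      # frequency-effect relationship), 0 = raw
                                      # allele-substitution effects
    mu: float | tuple = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in ("dh_shared_lines", "half_sib_disjoint"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_qtl > self.p:
            raise ValueError("n_qtl cannot exceed p")
        h2 = np.broadcast_to(np.asarray(self.h2, dtype=float), (self.m,))
        if np.any(h2 <= 0) or np.any(h2 >= 1):
            raise ValueError("heritabilities must lie in (0, 1)")
        R = self.corr_matrix()
        np.linalg.cholesky(R + 1e-10 * np.eye(self.m))

    def corr_matrix(self) -> np.ndarray:
        R = np.asarray(self.genetic_corr, dtype=float)
        if R.ndim == 0:
            R = np.full((self.m, self.m), float(R))
            np.fill_diagonal(R, 1.0)
        return R

    def h2_vector(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.h2, dtype=float), (self.m,)).copy()

    def mu_vector(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.mu, dtype=float), (self.m,)).copy()


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset, for recovery tests."""

    qtl_indices: np.ndarray
    effects: np.ndarray            # n_qtl x m per-environment allele effects
    genetic_values: pd.DataFrame   # individual_id, environment, g
    realized_h2: np.ndarray
    realized_genetic_corr: np.ndarray
    sigma2_e: np.ndarray

    def write(self, path) -> None:
        self.genetic_values.to_csv(path, sep="\t", index=False)


def _draw_maf_spectrum(rng, p: int, frac_rare: float) -> np.ndarray:
    """Bimodal allele-frequency spectrum: rare mass below 0.2, common near 0.5."""
    rare = rng.random(p) < frac_rare
    maf = np.empty(p)
    # rare component concentrated under 0.2 with most mass below 0.1
    maf[rare] = 0.2 * rng.beta(0.6, 1.6, size=rare.sum())
    # common component: a mode in the 0.4-0.5 bin
    maf[~rare] = 0.2 + 0.3 * rng.beta(2.0, 1.0, size=(~rare).sum())
    maf = np.clip(maf, 1e-4, 0.5)
    # random allele labelling so dosage means are not systematically low
    f = np.where(rng.random(p) < 0.5, maf, 1.0 - maf)
    return f


def simulate_genotypes(cfg: SimConfig) -> GenotypePanel:
    rng = np.random.default_rng(cfg.seed)
    f = _draw_maf_spectrum(rng, cfg.p, cfg.frac_rare)
    marker_ids = [f"M{l:05d}" for l in range(cfg.p)]
    if cfg.design == "dh_shared_lines":
        # fully homozygous lines: dosage 0 or 2, genotyped once
        calls = 2.0 * (rng.random((cfg.n, cfg.p)) < f)
        ids = [f"L{i:04d}" for i in range(cfg.n)]
        return GenotypePanel(individual_ids=ids, marker_ids=marker_ids, calls=calls)
    # half-sib: one common parent per family; offspring inherit one parental
    # gamete, the other from the population
    env_labels = [f"E{j+1}" for j in range(cfg.m)]
    per_env = cfg.n_families * cfg.family_size
    ids, envs, fams, rows = [], {}, {}, []
    for fam in range(cfg.n_families):
        parent = rng.random((2, cfg.p)) < f   # two parental haplotypes
        for j, env in enumerate(env_labels):
            pick = rng.integers(0, 2, size=(cfg.family_size, cfg.p))
            from_parent = np.where(pick == 0, parent[0], parent[1])
            from_pop = rng.random((cfg.family_size, cfg.p)) < f
            rows.append(from_parent.astype(float) + from_pop.astype(float))
            for o in range(cfg.family_size):
                iid = f"F{fam:03d}_{env}_{o:03d}"
                ids.append(iid)
                envs[iid] = env
                fams[iid] = f"F{fam:03d}"
    calls = np.vstack(rows)
    return GenotypePanel(individual_ids=ids, marker_ids=marker_ids, calls=calls,
                        env_of=envs, family_of=fams)


def simulate_phenotypes(panel: GenotypePanel, cfg: SimConfig,
                        trait: str = "trait") -> tuple[PhenotypeTable, SimTruth]:
    rng = np.random.default_rng(cfg.seed + 1)
    m = cfg.m
    env_labels = [f"E{j+1}" for j in range(m)]
    R = cfg.corr_matrix()
    h2 = cfg.h2_vector()
    mu = cfg.mu_vector()
    lam, U = np.linalg.eigh(R)
    LR = U * np.sqrt(np.clip(lam, 0.0, None))  # exact PSD square root
    qtl = rng.choice(cfg.p, size=cfg.n_qtl, replace=False)
    effects = rng.standard_normal((cfg.n_qtl, m)) @ LR.T  # rows ~ N(0, R)
    X = panel.calls[:, qtl]
    freq = panel.calls.mean(axis=0)[qtl] / 2.0
    if cfg.rare_effect_coupling > 0:
        het = np.clip(2.0 * freq * (1.0 - freq), 1e-4, None)
        effects = effects * het[:, None] ** (-0.5 * cfg.rare_effect_coupling)
    Xc = X - X.mean(axis=0, keepdims=True)
    gmat_by_ind = Xc @ effects  # n_individuals x m genetic values

    records = []
    gvals = []
    if cfg.design == "dh_shared_lines":
        env_rows = {env: np.arange(panel.n_individuals) for env in env_labels}
    else:
        env_rows = {env: np.array([i for i, iid in enumerate(panel.individual_ids)
                                   if panel.env_of[iid] == env])
                    for env in env_labels}
    var_g = np.empty(m)
    sigma2_e = np.empty(m)
    g_cols = {}
    for j, env in enumerate(env_labels):
        rows_j = env_rows[env]
        g = gmat_by_ind[rows_j, j]
        vg = g.var()
        if vg <= 0:
            raise ValueError("zero genetic variance; heritability unreachable")
        var_g[j] = vg
        sigma2_e[j] = vg * (1.0 - h2[j]) / h2[j] - cfg.sigma2_b
        if sigma2_e[j] <= 0:
            raise ValueError("sigma2_b too large for the target heritability")
        g_cols[env] = (rows_j, g)

    fam_effect = {}
    if cfg.sigma2_b > 0 and panel.family_of:
        for famid in sorted(set(panel.family_of.values())):
            fam_effect[famid] = rng.normal(0.0, np.sqrt(cfg.sigma2_b))

    for j, env in enumerate(env_labels):
        rows_j, g = g_cols[env]
        e = rng.normal(0.0, np.sqrt(sigma2_e[j]), size=rows_j.size)
        bvals = np.zeros(rows_j.size)
        if fam_effect:
            bvals = np.array([fam_effect[panel.family_of[panel.individual_ids[i]]]
                              for i in rows_j])
        yvals = mu[j] + g + bvals + e
        for idx, i in enumerate(rows_j):
            iid = panel.individual_ids[i]
            records.append({"individual_id": iid, "environment": env,
                            "trait": trait, "value": yvals[idx]})
            gvals.append({"individual_id": iid, "environment": env, "g": g[idx]})

    phenos = PhenotypeTable(pd.DataFrame(records))
    gdf = pd.DataFrame(gvals)
    # realized quantities
    realized_h2 = np.empty(m)
    for j, env in enumerate(env_labels):
        sub = phenos.records[(phenos.records["environment"] == env)]
        gsub = gdf[gdf["environment"] == env]["g"].to_numpy()
        realized_h2[j] = gsub.var() / sub["value"].var()
    if cfg.design == "dh_shared_lines":
        gm = np.column_stack([gdf[gdf["environment"] == e]["g"].to_numpy()
                              for e in env_labels])
        realized_corr = np.corrcoef(gm.T)
    else:
        realized_corr = np.corrcoef(effects.T) if cfg.n_qtl > 1 else np.eye(m)
    truth = SimTruth(qtl_indices=qtl, effects=effects, genetic_values=gdf,
                     realized_h2=realized_h2,
                     realized_genetic_corr=np.atleast_2d(realized_corr),
                     sigma2_e=sigma2_e)
    return phenos, truth


def subsample_families(panel: GenotypePanel, phenos: PhenotypeTable,
                       per_family_n: int, seed: int = 0):
    """Reduce every family to ``per_family_n`` individuals per environment."""
    if panel.family_of is None or panel.env_of is None:
        raise ValueError("subsampling requires family and environment labels")
    rng = np.random.default_rng(seed)
    keep: list[str] = []
    groups: dict[tuple, list[str]] = {}
    for iid in panel.individual_ids:
        groups.setdefault((panel.family_of[iid], panel.env_of[iid]), []).append(iid)
    for (fam, env), members in sorted(groups.items()):
        if len(members) < per_family_n:
            raise ValueError(
                f"family {fam} has only {len(members)} individuals in {env}")
        chosen = rng.choice(len(members), size=per_family_n, replace=False)
        keep.extend(members[i] for i in sorted(chosen))
    keep_set = set(keep)
    sub_panel = panel.subset_rows(keep)
    sub_recs = phenos.records[phenos.records["individual_id"].isin(keep_set)]
    return sub_panel, PhenotypeTable(sub_recs.reset_index(drop=True))


def simulate_dataset(cfg: SimConfig, trait: str = "trait"):
    """Convenience wrapper: genotypes + phenotypes + truth in one call."""
    panel = simulate_genotypes(cfg)
    phenos, truth = simulate_phenotypes(panel, cfg, trait=trait)
    return panel, phenos, truth
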