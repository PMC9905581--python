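"""Gaussian and weighted genomic kernels with MAF/association marker weights.

The Gaussian kernel maps squared Euclidean marker distance d2_ik into a
similarity exp(-h * d2_ik / s), with s the sample maximum of d2 so entries
lie in (0, 1] and the largest-distance pair sits at exp(-h). The weighted
kernel replaces d2 with a weighted distance d*2_ik = sum_l w_l (x_il - x_kl)^2
whose per-marker weights combine two signals:

* a Beta(MAF_l; alpha, beta) density that up-weights rare variants, scaled by
  a constant c1 chosen so the MAF term and the association terms have
  comparable maxima (c1 = max_l 1/(0.1 + p_l) over both p-value vectors,
  divided by Beta(min MAF; alpha, beta)); with alpha = 1 and both minima at
  zero, c1 ~= 10 / beta;
* inverse shifted FDR-adjusted p-values 1/(0.1 + p) for the marker main
  effect and its marker-by-environment interaction from a G x E GWAS.

Three weighting schemes are supported: MAF only, p-value only, and combined.
Weights are always squared, so they are nonnegative, and the weighted
distance is scale-invariant in the weights (a common factor cancels in
d*2 / s*), which makes the uniform-weight case coincide with the Gaussian
kernel exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import beta as beta_dist

__all__ = [
    "MarkerWeights",
    "KernelSet",
    "beta_density",
    "compute_c1",
    "weights_maf_pvalue",
    "weights_maf",
    "weights_pvalue",
    "gaussian_kernel",
    "weighted_kernel",
    "additive_kernel",
    "assemble_kernel_set",
    "write_weights",
]

PVALUE_SHIFT = 0.1  # shift in 1/(0.1 + p); caps a zero p-value's term at 10
DEFAULT_BETA_GRID = (12, 25, 50, 100, 200)


@dataclass
class MarkerWeights:
    """Per-marker weight vector plus the components it was built from."""

    w: np.ndarray
    scheme: str  # "MAF" | "Pvalue" | "MAF_Pvalue"
    alpha: float = 1.0
    beta: float | None = None
    c1: float | None = None
    maf: np.ndarray | None = None
    pvalue1: np.ndarray | None = None
    pvalue2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 1:
            raise ValueError("weights must be a vector")
        if (self.w < 0).any():
            raise ValueError("marker weights must be nonnegative")


@dataclass
class KernelSet:
    """Within- and cross-environment kernel blocks sharing one normalizer.

    ``full`` is the (sum n_j) x (sum n_j) kernel over all phenotyped records
    in environment-major order; ``blocks[(j, k)]`` are its sub-matrices.
    """

    environments: list[str]
    blocks: dict = field(default_factory=dict)
    full: np.ndarray | None = None
    h: float = 1.0
    normalizer: float | None = None
    record_envs: np.ndarray | None = None  # env label per row of ``full``
    record_ids: list[str] | None = None

    def env_slice(self, env: str) -> np.ndarray:
        return np.where(self.record_envs == env)[0]


# ---------------------------------------------------------------------------
# Weights


def beta_density(x, alpha: float, beta: float):
    """Beta(x; alpha, beta) density; with alpha = 1 this is beta*(1-x)^(beta-1)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("beta_density defined on [0, 1]")
    out = beta_dist.pdf(x, alpha, beta)
    return float(out) if out.ndim == 0 else out


def _inv_shifted(p: np.ndarray) -> np.ndarray:
    return 1.0 / (PVALUE_SHIFT + p)


def _check_pvalues(*vecs) -> list[np.ndarray]:
    out = []
    n = None
    for v in vecs:
        v = np.asarray(v, dtype=float)
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("p-values must lie in [0, 1]")
        if n is not None and v.shape != n:
            raise ValueError("p-value/MAF vectors must share one length")
        n = v.shape
        out.append(v)
    return out


def compute_c1(pvalue1, pvalue2, maf, alpha: float = 1.0, beta: float = 25.0) -> float:
    """Scaling constant for the MAF term of the marker weights.

    c1 = max over both adjusted p-value vectors of 1/(0.1 + p), divided by
    the Beta density at the smallest MAF. When the smallest adjusted p-value
    and the smallest MAF are both 0 (alpha = 1), this reduces to 10 / beta.
    """
    pvalue1, pvalue2, maf = _check_pvalues(pvalue1, pvalue2, maf)
    num = max(_inv_shifted(pvalue1).max(), _inv_shifted(pvalue2).max())
    den = beta_density(float(maf.min()), alpha, beta)
    if den <= 0 or not np.isfinite(den):
        raise ValueError(
            f"Beta density at min MAF {maf.min():g} is {den:g}; cannot scale"
        )
    return float(num / den)


def weights_maf_pvalue(maf, pvalue1, pvalue2, alpha: float = 1.0,
                       beta: float = 25.0) -> MarkerWeights:
    """Combined weights (c1*Beta(MAF) + 1/(0.1+p1) + 1/(0.1+p2))^2."""
    maf, pvalue1, pvalue2 = _check_pvalues(maf, pvalue1, pvalue2)
    c1 = compute_c1(pvalue1, pvalue2, maf, alpha, beta)
    base = c1 * beta_density(maf, alpha, beta) + _inv_shifted(pvalue1) + _inv_shifted(pvalue2)
    return MarkerWeights(w=base ** 2, scheme="MAF_Pvalue", alpha=alpha, beta=beta,
                         c1=c1, maf=maf, pvalue1=pvalue1, pvalue2=pvalue2)


def weights_maf(maf, alpha: float = 1.0, beta: float = 25.0,
                pvalue1=None, pvalue2=None) -> MarkerWeights:
    """MAF-only weights (c1*Beta(MAF))^2; p-values enter only through c1."""
    if pvalue1 is None or pvalue2 is None:
        raise ValueError("p-value vectors are required to form c1")
    maf, pvalue1, pvalue2 = _check_pvalues(maf, pvalue1, pvalue2)
    c1 = compute_c1(pvalue1, pvalue2, maf, alpha, beta)
    base = c1 * beta_density(maf, alpha, beta)
    return MarkerWeights(w=base ** 2, scheme="MAF", alpha=alpha, beta=beta,
                         c1=c1, maf=maf, pvalue1=pvalue1, pvalue2=pvalue2)


def weights_pvalue(pvalue1, pvalue2) -> MarkerWeights:
    """Association-only weights (1/(0.1+p1) + 1/(0.1+p2))^2; no MAF term."""
    pvalue1, pvalue2 = _check_pvalues(pvalue1, pvalue2)
    base = _inv_shifted(pvalue1) + _inv_shifted(pvalue2)
    return MarkerWeights(w=base ** 2, scheme="Pvalue",
                         pvalue1=pvalue1, pvalue2=pvalue2)


def write_weights(weights: MarkerWeights, marker_ids, path) -> None:
    p = len(weights.w)
    df = pd.DataFrame({
        "marker_id": list(marker_ids),
        "maf": weights.maf if weights.maf is not None else [np.nan] * p,
        "pvalue1_adj": weights.pvalue1 if weights.pvalue1 is not None else [np.nan] * p,
        "pvalue2_adj": weights.pvalue2 if weights.pvalue2 is not None else [np.nan] * p,
        "weight": weights.w,
    })
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Kernels


def _sq_dist(a: np.ndarray, b: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
    if w is None:
        return cdist(a, b, metric="sqeuclidean")
    return cdist(a, b, metric="sqeuclidean", w=w)


def _kernel_from_dist(d2: np.ndarray, h: float, normalizer: float | None) -> tuple[np.ndarray, float]:
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    s = float(d2.max()) if normalizer is None else float(normalizer)
    if s <= 0:
        raise ValueError("degenerate input: all genotypes identical (max distance 0)")
    return np.exp(-h * d2 / s), s


def gaussian_kernel(rows_a, rows_b=None, h: float = 1.0,
                    normalizer: float | None = None) -> np.ndarray:
    """Gaussian kernel block exp(-h d2/s) between two genotype sub-matrices.

    If ``normalizer`` is None, s is the maximum squared distance within the
    supplied rows (appropriate for a single-environment kernel read in
    isolation); multi-environment assembly passes the global maximum instead.
    """
    a = np.asarray(rows_a, dtype=float)
    b = a if rows_b is None else np.asarray(rows_b, dtype=float)
    K, _ = _kernel_from_dist(_sq_dist(a, b), h, normalizer)
    return K


def weighted_kernel(rows_a, rows_b=None, weights: MarkerWeights | None = None,
                    h: float = 1.0, normalizer: float | None = None) -> np.ndarray:
    """Weighted kernel block exp(-h d*2/s*), d*2 = sum_l w_l (x_il - x_kl)^2."""
    if weights is None:
        raise ValueError("weighted_kernel requires MarkerWeights")
    a = np.asarray(rows_a, dtype=float)
    b = a if rows_b is None else np.asarray(rows_b, dtype=float)
    w = weights.w
    if w.shape[0] != a.shape[1]:
        raise ValueError(
            f"weight length {w.shape[0]} does not match marker count {a.shape[1]}"
        )
    if (w < 0).any():
        raise ValueError("marker weights must be nonnegative")
    K, _ = _kernel_from_dist(_sq_dist(a, b, w), h, normalizer)
    return K


def additive_kernel(rows) -> np.ndarray:
    """Linear (GBLUP) relationship matrix ZZ'/c from centered dosages.

    c is the average diagonal of ZZ', so the kernel has mean diagonal 1; used
    for narrow-sense heritability estimation under the GBLUP convention.
    """
    x = np.asarray(rows, dtype=float)
    z = x - x.mean(axis=0, keepdims=True)
    zz = z @ z.T
    c = np.trace(zz) / zz.shape[0]
    if c <= 0:
        raise ValueError("degenerate input: no marker variance")
    return zz / c


def assemble_kernel_set(panel, env_membership: dict, weights: MarkerWeights | None = None,
                        h: float = 1.0, record_ids=None) -> KernelSet:
    """Full multi-environment kernel with one shared normalizer.

    ``env_membership`` maps record (individual) id -> environment label; the
    same individual id may appear under several environments via
    ``record_ids``, a list of (individual_id, environment) pairs. If
    ``record_ids`` is None it is derived from ``env_membership`` directly
    (each individual phenotyped once).

    One global maximum squared distance over all record pairs scales every
    block, so the assembled matrix is a valid positive semidefinite kernel
    and K_jk = K_kj'.
    """
    if record_ids is None:
        record_ids = sorted(env_membership.items(), key=lambda t: (t[1], t[0]))
    else:
        record_ids = list(record_ids)
    envs = sorted({e for _, e in record_ids})
    # environment-major record order
    record_ids.sort(key=lambda t: (t[1], t[0]))
    ids = [i for i, _ in record_ids]
    rec_envs = np.array([e for _, e in record_ids])
    rows = panel.calls[panel.row_index(ids)]
    w = weights.w if weights is not None else None
    d2 = _sq_dist(rows, rows, w)
    full, s = _kernel_from_dist(d2, h, None)
    # exact unit diagonal / symmetry despite float round-off
    full = 0.5 * (full + full.T)
    np.fill_diagonal(full, 1.0)
    blocks = {}
    for j in envs:
        for k in envs:
            blocks[(j, k)] = full[np.ix_(np.where(rec_envs == j)[0],
                                         np.where(rec_envs == k)[0])]
    return KernelSet(environments=envs, blocks=blocks, full=full, h=h,
                     normalizer=s, record_envs=rec_envs, record_ids=ids)
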