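"""Genotype/phenotype containers, file I/O and preprocessing.

Genotypes are biallelic SNP dosages coded 0/1/2 (AA, Aa, aa), one row per
individual and one column per marker, with missing calls allowed on input.
Phenotypes are long-format records (individual, environment, trait, value)
so the same genotype row can be referenced from several environments
(replicated lines) or each individual can appear in exactly one environment
(disjoint designs such as multi-site half-sib trials).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "GenotypePanel",
    "PhenotypeTable",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_families",
    "filter_missing",
    "impute_marker_mean",
    "compute_maf",
]


@dataclass
class GenotypePanel:
    """Individuals x markers dosage matrix with optional metadata.

    ``calls`` is a float array; missing calls are ``nan`` until imputation,
    after which every entry lies in [0, 2] (marker-mean imputation yields
    fractional dosages, which the Euclidean kernels accept).
    """

    individual_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray
    env_of: dict[str, str] | None = None
    family_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        n, p = self.calls.shape
        if n != len(self.individual_ids) or p != len(self.marker_ids):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.marker_ids)} markers"
            )
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.marker_ids)) != p:
            raise ValueError("duplicate marker ids")
        observed = self.calls[~np.isnan(self.calls)]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.calls).sum())

    def row_index(self, ids) -> np.ndarray:
        """Positions of ``ids`` among the panel's individuals."""
        lookup = {ind: i for i, ind in enumerate(self.individual_ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message check in tests
            raise KeyError(f"individual {exc.args[0]!r} has no genotype row") from None

    def subset_rows(self, ids) -> "GenotypePanel":
        """View-like panel restricted to ``ids`` (training rows during CV)."""
        idx = self.row_index(ids)
        sub_env = {i: self.env_of[i] for i in ids} if self.env_of else None
        sub_fam = {i: self.family_of[i] for i in ids} if self.family_of else None
        return GenotypePanel(
            individual_ids=list(ids),
            marker_ids=list(self.marker_ids),
            calls=self.calls[idx],
            env_of=sub_env,
            family_of=sub_fam,
        )


@dataclass
class PhenotypeTable:
    """Long-format trait records with environments indexed by sorted label."""

    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("individual_id", "environment", "trait", "value")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table lacks columns {missing}")
        df = df.astype({"individual_id": str, "environment": str, "trait": str})
        df["value"] = df["value"].astype(float)
        dup = df.duplicated(subset=["individual_id", "environment", "trait"])
        if dup.any():
            raise ValueError("duplicate (individual, environment, trait) records")
        self.records = df.reset_index(drop=True)

    @property
    def environments(self) -> list[str]:
        return sorted(self.records["environment"].unique())

    @property
    def traits(self) -> list[str]:
        return sorted(self.records["trait"].unique())

    def for_trait(self, trait: str) -> pd.DataFrame:
        """Records of one trait ordered environment-major, individuals stable."""
        if trait not in set(self.records["trait"]):
            raise KeyError(f"trait {trait!r} not present")
        sub = self.records[self.records["trait"] == trait]
        return sub.sort_values(
            ["environment", "individual_id"], kind="stable"
        ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O


def _sep(dialect: str) -> str:
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def read_genotypes(path, dialect: str = "tsv") -> GenotypePanel:
    """Read a genotype table: header of marker ids, first column individual id.

    Calls must be 0/1/2 or NA/empty; anything else is a parse error naming the
    offending row and column.
    """
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"no records in genotype file {path}")
    raw = df.to_numpy()
    calls = np.full(raw.shape, np.nan)
    for (i, j), tok in np.ndenumerate(raw):
        if tok is None or (isinstance(tok, float) and np.isnan(tok)):
            continue
        tok = str(tok).strip()
        if tok in ("", "NA", "nan", "NaN"):
            continue
        if tok not in ("0", "1", "2"):
            raise ValueError(
                f"invalid genotype token {tok!r} at individual "
                f"{df.index[i]!r}, marker {df.columns[j]!r}"
            )
        calls[i, j] = float(tok)
    panel = GenotypePanel(
        individual_ids=[str(i) for i in df.index],
        marker_ids=[str(c) for c in df.columns],
        calls=calls,
    )
    log.info(
        "read %d individuals x %d markers (%d missing calls) from %s",
        panel.n_individuals, panel.n_markers, panel.n_missing, path,
    )
    return panel


def write_genotypes(panel: GenotypePanel, path, dialect: str = "tsv") -> None:
    calls = panel.calls
    out = np.empty(calls.shape, dtype=object)
    for (i, j), v in np.ndenumerate(calls):
        if np.isnan(v):
            out[i, j] = "NA"
        else:
            out[i, j] = str(int(v)) if float(v).is_integer() else repr(v)
    pd.DataFrame(out, index=panel.individual_ids, columns=panel.marker_ids).to_csv(
        path, sep=_sep(dialect)
    )


def read_phenotypes(path, dialect: str = "tsv") -> PhenotypeTable:
    df = pd.read_csv(path, sep=_sep(dialect))
    if df.empty:
        raise ValueError(f"no records in phenotype file {path}")
    return PhenotypeTable(df)


def write_phenotypes(phenos: PhenotypeTable, path, dialect: str = "tsv") -> None:
    phenos.records.to_csv(path, sep=_sep(dialect), index=False)


def read_families(path, dialect: str = "tsv") -> dict[str, str]:
    """Family-membership table: columns individual_id, family_id."""
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str)
    for col in ("individual_id", "family_id"):
        if col not in df.columns:
            raise ValueError(f"family table lacks column {col!r}")
    return dict(zip(df["individual_id"], df["family_id"]))


# ---------------------------------------------------------------------------
# Preprocessing


def filter_missing(panel: GenotypePanel, max_missing: float = 0.5) -> GenotypePanel:
    """Drop markers whose missing fraction strictly exceeds ``max_missing``.

    A marker at exactly the threshold is kept. Survivor order is preserved.
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must lie in [0, 1]")
    frac = np.isnan(panel.calls).mean(axis=0)
    keep = frac <= max_missing
    if not keep.any():
        raise ValueError("all markers exceed the missing-rate threshold")
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("filtered %d/%d markers with missing fraction > %g",
                 n_drop, panel.n_markers, max_missing)
    return replace(
        panel,
        marker_ids=[m for m, k in zip(panel.marker_ids, keep) if k],
        calls=panel.calls[:, keep],
    )


def impute_marker_mean(panel: GenotypePanel) -> GenotypePanel:
    """Replace missing calls by the per-marker mean of observed dosages."""
    calls = panel.calls.copy()
    obs = ~np.isnan(calls)
    if not obs.any(axis=0).all():
        bad = [m for m, ok in zip(panel.marker_ids, obs.any(axis=0)) if not ok]
        raise ValueError(f"markers with no observed calls (filter first): {bad[:5]}")
    with np.errstate(invalid="ignore"):
        means = np.nanmean(calls, axis=0)
    idx = np.where(~obs)
    calls[idx] = means[idx[1]]
    return replace(panel, calls=calls)


def compute_maf(panel: GenotypePanel) -> np.ndarray:
    """Per-marker minor allele frequency min(f, 1-f), f = mean dosage / 2.

    The panel should be imputed; fractional imputed dosages simply enter the
    dosage mean. Returns a length-p vector in [0, 0.5].
    """
    if np.isnan(panel.calls).any():
        raise ValueError("panel has missing calls; impute before computing MAF")
    f = panel.calls.mean(axis=0) / 2.0
    return np.minimum(f, 1.0 - f)
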