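"""Structured run configuration, deterministic seed expansion and manifests.

Defaults follow the framework's reference settings: bandwidth h = 1, Beta
shape alpha = 1 with grid beta in {12, 25, 50, 100, 200}, single-environment
chains of 12000 iterations (6000 burn-in), multi-environment chains of
20000/10000 (replicated lines) or 100000/50000 (disjoint individuals), and
50 replicates of 70/30 cross-validation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "dump_config", "run_manifest",
           "stage_seed", "setup_logging"]

_STAGES = ("simulate", "partition", "gwas", "sampler", "select")


@dataclass
class RunConfig:
    # paths
    genotypes: str | None = None
    phenotypes: str | None = None
    families: str | None = None
    out_dir: str = "wkgs_out"
    trait: str | None = None
    # model variants
    variants: list = field(default_factory=lambda: ["SE_GK", "ME_GK",
                                                    "ME_WK_MAF_Pvalue"])
    # kernel options
    h: float = 1.0
    alpha: float = 1.0
    beta_grid: list = field(default_factory=lambda: [12, 25, 50, 100, 200])
    # sampler options
    iters_se: int = 12000
    burnin_se: int = 6000
    iters_me_kronecker: int = 20000
    burnin_me_kronecker: int = 10000
    iters_me_general: int = 100000
    burnin_me_general: int = 50000
    thin: int = 10
    regime: str | None = None          # None = choose from the design
    background_mode: str = "identity"
    # cross-validation options
    reps: int = 50
    train_frac: float = 0.7
    holdout: str = "line"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iters_se <= self.burnin_se:
            raise ValueError("iters_se must exceed burnin_se")
        if self.iters_me_kronecker <= self.burnin_me_kronecker:
            raise ValueError("iters_me_kronecker must exceed burnin_me_kronecker")
        if self.iters_me_general <= self.burnin_me_general:
            raise ValueError("iters_me_general must exceed burnin_me_general")
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must lie in (0, 1)")
        if self.holdout not in ("line", "cell"):
            raise ValueError("holdout must be 'line' or 'cell'")
        if self.background_mode not in ("identity", "half_sib"):
            raise ValueError("background_mode must be 'identity' or 'half_sib'")
        if self.h <= 0:
            raise ValueError("bandwidth h must be positive")
        if not self.beta_grid:
            raise ValueError("beta_grid must be nonempty")


def load_config(path) -> RunConfig:
    """Load a YAML config; unknown keys are rejected, defaults filled."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config: {exc}") from exc


def dump_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


def stage_seed(seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed derived from one global seed.

    Keeps every derived seed below 2**31 so downstream generators accept it.
    """
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; one of {_STAGES}")
    digest = hashlib.sha256(f"{seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _file_checksum(path) -> str:
    hsh = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            hsh.update(chunk)
    return hsh.hexdigest()


def run_manifest(cfg: RunConfig, inputs: dict | None = None,
                 outputs: list | None = None) -> dict:
    """Reproducibility record: config hash, input checksums, seeds, version."""
    from . import __version__
    cfg_dict = asdict(cfg)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()
    manifest = {
        "config": cfg_dict,
        "config_hash": cfg_hash,
        "seed": cfg.seed,
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in _STAGES},
        "inputs": {name: _file_checksum(p) for name, p in (inputs or {}).items()
                   if p and Path(p).exists()},
        "outputs": sorted(str(p) for p in (outputs or [])),
        "version": __version__,
    }
    return manifest


def write_manifest(manifest: dict, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import datetime
    manifest = dict(manifest)
    manifest["timestamp"] = datetime.datetime.now().isoformat()
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr, level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
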