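"""Pipeline orchestration: normalize -> score -> classify -> summarize.

A :class:`PipelineConfig` (read from YAML/JSON with strict key checking)
drives the stages in order; all randomness flows from one global seed
through named per-stage sub-seeds, so identical config + seed reproduces
every output byte-for-byte and any stage can be re-run in isolation.  Each
run writes a manifest recording the package version, a hash of the
normalized config, the seed, and checksums of the signature gene lists
actually used.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigError, DataError
from .io import (
    GeneSignature,
    make_annotation,
    read_count_matrix,
    lognormalize,
    read_signatures,
    write_scores,
)
from .scoring import score_signatures
from .senescence import (
    CELL_CYCLE_COL,
    SENESCENCE_COL,
    default_cell_cycle_signature,
    default_senescence_signature,
    plain_mean_score,
    senescence_scores,
)
from .subtypes import SUBTYPE_COLS, assign_subtype, subtype_senescence_table, summary_markdown

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated configuration of a full analysis run."""

    # input paths
    matrix: str = ""
    genes: str = ""
    barcodes: str = ""
    samples: str | None = None
    subtype_signatures: str | None = None
    senescence_signature: str | None = None
    cell_cycle_signature: str | None = None
    out_dir: str = "sencaf_out"
    # scoring parameters
    nbin: int = 25
    per_gene: int = 100
    expression: str = "lognorm"  # or "zscore"
    target_total: float = 1e4
    exclude_self: bool = True
    # senescence-index parameters
    per_sample_scaling: bool = False
    index_mode: str = "module"  # or "plain_mean"
    # misc
    seed: int = 0
    verbosity: str = "info"

    _PATH_FIELDS = (
        "matrix", "genes", "barcodes", "samples",
        "subtype_signatures", "senescence_signature", "cell_cycle_signature",
    )

    def validate(self) -> None:
        for name in ("matrix", "genes", "barcodes"):
            if not getattr(self, name):
                raise ConfigError(f"config field {name!r} is required")
        for name in self._PATH_FIELDS:
            val = getattr(self, name)
            if val is not None and val != "" and not Path(val).exists():
                raise ConfigError(f"config path {name}={val!r} does not exist")
        if self.nbin < 1:
            raise ConfigError("nbin must be >= 1")
        if self.per_gene < 1:
            raise ConfigError("per_gene must be >= 1")
        if self.expression not in ("lognorm", "zscore"):
            raise ConfigError(f"unknown expression mode {self.expression!r}")
        if self.index_mode not in ("module", "plain_mean"):
            raise ConfigError(f"unknown index mode {self.index_mode!r}")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")


_BOOL_FIELDS = {"exclude_self", "per_sample_scaling"}
_INT_FIELDS = {"nbin", "per_gene", "seed"}
_FLOAT_FIELDS = {"target_total"}


def validate_config(path) -> PipelineConfig:
    """Read a YAML/JSON config file into a normalized PipelineConfig.

    Unknown keys are rejected by name; values are type-checked.  An empty
    file yields all defaults (validation of required paths still applies at
    run time).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError(f"config file {path} must be a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(doc) - known)
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    for key, val in doc.items():
        if val is None:
            continue
        if key in _INT_FIELDS and (isinstance(val, bool) or not isinstance(val, int)):
            raise ConfigError(f"config key {key!r}: expected integer, got {val!r}")
        if key in _FLOAT_FIELDS and not isinstance(val, (int, float)):
            raise ConfigError(f"config key {key!r}: expected number, got {val!r}")
        if key in _BOOL_FIELDS and not isinstance(val, bool):
            raise ConfigError(f"config key {key!r}: expected boolean, got {val!r}")
    return PipelineConfig(**doc)


def _read_gene_list(path) -> tuple[str, ...]:
    with open(path) as fh:
        genes = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    return tuple(genes)


def _load_signatures(cfg: PipelineConfig) -> list[GeneSignature]:
    if cfg.senescence_signature:
        sen = GeneSignature(SENESCENCE_COL, _read_gene_list(cfg.senescence_signature))
    else:
        sen = default_senescence_signature()
    if cfg.cell_cycle_signature:
        cc = GeneSignature(CELL_CYCLE_COL, _read_gene_list(cfg.cell_cycle_signature))
    else:
        cc = default_cell_cycle_signature()
    if cfg.subtype_signatures:
        subs = read_signatures(cfg.subtype_signatures)
    else:
        from importlib import resources

        with resources.as_file(
            resources.files("sencaf.data").joinpath("caf_subtypes.yaml")
        ) as p:
            subs = read_signatures(p)
    by_name = {s.name: s for s in subs}
    missing = [n for n in SUBTYPE_COLS if n not in by_name]
    if missing:
        raise DataError(f"subtype signature file lacks signatures: {missing}")
    return [sen, cc] + [by_name[n] for n in SUBTYPE_COLS]


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _signature_checksums(sigs: list[GeneSignature]) -> dict[str, str]:
    return {
        s.name: hashlib.sha256("\n".join(s.genes).encode()).hexdigest()[:16]
        for s in sigs
    }


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Execute the full analysis and write its artifact files.

    Stages: read raw counts -> log-normalize -> score the senescence,
    cell-cycle and three subtype signatures against one shared bin
    assignment -> senescence index and classification -> subtype assignment
    -> per-sample / per-subtype summaries.  Returns the artifact paths.
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("[stage:read] reading count matrix")
    raw = read_count_matrix(cfg.matrix, cfg.genes, cfg.barcodes, cfg.samples)
    logger.info("[stage:normalize] %d genes x %d cells", *raw.shape)
    m = lognormalize(raw, target_total=cfg.target_total)

    sigs = _load_signatures(cfg)
    logger.info("[stage:score] scoring %d signatures", len(sigs))
    table = score_signatures(
        m, sigs, nbin=cfg.nbin, per_gene=cfg.per_gene, seed=cfg.seed,
        exclude_self=cfg.exclude_self, expression=cfg.expression,
    )
    if cfg.index_mode == "plain_mean":
        sen_sig = sigs[0]
        table.columns[SENESCENCE_COL] = plain_mean_score(
            m, sen_sig, column=SENESCENCE_COL
        )[SENESCENCE_COL]

    logger.info("[stage:classify] senescence index + subtype assignment")
    groups = m.sample_labels() if cfg.per_sample_scaling else None
    result = senescence_scores(table, groups=groups)
    subtype = assign_subtype(table)
    ann = make_annotation(m.barcodes, m.sample_labels(), result.senescent, subtype)

    logger.info("[stage:summarize] writing artifacts to %s", out_dir)
    full_table = table.merge(result.to_score_table())
    paths = {
        "scores": out_dir / "scores.tsv",
        "annotation": out_dir / "annotation.tsv",
        "summary_tsv": out_dir / "summary.tsv",
        "summary_md": out_dir / "summary.md",
        "manifest": out_dir / "manifest.json",
    }
    write_scores(full_table, ann, paths["scores"])
    ann.to_csv(paths["annotation"], sep="\t", index=False)
    paths["summary_tsv"].write_text(subtype_senescence_table(ann))
    paths["summary_md"].write_text(summary_markdown(ann))

    manifest = {
        "package": "sencaf",
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "config_sha256": _config_hash(cfg),
        "signature_checksums": _signature_checksums(sigs),
        "n_genes": raw.n_genes,
        "n_cells": raw.n_cells,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths


def run_from_manifest(manifest_path) -> dict[str, Path]:
    """Re-run a pipeline bit-identically from a previous run's manifest."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    cfg = PipelineConfig(**manifest["config"])
    return run_pipeline(cfg)
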