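"""Expression-bin-matched signature (module) scoring.

The module score of a gene set G in a cell is the mean log-normalized
expression of G minus the mean expression of a control gene set C drawn to
match G's expression-abundance profile:

    SC = mean[E(G)] - mean[E(C)]

Controls are drawn per signature gene: genes are ranked by their across-cell
mean expression and cut into equal-frequency bins; for each signature gene,
``per_gene`` control genes (default 100) are sampled uniformly from the same
bin.  Subtracting the control mean removes the component of the raw
signature mean driven by overall cell complexity / library depth, so scores
are comparable across cells of different total expression.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import DataError
from .io import LOGNORM, CountMatrix, GeneSignature, ScoreTable

logger = logging.getLogger(__name__)

DEFAULT_NBIN = 25
DEFAULT_PER_GENE = 100


@dataclass
class BinAssignment:
    """Equal-frequency expression bins over the genes of a matrix."""

    gene_ids: list[str]
    bin_of: dict[str, int]
    nbin: int

    def members(self, b: int) -> list[str]:
        return [g for g in self.gene_ids if self.bin_of[g] == b]


@dataclass
class ControlSet:
    """Control-gene multiset drawn for one signature.

    ``controls`` may contain repeats (draws fall back to sampling with
    replacement when a bin holds fewer than ``per_gene`` eligible genes);
    scoring weights genes by multiplicity.
    """

    for_signature: str
    controls: list[str]
    per_gene: int
    seed: int


def mean_expression_bins(m: CountMatrix, nbin: int = DEFAULT_NBIN) -> BinAssignment:
    """Rank genes by across-cell mean expression and cut into ``nbin``
    equal-frequency bins.

    Ties in the mean are broken by gene-symbol lexicographic order, making
    the assignment deterministic.  Bin sizes differ by at most one.
    """
    if m.layer_tag != LOGNORM:
        raise DataError("expected lognorm layer for binning")
    if nbin < 1:
        raise DataError("nbin must be >= 1")
    if nbin > m.n_genes:
        raise DataError(f"nbin={nbin} exceeds gene count {m.n_genes}")
    means = np.asarray(m.values.mean(axis=1)).ravel()
    order = sorted(range(m.n_genes), key=lambda i: (means[i], m.gene_ids[i]))
    bin_of: dict[str, int] = {}
    for b, chunk in enumerate(np.array_split(np.array(order), nbin)):
        for i in chunk:
            bin_of[m.gene_ids[int(i)]] = b
    return BinAssignment(gene_ids=list(m.gene_ids), bin_of=bin_of, nbin=nbin)


def draw_controls(
    sig: GeneSignature,
    bins: BinAssignment,
    per_gene: int = DEFAULT_PER_GENE,
    seed: int = 0,
    exclude_self: bool = True,
) -> ControlSet:
    """Draw ``per_gene`` abundance-matched control genes per signature gene.

    For each signature gene present in the matrix, controls are drawn
    uniformly from the gene's expression bin, excluding the signature gene
    itself when ``exclude_self``.  Draws are without replacement when the
    eligible bin population allows it, with replacement otherwise.  Absent
    signature genes are skipped with a warning; a signature with no gene in
    the matrix is an error.
    """
    if per_gene < 1:
        raise DataError("per_gene must be >= 1")
    present = [g for g in sig.genes if g in bins.bin_of]
    absent = [g for g in sig.genes if g not in bins.bin_of]
    if absent:
        logger.warning(
            "signature %r: %d gene(s) absent from matrix: %s",
            sig.name, len(absent), ", ".join(absent),
        )
    if not present:
        raise DataError(f"no gene of signature {sig.name!r} present in matrix")

    # precompute sorted bin membership once; sorted order keeps draws
    # independent of matrix gene order
    by_bin: dict[int, list[str]] = {}
    for g in bins.gene_ids:
        by_bin.setdefault(bins.bin_of[g], []).append(g)
    for b in by_bin:
        by_bin[b] = sorted(by_bin[b])

    rng = np.random.default_rng(seed)
    controls: list[str] = []
    for g in present:
        pool = by_bin[bins.bin_of[g]]
        if exclude_self:
            pool = [x for x in pool if x != g]
        if not pool:
            raise DataError(
                f"no eligible control genes for {g!r} (bin of size 1)"
            )
        replace = len(pool) < per_gene
        picks = rng.choice(len(pool), size=per_gene, replace=replace)
        controls.extend(pool[i] for i in picks)
    return ControlSet(
        for_signature=sig.name, controls=controls, per_gene=per_gene, seed=seed
    )


def _mean_rows(values, idx_of: dict[str, int], genes: list[str]) -> np.ndarray:
    """Multiplicity-weighted mean expression of ``genes`` per cell."""
    idx = np.array([idx_of[g] for g in genes], dtype=int)
    if sp.issparse(values):
        total = np.asarray(values[idx].sum(axis=0)).ravel()
    else:
        total = np.asarray(values)[idx].sum(axis=0)
    return total / len(genes)


def zscale_genes(X: np.ndarray) -> np.ndarray:
    """Per-gene z-scaling across cells; constant genes map to zero."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def signature_score(
    m: CountMatrix, sig: GeneSignature, ctrl: ControlSet, values=None
) -> ScoreTable:
    """Per-cell module score: mean over present signature genes minus the
    multiplicity-weighted mean over the control multiset.

    ``values`` optionally overrides the expression matrix (same gene/cell
    alignment as ``m``), e.g. a per-gene z-scaled transform of it.
    """
    if m.layer_tag != LOGNORM:
        raise DataError("expected lognorm layer for scoring")
    idx_of = m.gene_index()
    present = [g for g in sig.genes if g in idx_of]
    if not present:
        raise DataError(f"no gene of signature {sig.name!r} present in matrix")
    missing_ctrl = [g for g in ctrl.controls if g not in idx_of]
    if missing_ctrl:
        raise DataError(
            f"control set for {sig.name!r} references genes absent from the "
            f"matrix (was it drawn against a different bin assignment?)"
        )
    V = m.values if values is None else values
    score = _mean_rows(V, idx_of, present) - _mean_rows(V, idx_of, list(ctrl.controls))
    return ScoreTable(list(m.barcodes), {sig.name: score})


def subseed(seed: int, name: str) -> int:
    """Deterministic 31-bit sub-seed for a named stage or signature.

    Uses a keyed blake2s digest rather than ``hash()`` (which is salted per
    interpreter run), so adding a signature never perturbs the draws of the
    others and results replay across processes.
    """
    h = hashlib.blake2s(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "little") & 0x7FFFFFFF


def score_signatures(
    m: CountMatrix,
    sigs: list[GeneSignature],
    nbin: int = DEFAULT_NBIN,
    per_gene: int = DEFAULT_PER_GENE,
    seed: int = 0,
    exclude_self: bool = True,
    expression: str = "lognorm",
) -> ScoreTable:
    """Score several signatures against one shared bin assignment.

    Control draws are independent per signature, using sub-seeds derived
    deterministically from ``seed`` and the signature name.  Columns appear
    in input signature order.  Expression bins always come from the
    log-normalized means; ``expression="zscore"`` scores on per-gene
    z-scaled values instead of log-normalized ones.
    """
    if not sigs:
        raise DataError("empty signature list")
    names = [s.name for s in sigs]
    if len(set(names)) != len(names):
        raise DataError("duplicate signature names")
    if expression not in ("lognorm", "zscore"):
        raise DataError(f"unknown expression mode {expression!r}")
    bins = mean_expression_bins(m, nbin=nbin)
    values = zscale_genes(m.dense()) if expression == "zscore" else None
    table: ScoreTable | None = None
    for sig in sigs:
        ctrl = draw_controls(
            sig, bins, per_gene=per_gene, seed=subseed(seed, sig.name),
            exclude_self=exclude_self,
        )
        col = signature_score(m, sig, ctrl, values=values)
        table = col if table is None else table.merge(col)
    return table


def dump_controls(ctrl: ControlSet, path) -> None:
    """Audit dump of a control multiset as a two-column TSV."""
    counts = pd.Series(ctrl.controls).value_counts().sort_index()
    counts.rename_axis("gene").rename("n_draws").to_csv(path, sep="\t")
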