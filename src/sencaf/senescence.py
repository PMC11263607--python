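"""Composite senescence index and senescent/non-senescent classification.

Senescent cells up-regulate CDK inhibitors (p16/CDKN2A, p15/CDKN2B,
p21/CDKN1A, p27/CDKN1B) and the SASP factor PAI-1 (SERPINE1) while shutting
down the cell-cycle transcriptional program.  The index combines both axes:

    senescence_score = minmax01(sen_signature_score) - minmax01(cc_score)

with min-max scaling over the pooled cell population, and calls a cell
senescent iff its score is strictly greater than zero.  The score lives in
[-1, 1]: +1 is attained only by a cell at the maximum senescence-signature
score and minimum cell-cycle score, -1 by the reverse.

The default senescence signature is the five markers above; the default
cell-cycle signature is a packaged 53-gene list built as the intersection of
the KEGG, REACTOME and WikiPathways cell-cycle sets (a frozen reconstruction
shipped with the package so no database access is needed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import DataError
from .io import GeneSignature, ScoreTable

logger = logging.getLogger(__name__)

SENESCENCE_COL = "senescence"
CELL_CYCLE_COL = "cell_cycle"

#: The five senescence marker genes of the default signature.
SENESCENCE_GENES = ("CDKN2A", "CDKN2B", "CDKN1A", "CDKN1B", "SERPINE1")


@dataclass
class SenescenceResult:
    """Per-cell senescence index with its ingredients.

    ``senescence_score = sen_norm - cc_norm`` elementwise and
    ``senescent[i] <=> senescence_score[i] > 0``.
    """

    barcodes: list[str]
    sen_raw: np.ndarray
    cc_raw: np.ndarray
    sen_norm: np.ndarray
    cc_norm: np.ndarray
    senescence_score: np.ndarray
    senescent: np.ndarray

    def to_score_table(self) -> ScoreTable:
        return ScoreTable(
            list(self.barcodes),
            {
                "sen_raw": self.sen_raw,
                "cc_raw": self.cc_raw,
                "sen_norm": self.sen_norm,
                "cc_norm": self.cc_norm,
                "senescence_score": self.senescence_score,
            },
        )


def minmax01(x) -> np.ndarray:
    """Scale a vector linearly onto [0, 1].

    A constant vector has no scale; it maps to all zeros with a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise DataError("cannot min-max scale an empty vector")
    if not np.all(np.isfinite(x)):
        raise DataError("minmax01 input contains non-finite values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("constant vector passed to minmax01; returning zeros")
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def _scaled(x: np.ndarray, groups) -> np.ndarray:
    if groups is None:
        return minmax01(x)
    groups = np.asarray(groups)
    if groups.shape != x.shape:
        raise DataError("groups vector length does not match scores")
    out = np.empty_like(x, dtype=float)
    for g in np.unique(groups):
        mask = groups == g
        out[mask] = minmax01(x[mask])
    return out


def senescence_scores(
    scores: ScoreTable,
    sen_col: str = SENESCENCE_COL,
    cc_col: str = CELL_CYCLE_COL,
    groups=None,
) -> SenescenceResult:
    """Compute the senescence index from raw signature score columns.

    Both columns are min-max scaled across ALL cells pooled (the default),
    subtracted, and thresholded strictly at zero (a score of exactly 0 is
    non-senescent).  ``groups`` optionally supplies per-cell sample labels
    for within-sample scaling instead of pooled scaling.
    """
    for col in (sen_col, cc_col):
        if col not in scores.columns:
            raise DataError(f"score column {col!r} not found")
    sen_raw = scores[sen_col]
    cc_raw = scores[cc_col]
    sen_norm = _scaled(sen_raw, groups)
    cc_norm = _scaled(cc_raw, groups)
    score = sen_norm - cc_norm
    return SenescenceResult(
        barcodes=list(scores.barcodes),
        sen_raw=sen_raw.copy(),
        cc_raw=cc_raw.copy(),
        sen_norm=sen_norm,
        cc_norm=cc_norm,
        senescence_score=score,
        senescent=score > 0,
    )


def plain_mean_score(m, sig: GeneSignature, column: str | None = None) -> ScoreTable:
    """Unadjusted per-cell mean expression of a signature.

    Sensitivity-analysis alternative to the control-adjusted module score:
    no expression-bin-matched control subtraction.
    """
    import scipy.sparse as sp

    idx_of = m.gene_index()
    present = [g for g in sig.genes if g in idx_of]
    if not present:
        raise DataError(f"no gene of signature {sig.name!r} present in matrix")
    idx = np.array([idx_of[g] for g in present])
    if sp.issparse(m.values):
        mean = np.asarray(m.values[idx].mean(axis=0)).ravel()
    else:
        mean = np.asarray(m.values)[idx].mean(axis=0)
    return ScoreTable(list(m.barcodes), {column or sig.name: mean})


def default_senescence_signature() -> GeneSignature:
    """The five-marker senescence signature."""
    return GeneSignature(SENESCENCE_COL, SENESCENCE_GENES)


def _packaged_gene_list(name: str) -> list[str]:
    text = resources.files("sencaf.data").joinpath(name).read_text()
    return [
        ln.strip() for ln in text.splitlines()
        if ln.strip() and not ln.startswith("#")
    ]


def default_cell_cycle_signature(sources=None) -> GeneSignature:
    """Cell-cycle signature: the intersection of three gene-set files.

    ``sources`` is an optional triple of file paths, each a one-gene-per-line
    list (KEGG-, REACTOME- and WikiPathways-style cell-cycle sets).  Without
    sources, the frozen packaged intersection list is returned.  The
    intersection is sorted lexicographically.
    """
    if sources is None:
        genes = _packaged_gene_list("cell_cycle_signature.txt")
        return GeneSignature(CELL_CYCLE_COL, tuple(genes))
    if len(sources) != 3:
        raise DataError("expected exactly three cell-cycle source files")
    sets = []
    for path in sources:
        with open(path) as fh:
            genes = {ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")}
        if not genes:
            raise DataError(f"empty cell-cycle source list: {path}")
        sets.append(genes)
    common = sorted(sets[0] & sets[1] & sets[2])
    if not common:
        raise DataError("empty cell-cycle signature (disjoint source lists)")
    return GeneSignature(CELL_CYCLE_COL, tuple(common))
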