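"""Core domain types and file input/output.

The in-memory containers are deliberately small: a gene x cell
:class:`CountMatrix` (genes are rows, matching the orientation of common
sparse count exports), a named :class:`GeneSignature`, and a per-cell
:class:`ScoreTable`.  Per-cell annotations (sample, senescent flag, CAF
subtype) travel as a pandas DataFrame with a fixed schema
(:data:`ANNOTATION_COLUMNS`), the way observation metadata does in the
AnnData world; a thin adapter to/from :class:`anndata.AnnData` is provided
for interoperability.

Matrices are read from Matrix-Market coordinate files (with one-per-line
``genes.tsv`` / ``barcodes.tsv`` sidecars) or from TSV; scores and
annotations are written as TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .errors import DataError

logger = logging.getLogger(__name__)

RAW = "raw"
LOGNORM = "lognorm"

#: Schema of the per-cell annotation frame.
ANNOTATION_COLUMNS = ("barcode", "sample", "senescent", "subtype")

#: Allowed CAF subtype labels.
SUBTYPE_LABELS = ("iCAF", "myCAF", "apCAF", "unassigned")

DEFAULT_SAMPLE = "sample0"


@dataclass
class CountMatrix:
    """Gene x cell expression matrix with identifiers and sample labels.

    Parameters
    ----------
    values
        Dense ndarray or scipy sparse matrix of shape (n_genes, n_cells).
        Non-negative; integer-valued when ``layer_tag == "raw"``.
    gene_ids
        Unique gene symbols, one per row.
    barcodes
        Unique cell identifiers, one per column.
    sample_of
        Map barcode -> sample identifier.  Barcodes absent from the map
        default to ``"sample0"``.
    layer_tag
        ``"raw"`` for counts, ``"lognorm"`` for log1p-normalized values.
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    barcodes: list[str]
    sample_of: dict[str, str] = field(default_factory=dict)
    layer_tag: str = RAW

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.barcodes = [str(b) for b in self.barcodes]
        n_g, n_c = self.shape
        if n_g != len(self.gene_ids):
            raise DataError(
                f"matrix has {n_g} rows but {len(self.gene_ids)} gene ids"
            )
        if n_c != len(self.barcodes):
            raise DataError(
                f"matrix has {n_c} columns but {len(self.barcodes)} barcodes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("duplicate gene ids in CountMatrix")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise DataError("duplicate barcodes in CountMatrix")
        if self.layer_tag not in (RAW, LOGNORM):
            raise DataError(f"unknown layer tag {self.layer_tag!r}")
        self._validate_values()

    def _validate_values(self) -> None:
        data = self.values.data if sp.issparse(self.values) else np.asarray(self.values)
        if data.size == 0:
            return
        if not np.all(np.isfinite(data)):
            raise DataError("matrix contains non-finite values")
        if np.min(data) < 0:
            raise DataError("matrix contains negative values")
        if self.layer_tag == RAW and np.any(data != np.floor(data)):
            raise DataError("raw layer contains non-integer values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.shape[0]

    @property
    def n_cells(self) -> int:
        return self.shape[1]

    def sample_labels(self) -> np.ndarray:
        """Per-cell sample labels in barcode order."""
        return np.array(
            [self.sample_of.get(b, DEFAULT_SAMPLE) for b in self.barcodes]
        )

    def dense(self) -> np.ndarray:
        """Values as a dense float ndarray."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (cells x genes)."""
        import anndata as ad

        X = self.values.T.tocsr() if sp.issparse(self.values) else np.asarray(self.values).T
        obs = pd.DataFrame({"sample": self.sample_labels()}, index=self.barcodes)
        var = pd.DataFrame(index=self.gene_ids)
        adata = ad.AnnData(X=X, obs=obs, var=var)
        adata.uns["layer_tag"] = self.layer_tag
        return adata

    @classmethod
    def from_anndata(cls, adata, layer_tag: str | None = None) -> "CountMatrix":
        """Build a CountMatrix from an AnnData (cells x genes)."""
        X = adata.X
        values = X.T.tocsr() if sp.issparse(X) else np.asarray(X).T
        sample_of = {}
        if "sample" in adata.obs:
            sample_of = dict(zip(adata.obs_names, adata.obs["sample"].astype(str)))
        tag = layer_tag or adata.uns.get("layer_tag", RAW)
        return cls(
            values=values,
            gene_ids=list(adata.var_names),
            barcodes=list(adata.obs_names),
            sample_of=sample_of,
            layer_tag=tag,
        )


@dataclass(frozen=True)
class GeneSignature:
    """A named, ordered gene list (senescence, cell-cycle, or CAF subtype)."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(str(g) for g in self.genes))
        if not self.genes:
            raise DataError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise DataError(f"signature {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ScoreTable:
    """Per-cell scores for one or more signatures, aligned to barcodes."""

    barcodes: list[str]
    columns: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.barcodes = [str(b) for b in self.barcodes]
        for name, col in list(self.columns.items()):
            col = np.asarray(col, dtype=float)
            if col.shape != (len(self.barcodes),):
                raise DataError(
                    f"score column {name!r} has length {col.shape} "
                    f"but table has {len(self.barcodes)} barcodes"
                )
            if not np.all(np.isfinite(col)):
                raise DataError(f"score column {name!r} contains non-finite values")
            self.columns[name] = col

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.columns:
            raise DataError(f"score column {name!r} not found")
        return self.columns[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.columns, index=pd.Index(self.barcodes, name="barcode"))

    def merge(self, other: "ScoreTable") -> "ScoreTable":
        if other.barcodes != self.barcodes:
            raise DataError("cannot merge score tables with different barcodes")
        cols = dict(self.columns)
        cols.update(other.columns)
        return ScoreTable(self.barcodes, cols)


def make_annotation(
    barcodes, samples, senescent, subtype
) -> pd.DataFrame:
    """Assemble a validated per-cell annotation frame.

    Columns: barcode, sample, senescent (bool), subtype (one of
    iCAF/myCAF/apCAF/unassigned).
    """
    ann = pd.DataFrame(
        {
            "barcode": [str(b) for b in barcodes],
            "sample": [str(s) for s in samples],
            "senescent": np.asarray(senescent, dtype=bool),
            "subtype": list(subtype),
        }
    )
    validate_annotation(ann)
    return ann


def validate_annotation(ann: pd.DataFrame) -> None:
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise DataError(f"annotation frame missing columns: {missing}")
    bad = set(ann["subtype"]) - set(SUBTYPE_LABELS)
    if bad:
        raise DataError(f"unknown subtype labels: {sorted(bad)}")
    if ann["barcode"].duplicated().any():
        raise DataError("duplicate barcodes in annotation frame")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_lines(path) -> list[str]:
    with open(path) as fh:
        return [ln.rstrip("\n").split("\t")[0] for ln in fh if ln.strip()]


def _collapse_duplicate_genes(values, gene_ids: list[str]):
    """Sum rows sharing a gene symbol, preserving first-occurrence order."""
    if len(set(gene_ids)) == len(gene_ids):
        return values, gene_ids
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, g in enumerate(gene_ids):
        if g not in groups:
            groups[g] = []
            order.append(g)
        groups[g].append(i)
    dupes = [g for g in order if len(groups[g]) > 1]
    logger.warning(
        "collapsing %d duplicate gene symbol(s) by summation: %s",
        len(dupes),
        ", ".join(dupes[:10]) + ("..." if len(dupes) > 10 else ""),
    )
    dense = sp.issparse(values)
    rows = []
    for g in order:
        idx = groups[g]
        block = values[idx]
        rows.append(block.sum(axis=0))
    if dense:
        out = sp.csr_matrix(np.vstack([np.asarray(r).ravel() for r in rows]))
    else:
        out = np.vstack([np.asarray(r).ravel() for r in rows])
    return out, order


def read_count_matrix(
    path_matrix,
    path_genes,
    path_barcodes,
    path_samples=None,
) -> CountMatrix:
    """Read a raw count matrix with gene/barcode sidecars.

    ``path_matrix`` may be Matrix-Market coordinate format (``.mtx``,
    1-based indices per the standard) or a TSV with genes as rows, a header
    row of barcodes and gene ids in the first column.  Sidecars are
    one-identifier-per-line text.  ``path_samples``, if given, is a
    two-column TSV mapping barcode -> sample; unmapped barcodes get sample
    ``"sample0"``.

    Genes are expected as rows.  If the sidecar lengths uniquely determine
    that the stored matrix is transposed, it is auto-transposed; ambiguous
    or inconsistent dimensions are a hard error naming the offending file.
    Duplicate gene symbols are collapsed by summation with a warning.
    """
    path_matrix = Path(path_matrix)
    genes = _read_lines(path_genes)
    barcodes = _read_lines(path_barcodes)

    if path_matrix.suffix == ".mtx":
        values = scipy.io.mmread(str(path_matrix)).tocsr()
    else:
        df = pd.read_csv(path_matrix, sep="\t", index_col=0)
        values = df.to_numpy()

    n_r, n_c = values.shape
    if (n_r, n_c) == (len(genes), len(barcodes)):
        pass
    elif (n_c, n_r) == (len(genes), len(barcodes)) and n_r != n_c:
        values = values.T.tocsr() if sp.issparse(values) else values.T
        logger.warning("matrix stored cells x genes; auto-transposed")
    else:
        if n_r != len(genes) and n_c != len(genes):
            raise DataError(
                f"matrix shape {values.shape} matches neither orientation of "
                f"gene sidecar {path_genes} ({len(genes)} entries)"
            )
        raise DataError(
            f"matrix shape {values.shape} inconsistent with barcode sidecar "
            f"{path_barcodes} ({len(barcodes)} entries)"
        )

    values, genes = _collapse_duplicate_genes(values, genes)

    sample_of: dict[str, str] = {}
    if path_samples is not None:
        smap = pd.read_csv(
            path_samples, sep="\t", header=None, names=["barcode", "sample"],
            dtype=str,
        )
        sample_of = dict(zip(smap["barcode"], smap["sample"]))
    return CountMatrix(
        values=values,
        gene_ids=genes,
        barcodes=barcodes,
        sample_of=sample_of,
        layer_tag=RAW,
    )


def write_count_matrix(m: CountMatrix, out_dir) -> dict[str, Path]:
    """Write matrix.mtx + genes.tsv + barcodes.tsv + samples.tsv to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "genes": out_dir / "genes.tsv",
        "barcodes": out_dir / "barcodes.tsv",
        "samples": out_dir / "samples.tsv",
    }
    values = m.values if sp.issparse(m.values) else sp.coo_matrix(m.values)
    scipy.io.mmwrite(str(paths["matrix"]), values)
    paths["genes"].write_text("".join(g + "\n" for g in m.gene_ids))
    paths["barcodes"].write_text("".join(b + "\n" for b in m.barcodes))
    labels = m.sample_labels()
    with open(paths["samples"], "w") as fh:
        for b, s in zip(m.barcodes, labels):
            fh.write(f"{b}\t{s}\n")
    return paths


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def lognormalize(m: CountMatrix, target_total: float = 1e4) -> CountMatrix:
    """Depth-normalize to ``target_total`` counts per cell and log1p.

    Each raw count v in a cell with total T becomes
    ``log1p(v * target_total / T)`` (natural log).  Cells with zero total
    count are dropped with a warning.  Input must be the raw layer.
    """
    if m.layer_tag != RAW:
        raise DataError("expected raw layer")
    if target_total <= 0:
        raise DataError("target_total must be positive")
    X = m.dense()
    totals = X.sum(axis=0)
    keep = totals > 0
    if not np.all(keep):
        dropped = [b for b, k in zip(m.barcodes, keep) if not k]
        logger.warning("dropping %d zero-count cell(s): %s",
                       len(dropped), ", ".join(dropped[:10]))
        X = X[:, keep]
        totals = totals[keep]
    barcodes = [b for b, k in zip(m.barcodes, keep) if k]
    out = np.log1p(X * (target_total / totals)[None, :])
    return CountMatrix(
        values=out,
        gene_ids=list(m.gene_ids),
        barcodes=barcodes,
        sample_of=dict(m.sample_of),
        layer_tag=LOGNORM,
    )


# ---------------------------------------------------------------------------
# score / annotation output
# ---------------------------------------------------------------------------


def write_scores(s: ScoreTable, ann: pd.DataFrame | None, path) -> None:
    """Write a per-cell TSV of scores, optionally merged with annotations.

    Columns: barcode [, sample], one column per signature score
    [, senescent, subtype].  Row order follows the barcode order of ``s``.
    Floats are rendered with 9 significant digits.
    """
    df = s.to_frame().reset_index()
    if ann is not None and len(ann):
        validate_annotation(ann)
        if list(ann["barcode"]) != s.barcodes:
            raise DataError("annotation barcodes do not match score table")
        df.insert(1, "sample", list(ann["sample"]))
        df["senescent"] = list(ann["senescent"])
        df["subtype"] = list(ann["subtype"])
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_scores(path) -> tuple[ScoreTable, pd.DataFrame | None]:
    """Inverse of :func:`write_scores`."""
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "sample": str})
    barcodes = list(df["barcode"])
    meta_cols = {"barcode", "sample", "senescent", "subtype"}
    score_cols = [c for c in df.columns if c not in meta_cols]
    table = ScoreTable(barcodes, {c: df[c].to_numpy(float) for c in score_cols})
    ann = None
    if {"sample", "senescent", "subtype"} <= set(df.columns):
        ann = make_annotation(barcodes, df["sample"], df["senescent"], df["subtype"])
    return table, ann


# ---------------------------------------------------------------------------
# signature files
# ---------------------------------------------------------------------------


def read_signatures(path) -> list[GeneSignature]:
    """Read signatures from a YAML/JSON mapping {name: [gene, ...], ...}."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or not doc:
        raise DataError(f"signature file {path} must be a non-empty mapping")
    sigs = []
    for name, genes in doc.items():
        if not isinstance(genes, list):
            raise DataError(f"signature {name!r} in {path} is not a list")
        sigs.append(GeneSignature(name=str(name), genes=tuple(genes)))
    return sigs


def write_signatures(sigs: list[GeneSignature], path) -> None:
    doc = {s.name: list(s.genes) for s in sigs}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
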