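"""CAF subtype assignment and senescent-fraction summaries.

A cell is assigned to iCAF, myCAF or apCAF iff exactly one of the three
subtype module scores is strictly positive; cells positive for several
signatures, or for none, stay unassigned.  Summaries report the senescent
percentage per sample (denominator: all cells of the sample, assigned or
not) and per subtype (denominator: cells assigned to that subtype, pooled
across samples).  Two cohort-level numbers are kept distinct: the unweighted
mean of per-sample percentages, and the pooled fraction over all cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .io import ScoreTable, validate_annotation

SUBTYPE_COLS = ("iCAF", "myCAF", "apCAF")


def assign_subtype(scores: ScoreTable, columns=SUBTYPE_COLS) -> np.ndarray:
    """Label each cell with the unique subtype whose score is > 0.

    A score of exactly 0 does not count as positive.  Zero or two-plus
    positive scores yield ``"unassigned"``.
    """
    mat = np.column_stack([scores[c] for c in columns])
    positive = mat > 0
    n_pos = positive.sum(axis=1)
    labels = np.where(
        n_pos == 1,
        np.asarray(columns, dtype=object)[positive.argmax(axis=1)],
        "unassigned",
    )
    return labels.astype(object)


@dataclass
class SenescenceSummary:
    """Cohort summary of senescent-cell percentages."""

    per_sample: dict[str, tuple[int, int, float]]  # sample -> (n, n_sen, pct)
    overall_mean_pct: float
    overall_range: tuple[float, float]
    pooled_pct: float
    per_subtype: dict[str, tuple[int, int, float]]


def summarize_senescence(ann: pd.DataFrame) -> SenescenceSummary:
    """Summaries of senescent fractions per sample and per subtype.

    ``ann`` is a per-cell annotation frame (barcode, sample, senescent,
    subtype).  Per-sample percentages use all cells of the sample;
    the unweighted mean and range across samples are reported together with
    the pooled fraction over all cells.  Per-subtype percentages use only
    cells assigned to that subtype.
    """
    if ann is None or len(ann) == 0:
        raise DataError("cannot summarize an empty annotation table")
    validate_annotation(ann)

    per_sample: dict[str, tuple[int, int, float]] = {}
    for sample, grp in ann.groupby("sample", sort=True):
        n = len(grp)
        n_sen = int(grp["senescent"].sum())
        per_sample[str(sample)] = (n, n_sen, 100.0 * n_sen / n)

    pcts = [v[2] for v in per_sample.values()]
    pooled = 100.0 * ann["senescent"].sum() / len(ann)

    per_subtype: dict[str, tuple[int, int, float]] = {}
    for st in SUBTYPE_COLS:
        grp = ann[ann["subtype"] == st]
        n = len(grp)
        n_sen = int(grp["senescent"].sum())
        pct = 100.0 * n_sen / n if n else float("nan")
        per_subtype[st] = (n, n_sen, pct)

    return SenescenceSummary(
        per_sample=per_sample,
        overall_mean_pct=float(np.mean(pcts)),
        overall_range=(float(min(pcts)), float(max(pcts))),
        pooled_pct=float(pooled),
        per_subtype=per_subtype,
    )


def subtype_senescence_table(ann: pd.DataFrame) -> str:
    """Render the summary as a TSV string: one row per sample, then one per
    subtype.  Percentages carry one decimal place.

    Per-sample denominators include unassigned cells; per-subtype rows count
    only cells assigned to that subtype (cells positive for several or no
    subtype signatures enter no subtype row).
    """
    s = summarize_senescence(ann)
    lines = ["group\tlevel\tn_cells\tn_senescent\tpct_senescent"]
    for sample, (n, n_sen, pct) in s.per_sample.items():
        lines.append(f"sample\t{sample}\t{n}\t{n_sen}\t{pct:.1f}")
    for st, (n, n_sen, pct) in s.per_subtype.items():
        pct_s = f"{pct:.1f}" if n else "NA"
        lines.append(f"subtype\t{st}\t{n}\t{n_sen}\t{pct_s}")
    lines.append(
        f"cohort\tmean_of_samples\t{len(ann)}\t{int(ann['senescent'].sum())}"
        f"\t{s.overall_mean_pct:.1f}"
    )
    lines.append(
        f"cohort\tpooled\t{len(ann)}\t{int(ann['senescent'].sum())}"
        f"\t{s.pooled_pct:.1f}"
    )
    return "\n".join(lines) + "\n"


def summary_markdown(ann: pd.DataFrame) -> str:
    """Human-readable Markdown rendering of the summary."""
    s = summarize_senescence(ann)
    lo, hi = s.overall_range
    out = [
        "# Senescent CAF summary",
        "",
        f"- samples: {len(s.per_sample)}, cells: {len(ann)}",
        f"- mean per-sample senescent %: {s.overall_mean_pct:.1f} "
        f"(range {lo:.1f}-{hi:.1f})",
        f"- pooled senescent %: {s.pooled_pct:.1f}",
        "",
        "| subtype | cells | senescent | % senescent |",
        "|---|---|---|---|",
    ]
    for st, (n, n_sen, pct) in s.per_subtype.items():
        pct_s = f"{pct:.1f}" if n else "NA"
        out.append(f"| {st} | {n} | {n_sen} | {pct_s} |")
    out.append("")
    out.append(
        "Per-sample denominators include unassigned cells; subtype rows "
        "count only cells assigned to exactly one subtype."
    )
    return "\n".join(out) + "\n"
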