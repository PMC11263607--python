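"""Synthetic scRNA-seq counts and spatial point patterns with planted truth.

The count simulator emulates the structure of a multi-patient CAF census:
~21 tumor samples of 100-250 fibroblasts each, three overlapping subtype
programs (iCAF / myCAF / apCAF) realised as disjoint planted marker panels,
and a minority senescent subpopulation per sample whose frequency varies
across samples (default uniform on [0.03, 0.32], bracketing the per-subject
spread reported for human PDAC CAF cohorts).

Counts follow a gene-dispersed negative binomial:

    counts[g, c] ~ NB(mean = baseline_g * libsize_c * fold(g, c),  theta_g)

where fold(g, c) multiplies in the planted effects: subtype markers up in
cells of the matching subtype, senescence genes up and cell-cycle genes
down in senescent cells.  The gene list always contains the five literal
senescence markers (CDKN2A, CDKN2B, CDKN1A, CDKN1B, SERPINE1) and the
packaged 53-gene cell-cycle list, so the default signatures apply to
simulated matrices unmodified.

The point simulator places tumor cells uniformly in the unit square and
draws CAF positions either uniformly or pulled toward the nearest tumor
cell, with a per-class attraction strength — the structure behind
"marker-positive CAFs sit closer to cancer cells" comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import RAW, CountMatrix, GeneSignature, write_count_matrix, write_signatures
from .senescence import SENESCENCE_GENES, default_cell_cycle_signature

SUBTYPES = ("iCAF", "myCAF", "apCAF")


@dataclass
class SimConfig:
    """Parameters of the count simulator.

    Folds are multiplicative on negative-binomial means; ``cc_down_fold``
    divides.  ``sen_prob_per_sample`` is either an explicit per-sample
    vector or ``None``, in which case each sample's senescent probability
    is drawn uniformly from ``sen_prob_range``.
    """

    n_samples: int = 21
    cells_per_sample: tuple[int, int] = (100, 250)
    n_genes: int = 2000
    # gene-level baseline mean expression ~ LogNormal(mu, sigma)
    baseline_logmean: tuple[float, float] = (-1.5, 1.2)
    # signature/marker genes draw baselines from a moderately expressed
    # stratum so planted programs are detectable at shallow depth
    role_baseline_logmean: tuple[float, float] = (0.0, 0.5)
    # NB size parameter theta ~ LogNormal(mu, sigma); var = m + m^2/theta
    dispersion_logmean: tuple[float, float] = (0.0, 0.5)
    # per-cell depth multiplier ~ LogNormal(mu, sigma)
    libsize_logmean: tuple[float, float] = (0.0, 0.35)
    subtype_props: tuple[float, float, float] = (0.40, 0.40, 0.20)
    n_markers_per_subtype: int = 30
    subtype_marker_fold: float = 4.0
    sen_prob_per_sample: tuple[float, ...] | None = None
    sen_prob_range: tuple[float, float] = (0.03, 0.32)
    sen_up_fold: float = 6.0
    cc_down_fold: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        lo, hi = self.cells_per_sample
        if not (1 <= lo <= hi):
            raise ConfigError("cells_per_sample must be an increasing range >= 1")
        for name in ("subtype_marker_fold", "sen_up_fold", "cc_down_fold"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if abs(sum(self.subtype_props) - 1.0) > 1e-9 or min(self.subtype_props) < 0:
            raise ConfigError("subtype_props must be a probability simplex")
        if self.sen_prob_per_sample is not None:
            probs = self.sen_prob_per_sample
            if len(probs) != self.n_samples:
                raise ConfigError("sen_prob_per_sample length != n_samples")
            if min(probs) < 0 or max(probs) > 1:
                raise ConfigError("senescent probabilities must lie in [0, 1]")
        n_special = (
            len(SENESCENCE_GENES)
            + len(default_cell_cycle_signature().genes)
            + 3 * self.n_markers_per_subtype
        )
        if n_special > self.n_genes:
            raise ConfigError(
                f"{n_special} role genes requested but only {self.n_genes} genes"
            )


@dataclass
class GroundTruth:
    """Planted per-cell states and per-gene roles of a simulated matrix."""

    cells: pd.DataFrame  # barcode, sample, true_subtype, true_senescent
    gene_roles: dict[str, str]  # gene -> senescence|cell_cycle|iCAF|myCAF|apCAF|background
    sen_prob_per_sample: dict[str, float] = field(default_factory=dict)
    # per-gene generative parameters (gene, role, baseline, theta)
    gene_params: pd.DataFrame | None = None

    def marker_signatures(self) -> list[GeneSignature]:
        """The planted subtype marker panels as scoreable signatures."""
        sigs = []
        for st in SUBTYPES:
            genes = tuple(g for g, r in self.gene_roles.items() if r == st)
            sigs.append(GeneSignature(st, genes))
        return sigs


def _gene_table(cfg: SimConfig) -> tuple[list[str], dict[str, str]]:
    cc_genes = [g for g in default_cell_cycle_signature().genes
                if g not in SENESCENCE_GENES]
    roles: dict[str, str] = {g: "senescence" for g in SENESCENCE_GENES}
    roles.update({g: "cell_cycle" for g in cc_genes})
    for st in SUBTYPES:
        for k in range(cfg.n_markers_per_subtype):
            roles[f"{st}_MK{k + 1:03d}"] = st
    n_bg = cfg.n_genes - len(roles)
    for k in range(n_bg):
        roles[f"BG{k + 1:05d}"] = "background"
    genes = list(roles)
    return genes, roles


def simulate_counts(cfg: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw a raw count matrix and its ground truth from ``cfg``.

    Fully reproducible given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes, roles = _gene_table(cfg)
    n_genes = len(genes)

    # gene-level baselines and dispersions
    mu_bg, sd_bg = cfg.baseline_logmean
    mu_role, sd_role = cfg.role_baseline_logmean
    baseline = rng.lognormal(mu_bg, sd_bg, size=n_genes)
    is_role = np.array([roles[g] != "background" for g in genes])
    baseline[is_role] = rng.lognormal(mu_role, sd_role, size=int(is_role.sum()))
    theta = rng.lognormal(*cfg.dispersion_logmean, size=n_genes)

    # cells
    lo, hi = cfg.cells_per_sample
    n_cells_per = rng.integers(lo, hi + 1, size=cfg.n_samples)
    samples = [f"sample{i + 1:02d}" for i in range(cfg.n_samples)]
    cell_sample = np.repeat(samples, n_cells_per)
    n_cells = len(cell_sample)
    barcodes = [f"cell{i + 1:05d}" for i in range(n_cells)]

    if cfg.sen_prob_per_sample is None:
        sen_prob = rng.uniform(*cfg.sen_prob_range, size=cfg.n_samples)
    else:
        sen_prob = np.asarray(cfg.sen_prob_per_sample, dtype=float)
    prob_of = dict(zip(samples, sen_prob))
    senescent = rng.random(n_cells) < np.array([prob_of[s] for s in cell_sample])
    subtype = rng.choice(SUBTYPES, size=n_cells, p=cfg.subtype_props)
    libsize = rng.lognormal(*cfg.libsize_logmean, size=n_cells)

    # fold matrix (genes x cells), multiplicative effects
    log_fold = np.zeros((n_genes, n_cells))
    role_arr = np.array([roles[g] for g in genes])
    for st in SUBTYPES:
        g_idx = role_arr == st
        c_idx = subtype == st
        log_fold[np.ix_(g_idx, c_idx)] += np.log(cfg.subtype_marker_fold)
    sen_g = role_arr == "senescence"
    cc_g = role_arr == "cell_cycle"
    log_fold[np.ix_(sen_g, senescent)] += np.log(cfg.sen_up_fold)
    log_fold[np.ix_(cc_g, senescent)] -= np.log(cfg.cc_down_fold)

    mean = baseline[:, None] * libsize[None, :] * np.exp(log_fold)
    # NB via gamma-Poisson mixture
    lam = rng.gamma(shape=theta[:, None], scale=mean / theta[:, None])
    counts = rng.poisson(lam).astype(np.int64)

    matrix = CountMatrix(
        values=counts,
        gene_ids=genes,
        barcodes=barcodes,
        sample_of=dict(zip(barcodes, cell_sample)),
        layer_tag=RAW,
    )
    truth = GroundTruth(
        cells=pd.DataFrame(
            {
                "barcode": barcodes,
                "sample": cell_sample,
                "true_subtype": subtype,
                "true_senescent": senescent,
            }
        ),
        gene_roles=roles,
        sen_prob_per_sample={s: float(p) for s, p in prob_of.items()},
        gene_params=pd.DataFrame(
            {
                "gene": genes,
                "role": role_arr,
                "baseline": baseline,
                "theta": theta,
            }
        ),
    )
    return matrix, truth


def write_simulation(matrix: CountMatrix, truth: GroundTruth, out_dir) -> dict:
    """Emit the files the reader consumes, plus truth.tsv and the planted
    subtype signatures."""
    from pathlib import Path

    out_dir = Path(out_dir)
    paths = write_count_matrix(matrix, out_dir)
    truth_path = out_dir / "truth.tsv"
    truth.cells.to_csv(truth_path, sep="\t", index=False)
    sig_path = out_dir / "subtype_signatures.yaml"
    write_signatures(truth.marker_signatures(), sig_path)
    roles_path = out_dir / "gene_roles.tsv"
    pd.Series(truth.gene_roles, name="role").rename_axis("gene").to_csv(
        roles_path, sep="\t"
    )
    paths.update(truth=truth_path, signatures=sig_path, gene_roles=roles_path)
    return paths


def simulate_points(
    n_caf: int,
    n_tumor: int,
    attraction: float = 0.0,
    seed: int = 0,
    p_pos: float = 0.5,
    attraction_pos: float | None = None,
    attraction_neg: float | None = None,
) -> pd.DataFrame:
    """Simulate tumor-cell and CAF centroids in the unit square.

    Tumor cells are uniform.  Each CAF starts uniform and is displaced
    toward its nearest tumor cell by a fraction ``attraction`` of the
    separation (0 = uniform, 1 = coincident with the tumor cell).  CAFs are
    labelled ``CAF_p16pos`` with probability ``p_pos`` else ``CAF_p16neg``;
    ``attraction_pos`` / ``attraction_neg`` override the attraction per
    class, so an effect can be planted in one class only.

    Returns a frame with columns x, y, label.
    """
    if n_caf < 1 or n_tumor < 1:
        raise ConfigError("n_caf and n_tumor must be >= 1")
    for a in (attraction, attraction_pos, attraction_neg):
        if a is not None and not (0.0 <= a <= 1.0):
            raise ConfigError("attraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    tumor = rng.uniform(size=(n_tumor, 2))
    caf = rng.uniform(size=(n_caf, 2))
    pos = rng.random(n_caf) < p_pos
    a_pos = attraction if attraction_pos is None else attraction_pos
    a_neg = attraction if attraction_neg is None else attraction_neg
    strength = np.where(pos, a_pos, a_neg)

    from scipy.spatial import cKDTree

    _, nearest = cKDTree(tumor).query(caf)
    caf = caf + strength[:, None] * (tumor[nearest] - caf)

    frames = [
        pd.DataFrame({"x": tumor[:, 0], "y": tumor[:, 1], "label": "tumor"}),
        pd.DataFrame(
            {
                "x": caf[:, 0],
                "y": caf[:, 1],
                "label": np.where(pos, "CAF_p16pos", "CAF_p16neg"),
            }
        ),
    ]
    return pd.concat(frames, ignore_index=True)


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """A configuration with every planted effect switched off (all folds 1)."""
    return SimConfig(
        subtype_marker_fold=1.0, sen_up_fold=1.0, cc_down_fold=1.0,
        seed=seed, **overrides,
    )
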