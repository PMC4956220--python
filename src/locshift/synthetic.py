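"""Synthetic paired screens with known ground truth.

Emulates the structure the change-detection method assumes in real screens:
genes fall into localization clusters (compartments) with similar profiles;
a perturbation screen differs from wild type through cluster-specific global
effects (imaging/morphology shifts shared by all genes of a cluster), through
genuine localization changes in a small fraction of genes, and occasionally
through single aberrant cells (mis-segmentations) that can skew a mean-based
profile.  The generator writes single-cell tables in the same schema the
profiling pipeline consumes, so every downstream module can be exercised
end to end without any real images.

All magnitude parameters (noise SDs, change magnitude, shift norms, outlier
scale) are expressed on the *rescaled* profile scale — the scale on which
distances and z-scores are computed — and converted to raw per-cell feature
units (intensity x100, localization /10) when cells are emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import (
    CELL_TABLE_COLUMNS,
    DEFAULT_TYPES_USED,
    FEATURES,
    BinSpec,
    intensity_mask,
)

logger = logging.getLogger(__name__)

#: Default size-bin edges per cell type (arbitrary area units). Buds are
#: smaller than mothers; five equal-width bins per type.
DEFAULT_SIZE_EDGES = {
    "bud": np.linspace(8.0, 28.0, 6),
    "mother": np.linspace(30.0, 80.0, 6),
}


def default_bin_spec() -> BinSpec:
    """The generator's true binning (boundaries are the inner bin edges)."""
    return BinSpec(
        boundaries={t: tuple(e[1:-1]) for t, e in DEFAULT_SIZE_EDGES.items()},
        n_size_bins=5,
        types_used=DEFAULT_TYPES_USED,
    )


@dataclass
class SyntheticConfig:
    """Generation parameters; defaults describe a realistic mid-size screen pair.

    ``change_magnitude`` is the typical Euclidean norm of an injected change
    over the 50 localization features (intensity untouched), on the rescaled
    profile scale where typical localization profile values are ~5-20.  Actual
    per-gene norms span 0.3-1.7x this value: real localization changes vary in
    strength, and the subtle ones are the hard cases.  Per-cluster global
    shifts have norms comparable to the change magnitude (median equal), so
    the naive method genuinely confuses them with real changes.
    """

    n_genes: int = 1000
    n_clusters: int = 8
    cells_per_bin_mean: float = 12.0
    cells_per_bin_dispersion: float = 2.0
    min_cells_per_bin: int = 5
    cluster_centers: np.ndarray | None = None  # (n_clusters, 60), rescaled scale
    within_cluster_sd: float = 0.5
    cell_noise_sd: float = 1.0
    global_shift_per_cluster: np.ndarray | None = None  # (n_clusters, 60), rescaled
    global_shift_scale: float = 1.0
    change_fraction: float = 0.05
    change_magnitude: float = 4.5
    outlier_cell_rate: float = 0.0
    outlier_scale: float = 50.0
    cluster_sizes: str = "equal"  # or "zipf"
    wt_screen_id: str = "WT_sim"
    pert_screen_id: str = "pert_sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.change_fraction < 1:
            raise ValueError("change_fraction must be in [0, 1)")
        if not 0 <= self.outlier_cell_rate < 1:
            raise ValueError("outlier_cell_rate must be in [0, 1)")
        if self.cluster_sizes not in ("equal", "zipf"):
            raise ValueError("cluster_sizes must be 'equal' or 'zipf'")
        if self.n_clusters < 1 or self.n_genes < self.n_clusters:
            raise ValueError("need n_genes >= n_clusters >= 1")


@dataclass
class SyntheticScreens:
    """Generated screen pair plus the ground truth needed for evaluation."""

    wt_cells: pd.DataFrame
    pert_cells: pd.DataFrame
    truth: pd.DataFrame  # per gene: gene_id, cluster_id, is_changed
    injected_deltas: np.ndarray  # (n_genes, 60), rescaled scale
    outlier_cells: pd.DataFrame  # screen_id, cell_id, gene_id
    bin_spec: BinSpec
    config: SyntheticConfig

    @property
    def changed_genes(self) -> list[str]:
        return list(self.truth.loc[self.truth["is_changed"], "gene_id"])


def _rescale_to_raw(labels: list[str]) -> np.ndarray:
    """Per-column factor converting rescaled profile units to raw feature units."""
    return np.where(intensity_mask(labels), 100.0, 0.1)


def _cluster_assignment(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.cluster_sizes == "equal":
        return np.arange(cfg.n_genes) % cfg.n_clusters
    # Zipf-like skew: cluster c gets weight 1/(c+1); exercises k exceeding the
    # size of small compartments.
    w = 1.0 / np.arange(1, cfg.n_clusters + 1)
    w /= w.sum()
    counts = np.maximum(1, np.floor(w * cfg.n_genes).astype(int))
    while counts.sum() < cfg.n_genes:
        counts[np.argmax(w)] += 1
    while counts.sum() > cfg.n_genes:
        counts[np.argmax(counts)] -= 1
    return np.repeat(np.arange(cfg.n_clusters), counts)


def _auto_centers(cfg: SyntheticConfig, labels: list[str], rng: np.random.Generator) -> np.ndarray:
    """Cluster centres on the rescaled scale: INT ~ U(2, 6), localization ~ U(5, 20)."""
    int_mask = intensity_mask(labels)
    centers = np.empty((cfg.n_clusters, len(labels)))
    centers[:, int_mask] = rng.uniform(2.0, 6.0, (cfg.n_clusters, int(int_mask.sum())))
    centers[:, ~int_mask] = rng.uniform(5.0, 20.0, (cfg.n_clusters, int((~int_mask).sum())))
    return centers


def _auto_shifts(cfg: SyntheticConfig, labels: list[str], rng: np.random.Generator) -> np.ndarray:
    """Per-cluster global shifts, uneven across clusters.

    Shift norms are lognormal with median equal to the change magnitude:
    comparable in scale to genuine changes, but with some clusters shifted
    dramatically more than others — the uneven cluster-specific global
    effects that make raw change magnitudes an unreliable hit criterion.
    """
    shifts = rng.standard_normal((cfg.n_clusters, len(labels)))
    shifts /= np.linalg.norm(shifts, axis=1, keepdims=True)
    # geometric ladder of norms (median ~ change_magnitude), randomly assigned
    # to clusters: the unevenness is structural, only its placement is random
    rel = np.geomspace(0.25, 4.0, cfg.n_clusters) if cfg.n_clusters > 1 else np.ones(1)
    norms = rng.permutation(rel) * cfg.change_magnitude * cfg.global_shift_scale
    return shifts * norms[:, None]


def _draw_counts(cfg: SyntheticConfig, shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    """Cells per (gene, type, bin): negative binomial clamped at the filter floor."""
    mean, disp = cfg.cells_per_bin_mean, cfg.cells_per_bin_dispersion
    p = disp / (disp + mean)
    counts = rng.negative_binomial(disp, p, size=shape)
    return np.maximum(counts, cfg.min_cells_per_bin)


def _emit_cells(
    profiles_rescaled: np.ndarray,
    gene_ids: list[str],
    counts: np.ndarray,  # (n_genes, n_bins_total)
    spec: BinSpec,
    screen_id: str,
    cell_noise_sd: float,
    conv: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw single cells around each gene's per-bin profile values."""
    nf = len(FEATURES)
    frames = []
    bin_index = 0
    for t in spec.types_used:
        edges = DEFAULT_SIZE_EDGES[t]
        for b in range(spec.n_size_bins):
            cols = slice((spec.types_used.index(t) * spec.n_size_bins + b) * nf,
                         (spec.types_used.index(t) * spec.n_size_bins + b) * nf + nf)
            c = counts[:, bin_index]
            gene_rep = np.repeat(np.arange(len(gene_ids)), c)
            m = len(gene_rep)
            feats = profiles_rescaled[gene_rep, cols] + rng.normal(0.0, cell_noise_sd, (m, nf))
            # sizes drawn inside the intended bin, away from the edges
            lo, hi = edges[b], edges[b + 1]
            pad = 0.05 * (hi - lo)
            sizes = rng.uniform(lo + pad, hi - pad, m)
            df = pd.DataFrame(feats * conv[cols], columns=list(FEATURES))
            df.insert(0, "cell_size", sizes)
            df.insert(0, "cell_type", t)
            df.insert(0, "gene_idx", gene_rep)
            frames.append(df)
            bin_index += 1
    cells = pd.concat(frames, ignore_index=True)
    cells = cells.sort_values(["gene_idx", "cell_type", "cell_size"], ignore_index=True)
    cells.insert(0, "cell_id", [f"{screen_id}_c{i:07d}" for i in range(len(cells))])
    cells.insert(0, "screen_id", screen_id)
    cells.insert(0, "gene_id", [gene_ids[i] for i in cells.pop("gene_idx")])
    return cells[list(CELL_TABLE_COLUMNS)]


def generate_screens(config: SyntheticConfig) -> SyntheticScreens:
    """Generate a wild-type / perturbation cell-table pair with ground truth.

    Deterministic given ``config.seed``; each generation stage draws from its
    own substream of the master seed, so enabling a later stage (e.g. outlier
    cells) does not perturb earlier draws.
    """
    cfg = config
    spec = default_bin_spec()
    labels = spec.feature_labels()
    nfeat = len(labels)
    conv = _rescale_to_raw(labels)
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(6)]
    rng_structure, rng_counts, rng_changes, rng_wt, rng_pert, rng_out = streams

    gene_ids = [f"gene{i:04d}" for i in range(cfg.n_genes)]
    clusters = _cluster_assignment(cfg, rng_structure)
    centers = cfg.cluster_centers
    if centers is None:
        centers = _auto_centers(cfg, labels, rng_structure)
    centers = np.asarray(centers, dtype=float)
    if centers.shape != (cfg.n_clusters, nfeat):
        raise ValueError(f"cluster_centers must have shape ({cfg.n_clusters}, {nfeat})")
    profiles = centers[clusters] + rng_structure.normal(
        0.0, cfg.within_cluster_sd, (cfg.n_genes, nfeat)
    )

    shifts = cfg.global_shift_per_cluster
    if shifts is None:
        shifts = _auto_shifts(cfg, labels, rng_structure)
    shifts = np.asarray(shifts, dtype=float)
    if shifts.shape != (cfg.n_clusters, nfeat):
        raise ValueError(f"global_shift_per_cluster must have shape ({cfg.n_clusters}, {nfeat})")

    # injected localization changes: random direction in the 50 localization
    # features, fixed norm, intensity untouched
    n_changed = int(round(cfg.change_fraction * cfg.n_genes))
    if cfg.change_fraction > 0 and n_changed < 1:
        logger.warning("change_fraction x n_genes < 1; generating zero changes")
    changed_idx = (
        rng_changes.choice(cfg.n_genes, size=n_changed, replace=False)
        if n_changed
        else np.array([], dtype=int)
    )
    deltas = np.zeros((cfg.n_genes, nfeat))
    loc = ~intensity_mask(labels)
    if n_changed:
        dirs = rng_changes.standard_normal((n_changed, int(loc.sum())))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        mags = cfg.change_magnitude * rng_changes.uniform(0.3, 1.7, n_changed)
        deltas[np.ix_(changed_idx, loc)] = dirs * mags[:, None]

    counts_wt = _draw_counts(cfg, (cfg.n_genes, spec.n_profile_features // len(FEATURES)), rng_counts)
    counts_pert = _draw_counts(cfg, counts_wt.shape, rng_counts)

    wt_cells = _emit_cells(profiles, gene_ids, counts_wt, spec, cfg.wt_screen_id,
                           cfg.cell_noise_sd, conv, rng_wt)
    # change vector is wt - pert, so an injected delta appears in the
    # perturbation as profile - delta (and the cluster shift is subtracted)
    pert_profiles = profiles - shifts[clusters] - deltas
    pert_cells = _emit_cells(pert_profiles, gene_ids, counts_pert, spec, cfg.pert_screen_id,
                             cfg.cell_noise_sd, conv, rng_pert)

    outlier_rows = []
    if cfg.outlier_cell_rate > 0:
        gene_pos = {g: i for i, g in enumerate(gene_ids)}
        for cells, base_profiles, screen in (
            (wt_cells, profiles, cfg.wt_screen_id),
            (pert_cells, pert_profiles, cfg.pert_screen_id),
        ):
            hit = np.flatnonzero(rng_out.random(len(cells)) < cfg.outlier_cell_rate)
            if hit.size == 0:
                continue
            gidx = cells["gene_id"].iloc[hit].map(gene_pos).to_numpy()
            spans = _feature_spans(cells.iloc[hit], spec)
            base = np.stack([base_profiles[g, s] for g, s in zip(gidx, spans)])
            feats = base + cfg.outlier_scale * rng_out.standard_normal((hit.size, len(FEATURES)))
            conv_slices = np.stack([conv[s] for s in spans])
            cells.iloc[hit, [cells.columns.get_loc(f) for f in FEATURES]] = feats * conv_slices
            outlier_rows.append(cells.iloc[hit][["screen_id", "cell_id", "gene_id"]])
    outliers = (
        pd.concat(outlier_rows, ignore_index=True)
        if outlier_rows
        else pd.DataFrame(columns=["screen_id", "cell_id", "gene_id"])
    )

    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "cluster_id": clusters,
        "is_changed": np.isin(np.arange(cfg.n_genes), changed_idx),
    })
    return SyntheticScreens(
        wt_cells=wt_cells,
        pert_cells=pert_cells,
        truth=truth,
        injected_deltas=deltas,
        outlier_cells=outliers,
        bin_spec=spec,
        config=cfg,
    )


def _feature_spans(cells: pd.DataFrame, spec: BinSpec) -> list[slice]:
    """Profile column slice for each cell's (type, bin)."""
    nf = len(FEATURES)
    spans = []
    for ctype, size in zip(cells["cell_type"], cells["cell_size"]):
        b = spec.bin_of(ctype, float(size)) - 1
        base = (spec.types_used.index(ctype) * spec.n_size_bins + b) * nf
        spans.append(slice(base, base + nf))
    return spans


def inject_outlier_cell(
    cells: pd.DataFrame,
    gene_id: str,
    cell_type: str,
    size_bin: int,
    spec: BinSpec,
    scale: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, str]:
    """Corrupt one cell of one gene's (type, bin) with an extreme feature value.

    Models a mis-segmented or aberrantly expressing cell: the cell's six
    features are displaced by ``scale`` x standard normal on the rescaled
    profile scale.  Returns the modified table (a copy) and the corrupted
    cell's id.  The chosen cell is the lexicographically first in the bin, so
    the operation is deterministic given the rng state.
    """
    df = cells.copy()
    labels = spec.feature_labels()
    conv = _rescale_to_raw(labels)
    nf = len(FEATURES)
    in_gene = df["gene_id"] == gene_id
    sub = df.loc[in_gene & (df["cell_type"].str.lower() == cell_type)]
    hits = [
        cid for cid, size in zip(sub["cell_id"], sub["cell_size"])
        if spec.bin_of(cell_type, float(size)) == size_bin
    ]
    if not hits:
        raise ValueError(f"no {cell_type!r} cells of {gene_id!r} in bin {size_bin}")
    target = sorted(hits)[0]
    row = df.index[df["cell_id"] == target][0]
    base = (spec.types_used.index(cell_type) * spec.n_size_bins + (size_bin - 1)) * nf
    dev_rescaled = scale * rng.standard_normal(nf)
    for j, feat in enumerate(FEATURES):
        df.at[row, feat] = df.at[row, feat] + dev_rescaled[j] * conv[base + j]
    return df, target
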