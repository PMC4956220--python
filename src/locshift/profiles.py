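"""Per-gene feature profiles from single-cell imaging feature tables.

A screen is summarized one gene at a time: the gene's segmented cells are
split by cell type (bud / mother) and by cell size into five bins per type
as a proxy for cell-cycle stage, the six per-cell features (GFP intensity
plus five spread-of-signal measures) are aggregated within each of the ten
(type, bin) cells, and the resulting 60-value vector is rescaled so the
intensity and localization features lie in comparable ranges.  Genes with
fewer than ``min_cells`` cells in any bin of either screen are dropped
entirely, so a profile matrix never contains missing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import trim_mean

logger = logging.getLogger(__name__)

#: Per-cell features, in profile column order: GFP intensity, average distance
#: between proteins, average distance to protein mass centre, average distance
#: to cell periphery, average distance to cell centre, average distance to bud
#: neck.
FEATURES: tuple[str, ...] = ("INT", "SEF", "MCT", "EDG", "CEN", "NEC")
INTENSITY_FEATURE = "INT"
CELL_TYPES: tuple[str, ...] = ("mother", "bud", "lone")
DEFAULT_TYPES_USED: tuple[str, ...] = ("bud", "mother")
AGGREGATORS: tuple[str, ...] = ("mean", "truncated_mean", "median")

#: Column schema of a single-cell feature table.
CELL_TABLE_COLUMNS: tuple[str, ...] = (
    "gene_id", "screen_id", "cell_id", "cell_type", "cell_size", *FEATURES,
)


@dataclass(frozen=True)
class SingleCellRecord:
    """One segmented cell with its six localization features."""

    gene_id: str
    screen_id: str
    cell_id: str
    cell_type: str
    cell_size: float
    features: tuple[float, ...]  # in FEATURES order

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        if not (self.cell_size > 0 and np.isfinite(self.cell_size)):
            raise ValueError(f"cell_size must be positive and finite, got {self.cell_size}")
        if len(self.features) != len(FEATURES):
            raise ValueError(f"expected {len(FEATURES)} features, got {len(self.features)}")
        if not all(np.isfinite(v) for v in self.features):
            raise ValueError("all features must be finite")


def records_to_frame(records: Iterable[SingleCellRecord]) -> pd.DataFrame:
    """Assemble validated records into the canonical cell-table DataFrame."""
    rows = [
        (r.gene_id, r.screen_id, r.cell_id, r.cell_type, r.cell_size, *r.features)
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(CELL_TABLE_COLUMNS))


@dataclass(frozen=True)
class BinSpec:
    """Cell-type and size binning used to build gene profiles.

    ``boundaries`` maps each profiled cell type to ``n_size_bins - 1`` strictly
    increasing size thresholds.  Bins are half-open ``[lower, upper)``; the
    last bin is closed above, so every positive size maps to exactly one bin.
    """

    boundaries: Mapping[str, tuple[float, ...]]
    n_size_bins: int = 5
    types_used: tuple[str, ...] = DEFAULT_TYPES_USED

    def __post_init__(self) -> None:
        if self.n_size_bins < 1:
            raise ValueError("n_size_bins must be >= 1")
        for t in self.types_used:
            if t not in self.boundaries:
                raise ValueError(f"no size boundaries for cell type {t!r}")
            b = np.asarray(self.boundaries[t], dtype=float)
            if len(b) != self.n_size_bins - 1:
                raise ValueError(
                    f"type {t!r}: expected {self.n_size_bins - 1} boundaries, got {len(b)}"
                )
            if len(b) and not np.all(np.diff(b) > 0):
                raise ValueError(f"type {t!r}: boundaries must be strictly increasing")

    @property
    def n_profile_features(self) -> int:
        return self.n_size_bins * len(self.types_used) * len(FEATURES)

    def feature_labels(self) -> list[str]:
        """Profile column labels, ordered type -> bin -> feature."""
        return [
            f"{t}{b}_{f}"
            for t in self.types_used
            for b in range(1, self.n_size_bins + 1)
            for f in FEATURES
        ]

    def bin_of(self, cell_type: str, size: float) -> int:
        """1-based size bin for a single cell."""
        b = np.asarray(self.boundaries[cell_type], dtype=float)
        return int(np.searchsorted(b, size, side="right")) + 1

    @classmethod
    def from_quantiles(
        cls,
        cells: pd.DataFrame,
        n_size_bins: int = 5,
        types_used: Sequence[str] = DEFAULT_TYPES_USED,
    ) -> "BinSpec":
        """Equal-frequency boundaries per type from a reference (wild-type) screen.

        Quantile bins balance per-bin sample size, which is the point of
        merging size bins in the first place.
        """
        boundaries: dict[str, tuple[float, ...]] = {}
        qs = np.arange(1, n_size_bins) / n_size_bins
        for t in types_used:
            sizes = cells.loc[cells["cell_type"].str.lower() == t, "cell_size"].to_numpy(float)
            if sizes.size < n_size_bins:
                raise ValueError(f"too few {t!r} cells ({sizes.size}) for {n_size_bins} bins")
            b = np.quantile(sizes, qs)
            if not np.all(np.diff(b) > 0):
                raise ValueError(
                    f"degenerate quantile boundaries for type {t!r}; supply explicit boundaries"
                )
            boundaries[t] = tuple(float(x) for x in b)
        return cls(boundaries=boundaries, n_size_bins=n_size_bins, types_used=tuple(types_used))


@dataclass
class ProfileMatrix:
    """Genes x features aggregated profile matrix for one screen."""

    screen_id: str
    gene_ids: list[str]
    values: np.ndarray  # (n_genes, n_features)
    feature_labels: list[str]
    aggregator: str
    rescaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.feature_labels)):
            raise ValueError("values shape does not match gene_ids x feature_labels")
        if np.isnan(self.values).any():
            raise ValueError("profile matrix must not contain missing values")

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=self.feature_labels)


def assign_size_bins(
    cells: pd.DataFrame, spec: BinSpec, *, lone_policy: str = "drop"
) -> pd.DataFrame:
    """Normalize cell types and attach a 1-based ``size_bin`` column.

    Cells whose type is not profiled are removed: ``lone`` cells are dropped by
    default (``lone_policy="as_mother"`` folds them into the mother bins), and
    records with an unrecognized type are rejected with a logged warning.
    """
    if lone_policy not in ("drop", "as_mother"):
        raise ValueError(f"unknown lone_policy {lone_policy!r}")
    df = cells.copy()
    if df.empty:
        df["size_bin"] = pd.Series(dtype=int)
        return df
    df["cell_type"] = df["cell_type"].astype(str).str.lower()
    unknown = ~df["cell_type"].isin(CELL_TYPES)
    if unknown.any():
        logger.warning("rejecting %d cells with unknown cell_type", int(unknown.sum()))
        df = df.loc[~unknown]
    if lone_policy == "as_mother":
        df.loc[df["cell_type"] == "lone", "cell_type"] = "mother"
    df = df.loc[df["cell_type"].isin(spec.types_used)].copy()
    bins = np.zeros(len(df), dtype=int)
    sizes = df["cell_size"].to_numpy(float)
    for t in spec.types_used:
        mask = (df["cell_type"] == t).to_numpy()
        b = np.asarray(spec.boundaries[t], dtype=float)
        bins[mask] = np.searchsorted(b, sizes[mask], side="right") + 1
    df["size_bin"] = bins
    return df


def _bin_counts(binned: pd.DataFrame, spec: BinSpec) -> pd.DataFrame:
    """Per-gene cell counts over the full (type, bin) grid (missing -> 0)."""
    grid = pd.MultiIndex.from_product(
        [spec.types_used, range(1, spec.n_size_bins + 1)], names=["cell_type", "size_bin"]
    )
    if binned.empty:
        return pd.DataFrame(columns=grid)
    counts = (
        binned.groupby(["gene_id", "cell_type", "size_bin"], observed=True)
        .size()
        .unstack(["cell_type", "size_bin"], fill_value=0)
    )
    return counts.reindex(columns=grid, fill_value=0)


def filter_genes(
    wt_binned: pd.DataFrame,
    pert_binned: pd.DataFrame,
    spec: BinSpec,
    min_cells: int = 5,
) -> list[str]:
    """Genes with at least ``min_cells`` cells in every (type, bin) of both screens.

    Returns the retained genes sorted lexicographically.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    retained: list[set[str]] = []
    for binned in (wt_binned, pert_binned):
        counts = _bin_counts(binned, spec)
        if counts.empty:
            return []
        ok = counts.min(axis=1) >= min_cells
        retained.append(set(counts.index[ok]))
    return sorted(retained[0] & retained[1])


def _aggregate_group(values: np.ndarray, aggregator: str, trim_fraction: float) -> np.ndarray:
    if aggregator == "mean":
        return values.mean(axis=0)
    if aggregator == "median":
        return np.median(values, axis=0)
    if aggregator == "truncated_mean":
        # trim_mean cuts floor(trim_fraction * n) observations from each tail,
        # independently per feature column
        return trim_mean(values, trim_fraction, axis=0)
    raise ValueError(f"unknown aggregator {aggregator!r}; expected one of {AGGREGATORS}")


def aggregate_profiles(
    binned: pd.DataFrame,
    spec: BinSpec,
    genes: Sequence[str],
    screen_id: str,
    aggregator: str = "mean",
    trim_fraction: float = 0.05,
) -> ProfileMatrix:
    """Aggregate single-cell features into an unrescaled profile matrix.

    Every gene in ``genes`` must have passed :func:`filter_genes` with this
    ``spec``; an empty (type, bin) for a listed gene is an internal
    consistency error, not a silent NaN.
    """
    if aggregator not in AGGREGATORS:
        raise ValueError(f"unknown aggregator {aggregator!r}; expected one of {AGGREGATORS}")
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    gene_order = sorted(genes)
    labels = spec.feature_labels()
    values = np.full((len(gene_order), len(labels)), np.nan)
    gene_pos = {g: i for i, g in enumerate(gene_order)}
    # canonical cell order, so shuffled input yields bit-identical aggregates
    sub = binned.loc[binned["gene_id"].isin(gene_pos)].sort_values(
        ["gene_id", "cell_type", "size_bin", "cell_id"], kind="mergesort"
    )
    feat_cols = list(FEATURES)
    for (gene, ctype, sbin), grp in sub.groupby(
        ["gene_id", "cell_type", "size_bin"], observed=True, sort=False
    ):
        agg = _aggregate_group(grp[feat_cols].to_numpy(float), aggregator, trim_fraction)
        base = (spec.types_used.index(ctype) * spec.n_size_bins + (sbin - 1)) * len(FEATURES)
        values[gene_pos[gene], base : base + len(FEATURES)] = agg
    if np.isnan(values).any():
        bad = [gene_order[i] for i in np.unique(np.where(np.isnan(values))[0])]
        raise RuntimeError(
            f"empty (type, bin) for retained gene(s) {bad[:5]}: filter contract violated"
        )
    return ProfileMatrix(
        screen_id=screen_id,
        gene_ids=gene_order,
        values=values,
        feature_labels=labels,
        aggregator=aggregator,
        rescaled=False,
    )


def intensity_mask(feature_labels: Sequence[str]) -> np.ndarray:
    """Boolean mask over profile columns selecting the GFP-intensity features."""
    return np.array([lbl.endswith(f"_{INTENSITY_FEATURE}") for lbl in feature_labels])


def localization_mask(feature_labels: Sequence[str]) -> np.ndarray:
    """Mask selecting the localization (non-intensity) features used for RMS."""
    return ~intensity_mask(feature_labels)


def rescale_profile(
    matrix: ProfileMatrix,
    intensity_divisor: float = 100.0,
    localization_multiplier: float = 10.0,
) -> ProfileMatrix:
    """Bring intensity and localization features into comparable ranges.

    Intensity columns are divided by 100 and localization columns multiplied
    by 10.  Rescaling is tracked on the matrix and is not idempotent: applying
    it twice is an error.
    """
    if matrix.rescaled:
        raise ValueError("profile matrix is already rescaled")
    scale = np.where(
        intensity_mask(matrix.feature_labels), 1.0 / intensity_divisor, localization_multiplier
    )
    return replace(matrix, values=matrix.values * scale, rescaled=True)


def build_profiles(
    wt_cells: pd.DataFrame,
    pert_cells: pd.DataFrame,
    spec: BinSpec | None = None,
    aggregator: str = "mean",
    min_cells: int = 5,
    trim_fraction: float = 0.05,
    rescale: bool = True,
    lone_policy: str = "drop",
    intensity_divisor: float = 100.0,
    localization_multiplier: float = 10.0,
) -> tuple[ProfileMatrix, ProfileMatrix]:
    """Full table-to-profiles pipeline for a wild-type / perturbation pair.

    When ``spec`` is omitted, size-bin boundaries are per-type equal-frequency
    quintiles of the wild-type cell sizes, applied to both screens.  The gene
    set is the joint ``min_cells`` filter over both screens; attrition is
    logged so filtering can be audited.
    """
    if spec is None:
        spec = BinSpec.from_quantiles(wt_cells)
    wt_binned = assign_size_bins(wt_cells, spec, lone_policy=lone_policy)
    pert_binned = assign_size_bins(pert_cells, spec, lone_policy=lone_policy)
    n_in = len(set(wt_cells["gene_id"]) | set(pert_cells["gene_id"]))
    genes = filter_genes(wt_binned, pert_binned, spec, min_cells=min_cells)
    logger.info("gene filter: %d genes in, %d retained (min %d cells/bin)",
                n_in, len(genes), min_cells)
    if not genes:
        raise ValueError("no genes pass the per-bin cell-count filter")
    out = []
    for binned, screen_cells in ((wt_binned, wt_cells), (pert_binned, pert_cells)):
        screen_id = str(screen_cells["screen_id"].iloc[0]) if len(screen_cells) else ""
        pm = aggregate_profiles(binned, spec, genes, screen_id, aggregator, trim_fraction)
        if rescale:
            pm = rescale_profile(pm, intensity_divisor, localization_multiplier)
        out.append(pm)
    return out[0], out[1]
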