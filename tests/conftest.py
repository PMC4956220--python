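"""Shared fixtures: small generated screens and profile matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from locshift.profiles import FEATURES, BinSpec, build_profiles
from locshift.synthetic import SyntheticConfig, generate_screens


@pytest.fixture(scope="session")
def small_screens():
    """A small but fully structured screen pair (120 genes, 4 clusters)."""
    return generate_screens(SyntheticConfig(n_genes=120, n_clusters=4, seed=11))


@pytest.fixture(scope="session")
def small_profiles(small_screens):
    s = small_screens
    return build_profiles(s.wt_cells, s.pert_cells, spec=s.bin_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def simple_spec():
    """One type, explicit boundaries — convenient for hand-checkable binning."""
    return BinSpec(boundaries={"bud": (10.0, 20.0, 30.0, 40.0)}, n_size_bins=5,
                   types_used=("bud",))


def make_cells(rows: list[tuple]) -> pd.DataFrame:
    """Build a cell table from (gene, screen, cell, type, size, *features) tuples."""
    return pd.DataFrame(
        rows,
        columns=["gene_id", "screen_id", "cell_id", "cell_type", "cell_size", *FEATURES],
    )


def uniform_cells(
    gene_id: str,
    screen_id: str,
    spec: BinSpec,
    n_per_bin: int,
    rng: np.random.Generator,
    feature_base: float = 1.0,
) -> pd.DataFrame:
    """Cells evenly covering every (type, bin) of ``spec``."""
    rows = []
    i = 0
    for t in spec.types_used:
        b = list(spec.boundaries[t])
        edges = [b[0] - 5.0, *b, b[-1] + 5.0]
        for lo, hi in zip(edges[:-1], edges[1:]):
            for _ in range(n_per_bin):
                size = rng.uniform(lo + 0.1, hi - 0.1)
                feats = feature_base + rng.normal(0, 0.1, len(FEATURES))
                rows.append((gene_id, screen_id, f"{screen_id}_{gene_id}_{i}", t, size, *feats))
                i += 1
    return make_cells(rows)
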