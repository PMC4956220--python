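"""Ranking evaluation against a list of known localization changes.

The benchmark statistic is a recall curve: the fraction of known positives
recovered as a function of the fraction of all ranked genes retrieved by rank
cut-off.  A random ranking follows the x = y diagonal in expectation; a useful
ranking rises above it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class EvaluationCurve:
    """Recall vs fraction-of-genes-retrieved for one ranking."""

    method_label: str
    points: list[tuple[float, float]]  # (fraction_retrieved, fraction_known_found)
    n_genes: int
    n_known: int


def recall_curve(
    ranking: Sequence[str], known: Iterable[str], method_label: str = ""
) -> EvaluationCurve:
    """Recall of ``known`` genes along a ranked gene list.

    Known positives absent from the ranking are dropped from the denominator
    (with a logged count): a ranking cannot be penalized for genes that did
    not survive upstream filtering.  Points are stored at every rank where
    recall increases, plus the (1.0, final recall) endpoint.
    """
    ranking = list(ranking)
    n = len(ranking)
    if n == 0:
        raise ValueError("empty ranking")
    ranked_set = set(ranking)
    if len(ranked_set) != n:
        raise ValueError("ranking contains duplicate gene ids")
    known = set(known)
    known_in = known & ranked_set
    dropped = len(known) - len(known_in)
    if dropped:
        logger.info("%d of %d known positives absent from the ranking; evaluating %d",
                    dropped, len(known), len(known_in))
    if not known_in:
        raise ValueError("no known positives present in the ranking")
    points: list[tuple[float, float]] = []
    found = 0
    for r, gene in enumerate(ranking, start=1):
        if gene in known_in:
            found += 1
            points.append((r / n, found / len(known_in)))
    if not points or points[-1][0] < 1.0:
        points.append((1.0, found / len(known_in)))
    return EvaluationCurve(
        method_label=method_label, points=points, n_genes=n, n_known=len(known_in)
    )


def recall_at(curve: EvaluationCurve, fraction: float) -> float:
    """Recall at the largest rank cut-off not exceeding ``fraction`` of genes."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    best = 0.0
    for fr, rec in curve.points:
        if fr <= fraction:
            best = max(best, rec)
    return best


def curve_frame(curve: EvaluationCurve) -> pd.DataFrame:
    """Curve points as a two-column DataFrame."""
    return pd.DataFrame(curve.points, columns=["fraction_retrieved", "fraction_known_found"])


def plot_curves(curves: Sequence[EvaluationCurve], path: str, log_x: bool = True) -> None:
    """Plot recall curves (log10 x-axis by default) with the x = y reference."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for curve in curves:
        xs, ys = zip(*curve.points)
        ax.step((0.0,) + xs, (0.0,) + ys, where="post", label=curve.method_label or None)
    ref = np.linspace(1e-3, 1.0, 200)
    ax.plot(ref, ref, "k--", linewidth=0.8, label="x = y")
    if log_x:
        ax.set_xscale("log")
    ax.set_xlabel("fraction of genes retrieved")
    ax.set_ylabel("fraction of known changes found")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
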