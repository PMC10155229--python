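"""Pairwise TF co-occurrence over experimental peak sets.

Two TFs co-occur when their peaks fall into the same binding site of a
shared universe B (the coalesced union of all compared peak sets). For a
pair, a 2x2 contingency table over the sites of B is scored with the
log-likelihood ratio statistic G^2 = 2 * sum obs * ln(obs / exp) against
independence expectations (row total * column total / |B|), alongside the
plain overlap percentage 100 * n11 / count(t1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .intervals import GenomicInterval, PeakSet, RegionTree, merge_intervals

__all__ = ["ContingencyTable", "build_universe", "contingency", "g2_score", "cooccurrence_matrices"]


@dataclass(frozen=True)
class ContingencyTable:
    n11: int  # sites bound by both TFs
    n10: int  # t1 only
    n01: int  # t2 only
    n00: int  # neither
    universe_size: int

    def __post_init__(self) -> None:
        cells = (self.n11, self.n10, self.n01, self.n00)
        if any(c < 0 for c in cells):
            raise ValueError(f"negative contingency cell: {cells}")
        if sum(cells) != self.universe_size:
            raise ValueError("contingency cells must sum to the universe size")

    @property
    def count_t1(self) -> int:
        return self.n11 + self.n10

    @property
    def count_t2(self) -> int:
        return self.n11 + self.n01


def build_universe(peak_sets: list[PeakSet]) -> list[GenomicInterval]:
    """The binding-site universe B: merged union of all input intervals."""
    if len(peak_sets) < 2:
        raise ValueError("need at least 2 peak sets to build a universe")
    all_ivs = [iv for ps in peak_sets for iv in ps.intervals]
    if not all_ivs:
        raise ValueError("cannot build a universe from empty peak sets")
    return merge_intervals(all_ivs)


def contingency(
    t1: PeakSet, t2: PeakSet, universe: list[GenomicInterval]
) -> tuple[ContingencyTable, float]:
    """2x2 site counts for a TF pair plus the overlap percentage t1 -> t2.

    count(t) is the number of universe sites overlapped by at least one
    peak of t; n11 counts sites overlapped by both. The percentage is
    100 * n11 / count(t1), reported as 0 when count(t1) = 0.
    """
    tree1 = RegionTree(t1.intervals)
    tree2 = RegionTree(t2.intervals)
    c1 = c2 = both = 0
    for site in universe:
        h1 = tree1.any_overlap(site)
        h2 = tree2.any_overlap(site)
        c1 += h1
        c2 += h2
        both += h1 and h2
    table = ContingencyTable(
        n11=both,
        n10=c1 - both,
        n01=c2 - both,
        n00=len(universe) - c1 - c2 + both,
        universe_size=len(universe),
    )
    pct = 100.0 * both / c1 if c1 else 0.0
    return table, pct


def g2_score(table: ContingencyTable) -> float:
    """Log-likelihood ratio statistic for the 2x2 co-occurrence table.

    G^2 = 2 * sum over cells of obs * ln(obs / exp), with independence
    expectations exp = row_total * col_total / |B| and the convention
    0 * ln(0 / e) = 0. Returns inf when a zero-expectation cell has a
    nonzero observation (impossible under independence).
    """
    n = table.universe_size
    if n <= 0:
        raise ValueError("empty universe")
    c1, c2 = table.count_t1, table.count_t2
    cells = (
        (table.n11, c1 * c2 / n),
        (table.n10, c1 * (n - c2) / n),
        (table.n01, (n - c1) * c2 / n),
        (table.n00, (n - c1) * (n - c2) / n),
    )
    g2 = 0.0
    for obs, exp in cells:
        if obs == 0:
            continue
        if exp == 0:
            return math.inf
        g2 += obs * math.log(obs / exp)
    return 2.0 * g2


def cooccurrence_matrices(
    peak_sets: dict[str, PeakSet]
) -> dict[str, pd.DataFrame]:
    """All-pairs co-occurrence summary over named TF peak sets.

    Returns square DataFrames: ``percentage`` (row TF's peaks found in the
    column TF), ``g2``, ``n11``, and ``universe`` (|B| per pair).
    """
    names = sorted(peak_sets)
    universe = build_universe([peak_sets[n] for n in names])
    mats = {
        key: pd.DataFrame(0.0, index=names, columns=names)
        for key in ("percentage", "g2", "n11", "universe")
    }
    for i, a in enumerate(names):
        for b in names[i:]:
            pair_universe = (
                universe
                if len(names) == 2
                else build_universe([peak_sets[a], peak_sets[b]])
            )
            table, pct_ab = contingency(peak_sets[a], peak_sets[b], pair_universe)
            g2 = g2_score(table)
            pct_ba = 100.0 * table.n11 / table.count_t2 if table.count_t2 else 0.0
            mats["percentage"].loc[a, b] = pct_ab
            mats["percentage"].loc[b, a] = pct_ba
            mats["g2"].loc[a, b] = mats["g2"].loc[b, a] = g2
            mats["n11"].loc[a, b] = mats["n11"].loc[b, a] = table.n11
            mats["universe"].loc[a, b] = mats["universe"].loc[b, a] = len(pair_universe)
    return mats
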