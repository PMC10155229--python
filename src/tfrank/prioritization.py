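"""TF-target-gene scores, significance gating, and rank aggregation.

The combined score for a TF t and target gene g under one assay (histone
mark) and condition pair is

    omega(g, t) = |log2fc(g)| * a_w(g, t) * |eta(t)|,

multiplying expression change, binding evidence, and regression evidence.
Per assay m, each TF's positive omegas (the foreground FG(t, m)) are tested
one-sidedly against the pooled positive omegas of all TFs (the background
BG(m)) with a Mann-Whitney U test; a TF enters the significant set S(m)
when p < alpha and both its mean and median exceed the background's. Ranks
within S(m) (by mean omega, Iverson counting: the highest mean gets rank
|S(m)|) aggregate across assays into

    f(t) = sum over assays m in HM(t) of 1 - rank_m(t) / |S(m)|,

with rank_m(t) := |S(m)| when t is not significant in m, so that assay
contributes 0. TFs are reported ascending by f: 0 is best and means the
TF topped every assay where it was assessed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .affinity import TFGeneScoreMatrix
from .dynamite import RegressionResult
from .expression import DifferentialResult

__all__ = [
    "TFTGTable",
    "HMPrioritization",
    "GlobalRanking",
    "tf_tg_scores",
    "build_distributions",
    "mwu_one_sided",
    "prioritize_per_hm",
    "aggregate_global",
    "select_top_loci",
    "top_target_genes",
]

ALL_COMPONENTS = frozenset({"log2fc", "tepic", "dynamite"})


@dataclass
class TFTGTable:
    pairing: str
    assay: str
    entries: pd.DataFrame  # columns gene_id, tf, omega
    components: frozenset[str] = ALL_COMPONENTS


@dataclass
class HMPrioritization:
    """Per-assay foreground/background distributions and the significant set."""

    assay: str
    fg: dict[str, np.ndarray]  # tf -> positive omegas
    bg: np.ndarray  # pooled positive omegas
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)
    significant: list[str] = field(default_factory=list)  # S(m)
    ranks: dict[str, int] = field(default_factory=dict)  # rank_m(t), t in S(m)


@dataclass
class GlobalRanking:
    table: pd.DataFrame  # index tf; columns f, n_assay_hits, mean_omega + per-assay ranks

    @property
    def order(self) -> list[str]:
        return list(self.table.index)


def tf_tg_scores(
    diff: DifferentialResult,
    scores: TFGeneScoreMatrix,
    reg: RegressionResult,
    components: frozenset[str] | set[str] = ALL_COMPONENTS,
) -> TFTGTable:
    """Combined TF-target-gene scores for one (pair, assay).

    ``components`` selects which factors enter the product (omitted
    factors contribute 1), enabling the score-component ablation; the full
    set reproduces |log2fc| * a_w * |eta| exactly. Entries are emitted for
    each TF's target genes, i.e. genes with a_w(g, t) > 0.
    """
    components = frozenset(components)
    unknown = components - ALL_COMPONENTS
    if unknown:
        raise ValueError(f"unknown components: {sorted(unknown)}")
    genes = scores.scores.index.intersection(diff.table.index)
    abs_fc = diff.log2fc.loc[genes].abs()
    records: list[tuple[str, str, float]] = []
    for tf in scores.scores.columns:
        a_col = scores.scores.loc[genes, tf]
        targets = a_col[a_col > 0]
        if targets.empty:
            continue
        omega = pd.Series(1.0, index=targets.index)
        if "log2fc" in components:
            omega = omega * abs_fc.loc[targets.index]
        if "tepic" in components:
            omega = omega * targets
        if "dynamite" in components:
            omega = omega * reg.abs_eta(tf)
        records.extend((g, tf, float(w)) for g, w in omega.items())
    entries = pd.DataFrame(records, columns=["gene_id", "tf", "omega"])
    return TFTGTable(diff.pair[0] + "_vs_" + diff.pair[1], scores.assay, entries, components)


def build_distributions(tables: list[TFTGTable]) -> HMPrioritization:
    """Pool one assay's tables (over condition pairs) into FG/BG multisets.

    BG(m) holds every positive omega of the assay; FG(t, m) the positive
    omegas of TF t. FG(t, m) is a sub-multiset of BG(m) by construction.
    """
    if not tables:
        raise ValueError("no TF-TG tables supplied")
    assays = {t.assay for t in tables}
    if len(assays) > 1:
        raise ValueError(f"mixed assays: {sorted(assays)}")
    all_entries = pd.concat([t.entries for t in tables], ignore_index=True)
    positive = all_entries[all_entries["omega"] > 0]
    if positive.empty:
        raise ValueError("background distribution is empty (no positive scores)")
    fg = {
        tf: grp["omega"].to_numpy()
        for tf, grp in positive.groupby("tf", sort=True)
    }
    return HMPrioritization(assay=assays.pop(), fg=fg, bg=positive["omega"].to_numpy())


def mwu_one_sided(fg: np.ndarray, bg: np.ndarray) -> tuple[float, float]:
    """One-sided Mann-Whitney U test, alternative: fg stochastically greater.

    Small samples (|fg| + |bg| <= 12) are handled by exact enumeration of
    every group assignment (valid with and without ties); larger samples
    use the tie-corrected normal approximation with 0.5 continuity
    correction. Degenerate all-identical inputs give p = 1.
    """
    fg = np.asarray(fg, dtype=float)
    bg = np.asarray(bg, dtype=float)
    if fg.size == 0 or bg.size == 0:
        raise ValueError("empty sample in Mann-Whitney test")
    combined = np.concatenate([fg, bg])
    if np.unique(combined).size == 1:
        u = fg.size * bg.size / 2.0
        return u, 1.0
    u = float(stats.mannwhitneyu(fg, bg, alternative="greater").statistic)
    if combined.size <= 12:
        return u, _exact_enumeration_p(fg.size, combined, u)
    res = stats.mannwhitneyu(
        fg, bg, alternative="greater", method="asymptotic", use_continuity=True
    )
    return u, float(res.pvalue)


def _exact_enumeration_p(n_fg: int, combined: np.ndarray, u_obs: float) -> float:
    """P(U >= u_obs) over all assignments of the pooled values to groups.

    U is computed from midrank sums, so tied values are handled exactly:
    the pooled ranking is fixed, and each assignment's U is the rank sum
    of its foreground minus n_fg(n_fg+1)/2.
    """
    from itertools import combinations

    ranks = stats.rankdata(combined)
    offset = n_fg * (n_fg + 1) / 2
    count = total = 0
    for idx in combinations(range(combined.size), n_fg):
        total += 1
        if ranks[list(idx)].sum() - offset >= u_obs - 1e-9:
            count += 1
    return count / total


def prioritize_per_hm(dists: HMPrioritization, alpha: float = 0.05) -> HMPrioritization:
    """Apply the significance gate and rank the surviving TFs.

    t enters S(m) iff p < alpha AND mean(FG) > mean(BG) AND
    median(FG) > median(BG). rank_m(t) counts TFs in S(m) whose mean is
    <= t's mean, so the highest-mean TF holds rank |S(m)|.
    """
    bg_mean = float(np.mean(dists.bg))
    bg_median = float(np.median(dists.bg))
    rows = []
    for tf in sorted(dists.fg):
        values = dists.fg[tf]
        u, p = mwu_one_sided(values, dists.bg)
        fg_mean = float(np.mean(values))
        fg_median = float(np.median(values))
        sig = p < alpha and fg_mean > bg_mean and fg_median > bg_median
        rows.append(
            {
                "tf": tf,
                "n_fg": values.size,
                "n_bg": dists.bg.size,
                "u": u,
                "p": p,
                "fg_mean": fg_mean,
                "fg_median": fg_median,
                "bg_mean": bg_mean,
                "bg_median": bg_median,
                "significant": sig,
            }
        )
    table = pd.DataFrame(rows).set_index("tf")
    sig_tfs = list(table.index[table["significant"]])
    means = table.loc[sig_tfs, "fg_mean"]
    ranks = {
        t: int((means <= means[t]).sum())  # Iverson count over S(m)
        for t in sig_tfs
    }
    dists.stats = table
    dists.significant = sig_tfs
    dists.ranks = ranks
    return dists


def aggregate_global(per_hm: list[HMPrioritization]) -> GlobalRanking:
    """Aggregate per-assay ranks into the global score f(t), ascending.

    Only TFs significant in at least one assay are listed. An assay where
    a listed TF was assessed but not significant contributes 0 (its rank
    defaults to |S(m)|). Ties in f break by more assay hits, then larger
    overall mean omega, then name.
    """
    if not per_hm:
        raise ValueError("no per-assay prioritizations")
    listed = sorted({t for hm in per_hm for t in hm.significant})
    rows = []
    for tf in listed:
        f = 0.0
        hits = 0
        omega_all: list[np.ndarray] = []
        per_assay: dict[str, object] = {}
        for hm in per_hm:
            if tf not in hm.fg:
                per_assay[f"rank_{hm.assay}"] = ""
                continue  # not assessed in this assay: m not in HM(t)
            omega_all.append(hm.fg[tf])
            s_size = len(hm.significant)
            if tf in hm.ranks:
                rank = hm.ranks[tf]
                hits += 1
            else:
                rank = s_size  # summand 0 for assays the TF missed
            f += 1.0 - (rank / s_size if s_size else 1.0)
            per_assay[f"rank_{hm.assay}"] = rank if tf in hm.ranks else ""
        mean_omega = float(np.mean(np.concatenate(omega_all))) if omega_all else 0.0
        rows.append({"tf": tf, "f": f, "n_assay_hits": hits, "mean_omega": mean_omega, **per_assay})
    if not rows:
        empty = pd.DataFrame(columns=["f", "n_assay_hits", "mean_omega"])
        empty.index.name = "tf"
        return GlobalRanking(empty)
    table = pd.DataFrame(rows).set_index("tf")
    table["_neg_hits"] = -table["n_assay_hits"]
    table["_neg_omega"] = -table["mean_omega"]
    table = table.sort_index(kind="mergesort")  # name is the last tie-break
    table = table.sort_values(["f", "_neg_hits", "_neg_omega"], kind="mergesort")
    table = table.drop(columns=["_neg_hits", "_neg_omega"])
    return GlobalRanking(table)


def select_top_loci(
    diff: DifferentialResult, k: int = 30, direction: str = "up"
) -> list[str]:
    """Top-k up- or down-regulated genes by log2 fold change.

    Ties in log2fc keep a stable order by gene_id.
    """
    if direction not in {"up", "down"}:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    fc = diff.log2fc.sort_index()
    ascending = direction == "down"
    ordered = fc.sort_values(ascending=ascending, kind="mergesort")
    return list(ordered.index[: max(k, 0)])


def top_target_genes(scores: TFGeneScoreMatrix, tf: str, k: int = 30) -> list[str]:
    """The k genes a TF scores highest on (positive scores only)."""
    return scores.top_target_genes(tf, k)
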