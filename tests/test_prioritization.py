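import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tfrank.affinity import TFGeneScoreMatrix
from tfrank.dynamite import RegressionResult
from tfrank.expression import DifferentialResult
from tfrank.prioritization import (
    HMPrioritization,
    TFTGTable,
    aggregate_global,
    build_distributions,
    mwu_one_sided,
    prioritize_per_hm,
    select_top_loci,
    tf_tg_scores,
)


def make_diff(log2fc: dict) -> DifferentialResult:
    table = pd.DataFrame({"log2fc": pd.Series(log2fc)})
    return DifferentialResult(pair=("A", "B"), table=table)


def make_scores(frame: pd.DataFrame, assay="H1") -> TFGeneScoreMatrix:
    return TFGeneScoreMatrix("A_vs_B", assay, 50_000, 50_000, frame)


def make_reg(etas: dict) -> RegressionResult:
    return RegressionResult("A_vs_B", "H1", etas, 1.0, 0.5, 42)


class TestTfTgScores:
    def test_product_hand_value(self):
        diff = make_diff({"g": 1.0})
        scores = make_scores(pd.DataFrame({"t": [0.5]}, index=["g"]))
        reg = make_reg({"t": -0.2})
        table = tf_tg_scores(diff, scores, reg)
        assert table.entries["omega"].iloc[0] == pytest.approx(0.1)

    def test_zero_factor_annihilates(self):
        diff = make_diff({"g": 0.0})
        scores = make_scores(pd.DataFrame({"t": [0.5]}, index=["g"]))
        table = tf_tg_scores(diff, scores, make_reg({"t": 0.3}))
        assert table.entries["omega"].iloc[0] == 0.0

    def test_single_component_ablation_identity(self):
        diff = make_diff({"g": 3.0})
        scores = make_scores(pd.DataFrame({"t": [0.7]}, index=["g"]))
        reg = make_reg({"t": 0.9})
        only_binding = tf_tg_scores(diff, scores, reg, components={"tepic"})
        assert only_binding.entries["omega"].iloc[0] == pytest.approx(0.7)
        only_fc = tf_tg_scores(diff, scores, reg, components={"log2fc"})
        assert only_fc.entries["omega"].iloc[0] == pytest.approx(3.0)

    def test_full_components_equal_manual_product(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(12)]
        diff = make_diff(dict(zip(genes, rng.normal(size=12))))
        frame = pd.DataFrame(
            rng.random((12, 3)), index=genes, columns=["t1", "t2", "t3"]
        )
        etas = {"t1": 0.4, "t2": -0.3, "t3": 0.0}
        table = tf_tg_scores(diff, make_scores(frame), make_reg(etas))
        for _, row in table.entries.iterrows():
            expected = (
                abs(diff.log2fc[row.gene_id])
                * frame.loc[row.gene_id, row.tf]
                * abs(etas[row.tf])
            )
            assert row.omega == pytest.approx(expected, abs=1e-14)

    def test_entries_only_for_positive_binding(self):
        diff = make_diff({"g1": 1.0, "g2": 1.0})
        frame = pd.DataFrame({"t": [0.0, 0.4]}, index=["g1", "g2"])
        table = tf_tg_scores(diff, make_scores(frame), make_reg({"t": 1.0}))
        assert list(table.entries["gene_id"]) == ["g2"]


class TestDistributions:
    def _table(self, entries, assay="H1"):
        return TFTGTable(
            "A_vs_B",
            assay,
            pd.DataFrame(entries, columns=["gene_id", "tf", "omega"]),
        )

    def test_single_tf_foreground_equals_background(self):
        t = self._table([("g1", "t1", 1.0), ("g2", "t1", 2.0)])
        d = build_distributions([t])
        np.testing.assert_array_equal(np.sort(d.fg["t1"]), np.sort(d.bg))

    def test_disjoint_tfs_additive(self):
        t = self._table(
            [("g1", "t1", 1.0), ("g2", "t1", 2.0), ("g3", "t2", 3.0)]
        )
        d = build_distributions([t])
        assert d.bg.size == d.fg["t1"].size + d.fg["t2"].size

    def test_multiset_contents_match_enumeration(self):
        entries = [
            ("g1", "t1", 1.0),
            ("g2", "t1", 0.0),  # non-positive: excluded
            ("g1", "t2", 2.0),
            ("g2", "t2", 2.0),  # duplicated value kept as multiset
            ("g1", "t3", 5.0),
        ]
        d = build_distributions([self._table(entries)])
        assert sorted(d.bg) == [1.0, 2.0, 2.0, 5.0]
        assert sorted(d.fg["t2"]) == [2.0, 2.0]
        assert "t1" in d.fg and list(d.fg["t1"]) == [1.0]

    def test_foreground_subset_of_background(self):
        rng = np.random.default_rng(2)
        entries = [
            (f"g{i}", f"t{j}", float(v))
            for (i, j), v in zip(
                itertools.product(range(30), range(4)),
                rng.random(120) - 0.2,
            )
        ]
        d = build_distributions([self._table(entries)])
        bg = list(d.bg)
        for tf, fg in d.fg.items():
            remaining = bg.copy()
            for v in fg:
                assert v in remaining
                remaining.remove(v)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_distributions([self._table([("g", "t", 0.0)])])


def exact_mwu_p(fg, bg):
    """Enumeration oracle: P(U >= observed) over all group assignments."""
    pooled = list(fg) + list(bg)
    n1 = len(fg)

    def u_stat(f, b):
        return sum((x > y) + 0.5 * (x == y) for x in f for y in b)

    observed = u_stat(fg, bg)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        f = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if u_stat(f, b) >= observed - 1e-12:
            count += 1
    return count / total


class TestMwu:
    def test_worked_exact_example(self):
        u, p = mwu_one_sided(np.array([5.0, 6.0]), np.array([1.0, 2.0, 3.0, 4.0]))
        assert u == 8
        assert p == pytest.approx(1 / 15)

    def test_no_shift_gives_large_p(self):
        x = np.array([1.0, 2.0, 3.0])
        _, p = mwu_one_sided(x, x.copy())
        assert p >= 0.5

    def test_all_identical_p_is_one(self):
        _, p = mwu_one_sided(np.ones(5), np.ones(8))
        assert p == 1.0

    def test_exact_branch_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for n1 in range(1, 5):
            for n2 in range(1, 7):
                vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # untied
                fg, bg = vals[:n1], vals[n1:]
                _, p = mwu_one_sided(fg, bg)
                assert p == pytest.approx(exact_mwu_p(fg, bg), abs=1e-12)

    def test_tied_approximation_close_to_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            vals = rng.integers(1, 5, size=11).astype(float)  # heavy ties
            fg, bg = vals[:5], vals[5:]
            _, p = mwu_one_sided(fg, bg)
            assert p == pytest.approx(exact_mwu_p(fg, bg), abs=0.02)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mwu_one_sided(np.array([]), np.array([1.0]))


class TestPrioritizePerHm:
    def _dists(self, fg, bg):
        return HMPrioritization(
            assay="H1", fg={k: np.asarray(v, float) for k, v in fg.items()}, bg=np.asarray(bg, float)
        )

    def test_shifted_foreground_included(self):
        bg = list(np.arange(1.0, 31.0))
        fg = [x + 10 for x in bg[:30]]
        d = prioritize_per_hm(self._dists({"t": fg}, bg + fg))
        assert d.significant == ["t"]

    def test_identical_foreground_excluded(self):
        bg = list(np.arange(1.0, 31.0))
        d = prioritize_per_hm(self._dists({"t": bg}, bg))
        assert d.significant == []

    def test_iverson_ranks(self):
        bg = [1.0, 2.0] * 40
        high = [50.0] * 20
        low = [30.0] * 20
        d = prioritize_per_hm(
            self._dists({"hi": high, "lo": low}, bg + high + low)
        )
        assert d.ranks == {"hi": 2, "lo": 1}


class TestAggregateGlobal:
    def _hm(self, assay, fg_means, significant, ranks, extra_fg=()):
        fg = {t: np.array([m]) for t, m in fg_means.items()}
        for t in extra_fg:
            fg.setdefault(t, np.array([0.01]))
        return HMPrioritization(
            assay=assay,
            fg=fg,
            bg=np.concatenate(list(fg.values())),
            significant=significant,
            ranks=ranks,
        )

    def test_single_assay_worked_case(self):
        # means 9 > 5 > 1 -> ranks 3, 2, 1 -> f = 0, 1/3, 2/3
        hm = self._hm(
            "H1",
            {"a": 9.0, "b": 5.0, "c": 1.0},
            ["a", "b", "c"],
            {"a": 3, "b": 2, "c": 1},
        )
        ranking = aggregate_global([hm])
        assert list(ranking.table.index) == ["a", "b", "c"]
        np.testing.assert_allclose(ranking.table["f"], [0.0, 1 / 3, 2 / 3])

    def test_two_assay_worked_case(self):
        # rank 4 of 4 in m1 (summand 0) and rank 1 of 2 in m2 -> f = 0.5
        m1 = self._hm(
            "m1",
            {"t": 9.0, "x1": 8.0, "x2": 7.0, "x3": 6.0},
            ["t", "x1", "x2", "x3"],
            {"t": 4, "x1": 3, "x2": 2, "x3": 1},
        )
        m2 = self._hm(
            "m2", {"t": 1.0, "y": 5.0}, ["t", "y"], {"t": 1, "y": 2}
        )
        ranking = aggregate_global([m1, m2])
        assert ranking.table.loc["t", "f"] == pytest.approx(0.5)

    def test_top_everywhere_scores_zero(self):
        m1 = self._hm("m1", {"t": 9.0, "u": 1.0}, ["t", "u"], {"t": 2, "u": 1})
        m2 = self._hm("m2", {"t": 9.0, "v": 1.0}, ["t", "v"], {"t": 2, "v": 1})
        ranking = aggregate_global([m1, m2])
        assert ranking.table.loc["t", "f"] == 0.0
        assert ranking.order[0] == "t"

    def test_never_significant_tf_not_listed(self):
        hm = self._hm("H1", {"a": 9.0}, ["a"], {"a": 1}, extra_fg=["b"])
        ranking = aggregate_global([hm])
        assert list(ranking.table.index) == ["a"]

    def test_missed_assay_contributes_zero(self):
        # t significant only in m1 where it is top of 2 -> f = (1-2/2) + 0
        m1 = self._hm("m1", {"t": 9.0, "u": 5.0}, ["t", "u"], {"t": 2, "u": 1})
        m2 = self._hm("m2", {"v": 3.0}, ["v"], {"v": 1}, extra_fg=["t"])
        ranking = aggregate_global([m1, m2])
        assert ranking.table.loc["t", "f"] == 0.0
        assert ranking.table.loc["t", "n_assay_hits"] == 1

    def test_f_bounded_by_assay_count(self):
        rng = np.random.default_rng(4)
        hms = []
        for a in range(3):
            tfs = [f"t{i}" for i in range(6)]
            means = dict(zip(tfs, rng.random(6)))
            sig = tfs[:4]
            ordered = sorted(sig, key=means.get)
            ranks = {t: i + 1 for i, t in enumerate(ordered)}
            hms.append(self._hm(f"m{a}", means, sig, ranks))
        ranking = aggregate_global(hms)
        assert ((ranking.table["f"] >= 0) & (ranking.table["f"] < 3)).all()


class TestTopLists:
    def test_top_loci_directions(self):
        diff = make_diff({"g1": 3.0, "g2": -1.0, "g3": 0.5, "g4": 2.0, "g5": -4.0})
        assert select_top_loci(diff, k=3, direction="up") == ["g1", "g4", "g3"]
        assert select_top_loci(diff, k=3, direction="down") == ["g5", "g2", "g3"]
        assert select_top_loci(diff, k=0) == []

    def test_top_loci_ties_stable_by_gene_id(self):
        diff = make_diff({"gb": 1.0, "ga": 1.0, "gc": 2.0})
        assert select_top_loci(diff, k=3) == ["gc", "ga", "gb"]

    def test_top_targets_sorted_and_capped(self):
        frame = pd.DataFrame({"t": [0.3, 0.9, 0.9, 0.0]}, index=["g1", "g2", "g3", "g4"])
        sm = make_scores(frame)
        assert sm.top_target_genes("t", k=30) == ["g2", "g3", "g1"]
        assert sm.top_target_genes("t", k=1) == ["g2"]

    def test_all_zero_scores_warn_empty(self):
        sm = make_scores(pd.DataFrame({"t": [0.0, 0.0]}, index=["g1", "g2"]))
        with pytest.warns(UserWarning):
            assert sm.top_target_genes("t") == []
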