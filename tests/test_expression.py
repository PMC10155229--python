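import numpy as np
import pandas as pd
import pytest

from tfrank.expression import (
    filter_genes,
    log2_fold_change,
    normalized_counts,
    retained_motifs,
    size_factors,
    tpm,
)
from tfrank.io import CountMatrix, GeneAnnotationTable, GeneRecord, MotifModel


def make_counts(counts, groups=None, genes=None):
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    groups = groups or {s: "A" for s in samples}
    return CountMatrix(genes, samples, counts, groups)


def make_annotation(lengths, genes=None, symbols=None):
    genes = genes or [f"g{i}" for i in range(len(lengths))]
    symbols = symbols or genes
    return GeneAnnotationTable(
        GeneRecord(g, sym, "chr1", "+", 100, l)
        for g, sym, l in zip(genes, symbols, lengths)
    )


class TestSizeFactors:
    def test_doubled_sample_gets_double_factor(self):
        cm = make_counts([[10, 20], [100, 200]])
        f = size_factors(cm)
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_identical_samples_equal_factors(self):
        cm = make_counts([[5, 5, 5], [7, 7, 7]])
        np.testing.assert_allclose(size_factors(cm), 1.0)

    def test_all_zero_gene_matrix_errors(self):
        cm = make_counts([[0, 0]])
        with pytest.raises(ValueError, match="pseudocount"):
            size_factors(cm)

    def test_matches_deseq2_median_of_ratios(self):
        # independent oracle: pydeseq2's normalization on the same matrix
        from pydeseq2.preprocessing import deseq2_norm

        rng = np.random.default_rng(3)
        counts = rng.integers(1, 500, size=(40, 6))
        cm = make_counts(counts)
        _, oracle = deseq2_norm(pd.DataFrame(counts.T))
        np.testing.assert_allclose(size_factors(cm), np.asarray(oracle), rtol=1e-10)

    def test_library_scaling_absorbed_up_to_global_constant(self):
        # the size factor absorbs a library-size change; the reference
        # (per-gene geometric mean) shifts too, so invariance holds up to
        # one multiplicative constant shared by all cells
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 100, size=(30, 3))
        cm1 = make_counts(counts)
        scaled = counts.copy()
        scaled[:, 1] *= 7
        cm2 = make_counts(scaled)
        n1 = normalized_counts(cm1).to_numpy()
        n2 = normalized_counts(cm2).to_numpy()
        ratio = n2 / n1
        np.testing.assert_allclose(ratio, ratio.flat[0], rtol=1e-9)


class TestLog2FoldChange:
    groups = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}

    def test_equal_means_give_zero(self):
        cm = make_counts([[10, 10, 10, 10]], groups=self.groups)
        diff = log2_fold_change(cm, ("A", "B"))
        assert diff.log2fc["g0"] == pytest.approx(0.0)

    def test_pseudocount_arithmetic(self):
        # one gene anchors normalization; the other has means 0 vs 3
        cm = make_counts([[100, 100, 100, 100], [0, 0, 3, 3]], groups=self.groups)
        diff = log2_fold_change(cm, ("A", "B"), pseudocount=1.0)
        assert diff.log2fc["g1"] == pytest.approx(np.log2(4.0 / 1.0))

    def test_antisymmetry(self):
        rng = np.random.default_rng(8)
        cm = make_counts(rng.integers(1, 400, (20, 4)), groups=self.groups)
        ab = log2_fold_change(cm, ("A", "B")).log2fc
        ba = log2_fold_change(cm, ("B", "A")).log2fc
        np.testing.assert_allclose(ab.to_numpy(), -ba.to_numpy(), atol=1e-12)

    def test_unknown_group_rejected(self):
        cm = make_counts([[1, 2, 3, 4]], groups=self.groups)
        with pytest.raises(ValueError, match="unknown group"):
            log2_fold_change(cm, ("A", "Z"))


class TestTpm:
    def test_hand_arithmetic(self):
        cm = make_counts([[100], [100]])
        ann = make_annotation([1000, 2000])
        t = tpm(cm, ann)
        np.testing.assert_allclose(
            t["s0"].to_numpy(), [2e6 / 3, 1e6 / 3], rtol=1e-9
        )

    def test_single_gene_is_million(self):
        t = tpm(make_counts([[7]]), make_annotation([500]))
        assert t.iloc[0, 0] == pytest.approx(1e6)

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(1)
        cm = make_counts(rng.integers(0, 1000, (25, 4)))
        ann = make_annotation(list(rng.integers(200, 5000, 25)))
        t = tpm(cm, ann)
        np.testing.assert_allclose(t.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_count_sample_rejected(self):
        with pytest.raises(ValueError, match="zero-count"):
            tpm(make_counts([[0]]), make_annotation([100]))

    def test_unannotated_gene_rejected(self):
        cm = make_counts([[1], [1]])
        ann = make_annotation([100], genes=["g0"])
        with pytest.raises(ValueError, match="g1"):
            tpm(cm, ann)


class TestFilters:
    groups = {"s0": "A", "s1": "B"}

    def test_low_tpm_gene_removed(self):
        # g1 is short but drowned out: high count gene keeps its TPM low
        cm = make_counts([[100_000, 100_000], [3, 3]], groups=self.groups)
        ann = make_annotation([1000, 1000])
        kept = filter_genes(cm, ann, tpm_min=1000.0, mean_count_min=0.0)
        assert kept == ["g0"]

    def test_both_gates_applied(self):
        # g0 passes both; g1 fails the mean-count gate; g2 passes
        cm = make_counts(
            [[500, 500], [10, 10], [800, 900]], groups=self.groups
        )
        ann = make_annotation([1000, 1000, 1000])
        kept = filter_genes(cm, ann, tpm_min=1.0, mean_count_min=50.0)
        assert kept == ["g0", "g2"]

    def test_zero_thresholds_keep_everything(self):
        cm = make_counts([[5, 1], [1, 5], [2, 2]], groups=self.groups)
        ann = make_annotation([100, 100, 100])
        assert filter_genes(cm, ann, 0.0, 0.0) == ["g0", "g1", "g2"]

    def test_condition_specific_gene_survives_tpm_gate(self):
        # expressed only in group B; max-over-groups TPM must rescue it
        cm = make_counts([[1000, 1000], [0, 400]], groups=self.groups)
        ann = make_annotation([1000, 1000])
        kept = filter_genes(cm, ann, tpm_min=100.0, mean_count_min=0.0)
        assert "g1" in kept


class TestMotifRetention:
    def _motif(self, name):
        return MotifModel(name, np.full((4, 4), 0.25))

    def test_dimer_needs_every_expressed_constituent(self):
        cm = make_counts(
            [[1_000_000, 1_000_000], [1, 1], [500_000, 500_000]],
            groups={"s0": "A", "s1": "B"},
            genes=["g0", "g1", "g2"],
        )
        ann = make_annotation([1000, 1000, 1000], symbols=["TFA", "TFB", "TFC"])
        motifs = [
            self._motif("TFA..TFC"),  # both pass
            self._motif("TFA..TFB"),  # TFB fails TPM
            self._motif("TFA..UNKNOWN"),  # unknown partner carries no evidence
        ]
        kept = [m.tf_name for m in retained_motifs(motifs, cm, ann, tpm_min=10.0)]
        assert kept == ["TFA..TFC", "TFA..UNKNOWN"]
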