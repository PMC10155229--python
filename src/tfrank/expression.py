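"""Count normalization, fold changes, TPM, and expression filters.

Replaces the conventional DESeq2 stage with a plain median-of-ratios size
factor estimate and a pseudocounted log2 ratio: downstream scoring consumes
only the fold change, so no dispersion model or Wald test is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneAnnotationTable, MotifModel

__all__ = [
    "DifferentialResult",
    "size_factors",
    "normalized_counts",
    "log2_fold_change",
    "tpm",
    "filter_genes",
    "retained_motifs",
]


@dataclass
class DifferentialResult:
    """Per-gene differential summary for one ordered condition pair (A, B).

    log2fc is log2 of the pseudocounted ratio of normalized group means,
    positive when the gene is higher in group B.
    """

    pair: tuple[str, str]
    table: pd.DataFrame  # index gene_id; columns log2fc, mean_norm_count, tpm_<group>...

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors, one positive float per sample.

    For each gene with a positive geometric mean across samples, the
    ratio count/geomean is formed; a sample's factor is the median of
    those ratios (taken on the log scale, so an even number of genes
    averages geometrically, matching the reference DESeq2 estimator).
    Scaling one sample's counts by c is absorbed into its factor, leaving
    normalized counts unchanged up to one global constant.
    """
    c = counts.counts.astype(float)
    with np.errstate(divide="ignore"):
        logc = np.log(c)
    log_geomean = logc.mean(axis=1)  # -inf for genes with any zero
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; size factors are "
            "undefined (consider adding a pseudocount to the matrix)"
        )
    log_ratios = logc[usable] - log_geomean[usable, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    if np.any(factors <= 0):
        raise ValueError("non-positive size factor computed")
    return factors


def normalized_counts(counts: CountMatrix) -> pd.DataFrame:
    f = size_factors(counts)
    return pd.DataFrame(
        counts.counts / f[None, :], index=counts.genes, columns=counts.samples
    )


def log2_fold_change(
    counts: CountMatrix,
    pair: tuple[str, str],
    pseudocount: float = 1.0,
    annotation: GeneAnnotationTable | None = None,
) -> DifferentialResult:
    """log2 fold change of normalized group means for an ordered pair (A, B).

    log2fc(g) = log2((meanNorm_B + pseudocount) / (meanNorm_A + pseudocount)).
    The pseudocount keeps the ratio finite for genes unexpressed in one
    condition. Also records the overall mean normalized count and, when an
    annotation is supplied, per-group mean TPM.
    """
    group_a, group_b = pair
    norm = normalized_counts(counts)
    cols_a = [counts.samples[j] for j in counts.group_columns(group_a)]
    cols_b = [counts.samples[j] for j in counts.group_columns(group_b)]
    mean_a = norm[cols_a].mean(axis=1)
    mean_b = norm[cols_b].mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "mean_norm_count": norm.mean(axis=1),
            f"mean_norm_{group_a}": mean_a,
            f"mean_norm_{group_b}": mean_b,
        }
    )
    if annotation is not None:
        tpm_table = tpm(counts, annotation)
        for grp, cols in ((group_a, cols_a), (group_b, cols_b)):
            table[f"tpm_{grp}"] = tpm_table[cols].mean(axis=1)
    return DifferentialResult(pair=pair, table=table)


def tpm(counts: CountMatrix, annotation: GeneAnnotationTable) -> pd.DataFrame:
    """Transcripts-per-million, genes x samples; every column sums to 1e6."""
    missing = [g for g in counts.genes if g not in annotation]
    if missing:
        raise ValueError(f"genes absent from annotation: {missing[:10]}")
    lengths_kb = np.array(
        [annotation[g].exonic_length / 1000.0 for g in counts.genes]
    )
    rate = counts.counts / lengths_kb[:, None]
    denom = rate.sum(axis=0)
    if np.any(denom == 0):
        bad = [counts.samples[j] for j in np.flatnonzero(denom == 0)]
        raise ValueError(f"zero-count samples, TPM undefined: {bad}")
    return pd.DataFrame(
        1e6 * rate / denom[None, :], index=counts.genes, columns=counts.samples
    )


def filter_genes(
    counts: CountMatrix,
    annotation: GeneAnnotationTable,
    tpm_min: float = 1.0,
    mean_count_min: float = 50.0,
) -> list[str]:
    """Expression gate removing weakly expressed genes.

    A gene is retained iff its mean normalized count across all samples is
    >= ``mean_count_min`` AND the maximum over groups of its mean TPM is
    >= ``tpm_min`` (a gene expressed in only one condition must survive).
    """
    norm = normalized_counts(counts)
    tpm_table = tpm(counts, annotation)
    mean_norm = norm.mean(axis=1)
    group_tpm = pd.DataFrame(
        {
            grp: tpm_table[
                [counts.samples[j] for j in counts.group_columns(grp)]
            ].mean(axis=1)
            for grp in counts.groups
        }
    )
    max_tpm = group_tpm.max(axis=1)
    keep = (mean_norm >= mean_count_min) & (max_tpm >= tpm_min)
    return [g for g in counts.genes if keep[g]]


def gene_passes_tpm(
    symbol: str,
    counts: CountMatrix,
    annotation: GeneAnnotationTable,
    tpm_min: float,
    _tpm_cache: pd.DataFrame | None = None,
) -> bool | None:
    """Max-over-groups mean TPM test for a gene symbol; None when the
    symbol is not in the annotation or count matrix."""
    rec = annotation.get_by_symbol(symbol)
    if rec is None or rec.gene_id not in counts.genes:
        return None
    tpm_table = tpm(counts, annotation) if _tpm_cache is None else _tpm_cache
    best = max(
        tpm_table.loc[
            rec.gene_id, [counts.samples[j] for j in counts.group_columns(grp)]
        ].mean()
        for grp in counts.groups
    )
    return bool(best >= tpm_min)


def retained_motifs(
    motifs: list[MotifModel],
    counts: CountMatrix,
    annotation: GeneAnnotationTable,
    tpm_min: float = 1.0,
) -> list[MotifModel]:
    """TF expression filter.

    A motif (TF or dimer) is retained iff every constituent gene present
    in the annotation passes the TPM gate: a dimer cannot act when a
    partner is unexpressed. Constituents with no expression record carry
    no evidence either way and do not veto retention.
    """
    tpm_cache = tpm(counts, annotation)
    kept = []
    for motif in motifs:
        verdicts = [
            gene_passes_tpm(sym, counts, annotation, tpm_min, tpm_cache)
            for sym in motif.constituents
        ]
        if all(v is not False for v in verdicts):
            kept.append(motif)
    return kept
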