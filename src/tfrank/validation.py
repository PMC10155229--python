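"""Validation of predicted binding regions against experimental TF peaks.

Predicted regions (the top-affinity candidate regions of a TF) are matched
against an experimental peak tree: a prediction with any experimental peak
within ``match_distance`` bp is a true positive, else a false positive.
The affinity model localizes a broad high-energy area rather than the
exact bound base pairs, so the tolerance defaults to the TF-Gene scoring
window; set it to 0 for strict overlap. An equal number of length-matched
regions sampled away from the predictions supplies false negatives / true
negatives, giving the usual confusion metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .affinity import TFGeneScoreMatrix
from .intervals import CandidateRegion, GenomicInterval, RegionTree

__all__ = ["ConfusionMatrix", "predicted_regions", "classify", "metrics", "f1_score"]


def f1_score(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity; 0 when both are 0.

    Scale-free: works identically on fractions and on percentages.
    """
    if precision + sensitivity == 0:
        return 0.0
    return 2 * precision * sensitivity / (precision + sensitivity)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int
    tf_name: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


def predicted_regions(
    regions: list[CandidateRegion],
    affinities: pd.DataFrame,
    tf: str,
    quantile: float = 0.9,
) -> list[GenomicInterval]:
    """Regions whose affinity for ``tf`` reaches the per-TF quantile.

    The threshold is the ``quantile`` of the TF's positive affinities;
    ties at the threshold are kept. quantile=0 returns every
    positive-affinity region. No positive affinity yields an empty list
    with a warning.
    """
    if tf not in affinities.columns:
        raise KeyError(f"TF {tf!r} has no affinity column")
    if not 0 <= quantile <= 1:
        raise ValueError("quantile must lie in [0, 1]")
    values = affinities[tf].to_numpy()
    positive_mask = values > 0
    if not positive_mask.any():
        warnings.warn(f"TF {tf!r} has no positive affinities", stacklevel=2)
        return []
    threshold = float(np.quantile(values[positive_mask], quantile))
    keep = positive_mask & (values >= threshold)
    return [regions[i].interval for i in np.flatnonzero(keep)]


def classify(
    predicted: list[GenomicInterval],
    experimental: RegionTree,
    genome_bounds: dict[str, int],
    match_distance: int = 50_000,
    seed: int = 42,
    tf_name: str = "",
    return_negatives: bool = False,
):
    """Confusion counts for predicted regions vs experimental peaks.

    Each predicted region is a TP if an experimental peak lies within
    ``match_distance`` bp of it, else an FP. Then the same number of
    length-matched negative regions is drawn uniformly from the genome
    (chromosomes weighted by length, seeded rejection sampling excluding
    the predicted regions); a negative matching an experimental peak is
    an FN, otherwise a TN. Deterministic given the seed.
    ``return_negatives`` additionally returns the sampled negative regions.
    """
    if not predicted:
        cm = ConfusionMatrix(0, 0, 0, 0, tf_name, seed)
        return (cm, []) if return_negatives else cm
    pred_tree = RegionTree(predicted)

    def matches(iv: GenomicInterval) -> bool:
        lo = max(0, iv.start - match_distance)
        hi = iv.end + match_distance
        return experimental.any_overlap(GenomicInterval(iv.chrom, lo, hi))

    tp = sum(matches(iv) for iv in predicted)
    fp = len(predicted) - tp

    rng = np.random.default_rng(seed)
    chroms = sorted(genome_bounds)
    lengths = np.array([genome_bounds[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    fn = tn = 0
    negatives: list[GenomicInterval] = []
    max_attempts = 1000 * len(predicted)
    attempts = 0
    for iv in predicted:
        size = len(iv)
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    "could not place length-matched negative regions; "
                    "genome too crowded with predictions"
                )
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            limit = genome_bounds[chrom] - size
            if limit < 0:
                continue
            start = int(rng.integers(0, limit + 1))
            neg = GenomicInterval(chrom, start, start + size)
            if pred_tree.any_overlap(neg):
                continue
            break
        negatives.append(neg)
        if matches(neg):
            fn += 1
        else:
            tn += 1
    cm = ConfusionMatrix(tp, fp, fn, tn, tf_name, seed)
    return (cm, negatives) if return_negatives else cm


def metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Sensitivity, specificity, precision, accuracy, and F1.

    F1 is the harmonic mean of precision and sensitivity. Ratios with a
    zero denominator are reported as 0.
    """

    def ratio(num: float, den: float) -> float:
        return num / den if den else 0.0

    sens = ratio(cm.tp, cm.tp + cm.fn)
    spec = ratio(cm.tn, cm.tn + cm.fp)
    prec = ratio(cm.tp, cm.tp + cm.fp)
    acc = ratio(cm.tp + cm.tn, cm.tp + cm.fp + cm.fn + cm.tn)
    f1 = f1_score(prec, sens)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "accuracy": acc,
        "f1": f1,
    }
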