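"""Biophysical TF binding affinity and the decay-weighted TF-Gene score.

Affinity follows the TRAP model: every motif-length window on both strands
contributes an occupancy probability derived from a mismatch energy against
the motif consensus, and the affinity of a region is the expected number of
bound TF molecules, i.e. the sum of those probabilities. Per-gene scores
then aggregate region affinities around each TSS with exponential distance
decay and peak/motif length normalization:

    a_w(g, t) = sum over regions p within the window of
                a_{p,t} / (|p| - l) * exp(-d_{p,g} / d0)

with the denominator clamped to >= 1 for regions shorter than the motif.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import CandidateRegion
from .io import GeneAnnotationTable, MotifModel

__all__ = ["trap_affinity", "region_affinities", "tf_gene_scores", "TFGeneScoreMatrix"]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

TRAP_LAMBDA = 0.7
# ln R0 as an affine function of motif length, from the TRAP calibration
_LNR0_SLOPE = 0.584
_LNR0_INTERCEPT = -5.66


def _encode(sequence: str) -> np.ndarray:
    """Map a DNA string to integer codes A=0..T=3; anything else (N) -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        table[ord(base)] = idx
        table[ord(base.lower())] = idx
    return table[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def default_ln_r0(motif_length: int) -> float:
    return _LNR0_SLOPE * motif_length + _LNR0_INTERCEPT


def trap_affinity(
    motif: MotifModel,
    sequence: str,
    lambda_: float = TRAP_LAMBDA,
    ln_r0: float | None = None,
) -> float:
    """Expected TF occupancy of a sequence under the TRAP model.

    For each offset i (both strands) the mismatch energy is

        E_i = (1/lambda) * sum_j ln(M[j, consensus_j] / M[j, s_{i+j}])

    and the window binds with probability p_i = R0 e^{-E_i} / (1 + R0 e^{-E_i}).
    ``ln_r0`` defaults to 0.584 * L - 5.66. Windows containing any
    ambiguous base score 0. Sequences shorter than the motif return 0
    with a warning.
    """
    L = motif.length
    if ln_r0 is None:
        ln_r0 = default_ln_r0(L)
    if len(sequence) < L:
        warnings.warn(
            f"sequence shorter than motif ({len(sequence)} < {L}); affinity 0",
            stacklevel=2,
        )
        return 0.0

    codes = _encode(sequence)
    log_m = np.log(motif.matrix)  # L x 4
    consensus = log_m.max(axis=1)  # ln M[j, consensus_j]
    # mismatch score per (position, base); N column scores +inf energy
    w_fwd = np.full((L, 5), np.inf)
    w_fwd[:, :4] = consensus[:, None] - log_m
    # reverse strand: scanning the reverse complement of each window is
    # equivalent to scanning with the reverse-complemented motif
    w_rev = w_fwd[::-1, [3, 2, 1, 0, 4]]

    windows = np.lib.stride_tricks.sliding_window_view(codes, L)  # (n-L+1, L)
    total = 0.0
    r0 = math.exp(ln_r0)
    for w in (w_fwd, w_rev):
        energy = w[np.arange(L)[None, :], windows].sum(axis=1) / lambda_
        with np.errstate(over="ignore"):
            boltz = r0 * np.exp(-energy)
        p = boltz / (1.0 + boltz)
        p[~np.isfinite(energy)] = 0.0
        total += float(p.sum())
    return total


def region_affinities(
    regions: list[CandidateRegion],
    sequences: list[str],
    motifs: list[MotifModel],
    lambda_: float = TRAP_LAMBDA,
) -> pd.DataFrame:
    """Affinity of every motif in every region; rows regions, columns TFs."""
    if len(regions) != len(sequences):
        raise ValueError("regions and sequences differ in length")
    with warnings.catch_warnings():
        # short dip regions legitimately score 0; no need to warn per region
        warnings.simplefilter("ignore")
        data = {
            m.tf_name: [trap_affinity(m, seq, lambda_) for seq in sequences]
            for m in motifs
        }
    df = pd.DataFrame(data, index=range(len(regions)))
    df.attrs["motif_lengths"] = {m.tf_name: m.length for m in motifs}
    return df


@dataclass
class TFGeneScoreMatrix:
    """Gene x TF scores a_w(g,t) for one (pairing, assay, group) context."""

    pairing: str
    assay: str
    window: int
    d0: int
    scores: pd.DataFrame  # index gene_id, columns tf_name
    group: str = ""
    # per (gene, tf): list of (region, distance, affinity) triples
    region_links: dict[tuple[str, str], list[tuple[CandidateRegion, float, float]]] = field(
        default_factory=dict
    )

    def top_target_genes(self, tf: str, k: int = 30) -> list[str]:
        """The k genes with largest a_w(g,t); ties broken by gene_id.

        Genes scoring 0 never qualify; an all-zero column yields an empty
        list with a warning.
        """
        if tf not in self.scores.columns:
            raise KeyError(f"TF {tf!r} not scored")
        col = self.scores[tf]
        positive = col[col > 0]
        if positive.empty:
            warnings.warn(f"TF {tf!r} has no positive scores", stacklevel=2)
            return []
        # descending score; equal scores break ties by gene_id
        order = np.lexsort((positive.index.to_numpy(), -positive.to_numpy()))
        return list(positive.index[order][:k])


def tf_gene_scores(
    regions: list[CandidateRegion],
    affinities: pd.DataFrame,
    annotation: GeneAnnotationTable,
    genes: list[str] | None = None,
    window: int = 50_000,
    d0: int = 50_000,
    pairing: str = "",
    assay: str = "",
    group: str = "",
) -> TFGeneScoreMatrix:
    """Aggregate region affinities into per-gene TF scores.

    A region contributes to gene g iff its center lies within window/2 of
    the gene's TSS; its affinity is divided by max(|p| - l, 1) and decayed
    by exp(-d/d0) where d is the center-to-TSS distance.
    """
    if genes is None:
        genes = annotation.gene_ids
    tf_names = list(affinities.columns)
    motif_lengths = affinities.attrs.get("motif_lengths", {})
    score = np.zeros((len(genes), len(tf_names)))
    links: dict[tuple[str, str], list[tuple[CandidateRegion, float, float]]] = {}

    # bucket region indices by chromosome, sorted by center, for window lookup
    by_chrom: dict[str, list[int]] = {}
    for i, reg in enumerate(regions):
        by_chrom.setdefault(reg.interval.chrom, []).append(i)
    centers = np.array([r.interval.center for r in regions]) if regions else np.empty(0)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda i: centers[i])

    aff = affinities.to_numpy()
    half = window / 2
    for gi, gene_id in enumerate(genes):
        rec = annotation[gene_id]
        idxs = by_chrom.get(rec.chrom, [])
        if not idxs:
            continue
        chrom_centers = centers[idxs]
        lo = np.searchsorted(chrom_centers, rec.tss - half, side="left")
        hi = np.searchsorted(chrom_centers, rec.tss + half, side="right")
        for k in range(lo, hi):
            ri = idxs[k]
            reg = regions[ri]
            d = abs(reg.interval.center - rec.tss)
            decay = math.exp(-d / d0)
            length = len(reg.interval)
            for ti, tf in enumerate(tf_names):
                a_pt = aff[ri, ti]
                if a_pt == 0:
                    continue
                l = motif_lengths.get(tf, 0)
                denom = max(length - l, 1)
                score[gi, ti] += a_pt / denom * decay
                links.setdefault((gene_id, tf), []).append((reg, d, a_pt))

    return TFGeneScoreMatrix(
        pairing=pairing,
        assay=assay,
        window=window,
        d0=d0,
        scores=pd.DataFrame(score, index=genes, columns=tf_names),
        group=group,
        region_links=links,
    )
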