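"""Seeded generator of complete, internally consistent toy datasets.

Emulates a two-condition chromatin + expression study on a single small
chromosome: a designated driver TF gains condition-specific peaks carrying
planted motif instances near its target genes, whose transcript counts are
scaled up in the second condition; decoy TF motifs are planted uniformly
in peaks shared by both conditions. Everything the pipeline consumes
(genome FASTA, annotation TSV, JASPAR-style motifs, peak BEDs per group
and assay, a raw count TSV) is written in standard formats together with a
truth table, so parameter-recovery experiments need no external data.

The generator emulates condition-specific binding and differential
expression only; it does not model chromatin-state biology, mappability,
GC structure, or read-level noise, so passing recovery tests demonstrate
the scoring chain, not performance on real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ScenarioConfig", "Scenario", "generate_scenario", "generate_evaluation_peaks"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    effect_size is the multiplicative expression change of driver-target
    genes in the second condition (1.0 gives a null scenario with no
    differential signal); noise is the negative-binomial dispersion of the
    count model (var = mu + noise * mu^2).
    """

    seed: int = 42
    genome_length: int = 5_000_000
    n_genes: int = 200
    n_tfs: int = 10
    n_driver_tfs: int = 1
    groups: tuple[str, str] = ("condA", "condB")
    samples_per_group: int = 3
    assays: tuple[str, ...] = ("H3K27ac",)
    peaks_per_group: int = 120
    peak_length: int = 200
    shared_peaks: int = 30
    motif_length: int = 8
    motif_copies: int = 4
    effect_size: float = 4.0
    noise: float = 0.1
    fraction_driver_targets: float = 0.3

    def __post_init__(self) -> None:
        if self.n_tfs < 2:
            raise ValueError("need at least 2 TFs")
        if self.n_driver_tfs >= self.n_tfs:
            raise ValueError("driver TFs must be a proper subset of the motif set")
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")
        min_len = (self.n_genes + 1) * 500
        if self.genome_length < min_len:
            raise ValueError(
                f"genome too short for {self.n_genes} genes: need >= {min_len} bp"
            )

    @property
    def driver_tfs(self) -> tuple[str, ...]:
        return tuple(f"TF{i + 1:02d}" for i in range(self.n_driver_tfs))

    @property
    def tf_names(self) -> tuple[str, ...]:
        return tuple(f"TF{i + 1:02d}" for i in range(self.n_tfs))


@dataclass
class Scenario:
    """Paths and ground truth of a generated dataset."""

    config: ScenarioConfig
    root: Path
    genome_fasta: Path
    annotation: Path
    motifs: Path
    counts: Path
    peak_beds: dict[tuple[str, str], Path]  # (group, assay) -> BED path
    sample_groups: dict[str, str]
    truth: pd.DataFrame  # columns: kind, tf, gene_id, chrom, start, end, assay


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _consensus(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _pwm_counts(consensus: np.ndarray, total: int = 100, major: float = 0.85) -> np.ndarray:
    """4 x L count matrix concentrated on the consensus base."""
    L = consensus.size
    minor = (1 - major) / 3
    counts = np.full((4, L), minor * total)
    counts[consensus, np.arange(L)] = major * total
    return counts


def generate_scenario(cfg: ScenarioConfig, out_dir: str | Path) -> Scenario:
    """Write a complete dataset to ``out_dir``; deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    chrom = "chr1"

    genome = _random_sequence(rng, cfg.genome_length)

    # --- genes: TSS on a jittered grid, TF genes first so the expression
    # gate on motif constituents can be exercised
    spacing = cfg.genome_length / (cfg.n_genes + 1)
    tss = ((np.arange(1, cfg.n_genes + 1)) * spacing).astype(int)
    tss = tss + rng.integers(-int(spacing / 4), int(spacing / 4) + 1, cfg.n_genes)
    tss = np.clip(tss, 0, cfg.genome_length - 1)
    gene_ids = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    symbols = list(cfg.tf_names) + [
        f"GENE{i + 1:04d}" for i in range(cfg.n_genes - cfg.n_tfs)
    ]
    strands = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")
    lengths = np.maximum(200, rng.lognormal(7.3, 0.4, cfg.n_genes).astype(int))

    # --- motifs
    consensi = {tf: _consensus(rng, cfg.motif_length) for tf in cfg.tf_names}

    # --- driver targets: non-TF genes only
    candidate_targets = np.arange(cfg.n_tfs, cfg.n_genes)
    n_targets = int(round(cfg.fraction_driver_targets * candidate_targets.size))
    target_idx = np.sort(
        rng.choice(candidate_targets, size=n_targets, replace=False)
    )
    # partially overlapping per-assay target sets (identical for 1 assay)
    assay_targets: dict[str, np.ndarray] = {}
    n_assays = len(cfg.assays)
    if n_assays == 1:
        assay_targets[cfg.assays[0]] = target_idx
    else:
        third = max(1, n_targets // 3)
        for ai, assay in enumerate(cfg.assays):
            if ai == 0:
                assay_targets[assay] = target_idx[: 2 * third]
            else:
                assay_targets[assay] = target_idx[third:]

    def plant(site_start: int, motif: np.ndarray) -> None:
        genome[site_start : site_start + motif.size] = motif

    truth_rows: list[dict[str, object]] = []
    peak_rows: dict[tuple[str, str], list[tuple[int, int, str]]] = {
        (g, a): [] for g in cfg.groups for a in cfg.assays
    }
    group_a, group_b = cfg.groups

    for assay in cfg.assays:
        # background peaks, independent per group
        for group in cfg.groups:
            starts = rng.integers(
                0, cfg.genome_length - cfg.peak_length, cfg.peaks_per_group
            )
            peak_rows[(group, assay)].extend(
                (int(s), int(s) + cfg.peak_length, "background") for s in starts
            )
        # shared peaks carrying decoy motif instances, present in both groups
        decoys = [t for t in cfg.tf_names if t not in cfg.driver_tfs]
        shared_starts = rng.integers(
            0, cfg.genome_length - cfg.peak_length, cfg.shared_peaks
        )
        for s in shared_starts:
            s = int(s)
            tf = decoys[int(rng.integers(0, len(decoys)))]
            offset = int(rng.integers(0, cfg.peak_length - cfg.motif_length))
            plant(s + offset, consensi[tf])
            for group in cfg.groups:
                peak_rows[(group, assay)].append((s, s + cfg.peak_length, "shared"))
        # driver peaks near target TSSs, condition B only, with planted copies
        if cfg.effect_size > 1:
            for tf in cfg.driver_tfs:
                for gi in assay_targets[assay]:
                    center = int(tss[gi] + rng.integers(-500, 501))
                    start = max(
                        0,
                        min(
                            center - cfg.peak_length // 2,
                            cfg.genome_length - cfg.peak_length,
                        ),
                    )
                    slots = np.arange(0, cfg.peak_length - cfg.motif_length, cfg.motif_length + 2)
                    chosen = rng.choice(slots, size=cfg.motif_copies, replace=False)
                    for off in chosen:
                        plant(start + int(off), consensi[tf])
                    peak_rows[(group_b, assay)].append(
                        (start, start + cfg.peak_length, f"driver_{tf}")
                    )
                    truth_rows.append(
                        {
                            "kind": "site",
                            "tf": tf,
                            "gene_id": gene_ids[gi],
                            "chrom": chrom,
                            "start": start,
                            "end": start + cfg.peak_length,
                            "assay": assay,
                        }
                    )

    for tf in cfg.driver_tfs:
        truth_rows.append(
            {"kind": "driver", "tf": tf, "gene_id": "", "chrom": "", "start": -1, "end": -1, "assay": ""}
        )
    all_targets = sorted({int(i) for a in assay_targets.values() for i in a})
    for gi in all_targets:
        truth_rows.append(
            {
                "kind": "target",
                "tf": ",".join(cfg.driver_tfs),
                "gene_id": gene_ids[gi],
                "chrom": chrom,
                "start": int(tss[gi]),
                "end": int(tss[gi]) + 1,
                "assay": "",
            }
        )
    truth = pd.DataFrame(
        truth_rows, columns=["kind", "tf", "gene_id", "chrom", "start", "end", "assay"]
    )

    # --- counts: lognormal baseline means, NB sampling, targets scaled in B
    base_mean = rng.lognormal(5.5, 0.7, cfg.n_genes)
    target_mask = np.zeros(cfg.n_genes, dtype=bool)
    target_mask[all_targets] = True
    samples, groups_map = [], {}
    count_cols = {}
    for group in cfg.groups:
        for r in range(cfg.samples_per_group):
            name = f"{group}_r{r + 1}"
            samples.append(name)
            groups_map[name] = group
            mu = base_mean.copy()
            if group == group_b and cfg.effect_size > 1:
                mu[target_mask] *= cfg.effect_size
            if cfg.noise > 0:
                shape = 1.0 / cfg.noise
                lam = rng.gamma(shape, mu / shape)
            else:
                lam = mu
            count_cols[name] = rng.poisson(lam)

    # --- write everything
    genome_fasta = root / "genome.fa"
    seq = "".join(_BASES[genome])
    with open(genome_fasta, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")

    annotation = root / "annotation.tsv"
    pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": symbols,
            "chrom": chrom,
            "strand": strands,
            "tss": tss + 1,  # annotation TSV is 1-based
            "length": lengths,
            "description": ["synthetic gene"] * cfg.n_genes,
        }
    ).to_csv(annotation, sep="\t", index=False)

    motifs_path = root / "motifs.jaspar"
    with open(motifs_path, "w") as fh:
        for tf in cfg.tf_names:
            counts = _pwm_counts(consensi[tf])
            fh.write(f">{tf}\n")
            for bi, base in enumerate("ACGT"):
                row = " ".join(f"{v:.2f}" for v in counts[bi])
                fh.write(f"{base} [ {row} ]\n")

    counts_path = root / "counts.tsv"
    pd.DataFrame(count_cols, index=pd.Index(gene_ids, name="gene_id")).to_csv(
        counts_path, sep="\t"
    )

    peak_beds = {}
    peak_dir = root / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for (group, assay), rows in peak_rows.items():
        path = peak_dir / f"{group}_{assay}.bed"
        rows_sorted = sorted(rows)
        with open(path, "w") as fh:
            for start, end, label in rows_sorted:
                fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")
        peak_beds[(group, assay)] = path

    truth.to_csv(root / "truth.tsv", sep="\t", index=False)

    return Scenario(
        config=cfg,
        root=root,
        genome_fasta=genome_fasta,
        annotation=annotation,
        motifs=motifs_path,
        counts=counts_path,
        peak_beds=peak_beds,
        sample_groups=groups_map,
        truth=truth,
    )


def generate_evaluation_peaks(
    truth: pd.DataFrame,
    out_dir: str | Path,
    jitter_bp: int = 0,
    fpr: float = 0.0,
    seed: int = 42,
    peak_length: int = 200,
    genome_length: int = 5_000_000,
) -> dict[str, Path]:
    """Experimental-style evaluation peaks per driver TF.

    Peaks are centered on the planted sites, displaced by up to
    ``jitter_bp``; a fraction ``fpr`` of the emitted peaks is replaced by
    uniformly random peaks. Returns one BED path per driver TF.
    """
    if not 0 <= fpr <= 1:
        raise ValueError("fpr must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    sites = truth[truth["kind"] == "site"]
    out: dict[str, Path] = {}
    for tf, grp in sites.groupby("tf", sort=True):
        n_total = len(grp)
        n_random = int(round(fpr * n_total))
        n_real = n_total - n_random
        rows = []
        for _, site in grp.head(n_real).iterrows():
            center = (int(site["start"]) + int(site["end"])) // 2
            if jitter_bp:
                center += int(rng.integers(-jitter_bp, jitter_bp + 1))
            start = max(0, center - peak_length // 2)
            rows.append((site["chrom"], start, start + peak_length))
        for _ in range(n_random):
            s = int(rng.integers(0, genome_length - peak_length))
            rows.append(("chr1", s, s + peak_length))
        path = root / f"{tf}_eval.bed"
        with open(path, "w") as fh:
            for chrom, start, end in sorted(rows):
                fh.write(f"{chrom}\t{start}\t{end}\n")
        out[str(tf)] = path
    return out
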