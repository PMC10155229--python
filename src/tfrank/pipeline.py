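"""Pipeline configuration and end-to-end orchestration.

Runs, for every condition pair and assay with available peak data:
expression normalization and fold changes -> candidate-region derivation ->
biophysical affinities -> per-group TF-Gene scores -> logistic regression
on score changes -> combined TF-target-gene scores; then gates and ranks
TFs per assay, aggregates ranks globally, and optionally validates
predicted regions against experimental peaks and computes TF co-occurrence.
Assay/pair combinations with missing peak files are skipped with a logged
warning and simply do not contribute to the aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml
from pyfaidx import Fasta

from . import affinity as aff
from . import dynamite as dyn
from . import expression as expr
from . import prioritization as prio
from . import validation as val
from .cooccurrence import cooccurrence_matrices
from .intervals import (
    CandidateRegion,
    PeakSet,
    RegionTree,
    derive_dip_regions,
    filter_blacklist,
    merge_group_peaks,
)
from .io import fetch_sequence, read_bed, read_counts, read_gene_annotation, read_motifs

logger = logging.getLogger("tfrank")

__all__ = ["PipelineConfig", "PipelineResult", "load_config", "run_pipeline"]

_NON_HISTONE_PREFIXES = ("atac", "dnase", "footprint")


@dataclass
class PipelineConfig:
    genome: Path
    annotation: Path
    motifs: Path
    counts: Path
    sample_groups: dict[str, str]
    peaks: dict[str, dict[str, list[Path]]]  # group -> assay -> bed paths
    condition_pairs: list[tuple[str, str]]
    blacklist: Path | None = None
    evaluation_peaks: dict[str, Path] = field(default_factory=dict)
    window: int = 50_000
    d0: int = 50_000
    dip_max_gap: int = 500
    dip_mode: str = "add"
    tpm_min: float = 1.0
    mean_count_min: float = 50.0
    alpha: float = 0.05
    prediction_quantile: float = 0.9
    match_distance: int = 50_000
    seed: int = 42
    components: frozenset[str] = prio.ALL_COMPONENTS

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0 <= self.prediction_quantile <= 1:
            raise ValueError("prediction_quantile must lie in [0, 1]")
        for p in (self.window, self.d0, self.dip_max_gap):
            if p <= 0:
                raise ValueError("window, d0 and dip_max_gap must be positive")
        if self.dip_mode not in {"add", "replace", "off"}:
            raise ValueError(f"invalid dip_mode {self.dip_mode!r}")
        self.components = frozenset(self.components)
        if not self.components <= prio.ALL_COMPONENTS:
            raise ValueError(f"invalid components {sorted(self.components)}")
        for path in self._required_paths():
            if not Path(path).exists():
                raise FileNotFoundError(str(path))

    def _required_paths(self) -> list[Path]:
        paths = [self.genome, self.annotation, self.motifs, self.counts]
        if self.blacklist is not None:
            paths.append(self.blacklist)
        paths.extend(self.evaluation_peaks.values())
        for assays in self.peaks.values():
            for beds in assays.values():
                paths.extend(beds)
        return paths

    @property
    def assays(self) -> list[str]:
        seen: dict[str, None] = {}
        for assays in self.peaks.values():
            for a in assays:
                seen.setdefault(a, None)
        return list(seen)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a declarative YAML configuration file."""
    path = Path(path)
    with open(path) as fh:
        raw: dict[str, Any] = yaml.safe_load(fh)
    base = path.parent

    def resolve(p: str | None) -> Path | None:
        return None if p is None else (base / p)

    peaks = {
        group: {
            assay: [base / b for b in (beds if isinstance(beds, list) else [beds])]
            for assay, beds in assays.items()
        }
        for group, assays in raw["peaks"].items()
    }
    pairs_raw = raw.get("condition_pairs", "consecutive")
    groups_in_order = list(peaks)
    if pairs_raw == "consecutive":
        pairs = list(zip(groups_in_order, groups_in_order[1:]))
    elif pairs_raw == "pairwise":
        pairs = [
            (a, b)
            for i, a in enumerate(groups_in_order)
            for b in groups_in_order[i + 1 :]
        ]
    else:
        pairs = [tuple(p) for p in pairs_raw]
    params = raw.get("parameters", {})
    return PipelineConfig(
        genome=base / raw["genome"],
        annotation=base / raw["annotation"],
        motifs=base / raw["motifs"],
        counts=base / raw["counts"],
        sample_groups=dict(raw["sample_groups"]),
        peaks=peaks,
        condition_pairs=pairs,
        blacklist=resolve(raw.get("blacklist")),
        evaluation_peaks={
            tf: base / p for tf, p in (raw.get("evaluation_peaks") or {}).items()
        },
        **{k: v for k, v in params.items()},
    )


@dataclass
class PipelineResult:
    out_dir: Path
    global_ranking: prio.GlobalRanking
    per_hm: list[prio.HMPrioritization]
    differential: dict[tuple[str, str], expr.DifferentialResult]
    regressions: list[dyn.RegressionResult]
    tf_tg_tables: list[prio.TFTGTable]
    pair_scores: dict[tuple[str, str, str], aff.TFGeneScoreMatrix]  # (pair, assay)
    validation: pd.DataFrame | None = None
    cooccurrence: dict[str, pd.DataFrame] | None = None


def _assay_dip_mode(assay: str, configured: str) -> str:
    if assay.lower().startswith(_NON_HISTONE_PREFIXES):
        return "off"
    return configured


def _candidate_regions_for(
    cfg: PipelineConfig,
    group: str,
    assay: str,
    blacklist: PeakSet | None,
    pairing: str,
) -> list[CandidateRegion]:
    peak_sets = [
        read_bed(p, group=group, assay=assay) for p in cfg.peaks[group][assay]
    ]
    merged = merge_group_peaks(peak_sets)
    if blacklist is not None:
        merged = filter_blacklist(merged, blacklist)
    mode = _assay_dip_mode(assay, cfg.dip_mode)
    return derive_dip_regions(merged, cfg.dip_max_gap, mode, pairing=pairing)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    annotation = read_gene_annotation(cfg.annotation)
    counts = read_counts(cfg.counts, cfg.sample_groups)
    motifs = read_motifs(cfg.motifs)
    genome = Fasta(str(cfg.genome))
    blacklist = (
        read_bed(cfg.blacklist) if cfg.blacklist is not None else None
    )

    retained_genes = expr.filter_genes(
        counts, annotation, cfg.tpm_min, cfg.mean_count_min
    )
    motifs = expr.retained_motifs(motifs, counts, annotation, cfg.tpm_min)
    logger.info(
        "retained %d/%d genes and %d motifs after expression filters",
        len(retained_genes),
        len(counts.genes),
        len(motifs),
    )
    if not retained_genes or not motifs:
        raise ValueError("expression filters removed every gene or motif")

    differential: dict[tuple[str, str], expr.DifferentialResult] = {}
    for pair in cfg.condition_pairs:
        diff = expr.log2_fold_change(counts, pair, annotation=annotation)
        diff.table = diff.table.loc[
            [g for g in retained_genes if g in diff.table.index]
        ]
        differential[pair] = diff

    group_scores: dict[tuple[str, str], aff.TFGeneScoreMatrix] = {}
    group_region_affinities: dict[tuple[str, str], tuple[list, pd.DataFrame]] = {}

    def scores_for(group: str, assay: str, pairing: str) -> aff.TFGeneScoreMatrix:
        key = (group, assay)
        if key not in group_scores:
            regions = _candidate_regions_for(cfg, group, assay, blacklist, pairing)
            seqs = [fetch_sequence(genome, r.interval) for r in regions]
            affin = aff.region_affinities(regions, seqs, motifs)
            group_region_affinities[key] = (regions, affin)
            group_scores[key] = aff.tf_gene_scores(
                regions,
                affin,
                annotation,
                genes=retained_genes,
                window=cfg.window,
                d0=cfg.d0,
                pairing=pairing,
                assay=assay,
                group=group,
            )
            logger.info(
                "%s/%s: %d candidate regions scored", group, assay, len(regions)
            )
        return group_scores[key]

    tables: list[prio.TFTGTable] = []
    regressions: list[dyn.RegressionResult] = []
    pair_scores: dict[tuple[str, str, str], aff.TFGeneScoreMatrix] = {}
    for assay in cfg.assays:
        for pair in cfg.condition_pairs:
            group_a, group_b = pair
            missing = [
                g for g in pair if assay not in cfg.peaks.get(g, {})
            ]
            if missing:
                logger.warning(
                    "skipping %s for pair %s: no peak data for %s",
                    assay,
                    pair,
                    missing,
                )
                continue
            pairing = f"{group_a}_vs_{group_b}"
            sa = scores_for(group_a, assay, pairing)
            sb = scores_for(group_b, assay, pairing)
            diff = differential[pair]
            features, labels = dyn.build_features(sa.scores, sb.scores, diff.log2fc)
            reg = dyn.fit_logistic(
                features, labels, seed=cfg.seed, pairing=pairing, assay=assay
            )
            regressions.append(reg)
            # pairing-level binding evidence: mean of the two group matrices
            mean_scores = aff.TFGeneScoreMatrix(
                pairing=pairing,
                assay=assay,
                window=cfg.window,
                d0=cfg.d0,
                scores=(sa.scores + sb.scores) / 2,
            )
            pair_scores[(pairing, assay, "mean")] = mean_scores
            pair_scores[(pairing, assay, group_a)] = sa
            pair_scores[(pairing, assay, group_b)] = sb
            tables.append(
                prio.tf_tg_scores(diff, mean_scores, reg, cfg.components)
            )

    if not tables:
        raise ValueError("no condition pair x assay combination had usable data")

    per_hm = []
    for assay in cfg.assays:
        assay_tables = [t for t in tables if t.assay == assay]
        if not assay_tables:
            continue
        try:
            dists = prio.build_distributions(assay_tables)
        except ValueError:
            # every combined score is zero (e.g. all regression coefficients
            # shrunk away): nothing to test for this assay
            logger.warning("assay %s: no positive combined scores", assay)
            per_hm.append(
                prio.HMPrioritization(assay=assay, fg={}, bg=np.empty(0))
            )
            continue
        per_hm.append(prio.prioritize_per_hm(dists, cfg.alpha))
    ranking = prio.aggregate_global(per_hm)

    # --- optional validation against experimental peaks
    validation_df = None
    if cfg.evaluation_peaks:
        bounds = {name: len(genome[name]) for name in genome.keys()}
        rows = []
        for tf, bed in sorted(cfg.evaluation_peaks.items()):
            hits = [
                (key, group_region_affinities[key])
                for key in group_region_affinities
                if tf in group_region_affinities[key][1].columns
            ]
            if not hits:
                continue
            exp_tree = RegionTree(read_bed(bed).intervals)
            # pool candidate regions over groups/assays for this TF
            all_pred = []
            for _, (regions, affin) in hits:
                all_pred.extend(
                    val.predicted_regions(regions, affin, tf, cfg.prediction_quantile)
                )
            cm = val.classify(
                all_pred, exp_tree, bounds, cfg.match_distance, cfg.seed, tf
            )
            m = val.metrics(cm)
            rows.append(
                {"tf": tf, "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn, **m}
            )
        validation_df = pd.DataFrame(rows)

    cooc = None
    if len(cfg.evaluation_peaks) >= 2:
        peak_sets = {
            tf: read_bed(bed) for tf, bed in sorted(cfg.evaluation_peaks.items())
        }
        cooc = cooccurrence_matrices(peak_sets)

    result = PipelineResult(
        out_dir=out,
        global_ranking=ranking,
        per_hm=per_hm,
        differential=differential,
        regressions=regressions,
        tf_tg_tables=tables,
        pair_scores=pair_scores,
        validation=validation_df,
        cooccurrence=cooc,
    )
    write_outputs(result, cfg)
    return result


def write_outputs(result: PipelineResult, cfg: PipelineConfig) -> None:
    """Write every result table as TSV into the output directory."""
    out = result.out_dir
    result.global_ranking.table.to_csv(out / "global_ranking.tsv", sep="\t")
    for hm in result.per_hm:
        hm.stats.to_csv(out / f"prioritization_{hm.assay}.tsv", sep="\t")
    omega = pd.concat(
        [
            t.entries.assign(pairing=t.pairing, assay=t.assay)
            for t in result.tf_tg_tables
        ],
        ignore_index=True,
    )
    omega.to_csv(out / "tf_tg_scores.tsv", sep="\t", index=False)
    for pair, diff in result.differential.items():
        name = f"differential_{pair[0]}_vs_{pair[1]}.tsv"
        diff.table.to_csv(out / name, sep="\t", index_label="gene_id")
        for direction in ("up", "down"):
            loci = prio.select_top_loci(diff, k=30, direction=direction)
            pd.Series(loci, name="gene_id").to_csv(
                out / f"top_loci_{direction}_{pair[0]}_vs_{pair[1]}.tsv",
                sep="\t",
                index=False,
            )
    coef = pd.DataFrame(
        [
            {
                "pairing": r.pairing,
                "assay": r.assay,
                "tf": tf,
                "eta": eta,
                "abs_eta": abs(eta),
                "cv_accuracy": r.cv_accuracy,
                "C": r.hyperparameter,
            }
            for r in result.regressions
            for tf, eta in sorted(r.coefficients.items())
        ]
    )
    coef.to_csv(out / "regression_coefficients.tsv", sep="\t", index=False)
    # top targets per prioritized TF (from the pairing-mean score matrices)
    rows = []
    for (pairing, assay, tag), sm in result.pair_scores.items():
        if tag != "mean":
            continue
        for tf in result.global_ranking.order:
            if tf not in sm.scores.columns:
                continue
            for rank, gene in enumerate(sm.top_target_genes(tf, 30), start=1):
                rows.append(
                    {"pairing": pairing, "assay": assay, "tf": tf, "rank": rank, "gene_id": gene}
                )
    pd.DataFrame(rows).to_csv(out / "top_target_genes.tsv", sep="\t", index=False)
    if result.validation is not None and not result.validation.empty:
        result.validation.to_csv(out / "validation_metrics.tsv", sep="\t", index=False)
    if result.cooccurrence is not None:
        for key, mat in result.cooccurrence.items():
            mat.to_csv(out / f"cooccurrence_{key}.tsv", sep="\t")
    from .report import render_report

    (out / "report.html").write_text(render_report(result))
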