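"""Validating predicted binding regions against experimental peaks.

Simulates a study, derives the driver TF's predicted regions from its
planted sites, generates jittered experimental-style evaluation peaks,
and computes the confusion metrics with length-matched random negatives.
"""

import tempfile
from pathlib import Path

from tfrank.intervals import GenomicInterval, RegionTree
from tfrank.io import read_bed
from tfrank.simulate import ScenarioConfig, generate_evaluation_peaks, generate_scenario
from tfrank.validation import classify, metrics

workdir = Path(tempfile.mkdtemp())
scenario = generate_scenario(ScenarioConfig(seed=7), workdir / "data")
beds = generate_evaluation_peaks(
    scenario.truth, workdir / "eval", jitter_bp=200, fpr=0.2, seed=7,
    genome_length=scenario.config.genome_length,
)

driver = scenario.config.driver_tfs[0]
sites = scenario.truth[scenario.truth["kind"] == "site"]
predicted = [
    GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in sites.itertuples()
]
experimental = RegionTree(read_bed(beds[driver]).intervals)

cm = classify(
    predicted,
    experimental,
    {"chr1": scenario.config.genome_length},
    match_distance=500,
    seed=7,
)
m = metrics(cm)
print(f"{driver}: TP={cm.tp} FP={cm.fp} FN={cm.fn} TN={cm.tn}")
for name, value in m.items():
    print(f"  {name:12s} {100 * value:5.1f}%")
print("Negatives are length-matched random regions outside the predictions;")
print("an FN is such a region that still hits an experimental peak.")
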