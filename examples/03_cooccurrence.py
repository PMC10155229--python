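"""TF co-occurrence: overlap percentages and the G2 statistic.

Builds two TF peak sets that share half their binding sites and scores
their association over the merged binding-site universe.
"""

from tfrank.cooccurrence import build_universe, contingency, g2_score
from tfrank.intervals import GenomicInterval, PeakSet


def peaks(starts, length=200):
    return PeakSet([GenomicInterval("chr1", s, s + length) for s in starts])


shared = list(range(0, 20_000, 1000))  # 20 shared sites
tf_a = peaks(shared + list(range(50_000, 60_000, 1000)))  # + 10 private
tf_b = peaks(shared + list(range(80_000, 95_000, 1000)))  # + 15 private

universe = build_universe([tf_a, tf_b])
table, pct = contingency(tf_a, tf_b, universe)
g2 = g2_score(table)

print(f"binding-site universe |B| = {len(universe)}")
print(f"count(A) = {table.count_t1}, count(B) = {table.count_t2}, "
      f"co-occurring = {table.n11}")
print(f"{pct:.1f}% of A's sites are also bound by B")
print(f"G2 log-likelihood score = {g2:.2f}")
print("G2 near 0 would mean the overlap is what independence predicts;")
print("large values flag co-occurrence far beyond chance for this |B|.")
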