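"""Quantify selection with the non-uniformity statistic mu = Q/K.

Generates a synthetic cohort with 10 planted driver genes, then compares
the non-uniformity of silent mutations (no selection), all missense
mutations, and the high-impact missense bins.  mu ~ 1 means mutations are
spread evenly over genes; mu >> 1 means a few genes soak up the majority
of mutations — the hallmark of selection.  The length-proportional null
shows how much non-uniformity gene-length differences alone produce.
"""

from mutsel import CohortSpec, VariantClass, gen_cohort
from mutsel.selection_stats import length_null_non_uniformity, non_uniformity, tally

cohort = gen_cohort(CohortSpec(seed=1))

print(f"{'mutation set':<22}{'Q':>6}{'M':>7}{'K':>9}{'mu':>8}")
for name, cls, thr in [
    ("silent", VariantClass.SILENT, None),
    ("truncating", VariantClass.TRUNCATING, None),
    ("missense (all)", VariantClass.MISSENSE, None),
    ("missense FIS>2.5", VariantClass.MISSENSE, 2.5),
    ("missense FIS>3.0", VariantClass.MISSENSE, 3.0),
]:
    r = non_uniformity(tally(cohort.records, cls, fis_bin=thr))
    print(f"{name:<22}{r.q:>6}{r.m:>7}{r.k:>9.1f}{r.mu:>8.2f}")

null = length_null_non_uniformity(cohort.gene_lengths)
print(f"\nlength-proportional null: K = {null.k:.0f} of {null.q} genes, "
      f"mu = {null.mu:.2f}")
print("Silent mutations sit near the length null; the FIS>2.5 bin concentrates")
print("in far fewer effective genes, i.e. strong selection of high-impact mutations.")
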