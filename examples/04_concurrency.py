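"""Concurrency of high-impact missense mutations with other loss signals.

Two selection cross-checks: (1) genes hit by high-FIS missense mutations
are disproportionately also hit by truncating mutations in other tumors,
especially among tumor suppressors; (2) truncating mutations are enriched
in genes under copy-number loss (CNA state −1) relative to silent
mutations, with a Fisher exact p-value for the contrast.
"""

from mutsel import CohortSpec, VariantClass, gen_cohort
from mutsel.selection_stats import cna_concurrency, truncating_concurrency

cohort = gen_cohort(CohortSpec(seed=1))

print("genes with both binned missense and truncating hits (different tumors):")
for group in ("TS", "nCG"):
    out = truncating_concurrency(cohort.records, gene_group=group,
                                 annotations=cohort.annotations)
    row = "  ".join(f"{label}={pct:5.1f}%" for label, pct in out.items()
                    if pct is not None)
    print(f"  {group:<4} {row}")

res = cna_concurrency(cohort.records, cohort.cna_lookup, VariantClass.TRUNCATING)
print("\npercentage of mutations by CNA state (−1 loss ... 2 amplification):")
print("  silent:     " + "  ".join(f"{res.silent_percentages[s]:5.1f}" for s in (-1, 0, 1, 2)))
print("  truncating: " + "  ".join(f"{res.percentages[s]:5.1f}" for s in (-1, 0, 1, 2)))
print(f"  Fisher exact p (state −1): {res.p_loss:.2e}")
print("Truncating mutations pile into copy-loss genes; silent mutations do not.")
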