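# Methods

## Model and assumptions

### Functional impact score

The score treats a protein family multiple alignment as a statistical
ensemble in which each column reflects, independently of other columns,
the constraints evolution imposes on that position.  For a substitution
α→β at the column mapped from protein position *i*:

FIS_i(α→β) = −½ [ ln (n_i(β)+1)/n_i(α) + ln (n_ip(β)+1)/n_ip(α) ]

with family counts n_i(·), subfamily counts n_ip(·) taken in the subfamily
*p* containing the query sequence, natural logarithms, and a pseudocount
of +1 on the destination (β) counts only.  Gaps count as a 21st residue
type in the column tallies, but substitutions to or from a gap are never
scored (scored mutations are missense by construction).  Consequences
implemented as stated rather than patched:

* the score is 0 exactly when n_i(β)+1 = n_i(α) and n_ip(β)+1 = n_ip(α);
* if the query is alone in its subfamily, n_ip(α) = 1 and the subfamily
  term reduces to −½·ln(n_ip(β)+1), i.e. 0 for an unobserved β — the
  formula is applied as written, not special-cased;
* a mismatch between the annotated reference residue and the query's
  residue at the mapped column refuses to score (data integrity over
  coverage), as does a position beyond the ungapped query length.

Protein positions are 1-based (p.R273H style); alignment columns are
0-based internally, converted at the scoring boundary by walking the
query's non-gap characters.  No sequence weighting or redundancy filtering
is applied before counting.

Subfamily labels are expected to come from an external decomposition of
the family; when absent, a baseline average-linkage hierarchical
clustering on pairwise identity distance (1 − fraction of identical
characters) assigns them, cut at 4 clusters or the sequence count if
smaller, with ties resolved by input order so results are deterministic.
This baseline recovers clean block structure but is not a specificity-
position method; supplied labels are the first-class path.

### Non-uniformity of mutation distributions

For per-gene counts N_i of a filtered mutation set (Q mutated genes,
M = ΣN_i, p_i = N_i/M): λ = Σp_i² is the Simpson diversity index,
N = M·λ the weighted average mutations per gene, K = 1/λ the effective
number of mutated genes, and μ = Q/K = λ·Q the non-uniformity.  Limits:
equal counts give μ = 1 exactly; a single dominant gene gives K → 1 and
μ → Q.  μ is invariant under gene relabeling and proportional scaling of
all counts, so it compares mutation classes fairly regardless of their
absolute rates.  An empty filtered set is a valid tally that the statistic
refuses explicitly rather than returning NaN.

FIS bins are cumulative — "FIS>2.5" contains every scored missense
mutation above 2.5, not an interval — and unscored missense records are
excluded from binned statistics rather than imputed at 0, which would
deflate the high bins.  Bin thresholds default to
{all, >1, >2, >2.5, >3, >3.5}.

Gene-length differences alone produce non-uniformity.  The length null
sets p_i proportional to coding length and reports λ, K, μ over all genes;
it is reported beside the observed statistic, never subtracted from it,
because comparisons between large gene groups average out length effects.
Cancer-gene fractions are counted at mutation level; truncating
concurrency at gene level, requiring the missense and truncating hits to
come from different tumors (a same-tumor pair is no evidence of
independent selection).  The copy-number comparison contrasts a mutation
set's distribution over discretized states {−1, 0, 1, 2} with the silent
class via a two-sided Fisher exact test on the in-state/out-of-state 2×2
table at loss (−1) and gain (+1); an exact test is the conservative choice
at the small counts the high-FIS bins can reach.

### Driver nomination

Genes are ranked by n_high = #(missense FIS > high) + #(truncating), high
defaulting to 2.5, ties broken by total missense+truncating count then by
gene symbol.  The effective gene set is the top round-half-up(K) genes
(floor 1) over the chosen basis counts — all missense+truncating, or
high-functional only — with genes whose basis count is zero never
admitted.  The passenger rule flags n_low ≥ n_high with n_low = #(missense
FIS < 1.0); scores in the closed band [1.0, 2.5] count toward neither side
because that range is where impact prediction is least certain.  A gene
with no scored mutation outside the band has n_high = n_low = 0 and is
flagged by the literal ≥ rule; such genes rank last and cannot enter an
effective set.  Long genes (coding length strictly greater than 15,000 nt)
are flagged, not removed — removal is opt-in, since the passenger rule
already demotes most length-driven false positives.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, so every stage
is testable without external data:

* **Gene lengths**: log-normal(meanlog 7.25, sdlog 0.6) nucleotides
  (median ≈ 1.4 kb), floor 150 nt.
* **Family alignments**: a small number of template alignments (default 6,
  60 sequences × 80 columns, 3 equal subfamilies) shared across genes.
  10% of columns are family-conserved (one consensus residue in ≥95% of
  sequences), 30% of the remainder subfamily-specific, the rest uniform.
* **Mutations**: 100 tumors × 50 mutations; classes silent/truncating/
  missense at 0.3/0.1/0.6.  Passenger mutations of every class fall across
  genes proportionally to coding length.  The 10 driver genes receive a
  20-fold rate multiplier for missense and truncating mutations; the
  excess missense is placed at conserved columns (probability 0.8) with
  the least-observed residue as the alternate, so its high FIS arises from
  actually scoring the substitution against the alignment — the scoring
  function stays in the loop end to end.  A `fis_mode="sampled"` fast path
  draws FIS values from calibrated normal mixtures instead, for large-n
  property tests.
* **Copy number**: per (gene, sample) categorical states with marginals
  (−1: 0.15, 0: 0.65, 1: 0.17, 2: 0.03); truncating mutations choose their
  tumor with a 3-fold preference for samples where their gene is in loss.
* **Annotations**: drivers are annotated TS (hence CG); additional
  randomly chosen genes pad the TS/OG/CG lists to 40/15/100 so that group
  comparisons (TS vs nCG) have non-driver members on both sides.

All generation is deterministic given the seed.  What the generator does
*not* emulate: trinucleotide mutation signatures, hypermutator samples,
inter-gene conservation differences, and recurrent position-level hotspots
beyond what conserved-column placement produces.  Passing tests therefore
demonstrate that the statistics detect the planted concentration and
concurrency signals at realistic magnitudes — not that real cohorts will
show effects of the same size.

### What the planted signals do to the statistics

With all drivers equally selected, restricting a tally to a *small* gene
group (e.g. the drivers themselves) makes the high-FIS bin nearly uniform
and μ can decrease; the selection signal μ(FIS>2.5) > μ(all missense)
appears when the tally spans a broad gene population whose high bin keeps
a wide passenger tail while drivers dominate its mass.  Recovery tests
therefore compare bins over all genes.  Similarly, the Simpson K over
high-functional counts retains the passenger singleton tail (every gene
with one truncating mutation contributes), so the effective set is larger
than the driver set and recovery is measured as recall against a
size-matched random baseline plus precision at the top of the ranking.

The null configuration (selection strength 1, loss enrichment 1) is
exactly multinomial length-proportional sampling, so tests compare its μ
to the finite-M expectation of the length null, E[λ̂] = ((M−1)λ+1)/M and
E[Q̂] = Σ(1−(1−p_i)^M), which converges to λ·Q as M grows.

## Numerical and interface choices

* Counts are exact integers; λ, K, μ are computed in double precision and
  cross-checked in tests against brute-force recomputation to 1e−12.
* Percentages are displayed to one decimal; tests compare counts, never
  rounded percentages.
* Variant classes map from raw MAF labels case-insensitively; the default
  truncating set is {Nonsense, Frame_Shift_Del, Frame_Shift_Ins,
  Splice_Site, Nonstop} and is user-overridable, since "truncating" has no
  single canonical definition.  Unknown labels map to "other" and are kept
  but excluded from all statistics.
* Gene symbols are trimmed and upper-cased; no alias resolution.
* Non-standard residue characters (X, B, Z, *, .) are tallied as the gap
  type rather than rejected.
* Test problem sizes (e.g. 50 default cohorts for recovery, 100 small
  null cohorts, 150-gene null cohorts with 6000 mutations) were chosen so
  sampling error and finite-M bias are small relative to the effects under
  test while the whole suite stays fast.

## Known limitations

* The baseline subfamily clustering is a generic identity-based
  decomposition, not a specificity-determining-position method; scores
  depend on subfamily quality, so curated labels should be supplied when
  available.
* No multiple-testing correction is applied across bins or comparisons;
  p-values are raw by design.
* Homolog retrieval and alignment construction are out of scope:
  alignments are inputs.
* The length null uses coding length as the sole exposure; mutation-rate
  covariates (replication timing, expression) are not modeled.
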