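# mutsel

Somatic mutations in tumors are a mixture of *drivers*, which confer a
selective advantage to cancer cells, and functionally inert *passengers*.
`mutsel` implements an evolutionary-selection analysis of somatic mutation
catalogs: it scores missense mutations by an alignment-based functional
impact score, quantifies selection with a Simpson-diversity non-uniformity
statistic, measures the concurrency of high-impact missense mutations with
truncating mutations and copy-number loss, and nominates candidate driver
genes with a passenger-flagging rule.  It is aimed at cancer-genomics
analysts working with MAF-like mutation tables, protein family alignments,
gene annotation lists and discretized copy-number matrices — and it ships a
synthetic-cohort generator so the whole pipeline is testable end to end
without external data.

## The statistics

**Functional impact score (FIS).**  For a substitution α→β at protein
position *i*, with n_i(·) the residue-type counts in alignment column *i*
of the protein family and n_ip(·) the counts within the query's subfamily
*p* (gaps are the 21st residue type):

    FIS_i(α→β) = −½ [ ln (n_i(β)+1)/n_i(α)  +  ln (n_ip(β)+1)/n_ip(α) ]

High FIS marks substitutions toward residues rarely or never observed at an
evolutionarily conserved position.

**Non-uniformity μ.**  For per-gene mutation counts N_i (Q genes mutated,
M mutations, shares p_i = N_i/M):

    λ = Σ p_i²   (Simpson diversity)      K = 1/λ   (effective gene number)
    μ = Q/K = λ·Q

μ ≈ 1 when mutations spread evenly over genes (no selection); μ ≫ 1 when a
few genes carry the majority of mutations.  Selection shows up as μ rising
with the FIS threshold.

**Driver nomination.**  Genes are ranked by n_high = #(missense FIS > 2.5)
+ #truncating; the candidate driver set is the top round(K) genes with K
computed over those counts.  A gene with n_low = #(missense FIS < 1.0) ≥
n_high is flagged a probable passenger (scores in the uncertain band
[1.0, 2.5] count toward neither side), and genes with coding length above
15 kb are flagged as long-gene false-positive risks.

## Worked example

`examples/02_selection_nonuniformity.py` generates the default synthetic
cohort — 1000 genes, 100 tumors, 10 planted driver genes whose excess
missense mutations sit at conserved alignment columns — and prints:

```
mutation set               Q      M        K      mu
silent                   682   1419    476.4    1.43
truncating               336    516    153.2    2.19
missense (all)           860   3065    230.8    3.73
missense FIS>2.5         480   1129     56.7    8.47
missense FIS>3.0         214    603     19.9   10.76

length-proportional null: K = 691 of 1000 genes, mu = 1.45
```

Silent mutations are as uniform as gene-length differences alone predict
(μ 1.43 vs null 1.45: no selection), while the FIS>2.5 missense bin
concentrates 1129 mutations into ~57 effective genes (μ = 8.47): the
high-impact bin is under strong selection.  `examples/03_driver_nomination.py`
then recovers all 10 planted drivers at the top of the ranking
(driver recall 1.00 in the FIS>2.5+TM effective set), and
`examples/04_concurrency.py` shows truncating mutations piling into
copy-loss genes (36.2% vs 14.7% for silent, Fisher exact p ≈ 3e−23).

The other example scripts cover scoring single substitutions
(`01_functional_impact_scoring.py`) and the concurrency analyses.  The same
pipeline is scriptable from the shell:

```sh
mutsel simulate --out bundle --seed 7
mutsel score    --maf bundle/mutations.tsv --alignments bundle/alignments \
                --labels bundle/subfamily_labels.tsv --out scored.tsv
mutsel stats    --maf scored.tsv --genes bundle/gene_list.tsv \
                --cna bundle/cna.tsv --lengths bundle/gene_lengths.tsv --out stats/
mutsel nominate --scored scored.tsv --lengths bundle/gene_lengths.tsv --out nom/
```

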