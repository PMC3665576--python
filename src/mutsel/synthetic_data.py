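"""Synthetic cohorts with planted selection signatures.

Generates every input the pipeline consumes — protein family alignments,
MAF-like mutation tables, cancer-gene annotation lists, discretized
copy-number matrices and gene coding lengths — with the statistical
structure the analysis is designed to detect:

* passenger mutations fall across genes proportionally to coding length;
* planted driver genes receive a ``selection_strength``-fold excess of
  missense and truncating mutations, with the excess missense placed at
  conserved alignment columns (hence high FIS);
* truncating mutations are up-weighted into samples where their gene is in
  copy-loss (CNA state −1);
* silent mutations are pure length-proportional noise.

By default planted substitutions are actually scored against the generated
family alignments, keeping the scoring function in the loop end to end; a
fast mode samples FIS values from calibrated mixtures instead for large-n
property tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .fis_scoring import AMINO_ACIDS, AlignmentEnsemble, build_ensemble, score_table
from .io_formats import (
    GeneAnnotation,
    GeneLength,
    MutationRecord,
    VariantClass,
    write_mutation_table,
)

__all__ = ["CohortSpec", "SyntheticCohort", "gen_alignment", "gen_cohort", "make_fixture_suite"]

#: CNA state marginals (−1, 0, 1, 2): heterozygous-loss mass in the range
#: reported for real discretized tumor copy-number matrices.
CNA_STATE_PROBS = {-1: 0.15, 0: 0.65, 1: 0.17, 2: 0.03}


@dataclass
class CohortSpec:
    """Parameters of a synthetic tumor cohort.

    ``gene_length_distribution`` holds (meanlog, sdlog) of a log-normal in
    nucleotides (defaults give a ≈1.4 kb median, realistic for human coding
    sequence).  ``selection_strength`` multiplies the mutation rate of
    driver genes for missense and truncating classes; the excess missense
    is planted at conserved columns with probability
    ``driver_conserved_fraction``.  ``cna_loss_enrichment`` multiplies the
    chance that a truncating mutation lands in a sample where its gene is
    in copy-loss.
    """

    n_genes: int = 1000
    n_driver_genes: int = 10
    n_samples: int = 100
    mutations_per_sample: int = 50
    gene_length_distribution: tuple[float, float] = (7.25, 0.6)
    selection_strength: float = 20.0
    driver_conserved_fraction: float = 0.8
    silent_rate: float = 0.3
    truncating_rate: float = 0.1
    cna_loss_enrichment: float = 3.0
    seed: int = 0
    fis_mode: str = "scored"            # "scored" | "sampled"
    # annotation-list sizes (drivers are always annotated TS and CG)
    n_cancer_genes: int = 100
    n_ts_genes: int = 40
    n_og_genes: int = 15
    # family alignment templates shared across genes
    n_templates: int = 6
    template_n_seqs: int = 60
    template_n_cols: int = 80
    template_conserved_fraction: float = 0.1
    template_n_subfamilies: int = 3

    def validate(self) -> None:
        if min(self.n_genes, self.n_driver_genes, self.n_samples,
               self.mutations_per_sample, self.n_templates) < 1:
            raise ValueError("all counts must be >= 1")
        if self.n_driver_genes > self.n_genes:
            raise ValueError("n_driver_genes cannot exceed n_genes")
        for name in ("silent_rate", "truncating_rate", "driver_conserved_fraction",
                     "template_conserved_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.silent_rate + self.truncating_rate > 1.0:
            raise ValueError("silent_rate + truncating_rate must not exceed 1")
        if self.selection_strength < 1.0 or self.cna_loss_enrichment < 1.0:
            raise ValueError("rate multipliers must be >= 1")
        if self.fis_mode not in ("scored", "sampled"):
            raise ValueError(f"fis_mode must be 'scored' or 'sampled', got {self.fis_mode!r}")
        if not self.n_driver_genes <= self.n_ts_genes <= self.n_cancer_genes <= self.n_genes:
            raise ValueError("need n_driver_genes <= n_ts_genes <= n_cancer_genes <= n_genes")
        if self.n_og_genes > self.n_cancer_genes - self.n_ts_genes:
            raise ValueError("oncogene list does not fit inside the cancer-gene list")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    spec: CohortSpec
    records: list[MutationRecord]
    annotations: dict[str, GeneAnnotation]
    cna: pd.DataFrame                     # genes × samples, values in {−1,0,1,2}
    gene_lengths: list[GeneLength]
    drivers: set[str]
    gene_template: dict[str, int]
    ensembles: list[AlignmentEnsemble]
    conserved_masks: list[np.ndarray]

    @property
    def cna_lookup(self) -> dict[tuple[str, str], int]:
        out = {}
        for gene, row in self.cna.iterrows():
            for sample, state in row.items():
                out[(sample, gene)] = int(state)
        return out

    def ensembles_by_gene(self) -> dict[str, AlignmentEnsemble]:
        return {g: self.ensembles[t] for g, t in self.gene_template.items()}


def gen_alignment(
    n_seqs: int,
    n_cols: int,
    conserved_fraction: float,
    n_subfamilies: int,
    seed: int,
    p_consensus: float = 0.95,
    subfamily_fraction: float = 0.3,
):
    """Generate a gapless protein family alignment with known structure.

    Returns ``(pairs, labels, conserved_mask)`` where ``pairs`` is a list of
    (id, sequence), ``labels`` maps sequence id to subfamily, and
    ``conserved_mask`` marks the family-wide conserved columns.  Conserved
    columns carry a single consensus residue in ≥ ``p_consensus`` of
    sequences; a fraction of the remaining columns are subfamily-specific
    (distinct consensus per subfamily); the rest draw residues uniformly.
    Identical seeds give identical output.
    """
    if n_subfamilies > n_seqs:
        raise ValueError("n_subfamilies cannot exceed n_seqs")
    if not 0.0 <= conserved_fraction <= 1.0:
        raise ValueError("conserved_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))

    n_cons = int(round(conserved_fraction * n_cols))
    cols = rng.permutation(n_cols)
    conserved_cols = np.sort(cols[:n_cons])
    n_subspec = int(round(subfamily_fraction * (n_cols - n_cons)))
    subspec_cols = np.sort(cols[n_cons:n_cons + n_subspec])
    conserved_mask = np.zeros(n_cols, dtype=bool)
    conserved_mask[conserved_cols] = True

    # contiguous, near-equal subfamily blocks
    labels_arr = np.repeat(np.arange(n_subfamilies),
                           int(np.ceil(n_seqs / n_subfamilies)))[:n_seqs]

    seqs = rng.integers(0, 20, size=(n_seqs, n_cols))
    for c in conserved_cols:
        consensus = rng.integers(0, 20)
        noise = rng.random(n_seqs) >= p_consensus
        seqs[:, c] = consensus
        if noise.any():
            others = (consensus + 1 + rng.integers(0, 19, size=int(noise.sum()))) % 20
            seqs[noise, c] = others
    for c in subspec_cols:
        consensi = rng.choice(20, size=n_subfamilies, replace=False)
        noise = rng.random(n_seqs) >= 0.9
        seqs[:, c] = consensi[labels_arr]
        if noise.any():
            seqs[noise, c] = rng.integers(0, 20, size=int(noise.sum()))

    ids = [f"seq{i:03d}" for i in range(n_seqs)]
    pairs = [(ids[i], "".join(aa[seqs[i]])) for i in range(n_seqs)]
    labels = {ids[i]: int(labels_arr[i]) for i in range(n_seqs)}
    return pairs, labels, conserved_mask


def _rare_alt_table(ensemble: AlignmentEnsemble) -> np.ndarray:
    """Per column, residue indices sorted by ascending family count
    (20 amino-acid types only), for picking maximally unobserved alts."""
    counts = ensemble.counts[:, :20]
    return np.argsort(counts, axis=1, kind="stable")


def gen_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full cohort according to ``spec`` (deterministic in seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    meanlog, sdlog = spec.gene_length_distribution
    lengths_nt = np.maximum(150, np.round(rng.lognormal(meanlog, sdlog, spec.n_genes))).astype(int)
    gene_lengths = [GeneLength(gene=g, coding_length=int(n)) for g, n in zip(genes, lengths_nt)]

    # planted drivers and annotation lists (drivers are TS ⊂ CG)
    perm = rng.permutation(spec.n_genes)
    driver_idx = perm[:spec.n_driver_genes]
    cg_idx = perm[:spec.n_cancer_genes]
    ts_idx = perm[:spec.n_ts_genes]
    og_idx = perm[spec.n_ts_genes:spec.n_ts_genes + spec.n_og_genes]
    drivers = {genes[i] for i in driver_idx}
    annotations: dict[str, GeneAnnotation] = {}
    for i in cg_idx:
        cats = {"CG"}
        if i in ts_idx:
            cats.add("TS")
        if i in og_idx:
            cats.add("OG")
        annotations[genes[i]] = GeneAnnotation(gene=genes[i], categories=frozenset(cats))

    # family alignment templates, shared across genes
    ensembles: list[AlignmentEnsemble] = []
    conserved_masks: list[np.ndarray] = []
    for _ in range(spec.n_templates):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        pairs, labels, mask = gen_alignment(
            spec.template_n_seqs, spec.template_n_cols,
            spec.template_conserved_fraction, spec.template_n_subfamilies,
            seed=sub_seed,
        )
        ensembles.append(build_ensemble(pairs, query_id=pairs[0][0], subfamily_labels=labels))
        conserved_masks.append(mask)
    rare_tables = [_rare_alt_table(e) for e in ensembles]
    gene_template = {g: i % spec.n_templates for i, g in enumerate(genes)}

    # copy-number matrix
    states = np.array(list(CNA_STATE_PROBS))
    probs = np.array(list(CNA_STATE_PROBS.values()))
    cna_values = rng.choice(states, size=(spec.n_genes, spec.n_samples), p=probs).astype(int)
    samples = [f"S{i:03d}" for i in range(spec.n_samples)]
    cna = pd.DataFrame(cna_values, index=genes, columns=samples)

    # per-class gene-choice weights
    w_len = lengths_nt / lengths_nt.sum()
    w_sel = lengths_nt.astype(float).copy()
    w_sel[driver_idx] *= spec.selection_strength
    w_sel /= w_sel.sum()

    m_total = spec.n_samples * spec.mutations_per_sample
    p_mis = 1.0 - spec.silent_rate - spec.truncating_rate
    n_sil, n_trunc, n_mis = rng.multinomial(
        m_total, [spec.silent_rate, spec.truncating_rate, p_mis])
    is_driver = np.zeros(spec.n_genes, dtype=bool)
    is_driver[driver_idx] = True
    planted_excess = (spec.selection_strength - 1.0) / spec.selection_strength
    n_cols = spec.template_n_cols
    records: list[MutationRecord] = []

    def query_res(gi: int, col: int) -> str:
        return ensembles[gene_template[genes[gi]]].sequences[0][col]

    # silent: pure length-proportional noise
    gis = rng.choice(spec.n_genes, size=n_sil, p=w_len)
    cols = rng.integers(n_cols, size=n_sil)
    samp = rng.integers(spec.n_samples, size=n_sil)
    for gi, col, si in zip(gis, cols, samp):
        ref = query_res(gi, col)
        records.append(MutationRecord(
            sample_id=samples[si], gene=genes[gi], variant_class=VariantClass.SILENT,
            protein_pos=int(col) + 1, ref_aa=ref, alt_aa=ref,
        ))

    # truncating: driver-enriched gene choice, copy-loss-enriched sample choice
    gis = rng.choice(spec.n_genes, size=n_trunc, p=w_sel)
    cols = rng.integers(n_cols, size=n_trunc)
    for gi, col in zip(gis, cols):
        sw = np.where(cna_values[gi] == -1, spec.cna_loss_enrichment, 1.0)
        si = int(rng.choice(spec.n_samples, p=sw / sw.sum()))
        records.append(MutationRecord(
            sample_id=samples[si], gene=genes[gi], variant_class=VariantClass.TRUNCATING,
            protein_pos=int(col) + 1, ref_aa=query_res(gi, col), alt_aa=None,
        ))

    # missense: drivers receive the planted high-impact excess
    gis = rng.choice(spec.n_genes, size=n_mis, p=w_sel)
    samp = rng.integers(spec.n_samples, size=n_mis)
    cols = rng.integers(n_cols, size=n_mis)
    planted_arr = is_driver[gis] & (rng.random(n_mis) < planted_excess)
    use_conserved = planted_arr & (rng.random(n_mis) < spec.driver_conserved_fraction)
    conserved_hit = rng.random(n_mis) < spec.template_conserved_fraction  # sampled mode only
    for j in range(n_mis):
        gi = int(gis[j])
        t = gene_template[genes[gi]]
        ens, mask, rare = ensembles[t], conserved_masks[t], rare_tables[t]
        if use_conserved[j] and mask.any():
            col = int(rng.choice(np.flatnonzero(mask)))
            ref = ens.sequences[0][col]
            # alt = least-observed residue type in the family column
            for cand in rare[col]:
                alt = AMINO_ACIDS[cand]
                if alt != ref:
                    break
        else:
            col = int(cols[j])
            ref = ens.sequences[0][col]
            alt = AMINO_ACIDS[int(rng.integers(20))]
            while alt == ref:
                alt = AMINO_ACIDS[int(rng.integers(20))]
        fis = None
        if spec.fis_mode == "sampled":
            if planted_arr[j]:
                fis = float(rng.normal(3.3, 0.4))
            elif conserved_hit[j]:
                fis = float(rng.normal(2.9, 0.4))
            else:
                fis = float(rng.normal(0.3, 0.9))
        records.append(MutationRecord(
            sample_id=samples[samp[j]], gene=genes[gi], variant_class=VariantClass.MISSENSE,
            protein_pos=col + 1, ref_aa=ref, alt_aa=alt, fis=fis,
        ))

    if spec.fis_mode == "scored":
        by_gene = {g: ensembles[t] for g, t in gene_template.items()}
        records = score_table(records, by_gene)

    return SyntheticCohort(
        spec=spec, records=records, annotations=annotations, cna=cna,
        gene_lengths=gene_lengths, drivers=drivers, gene_template=gene_template,
        ensembles=ensembles, conserved_masks=conserved_masks,
    )


#: Spec for the miniature on-disk fixture bundle (runs end to end in seconds).
FIXTURE_SPEC_KW = dict(
    n_genes=120, n_driver_genes=5, n_samples=30, mutations_per_sample=40,
    n_cancer_genes=30, n_ts_genes=15, n_og_genes=6,
    n_templates=3, template_n_seqs=30, template_n_cols=60,
)


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a complete miniature input bundle to ``out_dir``.

    Emits an unscored MAF-like table, per-gene alignment FASTA files (one
    per gene carrying missense mutations), a subfamily label table, the
    gene list, CNA matrix, gene lengths and the planted-driver truth file —
    all in the formats the readers consume.  Deterministic in ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = CohortSpec(seed=seed, **FIXTURE_SPEC_KW)
    cohort = gen_cohort(spec)

    paths = {
        "mutations": out / "mutations.tsv",
        "gene_list": out / "gene_list.tsv",
        "cna": out / "cna.tsv",
        "lengths": out / "gene_lengths.tsv",
        "truth": out / "truth_drivers.txt",
        "labels": out / "subfamily_labels.tsv",
        "alignments": out / "alignments",
    }

    unscored = [r.copy_with(fis=None) if r.fis is not None else r for r in cohort.records]
    write_mutation_table(unscored, paths["mutations"])

    with open(paths["gene_list"], "w") as fh:
        fh.write("gene\tcategory\n")
        for gene in sorted(cohort.annotations):
            for cat in sorted(cohort.annotations[gene].categories):
                fh.write(f"{gene}\t{cat}\n")

    cohort.cna.to_csv(paths["cna"], sep="\t", index_label="gene")

    with open(paths["lengths"], "w") as fh:
        fh.write("gene\tcoding_length\n")
        for gl in cohort.gene_lengths:
            fh.write(f"{gl.gene}\t{gl.coding_length}\n")

    with open(paths["truth"], "w") as fh:
        for g in sorted(cohort.drivers):
            fh.write(g + "\n")

    # per-gene alignments: the gene's template with the query renamed to the
    # gene symbol, plus a global subfamily-label table
    mutated = sorted({r.gene for r in cohort.records if r.variant_class is VariantClass.MISSENSE})
    paths["alignments"].mkdir(exist_ok=True)
    with open(paths["labels"], "w") as fh:
        fh.write("gene\tseq_id\tsubfamily\n")
        for gene in mutated:
            ens = cohort.ensembles[cohort.gene_template[gene]]
            with open(paths["alignments"] / f"{gene}.fasta", "w") as fa:
                for i, (sid, seq) in enumerate(zip(ens.ids, ens.sequences)):
                    name = gene if i == ens.query_index else sid
                    fa.write(f">{name}\n{seq}\n")
            for i, sid in enumerate(ens.ids):
                name = gene if i == ens.query_index else sid
                fh.write(f"{gene}\t{name}\t{int(ens.subfamily_labels[i])}\n")

    return paths
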