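"""Selection statistics over somatic mutation tables.

The central quantity is the non-uniformity μ of a per-gene mutation
distribution.  For a set of mutations with per-gene counts N_i (Q genes
mutated, M = Σ N_i mutations, shares p_i = N_i / M):

    λ = Σ p_i²            (Simpson diversity index)
    N = M·λ               (weighted average mutations per gene)
    K = M/N = 1/λ         (effective number of mutated genes)
    μ = Q/K = λ·Q         (non-uniformity)

μ ≈ 1 when mutations are spread evenly over genes; μ ≫ 1 when a few genes
carry the majority of mutations, the signature of selection.  The module
also computes the FIS-binned cancer-gene fractions, the gene-level
concurrency of high-impact missense with truncating mutations, the
copy-number concurrency tables, and the gene-length null for μ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .io_formats import (
    CnaState,
    GeneAnnotation,
    GeneLength,
    MutationRecord,
    VariantClass,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MutationTally",
    "NonUniformityResult",
    "FisBinSpec",
    "DEFAULT_BINS",
    "GENE_GROUPS",
    "tally",
    "non_uniformity",
    "cancer_gene_fraction",
    "truncating_concurrency",
    "cna_concurrency",
    "CnaConcurrencyResult",
    "length_null_non_uniformity",
]

GENE_GROUPS = ("all", "TS", "OG", "CG", "nCG")


@dataclass
class MutationTally:
    """Per-gene mutation counts for a filtered mutation set."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        self.counts = {g: int(n) for g, n in self.counts.items() if n > 0}

    @property
    def Q(self) -> int:
        """Number of genes with at least one mutation."""
        return len(self.counts)

    @property
    def M(self) -> int:
        """Total number of mutations."""
        return sum(self.counts.values())

    @property
    def p(self) -> dict[str, float]:
        """Per-gene mutation shares p_i = N_i / M."""
        m = self.M
        return {g: n / m for g, n in self.counts.items()} if m else {}

    @property
    def is_empty(self) -> bool:
        return self.M == 0


@dataclass
class NonUniformityResult:
    """λ, N, K and μ for one mutation tally (or a length-based null)."""

    lambda_: float
    k: float
    mu: float
    n_avg: Optional[float]
    q: int
    m: Optional[int] = None


@dataclass(frozen=True)
class FisBinSpec:
    """Cumulative FIS bins: each threshold admits mutations with FIS strictly
    above it; ``None`` admits every scored missense mutation ("all")."""

    thresholds: tuple[Optional[float], ...] = (None, 1.0, 2.0, 2.5, 3.0, 3.5)

    def __post_init__(self) -> None:
        numeric = [t for t in self.thresholds if t is not None]
        if any(b <= a for a, b in zip(numeric, numeric[1:])):
            raise ValueError(f"bin thresholds must be strictly increasing: {numeric}")

    def label(self, threshold: Optional[float]) -> str:
        return "all" if threshold is None else f"FIS>{threshold:g}"

    @property
    def labels(self) -> list[str]:
        return [self.label(t) for t in self.thresholds]


DEFAULT_BINS = FisBinSpec()


def _in_group(
    gene: str,
    group: str,
    annotations: Optional[Mapping[str, GeneAnnotation]],
) -> bool:
    if group == "all":
        return True
    if annotations is None:
        raise ValueError(f"gene group {group!r} requires an annotation map")
    ann = annotations.get(gene)
    if group == "nCG":
        return ann is None or "CG" not in ann.categories
    return ann is not None and group in ann.categories


def _passes_bin(rec: MutationRecord, threshold: Optional[float]) -> bool:
    """FIS bin filter; applies to missense only, unscored records excluded."""
    if rec.variant_class is not VariantClass.MISSENSE:
        return True  # bins gate only missense records
    if threshold is None:
        return rec.fis is not None
    return rec.fis is not None and rec.fis > threshold


def tally(
    records: Iterable[MutationRecord],
    class_filter: Union[VariantClass, Iterable[VariantClass]],
    fis_bin: Optional[float] = None,
    gene_group: str = "all",
    annotations: Optional[Mapping[str, GeneAnnotation]] = None,
) -> MutationTally:
    """Count mutations per gene after class, FIS-bin and gene-group filters.

    ``fis_bin`` keeps missense mutations with FIS strictly above the
    threshold (``None`` keeps all *scored* missense); it never gates
    silent/truncating records.  An all-filtered-out result is a valid empty
    tally which downstream statistics refuse.
    """
    if isinstance(class_filter, VariantClass):
        classes = {class_filter}
    else:
        classes = set(class_filter)
    if gene_group not in GENE_GROUPS:
        raise ValueError(f"gene_group must be one of {GENE_GROUPS}, got {gene_group!r}")

    use_bin = VariantClass.MISSENSE in classes
    counts: dict[str, int] = {}
    for rec in records:
        if rec.variant_class not in classes:
            continue
        if not _in_group(rec.gene, gene_group, annotations):
            continue
        if use_bin and rec.variant_class is VariantClass.MISSENSE:
            if not _passes_bin(rec, fis_bin):
                continue
        counts[rec.gene] = counts.get(rec.gene, 0) + 1
    return MutationTally(counts=counts)


def non_uniformity(t: MutationTally) -> NonUniformityResult:
    """Compute λ, N, K and μ for a tally (refuses an empty one)."""
    if t.is_empty:
        raise ValueError("cannot compute non-uniformity of an empty tally (M = 0)")
    m = t.M
    p = np.array(list(t.counts.values()), dtype=float) / m
    lam = float(np.sum(p * p))
    k = 1.0 / lam
    return NonUniformityResult(lambda_=lam, k=k, mu=lam * t.Q, n_avg=m * lam, q=t.Q, m=m)


def cancer_gene_fraction(
    records: Sequence[MutationRecord],
    bin_spec: FisBinSpec = DEFAULT_BINS,
    annotations: Optional[Mapping[str, GeneAnnotation]] = None,
    category: str = "CG",
) -> dict[str, Optional[float]]:
    """Per-bin percentage of missense mutations hitting annotated genes.

    For every cumulative FIS bin: 100 × (missense mutations in the bin whose
    gene is in ``category``) / (missense mutations in the bin).  Companion
    percentages for the silent and truncating classes are included under the
    keys ``"silent"`` and ``"truncating"`` as flat references.  Empty bins
    report ``None``, not zero.  Counting is mutation-level.
    """
    if category not in ("TS", "OG", "CG"):
        raise ValueError(f"category must be TS, OG or CG, got {category!r}")

    def pct(pool: list[MutationRecord]) -> Optional[float]:
        if not pool:
            return None
        hits = sum(1 for r in pool if _in_group(r.gene, category, annotations))
        return 100.0 * hits / len(pool)

    out: dict[str, Optional[float]] = {}
    missense = [r for r in records if r.variant_class is VariantClass.MISSENSE]
    for thr in bin_spec.thresholds:
        out[bin_spec.label(thr)] = pct([r for r in missense if _passes_bin(r, thr)])
    out["silent"] = pct([r for r in records if r.variant_class is VariantClass.SILENT])
    out["truncating"] = pct([r for r in records if r.variant_class is VariantClass.TRUNCATING])
    return out


def truncating_concurrency(
    records: Sequence[MutationRecord],
    bin_spec: FisBinSpec = DEFAULT_BINS,
    gene_group: str = "all",
    annotations: Optional[Mapping[str, GeneAnnotation]] = None,
) -> dict[str, Optional[float]]:
    """Per-bin percentage of genes hit by both binned missense and truncating
    mutations found in *different* tumors.

    For each cumulative FIS bin: 100 × |genes in the group with ≥1 missense
    mutation in the bin AND ≥1 truncating mutation in a different sample| /
    |genes in the group with ≥1 missense mutation in the bin|.  A gene whose
    only missense and truncating hits come from one and the same sample is
    not concurrent.  Empty denominators report ``None``.
    """
    trunc_samples: dict[str, set[str]] = {}
    for r in records:
        if r.variant_class is VariantClass.TRUNCATING:
            trunc_samples.setdefault(r.gene, set()).add(r.sample_id)

    missense = [
        r for r in records
        if r.variant_class is VariantClass.MISSENSE
        and _in_group(r.gene, gene_group, annotations)
    ]

    out: dict[str, Optional[float]] = {}
    for thr in bin_spec.thresholds:
        mis_samples: dict[str, set[str]] = {}
        for r in missense:
            if _passes_bin(r, thr):
                mis_samples.setdefault(r.gene, set()).add(r.sample_id)
        if not mis_samples:
            out[bin_spec.label(thr)] = None
            continue
        concurrent = 0
        for gene, msamp in mis_samples.items():
            tsamp = trunc_samples.get(gene, set())
            if tsamp and len(msamp | tsamp) > 1:
                concurrent += 1
        out[bin_spec.label(thr)] = 100.0 * concurrent / len(mis_samples)
    return out


@dataclass
class CnaConcurrencyResult:
    """Distribution of a mutation set over CNA states, compared to silent.

    ``percentages``/``counts`` describe the selected mutation set; the
    reference silent class is under ``silent_*``.  ``p_loss``/``p_gain`` are
    two-sided Fisher exact p-values for the 2×2 tables (in state −1 / +1
    versus not) contrasting the set with silent mutations.
    """

    percentages: dict[int, float]
    counts: dict[int, int]
    silent_percentages: dict[int, float]
    silent_counts: dict[int, int]
    p_loss: float
    p_gain: float
    n_excluded: int = 0


CNA_STATES = (-1, 0, 1, 2)


def _cna_lookup(cna_states: Union[Sequence[CnaState], Mapping[tuple[str, str], int]]):
    if isinstance(cna_states, Mapping):
        return cna_states
    return {(s.sample_id, s.gene): s.state for s in cna_states}


def _state_counts(records: Iterable[MutationRecord], lookup) -> tuple[dict[int, int], int]:
    counts = {s: 0 for s in CNA_STATES}
    excluded = 0
    for r in records:
        state = lookup.get((r.sample_id, r.gene))
        if state is None:
            excluded += 1
        else:
            counts[state] += 1
    return counts, excluded


def _pcts(counts: dict[int, int]) -> dict[int, float]:
    total = sum(counts.values())
    if total == 0:
        return {s: float("nan") for s in CNA_STATES}
    return {s: 100.0 * counts[s] / total for s in CNA_STATES}


def cna_concurrency(
    records: Sequence[MutationRecord],
    cna_states: Union[Sequence[CnaState], Mapping[tuple[str, str], int]],
    class_or_bin: Union[VariantClass, float],
) -> CnaConcurrencyResult:
    """Distribution over CNA states of one mutation set vs the silent class.

    ``class_or_bin`` selects either a variant class or, when a float, the
    missense mutations with FIS strictly above that threshold.  Each
    mutation joins to a copy-number state by (sample, gene); unjoined
    records are excluded with a logged count.  Significance of the
    difference from the silent distribution at state −1 (loss) and state +1
    (gain) is a two-sided Fisher exact test on in-state/out-of-state counts.
    """
    lookup = _cna_lookup(cna_states)

    if isinstance(class_or_bin, VariantClass):
        selected = [r for r in records if r.variant_class is class_or_bin]
    else:
        thr = float(class_or_bin)
        selected = [
            r for r in records
            if r.variant_class is VariantClass.MISSENSE
            and r.fis is not None and r.fis > thr
        ]
    silent = [r for r in records if r.variant_class is VariantClass.SILENT]

    sel_counts, sel_excl = _state_counts(selected, lookup)
    sil_counts, sil_excl = _state_counts(silent, lookup)
    n_excluded = sel_excl + sil_excl
    if n_excluded:
        logger.info("CNA concurrency: %d mutation(s) without a matching CNA call excluded",
                    n_excluded)
    if sum(sel_counts.values()) == 0 or sum(sil_counts.values()) == 0:
        raise ValueError("no mutations joined to CNA states; cannot compare distributions")

    def fisher(state: int) -> float:
        a = sel_counts[state]
        b = sum(sel_counts.values()) - a
        c = sil_counts[state]
        d = sum(sil_counts.values()) - c
        return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])

    return CnaConcurrencyResult(
        percentages=_pcts(sel_counts),
        counts=sel_counts,
        silent_percentages=_pcts(sil_counts),
        silent_counts=sil_counts,
        p_loss=fisher(-1),
        p_gain=fisher(1),
        n_excluded=n_excluded,
    )


def length_null_non_uniformity(lengths: Sequence[GeneLength]) -> NonUniformityResult:
    """Non-uniformity expected when mutations fall proportionally to gene length.

    With p_i = length_i / Σ length: λ = Σ p_i², K = 1/λ and μ = λ·Q, where Q
    is the number of genes.  This is the length-driven null against which
    observed μ values are judged; it is reported separately, never folded
    into the observed statistic.
    """
    if not lengths:
        raise ValueError("need at least one gene length")
    arr = np.array([gl.coding_length for gl in lengths], dtype=float)
    if np.any(arr <= 0):
        raise ValueError("all gene lengths must be positive")
    p = arr / arr.sum()
    lam = float(np.sum(p * p))
    return NonUniformityResult(
        lambda_=lam, k=1.0 / lam, mu=lam * len(arr), n_avg=None, q=len(arr), m=None
    )
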