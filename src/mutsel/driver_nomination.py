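"""Driver-gene nomination from high-functional mutation burden.

Genes are ranked by their count of high-functional mutations — missense
with FIS above a high threshold (default 2.5) plus all truncating
mutations.  The candidate common-driver set ("effective gene set") is the
top round(K) genes, where K = 1/λ is the Simpson effective number of genes
computed over a chosen mutation basis.  Genes with at least as many
low-functional mutations (FIS below 1.0) as high-functional ones are
flagged as probable passengers; mutations scored inside the uncertainty
band [low, high] count toward neither side.  Very long genes can
accumulate high-functional mutations by chance; they are flagged (not
removed) above a coding-length cutoff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Optional, Sequence

from .io_formats import GeneLength, MutationRecord, VariantClass
from .selection_stats import MutationTally, non_uniformity

logger = logging.getLogger(__name__)

__all__ = [
    "GeneBurden",
    "rank_genes",
    "effective_gene_set",
    "passenger_summary",
    "long_gene_filter",
]


@dataclass
class GeneBurden:
    """Mutation burden of one gene.

    ``n_high`` counts missense with FIS > high threshold plus truncating
    mutations; ``n_low`` counts missense with FIS < low threshold;
    ``n_total_mm_tm`` counts all missense plus truncating mutations.
    """

    gene: str
    n_high: int
    n_low: int
    n_total_mm_tm: int
    is_passenger_flagged: bool
    exceeds_long_gene_cutoff: bool = False


def rank_genes(
    records: Iterable[MutationRecord],
    high_threshold: float = 2.5,
    low_threshold: float = 1.0,
) -> list[GeneBurden]:
    """Rank genes by high-functional mutation count, descending.

    Ties break by total missense+truncating count, then gene symbol.
    Scores inside the closed band [low_threshold, high_threshold] count in
    neither bucket; unscored missense count only toward the total.  The
    passenger flag is the literal rule n_low ≥ n_high.  Refuses input with
    no scored missense record.
    """
    if low_threshold > high_threshold:
        raise ValueError(
            f"low_threshold ({low_threshold}) must not exceed high_threshold ({high_threshold})"
        )
    n_scored = 0
    high: dict[str, int] = {}
    low: dict[str, int] = {}
    total: dict[str, int] = {}
    for rec in records:
        if rec.variant_class is VariantClass.TRUNCATING:
            total[rec.gene] = total.get(rec.gene, 0) + 1
            high[rec.gene] = high.get(rec.gene, 0) + 1
        elif rec.variant_class is VariantClass.MISSENSE:
            total[rec.gene] = total.get(rec.gene, 0) + 1
            if rec.fis is None:
                continue
            n_scored += 1
            if rec.fis > high_threshold:
                high[rec.gene] = high.get(rec.gene, 0) + 1
            elif rec.fis < low_threshold:
                low[rec.gene] = low.get(rec.gene, 0) + 1
    if n_scored == 0:
        raise ValueError("no scored missense records; run FIS scoring before ranking")

    burdens = [
        GeneBurden(
            gene=g,
            n_high=high.get(g, 0),
            n_low=low.get(g, 0),
            n_total_mm_tm=n,
            is_passenger_flagged=low.get(g, 0) >= high.get(g, 0),
        )
        for g, n in total.items()
    ]
    burdens.sort(key=lambda b: (-b.n_high, -b.n_total_mm_tm, b.gene))
    return burdens


TallyBasis = Literal["mm_tm", "fis_tm"]


def _basis_count(b: GeneBurden, basis: TallyBasis) -> int:
    return b.n_total_mm_tm if basis == "mm_tm" else b.n_high


def effective_gene_set(
    ranked: Sequence[GeneBurden],
    tally_basis: TallyBasis = "fis_tm",
) -> set[str]:
    """Top round(K) genes of the ranking, K = Simpson effective gene number.

    K = 1/λ is computed over the chosen per-gene mutation counts
    (``mm_tm``: all missense + truncating; ``fis_tm``: high-functional
    only), rounded half-up with floor 1.  Candidates are ordered by their
    basis count with the ranking's deterministic tie-break, and genes with
    a zero basis count can never enter the set.
    """
    if not ranked:
        raise ValueError("empty ranking")
    if tally_basis not in ("mm_tm", "fis_tm"):
        raise ValueError(f"tally_basis must be 'mm_tm' or 'fis_tm', got {tally_basis!r}")

    counts = {b.gene: _basis_count(b, tally_basis) for b in ranked}
    t = MutationTally(counts=counts)
    if t.is_empty:
        raise ValueError(f"basis {tally_basis!r} yields no mutations (M = 0)")
    k = non_uniformity(t).k
    size = max(1, math.floor(k + 0.5))

    candidates = [b for b in ranked if _basis_count(b, tally_basis) > 0]
    candidates.sort(key=lambda b: (-_basis_count(b, tally_basis), -b.n_high,
                                   -b.n_total_mm_tm, b.gene))
    return {b.gene for b in candidates[:size]}


def passenger_summary(
    sets: Mapping[str, Iterable[str]],
    burdens: Sequence[GeneBurden],
) -> dict[str, Optional[float]]:
    """Percentage of passenger-flagged genes within each named gene set.

    Empty sets report ``None``.  Every set member must have a burden entry.
    """
    flagged = {b.gene: b.is_passenger_flagged for b in burdens}
    out: dict[str, Optional[float]] = {}
    for name, genes in sets.items():
        genes = list(genes)
        if not genes:
            out[name] = None
            continue
        missing = [g for g in genes if g not in flagged]
        if missing:
            raise ValueError(f"set {name!r} contains genes without burdens: {missing[:5]}")
        out[name] = 100.0 * sum(flagged[g] for g in genes) / len(genes)
    return out


def long_gene_filter(
    burdens: Sequence[GeneBurden],
    lengths: Sequence[GeneLength],
    cutoff: int = 15000,
    exclude: bool = False,
) -> list[GeneBurden]:
    """Flag genes whose coding length is strictly greater than ``cutoff`` nt.

    Flagging is the default behavior; exclusion of flagged genes is opt-in.
    A gene without a known length is left unflagged with a warning.
    """
    length_of = {gl.gene: gl.coding_length for gl in lengths}
    out: list[GeneBurden] = []
    for b in burdens:
        n = length_of.get(b.gene)
        if n is None:
            logger.warning("no coding length for gene %s; long-gene flag left unset", b.gene)
            flagged = False
        else:
            flagged = n > cutoff
        if exclude and flagged:
            continue
        out.append(GeneBurden(
            gene=b.gene, n_high=b.n_high, n_low=b.n_low,
            n_total_mm_tm=b.n_total_mm_tm,
            is_passenger_flagged=b.is_passenger_flagged,
            exceeds_long_gene_cutoff=flagged,
        ))
    return out
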