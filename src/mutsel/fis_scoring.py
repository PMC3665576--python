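"""Functional impact scoring of residue substitutions.

The functional impact score (FIS) of a substitution α→β at protein position
*i* is an entropy-motivated conservation score computed from residue counts
in a column of a protein-family multiple alignment and of the subfamily the
query sequence belongs to::

    FIS_i(α→β) = −1/2 [ ln (n_i(β)+1)/n_i(α)  +  ln (n_ip(β)+1)/n_ip(α) ]

where n_i(·) counts residue types over the whole family in column *i*,
n_ip(·) counts them within the query's subfamily *p*, gaps are the 21st
residue type, logs are natural and the +1 pseudocount applies to the β
(destination) counts only.  A substitution toward a residue never observed
in a conserved column scores high; one toward a common residue scores near
or below zero.

Columns are treated independently: the score at position *i* uses only the
counts of column *i*.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .io_formats import MutationRecord, VariantClass

logger = logging.getLogger(__name__)

__all__ = [
    "AMINO_ACIDS",
    "ALPHABET",
    "AlignmentEnsemble",
    "FisResult",
    "build_ensemble",
    "score_mutation",
    "score_table",
    "fis_from_counts",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: 21-letter alphabet: 20 residue types plus the alignment gap.
ALPHABET = AMINO_ACIDS + GAP
_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
GAP_INDEX = _INDEX[GAP]


def _residue_index(ch: str) -> int:
    """Map a character to its alphabet index; anything non-standard
    (X, B, Z, '.', '*', ...) is counted as the gap type."""
    return _INDEX.get(ch.upper(), GAP_INDEX)


@dataclass
class AlignmentEnsemble:
    """Aligned homologous sequences with materialized column counts.

    ``counts[i, a]`` is n_i(α) for column *i* and residue-type index *a*;
    ``sub_counts[p, i, a]`` is n_ip(α) for subfamily *p*.  The query's
    subfamily is the cluster containing the query sequence.
    """

    ids: tuple[str, ...]
    sequences: tuple[str, ...]
    query_index: int
    subfamily_labels: np.ndarray          # shape (n_seqs,), 0-based cluster ids
    counts: np.ndarray                    # shape (n_cols, 21), int
    sub_counts: np.ndarray                # shape (n_subfamilies, n_cols, 21), int
    query_subfamily: int
    _pos_to_col: np.ndarray               # ungapped query position (0-based) -> column

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return self.counts.shape[0]

    @property
    def query_length(self) -> int:
        """Ungapped length of the query sequence."""
        return len(self._pos_to_col)

    def column_for_position(self, protein_pos: int) -> int:
        """Alignment column (0-based) of 1-based ungapped query position."""
        if not 1 <= protein_pos <= self.query_length:
            raise ValueError(
                f"protein position {protein_pos} is beyond the ungapped query "
                f"length {self.query_length}"
            )
        return int(self._pos_to_col[protein_pos - 1])


@dataclass
class FisResult:
    """Score of one substitution; ``fis = family_term + subfamily_term``."""

    protein_pos: int
    ref_aa: str
    alt_aa: str
    fis: float
    family_term: float
    subfamily_term: float
    gene: str = ""


def _identity_distance_matrix(seqs: Sequence[str]) -> np.ndarray:
    """Pairwise distance = 1 − fraction of identical characters (all columns)."""
    arr = np.array([[_residue_index(c) for c in s] for s in seqs], dtype=np.int8)
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        same = (arr[i] == arr[i + 1:]).mean(axis=1)
        dist[i, i + 1:] = 1.0 - same
        dist[i + 1:, i] = dist[i, i + 1:]
    return dist


def _baseline_clustering(seqs: Sequence[str], n_clusters: int) -> np.ndarray:
    """Average-linkage hierarchical clustering on identity distance.

    Deterministic given the sequence input order.  This is a simple stand-in
    for specialized subfamily decompositions; externally supplied labels are
    the first-class path.
    """
    n = len(seqs)
    k = max(1, min(n_clusters, n))
    if k == 1 or n == 1:
        return np.zeros(n, dtype=int)
    dist = _identity_distance_matrix(seqs)
    link = average(squareform(dist, checks=False))
    flat = fcluster(link, t=k, criterion="maxclust")
    # relabel clusters to 0..k-1 in order of first appearance
    order: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, c in enumerate(flat):
        if c not in order:
            order[c] = len(order)
        labels[i] = order[c]
    return labels


def build_ensemble(
    alignment,
    query_id: str,
    subfamily_labels: Optional[Mapping[str, int] | Sequence[int]] = None,
    n_clusters: int = 4,
) -> AlignmentEnsemble:
    """Materialize family and subfamily column counts for an alignment.

    ``alignment`` may be a Bio.Align.MultipleSeqAlignment or a sequence of
    ``(id, aligned_string)`` pairs.  When subfamily labels are not supplied,
    the baseline identity clustering assigns them (cut at ``n_clusters`` or
    the sequence count, whichever is smaller).
    """
    if hasattr(alignment, "get_alignment_length"):
        pairs = [(rec.id, str(rec.seq)) for rec in alignment]
    else:
        pairs = [(str(i), str(s)) for i, s in alignment]
    if not pairs:
        raise ValueError("empty alignment")
    ids = tuple(i for i, _ in pairs)
    seqs = tuple(s.upper() for _, s in pairs)

    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    if query_id not in ids:
        raise ValueError(f"query id {query_id!r} not found among alignment sequences")
    query_index = ids.index(query_id)

    if subfamily_labels is None:
        labels = _baseline_clustering(seqs, n_clusters)
    elif isinstance(subfamily_labels, Mapping):
        try:
            raw = [subfamily_labels[i] for i in ids]
        except KeyError as e:
            raise ValueError(f"subfamily label missing for sequence {e.args[0]!r}") from None
        labels = _relabel(raw)
    else:
        if len(subfamily_labels) != len(ids):
            raise ValueError("subfamily label list length does not match alignment")
        labels = _relabel(list(subfamily_labels))

    arr = np.array([[_residue_index(c) for c in s] for s in seqs], dtype=np.int64)
    n_cols = arr.shape[1]
    n_sub = int(labels.max()) + 1
    counts = np.zeros((n_cols, 21), dtype=np.int64)
    sub_counts = np.zeros((n_sub, n_cols, 21), dtype=np.int64)
    for s in range(len(seqs)):
        np.add.at(counts, (np.arange(n_cols), arr[s]), 1)
        np.add.at(sub_counts, (labels[s], np.arange(n_cols), arr[s]), 1)

    qseq = seqs[query_index]
    pos_to_col = np.array([i for i, c in enumerate(qseq) if _residue_index(c) != GAP_INDEX],
                          dtype=np.int64)

    return AlignmentEnsemble(
        ids=ids,
        sequences=seqs,
        query_index=query_index,
        subfamily_labels=labels,
        counts=counts,
        sub_counts=sub_counts,
        query_subfamily=int(labels[query_index]),
        _pos_to_col=pos_to_col,
    )


def _relabel(raw: Sequence[int]) -> np.ndarray:
    order: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, c in enumerate(raw):
        if c not in order:
            order[c] = len(order)
        out[i] = order[c]
    return out


def fis_from_counts(n_a: int, n_b: int, np_a: int, np_b: int) -> tuple[float, float, float]:
    """Evaluate the score from the four raw counts.

    Returns ``(fis, family_term, subfamily_term)``.  The pseudocount +1 is
    applied to the destination (β) counts only; logs are natural.
    """
    if n_a < 1 or np_a < 1:
        raise ValueError(
            f"source-residue counts must be >= 1 (family {n_a}, subfamily {np_a}); "
            "is the query sequence included in the alignment?"
        )
    family_term = -0.5 * math.log((n_b + 1) / n_a)
    subfamily_term = -0.5 * math.log((np_b + 1) / np_a)
    return family_term + subfamily_term, family_term, subfamily_term


def score_mutation(
    ensemble: AlignmentEnsemble,
    protein_pos: int,
    ref_aa: str,
    alt_aa: str,
    gene: str = "",
) -> FisResult:
    """Score the substitution ref→alt at a 1-based query protein position.

    The query must carry ``ref_aa`` at the mapped alignment column; a
    mismatch is refused rather than silently scored.  Substitutions to or
    from a gap are not scorable.
    """
    ref_aa, alt_aa = ref_aa.upper(), alt_aa.upper()
    if ref_aa not in _INDEX or ref_aa == GAP:
        raise ValueError(f"reference residue {ref_aa!r} is not one of the 20 amino acids")
    if alt_aa not in _INDEX or alt_aa == GAP:
        raise ValueError(f"alternate residue {alt_aa!r} is not one of the 20 amino acids")

    col = ensemble.column_for_position(protein_pos)
    found = ensemble.sequences[ensemble.query_index][col].upper()
    if found != ref_aa:
        raise ValueError(
            f"reference mismatch at protein position {protein_pos} "
            f"(column {col}): expected {ref_aa}, query carries {found}"
        )

    a, b = _INDEX[ref_aa], _INDEX[alt_aa]
    p = ensemble.query_subfamily
    fis, fam, sub = fis_from_counts(
        int(ensemble.counts[col, a]),
        int(ensemble.counts[col, b]),
        int(ensemble.sub_counts[p, col, a]),
        int(ensemble.sub_counts[p, col, b]),
    )
    return FisResult(
        protein_pos=protein_pos, ref_aa=ref_aa, alt_aa=alt_aa,
        fis=fis, family_term=fam, subfamily_term=sub, gene=gene,
    )


def score_table(
    records: Sequence[MutationRecord],
    ensembles: Mapping[str, AlignmentEnsemble],
) -> list[MutationRecord]:
    """Score every missense record that has an ensemble for its gene.

    Returns a new record list: missense records gain ``fis``; silent,
    truncating and other records are passed through unchanged.  Per-record
    failures (missing ensemble, reference mismatch, out-of-range position)
    are logged and leave ``fis`` absent.
    """
    out: list[MutationRecord] = []
    skipped: dict[str, int] = {}
    for rec in records:
        if rec.variant_class is not VariantClass.MISSENSE:
            out.append(rec)
            continue
        ens = ensembles.get(rec.gene)
        if ens is None:
            skipped[rec.gene] = skipped.get(rec.gene, 0) + 1
            out.append(rec)
            continue
        try:
            res = score_mutation(ens, rec.protein_pos, rec.ref_aa, rec.alt_aa, gene=rec.gene)
        except ValueError as e:
            logger.warning("could not score %s %s%d%s: %s",
                           rec.gene, rec.ref_aa, rec.protein_pos, rec.alt_aa, e)
            out.append(rec)
            continue
        out.append(rec.copy_with(fis=res.fis))
    for gene, n in sorted(skipped.items()):
        logger.warning("no alignment ensemble for gene %s: %d missense record(s) left unscored",
                       gene, n)
    return out
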