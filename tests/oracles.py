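"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's tally/ensemble intermediates: the
non-uniformity oracle recounts genes from the raw record list, and the
scoring oracle re-tallies residues by literal string scanning.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Sequence

from scipy.stats import hypergeom

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_non_uniformity(genes: Sequence[str]) -> tuple[float, float, float]:
    """(λ, K, μ) recomputed directly from a raw list of mutated-gene symbols."""
    m = len(genes)
    counts = Counter(genes)
    lam = sum((n / m) ** 2 for n in counts.values())
    return lam, 1.0 / lam, lam * len(counts)


def brute_force_fis(
    seqs: Sequence[str],
    labels: Sequence[int],
    query_index: int,
    protein_pos: int,
    ref_aa: str,
    alt_aa: str,
) -> float:
    """Score a substitution by literally scanning the alignment strings.

    Characters outside the 20 amino acids count as the gap type.  The
    column is the one holding the query's ``protein_pos``-th non-gap
    residue.
    """
    def kind(ch: str) -> str:
        ch = ch.upper()
        return ch if ch in AA20 else "-"

    query = seqs[query_index]
    seen = 0
    col = None
    for i, ch in enumerate(query):
        if kind(ch) != "-":
            seen += 1
            if seen == protein_pos:
                col = i
                break
    if col is None:
        raise ValueError("position beyond query length")
    if kind(query[col]) != ref_aa.upper():
        raise ValueError("reference mismatch")

    p = labels[query_index]
    n_a = sum(1 for s in seqs if kind(s[col]) == ref_aa.upper())
    n_b = sum(1 for s in seqs if kind(s[col]) == alt_aa.upper())
    np_a = sum(1 for s, l in zip(seqs, labels) if l == p and kind(s[col]) == ref_aa.upper())
    np_b = sum(1 for s, l in zip(seqs, labels) if l == p and kind(s[col]) == alt_aa.upper())
    return -0.5 * (math.log((n_b + 1) / n_a) + math.log((np_b + 1) / np_a))


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Sums the probabilities of all tables with the same margins whose
    probability does not exceed that of the observed table.
    """
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    dist = hypergeom(n, row1, col1)
    p_obs = dist.pmf(a)
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    total = 0.0
    for x in range(lo, hi + 1):
        px = dist.pmf(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)
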