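from __future__ import annotations

import numpy as np
import pytest

from mutsel.io_formats import MutationRecord, VariantClass


def make_record(
    gene: str,
    vclass: VariantClass = VariantClass.MISSENSE,
    sample: str = "S1",
    pos: int = 1,
    ref: str = "A",
    alt: str = "C",
    fis: float | None = None,
) -> MutationRecord:
    if vclass is VariantClass.SILENT:
        alt = ref
    if vclass in (VariantClass.TRUNCATING, VariantClass.OTHER):
        return MutationRecord(sample_id=sample, gene=gene, variant_class=vclass)
    return MutationRecord(
        sample_id=sample, gene=gene, variant_class=vclass,
        protein_pos=pos, ref_aa=ref, alt_aa=alt, fis=fis,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231107)


def random_small_alignment(rng: np.random.Generator, with_gaps: bool = True):
    """A random alignment of <= 8 sequences x <= 6 columns with labels."""
    n_seqs = int(rng.integers(2, 9))
    n_cols = int(rng.integers(1, 7))
    alphabet = list("ACDEG") + (["-"] if with_gaps else [])
    seqs = [
        "".join(rng.choice(alphabet, size=n_cols))
        for _ in range(n_seqs)
    ]
    # keep the query free of gaps in at least one column
    if all(c == "-" for c in seqs[0]):
        seqs[0] = "A" + seqs[0][1:]
    labels = [int(x) for x in rng.integers(0, min(3, n_seqs), size=n_seqs)]
    labels[0] = 0
    return seqs, labels
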