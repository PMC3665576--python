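"""Readers and validators for the pipeline's tabular and alignment inputs.

Handles MAF-like somatic mutation tables, per-gene protein multiple
alignments (FASTA/Stockholm), cancer-gene annotation lists, discretized
copy-number matrices and gene coding-length tables, and maps raw variant
classification labels onto the three mutation classes the analysis uses
(missense / silent / truncating, everything else "other").
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml
from Bio import AlignIO

logger = logging.getLogger(__name__)

__all__ = [
    "VariantClass",
    "MutationRecord",
    "GeneAnnotation",
    "CnaState",
    "GeneLength",
    "DialectConfig",
    "DEFAULT_CLASS_MAPPING",
    "classify_variant",
    "read_mutation_table",
    "write_mutation_table",
    "read_gene_list",
    "read_cna_matrix",
    "read_gene_lengths",
    "read_alignment",
    "read_subfamily_labels",
    "normalize_gene",
]


class VariantClass(enum.Enum):
    """The three mutation classes of the analysis, plus a catch-all."""

    MISSENSE = "missense"
    SILENT = "silent"
    TRUNCATING = "truncating"
    OTHER = "other"


#: Default mapping from raw MAF-style labels (lower-cased) to classes.
#: Truncating = the standard loss-of-function set; user-overridable.
DEFAULT_CLASS_MAPPING: dict[str, VariantClass] = {
    "missense_mutation": VariantClass.MISSENSE,
    "missense": VariantClass.MISSENSE,
    "silent": VariantClass.SILENT,
    "synonymous": VariantClass.SILENT,
    "nonsense_mutation": VariantClass.TRUNCATING,
    "frame_shift_del": VariantClass.TRUNCATING,
    "frame_shift_ins": VariantClass.TRUNCATING,
    "splice_site": VariantClass.TRUNCATING,
    "nonstop_mutation": VariantClass.TRUNCATING,
}


def normalize_gene(symbol: str) -> str:
    """Gene symbols are compared case-insensitively after trimming."""
    return str(symbol).strip().upper()


@dataclass
class MutationRecord:
    """One somatic mutation call.

    ``protein_pos`` is 1-based in the query protein (p.R273H style);
    ``fis`` is populated by the scoring stage and is ``None`` until then.
    """

    sample_id: str
    gene: str
    variant_class: VariantClass
    protein_pos: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    fis: Optional[float] = None
    raw_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.variant_class in (VariantClass.MISSENSE, VariantClass.SILENT):
            if self.protein_pos is None or self.protein_pos < 1:
                raise ValueError(
                    f"{self.variant_class.value} record for {self.gene} needs a "
                    f"protein position >= 1, got {self.protein_pos!r}"
                )
        if self.variant_class is VariantClass.MISSENSE and self.ref_aa == self.alt_aa:
            raise ValueError(
                f"missense record {self.gene}:{self.protein_pos} has identical "
                f"reference and alternate residue {self.ref_aa!r}"
            )

    def copy_with(self, **kw) -> "MutationRecord":
        return replace(self, **kw)


@dataclass(frozen=True)
class GeneAnnotation:
    """Membership of a gene in the tumor-suppressor (TS), oncogene (OG) and
    cancer-gene (CG) categories.  TS and OG are always subsets of CG."""

    gene: str
    categories: frozenset[str]

    def __post_init__(self) -> None:
        bad = self.categories - {"TS", "OG", "CG"}
        if bad:
            raise ValueError(f"unknown gene categories for {self.gene}: {sorted(bad)}")
        if ("TS" in self.categories or "OG" in self.categories) and "CG" not in self.categories:
            # containment is enforced at construction
            object.__setattr__(self, "categories", self.categories | {"CG"})


@dataclass(frozen=True)
class CnaState:
    """Discretized copy-number call for one gene in one sample.

    −1 heterozygous loss, 0 neutral, 1 gain, 2 amplification.
    """

    sample_id: str
    gene: str
    state: int

    def __post_init__(self) -> None:
        if self.state not in (-1, 0, 1, 2):
            raise ValueError(
                f"CNA state for ({self.gene}, {self.sample_id}) must be in "
                f"{{-1, 0, 1, 2}}, got {self.state}"
            )


@dataclass(frozen=True)
class GeneLength:
    """Coding length of a gene in nucleotides."""

    gene: str
    coding_length: int

    def __post_init__(self) -> None:
        if self.coding_length <= 0:
            raise ValueError(f"coding length of {self.gene} must be positive, got {self.coding_length}")


@dataclass
class DialectConfig:
    """Column names of a MAF-like table; defaults cover standard MAF exports."""

    sample_col: str = "Tumor_Sample_Barcode"
    gene_col: str = "Hugo_Symbol"
    class_col: str = "Variant_Classification"
    protein_col: str = "Protein_Change"
    fis_col: str = "FIS"
    class_mapping: Mapping[str, VariantClass] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MAPPING)
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DialectConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        mapping = dict(DEFAULT_CLASS_MAPPING)
        for label, cls_name in (raw.pop("class_mapping", None) or {}).items():
            mapping[str(label).lower()] = VariantClass(cls_name)
        return cls(**raw, class_mapping=mapping)


def classify_variant(
    raw_classification: str,
    mapping: Optional[Mapping[str, VariantClass]] = None,
) -> VariantClass:
    """Map a raw classification label to a mutation class.

    Total and deterministic: unknown labels map to ``OTHER``.  The mapping is
    keyed on lower-cased labels; class names themselves round-trip (the
    function is idempotent over its own output labels).
    """
    mapping = mapping if mapping is not None else DEFAULT_CLASS_MAPPING
    key = str(raw_classification).strip().lower()
    if key in mapping:
        return mapping[key]
    try:
        return VariantClass(key)
    except ValueError:
        return VariantClass.OTHER


_PROTEIN_CHANGE_RE = re.compile(r"^(?:p\.)?([A-Za-z])(\d+)([A-Za-z])$")


def _parse_protein_change(change: str) -> Optional[tuple[str, int, str]]:
    m = _PROTEIN_CHANGE_RE.match(str(change).strip())
    if not m:
        return None
    ref, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    if pos < 1:
        return None
    return ref, pos, alt


def read_mutation_table(
    path: str | Path,
    dialect: Optional[DialectConfig] = None,
) -> list[MutationRecord]:
    """Read a MAF-like tab-separated mutation table.

    Missense/silent rows whose protein-change string cannot be parsed are
    retained but demoted to class ``OTHER`` with a logged warning.  A missing
    mandatory column is fatal.
    """
    dialect = dialect or DialectConfig()
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in (dialect.sample_col, dialect.gene_col, dialect.class_col, dialect.protein_col):
        if col not in df.columns:
            raise ValueError(f"mutation table {path} is missing mandatory column {col!r}")

    has_fis = dialect.fis_col in df.columns
    records: list[MutationRecord] = []
    for idx, row in df.iterrows():
        raw_class = row[dialect.class_col]
        vclass = classify_variant(raw_class, dialect.class_mapping)
        gene = normalize_gene(row[dialect.gene_col])
        sample = str(row[dialect.sample_col]).strip()
        fis = None
        if has_fis and pd.notna(row[dialect.fis_col]) and str(row[dialect.fis_col]).strip():
            fis = float(row[dialect.fis_col])

        pos = ref = alt = None
        if vclass in (VariantClass.MISSENSE, VariantClass.SILENT):
            parsed = _parse_protein_change(row[dialect.protein_col])
            if parsed is None or (vclass is VariantClass.MISSENSE and parsed[0] == parsed[2]):
                logger.warning(
                    "row %d (%s): unparseable protein change %r on a %s row; "
                    "classified 'other'",
                    idx, gene, row[dialect.protein_col], vclass.value,
                )
                vclass = VariantClass.OTHER
            else:
                ref, pos, alt = parsed
        elif vclass is VariantClass.TRUNCATING:
            parsed = _parse_protein_change(row[dialect.protein_col])
            if parsed is not None:
                ref, pos, alt = parsed

        records.append(
            MutationRecord(
                sample_id=sample, gene=gene, variant_class=vclass,
                protein_pos=pos, ref_aa=ref, alt_aa=alt, fis=fis,
                raw_class=None if pd.isna(raw_class) else str(raw_class),
            )
        )
    return records


_CANONICAL_LABEL = {
    VariantClass.MISSENSE: "Missense_Mutation",
    VariantClass.SILENT: "Silent",
    VariantClass.TRUNCATING: "Nonsense_Mutation",
    VariantClass.OTHER: "Other",
}


def write_mutation_table(
    records: Iterable[MutationRecord],
    path: str | Path,
    dialect: Optional[DialectConfig] = None,
) -> None:
    """Write records as a MAF-like TSV that :func:`read_mutation_table` round-trips."""
    dialect = dialect or DialectConfig()
    rows = []
    for r in records:
        change = ""
        if r.protein_pos is not None and r.ref_aa and r.alt_aa:
            change = f"{r.ref_aa}{r.protein_pos}{r.alt_aa}"
        rows.append({
            dialect.sample_col: r.sample_id,
            dialect.gene_col: r.gene,
            dialect.class_col: r.raw_class or _CANONICAL_LABEL[r.variant_class],
            dialect.protein_col: change,
            dialect.fis_col: "" if r.fis is None else repr(float(r.fis)),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> dict[str, GeneAnnotation]:
    """Read a gene<TAB>category table into an annotation map.

    Duplicate gene rows are merged by category union; TS/OG membership
    implies CG.  Genes absent from the returned map are non-cancer genes.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    gene_col, cat_col = df.columns[0], df.columns[1]
    cats: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        gene = normalize_gene(row[gene_col])
        cats.setdefault(gene, set()).add(str(row[cat_col]).strip().upper())
    return {g: GeneAnnotation(gene=g, categories=frozenset(c)) for g, c in cats.items()}


def read_cna_matrix(path: str | Path) -> list[CnaState]:
    """Read a genes × samples matrix of discretized copy-number states.

    First column holds gene symbols; remaining column headers are sample ids.
    Any value outside {−1, 0, 1, 2} is fatal, naming the offending cell.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    states: list[CnaState] = []
    for gene, row in df.iterrows():
        g = normalize_gene(gene)
        for sample, value in row.items():
            v = int(value)
            if v not in (-1, 0, 1, 2):
                raise ValueError(
                    f"CNA matrix {path}: value {v} at gene {g!r}, sample "
                    f"{sample!r} is outside {{-1, 0, 1, 2}}"
                )
            states.append(CnaState(sample_id=str(sample).strip(), gene=g, state=v))
    return states


def read_gene_lengths(path: str | Path) -> list[GeneLength]:
    """Read a gene<TAB>coding_length table; conflicting duplicates are fatal."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    gene_col, len_col = df.columns[0], df.columns[1]
    seen: dict[str, int] = {}
    for _, row in df.iterrows():
        gene = normalize_gene(row[gene_col])
        length = int(row[len_col])
        if gene in seen and seen[gene] != length:
            raise ValueError(
                f"gene length table {path}: gene {gene!r} listed with "
                f"conflicting lengths {seen[gene]} and {length}"
            )
        seen[gene] = length
    return [GeneLength(gene=g, coding_length=n) for g, n in seen.items()]


def read_alignment(path: str | Path, fmt: Optional[str] = None):
    """Read a protein multiple alignment (FASTA or Stockholm) via Bio.AlignIO.

    Format is inferred from the extension when not given.
    """
    path = Path(path)
    if fmt is None:
        fmt = "stockholm" if path.suffix.lower() in {".sto", ".stk", ".stockholm"} else "fasta"
    return AlignIO.read(str(path), fmt)


def read_subfamily_labels(path: str | Path) -> dict[str, dict[str, int]]:
    """Read externally supplied subfamily labels.

    TSV with columns gene, sequence id, subfamily id; returns
    ``{gene: {seq_id: label}}``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    gcol, scol, pcol = df.columns[:3]
    out: dict[str, dict[str, int]] = {}
    for _, row in df.iterrows():
        out.setdefault(normalize_gene(row[gcol]), {})[str(row[scol])] = int(row[pcol])
    return out
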