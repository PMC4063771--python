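"""Sequence, locus-table and tree I/O.

Conventions used throughout the package:

* coordinates are 0-based half-open; conversion to 1-based happens only at
  I/O boundaries,
* sequences are stored as uppercase DNA (``U`` is folded to ``T`` on input;
  duplex logic re-interprets ``T`` as ``U``),
* minus-strand records are stored already reverse-complemented to sno-sense;
  the strand flag is metadata only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq

DNA_ALPHABET = set("ACGTN")

LOCUS_COLUMNS = [
    "gene_id",
    "species",
    "family",
    "sequence_id",
    "chrom",
    "start",
    "end",
    "strand",
    "order_index",
]


class ParseError(ValueError):
    """Raised for malformed input files."""


class ValidationError(ValueError):
    """Raised when a record violates a structural invariant."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and fold RNA to DNA letters."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class SnoRecord:
    """One snoRNA gene with species, family and genomic-order metadata."""

    gene_id: str
    species: str = ""
    family: str = ""
    sequence: str = ""
    chrom: str = ""
    start: int = -1
    end: int = -1
    strand: str = ""  # "+", "-" or "" (unset)
    order_index: int = -1

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        if len(self.sequence) < 1:
            raise ValidationError(f"{self.gene_id}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"{self.gene_id}: illegal characters {sorted(bad)} in sequence"
            )
        if self.start >= 0 and self.end >= 0:
            if self.end <= self.start:
                raise ValidationError(
                    f"{self.gene_id}: end ({self.end}) must exceed start ({self.start})"
                )
            if self.end - self.start != len(self.sequence):
                raise ValidationError(
                    f"{self.gene_id}: coordinate span {self.end - self.start} "
                    f"!= sequence length {len(self.sequence)}"
                )

    @property
    def coords_set(self) -> bool:
        return self.start >= 0 and self.end >= 0

    def with_family(self, family: str) -> "SnoRecord":
        return replace(self, family=family)


@dataclass
class LocusTable:
    """Ordered collection of :class:`SnoRecord` with unique gene ids."""

    records: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            if rec.gene_id in seen:
                raise ValidationError(f"duplicate gene_id {rec.gene_id!r}")
            seen.add(rec.gene_id)
        # order_index must be unique within (species, chrom) when set
        keyed = {}
        for rec in self.records:
            if rec.order_index >= 0:
                key = (rec.species, rec.chrom, rec.order_index)
                if key in keyed:
                    raise ValidationError(
                        f"duplicate order_index {rec.order_index} within "
                        f"({rec.species!r}, {rec.chrom!r})"
                    )
                keyed[key] = rec.gene_id

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_id(self, gene_id: str) -> SnoRecord:
        for rec in self.records:
            if rec.gene_id == gene_id:
                return rec
        raise KeyError(gene_id)

    def by_species(self, species: str) -> list:
        return [r for r in self.records if r.species == species]

    @property
    def species(self) -> list:
        out = []
        for rec in self.records:
            if rec.species not in out:
                out.append(rec.species)
        return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list:
    """Read a FASTA file into an ordered list of ``(id, sequence)`` tuples.

    Sequences are normalized (uppercase, U->T).  An empty sequence or a
    record without an identifier raises :class:`ParseError` naming the
    offending record.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: record with empty header")
        seq = normalize_sequence(str(rec.seq))
        if not seq:
            raise ParseError(f"{path}: empty sequence for record {rec.id!r}")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ParseError(
                f"{path}: record {rec.id!r} contains non-nucleotide characters "
                f"{sorted(bad)}"
            )
        out.append((rec.id, seq))
    return out


def write_fasta(records, path, width: int = 70) -> None:
    """Write ``(id, sequence)`` tuples (or SnoRecords) to FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, SnoRecord):
                name, seq = rec.gene_id, rec.sequence
            else:
                name, seq = rec
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_alignment(path) -> list:
    """Read aligned FASTA; gaps ('-') are preserved, rows must be equal length."""
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        rows.append((rec.id, seq))
    if not rows:
        raise ParseError(f"{path}: no records")
    width = len(rows[0][1])
    for name, seq in rows:
        if len(seq) != width:
            raise ParseError(f"{path}: ragged alignment at record {name!r}")
    return rows


# ---------------------------------------------------------------------------
# Locus table (TSV)
# ---------------------------------------------------------------------------

def read_locus_table(path) -> LocusTable:
    """Read the tab-separated locus table dialect.

    Required header: ``gene_id species family sequence_id chrom start end
    strand order_index``.  ``sequence_id`` may carry the sequence itself or
    be empty (sequences then come from a companion FASTA).  Missing optional
    fields are left unset.
    """
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        header = header_line.split("\t")
        if header != LOCUS_COLUMNS:
            raise ParseError(
                f"{path}: bad header {header!r}; expected {LOCUS_COLUMNS!r}"
            )
        records = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(LOCUS_COLUMNS):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(LOCUS_COLUMNS)} fields, "
                    f"got {len(fields)}"
                )
            row = dict(zip(LOCUS_COLUMNS, fields))
            try:
                rec = SnoRecord(
                    gene_id=row["gene_id"],
                    species=row["species"],
                    family=row["family"],
                    sequence=row["sequence_id"] or "N",
                    chrom=row["chrom"],
                    start=int(row["start"]) if row["start"] else -1,
                    end=int(row["end"]) if row["end"] else -1,
                    strand=row["strand"],
                    order_index=int(row["order_index"]) if row["order_index"] else -1,
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return LocusTable(records)


def write_locus_table(table: LocusTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(LOCUS_COLUMNS) + "\n")
        for rec in table:
            fh.write(
                "\t".join(
                    [
                        rec.gene_id,
                        rec.species,
                        rec.family,
                        rec.sequence,
                        rec.chrom,
                        str(rec.start) if rec.start >= 0 else "",
                        str(rec.end) if rec.end >= 0 else "",
                        rec.strand,
                        str(rec.order_index) if rec.order_index >= 0 else "",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(source, species_tree: bool = False) -> dendropy.Tree:
    """Parse a single rooted Newick tree.

    Internal node labels (bootstrap supports) are kept on ``node.label``.
    With ``species_tree=True`` duplicate leaf labels raise
    :class:`ParseError` (gene trees allow repeated species via distinct
    leaf ids).
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, ValueError):
            text = str(source)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ParseError(f"malformed newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if species_tree and len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ParseError(f"duplicate leaf labels in species tree: {dupes}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return text.strip() + ("\n" if not text.endswith("\n") else "")


def tree_from_string(text: str, **kw) -> dendropy.Tree:
    return read_newick(io.StringIO(text), **kw)
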