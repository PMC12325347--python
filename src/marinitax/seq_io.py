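"""Readers and writers for the formats every pipeline stage touches.

FASTA (protein / nucleotide / aligned nucleotide), ordered gene-annotation
TSV tables (dbCAN2-style labels), Newick trees with bootstrap supports as
internal-node labels, and square metrics matrices as TSV.

Conventions: a record id is the first whitespace-delimited token of its
header; genomic coordinates are 1-based inclusive in files while gene
ordinals are 0-based; alignment gaps ``-`` are legal only in nucleotide
FASTA explicitly declared as an alignment.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from skbio import TreeNode

PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYBZXJUO*")
NUCLEOTIDE_CHARS = frozenset("ACGTUNRYSWKMBDHV")

#: dbCAN2-style functional labels carried by gene tables. GH/GT/PL/CE/AA/CBM
#: are CAZyme classes; SULFATASE, TBDT (susC-like TonB-dependent transporter)
#: and SUSD mark the remaining PUL signature genes.
GENE_LABELS = (
    "GH", "GT", "PL", "CE", "AA", "CBM",
    "SULFATASE", "TBDT", "SUSD", "OTHER",
)

GENE_TABLE_COLUMNS = (
    "genome_id", "contig_id", "ordinal", "start", "end", "strand", "label",
)


class FormatError(ValueError):
    """A file violates the dialect this package reads."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record (protein or nucleotide)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record id must be non-empty")
        if not self.sequence:
            raise FormatError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Proteome:
    """All protein records of one genome; the unit of AAI/POCP comparison."""

    genome_id: str
    records: list[SequenceRecord] = field(default_factory=list)

    @property
    def n_proteins(self) -> int:
        return len(self.records)

    @property
    def n_residues(self) -> int:
        """Total residue count; the e-value search-space size n."""
        return sum(len(r) for r in self.records)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"proteome {self.genome_id!r} has no proteins")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise FormatError(f"duplicate protein ids in proteome {self.genome_id!r}")

    def __iter__(self):
        return iter(self.records)


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene in genome order.

    ``ordinal`` is the 0-based position of the gene along its contig in
    annotation order; ``start``/``end`` are 1-based inclusive nucleotide
    coordinates.
    """

    genome_id: str
    contig_id: str
    ordinal: int
    start: int
    end: int
    strand: str
    label: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.genome_id}/{self.contig_id}@{self.ordinal}: "
                f"start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.label not in GENE_LABELS:
            raise FormatError(
                f"unknown gene label {self.label!r}; expected one of {GENE_LABELS}"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(
    path: str | Path | io.TextIOBase,
    alphabet: str = "protein",
    alignment: bool = False,
) -> list[SequenceRecord]:
    """Read a text FASTA file into :class:`SequenceRecord` objects.

    Parameters
    ----------
    path
        File path or open text handle.
    alphabet
        ``"protein"`` or ``"nucleotide"``; controls character validation.
    alignment
        Permit ``-`` gap characters (nucleotide alignments only).

    Raises
    ------
    FormatError
        On duplicate ids, empty sequences, or characters outside the
        alphabet (reported with their line number).
    """
    if alphabet not in ("protein", "nucleotide"):
        raise ValueError(f"alphabet must be 'protein' or 'nucleotide', got {alphabet!r}")
    if alignment and alphabet != "nucleotide":
        raise ValueError("alignment gaps are supported only for nucleotide FASTA")
    allowed = PROTEIN_CHARS if alphabet == "protein" else NUCLEOTIDE_CHARS
    if alignment:
        allowed = allowed | {"-"}

    if isinstance(path, (str, Path)):
        handle = open(path)
        close = True
    else:
        handle, close = path, False

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        token, _, desc = header.partition(" ")
        if not token:
            raise FormatError(f"line {header_line}: empty FASTA header")
        if token in seen:
            raise FormatError(f"duplicate sequence id {token!r} (line {header_line})")
        if not seq:
            raise FormatError(f"record {token!r} (line {header_line}) has an empty sequence")
        seen.add(token)
        records.append(SequenceRecord(id=token, sequence=seq, description=desc.strip()))

    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"line {lineno}: sequence data before first '>' header")
                part = line.upper()
                bad = set(part) - allowed
                if bad:
                    raise FormatError(
                        f"line {lineno}: character(s) {sorted(bad)} not in the "
                        f"{alphabet} alphabet"
                    )
                chunks.append(part)
        flush()
    finally:
        if close:
            handle.close()
    return records


def write_fasta(
    records: Iterable[SequenceRecord],
    path: str | Path | io.TextIOBase,
    width: int = 60,
) -> None:
    """Write records as wrapped FASTA (round-trips with :func:`read_fasta`)."""
    if isinstance(path, (str, Path)):
        handle = open(path, "w")
        close = True
    else:
        handle, close = path, False
    try:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            handle.write(head + "\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")
    finally:
        if close:
            handle.close()


def read_proteome(path: str | Path, genome_id: str | None = None) -> Proteome:
    """Read one genome's protein FASTA as a :class:`Proteome`.

    ``genome_id`` defaults to the file stem.
    """
    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem
    return Proteome(genome_id=gid, records=read_fasta(path, alphabet="protein"))


# ---------------------------------------------------------------------------
# Gene tables


def read_gene_table(path: str | Path | io.TextIOBase) -> list[GeneFeature]:
    """Read an annotated gene table (TSV) into sorted :class:`GeneFeature` rows.

    The table must carry the columns ``genome_id, contig_id, ordinal, start,
    end, strand, label``. Rows may appear in any order; output is sorted by
    (genome_id, contig_id, ordinal) and ordinals must be consecutive from 0
    within each contig.
    """
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "contig_id": str})
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"gene table missing column(s): {sorted(missing)}")
    df = df.sort_values(["genome_id", "contig_id", "ordinal"], kind="stable")
    feats = [
        GeneFeature(
            genome_id=row.genome_id,
            contig_id=row.contig_id,
            ordinal=int(row.ordinal),
            start=int(row.start),
            end=int(row.end),
            strand=str(row.strand),
            label=str(row.label),
        )
        for row in df.itertuples(index=False)
    ]
    for (gid, cid), group in _group_by_contig(feats).items():
        ordinals = [f.ordinal for f in group]
        if ordinals != list(range(len(ordinals))):
            raise FormatError(
                f"contig {gid}/{cid}: ordinals must be consecutive from 0, got {ordinals}"
            )
    return feats


def write_gene_table(features: Sequence[GeneFeature], path: str | Path | io.TextIOBase) -> None:
    pd.DataFrame([f.__dict__ for f in features], columns=GENE_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def _group_by_contig(feats: Sequence[GeneFeature]) -> dict[tuple[str, str], list[GeneFeature]]:
    groups: dict[tuple[str, str], list[GeneFeature]] = {}
    for f in feats:
        groups.setdefault((f.genome_id, f.contig_id), []).append(f)
    return groups


# ---------------------------------------------------------------------------
# Newick


def read_newick(text: str | Path) -> TreeNode:
    """Parse a Newick string (or file path) into a tree.

    Numeric internal-node labels are interpreted as bootstrap supports and
    exposed as ``node.support``. Malformed parenthesis nesting raises a
    :class:`FormatError` carrying the character offset.
    """
    if isinstance(text, Path):
        text = text.read_text()
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(f"unbalanced ')' at character offset {offset}")
    if depth != 0:
        raise FormatError(
            f"unbalanced parentheses: {depth} '(' left open at end of input "
            f"(offset {len(text)})"
        )
    try:
        tree = TreeNode.read(io.StringIO(text))
    except Exception as exc:  # skbio's parse errors carry no offset
        raise FormatError(f"newick parse error: {exc}") from exc
    tree.assign_supports()
    return tree


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to Newick; ``node.support`` becomes the internal label."""
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


# ---------------------------------------------------------------------------
# Square matrices


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path | io.TextIOBase) -> None:
    """Write a square metrics matrix (genome ids as index and columns)."""
    if list(matrix.index) != list(matrix.columns):
        raise ValueError("matrix index and columns must list the same genome ids")
    matrix.to_csv(path, sep="\t", index_label="genome_id")


def read_matrix_tsv(path: str | Path | io.TextIOBase) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise FormatError("matrix row and column ids differ")
    return df
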