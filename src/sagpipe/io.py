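"""Readers and writers for the external formats the pipeline touches.

Internal conventions
--------------------
* Gene coordinates are 0-based, half-open.  ``read_gene_table`` /
  ``write_gene_table`` accept ``one_based=True`` to convert GFF-style
  1-based inclusive coordinates at the boundary; nothing downstream ever
  converts again.
* GC content is (G+C)/(A+C+G+T) over all contigs; ambiguous bases are
  excluded from both numerator and denominator.
* Hit tables are carried in a single in-memory type regardless of whether
  they came from a BLAST ``-outfmt 6`` TSV or a HMMER ``--tblout`` file.

Column mapping for the two hit-table dialects:

===============  =======================  ==========================
HitTable field   blast-tab-6 column       hmmer-tblout column
===============  =======================  ==========================
query            1 (qseqid)               1 (target name: sequence)
subject          2 (sseqid)               3 (query name: model)
pident           3 (pident)               n/a, stored as 0.0
length           4 (length)               n/a, stored as 0
evalue           11 (evalue)              5 (full sequence E-value)
bitscore         12 (bitscore)            6 (full sequence score)
===============  =======================  ==========================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_GC_BASES = frozenset("GCgc")
_UNAMBIG = frozenset("ACGTacgt")

GENE_TABLE_COLUMNS = ["gene_id", "genome_id", "contig_id", "start", "end", "strand"]

HIT_DIALECTS = ("blast-tab-6", "hmmer-tblout")


@dataclass
class SagAssembly:
    """A (possibly partial) genome assembly: ordered contigs plus metadata.

    ``cp_hours`` carries the MDA crossover point (hours to half-maximal
    dsDNA fluorescence) when known; it is metadata only and never enters
    any computation.
    """

    id: str
    contigs: list[tuple[str, str]] = field(default_factory=list)
    cp_hours: float | None = None

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)

    @property
    def gc_fraction(self) -> float:
        """(G+C)/(A+C+G+T); ambiguous bases excluded. 0.0 for an empty assembly."""
        gc = 0
        atgc = 0
        for _, seq in self.contigs:
            for base in seq:
                if base in _UNAMBIG:
                    atgc += 1
                    if base in _GC_BASES:
                        gc += 1
        return gc / atgc if atgc else 0.0

    @property
    def contig_ids(self) -> list[str]:
        return [cid for cid, _ in self.contigs]

    def contig_lengths(self) -> dict[str, int]:
        return {cid: len(seq) for cid, seq in self.contigs}

    def sequence(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)


@dataclass(frozen=True)
class Hit:
    """One pairwise search hit (one row of a hit table)."""

    query: str
    subject: str
    pident: float
    length: int
    bitscore: float
    evalue: float


@dataclass
class HitTable:
    """Ordered collection of :class:`Hit` rows from one search."""

    hits: list[Hit] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self) -> Iterator[Hit]:
        return iter(self.hits)

    def queries(self) -> set[str]:
        return {h.query for h in self.hits}

    def for_query(self, query: str) -> list[Hit]:
        return [h for h in self.hits if h.query == query]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(h.query, h.subject, h.pident, h.length, h.bitscore, h.evalue) for h in self.hits],
            columns=["query", "subject", "pident", "length", "bitscore", "evalue"],
        )


def read_fasta(path: str | Path, assembly_id: str | None = None, cp_hours: float | None = None) -> SagAssembly:
    """Read a FASTA file into a :class:`SagAssembly`, preserving contig order.

    Raises ``ValueError`` on an empty file or a duplicate contig id.
    """
    path = Path(path)
    contigs: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate contig id {rec.id!r} in {path}")
        seen.add(rec.id)
        contigs.append((rec.id, str(rec.seq)))
    if not contigs:
        raise ValueError(f"no sequences found in {path}")
    return SagAssembly(id=assembly_id or path.stem, contigs=contigs, cp_hours=cp_hours)


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    """Write (id, sequence) pairs to FASTA."""
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def filter_contigs(assembly: SagAssembly, min_len: int = 2000) -> SagAssembly:
    """Drop contigs not larger than ``min_len`` (strictly greater-than survives).

    ``min_len=0`` is the identity.  Removing every contig yields an empty
    assembly with ``total_length`` 0 and a warning, not an error.
    """
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    kept = [(cid, seq) for cid, seq in assembly.contigs if len(seq) > min_len]
    if not kept and assembly.contigs:
        warnings.warn(
            f"all {len(assembly.contigs)} contigs of {assembly.id} are <= {min_len} bp; "
            "assembly is now empty",
            stacklevel=2,
        )
    return SagAssembly(id=assembly.id, contigs=kept, cp_hours=assembly.cp_hours)


def _parse_blast6_row(fields: list[str], lineno: int, path: str) -> Hit:
    if len(fields) < 12:
        raise ValueError(f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}")
    try:
        return Hit(
            query=fields[0],
            subject=fields[1],
            pident=float(fields[2]),
            length=int(fields[3]),
            bitscore=float(fields[11]),
            evalue=float(fields[10]),
        )
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: malformed blast-tab-6 row ({exc})") from None


def _parse_tblout_row(fields: list[str], lineno: int, path: str) -> Hit:
    if len(fields) < 6:
        raise ValueError(f"{path}:{lineno}: expected >= 6 whitespace-separated columns, got {len(fields)}")
    try:
        return Hit(
            query=fields[0],
            subject=fields[2],
            pident=0.0,
            length=0,
            bitscore=float(fields[5]),
            evalue=float(fields[4]),
        )
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: malformed hmmer-tblout row ({exc})") from None


def read_hit_table(path: str | Path, dialect: str = "blast-tab-6") -> HitTable:
    """Parse a tabular search-result file.

    ``dialect`` is ``"blast-tab-6"`` (BLAST ``-outfmt 6``) or
    ``"hmmer-tblout"`` (HMMER ``--tblout``).  Lines starting with ``#`` are
    ignored; a malformed row raises ``ValueError`` naming the line number.
    """
    if dialect not in HIT_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {HIT_DIALECTS}")
    path = Path(path)
    hits: list[Hit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if dialect == "blast-tab-6":
                hits.append(_parse_blast6_row(line.split("\t"), lineno, str(path)))
            else:
                hits.append(_parse_tblout_row(line.split(), lineno, str(path)))
    return HitTable(hits)


def write_hit_table(table: HitTable, path: str | Path) -> None:
    """Write a :class:`HitTable` as BLAST ``-outfmt 6`` TSV.

    Columns not carried by :class:`Hit` (mismatches, gap opens, query and
    subject coordinates) are written as 0 placeholders; a read-back
    reproduces every carried field exactly.
    """
    with open(path, "w") as fh:
        for h in table.hits:
            fh.write(
                "\t".join(
                    [
                        h.query,
                        h.subject,
                        repr(h.pident),
                        str(h.length),
                        "0",
                        "0",
                        "0",
                        "0",
                        "0",
                        "0",
                        repr(h.evalue),
                        repr(h.bitscore),
                    ]
                )
                + "\n"
            )


def validate_gene_table(df: pd.DataFrame, contig_lengths: dict[str, int] | None = None) -> None:
    """Check gene-table invariants: column set, 0 <= start < end, strand in {+,-},
    gene ids unique within a genome, and (optionally) end <= contig length."""
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
        bad = df[(df["start"] < 0) | (df["start"] >= df["end"])]["gene_id"].tolist()
        raise ValueError(f"invalid coordinates (need 0 <= start < end) for genes: {bad[:5]}")
    if (~df["strand"].isin(["+", "-"])).any():
        raise ValueError("strand column must be '+' or '-'")
    dup = df.duplicated(subset=["genome_id", "gene_id"])
    if dup.any():
        raise ValueError(f"duplicate gene ids within a genome: {df[dup]['gene_id'].tolist()[:5]}")
    if contig_lengths is not None:
        lengths = df["contig_id"].map(contig_lengths)
        if (df["end"] > lengths).any():
            bad = df[df["end"] > lengths]["gene_id"].tolist()
            raise ValueError(f"gene end beyond contig length for genes: {bad[:5]}")


def read_gene_table(path: str | Path, one_based: bool = False) -> pd.DataFrame:
    """Read a gene table TSV (gene_id, genome_id, contig_id, start, end, strand).

    With ``one_based=True`` the file is interpreted as 1-based inclusive
    (GFF-style) and converted to the internal 0-based half-open convention.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "genome_id": str, "contig_id": str})
    if one_based:
        df = df.assign(start=df["start"] - 1)
    validate_gene_table(df)
    return df[GENE_TABLE_COLUMNS].copy()


def write_gene_table(df: pd.DataFrame, path: str | Path, one_based: bool = False) -> None:
    """Write a gene table TSV; ``one_based=True`` emits 1-based inclusive coordinates."""
    validate_gene_table(df)
    out = df[GENE_TABLE_COLUMNS].copy()
    if one_based:
        out["start"] = out["start"] + 1
    out.to_csv(path, sep="\t", index=False)
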