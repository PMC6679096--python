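"""Readers and writers for the formats the pipeline consumes and emits.

Four formats are supported, all optionally gzip-compressed:

* FASTA / FASTQ (Phred+33) for reads and reference databases,
* 12-column BLAST tabular output (legacy ``-m 8`` / ``outfmt 6``) for
  alignment hits,
* a two-column TSV mapping reference-sequence ids to species labels.

All downstream modules operate on the three in-memory types defined here:
:class:`SequenceRecord`, :class:`AlignmentHit` and :class:`TaxonomyMap`.
Sequences are normalized on input: uppercased, whitespace removed, and
IUPAC ambiguity codes other than N mapped to N (with a logged warning),
because the identity and deamination logic downstream is defined over
``{A, C, G, T, N}`` only.
"""

from __future__ import annotations

import gzip
import io
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# uppercase translation plus IUPAC-ambiguity -> N
_NORMALIZE = str.maketrans(
    "acgtnACGTN" + "ryswkmbdhvuRYSWKMBDHVU",
    "ACGTNACGTN" + "N" * 22,
)


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a normalized DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_seq(seq: str, *, context: str = "") -> str:
    """Uppercase, strip whitespace, map non-ACGTN IUPAC codes to N.

    Characters outside the IUPAC alphabet raise :class:`ParseError`.
    """
    compact = "".join(seq.split())
    out = compact.translate(_NORMALIZE)
    bad = set(out) - VALID_BASES
    if bad:
        raise ParseError(
            f"invalid sequence characters {sorted(bad)}"
            + (f" in {context}" if context else "")
        )
    if out != compact.upper():
        logger.warning(
            "ambiguity codes mapped to N%s", f" in {context}" if context else ""
        )
    return out


@dataclass(frozen=True)
class SequenceRecord:
    """One read or reference sequence.

    ``qual`` holds Phred scores (offset already removed), or None for
    FASTA input. The constructor does not normalize; use the readers or
    :func:`normalize_seq` for untrusted input.
    """

    id: str
    seq: str
    qual: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TaxonomyMap:
    """Mapping from reference-sequence id to species label."""

    entries: Mapping[str, str]

    def species_of(self, sid: str) -> str:
        try:
            return self.entries[sid]
        except KeyError:
            raise KeyError(
                f"reference id {sid!r} has no species label in the taxonomy map"
            ) from None

    def __contains__(self, sid: str) -> bool:
        return sid in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class AlignmentHit:
    """One local alignment in BLAST ``-m 8`` coordinates.

    Coordinates are 1-based inclusive, exactly as BLAST prints them;
    ``sstart > send`` encodes a minus-strand hit. ``qlen`` is the full
    read length (not part of the m8 format; supplied from the read file)
    and is required for query coverage. ``qaln``/``saln`` are the gapped
    aligned strings in read orientation, populated by the internal
    aligner or by realignment; ``score`` is the raw alignment score when
    produced internally.
    """

    qid: str
    sid: str
    pident: float
    alen: int
    mismatches: int
    gapopens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qlen: int | None = None
    qaln: str | None = None
    saln: str | None = None
    score: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.qstart <= self.qend:
            raise ValueError(
                f"hit {self.qid}->{self.sid}: bad query interval "
                f"[{self.qstart}, {self.qend}]"
            )
        if self.qlen is not None and self.qend > self.qlen:
            raise ValueError(
                f"hit {self.qid}->{self.sid}: qend {self.qend} > qlen {self.qlen}"
            )
        if (self.qaln is None) != (self.saln is None):
            raise ValueError(f"hit {self.qid}->{self.sid}: qaln/saln must come together")
        if self.qaln is not None:
            if len(self.qaln) != len(self.saln):
                raise ValueError(f"hit {self.qid}->{self.sid}: qaln/saln length differ")
            ungapped = len(self.qaln) - self.qaln.count("-")
            if ungapped != self.qend - self.qstart + 1:
                raise ValueError(
                    f"hit {self.qid}->{self.sid}: qaln spans {ungapped} bases, "
                    f"coordinates span {self.qend - self.qstart + 1}"
                )

    @property
    def is_minus(self) -> bool:
        return self.sstart > self.send

    def with_alignment(self, qaln: str, saln: str) -> "AlignmentHit":
        return replace(self, qaln=qaln, saln=saln)


def _open_text(path: str | Path, mode: str = "rt") -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> Iterator[SequenceRecord]:
    """Yield normalized records from a (possibly gzipped) FASTA file."""
    with _open_text(path) as fh:
        n = 0
        for title, seq in SimpleFastaParser(fh):
            rid = title.split()[0] if title.split() else ""
            if not rid:
                raise ParseError(f"{path}: FASTA record {n + 1} has an empty header")
            if not seq.strip():
                raise ParseError(f"{path}: record {rid!r} has an empty sequence")
            yield SequenceRecord(rid, normalize_seq(seq, context=rid))
            n += 1


def read_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    """Yield normalized records from a (possibly gzipped) Phred+33 FASTQ file."""
    with _open_text(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                rid = title.split()[0]
                if len(seq) != len(qual):
                    raise ParseError(
                        f"{path}: record {rid!r} sequence/quality length mismatch"
                    )
                yield SequenceRecord(
                    rid,
                    normalize_seq(seq, context=rid),
                    tuple(ord(c) - 33 for c in qual),
                )
        except ValueError as exc:
            if isinstance(exc, ParseError):
                raise
            raise ParseError(f"{path}: {exc}") from exc


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            if rec.qual is None:
                raise ValueError(f"record {rec.id!r} has no qualities; cannot write FASTQ")
            qual = "".join(chr(q + 33) for q in rec.qual)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


def read_lengths(records: Iterable[SequenceRecord]) -> dict[str, int]:
    """Map read id -> length, for feeding :func:`read_m8`."""
    return {rec.id: len(rec.seq) for rec in records}


def read_m8(path: str | Path, lengths: Mapping[str, int]) -> Iterator[AlignmentHit]:
    """Parse 12-column BLAST tabular hits.

    ``lengths`` supplies the full read length for each query id (the m8
    format does not carry it, and query coverage is undefined without
    it); ids missing from the mapping raise :class:`ParseError`.
    """
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            qid = fields[0]
            if qid not in lengths:
                raise ParseError(
                    f"{path}:{lineno}: query {qid!r} not found in the read file; "
                    "m8 input must be accompanied by its query FASTA/FASTQ"
                )
            try:
                hit = AlignmentHit(
                    qid=qid,
                    sid=fields[1],
                    pident=float(fields[2]),
                    alen=int(fields[3]),
                    mismatches=int(fields[4]),
                    gapopens=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    qlen=lengths[qid],
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            yield hit


def _fmt_evalue(e: float) -> str:
    if e == 0:
        return "0.0"
    if e >= 0.001:
        return f"{e:.3g}"
    return f"{e:.0e}"


def write_m8(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits as standard 12-column tabular, outfmt-6 compatible."""
    with _open_text(path, "wt") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    (
                        h.qid,
                        h.sid,
                        f"{h.pident:.2f}",
                        str(h.alen),
                        str(h.mismatches),
                        str(h.gapopens),
                        str(h.qstart),
                        str(h.qend),
                        str(h.sstart),
                        str(h.send),
                        _fmt_evalue(h.evalue),
                        f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )


def read_taxonomy_map(path: str | Path) -> TaxonomyMap:
    """Parse the 2-column TSV mapping reference id -> species label.

    Duplicate lines are tolerated when they agree; the same id mapped to
    two different species is an error, as is a blank species label.
    """
    entries: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            sid, species = parts[0].strip(), parts[1].strip()
            if not sid or not species:
                raise ParseError(f"{path}:{lineno}: blank sequence id or species label")
            if sid in entries and entries[sid] != species:
                raise ParseError(
                    f"{path}:{lineno}: id {sid!r} mapped to both "
                    f"{entries[sid]!r} and {species!r}"
                )
            entries[sid] = species
    return TaxonomyMap(entries)


def write_taxonomy_map(taxmap: TaxonomyMap, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for sid, species in taxmap.entries.items():
            fh.write(f"{sid}\t{species}\n")
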