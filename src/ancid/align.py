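"""BLASTn-like local alignment of short reads against a reference database.

The aligner is a stand-in for an external BLAST binary so the pipeline
runs self-contained: exact word matches (default word size 11) seed
candidate regions on both strands, overlapping seed windows are merged,
and each window is resolved by a full affine-gap Smith–Waterman over the
read and the window (Biopython's ``PairwiseAligner`` supplies the DP).
Because the window always contains the whole candidate region plus a
read-length margin, the reported score for a seeded alignment equals the
unrestricted Smith–Waterman optimum for that region — the window DP is a
superset of BLAST's x-drop extension.

E-values follow Karlin–Altschul statistics with the ungapped lambda
solved numerically from the scoring scheme; they will not numerically
match any particular BLAST release, and the downstream species calls
deliberately depend only on percent identity and query coverage, which
are robust to the scoring details.

Scoring convention: a gap of length *k* costs ``gap_open + k *
gap_extend`` (both negative), i.e. the opening penalty is charged in
addition to an extension penalty for every gapped base, matching the
classic blastn accounting. N never scores as a match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

from .seqio import AlignmentHit, SequenceRecord, reverse_complement, write_m8  # noqa: F401

__all__ = [
    "AlignerConfig",
    "local_align",
    "search",
    "query_coverage",
    "realign_hit",
    "write_m8",
]

# Ungapped Karlin-Altschul K for common blastn reward/penalty pairs;
# schemes without a tabulated K fall back to 0.5 (E-values then serve
# only as a relative reporting threshold).
_KA_K = {(1, -2): 0.621, (1, -3): 0.711, (2, -3): 0.673, (1, -1): 0.2}


@lru_cache(maxsize=None)
def _karlin_lambda(match: int, mismatch: int) -> float:
    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    hi = 2.0
    while f(hi) < 0:
        hi *= 2
    return brentq(f, 1e-9, hi)


@dataclass(frozen=True)
class AlignerConfig:
    """Parameters of the internal nucleotide aligner.

    Defaults mirror classic blastn: +1/-2 match/mismatch, affine gaps
    -5 open / -2 extend, word size 11. ``db_size`` is the effective
    database length used in the E-value; when None the summed subject
    length is used. ``x_drop`` is retained for interface compatibility
    with x-drop extenders; the windowed full DP used here never drops
    candidates, so it does not alter results.
    """

    word_size: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    x_drop: int = 20
    max_evalue: float = 1e-3
    db_size: int | None = None

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("match must be positive and mismatch negative")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")

    @property
    def karlin_lambda(self) -> float:
        """Ungapped lambda: solves sum_ij p_i p_j exp(lambda s_ij) = 1."""
        return _karlin_lambda(self.match, self.mismatch)

    @property
    def karlin_k(self) -> float:
        return _KA_K.get((self.match, self.mismatch), 0.5)

    def bitscore(self, raw: float) -> float:
        return (self.karlin_lambda * raw - math.log(self.karlin_k)) / math.log(2)

    def evalue(self, raw: float, qlen: int, db_size: int) -> float:
        return self.karlin_k * qlen * db_size * math.exp(-self.karlin_lambda * raw)


def _make_aligner(cfg: AlignerConfig, mode: str) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            matrix[a, b] = cfg.match if (a == b and a != "N") else cfg.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = matrix
    # PairwiseAligner charges open_gap_score for the first gapped base,
    # extend_gap_score for each subsequent one; fold the extension into
    # the opening charge to realize cost(k) = open + k * extend.
    aligner.open_gap_score = cfg.gap_open + cfg.gap_extend
    aligner.extend_gap_score = cfg.gap_extend
    return aligner


def query_coverage(hit: AlignmentHit) -> float:
    """Percent of the read covered by the local alignment: 100*(qend-qstart+1)/qlen."""
    if hit.qlen is None:
        raise ValueError(
            f"hit {hit.qid}->{hit.sid} has no query length; coverage is undefined"
        )
    return 100.0 * (hit.qend - hit.qstart + 1) / hit.qlen


def _column_stats(qaln: str, saln: str) -> tuple[int, int, int]:
    """(matches, mismatches, gapopens) over alignment columns; N never matches."""
    matches = mismatches = gapopens = 0
    in_qgap = in_sgap = False
    for qc, sc in zip(qaln, saln):
        if qc == "-":
            if not in_qgap:
                gapopens += 1
            in_qgap, in_sgap = True, False
        elif sc == "-":
            if not in_sgap:
                gapopens += 1
            in_qgap, in_sgap = False, True
        else:
            in_qgap = in_sgap = False
            if qc == sc and qc != "N":
                matches += 1
            else:
                mismatches += 1
    return matches, mismatches, gapopens


class _SeedIndex:
    """Exact word index over both strands of a set of subjects."""

    def __init__(self, subjects: Sequence[SequenceRecord], word: int):
        self.word = word
        self.subjects = subjects
        # strand strings: plus as-is, minus = reverse complement
        self.strands: list[tuple[int, int, str]] = []
        self.table: dict[str, list[tuple[int, int]]] = {}
        for si, rec in enumerate(subjects):
            for strand, s in ((1, rec.seq), (-1, reverse_complement(rec.seq))):
                key = len(self.strands)
                self.strands.append((si, strand, s))
                for pos in range(len(s) - word + 1):
                    kmer = s[pos : pos + word]
                    if "N" in kmer:
                        continue
                    self.table.setdefault(kmer, []).append((key, pos))

    def windows(
        self, qseq: str, pad: int = 50
    ) -> dict[int, list[tuple[int, int, list[tuple[int, int]]]]]:
        """Merged candidate subject intervals per strand-string key.

        Each seed (qpos, spos) induces the window that could contain any
        local alignment through it: ``[spos - qpos - pad, spos + (qlen -
        qpos) + pad]``; overlapping windows are merged. Each merged
        interval carries its seeds (one per diagonal) for the ungapped
        prefilter.
        """
        word, qlen = self.word, len(qseq)
        raw: dict[int, list[tuple[int, int, int, int]]] = {}
        for qpos in range(qlen - word + 1):
            entry = self.table.get(qseq[qpos : qpos + word])
            if not entry:
                continue
            for key, spos in entry:
                raw.setdefault(key, []).append(
                    (spos - qpos - pad, spos + (qlen - qpos) + pad, qpos, spos)
                )
        merged: dict[int, list[tuple[int, int, list[tuple[int, int]]]]] = {}
        for key, ivals in raw.items():
            ivals.sort()
            slen = len(self.strands[key][2])
            out: list[list] = []
            for lo, hi, qpos, spos in ivals:
                if out and lo <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], hi)
                    out[-1][2].append((qpos, spos))
                else:
                    out.append([lo, hi, [(qpos, spos)]])
            cleaned = []
            for lo, hi, seeds in out:
                per_diag: dict[int, tuple[int, int]] = {}
                for qpos, spos in seeds:
                    per_diag.setdefault(spos - qpos, (qpos, spos))
                cleaned.append((max(0, lo), min(slen, hi), list(per_diag.values())))
            merged[key] = cleaned
        return merged


def _ungapped_score(qseq: str, sstr: str, qpos: int, spos: int, word: int,
                    match: int, mismatch: int, x_drop: int) -> int:
    """X-drop ungapped extension of an exact word seed along its diagonal."""
    score = best = word * match
    i, j = qpos + word, spos + word
    qlen, slen = len(qseq), len(sstr)
    while i < qlen and j < slen:
        score += match if (qseq[i] == sstr[j] and qseq[i] != "N") else mismatch
        if score > best:
            best = score
        elif best - score > x_drop:
            break
        i += 1
        j += 1
    right = best
    score = best = 0
    i, j = qpos - 1, spos - 1
    while i >= 0 and j >= 0:
        score += match if (qseq[i] == sstr[j] and qseq[i] != "N") else mismatch
        if score > best:
            best = score
        elif best - score > x_drop:
            break
        i -= 1
        j -= 1
    return right + best


def _align_window(
    aligner: Align.PairwiseAligner,
    query: SequenceRecord,
    window_seq: str,
    win_start: int,
    subject: SequenceRecord,
    strand: int,
    cfg: AlignerConfig,
    db_size: int,
) -> AlignmentHit | None:
    alignments = aligner.align(window_seq, query.seq)
    try:
        best = alignments[0]
    except IndexError:
        return None
    if best.score <= 0:
        return None
    saln, qaln = best[0], best[1]
    tblocks, qblocks = best.aligned
    t0, t1 = int(tblocks[0][0]), int(tblocks[-1][1])
    q0, q1 = int(qblocks[0][0]), int(qblocks[-1][1])
    # 1-based inclusive coordinates on the strand string
    ss, se = win_start + t0 + 1, win_start + t1
    if strand == 1:
        sstart, send = ss, se
    else:
        slen = len(subject.seq)
        sstart, send = slen - ss + 1, slen - se + 1
    matches, mismatches, gapopens = _column_stats(qaln, saln)
    alen = len(qaln)
    raw = int(best.score)
    return AlignmentHit(
        qid=query.id,
        sid=subject.id,
        pident=round(100.0 * matches / alen, 2),
        alen=alen,
        mismatches=mismatches,
        gapopens=gapopens,
        qstart=q0 + 1,
        qend=q1,
        sstart=sstart,
        send=send,
        evalue=cfg.evalue(raw, len(query.seq), db_size),
        bitscore=round(cfg.bitscore(raw), 1),
        qlen=len(query.seq),
        qaln=qaln,
        saln=saln,
        score=raw,
    )


def _hits_for_read(
    query: SequenceRecord,
    index: _SeedIndex,
    aligner: Align.PairwiseAligner,
    cfg: AlignerConfig,
    db_size: int,
) -> list[AlignmentHit]:
    hits: list[AlignmentHit] = []
    seen: set[tuple[str, int, int, int, int]] = set()
    # smallest raw score whose E-value could pass the threshold; used with a
    # gap-sized safety margin to prefilter windows by ungapped seed extension
    min_raw = math.ceil(
        math.log(cfg.karlin_k * len(query.seq) * db_size / cfg.max_evalue)
        / cfg.karlin_lambda
    )
    prefilter = max(cfg.word_size * cfg.match, min_raw + cfg.gap_open)
    for key, ivals in index.windows(query.seq).items():
        si, strand, sstr = index.strands[key]
        subject = index.subjects[si]
        for lo, hi, seeds in ivals:
            if not any(
                _ungapped_score(
                    query.seq, sstr, qpos, spos, cfg.word_size,
                    cfg.match, cfg.mismatch, cfg.x_drop,
                )
                >= prefilter
                for qpos, spos in seeds
            ):
                continue
            hit = _align_window(
                aligner, query, sstr[lo:hi], lo, subject, strand, cfg, db_size
            )
            if hit is None or hit.evalue > cfg.max_evalue:
                continue
            sig = (hit.sid, hit.qstart, hit.qend, hit.sstart, hit.send)
            if sig in seen:
                continue
            seen.add(sig)
            hits.append(hit)
    hits.sort(key=lambda h: (-h.bitscore, h.sid, min(h.sstart, h.send)))
    return hits


def local_align(
    query: SequenceRecord, subject: SequenceRecord, cfg: AlignerConfig | None = None
) -> list[AlignmentHit]:
    """Local alignments of one read against one subject, both strands.

    Hits are sorted by descending bitscore, ties broken by smallest
    subject start. An empty list is a valid outcome (no seeded region
    reached the E-value threshold).
    """
    cfg = cfg or AlignerConfig()
    if len(query.seq) < cfg.word_size:
        raise ValueError(
            f"query {query.id!r} shorter than word size {cfg.word_size}"
        )
    index = _SeedIndex([subject], cfg.word_size)
    aligner = _make_aligner(cfg, "local")
    db_size = cfg.db_size or len(subject.seq)
    return _hits_for_read(query, index, aligner, cfg, db_size)


def search(
    reads: Iterable[SequenceRecord],
    database: Sequence[SequenceRecord],
    cfg: AlignerConfig | None = None,
) -> list[AlignmentHit]:
    """Align every read against every database sequence via a shared seed index.

    Output order is deterministic: by query id, then descending
    bitscore, then subject id.
    """
    cfg = cfg or AlignerConfig()
    database = list(database)
    if not database:
        raise ValueError("reference database is empty")
    index = _SeedIndex(database, cfg.word_size)
    aligner = _make_aligner(cfg, "local")
    db_size = cfg.db_size or sum(len(r.seq) for r in database)
    hits: list[AlignmentHit] = []
    for read in reads:
        if len(read.seq) < cfg.word_size:
            continue
        hits.extend(_hits_for_read(read, index, aligner, cfg, db_size))
    hits.sort(key=lambda h: (h.qid, -h.bitscore, h.sid, min(h.sstart, h.send)))
    return hits


def realign_hit(
    hit: AlignmentHit, query: SequenceRecord, subject: SequenceRecord,
    cfg: AlignerConfig | None = None,
) -> AlignmentHit:
    """Recover per-column differences for an externally produced hit.

    Globally aligns the read segment ``[qstart, qend]`` against the
    subject segment ``[sstart, send]`` (reverse-complemented for a
    minus-strand hit) and returns the hit with ``qaln``/``saln``
    populated, in read orientation. Needed because m8 files carry no
    aligned strings, and the deamination screen must inspect columns.
    """
    cfg = cfg or AlignerConfig()
    if query.id != hit.qid:
        raise ValueError(f"read {query.id!r} does not match hit query {hit.qid!r}")
    if subject.id != hit.sid:
        raise ValueError(f"subject {subject.id!r} does not match hit {hit.sid!r}")
    lo, hi = min(hit.sstart, hit.send), max(hit.sstart, hit.send)
    if lo < 1 or hi > len(subject.seq):
        raise ValueError(
            f"hit {hit.qid}->{hit.sid}: subject interval [{hit.sstart}, {hit.send}] "
            f"outside sequence of length {len(subject.seq)}"
        )
    if hit.qend > len(query.seq):
        raise ValueError(
            f"hit {hit.qid}->{hit.sid}: qend {hit.qend} beyond read length"
        )
    qseg = query.seq[hit.qstart - 1 : hit.qend]
    sseg = subject.seq[lo - 1 : hi]
    if hit.is_minus:
        sseg = reverse_complement(sseg)
    aligner = _make_aligner(cfg, "global")
    best = aligner.align(sseg, qseg)[0]
    return replace(hit, qaln=best[1], saln=best[0], qlen=hit.qlen or len(query.seq))
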