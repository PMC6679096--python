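"""Species calling from filtered alignment hits.

The decision procedure, applied to the hits of one sample against a
mitochondrial reference database:

1. **Deduplication** — a read aligning at several places within one
   reference sequence contributes a single hit: the one with the highest
   percent identity, ties broken uniformly at random (seeded). Hits to
   distinct reference sequences are all retained, so the valid mapping
   hits (VMH) of one read may span several species.
2. **Similarity/coverage filter** — keep hits with percent identity
   ``L >= L_min`` (default 98), optionally excluding perfect matches
   (``L < 100``; deamination makes a perfect match to a modern reference
   suspicious), and query coverage ``C >= C_min`` (default 96; local
   alignment of very short reads with low coverage inflates random
   hits).
3. **Deamination screen** (optional) — keep only hits showing at least
   one C→T or G→A difference within the first or last ``X`` read bases
   (default window 10, useful range 5–10), the signature of postmortem
   cytosine deamination. Requires a non-UDG library.
4. **Ranking** — count VMH per species, rank by count (the species
   ranking, SR), express each as a percentage of the total (PoVMH), and
   report the ratio ``R`` of the top species' PoVMH to the runner-up's
   as the confidence measure. The call is the top-ranked species unless
   too few VMH survive.
"""

from __future__ import annotations

import json
import random
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignerConfig, query_coverage, realign_hit, search
from .seqio import AlignmentHit, SequenceRecord, TaxonomyMap

__all__ = [
    "FilterConfig",
    "SpeciesRanking",
    "PipelineResult",
    "dedupe_hits",
    "filter_hits",
    "deamination_screen",
    "species_ranking",
    "identify_pipeline",
    "stability_analysis",
]

UNIDENTIFIED = "unidentified"


@dataclass(frozen=True)
class FilterConfig:
    """Filtering and calling parameters.

    ``L_min``/``exclude_perfect``/``C_min`` implement the recommended
    similarity band (98 <= L < 100) and coverage floor (C >= 96).
    ``X`` is the terminal screening window in bases (0 disables the
    screen). ``min_vmh`` is a floor below which no call is made —
    samples with a handful of surviving hits are effectively unmappable.
    ``min_ratio`` optionally flags calls whose top-to-second PoVMH ratio
    R falls below a user threshold; the default 1.0 never flags, since
    the ranking itself guarantees R >= 1. ``best_hit_per_read`` restricts
    each read to its single best surviving hit, a stricter counting mode
    for databases with very uneven species representation.
    """

    L_min: float = 98.0
    exclude_perfect: bool = True
    C_min: float = 96.0
    X: int = 10
    min_vmh: int = 10
    min_ratio: float = 1.0
    seed: int = 0
    best_hit_per_read: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.L_min <= 100:
            raise ValueError("L_min must lie in [0, 100]")
        if not 0 < self.C_min <= 100:
            raise ValueError("C_min must lie in (0, 100]")
        if self.X < 0:
            raise ValueError("X must be >= 0")
        if self.min_vmh < 1:
            raise ValueError("min_vmh must be >= 1")
        if self.min_ratio < 1:
            raise ValueError("min_ratio must be >= 1")


@dataclass(frozen=True)
class SpeciesRanking:
    """The decision object: ranked species with VMH counts and PoVMH."""

    rows: tuple[tuple[str, int, float], ...]  # (species, vmh, povmh), rank order
    total_vmh: int
    R: float | None
    call: str
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "call": self.call,
            "total_vmh": self.total_vmh,
            "R": self.R,
            "flags": list(self.flags),
            "ranking": [
                {"rank": i + 1, "species": sp, "vmh": v, "povmh": round(p, 4)}
                for i, (sp, v, p) in enumerate(self.rows)
            ],
        }

    def top(self, k: int) -> tuple[str, ...]:
        return tuple(sp for sp, _, _ in self.rows[:k])


def dedupe_hits(hits: Iterable[AlignmentHit], seed: int = 0) -> list[AlignmentHit]:
    """One hit per (read, reference sequence): highest percent identity,
    equal-identity ties resolved uniformly at random under ``seed``.

    Output preserves the first-occurrence order of each (qid, sid) pair.
    """
    groups: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        groups.setdefault((h.qid, h.sid), []).append(h)
    rng = random.Random(seed)
    out: list[AlignmentHit] = []
    for members in groups.values():
        best = max(m.pident for m in members)
        top = [m for m in members if m.pident == best]
        out.append(top[0] if len(top) == 1 else rng.choice(top))
    return out


def filter_hits(hits: Iterable[AlignmentHit], cfg: FilterConfig) -> list[AlignmentHit]:
    """Apply the similarity band and coverage floor; order preserved."""
    out = []
    for h in hits:
        if h.pident < cfg.L_min:
            continue
        if cfg.exclude_perfect and h.pident >= 100.0:
            continue
        if query_coverage(h) < cfg.C_min:
            continue
        out.append(h)
    return out


def _has_terminal_damage(hit: AlignmentHit, X: int) -> bool:
    if hit.qaln is None:
        raise ValueError(
            f"hit {hit.qid}->{hit.sid} carries no aligned strings; "
            "realign before deamination screening"
        )
    if hit.qlen is None:
        raise ValueError(f"hit {hit.qid}->{hit.sid} has no query length")
    pos = hit.qstart
    for qc, sc in zip(hit.qaln, hit.saln):
        if qc == "-":
            continue
        if sc != "-" and (pos <= X or pos > hit.qlen - X):
            if (sc == "C" and qc == "T") or (sc == "G" and qc == "A"):
                return True
        pos += 1
    return False


def deamination_screen(hits: Iterable[AlignmentHit], X: int) -> list[AlignmentHit]:
    """Keep hits with >= 1 C→T or G→A change within X bases of either read end.

    Positions are counted over the full read (locally trimmed terminal
    bases are offset via qstart); gap columns never qualify.
    """
    if X < 1:
        raise ValueError("screening window X must be >= 1")
    return [h for h in hits if _has_terminal_damage(h, X)]


def _best_hit_per_read(hits: Sequence[AlignmentHit], seed: int) -> list[AlignmentHit]:
    groups: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        groups.setdefault(h.qid, []).append(h)
    rng = random.Random(seed ^ 0x5EED)
    out = []
    for members in groups.values():
        best = max(m.pident for m in members)
        top = [m for m in members if m.pident == best]
        out.append(top[0] if len(top) == 1 else rng.choice(top))
    return out


def species_ranking(
    hits: Sequence[AlignmentHit], taxmap: TaxonomyMap, cfg: FilterConfig
) -> SpeciesRanking:
    """Count VMH per species and build the ranked decision object.

    Every surviving hit counts once; equal VMH counts are ordered
    lexicographically by species label for determinism. R is the ratio
    of the top two PoVMH values (equivalently VMH counts), defined only
    when at least two species are present.
    """
    counts: dict[str, int] = {}
    for h in hits:
        counts[taxmap.species_of(h.sid)] = counts.get(taxmap.species_of(h.sid), 0) + 1
    total = sum(counts.values())
    if total == 0:
        return SpeciesRanking((), 0, None, UNIDENTIFIED, ("no_hits", "low_vmh"))
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    rows = tuple(
        (sp, v, 100.0 * v / total) for sp, v in ordered
    )
    R = rows[0][2] / rows[1][2] if len(rows) >= 2 else None
    flags: list[str] = []
    if total >= cfg.min_vmh:
        call = rows[0][0]
    else:
        call = UNIDENTIFIED
        flags.append("low_vmh")
    if R is not None and R < cfg.min_ratio:
        flags.append("ambiguous_ratio")
    return SpeciesRanking(rows, total, R, call, tuple(flags))


@dataclass(frozen=True)
class PipelineResult:
    """Rankings before and after the deamination screen.

    ``post`` is None when screening is disabled; ``final`` is the
    ranking the call should be read from.
    """

    pre: SpeciesRanking
    post: SpeciesRanking | None
    n_raw_hits: int
    n_dedup: int
    n_filtered: int
    n_screened: int | None

    @property
    def final(self) -> SpeciesRanking:
        return self.post if self.post is not None else self.pre


def _prepare_hits(
    hits: Sequence[AlignmentHit],
    cfg: FilterConfig,
    db_by_id: Mapping[str, SequenceRecord] | None,
    reads_by_id: Mapping[str, SequenceRecord] | None,
) -> tuple[list[AlignmentHit], list[AlignmentHit]]:
    """dedupe -> (optional best-per-read) -> filter -> optional screen."""
    deduped = dedupe_hits(hits, cfg.seed)
    if cfg.best_hit_per_read:
        deduped = _best_hit_per_read(deduped, cfg.seed)
    filtered = filter_hits(deduped, cfg)
    if cfg.X == 0:
        return filtered, []
    need_realign = [h for h in filtered if h.qaln is None]
    if need_realign:
        if db_by_id is None or reads_by_id is None:
            raise ValueError(
                "hits lack aligned strings and no reads/database were "
                "provided for realignment; cannot screen for deamination"
            )
        filtered = [
            h
            if h.qaln is not None
            else realign_hit(h, reads_by_id[h.qid], db_by_id[h.sid])
            for h in filtered
        ]
    return filtered, deamination_screen(filtered, cfg.X)


def identify_pipeline(
    reads: Sequence[SequenceRecord],
    database: Sequence[SequenceRecord],
    taxmap: TaxonomyMap,
    cfg: FilterConfig | None = None,
    aligner_cfg: AlignerConfig | None = None,
    hits: Sequence[AlignmentHit] | None = None,
) -> PipelineResult:
    """End-to-end species identification for one sample.

    When ``hits`` is given (e.g. parsed from an external BLAST m8 file)
    the internal aligner is skipped; hits lacking per-column alignment
    strings are realigned on demand if screening is enabled. With
    ``cfg.X > 0`` both the pre-screen and post-screen rankings are
    returned so the effect of the deamination screen can be inspected.
    """
    cfg = cfg or FilterConfig()
    if hits is None:
        hits = search(reads, database, aligner_cfg)
    hits = list(hits)
    db_by_id = {r.id: r for r in database}
    reads_by_id = {r.id: r for r in reads}
    filtered, screened = _prepare_hits(hits, cfg, db_by_id, reads_by_id)
    pre = species_ranking(filtered, taxmap, cfg)
    post = species_ranking(screened, taxmap, cfg) if cfg.X > 0 else None
    return PipelineResult(
        pre=pre,
        post=post,
        n_raw_hits=len(hits),
        n_dedup=len(dedupe_hits(hits, cfg.seed)),
        n_filtered=len(filtered),
        n_screened=len(screened) if cfg.X > 0 else None,
    )


def stability_analysis(
    reads: Sequence[SequenceRecord],
    database: Sequence[SequenceRecord],
    taxmap: TaxonomyMap,
    cfg: FilterConfig | None = None,
    aligner_cfg: AlignerConfig | None = None,
    depths: Sequence[int] = (100, 500, 1000, 5000, 20000),
    k: int = 5,
    reps: int = 1,
    seed: int = 0,
    hits: Sequence[AlignmentHit] | None = None,
) -> tuple[pd.DataFrame, int | None]:
    """Minimal read depth at which the top-k species ranking stabilizes.

    Reads are aligned once; each (depth, rep) evaluates the decision
    procedure on a seeded random subsample of read ids. The top-k list
    (order-sensitive) is "stable from depth d" when it is identical for
    every depth >= d and every replicate. Returns the per-subsample
    table and the smallest such depth (None if never reached).
    """
    cfg = cfg or FilterConfig()
    if list(depths) != sorted(set(depths)):
        raise ValueError("depths must be strictly ascending")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if hits is None:
        hits = search(reads, database, aligner_cfg)
    db_by_id = {r.id: r for r in database}
    reads_by_id = {r.id: r for r in reads}
    hits_by_qid: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        hits_by_qid.setdefault(h.qid, []).append(h)
    all_ids = [r.id for r in reads]
    rng = np.random.default_rng(seed)
    records = []
    usable_depths = []
    for depth in depths:
        if depth > len(all_ids):
            warnings.warn(
                f"depth {depth} exceeds the {len(all_ids)} available reads; skipped"
            )
            continue
        usable_depths.append(depth)
        for rep in range(reps):
            chosen = rng.choice(len(all_ids), size=depth, replace=False)
            sub_hits = [
                h for i in chosen for h in hits_by_qid.get(all_ids[i], ())
            ]
            filtered, screened = _prepare_hits(sub_hits, cfg, db_by_id, reads_by_id)
            ranking = species_ranking(
                screened if cfg.X > 0 else filtered, taxmap, cfg
            )
            records.append(
                {"depth": depth, "rep": rep, "top_k": ranking.top(k)}
            )
    table = pd.DataFrame(records)
    stable_depth: int | None = None
    if not table.empty:
        for d in usable_depths:
            tails = table.loc[table["depth"] >= d, "top_k"]
            if tails.nunique() == 1:
                stable_depth = d
                break
        table["stable"] = [
            stable_depth is not None and row >= stable_depth for row in table["depth"]
        ]
    return table, stable_depth


def write_report(
    result: PipelineResult,
    cfg: FilterConfig,
    path: str | Path,
    fmt: str = "tsv",
) -> None:
    """Serialize a pipeline result deterministically (byte-identical reruns)."""
    payload = {
        "parameters": asdict(cfg),
        "n_raw_hits": result.n_raw_hits,
        "n_dedup": result.n_dedup,
        "n_filtered": result.n_filtered,
        "n_screened": result.n_screened,
        "pre_screen": result.pre.to_dict(),
        "post_screen": result.post.to_dict() if result.post else None,
    }
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return
    lines = []
    for key, value in sorted(asdict(cfg).items()):
        lines.append(f"# param\t{key}\t{value}")
    lines.append(
        f"# counts\traw={result.n_raw_hits}\tdedup={result.n_dedup}"
        f"\tfiltered={result.n_filtered}\tscreened={result.n_screened}"
    )
    for label, ranking in (("pre_screen", result.pre), ("post_screen", result.post)):
        if ranking is None:
            continue
        r_str = f"{ranking.R:.6f}" if ranking.R is not None else "NA"
        lines.append(
            f"# {label}\tcall={ranking.call}\ttotal_vmh={ranking.total_vmh}"
            f"\tR={r_str}\tflags={','.join(ranking.flags) or '.'}"
        )
    lines.append("section\trank\tspecies\tvmh\tpovmh")
    for label, ranking in (("pre_screen", result.pre), ("post_screen", result.post)):
        if ranking is None:
            continue
        for i, (sp, v, p) in enumerate(ranking.rows):
            lines.append(f"{label}\t{i + 1}\t{sp}\t{v}\t{p:.4f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
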