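"""Exhaustive local alignment of spacers against genomes.

Implements Smith-Waterman dynamic programming with the NUC44-style scheme
(match +5, mismatch -4, linear gap -8 per gapped position) and
Waterman-Eggert declumping: after each optimal local alignment is reported
its subject interval is masked and the DP is recomputed, yielding the k best
non-overlapping hits per strand. Hits from the two strands are merged by
descending score and the trivial self-alignment at the CRISPR locus is
excluded, leaving the per-spacer target list every downstream stage consumes.

The DP kernels are numba-compiled; coordinates in reported hits are always
on the direct strand, 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .genome_io import CRISPRArray, Genome, Spacer, reverse_complement

log = logging.getLogger(__name__)

_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to codes 0..3 (ACGT); ambiguity codes -> 4,
    which mismatch everything including themselves."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    """Local-alignment scoring: NUC44 ACGT values with a linear gap penalty.

    ``gap`` is the positive per-gapped-position cost (applied as -gap).
    """

    match: int = 5
    mismatch: int = -4
    gap: int = 8

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0 or self.gap <= 0:
            raise ValueError("require match > 0, mismatch < 0, gap > 0")


@dataclass(frozen=True)
class Alignment:
    """A single local alignment in subject/query coordinates (both 0-based
    half-open, subject as given to the call)."""

    score: int
    s_start: int
    s_end: int
    q_start: int
    q_end: int
    aligned_query: str = ""
    aligned_subject: str = ""


@dataclass
class Hit:
    """A scored spacer alignment on a genome, direct-strand coordinates.

    ``q_start``/``q_end`` are in spacer orientation; ``theoretical_start`` is
    the actual alignment start extended upstream by the spacer's unaligned
    prefix (q_start) and anchors all PAM windows.
    """

    spacer_id: str
    genome_id: str
    strand: str  # 'direct' | 'reverse'
    g_start: int
    g_end: int
    score: int
    q_start: int
    q_end: int
    rank: int | None = None
    theoretical_start: int | None = None
    edge_truncated: bool = False


# ---------------------------------------------------------------------------
# DP kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fill(q, s, match, mismatch, gap, masked, H):  # pragma: no cover - jit
    n = q.size
    m = s.size
    best = 0
    bi = 0
    bj = 0
    for j in range(1, m + 1):
        if masked[j - 1]:
            for i in range(1, n + 1):
                H[i, j] = 0
            continue
        sj = s[j - 1]
        for i in range(1, n + 1):
            qi = q[i - 1]
            sub = match if (qi == sj and qi < 4) else mismatch
            v = H[i - 1, j - 1] + sub
            t = H[i - 1, j] - gap
            if t > v:
                v = t
            t = H[i, j - 1] - gap
            if t > v:
                v = t
            if v < 0:
                v = 0
            H[i, j] = v
            # strict > with j-outer/i-inner scan -> ties resolve to the
            # smallest subject end, then the smallest query end
            if v > best:
                best = v
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def _trace_start(H, q, s, match, mismatch, gap, bi, bj):  # pragma: no cover
    i = bi
    j = bj
    while H[i, j] > 0:
        sub = match if (q[i - 1] == s[j - 1] and q[i - 1] < 4) else mismatch
        if H[i, j] == H[i - 1, j - 1] + sub:
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] - gap:
            i -= 1
        else:
            j -= 1
    return i, j


@njit(cache=True)
def _kbest(q, s, match, mismatch, gap, k, masked):  # pragma: no cover - jit
    n = q.size
    m = s.size
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    out = np.zeros((k, 5), dtype=np.int64)
    cnt = 0
    for _ in range(k):
        best, bi, bj = _fill(q, s, match, mismatch, gap, masked, H)
        if best <= 0:
            break
        i0, j0 = _trace_start(H, q, s, match, mismatch, gap, bi, bj)
        out[cnt, 0] = best
        out[cnt, 1] = j0
        out[cnt, 2] = bj
        out[cnt, 3] = i0
        out[cnt, 4] = bi
        cnt += 1
        for jj in range(j0, bj):
            masked[jj] = True
    return out[:cnt]


def _mask_array(length: int, intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    masked = np.zeros(length, dtype=np.bool_)
    for a, b in intervals:
        masked[max(0, a):max(0, b)] = True
    return masked


# ---------------------------------------------------------------------------
# Public alignment operations
# ---------------------------------------------------------------------------

def smith_waterman(query: str, subject: str,
                   scoring: ScoringScheme = ScoringScheme()) -> Alignment:
    """Optimal local alignment of two sequences.

    Traceback ties prefer diagonal over up (query gap consumed) over left;
    among equal-score cells the earliest subject end, then query end, wins.
    A pair with no positive-scoring alignment yields score 0 and empty
    intervals.
    """
    if not query or not subject:
        raise ValueError("query and subject must be non-empty")
    q = encode(query.upper())
    s = encode(subject.upper())
    H = np.zeros((q.size + 1, s.size + 1), dtype=np.int32)
    masked = np.zeros(s.size, dtype=np.bool_)
    best, bi, bj = _fill(q, s, scoring.match, scoring.mismatch, scoring.gap,
                         masked, H)
    if best <= 0:
        return Alignment(0, 0, 0, 0, 0)
    # python traceback mirroring _trace_start, recording the aligned strings
    i, j = int(bi), int(bj)
    aq: list[str] = []
    asub: list[str] = []
    while H[i, j] > 0:
        sub = scoring.match if (q[i - 1] == s[j - 1] and q[i - 1] < 4) \
            else scoring.mismatch
        if H[i, j] == H[i - 1, j - 1] + sub:
            aq.append(query[i - 1])
            asub.append(subject[j - 1])
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] - scoring.gap:
            aq.append(query[i - 1])
            asub.append("-")
            i -= 1
        else:
            aq.append("-")
            asub.append(subject[j - 1])
            j -= 1
    return Alignment(int(best), j, int(bj), i, int(bi),
                     "".join(reversed(aq)), "".join(reversed(asub)))


def k_best_alignments(query: str, subject: str, k: int = 10,
                      scoring: ScoringScheme = ScoringScheme(),
                      masked_intervals: Sequence[tuple[int, int]] = ()
                      ) -> list[Alignment]:
    """Waterman-Eggert style k best non-overlapping local alignments.

    Each reported alignment's subject interval is masked before the next
    round (query positions may be reused); fewer than k positive-score
    alignments yield a shorter list. ``masked_intervals`` (subject
    coordinates) are excluded from the search entirely.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not query or not subject:
        raise ValueError("query and subject must be non-empty")
    q = encode(query.upper())
    s = encode(subject.upper())
    masked = _mask_array(s.size, masked_intervals)
    raw = _kbest(q, s, scoring.match, scoring.mismatch, scoring.gap,
                 int(k), masked)
    return [Alignment(int(r[0]), int(r[1]), int(r[2]), int(r[3]), int(r[4]))
            for r in raw]


def top_k_hits(spacer: Spacer, genome: Genome, strand: str, k: int = 10,
               scoring: ScoringScheme = ScoringScheme(),
               masked_intervals: Sequence[tuple[int, int]] = ()
               ) -> list[Hit]:
    """k best non-overlapping hits of one spacer on one genome strand.

    Reverse-strand alignments are computed against the reverse complement
    and mapped back onto direct-strand coordinates. ``masked_intervals`` are
    given in direct-strand coordinates regardless of strand.
    """
    if strand not in ("direct", "reverse"):
        raise ValueError("strand must be 'direct' or 'reverse'")
    L = len(genome)
    if strand == "direct":
        subject = genome.sequence
        mask = masked_intervals
    else:
        subject = reverse_complement(genome.sequence)
        mask = [(L - b, L - a) for a, b in masked_intervals]
    alns = k_best_alignments(spacer.sequence, subject, k=k, scoring=scoring,
                             masked_intervals=mask)
    hits = []
    for a in alns:
        if strand == "direct":
            g_start, g_end = a.s_start, a.s_end
        else:
            g_start, g_end = L - a.s_end, L - a.s_start
        hits.append(Hit(spacer_id=spacer.spacer_id, genome_id=genome.id,
                        strand=strand, g_start=g_start, g_end=g_end,
                        score=a.score, q_start=a.q_start, q_end=a.q_end))
    return hits


def merge_and_rank(direct_hits: Sequence[Hit], reverse_hits: Sequence[Hit]
                   ) -> list[Hit]:
    """Merge per-strand hit lists into one list ranked by descending score.

    Ties: direct strand first, then lower direct-strand start. Ranks are
    assigned 1..m on the merged list.
    """
    merged = sorted(list(direct_hits) + list(reverse_hits),
                    key=lambda h: (-h.score, h.strand != "direct", h.g_start))
    for rank, h in enumerate(merged, start=1):
        h.rank = rank
    return merged


def exclude_self_hit(hits: Sequence[Hit], array: CRISPRArray) -> list[Hit]:
    """Drop every hit overlapping the CRISPR array interval and re-rank.

    The trivial hit is the spacer's own self-alignment, which on a host
    genome always ranks first; a warning is logged if no removed hit held
    rank 1.
    """
    overlaps = lambda h: (h.g_start < array.array_end
                          and h.g_end > array.array_start)  # noqa: E731
    removed = [h for h in hits if overlaps(h)]
    kept = [h for h in hits if not overlaps(h)]
    if removed and not any(h.rank == 1 for h in removed):
        log.warning("self-hit exclusion removed %d hit(s) but none ranked 1",
                    len(removed))
    for rank, h in enumerate(kept, start=1):
        h.rank = rank
    return kept


def theoretical_start(hit: Hit, genome_length: int,
                      circular: bool = False) -> Hit:
    """Annotate a hit with its theoretical alignment start.

    The theoretical start extends the actual start upstream by the spacer's
    unaligned prefix length (q_start). Upstream is decreasing direct-strand
    coordinate for a direct hit and increasing for a reverse hit. On a
    linear genome a start falling outside [0, L) flags the hit
    edge-truncated (excluded from PAM analysis); on a circular genome the
    coordinate wraps.
    """
    if hit.strand == "direct":
        t = hit.g_start - hit.q_start
    else:
        t = (hit.g_end - 1) + hit.q_start
    if 0 <= t < genome_length:
        hit.theoretical_start = t
        hit.edge_truncated = False
    elif circular:
        hit.theoretical_start = t % genome_length
        hit.edge_truncated = False
    else:
        hit.theoretical_start = t
        hit.edge_truncated = True
    return hit


# ---------------------------------------------------------------------------
# Per-spacer scan
# ---------------------------------------------------------------------------

def scan_spacer(spacer: Spacer, genome: Genome, *, k: int = 10,
                scoring: ScoringScheme = ScoringScheme(),
                array: CRISPRArray | None = None) -> tuple[list[Hit], list[Hit]]:
    """Scan both strands of a genome with one spacer.

    When ``array`` is given (host genome), the CRISPR locus is masked out of
    the declumping search so trivial repeat/array alignments never consume
    report slots; only the spacer's own window on the array's strand stays
    open, so the self-alignment is still reported (it validates the
    rank-1-self observation) and then removed by exclude_self_hit.

    Returns (retained, merged): the post-exclusion target list and the full
    ranked list including the self-hit.
    """
    mask_direct: list[tuple[int, int]] = []
    mask_reverse: list[tuple[int, int]] = []
    if array is not None:
        full = [(array.array_start, array.array_end)]
        sp = next((s for s in array.spacers if s.spacer_id == spacer.spacer_id),
                  None)
        if sp is not None and sp.start >= 0:
            carved = [(array.array_start, sp.start), (sp.end, array.array_end)]
            carved = [(a, b) for a, b in carved if b > a]
        else:
            carved = full
        self_strand = "direct" if array.strand == "+" else "reverse"
        mask_direct = carved if self_strand == "direct" else full
        mask_reverse = carved if self_strand == "reverse" else full

    direct = top_k_hits(spacer, genome, "direct", k=k, scoring=scoring,
                        masked_intervals=mask_direct)
    reverse = top_k_hits(spacer, genome, "reverse", k=k, scoring=scoring,
                         masked_intervals=mask_reverse)
    merged = merge_and_rank(direct, reverse)
    for h in merged:
        theoretical_start(h, len(genome), genome.circular)
    retained = exclude_self_hit(merged, array) if array is not None else merged
    return retained, merged


def scan_genome(spacers: Sequence[Spacer], genome: Genome, *, k: int = 10,
                scoring: ScoringScheme = ScoringScheme(),
                array: CRISPRArray | None = None) -> dict[str, list[Hit]]:
    """Retained ranked hits for every spacer against one genome."""
    out: dict[str, list[Hit]] = {}
    for sp in spacers:
        retained, _ = scan_spacer(sp, genome, k=k, scoring=scoring, array=array)
        out[sp.spacer_id] = retained
    return out
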