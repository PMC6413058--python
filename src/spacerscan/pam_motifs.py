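"""PAM-position 3-mer counting and overrepresentation calls.

Every retained hit anchors three flanking contexts at its theoretical
alignment start: the 3 nt immediately upstream (the putative PAM position),
the 6 nt immediately upstream, and the segment between the theoretical and
actual alignment starts (length q_start, empty for full-prefix alignments).
All contexts are read on the targeted strand - the reverse complement of
the hit strand, since the crRNA-guided complex base-pairs with the
complement of the reported protospacer - and reported 3'->5' by default
(switchable to 5'->3').

Counts over the 64 possible triplets on the real genome are compared with
Poisson fits to the same counts on the randomized replicates: the per-motif
rate is the mean replicate count, the bounds are central Poisson quantiles
(default 99.7%, the two-sided 3-sigma analogue), and the p-value is the
paired t-test of the real count against the replicate counts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .aligner import Hit
from .genome_io import Genome, reverse_complement

log = logging.getLogger(__name__)

ALL_TRIPLETS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product("ACGT", repeat=3))

CONTEXTS = ("adjacent3", "upstream6", "gap_segment")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class MotifTable:
    context: str
    counts: dict[str, int]  # all 64 triplets, always
    n_hits: int  # hits contributing at least one window


@dataclass
class MotifCall:
    motif: str
    observed: int
    lam: float  # Poisson mean over replicates
    lower: float
    upper: float
    status: str  # 'over' | 'under' | 'ns'
    p_value: float | None


@dataclass
class PamWheelRow:
    motif: str
    relative_abundance: float  # count / sum of over-motif counts
    literal_score: float  # (count - total) / total, emitted verbatim
    count_fraction: float  # the presumable intent: count / total over counts
    in_reference: bool | None


# ---------------------------------------------------------------------------
# Context extraction
# ---------------------------------------------------------------------------

def _genome_window(genome: Genome, a: int, b: int) -> str | None:
    """Direct-strand bases [a, b); wraps on circular genomes, None if the
    window leaves a linear genome."""
    L = len(genome)
    if 0 <= a and b <= L:
        return genome.sequence[a:b]
    if not genome.circular:
        return None
    return "".join(genome.sequence[i % L] for i in range(a, b))


def _on_targeted_strand(window: str, hit_strand: str, orientation: str) -> str:
    """Re-orient a direct-strand window onto the targeted strand.

    For a direct hit the targeted strand is the reverse strand
    (5'->3' = revcomp of the window); for a reverse hit it is the direct
    strand (5'->3' = the window itself). 3'->5' reporting reverses the
    5'->3' string.
    """
    if hit_strand == "direct":
        five_to_three = reverse_complement(window)
    else:
        five_to_three = window
    return five_to_three[::-1] if orientation == "3to5" else five_to_three


def extract_context(hit: Hit, genome: Genome, kind: str,
                    orientation: str = "3to5") -> str | None:
    """Flanking sequence of one hit on the targeted strand, or None when the
    window leaves a linear genome (context-skip) or the hit is
    edge-truncated."""
    if kind not in CONTEXTS:
        raise ValueError(f"unknown context kind {kind!r}")
    if orientation not in ("3to5", "5to3"):
        raise ValueError("orientation must be '3to5' or '5to3'")
    if hit.theoretical_start is None:
        raise ValueError("hit lacks theoretical_start; run theoretical_start()")
    if hit.edge_truncated:
        return None
    t = hit.theoretical_start
    width = {"adjacent3": 3, "upstream6": 6}.get(kind)
    if hit.strand == "direct":
        if kind == "gap_segment":
            a, b = t, hit.g_start
        else:
            a, b = t - width, t
    else:
        if kind == "gap_segment":
            a, b = hit.g_end, t + 1
        else:
            a, b = t + 1, t + 1 + width
    if b <= a:  # zero-length gap segment (q_start == 0)
        return ""
    window = _genome_window(genome, a, b)
    if window is None:
        return None
    return _on_targeted_strand(window, hit.strand, orientation)


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def count_motifs(contexts: Iterable[str | None], kind: str) -> MotifTable:
    """Triplet counts over extracted contexts.

    adjacent3 contributes one count per context; upstream6 and gap_segment
    count every overlapping 3-mer window. Windows containing non-ACGT
    letters are skipped; a context is counted in n_hits when it contributes
    at least one window.
    """
    if kind not in CONTEXTS:
        raise ValueError(f"unknown context kind {kind!r}")
    counts = dict.fromkeys(ALL_TRIPLETS, 0)
    n_hits = 0
    for ctx in contexts:
        if ctx is None:
            continue
        contributed = False
        windows = [ctx] if kind == "adjacent3" else \
            [ctx[i:i + 3] for i in range(len(ctx) - 2)]
        for w in windows:
            if len(w) == 3 and w in counts:
                counts[w] += 1
                contributed = True
        if contributed:
            n_hits += 1
    return MotifTable(context=kind, counts=counts, n_hits=n_hits)


def motif_table(hits: Sequence[Hit], genome: Genome, kind: str,
                orientation: str = "3to5") -> MotifTable:
    """Extract + count in one step for a hit list on one genome."""
    return count_motifs(
        (extract_context(h, genome, kind, orientation) for h in hits), kind)


# ---------------------------------------------------------------------------
# Over/underrepresentation
# ---------------------------------------------------------------------------

def motif_calls(real: MotifTable, replicates: Sequence[MotifTable],
                level: float = 0.997) -> list[MotifCall]:
    """Poisson-bound over/underrepresentation of each motif vs background.

    lambda = mean replicate count; bounds = central Poisson quantiles at
    ``level``. The p-value is a paired t-test of the single real count
    against the n replicate counts, which reduces to (and is computed as)
    a one-sample t-test of the replicate-minus-real differences.
    """
    if len(replicates) < 2:
        raise ValueError("need >= 2 replicate tables")
    if any(r.context != real.context for r in replicates):
        raise ValueError("replicate tables come from a different context")
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    calls = []
    for motif in ALL_TRIPLETS:
        obs = real.counts[motif]
        reps = np.array([r.counts[motif] for r in replicates], dtype=float)
        lam = float(reps.mean())
        lower = float(stats.poisson.ppf(lo_q, lam)) if lam > 0 else 0.0
        upper = float(stats.poisson.ppf(hi_q, lam)) if lam > 0 else 0.0
        if lam == 0 and obs == 0:
            status = "ns"
        elif obs > upper:
            status = "over"
        elif obs < lower:
            status = "under"
        else:
            status = "ns"
        diffs = reps - obs
        if np.allclose(diffs.std(ddof=1), 0.0):
            p = 1.0 if np.allclose(diffs, 0.0) else 0.0
        else:
            p = float(stats.ttest_1samp(diffs, 0.0).pvalue)
        calls.append(MotifCall(motif=motif, observed=obs, lam=lam,
                               lower=lower, upper=upper, status=status,
                               p_value=p))
    return calls


def pam_overlap(calls: Sequence[MotifCall],
                reference_pams: set[str]) -> float | None:
    """Percentage of overrepresented motifs present in an experimentally
    confirmed interference-PAM list; None when nothing is overrepresented."""
    if not reference_pams:
        raise ValueError("reference PAM set is empty")
    over = {c.motif for c in calls if c.status == "over"}
    if not over:
        return None
    return 100.0 * len(over & reference_pams) / len(over)


def load_pam_reference(path) -> tuple[set[str], str]:
    """Read a plain-text PAM list: optional '# orientation: <3to5|5to3>'
    header, then one triplet per line."""
    orientation = "3to5"
    motifs: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "orientation" in line:
                    orientation = line.split(":")[-1].strip()
                continue
            motif = line.upper()
            if len(motif) != 3 or any(b not in "ACGT" for b in motif):
                raise ValueError(f"bad PAM reference entry {line!r}")
            motifs.add(motif)
    return motifs, orientation


def pam_wheel(real: MotifTable, calls: Sequence[MotifCall],
              reference_pams: set[str] | None = None) -> list[PamWheelRow]:
    """Relative abundances of the overrepresented motifs.

    ``literal_score`` emits (count - total) / total verbatim, a legacy
    abundance formula that is negative for every motif and is reported
    unchanged rather than silently corrected; ``count_fraction`` is the
    count-fraction reading of the same quantity. Relative abundances sum
    to 1.
    """
    over = [c.motif for c in calls if c.status == "over"]
    if not over:
        raise ValueError("no overrepresented motifs to tabulate")
    total = sum(real.counts[m] for m in over)
    rows = []
    for m in sorted(over, key=lambda m: -real.counts[m]):
        count = real.counts[m]
        rows.append(PamWheelRow(
            motif=m,
            relative_abundance=count / total if total else 0.0,
            literal_score=(count - total) / total if total else 0.0,
            count_fraction=count / total if total else 0.0,
            in_reference=(m in reference_pams) if reference_pams else None))
    return rows
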