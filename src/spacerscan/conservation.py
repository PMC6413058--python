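"""Post-processing of homology-search results for spacers and targets.

Search execution is out of process: the module consumes standard 12-column
tabular output (blastn -outfmt 6) plus a local FASTA of subject sequences.
It applies the strict E < 1e-3 filter, decides whether a subject hit sits
inside a CRISPR array by locally aligning 40 nt flanks against the repeat
(cutoff score 25), and compares per-spacer vs per-target hit-count
distributions with Poisson three-sigma intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import aligner
from .genome_io import reverse_complement

log = logging.getLogger(__name__)

OUTFMT6_COLUMNS = ("qseqid", "sseqid", "pident", "length", "mismatch",
                   "gapopen", "qstart", "qend", "sstart", "send", "evalue",
                   "bitscore")


@dataclass
class ArrayContextCall:
    query_id: str
    subject_id: str
    upstream_score: int
    downstream_score: int
    in_array: bool
    upstream_truncated: bool = False
    downstream_truncated: bool = False
    resolved: bool = True


def read_search_table(path: str | Path) -> pd.DataFrame:
    """Read blastn -outfmt 6 tabular output; malformed rows are dropped with
    a warning."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=OUTFMT6_COLUMNS)
    for col in ("evalue", "bitscore", "pident"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("qstart", "qend", "sstart", "send", "length"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[["evalue", "sstart", "send"]].isna().any(axis=1)
    if bad.any():
        log.warning("dropping %d malformed search record(s)", int(bad.sum()))
    return df[~bad].reset_index(drop=True)


def filter_records(records: pd.DataFrame, e_max: float = 1e-3) -> pd.DataFrame:
    """Strict E-value filter: records with evalue < e_max are kept."""
    return records[records["evalue"] < e_max].reset_index(drop=True)


def array_context(record: Mapping, subject_seqs: Mapping[str, str],
                  repeat_seq: str, flank_len: int = 40, cutoff: int = 25,
                  scoring: aligner.ScoringScheme | None = None
                  ) -> ArrayContextCall:
    """Classify one search hit as lying inside a CRISPR array.

    The subject interval's flanks (``flank_len`` bases each side, in query
    orientation: minus-strand hits have their flanks reverse-complemented
    and swapped) are locally aligned against the repeat; the hit is
    in-array iff both flank scores reach ``cutoff``. Flanks shorter than
    ``flank_len`` are used as-is and flagged truncated. Subjects absent
    from ``subject_seqs`` yield an unresolved call, excluded from tallies.
    """
    scoring = scoring or aligner.ScoringScheme()
    qid, sid = str(record["qseqid"]), str(record["sseqid"])
    subject = subject_seqs.get(sid)
    if subject is None:
        return ArrayContextCall(qid, sid, 0, 0, False, resolved=False)
    sstart, send = int(record["sstart"]), int(record["send"])
    minus = sstart > send
    lo, hi = (send, sstart) if minus else (sstart, send)
    lo -= 1  # 1-based inclusive -> 0-based half-open
    left = subject[max(0, lo - flank_len):lo]
    right = subject[hi:hi + flank_len]
    if minus:
        upstream, downstream = reverse_complement(right), reverse_complement(left)
    else:
        upstream, downstream = left, right
    up_score = aligner.smith_waterman(upstream, repeat_seq, scoring).score \
        if upstream else 0
    down_score = aligner.smith_waterman(downstream, repeat_seq, scoring).score \
        if downstream else 0
    return ArrayContextCall(
        qid, sid, up_score, down_score,
        in_array=(up_score >= cutoff and down_score >= cutoff),
        upstream_truncated=len(upstream) < flank_len,
        downstream_truncated=len(downstream) < flank_len)


def flank_score_distribution(repeat_seq: str, n: int = 2000,
                             flank_len: int = 40, seed: int = 0,
                             scoring: aligner.ScoringScheme | None = None
                             ) -> np.ndarray:
    """Scores of random flanks against a repeat - the empirical distribution
    whose rapid fall-off below ~25 motivates the cutoff; emitted for
    inspection."""
    scoring = scoring or aligner.ScoringScheme()
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = np.empty(n, dtype=int)
    for i in range(n):
        flank = rng.choice(bases, size=flank_len).tobytes().decode()
        out[i] = aligner.smith_waterman(flank, repeat_seq, scoring).score
    return out


def distribution_compare(spacer_hit_counts: Sequence[int],
                         target_hit_counts) -> dict:
    """Compare spacer vs target phylogenetic hit-count distributions.

    Spacer side: total count summed over spacers, with a Poisson
    three-sigma interval total +/- 3*sqrt(total). Target side: per-target
    sums over spacers, averaged over targets, with the analogous interval
    on the mean. Verdict: separated iff the intervals are disjoint.
    """
    spacer_hit_counts = np.asarray(spacer_hit_counts, dtype=float)
    targets = np.atleast_2d(np.asarray(target_hit_counts, dtype=float))
    if spacer_hit_counts.size == 0 or targets.size == 0:
        raise ValueError("empty count input")
    s_total = float(spacer_hit_counts.sum())
    s_half = 3.0 * np.sqrt(s_total)
    per_target = targets.sum(axis=0)  # sum over spacers for each target
    t_mean = float(per_target.mean())
    t_half = 3.0 * np.sqrt(t_mean)
    s_lo, s_hi = s_total - s_half, s_total + s_half
    t_lo, t_hi = t_mean - t_half, t_mean + t_half
    return {
        "spacer_total": s_total, "spacer_interval": (s_lo, s_hi),
        "target_mean": t_mean, "target_interval": (t_lo, t_hi),
        "separated": bool(s_hi < t_lo or t_hi < s_lo),
    }
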