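"""Alignment core: Smith-Waterman, declumping, strand mapping, ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import _oracle
from spacerscan.aligner import (Alignment, Hit, ScoringScheme,
                                exclude_self_hit, k_best_alignments,
                                merge_and_rank, smith_waterman,
                                theoretical_start, top_k_hits)
from spacerscan.genome_io import CRISPRArray, Genome, Spacer, reverse_complement

BASES = "ACGT"


def _rand_seq(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


# ---------------------------------------------------------------------------
# smith_waterman
# ---------------------------------------------------------------------------

def test_self_alignment_scores_match_times_length():
    rng = np.random.default_rng(0)
    seq = _rand_seq(rng, 32)
    a = smith_waterman(seq, seq)
    assert a.score == 5 * 32
    assert (a.s_start, a.s_end, a.q_start, a.q_end) == (0, 32, 0, 32)
    assert a.aligned_query == a.aligned_subject == seq


def test_planted_substring_is_found_at_its_position():
    rng = np.random.default_rng(1)
    query = _rand_seq(rng, 24)
    subject = _rand_seq(rng, 200) + query + _rand_seq(rng, 276)
    a = smith_waterman(query, subject)
    assert a.score == 5 * 24
    assert (a.s_start, a.s_end) == (200, 224)


def test_single_mismatch_costs_nine_when_interior():
    query = "ACGTACGTACGT"
    subject = "ACGTAGGTACGT"  # C->G at position 5 (interior)
    a = smith_waterman(query, subject)
    assert a.score == 5 * 11 - 4  # 5*12 - 9


def test_gap_penalty_is_linear_per_position():
    # query = subject with 2 bases deleted: full-span alignment pays 2*gap
    subject = "ACGTACGTACGTACGTACGT"
    query = subject[:10] + subject[12:]
    a = smith_waterman(query, subject)
    assert a.score == 5 * 18 - 2 * 8


def test_disjoint_alphabets_score_zero():
    a = smith_waterman("AAAA", "CCCC")
    assert a.score == 0
    assert a.s_start == a.s_end == 0


def test_ambiguity_codes_mismatch_everything_including_themselves():
    assert smith_waterman("NNNN", "NNNN").score == 0
    # an N inside an otherwise exact match counts as a mismatch
    assert smith_waterman("ACGNACG", "ACGTACG").score == 5 * 6 - 4


def test_empty_inputs_are_rejected():
    with pytest.raises(ValueError):
        smith_waterman("", "ACGT")
    with pytest.raises(ValueError):
        smith_waterman("ACGT", "")


def test_scoring_scheme_validation():
    with pytest.raises(ValueError):
        ScoringScheme(match=0)
    with pytest.raises(ValueError):
        ScoringScheme(mismatch=1)
    with pytest.raises(ValueError):
        ScoringScheme(gap=0)


# ---------------------------------------------------------------------------
# k-best declumping
# ---------------------------------------------------------------------------

def test_two_identical_plants_are_both_reported_smallest_end_first():
    rng = np.random.default_rng(2)
    query = _rand_seq(rng, 20)
    subject = ("T" * 50) + query + ("T" * 50) + query + ("T" * 50)
    # guard against the filler interacting with the query
    assert "T" * 6 not in query
    alns = k_best_alignments(query, subject, k=2)
    assert [a.score for a in alns] == [100, 100]
    assert (alns[0].s_start, alns[0].s_end) == (50, 70)
    assert (alns[1].s_start, alns[1].s_end) == (120, 140)


def test_k_one_reproduces_single_best_alignment():
    rng = np.random.default_rng(3)
    query = _rand_seq(rng, 25)
    subject = _rand_seq(rng, 400)
    best = smith_waterman(query, subject)
    (only,) = k_best_alignments(query, subject, k=1)
    assert (only.score, only.s_start, only.s_end, only.q_start, only.q_end) \
        == (best.score, best.s_start, best.s_end, best.q_start, best.q_end)


def test_reported_subject_intervals_never_overlap():
    rng = np.random.default_rng(4)
    query = _rand_seq(rng, 30)
    subject = _rand_seq(rng, 500)
    alns = k_best_alignments(query, subject, k=10)
    ivals = sorted((a.s_start, a.s_end) for a in alns)
    for (a0, b0), (a1, b1) in zip(ivals, ivals[1:]):
        assert b0 <= a1


def test_scores_are_non_increasing():
    rng = np.random.default_rng(5)
    alns = k_best_alignments(_rand_seq(rng, 30), _rand_seq(rng, 500), k=10)
    scores = [a.score for a in alns]
    assert scores == sorted(scores, reverse=True)


def test_masked_interval_hides_the_best_plant():
    rng = np.random.default_rng(6)
    query = _rand_seq(rng, 20)
    subject = _rand_seq(rng, 100) + query + _rand_seq(rng, 100)
    (best,) = k_best_alignments(query, subject, k=1)
    assert best.s_start == 100
    (masked_best,) = k_best_alignments(query, subject, k=1,
                                       masked_intervals=[(100, 120)])
    assert masked_best.score < 100
    assert masked_best.s_end <= 100 or masked_best.s_start >= 120


def test_k_best_rejects_bad_k():
    with pytest.raises(ValueError):
        k_best_alignments("ACGT", "ACGT", k=0)


@settings(deadline=None, max_examples=60)
@given(st.data())
def test_k_best_matches_independent_oracle(data):
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    qlen = data.draw(st.integers(5, 30))
    slen = data.draw(st.integers(20, 200))
    query = _rand_seq(rng, qlen)
    subject = _rand_seq(rng, slen)
    got = [(a.score, a.s_start, a.s_end, a.q_start, a.q_end)
           for a in k_best_alignments(query, subject, k=5)]
    assert got == _oracle.k_best(query, subject, k=5)


# ---------------------------------------------------------------------------
# strand mapping
# ---------------------------------------------------------------------------

def test_reverse_strand_plant_maps_back_to_direct_coordinates():
    rng = np.random.default_rng(7)
    query = _rand_seq(rng, 24)
    filler_l, filler_r = _rand_seq(rng, 150), _rand_seq(rng, 150)
    genome = Genome("g", filler_l + reverse_complement(query) + filler_r)
    sp = Spacer("S1", query)
    hits = top_k_hits(sp, genome, "reverse", k=1)
    h = hits[0]
    assert h.strand == "reverse"
    assert h.score == 5 * 24
    assert (h.g_start, h.g_end) == (150, 174)


def test_direct_and_reverse_scans_see_mirror_images():
    rng = np.random.default_rng(8)
    query = _rand_seq(rng, 28)
    genome = Genome("g", _rand_seq(rng, 600))
    mirror = Genome("g2", reverse_complement(genome.sequence))
    sp = Spacer("S", query)
    fwd = top_k_hits(sp, genome, "direct", k=8)
    rev = top_k_hits(sp, mirror, "reverse", k=8)
    assert [h.score for h in fwd] == [h.score for h in rev]
    L = len(genome)
    assert [(h.g_start, h.g_end) for h in fwd] == \
        [(L - h.g_end, L - h.g_start) for h in rev]


def test_masked_intervals_are_direct_strand_on_both_strands():
    rng = np.random.default_rng(9)
    query = _rand_seq(rng, 20)
    genome = Genome("g", _rand_seq(rng, 100)
                    + reverse_complement(query) + _rand_seq(rng, 100))
    sp = Spacer("S", query)
    (h,) = top_k_hits(sp, genome, "reverse", k=1)
    assert (h.g_start, h.g_end) == (100, 120)
    (h2,) = top_k_hits(sp, genome, "reverse", k=1,
                       masked_intervals=[(100, 120)])
    assert h2.score < 100


# ---------------------------------------------------------------------------
# merge / rank / self-hit exclusion
# ---------------------------------------------------------------------------

def _hit(strand, g_start, score, sid="S1"):
    return Hit(spacer_id=sid, genome_id="g", strand=strand, g_start=g_start,
               g_end=g_start + 10, score=score, q_start=0, q_end=10)


def test_merge_ranks_by_score_then_direct_then_position():
    d = [_hit("direct", 500, 90), _hit("direct", 100, 80)]
    r = [_hit("reverse", 50, 90), _hit("reverse", 10, 95)]
    merged = merge_and_rank(d, r)
    assert [(h.score, h.strand, h.g_start) for h in merged] == [
        (95, "reverse", 10),
        (90, "direct", 500),   # tie at 90: direct before reverse
        (90, "reverse", 50),
        (80, "direct", 100)]
    assert [h.rank for h in merged] == [1, 2, 3, 4]


def test_equal_score_same_strand_orders_by_genome_start():
    merged = merge_and_rank([_hit("direct", 300, 70), _hit("direct", 20, 70)],
                            [])
    assert [h.g_start for h in merged] == [20, 300]


def test_self_hit_exclusion_drops_array_overlaps_and_reranks():
    arr = CRISPRArray(array_start=1000, array_end=1500, repeat_seq="A" * 28,
                      spacers=[])
    hits = merge_and_rank(
        [_hit("direct", 1200, 160), _hit("direct", 10, 80),
         _hit("direct", 990, 60)],  # overlaps [1000,1500) by its last 10 nt? no: [990,1000) touches only
        [_hit("reverse", 1495, 70)])
    kept = exclude_self_hit(hits, arr)
    # [1200,1210) and [1495,1505) overlap the array; [990,1000) only touches
    assert [(h.g_start, h.rank) for h in kept] == [(10, 1), (990, 2)]


# ---------------------------------------------------------------------------
# theoretical start
# ---------------------------------------------------------------------------

def test_theoretical_start_extends_direct_hits_leftwards():
    h = _hit("direct", 50, 40)
    h.q_start = 3
    theoretical_start(h, 1000)
    assert h.theoretical_start == 47 and not h.edge_truncated


def test_theoretical_start_extends_reverse_hits_rightwards():
    h = _hit("reverse", 50, 40)
    h.q_start = 3
    theoretical_start(h, 1000)
    assert h.theoretical_start == (h.g_end - 1) + 3 and not h.edge_truncated


def test_theoretical_start_flags_linear_edge_truncation():
    h = _hit("direct", 1, 40)
    h.q_start = 5
    theoretical_start(h, 1000, circular=False)
    assert h.edge_truncated and h.theoretical_start == -4


def test_theoretical_start_wraps_on_circular_genomes():
    h = _hit("direct", 1, 40)
    h.q_start = 5
    theoretical_start(h, 1000, circular=True)
    assert not h.edge_truncated and h.theoretical_start == 996
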