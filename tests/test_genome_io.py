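"""Genome/annotation readers, the coding/intergenic partition, array parsing."""

import numpy as np
import pytest
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from spacerscan.genome_io import (ArrayParseError, CoordinateError,
                                  CRISPRArray, GeneFeature, Genome,
                                  GenomeFormatError, IntergenicRegion,
                                  RegionIndex, Spacer, classify_intergenic,
                                  lift_array_to_genome, merge_features,
                                  parse_crispr_array, read_array_fasta,
                                  read_genome, reverse_complement)

BASES = "ACGT"


def _rand_seq(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def test_genbank_roundtrip_preserves_features_and_topology(tmp_path):
    rng = np.random.default_rng(0)
    seq = _rand_seq(rng, 500)
    rec = SeqRecord(Seq(seq), id="chr1", annotations={
        "molecule_type": "DNA", "topology": "circular"})
    rec.features = [
        SeqFeature(FeatureLocation(49, 150, strand=1), type="gene",
                   qualifiers={"locus_tag": ["gA"]}),
        SeqFeature(FeatureLocation(199, 300, strand=-1), type="gene",
                   qualifiers={"locus_tag": ["gB"]}),
    ]
    path = tmp_path / "g.gb"
    SeqIO.write([rec], str(path), "genbank")
    genome, feats = read_genome(path, "genbank")
    assert genome.sequence == seq and genome.circular
    assert [(f.gene_id, f.start, f.end, f.strand) for f in feats] == [
        ("gA", 49, 150, "+"), ("gB", 199, 300, "-")]


def test_gff3_one_based_inclusive_converts_to_zero_based_half_open(tmp_path):
    rng = np.random.default_rng(1)
    seq = _rand_seq(rng, 200)
    fasta = tmp_path / "g.fa"
    fasta.write_text(f">chr1\n{seq}\n")
    gff = tmp_path / "g.gff3"
    gff.write_text("##gff-version 3\n"
                   "chr1\tsrc\tgene\t11\t100\t.\t+\t.\tID=gA\n"
                   "chr1\tsrc\tgene\t120\t180\t.\t-\t.\tID=gB\n")
    genome, feats = read_genome(fasta, "fasta+gff3", gff_path=gff)
    assert [(f.start, f.end, f.strand) for f in feats] == [
        (10, 100, "+"), (119, 180, "-")]


def test_feature_beyond_sequence_end_is_a_coordinate_error(tmp_path):
    fasta = tmp_path / "g.fa"
    fasta.write_text(">chr1\nACGTACGT\n")
    gff = tmp_path / "g.gff3"
    gff.write_text("##gff-version 3\nchr1\tsrc\tgene\t1\t50\t.\t+\t.\tID=gA\n")
    with pytest.raises(CoordinateError):
        read_genome(fasta, "fasta+gff3", gff_path=gff)


def test_unparseable_genbank_raises_format_error(tmp_path):
    bad = tmp_path / "bad.gb"
    bad.write_text("this is not genbank\n")
    with pytest.raises(GenomeFormatError):
        read_genome(bad, "genbank")


def test_genome_provenance_is_validated():
    with pytest.raises(ValueError):
        Genome("g", "ACGT", provenance="mystery")
    with pytest.raises(ValueError):
        Genome("g", "")


# ---------------------------------------------------------------------------
# merge_features against a simple interval-union oracle
# ---------------------------------------------------------------------------

def _union_oracle(intervals, length):
    covered = np.zeros(length, dtype=bool)
    for a, b in intervals:
        covered[a:b] = True
    out, start = [], None
    for i, c in enumerate(covered):
        if c and start is None:
            start = i
        elif not c and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, length))
    return out


def test_merged_blocks_equal_interval_union():
    rng = np.random.default_rng(2)
    feats = []
    for i in range(40):
        a = int(rng.integers(0, 1900))
        b = a + int(rng.integers(1, 100))
        feats.append(GeneFeature(f"g{i}", a, b, str(rng.choice(["+", "-"]))))
    blocks = merge_features(feats)
    assert [(b.start, b.end) for b in blocks] == \
        _union_oracle([(f.start, f.end) for f in feats], 2000)
    assert sum(len(b.genes) for b in blocks) == len(feats)


def test_touching_genes_stay_separate_blocks():
    blocks = merge_features([GeneFeature("a", 0, 10, "+"),
                             GeneFeature("b", 10, 20, "-")])
    assert [(b.start, b.end) for b in blocks] == [(0, 10), (10, 20)]


def test_block_edge_strands_come_from_edge_genes():
    (block,) = merge_features([GeneFeature("a", 0, 50, "+"),
                               GeneFeature("b", 30, 80, "-")])
    assert (block.left_strand, block.right_strand) == ("+", "-")


# ---------------------------------------------------------------------------
# intergenic classification
# ---------------------------------------------------------------------------

GENES = [GeneFeature("A", 100, 200, "+"), GeneFeature("B", 300, 400, "-"),
         GeneFeature("C", 500, 600, "-"), GeneFeature("D", 700, 800, "+")]


def test_gap_categories_follow_flanking_orientations():
    regions = classify_intergenic(GENES, 1000)
    by_start = {r.start: r.category for r in regions}
    assert by_start[200] == "convergent"   # + then -
    assert by_start[400] == "upstream"     # - then -
    assert by_start[600] == "divergent"    # - then +
    assert by_start[0] == "upstream"       # linear start, gene points right
    assert by_start[800] == "convergent"   # linear end, gene points away? no:
    # gene D is '+', pointing toward the end -> the trailing gap is
    # downstream of D and upstream of nothing -> convergent


def test_strand_flip_swaps_divergent_and_convergent():
    flipped = [GeneFeature(g.gene_id, g.start, g.end,
                           "+" if g.strand == "-" else "-") for g in GENES]
    orig = {r.start: r.category for r in classify_intergenic(GENES, 1000)}
    flip = {r.start: r.category for r in classify_intergenic(flipped, 1000)}
    swap = {"divergent": "convergent", "convergent": "divergent",
            "upstream": "upstream"}
    # interior gaps (flanked on both sides) mirror exactly under a strand flip
    for s in (200, 400, 600):
        assert flip[s] == swap[orig[s]]
    # edge gaps flip between upstream and convergent: 'the gene points away'
    # reverses with its strand
    assert (orig[0], flip[0]) == ("upstream", "convergent")
    assert (orig[800], flip[800]) == ("convergent", "upstream")


def test_circular_origin_gap_is_one_wrapping_region():
    regions = classify_intergenic(GENES, 1000, circular=True)
    wrap = [r for r in regions if r.end > 1000]
    assert len(wrap) == 1
    (r,) = wrap
    assert (r.start, r.end, r.wraps) == (800, 1100, True)
    assert r.category == "upstream"  # D '+' then A '+'
    assert not any(r2.start == 0 for r2 in regions if r2 is not r)


def test_overlapping_raw_features_are_rejected():
    with pytest.raises(ValueError):
        classify_intergenic([GeneFeature("a", 0, 50, "+"),
                             GeneFeature("b", 25, 75, "+")], 100)


def test_region_index_tiles_every_base():
    idx = RegionIndex(GENES, 1000, circular=True)
    assert np.all(idx.is_coding | (idx.region_idx >= 0))
    # coding and intergenic are mutually exclusive
    assert not np.any(idx.is_coding & (idx.region_idx >= 0))
    covered = sum(b.end - b.start for b in idx.blocks)
    assert covered == sum(len(g) for g in GENES)


def test_region_intervals_cover_the_genome_exactly_once():
    idx = RegionIndex(GENES, 1000, circular=True)
    total = sum(b - a for a, b in idx.region_intervals())
    assert total == 1000


# ---------------------------------------------------------------------------
# CRISPR array parsing
# ---------------------------------------------------------------------------

def _array_locus(rng, n_spacers, repeat_len=28, spacer_len=32):
    repeat = _rand_seq(rng, repeat_len)
    spacers = [_rand_seq(rng, spacer_len) for _ in range(n_spacers)]
    locus = repeat + "".join(s + repeat for s in spacers)
    return repeat, spacers, locus


def test_two_spacer_locus_parses_to_ordered_spacers():
    rng = np.random.default_rng(3)
    repeat, spacers, locus = _array_locus(rng, 2)
    arr = parse_crispr_array(locus, repeat)
    assert [s.sequence for s in arr.spacers] == spacers
    assert [s.spacer_id for s in arr.spacers] == ["S1", "S2"]
    assert arr.spacers[0].start == 28 and arr.spacers[0].end == 60


def test_thirteen_repeats_yield_twelve_spacers():
    rng = np.random.default_rng(4)
    repeat, spacers, locus = _array_locus(rng, 12)
    arr = parse_crispr_array(locus, repeat)
    assert len(arr.spacers) == 12
    assert [s.sequence for s in arr.spacers] == spacers


def test_leader_on_the_right_reverses_spacer_numbering():
    rng = np.random.default_rng(5)
    repeat, spacers, locus = _array_locus(rng, 3)
    arr = parse_crispr_array(locus, repeat, leader_side="right")
    assert [s.sequence for s in arr.spacers] == spacers[::-1]
    assert [s.spacer_id for s in arr.spacers] == ["S1", "S2", "S3"]


def test_single_repeat_copy_is_an_error():
    rng = np.random.default_rng(6)
    repeat = _rand_seq(rng, 28)
    with pytest.raises(ArrayParseError):
        parse_crispr_array(repeat + _rand_seq(rng, 32), repeat)


def test_spacer_sharing_a_short_word_with_repeat_is_not_split():
    rng = np.random.default_rng(7)
    repeat = _rand_seq(rng, 28)
    # force a shared 6-mer (score 30 > 25) inside the middle spacer
    spacer = _rand_seq(rng, 13) + repeat[5:11] + _rand_seq(rng, 13)
    locus = repeat + spacer + repeat
    arr = parse_crispr_array(locus, repeat)
    assert [s.sequence for s in arr.spacers] == [spacer]


def test_lift_to_reverse_strand_places_revcomp_on_genome():
    rng = np.random.default_rng(8)
    repeat, spacers, locus = _array_locus(rng, 2)
    arr = parse_crispr_array(locus, repeat)
    offset = 100
    genome_seq = (_rand_seq(rng, offset) + reverse_complement(locus)
                  + _rand_seq(rng, 50))
    lifted = lift_array_to_genome(arr, offset, "-", len(genome_seq))
    assert (lifted.array_start, lifted.array_end) == (100, 100 + len(locus))
    for sp in lifted.spacers:
        assert genome_seq[sp.start:sp.end] == reverse_complement(sp.sequence)
        assert sp.sequence in locus


def test_lift_outside_genome_is_a_coordinate_error():
    rng = np.random.default_rng(9)
    repeat, _, locus = _array_locus(rng, 2)
    arr = parse_crispr_array(locus, repeat)
    with pytest.raises(CoordinateError):
        lift_array_to_genome(arr, 100, "+", len(locus))


def test_array_fasta_requires_leading_repeat_record(tmp_path):
    p = tmp_path / "arr.fa"
    p.write_text(">S1\nACGTACGT\n")
    with pytest.raises(GenomeFormatError):
        read_array_fasta(p)
    p.write_text(">repeat\nAAAACCCC\n>S1\nACGTACGT\n")
    arr = read_array_fasta(p)
    assert arr.repeat_seq == "AAAACCCC"
    assert arr.spacers[0].sequence == "ACGTACGT"
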