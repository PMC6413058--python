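"""Genome, annotation and CRISPR-array input handling.

Reads host/phage genomes (GenBank or FASTA + GFF3), derives the
coding/intergenic partition used by every downstream stage, classifies
intergenic regions by the orientation of their flanking genes, and splits a
CRISPR locus into an ordered repeat/spacer representation.

Coordinate convention: 0-based half-open on the direct strand everywhere in
memory; 1-based inclusive only in written reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

PROVENANCES = ("host", "phage", "randomized-host", "randomized-phage")


class SpacerScanError(Exception):
    """Base class for errors raised by this package."""


class GenomeFormatError(SpacerScanError):
    """Input file does not parse under the named standard."""


class CoordinateError(SpacerScanError):
    """A feature or hit lies outside its genome."""


class ArrayParseError(SpacerScanError):
    """A CRISPR locus could not be split into repeats and spacers."""


def reverse_complement(seq: str) -> str:
    """Reverse complement, IUPAC ambiguity codes included."""
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    """A nucleotide sequence with provenance.

    ``provenance`` records whether the sequence is a real host or phage
    genome or one of their composition-preserving randomizations; it is set
    once at construction and never mutated.
    """

    id: str
    sequence: str
    circular: bool = False
    provenance: str = "host"

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("genome sequence must be non-empty")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    gene_id: str
    start: int
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"gene {self.gene_id}: bad interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CodingBlock:
    """Strand-agnostic union of overlapping gene intervals.

    ``left_strand``/``right_strand`` are the strands of the constituent genes
    forming the block's left and right edges; they decide the categories of
    the neighbouring intergenic regions.
    """

    start: int
    end: int
    genes: tuple[GeneFeature, ...]
    left_strand: str
    right_strand: str


@dataclass(frozen=True)
class IntergenicRegion:
    start: int
    end: int  # may exceed genome length when the region wraps the origin
    category: str  # divergent | convergent | upstream | unclassifiable
    left_gene_id: str | None = None
    right_gene_id: str | None = None
    wraps: bool = False


@dataclass(frozen=True)
class Spacer:
    spacer_id: str
    sequence: str
    start: int = -1  # genome coordinates; -1 when only the sequence is known
    end: int = -1


@dataclass
class CRISPRArray:
    array_start: int
    array_end: int
    repeat_seq: str
    spacers: list[Spacer]
    strand: str = "+"  # genome strand carrying the array in leader orientation


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_PREFERRED_FEATURE_TYPES = ("gene", "CDS")


def read_genome(path: str | Path, format: str = "genbank", *,
                gff_path: str | Path | None = None,
                provenance: str = "host",
                circular: bool | None = None) -> tuple[Genome, list[GeneFeature]]:
    """Read a genome plus gene features from GenBank or FASTA + GFF3.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    Gene-level features are preferred; CDS features are used when no gene
    records exist. Features beyond the sequence end raise CoordinateError.
    """
    path = Path(path)
    if format == "genbank":
        try:
            record = SeqIO.read(str(path), "genbank")
        except Exception as exc:  # noqa: BLE001 - rewrap with file context
            raise GenomeFormatError(f"{path}: not a parseable GenBank record ({exc})") from exc
        if circular is None:
            circular = record.annotations.get("topology", "") == "circular"
        features = _features_from_genbank(record)
    elif format == "fasta+gff3":
        if gff_path is None:
            raise ValueError("fasta+gff3 format requires gff_path")
        try:
            record = SeqIO.read(str(path), "fasta")
        except Exception as exc:  # noqa: BLE001
            raise GenomeFormatError(f"{path}: not a parseable FASTA record ({exc})") from exc
        features = _features_from_gff3(gff_path)
        if circular is None:
            circular = False
    else:
        raise ValueError(f"unknown format {format!r}")

    genome = Genome(id=record.id, sequence=str(record.seq),
                    circular=bool(circular), provenance=provenance)
    for f in features:
        if f.end > len(genome):
            raise CoordinateError(
                f"{path}: feature {f.gene_id} ends at {f.end} beyond sequence "
                f"length {len(genome)}")
    return genome, sorted(features, key=lambda f: (f.start, f.end))


def _features_from_genbank(record) -> list[GeneFeature]:
    by_type: dict[str, list[GeneFeature]] = {t: [] for t in _PREFERRED_FEATURE_TYPES}
    for feat in record.features:
        if feat.type not in by_type:
            continue
        strand = "+" if (feat.location.strand or 1) >= 0 else "-"
        quals = feat.qualifiers
        name = (quals.get("locus_tag") or quals.get("gene")
                or quals.get("ID") or [f"{feat.type}_{int(feat.location.start)}"])[0]
        by_type[feat.type].append(GeneFeature(
            gene_id=str(name), start=int(feat.location.start),
            end=int(feat.location.end), strand=strand))
    for t in _PREFERRED_FEATURE_TYPES:
        if by_type[t]:
            return by_type[t]
    return []


def _features_from_gff3(gff_path: str | Path) -> list[GeneFeature]:
    import gffutils

    try:
        db = gffutils.create_db(str(gff_path), ":memory:",
                                merge_strategy="create_unique", force=True,
                                keep_order=True)
    except Exception as exc:  # noqa: BLE001
        raise GenomeFormatError(f"{gff_path}: not parseable GFF3 ({exc})") from exc
    out: list[GeneFeature] = []
    for ftype in _PREFERRED_FEATURE_TYPES:
        for feat in db.features_of_type(ftype):
            name = feat.attributes.get("ID", [f"{ftype}_{feat.start}"])[0]
            out.append(GeneFeature(gene_id=str(name), start=feat.start - 1,
                                   end=feat.end, strand="+" if feat.strand != "-" else "-"))
        if out:
            return out
    return out


# ---------------------------------------------------------------------------
# Coding/intergenic partition
# ---------------------------------------------------------------------------

def merge_features(features: Sequence[GeneFeature]) -> list[CodingBlock]:
    """Union overlapping/adjacent-overlapping gene intervals into blocks.

    The binary coding/intergenic partition needs a tiling, so overlaps are
    merged strand-agnostically; per-gene strands are kept for hit-level
    classification.
    """
    if not features:
        return []
    feats = sorted(features, key=lambda f: (f.start, f.end))
    blocks: list[CodingBlock] = []
    cur: list[GeneFeature] = [feats[0]]
    cur_end = feats[0].end
    for f in feats[1:]:
        if f.start < cur_end:  # strict overlap; touching genes stay separate
            cur.append(f)
            cur_end = max(cur_end, f.end)
        else:
            blocks.append(_finish_block(cur, cur_end))
            cur = [f]
            cur_end = f.end
    blocks.append(_finish_block(cur, cur_end))
    return blocks


def _finish_block(genes: list[GeneFeature], end: int) -> CodingBlock:
    start = min(g.start for g in genes)
    left = min(genes, key=lambda g: (g.start, -g.end))
    right = max(genes, key=lambda g: (g.end, g.start))
    return CodingBlock(start=start, end=end, genes=tuple(genes),
                       left_strand=left.strand, right_strand=right.strand)


def _gap_category(left_strand: str | None, right_strand: str | None) -> str:
    # A gap is upstream of a '+' gene to its right and of a '-' gene to its
    # left; upstream of both -> divergent, of neither -> convergent.
    if left_strand is None and right_strand is None:
        return "unclassifiable"
    if left_strand is None:  # linear genome, leading gap
        return "upstream" if right_strand == "+" else "convergent"
    if right_strand is None:  # linear genome, trailing gap
        return "upstream" if left_strand == "-" else "convergent"
    if left_strand == "-" and right_strand == "+":
        return "divergent"
    if left_strand == "+" and right_strand == "-":
        return "convergent"
    return "upstream"


def classify_intergenic(features: Sequence[GeneFeature] | Sequence[CodingBlock],
                        genome_length: int,
                        circular: bool = False) -> list[IntergenicRegion]:
    """Tile the annotation gaps and classify each by flanking gene strands.

    Accepts raw (non-overlapping) features or pre-merged CodingBlocks. On a
    circular genome the gap spanning the origin is emitted once with
    ``wraps=True`` and ``end > genome_length``.
    """
    blocks = [f if isinstance(f, CodingBlock) else
              CodingBlock(f.start, f.end, (f,), f.strand, f.strand)
              for f in features]
    blocks.sort(key=lambda b: b.start)
    for a, b in zip(blocks, blocks[1:]):
        if b.start < a.end:
            raise ValueError("features must be non-overlapping; call merge_features first")

    if not blocks:
        if not circular:
            raise ValueError("linear genome with no gene features cannot be partitioned")
        return [IntergenicRegion(0, genome_length, "unclassifiable")]

    regions: list[IntergenicRegion] = []
    for a, b in zip(blocks, blocks[1:]):
        if b.start > a.end:
            regions.append(IntergenicRegion(
                a.end, b.start, _gap_category(a.right_strand, b.left_strand),
                left_gene_id=_edge_gene(a, "right"), right_gene_id=_edge_gene(b, "left")))
    first, last = blocks[0], blocks[-1]
    if circular:
        if first.start > 0 or last.end < genome_length:
            # single region spanning the origin (possibly zero-offset at one end)
            regions.append(IntergenicRegion(
                last.end, genome_length + first.start,
                _gap_category(last.right_strand, first.left_strand),
                left_gene_id=_edge_gene(last, "right"),
                right_gene_id=_edge_gene(first, "left"),
                wraps=first.start > 0))
    else:
        if first.start > 0:
            regions.append(IntergenicRegion(
                0, first.start, _gap_category(None, first.left_strand),
                right_gene_id=_edge_gene(first, "left")))
        if last.end < genome_length:
            regions.append(IntergenicRegion(
                last.end, genome_length, _gap_category(last.right_strand, None),
                left_gene_id=_edge_gene(last, "right")))
    return sorted(regions, key=lambda r: r.start)


def _edge_gene(block: CodingBlock, side: str) -> str:
    if side == "left":
        return min(block.genes, key=lambda g: (g.start, -g.end)).gene_id
    return max(block.genes, key=lambda g: (g.end, g.start)).gene_id


class RegionIndex:
    """Per-base lookup of the coding/intergenic partition of one genome.

    Holds the merged coding blocks, the classified intergenic regions, the
    raw gene list, and int arrays mapping every base to its container; built
    once per genome and shared by classification and randomization.
    """

    def __init__(self, features: Sequence[GeneFeature], genome_length: int,
                 circular: bool = False):
        self.genome_length = int(genome_length)
        self.circular = bool(circular)
        self.genes = sorted(features, key=lambda f: (f.start, f.end))
        self.blocks = merge_features(self.genes)
        self.regions = classify_intergenic(self.blocks, genome_length, circular) \
            if (self.blocks or circular) else []
        # -1 where the base belongs to the other partition
        self.block_idx = np.full(genome_length, -1, dtype=np.int32)
        self.region_idx = np.full(genome_length, -1, dtype=np.int32)
        for i, b in enumerate(self.blocks):
            self.block_idx[b.start:b.end] = i
        for i, r in enumerate(self.regions):
            if r.end <= genome_length:
                self.region_idx[r.start:r.end] = i
            else:  # wraps the origin
                self.region_idx[r.start:] = i
                self.region_idx[:r.end - genome_length] = i
        self.is_coding = self.block_idx >= 0
        uncovered = np.count_nonzero((self.block_idx < 0) & (self.region_idx < 0))
        if uncovered:
            raise AssertionError(f"partition left {uncovered} bases uncovered")

    def region_intervals(self) -> list[tuple[int, int]]:
        """All partition units as direct-strand intervals (wrap regions give
        end > genome_length); used by the randomizer."""
        out = [(b.start, b.end) for b in self.blocks]
        out += [(r.start, r.end) for r in self.regions]
        return sorted(out)


# ---------------------------------------------------------------------------
# CRISPR array parsing
# ---------------------------------------------------------------------------

def parse_crispr_array(locus: str, repeat_seq: str, *,
                       leader_side: str = "left",
                       min_repeat_score: int = 25,
                       scoring=None) -> CRISPRArray:
    """Split a CRISPR locus into repeats and leader-ordered spacers.

    Repeat copies are located by local alignment of ``repeat_seq`` against the
    locus; a match must reach both ``min_repeat_score`` and 60% of the perfect
    repeat score, so a chance shared word inside a spacer is never mistaken
    for a repeat. Spacers are the maximal segments strictly between
    consecutive repeat matches, numbered S1.. from the leader side.
    """
    from . import aligner  # local import; aligner depends on this module

    if leader_side not in ("left", "right"):
        raise ValueError("leader_side must be 'left' or 'right'")
    locus = locus.upper()
    repeat_seq = repeat_seq.upper()
    scoring = scoring or aligner.ScoringScheme()
    threshold = max(min_repeat_score,
                    int(0.6 * scoring.match * len(repeat_seq)))
    max_copies = max(2, len(locus) // max(1, len(repeat_seq) // 2))
    hits = aligner.k_best_alignments(repeat_seq, locus, k=max_copies,
                                     scoring=scoring)
    matches = sorted((h.s_start, h.s_end) for h in hits if h.score >= threshold)
    if len(matches) < 2:
        raise ArrayParseError(
            f"found {len(matches)} repeat copies (need >= 2) at threshold {threshold}")

    gaps = [(a_end, b_start) for (_, a_end), (b_start, _) in zip(matches, matches[1:])]
    if leader_side == "right":
        gaps = gaps[::-1]
    spacers: list[Spacer] = []
    n = 0
    for g_start, g_end in gaps:
        if g_end <= g_start:
            log.warning("zero-length spacer between repeats at %d; skipped", g_start)
            continue
        n += 1
        spacers.append(Spacer(spacer_id=f"S{n}", sequence=locus[g_start:g_end],
                              start=g_start, end=g_end))
    return CRISPRArray(array_start=0, array_end=len(locus),
                       repeat_seq=repeat_seq, spacers=spacers, strand="+")


def lift_array_to_genome(array: CRISPRArray, genome_offset: int, strand: str,
                         genome_length: int) -> CRISPRArray:
    """Map a locus-relative array onto genome coordinates.

    ``strand`` is the genome strand on which the locus sequence (as parsed)
    reads 5'->3'. Spacer sequences keep their leader orientation; only the
    coordinates are transformed onto the direct strand.
    """
    locus_len = array.array_end - array.array_start
    if genome_offset + locus_len > genome_length:
        raise CoordinateError("array does not fit in genome at given offset")
    spacers = []
    for sp in array.spacers:
        if strand == "+":
            s, e = genome_offset + sp.start, genome_offset + sp.end
        else:
            s = genome_offset + (locus_len - sp.end)
            e = genome_offset + (locus_len - sp.start)
        spacers.append(Spacer(sp.spacer_id, sp.sequence, s, e))
    return CRISPRArray(array_start=genome_offset,
                       array_end=genome_offset + locus_len,
                       repeat_seq=array.repeat_seq, spacers=spacers,
                       strand=strand)


def read_array_fasta(path: str | Path) -> CRISPRArray:
    """Read a repeat + spacers from a 2-part FASTA (record 'repeat' first)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records or not records[0].id.lower().startswith("repeat"):
        raise GenomeFormatError(f"{path}: first record must be the repeat")
    repeat = str(records[0].seq).upper()
    spacers = [Spacer(rec.id, str(rec.seq).upper()) for rec in records[1:]]
    if not spacers:
        raise GenomeFormatError(f"{path}: no spacer records found")
    return CRISPRArray(array_start=0, array_end=0, repeat_seq=repeat,
                       spacers=spacers)
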