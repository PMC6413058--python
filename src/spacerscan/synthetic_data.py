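"""Synthetic annotated genomes with planted ground truth.

Generates a host genome with coding genes in mixed orientations (creating
divergent/convergent/upstream intergenic regions), an embedded CRISPR array
of alternating repeats and spacers, and planted protospacers - mutated
copies of the spacers - with configurable strand bias, region-category
weights, mismatch counts and planted PAM triplets, plus random phage-like
genomes. The generator emits the exact input formats the pipeline reads
(FASTA + GFF3 + array FASTA + truth TSV), so every stage is testable with
no download; it makes no attempt at codon structure or realistic gene
content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import (CRISPRArray, GeneFeature, Genome, RegionIndex,
                        Spacer, SpacerScanError, lift_array_to_genome,
                        reverse_complement)

log = logging.getLogger(__name__)

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SizingError(SpacerScanError):
    """The genome is too short to satisfy the plant table."""


@dataclass
class PlantSpec:
    """One planted protospacer.

    ``strand``/``category`` may be fixed or left None to be sampled: strand
    'reverse' with probability ``rho``, category from ``category_weights``
    (falling back to the config default). ``pam`` is a triplet in the
    reporting orientation of the PAM stage (3'->5' on the targeted strand)
    written immediately upstream of the planted protospacer.
    """

    spacer_id: str | None = None
    strand: str | None = None
    rho: float = 0.5
    category: str | None = None
    category_weights: dict[str, float] | None = None
    n_mismatches: int = 0
    pam: str | None = None


@dataclass
class PlantingConfig:
    """Study conditions for one synthetic host genome.

    Defaults describe an E. coli-like setting: a 100 kb circular chromosome,
    genes of 600-1200 nt separated by 100-300 nt gaps in random orientation
    (~80% coding), a Type I-E-like array of 12 32-nt spacers between 28-nt
    repeats carried on the reverse strand, and no planted protospacers.
    """

    genome_length: int = 100_000
    gene_length: tuple[int, int] = (600, 1200)
    gap_length: tuple[int, int] = (100, 300)
    orientation_pattern: str = "random"  # 'random' or a cycled '+-' string
    n_spacers: int = 12
    spacer_length: int = 32
    repeat_length: int = 28
    array_strand: str = "-"
    leader_side: str = "left"
    base_composition: tuple[float, float, float, float] = (.25, .25, .25, .25)
    circular: bool = True
    plants: list[PlantSpec] = field(default_factory=list)
    category_weights: dict[str, float] = field(default_factory=lambda: {
        "coding": 0.5, "divergent": 0.2, "upstream": 0.2, "convergent": 0.1})

    def __post_init__(self) -> None:
        for p in self.plants:
            if not 0.0 <= p.rho <= 1.0:
                raise ValueError("strand bias rho must lie in [0, 1]")
            if p.n_mismatches >= self.spacer_length / 2:
                raise ValueError("n_mismatches must stay below half the spacer")
            w = p.category_weights or self.category_weights
            if any(v < 0 for v in w.values()) or sum(w.values()) <= 0:
                raise ValueError("category weights must be >= 0 and sum > 0")


@dataclass
class SyntheticHost:
    genome: Genome
    features: list[GeneFeature]
    array: CRISPRArray
    truth: pd.DataFrame
    index: RegionIndex

    @property
    def spacers(self) -> list[Spacer]:
        return self.array.spacers


TRUTH_COLUMNS = ("plant_id", "spacer_id", "strand", "start", "end",
                 "category", "n_mismatches", "mismatch_positions", "pam",
                 "theoretical_start")

_PLANT_MARGIN = 6  # bases kept clear around a plant (room for the PAM window)


def _random_seq(rng: np.random.Generator, length: int,
                composition: Sequence[float]) -> str:
    return "".join(rng.choice(list(_BASES), size=length, p=list(composition)))


def make_plants(n: int, *, rho: float = 0.5,
                category_weights: dict[str, float] | None = None,
                n_mismatches: Sequence[int] | int = 0,
                pam: str | None = None, pam_fraction: float = 1.0,
                seed: int = 0) -> list[PlantSpec]:
    """Convenience plant table: n plants assigned to spacers round-robin.

    ``n_mismatches`` may be a single count or a sequence cycled over plants;
    ``pam_fraction`` of the plants carry the PAM triplet.
    """
    rng = np.random.default_rng([seed, 7])
    mm = [n_mismatches] * n if isinstance(n_mismatches, int) else \
        [n_mismatches[i % len(n_mismatches)] for i in range(n)]
    with_pam = rng.random(n) < pam_fraction if pam else np.zeros(n, bool)
    return [PlantSpec(spacer_id=None, rho=rho,
                      category_weights=category_weights,
                      n_mismatches=int(mm[i]),
                      pam=pam if with_pam[i] else None)
            for i in range(n)]


# ---------------------------------------------------------------------------
# Host generation
# ---------------------------------------------------------------------------

def generate_host(config: PlantingConfig, seed: int) -> SyntheticHost:
    """Generate an annotated host genome with embedded array and plants."""
    rng = np.random.default_rng([seed, 11])
    L = config.genome_length
    sl, rl, ns = config.spacer_length, config.repeat_length, config.n_spacers
    array_len = (ns + 1) * rl + ns * sl
    if array_len + 2000 > L:
        raise SizingError(f"genome of {L} nt cannot hold a {array_len} nt array")

    repeat = _random_seq(rng, rl, config.base_composition)
    spacer_seqs = [_random_seq(rng, sl, config.base_composition)
                   for _ in range(ns)]
    locus = repeat + "".join(s + repeat for s in spacer_seqs)

    genes, array_start = _layout(rng, config, array_len)
    features = [GeneFeature(f"gene{i + 1:04d}", s, e, strand)
                for i, (s, e, strand) in enumerate(genes)]

    seq = np.frombuffer(
        _random_seq(rng, L, config.base_composition).encode(), np.uint8).copy()
    oriented = locus if config.array_strand == "+" else reverse_complement(locus)
    seq[array_start:array_start + array_len] = np.frombuffer(
        oriented.encode(), np.uint8)

    locus_array = CRISPRArray(
        array_start=0, array_end=array_len, repeat_seq=repeat,
        spacers=[Spacer(f"S{i + 1}", s, rl + i * (sl + rl),
                        rl + i * (sl + rl) + sl)
                 for i, s in enumerate(spacer_seqs)])
    array = lift_array_to_genome(locus_array, array_start,
                                 config.array_strand, L)

    index = RegionIndex(features, L, config.circular)
    truth = _place_plants(rng, config, seq, index, array)

    genome = Genome(id=f"synhost_{seed}", sequence=seq.tobytes().decode(),
                    circular=config.circular, provenance="host")
    return SyntheticHost(genome=genome, features=features, array=array,
                         truth=truth, index=index)


def _layout(rng, config: PlantingConfig, array_len: int
            ) -> tuple[list[tuple[int, int, str]], int]:
    """Lay genes and gaps along the genome, widening one mid-genome gap to
    host the array. Returns (genes, array_start)."""
    L = config.genome_length
    genes: list[tuple[int, int, str]] = []
    pattern = config.orientation_pattern
    pos = int(rng.integers(*config.gap_length))  # leading gap (wraps if circular)
    array_start = -1
    i = 0
    while True:
        gl = int(rng.integers(*config.gene_length))
        if pos + gl + config.gap_length[1] + 1 > L:
            break
        strand = rng.choice(["+", "-"]) if pattern == "random" \
            else pattern[i % len(pattern)]
        genes.append((pos, pos + gl, strand))
        i += 1
        gap = int(rng.integers(*config.gap_length))
        pos += gl
        if array_start < 0 and pos > 0.45 * L:
            if pos + gap + array_len + 20 + config.gene_length[1] > L:
                raise SizingError("genome too short to embed the array")
            array_start = pos + gap
            gap += array_len + 20
        pos += gap
    if array_start < 0:
        raise SizingError("genome too short to embed the array")
    if not genes:
        raise SizingError("genome too short for a single gene")
    return genes, array_start


def _candidate_regions(index: RegionIndex, array: CRISPRArray
                       ) -> dict[str, list[tuple[int, int]]]:
    """Placement intervals per category, excluding the array's region and
    origin-wrapping regions (so truth categories stay crisp)."""
    cands: dict[str, list[tuple[int, int]]] = {
        "coding": [], "divergent": [], "convergent": [], "upstream": []}
    for g in index.genes:
        cands["coding"].append((g.start, g.end))
    for r in index.regions:
        if r.category not in cands or r.end > index.genome_length:
            continue
        if r.start < array.array_end and r.end > array.array_start:
            continue
        cands[r.category].append((r.start, r.end))
    return cands


def _place_plants(rng, config: PlantingConfig, seq: np.ndarray,
                  index: RegionIndex, array: CRISPRArray) -> pd.DataFrame:
    sl = config.spacer_length
    footprint = sl + 2 * _PLANT_MARGIN
    cands = _candidate_regions(index, array)
    occupied: list[tuple[int, int]] = [(array.array_start, array.array_end)]
    rows = []
    for pi, spec in enumerate(config.plants):
        sid = spec.spacer_id or f"S{pi % len(array.spacers) + 1}"
        spacer = next(s for s in array.spacers if s.spacer_id == sid)
        strand = spec.strand or \
            ("reverse" if rng.random() < spec.rho else "direct")
        weights = spec.category_weights or config.category_weights
        cats = [c for c, w in weights.items() if w > 0 and cands.get(c)]
        if not cats:
            raise SizingError("no candidate region for any weighted category")
        p = np.array([weights[c] for c in cats], dtype=float)
        category = str(rng.choice(cats, p=p / p.sum()))
        start = _sample_position(rng, cands[category], footprint, occupied)
        if start is None:
            raise SizingError(
                f"could not place plant {pi} in a {category} region")
        start += _PLANT_MARGIN
        occupied.append((start - _PLANT_MARGIN, start + sl + _PLANT_MARGIN))

        mut, mm_pos = _mutate(rng, spacer.sequence, spec.n_mismatches)
        if strand == "direct":
            text = mut
            t = start
        else:
            text = reverse_complement(mut)
            t = start + sl - 1
        seq[start:start + sl] = np.frombuffer(text.encode(), np.uint8)
        if spec.pam:
            _write_pam(seq, spec.pam, strand, t)
        rows.append(dict(plant_id=f"P{pi + 1:03d}", spacer_id=sid,
                         strand=strand, start=start, end=start + sl,
                         category=category, n_mismatches=spec.n_mismatches,
                         mismatch_positions=",".join(map(str, mm_pos)),
                         pam=spec.pam or "", theoretical_start=t))
    return pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))


def _sample_position(rng, regions: list[tuple[int, int]], footprint: int,
                     occupied: list[tuple[int, int]], tries: int = 400
                     ) -> int | None:
    """Uniform-ish rejection sampling of a free footprint start."""
    fitting = [(a, b) for a, b in regions if b - a >= footprint]
    if not fitting:
        return None
    sizes = np.array([b - a - footprint + 1 for a, b in fitting], dtype=float)
    for _ in range(tries):
        ri = int(rng.choice(len(fitting), p=sizes / sizes.sum()))
        a, b = fitting[ri]
        start = int(rng.integers(a, b - footprint + 1))
        if all(start + footprint <= oa or start >= ob for oa, ob in occupied):
            return start
    return None


def _mutate(rng, seq: str, n_mismatches: int) -> tuple[str, list[int]]:
    if n_mismatches == 0:
        return seq, []
    pos = sorted(rng.choice(len(seq), size=n_mismatches, replace=False).tolist())
    chars = list(seq)
    for p in pos:
        chars[p] = rng.choice([b for b in _BASES if b != chars[p]])
    return "".join(chars), pos


def _write_pam(seq: np.ndarray, pam: str, strand: str, t: int) -> None:
    """Write a PAM triplet (given 3'->5' on the targeted strand) immediately
    upstream of the theoretical start ``t``."""
    if strand == "direct":
        bases = pam.translate(_COMPLEMENT)  # elementwise complement
        a = t - 3
    else:
        bases = pam[::-1]
        a = t + 1
    if a < 0 or a + 3 > seq.size:
        raise SizingError("PAM window leaves the genome")
    seq[a:a + 3] = np.frombuffer(bases.encode(), np.uint8)


# ---------------------------------------------------------------------------
# Phage generation
# ---------------------------------------------------------------------------

def generate_phages(n: int, length: int = 30_000,
                    composition: Sequence[float] = (.25, .25, .25, .25),
                    seed: int = 0, *,
                    spacers: Sequence[Spacer] = (),
                    plants: Sequence[PlantSpec] = ()) -> list[Genome]:
    """i.i.d. random phage-like genomes, optionally with planted
    protospacers (placed uniformly; phages carry no annotation)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    genomes = []
    for gi in range(n):
        rng = np.random.default_rng([seed, 13, gi])
        seq = np.frombuffer(_random_seq(rng, length, composition).encode(),
                            np.uint8).copy()
        occupied: list[tuple[int, int]] = []
        for pi, spec in enumerate(plants):
            spacer = spacers[pi % len(spacers)] if spec.spacer_id is None else \
                next(s for s in spacers if s.spacer_id == spec.spacer_id)
            sl = len(spacer.sequence)
            start = _sample_position(rng, [(0, length)],
                                     sl + 2 * _PLANT_MARGIN, occupied)
            if start is None:
                raise SizingError("phage too short for its plant table")
            start += _PLANT_MARGIN
            occupied.append((start - _PLANT_MARGIN, start + sl + _PLANT_MARGIN))
            strand = spec.strand or \
                ("reverse" if rng.random() < spec.rho else "direct")
            mut, _ = _mutate(rng, spacer.sequence, spec.n_mismatches)
            text = mut if strand == "direct" else reverse_complement(mut)
            seq[start:start + sl] = np.frombuffer(text.encode(), np.uint8)
            if spec.pam:
                t = start if strand == "direct" else start + sl - 1
                _write_pam(seq, spec.pam, strand, t)
        genomes.append(Genome(id=f"synphage_{seed}_{gi}",
                              sequence=seq.tobytes().decode(),
                              circular=False, provenance="phage"))
    return genomes


# ---------------------------------------------------------------------------
# Writers (the exact formats the pipeline reads back)
# ---------------------------------------------------------------------------

def write_fasta(genomes: Sequence[Genome], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id} provenance={g.provenance} "
                     f"circular={str(g.circular).lower()}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i:i + width] + "\n")


def write_gff3(genome: Genome, features: Sequence[GeneFeature],
               path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for f in features:
            fh.write("\t".join([
                genome.id, "spacerscan", "gene", str(f.start + 1), str(f.end),
                ".", f.strand, ".", f"ID={f.gene_id}"]) + "\n")


def write_array_fasta(array: CRISPRArray, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">repeat\n{array.repeat_seq}\n")
        for sp in array.spacers:
            fh.write(f">{sp.spacer_id} start={sp.start + 1} end={sp.end}\n"
                     f"{sp.sequence}\n")


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# planted protospacer truth table (1-based inclusive)\n")
        out = truth.copy()
        if len(out):
            out["start"] = out["start"] + 1
            out["theoretical_start"] = out["theoretical_start"] + 1
        out.to_csv(fh, sep="\t", index=False)
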