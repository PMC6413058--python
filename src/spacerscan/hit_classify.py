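"""Functional classification of retained hits.

Each hit is assigned (i) coding vs intergenic by majority per-base overlap,
(ii) within coding the RNA+/RNA- category: a hit on a gene's coding strand
means the crRNA-bound target is the template strand, so interference can act
only on DNA (RNA-); a hit on the template strand puts the target on the
coding strand, reachable as both DNA and mRNA (RNA+); (iii) within
intergenic the divergent/convergent/upstream subcategory of the containing
region; and (iv) the genome strand of the hit itself (DC/RC).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .aligner import Hit
from .genome_io import GeneFeature, RegionIndex


@dataclass
class AnnotatedHit:
    """A hit plus its functional categories.

    ``rna_category`` is set iff the hit is coding; ``intergenic_category``
    iff intergenic. ``boundary_spanning`` flags hits whose aligned interval
    crosses a coding/intergenic boundary (classified by majority overlap,
    exact tie -> coding).
    """

    hit: Hit
    region_type: str  # 'coding' | 'intergenic'
    rna_category: str | None
    intergenic_category: str | None
    genome_strand: str  # 'DC' | 'RC'
    container_id: str
    boundary_spanning: bool

    @property
    def score(self) -> int:
        return self.hit.score

    @property
    def rank(self) -> int | None:
        return self.hit.rank


def classify_region(hit: Hit, index: RegionIndex) -> tuple[str, str, bool]:
    """(region_type, container id, boundary_spanning) by per-base majority."""
    a, b = hit.g_start, hit.g_end
    if not (0 <= a < b <= index.genome_length):
        raise ValueError(f"hit interval [{a},{b}) outside genome")
    coding_bases = int(np.count_nonzero(index.is_coding[a:b]))
    inter_bases = (b - a) - coding_bases
    spanning = coding_bases > 0 and inter_bases > 0
    if coding_bases >= inter_bases:  # exact tie -> coding
        gene = _majority_gene(hit, index)
        return "coding", gene.gene_id, spanning
    ids = index.region_idx[a:b]
    ids = ids[ids >= 0]
    counts = np.bincount(ids)
    region = index.regions[int(np.argmax(counts))]
    return "intergenic", f"intergenic_{region.start}", spanning


def _majority_gene(hit: Hit, index: RegionIndex) -> GeneFeature:
    best = None
    best_ov = -1
    for g in index.genes:
        ov = min(hit.g_end, g.end) - max(hit.g_start, g.start)
        if ov > best_ov:  # ties -> earliest-starting gene (genes pre-sorted)
            best, best_ov = g, ov
    if best is None or best_ov <= 0:
        raise ValueError("no overlapping gene for a coding-classified hit")
    return best


def rna_category(hit: Hit, gene: GeneFeature) -> str:
    """RNA- when the hit lies on the gene's coding strand, RNA+ on template."""
    gene_hit_strand = "direct" if gene.strand == "+" else "reverse"
    return "RNA-" if hit.strand == gene_hit_strand else "RNA+"


def genome_strand(hit: Hit) -> str:
    return "DC" if hit.strand == "direct" else "RC"


def annotate_hit(hit: Hit, index: RegionIndex) -> AnnotatedHit:
    region_type, container, spanning = classify_region(hit, index)
    rna = None
    inter = None
    if region_type == "coding":
        gene = next(g for g in index.genes if g.gene_id == container)
        rna = rna_category(hit, gene)
    else:
        start = int(container.split("_")[1])
        region = next(r for r in index.regions if r.start == start)
        inter = region.category
    return AnnotatedHit(hit=hit, region_type=region_type, rna_category=rna,
                        intergenic_category=inter,
                        genome_strand=genome_strand(hit),
                        container_id=container, boundary_spanning=spanning)


def annotate_hits(hits_by_spacer: dict[str, Sequence[Hit]],
                  index: RegionIndex) -> dict[str, list[AnnotatedHit]]:
    """Annotate every retained hit, preserving per-spacer rank order."""
    return {sid: [annotate_hit(h, index) for h in hits]
            for sid, hits in hits_by_spacer.items()}
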