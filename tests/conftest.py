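"""Shared fixtures: synthetic genomes and their (expensive) scans."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracle module

from spacerscan import (PlantingConfig, RandomizationConfig, annotate_hits,
                        generate_host, make_background, make_plants,
                        scan_genome)


@pytest.fixture(scope="session")
def host100():
    """Default-condition synthetic host: 100 kb, 12-spacer array, no plants."""
    return generate_host(PlantingConfig(), seed=11)


@pytest.fixture(scope="session")
def host100_hits(host100):
    return scan_genome(host100.spacers, host100.genome, array=host100.array)


@pytest.fixture(scope="session")
def host100_annotated(host100, host100_hits):
    return annotate_hits(host100_hits, host100.index)


#: Planted-truth study conditions: a gene-sparse 40 kb host whose "+-"
#: orientation pattern makes convergent gaps ~30% of the genome, with 96
#: planted protospacers (8 per spacer; reverse-strand bias rho=0.9; only
#: coding and divergent regions allowed; 0-2 mismatches cycled; PAM 'AAG'
#: on 80% of plants) against the standard 30-replicate randomized background.
PLANTED_CONFIG = PlantingConfig(
    genome_length=40_000,
    gene_length=(250, 350),
    gap_length=(400, 500),
    orientation_pattern="+-",
    n_spacers=12,
    plants=make_plants(
        96, rho=0.9,
        category_weights={"coding": 0.5, "divergent": 0.5,
                          "convergent": 0.0, "upstream": 0.0},
        n_mismatches=(0, 1, 2), pam="AAG", pam_fraction=0.8, seed=5),
)


@pytest.fixture(scope="session")
def planted():
    host = generate_host(PLANTED_CONFIG, seed=21)
    real = annotate_hits(
        scan_genome(host.spacers, host.genome, array=host.array), host.index)
    bg_genomes = make_background(host.genome, host.index,
                                 RandomizationConfig(30, seed=77))
    bg = [annotate_hits(scan_genome(host.spacers, g), host.index)
          for g in bg_genomes]
    return {"host": host, "real": real, "bg": bg, "bg_genomes": bg_genomes}
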