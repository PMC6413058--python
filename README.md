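# spacerscan

Do Type I-E CRISPR spacers target their own host genome?

`spacerscan` is a pipeline for answering that question quantitatively. It
aligns every spacer of a CRISPR array against a host (or phage) genome with
Smith–Waterman local alignment plus Waterman–Eggert declumping, so each
spacer reports its k best *non-overlapping* putative protospacers per
strand. Each retained hit is classified by annotation context (coding vs
intergenic; RNA+/RNA− on genes; divergent/convergent/upstream between
genes) and by genome strand (DC/RC). Every observed signal is then judged
against a composition-preserving null: the genome is re-drawn many times by
independently permuting the nucleotides of each coding block and intergenic
region, and the same scan is repeated on every replicate. On top of that
sit threshold profiles of summed alignment counts and mean scores (SAC/SAS)
with 3σ background bounds, Kolmogorov–Smirnov and t-tests on pooled score
distributions, Poisson over/under-representation calls for the 64 triplets
at the putative PAM position, and post-processing of external homology
searches (BLAST outfmt-6 tables) that decides whether conserved spacer
matches sit inside other CRISPR arrays.

Because the interesting statistical machinery is exactly the part that is
hard to validate on real data, the package ships a synthetic-data generator
that produces fully annotated host genomes with an embedded CRISPR array
and *planted* protospacers — with configurable strand bias, region-category
weights, mismatch counts and planted PAM triplets — so every stage can be
exercised against a known ground truth.

## Worked example

Generate a 20 kb annotated host with a 4-spacer array and one planted
protospacer (reverse strand, one mismatch, AAG PAM), scan it, and compare
with randomized backgrounds:

```python
from spacerscan import (PlantingConfig, PlantSpec, generate_host,
                        scan_genome, annotate_hits, make_background,
                        RandomizationConfig)
from spacerscan.sac_sas import CATEGORIES, sac
from spacerscan.pam_motifs import extract_context

host = generate_host(PlantingConfig(genome_length=20_000, n_spacers=4,
                                    plants=[PlantSpec(spacer_id="S1",
                                                      strand="reverse",
                                                      n_mismatches=1,
                                                      pam="AAG")]),
                     seed=42)
hits = scan_genome(host.spacers, host.genome, array=host.array)
print({s: len(h) for s, h in hits.items()})
# {'S1': 19, 'S2': 19, 'S3': 19, 'S4': 19}

best = hits["S1"][0]
print(best.strand, best.score, best.g_start, best.g_end)
# reverse 151 3597 3629        <- the planted protospacer:
print(host.truth.iloc[0][["strand", "start", "end", "pam"]].to_dict())
# {'strand': 'reverse', 'start': 3597, 'end': 3629, 'pam': 'AAG'}
print(extract_context(best, host.genome, "adjacent3"))
# AAG                          <- the planted PAM, read back off the genome

annotated = annotate_hits(hits, host.index)
bg = [annotate_hits(scan_genome(host.spacers, g), host.index)
      for g in make_background(host.genome, host.index,
                               RandomizationConfig(5, seed=0))]
print(sac(annotated, CATEGORIES["all"], 10),
      [sac(b, CATEGORIES["all"], 10) for b in bg])
# 40 [40, 40, 40, 40, 40]      <- 4 spacers x top-10 ranks, real and null
```

Every spacer retains 19 targets: 10 ranked hits per strand are merged into
20 and the spacer's trivial self-alignment at the CRISPR locus (always rank
1 on a host genome) is excluded.

## Command line

```bash
spacerscan simulate --seed 4 --out sim/          # synthetic host + truth
spacerscan run-all  --seed 1 --out results/      # full pipeline, simulated
spacerscan scan --host-fasta sim/host.fasta --host-gff sim/host.gff3 \
    --array-fasta sim/array.fasta --array-start 48215 --array-strand - \
    --out hits.tsv
spacerscan profile  --hits hits.tsv --out profiles.tsv
spacerscan conserve --search-table blast.tsv --subject-fasta subjects.fa \
    --repeat ACGGATCGTTAGCAGATCCGGATGCACA --out calls.tsv
```

`run-all` writes `host_hits.tsv`, `profiles.tsv`, `pam_calls.tsv`,
`score_tests.json` and a `manifest.json`; all outputs carry the seed and a
config hash, and reruns with the same configuration are bit-identical.
File-based runs accept GenBank or FASTA+GFF3 hosts, an array FASTA (repeat
record first), and optional phage multi-FASTA and YAML configuration.

## Layout

| module | responsibility |
| --- | --- |
| `genome_io` | GenBank/FASTA+GFF3 readers, coding/intergenic partition, CRISPR-array parsing |
| `aligner` | Smith–Waterman + Waterman–Eggert k-best declumping (numba kernels), strand merge, self-hit exclusion |
| `hit_classify` | per-hit region, RNA+/RNA−, intergenic category, DC/RC |
| `randomizer` | per-region composition-preserving genome permutation |
| `sac_sas` | SAC/SAS threshold profiles, 3σ bounds, z, paired t, KS/t score-pool tests |
| `pam_motifs` | PAM-position context extraction, 64-triplet counting, Poisson calls, PAM wheel |
| `conservation` | BLAST outfmt-6 post-processing, repeat-flank array-context rule, Poisson interval comparison |
| `synthetic_data` | annotated host/phage generator with planted ground truth |
| `pipeline` / `cli` | orchestration, TSV/JSON reports, `spacerscan` command |

See `docs/methods.md` for the modeling decisions, parameter choices and
known limitations.
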