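# Methods

This note records the model, the parameter choices, the numerical
conventions, and the known limitations of the `spacerscan` pipeline.

## Alignment model

Spacers are aligned by Smith–Waterman local alignment with a NUC44-style
nucleotide scheme: match +5, mismatch −4, and a linear gap penalty of −8
per gapped position. IUPAC ambiguity codes mismatch every base, including
themselves. Suboptimal hits are produced by Waterman–Eggert declumping:
after each optimal alignment is reported, its subject interval is masked
and the full dynamic program is recomputed, yielding the k best
*non-overlapping* alignments (default k = 10 per strand). Reverse-strand
hits are computed against the reverse complement and mapped back onto
direct-strand coordinates, then the two per-strand lists are merged by
descending score (ties: direct strand first, then lower genome start) and
ranked 1..2k.

Tie-breaking inside the DP is part of the reproducibility contract: among
equal-score cells the smallest subject end wins, then the smallest query
end; traceback prefers diagonal over query-gap over subject-gap moves. The
test suite checks the kernels against an independently written DP oracle
that shares only this contract.

### Self-hit handling on host genomes

Every spacer trivially matches its own position in the CRISPR array. Hits
overlapping the array interval are excluded from the retained list.
Operationally, the whole CRISPR locus is masked out of the declumping
search *except* the spacer's own window on the array's strand: the
self-alignment is therefore still found (it validates that the self-hit
ranks first, with the perfect score of 5 × spacer length) and is then
removed, while partial repeat/array matches never consume ranked slots. A
plain post-hoc filter would stochastically delete additional ranked hits
whenever a low-scoring chance alignment landed inside the locus, making
the retained-target count per spacer (19 = 2 × 10 − 1 by construction)
genome-dependent; with locus masking it is deterministic.

### Theoretical alignment start

Local alignments may trim mismatched spacer prefixes. The *theoretical
start* extends the actual alignment start upstream by the unaligned prefix
length (q_start): decreasing coordinate for direct hits, increasing for
reverse hits. On circular genomes the coordinate wraps; on linear genomes
out-of-range starts flag the hit as edge-truncated and exclude it from PAM
analysis. All PAM windows anchor at the theoretical start.

## Functional classification

Gene features (GenBank `gene`/`CDS` or GFF3) are merged strand-agnostically
into coding blocks; the gaps form intergenic regions classified by the
orientation of their flanking genes: divergent (upstream of both),
convergent (downstream of both), upstream (of exactly one). On circular
genomes the gap spanning the origin is a single wrapping region; on linear
genomes terminal gaps use the one available neighbour. Hits are assigned
coding/intergenic by per-base majority (exact ties go to coding, boundary
crossers are flagged), and within coding the RNA category: a hit on a
gene's coding strand means the crRNA-bound target is the template strand,
reachable only as DNA (RNA−); a hit on the template strand puts the target
on the coding strand, reachable as DNA and mRNA (RNA+). DC/RC records the
genome strand of the hit itself.

## Randomization null

The null model preserves local composition exactly: within every coding
block and every intergenic region independently, nucleotides are uniformly
permuted (wrapping regions are permuted across the origin). GC content,
region lengths and the annotation itself are conserved; all positional
signal is destroyed. The default background is 30 replicates; replicate i
is seeded with the pair (seed, i) so any single replicate is reproducible
in isolation. Unannotated phage genomes are shuffled as a single region.

## Statistics

- **SAC/SAS profiles.** For rank threshold k, SAC is the number of hits of
  rank ≤ k satisfying a category predicate, summed over the array; SAS is
  their mean score. Thresholds run 1–19 on hosts (the post-exclusion rank
  range) and 1–20 on phages. Background bounds are the per-threshold
  replicate mean ± 3 sample standard deviations (ddof = 1); per-threshold
  z-scores are reported (z = NaN where the background sd is zero), plus an
  overall paired t-test of the real profile against the background mean
  across the threshold grid.
- **Score pools.** All retained scores of one provenance are pooled and
  compared with a two-sample Kolmogorov–Smirnov test and an independent
  t-test (scipy implementations), with density-normalized histograms on a
  shared grid.
- **PAM motifs.** Three contexts anchor at the theoretical start, read on
  the *targeted* strand (the reverse complement of the hit strand) and
  reported 3'→5' by default: the adjacent 3 nt, the upstream 6 nt, and the
  gap segment between theoretical and actual starts. The adjacent-3 context
  contributes one triplet count; longer contexts count every overlapping
  3-mer window; windows with non-ACGT letters are skipped. Real counts over
  the 64-triplet universe are compared with a Poisson fit to the replicate
  counts: rate λ = mean replicate count, bounds = central Poisson quantiles
  at 99.7% (the two-sided 3σ analogue), p-value from a one-sample t-test of
  the replicate-minus-real differences. The PAM wheel reports relative
  abundances of over-represented motifs; its `literal_score` column emits
  the legacy formula (count − total)/total verbatim — it is negative for
  every motif — alongside the count-fraction reading.
- **Conservation.** External homology searches arrive as 12-column tabular
  output (blastn `-outfmt 6`). The E-value filter is strict (< 10⁻³). A
  subject hit is called in-array iff *both* 40 nt flanks align to the
  CRISPR repeat with score ≥ 25 (minus-strand hits have their flanks
  reverse-complemented and swapped; short flanks are used as-is and flagged
  truncated). Spacer-side vs target-side hit-count distributions are
  compared with Poisson 3σ intervals (total ± 3√total).

A caution on the flank cutoff: under the +5/−4 scheme a score of 25 is a
bare shared 5-mer, which roughly three quarters of random 40-mers reach
against a 28 nt repeat. The single-flank cutoff is therefore permissive by
design; the specificity of the in-array call comes from requiring both
flanks simultaneously, and the score distribution of random flanks falls
steeply far below the perfect-repeat score of 5 × repeat length (the
distribution is exposed via `conservation.flank_score_distribution`). For
the same reason the array parser requires repeat matches to reach 60% of
the perfect repeat score in addition to the cutoff, so a chance shared
word inside a spacer is never mistaken for a repeat copy.

## Synthetic data

`synthetic_data` generates annotated hosts: genes drawn uniformly from a
length range, separated by uniform gaps, in random or patterned
orientation; an array of alternating repeats (28 nt) and spacers (32 nt,
12 by default) embedded mid-genome on a configurable strand; i.i.d.
nucleotide composition everywhere else. Planted protospacers are mutated
spacer copies with configurable strand bias ρ, region-category weights,
per-plant mismatch counts, and an optional PAM triplet written immediately
upstream of the theoretical start in the reporting orientation. A truth
table records every plant. Default host conditions (100 kb circular
chromosome, 600–1200 nt genes, 100–300 nt gaps, ~80% coding) approximate
an E. coli-like setting at desk scale.

The planted-recovery study conditions used in the acceptance tests were
fixed a priori by a power analysis, before the tests were run: a 40 kb
host with 250–350 nt genes and 400–500 nt gaps in alternating "+−"
orientation (so convergent gaps cover roughly 30% of the genome and their
background SAC is large enough for a 3σ *lower* bound to be informative),
96 plants (8 per spacer) with ρ = 0.9, zero convergent weight, mismatch
counts cycling 0/1/2, and an AAG PAM on 80% of plants, against the default
30-replicate background. Under these conditions the expected reverse-minus-
direct SAC excess at k = 10 is ~75 against a background sd of ~11 (z ≈ 7),
and the planted PAM count exceeds its Poisson bound by an order of
magnitude, so the tests probe recovery with wide margins rather than
sitting on a statistical knife edge.

### Generator realism limits

The generator makes no attempt at codon structure, promoter or terminator
sequence, realistic gene-length or GC distributions, repeated elements, or
operon structure; genes never overlap the array, plants never overlap each
other, the array, or origin-wrapping regions; phages are i.i.d. sequence
with optional plants and no annotation. These simplifications are
deliberate: the null model permutes composition within regions, and a
generator whose only structure is the planted signal makes the null exact
by construction.

## Numerical conventions

- Coordinates are 0-based half-open on the direct strand in memory and
  1-based inclusive in written reports.
- Sample standard deviations use ddof = 1 everywhere; backgrounds need at
  least 2 replicates (the pipeline requires this at configuration time).
- Derived seeds use numpy `SeedSequence` entropy pairs (seed, i); all
  randomness in a run descends from the single configured seed, and reruns
  are bit-identical.
- Alignment scores are exact integers; DP matrices use 32-bit integers
  (scores are bounded by 5 × query length ≪ 2³¹).

## Limitations

- The declumping scan recomputes the full DP after each masking step
  (O(k·n·m) per strand); fine at desk scale, but a full-chromosome scan
  with many spacers is minutes, not seconds.
- Statistical calls treat replicate scans as exchangeable with the real
  scan; the pipeline's SAC machinery compares 19 host ranks against 20
  replicate ranks, which is immaterial for profile bounds but means pooled
  score distributions should be compared at matched rank depth and search
  space (the acceptance tests do exactly that).
- The paired t-test across a threshold grid treats thresholds as pairing
  units although neighbouring thresholds are strongly dependent; it is
  reported as a summary alongside the per-threshold z-scores, not as a
  calibrated p-value.
- The Poisson motif model takes λ from the replicate mean without
  accounting for estimation noise in λ; with 30 replicates the effect on
  the 99.7% bounds is small.
- `parse_crispr_array` assumes near-identical repeat copies; highly
  degenerate repeats (score < 60% of perfect) will not be recognized.
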