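"""End-to-end orchestration: scan -> classify -> profiles -> PAM -> tests.

A single RunConfig drives the whole analysis. Inputs are either simulated
(synthetic_data) or read from files (FASTA+GFF3 or GenBank host, array
FASTA + coordinates, phage multi-FASTA). Every output table is TSV with
'#'-prefixed header lines carrying the seed and a config hash; reruns with
the same config and seed are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import aligner, conservation, hit_classify, pam_motifs, randomizer, sac_sas
from .genome_io import (CRISPRArray, Genome, RegionIndex, SpacerScanError,
                        lift_array_to_genome, parse_crispr_array, read_genome)
from .synthetic_data import (PlantingConfig, SyntheticHost, generate_host,
                             generate_phages, write_array_fasta, write_fasta,
                             write_gff3, write_truth)

log = logging.getLogger(__name__)


class ConfigError(SpacerScanError):
    pass


@dataclass
class RunConfig:
    """Flat run configuration; every default is echoed into the manifest."""

    seed: int = 1
    # inputs: either simulate=True or host/array paths
    simulate: bool = True
    host_fasta: str | None = None
    host_gff: str | None = None
    host_genbank: str | None = None
    array_fasta: str | None = None
    array_start: int | None = None
    array_strand: str = "-"
    phage_fasta: str | None = None
    n_phages: int = 0
    phage_length: int = 30_000
    # simulation knobs (used when simulate)
    genome_length: int = 100_000
    n_spacers: int = 12
    spacer_length: int = 32
    repeat_length: int = 28
    # analysis parameters
    k_per_strand: int = 10
    match: int = 5
    mismatch: int = -4
    gap: int = 8
    n_randomizations: int = 30
    sigma_multiple: float = 3.0
    thresholds: tuple[int, ...] = sac_sas.HOST_THRESHOLDS
    pam_level: float = 0.997
    pam_orientation: str = "3to5"
    pam_reference: str | None = None
    # conservation inputs (optional)
    search_table: str | None = None
    subject_fasta: str | None = None

    @property
    def scoring(self) -> aligner.ScoringScheme:
        return aligner.ScoringScheme(self.match, self.mismatch, self.gap)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "thresholds" in data:
            data["thresholds"] = tuple(data["thresholds"])
        return cls(**data)


# ---------------------------------------------------------------------------
# Input loading
# ---------------------------------------------------------------------------

def load_inputs(config: RunConfig) -> tuple[Genome, RegionIndex, CRISPRArray,
                                            list[Genome]]:
    if config.simulate:
        host = generate_host(PlantingConfig(
            genome_length=config.genome_length, n_spacers=config.n_spacers,
            spacer_length=config.spacer_length,
            repeat_length=config.repeat_length,
            array_strand=config.array_strand), seed=config.seed)
        phages = generate_phages(config.n_phages, length=config.phage_length,
                                 seed=config.seed) if config.n_phages else []
        return host.genome, host.index, host.array, phages

    if config.host_genbank:
        genome, features = read_genome(config.host_genbank, "genbank")
    elif config.host_fasta and config.host_gff:
        genome, features = read_genome(config.host_fasta, "fasta+gff3",
                                       gff_path=config.host_gff)
    else:
        raise ConfigError("need host_genbank or host_fasta+host_gff")
    index = RegionIndex(features, len(genome), genome.circular)

    if not config.array_fasta or config.array_start is None:
        raise ConfigError("file-based runs need array_fasta and array_start")
    from .genome_io import read_array_fasta

    arr = read_array_fasta(config.array_fasta)
    locus = arr.repeat_seq + "".join(s.sequence + arr.repeat_seq
                                     for s in arr.spacers)
    parsed = parse_crispr_array(locus, arr.repeat_seq)
    # keep the supplied spacer ids/sequences, lift coordinates onto the genome
    for sp, given in zip(parsed.spacers, arr.spacers):
        if sp.sequence != given.sequence:
            raise ConfigError("array FASTA is inconsistent with its repeat")
    array = lift_array_to_genome(parsed, config.array_start,
                                 config.array_strand, len(genome))

    phages = []
    if config.phage_fasta:
        from Bio import SeqIO

        for rec in SeqIO.parse(config.phage_fasta, "fasta"):
            phages.append(Genome(id=rec.id, sequence=str(rec.seq),
                                 provenance="phage"))
    return genome, index, array, phages


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def scan_and_annotate(spacers, genome: Genome, index: RegionIndex | None,
                      array: CRISPRArray | None, config: RunConfig
                      ) -> dict[str, list]:
    """Scan all spacers against one genome and annotate retained hits.

    ``array`` None (phage/randomized genome) means no locus masking and no
    self-hit exclusion; ``index`` None skips functional annotation.
    """
    hits = aligner.scan_genome(spacers, genome, k=config.k_per_strand,
                               scoring=config.scoring, array=array)
    if index is None:
        return hits
    return hit_classify.annotate_hits(hits, index)


def hits_to_frame(hits_by_spacer: dict[str, Sequence], genome: Genome
                  ) -> pd.DataFrame:
    rows = []
    for sid, hits in hits_by_spacer.items():
        for h in hits:
            hit = getattr(h, "hit", h)
            row = dict(spacer_id=sid, genome_id=genome.id,
                       provenance=genome.provenance, strand=hit.strand,
                       start=hit.g_start + 1, end=hit.g_end, score=hit.score,
                       q_start=hit.q_start,
                       theoretical_start=(hit.theoretical_start + 1
                                          if hit.theoretical_start is not None
                                          else ""),
                       rank=hit.rank)
            if hasattr(h, "region_type"):
                row.update(region_type=h.region_type,
                           rna_category=h.rna_category or "NA",
                           intergenic_category=h.intergenic_category or "NA",
                           genome_strand=h.genome_strand,
                           container_id=h.container_id,
                           boundary_spanning=("yes" if h.boundary_spanning
                                              else "no"))
            rows.append(row)
    return pd.DataFrame(rows)


def profile_frame(real_hits, background_hits_list, config: RunConfig
                  ) -> pd.DataFrame:
    """Tidy per-category SAC/SAS profile table with background bounds."""
    rows = []
    for label, pred in sac_sas.CATEGORIES.items():
        real_p = sac_sas.category_profile(real_hits, pred, config.thresholds,
                                          label)
        reps = [sac_sas.category_profile(bh, pred, config.thresholds, label)
                for bh in background_hits_list]
        bg = sac_sas.background_bounds(reps, config.sigma_multiple)
        sig = sac_sas.profile_significance(real_p, bg)
        for i, k in enumerate(config.thresholds):
            rows.append(dict(
                category=label, threshold=k, sac=real_p.sac[i],
                sas=("" if real_p.sas[i] is None
                     else round(real_p.sas[i], 4)),
                bg_mean=round(bg.mean[i], 4), bg_sd=round(bg.sd[i], 4),
                lower=round(bg.lower[i], 4), upper=round(bg.upper[i], 4),
                z=("" if np.isnan(sig["z"][i]) else round(sig["z"][i], 4)),
                paired_p=("" if sig["p"] is None else sig["p"])))
    return pd.DataFrame(rows)


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig,
               extra: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        fh.write(f"# spacerscan seed={config.seed} "
                 f"config={config.config_hash()}\n")
        for line in extra:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "seed": config.seed,
                      "config_hash": config.config_hash(), "warnings": [],
                      "stages": {}}
    if config.n_randomizations < 2:
        raise ConfigError("n_randomizations must be >= 2 for background sd")

    genome, index, array, phages = load_inputs(config)
    spacers = array.spacers

    # scan + classify: real host
    host_hits = scan_and_annotate(spacers, genome, index, array, config)
    _write_tsv(hits_to_frame(host_hits, genome), outdir / "host_hits.tsv",
               config)
    n_retained = {sid: len(h) for sid, h in host_hits.items()}
    manifest["stages"]["scan_host"] = {
        "retained_per_spacer": n_retained,
        "total": int(sum(n_retained.values()))}

    # background: randomized hosts
    bg_cfg = randomizer.RandomizationConfig(
        n_randomizations=config.n_randomizations, seed=config.seed)
    background = randomizer.make_background(genome, index, bg_cfg)
    bg_hits = [scan_and_annotate(spacers, g, index, None, config)
               for g in background]
    manifest["stages"]["background"] = {"n": len(background)}

    # SAC/SAS profiles per category
    prof = profile_frame(host_hits, bg_hits, config)
    _write_tsv(prof, outdir / "profiles.tsv", config)

    # score pools + distribution tests
    pools = {
        "host": sac_sas.pool_scores([host_hits], "host"),
        "randomized-host": sac_sas.pool_scores(bg_hits, "randomized-host"),
    }
    tests = {"host_vs_randomized": _test_summary(
        pools["host"], pools["randomized-host"])}
    if phages:
        phage_hits = [scan_and_annotate(spacers, p, None, None, config)
                      for p in phages]
        rand_phages = [randomizer.randomize_genome(p, None, [config.seed, 17, i])
                       for i, p in enumerate(phages)]
        rand_hits = [scan_and_annotate(spacers, p, None, None, config)
                     for p in rand_phages]
        pools["phage"] = sac_sas.pool_scores(phage_hits, "phage")
        pools["randomized-phage"] = sac_sas.pool_scores(
            rand_hits, "randomized-phage")
        tests["phage_vs_randomized"] = _test_summary(
            pools["phage"], pools["randomized-phage"])
        tests["host_vs_phage"] = _test_summary(pools["host"], pools["phage"])
    with open(outdir / "score_tests.json", "w") as fh:
        json.dump(tests, fh, indent=2)

    # PAM motifs: real vs replicate tables per context
    pam_rows = []
    over_by_context = {}
    flat_host = [h.hit for hits in host_hits.values() for h in hits]
    flat_bg = [[h.hit for hits in bh.values() for h in hits]
               for bh in bg_hits]
    for kind in pam_motifs.CONTEXTS:
        real_t = pam_motifs.motif_table(flat_host, genome, kind,
                                        config.pam_orientation)
        rep_t = [pam_motifs.motif_table(fb, bg, kind, config.pam_orientation)
                 for fb, bg in zip(flat_bg, background)]
        calls = pam_motifs.motif_calls(real_t, rep_t, config.pam_level)
        over_by_context[kind] = [c.motif for c in calls if c.status == "over"]
        for c in calls:
            pam_rows.append(dict(context=kind, motif=c.motif,
                                 observed=c.observed, lam=round(c.lam, 4),
                                 lower=c.lower, upper=c.upper,
                                 status=c.status, p_value=c.p_value))
        if kind == "adjacent3" and over_by_context[kind]:
            ref = None
            if config.pam_reference:
                ref, _ = pam_motifs.load_pam_reference(config.pam_reference)
            wheel = pam_motifs.pam_wheel(real_t, calls, ref)
            _write_tsv(pd.DataFrame([asdict(w) for w in wheel]),
                       outdir / "pam_wheel.tsv", config)
            if ref:
                manifest["stages"]["pam_overlap_pct"] = \
                    pam_motifs.pam_overlap(calls, ref)
    _write_tsv(pd.DataFrame(pam_rows), outdir / "pam_calls.tsv", config)
    manifest["stages"]["pam"] = {"over": over_by_context}

    # conservation post-processing (optional inputs)
    if config.search_table and config.subject_fasta:
        from Bio import SeqIO

        subjects = {rec.id: str(rec.seq).upper()
                    for rec in SeqIO.parse(config.subject_fasta, "fasta")}
        records = conservation.filter_records(
            conservation.read_search_table(config.search_table))
        calls = [conservation.array_context(row, subjects, array.repeat_seq,
                                            scoring=config.scoring)
                 for _, row in records.iterrows()]
        _write_tsv(pd.DataFrame([asdict(c) for c in calls]),
                   outdir / "conservation_calls.tsv", config)
        manifest["stages"]["conservation"] = {
            "n_records": len(records),
            "n_in_array": sum(c.in_array for c in calls if c.resolved)}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _test_summary(pool_a, pool_b) -> dict:
    res = sac_sas.score_distribution_tests(pool_a, pool_b)
    return {k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in res.items()}


def simulate_to_files(config: PlantingConfig, seed: int, outdir: str | Path
                      ) -> SyntheticHost:
    """Generate a host and write the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    host = generate_host(config, seed)
    write_fasta([host.genome], outdir / "host.fasta")
    write_gff3(host.genome, host.features, outdir / "host.gff3")
    write_array_fasta(host.array, outdir / "array.fasta")
    write_truth(host.truth, outdir / "truth.tsv")
    return host
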