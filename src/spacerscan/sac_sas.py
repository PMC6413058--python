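"""SAC/SAS threshold profiles and their randomized-background statistics.

For a rank threshold k, the SAC value of a category is the number of hits
with rank <= k satisfying the category predicate, summed over the whole
CRISPR array; the SAS value is the mean alignment score of those hits.
Profiles computed on the real genome are compared with the per-threshold
mean +/- a sigma multiple of the sample sd over the randomized replicates,
with per-threshold z-scores and an overall paired t-test across the
threshold grid. Score pools (all retained hit scores of one provenance)
are compared with independent t and Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .hit_classify import AnnotatedHit

Predicate = Callable[[AnnotatedHit], bool]

HOST_THRESHOLDS = tuple(range(1, 20))   # 19 retained targets per spacer
PHAGE_THRESHOLDS = tuple(range(1, 21))  # no self-hit to remove

#: Category predicates of the analysis, keyed by profile label.
CATEGORIES: dict[str, Predicate] = {
    "all": lambda h: True,
    "coding": lambda h: h.region_type == "coding",
    "intergenic": lambda h: h.region_type == "intergenic",
    "divergent": lambda h: h.intergenic_category == "divergent",
    "convergent": lambda h: h.intergenic_category == "convergent",
    "upstream": lambda h: h.intergenic_category == "upstream",
    "RNA+": lambda h: h.rna_category == "RNA+",
    "RNA-": lambda h: h.rna_category == "RNA-",
    "DC": lambda h: h.genome_strand == "DC",
    "RC": lambda h: h.genome_strand == "RC",
}


@dataclass
class CategoryProfile:
    label: str
    thresholds: tuple[int, ...]
    sac: list[int]
    sas: list[float | None]


@dataclass
class BackgroundProfile:
    thresholds: tuple[int, ...]
    mean: np.ndarray
    sd: np.ndarray  # sample (n-1) sd
    sigma_multiple: float
    n_replicates: int

    @property
    def lower(self) -> np.ndarray:
        return self.mean - self.sigma_multiple * self.sd

    @property
    def upper(self) -> np.ndarray:
        return self.mean + self.sigma_multiple * self.sd


@dataclass
class ScorePool:
    label: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size and self.scores.min() <= 0:
            raise ValueError("retained hit scores must be positive")


def sac(hits_by_spacer: Mapping[str, Sequence[AnnotatedHit]],
        predicate: Predicate, k: int) -> int:
    """Sum over spacers of qualifying hits among each spacer's top k ranks."""
    if k < 1:
        raise ValueError("threshold k must be >= 1")
    return sum(1 for hits in hits_by_spacer.values()
               for h in hits if h.rank <= k and predicate(h))


def sas(hits_by_spacer: Mapping[str, Sequence[AnnotatedHit]],
        predicate: Predicate, k: int) -> float | None:
    """Mean score of the hits counted by sac; None when none qualify."""
    scores = [h.score for hits in hits_by_spacer.values()
              for h in hits if h.rank <= k and predicate(h)]
    return float(np.mean(scores)) if scores else None


def category_profile(hits_by_spacer: Mapping[str, Sequence[AnnotatedHit]],
                     predicate: Predicate,
                     thresholds: Sequence[int] = HOST_THRESHOLDS,
                     label: str = "") -> CategoryProfile:
    thresholds = tuple(thresholds)
    return CategoryProfile(
        label=label, thresholds=thresholds,
        sac=[sac(hits_by_spacer, predicate, k) for k in thresholds],
        sas=[sas(hits_by_spacer, predicate, k) for k in thresholds])


def background_bounds(profiles: Sequence[CategoryProfile],
                      sigma_multiple: float = 3.0) -> BackgroundProfile:
    """Normal-fit confidence bounds over randomized replicates, per threshold."""
    if len(profiles) < 2:
        raise ValueError("need >= 2 replicate profiles for an sd estimate")
    grids = {p.thresholds for p in profiles}
    if len(grids) != 1:
        raise ValueError("replicate profiles use differing threshold grids")
    mat = np.array([p.sac for p in profiles], dtype=float)
    return BackgroundProfile(thresholds=profiles[0].thresholds,
                             mean=mat.mean(axis=0), sd=mat.std(axis=0, ddof=1),
                             sigma_multiple=float(sigma_multiple),
                             n_replicates=len(profiles))


def profile_significance(real: CategoryProfile,
                         background: BackgroundProfile) -> dict:
    """Per-threshold z-scores plus an overall paired t-test.

    The pairing unit is the threshold: the real SAC profile is paired with
    the background mean profile across the threshold grid. Thresholds where
    the background sd is zero get z = nan (flagged, not zero).
    """
    if real.thresholds != background.thresholds:
        raise ValueError("threshold grids differ")
    sac_real = np.asarray(real.sac, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (sac_real - background.mean) / background.sd
        z[background.sd == 0] = np.nan
    out: dict = {"thresholds": real.thresholds, "z": z}
    if len(real.thresholds) < 2:
        out["t"] = out["p"] = None
        return out
    diffs = sac_real - background.mean
    if np.allclose(diffs.std(ddof=1), 0.0):
        out["t"] = 0.0 if np.allclose(diffs, 0.0) else np.inf
        out["p"] = 1.0 if np.allclose(diffs, 0.0) else 0.0
    else:
        t, p = stats.ttest_rel(sac_real, background.mean)
        out["t"], out["p"] = float(t), float(p)
    return out


def score_distribution_tests(pool_a: ScorePool, pool_b: ScorePool,
                             bins: int = 30) -> dict:
    """Independent two-sample t-test and two-sample KS test on score pools,
    plus density-normalized histograms on a shared grid."""
    a, b = pool_a.scores, pool_b.scores
    if a.size < 2 or b.size < 2:
        raise ValueError("both pools need >= 2 scores")
    ks = stats.ks_2samp(a, b)
    if a.std() == 0 and b.std() == 0:
        t_stat = t_p = None  # degenerate: t undefined, KS still meaningful
    else:
        t = stats.ttest_ind(a, b)
        t_stat, t_p = float(t.statistic), float(t.pvalue)
    edges = np.histogram_bin_edges(np.concatenate([a, b]), bins=bins)
    return {
        "t_stat": t_stat, "t_p": t_p,
        "ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue),
        "labels": (pool_a.label, pool_b.label),
        "n": (int(a.size), int(b.size)),
        "hist_a": np.histogram(a, bins=edges, density=True)[0],
        "hist_b": np.histogram(b, bins=edges, density=True)[0],
        "edges": edges,
    }


def pool_scores(hits_by_spacer_per_genome: Sequence[Mapping[str, Sequence]],
                label: str) -> ScorePool:
    """Flatten all retained hit scores across spacers and genomes into one
    provenance-labelled pool, ready for distribution comparison."""
    scores = [h.score for per_genome in hits_by_spacer_per_genome
              for hits in per_genome.values() for h in hits]
    return ScorePool(label=label, scores=np.asarray(scores, dtype=float))
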