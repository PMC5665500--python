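"""Synthetic survey populations and the small-sample simulation study.

The original evaluation drew sub-samples from a large multi-country corpus
of field surveys that is not publicly deposited.  This module generates
clustered, approximately normal MUAC populations that emulate that corpus
(configurable intracluster correlation, optional skewness, survey-level
metadata), and reproduces the sub-sampling scheme: 25 clusters drawn at
random, then 1-8 children per cluster, giving sample sizes 25..200; for
simple-random surveys, children are drawn directly.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    GAM_CUTOFF_MM,
    SAM_CUTOFF_MM,
    SurveyDataset,
    SurveyDataError,
    true_prevalence,
)
from .estimators import EstimationError, grid_estimates
from .sdref import SDReference

__all__ = [
    "PopulationSpec",
    "SimulationDesign",
    "generate_population",
    "subsample_clustered",
    "subsample_srs",
    "run_study",
    "RESULT_COLUMNS",
]


@dataclasses.dataclass
class PopulationSpec:
    """Recipe for one synthetic source-survey population.

    MUAC is built as cluster effect + child residual: cluster effects are
    Normal(0, sd^2 * icc); residuals carry the remaining variance
    sd^2 * (1 - icc) and are normal, or skew-normal (shape = ``skewness``)
    moment-corrected so the marginal mean and SD still match the spec.
    """

    n_clusters: int = 40
    children_per_cluster: int = 20
    muac_mean_mm: float = 135.0
    muac_sd_mm: float = 12.5
    icc: float = 0.05
    skewness: float = 0.0
    design: str = "clustered"
    region: str = "east_africa"
    livelihood: str = "agriculture"
    residence: str = "rural"
    date_period: str = "after_2006"
    survey_id: str = "synthetic"
    seed: int | None = None

    def validate(self) -> None:
        problems = []
        if not 0.0 <= self.icc < 1.0:
            problems.append(f"icc must be in [0, 1), got {self.icc}")
        if self.muac_sd_mm <= 0:
            problems.append(f"muac_sd_mm must be positive, got {self.muac_sd_mm}")
        if self.muac_mean_mm <= 0:
            problems.append(f"muac_mean_mm must be positive, got {self.muac_mean_mm}")
        if self.design == "clustered" and self.n_clusters < 25:
            problems.append(
                f"clustered populations need >= 25 clusters, got {self.n_clusters}"
            )
        if self.children_per_cluster < 1:
            problems.append("children_per_cluster must be >= 1")
        if self.design not in ("clustered", "simple_random"):
            problems.append(f"unknown design {self.design!r}")
        if problems:
            raise SurveyDataError("invalid population spec: " + "; ".join(problems))


def _skewnorm_params(shape: float, target_sd: float):
    """loc/scale so skewnorm(shape) has mean 0 and SD ``target_sd``."""
    delta = shape / np.sqrt(1.0 + shape**2)
    scale = target_sd / np.sqrt(1.0 - 2.0 * delta**2 / np.pi)
    loc = -scale * delta * np.sqrt(2.0 / np.pi)
    return loc, scale


def generate_population(
    spec: PopulationSpec, rng: np.random.Generator | None = None
) -> SurveyDataset:
    """Draw one synthetic population survey from its spec (seeded)."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_clusters * spec.children_per_cluster
    sd_between = spec.muac_sd_mm * np.sqrt(spec.icc)
    sd_within = spec.muac_sd_mm * np.sqrt(1.0 - spec.icc)

    cluster_effects = rng.normal(0.0, sd_between, size=spec.n_clusters)
    if spec.skewness == 0.0:
        resid = rng.normal(0.0, sd_within, size=n)
    else:
        loc, scale = _skewnorm_params(spec.skewness, sd_within)
        resid = stats.skewnorm.rvs(
            spec.skewness, loc=loc, scale=scale, size=n, random_state=rng
        )
    muac = (
        spec.muac_mean_mm
        + np.repeat(cluster_effects, spec.children_per_cluster)
        + resid
    )
    if spec.design == "clustered":
        clusters = np.repeat(
            np.array([f"c{j:03d}" for j in range(spec.n_clusters)]),
            spec.children_per_cluster,
        )
    else:
        clusters = None
    return SurveyDataset(
        survey_id=spec.survey_id,
        muac_mm=np.clip(muac, 1.0, None),
        cluster_id=clusters,
        design=spec.design,
        region=spec.region,
        livelihood=spec.livelihood,
        residence=spec.residence,
        date_period=spec.date_period,
    )


@dataclasses.dataclass
class SimulationDesign:
    """Sub-sampling grid: which sample sizes, how many replicates per cell."""

    sample_sizes: tuple[int, ...] = (25, 50, 75, 100, 125, 150, 175, 200)
    reps: int = 100
    n_clusters_sub: int = 25
    max_per_cluster: int = 8

    def __post_init__(self):
        self.sample_sizes = tuple(int(s) for s in self.sample_sizes)
        for s in self.sample_sizes:
            if s % self.n_clusters_sub:
                raise ValueError(
                    f"sample size {s} not divisible by {self.n_clusters_sub} clusters"
                )
            m = s // self.n_clusters_sub
            if not 1 <= m <= self.max_per_cluster:
                raise ValueError(
                    f"sample size {s} needs {m} children per cluster; "
                    f"allowed 1..{self.max_per_cluster}"
                )
        if self.reps < 1:
            raise ValueError("reps must be >= 1")

    def n_subsamples(self, n_populations: int) -> int:
        """Total sub-sampled surveys the study will generate."""
        return n_populations * self.reps * len(self.sample_sizes)


def subsample_clustered(
    src: SurveyDataset,
    target_n: int,
    n_clusters_sub: int = 25,
    rng: np.random.Generator | None = None,
) -> SurveyDataset:
    """Two-stage sub-sample: clusters without replacement, then children.

    Takes ``m = target_n / n_clusters_sub`` children per chosen cluster,
    both stages without replacement.  Clusters holding fewer than m
    children contribute everything; the shortfall is topped up from
    additionally drawn spare clusters so the sample size is exact.
    """
    if src.design != "clustered":
        raise SurveyDataError("source survey is not clustered")
    if target_n % n_clusters_sub:
        raise SurveyDataError(
            f"target_n={target_n} is not a multiple of {n_clusters_sub}"
        )
    rng = np.random.default_rng() if rng is None else rng
    labels = np.unique(src.cluster_id)
    if labels.size < n_clusters_sub:
        raise SurveyDataError(
            f"source has {labels.size} clusters; need >= {n_clusters_sub}"
        )
    m = target_n // n_clusters_sub
    order = rng.permutation(labels)
    chosen, spares = order[:n_clusters_sub], order[n_clusters_sub:]

    take_idx: list[np.ndarray] = []
    shortfall = 0
    for lab in chosen:
        members = np.flatnonzero(src.cluster_id == lab)
        if members.size <= m:
            take_idx.append(members)
            shortfall += m - members.size
        else:
            take_idx.append(rng.choice(members, size=m, replace=False))
    for lab in spares:
        if shortfall == 0:
            break
        members = np.flatnonzero(src.cluster_id == lab)
        take = min(shortfall, m, members.size)
        take_idx.append(rng.choice(members, size=take, replace=False))
        shortfall -= take
    if shortfall:
        raise SurveyDataError(
            f"source exhausted with {shortfall} records still missing for target_n={target_n}"
        )
    idx = np.concatenate(take_idx)
    return src.replace(
        muac_mm=src.muac_mm[idx],
        cluster_id=src.cluster_id[idx],
        survey_id=f"{src.survey_id}:sub{target_n}",
    )


def subsample_srs(
    src: SurveyDataset, target_n: int, rng: np.random.Generator | None = None
) -> SurveyDataset:
    """Simple random sub-sample of ``target_n`` children, without replacement."""
    if src.n < target_n:
        raise SurveyDataError(f"source has {src.n} records; need >= {target_n}")
    rng = np.random.default_rng() if rng is None else rng
    idx = rng.choice(src.n, size=target_n, replace=False)
    return src.replace(
        muac_mm=src.muac_mm[idx],
        cluster_id=None,
        design="simple_random",
        survey_id=f"{src.survey_id}:sub{target_n}",
    )


RESULT_COLUMNS = [
    "pop_id", "region", "livelihood", "residence", "date_period", "design",
    "true_gam", "true_sam", "true_prev", "sample_size", "rep", "method",
    "cutoff_mm", "point", "ci_low", "ci_high", "n",
    "mean_muac_mm", "sd_used_mm", "se_z", "error_code",
]


def run_study(
    populations: Sequence[SurveyDataset],
    design: SimulationDesign,
    methods: tuple[str, ...] = ("classic", "probit_I", "probit_II"),
    sdref: SDReference | None = None,
    cutoffs: tuple[float, ...] = (SAM_CUTOFF_MM, GAM_CUTOFF_MM),
    seed: int = 0,
    n_boot: int = 2000,
    conf: float = 0.95,
    progress: bool = False,
) -> pd.DataFrame:
    """Run the full sub-sampling study; one row per (subsample, method, cutoff).

    Reproducibility: the RNG for cell (population i, sample size j,
    replicate r) is ``SeedSequence(seed, spawn_key=(i, j, r))``, spawned
    into one substream for the sub-sampling draw plus one per method, so
    any single cell can be re-run in isolation and per-method failures do
    not perturb other methods' streams.  Estimator failures are recorded in
    ``error_code`` and the run continues.
    """
    rows: list[tuple] = []
    n_total = design.n_subsamples(len(populations))
    done = 0
    for i_pop, pop in enumerate(populations):
        truths = {c: true_prevalence(pop, c) for c in cutoffs}
        true_gam = true_prevalence(pop, GAM_CUTOFF_MM)
        true_sam = true_prevalence(pop, SAM_CUTOFF_MM)
        meta = (pop.survey_id, pop.region, pop.livelihood, pop.residence,
                pop.date_period, pop.design)
        for i_size, size in enumerate(design.sample_sizes):
            for rep in range(design.reps):
                cell = np.random.SeedSequence(seed, spawn_key=(i_pop, i_size, rep))
                streams = cell.spawn(1 + len(methods))
                sub_rng = np.random.default_rng(streams[0])
                if pop.design == "clustered":
                    sample = subsample_clustered(
                        pop, size, design.n_clusters_sub, rng=sub_rng
                    )
                else:
                    sample = subsample_srs(pop, size, rng=sub_rng)
                for j, method in enumerate(methods):
                    rng = np.random.default_rng(streams[1 + j])
                    try:
                        ests = grid_estimates(
                            sample, (method,), cutoffs, ref=sdref,
                            n_boot=n_boot, conf=conf, rng=rng,
                        )
                    except (EstimationError, SurveyDataError) as exc:
                        for cutoff in cutoffs:
                            rows.append(meta + (
                                true_gam, true_sam, truths[cutoff], size, rep,
                                method, cutoff, np.nan, np.nan, np.nan,
                                sample.n, np.nan, np.nan, np.nan,
                                type(exc).__name__,
                            ))
                        continue
                    for est in ests:
                        rows.append(meta + (
                            true_gam, true_sam, truths[est.cutoff_mm], size, rep,
                            est.method, est.cutoff_mm, est.point, est.ci_low,
                            est.ci_high, est.n, est.mean_muac_mm,
                            est.sd_used_mm, est.se_z, "",
                        ))
                done += 1
                if progress and done % 1000 == 0:
                    print(f"  {done}/{n_total} subsamples", flush=True)
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return df
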