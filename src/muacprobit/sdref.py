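"""Regional MUAC-SD reference database for PROBIT Method I.

Method I parameterises the normal MUAC distribution with the sample mean
but an *external* SD taken from prior surveys in the same geographic
stratum.  The reference stores, per region, the empirical distribution of
prior-survey SDs (weighted by effective sample size) and a bootstrap mean
SD used for the point estimate; confidence-interval replicates draw from
the empirical distribution.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
from scipy import stats

from .data import REGIONS, SurveyDataset, SurveyDataError

__all__ = [
    "RegionEntry",
    "SDReference",
    "survey_sd",
    "effective_sample_size",
    "build_sd_reference",
    "draw_sd",
    "builtin_reference",
    "BUILTIN_REGIONAL_MEAN_SD_MM",
]

#: Published regional mean MUAC SDs (mm) from a large multi-country
#: compilation of field surveys; usable when no prior-survey corpus is at
#: hand.  The full empirical distributions behind these means are not
#: public, so the built-in reference is a point mass per region unless a
#: dispersion is supplied.
BUILTIN_REGIONAL_MEAN_SD_MM = {
    "east_africa": 12.3,
    "west_africa": 12.8,
    "central_south_africa": 13.0,
    "caribbean": 12.8,
    "asia": 12.0,
}


@dataclasses.dataclass
class RegionEntry:
    mean_sd_mm: float
    sds: np.ndarray  # prior-survey SDs (mm)
    weights: np.ndarray  # effective sample sizes

    def __post_init__(self):
        self.sds = np.asarray(self.sds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.sds.size == 0:
            raise ValueError("region entry needs at least one SD")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be strictly positive")
        if self.mean_sd_mm <= 0:
            raise ValueError("mean_sd_mm must be positive")

    @property
    def n_surveys(self) -> int:
        return self.sds.size


class SDReference:
    """Per-region empirical distribution and bootstrap mean of prior-survey SDs."""

    def __init__(self, regions: dict[str, RegionEntry]):
        if not regions:
            raise ValueError("SD reference must cover at least one region")
        self.regions = dict(regions)

    def __contains__(self, region: str) -> bool:
        return region in self.regions

    def _entry(self, region: str) -> RegionEntry:
        try:
            return self.regions[region]
        except KeyError:
            raise KeyError(
                f"region {region!r} absent from SD reference "
                f"(have: {sorted(self.regions)})"
            ) from None

    def mean_sd(self, region: str) -> float:
        return self._entry(region).mean_sd_mm

    def draw(self, region: str, rng: np.random.Generator, size: int | None = None):
        """Sample SD(s) from the region's empirical distribution, ESS-weighted."""
        e = self._entry(region)
        p = e.weights / e.weights.sum()
        return rng.choice(e.sds, size=size, p=p)

    def to_json(self) -> str:
        payload = {
            r: {
                "mean_sd_mm": e.mean_sd_mm,
                "entries": [[float(s), float(w)] for s, w in zip(e.sds, e.weights)],
            }
            for r, e in self.regions.items()
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SDReference":
        payload = json.loads(text)
        regions = {}
        for r, d in payload.items():
            entries = np.asarray(d["entries"], dtype=float).reshape(-1, 2)
            regions[r] = RegionEntry(
                mean_sd_mm=float(d["mean_sd_mm"]),
                sds=entries[:, 0],
                weights=entries[:, 1],
            )
        return cls(regions)


def survey_sd(ds: SurveyDataset) -> float:
    """Sample SD (divisor n-1) of the survey's MUAC, in mm."""
    if ds.n < 2:
        raise SurveyDataError("survey SD needs at least 2 records")
    return float(np.std(ds.muac_mm, ddof=1))


def effective_sample_size(ds: SurveyDataset) -> float:
    """n / DEFF with DEFF = 1 + (mean cluster size - 1) * ICC.

    The intracluster correlation of MUAC is the one-way ANOVA estimate with
    clusters as groups, floored at zero; simple-random surveys have DEFF 1.
    """
    if ds.n == 0:
        raise SurveyDataError("effective sample size of an empty survey")
    if ds.design == "simple_random":
        return float(ds.n)
    labels, inverse = np.unique(ds.cluster_id, return_inverse=True)
    k = labels.size
    if k < 2:
        raise SurveyDataError("clustered survey needs >= 2 clusters for ICC")
    rho = max(0.0, anova_icc(ds.muac_mm, inverse, k))
    m_bar = ds.n / k
    deff = 1.0 + (m_bar - 1.0) * rho
    return float(ds.n / deff)


def anova_icc(values: np.ndarray, group_index: np.ndarray, k: int) -> float:
    """One-way ANOVA intraclass correlation (may be negative; caller floors)."""
    n = values.size
    sizes = np.bincount(group_index, minlength=k).astype(float)
    sums = np.bincount(group_index, weights=values, minlength=k)
    means = sums / sizes
    grand = values.mean()
    ss_between = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(np.sum((values - means[group_index]) ** 2))
    msb = ss_between / (k - 1)
    msw = ss_within / (n - k)
    # ANOVA-balanced "average" cluster size for unequal clusters
    m0 = (n - np.sum(sizes**2) / n) / (k - 1)
    denom = msb + (m0 - 1.0) * msw
    if denom <= 0:
        return 0.0
    return (msb - msw) / denom


def build_sd_reference(
    surveys: list[SurveyDataset],
    n_boot: int = 2000,
    seed: int | np.random.SeedSequence | None = None,
) -> SDReference:
    """Build the regional SD reference from prior surveys.

    Per region: each survey contributes its MUAC SD with weight equal to its
    effective sample size; whole surveys are resampled with replacement,
    probability proportional to weight, ``n_boot`` times; the reference mean
    SD is the mean over replications of the replicate-mean SD.  Regions with
    no surveys are omitted with a warning.
    """
    rng = np.random.default_rng(seed)
    by_region: dict[str, list[tuple[float, float]]] = {r: [] for r in REGIONS}
    for ds in surveys:
        sd = survey_sd(ds)
        if sd <= 0:
            raise SurveyDataError(
                f"survey {ds.survey_id!r} has zero MUAC variance; cannot contribute an SD"
            )
        by_region.setdefault(ds.region, []).append((sd, effective_sample_size(ds)))

    regions: dict[str, RegionEntry] = {}
    for region, pairs in by_region.items():
        if not pairs:
            warnings.warn(f"no surveys for region {region!r}; omitted from reference")
            continue
        sds = np.array([p[0] for p in pairs])
        weights = np.array([p[1] for p in pairs])
        p = weights / weights.sum()
        idx = rng.choice(sds.size, size=(n_boot, sds.size), p=p)
        replicate_means = sds[idx].mean(axis=1)
        regions[region] = RegionEntry(
            mean_sd_mm=float(replicate_means.mean()), sds=sds, weights=weights
        )
    if not regions:
        raise SurveyDataError("no region received any survey")
    return SDReference(regions)


def draw_sd(ref: SDReference, region: str, rng: np.random.Generator) -> float:
    """One SD from the region's empirical distribution (weight-proportional)."""
    return float(ref.draw(region, rng))


def builtin_reference(dispersion_mm: float = 0.0) -> SDReference:
    """The shipped regional reference of mean MUAC SDs.

    With ``dispersion_mm`` = 0 (default) each region is a point mass at its
    published mean, so Method I confidence intervals reflect mean-resampling
    variability only.  A positive dispersion replaces the point mass with
    nine equally weighted normal quantile atoms of that scale around the
    mean, as a stand-in for the unpublished empirical spread.
    """
    regions = {}
    for region, mean in BUILTIN_REGIONAL_MEAN_SD_MM.items():
        if dispersion_mm > 0:
            q = (np.arange(9) + 0.5) / 9
            sds = mean + dispersion_mm * stats.norm.ppf(q)
            weights = np.ones(9)
        else:
            sds = np.array([mean])
            weights = np.array([1.0])
        regions[region] = RegionEntry(mean_sd_mm=mean, sds=sds, weights=weights)
    return SDReference(regions)
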