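"""Prevalence estimators: the classic design-based proportion and two
PROBIT (normal-CDF) estimators, as model/results objects.

The PROBIT approach treats MUAC as a continuous, approximately normal
variable: with mean mu and SD sigma, the prevalence below a cutoff c is
p = Phi(z) with z = (c - mu) / sigma.  Method I takes sigma from an
external regional reference of prior-survey SDs; Method II takes both mu
and sigma from the sample itself.  Confidence intervals for both are built
on the z scale from a cluster bootstrap and back-transformed through Phi.

Usage::

    res = ProbitPrevalenceII(sample).fit(cutoff_mm=125, seed=1)
    print(res.summary())
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Union

import numpy as np
from scipy import stats

from .data import SurveyDataset, SurveyDataError
from .sdref import SDReference

__all__ = [
    "EstimationError",
    "DegenerateSampleError",
    "PrevalenceResults",
    "PrevalenceModel",
    "ClassicPrevalence",
    "ProbitPrevalenceI",
    "ProbitPrevalenceII",
    "probit_point",
    "classic_estimate",
    "probit_I_estimate",
    "probit_II_estimate",
    "probit_bootstrap_ci",
]


class EstimationError(ValueError):
    """An estimator's preconditions are violated."""


class DegenerateSampleError(EstimationError):
    """Sample (or replicate stream) has no usable MUAC variance."""


def probit_point(mean_muac_mm: float, sd_mm: float, cutoff_mm: float) -> float:
    """PROBIT prevalence: Phi((cutoff - mean) / sd), Phi the standard normal CDF."""
    if sd_mm <= 0:
        raise DegenerateSampleError(f"sd_mm must be positive, got {sd_mm}")
    return float(stats.norm.cdf((cutoff_mm - mean_muac_mm) / sd_mm))


@dataclasses.dataclass(frozen=True)
class PrevalenceResults:
    """Point estimate of prevalence with its 95% (or other) confidence interval.

    ``mean_muac_mm``, ``sd_used_mm`` and ``se_z`` are populated by the
    PROBIT methods only; ``se_z`` is the bootstrap standard error of the
    z-score (cutoff - mean)/sd.
    """

    method: str
    cutoff_mm: float
    point: float
    ci_low: float
    ci_high: float
    n: int
    conf: float = 0.95
    mean_muac_mm: float | None = None
    sd_used_mm: float | None = None
    se_z: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.ci_low <= self.point <= self.ci_high <= 1.0):
            raise EstimationError(
                f"invalid CI ordering: [{self.ci_low}, {self.point}, {self.ci_high}]"
            )

    @property
    def half_width(self) -> float:
        """Half the CI length — the 'precision' metric (smaller is better)."""
        return (self.ci_high - self.ci_low) / 2.0

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "cutoff_mm": self.cutoff_mm,
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n,
            "mean_muac_mm": self.mean_muac_mm,
            "sd_used_mm": self.sd_used_mm,
            "se_z": self.se_z,
        }

    def summary(self) -> str:
        lines = [
            f"Prevalence estimate ({self.method})",
            "-" * 44,
            f"cutoff            {self.cutoff_mm:8.1f} mm",
            f"n                 {self.n:8d}",
            f"prevalence        {100 * self.point:8.1f} %",
            f"{100 * self.conf:.0f}% CI            "
            f"[{100 * self.ci_low:5.1f}, {100 * self.ci_high:5.1f}] %",
        ]
        if self.mean_muac_mm is not None:
            lines.append(f"mean MUAC         {self.mean_muac_mm:8.2f} mm")
        if self.sd_used_mm is not None:
            lines.append(f"SD used           {self.sd_used_mm:8.2f} mm")
        if self.se_z is not None:
            lines.append(f"bootstrap SE(z)   {self.se_z:8.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# bootstrap machinery


def _cluster_stats(sample: SurveyDataset):
    labels, inverse = np.unique(sample.cluster_id, return_inverse=True)
    k = labels.size
    sizes = np.bincount(inverse, minlength=k).astype(float)
    sums = np.bincount(inverse, weights=sample.muac_mm, minlength=k)
    sumsq = np.bincount(inverse, weights=sample.muac_mm**2, minlength=k)
    return k, sizes, sums, sumsq, inverse


def bootstrap_moments(
    sample: SurveyDataset, n_boot: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate means and SDs of MUAC under the resampling scheme.

    Clustered samples resample whole clusters with replacement (same number
    of clusters, each carrying all its records); simple-random samples
    resample records.  Returns arrays of shape (n_boot,).
    """
    if sample.design == "clustered":
        k, sizes, sums, sumsq, _ = _cluster_stats(sample)
        if k < 2:
            raise EstimationError("cluster bootstrap needs >= 2 clusters")
        idx = rng.integers(0, k, size=(n_boot, k))
        nb = sizes[idx].sum(axis=1)
        s1 = sums[idx].sum(axis=1)
        s2 = sumsq[idx].sum(axis=1)
        mu = s1 / nb
        var = (s2 - nb * mu**2) / (nb - 1)
    else:
        n = sample.n
        idx = rng.integers(0, n, size=(n_boot, n))
        x = sample.muac_mm[idx]
        mu = x.mean(axis=1)
        var = x.var(axis=1, ddof=1) if n > 1 else np.zeros(n_boot)
    sd = np.sqrt(np.clip(var, 0.0, None))
    return mu, sd


SDSource = Union[float, str, Callable[[int, np.random.Generator], np.ndarray]]


def _replicate_sds(
    sd_source: SDSource, replicate_sd: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    if sd_source == "replicate":
        return replicate_sd
    if callable(sd_source):
        return np.asarray(sd_source(n, rng), dtype=float)
    return np.full(n, float(sd_source))


def probit_bootstrap_ci(
    sample: SurveyDataset,
    sd_source: SDSource,
    cutoff_mm: float,
    n_boot: int = 2000,
    conf: float = 0.95,
    rng: np.random.Generator | None = None,
    z_hat: float | None = None,
    sd_point: float | None = None,
) -> tuple[float, float, float]:
    """Bootstrap CI for a PROBIT prevalence, built on the z scale.

    Each replicate resamples the sample (clusters, or records for SRS),
    pairs the replicate mean with an SD given by ``sd_source`` — a fixed
    value, the string ``"replicate"`` for the resample's own SD, or a
    callable drawing from an SD reference — and forms
    z_b = (cutoff - mean_b)/sd_b.  ``se_z`` is the SD of the z_b; the CI is
    Phi(z_hat -/+ z_crit * se_z).  Replicates with zero SD are redrawn and
    counted; more than 10% redraws raises :class:`DegenerateSampleError`.
    """
    if n_boot < 2:
        raise EstimationError("n_boot must be >= 2")
    rng = np.random.default_rng() if rng is None else rng
    if z_hat is None:
        if sd_point is None:
            raise EstimationError("z_hat or sd_point required")
        z_hat = (cutoff_mm - float(sample.muac_mm.mean())) / sd_point

    mu_b, rep_sd = bootstrap_moments(sample, n_boot, rng)
    sd_b = _replicate_sds(sd_source, rep_sd, n_boot, rng)

    redraws = 0
    max_redraws = 0.1 * n_boot
    bad = sd_b <= 0
    while bad.any():
        redraws += int(bad.sum())
        if redraws > max_redraws:
            raise DegenerateSampleError(
                f"{redraws} zero-SD bootstrap replicates (> 10% of {n_boot})"
            )
        m = int(bad.sum())
        mu_new, sd_new = bootstrap_moments(sample, m, rng)
        mu_b[bad] = mu_new
        sd_b[bad] = _replicate_sds(sd_source, sd_new, m, rng)
        bad = sd_b <= 0

    z_b = (cutoff_mm - mu_b) / sd_b
    se_z = float(np.std(z_b, ddof=1))
    z_crit = stats.norm.ppf(0.5 + conf / 2.0)
    ci_low = float(stats.norm.cdf(z_hat - z_crit * se_z))
    ci_high = float(stats.norm.cdf(z_hat + z_crit * se_z))
    return ci_low, ci_high, se_z


# ---------------------------------------------------------------------------
# models


class PrevalenceModel:
    """Base class: a prevalence estimator bound to one survey sample."""

    method: str = ""

    def __init__(self, sample: SurveyDataset):
        if sample.n == 0:
            raise EstimationError("cannot estimate from an empty sample")
        if np.any(~np.isfinite(sample.muac_mm)):
            raise EstimationError("sample contains missing MUAC; clean it first")
        self.sample = sample

    def fit(self, cutoff_mm: float, **kwargs) -> PrevalenceResults:
        raise NotImplementedError


class ClassicPrevalence(PrevalenceModel):
    """Design-based proportion below the cutoff with survey-adjusted SE.

    Clustered samples use the Taylor-linearised (ratio) variance over
    cluster totals, which reduces to the between-cluster variance of
    cluster proportions for equal cluster sizes; simple-random samples use
    the binomial SE.  The CI is Wald, truncated to [0, 1].
    """

    method = "classic"

    def fit(self, cutoff_mm: float, conf: float = 0.95, **_ignored) -> PrevalenceResults:
        x = self.sample.muac_mm
        cases = (x < cutoff_mm).astype(float)
        p = float(cases.mean())
        n = self.sample.n
        if self.sample.design == "clustered":
            labels, inverse = np.unique(self.sample.cluster_id, return_inverse=True)
            k = labels.size
            if k < 2:
                raise EstimationError("clustered classic SE needs >= 2 clusters")
            m_j = np.bincount(inverse, minlength=k).astype(float)
            y_j = np.bincount(inverse, weights=cases, minlength=k)
            resid = y_j - p * m_j
            se = float(np.sqrt(k / (k - 1) * np.sum(resid**2)) / m_j.sum())
        else:
            se = float(np.sqrt(p * (1.0 - p) / n))
        z_crit = stats.norm.ppf(0.5 + conf / 2.0)
        return PrevalenceResults(
            method=self.method,
            cutoff_mm=cutoff_mm,
            point=p,
            ci_low=max(0.0, p - z_crit * se),
            ci_high=min(1.0, p + z_crit * se),
            n=n,
            conf=conf,
        )


class ProbitPrevalenceI(PrevalenceModel):
    """PROBIT Method I: sample mean MUAC, SD from a regional reference.

    The point estimate uses the reference's bootstrap mean SD for the
    sample's region; CI replicates pair each resampled mean with an SD
    drawn from the region's empirical (ESS-weighted) SD distribution.
    """

    method = "probit_I"

    def __init__(
        self, sample: SurveyDataset, sd_reference: SDReference, region: str | None = None
    ):
        super().__init__(sample)
        self.sd_reference = sd_reference
        self.region = region or sample.region
        if self.region not in sd_reference:
            raise EstimationError(
                f"region {self.region!r} missing from the SD reference"
            )

    def fit(
        self,
        cutoff_mm: float,
        conf: float = 0.95,
        n_boot: int = 2000,
        seed: int | np.random.Generator | None = None,
    ) -> PrevalenceResults:
        rng = np.random.default_rng(seed)
        mean = float(self.sample.muac_mm.mean())
        sd = self.sd_reference.mean_sd(self.region)
        z_hat = (cutoff_mm - mean) / sd
        draw = lambda size, r: self.sd_reference.draw(self.region, r, size)
        ci_low, ci_high, se_z = probit_bootstrap_ci(
            self.sample, draw, cutoff_mm, n_boot=n_boot, conf=conf, rng=rng, z_hat=z_hat
        )
        return PrevalenceResults(
            method=self.method,
            cutoff_mm=cutoff_mm,
            point=float(stats.norm.cdf(z_hat)),
            ci_low=ci_low,
            ci_high=ci_high,
            n=self.sample.n,
            conf=conf,
            mean_muac_mm=mean,
            sd_used_mm=sd,
            se_z=se_z,
        )


class ProbitPrevalenceII(PrevalenceModel):
    """PROBIT Method II: mean and SD both taken from the sample.

    CI replicates recompute both moments on each bootstrap resample.
    """

    method = "probit_II"

    def __init__(self, sample: SurveyDataset):
        super().__init__(sample)
        if sample.n < 2:
            raise EstimationError("PROBIT Method II needs >= 2 records")
        if float(np.std(sample.muac_mm, ddof=1)) <= 0:
            raise DegenerateSampleError("sample MUAC has zero variance")

    def fit(
        self,
        cutoff_mm: float,
        conf: float = 0.95,
        n_boot: int = 2000,
        seed: int | np.random.Generator | None = None,
    ) -> PrevalenceResults:
        rng = np.random.default_rng(seed)
        mean = float(self.sample.muac_mm.mean())
        sd = float(np.std(self.sample.muac_mm, ddof=1))
        z_hat = (cutoff_mm - mean) / sd
        ci_low, ci_high, se_z = probit_bootstrap_ci(
            self.sample, "replicate", cutoff_mm, n_boot=n_boot, conf=conf,
            rng=rng, z_hat=z_hat,
        )
        return PrevalenceResults(
            method=self.method,
            cutoff_mm=cutoff_mm,
            point=float(stats.norm.cdf(z_hat)),
            ci_low=ci_low,
            ci_high=ci_high,
            n=self.sample.n,
            conf=conf,
            mean_muac_mm=mean,
            sd_used_mm=sd,
            se_z=se_z,
        )


# ---------------------------------------------------------------------------
# functional wrappers


def classic_estimate(
    sample: SurveyDataset, cutoff_mm: float, conf: float = 0.95
) -> PrevalenceResults:
    return ClassicPrevalence(sample).fit(cutoff_mm, conf=conf)


def probit_I_estimate(
    sample: SurveyDataset,
    ref: SDReference,
    cutoff_mm: float,
    n_boot: int = 2000,
    seed: int | np.random.Generator | None = None,
    conf: float = 0.95,
) -> PrevalenceResults:
    return ProbitPrevalenceI(sample, ref).fit(cutoff_mm, conf=conf, n_boot=n_boot, seed=seed)


def probit_II_estimate(
    sample: SurveyDataset,
    cutoff_mm: float,
    n_boot: int = 2000,
    seed: int | np.random.Generator | None = None,
    conf: float = 0.95,
) -> PrevalenceResults:
    return ProbitPrevalenceII(sample).fit(cutoff_mm, conf=conf, n_boot=n_boot, seed=seed)


def grid_estimates(
    sample: SurveyDataset,
    methods: tuple[str, ...],
    cutoffs: tuple[float, ...],
    ref: SDReference | None = None,
    n_boot: int = 2000,
    conf: float = 0.95,
    rng: np.random.Generator | None = None,
) -> list[PrevalenceResults]:
    """All (method, cutoff) estimates for one sample, sharing one bootstrap.

    The simulation study calls this instead of the individual estimators: a
    single stream of resample moments (and one stream of reference-SD draws)
    serves both PROBIT methods at every cutoff, which is statistically
    equivalent and much cheaper than independent bootstraps.
    """
    rng = np.random.default_rng() if rng is None else rng
    z_crit = stats.norm.ppf(0.5 + conf / 2.0)
    out: list[PrevalenceResults] = []

    probit_methods = [m for m in methods if m in ("probit_I", "probit_II")]
    mu_b = sd_b = None
    if probit_methods:
        mu_b, sd_b = bootstrap_moments(sample, n_boot, rng)
    mean = float(sample.muac_mm.mean())
    sample_sd = float(np.std(sample.muac_mm, ddof=1)) if sample.n > 1 else 0.0

    for method in methods:
        if method == "classic":
            for cutoff in cutoffs:
                out.append(ClassicPrevalence(sample).fit(cutoff, conf=conf))
            continue
        if method == "probit_I":
            if ref is None:
                raise EstimationError("probit_I requires an SD reference")
            if sample.region not in ref:
                raise EstimationError(f"region {sample.region!r} not in SD reference")
            sd_point = ref.mean_sd(sample.region)
            sds = np.asarray(ref.draw(sample.region, rng, n_boot), dtype=float)
        elif method == "probit_II":
            if sample_sd <= 0:
                raise DegenerateSampleError("sample MUAC has zero variance")
            sd_point = sample_sd
            sds = sd_b
        else:
            raise EstimationError(f"unknown method {method!r}")

        bad = sds <= 0
        redraws = 0
        mu_use = mu_b.copy()
        sds = sds.copy()
        while bad.any():
            redraws += int(bad.sum())
            if redraws > 0.1 * n_boot:
                raise DegenerateSampleError("too many zero-SD bootstrap replicates")
            m = int(bad.sum())
            mu_new, sd_new = bootstrap_moments(sample, m, rng)
            mu_use[bad] = mu_new
            sds[bad] = sd_new if method == "probit_II" else np.asarray(
                ref.draw(sample.region, rng, m), dtype=float
            )
            bad = sds <= 0

        for cutoff in cutoffs:
            z_hat = (cutoff - mean) / sd_point
            z_b = (cutoff - mu_use) / sds
            se_z = float(np.std(z_b, ddof=1))
            out.append(
                PrevalenceResults(
                    method=method,
                    cutoff_mm=cutoff,
                    point=float(stats.norm.cdf(z_hat)),
                    ci_low=float(stats.norm.cdf(z_hat - z_crit * se_z)),
                    ci_high=float(stats.norm.cdf(z_hat + z_crit * se_z)),
                    n=sample.n,
                    conf=conf,
                    mean_muac_mm=mean,
                    sd_used_mm=sd_point,
                    se_z=se_z,
                )
            )
    return out
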