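"""Classic and PROBIT estimators: points, standard errors, bootstrap CIs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from muacprobit import (
    ClassicPrevalence,
    DegenerateSampleError,
    EstimationError,
    ProbitPrevalenceI,
    ProbitPrevalenceII,
    builtin_reference,
    classic_estimate,
    probit_II_estimate,
    probit_I_estimate,
    probit_bootstrap_ci,
    probit_point,
)

from conftest import make_survey


def normal_cdf_by_quadrature(z: float) -> float:
    """Independent oracle: numerically integrate the standard normal density."""
    val, _ = integrate.quad(
        lambda t: np.exp(-(t**2) / 2.0) / np.sqrt(2.0 * np.pi), -12.0, z
    )
    return val


def exact_moments_sample(mean, sd, n=40, seed=0, **meta):
    """SRS sample rescaled to the exact target mean and SD."""
    x = np.random.default_rng(seed).normal(0, 1, n)
    x = (x - x.mean()) / x.std(ddof=1)
    return make_survey(mean + sd * x, **meta)


class TestProbitPoint:
    def test_symmetry_exact_half(self):
        assert probit_point(125.0, 12.0, 125.0) == 0.5

    @pytest.mark.parametrize(
        "mean, sd, cutoff, expected",
        [(135, 12.0, 125, 0.2023), (137, 12.3, 115, 0.0368), (130, 13.0, 115, 0.1243)],
    )
    def test_reference_values(self, mean, sd, cutoff, expected):
        assert probit_point(mean, sd, cutoff) == pytest.approx(expected, abs=5e-5)

    def test_matches_quadrature_oracle_on_grid(self):
        for mean in (120.0, 131.3, 140.0, 145.0):
            for sd in (11.0, 12.5, 13.0):
                for cutoff in (115.0, 125.0, 135.0):
                    z = (cutoff - mean) / sd
                    assert probit_point(mean, sd, cutoff) == pytest.approx(
                        normal_cdf_by_quadrature(z), abs=1e-6
                    )

    def test_degenerate_sd_rejected(self):
        with pytest.raises(DegenerateSampleError):
            probit_point(135, 0.0, 125)

    def test_monotone_in_cutoff_and_mean(self):
        cutoffs = np.linspace(100, 160, 25)
        p = [probit_point(135, 12.5, c) for c in cutoffs]
        assert np.all(np.diff(p) > 0)
        means = np.linspace(110, 160, 25)
        p = [probit_point(m, 12.5, 125) for m in means]
        assert np.all(np.diff(p) < 0)


class TestClassicEstimate:
    def test_zero_between_cluster_variance(self):
        ds = make_survey([110, 130, 120, 140], clusters=["A", "A", "B", "B"])
        est = classic_estimate(ds, 125)
        assert est.point == 0.5
        assert est.ci_low == est.ci_high == 0.5

    def test_two_cluster_hand_formula_exact(self):
        # equal-size clusters: SE^2 = (1/(k(k-1))) * sum (p_j - pbar)^2
        ds = make_survey(
            [110, 115, 130, 120, 130, 140],
            clusters=["A", "A", "A", "B", "B", "B"],
        )
        est = classic_estimate(ds, 125)
        p_a, p_b = 2 / 3, 1 / 3
        se_hand = np.sqrt(((p_a - 0.5) ** 2 + (p_b - 0.5) ** 2) / (2 * 1))
        assert est.point == 0.5
        z = stats.norm.ppf(0.975)
        assert est.ci_high - est.point == pytest.approx(z * se_hand, abs=1e-12)
        assert est.point - est.ci_low == pytest.approx(z * se_hand, abs=1e-12)

    def test_srs_binomial_se(self):
        est = classic_estimate(make_survey([110, 130, 120, 140]), 125)
        assert est.point == 0.5
        assert est.ci_low == pytest.approx(0.5 - stats.norm.ppf(0.975) * 0.25, abs=1e-9)
        assert est.ci_high == pytest.approx(0.5 + stats.norm.ppf(0.975) * 0.25, abs=1e-9)

    def test_truncation_at_zero(self):
        est = classic_estimate(make_survey([130, 140, 150]), 125)
        assert est.point == 0.0 and est.ci_low == 0.0

    def test_srs_matches_independent_formula(self, rng):
        x = rng.normal(130, 12, 150)
        est = classic_estimate(make_survey(x), 125)
        p = np.mean(x < 125)
        se = np.sqrt(p * (1 - p) / 150)
        assert est.ci_high - est.ci_low == pytest.approx(
            2 * stats.norm.ppf(0.975) * se, abs=1e-12
        )

    def test_single_cluster_rejected(self):
        ds = make_survey([120, 130], clusters=["A", "A"])
        with pytest.raises(EstimationError):
            classic_estimate(ds, 125)


class TestProbitII:
    def test_point_when_mean_equals_cutoff(self):
        ds = make_survey([113, 117, 123, 127, 133, 137])
        est = ProbitPrevalenceII(ds).fit(125.0, n_boot=100, seed=0)
        assert est.point == 0.5
        # n-1 SD of {113,117,123,127,133,137}: sqrt(424/5)
        assert est.sd_used_mm == pytest.approx(np.sqrt(424 / 5), abs=1e-9)

    def test_point_uses_sample_moments(self):
        ds = exact_moments_sample(130.0, 13.0)
        est = probit_II_estimate(ds, 115.0, n_boot=100, seed=0)
        assert est.point == pytest.approx(0.1243, abs=5e-5)

    def test_seed_stability_of_ci(self):
        ds = exact_moments_sample(135.0, 12.5, n=120)
        a = probit_II_estimate(ds, 125.0, n_boot=2000, seed=1)
        b = probit_II_estimate(ds, 125.0, n_boot=2000, seed=2)
        assert a.point == b.point
        assert abs(a.ci_low - b.ci_low) < 0.01
        assert abs(a.ci_high - b.ci_high) < 0.01

    def test_zero_variance_sample_rejected(self):
        with pytest.raises(DegenerateSampleError):
            ProbitPrevalenceII(make_survey([125.0] * 10))

    def test_too_many_degenerate_replicates_rejected(self):
        # 2 of 3 clusters are constant at the same value: ~30% of cluster
        # resamples carry zero SD, beyond the 10% redraw allowance
        ds = make_survey(
            [125, 125, 125, 125, 130, 131],
            clusters=["A", "A", "B", "B", "C", "C"],
        )
        with pytest.raises(DegenerateSampleError):
            probit_II_estimate(ds, 125, n_boot=400, seed=0)


class TestProbitI:
    def test_point_with_builtin_asia_sd(self):
        ds = exact_moments_sample(135.0, 11.0, region="asia")
        est = probit_I_estimate(ds, builtin_reference(), 125.0, n_boot=100, seed=0)
        assert est.sd_used_mm == 12.0
        assert est.point == pytest.approx(0.2023, abs=5e-5)

    def test_singleton_reference_matches_probit_point(self):
        ds = exact_moments_sample(132.0, 12.5, region="east_africa")
        est = probit_I_estimate(ds, builtin_reference(), 125.0, n_boot=200, seed=3)
        assert est.point == probit_point(132.0, 12.3, 125.0)

    def test_deterministic_under_seed(self):
        ds = exact_moments_sample(135.0, 12.5, n=100, region="west_africa")
        a = probit_I_estimate(ds, builtin_reference(), 125.0, n_boot=500, seed=11)
        b = probit_I_estimate(ds, builtin_reference(), 125.0, n_boot=500, seed=11)
        assert (a.ci_low, a.ci_high, a.se_z) == (b.ci_low, b.ci_high, b.se_z)

    def test_missing_region_rejected(self):
        from muacprobit.sdref import RegionEntry, SDReference

        ref = SDReference({"asia": RegionEntry(12.0, [12.0], [1.0])})
        ds = exact_moments_sample(135.0, 12.5, region="east_africa")
        with pytest.raises(EstimationError, match="east_africa"):
            ProbitPrevalenceI(ds, ref)


class TestProbitBootstrapCi:
    def test_collapses_without_resampling_variance(self, rng):
        # all clusters identical and a constant SD: se_z = 0, CI = point
        ds = make_survey([120, 140] * 4, clusters=list("AABBCCDD"))
        lo, hi, se_z = probit_bootstrap_ci(
            ds, 12.5, 125.0, n_boot=200, rng=rng, sd_point=12.5
        )
        assert se_z == 0.0
        assert lo == hi == pytest.approx(probit_point(130.0, 12.5, 125.0), abs=1e-12)

    def test_fixed_sd_se_matches_sigma_over_sqrt_n(self):
        rng = np.random.default_rng(202)
        x = rng.normal(135, 12, 200)
        ds = make_survey(x)
        _, _, se_z = probit_bootstrap_ci(
            ds, 12.0, 125.0, n_boot=2000, rng=np.random.default_rng(7), sd_point=12.0
        )
        # bootstrap SE of the mean ~ sigma/sqrt(n); on the z scale divide by sigma
        assert se_z == pytest.approx(x.std(ddof=0) / np.sqrt(200) / 12.0, rel=0.15)

    def test_transform_consistency(self, rng):
        ds = make_survey(rng.normal(133, 12, 80))
        sd = float(np.std(ds.muac_mm, ddof=1))
        z_hat = (125.0 - ds.muac_mm.mean()) / sd
        lo, hi, se_z = probit_bootstrap_ci(
            ds, "replicate", 125.0, n_boot=500, rng=rng, z_hat=z_hat
        )
        z_crit = stats.norm.ppf(0.975)
        assert stats.norm.ppf(lo) == pytest.approx(z_hat - z_crit * se_z, abs=1e-9)
        assert stats.norm.ppf(hi) == pytest.approx(z_hat + z_crit * se_z, abs=1e-9)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    data=st.lists(st.floats(100, 180), min_size=8, max_size=24),
    cutoff=st.sampled_from([115.0, 125.0, 135.0]),
    seed=st.integers(0, 1000),
)
def test_ci_ordering_and_containment_fuzzed(data, cutoff, seed):
    """Every estimator yields 0 <= lo <= point <= hi <= 1 on arbitrary samples."""
    k = 4
    clusters = [f"c{i % k}" for i in range(len(data))]
    ds = make_survey(data, clusters=clusters)
    ests = [classic_estimate(ds, cutoff)]
    if np.std(ds.muac_mm, ddof=1) > 0:
        try:
            ests.append(probit_II_estimate(ds, cutoff, n_boot=50, seed=seed))
        except DegenerateSampleError:
            pass
        ests.append(
            probit_I_estimate(ds, builtin_reference(), cutoff, n_boot=50, seed=seed)
        )
    for est in ests:
        assert 0.0 <= est.ci_low <= est.point <= est.ci_high <= 1.0


def test_grid_estimates_match_standalone(clustered_population, rng):
    from muacprobit.estimators import grid_estimates
    from muacprobit.simulate import subsample_clustered

    sample = subsample_clustered(clustered_population, 100, rng=rng)
    ref = builtin_reference()
    grid = grid_estimates(
        sample, ("classic", "probit_I", "probit_II"), (115.0, 125.0),
        ref=ref, n_boot=300, rng=np.random.default_rng(5),
    )
    assert len(grid) == 6
    by_key = {(g.method, g.cutoff_mm): g for g in grid}
    # classic rows are exactly the standalone classic estimates
    for c in (115.0, 125.0):
        st_est = classic_estimate(sample, c)
        assert by_key[("classic", c)].point == st_est.point
        assert by_key[("classic", c)].ci_low == st_est.ci_low
    # probit points agree with standalone fits (points are bootstrap-free)
    assert by_key[("probit_II", 125.0)].point == probit_II_estimate(
        sample, 125.0, n_boot=10, seed=0
    ).point
    assert by_key[("probit_I", 115.0)].point == probit_I_estimate(
        sample, ref, 115.0, n_boot=10, seed=0
    ).point
    for g in grid:
        assert 0.0 <= g.ci_low <= g.point <= g.ci_high <= 1.0
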