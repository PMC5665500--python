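import numpy as np
import pytest

from muacprobit import PopulationSpec, SurveyDataset, generate_population


def make_survey(muac, clusters=None, **meta):
    """Small survey from literal values; clustered iff cluster labels given."""
    if clusters is not None:
        return SurveyDataset(
            survey_id=meta.pop("survey_id", "toy"),
            muac_mm=np.asarray(muac, dtype=float),
            cluster_id=np.asarray(clusters),
            design="clustered",
            **meta,
        )
    return SurveyDataset(
        survey_id=meta.pop("survey_id", "toy"),
        muac_mm=np.asarray(muac, dtype=float),
        design="simple_random",
        **meta,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clustered_population():
    """One seeded synthetic clustered population (40 clusters x 20 children)."""
    return generate_population(PopulationSpec(survey_id="pop0", seed=2024))


@pytest.fixture(scope="session")
def srs_population():
    spec = PopulationSpec(
        survey_id="srs0", design="simple_random", n_clusters=50,
        children_per_cluster=20, seed=77,
    )
    return generate_population(spec)
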