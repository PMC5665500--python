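"""Reference evaluation run: calibration of all three estimators on
synthetic normal clustered populations.

This is the package's standard benchmark: 50 populations (mean MUAC
135 mm, SD 12.5 mm, intracluster correlation 0.05, 40 clusters of 20
children), the full sample-size grid 25..200 with 100 replicates per
cell, and an SD reference for Method I built from 30 further synthetic
prior surveys drawn from the same regime.  Bootstrap replications are
held at 500 per interval, which keeps the full run around two minutes on
one core while leaving the bootstrap SE noise well below the metric
tolerances of interest.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data import GAM_CUTOFF_MM, SAM_CUTOFF_MM
from .sdref import SDReference, build_sd_reference
from .simulate import PopulationSpec, SimulationDesign, generate_population, run_study

__all__ = ["CalibrationStudy", "run_calibration_study"]


@dataclasses.dataclass
class CalibrationStudy:
    results: pd.DataFrame
    sdref: SDReference
    design: SimulationDesign
    n_populations: int
    seed: int


def run_calibration_study(
    seed: int = 1,
    n_populations: int = 50,
    reps: int = 100,
    n_boot: int = 500,
    n_reference_surveys: int = 30,
    sample_sizes: tuple[int, ...] = (25, 50, 75, 100, 125, 150, 175, 200),
    muac_mean_mm: float = 135.0,
    muac_sd_mm: float = 12.5,
    icc: float = 0.05,
    progress: bool = False,
) -> CalibrationStudy:
    """Run the standard calibration study (seeded, deterministic).

    Substreams are spawned from the master seed: ``(0, i)`` for population
    i, ``(3, i)`` for prior survey i of the SD reference, ``(1,)`` for the
    reference bootstrap, and the study cells as in :func:`run_study`.
    """

    def spec(i: int, sid: str) -> PopulationSpec:
        return PopulationSpec(
            muac_mean_mm=muac_mean_mm,
            muac_sd_mm=muac_sd_mm,
            icc=icc,
            survey_id=sid,
            region="east_africa",
        )

    populations = [
        generate_population(
            spec(i, f"pop{i:03d}"),
            rng=np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0, i))),
        )
        for i in range(n_populations)
    ]
    prior_surveys = [
        generate_population(
            spec(i, f"prior{i:03d}"),
            rng=np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3, i))),
        )
        for i in range(n_reference_surveys)
    ]
    sdref = build_sd_reference(
        prior_surveys, n_boot=2000, seed=np.random.SeedSequence(seed, spawn_key=(1,))
    )
    design = SimulationDesign(sample_sizes=sample_sizes, reps=reps)
    results = run_study(
        populations,
        design,
        methods=("classic", "probit_I", "probit_II"),
        sdref=sdref,
        cutoffs=(SAM_CUTOFF_MM, GAM_CUTOFF_MM),
        seed=seed,
        n_boot=n_boot,
        progress=progress,
    )
    return CalibrationStudy(
        results=results,
        sdref=sdref,
        design=design,
        n_populations=n_populations,
        seed=seed,
    )
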