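"""Child-level MUAC survey data: containers, CSV I/O, cleaning, true prevalence.

A survey is a set of child records, each carrying a mid-upper arm
circumference (MUAC, mm) and, for two-stage cluster surveys, a cluster
label.  A survey can play two roles: a *population* (the "true" prevalence
is read off it directly) or a *sample* handed to an estimator.
"""

from __future__ import annotations

import dataclasses
import json
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REGIONS",
    "LIVELIHOODS",
    "RESIDENCES",
    "DATE_PERIODS",
    "DEFAULT_BOUNDS",
    "GAM_CUTOFF_MM",
    "SAM_CUTOFF_MM",
    "ChildRecord",
    "SurveyDataset",
    "CleaningReport",
    "SurveyDataError",
    "read_survey_csv",
    "clean_records",
    "true_prevalence",
]

REGIONS = ("east_africa", "west_africa", "central_south_africa", "caribbean", "asia")
LIVELIHOODS = ("agriculture", "agro_pastoral", "pastoral", "other")
RESIDENCES = ("rural", "urban", "displaced", "other")
DATE_PERIODS = ("before_2006", "after_2006")

#: Fixed-range plausibility bounds (mm) for MUAC in children under five,
#: SMART-style flagging.  Configurable wherever cleaning is invoked.
DEFAULT_BOUNDS = (80.0, 220.0)

GAM_CUTOFF_MM = 125.0
SAM_CUTOFF_MM = 115.0


class SurveyDataError(ValueError):
    """Raised on malformed, empty or internally inconsistent survey data."""


class ChildRecord(NamedTuple):
    """One child's measurement.  ``cluster_id`` is None for simple-random surveys."""

    muac_mm: float
    cluster_id: str | None = None
    survey_id: str = ""


@dataclasses.dataclass
class SurveyDataset:
    """A survey: MUAC measurements plus design metadata.

    Parameters
    ----------
    survey_id : str
        Opaque label shared by all records.
    muac_mm : ndarray of float
        MUAC per child, millimetres.  NaN allowed before cleaning only.
    cluster_id : ndarray of str, or None
        Cluster membership per child; None for simple-random surveys.
    design : {'simple_random', 'clustered'}
    region, livelihood, residence, date_period : str
        Survey-level metadata used for stratified SD references and the
        bias regression.
    """

    survey_id: str
    muac_mm: np.ndarray
    cluster_id: np.ndarray | None = None
    design: str = "simple_random"
    region: str = "east_africa"
    livelihood: str = "agriculture"
    residence: str = "rural"
    date_period: str = "after_2006"

    def __post_init__(self) -> None:
        self.muac_mm = np.asarray(self.muac_mm, dtype=float)
        if self.muac_mm.ndim != 1:
            raise SurveyDataError("muac_mm must be one-dimensional")
        finite = self.muac_mm[np.isfinite(self.muac_mm)]
        if np.any(finite <= 0):
            raise SurveyDataError("muac_mm values must be strictly positive")
        if self.design not in ("simple_random", "clustered"):
            raise SurveyDataError(f"unknown design {self.design!r}")
        if self.design == "clustered":
            if self.cluster_id is None:
                raise SurveyDataError("clustered survey requires cluster ids")
            self.cluster_id = np.asarray(self.cluster_id)
            if self.cluster_id.shape != self.muac_mm.shape:
                raise SurveyDataError("cluster_id length must match muac_mm")
        else:
            self.cluster_id = None
        if self.region not in REGIONS:
            raise SurveyDataError(f"unknown region {self.region!r}")

    @property
    def n(self) -> int:
        return self.muac_mm.size

    @property
    def n_clusters(self) -> int:
        if self.cluster_id is None:
            return 0
        return len(np.unique(self.cluster_id))

    def validate_source(self, min_clusters: int = 25) -> None:
        """Check the eligibility rules for a survey used as a population.

        Clustered source surveys must hold at least ``min_clusters`` distinct
        clusters; samples drawn *from* a source are exempt.
        """
        if self.n == 0:
            raise SurveyDataError(f"survey {self.survey_id!r} is empty")
        if self.design == "clustered" and self.n_clusters < min_clusters:
            raise SurveyDataError(
                f"survey {self.survey_id!r} has {self.n_clusters} clusters; "
                f"eligible cluster surveys need >= {min_clusters}"
            )

    @classmethod
    def from_records(cls, records: Sequence[ChildRecord], **meta) -> "SurveyDataset":
        muac = np.array([r.muac_mm for r in records], dtype=float)
        clusters = [r.cluster_id for r in records]
        survey_id = meta.pop("survey_id", records[0].survey_id if records else "")
        if any(c is not None for c in clusters):
            meta.setdefault("design", "clustered")
            cl = np.array(["" if c is None else str(c) for c in clusters])
        else:
            meta.setdefault("design", "simple_random")
            cl = None
        return cls(survey_id=survey_id, muac_mm=muac, cluster_id=cl, **meta)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "survey_id": self.survey_id,
                "cluster_id": self.cluster_id if self.cluster_id is not None else "",
                "muac_mm": self.muac_mm,
                "region": self.region,
                "livelihood": self.livelihood,
                "residence": self.residence,
                "design": self.design,
                "date_period": self.date_period,
            }
        )
        return df

    def replace(self, **changes) -> "SurveyDataset":
        return dataclasses.replace(self, **changes)


@dataclasses.dataclass(frozen=True)
class CleaningReport:
    """Outcome of plausibility-range cleaning."""

    n_input: int
    n_excluded: int
    bounds_used: tuple[float, float]

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_excluded

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_excluded": self.n_excluded,
                "bounds_used": list(self.bounds_used),
            }
        )


DEFAULT_SCHEMA = {
    "survey_id": "survey_id",
    "cluster_id": "cluster_id",
    "muac_mm": "muac_mm",
    "region": "region",
    "livelihood": "livelihood",
    "residence": "residence",
    "design": "design",
    "date_period": "date_period",
}


def read_survey_csv(path, schema: dict | None = None) -> SurveyDataset:
    """Read one survey from a child-level CSV.

    ``schema`` remaps canonical column names to the file's columns.  Design
    is inferred from the presence of a non-empty cluster column unless a
    ``design`` column overrides it.  Raises :class:`SurveyDataError` on a
    missing MUAC column or a non-numeric MUAC value (naming the row).
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    muac_col = schema["muac_mm"]
    if muac_col not in df.columns:
        raise SurveyDataError(f"required column {muac_col!r} missing from {path}")

    muac = np.empty(len(df), dtype=float)
    for i, raw in enumerate(df[muac_col]):
        raw = raw.strip()
        if raw == "":
            muac[i] = np.nan
            continue
        try:
            muac[i] = float(raw)
        except ValueError:
            raise SurveyDataError(
                f"non-numeric MUAC value {raw!r} in row {i + 1} of {path}"
            ) from None

    cluster_col = schema["cluster_id"]
    clusters = None
    if cluster_col in df.columns and (df[cluster_col].str.strip() != "").any():
        clusters = df[cluster_col].str.strip().to_numpy()

    def _meta(key: str, default: str) -> str:
        col = schema[key]
        if col in df.columns and len(df) and df[col].iloc[0].strip():
            return df[col].iloc[0].strip()
        return default

    design = _meta("design", "clustered" if clusters is not None else "simple_random")
    if design == "simple_random":
        clusters = None
    return SurveyDataset(
        survey_id=_meta("survey_id", str(path)),
        muac_mm=muac,
        cluster_id=clusters,
        design=design,
        region=_meta("region", "east_africa"),
        livelihood=_meta("livelihood", "agriculture"),
        residence=_meta("residence", "rural"),
        date_period=_meta("date_period", "after_2006"),
    )


def clean_records(
    ds: SurveyDataset, bounds: tuple[float, float] = DEFAULT_BOUNDS
) -> tuple[SurveyDataset, CleaningReport]:
    """Drop records with implausible or missing MUAC.

    Keeps exactly the records with ``low <= muac_mm <= high``; missing MUAC
    counts as excluded.  Raises if nothing survives.
    """
    low, high = bounds
    if not low < high:
        raise ValueError(f"bounds must satisfy low < high, got {bounds}")
    keep = (ds.muac_mm >= low) & (ds.muac_mm <= high)  # NaN compares False
    report = CleaningReport(
        n_input=ds.n, n_excluded=int(ds.n - keep.sum()), bounds_used=(low, high)
    )
    if not keep.any():
        raise SurveyDataError(
            f"cleaning survey {ds.survey_id!r} with bounds {bounds} excluded all records"
        )
    cleaned = ds.replace(
        muac_mm=ds.muac_mm[keep],
        cluster_id=ds.cluster_id[keep] if ds.cluster_id is not None else None,
    )
    return cleaned, report


def true_prevalence(ds: SurveyDataset, cutoff_mm: float) -> float:
    """Population prevalence: proportion of children strictly below the cutoff.

    A child exactly at the cutoff is not a case (case definitions are
    MUAC < 115 mm for SAM and MUAC < 125 mm for GAM).
    """
    if ds.n == 0:
        raise SurveyDataError("cannot compute prevalence of an empty survey")
    return float(np.mean(ds.muac_mm < cutoff_mm))
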