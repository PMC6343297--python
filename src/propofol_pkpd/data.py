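"""Longitudinal trial data model and event-table CSV I/O.

A study dataset is a set of subjects, each with covariates, a dosing
schedule and multi-type observations (blood propofol concentration,
BIS, cAAI).  On disk the dataset is a single event table in the
pharmacometric convention: one row per dose or observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .params import PKParameters
from .pk import DoseEvent

#: Lower limit of quantification of the propofol assay, mg/L.
LLOQ = 0.005

OBS_TYPES = ("conc", "BIS", "cAAI")

COLUMNS = [
    "id",
    "time",
    "event",
    "amount",
    "duration",
    "dv",
    "dvtype",
    "weight",
    "age",
    "sex",
    "remi_rate",
    "below_loq",
]


class DatasetError(ValueError):
    """Malformed event table or dataset."""


@dataclass(frozen=True)
class Observation:
    """One measured value: concentration (mg/L) or index (BIS/cAAI units)."""

    time: float
    value: float
    obs_type: str
    below_loq: bool = False

    def __post_init__(self) -> None:
        if self.time < 0.0:
            raise DatasetError(f"observation time must be >= 0, got {self.time}")
        if self.obs_type not in OBS_TYPES:
            raise DatasetError(f"unknown observation type {self.obs_type!r}; expected one of {OBS_TYPES}")


@dataclass
class Subject:
    """One trial participant: covariates, dosing schedule, observations."""

    id: str
    weight: float
    age: float
    sex: str
    remi_rate: float
    doses: list[DoseEvent] = field(default_factory=list)
    observations: list[Observation] = field(default_factory=list)
    #: Individual PK parameters, set by the sequential PD step.
    pk_params: Optional[PKParameters] = None

    def obs_of_type(self, obs_type: str, exclude_below_loq: bool = True) -> list[Observation]:
        obs = [o for o in self.observations if o.obs_type == obs_type]
        if exclude_below_loq:
            obs = [o for o in obs if not o.below_loq]
        return sorted(obs, key=lambda o: o.time)

    def with_pk_params(self, pk: PKParameters) -> "Subject":
        return replace(self, pk_params=pk)


@dataclass
class StudyDataset:
    """Collection of subjects forming one (real or synthetic) trial."""

    subjects: list[Subject]

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def subject(self, sid: str) -> Subject:
        for s in self.subjects:
            if s.id == sid:
                return s
        raise KeyError(sid)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.subjects]

    def covariate_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [s.id for s in self.subjects],
                "weight": [s.weight for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "sex": [s.sex for s in self.subjects],
                "remi_rate": [s.remi_rate for s in self.subjects],
            }
        ).set_index("id")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            base = dict(id=s.id, weight=s.weight, age=s.age, sex=s.sex, remi_rate=s.remi_rate)
            for d in s.doses:
                rows.append(
                    dict(
                        base,
                        time=d.start,
                        event="dose",
                        amount=d.amount,
                        duration=d.duration,
                        dv=np.nan,
                        dvtype="",
                        below_loq=False,
                    )
                )
            for o in s.observations:
                rows.append(
                    dict(
                        base,
                        time=o.time,
                        event="observation",
                        amount=np.nan,
                        duration=np.nan,
                        dv=o.value,
                        dvtype=o.obs_type,
                        below_loq=o.below_loq,
                    )
                )
        df = pd.DataFrame(rows, columns=COLUMNS)
        return df.sort_values(["id", "time", "event"], kind="stable").reset_index(drop=True)


def write_dataset(dataset: StudyDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False, float_format="%.10g")


def dataset_from_frame(df: pd.DataFrame) -> StudyDataset:
    missing = [c for c in COLUMNS if c not in df.columns and c != "below_loq"]
    if missing:
        raise DatasetError(f"event table missing required columns: {missing}")
    subjects: dict[str, Subject] = {}
    for idx, row in df.iterrows():
        sid = str(row["id"])
        if float(row["time"]) < 0:
            raise DatasetError(f"row {idx}: negative time {row['time']}")
        if sid not in subjects:
            subjects[sid] = Subject(
                id=sid,
                weight=float(row["weight"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                remi_rate=float(row["remi_rate"]),
            )
        s = subjects[sid]
        kind = str(row["event"])
        if kind == "dose":
            try:
                s.doses.append(
                    DoseEvent(
                        start=float(row["time"]),
                        amount=float(row["amount"]),
                        duration=float(row["duration"]),
                    )
                )
            except ValueError as exc:
                raise DatasetError(f"row {idx}: invalid dose record ({exc})") from exc
        elif kind == "observation":
            dvtype = str(row["dvtype"])
            if dvtype not in OBS_TYPES:
                raise DatasetError(
                    f"row {idx}: unknown observation type {dvtype!r}; expected one of {OBS_TYPES}"
                )
            value = float(row["dv"])
            below = bool(row["below_loq"]) if "below_loq" in df.columns and not pd.isna(row.get("below_loq")) else False
            if dvtype == "conc" and value < LLOQ:
                below = True
            s.observations.append(
                Observation(time=float(row["time"]), value=value, obs_type=dvtype, below_loq=below)
            )
        else:
            raise DatasetError(f"row {idx}: unknown event kind {kind!r} (expected dose|observation)")
    for s in subjects.values():
        s.doses.sort(key=lambda d: d.start)
        s.observations.sort(key=lambda o: (o.time, o.obs_type))
    return StudyDataset(subjects=list(subjects.values()))


def read_dataset(path) -> StudyDataset:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return dataset_from_frame(df)


def resample_subjects(dataset: StudyDataset, rng: np.random.Generator) -> StudyDataset:
    """Bootstrap replicate: same number of subjects, drawn with replacement."""
    n = len(dataset)
    idx = rng.integers(0, n, size=n)
    subjects = []
    for k, i in enumerate(idx):
        src = dataset.subjects[int(i)]
        subjects.append(replace(src, id=f"bs{k:03d}_{src.id}"))
    return StudyDataset(subjects=subjects)
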