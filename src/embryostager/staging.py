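"""Two-level staging model for medfly embryogenesis.

The upper level comprises six embryogenetic events (Roman numerals) that
allow comparisons across insect orders; the lower level comprises
seventeen stages (Arabic numerals) adapted from the fruit fly framework:

=====  ====================  =======
event  name                  stages
=====  ====================  =======
I      blastoderm formation  1–5
II     early gastrulation    6–7
III    germband elongation   8–11
IV     germband retraction   12
V      dorsal closure        13–15
VI     muscular movement     16–17
=====  ====================  =======

Stage intervals are half-open ``[start, end)`` so every developmental time
maps to exactly one stage; the end of stage ``s`` coincides with the start
of stage ``s + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

N_STAGES = 17

EVENT_NAMES: dict[str, str] = {
    "I": "blastoderm formation",
    "II": "early gastrulation",
    "III": "germband elongation",
    "IV": "germband retraction",
    "V": "dorsal closure",
    "VI": "muscular movement",
}

EVENT_STAGES: dict[str, tuple[int, ...]] = {
    "I": (1, 2, 3, 4, 5),
    "II": (6, 7),
    "III": (8, 9, 10, 11),
    "IV": (12,),
    "V": (13, 14, 15),
    "VI": (16, 17),
}

STAGE_TO_EVENT: dict[int, str] = {
    stage: event for event, stages in EVENT_STAGES.items() for stage in stages
}


def event_of(stage: int) -> str:
    """Return the embryogenetic event (Roman numeral) containing a stage."""
    if stage not in STAGE_TO_EVENT:
        raise ConfigurationError(f"stage must be in 1..{N_STAGES}, got {stage}")
    return STAGE_TO_EVENT[stage]


@dataclass(frozen=True)
class StageAssignment:
    """Result of a developmental-time lookup."""

    time: float
    stage: int
    event: str


@dataclass
class StagingTable:
    """Per-dataset stage boundaries in hours.

    ``boundaries`` holds the 18 stage boundaries: the start of stage 1
    through the end of stage 17.  Stage ``s`` occupies
    ``[boundaries[s-1], boundaries[s])``.
    """

    dataset_id: str
    boundaries: np.ndarray

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries.shape != (N_STAGES + 1,):
            raise ConfigurationError(
                f"need {N_STAGES + 1} boundaries, got {self.boundaries.shape}"
            )
        diffs = np.diff(self.boundaries)
        if np.any(diffs < 0):
            bad = int(np.argmax(diffs < 0)) + 1
            raise ConfigurationError(
                f"boundaries not monotone at stage {bad} -> {bad + 1}"
            )

    @property
    def starts(self) -> np.ndarray:
        return self.boundaries[:-1]

    @property
    def ends(self) -> np.ndarray:
        return self.boundaries[1:]

    @property
    def span(self) -> float:
        return float(self.boundaries[-1] - self.boundaries[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dataset": self.dataset_id,
                "stage": np.arange(1, N_STAGES + 1),
                "start_h": self.starts,
                "end_h": self.ends,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, dataset_id: str | None = None) -> "StagingTable":
        df = df.sort_values("stage")
        if list(df["stage"]) != list(range(1, N_STAGES + 1)):
            raise ConfigurationError("table must contain exactly stages 1..17")
        if not np.allclose(df["end_h"].to_numpy()[:-1], df["start_h"].to_numpy()[1:]):
            raise ConfigurationError("stage end must equal next stage start")
        bounds = np.concatenate([df["start_h"].to_numpy(), df["end_h"].to_numpy()[-1:]])
        ds = dataset_id if dataset_id is not None else str(df["dataset"].iloc[0])
        return cls(ds, bounds)


def read_staging_tables(path) -> list[StagingTable]:
    """Read per-dataset stage tables from CSV (dataset, stage, start_h, end_h)."""
    df = pd.read_csv(path)
    return [
        StagingTable.from_frame(group, dataset_id=str(ds))
        for ds, group in df.groupby("dataset", sort=True)
    ]


def write_staging_tables(tables: list[StagingTable], path) -> None:
    pd.concat([t.to_frame() for t in tables], ignore_index=True).to_csv(path, index=False)


def stage_durations(table: StagingTable, normalized: bool = False) -> np.ndarray:
    """Per-stage durations in hours, or as fractions of total development.

    Normalized durations divide by their own sum, so they total exactly
    one up to the last unit of floating precision.
    """
    durations = np.diff(table.boundaries)
    if not normalized:
        return durations
    total = durations.sum()
    if total <= 0:
        raise ConfigurationError("table has zero total span")
    return durations / total


def aggregate_staging(tables: list[StagingTable]) -> dict[str, pd.DataFrame]:
    """Cross-dataset duration and boundary statistics (mean, sample SD).

    Returns two frames: ``"stages"`` with per-stage duration statistics and
    ``"boundaries"`` with per-boundary statistics, each in absolute hours
    and as fractions of total development.  Order of input tables does not
    matter.
    """
    if len(tables) < 2:
        raise ConfigurationError("need at least two tables to aggregate")
    dur_abs = np.stack([stage_durations(t) for t in tables])
    dur_norm = np.stack([stage_durations(t, normalized=True) for t in tables])
    bounds_abs = np.stack([t.boundaries for t in tables])
    bounds_norm = np.stack(
        [(t.boundaries - t.boundaries[0]) / t.span for t in tables]
    )
    stages = pd.DataFrame(
        {
            "stage": np.arange(1, N_STAGES + 1),
            "event": [event_of(s) for s in range(1, N_STAGES + 1)],
            "mean_duration_h": dur_abs.mean(axis=0),
            "sd_duration_h": dur_abs.std(axis=0, ddof=1),
            "mean_duration_norm": dur_norm.mean(axis=0),
            "sd_duration_norm": dur_norm.std(axis=0, ddof=1),
        }
    )
    boundaries = pd.DataFrame(
        {
            "boundary_start_of_stage": np.arange(1, N_STAGES + 2),
            "mean_h": bounds_abs.mean(axis=0),
            "sd_h": bounds_abs.std(axis=0, ddof=1),
            "mean_norm": bounds_norm.mean(axis=0),
            "sd_norm": bounds_norm.std(axis=0, ddof=1),
        }
    )
    return {"stages": stages, "boundaries": boundaries}


def classify_time(t: float, table: StagingTable, normalized: bool = False) -> StageAssignment:
    """Map a developmental time to its stage and event.

    ``t`` may be in hours or, with ``normalized=True``, a fraction of the
    table's total span.  Times outside ``[start of stage 1, end of stage
    17)`` are rejected.
    """
    bounds = table.boundaries
    if normalized:
        bounds = (bounds - bounds[0]) / table.span
    if not bounds[0] <= t < bounds[-1]:
        raise ConfigurationError(
            f"time {t} outside developmental span [{bounds[0]}, {bounds[-1]})"
        )
    stage = int(np.searchsorted(bounds, t, side="right"))
    stage = min(stage, N_STAGES)  # t exactly on an interior boundary opens the next stage
    return StageAssignment(time=float(t), stage=stage, event=event_of(stage))
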