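"""Processing of per-organ tracer measurements into estimator-ready datasets.

Raw organ measurements (iron concentration per gram of wet tissue) are
scaled to whole-organ amounts using organ weights with error propagation
for the product of two independent random factors, intestinal segments are
averaged into a single intestine value, negative over-corrected means are
clipped to zero, and every timepoint is rescaled so that the whole-body
tracer total follows the slow exponential body-loss law
100 * exp(-lambda * t) with lambda = 0.005/day by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .compartment_model import BODY_COMPARTMENTS, TracerTrajectory

__all__ = [
    "DEFAULT_LAMBDA_LOSS",
    "OrganObservation",
    "OrganWeight",
    "TracerDataset",
    "InvalidMeasurementError",
    "scale_to_body",
    "combine_intestinal_segments",
    "decaying_total",
    "normalize_to_decaying_total",
    "clip_negative",
    "dataset_from_trajectory",
    "organ_weights_from_csv",
    "organ_weights_to_csv",
]

#: Default long-term whole-body tracer loss rate (1/day).  The literature
#: also quotes ~0.004/day, hence the parameter is configurable downstream.
DEFAULT_LAMBDA_LOSS = 0.005

DATASET_COLUMNS = ["organ", "time_days", "mean_pct_dose", "sd_pct_dose", "n"]


class InvalidMeasurementError(ValueError):
    """A measurement violates its sign/shape contract."""


@dataclass(frozen=True)
class OrganObservation:
    """One aggregated measurement: mean +/- SD for an organ at a time."""

    organ: str
    time: float
    mean: float
    sd: float
    n_animals: int = 1

    def __post_init__(self):
        if self.sd < 0:
            raise InvalidMeasurementError(f"sd must be >= 0, got {self.sd}")
        if self.time < 0:
            raise InvalidMeasurementError(f"time must be >= 0, got {self.time}")
        if self.n_animals < 1:
            raise InvalidMeasurementError("n_animals must be >= 1")


@dataclass(frozen=True)
class OrganWeight:
    """Organ wet weight (g) per standard 25-g body, with its SD."""

    organ: str
    weight: float
    sd: float = 0.0

    def __post_init__(self):
        if self.weight <= 0:
            raise InvalidMeasurementError("organ weight must be > 0")
        if self.sd < 0:
            raise InvalidMeasurementError("weight sd must be >= 0")


@dataclass(frozen=True)
class TracerDataset:
    """Whole-body-scaled tracer observations, % of injected dose.

    ``observations`` holds one row per (organ, time): columns
    organ, time_days, mean_pct_dose, sd_pct_dose, n.
    """

    observations: pd.DataFrame
    diet: str | None = None
    normalized: bool = False
    clipped: tuple[tuple[str, float], ...] = field(default=())

    def __post_init__(self):
        df = self.observations
        missing = [c for c in DATASET_COLUMNS if c not in df.columns]
        if missing:
            raise InvalidMeasurementError(f"dataset missing columns {missing}")
        if df.duplicated(subset=["organ", "time_days"]).any():
            raise InvalidMeasurementError(
                "at most one observation per (organ, time) is allowed")
        df = df[DATASET_COLUMNS].reset_index(drop=True)
        object.__setattr__(self, "observations", df)

    @classmethod
    def from_observations(cls, obs: Iterable[OrganObservation],
                          diet: str | None = None,
                          normalized: bool = False) -> "TracerDataset":
        rows = [(o.organ, o.time, o.mean, o.sd, o.n_animals) for o in obs]
        df = pd.DataFrame(rows, columns=DATASET_COLUMNS)
        return cls(observations=df, diet=diet, normalized=normalized)

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.observations["time_days"].unique())

    @property
    def organs(self) -> tuple[str, ...]:
        return tuple(self.observations["organ"].unique())

    def to_csv(self, path) -> None:
        df = self.observations.copy()
        df.insert(0, "diet", self.diet if self.diet is not None else "")
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, normalized: bool = False) -> "TracerDataset":
        df = pd.read_csv(path)
        diet = None
        if "diet" in df.columns:
            diets = df["diet"].dropna().unique()
            diet = str(diets[0]) if len(diets) == 1 and str(diets[0]) else None
            df = df.drop(columns=["diet"])
        return cls(observations=df, diet=diet, normalized=normalized)


def scale_to_body(f: float, h: float, w: float, s: float) -> tuple[float, float]:
    """Whole-organ amount from concentration ``f +/- h`` and weight ``w +/- s``.

    mean = f*w; sd = sqrt(f^2 s^2 + w^2 h^2 + h^2 s^2), the exact SD of a
    product of two independent random variables.
    """
    if f < 0 or w < 0:
        raise InvalidMeasurementError("concentration and weight must be >= 0")
    if h < 0 or s < 0:
        raise InvalidMeasurementError("standard deviations must be >= 0")
    mean = f * w
    sd = math.sqrt(f * f * s * s + w * w * h * h + h * h * s * s)
    return mean, sd


def combine_intestinal_segments(
        segments: Sequence[OrganObservation]) -> OrganObservation:
    """Average intestinal segment observations into one intestine value.

    The combined mean is the unweighted mean of the segment means.  The SD
    follows from the same product-propagation rule as :func:`scale_to_body`
    applied to each segment scaled by the exact factor 1/n (zero SD), i.e.
    per-segment contribution h_i/n, combined in quadrature:
    sd = sqrt(sum h_i^2) / n.
    """
    if not segments:
        raise InvalidMeasurementError("need at least one segment")
    times = {seg.time for seg in segments}
    if len(times) != 1:
        raise InvalidMeasurementError(
            f"segments must share one timepoint, got {sorted(times)}")
    n = len(segments)
    mean = sum(seg.mean for seg in segments) / n
    sd = math.sqrt(sum(seg.sd ** 2 for seg in segments)) / n
    return OrganObservation(organ="intestine", time=segments[0].time,
                            mean=mean, sd=sd,
                            n_animals=min(seg.n_animals for seg in segments))


def decaying_total(t, lambda_loss: float = DEFAULT_LAMBDA_LOSS):
    """Whole-body tracer total (% of dose) at time t under slow body loss."""
    return 100.0 * np.exp(-lambda_loss * np.asarray(t, dtype=float))


def normalize_to_decaying_total(
        dataset: TracerDataset,
        lambda_loss: float = DEFAULT_LAMBDA_LOSS) -> TracerDataset:
    """Rescale each timepoint so the body total equals 100*exp(-lambda*t).

    Requires full body-compartment coverage at every timepoint (the total
    is otherwise meaningless).  Idempotent: totals already on the decay
    curve are rescaled by exactly 1.
    """
    df = dataset.observations.copy()
    for t, group in df.groupby("time_days"):
        missing = set(BODY_COMPARTMENTS) - set(group["organ"])
        if missing:
            raise InvalidMeasurementError(
                f"timepoint {t}: missing compartments {sorted(missing)}")
        total = group["mean_pct_dose"].sum()
        if total <= 0:
            raise InvalidMeasurementError(
                f"timepoint {t}: non-positive body total {total}")
        factor = float(decaying_total(t, lambda_loss)) / total
        sel = df["time_days"] == t
        df.loc[sel, "mean_pct_dose"] *= factor
        df.loc[sel, "sd_pct_dose"] *= factor
    return replace(dataset, observations=df, normalized=True)


def clip_negative(dataset: TracerDataset) -> TracerDataset:
    """Replace negative means with zero (over-correction artefacts).

    SDs are left untouched; the affected (organ, time) cells are recorded
    in ``clipped``.  Never alters non-negative cells.
    """
    df = dataset.observations.copy()
    neg = df["mean_pct_dose"] < 0
    clipped = tuple(
        (row.organ, float(row.time_days))
        for row in df[neg].itertuples())
    df.loc[neg, "mean_pct_dose"] = 0.0
    return replace(dataset, observations=df,
                   clipped=dataset.clipped + clipped)


def organ_weights_from_csv(path) -> dict[str, OrganWeight]:
    """Read organ weights from a CSV with columns organ, weight_g, sd_g."""
    df = pd.read_csv(path)
    return {row.organ: OrganWeight(row.organ, float(row.weight_g),
                                   float(getattr(row, "sd_g", 0.0)))
            for row in df.itertuples()}


def organ_weights_to_csv(weights: dict[str, OrganWeight], path) -> None:
    rows = [(w.organ, w.weight, w.sd) for w in weights.values()]
    pd.DataFrame(rows, columns=["organ", "weight_g", "sd_g"]).to_csv(
        path, index=False)


def dataset_from_trajectory(trajectory: TracerTrajectory,
                            sd: float | dict | None = None,
                            diet: str | None = None,
                            n: int = 1) -> TracerDataset:
    """Turn a simulated trajectory into a dataset (testing/synthesis aid).

    ``sd`` may be a constant, a per-organ mapping, or None (zero SD).
    """
    rows = []
    for organ in trajectory.compartments:
        series = trajectory[organ]
        for t, v in zip(trajectory.times, series):
            if isinstance(sd, dict):
                s = sd.get(organ, 0.0)
            else:
                s = float(sd) if sd is not None else 0.0
            rows.append((organ, float(t), float(v), s, n))
    df = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    return TracerDataset(observations=df, diet=diet)
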