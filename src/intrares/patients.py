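"""Virtual-patient generation: T stage → tumor diameter → diagnosis burden.

A virtual patient is defined by their tumor burden at diagnosis, sampled in
three steps that mirror how primary-tumor size enters the TNM staging of
non-small-cell lung cancer:

1. a T stage (T1–T4) is drawn from a multinomial whose probabilities are
   the stage counts of a reference clinical cohort;
2. a tumor diameter is drawn uniformly from that stage's diameter range;
3. the diameter is converted to a spherical volume (``π/6 · d³``) and then
   to a cell count at 10⁹ cells per cm³.

The default stage counts and diameter ranges are those of a 950-patient
NSCLC cohort (T1: 272, T2: 524, T3: 109, T4: 43; two stage-unknown Tx cases
are excluded since no diameter range exists for them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .model import ModelParams

T_STAGES: tuple[str, ...] = ("T1", "T2", "T3", "T4")

_DEFAULT_COUNTS = {"T1": 272, "T2": 524, "T3": 109, "T4": 43}
_DEFAULT_RANGES = {
    "T1": (0.5, 3.0),
    "T2": (3.0, 5.0),
    "T3": (5.0, 7.0),
    "T4": (7.0, 10.0),
}


@dataclass(frozen=True)
class StageDistribution:
    """Reference T-stage counts and per-stage tumor-diameter ranges (cm)."""

    counts: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_COUNTS))
    diameter_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_RANGES)
    )

    def __post_init__(self) -> None:
        total = 0
        for stage in T_STAGES:
            c = int(self.counts.get(stage, 0))
            if c < 0:
                raise ValueError(f"negative count for stage {stage}")
            total += c
            lo, hi = self.diameter_ranges[stage]
            if not 0 < lo < hi:
                raise ValueError(f"invalid diameter range for {stage}: ({lo}, {hi})")
        if total == 0:
            raise ValueError("all stage counts are zero")

    @property
    def probabilities(self) -> np.ndarray:
        c = np.array([self.counts.get(t, 0) for t in T_STAGES], dtype=float)
        return c / c.sum()

    @classmethod
    def from_csv(cls, path: str | Path) -> "StageDistribution":
        """Read columns (stage, count, diam_low_cm, diam_high_cm)."""
        df = pd.read_csv(path)
        counts = {}
        ranges = {}
        for _, row in df.iterrows():
            stage = str(row["stage"])
            counts[stage] = int(row["count"])
            ranges[stage] = (float(row["diam_low_cm"]), float(row["diam_high_cm"]))
        return cls(counts=counts, diameter_ranges=ranges)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {
                "stage": t,
                "count": self.counts.get(t, 0),
                "diam_low_cm": self.diameter_ranges[t][0],
                "diam_high_cm": self.diameter_ranges[t][1],
            }
            for t in T_STAGES
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class PatientProfile:
    """One virtual patient: stage, tumor size and cell burden at diagnosis."""

    t_stage: str
    diameter_cm: float
    volume_cm3: float
    m_diagnosis: int


def sample_t_stage(dist: StageDistribution, rng: np.random.Generator) -> str:
    """Draw a T stage with probability proportional to the cohort counts."""
    return T_STAGES[rng.choice(len(T_STAGES), p=dist.probabilities)]


def stage_to_diameter(
    stage: str, dist: StageDistribution, rng: np.random.Generator
) -> float:
    """Draw a tumor diameter uniformly from the stage's range."""
    if stage not in dist.diameter_ranges:
        raise ValueError(f"no diameter range for stage {stage!r}")
    lo, hi = dist.diameter_ranges[stage]
    return float(rng.uniform(lo, hi))


def diameter_to_volume(d_cm: float) -> float:
    """Spherical tumor volume in cm³ for diameter ``d_cm``."""
    if d_cm <= 0:
        raise ValueError(f"diameter must be positive, got {d_cm}")
    return math.pi / 6.0 * d_cm**3


def diameter_to_burden(d_cm: float, params: ModelParams) -> int:
    """Cell count of a spherical tumor of diameter ``d_cm``, at the model's
    packing density (default 10⁹ cells/cm³), rounded to the nearest cell."""
    return round(diameter_to_volume(d_cm) * params.cells_per_cm3)


def generate_patient(
    dist: StageDistribution, params: ModelParams, rng: np.random.Generator
) -> PatientProfile:
    """Sample one virtual patient (stage → diameter → volume → burden)."""
    stage = sample_t_stage(dist, rng)
    d = stage_to_diameter(stage, dist, rng)
    vol = diameter_to_volume(d)
    return PatientProfile(
        t_stage=stage,
        diameter_cm=d,
        volume_cm3=vol,
        m_diagnosis=round(vol * params.cells_per_cm3),
    )


def expected_mean_volume(dist: StageDistribution) -> float:
    """Analytic mean tumor volume (cm³) of the generator.

    Mixture over stages of ``π/6 · E[d³]`` with
    ``E[d³] = (hi⁴ − lo⁴) / (4 (hi − lo))`` for the uniform diameter draw —
    the closed-form oracle for cohort-level checks.
    """
    w = dist.probabilities
    e3 = []
    for t in T_STAGES:
        lo, hi = dist.diameter_ranges[t]
        e3.append((hi**4 - lo**4) / (4.0 * (hi - lo)))
    return math.pi / 6.0 * float(np.dot(w, e3))
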