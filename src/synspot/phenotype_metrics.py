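"""Motility-phenotype metrics: migration areas, reference standardisation,
and emergence-time histograms.

A motile zone spreading from a central inoculum is measured as two
perpendicular diameters (lateral and longitudinal, mm). The zone is treated
as the circle of the averaged diameter, its surface area ``A = pi * r**2``
is root-transformed, and genotypes are compared as root-area scores centred
on a reference genotype grown in the same environment (reference mean = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class MigrationMeasurement:
    replicate_id: str
    genotype: str
    environment: str
    diameter_lateral: float
    diameter_longitudinal: float

    def __post_init__(self) -> None:
        if self.diameter_lateral < 0 or self.diameter_longitudinal < 0:
            raise ValueError("diameters must be >= 0")


@dataclass(frozen=True)
class EmergenceRecord:
    """Day a line's motile phenotype emerged; censored = beyond the window."""

    line_id: str
    strain: str
    environment: str
    day: int
    censored: bool = False

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValueError("day must be >= 1")


def migration_area(
    m: MigrationMeasurement, per_axis: bool = False
) -> tuple[float, float]:
    """Surface area (mm^2) and root-transformed area (mm) of a motile zone.

    Default: radius = mean of the two diameters / 2, area = pi r^2.
    ``per_axis=True`` instead averages the two per-axis circle areas
    (the alternative reading of "averaged total surface area").
    """
    d1, d2 = m.diameter_lateral, m.diameter_longitudinal
    if per_axis:
        area = (math.pi * (d1 / 2) ** 2 + math.pi * (d2 / 2) ** 2) / 2
    else:
        r = (d1 + d2) / 4
        area = math.pi * r * r
    return area, math.sqrt(area)


def standardize_to_reference(
    measurements: list[MigrationMeasurement],
    reference_genotype: str,
    per_axis: bool = False,
    raw_scale: bool = False,
) -> pd.DataFrame:
    """Centre root-areas on the per-environment reference mean.

    Every measurement's score is its root-transformed area minus the mean
    root-area of ``reference_genotype`` replicates grown in the same
    environment, so the reference genotype scores average exactly 0 in each
    environment. ``raw_scale=True`` centres raw areas instead.

    Raises
    ------
    ValueError
        If an environment lacks reference measurements.
    """
    if not measurements:
        return pd.DataFrame(
            columns=["replicate_id", "genotype", "environment", "root_area", "score"]
        )
    rows = []
    for m in measurements:
        area, root = migration_area(m, per_axis=per_axis)
        rows.append(
            {
                "replicate_id": m.replicate_id,
                "genotype": m.genotype,
                "environment": m.environment,
                "area": area,
                "root_area": root,
            }
        )
    df = pd.DataFrame(rows)
    value_col = "area" if raw_scale else "root_area"
    ref = df[df["genotype"] == reference_genotype]
    missing = set(df["environment"]) - set(ref["environment"])
    if missing:
        raise ValueError(
            f"no {reference_genotype!r} reference measurements for "
            f"environment(s): {sorted(missing)}"
        )
    ref_means = ref.groupby("environment")[value_col].mean()
    df["score"] = df[value_col] - df["environment"].map(ref_means)
    return df


def emergence_histogram(
    records: list[EmergenceRecord], window: int = 10
) -> pd.Series:
    """Bin emergence days 1..window, pooling later/censored lines in "11+".

    The pooled bin is labelled ``f"{window + 1}+"``; counts always sum to
    the number of records.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    labels = [str(d) for d in range(1, window + 1)] + [f"{window + 1}+"]
    counts = dict.fromkeys(labels, 0)
    for r in records:
        if r.censored or r.day > window:
            counts[f"{window + 1}+"] += 1
        else:
            counts[str(r.day)] += 1
    out = pd.Series(counts, name="lines")
    out.index.name = "emergence_day"
    return out
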