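"""Relative fitness from serial-dilution competition assays.

A labeled reference strain is co-cultured with an unlabeled competitor;
the culture is diluted once per day and the reference frequency measured
daily by flow cytometry.  Generations elapsed per day equal
``log2(dilution_factor)``.  Under constant selection the log2 *odds* of the
reference are linear in generations, so the default estimator regresses
log2 odds on cumulative generations; fitting log2 frequency directly (a
good approximation near 50/50) is available as ``mode="frequency"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FitnessEstimate", "relative_fitness"]


@dataclass(frozen=True)
class FitnessEstimate:
    """Per-generation selection coefficient of the competitor strain.

    ``s > 0`` means the unlabeled competitor outcompetes the labeled
    reference (the reference frequency falls).  ``scale`` records whether
    the coefficient is in log2 units per generation (the slope of the log2
    fit) or converted to natural-log units (slope times ln 2).
    """

    s: float
    se: float
    n: int
    generations: float
    scale: str


def relative_fitness(
    series: pd.DataFrame,
    mode: str = "odds",
    scale: str = "log2",
) -> FitnessEstimate:
    """Estimate the competitor's selection coefficient from a frequency
    time course.

    ``series`` needs columns ``day``, ``frequency`` (reference-strain
    frequency, strictly inside (0, 1)) and ``dilution_factor``.  The slope
    of log2 odds (or log2 frequency) of the reference on cumulative
    generations is estimated by OLS; the reported ``s`` is its negative, so
    a reference strain losing ground yields a positive competitor fitness.
    ``scale="natural"`` multiplies by ln 2 to convert the per-generation
    log2 slope to a natural-log selection coefficient.
    """
    if mode not in ("odds", "frequency"):
        raise ValueError("mode must be 'odds' or 'frequency'")
    if scale not in ("log2", "natural"):
        raise ValueError("scale must be 'log2' or 'natural'")
    if len(series) < 3:
        raise ValueError("need at least 3 time points")
    f = series["frequency"].to_numpy(float)
    if ((f <= 0) | (f >= 1)).any():
        raise ValueError("frequencies must lie strictly inside (0, 1)")
    gens_per_day = np.log2(series["dilution_factor"].to_numpy(float))
    if (gens_per_day <= 0).any():
        raise ValueError("dilution_factor must exceed 1")
    gens = series["day"].to_numpy(float) * gens_per_day

    y = np.log2(f / (1.0 - f)) if mode == "odds" else np.log2(f)
    res = stats.linregress(gens, y)
    s = -float(res.slope)
    se = float(res.stderr)
    if scale == "natural":
        s *= math.log(2.0)
        se *= math.log(2.0)
    return FitnessEstimate(s=s, se=se, n=len(series), generations=float(gens[-1]), scale=scale)
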