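"""Cell-cycle landmark detection from single-cell time-lapse traces.

A trace samples one cell on a uniform frame grid: volume, bud-neck marker
intensity and nucleus count.  The bud neck appears at budding (START) and
disappears at cytokinesis, so for a tracked cell the marker is high before
its birth (the neck of the division that created it), low through G1, high
through the budded phase, and low again after its own division.  Nuclear
separation (nucleus count 1 -> 2) shortly precedes each division and
anchors the search for the bud-neck disappearance.

All reported landmark times are members of the trace's frame grid.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simkit import RECORD_COLUMNS, CENSOR_MARGIN_MIN

__all__ = [
    "volume_from_axes",
    "detect_nuclear_separation",
    "detect_birth",
    "detect_budding",
    "assemble_records",
    "iter_traces",
]

#: Fraction of the adjacent plateau below/above which the bud-neck signal
#: counts as disappeared/appeared ("significant" change).
DEFAULT_REL_DROP = 0.5
#: Frames a crossing must persist to count as a transition.
SUSTAIN_FRAMES = 2
#: Plateau estimation window (frames) and minimum plateau contrast relative
#: to the trace's high level, to avoid spurious crossings inside low regions.
_PLATEAU_WIN = 5
_MIN_PLATEAU_FRAC = 0.3


def volume_from_axes(major: float, minor: float) -> float:
    """Cell volume from its axis lengths, treating the cell as a prolate
    spheroid: ``V = (pi/6) * L * W**2``.

    ``major`` (L) must be at least ``minor`` (W); both positive.
    """
    if not (minor > 0 and major > 0):
        raise ValueError("axis lengths must be positive")
    if major < minor:
        raise ValueError("major axis shorter than minor axis (arguments swapped?)")
    return math.pi / 6.0 * major * minor * minor


def _as_arrays(trace: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = np.asarray(trace["time"], dtype=float)
    if t.size > 1:
        dt = np.diff(t)
        if (dt <= 0).any() or not np.allclose(dt, dt[0]):
            raise ValueError("trace times must be strictly increasing on a uniform grid")
    neck = np.asarray(trace["budneck"], dtype=float)
    nuclei = np.asarray(trace["nuclei"], dtype=float)
    return t, neck, nuclei


def detect_nuclear_separation(trace: pd.DataFrame) -> Optional[float]:
    """Time of the first nucleus-count 1 -> 2 transition, or None."""
    seps = _nuclear_separations(trace)
    return seps[0] if seps else None


def _nuclear_separations(trace: pd.DataFrame) -> list[float]:
    t, _, nuclei = _as_arrays(trace)
    idx = np.nonzero((nuclei[1:] == 2) & (nuclei[:-1] == 1))[0] + 1
    return list(t[idx])


def _drop_candidates(t: np.ndarray, neck: np.ndarray, rel_drop: float) -> list[int]:
    """Frames where the bud-neck signal falls below ``rel_drop`` times the
    trailing plateau and stays below for ``SUSTAIN_FRAMES`` frames."""
    high = np.quantile(neck, 0.9)
    out = []
    for i in range(1, neck.size - SUSTAIN_FRAMES + 1):
        plateau = np.median(neck[max(0, i - _PLATEAU_WIN) : i])
        if plateau < _MIN_PLATEAU_FRAC * high:
            continue
        thr = rel_drop * plateau
        if (neck[i : i + SUSTAIN_FRAMES] < thr).all():
            out.append(i)
    return out


def _rise_candidates(t: np.ndarray, neck: np.ndarray, rel_rise: float) -> list[int]:
    """Frames where the signal rises above ``rel_rise`` times the following
    plateau (sustained), marking bud-neck appearance."""
    high = np.quantile(neck, 0.9)
    out = []
    for i in range(1, neck.size - SUSTAIN_FRAMES + 1):
        plateau = np.median(neck[i : i + _PLATEAU_WIN])
        if plateau < _MIN_PLATEAU_FRAC * high:
            continue
        thr = rel_rise * plateau
        if neck[i - 1] < thr and (neck[i : i + SUSTAIN_FRAMES] >= thr).all():
            out.append(i)
    return out


def detect_birth(
    trace: pd.DataFrame,
    nuclear_sep: Optional[float],
    rel_drop: float = DEFAULT_REL_DROP,
    window: float = 30.0,
) -> Optional[float]:
    """Birth time: bud-neck disappearance within ``window`` minutes of the
    nuclear separation that created the cell.

    Among candidate drop frames in ``[nuclear_sep - window, nuclear_sep +
    window]`` the one closest to the nuclear separation is returned
    (earliest on ties).  Returns None when ``nuclear_sep`` is None or no
    candidate qualifies.
    """
    if nuclear_sep is None:
        return None
    t, neck, _ = _as_arrays(trace)
    cands = [
        t[i]
        for i in _drop_candidates(t, neck, rel_drop)
        if nuclear_sep - window <= t[i] <= nuclear_sep + window
    ]
    if not cands:
        return None
    return min(cands, key=lambda x: (abs(x - nuclear_sep), x))


def detect_budding(
    trace: pd.DataFrame,
    after: Optional[float] = None,
    rel_rise: float = DEFAULT_REL_DROP,
) -> Optional[float]:
    """Budding time: first sustained bud-neck appearance (after ``after``)."""
    t, neck, _ = _as_arrays(trace)
    for i in _rise_candidates(t, neck, rel_rise):
        if after is None or t[i] > after:
            return t[i]
    return None


def iter_traces(traces: pd.DataFrame):
    """Yield ``(cell_id, trace)`` pairs from a long-format trace table."""
    for cell_id, g in traces.groupby("cell_id", sort=True):
        yield cell_id, g.sort_values("time").reset_index(drop=True)


def assemble_records(
    traces: pd.DataFrame,
    movie_length: float,
    strain_id: str = "unknown",
    rel_drop: float = DEFAULT_REL_DROP,
    window: float = 30.0,
    censor_margin: float = CENSOR_MARGIN_MIN,
) -> pd.DataFrame:
    """Build cell-cycle records from landmark detection on each trace.

    Per cell: birth = bud-neck disappearance anchored at the first nuclear
    separation; budding = first sustained bud-neck appearance after birth;
    division = next bud-neck disappearance after budding, anchored at the
    following nuclear separation.  Volumes are read off the trace at the
    landmark frames.  A missing landmark yields a record flagged censored;
    cells born later than ``movie_length - censor_margin`` are excluded
    outright (their cycle cannot be scored reliably near the movie end).
    """
    rows = []
    for cell_id, tr in iter_traces(traces):
        t, neck, _ = _as_arrays(tr)
        vol = np.asarray(tr["volume"], dtype=float)
        seps = _nuclear_separations(tr)

        birth = detect_birth(tr, seps[0] if seps else None, rel_drop, window)
        budding = detect_budding(tr, after=birth, rel_rise=rel_drop) if birth is not None else None
        division = None
        if budding is not None:
            later_seps = [s for s in seps if s > budding]
            if later_seps:
                sub = tr.loc[tr["time"] > budding]
                division = detect_birth(sub, later_seps[0], rel_drop, window)

        if birth is not None and birth > movie_length - censor_margin:
            continue

        def vol_at(time: Optional[float]) -> float:
            if time is None:
                return np.nan
            return float(vol[np.argmin(np.abs(t - time))])

        censored = birth is None or budding is None or division is None
        rows.append(
            {
                "strain_id": strain_id,
                "cell_id": cell_id,
                "mother_id": -1,
                "generation": -1,
                "cell_role": "unknown",  # role needs lineage context the trace lacks
                "birth_time": np.nan if birth is None else birth,
                "birth_volume": vol_at(birth),
                "budding_time": np.nan if budding is None else budding,
                "budding_volume": vol_at(budding),
                "division_time": np.nan if division is None else division,
                "division_volume": vol_at(division),
                "growth_rate": np.nan,
                "censored": censored,
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)
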