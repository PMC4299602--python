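"""Flow-cytometry pre-screen: gating, DNA-content deconvolution, plate
normalization and candidate selection.

Event tables carry a DNA-stain fluorescence pulse area (DNA content) and
width (doublet discrimination) plus scatter channels.  The pipeline is:
gate events (stain area window, width trim, singlet gate), histogram the
gated areas into 100 smoothed bins, locate the informative histogram range
by a gradient rule, deconvolve the range into G1/S/G2 fractions with a
Dean-Jett mixture (two Gaussian peaks plus a broadened-uniform S phase),
normalize per-plate, and call small/short-G1 and large/long-G1 candidate
strains by z-score cuts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "GateReport",
    "CellCycleHistFit",
    "gate_events",
    "area_histogram",
    "smooth_histogram",
    "histogram_range",
    "fit_cell_cycle",
    "plate_normalize",
    "select_candidates",
    "prescreen_well",
    "RangeNotFoundError",
    "FitConvergenceError",
]

# Stain-area gate: events below AREA_MIN or above 2**18 - AREA_MIN are
# outside the instrument's reliable range and discarded.
AREA_MIN = 5_000.0
AREA_MAX = 2.0**18 - 5_000.0
WIDTH_TRIM_PCT = 1.0  # trim this percent of events at each width extreme
SINGLET_SD = 2.5  # singlet gate half-width in width SDs around the median
MIN_EVENTS = 5_000  # wells retaining fewer gated events are discarded
N_HIST_BINS = 100
# Histogram-range gradient rule, in percent-of-events units.
RANGE_MIN_BIN_PCT = 0.2
RANGE_RISE_PCT = 0.3
RANGE_FALL_PCT = -0.2
# Physical constraint on the G2/G1 DNA-content ratio.
G2_G1_RATIO = (1.8, 2.2)


class RangeNotFoundError(ValueError):
    """The gradient rule matched no histogram bin."""


class FitConvergenceError(RuntimeError):
    """Dean-Jett fit failed; the well should be re-measured."""


@dataclass(frozen=True)
class GateReport:
    n_input: int
    n_after_area: int
    n_after_width_trim: int
    n_after_singlet: int
    discarded_well: bool  # true when fewer than MIN_EVENTS remain

    @property
    def removed(self) -> dict[str, int]:
        return {
            "area": self.n_input - self.n_after_area,
            "width_trim": self.n_after_area - self.n_after_width_trim,
            "singlet": self.n_after_width_trim - self.n_after_singlet,
        }


@dataclass(frozen=True)
class CellCycleHistFit:
    mu_g1: float
    mu_g2: float
    sigma_g1: float
    sigma_g2: float
    f_g1: float
    f_s: float
    f_g2: float
    residual_rms: float

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (self.f_g1, self.f_s, self.f_g2)


# ---------------------------------------------------------------------------
# Gating


def gate_events(events: pd.DataFrame) -> tuple[pd.DataFrame, GateReport]:
    """Apply the stain-area window, width percentile trim and singlet gate,
    in that fixed order, returning the surviving events and a step-by-step
    count report.

    The singlet gate keeps events within :data:`SINGLET_SD` standard
    deviations of the median fluorescence width (doublets carry an inflated
    pulse width).  A degenerate width distribution (SD = 0) keeps all
    events.  Wells retaining fewer than :data:`MIN_EVENTS` events are
    flagged discarded.
    """
    if not len(events):
        raise ValueError("empty event table")
    n0 = len(events)
    area = events["area"].to_numpy(float)
    step1 = events.loc[(area >= AREA_MIN) & (area <= AREA_MAX)]
    n1 = len(step1)

    if n1:
        w = step1["width"].to_numpy(float)
        lo, hi = np.percentile(w, [WIDTH_TRIM_PCT, 100.0 - WIDTH_TRIM_PCT])
        step2 = step1.loc[(step1["width"] >= lo) & (step1["width"] <= hi)]
    else:
        step2 = step1
    n2 = len(step2)

    if n2:
        w = step2["width"].to_numpy(float)
        med, sd = np.median(w), np.std(w, ddof=1) if n2 > 1 else 0.0
        if sd > 0:
            step3 = step2.loc[np.abs(step2["width"] - med) <= SINGLET_SD * sd]
        else:
            step3 = step2
    else:
        step3 = step2
    n3 = len(step3)

    report = GateReport(n0, n1, n2, n3, discarded_well=n3 < MIN_EVENTS)
    return step3.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# Histogram and range detection


def area_histogram(areas: np.ndarray, n_bins: int = N_HIST_BINS) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of gated areas: (bin centers, fraction of events per bin)."""
    areas = np.asarray(areas, dtype=float)
    counts, edges = np.histogram(areas, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    frac = counts / counts.sum() if counts.sum() else counts.astype(float)
    return centers, frac


def smooth_histogram(fractions: np.ndarray, lam: Optional[float] = None) -> np.ndarray:
    """Cubic smoothing-spline smoothing of per-bin fractions.

    The smoothing parameter is chosen by generalized cross-validation when
    ``lam`` is None, which keeps the result deterministic for a given
    histogram.  Smoothed values are clipped at zero.
    """
    y = np.asarray(fractions, dtype=float)
    x = np.arange(y.size, dtype=float)
    spline = make_smoothing_spline(x, y, lam=lam)
    return np.clip(spline(x), 0.0, None)


def histogram_range(fractions: np.ndarray) -> tuple[int, int]:
    """Locate the informative bin range of a smoothed 100-bin histogram.

    Working in percent-of-events units with the gradient as the first
    difference of bin percentages: the lower limit is the lowest bin
    holding at least 0.2% of events whose gradient exceeds 0.3%; the upper
    limit is the highest bin whose gradient is below -0.2%.
    """
    pct = 100.0 * np.asarray(fractions, dtype=float)
    grad = np.diff(pct, prepend=pct[0])  # first bin has zero gradient
    low_ok = np.nonzero((pct >= RANGE_MIN_BIN_PCT) & (grad > RANGE_RISE_PCT))[0]
    high_ok = np.nonzero(grad < RANGE_FALL_PCT)[0]
    if low_ok.size == 0 or high_ok.size == 0:
        raise RangeNotFoundError("gradient rule matched no bin")
    low, high = int(low_ok[0]), int(high_ok[-1])
    # The upper limit excludes the empty super-G2 tail, not populated data:
    # when the histogram keeps substantial mass past the last steep fall
    # (e.g. an S plateau without a G2 peak), extend over those bins.
    while high + 1 < pct.size and pct[high + 1] >= RANGE_MIN_BIN_PCT:
        high += 1
    if high <= low:
        raise RangeNotFoundError(f"degenerate range [{low}, {high}]")
    return low, high


# ---------------------------------------------------------------------------
# Dean-Jett deconvolution


def _dj_model(x, mu1, ratio, s1, s2, f_g1, f_s):
    """Dean-Jett density on bin centers: Gaussian G1 and G2 peaks plus an
    S-phase component (uniform DNA synthesis between 1C and 2C convolved
    with a Gaussian, closed form via the normal CDF)."""
    mu2 = ratio * mu1
    f_g2 = 1.0 - f_g1 - f_s
    g1 = stats.norm.pdf(x, mu1, s1)
    g2 = stats.norm.pdf(x, mu2, s2)
    s_sigma = 0.5 * (s1 + s2)
    s = (stats.norm.cdf((x - mu1) / s_sigma) - stats.norm.cdf((x - mu2) / s_sigma)) / (mu2 - mu1)
    return f_g1 * g1 + f_s * s + f_g2 * g2


def fit_cell_cycle(
    centers: np.ndarray,
    fractions: np.ndarray,
    range_bins: Optional[tuple[int, int]] = None,
) -> CellCycleHistFit:
    """Least-squares Dean-Jett fit of a DNA-content histogram.

    ``centers``/``fractions`` describe the (smoothed) histogram; when
    ``range_bins`` is given only that bin range is fit.  The G2/G1 mean
    ratio is constrained to [1.8, 2.2] and fractions are non-negative and
    normalized.  The fit is scale invariant: multiplying the histogram by a
    constant does not change the recovered fractions.
    """
    x_raw = np.asarray(centers, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if range_bins is not None:
        lo, hi = range_bins
        x_raw, y = x_raw[lo : hi + 1], y[lo : hi + 1]
    if x_raw.size < 10:
        raise ValueError("too few histogram bins for a three-component fit")

    # Initialization from histogram peaks: the G1 peak is the first
    # prominent mode; with a single mode, its position inside the fitted
    # range decides whether it is the G1 or the G2 peak.
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(y, prominence=0.1 * y.max())
    if peaks.size >= 2:
        mu1_0 = x_raw[peaks[0]]
    elif peaks.size == 1:
        p = x_raw[peaks[0]]
        # The mode is the G2 peak only if the G1 peak it implies (at half
        # its position) would fall inside the fitted range.
        implied_g1_visible = 0.5 * p >= x_raw.min()
        mu1_0 = 0.5 * p if (implied_g1_visible and p > 0.5 * (x_raw[0] + x_raw[-1])) else p
    else:
        mu1_0 = x_raw[np.argmax(y)]
    mu1_0 = float(np.clip(mu1_0, x_raw.min() + 1e-9, x_raw.max()))

    # Fit on the G1-normalized scale (x ~ 1-2) so pdf values and residuals
    # are O(1) for the optimizer's default tolerances.
    x = x_raw / mu1_0
    total = np.trapezoid(y, x)
    if total <= 0:
        raise ValueError("histogram has no mass in the fitted range")
    dens = y / total

    p0 = [1.0, 2.0, 0.06, 0.08, 0.5, 0.2]
    lower = [x.min(), G2_G1_RATIO[0], 1e-3, 1e-3, 0.0, 0.0]
    upper = [max(1.2, 0.7 * x.max()), G2_G1_RATIO[1], 0.5, 0.5, 1.0, 1.0]
    p0[0] = float(np.clip(p0[0], lower[0], upper[0]))

    def residuals(p):
        f_g1, f_s = p[4], p[5]
        pen = max(0.0, f_g1 + f_s - 1.0)
        return np.append(_dj_model(x, *p) - dens, 10.0 * pen)

    try:
        res = optimize.least_squares(residuals, p0, bounds=(lower, upper), max_nfev=20_000)
    except ValueError as exc:  # pragma: no cover - defensive
        raise FitConvergenceError(str(exc)) from exc
    if not res.success:
        raise FitConvergenceError(f"Dean-Jett fit did not converge: {res.message}")
    mu1, ratio, s1, s2, f_g1, f_s = res.x
    f_g2 = max(0.0, 1.0 - f_g1 - f_s)
    norm = f_g1 + f_s + f_g2
    rms = float(np.sqrt(np.mean((_dj_model(x, *res.x) - dens) ** 2)))
    return CellCycleHistFit(
        mu_g1=float(mu1 * mu1_0),
        mu_g2=float(ratio * mu1 * mu1_0),
        sigma_g1=float(s1 * mu1_0),
        sigma_g2=float(s2 * mu1_0),
        f_g1=float(f_g1 / norm),
        f_s=float(f_s / norm),
        f_g2=float(f_g2 / norm),
        residual_rms=rms,
    )


# ---------------------------------------------------------------------------
# Plate normalization and candidate selection


def plate_normalize(
    values: pd.Series,
    plates: pd.Series,
    target_mean: float = 0.0,
    target_sd: float = 1.0,
) -> pd.Series:
    """Rescale every plate to a common mean and standard deviation.

    Removes plate-to-plate (day-to-day) batch shifts: within each plate the
    values are centred, divided by the sample SD and rescaled to the target
    moments.  Within-plate z-scores (hence rankings) are unchanged.
    """
    values = pd.Series(values).astype(float)
    out = values.copy()
    for plate, idx in values.groupby(pd.Series(plates).values).groups.items():
        v = values.loc[idx]
        if v.notna().sum() < 2:
            raise ValueError(f"plate {plate!r} has fewer than 2 finite values")
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"plate {plate!r} has zero standard deviation")
        out.loc[idx] = (v - v.mean()) / sd * target_sd + target_mean
    return out


def select_candidates(
    size_z: pd.Series,
    pct_g1_z: pd.Series,
    z_cut: float = 1.0,
) -> pd.Series:
    """Call candidate regulators from normalized size and %G1 metrics.

    ``negative_candidate``: small size AND short G1 (both z <= -z_cut), the
    whi-like pattern expected for a lost START inhibitor.
    ``positive_candidate``: large size AND long G1 (both z >= +z_cut).
    Discordant strains (e.g. small but long G1, the slow-growth signature)
    are left uncalled.  Strains missing either metric are skipped.
    """
    size_z = pd.Series(size_z).astype(float)
    pct_g1_z = pd.Series(pct_g1_z).astype(float)
    out = pd.Series("none", index=size_z.index, dtype=object)
    ok = size_z.notna() & pct_g1_z.notna()
    out[ok & (size_z <= -z_cut) & (pct_g1_z <= -z_cut)] = "negative_candidate"
    out[ok & (size_z >= z_cut) & (pct_g1_z >= z_cut)] = "positive_candidate"
    out[~ok] = "missing"
    return out


# ---------------------------------------------------------------------------
# Convenience: full per-well pipeline


def prescreen_well(events: pd.DataFrame) -> tuple[CellCycleHistFit, GateReport]:
    """Gate one well, build the smoothed 100-bin histogram, find its range
    and run the Dean-Jett fit."""
    gated, report = gate_events(events)
    if report.discarded_well:
        raise FitConvergenceError(
            f"well discarded: only {report.n_after_singlet} events after gating"
        )
    centers, frac = area_histogram(gated["area"].to_numpy(float))
    smoothed = smooth_histogram(frac)
    rng_bins = histogram_range(smoothed)
    fit = fit_cell_cycle(centers, smoothed, rng_bins)
    return fit, report
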