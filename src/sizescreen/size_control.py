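"""Size-control statistics and the mutant classification machinery.

The central quantity is the log volume added in G1,
``delta_v = log(Vs) - log(Vb)`` (budding over birth volume).  Regressed on
log birth volume its slope separates control laws: a perfect sizer
(checkpoint) gives slope -1, no size control (timer under exponential
growth) gives 0, and a weak sizer with gain g gives g - 1.

Mutants are compared to the reference strain with a birth-size-normalized
statistic: the overlap of the two central-80% log-birth-size intervals is
split into equal bins, per-bin median differences are averaged into a mean
offset, per-bin two-sided Wilcoxon rank-sum P-values are combined with
Fisher's method, and a strain is called non-normal for a response when the
combined P falls below alpha (default 0.001).  Crossing calls for G1
duration and delta_v yields nine categories; negative regulators must have
both shorter G1 *and* decreased delta_v, positive regulators longer G1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .simkit import daughters

__all__ = [
    "RESPONSES",
    "SizeControlFit",
    "BinnedComparison",
    "ClassificationResult",
    "delta_v",
    "response_values",
    "size_control_regression",
    "overlap_bins",
    "binned_offset",
    "fisher_combine",
    "wilcoxon_rank_sum",
    "classify_strain",
    "condition_invariance",
    "budded_phase_control",
    "strain_summary",
    "doubling_time_estimate",
    "expected_false_positives",
    "NoOverlapError",
    "SparseBinsError",
]

RESPONSES = ("g1_duration", "delta_v", "budded_duration")

#: Doubling-time band (min) within which G1-vs-birth-size comparisons are
#: growth-rate invariant; strains outside it are flagged slow-growing.
DOUBLING_TIME_BAND = (86.0, 124.0)

#: Largest per-sample size for which the exact Wilcoxon null is enumerated.
EXACT_WILCOXON_MAX_N = 25


class NoOverlapError(ValueError):
    """The two strains' central birth-size intervals do not overlap."""


class SparseBinsError(ValueError):
    """No bin holds enough cells from both samples."""


@dataclass(frozen=True)
class SizeControlFit:
    slope: float
    intercept: float
    pearson_r: float
    slope_se: float
    n: int

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided confidence interval for the slope (t distribution)."""
        half = stats.t.ppf(0.5 + level / 2.0, self.n - 2) * self.slope_se
        return self.slope - half, self.slope + half


@dataclass(frozen=True)
class BinnedComparison:
    response: str
    bin_edges: np.ndarray
    per_bin_median_diff: np.ndarray  # mutant - reference; NaN where bin dropped
    per_bin_p: np.ndarray
    per_bin_n_ref: np.ndarray
    per_bin_n_mut: np.ndarray
    mean_offset: float
    fisher_statistic: float
    fisher_df: int
    combined_p: float


@dataclass(frozen=True)
class ClassificationResult:
    strain_id: str
    g1_call: str  # shorter | normal | longer
    dv_call: str  # decreased | normal | increased
    category: str  # "<g1_call>/<dv_call>"
    regulator_label: str  # negative | positive | none
    g1: BinnedComparison
    dv: BinnedComparison
    doubling_time: float
    slow_growth_flag: bool


# ---------------------------------------------------------------------------
# Elementary quantities


def delta_v(birth_volume, budding_volume):
    """Log volume added in G1: ``log(Vs) - log(Vb)`` (natural log)."""
    vb = np.asarray(birth_volume, dtype=float)
    vs = np.asarray(budding_volume, dtype=float)
    if (vb <= 0).any() or (vs <= 0).any():
        raise ValueError("volumes must be positive")
    out = np.log(vs) - np.log(vb)
    return float(out) if out.ndim == 0 else out


def response_values(records: pd.DataFrame, response: str) -> np.ndarray:
    if response == "g1_duration":
        return (records["budding_time"] - records["birth_time"]).to_numpy(float)
    if response == "delta_v":
        return delta_v(records["birth_volume"], records["budding_volume"])
    if response == "budded_duration":
        return (records["division_time"] - records["budding_time"]).to_numpy(float)
    raise ValueError(f"unknown response {response!r}; expected one of {RESPONSES}")


def _predictor(records: pd.DataFrame, response: str) -> np.ndarray:
    # G1 responses are analyzed against log birth size; the budded-phase
    # analysis uses linear budding volume (slope in min per volume unit).
    if response == "budded_duration":
        return records["budding_volume"].to_numpy(float)
    return np.log(records["birth_volume"].to_numpy(float))


def _clean(records: pd.DataFrame, response: str) -> pd.DataFrame:
    cols = ["birth_volume", "budding_volume", "birth_time", "budding_time"]
    if response == "budded_duration":
        cols.append("division_time")
    rec = records
    if "censored" in rec:
        rec = rec.loc[~rec["censored"].astype(bool)]
    return rec.dropna(subset=[c for c in cols if c in rec])


# ---------------------------------------------------------------------------
# Regression


def size_control_regression(
    records: pd.DataFrame, response: str = "delta_v", min_n: int = 30
) -> SizeControlFit:
    """OLS of a G1 response on log birth volume over uncensored records.

    With ``response="delta_v"`` the fitted slope is the size-control
    strength: -1 for a perfect sizer, 0 for no control.
    """
    rec = _clean(records, response)
    if len(rec) < min_n:
        raise ValueError(f"need >= {min_n} uncensored records, got {len(rec)}")
    x = np.log(rec["birth_volume"].to_numpy(float))
    y = response_values(rec, response)
    res = stats.linregress(x, y)
    return SizeControlFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        slope_se=float(res.stderr),
        n=len(rec),
    )


# ---------------------------------------------------------------------------
# Binned comparison


def overlap_bins(
    x_reference: np.ndarray,
    x_mutant: np.ndarray,
    n_bins: int = 10,
    central: float = 0.80,
) -> np.ndarray:
    """Equal bins over the overlap of the two central-``central`` intervals.

    Each sample's central interval spans its (1-central)/2 to 1-(1-central)/2
    percentiles (10th-90th by default); the overlap is split into ``n_bins``
    equally spaced bins.  Raises :class:`NoOverlapError` when the intervals
    are disjoint (the strains cannot be compared at matched sizes).
    """
    xr = np.asarray(x_reference, dtype=float)
    xm = np.asarray(x_mutant, dtype=float)
    if xr.size == 0 or xm.size == 0:
        raise ValueError("both samples must be non-empty")
    tail = 100.0 * (1.0 - central) / 2.0
    lo = max(np.percentile(xr, tail), np.percentile(xm, tail))
    hi = min(np.percentile(xr, 100.0 - tail), np.percentile(xm, 100.0 - tail))
    if not lo < hi:
        raise NoOverlapError(
            f"central-{central:.0%} intervals do not overlap (lo={lo:.4g}, hi={hi:.4g})"
        )
    return np.linspace(lo, hi, n_bins + 1)


def fisher_combine(pvalues) -> tuple[float, int, float]:
    """Fisher's method: ``X^2 = -2 sum(ln p)`` referred to a chi-square
    with ``2k`` degrees of freedom.  Returns ``(X^2, df, combined_p)``."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite P-values to combine")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("P-values must lie in (0, 1]")
    x2 = float(-2.0 * np.sum(np.log(p)))
    df = int(2 * p.size)
    return x2, df, float(stats.chi2.sf(x2, df))


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) P-value.

    Exact null enumeration when both samples have at most
    :data:`EXACT_WILCOXON_MAX_N` observations and no ties; otherwise the
    normal approximation with tie and continuity corrections.  Completely
    tied data (zero rank variance) gives P = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0.0:
        return 1.0
    no_ties = np.unique(combined).size == combined.size
    if no_ties and max(x.size, y.size) <= EXACT_WILCOXON_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def binned_offset(
    reference: pd.DataFrame,
    mutant: pd.DataFrame,
    response: str = "g1_duration",
    bins: Optional[np.ndarray] = None,
    n_bins: int = 10,
    central: float = 0.80,
    min_count: int = 5,
) -> BinnedComparison:
    """Birth-size-normalized mutant-vs-reference comparison.

    Within each size bin the mutant-minus-reference difference of medians
    and a two-sided Wilcoxon rank-sum P are computed; bins holding fewer
    than ``min_count`` cells from either strain are dropped (degrees of
    freedom adjust).  The mean offset is the unweighted average of the
    per-bin median differences and Fisher's method combines the P-values:
    ``X^2 = -2 * sum(log p)`` on ``2 * n_contributing_bins`` degrees of
    freedom.
    """
    ref = _clean(reference, response)
    mut = _clean(mutant, response)
    xr, xm = _predictor(ref, response), _predictor(mut, response)
    if bins is None:
        bins = overlap_bins(xr, xm, n_bins=n_bins, central=central)
    bins = np.asarray(bins, dtype=float)
    k = bins.size - 1
    yr, ym = response_values(ref, response), response_values(mut, response)

    med_diff = np.full(k, np.nan)
    pvals = np.full(k, np.nan)
    n_ref = np.zeros(k, dtype=int)
    n_mut = np.zeros(k, dtype=int)
    for i in range(k):
        in_r = (xr >= bins[i]) & (xr < bins[i + 1] if i < k - 1 else xr <= bins[i + 1])
        in_m = (xm >= bins[i]) & (xm < bins[i + 1] if i < k - 1 else xm <= bins[i + 1])
        n_ref[i], n_mut[i] = int(in_r.sum()), int(in_m.sum())
        if n_ref[i] < min_count or n_mut[i] < min_count:
            continue
        med_diff[i] = np.median(ym[in_m]) - np.median(yr[in_r])
        pvals[i] = wilcoxon_rank_sum(yr[in_r], ym[in_m])

    ok = np.isfinite(pvals)
    if not ok.any():
        raise SparseBinsError(
            f"no bin holds >= {min_count} cells from both strains (response={response})"
        )
    x2, df, combined_p = fisher_combine(pvals[ok])
    return BinnedComparison(
        response=response,
        bin_edges=bins,
        per_bin_median_diff=med_diff,
        per_bin_p=pvals,
        per_bin_n_ref=n_ref,
        per_bin_n_mut=n_mut,
        mean_offset=float(np.nanmean(med_diff)),
        fisher_statistic=x2,
        fisher_df=df,
        combined_p=combined_p,
    )


# ---------------------------------------------------------------------------
# Classification


def doubling_time_estimate(records: pd.DataFrame) -> float:
    """Culture doubling time (min) from observed cycle lengths.

    Under asymmetric division the population number-growth rate ``r``
    solves the Euler-Lotka relation for a division producing one mother
    and one daughter, ``exp(-r*tau_m) + exp(-r*tau_d) = 1``, with ``tau_m``
    and ``tau_d`` the median mother and daughter cycle lengths; the
    doubling time is ``ln 2 / r``.  Mother cycles are much shorter than
    daughter cycles (daughters are born small and extend G1), so neither
    median alone is a doubling time.  When cell roles are unavailable the
    median cycle length of all cells is returned as a fallback.
    """
    rec = records
    if "censored" in rec:
        rec = rec.loc[~rec["censored"].astype(bool)]
    rec = rec.dropna(subset=["birth_time", "division_time"])
    if not len(rec):
        return float("nan")
    cycle = rec["division_time"] - rec["birth_time"]
    roles = rec["cell_role"] if "cell_role" in rec else pd.Series("unknown", index=rec.index)
    tau_m = float(cycle[roles == "mother"].median())
    tau_d = float(cycle[roles == "daughter"].median())
    if not (np.isfinite(tau_m) and np.isfinite(tau_d)):
        return float(cycle.median())

    def euler_lotka(r: float) -> float:
        return math.exp(-r * tau_m) + math.exp(-r * tau_d) - 1.0

    from scipy.optimize import brentq

    hi = 2.0 / min(tau_m, tau_d)
    r = brentq(euler_lotka, 1e-9, hi)
    return math.log(2.0) / r


def classify_strain(
    reference: pd.DataFrame,
    mutant: pd.DataFrame,
    strain_id: Optional[str] = None,
    alpha: float = 0.001,
    n_bins: int = 10,
    central: float = 0.80,
    min_count: int = 5,
    daughters_only: bool = True,
) -> ClassificationResult:
    """Place a mutant in the 3x3 (G1 duration x delta_v) category grid.

    Both responses share the bins from the log-birth-size overlap.  A
    response is called non-normal when its Fisher combined P is below
    ``alpha``; the direction is the sign of the mean offset.  ``negative``
    regulators require shorter G1 and decreased delta_v; ``positive``
    regulators require longer G1 (a shorter G1 with normal delta_v is not a
    negative-regulator call).  Strains whose doubling time falls outside
    86-124 min are flagged slow-growing: for them the G1-vs-birth-size
    comparison is no longer growth-rate invariant.
    """
    if strain_id is None:
        strain_id = str(mutant["strain_id"].iloc[0]) if len(mutant) else "mutant"
    ref = daughters(reference) if daughters_only else reference
    mut_d = daughters(mutant) if daughters_only else mutant
    ref_c, mut_c = _clean(ref, "g1_duration"), _clean(mut_d, "g1_duration")
    bins = overlap_bins(
        np.log(ref_c["birth_volume"].to_numpy(float)),
        np.log(mut_c["birth_volume"].to_numpy(float)),
        n_bins=n_bins,
        central=central,
    )
    g1 = binned_offset(ref, mut_d, "g1_duration", bins=bins, min_count=min_count)
    dv = binned_offset(ref, mut_d, "delta_v", bins=bins, min_count=min_count)

    if g1.combined_p < alpha:
        g1_call = "shorter" if g1.mean_offset < 0 else "longer"
    else:
        g1_call = "normal"
    if dv.combined_p < alpha:
        dv_call = "decreased" if dv.mean_offset < 0 else "increased"
    else:
        dv_call = "normal"

    if g1_call == "shorter" and dv_call == "decreased":
        label = "negative"
    elif g1_call == "longer":
        label = "positive"
    else:
        label = "none"

    td = doubling_time_estimate(mutant)
    slow = bool(np.isfinite(td) and not (DOUBLING_TIME_BAND[0] <= td <= DOUBLING_TIME_BAND[1]))
    return ClassificationResult(
        strain_id=strain_id,
        g1_call=g1_call,
        dv_call=dv_call,
        category=f"{g1_call}/{dv_call}",
        regulator_label=label,
        g1=g1,
        dv=dv,
        doubling_time=td,
        slow_growth_flag=slow,
    )


def expected_false_positives(alpha: float, n_strains: int, n_responses: int = 2) -> float:
    """Expected count of false non-normal calls across a screen of
    ``n_strains`` strains tested on ``n_responses`` responses at level
    ``alpha`` (no multiple-testing correction is applied in the screen;
    this expected count is the reported control)."""
    return alpha * n_strains * n_responses


# ---------------------------------------------------------------------------
# Condition invariance


def condition_invariance(
    samples: dict[str, pd.DataFrame],
    response: str = "g1_duration",
    n_bins: int = 10,
    central: float = 0.80,
    min_count: int = 5,
    daughters_only: bool = True,
) -> pd.DataFrame:
    """Compare a response across growth conditions at matched birth sizes.

    Bins span the intersection of every condition's central interval of log
    birth size.  The returned table has one row per bin with the per-
    condition median and count (``median_<name>``, ``n_<name>``) and, for
    every condition pair, a two-sided Wilcoxon P (``p_<a>_vs_<b>``).  With
    a single condition no tests are run.
    """
    if not samples:
        raise ValueError("need at least one condition sample")
    cleaned = {}
    for name, rec in samples.items():
        rec = daughters(rec) if daughters_only else rec
        cleaned[name] = _clean(rec, response)
    tail = 100.0 * (1.0 - central) / 2.0
    los, his = [], []
    for rec in cleaned.values():
        x = np.log(rec["birth_volume"].to_numpy(float))
        los.append(np.percentile(x, tail))
        his.append(np.percentile(x, 100.0 - tail))
    lo, hi = max(los), min(his)
    if not lo < hi:
        raise NoOverlapError("condition birth-size intervals do not overlap")
    bins = np.linspace(lo, hi, n_bins + 1)

    names = list(cleaned)
    rows = []
    for i in range(n_bins):
        row: dict = {"bin": i, "bin_lo": bins[i], "bin_hi": bins[i + 1]}
        values = {}
        for name in names:
            rec = cleaned[name]
            x = np.log(rec["birth_volume"].to_numpy(float))
            last = i == n_bins - 1
            mask = (x >= bins[i]) & ((x <= bins[i + 1]) if last else (x < bins[i + 1]))
            v = response_values(rec, response)[mask]
            values[name] = v
            row[f"n_{name}"] = v.size
            row[f"median_{name}"] = float(np.median(v)) if v.size else np.nan
        for a_i, a in enumerate(names):
            for b in names[a_i + 1 :]:
                va, vb = values[a], values[b]
                if va.size >= min_count and vb.size >= min_count:
                    row[f"p_{a}_vs_{b}"] = wilcoxon_rank_sum(va, vb)
                else:
                    row[f"p_{a}_vs_{b}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Budded-phase backup size control


def budded_phase_control(
    samples: dict[str, pd.DataFrame],
    n_per_strain: int = 300,
    seed: int = 0,
    n_bins: int = 10,
    daughters_only: bool = True,
) -> tuple[SizeControlFit, pd.DataFrame]:
    """Pooled regression of budded-phase duration on budding volume.

    From each strain, ``n_per_strain`` uncensored cells are drawn without
    replacement (all cells, with a warning-free fallback, when fewer are
    available) so every strain contributes equally; the pooled cells are
    fit by OLS and also binned on budding volume for a mean curve.  Returns
    the fit (slope in min per volume unit) and the binned table.
    """
    if not samples:
        raise ValueError("need at least one strain sample")
    rng = np.random.default_rng(seed)
    pooled = []
    for name in sorted(samples):
        rec = samples[name]
        rec = daughters(rec) if daughters_only else rec
        rec = _clean(rec, "budded_duration")
        if len(rec) > n_per_strain:
            idx = np.sort(rng.choice(len(rec), n_per_strain, replace=False))
            rec = rec.iloc[idx]
        pooled.append(rec)
    pool = pd.concat(pooled, ignore_index=True)
    if not len(pool):
        raise ValueError("no uncensored cells in the pooled sample")

    x = pool["budding_volume"].to_numpy(float)
    y = response_values(pool, "budded_duration")
    res = stats.linregress(x, y)
    fit = SizeControlFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        slope_se=float(res.stderr),
        n=len(pool),
    )
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    rows = []
    for i in range(n_bins):
        last = i == n_bins - 1
        mask = (x >= edges[i]) & ((x <= edges[i + 1]) if last else (x < edges[i + 1]))
        rows.append(
            {
                "bin_lo": edges[i],
                "bin_hi": edges[i + 1],
                "n": int(mask.sum()),
                "mean_budding_volume": float(x[mask].mean()) if mask.any() else np.nan,
                "mean_budded_duration": float(y[mask].mean()) if mask.any() else np.nan,
            }
        )
    return fit, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Summaries


def strain_summary(records: pd.DataFrame) -> pd.Series:
    """Per-strain summary: daughter birth/budding volumes and phase
    durations (mean and median), mother-based doubling time, counts."""
    if not len(records):
        raise ValueError("empty record set")
    d = daughters(records) if "cell_role" in records else records
    if not len(d):
        d = records
    g1 = (d["budding_time"] - d["birth_time"]).to_numpy(float)
    budded = (d["division_time"] - d["budding_time"]).to_numpy(float)
    out = {
        "strain_id": records["strain_id"].iloc[0] if "strain_id" in records else "unknown",
        "n_cells": len(records),
        "n_daughters": len(d),
        "mean_birth_volume": float(d["birth_volume"].mean()),
        "median_birth_volume": float(d["birth_volume"].median()),
        "mean_budding_volume": float(d["budding_volume"].mean()),
        "median_budding_volume": float(d["budding_volume"].median()),
        "mean_g1": float(np.nanmean(g1)),
        "median_g1": float(np.nanmedian(g1)),
        "mean_budded": float(np.nanmean(budded)),
        "median_budded": float(np.nanmedian(budded)),
        "doubling_time": doubling_time_estimate(records),
    }
    return pd.Series(out)
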