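"""Synthetic single-cell data with known ground truth.

Generates the four kinds of data the screen analysis consumes: tracked
cell-cycle lineages under pluggable G1 size-control laws, per-cell
time-lapse traces (volume, bud-neck marker, nucleus count), DNA-content
flow-cytometry event tables, and competition-assay frequency series.

The lineage model: each cell grows exponentially, ``V(t) = Vb * exp(a*t)``,
with a cell-specific rate ``a`` drawn at birth.  G1 ends (the cell buds)
according to the configured control law; the budded phase has a weakly
size-dependent duration; at division a fixed fraction ``phi`` of the
mother's volume becomes the daughter.  All times are minutes from movie
start, volumes are in arbitrary units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "CONTROL_MODES",
    "RECORD_COLUMNS",
    "TRACE_COLUMNS",
    "simulate_lineage",
    "simulate_traces",
    "simulate_flow_events",
    "simulate_competition",
    "daughters",
]

CONTROL_MODES = ("checkpoint", "weak_sizer", "timer", "size_programmed", "rate_modulated")

#: Cells born closer than this to the movie end are censored (their cycle
#: may not complete within the observation window).
CENSOR_MARGIN_MIN = 100.0

RECORD_COLUMNS = [
    "strain_id",
    "cell_id",
    "mother_id",
    "generation",
    "cell_role",
    "birth_time",
    "birth_volume",
    "budding_time",
    "budding_volume",
    "division_time",
    "division_volume",
    "growth_rate",
    "censored",
]

TRACE_COLUMNS = ["cell_id", "time", "volume", "budneck", "nuclei"]


class ConfigurationError(ValueError):
    """Raised for invalid or incomplete simulation configurations."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the lineage simulator.

    Only the parameters of the selected ``control_mode`` are used for G1;
    the budded phase, division asymmetry and founder distribution apply to
    every mode.

    Parameters
    ----------
    control_mode:
        G1 size-control law.  ``checkpoint``: bud when volume crosses a
        fixed threshold ``threshold_volume`` (with multiplicative noise);
        ``weak_sizer``: log budding volume = ``weak_sizer_intercept`` +
        ``weak_sizer_gain`` * log birth volume + noise; ``timer``: G1
        duration drawn around ``timer_mean`` independent of size;
        ``size_programmed``: G1 duration = max(0, tau0 - tau1 * log birth
        volume) + noise; ``rate_modulated``: stochastic G1 exit with hazard
        ``lambda0 * (V/V0)**k``, sampled exactly from the integrated hazard.
    mean_growth_rate:
        Population-mean exponential volume growth rate (1/min).  Per-cell
        rates are Normal(mean, cv*mean), truncated to positive.
    bud_fraction:
        Fraction ``phi`` of the division volume given to the daughter.
    birth_mu, birth_sigma:
        Log-mean / log-sd of founder birth volumes (lognormal).
    """

    control_mode: str = "checkpoint"
    strain_id: str = "WT"

    # growth
    mean_growth_rate: float = 0.007  # 1/min; volume doubling ~99 min
    growth_rate_cv: float = 0.10

    # checkpoint
    threshold_volume: Optional[float] = 40.0
    threshold_noise_cv: float = 0.05  # multiplicative (lognormal) noise on the threshold

    # weak sizer: log Vs = c + g * log Vb + noise
    weak_sizer_gain: Optional[float] = 0.5
    weak_sizer_intercept: Optional[float] = None  # default: median budding volume 40

    # timer
    timer_mean: Optional[float] = 60.0
    timer_sd: float = 5.0

    # size-programmed G1: T = max(0, tau0 - tau1 * log Vb) + noise
    size_programmed_tau0: Optional[float] = None  # default: log(40)/alpha
    size_programmed_tau1: Optional[float] = None  # default: 1/alpha
    g1_noise_sd: float = 3.0  # min, additive on timer/size-programmed durations

    # rate-modulated exit: hazard lambda0 * (V/V0)**k
    rate_lambda0: Optional[float] = 0.03
    rate_exponent: Optional[float] = 2.0
    rate_ref_volume: Optional[float] = 40.0

    # budded phase: duration = max(floor, a - b * Vs + noise).  The default
    # keeps mother sizes stationary under asymmetric division:
    # (1 - phi) * exp(alpha * Tb) < 1 requires Tb < ln(1/(1-phi))/alpha
    # (~73 min at the default alpha and phi).
    budded_base: float = 65.0
    budded_size_slope: float = 0.01  # min per volume unit
    budded_noise_sd: float = 3.0

    # division and founders
    bud_fraction: float = 0.4
    birth_mu: float = math.log(25.0)
    birth_sigma: float = 0.198  # ~20% CV

    # movie / sampling
    movie_length: float = 360.0
    sampling_interval: float = 3.0
    n_founders: int = 100
    max_cells: Optional[int] = None  # cap on concurrently tracked cells (long runs)

    # trace synthesis
    trace_noise_cv: float = 0.02  # multiplicative volume measurement noise
    nuclear_sep_offset: float = 12.0  # min before division; must be <= 30
    budneck_plateau: float = 1.0
    budneck_baseline: float = 0.05
    budneck_noise_sd: float = 0.03

    seed: int = 0

    def __post_init__(self) -> None:
        if self.control_mode not in CONTROL_MODES:
            raise ConfigurationError(f"unknown control_mode {self.control_mode!r}")
        positives = {
            "mean_growth_rate": self.mean_growth_rate,
            "movie_length": self.movie_length,
            "sampling_interval": self.sampling_interval,
            "budded_base": self.budded_base,
        }
        for name, value in positives.items():
            if not np.isfinite(value) or value <= 0:
                raise ConfigurationError(f"{name} must be finite and positive, got {value}")
        for name, value in (
            ("growth_rate_cv", self.growth_rate_cv),
            ("threshold_noise_cv", self.threshold_noise_cv),
            ("g1_noise_sd", self.g1_noise_sd),
            ("budded_noise_sd", self.budded_noise_sd),
            ("budded_size_slope", self.budded_size_slope),
            ("trace_noise_cv", self.trace_noise_cv),
        ):
            if not np.isfinite(value) or value < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0, got {value}")
        if not 0 < self.bud_fraction < 1:
            raise ConfigurationError("bud_fraction must lie in (0, 1)")
        if not np.isfinite(self.birth_mu) or not (self.birth_sigma >= 0):
            raise ConfigurationError("invalid birth lognormal parameters")
        if not 0 < self.nuclear_sep_offset <= 30:
            raise ConfigurationError("nuclear_sep_offset must lie in (0, 30] min")
        if self.n_founders < 1:
            raise ConfigurationError("n_founders must be >= 1")
        self._check_mode_params()

    def _check_mode_params(self) -> None:
        def require(name: str, value, positive: bool = True) -> None:
            if value is None or not np.isfinite(value) or (positive and value <= 0):
                raise ConfigurationError(
                    f"control_mode={self.control_mode!r} requires a finite"
                    f"{' positive' if positive else ''} {name}, got {value}"
                )

        mode = self.control_mode
        if mode == "checkpoint":
            require("threshold_volume", self.threshold_volume)
        elif mode == "weak_sizer":
            require("weak_sizer_gain", self.weak_sizer_gain)
            if not 0 < self.weak_sizer_gain < 1:
                raise ConfigurationError("weak_sizer_gain must lie in (0, 1)")
        elif mode == "timer":
            require("timer_mean", self.timer_mean)
        elif mode == "rate_modulated":
            require("rate_lambda0", self.rate_lambda0)
            require("rate_exponent", self.rate_exponent)
            require("rate_ref_volume", self.rate_ref_volume)
        # size_programmed defaults are derived from the growth rate below.

    # Derived defaults ---------------------------------------------------

    @property
    def sizer_intercept(self) -> float:
        """Weak-sizer intercept; defaults to a median budding volume of 40."""
        if self.weak_sizer_intercept is not None:
            return self.weak_sizer_intercept
        return math.log(40.0) - float(self.weak_sizer_gain) * self.birth_mu

    @property
    def tau0(self) -> float:
        if self.size_programmed_tau0 is not None:
            return self.size_programmed_tau0
        return math.log(40.0) / self.mean_growth_rate

    @property
    def tau1(self) -> float:
        if self.size_programmed_tau1 is not None:
            return self.size_programmed_tau1
        return 1.0 / self.mean_growth_rate

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# G1 exit sampling


def _g1_durations(cfg: SimConfig, vb: np.ndarray, alpha: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample G1 durations (min) for cells with birth volumes ``vb`` and
    growth rates ``alpha`` under the configured control law."""
    n = vb.size
    floor = cfg.sampling_interval
    log_vb = np.log(vb)
    mode = cfg.control_mode

    if mode == "checkpoint":
        sigma = math.sqrt(math.log1p(cfg.threshold_noise_cv**2))
        log_target = math.log(cfg.threshold_volume) + rng.normal(0.0, sigma, n)
        t = (log_target - log_vb) / alpha
    elif mode == "weak_sizer":
        sigma = math.sqrt(math.log1p(cfg.threshold_noise_cv**2))
        log_vs = cfg.sizer_intercept + cfg.weak_sizer_gain * log_vb + rng.normal(0.0, sigma, n)
        t = (log_vs - log_vb) / alpha
    elif mode == "timer":
        t = rng.normal(cfg.timer_mean, cfg.timer_sd, n)
    elif mode == "size_programmed":
        t = np.maximum(0.0, cfg.tau0 - cfg.tau1 * log_vb) + rng.normal(0.0, cfg.g1_noise_sd, n)
    elif mode == "rate_modulated":
        # Hazard h(t) = lambda0 * (V(t)/V0)**k with V(t) = Vb*exp(alpha*t).
        # Integrated hazard H(t) = lambda0*(Vb/V0)**k * (exp(k*alpha*t)-1)/(k*alpha)
        # is available in closed form, so exit times are sampled exactly by
        # inversion: T = log(1 + u*k*alpha/(lambda0*(Vb/V0)**k)) / (k*alpha).
        k = cfg.rate_exponent
        u = rng.exponential(1.0, n)
        ka = k * alpha
        scale = cfg.rate_lambda0 * (vb / cfg.rate_ref_volume) ** k
        t = np.log1p(u * ka / scale) / ka
    else:  # pragma: no cover - guarded by SimConfig
        raise ConfigurationError(mode)

    # Observable G1 cannot be shorter than the frame spacing.
    return np.maximum(floor, t)


# ---------------------------------------------------------------------------
# Lineage simulation


def simulate_lineage(config: SimConfig, include_censored: bool = False) -> pd.DataFrame:
    """Simulate a branching cell lineage and return one row per tracked cell.

    Founder cells (generation 0, role ``daughter``) are born at time 0 with
    lognormal volumes.  Each completed cycle spawns a daughter (receiving
    fraction ``bud_fraction`` of the division volume) and continues the
    mother (role ``mother``), both re-entering G1 under the same control
    law.  Cells born within :data:`CENSOR_MARGIN_MIN` of the movie end, or
    whose division falls beyond it, are flagged censored; by default they
    are dropped (pass ``include_censored=True`` to keep them, e.g. for
    trace synthesis).

    Returns a :class:`pandas.DataFrame` with :data:`RECORD_COLUMNS`.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n0 = cfg.n_founders

    def draw_alpha(n: int) -> np.ndarray:
        a = rng.normal(cfg.mean_growth_rate, cfg.growth_rate_cv * cfg.mean_growth_rate, n)
        tiny = 0.1 * cfg.mean_growth_rate
        return np.maximum(a, tiny)

    # Active front: cells that have been born but not yet simulated.
    birth_time = np.zeros(n0)
    vb = np.exp(rng.normal(cfg.birth_mu, cfg.birth_sigma, n0))
    generation = np.zeros(n0, dtype=int)
    role = np.full(n0, "daughter", dtype=object)
    mother = np.full(n0, -1, dtype=int)
    cell_id = np.arange(n0)
    next_id = n0

    out: list[pd.DataFrame] = []
    while birth_time.size:
        alpha = draw_alpha(birth_time.size)
        t_g1 = _g1_durations(cfg, vb, alpha, rng)
        t_bud = birth_time + t_g1
        vs = vb * np.exp(alpha * t_g1)
        t_budded = np.maximum(
            cfg.sampling_interval,
            cfg.budded_base - cfg.budded_size_slope * vs + rng.normal(0.0, cfg.budded_noise_sd, vs.size),
        )
        t_div = t_bud + t_budded
        vd = vs * np.exp(alpha * t_budded)
        censored = (birth_time > cfg.movie_length - CENSOR_MARGIN_MIN) | (t_div > cfg.movie_length)

        out.append(
            pd.DataFrame(
                {
                    "strain_id": cfg.strain_id,
                    "cell_id": cell_id,
                    "mother_id": mother,
                    "generation": generation,
                    "cell_role": role,
                    "birth_time": birth_time,
                    "birth_volume": vb,
                    "budding_time": t_bud,
                    "budding_volume": vs,
                    "division_time": t_div,
                    "division_volume": vd,
                    "growth_rate": alpha,
                    "censored": censored,
                }
            )
        )

        # Spawn the next front from cycles completed inside the movie.
        done = t_div < cfg.movie_length
        if not done.any():
            break
        d_vb = cfg.bud_fraction * vd[done]
        m_vb = (1.0 - cfg.bud_fraction) * vd[done]
        n_new = int(done.sum())
        d_ids = next_id + np.arange(n_new)
        m_ids = next_id + n_new + np.arange(n_new)
        next_id += 2 * n_new

        birth_time = np.concatenate([t_div[done], t_div[done]])
        vb = np.concatenate([d_vb, m_vb])
        generation = np.concatenate([generation[done] + 1, generation[done] + 1])
        role = np.concatenate(
            [np.full(n_new, "daughter", dtype=object), np.full(n_new, "mother", dtype=object)]
        )
        mother = np.concatenate([cell_id[done], cell_id[done]])
        cell_id = np.concatenate([d_ids, m_ids])

        if cfg.max_cells is not None and birth_time.size > cfg.max_cells:
            keep = rng.choice(birth_time.size, cfg.max_cells, replace=False)
            keep.sort()
            birth_time, vb = birth_time[keep], vb[keep]
            generation, role = generation[keep], role[keep]
            mother, cell_id = mother[keep], cell_id[keep]

    records = pd.concat(out, ignore_index=True)
    records = records.sort_values("cell_id", ignore_index=True)
    if not include_censored:
        records = records.loc[~records["censored"]].reset_index(drop=True)
    return records


def daughters(records: pd.DataFrame, uncensored: bool = True) -> pd.DataFrame:
    """Daughter-cell records (optionally only uncensored ones).

    Size control in budding yeast acts almost exclusively on daughters, so
    the quantitative analyses run on this subset.
    """
    mask = records["cell_role"] == "daughter"
    if uncensored and "censored" in records:
        mask &= ~records["censored"].astype(bool)
    return records.loc[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Trace synthesis

#: Lead time (min) of trace before birth: long enough to show the bud-neck
#: plateau and the nuclear separation of the division that created the cell.
_TRACE_LEAD = 24.0
_TRACE_TAIL = 6.0


def simulate_traces(records: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Emulate the imaging readouts for each tracked cell.

    Per cell, samples on the global frame grid (multiples of
    ``sampling_interval``) spanning a short window around the cycle:

    * volume — exponential growth from the true birth volume with
      multiplicative lognormal measurement noise;
    * bud-neck intensity — high plateau before birth (the neck whose
      disappearance marks birth) and during the budded phase, near zero in
      G1 and after division;
    * nucleus count — 2 during the ``nuclear_sep_offset`` minutes preceding
      birth and preceding division (nuclear separation), 1 otherwise.

    Frames beyond ``movie_length`` are not emitted, so cells whose cycle
    runs past the movie end produce truncated traces.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7ACE]))
    dt = cfg.sampling_interval
    sigma_v = math.sqrt(math.log1p(cfg.trace_noise_cv**2)) if cfg.trace_noise_cv > 0 else 0.0

    frames = []
    for row in records.itertuples(index=False):
        t0 = max(0.0, row.birth_time - _TRACE_LEAD)
        t1 = min(cfg.movie_length, row.division_time + _TRACE_TAIL)
        k0, k1 = math.ceil(t0 / dt), math.floor(t1 / dt)
        if k1 < k0:
            continue
        t = np.arange(k0, k1 + 1) * dt
        v = row.birth_volume * np.exp(row.growth_rate * (t - row.birth_time))
        if sigma_v:
            v = v * np.exp(rng.normal(0.0, sigma_v, t.size))
        neck_high = (t < row.birth_time) | ((t >= row.budding_time) & (t < row.division_time))
        neck = np.where(neck_high, cfg.budneck_plateau, cfg.budneck_baseline)
        if cfg.budneck_noise_sd:
            neck = np.abs(neck + rng.normal(0.0, cfg.budneck_noise_sd, t.size))
        off = cfg.nuclear_sep_offset
        two = ((t >= row.birth_time - off) & (t < row.birth_time)) | (
            (t >= row.division_time - off) & (t < row.division_time)
        )
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": row.cell_id,
                    "time": t,
                    "volume": v,
                    "budneck": neck,
                    "nuclei": np.where(two, 2, 1),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=TRACE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Flow-cytometry event synthesis


def simulate_flow_events(
    fractions: tuple[float, float, float],
    n_events: int = 30_000,
    cv: float = 0.05,
    doublet_rate: float = 0.0,
    debris_rate: float = 0.0,
    seed: int = 0,
    mean_g1_area: float = 50_000.0,
    width_mean: float = 100.0,
    width_sd: float = 8.0,
    well: str = "A1",
    plate: str = "P1",
) -> pd.DataFrame:
    """Generate a DNA-content event table with ground-truth labels.

    ``fractions`` are the (G1, S, G2) phase fractions among singlets.
    Singlet fluorescence areas sit at 1C (G1), 2C (G2) or uniformly in
    between (S), perturbed multiplicatively with Gaussian coefficient of
    variation ``cv``.  Doublets are sums of two singlet areas with an
    inflated pulse width; debris are low-area events below the stain gate.
    The ``label`` column records the true class of every event.
    """
    f = np.asarray(fractions, dtype=float)
    if f.size != 3 or (f < 0).any():
        raise ValueError("fractions must be three non-negative numbers")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {f.sum()!r}")
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not 0 <= doublet_rate < 1 or not 0 <= debris_rate < 1 or doublet_rate + debris_rate >= 1:
        raise ValueError("doublet_rate and debris_rate must be fractions summing below 1")

    rng = np.random.default_rng(seed)
    a1 = mean_g1_area

    def singlet_areas(n: int) -> tuple[np.ndarray, np.ndarray]:
        phase = rng.choice(3, n, p=f)
        base = np.where(phase == 0, a1, np.where(phase == 2, 2 * a1, 0.0))
        n_s = int((phase == 1).sum())
        base[phase == 1] = rng.uniform(a1, 2 * a1, n_s)
        area = base * (1.0 + cv * rng.standard_normal(n))
        return area, phase

    n_doub = int(round(doublet_rate * n_events))
    n_deb = int(round(debris_rate * n_events))
    n_sing = n_events - n_doub - n_deb

    s_area, s_phase = singlet_areas(n_sing)
    d_area = singlet_areas(n_doub)[0] + singlet_areas(n_doub)[0]
    deb_area = np.exp(rng.normal(math.log(3000.0), 0.4, n_deb))

    s_width = rng.normal(width_mean, width_sd, n_sing)
    d_width = rng.normal(1.8 * width_mean, 1.5 * width_sd, n_doub)
    deb_width = rng.normal(width_mean, width_sd, n_deb)

    area = np.concatenate([s_area, d_area, deb_area])
    width = np.concatenate([s_width, d_width, deb_width])
    phase_names = np.array(["g1", "s", "g2"], dtype=object)
    label = np.concatenate(
        [phase_names[s_phase], np.full(n_doub, "doublet", dtype=object), np.full(n_deb, "debris", dtype=object)]
    )

    fsc = (area / 1000.0) * (1.0 + 0.1 * rng.standard_normal(n_events))
    ssc = (area / 2000.0) * (1.0 + 0.2 * rng.standard_normal(n_events))

    events = pd.DataFrame(
        {
            "plate": plate,
            "well": well,
            "area": area,
            "width": width,
            "fsc": fsc,
            "ssc": ssc,
            "label": label,
        }
    )
    return events.sample(frac=1.0, random_state=np.random.RandomState(seed)).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Competition assay synthesis


def simulate_competition(
    s: float,
    generations_per_day: float = 10.0,
    n_days: int = 4,
    f0: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a serial-dilution competition between a labeled reference
    strain and a competitor with per-generation selection coefficient ``s``.

    Under constant selection the log2 odds of the reference decrease
    linearly by ``s`` per generation (``s > 0``: the competitor is fitter).
    One frequency observation is taken per day; observation noise of
    standard deviation ``noise_sd`` is added on the log2-odds scale.
    Returns a table with columns ``day``, ``frequency`` (of the reference)
    and ``dilution_factor`` (= ``2**generations_per_day``).
    """
    if not 0 < f0 < 1:
        raise ValueError("f0 must lie in (0, 1)")
    if n_days < 1 or generations_per_day <= 0 or noise_sd < 0:
        raise ValueError("invalid competition parameters")
    rng = np.random.default_rng(seed)
    days = np.arange(n_days + 1)
    logit0 = math.log2(f0 / (1.0 - f0))
    logit = logit0 - s * generations_per_day * days
    if noise_sd:
        logit = logit + rng.normal(0.0, noise_sd, days.size)
    freq = 1.0 / (1.0 + 2.0 ** (-logit))
    return pd.DataFrame(
        {"day": days, "frequency": freq, "dilution_factor": 2.0**generations_per_day}
    )
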