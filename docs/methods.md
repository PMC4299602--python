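# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the limitations of the `sizescreen` pipeline. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Lineage model

Each cell grows exponentially, `V(t) = V_b e^{αt}`, with a per-cell rate
`α ~ Normal(ᾱ, cv·ᾱ)` drawn at birth (truncated at `0.1·ᾱ`; defaults
`ᾱ = 0.007/min`, `cv = 0.10`, i.e. a ~99-min volume doubling). G1 ends
(the cell buds) according to the configured control law:

- **checkpoint** — bud when `V` crosses `V*` with multiplicative lognormal
  threshold noise (`threshold_noise_cv`, default 5%); the exit time is the
  analytic inversion `T = (log V*ε − log V_b)/α`.
- **weak_sizer** — `log V_s = c + g·log V_b + ε`, `g ∈ (0,1)`; the induced
  ΔV-vs-log V_b slope is `g − 1`.
- **timer** — `T ~ Normal(T̄, sd)`, independent of size.
- **size_programmed** — `T = max(0, τ₀ − τ₁·log V_b) + ε`: birth size
  directly sets G1 duration, so the G1-vs-birth-size curve is invariant to
  the growth rate while ΔV = αT scales with it. Defaults
  `τ₀ = log(40)/ᾱ`, `τ₁ = 1/ᾱ` mimic the checkpoint at the mean rate.
- **rate_modulated** — size sets the *rate* of cycle progression rather
  than acting as a hard requirement: G1 exit is a hazard process with
  `λ(t) = λ₀ (V(t)/V₀)^k`. Because `Λ(t) = λ₀(V_b/V₀)^k (e^{kαt}−1)/(kα)`
  is closed-form under exponential growth, exit times are sampled exactly
  by inverting the integrated hazard against an Exp(1) draw — no
  time-discretization bias. With `k ≥ 1` this law is sufficient for size
  homeostasis (bounded birth-size variance across generations), which the
  acceptance suite verifies.

All G1 durations are floored at one sampling interval: observable G1
cannot be shorter than the frame spacing.

The budded phase lasts `max(Δ, a − b·V_s + ε)` — a weak negative
dependence on budding size (the "backup" size control; `b` in min per
volume unit). At division the daughter receives a fixed fraction
`φ = 0.4` of the division volume and the mother keeps the rest; both
re-enter G1 under the same law. A single bud-fraction parameter is the
simplest asymmetric-division model.

**Default consistency.** Volumes are arbitrary "pxl³-like" units with no
physical calibration. Defaults (`V* = 40`, founder median birth volume 25,
`a = 65 min`, `b = 0.01`) were chosen jointly so the wild-type steady
state is stationary and realistic: mother sizes are stationary only when
`(1−φ)e^{αT_b} ≤ 1`, i.e. `T_b ≤ ln(1/(1−φ))/α ≈ 73 min`; with `a = 65`
the stationary daughter birth volume is `φ·V*·e^{αT_b} ≈ 25`, daughter
cycles run ≈131 min, mother cycles ≈73 min, and the culture doubling time
is ≈99 min, inside the 86–124 min band where the G1-vs-birth-size
comparison is growth-rate invariant. For the budded-phase analysis, whose
slope is quoted in min/pxl³, the tests use a ×50 volume scale
(`V* ≈ 2000`, `b = 0.01`, noise 15 min) so that the pooled regression has
the same signal-to-noise regime as the published wild-type fit.

**Movies and censoring.** Movies default to 360 min sampled every 3 min.
Cells born within 100 min of the movie end, or whose cycle runs past it,
are flagged censored and excluded from analyses by default. Cohort-style
studies (e.g. the 5,000-daughter slope benchmark) use a longer movie
(600 min) so that even slow, small-born founders complete their cycle —
otherwise movie-end truncation selectively removes long-G1 cells and
biases the regression; the lineage front after generation 0 is subsampled
(`max_cells`) to keep such runs cheap.

## Synthetic traces and landmark extraction

Traces emulate the imaging readouts on the global 3-min frame grid:
volume with multiplicative lognormal measurement noise (default CV 2%);
bud-neck marker high before birth (the neck whose disappearance defines
birth), low in G1, high through the budded phase, dropping at division;
nucleus count 2 during the 12 min preceding each division (nuclear
separation), 1 otherwise.

Extraction anchors each bud-neck disappearance at the nearest nuclear
separation (window ±30 min). A "significant decrease" is quantified as a
drop below 0.5 of the trailing plateau (median of the preceding 5 frames)
sustained for ≥2 frames; appearance is symmetric against the following
plateau. Candidate frames in low-signal regions are suppressed by
requiring the local plateau to reach 30% of the trace's 90th-percentile
intensity; ties between candidate drops are broken toward the nuclear
separation. All reported landmark times are members of the frame grid.

What the round trip does and does not show: extraction recovers ≥95% of
**daughter** landmarks within one frame at default noise. Mother cells
have G1 near the floor (~3–9 min), so the bud neck is low for fewer than
the two frames the sustained-drop rule demands and many mother births are
(correctly) left censored; this mirrors the analysis choice of reporting
daughters, where size control acts. Synthetic traces contain no
segmentation or tracking errors, no focus drift and no phototoxicity, so
the round trip validates the landmark logic, not image analysis.

## Growth-mode diagnostic

Both a linear (`V` on `t`) and an exponential (`log V` on `t`) OLS model
are fit per cell, by default over the G1 segment where size control acts.
The exponential fit uses log-linear OLS rather than nonlinear least
squares: it matches the multiplicative noise model and is deterministic.
Under exponential growth with size-independent `α`, the *linear* rate is
proportional to birth size (`dV/dt = αV`) while the exponential rate is
uncorrelated with it; under linear growth the pattern reverses. The
diagnostic reports both Pearson correlations with P-values and refuses
degenerate (zero-variance) inputs.

## The screening statistic

- Binning is on **log birth volume** (the scale on which all G1 responses
  are analyzed); the budded-phase analysis bins on linear budding volume
  to match its min-per-volume-unit slope units.
- "Central 80%" is read as the 10th–90th percentile interval; the bins are
  the 10 equal subdivisions of the two strains' interval overlap, and a
  strain with no overlap is reported unclassifiable.
- Wilcoxon rank-sum P-values are exact (SciPy's enumeration) when both
  bins hold ≤25 cells with no ties, otherwise the normal approximation
  with tie and continuity corrections; fully tied bins give P = 1.
- Bins with fewer than 5 cells from either strain are dropped and the
  Fisher degrees of freedom adjust (`df = 2 × contributing bins`).
- The mean offset is the unweighted average of per-bin median differences.
- No multiple-testing correction is applied across strains; the
  false-positive control is the expected count `α × strains × responses`,
  which the report computes.
- The doubling time used for the slow-growth flag solves the Euler–Lotka
  relation `e^{−rτ_m} + e^{−rτ_d} = 1` on the median mother and daughter
  cycle lengths (`T_double = ln2/r`); with exponential growth and
  homeostasis this equals the volume-growth doubling time. When cell
  roles are unknown (e.g. trace-extracted records), the median cycle
  length is used as a fallback.
- The budded-phase analysis subsamples 300 cells per strain without
  replacement (seeded, hence reproducible) so each strain contributes
  equally to the pooled fit.

Calibration shown by the acceptance suite: on independent null pairs the
classification rejects at no more than twice the nominal α per response
(the Fisher combination is exact when bins are independent), and injected
G1/ΔV offsets are recovered as the mean offset within ±1 min / ±0.02 at
500 cells per strain.

## Flow-cytometry pre-screen

Gating is fixed-order and fully reported: stain-area window
`[5000, 2¹⁸−5000]` → width trim at the 1st/99th percentiles → singlet gate
(within 2.5 SD of the median width); wells retaining <5,000 events are
flagged discarded. Histograms use 100 bins smoothed with a cubic
smoothing spline whose parameter is chosen by generalized cross-validation
(deterministic for a given histogram). The informative range follows the
gradient rule (lowest bin with ≥0.2% of events and gradient >0.3%; highest
bin with gradient <−0.2%, both in percent-of-events units, gradient = first
difference of bin percentages), then extends over any remaining bins still
holding ≥0.2% of events — the upper limit exists to exclude the empty
super-G2 tail, and without the extension a histogram lacking a G2 peak
(an S plateau ending in a shallow fall) would have its populated S region
truncated.

The Dean–Jett deconvolution fits `f_G1·N(μ₁,σ₁) + f_G2·N(μ₂,σ₂) + f_S·S`
with `S` a uniform on `(μ₁, μ₂)` convolved with a Gaussian of width
`(σ₁+σ₂)/2` (closed form via the normal CDF) — a zeroth-order S model,
identifiable at desk-scale event counts, rather than the original
quadratic (left as an extension hook). The G2/G1 mean ratio is constrained
to `[1.8, 2.2]`, fractions are non-negative and normalized, and the fit is
performed on the G1-peak-normalized abscissa so residuals are O(1) for
the optimizer. Initialization uses histogram peak detection; a single
mode is read as the G2 peak only if the G1 peak it implies falls inside
the fitted range. Manual verification of fits is replaced by automated
diagnostics (residual RMS, convergence failures raised as
re-measurement flags).

The size metric for candidate selection accepts any designated scalar
channel (forward-scatter width being the documented default) summarized
per well; plate normalization rescales every plate to common mean/SD
(within-plate z-scores unchanged), and candidates are called at
`|z| ≥ z_cut` (default 1, configurable — the screen's exact thresholds are
not published) concordantly in size and %G1: small + short G1 → negative
candidate; large + long G1 → positive candidate; discordant strains (the
slow-growth signature) are left uncalled.

## Competition fitness

Generations per day are `log2(dilution factor)`. The default estimator
regresses the log2 *odds* of the labeled reference on cumulative
generations — odds are exactly linear under constant selection, whereas
log2 frequency is only approximately linear away from 50/50 (that mode is
available as `mode="frequency"`). The reported `s` is the negative slope:
the per-generation selection coefficient of the unlabeled competitor, in
log2 units per generation; `scale="natural"` multiplies by ln 2 for the
natural-log convention. The noiseless generator/estimator round trip is
exact by construction; with observation noise the estimator is unbiased
within Monte-Carlo error.

## Problem sizes

Study-scale computations use: 5,000-daughter cohorts for slope benchmarks;
200 null strain pairs of 500 cells for type-I calibration; 30,000-event
wells over a 3×3 fraction grid for the deconvolution round trip; 8 strains
× 300 cells for the budded-phase pool; ≥20 generations with a 400-cell
population cap for homeostasis; 50 seeded assays for fitness recovery.

## Known limitations

- The simulator has no spatial or colony structure, no crowding, no
  mother-age effects beyond the volume bookkeeping, and a single global
  growth-rate regime per run.
- Whether mothers re-enter G1 under the same control law is not
  established; the simulator applies the same law to all cells, and the
  analyses report daughters separately.
- The division rule (fixed bud fraction φ) is the simplest asymmetric
  model; real asymmetry is partly geometric (growth directed into the bud).
- Landmark detection resolves events only to the frame grid and cannot
  score G1 phases shorter than two frames.
- Trace-extracted records lack lineage context (roles, generations), so
  role-dependent statistics fall back to pooled estimates.
- FCS binary ingestion is not implemented; event tables are delimited
  text behind the same schema.
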