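# Methods notes

## Scope and model

The package estimates size-structured fish abundance trends from
split-beam echosounder surveys. Fish that can be resolved as individual
echoes are counted per survey and per log₂ length class; the decline of
ln counts over a season is read as an instantaneous loss rate
(catch-curve logic applied to repeated whole-lake counts rather than age
compositions). The statistical unit is the *fish track* — one or more
sequential single-echo detections attributed to one fish.

Assumptions inherited from that design:

* fish are individually resolvable (checked via Sawada's N_v, kept
  below 0.01);
* the detection probability of a given size class is constant across the
  surveys being compared, so biases (dead zones, threshold losses)
  cancel out of the slope;
* Love's TS–length relation is used as a *relative* size scale for a
  mixed community, not as a species-specific calibration;
* no recruitment or immigration within the season, so the slope is a
  loss rate.

## The synthetic survey generator

Real split-beam recordings of this kind are proprietary, so the
simulator is a first-class component, not a fixture. It emulates:

* a day-0 roster of fish with log-uniform lengths within each class, TS
  from the Love relation plus N(0, 1 dB) individual scatter, uniform
  positions over a square basin below a 2 m surface layer;
* per-fish nested exponential survival, so class-k counts on day t have
  expectation N0_k·exp(rate_k·t) and binomial spread, and a fish dead on
  one day stays dead on later days;
* parallel transects spaced `transect_spacing_m` apart, offset per
  survey, sailed at 10 km/h with 6 pings/s;
* ping-level echoes: a quadratic-in-dB (Gaussian-amplitude) pulse
  envelope whose −6 dB width equals the nominal pulse length cτ/2,
  two-way beam-pattern loss from the quadratic split-beam model, linear
  intensity superposition of overlapping echoes, N(0, 2 dB) noise about a
  −75 dB floor, angle samples equal to the dominant fish's true angles
  plus N(0, 0.15°), and a painted bottom echo (−10 dB peak with an
  8 dB/m tail);
* a target-level fast path that emits the detections an ideal detector
  would accept (one per insonified fish whose compensation is within the
  cap and whose noisy TS clears the threshold), bypassing ping synthesis
  for statistical experiments.

It does **not** emulate: waveform/phase structure, multiple scattering,
vessel avoidance, fish movement within a survey (survey speed ≫ fish
speed at these ranges; most real tracks are single-ping), zooplankton
scattering layers, TS directivity of individual fish, or range-dependent
noise. Passing tests therefore demonstrate the *pipeline's* correctness
and statistical calibration under a faithful but idealized instrument
model — not robustness to every artefact of field data.

### Default conditions

Instrument defaults are typical 200 kHz freshwater values: pulse 0.4 ms,
sound speed 1490 m/s, sample interval 0.018 m, half-power beamwidth 6.5°
(read as the full two-sided angle; the alternative half-angle reading is
configurable via `half_power_beamwidth_deg`), transducer draft 0.45 m,
noise floor −75 dB.

The demo plot (`demo_config`) is a deliberately scaled-down survey:
1 km², 12.5 m transect spacing, 3.1 m per-survey offset, initial counts
{32400, 10800, 3600, 1200, 400} (a factor-3 spectrum), loss rates
{−0.067, −0.055, −0.029, −0.050, −0.036} day⁻¹, surveys on days
{0, 7, 8, 20, 23, 32}. The scaling keeps per-survey detected counts in
the thousands-to-tens range across classes — the same order as
full-reservoir field counts — while a single season simulates in ~2 s,
and puts the volumetric density near 0.005 fish/m³ so N_v stays ~0.002.
The full 84 km²/1850 m geometry remains the `SimConfig` default.

## Numerical and design choices

* **Beam model.** The industry's quadratic two-way model
  G2 = −6.0206[(θ_mi/δ)² + (θ_ma/δ)² − 0.18(θ_mi/δ)²(θ_ma/δ)²] with
  δ = half the half-power beamwidth. The instrument vendor's own
  compensation polynomial is unpublished; results using this model are
  labelled as such. Compensation is −G2, zero on axis, capped at 15 dB.
* **Detector.** Pulse width is measured at peak − 6 dB with linear-in-dB
  sub-sample interpolation (stabilizes normalized pulse length);
  plateau peaks keep the shallower sample (determinism); a pulse whose
  PLDL crossing runs into a masked sample or off the grid is rejected;
  overlapping accepted pulses are all rejected (multiple-target
  rejection rejects every party, not the weaker one). Angle SDs use the
  population convention (ddof=0), defined even for one-sample pulses.
* **Detection threshold.** −52.6 dB by default (the 4 cm fish); a −55 dB
  variant is a one-line config change.
* **Tracker.** Greedy nearest-in-range gated association (gap ≤ 2 pings,
  gate 0.4 m, one target per ping per track) replaces interactive α-β
  tracking; at survey speeds where most tracks are single-echo the two
  agree, and the test suite checks ≥95% partition agreement against a
  brute-force reference. The gate value is not derivable from published
  material; 0.4 m is chosen as ~1.3 pulse lengths and is configurable.
* **Size classes.** Half-open, lower-inclusive on both the length and TS
  scales (a clean partition with no double counting); the >64 cm class
  is capped at 128 cm and out-of-scheme tracks are excluded from counts.
  TS bounds are always recomputed from the length bounds via the
  relation — the published table's printed bounds differ from the
  equation by up to 0.04 dB (rounding), and the equation wins here.
* **Trend fits.** OLS through statsmodels; day is measured from each
  year's first survey so the intercept is the ln initial count.
  Zero-count surveys are dropped point-wise with a warning (no +1
  offsets, which would bias the slope); fewer than three usable points
  means no fit. A constant series returns slope 0 and R² 0 by
  convention (total sum of squares is zero). p-values are per-fit,
  unadjusted. Slope CIs use the t distribution with n−2 df.
* **Survival spans.** Summer survival uses the mean within-year
  first-to-last survey span (29.5 days from the published dates;
  inclusive day-counting conventions can be passed explicitly since the
  duration is an argument). The inter-annual gap is 336 days.
* **Inter-annual rates.** "Incremented" matching (class k in year 1 vs.
  class k+1 in year 2, largest class to itself) is the default, since
  a year's growth moves survivors roughly one log₂ class; same-class
  matching is available. Classes below 16 cm are skipped by default —
  their year-to-year dynamics are recruitment-driven.
* **Equivalent beam angle.** ψ ≈ 5.78·(θ_hp/2 in rad)² (circular
  aperture approximation), overridable where the instrument's true ψ is
  known. N_v densities come from detected targets per swept wedge
  volume L·tanθ_max·(R₂²−R₁²) per 2 m range stratum — a lower bound on
  true density, which is what a single-echo survey can measure.
* **Determinism.** One integer seed drives every stochastic draw;
  per-survey seeds are derived with `numpy.random.SeedSequence`. Same
  config + seed gives byte-identical pipeline outputs.

## Test design

Statistical tests are derandomized with fixed seeds and use first
principles tolerances (3.3–4σ bands from binomial/Poisson error), not
measured values. The end-to-end calibration check runs 50 replicate
seasons (alternating the two published-year rate sets) on the demo plot
and requires the OLS slope 95% CIs to cover the generating rates in at
least 90% of class-season fits. Detector and tracker are verified
against exhaustive scalar reference implementations on simulated noisy
pings; the regression path is verified against closed-form OLS to 1e−10.

## Known limitations

* The simulator's bottom is flat per survey unless a per-ping profile is
  supplied; there is no geometric dead-zone correction, so benthic fish
  are undercounted exactly as in field practice.
* Tracking degrades at densities well above the N_v < 0.01 regime; the
  greedy gate can merge co-located fish (a handful per ten thousand
  targets at demo density).
* Echo integration (Sv processing) is out of scope; N_v uses
  target-count densities only.
* The TS–length conversion is community-relative; absolute biomass or
  species composition is not attempted.
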