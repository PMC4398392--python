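# echosurvey

Size-based analysis of split-beam hydroacoustic fish surveys: from
ping-level echo data through single-target detection, fish tracking and
target-strength-to-length size classing, to per-size-class seasonal loss
(mortality) rates and survival estimates. Because raw split-beam
recordings of this kind are proprietary and rarely deposited, the package
includes a full forward simulator of a downward-looking 200 kHz
split-beam echosounder, so every stage of the pipeline is testable
against known ground truth.

It is aimed at fisheries acousticians and quantitative ecologists who
want a scriptable, reproducible alternative to GUI echogram packages for
the *counting* side of lake surveys: size spectra and catch-curve-style
decline rates of individually resolvable fish.

## The method

1. **Echogram editing.** A surface exclusion layer (default 2 m depth) and
   a near-bottom dead zone (default 0.55 m above a median-smoothed bottom
   pick) are masked out of each ping. Depth = range + transducer draft.
2. **Single-target detection.** Local echo maxima are accepted as single
   fish when they pass the standard split-beam criteria: compensated
   TS ≥ threshold (−52.6 dB, a ~4 cm fish), normalized pulse length in
   [0.7, 1.5] measured 6 dB below the peak, split-beam angle standard
   deviations ≤ 1.2° per axis, beam compensation ≤ 15 dB under the
   quadratic two-way beam model, and no overlapping pulses
   (multiple-target rejection). Sawada's
   N_v = (cτ/2)·ψ·R²·ρ is reported per range stratum; below 0.01 the
   single-echo counts are considered unbiased.
3. **Tracking.** Sequential targets within a 2-ping gap and a 0.4 m range
   gate are grouped into one fish; the track TS is the member maximum.
4. **Size classing.** Love's 200 kHz relation
   `L(cm) = 10^((TS + 64.09)/19.1)` converts TS to length; tracks fall
   into five log₂ classes (4–8, 8–16, 16–32, 32–64, 64–128 cm) whose TS
   bounds are recomputed from the length bounds.
5. **Trend analysis.** For each class and year, OLS of ln(count) on survey
   day gives the instantaneous loss rate Z (day⁻¹) as the slope and the
   ln initial count as the intercept; survival over t days is `exp(Z·t)`.
   Inter-annual rates compare a year's last survey to the next year's
   first, optionally promoting each class to the next larger one to
   account for growth. The mean adjacent-class intercept difference gives
   the abundance ratio per halving of length (~3 in boreal reservoirs).
6. **Survey diagnostics.** Degree of coverage L/√A, per-survey mean target
   depth with 95% CI, and the N_v profile.

## Worked example

Run the bundled demo — a 1 km² survey plot holding a factor-3 size
spectrum (32 400 fish of 4–8 cm down to 400 of 64–128 cm) declining at
per-class rates between −0.067 and −0.029 day⁻¹, surveyed six times over
32 days:

```sh
$ echosurvey run --seed 7 --outdir run_out
{"seed": 7, "stage_counts": {"targets_detected": 10472, "targets_in_tracks": 10472,
 "tracks": 10434, "tracks_classified": 10410}, "max_nv": 0.002003617321301865}
$ echosurvey report --summary run_out/summary.json
mean_loss_rate_large_per_day: -0.03745
summer_survival_large: 0.3016
abundance_ratio_per_halving: 2.88
max_nv: 0.002004
```

10 472 single targets become 10 434 tracks; the fitted mean loss rate of
the three classes ≥ 16 cm (−0.037 day⁻¹, vs. the generating mean
−0.038) implies ~30% survival over the 32-day season; adjacent size
classes differ by a factor ≈ 2.9 in initial abundance; and the maximum
N_v of 0.002 confirms densities are low enough for unbiased single-echo
counting. `run_out/` also holds the per-stage CSVs (targets, tracks,
per-survey class counts, per-class trend fits) and `summary.json`.

Individual stages are available as subcommands (`simulate`,
`detect-bottom`, `detect`, `track`, `classify`, `trends`, `metrics`) and
as plain library functions.

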