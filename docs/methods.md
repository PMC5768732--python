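# Methods

## The estimator and its assumptions

Echo integration treats the water column as a collection of independent,
single-target point scatterers. Per EDSU (one whole transect), the depth- and
ping-averaged area backscattering coefficient `s_a = ⟨Σ s_v Δz⟩` (m²/m²) is
divided by the in situ mean backscattering cross-section
`σ̄_bs = ⟨10^(TS/10)⟩` over that EDSU's accepted SEDs, giving areal density
`ρ_A = s_a/σ̄_bs × 10⁴` fish/ha. This is valid when

* echoes are resolvable as single targets — enforced by the SED acceptance
  rules and monitored by the multiple-echo bias index
  `Nv = (cτ/2)·ψ·R²·ρ_v < 0.1`;
* the backscatter is linear (no shadowing or multiple scattering), which holds
  in the density regime where Nv passes;
* the SEDs are a representative sample of the insonified population, so the
  same σ̄_bs describes the fish contributing to `s_a`.

Density is derived from the depth-integrated `s_a` rather than from a
volumetric density times a water-column height, so heterogeneity of depth
between transects cancels. TS convention is `TS = 10·log10(σ_bs)` with σ_bs
in m² and no 4π factor, consistent with the empirical constants of the
TS–length regression.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| echo length window | 0.8–1.2 | ratio to transmitted pulse | SED pulse-shape acceptance |
| max angle SD | 0.8 | degrees | SED beam-stability acceptance |
| multi-peak dip | 1.5 | dB | reject overlapping fish (dip ≥ 1.5 rejected) |
| TS threshold | −60 | dB re 1 m² | separates fish from plankton/noise |
| s_v threshold | −66 | dB re 1 m³⁻¹ | sample-level noise floor, applied before integration |
| surface / bottom layer | 1 / 1 (surface extendable to 5) | m | exclusion layers |
| processing depth limit | 100 | m | SNR cut |
| TVG | 40 log R (TS), 20 log R (s_v) | dB | spreading-loss compensation; absorption term defaults to 0 |
| beam full angle | 6.8 | degrees | footprint geometry |
| equivalent beam angle ψ | 0.0058 | sr | Nv index; nominal for a ~7° circular transducer, configurable |
| sound speed c, pulse τ | 1500, 4×10⁻⁴ | m/s, s | Nv index |
| TS–length | slope 19.1, constant 0.9·log₁₀f + 62.0 | dB, f in kHz | 64.07 at 200 kHz |
| length–weight | a = 0.0137, b = 3 | g, cm | generalist multi-species model |
| TS histogram | [−60, −20) dB, 1 dB bins, half-open | dB | biomass pipeline input |
| coverage threshold | Λ = D/√A ≥ 6 | — | survey-design adequacy |

The echo-length bounds are implemented as a dimensionless received/transmitted
pulse-length ratio, the convention of split-beam SED acceptance.

## The biomass pipeline

Per transect: (1) histogram the accepted SED TS values; (2) convert each dB
bin's two edges to length and evaluate the weight at the arithmetic midpoint
of the length bin (a `db_midpoint` alternative — weight at the length of the
dB midpoint — is available for sensitivity analysis and differs by < 1%);
(3) apportion the transect's areal density across bins by the TS-bin
proportions; (4) sum fish/ha × weight over bins, grams → t/ha; (5) summarise
per site as arithmetic mean ± SEM (sample SD / √n) over transects. A 5 cm
length-class table is produced for reporting; biomass itself always uses the
full-resolution dB bins. Mean fish size per site pools per-SED lengths across
the site's transects (a per-transect-mean alternative is a one-line change in
the report stage).

## The synthetic generator

`synthetic.simulate_transect` places fish by a spatial Poisson process at the
scenario's areal intensity over the insonified footprint, defined as transect
length × beam diameter at mid-water-column depth (the simplest defensible
footprint model; recorded in the truth record). Each fish draws a length from
a truncated lognormal (right-skewed size structure, truncated to [1, 200] cm
so lengths map inside the TS analysis window), a TS from the regression plus
Gaussian dB noise (default 3 dB — a plausible in situ spread from aspect,
behaviour and species), and echo-shape descriptors inside the default
acceptance windows. Its cross-section σ_bs = 10^(TS/10) is deposited into the
s_v bin at its depth, divided by the bin's insonified volume, so the energy
the integrator sees and the SEDs it averages are the same echoes — which is
also why, at zero TS noise, echo integration recovers the realized density
exactly (σ_bs cancels). Seeding is hierarchical: a master seed plus a stable
hash of the transect id gives per-transect streams, so any transect can be
regenerated in isolation.

An optional school event adds a dense contiguous patch (default 25 m × 9 m at
10× density), emulating the kind of stochastic aggregation — e.g. a large
jack school — that inflates a site mean and is handled by explicit
transect-id exclusion in the comparison plan, never automatically.

The four-site demo (`default_study_scenarios`) encodes a sandy control with
many small fish (130 fish/ha, mean 6 cm, 60–100 m), a rocky control with
fewer larger fish (99 fish/ha, 9.5 cm, 35–85 m), mixed-habitat park transects
(447 fish/ha, 11.4 cm, 50–95 m) and shallow reef transects (5388 fish/ha,
14.8 cm, 8–18 m). Transect counts 18/17/18/19 are used: a 72-transect survey
of which 53 are non-reef, near-balanced across sites.

What the generator does **not** emulate: dead-zone fish (fish are placed
clear of the exclusion margins, so truth describes the detectable population
— real surveys carry a negative near-bottom bias the method cannot see);
species identity; tilt/swimbladder TS structure beyond Gaussian dB noise;
vessel motion, tides or currents; waveform-level acoustics. Passing recovery
tests therefore demonstrate the estimator's internal consistency and
calibration, not robustness to these field effects.

## Statistical battery

Welch's ANOVA is computed closed-form (weights n_i/s_i², Satterthwaite-style
denominator df) and cross-checked in the test suite against an independent
implementation; Tukey HSD, Kruskal–Wallis, t, Mann–Whitney and KS delegate to
scipy; Dunn's post-hoc is computed from pooled tie-corrected ranks
(`Z = ΔR̄/√(S²(1/n_i+1/n_j))`, S² = [N(N+1)/12][1 − ΣT/(N³−N)]), unadjusted by
default with Bonferroni selectable. Welch + Tukey is an unusual pairing but
is implemented literally as the survey's stated battery. `auto` routing
gates on Shapiro–Wilk and Levene at α = 0.05, retries after log10, then falls
back to Kruskal–Wallis + Dunn; the route and gate p-values are always
recorded in the report.

Calibration: the empirical type-I study draws all groups from one normal
distribution at the sample sizes each test actually operates on —
transect-scale groups (3 × 12, 2 × 15) for the metric tests, per-fish-scale
samples (2 × 300) for the KS size-distribution test, whose discrete null is
badly conservative at transect-scale n. Tukey HSD is calibrated on its
familywise rate (any pair rejected), the quantity it is designed to control;
per-pair rates for an HSD are ~α/3 at k = 3 by construction.

## Cross-method comparison

UVC belt transects (default 50 m × 5 m) give density as counts/area and
biomass via the length–weight model (species a/b when provided, generalist
otherwise). The comparison tests per-transect density and biomass with
Mann–Whitney and the pooled size-class distributions with KS, after
reassigning acoustic per-SED lengths to the UVC 5 cm classes. The mechanism
demo adds a cryptic 2–5 cm stratum (2× the visible density) to the diver
observations only: divers count small fish sheltering in the reef matrix that
contribute almost no biomass and fall at or below the acoustic TS threshold.
The demo runs at zero TS noise to isolate this size-selectivity mechanism:
with 3 dB single-echo noise the cubic weight model inflates acoustic biomass
by ≈ e^{4.5(3·ln10/19.1)²} − 1 ≈ 80% (Jensen's inequality), a separate bias
that real surveys suppress by averaging several echoes per fish track.

## Numerical choices and degenerate inputs

* TS histogram bins are half-open [lo, hi); a SED at exactly −20 dB is
  excluded. Binning uses floor arithmetic, not `np.histogram`'s closed last
  bin.
* An EDSU with no SEDs raises/flags rather than reporting density zero; in
  the pipeline it falls back to the pooled site σ̄_bs, loudly logged and
  flagged `sigma_bs_pooled`.
* Rejection reasons are assigned in the fixed order echo_length → angle_sd →
  dip → ts_threshold (first failing rule), making reject tables deterministic.
* log10 transforms refuse non-positive values and list the offending indices;
  no silent +1 offsets.
* A ping whose surface layer reaches its bottom layer is fully masked with a
  warning.
* Survey CSVs are written with 17-significant-digit floats and read with
  pandas' round-trip parser, so write→read is field-for-field exact.
* Recovery experiments use 500 m transects over 20–30 m water (~0.15 ha
  footprint, ~75 fish at 500 fish/ha), 100 seeded replicates; the type-I
  study uses 2000 null simulations. These sizes give stable medians and
  rates while keeping the full validation run at a few minutes on one CPU.

## Known limitations

No dead-zone correction (acknowledged negative bias near the seabed); no
species apportioning of backscatter; no geostatistical variance for density
estimates; the Nv index uses a nominal ψ rather than a calibrated one; the
school-event model inflates density uniformly in a box rather than modelling
attenuation inside dense aggregations (another reason school transects are
excluded by annotation rather than corrected).
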