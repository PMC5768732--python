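# acoustica

Split-beam hydroacoustic fish-survey analysis: single-echo-detection (SED)
filtering, echo integration to areal fish density and the area backscattering
coefficient sA, target-strength→length and length→weight conversion, areal
biomass in t/ha, survey-coverage planning, between-site statistics, and the
comparison of acoustic surveys against diver underwater visual census (UVC)
belt transects. A seeded synthetic split-beam survey generator provides ground
truth, so every stage of the pipeline can be verified without raw echosounder
files.

The intended users are quantitative marine ecologists assessing fish
populations — for example inside versus outside a marine protected area —
with a downward-looking split-beam echosounder.

## The method

A split-beam sounder proposes candidate single fish echoes; these are accepted
as SEDs only if the received pulse resembles the transmitted one (relative
echo length in [0.8, 1.2]), the target is stable in the beam (angle SD ≤
0.8°), the echo envelope has no secondary peak with a ≥ 1.5 dB dip, and the
compensated target strength TS ≥ −60 dB. Volume backscattering samples below
−66 dB are zeroed, and exclusion layers remove 1 m at the surface, 1 m above
the seabed and everything past a 100 m processing limit. Range compensation is
the standard time-varied gain, 40 log R for point targets and 20 log R for
volume scattering.

Echo integration then divides energy per unit area by energy per fish. Per
EDSU (elementary sampling distance unit; one whole transect):

    s_a  = ⟨ Σ s_v Δz ⟩_pings            (m²/m²),   sA = s_a · 10⁴  (m²/ha)
    σ̄_bs = ⟨ 10^(TS/10) ⟩_SEDs           (m², in situ)
    ρ_A  = s_a / σ̄_bs · 10⁴              (fish/ha)

with the multiple-echo bias index Nv = (cτ/2)·ψ·R²·ρ_v required to be < 0.1.

TS converts to total length by a multi-species regression,
TS = 19.1 log₁₀L − (0.9 log₁₀f + 62.0), i.e. TS = 19.1 log₁₀L − 64.07 at
200 kHz, and length to weight by the generalist W = 0.0137·L³ (g, cm). Areal
biomass distributes ρ_A over the 1 dB TS histogram ([−60, −20) dB), converts
bin edges to lengths, takes the weight at each bin's length midpoint, and sums
to t/ha. Survey effort is planned with the degree of coverage Λ = D/√A
(adequate when Λ ≥ 6).

Site comparisons use Welch's one-way ANOVA with Tukey HSD post-hocs on raw or
log₁₀ metrics, falling back to Kruskal–Wallis with Dunn's post-hocs when
transformation does not rescue normality; two-sample contrasts use Welch's t,
Mann–Whitney or a two-sample Kolmogorov–Smirnov test on size classes.

## Worked example

```python
import numpy as np
from acoustica import (SiteScenario, simulate_transect, threshold_sv,
                       apply_exclusion_layers, filter_seds, integrate_transects,
                       ts_histogram, biomass_per_hectare)

scenario = SiteScenario("REEF", "basalt_reef", true_areal_density=500.0,
                        length_meanlog=np.log(12.0), length_sdlog=0.3,
                        depth_range_m=(20.0, 30.0))
pings, seds, truth = simulate_transect(scenario, 500.0,
                                       rng=np.random.default_rng(7),
                                       ts_noise_sd_dB=0.0)
pings = threshold_sv(pings)
pings, seds = apply_exclusion_layers(pings, seds)
accepted, _ = filter_seds(seds)
res = integrate_transects(pings, accepted)[0]
print(truth.density_fish_ha, res.density_fish_ha, res.n_sed)
bm, _ = biomass_per_hectare(ts_histogram(res.ts_values_dB), res.density_fish_ha)
print(truth.biomass_t_ha, bm)
```

prints

```
615.5447840450586 615.5447840450586 48
0.016849276235095727 0.017459827298486753
```

With zero TS noise the recovered density equals the realized truth exactly —
the per-fish cross-section cancels between the integrated s_a and the SED
mean — while the biomass estimate differs from the exact per-fish weight sum
only by the 1 dB histogram discretization (here ≈ 3.6%, shrinking as bins
refine).

The full pipeline (`acoustica run-full --seed 1 --out run/`, or
`acoustica.run_full(RunConfig(...))`) simulates a four-site demo survey —
sandy control, rocky control, mixed-habitat park transects and shallow
reef-specific transects — then filters, integrates, estimates biomass,
summarises per site and runs the between-site statistics, writing
`transects.csv`, `biomass.csv`, `site_summary.csv`, `report.json` and
`run.log`.

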