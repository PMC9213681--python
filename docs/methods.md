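# Methods

## Scope and data flow

The package characterizes fruit-growing sites by four hourly-temperature
response models (Utah chill units, Dynamic-model chill portions, Richardson
and Anderson growing degree hours), weekly frost / abnormal-heat
probabilities, and their evolution under warming scenarios. Two input
paths converge on the same hourly representation:

1. **Observed path** — hourly station records (CSV) → completeness
   screening → seasonal accumulation and event detection.
2. **Projection path** — daily Tmin/Tmax per grid point per GCM per
   scenario → hourly reconstruction → the same metric stack, computed per
   GCM and then ensemble-averaged.

## Model kernels

**Utah chill units.** Band weights 0 / +0.5 / +1.0 / +0.5 / 0 / −0.5 / −1.0
with band edges 1.4, 2.4, 9.1, 12.4, 15.9, 18.0 °C. Edge membership is
closed on the right: a temperature exactly on an edge takes the weight of
the band it closes (1.4 °C → 0; 9.1 °C → +1.0; 18.0 °C → −0.5).

**Dynamic model.** The canonical parameterization is transcribed as a
versioned constants table (E₀ = 4153.5, E₁ = 12888.8, A₀ = 139500,
A₁ = 2.567·10¹⁸, slope 1.6, transition temperature 277 K). Kelvin
conversion is K = °C + 273.15 exactly. Portion banking is deterministic —
when the precursor reaches 1, the fraction ξ·x is banked and the remainder
carries over — matching the convention of the standard horticultural
toolkits; the original probabilistic whole-portion variant is available as
`banking="stochastic"`. The hot-path accumulation is a numba-compiled
loop; a pure-Python single-step API (`dynamic_step`) exposes the same
recursion for inspection and is cross-checked against the loop in tests.

**Growing degree hours.** Richardson: base 4.5 °C, cap 25 °C. Anderson:
ASYMCUR cosine response with cardinals 4/25/36 °C and stress factor fixed
at 1 (no stress data is modelled).

## Accumulation windows and seasons

Chill: 1 November – 28 February (120 days, 2880 h); 29 February is always
excluded. Heat: 1 January – 8 April (98–99 days; 29 February included when
present). A season is labeled by the calendar year of its 1 November
start. Missing hours are never imputed: they contribute nothing to the
sums and reduce `hours_used`. A season enters station climatologies only
when both windows have ≥ 90 % of their hours; a station is retained only
with ≥ 5 such complete seasons (the completeness regulation behind the
real network's station selection is not public; this 90 % / 5-season rule
is the package's stated approximation and both thresholds are
configurable).

## Hourly reconstruction from daily extremes

Between sunrise and sunset the temperature follows
T(h) = Tmin + (Tmax − Tmin)·sin(π·(h − sunrise)/(daylength + 4)), placing
the maximum in mid-afternoon; after sunset it decays as
T(h) = T_sunset − b·ln(h − sunset + 1) with b chosen so the curve reaches
the next day's Tmin at the following sunrise (the "+1" keeps the curve
continuous at sunset). Pre-dawn hours continue the previous night's decay;
the first day of a series, having no predecessor, assumes a previous night
identical to its own. Sunrise/sunset come from the standard solar
declination / hour-angle formulas (Cooper declination, spherical
geometry); latitudes with polar day/night (|lat| ≥ 60°) are rejected.
Samples sit on the hour in local solar time; no daylight-saving shifts.

Two deliberate numerical choices: (i) when the following day's Tmin
exceeds the sunset temperature the "decay" rises, and is capped at the
owning day's Tmax so a reconstructed day never exceeds its own maximum —
the cap is shared by the pre-dawn continuation, keeping the series exactly
continuous at midnight; (ii) daily min/max of a reconstructed series
recover the inputs to ≈ 0.3 °C for meteorologically persistent day-to-day
sequences, but under abrupt synthetic day-to-day jumps the night curve can
undershoot, which is why the round-trip contract is stated (and tested)
per day and on smooth sequences.

No correction is applied for the systematic difference between real hourly
records and idealized curves; comparisons between the observed path and
the projection path inherit that bias.

## Events and weekly probabilities

Strict inequalities throughout: frost is < −1.0 °C, abnormal heat
> 25.0 °C, each for ≥ 3 consecutive hours. Runs are maximal (a 7-hour
run is one event), are split by any missing hour, and are attributed to
the week of their first hour. Weeks are fixed 7-day blocks of the calendar
year starting 1 January; the 1–2 day fragment after week 52 merges into
week 52. December weeks (≥ 49) attach to the following season so the
abnormal-heat analysis window (weeks 49 → 8) is contiguous within a
season. The weekly probability is #(years with ≥ 1 event in that week) /
n_years; repeated events within one station-week-year count once. Risk
maps retain only probabilities ≥ 10 % (configurable cutoff, inclusive).

## Future scenarios and ensembles

Four scenarios: horizons 2035 and 2055 × RCP4.5 and RCP8.5. Stations are
matched to projection grid points by great-circle distance (spherical
earth, R = 6371 km). Within each GCM, seasonal metrics are averaged over
complete season-years first (per-GCM climatology), then across GCMs with
equal weights (unweighted mean; median available as an option). Event
probabilities are likewise computed per GCM and then ensemble-averaged.
A configured GCM with no series at a matched grid point is a hard error.
Chill loss is current minus future ensemble portions; heat gain is future
ensemble minus current Anderson GDH.

## Spatial analysis

Chill classes: low < 60 portions, medium 60–80 (closed interval, matching
the usual "between 60 and 80" phrasing), high > 80, assigned from the
*current*-scenario station means. IDW surfaces use all stations with
weight d^(−2) (the exponent is configurable; 2 is the common default), on
a regular 0.05° (~5 km) grid, masked beyond 50 km from the nearest
station; a cell coincident with a station takes that station's value
exactly, and coincident stations with conflicting values are averaged with
a warning. Box summaries per class use Tukey whiskers (1.5 × IQR) with
outliers listed by station id.

## Synthetic weather generator

The generator exists because neither the original hourly station records
nor the downscaled daily projections are redistributable; it reproduces
the statistical features the analysis depends on, not any particular
geography.

Per station: T(t) = annual sinusoid (trough 15 January) + diurnal sinusoid
(peak 15:00 solar) + AR(1) Gaussian noise (lag-1 autocorrelation 0.85,
stationary sd ≈ 2 °C — persistent multi-day spells) + injected episodes.
Three archetypes ship as defaults, tuned once so their station means land
inside the three chill classes with margin and respond monotonically to
uniform warming:

| archetype     | annual mean | seasonal amp | diurnal amp | ≈ portions | class |
|---------------|------------:|-------------:|------------:|-----------:|-------|
| warm_coastal  | 17.0 °C     | 6.0 °C       | 3.5 °C      | ~50        | low   |
| intermediate  | 15.5 °C     | 6.5 °C       | 5.0 °C      | ~70        | med   |
| cold_interior | 12.0 °C     | 7.0 °C       | 5.0 °C      | ~87        | high  |

(Amplitudes are half peak-to-trough.) Each station draws a small
annual-mean jitter (±0.5 °C) so the gradient is a scatter, not three
points. Station coordinates are uniform in an Iberian-scale bounding box.
Calendar-year coverage is sampled on 6–21 years, top-heavy, so complete
seasons per station span 5–20 with median 20. Frost / abnormal-heat
episodes are injected per winter with Poisson counts at the archetype's
propensity: a random 4–8 h block is pushed past the event threshold
(frost: to a level in [−5, −1.5] °C; heat: [25.5, 30] °C) with the
adjacent hours nudged back across the threshold, so injected episodes are
distinct, detectable maximal runs. Everything derives from the spec seed
through per-station substreams; regeneration is bitwise identical.

Pseudo-GCM projections add a fixed per-GCM offset (scenario mean + N(0,
0.3 °C), drawn once per GCM) to the station's hourly record before daily
Tmin/Tmax extraction, at a grid point displaced < 4 km from the station
(emulating nearest-gridpoint matching distances). Default scenario mean
offsets are 1.0 / 1.4 / 1.8 / 2.5 °C for 2035_RCP4.5 / 2035_RCP8.5 /
2055_RCP4.5 / 2055_RCP8.5 — mid-century Iberian warming magnitudes with
the required ordering.

**What the generator does not emulate:** elevation and coastal-distance
effects, spatially correlated weather between stations, humidity/radiation
covariates, trends within the historical period, non-Gaussian temperature
tails, and GCM spread structure beyond a single additive offset. Passing
tests therefore demonstrate the correctness and internal consistency of
the metric stack and the qualitative response to warming — not a
validation against any real network.

## Problem sizes and determinism

Tests and the acceptance script run on a 60-station network (21-year
range, 11-GCM ensembles) for the statistical properties and a 12-station
network for scenario-ladder and end-to-end checks; these sizes give stable
statistics (class recovery, inter-model R², delta correlations) at a few
minutes of single-CPU compute. All randomness flows from explicit integer
seeds (numpy `default_rng` / `SeedSequence`); pipeline outputs are written
with fixed float formatting so identical configurations reproduce
byte-identical files.

## Known limitations

- The hourly idealization bias (smooth curves vs noisy reality) is left
  uncorrected and is visible when comparing observed-path and
  projection-path metrics at zero offset.
- Weekly probability estimates on few complete years are coarse
  (resolution 1/n_years).
- IDW with all-station neighborhoods smooths sharp gradients; no kriging,
  elevation covariates or cartography are provided beyond CSV/GeoJSON
  exports.
- Event thresholds are network-wide; no cultivar- or phenology-stage-
  specific damage thresholds are modelled.
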