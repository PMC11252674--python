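# Methods

This note documents the models, estimators, defaults, and numerical choices
behind the package, and what the synthetic-data tests do and do not show.

## Study design emulated by the generator

The synthetic world mirrors a staging-site capture study: nine study years
in three blocks (1978–80, 2004–06, 2008–10), captures of juvenile (JUV) and
adult (ADU) birds spread uniformly over 1 Aug–4 Oct, body mass recorded to
0.1 g and exposed culmen to 0.1 mm, and culmen lengths truncated above
31.5 mm (the analysis filter removes anything at or below that cutoff, which
in the real system excludes small-bodied males of a second subspecies).
Adults are deliberately sparse in the middle block (8 birds/year vs 270), so
that exactly six years survive the ">25 captures per age class" retention
rule of the balanced-baseline stage while juvenile condition data span all
nine years — the asymmetry the real study design has.

Mass is built multiplicatively: `mass = SLBM × L/100`, where SLBM follows
the culmen-by-age linear structure (defaults: intercept 10.5 g, culmen slope
1.00 g/mm, juvenile offset +4.0 g, juvenile culmen slope −0.10 g/mm, year
sd 0.3 g, residual sd 1.5 g) and `L` is the shifted fuel level. Before
22 Aug, `L = 100` exactly: pre-fuelling birds carry no modelled fuel, so
August mass scatter comes only from the SLBM residual, which is precisely
the assumption the structural-size regression makes. From 22 Aug,

```
log E[L] = α_age + β_age · t + u_year
u_year   = (γ/100) · (SST_w − SST_opt)² + ε_year
L        ~ Gamma(shape, mean = E[L])
```

with `t` days since 22 Aug, `SST_w` the mean SST over the true climate
window (11–24 June of the previous year), γ ≤ 0 the concave climate effect,
and ε_year ~ N(0, σ_y). The slope and intercept defaults are the published
point estimates for this system (β 0.0147/0.0220 log[%lbm]/day for JUV/ADU;
α = log(100 − 1.18) and log(100 − 1.00)). Because the year effect enters on
the log scale, its induced effect on condition (%lbm) has curvature
≈ 1.15 γ at typical fuel levels.

Weather is daily: SST = seasonal sinusoid (annual mean 5 °C, amplitude 6 °C,
peak in early September) + per-year anomaly (sd 0.3 °C) + AR(1) noise
(φ = 0.75, innovation sd 1.6 °C). Between-year precipitation levels are
coupled to the same year's 11–24 June SST at correlation −0.87, giving the
scan a realistic correlated nuisance variable. Winds are a mean vector
(3.5, −1.5) m/s plus smooth sinusoidal spatial modes and cell noise; the
resulting corridor 80th-percentile assistance sits near 5.4 m/s.

**Effect-size defaults.** The quadratic climate effect (γ = −1.5 %lbm/°C²,
optimum 4.5 °C) and the year-level noise terms (σ_y = 0.004 on the log
scale, gamma shape 150, SLBM year sd 0.3 g) were fixed once, by a
prospective power analysis, so that the default world is a genuinely
*strong-signal* regime: with only nine year-level observations, reliable
recovery of a two-week window out of 136 candidates demands a climate signal
that dominates year-level noise severalfold. The corresponding cost is that
annual condition ranges and scenario declines are larger than a mild-signal
world would show; tests that pass here demonstrate that the estimators
recover a strong signal and screen out a null one, not that every weak
real-world signal would be detected.

What the generator does **not** emulate: spatially resolved SST, hourly
weather, tides and moult, capture-method effects, the 0.5 g historical
rounding of early field seasons, and any behavioural response of birds to
conditions (departure timing is fixed by assumption).

## Estimators

**Structural size.** The three candidate mixed models are fitted by ML with
statsmodels MixedLM and compared by AIC with k = fixed effects + 2 variance
components. When a fit degenerates (zero residual variance on noiseless
data, singular designs) the candidate falls back to OLS (k = p + 1) with the
residual variance floored at 1e-30, which keeps perfect fits finitely
comparable. Structural-mass predictions use fixed effects only: year-level
mass variation is deliberately left inside fuel loads so the climate stage
can explain it, and for the same reason condition subtracts the
population-level (year-intercept-free) baseline prediction.

**Gamma GLMM** (`stagefuel.glmm`). The marginal likelihood of the gamma
log-link random-intercept model is approximated by adaptive Gauss–Hermite
quadrature (20 nodes) around the per-group posterior mode, which is found by
a 1-D Newton iteration; the integrand reduces to
`exp(−k n_g u − k S_g e^{−u})` with `S_g = Σ y_i e^{−η_i}`, so each
likelihood evaluation is O(n). Optimisation is L-BFGS-B over (β, log shape,
σ_u) with σ_u bounded at 0; a single-group dataset is fitted with σ_u pinned
to 0 and reduces to plain gamma regression. Standard errors come from a
finite-difference Hessian. The fit is cross-checked against R glmmTMB in
the test suite. The response is the *shifted* level `L = F + 100`: a gamma
response cannot have the slightly negative mean fuel loads observed at the
start of fuelling, and the shift is the minimal reconciliation; all reported
quantities are back-shifted.

**Fast LMM** (`stagefuel.lmm`). The window scan refits a year
random-intercept LMM thousands of times, so the one-way model is implemented
directly: for a variance ratio λ the GLS normal equations collapse to
group-level sufficient statistics via Woodbury's identity, and the profile
ML log-likelihood is maximised over log λ by bounded scalar search, with the
λ = 0 (OLS) boundary checked explicitly and assigned one fewer parameter.
Agreement with statsmodels MixedLM is at optimizer tolerance.

**Window scan.** Candidate windows live on a weekly lattice anchored at
1 May spanning 112 days (17 boundaries, C(17,2) = 136 windows, durations
1–16 weeks); windows are absolute calendar intervals, optionally lagged one
whole year. AICc uses n = number of condition records, k as above;
quadratic models always include the linear term; ties break toward shorter,
then earlier, windows. A zero-variance covariate (degenerate weather) is
flagged and scored at the baseline likelihood with the extra-parameter
penalty. The randomization `P_C` permutes the year-to-weather assignment —
condition data untouched, so within-year structure is preserved — re-scans,
and fits a normal distribution to the 10 randomized best ΔAICc values
(an empirical proportion over 10 draws has resolution 0.1; the normal fit
interpolates, as the threshold 0.10 otherwise sits exactly at one draw).
The exact scheme used by the original sliding-window tooling is not
published; this one is documented, not asserted identical.

**Model averaging.** Within the winning variable's scan set, models with
Akaike weight > 0.05 are renormalised and their polynomial responses
averaged pointwise. The curve's argmax is found on a 2001-point grid over
the fitted covariate range. Scenario offsets are curve differences against
a reference SST; values more than 2 °C outside the fitted range set an
extrapolation flag rather than an error — warm scenarios beyond the
observed study years are exactly the case of interest.

**Route and winds.** Spherical Earth, radius 6371.0 km; haversine distance;
average bearing is the circular mean of initial and final bearings. The
default endpoints (61.25° N 165.63° W → 46.93° N 124.10° W) are
configuration constants chosen from a map, so the 3205 km / 112.5° checks
carry ±5% / ±10° tolerances; the computed values (3067 km, 119.3°) sit
within them. The corridor is all grid cells within 250 km of the
great-circle polyline sampled every 25 km; quantiles interpolate linearly
between order statistics. Untenable samples (crosswind ≥ airspeed) are
excluded from percentiles, not clamped.

**Flight simulation.** Single-fuel (fat-only) energetics: the flight-muscle
burn of full dual-fuel implementations is omitted, which shifts absolute
ranges but not orderings. Profile power is recomputed from the current
mass's minimum-power speed each step, so it stays V-independent while
decaying with mass. Forward Euler at dt = 60 s is validated against the
closed-form arctan solution of `dm/dt = −(a m² + b)/(η e_fat)` to 0.1% and
against step-halving to 0.05%. The published method sets the cruise
airspeed to still-air speed plus the 80th-percentile wind assistance
(16.1 + 5.4 = 21.5 m/s) and uses it for both power and distance — a
deliberate conflation of airspeed and ground speed that this package
replicates as stated; the wingspan default (0.4028 m, flattened span) is
tuned within the species' plausible range so that 21.5 m/s is 1.98× the
minimum power speed at the reference departure mass (empty 0.055 kg +
50 %lbm). Normal fuel draws are truncated at zero with a logged count.

## Defaults worth knowing

| parameter | default | units | why |
|---|---|---|---|
| culmen cutoff | 31.5 | mm | subspecies filter, strict `>` |
| fuelling period | 22 Aug – 22 Sep | — | four closed 8-day periods |
| year retention | > 25 | captures/age | strict inequality |
| window season | 1 May – 21 Aug | — | 17 weekly boundaries |
| randomizations | 10 | — | coarse by the method's own choice |
| P_C threshold | 0.10 | — | signal claim |
| collinearity cutoff | 0.7 | Pearson r | subset exclusion |
| averaging threshold | 0.05 | Akaike weight | retained window models |
| airspeeds | 16.1 / 5.4 / 21.5 | m/s | still air / assistance / assisted |
| corridor | 250 | km half-width | assistance percentile |
| min distance | 3205 | km | reach criterion |
| draws | 100 | per scenario | departure fuel loads |

## Known limitations

- With nine year-level observations the scan's effective sample for
  identifying year-constant covariates is nine, whatever the record count;
  AICc's n = records is a convention (records are what the models are fitted
  to), not a claim of year-level information.
- `P_C` from a 10-draw normal fit is a coarse control; its type-I behaviour
  is verified only in the loose sense (≤ 3/10 null seeds crossing 0.10).
- Absolute flight ranges depend on physiological constants that are
  configuration inputs here; only orderings and recovery properties are
  asserted, not published range magnitudes.
- The balanced subsample discards data (by design, for equal age
  representation); baseline slopes are slightly less precise than a
  weighted alternative would be.
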