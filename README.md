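# stagefuel

Quantitative-ecology pipeline linking coastal sea-surface temperature (SST)
to the migratory fuel loads and flight performance of staging shorebirds.
The motivating system is the Dunlin (*Calidris alpina pacifica*) population
that fattens on Yukon–Kuskokwim Delta mudflats each autumn before a >3000 km
non-stop flight across the Gulf of Alaska, but every stage is a general,
configurable operation. The package is organised as an analysis project:
all computation lives in `src/stagefuel/`, the numbered scripts under
`analysis/` are thin narrative drivers, and a seeded synthetic-data
generator with a known truth record makes the whole chain testable by
parameter recovery.

## The analysis chain

1. **Body condition** (`stagefuel.condition`). Structural lean body mass
   (SLBM) is predicted from culmen length with a linear mixed model fitted
   to pre-fuelling captures (1–21 Aug): candidates `mass ~ culmen`,
   `~ culmen + age`, `~ culmen × age`, each with a year random intercept,
   compared by AIC (ML). A bird's fuel load is
   `F = 100 (mass − m̂_SLBM) / m̂_SLBM` (% of SLBM, "%lbm"). Age-specific
   fuelling baselines are gamma GLMMs with a log link on the shifted level
   `L = F + 100`:

   `log E[L] = α + β_Date · t + u_year,  u_year ~ N(0, σ²),  L ~ Gamma(shape)`

   with `t` the day offset from 22 Aug, fitted by adaptive Gauss–Hermite
   maximum likelihood (`stagefuel.glmm`). Pre-migratory body condition is
   `C = F − (exp(α + β_Date t) − 100)`.
2. **Climate windows** (`stagefuel.windows`). All 136 weekly candidate
   windows in 1 May–21 Aug (C(17,2) boundary pairs), each entering a year
   random-intercept LMM for `C` as a linear or quadratic fixed effect,
   optionally lagged one year; ranked by AICc (n = records). False-positive
   control re-scans 10 datasets with permuted year-to-weather assignment and
   converts the observed best ΔAICc into a normal-tail probability `P_C`
   (signal claimed when `P_C < 0.10`). Influential variables are combined by
   all-subsets AICc (subsets with two linear terms correlated at |r| > 0.7
   are excluded), and the winning variable's window models with Akaike
   weight > 0.05 are model-averaged into an SST → condition effect curve.
3. **Route and winds** (`stagefuel.route`). Spherical great-circle distance
   and average bearing between the staging site and wintering grounds;
   drift-compensated wind assistance
   `w_par + sqrt(Va² − w_perp²) − Va` per grid cell; the 80th percentile of
   assistance over the ±250 km corridor in the pre-departure window.
4. **Flight range** (`stagefuel.flight`). Classic flight-mechanics power
   curve `P = P_ind + P_par + P_pro` with
   `P_ind = 2k(mg)²/(πB²ρV)`, `P_par = ρV³S_b C_Db/2` and profile power tied
   to the power-curve minimum; fat-only fuel burned at
   `dm/dt = −P_chem/e_fat`; forward-Euler time marching until the bird is
   down to structural mass. Departure scenarios draw 100 normal fuel loads
   per age class, shift them by the climate effect curve, and report
   medians, IQRs, and the proportion of draws whose range covers the
   3205 km minimum migration distance.

## Worked example

```sh
python analysis/02_body_condition.py
python analysis/03_climate_windows.py
python analysis/05_flight_ranges.py
```

prints, for the default seeded world (abridged):

```
JUV: beta_Date = 0.0142 log[%lbm]/day [0.0135, 0.0150], gamma shape 127, n = 714
ADU: beta_Date = 0.0225 log[%lbm]/day [0.0218, 0.0232], gamma shape 133, n = 714
avg_sst_prev_year: best window 12 Jun-25 Jun (quadratic), dAICc -34.4, P_C = 0.0000
avg_precip:        best window 29 May-11 Jun (quadratic), dAICc  -8.5, P_C = 0.3925
scenario SST(prev June) = 4.8 C   JUV: median 3,571 km, reaching 0.61
scenario SST(prev June) = 10.3 C  JUV: median 0 km,     reaching 0.01, decline 98%
```

Reading: adults accumulate fuel ~50% faster than juveniles (0.0225 vs
0.0142 log[%lbm]/day, both recovering the generator's true slopes); the scan
pins the climate signal to the true mid-June previous-year SST window with a
concave response and a randomization probability far below the 0.10
threshold, while the precipitation scan is correctly screened out; and
pushing the scenario SST from the near-optimal 4.8 °C to a warm 10.3 °C
drives juvenile departure fuel loads down far enough that almost no draws
cover the minimum migration distance, while adults degrade less.

## Command line

`stagefuel generate|condition|scan|route|fly|run` expose the same stages on
CSV inputs; `stagefuel run --out DIR` executes the full chain and writes
`report.json`, `manifest.json` (config hash + stage seeds), and the
condition/scan tables.

## Layout

```
src/stagefuel/    synthetic.py  condition.py  glmm.py  lmm.py  windows.py
                  route.py  flight.py  pipeline.py  cli.py
analysis/         01_simulate_data.py ... 05_flight_ranges.py
tests/            unit + property + acceptance suites
docs/methods.md   model and estimator details, defaults, limitations
```
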