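# Methods

## The accounting model and its assumptions

The package treats the living calcifier community as a steady-state
reservoir: the CaCO₃ standing stock S (mg m⁻²) of each taxon turns over
on its typical lifespan τ (days), so daily production is P = S/τ. This
assumes (i) every sampled individual is alive (reasonable for
foraminifera, pteropods and heteropods, which sink quickly after death,
and for coccolithophores when only intact coccospheres are counted);
(ii) the stock is in approximate steady state over the sampling window;
and (iii) growth rates do not vary with shell size or season for the
zooplankton taxa. None of these are testable from a single survey; they
are the price of converting a snapshot inventory into a rate.

Turnover is the dominant uncertainty and is known only as a range, so
it is propagated with a flat (uniform) prior — a deliberately
conservative choice that widens the production intervals rather than
narrowing them. Under τ ~ U(a, b) the production mean has the closed
form E[S/τ] = S·ln(b/a)/(b−a), which the Monte-Carlo stage is tested
against. Coccolithophore turnover is sampled on the cell division rate
(uniform on 0.1–1.5 d⁻¹) and inverted, giving τ ∈ [0.67, 10] d; the
range is also quoted in the literature as 1.5–10 d, and both endpoints
are configurable, but the rate-space prior is the default because the
underlying measurement is a division rate. Note this choice matters:
a rate-space flat prior concentrates turnover near 1/⟨rate⟩ ≈ 1.25 d
and so yields higher coccolithophore production (and a higher
coccolithophore share of total production) than a τ-space flat prior
on [1.5, 10] d would.

Draws are matched across taxa within a station (one τ draw per taxon
per iteration, shared iteration index) so that per-draw share vectors
are coherent and sum to 100% exactly.

## Parameters

| parameter | default | units | note |
|---|---|---|---|
| WW→DW | 0.28 | – | wet to dry weight |
| DW→POC | 0.25 | – | dry weight to organic carbon |
| PIC:POC (pteropods) | 0.27/0.73 | – | read as fractions of total carbon |
| PIC:POC (heteropods) | 0.365 | – | midpoint of the 0.28–0.45 range |
| CaCO₃/PIC | 8.33 | mg/mg | M(CaCO₃)/M(C); validated to 2 decimals |
| τ pteropods/heteropods | 5–16 | d | flat prior |
| τ foraminifera | 14–28 | d | 10–30 d variant by config |
| division rate, coccolithophores | 0.1–1.5 | d⁻¹ | τ = 1/rate |
| PIC:POC prior (basin stats) | 0.20–0.56 | – | fPIC = r/(1+r) |
| production layer | 250 | m | compilation integration depth |
| zooplankton seasonal bias | 1.2 @ 22.75°N, 2.0 @ 50.1°N | – | linear in latitude, clamped |
| Earth radius | 6371 | km | spherical areas |
| n_draws | 10 000 | – | per-station Monte Carlo |

The Cymbuliidae linear dry-weight fit goes negative below L ≈ 0.077 mm;
tiny juveniles are legitimate inputs, so the mass is clamped to zero
with a warning rather than rejected. The Atlantidae exponential
ash-weight fit (0.769·e^(0.0023·L)) is nearly constant for lengths in
mm — incompatible with its reported goodness of fit, suggesting the
intended length unit may be µm — so the fit is applied as printed with
a configurable `length_scale` and no silent reinterpretation.

The coccolith mass table (coccoliths per sphere, pg CaCO₃ per
coccolith) ships as editable configuration with placeholder defaults in
the literature's typical range; these per-species values are data, not
code, and any species absent from the table raises a configuration
error naming it.

## Skew-robust basin statistics

Biomass compilations are dominated by small values with rare huge ones;
means are meaningless (the sample skewness of the heavy-tailed regime
is itself unstable, which is the point). The pipeline keeps zeros,
removes 3σ outliers in a single pass (statistics computed with zeros
included, sample sd — note that at n ≤ 9 no point can ever exceed 3σ,
since the maximum standardised deviation is (n−1)/√n), converts carbon
to CaCO₃ with fPIC = r/(1+r) under a flat PIC:POC prior, integrates
over the production layer, and divides by flat-prior turnover draws.

Summaries use a zero-truncated Gaussian KDE: each kernel is
renormalized by its own mass on [0, ∞), which up-weights observations
near zero instead of reflecting or discarding them; the density then
integrates to exactly 1 on the half-line. Bandwidth is Silverman's rule
on the untruncated sample. Percentiles are read off the analytic
mixture CDF on a dense grid extended to max + 7 bandwidths (residual
tail mass < 10⁻⁹); the mode is the density argmax on a 2048-point grid
spanning [0, max + 3 bandwidths]. An all-equal sample degenerates to a
point mass.

Point summaries pool the Monte-Carlo transformed value sets (default
100 draws of (r, τ); the pooled sample is capped at 20 000 values for
the KDE). Uncertainty comes from a bootstrap over records with one
(r, τ) draw per resample, summarized by the empirical median per
resample — a full KDE per resample would cost three orders of magnitude
more compute without materially changing the interval. With degenerate
priors the pipeline collapses to the closed form
biomass × 250 × fPIC × 8.33 / τ exactly, element by element, because
the transformation precedes any summarisation.

## Global extrapolation

Station annual production is regressed on annual-mean surface satellite
PIC by OLS with intercept (statsmodels under the hood); the non-zero
intercept absorbs the deep, satellite-invisible production of the
subtropical gyre. R² = 1 − SSres/SStot and the residual standard error
is √(SSres/(n−2)). The regression is applied per ocean cell, floored at
zero (the floor never binds with positive coefficients, but the
contract must be total), weighted by exact spherical band areas
R²·Δλ·(sin φ₊ − sin φ₋) — these sum to 4πR² to machine precision on any
regular grid — and summed. Annual climatology cells are the unweighted
mean over months with valid retrievals (high-latitude winter gaps are
excluded from the mean, not zero-filled), and the ocean mask is the set
of cells with at least one valid retrieval. The minimum estimate
multiplies the area fraction with annual PIC below 10 mg m⁻³ by the
supplied station rates and ocean area.

Sediment-trap comparisons are snapshot-to-snapshot: daily trap fluxes
are annualized ×365 and compared with *uncorrected* (not seasonally
adjusted) production at the matched station, because a 72-hour floating
trap samples the same instant the nets do.

## What the synthetic generator emulates — and what it does not

The generator reproduces the structure of a late-summer subtropical→
subpolar North Pacific transect: five stations from 22.75°N to 50.1°N;
total stocks rising from 700 to 3800 mg CaCO₃ m⁻²; taxon shares
80/15/4/1% (coccolithophores/pteropods/foraminifera/heteropods), hence
a 16% aragonite stock share; lognormal shell lengths per family;
Gaussian coccolithophore depth profiles that shoal poleward (peak depth
120 → 30 m, width 30 m) with fluorescence tracking the same shape;
tow depths 300 → 150 m with oblique flowmeter paths 2–3× the depth and
a 1/8 split; a zero-inflated (6.7%) lognormal biomass compilation of
1793 records whose CaCO₃ median at the midpoint fPIC is 0.5 mg m⁻³; a
two-regime global PIC field (5 / 80 mg m⁻³) whose low-PIC area fraction
is set to ≈ 0.87 by exact area-weighted search, with a subpolar
Northeast-Pacific bloom patch so the northern stations sit in the
high-PIC regime, a 71% ocean fraction drawn as a longitude sector, and
August-peaked seasonality with known August/annual ratios (1.2
subtropical, 2.0 subpolar); and trap fluxes at 20% of mid-turnover
production with aragonite fractions decreasing poleward.

Zooplankton shell lists are drawn lognormally and then closed exactly:
the last individual's length is solved from the allometric chain so the
realized sample mass equals the configured target. This removes count
granularity (a single Atlantid shell is a large fraction of a station's
heteropod mass under the printed exponential fit) and makes stock
recovery tests sharp; measurement noise enters instead through Poisson
microscopy counts on the coccolithophore filters, which is where
counting noise lives in real data. Consequently, passing recovery tests
demonstrate the correctness of the conversion/normalization algebra and
the calibration of the Monte-Carlo intervals — they do not demonstrate
robustness to net avoidance, mesh selectivity, preservation loss,
taxonomic misassignment, or the spatial sampling bias of real
compilations, none of which the generator attempts to emulate.

## Numerical choices

- All masses are carried in mg CaCO₃ at full floating precision; molar
  conversions (100.09 g mol⁻¹ CaCO₃, 12.011 g mol⁻¹ C) happen only at
  reporting boundaries.
- Profile integration is trapezoidal, never extrapolated above the
  first sample or below the last; the 1%-of-peak fluorescence bound is
  linearly interpolated between cast depths.
- Random streams are keyed by (seed, stage name) through SHA-256, so
  adding a stage does not perturb another stage's draws and runs are
  bit-reproducible.
- Percentile summaries use 2.5/16/32/50/68/84/97.5; cruise-style CIs
  are 16–84 (68%) and 2.5–97.5 (95%), compilation-style summaries
  report 32/50/68 plus the density mode.
- Expected per-individual shell mass (used to size synthetic samples)
  is computed by a 4001-point midpoint quadrature on the lognormal
  quantile transform.
- The acceptance script scales the Monte-Carlo stages to 10⁶ draws for
  closed-form checks and 200 bootstrap × 100 MC iterations for the
  compilation pipeline, sizes at which every stochastic check is stable
  to well under its test tolerance.

## Known limitations

- Steady-state production cannot capture bloom dynamics; the seasonal
  bias factor is a single multiplicative correction.
- The zooplankton seasonality correction interpolates between two
  time-series anchors and adjusts only the seasonal trend, not
  interannual variability.
- The global extrapolation assumes the subtropical deep-production bias
  scales with surface PIC everywhere, and is driven by the high-PIC
  stations; the regression's intercept variability propagates directly
  into the global total.
- Tow stocks apply no net-efficiency, mesh-selectivity, or day/night
  correction, and trap comparisons use matched stations only with no
  interpolation between trap depths.
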