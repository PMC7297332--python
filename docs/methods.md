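# Methods

## Scope and data model

`cathlar` models an interventional-cardiology dose study as a list of
procedure records.  Each record carries the procedure type (CA with PCI,
diagnostic CA, or "others" — ablations and device implantations), the
machine technique factors (fluoroscopy and cine tube voltage/current and
durations), the dose–area product (DAP, Gy·cm²), and one EPD reading per
staff member present, interpreted as Hp(10) in μSv measured over the
thyroid collar.  μSv is the canonical internal unit; mSv appears only at
the annualization and risk boundaries.  On disk a log is the `doselog-v1`
CSV (one row per procedure × operator); an optional trailing
`beam_directions` column preserves projection labels so write→read
round-trips are lossless.

Annualization multiplies the dose sum for a role over a monitoring window
by 12/window (months) and converts to mSv/yr.  Note that a caseload-weighted
combination of per-type mean doses is *not* guaranteed to reproduce an
annual dose computed from a worker's actual monthly records — per-operator
workloads matter — which is why the pipeline allows the per-role annual
doses to be pinned in configuration instead of recomputed from the log
(the study-replication profile pins 3.49 / 1.30 mSv/yr for primary /
assistant operators).

## Dosimeter conversions

All conversions are linear and homogeneous.  A collar Hp(10) reading is
converted to Hp(0.07) by +3%; readings carry their operational quantity so
the depth conversion cannot be applied twice.  Effective dose can be
estimated three ways, selected by `effective_dose_method`:

* `hp10_raw` (default): the collar Hp(10) is taken as whole-body dose.
  This is the convention used for the risk results: back-scaling the
  published occupational LAR percentages against the chronic coefficients
  is consistent with raw Hp(10) input, so it is the default.
* `niklason_two`: E = 0.02·(Hos − Hu) + Hu with Hos = Hp(0.07) over shield,
  Hu = Hp(10) under apron.
* `niklason_single`: E = 0.03·Hos, from assuming Hu ≈ 0.01·Hos.

The eye-lens dose from an unshielded neck dosimeter is 0.75 × neck dose.
No hand-dose estimator exists and none is provided.

## Synthetic dose-log generator

The generator emulates the study conditions: 71 procedures split with
probabilities 43/71, 16/71, 12/71 across CA-with-PCI / CA / others; one
primary operator per procedure (male, ages per-type normal); an assistant
present with probability 38/43, 6/16, 1/12 by type.  Per (type × role) dose
cells default to the published means ± SDs (59.33 ± 95.03, 39.81 ± 103.85,
21.92 ± 37.04 μSv primary; 30.03 ± 55.67, 14.67 ± 14.88, 4 μSv assistant);
DAP cells to 238.67 ± 201.51, 119.30 ± 54.40, 49.82 ± 126.27 Gy·cm².

*Family.*  Doses and DAP default to log-normal because the published SDs
exceed the means (CV > 1), which rules out any near-symmetric family on the
positive half-line.  Moment matching is exact: σ² = ln(1 + s²/m²),
μ = ln m − σ²/2.  A gamma alternative is available; with gamma marginals
the DAP coupling is imposed through a Gaussian copula and matches the
target R² only approximately.

*The single-observation cell.*  The assistant "others" cell has one case
and no published SD; its default SD is set equal to its mean (CV 1,
matching the adjacent assistant CA cell's CV ≈ 1.01).

*DAP–dose coupling.*  Operator dose is generated as
ln(dose) = a + b·ln(DAP) + ε, which keeps the dose marginal exactly
log-normal.  A single within-type log-scale correlation ρ is solved by
root-finding (Brent) so that the *pooled* population Pearson correlation²
across procedure types — weighted by type frequency and, for assistants, by
presence probability — equals the configured target (defaults 0.11 primary,
0.46 assistant).  Pooling is what a study-style regression on mixed
procedure types measures; between-type mean differences contribute part of
the pooled R².  The match holds in expectation: a single n = 71 sample
scatters widely around the target, so parameter-recovery checks average
fitted R² over replicate seeds rather than asserting on one draw.
Infeasible targets (beyond the maximum correlation the two log-normal
marginals admit) raise an error naming the role and the attainable range.

*Beam directions.*  Projection labels (LAO/RAO/AP/CRAN/CAU × fluoroscopy/
acquisition) are sampled from a configurable categorical distribution with
a flat default; no study-specific percentages are hard-coded, as none are
published numerically.

Identical seed + config ⇒ byte-identical output.

## Risk engine

Two routes compute the LAR of all-cancer incidence and mortality for a
constant (or per-age) annual dose from age 18 to 65.

**Coefficient scaling** multiplies the bundled chronic-exposure
coefficients — LAR per 100,000 persons exposed to 10 mSv/yr from 18 to 65 —
by D/10 (linear no-threshold).  Incidence coefficients are 3,059 (M) and
4,295 (F).  Mortality coefficients (1,691 M, 2,379 F) are back-calculated
from the published occupational mortality percentages at 3.49 and
1.30 mSv/yr and are consistent with the BEIR VII chronic table at the
precision those percentages carry; the provenance header states this
derivation.  This route refuses age ranges other than 18–65, for which the
coefficients are undefined.

**Full integral.**  A chronic schedule is decomposed into independent
annual acute exposures (the standard BEIR VII chronic treatment).  For the
dose received at age t, site-specific excess risk is accumulated over
attained ages a from t + L to 100 and weighted by the survival ratio
S(a)/S(e₀), with e₀ the age at first exposure — i.e. the whole schedule is
conditioned on being alive at the start of exposure.  Integration uses
trapezoidal weights on a 1-year grid by default; refining the step to 0.5
or 0.25 years changes results by < 0.5%.

Site models: stomach, colon, liver, lung, prostate, uterus, ovary, bladder,
thyroid, residual "other solid", and leukemia.  Solid sites use
β·D·exp(γe*)·(a/60)^η with e* = (min(e,30) − 30)/10; female breast uses the
pooled-cohort EAR-only model with a continuous exposure-age decline and a
piecewise attained-age slope (knot at 50); thyroid is ERR-only; leukemia
uses the linear–quadratic β·D(1 + θD) form with time-since-exposure terms.
ERR and EAR transports are combined as a weighted geometric mean (log
scale), weight 0.7 on ERR except lung (0.3).  DDREF 1.5 divides solid-site
dose terms; leukemia is exempt.  Mortality drives the ERR route with
baseline mortality rates and scales the EAR route by the age-specific
mortality/incidence ratio (clipped to [0,1]).  1 mSv Hp(10) is treated as
1 mGy low-LET organ dose at the model input.

All-cancer LAR is the sum over sites; `by_site=True` (CLI `--by-site`)
exposes the per-site decomposition.

### Population tables

BEIR VII's exact inputs (US 2000 decennial life table, SEER 1995–99
incidence, US 1995–99 mortality) are not redistributable here from a
verified source, so the bundled tables are *synthetic reconstructions*:
smooth PCHIP curves through sparse anchors calibrated to published summary
demographics (life expectancy ≈ 75/81 y, survival-to-65 ≈ 0.80/0.88,
realistic all-cancer and site-specific rate profiles).  The leukemia
baselines are non-CLL leukemia, because the radiogenic leukemia models
exclude chronic lymphocytic leukemia; lymphoma, myeloma and CLL are
excluded from the radiogenic total entirely (they carry no BEIR VII risk
model).  The "other solid" baseline is defined as the residual of the
all-cancer totals minus the excluded haematological sites and the named
sites, keeping the site table internally consistent.  Files are labelled
`synthetic` and can be replaced by user-supplied tables of the same layout.

Consequences: the full-integral route reproduces the chronic incidence
coefficients to within about 5% (M) and 8% (F) rather than exactly, and
its mortality estimates run ~15–25% above the back-calculated mortality
coefficients (the mortality/incidence transport is the most
table-sensitive step).  The coefficient-scaling route is exact by
construction and is the one used for reported occupational percentages.

### Reported precision

The report layer prints percentages at 2 decimal places
(lar_percent = lar_per_100k / 1000); full precision is retained internally.

## DAP–dose association

Simple OLS of EPD dose on DAP per role (statsmodels), slope p-value from
the two-sided t-test; for the bivariate fit R² equals the squared Pearson
correlation.  The published per-role statistics are bivariate, so simple
OLS is the primary estimator; `--adjusted` adds procedure-type indicator
covariates for the reading of "multiple regression" that adjusts for case
mix.  `scatter_export` writes the (DAP, dose) pairs plus the fitted-line
parameters as CSV for external plotting, keeping plotting libraries out of
the core.

## Pipeline

`run_pipeline` composes simulate/ingest → summarize → annualize → risk →
regress, writing a fixed artifact bundle plus a manifest (seed, config
hash, version).  Exactly one of an input log or a generator config must be
given; annual doses are pinned or recomputed as described above.  Output
location and log level are excluded from the manifest hash so identical
analyses produce byte-identical bundles anywhere.

## Problem sizes in the test suite

Generator calibration checks use 100,000 draws (mean within 2%, SD within
5% of the configured cell — the SD of a CV≈1.6 log-normal has a relative
standard error of ≈2.6% at this n, so the 5% band is a ~2σ check).
Coupling recovery averages fitted R² over 200 replicate seeds at
n = 10,000 (±0.03 band).  Full-integral checks run at the 10 mSv/yr
reference scenario.  These sizes keep the complete suite around a minute
of CPU while leaving Monte-Carlo noise well inside the asserted bands.

## Known limitations

* The population tables are smoothed reconstructions; absolute full-
  integral LARs inherit their uncertainty (the published coefficients
  themselves depend on tables not published alongside them).
* No uncertainty intervals on LAR (the BEIR VII subjective CIs are out of
  scope); no non-cancer endpoints; no site-level headline claims.
* The generator is statistical, not physical: no scatter geometry,
  shielding, or room-layout model; real logs exhibit operator-level
  clustering and temporal drift that it does not emulate.  Passing
  calibration tests therefore validate the pipeline's statistics, not any
  physical dose prediction.
* Coefficient scaling is exact linear no-threshold extrapolation; its
  validity at a few mSv/yr is an assumption of the underlying risk models,
  not a result of this package.
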