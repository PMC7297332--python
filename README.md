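# cathlar

Occupational radiation dose analysis and lifetime attributable cancer-risk
estimation for cardiac catheterization laboratory staff.

Interventional cardiology staff work beside the patient while the X-ray beam
is on; their exposure comes from Compton scatter and is monitored with
electronic personal dosimeters (EPDs) worn at the thyroid collar, reading
the personal dose equivalent Hp(10) in μSv per procedure.  `cathlar` turns a
log of such per-procedure readings — real or synthetic — into the numbers a
radiation-safety analysis needs:

* **Descriptive statistics** per procedure type (coronary angiography with
  PCI, diagnostic CA, device implantations/ablations) and staff role
  (primary / assistant operator), including technique factors and
  dose–area product (DAP, Gy·cm²).
* **Annualized operator dose** in mSv/yr from a monitoring window.
* **Dosimeter conversions**: Hp(10)→Hp(0.07) (+3%), the modified Niklason
  effective-dose algorithms `E = 0.02·(Hos − Hu) + Hu` (two dosimeters) and
  `E = 0.03·Hos` (collar only), and the eye-lens estimate
  `eye = 0.75 × neck`.
* **Lifetime attributable risk (LAR)** of all-cancer incidence and
  mortality under the BEIR VII risk models, for a chronic exposure from age
  *e* to retirement:

  LAR(e, s, D) = Σₐ M(e, s, D, a) · m(s, a) · S(s, a) / S(s, e),

  summed over attained ages *a* from *e + L* to 100 (latency L = 5 y for
  solid cancers, 2 y for leukemia), where m(s, a) is the baseline cancer
  rate, S the survival function, and M the dose response combining
  excess-relative-risk and excess-absolute-risk transport per cancer site
  (DDREF 1.5 on solid-cancer dose terms, linear–quadratic leukemia model).
  A linear no-threshold scaling of the BEIR VII chronic-exposure
  coefficients (3,059 male / 4,295 female incident cancers per 100,000 per
  10 mSv/yr from 18 to 65) is provided as the fast reference route, and the
  full integral as an independent numerical route.
* **DAP–dose association**: OLS of operator dose on DAP per role, with R²
  and slope inference.
* A **synthetic dose-log generator** that emulates a 71-procedure
  single-centre study (log-normal doses and DAP moment-matched to published
  means ± SDs, configurable DAP→dose coupling R², truncated-normal
  technique factors), so the whole pipeline is testable without any
  measured data.

## Worked example

Simulate a year's caseload, summarize it, and estimate risk:

```sh
$ cathlar simulate --n 71 --seed 42 --out log.csv
wrote 71 procedures to log.csv

$ cathlar summarize --in log.csv --role primary
procedure_type      role  n      mean        sd
            CA ASSISTANT  7 11.526928 10.430745
            CA   PRIMARY 23 31.927116 42.743167
        CA_PCI ASSISTANT 34 23.801365 27.070424
        CA_PCI   PRIMARY 40 55.972592 64.214097
        OTHERS ASSISTANT  1  1.444580       NaN
        OTHERS   PRIMARY  8 18.109836 23.079180
...
annual dose (primary): 3.12 mSv/yr
```

Each row is the per-procedure EPD dose (μSv) for one procedure type × role
cell; at n = 71 the sample means scatter around the generator's configured
cells (59.33 ± 95.03 μSv for CA-with-PCI primaries), and the annualized
primary dose lands near the configured regime of a few mSv/yr.

```sh
$ cathlar risk --annual-dose 3.49 --sex M --outcome incidence
LAR incidence (M, 3.49 mSv/yr, ages 18:65): 1.07% = 1067.6 per 100,000 [COEFFICIENT_SCALING]

$ cathlar risk --annual-dose 10 --sex F --outcome incidence --method integral
LAR incidence (F, 10.0 mSv/yr, ages 18:65): 4.64% = 4641.5 per 100,000 [FULL_INTEGRAL]
```

The first line says: a male operator receiving 3.49 mSv every year from age
18 to 65 accumulates an extra 1.07% lifetime probability of a cancer
diagnosis over baseline.  The second line runs the full site-by-site
integral at the BEIR VII reference chronic dose; it lands within ~8% of the
published 4,295 per 100,000 coefficient, the residual reflecting that the
bundled population tables are smoothed reconstructions (see
`docs/methods.md`).

```sh
$ cathlar regress --in log.csv --role assistant
role=ASSISTANT n=42 slope=0.1131 μSv/(Gy·cm²) intercept=-3.87 μSv R²=0.560 p=<0.001
```

DAP explains about half the assistant's dose variance at this sample size
(configured population R² 0.46; single-sample fits scatter around it).

`cathlar run --out bundle` executes the whole pipeline (simulate →
summarize → annualize → risk → regress) and writes `table1_summary.csv`,
`annual_dose.csv`, `table2_lar.csv`, `regression.csv` and a run manifest;
identical config + seed gives a byte-identical bundle.

## Data files

`src/cathlar/data/` ships plain-text parameter files with PROVENANCE
headers: the BEIR VII ERR/EAR site models and chronic-exposure LAR
coefficients, plus a synthetic US-2000-like life table and baseline cancer
rate tables (smoothed stand-ins for the national tables, not copies).
Users may substitute their own tables via
`load_default_tables(lifetable_path=..., rates_path=...)`.
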