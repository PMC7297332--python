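"""Regenerate the bundled synthetic US-2000-like population tables.

Sparse per-site anchors (smoothed reconstructions of SEER-era age-specific
rates) are PCHIP-interpolated to a full age grid; the 'other solid' site is
the residual of the all-cancer totals minus leukemia, lymphoma/myeloma/CLL
(no radiogenic risk model; excluded entirely), and the named sites, which
keeps the shipped site table consistent with the calibrated all-cancer
totals.  Output files carry a 5-year age grid to stay small; the package
re-interpolates at load.

Run from the repo root (rewrites src/cathlar/data/*.tsv), then prints the
demographic calibration statistics and the chronic-scenario LAR for
inspection.
"""

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

AGES = np.arange(101)
OUT_GRID = np.arange(0, 101, 5)

# --- life table anchors (survivorship to exact age) -------------------------
LIFE_ANCHORS = {
    "M": (
        [0, 1, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85, 90, 95, 100],
        [1.0, 0.9924, 0.9910, 0.9901, 0.9887, 0.9840, 0.9785, 0.9730, 0.9665,
         0.9580, 0.9460, 0.9290, 0.9040, 0.8640, 0.8020, 0.7130, 0.5950,
         0.4520, 0.2910, 0.1430, 0.0470, 0.0090],
    ),
    "F": (
        [0, 1, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85, 90, 95, 100],
        [1.0, 0.9938, 0.9927, 0.9920, 0.9911, 0.9891, 0.9870, 0.9846, 0.9813,
         0.9765, 0.9693, 0.9590, 0.9435, 0.9195, 0.8830, 0.8280, 0.7450,
         0.6230, 0.4580, 0.2710, 0.1100, 0.0250],
    ),
}

# --- all-cancer totals (incl. leukemia and lymphoma/myeloma) ----------------
TOTALS = {
    ("M", "incidence"): (
        [0, 10, 20, 30, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85, 90, 100],
        [17, 12, 32, 62, 140, 250, 450, 820, 1380, 2050, 2700, 3100, 3250, 3200, 3000, 2600],
    ),
    ("F", "incidence"): (
        [0, 10, 20, 30, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85, 90, 100],
        [15, 14, 33, 95, 250, 380, 550, 760, 1020, 1290, 1530, 1690, 1750, 1700, 1550, 1300],
    ),
    ("M", "mortality"): (
        [0, 10, 20, 30, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85, 90, 100],
        [3, 3.5, 6, 12, 55, 105, 195, 370, 630, 980, 1380, 1800, 2180, 2450, 2550, 2550],
    ),
    ("F", "mortality"): (
        [0, 10, 20, 30, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85, 90, 100],
        [3, 3.5, 7, 14, 50, 90, 150, 245, 385, 560, 770, 1000, 1230, 1420, 1520, 1520],
    ),
}

# --- named-site anchors -----------------------------------------------------
SITE_ANCHORS = {
    ("M", "stomach", "incidence"): ([0, 20, 30, 40, 50, 60, 70, 80, 90, 100],
                                    [0, 0.5, 1.5, 4, 10, 25, 55, 90, 110, 110]),
    ("F", "stomach", "incidence"): ([0, 30, 40, 50, 60, 70, 80, 90, 100],
                                    [0, 1, 2.5, 5, 11, 25, 45, 55, 55]),
    ("M", "colon", "incidence"): ([0, 20, 30, 40, 50, 55, 60, 65, 70, 75, 80, 85, 90, 100],
                                  [0, 1, 4, 12, 40, 70, 120, 180, 250, 320, 370, 390, 390, 380]),
    ("F", "colon", "incidence"): ([0, 30, 40, 50, 55, 60, 65, 70, 75, 80, 85, 90, 100],
                                  [0, 3, 10, 30, 50, 80, 120, 170, 230, 280, 300, 300, 290]),
    ("M", "liver", "incidence"): ([0, 20, 30, 40, 50, 60, 70, 80, 90, 100],
                                  [1, 0.5, 1.5, 4, 9, 16, 25, 30, 30, 30]),
    ("F", "liver", "incidence"): ([0, 30, 40, 50, 60, 70, 80, 90, 100],
                                  [0.5, 0.7, 1.5, 3.5, 6, 11, 14, 14, 14]),
    ("M", "lung", "incidence"): ([0, 20, 30, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85, 90, 100],
                                 [0, 0.5, 2, 15, 35, 70, 145, 265, 400, 500, 540, 500, 420, 330, 250]),
    ("F", "lung", "incidence"): ([0, 30, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85, 90, 100],
                                 [0, 2, 12, 25, 50, 95, 160, 230, 275, 290, 260, 200, 150, 120]),
    ("M", "prostate", "incidence"): ([0, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85, 90, 100],
                                     [0, 2, 12, 55, 180, 430, 780, 1020, 1080, 1000, 860, 750, 650]),
    ("F", "breast", "incidence"): ([0, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85, 90, 100],
                                   [0, 8, 25, 60, 120, 190, 245, 290, 340, 390, 430, 450, 430, 380, 330, 280]),
    ("F", "uterus", "incidence"): ([0, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75, 80, 90, 100],
                                   [0, 4, 8, 15, 25, 40, 55, 70, 85, 95, 95, 85, 70, 60]),
    ("F", "ovary", "incidence"): ([0, 30, 40, 50, 55, 60, 65, 70, 75, 80, 90, 100],
                                  [1, 5, 15, 26, 33, 40, 45, 50, 52, 50, 42, 40]),
    ("M", "bladder", "incidence"): ([0, 30, 40, 50, 60, 70, 80, 85, 90, 100],
                                    [0, 2, 6, 16, 45, 100, 160, 180, 180, 170]),
    ("F", "bladder", "incidence"): ([0, 30, 40, 50, 60, 70, 80, 90, 100],
                                    [0, 1, 2.5, 6, 13, 28, 45, 50, 48]),
    ("M", "thyroid", "incidence"): ([0, 20, 30, 40, 50, 60, 70, 80, 90, 100],
                                    [0, 2, 3.5, 5, 6.5, 8, 9, 9, 8, 8]),
    ("F", "thyroid", "incidence"): ([0, 20, 30, 40, 50, 60, 70, 80, 90, 100],
                                    [0, 6, 12, 15, 16, 16, 15, 13, 11, 10]),
    # non-CLL leukemia only (CLL carries no radiogenic risk model)
    ("M", "leukemia", "incidence"): ([0, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100],
                                     [6, 3.2, 2.8, 3.3, 4.5, 7, 14, 27, 45, 55, 55]),
    ("F", "leukemia", "incidence"): ([0, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100],
                                     [5, 2.8, 2.4, 2.6, 3.4, 5, 9, 17, 28, 34, 34]),
    # lymphoma + myeloma + CLL: no radiogenic model; subtracted, not shipped
    ("M", "lymphmyel", "incidence"): ([0, 20, 30, 40, 50, 60, 70, 80, 90, 100],
                                      [3, 4, 8.2, 16, 33, 68, 113, 150, 155, 155]),
    ("F", "lymphmyel", "incidence"): ([0, 20, 30, 40, 50, 60, 70, 80, 90, 100],
                                      [2, 3, 6.2, 11.6, 24, 50, 83, 109, 111, 111]),

    ("M", "stomach", "mortality"): ([0, 30, 40, 50, 60, 70, 80, 90, 100],
                                    [0, 1, 3, 7, 18, 40, 65, 80, 80]),
    ("F", "stomach", "mortality"): ([0, 30, 40, 50, 60, 70, 80, 90, 100],
                                    [0, 0.7, 2, 4, 8, 18, 33, 42, 42]),
    ("M", "colon", "mortality"): ([0, 30, 40, 50, 60, 65, 70, 75, 80, 85, 90, 100],
                                  [0, 1.5, 5, 16, 50, 80, 115, 155, 195, 220, 230, 230]),
    ("F", "colon", "mortality"): ([0, 30, 40, 50, 60, 65, 70, 75, 80, 85, 90, 100],
                                  [0, 1.2, 4, 12, 37, 60, 86, 116, 146, 165, 172, 172]),
    ("M", "liver", "mortality"): ([0, 20, 30, 40, 50, 60, 70, 80, 90, 100],
                                  [0.8, 0.5, 1.4, 3.8, 8.5, 15, 24, 29, 29, 29]),
    ("F", "liver", "mortality"): ([0, 30, 40, 50, 60, 70, 80, 90, 100],
                                  [0.4, 0.7, 1.4, 3.3, 5.7, 10.5, 13.5, 13.5, 13.5]),
    ("M", "lung", "mortality"): ([0, 30, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85, 90, 100],
                                 [0, 1.5, 10, 25, 60, 125, 230, 350, 450, 500, 470, 390, 300, 230]),
    ("F", "lung", "mortality"): ([0, 30, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85, 90, 100],
                                 [0, 1.5, 10, 20, 40, 75, 125, 180, 215, 230, 210, 160, 120, 100]),
    ("M", "prostate", "mortality"): ([0, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85, 90, 100],
                                     [0, 0.5, 1, 4, 12, 30, 70, 130, 220, 330, 430, 500, 500]),
    ("F", "breast", "mortality"): ([0, 25, 30, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85, 90, 100],
                                   [0, 1, 3, 12, 18, 26, 34, 42, 50, 58, 68, 85, 105, 130, 140]),
    ("F", "uterus", "mortality"): ([0, 30, 40, 50, 60, 65, 70, 75, 80, 90, 100],
                                   [0, 1, 3, 7, 13, 17, 21, 24, 27, 30, 30]),
    ("F", "ovary", "mortality"): ([0, 30, 40, 50, 55, 60, 65, 70, 75, 80, 90, 100],
                                  [0, 2, 7, 15, 21, 27, 32, 37, 40, 41, 38, 36]),
    ("M", "bladder", "mortality"): ([0, 40, 50, 60, 70, 80, 90, 100],
                                    [0, 1, 4, 12, 30, 60, 80, 80]),
    ("F", "bladder", "mortality"): ([0, 40, 50, 60, 70, 80, 90, 100],
                                    [0, 0.4, 1.5, 4, 9, 18, 25, 25]),
    ("M", "thyroid", "mortality"): ([0, 40, 60, 80, 100], [0, 0.2, 0.5, 1.5, 2]),
    ("F", "thyroid", "mortality"): ([0, 40, 60, 80, 90, 100], [0, 0.2, 0.5, 2, 3, 3]),
    ("M", "leukemia", "mortality"): ([0, 20, 30, 40, 50, 60, 70, 80, 90, 100],
                                     [1.2, 1.3, 1.6, 2.5, 5, 11, 23, 40, 50, 50]),
    ("F", "leukemia", "mortality"): ([0, 20, 30, 40, 50, 60, 70, 80, 90, 100],
                                     [1, 1, 1.2, 1.9, 3.5, 7, 14, 25, 33, 33]),
    ("M", "lymphmyel", "mortality"): ([0, 20, 30, 40, 50, 60, 70, 80, 90, 100],
                                      [1, 1.5, 3.1, 6.5, 14, 32, 63, 92, 105, 105]),
    ("F", "lymphmyel", "mortality"): ([0, 20, 30, 40, 50, 60, 70, 80, 90, 100],
                                      [0.8, 1, 2.1, 4.8, 11, 24, 46, 68, 79, 79]),
}

NAMED = {
    "M": ["stomach", "colon", "liver", "lung", "prostate", "bladder", "thyroid"],
    "F": ["stomach", "colon", "liver", "lung", "breast", "uterus", "ovary",
          "bladder", "thyroid"],
}

LIFE_HEADER = """\
# PROVENANCE: synthetic sex-specific period life table emulating US 2000
# demographics.  Constructed by monotone (PCHIP) interpolation of
# survivorship anchors chosen to reproduce published summary statistics of
# the US 2000 period life tables (life expectancy at birth ~74.3 y male /
# ~79.7 y female; survival to age 65 ~0.80 male / ~0.88 female).  A smoothed
# stand-in for the national table, not a copy of it.
# survival = S(a) = P(alive at exact age a | alive at birth).
"""

RATES_HEADER = """\
# PROVENANCE: synthetic baseline cancer rates (per 100,000 persons per year)
# by sex, cancer site, and attained age, incidence and mortality, on a
# 5-year age grid (interpolated to single years at load).  Constructed by
# PCHIP interpolation of age-group anchors emulating US cancer surveillance
# around 2000 (SEER-era incidence, US vital-statistics mortality); the
# 'other' site is the residual of the all-cancer totals minus leukemia,
# lymphoma/myeloma (no radiogenic risk model), and the named sites, so the
# shipped sites are jointly consistent with realistic all-cancer totals.
# Synthetic stand-ins for the national rate tables, not copies of them.
"""


def _interp(xs, ys):
    return np.clip(PchipInterpolator(xs, ys)(AGES), 0, None)


def build():
    rows = []
    for sex, (xs, ys) in LIFE_ANCHORS.items():
        s = np.minimum.accumulate(np.clip(PchipInterpolator(xs, ys)(AGES), 0, 1))
        s[0] = 1.0
        for a, v in zip(AGES, s):
            rows.append({"sex": sex, "age": int(a), "survival": round(float(v), 6)})
    life = pd.DataFrame(rows)

    rrows = []
    for sex in ("M", "F"):
        for outcome in ("incidence", "mortality"):
            total = _interp(*TOTALS[(sex, outcome)])
            named_sum = np.zeros_like(total)
            curves = {}
            for site in NAMED[sex] + ["leukemia", "lymphmyel"]:
                c = _interp(*SITE_ANCHORS[(sex, site, outcome)])
                curves[site] = c
                named_sum += c
            other = np.clip(total - named_sum, 0.1, None)
            curves["other"] = other
            if np.any(total - named_sum < 0):
                bad = AGES[(total - named_sum) < 0]
                print(f"WARNING: negative residual {sex} {outcome} at ages {bad}")
            del curves["lymphmyel"]  # not a radiogenic site; not shipped
            for site, c in curves.items():
                for a in OUT_GRID:
                    rrows.append(
                        {
                            "sex": sex,
                            "site": site,
                            "outcome": outcome,
                            "age": int(a),
                            "rate_per_100k": round(float(c[a]), 3),
                        }
                    )
    rates = pd.DataFrame(rrows)

    with open("src/cathlar/data/us2000_lifetable_synthetic.tsv", "w") as fh:
        fh.write(LIFE_HEADER)
        life.to_csv(fh, sep="\t", index=False)
    with open("src/cathlar/data/us_baseline_cancer_rates_synthetic.tsv", "w") as fh:
        fh.write(RATES_HEADER)
        rates.to_csv(fh, sep="\t", index=False)


def evaluate():
    from cathlar.dose_records import Sex
    from cathlar.risk import (
        ExposureScenario,
        Outcome,
        lar_full_integral,
        load_default_params,
        load_default_tables,
    )

    tables = load_default_tables()
    params = load_default_params()
    grid = np.arange(101)
    for sex in ("M", "F"):
        s = tables.survival(sex, grid)
        le = np.trapezoid(s, grid)
        print(f"{sex}: life expectancy {le:.1f}  S(65) {float(tables.survival(sex, 65)):.3f}")
        for outcome in ("incidence", "mortality"):
            total = sum(
                np.sum(tables.rate(Sex(sex), site, Outcome(outcome), grid) * s) / 1e5
                for site in params.sites_for(Sex(sex))
            )
            print(f"   lifetime cancer {outcome} risk (radiogenic sites): {total:.3f}")
    print()
    for sex, target_inc, target_mort in (("M", 3059, 1691), ("F", 4295, 2379)):
        sc = ExposureScenario(sex=sex, annual_dose_msv=10.0)
        for outcome, target in (("incidence", target_inc), ("mortality", target_mort)):
            res, sites = lar_full_integral(
                sc, Outcome(outcome), params, tables, by_site=True
            )
            rel = res.lar_per_100k / target - 1
            print(
                f"{sex} {outcome}: {res.lar_per_100k:8.1f} per 100k "
                f"(target {target}, {rel:+.1%})"
            )
            print("    " + "  ".join(f"{k}={v:.0f}" for k, v in sorted(sites.items())))


if __name__ == "__main__":
    build()
    evaluate()
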