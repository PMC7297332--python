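"""DAP–operator-dose association.

Quantifies how well the machine-reported dose-area product predicts the
scatter dose actually received by staff, via ordinary least squares of the
EPD dose (μSv) on DAP (Gy·cm²) per role.  For the simple bivariate fit the
coefficient of determination equals the squared Pearson correlation.  An
optional covariate-adjusted variant adds procedure-type dummies.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dose_records import ProcedureRecord, Role, records_to_frame

__all__ = ["RegressionResult", "regress_dose_on_dap", "scatter_export"]


@dataclass
class RegressionResult:
    """OLS fit of operator dose on DAP."""

    slope: float  # μSv per Gy·cm²
    intercept: float  # μSv
    r_squared: float
    p_value: float  # two-sided t-test on the DAP slope
    n: int
    role: Role
    adjusted: bool = False

    def format_p(self) -> str:
        return "<0.001" if self.p_value < 0.001 else f"{self.p_value:.3f}"


def _pairs(
    records: Sequence[ProcedureRecord] | pd.DataFrame, role: Role
) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = records_to_frame(list(records))
    if frame.empty:
        raise ValueError("no records supplied")
    sub = frame[frame["role"] == Role(role).value]
    sub = sub.dropna(subset=["dap_gycm2", "epd_dose_usv"])
    return sub


def regress_dose_on_dap(
    records: Sequence[ProcedureRecord] | pd.DataFrame,
    role: Role,
    adjusted: bool = False,
) -> RegressionResult:
    """OLS of EPD dose on DAP for one role.

    ``adjusted=True`` adds procedure-type indicator covariates; the reported
    slope, p-value, and R² then describe the adjusted model.
    """
    role = Role(role)
    sub = _pairs(records, role)
    n = len(sub)
    if n < 3:
        raise ValueError(f"need >= 3 usable (DAP, dose) pairs for {role.value}, got {n}")
    x = sub["dap_gycm2"].to_numpy(dtype=float)
    y = sub["epd_dose_usv"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in DAP; regression undefined")

    if adjusted:
        dummies = pd.get_dummies(sub["procedure_type"], drop_first=True, dtype=float)
        design = sm.add_constant(
            pd.concat(
                [pd.Series(x, index=sub.index, name="dap_gycm2"), dummies], axis=1
            )
        )
    else:
        design = sm.add_constant(pd.Series(x, index=sub.index, name="dap_gycm2"))
    fit = sm.OLS(y, np.asarray(design, dtype=float)).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        n=n,
        role=role,
        adjusted=adjusted,
    )


def scatter_export(
    records: Sequence[ProcedureRecord] | pd.DataFrame,
    role: Role,
    path: str | Path,
) -> RegressionResult:
    """Write the (DAP, dose) pairs for ``role`` plus fitted-line parameters
    as CSV (fit parameters in ``#``-prefixed header lines) for external
    plotting; returns the fit."""
    result = regress_dose_on_dap(records, role)
    sub = _pairs(records, role)
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        handle.write(f"# role={result.role.value} n={result.n}\n")
        handle.write(
            f"# slope={result.slope!r} intercept={result.intercept!r} "
            f"r_squared={result.r_squared!r} p_value={result.p_value!r}\n"
        )
        writer = csv.writer(handle)
        writer.writerow(["dap_gycm2", "epd_dose_usv"])
        for xv, yv in zip(sub["dap_gycm2"], sub["epd_dose_usv"]):
            writer.writerow([repr(float(xv)), repr(float(yv))])
    return result
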