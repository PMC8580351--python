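"""Driver-gene stage decomposition.

Published pan-cancer catalogs report the mean number of driver mutations per
tumor for each TCGA cancer type. Subtracting those counts from the fitted
number of carcinogenic stages k yields the "non-driver stages": the portion
of the multistage process not attributable to driver-gene mutation. The
difference may be negative for catalogs that count more drivers than the
model finds stages (endometrial cancer is the published example).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .model_fitting import REPRODUCTIVE_CODES


@dataclass
class DriverRecord:
    cancer_code: str
    drivers_iranzo: float
    drivers_bailey: float
    k_stages: float
    non_driver_iranzo: float
    non_driver_bailey: float
    n_cases: int | None = None


def build_driver_table(fit_table: pd.DataFrame,
                       driver_catalog: pd.DataFrame) -> pd.DataFrame:
    """Join fitted stage counts onto a driver catalog.

    ``fit_table`` holds one row per cancer_code x sex with a ``k`` column;
    non-reproductive cancers take the pooled-sex k, male-specific cancers
    (PRAD, TGCT) the male fit, and female-specific cancers (BRCA, CESC, OV,
    UCEC, UCS) the female fit. Non-driver columns are k minus each catalog's
    driver count.
    """
    male_only = {"PRAD", "TGCT"}
    rows = []
    for rec in driver_catalog.itertuples(index=False):
        code = rec.cancer_code
        if code in male_only:
            sex = "male"
        elif code in REPRODUCTIVE_CODES:
            sex = "female"
        else:
            sex = "pooled"
        match = fit_table[(fit_table["cancer_code"] == code)
                          & (fit_table["sex"] == sex)]
        if match.empty:
            raise KeyError(f"no {sex} fit for {code}")
        k = float(match["k"].iloc[0])
        rows.append({
            "cancer_code": code,
            "drivers_iranzo": rec.drivers_iranzo,
            "drivers_bailey": rec.drivers_bailey,
            "k_stages": k,
            "non_driver_iranzo": k - rec.drivers_iranzo,
            "non_driver_bailey": k - rec.drivers_bailey,
        })
    return pd.DataFrame(rows)


def driver_stage_regression(records: pd.DataFrame,
                            driver_column: str = "drivers_iranzo",
                            exclude_outliers: bool = True,
                            outlier_threshold: float = 3.0):
    """Unweighted OLS of driver counts on stage count k.

    When ``exclude_outliers`` is set, records whose externally studentized
    residual from a preliminary fit reaches ``outlier_threshold`` are dropped
    before the final regression. Returns a dict with slope, intercept,
    Pearson r, the slope P-value, n and the excluded codes.
    """
    t = records.dropna(subset=[driver_column, "k_stages"]).reset_index(drop=True)
    if len(t) < 4:
        raise ValueError("need at least 4 records")
    excluded: list[str] = []
    if exclude_outliers:
        X = sm.add_constant(t["k_stages"].to_numpy())
        pre = sm.OLS(t[driver_column].to_numpy(), X).fit()
        if pre.ssr > 1e-12 * max(1.0, float(pre.centered_tss)):
            student = pre.get_influence().resid_studentized_external
            out = np.abs(student) >= outlier_threshold
            excluded = t.loc[out, "cancer_code"].tolist()
            t = t[~out]
    X = sm.add_constant(t["k_stages"].to_numpy())
    fit = sm.OLS(t[driver_column].to_numpy(), X).fit()
    r = float(np.corrcoef(t["k_stages"], t[driver_column])[0, 1])
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "r": r,
        "p": float(fit.pvalues[1]),
        "n": int(len(t)),
        "excluded": excluded,
    }


def driver_fraction_summary(records: pd.DataFrame, subset_name: str = "all",
                            driver_column: str = "drivers_iranzo") -> dict:
    """Column means plus the percent stage contribution of driver mutations.

    ``subset_name``: ``all``, ``excl_ucec`` or ``nonrepro``. The percent
    contribution per cancer is drivers/k x 100; the 95% interval reported is
    a population interval, mean +/- 1.96 SD of the per-cancer percentages.
    """
    if subset_name == "all":
        t = records
    elif subset_name == "excl_ucec":
        t = records[records["cancer_code"] != "UCEC"]
    elif subset_name == "nonrepro":
        t = records[~records["cancer_code"].isin(REPRODUCTIVE_CODES)]
    else:
        raise KeyError(f"unknown subset {subset_name!r}")
    if len(t) < 2:
        raise ValueError("subset resolves fewer than 2 records")
    pct = 100.0 * t[driver_column] / t["k_stages"]
    return {
        "n": int(len(t)),
        "mean_drivers": float(t[driver_column].mean()),
        "mean_k": float(t["k_stages"].mean()),
        "mean_percent": float(pct.mean()),
        "percent_ci": (float(pct.mean() - 1.96 * pct.std(ddof=1)),
                       float(pct.mean() + 1.96 * pct.std(ddof=1))),
    }
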