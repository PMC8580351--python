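"""Crude age-specific incidence rates from registry-style tables.

Registry extracts arrive as case counts per 5-year age group, sex and cancer
type, alongside population (person-year) tables on the same strata. This
module turns those into crude rates per 100,000 person-years with Poisson
standard errors, infers the populations of the oldest age groups from the
census fraction of the 85+ population in each bin, and locates the observed
peak of each incidence curve.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

PER = 1e5

#: canonical 5-year age-group labels, "0-4" ... "110+"
AGE_GROUP_LABELS = [f"{lo}-{lo + 4}" for lo in range(0, 110, 5)] + ["110+"]
#: matching bin midpoints 2.5 ... 112.5
BIN_MIDPOINTS = np.arange(2.5, 115.0, 5.0)

OLDAGE_LABELS = ["85-89", "90-94", "95-99", "100-104", "105-109", "110+"]

_LABEL_RE = re.compile(r"^(\d+)\s*(?:-\s*(\d+)|\+)$")


def age_group_to_midpoint(label: str) -> float:
    """Parse an age-group label such as '70-74' or '110+' to its midpoint."""
    m = _LABEL_RE.match(str(label).strip())
    if not m:
        raise ValueError(f"unparseable age-group label: {label!r}")
    lo = int(m.group(1))
    return lo + 2.5


@dataclass
class AgeBinnedSeries:
    """Age-binned incidence for one cancer type and sex."""

    cancer_code: str
    sex: str  # male, female or pooled
    bin_midpoints: np.ndarray
    cases: np.ndarray
    person_years: np.ndarray
    rate: np.ndarray  # per 100,000 person-years
    rate_se: np.ndarray  # per 100,000 person-years; weighting SE (>0)
    valid: np.ndarray  # False where person-years are zero

    def __post_init__(self) -> None:
        mids = np.asarray(self.bin_midpoints, dtype=float)
        if mids.size > 1 and not np.allclose(np.diff(mids), 5.0):
            raise ValueError("bin midpoints must increase in 5-year steps")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cancer_code": self.cancer_code,
                "sex": self.sex,
                "age_midpoint": self.bin_midpoints,
                "cases": self.cases,
                "person_years": self.person_years,
                "rate": self.rate,
                "rate_se": self.rate_se,
                "valid": self.valid,
            }
        )


@dataclass
class OldAgeFractions:
    """Census fraction of the 85+ population in each old-age bin."""

    sex: str
    fractions: np.ndarray  # bins 85-89, 90-94, 95-99, 100-104, 105-109, 110+

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.size != len(OLDAGE_LABELS) or np.any(f < 0):
            raise ValueError("need 6 non-negative fractions")
        if not np.isclose(f.sum(), 1.0, atol=1e-8):
            raise ValueError("fractions must sum to 1")
        self.fractions = f


def compute_crude_rates(cases, person_years, cancer_code: str = "",
                        sex: str = "pooled", bin_midpoints=None) -> AgeBinnedSeries:
    """Crude rate and Poisson SE per bin.

    rate = cases / person_years * 1e5 and SE = sqrt(cases) / person_years
    * 1e5. Zero-case bins get a weighting SE computed as if one case had
    been observed, so inverse-variance weights stay finite and those bins
    stay in the fit with low weight. Bins with zero person-years are flagged
    invalid.
    """
    cases = np.asarray(cases, dtype=float)
    py = np.asarray(person_years, dtype=float)
    if cases.shape != py.shape:
        raise ValueError("cases and person_years must have equal length")
    if np.any(cases < 0):
        raise ValueError("negative case counts")
    if np.any(py < 0):
        raise ValueError("negative person-years")
    if np.any((cases > 0) & (py <= 0)):
        raise ValueError("cases observed in a bin with no person-years")
    if bin_midpoints is None:
        bin_midpoints = BIN_MIDPOINTS[: cases.size]
    valid = py > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(valid, cases / py * PER, np.nan)
        se = np.where(valid, np.sqrt(np.maximum(cases, 1.0)) / py * PER, np.nan)
    return AgeBinnedSeries(
        cancer_code=cancer_code,
        sex=sex,
        bin_midpoints=np.asarray(bin_midpoints, dtype=float),
        cases=cases,
        person_years=py,
        rate=rate,
        rate_se=se,
        valid=valid,
    )


def infer_oldage_populations(pop_85plus_total: float,
                             fractions: OldAgeFractions) -> np.ndarray:
    """Split an 85+ population total into per-bin person-years.

    The census fractions are assumed constant over the registry period; the
    returned bins sum to the total exactly.
    """
    if pop_85plus_total < 0:
        raise ValueError("total must be >= 0")
    return pop_85plus_total * fractions.fractions


def observed_peak(series: AgeBinnedSeries, max_age: float = 105.0) -> tuple[float, float]:
    """(age, rate) of the maximum-rate bin among bins with midpoint < max_age.

    The age cap avoids the unstable oldest-old rates; ties break toward the
    younger bin.
    """
    mask = series.valid & (series.bin_midpoints < max_age)
    if not np.any(mask):
        raise ValueError("no valid bins below the age cap")
    mids = series.bin_midpoints[mask]
    rates = series.rate[mask]
    i = int(np.argmax(rates))  # argmax returns the first of equal maxima
    return float(mids[i]), float(rates[i])


# ---------------------------------------------------------------------------
# CSV interface

def read_registry(case_csv, population_csv) -> list[AgeBinnedSeries]:
    """Read long-format case and population CSVs into AgeBinnedSeries.

    Case schema: cancer_code, sex, age_group, cases. Population schema:
    registry, sex, age_group, person_years (summed over registries).
    Pooled-sex series are built by summing cases and person-years across
    sexes before computing rates.
    """
    cases = pd.read_csv(case_csv)
    pops = pd.read_csv(population_csv)
    for df, cols in ((cases, {"cancer_code", "sex", "age_group", "cases"}),
                     (pops, {"sex", "age_group", "person_years"})):
        missing = cols - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
    cases = cases.copy()
    cases["age_midpoint"] = cases["age_group"].map(age_group_to_midpoint)
    pops = pops.groupby(["sex", "age_group"], as_index=False)["person_years"].sum()
    pops["age_midpoint"] = pops["age_group"].map(age_group_to_midpoint)

    out: list[AgeBinnedSeries] = []
    sexes = sorted(cases["sex"].unique())
    for code, sub in cases.groupby("cancer_code"):
        per_sex = {}
        for sex, ss in sub.groupby("sex"):
            merged = ss.merge(pops[pops["sex"] == sex],
                              on=["sex", "age_midpoint"], how="inner")
            merged = merged.sort_values("age_midpoint")
            per_sex[sex] = merged
            out.append(compute_crude_rates(
                merged["cases"].to_numpy(), merged["person_years"].to_numpy(),
                cancer_code=code, sex=sex,
                bin_midpoints=merged["age_midpoint"].to_numpy()))
        if len(per_sex) == 2 and set(per_sex) == {"male", "female"}:
            m, f = per_sex["male"], per_sex["female"]
            merged = m.merge(f, on="age_midpoint", suffixes=("_m", "_f"))
            out.append(compute_crude_rates(
                (merged["cases_m"] + merged["cases_f"]).to_numpy(),
                (merged["person_years_m"] + merged["person_years_f"]).to_numpy(),
                cancer_code=code, sex="pooled",
                bin_midpoints=merged["age_midpoint"].to_numpy()))
    _ = sexes
    return out


def write_series(series: list[AgeBinnedSeries], path) -> None:
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(path, index=False)


def read_series(path) -> list[AgeBinnedSeries]:
    df = pd.read_csv(path)
    out = []
    for (code, sex), sub in df.groupby(["cancer_code", "sex"], sort=True):
        sub = sub.sort_values("age_midpoint")
        out.append(AgeBinnedSeries(
            cancer_code=code, sex=sex,
            bin_midpoints=sub["age_midpoint"].to_numpy(dtype=float),
            cases=sub["cases"].to_numpy(dtype=float),
            person_years=sub["person_years"].to_numpy(dtype=float),
            rate=sub["rate"].to_numpy(dtype=float),
            rate_se=sub["rate_se"].to_numpy(dtype=float),
            valid=sub["valid"].to_numpy(dtype=bool)))
    return out
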