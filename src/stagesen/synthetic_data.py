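"""Synthetic registry generation and packaged fixture tables.

The simulator emulates the statistical structure of a cross-sectional cancer
registry: 5-year age bins with midpoints 2.5...112.5 years, per-bin person-
year denominators that decline smoothly in old age (with an 85+ tail split by
census-style fractions, so the old-age population-inference path is
exercised), and case counts drawn independently per bin as

    cases ~ Poisson( ASR(t_bin) * person_years_bin )

around the multistage-senescence expectation. It writes exactly the CSV
schemas the rate module reads, so the whole pipeline is testable without any
external download. The packaged fixture tables transcribe the published
per-cancer parameter and driver-catalog tables and are checksum-verified on
load.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import ModelParams, asr_senescence
from .incidence_rates import (AGE_GROUP_LABELS, BIN_MIDPOINTS, OLDAGE_LABELS,
                              OldAgeFractions, compute_crude_rates,
                              infer_oldage_populations)
from .model_fitting import FitConfig, fit_series

#: census-style split of the 85+ population across old-age bins
DEFAULT_OLDAGE_FRACTIONS = {
    "male": OldAgeFractions("male", np.array([0.66, 0.25, 0.07, 0.017, 0.0025, 0.0005])),
    "female": OldAgeFractions("female", np.array([0.60, 0.28, 0.095, 0.022, 0.0027, 0.0003])),
}


def population_template(py_base: float = 1e7, sex: str = "male",
                        fractions: OldAgeFractions | None = None) -> np.ndarray:
    """Per-bin person-years: flat to age 60, Gaussian decline afterwards.

    The 85+ bins are re-split from their aggregate by census-style fractions,
    mirroring how real old-age denominators are inferred rather than observed.
    """
    mids = BIN_MIDPOINTS
    py = np.full(mids.size, float(py_base))
    old = mids > 60
    py[old] = py_base * np.exp(-0.5 * ((mids[old] - 60.0) / 18.0) ** 2)
    fr = fractions or DEFAULT_OLDAGE_FRACTIONS.get(sex,
                                                   DEFAULT_OLDAGE_FRACTIONS["male"])
    tail = mids >= 85
    total_85 = py[tail].sum()
    py[tail] = infer_oldage_populations(total_85, fr)
    return py


@dataclass
class CohortSpec:
    """Truth description of a synthetic registry."""

    truth: dict  # cancer_code -> ModelParams (onset_offset encodes reproductive status)
    person_years: dict = field(default_factory=dict)  # sex -> per-bin PY
    sexes: tuple = ("male", "female")
    seed: int = 0

    def __post_init__(self) -> None:
        for sex in self.sexes:
            self.person_years.setdefault(sex, population_template(sex=sex))
            if np.any(np.asarray(self.person_years[sex]) <= 0):
                raise ValueError("person-years must be positive in every bin")


def expected_cases(params: ModelParams, person_years: np.ndarray) -> np.ndarray:
    """Poisson means per bin: ASR at the bin midpoint times person-years."""
    t = np.maximum(BIN_MIDPOINTS - params.onset_offset, 0.0)
    asr = np.where(t > 0, asr_senescence(np.maximum(t, 1e-12), params), 0.0)
    return asr * np.asarray(person_years, dtype=float)


def simulate_registry(spec: CohortSpec, out_dir: str | Path | None = None):
    """Draw one registry realisation; optionally write cases/population CSVs.

    Returns (cases_df, population_df) in the long schemas the rate reader
    consumes. Counts are independent Poisson per bin, cancer and sex;
    identical seeds give identical output.
    """
    rng = np.random.default_rng(spec.seed)
    case_rows, pop_rows = [], []
    for sex in spec.sexes:
        py = np.asarray(spec.person_years[sex], dtype=float)
        for label, p in zip(AGE_GROUP_LABELS, py):
            pop_rows.append({"registry": "synthetic", "sex": sex,
                             "age_group": label, "person_years": p})
        for code, params in spec.truth.items():
            mu = expected_cases(params, py)
            if np.any(mu > 1e9):
                raise ValueError("expected counts exceed 1e9 per bin")
            counts = rng.poisson(mu)
            for label, c in zip(AGE_GROUP_LABELS, counts):
                case_rows.append({"cancer_code": code, "sex": sex,
                                  "age_group": label, "cases": int(c)})
    cases = pd.DataFrame(case_rows)
    pops = pd.DataFrame(pop_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cases.to_csv(out_dir / "cases.csv", index=False)
        pops.to_csv(out_dir / "population.csv", index=False)
    return cases, pops


# ---------------------------------------------------------------------------
# packaged fixture tables

_DATA = resources.files("stagesen") / "data"


def _load_checked(name: str) -> pd.DataFrame:
    manifest = json.loads((_DATA / "manifest.json").read_text())
    raw = (_DATA / name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if manifest[name] != digest:
        raise RuntimeError(f"packaged fixture {name} failed its checksum")
    return pd.read_csv(_DATA / name)


def published_tables() -> dict[str, pd.DataFrame]:
    """Packaged transcriptions of the published per-cancer tables.

    Returns a dict with keys ``male`` (26 rows), ``female`` (29 rows),
    ``pooled`` (both sexes, non-reproductive cancers only, 24 rows) and
    ``drivers`` (driver-mutation catalog, 27 rows). Files are verified
    against a sha256 manifest before parsing.
    """
    files = {"male": "params_male.csv", "female": "params_female.csv",
             "pooled": "params_pooled.csv", "drivers": "driver_catalog.csv"}
    return {key: _load_checked(fname) for key, fname in files.items()}


# ---------------------------------------------------------------------------
# parameter-recovery experiment

def recovery_experiment(truth_grid, py_levels=(1e7,), replicates: int = 20,
                        seed: int = 0, start_age: float = 50.0) -> pd.DataFrame:
    """Simulate-and-refit experiment over a grid of true parameters.

    ``truth_grid`` is an iterable of (u, k, b) triples. For each cell and
    person-year level, ``replicates`` registries are simulated (single sex,
    flat person-years at the stated level, one cancer), rates computed and
    the model refit from ``start_age``; the returned table holds the
    per-parameter bias of every replicate plus cell-level median bias and
    RMSE. Deterministic under ``seed``.
    """
    rows = []
    for u, k, b in truth_grid:
        truth = ModelParams(k=k, b=b, u_mu=u)
        for py in py_levels:
            person_years = np.full(BIN_MIDPOINTS.size, float(py))
            for rep in range(replicates):
                cell_seed = (seed * 1_000_003 + hash((round(u, 6), round(k, 6),
                             round(b, 6), int(py), rep))) % (2**31)
                rng = np.random.default_rng(cell_seed)
                counts = rng.poisson(expected_cases(truth, person_years))
                series = compute_crude_rates(counts, person_years,
                                             cancer_code="SYN", sex="pooled")
                cfg = FitConfig(start_age=start_age, seed=cell_seed)
                fit = fit_series(series, cfg)
                rows.append({"u_true": u, "k_true": k, "b_true": b, "py": py,
                             "rep": rep,
                             "u_hat": fit.params.u_mu, "k_hat": fit.params.k,
                             "b_hat": fit.params.b,
                             "bias_u": fit.params.u_mu - u,
                             "bias_k": fit.params.k - k,
                             "bias_b": fit.params.b - b})
    df = pd.DataFrame(rows)
    summary = df.groupby(["u_true", "k_true", "b_true", "py"]).agg(
        median_bias_u=("bias_u", "median"),
        median_bias_k=("bias_k", "median"),
        median_bias_b=("bias_b", "median"),
        rmse_u=("bias_u", lambda x: float(np.sqrt(np.mean(np.square(x))))),
        rmse_k=("bias_k", lambda x: float(np.sqrt(np.mean(np.square(x))))),
        rmse_b=("bias_b", lambda x: float(np.sqrt(np.mean(np.square(x))))),
    ).reset_index()
    return df, summary
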