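"""Weighted nonlinear least-squares fit of the multistage-senescence model.

One AgeBinnedSeries is fit by minimising

    sum_i w_i * (rate_i - 1e5 * a * t_i^(k-1) * (1 - b*t_i))^2,
    w_i = 1 / SE_i^2,  t_i = age midpoint - onset offset,

over bins with midpoint >= the configured start age. The amplitude is fit in
log space (a > 0 by construction), k is bounded to (0.5, 20) and b is free in
sign — degenerate series genuinely produce negative b. The objective is
multimodal in (a, k), so the optimiser is restarted from a small ladder of
k guesses around the log-log slope of the data.

Standard errors come from the Jacobian-based covariance of the weighted
residuals; u's standard error follows by the delta method, and parameter
P-values are two-sided Wald t-tests against zero with n - 3 degrees of
freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import digamma

from .core_model import ModelParams, u_from_a, peak_age_argmax, \
    peak_rate, cumulative_probability
from .incidence_rates import PER, AgeBinnedSeries

#: cancers whose time axis starts at puberty (t = age - 15)
REPRODUCTIVE_CODES = frozenset({"PRAD", "TGCT", "BRCA", "CESC", "OV", "UCEC", "UCS"})

#: fitting-window start ages that differ from the default of 50 years
START_AGE_OVERRIDES = {"THCA": 30.0, "CESC": 30.0, "TGCT": 20.0}

K_BOUNDS = (0.5, 20.0)


@dataclass
class FitConfig:
    start_age: float = 50.0
    onset_offset: float = 0.0
    max_peak_age: float = 105.0
    p_exclusion_threshold: float = 0.1
    xtol: float = 1e-12
    ftol: float = 1e-12
    b0: float = 0.01
    k_multistart_offsets: tuple = (-2.0, 0.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.start_age < self.onset_offset:
            raise ValueError("start_age must be >= onset_offset")
        if not 0 < self.p_exclusion_threshold < 1:
            raise ValueError("exclusion threshold must be in (0, 1)")

    @classmethod
    def for_cancer(cls, cancer_code: str, **kw) -> "FitConfig":
        """Default configuration for a cancer code (start-age overrides and
        the reproductive onset offset applied)."""
        kw.setdefault("start_age", START_AGE_OVERRIDES.get(cancer_code, 50.0))
        kw.setdefault("onset_offset",
                      15.0 if cancer_code in REPRODUCTIVE_CODES else 0.0)
        return cls(**kw)


@dataclass
class FitResult:
    cancer_code: str
    sex: str
    params: ModelParams
    se_a: float
    se_k: float
    se_b: float
    se_u: float
    p_u: float
    p_k: float
    rss: float
    n_bins: int
    peak_age: float
    peak_rate: float
    pc: float
    included: bool

    def to_row(self) -> dict:
        return {
            "cancer_code": self.cancer_code,
            "sex": self.sex,
            "u_mu": self.params.u_mu,
            "k": self.params.k,
            "b": self.params.b,
            "a": self.params.a,
            "se_u": self.se_u,
            "se_k": self.se_k,
            "se_b": self.se_b,
            "p_u": self.p_u,
            "p_k": self.p_k,
            "peak_age_model": self.peak_age,
            "peak_rate_model": self.peak_rate,
            "pc_model": self.pc,
            "included": self.included,
            "rss": self.rss,
            "n_bins": self.n_bins,
        }


def _model_rate(t: np.ndarray, log_a: float, k: float, b: float) -> np.ndarray:
    # clamped at zero beyond the support, like the data-generating model:
    # zero-count bins past 1/b carry small substitute SEs, and an untruncated
    # negative tail would dominate the weighted cost there
    with np.errstate(divide="ignore"):
        logt = np.where(t > 0, np.log(np.where(t > 0, t, 1.0)), -np.inf)
    body = np.exp(log_a + (k - 1.0) * logt) * np.maximum(1.0 - b * t, 0.0)
    return PER * np.where((t == 0) & (k > 1), 0.0, body)


def _initial_guesses(t, rate, cfg: FitConfig):
    pos = rate > 0
    if pos.sum() >= 3:
        slope = np.polyfit(np.log(t[pos]), np.log(rate[pos]), 1)[0]
        k0 = float(np.clip(slope + 1.0, *K_BOUNDS))
    else:
        k0 = 5.0
    guesses = []
    i_max = int(np.argmax(rate))
    t_max = t[i_max]
    for dk in cfg.k_multistart_offsets:
        k_start = float(np.clip(k0 + dk, K_BOUNDS[0] + 1e-6, K_BOUNDS[1] - 1e-6))
        sen = max(1.0 - cfg.b0 * t_max, 0.05)
        a0 = max(rate[i_max], 1e-10) / PER / (t_max ** (k_start - 1.0) * sen)
        guesses.append((math.log(a0), k_start, cfg.b0))
    return guesses


def fit_series(series: AgeBinnedSeries, config: FitConfig | None = None) -> FitResult:
    """Fit one incidence series; returns parameters, errors and derived stats."""
    cfg = config or FitConfig.for_cancer(series.cancer_code)
    mask = series.valid & (series.bin_midpoints >= cfg.start_age)
    if mask.sum() < 6:
        raise ValueError("need at least 6 valid bins at or above start_age")
    t = series.bin_midpoints[mask] - cfg.onset_offset
    rate = series.rate[mask]
    se = series.rate_se[mask]
    if np.all(rate == 0):
        raise ValueError("degenerate series: all rates zero in window")

    def residuals(x):
        return (rate - _model_rate(t, *x)) / se

    best = None
    for x0 in _initial_guesses(t, rate, cfg):
        try:
            sol = optimize.least_squares(
                residuals, x0,
                bounds=([-np.inf, K_BOUNDS[0], -np.inf],
                        [np.inf, K_BOUNDS[1], np.inf]),
                xtol=cfg.xtol, ftol=cfg.ftol, gtol=1e-12, method="trf")
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError("model fit did not converge from any start")

    log_a, k, b = best.x
    a = math.exp(log_a)
    n, p = t.size, 3
    dof = max(n - p, 1)
    s2 = 2.0 * best.cost / dof
    JTJ = best.jac.T @ best.jac
    try:
        cov = s2 * np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(JTJ)

    u = u_from_a(a, k)
    # delta method: gradient of u w.r.t. (log a, k, b)
    g = np.array([u / k, u * (digamma(k) - math.log(u)) / k, 0.0])
    var_u = float(g @ cov @ g)
    se_u = math.sqrt(max(var_u, 0.0))
    se_loga, se_k, se_b = np.sqrt(np.maximum(np.diag(cov), 0.0))
    se_a = a * se_loga

    def wald_p(est, sd):
        if sd == 0:
            return 0.0
        return 2.0 * stats.t.sf(abs(est / sd), dof)

    p_u = wald_p(u, se_u)
    p_k = wald_p(k, se_k)

    params = ModelParams(k=k, b=b, a=a, onset_offset=cfg.onset_offset)
    if b > 0 and k > 1:
        pk_age = peak_age_argmax(params) + cfg.onset_offset
        pk_rate = peak_rate(params)
    else:
        pk_age, pk_rate = math.nan, math.nan
    if b > 0:
        pc = cumulative_probability(params)
    else:
        pc = math.nan
    included = (p_u <= cfg.p_exclusion_threshold) and (p_k <= cfg.p_exclusion_threshold)

    return FitResult(
        cancer_code=series.cancer_code, sex=series.sex, params=params,
        se_a=se_a, se_k=float(se_k), se_b=float(se_b), se_u=se_u,
        p_u=p_u, p_k=p_k, rss=2.0 * best.cost, n_bins=n,
        peak_age=pk_age, peak_rate=pk_rate, pc=pc, included=included)


def apply_inclusion_rules(results, *, use_coad_read_split: bool = True):
    """Filter fit results by the parameter-significance rule.

    Results with P(u) or P(k) above the threshold already carry
    ``included=False``; this separates kept from excluded and optionally drops
    the combined colorectal series (COADREAD) when COAD and READ enter
    individually, so colorectal cases are not double counted.
    Returns (kept, exclusion_log).
    """
    kept, log = [], []
    for r in results:
        if not r.included:
            log.append((r.cancer_code, r.sex, f"P(u)={r.p_u:.3g}, P(k)={r.p_k:.3g}"))
            continue
        if use_coad_read_split and r.cancer_code == "COADREAD":
            log.append((r.cancer_code, r.sex, "COAD and READ included separately"))
            continue
        kept.append(r)
    return kept, log


def results_to_frame(results) -> "pd.DataFrame":
    import pandas as pd
    return pd.DataFrame([r.to_row() for r in results])
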