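"""Closed-form equations of the multistage-senescence model.

The age-specific incidence rate (ASR) of an adult cancer is modelled as an
Armitage-Doll power law in age, damped by a linear senescence tumor-suppression
term:

    ASR(t) = u^k / Gamma(k) * t^(k-1) * (1 - b*t),    0 <= t <= 1/b

where ``k`` is the (continuous) number of carcinogenic stages, ``u`` the
per-year stage-transition rate (geometric mean across stages), ``b`` the
senescence tumor suppressor (1/year), and ``t`` age for non-reproductive
cancers or age minus 15 years for cancers of reproductive organs.

All power/gamma arithmetic is carried out in log space with a single
exponentiation at the end: u^k with u << 1 and k near 10 underflows in naive
arithmetic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.special import gammaln

__all__ = [
    "ModelParams",
    "TwoVariableConstants",
    "asr_power_law",
    "asr_senescence",
    "asr_factors",
    "asr_two_variable",
    "peak_age_closed_form",
    "peak_age_argmax",
    "cumulative_probability",
    "senescence_reduction",
    "u_from_a",
    "a_from_u",
    "lifetime_risk_any",
]


def a_from_u(u: float, k: float) -> float:
    """Amplitude a = u^k / Gamma(k) of the power-law term."""
    if u <= 0 or k <= 0:
        raise ValueError("u and k must be positive")
    return math.exp(k * math.log(u) - gammaln(k))


def u_from_a(a: float, k: float) -> float:
    """Geometric-mean stage-transition rate u = (a * Gamma(k))^(1/k)."""
    if a <= 0 or k <= 0:
        raise ValueError("a and k must be positive")
    return math.exp((math.log(a) + gammaln(k)) / k)


@dataclass
class ModelParams:
    """Fitted description of one cancer type.

    Parameters
    ----------
    a
        Multiplicative amplitude of the power law (per year^k). If omitted it
        is derived from ``u_mu`` via a = u^k/Gamma(k), and vice versa.
    u_mu
        Geometric-mean stage-transition rate, 1/year.
    k
        Number of carcinogenic stages; positive, not necessarily integer.
    b
        Senescence tumor suppressor, 1/year. May be <= 0 for degenerate fits,
        in which case the model has no finite support and no lifetime risk.
    onset_offset
        Years subtracted from age before evaluating t: 0 for non-reproductive
        cancers, 15 for reproductive ones.
    """

    k: float
    b: float
    a: float | None = None
    u_mu: float | None = None
    onset_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.onset_offset not in (0, 15):
            raise ValueError("onset_offset must be 0 or 15")
        if self.a is None and self.u_mu is None:
            raise ValueError("one of a, u_mu is required")
        if self.a is None:
            self.a = a_from_u(self.u_mu, self.k)
        elif self.u_mu is None:
            if self.a < 0:
                raise ValueError("a must be non-negative")
            self.u_mu = u_from_a(self.a, self.k) if self.a > 0 else 0.0
        else:
            if not math.isclose(self.a, a_from_u(self.u_mu, self.k), rel_tol=1e-10):
                raise ValueError("a and u_mu are inconsistent: a != u^k/Gamma(k)")

    @property
    def support_end(self) -> float:
        """Age t at which modelled incidence returns to zero (1/b)."""
        return 1.0 / self.b if self.b > 0 else math.inf


@dataclass(frozen=True)
class TwoVariableConstants:
    """Constants of the two-variable (age, stage) model.

    ``b`` is the pooled-sex mean senescence suppressor of non-reproductive
    cancers; ``c`` and ``d`` are the slope and negated intercept of the
    cross-cancer linear regression of u on k, so that u = c*k - d.
    """

    b: float = 0.0099
    c: float = 0.0046
    d: float = 0.0087

    def u_of_k(self, k: float) -> float:
        u = self.c * k - self.d
        if u <= 0:
            raise ValueError(f"c*k - d = {u:.3g} <= 0: model undefined at k={k}")
        return u


def _validate_tuk(t, u: float, k: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not (np.all(np.isfinite(t)) and math.isfinite(u) and math.isfinite(k)):
        raise ValueError("non-finite input")
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if u <= 0 or k <= 0:
        raise ValueError("u and k must be positive")
    if k < 1 and np.any(t == 0):
        raise ValueError("t=0 divergent for k<1")
    return t


def asr_power_law(t, u: float, k: float):
    """Armitage-Doll rate u^k/Gamma(k) * t^(k-1), per person-year."""
    t = _validate_tuk(t, u, k)
    with np.errstate(divide="ignore"):
        logt = np.where(t > 0, np.log(np.where(t > 0, t, 1.0)), -np.inf)
    log_rate = k * math.log(u) - gammaln(k) + (k - 1) * logt
    out = np.exp(log_rate)
    if k > 1:
        out = np.where(t == 0, 0.0, out)
    return out if out.ndim else float(out)

def asr_senescence(t, params: ModelParams):
    """Multistage-senescence rate a * t^(k-1) * (1 - b*t), per person-year.

    Beyond the support (t > 1/b for b > 0) the rate is clamped to 0: the
    (1 - b*t) factor is a suppression term and negative hazards are
    meaningless.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    k, b, a = params.k, params.b, params.a
    with np.errstate(divide="ignore", invalid="ignore"):
        logt = np.where(t > 0, np.log(np.where(t > 0, t, 1.0)), -np.inf)
        body = a * np.exp((k - 1) * logt) * (1.0 - b * t)
    if k > 1:
        body = np.where(t == 0, 0.0, body)
    elif k < 1 and np.any(t == 0):
        raise ValueError("t=0 divergent for k<1")
    out = np.where(body < 0, 0.0, body)
    return out if out.ndim else float(out)


def asr_factors(t: float, params: ModelParams) -> tuple[float, float, float]:
    """Decompose the rate into A*B*C.

    A = u^k/Gamma(k) is the age-independent stage-transition-rate tumor
    suppression term, B = t^(k-1) the power-law growth term, and
    C = (1 - b*t) the linear senescence tumor suppression term (unity at
    birth).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    A = params.a
    B = float(t) ** (params.k - 1.0)
    C = 1.0 - params.b * t
    return A, B, C


def asr_two_variable(t, k: float, consts: TwoVariableConstants = TwoVariableConstants(),
                     b: float | None = None):
    """Rate of the two-variable (age, stage) model: u replaced by c*k - d.

    ``b`` overrides the pooled default when a cancer-specific senescence
    suppressor is wanted (the published per-cancer tables combine u = c*k - d
    with each cancer's own fitted b).
    """
    u = consts.u_of_k(k)
    params = ModelParams(k=k, b=consts.b if b is None else b, u_mu=u)
    return asr_senescence(t, params)


def peak_age_closed_form(k: float, b: float) -> float:
    """Closed-form peak age k/(b*(k+1)) used for the illustrative stage ladder."""
    if b <= 0:
        raise ValueError("no finite peak for b <= 0")
    if k <= 0:
        raise ValueError("k must be positive")
    return k / (b * (k + 1.0))


def peak_age_argmax(params: ModelParams) -> float:
    """Analytic maximizer (k-1)/(b*k) of t^(k-1)*(1-b*t).

    This is the age at which the modelled incidence rate itself peaks; it is
    the quantity tabulated as the model-fitted age of peak incidence.
    """
    if params.b <= 0:
        raise ValueError("no finite peak for b <= 0")
    if params.k <= 1:
        raise ValueError("no interior maximum for k <= 1")
    return (params.k - 1.0) / (params.b * params.k)


def peak_rate(params: ModelParams, per: float = 1e5) -> float:
    """Modelled incidence rate at its peak, per `per` person-years."""
    return per * asr_senescence(peak_age_argmax(params), params)


def cumulative_probability(params: ModelParams) -> float:
    """Lifetime cumulative probability Pc = integral of ASR over [0, 1/b].

    Closed form a * b^(-k) * (1/k - 1/(k+1)). For b <= 0 the integral does
    not converge on a finite support; NaN is returned with a warning
    (mirroring degenerate published fits).
    """
    k, b, u = params.k, params.b, params.u_mu
    if b <= 0:
        warnings.warn("cumulative probability undefined for b <= 0; returning NaN",
                      RuntimeWarning, stacklevel=2)
        return math.nan
    if u == 0:
        return 0.0
    # log space: (u/b)^k overflows well inside the fitted k range otherwise
    log_pc = k * (math.log(u) - math.log(b)) - gammaln(k) \
        - math.log(k) - math.log(k + 1.0)
    return math.exp(log_pc) if log_pc < 700 else math.inf


def senescence_reduction(k: float, b: float = 0.0099) -> float:
    """Fractional reduction in lifetime risk attributable to senescence.

    Compares the cumulative probability over [0, 1/b] with and without the
    (1 - b*t) factor, amplitude and integration limit held fixed. Both
    integrals are evaluated and the analytic identity k/(k+1) is verified
    against their ratio.
    """
    if k <= 0 or b <= 0:
        raise ValueError("k and b must be positive")
    u = 0.02  # cancels in the ratio
    # both integrals in log space: with the (1-bt) factor the cumulative
    # probability over [0, 1/b] is (u/b)^k/Gamma(k) / (k(k+1)); without it,
    # amplitude and limit fixed, it is (u/b)^k/Gamma(k) / k
    log_common = k * (math.log(u) - math.log(b)) - gammaln(k)
    log_with = log_common - math.log(k) - math.log(k + 1.0)
    log_without = log_common - math.log(k)
    reduction = 1.0 - math.exp(log_with - log_without)
    analytic = k / (k + 1.0)
    if not math.isclose(reduction, analytic, rel_tol=1e-10):
        raise AssertionError("integral ratio disagrees with k/(k+1)")
    return reduction


def cumulative_probability_quadrature(params: ModelParams) -> float:
    """Adaptive-quadrature evaluation of Pc; oracle for the closed form."""
    if params.b <= 0:
        return math.nan
    val, _ = integrate.quad(lambda t: asr_senescence(t, params), 0.0,
                            params.support_end, limit=200)
    return val


def lifetime_risk_any(pcs) -> float:
    """Probability of at least one diagnosis among independent cancer risks.

    Independence complement rule 1 - prod(1 - Pc_i); monotone non-decreasing
    in every argument and never below max(Pc_i).
    """
    pcs = np.asarray(list(pcs), dtype=float)
    if pcs.size == 0:
        return 0.0
    if np.any(pcs < 0) or np.any(pcs >= 1):
        raise ValueError("each Pc must lie in [0, 1)")
    return 1.0 - float(np.prod(1.0 - pcs))
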