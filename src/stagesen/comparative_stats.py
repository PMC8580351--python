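"""Cross-cancer comparisons of fitted multistage-senescence parameters.

Every published summary statistic depends on an exact inclusion set (which
cancers, which sexes, whether the combined colorectal series stands in for
colon + rectum), so the row-selection rules are encoded as named subsets
rather than ad hoc boolean masks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model_fitting import REPRODUCTIVE_CODES

#: cancers the 2010-2013 analysis drops for failing the P > 0.1 rule
EXCLUDED_2010 = frozenset({"LGG", "PCPG"})
EXCLUDED_2010_FEMALE = frozenset({"LGG", "PCPG", "READ"})


def subset(table: pd.DataFrame, name: str) -> pd.DataFrame:
    """Named, reproducible row-selection rules for a parameter table.

    Available names:

    - ``nonrepro``: non-reproductive rows only
    - ``nonrepro_n21``: non-reproductive minus LGG/PCPG/COADREAD (READ kept)
    - ``nonrepro_n20``: as n21 but READ also dropped (paired-comparison set)
    - ``analysis``: minus LGG/PCPG/COADREAD (reproductive rows kept)
    - ``reproductive``: reproductive rows only
    - ``risk``: rows entering the any-cancer lifetime risk (minus COADREAD,
      minus the sex-specific published exclusion list)
    """
    t = table
    nonrepro = ~t["cancer_code"].isin(REPRODUCTIVE_CODES)
    drop3 = ~t["cancer_code"].isin(EXCLUDED_2010 | {"COADREAD"})
    if name == "nonrepro":
        return t[nonrepro]
    if name == "nonrepro_n21":
        return t[nonrepro & drop3]
    if name == "nonrepro_n20":
        return t[nonrepro & drop3 & (t["cancer_code"] != "READ")]
    if name == "analysis":
        return t[drop3]
    if name == "reproductive":
        return t[~nonrepro]
    if name == "risk":
        sexes = set(t["sex"].unique())
        excl = EXCLUDED_2010_FEMALE if sexes == {"female"} else EXCLUDED_2010
        return t[~t["cancer_code"].isin(excl | {"COADREAD"})]
    raise KeyError(f"unknown subset {name!r}")


def summarize_b(table: pd.DataFrame, subset_name: str | None = None,
                column: str = "b") -> tuple[float, float, int]:
    """Mean, sample SD (n-1 denominator) and n of a parameter column."""
    t = subset(table, subset_name) if subset_name else table
    vals = t[column].dropna()
    if len(vals) < 2:
        raise ValueError("subset resolves fewer than 2 rows")
    return float(vals.mean()), float(vals.std(ddof=1)), int(len(vals))


def paired_t(table_m: pd.DataFrame, table_f: pd.DataFrame, parameter: str,
             correction: bool = False, n_family: int = 1):
    """Classical paired t-test on per-cancer male-female differences.

    With ``correction`` the returned P is the Holm-adjusted member of a
    family of ``n_family`` tests (callers adjusting a whole family at once
    should use :func:`holm_adjust`).
    """
    m = table_m.set_index("cancer_code")[parameter]
    f = table_f.set_index("cancer_code")[parameter]
    common = sorted(set(m.index) & set(f.index))
    if not common:
        raise ValueError("no matched cancer keys")
    diffs = (m[common] - f[common]).to_numpy()
    if np.allclose(diffs, 0.0):
        return 0.0, 1.0, len(common)  # no variation, nothing to test
    res = stats.ttest_rel(m[common], f[common])
    p = float(res.pvalue)
    if correction:
        p = min(1.0, p * n_family)  # Holm for a single reported member
    return float(res.statistic), p, len(common)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted P-values (never smaller than the raw P)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="holm")[1]


def welch_t(group_a, group_b):
    """Welch unequal-variance t-test with Satterthwaite degrees of freedom."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def rank_corr(x, y):
    """Spearman rank correlation (ties mid-ranked) with t-approximation P."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def linear_corr(x, y):
    """Pearson product-moment correlation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def regress_u_on_k(table: pd.DataFrame, weights=None):
    """OLS of the stage-transition rate u on stage count k.

    Returns the two-variable-model constants (c, d) as the slope and the
    negated intercept, plus the slope P-value and the full statsmodels fit.
    The regression is unweighted by default, matching the published house
    style.
    """
    t = table.dropna(subset=["u_mu", "k"])
    if len(t) < 3:
        raise ValueError("need at least 3 rows")
    X = sm.add_constant(t["k"].to_numpy())
    model = sm.WLS(t["u_mu"].to_numpy(), X, weights=weights) if weights is not None \
        else sm.OLS(t["u_mu"].to_numpy(), X)
    fit = model.fit()
    c = float(fit.params[1])
    d = float(-fit.params[0])
    return c, d, float(fit.pvalues[1]), fit


def compare_slopes(x_a, y_a, x_b, y_b):
    """ANCOVA comparison of two simple regressions.

    F-tests the group-by-slope interaction for a common slope, then the
    group main effect (common intercept) given a shared slope. Returns
    (P_slope, P_intercept).
    """
    x = np.concatenate([np.asarray(x_a, float), np.asarray(x_b, float)])
    y = np.concatenate([np.asarray(y_a, float), np.asarray(y_b, float)])
    g = np.concatenate([np.zeros(len(np.atleast_1d(x_a))),
                        np.ones(len(np.atleast_1d(x_b)))])
    X_full = sm.add_constant(np.column_stack([x, g, x * g]))
    full = sm.OLS(y, X_full).fit()
    X_shared = sm.add_constant(np.column_stack([x, g]))
    shared = sm.OLS(y, X_shared).fit()
    X_common = sm.add_constant(x)
    common = sm.OLS(y, X_common).fit()
    p_slope = float(full.compare_f_test(shared)[1])
    p_intercept = float(shared.compare_f_test(common)[1])
    return p_slope, p_intercept


def extrinsic_association(ratio_table: pd.DataFrame,
                          extrinsic_table: pd.DataFrame):
    """Rank correlation between the observed/two-variable lifetime-risk ratio
    and a user-supplied extrinsic/intrinsic risk-ratio table.

    Both tables are keyed by ``cancer_code``; the extrinsic table must carry
    an ``extrinsic_ratio`` column (from published estimates, not shipped).
    """
    merged = ratio_table.merge(extrinsic_table, on="cancer_code")
    merged = merged.dropna(subset=["ratio_seer_twovar", "extrinsic_ratio"])
    return rank_corr(merged["ratio_seer_twovar"], merged["extrinsic_ratio"])
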