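"""Association statistics: Spearman + Benjamini-Hochberg, EDSS subgroups.

Each oculomotor parameter is correlated (Spearman, pairwise-complete)
with each clinical outcome; false-discovery control is applied with the
Benjamini-Hochberg step-up procedure within each outcome's family of
parameters (a global-family option is provided, since the published
correction scope is ambiguous).  The high/low-EDSS contrast z-scores
every parameter against the whole cohort, splits at EDSS <= 4 vs
>= 4.5, and compares subgroups with two-sided Mann-Whitney U tests.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05
EDSS_SPLIT = 4.0  # low: EDSS <= 4.0; high: EDSS >= 4.5
EXACT_SPEARMAN_MAX_N = 9
EXACT_MANNWHITNEY_MAX_N = 20


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone minimum)."""
    p = np.asarray(pvalues, dtype=float)
    ok = np.isfinite(p)
    adj = np.full_like(p, np.nan)
    if ok.sum():
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return adj


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact p by full enumeration of rank pairings (no ties)."""
    n = len(x)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    denom = np.sqrt(np.sum((rx - rx.mean()) ** 2)
                    * np.sum((ry - ry.mean()) ** 2))
    count = 0
    total = math.factorial(n)
    for perm in itertools.permutations(range(n)):
        r = np.dot(rx[list(perm)] - rx.mean(), ry - ry.mean()) / denom
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    return count / total


def spearman(x, y, exact_max_n: int = EXACT_SPEARMAN_MAX_N) \
        -> tuple[float, float, int]:
    """(rho, two-sided p, n) over pairwise-complete observations.

    Average ranks for ties; exact permutation p for small tie-free
    samples, otherwise the t-approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan"), n
    rho, p = sps.spearmanr(x, y)
    has_ties = (len(np.unique(x)) < n) or (len(np.unique(y)) < n)
    if n <= exact_max_n and not has_ties:
        p = _exact_spearman_p(x, y, rho)
    return float(rho), float(p), n


def spearman_with_fdr(profiles: pd.DataFrame, outcomes: pd.DataFrame,
                      alpha: float = DEFAULT_ALPHA,
                      family: str = "per_outcome") -> pd.DataFrame:
    """Parameter x outcome Spearman grid with BH-adjusted p-values.

    ``family`` is the BH correction scope: "per_outcome" corrects the
    set of parameters tested against one outcome; "global" corrects all
    parameter x outcome tests jointly.
    """
    if family not in ("per_outcome", "global"):
        raise ValueError("family must be 'per_outcome' or 'global'")
    rows = []
    for out_name in outcomes.columns:
        for par_name in profiles.columns:
            rho, p, n = spearman(profiles[par_name].values,
                                 outcomes[out_name].values)
            rows.append({"parameter": par_name, "outcome": out_name,
                         "rho": rho, "n": n, "p_raw": p})
    res = pd.DataFrame(rows)
    res["p_adj"] = np.nan
    if family == "per_outcome":
        for out_name, grp in res.groupby("outcome"):
            res.loc[grp.index, "p_adj"] = bh_adjust(grp["p_raw"].values)
    else:
        res["p_adj"] = bh_adjust(res["p_raw"].values)
    res["significant"] = res["p_adj"] < alpha
    res.attrs["bh_family"] = family
    res.attrs["alpha"] = alpha
    return res


def mannwhitney(low, high, exact_max_n: int = EXACT_MANNWHITNEY_MAX_N) \
        -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small tie-free samples,
    otherwise normal approximation with tie correction."""
    low = np.asarray(low, float)
    high = np.asarray(high, float)
    low = low[np.isfinite(low)]
    high = high[np.isfinite(high)]
    if len(low) == 0 or len(high) == 0:
        return float("nan"), float("nan")
    has_ties = len(np.unique(np.concatenate([low, high]))) < len(low) + len(high)
    method = "exact" if (min(len(low), len(high)) < exact_max_n
                         and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(low, high, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_edss_subgroups(profiles: pd.DataFrame, edss: pd.Series,
                           alpha: float = DEFAULT_ALPHA,
                           split: float = EDSS_SPLIT) -> pd.DataFrame:
    """High-vs-low EDSS contrast of whole-cohort z-scored parameters.

    Returns the radar-table data: per parameter, subgroup mean z, U,
    raw and BH-adjusted p, and subgroup sizes.  EDSS == split is low;
    the next half-step up is high.
    """
    edss = pd.Series(np.asarray(edss, float), index=profiles.index)
    low_mask = edss <= split
    high_mask = edss >= split + 0.5
    if not low_mask.any() or not high_mask.any():
        raise ValueError(
            f"empty EDSS subgroup at cutoff <= {split} vs >= {split + 0.5}")
    rows = []
    for name in profiles.columns:
        v = profiles[name].astype(float)
        sd = v.std(ddof=1, skipna=True)
        z = (v - v.mean(skipna=True)) / sd if sd > 0 else v * np.nan
        zl, zh = z[low_mask], z[high_mask]
        u, p = mannwhitney(zl.dropna().values, zh.dropna().values)
        rows.append({"parameter": name,
                     "mean_z_low": float(zl.mean(skipna=True)),
                     "mean_z_high": float(zh.mean(skipna=True)),
                     "u_statistic": u, "p_raw": p,
                     "n_low": int(zl.notna().sum()),
                     "n_high": int(zh.notna().sum())})
    res = pd.DataFrame(rows)
    res["p_adj"] = bh_adjust(res["p_raw"].values)
    res["significant"] = res["p_adj"] < alpha
    return res
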