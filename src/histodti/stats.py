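"""Estimation statistics for the group comparisons.

Effect sizes are Cohen's d (treated minus control, pooled-SD standardised)
with bias-corrected and accelerated (BCa) bootstrap confidence intervals;
hypothesis tests are studentised (Welch-t) two-sided permutation tests
(default 100,000 permutations, exhaustive when the group sizes permit);
multiplicity is handled with Benjamini-Hochberg step-up FDR within each
reporting family.  Reported CIs are left uncorrected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = [
    "EFFECT_SIZE_BANDS", "EffectSizeResult", "cohens_d", "bca_ci",
    "permutation_t_test", "PermutationResult", "bh_fdr", "effect_size_band",
    "effect_size_table",
]

#: conventional |d| thresholds
EFFECT_SIZE_BANDS = {"large": 0.8, "medium": 0.5, "small": 0.2}


@dataclass
class EffectSizeResult:
    parameter: str
    region: str
    d: float
    ci_low: float
    ci_high: float
    p: float
    q: float
    n_control: int
    n_treated: int
    band: str


def _as_1d(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0 or not np.all(np.isfinite(arr)):
        raise ValueError("inputs must be non-empty finite arrays")
    return arr


def cohens_d(control, treated) -> float:
    """Pooled-SD standardised mean difference, treated minus control."""
    c, t = _as_1d(control), _as_1d(treated)
    n1, n2 = len(c), len(t)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    s_pooled = math.sqrt(((n1 - 1) * c.var(ddof=1) + (n2 - 1) * t.var(ddof=1))
                         / (n1 + n2 - 2))
    if s_pooled == 0:
        raise ValueError("zero pooled SD: effect size undefined")
    return float((t.mean() - c.mean()) / s_pooled)


def _cohens_d_matrix(c: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Row-wise Cohen's d for (B, n1) control and (B, n2) treated samples."""
    n1, n2 = c.shape[1], t.shape[1]
    v1 = c.var(axis=1, ddof=1)
    v2 = t.var(axis=1, ddof=1)
    sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        return (t.mean(axis=1) - c.mean(axis=1)) / sp


def _bca_bounds(theta_hat: float, boot: np.ndarray, jack: np.ndarray,
                alpha: float) -> tuple[float, float]:
    """BCa percentile bounds from bootstrap replicates and jackknife values."""
    boot = boot[np.isfinite(boot)]
    if boot.size == 0 or np.allclose(boot, boot[0]):
        warnings.warn("degenerate bootstrap distribution; returning point interval")
        return theta_hat, theta_hat
    # bias correction from the fraction of replicates below the estimate
    prop = (np.sum(boot < theta_hat) + 0.5 * np.sum(boot == theta_hat)) / boot.size
    prop = min(max(prop, 1.0 / (boot.size + 1)), 1 - 1.0 / (boot.size + 1))
    z0 = ndtri(prop)
    # acceleration from jackknife skewness
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
    a = num / den if den > 0 else 0.0
    z_alpha = ndtri([alpha / 2.0, 1.0 - alpha / 2.0])
    adj = ndtr(z0 + (z0 + z_alpha) / (1.0 - a * (z0 + z_alpha)))
    lo, hi = np.quantile(boot, adj)
    return float(lo), float(hi)


def bca_ci(control, treated, statistic=cohens_d, n_boot: int = 5000,
           alpha: float = 0.05, seed: int | None = None) -> tuple[float, float]:
    """BCa bootstrap CI for a two-sample statistic (groups resampled independently)."""
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000 for a stable BCa interval")
    c, t = _as_1d(control), _as_1d(treated)
    rng = np.random.default_rng(seed)
    theta_hat = statistic(c, t)

    if statistic is cohens_d:
        ci = rng.integers(0, len(c), size=(n_boot, len(c)))
        ti = rng.integers(0, len(t), size=(n_boot, len(t)))
        boot = _cohens_d_matrix(c[ci], t[ti])
    else:
        boot = np.array([
            statistic(c[rng.integers(0, len(c), len(c))],
                      t[rng.integers(0, len(t), len(t))])
            for _ in range(n_boot)
        ])

    # jackknife over every observation (both groups)
    jack = []
    for i in range(len(c)):
        if len(c) > 2:
            jack.append(statistic(np.delete(c, i), t))
    for i in range(len(t)):
        if len(t) > 2:
            jack.append(statistic(c, np.delete(t, i)))
    jack = np.asarray(jack) if jack else np.array([theta_hat])

    return _bca_bounds(theta_hat, boot, jack, alpha)


def _welch_t(c: np.ndarray, t: np.ndarray) -> float:
    v1, v2 = c.var(ddof=1), t.var(ddof=1)
    se = math.sqrt(v1 / len(c) + v2 / len(t))
    if se == 0:
        return 0.0 if t.mean() == c.mean() else math.inf
    return (t.mean() - c.mean()) / se


@dataclass
class PermutationResult:
    p: float        # add-one corrected (sampled) or exact (exhaustive)
    p_raw: float    # raw proportion without the add-one correction
    t_obs: float
    n_perm: int
    exhaustive: bool


#: enumerate all label splits when their number is at most this
_EXHAUSTIVE_LIMIT = 200_000


def permutation_t_test(control, treated, n_perm: int = 100_000,
                       seed: int | None = None, exhaustive: bool | None = None,
                       return_details: bool = False):
    """Two-sided permutation test on the Welch t statistic.

    With ``exhaustive=None`` all ``C(n1+n2, n1)`` relabelings are enumerated
    whenever that count is small enough; otherwise ``n_perm`` random
    relabelings are sampled and the add-one convention
    ``p = (#{|t*| >= |t_obs|} + 1) / (n_perm + 1)`` applies.
    """
    c, t = _as_1d(control), _as_1d(treated)
    n1, n2 = len(c), len(t)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([c, t])
    if np.allclose(pooled, pooled[0]):
        res = PermutationResult(p=1.0, p_raw=1.0, t_obs=0.0, n_perm=0, exhaustive=True)
        return res if return_details else res.p

    t_obs = abs(_welch_t(c, t))
    n = n1 + n2
    n_splits = math.comb(n, n1)
    if exhaustive is None:
        exhaustive = n_splits <= min(_EXHAUSTIVE_LIMIT, n_perm)

    if exhaustive:
        count = 0
        idx_all = frozenset(range(n))
        for combo in combinations(range(n), n1):
            ci = np.fromiter(combo, int, n1)
            ti = np.fromiter(idx_all.difference(combo), int, n2)
            if abs(_welch_t(pooled[ci], pooled[ti])) >= t_obs - 1e-12:
                count += 1
        res = PermutationResult(p=count / n_splits, p_raw=count / n_splits,
                                t_obs=t_obs, n_perm=n_splits, exhaustive=True)
    else:
        rng = np.random.default_rng(seed)
        count = 0
        batch = 20_000
        done = 0
        while done < n_perm:
            b = min(batch, n_perm - done)
            perm = rng.permuted(np.broadcast_to(np.arange(n), (b, n)).copy(), axis=1)
            vals = pooled[perm]
            cg, tg = vals[:, :n1], vals[:, n1:]
            with np.errstate(divide="ignore", invalid="ignore"):
                se = np.sqrt(cg.var(axis=1, ddof=1) / n1 + tg.var(axis=1, ddof=1) / n2)
                tt = np.abs((tg.mean(axis=1) - cg.mean(axis=1)) / se)
            tt[np.isnan(tt)] = 0.0
            count += int(np.sum(tt >= t_obs - 1e-12))
            done += b
        res = PermutationResult(p=(count + 1) / (n_perm + 1), p_raw=count / n_perm,
                                t_obs=t_obs, n_perm=n_perm, exhaustive=False)
    return res if return_details else res.p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def effect_size_band(d: float) -> str:
    ad = abs(d)
    if ad >= EFFECT_SIZE_BANDS["large"]:
        return "large"
    if ad >= EFFECT_SIZE_BANDS["medium"]:
        return "medium"
    if ad >= EFFECT_SIZE_BANDS["small"]:
        return "small"
    return "negligible"


def effect_size_table(table: pd.DataFrame, parameters, *,
                      group_col: str = "group", region_col: str = "region",
                      control_label: str = "C", treated_label: str = "SE",
                      n_boot: int = 5000, n_perm: int = 100_000,
                      seed: int | None = None) -> pd.DataFrame:
    """Per (parameter, region) effect sizes with BH-FDR within the family.

    All treated-group labels other than ``control_label`` are pooled into
    one group when ``treated_label`` is absent from the table (e.g. two
    induction models analysed as a single status-epilepticus group).
    """
    rng = np.random.default_rng(seed)
    groups = set(table[group_col])
    if treated_label not in groups:
        treated_sel = table[group_col] != control_label
    else:
        treated_sel = table[group_col] == treated_label

    rows = []
    for param in parameters:
        for region in pd.unique(table[region_col]):
            sub = table[table[region_col] == region]
            c = sub.loc[sub[group_col] == control_label, param].to_numpy(float)
            t = sub.loc[treated_sel.loc[sub.index], param].to_numpy(float)
            d = cohens_d(c, t)
            lo, hi = bca_ci(c, t, n_boot=n_boot, seed=int(rng.integers(2**31)))
            p = permutation_t_test(c, t, n_perm=n_perm, seed=int(rng.integers(2**31)))
            rows.append(dict(parameter=param, region=region, d=d, ci_low=lo,
                             ci_high=hi, p=p, n_control=len(c), n_treated=len(t),
                             band=effect_size_band(d)))
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out[["parameter", "region", "d", "ci_low", "ci_high", "p", "q",
                "n_control", "n_treated", "band"]]
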