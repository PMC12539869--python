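"""Permutation-based statistical layer for group comparisons.

Every test reports a classical (distributional) p-value alongside a
permutation p-value computed with the add-one estimator

    p_perm = (1 + #{T_perm >= T_obs}) / (1 + n_perm)

so permutation p-values are never exactly zero and are reproducible
bit-for-bit given (data, n_perm, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DomainError

__all__ = [
    "PermTestResult",
    "LinRegResult",
    "perm_anova_oneway",
    "tukey_posthoc",
    "perm_linreg",
    "lilliefors",
    "levene",
    "summarize_groups",
    "percent_change",
    "round_to_nearest_ten",
]


@dataclass(frozen=True)
class PermTestResult:
    statistic_name: str
    observed: float
    p_perm: float
    n_perm: int
    seed: int | None
    p_classical: float
    extras: dict = field(default_factory=dict)


@dataclass(frozen=True)
class LinRegResult:
    slope: float
    intercept: float
    t_stat: float
    p_t: float
    r2: float
    r2_adj: float
    f_stat: float
    p_classical: float
    p_perm: float
    n_perm: int
    seed: int | None
    n: int


def _group_indices(groups) -> tuple[list, list[np.ndarray]]:
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    idx = [np.flatnonzero(groups == lab) for lab in labels]
    return labels, idx


def _f_oneway_rows(v: np.ndarray, idx: list[np.ndarray]) -> np.ndarray:
    """Row-wise one-way F statistic for a (n_rows, n) value matrix."""
    n = v.shape[1]
    k = len(idx)
    grand = v.mean(axis=1)
    sst = ((v - grand[:, None]) ** 2).sum(axis=1)
    ssb = np.zeros(v.shape[0])
    for ix in idx:
        ssb += ix.size * (v[:, ix].mean(axis=1) - grand) ** 2
    ssw = sst - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n - k))
    f[np.isnan(f)] = 0.0  # 0/0: all values equal
    f[np.isinf(f)] = np.inf
    return f


def _check_groups(values, groups, min_per_group=2):
    values = np.asarray(values, dtype=float)
    labels, idx = _group_indices(groups)
    if len(labels) < 2:
        raise ConfigError("need at least 2 groups")
    for lab, ix in zip(labels, idx):
        if ix.size < min_per_group:
            raise ConfigError(f"group {lab!r} has fewer than {min_per_group} values")
    return values, labels, idx


def perm_anova_oneway(values, groups, n_perm: int = 10000, seed=None) -> PermTestResult:
    """One-way ANOVA with a random-relabelling permutation null.

    Zero total variance yields F = 0 and p = 1 by convention.
    """
    values, labels, idx = _check_groups(values, groups)
    n, k = values.size, len(labels)
    f_obs = float(_f_oneway_rows(values[None, :], idx)[0])
    if np.ptp(values) == 0:
        return PermTestResult("F", 0.0, 1.0, n_perm, seed, 1.0,
                              extras={"df": (k - 1, n - k)})
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.broadcast_to(values, (n_perm, n)).copy(), axis=1)
    f_perm = _f_oneway_rows(perms, idx)
    p_perm = (1 + int((f_perm >= f_obs).sum())) / (1 + n_perm)
    p_classical = float(sps.f.sf(f_obs, k - 1, n - k))
    return PermTestResult("F", f_obs, p_perm, n_perm, seed, p_classical,
                          extras={"df": (k - 1, n - k)})


def tukey_posthoc(values, groups, n_perm: int = 0, seed=None) -> pd.DataFrame:
    """Tukey(-Kramer) pairwise comparisons via the studentized range.

    Q_ij = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)) with the
    pooled within-group mean square; adjusted p from the studentized-
    range distribution. With ``n_perm > 0`` a max-Q permutation p is
    reported alongside as a cross-check.
    """
    values, labels, idx = _check_groups(values, groups)
    n, k = values.size, len(labels)
    df_w = n - k
    means = np.array([values[ix].mean() for ix in idx])
    ssw = sum(((values[ix] - m) ** 2).sum() for ix, m in zip(idx, means))
    msw = ssw / df_w

    def q_stats(v_rows):
        ms = np.stack([v_rows[:, ix].mean(axis=1) for ix in idx], axis=1)
        ssw_r = np.zeros(v_rows.shape[0])
        for j, ix in enumerate(idx):
            ssw_r += ((v_rows[:, ix] - ms[:, j][:, None]) ** 2).sum(axis=1)
        msw_r = ssw_r / df_w
        qs = {}
        for a in range(k):
            for b in range(a + 1, k):
                se = np.sqrt(msw_r / 2 * (1 / idx[a].size + 1 / idx[b].size))
                with np.errstate(divide="ignore", invalid="ignore"):
                    q = np.abs(ms[:, a] - ms[:, b]) / se
                q[np.isnan(q)] = 0.0
                qs[(a, b)] = q
        return qs

    q_obs = q_stats(values[None, :])
    q_perm_max = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.broadcast_to(values, (n_perm, n)).copy(), axis=1)
        q_all = q_stats(perms)
        q_perm_max = np.max(np.stack(list(q_all.values())), axis=0)

    rows = []
    for (a, b), q in q_obs.items():
        q = float(q[0])
        if msw == 0:
            p = 1.0 if q == 0 else 0.0
        else:
            p = float(np.clip(sps.studentized_range.sf(q, k, df_w), 0, 1))
        row = dict(
            group_1=labels[a], group_2=labels[b],
            mean_1=means[a], mean_2=means[b],
            diff=means[a] - means[b], q=q, p_tukey=p,
        )
        if q_perm_max is not None:
            row["p_perm"] = (1 + int((q_perm_max >= q).sum())) / (1 + n_perm)
        rows.append(row)
    return pd.DataFrame(rows)


def perm_linreg(x, y, n_perm: int = 10000, seed=None) -> LinRegResult:
    """Simple OLS regression with a permutation p for the F statistic.

    The y vector is permuted against a fixed x; classical t and F
    p-values are reported alongside.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ConfigError("need n >= 3")
    if np.ptp(x) == 0:
        raise ConfigError("x must not be constant")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    slope = float(xc @ yc) / sxx
    intercept = float(y.mean() - slope * x.mean())
    if syy == 0:
        r2 = 0.0
    else:
        r2 = (float(xc @ yc) ** 2) / (sxx * syy)
    dof = n - 2
    with np.errstate(divide="ignore"):
        f_obs = r2 * dof / (1 - r2) if r2 < 1 else np.inf
    t_stat = float(np.sign(slope) * np.sqrt(f_obs)) if np.isfinite(f_obs) else np.inf
    p_t = float(2 * sps.t.sf(abs(t_stat), dof)) if np.isfinite(t_stat) else 0.0
    p_classical = float(sps.f.sf(f_obs, 1, dof)) if np.isfinite(f_obs) else 0.0
    r2_adj = 1 - (1 - r2) * (n - 1) / dof

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.broadcast_to(y, (n_perm, n)).copy(), axis=1)
    pc = perms - perms.mean(axis=1, keepdims=True)
    num = (pc @ xc) ** 2
    den = sxx * (pc * pc).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2_perm = np.where(den > 0, num / den, 0.0)
        f_perm = np.where(r2_perm < 1, r2_perm * dof / (1 - r2_perm), np.inf)
    p_perm = (1 + int((f_perm >= f_obs).sum())) / (1 + n_perm)
    return LinRegResult(
        slope=slope, intercept=intercept, t_stat=t_stat, p_t=p_t,
        r2=float(r2), r2_adj=float(r2_adj), f_stat=float(f_obs),
        p_classical=p_classical, p_perm=p_perm, n_perm=n_perm, seed=seed, n=n,
    )


def lilliefors(values, n_mc: int = 10000, seed=None) -> PermTestResult:
    """Lilliefors normality test (KS distance to a fitted normal).

    The null distribution of D is obtained by Monte Carlo: ``n_mc``
    standard-normal samples of the same n, each standardised with its
    own estimated mean and SD.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ConfigError("need n >= 4")
    if np.std(x, ddof=1) == 0:
        raise DomainError("zero variance sample")

    def d_stat(rows):
        z = (rows - rows.mean(axis=1, keepdims=True)) / rows.std(axis=1, ddof=1, keepdims=True)
        z = np.sort(z, axis=1)
        cdf = sps.norm.cdf(z)
        i = np.arange(1, n + 1)
        d_plus = (i / n - cdf).max(axis=1)
        d_minus = (cdf - (i - 1) / n).max(axis=1)
        return np.maximum(d_plus, d_minus)

    d_obs = float(d_stat(x[None, :])[0])
    rng = np.random.default_rng(seed)
    d_mc = d_stat(rng.standard_normal((n_mc, n)))
    p = (1 + int((d_mc >= d_obs).sum())) / (1 + n_mc)
    return PermTestResult("D", d_obs, p, n_mc, seed, p, extras={"n": n})


def levene(
    values, groups, center: str = "median", n_perm: int = 10000, seed=None
) -> PermTestResult:
    """Levene homogeneity-of-variance test (Brown-Forsythe by default).

    One-way ANOVA on absolute deviations from each group's center;
    classical F p and a permutation p (relabelling the raw values and
    re-centering per permutation) are both reported.
    """
    if center not in ("median", "mean"):
        raise ConfigError("center must be 'median' or 'mean'")
    values, labels, idx = _check_groups(values, groups)
    n, k = values.size, len(labels)
    cfun = np.median if center == "median" else np.mean

    def w_stat(v_rows):
        z = np.empty_like(v_rows)
        for ix in idx:
            block = v_rows[:, ix]
            c = (np.median(block, axis=1) if center == "median"
                 else block.mean(axis=1))
            z[:, ix] = np.abs(block - c[:, None])
        return _f_oneway_rows(z, idx)

    w_obs = float(w_stat(values[None, :])[0])
    z0 = np.concatenate([np.abs(values[ix] - cfun(values[ix])) for ix in idx])
    if np.ptp(z0) == 0:
        return PermTestResult("W", 0.0, 1.0, n_perm, seed, 1.0,
                              extras={"df": (k - 1, n - k), "center": center})
    p_classical = float(sps.f.sf(w_obs, k - 1, n - k))
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.broadcast_to(values, (n_perm, n)).copy(), axis=1)
    w_perm = w_stat(perms)
    p_perm = (1 + int((w_perm >= w_obs).sum())) / (1 + n_perm)
    return PermTestResult("W", w_obs, p_perm, n_perm, seed, p_classical,
                          extras={"df": (k - 1, n - k), "center": center})


def percent_change(reference: float, new: float) -> float:
    """Signed percent change from ``reference`` to ``new``."""
    if reference == 0:
        raise DomainError("reference value must be nonzero")
    return 100.0 * (new - reference) / reference


def round_to_nearest_ten(x: float) -> int:
    """Round to the nearest multiple of ten (halves away from zero)."""
    return int(np.floor(abs(x) / 10.0 + 0.5) * 10 * np.sign(x))


def summarize_groups(
    metrics: pd.DataFrame,
    endpoints: list[str],
    group_col: str = "group_psu",
) -> tuple[pd.DataFrame, dict]:
    """Per-group mean/sd/se per endpoint plus extreme-group effect sizes.

    Effect summaries compare the lowest- against the highest-salinity
    group for ``alpha`` (percent increase) and ``pcmax`` (percent
    decrease), raw and rounded to the nearest 10 %. Empty groups are
    omitted with a warning; a single group yields no effect summaries.
    """
    rows = []
    for g, sub in metrics.groupby(group_col, sort=False):
        if sub.empty:
            warnings.warn(f"group {g!r} is empty; omitted", stacklevel=2)
            continue
        for ep in endpoints:
            vals = sub[ep].dropna()
            n = len(vals)
            sd = float(vals.std(ddof=1)) if n >= 2 else np.nan
            rows.append(dict(
                group=g, endpoint=ep, n=n, mean=float(vals.mean()), sd=sd,
                se=sd / np.sqrt(n) if n >= 2 else np.nan,
            ))
    table = pd.DataFrame(rows)
    effects: dict = {}
    groups = sorted(table["group"].unique()) if not table.empty else []
    if len(groups) >= 2:
        lo_g, hi_g = groups[0], groups[-1]

        def mean_of(g, ep):
            sel = table[(table["group"] == g) & (table["endpoint"] == ep)]
            return float(sel["mean"].iloc[0]) if len(sel) else np.nan

        if "alpha" in endpoints:
            raw = percent_change(mean_of(hi_g, "alpha"), mean_of(lo_g, "alpha"))
            effects["alpha_pct_change_low_vs_high"] = {
                "raw": raw, "rounded": round_to_nearest_ten(raw),
            }
        if "pcmax" in endpoints:
            hi, lo = mean_of(hi_g, "pcmax"), mean_of(lo_g, "pcmax")
            raw = 100.0 * (hi - lo) / hi
            effects["pcmax_pct_decrease_low_vs_high"] = {
                "raw": raw, "rounded": round_to_nearest_ten(raw),
            }
    return table, effects
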