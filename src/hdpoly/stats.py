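"""Univariate statistical battery for cohort comparisons.

Implements the tests a mixed-design imaging-cohort analysis leans on:

* :func:`rm_anova` — univariate mixed-design (split-plot) ANOVA with one
  between-subject factor, one or two within-subject factors and at most
  one continuous covariate; Type III sums of squares, each within-effect
  tested against its own factor-by-subject error stratum, uncorrected
  (sphericity-unadjusted) degrees of freedom, and generalized eta
  squared (eta_G^2) effect sizes;
* :func:`oneway_anova` and :func:`tukey_hsd` — classical one-way F with
  eta squared plus studentized-range post-hocs;
* :func:`spearman` / :func:`partial_spearman` — rank correlations with
  Fisher-z confidence intervals;
* :func:`steiger_z` — Steiger's (1980) test comparing two dependent
  correlations that share one variable;
* :func:`mann_whitney_hl` — rank-sum test (both U conventions and the
  rank-sum W) with the Hodges-Lehmann shift estimate and its Moses
  order-statistic confidence interval;
* :func:`ks_normality` — Lilliefors-corrected one-sample KS normality
  check against a normal with the sample's mean and SD.

Greenhouse-Geisser epsilon is computed for single-within designs but
applied only on request; reported dfs default to the uncorrected ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "PosthocResult",
    "CorrelationResult",
    "RankTestResult",
    "rm_anova",
    "oneway_anova",
    "tukey_hsd",
    "spearman",
    "partial_spearman",
    "steiger_z",
    "mann_whitney_hl",
    "ks_normality",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class AnovaResult:
    """ANOVA table plus a human-readable design description."""

    table: pd.DataFrame  # effect, df_num, df_den, F, p, ges
    design: str
    gg_epsilon: dict[str, float] = field(default_factory=dict)

    def effect(self, name: str) -> pd.Series:
        row = self.table[self.table["effect"] == name]
        if row.empty:
            raise KeyError(f"no effect named {name!r}; have {list(self.table['effect'])}")
        return row.iloc[0]

    def summary(self) -> str:
        lines = [self.design, "-" * len(self.design)]
        for _, r in self.table.iterrows():
            lines.append(
                f"{r['effect']:>24s}  F({int(r['df_num'])}, {int(r['df_den'])}) = "
                f"{r['F']:.3f}  p = {r['p']:.4g}  gesq = {r['ges']:.3f}"
            )
        return "\n".join(lines)


@dataclass
class PosthocResult:
    """All pairwise group comparisons, Tukey (studentized-range) adjusted."""

    table: pd.DataFrame  # group_a, group_b, mean_diff, p_adj, ci_low, ci_high

    def comparison(self, a: str, b: str) -> pd.Series:
        for ga, gb in ((a, b), (b, a)):
            row = self.table[(self.table["group_a"] == ga) & (self.table["group_b"] == gb)]
            if not row.empty:
                r = row.iloc[0].copy()
                if (ga, gb) != (a, b):
                    r["mean_diff"] = -r["mean_diff"]
                    r["ci_low"], r["ci_high"] = -r["ci_high"], -r["ci_low"]
                return r
        raise KeyError(f"no comparison between {a!r} and {b!r}")


@dataclass
class CorrelationResult:
    rho: float
    p: float
    ci_low: float
    ci_high: float
    n: int
    kind: str  # "spearman" | "partial_spearman"


@dataclass
class RankTestResult:
    u_min: float
    u_max: float
    ranksum_w: float
    p: float
    hl_shift: float
    ci_low: float
    ci_high: float
    n1: int
    n2: int
    exact: bool


# ---------------------------------------------------------------------------
# design-matrix helpers (sum-to-zero coding so drop-term SS are Type III)


def _sum_code(levels: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Sum-to-zero (deviation) coding: L-1 columns, last level = -1 row."""
    L = len(levels)
    code = np.vstack([np.eye(L - 1), -np.ones(L - 1)])
    idx = np.searchsorted(levels, values)
    return code[idx]


def _interact(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Khatri-Rao product (all pairwise column products)."""
    return (a[:, :, None] * b[:, None, :]).reshape(len(a), -1)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _type3(terms: dict[str, np.ndarray], y: np.ndarray) -> tuple[dict[str, float], float]:
    """Drop-term (Type III, under sum coding) SS per term and full-model RSS."""
    names = list(terms)
    full = np.column_stack([terms[t] for t in names])
    rss_full = _rss(full, y)
    ss = {}
    for t in names:
        keep = [terms[k] for k in names if k != t]
        rss_red = _rss(np.column_stack(keep), y) if keep else float(y @ y)
        ss[t] = rss_red - rss_full
    return ss, rss_full


# ---------------------------------------------------------------------------
# mixed-design repeated-measures ANOVA


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: str | Sequence[str],
    between: str,
    covariate: str | None = None,
    gg_correct: bool = False,
) -> AnovaResult:
    """Univariate mixed-design ANOVA with optional continuous covariate.

    The design must be balanced within subjects: every subject observed
    exactly once at every combination of within-factor levels, and each
    subject in exactly one between-factor group.  Between-subject effects
    (Group, covariate) are tested on subject means against the
    subjects-within-groups error; each within-subject effect stratum
    (factor, or factor pair) is tested against its own interaction-with-
    subject error, the classical split-plot partition.  The covariate is
    centred and enters every stratum (main effect plus interaction with
    each within term).  Degrees of freedom are the uncorrected ones:
    for W within levels, G groups, n subjects and c covariates the
    within-effect error df is (W-1)(n-G-c).

    Generalized eta squared treats all factors as manipulated except the
    covariate (an observed variable): the denominator sums the effect SS,
    every error SS, and the SS of all covariate-related effects.

    Returns an :class:`AnovaResult`; Greenhouse-Geisser epsilon is
    attached for single-within designs and applied to dfs/p only when
    ``gg_correct`` is true.
    """
    within_list = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within_list) <= 2:
        raise ValueError("one or two within-subject factors supported")
    cols = [subject, between, dv, *within_list] + ([covariate] if covariate else [])
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"missing columns: {missing}")
    df = data[cols].copy()
    if df[dv].isna().any():
        raise ValueError("missing values in the response")

    # balance check
    cell = df.groupby([subject, *within_list], observed=True).size()
    expected = int(np.prod([df[w].nunique() for w in within_list]))
    per_subj = cell.groupby(level=0, observed=True).agg(["size", "max"])
    bad = per_subj[(per_subj["size"] != expected) | (per_subj["max"] != 1)]
    if len(bad):
        raise ValueError(
            f"unbalanced within-design (missing/duplicated cells) for subjects: "
            f"{list(bad.index)[:10]}"
        )
    gmap = df.groupby(subject, observed=True)[between].nunique()
    if (gmap != 1).any():
        raise ValueError("each subject must belong to exactly one between-factor group")

    subjects = np.sort(df[subject].unique())
    groups = np.sort(df[between].unique())
    n, G = len(subjects), len(groups)
    c = 1 if covariate else 0
    if covariate:
        cov_per_subj = df.groupby(subject, observed=True)[covariate].agg(["nunique", "first"])
        if (cov_per_subj["nunique"] != 1).any():
            raise ValueError("covariate must be constant within subject")
        cov_s = cov_per_subj["first"].reindex(subjects).to_numpy(dtype=float)
        if np.ptp(cov_s) == 0:
            raise ValueError("covariate is constant across subjects")
        cov_s = cov_s - cov_s.mean()
    else:
        cov_s = None
    group_s = df.groupby(subject, observed=True)[between].first().reindex(subjects).to_numpy()

    level_counts = {w: df[w].nunique() for w in within_list}
    W_total = expected

    effects: list[dict] = []
    error_ss: list[float] = []

    # ---- between-subject stratum (on subject means, SS scaled to cell units)
    ymeans = df.groupby(subject, observed=True)[dv].mean().reindex(subjects).to_numpy()
    terms: dict[str, np.ndarray] = {"(intercept)": np.ones((n, 1))}
    terms[between] = _sum_code(groups, group_s)
    if covariate:
        terms[covariate] = cov_s[:, None]
    ss_b, rss_b = _type3(terms, ymeans)
    df_err_b = n - G - c
    if df_err_b <= 0:
        raise ValueError("no residual degrees of freedom in the between stratum")
    error_ss.append(rss_b * W_total)
    for name in [between] + ([covariate] if covariate else []):
        effects.append(
            dict(effect=name, ss=ss_b[name] * W_total, df_num=G - 1 if name == between else 1,
                 ss_err=rss_b * W_total, df_den=df_err_b,
                 measured=(name == covariate))
        )

    # ---- within-subject strata
    gg_eps: dict[str, float] = {}
    for stratum in [s for r in (1, 2) for s in combinations(within_list, r)
                    if len(within_list) >= r]:
        sub = df.copy()
        collapse = [w for w in within_list if w not in stratum]
        m_scale = int(np.prod([level_counts[w] for w in collapse])) if collapse else 1
        if collapse:
            sub = (sub.groupby([subject, *stratum], observed=True, as_index=False)
                   .agg({dv: "mean", between: "first",
                         **({covariate: "first"} if covariate else {})}))
        sub = sub.sort_values([subject, *stratum], kind="mergesort").reset_index(drop=True)
        y = sub[dv].to_numpy(dtype=float)
        # annihilate everything below this stratum by within-subject centering:
        # for a single factor, remove the subject mean; for a factor pair,
        # double-center each subject's table so both margins (and with them
        # the subject, group, covariate and lower-stratum effects) vanish.
        # Sum-to-zero contrast columns are orthogonal to the removed spaces
        # in a balanced design, so the remaining stratum terms are fitted on
        # the centred response without subject dummies.
        shape = (n,) + tuple(level_counts[w] for w in stratum)
        cube = y.reshape(shape)
        if len(stratum) == 1:
            yc = (cube - cube.mean(axis=1, keepdims=True)).ravel()
        else:
            yc = (cube
                  - cube.mean(axis=1, keepdims=True)
                  - cube.mean(axis=2, keepdims=True)
                  + cube.mean(axis=(1, 2), keepdims=True)).ravel()
        w_codes = {w: _sum_code(np.sort(sub[w].unique()), sub[w].to_numpy())
                   for w in stratum}
        g_code = _sum_code(groups, sub[between].to_numpy())
        if covariate:
            x = sub[covariate].to_numpy(dtype=float)
            x = (x - df.groupby(subject, observed=True)[covariate].first().mean())[:, None]

        code = w_codes[stratum[0]]
        for w in stratum[1:]:
            code = _interact(code, w_codes[w])
        tname = "*".join(stratum)
        terms = {tname: code, f"{tname}*{between}": _interact(code, g_code)}
        if covariate:
            terms[f"{tname}*{covariate}"] = _interact(code, x)
        stratum_terms = list(terms)
        ss_w, rss_w = _type3(terms, yc)
        df_w = int(np.prod([level_counts[w] - 1 for w in stratum]))
        df_err_w = df_w * (n - G - c)
        err = rss_w * m_scale
        error_ss.append(err)
        for tname in stratum_terms:
            if tname.endswith(f"*{between}"):
                dnum = df_w * (G - 1)
            elif covariate and tname.endswith(f"*{covariate}"):
                dnum = df_w
            else:
                dnum = df_w
            effects.append(
                dict(effect=tname, ss=ss_w[tname] * m_scale, df_num=dnum,
                     ss_err=err, df_den=df_err_w,
                     measured=bool(covariate) and tname.endswith(f"*{covariate}"))
            )
        if len(stratum) == 1 and len(within_list) == 1:
            gg_eps[stratum[0]] = _gg_epsilon(df, dv, subject, stratum[0])

    measured_ss = sum(e["ss"] for e in effects if e["measured"])
    total_err = sum(error_ss)
    rows = []
    for e in effects:
        denom = total_err + measured_ss + (0.0 if e["measured"] else e["ss"])
        ges = e["ss"] / denom if denom > 0 else 0.0
        dn, dd = e["df_num"], e["df_den"]
        eps = 1.0
        if gg_correct and gg_eps:
            base = e["effect"].split("*")[0]
            eps = gg_eps.get(base, 1.0)
        F = (e["ss"] / dn) / (e["ss_err"] / dd) if e["ss_err"] > 0 else np.inf
        p = float(sps.f.sf(F, dn * eps, dd * eps)) if np.isfinite(F) else 0.0
        rows.append(dict(effect=e["effect"], df_num=dn, df_den=dd, F=F, p=p, ges=ges))
    table = pd.DataFrame(rows)
    desc = (
        f"mixed ANOVA: dv={dv}, within={'x'.join(within_list)} "
        f"({'x'.join(str(level_counts[w]) for w in within_list)} levels), "
        f"between={between} ({G} groups), n={n}"
        + (f", covariate={covariate}" if covariate else "")
        + (", GG-corrected" if gg_correct else ", uncorrected dfs")
    )
    return AnovaResult(table=table, design=desc, gg_epsilon=gg_eps)


def _gg_epsilon(df: pd.DataFrame, dv: str, subject: str, within: str) -> float:
    """Greenhouse-Geisser epsilon from the within-level covariance matrix."""
    wide = df.pivot_table(index=subject, columns=within, values=dv, observed=True)
    S = np.cov(wide.to_numpy(), rowvar=False)
    k = S.shape[0]
    mean_diag = np.trace(S) / k
    grand = S.mean()
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(S.mean(axis=1) ** 2) + k**2 * grand**2)
    return float(num / den) if den > 0 else 1.0


# ---------------------------------------------------------------------------
# one-way ANOVA + Tukey


def oneway_anova(values: Sequence[float], groups: Sequence) -> AnovaResult:
    """Classical one-way F test with eta-squared effect size."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    samples = [values[groups == g] for g in levels]
    if len(levels) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 values each")
    grand = values.mean()
    ss_b = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_w = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b, df_w = len(levels) - 1, len(values) - len(levels)
    F = (ss_b / df_b) / (ss_w / df_w) if ss_w > 0 else np.inf
    p = float(sps.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    eta2 = ss_b / (ss_b + ss_w) if (ss_b + ss_w) > 0 else 0.0
    table = pd.DataFrame(
        [dict(effect="group", df_num=df_b, df_den=df_w, F=float(F), p=p, ges=eta2)]
    )
    return AnovaResult(table=table, design=f"one-way ANOVA, {len(levels)} groups, n={len(values)}")


def tukey_hsd(values: Sequence[float], groups: Sequence) -> PosthocResult:
    """Tukey honest-significant-difference post-hocs with simultaneous 95% CIs."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    samples = [values[groups == g] for g in levels]
    if len(levels) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 values each")
    res = sps.tukey_hsd(*samples)
    ci = res.confidence_interval(confidence_level=0.95)
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            rows.append(
                dict(group_a=levels[i], group_b=levels[j],
                     mean_diff=float(samples[i].mean() - samples[j].mean()),
                     p_adj=float(res.pvalue[i, j]),
                     ci_low=float(ci.low[i, j]), ci_high=float(ci.high[i, j]))
            )
    return PosthocResult(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# rank correlations


def _fisher_ci(rho: float, n_eff: int) -> tuple[float, float]:
    if n_eff <= 3 or abs(rho) >= 1:
        return (-1.0, 1.0)
    z = math.atanh(rho)
    h = 1.959963984540054 / math.sqrt(n_eff - 3)
    return (math.tanh(z - h), math.tanh(z + h))


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with t-approximation p and Fisher-z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    rho, p = sps.spearmanr(x, y)
    lo, hi = _fisher_ci(float(rho), n)
    return CorrelationResult(rho=float(rho), p=float(p), ci_low=lo, ci_high=hi,
                             n=n, kind="spearman")


def partial_spearman(
    x: Sequence[float], y: Sequence[float], covariate: Sequence[float]
) -> CorrelationResult:
    """Rank partial correlation of x and y controlling for one covariate.

    Computed as the Pearson correlation of the residuals after regressing
    the (average-tie) ranks of x and y on the ranks of the covariate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariate, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("need n >= 5 for a partial correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0 or np.ptp(z) == 0:
        raise ValueError("constant input")
    rx, ry, rz = (sps.rankdata(v) for v in (x, y, z))
    D = np.column_stack([np.ones(n), rz])
    resid = lambda v: v - D @ np.linalg.lstsq(D, v, rcond=None)[0]
    ex, ey = resid(rx), resid(ry)
    rho = float(np.dot(ex, ey) / np.sqrt(np.dot(ex, ex) * np.dot(ey, ey)))
    dof = n - 3
    t = rho * math.sqrt(dof / max(1e-300, 1 - rho**2))
    p = 2 * float(sps.t.sf(abs(t), dof))
    lo, hi = _fisher_ci(rho, n - 1)  # one covariate costs one effective obs
    return CorrelationResult(rho=rho, p=p, ci_low=lo, ci_high=hi, n=n,
                             kind="partial_spearman")


def steiger_z(r_xy: float, r_xz: float, r_yz: float, n: int,
              compare_magnitudes: bool = True) -> tuple[float, float]:
    """Steiger's (1980) z for two dependent correlations sharing variable x.

    Tests r_xy against r_xz given the correlation r_yz between the two
    non-shared variables, using Fisher-transformed correlations and the
    pooled-correlation covariance term.  With ``compare_magnitudes`` the
    comparison is between |r_xy| and |r_xz| (signs of y/z are flipped,
    which also flips r_yz accordingly), matching how "explains more
    variance" comparisons are made.
    """
    for name, r in (("r_xy", r_xy), ("r_xz", r_xz), ("r_yz", r_yz)):
        if not -1 < r < 1:
            raise ValueError(f"{name} must be in (-1, 1), got {r}")
    if n < 4:
        raise ValueError("need n >= 4")
    R = np.array([[1, r_xy, r_xz], [r_xy, 1, r_yz], [r_xz, r_yz, 1]])
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError("implied correlation matrix is not positive semi-definite")
    if compare_magnitudes:
        sy = -1.0 if r_xy < 0 else 1.0
        sz = -1.0 if r_xz < 0 else 1.0
        r_xy, r_xz, r_yz = sy * r_xy, sz * r_xz, sy * sz * r_yz
    rbar = (r_xy + r_xz) / 2.0
    det_term = 1 - rbar**2
    psi = r_yz * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r_yz**2)
    sbar = psi / (det_term**2)
    z1, z2 = math.atanh(r_xy), math.atanh(r_xz)
    z = (z1 - z2) * math.sqrt((n - 3) / (2 * (1 - sbar)))
    p = 2 * float(sps.norm.sf(abs(z)))
    return float(z), p


# ---------------------------------------------------------------------------
# Mann-Whitney / Hodges-Lehmann


def _u_cdf_exact(n1: int, n2: int) -> np.ndarray:
    """Exact null CDF of the Mann-Whitney U statistic (no ties).

    Counts the subsets of the pooled ranks 1..n1+n2 of size n1 by their
    rank sum (subset-sum dynamic programme); U = ranksum - n1(n1+1)/2.
    Returns the CDF over U = 0..n1*n2.
    """
    n = n1 + n2
    smax = n1 * n + 1  # rank sums cannot exceed n1 * n
    # T[c, s] = number of size-c subsets of the ranks seen so far with sum s
    T = np.zeros((n1 + 1, smax), dtype=float)
    T[0, 0] = 1.0
    for r in range(1, n + 1):
        T[1:, r:] += T[:-1, :-r].copy()
    counts = T[n1]
    offset = n1 * (n1 + 1) // 2
    pmf = counts[offset: offset + n1 * n2 + 1]
    pmf = pmf / pmf.sum()
    return np.cumsum(pmf)


def mann_whitney_hl(x: Sequence[float], y: Sequence[float]) -> RankTestResult:
    """Two-sample rank test with Hodges-Lehmann shift estimate.

    Reports both U conventions (min and max of the two one-sided U
    statistics) plus the rank-sum W of the first sample, the two-tailed
    p (exact when n1*n2 <= 64 and tie-free, else normal approximation
    with tie correction), HL = median of all pairwise differences y - x,
    and the Moses order-statistic 95% confidence interval for the shift.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w1 = float(ranks[:n1].sum())
    u1 = w1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (n1 * n2 <= 64) and not has_ties
    method = "exact" if exact else "asymptotic"
    p = float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)

    diffs = np.sort((y[None, :] - x[:, None]).ravel())
    hl = float(np.median(diffs))
    N = n1 * n2
    # Moses CI: k-th smallest / k-th largest pairwise difference, with k from
    # the exact U null CDF when feasible, else its normal approximation
    alpha = 0.05
    if N <= 2000:
        cdf = _u_cdf_exact(n1, n2)
        below = np.flatnonzero(cdf <= alpha / 2)
        k = int(below[-1] + 1) if len(below) else 0
    else:
        mu, sd = N / 2.0, math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        k = int(math.floor(mu + sps.norm.ppf(alpha / 2) * sd))
        k = max(k, 0)
    if k < 1 or k > N - k:
        lo, hi = float(diffs[0]), float(diffs[-1])
    else:
        lo, hi = float(diffs[k - 1]), float(diffs[N - k])
    return RankTestResult(u_min=float(min(u1, u2)), u_max=float(max(u1, u2)),
                          ranksum_w=w1, p=p, hl_shift=hl, ci_low=lo, ci_high=hi,
                          n1=n1, n2=n2, exact=exact)


# ---------------------------------------------------------------------------
# normality


def ks_normality(x: Sequence[float], alpha: float = 0.05) -> tuple[float, float, bool]:
    """Lilliefors-corrected KS test against a fitted normal.

    One-sample Kolmogorov-Smirnov statistic against a normal with the
    sample mean and SD, with the p-value corrected for the estimated
    parameters (Lilliefors).  Returns (statistic, p, reject-at-alpha).
    """
    from statsmodels.stats.diagnostic import lilliefors

    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise ValueError("need n >= 5")
    if np.ptp(x) == 0:
        raise ValueError("constant input")
    stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    return float(stat), float(p), bool(p < alpha)
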