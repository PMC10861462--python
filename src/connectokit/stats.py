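"""Group-comparison and association statistics.

The screening scheme applied to every connectivity or network feature is:
an omnibus ANCOVA of the feature on group with mean framewise displacement
as a covariate (type-II partial F for the group factor); features passing
the gate at alpha get all pairwise two-sample t-tests; Benjamini-Hochberg
FDR is applied across the post-hoc p-values (pooled over gated features by
default). Demographics use one-way ANOVA and the chi-square test, and
brain-behaviour associations use Pearson correlations with FDR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class PairResult:
    pair: tuple[str, str]
    t: float
    p: float
    p_fdr: float = np.nan
    significant: bool = False


@dataclass
class GroupTestResult:
    """Omnibus + post-hoc results for one feature."""

    feature: str
    f: float
    p: float
    gated: bool
    group_means: dict[str, float] = field(default_factory=dict)
    covariate_coef: float = np.nan
    pairs: list[PairResult] = field(default_factory=list)


def _design(group: np.ndarray, covariate: np.ndarray | None):
    labels = [str(g) for g in group]
    levels = sorted(set(labels))
    n = len(labels)
    dummies = np.zeros((n, len(levels) - 1))
    for j, lev in enumerate(levels[1:]):
        dummies[:, j] = [lab == lev for lab in labels]
    cols = [np.ones(n), dummies]
    if covariate is not None:
        cols.append(np.asarray(covariate, dtype=float).reshape(n, -1))
    return np.column_stack(cols), levels


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return float(r @ r)


def ancova(
    y: np.ndarray, group: np.ndarray, covariate: np.ndarray | None
) -> tuple[float, float]:
    """Partial F-test for group in y ~ group + covariate (type-II SS).

    df = (g - 1, n - g - c) with c covariate columns. A covariate that is
    collinear with the group indicators triggers a warning and a fallback
    to plain one-way ANOVA.
    """
    y = np.asarray(y, dtype=float)
    labels = np.asarray(group)
    levels = sorted({str(g) for g in labels})
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    counts = [np.sum(labels.astype(str) == lev) for lev in levels]
    if min(counts) < 2:
        raise ValueError("every group needs n >= 2")
    n = y.size
    x_full, _ = _design(labels, covariate)
    if covariate is not None:
        if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
            warnings.warn(
                "covariate collinear with group; falling back to ANOVA",
                stacklevel=2,
            )
            return ancova(y, labels, None)
        # intercept + covariate only (single pseudo-group drops the dummies)
        x_red, _ = _design(np.zeros(n), covariate)
    else:
        x_red = np.ones((n, 1))
    df1 = len(levels) - 1
    df2 = n - x_full.shape[1]
    rss_f = _rss(x_full, y)
    rss_r = _rss(x_red, y)
    if rss_f <= 1e-300:
        if rss_r - rss_f <= 1e-300:
            return 0.0, 1.0  # y fully explained without the group factor
        return np.inf, 0.0
    f = ((rss_r - rss_f) / df1) / (rss_f / df2)
    f = max(f, 0.0)
    return float(f), float(sps.f.sf(f, df1, df2))


def posthoc_ttests(
    y: np.ndarray,
    group: np.ndarray,
    pairs: list[tuple[str, str]] | None = None,
    equal_var: bool = True,
) -> list[PairResult]:
    """Two-sided two-sample t-tests for the requested group pairs."""
    y = np.asarray(y, dtype=float)
    labels = np.asarray(group).astype(str)
    if pairs is None:
        pairs = list(combinations(sorted(set(labels)), 2))
    out = []
    for a, b in pairs:
        ya, yb = y[labels == a], y[labels == b]
        t, p = sps.ttest_ind(ya, yb, equal_var=equal_var)
        if np.isnan(t):  # zero variance in both samples
            t, p = 0.0, 1.0
        out.append(PairResult(pair=(a, b), t=float(t), p=float(p)))
    return out


def fdr_bh(
    pvals: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejected mask, adjusted p-values)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    rejected, p_adj, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return rejected, p_adj


def anova_oneway(y: np.ndarray, group: np.ndarray) -> tuple[float, float]:
    """Classic one-way ANOVA F and p."""
    labels = np.asarray(group).astype(str)
    samples = [np.asarray(y, float)[labels == lev]
               for lev in sorted(set(labels))]
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*samples)
    if np.isnan(f):  # zero variance everywhere
        return 0.0, 1.0
    return float(f), float(p)


def chi_square(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a contingency table (no Yates correction)."""
    table = np.asarray(table, dtype=float)
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def feature_screen(
    features: np.ndarray,
    group: np.ndarray,
    covariate: np.ndarray | None,
    alpha: float = 0.05,
    q: float = 0.05,
    feature_names: list[str] | None = None,
    pooled_fdr: bool = True,
    equal_var: bool = True,
) -> list[GroupTestResult]:
    """ANCOVA gate + post-hoc t-tests + FDR over every feature column.

    FDR is applied across the post-hoc p-values of all gated features
    (pooled family, the default) or within each feature.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[0] != len(group):
        features = features.T
    n, m = features.shape
    names = feature_names or [f"f{i}" for i in range(m)]
    labels = np.asarray(group).astype(str)
    levels = sorted(set(labels))
    results: list[GroupTestResult] = []
    for j in range(m):
        y = features[:, j]
        f, p = ancova(y, labels, covariate)
        res = GroupTestResult(
            feature=names[j], f=f, p=p, gated=bool(p < alpha),
            group_means={lev: float(y[labels == lev].mean())
                         for lev in levels},
        )
        if res.gated:
            res.pairs = posthoc_ttests(y, labels, equal_var=equal_var)
        results.append(res)

    gated_pairs = [pr for res in results for pr in res.pairs]
    if gated_pairs:
        if pooled_fdr:
            rej, adj = fdr_bh(np.array([pr.p for pr in gated_pairs]), q)
            for pr, r, a in zip(gated_pairs, rej, adj):
                pr.p_fdr, pr.significant = float(a), bool(r)
        else:
            for res in results:
                if res.pairs:
                    rej, adj = fdr_bh(np.array([pr.p for pr in res.pairs]), q)
                    for pr, r, a in zip(res.pairs, rej, adj):
                        pr.p_fdr, pr.significant = float(a), bool(r)
    return results


def clinical_correlations(
    metrics: np.ndarray,
    scores: np.ndarray,
    q: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pearson r between every metric and score column, with BH-FDR.

    Returns (r (m, s), p (m, s), significance mask (m, s)); FDR is applied
    jointly over all m*s tests.
    """
    x = np.atleast_2d(np.asarray(metrics, dtype=float))
    y = np.atleast_2d(np.asarray(scores, dtype=float))
    if x.shape[0] != y.shape[0]:
        raise ValueError("metrics and scores need the same number of subjects")
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 subjects")

    def standardize(a):
        a = a - a.mean(axis=0)
        sd = a.std(axis=0)
        sd[sd == 0] = np.inf  # constant column -> r = 0
        return a / sd

    r = standardize(x).T @ standardize(y) / n
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.abs(r) * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * sps.t.sf(tval, n - 2)
    p[~np.isfinite(tval)] = 0.0  # |r| = 1
    rej, _ = fdr_bh(p.ravel(), q)
    return r, p, rej.reshape(p.shape)
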