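"""Per-feature differential expression between groups.

Four tests are offered, chosen by the study design: a pooled-variance
Student t test and one-way ANOVA for replicated designs (run on log2
normalized values), and Fisher's exact test or a Pearson chi-squared test on
group-pooled counts for replicate-free designs.  Raw p-values drive the
significance call by default; Benjamini-Hochberg adjustment is available.

Every test returns one row per feature with the columns
``feature, mean_a, mean_b, log2fc, stat, p, p_adj, significant, direction``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError
from .io import CountMatrix, SampleMetadata
from .normalize import NormalizedMatrix

log = logging.getLogger(__name__)

DE_COLUMNS = [
    "feature", "mean_a", "mean_b", "log2fc", "stat", "p", "p_adj",
    "significant", "direction",
]


def _group_columns(values: pd.DataFrame, meta: SampleMetadata, group: str) -> pd.DataFrame:
    samples = meta.samples_of(group)
    if not samples:
        raise ConfigurationError(f"group {group!r} absent from metadata")
    missing = [s for s in samples if s not in values.columns]
    if missing:
        raise ConfigurationError(f"samples {missing} of group {group!r} absent from matrix")
    return values[samples]


def _finish(
    features, mean_a, mean_b, stat, p, alpha: float, adjust: bool, log2fc=None
) -> pd.DataFrame:
    log2fc = (mean_b - mean_a) if log2fc is None else log2fc
    p_adj = bh_adjust(p) if adjust else np.full(len(p), np.nan)
    crit = p_adj if adjust else p
    significant = crit < alpha
    direction = np.where(
        ~significant, "none", np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none"))
    )
    return pd.DataFrame(
        {
            "feature": features,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "stat": stat,
            "p": p,
            "p_adj": p_adj,
            "significant": significant,
            "direction": direction,
        }
    )


def de_ttest(
    norm: NormalizedMatrix,
    meta: SampleMetadata,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Two-sided pooled-variance Student t test per feature on log2 values.

    ``log2fc = mean_b - mean_a``.  Features constant within both groups and
    equal in mean get t = 0, p = 1.
    """
    if not norm.log2:
        raise ValueError("de_ttest expects log2-transformed values")
    a = _group_columns(norm.values, meta, group_a).to_numpy()
    b = _group_columns(norm.values, meta, group_b).to_numpy()
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ConfigurationError("t test needs >= 2 samples per group")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    ssa = ((a - ma[:, None]) ** 2).sum(axis=1)
    ssb = ((b - mb[:, None]) ** 2).sum(axis=1)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = mb - ma
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    zero_se = se == 0
    t[zero_se & (diff == 0)] = 0.0
    t[zero_se & (diff > 0)] = np.inf
    t[zero_se & (diff < 0)] = -np.inf
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return _finish(norm.feature_ids, ma, mb, t, p, alpha, adjust)


def _pooled_tables(
    counts: CountMatrix, meta: SampleMetadata, group_a: str, group_b: str
):
    a = _group_columns(counts.counts, meta, group_a).to_numpy().sum(axis=1)
    b = _group_columns(counts.counts, meta, group_b).to_numpy().sum(axis=1)
    return a, b, int(a.sum()), int(b.sum())


def _pooled_log2fc(xa, xb, na, nb, pseudocount: float = 0.5) -> np.ndarray:
    cpm_a = (xa + pseudocount) / na * 1e6
    cpm_b = (xb + pseudocount) / nb * 1e6
    return np.log2(cpm_b / cpm_a)


def fisher_exact_pvalue(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on one 2x2 table ``[[a, b], [c, d]]``.

    Returns (odds ratio, p).  The p-value sums hypergeometric probabilities
    no larger than that of the observed table.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return np.nan, 1.0
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def de_fisher(
    counts: CountMatrix,
    meta: SampleMetadata,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Fisher's exact test on per-feature 2x2 tables of group-pooled counts.

    The table is ``[[x_a, N_a - x_a], [x_b, N_b - x_b]]`` with N the pooled
    library size.  The two-sided p sums hypergeometric probabilities no
    larger than that of the observed table.  Fold change is computed from
    pooled CPM with pseudocount 0.5.
    """
    xa, xb, na, nb = _pooled_tables(counts, meta, group_a, group_b)
    p = np.ones(len(xa))
    odds = np.zeros(len(xa))
    for i, (a_i, b_i) in enumerate(zip(xa, xb)):
        if a_i + b_i == 0:
            log.info("de_fisher: zero margin for %s; p = 1", counts.feature_ids[i])
            p[i] = 1.0
            continue
        odds[i], p[i] = fisher_exact_pvalue(a_i, na - a_i, b_i, nb - b_i)
    lfc = _pooled_log2fc(xa, xb, na, nb)
    return _finish(
        counts.feature_ids, xa / na * 1e6, xb / nb * 1e6, odds, p, alpha, adjust, log2fc=lfc
    )


def de_chisq(
    counts: CountMatrix,
    meta: SampleMetadata,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Pearson chi-squared test (no continuity correction) on the same
    pooled 2x2 tables as :func:`de_fisher`; 1 degree of freedom."""
    xa, xb, na, nb = _pooled_tables(counts, meta, group_a, group_b)
    a, b = xa.astype(float), (na - xa).astype(float)
    c, d = xb.astype(float), (nb - xb).astype(float)
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * (a * d - b * c) ** 2 / denom
    zero = denom == 0
    if zero.any():
        log.info("de_chisq: %d features with a zero expected cell; p = 1", int(zero.sum()))
    chi2[zero] = 0.0
    p = stats.chi2.sf(chi2, df=1)
    p[zero] = 1.0
    lfc = _pooled_log2fc(xa, xb, na, nb)
    return _finish(
        counts.feature_ids, xa / na * 1e6, xb / nb * 1e6, chi2, p, alpha, adjust, log2fc=lfc
    )


def de_anova(
    norm: NormalizedMatrix,
    meta: SampleMetadata,
    groups: list[str],
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """One-way fixed-effects F test per feature on log2 values.

    With exactly two groups, F equals the square of the pooled t statistic
    and the p-values coincide.  ``mean_a``/``mean_b``/``log2fc`` report the
    first two groups.
    """
    if not norm.log2:
        raise ValueError("de_anova expects log2-transformed values")
    if len(groups) < 2:
        raise ConfigurationError("ANOVA needs >= 2 groups")
    blocks = [_group_columns(norm.values, meta, grp).to_numpy() for grp in groups]
    for grp, blk in zip(groups, blocks):
        if blk.shape[1] < 2:
            raise ConfigurationError(f"group {grp!r} has < 2 samples")
    k = len(blocks)
    ns = np.array([blk.shape[1] for blk in blocks])
    n_tot = int(ns.sum())
    means = np.stack([blk.mean(axis=1) for blk in blocks], axis=1)
    grand = sum(blk.sum(axis=1) for blk in blocks) / n_tot
    ssb = (ns[None, :] * (means - grand[:, None]) ** 2).sum(axis=1)
    ssw = sum(((blk - m[:, None]) ** 2).sum(axis=1) for blk, m in zip(blocks, means.T))
    df_b, df_w = k - 1, n_tot - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    zero_w = ssw == 0
    f[zero_w & (ssb == 0)] = 0.0
    f[zero_w & (ssb > 0)] = np.inf
    p = stats.f.sf(f, df_b, df_w)
    p[f == 0] = 1.0
    return _finish(norm.feature_ids, means[:, 0], means[:, 1], f, p, alpha, adjust)


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _round_half_up(x: float, digits: int = 1) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DESummary:
    """Headline counts of a DE run: totals, split by direction, and the
    percentages (half-up, 1 decimal) used in reporting."""

    n_total: int
    n_significant: int
    n_up: int
    n_down: int
    pct_significant: float
    pct_up: float
    pct_down: float


def summarize_de(results: pd.DataFrame, alpha: float) -> DESummary:
    """Summarize a DE table at threshold ``alpha`` on the raw p-value.

    ``pct_up``/``pct_down`` are percentages of the significant features;
    ``pct_significant`` is a percentage of all features.  All percentages are
    rounded half-up to 1 decimal.
    """
    sig = results["p"].to_numpy() < alpha
    up = sig & (results["log2fc"].to_numpy() > 0)
    down = sig & (results["log2fc"].to_numpy() < 0)
    n_total, n_sig = len(results), int(sig.sum())
    n_up, n_down = int(up.sum()), int(down.sum())
    if n_sig == 0:
        log.info("summarize_de: no significant features; direction percentages set to 0")
        pct_up = pct_down = 0.0
    else:
        pct_up = _round_half_up(100.0 * n_up / n_sig)
        pct_down = _round_half_up(100.0 * n_down / n_sig)
    pct_sig = _round_half_up(100.0 * n_sig / n_total) if n_total else 0.0
    return DESummary(n_total, n_sig, n_up, n_down, pct_sig, pct_up, pct_down)
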