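"""Core integration stage: Spearman correlation of each focus miRNA with its
significantly DE predicted targets, classification of each pair as inverse or
positive, and a per-miRNA one-proportion test on the inverse fraction with an
exact (Clopper-Pearson) confidence interval.

Spearman p-values are exact for small sample counts: for n <= 8 the two-sided
p enumerates all n! rank orderings; beyond that the usual t approximation
``t = rho * sqrt((n - 2) / (1 - rho^2))`` is used.  The one-proportion test
is the continuity-corrected normal z test against p0 = 0.5 (the null that a
significantly correlated target is equally likely inverse or positive); an
exact binomial variant is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .errors import ConsistencyError, UndefinedStatisticError
from .io import TargetMap
from .normalize import NormalizedMatrix
from .selection import SelectionResult

log = logging.getLogger(__name__)

EXACT_SPEARMAN_MAX_N = 8
_TIE_EPS = 1e-12

CORRELATION_COLUMNS = ["mirna", "gene", "rho", "p", "n", "class"]
PROPORTION_COLUMNS = [
    "mirna", "p", "ci_low", "ci_high", "inversely_related", "fgr_direction",
    "n_sig", "n_inverse",
]


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Raises :class:`UndefinedStatisticError` when either vector has zero rank
    variance (constant input).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    rx, ry = rankdata(x), rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise UndefinedStatisticError("zero rank variance: correlation undefined")
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    return float(np.clip(rho, -1.0, 1.0))


@lru_cache(maxsize=None)
def _exact_null_abs_rho(n: int) -> np.ndarray:
    """|rho| over all n! orderings of untied ranks 1..n (sorted ascending)."""
    base = np.arange(1, n + 1, dtype=float)
    c = base - base.mean()
    denom = (c ** 2).sum()
    perms = np.array(list(permutations(range(n))))
    rhos = (c[perms] * c[None, :]).sum(axis=1) / denom
    return np.sort(np.abs(rhos))


def spearman_pvalue(rho: float, n: int, method: str = "auto") -> float:
    """Two-sided p-value for a Spearman correlation of ``n`` observations.

    ``exact`` enumerates all n! equally likely rank orderings (untied ranks)
    and reports the fraction with |rho_perm| >= |rho| - 1e-12; ``t_approx``
    uses the t distribution with n - 2 degrees of freedom.  ``auto`` picks
    exact for n <= 8.
    """
    if not -1.0 - 1e-9 <= rho <= 1.0 + 1e-9:
        raise ValueError("|rho| must not exceed 1")
    rho = float(np.clip(rho, -1.0, 1.0))
    if n < 3:
        raise ValueError("need n >= 3")
    if method == "auto":
        method = "exact" if n <= EXACT_SPEARMAN_MAX_N else "t_approx"
    if method == "exact":
        null = _exact_null_abs_rho(n)
        k = np.searchsorted(null, abs(rho) - _TIE_EPS, side="left")
        return float((len(null) - k) / len(null))
    if method == "t_approx":
        if abs(rho) >= 1.0:
            return 0.0
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        return float(2.0 * stats.t.sf(abs(t), n - 2))
    raise ValueError(f"unknown method {method!r}")


def correlate_targets(
    mirna: str,
    targets,
    mirna_expr: NormalizedMatrix,
    mrna_expr: NormalizedMatrix,
    de_mrna_sig,
    alpha_corr: float = 0.05,
    method: str = "auto",
) -> pd.DataFrame:
    """Correlate one miRNA against its significantly DE targets.

    Targets outside ``de_mrna_sig`` or absent from the expression matrix are
    excluded (counts logged).  Correlation pools all samples of both groups.
    Each surviving pair is classified ``inverse`` (rho < 0, p < alpha_corr),
    ``positive`` (rho > 0, p < alpha_corr) or ``nonsignificant``.
    """
    if list(mirna_expr.sample_ids) != list(mrna_expr.sample_ids):
        raise ConsistencyError("miRNA and mRNA matrices must share the same samples in order")
    if mirna not in mirna_expr.values.index:
        raise ConsistencyError(f"miRNA {mirna!r} absent from expression matrix")
    de_mrna_sig = set(de_mrna_sig)
    x = mirna_expr.values.loc[mirna].to_numpy(dtype=float)
    n = len(x)
    records = []
    n_not_sig = n_absent = n_degenerate = 0
    for gene in targets:
        if gene not in de_mrna_sig:
            n_not_sig += 1
            continue
        if gene not in mrna_expr.values.index:
            n_absent += 1
            continue
        y = mrna_expr.values.loc[gene].to_numpy(dtype=float)
        try:
            rho = spearman_rho(x, y)
        except UndefinedStatisticError:
            n_degenerate += 1
            continue
        p = spearman_pvalue(rho, n, method=method)
        if p < alpha_corr:
            cls = "inverse" if rho < 0 else "positive"
        else:
            cls = "nonsignificant"
        records.append((mirna, gene, rho, p, n, cls))
    if n_not_sig or n_absent or n_degenerate:
        log.info(
            "correlate_targets(%s): excluded %d non-DE, %d absent, %d constant targets",
            mirna, n_not_sig, n_absent, n_degenerate,
        )
    return pd.DataFrame(records, columns=CORRELATION_COLUMNS)


# ---------------------------------------------------------------------------
# one-proportion test and exact interval
# ---------------------------------------------------------------------------

def one_proportion_test(x: int, n: int, p0: float = 0.5) -> tuple[float, float]:
    """Continuity-corrected one-proportion z test (two-sided).

    ``z = (|x/n - p0| - 1/(2n)) / sqrt(p0 (1 - p0) / n)`` with the corrected
    numerator floored at 0; the p-value is two-sided normal.
    """
    if n < 1:
        raise UndefinedStatisticError("one-proportion test undefined for n = 0")
    if not 0 <= x <= n:
        raise ValueError("x must lie in [0, n]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    num = max(abs(x / n - p0) - 1.0 / (2.0 * n), 0.0)
    z = num / np.sqrt(p0 * (1.0 - p0) / n)
    p = float(min(2.0 * stats.norm.sf(z), 1.0))
    return float(z), p


def one_proportion_test_exact(x: int, n: int, p0: float = 0.5) -> tuple[float, float]:
    """Exact binomial two-sided test; returns (p_hat, p)."""
    if n < 1:
        raise UndefinedStatisticError("one-proportion test undefined for n = 0")
    res = stats.binomtest(x, n, p0, alternative="two-sided")
    return x / n, float(res.pvalue)


def clopper_pearson_ci(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided binomial interval, in percent.

    Endpoints come from Beta-distribution quantiles; x = 0 pins the lower
    endpoint at 0 and x = n pins the upper at 100.  Full precision is
    returned; tables round to 2 decimals at write time.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError("x must lie in [0, n]")
    if not 0.0 < conf < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    a = 1.0 - conf
    low = 0.0 if x == 0 else float(stats.beta.ppf(a / 2.0, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1.0 - a / 2.0, x + 1, n - x))
    return 100.0 * low, 100.0 * high


def direction_call(n_inverse: int, n_positive: int) -> str:
    """Majority call on significantly correlated targets: YES (majority
    inverse), NO (majority positive) or EQUAL."""
    if n_inverse < 0 or n_positive < 0:
        raise ValueError("counts must be non-negative")
    if n_inverse > n_positive:
        return "YES"
    if n_inverse < n_positive:
        return "NO"
    return "EQUAL"


# ---------------------------------------------------------------------------
# full integration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntegrationResult:
    """Outputs of the integration stage.

    ``correlations``: one row per tested miRNA-target pair.
    ``proportion``: the Table-1-shaped per-miRNA proportion-test results.
    ``candidates``: regulator calls (proportion p < alpha_prop, direction
    YES) with their inverse-correlated target genes.
    """

    correlations: pd.DataFrame
    proportion: pd.DataFrame
    candidates: pd.DataFrame

    @property
    def candidate_regulators(self) -> frozenset[str]:
        return frozenset(self.candidates["mirna"])

    @property
    def candidate_pairs(self) -> frozenset[tuple[str, str]]:
        out = set()
        for row in self.candidates.itertuples():
            for gene in row.inverse_targets.split(";"):
                if gene:
                    out.add((row.mirna, gene))
        return frozenset(out)


def integrate(
    focus: SelectionResult,
    target_map: TargetMap,
    mirna_expr: NormalizedMatrix,
    mrna_expr: NormalizedMatrix,
    de_mirna: pd.DataFrame,
    de_mrna_sig,
    alpha_corr: float = 0.05,
    alpha_prop: float = 0.05,
    p0: float = 0.5,
    min_targets: int = 2,
    conf: float = 0.95,
    prop_method: str = "z",
    corr_method: str = "auto",
) -> IntegrationResult:
    """Run correlation + proportion testing for every focus miRNA.

    miRNAs with fewer than ``min_targets`` significantly correlated targets
    are excluded from testing (logged).  Output ordering is deterministic:
    proportion rows sort by p ascending then miRNA id; a miRNA enters the
    candidate set iff its proportion p < ``alpha_prop`` and its direction
    call is YES.
    """
    tmap = target_map.as_dict()
    de_dir = dict(zip(de_mirna["feature"], de_mirna["log2fc"]))
    corr_frames = []
    rows = []
    n_skipped = 0
    for mirna in focus.focus:
        if mirna not in de_dir:
            raise ConsistencyError(f"focus miRNA {mirna!r} absent from DE results")
        corr = correlate_targets(
            mirna, tmap.get(mirna, []), mirna_expr, mrna_expr, de_mrna_sig,
            alpha_corr=alpha_corr, method=corr_method,
        )
        corr_frames.append(corr)
        sig = corr[corr["class"] != "nonsignificant"]
        n_sig = len(sig)
        n_inverse = int((sig["class"] == "inverse").sum())
        n_positive = n_sig - n_inverse
        if n_sig < min_targets:
            n_skipped += 1
            continue
        if prop_method == "z":
            z, p = one_proportion_test(n_inverse, n_sig, p0)
        elif prop_method == "exact":
            z, p = one_proportion_test_exact(n_inverse, n_sig, p0)
        else:
            raise ValueError(f"unknown prop_method {prop_method!r}")
        ci_low, ci_high = clopper_pearson_ci(n_inverse, n_sig, conf)
        rows.append(
            {
                "mirna": mirna,
                "n_sig": n_sig,
                "n_inverse": n_inverse,
                "n_positive": n_positive,
                "p_hat": n_inverse / n_sig,
                "z": z,
                "p": p,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "inversely_related": direction_call(n_inverse, n_positive),
                "fgr_direction": "up" if de_dir[mirna] > 0 else "down",
            }
        )
    if n_skipped:
        log.info(
            "integrate: %d focus miRNAs had < %d significantly correlated targets",
            n_skipped, min_targets,
        )
    corr_frames = [f for f in corr_frames if len(f)]
    correlations = (
        pd.concat(corr_frames, ignore_index=True)
        if corr_frames
        else pd.DataFrame(columns=CORRELATION_COLUMNS)
    )
    prop = pd.DataFrame(
        rows,
        columns=[
            "mirna", "n_sig", "n_inverse", "n_positive", "p_hat", "z", "p",
            "ci_low", "ci_high", "inversely_related", "fgr_direction",
        ],
    )
    if len(prop):
        prop = prop.sort_values(["p", "mirna"], kind="mergesort").reset_index(drop=True)
    cand_rows = []
    for row in prop.itertuples():
        if row.p < alpha_prop and row.inversely_related == "YES":
            inv = correlations[
                (correlations["mirna"] == row.mirna) & (correlations["class"] == "inverse")
            ]["gene"]
            cand_rows.append(
                {
                    "mirna": row.mirna,
                    "fgr_direction": row.fgr_direction,
                    "n_inverse_targets": len(inv),
                    "inverse_targets": ";".join(inv),
                }
            )
    candidates = pd.DataFrame(
        cand_rows, columns=["mirna", "fgr_direction", "n_inverse_targets", "inverse_targets"]
    )
    log.info(
        "integrate: tested %d miRNAs, %d candidates (p < %g and majority-inverse)",
        len(prop), len(candidates), alpha_prop,
    )
    return IntegrationResult(correlations, prop, candidates)
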