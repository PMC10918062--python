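"""Count normalization: counts-per-million with optional TMM scale factors,
and log2 transformation.

TMM (trimmed mean of M-values) is computed from first principles: for each
sample, log2 expression ratios (M) against a reference sample are trimmed by
rank (30% on M, 5% on abundance A), and the surviving M values are combined
by a precision-weighted mean whose weights are the asymptotic inverse
variances of the log ratios.  Factors are rescaled to geometric mean 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import CountMatrix

log = logging.getLogger(__name__)

MIN_TMM_FEATURES = 10


@dataclass(frozen=True)
class NormalizedMatrix:
    """Normalized feature x sample matrix on the CPM scale (optionally log2)."""

    values: pd.DataFrame
    log2: bool = False
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("normalized values must be finite")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def cpm(counts: CountMatrix, tmm_factors: np.ndarray | list[float] | None = None) -> NormalizedMatrix:
    """Counts per million: ``counts / (library size * factor) * 1e6``.

    With all factors 1 (the default) each column sums to exactly 1e6.
    """
    df = counts.counts
    lib = df.sum(axis=0).to_numpy(dtype=float)
    for sample, size in zip(counts.sample_ids, lib):
        if size <= 0:
            raise ValueError(f"library size is zero for sample {sample!r}")
    if tmm_factors is None:
        factors = np.ones(len(lib))
    else:
        factors = np.asarray(tmm_factors, dtype=float)
        if factors.shape != lib.shape:
            raise ValueError("one TMM factor per sample required")
        if (factors <= 0).any():
            raise ValueError("TMM factors must be positive")
    values = df.to_numpy(dtype=float) / (lib * factors)[None, :] * 1e6
    return NormalizedMatrix(pd.DataFrame(values, index=df.index, columns=df.columns))


def _rank_trim_mask(values: np.ndarray, frac: float) -> np.ndarray:
    """Keep entries whose rank lies in the central (1 - 2*frac) band."""
    n = len(values)
    lo = np.floor(n * frac) + 1
    hi = n + 1 - lo
    r = rankdata(values)
    return (r >= lo) & (r <= hi)


def tmm_factors(
    counts: CountMatrix,
    ref_sample: str | None = None,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
) -> np.ndarray:
    """Per-sample TMM scale factors (geometric mean 1).

    The reference defaults to the sample whose 75th-percentile count fraction
    is closest to the mean of those fractions.  Features with a zero count in
    either member of a compared pair are excluded pairwise; if fewer than 10
    usable features remain the factor falls back to 1 with a warning.
    """
    df = counts.counts
    arr = df.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    if df.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    frac = arr / lib[None, :]
    if ref_sample is None:
        q75 = np.quantile(frac, 0.75, axis=0)
        ref = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        if ref_sample not in counts.sample_ids:
            raise ValueError(f"unknown reference sample {ref_sample!r}")
        ref = counts.sample_ids.index(ref_sample)

    factors = np.ones(df.shape[1])
    xr, nr = arr[:, ref], lib[ref]
    for s in range(df.shape[1]):
        if s == ref:
            continue
        xs, ns = arr[:, s], lib[s]
        usable = (xs > 0) & (xr > 0)
        if usable.sum() < MIN_TMM_FEATURES:
            log.warning(
                "TMM: only %d usable features for sample %s; factor set to 1",
                usable.sum(), counts.sample_ids[s],
            )
            continue
        ps, pr = xs[usable] / ns, xr[usable] / nr
        M = np.log2(ps / pr)
        A = 0.5 * np.log2(ps * pr)
        # near-identical compositions: no bias to correct
        if np.max(np.abs(M)) < 1e-6:
            continue
        keep = _rank_trim_mask(M, logratio_trim) & _rank_trim_mask(A, abundance_trim)
        if keep.sum() == 0:
            log.warning("TMM: trim removed all features for sample %s", counts.sample_ids[s])
            continue
        w = (ns - xs[usable]) / (ns * xs[usable]) + (nr - xr[usable]) / (nr * xr[usable])
        factors[s] = 2.0 ** (np.sum((M / w)[keep]) / np.sum((1.0 / w)[keep]))
    return factors / np.exp(np.mean(np.log(factors)))


def log2_transform(norm: NormalizedMatrix, pseudocount: float = 1.0) -> NormalizedMatrix:
    """``value <- log2(value + pseudocount)``; refuses -inf outcomes."""
    if norm.log2:
        raise ValueError("matrix is already log2-transformed")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    arr = norm.values.to_numpy()
    if pseudocount == 0 and (arr <= 0).any():
        raise ValueError("pseudocount 0 with zero values would produce -inf")
    out = np.log2(arr + pseudocount)
    return NormalizedMatrix(
        pd.DataFrame(out, index=norm.values.index, columns=norm.values.columns),
        log2=True,
        pseudocount=pseudocount,
    )
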