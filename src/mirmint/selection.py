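"""Abundance ranking of miRNAs in the case group and intersection with the
significant-DE set.

The focus set feeding the integration stage is the intersection of the top-N
most abundant miRNAs in the case group (N = 100 by default) with the miRNAs
called differentially expressed.  Abundance is the mean normalized (CPM)
count across the group's samples; ranking raw count sums instead is exposed
behind a flag for fidelity experiments, since raw sums confound library size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import ConsistencyError
from .io import SampleMetadata
from .normalize import NormalizedMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionResult:
    """Top-N abundance table and its intersection with the significant set.

    ``top`` has columns ``rank, mirna, group_mean, in_focus_set``; ``focus``
    lists the focus-set miRNAs preserving abundance order.
    """

    top: pd.DataFrame
    focus: tuple[str, ...]

    @property
    def n_top(self) -> int:
        return len(self.top)

    @property
    def n_focus(self) -> int:
        return len(self.focus)


def top_n_by_abundance(
    norm: NormalizedMatrix,
    meta: SampleMetadata,
    group: str,
    n: int = 100,
    ranking: str = "mean",
) -> pd.DataFrame:
    """Rank miRNAs by mean normalized count over the group's samples.

    Descending abundance; ties break by feature id ascending.  Returns
    ``min(n, n_features)`` rows with columns ``rank, mirna, group_mean``.
    ``ranking='sum'`` ranks by the per-group sum instead of the mean.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    samples = meta.samples_of(group)
    if not samples:
        raise ConsistencyError(f"group {group!r} absent from metadata")
    missing = [s for s in samples if s not in norm.values.columns]
    if missing:
        raise ConsistencyError(f"samples {missing} absent from matrix")
    sub = norm.values[samples]
    if ranking == "mean":
        score = sub.mean(axis=1)
    elif ranking == "sum":
        score = sub.sum(axis=1)
    else:
        raise ValueError(f"unknown ranking {ranking!r}")
    order = sorted(zip(norm.feature_ids, score), key=lambda t: (-t[1], t[0]))[:n]
    return pd.DataFrame(
        {
            "rank": range(1, len(order) + 1),
            "mirna": [m for m, _ in order],
            "group_mean": [v for _, v in order],
        }
    )


def intersect_with_de(top: pd.DataFrame, de: pd.DataFrame, alpha: float) -> SelectionResult:
    """Intersect the abundance top-N with the DE-significant miRNAs.

    Every top miRNA must appear in the DE table; significance is re-derived
    as ``p < alpha``.  Focus-set ordering preserves the abundance ranking.
    """
    de_p = dict(zip(de["feature"], de["p"]))
    missing = [m for m in top["mirna"] if m not in de_p]
    if missing:
        raise ConsistencyError(f"top miRNAs absent from DE results: {missing[:5]}")
    in_focus = [de_p[m] < alpha for m in top["mirna"]]
    table = top.copy()
    table["in_focus_set"] = in_focus
    focus = tuple(m for m, f in zip(top["mirna"], in_focus) if f)
    if not focus:
        log.warning("selection: focus set is empty; downstream stages will be vacuous")
    log.info("selection: %d of top %d miRNAs are significant", len(focus), len(top))
    return SelectionResult(table, focus)
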