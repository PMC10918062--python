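"""Seeded two-omics simulator with planted differential expression and
inverse miRNA -> target coupling.

The generator emulates a two-group bulk small-RNA study (control vs
caloric-restricted, a few biological replicates per group) together with a
matched mRNA expression matrix and a predicted target map, so that every
downstream stage of the pipeline can be scored against known ground truth.

Model
-----
Counts are negative-binomial.  Each feature f draws a baseline mean
``mu_f ~ LogNormal(mean_log_mu, sd_log_mu)``.  Sample s of feature f has mean

    mu_fs = mu_f * lib_s * 2**(g_s * lfc_f + c_fs)

where ``g_s`` is 1 in the restricted group, ``lfc_f`` the planted signed log2
fold change (0 for non-DE features), ``lib_s`` a per-sample library factor,
and ``c_fs`` the coupling shift (mRNAs only, see below).  The variance is
``mu + phi * mu**2`` with dispersion ``phi = nb_dispersion``.

A fixed fraction of miRNAs is differentially expressed; a subset of those
("regulators") additionally represses targets.  Regulators are planted among
the most abundant miRNAs, mirroring studies that restrict attention to the
top miRNAs by count.  For each regulator, a fraction ``frac_inverse_targets``
of its predicted targets is inversely coupled and the remainder positively
coupled: target t of regulator r is shifted by ``sign * coupling_strength *
z_s`` log2 units, where ``z_s`` is the regulator's standardized per-sample
latent log2 expression and sign is -1 (inverse) or +1 (positive).

Regulator target sets are drawn disjoint from each other, so every planted
pair carries a single unambiguous coupling sign; non-regulator miRNAs may
still share predicted targets freely.

All draws flow from a single ``numpy.random.default_rng(seed)`` in a fixed
order (baseline means, DE assignment, regulator abundances, library factors,
target map, disjoint regulator target re-draw, coupling signs, counts), so
identical seeds give identical datasets byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtri

from .errors import ConfigurationError
from .io import (
    CountMatrix,
    SampleMetadata,
    TargetMap,
    write_count_matrix,
    write_metadata,
    write_target_map,
)

log = logging.getLogger(__name__)

CONTROL = "control"
RESTRICTED = "restricted"


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults emulate the study scale (1546 miRNAs,
    two groups of 3 placentas, 16 abundant regulator miRNAs)."""

    n_mirna: int = 1546
    n_mrna: int = 5000
    n_per_group: int = 3
    frac_de_mirna: float = 0.15
    lfc_de: float = 2.0
    targets_per_mirna: int = 20
    n_regulators: int = 16
    frac_inverse_targets: float = 0.75
    coupling_strength: float = 1.5
    nb_dispersion: float = 0.1
    mean_log_mu: float = 6.0
    sd_log_mu: float = 1.5
    lib_size_factor_range: tuple[float, float] = (0.7, 1.3)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_mirna, self.n_mrna, self.n_per_group, self.targets_per_mirna) <= 0:
            raise ConfigurationError("sizes must be positive")
        for name in ("frac_de_mirna", "frac_inverse_targets"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.targets_per_mirna > self.n_mrna:
            raise ConfigurationError("targets_per_mirna exceeds the mRNA pool")
        if self.n_regulators * self.targets_per_mirna > self.n_mrna:
            raise ConfigurationError(
                "regulator target sets are disjoint: n_regulators * targets_per_mirna "
                "must not exceed n_mrna"
            )
        n_de = round(self.n_mirna * self.frac_de_mirna)
        if self.n_regulators > n_de:
            raise ConfigurationError(
                f"n_regulators={self.n_regulators} exceeds planted DE miRNAs ({n_de})"
            )
        lo, hi = self.lib_size_factor_range
        if not (0 < lo <= hi):
            raise ConfigurationError("lib_size_factor_range must be positive and ordered")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one simulated dataset.

    ``de_lfc`` maps each planted DE miRNA to its signed log2 fold change;
    ``regulators`` is the subset that represses targets; ``regulated_pairs``
    maps each coupled (miRNA, gene) pair to its sign (-1 inverse, +1 positive).
    """

    de_lfc: Mapping[str, float]
    regulators: frozenset[str]
    regulated_pairs: Mapping[tuple[str, str], int]

    @property
    def inverse_pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset(p for p, s in self.regulated_pairs.items() if s < 0)


@dataclass(frozen=True)
class SimDataset:
    mirna: CountMatrix
    mrna: CountMatrix
    metadata: SampleMetadata
    target_map: TargetMap
    truth: SyntheticTruth
    config: SimConfig


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_dataset(config: SimConfig) -> SimDataset:
    """Generate one seeded dataset (miRNA counts, mRNA counts, metadata,
    target map, truth)."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    n_s = 2 * cfg.n_per_group
    samples = [f"ctrl_{i + 1}" for i in range(cfg.n_per_group)] + [
        f"restr_{i + 1}" for i in range(cfg.n_per_group)
    ]
    groups = [CONTROL] * cfg.n_per_group + [RESTRICTED] * cfg.n_per_group
    g = np.array([0] * cfg.n_per_group + [1] * cfg.n_per_group, dtype=float)
    meta = SampleMetadata(tuple(samples), tuple(groups))

    mirna_ids = [f"miR-{i + 1:04d}" for i in range(cfg.n_mirna)]
    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_mrna)]

    # 1. baseline means
    mu_mi = rng.lognormal(cfg.mean_log_mu, cfg.sd_log_mu, cfg.n_mirna)
    mu_mr = rng.lognormal(cfg.mean_log_mu, cfg.sd_log_mu, cfg.n_mrna)

    # 2. planted DE miRNAs with signed log2 fold changes
    n_de = round(cfg.n_mirna * cfg.frac_de_mirna)
    de_idx = rng.choice(cfg.n_mirna, size=n_de, replace=False) if n_de else np.array([], int)
    de_signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc = np.zeros(cfg.n_mirna)
    lfc[de_idx] = de_signs * cfg.lfc_de

    # 3. regulators: a subset of the DE miRNAs, re-seated in the abundance
    # upper tail so they survive a top-N-by-count cut like the real study's
    reg_idx = (
        rng.choice(de_idx, size=cfg.n_regulators, replace=False)
        if cfg.n_regulators
        else np.array([], int)
    )
    if cfg.n_regulators:
        q = rng.uniform(0.997, 0.9999, size=cfg.n_regulators)
        mu_mi[reg_idx] = np.exp(cfg.mean_log_mu + cfg.sd_log_mu * ndtri(q))

    # 4. per-sample library factors (independent per assay)
    lo, hi = cfg.lib_size_factor_range
    lib_mi = rng.uniform(lo, hi, n_s)
    lib_mr = rng.uniform(lo, hi, n_s)

    # 5. target map: each miRNA draws targets without replacement
    target_idx = np.vstack(
        [rng.choice(cfg.n_mrna, size=cfg.targets_per_mirna, replace=False)
         for _ in range(cfg.n_mirna)]
    )
    pairs = tuple(
        (mirna_ids[i], gene_ids[j]) for i in range(cfg.n_mirna) for j in target_idx[i]
    )
    target_map = TargetMap(pairs)

    # 6. regulator target sets are re-drawn disjoint so every planted pair
    # carries a single unambiguous coupling sign
    used = np.zeros(cfg.n_mrna, dtype=bool)
    for i in sorted(reg_idx):
        avail = np.flatnonzero(~used)
        tgt = rng.choice(avail, size=cfg.targets_per_mirna, replace=False)
        target_idx[i] = tgt
        used[tgt] = True
    if len(reg_idx):
        pairs = tuple(
            (mirna_ids[i], gene_ids[j]) for i in range(cfg.n_mirna) for j in target_idx[i]
        )
        target_map = TargetMap(pairs)

    # 7. coupling: shift each regulator's targets by +/- coupling * z
    coupling = np.zeros((cfg.n_mrna, n_s))
    regulated: dict[tuple[str, str], int] = {}
    n_inv = round(cfg.frac_inverse_targets * cfg.targets_per_mirna)
    for i in sorted(reg_idx):
        latent = np.log2(mu_mi[i]) + g * lfc[i]
        sd = latent.std()
        z = (latent - latent.mean()) / sd if sd > 0 else np.zeros(n_s)
        tgt = target_idx[i]
        perm = rng.permutation(cfg.targets_per_mirna)
        for k, t in enumerate(tgt[perm]):
            sign = -1 if k < n_inv else 1
            coupling[t] += sign * cfg.coupling_strength * z
            regulated[(mirna_ids[i], gene_ids[t])] = sign

    # 8. counts
    mean_mi = mu_mi[:, None] * lib_mi[None, :] * 2.0 ** (g[None, :] * lfc[:, None])
    mean_mr = mu_mr[:, None] * lib_mr[None, :] * 2.0 ** coupling
    counts_mi = _nb_draw(rng, mean_mi, cfg.nb_dispersion)
    counts_mr = _nb_draw(rng, mean_mr, cfg.nb_dispersion)

    truth = SyntheticTruth(
        de_lfc={mirna_ids[i]: float(lfc[i]) for i in sorted(de_idx)},
        regulators=frozenset(mirna_ids[i] for i in reg_idx),
        regulated_pairs=regulated,
    )
    mirna = CountMatrix(pd.DataFrame(counts_mi, index=mirna_ids, columns=samples))
    mrna = CountMatrix(pd.DataFrame(counts_mr, index=gene_ids, columns=samples))
    log.info(
        "simulated %d miRNAs x %d samples (%d DE, %d regulators), %d mRNAs",
        cfg.n_mirna, n_s, n_de, cfg.n_regulators, cfg.n_mrna,
    )
    return SimDataset(mirna, mrna, meta, target_map, truth, cfg)


@dataclass(frozen=True)
class RecoveryReport:
    """Precision/recall of called regulators and called pairs against truth.

    By convention an empty called set has precision 1.0 and an empty truth
    set has recall 1.0 (degenerate cases are logged).
    """

    regulator_precision: float
    regulator_recall: float
    pair_precision: float
    pair_recall: float
    n_called_regulators: int
    n_true_regulators: int
    n_called_pairs: int
    n_true_pairs: int


def _prec_recall(called: frozenset, truth: frozenset, what: str) -> tuple[float, float]:
    if not called:
        log.info("recovery: empty called %s set; precision = 1.0 by convention", what)
        precision = 1.0
    else:
        precision = len(called & truth) / len(called)
    if not truth:
        log.info("recovery: empty truth %s set; recall = 1.0 by convention", what)
        recall = 1.0
    else:
        recall = len(called & truth) / len(truth)
    return precision, recall


def recovery_report(
    truth: SyntheticTruth,
    called_regulators: frozenset[str] | set[str],
    called_pairs: frozenset[tuple[str, str]] | set[tuple[str, str]],
) -> RecoveryReport:
    """Score called regulators and called inverse pairs against ground truth."""
    called_regulators = frozenset(called_regulators)
    called_pairs = frozenset(called_pairs)
    true_pairs = truth.inverse_pairs
    rp, rr = _prec_recall(called_regulators, truth.regulators, "regulator")
    pp, pr = _prec_recall(called_pairs, true_pairs, "pair")
    return RecoveryReport(
        rp, rr, pp, pr,
        len(called_regulators), len(truth.regulators),
        len(called_pairs), len(true_pairs),
    )


def write_dataset(ds: SimDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the four pipeline inputs plus truth tables and the resolved config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirna_counts": outdir / "mirna_counts.tsv",
        "mrna_counts": outdir / "mrna_counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "target_map": outdir / "target_map.tsv",
        "truth_de": outdir / "truth_de_mirnas.tsv",
        "truth_pairs": outdir / "truth_regulated_pairs.tsv",
        "sim_config": outdir / "sim_config.yaml",
    }
    write_count_matrix(ds.mirna, paths["mirna_counts"])
    write_count_matrix(ds.mrna, paths["mrna_counts"])
    write_metadata(ds.metadata, paths["metadata"])
    write_target_map(ds.target_map, paths["target_map"])
    lines = ["mirna\tlog2fc\tregulator"]
    for m, v in ds.truth.de_lfc.items():
        reg = "true" if m in ds.truth.regulators else "false"
        lines.append(f"{m}\t{v:.6g}\t{reg}")
    paths["truth_de"].write_text("\n".join(lines) + "\n", encoding="utf-8")
    lines = ["mirna\tgene\tsign"]
    for (m, gene), s in sorted(ds.truth.regulated_pairs.items()):
        lines.append(f"{m}\t{gene}\t{'inverse' if s < 0 else 'positive'}")
    paths["truth_pairs"].write_text("\n".join(lines) + "\n", encoding="utf-8")
    cfg = asdict(ds.config)
    cfg["lib_size_factor_range"] = list(cfg["lib_size_factor_range"])
    paths["sim_config"].write_text(yaml.safe_dump(cfg, sort_keys=True), encoding="utf-8")
    return paths


def read_truth(de_path: str | Path, pairs_path: str | Path) -> SyntheticTruth:
    de = pd.read_csv(de_path, sep="\t")
    pairs = pd.read_csv(pairs_path, sep="\t")
    return SyntheticTruth(
        de_lfc={r.mirna: float(r.log2fc) for r in de.itertuples()},
        regulators=frozenset(de.loc[de.regulator.astype(str).str.lower() == "true", "mirna"]),
        regulated_pairs={
            (r.mirna, r.gene): (-1 if r.sign == "inverse" else 1) for r in pairs.itertuples()
        },
    )
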