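"""End-to-end orchestration of the pipeline stages with a single run
configuration, file-based stage hand-off, and a hash manifest.

A run directory holds ``inputs/`` (either simulated or copied-by-reference
from configured paths), one TSV per stage output, the resolved run
configuration, and ``manifest.json`` recording the SHA-256 of every output so
two runs with the same config and seed can be compared byte-for-byte.

Stages communicate through files only, so ``run-all`` is exactly equivalent
to invoking the stage commands in sequence.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .de import DE_COLUMNS, de_anova, de_chisq, de_fisher, de_ttest, summarize_de
from .errors import ConfigurationError
from .integration import integrate
from .io import (
    read_count_matrix,
    read_metadata,
    read_target_map,
    write_results_table,
)
from .normalize import NormalizedMatrix, cpm, log2_transform, tmm_factors
from .selection import intersect_with_de, top_n_by_abundance
from .simulate import (
    CONTROL,
    RESTRICTED,
    SimConfig,
    generate_dataset,
    read_truth,
    recovery_report,
    write_dataset,
)

log = logging.getLogger(__name__)

RUN_CONFIG_FILE = "run_config.yaml"
INPUT_DIR = "inputs"


@dataclass
class RunConfig:
    """Run-level configuration; defaults mirror the study's constants
    (top_n = 100, alpha = 0.05, null proportion 0.5)."""

    out_dir: str = "run"
    mirna_counts: str | None = None
    mrna_counts: str | None = None
    metadata: str | None = None
    target_map: str | None = None
    group_control: str = CONTROL
    group_case: str = RESTRICTED
    test: str = "ttest"  # ttest | anova | fisher | chisq
    alpha_de: float = 0.05
    alpha_corr: float = 0.05
    alpha_prop: float = 0.05
    p0: float = 0.5
    top_n: int = 100
    min_targets: int = 2
    normalization: str = "cpm+tmm"  # cpm | cpm+tmm
    pseudocount: float = 1.0
    prop_method: str = "z"  # z | exact
    strip_species_prefix: bool = False
    seed: int = 0
    simulate: dict | None = None

    def validate(self) -> None:
        for name in ("alpha_de", "alpha_corr", "alpha_prop"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1)")
        if not 0.0 < self.p0 < 1.0:
            raise ConfigurationError("p0 must lie in (0, 1)")
        if self.top_n < 1:
            raise ConfigurationError("top_n must be >= 1")
        if self.test not in ("ttest", "anova", "fisher", "chisq"):
            raise ConfigurationError(f"unknown test {self.test!r}")
        if self.normalization not in ("cpm", "cpm+tmm"):
            raise ConfigurationError(f"unknown normalization {self.normalization!r}")
        if self.simulate is None:
            missing = [
                name
                for name in ("mirna_counts", "mrna_counts", "metadata", "target_map")
                if getattr(self, name) is None or not Path(getattr(self, name)).exists()
            ]
            if missing:
                raise ConfigurationError(f"missing input paths: {missing}")

    def sim_config(self) -> SimConfig:
        sim = dict(self.simulate or {})
        sim.setdefault("seed", self.seed)
        if "lib_size_factor_range" in sim:
            sim["lib_size_factor_range"] = tuple(sim["lib_size_factor_range"])
        return SimConfig(**sim)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def _rundir(config: RunConfig) -> Path:
    d = Path(config.out_dir)
    d.mkdir(parents=True, exist_ok=True)
    return d


def save_run_config(config: RunConfig) -> Path:
    d = _rundir(config)
    path = d / RUN_CONFIG_FILE
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True), encoding="utf-8")
    return path


def load_run_config(rundir: str | Path) -> RunConfig:
    path = Path(rundir) / RUN_CONFIG_FILE
    if not path.exists():
        raise ConfigurationError(f"no {RUN_CONFIG_FILE} in {rundir}; run simulate/run-all first")
    cfg = RunConfig(**yaml.safe_load(path.read_text(encoding="utf-8")))
    cfg.out_dir = str(rundir)
    return cfg


# ---------------------------------------------------------------------------
# stages (each reads its inputs from disk and writes its outputs to disk)
# ---------------------------------------------------------------------------

def _input_paths(config: RunConfig) -> dict[str, Path]:
    d = Path(config.out_dir) / INPUT_DIR
    if config.simulate is not None or d.exists():
        return {
            "mirna_counts": d / "mirna_counts.tsv",
            "mrna_counts": d / "mrna_counts.tsv",
            "metadata": d / "metadata.tsv",
            "target_map": d / "target_map.tsv",
            "truth_de": d / "truth_de_mirnas.tsv",
            "truth_pairs": d / "truth_regulated_pairs.tsv",
        }
    return {
        "mirna_counts": Path(config.mirna_counts),
        "mrna_counts": Path(config.mrna_counts),
        "metadata": Path(config.metadata),
        "target_map": Path(config.target_map),
        "truth_de": Path("/nonexistent"),
        "truth_pairs": Path("/nonexistent"),
    }


def stage_simulate(config: RunConfig) -> None:
    ds = generate_dataset(config.sim_config())
    write_dataset(ds, Path(config.out_dir) / INPUT_DIR)
    log.info("simulate: wrote inputs under %s", Path(config.out_dir) / INPUT_DIR)


def _write_matrix_tsv(norm: NormalizedMatrix, path: Path) -> None:
    df = norm.values.reset_index().rename(columns={"index": "feature"})
    write_results_table(df, path)


def _read_matrix_tsv(path: Path, log2: bool) -> NormalizedMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return NormalizedMatrix(df.astype(float), log2=log2)


def stage_normalize(config: RunConfig) -> None:
    paths = _input_paths(config)
    d = _rundir(config)
    for assay in ("mirna", "mrna"):
        counts = read_count_matrix(paths[f"{assay}_counts"])
        factors = tmm_factors(counts) if config.normalization == "cpm+tmm" else None
        norm = cpm(counts, factors)
        logged = log2_transform(norm, config.pseudocount)
        _write_matrix_tsv(norm, d / f"normalized_{assay}_cpm.tsv")
        _write_matrix_tsv(logged, d / f"normalized_{assay}_log2.tsv")
    log.info("normalize: wrote CPM and log2 matrices (%s)", config.normalization)


def _run_de(config: RunConfig, assay: str) -> pd.DataFrame:
    paths = _input_paths(config)
    d = Path(config.out_dir)
    meta = read_metadata(paths["metadata"])
    a, b = config.group_control, config.group_case
    if config.test in ("ttest", "anova"):
        norm = _read_matrix_tsv(d / f"normalized_{assay}_log2.tsv", log2=True)
        if config.test == "ttest":
            return de_ttest(norm, meta, a, b, alpha=config.alpha_de)
        return de_anova(norm, meta, [a, b], alpha=config.alpha_de)
    counts = read_count_matrix(paths[f"{assay}_counts"])
    fn = de_fisher if config.test == "fisher" else de_chisq
    return fn(counts, meta, a, b, alpha=config.alpha_de)


def stage_de(config: RunConfig) -> None:
    d = _rundir(config)
    for assay in ("mirna", "mrna"):
        res = _run_de(config, assay)
        write_results_table(res, d / f"de_{assay}.tsv", columns=DE_COLUMNS)
        if assay == "mirna":
            s = summarize_de(res, config.alpha_de)
            write_results_table(
                pd.DataFrame([vars(s)]),
                d / "de_summary.tsv",
                columns=[
                    "n_total", "n_significant", "n_up", "n_down",
                    "pct_significant", "pct_up", "pct_down",
                ],
            )
            log.info(
                "de: %d/%d miRNAs significant at alpha=%g (%s test)",
                s.n_significant, s.n_total, config.alpha_de, config.test,
            )


def stage_select(config: RunConfig) -> None:
    paths = _input_paths(config)
    d = _rundir(config)
    meta = read_metadata(paths["metadata"])
    norm = _read_matrix_tsv(d / "normalized_mirna_cpm.tsv", log2=False)
    de = pd.read_csv(d / "de_mirna.tsv", sep="\t")
    top = top_n_by_abundance(norm, meta, config.group_case, n=config.top_n)
    sel = intersect_with_de(top, de, config.alpha_de)
    write_results_table(
        sel.top, d / "selection.tsv", columns=["rank", "mirna", "group_mean", "in_focus_set"]
    )


def stage_integrate(config: RunConfig) -> None:
    paths = _input_paths(config)
    d = _rundir(config)
    mirna_log2 = _read_matrix_tsv(d / "normalized_mirna_log2.tsv", log2=True)
    mrna_log2 = _read_matrix_tsv(d / "normalized_mrna_log2.tsv", log2=True)
    tmap = read_target_map(
        paths["target_map"], strip_species_prefix=config.strip_species_prefix
    )
    de_mirna = pd.read_csv(d / "de_mirna.tsv", sep="\t")
    de_mrna = pd.read_csv(d / "de_mrna.tsv", sep="\t")
    de_mrna_sig = set(de_mrna.loc[de_mrna["p"] < config.alpha_de, "feature"])
    sel_table = pd.read_csv(d / "selection.tsv", sep="\t")
    from .selection import SelectionResult

    focus = SelectionResult(
        sel_table, tuple(sel_table.loc[sel_table["in_focus_set"], "mirna"])
    )
    result = integrate(
        focus, tmap, mirna_log2, mrna_log2, de_mirna, de_mrna_sig,
        alpha_corr=config.alpha_corr, alpha_prop=config.alpha_prop,
        p0=config.p0, min_targets=config.min_targets,
        prop_method=config.prop_method,
    )
    write_results_table(
        result.correlations, d / "correlations.tsv",
        columns=["mirna", "gene", "rho", "p", "n", "class"],
    )
    write_results_table(
        result.proportion, d / "proportion.tsv",
        columns=[
            "mirna", "p", "ci_low", "ci_high", "inversely_related",
            "fgr_direction", "n_sig", "n_inverse",
        ],
    )
    write_results_table(
        result.candidates, d / "candidates.tsv",
        columns=["mirna", "fgr_direction", "n_inverse_targets", "inverse_targets"],
    )
    if paths["truth_de"].exists() and paths["truth_pairs"].exists():
        truth = read_truth(paths["truth_de"], paths["truth_pairs"])
        rep = recovery_report(truth, result.candidate_regulators, result.candidate_pairs)
        write_results_table(
            pd.DataFrame([vars(rep)]), d / "recovery.tsv",
            columns=list(vars(rep).keys()),
        )
        log.info(
            "recovery: regulator precision %.3f recall %.3f",
            rep.regulator_precision, rep.regulator_recall,
        )


MANIFEST_OUTPUTS = [
    "normalized_mirna_cpm.tsv", "normalized_mirna_log2.tsv",
    "normalized_mrna_cpm.tsv", "normalized_mrna_log2.tsv",
    "de_mirna.tsv", "de_mrna.tsv", "de_summary.tsv", "selection.tsv",
    "correlations.tsv", "proportion.tsv", "candidates.tsv", "recovery.tsv",
]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(config: RunConfig) -> Path:
    d = Path(config.out_dir)
    outputs = {}
    for name in MANIFEST_OUTPUTS:
        p = d / name
        if p.exists():
            outputs[name] = _sha256(p)
    inputs = {}
    ind = d / INPUT_DIR
    if ind.exists():
        for p in sorted(ind.iterdir()):
            inputs[p.name] = _sha256(p)
    cfg = config.to_dict()
    cfg.pop("out_dir")  # path-independent manifests
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": cfg,
        "inputs": inputs,
        "outputs": outputs,
    }
    path = d / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path


STAGES = ("simulate", "normalize", "de", "select", "integrate")


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages in order and write the manifest.

    Returns the manifest path.  Identical config + seed gives byte-identical
    stage outputs and manifest hashes.
    """
    config.validate()
    save_run_config(config)
    stage_fns = {
        "simulate": stage_simulate,
        "normalize": stage_normalize,
        "de": stage_de,
        "select": stage_select,
        "integrate": stage_integrate,
    }
    for name in STAGES:
        if name == "simulate" and config.simulate is None:
            continue
        try:
            stage_fns[name](config)
        except Exception as exc:
            raise type(exc)(f"stage {name!r}: {exc}") from exc
    return write_manifest(config)
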