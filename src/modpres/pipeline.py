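"""End-to-end pipeline driver.

Ties the stages together for a multi-condition study: preprocessing per
condition, signed network construction (fixed or automatically selected soft
power), module detection on the reference network, preservation of the
reference modules in each test network, differential preservation between the
two test networks, and a plain-text report.  Everything is reproducible from
the single seed in the configuration: per-stage sub-seeds are derived
deterministically and all outputs are TSV with fixed formatting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .datasets import ExpressionDataset
from .modules import ModulePartition, detect_modules
from .network import (
    CoexpressionNetwork,
    correlation_matrix,
    select_soft_threshold,
    signed_adjacency,
)
from .preprocess import preprocess_pipeline
from .preservation import (
    ModulePreservation,
    ModulePreservationResults,
    cross_tabulate,
    delta_z_summary,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Configuration of a full differential-preservation run."""

    conditions: Dict[str, Dict[str, str]]  # name -> {expression: path, metadata: path}
    reference: str
    test_conditions: List[str] = field(default_factory=list)
    percentile: float = 5.0
    outlier_z_cut: float = -2.5
    already_log: bool = True
    covariates: List[str] = field(default_factory=lambda: ["age", "sex"])
    beta: Optional[Dict[str, int]] = None  # fixed soft power per condition
    beta_grid: List[int] = field(default_factory=lambda: list(range(1, 21)))
    target_fit: float = 0.90
    min_module_size: int = 30
    cut_height_quantile: float = 0.99
    min_gap_fraction: float = 0.05
    n_perm: int = 500
    seed: int = 0
    out_dir: str = "modpres_out"

    def __post_init__(self) -> None:
        if self.reference not in self.conditions:
            raise PipelineError(f"reference condition {self.reference!r} not configured")
        if not self.test_conditions:
            self.test_conditions = [c for c in self.conditions if c != self.reference]
        unknown = [c for c in self.test_conditions if c not in self.conditions]
        if unknown:
            raise PipelineError(f"unknown test conditions: {unknown}")
        if self.reference in self.test_conditions:
            raise PipelineError("the reference cannot be its own test condition")
        if not 1 <= len(self.test_conditions) <= 2:
            raise PipelineError(
                "differential preservation needs one or two test conditions"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "conditions": self.conditions,
            "reference": self.reference,
            "test_conditions": self.test_conditions,
            "percentile": self.percentile,
            "outlier_z_cut": self.outlier_z_cut,
            "already_log": self.already_log,
            "covariates": self.covariates,
            "beta": self.beta,
            "beta_grid": self.beta_grid,
            "target_fit": self.target_fit,
            "min_module_size": self.min_module_size,
            "cut_height_quantile": self.cut_height_quantile,
            "min_gap_fraction": self.min_gap_fraction,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "out_dir": self.out_dir,
        }


@dataclass
class PipelineBundle:
    """In-memory results of one pipeline run."""

    config: PipelineConfig
    datasets: Dict[str, ExpressionDataset]
    networks: Dict[str, CoexpressionNetwork]
    betas: Dict[str, int]
    partitions: Dict[str, ModulePartition]
    preservation: Dict[str, ModulePreservationResults]
    differential: Optional[pd.DataFrame]
    log: Dict[str, object]
    out_dir: Path


def _sub_seed(seed: int, k: int) -> int:
    """Deterministic 31-bit sub-seed for stage k."""
    return int(np.random.SeedSequence(seed).generate_state(k + 1)[k] % (2**31))


def run_pipeline(config: PipelineConfig) -> PipelineBundle:
    """Execute preprocess -> network -> modules -> preservation ->
    differential -> report, writing every stage's tables under
    ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: Dict[str, object] = {"config": config.to_dict(), "stages": {}}
    stage = "load"
    try:
        datasets: Dict[str, ExpressionDataset] = {}
        for cond, paths in config.conditions.items():
            datasets[cond] = ExpressionDataset.from_tsv(
                paths["expression"], paths.get("metadata")
            )

        stage = "preprocess"
        for cond in list(datasets):
            ds, info = preprocess_pipeline(
                datasets[cond],
                percentile=config.percentile,
                already_log=config.already_log,
                covariates=config.covariates,
                outlier_z_cut=config.outlier_z_cut,
            )
            info.pop("sample_tree", None)
            datasets[cond] = ds
            log["stages"][f"preprocess.{cond}"] = info

        # test networks must live on the reference's post-filter gene universe
        stage = "harmonize"
        shared = datasets[config.reference].gene_ids
        for cond in datasets:
            shared = shared.intersection(datasets[cond].gene_ids)
        shared = datasets[config.reference].gene_ids[
            datasets[config.reference].gene_ids.isin(shared)
        ]
        for cond in list(datasets):
            datasets[cond] = datasets[cond].subset_genes(shared)
        log["stages"]["harmonize"] = {"n_shared_genes": int(len(shared))}

        stage = "network"
        networks: Dict[str, CoexpressionNetwork] = {}
        betas: Dict[str, int] = {}
        for cond, ds in datasets.items():
            cor = correlation_matrix(ds)
            if config.beta and cond in config.beta:
                beta = int(config.beta[cond])
                scan_info = {"fixed": True}
            else:
                scan = select_soft_threshold(
                    cor, grid=config.beta_grid, target=config.target_fit
                )
                beta = scan.selected_beta
                scan.to_frame().to_csv(
                    out / f"soft_threshold_{cond}.tsv", sep="\t", index=False,
                    float_format="%.6g",
                )
                scan_info = {
                    "fixed": False,
                    "target_reached": scan.target_reached,
                }
            networks[cond] = signed_adjacency(cor, beta)
            betas[cond] = beta
            log["stages"][f"network.{cond}"] = {"beta": beta, **scan_info}

        stage = "modules"
        partitions: Dict[str, ModulePartition] = {}
        for cond in [config.reference] + config.test_conditions:
            part, _ = detect_modules(
                datasets[cond],
                networks[cond],
                min_module_size=config.min_module_size,
                cut_height_quantile=config.cut_height_quantile,
                min_gap_fraction=config.min_gap_fraction,
            )
            partitions[cond] = part
            part.to_frame().to_csv(
                out / f"modules_{cond}.tsv", sep="\t", float_format="%.6g",
                index_label="gene_id", na_rep="NA",
            )
            if part.eigengenes is not None:
                part.eigengenes.to_csv(
                    out / f"eigengenes_{cond}.tsv", sep="\t",
                    float_format="%.6g", index_label="module",
                )
            log["stages"][f"modules.{cond}"] = {
                "sizes": {k: int(v) for k, v in part.sizes().items()}
            }

        ref_part = partitions[config.reference]
        if not ref_part.module_names:
            raise PipelineError("no modules detected in the reference network")

        stage = "cross_tabulation"
        for cond in config.test_conditions:
            ct = cross_tabulate(ref_part.labels, partitions[cond].labels)
            ct.counts.to_csv(out / f"crosstab_counts_{cond}.tsv", sep="\t")
            ct.neg_log10_p.to_csv(
                out / f"crosstab_neglog10p_{cond}.tsv", sep="\t", float_format="%.6g"
            )

        stage = "preservation"
        preservation: Dict[str, ModulePreservationResults] = {}
        for k, cond in enumerate(config.test_conditions):
            model = ModulePreservation(
                datasets[config.reference],
                networks[config.reference],
                ref_part,
                datasets[cond],
                networks[cond],
            )
            res = model.fit(n_perm=config.n_perm, seed=_sub_seed(config.seed, k))
            res.to_tsv(out / f"preservation_{cond}.tsv")
            preservation[cond] = res
            log["stages"][f"preservation.{cond}"] = {
                "n_perm": config.n_perm,
                "seed": _sub_seed(config.seed, k),
            }

        stage = "differential"
        differential = None
        if len(config.test_conditions) == 2:
            a, b = config.test_conditions
            diff = delta_z_summary(preservation[a], preservation[b])
            differential = diff.sorted()
            diff.to_tsv(out / "differential.tsv")
        else:
            logger.warning(
                "only one test condition configured; differential stage skipped"
            )
            log["stages"]["differential"] = "skipped (one test condition)"

        stage = "report"
        with open(out / "run_log.yaml", "w") as fh:
            yaml.safe_dump(log, fh, sort_keys=True)
        report = render_report(out)
        (out / "report.txt").write_text(report)
        return PipelineBundle(
            config=config,
            datasets=datasets,
            networks=networks,
            betas=betas,
            partitions=partitions,
            preservation=preservation,
            differential=differential,
            log=log,
            out_dir=out,
        )
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc


# --------------------------------------------------------------------------- #
# reporting (rendered from the saved TSVs, so regeneration from a run
# directory reproduces the original report byte for byte)


def render_report(out_dir) -> str:
    """Build the textual run summary from a run directory's saved tables:
    the differential table sorted by delta_z (GOP first), per-test
    preservation blocks, and the strongest cross-tabulation overlaps."""
    out = Path(out_dir)
    with open(out / "run_log.yaml") as fh:
        log = yaml.safe_load(fh)
    cfg = log["config"]
    reference, tests = cfg["reference"], cfg["test_conditions"]
    lines: List[str] = []
    lines.append("Differential module preservation report")
    lines.append(
        f"reference={reference!r}  tests={tests}  "
        f"seed={cfg['seed']}  n_perm={cfg['n_perm']}"
    )
    betas = {
        c: log["stages"][f"network.{c}"]["beta"]
        for c in cfg["conditions"]
        if f"network.{c}" in log["stages"]
    }
    lines.append("betas: " + ", ".join(f"{c}={b}" for c, b in betas.items()))
    ref_sizes = log["stages"][f"modules.{reference}"]["sizes"]
    named = sorted(
        ((m, s) for m, s in ref_sizes.items() if m != "grey"), key=lambda t: -t[1]
    )
    lines.append(
        "reference modules: "
        + ", ".join(f"{m}({s})" for m, s in named)
        + f", grey({ref_sizes.get('grey', 0)})"
    )
    lines.append("")

    modules_tsv = pd.read_csv(out / f"modules_{reference}.tsv", sep="\t", index_col=0)

    def top_hubs(module: str, k: int = 3) -> str:
        sub = modules_tsv[(modules_tsv["module"] == module) & (modules_tsv.get("hub", 0) == 1)]
        return ";".join(sub.sort_values("kIM", ascending=False).index[:k])

    diff_path = out / "differential.tsv"
    if diff_path.exists():
        a, b = tests
        diff = pd.read_csv(diff_path, sep="\t", index_col=0)
        diff = diff.sort_values("delta_z", ascending=False)
        diff["hubs"] = [top_hubs(m) for m in diff.index]
        lines.append(
            f"Differential preservation delta_z = Z_summary[{a}] - Z_summary[{b}] "
            "(sorted by delta_z; positive = GOP, negative = LOP):"
        )
        lines.append(diff.to_string(float_format=lambda v: f"{v:.2f}"))
        lines.append("")
    for cond in tests:
        table = pd.read_csv(out / f"preservation_{cond}.tsv", sep="\t", index_col=0)
        lines.append(f"Preservation of reference modules in {cond!r}:")
        show = table[
            ["size", "Z_density", "Z_connectivity", "Z_summary", "well_preserved"]
        ]
        lines.append(show.to_string(float_format=lambda v: f"{v:.2f}"))
        lines.append("")
    for cond in tests:
        path = out / f"crosstab_neglog10p_{cond}.tsv"
        if path.exists():
            neglog = pd.read_csv(path, sep="\t", index_col=0)
            counts = pd.read_csv(
                out / f"crosstab_counts_{cond}.tsv", sep="\t", index_col=0
            )
            top = neglog.stack().sort_values(ascending=False).head(5)
            lines.append(f"Top module overlaps with {cond!r} (-log10 Fisher p):")
            for (r, c), v in top.items():
                lines.append(
                    f"  {r} ~ {c}: overlap={int(counts.at[r, c])}, -log10 p={v:.1f}"
                )
            lines.append("")
    return "\n".join(lines)
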