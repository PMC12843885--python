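"""End-to-end orchestration of the green- and black-tea analyses.

``run_green`` executes bin -> filter -> normalise -> random-forest
selection -> trend clustering -> formula assignment -> per-cluster
functional and structural enrichment on a 6-stage design and writes
cluster/pathway reports.  ``run_black`` repeats selection, clustering and
enrichment once per oxidation arm (4 h, overnight) and adds the
arm-differential Welch/BH comparisons at the oxidation and roasting
stages, with direction-split enrichment.

Every step logs its feature counts into a RunReport; reports are written
as TSV with fixed float formatting, so reruns under the same seed are
byte-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .binning import FeatureMatrix, build_feature_matrix, occupancy_filter, qc_filter
from .clustering import kmeans
from .enrichment import (
    EnrichmentConfig,
    functional_enrichment,
    structural_enrichment,
)
from .errors import PipelineError
from .formulas import (
    Assignment,
    assign_feature,
    class_frequency_table,
    classify_assignment,
    load_adduct_rules,
)
from .preprocess import (
    percent_relative_abundance,
    stage_mean_profiles,
    weight_normalise,
)
from .selection import (
    RFConfig,
    differential_features,
    encode_stage_response,
    select_features,
)
from .synthetic import SimulationConfig, SyntheticDataset, simulate_dataset, simulate_spectra

_FLOAT_FORMAT = "%.8g"


@dataclass
class PipelineConfig:
    """Everything one run needs; synthetic unless paths are supplied."""

    seed: int
    simulation: SimulationConfig | None = None
    outdir: str = "teametab-run"
    bin_width: float = 0.01
    mz_range: tuple = (55.0, 1200.0)
    occupancy_threshold: float = 2 / 3
    qc_max_rsd: float = 0.5
    normalise_mode: str = "dry-mass"
    ppm_tol: float = 3.0
    element_ranges: dict | None = None
    n_trees: int = 1000
    n_trees_null: int | None = 200
    n_permutations: int = 3000
    max_features: object = "third"
    alpha: float = 0.05
    k: int = 15
    consensus_threshold: float = 0.66
    structural_level: int = 2
    damping: float = 0.85
    n_null: int = 1000
    p_threshold: float = 0.05
    assign_scope: str = "selected"  # "selected" | "all"


@dataclass
class RunReport:
    seed: int
    version: str = __version__
    params: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    manifest: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "version": self.version,
                "params": self.params,
                "counts": self.counts,
                "manifest": self.manifest,
            },
            indent=2,
            sort_keys=True,
        )


def _write(report: RunReport, outdir: str, name: str, frame: pd.DataFrame) -> None:
    path = os.path.join(outdir, name)
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT)
    report.manifest.append(name)


def _prepare_matrix(cfg: PipelineConfig, dataset: SyntheticDataset, report: RunReport):
    """Spectra -> binning -> occupancy/QC filters -> weight normalisation."""
    design = dataset.design
    stages = list(dataset.config.stages)
    present = set(design.loc[~design["is_qc"].astype(bool), "stage"])
    missing = [s for s in stages if s not in present]
    if missing:
        raise PipelineError(f"binning: design lacks samples for stage(s) {missing}")
    spectra = simulate_spectra(dataset.matrix, dataset.config)
    matrix = build_feature_matrix(spectra, cfg.bin_width, cfg.mz_range)
    report.counts["features_binned"] = matrix.n_features
    labels = {}
    for _, row in design.iterrows():
        arm = row["arm"]
        arm_tag = "" if pd.isna(arm) or arm in (None, "") else f"-{arm}"
        labels[row["sample_id"]] = (
            "QC" if row["is_qc"] else f"{row['stage']}{arm_tag}"
        )
    matrix = occupancy_filter(matrix, labels, cfg.occupancy_threshold)
    report.counts["features_after_occupancy"] = matrix.n_features
    qc_ids = list(design.loc[design["is_qc"].astype(bool), "sample_id"])
    if len(qc_ids) >= 2:
        matrix = qc_filter(matrix, qc_ids, cfg.qc_max_rsd)
    report.counts["features_after_qc"] = matrix.n_features
    matrix = weight_normalise(matrix, design, mode=cfg.normalise_mode)
    return matrix


def _assign_features(cfg: PipelineConfig, matrix: FeatureMatrix, feature_ids, snapshot):
    rules = load_adduct_rules()
    assignments: dict[str, Assignment] = {}
    for fid in feature_ids:
        info = matrix.feature_info.loc[fid]
        a = assign_feature(
            fid,
            float(info["accurate_mz"]),
            str(info["polarity"]),
            rules,
            element_ranges=cfg.element_ranges,
            ppm_tol=cfg.ppm_tol,
        )
        assignments[fid] = classify_assignment(a, snapshot, cfg.consensus_threshold)
    return assignments


def _assignment_table(assignments: dict) -> pd.DataFrame:
    rows = []
    for fid in sorted(assignments):
        a = assignments[fid]
        best = a.best
        rows.append(
            {
                "feature": fid,
                "mz": a.mz,
                "polarity": a.polarity,
                "formula": best.formula if best else "",
                "adduct": best.adduct if best else "",
                "ppm": best.ppm if best else float("nan"),
                "n_candidates": len(a.candidates),
                "compounds": ";".join(best.compounds) if best else "",
                "tier": best.tier or "" if best else "",
                "consensus": "/".join(a.consensus_path),
                "consensus_depth": a.consensus_depth,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def summarise_classes(assignments) -> pd.DataFrame:
    """Level-to-level consensus-class flow counts (Sankey input).

    One flow per feature per adjacent level pair its consensus reaches;
    level-k node totals therefore match the class-frequency table.
    """
    from collections import Counter

    values = assignments.values() if isinstance(assignments, dict) else assignments
    flows: Counter = Counter()
    for a in values:
        for level in range(1, a.consensus_depth):
            flows[(level, a.consensus_path[level - 1], a.consensus_path[level])] += 1
    rows = [
        {"level": lvl, "source": src, "target": dst, "count": n}
        for (lvl, src, dst), n in sorted(flows.items())
    ]
    return pd.DataFrame(rows, columns=["level", "source", "target", "count"])


def _select_cluster_enrich(
    cfg: PipelineConfig,
    matrix: FeatureMatrix,
    dataset: SyntheticDataset,
    report: RunReport,
    arm: str | None,
    tag: str,
    outdir: str,
):
    """Shared selection -> clustering -> assignment -> enrichment block."""
    stages = list(dataset.config.stages)
    try:
        response = encode_stage_response(dataset.design, stages, arm=arm)
    except Exception as exc:
        raise PipelineError(f"encode{tag}: {exc}") from exc
    rf_cfg = RFConfig(
        seed=cfg.seed,
        n_trees=cfg.n_trees,
        max_features=cfg.max_features,
        n_permutations=cfg.n_permutations,
        n_trees_null=cfg.n_trees_null,
        alpha=cfg.alpha,
    )
    selection = select_features(matrix, response, rf_cfg)
    report.counts[f"selected{tag}"] = len(selection.selected)
    _write(
        report,
        outdir,
        f"selection{tag}.tsv",
        selection.importance.rename_axis("feature"),
    )
    report.params[f"model_r2{tag}"] = round(selection.model_r2, 6)
    report.params[f"model_p{tag}"] = selection.model_p
    selected = selection.selected
    if not selected:
        return selection, None, {}
    means = stage_mean_profiles(matrix.subset(selected), dataset.design, stages, arm=arm)
    profiles = percent_relative_abundance(means)
    k = min(cfg.k, max(1, len(profiles) - 1))
    clusters = kmeans(profiles, k=k, seed=cfg.seed)
    report.counts[f"clusters{tag}"] = clusters.k
    _write(
        report,
        outdir,
        f"clusters{tag}.tsv",
        clusters.labels.rename("cluster").rename_axis("feature").to_frame(),
    )
    _write(report, outdir, f"centroids{tag}.tsv", clusters.centroids)
    scope = selected if cfg.assign_scope == "selected" else list(matrix.values.index)
    assignments = _assign_features(cfg, matrix, scope, dataset.library)
    _write(report, outdir, f"assignments{tag}.tsv", _assignment_table(assignments))
    _write(
        report,
        outdir,
        f"class_frequencies{tag}.tsv",
        class_frequency_table(list(assignments.values())).set_index("level"),
    )
    _write(report, outdir, f"sankey{tag}.tsv", summarise_classes(assignments).set_index("level"))
    feature_compounds = {
        fid: (a.best.compounds if a.best else []) for fid, a in assignments.items()
    }
    enr_cfg = EnrichmentConfig(
        seed=cfg.seed,
        damping=cfg.damping,
        n_null=cfg.n_null,
        p_threshold=cfg.p_threshold,
    )
    functional = functional_enrichment(
        clusters.members, feature_compounds, dataset.graph, enr_cfg
    )
    _write(report, outdir, f"functional_enrichment{tag}.tsv", functional.set_index("cluster"))
    consensus = {fid: a.consensus_path for fid, a in assignments.items()}
    structural_rows = []
    background = [f for f in scope]
    for cluster_id, members in clusters.members.items():
        try:
            ora = structural_enrichment(
                members, background, consensus, level=cfg.structural_level
            )
        except Exception:
            continue
        ora.insert(0, "cluster", cluster_id)
        structural_rows.append(ora)
    structural = (
        pd.concat(structural_rows, ignore_index=True)
        if structural_rows
        else pd.DataFrame(columns=["cluster", "label", "a", "b", "c", "d", "p", "q"])
    )
    _write(report, outdir, f"structural_enrichment{tag}.tsv", structural.set_index("cluster"))
    return selection, clusters, assignments


def run_green(cfg: PipelineConfig) -> RunReport:
    """Full single-arm (green-tea style) analysis on a 6-stage design."""
    if cfg.simulation is None:
        raise PipelineError("run_green: no input configured (simulation is None)")
    dataset = simulate_dataset(cfg.simulation)
    os.makedirs(cfg.outdir, exist_ok=True)
    report = RunReport(seed=cfg.seed)
    report.params.update({"design": "green", "stages": list(dataset.config.stages)})
    matrix = _prepare_matrix(cfg, dataset, report)
    _select_cluster_enrich(cfg, matrix, dataset, report, arm=None, tag="", outdir=cfg.outdir)
    with open(os.path.join(cfg.outdir, "report.json"), "w") as fh:
        fh.write(report.to_json())
        fh.write("\n")
    return report


def run_black(cfg: PipelineConfig) -> RunReport:
    """Two-arm (black-tea style) analysis: arm-wise modelling + differentials."""
    if cfg.simulation is None:
        raise PipelineError("run_black: no input configured (simulation is None)")
    sim = cfg.simulation
    if not sim.arms or len(sim.arms) != 2:
        raise PipelineError("run_black: simulation must declare exactly 2 arms")
    dataset = simulate_dataset(sim)
    os.makedirs(cfg.outdir, exist_ok=True)
    report = RunReport(seed=cfg.seed)
    report.params.update(
        {"design": "black", "stages": list(sim.stages), "arms": list(sim.arms)}
    )
    matrix = _prepare_matrix(cfg, dataset, report)
    for arm in sim.arms:
        _select_cluster_enrich(
            cfg, matrix, dataset, report, arm=arm, tag=f"_{arm}", outdir=cfg.outdir
        )
    arm_a, arm_b = sim.arms
    enr_cfg = EnrichmentConfig(
        seed=cfg.seed, damping=cfg.damping, n_null=cfg.n_null, p_threshold=cfg.p_threshold
    )
    diff_functional = []
    for stage in sim.arm_split_stages:
        comparison = f"{stage} ({arm_a})~{stage} ({arm_b})"
        diff = differential_features(matrix, dataset.design, stage, arm_a, arm_b, cfg.alpha)
        _write(report, cfg.outdir, f"differential_{stage}.tsv", diff)
        report.counts[f"differential_{stage}"] = int(diff["significant"].sum())
        sig = diff[diff["significant"]]
        if not len(sig):
            continue
        assignments = _assign_features(cfg, matrix, list(sig.index), dataset.library)
        feature_compounds = {
            fid: (a.best.compounds if a.best else []) for fid, a in assignments.items()
        }
        for trend in ("decreased", "increased"):
            members = list(sig.index[sig["direction"] == trend])
            if not members:
                continue
            table = functional_enrichment(
                {trend: members}, feature_compounds, dataset.graph, enr_cfg
            )
            if len(table):
                table.insert(0, "comparison", comparison)
                table = table.rename(columns={"cluster": "trend"})
                diff_functional.append(table)
    functional = (
        pd.concat(diff_functional, ignore_index=True)
        if diff_functional
        else pd.DataFrame(columns=["comparison", "trend", "id", "name", "type", "p_score"])
    )
    _write(
        report, cfg.outdir, "differential_enrichment.tsv", functional.set_index("comparison")
    )
    with open(os.path.join(cfg.outdir, "report.json"), "w") as fh:
        fh.write(report.to_json())
        fh.write("\n")
    return report
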