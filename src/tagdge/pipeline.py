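"""End-to-end orchestration: simulate/ingest -> RPKM -> DEG screens ->
enrichment -> network -> qPCR check -> clustering and Venn summaries.

``run_all`` drives every stage, writes each stage's table under the output
directory, and emits a machine-readable ``summary.json`` whose counts can
be re-derived from the stage tables. Given the same inputs, config and
seed, two runs produce byte-identical outputs.

Contrast convention: the first-named condition of a contrast is the
control/denominator, so log2 ratios are treatment over control.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from . import __version__
from .coexpr_network import build_network, write_sif
from .data_model import (
    AnnotationMap,
    ConfigurationError,
    ExpressionMatrix,
    read_annotation_map,
    read_count_table,
    read_design,
    write_annotation_map,
    write_count_table,
    write_table,
)
from .enrichment import enrich, wego_tabulate
from .group_deg import build_noise_distribution, screen_group
from .normalization import rpkm_matrix
from .pairwise_deg import screen_pairwise
from .synthetic_data import (
    SimulationConfig,
    simulate_experiment,
    simulate_qpcr,
    write_truth,
)
from .validation_qpcr import concordance, relative_expression_from_table

__all__ = ["PipelineConfig", "run_all", "venn_partition", "cluster_expression"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, contrasts and thresholds of one full analysis run.

    Either ``sim`` (synthetic mode, the default) or ``counts_path`` +
    ``design_path`` (+ optional ``annotation_paths``) must be provided.
    ``contrasts`` is a list of (name, control_condition,
    treatment_condition) triples; when empty, a default set is derived from
    the condition labels.
    """

    outdir: str = "results/run"
    seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    counts_path: str | None = None
    design_path: str | None = None
    annotation_paths: dict[str, str] = field(default_factory=dict)
    contrasts: list[tuple[str, str, str]] = field(default_factory=list)
    q_max: float = 0.001
    min_abs_log2: float = 1.0
    noiseq_q: float = 0.8
    noise_scope: str = "all"  # "all" | "pair"
    alpha: float = 0.05
    r_min: float = 0.99
    network_q_max: float = 0.05
    network_max_genes: int = 500
    heatmap_max_genes: int = 200
    qpcr_targets: int = 10


def venn_partition(named_sets: Mapping[str, set]) -> dict[str, int]:
    """Exclusive-region counts for 2 or 3 named sets.

    Keys are '&'-joined sorted set names; every region (including empty
    ones) is reported, and the counts sum to the size of the union.
    """
    names = sorted(named_sets)
    if not 2 <= len(names) <= 3:
        raise ValueError(f"venn_partition supports 2 or 3 sets, got {len(names)}")
    sets = {k: set(v) for k, v in named_sets.items()}
    regions: dict[str, int] = {}
    from itertools import combinations

    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(*(sets[c] for c in names if c not in combo), set())
            regions["&".join(combo)] = len(inside - outside)
    return regions


def cluster_expression(log2_ratios: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Hierarchically cluster genes (rows) by their log2-ratio profiles.

    Average linkage on Euclidean row distances; rows are pre-sorted by gene
    id so that tie-breaking is deterministic. Returns the leaf-ordered gene
    list and the linkage matrix.
    """
    if log2_ratios.shape[0] < 2:
        raise ValueError("need >= 2 genes to cluster")
    arr = log2_ratios.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("log2 ratios must be finite")
    df = log2_ratios.sort_index(kind="stable")
    Z = linkage(
        df.to_numpy(dtype=float), method="average", metric="euclidean",
        optimal_ordering=True,
    )
    order = leaves_list(Z)
    return [df.index[i] for i in order], Z


def _default_contrasts(labels: Sequence[str]) -> list[tuple[str, str, str]]:
    """Treatment-wise contrasts per genotype plus genotype-wise per treatment."""
    split = [l.split("_", 1) for l in labels]
    if all(len(p) == 2 for p in split):
        genotypes = sorted({p[0] for p in split})
        treatments = [p[1] for p in split]
        treatments = sorted(set(treatments), key=treatments.index)
        out: list[tuple[str, str, str]] = []
        base = treatments[0]
        for g in genotypes:
            for t in treatments[1:]:
                if f"{g}_{base}" in labels and f"{g}_{t}" in labels:
                    out.append((f"{g}_{t}_vs_{base}", f"{g}_{base}", f"{g}_{t}"))
        if len(genotypes) == 2:
            ga, gb = genotypes
            for t in treatments:
                if f"{ga}_{t}" in labels and f"{gb}_{t}" in labels:
                    out.append((f"{gb}_vs_{ga}_{t}", f"{ga}_{t}", f"{gb}_{t}"))
        if out:
            return out
    return [(f"{b}_vs_{labels[0]}", labels[0], b) for b in labels[1:]]


def _load_inputs(config: PipelineConfig, outdir: Path):
    """Simulate (default) or read the experiment; returns all inputs."""
    if config.counts_path is None:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        genes, libraries, annotations, truth = simulate_experiment(sim)
        design = {lib.sample_id: (f"{lib.genotype}_{lib.treatment}" if lib.genotype else lib.treatment, lib.replicate) for lib in libraries}
        write_count_table(genes, libraries, outdir / "counts.tsv")
        with open(outdir / "design.tsv", "w", encoding="utf-8") as fh:
            fh.write("sample_id\tcondition\treplicate\n")
            for lib in libraries:
                cond, rep = design[lib.sample_id]
                fh.write(f"{lib.sample_id}\t{cond}\t{rep}\n")
        for ns, amap in annotations.items():
            write_annotation_map(amap, outdir / f"annotation_{ns}.tsv")
        write_truth(truth, outdir)
        return genes, libraries, annotations, truth, design
    if config.design_path is None:
        raise ConfigurationError("counts_path requires design_path")
    genes, libraries = read_count_table(config.counts_path)
    design = read_design(config.design_path)
    for lib in libraries:
        if lib.sample_id not in design:
            raise ConfigurationError(f"sample {lib.sample_id} missing from design")
        cond, rep = design[lib.sample_id]
        lib.treatment, lib.replicate = cond, rep
    annotations = {
        ns: read_annotation_map(p, ns) for ns, p in sorted(config.annotation_paths.items())
    }
    return genes, libraries, annotations, None, design


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; write tables and ``summary.json`` under the outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genes, libraries, annotations, truth, design = _load_inputs(config, outdir)
    by_id = {lib.sample_id: lib for lib in libraries}
    conditions: list[str] = []
    for lib in libraries:
        c = design[lib.sample_id][0]
        if c not in conditions:
            conditions.append(c)
    contrasts = config.contrasts or _default_contrasts(conditions)
    for name, ca, cb in contrasts:
        for c in (ca, cb):
            if c not in conditions:
                raise ConfigurationError(f"contrast {name}: unknown condition {c!r}")

    expr = rpkm_matrix(libraries, genes)
    expr.values.round(6).to_csv(outdir / "rpkm.tsv", sep="\t", float_format="%.6g")

    condition_of = lambda s: design[s][0]  # noqa: E731
    reps_of = {c: [s for s in expr.samples if design[s][0] == c] for c in conditions}
    noise_all = None
    if config.noise_scope == "all" and any(len(v) >= 2 for v in reps_of.values()):
        noise_all = build_noise_distribution(expr, condition_of)

    summary: dict = {
        "n_genes": len(genes),
        "n_libraries": len(libraries),
        "contrasts": {},
    }
    deg_by_contrast: dict[str, dict[str, float]] = {}
    up_sets: dict[str, set] = {}
    down_sets: dict[str, set] = {}
    q_best: dict[str, float] = {}

    for name, ctl, trt in contrasts:
        lib1 = by_id[reps_of[ctl][0]]
        lib2 = by_id[reps_of[trt][0]]
        records = screen_pairwise(lib1, lib2, genes, config.q_max, config.min_abs_log2)
        write_table(records, outdir / f"deg_{name}.tsv")
        up = {r.gene_id for r in records if r.direction == "up"}
        down = {r.gene_id for r in records if r.direction == "down"}
        up_sets[name], down_sets[name] = up, down
        deg_by_contrast[name] = {r.gene_id: r.log2_ratio for r in records}
        for r in records:
            if r.direction != "ns":
                q_best[r.gene_id] = min(q_best.get(r.gene_id, 1.0), r.q_fdr)
        entry: dict = {"up": len(up), "down": len(down)}

        if len(reps_of[ctl]) >= 2 or len(reps_of[trt]) >= 2:
            noise = noise_all if noise_all is not None else None
            group = screen_group(
                expr, condition_of, trt, ctl, config.noiseq_q, noise=noise
            )
            write_table(group, outdir / f"group_{name}.tsv")
            entry["group_called"] = sum(r.called for r in group)

        deg_set = up | down
        for ns in ("GO_BP", "KEGG"):
            if ns in annotations and deg_set:
                recs = enrich(deg_set, annotations[ns], config.alpha)
                write_table(recs, outdir / f"enrich_{name}_{ns}.tsv")
                entry[f"significant_terms_{ns}"] = sum(r.significant for r in recs)
        summary["contrasts"][name] = entry

    # WEGO-style GO-domain tabulation for the first contrast's up/down sets
    first = contrasts[0][0]
    go_maps = [annotations[ns] for ns in ("GO_BP", "GO_CC", "GO_MF") if ns in annotations]
    if go_maps:
        wego = wego_tabulate(go_maps, {f"{first}_up": up_sets[first], f"{first}_down": down_sets[first]})
        wego.to_csv(outdir / "wego.tsv", sep="\t", index=False)
        summary["wego_rows"] = int(len(wego))

    # co-expression network over called DEGs (plus the planted module when known)
    node_pool = sorted(q_best, key=lambda g: (q_best[g], g))[: config.network_max_genes]
    nodes = set(node_pool)
    if truth is not None:
        nodes |= truth.module_genes
    edges = []
    if len(nodes) >= 2 and len(expr.samples) >= 3:
        edges = build_network(expr, config.r_min, config.network_q_max, genes=nodes)
    write_table(edges, outdir / "network_edges.tsv")
    write_sif(edges, outdir / "network.sif")
    summary["network_nodes"] = len(nodes)
    summary["network_edges"] = len(edges)

    # qPCR sign-concordance check against the first chromium-bearing contrast
    if truth is not None and truth.de_genes:
        qpcr_contrast = next(
            (n for n, _c, t in contrasts if t in config.sim.de_conditions), first
        )
        measurements = simulate_qpcr(truth, n_targets=config.qpcr_targets, seed=config.seed + 1)
        rel = relative_expression_from_table(measurements, treatment_label=qpcr_contrast)
        write_table(rel, outdir / "qpcr_relative_expression.tsv")
        conc = concordance(rel, deg_by_contrast[qpcr_contrast])
        summary["qpcr_contrast"] = qpcr_contrast
        summary["qpcr_concordance"] = conc

    # clustered log2-ratio heatmap matrix over the strongest DEGs
    heat_genes = sorted(q_best, key=lambda g: (q_best[g], g))[: config.heatmap_max_genes]
    if len(heat_genes) >= 2:
        mat = pd.DataFrame(
            {name: [deg_by_contrast[name][g] for g in heat_genes] for name, _a, _b in contrasts},
            index=pd.Index(heat_genes, name="gene_id"),
        )
        order, _ = cluster_expression(mat)
        out = mat.loc[order].copy()
        out["mean_sign"] = np.sign(out.mean(axis=1)).astype(int)
        out.to_csv(outdir / "heatmap.tsv", sep="\t", float_format="%.6g")
        summary["heatmap_genes"] = len(order)

    # Venn partition of up/down sets over the first two-or-three contrasts
    venn_names = [n for n, _a, _b in contrasts[:3]]
    if len(venn_names) >= 2:
        summary["venn_up"] = venn_partition({n: up_sets[n] for n in venn_names})
        summary["venn_down"] = venn_partition({n: down_sets[n] for n in venn_names})

    run_log = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "q_max": config.q_max,
            "min_abs_log2": config.min_abs_log2,
            "noiseq_q": config.noiseq_q,
            "alpha": config.alpha,
            "r_min": config.r_min,
            "network_q_max": config.network_q_max,
        },
        "noise_scope": config.noise_scope,
        "contrasts": [list(c) for c in contrasts],
        "clustering": "average linkage, Euclidean distance",
    }
    with open(outdir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
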