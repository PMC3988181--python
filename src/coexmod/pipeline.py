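"""Pipeline orchestration, tissue expression profiles and overlap arithmetic.

``run_pipeline`` chains the stages — synthetic-data generation (or loading),
outlier screening, network construction with a density-guided cutoff,
topology diagnostics, module detection, GO enrichment, promoter motif
discovery and tissue profiles — writing every intermediate as a
tab-separated artifact.  Outputs are pure functions of (inputs, config,
seed); each stage draws from its own named substream of the root seed so
that toggling one stage never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import cisreg, goenrich, io as cio, moddetect, netbuild, preprocess, syndata, topology

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "tissue_profiles",
    "overlap_stats",
    "run_pipeline",
]

log = logging.getLogger("coexmod")

_STAGE_SEEDS = {"moddetect": 11, "probe_map": 12}


def tissue_profiles(
    x: pd.DataFrame, tissue_of_sample: pd.Series, genes: list[str] | None = None
) -> pd.DataFrame:
    """Per-gene log2 ratio of tissue-mean signal to the mean of tissue means.

    For each gene, the value for tissue ``t`` is ``log2(S_t / mean_t(S_t))``
    where ``S_t`` is the mean signal over that tissue's samples.  Genes whose
    per-tissue means are not all positive are dropped with a warning.
    """
    missing = set(x.columns) - set(tissue_of_sample.index)
    if missing:
        raise ValueError(f"samples without a tissue assignment: {sorted(missing)[:5]}")
    if genes is not None:
        x = x.loc[genes]
    by_tissue = x.T.groupby(tissue_of_sample.reindex(x.columns)).mean().T
    bad = (by_tissue <= 0).any(axis=1)
    if bad.any():
        import warnings

        warnings.warn(
            f"{int(bad.sum())} gene(s) with nonpositive tissue-mean signal dropped",
            stacklevel=2,
        )
        by_tissue = by_tissue[~bad]
    grand = by_tissue.mean(axis=1)
    return np.log2(by_tissue.div(grand, axis=0))


def overlap_stats(set_a: set, set_b: set) -> tuple[int, float, float]:
    """Overlap count and percentages of each set, rounded to 1 decimal.

    Percentages are ``100 * |A ∩ B| / |set|``; an empty set reports NaN.
    """
    common = len(set(set_a) & set(set_b))

    def pct(size: int) -> float:
        return round(100.0 * common / size, 1) if size else float("nan")

    return common, pct(len(set_a)), pct(len(set_b))


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-data pipeline run."""

    out_dir: str | Path = "coexmod_out"
    seed: int = 0
    syn: syndata.SynConfig | None = None
    outlier_k: float = 1.5
    cutoff_grid: tuple[float, ...] = tuple(netbuild.DEFAULT_CUTOFF_GRID)
    cutoff_offset: float = 0.05
    cutoff: float | None = None  # overrides the density-guided choice
    min_module_size: int = 3
    alpha_go: float = 0.05
    alpha_motif: float = 0.05
    keywords: tuple[str, ...] = ("cell wall",)
    motif_ks: tuple[int, ...] = (6, 8)
    motif_top: int = 10
    catalog_path: str | Path | None = None
    run_topology: bool = True
    run_enrich: bool = True
    run_cisreg: bool = True
    run_profiles: bool = True
    min_delta_q: float = 1e-6

    def resolved_syn(self) -> syndata.SynConfig:
        cfg = self.syn if self.syn is not None else syndata.SynConfig(seed=self.seed)
        return dataclasses.replace(cfg, seed=self.seed)


@dataclass
class PipelineResult:
    config: PipelineConfig
    expression: pd.DataFrame
    weights: pd.Series
    scan: pd.DataFrame
    cutoff: float
    network: netbuild.CoexpressionNetwork
    partition: moddetect.ModulePartition
    summary: pd.DataFrame
    report: topology.TopologyReport | None = None
    enrichment: pd.DataFrame | None = None
    selected_modules: list[int] = field(default_factory=list)
    motif_tables: dict[int, pd.DataFrame] = field(default_factory=dict)
    profiles: pd.DataFrame | None = None
    ari: float | None = None
    flagged_arrays: list[str] = field(default_factory=list)


def _planted_ari(partition: moddetect.ModulePartition, truth: pd.Series) -> float:
    """ARI between detected modules and planted labels over assigned nodes.

    Background genes carry no planted co-membership, so each gets its own
    singleton truth label; the score then measures recovery of the planted
    modules (both merging and fragmenting planted modules depress it).
    """
    nodes = sorted(partition.assignment)
    detected = [partition.assignment[n] for n in nodes]
    aligned = truth.reindex(nodes).fillna(-1).astype(int)
    planted = [
        int(lbl) if lbl >= 0 else -(i + 1) for i, lbl in enumerate(aligned.to_numpy())
    ]
    return float(adjusted_rand_score(planted, detected))


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute all enabled stages on a synthetic compendium; write artifacts."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    syn = cfg.resolved_syn()

    log.info("stage simulate: %d genes x %d samples", syn.n_genes, syn.n_samples)
    x = syndata.simulate_expression(syn)
    ann = syndata.simulate_annotation(syn)
    truth = syn.module_labels()
    cio.write_expression(x, out / "expression.tsv")
    cio.write_annotation(ann, out / "annotation.tsv")
    truth.rename_axis("gene_id").reset_index().to_csv(
        out / "truth_modules.tsv", sep="\t", index=False
    )

    log.info("stage preprocess: outlier screening")
    flagged = preprocess.flag_outlier_arrays(x, k=cfg.outlier_k)
    if flagged:
        x = x.drop(columns=flagged)
        log.info("dropped %d outlier array(s)", len(flagged))

    log.info("stage netbuild: weights, density scan, network")
    w = netbuild.sample_weights(x)
    corr = netbuild.weighted_corr_matrix(x, w)
    scan = netbuild.density_scan(x, w, np.asarray(cfg.cutoff_grid), corr=corr)
    cutoff = cfg.cutoff if cfg.cutoff is not None else netbuild.select_cutoff(
        scan, cfg.cutoff_offset
    )
    net = netbuild.build_network(x, w, cutoff, corr=corr)
    w.rename_axis("sample_id").reset_index().to_csv(
        out / "sample_weights.tsv", sep="\t", index=False, float_format="%.6f"
    )
    scan.to_csv(out / "density_scan.tsv", sep="\t", index=False, float_format="%.6g")
    net.write_edges(out / "edges.tsv")
    log.info("network: %d nodes, %d edges at cutoff %.2f", net.n_nodes, net.n_edges, cutoff)

    report = None
    if cfg.run_topology:
        log.info("stage topology")
        report = topology.topology_report(net)
        report.to_frame().to_csv(out / "topology.tsv", sep="\t", index=False,
                                 float_format="%.6g")
        report.degree_hist.to_csv(out / "degree_hist.tsv", sep="\t", index=False)
        report.ck_curve.to_csv(out / "ck_curve.tsv", sep="\t", index=False,
                               float_format="%.6g")

    log.info("stage moddetect")
    partition = moddetect.detect_modules(
        net, min_delta_q=cfg.min_delta_q, seed=_substream(cfg.seed, "moddetect")
    )
    summary = moddetect.module_summary(partition, net)
    partition.to_frame().to_csv(out / "modules.tsv", sep="\t", index=False)
    summary.to_csv(out / "module_summary.tsv", sep="\t", index=False)
    _write_module_edges(partition, net, out / "module_edges.tsv")
    ari = _planted_ari(partition, truth)
    log.info("modules: %d (Q=%.4f, planted-label ARI=%.3f)", len(summary), partition.q, ari)

    enrichment = None
    selected: list[int] = []
    if cfg.run_enrich:
        log.info("stage goenrich")
        enrichment = goenrich.enrich_modules(
            partition, ann, min_module_size=cfg.min_module_size, alpha=cfg.alpha_go
        )
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                          float_format="%.4g")
        selected = goenrich.select_modules_by_terms(
            enrichment, list(cfg.keywords), alpha=cfg.alpha_go
        )
        log.info("enriched modules: %d; keyword-selected: %s",
                 int(enrichment[enrichment["significant"]]["module_id"].nunique()), selected)

    motif_tables: dict[int, pd.DataFrame] = {}
    if cfg.run_cisreg:
        log.info("stage cisreg")
        genome = syndata.simulate_genome(syn)
        cio.write_fasta(genome.contigs, out / "genome.fasta")
        cio.write_gff3(genome.features, out / "genes.gff3")
        genome.motif_truth.to_csv(out / "truth_motifs.tsv", sep="\t", index=False)
        promoters, _ = cisreg.extract_promoters(
            genome.contigs, genome.features, list(truth.index), length=syn.promoter_len
        )
        catalog = (
            cio.read_catalog(cfg.catalog_path)
            if cfg.catalog_path
            else cisreg.load_default_catalog()
        )
        targets = selected or _largest_modules(summary, 1)
        frames = []
        for module_id in targets:
            fg_genes = set(partition.members(module_id))
            fg = {g: promoters[g] for g in fg_genes if g in promoters}
            bg = {g: s for g, s in promoters.items() if g not in fg_genes}
            module_results = []
            for k in cfg.motif_ks:
                res = cisreg.discover_motifs(
                    fg, bg, k, alpha=cfg.alpha_motif, top=cfg.motif_top
                )
                module_results.extend(cisreg.match_catalog(res, catalog))
            module_results.sort(key=lambda r: r.p_enrich)
            frames.append(cisreg.results_to_frame(module_results, module_id))
        motif_report = (
            pd.concat(frames, ignore_index=True)
            if frames
            else cisreg.results_to_frame([], None)
        )
        motif_report.to_csv(out / "motifs.tsv", sep="\t", index=False, float_format="%.4g")
        motif_tables = {m: f for m, f in zip(targets, frames)}
        log.info("motif report: %d rows over modules %s", len(motif_report), targets)

    profiles = None
    if cfg.run_profiles and syn.tissues:
        log.info("stage profiles")
        kept = [s for s in syn.sample_ids() if s in x.columns]
        profiles = tissue_profiles(
            x[kept], syn.tissue_of_sample().loc[kept], genes=sorted(partition.assignment)
        )
        profiles.to_csv(out / "tissue_profiles.tsv", sep="\t", index_label="gene_id",
                        float_format="%.6g")

    result = PipelineResult(
        config=cfg, expression=x, weights=w, scan=scan, cutoff=cutoff, network=net,
        partition=partition, summary=summary, report=report, enrichment=enrichment,
        selected_modules=selected, motif_tables=motif_tables, profiles=profiles,
        ari=ari, flagged_arrays=flagged,
    )
    run_summary = {
        "seed": cfg.seed,
        "n_genes": int(syn.n_genes),
        "n_samples_used": int(x.shape[1]),
        "cutoff": float(cutoff),
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "n_modules": int(len(summary)),
        "modularity_q": float(partition.q),
        "planted_ari": ari,
        "selected_modules": [int(m) for m in selected],
    }
    (out / "run_summary.json").write_text(json.dumps(run_summary, indent=2) + "\n")
    return result


def _substream(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_SEEDS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


def _largest_modules(summary: pd.DataFrame, n: int) -> list[int]:
    return summary.sort_values(["n_genes", "module_id"], ascending=[False, True])[
        "module_id"
    ].head(n).tolist()


def _write_module_edges(partition, net, path) -> None:
    """Per-module edge lists with correlation values, one table."""
    labels = partition.labels()
    edges = net.edges.copy()
    ma = edges["gene_a"].map(labels)
    mb = edges["gene_b"].map(labels)
    intra = edges[ma == mb].copy()
    intra.insert(0, "module_id", ma[ma == mb])
    intra = intra.sort_values(["module_id", "gene_a", "gene_b"], ignore_index=True)
    intra["r"] = intra["r"].map(lambda v: f"{v:.6f}")
    intra.to_csv(path, sep="\t", index=False)
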