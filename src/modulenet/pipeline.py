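"""End-to-end pipeline orchestration.

Runs co-expression module detection -> disease-module and core-gene
selection -> disease-network statistics -> drug proximity screening ->
diagnostic panel cross-validation, on either user-supplied files or the
synthetic scenario, writing per-stage TSVs and a JSON summary. All
randomness flows from the single configured seed; reruns with the same
seed are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import networkx as nx
import numpy as np
import pandas as pd

from . import coexpr, diagnostics, module_select, netstats, proximity, synth
from .config import PipelineConfig
from .io import (
    GeneSetCollection,
    read_drug_targets_tsv,
    read_edge_list,
    read_expression_tsv,
    read_gene_sets_gmt,
    standardize_per_batch,
    write_drug_targets_tsv,
    write_edge_list,
    write_expression_tsv,
    write_gene_sets_gmt,
)

__all__ = ["run_pipeline", "build_synthetic_inputs"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _child_seed(seed: int, key: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(key,)).generate_state(1)[0] % 2**31)


def build_synthetic_inputs(cfg: PipelineConfig):
    """Generate the full synthetic scenario from the configured seed.

    The interactome is a preferential-attachment graph whose nodes are
    relabelled so that (a) the expression-derived disease genes occupy a
    locality-clustered node set and (b) a few disease-module genes sit at
    planted disease-neighbour hubs (the recoverable key genes).
    """
    sp = cfg.synthetic
    expr, truth = synth.simulate_expression(
        n_genes=sp.n_genes,
        n_samples_per_condition=sp.n_samples_per_condition,
        module_sizes=sp.module_sizes,
        effect=sp.effect,
        loading=sp.loading,
        noise_sd=sp.noise_sd,
        n_disease_modules=sp.n_disease_modules,
        seed=_child_seed(cfg.seed, 1),
    )
    disease_genes = synth.sample_disease_gene_set(
        truth,
        n_from_disease_modules=sp.n_disease_from_modules,
        n_background=sp.n_disease_background,
        seed=_child_seed(cfg.seed, 2),
    )
    graph = synth.simulate_scale_free_network(
        sp.n_genes, sp.network_edges_per_node, seed=_child_seed(cfg.seed, 3)
    )
    dis_positions = synth.plant_disease_genes(
        graph, len(disease_genes), locality=sp.disease_locality, seed=_child_seed(cfg.seed, 4)
    )
    key_positions = synth.plant_key_genes(
        graph,
        dis_positions,
        n_key=sp.n_key_genes,
        links_per_key=sp.links_per_key,
        seed=_child_seed(cfg.seed, 5),
    )

    # key genes are disease-module members outside the catalogue, taken in
    # order of individual case/control discrimination so they survive the
    # core-gene filter
    dm = set(truth.disease_modules)
    case_mask = expr.case_mask
    pool = [
        g
        for g in expr.gene_ids
        if truth.module_of_gene[g] in dm and g not in disease_genes
    ]
    aucs = {
        g: module_select.gene_auc(expr.values[expr.gene_ids.index(g)], case_mask)
        for g in pool
    }
    key_labels = sorted(pool, key=lambda g: (-aucs[g], g))[: sp.n_key_genes]

    rng = np.random.default_rng(_child_seed(cfg.seed, 6))
    mapping = {}
    for pos, gene in zip(sorted(dis_positions), sorted(disease_genes)):
        mapping[pos] = gene
    for pos, gene in zip(sorted(key_positions), key_labels):
        mapping[pos] = gene
    rest_pos = sorted(set(graph.nodes()) - set(mapping))
    rest_genes = sorted(set(expr.gene_ids) - set(mapping.values()))
    rng.shuffle(rest_genes)
    mapping.update(dict(zip(rest_pos, rest_genes)))
    network = nx.relabel_nodes(graph, mapping)

    drugs, drug_truth = synth.simulate_drugs(
        network,
        disease_genes,
        n_proximal=sp.n_proximal_drugs,
        n_random=sp.n_random_drugs,
        targets_per_drug=sp.targets_per_drug,
        seed=_child_seed(cfg.seed, 7),
    )
    truth.disease_genes = set(disease_genes)
    truth.key_genes = set(key_labels)
    truth.drug_class = drug_truth.drug_class
    return expr, network, disease_genes, drugs, truth


def _load_inputs(cfg: PipelineConfig):
    expr = read_expression_tsv(cfg.expression_tsv, cfg.expression_labels_tsv)
    network = (
        read_edge_list(cfg.network_tsv, cfg.network_min_score)
        if cfg.network_tsv
        else None
    )
    disease_genes = None
    if cfg.disease_genes_gmt:
        coll = read_gene_sets_gmt(cfg.disease_genes_gmt)
        disease_genes = set().union(*coll.sets.values())
    drugs = read_drug_targets_tsv(cfg.drug_targets_tsv) if cfg.drug_targets_tsv else None
    return expr, network, disease_genes, drugs, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order and write the report bundle.

    Returns the summary dict (also written to ``summary.json``). Stages
    whose inputs are absent (no disease-gene set, no network, no drugs)
    are skipped and noted in the summary.
    """
    out = cfg.ensure_out_dir()
    summary: dict = {
        "seed": cfg.seed,
        "thresholds": cfg.thresholds(),
        "batch_correction": "per-batch per-gene standardization (not ComBat)",
        "skipped_stages": [],
    }

    stage = "inputs"
    try:
        if cfg.expression_tsv is None:
            expr, network, disease_genes, drugs, truth = build_synthetic_inputs(cfg)
            summary["synthetic"] = asdict(cfg.synthetic)
            write_expression_tsv(expr, out / "expression.tsv", out / "sample_labels.tsv")
            write_edge_list(network, out / "network.tsv")
            write_gene_sets_gmt(
                GeneSetCollection(sets={"disease_genes": set(disease_genes)}),
                out / "disease_genes.gmt",
            )
            write_drug_targets_tsv(drugs, out / "drug_targets.tsv")
            (out / "truth.json").write_text(
                json.dumps(
                    {
                        "module_of_gene": truth.module_of_gene,
                        "disease_modules": truth.disease_modules,
                        "disease_genes": sorted(truth.disease_genes),
                        "key_genes": sorted(truth.key_genes),
                        "drug_class": truth.drug_class,
                    },
                    indent=1,
                    sort_keys=True,
                )
            )
        else:
            expr, network, disease_genes, drugs, truth = _load_inputs(cfg)
        if len(set(expr.batch)) > 1:
            expr, flags = standardize_per_batch(expr)
            summary["batch_standardized_constant_genes"] = sorted(flags)
    except Exception as exc:  # noqa: BLE001 - stage failures must name the stage
        raise StageError(stage, exc) from exc

    stage = "coexpr"
    try:
        st = coexpr.pick_soft_threshold(expr, cfg.powers, cfg.r2_cutoff)
        matrices = coexpr.build_matrices(expr, st.chosen_power)
        partition, eigengenes = coexpr.detect_modules(
            matrices,
            expr,
            min_size=cfg.min_module_size,
            cut_height_fraction=cfg.cut_height_fraction,
            merge_cut=cfg.merge_cut,
            kme_clean=cfg.kme_clean,
        )
        st.table.to_csv(out / "soft_threshold.tsv", sep="\t", index=False)
        assign = [
            {"gene": g, "module": m} for g, m in sorted(partition.module_of_gene.items())
        ]
        pd.DataFrame(assign).to_csv(out / "modules.tsv", sep="\t", index=False)
        eigengenes.to_frame().to_csv(out / "eigengenes.tsv", sep="\t")
        summary["chosen_power"] = st.chosen_power
        summary["soft_threshold_warning"] = st.warning
        summary["n_modules"] = len(partition.module_labels)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "module_select"
    try:
        if disease_genes is not None:
            trait = coexpr.module_trait_stats(
                eigengenes, expr.condition, disease_genes, partition, expr.n_genes
            )
            disease_modules = coexpr.select_disease_modules(
                trait, alpha=cfg.alpha, fdr=cfg.fdr_cutoff
            )
        else:
            # without a catalogue, fall back to the two trait criteria only
            trait = coexpr.module_trait_stats(
                eigengenes, expr.condition, set(), partition, expr.n_genes
            )
            disease_modules = list(
                trait[(trait.p_corr < cfg.alpha) & (trait.fdr_diff < cfg.fdr_cutoff)].module
            )
            summary["skipped_stages"].append("module overlap test (no disease gene set)")
        trait.to_csv(out / "module_trait.tsv", sep="\t", index=False)
        core = module_select.select_core_genes(
            expr,
            partition,
            eigengenes,
            disease_modules,
            kme_cutoff=cfg.kme_cutoff,
            auc_cutoff=cfg.auc_cutoff,
        )
        core.to_csv(out / "core_genes.tsv", sep="\t", index=False)
        core_genes = list(core[core.selected].gene)
        summary["disease_modules"] = disease_modules
        summary["n_core_genes"] = len(core_genes)
        summary["core_genes"] = core_genes
        if cfg.gene_sets_gmt and core_genes:
            coll = read_gene_sets_gmt(cfg.gene_sets_gmt)
            ora_table = module_select.ora(core_genes, coll, set(expr.gene_ids))
            ora_table.to_csv(out / "ora.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "netstats"
    key_genes: list = []
    if network is None or disease_genes is None:
        summary["skipped_stages"].append("netstats (no network or disease gene set)")
    elif len(set(core_genes) - set(disease_genes)) < 2:
        summary["skipped_stages"].append(
            "netstats (fewer than 2 candidate core genes)"
        )
    else:
        try:
            netstats.set_node_classes(network, disease_genes, core_genes)
            rank = netstats.degree_rank(network)
            rank.rename("degree").to_csv(out / "degree_rank.tsv", sep="\t")
            gsea = netstats.preranked_gsea(
                rank,
                GeneSetCollection(sets={"disease_genes": set(disease_genes) & set(network.nodes())}),
                n_perm=cfg.gsea_n_perm,
                weight_p=cfg.gsea_weight,
                seed=_child_seed(cfg.seed, 8),
            )
            gsea.to_csv(out / "gsea_degree_rank.tsv", sep="\t", index=False)
            stats = netstats.node_disease_stats(
                network, n_perm=cfg.netstats_n_perm, seed=_child_seed(cfg.seed, 9)
            )
            stats.to_csv(out / "node_disease_stats.tsv", sep="\t", index=False)
            key_genes = netstats.select_key_genes(stats, alpha=cfg.alpha)
            summary["key_genes"] = key_genes
        except Exception as exc:
            raise StageError(stage, exc) from exc

    stage = "proximity"
    if network is None or disease_genes is None or drugs is None:
        summary["skipped_stages"].append("proximity (missing network, disease genes, or drugs)")
    else:
        try:
            screen = proximity.screen_drugs(
                network,
                disease_genes,
                drugs,
                n_perm=cfg.proximity_n_perm,
                seed=_child_seed(cfg.seed, 10),
                fdr_cutoff=cfg.fdr_cutoff,
                degree_matched=cfg.proximity_degree_matched,
            )
            screen.to_csv(out / "drug_proximity.tsv", sep="\t", index=False)
            summary["selected_drugs"] = list(screen[screen.selected].drug_id)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    stage = "diagnostics"
    try:
        panel = key_genes if key_genes else None
        if panel is None and core_genes:
            core_sorted = core[core.selected].sort_values(
                ["auc", "gene"], ascending=[False, True], kind="mergesort"
            )
            panel = list(core_sorted.gene.head(3))
            summary["panel_fallback"] = "top core genes by AUC (no key genes)"
        if panel:
            cm, roc = diagnostics.cross_validate(
                expr,
                panel,
                k=cfg.cv_folds,
                kernel=cfg.svm_kernel,
                c=cfg.svm_c,
                seed=_child_seed(cfg.seed, 11),
            )
            model = diagnostics.train_panel_svm(
                expr, panel, kernel=cfg.svm_kernel, c=cfg.svm_c, seed=_child_seed(cfg.seed, 11)
            )
            (out / "model.json").write_text(json.dumps(model.metadata(), sort_keys=True, indent=1))
            summary["panel"] = panel
            summary["cv_metrics"] = cm.as_dict()
            summary["cv_auc"] = roc.auc
        else:
            summary["skipped_stages"].append("diagnostics (no panel genes)")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))
    return summary
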