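"""End-to-end orchestration: variance filter -> robust correlation ->
soft-threshold report -> adjacency -> TOM -> dendrogram -> dynamic cut and
merge (+ hyperparameter sweep) -> eigengenes -> module-trait correlation
-> optional preservation / differential co-expression -> hub signatures ->
optional validation scoring -> driver-anchored candidate table -> optional
over-representation analysis.

Every stage is a plain function over the library types, so any stage can
be re-run standalone on prior outputs; ``run_pipeline`` chains them and
writes a manifest recording the configuration hash, seeds, package
version and per-stage output paths.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_io import (ExpressionMatrix, TraitTable, read_expression,
                      read_gmt, read_traits, filter_top_variable,
                      write_expression)
from .module_detect import (CutParams, EigengeneMatrix, ModulePartition,
                            cut_dynamic_hybrid, default_sweep_grid,
                            gene_module_stats, hyperparameter_sweep,
                            linkage_tree, merge_close_modules,
                            module_eigengenes, module_trait_correlation,
                            top_hub_genes)
from .netcore import (NetworkConfig, adjacency, correlation_matrix,
                      pick_soft_threshold, tom, write_symmetric_matrix)
from .preservation import diff_coexpression, permutation_preservation
from .signature import (ora_hypergeometric, paired_de_test, rank_candidates,
                        signature_score, validate_signature)

logger = logging.getLogger("coexmod")


@dataclass
class PipelineConfig:
    """Analysis settings; defaults encode the study's printed choices:
    top-20% variance filter, bicor, soft power 8, top-120 hub signatures,
    top-47 candidate set at the p < 0.05 driver screen."""

    expression_path: str | None = None
    traits_path: str | None = None
    validation_expression_path: str | None = None
    gene_sets_path: str | None = None
    reference_signature_path: str | None = None
    reference_signature_name: str | None = None

    variance_fraction: float = 0.20
    variance_metric: str = "variance"

    beta: int = 8
    network_type: str = "unsigned"
    correlation: str = "bicor"
    min_pairs: int = 3
    candidate_betas: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14, 16)
    fit_target: float = 0.8

    deep_split: int = 2
    min_module_size: int = 30
    merge_threshold: float = 0.15
    pam_stage: bool = True
    cut_height: float = 0.99
    run_sweep: bool = True

    n_perm: int = 200
    top_k_hubs: int = 120
    driver_gene: str | None = None
    direction: str = "negative"
    n_candidates: int = 47
    alpha: float = 0.05
    candidate_subset: str = "all"  # or "cases"

    out_dir: str = "coexmod_out"
    seed: int = 0

    def network_config(self) -> NetworkConfig:
        return NetworkConfig(beta=self.beta, network_type=self.network_type,
                             method=self.correlation, min_pairs=self.min_pairs)

    def cut_params(self) -> CutParams:
        return CutParams(deep_split=self.deep_split,
                         min_module_size=self.min_module_size,
                         merge_threshold=self.merge_threshold,
                         pam_stage=self.pam_stage, cut_height=self.cut_height)

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("candidate_betas",):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate_paths(self) -> None:
        for key in ("expression_path", "traits_path",
                    "validation_expression_path", "gene_sets_path",
                    "reference_signature_path"):
            p = getattr(self, key)
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"{key}: {p}")

    def config_hash(self) -> str:
        enc = json.dumps(dataclasses.asdict(self), sort_keys=True,
                         default=str).encode()
        return hashlib.sha256(enc).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory results of a full run (mirrors the files on disk)."""

    expr: ExpressionMatrix
    fit_table: pd.DataFrame
    chosen_beta: int
    partition: ModulePartition
    eigengenes: EigengeneMatrix
    stats: pd.DataFrame
    module_trait: pd.DataFrame | None = None
    module_trait_p: pd.DataFrame | None = None
    sweep_report: object | None = None
    preservation: object | None = None
    diffcoex: object | None = None
    validation_table: pd.DataFrame | None = None
    chosen_module: int | None = None
    candidates: pd.DataFrame | None = None
    de_table: pd.DataFrame | None = None
    ora: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def _file_hash(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def build_network(expr: ExpressionMatrix, cfg: PipelineConfig):
    """Correlation, soft-threshold report at the configured candidates,
    adjacency at the configured beta, and the TOM dissimilarity."""
    net = cfg.network_config()
    cor = correlation_matrix(expr, method=net.method, min_pairs=net.min_pairs)
    chosen, fit_table = pick_soft_threshold(cor, list(cfg.candidate_betas),
                                            net, target=cfg.fit_target)
    adj = adjacency(cor, net)
    t = tom(adj)
    return cor, fit_table, chosen, adj, t


def detect_modules(expr: ExpressionMatrix, dissim: np.ndarray,
                   cfg: PipelineConfig):
    tree = linkage_tree(dissim)
    part = cut_dynamic_hybrid(tree, dissim, cfg.cut_params())
    part = ModulePartition(expr.gene_ids, part.labels, part.n_stage1_branches)
    if part.module_labels:
        me = module_eigengenes(expr, part)
        part, me = merge_close_modules(expr, part, me, cfg.merge_threshold)
    else:
        me = None
    return tree, part, me


def driver_trait_table(expr: ExpressionMatrix, traits: TraitTable | None,
                       driver: str | None) -> TraitTable | None:
    """Trait table augmented with the driver gene's expression as a
    continuous trait (driver-defined traits for module screening)."""
    if traits is None and driver is None:
        return None
    df = traits.data.copy() if traits is not None else \
        pd.DataFrame(index=pd.Index(expr.sample_ids, name="sample_id"))
    if driver is not None and driver in expr.gene_ids:
        df[driver] = expr.data.loc[driver, df.index].to_numpy()
    return TraitTable(df)


def choose_module_by_driver(mt_result, driver: str,
                            direction: str | None = None) -> int:
    """Module with the strongest |R| against the driver trait; with a
    direction, the strongest module of that correlation sign (the module an
    anti-correlation screen should mine)."""
    col = mt_result.correlation[driver].astype(float)
    if direction == "negative":
        col = col[col < 0]
    elif direction == "positive":
        col = col[col > 0]
    if col.empty:
        raise ValueError(f"no module correlates with {driver!r} in the "
                         f"{direction} direction")
    best = col.abs().idxmax()
    return int(best.removeprefix("ME"))


def run_pipeline(cfg: PipelineConfig,
                 expr: ExpressionMatrix | None = None,
                 traits: TraitTable | None = None,
                 validation_expr: ExpressionMatrix | None = None
                 ) -> PipelineResult:
    """Execute the full analysis; inputs may be given in memory or read
    from the configured paths. Writes stage outputs and a manifest under
    ``cfg.out_dir``."""
    cfg.validate_paths()
    os.makedirs(cfg.out_dir, exist_ok=True)
    outputs: dict[str, str] = {}
    stages: list[str] = []

    def emit(stage: str, filename: str, writer) -> str:
        path = os.path.join(cfg.out_dir, filename)
        writer(path)
        outputs[stage] = path
        stages.append(stage)
        return path

    if expr is None:
        if cfg.expression_path is None:
            raise ValueError("no expression input given")
        expr = read_expression(cfg.expression_path)
    if traits is None and cfg.traits_path:
        traits = read_traits(cfg.traits_path)
    if validation_expr is None and cfg.validation_expression_path:
        validation_expr = read_expression(cfg.validation_expression_path)

    expr = filter_top_variable(expr, cfg.variance_fraction, cfg.variance_metric)
    emit("filter", "filtered_expression.tsv",
         lambda p: write_expression(expr, p))

    cor, fit_table, chosen_beta, adj, tmat = build_network(expr, cfg)
    emit("soft_threshold", "soft_threshold.tsv",
         lambda p: fit_table.to_csv(p, sep="\t", index=False,
                                    float_format="%.10g"))
    dissim = tmat.dissimilarity
    tree, part, me = detect_modules(expr, dissim, cfg)
    if me is None:
        raise RuntimeError("no modules detected")
    emit("modules", "partition.tsv", lambda p: part.to_frame().to_csv(p, sep="\t"))
    emit("eigengenes", "eigengenes.tsv",
         lambda p: me.values.to_csv(p, sep="\t", float_format="%.10g",
                                    index_label="sample_id"))
    stats_df = gene_module_stats(expr, part, adj, me)
    emit("gene_stats", "gene_module_stats.tsv",
         lambda p: stats_df.to_csv(p, sep="\t", float_format="%.10g"))

    result = PipelineResult(expr, fit_table, chosen_beta, part, me, stats_df)

    sweep = None
    if cfg.run_sweep:
        sweep = hyperparameter_sweep(expr, dissim, default_sweep_grid(), tree)
        emit("sweep", "sweep.json",
             lambda p: open(p, "w", encoding="utf-8").write(sweep.to_json()))
        result.sweep_report = sweep

    full_traits = driver_trait_table(expr, traits, cfg.driver_gene)
    if full_traits is not None and len(full_traits.trait_names):
        mt = module_trait_correlation(me, full_traits)
        result.module_trait, result.module_trait_p = mt.correlation, mt.p_values
        emit("module_trait", "module_trait.tsv", lambda p: pd.concat(
            [mt.correlation.add_prefix("R_"), mt.p_values.add_prefix("p_")],
            axis=1).to_csv(p, sep="\t", float_format="%.10g",
                           index_label="module"))
    else:
        mt = None

    if validation_expr is not None:
        pres = permutation_preservation(expr, validation_expr, part,
                                        cfg.network_config(),
                                        n_perm=cfg.n_perm, seed=cfg.seed)
        emit("preservation", "preservation.json",
             lambda p: open(p, "w", encoding="utf-8").write(pres.to_json()))
        result.preservation = pres

    if traits is not None and "condition" in traits.trait_names:
        pair = "pair" if "pair" in traits.trait_names else None
        dc = diff_coexpression(expr, traits, part, n_perm=cfg.n_perm,
                               seed=cfg.seed, pair=pair,
                               method=cfg.correlation)
        emit("diffcoex", "diffcoex_modules.tsv",
             lambda p: dc.module_stats.to_csv(p, sep="\t",
                                              float_format="%.10g"))
        result.diffcoex = dc

    hub_sigs = {l: top_hub_genes(stats_df, l, cfg.top_k_hubs)
                for l in part.module_labels}
    if validation_expr is not None and cfg.reference_signature_path:
        sigs = read_gmt(cfg.reference_signature_path)
        name = cfg.reference_signature_name or sigs.names()[0]
        vt = validate_signature(validation_expr, hub_sigs, sigs[name])
        emit("score", "signature_validation.tsv",
             lambda p: vt.to_csv(p, sep="\t", float_format="%.10g"))
        result.validation_table = vt

    if cfg.driver_gene and mt is not None and cfg.driver_gene in \
            mt.correlation.columns:
        chosen = choose_module_by_driver(mt, cfg.driver_gene, cfg.direction)
        result.chosen_module = chosen
        subset = None
        if cfg.candidate_subset == "cases" and traits is not None and \
                "condition" in traits.trait_names:
            cond = traits.binary("condition")
            subset = [s for s in expr.sample_ids
                      if s in cond.index and cond[s] == 1]
        cand = rank_candidates(expr, part, stats_df, chosen, cfg.driver_gene,
                               cfg.direction, cfg.n_candidates, cfg.alpha,
                               sample_subset=subset)
        emit("prioritize", "candidates.tsv",
             lambda p: cand.to_csv(p, sep="\t", float_format="%.10g"))
        result.candidates = cand
        if traits is not None and {"condition", "pair"} <= \
                set(traits.trait_names):
            top = list(cand.index[cand["top_n"]])
            if top:
                de = paired_de_test(expr, traits, top)
                emit("paired_de", "paired_de.tsv",
                     lambda p: de.to_csv(p, sep="\t", float_format="%.10g"))
                result.de_table = de

    if cfg.gene_sets_path and result.candidates is not None:
        sets = read_gmt(cfg.gene_sets_path)
        selection = list(result.candidates.index[result.candidates["top_n"]])
        if selection:
            ora = ora_hypergeometric(selection, sets, expr.gene_ids)
            emit("ora", "ora.tsv",
                 lambda p: ora.to_csv(p, sep="\t", float_format="%.10g"))
            result.ora = ora

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "chosen_beta": int(chosen_beta),
        "n_modules": len(part.module_labels),
        "module_sizes": {str(k): v for k, v in part.sizes.items()},
        "stages": stages,
        "outputs": {k: {"path": v, "sha256_16": _file_hash(v)}
                    for k, v in outputs.items()},
    }
    manifest_path = os.path.join(cfg.out_dir, "manifest.json")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    result.manifest = manifest
    return result
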