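"""End-to-end convenience wiring of the four scoring engines and the merge.

Runs the complete chain on a set of studies: z-score merge, DE detection,
the four pair-scoring engines (STRING-style backbone, Pearson delta-r with
half-thresholding, empirical-Bayes posterior, WGCNA weights), the weighted
rank-product merge with PFP q-values, and the merged network.  Used by the
synthetic-data evaluations and by the command-line interface; every step is
also callable on its own through the per-module APIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from . import eb_dc, network_enrichment, pearson_dc, rank_merge, string_backbone, wgcna
from .preprocess import MergedExpression, detect_de, zscore_merge
from .synthetic_data import (
    GroundTruth,
    SimulationConfig,
    simulate_studies,
    synthetic_string_links,
)


@dataclass
class PipelineResult:
    merged: MergedExpression
    de_table: pd.DataFrame
    de_genes: list[str]
    sets: dict[str, pearson_dc.ScoredPairSet]
    merge: rank_merge.MergeResult | None
    network: nx.Graph | None = None  # graph of accepted pairs

    @property
    def accepted(self) -> list[tuple[str, str]]:
        return [] if self.merge is None else self.merge.accepted_pairs


def score_all_methods(
    merged: MergedExpression,
    genes,
    string_edges: pd.DataFrame | None = None,
    pearson_alpha: float = 0.05,
    eb_fdr: float = 0.05,
    eb_variant: str = "one-step",
    wgcna_beta: float = 6.0,
    wgcna_top_fraction: float = 0.25,
    wgcna_differential: bool = True,
    seed: int = 0,
) -> dict[str, pearson_dc.ScoredPairSet]:
    """Run every available scoring engine over the gene set.

    The WGCNA engine runs in its differential variant by default (pair
    strength |a_case - a_control|) because the pipeline targets
    condition-dependent co-expression, and contributes its top quarter of
    pair weights so the merge sees a broad ranked list.  The STRING
    backbone is skipped when no links table is supplied.
    """
    sets: dict[str, pearson_dc.ScoredPairSet] = {}
    if string_edges is not None:
        parsed = string_backbone.parse_string_links(string_edges)
        sets["string"] = string_backbone.backbone_pairs(parsed, genes)

    corr = pearson_dc.condition_correlations(merged, genes)
    sets["pearson"], _ = pearson_dc.half_threshold_filter(corr, alpha=pearson_alpha)

    inputs = eb_dc.make_d_matrix(merged, genes)
    init = eb_dc.initialize_hyperparameters(inputs, seed=seed)
    model = eb_dc.fit_em(inputs, init, variant=eb_variant)
    sets["eb"], _ = eb_dc.eb_pairs(inputs, model, target_fdr=eb_fdr)

    wmodel = wgcna.build_wgcna(
        merged, genes, beta=wgcna_beta, differential=wgcna_differential
    )
    sets["wgcna"] = wgcna.wgcna_pairs(wmodel, top_fraction=wgcna_top_fraction)
    return sets


def run_pipeline(
    studies,
    string_edges: pd.DataFrame | None = None,
    de_genes=None,
    q_cut: float = 0.1,
    B: int = 500,
    seed: int = 0,
    weights: dict[str, float] | None = None,
    **engine_kwargs,
) -> PipelineResult:
    """Merge studies, call DE genes, score pairs, rank-merge, build network.

    ``de_genes`` overrides DE detection with an explicit gene set (useful
    for null calibrations where no gene passes the fold-change filter).
    """
    merged = zscore_merge(studies)
    de_table = detect_de(merged)
    if de_genes is None:
        de_genes = list(de_table.index[de_table["is_de"]])
    else:
        de_genes = list(de_genes)
    if len(de_genes) < 2:
        return PipelineResult(merged, de_table, de_genes, {}, None)
    sets = score_all_methods(
        merged, de_genes, string_edges=string_edges, seed=seed, **engine_kwargs
    )
    nonempty = [s for s in sets.values() if len(s) > 0]
    if not nonempty:
        return PipelineResult(merged, de_table, de_genes, sets, None)
    merge = rank_merge.merge_pairs(nonempty, weights=weights, B=B, seed=seed, q_cut=q_cut)
    net = network_enrichment.build_network(merge.accepted_pairs)
    return PipelineResult(merged, de_table, de_genes, sets, merge, net)


def evaluate_against_truth(
    result: PipelineResult, truth: GroundTruth
) -> dict[str, float]:
    """Precision/recall of the accepted pairs against the planted DC pairs.

    Precision is 1 when nothing is accepted (no false positives made).
    """
    accepted = {tuple(sorted(p)) for p in result.accepted}
    planted = truth.pair_set
    tp = len(accepted & planted)
    precision = tp / len(accepted) if accepted else 1.0
    recall = tp / len(planted) if planted else float("nan")
    return {
        "n_accepted": float(len(accepted)),
        "true_positives": float(tp),
        "precision": precision,
        "recall": recall,
    }


def run_planted_pipeline(
    config: SimulationConfig,
    q_cut: float = 0.1,
    B: int = 500,
    with_string: bool = True,
    **kwargs,
) -> tuple[PipelineResult, GroundTruth, dict[str, float]]:
    """Simulate studies under ``config``, run the pipeline, evaluate."""
    studies, truth = simulate_studies(config)
    edges = (
        synthetic_string_links(truth, seed=config.seed)
        if with_string and truth.dc_pairs
        else None
    )
    result = run_pipeline(
        studies, string_edges=edges, q_cut=q_cut, B=B, seed=config.seed, **kwargs
    )
    return result, truth, evaluate_against_truth(result, truth)
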