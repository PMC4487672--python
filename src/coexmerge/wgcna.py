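"""Weighted co-expression scoring: similarity, adjacency and topological overlap.

Follows the weighted gene co-expression network construction chain:
a correlation-based similarity matrix S (unsigned |cor| or signed
(1+cor)/2), turned into an adjacency A either by a hard signum threshold
(a_ij = 1 iff s_ij >= tau) or a soft power (a_ij = s_ij^beta), and the
topological overlap matrix (TOM) that credits shared neighbors:

    omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_u a_iu a_uj,  k_i = sum_u a_iu,

with dissimilarity d_ij = 1 - omega_ij.  A pair's "weight" strength is the
soft adjacency by default (TOM optionally); a differential variant scores
|a_case - a_control| to target condition-dependent co-expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import CASE, CONTROL, MergedExpression
from .pearson_dc import ScoredPairSet


@dataclass
class WGCNAModel:
    """Fitted similarity/adjacency/TOM matrices over a gene set."""

    genes: list[str]
    S: np.ndarray
    A: np.ndarray
    tom_matrix: np.ndarray
    weights: np.ndarray  # pair strengths used for selection
    mode: str
    beta: float
    differential: bool = False


def similarity(
    merged: MergedExpression,
    genes,
    mode: str = "unsigned",
    condition: str | None = None,
) -> pd.DataFrame:
    """Correlation similarity over the gene set, in [0, 1].

    ``mode="unsigned"`` gives |cor|; ``mode="signed"`` gives (1+cor)/2 so
    that perfectly anti-correlated genes score 0 and perfectly correlated
    ones 1.  With ``condition`` the correlation is computed on that
    condition's samples only.  Genes with zero variance are dropped with a
    warning.  The diagonal is not meaningful downstream and is left at the
    self-similarity value.
    """
    if mode not in {"unsigned", "signed"}:
        raise ValueError(f"unknown mode {mode!r}")
    genes = sorted(genes)
    cols = merged.sample_ids if condition is None else merged.samples_of(condition)
    if len(cols) < 3:
        raise ValueError("need at least 3 samples")
    mat = merged.expr.loc[genes, cols].to_numpy()
    sd = mat.std(axis=1)
    if (sd == 0).any():
        dropped = [g for g, s in zip(genes, sd) if s == 0]
        warnings.warn(f"dropping {len(dropped)} zero-variance gene(s)", stacklevel=2)
        keep = sd > 0
        genes = [g for g, k in zip(genes, keep) if k]
        mat = mat[keep]
    r = np.clip(np.corrcoef(mat), -1.0, 1.0)
    s = np.abs(r) if mode == "unsigned" else (1.0 + r) / 2.0
    return pd.DataFrame(s, index=genes, columns=genes)


def adjacency_hard(S, tau: float) -> np.ndarray:
    """Signum adjacency: 1 where s_ij >= tau, else 0; zero diagonal."""
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    s = np.asarray(S, dtype=float)
    a = (s >= tau).astype(float)
    np.fill_diagonal(a, 0.0)
    return a


def adjacency_soft(S, beta: float) -> np.ndarray:
    """Power adjacency a_ij = |s_ij|^beta; zero diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    a = np.abs(np.asarray(S, dtype=float)) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def tom(A) -> np.ndarray:
    """Topological overlap of a symmetric adjacency with zero diagonal.

    Entries lie in [0, 1] for adjacencies in [0, 1]; fully disconnected
    pairs (zero denominator) get overlap 0 by convention.  The diagonal is
    set to 0 (self-overlap is excluded from downstream use).
    """
    a = np.asarray(A, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    if a.min(initial=0.0) < 0 or a.max(initial=0.0) > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=0)
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = np.where(denom > 0, (l + a) / denom, 0.0)
    np.fill_diagonal(omega, 0.0)
    return omega


def tom_dissimilarity(omega) -> np.ndarray:
    """TOM-based dissimilarity d_ij = 1 - omega_ij."""
    return 1.0 - np.asarray(omega, dtype=float)


def pick_soft_power(
    S,
    powers=range(1, 13),
    target_r2: float = 0.8,
) -> int:
    """Smallest power whose degree distribution approximates scale-free.

    Helper (standard practice, not part of the scoring chain): for each
    candidate beta, regress log10 p(k) on log10 k over 10 connectivity bins
    and return the first beta reaching the target R^2, else the best one.
    """
    best_beta, best_r2 = None, -np.inf
    for beta in powers:
        a = adjacency_soft(S, beta)
        k = a.sum(axis=0)
        if np.allclose(k, 0):
            continue
        hist, edges = np.histogram(k, bins=10)
        centers = (edges[:-1] + edges[1:]) / 2.0
        ok = (hist > 0) & (centers > 0)
        if ok.sum() < 3:
            continue
        x, y = np.log10(centers[ok]), np.log10(hist[ok])
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
        if r2 >= target_r2:
            return int(beta)
        if r2 > best_r2:
            best_beta, best_r2 = int(beta), r2
    if best_beta is None:
        raise ValueError("could not evaluate scale-free fit on this similarity")
    return best_beta


def build_wgcna(
    merged: MergedExpression,
    genes,
    mode: str = "unsigned",
    beta: float = 6.0,
    differential: bool = False,
    use_tom: bool = False,
) -> WGCNAModel:
    """Fit the model and pick the pair-strength matrix.

    Default strength is the soft adjacency on all samples (``use_tom=True``
    switches to the TOM).  ``differential=True`` instead scores each pair by
    |a_case - a_control| computed from condition-specific similarities,
    which targets pairs whose co-expression depends on condition.
    """
    if differential:
        s_case = similarity(merged, genes, mode, condition=CASE)
        s_ctrl = similarity(merged, genes, mode, condition=CONTROL)
        common = [g for g in s_case.index if g in set(s_ctrl.index)]
        s_case = s_case.loc[common, common]
        s_ctrl = s_ctrl.loc[common, common]
        a_case = adjacency_soft(s_case.to_numpy(), beta)
        a_ctrl = adjacency_soft(s_ctrl.to_numpy(), beta)
        a = adjacency_soft(
            similarity(merged, common, mode).to_numpy(), beta
        )
        weights = np.abs(a_case - a_ctrl)
        s_mat, gene_list = s_case.to_numpy(), common
    else:
        s_df = similarity(merged, genes, mode)
        s_mat, gene_list = s_df.to_numpy(), list(s_df.index)
        a = adjacency_soft(s_mat, beta)
        weights = a
    omega = tom(a)
    if use_tom and not differential:
        weights = omega
    return WGCNAModel(
        genes=gene_list,
        S=s_mat,
        A=a,
        tom_matrix=omega,
        weights=weights,
        mode=mode,
        beta=beta,
        differential=differential,
    )


def wgcna_pairs(
    model: WGCNAModel,
    weight_threshold: float | None = None,
    top_fraction: float | None = None,
) -> ScoredPairSet:
    """Select pairs by weight threshold or top fraction; strength = weight."""
    if (weight_threshold is None) == (top_fraction is None):
        raise ValueError("give exactly one of weight_threshold / top_fraction")
    iu, ju = np.triu_indices(len(model.genes), k=1)
    w = model.weights[iu, ju]
    if top_fraction is not None:
        if not 0.0 < top_fraction <= 1.0:
            raise ValueError("top_fraction must lie in (0, 1]")
        n_keep = max(1, int(round(top_fraction * len(w)))) if len(w) else 0
        order = np.argsort(-w, kind="stable")[:n_keep]
        mask = np.zeros(len(w), dtype=bool)
        mask[order] = True
    else:
        mask = w >= weight_threshold
    scores = {
        (model.genes[i], model.genes[j]): float(wij)
        for i, j, wij, m in zip(iu, ju, w, mask)
        if m
    }
    return ScoredPairSet(method="wgcna", scores=scores)


def write_wgcna_tsv(model: WGCNAModel, path) -> None:
    iu, ju = np.triu_indices(len(model.genes), k=1)
    pd.DataFrame(
        {
            "gene_i": [model.genes[i] for i in iu],
            "gene_j": [model.genes[j] for j in ju],
            "s": model.S[iu, ju],
            "a": model.A[iu, ju],
            "tom": model.tom_matrix[iu, ju],
            "weight": model.weights[iu, ju],
        }
    ).to_csv(path, sep="\t", index=False)
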