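"""Weighted rank-product merging of per-method pair rankings with PFP q-values.

Each co-expression method contributes a candidate pair list ranked by its
own strength.  Within method i a pair's rank (1 = strongest, ties averaged)
is converted to a rank ratio rank/n_i.  The rank product of pair g is

    RP_g = prod_i (rank ratio_i)^{lambda_i},

where lambda_i weights method i (all 1 by default; a smaller exponent
flattens a method's contribution toward 1) and a method that did not score
the pair contributes a factor of 1.  The null distribution of RP is
estimated by B permutations of each method's rank assignments over its own
candidates (missing patterns preserved), giving the conservative expected
count E(RP_g) = #{null RP <= RP_g} / B and the percentage-of-false-positives
q-value q_g = E(RP_g)/rank(g).  Pairs are accepted along increasing RP up
to the last pair with q_g below the cutoff (q-values monotonized by a
running maximum so the accepted set is a contiguous prefix).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pearson_dc import ScoredPairSet


@dataclass
class MergeResult:
    """Merged table plus the settings that produced it.

    ``table`` is indexed by pair (tuples of gene ids) and carries one
    ``rr_<method>`` rank-ratio column per method (NaN where the pair is
    missing from that method) and the columns ``rp``, ``e_rp``, ``rank``,
    ``q`` (monotonized PFP) and ``accepted``.
    """

    table: pd.DataFrame
    methods: list[str]
    weights: dict[str, float]
    B: int
    seed: int
    q_cut: float

    @property
    def accepted_pairs(self) -> list[tuple[str, str]]:
        return list(self.table.index[self.table["accepted"]])


def build_rank_table(sets: list[ScoredPairSet]) -> pd.DataFrame:
    """Union-of-pairs table of per-method rank ratios.

    Within each method pairs are ranked by strength descending with ties
    averaged; the rank ratio is rank/n_i over that method's own list.
    Pairs absent from a method get NaN in its column.
    """
    sets = [s for s in sets if len(s) > 0]
    if not sets:
        raise ValueError("need at least one non-empty pair set")
    names = [s.method for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate method names")
    all_pairs = sorted({p for s in sets for p in s.pairs})
    table = pd.DataFrame(index=pd.Index(all_pairs, name="pair", tupleize_cols=False))
    for s in sets:
        strengths = np.array([s.scores[p] for p in s.pairs])
        ranks = stats.rankdata(-strengths, method="average")
        rr = pd.Series(ranks / len(s), index=pd.Index(s.pairs, tupleize_cols=False))
        table[f"rr_{s.method}"] = rr.reindex(table.index)
        table.attrs[f"n_{s.method}"] = len(s)
    return table


def _rr_matrix(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    methods = [c[3:] for c in table.columns if c.startswith("rr_")]
    return table[[f"rr_{m}" for m in methods]].to_numpy(), methods


def rank_product(
    table: pd.DataFrame,
    weights: dict[str, float] | None = None,
) -> pd.Series:
    """RP_g = prod over methods of (rank ratio)^lambda; missing factor = 1."""
    rr, methods = _rr_matrix(table)
    lam = _resolve_weights(methods, weights)
    factors = np.where(np.isnan(rr), 1.0, rr ** lam[None, :])
    return pd.Series(factors.prod(axis=1), index=table.index, name="rp")


def _resolve_weights(methods: list[str], weights) -> np.ndarray:
    if weights is None:
        return np.ones(len(methods))
    lam = np.array([float(weights.get(m, 1.0)) for m in methods])
    if np.any(lam <= 0):
        raise ValueError("method weights must be positive")
    return lam


def expected_rp(
    table: pd.DataFrame,
    weights: dict[str, float] | None = None,
    B: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Permutation estimate of E(RP_g), the expected null count at RP_g.

    For each of B permutations every method's observed rank ratios are
    reassigned uniformly at random over that method's own candidate pairs
    (its missing pattern is preserved), null RP values are recomputed for
    every pair, and E(RP_g) is the total count of null RP values at or
    below the observed RP_g divided by B.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    rr, methods = _rr_matrix(table)
    lam = _resolve_weights(methods, weights)
    obs = np.where(np.isnan(rr), 1.0, rr ** lam[None, :]).prod(axis=1)
    rng = np.random.default_rng(seed)
    null_values = np.empty((B, len(obs)))
    present = [~np.isnan(rr[:, j]) for j in range(rr.shape[1])]
    for b in range(B):
        null = np.ones_like(obs)
        for j in range(rr.shape[1]):
            idx = present[j]
            vals = rr[idx, j]
            null[idx] *= rng.permutation(vals) ** lam[j]
        null_values[b] = null
    flat = np.sort(null_values.ravel())
    counts = np.searchsorted(flat, obs, side="right")
    return pd.Series(counts / B, index=table.index, name="e_rp")


def merge_pairs(
    sets: list[ScoredPairSet],
    weights: dict[str, float] | None = None,
    B: int = 1000,
    seed: int = 0,
    q_cut: float = 0.1,
    min_methods: int = 1,
) -> MergeResult:
    """Full merge: rank table, RP, permutation E(RP), PFP q, acceptance.

    ``min_methods`` restricts the candidate universe to pairs scored by at
    least that many methods (default 1 = union of all sets).
    """
    table = build_rank_table(sets)
    rr, methods = _rr_matrix(table)
    if min_methods > 1:
        keep = (~np.isnan(rr)).sum(axis=1) >= min_methods
        table = table[keep]
    table = table.copy()
    table["rp"] = rank_product(table, weights)
    table["e_rp"] = expected_rp(table, weights, B=B, seed=seed)
    order = np.argsort(table["rp"].to_numpy(), kind="stable")
    ranks = np.empty(len(table), dtype=int)
    ranks[order] = np.arange(1, len(table) + 1)
    table["rank"] = ranks
    raw_q = table["e_rp"] / table["rank"]
    # running maximum along increasing RP makes q monotone, so acceptance
    # extends contiguously "up to" the last qualifying pair
    q_sorted = np.maximum.accumulate(raw_q.to_numpy()[order])
    q = np.empty(len(table))
    q[order] = q_sorted
    table["q"] = q
    table["accepted"] = table["q"] < q_cut
    table = table.sort_values("rank")
    lam = _resolve_weights(methods, weights)
    return MergeResult(
        table=table,
        methods=methods,
        weights=dict(zip(methods, lam)),
        B=B,
        seed=seed,
        q_cut=q_cut,
    )


def select_dc_pairs(merge: MergeResult, q_cut: float | None = None) -> list[tuple[str, str]]:
    """Accepted pairs in increasing-RP order (prefix with q below cutoff)."""
    q_cut = merge.q_cut if q_cut is None else q_cut
    t = merge.table.sort_values("rank")
    return list(t.index[t["q"] < q_cut])


def write_merge_tsv(merge: MergeResult, path) -> None:
    out = merge.table.copy()
    out.insert(0, "gene_i", [p[0] for p in out.index])
    out.insert(1, "gene_j", [p[1] for p in out.index])
    out.to_csv(path, sep="\t", index=False)
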