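"""Differential co-expression scoring by condition-specific Pearson correlation.

For every pair of DE genes the Pearson correlation is computed separately in
cases and in controls; the pair's strength is the absolute correlation
difference |r_case - r_control| (range [0, 2]).  Non-informative pairs are
removed with the half-thresholding convention: a pair survives if its
correlation is FDR-significant in at least one of the two conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import CASE, CONTROL, MergedExpression


@dataclass
class ScoredPairSet:
    """One method's candidate gene pairs with method-specific strengths.

    ``scores`` maps unordered pairs (stored as sorted 2-tuples of gene ids)
    to a finite strength; larger strength means stronger evidence.
    """

    method: str
    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized: dict[tuple[str, str], float] = {}
        for (gi, gj), s in self.scores.items():
            if gi == gj:
                raise ValueError(f"self-pair ({gi},{gj}) in {self.method}")
            if not np.isfinite(s):
                raise ValueError(f"non-finite strength for ({gi},{gj})")
            key = (gi, gj) if gi < gj else (gj, gi)
            if key in normalized and normalized[key] != s:
                raise ValueError(f"duplicate pair {key} in {self.method}")
            normalized[key] = float(s)
        self.scores = normalized

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self.scores)


def _correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of Pearson r via the t transform with n-2 df."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return p


def condition_correlations(
    merged: MergedExpression,
    genes,
    rank: bool = False,
) -> pd.DataFrame:
    """Per-pair Pearson correlations within cases and within controls.

    All m(m-1)/2 pairs of ``genes`` are computed (lexicographic pair order).
    With ``rank=True`` each gene's profile is rank-transformed within each
    condition first (Spearman-style).  Pairs involving a gene with zero
    within-condition variance are dropped with a warning.

    Returns a DataFrame with one row per pair and columns ``gene_i``,
    ``gene_j``, ``r_case``, ``r_control``, ``p_case``, ``p_control``,
    ``mean_abs`` ((|r_case|+|r_control|)/2) and ``delta``
    (|r_case - r_control|).
    """
    genes = sorted(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    sub = merged.expr.loc[genes]
    out = {}
    dropped: set[str] = set()
    for label in (CASE, CONTROL):
        cols = merged.samples_of(label)
        if len(cols) < 3:
            raise ValueError(f"need >=3 samples in condition {label!r}")
        mat = sub[cols].to_numpy()
        if rank:
            mat = np.apply_along_axis(stats.rankdata, 1, mat)
        sd = mat.std(axis=1)
        dropped |= {g for g, s in zip(genes, sd) if s == 0}
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(mat)
        out[label] = (r, len(cols))
    if dropped:
        warnings.warn(
            f"dropping pairs of {len(dropped)} zero-variance gene(s)", stacklevel=2
        )

    iu, ju = np.triu_indices(len(genes), k=1)
    keep = np.array(
        [genes[i] not in dropped and genes[j] not in dropped for i, j in zip(iu, ju)]
    )
    iu, ju = iu[keep], ju[keep]
    r_case = np.clip(out[CASE][0][iu, ju], -1.0, 1.0)
    r_ctrl = np.clip(out[CONTROL][0][iu, ju], -1.0, 1.0)
    return pd.DataFrame(
        {
            "gene_i": [genes[i] for i in iu],
            "gene_j": [genes[j] for j in ju],
            "r_case": r_case,
            "r_control": r_ctrl,
            "p_case": _correlation_pvalues(r_case, out[CASE][1]),
            "p_control": _correlation_pvalues(r_ctrl, out[CONTROL][1]),
            "mean_abs": (np.abs(r_case) + np.abs(r_ctrl)) / 2.0,
            "delta": np.abs(r_case - r_ctrl),
        }
    )


def half_threshold_filter(
    pairs: pd.DataFrame,
    alpha: float = 0.05,
    full_threshold: bool = False,
) -> tuple[ScoredPairSet, pd.DataFrame]:
    """Keep pairs significant in at least one condition (half-thresholding).

    Benjamini-Hochberg q-values are computed separately from the case and
    control p-value lists; a pair is kept iff at least one q-value is below
    ``alpha`` (both, with ``full_threshold=True``).  The retained strength
    is ``delta``.

    Returns the ``ScoredPairSet`` of kept pairs and the annotated table with
    ``q_case``, ``q_control`` and ``kept`` columns.
    """
    table = pairs.copy()
    if len(table) == 0:
        return ScoredPairSet(method="pearson"), table.assign(
            q_case=[], q_control=[], kept=[]
        )
    table["q_case"] = multipletests(table["p_case"], method="fdr_bh")[1]
    table["q_control"] = multipletests(table["p_control"], method="fdr_bh")[1]
    sig_case = table["q_case"] < alpha
    sig_ctrl = table["q_control"] < alpha
    table["kept"] = (sig_case & sig_ctrl) if full_threshold else (sig_case | sig_ctrl)
    kept = table[table["kept"]]
    scores = {
        (row.gene_i, row.gene_j): float(row.delta) for row in kept.itertuples()
    }
    return ScoredPairSet(method="pearson", scores=scores), table


def write_pair_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
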