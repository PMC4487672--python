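"""Static co-expression backbone from a STRING-style protein-links table.

STRING distributes per-channel association subscores (neighborhood, fusion,
co-occurrence, co-expression, experimental, database, text mining) for each
protein pair, either on a [0,1] scale or in its 0-1000 integer dialect.
Channels are combined under an independence assumption in a naive-Bayes
fashion: ``S = 1 - prod(1 - S_i)``.  The backbone restricts the table to
pairs of DE genes and scores each pair by a chosen channel subscore
(co-expression by default), with the combined score kept for reference.
No network access: the links table is always a local file or DataFrame.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable

import numpy as np
import pandas as pd

from .pearson_dc import ScoredPairSet

CHANNELS = (
    "neighborhood",
    "fusion",
    "cooccurrence",
    "coexpression",
    "experimental",
    "database",
    "textmining",
)

# STRING files spell the channel "cooccurence"
_CHANNEL_ALIASES = {"cooccurence": "cooccurrence"}
_ID_COLUMNS = ("protein1", "protein2")


def combine_scores(subscores: Iterable[float]) -> float:
    """Naive-Bayes combination: ``1 - prod(1 - S_i)`` over the subscores."""
    total = 1.0
    for s in subscores:
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"subscore {s} outside [0, 1]")
        total *= 1.0 - s
    return 1.0 - total


def parse_string_links(source, id_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Parse a STRING protein.links.detailed-style table into gene-pair edges.

    ``source`` is a path to a whitespace- or tab-delimited file with a
    header, or an equivalent DataFrame.  Subscores in the 0-1000 integer
    dialect are auto-detected (any value > 1) and divided by 1000.  With an
    ``id_map`` the protein ids are translated to gene symbols; rows with
    unmapped ids are dropped and their count is reported via
    ``result.attrs["n_unmapped"]`` and a warning.  Rows that collapse to
    self-edges are dropped; duplicate edges keep the per-channel maximum.

    Returns a DataFrame with ``gene_a``, ``gene_b`` (sorted within row),
    one column per channel, and ``combined_score``.
    """
    if isinstance(source, pd.DataFrame):
        raw = source.copy()
    else:
        raw = pd.read_csv(source, sep=None, engine="python")
    raw = raw.rename(columns=_CHANNEL_ALIASES)
    for col in _ID_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"missing required column {col!r}")
    channels = [ch for ch in CHANNELS if ch in raw.columns]
    if not channels:
        raise ValueError(f"no channel columns found among {CHANNELS}")

    sub = raw[channels].astype(float)
    if (sub.to_numpy() > 1.0).any():  # STRING's 0-1000 integer dialect
        sub = sub / 1000.0
    if ((sub.to_numpy() < 0) | (sub.to_numpy() > 1)).any():
        raise ValueError("channel subscores outside both the [0,1] and 0-1000 dialects")

    a = raw["protein1"].astype(str)
    b = raw["protein2"].astype(str)
    n_unmapped = 0
    if id_map is not None:
        mapped_a = a.map(id_map)
        mapped_b = b.map(id_map)
        ok = mapped_a.notna() & mapped_b.notna()
        n_unmapped = int((~ok).sum())
        if n_unmapped:
            warnings.warn(f"{n_unmapped} row(s) with unmapped ids dropped", stacklevel=2)
        a, b = mapped_a[ok], mapped_b[ok]
        sub = sub[ok.to_numpy()]

    edges = pd.DataFrame({"gene_a": np.minimum(a, b), "gene_b": np.maximum(a, b)})
    edges = pd.concat([edges.reset_index(drop=True), sub.reset_index(drop=True)], axis=1)
    self_edges = edges["gene_a"] == edges["gene_b"]
    edges = edges[~self_edges].reset_index(drop=True)

    if edges.duplicated(subset=["gene_a", "gene_b"]).any():
        warnings.warn("duplicate edges collapsed to per-channel maxima", stacklevel=2)
        edges = edges.groupby(["gene_a", "gene_b"], as_index=False)[channels].max()

    edges["combined_score"] = [
        combine_scores(row) for row in edges[channels].to_numpy()
    ]
    edges.attrs["n_unmapped"] = n_unmapped
    return edges


def backbone_pairs(
    edges: pd.DataFrame,
    de_genes,
    channel: str = "coexpression",
    min_score: float = 0.0,
) -> ScoredPairSet:
    """Backbone pair set: DE-gene pairs with channel subscore above min_score.

    Strength is the chosen channel's subscore (strictly greater than
    ``min_score``; zero-score edges are excluded at the default threshold).
    """
    de_genes = set(de_genes)
    if not de_genes:
        raise ValueError("empty DE gene set")
    if channel not in edges.columns:
        raise ValueError(f"channel {channel!r} not present in the edge table")
    mask = (
        edges["gene_a"].isin(de_genes)
        & edges["gene_b"].isin(de_genes)
        & (edges[channel] > min_score)
    )
    scores = {
        (row.gene_a, row.gene_b): float(getattr(row, channel))
        for row in edges[mask].itertuples()
    }
    return ScoredPairSet(method="string", scores=scores)


def write_backbone_tsv(pairs: ScoredPairSet, path) -> None:
    pd.DataFrame(
        [(gi, gj, s) for (gi, gj), s in sorted(pairs.scores.items())],
        columns=["gene_i", "gene_j", "score"],
    ).to_csv(path, sep="\t", index=False)
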