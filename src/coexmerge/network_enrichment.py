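"""Network characterization: hubs, EASE gene-set enrichment and NEA.

The accepted pairs form an undirected gene network.  Hub genes sit at or
above the 90% quantile of the degree distribution.  Gene-set enrichment of
the network genes uses the EASE score — a jackknifed one-sided Fisher exact
test in which the overlap count a' is replaced by a = a'-1, annihilating
single-gene overlaps.  Network enrichment analysis (NEA) scores the
connectivity n_AF between an altered gene set (AGS) and a functional gene
set (FGS) against a null of degree-preserving edge-swap randomizations:
d_AF = n_AF - mu_AF, with a z-score and an add-one empirical p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


def build_network(pairs) -> nx.Graph:
    """Undirected graph whose edges are the accepted pairs."""
    g = nx.Graph()
    for gi, gj in pairs:
        if gi == gj:
            raise ValueError(f"self-pair ({gi},{gj})")
        g.add_edge(gi, gj)
    return g


def hub_genes(net: nx.Graph, q: float = 0.90) -> set[str]:
    """Nodes with degree at or above the empirical q-quantile of degrees.

    The quantile uses linear interpolation; membership is inclusive (>=).
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    degrees = dict(net.degree())
    cutoff = float(np.quantile(list(degrees.values()), q))
    return {n for n, d in degrees.items() if d >= cutoff}


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file: one set per line, 'name<TAB>description<TAB>genes...'."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return sets


def write_gmt(sets: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + sorted(genes)) + "\n")


def ease_enrichment(
    gene_list,
    gene_sets: dict[str, set[str]],
    background,
    p_cut: float = 0.01,
    min_genes: int = 2,
) -> pd.DataFrame:
    """EASE-score enrichment of the gene list against each gene set.

    For each set a 2x2 table over the background is built (a' = overlap,
    a'+b = list size, a'+c = set size within the background) and the EASE
    score is the hypergeometric upper-tail probability P(X >= a) computed
    with the jackknifed count a = max(a'-1, 0).  ``passes`` flags sets with
    EASE score below ``p_cut`` and more than ``min_genes`` list genes.
    The plain Fisher p (with a') is reported alongside; EASE is never
    smaller than it.
    """
    background = set(background)
    gene_list = set(gene_list)
    if not gene_list or not background:
        raise ValueError("gene list and background must be non-empty")
    if not gene_list <= background:
        raise ValueError("gene list must be a subset of the background")
    n = len(background)
    rows = []
    for name, members in gene_sets.items():
        members = members & background
        a_prime = len(gene_list & members)
        list_size = len(gene_list)
        set_size = len(members)
        a = max(a_prime - 1, 0)
        ease_p = float(stats.hypergeom.sf(a - 1, n, set_size, list_size))
        fisher_p = float(stats.hypergeom.sf(a_prime - 1, n, set_size, list_size))
        rows.append(
            {
                "set": name,
                "a_prime": a_prime,
                "b": list_size - a_prime,
                "c": set_size - a_prime,
                "d": n - list_size - set_size + a_prime,
                "ease_p": ease_p,
                "fisher_p": fisher_p,
                "passes": (ease_p < p_cut) and (a_prime > min_genes),
            }
        )
    return pd.DataFrame(rows).set_index("set")


def difference_matrix(tumor, normal=None, log_scale: bool = True) -> pd.DataFrame:
    """Per-patient, per-gene expression differences against the cohort mean.

    With matched genes x patients matrices the per-patient log-ratio
    log(T/N) is computed (inputs already on log scale by default, in which
    case the ratio is the difference T - N), then centered by each gene's
    average log-ratio across patients.  With ``log_scale=False`` raw
    intensities are log2-transformed first and must be strictly positive.
    """
    t = pd.DataFrame(tumor).astype(float)
    if normal is not None:
        n = pd.DataFrame(normal).astype(float)
        if not t.index.equals(n.index) or not t.columns.equals(n.columns):
            raise ValueError("tumor and normal matrices must be aligned")
        if log_scale:
            ratio = t - n
        else:
            if (t.to_numpy() <= 0).any() or (n.to_numpy() <= 0).any():
                raise ValueError(
                    "non-positive intensities: pass log-scale data with "
                    "log_scale=True, or strictly positive raw intensities"
                )
            ratio = np.log2(t / n)
    else:
        ratio = t
    return ratio.sub(ratio.mean(axis=1), axis=0)


@dataclass
class NEAResult:
    """Connectivity of an AGS/FGS pair against the degree-preserving null."""

    n_af: int
    mu_af: float
    sd_af: float
    d_af: float
    z: float
    p: float
    R: int
    seed: int


def _count_links(edges, ags: set, fgs: set) -> int:
    """Edges with one endpoint in AGS and the other in FGS, counted once."""
    return sum(
        1
        for u, v in edges
        if (u in ags and v in fgs) or (u in fgs and v in ags)
    )


def _edge_swap(net: nx.Graph, nswap: int, rng) -> nx.Graph:
    """Degree-preserving randomization by double-edge swap attempts.

    Performs ``nswap`` swap *attempts*; proposals that would create a
    self-loop or a duplicate edge are rejected, so fully constrained graphs
    simply come back unchanged.  The degree sequence is always preserved.
    """
    edges = [tuple(e) for e in net.edges()]
    adj = {n: set(net.neighbors(n)) for n in net.nodes()}
    m = len(edges)
    if m < 2:
        return net.copy()
    for _ in range(nswap):
        i, j = rng.choice(m, size=2, replace=False)
        u, v = edges[i]
        x, y = edges[j]
        if rng.random() < 0.5:
            x, y = y, x
        # propose (u,v),(x,y) -> (u,x),(v,y)
        if len({u, v, x, y}) < 4:
            continue
        if x in adj[u] or y in adj[v]:
            continue
        adj[u].discard(v); adj[v].discard(u)
        adj[x].discard(y); adj[y].discard(x)
        adj[u].add(x); adj[x].add(u)
        adj[v].add(y); adj[y].add(v)
        edges[i] = (u, x)
        edges[j] = (v, y)
    out = nx.Graph()
    out.add_nodes_from(net.nodes())
    out.add_edges_from(edges)
    return out


def nea(
    ags,
    fgs,
    net: nx.Graph,
    R: int = 200,
    seed: int = 0,
    nswap_factor: int = 10,
) -> NEAResult:
    """Network enrichment of AGS against FGS over the supplied network.

    n_AF counts network edges with one endpoint in the AGS and the other in
    the FGS (an edge whose endpoints both lie in the intersection counts
    once).  The null draws R randomized networks, each obtained from the
    observed one by ``nswap_factor * |edges|`` degree-preserving double-edge
    swap attempts; mu_AF and sd are the null moments, d_AF = n_AF - mu_AF,
    z = d_AF/sd and p the add-one empirical upper-tail estimate
    (1 + #{null >= n_AF}) / (R + 1).
    """
    if R < 20:
        raise ValueError("R must be at least 20 for a usable null")
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = set(net.nodes())
    ags = set(ags) & nodes
    fgs = set(fgs) & nodes
    n_af = _count_links(net.edges(), ags, fgs)
    rng = np.random.default_rng(seed)
    nswap = nswap_factor * net.number_of_edges()
    observed_degrees = dict(net.degree())
    null = np.empty(R)
    for r in range(R):
        randomized = _edge_swap(net, nswap, rng)
        assert dict(randomized.degree()) == observed_degrees
        null[r] = _count_links(randomized.edges(), ags, fgs)
    mu = float(null.mean())
    sd = float(null.std(ddof=1)) if R > 1 else 0.0
    d = float(n_af - mu)
    if sd > 0:
        z = d / sd
    else:
        z = 0.0 if d == 0 else float(np.sign(d)) * np.inf
    p = float((1 + (null >= n_af).sum()) / (R + 1))
    return NEAResult(
        n_af=n_af, mu_af=mu, sd_af=sd, d_af=d, z=z, p=p, R=R, seed=seed
    )


def write_hub_tsv(net: nx.Graph, hubs: set, path) -> None:
    degrees = dict(net.degree())
    pd.DataFrame(
        {
            "gene": sorted(degrees),
            "degree": [degrees[g] for g in sorted(degrees)],
            "is_hub": [g in hubs for g in sorted(degrees)],
        }
    ).to_csv(path, sep="\t", index=False)
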