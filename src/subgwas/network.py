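"""wTO co-expression networks, egocentric neighborhoods and enrichment.

Per tissue, expression correlation is sharpened into a soft adjacency
:math:`A_{ij} = |\\mathrm{cor}(i,j)|^6` (WGCNA-style soft thresholding, zero
diagonal) and edges are weighted by the weighted topological overlap

.. math::

    wTO_{ij} = \\frac{A_{ij} + \\sum_{k \\ne i,j} A_{ik} A_{kj}}
                     {\\min(k_i, k_j) + 1 - A_{ij}},
    \\qquad k_i = \\sum_{u \\ne i} A_{iu},

which rewards gene pairs that are both directly correlated and share
neighbors.  Only the strongest 15% of links per tissue are kept.  For each
GWAS target gene, the egocentric network is its 25 strongest surviving
direct links; per-tissue egos are merged with the weight
:math:`\\sum_w wTO_{ij,w}^2` over the tissues in which the neighbor makes
the target's top 25.  Genes linked to two or more targets form the shared
neighborhood, which is tested for gene-set over-representation with Fisher's
exact (hypergeometric upper-tail) test and Benjamini–Hochberg FDR control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_POWER = 6
DEFAULT_TOP_FRACTION = 0.15
DEFAULT_EGO_K = 25


@dataclass
class WTONetwork:
    """Edge list of one tissue's wTO network (each unordered pair stored once)."""

    edges: pd.DataFrame  # columns gene_a, gene_b, weight; gene_a < gene_b
    tissue: str
    genes: tuple[str, ...] = ()


@dataclass
class EgoNetwork:
    """A target gene's strongest direct wTO links (weights sorted descending)."""

    target: str
    neighbors: pd.DataFrame  # columns neighbor, weight
    tissue: str  # tissue name, or "merged"


@dataclass
class SharedNeighborhood:
    """Genes linked to two or more target genes across merged ego networks."""

    edges: pd.DataFrame  # columns target, neighbor, weight
    targets_per_neighbor: pd.Series  # neighbor -> number of linked targets
    n_targets_largest_component: int
    shared_genes: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Adjacency and wTO
# ---------------------------------------------------------------------------


def soft_adjacency(expr: pd.DataFrame, power: int = DEFAULT_POWER) -> pd.DataFrame:
    """Soft-threshold adjacency ``|pearson(i,j)|^power`` with zero diagonal.

    ``expr`` is genes × samples.  Constant-expression genes must be removed
    beforehand (use :func:`drop_constant_genes`); one reaching this stage
    raises an error naming it.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for a correlation network")
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if (sd == 0).any():
        bad = expr.index[sd == 0][0]
        raise ValueError(f"constant-expression gene {bad!r}; drop it before building the network")
    r = np.corrcoef(values)
    a = np.abs(r) ** power
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def drop_constant_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Remove genes with zero variance in this tissue (logged)."""
    sd = expr.to_numpy(dtype=float).std(axis=1)
    n_bad = int((sd == 0).sum())
    if n_bad:
        logger.info("drop_constant_genes: removed %d constant genes", n_bad)
    return expr.loc[sd > 0]


def wto_matrix(adjacency: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Dense wTO matrix from a soft adjacency (vectorised form of the edge rule)."""
    a = np.asarray(adjacency, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T):
        raise ValueError("adjacency must be square and symmetric")
    if np.diagonal(a).any():
        raise ValueError("adjacency diagonal must be zero")
    k = a.sum(axis=1)
    numer = a + a @ a  # zero diagonal kills the k=i and k=j self terms
    denom = np.minimum.outer(k, k) + 1.0 - a
    w = numer / denom
    np.fill_diagonal(w, 0.0)
    return w


def wto_network(adjacency: pd.DataFrame, tissue: str = "") -> WTONetwork:
    """All-to-all wTO edge list for one tissue (upper triangle only)."""
    w = wto_matrix(adjacency)
    genes = np.asarray(adjacency.index, dtype=object)
    iu, ju = np.triu_indices(len(genes), k=1)
    edges = pd.DataFrame(
        {"gene_a": genes[iu], "gene_b": genes[ju], "weight": w[iu, ju]}
    )
    return WTONetwork(edges=edges, tissue=tissue, genes=tuple(genes))


def top_fraction_filter(net: WTONetwork, fraction: float = DEFAULT_TOP_FRACTION) -> WTONetwork:
    """Keep the ``ceil(fraction · M)`` strongest of the M stored edges.

    Ties at the cutoff weight are broken by (gene_a, gene_b) lexicographic
    order and logged.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    m = len(net.edges)
    if m == 0:
        return WTONetwork(edges=net.edges.copy(), tissue=net.tissue, genes=net.genes)
    n_keep = math.ceil(fraction * m)
    ordered = net.edges.sort_values(
        ["weight", "gene_a", "gene_b"], ascending=[False, True, True], kind="mergesort"
    )
    cutoff = ordered["weight"].iloc[n_keep - 1]
    n_at_cutoff = int((net.edges["weight"] == cutoff).sum())
    n_kept_at_cutoff = int((ordered["weight"].iloc[:n_keep] == cutoff).sum())
    if n_at_cutoff > n_kept_at_cutoff:
        logger.info(
            "top_fraction_filter: %d ties at cutoff weight %.6g; kept %d lexicographically",
            n_at_cutoff, cutoff, n_kept_at_cutoff,
        )
    kept = ordered.iloc[:n_keep].reset_index(drop=True)
    return WTONetwork(edges=kept, tissue=net.tissue, genes=net.genes)


# ---------------------------------------------------------------------------
# Egocentric networks
# ---------------------------------------------------------------------------


def egocentric_extract(net: WTONetwork, target: str, k: int = DEFAULT_EGO_K) -> EgoNetwork:
    """The target's ≤k strongest surviving direct links.

    A target with no surviving edges yields an empty ego network (flagged in
    the log — some GWAS genes show no strong co-expression in a tissue).
    """
    if net.genes and target not in net.genes:
        raise ValueError(f"target {target!r} not in the gene universe")
    e = net.edges
    touching = e[(e["gene_a"] == target) | (e["gene_b"] == target)].copy()
    if touching.empty:
        logger.info("egocentric_extract: target %s has no surviving links in %s", target, net.tissue)
        return EgoNetwork(target=target, neighbors=pd.DataFrame(columns=["neighbor", "weight"]), tissue=net.tissue)
    touching["neighbor"] = np.where(
        touching["gene_a"] == target, touching["gene_b"], touching["gene_a"]
    )
    ranked = touching.sort_values(
        ["weight", "neighbor"], ascending=[False, True], kind="mergesort"
    ).head(k)
    return EgoNetwork(
        target=target,
        neighbors=ranked[["neighbor", "weight"]].reset_index(drop=True),
        tissue=net.tissue,
    )


def merge_tissue_egos(egos: Sequence[EgoNetwork], k: int = DEFAULT_EGO_K) -> EgoNetwork:
    """Merge one target's per-tissue egos with weight Σ (per-tissue wTO)².

    A tissue contributes to a neighbor's merged weight only when the
    neighbor is among that tissue's top-k for the target.  The merged ego is
    the top k candidates by merged weight (ties lexicographic, logged).
    """
    targets = {e.target for e in egos}
    if len(targets) != 1:
        raise ValueError(f"mixed targets in merge: {sorted(targets)}")
    target = targets.pop()
    acc: dict[str, float] = {}
    for ego in egos:
        for neighbor, weight in zip(ego.neighbors["neighbor"], ego.neighbors["weight"]):
            acc[neighbor] = acc.get(neighbor, 0.0) + float(weight) ** 2
    merged = pd.DataFrame(
        sorted(acc.items(), key=lambda kv: (-kv[1], kv[0])), columns=["neighbor", "weight"]
    )
    if len(merged) > k:
        cutoff = merged["weight"].iloc[k - 1]
        if (merged["weight"] == cutoff).sum() > (merged["weight"].iloc[:k] == cutoff).sum():
            logger.info("merge_tissue_egos: ties at merged-weight cutoff for %s", target)
    return EgoNetwork(target=target, neighbors=merged.head(k).reset_index(drop=True), tissue="merged")


def shared_neighborhood(merged_egos: Sequence[EgoNetwork]) -> SharedNeighborhood:
    """Neighbors appearing in ≥2 merged egos, with their target links.

    Also reports how many targets each shared gene connects (node-size
    semantics of the shared-neighborhood plots) and how many targets the
    largest connected component of the target↔neighbor graph joins.
    """
    if len(merged_egos) < 2:
        raise ValueError("shared neighborhoods need at least two targets")
    rows = []
    for ego in merged_egos:
        for neighbor, weight in zip(ego.neighbors["neighbor"], ego.neighbors["weight"]):
            rows.append((ego.target, neighbor, float(weight)))
    edges = pd.DataFrame(rows, columns=["target", "neighbor", "weight"])
    counts = edges.groupby("neighbor")["target"].nunique()
    shared = counts[counts >= 2].index
    kept = edges[edges["neighbor"].isin(shared)].reset_index(drop=True)
    targets_per_neighbor = counts.loc[shared].sort_values(ascending=False)
    n_joined = 0
    if not kept.empty:
        g = nx.Graph()
        targets = {e.target for e in merged_egos}
        g.add_edges_from(zip("T:" + kept["target"], "N:" + kept["neighbor"]))
        comp_sizes = [
            sum(1 for node in comp if node.startswith("T:"))
            for comp in nx.connected_components(g)
        ]
        n_joined = max(comp_sizes, default=0)
    return SharedNeighborhood(
        edges=kept,
        targets_per_neighbor=targets_per_neighbor,
        n_targets_largest_component=n_joined,
        shared_genes=tuple(sorted(shared)),
    )


# ---------------------------------------------------------------------------
# Over-representation enrichment
# ---------------------------------------------------------------------------


def fisher_enrichment(
    study: Sequence[str],
    term_sets: Mapping[str, Sequence[str]],
    background: Sequence[str],
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher's exact over-representation of flat term sets, BH-adjusted.

    For each term with K annotated background genes, the p-value is the
    hypergeometric upper tail P(X ≥ k) of drawing k annotated genes in a
    study set of size n from a background of size N.  Fold enrichment is
    (k/n)/(K/N).  Terms with K = 0 are skipped; the FDR column is
    Benjamini–Hochberg over all tested terms.
    """
    bg = set(background)
    st = set(study)
    stray = sorted(st - bg)
    if stray:
        raise ValueError(f"study genes outside the background: {stray[:10]}")
    n_bg = len(bg)
    n_study = len(st)
    rows = []
    for term in sorted(term_sets):
        members = set(term_sets[term]) & bg
        big_k = len(members)
        if big_k == 0:
            continue
        k = len(members & st)
        p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_study)) if n_study else 1.0
        fe = (k / n_study) / (big_k / n_bg) if n_study else 0.0
        rows.append({"term": term, "K": big_k, "N": n_bg, "n_study": n_study, "k_study": k,
                     "fold_enrichment": fe, "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["term", "K", "N", "n_study", "k_study", "fold_enrichment", "p"])
    if out.empty:
        out["fdr"] = []
        out["significant"] = []
        return out
    from statsmodels.stats.multitest import multipletests

    _, fdr, _, _ = multipletests(out["p"], method="fdr_bh")
    out["fdr"] = np.maximum(fdr, out["p"])
    out["significant"] = out["fdr"] < fdr_alpha
    return out.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Convenience pipeline
# ---------------------------------------------------------------------------


def build_merged_egos(
    panels: Mapping[str, pd.DataFrame],
    targets: Sequence[str],
    power: int = DEFAULT_POWER,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    k: int = DEFAULT_EGO_K,
) -> dict[str, EgoNetwork]:
    """Per-tissue wTO → top-fraction filter → per-target ego → cross-tissue merge."""
    per_target: dict[str, list[EgoNetwork]] = {t: [] for t in targets}
    for tissue, expr in panels.items():
        expr = drop_constant_genes(expr)
        net = top_fraction_filter(wto_network(soft_adjacency(expr, power=power), tissue=tissue), top_fraction)
        for t in targets:
            if t not in net.genes:
                logger.info("build_merged_egos: target %s absent from %s", t, tissue)
                continue
            per_target[t].append(egocentric_extract(net, t, k=k))
    return {t: merge_tissue_egos(egos, k=k) if egos else EgoNetwork(t, pd.DataFrame(columns=["neighbor", "weight"]), "merged")
            for t, egos in per_target.items()}
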