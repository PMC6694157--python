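"""Pathway extension by limited random walks on weighted gene networks.

The weighted network is read as a Markov chain: each gene is a state and the
transition probability from gene i to gene j is the normalised edge weight

    P_ij = W_ij / sum_j W_ij.

For a pathway, its genes mapped into the network act as seeds.  From each
seed in turn, walks start, are absorbed the first time they reach any
*other* seed, and are truncated after L steps.  The relevance of a node (or
edge) is the expected number of times such walks enter it, accumulated by
forward probability propagation over the absorbing chain and averaged
uniformly over start seeds.  A companion score, the *seed delivery*, is the
expected mass a node hands directly into absorbing seeds; it separates
genes that route walks between pathway genes from genes that merely soak up
wandering probability, and is the default ranking when selecting the
extension.  The case- and control-network extensions are united with the
mapped genes into the final extended gene list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PathwayCollection
from .scca import WeightedNetwork

log = logging.getLogger(__name__)

# Short walks keep relevance local to seed-to-seed routes; long limits let
# probability mass diffuse into the network bulk where hub inflow swamps the
# genuinely connecting genes.
DEFAULT_WALK_LIMIT = 3


@dataclass
class TransitionMatrix:
    nodes: list[str]  # node order of P's rows/columns
    P: np.ndarray  # row-stochastic over non-isolated nodes

    def __post_init__(self) -> None:
        self.index = {g: i for i, g in enumerate(self.nodes)}


@dataclass
class RelevanceScores:
    seeds: list[str]  # mapped start seeds actually used
    L: int
    node_relevance: dict[str, float]  # expected entries into the node
    edge_relevance: dict[frozenset, float]
    seed_delivery: dict[str, float] = field(default_factory=dict)
    # expected mass the node passes directly into absorbing seeds

    @property
    def empty(self) -> bool:
        return not self.node_relevance and not self.edge_relevance


@dataclass
class SelectionRule:
    """How to truncate the relevance ranking into an extension set.

    ``ranking`` picks the score: ``delivery`` (default) ranks non-seed genes
    by the walk mass they hand directly into absorbing seeds, ``inflow`` by
    total expected entries.  ``mass`` (default kind): smallest prefix of the
    sorted candidates holding ``mass_fraction`` of the total score, capped
    at ``cap_factor`` times the mapped pathway size.  ``top_k``: fixed
    count.  ``quantile``: genes above the given score quantile.
    """

    kind: str = "mass"
    ranking: str = "delivery"
    k: int = 10
    quantile: float = 0.9
    mass_fraction: float = 0.7
    cap_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.kind not in ("mass", "top_k", "quantile"):
            raise ValueError(f"unknown selection rule {self.kind!r}")
        if self.ranking not in ("delivery", "inflow"):
            raise ValueError(f"unknown ranking {self.ranking!r}")


@dataclass
class ExtendedPathway:
    pathway_id: str
    pathway_name: str
    original_genes: list[str]
    mapped_genes: set[str]
    extension_case: set[str]
    extension_control: set[str]

    @property
    def final_genes(self) -> set[str]:
        return self.mapped_genes | self.extension_case | self.extension_control

    def final_gene_list(self) -> list[str]:
        # mapped originals first (input order), then extensions alphabetically
        ordered = [g for g in self.original_genes if g in self.mapped_genes]
        ordered += sorted(self.final_genes - self.mapped_genes)
        return ordered


def transition_matrix(net: WeightedNetwork) -> TransitionMatrix:
    """Row-normalise edge weights into walk probabilities (Markov chain).

    Nodes whose incident weights are all zero cannot be walked through; they
    are excluded from the chain (and logged).
    """
    nodes = sorted(net.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for edge, w in net.weights.items():
        a, b = sorted(edge)
        W[index[a], index[b]] = w
        W[index[b], index[a]] = w
    strength = W.sum(axis=1)
    keep = strength > 0
    if not keep.all():
        isolated = [g for g, k in zip(nodes, keep) if not k]
        log.info("excluding %d nodes with zero incident weight: %s",
                 len(isolated), isolated[:5])
    nodes = [g for g, k in zip(nodes, keep) if k]
    W = W[np.ix_(keep, keep)]
    P = W / W.sum(axis=1, keepdims=True)
    return TransitionMatrix(nodes, P)


def limited_kwalks(tm: TransitionMatrix, seeds: set[str], L: int = DEFAULT_WALK_LIMIT) -> RelevanceScores:
    """Expected passage counts of L-truncated seed-to-seed walks.

    For a start seed s the chain P' makes every other mapped seed absorbing.
    With forward probabilities alpha_0 = e_s and
    alpha_{t+1}(j) = sum_i alpha_t(i) P'_ij over transient i, the expected
    number of traversals of edge (i, j) is sum_{t<L} alpha_t(i) P'_ij and a
    node's relevance is its total expected inflow.  Scores are averaged
    uniformly over start seeds.  Fewer than two mapped seeds make seed-to-seed
    walks undefined: an empty relevance is returned.
    """
    if L < 1:
        raise ValueError(f"walk limit must be >= 1, got {L}")
    mapped = sorted(seeds & set(tm.nodes))
    if len(mapped) < 2:
        log.warning("fewer than 2 seeds mapped into the network; skipping walks")
        return RelevanceScores(mapped, L, {}, {})

    n = len(tm.nodes)
    seed_idx = np.array([tm.index[g] for g in mapped])
    passage = np.zeros((n, n))  # directed expected edge traversals, summed over starts
    delivery = np.zeros(n)
    for s in seed_idx:
        Pprime = tm.P.copy()
        absorbing = seed_idx[seed_idx != s]
        Pprime[absorbing, :] = 0.0  # walk stops on arrival at another seed
        alpha = np.zeros(n)
        alpha[s] = 1.0
        for _ in range(L):
            flow = Pprime * alpha[:, None]
            passage += flow
            delivery += flow[:, absorbing].sum(axis=1)
            alpha = flow.sum(axis=0)
            if alpha.sum() < 1e-15:
                break
    passage /= len(mapped)
    delivery /= len(mapped)

    inflow = passage.sum(axis=0)
    node_relevance = {g: float(inflow[i]) for g, i in tm.index.items()}
    seed_delivery = {g: float(delivery[i]) for g, i in tm.index.items()}
    edge_relevance: dict[frozenset, float] = {}
    ij = np.argwhere(passage + passage.T > 0)
    for i, j in ij:
        if i < j:
            edge = frozenset((tm.nodes[i], tm.nodes[j]))
            edge_relevance[edge] = float(passage[i, j] + passage[j, i])
    return RelevanceScores(mapped, L, node_relevance, edge_relevance, seed_delivery)


def select_extension(rel: RelevanceScores, seeds: set[str], rule: SelectionRule | None = None) -> set[str]:
    """Truncate the non-seed relevance ranking into the extension gene set.

    Ties at the cutoff are broken deterministically: higher score first,
    then lexicographically smaller gene symbol.
    """
    rule = rule or SelectionRule()
    scores = rel.seed_delivery if rule.ranking == "delivery" and rel.seed_delivery else rel.node_relevance
    candidates = [(g, r) for g, r in scores.items() if g not in seeds and r > 0]
    candidates.sort(key=lambda gr: (-gr[1], gr[0]))
    if not candidates:
        return set()

    if rule.kind == "top_k":
        return {g for g, _ in candidates[: max(rule.k, 0)]}
    if rule.kind == "quantile":
        cut = float(np.quantile([r for _, r in candidates], rule.quantile))
        return {g for g, r in candidates if r >= cut}

    total = sum(r for _, r in candidates)
    cap = max(1, int(math.floor(rule.cap_factor * len(rel.seeds))))
    chosen: set[str] = set()
    acc = 0.0
    for g, r in candidates[:cap]:
        if acc >= rule.mass_fraction * total:
            break
        chosen.add(g)
        acc += r
    return chosen


def extend_pathway(
    pathway: tuple[str, str, list[str]],
    net_case: WeightedNetwork,
    net_control: WeightedNetwork,
    L: int = DEFAULT_WALK_LIMIT,
    rule: SelectionRule | None = None,
    tm_case: TransitionMatrix | None = None,
    tm_control: TransitionMatrix | None = None,
) -> ExtendedPathway:
    """Extend one pathway in both phenotype networks and unite the results.

    Precomputed transition matrices may be passed to avoid rebuilding them
    for every pathway.
    """
    pid, name, genes = pathway
    original = set(genes)
    tm_case = tm_case or transition_matrix(net_case)
    tm_control = tm_control or transition_matrix(net_control)
    mapped = original & (set(tm_case.nodes) | set(tm_control.nodes))

    extensions: dict[str, set[str]] = {}
    for label, tm in (("case", tm_case), ("control", tm_control)):
        rel = limited_kwalks(tm, original, L)
        if rel.empty:
            log.warning("pathway %s: <2 genes mapped in %s network, not extended", pid, label)
            extensions[label] = set()
        else:
            extensions[label] = select_extension(rel, original, rule)
    return ExtendedPathway(pid, name, genes, mapped, extensions["case"], extensions["control"])


def extend_collection(
    collection: PathwayCollection,
    net_case: WeightedNetwork,
    net_control: WeightedNetwork,
    L: int = DEFAULT_WALK_LIMIT,
    rule: SelectionRule | None = None,
) -> list[ExtendedPathway]:
    tm_case = transition_matrix(net_case)
    tm_control = transition_matrix(net_control)
    return [
        extend_pathway(p, net_case, net_control, L, rule, tm_case, tm_control)
        for p in collection
    ]


def extended_collection(extended: list[ExtendedPathway]) -> PathwayCollection:
    """Extended pathways as a GMT-writable collection (final gene lists)."""
    return PathwayCollection(
        [(e.pathway_id, e.pathway_name, e.final_gene_list()) for e in extended if e.final_genes]
    )


def extension_report(extended: list[ExtendedPathway]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway_id": e.pathway_id,
                "n_original": len(e.original_genes),
                "n_mapped": len(e.mapped_genes),
                "n_extension_case": len(e.extension_case),
                "n_extension_control": len(e.extension_control),
                "n_final": len(e.final_genes),
            }
            for e in extended
        ]
    )


def write_relevance_edges(rel: RelevanceScores, path) -> None:
    """Relevance-annotated subnetwork edge list for visualisation tools."""
    rows = [
        (*sorted(edge), f"{r:.10g}")
        for edge, r in sorted(rel.edge_relevance.items(), key=lambda kv: -kv[1])
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "relevance"]).to_csv(
        path, sep="\t", index=False
    )
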