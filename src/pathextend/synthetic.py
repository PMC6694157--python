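"""Fully in-silico input bundles with planted, recoverable structure.

The generator emulates a two-phenotype multi-omics cohort over a gene
interaction network:

* a preferential-attachment background graph (realistic degree skew);
* disjoint pathways drawn as connected subgraphs of the background;
* planted *bridge* genes outside every pathway, each wired to several genes
  of its pathway — the ground truth the extension step should recover;
* a latent-factor cohort: genes of a pathway (and its bridges) share a
  per-sample factor with weight ``coupling_strength``, the factor drives
  expression directly and CpG beta values inversely (promoter-methylation
  convention) on the logit scale, so methylation and expression of coupled
  gene pairs co-vary the way the edge-weighting step expects;
* optional differential expression: a mean shift of ``de_effect_size`` in
  case samples, planted on the bridge genes by default.

Everything is deterministic given the spec's seed, and every generated file
parses back through the package's own readers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    CASE,
    CONTROL,
    ExpressionMatrix,
    InteractionEdgeList,
    MethylationMatrix,
    PathwayCollection,
    PhenotypeLabels,
    ProbeGeneMap,
    write_edges,
    write_expression,
    write_gmt,
    write_methylation,
    write_phenotypes,
    write_probe_map,
)


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic dataset."""

    seed: int
    n_genes: int = 200
    n_probes_per_gene: tuple[int, int] = (1, 5)
    n_samples_per_class: int = 40
    n_pathways: int = 5
    pathway_size: tuple[int, int] = (15, 15)
    n_planted_bridges_per_pathway: int = 3
    bridge_degree: int = 3  # seed genes each bridge is wired to
    coupling_strength: float = 0.8
    de_effect_size: float = 1.0
    noise_sd: float = 0.5
    de_target: str = "bridges"  # bridges | pathways | none

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("n_genes", "n_samples_per_class", "n_pathways",
                     "n_planted_bridges_per_pathway", "bridge_degree"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.coupling_strength < 1.0):
            raise ValueError("coupling_strength must lie in [0, 1)")
        if self.de_target not in ("bridges", "pathways", "none"):
            raise ValueError(f"unknown de_target {self.de_target!r}")
        need = self.n_pathways * (self.pathway_size[1] + self.n_planted_bridges_per_pathway)
        if need > self.n_genes:
            raise ValueError(
                f"infeasible spec: {need} pathway+bridge genes exceed {self.n_genes} genes"
            )


@dataclass
class PlantedTruth:
    """Ground truth for recovery scoring."""

    pathway_genes: dict[str, list[str]]
    bridges: dict[str, list[str]]  # pathway_id -> planted bridge genes
    de_genes: list[str]
    gene_group: dict[str, str] = field(default_factory=dict)  # gene -> pathway_id

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _gene_symbols(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _grow_connected(graph: nx.Graph, start: str, size: int, allowed: set[str], rng) -> set[str] | None:
    chosen = {start}
    frontier = sorted(set(graph[start]) & allowed)
    while len(chosen) < size and frontier:
        nxt = frontier[rng.integers(len(frontier))]
        chosen.add(nxt)
        frontier = sorted((set().union(*(set(graph[g]) for g in chosen)) & allowed) - chosen)
    return chosen if len(chosen) == size else None


def generate_network_and_pathways(
    spec: FixtureSpec,
) -> tuple[InteractionEdgeList, PathwayCollection, PlantedTruth]:
    """Background graph, connected disjoint pathways and wired-in bridges."""
    rng = np.random.default_rng([spec.seed, 0])
    symbols = _gene_symbols(spec.n_genes)
    ba = nx.barabasi_albert_graph(spec.n_genes, m=2, seed=int(rng.integers(2**31)))
    graph = nx.relabel_nodes(ba, dict(enumerate(symbols)))

    unused = set(symbols)
    pathways: list[tuple[str, str, list[str]]] = []
    truth_pathways: dict[str, list[str]] = {}
    for i in range(spec.n_pathways):
        size = int(rng.integers(spec.pathway_size[0], spec.pathway_size[1] + 1))
        members: set[str] | None = None
        for _ in range(200):
            start = sorted(unused)[rng.integers(len(unused))]
            members = _grow_connected(graph, start, size, unused, rng)
            if members is not None:
                break
        if members is None:
            raise RuntimeError("could not grow a connected pathway; graph too fragmented")
        unused -= members
        pid = f"PW{i + 1:02d}"
        pathways.append((pid, f"synthetic pathway {i + 1}", sorted(members)))
        truth_pathways[pid] = sorted(members)

    bridges: dict[str, list[str]] = {}
    gene_group: dict[str, str] = {}
    for pid, _, members in pathways:
        picked = sorted(unused)
        sel = rng.choice(len(picked), size=spec.n_planted_bridges_per_pathway, replace=False)
        chosen = [picked[j] for j in sorted(sel)]
        bridges[pid] = chosen
        unused -= set(chosen)
        for bridge in chosen:
            anchors = rng.choice(len(members), size=min(spec.bridge_degree, len(members)), replace=False)
            for j in anchors:
                graph.add_edge(bridge, members[j])
        for g in members + chosen:
            gene_group[g] = pid

    if spec.de_target == "bridges":
        de_genes = sorted(g for bs in bridges.values() for g in bs)
    elif spec.de_target == "pathways":
        de_genes = sorted(g for gs in truth_pathways.values() for g in gs)
    else:
        de_genes = []

    edges = InteractionEdgeList({frozenset(e) for e in graph.edges()})
    truth = PlantedTruth(truth_pathways, bridges, de_genes, gene_group)
    return edges, PathwayCollection(pathways), truth


def generate_cohort(
    spec: FixtureSpec,
    truth: PlantedTruth | None = None,
) -> tuple[ExpressionMatrix, MethylationMatrix, ProbeGeneMap, PhenotypeLabels]:
    """Latent-factor cohort matching the planted network structure."""
    if truth is None:
        _, _, truth = generate_network_and_pathways(spec)
    rng = np.random.default_rng([spec.seed, 1])
    symbols = _gene_symbols(spec.n_genes)
    n = 2 * spec.n_samples_per_class
    samples = [f"S{i:03d}" for i in range(1, n + 1)]
    labels = PhenotypeLabels(
        {s: (CASE if i < spec.n_samples_per_class else CONTROL) for i, s in enumerate(samples)}
    )
    is_case = np.array([labels.labels[s] == CASE for s in samples])

    c = spec.coupling_strength
    group_ids = sorted({pid for pid in truth.gene_group.values()})
    factors = {pid: rng.standard_normal(n) for pid in group_ids}

    z = np.empty((spec.n_genes, n))
    for gi, gene in enumerate(symbols):
        eps = rng.standard_normal(n)
        pid = truth.gene_group.get(gene)
        if pid is None:
            z[gi] = eps
        else:
            z[gi] = np.sqrt(c) * factors[pid] + np.sqrt(1.0 - c) * eps

    expr_values = z + spec.noise_sd * rng.standard_normal((spec.n_genes, n))
    de_rows = [i for i, g in enumerate(symbols) if g in set(truth.de_genes)]
    if de_rows:
        expr_values[np.ix_(de_rows, np.where(is_case)[0])] += spec.de_effect_size
    expr = ExpressionMatrix(pd.DataFrame(expr_values, index=symbols, columns=samples))

    # methylation: shared per-gene latent, anticorrelated with expression signal
    probes_by_gene: dict[str, list[str]] = {}
    probe_rows: list[np.ndarray] = []
    probe_ids: list[str] = []
    counter = 1
    lo, hi = spec.n_probes_per_gene
    for gi, gene in enumerate(symbols):
        m_g = np.sqrt(c) * z[gi] + np.sqrt(1.0 - c) * rng.standard_normal(n)
        u = int(rng.integers(lo, hi + 1))
        ids = [f"cg{counter + j:06d}" for j in range(u)]
        counter += u
        probes_by_gene[gene] = ids
        for _ in range(u):
            mu = rng.normal(0.0, 1.0)
            logit = mu - 1.5 * m_g + 0.5 * rng.standard_normal(n)
            probe_rows.append(1.0 / (1.0 + np.exp(-logit)))
        probe_ids.extend(ids)
    meth = MethylationMatrix(pd.DataFrame(np.vstack(probe_rows), index=probe_ids, columns=samples))
    return expr, meth, ProbeGeneMap(probes_by_gene), labels


def generate_bundle(spec: FixtureSpec):
    """Complete input bundle: cohort + network + pathways + ground truth."""
    edges, collection, truth = generate_network_and_pathways(spec)
    expr, meth, pmap, labels = generate_cohort(spec, truth)
    return expr, meth, pmap, labels, edges, collection, truth


def write_bundle(spec: FixtureSpec, outdir) -> dict[str, str]:
    """Write the full bundle as TSV/GMT/JSON files; returns path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, meth, pmap, labels, edges, collection, truth = generate_bundle(spec)
    paths = {
        "expression": outdir / "expression.tsv",
        "methylation": outdir / "methylation.tsv",
        "probe_map": outdir / "probe_map.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "edges": outdir / "edges.tsv",
        "pathways": outdir / "pathways.gmt",
        "truth": outdir / "truth.json",
    }
    write_expression(expr, paths["expression"])
    write_methylation(meth, paths["methylation"])
    write_probe_map(pmap, paths["probe_map"])
    write_phenotypes(labels, paths["phenotypes"])
    write_edges(edges, paths["edges"])
    write_gmt(collection, paths["pathways"])
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def mini_spec(seed: int) -> FixtureSpec:
    """Small preset used by the test suite (fast end-to-end runs)."""
    return FixtureSpec(
        seed=seed,
        n_genes=100,
        n_probes_per_gene=(1, 3),
        n_samples_per_class=15,
        n_pathways=3,
        pathway_size=(8, 10),
        n_planted_bridges_per_pathway=2,
        coupling_strength=0.8,
    )


def recovery_scores(
    extended_by_pathway: dict[str, set[str]],
    truth: PlantedTruth,
) -> tuple[float, float]:
    """Micro-averaged (recall, precision) of extensions vs planted bridges."""
    tp = fp = fn = 0
    for pid, planted in truth.bridges.items():
        selected = extended_by_pathway.get(pid, set())
        planted_set = set(planted)
        tp += len(selected & planted_set)
        fp += len(selected - planted_set)
        fn += len(planted_set - selected)
    recall = tp / (tp + fn) if tp + fn else 1.0
    precision = tp / (tp + fp) if tp + fp else 1.0
    return recall, precision
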