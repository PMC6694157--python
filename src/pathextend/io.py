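"""Readers, writers and in-memory containers for every external format.

All tabular inputs are UTF-8, tab-delimited TSV with a header row:

* expression matrix   — first column gene symbols, remaining columns samples
* methylation matrix  — first column CpG probe ids, remaining columns samples
* probe manifest      — columns ``probe_id``, ``gene`` (Illumina-manifest
  style; a ``;``-separated gene field duplicates the probe into each gene)
* interaction edges   — columns ``gene_a``, ``gene_b`` and optional ``source``
* phenotype labels    — columns ``sample_id``, ``label`` with labels in
  {case, control}

Pathway gene sets use the standard GMT format (name, description, members).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CohortError, FormatError, ValidationError

log = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"
PHENOTYPES = (CASE, CONTROL)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values (raw or log scale)."""

    data: pd.DataFrame  # index: gene symbols, columns: sample ids

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dupes)[:5]}")
        if self.data.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in expression matrix")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValidationError("non-finite expression values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def restrict_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(samples)].copy())


@dataclass
class MethylationMatrix:
    """CpG probes x samples beta values in [0, 1]; NaN marks missing."""

    data: pd.DataFrame  # index: probe ids, columns: sample ids

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate probe ids in methylation matrix")
        if self.data.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in methylation matrix")
        values = self.data.to_numpy(dtype=float)
        bad = (values < 0) | (values > 1)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"beta value {values[i, j]!r} outside [0, 1] at probe "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def restrict_samples(self, samples: Sequence[str]) -> "MethylationMatrix":
        return MethylationMatrix(self.data.loc[:, list(samples)].copy())


@dataclass
class ProbeGeneMap:
    """Many-to-one probe -> gene assignment.

    A manifest row listing several genes for one probe duplicates the probe
    under each gene, so ``probes_by_gene`` may repeat a probe id across genes.
    """

    probes_by_gene: dict[str, list[str]]

    def __post_init__(self) -> None:
        for gene, probes in self.probes_by_gene.items():
            if not gene:
                raise ValidationError("empty gene symbol in probe map")
            if len(probes) != len(set(probes)):
                raise ValidationError(f"probe listed twice for gene {gene!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.probes_by_gene)


@dataclass
class InteractionEdgeList:
    """Undirected, self-loop-free gene interaction edges."""

    edges: set[frozenset]
    source: str | None = None

    def __post_init__(self) -> None:
        for edge in self.edges:
            if len(edge) != 2:
                raise ValidationError(f"self-loop or malformed edge: {set(edge)}")

    @property
    def nodes(self) -> set[str]:
        return {g for edge in self.edges for g in edge}

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class PathwayCollection:
    """Ordered list of (pathway_id, name, member genes)."""

    pathways: list[tuple[str, str, list[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p[0] for p in self.pathways]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate pathway ids")
        for pid, _, genes in self.pathways:
            if not genes:
                raise ValidationError(f"pathway {pid!r} has an empty gene set")

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def gene_sets(self) -> dict[str, set[str]]:
        return {pid: set(genes) for pid, _, genes in self.pathways}

    def names(self) -> dict[str, str]:
        return {pid: name for pid, name, _ in self.pathways}


@dataclass
class PhenotypeLabels:
    """sample_id -> {case, control} with at least two samples per class."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        bad = {s: l for s, l in self.labels.items() if l not in PHENOTYPES}
        if bad:
            raise ValidationError(f"labels must be case/control, got {bad}")
        for phenotype in PHENOTYPES:
            n = sum(1 for l in self.labels.values() if l == phenotype)
            if n < 2:
                raise CohortError(f"fewer than 2 {phenotype!r} samples ({n})")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels)

    def samples_of(self, phenotype: str) -> list[str]:
        return [s for s, l in self.labels.items() if l == phenotype]

    def restrict_samples(self, samples: Sequence[str]) -> "PhenotypeLabels":
        return PhenotypeLabels({s: self.labels[s] for s in samples if s in self.labels})


# ---------------------------------------------------------------------------
# matrix readers / writers
# ---------------------------------------------------------------------------


def _read_tsv_matrix(path, kind: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty {kind} file") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: header row has no sample columns")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    # cells that fail to parse but are not literal NA markers
    invalid = numeric.isna() & ~df.isna() & ~df.apply(
        lambda col: col.str.strip().str.upper().isin({"NA", "NAN", ""})
    )
    if invalid.to_numpy().any():
        row = int(np.argwhere(invalid.to_numpy())[0][0])
        raise FormatError(
            f"{path}: non-numeric cell in row {row + 2} "
            f"(id {df.index[row]!r})"
        )
    numeric.index = numeric.index.astype(str)
    numeric.index.name = df.index.name
    return numeric


def read_expression(path, transform: str = "none") -> ExpressionMatrix:
    """Read a gene x sample expression TSV.

    ``transform="log2_plus1"`` applies log2(x + 1), the usual variance
    stabilisation for count-scale RNA-seq values.  Duplicate gene rows are
    collapsed by their mean.
    """
    if transform not in ("none", "log2_plus1"):
        raise ValueError(f"unknown transform {transform!r}")
    df = _read_tsv_matrix(path, "expression")
    if df.isna().to_numpy().any():
        raise FormatError(f"{path}: missing values are not allowed in expression data")
    if df.index.duplicated().any():
        log.info("collapsing %d duplicate gene rows by mean", int(df.index.duplicated().sum()))
        df = df.groupby(level=0, sort=False).mean()
    if transform == "log2_plus1":
        if (df.to_numpy() < 0).any():
            raise ValidationError(f"{path}: negative values under log2_plus1 transform")
        df = np.log2(df + 1.0)
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene")


def read_methylation(path) -> MethylationMatrix:
    """Read a probe x sample beta-value TSV; NA cells become missing (NaN)."""
    df = _read_tsv_matrix(path, "methylation")
    return MethylationMatrix(df)


def write_methylation(meth: MethylationMatrix, path) -> None:
    meth.data.to_csv(path, sep="\t", index_label="probe")


def impute_missing(
    meth: MethylationMatrix,
    labels: PhenotypeLabels,
    max_missing_fraction: float = 0.2,
) -> MethylationMatrix:
    """Handle missing betas: drop probes missing in more than
    ``max_missing_fraction`` of cohort samples, mean-impute the rest within
    each phenotype class."""
    df = meth.data.loc[:, labels.sample_ids].copy()
    keep = df.isna().mean(axis=1) <= max_missing_fraction
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropping %d probes with >%.0f%% missing betas", dropped, 100 * max_missing_fraction)
    df = df.loc[keep]
    for phenotype in PHENOTYPES:
        cols = labels.samples_of(phenotype)
        block = df.loc[:, cols]
        df.loc[:, cols] = block.T.fillna(block.mean(axis=1)).T
    # probes missing in an entire class fall back to the cohort mean
    if df.isna().to_numpy().any():
        df = df.T.fillna(df.mean(axis=1)).T
    return MethylationMatrix(df.dropna(axis=0))


# ---------------------------------------------------------------------------
# probe map / edges / labels
# ---------------------------------------------------------------------------


def read_probe_map(path) -> ProbeGeneMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probe_id", "gene"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: probe map needs columns {sorted(required)}")
    probes_by_gene: dict[str, list[str]] = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        if pd.isna(row.gene) or pd.isna(row.probe_id):
            raise FormatError(f"{path}: empty probe/gene field on line {lineno}")
        for gene in str(row.gene).split(";"):
            gene = gene.strip()
            if not gene:
                raise FormatError(f"{path}: empty gene symbol on line {lineno}")
            probes_by_gene.setdefault(gene, [])
            if row.probe_id in probes_by_gene[gene]:
                raise FormatError(f"{path}: probe {row.probe_id!r} repeated for gene {gene!r}")
            probes_by_gene[gene].append(str(row.probe_id))
    return ProbeGeneMap(probes_by_gene)


def write_probe_map(pmap: ProbeGeneMap, path) -> None:
    rows = [
        {"probe_id": probe, "gene": gene}
        for gene, probes in pmap.probes_by_gene.items()
        for probe in probes
    ]
    pd.DataFrame(rows, columns=["probe_id", "gene"]).to_csv(path, sep="\t", index=False)


def read_edges(path) -> InteractionEdgeList:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_a", "gene_b"}.issubset(df.columns):
        raise FormatError(f"{path}: edge list needs columns gene_a, gene_b")
    edges: set[frozenset] = set()
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        a, b = str(row.gene_a), str(row.gene_b)
        if pd.isna(row.gene_a) or pd.isna(row.gene_b) or not a or not b:
            raise FormatError(f"{path}: empty gene field on line {lineno}")
        if a == b:
            log.info("dropping self-loop %s on line %d", a, lineno)
            continue
        edges.add(frozenset((a, b)))
    return InteractionEdgeList(edges)


def write_edges(edgelist: InteractionEdgeList, path) -> None:
    rows = sorted(tuple(sorted(edge)) for edge in edgelist.edges)
    pd.DataFrame(rows, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> PhenotypeLabels:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "label"}.issubset(df.columns):
        raise FormatError(f"{path}: phenotype file needs columns sample_id, label")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids in phenotype file")
    return PhenotypeLabels(dict(zip(df["sample_id"], df["label"])))


def write_phenotypes(labels: PhenotypeLabels, path) -> None:
    pd.DataFrame(
        {"sample_id": labels.sample_ids, "label": [labels.labels[s] for s in labels.sample_ids]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path) -> PathwayCollection:
    pathways: list[tuple[str, str, list[str]]] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno} has fewer than 3 fields")
            pid, name, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if pid in seen:
                raise FormatError(f"{path}: duplicate pathway id {pid!r} on line {lineno}")
            seen.add(pid)
            pathways.append((pid, name, genes))
    return PathwayCollection(pathways)


def write_gmt(collection: PathwayCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for pid, name, genes in collection:
            handle.write("\t".join([pid, name, *genes]) + "\n")


# ---------------------------------------------------------------------------
# cohort intersection
# ---------------------------------------------------------------------------


def intersect_cohort(
    expr: ExpressionMatrix,
    meth: MethylationMatrix,
    labels: PhenotypeLabels,
) -> tuple[ExpressionMatrix, MethylationMatrix, PhenotypeLabels]:
    """Restrict all three objects to samples measured on both platforms.

    Only samples with expression, methylation and a phenotype label are
    retained, in a single canonical (sorted) order shared by the outputs.
    """
    common = set(expr.sample_ids) & set(meth.sample_ids) & set(labels.sample_ids)
    if not common:
        raise CohortError("no samples shared by expression, methylation and labels")
    order = sorted(common)
    for phenotype in PHENOTYPES:
        n = sum(1 for s in order if labels.labels[s] == phenotype)
        if n < 2:
            raise CohortError(
                f"class {phenotype!r} reduced to {n} sample(s) after intersection"
            )
    return (
        expr.restrict_samples(order),
        meth.restrict_samples(order),
        labels.restrict_samples(order),
    )
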