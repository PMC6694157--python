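"""Per-gene feature blocks: methylation principal components plus expression.

A gene is measured as a handful of CpG beta columns (its probes) and one
expression column.  Neighbouring CpG loci of a gene are strongly correlated,
so the beta submatrix is first reduced by centred PCA, retaining the smallest
number of components ``s`` whose cumulative explained variance reaches a
target fraction (default 0.80).  The retained component scores and the
expression vector are concatenated into a samples x (s + 1) block — the
per-gene feature matrix consumed by the sparse-CCA edge weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .io import ExpressionMatrix, MethylationMatrix, PhenotypeLabels, ProbeGeneMap

log = logging.getLogger(__name__)

DEFAULT_VARIANCE_TARGET = 0.80


@dataclass
class MethylationBlock:
    """PCA-reduced CpG betas for one gene on one sample set."""

    gene: str
    sample_ids: list[str]
    probe_ids: list[str]
    beta_submatrix: np.ndarray  # samples x u
    pcs: np.ndarray  # samples x s, centred component scores
    explained_variance: np.ndarray  # length s, non-increasing fractions
    zero_variance: bool = False

    @property
    def n_components(self) -> int:
        return self.pcs.shape[1]


@dataclass
class GeneFeatureBlock:
    """samples x p block: methylation PC scores then one expression column."""

    gene: str
    sample_ids: list[str]
    matrix: np.ndarray  # samples x p, p = s + 1
    expression_only: bool = False

    @property
    def p(self) -> int:
        return self.matrix.shape[1]


def _pca_sign_fix(scores: np.ndarray, loadings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # flip each component so its largest-magnitude loading is positive
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        k = int(np.argmax(np.abs(col)))
        if col[k] < 0:
            loadings[:, j] = -col
            scores[:, j] = -scores[:, j]
    return scores, loadings


def reduce_cpg(
    gene: str,
    beta_submatrix: pd.DataFrame | np.ndarray,
    variance_target: float = DEFAULT_VARIANCE_TARGET,
    probe_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> MethylationBlock:
    """Centred PCA of one gene's samples x probes beta submatrix.

    Retains the smallest ``s`` with cumulative explained variance at or above
    ``variance_target`` (always at least one component).  An all-constant
    submatrix yields a single zero-variance component flagged as such.
    """
    if isinstance(beta_submatrix, pd.DataFrame):
        probe_ids = list(beta_submatrix.columns)
        sample_ids = list(beta_submatrix.index)
        values = beta_submatrix.to_numpy(dtype=float)
    else:
        values = np.asarray(beta_submatrix, dtype=float)
        probe_ids = probe_ids or [f"{gene}_p{i}" for i in range(values.shape[1])]
        sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[0])]
    n, u = values.shape
    if u < 1:
        raise ValueError(f"gene {gene!r}: no probes")
    if n < 3:
        raise ValueError(f"gene {gene!r}: PCA needs at least 3 samples, got {n}")

    centred = values - values.mean(axis=0)
    # economy SVD: scores = U * S, loadings = V
    U, S, Vt = np.linalg.svd(centred, full_matrices=False)
    total_var = float(np.sum(S**2))
    if total_var <= 1e-24:
        return MethylationBlock(
            gene, sample_ids, probe_ids, values,
            pcs=np.zeros((n, 1)),
            explained_variance=np.array([0.0]),
            zero_variance=True,
        )
    evr = S**2 / total_var
    s = int(np.searchsorted(np.cumsum(evr), variance_target - 1e-12) + 1)
    s = min(max(s, 1), len(S))
    scores = U[:, :s] * S[:s]
    loadings = Vt[:s].T.copy()
    scores, _ = _pca_sign_fix(scores, loadings)
    return MethylationBlock(
        gene, sample_ids, probe_ids, values,
        pcs=scores, explained_variance=evr[:s],
    )


def merge_features(meth: MethylationBlock, expr_row: pd.Series) -> GeneFeatureBlock:
    """Concatenate PC scores with the gene's expression vector (p = s + 1)."""
    if list(expr_row.index) != meth.sample_ids:
        raise AlignmentError(
            f"gene {meth.gene!r}: expression sample order differs from methylation block"
        )
    matrix = np.column_stack([meth.pcs, expr_row.to_numpy(dtype=float)])
    return GeneFeatureBlock(meth.gene, meth.sample_ids, matrix)


def expression_only_block(gene: str, expr_row: pd.Series) -> GeneFeatureBlock:
    """Fallback block (p = 1) for genes with no mapped probes."""
    return GeneFeatureBlock(
        gene, list(expr_row.index),
        np.asarray(expr_row, dtype=float).reshape(-1, 1),
        expression_only=True,
    )


def build_feature_blocks(
    expr: ExpressionMatrix,
    meth: MethylationMatrix,
    probe_map: ProbeGeneMap,
    samples: list[str],
    variance_target: float = DEFAULT_VARIANCE_TARGET,
    include_expression_only: bool = True,
) -> dict[str, GeneFeatureBlock]:
    """Feature blocks for every measured gene, on one phenotype's samples.

    Component scores are computed on exactly the given samples, so case and
    control phenotypes get their own decompositions.  Genes with expression
    but no mapped probes become flagged expression-only blocks (p = 1) unless
    ``include_expression_only`` is false.
    """
    blocks: dict[str, GeneFeatureBlock] = {}
    meth_sub = meth.data.loc[:, samples]
    available_probes = set(meth.probe_ids)
    n_no_probe = 0
    for gene in expr.gene_ids:
        expr_row = expr.data.loc[gene, samples]
        probes = [
            p for p in probe_map.probes_by_gene.get(gene, []) if p in available_probes
        ]
        if probes:
            beta = meth_sub.loc[probes].T  # samples x u
            block = reduce_cpg(gene, beta, variance_target)
            blocks[gene] = merge_features(block, expr_row)
        elif include_expression_only:
            blocks[gene] = expression_only_block(gene, expr_row)
            n_no_probe += 1
    if n_no_probe:
        log.info("%d genes have no mapped probes; using expression-only blocks", n_no_probe)
    return blocks
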