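"""Sparse canonical correlation edge weights for gene interaction networks.

For each interacting gene pair the canonical correlation between their
feature blocks (methylation PCs + expression) serves as the edge weight:

    W_XY = corr(X a, Y b)

with sparse loading vectors a, b maximising ``a' X' Y b`` subject to
``||a||_2 <= 1, ||b||_2 <= 1, ||a||_1 <= c1 sqrt(p), ||b||_1 <= c2 sqrt(q)``.
The optimisation is the rank-1 penalized matrix decomposition: alternating
soft-thresholded updates where each half step solves its subproblem exactly
(soft-threshold then L2-normalise, with the threshold found by bisection on
the L1 bound), so the objective is non-decreasing along the iteration.

Running this on every edge of an interaction network, separately for case
and control samples, yields the two weighted phenotype-specific networks
that drive the pathway extension.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NetworkError
from .features import GeneFeatureBlock
from .io import InteractionEdgeList

log = logging.getLogger(__name__)

DEFAULT_C1 = 0.7
DEFAULT_C2 = 0.7
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 100
MIN_SAMPLES = 4  # below this the canonical correlation is essentially noise


@dataclass
class SCCAResult:
    a: np.ndarray
    b: np.ndarray
    weight: float  # signed canonical correlation, |weight| <= 1
    iterations: int
    converged: bool
    degenerate: bool = False  # a canonical variate had zero variance
    objective_trace: list[float] = field(default_factory=list)


@dataclass
class WeightedNetwork:
    """Phenotype-specific gene graph with nonnegative edge weights in [0, 1]."""

    phenotype: str
    weights: dict[frozenset, float]

    @property
    def nodes(self) -> set[str]:
        return {g for e in self.weights for g in e}

    @property
    def edges(self) -> set[frozenset]:
        return set(self.weights)

    def __len__(self) -> int:
        return len(self.weights)


def _standardize(M: np.ndarray) -> np.ndarray:
    """Center columns and scale to unit standard deviation.

    PCs and expression live on different scales; without this the expression
    column could dominate the cross-covariance.  Zero-variance columns are
    left centred (all zero) rather than divided by zero.
    """
    M = np.asarray(M, dtype=float)
    M = M - M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    sd[sd < 1e-12] = 1.0
    return M / sd


def _soft_threshold(v: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - delta, 0.0)


def _l1_constrained_unit(v: np.ndarray, c: float) -> np.ndarray:
    """argmax_u <u, v> subject to ||u||_2 <= 1, ||u||_1 <= c.

    For c >= 1 the solution is v soft-thresholded at the smallest delta >= 0
    whose L2-normalised result meets the L1 bound (found by bisection).  For
    c < 1 the L1 ball lies inside the L2 ball and the maximiser is the
    1-sparse vector c * sign(v_i) e_i; the final rescaling handles this
    uniformly, so both constraints always hold exactly.
    """
    norm = np.linalg.norm(v)
    if norm < 1e-300:
        return np.zeros_like(v)
    u = v / norm
    if np.abs(u).sum() <= c + 1e-12:
        return u
    lo, hi = 0.0, float(np.max(np.abs(v)))
    for _ in range(200):
        delta = 0.5 * (lo + hi)
        w = _soft_threshold(v, delta)
        wn = np.linalg.norm(w)
        if wn < 1e-300:
            hi = delta
            continue
        if np.abs(w).sum() / wn > c:
            lo = delta
        else:
            hi = delta
        if hi - lo < 1e-14 * (1.0 + hi):
            break
    w = _soft_threshold(v, hi)
    wn = np.linalg.norm(w)
    if wn < 1e-300:
        # threshold collapsed everything; keep the single largest coordinate
        w = np.zeros_like(v)
        k = int(np.argmax(np.abs(v)))
        w[k] = np.sign(v[k])
    else:
        w = w / wn
    l1 = np.abs(w).sum()
    if l1 > c:  # infeasible on the unit sphere (c < 1) or bisection residue
        w = w * (c / l1)
    return w


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    sx, sy = x.std(), y.std()
    if sx < 1e-12 or sy < 1e-12:
        return 0.0, True
    r = float(np.corrcoef(x, y)[0, 1])
    return max(-1.0, min(1.0, r)), False


def scca_pair(
    Xb: GeneFeatureBlock | np.ndarray,
    Yb: GeneFeatureBlock | np.ndarray,
    c1: float = DEFAULT_C1,
    c2: float = DEFAULT_C2,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    standardize: bool = True,
    keep_trace: bool = False,
) -> SCCAResult:
    """Rank-1 sparse CCA between two feature blocks.

    Initialised from the leading right singular vector of X'Y (deterministic,
    no RNG), alternating exact constrained updates of a and b until the
    loadings move by less than ``tol`` or ``max_iter`` is hit.  The returned
    ``weight`` is the Pearson correlation of the canonical variates Xa, Yb.
    """
    if not (0.0 < c1 < 1.0) or not (0.0 < c2 < 1.0):
        raise ValueError(f"c1, c2 must lie in (0, 1); got {c1}, {c2}")
    X = Xb.matrix if isinstance(Xb, GeneFeatureBlock) else np.asarray(Xb, float)
    Y = Yb.matrix if isinstance(Yb, GeneFeatureBlock) else np.asarray(Yb, float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("feature blocks have different sample counts")
    n = X.shape[0]
    if n < MIN_SAMPLES:
        raise ValueError(f"sparse CCA needs at least {MIN_SAMPLES} samples, got {n}")
    if standardize:
        X, Y = _standardize(X), _standardize(Y)
    p, q = X.shape[1], Y.shape[1]
    bound_a, bound_b = c1 * math.sqrt(p), c2 * math.sqrt(q)

    Z = X.T @ Y
    if np.abs(Z).max() < 1e-300:
        return SCCAResult(np.zeros(p), np.zeros(q), 0.0, 0, True, degenerate=True)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    b = Vt[0]
    if b[int(np.argmax(np.abs(b)))] < 0:  # deterministic sign
        b = -b
    b = _l1_constrained_unit(b, bound_b)
    a = _l1_constrained_unit(Z @ b, bound_a)

    trace: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        a_new = _l1_constrained_unit(Z @ b, bound_a)
        if keep_trace:
            trace.append(float(a_new @ Z @ b))
        b_new = _l1_constrained_unit(Z.T @ a_new, bound_b)
        if keep_trace:
            trace.append(float(a_new @ Z @ b_new))
        delta = max(np.abs(a_new - a).max(), np.abs(b_new - b).max())
        a, b = a_new, b_new
        if delta < tol:
            converged = True
            break

    weight, degenerate = _pearson(X @ a, Y @ b)
    return SCCAResult(a, b, weight, iterations, converged, degenerate, trace)


def build_weighted_network(
    blocks: dict[str, GeneFeatureBlock],
    edges: InteractionEdgeList,
    phenotype: str,
    c1: float = DEFAULT_C1,
    c2: float = DEFAULT_C2,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> WeightedNetwork:
    """Weight every edge whose endpoints both have feature blocks.

    Edges with either endpoint missing from ``blocks`` (gene not measured on
    both platforms) are deleted.  Negative canonical correlations are mapped
    to their absolute value so downstream random-walk transition matrices
    stay valid; association strength is what matters for the walk.
    """
    weights: dict[frozenset, float] = {}
    dropped = 0
    for edge in sorted(edges.edges, key=lambda e: tuple(sorted(e))):
        a, b = sorted(edge)
        if a not in blocks or b not in blocks:
            dropped += 1
            continue
        result = scca_pair(blocks[a], blocks[b], c1=c1, c2=c2, tol=tol, max_iter=max_iter)
        weights[edge] = abs(result.weight)
    if dropped:
        log.info("%s network: deleted %d edges lacking data at an endpoint", phenotype, dropped)
    if not weights:
        raise NetworkError(f"{phenotype} network has no surviving edges")
    return WeightedNetwork(phenotype, weights)


def write_network(net: WeightedNetwork, path) -> None:
    rows = [
        (*sorted(edge), f"{w:.10g}", net.phenotype)
        for edge, w in sorted(net.weights.items(), key=lambda kv: tuple(sorted(kv[0])))
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight", "phenotype"]).to_csv(
        path, sep="\t", index=False
    )


def read_network(path) -> WeightedNetwork:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    required = {"gene_a", "gene_b", "weight", "phenotype"}
    if not required.issubset(df.columns):
        raise NetworkError(f"{path}: network file needs columns {sorted(required)}")
    phenos = set(df["phenotype"].unique())
    if len(phenos) != 1:
        raise NetworkError(f"{path}: expected a single phenotype, got {sorted(phenos)}")
    weights = {
        frozenset((r.gene_a, r.gene_b)): float(r.weight) for r in df.itertuples(index=False)
    }
    return WeightedNetwork(phenos.pop(), weights)
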