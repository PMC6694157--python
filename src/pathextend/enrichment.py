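"""Altered-pathway identification: over-representation analysis and GSEA.

ORA: genes differentially expressed between case and control (Welch t-test,
Benjamini-Hochberg at alpha) are intersected with each pathway's gene list
and scored by the upper tail of the hypergeometric distribution,

    P(X >= k),  X ~ Hypergeom(N, M, n)

with N the background size, M the DE genes, n the pathway size within the
background and k the DE genes inside the pathway; BH correction is applied
across the tested collection.

GSEA: genes are ranked by the signal-to-noise ratio
(mean_case - mean_control) / (sd_case + sd_control), each gene set gets a
weighted Kolmogorov-Smirnov enrichment score (ES), and significance comes
from phenotype-label permutations: NES normalises ES by the mean same-sign
permutation ES, the nominal p is the same-sign permutation tail, and FDR q
follows the standard pooled-permutation-NES procedure.

Running either on extended instead of original pathway gene lists gives the
EP-ORA / EP-GSEA variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, PathwayCollection, PhenotypeLabels, CASE, CONTROL

log = logging.getLogger(__name__)

DEFAULT_DE_ALPHA = 0.05
DEFAULT_N_PERM = 1000
DEFAULT_WEIGHT_EXPONENT = 1.0


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


@dataclass
class DEResult:
    table: pd.DataFrame  # index gene; columns statistic, p_value, adjusted_p
    alpha: float

    @property
    def de_set(self) -> set[str]:
        return set(self.table.index[self.table["adjusted_p"] <= self.alpha])


def call_de(expr: ExpressionMatrix, labels: PhenotypeLabels, alpha: float = DEFAULT_DE_ALPHA) -> DEResult:
    """Per-gene Welch t-test (case vs control) with BH adjustment.

    Genes that are constant and identical in both classes get p = 1 rather
    than an undefined statistic.
    """
    case = expr.data.loc[:, labels.samples_of(CASE)].to_numpy(dtype=float)
    ctrl = expr.data.loc[:, labels.samples_of(CONTROL)].to_numpy(dtype=float)
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("Welch t-test needs at least 2 samples per class")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    adjusted = bh_adjust(list(p))
    table = pd.DataFrame(
        {"statistic": t, "p_value": p, "adjusted_p": adjusted}, index=expr.gene_ids
    )
    return DEResult(table, alpha)


# ---------------------------------------------------------------------------
# ORA
# ---------------------------------------------------------------------------


def hypergeom_pvalue(N: int, M: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts DE genes in a size-n pathway drawn from N background genes of
    which M are DE.  k = 0 gives 1.0 by convention (the empty lower sum).
    """
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric bounds N={N}, M={M}, n={n}")
    if not (0 <= k <= min(M, n)):
        raise ValueError(f"k={k} outside [0, min(M={M}, n={n})]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, M, n))


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return []
    if ((arr < 0) | (arr > 1)).any() or not np.isfinite(arr).all():
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(arr, method="fdr_bh")
    return [float(x) for x in adjusted]


@dataclass
class ORAResult:
    pathway_id: str
    pathway_name: str
    N: int
    M: int
    n: int
    k: int
    p_value: float
    adjusted_p: float
    rank: int


def run_ora(
    collection: PathwayCollection,
    de: DEResult,
    background: set[str],
) -> list[ORAResult]:
    """Hypergeometric test for every pathway with background genes.

    The BH correction runs across the tested collection only; results are
    sorted by adjusted p then pathway id, with dense ranks (ties share one).
    """
    if not background:
        raise ValueError("empty ORA background")
    de_bg = de.de_set & background
    N, M = len(background), len(de_bg)
    names = collection.names()
    tested: list[tuple[str, int, int, float]] = []
    for pid, _, genes in collection:
        in_bg = set(genes) & background
        if not in_bg:
            log.info("pathway %s has no background genes; skipped", pid)
            continue
        n_, k_ = len(in_bg), len(in_bg & de_bg)
        tested.append((pid, n_, k_, hypergeom_pvalue(N, M, n_, k_)))
    adjusted = bh_adjust([t[3] for t in tested])
    order = sorted(range(len(tested)), key=lambda i: (adjusted[i], tested[i][0]))
    ranks: dict[int, int] = {}
    last_p, rank = None, 0
    for i in order:
        if last_p is None or adjusted[i] > last_p:
            rank += 1
            last_p = adjusted[i]
        ranks[i] = rank
    return [
        ORAResult(tested[i][0], names[tested[i][0]], N, M, tested[i][1], tested[i][2],
                  tested[i][3], adjusted[i], ranks[i])
        for i in order
    ]


def ora_table(results: list[ORAResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id, "pathway_name": r.pathway_name,
                "N": r.N, "M": r.M, "n": r.n, "k": r.k,
                "p_value": r.p_value, "adjusted_p": r.adjusted_p, "rank": r.rank,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------


def _signal_to_noise(case: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    """(mean_case - mean_control) / (sd_case + sd_control) with sd floors.

    Each sample standard deviation is floored at max(0.2 * |mean|, 0.2) so
    near-constant genes cannot produce unbounded scores.
    """
    mc, m0 = case.mean(axis=1), ctrl.mean(axis=1)
    sc = np.maximum(case.std(axis=1, ddof=1), np.maximum(0.2 * np.abs(mc), 0.2))
    s0 = np.maximum(ctrl.std(axis=1, ddof=1), np.maximum(0.2 * np.abs(m0), 0.2))
    return (mc - m0) / (sc + s0)


def gsea_rank(expr: ExpressionMatrix, labels: PhenotypeLabels) -> pd.Series:
    """Genes ranked by signal-to-noise, descending; ties break by symbol."""
    case = expr.data.loc[:, labels.samples_of(CASE)].to_numpy(dtype=float)
    ctrl = expr.data.loc[:, labels.samples_of(CONTROL)].to_numpy(dtype=float)
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("signal-to-noise ranking needs at least 2 samples per class")
    scores = pd.Series(_signal_to_noise(case, ctrl), index=expr.gene_ids, name="s2n")
    frame = scores.reset_index()
    frame.columns = ["gene", "s2n"]
    frame = frame.sort_values(["s2n", "gene"], ascending=[False, True], kind="mergesort")
    return pd.Series(frame["s2n"].to_numpy(), index=frame["gene"].to_numpy(), name="s2n")


def gsea_es(
    ranked: pd.Series,
    gene_set: set[str],
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
) -> tuple[float, np.ndarray]:
    """Weighted Kolmogorov-Smirnov enrichment score and running-sum profile.

    Hits advance the running sum by |score|^exponent normalised over in-set
    genes; misses retreat by 1/(N - N_hit).  ES is the signed maximum
    deviation from zero.
    """
    hits = np.asarray([g in gene_set for g in ranked.index])
    if not hits.any():
        raise ValueError("gene set shares no genes with the ranked list")
    scores = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    hit_total = scores[hits].sum()
    n_miss = len(ranked) - int(hits.sum())
    step = np.where(
        hits,
        scores / hit_total if hit_total > 0 else 1.0 / hits.sum(),
        -1.0 / n_miss if n_miss > 0 else 0.0,
    )
    running = np.cumsum(step)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


@dataclass
class GSEAResult:
    pathway_id: str
    pathway_name: str
    size: int
    ES: float
    NES: float
    nominal_p: float
    FDR_q: float
    rank: int


def _es_for_sets(ranked: pd.Series, sets: dict[str, set[str]], exponent: float) -> dict[str, float]:
    return {pid: gsea_es(ranked, genes, exponent)[0] for pid, genes in sets.items()}


def gsea_significance(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    collection: PathwayCollection,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
    min_size: int = 2,
) -> list[GSEAResult]:
    """Phenotype-permutation GSEA over a pathway collection.

    Labels are permuted ``n_perm`` times; every permutation regenerates the
    signal-to-noise ranking and per-set ES.  NES divides ES by the mean
    same-sign permutation ES of that set; the nominal p is the same-sign
    permutation tail; FDR q compares the pooled permutation-NES distribution
    with the observed NES distribution, per sign.  Deterministic given seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 100:
        log.warning("n_perm=%d gives coarse p-value/FDR resolution", n_perm)
    rng = np.random.default_rng(seed)
    measured = set(expr.gene_ids)
    sets = {
        pid: set(genes) & measured
        for pid, _, genes in collection
        if len(set(genes) & measured) >= min_size
    }
    if not sets:
        return []
    names = collection.names()

    data = expr.data.to_numpy(dtype=float)
    genes = np.asarray(expr.gene_ids)
    is_case = np.asarray([labels.labels[s] == CASE for s in expr.sample_ids])
    n_case = int(is_case.sum())

    def ranking(mask: np.ndarray) -> pd.Series:
        s = _signal_to_noise(data[:, mask], data[:, ~mask])
        frame = pd.DataFrame({"gene": genes, "s2n": s})
        frame = frame.sort_values(["s2n", "gene"], ascending=[False, True], kind="mergesort")
        return pd.Series(frame["s2n"].to_numpy(), index=frame["gene"].to_numpy())

    observed = _es_for_sets(ranking(is_case), sets, weight_exponent)

    perm_es = np.empty((n_perm, len(sets)))
    pids = list(sets)
    for r in range(n_perm):
        mask = np.zeros(len(is_case), dtype=bool)
        mask[rng.choice(len(is_case), size=n_case, replace=False)] = True
        ranked = ranking(mask)
        for j, pid in enumerate(pids):
            perm_es[r, j] = gsea_es(ranked, sets[pid], weight_exponent)[0]

    # normalise observed and permutation ES by the mean same-sign permutation ES
    nes_obs: dict[str, float] = {}
    nominal: dict[str, float] = {}
    perm_nes = np.full_like(perm_es, np.nan)
    for j, pid in enumerate(pids):
        es = observed[pid]
        col = perm_es[:, j]
        pos, neg = col[col >= 0], col[col < 0]
        mean_pos = pos.mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan
        if pos.size:
            perm_nes[col >= 0, j] = col[col >= 0] / mean_pos
        if neg.size:
            perm_nes[col < 0, j] = col[col < 0] / mean_neg
        if es >= 0:
            nes_obs[pid] = es / mean_pos if np.isfinite(mean_pos) else 0.0
            nominal[pid] = float((pos >= es).sum() / pos.size) if pos.size else 1.0
        else:
            nes_obs[pid] = es / mean_neg if np.isfinite(mean_neg) else 0.0
            nominal[pid] = float((neg <= es).sum() / neg.size) if neg.size else 1.0

    pooled = perm_nes[np.isfinite(perm_nes)]
    obs_nes = np.asarray([nes_obs[pid] for pid in pids])
    fdr: dict[str, float] = {}
    for j, pid in enumerate(pids):
        nes = obs_nes[j]
        if nes >= 0:
            num_pool = pooled[pooled >= 0]
            frac_perm = (num_pool >= nes).sum() / num_pool.size if num_pool.size else 1.0
            obs_pos = obs_nes[obs_nes >= 0]
            frac_obs = (obs_pos >= nes).sum() / obs_pos.size if obs_pos.size else 1.0
        else:
            num_pool = pooled[pooled < 0]
            frac_perm = (num_pool <= nes).sum() / num_pool.size if num_pool.size else 1.0
            obs_neg = obs_nes[obs_nes < 0]
            frac_obs = (obs_neg <= nes).sum() / obs_neg.size if obs_neg.size else 1.0
        fdr[pid] = float(min(1.0, frac_perm / frac_obs)) if frac_obs > 0 else 1.0

    ordered = sorted(pids, key=lambda pid: (fdr[pid], nominal[pid], pid))
    results = [
        GSEAResult(pid, names[pid], len(sets[pid]), observed[pid], nes_obs[pid],
                   nominal[pid], fdr[pid], rank=i + 1)
        for i, pid in enumerate(ordered)
    ]
    return results


def gsea_table(results: list[GSEAResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id, "pathway_name": r.pathway_name,
                "size": r.size, "ES": r.ES, "NES": r.NES,
                "nominal_p": r.nominal_p, "FDR_q": r.FDR_q, "rank": r.rank,
            }
            for r in results
        ]
    )
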