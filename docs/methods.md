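# Methods

## Model overview

`pathextend` assumes that a phenotype perturbs the *coupling* between
interacting genes' molecular profiles, not just single-gene means. It
therefore scores each edge of a prior interaction network by how strongly
the two genes' joint methylation + expression profiles co-vary within one
phenotype's samples, and treats pathway membership as a soft boundary: any
gene that efficiently routes random walks between a pathway's members in
the weighted network is a candidate pathway component.

## Feature blocks

Each gene's CpG probes are summarised by centred PCA (no scaling — beta
values share the [0, 1] scale). The retained dimension *s* is the smallest
with cumulative explained variance ≥ `variance_target` (default 0.80,
always ≥ 1). Components are sign-fixed so the largest-magnitude loading is
positive, making scores reproducible; scores are invariant (up to sign) to
probe ordering. PCA is computed per phenotype on that phenotype's samples,
matching the phenotype-specific networks downstream; a pooled variant is a
one-line change in the caller. Genes with expression but no mapped probes
are kept as flagged expression-only blocks (p = 1) rather than dropped —
only genes missing a data type entirely cause edge deletion. All-constant
beta blocks return a single zero-variance component and are flagged.

Missing betas: probes missing in more than 20% of cohort samples are
dropped; the rest are mean-imputed within phenotype (configurable
`max_missing_fraction`).

## Sparse-CCA edge weights

The edge weight is the canonical correlation of the two blocks under
L2 and L1 constraints, solved as a rank-1 penalized matrix decomposition:
alternating updates `a ← argmax a'(X'Y)b`, `b ← argmax a'(X'Y)b` over
`{‖u‖₂ ≤ 1, ‖u‖₁ ≤ c√dim}`. Each half step is solved exactly by
soft-thresholding with the threshold located by bisection on the L1 bound,
so the bilinear objective is non-decreasing along the iteration (asserted
by test). When `c√dim < 1` (always for univariate blocks) no unit-L2
vector is L1-feasible and the exact maximiser is the 1-sparse vector on
the L1 ball; the implementation rescales onto the bound, which leaves the
weight — a correlation, scale-invariant — unchanged.

Numerical choices:

* columns are centred and unit-scaled before SCCA (PC scores and
  expression are on different scales);
* initialisation is the leading right singular vector of X̃ᵀỸ — fully
  deterministic, no RNG anywhere in the weighting;
* defaults c₁ = c₂ = 0.7, tolerance 1e-6 on the loading sup-norm change,
  100 iterations max; non-convergence is reported in the result flag, not
  raised;
* a zero-variance canonical variate yields weight 0 with a degeneracy flag;
* phenotypes with fewer than 4 samples are refused outright — canonical
  correlations at n < 4 are noise.

Negative canonical correlations are mapped to |W| on the network: the walk
transition matrix needs nonnegative weights, and association *strength* is
what should steer the walk. Edges with either endpoint unmeasured are
deleted.

## Limited-walk pathway extension

With P_ij = W_ij / Σ_j W_ij, walks start at each mapped pathway gene,
other mapped genes are made absorbing, and propagation is truncated at L
steps. Forward probabilities α_t give expected traversal counts
Σ_{t<L} α_t(i)P′_ij per directed edge; a node's relevance is its expected
inflow; both are averaged uniformly over start seeds. These quantities are
validated against closed-form hand recursions and a 10⁵-walk Monte-Carlo
simulator.

Selection of the extension was the genuinely open design choice. Ranking
non-seed genes by raw inflow fails on realistic (degree-skewed) networks:
probability mass that escapes the seed neighbourhood wanders the network
bulk for the remaining steps, so hubs accumulate large inflow without
connecting any seeds, and the effect worsens as L grows. We therefore rank
by **seed delivery** — the expected mass a node hands *directly into
absorbing seeds*, Σ_{t<L, s∈seeds} α_t(g)P′_gs — which is large exactly
for genes that route walks between pathway members. On the package's
default synthetic preset, inflow ranking at L = 50 with a 95% cumulative-
mass cutoff recovers planted bridge genes at precision ≈ 0.06; delivery
ranking at L = 3 with a 70% cutoff reaches recall ≥ 0.93 and precision
0.79–1.0 across seeds. Defaults are therefore L = 3,
`ranking="delivery"`, `mass_fraction=0.70`, capped at 3× the mapped
pathway size; `ranking="inflow"`, `top_k` and `quantile` rules remain
available. Short walk limits are not a concession: relevance is meant to
be local to seed-to-seed routes, and every quantity is monotone in L, so
raising L only adds diffuse mass.

Pathways with fewer than two mapped genes are left at their original genes
with a warning. Seeds isolated from all other seeds contribute no
relevance mass. The final gene list is mapped members ∪ case extension ∪
control extension; extension never removes genes.

## Enrichment

* DE: per-gene Welch t-test, BH step-up (via statsmodels), default
  α = 0.05. Constant identical genes get p = 1.
* ORA: upper tail P(X ≥ k), X ~ Hypergeom(N, M, n) with the standard
  C(N, n) denominator, computed by `scipy.stats.hypergeom.sf` and verified
  against exact rational enumeration for all N ≤ 30. Background defaults
  to measured genes present in either phenotype network. BH across the
  tested collection; dense ranks.
* GSEA: signal-to-noise (mean difference over summed sample sds, each sd
  floored at max(0.2·|mean|, 0.2)), weighted KS running statistic with
  exponent 1, phenotype-label permutations (default 1000). NES divides ES
  by the mean same-sign permutation ES per set; nominal p is the same-sign
  tail; FDR q is the pooled-permutation-NES ratio, clipped to [0, 1].
  Reporting thresholds: ORA adjusted p ≤ 0.05, GSEA FDR ≤ 25%.

## Synthetic data

The generator emulates a two-phenotype multi-omics cohort: a preferential-
attachment background graph (degree skew of real interactomes), disjoint
connected pathways grown inside it, and bridge genes wired to ≥ 2 members
of their pathway. A per-pathway latent factor f (per sample) couples the
group: member/bridge latents are √c·f + √(1−c)·ε with c the coupling
strength; expression is the latent plus Gaussian noise (sd 0.5); probe
betas are a sigmoid of a negatively-loaded gene latent (promoter
convention: methylation anticorrelates with expression) plus probe-level
offset and noise, so betas are bounded in (0, 1) and probes within a gene
are correlated, giving the PCA something real to compress. Differential
expression is a mean shift (default 1.0) in case samples, planted on
bridge genes by default so that extension sensitivity can be measured
against ground truth.

Default preset: 200 genes, 5 pathways of 15 genes, 3 bridges each wired to
3 members, coupling 0.8, 40 samples per class, 1–5 probes per gene. The
test suite uses a mini preset (100 genes, 3 pathways, 15 + 15 samples) to
keep end-to-end runs at a few seconds.

What the generator does **not** emulate: batch effects, platform-specific
intensity distributions, probe cross-hybridisation, copy-number
confounding, correlated noise between neighbouring genes, or realistic
pathway overlap (planted pathways are disjoint). Passing recovery tests
therefore shows the machinery is correct and well-calibrated under the
stated latent-factor model, not that real cohorts will yield comparable
precision; on real data the coupling signal is weaker and the interactome
noisier.

## Reproducibility and problem sizes

Everything stochastic (generator, GSEA permutations) is driven by explicit
seeds; the weighting and walk stages are deterministic by construction,
and the pipeline manifest hashes every artifact so reruns are verifiable
byte-for-byte. The bundled analyses use the default preset (ca. 440-edge
networks, ~1000 sparse-CCA fits per run, 200 GSEA permutations in the
summary script), sizes chosen so a complete from-scratch reproduction runs
in well under a minute on a laptop while still exercising every stage at
realistic per-gene dimensions.

## Known limitations

* Gene identifiers are matched as exact case-sensitive symbols; no alias
  resolution.
* The hypergeometric background is a single global set; per-pathway
  platform-specific backgrounds are not modelled.
* The sparse-CCA penalties c₁, c₂ are fixed, not tuned by permutation;
  the config exposes them but no tuning loop is provided.
* Exact (untruncated) walk relevance via the fundamental matrix is out of
  scope; the truncated forward recursion is the supported estimator.
* GSEA uses phenotype permutation only; the gene-permutation variant is
  not implemented.
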