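# Methods

## Network model and propagation

The interaction network is an undirected graph over gene symbols. Edges are
read from a 3-column (gene_a, gene_b, confidence) whitespace/TSV file and
kept when the confidence is **strictly greater** than the threshold
(default 0.9 on the unit scale; `score_scale="per_mille"` divides raw
STRING-style 0–1000 integers by 1000 first). Self-loops are discarded,
duplicate pairs collapsed, and genes left without a surviving edge dropped
(logged), so the constructed network never has isolated nodes. Adjacency is
**binary**: confidence filters edges but never weights the walk. Gene
identifiers are opaque, case-sensitive strings; optional stripping of a
taxon prefix (`9606.`) is off by default. Seed symbols absent from the
network are dropped with a warning and the seed distribution renormalized —
published seed lists routinely contain symbols the network lacks — but an
entirely unmapped seed set is an error.

Random walk with restart iterates p ← (1 − r)·A′p + r·p₀ on the
column-normalized adjacency A′ (entry (i,j) = Aᵢⱼ/deg(j), so every column
sums to 1 and probability mass is conserved). Defaults: restart r = 0.7 (the
standard value in network disease-gene prioritization — large enough to stay
local to the seeds, small enough to traverse module boundaries), convergence
when the **L1** difference between successive iterates is below 1e-6 (the
norm is not dictated by the underlying recipe; L1 is the common choice and
is exposed via `tol`), iteration cap 10,000 (a guard, never reached on
connected graphs at these tolerances). Because the walk matrix is
substochastic nowhere, the iteration is a contraction with factor (1 − r)
and the fixed point equals the direct solve of (I − (1−r)A′)p = r·p₀; the
test suite verifies agreement to 1e-6 L∞ up to 200 nodes. Ranking is by
visiting probability with **lexicographic tie-breaks**, making every
downstream result deterministic.

## Expansion cutoff

The ranked list is scanned top to bottom with the unweighted
Kolmogorov–Smirnov (GSEA-style) increments: +√((N−G)/G) at positives,
−√(G/(N−G)) otherwise, with N the **full network size** (not the ranked-list
length) and G the positive-set size. These magnitudes make a full scan of
all N genes terminate exactly at zero. The cutoff is the **first** position
attaining the maximum cumulative sum; a curve whose maximum is ≤ 0
(positives concentrated at the bottom) is flagged degenerate rather than
rejected.

Two positive-set conventions exist and both are implemented:

- `cross` (default): the positive set is the *other* disease's seeds and the
  expanding disease's own seeds are excluded from the ranking. The peak then
  marks where the expansion is maximally enriched for the other disease —
  the cross-disease reading used throughout the pipeline.
- `self`: the expanding seeds themselves are the positives and stay in the
  ranked list (they carry the restart mass, so they dominate the top ranks);
  they are removed from the predicted set afterwards. Excluding them, as in
  cross mode, would make a self-positive curve monotonically decreasing.

The expansion overlap defaults to including each disease's own seeds
(`include_seeds=True`): a gene predicted for one disease and seeding the
other is evidence of shared etiology. Both behaviors are exposed because
the convention is genuinely ambiguous in practice.

## Key-driver statistic

For every network gene (common-set members included — hubs inside the shared
neighborhood are legitimate drivers), with n neighbors of which m lie in the
common set of size M on an N-gene network, the score is the inclusive upper
tail P(X ≥ m) of Hypergeometric(N, M, n), computed through the survival
function (stable in the far tail). The BH family is all N network genes.
The driver threshold defaults to FDR p < 1e-8 — deliberately severe, because
neighborhood counts on a dense interactome make moderate enrichments common.

## Meta-analysis conventions

- **Effect direction**: exposure is the *present* genotype, so
  OR = (case_present · control_null)/(case_null · control_present); OR < 1
  means carrying the gene protects. The crude cross-product of the pooled
  GSTM1/ATDH table, (331·981)/(348·1308) ≈ 0.713, pins the direction.
- **Continuity correction**: Haldane–Anscombe +0.5 on all four cells, only
  when a zero cell occurs (never triggered by the shipped tables).
- **Per-study test**: uncorrected Pearson chi-square, 1 df — the only
  variant that reproduces the published per-study p-values (0.022, 0.014)
  to 3 decimals.
- **Model selection**: DerSimonian–Laird random effects for k < 20 studies,
  Mantel–Haenszel fixed effect with the Robins–Breslow–Greenland variance at
  k ≥ 20. Pooled CIs use the normal 1.96 critical value (RevMan convention).
- **Heterogeneity**: Cochran's Q (significant at p < 0.1),
  I² = max(0, (Q−df)/Q)·100 with the Higgins–Thompson test-based 95% CI on
  ln H (H = √(Q/df)): se(ln H) = (ln Q − ln df)/(2(√(2Q) − √(2df−1))) for
  Q > df, else √((1 − 1/(3(df−1)²))/(2(df−1))); back-transformed and
  truncated to [0, 100].
- **Sensitivity**: leave-one-out re-pooling under the model *not* used for
  the primary analysis, reporting the min/max overall-effect p.
- **Harbord's test**: per-study efficient score Z = a − (a+b)(a+c)/n and
  variance V = (a+b)(c+d)(a+c)(b+d)/(n²(n−1)); OLS of Z/√V on √V; two-sided
  t-test on the intercept with k−2 df (significant at p < 0.1). A perfect
  fit (all points exactly collinear, e.g. every balanced table has Z ≡ 0)
  has zero residual variance; it is defined as t = 0, p = 1 when the fitted
  intercept is itself zero — no evidence of asymmetry — and p = 0 otherwise.

## Credibility

Power uses the standard normal-approximation two-proportion z-test (pooled
proportion under the null, distinct proportions under the alternative), with
the case prevalence derived from the alternative OR via
p₁ = OR·p₀/(1 − p₀ + OR·p₀). FPRP is the Wacholder posterior
p(1−π)/(p(1−π) + power·π); the power term is evaluated at a stated
alternative OR, with the significance level defaulting to the observed p
(the conventional choice is ambiguous; α = 0.05 is available through the
`alpha` argument). Venice grades: amount A/B/C at n_minor > 1000 / 100–1000
(inclusive at both ends) / < 100; replication A/B/C at I² < 25 / 25–50 /
> 50; bias A if *any* supplied check passes (pooled OR in the 0.87–1.15
null band, genotyping quality, robustness to excluding the first published
study, no small-study effects) else C; overall strong iff all A, weak iff
any C, else moderate.

## Synthetic data

`simulate_network` plants the exact topology the key-driver statistic
targets: an Erdős–Rényi background (default n = 200, p = 0.03, mean degree
≈ 6 — sparse, like a high-confidence interactome), two 15-gene disease
modules wired internally at p = 0.8, and a bridge hub wired to 15 genes of
each module (degree 30). It reproduces the planted structure exactly per
seed. It does **not** emulate scale-free degree distributions, edge
confidence heterogeneity, or annotation noise in seed lists, so planted-
recovery tests demonstrate correctness of the machinery, not performance on
a real interactome.

`simulate_meta_studies` draws per-study true log ORs from Normal(θ, τ²),
converts to case prevalence through the OR relation at control prevalence
p₀, and samples binomial counts per arm (degenerate tables redrawn, capped).
Calibration checks run at the conditions the shipped tables represent:
θ = ln 0.71, τ² = 0.05, p₀ = 0.5714 and the 14 published arm sizes for the
estimator-bias check (bias < 0.02 on the log scale over 500 replicates);
θ = 0, τ² = 0, k = 10, 500/arm for the Q-test type-I check at the 0.1 level
over 1,000 replicates. The generator assumes binomial sampling and
normally distributed random effects — it does not model genotyping error,
covariate confounding, or publication selection.

## Known limitations and degenerate inputs

- The published GSTT1/ATDH table is internally inconsistent (two identical
  study rows; the printed control grand total 2,534 disagrees with its own
  column sums, 2,532). The fixture transcribes it verbatim, the loader
  checks the column sums, and `KNOWN_INCONSISTENT_FIXTURES` flags it so
  analyses can exclude it from exact comparisons.
- Full-scale expansion counts on a real STRING network depend on the
  database version and are supported as a run mode but not asserted
  anywhere.
- Exact reproduction of published FDR-corrected driver p-values requires
  the exact gene universe and p-value ranks of the original network; the
  far-tail raw p for a 13-neighbor/11-common gene is checked against an
  exact rational summation and against the published value's magnitude only.
- Degenerate running-sum inputs (G = 0 or G = N), zero-margin 2×2 tables,
  k < 2 pooling, k < 3 sensitivity/Harbord, and zero-degree transition
  columns all raise explicit errors rather than returning NaN.
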