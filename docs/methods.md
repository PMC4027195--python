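# Methods

## The model

For one biological sample we observe an mRNA expression vector
**x**⁽ᵒ⁾ ∈ ℝ₊ᴺ (RPKM-like), a miRNA expression vector **z** ∈ ℝ₊ᴹ
(RPM-like) and an N × M seed-match count matrix **C**, where c_{i,k} is the
number of conserved sites for miRNA k in the 3′UTR of gene i. The model
treats miRNA targeting as a competition for binding mass and infers, per
(gene, miRNA) pair, three probabilities of interaction:

* **mRNA competition** — transcripts carrying sites for the same miRNA
  dilute it. The probability that gene i attracts miRNA k is one minus the
  probability that every one of k's molecules is attracted by some other
  transcript:

      p⁽ˣ⁾_{i,k} = 1 − [ Σ_{j≠i} c_{j,k} x⁽ᵗ⁾_j / Σ_j c_{j,k} x⁽ᵗ⁾_j ]^{z_k}

  The exponent z_k encodes that an abundant miRNA makes many independent
  "draws" from the site-mass distribution.

* **miRNA competition** — the mirror image: miRNAs with sites on the same
  transcript compete for it, with exponent x⁽ᵗ⁾_i:

      p⁽ᶻ⁾_{i,k} = 1 − [ Σ_{l≠k} c_{i,l} z_l / Σ_l c_{i,l} z_l ]^{x⁽ᵗ⁾_i}

* **joint competition** — the element-wise product p⁽ʲ⁾ = p⁽ˣ⁾ ⊙ p⁽ᶻ⁾,
  treating the two competitions as independent.

A pair with no site (c_{i,k} = 0), or with an unexpressed miRNA (Eq. for
p⁽ˣ⁾) or unexpressed gene (p⁽ᶻ⁾), has probability exactly 0 — the
convention fraction⁰ ≡ 1 implements this and is consistent with dropping
non-expressed miRNAs up front. A degenerate denominator (no expressed
competitor carries a site) also yields 0, not NaN: there is no evidence of
targeting. Probability rows/columns are deliberately **not** normalized to
sum to one — a miRNA can target many genes with high probability, and vice
versa.

**x**⁽ᵗ⁾ is the hidden *total* transcribed mRNA: because bound miRNAs
degrade their targets, the observed level is an equilibrium below the
total. The two quantities are linked by a fixed-point alternation:

1. initialize x⁽ᵗ⁾ = x⁽ᵒ⁾ and fix the transcriptional capacity
   T = capacity_factor · Σᵢ x⁽ᵒ⁾ᵢ once (never re-estimated);
2. evaluate p⁽ˣ⁾; the expected reduction per pair is
   Δx_{i,k} = η · p⁽ˣ⁾_{i,k} · x⁽ᵗ⁾ᵢ;
3. re-estimate the total from the observed level,
   x* = x⁽ᵒ⁾ + Σ_k Δx_{·,k}, and renormalize x⁽ᵗ⁾ = x*·T/Σx* so the
   total mass is conserved at T;
4. evaluate p⁽ᶻ⁾ with the fresh x⁽ᵗ⁾;
5. stop when neither probability matrix changed by more than `tol`
   anywhere (both matrices are checked after a full alternation).

Anchoring step 3 at the observed profile (rather than accumulating
reductions onto the previous iterate) makes the update a contraction — the
η-scaled term is a small perturbation of a constant — so the alternation
settles in a handful of iterations; the 10 × 4 toy system converges in 4.
Accumulating instead produces a slow replicator-style drift of mass toward
high-probability genes that does not meet a 10⁻⁵ tolerance within any
reasonable cap; we therefore treat the total as re-estimated from the
observed level each round.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `eta` (η) | 0.001 | learning rate scaling the per-iteration expected reduction; only the fixed point's approach speed and the Δ magnitudes depend on it |
| `capacity_factor` | 1.3 | T = 1.3 · Σ x⁽ᵒ⁾: total transcription assumed 30% above the observed equilibrium; a free parameter of the model, fixing it prevents the totals from growing without bound |
| `tol` | 10⁻⁵ | convergence threshold on max |Δp| of both matrices |
| `max_iter` | 200 | safety cap; non-convergence returns the last iterate with `converged=False` and a warning |
| `expression_rescale` | `"none"` | `"mean_one"` divides x and z by their means before fitting |

On the exponent scale: the competition fractions are scale-invariant, but
x and z also enter Eqs. above as exponents, so their units matter there.
Quantile-normalized RPKM/RPM values can be ≫ 1, which drives most
seed-matched probabilities to 1 (the module logs a saturation warning when
more than half of them exceed 1 − 10⁻¹²). The `mean_one` rescale keeps
exponents O(1) and probabilities informative; it is the default for the
differential pipeline and optional elsewhere. Within a cohort the mean is
taken per sample, so cross-sample comparability additionally relies on
quantile normalization (below).

## Preprocessing

Cohorts are quantile-normalized (mRNA and miRNA matrices separately, since
they come from different platforms and scales): each sample's values are
replaced by the per-rank means across samples, ties receiving the mean of
the reference values at their tied ranks. Expression and seed matrix are
inner-joined on identifiers in the seed matrix's canonical (lexicographic)
order. miRNAs with expression ≤ 0 (configurable threshold) are removed
from both the expression vector and the seed-matrix columns before
fitting. NaN input is an error — these matrices are complete by
construction, and silent imputation would corrupt probabilities.

Seed-match matrices built from site-level tables use, per gene, only the
transcript with the longest 3′UTR (ties broken by smallest transcript id,
for determinism); counts for the same transcript and miRNA are summed.
miRNA family members are kept as separate columns: members can be
expressed differently, and competition within a family is part of the
model. File-level duplicate (gene, miRNA) triplet rows are rejected as
corruption rather than summed — aggregation is the site builder's job.

## Evaluation

Rankings are total orders: descending score, ties broken by (gene, miRNA)
lexicographically. AUROC is the Mann–Whitney pair statistic (ties ½);
precision–recall sweeps group tied scores at one threshold and integrate
by trapezoid over recall, anchored at (0, first precision). The Pearson
baseline ranks seed-matched pairs by correlation across samples, most
negative first; zero-variance pairs are flagged with sentinel score −2 and
sort after all defined values. The classifier loss is the mean
cross-entropy MCE = (1/N) Σ −tₙ ln pₙ with natural log; as written it
assigns zero loss to all normal (t = 0) samples, so an optional `full`
variant adds −(1 − tₙ) ln(1 − pₙ). This is provided, not silently
substituted.

## Differential analysis

Matched tumor/normal pairs are compared feature-wise with a paired t-test
(t = mean(d)/(sd(d)/√n), df = n − 1, two-sided Student p); zero-variance
differences give a flagged NaN that is excluded from multiplicity
correction. FDR control is Benjamini–Hochberg step-up (the procedure is
configurable in principle; BH is the default and the one used throughout).
The three-rule coherence filter keeps interaction (i, k) iff (i) the
interaction, the gene and the miRNA each pass their FDR cutoff (default
0.05 each, separately configurable per feature class); (ii)
sign(t_interaction) = sign(t_miRNA); (iii) sign(t_interaction) =
−sign(t_gene). Signs come from the t statistics. For probability-valued
features the "fold change" column reports the difference of means
(ratios are meaningless when a mean is 0); expression fold changes use
log2 with a pseudocount (default 1). Gene-level scores for enrichment
export are row means of the signature over all M miRNA columns, zeros
included.

## Synthetic data

The generator emulates the shape of the real inputs at desk scale
(default 300 genes × 20 miRNAs, versus ~13000 × 710 in real cohorts):

* seed counts: Bernoulli(0.15) site presence with geometric counts of
  mean 1.5 — sparse, small, integer, single sites dominating;
* expression: log-normal (μ = 0.5, σ = 1), long-tailed and nonnegative;
* truth: a `target_fraction` (default 0.1) of seed-matched pairs is
  labeled true, sampled with probability ∝ w(z_k) · w(x_i) where
  w(v) = v/(v + median v) — an interaction needs both partners present,
  and abundance makes it more likely (the same monotone intuition the
  competition model itself encodes); x is taken at its latent,
  pre-repression level;
* repression: each true interaction multiplies the gene's observed mRNA
  by 1 − repression_strength · w(z_k), so repression saturates with miRNA
  abundance and observed values stay positive.

Matched cohorts draw per-pair baselines (log-normal noise, σ = 0.15
around the base profile) and tumor samples with planted shifts: direction
"up" multiplies the miRNA by 4 and the gene by 0.7 (oncomir gain with
coherent target repression), "down" is the reciprocal, "incoherent"
shifts both up as a negative control for the sign rules. Auto-selected
planted miRNAs come from the 25th–60th expression percentile band: low
enough that the gain is a real biological change, high enough that a
few-fold shift crosses expression ranks after cohort quantile
normalization (with few miRNAs, rank resolution is coarse and a shift
that stays within one rank is invisible by construction). Planted genes
are drawn from above the median so their downregulation remains
detectable.

What the generator does **not** emulate: realistic 3′UTR length/site
structure, miRNA family seed sharing, count noise models
(negative-binomial overdispersion), batch effects, copy-number
confounding, ceRNA competition, or translational-only repression. Passing
tests demonstrate internal correctness and that the pipeline recovers
signal under its own generative assumptions — not performance on real
tumor cohorts.

## Problem sizes and numerical choices

Tests and the acceptance checks run at 10 × 4 (toy), up to 50 × 10
(reference-oracle comparisons), 300 × 20 (ranking benchmarks, 10
replicates) and 150 × 20 with 20 matched pairs (differential recovery) —
sizes at which every behavior of interest is already expressed and the
full suite runs in seconds. Probabilities are computed in log space
(exp(z · log f), f clamped to [0, 1]) for stability at large exponents;
capacity renormalization holds Σx⁽ᵗ⁾ = T to relative error 10⁻⁹; the
fit is fully deterministic (bit-identical reruns). Serialization uses
plain TSV with `#` comments allowed, round-tripping integer matrices
bit-exactly; the triplet dialect cannot represent all-zero rows/columns
(those features simply vanish), which the dense dialect preserves.

## Known limitations

* The capacity factor 1.3 is a modeling assumption, not an estimate; the
  signature depends on it only weakly through the exponents.
* The exponent scale question above means absolute probability values are
  unit-dependent; rankings are much more stable than values.
* Eq. for the plain MCE ignores normal-sample errors entirely; use
  `full=True` for a proper binary cross-entropy.
* The coherence filter inherits the paired t-test's normality assumption;
  with n = 14–58 pairs (typical matched cohorts) this is mild but real.
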