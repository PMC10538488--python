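# Methods

`dsmlink` quantifies how much identifying information a gene-expression
profile leaks about its owner's genotype, by building the strongest match
score an attacker could plausibly learn and measuring how well it links
expression profiles to candidate genotype profiles.

## Model

### Haplotype prior: Li–Stephens copying chain

Each phased haplotype h over V biallelic sites is modelled as an error-prone
mosaic copy of a reference panel of K haplotypes.  The hidden state z_s is
the panel row copied at site s.  Transitions follow the genetic map:

    P(switch between s and s+1) = 1 − exp(−ρ Δg_s / K),

with Δg_s the map distance in cM and ρ a population-scaled recombination
intensity (`recomb_scale`, default 1.0); conditional on a switch the new
source is uniform over the K rows (self included) and the prior over the
first state is uniform.  Emission is a symmetric copy error:
P(h_s ≠ panel[z_s, s]) = ε (default 0.01).  The forward–backward recursion
uses per-site scaling, is stable to V ≈ 1e5, and is validated against
exhaustive path enumeration on every instance small enough to enumerate.
The parameterization of the transition and emission factors is our
design choice; a degenerate map (Δg ≡ 0) is legal and collapses the chain to
a single copied row with errors.

### QTL factors and the conditional random field

For each eQTL s with eGene set Q(s), a logistic factor ties the allele to
the expression of its eGenes:

    φ_s(h_s, e) = h_s σ(α_s + β_sᵀ e_Q(s)) + (1 − h_s)(1 − σ(·)),

with e standardized per gene (mean/sd frozen from the training data).
Factor probabilities are clipped to [1e−12, 1 − 1e−12] before logs.  The
full conditional over a phased genotype x = (h^m, h^p) multiplies two
independent copying chains with the factors applied identically to both
haplotypes — the haplotype decoupling that makes inference linear rather
than quadratic in K.  An exact paired-chain version over K² joint states is
provided for small instances to measure what the decoupling changes; with a
genotype-level factor defined as the product of the two haplotype factors it
coincides with the decoupled model exactly, and a 3-level ordinal-logistic
dosage factor (our construction, cutpoints ±1) exercises the genuinely
coupled case.

### Match score

Candidates are ranked by log M(x, e) = log p̃(x | e) − log p_HMM(x).  Because
the factors enter the chain as per-site constants once the alleles are
observed, the chain terms cancel and log M reduces to the sum of log factor
probabilities at the observed alleles; the package computes match matrices
that way and tests that the reduction agrees with the definitional
forward–backward route to 1e−9.

### Training

Factors are learned jointly by maximizing the mean *normalized* conditional
log-likelihood over matched training pairs,

    Σ_i [ log p̃(h^m_i | e_i) + log p̃(h^p_i | e_i) − 2 log Z_h(e_i) ],

where the partition function Z_h(e) sums each chain over both the hidden
state and the free allele at every site.  Z couples the sites through the
panel's LD, which is what shrinks redundant factors: two perfectly linked
sites carrying the same eGene signal split it instead of double-counting.
The gradient has the closed form (observed dosage − 2 × posterior allele
probability) per site logit, so training uses hand-coded analytic gradients
with a hand-coded full-batch Adam optimizer (lr 0.025, 50 epochs, zero
initialization — a symmetric flat start).  Chain parameters (ε, ρ) stay
frozen.  Gradients are verified against central finite differences of the
objective (relative error < 1e−4).  Genomic windows of 750 eQTLs (the
default `window_size`) are trained as separate models whose scores add;
window panels tile the full site range so a single window reproduces
unwindowed training exactly.

Note the *unnormalized* objective would be constant in the chain and reduce
to independent per-site logistic regressions; the normalizer is the part
that calibrates for LD, and the package trains the normalized form.

## Baselines

**GNB** (Gaussian naive Bayes): after greedy significance-ordered pruning of
eQTLs with training-dosage |Pearson r| > 0.1, each retained eQTL (single
eGene) is scored by log N(e; μ_{s,d}, σ_s) + log P(d) over dosage classes
d ∈ {0, 1, 2}, with per-class means, a pooled within-class σ (floored at
1e−6), and frequency priors (floored at 1e−6).  Classes with fewer than two
training samples fall back to the linear regression of expression on dosage.
Phase is collapsed to dosage since it carries no expression signal.  The
published approach used additional normalization heuristics that are not
printed; we implement the plain log score.

**EBL** (extremity-based linking, hybrid): for retained eQTLs whose
eQTL–eGene correlation passes `corr_min`, expression beyond the
`extremity_q` / 1 − `extremity_q` empirical quantiles predicts the
corresponding homozygote (by the sign of the association); a candidate
matching the prediction contributes 0, a contradicted prediction −λ
(default λ = 5 nats; λ → ∞ recovers hard filtering — the original method
counts genotype agreements, which an additive per-site score generalizes).
All non-extreme sites contribute their GNB term, so with no extreme genes
EBL equals GNB bit for bit.

## Linking and evaluation

Forward linking assigns each query expression profile its argmax candidate
independently (no bipartite matching); ties break toward the lowest
candidate ID and are flagged.  Reverse linking reads the same pairwise
scores transposed.  A per-query Gaussian is fitted to the mismatching
candidates' scores (optionally on a 500-candidate subsample) and upper-tail
P-values measure how far the best match separates from impostors.  For
unknown-membership attacks a score threshold gates the calls; over the
threshold sweep, TPR is the fraction of present-match queries linked
correctly above threshold, FPR the fraction of holdout (matchless) queries
called at all, and precision counts correct calls among all calls.  AUROC
and AUPRC are trapezoidal areas over the sweep, averaged over 100 random
half-holdout trials by default.

## Synthetic study conditions

The generators emulate exactly the structure the models assume, so tests
isolate implementation correctness from model misfit:

- **Panel**: sites in LD blocks (`ld_block_size`, default 5); within a block
  every panel haplotype copies one of `n_founders` (default 4) founder
  segments, plus 3% mutation; allele frequencies pushed into [0.05, 0.95].
- **Individuals**: haplotypes drawn from the same copying process used for
  inference (switches from the genetic map with `recomb_scale` 50 in the
  fixtures — a few crossovers per haplotype — and copy error 0.01).
- **Expression**: e_g = Σ_s effect_{s,g} · dosage_s + N(0, noise_sd), effect
  magnitudes U(0.5, 1.5) with random signs, 3 eGenes per eQTL by default
  (redundant signals), plus pure-noise genes.  A misspecified-recombination
  mode (`hotspot_intensity`) adds hotspots unknown to the model.

Default experiment sizes keep every run at desk scale: K = 60 panel
haplotypes, V = 300 sites, 150 eQTLs, 300 training pairs, 50 queries, 250
decoys.  The parameter-recovery experiment uses independent common variants
(founder pool = panel size, founder frequencies U(0.35, 0.65)), slope 3 and
noise sd 0.5; the P-value calibration experiment deliberately uses a weak
fixture (V = 60, 30 single-gene eQTLs, noise sd 2.0, 2000 decoys) so
empirical P-values spread over several orders of magnitude instead of
saturating at 1/(n+1).

What passing these tests does **not** show: real expression is not linear in
dosage with Gaussian noise, real LD does not come from founder blocks, and
real panels are three orders of magnitude larger; absolute accuracies on the
fixtures say nothing about accuracies on real cohorts, only the *relative*
behaviour of the scorers and the internal consistency of the inference are
probed.

## Numerical and design notes

- All chain computations use per-site scaled linear space (equivalent to
  log-space up to rounding); the scaled and enumerated routes agree to
  1e−10 on every tested instance.
- Multiple eQTL records on one variant are merged into a single factor
  (one site, one factor), pooling their eGene sets.
- Non-eQTL panel sites carry unit evidence; they contribute LD information
  but no expression signal.
- The per-site genotype posterior of the decoupled model is the binomial
  family Binom(2, p): it cannot express "confidently heterozygous", and at
  extreme allele frequencies the frequency prior (held by the chain, not the
  factor) pushes heterozygote posteriors across MAP boundaries.  Per-site
  class prediction therefore uses the factor probabilities and is evaluated
  at common variants; this is a structural property of haplotype decoupling,
  not an implementation artifact.
- Fixed-budget full-batch Adam moves each parameter at most ~lr per epoch,
  so 50 epochs bound |β| by ≈ 1.25; comparisons that are properties of the
  optimum (e.g. duplicated-eGene calibration) are tested at 600 epochs.
- Known limitations: no unphased-genotype (diploid-state) chain, no
  imputation of non-eQTL sites, no per-site emission rates, no one-to-one
  assignment optimization, no cross-tissue score combination.  The reverse
  linking baseline is the DSM score itself read transposed; no external
  expression-prediction tool is wrapped.
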