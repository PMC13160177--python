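# Methods

## The model

`keju` treats an MPRA observation as one barcode measured in one RNA sample:
a DNA count `D_n`, an RNA count `R_n`, and labels for enhancer, RNA batch,
DNA batch, condition, and optionally motif, covariate (minimal promoter) and
negative-control status. The likelihood is a single negative-binomial GLM on
the RNA counts,

    R_n ~ NB( mu_n = S_br(n) · d_n · exp(alpha_e(n) + X_n'beta + Y_n'gamma),
              phi = phi_g(n) ),      Var = mu + mu²/phi,

with DNA entering only through the fixed offset `d_n = (D_n + p)/S_bd`. The
modeling position is that DNA counts carry little uncertainty relative to
RNA counts, so conditioning on them buys power without hurting calibration;
uncertainty is then modeled only where it matters, in the RNA, in a
batch-specific way.

Design matrices encode identifiability: `X` (one column per candidate) is
nonzero only for candidate enhancers in the alternate condition, so negative
controls never receive an effect size; `Y` (one column per covariate) is
nonzero for *every* alternate-condition observation, controls included —
that is how the controls anchor a separate null per covariate.

Overdispersion is shared: per RNA batch, enhancers are ranked by mean RNA
count and chunked into consecutive bins of `G` (default 50, remainder kept
in the last bin, ties broken by enhancer label for reproducibility). Each
bin gets one `phi_g`. This encodes the mean–variance trend, reduces the
parameter count, and `G = 1` recovers a fully per-(enhancer, batch)
dispersion model as an ablation.

Priors: `phi_g ~ Exp(1)`, `gamma_k ~ N(0,1)`. Transcription rates and
effects take one of three hierarchies — promoter+motif
(`alpha_e ~ N((1+r_k)theta_m + t_k, eps_m²)` with `r_k > -1`,
`beta_e ~ N(mu_m, sigma_m²)`), motif-only (`alpha_e ~ N(theta_m, eps_m²)`),
or flat (`alpha_e, beta_e ~ N(0,1)`). Motif-level means and intercepts get
`N(0,1)`; group variances get `Inv-Gamma(1,1)` on the variance scale; `r_k`
gets `N(0,1)` truncated at −1 (realized by the transform `r = -1 + exp(u)`).

Significance: `lfsr_e = min(Pr(beta_e ≥ 0), Pr(beta_e ≤ 0))`, estimated as
draw fractions; an effect is significant when `lfsr < 0.05` (strict
inequality, threshold configurable in (0, 0.5]).

## Preprocessing defaults

* Coverage filter: drop an enhancer when its average number of barcodes per
  RNA batch with both counts strictly above 5 falls below 10 (averaged over
  all RNA batches in the table).
* Size factors: 75th percentile of each batch's counts (linear
  interpolation, zeros included; a positive-only variant is available),
  rescaled to mean 1 within each modality. DNA factors are computed on
  deduplicated (DNA batch, enhancer, barcode) observations so pooled designs
  do not count the same plasmid measurement twice.
* DNA pseudocount: default 1 (configurable, including 0). The offset
  `d_n = D_n/S_bd` is degenerate at `D_n = 0` — the GLM mean would be pinned
  at zero — so preprocessing adds the pseudocount before forming offsets.
* Condition coding is strictly two-level (control vs alternate);
  multi-treatment experiments are analyzed as separate pairwise fits.
* Binning uses raw within-batch mean counts; size-factor scaling is a
  monotone within-batch transform and cannot change the ordering.

## Sampling

No-U-Turn sampling (multinomial trajectories, dual-averaging step size,
diagonal mass matrix) over an unconstrained vector; dispersions and group
variances are log-transformed with the Jacobian included. Both models
supply analytic gradients, so each leapfrog step is a handful of vectorized
array operations.

Two numerical choices matter in practice:

* **Centered parameterization.** Barcode-level counts make the enhancer
  parameters strongly likelihood-identified; the non-centered form then
  couples `z`, `theta`, `eps`, `r` on a narrow manifold and mixes poorly,
  while the centered form mixes well. `Inv-Gamma(1,1)` vanishes rapidly at
  zero variance, so the classical funnel does not open.
* **Curvature warm start.** Chains start at the posterior mode (L-BFGS on
  the unconstrained density) with the inverse diagonal negative Hessian as
  the initial mass matrix; one long warmup window refines it from draws,
  shrunk toward the curvature estimate. This cuts warmup by an order of
  magnitude on these posteriors.

Defaults are 4 chains × (1000 warmup + 1000 samples); the tests and the
acceptance script use 2 chains × (200–400 + 200–400) to keep desk-scale
runtimes in seconds per fit. Convergence trouble (split-R̂ above 1.01,
post-warmup divergences) warns and is recorded in the results manifest,
never silently swallowed. Extreme corners of parameter space (|z| > 40, or
linear predictors beyond ±200) are rejected with density −∞; the sampler
treats them as divergent, which only matters during early step-size search.

Given a seed, fits are bit-reproducible: chain *c* draws from
`SeedSequence((seed, c))` and chains run sequentially.

## The alternate simulation model

For benchmarking, simulating from the model under test flatters it. The
simulation model is therefore a different, deliberately plainer generative
process: two NB GLMs,

    D ~ NB(S_bd · exp(d_{e,bd}), phi_e^d),
    R ~ NB(S_br · exp(d_{e,bd} + alpha_e + X'beta + Y'gamma), phi_e^r),

with per-enhancer, per-modality dispersions, no batch-specific RNA
dispersion and no motif shrinkage (asserted in tests, not "fixed"). Priors
are `N(0,2)` on all location parameters and `Exp(1)` on dispersions. DNA
counts are deduplicated to one observation per (DNA batch, enhancer,
barcode) before fitting — the duplicated pooled layout would understate DNA
dispersion. Simulation draws one posterior sample uniformly per replicate
(seeded per replicate), regenerates both modalities, mirrors the source
scaffolding with barcodes capped at 25 per enhancer (fewer are kept as-is),
and adds a pseudocount of 1 to simulated DNA counts. Source size factors
are reused and recorded rather than refit.

## The synthetic-data generator

`keju.synth` samples the full hierarchy forward: motif transcription levels
`theta_m ~ N(0, 1)`, promoter slopes/intercepts (defaults give a second
promoter double slope, +0.5 intercept, emulating a strong minimal promoter
next to a weak one), enhancer rates `alpha_e` with within-motif spread 0.5,
motif-level effects (a fraction of motifs active, default 0.4, with means
`N(0,1)` and within-motif spread 0.25 — effects are a motif-level property,
matching the model's exchangeability assumption), covariate correction
factors, and lognormal size-factor spread (sd 0.15). DNA counts are NB
around per-(enhancer, pool) log-means (median count ≈ 100); RNA counts are
then drawn from the regression equation using the *realized* DNA offsets.
Dispersions follow an increasing mean–count trend (defaults 4→32 for RNA by
count quartile; 100 for DNA, i.e. DNA is close to Poisson) — RNA noise well
above Poisson, DNA noise low, as in real assays.

A table's `rna_batch` label denotes one RNA sample = (replicate,
condition): `n_replicates` replicates are each measured in both conditions,
so a config with `E` enhancers, `b` barcodes and `B_r` replicates yields
`E·b·B_r·2` rows. Paired designs give each replicate its own DNA pool
(shared by its two condition samples); pooled designs share fewer pools
across replicates, duplicating each barcode's DNA count across the samples
it serves.

What the generator does *not* emulate: sequence content, barcode collisions
and PCR jackpotting, condition-correlated library composition drift, or
heavy-tailed count contamination. Passing tests therefore demonstrate
correctness of the inference machinery under the assumed NB/batch/motif
structure, not robustness to every artifact of real libraries.

For fixed-magnitude power grids, `effect_sizes=(0.25, 0.5, 1.0)` (natural
log scale) assigns candidates those magnitudes cyclically with random
signs.

## Benchmarking protocols

* **Power**: |significant ∩ truth| / |truth| against a ground-truth call
  set (in simulations, the calls made on the source data).
* **Masked-control FPR**: negative controls are split in half (labeled half
  keeps the extra one when odd, seeded); masked controls re-enter the fit
  as candidates, each under its own pseudo-motif by default so no real
  motif group absorbs them (configurable to keep labels). FPR = fraction of
  masked controls called significant. Correction factors are learned from
  the labeled half only — the masked half must stay blind.
* **Subsampling grid**: barcodes are capped per enhancer by trailing-number
  order (numbered barcodes) or sorted label, and the model refits at each
  (cap, G) cell. Ground truth is the full-data `G = 50` call set; the
  (max cap, 50) cell *is* that computation, so its power is exactly 1 — a
  self-consistency anchor, reused rather than recomputed.
* A decile-stratification utility reports the fraction significant per
  mean-count bin (control condition), optionally per covariate.

## Design choices and limitations

* **Recovery harnesses condition on the generating size factors.** Truth
  parameters are defined on the generator's normalization scale; re-
  estimated upper-quartile factors absorb part of any global condition
  shift, which biases `alpha`/`gamma` recovery by a few percent per batch
  and is invisible to real-data use (where there is no "true" scale).
  Pipeline defaults always estimate factors from data.
* **Trend-line identifiability.** `t_k + (1+r_k)·theta_m` is well
  identified, but `(theta, r, t)` individually ride a ridge (rescaling
  `theta` trades off against slopes) resolved only by their priors. Slope
  *ratios* between promoters are recovered reliably; absolute slopes shrink
  toward zero. The promoter case warns when only one covariate is present.
* **No sum-to-zero constraint** on `gamma` or motif means; negative-control
  rows in `Y` anchor `gamma` softly. With few controls per covariate,
  `gamma` and the control-motif `theta` can trade off.
* Masked-control refits currently re-estimate size factors on the same
  table (masking changes labels, not counts, so factors are unchanged).
* The LFSR is the draw-fraction estimator; with `n` retained draws its
  granularity is `1/n`, so thresholds well below `1/n` are meaningless.
* Multi-condition designs, variational inference, and barcode-to-enhancer
  mapping from raw reads are out of scope.
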