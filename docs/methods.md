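# Methods

This note documents the models and procedures implemented in `commvade`,
the assumptions behind them, the parameters that matter, and what the
synthetic study conditions do and do not establish about real data.

## Study design being emulated

Two anaerobic-digester communities — a low-biogas-producing resident (LP)
and a high-producing invader (HP) — are grown in replicate fed-batch
fermenters. After two weekly feedings, 20 LP replicates are invaded with
HP at 10, 1, 0.1, or 0.01 % by volume (5 replicates per dose); 5 LP and 5
HP replicates stay pure. Cultivation continues for six more weekly
feedings. Endpoint communities are read out as 16S ASV count tables
(350–500 k reads per sample; one pure-HP sample is dropped to mirror a
failed sequencing run, leaving 29 sequenced samples out of 30), and every
fermenter logs weekly cumulative CO2-stripped biogas over the 8 weeks.

## Simulator

### Sources and invasion

Each source community draws per-ASV abundances i.i.d. lognormal(0, σ) over
its support (150 shared ASVs, 80 unique to each community) and normalizes.
σ = 2.5 by default: amplicon abundance distributions are heavy-tailed over
several decades, and this is what makes rare-taxon loss gradual in dose.
Invasion is volumetric mixing, `(1−d)·LP + d·HP`.

### Transfer dynamics

Each weekly feeding is one Wright–Fisher generation: taxon weights `w_i`
rescale frequencies, then `bottleneck_N` cells (default 1e5) are drawn
multinomially. Taxa hitting zero stay zero; there is no migration. Pure
communities transfer neutrally (`w_i = 1`): each is treated as being at its
own competitive equilibrium, and the invader's advantage is an advantage
*over the resident* (e.g. exploiting substrate the LP community uses
poorly), not over its own community. This matters for attribution: if
HP-unique taxa outgrew their own community, the pure-HP endpoints would
lose their shared taxa and the presence-rule oracle would collapse.

In invaded communities, an HP-origin unique taxon at frequency `p_i` has

    w_i = 1 + s_rep   if p_i ≥ establishment_freq
    w_i = w_sub       if 0 < p_i < establishment_freq

with `s_rep = exp(ln(1+s) + ε) − 1`, `ε ~ Normal(0, fitness_rep_sigma)`
drawn once per replicate, and `w_sub = 0` by default. Shared taxa evolve
neutrally everywhere (the attribution rule cannot use them anyway).

The three pieces have distinct jobs and distinct empirical anchors:

* **s (default 16).** Strong selection drives the established invader
  biomass toward fixation within the six post-invasion transfers from any
  dose, which is what makes the invader *read share* approximately
  dose-independent (a saturation effect) even as the number of established
  invader ASVs varies strongly with dose. Weak selection cannot do this:
  six transfers at s = 1 shift log-odds by ~4.2, far less than the ~6.9
  spread of starting log-odds across a 3-decade dose range, so read shares
  would track dose. The sweep regime yields invader read shares near 1,
  higher than real endpoint shares; the *flatness*, not the level, is the
  emulated feature.
* **establishment_freq (default 1e-6).** A positive-density-dependence
  (Allee/priority-effect) threshold: invader taxa entering below this
  community frequency fail to establish. It converts dose into a sharp
  per-taxon abundance cutoff `p_i ≥ establishment_freq/d`, which produces
  the dose-ordered invader richness, the taxa present only above the
  functional tipping point, and the stepped gas response. Pure multinomial
  thinning cannot produce this sharpness: survival probabilities at
  adjacent 10× doses are too correlated for any taxon to be reliably
  prevalent at 1 % yet absent from all ten lower-dose replicates.
* **fitness_rep_sigma (default 0.5).** Replicate fermenters differ
  biologically; the jitter on ln(1+s) reproduces the large between-replicate
  spread in invasion outcome that makes the read-share dose test
  non-significant despite ordered means. The default matches the regime in
  which within-dose spread dominates the residual between-dose differences.

These defaults were fixed once, by a desk-scale calibration against the
qualitative pattern set the simulator exists to generate (count ordering,
flat read share, stepped gas, screen recovery), and are not tuned per
analysis.

### Key taxa and gas

`n_key_taxa` (8) HP-unique ASVs are planted with abundances log-uniform in
the "tipping band" — above the establishment cutoff at 1 % dose, below it
at 0.1 %, with a ×2 safety margin on both sides — so they establish at the
two high doses and deterministically fail below (the `key_taxa_rare_bias`
flag; planting uniformly over HP-unique taxa is the alternative). Weekly
gas rates are piecewise constant:

* pure HP: `gas_hp_rate` (320 mL/week) throughout;
* pure LP, and invaded fermenters where fewer than `key_taxa_k` (5) key
  taxa established: `gas_base_rate` (200 mL/week);
* invaded fermenters with the key taxa: `gas_base_rate` until
  `gas_lag_weeks` (4) after invasion, then `gas_boost_rate` (680 mL/week).

The boost is a *catch-up* rate, deliberately above the pure-HP steady rate:
undigested feed accumulates during the lag, so once the key taxa establish,
cumulative production converges to the pure-HP trajectory (the default is
exactly `4·hp − 3·base`, making the expected week-8 totals of boosted
invaded and pure HP equal). Gaussian noise (sd 20 mL/week) is added to
weekly increments and clipped at zero, keeping cumulative series monotone.
Rates are in mL per week of CO2-stripped biogas at bench scale; only
ratios matter to the verdict structure.

### Randomness

All randomness flows from one seed. Global structures (source profiles,
key-taxon choice, tree) use a root stream; every sample uses a substream
keyed by a stable hash of (treatment, replicate), so changing the replicate
count or dose set never perturbs other samples. The phylogeny is a random
coalescent-style topology with Exp(1) branch lengths — UniFrac needs a
valid rooted tree, not a realistic 16S tree.

## Analysis procedures

* **Attribution** uses pure *endpoint* replicates only; presence means
  count > threshold (default 0) in ≥1 replicate. Headline fractions use
  known-origin denominators; worst-case variants use full totals. Samples
  with no attributable reads carry missing metrics (never 0) and are
  dropped listwise from dose tests, with a logged count.
* **Dose tests** are one-way fixed-effects ANOVA with dose categorical
  (scipy `f_oneway`; full-vs-null F equals the one-way F here), with
  Tukey-adjusted pairwise contrasts from statsmodels.
* **UniFrac** is computed in one postorder accumulation per sample over a
  flattened tree index; the root edge is excluded. Weighted UniFrac
  defaults to the normalized variant (bounded [0,1]); the raw variant is a
  flag. Unrarefied counts are converted to relative abundances on the fly.
* **PERMANOVA** uses `SS_total = (1/N)Σ_{i<j} d²`, within-group analogues
  scaled by group size, `pseudo-F = (SS_b/(a−1))/(SS_w/(N−a))`, and
  whole-label permutation with the add-one estimator
  `p = (1+#{F* ≥ F})/(1+n_perm)` (ties count as extreme; p is never 0;
  default 999 permutations). Zero within-group sums give an infinite-F
  sentinel; an all-zero distance matrix sets a degenerate flag instead of
  testing. Pairwise PERMANOVA adjusts with Bonferroni (default) or Holm.
  Note that with 5-vs-5 groups the smallest attainable permutation p
  (~0.009) cannot survive a 15-pair Bonferroni factor — adjusted pairwise
  separation is structurally impossible at that design size.
* **Screen** stage 1 reads "present in the high doses" as a conjunction
  over treatments (flag-switchable to a union), stage 2 applies strict
  >50 % prevalence within each high treatment separately (flag-switchable
  to pooled). Raising the presence threshold tightens the high-side
  condition but *relaxes* the low-side absence condition, so the full
  screen is not monotone in the threshold; only the high-side criteria are.
* **Dunnett many-to-one** pools variance across all groups, forms
  treatment-vs-control t statistics with correlations
  `ρ_ij = √(λ_i λ_j)`, `λ_i = n_i/(n_i+n_0)`, and computes adjusted
  p-values as the Monte-Carlo tail of max|T| under the multivariate-t null
  (default 1e5 seeded draws; adjusted p is floored at the raw p to remove
  MC undershoot). The dose trend regresses total gas on log10(dose) by OLS
  (doses span 3 decades); a raw-dose fit is available by flag.

## What the synthetic conditions do not show

The simulator reproduces the *structure* of the experiment and the
qualitative result set, not the measured numbers: real ASV richness is
several-fold higher, real attributable-read fractions are far lower (most
reads sit in shared taxa), real invader read shares are intermediate
rather than near-saturated, and the establishment threshold stands in for
unidentified mechanisms (priority effects, density dependence, co-selection)
that the experiment cannot distinguish. Passing tests therefore demonstrate
that the analysis code recovers planted truth and reproduces the pattern
set under a plausible generative model — not that the model is the
mechanism operating in real digesters.

## Numerical choices and degenerate inputs

Counts must be exactly integral on read (a 3.5 is a format error, not a
rounding candidate). Zero-sum samples are rejected at validation with the
sample named. Pielou evenness is undefined (missing, with a warning) below
richness 2. Identical-sample UniFrac is exactly 0; empty-denominator
normalized weighted UniFrac returns 0. ANOVA with zero residual variance
returns F = 0, p = 1 when group means tie and an infinite-F sentinel with
p = 0 otherwise. Dunnett t statistics with zero pooled variance are 0 when
the mean difference is 0 and ±∞ otherwise. Problem sizes throughout
(20-study banks, 999 permutations, 1e5 Monte-Carlo draws, 1e4 extinction
replicates) were chosen to keep every check comfortably inside a desk-scale
run while leaving Monte-Carlo error well below the decision margins.
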