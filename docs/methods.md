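# Methods

This document describes the statistical models implemented in
`selcontrast`, the assumptions behind them, the synthetic-data generator
used for calibration and power studies, and the main numerical choices
and limitations.

## Problem setting

`selcontrast` compares the strength, prevalence and location of positive
selection between two sets of homologous protein-coding sequences — the
motivating case being S-RNase alleles of gametophytic self-incompatibility
systems, where balancing selection maintains highly diverged allelic
lineages within species (younger, recently re-diversified Physalis allele
sets versus older Solanum allele sets). All inference is codon-based:
selection is measured by the ratio of non-synonymous to synonymous
substitution rates (dN/dS, written ω), with ω > 1 indicating positive
selection.

## Codon substitution model

The core model is a Muse–Gaut/Goldman–Yang style Markov process on the 61
sense codons (stop codons are excluded from the state space, so
transitions into stops have rate zero by construction):

- Single-nucleotide changes only; multi-nucleotide instantaneous changes
  have rate 0.
- Rate of a synonymous change `i -> j`: `r_ij = s_ij * pi_j * alpha`;
  non-synonymous: `r_ij = s_ij * pi_j * beta`, where `s_ij` are nucleotide
  exchangeabilities (HKY85 with transition/transversion ratio κ, or GTR)
  and `pi_j` the equilibrium codon frequency.
- Codon frequencies come from F3×4 (position-specific nucleotide
  frequencies) or F61 (empirical codon frequencies).
- The generator matrix is **neutral-normalized**: Q is scaled so that one
  unit of branch length equals one expected substitution per codon when
  α = β = 1. Consequently (α, β) act as synonymous/non-synonymous rate
  multipliers on a fixed branch-length scaffold, and per-site estimates
  convert to dS = α·t/3 and dN = β·t/3 (per nucleotide site within the
  codon).

Likelihoods are computed by Felsenstein's pruning algorithm with
per-branch transition matrices from the spectral decomposition of Q.
Missing data (gaps, ambiguity codes, stops in input files) are
marginalized as fully uncertain states. Correctness of the pruning
implementation is checked against brute-force enumeration of ancestral
states on small trees (tolerance 1e-8).

### Global fit

`fit_global_model` estimates branch lengths, κ (or GTR exchangeabilities)
and a single global (α, β) by L-BFGS-B on the exact likelihood. All
site-level machinery below freezes the branch lengths and nucleotide
parameters at this fit, a standard two-stage design that keeps per-site
models identifiable.

### Site rate surfaces

Per-site analyses are accelerated through two precomputed interpolation
structures:

- `SiteRateSurface`: per-site log-likelihood on a logarithmic (dS, dN)
  grid with cubic interpolation, used by the REL mixture machinery.
- `OmegaProfile`: per-site log-likelihood along a 1-D log-ω spline
  (dS fixed at the global estimate), used by the site-class models and
  the MCMC sampler.

Grid bounds and knot densities were chosen so that interpolated
log-likelihoods track exact recomputation to well below the statistical
noise of the tests that consume them (verified in the test suite).

## FEL: fixed-effects per-site tests

`fel_scan` re-estimates (dS, dN) independently at every codon and tests
positive selection by a likelihood-ratio test of the null dN = dS against
the free alternative, with one degree of freedom and the one-sided
convention that only sites with dN̂ > dŜ are called positive. `fel_csp`
contrasts a site between two datasets (shared dS, common vs distinct dN),
and `fel_clade` contrasts foreground/background dN at a site within one
tree.

`run_power_analysis` simulates replicate alignments from a per-site rate
template (by default 25% strictly neutral sites and dN ≤ dS elsewhere,
echoing fitted rate mixtures), rescans them, and reports false-positive
and power rates over a grid of significance levels. The per-site LRT is
conservative-to-nominal on data of this shape: empirical false-positive
rates at p ≤ 0.05 sit near 4–5%.

## REL: random-effects mixtures and cross-dataset tests

`fit_rel` models sites as draws from four latent (dS, dN) classes with
structural roles — one positively selected (ω > 1), one neutral (ω = 1),
two purifying (ω ≤ 1) — enforced by reparameterization (logistic for
purifying ratios, log(ω−1) for the positive excess), so parameter counts
are exact: 7 rate parameters + 3 mixing logits per dataset.

Fitting two datasets jointly under nested ties yields the cross-dataset
hypothesis tests:

| constraint              | tie                                        | df |
|-------------------------|--------------------------------------------|----|
| `same_strength`         | positive-class ω equal                     | 1  |
| `same_proportion`       | positive-class weight equal                | 1  |
| `same_regime`           | both of the above                          | 2  |
| `shared_distributions`  | entire distribution shared                 | 10 |

### Optimizer strategy

The mixture likelihood is multimodal, and the constrained fits have
boundary optima that plain hill-climbing misses. Three ingredients make
the tests reliable:

- **Moment initialization**: per-site grid-argmax (dS, dN) points are
  bucketed into the four roles (with a dedicated near-zero-ω bucket when
  nearly invariant protein sites are present) to build a data-driven
  starting distribution; fixed strong-positive, no-positive and
  zero-ω-class starts cover the remaining basins.
- **Structured constrained inits**: ratio ties can be satisfied at no
  cost by shrinking one positive-class weight to ~0; weight ties by
  parking a positive class at ω ≈ 1 where it mimics the neutral class.
  Each constrained fit starts from explicit versions of these evasion
  configurations in addition to the free optimum.
- **Label-swap inits**: when one dataset's weakly positive sites are
  absorbed by its fitted *neutral* class (its nominal "positive" slot
  capturing a different minor class), weight ties must be evaluated in
  the swapped labeling — positive slot holding the large near-neutral
  class at the tied weight. Without these starts, weight-tied nulls can
  be falsely rejected with large statistics even when true.
- **Free-fit re-polish**: if any constrained fit beats the free fit, the
  free model is re-optimized from the constrained optimum, so reported
  LRT statistics are never negative beyond optimizer tolerance.

## Empirical-Bayes and MCMC site inference

`site_class_posteriors` gives P(class | site) ∝ class weight × site
likelihood for any fitted mixture. `bayes.SitePosteriorSet` runs a
vectorized random-walk Metropolis sampler in log ω over all sites of a
dataset simultaneously (reflecting bounds via rejection outside the
support). `omega_ratio_test` resamples two independent site posteriors
into ratio draws ω₁/ω₂ and reports the geometric mean and 95% highest
posterior density interval; a site is differential when the HPD excludes
1, optionally screened by P(ω > 1) ≥ 0.95 in at least one dataset
(`call_differential_sites`). Chain defaults are 500,000 generations
(thin 100, burn-in 50,000); `ChainConfig.fast()` scales these down for
simulation studies, with Gelman–Rubin diagnostics available.

## Clade partition models

`clades.fit_clade_model` compartmentalizes a phylogeny into background
branches, a designated monophyletic clade and its stem branch, and fits
five nested ways of tying ω across compartments (HKY85 nucleotide level,
branch lengths frozen at the dataset fit). Models are compared by LRTs
against the single-ratio model and by AIC = 2k − 2 lnL where k counts
free ω parameters.

One shared **branch-scale nuisance parameter** is co-estimated with the
compartment ω's: the input branch lengths come from a single-ω fit whose
compromise scale otherwise biases compartment rates (background ω's pulled
low, inflating support for over-parameterized models). The scale is
identified by synonymous divergence and is common to all five models, so
AIC differences remain driven by the ω structure. Profile-likelihood
confidence intervals are computed by bisection on the re-optimized
likelihood (χ²₁-based drop), warm-started from the MLE.

## Diversity and divergence regression

`pairwise_pi` implements Nei–Gojobori (1986) counting: synonymous and
non-synonymous sites per codon with pathway averaging, pairwise
differences classified the same way, and π as mean differences per site
(uncorrected by default; Jukes–Cantor correction optional). With the deep
divergences typical of S-allele samples, raw π saturates, which is why
calibration targets below are stated in raw π.

`terminal_branch_rates` re-optimizes each terminal branch's (α, β) with
everything else fixed and converts to per-site dN and dS.
`dnds_regression` contrasts two groups of terminal-branch (dS, dN) points
by OLS: per-group slope/intercept with standard errors, a quadratic
curvature check, and the group × dS interaction as the test for different
slopes.

## Synthetic data generator

`simulate_alignment` evolves sense-codon states down a tree with per-site
(dS, dN) multipliers drawn from a `SiteOmegaSpec`; because the state space
holds only sense codons, no stop-rejection is needed. All randomness flows
from explicit PCG64 seeds; outputs are deterministic given a config.

### Allelic genealogies

`simulate_tree(shape="allelic")` emulates genealogies maintained by
long-term balancing selection: `n_lineages` long stems (jittered ±15%)
joined by a short basal radiation, each stem carrying a shallow
re-diversified coalescent subtree (15% of the stem length). Most leaf
pairs are therefore separated by two long stems, making pairwise
divergences nearly uniform — the hallmark of trans-specifically maintained
allele samples, where within-species diversity is as deep as genus-wide
diversity. At a fixed mean pairwise divergence such star-like trees carry
several-fold more total branch length than a Kingman coalescent, which is
exactly the extra information real allele samples provide to per-site and
mixture methods; using coalescent shapes here badly understates achievable
power.

### Reference scenario

`make_differential_scenario` builds the two-dataset contrast: dataset 1
(48 taxa by default) drawn from a fitted Physalis-like rate mixture whose
positive class has ω ≈ 2.66 with weight 0.46; dataset 2 (49 taxa) from a
Solanum-like mixture with positive ω ≈ 1.14 and weight 0.35. Tree depths
are calibrated so that raw NG86 synonymous diversity lands near 0.33
(set 1) and 0.48 (set 2) at the default sample sizes — with the allelic
shape this corresponds to mean pairwise paths of 1.08 and 2.05 expected
neutral substitutions per codon. `share_proportions=True` ties the
positive-class weight across the two generating mixtures (at the midpoint
of the defaults) while leaving strengths different, giving a scenario
where only the strength hypothesis is false. Truth tables record each
site's generating class and rates and which sites are truly differential.

`simulate_branch_class_alignment` evolves alignments with branch-
compartment-specific ω on a tagged tree (for the clade models), and
`fel_template_rates` produces the neutral-plus-purifying per-site
templates used in FEL calibration studies.

## Numerical choices

- Per-site grids/splines are logarithmic in the rates; interpolation
  error is validated against exact recomputation in the tests.
- Mixture, site-class and clade-model fits use L-BFGS-B on bounded,
  smoothly reparameterized (log/logit) coordinates; profile-likelihood
  bisection chains warm starts from the previous step's solution.
- All LRT statistics are clipped at 0; a negative statistic beyond
  tolerance raises a convergence warning rather than being silently
  swallowed.
- Integer seeds are kept below 2³¹ for portability; seed trees are
  derived with `numpy.random.SeedSequence`.

## Limitations

- Two-stage estimation (branch lengths frozen at the global fit) ignores
  uncertainty in the scaffold; per-site intervals are conditional on it.
- The REL mixture fixes four classes with structural roles; data
  generated by qualitatively different regimes (e.g. two distinct
  positive classes) are projected onto this shape.
- χ² reference distributions are asymptotic; weight parameters near
  boundaries make the 1-df tests mildly conservative, which the
  simulation calibrations quantify.
- The HPD ratio test assumes the two datasets' posteriors are
  independent, which holds by construction here but would not for
  overlapping samples.
- No indel or recombination simulation; alignments are assumed correct
  and recombination-free.
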