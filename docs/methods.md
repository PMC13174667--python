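# Methods

## The estimation problem

CpG dinucleotides mutate by C>T transition at rates an order of magnitude
above the genomic background, driven largely by deamination of
5-methylcytosine. The rate varies with the bases flanking the CpG, and the
flanking-sequence effect itself differs between methylated and unmethylated
cytosines. `cpgmut` estimates, from polymorphism presence/absence data, the
*sample-scaled mutation rate* muT — the per-generation rate mu times the
total branch length T of the coalescent tree connecting the sampled
genomes — separately for unmethylated and methylated CpGs in every k-mer
sequence context.

Each CpG dinucleotide contributes two analysis units: the forward-strand C
and the cytosine paired with the forward-strand G, each read in its own
strand's context (the two contexts are reverse complements of one another).
Both records share the coordinate of the forward-strand C plus a strand
flag, which keeps the two halves of one dinucleotide joinable for the
asymmetry analysis.

## Model

For cytosine *i* in context *c* with methylation fraction m_i in [0, 1],
the scaled rate is linear in methylation with context-specific intercept
and slope:

    muT_i = alphaT_c + betaT_c * m_i

At sample sizes where recurrent mutation is common, the probability that a
site is observed polymorphic is not proportional to its rate but saturates
as

    p_i = 1 - exp(-muT_i)

Polymorphism state y_i in {0, 1} is a Bernoulli draw with success
probability p_i. This is a binomial GLM with the non-canonical link

    eta = link(p) = log(1 - p),    p = 1 - e^eta,    dp/deta = -e^eta

under which the linear predictor is eta_i = -muT_i, so every muT estimate
and its confidence interval are linear functions of the coefficients. T is
assumed constant across sites; it is not separately identifiable from mu
and is only an explicit quantity inside the simulator (which draws with the
product muT directly).

### Model specifications

All models share one structure: an intercept, treatment-coded dummies for
one or more categorical context factors and — unless methylation terms are
disabled — a methylation main effect plus factor-by-methylation
interactions, giving every factor both a baseline and a slope effect.

| name                    | factors           | parameters |
|-------------------------|-------------------|-----------:|
| `4mer`                  | full 4-mer        | 32         |
| `up1_down1`             | U1, D1            | 14         |
| `6mer`                  | full 6-mer        | 512        |
| `up21_down12`           | U21, D12 dimers   | 62         |
| `additive_positions`    | U2, U1, D1, D2    | 26         |
| `context_only_4mer`     | full 4-mer, no m  | 16         |
| `context_only_up1_down1`| U1, D1, no m      | 7          |

U/D factors are single flank bases (or dimers) extracted from the context
string; a single k-mer factor crossed with m is equivalent to a free
(intercept, slope) pair per context. The `context_only_*` variants drop
every methylation term, for taxa with negligible DNA methylation. The
chains `up1_down1 < 4mer < 6mer` and `additive_positions < up21_down12 <
6mer` are nested, so residual deviance is non-increasing along them — a
property the tests verify on simulated data.

Reference levels are the lexicographically first level of each factor;
predictions are coding-invariant (tested by relabeling).

## Fitting

The exact Bernoulli log-likelihood is maximized by Fisher scoring with
step-halving. Per observation, l_i = y_i log p_i + (1 - y_i) eta_i; the
second derivative in eta is -y_i e^eta / p^2 <= 0, so the likelihood is
concave in the coefficients and any interior optimum is global. Iteration
weights use the expected information, (1 - p)/p, which is positive for
every row; convergence is declared when the relative log-likelihood change
falls below 1e-10 (at most 100 iterations).

The valid region {eta < 0} is open and the starting point (the
intercept-only closed form -log(1 - mean(y)) with zero context effects) is
interior, so the line search halves any step that would leave the region;
only if no feasible improving step exists is a clipped evaluation accepted
(probabilities clipped to [1e-12, 1 - 1e-12]) and the fit flagged via its
clipped-observation count. Under the default study conditions fits are
interior and unclipped.

Reported coefficient covariance is the inverse *observed* information at
the MLE, Sigma = (X' W X)^-1 with W_ii = y_i (1 - p_i)/p_i^2 — only
polymorphic rows carry curvature. Observed and expected information agree
in expectation; at the simulation sizes used here the resulting Wald
standard errors differ from expected-information ones by a few percent and
give 95% intervals with empirical coverage within [93%, 97%] (verified
over 200 replicate fits in the acceptance checks). Intervals are normal
approximations on the eta scale — muT is linear in the coefficients — with
no profile likelihood.

Model comparison uses AIC = 2p - 2 logL, BIC = p log n - 2 logL, and the
proportion of deviance explained (D_null - D_resid)/D_null, where the null
model is the intercept-only fit with the same link (its MLE has the closed
form above, so the null deviance is computed exactly rather than by
iteration).

Design matrices are assembled sparse (2-10 nonzeros per row), which keeps
the 512-column 6-mer fit cheap; the normal equations are solved densely at
p x p.

## Data preparation

* **Coordinates** are 0-based half-open everywhere internally; VCF
  positions are converted on read, BED is native.
* **Masking**: only uppercase A/C/G/T is analyzable. N and lowercase
  (soft-masked) bases can neither be part of the CpG dimer nor of a context
  window; a window that leaves the sequence or touches a masked base yields
  a missing context, never a clipped k-mer.
* **Regions**: the analyzable genome is include-BED minus exclude-BEDs
  (e.g. genic and conserved regions), with interval subtract/intersect
  verified against per-base brute force. Both bases of the CG dimer must
  lie inside; flank bases need only be unmasked.
* **Overlapping CGs** ("CGCG") each emit their own strand pair.
* **Methylation** is pooled across samples per site — sum of methylated
  reads over sum of total reads — which dampens the downward bias that C/T
  genotypes introduce into per-individual bisulfite calls. Sites with
  pooled coverage below `min_coverage` (default 5 reads) are dropped. The
  pooled value is CpG-level by default (applied to both strand records,
  matching per-CpG WGBS reporting); strand-resolved joining is available.
* **Polarization** is by minor allele frequency: the major allele is
  ancestral, the minor derived. An exact tie (AC = AN/2) is unpolarizable
  and the affected strand record is excluded entirely. Singletons
  (minor-allele count 1, covering AC = 1 and AC = AN - 1) may be kept,
  dropped, or dropped unless inside a user-supplied mappability region set.
* **Outcome**: y = 1 iff a polarized C>T event sits at the focal cytosine
  on its strand (a forward-strand G>A is a reverse-strand C>T). A non-C>T
  variant at the focal position leaves y = 0 by default, since the outcome
  is presence of a C>T polymorphism; `drop_nonancestral_cpg` instead
  removes sites whose inferred ancestral base is not the expected C/G
  (ancestrally not a CpG). Variants at positions never extracted as CpG
  cytosines are ignored with a counted warning.

## Post-fit analyses

* **Concordance** between two estimate sets (different models, strata or
  datasets) is the Pearson correlation of point estimates over shared
  (context, state) cells, per methylation state — unweighted, since the
  comparison is of the estimates themselves.
* **Asymmetry**: for each non-palindromic reverse-complement 4-mer pair,
  delta = muT_a - muT_b with se = sqrt(se_a^2 + se_b^2) (independent-errors
  propagation; the two estimates come from disjoint site sets, so their
  cross-covariance in a joint fit is negligible though not exactly zero),
  a two-sided normal z-test, and optional Bonferroni adjustment over the
  6 pairs x 2 states family. Both raw and adjusted p are emitted.
* **Methylation bins**: 20 equal-width bins on [0, 1], last bin closed,
  with Wilson 95% intervals — chosen over Wald for sane behaviour at rates
  near 0 and 1. Empty bins are emitted with n = 0 and an undefined rate.
* **Stratified refits** accept any per-site label (e.g. recombination-rate
  bins at cutpoints like 0.389 / 0.026 / 4.877e-05) and report per-stratum
  fits plus concordance against the pooled fit, flagging strata that lack
  context levels present overall.

## Synthetic data

The simulator draws from the model's own generative direction. Defaults
are the study conditions used throughout the tests: per-context alphaT
uniform on [0.01, 0.05] and betaT on [0.2, 0.6], putting p in roughly
0.01-0.4 — the regime where the saturation correction matters; methylation
from the mixture 0.45 Beta(0.6, 8) + 0.55 Beta(8, 0.6), a bimodal
landscape with a dominant near-1 mode mimicking sperm WGBS; 20,000 sites
per context; one global integer seed driving all randomness. Variants:
binary methylation (for exact stratum closed forms), zeroed slopes (null
checks), strand-symmetric truth (asymmetry calibration), and additive
flank-effect truth whose effect ranges reproduce the same alphaT/betaT
span (concordance checks).

A byte-level fixture generator emits a mutually consistent
FASTA + include/exclude BED + VCF + methylation TSV bundle together with
the expected annotated site table computed by an independent character-scan
enumeration, so end-to-end tests compare the pipeline against an oracle
that shares none of its code.

What the simulator does **not** emulate: genealogical heterogeneity in T
(the model's own constant-T assumption is built into the draws), linkage
between neighbouring sites, allele-frequency information beyond
presence/absence, methylation measurement error and genotype-driven
bisulfite bias, selection, and gBGC. Passing recovery and calibration
tests therefore show the estimator inverts its assumed generative model
correctly at realistic sizes — not that real-genome violations of these
assumptions are harmless.

## Numerical and design choices

* Newton/Fisher scoring on the exact likelihood rather than packaged IRLS;
  at convergence they coincide, which a statsmodels fit with the same link
  confirms to ~1e-6 per coefficient in the tests.
* Grid-search maximum likelihood (coordinate-wise refinement) serves as a
  second, derivative-free oracle for small models.
* The link round trip p -> eta -> p is evaluated with expm1/log1p; the
  reverse composition eta -> p -> eta is exact to 1e-12 for |eta| <= 8 and
  degrades like eps * e^|eta| beyond, an inherent float64 limit of
  representing p near 1.
* Deterministic tie-breaks: lexicographic context enumeration, reference
  levels, and pair ordering (smaller member first).
* Degenerate inputs: empty FASTA/BED give empty collections; an all-zero
  (or all-one) outcome makes the null model saturated and the fit is
  flagged rather than silently accepted; prediction at unseen factor
  levels raises naming the level; methylation states other than {0, 1} are
  refused (extrapolation in m is out of contract).

## Problem sizes

Test and validation runs use 16 contexts x 20,000 sites for recovery and
coverage (200 replicates), 16 x 10,000 for asymmetry calibration (50
replicates, 600 pair-tests), 256 6-mer contexts x 400 sites for nesting,
and 16 x 100,000 for cross-model concordance. These sizes give the
stochastic checks comfortable margins (e.g. binomial SE of the coverage
estimate ~0.3 percentage points over 6,400 cells) while a full validation
pass completes in minutes on one core.

## Known limitations

* Constant T across sites: heterogeneity in genealogy depth biases
  absolute muT and, mildly, comparisons between contexts; rank orders are
  robust when rate differences are large.
* MAF polarization misassigns ancestry for a small fraction of variants
  (more often at high derived-allele frequencies); the package takes AC/AN
  as given and offers no outgroup-based polarization.
* Observed-information standard errors require polymorphic sites in every
  estimable cell; extremely sparse contexts can make the information
  matrix ill-conditioned, in which case the fit falls back to a
  pseudo-inverse and is flagged as unconverged.
* Multiallelic sites are excluded rather than decomposed.
* No overdispersion/quasi-likelihood layer: the Bernoulli variance is
  assumed exact.
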