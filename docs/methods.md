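# Methods

This note documents the models behind `dupfit`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical decisions a maintainer would want written down.

## Competition model and estimation

The assay competes a red- against a green-labelled strain under serial
dilution. With `R` the red frequency and `G = 1 − R`, deterministic
logistic competition `dR/dt = sRG` gives

    logit R(t) = logit R(0) + s·t,

so *s* is the per-generation change in the log-odds of sampling a red
cell. Counts are modelled binomially at each assayed generation; the
likelihood is a binomial logistic regression of red fraction on
generation. Drift, mutation during the assay, recombination and
non-transitive interactions are all ignored — defensible because the assay
spans ~40 generations, orders of magnitude less than the effective
population size, and the implementation inherits those assumptions.

Estimators:

* `estimate_s_closed_form` — the two-timepoint formula
  `s = [log(r₂/g₂) − log(r₁/g₁)]/(t₂−t₁)`, which is the exact MLE at two
  timepoints. `R0_hat` back-extrapolates the fitted log-odds line to
  generation 0. The reported standard error is the delta-method value
  `sqrt(1/r₁+1/g₁+1/r₂+1/g₂)/(t₂−t₁)`; it is informational only.
* `estimate_s_mle` — joint Newton/IRLS maximization of `(R0, s)` with the
  exact Fisher information, step-halving, convergence when the
  log-likelihood changes by < 1e-10 (200 iterations max). Non-convergence
  is flagged on the estimate, never silently ignored. At two timepoints it
  agrees with the closed form to ≤ 1e-8 (enforced by tests); the
  `statsmodels` binomial GLM serves as an independent cross-check in the
  test suite, not as the implementation.

Censoring, in order of precedence: a total count below 50 at any
timepoint ⇒ `equally_lethal`, s = 0; otherwise any single channel below 50
at any timepoint ⇒ `censored_low`, reported at the ±0.3 bound with the
sign against the depleted channel. The per-channel floor applies at every
assayed timepoint, not only the last, because strongly deleterious strains
can already be undetectable at generation 20. No estimator ever runs on a
zero count.

The detection limit solves `R(t_final) = 1/50000` for *s* by bisection
(|Δs| < 1e-6) from an even start; at `t_final = 40` this gives
s = −0.2705. The −0.3 figure used throughout as the censoring bound is a
rounded convention, and the two are deliberately kept distinct: the
package reports the computed root and uses 0.3 only for censoring.

Assay resolution is `1.96 × SD` of null-competition estimates (sample SD,
n−1 denominator). Effect calls require two fluorophore-swapped replicates:
deleterious/beneficial iff both exceed |s| ≥ 0.005 with the same sign,
inconsistent when signs disagree and either exceeds the threshold, and a
censored replicate forces the call in its direction. The 0.005 threshold
is deliberately wider than the measured resolution (~0.0033) to absorb
day-to-day variation.

Effective population size uses the harmonic mean over one growth cycle:
with bottleneck `N_b = density·volume/dilution` and `g = log2(dilution)`
doublings, `Ne = g / Σ_{i<g} 1/(N_b·2^i)`. The harmonic mean (rather than
bottleneck × generations) is the standard choice for fluctuating census
size; with a conservative 2×10⁸ cells/mL at saturation, a 0.32 mL culture
and 1024-fold dilution it gives ~3.1×10⁵. The exact culture volume behind
any particular reported figure is not recoverable, so this is a
documented formula choice, not a reproduction.

## Synthetic competition data

`simulate_competition` draws one Gaussian perturbation ε ~ N(0, bio_sd)
of *s* per well — not per timepoint — because replicate scatter in this
design is dominated by well-level effects (growth conditions, non-shared
background SNPs), then samples binomial counts on the logistic trajectory
at 50,000 cells per timepoint, generations 20 and 40. `calibrated_bio_sd`
sets the well-level SD so that the *fitted* null-screen SD equals 0.0017:
bio_sd² = 0.0017² − sampling variance of the estimator (delta method at
s = 0). Screens are the full 8×8 cross-product (64 wells; 16
contamination-control wells are carried as a count only, since their
content is a design detail the analyses never consume); relative fitness
composes additively on the *s* scale (`s_well = s_red − s_green`), and the
diagonal competes fluorophore-swapped copies of the same genotype, so its
true *s* is 0 by construction. The matrix convention everywhere is
`M[red, green] = s` of the row (red) genotype relative to the column
genotype.

What the generator does **not** emulate: raw cytometry events, gating,
doublets, drift through dilution bottlenecks, mutation during the assay,
or non-transitive fitness interactions. Passing tests therefore show the
estimators and the clustering behave correctly under the model's own
assumptions — they do not validate gating pipelines or detect epistasis.

## Genotype landscape

Alleles carry a subset of eight functional elements, a promoter and a
provenance; alleles declared as extant paralogs are validated against the
known layout (extant Bub1 lacks the first KEN box and carries the kinase
domain; extant Mad3 carries both KEN boxes and no kinase). Edges connect
genotypes that differ by exactly one event:

* **duplication** — the empty locus receives a copy of the occupied
  allele, under the target locus's promoter (encoding the convention that
  promoter change accompanies the duplication; promoter-change events are
  otherwise excluded from the edge relation, as promoter evolution is
  untested);
* **element_loss** — one allele loses exactly one element;
* **gene_loss** — one locus is emptied.

No edge adds an element, and losing a still-identical duplicate (which
would exactly undo the duplication) is excluded as a reversion; together
these make the landscape a DAG, so path enumeration by depth-first search
is exhaustive and terminates. A node with no outgoing edges counts as
vacuously absorbing — the convention matters only for sink genotypes, and
the absorbing claim of interest concerns the extant pair, which has
explicit deleterious exits.

`dupfit.presets` ships a *reconstruction* of the assayed genotype set
(no curated table of the compositions exists): single-copy ancestor,
fresh duplicate, a stepwise degeneration series to the extant-like pair,
and the two single-gene exits. Its synthetic fitness truth keys on the two
pathway functions the assay detects: losing all kinase domains is strongly
deleterious (−0.35, beyond the censoring bound), losing all first KEN
boxes mildly so (−0.015), everything else wild-type-like (0).

### Clustering

`cluster_fitness_classes` computes pairwise-complete Euclidean distances
between matrix rows, rescaled by `sqrt(p/p_observed)` so rows with missing
wells remain comparable, then average-linkage agglomeration
(`scipy.cluster.hierarchy`). Rows are sorted lexicographically first, so
equal-distance ties break deterministically and the partition is invariant
to input order; it is also invariant to adding a constant to all observed
entries. Flat classes count every *separating* merge — height above
`sep_factor` (default 3) times the median merge height — and cut just
below the smallest of them, capped at 6 classes. A single largest-gap cut
was considered and rejected: fitness plateaus sit at very different depths
(−0.015 vs −0.3), so the one biggest gap always isolates only the lethal
class and merges the mild one into wild type; counting all clear jumps
recovers every plateau that stands out of the noise floor. An all-equal
matrix yields one class. Censored estimates enter the matrix at the −0.3
bound (they are not numeric measurements, but the bound is exactly what
the heat map displays).

### Edge classification

Each edge needs ≥ 2 replicate contrasts of child vs parent. Direct
competitions are used when present (the swapped-fluorophore well enters
with its sign flipped); otherwise the contrast is composed through a
reference genotype: `s_child,parent = s_child,ref − s_parent,ref`,
replicate by replicate. Composition with one censored leg propagates the
censoring direction; with both legs censored the contrast is not
estimable and the edge is labelled `unknown` — never silently neutral.
Neutral-path enumeration refuses to treat unknown edges as safe: they are
traversed but mark the whole path indeterminate, and `is_absorbing`
raises on unclassified exits.

## Constraint scan

The emission model is a reversible amino-acid process: symmetric
exchangeabilities × stationary frequencies, normalized to one expected
substitution per unit branch length, exponentiated exactly through the
symmetrized eigendecomposition. The default is an equal-exchangeability
(Poisson-type) model with uniform frequencies; empirical matrices (WAG,
LG, …) load from PAML-dialect files (19 lower-triangle rows + one
frequency line; `data/equal_rates.paml` documents the dialect). For the
synthetic analyses here the default is also the generative model, so no
model misspecification is introduced; for real alignments an empirical
matrix should be supplied. Branch lengths are taken as given on the input
tree and never re-estimated.

Column likelihoods use Felsenstein pruning vectorized over columns, with
gaps as missing data (partial-likelihood vector of ones). The two-state
HMM multiplies every branch by ρ_c < 1 in the conserved state and 1 in the
background state. Forward–backward is implemented in scaled space and in
log space; the two must agree to 1e-8 (tested). Decoding thresholds the
conserved posterior at 0.5 with a minimum run of 3 columns — posterior
thresholding rather than Viterbi, to keep sensitivity for short motifs.
When HMM parameters are not supplied they are fitted by Baum–Welch with
10 jittered restarts (initial ρ_c = 0.2, self-transition 0.95); all HMM
hyper-parameters are package decisions, as the upstream method is not
fully specified anywhere reproducible.

The relaxation test compares one rate shared by all branches against
separate rates inside and outside a flagged clade (newick internal-node
label starting with `DUP`; the stem branch counts as inside). Rates are
optimized by golden section on [1e-4, 10] (tolerance 1e-6; per-coordinate
descent for the two-rate model, started at the one-rate optimum so
lnL₂ ≥ lnL₁ holds by construction). `2ΔlnL` is referred to χ²(1);
direction is "relaxed" when the in-clade rate exceeds the out-of-clade
rate. An optimizer pinned at the upper rate bound is flagged. With two
paralog clades the out-of-clade rate for one test includes the other
paralog's branches; this matches the pre/post-duplication contrast when
the tested clade is the only rate-shifted lineage and is the documented
approximation otherwise. Benjamini–Hochberg runs across all region×clade
tests (the correction method upstream is unstated; BH is the package's
choice for a discovery-style scan). Regions entirely gapped in a paralog
are flagged unalignable for that clade and skipped in its tests.

Coordinates are 0-based half-open alignment columns everywhere; the
pre-to-full column map is built from the shared rows' ungapped residues
and validated for consistency across rows.

## Count statistics

Fisher's exact test enumerates the hypergeometric support in log space and
sums every table whose probability is at most the observed one (relative
tolerance 1e-7) — the probability-mass two-sided rule, which is the
dominant convention but not the only one, hence documented. The all-zero
table returns p = 1 by convention. Sectoring comparisons use the raw
sectored-vs-white denominators, starred at p < 0.001. Localization
fractions use percentile bootstrap (≥ 1000 resamples, seeded); cells
scored as showing both localizations contribute to both marginal
fractions. Pairwise localization tests are Holm–Bonferroni corrected at
0.05 — the correction method is a package decision where the upstream
choice is unstated.

## Problem sizes and determinism

The synthetic rerun (`study_rerun`, driven by `scripts/acceptance.py`)
uses: one 64-well null screen for the resolution estimate; 100 simulated
screens for class recovery; 1000 wells per effect size for estimator
calibration; and 1000 simulated 30-column regions on an 8-taxon tree for
the null LRT calibration — sizes chosen so Monte-Carlo error is small
relative to the tolerances being checked while the whole rerun stays at a
few minutes on one CPU. Decode-recovery tests use 4-taxon trees of
root-to-tip depth ~1 substitution/site, where a 30-column conserved region
is comfortably identifiable; at half that depth boundary placement is
information-limited and accuracy degrades, which is a property of the
data, not the decoder. Every stochastic operation takes an explicit seed
and is reproducible byte-for-byte; the pipeline manifest records seeds and
input digests.

## Known limitations

* The landscape covers the genotypes it is given; absorption is relative
  to that set, and no inference is made about which path evolution took.
* Fitness composition assumes transitivity on the *s* scale; epistasis
  between loci beyond the encoded truth classes is not modelled.
* The constraint scan is protein-level (no codon models, no dN/dS) and
  requires pre-aligned input; alignment uncertainty is not propagated.
* Bootstrap CIs are percentile intervals; for fractions at 0 or 1 they
  collapse to a point, as percentile intervals do.
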