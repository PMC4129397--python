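# Methods

## Problem and observation model

A gene-content haplotype over L clustered loci is a binary vector
(1 = gene present on that chromosome, 0 = absent).  An individual carries
an unordered pair of such haplotypes (a diplotype).  Locus-specific
genotyping censors the copy number: the observed code per locus is
`ABSENT` (true genotype (0,0)), `PRESENT` ((1,?): at least one copy, the
second chromosome unknown) or `MISSING` ((?,?)).  A second "full" dialect
records exact copy numbers 0/1/2 and is used for no-missing-data
experiments.  The two dialects are never mixed within a dataset; the
`FULL(1)`/`FULL(2)` codes down-convert to `PRESENT` and that conversion
commutes with observing a diplotype.

## The diploid mosaic HMM

Each chromosome is modeled as an imperfect mosaic of H reference
haplotypes with multiplicity weights w (total W).  The hidden diploid
state at locus l is the ordered template pair S_l = (x_l, y_l) and the
joint likelihood factorizes as
`Pr(S_1) Π Pr(S_l | S_{l−1}) Π Pr(G_l | S_l)`.

This package adopts the standard mosaic-model choices for the three
probability functions and documents them explicitly:

* **Initial state**: Pr(S_1 = (x,y)) ∝ w_x · w_y.
* **Transition** per chromosome across interval l: stay with probability
  (1−θ_l) plus a switch term; a switch lands on template k — *including
  the current one* — with probability θ_l · w_k / W.  The diploid kernel
  is the product of the two chromosome kernels, and the forward update
  uses its rank-1 (row/column-sum) structure so one locus costs O(H²),
  never O(H⁴).
* **Emission**: each chromosome emits its template allele with
  probability 1−ε and flips it with probability ε (a symmetric error
  absorbing gene conversion, mutation and genotyping error); the two
  chromosomes emit independently.  An observed code's emission sums over
  the compatible ordered emitted pairs: `ABSENT` → both emit 0,
  `PRESENT` → the complement, `MISSING` → 1, `FULL(g)` → ordered pairs
  with copy sum g.

Forward filtering renormalizes per locus and stores both the predictive
and filtering distributions plus the normalization constants.  An
all-zero layer (possible only at ε = 0) raises an explicit infeasibility
error; no silent renormalization of zero vectors ever occurs.

**Backward sampling** draws, locus by locus from L down to 1, a diploid
state and an ordered imputed-allele pair jointly from the exact posterior
of the unconstrained model.  Imputed alleles are always conditioned on
the observed code (an `ABSENT` locus imputes (0,0) with probability 1; a
`PRESENT` locus never imputes (0,0)).

## Pattern constraints

Three deterministic constraint types are supported: anchor (framework)
loci present on every haplotype; always-together pairs (equal alleles on
the same chromosome thread — a haplotype-level, not genotype-level,
constraint); mutually exclusive pairs, enforced as *exactly one present*
(XOR) because such pairs behave as allelic variants of a single ancestral
locus and the bundled panel's exclusive column pairs are exact
complements.

During backward sampling each candidate (state, allele pair) is
re-weighted by the compatibility of the implied allele suffix: 1−β if
every pattern wholly contained in loci l..L is satisfied on both threads,
β otherwise.  β = 0 (default) is the hard constraint.  A pattern pair is
checked when sampling reaches its lower locus; once a sampled choice
violates a pattern the factor becomes constant and later checks are
skipped, which matches the literal suffix-conditional probability.  The
forward table is pattern-agnostic: re-weighting only at sampling time
keeps the sampler exact for the unconstrained model and a correctly
normalized per-step conditional sampler for the constrained one.

A naive suffix sampler can dead-end at β = 0 even for individuals that do
have compatible pairs: it commits at the upper locus of a pattern pair
before seeing the observation at the lower one.  The sampler therefore
pre-computes, once per individual, arc-consistent per-locus masks of
admissible ordered allele pairs — the observation-admissible candidates,
pruned by anchors and propagated through every together/exclusive pair to
a fixed point.  Sampling from these masks is backtrack-free for any
individual that has a compatible pair at all, so under β = 0 every
sampled and every consensus haplotype satisfies all patterns.  An
individual whose masks collapse to empty (no compatible pair exists, the
known drawback of hard constraints) is logged and sampled with β = 1e-6
from the raw observation masks, the escape hatch that can also reveal
novel haplotypes.  A bounded redraw plus the same soft fallback remains
for the ε = 0 corner case, where a zero emission can still annul the only
admissible candidate.

## Gibbs sampling, panels, consensus

Sampling sweeps over individuals for `iterations` sweeps (default 50,
burn-in 10).  Each individual's panel collapses the external identified
haplotypes (weight 1 each, constant across sweeps) with the internal
haplotypes of all *other* individuals taken at the start of the sweep
(Jacobi-style update).  Using start-of-sweep states makes results
invariant to individual order: random substreams are keyed by a stable
individual id through a counter-based seed table derived from the single
master seed, so permuting the input rows permutes the output bitwise.

Initialization prefers a pair of external references that reproduces the
observation and satisfies the patterns; otherwise it builds a random
observation-compatible pair honoring the patterns (suffix-ordered fill
with restarts), falling back to an unconstrained observation-compatible
pair with a warning for individuals with no pattern-compatible
completion.

The consensus diplotype is the modal unordered pair over post-burn-in
sweeps (ties broken deterministically toward the lexicographically
smallest pair) with its support fraction reported.  Haplotype frequencies
are estimated from the final sweep's 2N haplotypes (for n = 100, exactly
200 haplotypes); individuals that remain infeasible even after the β
fallback are flagged and excluded from the frequency estimate.

### Switch and error rates

θ (per-interval switch rate) and ε (per-allele error rate) start at 0.01
and are, by default, re-estimated after every sweep from the sampled
paths: θ̂ = (template switches) / 2N(L−1), ε̂ = (imputed-allele
mismatches against the template) / 2NL, clipped to [1e-6, 1] and
[1e-6, 0.499].  Under the package's study conditions the data support
θ ≈ 0.005 and ε ≈ 0.003; keeping both fixed at 0.01 injects excess mosaic
noise into the final sweep, inflating spurious haplotypes (measured at
the original distribution, n = 100: haplotype-identification index 0.66
fixed vs 0.80 re-estimated, with frequency recovery improving
correspondingly).  Since the mosaic model's rates are fitted quantities
in the tradition this package follows, re-estimation is the default;
`reestimate_rates=False` (CLI `--fixed-rates`) restores constant rates.
The counting estimator ignores unobservable same-template switches, so
θ̂ is a slight underestimate; this bias is immaterial at these rates.

## Synthetic data generator

The generator defines the study conditions and emulates:

* the bundled 17-haplotype / 14-locus panel with printed frequencies
  (sum 0.998, used as given — sampling normalizes implicitly).  Locus
  names are generic (`g1..g14`) because the mapping from table columns to
  gene names is not fixed; the pattern columns are identified
  structurally (columns 1, 7, 14 all-present anchors; 2–3 identical;
  3–4 and 8–9 complementary);
* Hardy–Weinberg sampling, and departures that re-weight homozygous
  pairs by w_HOM and heterozygous pairs by w_HET with normalizer α from
  α(w_HOM F_HOM + w_HET F_HET) = 1 (w_HOM = 2, w_HET = 1 gives measurable
  excess homozygosity);
* the frequency ladder: per step, −0.05 from the major haplotype and
  +0.005 to each of the ten *originally* rarest haplotypes (both groups
  fixed from the original table; mass preserved exactly).  Nine steps
  flatten the major haplotype from 0.552 to 0.102 and the frequency
  standard deviation from 0.131 to 0.024;
* identified references (the 10 most frequent haplotypes, 95.9% of raw
  mass) and their corrupted variant: the top two references with alleles
  flipped at two loci (defaults to 1-based columns 5 and 6 — the choice
  of columns is configurable and does not affect which haplotypes are
  replaced, which is what the mass calculations depend on).  The entries
  replaced by corrupted copies carry 66% of mass originally and 21% at
  the flattest ladder step.

What the generator does **not** emulate: genotyping artifacts beyond the
symmetric error model, linkage to allelic (sequence-level) variation,
copy numbers above two, population structure, or recombination-driven
novel haplotypes.  Passing benchmarks therefore demonstrate correctness
of the inference machinery under the stated generative model, not
robustness to real-world typing artifacts.

## Evaluation statistics

Per replicate: IH = 2(K_true − K_miss)/(K_true + K_est) on exact
binary-string sets, where the true set is what the replicate's sample
actually contains and the estimated set is the support of the final-sweep
frequency table (no frequency floor; an optional threshold exists);
SAD sums |θ̂ − θ| over the union of haplotypes against the *generating*
frequencies; IE is the fraction of individuals with a wrong unordered
pair; IME is the part whose pair is incompatible with the observed codes
(a convention under which a sampler conditioned on the observations has
IME = 0; passing full-dialect observations of the truth yields the
copy-number-based variant instead); ISE = IE − IME; SE is the
per-individual Hamming distance between pairs, minimized over the two
phase alignments (the minimizing convention keeps SE ≤ IE; a fixed
canonical alignment is available via `se_alignment="fixed"`).

## Numerical and design choices

* Loci are 1-based in all user-facing I/O, 0-based internally.
* Observation codes are a closed enumeration; dialect mixing is a
  load-time error.
* Zero-weight panel entries are permitted in the compiled kernels (they
  behave as absent templates), which lets the per-sweep panel be built
  once and adjusted per individual by decrementing that individual's own
  two haplotypes.
* Consensus ties, top-k/bottom-k frequency ties and all random draws are
  deterministic given the master seed.
* The benchmark derives per-(step, replicate) streams via
  `SeedSequence(seed, spawn_key=(step, replicate))`, making cells
  independent and runs bitwise reproducible.
* Problem sizes: the bundled benchmark and the acceptance script use 100
  replicates of n = 100 per ladder step, enough to pin the mean error
  rates to well under the reporting precision; the enumeration-oracle
  checks cover L ≤ 4, H ≤ 3 exactly and 10⁵ Monte-Carlo draws for the
  sampling distribution.

## Known limitations

* The per-step constrained sampler is exact for the unconstrained model
  but only stepwise-normalized for the constrained one (no global
  renormalization over all pattern-compatible paths); this matches the
  sampling scheme it implements.
* IH/SAD depend on the final sweep only, so they inherit one sweep's
  Monte-Carlo noise by design (matching the frequency-estimation
  convention implemented here); a pooled post-burn-in estimator exists
  (`frequency_estimator="pooled"`) but is not the default.
* Copy numbers above 2 and allele-level variation within a gene are out
  of scope.
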