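# kirphase

Haplotype phasing for **present/absent gene-content data** from clustered
gene families, with the KIR region (chromosome 19q13.4) as the motivating
case.  Locus-specific KIR typing reports each gene as *present* or
*absent*; when a gene is present, the copy number (one or two) is unknown,
so the per-locus genotype is `(0,0)`, `(1,?)` or `(?,?)`.  That censoring
makes standard phasing ineffective — but decades of KIR studies have
produced known haplotypes and hard structural patterns (framework genes on
every haplotype, gene pairs in complete positive or negative LD) that can
carry the inference.

`kirphase` provides:

* a **diploid mosaic HMM** (Li–Stephens style): each chromosome is an
  imperfect mosaic of reference haplotypes, with per-interval switch rate
  θ and per-allele error rate ε; emission of an observed code sums over
  all compatible true genotypes, e.g.
  `Pr(G=(1,?) | S) = Pr(G=(1,0) | S) + Pr(G=(1,1) | S)`;
* a **Gibbs sampler** over individuals whose reference panel combines
  *external* identified haplotypes (constant across sweeps) with
  *internal* haplotypes — the current estimates for all other
  individuals;
* **pattern-constrained backward sampling**: candidate states at locus
  *l* are re-weighted by `Pr(S_l..S_L | patterns)` — `1−β` when the
  implied haplotype suffix is compatible with every anchor /
  always-together / mutually-exclusive constraint, `β` otherwise (hard
  constraint at β = 0, the default);
* a **simulator** reproducing the standard study conditions: a bundled
  17-haplotype, 14-locus frequency table, Hardy–Weinberg or
  departure-from-HWE diplotype sampling
  (`α (w_HOM F_HOM + w_HET F_HET) = 1`), a frequency-flattening ladder
  and an "incorrect reference" construction;
* the six **evaluation statistics** used in this literature:
  `IH = 2(K_true − K_miss)/(K_true + K_est)`,
  `SAD = Σ_k |θ̂_k − θ_k|`, the individual error rate `IE = IME + ISE`,
  and the Hamming-based similarity error `SE`.

## Worked example

`examples/01_phase_simulated_sample.py` simulates 100 individuals from
the bundled frequency table under HWE, reduces them to present/absent
codes, and phases them with the 10 most frequent haplotypes as external
references plus the KIR patterns:

```text
correctly phased individuals: 90 / 100
mean consensus support: 0.912
  IH = 0.957
 SAD = 0.188
  IE = 0.100
 IME = 0.000
 ISE = 0.100
  SE = 0.009
```

`IH = 0.957` says nearly every haplotype actually present in the sample
was recovered without spurious extras; `IE = 0.10` is the fraction of
individuals with a wrong consensus pair, all of it switch error
(`IME = 0` because every sampled pair is genotype-compatible by
construction); `SE = 0.009` says those wrong pairs differ from the truth
at very few alleles.  The other examples walk the frequency ladder,
run a small replicated benchmark, and contrast constrained with
unconstrained sampling.

A thin CLI wraps the same library calls:

```bash
kirphase simulate --n 100 --seed 1 --out geno.tsv
kirphase infer geno.tsv --refs src/kirphase/data/table1_haplotypes.tsv \
    --patterns src/kirphase/data/kir_patterns.yaml --seed 1 --out phased.tsv
kirphase evaluate phased.tsv geno.truth.tsv geno.tsv
kirphase benchmark --n 100 --reps 20 --step 0 --step 9 --seed 1 --out bench/
```

## Layout

| Path | Contents |
| --- | --- |
| `src/kirphase/datamodel.py` | haplotypes, diplotypes, observation codes, panels, parameters |
| `src/kirphase/patterns.py` | anchor / together / exclusive constraint logic and β-weighting |
| `src/kirphase/hmm_core.py` | emission, forward filtering, constrained backward sampling |
| `src/kirphase/_kernels.py` | numba-compiled inner loops |
| `src/kirphase/sampler.py` | Gibbs orchestration, panels, consensus, frequency estimation |
| `src/kirphase/simulator.py` | study-condition data generator and ladder constructions |
| `src/kirphase/metrics.py` | IH, SAD, IE, IME, ISE, SE |
| `src/kirphase/io.py`, `benchmark.py`, `cli.py` | file formats, replicated experiments, CLI |
| `docs/methods.md` | model, assumptions, parameter choices, limitations |
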