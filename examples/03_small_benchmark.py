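"""A small replicated benchmark across three ladder steps.

Runs 10 replicates of n=50 at ladder steps 0, 5 and 9 under HWE and prints
the mean of each evaluation statistic per step.  (The full-scale study
conditions use n=100 with 100+ replicates per step; see
scripts/acceptance.py.)
"""

from kirphase.benchmark import BenchmarkConfig, run_benchmark, summarize

config = BenchmarkConfig(n=50, replicates=10, steps=(0, 5, 9), seed=7)
df = run_benchmark(config)
print(summarize(df).round(3))
# IE and SE grow as the distribution flattens (step 9): with no dominant
# haplotype the present-absent codes leave many more pairs plausible.
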