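"""Replicated simulation-inference-evaluation experiments.

One benchmark cell fixes a frequency-ladder step and a Hardy–Weinberg
setting, simulates ``replicates`` samples of ``n`` individuals, phases each
with the HMM Gibbs sampler (optionally supplying the identified reference
haplotypes, their corrupted variant, and the pattern constraints) and
scores the six evaluation statistics against the stored truth.

Determinism: every replicate derives its simulation stream and its sampler
seed from ``SeedSequence(seed, spawn_key=(step, replicate))``, so runs with
the same configuration are bitwise reproducible and cells are independent.
"""

from __future__ import annotations

from collections.abc import Callable, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import Dialect, FrequencyTable, Haplotype, HMMParameters
from .metrics import ReplicateMetrics, evaluate_replicate
from .sampler import run_inference
from .simulator import (
    DepartureWeights,
    builtin_patterns,
    builtin_table1,
    identified_references,
    make_incorrect_references,
    modify_distribution,
    simulate_sample,
)

__all__ = ["BenchmarkConfig", "run_benchmark", "run_cell"]


@dataclass(frozen=True)
class BenchmarkConfig:
    """Study conditions for one benchmark run."""

    n: int = 100                      # individuals per replicate
    replicates: int = 100             # replicates per ladder step
    steps: tuple[int, ...] = (0,)     # frequency-ladder steps to cover
    weights: DepartureWeights = field(default_factory=DepartureWeights)
    dialect: Dialect = Dialect.PRESENT_ABSENT
    missing_rate: float = 0.0
    use_identified: bool = True       # supply the 10 identified references
    n_identified: int = 10
    use_incorrect: bool = False       # corrupt the top two references
    flip_loci: tuple[int, int] = (4, 5)
    use_patterns: bool = True
    params: HMMParameters = field(default_factory=HMMParameters)
    reestimate_rates: bool = True
    se_alignment: str = "min"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicate count must be positive")
        if self.n < 1:
            raise ValueError("sample size must be positive")
        if any(not (0 <= s <= 9) for s in self.steps):
            raise ValueError("ladder steps must lie in 0..9")


def _references(config: BenchmarkConfig, original: FrequencyTable) -> list[Haplotype]:
    """External references are fixed from the ORIGINAL distribution."""
    if not config.use_identified:
        return []
    refs = identified_references(original, config.n_identified)
    if config.use_incorrect:
        refs = make_incorrect_references(refs, flip_loci=config.flip_loci)
    return refs


def run_cell(
    config: BenchmarkConfig,
    step: int,
    progress: Callable[[int], None] | None = None,
) -> list[ReplicateMetrics]:
    """Run all replicates of one ladder step and return their metrics."""
    _, original = builtin_table1()
    freqs = modify_distribution(original, step)
    refs = _references(config, original)
    patterns = builtin_patterns() if config.use_patterns else None
    out: list[ReplicateMetrics] = []
    for rep in range(config.replicates):
        ss = np.random.SeedSequence(config.seed, spawn_key=(step, rep))
        sim_seed, hmm_seed = (int(s) for s in ss.generate_state(2, np.uint32) >> np.uint32(1))
        truth, obs = simulate_sample(
            freqs,
            config.weights,
            n=config.n,
            dialect=config.dialect,
            missing_rate=config.missing_rate,
            rng=np.random.default_rng(sim_seed),
        )
        result = run_inference(
            obs, refs, patterns, replace(config.params, seed=hmm_seed),
            reestimate_rates=config.reestimate_rates,
        )
        out.append(
            evaluate_replicate(
                truth,
                list(result.consensus),
                obs,
                freqs,
                result.frequencies,
                se_alignment=config.se_alignment,
            )
        )
        if progress is not None:
            progress(1)
    return out


def run_benchmark(
    config: BenchmarkConfig,
    progress: Callable[[int], None] | None = None,
) -> pd.DataFrame:
    """Run every requested ladder step; one row per (step, replicate)."""
    rows = []
    for step in config.steps:
        for rep, m in enumerate(run_cell(config, step, progress=progress)):
            rows.append(
                {
                    "step": step,
                    "replicate": rep,
                    "ih": m.ih,
                    "sad": m.sad,
                    "ie": m.ie,
                    "ime": m.ime,
                    "ise": m.ise,
                    "se": m.se,
                }
            )
    return pd.DataFrame(rows)


def summarize(df: pd.DataFrame) -> pd.DataFrame:
    """Mean of each statistic per ladder step."""
    return df.groupby("step")[["ih", "sad", "ie", "ime", "ise", "se"]].mean()
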