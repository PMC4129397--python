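"""Diploid mosaic HMM: emission, forward filtering, constrained sampling.

Each chromosome of an individual is modeled as an imperfect mosaic of the
reference haplotypes (Li–Stephens style).  The hidden diploid state at locus
l names the two template haplotypes; transitions reflect historical
recombination (per-interval switch rate theta), and a symmetric per-allele
error rate epsilon absorbs gene conversion, mutation and genotyping error.
Observed genotypes may be exact copy numbers, present-absent codes (copy
number censored at one), or missing; the emission of an observed code is the
sum of the emissions of all true genotypes compatible with it.

Backward sampling draws a state path and an ordered imputed-allele pair per
locus from the exact posterior of the unconstrained model; when a pattern
set is supplied each candidate is re-weighted by the compatibility of the
implied allele suffix (hard indicator at ``beta = 0``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .datamodel import (
    Code,
    DiploidState,
    Haplotype,
    HMMParameters,
    ObservedGenotype,
    PatternSet,
    WeightedReferencePanel,
)
from .patterns import allowed_pair_masks, pattern_arrays

__all__ = [
    "InfeasibleGenotypeError",
    "ConstraintInfeasibleError",
    "ForwardTable",
    "SampledPath",
    "allele_emission",
    "genotype_emission",
    "forward_pass",
    "backward_sample",
]


class InfeasibleGenotypeError(ValueError):
    """No diploid state can emit the observations (possible only at eps=0)."""


class ConstraintInfeasibleError(RuntimeError):
    """No pattern-admissible candidate exists at some locus under beta=0."""


@dataclass(frozen=True)
class ForwardTable:
    """Forward quantities over the H*H diploid state space.

    predictive
        (L, H, H) array, ``predictive[l]`` = Pr(S_l | G_1..l-1).
    filtering
        (L, H, H) array, ``filtering[l]`` = Pr(S_l | G_1..l); the locus-L
        layer is the exact posterior of the final state.
    norms
        (L,) per-locus normalization constants Pr(G_l | G_1..l-1).
    """

    predictive: np.ndarray
    filtering: np.ndarray
    norms: np.ndarray

    @property
    def n_loci(self) -> int:
        return self.predictive.shape[0]

    @property
    def n_templates(self) -> int:
        return self.predictive.shape[1]

    def log_likelihood(self) -> float:
        return float(np.log(self.norms).sum())


@dataclass(frozen=True)
class SampledPath:
    """One posterior draw: diploid states plus ordered imputed alleles."""

    states: tuple[DiploidState, ...]
    imputed_alleles: np.ndarray  # (L, 2) int8, columns = chromosome threads

    def haplotypes(self) -> tuple[Haplotype, Haplotype]:
        return (
            Haplotype.from_array(self.imputed_alleles[:, 0]),
            Haplotype.from_array(self.imputed_alleles[:, 1]),
        )


def allele_emission(template_allele: int, emitted_allele: int, epsilon: float) -> float:
    """Pr(emitted | template) under the symmetric per-allele error model."""
    return 1.0 - epsilon if template_allele == emitted_allele else epsilon


def genotype_emission(
    obs: Code,
    state: DiploidState,
    panel: WeightedReferencePanel,
    l: int,
    epsilon: float,
) -> float:
    """Pr(observed code | diploid state) at locus l.

    Sums the ordered emitted-allele pairs over all true genotypes compatible
    with the observed code: ABSENT requires both chromosomes to emit 0,
    PRESENT is its complement, MISSING is compatible with everything, and
    FULL(g) keeps the ordered pairs with copy sum g.
    """
    tx = panel.haplotypes[state.x].alleles[l]
    ty = panel.haplotypes[state.y].alleles[l]
    p0x = allele_emission(tx, 0, epsilon)
    p0y = allele_emission(ty, 0, epsilon)
    if obs in (Code.ABSENT, Code.FULL0):
        return p0x * p0y
    if obs is Code.PRESENT:
        return 1.0 - p0x * p0y
    if obs is Code.MISSING:
        return 1.0
    if obs is Code.FULL1:
        return p0x * (1.0 - p0y) + (1.0 - p0x) * p0y
    return (1.0 - p0x) * (1.0 - p0y)  # FULL2


def forward_pass(
    obs: ObservedGenotype,
    panel: WeightedReferencePanel,
    params: HMMParameters,
) -> ForwardTable:
    """Normalized forward filtering; raises if the data are infeasible."""
    if len(obs) != panel.n_loci:
        raise ValueError("observation length must match the panel")
    pre, post, norms, status = _kernels.forward(
        panel.alleles_matrix(),
        panel.weights_array(),
        obs.as_array(),
        params.theta_array(panel.n_loci),
        params.error_rate,
    )
    if status == _kernels.STATUS_INFEASIBLE:
        raise InfeasibleGenotypeError(
            "observed genotype cannot be emitted by any panel state "
            "(all-zero forward layer; only possible with error_rate = 0)"
        )
    return ForwardTable(predictive=pre, filtering=post, norms=norms)


def backward_sample(
    fwd: ForwardTable,
    obs: ObservedGenotype,
    panel: WeightedReferencePanel,
    params: HMMParameters,
    patterns: PatternSet | None = None,
    rng: np.random.Generator | None = None,
    *,
    seed: int | None = None,
) -> SampledPath:
    """Draw one constrained posterior path given a forward table.

    Randomness is controlled either by ``rng`` (one 31-bit seed is drawn
    from it) or by an explicit ``seed``; exactly one must be supplied.
    """
    if (rng is None) == (seed is None):
        raise ValueError("supply exactly one of rng or seed")
    if seed is None:
        seed = int(rng.integers(0, 2**31 - 1))
    anchors, pair_i, pair_j, pair_kind, use_pat = pattern_arrays(
        patterns, panel.n_loci
    )
    obs_arr = obs.as_array()
    if use_pat and params.pattern_relaxation == 0.0:
        allowed = allowed_pair_masks(obs_arr, patterns)
        if allowed is None:
            raise ConstraintInfeasibleError(
                "the observation admits no pattern-compatible haplotype pair"
            )
    else:
        allowed = _kernels.CODE_MASK[obs_arr]
    states, alleles, status = _kernels.backward_sample(
        panel.alleles_matrix(),
        panel.weights_array(),
        fwd.predictive,
        allowed,
        params.theta_array(panel.n_loci),
        params.error_rate,
        params.pattern_relaxation,
        anchors,
        pair_i,
        pair_j,
        pair_kind,
        use_pat,
        seed,
    )
    if status == _kernels.STATUS_CONSTRAINED:
        raise ConstraintInfeasibleError(
            "no pattern-compatible candidate at some locus with beta = 0"
        )
    return SampledPath(
        states=tuple(DiploidState(x, y) for x, y in states),
        imputed_alleles=alleles,
    )
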