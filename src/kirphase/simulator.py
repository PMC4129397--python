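"""Synthetic data generation for gene-content phasing studies.

The generator reproduces the study conditions used throughout the package's
benchmarks: diplotypes drawn from a 17-haplotype, 14-locus KIR panel with
known frequencies, either under Hardy–Weinberg equilibrium or with a
controlled departure (re-weighting homozygous vs heterozygous pairs), then
reduced to the present-absent observation dialect.  A frequency "ladder"
flattens the distribution step by step — each step moves 0.05 off the major
haplotype and adds 0.005 to each of the ten originally rarest ones — and an
"incorrect reference" construction corrupts the two most frequent
identified haplotypes by flipping their alleles at two loci.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .datamodel import (
    Code,
    Dialect,
    Diplotype,
    FrequencyTable,
    Haplotype,
    LocusPanel,
    ObservedGenotype,
    PatternSet,
    observe,
)
from .io import kir_patterns_path, read_haplotypes, read_patterns, table1_path

__all__ = [
    "DepartureWeights",
    "DistributionSummary",
    "builtin_table1",
    "builtin_patterns",
    "modify_distribution",
    "pair_distribution",
    "simulate_sample",
    "identified_references",
    "make_incorrect_references",
    "distribution_summary",
]


@dataclass(frozen=True)
class DepartureWeights:
    """Hardy–Weinberg departure parameters.

    Homozygous pairs are re-weighted by ``w_hom`` and heterozygous pairs by
    ``w_het``; the normalizer alpha restores total mass 1 via
    ``alpha * (w_hom * F_hom + w_het * F_het) = 1`` where F_hom / F_het are
    the HWE probability masses of homozygous / heterozygous pairs.  Equal
    weights recover HWE; ``w_hom > w_het`` gives excess homozygosity.
    """

    w_hom: float = 1.0
    w_het: float = 1.0

    def __post_init__(self) -> None:
        if self.w_hom <= 0 or self.w_het <= 0:
            raise ValueError("departure weights must be positive")

    def alpha(self, freqs: FrequencyTable) -> float:
        p = np.asarray(list(freqs.values()))
        p = p / p.sum()
        f_hom = float(np.sum(p**2))
        return 1.0 / (self.w_hom * f_hom + self.w_het * (1.0 - f_hom))


@dataclass(frozen=True)
class DistributionSummary:
    """Descriptors of one simulated frequency distribution."""

    sd: float                # sample standard deviation of the frequencies
    identified_pct: int      # % of total mass carried by identified haplotypes
    incorrect_pct: int       # % of total mass carried by the corrupted entries


def builtin_table1() -> tuple[LocusPanel, FrequencyTable]:
    """The bundled 17-haplotype / 14-locus panel with its frequencies.

    The printed frequencies sum to 0.998 and are used exactly as given;
    sampling normalizes implicitly.
    """
    loci, haps, table = read_haplotypes(table1_path())
    assert loci is not None and table is not None
    return loci, table


def builtin_patterns() -> PatternSet:
    """The bundled KIR pattern set (anchors {1,7,14}, together {(2,3)},
    exclusive {(3,4), (8,9)} in 1-based positions)."""
    loci, _ = builtin_table1()
    return read_patterns(kir_patterns_path(), loci=loci)


def modify_distribution(freqs: FrequencyTable, steps: int) -> FrequencyTable:
    """Flatten the distribution by ``steps`` ladder steps.

    Each step subtracts 0.05 from the most frequent haplotype and adds
    0.005 to each of the ten least frequent ones; both groups are fixed
    once from the input table (ties broken by table order), so total mass
    is preserved exactly.
    """
    if not (0 <= steps <= 9):
        raise ValueError("steps must lie in 0..9")
    items = list(freqs.items())
    if len(items) < 11:
        raise ValueError("ladder needs a table with at least 11 haplotypes")
    order_desc = sorted(range(len(items)), key=lambda i: (-items[i][1], i))
    order_asc = sorted(range(len(items)), key=lambda i: (items[i][1], i))
    top = order_desc[0]
    bottom = set(order_asc[:10])
    out = {}
    for i, (h, f) in enumerate(items):
        g = f - 0.05 * steps if i == top else f
        if i in bottom:
            g += 0.005 * steps
        if g < 0:
            raise ValueError("ladder step would drive a frequency below 0")
        out[h] = g
    return FrequencyTable(out)


def pair_distribution(
    freqs: FrequencyTable, w: DepartureWeights | None = None
) -> dict[Diplotype, float]:
    """Exact unordered-diplotype distribution under the departure model.

    P(h,h) = alpha * w_hom * p_h^2 and P(h,g) = alpha * w_het * 2 p_h p_g
    for h != g, with frequencies normalized to probabilities; the result
    sums to 1 by construction of alpha.
    """
    if w is None:
        w = DepartureWeights()
    haps = list(freqs)
    p = np.asarray([freqs[h] for h in haps])
    p = p / p.sum()
    alpha = w.alpha(freqs)
    out: dict[Diplotype, float] = {}
    for i, hi in enumerate(haps):
        for j in range(i, len(haps)):
            if i == j:
                pr = alpha * w.w_hom * p[i] * p[i]
            else:
                pr = alpha * w.w_het * 2.0 * p[i] * p[j]
            if pr > 0.0:
                out[Diplotype((hi, haps[j]))] = out.get(Diplotype((hi, haps[j])), 0.0) + pr
    return out


def simulate_sample(
    freqs: FrequencyTable,
    w: DepartureWeights | None = None,
    n: int = 100,
    dialect: Dialect = Dialect.PRESENT_ABSENT,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[list[Diplotype], list[ObservedGenotype]]:
    """Draw ``n`` individuals and their observed genotypes.

    True diplotypes are returned alongside the observations so downstream
    evaluation can score the inference against the truth.  ``missing_rate``
    independently masks each locus to MISSING (the default study conditions
    generate none: the information loss comes from the present-absent
    conversion itself).
    """
    if n < 1:
        raise ValueError("sample size must be at least 1")
    if not (0.0 <= missing_rate <= 1.0):
        raise ValueError("missing rate must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    dist = pair_distribution(freqs, w)
    pairs = list(dist)
    probs = np.asarray([dist[d] for d in pairs])
    probs = probs / probs.sum()
    draws = rng.choice(len(pairs), size=n, p=probs)
    truth = [pairs[k] for k in draws]
    observations = []
    for d in truth:
        o = observe(d, dialect)
        if missing_rate > 0.0:
            mask = rng.random(len(o)) < missing_rate
            if mask.any():
                o = ObservedGenotype(
                    tuple(
                        Code.MISSING if mask[l] else c for l, c in enumerate(o.codes)
                    ),
                    o.dialect,
                )
        observations.append(o)
    return truth, observations


def identified_references(freqs: FrequencyTable, k: int = 10) -> list[Haplotype]:
    """The ``k`` most frequent haplotypes (ties broken by table order)."""
    if k > len(freqs):
        raise ValueError("k exceeds the table size")
    return [h for h, _ in freqs.by_frequency()[:k]]


def make_incorrect_references(
    refs: Sequence[Haplotype],
    target_ranks: tuple[int, int] = (1, 2),
    flip_loci: tuple[int, int] = (4, 5),
) -> list[Haplotype]:
    """Corrupt the reference list by flipping two loci of its top members.

    ``refs`` must be ordered by descending frequency (as returned by
    :func:`identified_references`); the members at 1-based ``target_ranks``
    are replaced by copies whose alleles at the two 0-based ``flip_loci``
    are inverted.  A corrupted haplotype that coincides with an existing
    reference would not be incorrect at all and raises.
    """
    out = list(refs)
    existing = set(refs)
    for rank in target_ranks:
        if not (1 <= rank <= len(out)):
            raise ValueError(f"target rank {rank} outside the reference list")
        a = out[rank - 1].to_array()
        for l in flip_loci:
            if not (0 <= l < a.shape[0]):
                raise ValueError(f"flip locus {l} out of range")
            a[l] = 1 - a[l]
        flipped = Haplotype.from_array(a)
        if flipped in existing:
            raise ValueError("flipped haplotype coincides with an existing reference")
        out[rank - 1] = flipped
    return out


def distribution_summary(
    freqs: FrequencyTable,
    identified: Sequence[Haplotype],
    replaced: Sequence[Haplotype] = (),
) -> DistributionSummary:
    """Summarize a simulation distribution.

    ``identified`` are the reference haplotypes supplied to the phaser;
    ``replaced`` are the true haplotypes whose corrupted copies stand in
    the reference list, so their mass measures the degree of reference
    misspecification.  Percentages are of total table mass, rounded to
    whole percents; the standard deviation uses the n-1 denominator.
    """
    values = np.asarray(list(freqs.values()))
    total = values.sum()
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    ident = 100.0 * sum(freqs.get(h) for h in set(identified)) / total
    incorr = 100.0 * sum(freqs.get(h) for h in set(replaced)) / total
    return DistributionSummary(
        sd=sd,
        identified_pct=int(round(ident)),
        incorrect_pct=int(round(incorr)),
    )
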