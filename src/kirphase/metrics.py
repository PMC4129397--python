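"""Evaluation statistics for haplotype inference.

Six statistics, computed per replicate and averaged across replicates:

* ``IH``  — haplotype identification index,
  ``2 (K_true - K_miss) / (K_true + K_est)`` where ``K_true`` is the number
  of distinct true haplotypes, ``K_est`` the number of distinct estimated
  ones and ``K_miss`` the true haplotypes not recovered; 1 is perfect,
  0 means no true haplotype was found.
* ``SAD`` — sum of absolute differences between estimated and true
  haplotype frequencies over the union of haplotypes (range 0..2).
* ``IE``  — proportion of individuals whose unordered inferred pair
  differs from the truth; it splits exactly into
* ``IME`` — the part whose inferred pair is not even compatible with the
  genotype, and
* ``ISE`` — the remainder, attributed to switching between the haplotypes.
* ``SE``  — similarity error: per individual the phase-alignment-minimized
  Hamming distance between true and inferred pairs divided by twice the
  number of loci, averaged over individuals.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np

from .datamodel import (
    Diplotype,
    FrequencyTable,
    Haplotype,
    ObservedGenotype,
    pair_compatible_with_observation,
)

__all__ = [
    "ReplicateMetrics",
    "EvaluationReport",
    "ih_index",
    "sad",
    "diplotype_errors",
    "similarity_error",
    "evaluate_replicate",
]


def ih_index(true_set: Iterable[Haplotype], est_set: Iterable[Haplotype]) -> float:
    """Haplotype identification index on exact binary-string sets."""
    t = set(true_set)
    e = set(est_set)
    if not t:
        raise ValueError("true haplotype set must not be empty")
    k_true = len(t)
    k_est = len(e)
    k_miss = len(t - e)
    return 2.0 * (k_true - k_miss) / (k_true + k_est)


def sad(true_freqs: FrequencyTable, est_freqs: FrequencyTable) -> float:
    """Sum of absolute frequency differences over the union of haplotypes."""
    union = set(true_freqs) | set(est_freqs)
    return float(
        sum(abs(est_freqs.get(h, 0.0) - true_freqs.get(h, 0.0)) for h in union)
    )


def diplotype_errors(
    true_pairs: Sequence[Diplotype],
    est_pairs: Sequence[Diplotype],
    observed: Sequence[ObservedGenotype],
) -> tuple[float, float, float]:
    """(IE, IME, ISE): individual error rate and its two components.

    An individual counts toward IME when its inferred pair cannot have
    produced the observed genotype codes (which implies the pair is wrong,
    since the true pair always can); the remaining errors are switch
    errors, so IE = IME + ISE exactly.
    """
    if not (len(true_pairs) == len(est_pairs) == len(observed)):
        raise ValueError("inputs must have equal length")
    n = len(true_pairs)
    wrong = 0
    incompatible = 0
    for t, e, o in zip(true_pairs, est_pairs, observed):
        if e != t:
            wrong += 1
            if not pair_compatible_with_observation(e.pair[0], e.pair[1], o):
                incompatible += 1
    ie = wrong / n
    ime = incompatible / n
    return ie, ime, ie - ime


def similarity_error(
    true_pairs: Sequence[Diplotype],
    est_pairs: Sequence[Diplotype],
    n_loci: int | None = None,
    alignment: str = "min",
) -> float:
    """Mean per-individual normalized Hamming distance between pairs.

    ``alignment='min'`` (default) matches true and estimated haplotypes in
    the phase orientation minimizing the summed Hamming distance, which
    keeps SE <= IE; ``alignment='fixed'`` uses the canonical stored order
    of each unordered pair.
    """
    if len(true_pairs) != len(est_pairs):
        raise ValueError("inputs must have equal length")
    if alignment not in ("min", "fixed"):
        raise ValueError("alignment must be 'min' or 'fixed'")
    if n_loci is None:
        n_loci = len(true_pairs[0])
    total = 0.0
    for t, e in zip(true_pairs, est_pairs):
        t1, t2 = (h.to_array() for h in t.pair)
        e1, e2 = (h.to_array() for h in e.pair)
        d1 = int(np.count_nonzero(t1 != e1) + np.count_nonzero(t2 != e2))
        if alignment == "min":
            d2 = int(np.count_nonzero(t1 != e2) + np.count_nonzero(t2 != e1))
            d1 = min(d1, d2)
        total += d1 / (2.0 * n_loci)
    return total / len(true_pairs)


@dataclass(frozen=True)
class ReplicateMetrics:
    """The six statistics for one replicate."""

    ih: float
    sad: float
    ie: float
    ime: float
    ise: float
    se: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ih <= 1.0):
            raise ValueError("IH out of range [0, 1]")
        if not (0.0 <= self.sad <= 2.0):
            raise ValueError("SAD out of range [0, 2]")
        for name in ("ie", "ime", "ise", "se"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1.0):
                raise ValueError(f"{name.upper()} out of range [0, 1]")
        if abs(self.ie - (self.ime + self.ise)) > 1e-9:
            raise ValueError("IE must equal IME + ISE")
        if self.se > self.ie + 1e-9:
            raise ValueError("SE cannot exceed IE")


@dataclass(frozen=True)
class EvaluationReport:
    """Per-replicate statistics plus their means."""

    replicates: tuple[ReplicateMetrics, ...]

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("report needs at least one replicate")

    def mean(self, name: str) -> float:
        return float(np.mean([getattr(r, name) for r in self.replicates]))

    def means(self) -> dict[str, float]:
        return {k: self.mean(k) for k in ("ih", "sad", "ie", "ime", "ise", "se")}


def evaluate_replicate(
    true_pairs: Sequence[Diplotype],
    est_pairs: Sequence[Diplotype],
    observed: Sequence[ObservedGenotype],
    true_freqs: FrequencyTable,
    est_freqs: FrequencyTable,
    se_alignment: str = "min",
    ih_min_frequency: float = 0.0,
) -> ReplicateMetrics:
    """Score one replicate of inference against its simulation truth.

    The true haplotype set for IH is the set actually present in the
    replicate's sampled individuals; frequencies are compared against the
    generating distribution ``true_freqs``.  By default every estimated
    haplotype with positive frequency counts toward K_est;
    ``ih_min_frequency`` raises that floor.
    """
    true_set = {h for d in true_pairs for h in d.pair}
    est_set = {
        h for h, f in est_freqs.items() if f > 0 and f >= ih_min_frequency
    }
    ie, ime, ise = diplotype_errors(true_pairs, est_pairs, observed)
    return ReplicateMetrics(
        ih=ih_index(true_set, est_set),
        sad=sad(true_freqs, est_freqs),
        ie=ie,
        ime=ime,
        ise=ise,
        se=similarity_error(true_pairs, est_pairs, alignment=se_alignment),
    )
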