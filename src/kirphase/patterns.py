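"""Pattern-compatibility logic for gene-content haplotypes.

A :class:`~kirphase.datamodel.PatternSet` encodes deterministic constraints
(anchor genes, always-together pairs, mutually exclusive pairs).  During
backward sampling the HMM weights candidate states by whether the haplotype
suffix they imply is compatible with every pattern wholly contained in that
suffix: weight ``1 - beta`` if compatible, ``beta`` otherwise.  ``beta = 0``
recovers the hard constraint that forbids incompatible haplotypes outright.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from .datamodel import Haplotype, PatternSet

__all__ = [
    "haplotype_compatible",
    "suffix_pair_compatible",
    "constraint_weight",
    "pattern_arrays",
    "allowed_pair_masks",
]


def haplotype_compatible(h: Haplotype, p: PatternSet) -> bool:
    """True iff a full-length haplotype violates no pattern."""
    a = h.alleles
    L = len(a)
    for locus in p.anchors:
        if locus >= L:
            raise IndexError(f"anchor locus {locus} out of range for L={L}")
        if a[locus] != 1:
            return False
    for i, j in p.together:
        if j >= L:
            raise IndexError(f"pattern locus {j} out of range for L={L}")
        if a[i] != a[j]:
            return False
    for i, j in p.exclusive:
        if j >= L:
            raise IndexError(f"pattern locus {j} out of range for L={L}")
        if a[i] + a[j] != 1:
            return False
    return True


def suffix_pair_compatible(
    allele_pairs: Sequence[tuple[int, int]], p: PatternSet, l: int
) -> bool:
    """Check the two chromosome threads of a contiguous suffix of loci.

    ``allele_pairs[k]`` holds the ordered alleles (thread 1, thread 2) at
    locus ``l + k``; the suffix covers loci ``l .. l + len(allele_pairs) - 1``.
    Patterns with any constrained locus outside the suffix impose no
    constraint (they may still be violated or satisfied once the prefix is
    filled in).
    """
    if l < 0:
        raise IndexError("suffix start locus must be non-negative")
    n = len(allele_pairs)
    hi = l + n  # exclusive upper bound of covered loci
    if p.n_loci is not None and hi > p.n_loci:
        raise IndexError("suffix extends beyond the locus panel")

    def inside(locus: int) -> bool:
        return l <= locus < hi

    for locus in p.anchors:
        if inside(locus):
            a, b = allele_pairs[locus - l]
            if a != 1 or b != 1:
                return False
    for i, j in p.together:
        if inside(i) and inside(j):
            ai, bi = allele_pairs[i - l]
            aj, bj = allele_pairs[j - l]
            if ai != aj or bi != bj:
                return False
    for i, j in p.exclusive:
        if inside(i) and inside(j):
            ai, bi = allele_pairs[i - l]
            aj, bj = allele_pairs[j - l]
            if ai + aj != 1 or bi + bj != 1:
                return False
    return True


def constraint_weight(compatible: bool, beta: float = 0.0) -> float:
    """Sampling weight of a suffix: ``1 - beta`` if compatible, else ``beta``."""
    if not (0.0 <= beta < 1.0):
        raise ValueError("beta must lie in [0, 1)")
    return 1.0 - beta if compatible else beta


def allowed_pair_masks(obs_codes: np.ndarray, p: PatternSet) -> np.ndarray | None:
    """Arc-consistent per-locus masks of admissible ordered allele pairs.

    Starting from the pairs each observation code admits, anchors prune
    their own locus and every pattern pair propagates between its two loci
    (together: identical pair required at both; exclusive: the complement
    pair) until a fixed point.  Backward sampling that draws the upper
    locus of each pair from these masks can always complete the lower
    locus, so hard-constraint sampling becomes backtrack-free for any
    individual that has a compatible haplotype pair at all.

    Returns an (L, 4) int8 mask over the ordered pairs
    (0,0), (0,1), (1,0), (1,1), or None when some locus admits no
    candidate — the signature of an individual with no pattern-compatible
    completion.
    """
    from ._kernels import CODE_MASK

    codes = np.asarray(obs_codes, dtype=np.int8)
    allowed = CODE_MASK[codes].astype(bool)
    for locus in p.anchors:
        allowed[locus] &= np.array([False, False, False, True])
    pairs = [(i, j, 0) for i, j in p.together] + [(i, j, 1) for i, j in p.exclusive]
    changed = True
    while changed:
        changed = False
        for i, j, kind in pairs:
            if kind == 0:  # identical ordered pair on both loci
                new_i = allowed[i] & allowed[j]
                new_j = new_i
            else:  # exclusive: (a, b) at one locus forces (1-a, 1-b) at the other
                new_i = allowed[i] & allowed[j][::-1]
                new_j = allowed[j] & allowed[i][::-1]
            if not np.array_equal(new_i, allowed[i]) or not np.array_equal(
                new_j, allowed[j]
            ):
                allowed[i] = new_i
                allowed[j] = new_j
                changed = True
    if not allowed.any(axis=1).all():
        return None
    return allowed.astype(np.int8)


def pattern_arrays(
    p: PatternSet | None, n_loci: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, bool]:
    """Flatten a pattern set into arrays consumed by the compiled kernels.

    Returns ``(anchors, pair_i, pair_j, pair_kind, use_patterns)`` where
    ``anchors`` is an int8 indicator over loci, pairs are stored with
    ``pair_i < pair_j`` (the kernel checks a pair when sampling reaches its
    lower locus, the upper one being already part of the suffix) and
    ``pair_kind`` is 0 for together, 1 for exclusive.
    """
    if p is None or p.is_empty():
        return (
            np.zeros(n_loci, dtype=np.int8),
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int8),
            False,
        )
    if any(l >= n_loci for l in p.anchors) or any(
        j >= n_loci for _, j in (p.together | p.exclusive)
    ):
        raise IndexError("pattern locus out of range for the panel")
    anchors = np.zeros(n_loci, dtype=np.int8)
    for locus in p.anchors:
        anchors[locus] = 1
    pairs = [(i, j, 0) for i, j in sorted(p.together)] + [
        (i, j, 1) for i, j in sorted(p.exclusive)
    ]
    pair_i = np.asarray([q[0] for q in pairs], dtype=np.int64)
    pair_j = np.asarray([q[1] for q in pairs], dtype=np.int64)
    pair_kind = np.asarray([q[2] for q in pairs], dtype=np.int8)
    return anchors, pair_i, pair_j, pair_kind, True
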