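"""Gibbs orchestration across individuals, iterations and reference panels.

Each sweep re-samples every individual's haplotype pair from the mosaic HMM
whose reference panel combines the external identified haplotypes (constant
across iterations, weight 1 each) with the internal haplotypes — the
current estimates for all OTHER individuals taken at the start of the
sweep.  Consensus diplotypes are the modal sampled pair over post-burn-in
sweeps, and haplotype frequencies are estimated from the 2N haplotypes of
the final sweep.

Reproducibility contract: one master seed; the substream for (sweep,
individual) is derived from a counter-based seed table keyed by a stable
individual id, so permuting the input order permutes the results without
changing them.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .datamodel import (
    Code,
    Diplotype,
    FrequencyTable,
    Haplotype,
    HMMParameters,
    ObservedGenotype,
    PatternSet,
    pair_compatible_with_observation,
)
from .patterns import allowed_pair_masks, haplotype_compatible, pattern_arrays

__all__ = ["InferenceResult", "initialize", "run_inference", "estimate_frequencies"]

logger = logging.getLogger(__name__)

_FALLBACK_BETA = 1e-6
_HARD_RETRIES = 10  # fresh beta=0 draws before softening the constraint

# ordered allele pairs admissible per observation code, for initialization
_CODE_PAIRS: dict[Code, tuple[tuple[int, int], ...]] = {
    Code.ABSENT: ((0, 0),),
    Code.PRESENT: ((0, 1), (1, 0), (1, 1)),
    Code.MISSING: ((0, 0), (0, 1), (1, 0), (1, 1)),
    Code.FULL0: ((0, 0),),
    Code.FULL1: ((0, 1), (1, 0)),
    Code.FULL2: ((1, 1),),
}


@dataclass(frozen=True)
class InferenceResult:
    """Phasing output for one sample.

    consensus
        Modal unordered haplotype pair per individual over post-burn-in
        sweeps (ties broken toward the lexicographically smallest pair).
    support
        Fraction of post-burn-in sweeps yielding the consensus pair.
    frequencies
        Haplotype frequencies estimated from the final sweep's haplotypes
        of non-flagged individuals.
    fallbacks
        (sweep, individual id) events where the hard pattern constraint
        stayed infeasible across repeated draws and sampling fell back to
        beta = 1e-6 (the escape hatch for individuals with no compatible
        haplotype pair).
    flagged
        Ids of individuals that stayed infeasible even after the fallback;
        they keep their previous pair and are excluded from the frequency
        estimate.
    switch_counts / mismatch_counts
        Per-sweep totals of sampled template switches and imputed-allele
        mismatches against the template (diagnostics, also used by the
        optional rate re-estimation).
    """

    consensus: tuple[Diplotype, ...]
    support: np.ndarray
    frequencies: FrequencyTable
    fallbacks: tuple[tuple[int, int], ...] = ()
    flagged: tuple[int, ...] = ()
    switch_counts: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    mismatch_counts: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))


def estimate_frequencies(final_haplotypes: Sequence[Haplotype]) -> FrequencyTable:
    """Relative counts of the distinct haplotypes in the final sweep."""
    if len(final_haplotypes) == 0:
        raise ValueError("cannot estimate frequencies from an empty set")
    counts = Counter(final_haplotypes)
    total = len(final_haplotypes)
    return FrequencyTable({h: c / total for h, c in counts.items()})


def _external_pair_candidates(
    obs: ObservedGenotype,
    refs: Sequence[Haplotype],
    ref_ok: Sequence[bool],
) -> list[tuple[int, int]]:
    out = []
    for i in range(len(refs)):
        if not ref_ok[i]:
            continue
        for j in range(i, len(refs)):
            if not ref_ok[j]:
                continue
            if pair_compatible_with_observation(refs[i], refs[j], obs):
                out.append((i, j))
    return out


_PAIR_TUPLES = ((0, 0), (0, 1), (1, 0), (1, 1))


def _sequential_pair(
    obs: ObservedGenotype,
    patterns: PatternSet | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """Sample an observation-compatible ordered pair honoring the patterns.

    Fills loci from last to first from arc-consistent candidate masks, so a
    pattern pair is resolvable when its lower locus is reached (mirroring
    the HMM's suffix constraint).  Returns the (L, 2) allele array and
    whether patterns are satisfied; individuals with no pattern-compatible
    completion get an unconstrained observation-compatible pair.
    """
    L = len(obs)
    alleles = np.zeros((L, 2), dtype=np.int8)
    use_pat = patterns is not None and not patterns.is_empty()
    mask = allowed_pair_masks(obs.as_array(), patterns) if use_pat else None
    if mask is None:
        # unconstrained fill: observation compatibility only
        for l in range(L):
            cands = _CODE_PAIRS[obs.codes[l]]
            a, b = cands[rng.integers(len(cands))]
            alleles[l, 0] = a
            alleles[l, 1] = b
        return alleles, not use_pat
    pair_list = [(i, j, 0) for i, j in patterns.together] + [
        (i, j, 1) for i, j in patterns.exclusive
    ]
    for l in range(L - 1, -1, -1):
        cands = [_PAIR_TUPLES[p] for p in range(4) if mask[l, p]]
        kept = []
        for a, b in cands:
            good = True
            for i, j, kind in pair_list:
                if i == l:
                    if kind == 0:
                        if a != alleles[j, 0] or b != alleles[j, 1]:
                            good = False
                            break
                    elif a + alleles[j, 0] != 1 or b + alleles[j, 1] != 1:
                        good = False
                        break
            if good:
                kept.append((a, b))
        a, b = kept[rng.integers(len(kept))]  # non-empty by arc consistency
        alleles[l, 0] = a
        alleles[l, 1] = b
    return alleles, True


def initialize(
    obs_all: Sequence[ObservedGenotype],
    external_refs: Sequence[Haplotype],
    patterns: PatternSet | None,
    rng: np.random.Generator,
) -> list[Diplotype]:
    """Assign a starting haplotype pair per individual from its observations.

    Pairs of external references that reproduce the observation (and satisfy
    the patterns) are preferred; otherwise a random observation- and
    pattern-compatible pair is built, falling back to an unconstrained
    observation-compatible pair with a warning when no pattern-compatible
    completion is found.
    """
    if len(obs_all) == 0:
        raise ValueError("sample must not be empty")
    refs = list(external_refs)
    if patterns is not None and not patterns.is_empty():
        ref_ok = [haplotype_compatible(h, patterns) for h in refs]
    else:
        ref_ok = [True] * len(refs)
    out: list[Diplotype] = []
    for n, obs in enumerate(obs_all):
        cands = _external_pair_candidates(obs, refs, ref_ok) if refs else []
        if cands:
            i, j = cands[rng.integers(len(cands))]
            out.append(Diplotype((refs[i], refs[j])))
            continue
        alleles, pat_ok = _sequential_pair(obs, patterns, rng)
        if not pat_ok and patterns is not None and not patterns.is_empty():
            logger.warning(
                "individual %d has no pattern-compatible completion; "
                "initialized unconstrained", n,
            )
        out.append(
            Diplotype((Haplotype.from_array(alleles[:, 0]), Haplotype.from_array(alleles[:, 1])))
        )
    return out


def run_inference(
    obs_all: Sequence[ObservedGenotype],
    external_refs: Sequence[Haplotype],
    patterns: PatternSet | None,
    params: HMMParameters,
    *,
    ids: Sequence[int] | None = None,
    reestimate_rates: bool = True,
    frequency_estimator: str = "final",
    external_weights: Sequence[float] | None = None,
) -> InferenceResult:
    """Run the full Gibbs sampler and return consensus phasing.

    ``ids`` are the stable individual identifiers keying the per-(sweep,
    individual) random substreams; they default to the row index.
    ``reestimate_rates`` (default on) re-estimates the switch and error
    rates each sweep from the sampled template switches and allele
    mismatches, starting from the values in ``params`` — the mosaic model's
    rates are fitted quantities, and leaving them at an arbitrary constant
    inflates spurious mosaic haplotypes in the final sweep.  Pass False to
    keep the rates fixed at ``params`` throughout.
    ``frequency_estimator`` is ``"final"`` (default: the last sweep's 2N
    haplotypes) or ``"pooled"`` (all post-burn-in sweeps).
    ``external_weights`` optionally gives each external reference a panel
    multiplicity (default: weight 1 each).
    """
    if frequency_estimator not in ("final", "pooled"):
        raise ValueError("frequency_estimator must be 'final' or 'pooled'")
    N = len(obs_all)
    if N == 0:
        raise ValueError("sample must not be empty")
    L = len(obs_all[0])
    if any(len(o) != L for o in obs_all):
        raise ValueError("all observations must cover the same loci")
    ids = list(range(N)) if ids is None else [int(i) for i in ids]
    if len(ids) != N or len(set(ids)) != N:
        raise ValueError("ids must be unique and align with the sample")

    obs_arr = np.stack([o.as_array() for o in obs_all])
    theta = params.theta_array(L)
    eps = params.error_rate
    beta = params.pattern_relaxation
    anchors, pair_i, pair_j, pair_kind, use_pat = pattern_arrays(patterns, L)
    T, B = params.iterations, params.burn_in

    # per-individual candidate masks (fixed across sweeps): under the hard
    # constraint, arc-consistent pruning makes sampling backtrack-free;
    # individuals with no pattern-compatible completion sample softly
    base_masks = _kernels.CODE_MASK[obs_arr]  # (N, L, 4)
    masks = np.ascontiguousarray(base_masks).copy()
    incompatible = np.zeros(N, dtype=bool)
    if use_pat and beta == 0.0:
        for n in range(N):
            m = allowed_pair_masks(obs_arr[n], patterns)
            if m is None:
                incompatible[n] = True
                logger.warning(
                    "individual %d has no pattern-compatible haplotype pair; "
                    "sampling with beta=%g", ids[n], _FALLBACK_BETA,
                )
            else:
                masks[n] = m

    # counter-based seed table: row 0 for initialization, then one row per
    # sweep; two 31-bit seeds per individual (primary + fallback draw)
    max_id = max(ids)
    seed_words = np.random.SeedSequence(params.seed).generate_state(
        (T + 1) * (max_id + 1) * 2, np.uint32
    ).reshape(T + 1, max_id + 1, 2) >> np.uint32(1)

    ext: list[Haplotype] = []
    ext_w: list[float] = []
    if external_weights is not None and len(external_weights) != len(external_refs):
        raise ValueError("external weights must align with external references")
    for k, h in enumerate(external_refs):
        if len(h) != L:
            raise ValueError("external reference length must match the data")
        wt = 1.0 if external_weights is None else float(external_weights[k])
        if wt <= 0:
            raise ValueError("external weights must be positive")
        if h in ext:
            ext_w[ext.index(h)] += wt
        else:
            ext.append(h)
            ext_w.append(wt)
    ext_rows = [h.to_array() for h in ext]

    # initialization is keyed per individual id as well, so that permuting
    # the input rows permutes the starting pairs without changing them
    start = [
        initialize([obs_all[n]], ext, patterns, np.random.default_rng(int(seed_words[0, ids[n], 0])))[0]
        for n in range(N)
    ]
    haps = np.empty((N, 2, L), dtype=np.int8)
    for n, d in enumerate(start):
        haps[n, 0] = d.pair[0].to_array()
        haps[n, 1] = d.pair[1].to_array()

    pair_counts: list[Counter] = [Counter() for _ in range(N)]
    fallbacks: list[tuple[int, int]] = []
    flagged: set[int] = set()
    switch_counts = np.zeros(T, dtype=np.int64)
    mismatch_counts = np.zeros(T, dtype=np.int64)

    for it in range(T):
        # collapse externals + all current internal haplotypes once per sweep
        index: dict[bytes, int] = {}
        rows: list[np.ndarray] = []
        weights: list[float] = []

        def _add(row: np.ndarray, wt: float) -> int:
            key = row.tobytes()
            k = index.get(key)
            if k is None:
                k = len(rows)
                index[key] = k
                rows.append(row)
                weights.append(0.0)
            weights[k] += wt
            return k

        for r, wt in zip(ext_rows, ext_w):
            _add(r, wt)
        own_idx = np.empty((N, 2), dtype=np.int64)
        for n in range(N):
            own_idx[n, 0] = _add(haps[n, 0], 1.0)
            own_idx[n, 1] = _add(haps[n, 1], 1.0)
        hap_mat = np.ascontiguousarray(np.stack(rows))
        w_all = np.asarray(weights)

        new_haps = haps.copy()
        for n in range(N):
            w = w_all.copy()
            w[own_idx[n, 0]] -= 1.0
            w[own_idx[n, 1]] -= 1.0
            if w.sum() <= 0.0:  # single individual, no external refs
                w[own_idx[n, 0]] += 1.0
                w[own_idx[n, 1]] += 1.0
            if incompatible[n]:
                # no compatible pair exists: soft constraint from the start
                fallbacks.append((it, ids[n]))
                states, alleles, status = _kernels.sample_individual(
                    hap_mat, w, obs_arr[n], base_masks[n], theta, eps,
                    _FALLBACK_BETA, anchors, pair_i, pair_j, pair_kind,
                    use_pat, int(seed_words[it + 1, ids[n], 0]),
                )
            else:
                states, alleles, status = _kernels.sample_individual(
                    hap_mat, w, obs_arr[n], masks[n], theta, eps, beta,
                    anchors, pair_i, pair_j, pair_kind, use_pat,
                    int(seed_words[it + 1, ids[n], 0]),
                )
            if status == _kernels.STATUS_CONSTRAINED and beta == 0.0 and use_pat:
                # arc consistency precludes dead ends for feasible
                # individuals except at error_rate 0, where an emission can
                # still zero out the only admissible candidate: redraw under
                # the hard constraint, then soften as a last resort
                retry_base = int(seed_words[it + 1, ids[n], 1])
                for k in range(_HARD_RETRIES):
                    states, alleles, status = _kernels.sample_individual(
                        hap_mat, w, obs_arr[n], masks[n], theta, eps, 0.0,
                        anchors, pair_i, pair_j, pair_kind, use_pat,
                        (retry_base + k) & 0x7FFFFFFF,
                    )
                    if status != _kernels.STATUS_CONSTRAINED:
                        break
                if status == _kernels.STATUS_CONSTRAINED:
                    fallbacks.append((it, ids[n]))
                    logger.info(
                        "sweep %d individual %d: hard pattern constraint "
                        "infeasible, retrying with beta=%g", it, ids[n], _FALLBACK_BETA,
                    )
                    states, alleles, status = _kernels.sample_individual(
                        hap_mat, w, obs_arr[n], base_masks[n], theta, eps,
                        _FALLBACK_BETA, anchors, pair_i, pair_j, pair_kind,
                        use_pat, (retry_base + _HARD_RETRIES) & 0x7FFFFFFF,
                    )
            if status != _kernels.STATUS_OK:
                if ids[n] not in flagged:
                    logger.warning(
                        "individual %d infeasible even after relaxation; "
                        "keeping previous pair and excluding it from the "
                        "frequency estimate", ids[n],
                    )
                flagged.add(ids[n])
                continue
            new_haps[n, 0] = alleles[:, 0]
            new_haps[n, 1] = alleles[:, 1]
            switch_counts[it] += int(np.count_nonzero(states[1:] != states[:-1]))
            mismatch_counts[it] += int(
                np.count_nonzero(hap_mat[states[:, 0], np.arange(L)] != alleles[:, 0])
                + np.count_nonzero(hap_mat[states[:, 1], np.arange(L)] != alleles[:, 1])
            )
        haps = new_haps
        if reestimate_rates:
            denom_s = 2.0 * N * max(L - 1, 1)
            denom_m = 2.0 * N * L
            theta = np.full(
                max(L - 1, 0),
                float(np.clip(switch_counts[it] / denom_s, 1e-6, 1.0)),
            )
            eps = float(np.clip(mismatch_counts[it] / denom_m, 1e-6, 0.499))
        if it >= B:
            for n in range(N):
                key = tuple(sorted((haps[n, 0].tobytes(), haps[n, 1].tobytes())))
                pair_counts[n][key] += 1

    n_recorded = T - B
    consensus: list[Diplotype] = []
    support = np.empty(N)
    for n in range(N):
        top = max(pair_counts[n].values())
        best = min(k for k, c in pair_counts[n].items() if c == top)
        consensus.append(
            Diplotype(
                (
                    Haplotype.from_array(np.frombuffer(best[0], dtype=np.int8)),
                    Haplotype.from_array(np.frombuffer(best[1], dtype=np.int8)),
                )
            )
        )
        support[n] = top / n_recorded

    keep = [n for n in range(N) if ids[n] not in flagged] or list(range(N))
    final: list[Haplotype] = []
    if frequency_estimator == "final":
        for n in keep:
            final.append(Haplotype.from_array(haps[n, 0]))
            final.append(Haplotype.from_array(haps[n, 1]))
    else:  # pooled over every post-burn-in sweep
        for n in keep:
            for (b1, b2), c in pair_counts[n].items():
                for b in (b1, b2):
                    final.extend(
                        [Haplotype.from_array(np.frombuffer(b, dtype=np.int8))] * c
                    )
    return InferenceResult(
        consensus=tuple(consensus),
        support=support,
        frequencies=estimate_frequencies(final),
        fallbacks=tuple(fallbacks),
        flagged=tuple(sorted(flagged)),
        switch_counts=switch_counts,
        mismatch_counts=mismatch_counts,
    )
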