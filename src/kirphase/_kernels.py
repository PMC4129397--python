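"""Compiled inner loops of the diploid mosaic HMM.

All kernels operate on plain arrays: the reference panel as an (H, L) int8
allele matrix with float64 multiplicity weights (zero weights are allowed
and behave as absent templates), observations as int8 codes matching
:class:`kirphase.datamodel.Code`, and pattern constraints flattened by
:func:`kirphase.patterns.pattern_arrays`.

Model conventions (the standard mosaic forms):

* initial diploid state prior proportional to ``w[x] * w[y]``;
* per-chromosome transition across interval l: stay on the current template
  with probability ``1 - theta_l`` plus a switch term; a switch lands on
  template k (including the current one) with probability
  ``theta_l * w[k] / W``;
* per-allele emission: the emitted allele equals the template allele with
  probability ``1 - eps``, flips with probability ``eps``; the two
  chromosomes emit independently and the observation code determines which
  ordered emitted pairs are admissible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Ordered emitted allele pairs (thread 1, thread 2).
PAIRS = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)

# Admissible pair mask per observation code
# (rows: ABSENT, PRESENT, MISSING, FULL0, FULL1, FULL2).
CODE_MASK = np.array(
    [
        [1, 0, 0, 0],
        [0, 1, 1, 1],
        [1, 1, 1, 1],
        [1, 0, 0, 0],
        [0, 1, 1, 0],
        [0, 0, 0, 1],
    ],
    dtype=np.int8,
)

STATUS_OK = 0
STATUS_INFEASIBLE = 1  # a forward layer summed to zero
STATUS_CONSTRAINED = 2  # no pattern-admissible candidate during sampling


@njit(cache=True)
def _emission_layer(hap, obs_l, l, eps, out):
    """out[x, y] = Pr(observed code at locus l | templates x, y)."""
    H = hap.shape[0]
    a0 = np.empty(H)
    for x in range(H):
        a0[x] = eps if hap[x, l] == 1 else 1.0 - eps
    for x in range(H):
        for y in range(H):
            p00 = a0[x] * a0[y]
            if obs_l == 0 or obs_l == 3:  # ABSENT / FULL0
                out[x, y] = p00
            elif obs_l == 1:  # PRESENT
                out[x, y] = 1.0 - p00
            elif obs_l == 2:  # MISSING
                out[x, y] = 1.0
            elif obs_l == 4:  # FULL1
                out[x, y] = a0[x] * (1.0 - a0[y]) + (1.0 - a0[x]) * a0[y]
            else:  # FULL2
                out[x, y] = (1.0 - a0[x]) * (1.0 - a0[y])


@njit(cache=True)
def forward(hap, w, obs, theta, eps):
    """Normalized forward filtering over the H*H diploid state space.

    Returns ``(pre, post, norms, status)`` where ``pre[l]`` is the predictive
    distribution Pr(S_l | G_1..l-1), ``post[l]`` the filtering distribution
    Pr(S_l | G_1..l) and ``norms[l]`` the per-locus normalization constant
    Pr(G_l | G_1..l-1).  The transition update uses the row/column rank-1
    factorization so each locus costs O(H^2).
    """
    H, L = hap.shape
    pre = np.empty((L, H, H))
    post = np.empty((L, H, H))
    norms = np.zeros(L)
    W = w.sum()
    pw = w / W
    for x in range(H):
        for y in range(H):
            pre[0, x, y] = pw[x] * pw[y]
    emis = np.empty((H, H))
    tmp = np.empty((H, H))
    for l in range(L):
        if l > 0:
            th = theta[l - 1]
            prev = post[l - 1]
            for y in range(H):
                s = 0.0
                for x in range(H):
                    s += prev[x, y]
                for x in range(H):
                    tmp[x, y] = (1.0 - th) * prev[x, y] + th * pw[x] * s
            for x in range(H):
                s = 0.0
                for y in range(H):
                    s += tmp[x, y]
                for y in range(H):
                    pre[l, x, y] = (1.0 - th) * tmp[x, y] + th * pw[y] * s
        _emission_layer(hap, obs[l], l, eps, emis)
        tot = 0.0
        for x in range(H):
            for y in range(H):
                v = pre[l, x, y] * emis[x, y]
                post[l, x, y] = v
                tot += v
        norms[l] = tot
        if tot <= 0.0:
            return pre, post, norms, STATUS_INFEASIBLE
        inv = 1.0 / tot
        for x in range(H):
            for y in range(H):
                post[l, x, y] *= inv
    return pre, post, norms, STATUS_OK


@njit(cache=True)
def backward_sample(
    hap, w, pre, allowed, theta, eps, beta,
    anchors, pair_i, pair_j, pair_kind, use_patterns, seed,
):
    """Constrained backward sampling of diploid states and imputed alleles.

    Samples jointly, locus by locus from L down to 1, a diploid state and an
    ordered emitted-allele pair; candidates are restricted to the (L, 4)
    ``allowed`` mask (observation-admissible pairs, optionally pruned to
    arc consistency with the patterns), weighted by the backward kernel
    times the emission probability times the pattern weight of the implied
    allele suffix (``1 - beta`` compatible, ``beta`` not).  Once a sampled
    choice violates a pattern the whole suffix is incompatible and the
    factor becomes a constant, so later checks are skipped.  Returns
    ``(states, alleles, status)``.
    """
    np.random.seed(seed)
    H, L = hap.shape
    states = np.zeros((L, 2), dtype=np.int64)
    alleles = np.zeros((L, 2), dtype=np.int8)
    W = w.sum()
    pw = w / W
    wt = np.empty((H, H, 4))
    a0 = np.empty(H)
    f1 = np.ones(H)
    f2 = np.ones(H)
    pf = np.empty(4)
    newviol = np.zeros(4, dtype=np.int8)
    violated = False
    for step in range(L):
        l = L - 1 - step
        for x in range(H):
            a0[x] = eps if hap[x, l] == 1 else 1.0 - eps
        if l < L - 1:
            th = theta[l]
            xn = states[l + 1, 0]
            yn = states[l + 1, 1]
            c1 = th * pw[xn]
            c2 = th * pw[yn]
            for x in range(H):
                f1[x] = c1
                f2[x] = c2
            f1[xn] += 1.0 - th
            f2[yn] += 1.0 - th
        # pattern weight per candidate allele pair (state-independent)
        for p in range(4):
            newviol[p] = 0
            if allowed[l, p] == 0:
                pf[p] = -1.0  # inadmissible under the observation/mask
                continue
            if use_patterns and not violated:
                a = PAIRS[p, 0]
                b = PAIRS[p, 1]
                ok = True
                if anchors[l] == 1 and (a != 1 or b != 1):
                    ok = False
                if ok:
                    for k in range(pair_i.shape[0]):
                        if pair_i[k] == l:
                            j = pair_j[k]
                            if pair_kind[k] == 0:  # together
                                if a != alleles[j, 0] or b != alleles[j, 1]:
                                    ok = False
                                    break
                            else:  # exclusive: exactly one present
                                if a + alleles[j, 0] != 1 or b + alleles[j, 1] != 1:
                                    ok = False
                                    break
                if ok:
                    pf[p] = 1.0 - beta
                else:
                    pf[p] = beta
                    newviol[p] = 1
            else:
                pf[p] = 1.0
        tot = 0.0
        for x in range(H):
            for y in range(H):
                base = pre[l, x, y] * f1[x] * f2[y]
                for p in range(4):
                    if pf[p] < 0.0:
                        wt[x, y, p] = 0.0
                        continue
                    e1 = (1.0 - a0[x]) if PAIRS[p, 0] == 1 else a0[x]
                    e2 = (1.0 - a0[y]) if PAIRS[p, 1] == 1 else a0[y]
                    v = base * e1 * e2 * pf[p]
                    wt[x, y, p] = v
                    tot += v
        if tot <= 0.0:
            return states, alleles, STATUS_CONSTRAINED
        u = np.random.random() * tot
        acc = 0.0
        sel = -1
        last = -1
        for x in range(H):
            for y in range(H):
                for p in range(4):
                    v = wt[x, y, p]
                    if v <= 0.0:
                        continue
                    acc += v
                    last = (x * H + y) * 4 + p
                    if sel < 0 and acc >= u:
                        sel = last
        if sel < 0:
            sel = last  # floating-point slack: fall back to the last candidate
        sp = sel % 4
        sy = (sel // 4) % H
        sx = sel // (4 * H)
        states[l, 0] = sx
        states[l, 1] = sy
        alleles[l, 0] = PAIRS[sp, 0]
        alleles[l, 1] = PAIRS[sp, 1]
        if use_patterns and not violated and newviol[sp] == 1:
            violated = True
    return states, alleles, STATUS_OK


@njit(cache=True)
def sample_individual(
    hap, w, obs, allowed, theta, eps, beta,
    anchors, pair_i, pair_j, pair_kind, use_patterns, seed,
):
    """Forward filtering + constrained backward sampling in one call."""
    pre, post, norms, status = forward(hap, w, obs, theta, eps)
    if status != STATUS_OK:
        return (
            np.zeros((0, 2), dtype=np.int64),
            np.zeros((0, 2), dtype=np.int8),
            status,
        )
    return backward_sample(
        hap, w, pre, allowed, theta, eps, beta,
        anchors, pair_i, pair_j, pair_kind, use_patterns, seed,
    )
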