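"""Exhaustive-enumeration oracle for the diploid mosaic HMM.

Pure-Python reimplementation of the model by brute force over all diploid
state paths; tractable for L <= 4 and H <= 3 and deliberately independent
of the package's forward/backward code paths.
"""

from __future__ import annotations

import itertools

import numpy as np

from kirphase.datamodel import Code


def emission(code: int, tx: int, ty: int, eps: float) -> float:
    """Pr(observed code | template alleles), summed over compatible truths."""
    p0x = 1.0 - eps if tx == 0 else eps
    p0y = 1.0 - eps if ty == 0 else eps
    if code in (Code.ABSENT, Code.FULL0):
        return p0x * p0y
    if code == Code.PRESENT:
        return 1.0 - p0x * p0y
    if code == Code.MISSING:
        return 1.0
    if code == Code.FULL1:
        return p0x * (1.0 - p0y) + (1.0 - p0x) * p0y
    return (1.0 - p0x) * (1.0 - p0y)


def transition(th: float, w: np.ndarray, i: int, j: int) -> float:
    """Per-chromosome switch kernel (landing includes the current template)."""
    pw = w / w.sum()
    return th * pw[j] + (1.0 - th) * (i == j)


def enumerate_paths(
    hap: np.ndarray, w: np.ndarray, codes: list[int], theta: np.ndarray, eps: float
) -> dict[tuple, float]:
    """Unnormalized joint Pr(G, path) for every diploid state path."""
    H, L = hap.shape
    pw = w / w.sum()
    states = [(x, y) for x in range(H) for y in range(H)]
    joint: dict[tuple, float] = {}
    for path in itertools.product(states, repeat=L):
        p = pw[path[0][0]] * pw[path[0][1]]
        for l in range(1, L):
            p *= transition(theta[l - 1], w, path[l - 1][0], path[l][0])
            p *= transition(theta[l - 1], w, path[l - 1][1], path[l][1])
        for l in range(L):
            p *= emission(codes[l], hap[path[l][0], l], hap[path[l][1], l], eps)
        joint[path] = p
    return joint


def filtering_marginal(
    hap: np.ndarray, w: np.ndarray, codes: list[int], theta: np.ndarray, eps: float, l: int
) -> np.ndarray:
    """Pr(S_l | G_1..l) by enumerating all prefixes up to locus l."""
    H = hap.shape[0]
    prefix = enumerate_paths(hap[:, : l + 1], w, codes[: l + 1], theta[:l], eps)
    out = np.zeros((H, H))
    for path, p in prefix.items():
        out[path[-1]] += p
    return out / out.sum()


def posterior_paths(
    hap: np.ndarray, w: np.ndarray, codes: list[int], theta: np.ndarray, eps: float
) -> dict[tuple, float]:
    """Normalized posterior over full diploid state paths."""
    joint = enumerate_paths(hap, w, codes, theta, eps)
    z = sum(joint.values())
    return {k: v / z for k, v in joint.items()}
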