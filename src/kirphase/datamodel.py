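"""Core domain types for gene-content haplotype phasing.

The data model covers binary gene-content haplotypes over a panel of
clustered loci (e.g. the KIR region on 19q13.4, where locus-specific PCR
reports each gene as present or absent), the partially observed genotypes
such typing produces, and the weighted reference panels the mosaic HMM
conditions on.

Observation coding
------------------
A diploid individual carries an unordered pair of haplotypes.  At one locus
the true genotype is the unordered copy pair, but locus-specific typing only
reports:

* ``ABSENT``  — the gene is absent on both chromosomes, genotype (0, 0);
* ``PRESENT`` — at least one copy is present, genotype (1, ?): the second
  chromosome's status is unknown;
* ``MISSING`` — no call, genotype (?, ?).

A second, fully informative dialect records the exact copy number
(``FULL(g)``, g in {0, 1, 2}); it is used for no-missing-data experiments.
The two dialects are never mixed within one dataset.
"""

from __future__ import annotations

import enum
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Code",
    "Dialect",
    "LocusPanel",
    "Haplotype",
    "Diplotype",
    "ObservedGenotype",
    "DiploidState",
    "WeightedReferencePanel",
    "HMMParameters",
    "FrequencyTable",
    "PatternSet",
    "collapse_panel",
    "observe",
    "pair_compatible_with_observation",
]


class Code(enum.IntEnum):
    """Per-locus observation code.

    The integer values are shared with the compiled sampling kernels and
    must not be reordered.
    """

    ABSENT = 0   # true genotype (0, 0)
    PRESENT = 1  # true genotype (1, ?)
    MISSING = 2  # true genotype (?, ?)
    FULL0 = 3    # exact copy number 0 (full dialect)
    FULL1 = 4    # exact copy number 1
    FULL2 = 5    # exact copy number 2

    @staticmethod
    def full(g: int) -> "Code":
        if g not in (0, 1, 2):
            raise ValueError(f"copy number must be 0, 1 or 2, got {g}")
        return Code(Code.FULL0 + g)


class Dialect(str, enum.Enum):
    """Dataset-wide observation dialect."""

    PRESENT_ABSENT = "present-absent"
    FULL = "full"


_PRESENT_ABSENT_CODES = frozenset({Code.ABSENT, Code.PRESENT, Code.MISSING})
_FULL_CODES = frozenset({Code.ABSENT, Code.MISSING, Code.FULL0, Code.FULL1, Code.FULL2})


@dataclass(frozen=True)
class LocusPanel:
    """Ordered locus (gene) names defining column semantics; length L."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(names) == 0:
            raise ValueError("locus panel must contain at least one locus")
        if any(not n for n in names):
            raise ValueError("locus names must be non-empty")
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @classmethod
    def generic(cls, n_loci: int) -> "LocusPanel":
        return cls(tuple(f"g{i + 1}" for i in range(n_loci)))


@dataclass(frozen=True, order=True)
class Haplotype:
    """Binary gene-content vector: 1 = gene present, 0 = absent."""

    alleles: tuple[int, ...]

    def __post_init__(self) -> None:
        alleles = tuple(int(a) for a in self.alleles)
        object.__setattr__(self, "alleles", alleles)
        if len(alleles) == 0:
            raise ValueError("haplotype must cover at least one locus")
        if any(a not in (0, 1) for a in alleles):
            raise ValueError("alleles must be 0 (absent) or 1 (present)")

    def __len__(self) -> int:
        return len(self.alleles)

    def __str__(self) -> str:
        return " ".join(str(a) for a in self.alleles)

    def to_array(self) -> np.ndarray:
        return np.asarray(self.alleles, dtype=np.int8)

    @classmethod
    def from_string(cls, s: str) -> "Haplotype":
        """Parse either '1 0 0 1' or compact '1001'."""
        tokens = s.split() if any(c.isspace() for c in s) else list(s)
        return cls(tuple(int(t) for t in tokens))

    @classmethod
    def from_array(cls, a: np.ndarray) -> "Haplotype":
        return cls(tuple(int(x) for x in a))


@dataclass(frozen=True)
class Diplotype:
    """Unordered pair of haplotypes; equality and hashing ignore order."""

    pair: tuple[Haplotype, Haplotype]

    def __post_init__(self) -> None:
        a, b = self.pair
        if len(a) != len(b):
            raise ValueError("haplotypes in a diplotype must have equal length")
        object.__setattr__(self, "pair", (a, b) if a <= b else (b, a))

    def __len__(self) -> int:
        return len(self.pair[0])

    def __iter__(self) -> Iterator[Haplotype]:
        return iter(self.pair)

    def is_homozygous(self) -> bool:
        return self.pair[0] == self.pair[1]

    def copy_sum(self, locus: int) -> int:
        return self.pair[0].alleles[locus] + self.pair[1].alleles[locus]


class DiploidState(tuple):
    """Ordered pair (x, y) of reference-haplotype indices, one per chromosome."""

    __slots__ = ()

    def __new__(cls, x: int, y: int):
        return super().__new__(cls, (int(x), int(y)))

    @property
    def x(self) -> int:
        return self[0]

    @property
    def y(self) -> int:
        return self[1]


@dataclass(frozen=True)
class ObservedGenotype:
    """Vector of per-locus observation codes under one dataset dialect."""

    codes: tuple[Code, ...]
    dialect: Dialect = Dialect.PRESENT_ABSENT

    def __post_init__(self) -> None:
        codes = tuple(Code(c) for c in self.codes)
        object.__setattr__(self, "codes", codes)
        if len(codes) == 0:
            raise ValueError("observed genotype must cover at least one locus")
        allowed = _PRESENT_ABSENT_CODES if self.dialect is Dialect.PRESENT_ABSENT else _FULL_CODES
        bad = [c for c in codes if c not in allowed]
        if bad:
            raise ValueError(
                f"codes {sorted({c.name for c in bad})} are not valid in the "
                f"{self.dialect.value} dialect (dialect mixing is an error)"
            )

    def __len__(self) -> int:
        return len(self.codes)

    def as_array(self) -> np.ndarray:
        return np.asarray([int(c) for c in self.codes], dtype=np.int8)

    def to_present_absent(self) -> "ObservedGenotype":
        """Down-convert exact copy numbers to the present-absent dialect."""
        mapping = {
            Code.FULL0: Code.ABSENT,
            Code.FULL1: Code.PRESENT,
            Code.FULL2: Code.PRESENT,
        }
        return ObservedGenotype(
            tuple(mapping.get(c, c) for c in self.codes), Dialect.PRESENT_ABSENT
        )


@dataclass(frozen=True)
class WeightedReferencePanel:
    """Distinct reference haplotypes with positive multiplicity weights.

    External haplotypes are previously identified references supplied from
    outside the sample; internal ones are the current estimates for the
    other individuals in the sample.
    """

    haplotypes: tuple[Haplotype, ...]
    weights: tuple[float, ...]
    external: tuple[bool, ...]

    def __post_init__(self) -> None:
        haps = tuple(self.haplotypes)
        weights = tuple(float(w) for w in self.weights)
        external = tuple(bool(e) for e in self.external)
        object.__setattr__(self, "haplotypes", haps)
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "external", external)
        if not haps:
            raise ValueError("reference panel must not be empty")
        if not (len(haps) == len(weights) == len(external)):
            raise ValueError("haplotypes, weights and external flags must align")
        lengths = {len(h) for h in haps}
        if len(lengths) != 1:
            raise ValueError("reference haplotypes must have uniform length")
        if len(set(haps)) != len(haps):
            raise ValueError("reference haplotypes must be pairwise distinct")
        if any(w <= 0 for w in weights):
            raise ValueError("weights must be positive")

    def __len__(self) -> int:
        return len(self.haplotypes)

    @property
    def n_loci(self) -> int:
        return len(self.haplotypes[0])

    @property
    def total_weight(self) -> float:
        return float(sum(self.weights))

    def alleles_matrix(self) -> np.ndarray:
        return np.stack([h.to_array() for h in self.haplotypes])

    def weights_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=np.float64)


@dataclass(frozen=True)
class HMMParameters:
    """Tunable parameters of the mosaic HMM and its Gibbs sampler.

    crossover_rate
        Per-interval template-switch probability theta; a scalar applies to
        every interval, or a sequence gives one value per interval (L-1).
    error_rate
        Symmetric per-allele emission error epsilon, absorbing gene
        conversion, mutation and genotyping error.
    pattern_relaxation
        Soft-constraint weight beta: pattern-compatible suffixes receive
        weight 1-beta, incompatible ones beta. beta = 0 is the hard
        constraint.
    """

    crossover_rate: float | tuple[float, ...] = 0.01
    error_rate: float = 0.01
    pattern_relaxation: float = 0.0
    iterations: int = 50
    burn_in: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        cr = self.crossover_rate
        if isinstance(cr, Iterable) and not isinstance(cr, (int, float)):
            cr = tuple(float(t) for t in cr)
            object.__setattr__(self, "crossover_rate", cr)
            values = cr
        else:
            object.__setattr__(self, "crossover_rate", float(cr))
            values = (float(cr),)
        if any(not (0.0 <= t <= 1.0) for t in values):
            raise ValueError("crossover rates must lie in [0, 1]")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error rate must lie in [0, 0.5)")
        if not (0.0 <= self.pattern_relaxation < 1.0):
            raise ValueError("pattern relaxation beta must lie in [0, 1)")
        if self.iterations < 1:
            raise ValueError("iterations must be positive")
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("burn-in must be non-negative and below iterations")

    def theta_array(self, n_loci: int) -> np.ndarray:
        """Per-interval switch rates as an (L-1,) array."""
        if isinstance(self.crossover_rate, tuple):
            if len(self.crossover_rate) != n_loci - 1:
                raise ValueError(
                    f"expected {n_loci - 1} per-interval crossover rates, "
                    f"got {len(self.crossover_rate)}"
                )
            return np.asarray(self.crossover_rate, dtype=np.float64)
        return np.full(max(n_loci - 1, 0), self.crossover_rate, dtype=np.float64)


class FrequencyTable(Mapping):
    """Map from haplotype to population frequency.

    Frequencies are used as given (printed tables may sum to slightly less
    than 1); validation only requires the total to be within 0.01 of 1.
    """

    __slots__ = ("_entries",)

    def __init__(self, entries: Mapping[Haplotype, float]):
        d = {h: float(f) for h, f in entries.items()}
        if not d:
            raise ValueError("frequency table must not be empty")
        if any(f < 0 for f in d.values()):
            raise ValueError("frequencies must be non-negative")
        total = sum(d.values())
        if abs(total - 1.0) > 0.01:
            raise ValueError(f"frequencies must sum to ~1 (+-0.01), got {total:.4f}")
        self._entries = d

    def __getitem__(self, h: Haplotype) -> float:
        return self._entries[h]

    def __iter__(self) -> Iterator[Haplotype]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __repr__(self) -> str:
        return f"FrequencyTable({len(self)} haplotypes, total={self.total:.3f})"

    @property
    def total(self) -> float:
        return float(sum(self._entries.values()))

    def get(self, h: Haplotype, default: float = 0.0) -> float:
        return self._entries.get(h, default)

    def by_frequency(self) -> list[tuple[Haplotype, float]]:
        """Entries sorted by descending frequency, insertion order on ties."""
        items = list(self._entries.items())
        order = sorted(range(len(items)), key=lambda i: (-items[i][1], i))
        return [items[i] for i in order]


@dataclass(frozen=True)
class PatternSet:
    """Deterministic haplotype constraints observed in the study region.

    anchors
        Loci (framework genes) present on every haplotype.
    together
        Unordered locus pairs in complete positive LD: on any haplotype the
        two genes are either both present or both absent.
    exclusive
        Unordered locus pairs in complete negative LD (allelic variants of
        one ancestral locus): exactly one of the two is present on every
        haplotype.

    All loci are 0-based internal indices; user-facing I/O is 1-based.
    """

    anchors: frozenset[int] = frozenset()
    together: frozenset[tuple[int, int]] = frozenset()
    exclusive: frozenset[tuple[int, int]] = frozenset()
    n_loci: int | None = None

    def __post_init__(self) -> None:
        anchors = frozenset(int(a) for a in self.anchors)
        together = frozenset(self._norm_pair(p) for p in self.together)
        exclusive = frozenset(self._norm_pair(p) for p in self.exclusive)
        object.__setattr__(self, "anchors", anchors)
        object.__setattr__(self, "together", together)
        object.__setattr__(self, "exclusive", exclusive)
        loci = set(anchors)
        for i, j in together | exclusive:
            loci.update((i, j))
        if any(l < 0 for l in loci):
            raise ValueError("pattern loci must be non-negative")
        if self.n_loci is not None and any(l >= self.n_loci for l in loci):
            raise ValueError("pattern locus out of range for the panel")
        if together & exclusive:
            raise ValueError("a pair cannot be both 'together' and 'exclusive'")
        excl_loci = {l for p in exclusive for l in p}
        if anchors & excl_loci:
            raise ValueError("anchor loci cannot be members of exclusive pairs")

    @staticmethod
    def _norm_pair(p: Sequence[int]) -> tuple[int, int]:
        i, j = int(p[0]), int(p[1])
        if i == j:
            raise ValueError("pattern pairs must involve two distinct loci")
        return (i, j) if i < j else (j, i)

    def is_empty(self) -> bool:
        return not (self.anchors or self.together or self.exclusive)

    @classmethod
    def from_config(
        cls, config: Mapping, loci: LocusPanel | None = None, n_loci: int | None = None
    ) -> "PatternSet":
        """Build from a configuration mapping with 1-based positions or names."""

        def resolve(v) -> int:
            if isinstance(v, str):
                if loci is None:
                    raise ValueError(f"locus name {v!r} given but no locus panel")
                return loci.index(v)
            idx = int(v) - 1
            if idx < 0:
                raise ValueError(f"1-based locus positions must be >= 1, got {v}")
            return idx

        if n_loci is None and loci is not None:
            n_loci = len(loci)
        return cls(
            anchors=frozenset(resolve(a) for a in config.get("anchors", ())),
            together=frozenset(
                (resolve(p[0]), resolve(p[1])) for p in config.get("together", ())
            ),
            exclusive=frozenset(
                (resolve(p[0]), resolve(p[1])) for p in config.get("exclusive", ())
            ),
            n_loci=n_loci,
        )


def collapse_panel(
    haplotypes: Sequence[Haplotype],
    external: Sequence[bool] | None = None,
) -> WeightedReferencePanel:
    """Collapse a haplotype multiset into a weighted panel of unique entries.

    Weights equal input multiplicities, so total weight equals the input
    count; an entry is flagged external if any contributing copy was.
    """
    if len(haplotypes) == 0:
        raise ValueError("cannot collapse an empty haplotype list")
    if external is None:
        external = [False] * len(haplotypes)
    if len(external) != len(haplotypes):
        raise ValueError("external flags must align with haplotypes")
    lengths = {len(h) for h in haplotypes}
    if len(lengths) != 1:
        raise ValueError("haplotypes must have uniform length")
    weights: dict[Haplotype, float] = {}
    ext: dict[Haplotype, bool] = {}
    for h, e in zip(haplotypes, external):
        weights[h] = weights.get(h, 0.0) + 1.0
        ext[h] = ext.get(h, False) or bool(e)
    uniq = list(weights)
    return WeightedReferencePanel(
        haplotypes=tuple(uniq),
        weights=tuple(weights[h] for h in uniq),
        external=tuple(ext[h] for h in uniq),
    )


def observe(true_diplotype: Diplotype, dialect: Dialect = Dialect.PRESENT_ABSENT) -> ObservedGenotype:
    """Deterministically reduce a true diplotype to its observed genotype.

    Present-absent dialect: copy sum 0 maps to ABSENT, copy sum >= 1 to
    PRESENT (the second chromosome's status is lost).  Full dialect keeps
    the exact copy number (sum 0 is ABSENT in both dialects).
    """
    codes = []
    for l in range(len(true_diplotype)):
        s = true_diplotype.copy_sum(l)
        if s == 0:
            codes.append(Code.ABSENT)
        elif dialect is Dialect.PRESENT_ABSENT:
            codes.append(Code.PRESENT)
        else:
            codes.append(Code.full(s))
    return ObservedGenotype(tuple(codes), dialect)


def pair_compatible_with_observation(
    h1: Haplotype, h2: Haplotype, obs: ObservedGenotype
) -> bool:
    """True iff the unordered pair could have produced the observed codes."""
    for l, c in enumerate(obs.codes):
        s = h1.alleles[l] + h2.alleles[l]
        if c in (Code.ABSENT, Code.FULL0):
            if s != 0:
                return False
        elif c is Code.PRESENT:
            if s == 0:
                return False
        elif c is Code.FULL1:
            if s != 1:
                return False
        elif c is Code.FULL2:
            if s != 2:
                return False
        # MISSING imposes nothing
    return True
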