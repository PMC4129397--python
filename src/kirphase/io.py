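"""Plain-text file formats: haplotype panels, genotype matrices, patterns.

Gene-content presence/absence has no standard variant representation, so
the package uses small TSV files with ``#``-prefixed metadata lines:

* haplotype panel: optional ``#loci:`` header naming the columns, then rows
  ``id <TAB> frequency-or-. <TAB> a_1 ... a_L`` with alleles 0/1;
* genotype matrix: a ``#dialect:`` tag, a header row ``sample`` + locus
  names, then one row per individual with codes ``A``/``P``/``M``
  (present-absent) or ``0``/``1``/``2``/``M`` (full dialect);
* pattern configuration: YAML or JSON with keys ``anchors``, ``together``,
  ``exclusive``; loci as 1-based column positions or panel names.

All user-facing locus positions are 1-based; internal indices are 0-based.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import yaml

from .datamodel import (
    Code,
    Dialect,
    Diplotype,
    FrequencyTable,
    Haplotype,
    LocusPanel,
    ObservedGenotype,
    PatternSet,
)

__all__ = [
    "FormatError",
    "read_haplotypes",
    "write_haplotypes",
    "read_genotypes",
    "write_genotypes",
    "read_patterns",
    "write_patterns",
    "write_phased",
    "write_frequencies",
    "table1_path",
    "kir_patterns_path",
]


class FormatError(ValueError):
    """Malformed input file."""


_PA_TO_CHAR = {Code.ABSENT: "A", Code.PRESENT: "P", Code.MISSING: "M"}
_CHAR_TO_PA = {v: k for k, v in _PA_TO_CHAR.items()}
_FULL_TO_CHAR = {Code.ABSENT: "0", Code.FULL0: "0", Code.FULL1: "1", Code.FULL2: "2", Code.MISSING: "M"}
_CHAR_TO_FULL = {"0": Code.ABSENT, "1": Code.FULL1, "2": Code.FULL2, "M": Code.MISSING}


def table1_path() -> Path:
    """Bundled 17-haplotype, 14-locus reference panel with frequencies."""
    return Path(__file__).parent / "data" / "table1_haplotypes.tsv"


def kir_patterns_path() -> Path:
    """Bundled KIR pattern configuration (anchors, together, exclusive)."""
    return Path(__file__).parent / "data" / "kir_patterns.yaml"


def read_haplotypes(
    path: str | Path,
) -> tuple[LocusPanel | None, list[Haplotype], FrequencyTable | None]:
    """Read a haplotype panel TSV; frequencies are optional ('.')."""
    loci: LocusPanel | None = None
    ids: list[str] = []
    haps: list[Haplotype] = []
    freqs: list[float | None] = []
    n_alleles: int | None = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            if line.startswith("#loci:"):
                names = line[len("#loci:"):].split()
                loci = LocusPanel(tuple(names))
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected id, frequency and alleles")
        hid, freq_s, alleles = fields[0], fields[1], fields[2:]
        if hid in ids:
            raise FormatError(f"{path}:{lineno}: duplicate haplotype id {hid!r}")
        if n_alleles is None:
            n_alleles = len(alleles)
        elif len(alleles) != n_alleles:
            raise FormatError(f"{path}:{lineno}: ragged row ({len(alleles)} alleles, expected {n_alleles})")
        if any(a not in ("0", "1") for a in alleles):
            raise FormatError(f"{path}:{lineno}: alleles must be 0 or 1")
        ids.append(hid)
        haps.append(Haplotype(tuple(int(a) for a in alleles)))
        freqs.append(None if freq_s == "." else float(freq_s))
    if not haps:
        raise FormatError(f"{path}: no haplotypes found")
    if loci is not None and len(loci) != len(haps[0]):
        raise FormatError(f"{path}: #loci header does not match allele columns")
    has_freq = [f is not None for f in freqs]
    if any(has_freq) and not all(has_freq):
        raise FormatError(f"{path}: frequencies must be given for all rows or none")
    table = FrequencyTable(dict(zip(haps, freqs))) if all(has_freq) else None
    return loci, haps, table


def write_haplotypes(
    path: str | Path,
    haplotypes: Sequence[Haplotype],
    frequencies: FrequencyTable | Mapping[Haplotype, float] | None = None,
    loci: LocusPanel | None = None,
    ids: Sequence[str] | None = None,
) -> None:
    lines = []
    if loci is not None:
        lines.append("#loci:\t" + "\t".join(loci.names))
    for k, h in enumerate(haplotypes):
        hid = ids[k] if ids is not None else str(k + 1)
        f = "." if frequencies is None else format(frequencies[h], "g")
        lines.append("\t".join([hid, f] + [str(a) for a in h.alleles]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotypes(
    path: str | Path,
) -> tuple[LocusPanel, list[str], list[ObservedGenotype]]:
    """Read a genotype matrix; the dialect comes from the ``#dialect:`` tag."""
    dialect: Dialect | None = None
    header: list[str] | None = None
    sample_ids: list[str] = []
    rows: list[ObservedGenotype] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            if line.startswith("#dialect:"):
                tag = line[len("#dialect:"):].strip()
                try:
                    dialect = Dialect(tag)
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: unknown dialect {tag!r}") from exc
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            if header[0] != "sample" or len(header) < 2:
                raise FormatError(f"{path}:{lineno}: header must be 'sample' + locus names")
            continue
        if dialect is None:
            raise FormatError(f"{path}: missing '#dialect:' tag")
        if len(fields) != len(header):
            raise FormatError(f"{path}:{lineno}: ragged row")
        mapping = _CHAR_TO_PA if dialect is Dialect.PRESENT_ABSENT else _CHAR_TO_FULL
        codes = []
        for tok in fields[1:]:
            if tok not in mapping:
                raise FormatError(
                    f"{path}:{lineno}: unknown code {tok!r} for the {dialect.value} dialect"
                )
            codes.append(mapping[tok])
        sample_ids.append(fields[0])
        rows.append(ObservedGenotype(tuple(codes), dialect))
    if header is None or not rows:
        raise FormatError(f"{path}: no genotype rows found")
    return LocusPanel(tuple(header[1:])), sample_ids, rows


def write_genotypes(
    path: str | Path,
    observations: Sequence[ObservedGenotype],
    loci: LocusPanel | None = None,
    sample_ids: Sequence[str] | None = None,
) -> None:
    if not observations:
        raise ValueError("nothing to write")
    dialect = observations[0].dialect
    if any(o.dialect is not dialect for o in observations):
        raise ValueError("mixed dialects in one dataset")
    L = len(observations[0])
    if loci is None:
        loci = LocusPanel.generic(L)
    mapping = _PA_TO_CHAR if dialect is Dialect.PRESENT_ABSENT else _FULL_TO_CHAR
    lines = [f"#dialect: {dialect.value}", "\t".join(["sample"] + list(loci.names))]
    for k, o in enumerate(observations):
        sid = sample_ids[k] if sample_ids is not None else f"S{k + 1}"
        lines.append("\t".join([sid] + [mapping[c] for c in o.codes]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_patterns(path: str | Path, loci: LocusPanel | None = None) -> PatternSet:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        config = json.loads(text)
    else:
        config = yaml.safe_load(text)
    if not isinstance(config, Mapping):
        raise FormatError(f"{path}: pattern file must contain a mapping")
    return PatternSet.from_config(config, loci=loci)


def write_patterns(path: str | Path, patterns: PatternSet) -> None:
    config = {
        "anchors": sorted(a + 1 for a in patterns.anchors),
        "together": [[i + 1, j + 1] for i, j in sorted(patterns.together)],
        "exclusive": [[i + 1, j + 1] for i, j in sorted(patterns.exclusive)],
    }
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def write_phased(
    path: str | Path,
    diplotypes: Sequence[Diplotype],
    support: Sequence[float] | None = None,
    loci: LocusPanel | None = None,
    sample_ids: Sequence[str] | None = None,
) -> None:
    """Two haplotype rows per sample with the consensus support fraction."""
    if not diplotypes:
        raise ValueError("nothing to write")
    L = len(diplotypes[0])
    if loci is None:
        loci = LocusPanel.generic(L)
    lines = ["\t".join(["sample", "haplotype", "support"] + list(loci.names))]
    for k, d in enumerate(diplotypes):
        sid = sample_ids[k] if sample_ids is not None else f"S{k + 1}"
        s = format(support[k], "g") if support is not None else "."
        for which, h in enumerate(d.pair, start=1):
            lines.append("\t".join([sid, str(which), s] + [str(a) for a in h.alleles]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_frequencies(
    path: str | Path, table: FrequencyTable, loci: LocusPanel | None = None
) -> None:
    write_haplotypes(
        path,
        [h for h, _ in table.by_frequency()],
        frequencies=table,
        loci=loci,
    )
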