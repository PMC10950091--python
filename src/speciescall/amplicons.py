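"""Minimal allele-probe genotyper for single-end amplicon reads.

GT-seq genotyping counts, per locus, the reads carrying each allele's short
in-silico probe (the allele base plus flanking context) and converts the two
counts into a genotype by depth and allele-ratio thresholds.  This module
implements that path for multiple SNPs per amplicon -- each variant position
has its own probe pair, so one amplicon's reads can be genotyped at several
loci -- plus a synthetic read generator so the whole FASTQ -> genotypes ->
species-call pipeline is testable offline.

The genotype-calling thresholds here are documented configuration defaults of
this package, not a reproduction of any particular production pipeline's
values.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
from Bio import SeqIO

from .genotypes import MISSING_CODE, GenotypeMatrix
from .panel import VALID_NUCLEOTIDES, SpeciesPanel
import pandas as pd

__all__ = [
    "READ_LENGTH",
    "AlleleProbe",
    "LocusCounts",
    "design_probes",
    "parse_probe_seq",
    "write_probe_seq",
    "count_probe_hits",
    "call_genotype_from_counts",
    "genotype_reads",
    "generate_synthetic_fastq",
]

#: Single-end read length of the targeted sequencing chemistry.
READ_LENGTH = 77

_NUCS = ("A", "C", "G", "T")


@dataclass(frozen=True)
class AlleleProbe:
    """Allele-specific oligonucleotide probe for one locus allele."""

    locus_id: str
    allele: str
    probe_seq: str
    amplicon_id: str

    def __post_init__(self) -> None:
        if self.allele not in VALID_NUCLEOTIDES:
            raise ValueError(f"{self.locus_id}: invalid allele {self.allele!r}")
        seq = self.probe_seq.upper()
        object.__setattr__(self, "probe_seq", seq)
        if not seq or any(c not in VALID_NUCLEOTIDES for c in seq):
            raise ValueError(f"{self.locus_id}: invalid probe sequence {seq!r}")
        if len(seq) >= READ_LENGTH:
            raise ValueError(
                f"{self.locus_id}: probe ({len(seq)} bp) must be shorter than "
                f"the {READ_LENGTH} bp read length"
            )


@dataclass
class LocusCounts:
    """Per-locus read support for the two alleles."""

    count_allele1: int = 0
    count_allele2: int = 0

    @property
    def total(self) -> int:
        return self.count_allele1 + self.count_allele2


def _amplicon_of(locus_id: str) -> str:
    # locus ids are "<amplicon>-<position>[b]"
    return locus_id.rsplit("-", 1)[0] if "-" in locus_id else locus_id


def design_probes(
    panel: SpeciesPanel, flank: int = 7, seed: int = 0
) -> list[AlleleProbe]:
    """Synthesise a probe pair per panel entry: the allele base embedded in
    random flanking context (same flanks for the two alleles of an entry, so
    the pair differs at exactly the variant base).  Deterministic per seed;
    regenerates on the rare collision between probes of different loci."""
    rng = np.random.default_rng(seed)
    probes: list[AlleleProbe] = []
    seen: set[str] = set()
    for entry in panel:
        for _ in range(100):
            left = "".join(rng.choice(_NUCS, size=flank))
            right = "".join(rng.choice(_NUCS, size=flank))
            pair = [left + a + right for a in (entry.allele1, entry.allele2)]
            if not any(p in seen for p in pair):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not find collision-free probes")
        seen.update(pair)
        amplicon = _amplicon_of(entry.locus_id)
        probes.append(AlleleProbe(entry.locus_id, entry.allele1, pair[0], amplicon))
        probes.append(AlleleProbe(entry.locus_id, entry.allele2, pair[1], amplicon))
    return probes


def parse_probe_seq(source: TextIO | str) -> list[AlleleProbe]:
    """Parse a probe-seq CSV (columns: locus, amplicon, allele, probe).

    Multiple loci may share an amplicon id; duplicate (locus, allele) rows
    and single-probe loci are rejected.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    rows = [r for r in csv.reader(source) if r]
    if rows and rows[0] and rows[0][0].lower() in {"locus", "locus_id"}:
        rows = rows[1:]
    probes: list[AlleleProbe] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(rows, start=1):
        if len(row) != 4:
            raise ValueError(f"probe row {i}: expected 4 fields, found {len(row)}")
        locus, amplicon, allele, seq = (f.strip() for f in row)
        key = (locus, allele.upper())
        if key in seen:
            raise ValueError(f"probe row {i}: duplicate probe for {key}")
        seen.add(key)
        probes.append(AlleleProbe(locus, allele.upper(), seq, amplicon))
    by_locus: dict[str, list[AlleleProbe]] = {}
    for p in probes:
        by_locus.setdefault(p.locus_id, []).append(p)
    for locus, pair in by_locus.items():
        if len(pair) != 2:
            raise ValueError(f"{locus}: expected 2 allele probes, found {len(pair)}")
        if pair[0].probe_seq == pair[1].probe_seq:
            raise ValueError(f"{locus}: the two allele probes are identical")
    return probes


def write_probe_seq(probes: Sequence[AlleleProbe], dest: TextIO | str) -> None:
    handle: TextIO
    close = False
    if isinstance(dest, str):
        handle = open(dest, "w", encoding="utf-8", newline="")
        close = True
    else:
        handle = dest
    try:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["locus", "amplicon", "allele", "probe"])
        for p in probes:
            writer.writerow([p.locus_id, p.amplicon_id, p.allele, p.probe_seq])
    finally:
        if close:
            handle.close()


def _read_sequences(reads: Iterable[str] | TextIO | str) -> Iterable[str]:
    if isinstance(reads, str):
        with open(reads) as handle:
            yield from (str(r.seq) for r in SeqIO.parse(handle, "fastq"))
        return
    if hasattr(reads, "read"):
        yield from (str(r.seq) for r in SeqIO.parse(reads, "fastq"))
        return
    yield from reads


def count_probe_hits(
    reads: Iterable[str] | TextIO | str, probes: Sequence[AlleleProbe]
) -> dict[str, LocusCounts]:
    """Exact forward-orientation substring counting of each probe against
    each read: one increment per (read, probe) hit.  *reads* may be a FASTQ
    path, an open FASTQ handle, or an iterable of sequence strings.
    Read-order invariant by construction."""
    by_locus: dict[str, LocusCounts] = {}
    probe_pairs: dict[str, dict[str, str]] = {}
    for p in probes:
        by_locus.setdefault(p.locus_id, LocusCounts())
        probe_pairs.setdefault(p.locus_id, {})[p.allele] = p.probe_seq
    # fixed allele order per locus: probe file order
    ordered: list[tuple[str, str, str]] = []
    done: set[str] = set()
    for p in probes:
        if p.locus_id in done:
            continue
        alleles = list(probe_pairs[p.locus_id].items())
        ordered.append((p.locus_id, alleles[0][1], alleles[1][1]))
        done.add(p.locus_id)
    for seq in _read_sequences(reads):
        seq = seq.upper()
        for locus, probe1, probe2 in ordered:
            counts = by_locus[locus]
            if probe1 in seq:
                counts.count_allele1 += 1
            if probe2 in seq:
                counts.count_allele2 += 1
    return by_locus


def call_genotype_from_counts(
    counts: LocusCounts,
    allele1: str,
    allele2: str,
    min_depth: int = 10,
    hom_ratio: float = 0.9,
    het_band: tuple[float, float] = (0.2, 0.8),
) -> str:
    """Convert allele counts to a two-character genotype code.

    ``r = c1 / (c1 + c2)``; total depth below *min_depth* or ``r`` in the
    ambiguous gaps between the homozygote and heterozygote bands yields the
    missing code.  Thresholds are configurable package defaults.
    """
    lo, hi = het_band
    if not 0 <= 1 - hom_ratio <= lo < hi <= hom_ratio <= 1:
        raise ValueError("require 0 <= 1-hom_ratio <= lo < hi <= hom_ratio <= 1")
    if counts.total < min_depth:
        return MISSING_CODE
    r = counts.count_allele1 / counts.total
    if r >= hom_ratio:
        return allele1 * 2
    if r <= 1 - hom_ratio:
        return allele2 * 2
    if lo <= r <= hi:
        return "".join(sorted(allele1 + allele2))
    return MISSING_CODE


def genotype_reads(
    reads: Iterable[str] | TextIO | str,
    probes: Sequence[AlleleProbe],
    sample_id: str = "sample",
    min_depth: int = 10,
    hom_ratio: float = 0.9,
    het_band: tuple[float, float] = (0.2, 0.8),
) -> GenotypeMatrix:
    """Full probe path for one sample: count hits, call genotypes, and wrap
    the result as a single-row wide-format :class:`GenotypeMatrix`."""
    counts = count_probe_hits(reads, probes)
    allele_order: dict[str, list[str]] = {}
    for p in probes:
        allele_order.setdefault(p.locus_id, []).append(p.allele)
    codes = {
        locus: call_genotype_from_counts(
            counts[locus],
            allele_order[locus][0],
            allele_order[locus][1],
            min_depth=min_depth,
            hom_ratio=hom_ratio,
            het_band=het_band,
        )
        for locus in counts
    }
    calls = pd.DataFrame([codes], index=pd.Index([sample_id], name="Sample"))
    return GenotypeMatrix(calls=calls, extra=calls.iloc[:, :0])


def generate_synthetic_fastq(
    panel: SpeciesPanel,
    probes: Sequence[AlleleProbe],
    species: str,
    dest: TextIO | str,
    depth: int = 50,
    error_rate: float = 0.0,
    dropout: float = 0.0,
    seed: int = 0,
) -> int:
    """Write synthetic single-end reads for an individual of *species*.

    For each informative locus the expected allele's probe is embedded at a
    random offset in a random background read of :data:`READ_LENGTH` bases;
    per-base errors are applied at *error_rate*.  *dropout* removes a random
    fraction of informative loci entirely, emulating the reduced genotyping
    success of non-target species on a species-specific panel.  Returns the
    number of reads written; deterministic per seed.
    """
    if species not in panel.species:
        raise KeyError(f"unknown species code {species!r}")
    rng = np.random.default_rng(seed)
    probe_of = {(p.locus_id, p.allele): p.probe_seq for p in probes}
    handle: TextIO
    close = False
    if isinstance(dest, str):
        handle = open(dest, "w", encoding="utf-8", newline="")
        close = True
    else:
        handle = dest
    n_written = 0
    try:
        for locus in panel.informative_loci(species):
            if dropout and rng.random() < dropout:
                continue
            genotype = panel.expected_genotype(species, locus)
            assert genotype is not None
            probe = probe_of[(locus, genotype[0])]
            slack = READ_LENGTH - len(probe)
            for i in range(depth):
                offset = int(rng.integers(slack + 1))
                read = rng.choice(_NUCS, size=READ_LENGTH)
                read[offset : offset + len(probe)] = list(probe)
                if error_rate:
                    errs = rng.random(READ_LENGTH) < error_rate
                    if errs.any():
                        shift = rng.integers(1, 4, size=int(errs.sum()))
                        idx = np.nonzero(errs)[0]
                        originals = np.array(
                            [_NUCS.index(b) for b in read[idx]]
                        )
                        read[idx] = [
                            _NUCS[(o + s) % 4] for o, s in zip(originals, shift)
                        ]
                seq = "".join(read)
                handle.write(f"@{species}_{locus}_{i}\n{seq}\n+\n{'I' * READ_LENGTH}\n")
                n_written += 1
    finally:
        if close:
            handle.close()
    return n_written
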