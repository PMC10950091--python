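"""Wide-format genotype tables and per-entry genotype classification.

GT-seq genotyping pipelines emit one row per sample and one column per locus,
each cell holding a two-character nucleotide genotype (``AA``, ``AG``...) or a
missing code.  This module reads and writes that format, normalises missing
codes, and classifies a genotype code against a species-seq entry.
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

import pandas as pd

from .panel import VALID_NUCLEOTIDES, SpeciesSeqEntry

__all__ = [
    "MISSING_CODE",
    "GenotypeClass",
    "GenotypeMatrix",
    "normalize_code",
    "classify_genotype",
    "read_wide_genotypes",
    "write_wide_genotypes",
    "append_call_columns",
]

#: Canonical missing-genotype code emitted by this package.
MISSING_CODE = "00"

#: Raw spellings normalised to :data:`MISSING_CODE` on input.
_MISSING_ALIASES = {"", "0", "00", "NA", "N/A", "NAN", "--", "."}


class GenotypeClass(enum.Enum):
    """Classification of a genotype code relative to one species-seq entry.

    Exactly one class applies to every (code, entry) pair.  ``FOREIGN`` marks
    a genotype carrying an allele outside the entry's two alleles -- e.g. the
    third allele of a tri-allelic site seen through the other entry of its
    pair.  Foreign genotypes never contribute to scores but are tallied for
    diagnostics.
    """

    HOM_ALLELE1 = "hom_allele1"
    HOM_ALLELE2 = "hom_allele2"
    HETEROZYGOUS = "heterozygous"
    MISSING = "missing"
    FOREIGN = "foreign"


def normalize_code(code: object) -> str:
    """Normalise a raw genotype cell: uppercase, canonical missing code."""
    if code is None or (isinstance(code, float) and pd.isna(code)):
        return MISSING_CODE
    text = str(code).strip().upper()
    if text in _MISSING_ALIASES:
        return MISSING_CODE
    return text


def classify_genotype(code: str, entry: SpeciesSeqEntry) -> GenotypeClass:
    """Classify a normalised two-character genotype against *entry*.

    The two allele characters are an unordered pair: ``AG`` and ``GA`` are
    both heterozygous for an A/G entry.
    """
    if code == MISSING_CODE:
        return GenotypeClass.MISSING
    if len(code) != 2 or any(c not in VALID_NUCLEOTIDES for c in code):
        return GenotypeClass.MISSING
    a, b = code[0], code[1]
    alleles = {entry.allele1, entry.allele2}
    if a not in alleles or b not in alleles:
        return GenotypeClass.FOREIGN
    if a != b:
        return GenotypeClass.HETEROZYGOUS
    if a == entry.allele1:
        return GenotypeClass.HOM_ALLELE1
    return GenotypeClass.HOM_ALLELE2


def _is_genotype_column(values: Iterable[str]) -> bool:
    for v in values:
        code = normalize_code(v)
        if code == MISSING_CODE:
            continue
        if len(code) != 2 or any(c not in VALID_NUCLEOTIDES for c in code):
            return False
    return True


@dataclass
class GenotypeMatrix:
    """Samples x loci genotype calls plus verbatim passthrough columns.

    ``calls`` is a string DataFrame indexed by sample id with one column per
    locus (normalised codes, :data:`MISSING_CODE` for missing).  ``extra``
    preserves any non-genotype columns bit-exactly, and ``column_order``
    remembers the original on-disk column sequence so writing reproduces it.
    """

    calls: pd.DataFrame
    extra: pd.DataFrame
    sample_column: str = "Sample"
    column_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.calls.index.has_duplicates:
            dups = self.calls.index[self.calls.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        if not self.column_order:
            self.column_order = tuple(self.extra.columns) + tuple(self.calls.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    def genotypes_of(self, sample_id: str) -> dict[str, str]:
        """Locus -> genotype code mapping for one sample."""
        return self.calls.loc[sample_id].to_dict()

    def to_frame(self) -> pd.DataFrame:
        """Reassemble the original wide table (original column order)."""
        merged = pd.concat([self.extra, self.calls], axis=1)
        frame = merged[list(self.column_order)].copy()
        frame.insert(0, self.sample_column, self.calls.index)
        return frame.reset_index(drop=True)


def read_wide_genotypes(source: TextIO | str) -> GenotypeMatrix:
    """Read a comma-separated wide genotype table.

    The first column is the sample id; every remaining column whose values
    all look like genotype codes (or missing) is treated as a locus, other
    columns are carried through verbatim.  Loci that are absent from a panel
    are simply ignored by panel-aware steps downstream.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    rows = [row for row in csv.reader(source) if row]
    if len(rows) < 2:
        raise ValueError("genotype table needs a header row and >=1 sample row")
    header = rows[0]
    width = len(header)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ValueError(
                f"row {i}: expected {width} fields, found {len(row)} (ragged table)"
            )
    frame = pd.DataFrame(rows[1:], columns=header, dtype=str)
    sample_column = header[0]
    samples = frame[sample_column]
    if samples.duplicated().any():
        dups = samples[samples.duplicated()].tolist()
        raise ValueError(f"duplicate sample IDs: {dups}")
    body = frame.drop(columns=[sample_column])
    body.index = pd.Index(samples, name=sample_column)
    locus_cols = [c for c in body.columns if _is_genotype_column(body[c])]
    extra_cols = [c for c in body.columns if c not in locus_cols]
    calls = body[locus_cols].map(normalize_code)
    return GenotypeMatrix(
        calls=calls,
        extra=body[extra_cols],
        sample_column=sample_column,
        column_order=tuple(body.columns),
    )


def write_wide_genotypes(matrix: GenotypeMatrix, dest: TextIO | str) -> None:
    """Write *matrix* back to CSV, preserving the input column order."""
    matrix.to_frame().to_csv(dest, index=False)


def append_call_columns(
    matrix: GenotypeMatrix, calls: Sequence["SpeciesCall"]
) -> pd.DataFrame:
    """Return the wide table with two appended columns.

    ``SpeciesCall`` holds the rendered species call (semicolon-delimited
    candidates, ``-ReviewHET`` suffix, ``NoCall`` sentinel) and
    ``HetGenotyped`` the count string ``HET=<h>;GT=<g>`` over
    species-informative loci.  Original columns are untouched; *calls* must
    align one-to-one with the matrix rows.
    """
    if len(calls) != len(matrix.sample_ids):
        raise ValueError(
            f"{len(calls)} calls for {len(matrix.sample_ids)} samples"
        )
    frame = matrix.to_frame()
    frame["SpeciesCall"] = [c.render() for c in calls]
    frame["HetGenotyped"] = [
        f"HET={c.het_count};GT={c.genotyped_count}" for c in calls
    ]
    return frame
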