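"""Species-seq panel definitions.

A *species-seq* file describes a panel of species-informative SNP loci for
amplicon (GT-seq) genotyping.  Each row maps the two alleles of a bi-allelic
variant to the sets of species expected to be homozygous for that allele, and
assigns the locus a scoring weight.  Tri-allelic variant positions are encoded
as two bi-allelic rows sharing the variant position but carrying distinct
locus ids, so the downstream scorer can stay strictly bi-allelic.

The file dialect accepted here is six delimiter-separated columns::

    locus_id, allele1, allele2, assoc1, assoc2, weight

with comma or tab as the column delimiter (auto-sniffed), an optional header
row (auto-detected), and association sets written as ``:``-separated species
codes (``;`` also accepted).  An empty association field means the allele has
no species associated with it -- species whose genotype at a locus is
polymorphic, or which fail to amplify there, are simply omitted from both
sides.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

__all__ = [
    "VALID_NUCLEOTIDES",
    "DEFAULT_SPECIES_CODES",
    "PanelError",
    "PanelFormatError",
    "PanelValidationError",
    "SpeciesSeqEntry",
    "SpeciesPanel",
    "CallParams",
    "parse_species_seq",
    "read_species_seq",
    "write_species_seq",
]

VALID_NUCLEOTIDES = frozenset("ACGT")

#: Species-code vocabulary used by the bundled salmonid reference panel:
#: genus initial + first two letters of the species epithet, with the two
#: Cutthroat Trout subspecies groups disambiguated as Ocl1/Ocl2.  Codes are
#: free strings elsewhere in the package; this tuple is documentation, not an
#: enforced registry.
DEFAULT_SPECIES_CODES = (
    "Ocl1",  # Coastal Cutthroat Trout (O. clarkii clarkii)
    "Ocl2",  # Yellowstone/Bonneville Cutthroat Trout
    "Ogo",   # Pink Salmon (O. gorbuscha)
    "Oke",   # Chum Salmon (O. keta)
    "Oki",   # Coho Salmon (O. kisutch)
    "Oma",   # Masu Salmon (O. masou)
    "Omy",   # Steelhead/Rainbow Trout (O. mykiss)
    "One",   # Sockeye Salmon (O. nerka)
    "Ots",   # Chinook Salmon (O. tshawytscha)
    "Sco",   # Bull Trout (Salvelinus confluentus)
    "Sfo",   # Brook Trout (Salvelinus fontinalis)
    "Ssa",   # Atlantic Salmon (Salmo salar)
    "Str",   # Brown Trout (Salmo trutta)
)

_ASSOC_SPLIT = re.compile(r"[:;|]")


class PanelError(ValueError):
    """Base class for species-seq problems."""


class PanelFormatError(PanelError):
    """Malformed species-seq text (wrong column count, bad numbers...)."""


class PanelValidationError(PanelError):
    """Structurally parseable but semantically invalid panel content."""


@dataclass(frozen=True)
class SpeciesSeqEntry:
    """One bi-allelic species-seq row.

    Parameters
    ----------
    locus_id:
        Unique locus name; by convention the amplicon name plus the 1-based
        variant position counted from the first base of the forward primer.
    allele1, allele2:
        The two single-nucleotide alleles (distinct, from ``ACGT``).
    assoc1, assoc2:
        Disjoint sets of species codes expected homozygous for allele 1 and
        allele 2 respectively.  Their union may omit species.
    weight:
        Positive locus-specific scoring weight ``w``.  The salmonid reference
        panel uses 2 for variants diagnostic of a single species and 1 for
        variants informative for a subset of species.
    """

    locus_id: str
    allele1: str
    allele2: str
    assoc1: frozenset[str]
    assoc2: frozenset[str]
    weight: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "assoc1", frozenset(self.assoc1))
        object.__setattr__(self, "assoc2", frozenset(self.assoc2))
        for allele in (self.allele1, self.allele2):
            if allele not in VALID_NUCLEOTIDES:
                raise PanelValidationError(
                    f"{self.locus_id}: invalid nucleotide {allele!r}"
                )
        if self.allele1 == self.allele2:
            raise PanelValidationError(
                f"{self.locus_id}: alleles must differ (both {self.allele1!r})"
            )
        if self.assoc1 & self.assoc2:
            both = ",".join(sorted(self.assoc1 & self.assoc2))
            raise PanelValidationError(
                f"{self.locus_id}: species on both alleles: {both}"
            )
        if not (self.assoc1 or self.assoc2):
            raise PanelValidationError(
                f"{self.locus_id}: entry associates no species at all"
            )
        if not self.weight > 0:
            raise PanelValidationError(
                f"{self.locus_id}: weight must be positive, got {self.weight}"
            )

    @property
    def species(self) -> frozenset[str]:
        """All species associated with either allele of this entry."""
        return self.assoc1 | self.assoc2

    def expected_genotype(self, species: str) -> str | None:
        """Homozygous genotype expected for *species*, or None if omitted."""
        if species in self.assoc1:
            return self.allele1 * 2
        if species in self.assoc2:
            return self.allele2 * 2
        return None


@dataclass(frozen=True)
class CallParams:
    """Thresholds of the species-calling decision rule.

    thres_ms:
        Minimum proportion of the *absolute maximum* score (``S/M``) that at
        least one species must reach before any call is made.  With equal
        locus weights this corresponds to the genotyping success rate over
        species-informative loci.
    buff_mp:
        Candidate buffer: species whose proportion of *maximum possible*
        score (``S/P``) lies within ``buff_mp`` of the best observed
        proportion are co-reported as candidates.
    prune_ms:
        When multiple candidates remain, those with ``S/M`` below this
        proportion are pruned -- they are supported by too few loci even if
        every locus they did genotype at agrees with them.
    thres_het:
        Heterozygosity review threshold: when the fraction of heterozygous
        calls among successfully genotyped species-informative loci exceeds
        this value the call is flagged ``ReviewHET`` (possible contamination,
        interspecific hybrid, or shared polymorphism).
    """

    thres_ms: float = 0.5
    buff_mp: float = 1e-3
    prune_ms: float = 0.34
    thres_het: float = 0.06

    def __post_init__(self) -> None:
        for name in ("thres_ms", "prune_ms", "thres_het"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.buff_mp < 0:
            raise ValueError(f"buff_mp must be non-negative, got {self.buff_mp}")


class SpeciesPanel:
    """An ordered, validated collection of :class:`SpeciesSeqEntry` rows."""

    def __init__(self, entries: Iterable[SpeciesSeqEntry]):
        self.entries: tuple[SpeciesSeqEntry, ...] = tuple(entries)
        if not self.entries:
            raise PanelValidationError("panel has no entries")
        seen: set[str] = set()
        for entry in self.entries:
            if entry.locus_id in seen:
                raise PanelValidationError(
                    f"duplicate locus_id {entry.locus_id!r}; tri-allelic "
                    "double entries must carry distinct locus_id suffixes"
                )
            seen.add(entry.locus_id)
        self._by_locus: dict[str, SpeciesSeqEntry] = {
            e.locus_id: e for e in self.entries
        }
        self.species: frozenset[str] = frozenset().union(
            *(e.species for e in self.entries)
        )
        # every species has >=1 informative entry by construction of
        # self.species; positive weights guarantee M_s > 0.

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[SpeciesSeqEntry]:
        return iter(self.entries)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._by_locus

    def __getitem__(self, locus_id: str) -> SpeciesSeqEntry:
        return self._by_locus[locus_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpeciesPanel):
            return NotImplemented
        return self.entries == other.entries

    def __hash__(self) -> int:  # frozen content
        return hash(self.entries)

    @property
    def locus_ids(self) -> tuple[str, ...]:
        return tuple(e.locus_id for e in self.entries)

    # -- bookkeeping --------------------------------------------------------

    def absolute_max_scores(self) -> dict[str, float]:
        """``M_s``: the score each species reaches with complete, expected
        homozygous data -- the sum of weights over its informative entries."""
        totals: dict[str, float] = {s: 0.0 for s in sorted(self.species)}
        for entry in self.entries:
            for s in entry.species:
                totals[s] += entry.weight
        return totals

    def informative_loci(self, species: str) -> list[str]:
        """Locus ids (panel order) at which *species* has an allele
        association, i.e. an expected homozygous genotype."""
        if species not in self.species:
            raise KeyError(f"unknown species code {species!r}")
        return [e.locus_id for e in self.entries if species in e.species]

    def n_informative(self, species: str) -> int:
        return len(self.informative_loci(species))

    def expected_genotype(self, species: str, locus_id: str) -> str | None:
        """Expected homozygous genotype of *species* at *locus_id*; ``None``
        when the species carries no association there."""
        return self._by_locus[locus_id].expected_genotype(species)


# -- file I/O ---------------------------------------------------------------


def _split_assoc(text: str) -> frozenset[str]:
    text = text.strip()
    if not text:
        return frozenset()
    return frozenset(tok.strip() for tok in _ASSOC_SPLIT.split(text) if tok.strip())


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def _looks_like_header(row: Sequence[str]) -> bool:
    # data rows carry a single nucleotide in the allele-1 column; a header
    # carries a column name there.  Malformed rows are not headers -- they
    # must surface as row errors, not be skipped.
    return len(row) == 6 and row[1].strip().upper() not in VALID_NUCLEOTIDES


def parse_species_seq(
    source: TextIO | str, delimiter: str | None = None
) -> SpeciesPanel:
    """Parse a species-seq definition from a text stream or string.

    Raises :class:`PanelFormatError` naming the offending row for malformed
    input and :class:`PanelValidationError` for semantic problems (overlapping
    association sets, invalid nucleotides, duplicate locus ids).
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    text = source.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise PanelFormatError("species-seq source is empty")
    if delimiter is None:
        delimiter = _sniff_delimiter(lines[0])
    rows = list(csv.reader(lines, delimiter=delimiter))
    start = 1 if rows and _looks_like_header(rows[0]) else 0
    entries: list[SpeciesSeqEntry] = []
    for i, row in enumerate(rows[start:], start=start + 1):
        if len(row) != 6:
            raise PanelFormatError(
                f"row {i}: expected 6 fields, found {len(row)}"
            )
        locus, a1, a2, as1, as2, w = (f.strip() for f in row)
        try:
            weight = float(w)
        except ValueError as exc:
            raise PanelFormatError(f"row {i}: weight {w!r} is not a number") from exc
        try:
            entries.append(
                SpeciesSeqEntry(
                    locus_id=locus,
                    allele1=a1.upper(),
                    allele2=a2.upper(),
                    assoc1=_split_assoc(as1),
                    assoc2=_split_assoc(as2),
                    weight=weight,
                )
            )
        except PanelValidationError as exc:
            raise PanelValidationError(f"row {i}: {exc}") from exc
    return SpeciesPanel(entries)


def read_species_seq(path: str, delimiter: str | None = None) -> SpeciesPanel:
    with open(path, "r", encoding="utf-8") as handle:
        return parse_species_seq(handle, delimiter=delimiter)


def write_species_seq(
    panel: SpeciesPanel, dest: TextIO | str, delimiter: str = ",", header: bool = True
) -> None:
    """Write *panel* back to species-seq text (association sets sorted and
    ``:``-joined, so write -> parse round-trips to an equal panel)."""
    handle: TextIO
    close = False
    if isinstance(dest, str):
        handle = open(dest, "w", encoding="utf-8", newline="")
        close = True
    else:
        handle = dest
    try:
        writer = csv.writer(handle, delimiter=delimiter, lineterminator="\n")
        if header:
            writer.writerow(
                ["locus", "allele1", "allele2", "assoc1", "assoc2", "weight"]
            )
        for e in panel:
            w = int(e.weight) if float(e.weight).is_integer() else e.weight
            writer.writerow(
                [
                    e.locus_id,
                    e.allele1,
                    e.allele2,
                    ":".join(sorted(e.assoc1)),
                    ":".join(sorted(e.assoc2)),
                    w,
                ]
            )
    finally:
        if close:
            handle.close()
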