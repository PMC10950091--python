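"""Panel-level diagnostics used during marker validation.

Non-target species on a species-specific GT-seq panel genotype at fewer loci
and show lower heterozygosity than the target species, so per-sample
genotyping success and observed heterozygosity are first-line screens.  For
known-species collections, per-(species, locus) alternative-allele
frequencies verify that loci assumed fixed within a species really are --
segregating loci lose diagnostic value and their species association should
be reviewed and possibly dropped from the species-seq file.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING_CODE, GenotypeClass, GenotypeMatrix, classify_genotype
from .panel import SpeciesPanel

__all__ = [
    "genotyping_success",
    "observed_heterozygosity",
    "sample_summary",
    "species_allele_frequencies",
    "flag_problem_associations",
]


def _check_loci(matrix: GenotypeMatrix, loci: Sequence[str]) -> list[str]:
    loci = list(loci)
    if not loci:
        raise ValueError("locus list is empty")
    absent = [l for l in loci if l not in matrix.calls.columns]
    if absent:
        raise KeyError(f"loci not in matrix: {absent}")
    return loci


def genotyping_success(matrix: GenotypeMatrix, loci: Sequence[str]) -> pd.Series:
    """Per-sample fraction of non-missing calls over *loci*.

    Laboratories commonly require >0.90 on the target panel's polymorphic
    loci as a generic filter against non-target species and poor DNA.
    """
    loci = _check_loci(matrix, loci)
    sub = matrix.calls[loci]
    called = (sub != MISSING_CODE).sum(axis=1)
    return (called / len(loci)).rename("genotyping_success")


def observed_heterozygosity(matrix: GenotypeMatrix, loci: Sequence[str]) -> pd.Series:
    """Per-sample heterozygous fraction among non-missing calls over *loci*
    (0 when nothing genotyped).  A genotype is heterozygous when its two
    characters differ."""
    loci = _check_loci(matrix, loci)
    sub = matrix.calls[loci]
    called = (sub != MISSING_CODE).to_numpy()
    het = sub.map(lambda c: len(c) == 2 and c[0] != c[1]).to_numpy()
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore"):
        ratio = np.where(n_called > 0, het.sum(axis=1) / np.maximum(n_called, 1), 0.0)
    return pd.Series(ratio, index=matrix.calls.index, name="observed_heterozygosity")


def sample_summary(matrix: GenotypeMatrix, loci: Sequence[str]) -> pd.DataFrame:
    """Per-sample genotyping success and observed heterozygosity."""
    return pd.concat(
        [genotyping_success(matrix, loci), observed_heterozygosity(matrix, loci)],
        axis=1,
    )


def species_allele_frequencies(
    matrix: GenotypeMatrix,
    truth: Mapping[str, str],
    panel: SpeciesPanel,
) -> pd.DataFrame:
    """Alternative-allele frequency per (species, panel entry).

    For a species associated with one allele of an entry, the *alternative*
    allele is the entry's other allele.  Frequencies count two alleles per
    homozygote and one per heterozygote, over non-missing, non-foreign
    genotypes of that species' samples.  Pairs with no usable genotypes, and
    species without an association at an entry, are omitted.

    Returns a DataFrame with columns ``species, locus_id, alt_freq, n``.
    """
    missing_truth = [s for s in matrix.sample_ids if s not in truth]
    if missing_truth:
        raise KeyError(f"samples without a truth species: {missing_truth}")
    by_species: dict[str, list[str]] = {}
    for sample in matrix.sample_ids:
        by_species.setdefault(truth[sample], []).append(sample)

    rows = []
    for entry in panel:
        if entry.locus_id not in matrix.calls.columns:
            continue
        column = matrix.calls[entry.locus_id]
        for species, samples in by_species.items():
            if species not in entry.species:
                continue
            alt_alleles = 0
            n = 0
            for code in column.loc[samples]:
                klass = classify_genotype(code, entry)
                if klass in (GenotypeClass.MISSING, GenotypeClass.FOREIGN):
                    continue
                n += 1
                if klass is GenotypeClass.HETEROZYGOUS:
                    alt_alleles += 1
                elif entry.expected_genotype(species) != code:
                    alt_alleles += 2
            if n:
                rows.append((species, entry.locus_id, alt_alleles / (2 * n), n))
    return pd.DataFrame(rows, columns=["species", "locus_id", "alt_freq", "n"])


def flag_problem_associations(
    freqs: pd.DataFrame, cutoff: float = 0.1
) -> list[tuple[str, str]]:
    """(species, locus_id) pairs whose alternative-allele frequency reaches
    *cutoff*, for manual review / removal of the association.

    The cutoff is an explicit parameter: low-frequency shared polymorphisms
    (a few percent) barely affect the scoring system because they are rarely
    homozygous, while frequencies above ~0.1 warrant dropping the
    association.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in (0, 1], got {cutoff}")
    flagged = freqs[freqs["alt_freq"] >= cutoff]
    return list(flagged[["species", "locus_id"]].itertuples(index=False, name=None))
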