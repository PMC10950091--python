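"""Synthetic reference panel for the 13 salmonid taxa (SYNTHETIC DATA).

The species-identification markers used for Columbia River basin salmonid
monitoring comprise 19 GT-seq amplicons carrying 51 species-informative
variant positions that discriminate 11 species and two Cutthroat Trout
subspecies groups.  This module rebuilds a species-seq panel with that
published *bookkeeping* -- amplicon names, variant positions, per-species
diagnostic and total variant counts, the two tri-allelic double entries, the
Coho and Brown Trout omissions at One_2.70711-39-43, and the 2/1 weight
scheme -- but the per-locus allele-to-species bipartitions themselves are
NOT public, so they are synthesised here: deterministic, phylogenetically
structured (congeners usually share an allele, with occasional within-clade
splits), and fixed by an internal seed.

Everything computed from this panel is therefore exact at the bookkeeping
level and *representative but not identical* at the level of which species
pairs share alleles at which loci.  Simulation results on this panel
reproduce the qualitative behaviour of the deployed marker set, not its
exact confusion percentages.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .panel import SpeciesPanel, SpeciesSeqEntry

__all__ = [
    "SPECIES_TOTALS",
    "SPECIES_DIAG_COUNTS",
    "AMPLICON_POSITIONS",
    "synthetic_reference_panel",
]

#: Per-species counts of species-seq entries (informative + diagnostic).
SPECIES_TOTALS: dict[str, int] = {
    "Ocl1": 51, "Ocl2": 51, "Ogo": 50, "Oke": 51, "Oki": 51, "Oma": 3,
    "Omy": 48, "One": 51, "Ots": 51, "Sco": 44, "Sfo": 46, "Ssa": 43,
    "Str": 40,
}

#: Per-species counts of single-species diagnostic (weight-2) entries.
SPECIES_DIAG_COUNTS: dict[str, int] = {
    "Ocl1": 0, "Ocl2": 3, "Ogo": 6, "Oke": 5, "Oki": 4, "Oma": 2,
    "Omy": 2, "One": 3, "Ots": 3, "Sco": 1, "Sfo": 2, "Ssa": 3, "Str": 0,
}

#: Amplicon -> 1-based variant positions (from the first base of the forward
#: primer).  51 positions over 19 amplicons.
AMPLICON_POSITIONS: dict[str, tuple[int, ...]] = {
    "Oki_101419-103": (27, 44),
    "Oki_105105-245": (23,),
    "Oki_106172-60": (38, 47, 53),
    "Oki_111681-407": (38,),
    "Oki_120255mod": (34, 40, 48, 50, 54, 55, 68, 70, 72, 76),
    "Oki_126619-265": (31, 35, 50),
    "Oki_aspAT-273": (37, 45),
    "Oki_RAD41030-31": (36, 37, 41, 55),
    "Oki_RAD51585-47": (25, 28, 31),
    "Omy_myclarp404-111": (45,),
    "Omy_RAD13034-67": (21, 35),
    "Omy_RAD79314-58": (25, 27, 31, 66),
    "One_1a.54542-52": (44, 47),
    "One_2.70711-39": (28, 30, 43, 57, 64),
    "Ots_ARNT": (29,),
    "Ots_crRAD9615-69": (19, 50),
    "Ots_myo1a-384": (36,),
    "Ots_P53": (25, 28, 40),
    "Ots_unk9480-51": (38,),
}

#: Tri-allelic variant positions: encoded as the main bi-allelic entry plus a
#: second entry (locus id suffixed ``b``) that captures the third allele.
_TRI_ALLELIC = {"Oki_106172-60": 47, "Ots_ARNT": 29}

#: Diagnostic entry -> diagnosed species.  Which amplicon diagnoses which
#: species is only partly public (Omy at Omy_myclarp404-111-45, Ocl2 at the
#: tri-allelic Cutthroat allele, Oma inside Oki_120255mod); the remaining
#: placements are synthesised to satisfy the per-amplicon and per-species
#: diagnostic counts.
_DIAG_SPECIES: dict[str, str] = {
    "Oki_105105-245-23": "Oke",
    "Oki_106172-60-47b": "Ocl2",
    "Oki_111681-407-38": "Ogo",
    "Oki_120255mod-34": "Ogo",
    "Oki_120255mod-40": "Ogo",
    "Oki_120255mod-48": "Oke",
    "Oki_120255mod-50": "Oki",
    "Oki_120255mod-54": "Oma",
    "Oki_120255mod-55": "Oma",
    "Oki_120255mod-68": "Omy",
    "Oki_120255mod-70": "One",
    "Oki_120255mod-72": "Ots",
    "Oki_120255mod-76": "Ssa",
    "Oki_126619-265-31": "Oke",
    "Oki_126619-265-35": "Ogo",
    "Oki_aspAT-273-37": "Sfo",
    "Oki_RAD41030-31-36": "Oki",
    "Oki_RAD41030-31-37": "Oki",
    "Oki_RAD41030-31-41": "Ssa",
    "Oki_RAD51585-47-25": "Sco",
    "Oki_RAD51585-47-28": "Sfo",
    "Omy_myclarp404-111-45": "Omy",
    "Omy_RAD13034-67-21": "Oki",
    "Omy_RAD79314-58-25": "Ssa",
    "One_1a.54542-52-44": "One",
    "One_2.70711-39-28": "One",
    "One_2.70711-39-30": "Oke",
    "One_2.70711-39-57": "Oke",
    "One_2.70711-39-64": "Ogo",
    "Ots_ARNT-29b": "Ots",
    "Ots_crRAD9615-69-19": "Ots",
    "Ots_myo1a-384-36": "Ogo",
    "Ots_P53-25": "Ocl2",
    "Ots_P53-28": "Ocl2",
}

#: Masu Salmon is described by only three loci, all inside the
#: Oki_120255mod amplicon: its two diagnostic entries plus one more.
_OMA_LOCI = {"Oki_120255mod-34", "Oki_120255mod-54", "Oki_120255mod-55"}

#: Clades used to structure informative-entry bipartitions: congeners tend to
#: share alleles, so ambiguity concentrates among close relatives.
_CLADES: tuple[tuple[str, ...], ...] = (
    ("Ssa", "Str"),
    ("Sco", "Sfo"),
    ("Ogo", "Oke"),
    ("One",),
    ("Oki",),
    ("Ots",),
    ("Oma",),
    ("Omy", "Ocl1", "Ocl2"),
)

#: Probability that a multi-species clade is split across an informative
#: entry's two alleles (incomplete lineage sorting / within-genus variants).
_CLADE_SPLIT_P = 0.2

_BUILD_SEED = 7

_NUCS = ("A", "C", "G", "T")


def _entry_locus_ids() -> list[str]:
    ids: list[str] = []
    for amplicon, positions in AMPLICON_POSITIONS.items():
        for pos in positions:
            ids.append(f"{amplicon}-{pos}")
            if _TRI_ALLELIC.get(amplicon) == pos:
                ids.append(f"{amplicon}-{pos}b")
    return ids


def _required_absences(locus_ids: list[str]) -> dict[str, set[str]]:
    tri_main = {f"{a}-{p}" for a, p in _TRI_ALLELIC.items()}
    tri_b = {f"{a}-{p}b" for a, p in _TRI_ALLELIC.items()}
    absent: dict[str, set[str]] = {s: set() for s in SPECIES_TOTALS}
    # Masu: only the three Beacham & Wallace-derived loci amplify.
    absent["Oma"] = {l for l in locus_ids if l not in _OMA_LOCI}
    # Polymorphic / segregating associations dropped at One_2.70711-39-43.
    absent["Oki"].add("One_2.70711-39-43")
    absent["Str"].add("One_2.70711-39-43")
    # Tri-allelic third-allele carriers are absent from the main entry and
    # the non-carriers of the third allele are absent from the ``b`` entry.
    absent["Ocl2"].add("Oki_106172-60-47")
    absent["Ots"].add("Ots_ARNT-29")
    for s in ("Sco", "Sfo", "Ssa", "Str"):
        absent[s].update(tri_b)
    return absent


def _fill_absences(
    locus_ids: list[str], absent: dict[str, set[str]], rng: np.random.Generator
) -> None:
    """Spread each species' remaining association omissions (cross-species
    amplification failures, segregating loci) over eligible entries."""
    tri = {f"{a}-{p}{s}" for a, p in _TRI_ALLELIC.items() for s in ("", "b")}
    for species in sorted(SPECIES_TOTALS):
        if species == "Oma":
            continue
        need = len(locus_ids) - SPECIES_TOTALS[species] - len(absent[species])
        if need <= 0:
            continue
        eligible = [
            l
            for l in locus_ids
            if l not in absent[species]
            and l not in tri
            and _DIAG_SPECIES.get(l) != species
        ]
        picks = rng.choice(len(eligible), size=need, replace=False)
        absent[species].update(eligible[i] for i in picks)


def _bipartition(
    present: frozenset[str], rng: np.random.Generator
) -> tuple[frozenset[str], frozenset[str]]:
    """Clade-structured random bipartition of the present species."""
    for _ in range(100):
        side1: set[str] = set()
        side2: set[str] = set()
        for clade in _CLADES:
            members = [s for s in clade if s in present]
            if not members:
                continue
            primary = side1 if rng.random() < 0.5 else side2
            other = side2 if primary is side1 else side1
            primary.update(members)
            if len(members) >= 2 and rng.random() < _CLADE_SPLIT_P:
                moved = members[int(rng.integers(len(members)))]
                primary.discard(moved)
                other.add(moved)
        if side1 and side2:
            return frozenset(side1), frozenset(side2)
    raise RuntimeError("could not bipartition present species")


def _allele_pair(rng: np.random.Generator) -> tuple[str, str]:
    i, j = rng.choice(4, size=2, replace=False)
    return _NUCS[i], _NUCS[j]


@lru_cache(maxsize=1)
def synthetic_reference_panel() -> SpeciesPanel:
    """Build the deterministic synthetic 13-species reference panel.

    53 species-seq entries over 51 variant positions in 19 amplicons; 34
    weight-2 single-species diagnostic entries; per-species totals matching
    the deployed marker set's bookkeeping.  Association bipartitions are
    synthetic (see module docstring).
    """
    rng = np.random.default_rng(_BUILD_SEED)
    locus_ids = _entry_locus_ids()
    absent = _required_absences(locus_ids)
    _fill_absences(locus_ids, absent, rng)

    tri_main = {f"{a}-{p}": a for a, p in _TRI_ALLELIC.items()}
    tri_b = {f"{a}-{p}b": a for a, p in _TRI_ALLELIC.items()}
    # shared reference allele + two alternates per tri-allelic position
    tri_alleles: dict[str, tuple[str, str, str]] = {}
    for amplicon in _TRI_ALLELIC:
        idx = rng.choice(4, size=3, replace=False)
        tri_alleles[amplicon] = tuple(_NUCS[i] for i in idx)  # (ref, alt, third)

    entries: list[SpeciesSeqEntry] = []
    for locus in locus_ids:
        present = frozenset(
            s for s in SPECIES_TOTALS if locus not in absent[s]
        )
        diag = _DIAG_SPECIES.get(locus)
        if locus in tri_main:
            ref, alt, _ = tri_alleles[tri_main[locus]]
            # third-allele carriers are already absent; Salmo/Salvelinus
            # carry the alternate allele here.
            side2 = frozenset(
                s for s in ("Sco", "Sfo", "Ssa", "Str") if s in present
            )
            entries.append(
                SpeciesSeqEntry(locus, ref, alt, present - side2, side2, 1.0)
            )
        elif locus in tri_b:
            ref, _, third = tri_alleles[tri_b[locus]]
            assert diag is not None
            entries.append(
                SpeciesSeqEntry(
                    locus, third, ref, frozenset({diag}),
                    present - {diag}, 2.0,
                )
            )
        elif diag is not None:
            a1, a2 = _allele_pair(rng)
            entries.append(
                SpeciesSeqEntry(
                    locus, a1, a2, frozenset({diag}), present - {diag}, 2.0
                )
            )
        else:
            a1, a2 = _allele_pair(rng)
            side1, side2 = _bipartition(present, rng)
            entries.append(SpeciesSeqEntry(locus, a1, a2, side1, side2, 1.0))

    panel = SpeciesPanel(entries)
    _validate(panel)
    return panel


def _validate(panel: SpeciesPanel) -> None:
    assert len(panel) == 53
    positions = {l[:-1] if l.endswith("b") else l for l in panel.locus_ids}
    assert len(positions) == 51
    assert panel.species == frozenset(SPECIES_TOTALS)
    for species, total in SPECIES_TOTALS.items():
        got = panel.n_informative(species)
        assert got == total, f"{species}: {got} != {total}"
    diag_counts = {s: 0 for s in SPECIES_TOTALS}
    n_weight2 = 0
    for entry in panel:
        if entry.weight == 2.0:
            n_weight2 += 1
            (diag,) = (
                entry.assoc1 if len(entry.assoc1) == 1 else entry.assoc2
            )
            diag_counts[diag] += 1
    assert n_weight2 == 34
    assert diag_counts == SPECIES_DIAG_COUNTS
    assert panel.expected_genotype("Oki", "One_2.70711-39-43") is None
    assert panel.expected_genotype("Str", "One_2.70711-39-43") is None
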