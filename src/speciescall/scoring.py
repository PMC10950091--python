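"""The weighted allelic-association species scoring system.

For every sample, each species accumulates a score ``S``: a homozygous
genotype matching an entry's allele 1 adds the locus weight to every species
associated with allele 1 and subtracts it from every species associated with
allele 2 (and symmetrically for allele-2 homozygotes).  Heterozygous, missing
and foreign genotypes contribute nothing -- the panel targets fixed
differences, so only homozygotes carry species information.

Three normalisations of ``S`` drive the call:

* ``M`` (absolute maximum): score attainable with complete expected data.
  The gate ``max_s S_s/M_s >= thresMS`` decides whether any call is made.
* ``P`` (maximum possible): score attainable given the loci that actually
  genotyped homozygous in this sample.  Ranking uses ``q = S/P`` so that a
  species is not penalised merely because its most informative loci failed.
* Candidates within ``buffMP`` of the best ``q`` are co-reported; when more
  than one remains, those with ``S/M < pruneMS`` are pruned (high ``q`` built
  on too few loci).

A sample whose heterozygosity over genotyped species-informative loci exceeds
``thresHET`` is flagged ``ReviewHET`` (contamination, F1 hybrid, or shared
polymorphism).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genotypes import (
    MISSING_CODE,
    GenotypeClass,
    GenotypeMatrix,
    classify_genotype,
    normalize_code,
)
from .panel import CallParams, SpeciesPanel

__all__ = [
    "ScoreCard",
    "SpeciesCall",
    "PanelArrays",
    "score_sample",
    "call_from_scorecard",
    "call_sample",
    "call_all",
]

# integer genotype-state codes used by the vectorised path
STATE_MISSING = 0
STATE_HOM1 = 1
STATE_HOM2 = 2
STATE_HET = 3
STATE_FOREIGN = 4

_CLASS_TO_STATE = {
    GenotypeClass.MISSING: STATE_MISSING,
    GenotypeClass.HOM_ALLELE1: STATE_HOM1,
    GenotypeClass.HOM_ALLELE2: STATE_HOM2,
    GenotypeClass.HETEROZYGOUS: STATE_HET,
    GenotypeClass.FOREIGN: STATE_FOREIGN,
}


@dataclass(frozen=True)
class ScoreCard:
    """Per-sample association scores and their normalisers.

    Invariants: ``-P_s <= S_s <= P_s <= M_s`` for every species, and
    ``het_count <= genotyped_count <= len(panel)``.
    """

    species: tuple[str, ...]
    scores: dict[str, float]          # S_s
    max_possible: dict[str, float]    # P_s
    absolute_max: dict[str, float]    # M_s
    het_count: int
    genotyped_count: int
    foreign_count: int = 0


@dataclass(frozen=True)
class SpeciesCall:
    """Ordered candidate species plus review flags for one sample."""

    candidates: tuple[str, ...]
    review_het: bool
    het_count: int
    genotyped_count: int

    def render(self) -> str:
        """``X``, ``X;Y``, ``NoCall``, with ``-ReviewHET`` suffix when
        flagged."""
        base = ";".join(self.candidates) if self.candidates else "NoCall"
        return base + "-ReviewHET" if self.review_het else base


class PanelArrays:
    """Dense panel representation for vectorised scoring.

    ``assoc1``/``assoc2`` are (entries x species) 0/1 matrices, ``weights``
    the per-entry weights and ``abs_max`` the per-species ``M`` vector.
    Species are ordered alphabetically.
    """

    def __init__(self, panel: SpeciesPanel):
        self.panel = panel
        self.species: tuple[str, ...] = tuple(sorted(panel.species))
        self.locus_ids: tuple[str, ...] = panel.locus_ids
        index = {s: j for j, s in enumerate(self.species)}
        n_e, n_s = len(panel), len(self.species)
        self.assoc1 = np.zeros((n_e, n_s), dtype=np.float64)
        self.assoc2 = np.zeros((n_e, n_s), dtype=np.float64)
        self.weights = np.empty(n_e, dtype=np.float64)
        for i, entry in enumerate(panel):
            self.weights[i] = entry.weight
            for s in entry.assoc1:
                self.assoc1[i, index[s]] = 1.0
            for s in entry.assoc2:
                self.assoc2[i, index[s]] = 1.0
        self._signed = (self.assoc1 - self.assoc2) * self.weights[:, None]
        self._support = (self.assoc1 + self.assoc2) * self.weights[:, None]
        self.abs_max = self._support.sum(axis=0)

    # -- scoring ------------------------------------------------------------

    def score_states(
        self, states: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Score a (samples x entries) state matrix.

        Returns ``(S, P, H, G, F)``: scores and max-possible per species,
        and per-sample het / genotyped / foreign counts.
        """
        states = np.atleast_2d(states)
        hom1 = states == STATE_HOM1
        hom2 = states == STATE_HOM2
        direction = hom1.astype(np.float64) - hom2.astype(np.float64)
        scorable = hom1.astype(np.float64) + hom2.astype(np.float64)
        scores = direction @ self._signed
        max_possible = scorable @ self._support
        het = (states == STATE_HET).sum(axis=1)
        genotyped = (states != STATE_MISSING).sum(axis=1)
        foreign = (states == STATE_FOREIGN).sum(axis=1)
        return scores, max_possible, het, genotyped, foreign

    def call_batch(
        self,
        scores: np.ndarray,
        max_possible: np.ndarray,
        het: np.ndarray,
        genotyped: np.ndarray,
        params: CallParams,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Apply the calling rule to a scored batch.

        Returns ``(candidates, review)``: a (samples x species) boolean
        candidate matrix (all-False rows are no-calls) and the per-sample
        ReviewHET flags.
        """
        with np.errstate(divide="ignore", invalid="ignore"):
            frac_ms = scores / self.abs_max[None, :]
            frac_mp = np.where(max_possible > 0, scores / max_possible, -np.inf)
        gate = (frac_ms >= params.thres_ms).any(axis=1)
        best = frac_mp.max(axis=1)
        with np.errstate(invalid="ignore"):
            # best - frac_mp is NaN for all-missing rows (-inf - -inf);
            # comparisons with NaN are False, which is the wanted no-call.
            candidates = (best[:, None] - frac_mp <= params.buff_mp) & (
                max_possible > 0
            )
        candidates &= gate[:, None]
        multi = candidates.sum(axis=1) > 1
        pruned = candidates & (frac_ms >= params.prune_ms)
        candidates = np.where(multi[:, None], pruned, candidates)
        with np.errstate(invalid="ignore"):
            review = (genotyped > 0) & (het / np.maximum(genotyped, 1) > params.thres_het)
        return candidates, review

    # -- genotype conversion ------------------------------------------------

    def states_from_mapping(self, genotypes: Mapping[str, str]) -> np.ndarray:
        """State vector for one sample given a locus -> code mapping (loci
        absent from the mapping are missing)."""
        states = np.zeros(len(self.locus_ids), dtype=np.int8)
        for i, entry in enumerate(self.panel):
            code = normalize_code(genotypes.get(entry.locus_id, MISSING_CODE))
            states[i] = _CLASS_TO_STATE[classify_genotype(code, entry)]
        return states

    def states_from_matrix(self, matrix: GenotypeMatrix) -> np.ndarray:
        """(samples x entries) state matrix; matrix loci outside the panel
        are ignored, panel loci outside the matrix are missing."""
        n = len(matrix.sample_ids)
        states = np.zeros((n, len(self.locus_ids)), dtype=np.int8)
        for i, entry in enumerate(self.panel):
            if entry.locus_id not in matrix.calls.columns:
                continue
            column = matrix.calls[entry.locus_id].to_numpy()
            # classify unique codes once per column
            codes, inverse = np.unique(column, return_inverse=True)
            mapped = np.array(
                [_CLASS_TO_STATE[classify_genotype(c, entry)] for c in codes],
                dtype=np.int8,
            )
            states[:, i] = mapped[inverse]
        return states


def _order_candidates(
    mask: np.ndarray, frac_mp: np.ndarray, species: Sequence[str]
) -> tuple[str, ...]:
    """Candidate ordering: descending S/P, alphabetical tie-break."""
    chosen = [(float(-frac_mp[j]), species[j]) for j in np.nonzero(mask)[0]]
    return tuple(name for _, name in sorted(chosen))


def score_sample(
    genotypes: Mapping[str, str], panel: SpeciesPanel | PanelArrays
) -> ScoreCard:
    """Score one sample (locus -> genotype-code mapping) against *panel*."""
    arrays = panel if isinstance(panel, PanelArrays) else PanelArrays(panel)
    states = arrays.states_from_mapping(genotypes)
    S, P, H, G, F = arrays.score_states(states)
    return ScoreCard(
        species=arrays.species,
        scores=dict(zip(arrays.species, S[0])),
        max_possible=dict(zip(arrays.species, P[0])),
        absolute_max=dict(zip(arrays.species, arrays.abs_max)),
        het_count=int(H[0]),
        genotyped_count=int(G[0]),
        foreign_count=int(F[0]),
    )


def call_from_scorecard(
    card: ScoreCard, params: CallParams | None = None
) -> SpeciesCall:
    """Turn a :class:`ScoreCard` into a :class:`SpeciesCall`."""
    params = params or CallParams()
    species = card.species
    S = np.array([card.scores[s] for s in species])
    P = np.array([card.max_possible[s] for s in species])
    M = np.array([card.absolute_max[s] for s in species])

    with np.errstate(divide="ignore", invalid="ignore"):
        frac_ms = S / M
        frac_mp = np.where(P > 0, S / P, -np.inf)
    candidates: tuple[str, ...] = ()
    if (frac_ms >= params.thres_ms).any():
        mask = (frac_mp.max() - frac_mp <= params.buff_mp) & (P > 0)
        if mask.sum() > 1:
            mask &= frac_ms >= params.prune_ms
        candidates = _order_candidates(mask, frac_mp, species)
    review = (
        card.genotyped_count > 0
        and card.het_count / card.genotyped_count > params.thres_het
    )
    return SpeciesCall(
        candidates=candidates,
        review_het=review,
        het_count=card.het_count,
        genotyped_count=card.genotyped_count,
    )


def call_sample(
    genotypes: Mapping[str, str],
    panel: SpeciesPanel | PanelArrays,
    params: CallParams | None = None,
) -> SpeciesCall:
    """Score and call a single sample."""
    return call_from_scorecard(score_sample(genotypes, panel), params)


def call_all(
    matrix: GenotypeMatrix,
    panel: SpeciesPanel | PanelArrays,
    params: CallParams | None = None,
) -> list[SpeciesCall]:
    """Call every sample of a genotype matrix (vectorised, order preserved)."""
    params = params or CallParams()
    arrays = panel if isinstance(panel, PanelArrays) else PanelArrays(panel)
    states = arrays.states_from_matrix(matrix)
    S, P, H, G, _ = arrays.score_states(states)
    cand, review = arrays.call_batch(S, P, H, G, params)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac_mp = np.where(P > 0, S / P, -np.inf)
    calls = []
    for i in range(states.shape[0]):
        calls.append(
            SpeciesCall(
                candidates=_order_candidates(cand[i], frac_mp[i], arrays.species),
                review_het=bool(review[i]),
                het_count=int(H[i]),
                genotyped_count=int(G[i]),
            )
        )
    return calls
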