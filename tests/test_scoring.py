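import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from speciescall import (
    CallParams,
    GenotypeMatrix,
    SpeciesPanel,
    SpeciesSeqEntry,
    call_all,
    call_from_scorecard,
    call_sample,
    score_sample,
)
from speciescall.simulate import expected_profile, generate_toy_panel

from _oracle import oracle_call, oracle_scorecard

X_PROFILE = {"L1": "AA", "L2": "CC", "L3": "TT", "L4": "CC"}


class TestScoreSample:
    def test_full_profile_scorecard(self, tp1):
        card = score_sample(X_PROFILE, tp1)
        assert card.scores == {"X": 7.0, "Y": -1.0, "Z": -3.0}
        assert card.max_possible == {"X": 7.0, "Y": 7.0, "Z": 7.0}
        assert card.het_count == 0
        assert card.genotyped_count == 4

    def test_single_locus(self, tp1):
        card = score_sample({"L2": "CC"}, tp1)
        assert card.scores == {"X": 1.0, "Y": 1.0, "Z": -1.0}
        assert card.max_possible == {"X": 1.0, "Y": 1.0, "Z": 1.0}
        assert card.genotyped_count == 1

    def test_all_missing(self, tp1):
        card = score_sample({}, tp1)
        assert set(card.scores.values()) == {0.0}
        assert set(card.max_possible.values()) == {0.0}
        assert card.het_count == card.genotyped_count == 0

    def test_scorecard_inequalities_hold(self, tp1):
        rng = np.random.default_rng(3)
        codes = ["AA", "GG", "AG", "CC", "TT", "CT", "00", "AT"]
        for _ in range(50):
            genotypes = {
                f"L{i}": codes[rng.integers(len(codes))] for i in range(1, 5)
            }
            card = score_sample(genotypes, tp1)
            for s in card.species:
                assert -card.max_possible[s] <= card.scores[s] <= card.max_possible[s]
                assert card.max_possible[s] <= card.absolute_max[s]
            assert card.het_count <= card.genotyped_count <= 4


class TestCalling:
    def test_full_profile_called_exclusively(self, tp1):
        call = call_sample(X_PROFILE, tp1)
        assert call.candidates == ("X",)
        assert not call.review_het

    def test_gate_failure_is_nocall(self, tp1):
        call = call_sample({"L2": "CC"}, tp1)
        assert call.candidates == ()
        assert call.render() == "NoCall"

    def test_heterozygous_locus_flags_review(self, tp1):
        call = call_sample({**X_PROFILE, "L1": "AG"}, tp1)
        assert call.candidates == ("X",)
        assert call.review_het  # 1 het of 4 genotyped > 0.06
        assert call.render() == "X-ReviewHET"

    def test_pruning_removes_sparsely_supported_candidate(self):
        # Species A is described by three weight-1 loci but genotypes at only
        # one of them, where it shares the allele with the true species B:
        # q_A = 1/1 puts A among the candidates, yet S_A/M_A = 1/3 < 0.34
        # prunes it, leaving the fully supported B.
        f = frozenset
        panel = SpeciesPanel(
            [
                SpeciesSeqEntry("P1", "A", "G", f({"A", "B"}), f({"C"}), 1.0),
                SpeciesSeqEntry("P2", "C", "T", f({"A"}), f({"B", "C"}), 1.0),
                SpeciesSeqEntry("P3", "C", "T", f({"A"}), f({"B", "C"}), 1.0),
                SpeciesSeqEntry("P4", "A", "C", f({"B"}), f({"C"}), 1.0),
                SpeciesSeqEntry("P5", "G", "T", f({"B"}), f({"C"}), 1.0),
            ]
        )
        genotypes = {"P1": "AA", "P4": "AA", "P5": "GG"}
        card = score_sample(genotypes, panel)
        assert card.scores["A"] == card.max_possible["A"] == 1.0
        assert card.absolute_max["A"] == 3.0
        call = call_from_scorecard(card)
        assert call.candidates == ("B",)
        # without pruning both would be reported
        relaxed = call_from_scorecard(card, CallParams(prune_ms=0.0))
        assert relaxed.candidates == ("A", "B")

    def test_scores_invariant_to_entry_order(self, tp1):
        reversed_panel = SpeciesPanel(tuple(reversed(tp1.entries)))
        a = score_sample(X_PROFILE, tp1)
        b = score_sample(X_PROFILE, reversed_panel)
        assert a.scores == b.scores and a.max_possible == b.max_possible

    def test_call_all_preserves_sample_order(self, tp1):
        profiles = {s: expected_profile(tp1, s) for s in "XYZ"}
        calls_df = pd.DataFrame.from_dict(profiles, orient="index").astype(str)
        matrix = GenotypeMatrix(calls=calls_df, extra=calls_df.iloc[:, :0])
        calls = call_all(matrix, tp1)
        assert [c.candidates for c in calls] == [("X",), ("Y",), ("Z",)]
        shuffled = GenotypeMatrix(
            calls=calls_df.iloc[[2, 0, 1]], extra=calls_df.iloc[[2, 0, 1], :0]
        )
        assert [c.candidates for c in call_all(shuffled, tp1)] == [
            ("Z",),
            ("X",),
            ("Y",),
        ]


def _random_instance(seed):
    rng = np.random.default_rng(seed)
    panel = generate_toy_panel(
        n_species=int(rng.integers(2, 7)),
        n_loci=int(rng.integers(1, 9)),
        diag_fraction=float(rng.random()),
        seed=seed,
    )
    genotypes = {}
    for entry in panel:
        roll = rng.random()
        if roll < 0.2:
            continue  # missing
        if roll < 0.45:
            genotypes[entry.locus_id] = entry.allele1 * 2
        elif roll < 0.7:
            genotypes[entry.locus_id] = entry.allele2 * 2
        elif roll < 0.85:
            genotypes[entry.locus_id] = entry.allele1 + entry.allele2
        else:
            nucs = "ACGT"
            genotypes[entry.locus_id] = "".join(
                nucs[rng.integers(4)] for _ in range(2)
            )
    return panel, genotypes


class TestOracleEquivalence:
    @pytest.mark.parametrize("block", range(4))
    def test_production_matches_brute_force(self, block):
        for seed in range(block * 50, (block + 1) * 50):
            panel, genotypes = _random_instance(seed)
            card = score_sample(genotypes, panel)
            S, P, M, het, genotyped = oracle_scorecard(genotypes, panel)
            assert card.scores == pytest.approx(S, abs=0)
            assert card.max_possible == pytest.approx(P, abs=0)
            assert card.absolute_max == pytest.approx(M, abs=0)
            assert (card.het_count, card.genotyped_count) == (het, genotyped)
            call = call_from_scorecard(card)
            cand, review = oracle_call(genotypes, panel)
            assert list(call.candidates) == cand
            assert call.review_het == review


@st.composite
def informative_subsets(draw):
    panel = generate_toy_panel(4, 6, 0.5, seed=draw(st.integers(0, 20)))
    species = draw(st.sampled_from(sorted(panel.species)))
    loci = panel.informative_loci(species)
    keep = draw(st.sets(st.sampled_from(loci)))
    return panel, species, keep


class TestProperties:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(informative_subsets())
    def test_candidate_inclusion_guarantee(self, case):
        """Expected homozygous genotypes at any subset of a species'
        informative loci give it the top possible-score proportion, so a
        made call always includes the true species before pruning."""
        panel, species, keep = case
        genotypes = {
            l: panel.expected_genotype(species, l) for l in keep
        }
        card = score_sample(genotypes, panel)
        assert card.scores[species] == card.max_possible[species]
        call = call_from_scorecard(card, CallParams(prune_ms=0.0))
        if call.candidates:
            assert species in call.candidates

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 500), st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_raising_gate_never_creates_calls(self, seed, t_lo, t_hi):
        lo, hi = sorted((t_lo, t_hi))
        panel, genotypes = _random_instance(seed)
        strict = call_sample(genotypes, panel, CallParams(thres_ms=hi))
        lenient = call_sample(genotypes, panel, CallParams(thres_ms=lo))
        if strict.candidates:
            assert lenient.candidates
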