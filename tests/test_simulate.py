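import itertools

import numpy as np
import pytest

from speciescall import (
    CallParams,
    Outcome,
    SpeciesCall,
    call_sample,
    classify_outcome,
)
from speciescall.simulate import (
    SimulationResult,
    expected_profile,
    generate_toy_panel,
    missing_success_bins,
    run_shared_poly_grid,
    simulate_missing_study,
    simulate_shared_poly_study,
    summarize,
    tp1_panel,
)


class TestExpectedProfiles:
    def test_tp1_profile(self, tp1):
        assert expected_profile(tp1, "X") == {
            "L1": "AA",
            "L2": "CC",
            "L3": "TT",
            "L4": "CC",
        }

    def test_profile_scores_at_absolute_max(self, ref_panel):
        from speciescall import score_sample

        for species in sorted(ref_panel.species):
            card = score_sample(expected_profile(ref_panel, species), ref_panel)
            assert card.scores[species] == card.absolute_max[species]

    def test_masu_like_species_has_three_loci(self, ref_panel):
        assert len(expected_profile(ref_panel, "Oma")) == 3


class TestOutcomeClassification:
    @pytest.mark.parametrize(
        "candidates, truth, expected",
        [
            (("X",), "X", Outcome.EXCLUSIVE_CORRECT),
            (("X", "Y"), "X", Outcome.TRUE_INCLUDED),
            (("Y",), "X", Outcome.TRUE_EXCLUDED),
            ((), "X", Outcome.NO_CALL),
        ],
    )
    def test_partition(self, candidates, truth, expected):
        call = SpeciesCall(candidates, False, 0, 4)
        assert classify_outcome(call, truth) is expected


class TestMissingStudy:
    def test_replicate_accounting_and_no_exclusion(self, tp1):
        result = simulate_missing_study(tp1, reps=100, seed=2)
        frame = result.scenarios
        # n_informative x reps simulated genotypes per species
        assert result.total_calls == 3 * 4 * 100
        assert frame.groupby("species")["reps"].sum().eq(400).all()
        assert frame["n_excluded"].sum() == 0

    def test_full_omission_is_always_nocall(self, tp1):
        result = simulate_missing_study(tp1, species="X", reps=50, seed=0)
        last = result.scenarios.query("k == 4").iloc[0]
        assert last["n_nocall"] == 50

    def test_single_retained_locus_matches_exhaustive_enumeration(self, tp1):
        # k = 3 leaves one locus: every one of the four single-locus
        # retentions fails the thresMS gate (best S/M is 2/7), so the
        # simulator must report 100% no-call for this level.
        for locus in tp1.locus_ids:
            genotypes = {locus: expected_profile(tp1, "X")[locus]}
            assert call_sample(genotypes, tp1).candidates == ()
        result = simulate_missing_study(tp1, species="X", reps=200, seed=3)
        row = result.scenarios.query("k == 3").iloc[0]
        assert row["n_nocall"] == 200

    def test_seeded_bit_reproducibility(self, tp1):
        a = simulate_missing_study(tp1, reps=60, seed=9).scenarios
        b = simulate_missing_study(tp1, reps=60, seed=9).scenarios
        assert a.equals(b)
        c = simulate_missing_study(tp1, reps=60, seed=10).scenarios
        assert not a.equals(c)

    def test_per_species_stream_independent_of_run_composition(self, tp1):
        alone = simulate_missing_study(tp1, species="Y", reps=40, seed=4).scenarios
        together = simulate_missing_study(tp1, reps=40, seed=4).scenarios
        subset = together.query("species == 'Y'").reset_index(drop=True)
        assert alone.equals(subset)

    def test_success_binning(self, ref_panel):
        result = simulate_missing_study(ref_panel, species="Ots", reps=20, seed=0)
        bins = missing_success_bins(result)
        assert (bins["bin_hi"] - bins["bin_lo"]).eq(2.0).all()
        assert bins["reps"].sum() == result.total_calls


class TestSharedPolyStudy:
    def test_zero_frequency_is_degenerate(self, tp1):
        result = run_shared_poly_grid(
            tp1, k_grid=(1, 2, 4), p_grid=(0.0,), reps=100, seed=1
        )
        frame = result.scenarios
        assert (frame["n_exclusive"] == 100).all()

    def test_adversarial_limit_can_exclude_truth(self, tp1):
        result = simulate_shared_poly_study(tp1, "X", k=4, p=1.0, reps=100, seed=1)
        row = result.scenarios.iloc[0]
        assert row["n_exclusive"] == 0
        assert row["n_excluded"] + row["n_nocall"] == 100

    def test_k_bounds_enforced(self, tp1):
        with pytest.raises(ValueError, match="informative"):
            simulate_shared_poly_study(tp1, "X", k=5, p=0.1, reps=10, seed=0)

    def test_grid_skips_oversized_k(self, ref_panel):
        result = run_shared_poly_grid(
            ref_panel, species="Oma", k_grid=(1, 2, 5, 10, 15),
            p_grid=(0.1,), reps=20, seed=0
        )
        assert sorted(result.scenarios["k"]) == [1, 2]

    def test_single_affected_locus_matches_enumeration_oracle(self, tp1):
        # Exact law for (species X, k = 1, p = 0.2): condition on the
        # affected locus (uniform over 4) and its genotype class
        # (0.64 expected hom / 0.32 het / 0.04 alternative hom), call each
        # case once, and accumulate the outcome probabilities.
        p = 0.2
        probs = dict.fromkeys(Outcome, 0.0)
        profile = expected_profile(tp1, "X")
        for locus in tp1.locus_ids:
            entry = tp1[locus]
            expected = profile[locus]
            alt = (
                entry.allele2 if expected[0] == entry.allele1 else entry.allele1
            )
            cases = {
                expected: (1 - p) ** 2,
                entry.allele1 + entry.allele2: 2 * p * (1 - p),
                alt * 2: p**2,
            }
            for code, prob in cases.items():
                call = call_sample({**profile, locus: code}, tp1)
                probs[classify_outcome(call, "X")] += prob / 4.0
        assert probs[Outcome.EXCLUSIVE_CORRECT] == pytest.approx(0.97)
        assert probs[Outcome.NO_CALL] == pytest.approx(0.03)

        reps = 4000
        result = simulate_shared_poly_study(tp1, "X", k=1, p=p, reps=reps, seed=6)
        row = result.scenarios.iloc[0]
        # 3 sigma of a binomial rate at p ~ 0.97, n = 4000 is ~0.008
        assert row["n_exclusive"] / reps == pytest.approx(
            probs[Outcome.EXCLUSIVE_CORRECT], abs=0.015
        )
        assert row["n_excluded"] == 0

    def test_accuracy_degrades_with_frequency(self, ref_panel, ref_arrays):
        rows = []
        for p in (0.01, 0.2):
            result = run_shared_poly_grid(
                ref_arrays, k_grid=(15,), p_grid=(p,), reps=400, seed=2,
                species=[s for s in sorted(ref_panel.species) if s != "Oma"],
            )
            frame = result.scenarios
            rows.append(frame["n_exclusive"].sum() / frame["reps"].sum())
        assert rows[1] < rows[0]


class TestSummarize:
    def test_single_result_passthrough(self, tp1):
        result = simulate_shared_poly_study(tp1, "X", k=1, p=0.1, reps=200, seed=0)
        table = summarize(result, n_boot=200)
        row = table.iloc[0]
        observed = result.scenarios.iloc[0]["n_exclusive"] / 200
        assert row["exclusive_rate"] == pytest.approx(observed)
        assert row["exclusive_lo"] <= row["exclusive_rate"] <= row["exclusive_hi"]

    def test_cross_species_mean_is_hand_average(self, tp1):
        parts = [
            simulate_shared_poly_study(tp1, s, k=2, p=0.2, reps=300, seed=1)
            for s in ("X", "Y")
        ]
        combined = SimulationResult.concat(parts)
        table = summarize(combined, n_boot=100)
        rates = [r.scenarios.iloc[0]["n_exclusive"] / 300 for r in parts]
        assert table.iloc[0]["exclusive_rate"] == pytest.approx(
            sum(rates) / 2
        )

    def test_exclusion_filter(self, tp1):
        parts = [
            simulate_shared_poly_study(tp1, s, k=1, p=0.2, reps=100, seed=1)
            for s in ("X", "Y")
        ]
        table = summarize(SimulationResult.concat(parts), exclude=["Y"], n_boot=50)
        assert table.iloc[0]["n_species"] == 1

    def test_ci_width_shrinks_with_reps(self, tp1):
        widths = []
        for reps in (200, 3200):
            result = simulate_shared_poly_study(
                tp1, "X", k=2, p=0.3, reps=reps, seed=7
            )
            row = summarize(result, n_boot=400).iloc[0]
            widths.append(row["exclusive_hi"] - row["exclusive_lo"])
        # 16x the replicates ~ 4x narrower
        assert widths[1] < widths[0] / 2


class TestToyPanels:
    def test_tp1_fixture_definition(self, tp1):
        entry = tp1["L3"]
        assert (entry.allele1, entry.allele2) == ("G", "T")
        assert entry.assoc1 == {"Y"} and entry.assoc2 == {"X", "Z"}
        assert entry.weight == 2

    def test_generator_deterministic_and_valid(self):
        a = generate_toy_panel(5, 8, 0.4, seed=3)
        b = generate_toy_panel(5, 8, 0.4, seed=3)
        assert a == b
        for species in a.species:
            assert a.n_informative(species) == 8

    def test_generator_diag_fraction(self):
        panel = generate_toy_panel(4, 10, 0.3, seed=1)
        n_diag = sum(1 for e in panel if e.weight == 2)
        assert n_diag == 3

    def test_generator_argument_validation(self):
        with pytest.raises(ValueError):
            generate_toy_panel(1, 4)
        with pytest.raises(ValueError):
            generate_toy_panel(3, 0)
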