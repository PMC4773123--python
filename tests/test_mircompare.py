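import numpy as np
import pytest

from mirseed.core_io import ReferenceEntry
from mirseed.errors import ConfigError, InvalidOffsetError, MalformedPatternError
from mirseed.fixtures import load_fixture
from mirseed.mircompare import (CompareParams, compare_libraries, compare_pair,
                                overlay, round_half_up, score_pattern)

PARAMS = CompareParams()


class TestScorePattern:
    def test_all_nine_printed_patterns_reproduce_printed_r_values(self):
        t5 = load_fixture("table5")
        for row in t5.rows.itertuples():
            matches, length, _ = score_pattern(row.alignment_pattern)
            assert round_half_up(matches, length) == row.r_value, row.alignment_pattern

    @pytest.mark.parametrize("pattern, matches, length", [
        ("-GGAC-AGG-U-CA--CC-CC", 14, 21),
        ("UC--UUGGU--A---CG-GA-", 12, 21),
        ("AC-UU-GCUC-G-UGGUG", 14, 18),
        ("-AAAG-GAU-GCA-UG-U--", 13, 20),
        ("----", 0, 4),
    ])
    def test_match_and_length_counting(self, pattern, matches, length):
        got_matches, got_length, r = score_pattern(pattern)
        assert (got_matches, got_length) == (matches, length)
        assert r == pytest.approx(matches / length)

    def test_foreign_character_rejected(self):
        with pytest.raises(MalformedPatternError):
            score_pattern("AC-GT-")  # T is not pattern alphabet


class TestOverlay:
    def test_identical_sequences_offset_zero(self):
        seq = "UCGCUUGGUGCAGGUCGGGAC"
        pattern, matches, length = overlay(seq, seq, 0)
        assert pattern == seq and matches == len(seq) == length

    def test_partial_coverage_half_r(self):
        animal = "ACGUACGUACGUACGUACGU"  # 20-mer
        plant = animal[:10]
        pattern, matches, length = overlay(plant, animal, 0)
        assert matches == 10 and length == 20
        assert pattern == plant + "-" * 10

    def test_zero_overlap_offset_is_error(self):
        with pytest.raises(InvalidOffsetError):
            overlay("ACGUACGUAC", "ACGUACGUAC", 10)

    def test_negative_offset_plant_overhangs_left(self):
        plant = "GGACGUACGUAC"
        animal = plant[2:]
        pattern, matches, _ = overlay(plant, animal, -2)
        assert matches == len(animal)


class TestComparePair:
    def test_identical_pair_passes_with_full_seed(self):
        seq = "UCGCUUGGUGCAGGUCGGGAC"
        result = compare_pair(seq, seq, PARAMS)
        assert result.r_value == pytest.approx(1.0)
        assert result.seed_matches == 7  # window 2..8
        assert result.passes

    def test_printed_pattern_row_r_value(self):
        # reconstructed from a printed pair: 14 matches over an 18-mer frame
        matches, length, _ = score_pattern("AC-UU-GCUC-G-UGGUG")
        assert round_half_up(matches, length) == 0.78

    def test_r_below_threshold_fails(self):
        plant = "UCGCUUGGUGCAGGUCGGGAC"
        rng = np.random.default_rng(0)
        # mutate to push the best r under 0.55
        animal = list(plant)
        for i in range(0, len(animal), 2):
            animal[i] = {"A": "C", "C": "G", "G": "U", "U": "A"}[animal[i]]
        result = compare_pair(plant, "".join(animal), PARAMS)
        if result.r_value < PARAMS.r_min:
            assert not result.passes

    def test_hamming_distance_controls_r(self):
        plant = "UCGCUUGGUGCAGGUCGGGAC"  # 21-mer
        for d in (0, 1, 2, 3):
            animal = list(plant)
            for i in range(d):
                pos = 9 + i
                animal[pos] = {"A": "C", "C": "G", "G": "U", "U": "A"}[animal[pos]]
            result = compare_pair(plant, "".join(animal), PARAMS)
            assert result.offset == 0
            assert result.r_value == pytest.approx((21 - d) / 21)

    def test_equals_brute_force_over_all_offsets(self):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGU"))
        for _ in range(30):
            plant = "".join(rng.choice(bases, size=int(rng.integers(15, 30))))
            animal = "".join(rng.choice(bases, size=int(rng.integers(15, 30))))
            result = compare_pair(plant, animal, PARAMS)
            best = -1
            n_p, n_a = len(plant), len(animal)
            min_ov = min(PARAMS.min_overlap, n_p, n_a)
            for offset in range(-n_p + 1, n_a):
                lo, hi = max(0, offset), min(n_a, offset + n_p)
                if hi - lo < min_ov:
                    continue
                matches = sum(1 for i in range(lo, hi)
                              if plant[i - offset] == animal[i])
                best = max(best, matches)
            assert result.matches == best

    def test_invariant_under_dna_relabeling(self):
        plant = "UCGCUUGGUGCAGGUCGGGAC"
        animal = "UCGCUUGGUGCAGGUCGGGAA"
        r_rna = compare_pair(plant, animal, PARAMS).r_value
        r_dna = compare_pair(plant.replace("U", "T"),
                             animal.replace("U", "T"), PARAMS).r_value
        assert r_rna == r_dna

    def test_sequences_shorter_than_seed_window_rejected(self):
        with pytest.raises(ConfigError):
            compare_pair("ACGUACG", "ACGUACGUACGUACG", PARAMS)


class TestCompareLibraries:
    def _entries(self, seqs, species):
        return [ReferenceEntry(f"{species}-m{i}", species, f"m{i}", f"m{i}",
                               "miRNA", s, "mature")
                for i, s in enumerate(seqs)]

    def test_self_comparison_all_pairs_pass_with_r_one(self):
        seqs = ["UCGCUUGGUGCAGGUCGGGAC", "AAGCUCAGGAGGGAUAGCGCC"]
        plant = self._entries(seqs, "mol")
        animal = self._entries(seqs, "hsa")
        results = compare_libraries(plant, animal, PARAMS)
        self_pairs = [r for r in results if r.r_value == pytest.approx(1.0)]
        assert len(self_pairs) == 2

    def test_raising_r_min_never_enlarges_passing_set(self, sim_refs):
        focal = [e for e in sim_refs.plant if e.species_code == "mol"][:20]
        sets = []
        for r_min in (0.4, 0.55, 0.7):
            params = CompareParams(r_min=r_min)
            results = compare_libraries(focal, sim_refs.animal, params)
            sets.append({(r.plant_name, r.animal_name) for r in results})
        assert sets[2] <= sets[1] <= sets[0]

    def test_planted_mimic_recovered_at_expected_r(self, sim_refs):
        plant_by_name = {e.full_name: e for e in sim_refs.plant
                         if e.species_code == "mol"}
        animal_by_name = {e.full_name: e for e in sim_refs.animal}
        for animal_name, (plant_name, d) in sim_refs.mimic_pairs.items():
            plant = plant_by_name[plant_name]
            animal = animal_by_name[animal_name]
            result = compare_pair(plant.sequence, animal.sequence, PARAMS,
                                  plant_name=plant_name, animal_name=animal_name)
            n = len(animal.sequence)
            assert result.r_value >= (n - d) / n

    def test_empty_library_rejected(self):
        with pytest.raises(ConfigError):
            compare_libraries([], self._entries(["A" * 21], "hsa"), PARAMS)


def test_round_half_up_boundary():
    # 0.675 rounds up to 0.68, not banker's 0.67 (27/40 = 0.675 exactly)
    assert round_half_up(27, 40) == 0.68
    assert round_half_up(12, 17) == 0.71
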