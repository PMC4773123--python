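import numpy as np
import pytest

from mirseed.annotate import (AnnotationParams, annotate_tags,
                              extract_novel_candidates, family_summary,
                              identify_conserved, length_distribution,
                              subtract_ncrna)
from mirseed.core_io import ReferenceEntry, UniqueTag
from mirseed.errors import ConfigError


def ref(seq, species="ath", name="miR166a", rna_class="miRNA", arm="mature"):
    return ReferenceEntry(accession=f"{species}-{name}", species_code=species,
                          name=name, family="miR166", rna_class=rna_class,
                          sequence=seq, arm=arm)


RRNA = ref("ACGU" * 30 + "UCAGGUCAAGGAUCGGUACGAU", species="ref",
           name="rRNA_1", rna_class="rRNA")
PARAMS = AnnotationParams()


class TestNcrnaSubtraction:
    def test_tag_inside_reference_window_removed(self):
        window = RRNA.sequence[10:30]
        retained, removed, short, _ = subtract_ncrna(
            [UniqueTag(window, 5)], [RRNA], PARAMS)
        assert retained == [] and len(removed) == 1

    def test_single_mismatch_is_retained(self):
        window = list(RRNA.sequence[10:30])
        window[7] = {"A": "C"}.get(window[7], "A")
        tag = UniqueTag("".join(window), 5)
        retained, removed, _, _ = subtract_ncrna([tag], [RRNA], PARAMS)
        assert retained == [tag] and removed == []

    def test_short_tag_removed_and_counted_separately(self):
        tag = UniqueTag("ACGUACGUACGUAC", 3)  # 14 nt
        retained, removed, short, counts = subtract_ncrna([tag], [RRNA], PARAMS)
        assert short == [tag] and retained == [] and removed == []
        frame = counts.to_frame()
        assert frame.loc[frame.stage == "short_tag_filter", "discarded"].iloc[0] == 1

    def test_no_cross_boundary_matches(self):
        a, b = ref("A" * 20, name="x", rna_class="rRNA"), ref("C" * 20, name="y", rna_class="rRNA")
        straddler = UniqueTag("A" * 10 + "C" * 10, 5)
        retained, removed, _, _ = subtract_ncrna([straddler], [a, b], PARAMS)
        assert retained == [straddler]

    def test_empty_reference_is_config_error(self):
        with pytest.raises(ConfigError):
            subtract_ncrna([UniqueTag("ACGUACGUACGUACGU", 1)], [], PARAMS)


class TestIdentifyConserved:
    REFERENCE = [ref("UCGCUUGGUGCAGGUCGGGAC", species="osa", name="miR168a")]

    def test_exact_match_annotated_with_species_prefix(self):
        tag = UniqueTag("UCGCUUGGUGCAGGUCGGGAC", 165)
        anns, unmatched, below = identify_conserved([tag], self.REFERENCE, PARAMS)
        (ann,) = anns
        assert ann.assigned_name == "mol-miR168a"
        assert ann.family == "miR168"
        assert ann.count == 165
        assert unmatched == [] and below == []

    def test_count_below_threshold_excluded(self):
        tag = UniqueTag("UCGCUUGGUGCAGGUCGGGAC", 9)
        anns, unmatched, below = identify_conserved([tag], self.REFERENCE, PARAMS)
        assert anns == [] and below == [tag]

    def test_count_at_threshold_included(self):
        tag = UniqueTag("UCGCUUGGUGCAGGUCGGGAC", 10)
        anns, _, _ = identify_conserved([tag], self.REFERENCE, PARAMS)
        assert len(anns) == 1

    def test_unmatched_tag_returned(self):
        tag = UniqueTag("AAGCUCAGGAGGGAUAGCGCC", 50)
        anns, unmatched, _ = identify_conserved([tag], self.REFERENCE, PARAMS)
        assert anns == [] and unmatched == [tag]

    def test_multi_species_tie_break_and_sources(self):
        seq = "UCGCUUGGUGCAGGUCGGGAC"
        reference = [ref(seq, species="osa", name="miR168a"),
                     ref(seq, species="ath", name="miR168b"),
                     ref(seq, species="ath", name="miR168a")]
        anns, _, _ = identify_conserved([UniqueTag(seq, 20)], reference, PARAMS)
        (ann,) = anns
        assert ann.assigned_name == "mol-miR168a"  # lexicographically smallest pair
        assert len(ann.sources) == 3

    def test_overhang_is_not_a_match(self):
        # tag is a proper substring of the reference: full-length equality fails
        tag = UniqueTag("UCGCUUGGUGCAGGUCGGGA", 20)
        anns, unmatched, _ = identify_conserved([tag], self.REFERENCE, PARAMS)
        assert anns == [] and unmatched == [tag]


class TestNovelCandidates:
    def test_length_boundary_inclusive_at_18(self):
        tags = [UniqueTag("A" * 17, 12), UniqueTag("ACGUACGUACGUACGUAC", 12),
                UniqueTag("ACGUACGUACGUACGUACGUA", 12)]
        candidates, rest = extract_novel_candidates(tags, PARAMS)
        assert len(candidates) == 2 and len(rest) == 1

    def test_empty_input(self):
        assert extract_novel_candidates([], PARAMS) == ([], [])


class TestBruteForceOracle:
    """Exact-identity matching must agree with an all-pairs scan."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_subtraction_and_identification_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGU"))
        refs = [ref("".join(rng.choice(bases, size=rng.integers(30, 80))),
                    species="ath", name=f"nc{i}", rna_class="rRNA")
                for i in range(20)]
        mirnas = [ref("".join(rng.choice(bases, size=rng.integers(18, 25))),
                      species="osa", name=f"miR{200 + i}")
                  for i in range(30)]
        tags = []
        for i in range(150):
            draw = rng.random()
            if draw < 0.3:  # window of an ncRNA
                source = refs[rng.integers(len(refs))].sequence
                length = int(rng.integers(15, min(30, len(source))))
                start = int(rng.integers(0, len(source) - length + 1))
                seq = source[start:start + length]
            elif draw < 0.6:  # exact mature sequence
                seq = mirnas[rng.integers(len(mirnas))].sequence
            else:
                seq = "".join(rng.choice(bases, size=rng.integers(15, 26)))
            tags.append(UniqueTag(seq, int(rng.integers(1, 40))))
        tags = list({t.sequence: t for t in tags}.values())

        retained, removed, short, _ = subtract_ncrna(tags, refs, PARAMS)
        for tag in tags:
            if len(tag.sequence) < PARAMS.min_tag_length:
                assert tag in short
            elif any(tag.sequence in r.sequence for r in refs):
                assert tag in removed
            else:
                assert tag in retained

        anns, unmatched, below = identify_conserved(retained, mirnas, PARAMS)
        annotated = {a.sequence for a in anns}
        for tag in retained:
            if tag.count < PARAMS.min_count:
                assert tag in below
            elif any(tag.sequence == m.sequence for m in mirnas):
                assert tag.sequence in annotated
            else:
                assert tag in unmatched


class TestPartition:
    def test_every_tag_lands_in_exactly_one_bin(self, sim_library, sim_refs,
                                                preprocess_params):
        from mirseed.preprocess import collapse, run_preprocess

        reads, _ = sim_library
        clean, _ = run_preprocess(reads, preprocess_params)
        tags = collapse(clean)
        bins, _ = annotate_tags(tags, sim_refs.ncrna, sim_refs.plant, PARAMS)
        n_binned = (len(bins.short) + len(bins.ncrna) + len(bins.conserved)
                    + len(bins.below_abundance) + len(bins.candidate)
                    + len(bins.other_unmatched))
        assert n_binned == len(tags)
        total = (sum(t.count for t in bins.short + bins.ncrna
                     + bins.below_abundance + bins.candidate
                     + bins.other_unmatched)
                 + sum(a.count for a in bins.conserved))
        assert total == sum(t.count for t in tags)


class TestProfiles:
    def test_family_summary_single_annotation(self):
        from mirseed.annotate import AnnotatedMiRNA

        ann = AnnotatedMiRNA("mol-miR168a", "miR168", "mature",
                             "UCGCUUGGUGCAGGUCGGGAC", 165, [])
        (summary,) = family_summary([ann])
        assert (summary.family, summary.n_members, summary.total_count) == \
            ("miR168", 1, 165)

    def test_length_distribution_by_read_and_by_tag(self):
        tags = [UniqueTag("A" * 21, 3), UniqueTag("C" * 24, 1)]
        by_read = length_distribution(tags, "by_read")
        assert by_read[21] == pytest.approx(0.75)
        assert by_read[24] == pytest.approx(0.25)
        by_tag = length_distribution(tags, "by_tag")
        assert by_tag[21] == by_tag[24] == pytest.approx(0.5)

    def test_length_distribution_empty(self):
        assert length_distribution([], "by_read").empty

    def test_proportions_sum_to_one(self, sim_library, preprocess_params):
        from mirseed.preprocess import collapse, run_preprocess

        reads, _ = sim_library
        clean, _ = run_preprocess(reads, preprocess_params)
        dist = length_distribution(collapse(clean), "by_read")
        assert dist.sum() == pytest.approx(1.0)
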