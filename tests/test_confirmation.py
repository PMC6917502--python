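"""Secondary-siRNA locus filters, phasing registers, degradome peak filters."""

import itertools

import numpy as np
import pytest

from transrna import confirmation, targeting
from transrna.seq_io import DegradomeProfile, LocusAlignmentSummary, LocusRead, TranscriptAnnotation

SRNA = "ACGTACGTACGTACGTACGTA"


def make_interaction(transcript_id="T1", site_start=300, score=2.0, length=21):
    return targeting.TargetInteraction(
        srna_seq=SRNA,
        transcript_id=transcript_id,
        site_start=site_start,
        site_end=site_start + length,
        score=score,
        pairing=[],
        predicted_cut=site_start + length - 10,
    )


def make_annotation(transcript_id="T1", organellar=False, length=600):
    return TranscriptAnnotation(
        transcript_id=transcript_id,
        seq="A" * length,
        cds_start=51,
        cds_end=531,
        organellar=organellar,
        gene_id="G1",
    )


def degradome_case(fail: set[int]):
    """Construct one degradome test case failing exactly the filters in
    ``fail`` (1-based filter indices). Returns (profiles, prediction, annot)."""
    hit = make_interaction(
        site_start=90 if 2 in fail else 300,
        score=7.0 if 1 in fail else 2.0,
    )
    annotation = make_annotation(organellar=3 in fail)
    cut = hit.predicted_cut
    profiles = []
    peak_depth = 40
    for rep_idx in range(3):
        prof = DegradomeProfile("T1", f"HD{rep_idx + 1}", "treatment")
        if 4 in fail:
            # 20 heavily occupied positions push the median above the peak
            for pos in range(10, 30):
                prof.depth[pos] = 60
        else:
            prof.depth[10] = 1  # light background below the peak
        if not (5 in fail and rep_idx == 2):
            prof.depth[cut] = peak_depth
        profiles.append(prof)
    control = DegradomeProfile("T1", "CD1", "control")
    if 6 in fail:
        control.depth[cut] = peak_depth // 5  # 5-fold, below the 10-fold rule
    profiles.append(control)
    return profiles, hit, {"T1": annotation}


class TestDegradomeConfirm:
    @pytest.mark.parametrize(
        "fail", [set(bits) for r in range(7) for bits in itertools.combinations(range(1, 7), r)]
    )
    def test_all_64_filter_combinations(self, fail):
        """Every pass/fail combination of the six filters lands exactly where
        constructed; confirmation is the all-pass conjunction."""
        profiles, hit, annotations = degradome_case(fail)
        (call,) = confirmation.degradome_confirm(profiles, [hit], annotations)
        assert call.passes == [i not in fail for i in range(1, 7)]
        assert call.confirmed == (not fail)

    def test_toggling_one_condition_flips_one_filter(self):
        for f in range(1, 7):
            profiles, hit, annotations = degradome_case({f})
            (call,) = confirmation.degradome_confirm(profiles, [hit], annotations)
            base_profiles, base_hit, base_ann = degradome_case(set())
            (base,) = confirmation.degradome_confirm(base_profiles, [base_hit], base_ann)
            flipped = [a != b for a, b in zip(call.passes, base.passes)]
            assert flipped == [i == f for i in range(1, 7)]

    def test_two_of_three_replicates_fails_presence_only(self):
        profiles, hit, annotations = degradome_case({5})
        (call,) = confirmation.degradome_confirm(profiles, [hit], annotations)
        assert call.passes[4] is False
        assert all(call.passes[:4]) and call.passes[5]

    def test_hundred_nt_start_rule_boundary(self):
        # site_start 100 (0-based) is NOT greater than 100 -> fails
        profiles, hit, annotations = degradome_case(set())
        hit.site_start, hit.site_end = 100, 121
        hit.predicted_cut = hit.site_end - 10
        prof_at = [DegradomeProfile("T1", f"HD{i+1}", "treatment", {hit.predicted_cut: 40}) for i in range(3)]
        (call,) = confirmation.degradome_confirm(prof_at, [hit], annotations)
        assert call.passes[1] is False
        hit.site_start, hit.site_end = 101, 122
        hit.predicted_cut = hit.site_end - 10
        prof_at = [DegradomeProfile("T1", f"HD{i+1}", "treatment", {hit.predicted_cut: 40}) for i in range(3)]
        (call,) = confirmation.degradome_confirm(prof_at, [hit], annotations)
        assert call.passes[1] is True

    def test_ten_fold_rule_boundary(self):
        profiles, hit, annotations = degradome_case(set())
        control = [p for p in profiles if p.condition == "control"][0]
        control.depth[hit.predicted_cut] = 4  # 40/4 = 10: passes (>= 10-fold)
        (call,) = confirmation.degradome_confirm(profiles, [hit], annotations)
        assert call.passes[5] is True and call.fold_vs_control == pytest.approx(10.0)
        control.depth[hit.predicted_cut] = 5  # 40/5 = 8 < 10: fails
        (call,) = confirmation.degradome_confirm(profiles, [hit], annotations)
        assert call.passes[5] is False

    def test_control_filter_can_be_disabled(self):
        profiles, hit, annotations = degradome_case({6})
        (call,) = confirmation.degradome_confirm(
            profiles, [hit], annotations, require_control_fold=False
        )
        assert call.confirmed

    def test_unknown_transcript_is_error(self):
        profiles, hit, annotations = degradome_case(set())
        hit.transcript_id = "nope"
        with pytest.raises(KeyError, match="nope"):
            confirmation.degradome_confirm(profiles, [hit], annotations)


def locus_case(fail: set[int], up: bool = True):
    """LocusStats + prediction failing exactly the given locus filters:
    1 site score, 2 unstranded, 3 predominant 21/22-nt size, 4 depth."""
    depth = 19 if 4 in fail else 200
    plus_fraction = 0.95 if 2 in fail else 0.5
    sizes = {24: depth} if 3 in fail else {21: depth - depth // 3, 22: depth // 3}
    top = max(sizes.values())
    stats = confirmation.LocusStats(
        gene_id="G1",
        depth=depth,
        plus_fraction=plus_fraction,
        size_histogram=sizes,
        predominant_sizes={k for k, v in sizes.items() if v == top},
        up_regulated=up,
        padj=0.01 if up else 0.9,
    )
    hit = make_interaction(score=7.0 if 1 in fail else 2.0)
    return stats, hit


class TestSecondarySirnaConfirm:
    @pytest.mark.parametrize(
        "fail,up",
        [
            (set(bits), up)
            for r in range(5)
            for bits in itertools.combinations(range(1, 5), r)
            for up in (True, False)
        ],
    )
    def test_filter_truth_table(self, fail, up):
        stats, hit = locus_case(fail, up)
        (call,) = confirmation.secondary_sirna_confirm(
            {"G1": stats}, [hit], {"T1": "G1"}
        )
        assert call.passes == [i not in fail for i in range(1, 5)]
        assert call.confirmed == (up and not fail)

    def test_depth_boundary_19_vs_20(self):
        stats, hit = locus_case(set())
        stats.depth = 19
        (call,) = confirmation.secondary_sirna_confirm({"G1": stats}, [hit], {"T1": "G1"})
        assert call.passes == [True, True, True, False]
        stats.depth = 20
        (call,) = confirmation.secondary_sirna_confirm({"G1": stats}, [hit], {"T1": "G1"})
        assert call.confirmed

    def test_size_tie_including_21_or_22_passes(self):
        stats, hit = locus_case(set())
        stats.size_histogram = {21: 50, 24: 50}
        stats.predominant_sizes = {21, 24}
        (call,) = confirmation.secondary_sirna_confirm({"G1": stats}, [hit], {"T1": "G1"})
        assert call.passes[2] is True

    def test_unknown_gene_in_prediction_is_error(self):
        stats, hit = locus_case(set())
        with pytest.raises(KeyError):
            confirmation.secondary_sirna_confirm({"G1": stats}, [hit], {})

    def test_both_channel_intersection(self):
        stats, hit = locus_case(set())
        locus_calls = confirmation.secondary_sirna_confirm({"G1": stats}, [hit], {"T1": "G1"})
        profiles, dhit, annotations = degradome_case(set())
        peak_calls = confirmation.degradome_confirm(profiles, [dhit], annotations)
        both = confirmation.confirmed_by_both(locus_calls, peak_calls, {"T1": "G1"})
        assert both == {"G1"}
        profiles, dhit, annotations = degradome_case({6})
        peak_calls = confirmation.degradome_confirm(profiles, [dhit], annotations)
        assert confirmation.confirmed_by_both(locus_calls, peak_calls, {"T1": "G1"}) == set()


class TestPhasing:
    def test_perfectly_phased_reads(self):
        cut = 400
        profile = confirmation.phasing_profile([cut, cut + 21, cut + 42, cut + 63], cut)
        assert profile.in_phase_fraction == 1.0
        assert profile.register_counts[0] == 4 and sum(profile.register_counts) == 4

    def test_offset_reads_land_in_register_two(self):
        cut = 400
        profile = confirmation.phasing_profile([cut + 1, cut + 22], cut)
        assert profile.register_counts[1] == 2
        assert profile.in_phase_fraction == 0.0

    def test_uniform_positions_near_one_twentyfirst(self, rng):
        positions = rng.integers(0, 10_000, size=10_000)
        profile = confirmation.phasing_profile(positions.tolist(), cut_pos=0)
        n = sum(profile.register_counts)
        assert n == 10_000
        p = 1 / 21
        sd = np.sqrt(p * (1 - p) / n)
        for count in profile.register_counts:
            assert abs(count / n - p) < 3 * sd

    def test_empty_reads_is_error(self):
        with pytest.raises(ValueError):
            confirmation.phasing_profile([], 100)

    def test_total_is_conserved(self, rng):
        positions = rng.integers(0, 500, size=321).tolist()
        profile = confirmation.phasing_profile(positions, 42)
        assert sum(profile.register_counts) == 321


class TestLocusStats:
    def test_from_summaries_aggregates_strands_and_sizes(self):
        reads_plus = [LocusRead(10 + 21 * k, 21, "+") for k in range(6)]
        reads_minus = [LocusRead(12 + 21 * k, 22, "-") for k in range(4)]
        summaries = [
            LocusAlignmentSummary("G1", "LI1", reads_plus),
            LocusAlignmentSummary("G1", "LI2", reads_minus),
            LocusAlignmentSummary("G2", "LI1", [LocusRead(5, 24, "+")]),
        ]
        stats = confirmation.LocusStats.from_summaries(summaries, "G1")
        assert stats.depth == 10
        assert stats.plus_fraction == pytest.approx(0.6)
        assert stats.size_histogram == {21: 6, 22: 4}
        assert stats.predominant_sizes == {21}
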