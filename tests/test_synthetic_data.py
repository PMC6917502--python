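"""Generators: determinism, truth completeness, and statistical structure."""

import numpy as np
import pytest

from transrna import synthetic_data as sd
from transrna.covariation import translate_codons
from transrna.discovery import levenshtein
from transrna.seq_io import reverse_complement
from transrna.targeting import build_pairing, complementarity_score


class TestConfig:
    def test_rate_ordering_enforced(self):
        with pytest.raises(ValueError):
            sd.ScenarioConfig(synonymous_rate=0.01, nonsynonymous_rate=0.5)

    def test_fold_change_must_exceed_one(self):
        with pytest.raises(ValueError):
            sd.ScenarioConfig(fold_change=1.0)


class TestDeterminism:
    def test_same_seed_same_scenario(self):
        a = sd.make_scenario(seed=3)
        b = sd.make_scenario(seed=3)
        assert a.transcripts == b.transcripts
        assert [r.counts for r in a.srna_records] == [r.counts for r in b.srna_records]
        assert a.truth_dict() == b.truth_dict()

    def test_different_seed_differs(self):
        a = sd.make_scenario(seed=3)
        b = sd.make_scenario(seed=4)
        assert a.transcripts != b.transcripts

    def test_write_scenario_byte_identical(self, tmp_path):
        a = sd.make_scenario(seed=5)
        p1 = sd.write_scenario(a, tmp_path / "run1")
        p2 = sd.write_scenario(sd.make_scenario(seed=5), tmp_path / "run2")
        for name in p1:
            assert open(p1[name], "rb").read() == open(p2[name], "rb").read()


class TestSuperfamilies:
    def test_covarying_member_variation_is_synonymous(self):
        cfg = sd.ScenarioConfig(n_superfamilies=2, n_null_families=0, nonsynonymous_rate=0.0)
        for fam in sd.make_superfamilies_and_homologs(cfg, seed=1):
            base_pep = translate_codons(fam.base_site)
            for _, member in fam.members:
                assert translate_codons(reverse_complement(member)) == base_pep

    def test_homolog_translations_mostly_conserved(self):
        cfg = sd.ScenarioConfig(n_superfamilies=3, n_null_families=0)
        rates = []
        for fam in sd.make_superfamilies_and_homologs(cfg, seed=2):
            base_pep = translate_codons(fam.base_site)
            for site in fam.species_sites.values():
                pep = translate_codons(site)
                rates.append(np.mean([a != b for a, b in zip(pep, base_pep)]))
        # nonsynonymous rate 0.02/codon: amino-acid divergence stays rare
        assert np.mean(rates) < 0.1

    def test_causative_srna_within_score_six_of_reference_site(self):
        cfg = sd.ScenarioConfig(n_superfamilies=4, n_null_families=2)
        for fam in sd.make_superfamilies_and_homologs(cfg, seed=3):
            site = fam.base_site
            pairing = build_pairing(fam.causative_srna, site)
            assert complementarity_score(fam.causative_srna, site, pairing) <= 6.0
            # outside the read-condensation radius of the perfect complement
            assert levenshtein(fam.causative_srna, reverse_complement(site)) >= 3

    def test_null_family_variation_decoupled_from_frame(self):
        """Null members vary at permuted (frame-free) positions: the fraction
        of variable positions landing on third codon positions stays near 1/3,
        while covarying families concentrate variation there."""
        cfg = sd.ScenarioConfig(
            n_superfamilies=12, n_null_families=6, members_per_family=8, nonsynonymous_rate=0.0
        )
        fams = sd.make_superfamilies_and_homologs(cfg, seed=4)

        def third_position_fraction(fam):
            members = [reverse_complement(s) for _, s in fam.members]
            variable = [
                i for i in range(21) if len({m[i] for m in members}) > 1
            ]
            if not variable:
                return None
            return np.mean([i % 3 == 2 for i in variable])

        null_frac = np.mean([f for fam in fams if not fam.covarying if (f := third_position_fraction(fam)) is not None])
        cov_frac = np.mean([f for fam in fams if fam.covarying if (f := third_position_fraction(fam)) is not None])
        assert cov_frac > 0.8
        assert null_frac < 0.6


class TestTranscriptome:
    def test_registry_complete_and_sites_planted(self, scenario):
        true_entries = [p for p in scenario.registry if p.kind == "true"]
        assert len(true_entries) == scenario.config.n_superfamilies
        decoy_kinds = {p.kind for p in scenario.registry if p.kind != "true"}
        assert decoy_kinds == {
            "near_tss", "organellar", "below_median", "peak_2of3", "low_fold",
            "stranded", "wrong_size", "low_depth", "not_up",
        }
        for p in scenario.registry:
            site = scenario.transcripts[p.transcript_id][p.site_start : p.site_end]
            # the planted causative sRNA scores well against its site
            pairing = build_pairing(p.srna, site)
            assert complementarity_score(p.srna, site, pairing) <= 6.0

    def test_true_sites_deep_in_transcript_and_in_cds(self, scenario):
        for p in scenario.registry:
            ann = scenario.annotations[p.transcript_id]
            if p.kind == "true":
                assert p.site_start > 100
                assert ann.cds_start <= p.site_start and p.site_end <= ann.cds_end
                assert (p.site_start - ann.cds_start) % 3 == 0
            if p.kind == "near_tss":
                assert p.site_start <= 100
            if p.kind == "organellar":
                assert ann.organellar

    def test_organellar_flag_only_on_decoy(self, scenario):
        organellar = {tid for tid, a in scenario.annotations.items() if a.organellar}
        decoy = {p.transcript_id for p in scenario.registry if p.kind == "organellar"}
        assert organellar == decoy


class TestLibraries:
    def test_nb_mean_recovery_of_planted_fold(self):
        cfg = sd.ScenarioConfig()
        means = []
        for seed in range(6):
            scen = sd.make_scenario(seed=seed)
            fam = scen.families[-1]
            iso, seq = fam.members[1][0], fam.members[1][1]
            rec = next(r for r in scen.srna_records if r.seq == seq)
            interface = [rec.counts[lib] for lib in scen.libraries[f"{iso}_interface"]]
            means.append(np.mean(interface))
        expected = cfg.base_mean * cfg.fold_change
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - expected) < 3 * max(se, 1.0) + 3 * expected * np.sqrt(cfg.dispersion / 18)

    def test_background_srnas_not_differential(self, scenario):
        planted = {s for _, s in scenario.planted_hi} | {s for _, s in scenario.host_filtered_hi}
        planted |= {s for _, s in scenario.expected_condensed_hi}
        variants = {v for vs in scenario.error_variants.values() for v in vs}
        ratios = []
        for rec in scenario.srna_records:
            if rec.seq in planted or rec.seq in variants or len(rec.seq) != 21:
                continue
            interface = np.mean([rec.counts[lib] for lib in scenario.libraries["ccm_interface"]])
            stem = np.mean([rec.counts[lib] for lib in scenario.libraries["ccm_stem"]])
            if stem > 0 and interface > 0:
                ratios.append(interface / stem)
        assert ratios and 0.6 < float(np.median(ratios)) < 1.6

    def test_error_variants_within_condensation_radius(self, scenario):
        for parent, variants in scenario.error_variants.items():
            for var in variants:
                assert 1 <= levenshtein(parent, var) <= 2

    def test_host_filtered_members_are_transcript_substrings(self, scenario):
        for _, seq in scenario.host_filtered_hi:
            rc = reverse_complement(seq)
            assert any(rc in t or seq in t for t in scenario.transcripts.values())


class TestDegradomePhasing:
    def test_true_peaks_in_all_treatment_replicates(self, scenario):
        for p in scenario.registry:
            if p.kind != "true":
                continue
            reps = [
                prof for prof in scenario.degradome
                if prof.transcript_id == p.transcript_id and prof.condition == "treatment"
            ]
            assert len(reps) == scenario.config.n_degradome_replicates
            assert all(prof.depth.get(p.cut_pos, 0) >= 1 for prof in reps)

    def test_peak_2of3_missing_from_one_replicate(self, scenario):
        p = next(p for p in scenario.registry if p.kind == "peak_2of3")
        depths = [
            prof.depth.get(p.cut_pos, 0)
            for prof in scenario.degradome
            if prof.transcript_id == p.transcript_id and prof.condition == "treatment"
        ]
        assert sorted(d > 0 for d in depths) == [False, True, True]

    def test_zero_phasing_noise_gives_perfect_phase(self):
        cfg = sd.ScenarioConfig(phasing_noise=0.0)
        scen = sd.make_scenario(cfg, seed=8)
        from transrna.confirmation import phasing_profile

        p = next(p for p in scen.registry if p.kind == "true")
        positions = [
            r.pos5
            for s in scen.locus_summaries
            if s.gene_id == p.gene_id and s.library_id.startswith("LI")
            for r in s.reads
            if r.strand == "+"
        ]
        assert phasing_profile(positions, p.cut_pos).in_phase_fraction == 1.0

    def test_low_depth_locus_has_nineteen_reads(self, scenario):
        p = next(p for p in scenario.registry if p.kind == "low_depth")
        n = sum(
            len(s.reads)
            for s in scenario.locus_summaries
            if s.gene_id == p.gene_id and s.library_id.startswith("LI")
        )
        assert n == 19
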