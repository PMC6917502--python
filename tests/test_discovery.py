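"""Discovery chain: size filter, greedy condensation, host filter, NB test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transrna import discovery
from transrna.seq_io import SequenceRecord


def lev_dp(a: str, b: str) -> int:
    """Independent dynamic-programming Levenshtein distance (test oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def oracle_condense(records, dist, rpm_min, totals):
    """Literal transcription of the greedy algorithm with all pairwise
    distances computed by the DP oracle."""
    order = sorted(records, key=lambda r: (-sum(r.counts.values()), r.seq))
    reps: list[str] = []
    clusters: dict[str, dict] = {}
    for rec in order:
        home = None
        for rep in reps:
            if lev_dp(rec.seq, rep) <= dist:
                home = rep
                break
        if home is None:
            reps.append(rec.seq)
            clusters[rec.seq] = {"members": {rec.seq}, "counts": dict(rec.counts)}
        else:
            clusters[home]["members"].add(rec.seq)
            for lib, n in rec.counts.items():
                clusters[home]["counts"][lib] = clusters[home]["counts"].get(lib, 0) + n
    out = {}
    for rep, data in clusters.items():
        max_rpm = max(
            1e6 * n / totals[lib] for lib, n in data["counts"].items() if totals.get(lib)
        )
        if max_rpm >= rpm_min:
            out[rep] = (frozenset(data["members"]), tuple(sorted(data["counts"].items())))
    return out


def random_cloud_records(rng, n_clouds=3, n_background=40, libs=("L1", "L2")):
    """Unique sequences: a few abundant representatives with <=2-edit variant
    clouds plus random background reads."""
    records = {}

    def add(seq, mean):
        if seq in records:
            return
        records[seq] = SequenceRecord(
            id=seq, seq=seq, counts={lib: int(rng.poisson(mean)) + 1 for lib in libs}
        )

    for _ in range(n_clouds):
        rep = "".join(rng.choice(list("ACGT"), size=21))
        add(rep, 300)
        for _ in range(int(rng.integers(2, 6))):
            var = list(rep)
            for _ in range(int(rng.integers(1, 3))):
                pos = int(rng.integers(21))
                var[pos] = rng.choice([b for b in "ACGT" if b != var[pos]])
            add("".join(var), 20)
    for _ in range(n_background):
        add("".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 25)))), 50)
    return list(records.values())


class TestSizeFilter:
    def test_band_boundaries(self):
        records = [SequenceRecord(id=str(n), seq="A" * n) for n in (19, 20, 24, 25)]
        kept = discovery.size_filter(records, 20, 24)
        assert [len(r.seq) for r in kept] == [20, 24]

    def test_empty_input(self):
        assert discovery.size_filter([], 20, 24) == []

    def test_all_in_band_is_identity(self):
        records = [SequenceRecord(id=str(i), seq="ACGTACGTACGTACGTACGTA") for i in range(3)]
        assert discovery.size_filter(records, 20, 24) == records


class TestCondense:
    def test_variant_cloud_combined_abundance(self):
        a = "ACGTACGTACGTACGTACGTA"
        a_var = "ACGTACGTACGTACGTACGTT"  # one substitution
        records = [
            SequenceRecord(id="a", seq=a, counts={"L1": 100}),
            SequenceRecord(id="v", seq=a_var, counts={"L1": 5}),
        ]
        (cluster,) = discovery.condense(records, condense_dist=2, rpm_min=0.5)
        assert cluster.representative_seq == a
        assert cluster.counts == {"L1": 105}
        assert cluster.members == {a, a_var}

    def test_distant_sequences_stay_separate(self):
        records = [
            SequenceRecord(id="a", seq="A" * 21, counts={"L1": 10}),
            SequenceRecord(id="b", seq="C" * 21, counts={"L1": 10}),
        ]
        clusters = discovery.condense(records, condense_dist=2, rpm_min=0.5)
        assert len(clusters) == 2

    def test_rpm_floor_discards_lonely_reads(self):
        # 1 read in a million-read library = 1 RPM >= 0.5; 1 in 4M = 0.25 < 0.5
        records = [SequenceRecord(id="a", seq="A" * 21, counts={"L1": 1})]
        kept = discovery.condense(records, 2, 0.5, totals={"L1": 4_000_000})
        assert kept == []
        kept = discovery.condense(records, 2, 0.5, totals={"L1": 1_000_000})
        assert len(kept) == 1

    def test_no_library_counts_is_error(self):
        with pytest.raises(ValueError):
            discovery.condense([SequenceRecord(id="a", seq="A" * 21)], 2, 0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        records = random_cloud_records(rng)
        totals = discovery.library_totals(records)
        got = {
            c.representative_seq: (frozenset(c.members), tuple(sorted(c.counts.items())))
            for c in discovery.condense(records, 2, 0.5, totals)
        }
        assert got == oracle_condense(records, 2, 0.5, totals)

    def test_count_conservation_before_rpm_discard(self, rng):
        records = random_cloud_records(rng)
        totals = discovery.library_totals(records)
        clusters = discovery.condense(records, 2, rpm_min=0.0, totals=totals)
        for lib in totals:
            assert sum(c.counts[lib] for c in clusters) == totals[lib]

    def test_permutation_invariance(self, rng):
        records = random_cloud_records(rng, n_clouds=2, n_background=20)
        reference = discovery.condense(records, 2, 0.5)
        perm = list(records)
        rng.shuffle(perm)
        shuffled = discovery.condense(perm, 2, 0.5)
        assert {c.representative_seq for c in reference} == {
            c.representative_seq for c in shuffled
        }


class TestHostFilter:
    def make_cluster(self, seq, counts, totals):
        (cluster,) = discovery.condense(
            [SequenceRecord(id=seq, seq=seq, counts=counts)], 2, 0.0, totals
        )
        return cluster

    def test_rule1_host_mirna_similarity(self):
        mir = "ACGTACGTACGTACGTACGTA"
        cluster = self.make_cluster(mir, {"P1": 100, "P2": 100}, {"P1": 1000, "P2": 1000})
        kept = discovery.host_filter(
            [cluster],
            [SequenceRecord(id="miR", seq=mir)],
            discovery.HostSequenceIndex([]),
            control_libs=[],
            parasite_libs=["P1", "P2"],
        )
        assert kept == []

    def test_rule2_reverse_complement_substring(self):
        srna = "ACGTACGTACGTACGTACGTA"
        host = "TTTT" + "TACGTACGTACGTACGTACGT" + "GGGG"  # contains revcomp(srna)
        cluster = self.make_cluster(srna, {"P1": 100, "P2": 100}, {"P1": 1000, "P2": 1000})
        kept = discovery.host_filter(
            [cluster], [], discovery.HostSequenceIndex([host]), [], ["P1", "P2"]
        )
        assert kept == []

    def test_rule3_hundredth_boundary_is_strict(self):
        srna = "ACGTACGTACGTACGTACGTA"
        # control 0.4 RPM vs parasite 50 RPM: 0.4 <= 0.5 -> retained
        counts = {"C1": 4, "P1": 500}
        totals = {"C1": 10_000_000, "P1": 10_000_000}
        cluster = self.make_cluster(srna, counts, totals)
        kept = discovery.host_filter(
            [cluster], [], discovery.HostSequenceIndex([]), ["C1"], ["P1"]
        )
        assert len(kept) == 1
        # control 0.6 RPM > 0.5 -> removed
        cluster = self.make_cluster(srna, {"C1": 6, "P1": 500}, totals)
        kept = discovery.host_filter(
            [cluster], [], discovery.HostSequenceIndex([]), ["C1"], ["P1"]
        )
        assert kept == []

    def test_zero_parasite_with_control_signal_removed(self):
        srna = "ACGTACGTACGTACGTACGTA"
        totals = {"C1": 1000, "P1": 1000}
        cluster = self.make_cluster(srna, {"C1": 10, "P1": 0}, totals)
        assert (
            discovery.host_filter([cluster], [], discovery.HostSequenceIndex([]), ["C1"], ["P1"])
            == []
        )
        cluster = self.make_cluster(srna, {"C1": 0, "P1": 0}, totals)
        assert (
            len(discovery.host_filter([cluster], [], discovery.HostSequenceIndex([]), ["C1"], ["P1"]))
            == 1
        )


class TestCallHiSrnas:
    def make_condensed(self, counts_rows, libs):
        out = []
        for i, row in enumerate(counts_rows):
            seq = np.base_repr(i + 4**10, base=4)
            seq = seq.translate(str.maketrans("0123", "ACGT"))[-21:].rjust(21, "A")
            out.append(
                discovery.CondensedSRNA(
                    representative_seq=seq,
                    members={seq},
                    counts=dict(zip(libs, row)),
                )
            )
        return out

    def test_all_equal_counts_no_calls(self):
        libs = ["I1", "I2", "I3", "S1", "S2", "S3"]
        condensed = self.make_condensed([[50] * 6] * 20, libs)
        calls = discovery.call_hi_srnas(condensed, libs[:3], libs[3:], fdr=0.99)
        assert calls == []

    def test_fewer_than_two_replicates_is_error(self):
        libs = ["I1", "S1", "S2"]
        condensed = self.make_condensed([[50, 50, 50]], libs)
        with pytest.raises(ValueError, match="replicate"):
            discovery.call_hi_srnas(condensed, ["I1"], ["S1", "S2"])

    def test_calls_are_subset_and_fdr_monotone(self, rng):
        libs = ["I1", "I2", "I3", "S1", "S2", "S3"]
        rows = rng.negative_binomial(20, 20 / (20 + 100.0), size=(50, 6))
        rows[:10, :3] *= 8
        condensed = self.make_condensed(rows.tolist(), libs)
        strict = discovery.call_hi_srnas(condensed, libs[:3], libs[3:], fdr=0.05)
        loose = discovery.call_hi_srnas(condensed, libs[:3], libs[3:], fdr=0.2)
        reps = {c.representative_seq for c in condensed}
        assert {h.representative_seq for h in strict} <= reps
        assert {h.representative_seq for h in strict} <= {
            h.representative_seq for h in loose
        }
        assert all(h.log2fc > 0 for h in loose)


class TestBenjaminiHochberg:
    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        pvals = rng.uniform(size=200)
        ours = discovery.benjamini_hochberg(pvals)
        _, theirs, _, _ = multipletests(pvals, method="fdr_bh")
        assert np.allclose(ours, theirs)


@settings(max_examples=30, deadline=None)
@given(
    st.text(alphabet="ACGT", min_size=1, max_size=25),
    st.text(alphabet="ACGT", min_size=1, max_size=25),
)
def test_levenshtein_matches_dp_oracle(a, b):
    assert discovery.levenshtein(a, b) == lev_dp(a, b)
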