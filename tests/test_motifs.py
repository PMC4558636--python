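"""Motif scanners against brute-force oracles, plus summary statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from phloemscan.genome import DownstreamSequence, reverse_complement
from phloemscan.motifs import (
    CuParams,
    MotifDefinition,
    builtin_motifs,
    cooccurrence_table,
    find_cu_runs,
    hits_to_frame,
    load_pwm,
    multiplicity_histogram,
    parse_consensus,
    positional_profile,
    ptb_cluster_call,
    rbp50_definition,
    rbp50_screen,
    scan_consensus,
    scan_pwm,
)

from conftest import random_dna
from oracles import oracle_consensus, oracle_cu_runs, oracle_pwm

DEFS = builtin_motifs()


class TestParseConsensus:
    def test_rna_letters_map_to_dna(self):
        assert parse_consensus("UGUA[UCA]AUA") == parse_consensus("TGTA[TCA]ATA")

    def test_bracket_degeneracy(self):
        positions = parse_consensus("A[CT]G")
        assert positions == (frozenset("A"), frozenset("CT"), frozenset("G"))

    @pytest.mark.parametrize("bad", ["A[XY]G", "A[]G", "AXG"])
    def test_invalid_positions_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_consensus(bad)


class TestScanConsensus:
    def test_pumilio_exact_element(self):
        hs = scan_consensus("TGTACATA", DEFS["pumilio"], gene_id="g")
        assert hs.hit_positions == (0,) and hs.is_target

    def test_pumilio_disallowed_fifth_base(self):
        hs = scan_consensus("TGTAGATA", DEFS["pumilio"], gene_id="g")
        assert hs.count == 0 and not hs.is_target

    def test_nova_two_hits(self):
        hs = scan_consensus("ACATTTCACACATTTCAT", DEFS["nova"], gene_id="g")
        assert hs.hit_positions == (0, 9)

    def test_overlapping_hits_all_reported(self):
        # a self-overlapping degenerate motif: TT[CT]T matches TTTTT at 0 and 1
        motif = MotifDefinition.consensus("m", "TT[CT]T")
        hits = scan_consensus("TTTTT", motif).hit_positions
        assert hits == (0, 1)
        assert list(hits) == oracle_consensus("TTTTT", motif.positions)

    def test_sequence_shorter_than_motif(self):
        assert scan_consensus("TGT", DEFS["pumilio"]).count == 0

    def test_n_never_matches(self):
        assert scan_consensus("TGTANATA", DEFS["pumilio"]).count == 0

    def test_accepts_downstream_sequence(self):
        dss = DownstreamSequence("g7", 8, "TGTACATA", False)
        assert scan_consensus(dss, DEFS["pumilio"]).gene_id == "g7"

    @given(st.text(alphabet="ACGTN", min_size=0, max_size=300))
    def test_matches_bruteforce(self, seq):
        for motif in (DEFS["pumilio"], DEFS["nova"]):
            assert list(scan_consensus(seq, motif).hit_positions) == oracle_consensus(
                seq, motif.positions
            )

    @given(st.text(alphabet="ACGT", min_size=10, max_size=200))
    def test_reverse_complement_consistency(self, seq):
        """Scanning the RC with the RC'd motif mirrors the hit positions."""
        motif = DEFS["pumilio"]
        rc_positions = tuple(
            frozenset(reverse_complement(b) for b in s) for s in reversed(motif.positions)
        )
        rc_motif = MotifDefinition(name="rc", kind="consensus", positions=rc_positions)
        fwd = scan_consensus(seq, motif).hit_positions
        rc = scan_consensus(reverse_complement(seq), rc_motif).hit_positions
        w = len(motif.positions)
        mirrored = tuple(sorted(len(seq) - w - p for p in fwd))
        assert rc == mirrored


class TestScanPwm:
    def test_degenerate_pwm_reproduces_consensus(self, rng):
        """0/-inf PWM at threshold 0 equals the consensus scanner on random input."""
        motif = DEFS["pumilio"]
        matrix = [
            [0.0 if b in allowed else -np.inf for b in "ACGT"]
            for allowed in motif.positions
        ]
        pwm = MotifDefinition.pwm("pum_pwm", matrix, threshold=0.0)
        for _ in range(1000):
            seq = random_dna(rng, int(rng.integers(8, 60)))
            assert scan_pwm(seq, pwm).hit_positions == scan_consensus(seq, motif).hit_positions

    def test_uniform_pwm_threshold_minus_inf_hits_everywhere(self):
        pwm = MotifDefinition.pwm("u", [[0.0] * 4] * 3, threshold=-np.inf)
        seq = "ACGTACGT"
        assert scan_pwm(seq, pwm).count == len(seq) - 3 + 1

    def test_threshold_plus_inf_never_hits(self):
        pwm = MotifDefinition.pwm("u", [[0.0] * 4] * 3, threshold=np.inf)
        assert scan_pwm("ACGTACGT", pwm).count == 0

    def test_n_disqualifies_offset(self):
        pwm = MotifDefinition.pwm("u", [[0.0] * 4] * 3, threshold=-np.inf)
        assert scan_pwm("ANA", pwm).count == 0

    def test_default_threshold_is_fraction_of_max(self):
        matrix = [[2.0, 0.0, 0.0, 0.0], [0.0, 3.0, 0.0, 0.0]]
        pwm = MotifDefinition.pwm("m", matrix)  # threshold_frac=0.8
        assert pwm.threshold == pytest.approx(0.8 * 5.0)

    @given(st.text(alphabet="ACGTN", min_size=0, max_size=200), st.integers(0, 2**32 - 1))
    def test_matches_bruteforce(self, seq, seed):
        r = np.random.default_rng(seed)
        width = int(r.integers(2, 8))
        matrix = r.normal(size=(width, 4)).round(3).tolist()
        threshold = float(r.normal())
        pwm = MotifDefinition.pwm("m", matrix, threshold=threshold)
        assert list(scan_pwm(seq, pwm).hit_positions) == oracle_pwm(seq, matrix, threshold)

    def test_load_pwm_roundtrip(self, tmp_path):
        text = "A C G T\n2 0 0 0\n0 0 0 2\n"
        path = tmp_path / "m.pwm"
        path.write_text(text)
        pwm = load_pwm(str(path), name="at", threshold=4.0)
        assert scan_pwm("CATC", pwm).hit_positions == (1,)

    def test_load_pwm_bad_header(self):
        with pytest.raises(ValueError, match="header"):
            load_pwm("A C G\n1 2 3\n")


class TestCuRuns:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("CTCTAACTTTAACT", [(0, 4), (6, 4)]),  # hand enumeration
            ("CCCCCCCC", [(0, 8)]),  # one maximal run, not two
            ("AGAGAG", []),
            ("", []),
        ],
    )
    def test_examples(self, seq, expected):
        assert find_cu_runs(seq, 4) == expected

    def test_min_run_length_must_be_positive(self):
        with pytest.raises(ValueError):
            find_cu_runs("CCCC", 0)

    @given(st.text(alphabet="ACGT", min_size=0, max_size=400), st.integers(1, 6))
    def test_matches_bruteforce(self, seq, min_len):
        assert find_cu_runs(seq, min_len) == oracle_cu_runs(seq, min_len)


def _dss200(seq: str) -> DownstreamSequence:
    padded = (seq + "A" * 200)[:200]
    return DownstreamSequence("g", 200, padded, False)


class TestPtbClusterCall:
    def test_four_planted_runs_is_target(self):
        seq = list("A" * 200)
        for start in (0, 20, 40, 60):
            seq[start : start + 4] = "CTCT"
        hs = ptb_cluster_call(_dss200("".join(seq)))
        assert hs.is_target and hs.count == 4
        assert hs.hit_positions == (0, 20, 40, 60)

    def test_three_runs_is_not_target(self):
        seq = list("A" * 200)
        for start in (0, 20, 40):
            seq[start : start + 4] = "CTCT"
        hs = ptb_cluster_call(_dss200("".join(seq)))
        assert not hs.is_target and hs.count == 3

    def test_single_long_pyrimidine_tract_is_one_run(self):
        hs = ptb_cluster_call(_dss200("C" * 200))
        assert hs.count == 1 and not hs.is_target

    def test_window_mismatch_is_error(self):
        dss = DownstreamSequence("g", 500, "A" * 500, False)
        with pytest.raises(ValueError, match="200-nt"):
            ptb_cluster_call(dss, CuParams(window=200))

    @given(st.text(alphabet="ACGT", min_size=0, max_size=150),
           st.text(alphabet="ACGT", min_size=0, max_size=50))
    def test_appending_never_decreases_run_count(self, seq, extra):
        before = ptb_cluster_call(seq, gene_id="g").count
        after = ptb_cluster_call(seq + extra, gene_id="g").count
        assert after >= before

    @given(st.text(alphabet="ACGT", min_size=0, max_size=500))
    def test_window_prefix_consistency(self, seq):
        """Consensus hits at 200 nt equal the 500-nt hits starting before the cut."""
        motif = DEFS["pumilio"]
        w = len(motif.positions)
        long_hits = scan_consensus(seq, motif).hit_positions
        short_hits = scan_consensus(seq[:200], motif).hit_positions
        assert short_hits == tuple(p for p in long_hits if p < 200 - (w - 1))


class TestRbp50:
    def test_exact_motif_hits(self):
        assert rbp50_screen(_dss200("TTCTCTCTCCTTCTT")).count == 1

    def test_lowercase_positions_accept_pyrimidines(self):
        assert rbp50_screen(_dss200("TTCTCTCTTTTTCTT")).count == 1

    def test_lowercase_positions_reject_purines_by_default(self):
        assert rbp50_screen(_dss200("TTCTCTCTGGGTCTT")).count == 0

    def test_exact_policy_rejects_tt_variant(self):
        assert rbp50_screen(_dss200("TTCTCTCTTTTTCTT"), lowercase_policy="exact").count == 0

    def test_any_policy_accepts_purines(self):
        assert rbp50_screen(_dss200("TTCTCTCTGGGTCTT"), lowercase_policy="any").count == 1

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            rbp50_definition("weird")

    @given(st.text(alphabet="CT", min_size=15, max_size=120))
    def test_matches_bruteforce_on_pyrimidine_tracts(self, seq):
        motif = rbp50_definition()
        assert list(scan_consensus(seq, motif).hit_positions) == oracle_consensus(
            seq, motif.positions
        )


def _hitset(gene, motif, positions):
    from phloemscan.motifs import MotifHitSet

    return MotifHitSet(gene, motif, tuple(positions), len(positions), len(positions) >= 1)


class TestMultiplicity:
    def test_histogram_counts_genes_per_multiplicity(self):
        hits = [
            _hitset("g1", "pumilio", (0,)),
            _hitset("g2", "pumilio", (5,)),
            _hitset("g3", "pumilio", (0, 9)),
            _hitset("g4", "pumilio", tuple(range(0, 70, 10))),
        ]
        assert multiplicity_histogram(hits) == {1: 2, 2: 1, 7: 1}

    def test_zero_hit_genes_excluded(self):
        assert multiplicity_histogram([_hitset("g", "m", ())]) == {}

    def test_empty_input(self):
        assert multiplicity_histogram([]) == {}

    def test_mixed_motifs_rejected(self):
        hits = [_hitset("g1", "pumilio", (0,)), _hitset("g2", "nova", (0,))]
        with pytest.raises(ValueError, match="mixed"):
            multiplicity_histogram(hits)


class TestCooccurrence:
    def test_triple_positive_counts_in_all_combinations(self):
        table = cooccurrence_table({"a": {"g"}, "b": {"g"}, "c": {"g"}})
        assert (table["inclusion"] == 1).all()
        excl = dict(zip(table["combination"], table["exclusive"]))
        assert excl["a+b+c"] == 1
        assert excl["a"] == excl["a+b"] == 0

    def test_disjoint_positives(self):
        table = cooccurrence_table({"a": {"g1"}, "b": {"g2"}, "c": {"g3"}})
        rows = table.set_index("combination")
        assert rows.loc["a+b", "inclusion"] == 0
        assert rows.loc["a", "inclusion"] == 1
        assert rows.loc["a", "exclusive"] == 1

    @given(st.integers(0, 2**32 - 1))
    def test_random_assignment_matches_set_algebra(self, seed):
        r = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        sets = {m: {g for g in genes if r.random() < 0.4} for m in "abc"}
        table = cooccurrence_table(sets).set_index("combination")
        for combo in ("a", "b", "c", "a+b", "a+c", "b+c", "a+b+c"):
            members = combo.split("+")
            inter = set(genes)
            for m in members:
                inter &= sets[m]
            outside = set().union(*(sets[m] for m in "abc" if m not in members)) if len(members) < 3 else set()
            assert table.loc[combo, "inclusion"] == len(inter)
            assert table.loc[combo, "exclusive"] == len(inter - outside)


class TestPositionalProfile:
    def test_all_hits_in_first_bin(self):
        hits = [_hitset(f"g{i}", "pumilio", (i % 100,)) for i in range(100)]
        prof = positional_profile(hits, window=500, bin_width=100)
        assert prof.bin_counts == (100, 0, 0, 0, 0)
        assert prof.statistic == pytest.approx(400.0)
        assert prof.enrichment_p < 1e-10

    def test_uniform_counts_give_p_one(self):
        hits = [_hitset(f"g{i}", "m", (i,)) for i in range(500)]
        prof = positional_profile(hits, window=500, bin_width=100)
        assert prof.bin_counts == (100,) * 5
        assert prof.statistic == 0.0 and prof.enrichment_p == 1.0

    def test_no_hits_gives_zero_profile(self):
        prof = positional_profile([], window=500, bin_width=100, motif_name="m")
        assert prof.bin_counts == (0,) * 5 and prof.enrichment_p == 1.0

    def test_bin_width_must_divide_window(self):
        with pytest.raises(ValueError):
            positional_profile([], window=500, bin_width=300)

    def test_null_p_values_are_uniform(self, rng):
        """Seeded uniform hit positions yield approximately Uniform(0,1) p-values."""
        pvals = []
        for _ in range(200):
            offsets = rng.integers(0, 500, size=300)
            hits = [_hitset(f"g{i}", "m", (int(o),)) for i, o in enumerate(offsets)]
            pvals.append(positional_profile(hits, 500, 100).enrichment_p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_hits_frame_layout(self):
        frame = hits_to_frame([_hitset("g1", "m", (3, 8))], window=200)
        assert list(frame.columns) == ["gene_id", "motif", "position", "window"]
        assert frame["position"].tolist() == [3, 8]
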