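"""Library design: packing geometry, controls, combinatorics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from miaa import design as d

MOTIF8_A = d.MotifHypothesis("mA", "ACGTACGT", source="DeepAccess")
MOTIF8_B = d.MotifHypothesis("mB", "TTGGCCAA", source="DeepAccess")
MOTIF12 = d.MotifHypothesis("m12", "ACGTACGTACGT", source="DeepAccess")


def _random_bg(length=100, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


class TestMotifHypothesis:
    def test_rejects_non_iupac(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            d.MotifHypothesis("x", "ACGX")

    def test_discovery_motifs_length_bounded(self):
        with pytest.raises(ValueError, match="8-12"):
            d.MotifHypothesis("x", "ACGT", source="KMAC")
        # consensus-TF motifs may be shorter
        d.MotifHypothesis("x", "ACGT", source="consensus-TF")


class TestGCContent:
    @pytest.mark.parametrize(
        "seq,expected", [("GCGC", 1.0), ("ATAT", 0.0), ("ACGT", 0.5)]
    )
    def test_closed_form(self, seq, expected):
        assert d.gc_content(seq) == expected

    def test_rejects_ambiguity_codes(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            d.gc_content("ACGN")


class TestPerturbNative:
    def test_panel_of_24_from_6_natives(self, background_panel):
        assert len(background_panel) == 24
        assert all(len(b) == 100 for b in background_panel)

    def test_hamming_distance_forced_by_rate(self):
        native = _random_bg(seed=1)
        variants = d.perturb_native(native, 3, 0.1, [], seed=2)
        for v in variants:
            hamming = sum(a != b for a, b in zip(native, v))
            assert hamming == 10

    def test_forbidden_motif_screened_out(self):
        native = _random_bg(seed=3)
        gatc = d.MotifHypothesis("dam", "GATC")
        variants = d.perturb_native(native, 5, 0.1, [gatc], seed=4)
        for v in variants:
            assert "GATC" not in v

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            d.perturb_native(_random_bg(), 1, 1.5, [], seed=0)


class TestPackSingleMotif:
    def test_seven_placements_at_printed_positions(self):
        ds = d.pack_single_motif(_random_bg(seed=5), MOTIF8_A)
        starts = [s for _, s, _ in ds.placements]
        assert starts == [2, 16, 30, 44, 58, 72, 86]
        assert len(ds.placements) == 7
        # 8-nt motif at start 86 ends at position 93
        assert starts[-1] + len(MOTIF8_A) - 1 == 93

    def test_12nt_motif_fits(self):
        ds = d.pack_single_motif(_random_bg(seed=6), MOTIF12)
        last_end = max(s for _, s, _ in ds.placements) + len(MOTIF12) - 1
        assert last_end == 97 <= 100

    def test_scan_oracle_finds_all_copies(self):
        ds = d.pack_single_motif(_random_bg(seed=7), MOTIF8_A)
        hits = d.scan_motif("ACGTACGT", ds.variable_seq)
        assert len(hits) >= 7
        assert set([2, 16, 30, 44, 58, 72, 86]) <= set(hits)

    def test_length_preserved(self):
        ds = d.pack_single_motif(_random_bg(seed=8), MOTIF12)
        assert len(ds.variable_seq) == 100

    def test_overlong_motif_rejected(self):
        longm = d.MotifHypothesis("long", "A" * 15)
        with pytest.raises(ValueError, match="overlap"):
            d.pack_single_motif(_random_bg(), longm)


class TestPackMotifPair:
    def test_alternating_4_plus_3_layout(self):
        ds = d.pack_motif_pair(_random_bg(seed=9), MOTIF8_A, MOTIF8_B)
        a_starts = [s for m, s, _ in ds.placements if m == "mA"]
        b_starts = [s for m, s, _ in ds.placements if m == "mB"]
        assert a_starts == [2, 30, 58, 86]
        assert b_starts == [16, 44, 72]
        # alternating A/B along the sequence
        order = [m for m, _, _ in sorted(ds.placements, key=lambda p: p[1])]
        assert order == ["mA", "mB", "mA", "mB", "mA", "mB", "mA"]

    def test_scan_oracle_at_stated_offsets(self):
        ds = d.pack_motif_pair(_random_bg(seed=10), MOTIF8_A, MOTIF8_B)
        hits = d.scan_motif("ACGTACGT", ds.variable_seq)
        assert {2, 30, 58, 86} <= set(hits)

    def test_identical_motifs_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            d.pack_motif_pair(_random_bg(), MOTIF8_A, MOTIF8_A)


class TestChainPacking:
    def test_four_base_overlap_extension(self):
        seed = d.MotifHypothesis("s", "ACGTACGT", source="DeepAccess")
        cand = d.MotifHypothesis("c", "ACGTTTTT", source="DeepAccess")
        out = d.chain_pack_motifs(seed, [(cand, 1.0)], overlap=4, target_length=12)
        assert out == "ACGTACGTTTTT"

    def test_higher_score_wins(self):
        seed = d.MotifHypothesis("s", "ACGTACGT", source="DeepAccess")
        lo = d.MotifHypothesis("lo", "ACGTTTTT", source="DeepAccess")
        hi = d.MotifHypothesis("hi", "ACGTGGGG", source="DeepAccess")
        out = d.chain_pack_motifs(seed, [(lo, 3.0), (hi, 5.0)], overlap=4, target_length=12)
        assert out == "ACGTACGTGGGG"

    def test_chain_length_arithmetic(self):
        # every extension adds (len - overlap) bases before trim/pad
        seed = d.MotifHypothesis("s", "AAAACCCC", source="DeepAccess")
        m1 = d.MotifHypothesis("m1", "CCCCGGGG", source="DeepAccess")
        m2 = d.MotifHypothesis("m2", "GGGGTTTT", source="DeepAccess")
        out = d.chain_pack_motifs(seed, [(m1, 2.0), (m2, 1.0)], overlap=4, target_length=16)
        assert out == "AAAACCCCGGGGTTTT"
        assert len(out) == 8 + (8 - 4) + (8 - 4)

    def test_no_compatible_candidate_pads(self):
        seed = d.MotifHypothesis("s", "ACGTACGT", source="DeepAccess")
        bad = d.MotifHypothesis("b", "TTTTTTTT", source="DeepAccess")
        out = d.chain_pack_motifs(seed, [(bad, 1.0)], overlap=4, target_length=20)
        assert out.startswith("ACGTACGT") and len(out) == 20


def _brute_force_arrangement_count(n_per_set, copy_numbers):
    total = 0
    for n in n_per_set:
        total += n * len(copy_numbers)  # homotypic
        if 2 in copy_numbers:
            total += n * (n - 1)  # ordered pairs
        if 3 in copy_numbers and n >= 3:
            total += n * (n - 1) * (n - 2)  # ordered triples
    return total


class TestEnumerateArrangements:
    def _sets(self, n1, n2):
        mk = lambda tag, n: [
            d.MotifHypothesis(f"{tag}{i}", "ACGTACGT", source="DeepAccess") for i in range(n)
        ]
        return mk("a", n1), mk("b", n2)

    def test_standard_two_sets_of_three(self):
        arrs = d.enumerate_arrangements(self._sets(3, 3))
        assert len(arrs) == 42
        homo = [a for a in arrs if a.is_homotypic]
        hetero = [a for a in arrs if not a.is_homotypic]
        assert len(homo) == 18
        assert len([a for a in hetero if a.n_instances == 2]) == 12
        assert len([a for a in hetero if a.n_instances == 3]) == 12

    def test_two_instance_count_is_18(self):
        arrs = d.enumerate_arrangements(self._sets(3, 3))
        assert sum(1 for a in arrs if a.n_instances == 2) == 18

    def test_single_motif_single_copy(self):
        one = [d.MotifHypothesis("x", "ACGTACGT", source="DeepAccess")]
        arrs = d.enumerate_arrangements((one, []), copy_numbers={1})
        assert len(arrs) == 1 and arrs[0].is_homotypic

    def test_duplicate_ids_rejected(self):
        s1, _ = self._sets(3, 3)
        dup = s1 + [s1[0]]
        with pytest.raises(ValueError, match="duplicate"):
            d.enumerate_arrangements((dup, []))

    def test_ids_deterministic_and_unique(self):
        arrs = d.enumerate_arrangements(self._sets(3, 3))
        ids = [a.id for a in arrs]
        assert len(set(ids)) == len(ids)
        assert ids == [a.id for a in d.enumerate_arrangements(self._sets(3, 3))]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        n1=hst.integers(min_value=1, max_value=4),
        n2=hst.integers(min_value=1, max_value=4),
    )
    def test_count_matches_brute_force(self, n1, n2):
        arrs = d.enumerate_arrangements(self._sets(n1, n2))
        assert len(arrs) == _brute_force_arrangement_count([n1, n2], {1, 2, 3})


class TestPackArrangement:
    MOTIFS = {
        "m8": d.MotifHypothesis("m8", "ACGTACGT", source="DeepAccess"),
        "n8": d.MotifHypothesis("n8", "TTGGCCAA", source="DeepAccess"),
        "p8": d.MotifHypothesis("p8", "GGATTACC", source="DeepAccess"),
        "m10": d.MotifHypothesis("m10", "ACGTACGTAC", source="DeepAccess"),
    }

    def test_three_motifs_spacing_6_centered(self):
        arr = d.Arrangement("a", ("m8", "n8", "p8"), spacing_nt=6)
        bg = _random_bg(70, seed=11)
        ds = d.pack_arrangement(bg, arr, self.MOTIFS)
        starts = [s for _, s, _ in ds.placements]
        # span 8+6+8+6+8 = 36; offset floor((70-36)/2)+1 = 18
        assert starts == [18, 32, 46]
        assert len(ds.variable_seq) == 70

    def test_single_motif_centered(self):
        arr = d.Arrangement("a", ("m8",), spacing_nt=20)
        ds = d.pack_arrangement(_random_bg(70, seed=12), arr, self.MOTIFS)
        assert ds.placements == [("m8", 32, 0)]

    def test_exact_fit_offset_1(self):
        arr = d.Arrangement("a", ("m10", "m10", "m10"), spacing_nt=20)
        ds = d.pack_arrangement(_random_bg(70, seed=13), arr, self.MOTIFS)
        assert ds.placements[0][1] == 1

    def test_overflow_rejected_with_span(self):
        arr = d.Arrangement("a", ("m10", "m10", "m10"), spacing_nt=21)
        with pytest.raises(ValueError, match="72"):
            d.pack_arrangement(_random_bg(70, seed=14), arr, self.MOTIFS)

    def test_gap_between_motifs_is_spacing(self):
        arr = d.Arrangement("a", ("m8", "n8"), spacing_nt=6)
        ds = d.pack_arrangement(_random_bg(70, seed=15), arr, self.MOTIFS)
        (_, s1, _), (_, s2, _) = ds.placements
        assert s2 - (s1 + 8 - 1) - 1 == 6


class TestShuffleControl:
    def test_multiset_conserved_and_involution(self):
        ds = d.pack_single_motif(_random_bg(seed=16), MOTIF8_A, background_id="bg0")
        ctrl = d.shuffle_control(ds, seed=3)
        assert sorted(ctrl.variable_seq) == sorted(ds.variable_seq)
        assert ctrl.gc == ds.gc
        assert ctrl.shuffle_partner_id == ds.id
        assert ds.shuffle_partner_id == ctrl.id
        assert ctrl.design_class == "shuffle_control"

    def test_homopolymer_fixed_point(self):
        ds = d.DesignedSequence(id="h", variable_seq="A" * 50, background_id="bg")
        assert d.shuffle_control(ds, seed=1).variable_seq == "A" * 50


class TestAssembleOligo:
    FLANK5 = "T" * 25
    FLANK3 = "A" + "GATC" + "T" * 20

    def _design(self, n):
        return d.DesignedSequence(id="x", variable_seq="C" * n, background_id="bg")

    @pytest.mark.parametrize("var_len,oligo_len", [(100, 150), (70, 120)])
    def test_total_length(self, var_len, oligo_len):
        oligo = d.assemble_oligo(self._design(var_len), self.FLANK5, self.FLANK3)
        assert len(oligo) == oligo_len

    def test_gatc_one_nt_downstream_of_variable(self):
        oligo = d.assemble_oligo(self._design(100), self.FLANK5, self.FLANK3)
        # variable region ends at 1-based 125; 1-nt gap; GATC at 127-130
        assert oligo[126:130] == "GATC"

    def test_bad_flanks_rejected(self):
        with pytest.raises(ValueError, match="25 nt"):
            d.assemble_oligo(self._design(100), "T" * 24, self.FLANK3)
        with pytest.raises(ValueError, match="GATC"):
            d.assemble_oligo(self._design(100), self.FLANK5, "T" * 25)


class TestIupac:
    def test_concretize_resolves_to_allowed_bases(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            out = d.concretize_motif("RYSWKMN", rng)
            assert d.iupac_matches("RYSWKMN", out)

    def test_concretize_deterministic_under_seed(self):
        a = d.concretize_motif("NNNNNNNN", np.random.default_rng(5))
        b = d.concretize_motif("NNNNNNNN", np.random.default_rng(5))
        assert a == b


@settings(deadline=None, max_examples=50, derandomize=True)
@given(seed=hst.integers(min_value=0, max_value=10_000))
def test_packing_never_changes_length(seed):
    bg = _random_bg(100, seed=seed)
    rng = np.random.default_rng(seed)
    for packed in (
        d.pack_single_motif(bg, MOTIF8_A, rng=rng),
        d.pack_motif_pair(bg, MOTIF8_A, MOTIF8_B, rng=rng),
    ):
        assert len(packed.variable_seq) == 100
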