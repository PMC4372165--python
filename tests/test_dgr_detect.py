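import numpy as np
import pytest

from _oracles import oracle_repeat_pair_exists
from dgrscope import dgr_detect as dd
from dgrscope.seqcore import GenomeRecord, OrfFeature, revcomp


def _rand_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(4, size=n)])


def _anchor(record_id, start, end):
    length = (end - start) - (end - start) % 3
    return dd.RtCandidate(
        orf=OrfFeature(record_id, start, start + length, "+", "M" * (length // 3 - 1)),
        motif_hits=[("RT_catalytic", 1)],
    )


def _pair(seq_a, seq_b, orientation="direct", gap=300):
    """A RepeatPair with explicit alignment rows for classifier tests."""
    return dd.RepeatPair(
        record_id="r",
        copyA_start=0,
        copyA_end=len(seq_a),
        copyB_start=len(seq_a) + gap,
        copyB_end=len(seq_a) + gap + len(seq_b),
        orientation=orientation,
        aligned_len=len(seq_a),
        alignment=(seq_a, seq_b),
    )


class TestScanRtCandidates:
    def test_yadd_motif_hit(self):
        orf = OrfFeature("r", 0, 363, "+", "M" + "A" * 59 + "YADD" + "G" * 56)
        [cand] = dd.scan_rt_candidates([orf])
        assert cand.motif_hits == [("RT_catalytic", 60)]
        assert cand.score == 1

    def test_no_motif_not_emitted(self):
        orf = OrfFeature("r", 0, 363, "+", "M" + "G" * 119)
        assert dd.scan_rt_candidates([orf]) == []

    def test_short_protein_excluded(self):
        orf = OrfFeature("r", 0, 63, "+", "MYADD" + "G" * 15)
        assert dd.scan_rt_candidates([orf]) == []

    def test_empty_input(self):
        assert dd.scan_rt_candidates([]) == []


class TestFindRepeatPairs:
    def test_identical_copies_full_length(self):
        rng = np.random.default_rng(0)
        copy = _rand_seq(rng, 200)
        seq = _rand_seq(rng, 500) + copy + _rand_seq(rng, 400) + copy + _rand_seq(rng, 500)
        rec = GenomeRecord("r", seq)
        anchor = _anchor("r", 1600, 1660)
        pairs = dd.find_repeat_pairs(rec, anchor)
        assert len(pairs) == 1
        p = pairs[0]
        # boundaries exact up to chance-matching flank bases (<= 3 bp)
        assert abs(p.copyA_start - 500) <= 3 and abs(p.copyA_end - 700) <= 3
        assert abs(p.copyB_start - 1100) <= 3 and abs(p.copyB_end - 1300) <= 3
        assert p.aligned_len >= 200
        assert p.alignment[0] == p.alignment[1]

    def test_planted_substituted_pair_recovered(self):
        rng = np.random.default_rng(1)
        tr = _rand_seq(rng, 114)
        vr = list(tr)
        for pos in range(15, 114 - 15, 9):  # 10 interior substitutions, well spaced
            vr[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[vr[pos]]
        vr = "".join(vr)
        seq = _rand_seq(rng, 1000) + vr + _rand_seq(rng, 2000) + tr + _rand_seq(rng, 1000)
        rec = GenomeRecord("r", seq)
        pairs = dd.find_repeat_pairs(rec, _anchor("r", 3800, 3890))
        spanning = [
            p for p in pairs
            if abs(p.copyA_start - 1000) <= 3 and abs(p.copyA_end - 1114) <= 3
        ]
        assert len(spanning) == 1
        assert spanning[0].aligned_len >= 108

    def test_inverted_pair_detected(self):
        rng = np.random.default_rng(2)
        copy = _rand_seq(rng, 120)
        seq = _rand_seq(rng, 800) + copy + _rand_seq(rng, 700) + revcomp(copy) + _rand_seq(rng, 800)
        rec = GenomeRecord("r", seq)
        pairs = dd.find_repeat_pairs(rec, _anchor("r", 2300, 2360))
        inv = [p for p in pairs if p.orientation == "inverted"]
        assert len(inv) == 1
        p = inv[0]
        assert abs(p.copyA_start - 800) <= 3 and abs(p.copyA_end - 920) <= 3
        assert abs(p.copyB_start - 1620) <= 3 and abs(p.copyB_end - 1740) <= 3
        # rows compare position-wise; chance-matching flank bases may add a
        # mismatch column or two at the edges
        mm = sum(a != b for a, b in zip(*p.alignment))
        assert mm <= 2

    def test_no_repeats_empty(self):
        rng = np.random.default_rng(3)
        rec = GenomeRecord("r", _rand_seq(rng, 3000))
        assert dd.find_repeat_pairs(rec, _anchor("r", 1500, 1560)) == []

    def test_anchor_outside_record_rejected(self):
        rec = GenomeRecord("r", "ACGT" * 100)
        with pytest.raises(ValueError):
            dd.find_repeat_pairs(rec, _anchor("r", 600, 660))

    def test_revcomp_invariance_on_planted_pair(self):
        rng = np.random.default_rng(4)
        copy = _rand_seq(rng, 150)
        seq = _rand_seq(rng, 600) + copy + _rand_seq(rng, 500) + copy + _rand_seq(rng, 600)
        rec = GenomeRecord("r", seq)
        L = len(seq)
        fwd = dd.find_repeat_pairs(rec, _anchor("r", 1450, 1510))
        rc_rec = GenomeRecord("r", revcomp(seq))
        rc = dd.find_repeat_pairs(rc_rec, _anchor("r", L - 1510, L - 1450))

        def canon(pairs, flip):
            out = set()
            for p in pairs:
                ivs = [(p.copyA_start, p.copyA_end), (p.copyB_start, p.copyB_end)]
                if flip:
                    ivs = [(L - e, L - s) for s, e in ivs]
                out.add((frozenset(ivs), p.orientation))
            return out

        assert canon(fwd, False) == canon(rc, True)

    def test_agrees_with_existence_oracle_on_small_windows(self):
        rng = np.random.default_rng(5)
        for k in range(12):
            window = _rand_seq(rng, 180)
            plant = k % 2 == 0
            if plant:
                copy = _rand_seq(rng, 30)
                mutated = list(copy)
                mutated[14] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[14]]
                window = window[:20] + copy + window[50:120] + "".join(mutated) + window[150:]
            rec = GenomeRecord("r", window)
            got = dd.find_repeat_pairs(
                rec, _anchor("r", 60, 120), window_bp=200, min_repeat_len=30, seed_len=12
            )
            expected = oracle_repeat_pair_exists(window, 30, 0.25)
            assert (len(got) > 0) == expected, f"iteration {k}: plant={plant}"


class TestClassifyTrVr:
    def test_twelve_adenine_zero_other_passes(self):
        tr = ("GCT" * 30 + "AAA" * 8)[:114]
        tr = "C" * 30 + "A" * 12 + "G" * 36 + "T" * 36  # 114 bp, 12 As
        vr = tr.replace("A", "C")
        call = dd.classify_tr_vr(_pair(tr, vr))
        assert call.passed
        assert call.tr == (0, 114)  # copyA (the adenine-bearing copy) is TR
        assert call.profile.n_adenine_wrt_A == 12

    def test_identical_copies_fail_with_reason(self):
        s = "ACGT" * 30
        call = dd.classify_tr_vr(_pair(s, s))
        assert not call.passed
        assert call.reasons == ["adenine-mismatches<10"]

    def test_non_adenine_excess_at_150bp(self):
        # 11 adenine-specific + 4 non-adenine mismatches; allowance 2*1.5=3.0 < 4
        tr = "A" * 11 + "C" * 139
        vr = "G" * 11 + "T" * 4 + "C" * 135
        call = dd.classify_tr_vr(_pair(tr, vr))
        assert not call.passed
        assert "non-adenine-excess" in call.reasons

    def test_nine_adenine_fails(self):
        tr = "A" * 9 + "C" * 105
        vr = "G" * 9 + "C" * 105
        call = dd.classify_tr_vr(_pair(tr, vr))
        assert not call.passed
        assert call.reasons == ["adenine-mismatches<10"]

    def test_copy_order_symmetry(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            tr = "".join(np.array(list("ACGT"))[rng.integers(4, size=120)])
            vr = list(tr)
            for pos in rng.choice(120, size=rng.integers(0, 25), replace=False):
                vr[pos] = "ACGT"[rng.integers(4)]
            vr = "".join(vr)
            fwd = dd.classify_tr_vr(_pair(tr, vr))
            swapped = dd.classify_tr_vr(
                dd.RepeatPair("r", 0, 120, 420, 540, "direct", 120, (vr, tr))
            )
            assert fwd.passed == swapped.passed
            assert set(fwd.reasons) == set(swapped.reasons)
            if fwd.passed:
                # template label swaps with the copy order, intervals aside
                assert (fwd.profile.n_adenine_wrt_A, fwd.profile.n_adenine_wrt_B) == (
                    swapped.profile.n_adenine_wrt_B,
                    swapped.profile.n_adenine_wrt_A,
                )

    def test_ambiguous_template_rejected(self):
        # equal adenine evidence on both copies: A<->C one way, C<->A the other
        tr = "A" * 10 + "C" * 10 + "G" * 1180
        vr = "C" * 10 + "A" * 10 + "G" * 1180
        call = dd.classify_tr_vr(_pair(tr, vr))
        assert not call.passed
        assert call.reasons == ["ambiguous-template"]


class TestAssembleAndIdentity:
    def test_synthetic_genome_assembles_complete_cassette(self, default_sim, default_detection):
        record, truth = default_sim
        t = truth.cassettes[0]
        complete = [c for c in default_detection["cassettes"] if c["complete"]]
        assert len(complete) == 1
        c = complete[0]
        assert abs(c["vr"][0] - t.vr[0]) <= 3 and abs(c["vr"][1] - t.vr[1]) <= 3
        assert abs(c["tr"][0] - t.tr[0]) <= 3 and abs(c["tr"][1] - t.tr[1]) <= 3
        assert c["tp"][0] <= c["vr"][0] and c["vr"][1] <= c["tp"][1]
        assert c["imh"]["motif_pair"] == "TGGGGT/TGGAAT"
        assert c["hairpin"]["loop_class"] == "GRA"
        assert c["avd"] is not None and abs(c["avd"]["pI"] - 9) <= 1

    def test_intergenic_vr_flagged_no_tp(self):
        rng = np.random.default_rng(8)
        seq = "".join(np.array(list("ACGT"))[rng.integers(4, size=2000)])
        rec = GenomeRecord("r", seq)
        tr, vr = (1000, 1114), (300, 414)
        prof = dd.MismatchProfile([], 12, 0, 0, 12, 114)
        call = dd.TrVrCall(tr, vr, "+", prof, True)
        cassettes = dd.assemble_cassette(rec, _anchor("r", 1500, 1560), [call], orfs=[])
        assert len(cassettes) == 1
        assert "no-TP" in cassettes[0].flags

    def test_partial_cassette_without_rt_flagged(self):
        rng = np.random.default_rng(9)
        seq = "".join(np.array(list("ACGT"))[rng.integers(4, size=2000)])
        rec = GenomeRecord("r", seq)
        prof = dd.MismatchProfile([], 12, 0, 0, 12, 114)
        call = dd.TrVrCall((1000, 1114), (300, 414), "+", prof, True)
        [cassette] = dd.assemble_cassette(rec, None, [call], orfs=[])
        assert not cassette.complete
        assert "partial" in cassette.flags

    def test_identity_trivial_and_hand_aligned(self):
        assert dd.percent_identity("ACGT", "ACGT") == 100.0
        assert dd.percent_identity("ACGT", "ACGA") == 75.0

    def test_identity_missing_feature_is_na(self, default_sim):
        record, _ = default_sim
        prof = dd.MismatchProfile([], 12, 0, 0, 12, 114)
        call = dd.TrVrCall((1000, 1114), (300, 414), "+", prof, True)
        c1 = dd.DgrCassette("r", _anchor(record.id, 1500, 1560), call)
        c2 = dd.DgrCassette("r", None, call)
        ident = dd.cassette_identity(c1, c2, record, record)
        assert ident["RT"] == "NA"
        assert ident["VR"] != "NA"
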