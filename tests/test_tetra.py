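import numpy as np
import pytest
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform

from dgrscope import tetra


def _rand_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(4, size=n)])


class TestFragmentWindows:
    @pytest.mark.parametrize(
        "length,n,starts",
        [(5000, 1, [0]), (6000, 3, [0, 500, 1000]), (4999, 0, [])],
    )
    def test_window_counts(self, length, n, starts):
        windows = tetra.fragment_windows(length)
        assert len(windows) == n
        assert [s for s, _ in windows] == starts

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError):
            tetra.fragment_windows(10000, window=5000, step=6000)


class TestTetraOdds:
    def test_homopolymer_neutral(self):
        odds = tetra.tetra_odds("AAAAA")
        assert odds[0] == pytest.approx(1.0)  # AAAA: 2 observed, 2 expected
        assert np.allclose(odds, 1.0)  # all other 4-mers: 0 observed, 0 expected

    def test_conservation_sum_observed_equals_sum_expected(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            seq = _rand_seq(rng, 2000)
            codes = tetra._encode(seq)
            kc = ((codes[:-3] * 4 + codes[1:-2]) * 4 + codes[2:-1]) * 4 + codes[3:]
            observed = np.bincount(kc, minlength=256)
            mono = np.bincount(codes, minlength=4) / len(seq)
            idx = np.arange(256)
            expected = len(kc) * (
                mono[(idx >> 6) & 3] * mono[(idx >> 4) & 3] * mono[(idx >> 2) & 3] * mono[idx & 3]
            )
            # not exactly equal position-wise, but the totals must balance
            assert observed.sum() == len(seq) - 3
            assert expected.sum() == pytest.approx(observed.sum(), rel=1e-9)
            # and the implementation's odds are observed/expected
            odds = tetra.tetra_odds(seq)
            nz = expected > 0
            assert np.allclose(odds[nz], observed[nz] / expected[nz])

    def test_n_positions_skipped(self):
        odds = tetra.tetra_odds("ACGTNACGT")
        assert np.all(np.isfinite(odds))

    def test_window_too_ambiguous_rejected(self):
        with pytest.raises(ValueError):
            tetra.tetra_odds("ANN")

    def test_uniform_random_odds_near_one(self):
        rng = np.random.default_rng(32)
        odds = tetra.tetra_odds(_rand_seq(rng, 100_000))
        assert np.mean(np.abs(odds - 1)) < 0.2

    def test_depends_only_on_content(self):
        seq = "ACGTACGGTACCGT" * 40
        a = tetra.TetraProfile("x", 0, len(seq), tetra.tetra_odds(seq), "genome")
        b = tetra.TetraProfile("y", 999, 999 + len(seq), tetra.tetra_odds(seq), "DGR")
        assert np.array_equal(a.odds, b.odds)


class TestConcatAndProfile:
    def test_ten_cassettes_thirty_three_windows(self):
        rng = np.random.default_rng(33)
        seqs = [_rand_seq(rng, 2100) for _ in range(10)]
        profiles = tetra.concat_and_profile(seqs, "DGR")
        assert len(profiles) == 33  # floor((21000-5000)/500)+1
        assert all(p.group == "DGR" for p in profiles)

    def test_single_sequence_matches_composition(self):
        rng = np.random.default_rng(34)
        seq = _rand_seq(rng, 6000)
        via_concat = tetra.concat_and_profile([seq], "g")
        direct = tetra.profile_sequence(seq, "g", "g")
        for a, b in zip(via_concat, direct):
            assert np.array_equal(a.odds, b.odds)

    def test_too_short_concatenation_advises(self):
        with pytest.raises(ValueError, match="window"):
            tetra.concat_and_profile(["ACGT" * 100], "g")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tetra.concat_and_profile([], "g")


class TestNmds:
    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(35)
        X = rng.normal(size=(15, 8))
        a = tetra.nmds(X, seed=7, n_starts=4)
        b = tetra.nmds(X, seed=7, n_starts=4)
        assert np.array_equal(a.coords, b.coords)
        assert a.stress == b.stress

    def test_planar_self_consistency(self):
        rng = np.random.default_rng(36)
        pts = rng.normal(size=(30, 2))
        res = tetra.nmds(pts, seed=1, n_starts=8)
        assert res.stress < 0.05
        _, _, disparity = procrustes(pts, res.coords)
        scale = np.sqrt(((pts - pts.mean(0)) ** 2).sum())
        assert np.sqrt(disparity) < 0.10  # procrustes M^2 is already normalized

    def test_coords_centered(self):
        rng = np.random.default_rng(37)
        res = tetra.nmds(rng.normal(size=(12, 5)), seed=2, n_starts=3)
        assert np.allclose(res.coords.mean(axis=0), 0, atol=1e-9)

    def test_rank_order_preserved_for_symmetric_configuration(self):
        pts = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2], [0.5, 0.29]])
        res = tetra.nmds(pts, seed=3, n_starts=8)
        d_in = pdist(pts)
        d_out = pdist(res.coords)
        order_in = np.argsort(d_in)
        # the largest input distances stay the largest output distances
        assert set(order_in[-3:]) == set(np.argsort(d_out)[-3:])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            tetra.nmds(np.zeros((3, 4)), seed=0)


class TestEllipsesAndOutliers:
    def test_degenerate_identical_points(self):
        coords = np.zeros((5, 2))
        [e] = tetra.confidence_ellipse(coords, ["g"] * 5)
        assert np.allclose(e.semi_axes, 0)

    def test_isotropic_gaussian_axes(self):
        rng = np.random.default_rng(38)
        pts = rng.normal(size=(10_000, 2))
        [e] = tetra.confidence_ellipse(pts, ["g"] * 10_000)
        assert np.all(np.abs(e.semi_axes - np.sqrt(5.991)) / np.sqrt(5.991) < 0.05)

    def test_anisotropic_axis_ratio_and_angle(self):
        rng = np.random.default_rng(39)
        pts = rng.normal(size=(10_000, 2)) * np.array([2.0, 1.0])
        [e] = tetra.confidence_ellipse(pts, ["g"] * 10_000)
        ratio = e.semi_axes[0] / e.semi_axes[1]
        assert abs(ratio - 2.0) / 2.0 < 0.10
        angle = abs(((e.angle + np.pi / 2) % np.pi) - np.pi / 2)
        assert angle < 0.1

    def test_higher_level_contains_lower(self):
        rng = np.random.default_rng(40)
        pts = rng.normal(size=(50, 2))
        [e95] = tetra.confidence_ellipse(pts, ["g"] * 50, level=0.95)
        [e99] = tetra.confidence_ellipse(pts, ["g"] * 50, level=0.99)
        assert np.all(e99.semi_axes > e95.semi_axes)

    def test_small_group_skipped(self):
        coords = np.zeros((4, 2))
        out = tetra.confidence_ellipse(coords, ["a", "a", "a", "b"])
        assert [e.group for e in out] == ["a"]

    def test_outlier_fraction_near_level_complement(self):
        rng = np.random.default_rng(41)
        coords = rng.normal(size=(4000, 2))
        flags, fractions = tetra.outlier_report(coords, ["genome"] * 4000, "genome")
        assert abs(fractions["genome"] - 0.05) < 0.015

    def test_shifted_group_mostly_flagged(self):
        rng = np.random.default_rng(42)
        core = rng.normal(size=(500, 2))
        shifted = rng.normal(size=(100, 2)) + 5.0
        coords = np.vstack([core, shifted])
        labels = ["genome"] * 500 + ["RT"] * 100
        _, fractions = tetra.outlier_report(coords, labels, "genome")
        assert fractions["RT"] > 0.5

    def test_centroid_not_flagged(self):
        rng = np.random.default_rng(43)
        core = rng.normal(size=(200, 2))
        coords = np.vstack([core, core.mean(axis=0, keepdims=True)])
        flags, _ = tetra.outlier_report(coords, ["genome"] * 200 + ["DGR"], "genome")
        assert not flags[-1]


class TestCompositionalShiftEndToEnd:
    def test_dinucleotide_biased_windows_are_outliers(self):
        """Windows with strong dinucleotide structure separate from an iid
        genome core in the ordination. (A pure GC shift would not: the
        zero-order-Markov odds ratio normalizes mononucleotide composition
        away by construction.)"""
        rng = np.random.default_rng(44)

        def biased(n, gc):
            p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
            return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])

        def markov(n):
            # CG-avoiding first-order chain, a classic genome-signature driver
            trans = np.full((4, 4), 0.25)
            trans[1, 2] = 0.02  # C -> G suppressed
            trans[1] /= trans[1].sum()
            out = [int(rng.integers(4))]
            for _ in range(n - 1):
                out.append(int(rng.choice(4, p=trans[out[-1]])))
            return "".join("ACGT"[i] for i in out)

        genome_windows = [biased(5000, 0.45) for _ in range(30)]
        shifted_windows = [markov(5000) for _ in range(8)]
        profiles = [
            tetra.TetraProfile("g", 0, 5000, tetra.tetra_odds(w), "genome")
            for w in genome_windows
        ] + [
            tetra.TetraProfile("s", 0, 5000, tetra.tetra_odds(w), "RT")
            for w in shifted_windows
        ]
        res = tetra.nmds(profiles, seed=5, n_starts=8)
        labels = [p.group for p in profiles]
        _, fractions = tetra.outlier_report(res.coords, labels, "genome")
        assert fractions["RT"] > 0.5
        assert fractions["genome"] < 0.3
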