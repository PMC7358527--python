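"""Fingerprint chain: band calling, Dice, transforms, UPGMA, NMDS."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from soilvir import (
    BandProfile,
    DissimilarityMatrix,
    average_dissimilarity,
    call_bands,
    dice_similarity,
    fingerprint_pipeline,
    match_bands,
    nmds,
    similarity_matrix,
    to_dissimilarity,
    upgma,
)
from conftest import random_dissimilarity


def naive_average_linkage(dmat, labels):
    """Independent UPGMA oracle: recompute every inter-cluster mean from the
    original matrix at each step (no Lance-Williams update)."""
    index = {lab: i for i, lab in enumerate(labels)}
    clusters = {frozenset([lab]): None for lab in labels}
    merges = {}  # frozenset of leaves -> merge height
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = np.mean([dmat[index[x], index[y]] for x in a for y in b])
            key = (d, tuple(sorted((min(a), min(b)))))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _), a, b = best
        merged = a | b
        merges[merged] = d
        del clusters[a], clusters[b]
        clusters[merged] = None
    return merges


class TestBandCalling:
    @staticmethod
    def _trace_with_peaks(amplitudes, centers, width=3.0, n=500):
        pos = np.linspace(100, 900, n)
        trace = np.zeros(n)
        for amp, cen in zip(amplitudes, centers):
            trace += amp * np.exp(-0.5 * ((pos - cen) / width) ** 2)
        return pos, trace

    def test_single_gaussian_peak(self):
        pos, trace = self._trace_with_peaks([1.0], [400.0])
        prof = call_bands(pos, trace, "lane")
        assert prof.bands.size == 1
        assert prof.bands[0] == pytest.approx(400.0, abs=2.0)

    def test_threshold_tiers(self):
        # 100% -> band, 4% -> uncertain (between grey zone and profiling), 1% -> dropped
        pos, trace = self._trace_with_peaks([1.0, 0.04, 0.01], [300.0, 500.0, 700.0])
        prof = call_bands(pos, trace, "lane")
        assert prof.bands.size == 1
        assert prof.uncertain.size == 1
        assert prof.uncertain[0] == pytest.approx(500.0, abs=2.0)

    def test_flat_trace_empty(self):
        prof = call_bands(np.linspace(0, 100, 50), np.zeros(50), "lane")
        assert prof.bands.size == 0


class TestMatchBands:
    def test_identical_profiles_identical_rows(self):
        profs = [BandProfile("a", [200.0, 400.0]), BandProfile("b", [200.0, 400.0])]
        _, presence = match_bands(profs)
        assert np.array_equal(presence[0], presence[1])

    def test_proportional_tolerance_merges(self):
        # 400 vs 406 at 2% tolerance (~8 bp) share a column
        profs = [BandProfile("a", [400.0]), BandProfile("b", [406.0])]
        positions, presence = match_bands(profs)
        assert positions.size == 1

    def test_distant_bands_distinct(self):
        profs = [BandProfile("a", [400.0]), BandProfile("b", [450.0])]
        positions, _ = match_bands(profs)
        assert positions.size == 2


class TestDice:
    def test_identity_and_disjoint(self):
        a = np.array([1, 1, 1, 1, 1], bool)
        assert dice_similarity(a, a) == 100.0
        b = np.array([0, 0, 0, 0, 0], bool)
        sets = np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1])
        assert dice_similarity(*sets) == 0.0
        with pytest.raises(ValueError):
            dice_similarity(b, b)

    def test_hand_enumeration(self):
        # bands {200,400,600} vs {400,600,800}: 2 shared of 3+3
        profs = [BandProfile("a", [200.0, 400.0, 600.0]), BandProfile("b", [400.0, 600.0, 800.0])]
        sim = similarity_matrix(profs)
        assert sim.values[0, 1] == pytest.approx(100 * 2 * 2 / 6)

    def test_matches_set_intersection_oracle(self):
        """Dice equals the brute-force set formula on random binary pairs."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            a = rng.random(30) < 0.4
            b = rng.random(30) < 0.4
            if not (a.any() or b.any()):
                continue
            sa, sb = set(np.where(a)[0]), set(np.where(b)[0])
            expected = 100.0 * 2 * len(sa & sb) / (len(sa) + len(sb))
            assert dice_similarity(a, b) == expected


class TestTransforms:
    def _sim(self):
        profs = [
            BandProfile("a", [200.0, 400.0, 600.0]),
            BandProfile("b", [400.0, 600.0, 800.0]),
            BandProfile("c", [200.0, 800.0]),
        ]
        return similarity_matrix(profs)

    def test_matrix_contract(self):
        sim = self._sim()
        assert sim.values.shape == (3, 3)
        assert np.allclose(np.diag(sim.values), 100.0)
        assert np.allclose(sim.values, sim.values.T)

    def test_involution(self):
        sim = self._sim()
        dis = to_dissimilarity(sim)
        assert np.allclose(np.diag(dis.values), 0.0)
        back = 100.0 - dis.values
        assert np.allclose(back, sim.values)

    def test_average_dissimilarity_hand(self):
        d = DissimilarityMatrix(
            labels=("a", "b", "c"),
            values=np.array([[0, 10, 20], [10, 0, 30], [20, 30, 0]], float),
        )
        summary = average_dissimilarity(d)
        assert summary.mean == pytest.approx(20.0)
        assert summary.max == pytest.approx(30.0)

    def test_average_linearity_with_similarity(self):
        sim = self._sim()
        dis = to_dissimilarity(sim)
        iu = np.triu_indices(3, k=1)
        assert average_dissimilarity(dis).mean == pytest.approx(
            100.0 - sim.values[iu].mean()
        )


class TestUpgma:
    def test_three_leaf_hand_trace(self):
        d = DissimilarityMatrix(
            labels=("A", "B", "C"),
            values=np.array([[0, 2, 8], [2, 0, 6], [8, 6, 0]], float),
        )
        tree = upgma(d)
        assert tree.merge_heights() == pytest.approx([2.0, 7.0])

    def test_equal_distances_tie_rule(self):
        d = DissimilarityMatrix(labels=("A", "B", "C", "D"), values=5.0 * (1 - np.eye(4)))
        tree = upgma(d)
        assert tree.merge_heights() == pytest.approx([5.0, 5.0, 5.0])

    def test_ultrametric_property(self, rng):
        mat = random_dissimilarity(rng, 8)
        tree = upgma(DissimilarityMatrix(labels=tuple("ABCDEFGH"), values=mat))
        labels, coph = tree.cophenetic_matrix()
        # three-point ultrametric condition on cophenetic distances
        for i, j, k in itertools.combinations(range(8), 3):
            sides = sorted([coph[i, j], coph[i, k], coph[j, k]])
            assert sides[1] == pytest.approx(sides[2])

    def test_matches_exhaustive_average_linkage_oracle(self, rng):
        labels = tuple("ABCDEF")
        for _ in range(15):
            mat = random_dissimilarity(rng, 6)
            tree = upgma(DissimilarityMatrix(labels=labels, values=mat))
            oracle = naive_average_linkage(mat, labels)
            got_labels, coph = tree.cophenetic_matrix()
            index = {lab: i for i, lab in enumerate(got_labels)}
            # every oracle merge height appears as the LCA height of its leaves
            for members, height in oracle.items():
                pairs = list(itertools.combinations(sorted(members), 2))
                lca = max(coph[index[a], index[b]] for a, b in pairs)
                assert lca == pytest.approx(height, abs=1e-9)


class TestNmds:
    def test_exactly_embeddable_square(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        d = DissimilarityMatrix(labels=("a", "b", "c", "d"),
                                values=squareform(pdist(pts)))
        res = nmds(d, seed=0)
        assert res.stress < 1e-6

    def test_three_points_always_embed(self):
        d = DissimilarityMatrix(
            labels=("a", "b", "c"),
            values=np.array([[0, 3, 5], [3, 0, 4], [5, 4, 0]], float),
        )
        res = nmds(d, seed=0)
        assert res.stress < 1e-6

    def test_stress_sequence_non_increasing(self, rng):
        mat = random_dissimilarity(rng, 12)
        res = nmds(DissimilarityMatrix(labels=tuple("abcdefghijkl"), values=mat), seed=3)
        hist = res.stress_history
        assert all(a >= b for a, b in zip(hist, hist[1:]))

    def test_determinism(self, rng):
        mat = random_dissimilarity(rng, 9)
        d = DissimilarityMatrix(labels=tuple("abcdefghi"), values=mat)
        r1 = nmds(d, seed=5)
        r2 = nmds(d, seed=5)
        assert r1.stress == r2.stress
        assert np.array_equal(r1.coordinates, r2.coordinates)

    def test_zero_dissimilarity_adjusted_with_warning(self, caplog):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], float)
        mat = squareform(pdist(pts))
        d = DissimilarityMatrix(labels=tuple("abcde"), values=mat)
        import logging

        with caplog.at_level(logging.WARNING, logger="soilvir.fingerprint"):
            res = nmds(d, seed=0)
        assert "zero off-diagonal" in caplog.text
        assert np.isfinite(res.stress)


class TestPipeline:
    def test_identical_profiles_skip_mds(self, caplog):
        import logging

        profs = [BandProfile(lab, [200.0, 400.0]) for lab in ("a", "b", "c")]
        with caplog.at_level(logging.WARNING, logger="soilvir.fingerprint"):
            result = fingerprint_pipeline(profs)
        assert result.mds is None
        assert result.summary.mean == 0.0

    def test_disjoint_pools_split_at_root(self):
        groupA = [BandProfile(f"A{i}", [200.0 + 4 * i, 220.0]) for i in range(3)]
        groupB = [BandProfile(f"B{i}", [700.0 + 9 * i, 800.0]) for i in range(3)]
        result = fingerprint_pipeline(groupA + groupB, seed=1)
        root = result.dendrogram.root
        sides = [set(child.leaves()) for child in root.children]
        assert {frozenset(s) for s in sides} == {
            frozenset({"A0", "A1", "A2"}),
            frozenset({"B0", "B1", "B2"}),
        }

    def test_too_few_profiles(self):
        with pytest.raises(ValueError):
            fingerprint_pipeline([BandProfile("a", [1.0]), BandProfile("b", [2.0])])
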