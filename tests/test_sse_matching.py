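"""Pair graph: vertex scores, edge admissibility, voting, greedy matching."""
import numpy as np
import pytest

from adswap.ad_image import build_ad_image
from adswap.config import DEFAULT
from adswap.sse_matching import (PairGraph, SSEPairScore, build_edges,
                                 candidate_vertices, dump_scores_tsv, edge_weight,
                                 match_images, match_sses, sse_pair_scores,
                                 vertex_weights)
from adswap.structure_io import extract_sses
from .test_ad_image import make_sse


@pytest.fixture()
def toy_image():
    sses = [make_sse(0, [1, 0, 0], [0, 0, 0], length=12, n_x=8, first=0, last=7),
            make_sse(1, [0, 1, 0], [8, 0, 6], length=9, n_x=6, first=10, last=15),
            make_sse(2, [0, 0, 1], [0, 9, 10], length=15, n_x=10, first=18, last=27)]
    return build_ad_image(sses)


@pytest.fixture()
def self_graph(toy_image):
    g = candidate_vertices(toy_image, toy_image)
    build_edges(g)
    vertex_weights(g)
    return g


class TestVertices:
    def test_self_pairing_attains_maximal_score(self, toy_image):
        g = candidate_vertices(toy_image, toy_image)
        for k in range(g.n_vertices):
            if g.vq[k] == g.vs[k]:
                assert g.score[k] == pytest.approx(DEFAULT.s_c)
        # and no vertex can beat the identity score
        assert g.score.max() <= DEFAULT.s_c + 1e-12

    def test_blocked_vertices_subset_of_brute_force(self, ds_pair):
        _, closed, opened = ds_pair
        img_q = build_ad_image(extract_sses(closed))
        img_s = build_ad_image(extract_sses(opened))
        blocked = candidate_vertices(img_q, img_s, use_blocks=True)
        brute = candidate_vertices(img_q, img_s, use_blocks=False)
        assert set(zip(blocked.vq, blocked.vs)) <= set(zip(brute.vq, brute.vs))
        assert (brute.score > 0).all()

    def test_a_point_may_pair_with_several_nearby_points(self, ds_pair):
        # a query point paired with two or more nearby subject points
        _, closed, opened = ds_pair
        img_q = build_ad_image(extract_sses(closed))
        img_s = build_ad_image(extract_sses(opened))
        g = candidate_vertices(img_q, img_s)
        counts = np.bincount(g.vq, minlength=len(img_q))
        assert counts.max() >= 2


class TestEdges:
    def test_contradictory_vertices_rejected(self, self_graph):
        g = self_graph
        # two vertices sharing the query point but not the subject point
        shared = None
        for a in range(g.n_vertices):
            for b in range(a + 1, g.n_vertices):
                if g.vq[a] == g.vq[b] and g.vs[a] != g.vs[b]:
                    shared = (a, b)
                    break
            if shared:
                break
        assert shared is not None
        assert edge_weight(g, *shared) is None
        # and no scored edge joins them
        mask = ((g.edges_p == shared[0]) & (g.edges_q == shared[1]))
        assert not mask.any()

    def test_no_duplicate_edges(self, self_graph):
        g = self_graph
        seen = set(zip(g.edges_p.tolist(), g.edges_q.tolist()))
        assert len(seen) == len(g.edges_w)
        assert all(p < q for p, q in seen)

    def test_identity_pairings_get_maximal_weight_for_their_separation(self, self_graph):
        g = self_graph
        idv = [k for k in range(g.n_vertices) if g.vq[k] == g.vs[k]]
        for a in idv:
            for b in idv:
                if a >= b:
                    continue
                w = edge_weight(g, a, b)
                if w is None:
                    continue
                # all difference terms vanish: weight = 4 * exp(-(d/d_t)^2)
                d = np.linalg.norm(g.img_q.centers[g.vq[a]] - g.img_q.centers[g.vq[b]])
                assert w == pytest.approx(4.0 * np.exp(-(d / DEFAULT.d_t) ** 2))

    def test_edge_needs_two_distinct_vertices(self, self_graph):
        with pytest.raises(ValueError):
            edge_weight(self_graph, 0, 0)


class TestVoting:
    def _manual_graph(self, toy_image, weights):
        n = len(weights)
        g = PairGraph(toy_image, toy_image,
                      vq=np.array([w[0] for w in weights]),
                      vs=np.array([w[1] for w in weights]),
                      score=np.ones(n))
        g.w = np.array([w[2] for w in weights], dtype=float)
        return g

    def test_vertex_weight_sums_positive_incident_edges(self, toy_image):
        g = PairGraph(toy_image, toy_image,
                      vq=np.arange(4), vs=np.arange(4), score=np.ones(4))
        g.edges_p = np.array([0, 0, 0])
        g.edges_q = np.array([1, 2, 3])
        g.edges_w = np.array([0.61, 0.51, 0.33])
        vertex_weights(g)
        assert g.w[0] == pytest.approx(1.45)

    def test_isolated_vertex_and_negative_edges(self, toy_image):
        g = PairGraph(toy_image, toy_image,
                      vq=np.arange(4), vs=np.arange(4), score=np.ones(4))
        g.edges_p = np.array([0, 0, 1])
        g.edges_q = np.array([1, 2, 2])
        g.edges_w = np.array([0.5, -0.2, -0.9])
        vertex_weights(g)
        assert g.w[0] == pytest.approx(0.5)   # negative edge excluded
        assert g.w[3] == 0.0                  # isolated vertex

    def test_matching_score_sums_qualifying_vertices(self, toy_image):
        # A-D points of the 3-SSE image: 0=(0,1), 1=(0,2), 2=(1,2).
        # Vertices whose Q point and S point both contain SSE 0 / SSE 0'
        # carry weights 1.45 + 1.28 + 0.33 = 3.06.
        g = self._manual_graph(toy_image, [(0, 0, 1.45), (1, 1, 1.28),
                                           (0, 1, 0.33), (2, 2, 0.50)])
        scores = {(s.a, s.a_prime): s for s in sse_pair_scores(g)}
        assert scores[(0, 0)].m_raw == pytest.approx(3.06)
        # identical SSE sizes: weighting g = 1
        assert scores[(0, 0)].m_weighted == pytest.approx(3.06)

    def test_m_raw_equals_brute_force_enumeration(self, self_graph):
        g = self_graph
        scores = {(s.a, s.a_prime): s.m_raw for s in sse_pair_scores(g)}
        pts = g.img_q.points
        for (a, ap), m in scores.items():
            expect = 0.0
            for k in range(g.n_vertices):
                pq, ps = pts[g.vq[k]], pts[g.vs[k]]
                if a in (pq.sse_a, pq.sse_b) and ap in (ps.sse_a, ps.sse_b):
                    expect += g.w[k]
            assert m == pytest.approx(expect)

    def test_size_dissimilarity_reduces_weighted_score(self, self_graph):
        scores = sse_pair_scores(self_graph)
        for s in scores:
            if s.a == s.a_prime:
                assert s.m_weighted == pytest.approx(s.m_raw)
            else:
                assert s.m_weighted <= s.m_raw


class TestGreedyMatching:
    def test_identical_images_match_identity(self, toy_image):
        match, _ = match_images(toy_image, toy_image)
        assert match.pairs == [(0, 0), (1, 1), (2, 2)]

    def test_sequential_order_rule(self):
        scores = [SSEPairScore(0, 1, 5.0, 5.0), SSEPairScore(1, 0, 4.0, 4.0),
                  SSEPairScore(1, 2, 3.0, 3.0)]
        seq = match_sses(scores, sequential=True)
        assert seq.pairs == [(0, 1), (1, 2)]       # (1,0) crosses (0,1)
        free = match_sses(scores, sequential=False)
        assert (1, 0) in free.pairs

    def test_one_to_one_and_empty(self):
        scores = [SSEPairScore(0, 0, 5.0, 5.0), SSEPairScore(0, 1, 4.0, 4.0),
                  SSEPairScore(1, 1, 3.0, 3.0)]
        m = match_sses(scores)
        assert m.pairs == [(0, 0), (1, 1)]
        assert match_sses([]).pairs == []

    def test_symmetry_of_matching(self, ds_pair):
        _, closed, opened = ds_pair
        img_q = build_ad_image(extract_sses(closed))
        img_s = build_ad_image(extract_sses(opened))
        fwd, _ = match_images(img_q, img_s)
        rev, _ = match_images(img_s, img_q)
        assert set(fwd.pairs) == {(b, a) for a, b in rev.pairs}

    def test_score_table_tsv_dump(self, self_graph, tmp_path):
        scores = sse_pair_scores(self_graph)
        dump_scores_tsv(scores, tmp_path / "scores.tsv")
        lines = (tmp_path / "scores.tsv").read_text().splitlines()
        assert lines[0] == "sse_Q\tsse_S\tm_raw\tm_weighted"
        assert len(lines) == len(scores) + 1

    def test_ds_pair_matches_both_domains(self, ds_pair):
        spec, closed, opened = ds_pair
        img_q = build_ad_image(extract_sses(closed))
        img_s = build_ad_image(extract_sses(opened))
        match, _ = match_images(img_q, img_s)
        n_main = len(spec.sse_layout[0])
        matched_q = {a for a, _ in match.pairs}
        assert matched_q & set(range(n_main)), "main-domain SSEs matched"
        assert matched_q & set(range(n_main, n_main + len(spec.sse_layout[1]))), \
            "swapped-domain SSEs matched despite the conformational change"
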