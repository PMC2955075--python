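"""Pair-graph matching of SSEs between two A-D images.

A vertex of the pair graph is a candidate pairing of one query A-D point with
one subject A-D point; its score compares the two points' plane positions,
SSE-pair dihedrals and connecting-chain lengths.  An edge between two vertices
scores the geometric compatibility of the two pairings using intra-protein
center distances and the angles the component SSE vectors make with the
inter-center axis.  Vertex weights (sums of positive incident edge weights)
are then voted onto SSE pairs, and a greedy scan of the descending score list
extracts a one-to-one, optionally sequence-order-preserving, SSE equivalence.

Matching never superposes the structures, which is what lets SSEs of both the
main and the swapped domain of a closed/open pair be matched simultaneously.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ad_image import ADImage, block_neighborhood
from .config import Config, DEFAULT

__all__ = [
    "PairGraph",
    "SSEPairScore",
    "SSEMatch",
    "candidate_vertices",
    "vertex_score",
    "build_edges",
    "edge_weight",
    "vertex_weights",
    "sse_pair_scores",
    "match_sses",
    "match_images",
    "dump_scores_tsv",
]


@dataclass
class PairGraph:
    """Vertices as parallel arrays; edges as (p, q, weight) triples."""
    img_q: ADImage
    img_s: ADImage
    vq: np.ndarray            # query point index per vertex
    vs: np.ndarray            # subject point index per vertex
    score: np.ndarray         # S_ij geometric similarity, > 0 for kept vertices
    edges_p: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    edges_q: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    edges_w: np.ndarray = field(default_factory=lambda: np.empty(0))
    w: np.ndarray | None = None   # W_i,j total vertex weights

    @property
    def n_vertices(self) -> int:
        return len(self.vq)


@dataclass
class SSEPairScore:
    a: int                    # SSE index in Q
    a_prime: int              # SSE index in S
    m_raw: float
    m_weighted: float


@dataclass
class SSEMatch:
    pairs: list[tuple[int, int]]
    mode: str                 # "sequential" | "order-independent"


def vertex_score(pq, ps, config: Config = DEFAULT) -> float:
    """S_ij = S_c − (k1·d_ij + k2·Δdihedral + k3·Δchain_sep), where d_ij is the
    distance of the two points in the virtually superimposed A-D planes."""
    d = float(np.hypot(pq.norm_xy[0] - ps.norm_xy[0], pq.norm_xy[1] - ps.norm_xy[1]))
    return config.s_c - (config.k1 * d
                         + config.k2 * abs(pq.dihedral - ps.dihedral)
                         + config.k3 * abs(pq.chain_sep - ps.chain_sep))


def candidate_vertices(img_q: ADImage, img_s: ADImage,
                       config: Config = DEFAULT,
                       use_blocks: bool = True) -> PairGraph:
    """Vertices with positive geometric similarity; candidates restricted to
    the subject points in each query point's 5×5 block neighborhood unless
    ``use_blocks`` is False (brute force)."""
    vq, vs, sc = [], [], []
    for qi, pq in enumerate(img_q.points):
        if use_blocks:
            cand = block_neighborhood(pq, img_s, config=config)
        else:
            cand = range(len(img_s))
        for sj in cand:
            s = vertex_score(pq, img_s.points[sj], config)
            if s > 0:
                vq.append(qi)
                vs.append(sj)
                sc.append(s)
    return PairGraph(img_q, img_s,
                     np.array(vq, dtype=int), np.array(vs, dtype=int),
                     np.array(sc, dtype=float))


def _angles_between(dirs_a: np.ndarray, dirs_b: np.ndarray) -> np.ndarray:
    """Row-wise angle (radians, [0, π]) between two arrays of unit vectors."""
    dot = np.clip(np.einsum("ij,ij->i", dirs_a, dirs_b), -1.0, 1.0)
    return np.arccos(dot)


def _side_terms(img: ADImage, p_pts: np.ndarray, q_pts: np.ndarray):
    """Per-protein geometry for vertex pairs: inter-center distance and the
    α/β/γ angle triple (radians)."""
    dirs = np.array([s.direction for s in img.sses])
    a_idx = np.array([pt.sse_a for pt in img.points])
    b_idx = np.array([pt.sse_b for pt in img.points])
    c1 = img.centers[p_pts]
    c2 = img.centers[q_pts]
    axis = c2 - c1
    d = np.linalg.norm(axis, axis=1)
    safe = np.where(d > 1e-9, d, 1.0)
    u = axis / safe[:, None]
    a1 = dirs[a_idx[p_pts]]
    b1 = dirs[b_idx[p_pts]]
    a2 = dirs[a_idx[q_pts]]
    b2 = dirs[b_idx[q_pts]]
    alpha = 0.5 * (_angles_between(a1, u) + _angles_between(a2, u))
    beta = 0.5 * (_angles_between(b1, u) + _angles_between(b2, u))
    gamma = 0.5 * (_angles_between(a1, a2) + _angles_between(b1, b2))
    return d, alpha, beta, gamma


def build_edges(graph: PairGraph, config: Config = DEFAULT) -> PairGraph:
    """Score all admissible vertex pairs.

    Bad edges are excluded: a pair of vertices sharing a query point or a
    subject point is contradictory (one A-D point would be equivalent to two
    different points of the other image); redundant duplicates cannot arise
    because points are kept in canonical (a < b) order and each unordered
    vertex pair is enumerated once.
    """
    n = graph.n_vertices
    if n < 2:
        graph.edges_p = np.empty(0, dtype=int)
        graph.edges_q = np.empty(0, dtype=int)
        graph.edges_w = np.empty(0)
        return graph
    p, q = np.triu_indices(n, k=1)
    ok = (graph.vq[p] != graph.vq[q]) & (graph.vs[p] != graph.vs[q])
    p, q = p[ok], q[ok]
    d_q, al_q, be_q, ga_q = _side_terms(graph.img_q, graph.vq[p], graph.vq[q])
    d_s, al_s, be_s, ga_s = _side_terms(graph.img_s, graph.vs[p], graph.vs[q])
    t_d = 1.0 - np.abs(d_q - d_s) / config.k_d
    t_a = 1.0 - config.k_alpha * np.abs(al_q - al_s)
    t_b = 1.0 - config.k_beta * np.abs(be_q - be_s)
    t_g = 1.0 - config.k_gamma * np.abs(ga_q - ga_s)
    d_bar = 0.5 * (d_q + d_s)
    w = np.exp(-((d_bar / config.d_t) ** 2)) * (t_d + t_a + t_b + t_g)
    graph.edges_p, graph.edges_q, graph.edges_w = p, q, w
    return graph


def edge_weight(graph: PairGraph, p: int, q: int,
                config: Config = DEFAULT) -> float | None:
    """Weight of the edge between vertices ``p`` and ``q``; None if the edge is
    rejected as contradictory.  Scalar companion of :func:`build_edges`."""
    if p == q:
        raise ValueError("an edge needs two distinct vertices")
    if graph.vq[p] == graph.vq[q] or graph.vs[p] == graph.vs[q]:
        return None
    pi, qi = np.array([p]), np.array([q])
    d_q, al_q, be_q, ga_q = _side_terms(graph.img_q, graph.vq[pi], graph.vq[qi])
    d_s, al_s, be_s, ga_s = _side_terms(graph.img_s, graph.vs[pi], graph.vs[qi])
    t = (1.0 - abs(d_q[0] - d_s[0]) / config.k_d
         + 1.0 - config.k_alpha * abs(al_q[0] - al_s[0])
         + 1.0 - config.k_beta * abs(be_q[0] - be_s[0])
         + 1.0 - config.k_gamma * abs(ga_q[0] - ga_s[0]))
    return float(np.exp(-((0.5 * (d_q[0] + d_s[0]) / config.d_t) ** 2)) * t)


def vertex_weights(graph: PairGraph) -> PairGraph:
    """W_i,j: sum of the positive weights of a vertex's incident edges."""
    w = np.zeros(graph.n_vertices)
    pos = graph.edges_w > 0
    np.add.at(w, graph.edges_p[pos], graph.edges_w[pos])
    np.add.at(w, graph.edges_q[pos], graph.edges_w[pos])
    graph.w = w
    return graph


def sse_pair_scores(graph: PairGraph, config: Config = DEFAULT) -> list[SSEPairScore]:
    """Vote vertex weights onto SSE pairs (a, a′).

    A vertex contributes its whole weight to every (a, a′) with a among its
    query point's SSEs and a′ among its subject point's SSEs.  The raw sum is
    divided by a size-similarity weighting g ≥ 1 and the list is returned in
    descending weighted order with zero-score pairs dropped.
    """
    if graph.w is None:
        vertex_weights(graph)
    raw: dict[tuple[int, int], float] = {}
    pts_q, pts_s = graph.img_q.points, graph.img_s.points
    for k in range(graph.n_vertices):
        wk = float(graph.w[k])
        if wk == 0.0:
            continue
        pq = pts_q[graph.vq[k]]
        ps = pts_s[graph.vs[k]]
        for a in (pq.sse_a, pq.sse_b):
            for ap in (ps.sse_a, ps.sse_b):
                raw[(a, ap)] = raw.get((a, ap), 0.0) + wk
    out = []
    for (a, ap), m in raw.items():
        if m <= 0.0:
            continue
        sa, sb = graph.img_q.sses[a], graph.img_s.sses[ap]
        g = (1.0
             + abs(sa.length - sb.length) / max(sa.length, sb.length)
             + abs(sa.n_x - sb.n_x) / max(sa.n_x, sb.n_x))
        out.append(SSEPairScore(a, ap, m, m / g))
    out.sort(key=lambda s: (-s.m_weighted, s.a + s.a_prime, s.a))
    return out


def match_sses(scores: list[SSEPairScore], sequential: bool = True) -> SSEMatch:
    """Greedy extraction of a one-to-one SSE equivalence from the descending
    score list.  In sequential mode a candidate must preserve the SSE sequence
    order already fixed by the accepted pairs."""
    used_q: set[int] = set()
    used_s: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for s in scores:
        if s.a in used_q or s.a_prime in used_s:
            continue
        if sequential and any((s.a - a0) * (s.a_prime - b0) <= 0 for a0, b0 in pairs):
            continue
        pairs.append((s.a, s.a_prime))
        used_q.add(s.a)
        used_s.add(s.a_prime)
    pairs.sort()
    return SSEMatch(pairs, "sequential" if sequential else "order-independent")


def match_images(img_q: ADImage, img_s: ADImage, config: Config = DEFAULT,
                 sequential: bool = True, use_blocks: bool = True
                 ) -> tuple[SSEMatch, PairGraph]:
    """Full matching pipeline: vertices → edges → weights → votes → greedy."""
    graph = candidate_vertices(img_q, img_s, config, use_blocks=use_blocks)
    build_edges(graph, config)
    vertex_weights(graph)
    scores = sse_pair_scores(graph, config)
    return match_sses(scores, sequential=sequential), graph


def dump_scores_tsv(scores: list[SSEPairScore], path) -> None:
    """Write the vote table as TSV (sse_Q, sse_S, m_raw, m_weighted)."""
    with open(path, "w") as fh:
        fh.write("sse_Q\tsse_S\tm_raw\tm_weighted\n")
        for s in scores:
            fh.write(f"{s.a}\t{s.a_prime}\t{s.m_raw:.4f}\t{s.m_weighted:.4f}\n")
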