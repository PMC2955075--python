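"""Superposition-dependent residue alignment and structural similarity measures.

Matched SSEs seed residue equivalences; Kabsch superposition (SVD, proper
rotation) and a dynamic program that maximizes the number of close residue
pairs are iterated, eliminating pairs farther apart than a cutoff, until the
RMSD stabilizes.  Because distances are restricted, a closed/open pair is
generally aligned only over its larger (main) domain — the behaviour the hinge
detector exploits.

"Virtual" measures treat the main and swapped domains as independently
superposed: the virtual alignment size, vRMSD, and the v-variants of the
alignment ratio, Q-score and structural diversity (S-div).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .config import Config, DEFAULT
from .sse_matching import SSEMatch
from .structure_io import ProteinChain, SSEVector

__all__ = [
    "Alignment",
    "SimilarityMeasures",
    "VirtualMeasures",
    "AlignmentError",
    "kabsch_superpose",
    "dp_pairs",
    "iterative_align",
    "align_with_anchors",
    "align_fragments",
    "alignment_ratio",
    "compute_measures",
    "virtual_combine",
]


class AlignmentError(RuntimeError):
    """No residue equivalences survive superposition."""


@dataclass
class Alignment:
    pairs: list[tuple[int, int]]      # positional residue indices, strictly increasing
    rotation: np.ndarray              # applied to the subject: x' = R x + t
    translation: np.ndarray
    rmsd: float

    @property
    def n_e(self) -> int:
        return len(self.pairs)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class SimilarityMeasures:
    rmsd: float
    alignment_ratio: float            # percent
    q_score: float
    s_div: float | None               # Å per normalized residue; None if N_e = 0


@dataclass
class VirtualMeasures:
    v_alignment_size: int
    v_ratio: float
    v_rmsd: float
    v_q_score: float
    v_s_div: float | None


# ---------------------------------------------------------------------------
# Kabsch

def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares superposition of ``coords_b`` onto ``coords_a``.

    Returns (R, t, rmsd) with R a proper rotation (det = +1) minimizing
    ||a - (R b + t)||; the classical SVD solution.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate lists differ in shape: {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 paired coordinates")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (b - cb).T @ (a - ca)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = ca - rot @ cb
    moved = b @ rot.T + t
    rmsd = float(np.sqrt(((a - moved) ** 2).sum() / a.shape[0]))
    return rot, t, rmsd


# ---------------------------------------------------------------------------
# dynamic programming over a distance matrix

_NEG = -1e9


def dp_pairs(dist: np.ndarray, cutoff: float, gap_open: float) -> list[tuple[int, int]]:
    """Monotone residue pairing maximizing the number of pairs with distance
    ≤ cutoff; affine gaps (open ``gap_open`` pair-equivalents, free extension),
    free terminal gaps.  Pairs beyond the cutoff are never created."""
    n, m = dist.shape
    # every admissible pair counts 1; a small distance bonus breaks register
    # ties (e.g. helix alignments shifted by one turn) toward the closer fit
    s = np.where(dist <= cutoff, 1.0 + 0.25 * (1.0 - dist / cutoff), _NEG)
    mat = np.full((n + 1, m + 1), 0.0)
    ix = np.full((n + 1, m + 1), 0.0)    # gap in the query (move along subject)
    iy = np.full((n + 1, m + 1), 0.0)    # gap in the subject
    for i in range(1, n + 1):
        prev_best = np.maximum.reduce([mat[i - 1, :-1], ix[i - 1, :-1], iy[i - 1, :-1],
                                       np.zeros(m)])
        mat[i, 1:] = s[i - 1, :] + prev_best
        iy[i, :] = np.maximum(iy[i - 1, :], mat[i - 1, :] - gap_open)
        tmp = mat[i, :-1] - gap_open
        tmp = tmp.copy()
        tmp[0] = max(tmp[0], ix[i, 0])
        ix[i, 1:] = np.maximum.accumulate(tmp)
    i, j = np.unravel_index(np.argmax(mat), mat.shape)
    if mat[i, j] <= 0:
        return []
    pairs = []
    state = "M"
    while i > 0 and j > 0:
        if state == "M":
            pairs.append((i - 1, j - 1))
            cands = {"M": mat[i - 1, j - 1], "X": ix[i - 1, j - 1],
                     "Y": iy[i - 1, j - 1], "0": 0.0}
            state = max(cands, key=cands.get)
            i, j = i - 1, j - 1
            if state == "0":
                break
        elif state == "X":
            # ix[i, j] = max(ix[i, j-1], mat[i, j-1] - open)
            if mat[i, j - 1] - gap_open >= ix[i, j - 1] - 1e-12:
                state = "M"
            j -= 1
        else:  # Y
            if mat[i - 1, j] - gap_open >= iy[i - 1, j] - 1e-12:
                state = "M"
            i -= 1
    pairs.reverse()
    return pairs


# ---------------------------------------------------------------------------
# iterative anchored alignment

def _seed_pairs_from_match(match: SSEMatch, sses_q: list[SSEVector],
                           sses_s: list[SSEVector]) -> list[tuple[int, int]]:
    pairs = []
    for a, ap in match.pairs:
        sq, ss = sses_q[a], sses_s[ap]
        n = min(sq.n_x, ss.n_x)
        pairs.extend((sq.first_pos + k, ss.first_pos + k) for k in range(n))
    pairs.sort()
    # enforce joint monotonicity (order-independent matches may cross)
    out = []
    last_s = -1
    for qa, sa in pairs:
        if sa > last_s:
            out.append((qa, sa))
            last_s = sa
    return out


def iterative_align(coords_q: np.ndarray, coords_s: np.ndarray,
                    seed_pairs: list[tuple[int, int]],
                    config: Config = DEFAULT) -> Alignment:
    """Iterate {superpose on current pairs; eliminate far pairs; re-derive
    pairs by DP} until the RMSD change drops below tolerance."""
    pairs = [p for p in seed_pairs]
    if len(pairs) < 3:
        raise AlignmentError("fewer than 3 seed residue pairs")

    # stage 1: trim the anchor set to a rigidly consistent consensus.  A
    # closed/open pair seeds anchors in both domains; the least-squares fit is
    # a compromise, so far pairs are shed gradually (at most a quarter per
    # round) until everything left sits within the cutoff — the larger domain,
    # holding the majority of anchors, wins.
    for _ in range(config.max_iter):
        qi = np.array([p[0] for p in pairs])
        si = np.array([p[1] for p in pairs])
        rot, t, _ = kabsch_superpose(coords_q[qi], coords_s[si])
        d = np.linalg.norm(coords_q[qi] - (coords_s[si] @ rot.T + t), axis=1)
        bad = d > config.pair_cutoff
        if not bad.any() or len(pairs) <= 3:
            break
        n_drop = int(min(bad.sum(), max(1, len(pairs) // 4)))
        worst = set(np.argsort(d)[-n_drop:])
        pairs = [pairs[k] for k in range(len(pairs)) if k not in worst]
        if len(pairs) < 3:
            raise AlignmentError("alignment failed: no surviving residue pairs")

    # stage 2: alternate {superpose; eliminate far pairs; re-derive by DP}
    # until the RMSD stabilizes
    prev_rmsd = None
    for _ in range(config.max_iter):
        qi = np.array([p[0] for p in pairs])
        si = np.array([p[1] for p in pairs])
        rot, t, rmsd = kabsch_superpose(coords_q[qi], coords_s[si])
        moved = coords_s @ rot.T + t
        d = np.linalg.norm(coords_q[qi] - moved[si], axis=1)
        kept = [pairs[k] for k in range(len(pairs)) if d[k] <= config.pair_cutoff]
        if len(kept) < 3:
            raise AlignmentError("alignment failed: no surviving residue pairs")
        new_pairs = dp_pairs(cdist(coords_q, moved), config.pair_cutoff, config.gap_open)
        pairs = new_pairs if len(new_pairs) >= 3 else kept
        if prev_rmsd is not None and abs(prev_rmsd - rmsd) < config.rmsd_tol:
            break
        prev_rmsd = rmsd
    qi = np.array([p[0] for p in pairs])
    si = np.array([p[1] for p in pairs])
    rot, t, rmsd = kabsch_superpose(coords_q[qi], coords_s[si])
    d = np.linalg.norm(coords_q[qi] - (coords_s[si] @ rot.T + t), axis=1)
    final = [pairs[k] for k in range(len(pairs)) if d[k] <= config.pair_cutoff]
    if len(final) < 3:
        raise AlignmentError("alignment failed: no surviving residue pairs")
    qi = np.array([p[0] for p in final])
    si = np.array([p[1] for p in final])
    rot, t, rmsd = kabsch_superpose(coords_q[qi], coords_s[si])
    return Alignment(final, rot, t, rmsd)


def align_with_anchors(chain_q: ProteinChain, chain_s: ProteinChain,
                       match: SSEMatch, sses_q: list[SSEVector],
                       sses_s: list[SSEVector],
                       config: Config = DEFAULT) -> Alignment:
    """Residue-level alignment seeded by the matched SSEs.

    The iteration converges to one rigidly consistent region.  Because the
    method prefers the larger domain (the DP maximizes the number of
    equivalent pairs), the anchors left outside the converged region are also
    tried as an alternative seed and the alignment with more pairs wins.
    """
    if not match.pairs:
        raise AlignmentError("empty SSE match: nothing to anchor")
    seed_sets = [_seed_pairs_from_match(match, sses_q, sses_s)]
    # multi-start: every window of two adjacent matched SSE pairs pins a
    # candidate transform; the DP then grows it over the whole chains
    ordered = sorted(match.pairs)
    for w in range(len(ordered) - 1):
        window = SSEMatch(ordered[w:w + 2], match.mode)
        seed_sets.append(_seed_pairs_from_match(window, sses_q, sses_s))
    best = None
    err: AlignmentError | None = None
    for seeds in seed_sets:
        if len(seeds) < 3:
            continue
        try:
            aln = iterative_align(chain_q.ca, chain_s.ca, seeds, config)
        except AlignmentError as exc:
            err = exc
            continue
        if best is None or aln.n_e > best.n_e or \
                (aln.n_e == best.n_e and aln.rmsd < best.rmsd):
            best = aln
    if best is None:
        raise err if err is not None else AlignmentError("alignment failed")
    return best


def align_fragments(coords_q: np.ndarray, coords_s: np.ndarray,
                    anchor: str = "start", config: Config = DEFAULT,
                    seeds: list[tuple[int, int]] | None = None) -> Alignment:
    """Rigidly align two fragments (candidate swapped domains).

    Seeded by the matched SSEs inside the fragments when provided, otherwise
    by index-wise pairing from the hinge-proximal end (``anchor``: start|end).
    """
    n = min(len(coords_q), len(coords_s))
    if n < 3:
        raise AlignmentError("fragment shorter than 3 residues")
    if anchor == "start":
        index_seeds = [(k, k) for k in range(n)]
    else:
        off_q = len(coords_q) - n
        off_s = len(coords_s) - n
        index_seeds = [(off_q + k, off_s + k) for k in range(n)]
    best = None
    err: AlignmentError | None = None
    for seed_set in ([seeds] if seeds else []) + [index_seeds]:
        try:
            aln = iterative_align(coords_q, coords_s, seed_set, config)
        except AlignmentError as exc:
            err = exc
            continue
        if best is None or aln.n_e > best.n_e or \
                (aln.n_e == best.n_e and aln.rmsd < best.rmsd):
            best = aln
    if best is None:
        raise err if err is not None else AlignmentError("fragment alignment failed")
    return best


# ---------------------------------------------------------------------------
# measures

def alignment_ratio(n_e: float, n_c: float, n_o: float) -> float:
    """Percent of residues aligned, normalized by the mean protein size."""
    mean = 0.5 * (n_c + n_o)
    return 100.0 * n_e / mean if mean > 0 else 0.0


def compute_measures(n_e: float, rmsd: float, n_c: float, n_o: float,
                     config: Config = DEFAULT) -> SimilarityMeasures:
    """Alignment ratio, Q-score and S-div for an alignment of ``n_e`` pairs
    between proteins of ``n_c`` and ``n_o`` residues."""
    if n_e <= 0:
        return SimilarityMeasures(rmsd=rmsd, alignment_ratio=0.0, q_score=0.0, s_div=None)
    ratio = alignment_ratio(n_e, n_c, n_o)
    q = (n_e ** 2) / (n_c * n_o) / (1.0 + (rmsd / config.q_r0) ** 2)
    s_div = rmsd / (n_e / min(n_c, n_o))
    return SimilarityMeasures(rmsd=rmsd, alignment_ratio=ratio, q_score=float(q),
                              s_div=float(s_div))


def measures_of(aln: Alignment, n_c: int, n_o: int,
                config: Config = DEFAULT) -> SimilarityMeasures:
    return compute_measures(aln.n_e, aln.rmsd, n_c, n_o, config)


def virtual_combine(main_aln: Alignment, swap_aln: Alignment,
                    n_c: int, n_o: int, config: Config = DEFAULT) -> VirtualMeasures:
    """Virtual measures over the union of the two alignments, each domain
    under its own optimal transform."""
    q_main = {p[0] for p in main_aln.pairs}
    q_swap = {p[0] for p in swap_aln.pairs}
    s_main = {p[1] for p in main_aln.pairs}
    s_swap = {p[1] for p in swap_aln.pairs}
    if (q_main & q_swap) or (s_main & s_swap):
        raise ValueError("main and swapped alignments overlap in residues")
    n_total = main_aln.n_e + swap_aln.n_e
    v_rmsd = float(np.sqrt((main_aln.rmsd ** 2 * main_aln.n_e
                            + swap_aln.rmsd ** 2 * swap_aln.n_e) / n_total))
    m = compute_measures(n_total, v_rmsd, n_c, n_o, config)
    return VirtualMeasures(v_alignment_size=n_total, v_ratio=m.alignment_ratio,
                           v_rmsd=v_rmsd, v_q_score=m.q_score, v_s_div=m.s_div)
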