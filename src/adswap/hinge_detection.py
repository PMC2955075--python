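"""Hinge-loop detection from the A·D profile.

After the superposition-dependent alignment, every matched SSE pair gets an
angle-distance product P_ad = (θ/θ_u)·(d/d_u): aligned pairs score near zero,
matched-but-unaligned pairs (the candidate swapped domain) score high.  The
profile of P_ad along the sequence is denoised by 1-D grayscale morphological
opening+closing, its absolute consecutive differences are screened by a
Student-t threshold, and significant transitions localize candidate hinge
loops.  Opening points are then refined against the residue alignment mask
(peak-first / bifurcation-last scan), candidate swapped domains are validated
by fragment superposition, and hinge ranges are determined by extending over
aligned residue pairs with large φ/ψ differences.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .config import Config, DEFAULT
from .rigid_alignment import Alignment, AlignmentError, align_fragments
from .structure_io import ProteinChain, SSEVector, angle_diff, vector_angle

__all__ = [
    "ADProfile",
    "HingeCandidate",
    "HingeValidation",
    "ad_product",
    "build_profile",
    "smooth_profile",
    "detect_transitions",
    "classify_ds_type",
    "initial_opening_point",
    "assign_small_swapped_domain",
    "refine_opening_point",
    "validate_hinge",
    "determine_hinge_range",
]


@dataclass
class ADProfile:
    entries: np.ndarray                       # P_ad per matched SSE pair, query order
    smoothed: np.ndarray
    diffs: np.ndarray                         # |consecutive differences| of smoothed
    annotations: list[tuple[int, int]]        # (query SSE index, subject SSE index)


@dataclass
class HingeCandidate:
    """A candidate hinge boundary, per protein, before refinement."""
    ds_type: str                              # N | C | middle
    side: str                                 # N | C (one per hinge loop)
    o_q: int                                  # initial opening point, positional
    o_s: int


@dataclass
class HingeValidation:
    eta: int
    swap_alignment: Alignment | None          # pairs in full-chain positional indices
    q_fragment: tuple[int, int] | None        # inclusive positional range
    s_fragment: tuple[int, int] | None
    reason: str = ""


# ---------------------------------------------------------------------------
# profile

def ad_product(theta: float, dist: float, config: Config = DEFAULT) -> float:
    """P_ad = (θ/θ_u)·(d/d_u) with θ_u = 180°, d_u = 25 Å; unbounded above."""
    return (theta / config.theta_u) * (dist / config.d_u)


def build_profile(match_pairs: list[tuple[int, int]],
                  sses_q: list[SSEVector], sses_s: list[SSEVector],
                  main_aln: Alignment, config: Config = DEFAULT) -> ADProfile:
    """A·D profile over matched SSE pairs in query sequence order, measured
    after applying the main alignment's transform to the subject."""
    rot, t = main_aln.rotation, main_aln.translation
    entries, ann = [], []
    for a, ap in sorted(match_pairs):
        sq, ss = sses_q[a], sses_s[ap]
        d_moved = ss.direction @ rot.T
        c_moved = ss.centroid @ rot.T + t
        theta = vector_angle(sq.direction, d_moved)
        dist = float(np.linalg.norm(sq.centroid - c_moved))
        entries.append(ad_product(theta, dist, config))
        ann.append((a, ap))
    entries = np.array(entries)
    smoothed = smooth_profile(entries, config)
    return ADProfile(entries, smoothed, np.abs(np.diff(smoothed)), ann)


def smooth_profile(entries: np.ndarray, config: Config = DEFAULT) -> np.ndarray:
    """Grayscale morphological opening followed by closing (flat element of
    width 3): removes isolated single-point peaks and valleys, keeps plateaus
    at least as wide as the element."""
    x = np.asarray(entries, dtype=float)
    if x.size < 3:
        warnings.warn("profile too short to smooth; returned unchanged")
        return x.copy()
    size = config.smooth_width
    opened = ndimage.grey_opening(x, size=size, mode="nearest")
    return ndimage.grey_closing(opened, size=size, mode="nearest")


def detect_transitions(smoothed: np.ndarray, config: Config = DEFAULT
                       ) -> tuple[list[int], float, np.ndarray]:
    """Indices k whose |p_(k+1) − p_k| exceeds the upper bound of the
    two-sided 80% confidence interval of the mean absolute difference.

    Returns (significant indices, threshold, diffs).  Zero-variance difference
    sequences yield no transitions.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    if smoothed.size < 2:
        return [], float("nan"), np.empty(0)
    diffs = np.abs(np.diff(smoothed))
    n = diffs.size
    sd = diffs.std(ddof=1) if n > 1 else 0.0
    if sd == 0.0:
        return [], float(diffs.mean()), diffs
    t_crit = stats.t.ppf(0.5 + config.confidence / 2.0, n - 1)
    threshold = float(diffs.mean() + t_crit * sd / np.sqrt(n))
    return [int(k) for k in np.nonzero(diffs > threshold)[0]], threshold, diffs


def classify_ds_type(smoothed: np.ndarray, transitions: list[int]
                     ) -> tuple[str, tuple[int | None, int | None]]:
    """Locate the high-valued region of the profile.

    Returns (ds_type, (k_left, k_right)) where the k's are the transition
    indices bounding the high region (None when it touches an end).  A profile
    with no significant transition is typed "none" (small-domain path).
    """
    if not transitions:
        return "none", (None, None)
    bounds = [-1] + sorted(transitions) + [smoothed.size - 1]
    seg_means = []
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        seg_means.append(smoothed[b0 + 1:b1 + 1].mean())
    hi = int(np.argmax(seg_means))
    k_left = None if hi == 0 else bounds[hi]
    k_right = None if hi == len(seg_means) - 1 else bounds[hi + 1]
    if k_left is None and k_right is not None:
        return "N", (None, k_right)
    if k_right is None and k_left is not None:
        return "C", (k_left, None)
    if k_left is not None and k_right is not None:
        return "middle", (k_left, k_right)
    return "none", (None, None)


# ---------------------------------------------------------------------------
# opening points

def initial_opening_point(ds_type: str, profile: ADProfile,
                          sses_q: list[SSEVector], sses_s: list[SSEVector],
                          bounds: tuple[int | None, int | None]
                          ) -> list[HingeCandidate]:
    """Approximate opening points from the profile transition(s).

    N-swap: first residue of the SSE on the C side of the transition.
    C-swap: last residue of the SSE on the N side.  A middle swap combines
    both rules, producing two hinge candidates.
    """
    k_left, k_right = bounds
    out = []
    if ds_type == "C":
        a, ap = profile.annotations[k_left]
        out.append(HingeCandidate("C", "C", sses_q[a].last_pos, sses_s[ap].last_pos))
    elif ds_type == "N":
        a, ap = profile.annotations[k_right + 1]
        out.append(HingeCandidate("N", "N", sses_q[a].first_pos, sses_s[ap].first_pos))
    elif ds_type == "middle":
        a, ap = profile.annotations[k_left]
        out.append(HingeCandidate("middle", "N_of_middle",
                                  sses_q[a].last_pos, sses_s[ap].last_pos))
        a, ap = profile.annotations[k_right + 1]
        out.append(HingeCandidate("middle", "C_of_middle",
                                  sses_q[a].first_pos, sses_s[ap].first_pos))
    return out


def _aligned_mask(n: int, aln: Alignment, which: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for p in aln.pairs:
        mask[p[which]] = True
    return mask


def assign_small_swapped_domain(profile: ADProfile, main_aln: Alignment,
                                chain_q: ProteinChain, chain_s: ProteinChain,
                                sses_q: list[SSEVector], sses_s: list[SSEVector]
                                ) -> list[HingeCandidate]:
    """Small-swapped-domain path for flat profiles.

    The unaligned terminal region before the first (after the last) aligned
    SSE pair is proposed as an N- (C-) swapped candidate; an interior
    unaligned fragment becomes a middle candidate with opening points at the
    bifurcation edges.  Returns an empty list when everything is aligned.
    """
    mask_q = _aligned_mask(len(chain_q), main_aln, 0)
    mask_s = _aligned_mask(len(chain_s), main_aln, 1)
    aligned_pairs = [(a, ap) for a, ap in profile.annotations
                     if mask_q[sses_q[a].first_pos:sses_q[a].last_pos + 1].any()]
    cands: list[HingeCandidate] = []
    if not aligned_pairs:
        return cands
    first_a, first_ap = aligned_pairs[0]
    last_a, last_ap = aligned_pairs[-1]
    n_tail_q = sses_q[first_a].first_pos          # residues before the first aligned SSE
    n_tail_s = sses_s[first_ap].first_pos
    c_tail_q = len(chain_q) - 1 - sses_q[last_a].last_pos
    c_tail_s = len(chain_s) - 1 - sses_s[last_ap].last_pos
    if min(n_tail_q, n_tail_s) > 0 and (~mask_q[:n_tail_q]).any():
        cands.append(HingeCandidate("N", "N",
                                    sses_q[first_a].first_pos, sses_s[first_ap].first_pos))
    if min(c_tail_q, c_tail_s) > 0 and (~mask_q[len(chain_q) - c_tail_q:]).any():
        cands.append(HingeCandidate("C", "C",
                                    sses_q[last_a].last_pos, sses_s[last_ap].last_pos))
    if not cands:
        # interior bifurcation: longest interior run unaligned in both proteins'
        # aligned-pair gap structure
        run = _longest_interior_gap(mask_q)
        run_s = _longest_interior_gap(mask_s)
        if run is not None and run_s is not None:
            cands.append(HingeCandidate("middle", "N_of_middle", run[0] - 1, run_s[0] - 1))
            cands.append(HingeCandidate("middle", "C_of_middle", run[1] + 1, run_s[1] + 1))
    return cands


def _longest_interior_gap(mask: np.ndarray) -> tuple[int, int] | None:
    best = None
    i = 0
    n = len(mask)
    while i < n:
        if not mask[i]:
            j = i
            while j + 1 < n and not mask[j + 1]:
                j += 1
            if i > 0 and j < n - 1 and (best is None or j - i > best[1] - best[0]):
                best = (i, j)
            i = j + 1
        else:
            i += 1
    return best


def refine_opening_point(mask: np.ndarray, o: int, toward_peak: int,
                         config: Config = DEFAULT) -> int | None:
    """Peak-first / bifurcation-last refinement of an opening point.

    PF stage: a probe moves from ``o`` toward the well-superimposed region
    (``toward_peak`` = ±1) until more than ``pf_run`` consecutive residues are
    aligned.  BL stage: from that stop point the probe returns toward the
    bifurcation, counting unaligned residues N_u; once N_u exceeds T_N the
    candidate is confirmed and the opening point is the boundary — the last
    aligned residue passed.  A probe reaching the terminus with N_u ≤ T_N
    means an over-extended candidate: returns None (rejection).
    """
    n = len(mask)
    o = int(np.clip(o, 0, n - 1))
    # PF stage
    run = 0
    stop = None
    p = o
    while 0 <= p < n:
        run = run + 1 if mask[p] else 0
        if run > config.pf_run:
            stop = p
            break
        p += toward_peak
    if stop is None:
        return None
    # BL stage: the bifurcation starts at the first run of at least two
    # consecutive unaligned residues (isolated unaligned residues are local
    # noise); the cumulative count N_u must still exceed T_N to confirm the
    # bifurcation, otherwise the candidate is over-extended
    n_u = 0
    last_aligned = stop
    boundary = None
    run = 0
    p = stop
    while 0 <= p < n:
        if mask[p]:
            last_aligned = p
            run = 0
        else:
            run += 1
            if run == 2 and boundary is None:
                boundary = last_aligned
            n_u += 1
            if n_u > config.t_n:
                return boundary if boundary is not None else last_aligned
        p -= toward_peak
    return None


# ---------------------------------------------------------------------------
# validation

def _fragment_range(side: str, o: int, n: int) -> tuple[int, int] | None:
    if side in ("C", "N_of_middle"):
        lo, hi = o + 1, n - 1
    else:  # "N", "C_of_middle"
        lo, hi = 0, o - 1
    if hi < lo:
        return None
    return lo, hi


def validate_hinge(chain_q: ProteinChain, chain_s: ProteinChain,
                   o_q: int, o_s: int, side: str, main_aln: Alignment,
                   config: Config = DEFAULT,
                   frag_q: tuple[int, int] | None = None,
                   frag_s: tuple[int, int] | None = None,
                   seed_pairs: list[tuple[int, int]] | None = None) -> HingeValidation:
    """Feasibility of a candidate hinge loop and its swapped domain.

    Quick screen: the fraction of the candidate fragment left unaligned by the
    main-domain superposition must reach T_L.  The two fragments are then
    rigidly superposed; acceptance requires aligned residues ≥ 50% of the
    smaller fragment and RMSD < 4 Å.  Acceptance sets η = 1.
    """
    if frag_q is None:
        frag_q = _fragment_range(side, o_q, len(chain_q))
    if frag_s is None:
        frag_s = _fragment_range(side, o_s, len(chain_s))
    if frag_q is None or frag_s is None:
        return HingeValidation(0, None, None, None, "empty candidate fragment")
    len_q = frag_q[1] - frag_q[0] + 1
    len_s = frag_s[1] - frag_s[0] + 1
    if min(len_q, len_s) < 3:
        return HingeValidation(0, None, frag_q, frag_s, "fragment shorter than 3 residues")
    mask_q = _aligned_mask(len(chain_q), main_aln, 0)
    mask_s = _aligned_mask(len(chain_s), main_aln, 1)
    unal_q = float((~mask_q[frag_q[0]:frag_q[1] + 1]).mean())
    unal_s = float((~mask_s[frag_s[0]:frag_s[1] + 1]).mean())
    if unal_q < config.t_l or unal_s < config.t_l:
        return HingeValidation(0, None, frag_q, frag_s,
                               "candidate fragment mostly aligned by the main superposition")
    anchor = "start" if side in ("C", "N_of_middle", "middle") else "end"
    local_seeds = None
    if seed_pairs:
        local_seeds = [(q - frag_q[0], s - frag_s[0]) for q, s in seed_pairs
                       if frag_q[0] <= q <= frag_q[1] and frag_s[0] <= s <= frag_s[1]]
        if len(local_seeds) < 3:
            local_seeds = None
    try:
        local = align_fragments(chain_q.ca[frag_q[0]:frag_q[1] + 1],
                                chain_s.ca[frag_s[0]:frag_s[1] + 1],
                                anchor=anchor, config=config, seeds=local_seeds)
    except AlignmentError as exc:
        return HingeValidation(0, None, frag_q, frag_s, str(exc))
    if local.n_e < config.frag_min_ratio * min(len_q, len_s):
        return HingeValidation(0, None, frag_q, frag_s, "fragment alignment ratio below 50%")
    if local.rmsd >= config.frag_max_rmsd:
        return HingeValidation(0, None, frag_q, frag_s, "fragment RMSD at or above 4 Å")
    global_pairs = [(frag_q[0] + a, frag_s[0] + b) for a, b in local.pairs]
    swap_aln = Alignment(global_pairs, local.rotation, local.translation, local.rmsd)
    return HingeValidation(1, swap_aln, frag_q, frag_s, "accepted")


# ---------------------------------------------------------------------------
# hinge range

def determine_hinge_range(o: int, side: str,
                          pair_info: dict[int, tuple[float, float | None]],
                          n_len: int, swap_range: tuple[int, int],
                          n_hl: int, config: Config = DEFAULT,
                          theta0: float | None = None,
                          extra_stops: bool = True) -> tuple[int, int]:
    """Extend the hinge loop from the refined opening point.

    ``pair_info`` maps a residue position to (Cα-Cα distance under the
    relevant superposition, φ/ψ difference in degrees or None when undefined)
    for aligned residue pairs.  Starting at the boundary, both ends extend
    while aligned pairs differ by at least θ₀ = 25°·n_hl; an end stops when
    two consecutive aligned pairs fall below θ₀, when each of the last three
    included aligned pairs sits within 2.6 Å, or when the candidate swapped
    domain would shrink to ≤ 10 residues.  ``theta0``/``extra_stops`` expose
    the original fixed-cutoff variant for comparison runs.
    """
    if theta0 is None:
        theta0 = config.theta0_base * n_hl
    swapped_side = +1 if side in ("C", "N_of_middle") else -1

    def extend(start: int, step: int) -> list[int]:
        included: list[int] = []
        buffer: list[int] = []          # unaligned residues pending evidence
        below_prev: int | None = None   # position of a pending below-cutoff pair
        recent: list[float] = []
        q = start
        while 0 <= q < n_len:
            if extra_stops and step == swapped_side:
                remaining = (swap_range[1] - q) if step > 0 else (q - swap_range[0])
                if remaining <= config.min_swap:
                    break
            info = pair_info.get(q)
            if info is None:
                # no torsion evidence: joins the hinge only if flanked by
                # evidenced residues; a long unaligned run ends the extension
                buffer.append(q)
                if len(buffer) > config.t_n:
                    break
                q += step
                continue
            ca_d, tor = info
            if tor is None:
                break                   # torsions undefined: this end stops here
            if tor < theta0:
                if below_prev is not None:
                    if included and included[-1] == below_prev:
                        included.pop()  # drop the first of the two below-cutoff pairs
                    break
                below_prev = q
            else:
                below_prev = None
            included.extend(buffer)
            buffer = []
            included.append(q)
            recent.append(ca_d)
            if extra_stops and len(recent) >= 3 and all(d <= config.ca_stop for d in recent[-3:]):
                break
            q += step
        return included

    if side in ("C", "N_of_middle"):
        left = extend(o, -1)
        right = extend(o + 1, +1)
    else:
        left = extend(o - 1, -1)
        right = extend(o, +1)
    included = left + right
    if not included:
        lo = max(0, o if side in ("C", "N_of_middle") else o - 1)
        hi = min(n_len - 1, lo + 1)
        return lo, hi
    return min(included), max(included)


def torsion_difference(chain_q: ProteinChain, chain_s: ProteinChain,
                       qpos: int, spos: int) -> float | None:
    """max(|Δφ|, |Δψ|) with periodic wrapping; None when either is undefined."""
    rq, rs = chain_q.residues[qpos], chain_s.residues[spos]
    if rq.phi is None or rs.phi is None or rq.psi is None or rs.psi is None:
        return None
    return max(angle_diff(rq.phi, rs.phi), angle_diff(rq.psi, rs.psi))
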