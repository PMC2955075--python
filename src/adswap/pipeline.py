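"""End-to-end pairwise DS comparison.

``compare_pair`` runs the whole method on two chains: SSE extraction → A-D
images → pair-graph SSE matching → anchored rigid alignment → A·D profile →
hinge detection/validation → swap factors → DS score.  "No DS relationship"
is a successful outcome (η = 0, score 0), not an error.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .ad_image import build_ad_image
from .config import Config, DEFAULT
from .ds_score import DSFactors, DSModel, ds_score, gamma_d, gamma_theta, mu_sd
from .hinge_detection import (ADProfile, HingeCandidate, HingeValidation,
                              assign_small_swapped_domain, build_profile,
                              classify_ds_type, detect_transitions,
                              determine_hinge_range, initial_opening_point,
                              refine_opening_point, torsion_difference,
                              validate_hinge)
from .rigid_alignment import (Alignment, AlignmentError, align_with_anchors,
                              _seed_pairs_from_match, compute_measures,
                              virtual_combine)
from .sse_matching import match_images
from .structure_io import ProteinChain, extract_sses

__all__ = ["DSReport", "HingeLoopReport", "compare_pair"]


@dataclass
class HingeLoopReport:
    protein: str                       # "Q" | "S"
    opening_point_initial: int         # author residue numbers
    opening_point_refined: int
    range: tuple[int, int]
    length: int
    n_hl: int
    theta0: float


@dataclass
class DSReport:
    query: str
    subject: str
    ds_score: float = 0.0
    is_ds: bool = False
    ds_type: str = "none"
    eta: int = 0
    factors: dict | None = None
    measures: dict = field(default_factory=dict)
    hinges: list[HingeLoopReport] = field(default_factory=list)
    profile: list[float] = field(default_factory=list)
    profile_smoothed: list[float] = field(default_factory=list)
    transition_threshold: float | None = None
    matched_sses: list[tuple[int, int]] = field(default_factory=list)
    diagnostic: str = ""
    main_alignment: Alignment | None = None
    swap_alignment: Alignment | None = None
    swap_fragment_q: tuple[int, int] | None = None   # positional, inclusive
    swap_fragment_s: tuple[int, int] | None = None

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, float):
                return x if np.isfinite(x) else None
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [clean(v) for v in x]
            return x
        d = {
            "query": self.query, "subject": self.subject,
            "ds_score": self.ds_score, "is_ds": self.is_ds,
            "ds_type": self.ds_type, "eta": self.eta,
            "factors": clean(self.factors),
            "measures": clean(self.measures),
            "hinges": [asdict(h) for h in self.hinges],
            "profile": clean(list(self.profile)),
            "profile_smoothed": clean(list(self.profile_smoothed)),
            "transition_threshold": clean(self.transition_threshold),
            "matched_sses": [list(p) for p in self.matched_sses],
            "diagnostic": self.diagnostic,
        }
        return d


def _measure_dict(m) -> dict:
    return asdict(m)


def _hinge_pair_info(chain_q, chain_s, main_aln, swap_aln):
    """Per-protein map: residue position → (Cα distance under the relevant
    superposition, φ/ψ difference).  Main-domain pairs use the main transform,
    swapped pairs their own."""
    info_q: dict[int, tuple[float, float | None]] = {}
    info_s: dict[int, tuple[float, float | None]] = {}
    for aln in (main_aln, swap_aln):
        if aln is None:
            continue
        moved = aln.transform(chain_s.ca)
        for qi, si in aln.pairs:
            d = float(np.linalg.norm(chain_q.ca[qi] - moved[si]))
            tor = torsion_difference(chain_q, chain_s, qi, si)
            info_q[qi] = (d, tor)
            info_s[si] = (d, tor)
    return info_q, info_s


def compare_pair(chain_q: ProteinChain, chain_s: ProteinChain,
                 config: Config = DEFAULT, model: DSModel | None = None,
                 sequential: bool = True, sse_source: str = "records") -> DSReport:
    """Full DS detection on two chains; returns a DSReport."""
    model = model or DSModel()
    report = DSReport(query=chain_q.id, subject=chain_s.id)

    sses_q = extract_sses(chain_q, source=sse_source, min_len=config.min_sse_len)
    sses_s = extract_sses(chain_s, source=sse_source, min_len=config.min_sse_len)
    if len(sses_q) < 2 or len(sses_s) < 2:
        report.diagnostic = (f"too few SSEs (query {len(sses_q)}, subject {len(sses_s)}); "
                             "comparison aborted")
        return report

    img_q = build_ad_image(sses_q, chain_q.id, config)
    img_s = build_ad_image(sses_s, chain_s.id, config)
    match, _ = match_images(img_q, img_s, config, sequential=sequential)
    report.matched_sses = list(match.pairs)
    if not match.pairs:
        report.diagnostic = "no SSE similarity found"
        return report

    try:
        main_aln = align_with_anchors(chain_q, chain_s, match, sses_q, sses_s, config)
    except AlignmentError as exc:
        report.diagnostic = f"rigid alignment failed: {exc}"
        return report
    report.main_alignment = main_aln

    n_q, n_s = len(chain_q), len(chain_s)
    rigid = compute_measures(main_aln.n_e, main_aln.rmsd, n_q, n_s, config)
    report.measures["rigid"] = _measure_dict(rigid)

    profile = build_profile(match.pairs, sses_q, sses_s, main_aln, config)
    report.profile = [float(x) for x in profile.entries]
    report.profile_smoothed = [float(x) for x in profile.smoothed]
    transitions, threshold, _ = detect_transitions(profile.smoothed, config)
    report.transition_threshold = threshold

    ds_type, bounds = classify_ds_type(profile.smoothed, transitions)
    if ds_type != "none":
        candidates = initial_opening_point(ds_type, profile, sses_q, sses_s, bounds)
    else:
        candidates = assign_small_swapped_domain(profile, main_aln, chain_q, chain_s,
                                                 sses_q, sses_s)
        if candidates:
            ds_type = candidates[0].ds_type
    if not candidates:
        report.diagnostic = "no candidate hinge loop (profile flat, chains fully aligned)"
        return report

    mask_q = np.zeros(n_q, dtype=bool)
    mask_s = np.zeros(n_s, dtype=bool)
    for qi, si in main_aln.pairs:
        mask_q[qi] = True
        mask_s[si] = True

    _PEAK = {"C": -1, "N": +1, "N_of_middle": -1, "C_of_middle": +1}
    refined: list[tuple[HingeCandidate, int, int]] = []
    for cand in candidates:
        direction = _PEAK[cand.side]
        oq = refine_opening_point(mask_q, cand.o_q, direction, config)
        os_ = refine_opening_point(mask_s, cand.o_s, direction, config)
        if oq is None or os_ is None:
            continue
        refined.append((cand, oq, os_))
    if not refined or (ds_type == "middle" and len(refined) < 2):
        report.ds_type = ds_type
        report.diagnostic = "candidate hinge rejected during opening-point refinement"
        return report

    if ds_type == "middle":
        (cn, oq_n, os_n), (cc, oq_c, os_c) = refined[0], refined[1]
        frag_q = (oq_n + 1, oq_c - 1)
        frag_s = (os_n + 1, os_c - 1)
        if frag_q[1] - frag_q[0] < 2 or frag_s[1] - frag_s[0] < 2:
            report.ds_type = ds_type
            report.diagnostic = "middle candidate fragment too short"
            return report
        val = validate_hinge(chain_q, chain_s, oq_n, os_n, "middle", main_aln,
                             config, frag_q=frag_q, frag_s=frag_s,
                             seed_pairs=_seed_pairs_from_match(match, sses_q, sses_s))
        hinge_points = [(cn, oq_n, os_n), (cc, oq_c, os_c)]
        n_hl = 2
    else:
        cand, oq, os_ = refined[0]
        val = validate_hinge(chain_q, chain_s, oq, os_, cand.side, main_aln, config,
                             seed_pairs=_seed_pairs_from_match(match, sses_q, sses_s))
        hinge_points = [(cand, oq, os_)]
        n_hl = 1

    report.ds_type = ds_type
    report.eta = val.eta
    if val.eta == 0:
        report.diagnostic = f"hinge validation failed: {val.reason}"
        return report

    swap_aln = val.swap_alignment
    report.swap_alignment = swap_aln
    frag_q, frag_s = val.q_fragment, val.s_fragment
    report.swap_fragment_q, report.swap_fragment_s = frag_q, frag_s
    len_fq = frag_q[1] - frag_q[0] + 1
    len_fs = frag_s[1] - frag_s[0] + 1

    # the main alignment may keep stragglers inside the swapped fragments
    # (residues near the hinge axis move little); restrict it to the main
    # domains and refit so the virtual superposition sees disjoint domains
    trimmed = [(qi, si) for qi, si in main_aln.pairs
               if not (frag_q[0] <= qi <= frag_q[1]) and not (frag_s[0] <= si <= frag_s[1])]
    if len(trimmed) >= 3 and len(trimmed) < main_aln.n_e:
        from .rigid_alignment import kabsch_superpose
        qi = np.array([p[0] for p in trimmed])
        si = np.array([p[1] for p in trimmed])
        rot, t, rmsd = kabsch_superpose(chain_q.ca[qi], chain_s.ca[si])
        main_aln = Alignment(trimmed, rot, t, rmsd)
        report.main_alignment = main_aln

    main_sizes = (n_q - len_fq, n_s - len_fs)
    report.measures["main"] = _measure_dict(
        compute_measures(main_aln.n_e, main_aln.rmsd, *main_sizes, config))
    report.measures["swapped"] = _measure_dict(
        compute_measures(swap_aln.n_e, swap_aln.rmsd, len_fq, len_fs, config))
    try:
        virtual = virtual_combine(main_aln, swap_aln, n_q, n_s, config)
    except ValueError:
        virtual = None
    if virtual is not None:
        report.measures["virtual"] = asdict(virtual)

    # hinge ranges
    info_q, info_s = _hinge_pair_info(chain_q, chain_s, main_aln, swap_aln)
    theta0 = config.theta0_base * n_hl
    for cand, oq, os_ in hinge_points:
        rng_q = determine_hinge_range(oq, cand.side, info_q, n_q, frag_q, n_hl, config)
        rng_s = determine_hinge_range(os_, cand.side, info_s, n_s, frag_s, n_hl, config)
        for protein, chain, o0, o1, rng in (
                ("Q", chain_q, cand.o_q, oq, rng_q), ("S", chain_s, cand.o_s, os_, rng_s)):
            report.hinges.append(HingeLoopReport(
                protein=protein,
                opening_point_initial=chain.residues[int(np.clip(o0, 0, len(chain) - 1))].seq_id[0],
                opening_point_refined=chain.residues[o1].seq_id[0],
                range=(chain.residues[rng[0]].seq_id[0], chain.residues[rng[1]].seq_id[0]),
                length=rng[1] - rng[0] + 1,
                n_hl=n_hl, theta0=theta0))

    # swap factors, hinge excluded from the representative-vector domains
    hinge_pos_q = set()
    hinge_pos_s = set()
    for h, (cand, oq, os_) in zip(range(len(hinge_points)), hinge_points):
        rng_q = determine_hinge_range(oq, cand.side, info_q, n_q, frag_q, n_hl, config)
        rng_s = determine_hinge_range(os_, cand.side, info_s, n_s, frag_s, n_hl, config)
        hinge_pos_q.update(range(rng_q[0], rng_q[1] + 1))
        hinge_pos_s.update(range(rng_s[0], rng_s[1] + 1))
    dom_q = [p for p in range(frag_q[0], frag_q[1] + 1) if p not in hinge_pos_q]
    dom_s = [p for p in range(frag_s[0], frag_s[1] + 1) if p not in hinge_pos_s]
    if len(dom_q) < 3 or len(dom_s) < 3:
        dom_q = list(range(frag_q[0], frag_q[1] + 1))
        dom_s = list(range(frag_s[0], frag_s[1] + 1))
    moved_s = main_aln.transform(chain_s.ca)
    hinge_at = "start" if hinge_points[0][0].side in ("C", "N_of_middle") else "end"
    first_cand, oq0, os0 = hinge_points[0]
    gt = gamma_theta(chain_q.ca[dom_q], moved_s[dom_s],
                     chain_q.ca[oq0], moved_s[os0], hinge_at=hinge_at)
    qi = np.array([p[0] for p in swap_aln.pairs])
    si = np.array([p[1] for p in swap_aln.pairs])
    gd = gamma_d(chain_q.ca[qi], moved_s[si])
    mu = mu_sd(swap_aln.rmsd, swap_aln.n_e, len_fs, len_fq)
    s0 = virtual.v_q_score if virtual is not None else 0.0
    factors = DSFactors(gamma_theta=gt, gamma_d=gd, mu_sd=mu, eta=val.eta, s0=s0)
    report.factors = {"gamma_theta": gt, "gamma_d": gd, "mu_sd": mu,
                      "eta": val.eta, "s0": s0}
    report.ds_score = ds_score(factors, model)
    report.is_ds = report.ds_score > model.cutoff
    report.diagnostic = "ok"
    return report
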