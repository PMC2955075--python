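"""A·D profile, transition test, opening points, validation, hinge ranges."""
import numpy as np
import pytest

from adswap.config import Config
from adswap.hinge_detection import (ADProfile, ad_product, assign_small_swapped_domain,
                                    classify_ds_type, determine_hinge_range,
                                    detect_transitions, initial_opening_point,
                                    refine_opening_point, smooth_profile,
                                    validate_hinge)
from adswap.pipeline import compare_pair
from adswap.rigid_alignment import Alignment
from adswap.synthetic import FixtureSpec, make_closed_form, make_open_form
from .test_ad_image import make_sse

# the ten-point smoothened profile of the crystallin worked example
WORKED_PROFILE = np.array([1.10] * 4 + [4.50] * 3 + [4.37] * 3)


class TestADProduct:
    def test_normalization_anchors(self):
        assert ad_product(0.0, 17.0) == 0.0
        assert ad_product(180.0, 25.0) == pytest.approx(1.0)
        assert ad_product(90.0, 12.5) == pytest.approx(0.25)

    def test_unbounded_above(self):
        assert ad_product(180.0, 50.0) == pytest.approx(2.0)


class TestSmoothing:
    def test_constant_profile_unchanged(self):
        x = np.full(8, 2.5)
        assert np.allclose(smooth_profile(x), x)

    def test_single_spike_removed(self):
        assert np.allclose(smooth_profile(np.array([1, 1, 9, 1, 1.0])), 1.0)

    def test_single_valley_removed(self):
        assert np.allclose(smooth_profile(np.array([4, 4, 0.5, 4, 4.0])), 4.0)

    def test_plateaus_survive(self):
        x = np.array([1.0] * 4 + [5.0] * 3 + [4.0] * 3)
        assert np.allclose(smooth_profile(x), x)

    def test_short_profile_returned_unchanged_with_warning(self):
        with pytest.warns(UserWarning):
            out = smooth_profile(np.array([1.0, 2.0]))
        assert np.allclose(out, [1.0, 2.0])


class TestTransitions:
    def test_worked_example_threshold_and_single_transition(self):
        sig, threshold, diffs = detect_transitions(WORKED_PROFILE)
        assert np.allclose(diffs, [0, 0, 0, 3.40, 0, 0, 0.13, 0, 0], atol=1e-12)
        assert threshold == pytest.approx(0.92, abs=0.005)
        assert sig == [3]                      # between p4 and p5
        assert diffs[3] == pytest.approx(3.40)

    def test_flat_profile_has_no_transition(self):
        sig, _, _ = detect_transitions(np.full(10, 1.0))
        assert sig == []

    def test_uniform_nonzero_diffs_not_significant(self):
        sig, _, _ = detect_transitions(np.arange(10, dtype=float))
        assert sig == []


class TestClassification:
    def test_low_then_high_is_c_terminal(self):
        ds_type, bounds = classify_ds_type(WORKED_PROFILE, [3])
        assert ds_type == "C"
        assert bounds == (3, None)

    def test_mirror_profile_is_n_terminal(self):
        ds_type, bounds = classify_ds_type(WORKED_PROFILE[::-1].copy(), [6])
        assert ds_type == "N"
        assert bounds == (None, 6)

    def test_interior_high_region_is_middle(self):
        prof = np.array([1.0] * 3 + [5.0] * 4 + [1.0] * 3)
        sig, _, _ = detect_transitions(prof)
        ds_type, bounds = classify_ds_type(prof, sig)
        assert ds_type == "middle"
        assert bounds == (2, 6)

    def test_no_transition_is_none(self):
        assert classify_ds_type(np.full(8, 1.0), [])[0] == "none"


def _profile_with_sses(n=6):
    sses = [make_sse(i, [1, 0, 0], [0, 0, 6.0 * i],
                     first=10 * i, last=10 * i + 7) for i in range(n)]
    prof = ADProfile(entries=np.zeros(n), smoothed=np.zeros(n),
                     diffs=np.zeros(n - 1), annotations=[(i, i) for i in range(n)])
    return prof, sses


class TestOpeningPoints:
    def test_c_swap_uses_last_residue_of_nside_sse(self):
        prof, sses = _profile_with_sses()
        cands = initial_opening_point("C", prof, sses, sses, (2, None))
        assert len(cands) == 1
        assert cands[0].o_q == sses[2].last_pos
        assert cands[0].side == "C"

    def test_n_swap_uses_first_residue_of_cside_sse(self):
        prof, sses = _profile_with_sses()
        cands = initial_opening_point("N", prof, sses, sses, (None, 1))
        assert cands[0].o_q == sses[2].first_pos

    def test_middle_combines_both_rules(self):
        prof, sses = _profile_with_sses()
        cands = initial_opening_point("middle", prof, sses, sses, (1, 3))
        assert len(cands) == 2
        assert cands[0].o_q == sses[1].last_pos      # C-swap rule on the N side
        assert cands[1].o_q == sses[4].first_pos     # N-swap rule on the C side


class TestRefinement:
    def test_clean_boundary(self):
        mask = np.array([True] * 6 + [False] * 20)
        assert refine_opening_point(mask, 5, toward_peak=-1) == 5

    def test_all_aligned_rejected_as_over_extended(self):
        mask = np.ones(30, dtype=bool)
        assert refine_opening_point(mask, 20, toward_peak=-1) is None

    def test_short_unaligned_tail_rejected(self):
        mask = np.array([True] * 26 + [False] * 4)   # N_u never exceeds T_N=4
        assert refine_opening_point(mask, 25, toward_peak=-1) is None

    def test_pf_requires_six_consecutive_aligned(self):
        # interleaved aligned singletons must not satisfy the peak condition
        mask = np.array(([True] * 3 + [False]) * 5 + [True] * 8 + [False] * 10)
        o = len(mask) - 12
        got = refine_opening_point(mask, o, toward_peak=-1)
        assert got == 27          # end of the 8-long aligned run

    def test_isolated_unaligned_blip_tolerated(self):
        mask = np.array([True] * 10 + [False] + [True, True] + [False] * 10)
        assert refine_opening_point(mask, 9, toward_peak=-1) == 12


class TestValidation:
    def test_true_swapped_fragments_accepted(self, clean_pair):
        spec, closed, opened = clean_pair
        pivot = spec.hinge_positions()[-1]
        pairs = [(i, i) for i in range(pivot + 1)]
        main = Alignment(pairs, np.eye(3), np.zeros(3), 0.0)
        val = validate_hinge(closed, opened, pivot, pivot, "C", main)
        assert val.eta == 1
        assert val.swap_alignment.rmsd == pytest.approx(0.0, abs=1e-6)

    def test_mostly_aligned_fragment_screened_out(self, clean_pair):
        spec, closed, opened = clean_pair
        pivot = spec.hinge_positions()[-1]
        # pretend the whole chain aligned: the quick T_L screen must reject
        main = Alignment([(i, i) for i in range(len(closed))],
                         np.eye(3), np.zeros(3), 0.0)
        val = validate_hinge(closed, opened, pivot, pivot, "C", main)
        assert val.eta == 0
        assert "aligned" in val.reason

    def test_dissimilar_fragments_rejected(self, clean_pair):
        spec, closed, _ = clean_pair
        pivot = spec.hinge_positions()[-1]
        main = Alignment([(i, i) for i in range(pivot + 1)],
                         np.eye(3), np.zeros(3), 0.0)
        import copy
        stretched = copy.deepcopy(closed)
        for r in stretched.residues[pivot + 1:]:
            r.ca *= 1.8                      # not rigidly matchable
        stretched.ca = np.array([r.ca for r in stretched.residues])
        val = validate_hinge(closed, stretched, pivot, pivot, "C", main)
        assert val.eta == 0

    def test_tiny_fragment_rejected(self, clean_pair):
        spec, closed, opened = clean_pair
        n = len(closed)
        main = Alignment([(i, i) for i in range(n - 2)], np.eye(3), np.zeros(3), 0.0)
        val = validate_hinge(closed, opened, n - 3, n - 3, "C", main)
        assert val.eta == 0
        assert "3 residues" in val.reason


class TestHingeRange:
    def _info(self, diffs, dist=5.0):
        return {pos: (dist, tor) for pos, tor in diffs.items()}

    def test_extension_stops_after_two_consecutive_below_cutoff(self):
        # a single below-cutoff pair (46) is included; the pair 52/53 both
        # below the cutoff stops the right extension, excluding 52; the long
        # unaligned stretch before 46 never extends the hinge
        diffs = {46: 10.0, 47: 40.0, 48: 40.0, 49: 40.0,
                 50: 40.0, 51: 40.0, 52: 10.0, 53: 10.0}
        rng = determine_hinge_range(49, "C", self._info(diffs), 100, (50, 95), 1)
        assert rng == (46, 51)

    def test_no_extension_collapses_to_minimal_region(self):
        diffs = {i: 5.0 for i in range(40, 60)}
        rng = determine_hinge_range(49, "C", self._info(diffs), 100, (50, 95), 1)
        assert rng == (49, 50)

    def test_close_ca_pairs_stop_extension(self):
        diffs = {i: 60.0 for i in range(30, 70)}
        info = {pos: (1.0, tor) for pos, tor in diffs.items()}  # all within 2.6 Å
        rng = determine_hinge_range(49, "C", info, 100, (50, 95), 1)
        # each direction stops once three included aligned pairs are close
        assert rng[1] - rng[0] + 1 <= 6

    def test_swapped_domain_floor_limits_extension(self):
        diffs = {i: 60.0 for i in range(30, 70)}
        rng = determine_hinge_range(49, "C", self._info(diffs), 100, (50, 62), 1)
        assert rng[1] <= 52      # 62 - 10

    def test_middle_cutoff_doubling_gives_subset(self):
        diffs = {i: 30.0 for i in range(44, 56)}  # between 25° and 50°
        info = self._info(diffs)
        single = determine_hinge_range(49, "C", info, 100, (50, 95), 1)
        double = determine_hinge_range(49, "C", info, 100, (50, 95), 2)
        assert single[0] <= double[0] and double[1] <= single[1]

    def test_undefined_torsion_stops_that_end(self):
        diffs = {46: 60.0, 47: 60.0, 48: 60.0, 49: 60.0, 50: 60.0, 51: 60.0}
        info = self._info(diffs)
        info[47] = (5.0, None)
        rng = determine_hinge_range(49, "C", info, 100, (50, 95), 1)
        assert rng[0] >= 48


class TestSmallSwappedDomain:
    def _chain(self, seed=0):
        spec = FixtureSpec(seed=seed)
        return spec, make_closed_form(spec)

    def test_unaligned_n_tail_becomes_candidate(self):
        spec, chain = self._chain()
        from adswap.structure_io import extract_sses
        sses = extract_sses(chain)
        tail_end = sses[0].last_pos          # leave the first SSE unaligned
        pairs = [(i, i) for i in range(tail_end + 1, len(chain))]
        main = Alignment(pairs, np.eye(3), np.zeros(3), 0.5)
        prof = ADProfile(np.zeros(len(sses)), np.zeros(len(sses)),
                         np.zeros(len(sses) - 1), [(i, i) for i in range(len(sses))])
        cands = assign_small_swapped_domain(prof, main, chain, chain, sses, sses)
        assert cands and cands[0].ds_type == "N"
        assert cands[0].o_q == sses[1].first_pos

    def test_fully_aligned_homolog_yields_no_candidate(self):
        spec, chain = self._chain()
        from adswap.structure_io import extract_sses
        sses = extract_sses(chain)
        main = Alignment([(i, i) for i in range(len(chain))],
                         np.eye(3), np.zeros(3), 0.2)
        prof = ADProfile(np.zeros(len(sses)), np.zeros(len(sses)),
                         np.zeros(len(sses) - 1), [(i, i) for i in range(len(sses))])
        assert assign_small_swapped_domain(prof, main, chain, chain, sses, sses) == []

    def test_interior_gap_becomes_middle_candidate(self):
        spec, chain = self._chain()
        from adswap.structure_io import extract_sses
        sses = extract_sses(chain)
        gap = range(30, 38)
        pairs = [(i, i) for i in range(len(chain)) if i not in gap]
        main = Alignment(pairs, np.eye(3), np.zeros(3), 0.5)
        prof = ADProfile(np.zeros(len(sses)), np.zeros(len(sses)),
                         np.zeros(len(sses) - 1), [(i, i) for i in range(len(sses))])
        cands = assign_small_swapped_domain(prof, main, chain, chain, sses, sses)
        assert len(cands) == 2
        assert cands[0].ds_type == "middle"
        assert cands[0].o_q == 29 and cands[1].o_q == 38


class TestEndToEndWorkedExample:
    def test_transition_localizes_hinge_between_flanking_sses(self):
        sig, threshold, _ = detect_transitions(WORKED_PROFILE)
        assert threshold == pytest.approx(0.92, abs=0.005)
        ds_type, bounds = classify_ds_type(WORKED_PROFILE, sig)
        assert ds_type == "C"
        prof, sses = _profile_with_sses(10)
        cands = initial_opening_point(ds_type, prof, sses, sses, bounds)
        # hinge between the SSE pairs constituting p4 and p5
        assert cands[0].o_q == sses[3].last_pos

    def test_small_rotation_blurs_the_boundary_less_than_three_residues(self):
        spec = FixtureSpec(seed=13, noise_sigma=0.2)
        closed = make_closed_form(spec)
        opened = make_open_form(closed, spec)
        rep = compare_pair(closed, opened)
        assert rep.eta == 1
        pivot_seq = spec.hinge_positions()[-1] + 1
        for h in rep.hinges:
            assert abs(h.opening_point_refined - pivot_seq) <= 3
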