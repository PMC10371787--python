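"""Solver stages: propagation, boundaries, overlap repair, full round trips."""

import pytest

from revnano.contactmap import hamming
from revnano.errors import OverlapError, Stage2Error
from revnano.seqio import Section, VirtualStaple, make_design, split_virtual
from revnano.solver import (
    E2_THRESHOLD,
    ClaimState,
    SolverParams,
    stage1_propagate,
    stage2_check,
    stage3_fix_overlaps,
    solve,
    solve_naive,
)
from revnano.srt import SolverMode, build_srt
from revnano.synthgen import RasterSpec, add_noise, forward_design


def _claims(scaffold_seq: str, staples: list[str], params: SolverParams) -> ClaimState:
    design = make_design(scaffold_seq, staples)
    virtuals = split_virtual(design)
    srts = [build_srt(v, design.scaffold, params.mu_min, params.sigma) for v in virtuals]
    return ClaimState(design, virtuals, srts, params)


def vstub(parent_id: int) -> VirtualStaple:
    return VirtualStaple(parent_id, 0, "ACGT", 0)


class TestBetaBoundary:
    def test_claimed_fraction_exactly_beta_blocks_a_section(self):
        params = SolverParams(mu_min=4, sigma=0, beta=0.5)
        claims = _claims("AAAACCCCGGGGTTTT", ["TTTT"], params)
        sec = Section(start=3, mu=4, staple_offset=0)  # bases {3,2,1,0}
        claims.claimed_by[3].add(99)
        claims.claimed_by[2].add(99)
        assert claims._section_blocked(sec, 0)  # 2/4 == beta -> unavailable

    def test_claimed_fraction_below_beta_keeps_section(self):
        params = SolverParams(mu_min=4, sigma=0, beta=0.5)
        claims = _claims("AAAACCCCGGGGTTTT", ["TTTT"], params)
        sec = Section(start=3, mu=4, staple_offset=0)
        claims.claimed_by[3].add(99)
        assert not claims._section_blocked(sec, 0)  # 1/4 < beta

    def test_own_claims_do_not_block(self):
        params = SolverParams(mu_min=4, sigma=0, beta=0.25)
        claims = _claims("AAAACCCCGGGGTTTT", ["TTTT"], params)
        sec = Section(start=3, mu=4, staple_offset=0)
        for b in (3, 2, 1, 0):
            claims.claimed_by[b].add(0)  # the staple's own footprint
        assert not claims._section_blocked(sec, 0)


class TestE2Boundary:
    class Stub:
        def __init__(self, frac):
            self._frac = frac

        def placed_fraction(self):
            return self._frac

    def test_exactly_the_threshold_proceeds(self):
        stage2_check(self.Stub(E2_THRESHOLD))  # must not raise

    def test_below_the_threshold_raises(self):
        with pytest.raises(Stage2Error):
            stage2_check(self.Stub(E2_THRESHOLD - 1e-9))

    def test_pipeline_raises_e2_when_no_staple_matches(self):
        design = forward_design(RasterSpec(seed=0))[0]
        bad = make_design(design.scaffold.sequence, ["G" * 32, "G" * 32])
        with pytest.raises(Stage2Error):
            solve(bad)


class TestStage3Overlaps:
    def test_three_staple_overlap_raises_e4(self):
        routes = {i: (Section(start=5, mu=4, staple_offset=0),) for i in range(3)}
        with pytest.raises(OverlapError):
            stage3_fix_overlaps(routes, [vstub(i) for i in range(3)], 20, False)

    def test_three_prime_terminus_preferred_for_trimming(self):
        # A's staple-3' end (scaffold base 5) intrudes into B's 5' start
        routes = {
            0: (Section(start=10, mu=6, staple_offset=0),),  # bases 10..5
            1: (Section(start=5, mu=5, staple_offset=0),),  # bases 5..1
        }
        fixed = stage3_fix_overlaps(routes, [vstub(0), vstub(1)], 20, False)
        assert fixed[0] == (Section(10, 5, 0),)  # 3' base trimmed off A
        assert fixed[1] == (Section(5, 5, 0),)  # B untouched

    def test_five_prime_fallback_shifts_start_and_offset(self):
        # shared bases sit at A's 5' head only: B wholly contains its 3' run
        routes = {
            0: (Section(start=10, mu=4, staple_offset=0),),  # bases 10..7
            1: (Section(start=12, mu=3, staple_offset=0),),  # bases 12..10
        }
        fixed = stage3_fix_overlaps(routes, [vstub(0), vstub(1)], 20, False)
        # B's 3' terminus (base 10) is the preferred trim
        assert fixed[1] == (Section(12, 2, 0),)
        assert fixed[0] == (Section(10, 4, 0),)

    def test_interior_overlap_without_terminus_resolution_raises_e4(self):
        routes = {
            0: (Section(start=10, mu=6, staple_offset=0),),  # bases 10..5
            1: (Section(start=7, mu=1, staple_offset=0),),  # base 7, interior of A
        }
        with pytest.raises(OverlapError):
            stage3_fix_overlaps(routes, [vstub(0), vstub(1)], 20, False)

    def test_disjoint_routes_pass_through(self):
        routes = {
            0: (Section(start=5, mu=4, staple_offset=0),),
            1: (Section(start=15, mu=4, staple_offset=0),),
        }
        assert stage3_fix_overlaps(routes, [vstub(0), vstub(1)], 20, False) == routes


class TestStage1:
    def test_footprints_only_grow(self, decoy_fixture):
        design, _, _, _ = decoy_fixture
        params = SolverParams()
        virtuals = split_virtual(design)
        srts = [build_srt(v, design.scaffold, params.mu_min, params.sigma)
                for v in virtuals]
        claims = ClaimState(design, virtuals, srts, params)
        before = [st.footprint for st in claims.states]
        stage1_propagate(claims)  # raises RuntimeError if any footprint shrank
        for old, st in zip(before, claims.states):
            assert st.unplaceable or st.footprint >= old


class TestRoundTrip:
    def test_engineered_fixture_recovers_exactly(self, raster):
        design, gt = raster
        cm, report = solve(design)
        assert hamming(gt, cm) == 0
        assert report.sp_percent == 100.0

    def test_three_section_fixture_recovers_exactly(self, raster_three_section):
        design, gt = raster_three_section
        cm, report = solve(design)
        assert hamming(gt, cm) == 0 and report.sp_percent == 100.0

    def test_linear_scaffold_recovers_exactly(self, raster_linear):
        design, gt = raster_linear
        cm, report = solve(design)
        assert hamming(gt, cm) == 0 and report.sp_percent == 100.0

    def test_rna_scaffold_recovers_exactly(self):
        design, gt = forward_design(RasterSpec(seed=4, material="RNA"))
        cm, report = solve(design)
        assert hamming(gt, cm) == 0 and report.sp_percent == 100.0

    def test_deterministic_repeatability(self, decoy_fixture):
        design, _, _, _ = decoy_fixture
        cm1, _ = solve(design)
        cm2, _ = solve(design)
        assert cm1 == cm2

    def test_nondeterministic_mode_still_recovers_engineered_fixture(self, raster):
        design, gt = raster
        params = SolverParams(mode=SolverMode.NONDETERMINISTIC, seed=7)
        cm, _ = solve(design, params)
        assert hamming(gt, cm) == 0

    def test_contaminant_staples_are_omitted_not_fatal(self, raster):
        design, gt = raster
        noisy = add_noise(design, n_contaminants=2, seed=3)
        cm, report = solve(noisy)
        assert hamming(gt, cm) == 0
        assert len(report.omitted_parents) == 2
        assert report.sp_percent == pytest.approx(100.0 * 8 / 10)

    def test_empty_staple_list_is_sp100_by_convention(self):
        design = make_design("ACGT" * 16, [])
        cm, report = solve(design)
        assert report.sp_percent == 100.0 and cm.paired_fraction() == 0.0


class TestNaive:
    def test_matches_solver_on_repeat_free_fixture(self, raster):
        design, _ = raster
        cm_solver, _ = solve(design)
        cm_naive, _ = solve_naive(design)
        assert cm_solver == cm_naive

    def test_misroutes_on_decoy_but_solver_recovers(self, decoy_fixture):
        design, gt, _, _ = decoy_fixture
        cm_naive, _ = solve_naive(design)
        cm_solver, _ = solve(design)
        assert hamming(gt, cm_solver) == 0
        assert hamming(gt, cm_naive) > 0

    def test_decoy_error_localised_to_the_lured_staple(self, decoy_fixture):
        design, gt, y, L = decoy_fixture
        cm_naive, _ = solve_naive(design)
        wrong = [
            i for i in range(gt.n)
            if (int(gt.staple_id[i]), int(gt.staple_base[i]))
            != (int(cm_naive.staple_id[i]), int(cm_naive.staple_base[i]))
        ]
        involved = {int(gt.staple_id[i]) for i in wrong} | {
            int(cm_naive.staple_id[i]) for i in wrong
        }
        assert involved <= {0, -1}  # only staple 0 (and unpaired) affected
        assert any(y <= i < y + L for i in wrong)  # the lure itself is misbound
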