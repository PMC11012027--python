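"""Slab profiles, four-region flow counting, area series, block errors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import permgrad as pg
from permgrad.analysis import _stats_from_blocks

from conftest import make_toy_trajectory


class TestBlockAverage:
    def test_constant_series_has_zero_stderr(self):
        stats = pg.block_average(np.full(100, 3.7), block_size=10.0, frame_interval=1.0)
        assert stats.mean == pytest.approx(3.7)
        assert stats.stderr == 0.0
        assert stats.n_blocks == 10

    def test_iid_normal_matches_clt(self):
        # 10 blocks of 100 i.i.d. N(0,1): stderr ≈ (1/√100)/√10 = 0.0316
        rng = np.random.default_rng(42)
        x = rng.standard_normal(1000)
        stats = pg.block_average(x, block_size=100.0, frame_interval=1.0)
        expected = 0.1 / np.sqrt(10)
        # stderr of the stderr estimate itself ~ expected/√(2·(n_blocks-1))
        assert stats.stderr == pytest.approx(expected, rel=3 / np.sqrt(2 * 9))

    def test_ar1_series_inflates_block_error_over_naive(self):
        # strongly autocorrelated series: naive SD/√N understates the error
        rng = np.random.default_rng(7)
        n, phi = 20_000, 0.995
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        stats = pg.block_average(x, block_size=1000.0, frame_interval=1.0)
        naive = x.std(ddof=1) / np.sqrt(n)
        assert stats.stderr > 2 * naive

    def test_trailing_partial_block_dropped(self):
        x = np.arange(25, dtype=float)
        stats = pg.block_average(x, block_size=10.0, frame_interval=1.0)
        assert stats.n_blocks == 2
        assert stats.mean == pytest.approx(np.mean([np.mean(x[:10]), np.mean(x[10:20])]))

    def test_fewer_than_two_blocks_is_an_error(self):
        with pytest.raises(ValueError, match="2 complete"):
            pg.block_average(np.arange(15.0), block_size=10.0, frame_interval=1.0)


class TestConcentrationProfile:
    def test_uniform_density_gives_closed_form_concentration(self):
        # N=500 uniform in 100x100x220 ų: c = 500/2.2e6 Å⁻³ = 377 mmol/L
        rng = np.random.default_rng(0)
        z = rng.uniform(-110, 110, size=(40, 500))
        traj = make_toy_trajectory(z)
        prof = pg.concentration_profile(traj, bin_width=1.0, block_size=10.0)
        expected = 500 / 2.2e6 * pg.units.PER_A3_TO_MMOL_PER_L
        assert expected == pytest.approx(377, rel=0.01)
        assert prof.mean_concentration.mean() == pytest.approx(expected, rel=1e-9)
        assert np.all(np.abs(prof.mean_concentration - expected) < 6 * expected / np.sqrt(500 * 40 / 220))

    def test_single_fixed_particle_occupies_one_slab(self):
        traj = make_toy_trajectory(np.full((4, 1), 5.3))
        prof = pg.concentration_profile(traj, bin_width=1.0, block_size=2.0)
        i = prof.bin_index(5.3)
        assert prof.bin_edges[i] == 5.0 and prof.bin_edges[i + 1] == 6.0
        assert prof.mean_concentration[i] == pytest.approx(166.054, abs=0.01)
        others = np.delete(prof.mean_concentration, i)
        assert np.all(others == 0.0)
        assert np.all(np.delete(prof.stderr, i) == 0.0)

    def test_counts_are_conserved_exactly(self):
        rng = np.random.default_rng(3)
        z = rng.uniform(-110, 110, size=(20, 37))
        traj = make_toy_trajectory(z)
        prof = pg.concentration_profile(traj, bin_width=1.0, block_size=5.0)
        widths = np.diff(prof.bin_edges)
        volumes = prof.mean_area * widths
        total = np.sum(prof.mean_concentration * volumes) / pg.units.PER_A3_TO_MMOL_PER_L
        assert total == pytest.approx(37, rel=1e-9)

    def test_nondividing_bin_width_truncates_last_slab(self):
        traj = make_toy_trajectory(np.zeros((4, 3)))
        prof = pg.concentration_profile(traj, bin_width=7.0, block_size=2.0)
        widths = np.diff(prof.bin_edges)
        assert widths[-1] == pytest.approx(220 - 7.0 * 31)
        assert prof.bin_edges[-1] == pytest.approx(110.0)

    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        traj = make_toy_trajectory(rng.uniform(-110, 110, size=(10, 20)))
        prof = pg.concentration_profile(traj, 1.0, 5.0)
        path = tmp_path / "prof.tsv"
        prof.to_tsv(path)
        back = pg.SlabProfile.from_tsv(path)
        assert np.array_equal(back.bin_edges, prof.bin_edges)
        assert np.array_equal(back.mean_concentration, prof.mean_concentration)
        assert np.array_equal(back.block_means, prof.block_means)


class TestCountFlow:
    """The four hand-crafted counting cases plus structural properties."""

    @pytest.mark.parametrize(
        "z0, z1, expected",
        [
            (-5.0, +5.0, +1),  # crossing along the normal
            (+5.0, -5.0, -1),  # crossing against the normal
            (-105.0, +105.0, 0),  # periodic wrap between the flanks
            (+5.0, +5.0, 0),  # staying put
        ],
        ids=["up_crossing", "down_crossing", "boundary_wrap", "no_move"],
    )
    def test_hand_crafted_cases(self, z0, z1, expected):
        traj = make_toy_trajectory([[z0], [z1]])
        flow = pg.count_flow(traj, boundary_z=0.0, region_half_width=40.0)
        assert flow.total == expected

    def test_multi_region_jump_contributes_zero_but_is_logged(self):
        traj = make_toy_trajectory([[-50.0], [+5.0]])  # I -> II
        flow = pg.count_flow(traj)
        assert flow.total == 0
        assert flow.n_skipped == 1

    def test_accumulated_is_cumsum_of_increments(self):
        rng = np.random.default_rng(1)
        z = rng.uniform(-110, 110, size=(50, 10))
        flow = pg.count_flow(make_toy_trajectory(z))
        assert np.array_equal(flow.accumulated, np.concatenate([[0], np.cumsum(flow.increments)]))
        assert np.all(np.abs(flow.increments) <= 10)

    def test_time_reversal_negates_flow_exactly(self):
        rng = np.random.default_rng(2)
        z = np.cumsum(rng.normal(0, 15, size=(200, 20)), axis=0)
        z = (z + 110) % 220 - 110
        traj = make_toy_trajectory(z)
        rev = make_toy_trajectory(z[::-1])
        fwd = pg.count_flow(traj)
        bwd = pg.count_flow(rev)
        assert bwd.total == -fwd.total
        assert np.array_equal(bwd.increments, -fwd.increments[::-1])

    def test_oversized_regions_rejected(self):
        traj = make_toy_trajectory([[0.0], [1.0]])
        with pytest.raises(ValueError, match="flank"):
            pg.count_flow(traj, boundary_z=0.0, region_half_width=110.0)
        with pytest.raises(ValueError, match="flank"):
            pg.count_flow(traj, boundary_z=80.0, region_half_width=40.0)

    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        z = rng.uniform(-110, 110, size=(30, 5))
        flow = pg.count_flow(make_toy_trajectory(z))
        path = tmp_path / "flow.tsv"
        flow.to_tsv(path)
        back = pg.FlowCount.from_tsv(path)
        assert np.array_equal(back.increments, flow.increments)
        assert back.boundary_z == flow.boundary_z


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_flow_antisymmetry_for_random_walks(seed):
    """Reversing any trajectory in time negates the accumulated flow."""
    rng = np.random.default_rng(seed)
    z = np.cumsum(rng.normal(0, 20, size=(30, 5)), axis=0)
    z = (z + 110) % 220 - 110
    fwd = pg.count_flow(make_toy_trajectory(z))
    bwd = pg.count_flow(make_toy_trajectory(z[::-1]))
    assert bwd.total == -fwd.total


class TestAreaSeries:
    def test_constant_box(self):
        traj = make_toy_trajectory(np.zeros((10, 2)))
        stats = pg.area_series(traj, block_size=5.0)
        assert stats.mean == 10_000.0
        assert stats.stderr == 0.0

    def test_alternating_areas_average(self):
        z = np.zeros((20, 1))
        traj = make_toy_trajectory(z)
        side = np.where(np.arange(20) % 2 == 0, np.sqrt(9400.0), np.sqrt(9468.0))
        traj.box_xy[:, 0] = side
        traj.box_xy[:, 1] = side
        stats = pg.area_series(traj, block_size=10.0)
        assert stats.mean == pytest.approx(9434.0)

    def test_missing_box_record_names_frame(self):
        traj = make_toy_trajectory(np.zeros((6, 1)))
        traj.box_xy[3, 0] = np.nan
        with pytest.raises(ValueError, match="frame 3"):
            pg.area_series(traj, block_size=2.0)


class TestDeltaC:
    def test_symmetric_profile_gives_zero(self):
        z = np.concatenate([np.full((8, 5), 30.5), np.full((8, 5), -29.5)], axis=1)
        prof = pg.concentration_profile(make_toy_trajectory(z), 1.0, 4.0)
        dc = pg.delta_c(prof, 30.0, -30.0)
        assert dc.value == 0.0

    def test_uses_containing_slab_not_interpolation(self):
        z = np.full((8, 3), 30.9)  # in slab [30, 31)
        prof = pg.concentration_profile(make_toy_trajectory(z), 1.0, 4.0)
        dc = pg.delta_c(prof, 30.0, -30.0)
        assert dc.value == pytest.approx(3 * 166.054, rel=1e-4)

    def test_stderr_combines_in_quadrature(self):
        rng = np.random.default_rng(9)
        traj = make_toy_trajectory(rng.uniform(-110, 110, size=(40, 100)))
        prof = pg.concentration_profile(traj, 1.0, 10.0)
        dc = pg.delta_c(prof, 30.0, -30.0)
        _, sp = prof.concentration_at(30.0)
        _, sm = prof.concentration_at(-30.0)
        assert dc.stderr == pytest.approx(np.hypot(sp, sm))

    def test_position_outside_profile_rejected(self):
        prof = pg.concentration_profile(make_toy_trajectory(np.zeros((4, 1))), 1.0, 2.0)
        with pytest.raises(ValueError, match="outside"):
            pg.delta_c(prof, 150.0, -30.0)


def test_stats_from_blocks_needs_two():
    with pytest.raises(ValueError):
        _stats_from_blocks(np.array([1.0]), 10.0)
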