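"""Depth-search planning, rough z-alignment, and the global 3D solve."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import dense_solve, gauge_removed_position_errors, make_tile, synth_matches
from icat.errors import ConnectivityError, RegistrationError
from icat.montage import solve_montage
from icat.solver import SolverOptions, solve_tile_transforms
from icat.synthetic import simulate_serial_stack
from icat.tiles import nominal_transform
from icat.transforms import AffineTransform2D
from icat.volume import (
    align_serial_stack,
    build_depth_plan,
    cross_section_matches,
    export_stack,
    minimal_connecting_depth,
    rough_align_z,
    solve_volume,
)


class TestBuildDepthPlan:
    def test_gap_bridged_only_at_depth_three(self):
        present = [8, 11]
        plan2 = build_depth_plan(present, 2)
        assert plan2.pairs == [] and not plan2.connected
        plan3 = build_depth_plan(present, 3)
        assert plan3.pairs == [(8, 11)] and plan3.connected

    def test_contiguous_chain_at_depth_one(self):
        plan = build_depth_plan(list(range(5)), 1)
        assert plan.pairs == [(0, 1), (1, 2), (2, 3), (3, 4)]
        assert plan.connected

    @settings(max_examples=50, derandomize=True)
    @given(st.sets(st.integers(0, 30), min_size=2, max_size=10))
    def test_full_depth_gives_complete_graph(self, zs):
        present = sorted(zs)
        span = present[-1] - present[0]
        plan = build_depth_plan(present, span)
        n = len(present)
        assert len(plan.pairs) == n * (n - 1) // 2  # combinatorial oracle
        assert plan.connected

    def test_minimal_connecting_depth_is_largest_jump(self):
        assert minimal_connecting_depth([0, 1, 2, 4, 8]) == 4
        assert minimal_connecting_depth([8, 11]) == 3
        assert minimal_connecting_depth([5]) == 1


class TestRoughAlignZ:
    def test_recovers_cumulative_drift(self):
        sections, truth = simulate_serial_stack(
            6, drift_step=(5.0, 3.0), size=192, seed=11
        )
        rough = rough_align_z(sections, downsample_factor=1)
        for z in sections:
            expected = np.array(truth.section_drift[z])
            assert np.abs(rough[z].translation - expected).max() < 1.0

    def test_single_section_identity(self):
        sections, _ = simulate_serial_stack(1, size=192, seed=1)
        rough = rough_align_z(sections, downsample_factor=1)
        assert rough[0].almost_equals(AffineTransform2D.identity())

    def test_blank_section_error_names_pair(self):
        sections, _ = simulate_serial_stack(3, size=192, seed=2)
        sections[1] = np.zeros_like(sections[1])
        with pytest.raises(RegistrationError, match="z=0 and z=1"):
            rough_align_z(sections, downsample_factor=1)


class TestCrossSectionMatches:
    def test_duplicate_sections_match_at_zero_displacement(self):
        sections, _ = simulate_serial_stack(1, size=256, seed=5)
        img = sections[0]
        tiles = {
            0: [make_tile("z0", size=256)],
            1: [make_tile("z1", size=256, z=1)],
        }
        tiles[0][0].image = img
        tiles[1][0].image = img.copy()
        plan = build_depth_plan([0, 1], 1)
        rough = {0: AffineTransform2D.identity(), 1: AffineTransform2D.identity()}
        out = cross_section_matches(tiles, plan, rough)
        assert len(out) == 1
        disp = out[0].points_b - out[0].points_a
        assert np.median(np.hypot(*disp.T)) < 1.0

    def test_drifted_stack_matches_agree_with_truth(self):
        sections, truth = simulate_serial_stack(3, drift_sigma=6, size=256, seed=8)
        tiles = {}
        rough = {}
        for z, img in sections.items():
            t = make_tile(f"z{z}", size=256, z=z)
            t.image = img
            tiles[z] = [t]
            rough[z] = AffineTransform2D.from_translation(*truth.section_drift[z])
        plan = build_depth_plan(sorted(sections), 2)
        out = cross_section_matches(tiles, plan, rough)
        assert out, "expected inter-section matches"
        ok = total = 0
        for m in out:
            za = int(m.tile_id_a[1:])
            zb = int(m.tile_id_b[1:])
            # truth: point p in section za corresponds to p + d_za - d_zb in zb
            shift = np.array(truth.section_drift[za]) - np.array(truth.section_drift[zb])
            err = np.hypot(*(m.points_b - (m.points_a + shift)).T)
            ok += (err < 2.0).sum()
            total += len(err)
        assert ok / total >= 0.9

    def test_unrelated_sections_produce_no_sets(self):
        a, _ = simulate_serial_stack(1, size=256, seed=21)
        b, _ = simulate_serial_stack(1, size=256, seed=99)
        tiles = {0: [make_tile("z0", size=256)], 1: [make_tile("z1", size=256, z=1)]}
        tiles[0][0].image = a[0]
        tiles[1][0].image = b[0]
        plan = build_depth_plan([0, 1], 1)
        rough = {0: AffineTransform2D.identity(), 1: AffineTransform2D.identity()}
        out = cross_section_matches(tiles, plan, rough)
        assert sum(len(m) for m in out) < 5


class TestSolveVolume:
    def _stack(self, rng, n_sections=3, grid=2, drift=6.0, jitter=4.0):
        tiles, truth = [], {}
        for z in range(n_sections):
            dz = rng.normal(0, drift, 2) if z else np.zeros(2)
            dz = np.cumsum([dz], axis=0)[0]
            for r in range(grid):
                for c in range(grid):
                    tid = f"z{z}_r{r}c{c}"
                    nominal = np.array([20 + c * 85.0, 20 + r * 85.0])
                    truth[tid] = AffineTransform2D.from_translation(
                        *(nominal + rng.uniform(-jitter, jitter, 2) + dz)
                    )
                    tiles.append(
                        make_tile(
                            tid, size=96, z=z,
                            stage_xy=tuple((nominal + 47.5) * 5.0 / 1000.0),
                            transform=AffineTransform2D.from_translation(*nominal),
                        )
                    )
        tilemap = {t.tile_id: t for t in tiles}
        intra, inter = [], []
        for z in range(n_sections):
            ids = [f"z{z}_r{r}c{c}" for r in range(grid) for c in range(grid)]
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    intra.append(
                        synth_matches(tilemap[ids[i]], tilemap[ids[j]],
                                      truth[ids[i]], truth[ids[j]], n=12,
                                      noise=0.3, rng=rng)
                    )
            if z:
                for r in range(grid):
                    for c in range(grid):
                        a, b = f"z{z-1}_r{r}c{c}", f"z{z}_r{r}c{c}"
                        inter.append(
                            synth_matches(tilemap[a], tilemap[b], truth[a],
                                          truth[b], n=12, noise=0.3, rng=rng)
                        )
        return tiles, truth, intra, inter

    def test_empty_inter_reduces_to_montage(self, rng):
        tiles, truth, intra, _ = self._stack(rng, n_sections=1)
        opts = SolverOptions(lam=0.01, model="translation")
        vol = solve_volume(tiles, intra=intra, inter=[], opts=opts)
        mon = solve_montage(tiles, intra, SolverOptions(lam=0.01, model="translation"))
        # same system up to init: solve_volume uses tile transforms as init,
        # solve_montage uses stage transforms; feed identical init
        init = {t.tile_id: nominal_transform(t) for t in tiles}
        vol2 = solve_volume(tiles, intra=intra, inter=[],
                            opts=SolverOptions(lam=0.01, model="translation"), init=init)
        for tid in truth:
            assert np.abs(
                np.array(vol2.transforms[tid].to_params())
                - np.array(mon.transforms[tid].to_params())
            ).max() < 1e-8

    def test_matches_dense_oracle_small_stack(self, rng):
        tiles, truth, intra, inter = self._stack(rng, n_sections=3, grid=2)
        opts = SolverOptions(lam=0.01, model="affine")
        res = solve_volume(tiles, intra=intra, inter=inter, opts=opts,
                           inter_weight=0.5)
        weighted = intra + [m.scaled(0.5) for m in inter]
        init = {t.tile_id: t.transform for t in tiles}
        anchor = min(t.tile_id for t in tiles if t.section_index == 0)
        oracle = dense_solve(tiles, weighted, init, lam=0.01, model="affine",
                             anchor=anchor)
        for tid in truth:
            assert np.abs(
                np.array(res.transforms[tid].to_params())
                - np.array(oracle[tid].to_params())
            ).max() < 1e-8

    def test_disconnected_sections_error_advises_depth(self, rng):
        tiles, truth, intra, inter = self._stack(rng, n_sections=3)
        # drop every inter match touching section 2
        inter_kept = [m for m in inter if "z2" not in (m.tile_id_a[:2], m.tile_id_b[:2])]
        with pytest.raises(ConnectivityError, match="depth"):
            solve_volume(tiles, intra=intra, inter=inter_kept,
                         opts=SolverOptions(model="translation"))

    def test_section_relabeling_preserves_geometry(self, rng):
        tiles, truth, intra, inter = self._stack(rng, n_sections=3)
        res = solve_volume(tiles, intra=intra, inter=inter,
                           opts=SolverOptions(lam=0.01, model="translation"))
        shifted_tiles = [
            make_tile(t.tile_id, size=96, z=t.section_index + 10,
                      stage_xy=t.stage_xy, transform=t.transform)
            for t in tiles
        ]
        res2 = solve_volume(shifted_tiles, intra=intra, inter=inter,
                            opts=SolverOptions(lam=0.01, model="translation"))
        for tid in truth:
            assert np.allclose(
                res.transforms[tid].to_params(), res2.transforms[tid].to_params(),
                atol=1e-10,
            )

    def test_nine_section_drift_recovery(self):
        rng = np.random.default_rng(1234)
        tiles, truth, intra, inter = self._stack(
            rng, n_sections=9, grid=2, drift=10.0, jitter=4.0
        )
        res = solve_volume(tiles, intra=intra, inter=inter,
                          opts=SolverOptions(lam=0.005, model="translation"))
        errs = gauge_removed_position_errors(res.transforms, truth, tiles)
        assert np.median(np.hypot(*errs.T)) < 1.0


class TestAlignSerialStack:
    def test_gap_alignment_needs_depth_three(self):
        sections, truth = simulate_serial_stack(
            12, missing={9, 10}, size=160, drift_sigma=4, seed=3
        )
        with pytest.raises(ConnectivityError):
            align_serial_stack(sections, depth=2)
        transforms, plan, result = align_serial_stack(sections, depth=3)
        assert plan.connected
        for z in sections:
            expected = np.array(truth.section_drift[z])
            assert np.abs(transforms[z].translation - expected).max() < 1.0

    def test_auto_depth_raises_to_minimal(self):
        sections, _ = simulate_serial_stack(
            12, missing={9, 10}, size=160, drift_sigma=4, seed=3
        )
        transforms, plan, _ = align_serial_stack(sections, depth=2, auto_depth=True)
        assert plan.depth == 3
        assert len(transforms) == 10


class TestExportStack:
    def test_plane_count_matches_present_sections(self, tmp_path):
        sections, _ = simulate_serial_stack(5, missing={2}, size=192, seed=4)
        transforms = {z: AffineTransform2D.from_translation(z, 0) for z in sections}
        out = export_stack(sections, transforms, path=str(tmp_path / "v.tif"))
        assert out.shape[0] == 4
        import tifffile

        assert tifffile.imread(tmp_path / "v.tif").shape[0] == 4
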