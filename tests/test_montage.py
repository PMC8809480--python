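"""Acquisition geometry, SIFT features, matching, and the montage solver."""

import numpy as np
import pytest

from conftest import dense_solve, gauge_removed_position_errors, make_tile, synth_matches
from icat.errors import ConnectivityError
from icat.montage import (
    candidate_neighbors,
    em_field_width,
    extract_features,
    match_features,
    plan_acquisition_grid,
    solve_montage,
)
from icat.solver import SolverOptions, solve_tile_transforms
from icat.synthetic import make_tissue_texture, simulate_tileset
from icat.tiles import nominal_transform
from icat.transforms import AffineTransform2D


class TestEmFieldWidth:
    def test_twenty_percent_overlap_leaves_sixty_percent(self):
        assert em_field_width(1.0, 0.20) == pytest.approx(0.6)

    def test_no_overlap_limit(self):
        assert em_field_width(100.0, 0.0) == 100.0

    def test_paper_scale_field(self):
        # 233.3 μm FM field with 20% overlap -> ~140 μm EM field
        assert em_field_width(233.3, 0.2) == pytest.approx(139.98)

    def test_half_overlap_leaves_nothing(self):
        with pytest.raises(ValueError, match="no EM field remains"):
            em_field_width(100.0, 0.5)


class TestPlanAcquisitionGrid:
    def test_two_by_two_grid(self):
        pos = plan_acquisition_grid((0, 0, 100, 100), w_fm=100, o_fm=0.2)
        assert len(pos) == 4  # pitch 80 -> ceil(100/80)=2 per axis
        xs = sorted({p[0] for p in pos})
        assert xs[1] - xs[0] == pytest.approx(80.0)

    def test_small_box_single_center_position(self):
        pos = plan_acquisition_grid((10, 20, 40, 45), w_fm=100, o_fm=0.2)
        assert pos == [(25.0, 32.5)]

    def test_serpentine_order(self):
        pos = plan_acquisition_grid((0, 0, 200, 200), w_fm=100, o_fm=0.2)
        row0 = [p for p in pos[:3]]
        row1 = [p for p in pos[3:6]]
        assert [p[0] for p in row1] == sorted([p[0] for p in row0], reverse=True)

    def test_fm_coverage_and_em_gaps(self):
        box = (0.0, 0.0, 300.0, 220.0)
        w_fm, o_fm = 100.0, 0.2
        pos = plan_acquisition_grid(box, w_fm, o_fm)
        w_em = em_field_width(w_fm, o_fm)
        xs = np.linspace(box[0] + 0.5, box[2] - 0.5, 40)
        ys = np.linspace(box[1] + 0.5, box[3] - 0.5, 40)
        for x in xs:
            for y in ys:
                fm_hits = sum(
                    abs(x - px) <= w_fm / 2 and abs(y - py) <= w_fm / 2 for px, py in pos
                )
                assert fm_hits >= 1  # FM fields cover the whole box
                em_hits = sum(
                    abs(x - px) < w_em / 2 and abs(y - py) < w_em / 2 for px, py in pos
                )
                assert em_hits <= 1  # EM fields never double-expose


class TestExtractFeatures:
    def test_textured_tile_yields_keypoints(self):
        tex, _ = make_tissue_texture(1, size=256)
        feats = extract_features(tex)
        assert len(feats) >= 50
        assert feats.descriptors.shape[0] == len(feats)

    def test_constant_image_empty(self):
        assert len(extract_features(np.full((128, 128), 7, np.uint8))) == 0

    def test_shifted_image_matches_displace_by_shift(self):
        tex, _ = make_tissue_texture(2, size=256)
        shifted = np.roll(tex, 10, axis=1)
        fa = extract_features(tex[:, :200])
        fb = extract_features(shifted[:, :200])
        m = match_features(fa, fb)
        disp = m.points_b - m.points_a
        good = np.abs(disp - [10, 0]).max(axis=1) <= 0.5
        assert good.mean() >= 0.8


class TestCandidateNeighbors:
    def test_two_by_two_grid_rook_and_diagonal(self):
        tiles = []
        for r in range(2):
            for c in range(2):
                # 64 px at 5 nm = 0.32 um field; 10% overlap pitch
                tiles.append(
                    make_tile(f"r{r}c{c}", size=64, stage_xy=(c * 0.29, r * 0.29))
                )
        pairs = candidate_neighbors(tiles)
        assert len(pairs) == 6  # 4 rook + 2 diagonal

    def test_single_tile_no_pairs(self):
        assert candidate_neighbors([make_tile("only")]) == []

    def test_distant_tiles_no_pairs(self):
        a = make_tile("a", stage_xy=(0, 0))
        b = make_tile("b", stage_xy=(100, 100))
        assert candidate_neighbors([a, b]) == []


class TestMatchFeatures:
    def test_self_match_zero_displacement(self):
        tex, _ = make_tissue_texture(3, size=256)
        f = extract_features(tex)
        m = match_features(f, f)
        assert len(m) > 10
        assert np.median(np.hypot(*(m.points_b - m.points_a).T)) < 0.5

    def test_neighbor_offset_recovered(self):
        tex, _ = make_tissue_texture(4, size=640)
        tiles, truth = simulate_tileset(tex, 1, 2, 320, overlap=0.125, jitter=2, seed=9)
        fa = extract_features(tiles[0].image)
        fb = extract_features(tiles[1].image)
        m = match_features(fa, fb)
        t0 = truth.tile_transforms[tiles[0].tile_id].translation
        t1 = truth.tile_transforms[tiles[1].tile_id].translation
        disp_true = t0 - t1
        disp = np.median(m.points_b - m.points_a, axis=0)
        assert np.abs(disp - disp_true).max() < 0.5

    def test_unrelated_textures_give_few_inliers(self):
        a, _ = make_tissue_texture(10, size=256)
        b, _ = make_tissue_texture(77, size=256)
        m = match_features(extract_features(a), extract_features(b))
        assert len(m) < 5


class TestSolveMontage:
    def test_two_tiles_exact_offset(self):
        a = make_tile("a", size=256, stage_xy=(0.0, 0.0))
        b = make_tile("b", size=256, stage_xy=(1.12, 0.0))  # 224 world px
        ta = AffineTransform2D.from_translation(0, 0)
        tb = AffineTransform2D.from_translation(225.5, 0.0)  # truth, off-nominal
        m = synth_matches(a, b, ta, tb, n=10)
        res = solve_montage([a, b], [m], SolverOptions(lam=0.0, model="translation"))
        rel = res.transforms["b"].translation - res.transforms["a"].translation
        assert np.abs(rel - [225.5, 0.0]).max() < 1e-6
        assert res.rms < 1e-9

    def test_single_tile_returns_anchor_unchanged(self):
        t = make_tile("only", stage_xy=(2.0, 3.0))
        res = solve_montage([t], [], SolverOptions())
        assert res.transforms["only"].almost_equals(nominal_transform(t))

    def test_disconnected_graph_lists_components(self):
        tiles = [make_tile("a"), make_tile("b", stage_xy=(0.29, 0)),
                 make_tile("c", stage_xy=(10, 10))]
        m = synth_matches(tiles[0], tiles[1], AffineTransform2D(), AffineTransform2D())
        with pytest.raises(ConnectivityError, match="c"):
            solve_montage(tiles, [m], SolverOptions())

    def test_three_by_three_jitter_recovery(self):
        rng = np.random.default_rng(1234)
        tiles, truth = [], {}
        pitch_px = 448.0
        for r in range(3):
            for c in range(3):
                tid = f"r{r}c{c}"
                nominal = np.array([c * pitch_px, r * pitch_px])
                jit = rng.uniform(-20, 20, 2)
                stage_um = tuple((nominal + 255.5) * 5.0 / 1000.0)
                tiles.append(make_tile(tid, size=512, stage_xy=stage_um))
                truth[tid] = AffineTransform2D.from_translation(*(nominal + jit))
        matches = []
        ids = [t.tile_id for t in tiles]
        for i, a in enumerate(tiles):
            for b in tiles[i + 1:]:
                da = truth[a.tile_id].translation - truth[b.tile_id].translation
                if np.abs(da).max() < pitch_px * 1.2 and np.hypot(*da) < pitch_px * 1.3:
                    matches.append(
                        synth_matches(a, b, truth[a.tile_id], truth[b.tile_id],
                                      n=15, noise=0.3, rng=rng)
                    )
        res = solve_montage(tiles, matches, SolverOptions(lam=0.005, model="translation"))
        errs = gauge_removed_position_errors(res.transforms, truth, tiles)
        assert np.hypot(*errs.T).max() < 0.5
        assert res.rms <= 0.5

    def test_gauge_invariance_under_stage_shift(self):
        rng = np.random.default_rng(5)
        tiles = [make_tile("a", size=128), make_tile("b", size=128, stage_xy=(0.56, 0.0))]
        truth = {
            "a": AffineTransform2D.from_translation(0, 0),
            "b": AffineTransform2D.from_translation(113.0, 1.0),
        }
        m = synth_matches(tiles[0], tiles[1], truth["a"], truth["b"], n=12, rng=rng)
        base = solve_montage(tiles, [m], SolverOptions(lam=0.01))
        shifted_tiles = [
            make_tile(t.tile_id, size=128, stage_xy=(t.stage_xy[0] + 1.0, t.stage_xy[1] + 2.0))
            for t in tiles
        ]
        shifted = solve_montage(shifted_tiles, [m], SolverOptions(lam=0.01))
        delta = np.array([1.0, 2.0]) * 1000.0 / 5.0
        for tid in ("a", "b"):
            assert np.allclose(
                shifted.transforms[tid].translation,
                base.transforms[tid].translation + delta,
                atol=1e-8,
            )

    @pytest.mark.parametrize("model", ["translation", "rigid", "affine"])
    @pytest.mark.parametrize("lam", [0.0, 0.01])
    def test_matches_dense_oracle(self, model, lam, rng):
        tiles = []
        truth = {}
        for r in range(2):
            for c in range(3):
                tid = f"r{r}c{c}"
                tiles.append(
                    make_tile(tid, size=96, stage_xy=(c * 0.45, r * 0.45))
                )
                truth[tid] = AffineTransform2D.from_translation(
                    c * 90 + rng.uniform(-3, 3), r * 90 + rng.uniform(-3, 3)
                )
        matches = []
        ids = list(truth)
        for i, a in enumerate(tiles):
            for b in tiles[i + 1:]:
                matches.append(
                    synth_matches(a, b, truth[a.tile_id], truth[b.tile_id],
                                  n=12, noise=0.4, rng=rng)
                )
        init = {t.tile_id: nominal_transform(t) for t in tiles}
        res = solve_tile_transforms(
            tiles, matches, init, SolverOptions(lam=lam, model=model)
        )
        oracle = dense_solve(tiles, matches, init, lam=lam, model=model)
        for tid in ids:
            assert np.abs(
                np.array(res.transforms[tid].to_params())
                - np.array(oracle[tid].to_params())
            ).max() < 1e-8

    def test_data_term_monotone_in_lambda(self, rng):
        tiles = [make_tile("a", size=96), make_tile("b", size=96, stage_xy=(0.4, 0.0))]
        truth = {
            "a": AffineTransform2D.from_translation(0, 0),
            "b": AffineTransform2D.from_translation(83.0, 2.0),
        }
        m = synth_matches(tiles[0], tiles[1], truth["a"], truth["b"], n=15, noise=0.5, rng=rng)
        data_terms = []
        for lam in (1.0, 0.1, 0.01, 0.001):
            res = solve_montage(tiles, [m], SolverOptions(lam=lam))
            data_terms.append(res.rms)
        assert all(a >= b - 1e-12 for a, b in zip(data_terms, data_terms[1:]))
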