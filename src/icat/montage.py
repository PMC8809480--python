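"""Acquisition-grid planning and 2D montage stitching of EM tiles.

The correlative acquisition alternates an FM tile (acquired first, to keep
the fluorophores unbleached) and a low-magnification EM tile at each grid
position; FM tiles carry a 20% overlap for ROI mosaicking, while the EM
field is shrunk to w_em = w_fm·(1 − 2·o_fm) so the beam never irradiates the
overlap region of a neighboring, not-yet-acquired FM field. High-
magnification tiles (5 nm px⁻¹, 10–15% overlap) over the fluorescence-
selected ROI are stitched by extracting SIFT features, matching them between
stage-predicted neighbors, and solving one regularized least-squares system
for the per-tile transforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import SIFT, match_descriptors
from skimage.measure import ransac
from skimage.transform import AffineTransform as _SkAffine
from skimage.transform import SimilarityTransform as _SkSimilarity

from .solver import SolverOptions, SolveResult, solve_tile_transforms
from .tiles import PointMatchSet, Tile, nominal_transform, stage_footprint
from .transforms import AffineTransform2D

__all__ = [
    "FeatureSet",
    "em_field_width",
    "plan_acquisition_grid",
    "extract_features",
    "candidate_neighbors",
    "match_features",
    "solve_montage",
]

DEFAULT_RANSAC_SEED = 1234


@dataclass
class FeatureSet:
    """SIFT keypoints (sub-pixel, tile-local (x, y)) with descriptors."""

    keypoints: np.ndarray
    descriptors: np.ndarray
    scales: np.ndarray
    orientations: np.ndarray

    def __post_init__(self) -> None:
        self.keypoints = np.asarray(self.keypoints, dtype=float).reshape(-1, 2)
        self.descriptors = np.asarray(self.descriptors)
        if len(self.keypoints) != len(self.descriptors):
            raise ValueError("|keypoints| must equal |descriptors|")

    def __len__(self) -> int:
        return len(self.keypoints)

    @classmethod
    def empty(cls) -> "FeatureSet":
        return cls(
            np.empty((0, 2)), np.empty((0, 128)), np.empty(0), np.empty(0)
        )


# -------------------------------------------------------- acquisition geometry

def em_field_width(w_fm: float, o_fm: float) -> float:
    """EM field width that avoids the overlap band of neighboring FM fields:
    w_em = w_fm·(1 − 2·o_fm). With the 20% FM overlap this gives 0.6·w_fm
    (≈140 μm for a ≈233 μm FM field)."""
    if not 0.0 <= o_fm < 0.5:
        raise ValueError(f"no EM field remains for o_fm={o_fm} (need 0 <= o_fm < 0.5)")
    if w_fm <= 0:
        raise ValueError("w_fm must be positive")
    return w_fm * (1.0 - 2.0 * o_fm)


def plan_acquisition_grid(
    section_box: tuple, w_fm: float, o_fm: float = 0.2
) -> list[tuple[float, float]]:
    """Row-major serpentine grid of FM/EM stage positions covering a section.

    ``section_box`` is (x0, y0, x1, y1) in stage μm; pitch is
    w_fm·(1 − o_fm); the grid is centered on the box so the union of FM
    fields covers it. Returns tile-center positions in acquisition order.
    """
    x0, y0, x1, y1 = (float(v) for v in section_box)
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"empty section box {section_box}")
    if not 0.0 <= o_fm < 1.0:
        raise ValueError("o_fm must lie in [0, 1)")
    pitch = w_fm * (1.0 - o_fm)
    nx = max(1, int(np.ceil((x1 - x0) / pitch)))
    ny = max(1, int(np.ceil((y1 - y0) / pitch)))
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    xs = cx - (nx - 1) * pitch / 2.0 + np.arange(nx) * pitch
    ys = cy - (ny - 1) * pitch / 2.0 + np.arange(ny) * pitch
    positions: list[tuple[float, float]] = []
    for r, y in enumerate(ys):
        row_xs = xs if r % 2 == 0 else xs[::-1]
        positions.extend((float(x), float(y)) for x in row_xs)
    return positions


# ----------------------------------------------------------------- features

def extract_features(image: np.ndarray, upsampling: int | None = None) -> FeatureSet:
    """Extract SIFT keypoints + descriptors; deterministic for a given input.

    Returns an empty set on featureless (e.g. constant) images. By default,
    initial 2× upsampling is enabled only for small images (< 150 px on a
    side), where the keypoint budget is otherwise too thin; larger tiles get
    sub-pixel keypoints from scale-space interpolation alone.
    """
    image = np.asarray(image)
    if image.size == 0 or float(np.ptp(image.astype(float))) == 0.0:
        return FeatureSet.empty()
    if upsampling is None:
        upsampling = 2 if min(image.shape) < 150 else 1
    sift = SIFT(upsampling=upsampling)
    try:
        sift.detect_and_extract(image)
    except RuntimeError:  # skimage raises when nothing survives filtering
        return FeatureSet.empty()
    keypoints = sift.positions[:, ::-1]  # (row, col) -> (x, y)
    return FeatureSet(
        keypoints=keypoints,
        descriptors=sift.descriptors,
        scales=sift.sigmas,
        orientations=sift.orientations,
    )


def candidate_neighbors(tiles: list[Tile]) -> list[tuple[str, str]]:
    """Tile pairs whose stage-predicted footprints (dilated by 10% of the
    field width) overlap — the montage's potential neighbors."""
    if len({t.modality for t in tiles}) > 1:
        raise ValueError("tiles of one montage must share modality")
    boxes = {}
    for t in tiles:
        x0, y0, x1, y1 = stage_footprint(t)
        dx, dy = 0.1 * (x1 - x0), 0.1 * (y1 - y0)
        boxes[t.tile_id] = (x0 - dx / 2, y0 - dy / 2, x1 + dx / 2, y1 + dy / 2)
    ids = sorted(boxes)
    pairs = []
    for i, a in enumerate(ids):
        ax0, ay0, ax1, ay1 = boxes[a]
        for b in ids[i + 1 :]:
            bx0, by0, bx1, by1 = boxes[b]
            if ax0 <= bx1 and bx0 <= ax1 and ay0 <= by1 and by0 <= ay1:
                pairs.append((a, b))
    return pairs


def _ransac_translation(
    pa: np.ndarray,
    pb: np.ndarray,
    threshold: float,
    max_trials: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """1-sample RANSAC on displacements pb − pa; returns inlier mask."""
    disp = pb - pa
    n = len(disp)
    best = np.zeros(n, dtype=bool)
    order = rng.permutation(n)
    for k in order[: min(max_trials, n)]:
        inl = np.hypot(*(disp - disp[k]).T) <= threshold
        if inl.sum() > best.sum():
            best = inl
    if best.any():  # refine around the inlier consensus displacement
        center = disp[best].mean(axis=0)
        best = np.hypot(*(disp - center).T) <= threshold
    return best


def match_features(
    fa: FeatureSet,
    fb: FeatureSet,
    tile_id_a: str = "a",
    tile_id_b: str = "b",
    model: str = "translation",
    max_ratio: float = 0.8,
    residual_threshold: float = 3.0,
    max_trials: int = 1000,
    seed: int = DEFAULT_RANSAC_SEED,
    min_inliers: int = 3,
) -> PointMatchSet:
    """Descriptor matching with Lowe's ratio test, then RANSAC consensus
    under the montage transform model. Returns the inliers with weight 1;
    empty on failure (the caller decides whether that is an error).

    A consensus smaller than ``min_inliers`` is indistinguishable from
    chance agreement between unrelated textures and is returned empty; for
    the rigid/affine models the floor is raised to twice the minimal sample
    (a minimal-sample model fits its own support perfectly, so tiny
    consensus sets carry no evidence)."""
    if len(fa) == 0 or len(fb) == 0:
        return PointMatchSet(tile_id_a, tile_id_b, np.empty((0, 2, 2)), np.empty(0))
    idx = match_descriptors(
        fa.descriptors, fb.descriptors, max_ratio=max_ratio, cross_check=True
    )
    if len(idx) == 0:
        return PointMatchSet(tile_id_a, tile_id_b, np.empty((0, 2, 2)), np.empty(0))
    pa = fa.keypoints[idx[:, 0]]
    pb = fb.keypoints[idx[:, 1]]

    if model == "translation":
        rng = np.random.default_rng(seed)
        inliers = _ransac_translation(pa, pb, residual_threshold, max_trials, rng)
    else:
        model_cls = _SkSimilarity if model == "rigid" else _SkAffine
        min_samples = 2 if model == "rigid" else 3
        min_inliers = max(min_inliers, 2 * min_samples)
        if len(pa) < min_samples:
            inliers = np.zeros(len(pa), dtype=bool)
        else:
            try:
                _, inliers = ransac(
                    (pa, pb),
                    model_cls,
                    min_samples=min_samples,
                    residual_threshold=residual_threshold,
                    max_trials=max_trials,
                    rng=seed,
                )
            except ValueError:
                inliers = np.zeros(len(pa), dtype=bool)
            if inliers is None:
                inliers = np.zeros(len(pa), dtype=bool)

    pa, pb = pa[inliers], pb[inliers]
    if len(pa) < min_inliers:
        return PointMatchSet(tile_id_a, tile_id_b, np.empty((0, 2, 2)), np.empty(0))
    pairs = np.stack([pa, pb], axis=1)
    # drop exact duplicates (distinct descriptors at one interpolated position)
    _, keep = np.unique(pairs.reshape(len(pairs), 4), axis=0, return_index=True)
    pairs = pairs[np.sort(keep)]
    return PointMatchSet(tile_id_a, tile_id_b, pairs, np.ones(len(pairs)))


def solve_montage(
    tiles: list[Tile],
    matches: list[PointMatchSet],
    opts: SolverOptions | None = None,
) -> SolveResult:
    """Solve one section's montage: per-tile transforms minimizing the
    squared distances between matched features, regularized toward the
    stage-derived transforms, with the anchor tile gauge-fixed."""
    init = {t.tile_id: nominal_transform(t) for t in tiles}
    return solve_tile_transforms(tiles, matches, init, opts or SolverOptions())
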