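"""Fiducial-free FM → EM registration from cathodoluminescent spot grids.

The electron beam is parked at a grid of known scan positions; the substrate
cathodoluminesces, and the fluorescence camera records the emitted spots with
the excitation light off. Because the beam positions are known in EM pixel
coordinates while the spots are localized in FM camera coordinates, matching
the two point sets yields the cross-modal affine transform directly — no
artificial fiducial markers are required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

from .errors import RegistrationError, SpotDetectionError
from .tiles import PointMatchSet
from .transforms import AffineTransform2D

__all__ = [
    "BeamSpotGrid",
    "SpotDetections",
    "detect_spots",
    "match_grid",
    "fit_affine",
    "register_cross_modal",
]


@dataclass
class BeamSpotGrid:
    """Known electron-beam dwell positions, in the EM tile's pixel frame."""

    positions: np.ndarray  # (N, 2) as (x, y)
    shape: tuple[int, int]  # (rows, cols)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        rows, cols = self.shape
        if len(self.positions) != rows * cols:
            raise ValueError("|positions| must equal rows*cols")
        if len(np.unique(self.positions, axis=0)) != len(self.positions):
            raise ValueError("beam positions must be distinct")

    @property
    def pitch(self) -> float:
        """Smallest pairwise distance between beam positions."""
        d = self.positions[:, None, :] - self.positions[None, :, :]
        dist = np.hypot(d[..., 0], d[..., 1])
        dist[np.diag_indices(len(dist))] = np.inf
        return float(dist.min())


@dataclass
class SpotDetections:
    """Sub-pixel CL spot centroids in the FM camera frame."""

    centroids: np.ndarray  # (N, 2) as (x, y)
    intensities: np.ndarray
    residuals: np.ndarray

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        self.intensities = np.asarray(self.intensities, dtype=float).reshape(-1)
        self.residuals = np.asarray(self.residuals, dtype=float).reshape(-1)

    def __len__(self) -> int:
        return len(self.centroids)


def _gaussian_model(params, xg, yg):
    amp, x0, y0, sigma, off = params
    return off + amp * np.exp(-(((xg - x0) ** 2 + (yg - y0) ** 2) / (2.0 * sigma**2)))


def _refine_spot(img: np.ndarray, peak_yx: tuple[int, int], half: int = 3):
    """Sub-pixel refinement: 2D isotropic Gaussian fit in a (2·half+1)² window,
    falling back to an intensity-weighted centroid if the fit misbehaves."""
    py, px = peak_yx
    y0 = max(0, py - half)
    y1 = min(img.shape[0], py + half + 1)
    x0 = max(0, px - half)
    x1 = min(img.shape[1], px + half + 1)
    win = img[y0:y1, x0:x1].astype(float)
    yg, xg = np.mgrid[y0:y1, x0:x1]

    off0 = float(win.min())
    amp0 = float(win.max() - off0)
    p0 = [max(amp0, 1e-6), float(px), float(py), 1.5, off0]
    try:
        res = least_squares(
            lambda p: (_gaussian_model(p, xg, yg) - win).ravel(),
            p0,
            bounds=(
                [0.0, x0 - 1.0, y0 - 1.0, 0.3, -np.inf],
                [np.inf, x1, y1, 2.0 * half, np.inf],
            ),
            max_nfev=200,
        )
        amp, cx, cy, sigma, _ = res.x
        ok = res.success and amp > 0 and x0 - 1 < cx < x1 and y0 - 1 < cy < y1
        if ok:
            rms = float(np.sqrt(np.mean(res.fun**2)))
            return (cx, cy), float(amp), rms
    except Exception:
        pass
    # fallback: background-subtracted intensity-weighted centroid
    w = np.clip(win - off0, 0.0, None)
    tot = w.sum()
    if tot <= 0:
        return (float(px), float(py)), 0.0, np.inf
    cx = float((w * xg).sum() / tot)
    cy = float((w * yg).sum() / tot)
    return (cx, cy), float(w.max()), float(np.sqrt(np.mean(w**2)))


def detect_spots(fm_image: np.ndarray, n_expected: int) -> SpotDetections:
    """Localize up to ``n_expected`` CL spots to sub-pixel precision.

    Local maxima above background mean + 5σ (σ-clipped estimate) seed a 2D
    Gaussian fit per spot; a 7×7 intensity-weighted centroid is the fallback.
    """
    if n_expected < 1:
        raise ValueError("n_expected must be >= 1")
    img = np.asarray(fm_image, dtype=float)

    # sigma-clipped background statistics (spots are sparse outliers)
    flat = img.ravel()
    for _ in range(3):
        mu, sd = flat.mean(), flat.std()
        keep = np.abs(flat - mu) <= 3.0 * max(sd, 1e-12)
        if keep.all():
            break
        flat = flat[keep]
    mu, sd = flat.mean(), flat.std()
    threshold = mu + 5.0 * sd

    peaks = peak_local_max(
        img,
        min_distance=3,
        threshold_abs=threshold,
        num_peaks=n_expected,
        exclude_border=False,
    )
    if len(peaks) == 0:
        raise SpotDetectionError("no CL spots found")

    centroids, intensities, residuals = [], [], []
    for py, px in peaks:
        (cx, cy), amp, rms = _refine_spot(img, (int(py), int(px)))
        cx = float(np.clip(cx, 0, img.shape[1] - 1))
        cy = float(np.clip(cy, 0, img.shape[0] - 1))
        centroids.append((cx, cy))
        intensities.append(amp)
        residuals.append(rms)
    return SpotDetections(np.array(centroids), np.array(intensities), np.array(residuals))


def _normalize(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    center = points.mean(axis=0)
    centered = points - center
    scale = float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))
    scale = max(scale, 1e-12)
    return centered / scale, center, scale


def _principal_angle(points: np.ndarray) -> float:
    cov = np.cov(points.T)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, -1]
    return float(np.arctan2(v[1], v[0]))


def _mutual_pairs(a: np.ndarray, b: np.ndarray, reject: float) -> list[tuple[int, int]]:
    tree_b = cKDTree(b)
    tree_a = cKDTree(a)
    d_ab, idx_ab = tree_b.query(a)
    _, idx_ba = tree_a.query(b)
    return [
        (i, int(idx_ab[i]))
        for i in range(len(a))
        if idx_ba[idx_ab[i]] == i and d_ab[i] <= reject
    ]


def match_grid(spots: SpotDetections, grid: BeamSpotGrid) -> PointMatchSet:
    """One-to-one assignment of detected spots to beam positions.

    Both point sets are normalized (centroid + RMS scale). Candidate
    rotations — the principal-axis difference with the 90° symmetries of a
    near-square grid, plus a coarse 15° sweep — are scored by mutual-
    nearest-neighbor pairing with rejection beyond 0.25 × grid pitch. The
    winning pairing is refined: an affine fit to the accepted pairs re-maps
    the spots and the pairing is repeated, which recovers corner spots that
    a pure rotation pre-alignment leaves outside the rejection radius.
    """
    if len(spots) < 3:
        raise RegistrationError("degenerate CL correspondence: need >= 3 spots")
    s_norm, _, s_scale = _normalize(spots.centroids)
    g_norm, _, g_scale = _normalize(grid.positions)
    pitch_norm = grid.pitch / g_scale
    reject = 0.25 * pitch_norm

    delta = _principal_angle(g_norm) - _principal_angle(s_norm)
    candidates = [0.0] + [delta + k * np.pi / 2.0 for k in range(4)]
    candidates += list(np.deg2rad(np.arange(-180, 180, 15.0)))

    def _refine(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
        """Fit on the current pairing and re-pair in the EM frame; recovers
        spots a pure rotation pre-alignment leaves outside the radius."""
        for _ in range(2):
            if len(pairs) < 3:
                return pairs
            src = spots.centroids[[i for i, _ in pairs]]
            dst = grid.positions[[j for _, j in pairs]]
            try:
                t = fit_affine(
                    PointMatchSet(
                        "fm", "em", np.stack([src, dst], axis=1), np.ones(len(src))
                    )
                )
            except RegistrationError:
                return pairs
            refined = _mutual_pairs(
                t.apply(spots.centroids), grid.positions, 0.25 * grid.pitch
            )
            if len(refined) < len(pairs):
                return pairs
            pairs = refined
        return pairs

    # every candidate rotation is refined before scoring: a square grid has
    # accidental diagonal pseudo-alignments whose raw mutual-NN count can
    # beat the true rotation, but they collapse under refinement. Among
    # refined candidates of equal support the smallest rotation wins (the
    # instrument's FM-EM rotation is modest; a symmetric grid is otherwise
    # 4-fold ambiguous).
    best_pairs: list[tuple[int, int]] = []
    best_key = (-1, np.inf)
    for ang in candidates:
        c, s = np.cos(ang), np.sin(ang)
        rot = s_norm @ np.array([[c, s], [-s, c]])  # rotate spots by +ang
        pairs = _refine(_mutual_pairs(rot, g_norm, reject))
        key = (len(pairs), abs(ang))
        if key[0] > best_key[0] or (key[0] == best_key[0] and key[1] < best_key[1]):
            best_key = key
            best_pairs = pairs

    if len(best_pairs) < 3:
        raise RegistrationError(
            f"degenerate CL correspondence: only {len(best_pairs)} accepted pairs"
        )
    pairs = np.array(
        [
            (spots.centroids[i], grid.positions[j])
            for i, j in sorted(best_pairs, key=lambda p: p[1])
        ]
    )
    return PointMatchSet("fm", "em", pairs, np.ones(len(pairs)))


def fit_affine(matches: PointMatchSet) -> AffineTransform2D:
    """Weighted linear least-squares affine fit: minimizes
    Σ wᵢ‖A pᵢ + t − qᵢ‖² over the 6 coefficients."""
    if len(matches) < 3:
        raise RegistrationError("rank-deficient fit: need >= 3 point pairs")
    p, q, w = matches.points_a, matches.points_b, matches.weights
    n = len(p)
    design = np.zeros((2 * n, 6))
    rhs = np.zeros(2 * n)
    design[0::2, 0] = p[:, 0]
    design[0::2, 1] = p[:, 1]
    design[0::2, 2] = 1.0
    design[1::2, 3] = p[:, 0]
    design[1::2, 4] = p[:, 1]
    design[1::2, 5] = 1.0
    rhs[0::2] = q[:, 0]
    rhs[1::2] = q[:, 1]
    sw = np.sqrt(np.repeat(w, 2))
    sol, _, rank, _ = np.linalg.lstsq(design * sw[:, None], rhs * sw, rcond=None)
    if rank < 6:
        raise RegistrationError("rank-deficient fit: collinear support")
    a11, a12, tx, a21, a22, ty = sol
    return AffineTransform2D(a11, a12, a21, a22, tx, ty)


def register_cross_modal(fm_image: np.ndarray, grid: BeamSpotGrid) -> AffineTransform2D:
    """Full cross-modal registration: detect spots, match to the beam grid,
    fit the FM-pixel → EM-pixel affine transform."""
    spots = detect_spots(fm_image, n_expected=len(grid.positions))
    matches = match_grid(spots, grid)
    return fit_affine(matches)
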