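"""Synthetic acquisitions with known ground truth.

The microscope is emulated end to end: tissue-like section textures
(band-limited background, dark elliptical nuclei, granular speckle — a
rough stand-in for pancreas ultrastructure), fluorescence channels derived
from the texture's nucleus/granule masks, tile grids cropped at
ground-truth-perturbed positions with noise and shading, cathodoluminescent
spot frames, slide overviews with rectangular section footprints, and
serial-section stacks with cumulative drift and discarded sections.

All generators are deterministic under a fixed seed; one global seed fans
out to per-component seeds by stable hashing so regenerating one fixture
never shifts another. Synthetic scales honor the real acquisition ratios
(EM-high 5 nm px⁻¹, EM-low 38 nm px⁻¹, FM coarser still, overview ~7 μm
px⁻¹) at scaled-down image sizes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse

from .cross_modal import BeamSpotGrid
from .tiles import Tile
from .transforms import AffineTransform2D

__all__ = [
    "GroundTruth",
    "sub_seed",
    "make_tissue_texture",
    "simulate_fm_channel",
    "simulate_tileset",
    "simulate_cl_acquisition",
    "simulate_slide_overview",
    "simulate_serial_stack",
]


@dataclass
class GroundTruth:
    """Everything a test needs to compute a stage's ideal output without
    running the stage."""

    seed: int
    tile_transforms: dict[str, AffineTransform2D] = field(default_factory=dict)
    section_drift: dict[int, tuple[float, float]] = field(default_factory=dict)
    cl_transform: AffineTransform2D | None = None
    spot_centers: np.ndarray | None = None
    section_boxes: list[tuple[int, int, int, int]] = field(default_factory=list)
    nucleus_centers: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


def sub_seed(seed: int, name: str) -> int:
    """Stable per-component seed below 2³¹."""
    return zlib.crc32(f"{seed}:{name}".encode()) & 0x7FFFFFFF


# ------------------------------------------------------------------ textures

def make_tissue_texture(
    seed: int,
    size: int = 512,
    nucleus_density: float = 2e-5,
) -> tuple[np.ndarray, np.ndarray]:
    """Tissue-like uint8 raster plus a boolean nucleus mask.

    Band-limited noise at two scales forms the cytoplasmic background, dark
    ellipses play nuclei (count ~ Poisson(density · area)), and bright
    granular speckle provides the high-frequency contrast that feature
    extraction feeds on.
    """
    if size < 256:
        raise ValueError("size must be >= 256")
    rng = np.random.default_rng(seed)
    coarse = ndi.gaussian_filter(rng.normal(size=(size, size)), 8.0)
    fine = ndi.gaussian_filter(rng.normal(size=(size, size)), 1.5)
    img = 0.6 * coarse / max(coarse.std(), 1e-9) + 0.8 * fine / max(fine.std(), 1e-9)

    # granular speckle: sparse bright points, lightly blurred
    n_speckle = max(20, int(size * size * 2e-3))
    sy = rng.integers(0, size, n_speckle)
    sx = rng.integers(0, size, n_speckle)
    speckle = np.zeros((size, size))
    speckle[sy, sx] = rng.uniform(2.0, 5.0, n_speckle)
    img += ndi.gaussian_filter(speckle, 1.0)

    mask = np.zeros((size, size), dtype=bool)
    n_nuclei = rng.poisson(nucleus_density * size * size)
    centers = []
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(0, size, 2)
        ry, rx = rng.uniform(8, 18, 2)
        rr, cc = draw_ellipse(cy, cx, ry, rx, shape=(size, size))
        mask[rr, cc] = True
        centers.append((cx, cy))
    img = np.where(mask, img - 2.5, img)

    lo, hi = np.percentile(img, (0.5, 99.5))
    img = np.clip((img - lo) / max(hi - lo, 1e-9), 0, 1)
    raster = (img * 255).astype(np.uint8)
    return raster, mask


def simulate_fm_channel(
    texture: np.ndarray,
    mask: np.ndarray,
    channel: str = "nuclear",
    fm_factor: int = 4,
    seed: int = 0,
    blur_sigma: float = 4.0,
    background: float = 20.0,
    noise_sigma: float = 2.0,
) -> np.ndarray:
    """Simulated fluorescence channel at an ``fm_factor``-times coarser pixel
    size than the texture. ``nuclear`` blurs the nucleus mask (a Hoechst-like
    stain); ``label`` blurs a random subset of the bright speckle (an
    immunolabel-like stain)."""
    rng = np.random.default_rng(sub_seed(seed, f"fm-{channel}"))
    if channel == "nuclear":
        source = mask.astype(float) * 200.0
    elif channel == "label":
        bright = texture.astype(float) > np.percentile(texture, 98)
        keep = rng.random(bright.shape) < 0.5
        source = (bright & keep & ~mask).astype(float) * 200.0
    else:
        raise ValueError(f"unknown channel {channel!r}")
    blurred = ndi.gaussian_filter(source, blur_sigma)
    coarse = blurred[::fm_factor, ::fm_factor]
    out = coarse + background + rng.normal(0, noise_sigma, coarse.shape)
    return np.clip(out, 0, 255).astype(np.uint8)


def sample_view(
    source: np.ndarray,
    transform: AffineTransform2D,
    out_shape: tuple[int, int],
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Sample a view of ``source`` under an exactly known transform:
    out[p] = source(transform(p)) with bilinear interpolation. The inverse
    of ``transform`` is then the view's true local→source mapping."""
    h, w = out_shape
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    pts = transform.apply(np.column_stack([xs.ravel(), ys.ravel()]))
    img = ndi.map_coordinates(
        np.asarray(source, dtype=float),
        [pts[:, 1].reshape(h, w), pts[:, 0].reshape(h, w)],
        order=1,
        mode="nearest",
    )
    if noise_sigma > 0:
        rng = np.random.default_rng(sub_seed(seed, "view-noise"))
        img = img + rng.normal(0, noise_sigma, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


# ------------------------------------------------------------------ tilesets

def simulate_tileset(
    section: np.ndarray,
    rows: int,
    cols: int,
    tile_size: int,
    overlap: float = 0.125,
    jitter: float = 0.0,
    noise_sigma: float = 0.0,
    shading: float = 0.0,
    seed: int = 0,
    pixel_size_nm: float = 5.0,
    modality: str = "EM_HIGH",
    section_index: int = 0,
    id_prefix: str = "hm",
) -> tuple[list[Tile], GroundTruth]:
    """Crop a rows×cols tile grid from a section raster.

    The true tile origin is the nominal grid position plus U(−jitter,
    +jitter) per axis; the stage coordinates record only the nominal
    position, so the jitter is hidden and must be recovered by stitching.
    Per-tile Gaussian noise and a linear shading ramp emulate detector
    imperfections. Ground truth carries each tile's true local→section
    transform. The section raster is assumed to be at ``pixel_size_nm``.
    """
    rng = np.random.default_rng(sub_seed(seed, "tileset"))
    pitch = tile_size * (1.0 - overlap)
    margin = int(np.ceil(jitter)) + 2
    need_w = margin * 2 + int(np.ceil((cols - 1) * pitch)) + tile_size
    need_h = margin * 2 + int(np.ceil((rows - 1) * pitch)) + tile_size
    if section.shape[0] < need_h or section.shape[1] < need_w:
        raise ValueError(
            f"section {section.shape} too small for grid (needs {need_h}x{need_w})"
        )
    sec = np.asarray(section, dtype=float)
    tiles: list[Tile] = []
    truth = GroundTruth(seed=seed)
    ramp = 1.0 + shading * (np.arange(tile_size) / max(tile_size - 1, 1) - 0.5)
    for r in range(rows):
        for c in range(cols):
            nominal = np.array([margin + c * pitch, margin + r * pitch])
            true = nominal + rng.uniform(-jitter, jitter, 2)
            ys, xs = np.mgrid[0:tile_size, 0:tile_size]
            img = ndi.map_coordinates(
                sec, [ys + true[1], xs + true[0]], order=1, mode="nearest"
            )
            img = img * ramp[None, :]
            if noise_sigma > 0:
                img = img + rng.normal(0, noise_sigma, img.shape)
            img = np.clip(img, 0, 255).astype(np.uint8)
            tid = f"{id_prefix}_z{section_index:03d}_r{r}c{c}"
            center_px = nominal + (tile_size - 1) / 2.0
            stage_um = tuple(center_px * pixel_size_nm / 1000.0)
            tiles.append(
                Tile(
                    tile_id=tid,
                    modality=modality,
                    section_index=section_index,
                    image=img,
                    stage_xy=stage_um,
                    pixel_size_nm=pixel_size_nm,
                )
            )
            truth.tile_transforms[tid] = AffineTransform2D.from_translation(*true)
    return tiles, truth


# ----------------------------------------------------------------- CL frames

def simulate_cl_acquisition(
    truth_transform: AffineTransform2D,
    grid_shape: tuple[int, int] = (3, 3),
    image_size: int = 128,
    spot_sigma: float = 2.0,
    snr: float = 50.0,
    seed: int = 0,
    pitch: float | None = None,
) -> tuple[np.ndarray, BeamSpotGrid, GroundTruth]:
    """Render a CL-spot camera frame for a known FM→EM transform.

    Spot centers are laid out as a grid in the FM frame (default pitch 1/4
    of the field, centered); the corresponding beam positions are the truth
    transform applied to those centers — so registering frame against grid
    should recover ``truth_transform``. Amplitude / noise-σ = ``snr``.
    """
    rows, cols = grid_shape
    if pitch is None:
        # quarter-field pitch, clamped so the outer ring stays well inside
        # the frame (border spots would be truncated by the camera edge)
        pitch = image_size / 4.0
        n_max = max(rows, cols)
        if n_max > 1:
            pitch = min(pitch, (image_size - 1 - 8.0 * spot_sigma) / (n_max - 1))
    rng = np.random.default_rng(sub_seed(seed, "cl"))
    cx = (image_size - 1) / 2.0
    xs = cx + (np.arange(cols) - (cols - 1) / 2.0) * pitch
    ys = cx + (np.arange(rows) - (rows - 1) / 2.0) * pitch
    gx, gy = np.meshgrid(xs, ys)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    beam = truth_transform.apply(centers)

    amp = 200.0
    noise = amp / snr
    yy, xx = np.mgrid[0:image_size, 0:image_size].astype(float)
    frame = np.zeros((image_size, image_size))
    for sx, sy in centers:
        frame += amp * np.exp(
            -(((xx - sx) ** 2 + (yy - sy) ** 2) / (2.0 * spot_sigma**2))
        )
    frame += 10.0
    if noise > 0:
        frame = frame + rng.normal(0, noise, frame.shape)
    grid = BeamSpotGrid(positions=beam, shape=grid_shape)
    truth = GroundTruth(seed=seed, cl_transform=truth_transform, spot_centers=centers)
    return frame, grid, truth


# ------------------------------------------------------------ slide overview

def simulate_slide_overview(
    n_sections: int = 9,
    layout: tuple[int, int] | None = None,
    seed: int = 0,
    image_size: int = 480,
    section_size: int = 40,
    noise_sigma: float = 0.0,
) -> tuple[np.ndarray, GroundTruth]:
    """RGB slide overview: bright section rectangles on a dark substrate.

    Sections are placed on a rows×cols grid (default near-square) with
    positional jitter small enough to keep the rectangles disjoint. Ground
    truth records each rectangle's pixel box (x0, y0, x1, y1), row-major.
    """
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    if layout is None:
        cols = int(np.ceil(np.sqrt(n_sections)))
        rows = int(np.ceil(n_sections / cols))
        layout = (rows, cols)
    rows, cols = layout
    if rows * cols < n_sections:
        raise ValueError("layout too small for n_sections")
    rng = np.random.default_rng(sub_seed(seed, "overview"))
    cell_w = image_size / cols
    cell_h = image_size / rows
    if cell_w < section_size + 8 or cell_h < section_size + 8:
        raise ValueError("image too small for layout")

    img = np.full((image_size, image_size, 3), 30.0)
    truth = GroundTruth(seed=seed)
    placed = 0
    for r in range(rows):
        for c in range(cols):
            if placed == n_sections:
                break
            slack_x = cell_w - section_size - 8
            slack_y = cell_h - section_size - 8
            x0 = int(c * cell_w + 4 + rng.uniform(0, slack_x))
            y0 = int(r * cell_h + 4 + rng.uniform(0, slack_y))
            x1, y1 = x0 + section_size, y0 + section_size
            tint = rng.uniform(-15, 15, 3)
            img[y0:y1, x0:x1] = np.clip(190.0 + tint, 0, 255)
            truth.section_boxes.append((x0, y0, x1, y1))
            placed += 1
    if noise_sigma > 0:
        img = img + rng.normal(0, noise_sigma, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), truth


# -------------------------------------------------------------- serial stack

def simulate_serial_stack(
    n_sections: int,
    missing: set[int] | frozenset[int] = frozenset(),
    drift_sigma: float = 5.0,
    drift_step: tuple[float, float] | None = None,
    size: int = 256,
    seed: int = 0,
    decorrelation: float = 0.03,
) -> tuple[dict[int, np.ndarray], GroundTruth]:
    """Serial sections sharing one texture, with cumulative drift and
    decorrelation noise; ``missing`` indices are cut but discarded, so they
    are absent from the output while remaining in the metadata.

    ``drift_step`` fixes a deterministic per-section step; otherwise steps
    are N(0, drift_sigma) per axis. Section z's raster is the base texture
    sampled at offset drift(z), so the transform mapping section z pixels
    into section 0's frame is translation(drift(z) − drift(0)).
    """
    missing = set(missing)
    if not missing <= set(range(n_sections)):
        raise ValueError("missing indices must lie in range(n_sections)")
    rng = np.random.default_rng(sub_seed(seed, "stack"))
    if drift_step is not None:
        steps = np.tile(np.asarray(drift_step, dtype=float), (n_sections, 1))
        steps[0] = 0.0
    else:
        steps = rng.normal(0, drift_sigma, (n_sections, 2))
        steps[0] = 0.0
    drift = np.cumsum(steps, axis=0)

    margin = int(np.ceil(np.abs(drift).max())) + 2
    tex_size = max(size + 2 * margin, 256)
    base, _ = make_tissue_texture(sub_seed(seed, "stack-texture"), tex_size)
    base = base.astype(float)

    sections: dict[int, np.ndarray] = {}
    truth = GroundTruth(seed=seed)
    ys, xs = np.mgrid[0:size, 0:size].astype(float)
    for z in range(n_sections):
        dx, dy = drift[z]
        truth.section_drift[z] = (float(dx), float(dy))
        if z in missing:
            continue
        img = ndi.map_coordinates(
            base, [ys + margin + dy, xs + margin + dx], order=1, mode="nearest"
        )
        if decorrelation > 0:
            img = img + rng.normal(0, decorrelation * 255.0, img.shape)
        sections[z] = np.clip(img, 0, 255).astype(np.uint8)
    truth.extra["missing"] = sorted(missing)
    truth.extra["n_sections"] = n_sections
    return sections, truth
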