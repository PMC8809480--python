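"""Cross-spatial registration and fluorescence overlay propagation.

The fluorescence tile can only be registered to the *low-magnification* EM
tile acquired at the same grid position (via CL spots). To carry the
fluorescence onto the stitched high-magnification montage, each low-mag tile
is registered to a composite of the high-mag tiles it overlaps ("cross-
spatial" registration), and the resulting transform chain

    T_fm_to_world = T_emlow_to_world ∘ T_fm_to_emlow

is propagated to the FM tile. The overlay accuracy is bounded below by the
low-mag EM pixel size (38 nm), and degrades further where the FM field
extends into the gaps between low-mag tiles and the transform must be
extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import RegistrationError
from .cross_modal import fit_affine
from .montage import extract_features, match_features
from .tiles import (
    WORLD_PIXEL_SIZE_NM,
    Tile,
    render_composite,
    stage_footprint,
    world_footprint,
)
from .transforms import AffineTransform2D, compose

__all__ = [
    "OverlayChain",
    "find_overlapping_highmag",
    "register_lowmag_to_montage",
    "overlay_fm",
    "extrapolation_fraction",
]


@dataclass
class OverlayChain:
    """The two-link transform chain carrying an FM tile into the world frame."""

    t_fm_to_emlow: AffineTransform2D | None = None
    t_emlow_to_world: AffineTransform2D | None = None

    @property
    def t_fm_to_world(self) -> AffineTransform2D:
        if self.t_fm_to_emlow is None or self.t_emlow_to_world is None:
            raise RegistrationError(
                "overlay chain incomplete: need both the cross-modal (FM→EM-low) "
                "and cross-spatial (EM-low→world) transforms"
            )
        return compose(self.t_emlow_to_world, self.t_fm_to_emlow)


def find_overlapping_highmag(emlow_tile: Tile, highmag: list[Tile]) -> list[Tile]:
    """High-mag tiles whose world footprint intersects the low-mag tile's
    stage footprint (closed convention: shared edges count)."""
    x0, y0, x1, y1 = stage_footprint(emlow_tile)
    out = []
    for t in highmag:
        if t.section_index != emlow_tile.section_index:
            continue
        bx0, by0, bx1, by1 = world_footprint(t)
        if x0 <= bx1 and bx0 <= x1 and y0 <= by1 and by0 <= y1:
            out.append(t)
    return out


def register_lowmag_to_montage(
    emlow_tile: Tile,
    highmag: list[Tile],
    seed: int = 1234,
    scale_tolerance: float = 0.05,
) -> AffineTransform2D:
    """Register a low-mag EM tile to the stitched high-mag montage.

    A composite of the overlapping high-mag tiles is rendered at the low-mag
    pixel scale over the overlap bbox, SIFT features are matched between the
    low-mag tile and the composite, and an affine fit maps low-mag pixels to
    the world frame. The linear part's singular values must agree with the
    nominal pixel-size ratio (38/5 = 7.6) within ``scale_tolerance``.
    """
    overlapping = find_overlapping_highmag(emlow_tile, highmag)
    if not overlapping:
        raise RegistrationError(
            f"cross-spatial registration failed: tile {emlow_tile.tile_id} "
            "overlaps no high-magnification tile"
        )
    lx0, ly0, lx1, ly1 = stage_footprint(emlow_tile)
    hx0 = min(world_footprint(t)[0] for t in overlapping)
    hy0 = min(world_footprint(t)[1] for t in overlapping)
    hx1 = max(world_footprint(t)[2] for t in overlapping)
    hy1 = max(world_footprint(t)[3] for t in overlapping)
    bbox = (max(lx0, hx0), max(ly0, hy0), min(lx1, hx1), min(ly1, hy1))

    composite = render_composite(
        overlapping, bbox, out_pixel_size_nm=emlow_tile.pixel_size_nm
    )
    # low-mag views are small; initial 2x upsampling recovers enough keypoints
    f_low = extract_features(emlow_tile.image, upsampling=2)
    f_comp = extract_features(composite, upsampling=2)
    matches = match_features(
        f_low,
        f_comp,
        tile_id_a=emlow_tile.tile_id,
        tile_id_b="composite",
        model="affine",
        seed=seed,
    )
    if len(matches) < 3:
        raise RegistrationError(
            f"cross-spatial registration failed: {len(matches)} inlier matches "
            f"for tile {emlow_tile.tile_id}"
        )
    t_low_to_comp = fit_affine(matches)
    s = emlow_tile.pixel_size_nm / WORLD_PIXEL_SIZE_NM
    t_comp_to_world = AffineTransform2D(s, 0.0, 0.0, s, bbox[0], bbox[1])
    t_low_to_world = compose(t_comp_to_world, t_low_to_comp)

    nominal = s
    singulars = np.linalg.svd(t_low_to_world.linear, compute_uv=False)
    if np.any(np.abs(singulars / nominal - 1.0) > scale_tolerance):
        raise RegistrationError(
            f"cross-spatial registration failed: recovered scale "
            f"{singulars} deviates >{scale_tolerance:.0%} from nominal {nominal}"
        )
    return t_low_to_world


def overlay_fm(fm_tile: Tile, chain: OverlayChain) -> Tile:
    """Propagate the transform chain to an FM tile: its transform becomes
    T_emlow_to_world ∘ T_fm_to_emlow."""
    return fm_tile.with_transform(chain.t_fm_to_world)


def extrapolation_fraction(
    fm_tile: Tile, chain: OverlayChain, emlow_tile: Tile, grid: int = 32
) -> float:
    """Fraction of the FM tile's area that maps outside the low-mag tile's
    footprint — where the overlay transform is extrapolated and the stated
    sub-pixel accuracy no longer holds."""
    xs = np.linspace(0, fm_tile.width - 1, grid)
    ys = np.linspace(0, fm_tile.height - 1, grid)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    in_low = chain.t_fm_to_emlow.apply(pts)
    inside = (
        (in_low[:, 0] >= 0)
        & (in_low[:, 0] <= emlow_tile.width - 1)
        & (in_low[:, 1] >= 0)
        & (in_low[:, 1] <= emlow_tile.height - 1)
    )
    return float(1.0 - inside.mean())
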