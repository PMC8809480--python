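"""Serial-section 3D alignment: rough z-registration, depth-search planning,
cross-section feature matching, and the global fine solve.

Sections are aligned in two passes. A rough pass registers a downsampled
render of each section to its nearest preceding present section (full-
resolution montages are far too large for whole-section feature
extraction). The fine pass then solves one sparse least-squares system over
*all* tiles of *all* sections, combining the intra-section montage matches
with inter-section matches found within a depth-search window d: features
are matched between sections za < zb whenever zb − za ≤ d. Raising d bridges
discarded sections — with sections 9 and 10 missing, d must reach 3 before
sections 8 and 11 can be matched and the stack reconnects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.transform import rescale

from .errors import ConnectivityError, RegistrationError
from .cross_modal import fit_affine
from .montage import FeatureSet, extract_features, match_features
from .solver import SolverOptions, SolveResult, solve_tile_transforms
from .tiles import PointMatchSet, SECTION_THICKNESS_NM, Tile, world_footprint
from .transforms import AffineTransform2D, compose

__all__ = [
    "DepthSearchPlan",
    "build_depth_plan",
    "rough_align_z",
    "cross_section_matches",
    "solve_volume",
    "align_serial_stack",
    "export_stack",
]


@dataclass
class DepthSearchPlan:
    """Which section pairs to match: all (za, zb) with 0 < zb − za ≤ depth,
    both present. ``connected`` reports whether these pairs span the whole
    present set."""

    present: list[int]
    depth: int
    pairs: list[tuple[int, int]] = field(default_factory=list)
    connected: bool = True


def build_depth_plan(present_z: list[int], depth: int) -> DepthSearchPlan:
    """Enumerate matchable section pairs for a depth-search window ``depth``
    and report graph connectivity over the present sections."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    present = sorted(set(int(z) for z in present_z))
    pairs = [
        (za, zb)
        for i, za in enumerate(present)
        for zb in present[i + 1 :]
        if zb - za <= depth
    ]
    graph = nx.Graph()
    graph.add_nodes_from(present)
    graph.add_edges_from(pairs)
    connected = len(present) <= 1 or nx.is_connected(graph)
    return DepthSearchPlan(present=present, depth=depth, pairs=pairs, connected=connected)


def minimal_connecting_depth(present_z: list[int], max_depth: int | None = None) -> int:
    """Smallest depth-search window for which the section graph is connected
    (= the largest index jump between consecutive present sections)."""
    present = sorted(set(int(z) for z in present_z))
    if len(present) <= 1:
        return 1
    needed = max(b - a for a, b in zip(present, present[1:]))
    if max_depth is not None and needed > max_depth:
        raise ConnectivityError(
            f"no depth <= {max_depth} connects the section graph (needs {needed})"
        )
    return needed


def _downsample(img: np.ndarray, factor: float) -> np.ndarray:
    if factor == 1:
        return img
    return rescale(
        np.asarray(img, dtype=float), 1.0 / factor, anti_aliasing=True, preserve_range=True
    )


def rough_align_z(
    sections: dict[int, np.ndarray],
    downsample_factor: float = 16,
    seed: int = 1234,
) -> dict[int, AffineTransform2D]:
    """Rough per-section alignment on downsampled renders.

    The first present section is fixed to identity; each later section is
    registered (SIFT + affine fit) to its nearest preceding present section,
    then the pairwise transforms are chained and rescaled to full
    resolution. Returns per-section transforms into the first section's
    frame.
    """
    if not sections:
        raise ValueError("no sections to align")
    zs = sorted(sections)
    f = float(downsample_factor)
    scale = AffineTransform2D.from_scale(f)
    feats: dict[int, FeatureSet] = {}

    def _features(z: int) -> FeatureSet:
        if z not in feats:
            feats[z] = extract_features(_downsample(sections[z], f))
        return feats[z]

    transforms = {zs[0]: AffineTransform2D.identity()}
    for prev, cur in zip(zs, zs[1:]):
        matches = match_features(
            _features(cur),
            _features(prev),
            tile_id_a=f"z{cur}",
            tile_id_b=f"z{prev}",
            model="affine",
            seed=seed,
        )
        if len(matches) < 3:
            raise RegistrationError(
                f"rough z-alignment failed between sections z={prev} and z={cur}: "
                f"{len(matches)} matches"
            )
        t_ds = fit_affine(matches)  # cur_ds -> prev_ds
        t_full = compose(scale, compose(t_ds, scale.invert()))
        transforms[cur] = compose(transforms[prev], t_full)
    return transforms


def cross_section_matches(
    tiles_by_section: dict[int, list[Tile]],
    plan: DepthSearchPlan,
    rough: dict[int, AffineTransform2D],
    features: dict[str, FeatureSet] | None = None,
    seed: int = 1234,
    model: str = "affine",
    search_radius_factor: float = 2.0,
    max_rough_residual: float = 20.0,
    max_pair_spread: float = 5.0,
) -> list[PointMatchSet]:
    """Match cached per-tile features between the sections of each plan pair.

    Candidate tile pairs are pruned by rough-aligned proximity (centers
    within ``search_radius_factor`` × the tile field); surviving pairs run
    the same ratio-test + RANSAC filter as montage stitching. The rough
    alignment then acts as a sanity gate: pairs are mapped to the rough-
    aligned world frame, pairs deviating more than ``max_pair_spread`` px
    from the set's median displacement are dropped (a degenerate RANSAC
    consensus can admit wild outliers), and whole sets whose median
    displacement exceeds ``max_rough_residual`` px are rejected. Matches are
    expressed in tile-local frames. Features extracted during 2D stitching
    can be passed in via ``features`` and are computed (and cached) on
    demand otherwise.
    """
    features = {} if features is None else features

    def _feat(tile: Tile) -> FeatureSet:
        if tile.tile_id not in features:
            features[tile.tile_id] = extract_features(tile.image)
        return features[tile.tile_id]

    def _center(tile: Tile, z: int) -> np.ndarray:
        t = compose(rough[z], tile.transform)
        return t.apply([(tile.width - 1) / 2.0, (tile.height - 1) / 2.0])

    out: list[PointMatchSet] = []
    for za, zb in plan.pairs:
        for ta in tiles_by_section.get(za, []):
            ca = _center(ta, za)
            x0, y0, x1, y1 = world_footprint(ta)
            radius = search_radius_factor * max(x1 - x0, y1 - y0)
            for tb in tiles_by_section.get(zb, []):
                if np.hypot(*(ca - _center(tb, zb))) > radius:
                    continue
                m = match_features(
                    _feat(ta),
                    _feat(tb),
                    tile_id_a=ta.tile_id,
                    tile_id_b=tb.tile_id,
                    model=model,
                    seed=seed,
                )
                if not len(m):
                    continue
                wa = compose(rough[za], ta.transform).apply(m.points_a)
                wb = compose(rough[zb], tb.transform).apply(m.points_b)
                disp = wa - wb
                med = np.median(disp, axis=0)
                if np.hypot(*med) > max_rough_residual:
                    continue
                keep = np.hypot(*(disp - med).T) <= max_pair_spread
                if keep.sum() >= 3:
                    out.append(
                        PointMatchSet(
                            m.tile_id_a, m.tile_id_b, m.pairs[keep], m.weights[keep]
                        )
                    )
    return out


def _check_section_connectivity(
    tiles: list[Tile], matches: list[PointMatchSet]
) -> None:
    graph = nx.Graph()
    section_of = {t.tile_id: t.section_index for t in tiles}
    graph.add_nodes_from(section_of)
    graph.add_edges_from(
        (m.tile_id_a, m.tile_id_b) for m in matches if len(m) > 0
    )
    comps = list(nx.connected_components(graph))
    if len(comps) > 1:
        groups = sorted(sorted({section_of[tid] for tid in c}) for c in comps)
        raise ConnectivityError(
            "match graph disconnected across section groups "
            + "; ".join(str(g) for g in groups)
            + " — increase the feature depth-search window d",
            components=groups,
        )


def solve_volume(
    tiles: list[Tile],
    intra: list[PointMatchSet],
    inter: list[PointMatchSet],
    opts: SolverOptions | None = None,
    init: dict[str, AffineTransform2D] | None = None,
    inter_weight: float = 0.5,
) -> SolveResult:
    """Fine 3D alignment: one sparse least-squares solve over all tiles of
    all sections, combining intra-section (montage) and inter-section
    matches. ``init`` defaults to each tile's current transform, expected to
    be the montage solution composed with the rough z transform. Inter-
    section matches are down-weighted by ``inter_weight`` relative to intra.
    The gauge is fixed by anchoring the first section's anchor tile."""
    opts = opts or SolverOptions()
    if init is None:
        init = {t.tile_id: t.transform for t in tiles}
    weighted_inter = [m.scaled(inter_weight) for m in inter]
    all_matches = list(intra) + weighted_inter
    _check_section_connectivity(tiles, all_matches)
    if opts.anchor_tile is None:
        z0 = min(t.section_index for t in tiles)
        anchor = min(t.tile_id for t in tiles if t.section_index == z0)
        opts = SolverOptions(
            lam=opts.lam,
            model=opts.model,
            anchor_tile=anchor,
            max_iter=opts.max_iter,
            tol=opts.tol,
        )
    return solve_tile_transforms(tiles, all_matches, init, opts)


def align_serial_stack(
    sections: dict[int, np.ndarray],
    depth: int = 2,
    downsample_factor: float = 1,
    auto_depth: bool = False,
    seed: int = 1234,
    opts: SolverOptions | None = None,
    pixel_size_nm: float = 5.0,
):
    """End-to-end alignment of a stack of single-raster sections.

    Wraps each section as one tile, runs rough z-alignment, builds the
    depth-search plan (optionally raising d to the minimal connecting value
    when ``auto_depth``), matches features across sections and solves the
    global system. Returns ``(transforms per z, plan, result)``.
    """
    zs = sorted(sections)
    plan = build_depth_plan(zs, depth)
    if not plan.connected:
        if auto_depth:
            plan = build_depth_plan(zs, minimal_connecting_depth(zs))
        # otherwise proceed: the solve will raise a ConnectivityError naming
        # the disconnected section groups, mirroring the manual mitigation
    rough = rough_align_z(sections, downsample_factor, seed=seed)
    tiles = []
    features: dict[str, FeatureSet] = {}
    for z in zs:
        img = sections[z]
        tile = Tile(
            tile_id=f"z{z:04d}",
            modality="EM_HIGH",
            section_index=z,
            image=img,
            stage_xy=(0.0, 0.0),
            pixel_size_nm=pixel_size_nm,
            transform=rough[z],
        )
        tiles.append(tile)
    matches = cross_section_matches(
        {z: [t] for z, t in zip(zs, tiles)},
        plan,
        {z: AffineTransform2D.identity() for z in zs},  # tiles already carry rough
        features=features,
        seed=seed,
    )
    opts = opts or SolverOptions(model="affine", lam=0.005)
    result = solve_volume(tiles, intra=[], inter=matches, opts=opts)
    transforms = {z: result.transforms[t.tile_id] for z, t in zip(zs, tiles)}
    return transforms, plan, result


def export_stack(
    sections: dict[int, np.ndarray],
    transforms: dict[int, AffineTransform2D],
    path: str | None = None,
    section_thickness_nm: float = SECTION_THICKNESS_NM,
) -> np.ndarray:
    """Render the aligned stack into a common frame; one z-plane per present
    section. Writes an ImageJ-style TIFF with 100 nm z-spacing metadata when
    ``path`` is given."""
    zs = sorted(sections)
    corners = []
    for z in zs:
        h, w = sections[z].shape
        local = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], float)
        corners.append(transforms[z].apply(local))
    corners = np.vstack(corners)
    x0, y0 = np.floor(corners.min(axis=0)).astype(int)
    x1, y1 = np.ceil(corners.max(axis=0)).astype(int)
    width, height = x1 - x0 + 1, y1 - y0 + 1
    gx, gy = np.meshgrid(np.arange(width) + x0, np.arange(height) + y0)

    planes = []
    for z in zs:
        inv = transforms[z].invert()
        lin, tr = inv.linear, inv.translation
        lx = lin[0, 0] * gx + lin[0, 1] * gy + tr[0]
        ly = lin[1, 0] * gx + lin[1, 1] * gy + tr[1]
        planes.append(
            ndi.map_coordinates(
                np.asarray(sections[z], dtype=float), [ly, lx], order=1, cval=0.0
            )
        )
    stack = np.stack(planes).astype(np.float32)
    if path is not None:
        tifffile.imwrite(
            path,
            stack,
            imagej=True,
            metadata={"spacing": section_thickness_nm / 1000.0, "unit": "um", "axes": "ZYX"},
        )
    return stack
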