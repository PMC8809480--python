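"""Core data model: tiles, point-match sets, tile stores, composite rendering.

A :class:`Tile` is one acquired raster (fluorescence, low- or high-
magnification EM, or the slide overview) with its stage position, pixel size
and current transform into the section world frame. The world frame per
section is the high-magnification EM pixel grid at 5 nm px⁻¹; low-mag EM
(38 nm px⁻¹) and FM tiles are expressed in it through their transforms, so
fluorescence overlays land at full EM resolution.

The on-disk tile store is a directory of single-plane TIFFs plus one JSON
metadata file in the "icat-spec-1" dialect (one record per tile: id,
modality, z, stage position in μm, pixel size in nm, the six transform
coefficients row-major, and the image path).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import tifffile
from scipy import ndimage as ndi

from .errors import RenderError, StoreFormatError
from .transforms import AffineTransform2D

__all__ = [
    "WORLD_PIXEL_SIZE_NM",
    "SECTION_THICKNESS_NM",
    "MODALITIES",
    "Tile",
    "PointMatchSet",
    "TileStore",
    "nominal_transform",
    "world_footprint",
    "stage_footprint",
    "render_composite",
    "read_store",
    "write_store",
]

WORLD_PIXEL_SIZE_NM = 5.0
SECTION_THICKNESS_NM = 100.0
MODALITIES = ("FM", "EM_LOW", "EM_HIGH", "OVERVIEW")

SCHEMA_VERSION = "icat-spec-1"


@dataclass
class Tile:
    """One acquired raster with acquisition geometry.

    ``stage_xy`` is the stage position of the tile *center* in μm;
    ``transform`` maps tile-local pixels into the section world frame.
    """

    tile_id: str
    modality: str
    section_index: int
    image: np.ndarray
    stage_xy: tuple[float, float]
    pixel_size_nm: float
    transform: AffineTransform2D = field(default_factory=AffineTransform2D)
    channel: str | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.image.ndim != 2 or self.image.size == 0:
            raise ValueError(f"tile {self.tile_id}: image must be non-empty 2D")
        if not self.pixel_size_nm > 0:
            raise ValueError(f"tile {self.tile_id}: pixel_size_nm must be > 0")
        self.stage_xy = (float(self.stage_xy[0]), float(self.stage_xy[1]))

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]

    @property
    def field_size_um(self) -> tuple[float, float]:
        """Physical field size (width, height) in μm."""
        return (
            self.width * self.pixel_size_nm / 1000.0,
            self.height * self.pixel_size_nm / 1000.0,
        )

    def with_transform(self, transform: AffineTransform2D) -> "Tile":
        return replace(self, transform=transform)

    def corners_local(self) -> np.ndarray:
        """Tile corner pixel centers, (4, 2) as (x, y)."""
        w, h = self.width - 1, self.height - 1
        return np.array([[0, 0], [w, 0], [w, h], [0, h]], dtype=float)


@dataclass
class PointMatchSet:
    """Weighted point correspondences between two tiles (or two sections).

    ``pairs`` is an (N, 2, 2) array: pairs[i] = (p_a, p_b) with each point in
    its tile's local pixel frame; ``weights`` are per-pair in [0, 1].
    """

    tile_id_a: str
    tile_id_b: str
    pairs: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=float).reshape(-1, 2, 2)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if len(self.pairs) != len(self.weights):
            raise ValueError("|pairs| must equal |weights|")
        if len(self.pairs) and (
            self.weights.min() < 0.0 or self.weights.max() > 1.0
        ):
            raise ValueError("weights must lie in [0, 1]")
        if len(self.pairs) > 1:
            flat = self.pairs.reshape(len(self.pairs), 4)
            if len(np.unique(flat, axis=0)) != len(flat):
                raise ValueError("duplicate point pairs")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def points_a(self) -> np.ndarray:
        return self.pairs[:, 0, :]

    @property
    def points_b(self) -> np.ndarray:
        return self.pairs[:, 1, :]

    def scaled(self, factor: float) -> "PointMatchSet":
        """Copy with weights multiplied by ``factor`` (clipped to [0, 1])."""
        return PointMatchSet(
            self.tile_id_a,
            self.tile_id_b,
            self.pairs.copy(),
            np.clip(self.weights * factor, 0.0, 1.0),
        )


class TileStore:
    """Named stacks of tiles grouped by section index.

    Stands in for a tile-server database: a plain in-memory container with a
    lossless JSON + TIFF serialization.
    """

    def __init__(self, metadata: dict | None = None):
        self.stacks: dict[str, list[Tile]] = {}
        self.metadata: dict = {
            "world_pixel_size_nm": WORLD_PIXEL_SIZE_NM,
            "section_thickness_nm": SECTION_THICKNESS_NM,
        }
        if metadata:
            self.metadata.update(metadata)

    def add(self, stack: str, tile: Tile) -> None:
        tiles = self.stacks.setdefault(stack, [])
        if any(t.tile_id == tile.tile_id for t in tiles):
            raise ValueError(f"duplicate tile_id {tile.tile_id!r} in stack {stack!r}")
        tiles.append(tile)

    def tiles(self, stack: str, z: int | None = None) -> list[Tile]:
        tiles = self.stacks.get(stack, [])
        if z is None:
            return list(tiles)
        return [t for t in tiles if t.section_index == z]

    def get(self, stack: str, tile_id: str) -> Tile:
        for t in self.stacks.get(stack, []):
            if t.tile_id == tile_id:
                return t
        raise KeyError(f"tile {tile_id!r} not in stack {stack!r}")

    def section_indices(self, stack: str) -> list[int]:
        return sorted({t.section_index for t in self.stacks.get(stack, [])})


# ------------------------------------------------------------------ geometry

def nominal_transform(
    tile: Tile, world_pixel_size_nm: float = WORLD_PIXEL_SIZE_NM
) -> AffineTransform2D:
    """Stage-derived initial transform: pure scale + translation placing the
    tile center at its stage position."""
    s = tile.pixel_size_nm / world_pixel_size_nm
    cx, cy = (tile.width - 1) / 2.0, (tile.height - 1) / 2.0
    px = tile.stage_xy[0] * 1000.0 / world_pixel_size_nm
    py = tile.stage_xy[1] * 1000.0 / world_pixel_size_nm
    return AffineTransform2D(s, 0.0, 0.0, s, px - s * cx, py - s * cy)


def world_footprint(tile: Tile, transform: AffineTransform2D | None = None) -> tuple:
    """Axis-aligned world-frame bbox (x0, y0, x1, y1) of the tile under
    ``transform`` (default: the tile's current transform)."""
    t = transform if transform is not None else tile.transform
    corners = t.apply(tile.corners_local())
    return (
        corners[:, 0].min(),
        corners[:, 1].min(),
        corners[:, 0].max(),
        corners[:, 1].max(),
    )


def stage_footprint(
    tile: Tile, world_pixel_size_nm: float = WORLD_PIXEL_SIZE_NM
) -> tuple:
    """World-frame bbox the stage coordinates predict (ignoring any solve)."""
    return world_footprint(tile, nominal_transform(tile, world_pixel_size_nm))


def _boxes_intersect(a: tuple, b: tuple) -> bool:
    """Closed-footprint convention: touching edges count as overlap."""
    return a[0] <= b[2] and b[0] <= a[2] and a[1] <= b[3] and b[1] <= a[3]


# ----------------------------------------------------------------- rendering

def render_composite(
    tiles: Sequence[Tile],
    bbox: tuple,
    out_pixel_size_nm: float = WORLD_PIXEL_SIZE_NM,
    world_pixel_size_nm: float = WORLD_PIXEL_SIZE_NM,
) -> np.ndarray:
    """Render tiles into a world-frame bbox at the requested scale.

    Painter's order (last tile wins where tiles overlap), inverse-transform
    bilinear sampling, zeros where no tile covers. ``bbox`` is
    (x0, y0, x1, y1) in world pixels; output pixel (i, j) samples world point
    (x0 + j·s, y0 + i·s) with s = out_pixel_size_nm / world_pixel_size_nm.
    """
    x0, y0, x1, y1 = (float(v) for v in bbox)
    if x1 <= x0 or y1 <= y0:
        raise RenderError(f"empty bbox {bbox}")
    hit = [t for t in tiles if _boxes_intersect(world_footprint(t), (x0, y0, x1, y1))]
    if not hit:
        raise RenderError(f"no tile intersects bbox {bbox}")

    s = out_pixel_size_nm / world_pixel_size_nm
    n_cols = max(1, int(np.ceil((x1 - x0) / s)))
    n_rows = max(1, int(np.ceil((y1 - y0) / s)))
    xs = x0 + np.arange(n_cols) * s
    ys = y0 + np.arange(n_rows) * s
    wx, wy = np.meshgrid(xs, ys)

    out = np.zeros((n_rows, n_cols), dtype=float)
    eps = 1e-9
    for tile in hit:
        inv = tile.transform.invert()
        lin, tr = inv.linear, inv.translation
        lx = lin[0, 0] * wx + lin[0, 1] * wy + tr[0]
        ly = lin[1, 0] * wx + lin[1, 1] * wy + tr[1]
        valid = (
            (lx >= -eps)
            & (lx <= tile.width - 1 + eps)
            & (ly >= -eps)
            & (ly <= tile.height - 1 + eps)
        )
        if not valid.any():
            continue
        sampled = ndi.map_coordinates(
            tile.image.astype(float), [ly, lx], order=1, mode="constant", cval=0.0
        )
        out[valid] = sampled[valid]

    dtypes = {t.image.dtype for t in hit}
    if len(dtypes) == 1 and np.issubdtype(next(iter(dtypes)), np.integer):
        info = np.iinfo(next(iter(dtypes)))
        return np.clip(np.rint(out), info.min, info.max).astype(next(iter(dtypes)))
    return out.astype(np.float32)


# ------------------------------------------------------------------ store IO

_RECORD_KEYS = {
    "id",
    "modality",
    "z",
    "stage_xy_um",
    "pixel_size_nm",
    "transform",
    "image",
    "channel",
}


def write_store(store: TileStore, path: str | os.PathLike) -> None:
    path = os.fspath(path)
    os.makedirs(path, exist_ok=True)
    records: dict[str, list[dict]] = {}
    for stack, tiles in store.stacks.items():
        recs = []
        for tile in tiles:
            rel = os.path.join("tiles", stack, f"{tile.tile_id}.tif")
            full = os.path.join(path, rel)
            os.makedirs(os.path.dirname(full), exist_ok=True)
            tifffile.imwrite(full, tile.image)
            recs.append(
                {
                    "id": tile.tile_id,
                    "modality": tile.modality,
                    "z": tile.section_index,
                    "stage_xy_um": list(tile.stage_xy),
                    "pixel_size_nm": tile.pixel_size_nm,
                    "transform": tile.transform.to_params(),
                    "image": rel.replace(os.sep, "/"),
                    "channel": tile.channel,
                }
            )
        records[stack] = recs
    doc = {"schema": SCHEMA_VERSION, "metadata": store.metadata, "stacks": records}
    with open(os.path.join(path, "store.json"), "w") as fh:
        json.dump(doc, fh, indent=1)


def _read_image(path: str) -> np.ndarray:
    if path.lower().endswith((".png", ".jpg", ".jpeg")):
        import imageio.v3 as iio

        return np.asarray(iio.imread(path))
    return tifffile.imread(path)


def read_store(path: str | os.PathLike) -> TileStore:
    path = os.fspath(path)
    meta_path = os.path.join(path, "store.json")
    if not os.path.exists(meta_path):
        raise StoreFormatError(f"no store.json under {path!r}")
    with open(meta_path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != SCHEMA_VERSION:
        raise StoreFormatError(f"unsupported schema {doc.get('schema')!r}")
    store = TileStore(metadata=doc.get("metadata", {}))
    for stack, recs in doc.get("stacks", {}).items():
        for rec in recs:
            tid = rec.get("id", "<missing id>")
            unknown = set(rec) - _RECORD_KEYS
            missing = _RECORD_KEYS - {"channel"} - set(rec)
            if unknown or missing:
                raise StoreFormatError(
                    f"tile {tid!r}: malformed record "
                    f"(missing {sorted(missing)}, unknown {sorted(unknown)})"
                )
            params = rec["transform"]
            if len(params) != 6:
                raise StoreFormatError(
                    f"tile {tid!r}: transform must have 6 coefficients, "
                    f"got {len(params)}"
                )
            img_path = os.path.join(path, rec["image"])
            if not os.path.exists(img_path):
                raise StoreFormatError(f"tile {tid!r}: missing image {rec['image']!r}")
            tile = Tile(
                tile_id=rec["id"],
                modality=rec["modality"],
                section_index=int(rec["z"]),
                image=_read_image(img_path),
                stage_xy=tuple(rec["stage_xy_um"]),
                pixel_size_nm=float(rec["pixel_size_nm"]),
                transform=AffineTransform2D.from_params(params),
                channel=rec.get("channel"),
            )
            store.add(stack, tile)
    return store
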