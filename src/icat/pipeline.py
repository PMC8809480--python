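"""Pipeline orchestration: simulate/ingest → segment → register-cl → stitch
→ overlay → align3d → export, with a structured config, run log and QC
report.

Each stage is idempotent: it detects its existing outputs in the store and
skips unless forced. Any stage failure aborts the run with the stage name;
partial state (including the report so far) is persisted. The report
includes per-stage residuals, section connectivity, and the imaged-area
accounting — the ratio of full-section area to fluorescence-selected ROI
area that quantifies how much acquisition the targeting saves.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import tifffile
import yaml
from scipy import ndimage as ndi

from . import synthetic
from .cross_modal import register_cross_modal, BeamSpotGrid
from .errors import ConnectivityError, PipelineError
from .montage import (
    FeatureSet,
    candidate_neighbors,
    extract_features,
    match_features,
    solve_montage,
)
from .overlay import OverlayChain, extrapolation_fraction, overlay_fm, register_lowmag_to_montage
from .section_detection import boxes_to_stage, segment_sections
from .solver import SolverOptions
from .tiles import (
    WORLD_PIXEL_SIZE_NM,
    PointMatchSet,
    Tile,
    TileStore,
    read_store,
    render_composite,
    world_footprint,
    write_store,
)
from .transforms import AffineTransform2D, compose
from .volume import (
    build_depth_plan,
    cross_section_matches,
    minimal_connecting_depth,
    rough_align_z,
    solve_volume,
)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "roi_select",
    "area_reduction_factor",
    "build_preset_store",
]

logger = logging.getLogger("icat")

STAGE_ORDER = ["simulate", "segment", "register_cl", "stitch", "overlay", "align3d", "export"]

_DEFAULTS: dict = {
    "store": None,
    "seed": 1234,
    "preset": None,
    "force": False,
    "log_level": "INFO",
    "stages": {name: True for name in STAGE_ORDER},
    "segment": {"n_sections": None, "pixel_size_um": 7.0},
    "stitch": {"model": "translation", "lam": 0.005},
    "roi": {"strategy": "otsu", "threshold": None, "min_area_px": 4},
    "align3d": {"depth": 2, "auto_depth": False, "lam": 0.005, "downsample": 2, "model": "affine"},
    "export": {"downsample": 4},
}


def _merge_strict(defaults: dict, given: dict, path: str = "") -> dict:
    out = {}
    unknown = set(given) - set(defaults)
    if unknown:
        raise PipelineError(f"unknown config keys at {path or 'top level'}: {sorted(unknown)}")
    for key, dval in defaults.items():
        if isinstance(dval, dict) and dval:
            sub = given.get(key) or {}
            if not isinstance(sub, dict):
                raise PipelineError(f"config key {path}{key} must be a mapping")
            out[key] = _merge_strict(dval, sub, f"{path}{key}.")
        else:
            out[key] = given.get(key, dval)
    return out


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    values: dict = field(default_factory=lambda: _merge_strict(_DEFAULTS, {}))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls(_merge_strict(_DEFAULTS, d or {}))
        if not cfg.values.get("store"):
            raise PipelineError("config must set 'store'")
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def __getitem__(self, key):
        return self.values[key]


# ------------------------------------------------------------- ROI selection

def roi_select(
    mosaic: np.ndarray,
    transform: AffineTransform2D | None = None,
    strategy: str = "otsu",
    threshold: float | None = None,
    min_area_px: int = 0,
) -> list[tuple[float, float, float, float]]:
    """Fluorescence-driven ROI selection on a stitched FM mosaic.

    Thresholding (Otsu or absolute) + connected components + minimum-area
    filter; returns ROI bounding boxes mapped through ``transform`` (mosaic
    pixels → world frame; identity when omitted). Empty list with a warning
    when nothing exceeds threshold."""
    img = np.asarray(mosaic, dtype=float)
    if strategy == "absolute":
        if threshold is None:
            raise PipelineError("absolute ROI strategy requires a threshold")
        t = float(threshold)
    elif strategy == "otsu":
        from skimage.filters import threshold_otsu

        if float(np.ptp(img)) == 0.0:
            logger.warning("ROI selection: flat mosaic, no ROI found")
            return []
        t = float(threshold_otsu(img))
    else:
        raise PipelineError(f"unknown ROI strategy {strategy!r}")
    mask = img > t
    labels, n = ndi.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n == 0:
        logger.warning("ROI selection: no ROI found")
        return []
    transform = transform or AffineTransform2D.identity()
    boxes = []
    for sl in ndi.find_objects(labels):
        if sl is None:
            continue
        area = (sl[0].stop - sl[0].start) * (sl[1].stop - sl[1].start)
        if area < min_area_px:
            continue
        corners = np.array(
            [
                [sl[1].start, sl[0].start],
                [sl[1].stop, sl[0].start],
                [sl[1].stop, sl[0].stop],
                [sl[1].start, sl[0].stop],
            ],
            float,
        )
        world = transform.apply(corners)
        boxes.append(
            (
                float(world[:, 0].min()),
                float(world[:, 1].min()),
                float(world[:, 0].max()),
                float(world[:, 1].max()),
            )
        )
    if not boxes:
        logger.warning("ROI selection: all candidates below min area")
    return boxes


def area_reduction_factor(section_box: tuple, roi_boxes: list[tuple]) -> float:
    """(full-section area) / (summed ROI area): the acquisition-reduction
    bookkeeping. Exactly the geometric ratio of the configured boxes."""
    sx0, sy0, sx1, sy1 = section_box
    section_area = (sx1 - sx0) * (sy1 - sy0)
    roi_area = sum((x1 - x0) * (y1 - y0) for x0, y0, x1, y1 in roi_boxes)
    if roi_area <= 0:
        raise PipelineError("ROI area is zero; no reduction factor defined")
    return float(section_area / roi_area)


# ------------------------------------------------------------------- presets

_PRESETS = {
    # n_sections, missing, section raster px (at 5 nm), montage grid, FM/EM-low?
    "tiny": dict(n=1, missing=(), size=768, grid=(2, 2, 384), drift=0.0, clem=True),
    "rat9": dict(n=9, missing=(), size=768, grid=(2, 2, 384), drift=4.0, clem=True),
    "zebrafish66": dict(n=66, missing=(9, 10, 34), size=192, grid=(1, 1, 160), drift=2.0, clem=False),
}

EMLOW_SCALE = 38.0 / WORLD_PIXEL_SIZE_NM  # 7.6
FM_FACTOR = 16  # FM pixel = 16 × 5 nm = 80 nm


def build_preset_store(preset: str, path: str, seed: int) -> None:
    """Write a complete synthetic TileStore (plus overview, CL frames and
    ground truth) for one of the named study presets."""
    if preset not in _PRESETS:
        raise PipelineError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    p = _PRESETS[preset]
    sections, stack_truth = synthetic.simulate_serial_stack(
        p["n"], missing=set(p["missing"]), drift_sigma=p["drift"], size=p["size"], seed=seed
    )
    store = TileStore(metadata={"preset": preset, "seed": seed})
    truth_doc: dict = {
        "seed": seed,
        "missing": sorted(p["missing"]),
        "n_sections": p["n"],
        "section_drift": {str(z): list(d) for z, d in stack_truth.section_drift.items()},
        "tiles": {},
        "cl_transforms": {},
        "roi_center_world": {},
    }

    rows, cols, tile_size = p["grid"]
    for z, raster in sections.items():
        tiles, truth = synthetic.simulate_tileset(
            raster,
            rows,
            cols,
            tile_size,
            overlap=0.125,
            jitter=3.0,
            noise_sigma=2.0,
            seed=synthetic.sub_seed(seed, f"tiles-z{z}"),
            section_index=z,
        )
        for t in tiles:
            store.add("em_high", t)
            truth_doc["tiles"][t.tile_id] = truth.tile_transforms[t.tile_id].to_params()

        if p["clem"]:
            h, w = raster.shape
            # EM-low proxy: exactly known 7.6× view of the section
            t_low_to_world = AffineTransform2D.from_scale(EMLOW_SCALE)
            low_shape = (int(h / EMLOW_SCALE), int(w / EMLOW_SCALE))
            low_img = synthetic.sample_view(
                raster, t_low_to_world, low_shape, noise_sigma=1.0,
                seed=synthetic.sub_seed(seed, f"low-z{z}"),
            )
            center_world = t_low_to_world.apply(
                [(low_shape[1] - 1) / 2.0, (low_shape[0] - 1) / 2.0]
            )
            low = Tile(
                tile_id=f"lm_z{z:03d}",
                modality="EM_LOW",
                section_index=z,
                image=low_img,
                stage_xy=tuple(center_world * WORLD_PIXEL_SIZE_NM / 1000.0),
                pixel_size_nm=38.0,
            )
            store.add("em_low", low)
            truth_doc["tiles"][low.tile_id] = t_low_to_world.to_params()

            # FM tile: blurred label channel of the same section + ROI blob
            fm_img = synthetic.simulate_fm_channel(
                raster,
                np.zeros_like(raster, dtype=bool),
                channel="label",
                fm_factor=FM_FACTOR,
                seed=synthetic.sub_seed(seed, f"fm-z{z}"),
            ).astype(float)
            fh, fw = fm_img.shape
            roi_c = (fw * 0.6, fh * 0.55)
            yy, xx = np.mgrid[0:fh, 0:fw].astype(float)
            fm_img += 150.0 * np.exp(
                -(((xx - roi_c[0]) ** 2 + (yy - roi_c[1]) ** 2) / (2.0 * (fh / 10.0) ** 2))
            )
            fm_img = np.clip(fm_img, 0, 255).astype(np.uint8)
            t_fm_to_world = AffineTransform2D.from_scale(FM_FACTOR)
            t_fm_to_emlow = compose(t_low_to_world.invert(), t_fm_to_world)
            fm_center = t_fm_to_world.apply([(fw - 1) / 2.0, (fh - 1) / 2.0])
            fm = Tile(
                tile_id=f"fm_z{z:03d}",
                modality="FM",
                section_index=z,
                image=fm_img,
                stage_xy=tuple(fm_center * WORLD_PIXEL_SIZE_NM / 1000.0),
                pixel_size_nm=FM_FACTOR * WORLD_PIXEL_SIZE_NM,
                channel="label",
            )
            store.add("fm", fm)
            truth_doc["tiles"][fm.tile_id] = t_fm_to_world.to_params()
            truth_doc["roi_center_world"][str(z)] = list(
                t_fm_to_world.apply(np.array(roi_c))
            )

            # CL frame in the FM camera with the true cross-modal transform
            # camera frame shares the FM pixel grid; its extent is fixed by
            # the camera, not by the (scaled-down) FM tile
            frame, grid, _ = synthetic.simulate_cl_acquisition(
                t_fm_to_emlow,
                grid_shape=(3, 3),
                image_size=64,
                spot_sigma=1.5,
                snr=50.0,
                seed=synthetic.sub_seed(seed, f"cl-z{z}"),
            )
            os.makedirs(os.path.join(path, "cl"), exist_ok=True)
            tifffile.imwrite(
                os.path.join(path, "cl", f"z{z:03d}_frame.tif"),
                frame.astype(np.float32),
            )
            with open(os.path.join(path, "cl", f"z{z:03d}_grid.json"), "w") as fh2:
                json.dump(
                    {"positions": grid.positions.tolist(), "shape": list(grid.shape)},
                    fh2,
                )
            truth_doc["cl_transforms"][str(z)] = t_fm_to_emlow.to_params()

    write_store(store, path)
    n_overview = len(sections)
    overview, ov_truth = synthetic.simulate_slide_overview(
        n_sections=min(n_overview, 63),
        seed=synthetic.sub_seed(seed, "overview"),
        noise_sigma=2.0,
    )
    tifffile.imwrite(os.path.join(path, "overview.tif"), overview)
    truth_doc["overview_boxes"] = [list(b) for b in ov_truth.section_boxes]
    with open(os.path.join(path, "truth.json"), "w") as fh3:
        json.dump(truth_doc, fh3, indent=1)


# -------------------------------------------------------------------- stages

def _stage_simulate(cfg: PipelineConfig, report: dict) -> dict:
    path = cfg["store"]
    if cfg["preset"] is None:
        return {"status": "skipped (no preset; using existing store)"}
    if os.path.exists(os.path.join(path, "store.json")) and not cfg["force"]:
        return {"status": "skipped (cached)"}
    build_preset_store(cfg["preset"], path, cfg["seed"])
    return {"status": "ok", "preset": cfg["preset"]}


def _stage_segment(cfg: PipelineConfig, report: dict) -> dict:
    path = cfg["store"]
    src = os.path.join(path, "overview.tif")
    if not os.path.exists(src):
        return {"status": "skipped (no overview image)"}
    out = os.path.join(path, "section_boxes.json")
    if os.path.exists(out) and not cfg["force"]:
        with open(out) as fh:
            return json.load(fh) | {"status": "skipped (cached)"}
    overview = tifffile.imread(src)
    n = cfg["segment"]["n_sections"]
    if n is None:
        truth_path = os.path.join(path, "truth.json")
        if os.path.exists(truth_path):
            with open(truth_path) as fh:
                doc = json.load(fh)
            n = len(doc.get("overview_boxes", [])) or None
    if n is None:
        raise PipelineError("segment: n_sections not configured and not inferable")
    label_map = segment_sections(overview, n, cfg["segment"]["pixel_size_um"])
    boxes_um = boxes_to_stage(label_map)
    tifffile.imwrite(os.path.join(path, "section_labels.tif"), label_map.labels)
    metrics = {
        "status": "ok",
        "n_sections": label_map.n_sections,
        "boxes_px": [list(b) for b in label_map.boxes_px],
        "boxes_um": [list(b) for b in boxes_um],
    }
    with open(out, "w") as fh:
        json.dump({k: v for k, v in metrics.items() if k != "status"}, fh, indent=1)
    return metrics


def _stage_register_cl(cfg: PipelineConfig, report: dict) -> dict:
    path = cfg["store"]
    cl_dir = os.path.join(path, "cl")
    if not os.path.isdir(cl_dir):
        return {"status": "skipped (no CL frames)"}
    out = os.path.join(path, "cl_transforms.json")
    if os.path.exists(out) and not cfg["force"]:
        return {"status": "skipped (cached)"}
    transforms = {}
    for name in sorted(os.listdir(cl_dir)):
        if not name.endswith("_frame.tif"):
            continue
        z = name.split("_")[0].lstrip("z")
        frame = tifffile.imread(os.path.join(cl_dir, name))
        with open(os.path.join(cl_dir, f"z{z}_grid.json")) as fh:
            gdoc = json.load(fh)
        grid = BeamSpotGrid(np.array(gdoc["positions"]), tuple(gdoc["shape"]))
        transforms[str(int(z))] = register_cross_modal(frame, grid).to_params()
    with open(out, "w") as fh:
        json.dump(transforms, fh, indent=1)
    return {"status": "ok", "n_registered": len(transforms)}


def _save_features(path: str, tile_id: str, fs: FeatureSet) -> None:
    os.makedirs(path, exist_ok=True)
    np.savez_compressed(
        os.path.join(path, f"{tile_id}.npz"),
        keypoints=fs.keypoints,
        descriptors=fs.descriptors,
        scales=fs.scales,
        orientations=fs.orientations,
    )


def _load_features(path: str, tile_id: str) -> FeatureSet | None:
    f = os.path.join(path, f"{tile_id}.npz")
    if not os.path.exists(f):
        return None
    with np.load(f) as d:
        return FeatureSet(d["keypoints"], d["descriptors"], d["scales"], d["orientations"])


def _stage_stitch(cfg: PipelineConfig, report: dict) -> dict:
    path = cfg["store"]
    out = os.path.join(path, "stitch_report.json")
    if os.path.exists(out) and not cfg["force"]:
        with open(out) as fh:
            return json.load(fh) | {"status": "skipped (cached)"}
    store = read_store(path)
    feat_dir = os.path.join(path, "features")
    opts = SolverOptions(lam=cfg["stitch"]["lam"], model=cfg["stitch"]["model"])
    per_z = {}
    saved_matches = []
    for z in store.section_indices("em_high"):
        tiles = store.tiles("em_high", z)
        feats = {}
        for t in tiles:
            fs = _load_features(feat_dir, t.tile_id)
            if fs is None:
                fs = extract_features(t.image)
                _save_features(feat_dir, t.tile_id, fs)
            feats[t.tile_id] = fs
        matches = []
        for a, b in candidate_neighbors(tiles):
            m = match_features(
                feats[a], feats[b], tile_id_a=a, tile_id_b=b,
                model=cfg["stitch"]["model"], seed=cfg["seed"],
            )
            if len(m):
                matches.append(m)
        result = solve_montage(tiles, matches, opts)
        for t in tiles:
            t.transform = result.transforms[t.tile_id]
        per_z[str(z)] = {"rms_px": result.rms, "n_match_sets": len(matches)}
        saved_matches.extend(
            {
                "a": m.tile_id_a,
                "b": m.tile_id_b,
                "pairs": m.pairs.tolist(),
                "weights": m.weights.tolist(),
            }
            for m in matches
        )
    write_store(store, path)
    # persist the montage matches so the 3D solve can reuse them as its
    # intra-section constraints
    with open(os.path.join(path, "intra_matches.json"), "w") as fh:
        json.dump(saved_matches, fh)
    metrics = {"status": "ok", "sections": per_z}
    with open(out, "w") as fh:
        json.dump({"sections": per_z}, fh, indent=1)
    return metrics


def _stage_overlay(cfg: PipelineConfig, report: dict) -> dict:
    path = cfg["store"]
    store = read_store(path)
    if not store.tiles("em_low") or not store.tiles("fm"):
        return {"status": "skipped (no FM / EM-low tiles)"}
    out = os.path.join(path, "overlay_report.json")
    if os.path.exists(out) and not cfg["force"]:
        with open(out) as fh:
            return json.load(fh) | {"status": "skipped (cached)"}
    with open(os.path.join(path, "cl_transforms.json")) as fh:
        cl = {int(k): AffineTransform2D.from_params(v) for k, v in json.load(fh).items()}
    per_tile = {}
    roi_world: list = []
    section_areas = []
    for z in store.section_indices("em_low"):
        highmag = store.tiles("em_high", z)
        for low in store.tiles("em_low", z):
            t_cs = register_lowmag_to_montage(low, highmag, seed=cfg["seed"])
            low.transform = t_cs
            chain = OverlayChain(t_fm_to_emlow=cl[z], t_emlow_to_world=t_cs)
            for fm in store.tiles("fm", z):
                updated = overlay_fm(fm, chain)
                fm.transform = updated.transform
                per_tile[fm.tile_id] = {
                    "extrapolated_fraction": extrapolation_fraction(fm, chain, low),
                }
        # ROI selection on this section's FM mosaic (FM-scale render)
        fms = store.tiles("fm", z)
        if fms:
            bbox = world_footprint(fms[0])
            for t in fms[1:]:
                b = world_footprint(t)
                bbox = (min(bbox[0], b[0]), min(bbox[1], b[1]),
                        max(bbox[2], b[2]), max(bbox[3], b[3]))
            mosaic = render_composite(fms, bbox, out_pixel_size_nm=fms[0].pixel_size_nm)
            scale = fms[0].pixel_size_nm / WORLD_PIXEL_SIZE_NM
            t_mosaic = AffineTransform2D(scale, 0, 0, scale, bbox[0], bbox[1])
            rois = roi_select(
                mosaic, t_mosaic,
                strategy=cfg["roi"]["strategy"],
                threshold=cfg["roi"]["threshold"],
                min_area_px=cfg["roi"]["min_area_px"],
            )
            roi_world.extend(rois)
            hm_boxes = [world_footprint(t) for t in store.tiles("em_high", z)]
            if hm_boxes:
                sx0 = min(b[0] for b in hm_boxes); sy0 = min(b[1] for b in hm_boxes)
                sx1 = max(b[2] for b in hm_boxes); sy1 = max(b[3] for b in hm_boxes)
                section_areas.append((sx0, sy0, sx1, sy1))
    write_store(store, path)
    metrics: dict = {"status": "ok", "fm_tiles": per_tile, "n_roi": len(roi_world),
                     "roi_boxes_world": [list(b) for b in roi_world]}
    if roi_world and section_areas:
        metrics["area_reduction_factor"] = area_reduction_factor(
            section_areas[0], roi_world[: 1]
        )
    with open(out, "w") as fh:
        json.dump({k: v for k, v in metrics.items() if k != "status"}, fh, indent=1)
    return metrics


def _stage_align3d(cfg: PipelineConfig, report: dict) -> dict:
    path = cfg["store"]
    store = read_store(path)
    zs = store.section_indices("em_high")
    if len(zs) < 2:
        return {"status": "skipped (single section)"}
    out = os.path.join(path, "align3d_report.json")
    if os.path.exists(out) and not cfg["force"]:
        with open(out) as fh:
            return json.load(fh) | {"status": "skipped (cached)"}
    acfg = cfg["align3d"]
    depth = acfg["depth"]
    plan = build_depth_plan(zs, depth)
    if not plan.connected and acfg["auto_depth"]:
        depth = minimal_connecting_depth(zs)
        plan = build_depth_plan(zs, depth)

    ds = float(acfg["downsample"])
    # keep the rough-alignment renders feature-rich: at least ~128 px a side
    sample = store.tiles("em_high", zs[0])
    sb = [world_footprint(t) for t in sample]
    min_extent = min(
        max(b[2] for b in sb) - min(b[0] for b in sb),
        max(b[3] for b in sb) - min(b[1] for b in sb),
    )
    ds = max(1.0, min(ds, min_extent / 128.0))
    renders: dict[int, np.ndarray] = {}
    offsets: dict[int, np.ndarray] = {}
    for z in zs:
        tiles = store.tiles("em_high", z)
        boxes = [world_footprint(t) for t in tiles]
        bbox = (
            min(b[0] for b in boxes), min(b[1] for b in boxes),
            max(b[2] for b in boxes), max(b[3] for b in boxes),
        )
        renders[z] = render_composite(
            tiles, bbox, out_pixel_size_nm=WORLD_PIXEL_SIZE_NM * ds
        )
        offsets[z] = np.array([bbox[0], bbox[1]])
    rough_r = rough_align_z(renders, downsample_factor=1, seed=cfg["seed"])
    rough_world = {}
    for z in zs:
        a = AffineTransform2D(ds, 0, 0, ds, offsets[z][0], offsets[z][1])
        a0 = AffineTransform2D(ds, 0, 0, ds, offsets[zs[0]][0], offsets[zs[0]][1])
        rough_world[z] = compose(a0, compose(rough_r[z], a.invert()))

    feat_dir = os.path.join(path, "features")
    tiles_by_z = {z: store.tiles("em_high", z) for z in zs}
    features = {}
    for z in zs:
        for t in tiles_by_z[z]:
            fs = _load_features(feat_dir, t.tile_id)
            if fs is not None:
                features[t.tile_id] = fs
    inter = cross_section_matches(
        tiles_by_z, plan, rough_world, features=features, seed=cfg["seed"]
    )
    intra: list[PointMatchSet] = []
    intra_path = os.path.join(path, "intra_matches.json")
    if os.path.exists(intra_path):
        with open(intra_path) as fh:
            intra = [
                PointMatchSet(d["a"], d["b"], np.array(d["pairs"]), np.array(d["weights"]))
                for d in json.load(fh)
            ]
    all_tiles = [t for z in zs for t in tiles_by_z[z]]
    init = {
        t.tile_id: compose(rough_world[t.section_index], t.transform)
        for t in all_tiles
    }
    opts = SolverOptions(lam=acfg["lam"], model=acfg["model"])
    try:
        result = solve_volume(all_tiles, intra=intra, inter=inter, opts=opts, init=init)
    except ConnectivityError as exc:
        raise PipelineError(
            f"align3d: {exc} (depth={depth}; rerun with a larger depth or --auto-depth)"
        ) from exc
    # solved world transforms live beside the store: the montage transforms
    # in store.json stay untouched so every stage keeps its own inputs
    with open(os.path.join(path, "volume_transforms.json"), "w") as fh:
        json.dump(
            {tid: t.to_params() for tid, t in result.transforms.items()}, fh, indent=1
        )
    metrics = {
        "status": "ok",
        "depth": depth,
        "connected": plan.connected or acfg["auto_depth"],
        "n_inter_match_sets": len(inter),
        "rms_px": result.rms,
        "n_sections": len(zs),
    }
    with open(out, "w") as fh:
        json.dump({k: v for k, v in metrics.items() if k != "status"}, fh, indent=1)
    return metrics


def _stage_export(cfg: PipelineConfig, report: dict) -> dict:
    path = cfg["store"]
    out = os.path.join(path, "volume.tif")
    if os.path.exists(out) and not cfg["force"]:
        return {"status": "skipped (cached)"}
    store = read_store(path)
    zs = store.section_indices("em_high")
    if not zs:
        return {"status": "skipped (nothing to export)"}
    vt_path = os.path.join(path, "volume_transforms.json")
    if os.path.exists(vt_path):
        with open(vt_path) as fh:
            solved = {k: AffineTransform2D.from_params(v) for k, v in json.load(fh).items()}
        for t in store.tiles("em_high"):
            if t.tile_id in solved:
                t.transform = solved[t.tile_id]
    ds = float(cfg["export"]["downsample"])
    boxes = [world_footprint(t) for z in zs for t in store.tiles("em_high", z)]
    bbox = (
        min(b[0] for b in boxes), min(b[1] for b in boxes),
        max(b[2] for b in boxes), max(b[3] for b in boxes),
    )
    planes = [
        render_composite(
            store.tiles("em_high", z), bbox, out_pixel_size_nm=WORLD_PIXEL_SIZE_NM * ds
        ).astype(np.float32)
        for z in zs
    ]
    stack = np.stack(planes)
    tifffile.imwrite(
        out, stack, imagej=True,
        metadata={"spacing": store.metadata["section_thickness_nm"] / 1000.0,
                  "unit": "um", "axes": "ZYX"},
    )
    return {"status": "ok", "z_planes": len(zs), "shape": list(stack.shape)}


_STAGE_FN = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "register_cl": _stage_register_cl,
    "stitch": _stage_stitch,
    "overlay": _stage_overlay,
    "align3d": _stage_align3d,
    "export": _stage_export,
}


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Run all enabled stages in order; abort on the first failure with the
    stage name, persisting partial state. Returns (and writes) the run
    report: per-stage status and metrics, with the config echoed."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    path = config["store"]
    os.makedirs(path, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config["log_level"], logging.INFO))
    log_path = os.path.join(path, "run.log")
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    report: dict = {"config": config.values, "stages": {}}
    try:
        for stage in STAGE_ORDER:
            if not config["stages"].get(stage, True):
                report["stages"][stage] = {"status": "skipped (disabled)"}
                continue
            logger.info("stage %s: start", stage)
            try:
                report["stages"][stage] = _STAGE_FN[stage](config, report)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
            logger.info("stage %s: %s", stage, report["stages"][stage]["status"])
    finally:
        with open(os.path.join(path, "report.json"), "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        logger.removeHandler(handler)
        handler.close()
    return report
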