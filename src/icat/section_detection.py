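"""Serial-section detection on the slide-overview image.

The ultramicrotome deposits a ribbon of ~100 nm sections on an ITO-coated
glass slide; a digital light microscope images the whole slide at low
magnification (~7 μm px⁻¹). Each section must be found and labelled so its
stage-coordinate bounding box can be handed to the microscope for
navigation.

The segmentation routine is marker-controlled watershed with a fixed
pipeline order: (i) input RGB overview, (ii) contrast stretch + grayscale,
(iii) intensity threshold → binary mask, (iv) gradient magnitude of the
masked grayscale, (v) one marker per expected section at deep gradient
minima (plus one background marker), (vi) watershed flood of the gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import color, filters, segmentation

from .errors import SectionDetectionError

__all__ = ["SectionLabelMap", "segment_sections", "boxes_to_stage"]


@dataclass
class SectionLabelMap:
    """Labelled overview raster plus per-section bounding boxes.

    ``labels`` uses 0 for background and 1..n for sections. Boxes are
    (x0, y0, x1, y1) with exclusive upper edges, in overview pixels;
    :meth:`boxes_um` converts through the overview pixel size.
    """

    labels: np.ndarray
    n_sections: int
    boxes_px: list[tuple[int, int, int, int]]
    pixel_size_um: float

    def boxes_um(self, origin_um: tuple[float, float] = (0.0, 0.0)) -> list[tuple]:
        out = []
        for x0, y0, x1, y1 in self.boxes_px:
            out.append(
                (
                    x0 * self.pixel_size_um + origin_um[0],
                    y0 * self.pixel_size_um + origin_um[1],
                    x1 * self.pixel_size_um + origin_um[0],
                    y1 * self.pixel_size_um + origin_um[1],
                )
            )
        return out


def _to_gray(overview: np.ndarray) -> np.ndarray:
    img = np.asarray(overview)
    if img.ndim == 3:
        gray = color.rgb2gray(img)  # float in [0, 1]
    else:
        gray = img.astype(float)
        if gray.max() > 1.0:
            gray = gray / 255.0
    return gray


def _contrast_stretch(gray: np.ndarray) -> np.ndarray:
    # linear 1st–99th percentile stretch; a light Gaussian tames sensor noise
    p1, p99 = np.percentile(gray, (1, 99))
    if p99 - p1 > 1e-9:
        gray = np.clip((gray - p1) / (p99 - p1), 0.0, 1.0)
    return ndi.gaussian_filter(gray, 1.0)


def _place_markers(
    mask: np.ndarray, gradient: np.ndarray, n_sections: int, min_distance: int
) -> np.ndarray:
    """Pick one marker per section: candidates are in-mask pixels in the
    lowest gradient quartile, ranked by distance from the mask boundary
    (resolves the flat-plateau ties inside uniform sections), selected
    greedily under a minimum pairwise separation."""
    dist = ndi.distance_transform_edt(mask)
    in_mask = gradient[mask]
    if in_mask.size == 0:
        raise SectionDetectionError("insufficient distinct sections: empty mask")
    # tolerance absorbs float noise in "flat" plateaus (sobel of a constant
    # region is ~1e-17, not exactly 0)
    low_thresh = np.percentile(in_mask, 25) + 1e-6 * max(float(gradient.max()), 1e-12)
    low = mask & (gradient <= low_thresh)
    ys, xs = np.nonzero(low)
    if ys.size == 0:
        raise SectionDetectionError("insufficient distinct sections: no gradient minima")
    order = np.argsort(-dist[ys, xs], kind="stable")
    chosen: list[tuple[int, int]] = []
    md2 = float(min_distance) ** 2
    for idx in order:
        y, x = int(ys[idx]), int(xs[idx])
        if all((y - cy) ** 2 + (x - cx) ** 2 >= md2 for cy, cx in chosen):
            chosen.append((y, x))
            if len(chosen) == n_sections:
                break
    if len(chosen) < n_sections:
        raise SectionDetectionError(
            f"insufficient distinct sections: found {len(chosen)} marker "
            f"candidates, need {n_sections}"
        )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for lab, (y, x) in enumerate(chosen, start=1):
        markers[y, x] = lab
    # one background marker at the point farthest from any section
    bg_dist = ndi.distance_transform_edt(~mask)
    by, bx = np.unravel_index(np.argmax(bg_dist), mask.shape)
    markers[by, bx] = n_sections + 1
    return markers


def segment_sections(
    overview: np.ndarray,
    n_sections: int,
    overview_pixel_size_um: float = 7.0,
    markers: list[tuple[int, int]] | None = None,
    min_marker_distance: int | None = None,
) -> SectionLabelMap:
    """Detect and label ``n_sections`` serial sections on the slide overview.

    Parameters
    ----------
    overview : RGB or grayscale raster, at least 64×64.
    n_sections : number of sections present (= number of watershed markers).
    overview_pixel_size_um : overview pixel size (~7 μm px⁻¹ at 30×).
    markers : optional user-supplied (y, x) marker positions, one per
        section, overriding automatic seeding.
    min_marker_distance : minimum separation between automatic markers;
        default ~half the expected section diameter.
    """
    if n_sections < 1:
        raise SectionDetectionError("n_sections must be >= 1")
    overview = np.asarray(overview)
    if overview.shape[0] < 64 or overview.shape[1] < 64:
        raise SectionDetectionError("overview must be larger than 64x64")

    gray = _contrast_stretch(_to_gray(overview))
    thresh = filters.threshold_otsu(gray)
    mask = gray > thresh
    if not mask.any():
        raise SectionDetectionError("insufficient distinct sections: empty mask")

    gradient = filters.sobel(gray * mask)

    if markers is not None:
        if len(markers) != n_sections:
            raise SectionDetectionError(
                f"need {n_sections} markers, got {len(markers)}"
            )
        marker_img = np.zeros(mask.shape, dtype=np.int32)
        for lab, (y, x) in enumerate(markers, start=1):
            marker_img[int(y), int(x)] = lab
        bg_dist = ndi.distance_transform_edt(~mask)
        by, bx = np.unravel_index(np.argmax(bg_dist), mask.shape)
        marker_img[by, bx] = n_sections + 1
    else:
        if min_marker_distance is None:
            min_marker_distance = max(3, int(round(0.5 * np.sqrt(mask.sum() / n_sections))))
        marker_img = _place_markers(mask, gradient, n_sections, min_marker_distance)

    labels = segmentation.watershed(gradient, marker_img, connectivity=1)
    labels[labels == n_sections + 1] = 0
    labels *= mask  # basins stop at the thresholded section outlines

    present = np.unique(labels)
    present = present[present > 0]
    if len(present) != n_sections:
        raise SectionDetectionError(
            f"insufficient distinct sections: watershed produced "
            f"{len(present)} labels, expected {n_sections}"
        )

    boxes: list[tuple[int, int, int, int]] = []
    slices = ndi.find_objects(labels)
    for lab in range(1, n_sections + 1):
        sl = slices[lab - 1]
        if sl is None:
            raise SectionDetectionError(f"label {lab} vanished during watershed")
        boxes.append((sl[1].start, sl[0].start, sl[1].stop, sl[0].stop))
    return SectionLabelMap(
        labels=labels.astype(np.int32),
        n_sections=n_sections,
        boxes_px=boxes,
        pixel_size_um=float(overview_pixel_size_um),
    )


def boxes_to_stage(
    label_map: SectionLabelMap, overview_origin_um: tuple[float, float] = (0.0, 0.0)
) -> list[tuple[float, float, float, float]]:
    """Convert per-section pixel boxes to stage-frame μm boxes:
    ``box_stage = box_px · pixel_size + origin``, in label order."""
    return label_map.boxes_um(overview_origin_um)
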