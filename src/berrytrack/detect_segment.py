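"""Detection and segmentation plumbing around pluggable predictors.

The trained detector (boxes on 416x416 tiles) and segmenter (binary
masks on 128x128 vignettes) are plug-ins behind
:class:`PredictorInterface`; this module owns everything around them:
tile planning over the full image, merging and de-duplicating tile
detections, confidence filtering, vignette cropping and the
mask-to-ellipse back-projection.  An oracle predictor driven by
simulator ground truth stands in for trained weights in tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Protocol

import numpy as np
from skimage import measure
from skimage.transform import resize

from berrytrack.geometry import Box, Ellipse, EllipseFitError, ellipse_to_bbox, fit_ellipse

__all__ = [
    "TILE_SIZE",
    "MAX_TILE_SPACING",
    "NMS_IOU",
    "CONFIDENCE_THRESHOLD",
    "VIGNETTE_SIZE",
    "ZOOM_FACTOR",
    "TilePlan",
    "VignetteTransform",
    "PredictorInterface",
    "OraclePredictor",
    "plan_tiles",
    "nms",
    "filter_confidence",
    "crop_vignette",
    "mask_to_ellipse",
    "run_frame",
]

logger = logging.getLogger(__name__)

TILE_SIZE = 416          # detector input side (px)
MAX_TILE_SPACING = 270   # maximum offset between consecutive tiles (px)
NMS_IOU = 0.70           # box pairs above this IoU are redundant
CONFIDENCE_THRESHOLD = 0.89  # detector score threshold s
VIGNETTE_SIZE = 128      # segmenter input side (px)
ZOOM_FACTOR = 0.75       # z: box side / vignette crop side ratio


@dataclass(frozen=True)
class TilePlan:
    """Grid of tile top-left corners covering the whole image."""

    offsets: tuple[tuple[int, int], ...]  # (col, row) top-left corners
    tile_size: int = TILE_SIZE


@dataclass(frozen=True)
class VignetteTransform:
    """Invertible map between image and 128x128 vignette coordinates."""

    crop_center: tuple[float, float]  # (col, row) in image coords
    crop_size: int                    # square crop side, px, before resize
    scale: float                      # VIGNETTE_SIZE / crop_size
    crop_origin: tuple[int, int]      # integer (col, row) of crop top-left

    def to_image(self, cols, rows):
        """Vignette (col, row) -> image (col, row)."""
        c0, r0 = self.crop_origin
        return (np.asarray(cols) / self.scale + c0, np.asarray(rows) / self.scale + r0)

    def to_vignette(self, cols, rows):
        c0, r0 = self.crop_origin
        return ((np.asarray(cols) - c0) * self.scale, (np.asarray(rows) - r0) * self.scale)


class PredictorInterface(Protocol):
    """Contract for pluggable detection/segmentation models.

    ``detect`` receives one RGB tile plus its (col, row) offset in the
    frame and returns boxes in *tile* coordinates with confidence
    scores.  ``segment`` receives one 128x128 RGB vignette plus the
    transform that produced it and returns a 128x128 binary mask of the
    full (de-occluded) berry shape in vignette coordinates.
    """

    def detect(self, tile: np.ndarray, offset: tuple[int, int]) -> list[Box]: ...

    def segment(self, vignette: np.ndarray, transform: VignetteTransform) -> np.ndarray: ...


def plan_tiles(image_height: int, image_width: int, tile_size: int = TILE_SIZE,
               max_spacing: int = MAX_TILE_SPACING) -> TilePlan:
    """Tile offsets covering every pixel with bounded spacing.

    Offsets include 0 and ``dim - tile_size`` on each axis; consecutive
    offsets differ by at most ``max_spacing`` px so that any berry is
    fully inside at least one tile.  Images smaller than one tile are
    handled by a single (0, 0) tile with zero padding at crop time.
    """
    if image_height <= 0 or image_width <= 0:
        raise ValueError("image dimensions must be positive")

    def axis_offsets(dim: int) -> list[int]:
        last = max(dim - tile_size, 0)
        if last == 0:
            return [0]
        n = int(np.ceil(last / max_spacing)) + 1
        return [int(round(v)) for v in np.linspace(0, last, n)]

    cols = axis_offsets(image_width)
    rows = axis_offsets(image_height)
    offsets = tuple((c, r) for r in rows for c in cols)
    return TilePlan(offsets=offsets, tile_size=tile_size)


def nms(boxes: list[Box], iou_max: float = NMS_IOU) -> list[Box]:
    """Greedy non-maximum suppression by descending score.

    Any surviving pair of boxes has IoU <= ``iou_max``.
    """
    order = sorted(range(len(boxes)), key=lambda i: (-(boxes[i].score or 0.0), i))
    kept: list[Box] = []
    for i in order:
        if all(boxes[i].iou(k) <= iou_max for k in kept):
            kept.append(boxes[i])
    return kept


def filter_confidence(boxes: list[Box], s: float = CONFIDENCE_THRESHOLD) -> list[Box]:
    """Drop boxes whose confidence is below the threshold ``s``."""
    return [b for b in boxes if b.score is not None and b.score >= s]


def _crop_padded(image: np.ndarray, c0: int, r0: int, side: int) -> np.ndarray:
    """Square crop with zero padding outside the frame."""
    out_shape = (side, side) + image.shape[2:]
    out = np.zeros(out_shape, dtype=image.dtype)
    r1, c1 = r0 + side, c0 + side
    sr0, sc0 = max(r0, 0), max(c0, 0)
    sr1, sc1 = min(r1, image.shape[0]), min(c1, image.shape[1])
    if sr1 > sr0 and sc1 > sc0:
        out[sr0 - r0:sr1 - r0, sc0 - c0:sc1 - c0] = image[sr0:sr1, sc0:sc1]
    return out


def crop_vignette(image: np.ndarray, box: Box,
                  zoom: float = ZOOM_FACTOR,
                  size: int = VIGNETTE_SIZE) -> tuple[np.ndarray, VignetteTransform]:
    """Square crop of side max(w_b, h_b)/z around the box centre, resized
    to ``size`` x ``size`` by bilinear interpolation.

    Out-of-frame area is zero-padded; the returned transform is exactly
    invertible (it stores the integer crop origin and the resize scale).
    """
    side = max(1, int(round(max(box.w_b, box.h_b) / zoom)))
    c0 = int(round(box.x_b - side / 2.0))
    r0 = int(round(box.y_b - side / 2.0))
    crop = _crop_padded(image, c0, r0, side)
    vignette = resize(crop, (size, size), order=1, preserve_range=True,
                      anti_aliasing=False).astype(image.dtype)
    t = VignetteTransform(crop_center=(box.x_b, box.y_b), crop_size=side,
                          scale=size / side, crop_origin=(c0, r0))
    return vignette, t


class SegmentationError(RuntimeError):
    """Per-berry failure during mask post-processing (berry skipped)."""


def mask_to_ellipse(mask: np.ndarray, t: VignetteTransform,
                    min_pixels: int = 20) -> Ellipse:
    """Fit an ellipse to the largest component of a binary vignette mask
    and map its parameters back to image coordinates.

    Raises :class:`SegmentationError` on an empty/too-small mask or on
    ellipse-fit failure; callers skip the berry and log the reason.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.sum() < min_pixels:
        raise SegmentationError(f"mask has fewer than {min_pixels} foreground px")
    labels = measure.label(mask)
    if labels.max() > 1:
        counts = np.bincount(labels.ravel())[1:]
        mask = labels == (int(np.argmax(counts)) + 1)
        if mask.sum() < min_pixels:
            raise SegmentationError("largest component below minimum size")
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise SegmentationError("no contour found")
    contour = max(contours, key=len)  # (row, col) order from skimage
    pts = contour[:, ::-1]            # -> (col, row)
    try:
        e_vig = fit_ellipse(pts)
    except EllipseFitError as exc:
        raise SegmentationError(f"ellipse fit failed: {exc}") from exc
    xc, yc = t.to_image(e_vig.x_e, e_vig.y_e)
    return Ellipse(float(xc), float(yc), e_vig.w_e / t.scale, e_vig.h_e / t.scale,
                   e_vig.a_e)


@dataclass
class FrameDetection:
    """One segmented berry in one frame (geometry + confidence)."""

    ellipse: Ellipse
    score: float


def _box_inside_tile(b: Box, tile_size: int) -> bool:
    x0, y0, x1, y1 = b.bounds
    return x0 >= 0 and y0 >= 0 and x1 <= tile_size and y1 <= tile_size


def run_frame(image: np.ndarray, predictor: PredictorInterface,
              confidence_threshold: float = CONFIDENCE_THRESHOLD,
              nms_iou: float = NMS_IOU) -> list[FrameDetection]:
    """Full single-frame pipeline: tiles -> detect -> merge -> NMS ->
    confidence filter -> per-box vignette segmentation -> ellipses.

    Tile-level boxes clipped by a tile edge are discarded before the
    merge; the overlap between neighbouring tiles guarantees that every
    berry is fully contained in at least one tile.  The confidence
    threshold is a property of the plugged detector's score scale
    (0.89 for the trained detector; 0.5 when the oracle predictor
    reports visibility fractions as scores).
    """
    h, w = image.shape[:2]
    plan = plan_tiles(h, w)
    merged: list[Box] = []
    for (c0, r0) in plan.offsets:
        tile = _crop_padded(image, c0, r0, plan.tile_size)
        for b in predictor.detect(tile, (c0, r0)):
            if _box_inside_tile(b, plan.tile_size):
                merged.append(Box(b.x_b + c0, b.y_b + r0, b.w_b, b.h_b, b.score))
    surviving = filter_confidence(nms(merged, iou_max=nms_iou), s=confidence_threshold)
    out: list[FrameDetection] = []
    for box in surviving:
        vignette, t = crop_vignette(image, box)
        mask = predictor.segment(vignette, t)
        try:
            ellipse = mask_to_ellipse(mask, t)
        except SegmentationError as exc:
            logger.warning("berry at (%.0f, %.0f) skipped: %s", box.x_b, box.y_b, exc)
            continue
        out.append(FrameDetection(ellipse=ellipse, score=float(box.score or 0.0)))
    return out


class OraclePredictor:
    """Ground-truth-driven predictor for simulator renders.

    Emulates the behaviour the trained models are optimised for:
    ``detect`` returns the enclosing boxes of berries whose visible
    contour fraction is at least 0.5 (score = visibility), and
    ``segment`` returns the rasterized *complete* ground-truth ellipse
    mask — the shape of the berry as if it were not occluded.
    """

    def __init__(self, ellipses: list[Ellipse], visibilities: list[float],
                 min_visibility: float = 0.5):
        self.ellipses = list(ellipses)
        self.visibilities = [float(v) for v in visibilities]
        self.min_visibility = min_visibility

    def detect(self, tile: np.ndarray, offset: tuple[int, int]) -> list[Box]:
        c0, r0 = offset
        boxes = []
        for e, vis in zip(self.ellipses, self.visibilities):
            if vis < self.min_visibility:
                continue
            b = ellipse_to_bbox(e, score=vis)
            boxes.append(Box(b.x_b - c0, b.y_b - r0, b.w_b, b.h_b, score=vis))
        return boxes

    def segment(self, vignette: np.ndarray, transform: VignetteTransform) -> np.ndarray:
        # the berry this vignette belongs to = nearest ground-truth centre
        cx, cy = transform.crop_center
        candidates = [
            (abs(e.x_e - cx) + abs(e.y_e - cy), i)
            for i, (e, vis) in enumerate(zip(self.ellipses, self.visibilities))
            if vis >= self.min_visibility
        ]
        if not candidates:
            return np.zeros((VIGNETTE_SIZE, VIGNETTE_SIZE), dtype=bool)
        _, idx = min(candidates)
        e = self.ellipses[idx]
        cols, rows = np.meshgrid(np.arange(VIGNETTE_SIZE), np.arange(VIGNETTE_SIZE))
        icols, irows = transform.to_image(cols + 0.5, rows + 0.5)
        return e.contains(icols, irows)
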