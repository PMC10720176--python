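"""Per-berry colour and size features.

Hue is expressed throughout on a half-circle 0-180 degree scale (the
standard 0-360 hue divided by two), which makes the centring formula
H = (180 - h_raw - h_50) mod 180 well defined.  Size features reduce
the fitted ellipse to a projected area A and the volume V of the
sphere with the same projected area; a constant chessboard-derived
calibration factor converts px^3 to mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from berrytrack.geometry import Ellipse, ellipse_to_bbox

__all__ = [
    "H50",
    "ML_PER_PX3",
    "BerryObservation",
    "FeatureError",
    "berry_pixel_set",
    "circular_mean_hue",
    "centred_hue",
    "projected_area",
    "sphere_volume",
    "extract_features",
    "image_hue",
]

#: mean raw hue of berries halfway through their colour change (degrees)
H50 = 100.0
#: chessboard calibration: mL per cubic pixel
ML_PER_PX3 = 3.94e-6


class FeatureError(RuntimeError):
    """Per-berry feature failure (e.g. no pixel left for hue)."""


@dataclass
class BerryObservation:
    """One segmented berry in one frame, with extracted features."""

    frame: int
    time: float           # days since series start
    ellipse: Ellipse
    score: float
    h_raw: float | None = None   # raw hue, degrees on the 0-180 scale
    H: float | None = None       # centred hue, degrees in [0, 180)
    A: float | None = None       # projected area, px^2
    V: float | None = None       # sphere-equivalent volume, px^3
    V_mL: float | None = None
    label: int = -1              # tracking label; -1 = unlabeled


def edge_margin(e: Ellipse) -> float:
    """Pixels near the ellipse edge excluded from hue: dp = max(3, w_e/4)."""
    return max(3.0, e.w_e / 4.0)


def berry_pixel_set(e: Ellipse, others: list[Ellipse],
                    image_shape: tuple[int, int]) -> np.ndarray:
    """Pixel (col, row) coordinates used for the berry's hue.

    Keeps pixels strictly inside ``e`` that are at least
    dp = max(3, w_e/4) px away from its edge and inside no other
    ellipse of the frame.  Distances are computed on the rasterized
    ellipse mask with an exact Euclidean distance transform.
    """
    h_img, w_img = image_shape[:2]
    bb = ellipse_to_bbox(e)
    c0 = max(int(math.floor(bb.x_b - bb.w_b / 2)) - 1, 0)
    r0 = max(int(math.floor(bb.y_b - bb.h_b / 2)) - 1, 0)
    c1 = min(int(math.ceil(bb.x_b + bb.w_b / 2)) + 2, w_img)
    r1 = min(int(math.ceil(bb.y_b + bb.h_b / 2)) + 2, h_img)
    if c1 <= c0 or r1 <= r0:
        raise FeatureError("ellipse entirely outside the image")
    cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    inside = e.contains(cols, rows)
    if not inside.any():
        raise FeatureError("rasterized ellipse is empty")
    dist = ndimage.distance_transform_edt(inside)
    keep = dist >= edge_margin(e)
    for other in others:
        if not keep.any():
            break
        keep &= ~other.contains(cols, rows)
    if not keep.any():
        raise FeatureError("no pixel left after edge/overlap exclusion")
    return np.column_stack([cols[keep], rows[keep]])


def circular_mean_hue(hues) -> float:
    """Circular mean of hue values on the 180-degree-period scale."""
    h = np.asarray(hues, dtype=float)
    if h.size == 0:
        raise FeatureError("empty hue set")
    ang = np.deg2rad(h * 2.0)  # unfold to the full circle
    s, c = np.sin(ang).mean(), np.cos(ang).mean()
    if math.hypot(s, c) < 1e-9:
        raise FeatureError("undefined circular mean (balanced hues)")
    return float(np.rad2deg(math.atan2(s, c)) / 2.0 % 180.0)


def centred_hue(h_raw: float, h_50: float = H50) -> float:
    """Centred berry hue H = (180 - h_raw - h_50) mod 180, in [0, 180)."""
    return float((180.0 - h_raw - h_50) % 180.0)


def projected_area(e: Ellipse) -> float:
    """Projected area of the fitted ellipse: A = (w_e/2)(h_e/2)pi."""
    return (e.w_e / 2.0) * (e.h_e / 2.0) * math.pi


def sphere_volume(A: float, printed_form: bool = False) -> float:
    """Volume of the sphere whose cross-section area is A.

    V = (4pi/3) (A/pi)^(3/2): the radius of that sphere is sqrt(A/pi).
    ``printed_form=True`` evaluates (4pi/3)(A/pi)^(1/3) instead, a
    dimensionally inconsistent variant kept for comparison with other
    reports of the same transform.
    """
    if A <= 0:
        raise ValueError("area must be positive")
    exponent = 1.0 / 3.0 if printed_form else 1.5
    return (4.0 * math.pi / 3.0) * (A / math.pi) ** exponent


def image_hue(image: np.ndarray) -> np.ndarray:
    """Per-pixel hue of an 8-bit RGB image on the 0-180 degree scale."""
    from skimage.color import rgb2hsv

    hsv = rgb2hsv(image[..., :3])
    return hsv[..., 0] * 180.0


def extract_features(obs: BerryObservation, frame_ellipses: list[Ellipse],
                     hue_map: np.ndarray | None = None) -> BerryObservation:
    """Fill A, V, V_mL and (when an image hue map is given) h_raw and H.

    ``frame_ellipses`` is the frame's full ellipse list; pixels shared
    with other berries are excluded from the hue computation.  Hue
    failures leave h_raw/H unset (the berry keeps its size features).
    """
    e = obs.ellipse
    obs.A = projected_area(e)
    obs.V = sphere_volume(obs.A)
    obs.V_mL = obs.V * ML_PER_PX3
    if hue_map is not None:
        others = [o for o in frame_ellipses if o is not e]
        try:
            pix = berry_pixel_set(e, others, hue_map.shape[:2])
            obs.h_raw = circular_mean_hue(hue_map[pix[:, 1], pix[:, 0]])
            obs.H = centred_hue(obs.h_raw)
        except FeatureError:
            obs.h_raw = None
            obs.H = None
    return obs
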