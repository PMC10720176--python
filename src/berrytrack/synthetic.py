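"""Ground-truthed time-lapse bunch simulator.

Generates a 2D bunch of overlapping elliptical berries with persistent
identities, per-berry asynchronous sigmoid growth (about +60% volume
over an 18-day 15-85% rise by default), a green-to-dark hue transition
lagging growth resumption, per-frame affine camera jitter, optional
abrupt events (rigid rotations, non-affine rearrangements) and
depth-order occlusion.  Frames are sampled every 8 h by default, the
median interval of indoor phenotyping-platform acquisitions.

The simulator is 2D with a depth order rather than a true 3D scene;
that is sufficient to create the occlusion/visibility regimes the
pipeline must handle.  Visibility is the fraction of a berry's boundary
arc not covered by shallower berries, matching the "at least 50% of
contours visible" measurability criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from berrytrack.geometry import Ellipse

__all__ = ["SimConfig", "GroundTruth", "FrameRecord", "BerryTruth",
           "simulate", "render", "scenario_library"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; the seed fully determines the output."""

    n_berries: int = 60
    n_frames: int = 100
    step_hours: float = 8.0
    # layout
    image_size: tuple[int, int] = (2048, 2448)   # (height, width) px
    cluster_spread: float = 300.0                # std of berry centres (px)
    radius_range: tuple[float, float] = (22.0, 34.0)  # initial semi-minor (px)
    aspect_range: tuple[float, float] = (1.0, 1.25)   # h_e / w_e
    min_centre_spacing: float = 40.0             # rejection-sampling spacing (px)
    # growth: plateau -> logistic -> plateau on volume
    onset_mean_days: float = 6.0
    onset_spread_days: float = 2.0               # uniform half-width around the mean
    rise_days: float = 18.0                      # 15-85% rise duration of the volume logistic
    rise_spread_days: float = 0.0
    amplitude: float = 0.6                       # (V_max - V_0) / V_0
    amplitude_spread: float = 0.0
    shrivel_fraction: float = 0.0                # fraction of berries shrivelling after peak
    shrivel_rate: float = 0.005                  # relative volume loss per day
    # colour (hue on the 0-180 half-circle scale)
    hue_start: float = 80.0                      # green
    hue_end: float = 170.0                       # dark red-violet (reached through 0)
    hue_lag_days: float = 4.0                    # coloration onset lag after growth onset
    hue_rise_days: float = 8.0
    # per-frame camera jitter (absolute, around the cluster centre)
    jitter_shift: float = 0.0                    # max |translation| per axis (px)
    jitter_rot_deg: float = 0.0                  # max |rotation| (deg)
    jitter_scale: float = 0.0                    # max |scale - 1|
    # events: frame -> ("rotation", deg) or ("shuffle", None); persistent from that frame on
    events: tuple[tuple[int, str, float | None], ...] = ()
    measurement_noise: float = 0.0               # relative sd on rendered-free radius readout
    seed: int = 0

    def __post_init__(self):
        if self.n_berries < 1 or self.n_frames < 1:
            raise ValueError("need at least one berry and one frame")
        if self.rise_days <= 0 or self.hue_rise_days <= 0:
            raise ValueError("rise durations must be positive")


@dataclass
class BerryTruth:
    """Per-berry latent kinetics parameters."""

    berry_id: int
    onset_days: float        # time of V_s = 0.15 (growth resumption)
    rise_days: float         # 15-85% rise duration -> true RD = rise/0.7
    amplitude: float         # (V_max - V_0)/V_0
    hue_onset_days: float    # time of H_s = 0.15 (coloration start)
    shrivels: bool
    base_radius: float
    aspect: float
    angle: float
    depth: int               # 0 = closest to the camera


@dataclass
class FrameRecord:
    """Ground truth of one frame."""

    frame: int
    time_days: float
    ellipses: list[Ellipse]
    true_ids: list[int]
    visibility: list[float]
    hues: list[float]


@dataclass
class GroundTruth:
    config: SimConfig
    berries: list[BerryTruth]
    frames: list[FrameRecord]


_LOGISTIC_K = 2.0 * math.log(0.85 / 0.15)  # rise_days * k = this constant


def _logistic(t, mid, rise):
    """Sigmoid from 0 to 1 whose 15-85% rise takes ``rise`` days."""
    k = _LOGISTIC_K / rise
    return 1.0 / (1.0 + np.exp(-k * (np.asarray(t, dtype=float) - mid)))


def volume_curve(t, onset, rise, amplitude, shrivels=False, shrivel_rate=0.0):
    """Relative volume V(t)/V_0: plateau, logistic rise, optional shrivel."""
    mid = onset + rise / 2.0  # onset is the 15% crossing of the scaled curve
    v = 1.0 + amplitude * _logistic(t, mid, rise)
    if shrivels and shrivel_rate > 0:
        t = np.asarray(t, dtype=float)
        peak = mid + rise  # effectively at plateau
        decline = np.clip(t - peak, 0.0, None) * shrivel_rate * (1.0 + amplitude)
        v = v - decline
    return v


def hue_curve(t, hue_onset, rise, hue_start, hue_end):
    """Raw hue (0-180 scale): circular descent from green through red.

    The path runs from ``hue_start`` downward through 0 and wraps to
    ``hue_end``, which makes the centred hue H increase monotonically.
    """
    end_unwrapped = hue_end - 180.0 if hue_end > hue_start else hue_end
    mid = hue_onset + rise / 2.0
    h = hue_start + (end_unwrapped - hue_start) * _logistic(t, mid, rise)
    return np.mod(h, 180.0)


def _sample_layout(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Berry centres around the image centre, loosely spaced."""
    h, w = cfg.image_size
    centre = np.array([w / 2.0, h / 2.0])
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < cfg.n_berries and attempts < 10000 * cfg.n_berries:
        p = centre + rng.normal(0.0, cfg.cluster_spread, 2)
        attempts += 1
        if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < cfg.min_centre_spacing:
            continue
        pts.append(p)
    if len(pts) < cfg.n_berries:  # dense config: give up on spacing
        while len(pts) < cfg.n_berries:
            pts.append(centre + rng.normal(0.0, cfg.cluster_spread, 2))
    return np.array(pts)


def _frame_affine(cfg: SimConfig, rng: np.random.Generator, frame: int,
                  active_rotation: float) -> tuple[np.ndarray, np.ndarray]:
    """Affine (A, b) applied to all berry centres of one frame, about the
    image centre: persistent event rotation composed with i.i.d. jitter."""
    rot = math.radians(active_rotation + rng.uniform(-cfg.jitter_rot_deg,
                                                     cfg.jitter_rot_deg))
    scale = 1.0 + rng.uniform(-cfg.jitter_scale, cfg.jitter_scale)
    shift = rng.uniform(-cfg.jitter_shift, cfg.jitter_shift, 2)
    A = scale * np.array([[math.cos(rot), -math.sin(rot)],
                          [math.sin(rot), math.cos(rot)]])
    h, w = cfg.image_size
    c = np.array([w / 2.0, h / 2.0])
    b = c - A @ c + shift
    return A, b


def _boundary_visibility(ellipses: list[Ellipse], depths: np.ndarray,
                         n_arc: int = 64) -> list[float]:
    """Fraction of each berry's boundary not covered by shallower berries."""
    vis = []
    for i, e in enumerate(ellipses):
        pts = e.boundary_points(n_arc)
        covered = np.zeros(len(pts), dtype=bool)
        for j, other in enumerate(ellipses):
            if j == i or depths[j] >= depths[i]:
                continue
            covered |= other.contains(pts[:, 0], pts[:, 1])
        vis.append(1.0 - covered.mean())
    return vis


def simulate(config: SimConfig) -> GroundTruth:
    """Run the simulator; same config (incl. seed) -> identical output."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    centres = _sample_layout(cfg, rng)
    depths = rng.permutation(cfg.n_berries)

    berries = []
    for i in range(cfg.n_berries):
        onset = cfg.onset_mean_days + rng.uniform(-cfg.onset_spread_days,
                                                  cfg.onset_spread_days)
        rise = max(cfg.rise_days + rng.uniform(-cfg.rise_spread_days,
                                               cfg.rise_spread_days), 1.0)
        amp = max(cfg.amplitude + rng.uniform(-cfg.amplitude_spread,
                                              cfg.amplitude_spread), 0.05)
        berries.append(BerryTruth(
            berry_id=i,
            onset_days=onset,
            rise_days=rise,
            amplitude=amp,
            hue_onset_days=onset + cfg.hue_lag_days,
            shrivels=bool(rng.random() < cfg.shrivel_fraction),
            base_radius=rng.uniform(*cfg.radius_range),
            aspect=rng.uniform(*cfg.aspect_range),
            angle=rng.uniform(0.0, 180.0),
            depth=int(depths[i]),
        ))

    events = {f: (kind, value) for f, kind, value in cfg.events}
    active_rotation = 0.0
    frames = []
    for f in range(cfg.n_frames):
        if f in events:
            kind, value = events[f]
            if kind == "rotation":
                active_rotation = float(value or 0.0)
            elif kind == "shuffle":
                centres = _sample_layout(cfg, rng)
            else:
                raise ValueError(f"unknown event kind {kind!r}")
        t_days = f * cfg.step_hours / 24.0
        A, b = _frame_affine(cfg, rng, f, active_rotation)
        moved = centres @ A.T + b
        scale_f = float(np.sqrt(abs(np.linalg.det(A))))
        ellipses, hues = [], []
        for berry, c in zip(berries, moved):
            rel_v = float(volume_curve(t_days, berry.onset_days, berry.rise_days,
                                       berry.amplitude, berry.shrivels,
                                       cfg.shrivel_rate))
            rel_v = max(rel_v, 0.05)
            if cfg.measurement_noise > 0:
                rel_v *= max(1.0 + rng.normal(0.0, cfg.measurement_noise), 0.05)
            r = berry.base_radius * rel_v ** (1.0 / 3.0) * scale_f
            ellipses.append(Ellipse(c[0], c[1], 2.0 * r, 2.0 * r * berry.aspect,
                                    berry.angle))
            hues.append(float(hue_curve(t_days, berry.hue_onset_days,
                                        cfg.hue_rise_days, cfg.hue_start,
                                        cfg.hue_end)))
        vis = _boundary_visibility(ellipses, depths)
        frames.append(FrameRecord(frame=f, time_days=t_days, ellipses=ellipses,
                                  true_ids=list(range(cfg.n_berries)),
                                  visibility=vis, hues=hues))
    return GroundTruth(config=cfg, berries=berries, frames=frames)


def render(gt: GroundTruth, frame: int, noise_sd: float = 2.0,
           saturation: float = 0.75, value: float = 0.55,
           background: tuple[int, int, int] = (30, 30, 30)) -> np.ndarray:
    """8-bit RGB raster of one frame: berries painted back to front as
    filled ellipses in their frame hue, plus additive pixel noise."""
    from matplotlib.colors import hsv_to_rgb
    from skimage.draw import ellipse as draw_ellipse

    cfg = gt.config
    rec = gt.frames[frame]
    h, w = cfg.image_size
    img = np.zeros((h, w, 3), dtype=float)
    img[:] = np.array(background, dtype=float) / 255.0
    depths = {b.berry_id: b.depth for b in gt.berries}
    order = sorted(range(len(rec.ellipses)),
                   key=lambda i: -depths[rec.true_ids[i]])  # deepest first
    for i in order:
        e = rec.ellipses[i]
        rgb = hsv_to_rgb([rec.hues[i] / 180.0, saturation, value])
        rr, cc = draw_ellipse(e.y_e, e.x_e, e.h_e / 2.0, e.w_e / 2.0,
                              shape=(h, w), rotation=-math.radians(e.a_e))
        img[rr, cc] = rgb
    out = img * 255.0
    if noise_sd > 0:
        rng = np.random.default_rng(cfg.seed * 100003 + frame)
        out = out + rng.normal(0.0, noise_sd, out.shape)
    return np.clip(out, 0, 255).astype(np.uint8)


def ground_truth_series(gt: GroundTruth, min_visibility: float = 0.5):
    """Observation series as an ideal detector would produce it.

    Berries below the visibility threshold are dropped (the
    measurability rule); size and colour features are computed from the
    ground-truth ellipses and hues.  Returns ``(series, true_ids)``
    where ``true_ids[frame]`` aligns with the frame's observations —
    the identity oracle for tracking evaluation.
    """
    from berrytrack.features import (BerryObservation, centred_hue,
                                     projected_area, sphere_volume, ML_PER_PX3)
    from berrytrack.tracking import FrameSet

    series: list[FrameSet] = []
    true_ids: dict[int, list[int]] = {}
    for rec in gt.frames:
        obs_list: list[BerryObservation] = []
        ids: list[int] = []
        for e, bid, vis, hue in zip(rec.ellipses, rec.true_ids,
                                    rec.visibility, rec.hues):
            if vis < min_visibility:
                continue
            A = projected_area(e)
            V = sphere_volume(A)
            obs_list.append(BerryObservation(
                frame=rec.frame, time=rec.time_days, ellipse=e, score=vis,
                h_raw=hue, H=centred_hue(hue), A=A, V=V, V_mL=V * ML_PER_PX3,
            ))
            ids.append(bid)
        series.append(FrameSet(t=rec.frame, observations=obs_list,
                               time_days=rec.time_days))
        true_ids[rec.frame] = ids
    return series, true_ids


def cohort_series(gt: GroundTruth, min_visibility: float = 0.0):
    """Per-berry kinetics series keyed by true identity.

    Bypasses tracking (identities are known): the idealized input for
    kinetics parameter-recovery studies.  Returns a list of
    :class:`berrytrack.kinetics.BerrySeries`.
    """
    from berrytrack.kinetics import BerrySeries

    series, true_ids = ground_truth_series(gt, min_visibility=min_visibility)
    n_frames = len(series)
    per: dict[int, list[tuple[float, float, float]]] = {}
    for fs in series:
        for o, tid in zip(fs.observations, true_ids[fs.t]):
            per.setdefault(tid, []).append((o.time, o.V, o.H))
    out = []
    for tid in sorted(per):
        rows = sorted(per[tid])
        t = np.array([r[0] for r in rows])
        v = np.array([r[1] for r in rows])
        h = np.array([r[2] for r in rows])
        out.append(BerrySeries(label=tid, times=t, V=v, H=h,
                               coverage=len(rows) / n_frames))
    return out


def scenario_library() -> dict[str, SimConfig]:
    """Named study conditions exercising the pipeline's failure modes."""
    nominal = SimConfig(
        n_berries=60, n_frames=100, step_hours=8.0,
        jitter_shift=10.0, jitter_rot_deg=3.0, jitter_scale=0.01,
        seed=0,
    )
    return {
        # perfectly still bunch: tracking must be trivially perfect
        "static": replace(nominal, jitter_shift=0.0, jitter_rot_deg=0.0,
                          jitter_scale=0.0, n_berries=30, n_frames=40),
        # the nominal platform conditions: small affine jitter every frame
        "nominal_jitter": nominal,
        # camera/bunch rotates abruptly mid-series and rotates back later
        "rigid_rotation_event": replace(
            nominal, events=((40, "rotation", 20.0), (70, "rotation", 0.0))),
        # the bunch is rearranged mid-series (non-affine): tracking cannot
        # and should not bridge the break
        "nonaffine_break": replace(nominal, n_frames=60,
                                   events=((30, "shuffle", None),)),
        # tight cluster: strong overlaps and sub-50% visibilities
        "dense_occlusion": replace(nominal, n_berries=40, n_frames=40,
                                   cluster_spread=120.0, min_centre_spacing=30.0),
        # ripening onsets spread over about one rise duration: the
        # conditions under which the "mean berry" overestimates RD
        # small frames that render quickly: for image-pipeline work
        "mini_render": replace(
            nominal, n_berries=12, n_frames=6, image_size=(512, 512),
            cluster_spread=110.0, radius_range=(18.0, 26.0),
            min_centre_spacing=45.0, jitter_shift=4.0, jitter_rot_deg=1.0,
            jitter_scale=0.005),
        # onsets span 18 days (= the 15-85% rise duration); the series is
        # long enough (70 days) for every berry to show both plateaus
        "asynchronous_cohort": replace(
            nominal, n_berries=50, n_frames=210, jitter_shift=5.0,
            onset_mean_days=20.0, onset_spread_days=9.0,
            rise_days=18.0, amplitude=0.6, measurement_noise=0.05,
        ),
    }
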