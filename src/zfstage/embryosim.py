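"""Synthetic multi-well brightfield embryo plates.

Renders cartoon zebrafish-like embryos whose morphology is a monotone
function of developmental stage — an elliptical yolk, a circular-arc body
wrapping the yolk, a tapering tail, periodic somite-like stripes, an eye
disc appearing at a fixed onset stage, and stage-increasing pigmentation —
over a bright background with a mild illumination gradient and Gaussian
noise.  Stage progression is scaled with incubation temperature through the
rate model, so a plate simulated at 25.0 degC develops at 80.5% of the rate
of one at 28.5 degC.  Everything is bit-reproducible from the plate spec and
seed, which makes the whole downstream pipeline (loading, training,
prediction, slope statistics) testable without any archived microscopy data.

The morphology model is entirely invented: it stands in for real staging
landmarks (somite number, eye primordium, tail extension) with shapes that
are cheap to draw, resolvable at 64-256 px, and strictly monotone in stage
so that a small CNN can recover relative developmental rates from it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .devstats import RateModel, stage_at_time

__all__ = [
    "EmbryoPhenotype",
    "SimPlateSpec",
    "phenotype_at_stage",
    "render_embryo",
    "simulate_plate",
    "STAGE_MIN",
    "STAGE_MAX",
    "EYE_ONSET_STAGE",
]

STAGE_MIN = 2.0    # hpf-equivalent
STAGE_MAX = 55.0
EYE_ONSET_STAGE = 24.0  # eye disc appears at/after this stage
MAX_STRIPES = 30        # somite-style cap

MANIFEST_COLUMNS = ["path", "well", "frame", "time_h", "temperature_c", "hpf"]


@dataclass(frozen=True)
class EmbryoPhenotype:
    """Geometric/intensity description of one rendered embryo."""

    yolk_radius: float        # px
    body_arc_degrees: float   # arc of body axis around the yolk
    tail_length: float        # px
    eye_present: bool
    stripe_count: int         # somite-like bands
    pigment_level: float      # [0, 1]


@dataclass(frozen=True)
class SimPlateSpec:
    """Parameters of one simulated plate acquisition.

    Defaults emulate the acquisition protocol of the real experiment: one
    embryo per well, frames every 15 min (0.25 h) starting around 3 hpf,
    with per-well fertilisation jitter up to 30 min.
    """

    n_wells: int = 24
    temperature: float = 28.5   # degC
    t_start: float = 3.0        # hours post fertilisation at first frame
    interval: float = 0.25      # hours between frames
    n_frames: int = 172         # ~43 h of imaging at 15-min intervals
    image_height: int = 180
    image_width: int = 240
    noise_sigma: float = 0.02   # intensity units on [0, 1] scale
    illumination_tilt: float = 0.06  # peak-to-peak intensity of the gradient
    jitter_window: float = 0.5  # h; per-well uniform fertilisation-time jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        if self.image_width <= self.image_height:
            raise ValueError(
                f"image_width ({self.image_width}) must exceed image_height "
                f"({self.image_height}); the crop layer crops in x only"
            )


def phenotype_at_stage(stage: float) -> EmbryoPhenotype:
    """Deterministic stage -> phenotype map; all fields monotone in stage.

    ``frac`` is the position of ``stage`` within the supported range.
    Geometry is expressed in units of a nominal 100-px frame height and
    scaled at render time, so every feature fits the frame at every stage.
    """
    if not (STAGE_MIN <= stage <= STAGE_MAX):
        raise ValueError(
            f"stage {stage:.3g} outside supported range [{STAGE_MIN}, {STAGE_MAX}]"
        )
    frac = (stage - STAGE_MIN) / (STAGE_MAX - STAGE_MIN)
    return EmbryoPhenotype(
        yolk_radius=14.0 - 4.0 * frac,             # yolk is consumed over time
        body_arc_degrees=40.0 + 260.0 * frac,      # body wraps the yolk
        tail_length=2.0 + 26.0 * frac,             # straightened tail extends
        eye_present=stage >= EYE_ONSET_STAGE,
        stripe_count=min(int(stage / 1.5), MAX_STRIPES),
        pigment_level=0.15 + 0.75 * frac,
    )


def _draw_embryo(
    frame_hw: tuple[int, int],
    phen: EmbryoPhenotype,
    center: tuple[float, float],
    orientation_rad: float,
) -> np.ndarray:
    """Soft occupancy mask (0..1, 1 = full pigment) of the embryo shapes."""
    h, w = frame_hw
    scale = h / 100.0  # geometry defined on a nominal 100-px frame height
    cy, cx = center
    yy, xx = np.mgrid[0:h, 0:w]
    dy = (yy - cy) / scale
    dx = (xx - cx) / scale
    r = np.hypot(dx, dy)
    # polar angle measured from the embryo's orientation, wrapped to [0, 2pi)
    theta = np.mod(np.arctan2(dy, dx) - orientation_rad, 2 * np.pi)

    mask = np.zeros((h, w), dtype=float)

    # yolk: slightly elliptical disc (soft 1-px edge)
    ey = dy * np.cos(orientation_rad) - dx * np.sin(orientation_rad)
    ex = dx * np.cos(orientation_rad) + dy * np.sin(orientation_rad)
    yolk_q = np.hypot(ex / 1.15, ey / 0.9)
    mask = np.maximum(mask, 0.55 * np.clip(phen.yolk_radius - yolk_q + 1.0, 0, 1))

    # body: annular band hugging the yolk over body_arc degrees
    arc = np.deg2rad(phen.body_arc_degrees)
    band_in = phen.yolk_radius - 1.0
    band_out = phen.yolk_radius + 5.0
    in_band = (r >= band_in) & (r <= band_out) & (theta <= arc)
    body = np.where(in_band, 1.0, 0.0)
    # somite-like stripes: periodic darkening along the body arc
    if phen.stripe_count > 0:
        phase = np.cos(theta * phen.stripe_count * 2 * np.pi / max(arc, 1e-6))
        body = np.where(in_band, 0.75 + 0.25 * (phase > 0.0), 0.0)
    mask = np.maximum(mask, body)

    # tail: tapering segment leaving the end of the body arc, directed outward
    tail_dir = orientation_rad + arc
    tx0 = cx + scale * (band_in + 2.0) * np.cos(tail_dir)
    ty0 = cy + scale * (band_in + 2.0) * np.sin(tail_dir)
    ux, uy = np.cos(tail_dir + np.pi / 2.2), np.sin(tail_dir + np.pi / 2.2)
    px = (xx - tx0) / scale
    py = (yy - ty0) / scale
    along = px * ux + py * uy
    across = np.abs(-px * uy + py * ux)
    width0 = 2.5
    taper = width0 * np.clip(1.0 - along / max(phen.tail_length, 1e-6), 0.05, 1.0)
    tail = (along >= 0) & (along <= phen.tail_length) & (across <= taper)
    mask = np.maximum(mask, np.where(tail, 0.9, 0.0))

    # eye: small dark disc near the start of the body axis
    if phen.eye_present:
        eye_r = phen.yolk_radius + 2.0
        ex0 = cx + scale * eye_r * np.cos(orientation_rad + 0.35)
        ey0 = cy + scale * eye_r * np.sin(orientation_rad + 0.35)
        eye = np.hypot(xx - ex0, yy - ey0) <= 2.2 * scale
        mask = np.maximum(mask, np.where(eye, 1.0, 0.0))

    return mask


def render_embryo(
    stage: float,
    frame_size: tuple[int, int] = (180, 240),
    rng_seed: int = 0,
    noise_sigma: float = 0.02,
    illumination_tilt: float = 0.06,
) -> tuple[np.ndarray, EmbryoPhenotype]:
    """Render one embryo at ``stage`` into a float image on [0, 1].

    Brightfield-style: bright background (~0.85), embryo darker in
    proportion to its pigment level.  The embryo centroid is placed
    uniformly in the central third of the frame and its orientation
    uniformly in [0, 360) degrees.  Deterministic given (stage, seed).
    """
    phen = phenotype_at_stage(stage)
    h, w = frame_size
    rng = np.random.default_rng(rng_seed)
    cy = h * (0.5 + 0.16 * (rng.random() - 0.5))
    cx = w * (0.5 + 0.16 * (rng.random() - 0.5))
    orientation = rng.random() * 2 * np.pi

    mask = _draw_embryo((h, w), phen, (cy, cx), orientation)
    background = 0.85 + illumination_tilt * (
        np.linspace(-0.5, 0.5, w)[None, :] + 0.3 * np.linspace(-0.5, 0.5, h)[:, None]
    )
    img = background - 0.65 * phen.pigment_level * mask
    img = img + rng.normal(0.0, noise_sigma, size=(h, w))
    return np.clip(img, 0.0, 1.0), phen


def _well_name(i: int) -> str:
    # 96-well-style names: A1..H12, then wrapping with a numeric suffix
    row = "ABCDEFGH"[(i // 12) % 8]
    col = i % 12 + 1
    rep = i // 96
    return f"{row}{col}" if rep == 0 else f"{row}{col}_{rep}"


def simulate_plate(
    spec: SimPlateSpec,
    out_dir: str | os.PathLike,
    rate_model: RateModel = RateModel(),
) -> pd.DataFrame:
    """Simulate a plate time-lapse and write images + manifest to ``out_dir``.

    Writes one 16-bit single-channel TIFF per (well, frame) and a
    ``manifest.csv`` with columns ``path,well,frame,time_h,temperature_c,hpf``.
    ``time_h`` is wall-clock hours post fertilisation for that well
    (including its per-well fertilisation jitter) and ``hpf`` the
    reference-equivalent stage label ``time_h * (0.055 T - c)``.

    Raises the rate model's domain error up front if the temperature gives a
    nonpositive developmental rate.
    """
    # validate temperature before writing anything
    stage_at_time(1.0, spec.temperature, rate_model)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for i in range(spec.n_wells):
        well = _well_name(i)
        jitter = rng.random() * spec.jitter_window
        well_seed = int(rng.integers(0, 2**31 - 1))
        for k in range(spec.n_frames):
            t = spec.t_start + jitter + k * spec.interval
            stage = stage_at_time(t, spec.temperature, rate_model)
            img, _ = render_embryo(
                stage,
                (spec.image_height, spec.image_width),
                rng_seed=well_seed + k,
                noise_sigma=spec.noise_sigma,
                illumination_tilt=spec.illumination_tilt,
            )
            fname = f"{well}_f{k:04d}.tif"
            tifffile.imwrite(
                out / fname, np.round(img * 65535).astype(np.uint16)
            )
            rows.append(
                {
                    "path": fname,
                    "well": well,
                    "frame": k,
                    "time_h": t,
                    "temperature_c": spec.temperature,
                    "hpf": stage,
                }
            )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
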