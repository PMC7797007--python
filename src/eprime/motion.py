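"""Stochastic image-domain motion point-spread functions for half-scan cardiac CT.

In-plane coronary motion during a half-scan acquisition blurs the vessel along
a curved, asymmetric path: only the motion component along the detector
*channel direction* ``s(theta) = [sin(theta), -cos(theta)]`` produces data
inconsistencies, and that direction rotates with the source.  A single motion
PSF instance is the time-weighted path of the channel-projected displacement
``(v . s(theta_t)) t s(theta_t)`` splatted onto the hyper-resolution grid.

Dual-source geometries and multisegment reconstruction split the angular span
into contiguous subsets acquired in proportionally shorter time windows, which
shortens the displacement path (better effective temporal resolution) without
changing the angular coverage.  Because the relative direction of vessel motion
and the source start angle are unsynchronised with the cardiac cycle, both are
drawn uniformly at random per acquisition, making the motion operator
stochastic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .phantom import GridSpec, GeometryError

__all__ = [
    "AcquisitionGeometry",
    "MotionState",
    "MotionKernel",
    "channel_direction",
    "reconstruction_weights",
    "synthesize_mpsf",
    "sample_mpsf_ensemble",
    "segment_velocity",
    "load_segment_velocity_table",
    "effective_temporal_resolution",
]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Rotation time, source/segment count and reconstruction span of a scan."""

    rotation_time: float  # s
    n_sources: int = 1
    n_segments: int = 1
    recon_span: float = math.pi  # rad; half-scan by default
    rotation_sense: str = "cw"
    weighting_scheme: str = "uniform"

    def __post_init__(self) -> None:
        if self.rotation_time <= 0:
            raise ValueError("rotation_time must be positive")
        if self.n_sources not in (1, 2):
            raise ValueError("n_sources must be 1 or 2")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if not 0 < self.recon_span <= 2 * math.pi:
            raise ValueError("recon_span must lie in (0, 2*pi]")
        if self.rotation_sense not in ("cw", "ccw"):
            raise ValueError("rotation_sense must be 'cw' or 'ccw'")
        if self.weighting_scheme not in ("uniform", "smooth-transition"):
            raise ValueError("unknown weighting scheme")


@dataclass(frozen=True)
class MotionState:
    """Constant in-plane velocity during one acquisition window."""

    speed: float  # mm/s
    direction: float = 0.0  # rad
    start_angle: float = 0.0  # rad, source angle at the start of acquisition

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("speed must be >= 0")


@dataclass
class MotionKernel:
    """One stochastic motion PSF instance on the hyper grid (sums to one)."""

    values: np.ndarray
    pixel_size: float  # mm
    effective_temporal_resolution: float  # ms

    def __post_init__(self) -> None:
        s = float(self.values.sum())
        if not math.isclose(s, 1.0, abs_tol=1e-9):
            raise ValueError(f"kernel must sum to 1, got {s}")
        if (self.values < -1e-12).any():
            raise ValueError("kernel must be non-negative")


def channel_direction(theta: float | np.ndarray) -> np.ndarray:
    """Detector channel direction for source projection angle ``theta``.

    Returns ``[sin(theta), -cos(theta)]``, the in-plane unit vector
    perpendicular to the source-to-detector axis for a clockwise rotation.
    For array input the result has shape ``theta.shape + (2,)``.
    """
    theta = np.asarray(theta, dtype=float)
    return np.stack([np.sin(theta), -np.cos(theta)], axis=-1)


def reconstruction_weights(angles: np.ndarray, scheme: str = "uniform") -> np.ndarray:
    """Per-projection reconstruction weights, normalised to unit sum.

    ``uniform`` gives equal weights; ``smooth-transition`` tapers the first and
    last 10% of the span with a raised-cosine ramp to soften the data
    transition at the half-scan endpoints.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("empty projection angle set")
    if scheme == "uniform":
        w = np.ones_like(angles)
    elif scheme == "smooth-transition":
        lo, hi = float(angles.min()), float(angles.max())
        span = hi - lo if hi > lo else 1.0
        u = (angles - lo) / span
        ramp = 0.1
        w = np.ones_like(u)
        head = u < ramp
        tail = u > 1.0 - ramp
        w[head] = np.sin(0.5 * np.pi * u[head] / ramp) ** 2
        w[tail] = np.sin(0.5 * np.pi * (1.0 - u[tail]) / ramp) ** 2
    else:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    return w / w.sum()


def effective_temporal_resolution(geom: AcquisitionGeometry) -> float:
    """Effective acquisition time window in milliseconds.

    ``rotation_time * recon_span / (2*pi) / (n_sources * n_segments)``: the
    time to sweep the reconstruction span, shortened by splitting it across
    sources and/or heartbeat segments.
    """
    k = geom.n_sources * geom.n_segments
    return 1e3 * geom.rotation_time * geom.recon_span / (2.0 * math.pi) / k


def motion_sample_points(
    motion: MotionState, geom: AcquisitionGeometry, n_angle_samples: int
) -> tuple[np.ndarray, np.ndarray]:
    """Displacement points (mm) and weights of the sampled motion path.

    The span is partitioned into ``n_sources * n_segments`` contiguous angular
    subsets; within each subset local time restarts at zero (each subset is
    acquired in its own shortened window), anchoring every subset path at the
    origin.
    """
    if n_angle_samples < 64:
        raise ValueError("n_angle_samples must be >= 64")
    k = geom.n_sources * geom.n_segments
    omega = 2.0 * math.pi / geom.rotation_time
    sense = 1.0 if geom.rotation_sense == "cw" else -1.0

    # midpoint angle sampling across the full span
    u = (np.arange(n_angle_samples) + 0.5) / n_angle_samples
    theta = motion.start_angle + sense * u * geom.recon_span
    weights = reconstruction_weights(theta, geom.weighting_scheme)

    subset = np.minimum((u * k).astype(int), k - 1)
    subset_start = motion.start_angle + sense * subset * geom.recon_span / k
    t_local = np.abs(theta - subset_start) / omega  # s, restarts per subset

    s = channel_direction(theta)  # (n, 2)
    v = motion.speed * np.array([math.cos(motion.direction),
                                 math.sin(motion.direction)])
    proj = s @ v  # mm/s along the channel direction
    points = (proj * t_local)[:, None] * s
    return points, weights


def _splat_bilinear(points: np.ndarray, weights: np.ndarray, n: int, h: float) -> np.ndarray:
    """Accumulate weighted points onto an odd-sized grid by bilinear splatting."""
    out = np.zeros((n, n))
    c = (n - 1) / 2.0
    gx = points[:, 0] / h + c
    gy = points[:, 1] / h + c
    x0 = np.floor(gx).astype(int)
    y0 = np.floor(gy).astype(int)
    fx = gx - x0
    fy = gy - y0
    for dx, dy, w in (
        (0, 0, (1 - fx) * (1 - fy)),
        (1, 0, fx * (1 - fy)),
        (0, 1, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        np.add.at(out, (y0 + dy, x0 + dx), weights * w)
    return out


def synthesize_mpsf(
    motion: MotionState,
    geom: AcquisitionGeometry,
    grid: GridSpec,
    n_angle_samples: int = 2048,
) -> MotionKernel:
    """Synthesize one motion PSF instance on the hyper-resolution grid."""
    points, weights = motion_sample_points(motion, geom, n_angle_samples)
    h = grid.hyper_pixel_size
    max_disp = float(np.abs(points).max()) if points.size else 0.0
    half_px = int(math.ceil(max_disp / h)) + 1
    n = 2 * half_px + 1
    if n > grid.n_hyper:
        raise GeometryError(
            f"motion kernel support ({n} px) exceeds grid ({grid.n_hyper} px); "
            "enlarge the field of view or reduce speed"
        )
    values = _splat_bilinear(points, weights, n, h)
    values /= values.sum()
    return MotionKernel(
        values=values,
        pixel_size=h,
        effective_temporal_resolution=effective_temporal_resolution(geom),
    )


def sample_mpsf_ensemble(
    speed: float,
    geom: AcquisitionGeometry,
    grid: GridSpec,
    n: int,
    seed: int | np.random.SeedSequence = 0,
    n_angle_samples: int = 2048,
) -> list[MotionKernel]:
    """Draw ``n`` independent motion PSF instances.

    Motion direction and source start angle are each uniform on [0, 2*pi) and
    independent across draws; per-draw RNG streams are spawned from the root
    seed so the ensemble is reproducible and order-independent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    kernels = []
    for child in root.spawn(n):
        rng = np.random.default_rng(child)
        direction, start = rng.uniform(0.0, 2.0 * math.pi, size=2)
        kernels.append(
            synthesize_mpsf(
                MotionState(speed=speed, direction=direction, start_angle=start),
                geom, grid, n_angle_samples,
            )
        )
    return kernels


def load_segment_velocity_table() -> pd.DataFrame:
    """Shipped vessel-velocity lookup (affine in heart rate, editable)."""
    with resources.files("eprime.data").joinpath("segment_velocity.csv").open() as fh:
        return pd.read_csv(fh)


def segment_velocity(
    heart_rate: float,
    sex: str,
    aha_segment: str,
    table: pd.DataFrame | None = None,
    valid_range: tuple[float, float] = (10.0, 50.0),
) -> float:
    """In-plane vessel speed (mm/s) at the quiescent cardiac phase.

    Affine in resting heart rate: ``v = v_at_60bpm + slope * (HR - 60)``,
    looked up per sex and AHA segment and clipped to the configured range.
    """
    if heart_rate <= 0:
        raise ValueError("heart_rate must be positive")
    if table is None:
        table = load_segment_velocity_table()
    rows = table[(table["sex"] == sex) & (table["segment_id"] == aha_segment)]
    if rows.empty:
        valid = sorted(table["segment_id"].unique())
        raise KeyError(
            f"no velocity entry for sex={sex!r}, segment={aha_segment!r}; "
            f"valid segments: {valid}"
        )
    v60 = float(rows["v_at_60bpm_mm_s"].iloc[0])
    slope = float(rows["slope_mm_s_per_bpm"].iloc[0])
    v = v60 + slope * (heart_rate - 60.0)
    return float(np.clip(v, *valid_range))
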