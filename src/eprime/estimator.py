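"""Ideal maximum-likelihood stenosis estimation and the estimability index e'.

For Gaussian noise the ideal (maximum-likelihood, no prewhitening) estimate of
stenosis is the parameter of the noise-free template minimising the pixel-wise
squared difference with the observed image instance.  Repeating the estimate
over an ensemble of stochastic noise and motion realisations yields a
distribution of estimates whose spread quantifies the achievable precision;
the estimability index is its reciprocal,

    e' = 1 / SD(stenosis estimates),

with stenosis on the fractional [0, 1] scale, so e' = 25.58 corresponds to a
precision (SD) of 3.91%.  Cases with local plaque CNR <= 1 or vessel speed
>= 40 mm/s are outside the regime where the index is informative and are
flagged nondiagnostic with e' reported as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cases import CaseSpec
from .imaging import (
    apply_blur,
    downsample,
    generate_correlated_noise,
    parametric_nps,
    parametric_ttf,
    ttf_to_psf,
)
from .motion import (
    AcquisitionGeometry,
    MotionState,
    segment_velocity,
    synthesize_mpsf,
)
from .phantom import (
    GeometryError,
    GridSpec,
    PLAQUE_HU,
    VesselSpec,
    adjusted_lumen_hu,
    lumen_reference_diameter,
    render_cross_section,
)

__all__ = [
    "EngineConfig",
    "TemplateBank",
    "EstimateDistribution",
    "EstimabilityResult",
    "build_template_bank",
    "mle_estimate",
    "estimate_distribution",
    "estimability_index",
    "compute_case_eprime",
    "closed_form_eprime_white_noise",
    "precision_pct_from_eprime",
    "ci95_width_pct_from_eprime",
    "case_cnr",
]

DEFAULT_STENOSIS_GRID = np.round(np.arange(0.15, 0.85 + 1e-9, 0.01), 4)

#: Degeneracy thresholds beyond which the index is reported as zero.
CNR_DEGENERACY_THRESHOLD = 1.0
VELOCITY_DEGENERACY_THRESHOLD = 40.0  # mm/s

#: TTF f50 defaults by the dominant contrast edge (plaque material class).
TTF_F50_BY_MATERIAL = {"noncalcified": 0.36, "mixed": 0.40, "calcified": 0.44}


@dataclass
class EngineConfig:
    """Numerical configuration of the simulation engine.

    The field of view must accommodate the vessel plus the motion-blur extent;
    the stenosis grid is the template bank's parameter axis.
    """

    hyper_factor: int = 10
    field_of_view: float = 12.8  # mm
    stenosis_grid: np.ndarray = field(
        default_factory=lambda: DEFAULT_STENOSIS_GRID.copy()
    )
    n_angle_samples: int = 1024
    ttf_shape: str = "gaussian"
    nps_shape: str = "bandpass"
    nps_peak_default: float = 0.25  # mm^-1
    template_motion: str = "direction_averaged"  # none | direction_averaged
    template_motion_directions: int = 12

    def grid_for(self, case: CaseSpec) -> GridSpec:
        return GridSpec(
            clinical_pixel_size=case.scanner.pixel_size_mm,
            hyper_factor=self.hyper_factor,
            field_of_view=self.field_of_view,
        )


@dataclass
class TemplateBank:
    """Noise-free templates indexed by stenosis (plus optional nuisance axes).

    ``images`` has one row per template at clinical resolution;
    ``stenosis_values`` gives the stenosis coordinate of every row, so a bank
    with nuisance axes (e.g. velocity) is simply a longer flat list.
    """

    stenosis_values: np.ndarray
    images: np.ndarray  # (n_templates, ny, nx)
    case_id: str
    grid: GridSpec
    velocity_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.images.shape[0] != self.stenosis_values.shape[0]:
            raise ValueError("one stenosis coordinate per template required")


@dataclass
class EstimateDistribution:
    """Ensemble of per-instance ML stenosis estimates."""

    estimates: np.ndarray  # fractions
    truth: float
    n_instances: int
    n_edge_clips: int = 0

    @property
    def mean(self) -> float:
        return float(self.estimates.mean())

    @property
    def sd(self) -> float:
        return float(self.estimates.std(ddof=1))

    @property
    def bias(self) -> float:
        return self.mean - self.truth


@dataclass
class EstimabilityFlags:
    degenerate_cnr: bool = False
    degenerate_velocity: bool = False
    zero_variance: bool = False
    edge_clipping: bool = False


@dataclass
class EstimabilityResult:
    """The scalar index e' with its precision equivalent and degeneracy flags."""

    e_prime: float
    precision_pct: float
    flags: EstimabilityFlags
    mean: float = math.nan
    bias: float = math.nan
    n_instances: int = 0

    def to_dict(self) -> dict:
        return {
            "e_prime": self.e_prime,
            "precision_pct": self.precision_pct,
            "mean": self.mean,
            "bias": self.bias,
            "n_instances": self.n_instances,
            "flags": vars(self.flags).copy(),
        }


def precision_pct_from_eprime(e_prime: float) -> float:
    """Stenosis estimation precision (SD, percent) equivalent to an e' value."""
    if e_prime <= 0:
        raise ValueError("e_prime must be positive")
    return 100.0 / e_prime


def ci95_width_pct_from_eprime(e_prime: float) -> float:
    """Width of the +/-2 SD (95%) stenosis interval, in percent."""
    return 4.0 * precision_pct_from_eprime(e_prime)


def _case_derived(case: CaseSpec, engine: EngineConfig):
    """Resolve diameter, speed, grid, curves and geometry for a case."""
    grid = engine.grid_for(case)
    diameter = (
        case.diameter_mm
        if case.diameter_mm is not None
        else lumen_reference_diameter(case.sex, case.aha_segment)
    )
    speed = (
        case.velocity_mm_s
        if case.velocity_mm_s is not None
        else segment_velocity(case.heart_rate, case.sex, case.aha_segment)
    )
    f50 = case.scanner.ttf_f50 or TTF_F50_BY_MATERIAL[case.plaque_material]
    ttf = parametric_ttf(f50, shape=engine.ttf_shape)
    nps = parametric_nps(
        case.scanner.nps_peak or engine.nps_peak_default,
        sigma=case.scanner.sigma_hu,
        shape=engine.nps_shape,
    )
    geom = AcquisitionGeometry(
        rotation_time=case.scanner.rotation_time_s,
        n_sources=case.scanner.n_sources,
        n_segments=case.scanner.n_segments,
    )
    return grid, diameter, speed, ttf, nps, geom


def _vessel_at(case: CaseSpec, stenosis: float, diameter: float, grid: GridSpec) -> VesselSpec:
    plaque_hu = PLAQUE_HU[case.plaque_material]
    lumen_hu = adjusted_lumen_hu(
        case.lumen_enhancement, stenosis, diameter, grid, plaque_hu=plaque_hu
    )
    return VesselSpec(
        reference_lumen_diameter=diameter,
        stenosis_fraction=stenosis,
        plaque_material=case.plaque_material,
        lumen_hu=lumen_hu,
    )


def case_cnr(case: CaseSpec, engine: EngineConfig | None = None) -> float:
    """Local plaque contrast-to-noise ratio |lumen - plaque| / sigma."""
    engine = engine or EngineConfig()
    grid, diameter, _, _, _, _ = _case_derived(case, engine)
    plaque_hu = PLAQUE_HU[case.plaque_material]
    lumen_hu = adjusted_lumen_hu(
        case.lumen_enhancement, case.stenosis_fraction, diameter, grid,
        plaque_hu=plaque_hu,
    )
    sigma = case.scanner.sigma_hu
    if sigma == 0:
        return math.inf
    return abs(lumen_hu - plaque_hu) / sigma


def _direction_averaged_kernel(speed, geom, grid, engine, n_directions):
    """Deterministic mean motion kernel over evenly spaced directions/angles."""
    kernels = []
    for i in range(n_directions):
        direction = 2.0 * math.pi * i / n_directions
        start = 2.0 * math.pi * ((i * 0.618034) % 1.0)
        kernels.append(
            synthesize_mpsf(
                MotionState(speed=speed, direction=direction, start_angle=start),
                geom, grid, engine.n_angle_samples,
            )
        )
    n = max(k.values.shape[0] for k in kernels)
    acc = np.zeros((n, n))
    for k in kernels:
        m = k.values.shape[0]
        o = (n - m) // 2
        acc[o : o + m, o : o + m] += k.values
    acc /= acc.sum()
    from .motion import MotionKernel

    return MotionKernel(
        values=acc, pixel_size=grid.hyper_pixel_size,
        effective_temporal_resolution=kernels[0].effective_temporal_resolution,
    )


def build_template_bank(
    case: CaseSpec,
    stenosis_grid: np.ndarray | None = None,
    nuisance_config: dict | None = None,
    engine: EngineConfig | None = None,
) -> TemplateBank:
    """Precompute the noise-free template images for the estimation task.

    Templates run the deterministic chain only (phantom, system blur, optional
    nominal motion blur, downsampling).  By default templates are motion-free:
    the stochastic asymmetric motion blur has an unknown random direction that
    the observer cannot prewhiten.  ``nuisance_config`` options:

    - ``{"motion": "direction_averaged"}``: add a deterministic
      direction-averaged motion blur at the case velocity;
    - ``{"velocities": [...]}``: a full velocity-by-stenosis bank whose
      estimate is the stenosis coordinate of the global argmin.
    """
    engine = engine or EngineConfig()
    nuisance = nuisance_config or {}
    grid, diameter, speed, ttf, _, geom = _case_derived(case, engine)
    if stenosis_grid is None:
        stenosis_grid = engine.stenosis_grid
    stenosis_grid = np.asarray(stenosis_grid, dtype=float)
    if stenosis_grid.size == 0 or np.any(np.diff(stenosis_grid) <= 0):
        raise ValueError("stenosis grid must be non-empty and strictly increasing")

    system_kernel = ttf_to_psf(ttf, grid)

    motion_mode = nuisance.get("motion", engine.template_motion)
    velocities = nuisance.get("velocities")
    if velocities is not None:
        vel_axis = np.asarray(velocities, dtype=float)
    elif motion_mode == "direction_averaged":
        vel_axis = np.array([speed])
    else:
        vel_axis = np.array([0.0])

    # vectorised rendering: the wall/plaque layers are shared by all templates,
    # only the stenosed-lumen disk and its volume-averaged HU vary
    from .imaging import _embed_kernel
    from .phantom import PLAQUE_HU as _PHU, _disk_coverage, _pixel_centres

    h = grid.hyper_pixel_size
    n = grid.n_hyper
    c = _pixel_centres(n, h)
    rr = np.hypot(c[:, None], c[None, :])
    plaque_hu = _PHU[case.plaque_material]
    probe = _vessel_at(case, float(stenosis_grid[0]), diameter, grid)
    if probe.outer_diameter >= grid.extent:
        raise GeometryError(
            f"vessel outer diameter {probe.outer_diameter:.2f} mm does not fit "
            f"field of view {grid.extent:.2f} mm"
        )
    base = (
        probe.background_hu
        + (probe.wall_hu - probe.background_hu)
        * _disk_coverage(rr, probe.outer_diameter / 2.0, h)
        + (plaque_hu - probe.wall_hu)
        * _disk_coverage(rr, diameter / 2.0, h)
    )
    lumen_hu = np.array([
        adjusted_lumen_hu(case.lumen_enhancement, float(s), diameter, grid,
                          plaque_hu=plaque_hu)
        for s in stenosis_grid
    ])
    r_sten = (1.0 - stenosis_grid) * diameter / 2.0
    cov = np.clip((r_sten[:, None, None] - rr[None]) / h + 0.5, 0.0, 1.0)
    cov = cov * cov * (3.0 - 2.0 * cov)
    stack = base[None] + (lumen_hu - plaque_hu)[:, None, None] * cov

    transfer = np.fft.rfft2(_embed_kernel(system_kernel.values, (n, n)))

    images = []
    sten_coord = []
    vel_coord = []
    for v in vel_axis:
        H = transfer
        if v > 0:
            mk = _direction_averaged_kernel(
                v, geom, grid, engine, engine.template_motion_directions
            )
            H = transfer * np.fft.rfft2(_embed_kernel(mk.values, (n, n)))
        for i, s in enumerate(stenosis_grid):
            img = np.fft.irfft2(np.fft.rfft2(stack[i]) * H, s=(n, n))
            images.append(downsample(img, grid.hyper_factor))
            sten_coord.append(float(s))
            vel_coord.append(float(v))
    return TemplateBank(
        stenosis_values=np.array(sten_coord),
        images=np.stack(images),
        case_id=case.case_id,
        grid=grid,
        velocity_values=np.array(vel_coord) if vel_axis.size > 1 else None,
    )


def mle_estimate(
    instance: np.ndarray, bank: TemplateBank, rel_tie_tol: float = 1e-9
) -> float:
    """Stenosis of the template minimising the pixel-wise squared difference.

    Residual ties within a relative tolerance return the mean of the tied
    stenosis values (the blur null space can make distinct templates equally
    good fits).
    """
    if bank.images.shape[0] == 0:
        raise ValueError("empty template bank")
    x = np.asarray(instance, dtype=float)
    if x.shape != bank.images.shape[1:]:
        raise ValueError("instance shape does not match bank templates")
    diffs = bank.images - x[None]
    residuals = np.einsum("ijk,ijk->i", diffs, diffs)
    r0 = residuals.min()
    tol = rel_tie_tol * max(r0, 1.0) + 1e-15
    tied = residuals <= r0 + tol
    return float(bank.stenosis_values[tied].mean())


def estimate_distribution(
    case: CaseSpec,
    n_instances: int = 2300,
    seed: int | np.random.SeedSequence = 0,
    engine: EngineConfig | None = None,
    bank: TemplateBank | None = None,
    nuisance_config: dict | None = None,
) -> EstimateDistribution:
    """Monte-Carlo ensemble of ML stenosis estimates for one case.

    Each instance draws an independent motion direction and source start angle
    (uniform on [0, 2*pi)) and an independent correlated-noise field; streams
    are spawned per instance from the root seed, so the ensemble is
    reproducible and order-independent.
    """
    if n_instances < 2:
        raise ValueError("n_instances must be >= 2 (SD undefined otherwise)")
    engine = engine or EngineConfig()
    grid, diameter, speed, ttf, nps, geom = _case_derived(case, engine)
    if bank is None:
        bank = build_template_bank(case, engine=engine, nuisance_config=nuisance_config)

    # deterministic part of the chain, computed once
    vessel = _vessel_at(case, case.stenosis_fraction, diameter, grid)
    base = render_cross_section(vessel, grid).values
    system_kernel = ttf_to_psf(ttf, grid)
    base = apply_blur(base, system_kernel, grid.hyper_pixel_size)
    base_spectrum = np.fft.rfft2(base)

    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    estimates = np.empty(n_instances)
    lo, hi = bank.stenosis_values.min(), bank.stenosis_values.max()
    n_edge = 0
    for i, child in enumerate(root.spawn(n_instances)):
        rng = np.random.default_rng(child)
        if speed > 0:
            direction, start = rng.uniform(0.0, 2.0 * math.pi, size=2)
            mk = synthesize_mpsf(
                MotionState(speed=speed, direction=direction, start_angle=start),
                geom, grid, engine.n_angle_samples,
            )
            from .imaging import _embed_kernel

            kpad = _embed_kernel(mk.values, base.shape)
            blurred = np.fft.irfft2(base_spectrum * np.fft.rfft2(kpad), s=base.shape)
        else:
            blurred = base
        img = downsample(blurred, grid.hyper_factor)
        if nps.sigma > 0:
            img = img + generate_correlated_noise(
                nps, img.shape, rng, grid.clinical_pixel_size
            )
        est = mle_estimate(img, bank)
        if est <= lo or est >= hi:
            n_edge += 1
        estimates[i] = est
    return EstimateDistribution(
        estimates=estimates,
        truth=case.stenosis_fraction,
        n_instances=n_instances,
        n_edge_clips=n_edge,
    )


def estimability_index(
    dist: EstimateDistribution,
    case: CaseSpec,
    engine: EngineConfig | None = None,
) -> EstimabilityResult:
    """Convert an estimate ensemble into the scalar e' with degeneracy flags."""
    engine = engine or EngineConfig()
    _, _, speed, _, _, _ = _case_derived(case, engine)
    flags = EstimabilityFlags(
        degenerate_cnr=case_cnr(case, engine) <= CNR_DEGENERACY_THRESHOLD,
        degenerate_velocity=speed >= VELOCITY_DEGENERACY_THRESHOLD,
        edge_clipping=dist.n_edge_clips > 0,
    )
    sd = dist.sd
    if flags.degenerate_cnr or flags.degenerate_velocity:
        return EstimabilityResult(
            e_prime=0.0, precision_pct=math.nan, flags=flags,
            mean=dist.mean, bias=dist.bias, n_instances=dist.n_instances,
        )
    if sd == 0.0:
        flags.zero_variance = True
        return EstimabilityResult(
            e_prime=math.inf, precision_pct=0.0, flags=flags,
            mean=dist.mean, bias=dist.bias, n_instances=dist.n_instances,
        )
    return EstimabilityResult(
        e_prime=1.0 / sd, precision_pct=100.0 * sd, flags=flags,
        mean=dist.mean, bias=dist.bias, n_instances=dist.n_instances,
    )


def compute_case_eprime(
    case: CaseSpec,
    n_instances: int = 2300,
    seed: int | np.random.SeedSequence = 0,
    engine: EngineConfig | None = None,
    nuisance_config: dict | None = None,
) -> EstimabilityResult:
    """End-to-end e' for one case (bank build, ensemble, index)."""
    engine = engine or EngineConfig()
    _, _, speed, _, _, _ = _case_derived(case, engine)
    flags = EstimabilityFlags(
        degenerate_cnr=case_cnr(case, engine) <= CNR_DEGENERACY_THRESHOLD,
        degenerate_velocity=speed >= VELOCITY_DEGENERACY_THRESHOLD,
    )
    if flags.degenerate_cnr or flags.degenerate_velocity:
        # nondiagnostic regardless of the ensemble; skip the simulation
        return EstimabilityResult(
            e_prime=0.0, precision_pct=math.nan, flags=flags, n_instances=0
        )
    dist = estimate_distribution(
        case, n_instances=n_instances, seed=seed, engine=engine,
        nuisance_config=nuisance_config,
    )
    return estimability_index(dist, case, engine)


def closed_form_eprime_white_noise(
    bank: TemplateBank, sigma: float, truth: float | None = None
) -> float:
    """Analytic matched-filter e' for white noise via local linearisation.

    Linearising the template image around the true stenosis gives the estimate
    variance ``sigma**2 / ||dT/ds||**2``, hence ``e' = ||dT/ds|| / sigma`` with
    the template gradient taken by central finite differences on the bank.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if bank.velocity_values is not None:
        raise ValueError("closed form requires a stenosis-only bank")
    s = bank.stenosis_values
    if s.size < 3:
        raise ValueError("bank too small for finite differences")
    idx = int(np.argmin(np.abs(s - (truth if truth is not None else s[s.size // 2]))))
    idx = min(max(idx, 1), s.size - 2)
    grad = (bank.images[idx + 1] - bank.images[idx - 1]) / (s[idx + 1] - s[idx - 1])
    return float(np.sqrt((grad**2).sum()) / sigma)
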