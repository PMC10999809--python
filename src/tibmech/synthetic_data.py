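"""Synthetic inputs with known ground truth.

Emulates the three experimental data streams of a distal-tibia compression
study: (a) micro-CT density volumes of a lapped bone section (cortical shell
around an anisotropic trabecular structure of controlled BV/TV), (b) a
density calibration phantom, (c) force-displacement records of a
preconditioned monotonic compression to failure, and (d) pre/post test
volume pairs related by a known deformation field (e.g. a localized
compaction band), which serve as ground truth for registration-based strain
mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import ndimage

from .structural_analysis import LoadCurve
from .volumes import DensityVolume

__all__ = [
    "WeakBand",
    "SyntheticSpec",
    "SectionTruth",
    "generate_section",
    "generate_phantom",
    "PhantomTruth",
    "generate_load_curve",
    "GroundTruthDeformation",
    "identity_deformation",
    "rotation_about_z",
    "compaction_band",
    "uniform_dilation",
    "apply_deformation",
    "downscale",
]


@dataclass
class WeakBand:
    """Horizontal band of locally reduced BV/TV (failure-prone zone)."""

    center_mm: float
    width_mm: float
    bvtv_multiplier: float  # in (0, 1]

    def __post_init__(self) -> None:
        if not 0 < self.bvtv_multiplier <= 1:
            raise ValueError("bvtv_multiplier must be in (0, 1]")
        if self.width_mm <= 0:
            raise ValueError("width_mm must be positive")


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic bone section.

    Defaults describe the full-size study condition: a ~30 mm diameter,
    30.6 mm tall distal tibia section at the 72.5 um working voxel size
    (micro-CT downscaled by a factor 3). Tests and the study driver pass
    smaller grids; the physics of the generator is scale-free.
    """

    grid_shape: tuple[int, int, int] = (422, 414, 414)  # (nz, ny, nx) voxels
    spacing: float = 0.0725  # mm/voxel, isotropic
    target_bvtv: float = 0.20
    anisotropy_ratio: float = 1.6  # vertical elongation of trabeculae, >= 1
    cortical_thickness: float = 1.0  # mm
    tissue_density: float = 700.0  # mgHA/cm^3
    noise_sd: float = 25.0  # mgHA/cm^3
    correlation_length: float = 0.35  # mm, in-plane texture scale
    weak_band: WeakBand | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_bvtv < 1:
            raise ValueError("target_bvtv must be in (0, 1)")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.anisotropy_ratio < 1:
            raise ValueError("anisotropy_ratio must be >= 1")
        if min(self.grid_shape) < 8:
            raise ValueError("degenerate grid: need >= 8 voxels per axis")


@dataclass
class SectionTruth:
    """Ground truth accompanying a generated section."""

    bone_mask: np.ndarray  # bool, noise-free bone phase
    interior_mask: np.ndarray  # bool, trabecular compartment
    cortex_mask: np.ndarray  # bool, cortical shell
    periosteal_mask: np.ndarray  # bool, cortex + interior
    bvtv_map: np.ndarray  # float, nominal local BV/TV target per voxel
    realized_bvtv: float  # interior bone fraction by direct voxel count
    spec: SyntheticSpec


def _cylinder_masks(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nz, ny, nx = spec.grid_shape
    y = (np.arange(ny) - (ny - 1) / 2.0) * spec.spacing
    x = (np.arange(nx) - (nx - 1) / 2.0) * spec.spacing
    r = np.hypot(y[:, None], x[None, :])
    radius = 0.5 * min(nx, ny) * spec.spacing - spec.spacing
    perio2d = r <= radius
    interior2d = r <= radius - spec.cortical_thickness
    cortex2d = perio2d & ~interior2d
    rep = lambda m: np.broadcast_to(m, (nz, ny, nx)).copy()
    return rep(perio2d), rep(cortex2d), rep(interior2d)


def generate_section(spec: SyntheticSpec) -> tuple[DensityVolume, SectionTruth]:
    """Generate a density volume of a bone section plus its ground truth.

    The trabecular texture is a thresholded anisotropic Gaussian random
    field: white noise smoothed with an anisotropic Gaussian whose vertical
    correlation length is ``anisotropy_ratio`` times the in-plane one. The
    threshold is the empirical quantile of the field inside the trabecular
    compartment, so the realized BV/TV matches the target almost exactly.
    An optional weak band applies a locally higher threshold, reducing the
    band's BV/TV by ``bvtv_multiplier``.
    """
    rng = np.random.default_rng(spec.seed)
    perio, cortex, interior = _cylinder_masks(spec)
    nz, ny, nx = spec.grid_shape

    sigma_xy = spec.correlation_length / spec.spacing
    sigma_z = sigma_xy * spec.anisotropy_ratio
    fld = ndimage.gaussian_filter(rng.standard_normal(spec.grid_shape), (sigma_z, sigma_xy, sigma_xy))

    z_mm = (np.arange(nz) + 0.5) * spec.spacing
    band3d = np.zeros(spec.grid_shape, dtype=bool)
    if spec.weak_band is not None:
        inband = np.abs(z_mm - spec.weak_band.center_mm) <= spec.weak_band.width_mm / 2.0
        band3d[inband] = True
    band3d &= interior

    bone = np.zeros(spec.grid_shape, dtype=bool)
    base_region = interior & ~band3d
    if base_region.any():
        thr = np.quantile(fld[base_region], 1.0 - spec.target_bvtv)
        bone[base_region] = fld[base_region] > thr
    if band3d.any():
        bvtv_band = spec.target_bvtv * spec.weak_band.bvtv_multiplier
        thr_b = np.quantile(fld[band3d], 1.0 - bvtv_band)
        bone[band3d] = fld[band3d] > thr_b
    bone |= cortex

    bvtv_map = np.zeros(spec.grid_shape, dtype=float)
    bvtv_map[interior] = spec.target_bvtv
    if band3d.any():
        bvtv_map[band3d] = spec.target_bvtv * spec.weak_band.bvtv_multiplier
    bvtv_map[cortex] = 1.0

    gray = np.where(bone, spec.tissue_density, 0.0)
    if spec.noise_sd > 0:
        gray = gray + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)

    vol = DensityVolume(
        gray,
        spec.spacing,
        metadata={"seed": spec.seed, "target_bvtv": spec.target_bvtv, "kind": "synthetic_section"},
    )
    realized = float(bone[interior].mean()) if interior.any() else float("nan")
    truth = SectionTruth(bone, interior, cortex, perio, bvtv_map, realized, spec)
    return vol, truth


@dataclass
class PhantomTruth:
    rod_masks: list[np.ndarray]
    densities: list[float]
    mean_gray: list[float]  # realized mean gray value per rod
    pairs: list[tuple[float, float]]  # (gray, density)


def generate_phantom(
    densities: list[float],
    rod_radius_vox: int = 8,
    slab_height: int = 16,
    noise_sd: float = 0.0,
    gray_slope: float = 1.0,
    gray_intercept: float = 0.0,
    seed: int = 0,
) -> tuple[DensityVolume, PhantomTruth]:
    """Density calibration phantom: labeled rods of known mineral density.

    Gray values are an affine map of density (``gray_slope``/``gray_intercept``
    emulate uncalibrated scanner output) plus optional Gaussian noise; the
    truth records the realized mean gray per rod for regression oracles.
    """
    densities = [float(d) for d in densities]
    if len(set(densities)) < 2:
        raise ValueError("need at least 2 distinct phantom densities")
    rng = np.random.default_rng(seed)
    n = len(densities)
    pitch = 4 * rod_radius_vox
    ny = pitch + 2
    nx = pitch * n + 2
    vol = np.zeros((slab_height, ny, nx), dtype=float)
    masks = []
    yy, xx = np.mgrid[0:ny, 0:nx]
    for i, dens in enumerate(densities):
        cy, cx = ny / 2.0, pitch * (i + 0.5)
        rod2d = (yy - cy) ** 2 + (xx - cx) ** 2 <= rod_radius_vox**2
        rod = np.broadcast_to(rod2d, vol.shape)
        vol[rod] = gray_slope * dens + gray_intercept
        masks.append(rod.copy())
    if noise_sd > 0:
        vol = vol + rng.normal(0.0, noise_sd, size=vol.shape)
    mean_gray = [float(vol[m].mean()) for m in masks]
    pairs = list(zip(mean_gray, densities))
    dv = DensityVolume(vol, 0.0725, metadata={"kind": "synthetic_phantom", "seed": seed})
    return dv, PhantomTruth(masks, densities, mean_gray, pairs)


def generate_load_curve(
    stiffness: float,
    yield_force: float,
    ultimate_force: float,
    ultimate_disp: float,
    n_precycles: int = 5,
    sampling_rate: float = 100.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    height_mm: float = 30.6,
    area_mm2: float = 600.0,
    disp_rate: float = 0.1,
) -> LoadCurve:
    """Synthesize a compression test record (kN vs mm vs s).

    Shape: ``n_precycles`` elastic preconditioning half-sine cycles, a
    monotonic ramp (exactly linear at slope ``stiffness`` up to a
    proportional limit, then piecewise-linear through the 0.2 %-offset yield
    point and the ultimate point), post-ultimate linear softening to a
    plateau, and an unload back to zero force. The noise-free curve
    round-trips through the structural extractors: its maximal slope equals
    ``stiffness``, the offset criterion returns ``yield_force``, and the
    absolute maximum equals ``ultimate_force``.
    """
    if ultimate_force < yield_force:
        raise ValueError("ultimate_force must be >= yield_force")
    d_offset = 0.002 * height_mm
    d_yield = yield_force / stiffness + d_offset
    if ultimate_disp <= d_yield:
        raise ValueError("ultimate_disp must exceed the offset-yield displacement")
    rng = np.random.default_rng(seed)

    d_prop = 0.85 * yield_force / stiffness  # end of the exactly linear range
    dt = 1.0 / sampling_rate

    t_parts, f_parts = [], []
    d_parts = []
    t0 = 0.0

    # preconditioning: elastic half-sine-squared displacement cycles
    d_pre = 0.25 * yield_force / stiffness
    for _ in range(n_precycles):
        period = np.pi * d_pre / disp_rate
        tt = np.arange(0.0, period, dt)
        t_parts.append(t0 + tt)
        dd = d_pre * np.sin(np.pi * tt / period) ** 2
        d_parts.append(dd)
        f_parts.append(stiffness * dd)
        t0 += period

    # monotonic ramp: piecewise linear force law, with samples inserted at
    # the kinks so trapezoids/intersections on the record are exact
    xk = np.array([0.0, d_prop, d_yield, ultimate_disp])
    fk = np.array([0.0, stiffness * d_prop, yield_force, ultimate_force])
    t_ramp = ultimate_disp / disp_rate
    tt = np.union1d(np.arange(0.0, t_ramp, dt), xk / disp_rate)
    dd = tt * disp_rate
    t_parts.append(t0 + tt)
    d_parts.append(dd)
    f_parts.append(np.interp(dd, xk, fk))
    t0 += t_ramp + dt

    # post-ultimate: linear softening to a plateau, then plateau
    f_drop = 0.75 * ultimate_force
    d_soft_end = ultimate_disp * 1.15
    d_plateau_end = ultimate_disp * 1.25
    soft_x = np.array([ultimate_disp, d_soft_end, d_plateau_end])
    soft_f = np.array([ultimate_force, f_drop, f_drop])
    tt = np.arange(dt, (d_plateau_end - ultimate_disp) / disp_rate, dt)
    if len(tt):
        dd = ultimate_disp + tt * disp_rate
        t_parts.append(t0 + tt)
        d_parts.append(dd)
        f_parts.append(np.interp(dd, soft_x, soft_f))
        t0 += tt[-1] + dt
        d_top = dd[-1]
    else:
        d_top = ultimate_disp

    # unload at the elastic slope back to zero force
    d_unload_span = f_drop / stiffness
    tt = np.arange(dt, d_unload_span / disp_rate + dt, dt)
    if len(tt):
        dd = d_top - tt * disp_rate
        t_parts.append(t0 + tt)
        d_parts.append(dd)
        f_parts.append(np.maximum(f_drop - stiffness * (d_top - dd), 0.0))

    time = np.concatenate(t_parts)
    disp = np.concatenate(d_parts)
    force = np.concatenate(f_parts)

    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, size=force.shape)

    meta = {
        "height_mm": height_mm,
        "area_mm2": area_mm2,
        "true_stiffness": stiffness,
        "true_yield_force": yield_force,
        "true_ultimate_force": ultimate_force,
        "true_ultimate_disp": ultimate_disp,
        "seed": seed,
        "noise_sd": noise_sd,
        "n_precycles": n_precycles,
    }
    return LoadCurve(time=time, displacement=disp, force=force, metadata=meta)


@dataclass
class GroundTruthDeformation:
    """Analytic deformation phi(X) = X + u(X) with known gradient.

    ``displacement``/``inverse_map``/``gradient`` act on coordinate arrays of
    shape (..., 3) ordered (x, y, z) in mm. ``gradient`` returns F = I + du/dX
    with det F > 0 everywhere on the admissible domain.
    """

    displacement: Callable[[np.ndarray], np.ndarray]
    inverse_map: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    description: str = ""

    def true_F_on_grid(self, centers: np.ndarray) -> np.ndarray:
        """Per-cell true F at cell-center coordinates (..., 3)."""
        return self.gradient(centers)


def identity_deformation() -> GroundTruthDeformation:
    eye = lambda p: np.broadcast_to(np.eye(3), p.shape[:-1] + (3, 3)).copy()
    return GroundTruthDeformation(
        displacement=lambda p: np.zeros_like(p),
        inverse_map=lambda p: p.copy(),
        gradient=eye,
        description="identity",
    )


def rotation_about_z(angle_deg: float, center: tuple[float, float, float]) -> GroundTruthDeformation:
    """Rigid rotation about the vertical axis through ``center`` (x, y, z)."""
    a = np.deg2rad(angle_deg)
    R = np.array([[np.cos(a), -np.sin(a), 0.0], [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]])
    c = np.asarray(center, dtype=float)

    def fwd(p):
        return (p - c) @ R.T + c

    def grad(p):
        return np.broadcast_to(R, p.shape[:-1] + (3, 3)).copy()

    return GroundTruthDeformation(
        displacement=lambda p: fwd(p) - p,
        inverse_map=lambda p: (p - c) @ R + c,
        gradient=grad,
        description=f"rigid rotation {angle_deg} deg about z",
    )


def compaction_band(center_mm: float, width_mm: float, shortening_mm: float) -> GroundTruthDeformation:
    """Localized compaction: material above the band moves down by delta.

    Inside the band (height ``width_mm`` centred at ``center_mm``) the
    vertical stretch is 1 - delta/w, so F = diag(1, 1, 1 - delta/w) and
    J = 1 - delta/w there; outside, F = I. Requires delta < w (det F > 0).
    """
    w, delta = float(width_mm), float(shortening_mm)
    if delta >= w:
        raise ValueError("shortening must be smaller than band width (det F > 0)")
    z_lo, z_hi = center_mm - w / 2.0, center_mm + w / 2.0
    s = 1.0 - delta / w

    def uz(z):
        return -delta * np.clip((z - z_lo) / w, 0.0, 1.0)

    def disp(p):
        u = np.zeros_like(p)
        u[..., 2] = uz(p[..., 2])
        return u

    def inv(p):
        y = p[..., 2]
        z = np.where(y <= z_lo, y, np.where(y >= z_hi - delta, y + delta, (y - z_lo) / s + z_lo))
        out = p.copy()
        out[..., 2] = z
        return out

    def grad(p):
        F = np.broadcast_to(np.eye(3), p.shape[:-1] + (3, 3)).copy()
        inband = (p[..., 2] > z_lo) & (p[..., 2] < z_hi)
        F[..., 2, 2] = np.where(inband, s, 1.0)
        return F

    return GroundTruthDeformation(disp, inv, grad, f"compaction band d/w={delta / w:.3f}")


def uniform_dilation(alpha: float, center: tuple[float, float, float] = (0, 0, 0)) -> GroundTruthDeformation:
    c = np.asarray(center, dtype=float)
    F = (1.0 + alpha) * np.eye(3)
    return GroundTruthDeformation(
        displacement=lambda p: alpha * (p - c),
        inverse_map=lambda p: (p - c) / (1.0 + alpha) + c,
        gradient=lambda p: np.broadcast_to(F, p.shape[:-1] + (3, 3)).copy(),
        description=f"uniform dilation {alpha}",
    )


def apply_deformation(
    pre: DensityVolume, truth: GroundTruthDeformation, order: int = 1
) -> DensityVolume:
    """Resample ``pre`` through the deformation: post(y) = pre(phi^-1(y)).

    Linear interpolation by default (exact at grid points for the identity).
    Raises if the inverse map requests material outside the pre-test domain
    by more than one voxel beyond where the pre image carries bone.
    """
    nz, ny, nx = pre.shape
    zz, yy, xx = np.meshgrid(
        np.arange(nz, dtype=float), np.arange(ny, dtype=float), np.arange(nx, dtype=float),
        indexing="ij",
    )
    pts = np.stack([xx, yy, zz], axis=-1) * pre.spacing  # (x, y, z) mm
    src = truth.inverse_map(pts) / pre.spacing
    coords = np.stack([src[..., 2], src[..., 1], src[..., 0]])  # back to (z, y, x) index order
    post = ndimage.map_coordinates(pre.data, coords, order=order, mode="constant", cval=0.0)
    meta = dict(pre.metadata)
    meta["deformation"] = truth.description
    return DensityVolume(post, pre.spacing, pre.origin, meta)


def downscale(vol: DensityVolume, factor: int = 3) -> DensityVolume:
    """Block-mean downscaling (micro-CT to working resolution emulation)."""
    nz, ny, nx = (s - s % factor for s in vol.shape)
    d = vol.data[:nz, :ny, :nx]
    d = d.reshape(nz // factor, factor, ny // factor, factor, nx // factor, factor)
    out = d.mean(axis=(1, 3, 5))
    return DensityVolume(out, vol.spacing * factor, vol.origin, dict(vol.metadata))


def save_ground_truth(truth: GroundTruthDeformation, centers: np.ndarray, path: str | Path) -> None:
    """Persist a deformation's description and per-cell true F as JSON + npy."""
    path = Path(path)
    F = truth.true_F_on_grid(centers)
    np.save(path.with_suffix(".npy"), F)
    path.with_suffix(".json").write_text(
        json.dumps({"description": truth.description, "grid_shape": list(F.shape[:-2])})
    )
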