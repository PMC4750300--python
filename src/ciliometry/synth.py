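"""Synthetic confocal Z-stacks of straight cilia with known geometry.

A ground-truth cilium is a straight 3D segment (the continuous-slope
assumption under which the Pythagorean length estimate is exact).  The
renderer deposits a uniform linear intensity density along the segment,
convolves with a separable anisotropic Gaussian PSF (axial σ larger than
lateral, the standard confocal approximation), adds a constant background
and Gaussian read-out noise, and quantises to 8-bit.

Ground truth returned alongside the rendered volume — projected endpoints
and the slice span of the un-blurred segment — is analytic, so it is
independent of any detection step.  Two identities make these stacks an
oracle for the measurement methods: the true projected length is
``L·cos(elevation)`` and the true axial extent is ``L·sin(elevation)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .stack_io import CiliumAnnotation, ZStack

__all__ = [
    "GroundTruthCilium",
    "RenderConfig",
    "render_stack",
    "resample_z",
    "slice_span",
    "simulate_cohort",
    "CohortSample",
]


@dataclass(frozen=True)
class GroundTruthCilium:
    """True 3D segment parameters of one synthetic cilium.

    ``base_xyz`` is the starting endpoint in µm (x, y, z order);
    ``elevation_deg`` is the angle between the cilium axis and the imaging
    (x–y) plane, 0° lying flat and 90° perpendicular to the coverslip;
    ``azimuth_deg`` is the in-plane direction; ``amplitude`` the post-blur
    peak intensity on the 8-bit scale.
    """

    cilium_id: str
    base_xyz: tuple[float, float, float]
    length_um: float
    elevation_deg: float
    azimuth_deg: float = 0.0
    amplitude: float = 100.0

    def __post_init__(self) -> None:
        if not self.length_um > 0:
            raise ValueError("length_um must be positive")
        if not 0.0 <= self.elevation_deg <= 90.0:
            raise ValueError("elevation_deg must lie in [0, 90]")
        if not 0.0 < self.amplitude <= 255.0:
            raise ValueError("amplitude must lie in (0, 255]")

    @property
    def direction(self) -> np.ndarray:
        """Unit direction vector (x, y, z)."""
        el = math.radians(self.elevation_deg)
        az = math.radians(self.azimuth_deg)
        return np.array([math.cos(el) * math.cos(az), math.cos(el) * math.sin(az), math.sin(el)])

    @property
    def end_xyz(self) -> np.ndarray:
        return np.asarray(self.base_xyz, float) + self.length_um * self.direction

    @property
    def projected_length_um(self) -> float:
        """True length of the segment's x–y projection: L·cos(elevation)."""
        return self.length_um * math.cos(math.radians(self.elevation_deg))

    @property
    def z_extent_um(self) -> float:
        """True axial extent of the segment: L·sin(elevation)."""
        return self.length_um * math.sin(math.radians(self.elevation_deg))


@dataclass(frozen=True)
class RenderConfig:
    """Rendering parameters (sizes in voxels, physical scales in µm)."""

    shape: tuple[int, int, int]  # (nz, ny, nx)
    dxy: float = 0.1
    dz: float = 0.25
    psf_sigma_xy: float = 0.1
    psf_sigma_z: float = 0.3
    background_level: float = 10.0
    noise_sd: float = 5.0
    seed: int = 0
    poisson: bool = False
    allow_saturation: bool = False

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError("shape must be a positive (nz, ny, nx) triple")
        if not (self.psf_sigma_xy > 0 and self.psf_sigma_z >= self.psf_sigma_xy):
            raise ValueError("need psf_sigma_z >= psf_sigma_xy > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (self.dxy > 0 and self.dz > 0):
            raise ValueError("dxy and dz must be positive")


def slice_span(z_lo_um: float, z_hi_um: float, dz: float, nz: int | None = None,
               origin_um: float = 0.0) -> tuple[int, int]:
    """Inclusive slice-index span covering an axial interval.

    Slice ``k`` samples the slab ``[origin + (k-1/2)·dz, origin + (k+1/2)·dz)``;
    a cilium appears in every slice whose slab its segment touches, which
    reduces to nearest-integer rounding of the endpoint coordinates.  A flat
    segment lying exactly on a slice plane therefore spans one slice.
    """
    if z_hi_um < z_lo_um:
        raise ValueError("need z_lo_um <= z_hi_um")
    eps = 1e-9
    z_first = int(math.floor((z_lo_um - origin_um) / dz + 0.5 + eps))
    z_last = int(math.floor((z_hi_um - origin_um) / dz + 0.5 + eps))
    if nz is not None:
        z_first = min(max(z_first, 0), nz - 1)
        z_last = min(max(z_last, 0), nz - 1)
    return z_first, z_last


def _analytic_annotation(c: GroundTruthCilium, cfg: RenderConfig) -> CiliumAnnotation:
    base = np.asarray(c.base_xyz, float)
    end = c.end_xyz
    zf, zl = slice_span(min(base[2], end[2]), max(base[2], end[2]), cfg.dz, cfg.shape[0])
    p0 = base[:2] / cfg.dxy
    p1 = end[:2] / cfg.dxy
    if np.allclose(p0, p1):
        # perpendicular cilium: the projection degenerates to a point;
        # offset the second point by a negligible amount to keep a valid polyline
        p1 = p1 + np.array([1e-6, 0.0])
    return CiliumAnnotation(cilium_id=c.cilium_id, points_xy=np.stack([p0, p1]),
                            z_first=zf, z_last=zl)


def _check_inside(c: GroundTruthCilium, cfg: RenderConfig) -> None:
    nz, ny, nx = cfg.shape
    pad_xy = 3.0 * cfg.psf_sigma_xy
    pad_z = 3.0 * cfg.psf_sigma_z
    hi = np.array([(nx - 1) * cfg.dxy - pad_xy, (ny - 1) * cfg.dxy - pad_xy,
                   (nz - 1) * cfg.dz - pad_z])
    lo = np.array([pad_xy, pad_xy, pad_z])
    for p in (np.asarray(c.base_xyz, float), c.end_xyz):
        if np.any(p < lo - 1e-9) or np.any(p > hi + 1e-9):
            raise ValueError(
                f"cilium {c.cilium_id!r} does not fit inside the volume after PSF padding"
            )


def _splat_segment(c: GroundTruthCilium, cfg: RenderConfig) -> np.ndarray:
    """Deposit the segment's uniform linear density on the voxel grid.

    Sub-voxel sample positions are distributed trilinearly over the eight
    neighbouring voxels so that the deposited mass is smooth in the segment's
    sub-voxel placement.
    """
    nz, ny, nx = cfg.shape
    step = min(cfg.dxy, cfg.dz) / 4.0
    n = max(2, int(math.ceil(c.length_um / step)) + 1)
    t = np.linspace(0.0, c.length_um, n)
    pts = np.asarray(c.base_xyz, float)[None, :] + t[:, None] * c.direction[None, :]
    # voxel-index coordinates, (z, y, x)
    zi = pts[:, 2] / cfg.dz
    yi = pts[:, 1] / cfg.dxy
    xi = pts[:, 0] / cfg.dxy
    vol = np.zeros((nz, ny, nx), dtype=np.float64)
    w = np.full(n, 1.0 / n)
    z0 = np.floor(zi).astype(int)
    y0 = np.floor(yi).astype(int)
    x0 = np.floor(xi).astype(int)
    fz, fy, fx = zi - z0, yi - y0, xi - x0
    for dz_ in (0, 1):
        for dy_ in (0, 1):
            for dx_ in (0, 1):
                wz = fz if dz_ else 1.0 - fz
                wy = fy if dy_ else 1.0 - fy
                wx = fx if dx_ else 1.0 - fx
                np.add.at(vol, (np.clip(z0 + dz_, 0, nz - 1),
                                np.clip(y0 + dy_, 0, ny - 1),
                                np.clip(x0 + dx_, 0, nx - 1)), w * wz * wy * wx)
    return vol


def render_stack(cilia: Sequence[GroundTruthCilium], cfg: RenderConfig
                 ) -> tuple[ZStack, list[CiliumAnnotation]]:
    """Render ground-truth cilia into a noisy 8-bit Z-stack.

    Each cilium is normalised so its post-blur peak equals its
    ``amplitude``, then summed onto the background.  Deterministic for a
    fixed ``cfg.seed``.

    Returns the stack together with the analytic annotations (projected
    endpoints in pixel units and the slice span of the un-blurred segment).
    """
    if not cfg.allow_saturation:
        for c in cilia:
            if c.amplitude + cfg.background_level > 255.0:
                raise ValueError(
                    f"cilium {c.cilium_id!r}: amplitude + background exceeds the 8-bit "
                    "ceiling; pass allow_saturation=True to render anyway"
                )
    vol = np.zeros(cfg.shape, dtype=np.float64)
    sigma_vox = (cfg.psf_sigma_z / cfg.dz, cfg.psf_sigma_xy / cfg.dxy, cfg.psf_sigma_xy / cfg.dxy)
    annotations = []
    for c in cilia:
        _check_inside(c, cfg)
        field = ndimage.gaussian_filter(_splat_segment(c, cfg), sigma_vox)
        peak = field.max()
        if peak > 0:
            vol += field * (c.amplitude / peak)
        annotations.append(_analytic_annotation(c, cfg))
    vol += cfg.background_level
    rng = np.random.default_rng(cfg.seed)
    if cfg.poisson:
        vol = rng.poisson(np.clip(vol, 0, None)).astype(np.float64)
    if cfg.noise_sd > 0:
        vol += rng.normal(0.0, cfg.noise_sd, size=vol.shape)
    voxels = np.clip(np.rint(vol), 0, 255).astype(np.uint8)
    return ZStack(voxels=voxels, dxy=cfg.dxy, dz=cfg.dz), annotations


def resample_z(stack: ZStack, new_dz: float, origin_um: float = 0.0) -> ZStack:
    """Resample a stack onto a coarser axial grid (linear interpolation).

    The new grid samples ``z = origin_um + k·new_dz`` for every position
    inside the original axial range; ``origin_um`` models the uncontrolled
    grid phase of a fresh acquisition.  In-plane content is untouched.
    Downsampling only: ``new_dz`` must not be finer than the input step.
    """
    if new_dz < stack.dz - 1e-12:
        raise ValueError(f"new_dz={new_dz} is finer than the stack's dz={stack.dz}")
    if not 0.0 <= origin_um < new_dz + 1e-12:
        raise ValueError("origin_um must lie in [0, new_dz)")
    if abs(new_dz - stack.dz) < 1e-12 and origin_um == 0.0:
        return ZStack(voxels=stack.voxels.copy(), dxy=stack.dxy, dz=stack.dz)
    z_max = stack.z_range_um
    n_new = int(math.floor((z_max - origin_um) / new_dz + 1e-9)) + 1
    if n_new < 1:
        raise ValueError("resampled grid contains no slices inside the stack")
    z_new = origin_um + new_dz * np.arange(n_new)
    idx = z_new / stack.dz
    lo = np.floor(idx).astype(int)
    hi = np.minimum(lo + 1, stack.nz - 1)
    frac = (idx - lo)[:, None, None]
    vox = stack.voxels.astype(np.float64)
    out = (1.0 - frac) * vox[lo] + frac * vox[hi]
    return ZStack(voxels=np.clip(np.rint(out), 0, 255).astype(np.uint8),
                  dxy=stack.dxy, dz=new_dz)


@dataclass(frozen=True)
class CohortSample:
    """One synthetic cilium with its rendered stack and ground truth."""

    truth: GroundTruthCilium
    stack: ZStack
    annotation: CiliumAnnotation
    population: str  # "flat" or "angled" by construction (elevation draw)


def _volume_for(c_len: float, elevation: float, azimuth: float, cfg: RenderConfig,
                margin_xy: float = 0.8, margin_z: float = 1.0
                ) -> tuple[tuple[int, int, int], tuple[float, float, float]]:
    """Smallest volume shape and base position that hold the segment with margins."""
    el, az = math.radians(elevation), math.radians(azimuth)
    ex = c_len * math.cos(el) * math.cos(az)
    ey = c_len * math.cos(el) * math.sin(az)
    ezz = c_len * math.sin(el)
    nx = int(math.ceil((abs(ex) + 2 * margin_xy) / cfg.dxy)) + 1
    ny = int(math.ceil((abs(ey) + 2 * margin_xy) / cfg.dxy)) + 1
    nz = int(math.ceil((ezz + 2 * margin_z) / cfg.dz)) + 1
    bx = margin_xy if ex >= 0 else margin_xy + abs(ex)
    by = margin_xy if ey >= 0 else margin_xy + abs(ey)
    return (nz, ny, nx), (bx, by, margin_z)


def simulate_cohort(n_flat: int = 31, n_angled: int = 31, *, seed: int = 0,
                    mean_length_um: float = 3.0, sd_length_um: float = 0.7,
                    length_bounds_um: tuple[float, float] = (1.5, 6.0),
                    flat_elevation_deg: tuple[float, float] = (0.0, 5.0),
                    angled_elevation_deg: tuple[float, float] = (45.0, 70.0),
                    base_config: RenderConfig | None = None) -> list[CohortSample]:
    """Simulate a two-population cohort of rendered cilia.

    Both populations draw true lengths from the same distribution (normal,
    truncated to ``length_bounds_um``); they differ only in elevation:
    "flat" cilia lie close to the imaging plane, "angled" cilia are tilted
    out of it.  Each cilium is rendered in its own tight volume.
    """
    rng = np.random.default_rng(seed)
    base = base_config or RenderConfig(shape=(1, 1, 1))
    samples: list[CohortSample] = []
    pops = [("flat", flat_elevation_deg)] * n_flat + [("angled", angled_elevation_deg)] * n_angled
    for i, (pop, el_range) in enumerate(pops):
        length = float(np.clip(rng.normal(mean_length_um, sd_length_um), *length_bounds_um))
        elevation = float(rng.uniform(*el_range))
        azimuth = float(rng.uniform(0.0, 360.0))
        shape, base_xyz = _volume_for(length, elevation, azimuth, base)
        cfg = replace(base, shape=shape, seed=int(rng.integers(0, 2**31 - 1)))
        truth = GroundTruthCilium(
            cilium_id=f"c{i:03d}", base_xyz=base_xyz, length_um=length,
            elevation_deg=elevation, azimuth_deg=azimuth,
        )
        stack, anns = render_stack([truth], cfg)
        samples.append(CohortSample(truth=truth, stack=stack, annotation=anns[0], population=pop))
    return samples
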