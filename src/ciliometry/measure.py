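"""The three cilium-length measurement methods and the flat/angled classifier.

MIP
    Length of the annotated polyline on the maximum intensity projection.
    Ignores axial extent entirely, so a cilium tilted out of the imaging
    plane is underestimated by a factor ≈ cos(elevation).
PyT
    Pythagorean estimate ``c = sqrt(a² + b²)`` where ``a`` is the projected
    (MIP) length and ``b`` the axial extent taken from the slice span:
    ``b = (z_last − z_first)·dz``.  Exact for a straight cilium up to the
    axial quantisation of the slice grid.
DAAS
    Measurement on a vertical "side view" plane resliced through the stack
    along the cilium's in-plane direction, built column-by-column by
    bilinear interpolation within each slice.  The polyline is measured
    with the plane's anisotropic calibration (``ds`` per column, ``dz``
    per row).

Flat cilia are those whose whole signal appears in at most
``flat_max_slices`` (default four) Z-slices; anything spanning more is
angled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

from .stack_io import CiliumAnnotation, ZStack

__all__ = [
    "FLAT",
    "ANGLED",
    "METHODS",
    "MeasureConfig",
    "LengthMeasurement",
    "ReplicateSummary",
    "ReslicedPlane",
    "max_projection",
    "polyline_length_2d",
    "z_extent",
    "measure_mip",
    "measure_pyt",
    "reslice",
    "measure_daas",
    "auto_endpoints",
    "daas_from_stack",
    "detect_z_span",
    "classify",
    "average_replicates",
    "measure_dataset",
]

FLAT = "FLAT"
ANGLED = "ANGLED"
METHODS = ("MIP", "PYT", "DAAS")


@dataclass(frozen=True)
class MeasureConfig:
    """Measurement parameters.

    ``intensity_lo``/``intensity_hi`` delimit the grayscale window in which
    cilia are measured (8-bit scale, default 55–255); ``flat_max_slices``
    is the largest slice span still classified as flat (default 4).
    """

    intensity_lo: float = 55.0
    intensity_hi: float = 255.0
    flat_max_slices: int = 4

    def __post_init__(self) -> None:
        if not 0 <= self.intensity_lo < self.intensity_hi <= 255:
            raise ValueError("need 0 <= intensity_lo < intensity_hi <= 255")
        if self.flat_max_slices < 1:
            raise ValueError("flat_max_slices must be >= 1")


@dataclass(frozen=True)
class LengthMeasurement:
    """One method's length estimate for one cilium replicate."""

    cilium_id: str
    method: str
    replicate: int
    length_um: float

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}; got {self.method!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if not self.length_um >= 0:
            raise ValueError("length_um must be non-negative")


@dataclass(frozen=True)
class ReslicedPlane:
    """Vertical side-view plane through the stack along a selected vector.

    ``pixels`` is indexed ``(z, s)`` with ``s`` the distance along the
    vector; one column per ``ds`` (= the stack's dxy) and one row per
    original slice.  ``s_origin_um`` is the physical s-coordinate of column
    0 relative to the first selected point (negative when the plane extends
    behind it).
    """

    pixels: np.ndarray
    ds: float
    dz: float
    s_origin_um: float = 0.0

    def __post_init__(self) -> None:
        if not (self.ds > 0 and self.dz > 0):
            raise ValueError("ds and dz must be positive")


def max_projection(stack: ZStack) -> tuple[np.ndarray, float]:
    """Maximum intensity projection: per-pixel maximum across all slices.

    Returns the 2D image (y, x) and its pixel calibration (µm/pixel).
    """
    return stack.voxels.max(axis=0), stack.dxy


def polyline_length_2d(points_xy: np.ndarray, dxy: float) -> float:
    """Euclidean length of a 2D polyline in µm (points in pixel units)."""
    pts = np.asarray(points_xy, float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    return float(np.hypot(*np.diff(pts, axis=0).T).sum() * dxy)


def z_extent(annotation: CiliumAnnotation, dz: float) -> float:
    """Axial extent ``b`` in µm: slice-interval count × step size.

    Uses intervals, not slice count, so a cilium visible in exactly one
    slice has zero axial extent.
    """
    return (annotation.z_last - annotation.z_first) * dz


def measure_mip(annotation: CiliumAnnotation, dxy: float, replicate: int = 1) -> LengthMeasurement:
    """Projected (MIP) length: the polyline length only, no axial term."""
    return LengthMeasurement(annotation.cilium_id, "MIP", replicate,
                             polyline_length_2d(annotation.points_xy, dxy))


def measure_pyt(annotation: CiliumAnnotation, dxy: float, dz: float,
                replicate: int = 1) -> LengthMeasurement:
    """Pythagorean length ``c = sqrt(a² + b²)``.

    ``a`` is the projected polyline length, ``b`` the axial extent from the
    slice span.  For a single-slice cilium ``b = 0`` and PyT reduces
    exactly to MIP.
    """
    a = polyline_length_2d(annotation.points_xy, dxy)
    b = z_extent(annotation, dz)
    return LengthMeasurement(annotation.cilium_id, "PYT", replicate, math.hypot(a, b))


def classify(annotation: CiliumAnnotation, cfg: MeasureConfig = MeasureConfig()) -> str:
    """Flat/angled classification from the slice span alone.

    FLAT iff the cilium's whole signal appears in at most
    ``cfg.flat_max_slices`` slices (inclusive span); otherwise ANGLED.
    """
    return FLAT if annotation.span_slices <= cfg.flat_max_slices else ANGLED


def reslice(stack: ZStack, p1_xy: Sequence[float], p2_xy: Sequence[float],
            margin_um: float = 1.0) -> ReslicedPlane:
    """Build the DAAS side-view plane along the vector p1→p2.

    The slicing plane contains the z-axis, so sample z-coordinates coincide
    with slice positions and each sample is a bilinear interpolation of the
    four neighbouring pixels within its own slice.  Columns are spaced at
    the stack's own in-plane resolution and extend ``margin_um`` beyond
    both selected points (clipped to the image bounds).
    """
    p1 = np.asarray(p1_xy, float)
    p2 = np.asarray(p2_xy, float)
    v = p2 - p1
    norm_px = float(np.hypot(*v))
    if norm_px == 0.0:
        raise ValueError("p1 and p2 must be distinct")
    for p in (p1, p2):
        if not (0 <= p[0] <= stack.nx - 1 and 0 <= p[1] <= stack.ny - 1):
            raise ValueError(f"point {tuple(p)} outside image bounds")
    u = v / norm_px
    margin_px = margin_um / stack.dxy
    t = np.arange(-math.floor(margin_px), math.floor(norm_px + margin_px) + 1, dtype=float)
    xs = p1[0] + u[0] * t
    ys = p1[1] + u[1] * t
    inside = (xs >= 0) & (xs <= stack.nx - 1) & (ys >= 0) & (ys <= stack.ny - 1)
    if not inside.any():
        raise ValueError("resliced plane lies entirely outside the image")
    t, xs, ys = t[inside], xs[inside], ys[inside]
    zz = np.repeat(np.arange(stack.nz, dtype=float), t.size)
    yy = np.tile(ys, stack.nz)
    xx = np.tile(xs, stack.nz)
    samples = ndimage.map_coordinates(stack.voxels.astype(np.float64),
                                      np.stack([zz, yy, xx]), order=1)
    pixels = samples.reshape(stack.nz, t.size)
    return ReslicedPlane(pixels=pixels, ds=stack.dxy, dz=stack.dz,
                         s_origin_um=float(t[0]) * stack.dxy)


def measure_daas(plane: ReslicedPlane, points_sz: np.ndarray, cilium_id: str = "",
                 replicate: int = 1) -> LengthMeasurement:
    """Anisotropy-aware polyline length on the resliced plane.

    ``points_sz`` is an ordered list of ``(s, z)`` picks in plane pixel
    units (column, row); each segment contributes
    ``sqrt((Δs·ds)² + (Δz·dz)²)`` µm.
    """
    pts = np.asarray(points_sz, float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    d = np.diff(pts, axis=0)
    length = float(np.hypot(d[:, 0] * plane.ds, d[:, 1] * plane.dz).sum())
    return LengthMeasurement(cilium_id, "DAAS", replicate, length)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels = skmeasure.label(mask, connectivity=2)
    if labels.max() == 0:
        raise ValueError("no pixel above the intensity threshold")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def _farthest_pair(coords: np.ndarray, spacing: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Most mutually distant pixel pair under the physical metric.

    Ties are broken by the lexicographically smallest (row, col) pair, so
    the result is deterministic.
    """
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    coords = coords[order]
    phys = coords * np.asarray(spacing, float)
    d2 = ((phys[:, None, :] - phys[None, :, :]) ** 2).sum(axis=2)
    best = d2.max()
    ii, jj = np.nonzero(d2 >= best - 1e-12)
    keep = ii <= jj
    ii, jj = ii[keep], jj[keep]
    k = 0  # lexicographically smallest (coords are sorted, nonzero scans row-major)
    return coords[ii[k]].astype(float), coords[jj[k]].astype(float)


def _principal_axis(image: np.ndarray, comp: np.ndarray, spacing: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Intensity-weighted centroid and principal axis of a component.

    Both are computed in physical (µm) coordinates; with an anisotropic
    PSF the weighted principal axis tracks the streak direction far better
    than the chord between the mask's extremal pixels, whose corners are
    inflated along the more-blurred axis.
    """
    coords = np.argwhere(comp).astype(float)
    w = image[comp].astype(float)
    phys = coords * spacing
    centroid = (phys * w[:, None]).sum(axis=0) / w.sum()
    d = phys - centroid
    cov = (d[:, :, None] * d[:, None, :] * w[:, None, None]).sum(axis=0) / w.sum()
    evals, evecs = np.linalg.eigh(cov)
    return centroid, evecs[:, int(np.argmax(evals))]


def _ridge_axis(image: np.ndarray, centroid: np.ndarray, axis: np.ndarray,
                spacing: np.ndarray, half_len: float, floor: float,
                n_iter: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Refine a streak axis by tracking the intensity-weighted centerline.

    The weighted principal axis of a short streak is rotated towards the
    more-blurred direction of an anisotropic PSF.  The centerline is not:
    perpendicular blur is symmetric about the core, so the
    background-subtracted perpendicular centroid at stations along the
    streak sits on the true axis.  A straight line through those ridge
    points re-estimates centroid and direction; tip stations are excluded
    because longitudinal edge effects skew their perpendicular profiles.
    """
    step = 0.25 * float(spacing.min())
    offs = np.arange(-0.5, 0.5 + step / 2, step)
    for _ in range(n_iter):
        span = 0.6 * half_len
        if span < 2 * step:
            break
        ts = np.linspace(-span, span, 15)
        perp = np.array([-axis[1], axis[0]])
        base = centroid[None, :] + ts[:, None] * axis[None, :]
        pos = base[:, None, :] + offs[None, :, None] * perp[None, None, :]
        pix = pos / spacing[None, None, :]
        vals = ndimage.map_coordinates(image.astype(np.float64),
                                       pix.reshape(-1, 2).T, order=1,
                                       mode="nearest").reshape(len(ts), len(offs))
        wts = np.clip(vals - floor, 0.0, None)
        good = wts.sum(axis=1) > 0
        if good.sum() < 2:
            break
        delta = (wts[good] * offs[None, :]).sum(axis=1) / wts[good].sum(axis=1)
        pts = base[good] + delta[:, None] * perp[None, :]
        centroid = pts.mean(axis=0)
        d = pts - centroid
        cov = d.T @ d
        evals, evecs = np.linalg.eigh(cov)
        new_axis = evecs[:, int(np.argmax(evals))]
        if new_axis @ axis < 0:
            new_axis = -new_axis
        axis = new_axis
    return centroid, axis


def _half_crossings(image: np.ndarray, centroid: np.ndarray, axis: np.ndarray,
                    spacing: np.ndarray, half_len: float, half_level: float
                    ) -> tuple[np.ndarray, np.ndarray] | None:
    """Outermost half-level crossings of the intensity profile along an axis.

    For a uniform line blurred by a symmetric PSF, intensity at the true
    tip is exactly halfway between the line's plateau and the background,
    so the outermost crossings of that level along the streak axis are
    unbiased tip estimates.  Returns two sub-pixel (row, col) positions or
    None when the profile never reaches the level.
    """
    step = 0.25 * float(spacing.min())
    T = half_len + 1.0
    ts = np.arange(-T, T + step / 2, step)
    pix = (centroid[None, :] + ts[:, None] * axis[None, :]) / spacing[None, :]
    vals = ndimage.map_coordinates(image.astype(np.float64), pix.T, order=1, mode="nearest")
    above = vals >= half_level
    if not above.any():
        return None

    def cross(k_outer: int, k_inner: int) -> float:
        v0, v1 = vals[k_outer], vals[k_inner]
        frac = 0.0 if v1 == v0 else (half_level - v0) / (v1 - v0)
        return ts[k_outer] + frac * (ts[k_inner] - ts[k_outer])

    k_lo = int(np.argmax(above))
    k_hi = len(ts) - 1 - int(np.argmax(above[::-1]))
    t_lo = ts[0] if k_lo == 0 else cross(k_lo - 1, k_lo)
    t_hi = ts[-1] if k_hi == len(ts) - 1 else cross(k_hi + 1, k_hi)
    p_lo = (centroid + t_lo * axis) / spacing
    p_hi = (centroid + t_hi * axis) / spacing
    return p_lo, p_hi


def auto_endpoints(image: np.ndarray, cfg: MeasureConfig = MeasureConfig(),
                   spacing: tuple[float, float] = (1.0, 1.0),
                   refine: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Automatic endpoint picks replacing the operator's clicks.

    Thresholds the image at ``cfg.intensity_lo``, keeps the largest
    connected component and finds its two most mutually distant pixels
    under the physical metric given by ``spacing`` (µm per row, µm per
    column).  With ``refine`` (the default) the pair is then replaced by
    sub-pixel tip estimates: the streak axis is taken from the component's
    intensity-weighted principal axis and each tip is the outermost
    crossing of the half-way level between the component's plateau and the
    background along that axis.

    Returns two ``(row, col)`` positions ordered lexicographically.
    """
    img = np.asarray(image, float)
    mask = (img >= cfg.intensity_lo) & (img <= cfg.intensity_hi)
    comp = _largest_component(mask)
    coords = np.argwhere(comp)
    e0, e1 = _farthest_pair(coords, spacing)
    if refine and not np.array_equal(e0, e1):
        sp = np.asarray(spacing, float)
        plateau = float(img[comp].max())
        outside = img[~comp]
        floor = float(np.median(outside)) if outside.size else 0.0
        centroid, axis = _principal_axis(img, comp, sp)
        half_len = 0.5 * float(np.hypot(*((e1 - e0) * sp)))
        centroid, axis = _ridge_axis(img, centroid, axis, sp, half_len, floor)
        refined = _half_crossings(img, centroid, axis, sp, half_len,
                                  0.5 * (plateau + floor))
        if refined is not None:
            e0, e1 = refined
    if tuple(e1) < tuple(e0):
        e0, e1 = e1, e0
    return e0, e1


def daas_from_stack(stack: ZStack, annotation: CiliumAnnotation,
                    cfg: MeasureConfig = MeasureConfig(), margin_um: float = 1.0,
                    replicate: int = 1) -> LengthMeasurement:
    """Full automatic DAAS measurement for one annotated cilium.

    Reslices along the annotation's first→last point, auto-picks the two
    endpoints on the side view, and measures the anisotropic segment
    length.
    """
    plane = reslice(stack, annotation.points_xy[0], annotation.points_xy[-1], margin_um)
    (r0, c0), (r1, c1) = auto_endpoints(plane.pixels, cfg, spacing=(plane.dz, plane.ds))
    pts_sz = np.array([[c0, r0], [c1, r1]])
    return measure_daas(plane, pts_sz, cilium_id=annotation.cilium_id, replicate=replicate)


def detect_z_span(stack: ZStack, annotation: CiliumAnnotation,
                  cfg: MeasureConfig = MeasureConfig(), window_um: float = 0.5
                  ) -> tuple[int, int]:
    """Slice span in which the cilium's signal *appears* at the threshold.

    Emulates the operator stepping through the stack: a slice shows the
    cilium when, within ``window_um`` of the annotated polyline, the 3×3
    mean-filtered intensity reaches ``cfg.intensity_lo``.  The mild
    smoothing keeps single noise voxels from extending the span.
    """
    pts = annotation.points_xy
    yy, xx = np.mgrid[0:stack.ny, 0:stack.nx]
    dist2 = np.full((stack.ny, stack.nx), np.inf)
    for p, q in zip(pts[:-1], pts[1:]):
        d = q - p
        rel = np.stack([xx - p[0], yy - p[1]], axis=-1)
        tt = np.clip((rel @ d) / (d @ d), 0.0, 1.0)
        proj = p[None, None, :] + tt[..., None] * d[None, None, :]
        dd = (xx - proj[..., 0]) ** 2 + (yy - proj[..., 1]) ** 2
        dist2 = np.minimum(dist2, dd)
    window = dist2 <= (window_um / stack.dxy) ** 2
    visible = []
    for z in range(stack.nz):
        sm = ndimage.uniform_filter(stack.voxels[z].astype(np.float64), size=3)
        visible.append(bool((sm[window] >= cfg.intensity_lo).any()))
    visible = np.asarray(visible)
    if not visible.any():
        raise ValueError(f"cilium {annotation.cilium_id!r}: no signal above threshold")
    zs = np.nonzero(visible)[0]
    return int(zs[0]), int(zs[-1])


@dataclass(frozen=True)
class ReplicateSummary:
    """Replicate-averaged length for one cilium and method."""

    cilium_id: str
    method: str
    mean_um: float
    range_um: float  # max − min across replicates; QC against the 0.3 µm technical ceiling
    n: int


def average_replicates(measurements: Sequence[LengthMeasurement]) -> ReplicateSummary:
    """Arithmetic mean of repeated measurements of one cilium and method.

    Also reports the replicate range (max − min) as a technical-error QC
    statistic.  Order of the input does not matter.
    """
    if not measurements:
        raise ValueError("need at least one measurement")
    ids = {m.cilium_id for m in measurements}
    methods = {m.method for m in measurements}
    if len(ids) != 1 or len(methods) != 1:
        raise ValueError(f"mixed cilium ids {ids} or methods {methods}")
    lengths = np.array([m.length_um for m in measurements], float)
    return ReplicateSummary(cilium_id=measurements[0].cilium_id, method=measurements[0].method,
                            mean_um=float(lengths.mean()),
                            range_um=float(lengths.max() - lengths.min()), n=lengths.size)


def _jittered(annotation: CiliumAnnotation, sd_px: float, rng: np.random.Generator
              ) -> CiliumAnnotation:
    if sd_px <= 0:
        return annotation
    pts = annotation.points_xy + rng.normal(0.0, sd_px, size=annotation.points_xy.shape)
    return CiliumAnnotation(annotation.cilium_id, pts, annotation.z_first, annotation.z_last)


def measure_dataset(items: Iterable[tuple[ZStack, CiliumAnnotation]],
                    cfg: MeasureConfig = MeasureConfig(), *,
                    methods: Sequence[str] = METHODS, n_replicates: int = 3,
                    jitter_um: float = 0.05, seed: int = 0,
                    z_span: str = "detected") -> "pd.DataFrame":
    """Measure every cilium with every requested method.

    Emulates the full operator protocol: the slice span used by PyT and by
    the flat/angled classification is, by default, judged from the image at
    the intensity threshold (``z_span="detected"``; pass ``"annotation"``
    to trust the annotated span verbatim), and each of the
    ``n_replicates`` repeated measurements perturbs the clicked endpoints
    by a seeded Gaussian jitter of ``jitter_um`` per coordinate
    (``jitter_um=0`` makes replicates identical).

    Returns a tidy DataFrame with one row per cilium × method × replicate:
    ``cilium_id, method, replicate, length_um, classification``.
    """
    import pandas as pd

    if z_span not in ("detected", "annotation"):
        raise ValueError("z_span must be 'detected' or 'annotation'")
    bad = [m for m in methods if m not in METHODS]
    if bad:
        raise ValueError(f"unknown methods {bad}")
    rng = np.random.default_rng(seed)
    rows = []
    for stack, ann in items:
        if z_span == "detected":
            zf, zl = detect_z_span(stack, ann, cfg)
            ann = CiliumAnnotation(ann.cilium_id, ann.points_xy, zf, zl)
        label = classify(ann, cfg)
        sd_px = jitter_um / stack.dxy
        for rep in range(1, n_replicates + 1):
            jit = _jittered(ann, sd_px, rng)
            for method in methods:
                if method == "MIP":
                    m = measure_mip(jit, stack.dxy, replicate=rep)
                elif method == "PYT":
                    m = measure_pyt(jit, stack.dxy, stack.dz, replicate=rep)
                else:
                    m = daas_from_stack(stack, jit, cfg, replicate=rep)
                rows.append((m.cilium_id, m.method, m.replicate, m.length_um, label))
    return pd.DataFrame(rows, columns=["cilium_id", "method", "replicate",
                                       "length_um", "classification"])
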