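"""Synthetic fluorescent-microangiography phantoms with known ground truth.

The study design this package supports — perfusing the renal vasculature with
a fluorescent microsphere/agarose mixture and optically sectioning it — has no
public image data, so every pipeline stage is validated against phantoms whose
vascular geometry is known exactly.

Two phantom kinds are generated:

* ``glomerulus`` — a set of smooth capillary loops entering and exiting near
  one pole (the vascular pole) and confined to an ellipsoidal tuft envelope.
  Loops are added until the rasterised lumen volume reaches a requested
  pre-dropout capillary density; segmental dropout then removes whole loop
  segments, mimicking the segmental capillary loss of sclerotic glomeruli.
* ``cortex`` — an anastomotic random tube plexus filling the field at a target
  lumen volume fraction, optionally with embedded glomerular tufts whose ROI
  masks are recorded so the glomerular-exclusion workflow can be exercised.

Imaging degradation (microsphere speckle, anisotropic PSF blur, tubular
autofluorescence on a second channel, sensor noise) is applied by
:func:`render_imaging`. Everything is a pure function of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from functools import lru_cache

import numpy as np
from scipy import interpolate, ndimage

from .geometry import (
    DEFAULT_DXY_UM,
    DEFAULT_DZ_UM,
    Ellipsoid,
    VoxelGeometry,
)
from .stack import ImageStack


class PhantomParameterError(ValueError):
    """Invalid phantom parameters (geometry does not fit, bad ranges, ...)."""


class GenerationError(RuntimeError):
    """A requested phantom property could not be realised within bounded attempts."""


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class PhantomParams:
    """Full parameterisation of a synthetic FMA phantom.

    Length scales are µm. ``tuft_semi_axes`` are assigned to the (x, y, z)
    axes with the vascular pole on the -z face. The defaults describe a
    sham-like rat glomerulus: envelope volume ≈ 1.4×10⁶ µm³ and pre-dropout
    capillary density 0.30, i.e. a capillary volume ≈ 4×10⁵ µm³, inside the
    2–5×10⁵ µm³ range established for rat glomeruli by electron-microscopic
    morphometry.
    """

    kind: str = "glomerulus"
    stack_shape: tuple[int, int, int] | None = None  # (z, y, x); None = auto
    voxel_xy: float = DEFAULT_DXY_UM
    voxel_z: float = DEFAULT_DZ_UM
    tuft_semi_axes: tuple[float, float, float] = (75.0, 70.0, 64.0)
    n_loops: int = 40
    capillary_density_target: float | None = 0.30  # pre-dropout lumen fraction
    tube_radius_mean: float = 3.5
    tube_radius_sd: float = 0.5
    segments_per_loop: int = 8
    dropout_fraction: float = 0.0
    enlargement_factor: float = 1.0
    loops_follow_enlargement: bool = True
    plexus_density: float = 0.05
    n_glomeruli: int = 0
    embedded_glomerulus_scale: float = 0.35
    psf_sigma_xy: float = 0.6
    psf_sigma_z: float = 1.2
    speckle_grain: float = 1.5
    speckle_amplitude: float = 0.35
    peak_intensity: float = 220.0
    autofluorescence_level: float = 30.0
    noise_sd: float = 6.0
    bit_depth: int = 8
    render_red: bool = True   # autofluorescence channel (not used by measurement)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("glomerulus", "cortex"):
            raise PhantomParameterError(f"unknown phantom kind {self.kind!r}")
        if not 0.0 <= self.dropout_fraction <= 1.0:
            raise PhantomParameterError(
                f"dropout_fraction must be in [0, 1], got {self.dropout_fraction}"
            )
        for name in ("voxel_xy", "voxel_z", "tube_radius_mean", "enlargement_factor"):
            if getattr(self, name) <= 0:
                raise PhantomParameterError(f"{name} must be > 0")
        if any(s <= 0 for s in self.tuft_semi_axes):
            raise PhantomParameterError("tuft semi-axes must be > 0")
        for name in ("psf_sigma_xy", "psf_sigma_z", "speckle_grain",
                     "speckle_amplitude", "noise_sd", "autofluorescence_level",
                     "tube_radius_sd"):
            if getattr(self, name) < 0:
                raise PhantomParameterError(f"{name} must be >= 0")
        if self.capillary_density_target is not None and not (
            0.0 < self.capillary_density_target < 1.0
        ):
            raise PhantomParameterError("capillary_density_target must be in (0, 1)")
        if not 0.0 < self.plexus_density < 1.0:
            raise PhantomParameterError("plexus_density must be in (0, 1)")
        if self.bit_depth not in (8, 16):
            raise PhantomParameterError("bit_depth must be 8 or 16")

    @property
    def geometry(self) -> VoxelGeometry:
        return VoxelGeometry(dx=self.voxel_xy, dy=self.voxel_xy, dz=self.voxel_z)

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)

    @property
    def max_intensity(self) -> int:
        return (1 << self.bit_depth) - 1

    def resolved_shape(self) -> tuple[int, int, int]:
        """Stack shape, auto-sized around the morphology when not given."""
        if self.stack_shape is not None:
            return tuple(int(s) for s in self.stack_shape)
        margin = 4.0 * self.tube_radius_mean + 3.0 * max(
            self.psf_sigma_xy, self.psf_sigma_z
        ) + 4.0
        if self.kind == "glomerulus":
            sx, sy, sz = (s * self.enlargement_factor for s in self.tuft_semi_axes)
            ex, ey, ez = 2 * sx + 2 * margin, 2 * sy + 2 * margin, 2 * sz + 2 * margin
        else:
            ex = ey = 190.0
            ez = 120.0
        return (
            int(np.ceil(ez / self.voxel_z)),
            int(np.ceil(ey / self.voxel_xy)),
            int(np.ceil(ex / self.voxel_xy)),
        )


#: Morphology presets for the two study arms of the remnant-kidney comparison.
#: ``snx`` reproduces the direction (not measured magnitudes) of the disease
#: contrasts: glomerular enlargement with segmental capillary dropout.
PRESETS: dict[str, dict] = {
    "sham": {"enlargement_factor": 1.0, "dropout_fraction": 0.0},
    "snx": {"enlargement_factor": 1.4, "dropout_fraction": 0.35},
}

#: Cortex-kind dropout for the disease preset (peritubular loss is more severe
#: than glomerular loss in the remnant-kidney model).
PRESET_CORTEX_DROPOUT = {"sham": 0.0, "snx": 0.5}

#: Voxel-geometry scales. "full" is the native confocal geometry; "coarse" is
#: a decimated geometry for large simulated cohorts (same µm-scale morphology).
SCALES: dict[str, dict] = {
    "full": {"voxel_xy": DEFAULT_DXY_UM, "voxel_z": DEFAULT_DZ_UM},
    "coarse": {"voxel_xy": 3.5, "voxel_z": 3.5},
}


def preset_params(preset: str, kind: str = "glomerulus", scale: str = "full",
                  **overrides) -> PhantomParams:
    """Build :class:`PhantomParams` from a named preset / scale combination."""
    if preset not in PRESETS:
        raise PhantomParameterError(f"unknown preset {preset!r}; have {list(PRESETS)}")
    if scale not in SCALES:
        raise PhantomParameterError(f"unknown scale {scale!r}; have {list(SCALES)}")
    fields = {**PRESETS[preset], **SCALES[scale], "kind": kind}
    if kind == "cortex":
        fields["dropout_fraction"] = PRESET_CORTEX_DROPOUT[preset]
    fields.update(overrides)
    return PhantomParams(**fields)


# ---------------------------------------------------------------------------
# tube geometry


@dataclass(frozen=True)
class TubeSegment:
    """One contiguous piece of a capillary tube: a polyline with a radius.

    ``samples`` optionally caches the centerline resampled at the
    rasterisation step (µm), to avoid recomputing it at every stamping pass.
    """

    points: np.ndarray  # (n, 3) physical (z, y, x) µm
    radius: float
    loop_id: int
    samples: np.ndarray | None = None

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def measure(self) -> float:
        """Analytic lumen measure length·πr², µm³ (ignores overlaps)."""
        return self.length * np.pi * self.radius**2


@dataclass(frozen=True)
class TubeNetwork:
    """A collection of tube segments; dropout removes whole segments."""

    segments: tuple[TubeSegment, ...]

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def total_measure(self) -> float:
        return float(sum(s.measure for s in self.segments))

    def __add__(self, other: "TubeNetwork") -> "TubeNetwork":
        return TubeNetwork(self.segments + other.segments)


def apply_dropout(
    network: TubeNetwork,
    fraction: float,
    seed: int | np.random.Generator,
    shape: tuple[int, int, int] | None = None,
    geometry: VoxelGeometry | None = None,
) -> tuple[TubeNetwork, float]:
    """Remove whole tube segments totalling ≈ ``fraction`` of the lumen volume.

    Segment-wise removal mimics segmental capillary loss (contiguous arcs
    disappear, rather than scattered voxels). When ``shape`` and ``geometry``
    are given the removed volume is accounted on the rasterisation grid with
    per-voxel coverage counts, so tube overlaps do not bias the realised
    fraction; otherwise the analytic measure length·πr² is used. Returns the
    retained network and the realised removed fraction. fraction 0 is the
    identity, 1 empties the network.
    """
    if not 0.0 <= fraction <= 1.0:
        raise PhantomParameterError(f"dropout fraction must be in [0, 1], got {fraction}")
    if fraction == 0.0 or len(network) == 0:
        return network, 0.0
    if fraction == 1.0:
        return TubeNetwork(()), 1.0
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    order = rng.permutation(len(network))

    if shape is not None and geometry is not None:
        net, realized, _ = _dropout_with_mask(network, fraction, order, shape,
                                              geometry)
        return net, realized

    measures = np.array([s.measure for s in network.segments])
    total_m = measures.sum()
    removed = set()
    acc_m = 0.0
    for i in order:
        if acc_m >= fraction * total_m:
            break
        removed.add(int(i))
        acc_m += measures[i]
    retained = tuple(s for i, s in enumerate(network.segments) if i not in removed)
    return TubeNetwork(retained), float(acc_m / total_m)


def _dropout_with_mask(
    network: TubeNetwork,
    fraction: float,
    order: np.ndarray,
    shape: tuple[int, int, int],
    geometry: VoxelGeometry,
) -> tuple[TubeNetwork, float, np.ndarray]:
    """Voxel-exact segment dropout; also returns the retained mask directly
    (counts > 0 after removal), saving a re-rasterisation pass."""
    vox_lists = [_segment_voxels(s, shape, geometry) for s in network.segments]
    counts = np.zeros(int(np.prod(shape)), dtype=np.uint16)
    for v in vox_lists:
        counts[v] += 1
    total = int(np.count_nonzero(counts))
    removed: set[int] = set()
    acc = 0
    for i in order:
        if acc >= fraction * total:
            break
        v = vox_lists[i]
        counts[v] -= 1
        acc += int(np.count_nonzero(counts[v] == 0))
        removed.add(int(i))
    retained = tuple(s for i, s in enumerate(network.segments)
                     if i not in removed)
    mask = (counts > 0).reshape(shape)
    return TubeNetwork(retained), float(acc / total), mask


def _segment_voxels(
    seg: TubeSegment, shape: tuple[int, int, int], geometry: VoxelGeometry
) -> np.ndarray:
    """Unique flat voxel indices covered by one segment (same stamping as
    :func:`rasterize_network`)."""
    sp = geometry.spacing_zyx
    step = 0.5 * float(sp.min())
    shape_arr = np.array(shape)
    pts = (seg.samples if seg.samples is not None
           else _resample_polyline(seg.points, step))
    offs = _ball_offsets(round(seg.radius, 1), geometry.dz, geometry.dy, geometry.dx)
    centers = np.rint(pts / sp).astype(np.int64)
    cand = (centers[:, None, :] + offs[None, :, :]).reshape(-1, 3)
    ok = np.all((cand >= 0) & (cand < shape_arr), axis=1)
    cand = cand[ok]
    flat = np.ravel_multi_index((cand[:, 0], cand[:, 1], cand[:, 2]), shape)
    return np.unique(flat)


def _loop_path(
    rng: np.random.Generator,
    rho_max: float,
    shell_fraction: float = 0.6,
    n_eval: int = 140,
) -> np.ndarray:
    """One capillary loop in normalised tuft coordinates (unit ball).

    A loop is a perturbed circle on a spherical shell: with probability
    ``shell_fraction`` the shell sits just under the envelope surface (the
    outermost loops are what define the tuft envelope in vivo), otherwise in
    the interior. Smooth low-order Fourier perturbations wobble the radius
    and the out-of-plane coordinate; points are radially clamped to
    ``rho_max`` so the finished tube stays inside the envelope.
    """
    if rng.uniform() < shell_fraction:
        rho = rho_max * rng.uniform(0.95, 1.0)
    else:
        rho = rho_max * rng.uniform(0.45, 0.92)
    # random orthonormal frame
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    e1, e2, e3 = q[:, 0], q[:, 1], q[:, 2]
    theta = np.linspace(0.0, 2 * np.pi, n_eval, endpoint=False)

    def fourier(amp: float) -> np.ndarray:
        out = np.zeros_like(theta)
        for k in (2, 3, 4):
            out += (rng.normal(0, amp / k) * np.cos(k * theta)
                    + rng.normal(0, amp / k) * np.sin(k * theta))
        return out

    radial = rho * (1.0 + fourier(0.10))
    wobble = rho * fourier(0.12)
    pts = (radial[:, None] * (np.cos(theta)[:, None] * e1
                              + np.sin(theta)[:, None] * e2)
           + wobble[:, None] * e3)
    pts = np.vstack([pts, pts[:1]])  # close the loop
    norms = np.linalg.norm(pts, axis=1)
    over = norms > rho_max
    pts[over] *= (rho_max / norms[over])[:, None]
    return pts


def _split_loop(pts: np.ndarray, radius: float, loop_id: int,
                n_segments: int, sample_step: float | None = None) -> list[TubeSegment]:
    """Split a closed polyline into contiguous tube segments (shared endpoints).

    The whole polyline is resampled once at ``sample_step`` and the samples
    are assigned to segments by arclength, so stamping stays gap-free while
    each segment carries its own cached sample points.
    """
    cuts = np.linspace(0, len(pts) - 1, n_segments + 1).astype(int)
    samples_all = sample_t = arclen = None
    if sample_step is not None:
        d = np.diff(pts, axis=0)
        seglen = np.sqrt((d * d).sum(axis=1))
        arclen = np.concatenate(([0.0], np.cumsum(seglen)))
        total = arclen[-1]
        n = max(int(np.ceil(total / sample_step)) + 1, 2)
        sample_t = np.linspace(0.0, total, n)
        idx = np.clip(np.searchsorted(arclen, sample_t, side="right"), 1,
                      len(arclen) - 1)
        w = (sample_t - arclen[idx - 1]) / np.maximum(seglen[idx - 1], 1e-12)
        samples_all = pts[idx - 1] + w[:, None] * d[idx - 1]
    segs = []
    for s, e in zip(cuts[:-1], cuts[1:]):
        if e <= s:
            continue
        piece = pts[s:e + 1].copy()
        samples = None
        if samples_all is not None:
            m = (sample_t >= arclen[s]) & (sample_t <= arclen[e])
            samples = samples_all[m] if m.any() else piece[[0, -1]]
        segs.append(TubeSegment(points=piece, radius=radius,
                                loop_id=loop_id, samples=samples))
    return segs


def _normalized_to_physical(pts: np.ndarray, semi_axes_xyz: np.ndarray,
                            center_zyx: np.ndarray) -> np.ndarray:
    """Map normalised (x, y, z) unit-ball coordinates to physical (z, y, x) µm."""
    phys = np.empty_like(pts)
    phys[:, 0] = pts[:, 2] * semi_axes_xyz[2]
    phys[:, 1] = pts[:, 1] * semi_axes_xyz[1]
    phys[:, 2] = pts[:, 0] * semi_axes_xyz[0]
    return phys + center_zyx


# ---------------------------------------------------------------------------
# rasterization


@lru_cache(maxsize=64)
def _ball_offsets(radius_q: float, dz: float, dy: float, dx: float) -> np.ndarray:
    """Integer voxel offsets whose centres lie within ``radius_q`` µm of origin."""
    nz = max(int(radius_q / dz), 0)
    ny = max(int(radius_q / dy), 0)
    nx = max(int(radius_q / dx), 0)
    oz, oy, ox = np.meshgrid(
        np.arange(-nz, nz + 1), np.arange(-ny, ny + 1), np.arange(-nx, nx + 1),
        indexing="ij",
    )
    d2 = (oz * dz) ** 2 + (oy * dy) ** 2 + (ox * dx) ** 2
    sel = d2 <= radius_q**2
    offs = np.stack([oz[sel], oy[sel], ox[sel]], axis=1).astype(np.int64)
    if len(offs) == 0:
        offs = np.zeros((1, 3), dtype=np.int64)
    return offs


def _resample_polyline(pts: np.ndarray, step: float) -> np.ndarray:
    d = np.diff(pts, axis=0)
    seglen = np.sqrt((d * d).sum(axis=1))
    arclen = np.concatenate(([0.0], np.cumsum(seglen)))
    total = arclen[-1]
    if total <= step:
        return pts[[0, -1]] if len(pts) > 1 else pts
    n = max(int(np.ceil(total / step)) + 1, 2)
    t = np.linspace(0.0, total, n)
    idx = np.clip(np.searchsorted(arclen, t, side="right"), 1, len(arclen) - 1)
    w = (t - arclen[idx - 1]) / np.maximum(seglen[idx - 1], 1e-12)
    return pts[idx - 1] + w[:, None] * d[idx - 1]


def _stamp_points(
    centers_um: np.ndarray,
    radius: float,
    shape: tuple[int, int, int],
    geometry: VoxelGeometry,
    mask: np.ndarray,
) -> None:
    offs = _ball_offsets(round(radius, 1), geometry.dz, geometry.dy, geometry.dx)
    centers = np.rint(centers_um / geometry.spacing_zyx).astype(np.int64)
    cand = (centers[:, None, :] + offs[None, :, :]).reshape(-1, 3)
    ok = np.all((cand >= 0) & (cand < np.array(shape)), axis=1)
    cand = cand[ok]
    mask[cand[:, 0], cand[:, 1], cand[:, 2]] = True


def rasterize_network(
    network: TubeNetwork,
    shape: tuple[int, int, int],
    geometry: VoxelGeometry,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Stamp tube segments into a boolean voxel mask.

    A voxel is set when its centre lies within a segment's radius (rounded to
    0.1 µm) of the finely resampled centerline. Stamping uses a metric ball
    of integer offsets, so the anisotropic z-step is honoured. Segments are
    grouped by radius and stamped in one vectorised pass per group.
    """
    mask = out if out is not None else np.zeros(shape, dtype=bool)
    sp = geometry.spacing_zyx
    step = 0.5 * float(sp.min())
    by_radius: dict[float, list[np.ndarray]] = {}
    for seg in network.segments:
        samples = (seg.samples if seg.samples is not None
                   else _resample_polyline(seg.points, step))
        by_radius.setdefault(round(seg.radius, 1), []).append(samples)
    for radius, pts_list in by_radius.items():
        _stamp_points(np.vstack(pts_list), radius, shape, geometry, mask)
    return mask


# ---------------------------------------------------------------------------
# truth manifest


@dataclass
class PhantomTruth:
    """Ground-truth manifest accompanying a generated phantom.

    ``true_capillary_volume`` is always the voxel count of
    ``true_vessel_mask`` times the voxel volume, exactly.
    """

    kind: str
    seed: int
    true_vessel_mask: np.ndarray
    true_capillary_volume: float
    true_density: float
    dropout_applied: float
    true_tuft_ellipsoid: Ellipsoid | None = None
    glomerulus_rois: list[np.ndarray] = field(default_factory=list)
    plexus_volume: float | None = None
    glomerulus_volumes: list[float] = field(default_factory=list)
    requested_capillary_volume: float | None = None
    params: PhantomParams | None = None

    def to_manifest(self) -> dict:
        """JSON-serialisable summary (masks reported as voxel counts)."""
        return {
            "kind": self.kind,
            "seed": self.seed,
            "true_capillary_volume_um3": self.true_capillary_volume,
            "true_density": self.true_density,
            "dropout_applied": self.dropout_applied,
            "true_vessel_voxels": int(self.true_vessel_mask.sum()),
            "tuft_semi_axes_um": (
                list(self.true_tuft_ellipsoid.semi_axes)
                if self.true_tuft_ellipsoid else None
            ),
            "tuft_volume_um3": (
                self.true_tuft_ellipsoid.volume if self.true_tuft_ellipsoid else None
            ),
            "n_glomerulus_rois": len(self.glomerulus_rois),
            "plexus_volume_um3": self.plexus_volume,
            "glomerulus_volumes_um3": list(self.glomerulus_volumes),
            "requested_capillary_volume_um3": self.requested_capillary_volume,
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.params).items()} if self.params else None,
        }


# ---------------------------------------------------------------------------
# imaging model


def render_imaging(
    true_mask: np.ndarray,
    params: PhantomParams,
    rng: np.random.Generator | int | None = None,
    autofluorescence_mask: np.ndarray | None = None,
) -> ImageStack:
    """Render a binary lumen mask into a two-channel intensity stack.

    Green channel: mask × multiplicative speckle (smoothed at
    ``speckle_grain`` µm, modelling the granular microsphere filling)
    convolved with an anisotropic Gaussian PSF, plus Gaussian sensor noise.
    Red channel: uniform autofluorescence over the parenchyma mask (default:
    everything outside the vessels), same PSF and noise. Intensities are
    clipped to the stack's dynamic range.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(params.seed if rng is None else rng)
    geometry = params.geometry
    shape = true_mask.shape
    maxval = float(params.max_intensity)
    peak = min(params.peak_intensity, maxval)

    green = true_mask.astype(np.float32) * peak
    if params.speckle_amplitude > 0 and params.speckle_grain > 0:
        field_ = rng.standard_normal(shape).astype(np.float32)
        sig = params.speckle_grain / geometry.spacing_zyx
        field_ = ndimage.gaussian_filter(field_, sigma=sig)
        sd = field_.std()
        if sd > 0:
            field_ /= sd
        green *= np.clip(1.0 + params.speckle_amplitude * field_, 0.0, None)
    elif params.speckle_amplitude > 0:
        green *= np.clip(
            1.0 + params.speckle_amplitude
            * rng.standard_normal(shape).astype(np.float32), 0.0, None,
        )

    psf_sigma = np.array([params.psf_sigma_z, params.psf_sigma_xy,
                          params.psf_sigma_xy]) / geometry.spacing_zyx
    if np.any(psf_sigma > 0):
        green = ndimage.gaussian_filter(green, sigma=psf_sigma)
    if params.noise_sd > 0:
        green = green + rng.normal(0.0, params.noise_sd, shape).astype(np.float32)

    dtype = params.dtype
    channels = {"green": np.clip(np.rint(green), 0, maxval).astype(dtype)}
    if params.render_red:
        if autofluorescence_mask is None:
            autofluorescence_mask = ~true_mask
        red = autofluorescence_mask.astype(np.float32) * params.autofluorescence_level
        if np.any(psf_sigma > 0):
            red = ndimage.gaussian_filter(red, sigma=psf_sigma)
        if params.noise_sd > 0:
            red = red + rng.normal(0.0, params.noise_sd, shape).astype(np.float32)
        channels["red"] = np.clip(np.rint(red), 0, maxval).astype(dtype)
    return ImageStack(
        channels=channels,
        geometry=geometry,
        provenance={"generator": "fmaquant.phantom", "kind": params.kind,
                    "seed": params.seed},
    )


# ---------------------------------------------------------------------------
# glomerular phantom


def _build_glomerular_network(
    params: PhantomParams,
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    loop_envelope: Ellipsoid,
    target_volume: float | None,
) -> tuple[TubeNetwork, np.ndarray]:
    """Add capillary loops until the rasterised lumen volume reaches target."""
    geometry = params.geometry
    # params.tuft_semi_axes are already scaled to the loop envelope here,
    # assigned to the (x, y, z) axes in the order given
    semi_xyz = np.array(params.tuft_semi_axes, dtype=float)
    center = np.asarray(loop_envelope.center)
    voxvol = geometry.voxel_volume

    segments: list[TubeSegment] = []
    mask = np.zeros(shape, dtype=bool)
    max_loops = params.n_loops if target_volume is None else max(
        6 * params.n_loops, 160
    )
    count = 0
    for loop_id in range(max_loops):
        if target_volume is None and loop_id >= params.n_loops:
            break
        if target_volume is not None and count * voxvol >= 0.98 * target_volume:
            break
        radius = max(0.8, rng.normal(params.tube_radius_mean, params.tube_radius_sd))
        rho_max = 1.0 - radius / semi_xyz.min()
        if rho_max <= 0.3:
            raise PhantomParameterError(
                "tube radius too large for the tuft semi-axes: loops cannot "
                "stay inside the envelope"
            )
        pts = _loop_path(rng, rho_max)
        phys = _normalized_to_physical(pts, semi_xyz, center)
        loop_segs = _split_loop(phys, radius, loop_id, params.segments_per_loop,
                                sample_step=0.5 * float(geometry.spacing_zyx.min()))
        segments.extend(loop_segs)
        rasterize_network(TubeNetwork(tuple(loop_segs)), shape, geometry, out=mask)
        count = int(np.count_nonzero(mask))
    if target_volume is not None and count * voxvol < 0.90 * target_volume:
        raise GenerationError(
            f"requested capillary density {params.capillary_density_target} "
            f"unreachable: reached {count * voxvol:.3g} of {target_volume:.3g} µm³ "
            f"after {max_loops} loops"
        )
    segments = _connect_components(segments, mask, shape, geometry,
                                   params.tube_radius_mean)
    return TubeNetwork(tuple(segments)), mask


def _connect_components(
    segments: list[TubeSegment],
    mask: np.ndarray,
    shape: tuple[int, int, int],
    geometry: VoxelGeometry,
    radius: float,
    max_connectors: int = 60,
) -> list[TubeSegment]:
    """Guarantee a connected loop set by adding straight connector tubes
    (afferent/efferent-like bridges) between disconnected pieces."""
    structure = ndimage.generate_binary_structure(3, 3)  # 26-connectivity
    sp = geometry.spacing_zyx
    segments = list(segments)
    for _ in range(max_connectors):
        labels, n = ndimage.label(mask, structure=structure)
        if n <= 1:
            break
        sizes = np.bincount(labels.ravel())[1:]
        main = int(np.argmax(sizes)) + 1
        other = int(np.argmax(np.where(np.arange(1, n + 1) != main, sizes, -1))) + 1
        pa = _sample_component(labels, main) * sp
        pb = _sample_component(labels, other) * sp
        d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
        i, j = np.unravel_index(np.argmin(d2), d2.shape)
        line = np.linspace(pb[j], pa[i], 24)
        seg = TubeSegment(points=line, radius=radius, loop_id=-1,
                          samples=_resample_polyline(
                              line, 0.5 * float(sp.min())))
        segments.append(seg)
        rasterize_network(TubeNetwork((seg,)), shape, geometry, out=mask)
    return segments


def _sample_component(labels: np.ndarray, label: int,
                      max_points: int = 2000) -> np.ndarray:
    pts = np.argwhere(labels == label)
    if len(pts) > max_points:
        idx = np.linspace(0, len(pts) - 1, max_points).astype(int)
        pts = pts[idx]
    return pts.astype(float)


def generate_glomerular_phantom(
    params: PhantomParams,
) -> tuple[ImageStack, PhantomTruth]:
    """Generate a single-glomerulus FMA phantom stack with its truth manifest.

    The truth ellipsoid is the tuft envelope after enlargement; with
    ``loops_follow_enlargement=False`` the capillary geometry stays confined
    to the un-enlarged tuft (fixed capillary geometry inside a larger
    envelope), which isolates the effect of glomerular enlargement on density.
    """
    if params.kind != "glomerulus":
        raise PhantomParameterError("params.kind must be 'glomerulus'")
    shape = params.resolved_shape()
    geometry = params.geometry
    f = params.enlargement_factor
    sx, sy, sz = (s * f for s in params.tuft_semi_axes)
    extent = np.array([shape[0] * geometry.dz, shape[1] * geometry.dy,
                       shape[2] * geometry.dx])
    needed = np.array([2 * sz, 2 * sy, 2 * sx]) + 4 * params.tube_radius_mean
    if np.any(needed > extent):
        raise PhantomParameterError(
            f"tuft (semi-axes {(sx, sy, sz)} µm after enlargement) does not fit "
            f"the stack extent {tuple(extent)} µm with a 2-tube-radius margin"
        )
    center = extent / 2.0
    a_, b_, c_ = sorted([sx, sy, sz], reverse=True)
    truth_ellipsoid = Ellipsoid(a_, b_, c_, center=tuple(center),
                                axes=_axes_for_xyz_semi(sx, sy, sz))

    loop_f = f if params.loops_follow_enlargement else 1.0
    la, lb, lc = sorted([s * loop_f for s in params.tuft_semi_axes], reverse=True)
    loop_envelope = Ellipsoid(la, lb, lc, center=tuple(center),
                              axes=truth_ellipsoid.axes)

    target_volume = None
    if params.capillary_density_target is not None:
        target_volume = params.capillary_density_target * loop_envelope.volume

    ss = np.random.SeedSequence(params.seed)
    rng_loops, rng_drop, rng_render = (np.random.default_rng(c)
                                       for c in ss.spawn(3))

    # loop geometry is built in the (possibly un-enlarged) loop envelope
    loop_semi_params = replace(
        params, tuft_semi_axes=tuple(s * loop_f for s in params.tuft_semi_axes)
    )
    network, build_mask = _build_glomerular_network(
        loop_semi_params, rng_loops, shape, loop_envelope, target_volume
    )
    if params.dropout_fraction == 0.0:
        retained, realized_drop = network, 0.0
        true_mask = build_mask
    elif params.dropout_fraction == 1.0:
        retained, realized_drop = TubeNetwork(()), 1.0
        true_mask = np.zeros(shape, dtype=bool)
    else:
        retained, realized_drop, true_mask = _dropout_with_mask(
            network, params.dropout_fraction,
            rng_drop.permutation(len(network)), shape, geometry)
    n_voxels = int(np.count_nonzero(true_mask))
    true_volume = n_voxels * geometry.voxel_volume
    true_density = true_volume / truth_ellipsoid.volume
    if params.dropout_fraction < 1.0 and not 0.0 < true_density <= 1.0:
        raise GenerationError(
            f"generated capillary density {true_density:.3g} outside (0, 1]"
        )

    tuft_roi = truth_ellipsoid.rasterize(shape, geometry)
    stack = render_imaging(true_mask, params, rng_render,
                           autofluorescence_mask=~tuft_roi)
    stack.provenance["params"] = {k: (list(v) if isinstance(v, tuple) else v)
                                  for k, v in asdict(params).items()}
    truth = PhantomTruth(
        kind="glomerulus",
        seed=params.seed,
        true_vessel_mask=true_mask,
        true_capillary_volume=true_volume,
        true_density=true_density,
        dropout_applied=realized_drop,
        true_tuft_ellipsoid=truth_ellipsoid,
        glomerulus_rois=[tuft_roi],
        requested_capillary_volume=target_volume,
        params=params,
    )
    return stack, truth


def _axes_for_xyz_semi(sx: float, sy: float, sz: float) -> np.ndarray:
    """Principal directions (columns, zyx coords) for an axis-aligned tuft."""
    # unit vectors for x, y, z in (z, y, x) coordinates
    ux, uy, uz = np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 0.0]), \
        np.array([1.0, 0.0, 0.0])
    pairs = sorted(zip((sx, sy, sz), (ux, uy, uz)), key=lambda p: -p[0])
    return np.stack([v for _, v in pairs], axis=1)


# ---------------------------------------------------------------------------
# cortex phantom


def _random_plexus_tube(
    rng: np.random.Generator,
    extent: np.ndarray,
    existing: list[TubeSegment],
    radius: float,
    margin: float,
) -> np.ndarray:
    """One wandering tube path across the field; half start from an existing
    tube to create junctions (the plexus is anastomotic)."""
    lo, hi = margin, extent - margin
    if existing and rng.uniform() < 0.5:
        seg = existing[rng.integers(len(existing))]
        p0 = seg.points[rng.integers(len(seg.points))]
    else:
        p0 = rng.uniform(lo, hi)
    p1 = rng.uniform(lo, hi)
    mids = np.linspace(p0, p1, 4)[1:-1]
    mids += rng.normal(0.0, 0.15 * np.linalg.norm(p1 - p0), mids.shape)
    ctrl = np.vstack([p0, mids, p1])
    ctrl = np.clip(ctrl, lo, hi)
    tck, _ = interpolate.splprep(ctrl.T, k=3, s=0)
    u = np.linspace(0, 1, 60)
    pts = np.array(interpolate.splev(u, tck)).T
    return np.clip(pts, lo, hi)


def generate_cortex_phantom(params: PhantomParams) -> tuple[ImageStack, PhantomTruth]:
    """Generate a cortical-field phantom: anastomotic peritubular plexus at a
    target lumen volume fraction, with ``n_glomeruli`` embedded tufts whose
    ROI masks are recorded in the truth manifest."""
    if params.kind != "cortex":
        raise PhantomParameterError("params.kind must be 'cortex'")
    shape = params.resolved_shape()
    geometry = params.geometry
    extent = np.array(shape) * geometry.spacing_zyx
    voxvol = geometry.voxel_volume

    ss = np.random.SeedSequence(params.seed)
    rng_place, rng_glom, rng_plexus, rng_drop, rng_render = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )

    # --- embedded glomerular tufts -------------------------------------
    scale = params.embedded_glomerulus_scale * params.enlargement_factor
    semi = np.array(sorted(params.tuft_semi_axes, reverse=True)) * scale
    rois: list[np.ndarray] = []
    centers: list[np.ndarray] = []
    glom_segments: list[TubeSegment] = []
    if params.n_glomeruli > 0:
        pad = semi.max() + 2 * params.tube_radius_mean + 2.0
        if np.any(2 * pad >= extent):
            raise PhantomParameterError(
                "embedded glomeruli do not fit the cortex field"
            )
        # two translates of the same ellipsoid are disjoint iff the centre
        # offset, normalised by twice the semi-axes (plus clearance), exceeds 1.
        # an unlucky early placement can make later ones impossible, so on
        # failure the whole placement is regenerated (bounded rounds).
        sep_zyx = 2.0 * semi + 4.0  # Ellipsoid(*semi) maps semi axes to (z, y, x)
        for _round in range(200):
            centers = []
            for _ in range(params.n_glomeruli):
                for _attempt in range(60):
                    c = rng_place.uniform(pad, extent - pad)
                    if all((((c - c0) / sep_zyx) ** 2).sum() >= 1.0
                           for c0 in centers):
                        centers.append(c)
                        break
            if len(centers) == params.n_glomeruli:
                break
        else:
            raise GenerationError(
                f"could not place {params.n_glomeruli} non-overlapping "
                f"glomeruli in the field after bounded retries"
            )
        glom_params = replace(
            params, kind="glomerulus",
            tuft_semi_axes=tuple(s * scale for s in params.tuft_semi_axes),
        )
        for c in centers:
            ell = Ellipsoid(*semi, center=tuple(c))
            rois.append(ell.rasterize(shape, geometry))
            target = (params.capillary_density_target or 0.30) * ell.volume
            net, _ = _build_glomerular_network(glom_params, rng_glom, shape,
                                               ell, target)
            glom_segments.extend(net.segments)
    roi_union = np.zeros(shape, dtype=bool)
    for r in rois:
        roi_union |= r
    field_outside = ~roi_union
    n_field = int(np.count_nonzero(field_outside))

    # --- anastomotic plexus, grown to the target lumen fraction ---------
    plexus_segments: list[TubeSegment] = []
    plexus_mask = np.zeros(shape, dtype=bool)
    max_tubes = 800
    margin = params.tube_radius_mean + 1.0
    frac = 0.0
    for tube_id in range(max_tubes):
        if frac >= params.plexus_density - 0.001:
            break
        radius = max(0.8, rng_plexus.normal(params.tube_radius_mean,
                                            params.tube_radius_sd))
        pts = _random_plexus_tube(rng_plexus, extent, plexus_segments, radius,
                                  margin)
        segs = _split_loop(pts, radius, 10_000 + tube_id, 4,
                           sample_step=0.5 * float(geometry.spacing_zyx.min()))
        plexus_segments.extend(segs)
        rasterize_network(TubeNetwork(tuple(segs)), shape, geometry,
                          out=plexus_mask)
        frac = np.count_nonzero(plexus_mask & field_outside) / n_field
    if frac < params.plexus_density - 0.004:
        raise GenerationError(
            f"plexus density {params.plexus_density} unreachable after "
            f"{max_tubes} tubes (reached {frac:.4f})"
        )

    # --- segmental dropout over the whole network -----------------------
    full = TubeNetwork(tuple(plexus_segments + glom_segments))
    if params.dropout_fraction == 0.0:
        retained, realized_drop = full, 0.0
        union = rasterize_network(full, shape, geometry)
    elif params.dropout_fraction == 1.0:
        retained, realized_drop = TubeNetwork(()), 1.0
        union = np.zeros(shape, dtype=bool)
    else:
        retained, realized_drop, union = _dropout_with_mask(
            full, params.dropout_fraction,
            rng_drop.permutation(len(full)), shape, geometry)
    # glomerular loops are confined to the ROIs, so the field side of the
    # union is pure plexus; inside the ROIs only glomerular tubes count
    # (plexus paths crossing an ROI are carved away)
    plexus_final = union & field_outside
    retained_glom = TubeNetwork(tuple(s for s in retained.segments
                                      if s.loop_id < 10_000))
    glom_final = np.zeros(shape, dtype=bool)
    if len(retained_glom):
        rasterize_network(retained_glom, shape, geometry, out=glom_final)
        glom_final &= roi_union
    true_mask = plexus_final | glom_final

    plexus_volume = float(np.count_nonzero(plexus_final) * voxvol)
    glom_volumes = [float(np.count_nonzero(true_mask & r) * voxvol) for r in rois]
    true_volume = float(np.count_nonzero(true_mask) * voxvol)
    true_density = np.count_nonzero(plexus_final) / n_field

    stack = render_imaging(true_mask, params, rng_render,
                           autofluorescence_mask=~true_mask)
    stack.provenance["params"] = {k: (list(v) if isinstance(v, tuple) else v)
                                  for k, v in asdict(params).items()}
    truth = PhantomTruth(
        kind="cortex",
        seed=params.seed,
        true_vessel_mask=true_mask,
        true_capillary_volume=true_volume,
        true_density=float(true_density),
        dropout_applied=realized_drop,
        glomerulus_rois=rois,
        plexus_volume=plexus_volume,
        glomerulus_volumes=glom_volumes,
        requested_capillary_volume=params.plexus_density * n_field * voxvol,
        params=params,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# 2D immunostain sections


@dataclass
class IhcSection:
    """Synthetic 2D immunostained section with exact ground truth."""

    image: np.ndarray        # (H, W, 3) uint8 RGB
    stain_mask: np.ndarray   # (H, W) bool, ground-truth positive pixels
    area_fraction: float     # realised stained-pixel fraction
    seed: int


def generate_ihc_section(
    area_fraction_target: float,
    field_shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    noise_sd: float = 0.0,
) -> IhcSection:
    """Scatter DAB-like stained blobs on a counterstain background until the
    stained-pixel fraction is within 0.5 percentage points of target.

    The image is composed in Haematoxylin–Eosin–DAB absorbance space and
    converted to RGB, so the standard colour-deconvolution readout applies.
    Returns the image together with the exact realised fraction and mask.
    """
    if not 0.0 <= area_fraction_target <= 1.0:
        raise PhantomParameterError("area_fraction_target must be in [0, 1]")
    if area_fraction_target > 0.95:
        raise GenerationError(
            f"stained-area target {area_fraction_target} unreachable with "
            "blob placement (max supported 0.95)"
        )
    from skimage.color import hed2rgb  # deferred: keeps import cost local

    rng = np.random.default_rng(seed)
    h, w = field_shape
    npix = h * w
    stain = np.zeros((h, w), dtype=bool)
    target_pix = area_fraction_target * npix
    yy, xx = np.mgrid[0:h, 0:w]
    attempts = 0
    while stain.sum() < target_pix - 0.005 * npix and attempts < 20_000:
        attempts += 1
        remaining = target_pix - stain.sum()
        r = rng.uniform(3.0, 9.0)
        if np.pi * r * r > remaining + 0.005 * npix:
            r = max(1.0, np.sqrt(remaining / np.pi))
        cy, cx = rng.uniform(r, h - r), rng.uniform(r, w - r)
        ry, rx = r * rng.uniform(0.7, 1.3), r
        blob = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        stain |= blob
    realized = stain.sum() / npix
    if abs(realized - area_fraction_target) > 0.005:
        raise GenerationError(
            f"stained-area target {area_fraction_target} not reached "
            f"(realised {realized:.4f}) after bounded attempts"
        )
    hed = np.zeros((h, w, 3), dtype=float)
    hed[..., 0] = 0.25                       # haematoxylin counterstain
    hed[..., 2] = np.where(stain, 0.40, 0.0)  # DAB
    if noise_sd > 0:
        # stain-density heterogeneity: noise in absorbance space
        hed = np.clip(hed + rng.normal(0.0, noise_sd, hed.shape), 0.0, None)
    rgb = np.clip(hed2rgb(hed), 0.0, 1.0)
    image = np.rint(rgb * 255).astype(np.uint8)
    return IhcSection(image=image, stain_mask=stain,
                      area_fraction=float(realized), seed=seed)
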