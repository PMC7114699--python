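"""Synthetic pre/post-expansion scene simulator with exact ground truth.

The simulated specimen mirrors the imaging geometry of the
photobleached-cube assay: an ellipsoidal nucleus of roughly uniform
fluorophore density into which a darker cubical volume has been bleached.
Lateral cube edges are sharp; the axial edge profile is tunable
(``axial_edge_sigma``) to emulate the difference between two-photon
bleaching (excitation confined to the focal volume, sharp axial edges)
and one-photon bleaching (an axially extended bleach cone, soft edges).

Deformations are applied analytically to the scene *geometry* in
continuous micrometer coordinates before rendering — never by warping
rendered pixels — so per-line ground-truth expansion factors are
available in closed form and carry no interpolation bias.  Rendering
then samples the deformed scene at the requested voxel grid, applies an
anisotropic Gaussian PSF (worse axially, identical in image-space
micrometers pre and post), Poisson shot noise plus Gaussian read noise,
and quantizes to the detector bit depth.  Post-expansion fluorophores
are diluted by the volumetric expansion, so the rendered post stack is
dimmer with a compressed histogram — exercising the intensity rescale
step exactly the way real data does.

Same seed and spec give bit-identical stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import ndimage
from scipy.special import erf

from .io_stacks import ImageStack

__all__ = [
    "SceneSpec",
    "DeformSpec",
    "render_pre",
    "render_post",
    "ground_truth_ef",
    "simulate_pair",
    "shear_rate_for_total_change",
    "VOXELS_PRE",
    "VOXELS_POST",
]

#: default voxel sizes (dz, dy, dx) in micrometers: Nyquist-like sampling
#: at a high-NA 63x acquisition pre-expansion and a 20x post-expansion
VOXELS_PRE: tuple[float, float, float] = (0.3, 0.1, 0.1)
VOXELS_POST: tuple[float, float, float] = (1.5, 0.5, 0.5)


@dataclass(frozen=True)
class SceneSpec:
    """Geometry, optics and noise of one simulated specimen.

    All lengths in micrometers, scene origin at the nucleus center.
    Defaults describe a typical adherent-cell nucleus with a bleached
    cube of 8 um lateral side and 6 um axial height (bleached fiducials
    typically span 5-10 um axially), bleached to 85% depth, imaged with
    a confocal PSF that is ~4x worse axially than laterally at a target
    shot-noise SNR of 10.
    """

    nucleus_semiaxes: tuple[float, float, float] = (11.0, 10.0, 7.5)  # (x, y, z)
    nucleus_intensity: float = 20000.0
    cube_size: tuple[float, float, float] = (8.0, 8.0, 6.0)  # (sx, sy, sz)
    cube_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    bleach_depth: float = 0.85
    texture_amp: float = 0.10  # fractional chromatin-texture modulation
    texture_scale: float = 1.0  # correlation length of the texture, um
    rough_amp: float = 0.015  # sd of lateral bleach-boundary waviness, um
    rough_amp_axial: float = 0.30  # sd of axial-face waviness, um (focus jitter)
    rough_scale: float = 1.0  # correlation length of the waviness, um
    axial_edge_sigma: float = 1.0  # 2PE-like focal confinement; >=3 emulates 1PE
    psf_sigma: tuple[float, float] = (0.12, 0.45)  # (lateral, axial)
    snr: float = 10.0  # shot-noise SNR at nucleus intensity; 0 disables noise
    read_noise_frac: float = 0.01  # Gaussian read sigma / nucleus intensity
    bit_depth: int = 16
    seed: int = 0
    texture_seed: int | None = None  # specimen texture; defaults to `seed`

    def __post_init__(self):
        if not 0 <= self.bleach_depth <= 1:
            raise ValueError(f"bleach_depth must be in [0, 1], got {self.bleach_depth}")
        a, b, c = self.nucleus_semiaxes
        cx, cy, cz = self.cube_center
        sx, sy, sz = self.cube_size
        # every cube corner must lie inside the ellipsoid
        for ex in (-1, 1):
            for ey in (-1, 1):
                for ez in (-1, 1):
                    px, py, pz = cx + ex * sx / 2, cy + ey * sy / 2, cz + ez * sz / 2
                    if (px / a) ** 2 + (py / b) ** 2 + (pz / c) ** 2 > 1.0 + 1e-9:
                        raise ValueError("cube outside nucleus: corner beyond ellipsoid")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        for k in ("nucleus_semiaxes", "cube_size", "cube_center", "psf_sigma"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        for k in ("nucleus_semiaxes", "cube_size", "cube_center", "psf_sigma"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SceneSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class DeformSpec:
    """Ground-truth expansion transform applied to scene geometry.

    Modes
    -----
    ``isotropic``
        Uniform scale (a scalar) in all directions.
    ``affine``
        Independent per-axis scales ``(sx, sy, sz)``.
    ``shear``
        Lateral x-scale varies linearly with post-expansion height y:
        width factor ``sx * (1 + shear_rate * y_post)``, so the square's
        width changes by ``shear_rate`` (fraction) per micrometer of
        height — a local distortion that leaves medians almost unchanged.
    ``piecewise_z``
        The part of the cube with pre-expansion x below
        ``cube_x0 + z_split * sx`` expands axially by ``z_scales[0]``,
        the rest by ``z_scales[1]`` (lateral scale stays uniform) — a
        spatially anisotropic expansion producing a bimodal z-EF
        distribution.  The gel deforms continuously, so the two regimes
        blend over ``z_twidth`` micrometers (pre-expansion) around the
        split plane rather than jumping discontinuously.
    """

    mode: str = "isotropic"
    scale: float | tuple[float, float, float] = 4.9
    shear_rate: float = 0.0  # fractional width change per um of post height
    z_scales: tuple[float, float] = (5.0, 2.0)
    z_split: float = 0.5
    z_twidth: float = 0.5  # transition width of the axial-scale step, um

    def __post_init__(self):
        if self.mode not in ("isotropic", "affine", "shear", "piecewise_z"):
            raise ValueError(f"unknown deformation mode {self.mode!r}")
        if np.any(np.asarray(self.scales) <= 0):
            raise ValueError("all scales must be positive")
        if self.mode == "piecewise_z":
            if not 0 < self.z_split < 1:
                raise ValueError(f"z_split must be in (0, 1), got {self.z_split}")
            if min(self.z_scales) <= 0:
                raise ValueError("z_scales must be positive")

    @property
    def scales(self) -> tuple[float, float, float]:
        """Per-axis (sx, sy, sz) scale factors (the z ones are nominal
        for ``piecewise_z``, where z varies spatially)."""
        if np.isscalar(self.scale):
            s = float(self.scale)
            base = (s, s, s)
        else:
            base = tuple(float(v) for v in self.scale)
        if self.mode == "piecewise_z":
            return (base[0], base[1], max(self.z_scales))
        return base

    @property
    def volume_factor(self) -> float:
        sx, sy, sz = self.scales
        if self.mode == "piecewise_z":
            zl, zr = self.z_scales
            sz = self.z_split * zl + (1 - self.z_split) * zr
        return sx * sy * sz

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "scale": list(self.scale) if not np.isscalar(self.scale) else self.scale,
            "shear_rate": self.shear_rate,
            "z_scales": list(self.z_scales),
            "z_split": self.z_split,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DeformSpec":
        d = dict(d)
        if "scale" in d and isinstance(d["scale"], (list, tuple)):
            d["scale"] = tuple(d["scale"])
        if "z_scales" in d:
            d["z_scales"] = tuple(d["z_scales"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "DeformSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


IDENTITY = DeformSpec(mode="isotropic", scale=1.0)


def shear_rate_for_total_change(total_change: float, scene: SceneSpec, lateral_scale: float) -> float:
    """Shear rate producing ``total_change`` fractional width change
    across the full post-expansion height of the bleached square."""
    return total_change / (lateral_scale * scene.cube_size[1])


# ---------------------------------------------------------------------------
# geometry


def _texture_field(scene: SceneSpec):
    """Smooth multiplicative chromatin texture, a function of
    pre-expansion coordinates so it deforms with the specimen.

    A lattice of white noise at half the correlation length, Gaussian
    smoothed and normalised to unit variance, linearly interpolated at
    query points.  The nucleus is only *roughly* uniform: this texture
    is what makes individual pixel lines differ, as they do in real
    nuclei.  Seeded independently of the shot noise by scene.seed so pre
    and post renders of the same scene see the same specimen.
    """
    if scene.texture_amp <= 0:
        return None
    spacing = scene.texture_scale / 2.0
    half = [s + 2 * scene.texture_scale for s in scene.nucleus_semiaxes]  # (x, y, z)
    ns = [int(np.ceil(2 * h / spacing)) + 1 for h in half]
    tseed = scene.seed if scene.texture_seed is None else scene.texture_seed
    rng = np.random.default_rng(np.random.SeedSequence([int(tseed) % 2**31, 0x7E57]))
    lattice = rng.standard_normal(ns[::-1])  # (z, y, x) order
    sm = ndimage.gaussian_filter(lattice, sigma=2.0, mode="reflect")
    sm /= sm.std() or 1.0
    sm = sm.astype(np.float32)

    def sample(x, y, z):
        shape = np.broadcast_shapes(np.shape(x), np.shape(y), np.shape(z))
        coords = [
            np.broadcast_to((z + half[2]) / spacing, shape),
            np.broadcast_to((y + half[1]) / spacing, shape),
            np.broadcast_to((x + half[0]) / spacing, shape),
        ]
        return ndimage.map_coordinates(sm, coords, order=1, mode="nearest")

    return sample


def _face_roughness(scene: SceneSpec):
    """Six smooth random displacement fields (um), one per cube face.

    The bleach boundary of a real square is sharp but not perfectly
    straight: scanning and dye diffusion make each face wander by a
    fraction of a micrometer, spatially correlated along the face, and
    the axial faces wander more than the lateral ones (the axial
    placement of the bleach cone is limited by the focal extent, not by
    the galvo raster).  Each field is detrended — the raster keeps the
    square straight at large scales, so the waviness carries no net tilt
    that would mimic a shear.  The fields are functions of
    pre-expansion coordinates, so the waviness expands with the gel and
    leaves the per-line ground-truth EF exact.  Returns ``None`` when
    both amplitudes are 0.
    """
    if scene.rough_amp <= 0 and scene.rough_amp_axial <= 0:
        return None
    spacing = scene.rough_scale / 2.0
    half = max(scene.nucleus_semiaxes) + 2 * scene.rough_scale
    n = int(np.ceil(2 * half / spacing)) + 1
    tseed = scene.seed if scene.texture_seed is None else scene.texture_seed
    rng = np.random.default_rng(np.random.SeedSequence([int(tseed) % 2**31, 0xFACE]))
    ii, jj = np.mgrid[0:n, 0:n]
    design = np.column_stack([np.ones(n * n), ii.ravel() - ii.mean(), jj.ravel() - jj.mean()])

    def make_field(amp: float):
        lattice = ndimage.gaussian_filter(rng.standard_normal((n, n)), 2.0, mode="reflect")
        coef, *_ = np.linalg.lstsq(design, lattice.ravel(), rcond=None)
        lattice = lattice - (design @ coef).reshape(n, n)
        lattice *= amp / (lattice.std() or 1.0)

        def sample(u, v):
            shape = np.broadcast_shapes(np.shape(u), np.shape(v))
            coords = [
                np.broadcast_to((u + half) / spacing, shape),
                np.broadcast_to((v + half) / spacing, shape),
            ]
            return ndimage.map_coordinates(lattice, coords, order=1, mode="nearest")

        return sample

    amps = {
        "x-": scene.rough_amp,
        "x+": scene.rough_amp,
        "y-": scene.rough_amp,
        "y+": scene.rough_amp,
        "z-": scene.rough_amp_axial,
        "z+": scene.rough_amp_axial,
    }
    return {face: make_field(amp) for face, amp in amps.items()}


def _inverse_map(deform: DeformSpec, scene: SceneSpec, X, Y, Z):
    """Map post-expansion coordinates back to pre-expansion scene
    coordinates (all micrometers, broadcastable arrays)."""
    sx, sy, sz = deform.scales
    if deform.mode in ("isotropic", "affine"):
        return X / sx, Y / sy, Z / sz
    if deform.mode == "shear":
        y = Y / sy
        x = X / (sx * (1.0 + deform.shear_rate * Y))
        return x, y, Z / sz
    # piecewise_z: axial scale is a smooth step in pre-expansion x
    x = X / sx
    y = Y / sy
    z = Z / _axial_scale_profile(deform, scene, x)
    return x, y, z


def _axial_scale_profile(deform: DeformSpec, scene: SceneSpec, x):
    """Axial scale factor as a function of pre-expansion x for the
    piecewise_z mode: a logistic blend from ``z_scales[0]`` (left of the
    split plane) to ``z_scales[1]`` over ``z_twidth`` micrometers."""
    x0 = scene.cube_center[0] - scene.cube_size[0] / 2
    boundary = x0 + deform.z_split * scene.cube_size[0]
    zl, zr = deform.z_scales
    if deform.z_twidth <= 0:
        return np.where(x < boundary, zl, zr)
    w = deform.z_twidth / 4.0  # logistic scale: ~z_twidth from 12% to 88%
    frac = 1.0 / (1.0 + np.exp(-np.clip((x - boundary) / w, -60, 60)))
    return zl + (zr - zl) * frac


def _fov_half_extents(scene: SceneSpec, deform: DeformSpec, margin: float):
    a, b, c = scene.nucleus_semiaxes
    sx, sy, sz = deform.scales
    hx = a * sx
    hy = b * sy
    hz = c * sz
    if deform.mode == "shear":
        hx *= 1.0 + abs(deform.shear_rate) * hy
    return hx + margin, hy + margin, hz + margin


def _axis_coords(half_extent: float, step: float) -> np.ndarray:
    n = max(int(np.ceil(2 * half_extent / step)), 2)
    return (np.arange(n) - (n - 1) / 2) * step


def _render(
    scene: SceneSpec,
    deform: DeformSpec,
    voxel: tuple[float, float, float],
    margin: float,
    dilute: bool,
) -> ImageStack:
    dz, dy, dx = voxel
    hx, hy, hz = _fov_half_extents(scene, deform, margin)
    zc = _axis_coords(hz, dz)[:, None, None]
    yc = _axis_coords(hy, dy)[None, :, None]
    xc = _axis_coords(hx, dx)[None, None, :]

    x, y, z = _inverse_map(deform, scene, xc, yc, zc)
    a, b, c = scene.nucleus_semiaxes
    inside = ((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2) <= 1.0

    cx, cy, cz = scene.cube_center
    sx2, sy2, sz2 = (s / 2 for s in scene.cube_size)
    rough = _face_roughness(scene)
    if rough is None:
        lateral = (np.abs(x - cx) <= sx2) & (np.abs(y - cy) <= sy2)
        z_lo = cz - sz2
        z_hi = cz + sz2
    else:
        lateral = (
            (x >= cx - sx2 - rough["x-"](y, z))
            & (x <= cx + sx2 + rough["x+"](y, z))
            & (y >= cy - sy2 - rough["y-"](x, z))
            & (y <= cy + sy2 + rough["y+"](x, z))
        )
        z_lo = cz - sz2 - rough["z-"](x, y)
        z_hi = cz + sz2 + rough["z+"](x, y)
    sig = scene.axial_edge_sigma
    if sig > 0:
        rt2s = np.sqrt(2.0) * sig
        axial = 0.5 * (erf((z - z_lo) / rt2s) - erf((z - z_hi) / rt2s))
    else:
        axial = ((z >= z_lo) & (z <= z_hi)).astype(float)

    intensity = scene.nucleus_intensity
    if dilute:
        intensity /= deform.volume_factor
    shape = np.broadcast_shapes(np.shape(x), np.shape(y), np.shape(z), inside.shape)
    field = np.asarray(
        intensity * inside * (1.0 - scene.bleach_depth * lateral * axial), dtype=np.float32
    )
    if field.shape != shape:
        field = np.broadcast_to(field, shape).copy()
    tex = _texture_field(scene)
    if tex is not None:
        # texture only matters where there is signal
        zz, yy, xx = np.nonzero(np.broadcast_to(inside, shape))
        xv = np.broadcast_to(x, shape)[zz, yy, xx]
        yv = np.broadcast_to(y, shape)[zz, yy, xx]
        zv = np.broadcast_to(z, shape)[zz, yy, xx]
        density = np.clip(1.0 + scene.texture_amp * tex(xv, yv, zv), 0.05, None)
        field[zz, yy, xx] *= density.astype(np.float32)

    lat_sig, ax_sig = scene.psf_sigma
    if lat_sig > 0 or ax_sig > 0:
        field = ndimage.gaussian_filter(field, sigma=(ax_sig / dz, lat_sig / dy, lat_sig / dx))

    if scene.snr > 0:
        rng = np.random.default_rng(scene.seed)
        gain = scene.snr**2 / intensity
        field = rng.poisson(field * gain) / gain
        field = field + rng.normal(0.0, scene.read_noise_frac * intensity, size=field.shape)

    dtype = np.uint8 if scene.bit_depth == 8 else np.uint16
    voxels = np.clip(np.rint(field), 0, 2**scene.bit_depth - 1).astype(dtype)
    return ImageStack(voxels=voxels, dx=dx, dy=dy, dz=dz, bit_depth=scene.bit_depth)


def render_pre(
    scene: SceneSpec,
    voxel: tuple[float, float, float] = VOXELS_PRE,
    margin: float = 2.0,
) -> ImageStack:
    """Render the undeformed scene at pre-expansion voxel sizes
    ``(dz, dy, dx)`` with ``margin`` micrometers of background around
    the nucleus."""
    return _render(scene, IDENTITY, voxel, margin, dilute=False)


def render_post(
    scene: SceneSpec,
    deform: DeformSpec,
    voxel: tuple[float, float, float] = VOXELS_POST,
    margin: float = 2.0,
) -> ImageStack:
    """Render the deformed scene at post-expansion voxel sizes.

    The deformation acts on geometry in continuous coordinates; the
    fluorophore density is diluted by the volumetric expansion factor.
    An identity deformation at pre-expansion voxel sizes reproduces
    :func:`render_pre` bit-identically for the same seed.
    """
    return _render(scene, deform, voxel, margin, dilute=True)


def ground_truth_ef(
    scene: SceneSpec,
    deform: DeformSpec,
    axis: str,
    voxel_pre: tuple[float, float, float] = VOXELS_PRE,
) -> np.ndarray:
    """Closed-form per-line expansion factors from the deformation alone.

    One value per pre-expansion pixel line crossing the cube: constant
    for isotropic/affine modes, linear in line index for shear (axis x),
    and a step function across x for ``piecewise_z`` (axis z, as seen in
    the xz reslice).  No imaging effects enter.
    """
    if axis not in ("x", "y", "z"):
        raise ValueError(f"unknown axis {axis!r}")
    dz, dy, dx = voxel_pre
    sxs, sys_, szs = deform.scales
    sx, sy, sz = scene.cube_size
    if deform.mode == "shear" and axis == "x":
        n = max(int(round(sy / dy)), 1)
        y_pre = (np.arange(n) + 0.5) / n * sy - sy / 2
        return sxs * (1.0 + deform.shear_rate * sys_ * y_pre)
    if deform.mode == "piecewise_z" and axis == "z":
        n = max(int(round(sx / dx)), 1)
        x0 = scene.cube_center[0] - sx / 2
        x_pre = x0 + (np.arange(n) + 0.5) / n * sx
        return _axial_scale_profile(deform, scene, x_pre)
    const = {"x": sxs, "y": sys_, "z": szs}[axis]
    n_lines = {
        "x": max(int(round(sy / dy)), 1),  # x-lines stack along y
        "y": max(int(round(sx / dx)), 1),
        "z": max(int(round(sx / dx)), 1),  # z-lines across x in the xz view
    }[axis]
    return np.full(n_lines, const)


def simulate_pair(
    scene: SceneSpec,
    deform: DeformSpec,
    voxel_pre: tuple[float, float, float] = VOXELS_PRE,
    voxel_post: tuple[float, float, float] = VOXELS_POST,
    seed: int | None = None,
) -> tuple[ImageStack, ImageStack, dict]:
    """Render a pre/post pair with independent noise plus ground truth.

    ``seed`` overrides ``scene.seed``; the pre stack uses the seed
    itself and the post stack seed+1, so the pair's noise realisations
    are independent while each render stays deterministic.
    """
    s = scene.seed if seed is None else int(seed)
    pre = render_pre(replace(scene, seed=s, texture_seed=s), voxel_pre)
    post = render_post(replace(scene, seed=s + 1, texture_seed=s), deform, voxel_post)
    truth = {
        "deform": deform.to_dict(),
        "scene": scene.to_dict(),
        "seed": s,
        "ef": {ax: ground_truth_ef(scene, deform, ax, voxel_pre).tolist() for ax in "xyz"},
    }
    return pre, post, truth
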