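"""Image-stack I/O and orthogonal reslicing.

A stack is a single-channel 3D intensity volume indexed ``(z, y, x)``
(page-major, matching multi-page TIFF layout) together with its voxel
sizes in micrometers.  Voxel sizes travel with the data: the expansion
factor is a ratio of physical lengths, so every pixel count downstream
is converted to micrometers using these values.

Reslicing re-indexes the volume so that xz- or yz-planes become the
viewed images, which lets the z-dimension be analysed with exactly the
same 2D line-counting machinery as x and y.  It is a pure axis
permutation: no interpolation, every voxel value preserved.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import tifffile

__all__ = ["ImageStack", "read_stack", "write_stack", "reslice"]


@dataclass(frozen=True)
class ImageStack:
    """A 3D grayscale volume with voxel metadata.

    Parameters
    ----------
    voxels
        Non-negative intensities, shape ``(nz, ny, nx)``, dtype uint8 or
        uint16.
    dx, dy, dz
        Micrometers per pixel along x, y and per z-step.  All positive.
    bit_depth
        8 or 16; intensities must fit in ``[0, 2**bit_depth - 1]``.
    """

    voxels: np.ndarray
    dx: float
    dy: float
    dz: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError(f"voxels must be 3D (z, y, x), got shape {v.shape}")
        if min(v.shape) < 2:
            raise ValueError(f"stack needs >= 2 planes in every dimension, got {v.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        for name, step in (("dx", self.dx), ("dy", self.dy), ("dz", self.dz)):
            if not (step > 0 and np.isfinite(step)):
                raise ValueError(f"{name} must be a positive finite voxel size, got {step}")
        if v.min() < 0 or v.max() > 2**self.bit_depth - 1:
            raise ValueError("intensities outside [0, 2**bit_depth - 1]")
        object.__setattr__(self, "voxels", v)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def dtype_max(self) -> int:
        return 2**self.bit_depth - 1

    def astype_stack(self, voxels: np.ndarray) -> "ImageStack":
        """New stack with the same metadata but different voxels."""
        return replace(self, voxels=voxels)


def _dtype_for(bit_depth: int) -> np.dtype:
    return np.dtype(np.uint8 if bit_depth == 8 else np.uint16)


def read_stack(
    path: str | os.PathLike,
    dx: float | None = None,
    dy: float | None = None,
    dz: float | None = None,
) -> ImageStack:
    """Read a single-channel multi-page TIFF as an :class:`ImageStack`.

    Voxel sizes are taken from OME metadata when present; explicit
    ``dx``/``dy``/``dz`` arguments override whatever the file says
    (microscopy TIFF metadata is unreliable).  Raises if neither source
    provides a positive size.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such stack: {path}")
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = _voxel_sizes_from_ome(tf)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(
            f"unsupported layout: expected single-channel z-stack, got shape {data.shape}"
        )
    if data.dtype == np.uint8:
        bit_depth = 8
    elif data.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ValueError(f"unsupported layout: dtype {data.dtype} (need uint8/uint16)")
    sizes = {}
    for name, override in (("dx", dx), ("dy", dy), ("dz", dz)):
        val = override if override is not None else meta.get(name)
        if val is None or not val > 0:
            raise ValueError(f"voxel size {name} missing or non-positive (got {val})")
        sizes[name] = float(val)
    return ImageStack(voxels=data, bit_depth=bit_depth, **sizes)


def _voxel_sizes_from_ome(tf: "tifffile.TiffFile") -> dict[str, float]:
    out: dict[str, float] = {}
    ome = tf.ome_metadata
    if not ome:
        return out
    # tifffile exposes OME-XML as a string; pull PhysicalSize attributes.
    import re

    for axis, key in (("X", "dx"), ("Y", "dy"), ("Z", "dz")):
        m = re.search(rf'PhysicalSize{axis}="([0-9.eE+-]+)"', ome)
        if m:
            out[key] = float(m.group(1))
    return out


def write_stack(stack: ImageStack, path: str | os.PathLike) -> str:
    """Write ``stack`` as an OME-TIFF with voxel sizes in metadata.

    Round-trips bit-exactly through :func:`read_stack`.
    """
    import hashlib
    import uuid as _uuid

    data = np.ascontiguousarray(stack.voxels, dtype=_dtype_for(stack.bit_depth))
    # derive the OME UUID from the content so identical stacks produce
    # byte-identical files
    digest = hashlib.sha256(data.tobytes()).hexdigest()
    stable_uuid = str(_uuid.UUID(digest[:32]))
    tifffile.imwrite(
        path,
        data,
        ome=True,
        datetime=False,  # byte-identical output for identical stacks
        metadata={
            "UUID": f"urn:uuid:{stable_uuid}",
            "axes": "ZYX",
            "PhysicalSizeX": stack.dx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.dz,
            "PhysicalSizeZUnit": "µm",
        },
    )
    return os.fspath(path)


# (plane axis, row axis, col axis) of the output expressed in input (z, y, x)
# indices, plus which voxel sizes the output inherits.
_VIEWS = {
    # xz view: planes stacked along y, each plane shows rows=z, cols=x
    "xz": ((1, 0, 2), lambda s: {"dz": s.dy, "dy": s.dz, "dx": s.dx}),
    # yz view: planes stacked along x, each plane shows rows=z, cols=y
    "yz": ((2, 0, 1), lambda s: {"dz": s.dx, "dy": s.dz, "dx": s.dy}),
}


def reslice(stack: ImageStack, view: str) -> ImageStack:
    """Orthogonally reslice so xz- or yz-planes become the images.

    ``view="xz"``: output indexed ``(y, z, x)`` — plane step is dy, rows
    are z (size dz), columns are x (size dx).  ``view="yz"``: output
    indexed ``(x, z, y)``.  Pure permutation; no interpolation even for
    anisotropic voxels (downstream code multiplies counts by the right
    per-axis step, so resampling would only add error).
    """
    if view not in _VIEWS:
        raise ValueError(f"unknown view {view!r}; expected 'xz' or 'yz'")
    perm, sizes = _VIEWS[view]
    return ImageStack(
        voxels=np.ascontiguousarray(np.transpose(stack.voxels, perm)),
        bit_depth=stack.bit_depth,
        **sizes(stack),
    )
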