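"""Bring pre- and post-expansion stacks into comparable form.

The post-expansion acquisition is typically rotated relative to the
pre-expansion one and its intensity histogram is less spread out, so the
stack is rotationally aligned and rescaled before both stacks are
median-smoothed and the dark photobleached cube is segmented by an
intensity threshold.  The analysis then proceeds on binary masks only;
absolute position never matters, which is why no translation/registration
step exists.

Conventions: angles are degrees, positive = counterclockwise in the
standard image display (x right, y down); orientations of the fiducial
are defined modulo 90 degrees (a square looks the same after a quarter
turn) and reported in (-45, 45], with the tie at exactly +/-45 resolved
to +45.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io_stacks import ImageStack

__all__ = [
    "CubeMask",
    "SegmentationError",
    "estimate_rotation",
    "rotate_stack",
    "rescale_intensity",
    "smooth_median",
    "segment_cube",
    "select_analysis_planes",
]


class SegmentationError(RuntimeError):
    """No usable bleached-cube component could be extracted."""


@dataclass(frozen=True)
class CubeMask:
    """Binary mask of the bleached cube within its source stack.

    ``mask`` has the source stack's shape; ``bbox`` is the inclusive
    ``((z0, z1), (y0, y1), (x0, x1))`` bounding box of the (single)
    largest connected bleached component; ``middle_z`` is the rounded
    median z-coordinate of mask voxels (robust to ragged cube faces, in
    contrast to the bbox midpoint).  ``polarity`` records that "bleached"
    means below threshold unless segmentation was inverted.
    """

    mask: np.ndarray
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    middle_z: int
    polarity: str
    threshold: float
    dx: float
    dy: float
    dz: float

    @property
    def middle_y(self) -> int:
        return _rounded_median(np.nonzero(self.mask)[1])

    @property
    def middle_x(self) -> int:
        return _rounded_median(np.nonzero(self.mask)[2])


def _rounded_median(idx: np.ndarray) -> int:
    return int(np.floor(np.median(idx) + 0.5))


# ---------------------------------------------------------------------------
# rotation


def _moment_orientation(mask: np.ndarray) -> tuple[float, float]:
    """Principal-axis angle (deg, CCW from +x in display coords) and an
    elongation measure in [0, 1] quantifying how well-defined it is."""
    r, c = np.nonzero(mask)
    x = c - c.mean()
    y = r - r.mean()
    mu20 = np.mean(x * x)
    mu02 = np.mean(y * y)
    mu11 = np.mean(x * y)
    # y grows downward, so flip sign to get CCW-positive display angles
    theta = 0.5 * np.degrees(np.arctan2(-2 * mu11, mu20 - mu02))
    elong = np.hypot(mu20 - mu02, 2 * mu11) / (mu20 + mu02)
    return theta, elong


def _bbox_orientation(mask: np.ndarray) -> float:
    """Edge orientation (deg, mod 90) of a roughly rectangular mask by
    minimum-area rotated bounding box, coarse-to-fine and deterministic.

    Needed because second central moments are degenerate for 4-fold
    symmetric shapes: a square fiducial has mu20 == mu02 and mu11 == 0,
    so the principal-axis angle is numerically meaningless there.
    """
    r, c = np.nonzero(mask)
    x = c - c.mean()
    y = -(r - r.mean())  # CCW-positive frame

    def area(angle_deg: float) -> float:
        a = np.radians(angle_deg)
        u = x * np.cos(a) + y * np.sin(a)
        v = -x * np.sin(a) + y * np.cos(a)
        return (u.max() - u.min()) * (v.max() - v.min())

    coarse = np.arange(-45.0, 45.0, 1.0)
    best = coarse[int(np.argmin([area(a) for a in coarse]))]
    fine = np.arange(best - 1.0, best + 1.0 + 1e-9, 0.05)
    best = fine[int(np.argmin([area(a) for a in fine]))]
    return _wrap_quarter(best)


def _wrap_quarter(angle: float) -> float:
    """Map an angle to (-45, 45] modulo 90."""
    a = (angle + 45.0) % 90.0 - 45.0
    if a <= -45.0 + 1e-12:
        a = 45.0
    return float(a)


_ELONGATION_MIN = 0.05  # below this, moments are too degenerate to trust
MIN_COMPONENT_PX = 25


def _plane_orientation(mask: np.ndarray) -> float:
    if mask.sum() < MIN_COMPONENT_PX:
        raise SegmentationError(
            f"component too small for stable moments ({int(mask.sum())} < {MIN_COMPONENT_PX} px)"
        )
    theta, elong = _moment_orientation(mask)
    if elong >= _ELONGATION_MIN:
        return _wrap_quarter(theta)
    return _bbox_orientation(mask)


def estimate_rotation(pre_mask_plane: np.ndarray, post_mask_plane: np.ndarray) -> float:
    """Angle (degrees, in (-45, 45]) to rotate the post plane so its
    fiducial edges align with the pre plane's.

    Uses the second-central-moment principal axis when the component is
    clearly elongated; falls back to a minimum-area rotated-bounding-box
    search for (near-)square components where moments are degenerate.
    The tie between +45 and -45 resolves to +45.
    """
    for name, m in (("pre", pre_mask_plane), ("post", post_mask_plane)):
        if not np.any(m):
            raise SegmentationError(f"nothing to align: empty {name} mask plane")
    pre_or = _plane_orientation(np.asarray(pre_mask_plane, bool))
    post_or = _plane_orientation(np.asarray(post_mask_plane, bool))
    return _wrap_quarter(pre_or - post_or)


def _border_mode(plane: np.ndarray) -> int:
    border = np.concatenate(
        [plane[0, :], plane[-1, :], plane[1:-1, 0], plane[1:-1, -1]]
    ).astype(np.int64)
    return int(np.bincount(border).argmax())


def rotate_stack(stack: ImageStack, angle: float) -> ImageStack:
    """Rotate every xy-plane about its center by ``angle`` degrees (CCW
    positive in display coordinates) with first-order interpolation.

    Output shape is unchanged; regions rotated in from outside the frame
    are filled with the plane's background value, estimated as the modal
    intensity of its border pixels.
    """
    if not np.isfinite(angle):
        raise ValueError(f"angle must be finite, got {angle}")
    if angle == 0:
        return stack
    out = np.empty_like(stack.voxels)
    for i, plane in enumerate(stack.voxels):
        bg = _border_mode(plane)
        rot = ndimage.rotate(
            plane.astype(np.float64),
            angle,
            reshape=False,
            order=1,
            mode="constant",
            cval=float(bg),
        )
        out[i] = np.clip(np.rint(rot), 0, stack.dtype_max).astype(out.dtype)
    return stack.astype_stack(out)


# ---------------------------------------------------------------------------
# intensity


def rescale_intensity(stack: ImageStack, low_pct: float = 0.5, high_pct: float = 99.5) -> ImageStack:
    """Linearly stretch intensities so the ``low_pct``/``high_pct``
    percentiles of the *nonzero* voxels map to 0 and the dtype maximum.

    Percentiles are taken over nonzero voxels so the (often large) black
    background outside the nucleus does not dominate the histogram.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError(f"need 0 <= low < high <= 100, got ({low_pct}, {high_pct})")
    v = stack.voxels
    nz = v[v > 0]
    if nz.size == 0:
        raise ValueError("degenerate histogram: image is identically zero")
    # extreme percentiles (0/100) mean the global min/max, zeros included;
    # anything in between is computed on nonzero voxels so the black
    # background outside the nucleus cannot dominate
    lo = np.percentile(v if low_pct == 0 else nz, low_pct)
    hi = np.percentile(v if high_pct == 100 else nz, high_pct)
    if hi <= lo:
        raise ValueError("degenerate histogram: percentile range collapsed")
    scaled = (v.astype(np.float64) - lo) * (stack.dtype_max / (hi - lo))
    out = np.clip(np.rint(scaled), 0, stack.dtype_max).astype(v.dtype)
    return stack.astype_stack(out)


def smooth_median(stack: ImageStack, radius: int = 1) -> ImageStack:
    """Per-plane 2D median filter over a (2*radius+1)^2 window, reflected
    at the edges.  Planes are filtered independently because the z-step
    is much coarser than the pixel size, so a 3D window would be heavily
    anisotropic in physical units."""
    if radius < 1 or int(radius) != radius:
        raise ValueError(f"radius must be a positive integer, got {radius}")
    k = 2 * int(radius) + 1
    out = ndimage.median_filter(stack.voxels, size=(1, k, k), mode="reflect")
    return stack.astype_stack(out)


# ---------------------------------------------------------------------------
# segmentation


def _auto_threshold(stack: ImageStack) -> float:
    """Otsu's threshold computed within the nucleus region, taken as
    voxels above 10% of the dtype maximum (excludes the black background
    outside the nucleus so the split is cube-vs-nucleus)."""
    v = stack.voxels
    sample = v[v > 0.1 * stack.dtype_max]
    if sample.size == 0 or sample.min() == sample.max():
        raise SegmentationError("no bleached cube detected: nucleus region is empty or flat")
    return float(threshold_otsu(sample))


_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # faces only: 6-connectivity


def segment_cube(
    stack: ImageStack,
    threshold: float | str = "auto",
    invert_polarity: bool = False,
    open_radius: int = 0,
) -> CubeMask:
    """Segment the bleached cube as the largest interior below-threshold
    component.

    Voxels below ``threshold`` (above, when ``invert_polarity``) are
    labelled with 6-connectivity; components touching the stack's xy
    border are discarded (the dark background outside the nucleus always
    touches it, and a cube clipped by the field of view cannot be
    measured); the largest remaining component is the cube.
    ``threshold="auto"`` uses Otsu's method on the nucleus region.

    ``open_radius`` applies a binary opening with a 6-connected cross of
    that radius before labelling.  Nuclei are only roughly uniform: dark
    chromatin pockets can form voxel-thin bridges between the cube and
    the dark surround, which would wrongly merge them into one
    border-touching component.  Opening severs such sub-resolution
    bridges at the cost of slightly rounding the component's edges and
    corners, so it is off by default here; the analysis pipeline enables
    it (see ``RunConfig.open_radius``) because noisy nuclei need it far
    more than they need pixel-perfect cube corners.
    """
    thr = _auto_threshold(stack) if threshold == "auto" else float(threshold)
    # "bleached" is at-or-below threshold, matching the Otsu convention
    # that foreground (here: unbleached nucleus) is strictly above it
    if invert_polarity:
        binary = stack.voxels > thr
        polarity = "above_threshold"
    else:
        binary = stack.voxels <= thr
        polarity = "below_threshold"
    if not binary.any():
        raise SegmentationError("no bleached cube detected: no voxels beyond threshold")
    if open_radius:
        binary = ndimage.binary_opening(binary, structure=_STRUCT6, iterations=int(open_radius))
        if not binary.any():
            raise SegmentationError(
                "no bleached cube detected: nothing beyond threshold survives opening"
            )
    labels, n = ndimage.label(binary, structure=_STRUCT6)
    border_labels = np.unique(
        np.concatenate(
            [
                labels[:, 0, :].ravel(),
                labels[:, -1, :].ravel(),
                labels[:, :, 0].ravel(),
                labels[:, :, -1].ravel(),
            ]
        )
    )
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    counts[0] = 0
    counts[border_labels] = 0
    if counts.max() == 0:
        raise SegmentationError(
            "no bleached cube detected away from the xy border "
            "(cube may exceed the field of view)"
        )
    best = int(counts.argmax())
    mask = labels == best
    zz, yy, xx = np.nonzero(mask)
    bbox = (
        (int(zz.min()), int(zz.max())),
        (int(yy.min()), int(yy.max())),
        (int(xx.min()), int(xx.max())),
    )
    return CubeMask(
        mask=mask,
        bbox=bbox,
        middle_z=_rounded_median(zz),
        polarity=polarity,
        threshold=thr,
        dx=stack.dx,
        dy=stack.dy,
        dz=stack.dz,
    )


def select_analysis_planes(
    mask: CubeMask, axis: str, z_view: str = "xz"
) -> tuple[np.ndarray, tuple[float, float]]:
    """Extract the 2D analysis plane for one axis.

    For ``axis`` x or y: the xy mask plane at the cube's mid-height
    (``middle_z``), with in-plane pixel sizes ``(dy, dx)`` as
    (row, column) steps.  For ``axis`` z: the orthogonally resliced
    plane through the cube's mid-row — the xz plane at the rounded
    median y (``z_view="xz"``, sizes ``(dz, dx)``) or the yz plane at
    the rounded median x (``z_view="yz"``, sizes ``(dz, dy)``).
    """
    if axis in ("x", "y"):
        return mask.mask[mask.middle_z], (mask.dy, mask.dx)
    if axis == "z":
        if z_view == "xz":
            return mask.mask[:, mask.middle_y, :], (mask.dz, mask.dx)
        if z_view == "yz":
            return mask.mask[:, :, mask.middle_x], (mask.dz, mask.dy)
        raise ValueError(f"unknown z_view {z_view!r}; expected 'xz' or 'yz'")
    raise ValueError(f"unknown axis {axis!r}; expected 'x', 'y' or 'z'")
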