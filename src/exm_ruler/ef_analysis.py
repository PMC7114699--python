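"""Per-pixel-line expansion factors, robust summaries, and the isotropy verdict.

The measurement principle: within the analysis plane of each axis, every
pixel line crossing the segmented bleached square has a physical length
(bleached-pixel count x pixel size, micrometers).  Dividing the
post-expansion length of a line by the length of its matched
pre-expansion line gives a *local* expansion factor (EF).  The per-axis
EF distributions are summarised by their median (robust to the outliers
the ragged square borders always produce) and by the unscaled median
absolute deviation, MAD = median(|ef_i - median|) — no normal-consistency
factor is applied.

Two further diagnostics catch distortions that leave medians untouched:

* the **slope statistic** — the least-squares slope of post-expansion
  line lengths versus line index.  A photobleached square is straight by
  construction, so the slope of an isotropically expanded square
  approaches zero; a local distortion (e.g. shear) makes it deviate.
* **two-regime detection** — a deterministic 1D two-cluster split of the
  EF values; a clearly bimodal distribution (e.g. one part of the cube
  expanded ~5x, another ~2x along z) marks the expansion as anisotropic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_stacks import ImageStack, reslice
from .preprocess import (
    CubeMask,
    estimate_rotation,
    rescale_intensity,
    rotate_stack,
    segment_cube,
    select_analysis_planes,
    smooth_median,
)

__all__ = [
    "LineProfile",
    "EFDistribution",
    "IsotropyReport",
    "count_lines",
    "match_lines",
    "line_ef",
    "apply_outlier_rules",
    "summarize",
    "slope_statistic",
    "detect_two_regimes",
    "classify",
    "run_pair",
    "PipelineError",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, msg: str):
        self.stage = stage
        super().__init__(f"[{stage}] {msg}")


@dataclass(frozen=True)
class LineProfile:
    """Bleached-pixel counts for the pixel lines of one analysis plane.

    ``counts[i]`` is the number of bleached pixels in the i-th line
    (ordered by increasing index within the mask's bounding box);
    ``step`` converts a count to micrometers along the line's axis;
    ``line_spacing`` is the micrometer distance between successive lines.
    """

    axis: str
    counts: np.ndarray
    step: float
    line_spacing: float

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 1 or c.size == 0:
            raise ValueError("counts must be a non-empty 1D sequence")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def n_lines(self) -> int:
        return int(self.counts.size)

    def lengths_um(self) -> np.ndarray:
        return self.counts * self.step


@dataclass
class EFDistribution:
    """Per-line expansion factors for one axis, with retention flags.

    ``ef`` holds one value per matched pre-expansion line (NaN where the
    pre line had zero bleached pixels); ``retained`` marks lines that
    survive the border-outlier rules.  Summaries are computed over
    retained lines only.
    """

    axis: str
    ef: np.ndarray
    retained: np.ndarray
    pre_counts: np.ndarray
    post_counts: np.ndarray
    pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.ef = np.asarray(self.ef, dtype=float)
        self.retained = np.asarray(self.retained, dtype=bool)
        self.pre_counts = np.asarray(self.pre_counts, dtype=np.int64)
        self.post_counts = np.asarray(self.post_counts, dtype=np.int64)
        if not (len(self.ef) == len(self.retained) == len(self.pre_counts) == len(self.post_counts)):
            raise ValueError("ef, retained and count arrays must be parallel")

    @property
    def n_lines(self) -> int:
        """Number of retained lines."""
        return int(self.retained.sum())

    @property
    def median_ef(self) -> float:
        return summarize(self)[0]

    @property
    def mad_ef(self) -> float:
        return summarize(self)[1]


# ---------------------------------------------------------------------------
# line counting and matching


def count_lines(plane: np.ndarray, direction: str) -> tuple[np.ndarray, tuple[int, int]]:
    """Count bleached (true) pixels per row or column of a binary plane,
    restricted to the bounding box of the true pixels.

    Returns ``(counts, (lo, hi))`` where ``lo..hi`` (inclusive) are the
    bounding-box indices of the counted lines in the full plane.
    """
    p = np.asarray(plane, dtype=bool)
    if p.ndim != 2:
        raise ValueError("plane must be 2D")
    if not p.any():
        raise ValueError("empty plane: no bleached pixels to count")
    if direction not in ("rows", "cols"):
        raise ValueError(f"direction must be 'rows' or 'cols', got {direction!r}")
    axis_lines = 0 if direction == "rows" else 1
    sums = p.sum(axis=1 - axis_lines)
    nz = np.nonzero(sums)[0]
    lo, hi = int(nz.min()), int(nz.max())
    return sums[lo : hi + 1].astype(np.int64), (lo, hi)


def profile_from_plane(
    plane: np.ndarray, direction: str, axis: str, step: float, line_spacing: float
) -> LineProfile:
    """Build a :class:`LineProfile` from a binary analysis plane."""
    counts, _ = count_lines(plane, direction)
    return LineProfile(axis=axis, counts=counts, step=step, line_spacing=line_spacing)


def match_lines(pre: LineProfile, post: LineProfile) -> list[tuple[int, int]]:
    """Match each pre-expansion line to a post-expansion line by
    proportional index mapping: i -> round(i * (n_post-1)/(n_pre-1)).

    The pre-expansion grid is the reference: exactly one pair per pre
    line, monotone non-decreasing in the post index.  Single-line
    profiles map 0 -> 0.  Rounding is half-up.
    """
    if pre.axis != post.axis:
        raise ValueError(f"axis mismatch: {pre.axis!r} vs {post.axis!r}")
    n_pre, n_post = pre.n_lines, post.n_lines
    if n_pre == 1:
        return [(0, 0)]
    ratio = (n_post - 1) / (n_pre - 1)
    return [(i, int(np.floor(i * ratio + 0.5))) for i in range(n_pre)]


def line_ef(
    pre: LineProfile, post: LineProfile, pairs: list[tuple[int, int]] | None = None
) -> EFDistribution:
    """Per-line expansion factors from matched profiles.

    ``ef[k] = (post.counts[j] * post.step) / (pre.counts[i] * pre.step)``
    for pair ``k = (i, j)``.  Lines whose pre-expansion count is zero get
    an undefined (NaN) entry flagged not-retained — never infinity.
    """
    if pairs is None:
        pairs = match_lines(pre, post)
    n = len(pairs)
    ef = np.full(n, np.nan)
    retained = np.ones(n, dtype=bool)
    pre_counts = np.empty(n, dtype=np.int64)
    post_counts = np.empty(n, dtype=np.int64)
    for k, (i, j) in enumerate(pairs):
        pre_counts[k] = pre.counts[i]
        post_counts[k] = post.counts[j]
        if pre.counts[i] == 0:
            retained[k] = False
        else:
            ef[k] = (post.counts[j] * post.step) / (pre.counts[i] * pre.step)
    return EFDistribution(
        axis=pre.axis,
        ef=ef,
        retained=retained,
        pre_counts=pre_counts,
        post_counts=post_counts,
        pairs=list(pairs),
    )


# ---------------------------------------------------------------------------
# outlier rules and summaries


def apply_outlier_rules(
    dist: EFDistribution,
    border_width: int = 3,
    ef_lo: float = 2.0,
    ef_hi: float = 10.0,
    few_px_frac: float = 0.2,
) -> EFDistribution:
    """Drop non-representative border lines; never touch interior lines.

    A line is excluded iff it lies within ``border_width`` lines of
    either end of the square AND (its EF falls below ``ef_lo`` or above
    ``ef_hi``, or its pre-expansion count is below ``few_px_frac`` times
    the median pre-expansion count).  Such values come from the few
    ragged rows at the square's borders and do not represent the actual
    expansion; outliers in the middle of the square are genuine and are
    always kept.
    """
    n = len(dist.ef)
    retained = dist.retained.copy()
    median_pre = np.median(dist.pre_counts)
    for k in range(n):
        if k >= border_width and k < n - border_width:
            continue  # interior lines are never removed
        bad_ef = np.isfinite(dist.ef[k]) and (dist.ef[k] < ef_lo or dist.ef[k] > ef_hi)
        few_px = dist.pre_counts[k] < few_px_frac * median_pre
        if bad_ef or few_px:
            retained[k] = False
    if not retained.any():
        raise ValueError("all lines removed by outlier rules: segmentation failure")
    return replace(dist, retained=retained)


def summarize(dist: EFDistribution) -> tuple[float, float, int]:
    """Median, unscaled MAD and count over the retained EF values.

    The median resists the border outliers every segmented square shows;
    the MAD is the median of absolute deviations from that median, with
    no 1.4826 consistency factor.
    """
    vals = dist.ef[dist.retained]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no retained lines to summarize")
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    return med, mad, int(vals.size)


def slope_statistic(post_counts: np.ndarray, retained: np.ndarray | None = None) -> float:
    """Normalized slope of post-expansion line lengths vs line index.

    Ordinary least-squares slope of the retained post-expansion counts
    against their line indices, divided by the mean retained count —
    i.e. the fractional width change per line.  Near zero for an
    intrinsically straight, isotropically expanded square; deviates
    under local distortion.  Sign follows increasing line index.
    """
    post_counts = np.asarray(post_counts, dtype=float)
    if retained is None:
        retained = np.ones(post_counts.shape, dtype=bool)
    idx = np.nonzero(np.asarray(retained, dtype=bool))[0]
    if idx.size < 3:
        raise ValueError(f"need >= 3 retained lines for a slope, got {idx.size}")
    y = post_counts[idx]
    x = idx.astype(float)
    xc = x - x.mean()
    slope = float(xc @ (y - y.mean()) / (xc @ xc))
    mean = float(y.mean())
    if mean == 0:
        raise ValueError("mean retained count is zero")
    return slope / mean


def detect_two_regimes(
    dist_or_values: "EFDistribution | np.ndarray",
    regime_sep: float = 3.0,
    min_frac: float = 0.2,
    min_rel_sep: float = 0.25,
) -> tuple[bool, float, float]:
    """Flag a bimodal EF distribution via an exhaustive 1D two-cluster split.

    All splits of the sorted retained EF values are searched for the
    minimum within-cluster sum of squares (deterministic — no fitted
    mixture).  The distribution is flagged two-regime iff the cluster
    centers are separated by more than ``regime_sep`` pooled
    within-cluster standard deviations, each cluster holds at least
    ``min_frac`` of the lines, and the centers differ by at least
    ``min_rel_sep`` of their mean.  The last condition is a materiality
    floor: per-line EFs are ratios of integer pixel counts and therefore
    live on a lattice with steps of a few percent; a split across one
    such quantization step can have near-zero within-cluster spread
    without representing distinct physical expansion regimes, which
    differ by tens of percent (e.g. ~5x vs ~2x).
    Returns ``(flag, center_low, center_high)``.
    """
    if isinstance(dist_or_values, EFDistribution):
        vals = dist_or_values.ef[dist_or_values.retained]
    else:
        vals = np.asarray(dist_or_values, dtype=float)
    vals = np.sort(vals[np.isfinite(vals)])
    n = vals.size
    if n < 6:
        raise ValueError(f"need >= 6 retained lines for regime detection, got {n}")
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    csq = np.concatenate([[0.0], np.cumsum(vals**2)])

    def wcss_upto(k: int) -> float:  # SS of vals[:k]
        return csq[k] - csum[k] ** 2 / k

    best_k, best = 1, np.inf
    for k in range(1, n):
        w = wcss_upto(k) + (csq[n] - csq[k] - (csum[n] - csum[k]) ** 2 / (n - k))
        if w < best - 1e-15:
            best, best_k = w, k
    lo = vals[:best_k]
    hi = vals[best_k:]
    c_lo, c_hi = float(lo.mean()), float(hi.mean())
    pooled_sd = float(np.sqrt(max(best, 0.0) / (n - 2))) if n > 2 else 0.0
    balanced = min(lo.size, hi.size) >= min_frac * n
    sep = c_hi - c_lo
    material = sep >= min_rel_sep * 0.5 * (c_hi + c_lo)
    flag = bool(balanced and material and sep > regime_sep * pooled_sd)
    return flag, c_lo, c_hi


# ---------------------------------------------------------------------------
# classification and the full pipeline


@dataclass
class IsotropyReport:
    """Per-axis EF distributions, distortion diagnostics and the verdict.

    ``distributions`` maps axis name -> :class:`EFDistribution`; axes
    ``x`` and ``y`` come from the middle xy-plane, ``z`` pools both
    orthogonal reslices, which are also reported separately as ``z_xz``
    and ``z_yz``.  ``slope`` is the per-line normalized slope statistic;
    ``slope_total`` multiplies it by (n_retained - 1), giving the total
    fractional width change across the square — the quantity compared
    against ``slope_tol``, so the test is independent of how finely the
    square is sampled.  ``verdict`` is one of ``isotropic``,
    ``local_distortion``, ``anisotropic``.
    """

    distributions: dict[str, EFDistribution]
    slope: dict[str, float]
    slope_total: dict[str, float]
    two_regime: dict[str, bool]
    regime_centers: dict[str, tuple[float, float]]
    verdict: str
    parameters: dict
    rotation_applied: float = 0.0

    def summary_stats(self) -> dict[str, dict[str, float]]:
        out = {}
        for axis, dist in self.distributions.items():
            med, mad, n = summarize(dist)
            out[axis] = {"median_ef": med, "mad_ef": mad, "n_lines": n}
        return out


_MAIN_AXES = ("x", "y", "z")


def classify(
    distributions: dict[str, EFDistribution],
    slopes: dict[str, float],
    two_regime: dict[str, bool],
    median_tol: float = 0.3,
    slope_tol: float = 0.02,
) -> str:
    """Categorical verdict from per-axis summaries and diagnostics.

    * any axis bimodal (two-regime) -> ``anisotropic``: part of the cube
      expanded at a distinctly different factor;
    * else any in-plane (x, y) across-square slope magnitude above
      ``slope_tol``, or the per-axis medians spreading by more than
      ``median_tol`` -> ``local_distortion``;
    * else ``isotropic``.

    The slope criterion applies to the lateral axes only: the bleaching
    raster makes the square intrinsically straight in the xy-plane, so a
    nonzero lateral slope is diagnostic.  The cube's axial extent offers
    no such straightness guarantee (its faces carry focus jitter), so
    the z slope is reported as a diagnostic but does not enter the
    verdict.
    """
    missing = [a for a in _MAIN_AXES if a not in distributions]
    if missing:
        raise ValueError(f"missing axis distributions: {missing}")
    if any(two_regime.get(a, False) for a in _MAIN_AXES):
        return "anisotropic"
    medians = [summarize(distributions[a])[0] for a in _MAIN_AXES]
    median_spread = max(medians) - min(medians)
    if any(abs(slopes.get(a, 0.0)) > slope_tol for a in ("x", "y")):
        return "local_distortion"
    if median_spread > median_tol:
        return "local_distortion"
    return "isotropic"


def _segment_pipeline(stack: ImageStack, config) -> CubeMask:
    s = rescale_intensity(stack, *config.rescale_percentiles)
    s = smooth_median(s, config.median_radius)
    return segment_cube(s, config.threshold, config.invert_polarity, config.open_radius)


def _axis_distribution(
    pre_mask: CubeMask, post_mask: CubeMask, axis: str, z_view: str, config
) -> tuple[EFDistribution, float, float]:
    """EF distribution plus (slope, slope_total) for one axis/view."""
    pre_plane, (pre_row, pre_col) = select_analysis_planes(pre_mask, axis, z_view)
    post_plane, (post_row, post_col) = select_analysis_planes(post_mask, axis, z_view)
    if axis == "x":
        direction = "rows"
        pre_step, pre_spacing = pre_col, pre_row
        post_step, post_spacing = post_col, post_row
    else:  # y, or z where lines run along z (plane rows): one line per column
        direction = "cols"
        pre_step, pre_spacing = pre_row, pre_col
        post_step, post_spacing = post_row, post_col
    name = axis if axis != "z" else f"z_{z_view}"
    pre_prof = profile_from_plane(pre_plane, direction, name, pre_step, pre_spacing)
    post_prof = profile_from_plane(post_plane, direction, name, post_step, post_spacing)
    dist = line_ef(pre_prof, post_prof)
    dist = apply_outlier_rules(
        dist, config.border_width, config.ef_lo, config.ef_hi, config.few_px_frac
    )
    # The slope is fitted on interior retained lines only: the square's
    # corners produce partial border rows whose counts ramp up from zero,
    # and their leverage would swamp the straightness signal the slope is
    # meant to capture.
    interior = np.zeros(len(dist.ef), dtype=bool)
    bw = config.border_width
    interior[bw : len(dist.ef) - bw] = True
    use = dist.retained & interior
    if use.sum() >= 3:
        slope = slope_statistic(dist.post_counts, use)
        slope_total = slope * max(int(use.sum()) - 1, 1)
    else:
        slope = slope_statistic(dist.post_counts, dist.retained)
        slope_total = slope * max(int(dist.retained.sum()) - 1, 1)
    return dist, slope, slope_total


def run_pair(pre: ImageStack, post: ImageStack, config=None) -> IsotropyReport:
    """Full analysis of a pre/post-expansion stack pair.

    Stages: rotational alignment of the post stack (estimated from the
    mid-cube mask planes unless a fixed angle is configured), intensity
    rescale, median smoothing, cube segmentation on both stacks, then
    per-axis line profiles, matched EFs, border-outlier rules, robust
    summaries, slope statistics, two-regime detection and the verdict.
    Deterministic given inputs and configuration.
    """
    from .config import RunConfig

    if config is None:
        config = RunConfig()

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError(name, str(e)) from e

    pre_mask = stage("segment_pre", _segment_pipeline, pre, config)

    if config.angle == "auto":
        coarse_post = stage("segment_post", _segment_pipeline, post, config)
        angle = stage(
            "estimate_rotation",
            estimate_rotation,
            pre_mask.mask[pre_mask.middle_z],
            coarse_post.mask[coarse_post.middle_z],
        )
    else:
        coarse_post = None
        angle = float(config.angle)
    if abs(angle) >= config.min_rotation:
        post = stage("rotate", rotate_stack, post, angle)
        post_mask = stage("segment_post", _segment_pipeline, post, config)
    elif coarse_post is not None:
        post_mask = coarse_post
    else:
        post_mask = stage("segment_post", _segment_pipeline, post, config)

    dists: dict[str, EFDistribution] = {}
    slopes: dict[str, float] = {}
    slopes_total: dict[str, float] = {}
    for axis in ("x", "y"):
        dists[axis], slopes[axis], slopes_total[axis] = stage(
            f"ef_{axis}", _axis_distribution, pre_mask, post_mask, axis, "xz", config
        )
    for view in ("xz", "yz"):
        name = f"z_{view}"
        dists[name], slopes[name], slopes_total[name] = stage(
            f"ef_{name}", _axis_distribution, pre_mask, post_mask, "z", view, config
        )
    # pooled z distribution: both orthogonal views together
    zx, zy = dists["z_xz"], dists["z_yz"]
    dists["z"] = EFDistribution(
        axis="z",
        ef=np.concatenate([zx.ef, zy.ef]),
        retained=np.concatenate([zx.retained, zy.retained]),
        pre_counts=np.concatenate([zx.pre_counts, zy.pre_counts]),
        post_counts=np.concatenate([zx.post_counts, zy.post_counts]),
        pairs=zx.pairs + zy.pairs,
    )
    # the z slope is per-view (a pooled fit would fabricate a slope at the
    # junction of the two reslices); report the larger-magnitude view
    z_view_key = max(("z_xz", "z_yz"), key=lambda k: abs(slopes_total[k]))
    slopes["z"] = slopes[z_view_key]
    slopes_total["z"] = slopes_total[z_view_key]

    two_regime: dict[str, bool] = {}
    centers: dict[str, tuple[float, float]] = {}
    for name, d in dists.items():
        try:
            flag, lo, hi = detect_two_regimes(
                d, config.regime_sep, min_rel_sep=config.regime_min_rel_sep
            )
        except ValueError:
            flag, lo, hi = False, np.nan, np.nan
        two_regime[name] = flag
        centers[name] = (lo, hi)

    verdict = stage(
        "classify",
        classify,
        {a: dists[a] for a in _MAIN_AXES},
        {a: slopes_total[a] for a in _MAIN_AXES},
        {a: two_regime[a] for a in _MAIN_AXES},
        config.median_tol,
        config.slope_tol,
    )
    return IsotropyReport(
        distributions=dists,
        slope=slopes,
        slope_total=slopes_total,
        two_regime=two_regime,
        regime_centers=centers,
        verdict=verdict,
        parameters=config.to_dict(),
        rotation_applied=angle,
    )
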