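"""Run configuration: every analysis knob with its default, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Parameters of the pre/post analysis pipeline.

    Every value is echoed verbatim into the JSON report so a run is
    fully reproducible from its output.

    Attributes
    ----------
    threshold
        Segmentation threshold (intensity) or ``"auto"`` for Otsu's
        method on the nucleus region.
    median_radius
        Half-width of the per-plane median filter window (pixels).
    rescale_percentiles
        (low, high) percentiles of nonzero voxels mapped to the full
        intensity range; (0.5, 99.5) is robust to hot pixels.
    angle
        ``"auto"`` to estimate the post-stack rotation from the fiducial
        masks, or a fixed angle in degrees (0 disables rotation).
    min_rotation
        Estimated angles below this magnitude (degrees) are not applied:
        interpolating by a fraction of a degree only blurs edges.
    border_width, ef_lo, ef_hi, few_px_frac
        Border-outlier rules: within ``border_width`` lines of either
        end of the square, lines with EF outside [ef_lo, ef_hi] or with
        fewer than ``few_px_frac`` x median pre-expansion pixels are
        dropped; interior lines are never dropped.
    regime_sep
        Two-regime flag requires cluster centers separated by more than
        this many pooled within-cluster standard deviations.
    regime_min_rel_sep
        Materiality floor for the two-regime flag: centers must differ
        by at least this fraction of their mean, so splits across a
        single count-quantization step are not called regimes.
    open_radius
        Radius of the binary opening applied before connected-component
        labelling in segmentation (0 disables); severs voxel-thin dark
        bridges between the cube and the background.
    median_tol, slope_tol
        Verdict thresholds: maximum spread of per-axis median EFs, and
        maximum total fractional width change across the square (the
        across-square slope statistic).  ``slope_tol`` is a tool
        default, not a literature value — tune it to your optics.
    """

    threshold: float | str = "auto"
    median_radius: int = 1
    rescale_percentiles: tuple[float, float] = (0.5, 99.5)
    angle: float | str = "auto"
    invert_polarity: bool = False
    open_radius: int = 1
    min_rotation: float = 0.25
    border_width: int = 3
    ef_lo: float = 2.0
    ef_hi: float = 10.0
    few_px_frac: float = 0.2
    regime_sep: float = 3.0
    regime_min_rel_sep: float = 0.25
    median_tol: float = 0.3
    slope_tol: float = 0.02
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rescale_percentiles"] = list(self.rescale_percentiles)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "rescale_percentiles" in d:
            d["rescale_percentiles"] = tuple(d["rescale_percentiles"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
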