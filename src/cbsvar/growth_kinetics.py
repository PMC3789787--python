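"""Growth-rate estimation from microplate OD595 time-series.

The assay measures yeast growth every 30 min for 72-96 h starting at
OD595 ~ 0.01.  Rates are obtained by (1) rescaling each well's raw trace
to its resuspended endpoint read, (2) log10-transforming, (3) taking the
least-squares slope over the points falling between two fixed cell
densities (0.05-0.1 OD for HEM1 strains, 0.1-0.2 for hem1-delta strains,
whose cultures are denser in exponential phase), (4) applying a
multiplicative plate-normalization factor anchored to the reference
(major-allele) strain, and (5) expressing each variant rate as a ratio to
the major-allele rate in the same medium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .data_model import AssayCondition

__all__ = [
    "GrowthCurve",
    "RateEstimate",
    "PlateNormalization",
    "default_window",
    "normalize_curve",
    "estimate_rate",
    "plate_normalize",
    "relative_rate",
]

logger = logging.getLogger(__name__)

#: OD595 window bounds for the fixed-density slope, keyed by strain background
WINDOW_HEM1 = (0.05, 0.1)
WINDOW_HEM1_DELTA = (0.1, 0.2)


class InvalidCurveError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class GrowthCurve:
    """One well's OD595 time-series plus metadata."""

    well_id: str
    strain_label: str           # variant token or "major"
    plate_id: str
    condition: AssayCondition
    times: np.ndarray           # hours, strictly increasing
    od: np.ndarray              # OD595, same length
    endpoint_od: float          # resuspended endpoint read

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od", od)
        if times.ndim != 1 or times.size < 2 or od.shape != times.shape:
            raise InvalidCurveError(
                f"{self.well_id}: need matched time/OD vectors with >= 2 points")
        if np.any(np.diff(times) <= 0):
            raise InvalidCurveError(f"{self.well_id}: times must be strictly increasing")
        if np.any(od < 0):
            raise InvalidCurveError(f"{self.well_id}: negative OD reading")
        if not self.endpoint_od > 0:
            raise InvalidCurveError(f"{self.well_id}: endpoint OD must be positive")


@dataclass(frozen=True)
class RateEstimate:
    """Log10-slope of a curve within the fixed-density window."""

    rate: float | None          # log10 OD per hour; None if window not attained
    window: tuple[float, float]
    n_points_used: int
    attained_window: bool

    def __post_init__(self) -> None:
        if self.attained_window and (self.rate is None or self.n_points_used < 2):
            raise ValueError("attained window requires a rate from >= 2 points")
        if not self.attained_window and self.rate is not None:
            raise ValueError("rate reported without attaining the window")


@dataclass(frozen=True)
class PlateNormalization:
    plate_id: str
    factor: float

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise ValueError("normalization factor must be positive")


def default_window(condition: AssayCondition) -> tuple[float, float]:
    """Fixed-density slope window for the strain background of a condition."""
    return WINDOW_HEM1_DELTA if condition.hem1_deleted else WINDOW_HEM1


def normalize_curve(curve: GrowthCurve) -> GrowthCurve:
    """Rescale raw OD values so the final timepoint equals the endpoint read.

    The endpoint read is taken after resuspending the settled cells, so it
    is the well's true final density; rescaling removes per-well gain (path
    length, settling) by a single multiplicative factor.
    """
    final = curve.od[-1]
    if final <= 0:
        raise InvalidCurveError(
            f"{curve.well_id}: final OD reading is {final}; cannot rescale")
    factor = curve.endpoint_od / final
    return replace(curve, od=curve.od * factor)


def estimate_rate(curve: GrowthCurve,
                  window: tuple[float, float] | None = None,
                  *, two_point: bool = False) -> RateEstimate:
    """Slope of log10(OD) vs time over the points inside the density window.

    Window membership is inclusive on both bounds.  By default the slope is
    the ordinary least-squares fit over all in-window points; ``two_point``
    uses only the first and last in-window reads.  If fewer than two points
    fall inside the window the estimate is reported as not attained rather
    than raising.
    """
    if window is None:
        window = default_window(curve.condition)
    lower, upper = window
    if not lower < upper:
        raise ValueError(f"window bounds must satisfy lower < upper, got {window}")

    od = curve.od
    times = curve.times
    positive = od > 0
    if not positive.all():
        logger.warning("%s: dropping %d non-positive OD reads before log transform",
                       curve.well_id, int((~positive).sum()))
        od = od[positive]
        times = times[positive]
    mask = (od >= lower) & (od <= upper)
    n = int(mask.sum())
    if n < 2:
        return RateEstimate(rate=None, window=window, n_points_used=n,
                            attained_window=False)
    t = times[mask]
    y = np.log10(od[mask])
    if two_point:
        slope = (y[-1] - y[0]) / (t[-1] - t[0])
        n = 2
    else:
        slope = float(np.polyfit(t, y, 1)[0])
    return RateEstimate(rate=float(slope), window=window, n_points_used=n,
                        attained_window=True)


def plate_normalize(
    rates: dict[str, list[tuple[str, float]]],
    reference_strain: str = "major",
) -> tuple[dict[str, list[tuple[str, float]]], dict[str, PlateNormalization]]:
    """Remove plate-to-plate rate variation, anchored to the reference strain.

    ``rates`` maps plate_id to ``(strain_label, rate)`` pairs.  Each plate's
    factor is (grand mean of reference rates over all plates) / (mean
    reference rate on that plate); every rate on the plate is multiplied by
    its factor, which makes the per-plate reference means equal and leaves
    variant/reference ratios unchanged within a plate.
    """
    ref_means: dict[str, float] = {}
    for plate_id, pairs in rates.items():
        ref = [r for s, r in pairs if s == reference_strain]
        if not ref:
            raise NormalizationError(
                f"plate {plate_id!r} has no usable {reference_strain!r} rate")
        ref_means[plate_id] = float(np.mean(ref))
    grand = float(np.mean(list(ref_means.values())))
    factors = {p: PlateNormalization(p, grand / m) for p, m in ref_means.items()}
    normalized = {
        p: [(s, r * factors[p].factor) for s, r in pairs]
        for p, pairs in rates.items()
    }
    return normalized, factors


def relative_rate(variant_rate: float, major_rate: float) -> float:
    """Variant growth rate as a ratio to the major-allele rate."""
    if not major_rate > 0:
        raise ValueError(f"major-allele rate must be positive, got {major_rate}")
    return variant_rate / major_rate
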