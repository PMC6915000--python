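"""The time-continuous symmetry function (SF) and its parameterization.

For two curves x1(t), x2(t) on the common %CT grid,

    SF(t) = (x1(t) - x2(t)) / (0.5 * (Range(x1) + Range(x2))) * 100%

where Range(x) is the scalar max - min of the curve over the whole cycle.
SF is the classical symmetry index generalised over the cycle: zero means
equality of the sides at that instant, the sign names the dominant
(first-labelled) side, and +/-200% corresponds to the hypothetical case of
equal-range curves whose extremes are opposite and simultaneous.

The denominator is a constant per comparison, so SF inherits the
instability of ratio indices for very small ranges of motion: a 1 deg side
difference reads as 20% when the mean ROM is 5 deg but only 2% when it is
50 deg. Near-zero denominators raise DegenerateRangeError rather than
returning huge finite values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, DegenerateRangeError, InputError
from .gait_model import CurveParams, NormalizedCurve, PhaseHit, SFCurve, locate_phase
from .normalization import validate_pair

__all__ = [
    "DEGENERATE_RANGE_EPS",
    "SYMMETRIC_THRESHOLD",
    "ASYMMETRIC_THRESHOLD",
    "SFResult",
    "curve_range",
    "symmetry_function",
    "parameterize",
    "classify_asymmetry",
    "annotate_phases",
    "compute_sf",
]

#: Below this mean range (degrees) the SF denominator is considered degenerate.
DEGENERATE_RANGE_EPS = 1e-6

#: Symmetry-index thresholds (percent): below 10 is typical of non-injured
#: populations, 15 or more is associated with injury; in between is
#: borderline.
SYMMETRIC_THRESHOLD = 10.0
ASYMMETRIC_THRESHOLD = 15.0


def curve_range(curve: NormalizedCurve | SFCurve | np.ndarray) -> float:
    """Scalar range (max - min) of a curve over the whole cycle."""
    values = curve if isinstance(curve, np.ndarray) else curve.values
    if not np.all(np.isfinite(values)):
        raise InputError("curve values must be finite")
    return float(np.max(values) - np.min(values))


def symmetry_function(
    first: NormalizedCurve,
    second: NormalizedCurve,
    first_label: str | None = None,
    second_label: str | None = None,
) -> SFCurve:
    """Pointwise SF between two normalized curves (percent).

    Positive values mean the ``first`` curve dominates. Labels default to
    the curves' side attributes.

    Raises
    ------
    InputError
        If the curves fail :func:`gaitsf.normalization.validate_pair`.
    DegenerateRangeError
        If the mean of the two ranges falls below ``DEGENERATE_RANGE_EPS``.
    """
    check = validate_pair(first, second)
    if not check:
        raise InputError(f"curves not comparable: {check.reason}")
    denom = 0.5 * (curve_range(first) + curve_range(second))
    if denom < DEGENERATE_RANGE_EPS:
        raise DegenerateRangeError(
            f"mean range {denom:.3g} deg below {DEGENERATE_RANGE_EPS} deg; "
            "SF is undefined for (near-)constant curves"
        )
    values = (first.values - second.values) / denom * 100.0
    if first_label is None:
        first_label = first.side.value if first.side is not None else "first"
    if second_label is None:
        second_label = second.side.value if second.side is not None else "second"
    return SFCurve(
        values=values,
        first_label=first_label,
        second_label=second_label,
        joint=first.joint or second.joint,
    )


def parameterize(curve: SFCurve | NormalizedCurve | np.ndarray) -> CurveParams:
    """Extract Peak^min, Peak^max, their first-occurrence times, and range.

    Ties between grid points attaining an extreme are broken by the first
    occurrence in ascending %CT. Units follow the source curve (degrees for
    angle curves, percent for SF curves); times are %CT.
    """
    if isinstance(curve, np.ndarray):
        values = np.asarray(curve, dtype=float)
        grid = np.linspace(0.0, 100.0, values.size)
    else:
        values = curve.values
        grid = curve.grid
    if not np.all(np.isfinite(values)):
        raise InputError("curve values must be finite")
    i_min = int(np.argmin(values))
    i_max = int(np.argmax(values))
    peak_min = float(values[i_min])
    peak_max = float(values[i_max])
    return CurveParams(
        peak_min=peak_min,
        t_min=float(grid[i_min]),
        peak_max=peak_max,
        t_max=float(grid[i_max]),
        rom=peak_max - peak_min,
    )


def classify_asymmetry(
    params: CurveParams,
    statistic: str = "peak_abs",
    curve: SFCurve | None = None,
) -> str:
    """Classify an SF curve's asymmetry magnitude against the 10/15% cutoffs.

    ``peak_abs`` uses max(|Peak^min|, |Peak^max|); ``mean_abs`` uses the
    mean of |SF(t)| and requires the curve. s < 10 -> "symmetric",
    10 <= s < 15 -> "borderline", s >= 15 -> "asymmetric".
    """
    if statistic == "peak_abs":
        s = max(abs(params.peak_min), abs(params.peak_max))
    elif statistic == "mean_abs":
        if curve is None:
            raise ConfigurationError("mean_abs statistic requires the SF curve")
        s = float(np.mean(np.abs(curve.values)))
    else:
        raise ConfigurationError(f"unknown statistic {statistic!r}")
    if s < SYMMETRIC_THRESHOLD:
        return "symmetric"
    if s < ASYMMETRIC_THRESHOLD:
        return "borderline"
    return "asymmetric"


@dataclass(frozen=True)
class SFResult:
    """An SF curve with its parameters, peak phases and classification."""

    curve: SFCurve
    params: CurveParams
    peak_phases: tuple[PhaseHit, PhaseHit] | None = None
    classification: str | None = None


def annotate_phases(result: SFResult) -> SFResult:
    """Attach the Perry phases of t_min and t_max (areas of greatest
    asymmetry)."""
    phases = (locate_phase(result.params.t_min), locate_phase(result.params.t_max))
    return replace(result, peak_phases=phases)


def compute_sf(
    first: NormalizedCurve,
    second: NormalizedCurve,
    statistic: str = "peak_abs",
    first_label: str | None = None,
    second_label: str | None = None,
) -> SFResult:
    """Full SF pipeline for one curve pair: curve, params, phases, class."""
    curve = symmetry_function(first, second, first_label, second_label)
    params = parameterize(curve)
    result = SFResult(
        curve=curve,
        params=params,
        classification=classify_asymmetry(params, statistic, curve=curve),
    )
    return annotate_phases(result)
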