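"""Time normalization of gait cycles to the canonical 101-point %CT grid.

Each measured cycle, sampled at arbitrary (strictly increasing) times, is
resampled with piecewise Lagrange interpolating polynomials: for every grid
time the four nearest samples define a local cubic interpolant which is
evaluated there. Local windows avoid the Runge oscillation a single global
polynomial over ~100 samples would exhibit, while keeping the two defining
properties needed downstream: the interpolant reproduces the sample values
exactly at the sample times, and it is exact for polynomials up to cubic.
The window is clamped at the cycle ends.

No detrending or smoothing is applied: within one gait cycle the angle
waveform itself is the signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, InsufficientDataError
from .gait_model import AngleCycle, NormalizedCurve

__all__ = ["time_normalize", "validate_pair", "PairCheck", "lagrange_resample"]

_ORDER = 3  # local polynomial order; window size = order + 1 samples


def lagrange_resample(
    times: np.ndarray, values: np.ndarray, targets: np.ndarray
) -> np.ndarray:
    """Evaluate local cubic Lagrange interpolants of (times, values) at targets.

    For each target the window of ``_ORDER + 1`` consecutive samples whose
    left edge puts the target nearest the window centre is used (clamped at
    the ends). The interpolant is evaluated in barycentric form anchored at
    the window's first value, so evaluation at a time bitwise-equal to a
    sample time returns that sample value bit-identically and constant
    traces are reproduced exactly.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    targets = np.asarray(targets, dtype=float)
    n = times.size
    w = _ORDER + 1
    if n < w:
        raise InsufficientDataError(f"need >= {w} samples, got {n}")
    # left index of the interval containing each target
    left = np.searchsorted(times, targets, side="right") - 1
    start = np.clip(left - (w - 1) // 2, 0, n - w)
    out = np.empty_like(targets)
    for k, (x, s) in enumerate(zip(targets, start)):
        ts = times[s : s + w]
        ys = values[s : s + w]
        diff = x - ts
        hit = np.nonzero(diff == 0.0)[0]
        if hit.size:
            out[k] = ys[hit[0]]
            continue
        # barycentric form of the local Lagrange interpolant: exact for
        # constants (weights normalised) and stable within the window
        weights = np.empty(w)
        for i in range(w):
            denom = 1.0
            for j in range(w):
                if j != i:
                    denom *= ts[i] - ts[j]
            weights[i] = 1.0 / denom
        q = weights / diff
        # interpolate the residual about ys[0]: constants come out exact
        out[k] = ys[0] + np.dot(q, ys - ys[0]) / np.sum(q)
    return out


def time_normalize(cycle: AngleCycle, n_points: int = 101) -> NormalizedCurve:
    """Resample one cycle to the 0-100%CT grid (1%CT step by default).

    Grid time k maps to ``t0 + k*(t_end - t0)/(n_points - 1)`` where t0 and
    t_end are the first and last sample times of the cycle; 0%CT is the
    first sample and 100%CT the last. ``n_points`` is configurable for
    testing only — downstream operations expect 101.
    """
    if n_points < 2:
        raise InputError("n_points must be >= 2")
    t0 = cycle.times[0]
    span = cycle.times[-1] - t0
    grid_times = t0 + np.arange(n_points) * (span / (n_points - 1))
    # guard against rounding pushing the last grid point past the data
    grid_times[-1] = cycle.times[-1]
    values = lagrange_resample(cycle.times, cycle.angles, grid_times)
    return NormalizedCurve(
        values=values,
        joint=cycle.joint,
        side=cycle.side,
        subject_id=cycle.subject_id,
        group=cycle.group,
        cycle_index=cycle.cycle_index,
    )


@dataclass(frozen=True)
class PairCheck:
    """Truthy/falsy result of a curve-pair validation with diagnostic."""

    ok: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.ok


def validate_pair(first: NormalizedCurve, second: NormalizedCurve) -> PairCheck:
    """Check that two curves are comparable for the symmetry function.

    Both must be 101-point curves of the same joint (the SF requires equal
    time bases). Returns a diagnostic rather than raising, so callers can
    surface the reason.
    """
    if first.values.size != 101 or second.values.size != 101:
        return PairCheck(
            False,
            f"curves must have 101 points, got {first.values.size} "
            f"and {second.values.size}",
        )
    if first.joint is not None and second.joint is not None and first.joint != second.joint:
        return PairCheck(
            False,
            f"joint mismatch: {first.joint.value} vs {second.joint.value}",
        )
    return PairCheck(True)
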