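"""Per-side angle-curve parameterization and the group summary table.

Angle curves are parameterized per cycle (Peak^min, t_min, Peak^max, t_max,
ROM), averaged within subject, then summarised as mean +/- SD across
subjects per (group, side, joint). That order — cycle -> subject -> group —
weights subjects equally regardless of how many cycles each contributed.

Peak times are averaged linearly in %GC. For peaks that sit near the cycle
boundary this can split mass between ~0 and ~100%GC; no circular averaging
is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError
from .gait_model import CurveParams, NormalizedCurve, SubjectSet
from .normalization import time_normalize
from .symmetry import parameterize

__all__ = ["angle_params", "subject_param_frame", "group_param_table"]


def angle_params(curve: NormalizedCurve) -> CurveParams:
    """Parameterize one angle curve (degrees / %GC).

    Shared implementation with SF-curve parameterization: extremes, their
    first-occurrence times, and ROM = Peak^max - Peak^min.
    """
    return parameterize(curve)


def subject_param_frame(subjects: SubjectSet) -> pd.DataFrame:
    """Per-subject mean curve parameters.

    Each cycle is time-normalized and parameterized; parameters are then
    averaged over that subject's cycles. One row per
    (group, subject_id, side, joint) with columns peak_min, t_min,
    peak_max, t_max, rom.
    """
    if len(subjects) == 0:
        raise InputError("empty subject set")
    rows = []
    for cycle in subjects:
        params = angle_params(time_normalize(cycle))
        rows.append(
            {
                "group": cycle.group.value,
                "subject_id": cycle.subject_id,
                "side": cycle.side.value,
                "joint": cycle.joint.value,
                "cycle_index": cycle.cycle_index,
                **params.as_dict(),
            }
        )
    per_cycle = pd.DataFrame(rows)
    return (
        per_cycle.groupby(["group", "subject_id", "side", "joint"], sort=False)[
            list(CurveParams.FIELDS)
        ]
        .mean()
        .reset_index()
    )


def group_param_table(subjects: SubjectSet) -> pd.DataFrame:
    """Group-level summary: mean +/- SD of curve parameters across subjects.

    Index is (joint, parameter); columns are a MultiIndex
    (group, side) x (mean, sd, n). SD is the unbiased sample SD across
    subjects; cells with a single subject get SD = NaN (n = 1 is visible in
    the n column), and absent (group, side, joint) cells are simply missing
    rather than zero-filled.
    """
    per_subject = subject_param_frame(subjects)
    long = per_subject.melt(
        id_vars=["group", "subject_id", "side", "joint"],
        value_vars=list(CurveParams.FIELDS),
        var_name="parameter",
    )
    table = (
        long.groupby(["joint", "parameter", "group", "side"], sort=False)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .unstack(["group", "side"])
    )
    # order columns (group, side, stat) for a Table-1-like layout
    table = table.reorder_levels([1, 2, 0], axis=1).sort_index(axis=1)
    joints = list(dict.fromkeys(long["joint"]))
    rows = pd.MultiIndex.from_product(
        [joints, CurveParams.FIELDS], names=["joint", "parameter"]
    )
    return table.reindex(rows)
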