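"""Ensemble curves, cohort-level SF aggregation and the statistical protocol.

Side comparisons (same subjects, both limbs) use paired t-tests; group
comparisons (independent cohorts) use Welch's two-sample t-test, chosen
over the pooled variant because patient groups typically show larger
waveform variability than controls. Each sample is screened with the
Shapiro-Wilk normality test; a failure flags the parametric result as
"assumption violated" but does not switch the test — the protocol is
parametric throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError, InsufficientDataError
from .gait_model import (
    CurveParams,
    Group,
    NormalizedCurve,
    SFCurve,
    Side,
    SubjectSet,
    canonical_sign_labels,
)
from .normalization import time_normalize
from .symmetry import SFResult, annotate_phases, classify_asymmetry, parameterize, symmetry_function

__all__ = [
    "EnsembleCurve",
    "ensemble",
    "compare_params",
    "CohortSF",
    "cohort_sf",
]


@dataclass(frozen=True)
class EnsembleCurve:
    """Pointwise mean and SD across curves, with the contributing count."""

    mean: np.ndarray
    sd: np.ndarray
    n: int
    joint: object = None

    def as_curve(self, **attrs) -> NormalizedCurve:
        return NormalizedCurve(values=self.mean, joint=self.joint, **attrs)


def ensemble(curves: list[NormalizedCurve]) -> EnsembleCurve:
    """Pointwise mean +/- SD over curves of the same joint and length.

    SD is the unbiased sample SD (ddof=1); a single curve yields SD = 0.
    """
    if not curves:
        raise InputError("cannot ensemble an empty list of curves")
    lengths = {c.values.size for c in curves}
    if len(lengths) != 1:
        raise InputError(f"curves differ in length: {sorted(lengths)}")
    joints = {c.joint for c in curves if c.joint is not None}
    if len(joints) > 1:
        raise InputError(f"curves mix joints: {sorted(j.value for j in joints)}")
    stack = np.stack([c.values for c in curves])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros_like(mean)
    return EnsembleCurve(mean=mean, sd=sd, n=stack.shape[0], joint=joints.pop() if joints else None)


def _t_report(x: np.ndarray, y: np.ndarray, paired: bool, alpha: float) -> dict:
    """One parametric comparison with normality screening.

    Zero-variance identical samples are reported as t=0, p=1 (scipy yields
    NaN for the 0/0 statistic).
    """
    def _shapiro_p(v: np.ndarray) -> float:
        # constant samples trip a scipy zero-range warning; short-circuit
        if np.ptp(v) == 0.0:
            return 1.0
        return float(stats.shapiro(v).pvalue)

    sw_x = _shapiro_p(x)
    sw_y = _shapiro_p(y)
    if paired:
        res = stats.ttest_rel(x, y)
    else:
        res = stats.ttest_ind(x, y, equal_var=False)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t) and np.isclose(np.mean(x) - np.mean(y), 0.0):
        t, p = 0.0, 1.0
    normal = bool(sw_x >= alpha and sw_y >= alpha)
    return {
        "test": "paired t" if paired else "Welch t",
        "statistic": t,
        "p_value": p,
        "significant": bool(p < alpha),
        "shapiro_p_first": sw_x,
        "shapiro_p_second": sw_y,
        "parametric_assumption_violated": not normal,
    }


def compare_params(
    a: list[CurveParams],
    b: list[CurveParams],
    paired: bool,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare two samples of curve parameters, one test per parameter.

    ``paired=True`` for side comparisons (both samples from the same
    subjects, matching order), ``paired=False`` for uTHR-vs-normal group
    comparisons (Welch). Returns one row per parameter with the test
    statistic, p-value, significance flag at ``alpha``, and Shapiro-Wilk
    screening results.
    """
    if len(a) < 3 or len(b) < 3:
        raise InsufficientSampleError(len(a), len(b))
    if paired and len(a) != len(b):
        raise InputError("paired comparison requires equal sample sizes")
    rows = {}
    for name in CurveParams.FIELDS:
        x = np.array([getattr(p, name) for p in a], dtype=float)
        y = np.array([getattr(p, name) for p in b], dtype=float)
        rows[name] = _t_report(x, y, paired, alpha)
    report = pd.DataFrame(rows).T
    report.index.name = "parameter"
    return report


class InsufficientSampleError(InsufficientDataError):
    def __init__(self, n_a: int, n_b: int):
        super().__init__(f"need >= 3 observations per sample, got {n_a} and {n_b}")


# ---------------------------------------------------------------------------
# Cohort-level SF
# ---------------------------------------------------------------------------


@dataclass
class CohortSF:
    """SF results for a cohort: per-subject results and the mean-curve SF.

    ``per_subject`` maps (joint, subject_id) to the SFResult of that
    subject's cycle-averaged SF curve; ``mean_curve`` maps joint to the SF
    of the ensemble-mean curves (the two aggregation modes the toolkit
    offers — their results differ, and neither is canonical).
    """

    mode: str
    per_subject: dict = field(default_factory=dict)
    mean_curve: dict = field(default_factory=dict)

    def subject_params(self, joint) -> list[CurveParams]:
        return [r.params for (j, _s), r in self.per_subject.items() if j == joint]


def _mean_sf_result(sf_curves: list[SFCurve], statistic: str) -> SFResult:
    stack = np.stack([c.values for c in sf_curves])
    mean = SFCurve(
        values=stack.mean(axis=0),
        first_label=sf_curves[0].first_label,
        second_label=sf_curves[0].second_label,
        joint=sf_curves[0].joint,
    )
    params = parameterize(mean)
    return annotate_phases(
        SFResult(
            curve=mean,
            params=params,
            classification=classify_asymmetry(params, statistic, curve=mean),
        )
    )


def _normalized_by_cycle(cycles: SubjectSet) -> dict[int, NormalizedCurve]:
    return {c.cycle_index: time_normalize(c) for c in cycles}


def cohort_sf(
    subjects: SubjectSet,
    mode: str,
    statistic: str = "peak_abs",
) -> CohortSF:
    """Run the SF pipeline over a cohort in one of the comparison modes.

    ``normal_LR`` compares right vs left within the normal group;
    ``uTHR_sides`` compares uninvolved vs involved within the uTHR group;
    ``uTHR_vs_normal`` compares the normal group's ensemble-mean reference
    curve against each uTHR subject's involved side.

    Per-subject results pair cycles by cycle_index, compute SF per cycle
    pair, average the SF curves within the subject, then parameterize.
    The mean-curve result computes a single SF between the ensemble means.
    """
    first_side, second_side = canonical_sign_labels(mode)
    out = CohortSF(mode=mode)
    if mode == "normal_LR":
        first_sel = dict(group=Group.NORMAL, side=first_side)
        second_sel = dict(group=Group.NORMAL, side=second_side)
    elif mode == "uTHR_sides":
        first_sel = dict(group=Group.UTHR, side=first_side)
        second_sel = dict(group=Group.UTHR, side=second_side)
    elif mode == "uTHR_vs_normal":
        first_sel = dict(group=Group.NORMAL)
        second_sel = dict(group=Group.UTHR, side=Side.INVOLVED)
    else:  # pragma: no cover - canonical_sign_labels already rejects
        raise ConfigurationError(f"unknown comparison mode {mode!r}")

    for joint in subjects.joints():
        second_set = subjects.select(joint=joint, **second_sel)
        if mode == "uTHR_vs_normal":
            # normative reference: ensemble mean over all normal-side curves
            ref_curves = [
                time_normalize(c) for c in subjects.select(joint=joint, **first_sel)
            ]
            if not ref_curves or len(second_set) == 0:
                continue
            reference = ensemble(ref_curves).as_curve(side=first_side)
            sf_per_subject = {}
            for sid in second_set.subjects():
                curves = [
                    time_normalize(c) for c in second_set.select(subject_id=sid)
                ]
                sfs = [
                    symmetry_function(
                        reference, c, "normal", second_side.value
                    )
                    for c in curves
                ]
                sf_per_subject[sid] = sfs
            involved_mean = ensemble(
                [time_normalize(c) for c in second_set]
            ).as_curve(side=Side.INVOLVED)
            mean_sf = symmetry_function(
                reference, involved_mean, "normal", second_side.value
            )
        else:
            first_set = subjects.select(joint=joint, **first_sel)
            if len(first_set) == 0 or len(second_set) == 0:
                continue
            sf_per_subject = {}
            for sid in first_set.subjects():
                firsts = _normalized_by_cycle(first_set.select(subject_id=sid))
                seconds = _normalized_by_cycle(second_set.select(subject_id=sid))
                shared = sorted(set(firsts) & set(seconds))
                if not shared:
                    continue
                sf_per_subject[sid] = [
                    symmetry_function(firsts[k], seconds[k]) for k in shared
                ]
            mean_first = ensemble([time_normalize(c) for c in first_set])
            mean_second = ensemble([time_normalize(c) for c in second_set])
            mean_sf = symmetry_function(
                mean_first.as_curve(side=first_side),
                mean_second.as_curve(side=second_side),
            )
        for sid, sfs in sf_per_subject.items():
            out.per_subject[(joint, sid)] = _mean_sf_result(sfs, statistic)
        params = parameterize(mean_sf)
        out.mean_curve[joint] = annotate_phases(
            SFResult(
                curve=mean_sf,
                params=params,
                classification=classify_asymmetry(params, statistic, curve=mean_sf),
            )
        )
    return out
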