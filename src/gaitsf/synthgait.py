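"""Synthetic bilateral sagittal-plane gait waveforms with known asymmetry.

Templates are truncated Fourier series over the gait cycle (periodic by
construction, <= 6 harmonics), calibrated so the default normal-group
shapes carry realistic ranges of motion for slow adult walking: hip
flexion-extension ~44 deg, knee flexion-extension ~57 deg, ankle
dorsi-plantar flexion ~32 deg, pelvic tilt ~1 deg (a literature-typical
~3 deg pelvis is available via ``pelvis_rom="typical"``).

Asymmetry is injected through four separable mechanisms applied to one
side: amplitude scaling about the template mean (so scale and offset
effects do not mix), a phase shift in %CT, a constant angular offset, and
additive white Gaussian measurement noise. Each mechanism has a closed-form
effect on the downstream symmetry function, which is what makes the whole
pipeline testable without motion-capture data.

The ``uTHR`` preset emulates the hallmark early post-operative pattern
after unilateral total hip replacement: strongly reduced hip range of
motion on both sides (more on the involved side), an elevated anterior
pelvic-tilt baseline with the two sides' pelvic waves in near antiphase,
and redistributed knee/ankle ranges. The ``normal`` preset produces
near-symmetric gait with small random side differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, InputError
from .gait_model import (
    AngleCycle,
    Group,
    Joint,
    NormalizedCurve,
    Side,
    SubjectSet,
    opposite_side,
)

__all__ = [
    "Harmonic",
    "TemplateSpec",
    "AsymmetrySpec",
    "render_template",
    "evaluate_template",
    "simulate_subject",
    "preset_cohort",
    "default_template",
]


@dataclass(frozen=True)
class Harmonic:
    """One Fourier component: amplitude * cos(2*pi*order*t/100 + phase)."""

    order: int
    amplitude: float  # degrees
    phase: float  # radians


@dataclass(frozen=True)
class TemplateSpec:
    """A noise-free periodic angle waveform for one joint."""

    joint: Joint
    harmonics: tuple[Harmonic, ...]
    baseline: float = 0.0  # degrees

    def __post_init__(self) -> None:
        object.__setattr__(self, "joint", Joint(self.joint))
        object.__setattr__(
            self, "harmonics", tuple(Harmonic(*h) if not isinstance(h, Harmonic) else h for h in self.harmonics)
        )
        if len(self.harmonics) < 1:
            raise InputError("template needs at least one harmonic")

    def scaled(self, amplitude_factor: float, baseline: float | None = None) -> "TemplateSpec":
        """Template with all harmonic amplitudes scaled (and optional new baseline)."""
        harmonics = tuple(
            Harmonic(h.order, h.amplitude * amplitude_factor, h.phase)
            for h in self.harmonics
        )
        return replace(
            self,
            harmonics=harmonics,
            baseline=self.baseline if baseline is None else baseline,
        )


@dataclass(frozen=True)
class AsymmetrySpec:
    """Transform applied to one side relative to the shared template.

    amplitude_scale is applied about the template mean (its baseline), so
    it changes range but not the mean; phase_shift is in %CT (positive =
    the affected side lags); offset is a constant added in degrees;
    noise_sd is the per-sample measurement noise applied to BOTH sides.
    """

    amplitude_scale: float = 1.0
    phase_shift: float = 0.0  # %CT
    offset: float = 0.0  # degrees
    noise_sd: float = 0.0  # degrees
    applied_side: Side = Side.INVOLVED

    def __post_init__(self) -> None:
        object.__setattr__(self, "applied_side", Side(self.applied_side))
        if self.amplitude_scale <= 0:
            raise InputError("amplitude_scale must be > 0")
        if abs(self.phase_shift) >= 50:
            raise InputError("|phase_shift| must be < 50 %CT")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")


def evaluate_template(spec: TemplateSpec, pct: np.ndarray) -> np.ndarray:
    """Evaluate the template at arbitrary %CT positions (periodic in 100)."""
    pct = np.asarray(pct, dtype=float)
    out = np.full(pct.shape, spec.baseline, dtype=float)
    for h in spec.harmonics:
        out += h.amplitude * np.cos(2.0 * np.pi * h.order * pct / 100.0 + h.phase)
    return out


def render_template(spec: TemplateSpec, n_points: int = 101) -> NormalizedCurve:
    """Deterministic 101-point evaluation of the template on the %CT grid."""
    pct = np.linspace(0.0, 100.0, n_points)
    return NormalizedCurve(values=evaluate_template(spec, pct), joint=spec.joint)


def _phase_peak(order: int, t_peak_pct: float) -> float:
    """Phase (radians) placing a harmonic's maximum at t_peak_pct."""
    return -2.0 * np.pi * order * t_peak_pct / 100.0


def default_template(joint: Joint | str, pelvis_rom: str = "printed") -> TemplateSpec:
    """Normal-group template for a joint.

    ``pelvis_rom="printed"`` keeps the ~1 deg pelvic tilt range the
    calibration targets prescribe; ``"typical"`` switches to a
    literature-typical ~3 deg range.
    """
    joint = Joint(joint)
    if joint == Joint.PELVIS:
        amp = 0.5 if pelvis_rom == "printed" else 1.5
        if pelvis_rom not in ("printed", "typical"):
            raise ConfigurationError(f"unknown pelvis_rom {pelvis_rom!r}")
        # double oscillation per stride, peaks near each initial contact
        return TemplateSpec(
            joint,
            (Harmonic(2, amp, _phase_peak(2, 1.0)),),
            baseline=7.35,
        )
    if joint == Joint.HIP:
        return TemplateSpec(
            joint,
            (
                Harmonic(1, 21.0, _phase_peak(1, 92.0)),
                Harmonic(2, 2.5, _phase_peak(2, 40.0)),
            ),
            baseline=12.1,
        )
    if joint == Joint.KNEE:
        return TemplateSpec(
            joint,
            (
                Harmonic(1, 25.0, _phase_peak(1, 72.0)),
                Harmonic(2, 10.0, _phase_peak(2, 14.0)),
            ),
            baseline=30.0,
        )
    if joint == Joint.ANKLE:
        return TemplateSpec(
            joint,
            (
                Harmonic(1, 10.0, _phase_peak(1, 40.0)),
                Harmonic(2, 7.0, _phase_peak(2, 47.0)),
            ),
            baseline=-4.0,
        )
    raise ConfigurationError(f"no template for joint {joint!r}")  # pragma: no cover


def simulate_subject(
    template: TemplateSpec,
    asym: AsymmetrySpec,
    n_cycles: int,
    seed: int | np.random.Generator,
    *,
    subject_id: str = "S000",
    group: Group | str = Group.NORMAL,
    cycle_duration: float = 1.1,
    sampling_hz: float = 120.0,
    n_samples: int | None = None,
) -> list[tuple[AngleCycle, AngleCycle]]:
    """Simulate paired cycles for one subject and one joint.

    Returns ``n_cycles`` pairs ``(baseline_side, affected_side)``: the
    baseline side is the template plus measurement noise, the affected side
    (``asym.applied_side``) is the template scaled about its mean, shifted
    by ``phase_shift`` and offset by ``offset``, plus noise. Identical seed
    -> identical output.

    ``n_samples`` overrides the 120 Hz sampling with an exact count of
    evenly spaced samples spanning the cycle (e.g. 201 samples over a 1 s
    cycle puts every 1%CT grid node on a sample, making downstream
    interpolation node-exact for oracle checks).
    """
    if n_cycles < 1:
        raise InputError("n_cycles must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    group = Group(group)
    affected = asym.applied_side
    base_side = opposite_side(affected)
    if n_samples is None:
        n_samples = int(np.floor(cycle_duration * sampling_hz)) + 1
        times = np.arange(n_samples) / sampling_hz
    else:
        times = np.arange(n_samples) * (cycle_duration / (n_samples - 1))
    pct = (times - times[0]) / (times[-1] - times[0]) * 100.0

    base_clean = evaluate_template(template, pct)
    shifted = evaluate_template(template, pct - asym.phase_shift)
    affected_clean = (
        asym.amplitude_scale * (shifted - template.baseline)
        + template.baseline
        + asym.offset
    )

    pairs = []
    for k in range(n_cycles):
        noise_b = rng.normal(0.0, asym.noise_sd, size=pct.size) if asym.noise_sd else 0.0
        noise_a = rng.normal(0.0, asym.noise_sd, size=pct.size) if asym.noise_sd else 0.0
        pairs.append(
            (
                AngleCycle(
                    subject_id=subject_id,
                    group=group,
                    side=base_side,
                    joint=template.joint,
                    times=times,
                    angles=base_clean + noise_b,
                    cycle_index=k,
                ),
                AngleCycle(
                    subject_id=subject_id,
                    group=group,
                    side=affected,
                    joint=template.joint,
                    times=times,
                    angles=affected_clean + noise_a,
                    cycle_index=k,
                ),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Preset cohorts
# ---------------------------------------------------------------------------

# Per-joint preset parameters. Means target the calibration magnitudes
# described in the module docstring; SDs are the documented between-subject
# jitter. Template entries modify the normal template (amplitude factor,
# baseline); asym entries are the means of the AsymmetrySpec fields.
_NORMAL_PRESET = {
    Joint.PELVIS: dict(
        tmpl_scale=1.0, tmpl_baseline=None,
        scale=1.0, scale_sd=0.01, shift=0.0, shift_sd=0.3,
        offset=0.0, offset_sd=0.02, noise=0.01,
    ),
    Joint.HIP: dict(
        tmpl_scale=1.0, tmpl_baseline=None,
        scale=1.0, scale_sd=0.015, shift=0.0, shift_sd=0.5,
        offset=0.0, offset_sd=0.3, noise=0.25,
    ),
    Joint.KNEE: dict(
        tmpl_scale=1.0, tmpl_baseline=None,
        scale=1.0, scale_sd=0.015, shift=0.0, shift_sd=0.5,
        offset=0.0, offset_sd=0.4, noise=0.3,
    ),
    Joint.ANKLE: dict(
        tmpl_scale=1.0, tmpl_baseline=None,
        scale=1.0, scale_sd=0.015, shift=0.0, shift_sd=0.5,
        offset=0.0, offset_sd=0.25, noise=0.2,
    ),
}

# uTHR preset: the uninvolved side is the (rescaled) template, the involved
# side carries the AsymmetrySpec. Hip ROM targets 19.0 deg uninvolved vs
# 12.6 deg involved; pelvis gains ~+9.5 deg baseline, ~4.8 deg ROM and a
# near-antiphase (~49 %CT) shift between sides; knee and ankle ranges are
# larger on the involved side (46.1 vs 34.2 and 40.0 vs 29.6 deg).
_UTHR_PRESET = {
    Joint.PELVIS: dict(
        tmpl_override=lambda: TemplateSpec(
            Joint.PELVIS,
            (Harmonic(1, 2.35, _phase_peak(1, 58.0)),),
            baseline=16.4,
        ),
        tmpl_scale=1.0, tmpl_baseline=None,
        scale=1.02, scale_sd=0.03, shift=-49.0, shift_sd=0.5,
        offset=0.3, offset_sd=0.15, noise=0.05,
    ),
    Joint.HIP: dict(
        tmpl_scale=19.0 / 44.0, tmpl_baseline=31.0,
        scale=12.6 / 19.0, scale_sd=0.04, shift=16.0, shift_sd=2.0,
        offset=2.5, offset_sd=0.8, noise=0.25,
    ),
    Joint.KNEE: dict(
        tmpl_scale=34.2 / 57.0, tmpl_baseline=34.9,
        scale=46.1 / 34.2, scale_sd=0.05, shift=-2.0, shift_sd=1.0,
        offset=-0.5, offset_sd=0.5, noise=0.3,
    ),
    Joint.ANKLE: dict(
        tmpl_scale=29.6 / 32.0, tmpl_baseline=2.6,
        scale=40.0 / 29.6, scale_sd=0.05, shift=3.0, shift_sd=1.5,
        offset=-3.0, offset_sd=0.5, noise=0.25,
    ),
}

#: Between-subject coefficient of variation on template amplitudes.
_SUBJECT_AMPLITUDE_CV = 0.05


def preset_cohort(
    name: str,
    n_subjects: int,
    seed: int,
    *,
    n_cycles: int = 9,
    pelvis_rom: str = "printed",
    cycle_duration: float = 1.1,
    sampling_hz: float = 120.0,
) -> SubjectSet:
    """Generate a cohort from the ``normal`` or ``uTHR`` preset.

    Each subject gets all four sagittal-plane joints, ``n_cycles`` cycles
    per side (default 9, emulating 3 trials x 3 cycles). Subject-level
    jitter: template amplitudes vary with a 5% CV, and each AsymmetrySpec
    field is drawn around its preset mean with the documented SD.
    Reproducible under ``seed``.
    """
    if n_subjects < 1:
        raise InputError("n_subjects must be >= 1")
    if name == "normal":
        preset, group = _NORMAL_PRESET, Group.NORMAL
        sides = (Side.RIGHT, Side.LEFT)  # affected = left
    elif name == "uTHR":
        preset, group = _UTHR_PRESET, Group.UTHR
        sides = (Side.UNINVOLVED, Side.INVOLVED)
    else:
        raise ConfigurationError(f"unknown preset {name!r}; expected 'normal' or 'uTHR'")
    rng = np.random.default_rng(seed)
    out = SubjectSet()
    for s in range(n_subjects):
        subject_id = f"{name}{s + 1:02d}"
        for joint, cfg in preset.items():
            if "tmpl_override" in cfg:
                template = cfg["tmpl_override"]()
            else:
                template = default_template(joint, pelvis_rom=pelvis_rom)
            template = template.scaled(
                cfg["tmpl_scale"] * rng.normal(1.0, _SUBJECT_AMPLITUDE_CV),
                baseline=cfg["tmpl_baseline"],
            )
            asym = AsymmetrySpec(
                amplitude_scale=max(cfg["scale"] + rng.normal(0.0, cfg["scale_sd"]), 0.05),
                phase_shift=float(
                    np.clip(cfg["shift"] + rng.normal(0.0, cfg["shift_sd"]), -49.9, 49.9)
                ),
                offset=cfg["offset"] + rng.normal(0.0, cfg["offset_sd"]),
                noise_sd=cfg["noise"],
                applied_side=sides[1],
            )
            pairs = simulate_subject(
                template,
                asym,
                n_cycles,
                rng,
                subject_id=subject_id,
                group=group,
                cycle_duration=cycle_duration,
                sampling_hz=sampling_hz,
            )
            for base, affected in pairs:
                out.add(base)
                out.add(affected)
    return out
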