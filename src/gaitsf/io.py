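"""Long-format CSV ingestion and report writing.

The interchange format is a tidy CSV with one row per sample:
``subject_id, group, side, joint, cycle_index`` plus either
``time_s, angle_deg`` (raw cycles) or ``pct_ct, angle_deg`` (pre-normalized
curves). All files are UTF-8 with '.' decimal separators and '\\n' line
endings; numeric fields round-trip at full precision (repr formatting).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, SchemaError
from .gait_model import (
    AngleCycle,
    Group,
    Joint,
    NormalizedCurve,
    Side,
    SubjectSet,
)
from .group_stats import CohortSF
from .normalization import lagrange_resample

logger = logging.getLogger("gaitsf")

__all__ = ["read_cycles", "write_cycles", "write_report"]

_KEY_COLUMNS = ["subject_id", "group", "side", "joint", "cycle_index"]


def write_cycles(subjects: SubjectSet, path: str | Path) -> None:
    """Write a SubjectSet as the long-format CSV."""
    subjects.to_frame().to_csv(path, index=False, lineterminator="\n")


def _validate_schema(df: pd.DataFrame, path) -> str:
    missing = [c for c in _KEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    if "angle_deg" not in df.columns:
        raise SchemaError(f"{path}: missing column(s) angle_deg")
    if "time_s" in df.columns:
        axis = "time_s"
    elif "pct_ct" in df.columns:
        axis = "pct_ct"
    else:
        raise SchemaError(f"{path}: need either a time_s or a pct_ct column")
    bad = df.index[pd.to_numeric(df["angle_deg"], errors="coerce").isna()]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:5])  # 1-based incl. header
        raise SchemaError(f"{path}: non-numeric angle_deg at row(s) {rows}")
    dup = df.duplicated(subset=_KEY_COLUMNS + [axis])
    if dup.any():
        rows = ", ".join(str(i + 2) for i in df.index[dup][:5])
        raise SchemaError(f"{path}: duplicated (subject, side, joint, cycle, {axis}) key at row(s) {rows}")
    return axis


def read_cycles(path: str | Path) -> SubjectSet:
    """Read the long-format CSV into a SubjectSet.

    ``time_s`` input yields raw AngleCycles for later normalization.
    ``pct_ct`` input must supply the exact 0..100 integer grid per cycle;
    anything else is accepted with a warning, and the cycle is treated as a
    raw trace on the %CT axis (it will be re-normalized downstream). For
    uniformity both variants are returned as AngleCycles — for pct_ct input
    the "time" axis is %CT/100 seconds, which normalization maps back onto
    the canonical grid.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    axis = _validate_schema(df, path)
    out = SubjectSet()
    for key, sub in df.groupby(_KEY_COLUMNS, sort=False):
        subject_id, group, side, joint, cycle_index = key
        sub = sub.sort_values(axis)
        t = sub[axis].to_numpy(dtype=float)
        y = sub["angle_deg"].to_numpy(dtype=float)
        if axis == "pct_ct" and not (
            t.size == 101 and np.array_equal(t, np.arange(101.0))
        ):
            logger.warning(
                "subject %s %s %s cycle %s: pct_ct not the 0..100 integer grid "
                "(%d points); will be re-normalized",
                subject_id, side, joint, cycle_index, t.size,
            )
        if axis == "pct_ct":
            t = t / 100.0
        try:
            out.add(
                AngleCycle(
                    subject_id=str(subject_id),
                    group=Group(group),
                    side=Side(side),
                    joint=Joint(joint),
                    times=t,
                    angles=y,
                    cycle_index=int(cycle_index),
                )
            )
        except (InputError, ValueError) as exc:
            raise SchemaError(
                f"{path}: invalid cycle {key}: {exc}"
            ) from exc
    logger.info("read %d cycles (%d subjects) from %s", len(out), len(out.subjects()), path)
    return out


def _sf_frame(result) -> pd.DataFrame:
    return pd.DataFrame(
        {"pct_ct": result.curve.grid, "sf_percent": result.curve.values}
    )


def write_report(results: CohortSF, out_dir: str | Path, plots: bool = True) -> list[Path]:
    """Write per-joint SF curve CSVs, a params CSV, summary JSON and plots.

    Raises InputError on an empty result set (no partial files are
    written). Returns the list of files written.
    """
    if not results.mean_curve:
        raise InputError("empty result set; nothing to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    param_rows = []
    summary = {"mode": results.mode, "joints": {}}
    for joint, res in results.mean_curve.items():
        short = joint.value.split("_")[0]
        sf_path = out_dir / f"sf_{short}.csv"
        _sf_frame(res).to_csv(sf_path, index=False, lineterminator="\n")
        written.append(sf_path)
        row = {"joint": joint.value, "scope": "mean_curve", **res.params.as_dict()}
        param_rows.append(row)
        summary["joints"][joint.value] = {
            "sign_convention": f"{res.curve.first_label} - {res.curve.second_label}",
            "classification": res.classification,
            "peak_min": res.params.peak_min,
            "t_min_pct": res.params.t_min,
            "phase_at_min": res.peak_phases[0].name,
            "ic_at_min": res.peak_phases[0].ic,
            "peak_max": res.params.peak_max,
            "t_max_pct": res.params.t_max,
            "phase_at_max": res.peak_phases[1].name,
            "ic_at_max": res.peak_phases[1].ic,
            "rom": res.params.rom,
        }
    for (joint, sid), res in results.per_subject.items():
        param_rows.append(
            {
                "joint": joint.value,
                "scope": sid,
                **res.params.as_dict(),
                "classification": res.classification,
            }
        )
    params_path = out_dir / "params.csv"
    pd.DataFrame(param_rows).to_csv(params_path, index=False, lineterminator="\n")
    written.append(params_path)

    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2) + "\n")
    written.append(summary_path)

    if plots:
        written.extend(_plot_sf(results, out_dir))
    logger.info("wrote %d report files to %s", len(written), out_dir)
    return written


def _plot_sf(results: CohortSF, out_dir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for joint, res in results.mean_curve.items():
        fig, ax = plt.subplots(figsize=(6, 3.2))
        subject_curves = [
            r.curve.values
            for (j, _s), r in results.per_subject.items()
            if j == joint
        ]
        for vals in subject_curves:
            ax.plot(res.curve.grid, vals, color="0.8", lw=0.6)
        ax.plot(res.curve.grid, res.curve.values, color="C0", lw=1.8,
                label=f"{res.curve.first_label} - {res.curve.second_label}")
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("% cycle time")
        ax.set_ylabel("SF (%)")
        ax.set_title(joint.value)
        ax.legend(loc="best", fontsize=8)
        fig.tight_layout()
        path = out_dir / f"sf_{joint.value.split('_')[0]}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written
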