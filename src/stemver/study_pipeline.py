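"""End-to-end validation study on synthetic cohorts.

Reproduces the structure of a radiographic validation study of the
transverse-version reconstruction: a virtual cohort is drawn, each hip is
"measured" on an orthogonal and a non-orthogonal image series with manual
noise, the transverse version is calculated from the coronal and sagittal
angles on each series, and agreement statistics are computed for

* the **orthogonal** comparison — manually measured TV vs TV calculated
  from the manually measured (CI, SI) on the same orthogonal images; and
* the **non-orthogonal** comparison — calculated TV from the orthogonal
  series vs calculated TV from a series whose sagittal plane is misaligned
  by ``delta`` degrees (85-degree biplanar acquisition for delta = 5).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement_stats import AgreementReport, agreement_report
from .synthetic_cohort import (
    Cohort,
    CohortSpec,
    NoiseModel,
    apply_noise,
    calibrate_noise,
    sample_orientations,
)
from .trig_core import DEGENERACY_TOL_DEG, PlaneMisalignment, tv_from_ci_si

__all__ = [
    "StudyConfig",
    "StudyReport",
    "convert_table",
    "run_validation_study",
    "summarize_angles",
    "load_config",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of one validation-study run.

    Either ``sigma`` (explicit noise SD, degrees) or ``noise_target`` (a
    median absolute manual-vs-calculated TV difference to calibrate sigma
    against; 1.3 degrees by default) controls measurement noise; ``sigma``
    wins when both are set.
    """

    cohort: CohortSpec
    noise_target: float = 1.3
    sigma: float | None = None
    delta: float = 5.0
    replicates: int = 1
    outdir: Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        PlaneMisalignment(self.delta)  # range check
        if self.outdir is not None:
            object.__setattr__(self, "outdir", Path(self.outdir))


@dataclass
class StudyReport:
    """Per-replicate agreement reports plus cohort angle summaries."""

    orthogonal: list[AgreementReport]
    nonorthogonal: list[AgreementReport]
    angle_summaries: pd.DataFrame
    sigma: float
    config: StudyConfig

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for series, reports in (
            ("manual_vs_calculated", self.orthogonal),
            ("orthogonal_vs_nonorthogonal_calculated", self.nonorthogonal),
        ):
            for i, r in enumerate(reports):
                rows.append(
                    {
                        "replicate": i,
                        "series": series,
                        "icc": r.icc,
                        "icc_ci_low": r.icc_ci_low,
                        "icc_ci_high": r.icc_ci_high,
                        "bias": r.bias,
                        "loa_low": r.loa_low,
                        "loa_high": r.loa_high,
                        "median_abs_diff": r.median_abs_diff,
                        "mad_iqr_low": r.mad_iqr_low,
                        "mad_iqr_high": r.mad_iqr_high,
                        "n": r.n,
                    }
                )
        return pd.DataFrame(rows)


def convert_table(angles: pd.DataFrame) -> pd.DataFrame:
    """Append the calculated transverse version to a table of coronal and
    sagittal angles.

    Expects columns ``ci_deg`` and ``si_deg`` (degrees).  Valid rows get
    ``tv_deg`` and status ``"ok"``; rows whose angles fall on/outside the
    open working domains are flagged in the ``status`` column and get no
    value — never a silently wrong number.
    """
    for col in ("ci_deg", "si_deg"):
        if col not in angles.columns:
            raise ValueError(f"missing required column {col!r}")
    out = angles.copy()
    ci = pd.to_numeric(out["ci_deg"], errors="coerce").to_numpy(dtype=float)
    si = pd.to_numeric(out["si_deg"], errors="coerce").to_numpy(dtype=float)

    tol = DEGENERACY_TOL_DEG
    status = np.full(len(out), "ok", dtype=object)
    status[~np.isfinite(ci) | ~np.isfinite(si)] = "invalid: non-numeric angle"
    finite = np.isfinite(ci) & np.isfinite(si)
    bad_ci = finite & ((ci <= tol) | (ci >= 90.0 - tol))
    status[bad_ci] = "degenerate: ci outside open (0, 90) deg"
    bad_si = finite & ~bad_ci & ((si <= -90.0 + tol) | (si >= 90.0 - tol))
    status[bad_si] = "degenerate: si outside open (-90, 90) deg"

    ok = status == "ok"
    tv = np.full(len(out), np.nan)
    if np.any(ok):
        tv[ok] = tv_from_ci_si(ci[ok], si[ok])
    out["tv_deg"] = tv
    out["status"] = status
    n_flagged = int((~ok).sum())
    if n_flagged:
        logger.warning("%d row(s) flagged as degenerate/invalid", n_flagged)
    return out


def summarize_angles(cohort: Cohort | pd.DataFrame) -> pd.DataFrame:
    """Mean, sample SD and range per angle column, in degrees.

    Mirrors the ``mean +/- SD (range)`` presentation of cohort tables;
    values are kept at full precision here and rounded only for display.
    """
    df = cohort.frame if isinstance(cohort, Cohort) else cohort
    cols = [c for c in df.columns if c != "hip_id" and pd.api.types.is_numeric_dtype(df[c])]
    if df.empty or not cols:
        raise ValueError("empty cohort")
    rows = {}
    for c in cols:
        v = df[c].to_numpy(dtype=float)
        rows[c] = {
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            "min": float(np.min(v)),
            "max": float(np.max(v)),
        }
    return pd.DataFrame(rows).T[["mean", "sd", "min", "max"]]


def run_validation_study(config: StudyConfig) -> StudyReport:
    """Simulate the full validation study and return agreement reports.

    Deterministic for a fixed ``config.seed``; replicates use derived
    seeds.  When ``config.outdir`` is set, writes ``study_report.csv``,
    ``angle_summaries.csv`` and a ``study.log`` recording every parameter.
    """
    if config.sigma is not None:
        sigma = config.sigma
    elif config.noise_target == 0:
        sigma = 0.0
    else:
        cal_spec = dataclasses.replace(config.cohort, seed=(config.seed + 77) % 2**31)
        sigma = calibrate_noise(cal_spec, config.noise_target).sigma

    mis = PlaneMisalignment(config.delta)
    orth_reports: list[AgreementReport] = []
    non_reports: list[AgreementReport] = []
    summaries = None
    for rep in range(config.replicates):
        seed_r = (config.seed + 104729 * rep) % 2**31
        spec_r = dataclasses.replace(config.cohort, seed=seed_r)
        cohort = sample_orientations(spec_r)
        noisy = apply_noise(cohort, NoiseModel(sigma=sigma, seed=(seed_r + 500009) % 2**31), mis)
        df = noisy.frame

        calc_orth = tv_from_ci_si(df["ci_meas"].to_numpy(), df["si_meas"].to_numpy())
        manual = df["tv_meas"].to_numpy()
        orth_reports.append(agreement_report(manual, calc_orth, model="mixed"))

        calc_non = tv_from_ci_si(
            df["ci_nonorth_meas"].to_numpy(), df["si_nonorth_meas"].to_numpy()
        )
        non_reports.append(agreement_report(calc_orth, calc_non, model="mixed"))

        if rep == 0:
            df = df.assign(tv_calc=calc_orth, tv_nonorth_calc=calc_non)
            summaries = summarize_angles(df)

    report = StudyReport(
        orthogonal=orth_reports,
        nonorthogonal=non_reports,
        angle_summaries=summaries,
        sigma=sigma,
        config=config,
    )

    logger.info(
        "validation study: version=%s seed=%d n=%d sigma=%.4f delta=%.2f replicates=%d",
        __version__,
        config.seed,
        config.cohort.n,
        sigma,
        config.delta,
        config.replicates,
    )
    if config.outdir is not None:
        config.outdir.mkdir(parents=True, exist_ok=True)
        report.to_frame().to_csv(config.outdir / "study_report.csv", index=False)
        summaries.to_csv(config.outdir / "angle_summaries.csv")
        with open(config.outdir / "study.log", "w", encoding="utf-8") as fh:
            fh.write(f"stemver {__version__}\n")
            fh.write(f"seed = {config.seed}\n")
            fh.write(f"sigma = {sigma}\n")
            fh.write(f"delta = {config.delta}\n")
            fh.write(f"replicates = {config.replicates}\n")
            for k, v in dataclasses.asdict(config.cohort).items():
                fh.write(f"cohort.{k} = {v}\n")
    return report


def load_config(path) -> dict[str, str]:
    """Read a plain ``key = value`` configuration file.

    Blank lines and ``#`` comments are ignored; keys mirror the CLI flags
    (e.g. ``n = 10000``, ``delta = 5``).  Values are returned as strings;
    the CLI coerces and lets explicit flags override.
    """
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out
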