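"""Batch validation records and replicate summaries.

One :class:`ValidationRecord` per predicted profile collects everything the
comparison against the experimental profile yields: similarity factors and
verdict, the Higuchi and Korsmeyer-Peppas window fits, and the slope /
intercept comparison p-values — with the convention that an intercept
p-value is reported as NA whenever the slope test already rejects, and that
profiles with fewer than four points in the 20-60 % release window are
flagged excluded with all kinetic fields NA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .kinetics import (
    KineticFit,
    ProfileExcluded,
    compare_regressions,
    fit_higuchi,
    fit_korsmeyer_peppas,
)
from .profile_metrics import DissolutionProfile, SimilarityResult, compare_profiles

__all__ = [
    "ValidationRecord",
    "ReplicateSummary",
    "run_validation",
    "summarize_replicates",
    "records_to_dataframe",
    "write_records_csv",
    "NA",
]

NA = "NA"

# Table-style column order for serialised records.
REPORT_COLUMNS = [
    "matrix",
    "desirability",
    "f1",
    "f2",
    "similar",
    "higuchi_slope",
    "higuchi_intercept",
    "higuchi_r2",
    "higuchi_adjusted_r2",
    "kp_slope",
    "kp_intercept",
    "kp_r2",
    "kp_adjusted_r2",
    "higuchi_p_slope",
    "higuchi_p_intercept",
    "kp_p_slope",
    "kp_p_intercept",
    "excluded",
    "exclusion_reason",
]


@dataclass
class ValidationRecord:
    """One row of the validation report for a single predicted profile."""

    label: str
    desirability: float | None = None
    similarity: SimilarityResult | None = None
    higuchi: KineticFit | None = None
    korsmeyer_peppas: KineticFit | None = None
    higuchi_comparison: object | None = None
    kp_comparison: object | None = None
    excluded: bool = False
    exclusion_reason: str = ""
    error: str = ""

    def to_row(self) -> dict:
        def fit_fields(prefix: str, fit: KineticFit | None, comp) -> dict:
            if fit is None:
                return {
                    f"{prefix}_slope": NA,
                    f"{prefix}_intercept": NA,
                    f"{prefix}_r2": NA,
                    f"{prefix}_adjusted_r2": NA,
                    f"{prefix}_p_slope": NA,
                    f"{prefix}_p_intercept": NA,
                }
            row = {
                f"{prefix}_slope": fit.slope,
                f"{prefix}_intercept": fit.intercept,
                f"{prefix}_r2": fit.r2,
                f"{prefix}_adjusted_r2": fit.adjusted_r2,
                f"{prefix}_p_slope": NA,
                f"{prefix}_p_intercept": NA,
            }
            if comp is not None:
                row[f"{prefix}_p_slope"] = comp.p_slope
                row[f"{prefix}_p_intercept"] = (
                    comp.p_intercept if comp.p_intercept is not None else NA
                )
            return row

        row = {
            "matrix": self.label,
            "desirability": self.desirability if self.desirability is not None else NA,
            "f1": self.similarity.f1 if self.similarity else NA,
            "f2": self.similarity.f2 if self.similarity else NA,
            "similar": self.similarity.verdict if self.similarity else NA,
        }
        row.update(fit_fields("higuchi", self.higuchi, self.higuchi_comparison))
        row.update(fit_fields("kp", self.korsmeyer_peppas, self.kp_comparison))
        row["excluded"] = self.excluded
        row["exclusion_reason"] = self.exclusion_reason or (self.error or "")
        return row


@dataclass
class ReplicateSummary:
    """Pointwise mean and sample SD of replicate profiles (x-bar +/- SD)."""

    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "mean_released_pct": self.mean,
                "sd_released_pct": self.sd,
            }
        )


def run_validation(
    experimental: DissolutionProfile,
    predictions: Sequence[DissolutionProfile],
    desirabilities: Sequence[float | None] | None = None,
    t_max: float = 720.0,
    release_cut: float = 99.5,
    window: tuple[float, float] = (20.0, 60.0),
    alpha: float = 0.05,
) -> list[ValidationRecord]:
    """Validate each predicted profile against the experimental one.

    Per prediction: common-grid point selection and f1/f2 with verdict, then
    the two kinetic window fits and the slope/elevation comparisons against
    the experimental fits.  Per-prediction failures are recorded in the
    record's ``error`` field rather than aborting the batch.
    """
    if desirabilities is None:
        desirabilities = [None] * len(predictions)
    lo, hi = window
    try:
        ref_hig = fit_higuchi(experimental, lo, hi)
        ref_kp = fit_korsmeyer_peppas(experimental, lo, hi)
    except ProfileExcluded as exc:
        raise ValueError(
            f"experimental profile unusable for kinetic analysis: {exc}"
        ) from exc

    records: list[ValidationRecord] = []
    for pred, desirability in zip(predictions, desirabilities):
        rec = ValidationRecord(label=pred.label, desirability=desirability)
        try:
            rec.similarity = compare_profiles(
                experimental, pred, t_max=t_max, release_cut=release_cut
            )
        except Exception as exc:  # per-prediction failure is not fatal
            rec.error = f"similarity failed: {exc}"
            records.append(rec)
            continue
        try:
            rec.higuchi = fit_higuchi(pred, lo, hi)
            rec.korsmeyer_peppas = fit_korsmeyer_peppas(pred, lo, hi)
            rec.higuchi_comparison = compare_regressions(rec.higuchi, ref_hig, alpha)
            rec.kp_comparison = compare_regressions(rec.korsmeyer_peppas, ref_kp, alpha)
        except ProfileExcluded as exc:
            rec.excluded = True
            rec.exclusion_reason = str(exc)
            rec.higuchi = rec.korsmeyer_peppas = None
        except Exception as exc:
            rec.error = f"kinetics failed: {exc}"
        records.append(rec)
    return records


def summarize_replicates(profiles: Sequence[DissolutionProfile]) -> ReplicateSummary:
    """Pointwise mean and sample standard deviation across replicates.

    All profiles must share one time grid.  With a single replicate the SD
    is NaN (rendered NA).
    """
    if not profiles:
        raise ValueError("at least one profile required")
    times = profiles[0].times
    for p in profiles[1:]:
        if p.times.size != times.size or not np.array_equal(p.times, times):
            raise ValueError(
                f"replicate {p.label or '<unlabelled>'} has a mismatched time grid"
            )
    data = np.vstack([p.released for p in profiles])
    mean = data.mean(axis=0)
    sd = (
        data.std(axis=0, ddof=1)
        if len(profiles) > 1
        else np.full(times.size, np.nan)
    )
    return ReplicateSummary(times=times, mean=mean, sd=sd, n=len(profiles))


def records_to_dataframe(records: Sequence[ValidationRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.to_row() for r in records])
    return df[REPORT_COLUMNS]


def write_records_csv(records: Sequence[ValidationRecord], path: str | Path) -> Path:
    """Serialise records with the literal string ``NA`` for absent values."""
    df = records_to_dataframe(records)
    df.to_csv(path, index=False, na_rep=NA)
    return Path(path)
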