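"""Dissolution profile similarity: point selection, f1/f2 factors, verdicts.

The difference factor f1 and similarity factor f2 are the regulatory
standard for pairwise comparison of cumulative-release profiles:

    f1 = 100 x sum |R_t - T_t| / sum R_t
    f2 = 50 x log10( 100 / sqrt(1 + (1/n) sum (R_t - T_t)^2) )

with R_t the reference (experimental) and T_t the test (predicted) percent
released at common sampling times.  Identical profiles give f1 = 0 and
f2 = 100; the conventional similarity verdict requires f1 < 15 and f2 > 50.

Points are selected on a shared time grid up to 12 h or up to complete
release of the reference, whichever comes first; no interpolation is
performed — mismatched grids are a user error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DissolutionProfile",
    "SimilarityResult",
    "GridMismatchError",
    "read_profile_csv",
    "write_profile_csv",
    "select_points",
    "f1",
    "f2",
    "similarity_verdict",
    "compare_profiles",
]


class GridMismatchError(ValueError):
    """The two profiles do not share the required common time grid."""


@dataclass
class DissolutionProfile:
    """Cumulative drug release over time.

    ``times`` in minutes, strictly increasing; ``released`` in percent of
    the total API content.
    """

    times: np.ndarray
    released: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.released = np.asarray(self.released, dtype=float)
        if self.times.ndim != 1 or self.times.size < 1:
            raise ValueError("profile needs at least one time point")
        if self.times.size != self.released.size:
            raise ValueError("times and released must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.released < 0):
            raise ValueError("released values must be nonnegative")

    def __len__(self) -> int:
        return int(self.times.size)


def read_profile_csv(path: str | Path, label: str | None = None) -> DissolutionProfile:
    """Read a two-column profile CSV (``time_min``, ``released_pct``)."""
    df = pd.read_csv(path)
    missing = {"time_min", "released_pct"} - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing columns {sorted(missing)}")
    return DissolutionProfile(
        times=df["time_min"].to_numpy(),
        released=df["released_pct"].to_numpy(),
        label=label if label is not None else Path(path).stem,
    )


def write_profile_csv(profile: DissolutionProfile, path: str | Path) -> Path:
    pd.DataFrame(
        {"time_min": profile.times, "released_pct": profile.released}
    ).to_csv(path, index=False)
    return Path(path)


@dataclass
class SimilarityResult:
    f1: float
    f2: float
    n_points: int
    truncation_time: float
    verdict: bool
    limits: tuple[float, float] = field(default=(15.0, 50.0))


def select_points(
    ref: DissolutionProfile,
    test: DissolutionProfile,
    t_max: float = 720.0,
    release_cut: float = 99.5,
    include_t0: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pair reference and test releases on the common grid up to truncation.

    The window ends at ``t_max`` (default 12 h) or at the first reference
    point reaching ``release_cut`` percent (that point included), whichever
    is earlier.  The ``t = 0`` sample is excluded by default.  Returns
    ``(times, R_t, T_t)``.
    """
    cut_idx = np.flatnonzero(ref.released >= release_cut)
    t_cut = ref.times[cut_idx[0]] if cut_idx.size else math.inf
    t_end = min(t_max, t_cut)
    sel = ref.times <= t_end
    if not include_t0:
        sel &= ref.times > 0
    times = ref.times[sel]
    if times.size == 0:
        raise GridMismatchError("no common time points in the selection window")
    test_map = {t: r for t, r in zip(test.times, test.released)}
    t_vals = np.empty_like(times)
    for i, t in enumerate(times):
        if t not in test_map:
            raise GridMismatchError(
                f"test profile lacks the reference sampling time t = {t:g} min"
            )
        t_vals[i] = test_map[t]
    return times, ref.released[sel], t_vals


def f1(reference: np.ndarray, test: np.ndarray) -> float:
    """Difference factor: 100 x sum|R - T| / sum R (not symmetric)."""
    r = np.asarray(reference, dtype=float)
    t = np.asarray(test, dtype=float)
    if r.size < 1:
        raise ValueError("at least one pair required")
    denom = r.sum()
    if denom <= 0:
        raise ValueError("reference profile sums to zero; f1 undefined")
    return 100.0 * float(np.abs(r - t).sum()) / float(denom)


def f2(reference: np.ndarray, test: np.ndarray) -> float:
    """Similarity factor: 50 log10(100 / sqrt(1 + mean squared difference))."""
    r = np.asarray(reference, dtype=float)
    t = np.asarray(test, dtype=float)
    if r.size < 1:
        raise ValueError("at least one pair required")
    msd = float(np.mean((r - t) ** 2))
    return 50.0 * math.log10(100.0 / math.sqrt(1.0 + msd))


def similarity_verdict(
    f1_value: float, f2_value: float, limit_f1: float = 15.0, limit_f2: float = 50.0
) -> bool:
    """Conventional similarity rule: f1 strictly below 15 and f2 strictly
    above 50 (limits configurable)."""
    return f1_value < limit_f1 and f2_value > limit_f2


def compare_profiles(
    ref: DissolutionProfile,
    test: DissolutionProfile,
    t_max: float = 720.0,
    release_cut: float = 99.5,
    limit_f1: float = 15.0,
    limit_f2: float = 50.0,
    include_t0: bool = False,
) -> SimilarityResult:
    """Full similarity comparison: select points, compute f1/f2, judge."""
    times, r, t = select_points(
        ref, test, t_max=t_max, release_cut=release_cut, include_t0=include_t0
    )
    f1_v = f1(r, t)
    f2_v = f2(r, t)
    return SimilarityResult(
        f1=f1_v,
        f2=f2_v,
        n_points=int(times.size),
        truncation_time=float(times[-1]),
        verdict=similarity_verdict(f1_v, f2_v, limit_f1, limit_f2),
        limits=(limit_f1, limit_f2),
    )
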