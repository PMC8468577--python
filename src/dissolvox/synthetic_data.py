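"""Synthetic dissolution profiles and tablet fixtures with known ground truth.

Everything the validation pipeline consumes — labelled voxel matrices,
tablet composition records and cumulative release profiles — can be
generated here with its generating parameters recorded, so each analysis
stage is testable against exact bookkeeping rather than downloads.

The composition fixtures reproduce the worked example of a theophylline /
ethyl cellulose (25/75) compact: the real tablet's gravimetric masses and
the virtual masses recovered from segmented tomography images, from which
the recovery-rate arithmetic follows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .tablet_generation import GenerationParams, generate_distributed
from .voxel_matrix import (
    API,
    EXCIPIENT,
    KG_M3_TO_MG_MM3,
    Compound,
    TabletSpec,
    VoxelMatrix,
)
from .profile_metrics import DissolutionProfile

__all__ = [
    "THEOPHYLLINE",
    "ETHYL_CELLULOSE",
    "SyntheticProfileSpec",
    "synth_profile",
    "CompositionRow",
    "T25E75_ROWS",
    "synth_tablet_fixture",
    "TabletFixture",
]

# Reference compound parameter sets for the worked theophylline /
# ethyl cellulose example (helium densities, saturation solubility in pH 6.6
# phosphate buffer, contact angle of the matrix former as used after the
# wettability adjustment).
THEOPHYLLINE = Compound(
    id=API,
    name="theophylline anhydrate",
    density=1447.2,
    solubility=10.09,
    molar_mass=180.16,
    contact_angle=0.0,
)
ETHYL_CELLULOSE = Compound(
    id=EXCIPIENT,
    name="ethyl cellulose",
    density=1139.9,
    solubility=0.0,
    molar_mass=75_000.0,
    contact_angle=89.0,
    pore_size=0.5,
)


@dataclass
class SyntheticProfileSpec:
    """Generating model of a synthetic cumulative release profile.

    ``model='power_law'``: k t^n; ``'square_root'``: k sqrt(t);
    ``'logistic'``: cap / (1 + exp(-k (t - n))) with ``n`` the midpoint time
    in minutes.  Gaussian noise (sd in percentage points) is added, values
    are clipped to [0, cap] and made nondecreasing by running maximum.
    """

    model: Literal["power_law", "square_root", "logistic"]
    k: float
    n: float = 0.5
    times: np.ndarray = field(default_factory=lambda: np.arange(10.0, 730.0, 10.0))
    noise_sd: float = 0.0
    cap: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.k <= 0 or self.n <= 0:
            raise ValueError("k and n must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")


def synth_profile(spec: SyntheticProfileSpec, label: str = "") -> DissolutionProfile:
    """Generate a seed-deterministic dissolution profile from its model."""
    t = spec.times
    if spec.model == "power_law":
        base = spec.k * t**spec.n
    elif spec.model == "square_root":
        base = spec.k * np.sqrt(t)
    elif spec.model == "logistic":
        base = spec.cap / (1.0 + np.exp(-spec.k * (t - spec.n)))
    else:
        raise ValueError(f"unknown profile model {spec.model!r}")
    released = np.minimum(spec.cap, base)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        released = released + rng.normal(0.0, spec.noise_sd, size=t.size)
    released = np.clip(released, 0.0, spec.cap)
    released = np.maximum.accumulate(released)
    return DissolutionProfile(times=t, released=released, label=label)


@dataclass(frozen=True)
class CompositionRow:
    """One selected-matrix record: real tablet masses vs. virtual masses.

    Masses in mg.  ``desirability`` is the published tablet desirability of
    the processing pathway, carried for reporting only.
    """

    name: str
    real_api_mg: float
    real_excipient_mg: float
    virtual_api_mg: float
    virtual_excipient_mg: float
    desirability: float | None = None


# Worked rows of the 25/75 theophylline/ethyl cellulose tablet (tablet 3
# unless noted): real gravimetric masses 86.9 / 329.5 mg.
T25E75_ROWS: dict[str, CompositionRow] = {
    "T7": CompositionRow("T7", 86.9, 329.5, 73.3, 329.2, desirability=0.506),
    "T4": CompositionRow("T4", 86.9, 329.5, 96.1, 323.8, desirability=0.801),
    "B1": CompositionRow("B1", 86.9, 329.5, 90.0, 329.0, desirability=0.982),
    "D": CompositionRow("D", 89.8, 320.4, 88.6, 316.2),  # tablet 1 targets
    "G": CompositionRow("G", 89.8, 320.4, 88.6, 316.2),
}


@dataclass
class TabletFixture:
    """A generated matrix paired with its real-tablet spec and ground truth."""

    matrix: VoxelMatrix
    spec: TabletSpec
    ground_truth: dict


def synth_tablet_fixture(
    row: CompositionRow,
    api: Compound = THEOPHYLLINE,
    excipient: Compound = ETHYL_CELLULOSE,
    voxel_edge: float = 0.2,
    diameter: float = 11.28,
    height: float = 4.0,
    seed: int = 0,
) -> TabletFixture:
    """Build a voxel matrix realising a composition row's virtual masses.

    The matrix is generated at a coarse voxel edge (default 0.2 mm) so the
    fixture stays small; compound masses reproduce the row's virtual masses
    within one voxel-mass, so the recovery arithmetic against the row's real
    masses reproduces the published recovery rates.
    """
    s = int(np.ceil(height / voxel_edge))
    rc = int(np.ceil(diameter / voxel_edge)) + 2
    params = GenerationParams(
        shape=(s, rc, rc),
        voxel_edge=voxel_edge,
        diameter=diameter,
        height=height,
        target_masses={api.id: row.virtual_api_mg, excipient.id: row.virtual_excipient_mg},
        mode="distributed",
        seed=seed,
    )
    matrix = generate_distributed(params, [api, excipient])
    spec = TabletSpec(
        diameter=diameter,
        height=height,
        total_mass=row.real_api_mg + row.real_excipient_mg,
        api_mass=row.real_api_mg,
        excipient_mass=row.real_excipient_mg,
    )
    voxel_mass = {
        c.id: voxel_edge**3 * c.density * KG_M3_TO_MG_MM3 for c in (api, excipient)
    }
    counts = matrix.counts()
    ground_truth = {
        "seed": seed,
        "voxel_edge_mm": voxel_edge,
        "target_masses_mg": dict(params.target_masses),
        "voxel_counts": counts,
        "achieved_masses_mg": {
            g: counts.get(g, 0) * voxel_mass[g] for g in voxel_mass
        },
        "air_fraction": counts.get(0, 0) / matrix.labels.size,
    }
    return TabletFixture(matrix=matrix, spec=spec, ground_truth=ground_truth)
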