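"""A transparent voxel dissolution simulator (reference fixture).

This cellular-automaton engine exists so the validation pipeline — matrix
in, predicted profile out, statistics against the experiment — can run end
to end on open code.  It is an original, deliberately simple design and is
NOT a reproduction of any proprietary dissolution engine; none of its
numeric output is a reproduction target.

Update rule, per time step:

1. Medium ingress.  Medium occupies air voxels 6-connected to the bounding
   box faces; the wetting front advances one voxel per step.  Wettable
   excipient voxels (contact angle < 90 deg) in contact with medium become
   conductive with a per-step probability proportional to their
   intraparticular porosity, letting the medium percolate through the
   matrix former; unwettable or zero-porosity excipient blocks ingress.
2. Dissolution.  Every soluble voxel in contact with medium loses mass at a
   rate proportional to its solubility, its wetted face count and a
   convection factor (1 + mixing parameter).  Exhausted voxels become wet
   air.  Dissolved mass accumulates into the cumulative release profile,
   sampled every ``sampling_interval`` seconds.

Mass is conserved exactly: released + remaining solid = initial at every
sample.  Profiles are nondecreasing and capped at 100 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .profile_metrics import DissolutionProfile
from .voxel_matrix import AIR, KG_M3_TO_MG_MM3, MEDIUM, Compound, VoxelMatrix

__all__ = ["SimulationConfig", "MediumProperties", "check_wettability", "simulate"]


@dataclass(frozen=True)
class MediumProperties:
    """Dissolution medium bulk properties (passthroughs for the fixture)."""

    density: float = 1007.0  # kg/m^3
    viscosity: float = 0.0006865  # Pa s
    tension: float = 67.9  # mN/m


@dataclass
class SimulationConfig:
    """Configuration of the reference dissolution fixture.

    ``iterations`` counts time steps of ``time_step`` seconds (43,200 one-
    second steps = 12 h); the profile is sampled every
    ``sampling_interval`` seconds.  ``dissolution_rate`` is the fixture's
    empirical rate constant: mg dissolved per wetted face, per unit
    solubility (mg/mL), per step.  ``percolation_rate`` scales the per-step
    wetting probability of wettable excipient (multiplied by its
    intraparticular porosity fraction).
    """

    compounds: Sequence[Compound]
    unitcube: float = 0.028  # mm
    iterations: int = 43_200
    sampling_interval: int = 600  # s
    time_step: float = 1.0  # s
    mixing_parameter: float = 0.05
    medium: MediumProperties = field(default_factory=MediumProperties)
    dissolution_rate: float = 3e-5
    percolation_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.sampling_interval < 1:
            raise ValueError("sampling interval must be >= 1 s")
        if not 0.0 <= self.mixing_parameter <= 1.0:
            raise ValueError("mixing parameter must lie in [0, 1]")


def check_wettability(compounds: Sequence[Compound]) -> dict[int, bool]:
    """Wettable iff the contact angle is strictly below 90 degrees.

    An unwettable matrix former blocks medium ingress through its voxels,
    which is how a simulation signals that an enclosed drug cluster cannot
    be reached.
    """
    return {c.id: c.contact_angle < 90.0 for c in compounds}


def _face_count(mask: np.ndarray) -> np.ndarray:
    """Number of 6-neighbour True faces per voxel (boundary = outside)."""
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    count = np.zeros(mask.shape, dtype=np.uint8)
    count += padded[:-2, 1:-1, 1:-1]
    count += padded[2:, 1:-1, 1:-1]
    count += padded[1:-1, :-2, 1:-1]
    count += padded[1:-1, 2:, 1:-1]
    count += padded[1:-1, 1:-1, :-2]
    count += padded[1:-1, 1:-1, 2:]
    return count


def _exterior_wet(open_mask: np.ndarray) -> np.ndarray:
    """Open voxels 6-connected to the bounding-box faces."""
    from scipy import ndimage

    labels, n = ndimage.label(open_mask, structure=ndimage.generate_binary_structure(3, 1))
    if n == 0:
        return np.zeros_like(open_mask)
    edge_labels = set()
    for face in (
        labels[0], labels[-1], labels[:, 0], labels[:, -1], labels[:, :, 0], labels[:, :, -1]
    ):
        edge_labels.update(np.unique(face).tolist())
    edge_labels.discard(0)
    return np.isin(labels, sorted(edge_labels))


def simulate(
    matrix: VoxelMatrix, config: SimulationConfig, return_state: bool = False
) -> DissolutionProfile | tuple[DissolutionProfile, dict]:
    """Run the reference dissolution fixture on a voxel matrix.

    Returns the cumulative percent of the soluble drug released, sampled
    every ``sampling_interval`` seconds.  Deterministic given
    ``config.seed``.  With ``return_state=True`` also returns a diagnostics
    dict carrying the initial soluble mass and, per sample, the released and
    remaining solid soluble mass (mg), for mass-balance auditing.
    """
    by_id = {c.id: c for c in config.compounds}
    labels = np.array(matrix.labels, copy=True)
    present = set(np.unique(labels).tolist()) - {AIR, MEDIUM}
    unknown = present - set(by_id)
    if unknown:
        raise KeyError(f"matrix labels {sorted(unknown)} missing from config compounds")

    soluble_ids = [g for g in present if by_id[g].solubility > 0]
    if not soluble_ids:
        raise ValueError("no soluble compound in the matrix; nothing to simulate")
    wettability = check_wettability([by_id[g] for g in present])

    voxel_volume = matrix.voxel_edge**3
    mass = np.zeros(labels.shape, dtype=float)
    for g in present:
        mass[labels == g] = voxel_volume * by_id[g].density * KG_M3_TO_MG_MM3
    soluble = np.isin(labels, soluble_ids)
    initial_soluble_mass = float(mass[soluble].sum())

    solubility = np.zeros(labels.shape, dtype=float)
    for g in soluble_ids:
        solubility[labels == g] = by_id[g].solubility

    # conductive = voxels the medium can occupy or pass through
    open_mask = (labels == AIR) | (labels == MEDIUM)
    wet = _exterior_wet(open_mask)
    wet |= labels == MEDIUM

    rng = np.random.default_rng(config.seed)
    convection = 1.0 + config.mixing_parameter
    rate = config.dissolution_rate * convection * config.time_step

    # per-compound wetting probability for wettable porous excipients
    perc_prob = np.zeros(labels.shape, dtype=float)
    for g in present:
        comp = by_id[g]
        if comp.solubility == 0 and wettability[g] and comp.intraparticular_porosity > 0:
            perc_prob[labels == g] = (
                config.percolation_rate * comp.intraparticular_porosity / 100.0
            )

    n_steps = config.iterations
    sample_every = max(1, int(round(config.sampling_interval / config.time_step)))
    times_min: list[float] = []
    released_pct: list[float] = []
    released_samples: list[float] = []
    remaining_samples: list[float] = []
    released_mass = 0.0

    for step in range(1, n_steps + 1):
        wet_faces = _face_count(wet)

        # 1a. medium advances one voxel per step through open voxels
        newly_wet_air = open_mask & ~wet & (wet_faces > 0)
        # 1b. percolation through wettable porous excipient
        candidate = (~wet) & (perc_prob > 0) & (wet_faces > 0)
        if candidate.any():
            draws = rng.random(int(candidate.sum()))
            probs = 1.0 - (1.0 - perc_prob[candidate]) ** wet_faces[candidate]
            newly_perc = np.zeros_like(candidate)
            newly_perc[candidate] = draws < probs
        else:
            newly_perc = np.zeros_like(candidate)
        wet |= newly_wet_air | newly_perc

        # 2. dissolution of soluble voxels touching medium
        active = soluble & (mass > 0) & (wet_faces > 0)
        if active.any():
            dm = rate * solubility[active] * wet_faces[active]
            taken = np.minimum(dm, mass[active])
            released_mass += float(taken.sum())
            mass[active] -= taken
            exhausted = np.zeros_like(active)
            exhausted[active] = mass[active] == 0.0
            if exhausted.any():
                labels[exhausted] = AIR
                soluble[exhausted] = False
                open_mask |= exhausted
                wet |= exhausted  # was in contact with medium when it vanished

        if step % sample_every == 0:
            times_min.append(step * config.time_step / 60.0)
            released_pct.append(
                min(100.0, 100.0 * released_mass / initial_soluble_mass)
            )
            released_samples.append(released_mass)
            remaining_samples.append(float(mass[soluble].sum()))

    if not times_min:
        times_min = [n_steps * config.time_step / 60.0]
        released_pct = [min(100.0, 100.0 * released_mass / initial_soluble_mass)]
        released_samples = [released_mass]
        remaining_samples = [float(mass[soluble].sum())]
    profile = DissolutionProfile(
        times=np.asarray(times_min),
        released=np.asarray(released_pct),
        label="reference fixture",
    )
    if return_state:
        return profile, {
            "initial_soluble_mass_mg": initial_soluble_mass,
            "released_mass_mg": np.asarray(released_samples),
            "remaining_soluble_mass_mg": np.asarray(remaining_samples),
        }
    return profile
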