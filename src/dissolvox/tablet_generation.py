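"""Virtual tablet construction: random placement, seed-and-grow, densify.

Two construction modes mirror how particle-arrangement software builds
virtual compacts: voxels assigned to compounds uniformly at random inside a
cylindrical die ("distributed"), or a fixed number of randomly placed seeds
per compound grown by single-voxel accretion until the target mass is
reached ("seed and grow").  :func:`densify` converts the remaining
interparticular air into compound voxels at a fixed voxel-count ratio,
producing the zero-interparticular-porosity variants used to probe whether a
dissolution engine's internal porosity correction can mimic a percolating
drug cluster.

All randomness flows through one seeded ``numpy`` generator, so matrices are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .voxel_matrix import (
    AIR,
    DEFAULT_LABEL_MAP,
    KG_M3_TO_MG_MM3,
    Compound,
    VoxelMatrix,
    cylinder_mask,
)

__all__ = [
    "GenerationParams",
    "InfeasibleTargetError",
    "GrowthBlockedError",
    "generate_distributed",
    "generate_seed_grow",
    "densify",
]

Mode = Literal["distributed", "seed_grow"]

# 6-neighbourhood offsets (faces only) used for cluster growth.
_NEIGHBOURS = np.array(
    [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)],
    dtype=np.int64,
)


class InfeasibleTargetError(ValueError):
    """Required solid volume exceeds the cylinder volume."""


class GrowthBlockedError(RuntimeError):
    """All clusters of a compound are enclosed before reaching the target."""


@dataclass
class GenerationParams:
    """Parameters of virtual tablet construction.

    ``target_masses`` maps compound grey value to target mass (mg).
    ``n_seeds`` (seed_grow only) maps compound grey value to the number of
    seed voxels, i.e. particles; growth steps then set the particle size.
    """

    shape: tuple[int, int, int]
    voxel_edge: float
    diameter: float
    height: float
    target_masses: Mapping[int, float]
    mode: Mode = "distributed"
    n_seeds: Mapping[int, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.target_masses.values()):
            raise ValueError("target masses must be nonnegative")
        s, r, c = self.shape
        if self.height > s * self.voxel_edge + 1e-12:
            raise ValueError("cylinder height exceeds the grid")
        if self.diameter > min(r, c) * self.voxel_edge + 1e-12:
            raise ValueError("cylinder diameter exceeds the grid")
        if self.mode == "seed_grow":
            for g, m in self.target_masses.items():
                if m > 0 and self.n_seeds.get(g, 0) < 1:
                    raise ValueError(f"seed_grow requires >= 1 seed for compound {g}")

    def mask(self) -> np.ndarray:
        return cylinder_mask(self.shape, self.voxel_edge, self.diameter, self.height)


def _voxel_counts(
    params: GenerationParams, compounds: Sequence[Compound], n_available: int
) -> dict[int, int]:
    """Target voxel count per compound; nearest count keeps |mass error| within
    one voxel-mass."""
    by_id = {c.id: c for c in compounds}
    counts: dict[int, int] = {}
    for label, target in params.target_masses.items():
        if label not in by_id:
            raise KeyError(f"no Compound provided for grey value {label}")
        vm = params.voxel_edge**3 * by_id[label].density * KG_M3_TO_MG_MM3
        counts[label] = int(round(target / vm))
    if sum(counts.values()) > n_available:
        raise InfeasibleTargetError(
            f"targets need {sum(counts.values())} voxels but the cylinder "
            f"holds only {n_available}"
        )
    return counts


def _label_map_for(labels: Sequence[int]) -> dict[int, str]:
    lm = {AIR: "air"}
    for g in labels:
        lm[g] = DEFAULT_LABEL_MAP.get(g, "compound")
        if lm[g] != "compound":
            lm[g] = "compound"
    lm[AIR] = "air"
    return lm


def generate_distributed(
    params: GenerationParams, compounds: Sequence[Compound]
) -> VoxelMatrix:
    """Assign in-cylinder voxels to compounds uniformly at random.

    Each compound receives the voxel count closest to its target mass;
    remaining in-cylinder voxels stay air.  Deterministic given the seed.
    """
    rng = np.random.default_rng(params.seed)
    mask = params.mask()
    flat = np.flatnonzero(mask.ravel())
    counts = _voxel_counts(params, compounds, flat.size)
    order = rng.permutation(flat)
    labels = np.zeros(params.shape, dtype=np.uint8).ravel()
    start = 0
    for g in sorted(counts):
        n = counts[g]
        labels[order[start : start + n]] = g
        start += n
    labels = labels.reshape(params.shape)
    return VoxelMatrix(
        labels=labels,
        voxel_edge=params.voxel_edge,
        label_map=_label_map_for(sorted(counts)),
    )


def _empty_neighbours(voxel, labels, mask):
    z, y, x = voxel
    out = []
    s, r, c = labels.shape
    for dz, dy, dx in _NEIGHBOURS:
        nz, ny, nx = z + dz, y + dy, x + dx
        if 0 <= nz < s and 0 <= ny < r and 0 <= nx < c:
            if mask[nz, ny, nx] and labels[nz, ny, nx] == AIR:
                out.append((int(nz), int(ny), int(nx)))
    return out


def generate_seed_grow(
    params: GenerationParams, compounds: Sequence[Compound]
) -> VoxelMatrix:
    """Place random seeds and grow 6-connected clusters to the target mass.

    Growth proceeds in rounds; each round every surviving cluster of every
    unfinished compound accretes one uniformly chosen empty face-neighbour.
    A compound whose clusters are all enclosed before reaching its target
    raises :class:`GrowthBlockedError`.
    """
    rng = np.random.default_rng(params.seed)
    mask = params.mask()
    flat = np.flatnonzero(mask.ravel())
    counts = _voxel_counts(params, compounds, flat.size)
    labels = np.zeros(params.shape, dtype=np.uint8)

    order = rng.permutation(flat)
    seed_positions: dict[int, list[tuple[int, int, int]]] = {}
    cursor = 0
    for g in sorted(counts):
        if counts[g] == 0:
            continue
        n_seeds = min(params.n_seeds.get(g, 1), counts[g])
        pos = [
            tuple(int(v) for v in np.unravel_index(order[cursor + i], params.shape))
            for i in range(n_seeds)
        ]
        cursor += n_seeds
        seed_positions[g] = pos
        for p in pos:
            labels[p] = g

    # Per-cluster frontier of candidate empty neighbours, lazily revalidated.
    clusters: dict[int, list[set]] = {}
    achieved = {g: len(p) for g, p in seed_positions.items()}
    for g, positions in seed_positions.items():
        clusters[g] = [set(_empty_neighbours(p, labels, mask)) for p in positions]

    unfinished = {g for g in seed_positions if achieved[g] < counts[g]}
    while unfinished:
        progressed = False
        for g in sorted(unfinished):
            alive = False
            for frontier in clusters[g]:
                if achieved[g] >= counts[g]:
                    break
                stale = [v for v in frontier if labels[v] != AIR]
                frontier.difference_update(stale)
                if not frontier:
                    continue
                alive = True
                candidates = sorted(frontier)
                chosen = candidates[rng.integers(len(candidates))]
                labels[chosen] = g
                achieved[g] += 1
                frontier.discard(chosen)
                frontier.update(_empty_neighbours(chosen, labels, mask))
                progressed = True
            if achieved[g] >= counts[g]:
                unfinished.discard(g)
            elif not alive:
                raise GrowthBlockedError(
                    f"compound {g} enclosed at {achieved[g]}/{counts[g]} voxels"
                )
        if not progressed and unfinished:
            blocked = sorted(unfinished)[0]
            raise GrowthBlockedError(
                f"compound {blocked} enclosed at "
                f"{achieved[blocked]}/{counts[blocked]} voxels"
            )

    return VoxelMatrix(
        labels=labels,
        voxel_edge=params.voxel_edge,
        label_map=_label_map_for(sorted(counts)),
    )


def _ratio_quotas(existing: dict[int, int], n_fill: int) -> dict[int, int]:
    """Split ``n_fill`` voxels across compounds in proportion to existing
    counts (largest-remainder), keeping the voxel-count ratio within one
    voxel of the original."""
    total = sum(existing.values())
    raw = {g: n_fill * c / total for g, c in existing.items()}
    quotas = {g: int(np.floor(v)) for g, v in raw.items()}
    remainder = n_fill - sum(quotas.values())
    by_frac = sorted(raw, key=lambda g: (raw[g] - np.floor(raw[g]), g), reverse=True)
    for g in by_frac[:remainder]:
        quotas[g] += 1
    return quotas


def densify(
    matrix: VoxelMatrix,
    mode: Mode = "distributed",
    mask: np.ndarray | None = None,
    seed: int = 0,
) -> VoxelMatrix:
    """Convert in-region air into compounds, keeping the voxel-count ratio.

    Produces the zero-interparticular-porosity variant of a tablet: every
    air voxel inside ``mask`` (default: every air voxel, for matrices already
    cropped to the tablet) becomes a compound voxel, split across compounds
    in proportion to their existing voxel counts (within one voxel).
    Pre-existing compound voxels are never modified.  ``mode='distributed'``
    assigns randomly; ``mode='seed_grow'`` grows existing clusters outward so
    particles stay compact.
    """
    rng = np.random.default_rng(seed)
    labels = np.array(matrix.labels, copy=True)
    if mask is None:
        region = np.ones(labels.shape, dtype=bool)
    else:
        region = np.asarray(mask, dtype=bool)
    compound_ids = [g for g in matrix.compound_labels() if (labels == g).any()]
    if len(compound_ids) < 1:
        raise ValueError("matrix contains no compound voxels to densify against")
    existing = {g: int((labels == g).sum()) for g in compound_ids}
    air_mask = (labels == AIR) & region
    n_fill = int(air_mask.sum())
    if n_fill == 0:
        return VoxelMatrix(labels=labels, voxel_edge=matrix.voxel_edge,
                           label_map=dict(matrix.label_map))
    quotas = _ratio_quotas(existing, n_fill)

    if mode == "distributed":
        idx = rng.permutation(np.flatnonzero(air_mask.ravel()))
        flat = labels.ravel()
        start = 0
        for g in sorted(quotas):
            flat[idx[start : start + quotas[g]]] = g
            start += quotas[g]
        labels = flat.reshape(matrix.labels.shape)
    else:
        remaining = dict(quotas)
        air = air_mask.copy()
        while air.any() and any(v > 0 for v in remaining.values()):
            assigned_this_pass = False
            air_idx = np.argwhere(air)
            rng.shuffle(air_idx)
            for z, y, x in air_idx:
                neigh_labels = []
                for dz, dy, dx in _NEIGHBOURS:
                    nz, ny, nx = z + dz, y + dy, x + dx
                    if (
                        0 <= nz < labels.shape[0]
                        and 0 <= ny < labels.shape[1]
                        and 0 <= nx < labels.shape[2]
                        and labels[nz, ny, nx] in remaining
                        and remaining[labels[nz, ny, nx]] > 0
                    ):
                        neigh_labels.append(int(labels[nz, ny, nx]))
                if neigh_labels:
                    g = neigh_labels[rng.integers(len(neigh_labels))]
                    labels[z, y, x] = g
                    remaining[g] -= 1
                    air[z, y, x] = False
                    assigned_this_pass = True
            if not assigned_this_pass:
                break
        # isolated pockets or exhausted quotas: assign directly
        leftover = np.argwhere((labels == AIR) & region)
        pool = [g for g in sorted(remaining) for _ in range(remaining[g])]
        for (z, y, x), g in zip(leftover, pool):
            labels[z, y, x] = g

    return VoxelMatrix(
        labels=labels,
        voxel_edge=matrix.voxel_edge,
        label_map=dict(matrix.label_map),
    )
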