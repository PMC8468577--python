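"""Voxel tablet matrices: data model, TIFF stack I/O and composition accounting.

A virtual tablet is a 3D grid of 8-bit labels where each grey value identifies
a compound (or air, or dissolution medium).  This module provides the
:class:`VoxelMatrix` container, round-trip TIFF I/O, and the gravimetric
bookkeeping used to judge how faithfully a virtual matrix represents the real
tablet it was derived from: per-compound masses, image porosity, recovery
rates against the real tablet's composition, and the Derringer-style
desirability score aggregating them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "AIR",
    "API",
    "EXCIPIENT",
    "MEDIUM",
    "DEFAULT_LABEL_MAP",
    "Compound",
    "VoxelMatrix",
    "TabletSpec",
    "CompositionReport",
    "UnknownLabelError",
    "TiffFormatError",
    "read_tiff_stack",
    "write_tiff_stack",
    "compound_masses",
    "image_porosity",
    "cylinder_mask",
    "recovery_report",
    "desirability_score",
    "linear_ramp_desirability",
    "round_half_up",
]

# Conventional grey values for a binary tablet: air 0, drug 1, matrix
# former 31, dissolution medium 200.  Fully overridable via label_map.
AIR = 0
API = 1
EXCIPIENT = 31
MEDIUM = 200

DEFAULT_LABEL_MAP: dict[int, str] = {
    AIR: "air",
    API: "compound",
    EXCIPIENT: "compound",
    MEDIUM: "medium",
}

# 1 kg/m^3 == 1e-3 mg/mm^3; voxel edges are millimetres, masses milligrams.
KG_M3_TO_MG_MM3 = 1e-3


class UnknownLabelError(ValueError):
    """A grey value in the stack is not covered by the label map."""


class TiffFormatError(ValueError):
    """The input TIFF is not an 8-bit grayscale stack."""


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching printed report precision."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Compound:
    """Physical and transport properties of one formulation compound.

    Parameters
    ----------
    id : int
        8-bit grey value identifying the compound in label volumes.
    name : str
        Human-readable name.
    density : float
        True (helium) density in kg/m^3.
    solubility : float
        Saturation solubility in the dissolution medium, mg/mL.
    molar_mass : float
        Molar mass in Da.
    contact_angle : float
        Contact angle against the medium in degrees; wettable below 90.
    intraparticular_porosity : float
        Sub-voxel porosity assigned to the compound, percent.
    pore_size : float
        Characteristic intraparticular pore size, micrometres.
    """

    id: int
    name: str
    density: float
    solubility: float = 0.0
    molar_mass: float = float("nan")
    contact_angle: float = 0.0
    intraparticular_porosity: float = 0.0
    pore_size: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.id <= 255:
            raise ValueError(f"compound id {self.id} outside 8-bit range")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.solubility < 0:
            raise ValueError("solubility must be nonnegative")
        if not 0 <= self.contact_angle <= 180:
            raise ValueError("contact angle must lie in [0, 180] degrees")
        if not 0 <= self.intraparticular_porosity < 100:
            raise ValueError("intraparticular porosity must lie in [0, 100)")

    @property
    def wettable(self) -> bool:
        return self.contact_angle < 90.0


@dataclass
class VoxelMatrix:
    """A labelled voxel volume with a physical edge length.

    ``labels`` is indexed ``(slice, row, col)``; axis 0 runs along the tablet
    height so the slice count equals the number of TIFF pages.
    """

    labels: np.ndarray
    voxel_edge: float
    label_map: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or min(self.labels.shape) < 1:
            raise ValueError("labels must be a non-empty 3D array")
        if self.voxel_edge <= 0:
            raise ValueError("voxel_edge must be positive")
        present = set(np.unique(self.labels).tolist())
        unknown = present - set(self.label_map)
        if unknown:
            raise UnknownLabelError(
                f"grey values {sorted(unknown)} missing from label_map"
            )

    @property
    def n_slices(self) -> int:
        return self.labels.shape[0]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return self.voxel_edge**3

    def counts(self) -> dict[int, int]:
        """Voxel count per grey value present in the volume."""
        values, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))

    def compound_labels(self) -> list[int]:
        return sorted(
            g for g, role in self.label_map.items() if role == "compound"
        )


@dataclass(frozen=True)
class TabletSpec:
    """Geometry and gravimetric composition of the real (imaged) tablet.

    Masses in mg, lengths in mm.  The tablet is a lubricant-free binary
    compact, so API and excipient masses must account for the total mass up
    to rounding of the printed values.
    """

    diameter: float
    height: float
    total_mass: float
    api_mass: float
    excipient_mass: float

    def __post_init__(self) -> None:
        for name in ("diameter", "height", "total_mass", "api_mass", "excipient_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.api_mass + self.excipient_mass > self.total_mass * 1.01:
            raise ValueError("component masses exceed total mass beyond rounding")

    @property
    def apparent_volume(self) -> float:
        """Cylinder volume pi (D/2)^2 h in mm^3."""
        return math.pi * (self.diameter / 2.0) ** 2 * self.height


def read_tiff_stack(
    path: str | Path,
    label_map: Mapping[int, str] | None = None,
    voxel_edge: float = 0.028,
) -> VoxelMatrix:
    """Read a labelled 8-bit grayscale TIFF stack as a voxel matrix.

    ``path`` may be a multi-page TIFF or a directory of numbered single-page
    TIFFs (sorted lexicographically).  Slice order follows page/file order.

    Raises
    ------
    TiffFormatError
        If the stack is not 8-bit grayscale.
    UnknownLabelError
        If a grey value in the stack is absent from ``label_map``; the error
        names the value and the first slice containing it.
    """
    label_map = dict(DEFAULT_LABEL_MAP) if label_map is None else dict(label_map)
    path = Path(path)
    if path.is_dir():
        pages = sorted(p for p in path.iterdir() if p.suffix.lower() in {".tif", ".tiff"})
        if not pages:
            raise FileNotFoundError(f"no TIFF files in directory {path}")
        slices = [tifffile.imread(p) for p in pages]
        data = np.stack(slices, axis=0)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[np.newaxis, ...]
    if data.dtype != np.uint8:
        raise TiffFormatError(f"expected 8-bit grayscale data, got dtype {data.dtype}")
    if data.ndim != 3:
        raise TiffFormatError(f"expected a grayscale stack, got shape {data.shape}")
    for value in np.unique(data):
        if int(value) not in label_map:
            slice_idx = int(np.argmax((data == value).any(axis=(1, 2))))
            raise UnknownLabelError(
                f"grey value {int(value)} (first seen in slice {slice_idx}) "
                "is not in the label map"
            )
    return VoxelMatrix(labels=data, voxel_edge=voxel_edge, label_map=label_map)


def write_tiff_stack(matrix: VoxelMatrix, path: str | Path) -> Path:
    """Write a voxel matrix as a multi-page 8-bit grayscale TIFF.

    Round-trips bit-exactly with :func:`read_tiff_stack`.
    """
    labels = np.asarray(matrix.labels)
    if labels.min() < 0 or labels.max() > 255:
        raise ValueError("labels outside 8-bit range cannot be written")
    path = Path(path)
    tifffile.imwrite(path, labels.astype(np.uint8), photometric="minisblack")
    return path


def compound_masses(
    matrix: VoxelMatrix, compounds: Sequence[Compound]
) -> dict[int, float]:
    """Per-compound mass (mg) implied by voxel counts and true densities.

    mass = voxel_count x voxel_edge^3 x density, with mm^3 x kg/m^3
    resolved to mg.
    """
    by_id = {c.id: c for c in compounds}
    masses: dict[int, float] = {}
    for label in matrix.compound_labels():
        if matrix.count(label) and label not in by_id:
            raise KeyError(f"no Compound provided for grey value {label}")
        if label in by_id:
            masses[label] = (
                matrix.count(label)
                * matrix.voxel_volume
                * by_id[label].density
                * KG_M3_TO_MG_MM3
            )
    return masses


def cylinder_mask(
    shape: tuple[int, int, int],
    voxel_edge: float,
    diameter: float,
    height: float,
) -> np.ndarray:
    """Boolean mask of voxels whose centres lie inside a centred cylinder.

    The cylinder axis runs along axis 0 (the slice/height axis); ``diameter``
    and ``height`` are in mm.
    """
    s, r, c = shape
    z = (np.arange(s) + 0.5) * voxel_edge
    y = (np.arange(r) + 0.5) * voxel_edge
    x = (np.arange(c) + 0.5) * voxel_edge
    z0 = s * voxel_edge / 2.0
    y0 = r * voxel_edge / 2.0
    x0 = c * voxel_edge / 2.0
    in_height = np.abs(z - z0) <= height / 2.0
    rad2 = (y[:, None] - y0) ** 2 + (x[None, :] - x0) ** 2
    in_disc = rad2 <= (diameter / 2.0) ** 2
    return in_height[:, None, None] & in_disc[None, :, :]


def image_porosity(matrix: VoxelMatrix, region: np.ndarray | None = None) -> float:
    """Air-voxel fraction of the evaluation region, in percent.

    By default the region is the full (cropped) stack; pass a boolean mask
    (e.g. from :func:`cylinder_mask`) for tablets generated inside an air
    bounding box.
    """
    air_labels = [g for g, role in matrix.label_map.items() if role == "air"]
    is_air = np.isin(matrix.labels, air_labels)
    if region is not None:
        region = np.asarray(region, dtype=bool)
        if region.shape != matrix.labels.shape:
            raise ValueError("region mask shape does not match the matrix")
        total = int(region.sum())
        air = int(np.count_nonzero(is_air & region))
    else:
        total = matrix.labels.size
        air = int(np.count_nonzero(is_air))
    if total == 0:
        raise ValueError("empty evaluation region")
    return 100.0 * air / total


def linear_ramp_desirability(recovery: float, width: float = 25.0) -> float:
    """Two-sided linear ramp: 1 at 100 % recovery, 0 beyond ``width`` points."""
    return max(0.0, 1.0 - abs(recovery - 100.0) / width)


@dataclass
class CompositionReport:
    """Composition accounting of a virtual matrix against the real tablet.

    Recovery rates are 100 x virtual/real for API, excipient and total
    masses; ratio recoveries compare the virtual composition ratios with the
    real ones.  ``desirability`` is the geometric mean of the six
    per-parameter desirability scores.
    """

    voxel_counts: dict[int, int]
    masses: dict[int, float]
    image_porosity: float
    recovery_api: float
    recovery_excipient: float
    recovery_total: float
    recovery_ratio_api_ex: float
    recovery_ratio_api_total: float
    recovery_ratio_ex_total: float
    desirability: float

    def recoveries(self) -> dict[str, float]:
        return {
            "api": self.recovery_api,
            "excipient": self.recovery_excipient,
            "total": self.recovery_total,
            "ratio_api_ex": self.recovery_ratio_api_ex,
            "ratio_api_total": self.recovery_ratio_api_total,
            "ratio_ex_total": self.recovery_ratio_ex_total,
        }

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        """Recovery rates rounded half-up to the printed report precision."""
        return {k: round_half_up(v, ndigits) for k, v in self.recoveries().items()}

    def to_dict(self) -> dict:
        d = {
            "image_porosity_pct": self.image_porosity,
            "desirability": self.desirability,
        }
        for k, v in self.recoveries().items():
            d[f"recovery_{k}_pct"] = v
        for label, count in self.voxel_counts.items():
            d[f"voxels_{label}"] = count
        for label, mass in self.masses.items():
            d[f"mass_{label}_mg"] = mass
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame([self.to_dict()]).to_csv(path, index=False)


def desirability_score(
    components: Sequence[float],
    mapping: Callable[[float], float] | None = None,
) -> float:
    """Geometric mean of per-parameter desirability values.

    ``components`` are either desirabilities in [0, 1] (``mapping`` None) or
    recovery percentages transformed by ``mapping``.  Any zero component
    annihilates the score; values are clamped into [0, 1].
    """
    values = [mapping(c) for c in components] if mapping else list(components)
    values = [min(1.0, max(0.0, v)) for v in values]
    if not values:
        raise ValueError("at least one desirability component required")
    if any(v == 0.0 for v in values):
        return 0.0
    return float(math.exp(sum(math.log(v) for v in values) / len(values)))


def recovery_report(
    matrix: VoxelMatrix,
    compounds: Sequence[Compound],
    real: TabletSpec,
    api_id: int = API,
    excipient_id: int = EXCIPIENT,
    desirability_fn: Callable[[float], float] = linear_ramp_desirability,
    region: np.ndarray | None = None,
) -> CompositionReport:
    """Compare a virtual matrix's composition with the real tablet's.

    The six recovery parameters (API, excipient, total mass, and the three
    composition ratios) each map through ``desirability_fn`` to a [0, 1]
    score; the tablet desirability is their geometric mean.
    """
    if real.api_mass <= 0 or real.excipient_mass <= 0:
        raise ValueError("real tablet masses must be positive")
    masses = compound_masses(matrix, compounds)
    m_api = masses.get(api_id, 0.0)
    m_ex = masses.get(excipient_id, 0.0)
    m_total = m_api + m_ex
    rec_api = 100.0 * m_api / real.api_mass
    rec_ex = 100.0 * m_ex / real.excipient_mass
    real_total = real.api_mass + real.excipient_mass
    rec_total = 100.0 * m_total / real_total

    def ratio_recovery(virt_num, virt_den, real_num, real_den):
        if virt_den == 0:
            return 0.0
        return 100.0 * (virt_num / virt_den) / (real_num / real_den)

    rr_api_ex = ratio_recovery(m_api, m_ex, real.api_mass, real.excipient_mass)
    rr_api_tot = ratio_recovery(m_api, m_total, real.api_mass, real_total)
    rr_ex_tot = ratio_recovery(m_ex, m_total, real.excipient_mass, real_total)
    recoveries = [rec_api, rec_ex, rec_total, rr_api_ex, rr_api_tot, rr_ex_tot]
    return CompositionReport(
        voxel_counts=matrix.counts(),
        masses=masses,
        image_porosity=image_porosity(matrix, region=region),
        recovery_api=rec_api,
        recovery_excipient=rec_ex,
        recovery_total=rec_total,
        recovery_ratio_api_ex=rr_api_ex,
        recovery_ratio_api_total=rr_api_tot,
        recovery_ratio_ex_total=rr_ex_tot,
        desirability=desirability_score(recoveries, mapping=desirability_fn),
    )
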