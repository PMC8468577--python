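"""Porosity arithmetic linking real tablets to their virtual matrices.

Two quantities drive the porosity correction of a voxel dissolution
calculation:

* the measured tablet porosity, phi_tablet = (1 - V_true / V_apparent) x 100,
  where the true volume follows from the component masses and helium
  densities and the apparent volume from the cylinder geometry;
* the virtual excipient porosity phi_ex assigned to the matrix former so
  that the voxel image (whose interparticular porosity phi_image is usually
  lower than the real porosity, because sub-voxel voids are segmented into
  particles) carries the missing void volume as intraparticular porosity:

      phi_ex = S (phi_tablet - phi_image) Vx_size (Vx_API + Vx_ex)
               (1 + 0.01 phi_tablet) / (h Vx_ex)

Percent values are carried on the 0-100 scale throughout (hence the
``0.01 x phi_tablet`` term).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .voxel_matrix import Compound, TabletSpec

__all__ = ["PorosityInputs", "tablet_porosity", "excipient_virtual_porosity"]


@dataclass(frozen=True)
class PorosityInputs:
    """Inputs of the virtual excipient-porosity correction.

    ``s`` is the slice count of the image stack, ``h`` the tablet height
    (mm), ``vx_size`` the voxel edge (mm), ``vx_api``/``vx_ex`` the voxel
    counts of drug and matrix former; porosities are percent.
    """

    s: int
    h: float
    phi_tablet: float
    phi_image: float
    vx_size: float
    vx_api: int
    vx_ex: int

    def __post_init__(self) -> None:
        if self.s < 1:
            raise ValueError("slice count must be >= 1")
        if self.h <= 0 or self.vx_size <= 0:
            raise ValueError("height and voxel size must be positive")
        if not (0 <= self.phi_tablet <= 100 and 0 <= self.phi_image <= 100):
            raise ValueError("porosities must lie in [0, 100] percent")
        if self.vx_ex < 1:
            raise ValueError("excipient voxel count must be >= 1")
        if self.vx_api < 0:
            raise ValueError("API voxel count must be nonnegative")


def tablet_porosity(spec: TabletSpec, api: Compound, excipient: Compound) -> float:
    """Tablet porosity (percent) from masses, densities and geometry.

    phi_tablet = (1 - (m_API/rho_API + m_ex/rho_ex) / (pi (D/2)^2 h)) x 100,
    with masses in mg, densities in kg/m^3 and lengths in mm.  A result
    outside [-5, 100] signals inconsistent inputs and raises.
    """
    # kg/m^3 -> mg/mm^3 so that mg / (mg/mm^3) gives mm^3
    v_true = spec.api_mass / (api.density * 1e-3) + spec.excipient_mass / (
        excipient.density * 1e-3
    )
    v_apparent = math.pi * (spec.diameter / 2.0) ** 2 * spec.height
    phi = (1.0 - v_true / v_apparent) * 100.0
    if not -5.0 <= phi <= 100.0:
        raise ValueError(
            f"computed porosity {phi:.2f} % outside [-5, 100]: inconsistent inputs"
        )
    return phi


def excipient_virtual_porosity(inp: PorosityInputs) -> float:
    """Virtual excipient porosity (percent) for the dissolution calculation.

    Implements the correction literally: the porosity deficit of the image
    (phi_tablet - phi_image) is converted to an intraparticular porosity
    assigned to the excipient voxels.  A negative result (image porosity
    exceeding the measured porosity, i.e. over-segmented voids) is returned
    with a warning rather than raised.
    """
    phi_ex = (
        inp.s
        * (inp.phi_tablet - inp.phi_image)
        * inp.vx_size
        * (inp.vx_api + inp.vx_ex)
        * (1.0 + 0.01 * inp.phi_tablet)
        / (inp.h * inp.vx_ex)
    )
    if phi_ex < 0:
        warnings.warn(
            "virtual excipient porosity is negative: image porosity exceeds "
            "the measured tablet porosity (over-segmented voids)",
            stacklevel=2,
        )
    return phi_ex
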