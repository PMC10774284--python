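"""Unit conventions and conversion factors.

Internal units used throughout the package:

* length: micrometres (um); aggregate "size" x is a volume in um^3 with
  x = R^3 up to the spherical prefactor (the kernel's units absorb it).
* time: hours.
* concentration: millimolar (mM).
* single-cell flux rate: nmol per 10^6 cells per hour (the MFA convention).
* diffusivity: um^2 per hour.

The identity 1 nmol/um^3 = 10^6 mol/L = 10^9 mM links volumetric reaction
rates to concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: radius of a single iPS cell, um
SINGLE_CELL_RADIUS_UM = 7.5

#: volume of a single cell sphere, um^3
SINGLE_CELL_VOLUME_UM3 = (4.0 / 3.0) * np.pi * SINGLE_CELL_RADIUS_UM**3

#: converts a per-cell flux (nmol/10^6 cells/h) weighted by a cell density in
#: cells/mL into a bulk concentration rate in mM/h:
#: v [nmol/1e6 cells/h] * G [cells/mL] * 1e-6 -> nmol/mL/h = uM/h; * 1e-3 -> mM/h
FLUX_TO_MM_PER_CELL_PER_ML = 1e-9

#: converts a per-cell flux into the rate of change of that cell's own
#: intracellular concentration (mM/h): v * 1e-6 nmol/h spread over one cell
#: volume, times 1e9 mM per nmol/um^3.
CELL_FLUX_TO_MM = 1e3 * 3.0 / (4.0 * np.pi * SINGLE_CELL_RADIUS_UM**3)

#: multiplying N @ v by gamma (from :func:`unit_gamma`) and by this constant
#: yields a volumetric reaction rate in mM/h (see unit_gamma docstring).
GAMMA_TO_MM_PER_H = 1e-3


@dataclass(frozen=True)
class UnitConversion:
    """Flux-to-volumetric-rate conversion for cells packed in an aggregate.

    ``gamma`` follows the convention of expressing fluxes per 10^6 cells:
    ``gamma = 3e6 / (4 pi eps 7.5^3)`` so that ``gamma * cell_volume = 1e6``.
    ``rho = (N @ v) * gamma * GAMMA_TO_MM_PER_H`` is then a volumetric rate
    in mM/h for tissue at the given porosity.
    """

    gamma: float
    cell_volume: float  # A = eps * (4 pi / 3) * 7.5^3, um^3 per cell
    porosity: float


def unit_gamma(porosity: float) -> UnitConversion:
    """Conversion factor between per-cell flux and volumetric reaction rate.

    The average aggregate volume attributed to each cell is
    ``A = eps * (4 pi / 3) * 7.5^3`` um^3 with porosity ``eps``; a flux of
    1 nmol/10^6 cells/h over that volume gives the factor
    ``gamma = 3e6 / (4 pi eps 7.5^3)``.
    """
    if not 0.0 < porosity < 1.0:
        raise ValueError(f"porosity must lie in (0, 1), got {porosity}")
    cell_volume = porosity * SINGLE_CELL_VOLUME_UM3
    gamma = 3e6 / (4.0 * np.pi * porosity * SINGLE_CELL_RADIUS_UM**3)
    return UnitConversion(gamma=gamma, cell_volume=cell_volume, porosity=porosity)
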