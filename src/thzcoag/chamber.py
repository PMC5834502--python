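"""Forward model of the polyethylene-windowed fluidic chamber.

A thin liquid channel of thickness d sits between two polyethylene (PE)
windows.  At normal incidence the field transmitted through the channel
region is, relative to the source field,

    empty  : T_{PE-air} * e^{i omega d / c} * T_{PE-air}
    filled : T_{PE-liq} * e^{i omega d n / c} * e^{-omega d kappa / c} * T_{liq-PE}

with the Fresnel field-transmission coefficient
T_{a-b} = 2 n_bar_a / (n_bar_a + n_bar_b) and n_bar = n + i kappa.  PE is
treated as lossless with index 1.5; THz absorption in air is neglected.
The model is single-pass; a first-order Fabry-Perot echo of the channel
can be enabled to emulate the residual etalon ripple of a real cell
(free spectral range c / (2 n d), ~0.6 THz for 100 um of water).
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, model_validator

from .units import C_UM_PER_PS, angular_frequency


class ChamberGeometry(BaseModel):
    """Fluidic channel thickness and window/ambient refractive indices."""

    thickness_um: float = 100.0
    window_index: float = 1.5
    air_index: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "ChamberGeometry":
        if self.thickness_um <= 0:
            raise ValueError("channel thickness must be positive")
        if self.window_index <= 0 or self.air_index <= 0:
            raise ValueError("refractive indices must be positive")
        return self


def fresnel_transmission(n_a, n_b):
    """Field transmission T_{a-b} = 2 n_bar_a / (n_bar_a + n_bar_b)."""
    n_a = np.asarray(n_a, dtype=complex)
    return 2.0 * n_a / (n_a + n_b)


def chamber_transfer(freq_thz, geometry: ChamberGeometry, liquid_index=None, *,
                     filled: bool, include_echo: bool = False):
    """Complex transfer factor of the channel region for one arm.

    Parameters
    ----------
    freq_thz : array
        Frequencies in THz (may include 0; the phase factor is well defined).
    liquid_index : complex array, required when ``filled``
        n + i kappa of the liquid on the same grid.
    filled : bool
        False -> empty (air-filled) channel, True -> liquid-filled.
    include_echo : bool
        Add the first internal round-trip echo of the channel
        (single first-order term, not a full etalon sum).
    """
    omega = angular_frequency(freq_thz)
    phase = omega * geometry.thickness_um / C_UM_PER_PS
    n_pe = geometry.window_index
    if not filled:
        n_bar = complex(geometry.air_index)
        transfer = (fresnel_transmission(n_pe, n_bar) ** 2) * np.exp(1j * phase * n_bar)
    else:
        if liquid_index is None:
            raise ValueError("liquid_index required for a filled chamber")
        n_bar = np.asarray(liquid_index, dtype=complex)
        transfer = (
            fresnel_transmission(n_pe, n_bar)
            * np.exp(1j * phase * n_bar)
            * fresnel_transmission(n_bar, n_pe)
        )
    if include_echo:
        r = (n_bar - n_pe) / (n_bar + n_pe)  # internal reflection at liquid->PE
        transfer = transfer * (1.0 + r**2 * np.exp(2j * phase * n_bar))
    return transfer


def interface_correction(liquid_index, geometry: ChamberGeometry):
    """Ratio of filled to empty interface terms,

        C = (T_{PE-liq} T_{liq-PE}) / (T_{PE-air} T_{PE-air}),

    the factor the iterative extraction eliminates from the measured
    sample/reference spectral ratio.
    """
    n_pe = geometry.window_index
    n_bar = np.asarray(liquid_index, dtype=complex)
    filled = fresnel_transmission(n_pe, n_bar) * fresnel_transmission(n_bar, n_pe)
    empty = fresnel_transmission(n_pe, geometry.air_index) ** 2
    return filled / empty


def free_spectral_range_ghz(n, thickness_um):
    """Etalon fringe spacing c / (2 n d) in GHz."""
    return C_UM_PER_PS / (2.0 * n * thickness_um) * 1.0e3
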