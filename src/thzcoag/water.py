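"""Two-relaxation (double-Debye) dielectric model of liquid water.

Blood plasma is overwhelmingly water by volume, so the generator's baseline
optical response of the liquid in the chamber is that of bulk water: a slow
~8 ps cooperative reorientation relaxation plus a fast ~0.2 ps relaxation.
Under the e^{-i omega t} time convention used here,

    eps(omega) = eps_inf
               + (eps_s - eps_1) / (1 - i omega tau_slow)
               + (eps_1 - eps_inf) / (1 - i omega tau_fast)

with Im eps >= 0 meaning loss, and complex refractive index
n_bar = sqrt(eps) = n + i kappa with n > 0, kappa >= 0.

Default parameters are room-temperature literature values for water; they
live in config and are overridable.  At 0.35 THz the defaults give
n ~ 2.46 and kappa ~ 0.94, i.e. alpha in the low hundreds of cm^-1 —
the familiar strong sub-THz water absorption.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, model_validator


class DoubleDebyeModel(BaseModel):
    """Parameters of the two-relaxation water permittivity.

    eps_static > eps_intermediate > eps_inf > 1 and tau_slow > tau_fast > 0.
    """

    eps_static: float = 78.36
    eps_intermediate: float = 5.16
    eps_inf: float = 3.49
    tau_slow_ps: float = 8.24
    tau_fast_ps: float = 0.18

    @model_validator(mode="after")
    def _check_invariants(self) -> "DoubleDebyeModel":
        if not (self.eps_static > self.eps_intermediate > self.eps_inf > 1.0):
            raise ValueError("require eps_static > eps_intermediate > eps_inf > 1")
        if not (self.tau_slow_ps > self.tau_fast_ps > 0.0):
            raise ValueError("require tau_slow > tau_fast > 0")
        return self


#: default water model shared across the package
WATER = DoubleDebyeModel()


def debye_permittivity(freq_thz, model: DoubleDebyeModel | None = None):
    """Complex relative permittivity eps(omega) of the two-relaxation model.

    Parameters
    ----------
    freq_thz : float or array
        Frequency in THz, strictly positive.
    model : DoubleDebyeModel, optional
        Defaults to the package water model.

    Returns
    -------
    complex or complex ndarray with Im eps > 0 (lossy medium).
    """
    model = model or WATER
    f = np.asarray(freq_thz, dtype=float)
    if np.any(f <= 0.0):
        raise ValueError("frequency must be positive")
    omega = 2.0 * np.pi * f  # rad/ps
    eps = (
        model.eps_inf
        + (model.eps_static - model.eps_intermediate) / (1.0 - 1j * omega * model.tau_slow_ps)
        + (model.eps_intermediate - model.eps_inf) / (1.0 - 1j * omega * model.tau_fast_ps)
    )
    eps = np.asarray(eps)
    return complex(eps) if eps.ndim == 0 else eps


def complex_index(freq_thz, model: DoubleDebyeModel | None = None):
    """(n, kappa) of the model liquid: principal square root of eps.

    The principal branch gives Re >= 0 and, for Im eps > 0, kappa >= 0.
    """
    nbar = np.sqrt(debye_permittivity(freq_thz, model))
    return np.real(nbar), np.imag(nbar)
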