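"""Unit conventions used throughout the package.

Frequencies are carried in THz, times in ps, lengths in um and absorption
constants in cm^-1.  These are mutually consistent: 1/ps = 1 THz and the
speed of light is 299.792458 um/ps, so ``omega * d / c`` is dimensionless
when omega is in rad/ps and d in um.
"""

from __future__ import annotations

import numpy as np

#: speed of light in um/ps (equivalently mm/ns, or 1e-6 m / 1e-12 s)
C_UM_PER_PS = 299.792458

#: cm^-1 per um^-1
PER_UM_TO_PER_CM = 1.0e4


def angular_frequency(freq_thz):
    """omega in rad/ps for a frequency in THz."""
    return 2.0 * np.pi * np.asarray(freq_thz, dtype=float)


def kappa_to_alpha_cm1(freq_thz, kappa):
    """Power absorption constant alpha = 2 omega kappa / c, in cm^-1.

    kappa is the extinction coefficient (imaginary part of the refractive
    index); alpha describes intensity attenuation I = I0 exp(-alpha z).
    """
    return 2.0 * angular_frequency(freq_thz) * np.asarray(kappa) / C_UM_PER_PS * PER_UM_TO_PER_CM


def alpha_cm1_to_kappa(freq_thz, alpha_cm1):
    """Inverse of :func:`kappa_to_alpha_cm1`."""
    return np.asarray(alpha_cm1) / PER_UM_TO_PER_CM * C_UM_PER_PS / (2.0 * angular_frequency(freq_thz))
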