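"""Physical constants for backbone amide :sup:`15`\\ N relaxation.

All relaxation equations in :mod:`amidyn.mfa` and the reduced spectral
density mapping in :mod:`amidyn.jmap` draw their interaction constants from
a single :class:`NMRConstants` instance so the two stay mutually
consistent.  The dipolar coupling constant is

.. math:: d = \\frac{\\mu_0 \\hbar \\gamma_H \\gamma_N}{4\\pi r_{NH}^3}

(rad/s) and the CSA constant at a given field is :math:`c^2 =
(\\omega_N \\Delta\\sigma)^2 / 3`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MU_0 = 4.0e-7 * np.pi  # vacuum permeability, T^2 m^3 / J
HBAR = 1.054571817e-34  # reduced Planck constant, J s


@dataclass(frozen=True)
class NMRConstants:
    """Spin-pair constants for the amide N-H vector.

    Parameters
    ----------
    gamma_H : float
        1H gyromagnetic ratio, rad s^-1 T^-1.
    gamma_N : float
        15N gyromagnetic ratio, rad s^-1 T^-1 (negative).
    r_NH : float
        Effective N-H bond length in metres.
    delta_sigma : float
        15N chemical shift anisotropy in ppm.
    """

    gamma_H: float = 2.6752218744e8
    gamma_N: float = -2.7126e7
    r_NH: float = 1.02e-10
    delta_sigma: float = -160.0

    def __post_init__(self) -> None:
        if not (self.gamma_N < 0.0 < self.gamma_H):
            raise ValueError("expected gamma_N < 0 < gamma_H")
        if not (0.9e-10 <= self.r_NH <= 1.1e-10):
            raise ValueError("r_NH outside the physical 0.9-1.1 A range")

    def omega_H(self, field_MHz: float) -> float:
        """1H angular Larmor frequency (rad/s) at a field given in MHz."""
        return 2.0 * np.pi * field_MHz * 1e6

    def omega_N(self, field_MHz: float) -> float:
        """15N angular Larmor frequency (rad/s); sign dropped, magnitude used."""
        B0 = self.omega_H(field_MHz) / self.gamma_H
        return abs(self.gamma_N) * B0

    @property
    def d2(self) -> float:
        """Squared dipolar coupling constant d^2, (rad/s)^2."""
        d = MU_0 * HBAR * self.gamma_H * self.gamma_N / (4.0 * np.pi * self.r_NH**3)
        return d * d

    def c2(self, field_MHz: float) -> float:
        """Squared CSA constant c^2 = (omega_N * delta_sigma)^2 / 3 at a field."""
        return (self.omega_N(field_MHz) * self.delta_sigma * 1e-6) ** 2 / 3.0


DEFAULT_CONSTANTS = NMRConstants()
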