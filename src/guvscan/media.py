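"""Dielectric models of the liquid media.

The carrier medium is a 0.1 M glucose–water solution.  Glucose is non-ionic
and at 0.1 M its correction to the water relaxation is negligible at GHz
frequencies, so the medium is modelled as pure water with a single-Debye
relaxation at 25 °C and zero ionic conductivity.

Sign convention throughout the package: ``eps = eps' - j eps''`` with
``eps'' >= 0`` for lossy media.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m


@dataclass(frozen=True)
class DebyeMedium:
    """Single-Debye dielectric relaxation.

    Parameters
    ----------
    eps_static : float
        Low-frequency (static) relative permittivity.
    eps_inf : float
        High-frequency relative permittivity.
    tau_s : float
        Relaxation time in seconds.
    conductivity : float
        Ionic conductivity in S/m (adds ``sigma / (omega eps0)`` to eps'').
    """

    eps_static: float = 78.4
    eps_inf: float = 5.2
    tau_s: float = 8.27e-12
    conductivity: float = 0.0

    def permittivity(self, frequency_hz):
        """Complex relative permittivity ``eps' - j eps''`` at ``frequency_hz``."""
        f = np.asarray(frequency_hz, dtype=float)
        if np.any(f <= 0):
            raise ValueError("frequency must be positive")
        omega = 2.0 * np.pi * f
        eps = self.eps_inf + (self.eps_static - self.eps_inf) / (1.0 + 1j * omega * self.tau_s)
        if self.conductivity:
            eps = eps - 1j * self.conductivity / (omega * EPS0)
        out = np.asarray(eps, dtype=complex)
        return complex(out) if out.ndim == 0 else out


#: Default channel liquid (0.1 M glucose-water ~ pure water at 25 degC).
WATER = DebyeMedium()
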