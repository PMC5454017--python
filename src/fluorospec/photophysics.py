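"""Fluorophore photophysics: quantum yield, detected intensity, dipole-dipole
energy transfer.

All functions are pure and unit-agnostic: rates may be given in any single
consistent unit (the quantum yield is a ratio), distances in any single
consistent unit (only ``r0/r`` enters), and the lifetime's unit fixes the
unit of the returned transfer rate.

``fret_efficiency`` is not one of the three printed relations; it is the
standard completion E = k_t / (k_t + 1/tau_d) needed to convert a transfer
rate into donor quenching for the simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PhotophysicsParams",
    "quantum_yield",
    "emitted_intensity",
    "fret_rate",
    "fret_efficiency",
]

FOUR_PI = 4.0 * math.pi


def quantum_yield(kr: float, knr: float) -> float:
    """Fluorescence quantum efficiency Q = kr / (kr + knr).

    Equals the fraction of absorbed photons that are re-emitted.  Strictly
    increasing in the radiative rate ``kr`` and strictly decreasing in the
    nonradiative rate ``knr``.

    Raises
    ------
    ValueError
        If either rate is negative or both are zero.
    """
    if kr < 0 or knr < 0:
        raise ValueError("rates must be non-negative")
    total = kr + knr
    if total == 0:
        raise ValueError("kr + knr must be positive")
    return kr / total


def emitted_intensity(omega: float, q: float, n: float) -> float:
    """Photon count reaching the detector: (omega / 4*pi) * q * n.

    Parameters
    ----------
    omega
        Collection solid angle in steradians, in (0, 4*pi].
    q
        Quantum efficiency in [0, 1].
    n
        Number of excited molecules.
    """
    if not 0 < omega <= FOUR_PI:
        raise ValueError(f"omega must be in (0, 4*pi], got {omega!r}")
    if not 0 <= q <= 1:
        raise ValueError(f"quantum efficiency must be in [0, 1], got {q!r}")
    if n < 0:
        raise ValueError("number of excited molecules must be non-negative")
    return (omega / FOUR_PI) * q * n


def fret_rate(tau_d: float, r0: float, r: float) -> float:
    """Donor-to-acceptor energy transfer rate (1/tau_d) * (r0/r)**6.

    ``r0`` is the distance at which transfer and spontaneous donor decay are
    equally fast; the rate falls with the sixth power of the separation
    ``r``.  Treated as an equality; any proportionality constant is absorbed
    into amplitude calibration downstream.
    """
    if tau_d <= 0:
        raise ValueError("tau_d must be positive")
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    if r <= 0:
        raise ValueError("r must be positive")
    return (1.0 / tau_d) * (r0 / r) ** 6


def fret_efficiency(tau_d: float, r0: float, r: float) -> float:
    """Fraction of donor excitations transferred: k_t / (k_t + 1/tau_d).

    Algebraically 1 / (1 + (r/r0)**6): exactly 0.5 at ``r = r0``, strictly
    decreasing in ``r``, independent of ``tau_d`` (which must still be
    positive for the underlying rates to exist).
    """
    if tau_d <= 0:
        raise ValueError("tau_d must be positive")
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    if r <= 0:
        raise ValueError("r must be positive")
    return 1.0 / (1.0 + (r / r0) ** 6)


@dataclass(frozen=True)
class PhotophysicsParams:
    """Rate and geometry parameters for one fluorophore.

    ``r0``/``r`` describe the donor-acceptor pair the fluorophore takes part
    in (as donor); they are ignored for fluorophores not acting as donors.
    """

    kr: float = 1e8
    knr: float = 3e8
    tau_d: float = 3e-9
    r0: float = 3.0
    r: float = 4.5
    omega: float = 0.1
    n_excited: float = 1e6

    def __post_init__(self) -> None:
        if self.kr < 0 or self.knr < 0:
            raise ValueError("kr and knr must be non-negative")
        if self.kr + self.knr == 0:
            raise ValueError("kr + knr must be positive")
        if self.tau_d <= 0:
            raise ValueError("tau_d must be positive")
        if self.r0 <= 0 or self.r <= 0:
            raise ValueError("r0 and r must be positive")
        if not 0 < self.omega <= FOUR_PI:
            raise ValueError("omega must be in (0, 4*pi]")
        if self.n_excited < 0:
            raise ValueError("n_excited must be non-negative")

    @property
    def quantum_yield(self) -> float:
        return quantum_yield(self.kr, self.knr)

    @property
    def transfer_rate(self) -> float:
        return fret_rate(self.tau_d, self.r0, self.r)

    @property
    def transfer_efficiency(self) -> float:
        return fret_efficiency(self.tau_d, self.r0, self.r)

    @property
    def brightness(self) -> float:
        """Detected photon count for this parameter set."""
        return emitted_intensity(self.omega, self.quantum_yield, self.n_excited)
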