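"""Hertz spherical-contact physics and probe metadata.

Internal unit convention (fixed across the package): Young's modulus in kPa,
force in nN, deflection and indentation in nm, piezo position in µm,
cantilever spring constant in N/m (1 N/m × 1 nm = 1 nN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidConfigError

# (kPa · µm^1/2 · nm^3/2) -> nN:  1e3 Pa · 1e-3 m^1/2 · 1e-13.5 m^3/2 · 1e9
_UNIT_FACTOR = 10.0 ** -4.5


@dataclass(frozen=True)
class ProbeSpec:
    """Colloidal-probe cantilever metadata.

    Parameters
    ----------
    spring_constant : float
        Cantilever spring constant k, N/m. Must lie in (0, 10].
    bead_radius : float
        Radius of the attached silica bead, µm (4.5 µm diameter bead by
        default, so R = 2.25 µm).
    poisson_ratio : float
        Poisson ratio of the sample, in [0, 0.5]; 0.5 models an
        incompressible cell.
    trigger_force : float
        Deflection trigger, nN: the approach stops once the cantilever
        force exceeds this value (2 nN protects the cell).
    indent_velocity : float
        Indentation speed, µm/s. Metadata only; it does not enter the
        quasi-static Hertz model.
    """

    spring_constant: float = 0.08
    bead_radius: float = 2.25
    poisson_ratio: float = 0.5
    trigger_force: float = 2.0
    indent_velocity: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.spring_constant <= 10.0):
            raise InvalidConfigError(
                f"spring_constant must be in (0, 10] N/m, got {self.spring_constant}"
            )
        if self.bead_radius <= 0:
            raise InvalidConfigError("bead_radius must be positive (µm)")
        if not (0.0 <= self.poisson_ratio <= 0.5):
            raise InvalidConfigError("poisson_ratio must be in [0, 0.5]")
        if self.trigger_force <= 0:
            raise InvalidConfigError("trigger_force must be positive (nN)")


def hertz_prefactor(probe: ProbeSpec) -> float:
    """Geometric prefactor A with F = A · E · δ^{3/2}.

    Units: A in nN / (kPa · nm^{3/2}); multiply by E in kPa and δ^{3/2}
    in nm^{3/2} to obtain force in nN.
    """
    nu = probe.poisson_ratio
    return (4.0 / 3.0) / (1.0 - nu**2) * np.sqrt(probe.bead_radius) * _UNIT_FACTOR


def hertz_force(indentation_nm, youngs_modulus_kpa: float, probe: ProbeSpec):
    """Hertzian force of a rigid sphere on an elastic half-space.

    F = (4/3) · E/(1−ν²) · √R · δ^{3/2}, evaluated in package units
    (δ in nm, E in kPa, R in µm, F in nN). Negative indentations (no
    contact) return zero force.
    """
    delta = np.clip(np.asarray(indentation_nm, dtype=float), 0.0, None)
    return hertz_prefactor(probe) * youngs_modulus_kpa * delta**1.5
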