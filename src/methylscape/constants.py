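"""Physical and geometric constants for methyl relaxation analysis.

All constants are SI unless noted. The intra-methyl dipolar geometry
(``r_hh``, ``theta_axis_hh``) follows the standard values used in methyl
triple-quantum relaxation work: three protons on a 1.813 Å H–H triangle
whose H–H vectors are perpendicular to the three-fold symmetry axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants entering the η ↔ O²axis conversion and Stokes–Einstein.

    Attributes
    ----------
    gamma_h : float
        Proton gyromagnetic ratio, rad s⁻¹ T⁻¹.
    hbar : float
        Reduced Planck constant, J s.
    mu0_over_4pi : float
        Magnetic constant μ₀/4π, T² m³ J⁻¹; required for the dipolar
        coupling in SI units.
    r_hh : float
        Intra-methyl H–H distance, Å.
    theta_axis_hh : float
        Angle between the methyl symmetry axis and the H–H vector, degrees.
        90° gives a geometric factor P2(cos θ) = −1/2.
    k_b : float
        Boltzmann constant, J K⁻¹.
    """

    gamma_h: float = 2.6752218744e8
    hbar: float = 1.054571817e-34
    mu0_over_4pi: float = 1.0e-7
    r_hh: float = 1.813
    theta_axis_hh: float = 90.0
    k_b: float = 1.380649e-23

    @property
    def geometric_factor(self) -> float:
        """P2(cos θ_axis,HH) = (3 cos²θ − 1)/2; −1/2 for θ = 90°."""
        c = np.cos(np.radians(self.theta_axis_hh))
        return 0.5 * (3.0 * c * c - 1.0)

    @property
    def dipolar_coupling(self) -> float:
        """(μ₀/4π)·γ_H²·ħ/r_HH³ in rad s⁻¹ (r_HH converted Å → m)."""
        r_m = self.r_hh * 1e-10
        return self.mu0_over_4pi * self.gamma_h**2 * self.hbar / r_m**3


DEFAULT_CONSTANTS = PhysicalConstants()
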