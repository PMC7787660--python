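"""Closed-form lateral resolution of confocal and STED microscopy.

Used to parameterize the synthetic point-spread functions and to document
acquisition settings. Confocal: Δd = 0.4·λ/NA. STED: the depletion beam
shrinks the effective spot by the saturation factor ζ = I/I_sat,
Δd = 0.5·λ / (NA·√(1+ζ)), which reduces to the diffraction limit at ζ = 0
and decreases monotonically in ζ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OpticsParams", "confocal_resolution", "sted_resolution"]


@dataclass(frozen=True)
class OpticsParams:
    wavelength_nm: float
    numerical_aperture: float
    saturation_factor: float = 0.0  # ζ = I / I_sat

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be > 0")
        if not 0 < self.numerical_aperture <= 1.7:
            raise ValueError("numerical aperture must be in (0, 1.7]")
        if self.saturation_factor < 0:
            raise ValueError("saturation factor must be >= 0")


def confocal_resolution(params: OpticsParams) -> float:
    """Confocal lateral resolution Δd = 0.4·λ/NA, in nm."""
    return 0.4 * params.wavelength_nm / params.numerical_aperture


def sted_resolution(params: OpticsParams) -> float:
    """STED lateral resolution Δd = 0.5·λ / (NA·√(1+ζ)), in nm."""
    return 0.5 * params.wavelength_nm / (
        params.numerical_aperture * float(np.sqrt(1.0 + params.saturation_factor))
    )
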