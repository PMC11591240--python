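"""Scherrer crystallite size from XRD peak parameters.

L = K lambda / (beta_rad cos(theta)), with beta the peak's full width at
half maximum and theta half the diffractometer's 2-theta angle.  Defaults
match the catalyst characterization: shape factor K = 0.94 and Cu K-alpha
radiation (lambda = 0.15406 nm).  No instrumental-broadening correction is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiffractionPeak", "scherrer_size"]

SHAPE_FACTOR = 0.94
CU_K_ALPHA_NM = 0.15406


@dataclass(frozen=True)
class DiffractionPeak:
    """One diffraction peak: 2-theta and FWHM in degrees."""

    two_theta: float                 # degrees
    fwhm: float                      # degrees
    shape_factor: float = SHAPE_FACTOR
    wavelength: float = CU_K_ALPHA_NM  # nm
    plane: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.two_theta < 180.0):
            raise ValueError(f"2-theta must lie in (0, 180) deg, got {self.two_theta}")
        if self.fwhm <= 0:
            raise ValueError("FWHM must be positive")
        if self.wavelength <= 0 or self.shape_factor <= 0:
            raise ValueError("wavelength and shape factor must be positive")


def scherrer_size(peak: DiffractionPeak) -> float:
    """Crystallite size in nm (multiply by 10 for angstrom)."""
    theta = np.deg2rad(peak.two_theta / 2.0)
    beta = np.deg2rad(peak.fwhm)
    cos_t = np.cos(theta)
    if cos_t <= 0:
        raise ValueError("peak angle leaves no diffracting geometry (cos <= 0)")
    return float(peak.shape_factor * peak.wavelength / (beta * cos_t))
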