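"""Dissolved-oxygen readout from Ruthenium-probe fluorescence quenching.

The Ru(dpp) probe's fluorescence is collisionally quenched by dissolved
oxygen following the Stern-Volmer law

    I_zero / I = 1 + K_SV * pO2

where I_zero is the unquenched (zero-oxygen) intensity and K_SV the
Stern-Volmer constant (per % pO2).  A two-point calibration — the
zero-oxygen level and the level of a solution equilibrated at a reference
pO2 (20% by default, air-saturated) — fixes K_SV, after which intensity
converts linearly in quencher concentration to oxygen partial pressure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, InvalidInputError


@dataclass(frozen=True)
class O2Calibration:
    i_zero: float  # grey level at zero oxygen
    k_sv: float  # per % pO2

    def __post_init__(self):
        if self.i_zero <= 0 or self.k_sv <= 0:
            raise CalibrationError("I_zero and K_SV must be positive")


def calibrate_stern_volmer(i_zero: float, i_ref: float,
                           po2_ref: float = 20.0) -> O2Calibration:
    """K_SV = (I_zero/I_ref - 1) / pO2_ref from the two calibration points."""
    if i_ref <= 0 or po2_ref <= 0:
        raise InvalidInputError("reference intensity and pO2 must be positive")
    if i_ref >= i_zero:
        raise CalibrationError(
            "no quenching: reference intensity must lie below I_zero")
    return O2Calibration(i_zero=float(i_zero),
                         k_sv=(i_zero / i_ref - 1.0) / po2_ref)


def po2_from_intensity(intensity, calibration: O2Calibration):
    """pO2 (%) = (I_zero/I - 1) / K_SV; strictly decreasing in intensity."""
    i = np.asarray(intensity, dtype=float)
    if np.any(i <= 0):
        raise InvalidInputError("intensity must be positive")
    if np.any(i > calibration.i_zero):
        raise InvalidInputError(
            "intensity above the unquenched level implies negative pO2")
    out = (calibration.i_zero / i - 1.0) / calibration.k_sv
    return out if out.shape else float(out)


def intensity_from_po2(po2, calibration: O2Calibration):
    """Inverse map I = I_zero / (1 + K_SV pO2), used by the generator."""
    p = np.asarray(po2, dtype=float)
    if np.any(p < 0):
        raise InvalidInputError("pO2 must be >= 0")
    out = calibration.i_zero / (1.0 + calibration.k_sv * p)
    return out if out.shape else float(out)
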