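"""Modified Beer-Lambert law constants and the forward/inverse conversions.

The optical-density change at wavelength lambda produced by concentration
changes ``dc`` (molar) of oxy- and deoxyhemoglobin over a source-detector
separation ``d`` (cm) with differential pathlength factor ``DPF(lambda)`` is

    dOD(lambda) = [eps_HbO(lambda) dHbO + eps_HbR(lambda) dHbR] * d * DPF(lambda)

with base-10 molar extinction coefficients ``eps`` in 1/(M cm).  The inverse
solves the 2x2 linear system per sample.  Both directions share the constants
below so they are exact inverses of each other.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError

#: base-10 molar extinction coefficients, 1/(M cm), from the standard
#: compiled hemoglobin tables (Prahl/Gratzer) used by fNIRS toolboxes
EXTINCTION = {
    760: {"HbO": 586.0, "HbR": 1548.52},
    850: {"HbO": 1058.0, "HbR": 691.32},
}

#: differential pathlength factors, wavelength order (760 nm, 850 nm)
DEFAULT_DPF = (7.25, 6.38)

MOLAR_PER_UM = 1e-6


def extinction_matrix(wavelengths=(760, 850)) -> np.ndarray:
    """2x2 matrix E with E[i] = (eps_HbO, eps_HbR) at wavelengths[i]."""
    try:
        return np.array(
            [[EXTINCTION[w]["HbO"], EXTINCTION[w]["HbR"]] for w in wavelengths],
            dtype=float,
        )
    except KeyError as exc:
        raise ValidationError(f"no extinction data for wavelength {exc}") from exc


def mbll_forward_od(dhbo_um: np.ndarray, dhbr_um: np.ndarray, d_cm: float,
                    dpf=DEFAULT_DPF, wavelengths=(760, 850)) -> np.ndarray:
    """Concentration changes (micromolar) -> optical-density changes.

    Returns an array shaped ``(2,) + dhbo.shape`` (wavelength axis first).
    """
    E = extinction_matrix(wavelengths)
    dhbo_m = np.asarray(dhbo_um, dtype=float) * MOLAR_PER_UM
    dhbr_m = np.asarray(dhbr_um, dtype=float) * MOLAR_PER_UM
    out = np.empty((2,) + dhbo_m.shape)
    for wi in range(2):
        out[wi] = (E[wi, 0] * dhbo_m + E[wi, 1] * dhbr_m) * d_cm * dpf[wi]
    return out


def mbll_inverse(dod: np.ndarray, d_cm: float, dpf=DEFAULT_DPF,
                 wavelengths=(760, 850)) -> tuple[np.ndarray, np.ndarray]:
    """Optical-density changes ``(2, ...)`` -> (dHbO, dHbR) in micromolar."""
    dod = np.asarray(dod, dtype=float)
    if dod.shape[0] != 2:
        raise ValidationError("dOD must have the 2-wavelength axis first")
    # fold pathlength into the system matrix: dOD = A @ dc  with dc in M
    E = extinction_matrix(wavelengths)
    A = E * (d_cm * np.asarray(dpf, dtype=float)[:, None])
    if abs(np.linalg.det(A)) < 1e-12 * np.abs(A).max() ** 2:
        raise ValidationError("extinction system is singular for these wavelengths")
    flat = dod.reshape(2, -1)
    conc = np.linalg.solve(A, flat) / MOLAR_PER_UM
    dhbo = conc[0].reshape(dod.shape[1:])
    dhbr = conc[1].reshape(dod.shape[1:])
    return dhbo, dhbr
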