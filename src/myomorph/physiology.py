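"""Fiber length prediction, PCSA, and specific tension.

PCSA (physiological cross-sectional area) is the standard architectural
normalizer for muscle force:

    PCSA [cm^2] = m [g] * cos(theta) / (rho [g/cm^3] * Lf [cm])

with pennation angle theta and fiber length Lf.  Fiber length is
abstracted as a fixed fiber-length-to-muscle-length ratio per muscle
(the architecture model behind that ratio is external to this package);
specific tension is peak tetanic force over PCSA (N/cm^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "ArchitectureParams",
    "predict_fiber_length",
    "compute_pcsa",
    "specific_tension",
    "add_physiology",
]


@dataclass(frozen=True)
class ArchitectureParams:
    """Per-muscle architectural constants.

    ``fl_to_ml_ratio`` and ``pennation_deg`` default to a parallel-fibered
    placeholder architecture; users should substitute muscle-specific
    values from their own architecture model.
    """

    fl_to_ml_ratio: float = 0.6
    pennation_deg: float = 0.0
    density_g_cm3: float = 1.056

    def __post_init__(self):
        if not 0 < self.fl_to_ml_ratio <= 1:
            raise InputError("fl_to_ml_ratio must be in (0, 1]")
        if not 0 <= self.pennation_deg < 90:
            raise InputError("pennation angle must be in [0, 90) degrees")
        if not self.density_g_cm3 > 0:
            raise InputError("density must be positive")


def predict_fiber_length(muscle_length_cm, params: ArchitectureParams):
    """Fiber length Lf = Lm * fl_to_ml_ratio (cm).

    Normalized fiber length (the dFL input of the mass-deficit model) is
    this value over the sex-matched sham mean.
    """
    lm = np.asarray(muscle_length_cm, dtype=float)
    if np.any(lm <= 0):
        raise InputError("muscle length must be positive")
    out = lm * params.fl_to_ml_ratio
    return float(out) if np.isscalar(muscle_length_cm) else out


def compute_pcsa(mass_g, fiber_length_cm, params: ArchitectureParams):
    """PCSA = m * cos(theta) / (rho * Lf), cm^2."""
    m = np.asarray(mass_g, dtype=float)
    lf = np.asarray(fiber_length_cm, dtype=float)
    if np.any(m <= 0) or np.any(lf <= 0):
        raise InputError("mass and fiber length must be positive")
    out = m * np.cos(np.deg2rad(params.pennation_deg)) / (params.density_g_cm3 * lf)
    return float(out) if np.isscalar(mass_g) and np.isscalar(fiber_length_cm) else out


def specific_tension(p0_n, pcsa_cm2):
    """Peak tetanic force over PCSA, N/cm^2."""
    p0 = np.asarray(p0_n, dtype=float)
    pcsa = np.asarray(pcsa_cm2, dtype=float)
    if np.any(pcsa <= 0):
        raise InputError("PCSA must be positive")
    out = p0 / pcsa
    return float(out) if np.isscalar(p0_n) and np.isscalar(pcsa_cm2) else out


def add_physiology(df: pd.DataFrame, params: ArchitectureParams) -> pd.DataFrame:
    """Append predicted fiber length, PCSA and specific tension columns.

    Expects ``muscle_length_cm``, ``ss_mass_mg`` and ``p0_n`` columns;
    returns a copy with ``pred_fiber_length_cm``, ``pcsa_cm2`` and
    ``specific_tension_n_cm2`` added.
    """
    out = df.copy()
    lf = predict_fiber_length(out["muscle_length_cm"].to_numpy(), params)
    pcsa = compute_pcsa(out["ss_mass_mg"].to_numpy() / 1e3, lf, params)
    out["pred_fiber_length_cm"] = lf
    out["pcsa_cm2"] = pcsa
    out["specific_tension_n_cm2"] = specific_tension(out["p0_n"].to_numpy(), pcsa)
    return out
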