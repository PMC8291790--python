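"""Arrhenius activation-energy fitting, activity normalization, peptide mass.

The activation energy of an enzymatic reaction is obtained from the Arrhenius
plot: ordinary least squares of ln(velocity) against 1/T (T in kelvin), with
Ea = −slope·R, R = 8.314 J K⁻¹ mol⁻¹.  A lower Ea indicates a catalyst better
suited to low temperatures.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)

GAS_CONSTANT = 8.314  # J / (K mol)
KELVIN_OFFSET = 273.15
WATER_MASS = 18.015  # Da, average


@dataclass
class ArrheniusFit:
    ea_kj_mol: float
    slope: float
    intercept: float
    r_squared: float


def arrhenius_ea(table: pd.DataFrame) -> ArrheniusFit:
    """Fit ln(velocity) vs 1/T(K) and return Ea in kJ/mol.

    ``table`` needs columns ``temperature`` (°C) and ``velocity`` (any
    consistent activity unit; scaling all velocities by a constant changes the
    intercept, never Ea).
    """
    temps = np.asarray(table["temperature"], dtype=float)
    vel = np.asarray(table["velocity"], dtype=float)
    if np.any(vel <= 0):
        raise ValidationError("velocities must be positive for an Arrhenius fit")
    if np.unique(temps).size < 2:
        raise ValidationError("at least 2 distinct temperatures are required")
    x = 1.0 / (temps + KELVIN_OFFSET)
    y = np.log(vel)
    fit = stats.linregress(x, y)
    return ArrheniusFit(
        ea_kj_mol=-fit.slope * GAS_CONSTANT / 1000.0,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


@dataclass
class ActivityCurve:
    """Raw activity measurements with their normalized (relative %) values."""

    condition: np.ndarray
    raw: np.ndarray
    relative: np.ndarray
    mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"condition": self.condition, "raw": self.raw, "relative": self.relative}
        )


def normalize_activity(
    raw: np.ndarray | list[float],
    mode: str = "percent-of-max",
    control: float | None = None,
    condition: np.ndarray | list | None = None,
) -> ActivityCurve:
    """Normalize raw activities to percent of the maximum or of a control.

    ``percent-of-max`` suits optimum curves (the optimum reads 100%);
    ``percent-of-control`` suits residual-activity stability curves, where
    ``control`` is the untreated measurement.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValidationError("empty activity curve")
    if mode == "percent-of-max":
        denom = raw.max()
        if denom <= 0:
            raise ValidationError("maximum activity must be positive")
    elif mode == "percent-of-control":
        if control is None or control <= 0:
            raise ValidationError("percent-of-control requires a positive control value")
        denom = control
    else:
        raise ValidationError(f"unknown normalization mode: {mode!r}")
    cond = np.arange(raw.size) if condition is None else np.asarray(condition)
    return ActivityCurve(cond, raw, 100.0 * raw / denom, mode)


_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def peptide_mass(sequence: str) -> float:
    """Average molecular mass (Da) of a peptide: residue masses + one water.

    Average (not monoisotopic) masses are used, matching gel-scale estimates
    such as a 42-residue fusion tag of ≈4.6 kDa.
    """
    seq = sequence.upper()
    for ch in seq:
        if ch not in _STANDARD_AA:
            raise ValidationError(f"unknown amino acid letter {ch!r}")
    if not seq:
        warnings.warn("empty sequence: returning the mass of one water molecule")
        return WATER_MASS
    return float(molecular_weight(seq, seq_type="protein", monoisotopic=False))
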