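"""Reagent quality-control computations.

Exact monoisotopic mass and protonated m/z for a molecular formula (to check
printed HRMS values for a drug–fluorophore conjugate), and the
fluorophore:antibody degree of labeling from dual-wavelength absorbance with
an acceptance band check.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "MolecularFormula",
    "ConjugateReading",
    "monoisotopic_mass",
    "mz_for_charge",
    "degree_of_labeling",
    "check_labeling_band",
    "PROTON_MASS_DA",
]

# Mass of the proton (not the 1H atom): ESI adducts add H+ with no electron.
PROTON_MASS_DA = 1.007276

# IUPAC/CODATA monoisotopic (most abundant isotope) atomic masses, Da.
MONOISOTOPIC_MASS_DA: dict[str, float] = {
    "H": 1.0078250319,
    "D": 2.0141017780,
    "B": 11.0093055,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "F": 18.9984032,
    "Na": 22.98976928,
    "Mg": 23.9850419,
    "Si": 27.9769265327,
    "P": 30.97376151,
    "S": 31.97207069,
    "Cl": 34.96885271,
    "K": 38.9637069,
    "Ca": 39.9625912,
    "Fe": 55.9349421,
    "Cu": 62.9296011,
    "Zn": 63.9291466,
    "Se": 79.9165218,
    "Br": 78.9183376,
    "I": 126.904468,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element → count mapping, e.g. C47 H60 F2 N10 O12 S."""

    element_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for el, count in self.element_counts.items():
            if not isinstance(count, int) or count < 0:
                raise ValueError(f"count for element {el!r} must be a non-negative integer")

    @classmethod
    def parse(cls, formula: str) -> "MolecularFormula":
        """Parse a Hill-style formula string such as ``"C47H60F2N10O12S"``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
            el = match.group(1)
            counts[el] = counts.get(el, 0) + (int(match.group(2)) if match.group(2) else 1)
            pos = match.end()
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        return cls(counts)


def monoisotopic_mass(formula: MolecularFormula | str) -> float:
    """Σ count · most-abundant-isotope mass, in Da."""
    if isinstance(formula, str):
        formula = MolecularFormula.parse(formula)
    mass = 0.0
    for el, count in formula.element_counts.items():
        if el not in MONOISOTOPIC_MASS_DA:
            raise ValueError(f"unknown element symbol {el!r}")
        mass += count * MONOISOTOPIC_MASS_DA[el]
    return mass


def mz_for_charge(formula: MolecularFormula | str, z: int) -> float:
    """m/z of the [M+zH]^z+ adduct, rounded to 4 decimals as HRMS reports print."""
    if z < 1:
        raise ValueError("charge z must be a positive integer")
    m = monoisotopic_mass(formula)
    return round((m + z * PROTON_MASS_DA) / z, 4)


@dataclass
class ConjugateReading:
    """Spectrophotometric readings for one antibody–dye conjugate.

    ``correction_factor`` is the dye's fractional contribution at 280 nm
    (CF = A280_dye / Amax_dye), used to correct the protein absorbance.
    """

    absorbance_max: float
    absorbance_280: float
    epsilon_dye: float
    epsilon_protein_280: float
    correction_factor: float = 0.0
    path_length_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.absorbance_max < 0 or self.absorbance_280 < 0:
            raise ValueError("absorbances must be non-negative")
        if self.epsilon_dye <= 0 or self.epsilon_protein_280 <= 0:
            raise ValueError("extinction coefficients must be positive")
        if not 0 <= self.correction_factor <= 1:
            raise ValueError("correction_factor must lie in [0, 1]")
        if self.path_length_cm <= 0:
            raise ValueError("path_length_cm must be positive")


def degree_of_labeling(reading: ConjugateReading) -> float:
    """Molar dye:protein ratio by the Beer–Lambert quotient.

    ratio = (A_max / ε_dye) / ((A_280 − CF·A_max) / ε_protein), per unit path
    length.  An over-corrected protein absorbance (≤ 0) is an error, not a
    silent infinity.
    """
    dye_molar = reading.absorbance_max / (reading.epsilon_dye * reading.path_length_cm)
    a_protein = reading.absorbance_280 - reading.correction_factor * reading.absorbance_max
    if a_protein <= 0:
        raise ValueError(
            "corrected protein absorbance is non-positive; the reading is "
            "over-corrected or protein-free"
        )
    protein_molar = a_protein / (reading.epsilon_protein_280 * reading.path_length_cm)
    return dye_molar / protein_molar


def check_labeling_band(ratio: float, low: float = 1.1, high: float = 3.3) -> bool:
    """Inclusive acceptance band for the dye:antibody ratio (default 1.1–3.3)."""
    if ratio < 0:
        raise ValueError("degree of labeling cannot be negative")
    return low <= ratio <= high
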