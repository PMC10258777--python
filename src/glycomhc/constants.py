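"""Physical constants and residue mass tables (monoisotopic, Da).

Values are fixed to six decimals and versioned here; nothing else in the
package hard-codes a mass.
"""

from __future__ import annotations

from types import MappingProxyType

MASS_TABLE_VERSION = "2023.1"

PROTON: float = 1.007276
WATER: float = 18.010565
ISOTOPE_SPACING: float = 1.00335  # C13-C12, used for monoisotopic peak errors

# 20 standard amino-acid residue masses.
AA_RESIDUE_MASSES: MappingProxyType[str, float] = MappingProxyType({
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047679,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
})

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

# Monosaccharide residue masses (glycosidic-bond residues).
MONOSACCHARIDE_MASSES: MappingProxyType[str, float] = MappingProxyType({
    "HexNAc": 203.079373,
    "Hex": 162.052824,
    "Fuc": 146.057909,
    "NeuAc": 291.095417,
    "NeuGc": 307.090331,
})

# Canonical residue order used by the composition formatter.
MONOSACCHARIDE_ORDER: tuple[str, ...] = ("HexNAc", "Hex", "Fuc", "NeuAc", "NeuGc")

# Variable modification masses.
MOD_MET_OXIDATION: float = 15.994915
MOD_NTERM_ACETYL: float = 42.010565
MOD_CYS_CYSTEINYLATION: float = 119.004099


def peptide_mass(sequence: str, mod_mass: float = 0.0) -> float:
    """Monoisotopic neutral mass of a peptide (+ total modification mass)."""
    try:
        return sum(AA_RESIDUE_MASSES[a] for a in sequence) + WATER + mod_mass
    except KeyError as exc:
        raise ValueError(f"unknown amino acid residue: {exc.args[0]!r}") from None


def mz_from_mass(neutral_mass: float, charge: int) -> float:
    """m/z of an ion of the given neutral mass and positive charge."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON) / charge


def mass_from_mz(mz: float, charge: int) -> float:
    """Neutral mass from observed m/z and charge."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz * charge - charge * PROTON


def ppm_error(observed: float, expected: float) -> float:
    """Signed mass error in parts per million."""
    return (observed - expected) / expected * 1e6
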