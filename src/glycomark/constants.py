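"""Monoisotopic mass constants for peptide m/z arithmetic.

Residue masses are the standard monoisotopic values for the 20 proteinogenic
amino-acid residues (i.e. the amino acid minus one water), fixed to five
decimals so that theoretical m/z values are reproducible to well below 1 ppm.
Modification deltas cover the three modifications that occur on tryptic
Amadori peptides from carbamidomethylated plasma digests: the Amadori
(fructosamine) adduct of one hexose on lysine, carbamidomethylation of
cysteine, and methionine oxidation.
"""

from __future__ import annotations

from enum import Enum
from types import MappingProxyType

#: Monoisotopic residue masses in Da (residue = amino acid - H2O).
RESIDUE_MASSES = MappingProxyType(
    {
        "G": 57.02146,
        "A": 71.03711,
        "S": 87.03203,
        "P": 97.05276,
        "V": 99.06841,
        "T": 101.04768,
        "C": 103.00919,
        "L": 113.08406,
        "I": 113.08406,
        "N": 114.04293,
        "D": 115.02694,
        "Q": 128.05858,
        "K": 128.09496,
        "E": 129.04259,
        "M": 131.04049,
        "H": 137.05891,
        "F": 147.06841,
        "R": 156.10111,
        "Y": 163.06333,
        "W": 186.07931,
    }
)

WATER = 18.010565
PROTON = 1.00727646
FORMALDEHYDE = 30.010565


class ModKind(str, Enum):
    """Residue modification kinds relevant to glycated plasma digests."""

    AMADORI = "AMADORI"  # +1 hexose on K (fructosamine / Amadori compound)
    CARBAMIDOMETHYL = "CARBAMIDOMETHYL"  # iodoacetamide-alkylated C
    OXIDATION = "OXIDATION"  # methionine sulfoxide


#: Monoisotopic mass shifts in Da added by each modification.
MOD_DELTAS = MappingProxyType(
    {
        ModKind.AMADORI: 162.052824,
        ModKind.CARBAMIDOMETHYL: 57.021464,
        ModKind.OXIDATION: 15.994915,
    }
)

#: Residue each modification is chemically restricted to.
MOD_TARGETS = MappingProxyType(
    {
        ModKind.AMADORI: "K",
        ModKind.CARBAMIDOMETHYL: "C",
        ModKind.OXIDATION: "M",
    }
)
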