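"""Mass arithmetic for Amadori-modified tryptic peptides.

Glycation of a lysine ε-amine by glucose yields a fructosamine (Amadori
compound), adding one hexose (+162.052824 Da) to the peptide.  Annotation of
glycated peptides in LC-MS data rests on computing theoretical m/z values of
their multiply protonated quasi-molecular ions and matching them against
observed centroids within a ppm tolerance.  This module provides the peptide
model, neutral-mass and m/z arithmetic, charge-state enumeration, in-silico
tryptic digestion (with cleavage suppression at glycated lysines), and the
diagnostic neutral-loss ladder (water and formaldehyde losses) that is
characteristic of glucose-derived Amadori compounds.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

from .constants import (
    FORMALDEHYDE,
    MOD_DELTAS,
    MOD_TARGETS,
    PROTON,
    RESIDUE_MASSES,
    WATER,
    ModKind,
)

__all__ = [
    "ModifiedPeptide",
    "IonSpecies",
    "DigestPeptide",
    "monoisotopic_mass",
    "mz_for_charge",
    "ppm_error",
    "enumerate_charge_states",
    "tryptic_digest",
    "amadori_loss_ladder",
    "parse_modified_sequence",
]

_VALID_RESIDUES = frozenset(RESIDUE_MASSES)


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with site-localized modifications.

    Parameters
    ----------
    sequence : str
        Amino-acid sequence over the 20-letter alphabet.
    modifications : tuple of (int, ModKind)
        ``(position, kind)`` pairs with 1-based residue positions.  At most
        one modification per position; AMADORI is only valid on K,
        CARBAMIDOMETHYL on C, OXIDATION on M.
    """

    sequence: str
    modifications: tuple[tuple[int, ModKind], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for ch in self.sequence:
            if ch not in _VALID_RESIDUES:
                raise ValueError(f"unknown amino-acid residue {ch!r} in sequence")
        mods = tuple((int(pos), ModKind(kind)) for pos, kind in self.modifications)
        object.__setattr__(self, "modifications", mods)
        seen: set[int] = set()
        for pos, kind in mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"modification position {pos} outside 1..{len(self.sequence)}"
                )
            if pos in seen:
                raise ValueError(f"multiple modifications at position {pos}")
            seen.add(pos)
            residue = self.sequence[pos - 1]
            if residue != MOD_TARGETS[kind]:
                raise ValueError(
                    f"{kind.value} not allowed on {residue!r} at position {pos} "
                    f"(requires {MOD_TARGETS[kind]!r})"
                )

    @property
    def amadori_positions(self) -> tuple[int, ...]:
        return tuple(p for p, k in self.modifications if k is ModKind.AMADORI)

    def __str__(self) -> str:
        marks = {p: k for p, k in self.modifications}
        out = []
        for i, ch in enumerate(self.sequence, start=1):
            out.append(ch + ("*" if i in marks else ""))
        return "".join(out)


@dataclass(frozen=True)
class IonSpecies:
    """A protonated quasi-molecular ion of a modified peptide."""

    peptide: ModifiedPeptide
    charge: int
    mz: float

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")


@dataclass(frozen=True)
class DigestPeptide:
    """A tryptic peptide with its origin span and missed-cleavage count."""

    sequence: str
    start: int  # 1-based position in the parent protein
    end: int  # 1-based, inclusive
    missed_cleavages: int


def monoisotopic_mass(peptide: ModifiedPeptide | str) -> float:
    """Neutral monoisotopic mass of a (modified) peptide in Da.

    The mass is the sum of the residue masses, one water for the termini,
    and the modification deltas.
    """
    if isinstance(peptide, str):
        peptide = ModifiedPeptide(peptide)
    mass = sum(RESIDUE_MASSES[ch] for ch in peptide.sequence) + WATER
    mass += sum(MOD_DELTAS[kind] for _, kind in peptide.modifications)
    return mass


def mz_for_charge(mass: float, charge: int) -> float:
    """m/z of the ``[M + zH]^z+`` ion for a neutral mass (Da)."""
    if mass <= 0:
        raise ValueError("neutral mass must be positive")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (mass + charge * PROTON) / charge


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


def _basic_site_count(peptide: ModifiedPeptide) -> int:
    """Count protonatable basic sites: R, H, non-glycated K, plus N-terminus."""
    amadori = set(peptide.amadori_positions)
    n = 1  # N-terminal amine
    for i, ch in enumerate(peptide.sequence, start=1):
        if ch in "RH":
            n += 1
        elif ch == "K" and i not in amadori:
            n += 1
    return n


def enumerate_charge_states(
    peptide: ModifiedPeptide,
    z_min: int = 2,
    z_max: int | None = None,
    z_cap: int = 5,
) -> list[IonSpecies]:
    """Theoretical ions for all plausible charge states of a peptide.

    When ``z_max`` is not given it defaults to one more than the number of
    basic sites (R, H, K without Amadori, N-terminus), capped at ``z_cap``;
    electrospray of tryptic peptides rarely populates higher states.
    """
    if z_max is None:
        z_max = min(z_cap, 1 + _basic_site_count(peptide))
    if z_min > z_max:
        raise ValueError(f"z_min={z_min} exceeds z_max={z_max}")
    mass = monoisotopic_mass(peptide)
    return [
        IonSpecies(peptide, z, mz_for_charge(mass, z)) for z in range(z_min, z_max + 1)
    ]


def tryptic_digest(
    protein_sequence: str,
    max_missed: int = 3,
    glycation_sites: set[int] | frozenset[int] | None = None,
    suppress_glycated: bool = True,
) -> list[DigestPeptide]:
    """In-silico tryptic digestion with missed cleavages.

    Trypsin cleaves C-terminal to K or R, but not before proline.  A glycated
    lysine (position listed in ``glycation_sites``, 1-based) carries a bulky
    Amadori adduct on its ε-amine and resists cleavage; with
    ``suppress_glycated`` those sites are not cut, which is why glycated
    tryptic peptides typically contain an internal modified lysine.

    Returns all peptides with at most ``max_missed`` internal (non-suppressed)
    cleavage sites, with their 1-based spans and missed-cleavage counts.
    """
    if not protein_sequence:
        raise ValueError("protein sequence must be non-empty")
    glycation_sites = frozenset(glycation_sites or ())

    cut_after: list[int] = []  # 1-based positions after which cleavage occurs
    n = len(protein_sequence)
    for i in range(1, n):  # no cut after the last residue
        ch = protein_sequence[i - 1]
        if ch not in "KR":
            continue
        if protein_sequence[i] == "P":
            continue
        if suppress_glycated and ch == "K" and i in glycation_sites:
            continue
        cut_after.append(i)

    boundaries = [0, *cut_after, n]
    peptides: list[DigestPeptide] = []
    for i, j in itertools.combinations(range(len(boundaries)), 2):
        missed = j - i - 1
        if missed > max_missed:
            continue
        start, end = boundaries[i] + 1, boundaries[j]
        peptides.append(
            DigestPeptide(protein_sequence[start - 1 : end], start, end, missed)
        )
    return peptides


def amadori_loss_ladder(
    ion: IonSpecies, n_water: int = 3
) -> list[tuple[str, float]]:
    """Diagnostic neutral-loss m/z ladder of a glycated precursor ion.

    Glucose-derived Amadori compounds lose up to three waters and, after the
    third water, one formaldehyde from the quasi-molecular ion.  The returned
    ladder holds ``-kH2O`` peaks for k = 1..n_water and the combined
    ``-(n_water*H2O + CH2O)`` peak, all at the precursor's charge state.
    """
    if not ion.peptide.amadori_positions:
        raise ValueError("loss ladder requires an Amadori-modified peptide")
    if n_water < 1:
        raise ValueError("n_water must be >= 1")
    ladder: list[tuple[str, float]] = []
    for k in range(1, n_water + 1):
        label = f"-{k}H2O" if k > 1 else "-H2O"
        ladder.append((label, ion.mz - k * WATER / ion.charge))
    total = n_water * WATER + FORMALDEHYDE
    ladder.append((f"-({n_water}H2O+CH2O)", ion.mz - total / ion.charge))
    return ladder


_MOD_ALIASES = {
    "AMADORI": ModKind.AMADORI,
    "AM": ModKind.AMADORI,
    "CARBAMIDOMETHYL": ModKind.CARBAMIDOMETHYL,
    "CAM": ModKind.CARBAMIDOMETHYL,
    "OXIDATION": ModKind.OXIDATION,
    "OX": ModKind.OXIDATION,
}

_STARRED = re.compile(r"([A-Z])(\*?)")


def parse_modified_sequence(text: str) -> ModifiedPeptide:
    """Parse star notation like ``VTK*C*C*TESLVNR`` into a ModifiedPeptide.

    A star after a residue marks the modification implied by its chemistry:
    ``K*`` = Amadori lysine, ``C*`` = carbamidomethyl cysteine, ``M*`` =
    methionine sulfoxide.
    """
    sequence = []
    mods: list[tuple[int, ModKind]] = []
    pos = 0
    for match in _STARRED.finditer(text):
        residue, star = match.groups()
        pos += 1
        sequence.append(residue)
        if star:
            try:
                kind = next(k for k, r in MOD_TARGETS.items() if r == residue)
            except StopIteration:
                raise ValueError(
                    f"no modification defined for starred residue {residue!r}"
                ) from None
            mods.append((pos, kind))
    if pos != len(text.replace("*", "")):
        raise ValueError(f"could not parse modified sequence {text!r}")
    return ModifiedPeptide("".join(sequence), tuple(mods))


def parse_mod_spec(sequence: str, spec: str) -> ModifiedPeptide:
    """Parse a delimited modification spec like ``K3:AMADORI;C5:CAM``."""
    mods: list[tuple[int, ModKind]] = []
    if spec.strip():
        for token in spec.split(";"):
            token = token.strip()
            if not token:
                continue
            site, _, name = token.partition(":")
            m = re.fullmatch(r"([A-Z])(\d+)", site.strip())
            if m is None or not name:
                raise ValueError(f"malformed modification token {token!r}")
            residue, pos = m.group(1), int(m.group(2))
            kind = _MOD_ALIASES.get(name.strip().upper())
            if kind is None:
                raise ValueError(f"unknown modification name {name!r}")
            if sequence[pos - 1 : pos] != residue:
                raise ValueError(
                    f"spec says {residue}{pos} but sequence has "
                    f"{sequence[pos - 1:pos] or 'nothing'!r} there"
                )
            mods.append((pos, kind))
    return ModifiedPeptide(sequence, tuple(mods))
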