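"""Peptide chemistry: monoisotopic masses, modification deltas, in-silico
fully tryptic digestion, and delta-mass / isotope-class accounting.

All masses are monoisotopic and in daltons.  The peptide mass convention
throughout is MH: the singly protonated mass, i.e. the neutral monoisotopic
peptide mass plus one hydrogen-atom mass (the convention of ion-trap search
engines that report "MH+").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ATOMIC_MASS",
    "RESIDUE_COMPOSITION",
    "ResidueMassTable",
    "Modification",
    "PeptideRecord",
    "DeltaMassBin",
    "STANDARD_MODIFICATIONS",
    "WATER",
    "PROTON",
    "NEUTRON_SPACING",
    "modification_delta",
    "peptide_mh",
    "tryptic_digest",
    "cleavage_sites",
    "classify_delta",
]

# IUPAC/CODATA monoisotopic atomic masses, Da.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Se": 79.9165213,
}

# Elemental composition of the 20 standard amino-acid residues
# (residue = amino acid minus water, as found in a peptide chain).
RESIDUE_COMPOSITION: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}


def _composition_mass(composition: Mapping[str, int],
                      atom: Mapping[str, float]) -> float:
    total = 0.0
    for element, count in composition.items():
        if element not in atom:
            raise KeyError(f"unknown element {element!r} in composition")
        total += count * atom[element]
    return total


@dataclass(frozen=True)
class ResidueMassTable:
    """Monoisotopic residue and atomic masses.

    ``residue`` maps one-letter codes to residue masses; ``atom`` maps element
    symbols to atomic masses.  Water and hydrogen are derivable from ``atom``.
    """

    residue: Mapping[str, float]
    atom: Mapping[str, float]

    @property
    def water(self) -> float:
        return 2 * self.atom["H"] + self.atom["O"]

    @property
    def hydrogen(self) -> float:
        return self.atom["H"]

    @classmethod
    def default(cls) -> "ResidueMassTable":
        residue = {
            aa: _composition_mass(comp, ATOMIC_MASS)
            for aa, comp in RESIDUE_COMPOSITION.items()
        }
        return cls(residue=residue, atom=dict(ATOMIC_MASS))


DEFAULT_TABLE = ResidueMassTable.default()
WATER = DEFAULT_TABLE.water
PROTON = DEFAULT_TABLE.hydrogen  # hydrogen-atom mass; MH = M + this

# Nominal isotope spacing used for delta-mass classification, Da.
NEUTRON_SPACING = 1.00335


def modification_delta(composition: Mapping[str, int],
                       table: ResidueMassTable = DEFAULT_TABLE) -> float:
    """Monoisotopic mass delta of an elemental composition.

    Negative counts express losses (e.g. deamidation is ``{O:1, N:-1, H:-1}``).
    Raises ``KeyError`` naming the element if one is unknown.
    """
    return _composition_mass(composition, table.atom)


@dataclass(frozen=True)
class Modification:
    """A named mass modification targeting a residue or terminus."""

    name: str
    target: str  # one-letter residue code, or "N-term"/"C-term"
    composition: Mapping[str, int]
    delta: float = field(default=0.0)

    def __post_init__(self) -> None:
        computed = modification_delta(self.composition)
        if self.delta == 0.0:
            object.__setattr__(self, "delta", computed)
        elif abs(self.delta - computed) > 1e-5:
            raise ValueError(
                f"modification {self.name}: declared delta {self.delta} "
                f"disagrees with composition mass {computed:.6f}"
            )


# Modifications accepted by the search configuration being emulated:
# carbamidomethyl (glycine-substitution-equivalent) at C, single/double
# oxidation at M/W, deamidation at N/Q.
STANDARD_MODIFICATIONS: dict[str, Modification] = {
    m.name: m
    for m in (
        Modification("CAM", "C", {"C": 2, "H": 3, "N": 1, "O": 1}),
        Modification("Oxidation", "M", {"O": 1}),
        Modification("DoubleOxidation", "W", {"O": 2}),
        Modification("Deamidation", "N", {"O": 1, "N": -1, "H": -1}),
        Modification("Hydroxyl", "C-term", {"O": 1, "H": 1}),
        Modification("Proton", "N-term", {"H": 1}),
    )
}


@dataclass
class PeptideRecord:
    """A tryptic peptide with provenance.

    ``missed_cleavages`` equals the number of internal K/R positions;
    ``mh_theoretical`` is the singly protonated monoisotopic mass including
    any modifications.
    """

    sequence: str
    modifications: list[tuple[int, Modification]] = field(default_factory=list)
    mh_theoretical: float = 0.0
    missed_cleavages: int = 0
    parent_accessions: set[str] = field(default_factory=set)
    start: int = 0  # 0-based offset in the parent protein


def peptide_mh(sequence: str,
               modifications: Sequence[tuple[int, Modification]] = (),
               table: ResidueMassTable = DEFAULT_TABLE) -> float:
    """MH of a peptide: residue masses + water + one hydrogen + mod deltas.

    ``modifications`` is a sequence of ``(position, Modification)`` with
    1-based positions (position ignored for the mass itself).
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    try:
        mass = sum(table.residue[aa] for aa in sequence)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in {sequence!r}") from exc
    mass += table.water + table.hydrogen
    for _pos, mod in modifications:
        mass += mod.delta
    return mass


def cleavage_sites(sequence: str, no_cleave_before_proline: bool = False) -> list[int]:
    """Positions after which trypsin cleaves ([RK]|[X]; optional proline rule)."""
    sites = []
    n = len(sequence)
    for i, aa in enumerate(sequence):
        if aa in "KR" and i < n - 1:
            if no_cleave_before_proline and sequence[i + 1] == "P":
                continue
            sites.append(i)
    return sites


def tryptic_digest(protein_sequence: str,
                   max_missed: int = 0,
                   accession: str | None = None,
                   no_cleave_before_proline: bool = False,
                   table: ResidueMassTable = DEFAULT_TABLE,
                   compute_mh: bool = True) -> list[PeptideRecord]:
    """Fully tryptic digest: cleave after every K or R ([RK]|[X]).

    Emits every peptide with 0..``max_missed`` missed cleavages.  An empty
    protein yields an empty list.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if not protein_sequence:
        return []
    sites = cleavage_sites(protein_sequence, no_cleave_before_proline)
    bounds = [0] + [s + 1 for s in sites] + [len(protein_sequence)]
    parents = {accession} if accession else set()
    out: list[PeptideRecord] = []
    nfrag = len(bounds) - 1
    for i in range(nfrag):
        for mc in range(0, max_missed + 1):
            j = i + mc + 1
            if j > nfrag:
                break
            seq = protein_sequence[bounds[i]:bounds[j]]
            out.append(
                PeptideRecord(
                    sequence=seq,
                    mh_theoretical=peptide_mh(seq, table=table) if compute_mh else 0.0,
                    missed_cleavages=mc,
                    parent_accessions=set(parents),
                    start=bounds[i],
                )
            )
    return out


@dataclass(frozen=True)
class DeltaMassBin:
    """Observed-minus-theoretical MH classified to the nearest isotope."""

    delta: float
    isotope_class: int
    in_band: bool


def classify_delta(observed_mh: float, theoretical_mh: float) -> DeltaMassBin:
    """Classify a precursor delta mass to an integer isotope class.

    The class is the nearest integer to delta / 1.00335; the bin is in-band
    when the residual from that class is at most 0.5 Da and the class lies in
    [-2, +4] (the range over which heavy-isotope and hydrogen-rearrangement
    precursors are accepted).  Out-of-band deltas are flagged, not dropped.
    """
    if observed_mh <= 0 or theoretical_mh <= 0:
        raise ValueError("masses must be positive")
    delta = observed_mh - theoretical_mh
    cls = int(np.rint(delta / NEUTRON_SPACING))
    residual = abs(delta - cls * NEUTRON_SPACING)
    in_band = residual <= 0.5 and -2 <= cls <= 4
    return DeltaMassBin(delta=delta, isotope_class=cls, in_band=in_band)
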