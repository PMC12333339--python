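"""Size and hydrophobicity descriptors for the chemical-space analysis.

Three descriptors locate a peptide in the space plots: exact
(monoisotopic) molecular weight in Da, the Wildman-Crippen atom-additive
logP (SlogP), and the residue count. SlogP and the graph-level
monoisotopic mass are delegated to RDKit; :func:`residue_mw` is an
independent residue-table fast path for canonical peptides that must
agree with the graph route to 1e-4 Da.

Printed-mass convention: collection reports quote peptide masses as
integers obtained by *truncating* the monoisotopic sum (G -> 75 Da,
RRPPPFFF -> 1062 Da from 1062.576); :func:`printed_mw` applies that
convention. Full-precision values are used everywhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from rdkit.Chem import Crippen, Descriptors

from .notation import MolecularGraph, PeptideSequence

__all__ = [
    "DescriptorSet",
    "exact_mw",
    "residue_mw",
    "printed_mw",
    "logp",
    "peptide_length",
    "WATER_MONOISOTOPIC",
    "RESIDUE_MONOISOTOPIC",
]

#: Monoisotopic mass of water (Da).
WATER_MONOISOTOPIC = 18.0105646863

#: Monoisotopic residue masses (Da): the mass each residue contributes to
#: a peptide chain (free amino acid minus one water).
RESIDUE_MONOISOTOPIC: dict[str, float] = {
    "G": 57.02146372,
    "A": 71.03711378,
    "S": 87.03202840,
    "P": 97.05276384,
    "V": 99.06841391,
    "T": 101.04767846,
    "C": 103.00918447,
    "L": 113.08406397,
    "I": 113.08406397,
    "N": 114.04292744,
    "D": 115.02694302,
    "Q": 128.05857750,
    "K": 128.09496301,
    "E": 129.04259308,
    "M": 131.04048460,
    "H": 137.05891186,
    "F": 147.06841391,
    "R": 156.10111102,
    "Y": 163.06332852,
    "W": 186.07931294,
}


class DescriptorError(ValueError):
    pass


@dataclass(frozen=True)
class DescriptorSet:
    """Descriptors of one peptide: monoisotopic mass (Da), SlogP, residue
    count."""

    exact_mw: float
    logp: float
    length: int

    def __post_init__(self) -> None:
        if self.exact_mw <= 0:
            raise DescriptorError("exact_mw must be positive")
        if self.length < 1:
            raise DescriptorError("length must be at least 1")


def exact_mw(g: MolecularGraph) -> float:
    """Monoisotopic molecular weight (Da) of an assembled peptide graph."""
    return Descriptors.ExactMolWt(g.mol)


def residue_mw(seq: str) -> float:
    """Monoisotopic mass (Da) of a linear canonical peptide from residue
    masses: sum of residue masses plus one water for the free termini."""
    if not seq:
        raise DescriptorError("empty sequence")
    try:
        total = sum(RESIDUE_MONOISOTOPIC[r] for r in seq)
    except KeyError as exc:
        raise DescriptorError(f"non-canonical residue {exc.args[0]!r}") from None
    return total + WATER_MONOISOTOPIC


def printed_mw(mass: float) -> int:
    """Integer mass as quoted in collection reports (truncation of the
    monoisotopic sum)."""
    return math.floor(mass)


def logp(g: MolecularGraph) -> float:
    """Wildman-Crippen atom-additive logP (SlogP) of an assembled graph.

    Deterministic for a fixed graph; peptides are treated as neutral
    (uncharged termini and side chains).
    """
    return Crippen.MolLogP(g.mol)


def peptide_length(p: PeptideSequence | str) -> int:
    """Residue count of a peptide (terminal caps excluded); accepts either
    a :class:`PeptideSequence` or a plain one-letter string."""
    if isinstance(p, str):
        if not p:
            raise DescriptorError("empty sequence")
        return len(p)
    return p.residue_count()
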