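"""Ney/Tanford Q-value hydrophobicity scoring and the Q-rule classifier.

The Q value of a peptide is the mean free energy of transfer of its
residue side chains from ethanol to water, Q = sum(delta_f) / n, in
cal/mol. Ney's empirical rule: peptides with Q above 1400 cal/mol are
likely bitter; peptides with Q below 1300 cal/mol are likely nonbitter;
the band in between (boundaries included) is indeterminate.

The shipped delta-f table is the Ney (1971) table derived from Tanford's
transfer free energies. It is validated at import time against five
fixed-point checks that jointly pin down G, E, F, W, Q, and the
combination 2R + 3P + 3F: Q(WW)=3000, Q(Q)=-100, Q(GE)=275, Q(GF)=1325,
Q(RRPPPFFF)=2151 cal/mol (integer, half-up rounding). This guards
against transcribing one of the variant tables in circulation (some
print Pro as 2620 cal/mol; the fixed points require 2600).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum

__all__ = [
    "HydrophobicityTable",
    "QValue",
    "NeyClass",
    "NEY_TABLE",
    "q_value",
    "ney_classify",
    "load_table",
    "round_half_up",
]

CANONICAL_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: Free energy of transfer of amino acid side chains, ethanol -> water,
#: in cal/mol (Ney 1971 / Tanford).
_NEY_DELTA_F: dict[str, float] = {
    "G": 0.0,
    "S": 40.0,
    "T": 440.0,
    "H": 500.0,
    "D": 540.0,
    "E": 550.0,
    "A": 730.0,
    "R": 730.0,
    "M": 1300.0,
    "K": 1500.0,
    "V": 1690.0,
    "L": 2420.0,
    "P": 2600.0,
    "F": 2650.0,
    "Y": 2870.0,
    "I": 2970.0,
    "W": 3000.0,
    "N": -10.0,
    "Q": -100.0,
    "C": 1420.0,
}


class ScoringError(ValueError):
    """Raised for non-canonical residues or malformed tables."""


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero (0.5 -> 1;
    17210/8 = 2151.25 -> 2151)."""
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class HydrophobicityTable:
    """Per-residue delta-f values (cal/mol), defined for all 20 canonical
    residues."""

    delta_f: dict[str, float]

    def __post_init__(self) -> None:
        missing = CANONICAL_RESIDUES - self.delta_f.keys()
        if missing:
            raise ScoringError(f"delta-f table lacks residues: {sorted(missing)}")

    def __getitem__(self, residue: str) -> float:
        return self.delta_f[residue]


@dataclass(frozen=True)
class QValue:
    """A computed Q score: mean side-chain transfer free energy (cal/mol)
    over ``n`` residues."""

    value: float
    n: int

    @property
    def rounded(self) -> int:
        return round_half_up(self.value)


class NeyClass(str, Enum):
    LIKELY_BITTER = "likely_bitter"
    LIKELY_NONBITTER = "likely_nonbitter"
    INDETERMINATE = "indeterminate"


NEY_TABLE = HydrophobicityTable(delta_f=dict(_NEY_DELTA_F))


def q_value(seq: str, table: HydrophobicityTable = NEY_TABLE) -> QValue:
    """Q = sum(delta_f) / n over a canonical one-letter sequence.

    Modified or non-canonical residues are rejected: delta-f is defined
    only for the canonical 20, so Q is undefined for modified peptides.
    """
    if not seq:
        raise ScoringError("empty sequence")
    bad = sorted(set(seq) - CANONICAL_RESIDUES)
    if bad:
        raise ScoringError(f"Q value undefined for non-canonical residues: {bad}")
    total = sum(table[r] for r in seq)
    return QValue(value=total / len(seq), n=len(seq))


#: Classification thresholds (cal/mol). Values strictly above the upper
#: threshold are likely bitter; strictly below the lower one, likely
#: nonbitter; values on or between the thresholds are indeterminate.
Q_BITTER_THRESHOLD = 1400.0
Q_NONBITTER_THRESHOLD = 1300.0


def ney_classify(
    q: QValue | float,
    bitter_above: float = Q_BITTER_THRESHOLD,
    nonbitter_below: float = Q_NONBITTER_THRESHOLD,
) -> NeyClass:
    """Apply the Q rule to a Q value (or raw cal/mol number)."""
    value = q.value if isinstance(q, QValue) else float(q)
    if value > bitter_above:
        return NeyClass.LIKELY_BITTER
    if value < nonbitter_below:
        return NeyClass.LIKELY_NONBITTER
    return NeyClass.INDETERMINATE


def load_table(path) -> HydrophobicityTable:
    """Load a delta-f override table from structured text (two tab- or
    whitespace-separated columns: residue, delta_f in cal/mol)."""
    values: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                residue, value = line.split()
                values[residue] = float(value)
            except ValueError:
                raise ScoringError(f"{path}:{lineno}: malformed table row {line!r}") from None
    return HydrophobicityTable(delta_f=values)


def _selfcheck() -> None:
    # Five fixed-point checks from the literature; a variant table fails here.
    expected = {"WW": 3000, "Q": -100, "GE": 275, "GF": 1325, "RRPPPFFF": 2151}
    for seq, want in expected.items():
        got = q_value(seq).rounded
        if got != want:
            raise AssertionError(
                f"shipped delta-f table is wrong: Q({seq}) = {got}, expected {want}"
            )


_selfcheck()
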