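"""Peptide string notations over a monomer library.

One internal representation — :class:`PeptideSequence` (ordered monomer
ids per chain, plus explicit connections for cycles, branches and
side-chain linkages) — sits behind three interchangeable notations:

* **extended FASTA** — the one-letter code extended with ``(D)-X`` for
  D-amino acids, bracketed tokens for modified monomers (``[pGlu]``,
  ``[Nle]``, ``[M(O)]``, ...), a ``cyclo(...)`` wrapper for head-to-tail
  cycles, and a ``gE-``/``gD-`` (``γE-``/``γD-``) prefix for
  gamma-glutamyl/gamma-aspartyl linkages;
* **HELM v2** (PEPTIDE polymers) — ``PEPTIDE1{G.F}$$$$`` with explicit
  connections such as ``PEPTIDE1,PEPTIDE1,3:R2-1:R1``;
* **BILN** — hyphen-separated monomer ids with paired parenthesised bond
  indices, e.g. ``A(1,1)-P-G(1,2)`` for a head-to-tail cyclic tripeptide.

:func:`assemble` condenses a :class:`PeptideSequence` into an RDKit
molecular graph, removing one water per amide/ester bond formed and
recording the residue of origin for every atom.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .monomers import MonomerError, MonomerLibrary

__all__ = [
    "PeptideSequence",
    "Site",
    "Connection",
    "MolecularGraph",
    "NotationError",
    "parse_fasta_extended",
    "write_fasta_extended",
    "parse_helm",
    "write_helm",
    "parse_biln",
    "write_biln",
    "convert",
    "three_to_one",
    "assemble",
]


class NotationError(ValueError):
    """Raised for malformed notation strings or invalid sequences."""


# Extended-FASTA bracket tokens -> monomer ids. The bracket convention for
# modified residues is standard; the token inventory itself is a library
# constant of this module.
FASTA_TOKEN_TABLE: dict[str, str] = {
    "[pGlu]": "pGlu",
    "[Nle]": "Nle",
    "[Nva]": "Nva",
    "[Orn]": "Orn",
    "[M(O)]": "MetO",
    "[pS]": "pS",
    "[Ac]": "Ac",
    "[Lac]": "Lac",
    "[Succ]": "Succ",
    "[OMe]": "OMe",
}
_TOKEN_FOR_ID = {v: k for k, v in FASTA_TOKEN_TABLE.items()}

#: Terminal cap monomers that do not count toward residue length.
CAP_IDS = frozenset({"Ac", "Lac", "Succ", "OMe"})


@dataclass(frozen=True, order=True)
class Site:
    """One end of a connection: chain index (0-based), residue position
    (1-based from the N-terminus), attachment label."""

    chain: int
    position: int
    label: str


@dataclass(frozen=True)
class Connection:
    """An explicit bond between two attachment points."""

    a: Site
    b: Site

    def normalized(self) -> "Connection":
        return self if self.a <= self.b else Connection(self.b, self.a)


@dataclass
class PeptideSequence:
    """Ordered monomer ids per chain plus explicit connections."""

    chains: list[list[str]]
    connections: list[Connection] = field(default_factory=list)
    annotations: dict = field(default_factory=dict, compare=False)

    def __eq__(self, other) -> bool:  # connection order is not semantic
        if not isinstance(other, PeptideSequence):
            return NotImplemented
        return self.chains == other.chains and sorted(
            c.normalized() for c in self.connections
        ) == sorted(c.normalized() for c in other.connections)

    def validate(self, lib: MonomerLibrary) -> None:
        if not self.chains or not all(self.chains):
            raise NotationError("peptide must have at least one non-empty chain")
        for chain in self.chains:
            for mid in chain:
                lib.lookup(mid)  # raises MonomerError for unknown ids
        used: set[Site] = set()
        for conn in self.connections:
            for site in (conn.a, conn.b):
                if not 0 <= site.chain < len(self.chains):
                    raise NotationError(f"connection cites chain {site.chain + 1}, none such")
                chain = self.chains[site.chain]
                if not 1 <= site.position <= len(chain):
                    raise NotationError(
                        f"connection cites residue {site.position} of a "
                        f"{len(chain)}-residue chain"
                    )
                monomer = lib.lookup(chain[site.position - 1])
                if site.label not in monomer.attachments:
                    raise NotationError(
                        f"monomer {monomer.id!r} has no attachment {site.label}"
                    )
                if site in used:
                    raise NotationError(
                        f"attachment {site.label} of residue {site.position} "
                        f"(chain {site.chain + 1}) used in more than one connection"
                    )
                used.add(site)

    def monomer_count(self) -> int:
        return sum(len(c) for c in self.chains)

    def residue_count(self) -> int:
        """Monomer count excluding terminal caps (Ac/Lac/Succ/OMe)."""
        return sum(1 for chain in self.chains for m in chain if m not in CAP_IDS)


# --------------------------------------------------------------------------
# extended FASTA

_D_TOKEN = re.compile(r"\(D\)-([A-Z])")


def parse_fasta_extended(s: str, lib: MonomerLibrary) -> PeptideSequence:
    """Parse the extended one-letter dialect into a :class:`PeptideSequence`.

    ``(D)-X`` maps to the D-monomer ``dX``; bracketed tokens map through
    :data:`FASTA_TOKEN_TABLE`; ``cyclo(...)`` adds a head-to-tail
    connection; a leading ``gE-``/``gD-`` (or ``γE-``/``γD-``) builds the
    gamma-linked structure (side-chain carboxyl of Glu/Asp to the amine of
    the following residue).
    """
    s = s.strip()
    if not s:
        raise NotationError("empty extended-FASTA string")
    cyclic = False
    if s.startswith("cyclo(") and s.endswith(")"):
        cyclic = True
        s = s[len("cyclo(") : -1]
    gamma: str | None = None
    for prefix, mid in (("γE-", "E"), ("gE-", "E"), ("γD-", "D"), ("gD-", "D")):
        if s.startswith(prefix):
            gamma = mid
            s = s[len(prefix) :]
            break
    chain: list[str] = []
    i = 0
    while i < len(s):
        ch = s[i]
        if ch in "- ":
            i += 1
            continue
        m = _D_TOKEN.match(s, i)
        if m:
            mid = "d" + m.group(1)
            if mid not in lib:
                raise NotationError(f"unknown D-monomer token {m.group(0)!r} at position {i}")
            chain.append(mid)
            i = m.end()
            continue
        if ch == "[":
            j = s.find("]", i)
            if j < 0:
                raise NotationError(f"unterminated bracket token at position {i}")
            token = s[i : j + 1]
            if token not in FASTA_TOKEN_TABLE:
                raise NotationError(f"unknown bracket token {token!r} at position {i}")
            chain.append(FASTA_TOKEN_TABLE[token])
            i = j + 1
            continue
        if ch.isalpha() and ch.isupper() and ch in lib:
            chain.append(ch)
            i += 1
            continue
        raise NotationError(f"unknown token {ch!r} at position {i}")
    if not chain:
        raise NotationError("extended-FASTA string contains no residues")
    connections: list[Connection] = []
    if gamma is not None:
        # gamma-linked: Glu/Asp in its own chain, side-chain acid to the
        # amine of the first residue of the remainder.
        p = PeptideSequence(chains=[[gamma], chain], connections=[
            Connection(Site(0, 1, "R3"), Site(1, 1, "R1"))
        ])
        p.validate(lib)
        return p
    if cyclic:
        connections.append(
            Connection(Site(0, len(chain), "R2"), Site(0, 1, "R1"))
        )
    p = PeptideSequence(chains=[chain], connections=connections)
    p.validate(lib)
    return p


def write_fasta_extended(p: PeptideSequence, lib: MonomerLibrary) -> str:
    """Emit the extended one-letter dialect (inverse of the parser for the
    structures the dialect can express)."""

    def token(mid: str) -> str:
        monomer = lib.lookup(mid)
        if monomer.natural and monomer.one_letter:
            return monomer.one_letter
        if mid in _TOKEN_FOR_ID:
            return _TOKEN_FOR_ID[mid]
        if mid.startswith("d") and len(mid) == 2:
            return f"(D)-{mid[1]}"
        raise NotationError(f"monomer {mid!r} has no extended-FASTA token")

    if len(p.chains) == 2 and len(p.chains[0]) == 1 and p.chains[0][0] in ("E", "D"):
        conns = [c.normalized() for c in p.connections]
        want = Connection(Site(0, 1, "R3"), Site(1, 1, "R1")).normalized()
        if conns == [want]:
            return f"g{p.chains[0][0]}-" + "".join(token(m) for m in p.chains[1])
    if len(p.chains) != 1:
        raise NotationError("extended FASTA supports one chain (plus gamma prefix)")
    chain = p.chains[0]
    body = "".join(token(m) for m in chain)
    if not p.connections:
        return body
    cycle = Connection(Site(0, len(chain), "R2"), Site(0, 1, "R1")).normalized()
    if [c.normalized() for c in p.connections] == [cycle]:
        return f"cyclo({body})"
    raise NotationError("extended FASTA cannot express these connections")


# --------------------------------------------------------------------------
# HELM v2 (PEPTIDE subset)

_HELM_POLYMER = re.compile(r"^PEPTIDE(\d+)\{(.*)\}$")
_HELM_CONN = re.compile(r"^PEPTIDE(\d+),PEPTIDE(\d+),(\d+):(R\d)-(\d+):(R\d)$")


def _split_helm_monomers(body: str) -> list[str]:
    tokens = []
    for tok in body.split("."):
        tok = tok.strip()
        if tok.startswith("[") and tok.endswith("]"):
            tok = tok[1:-1]
        if not tok:
            raise NotationError(f"empty monomer token in polymer body {body!r}")
        tokens.append(tok)
    return tokens


def parse_helm(s: str, lib: MonomerLibrary) -> PeptideSequence:
    """Parse a HELM v2 string (simple PEPTIDE polymers + connections)."""
    s = s.strip()
    if s.endswith("V2.0"):  # optional trailing version section
        s = s[: -len("V2.0")]
    sections = s.split("$")
    if len(sections) < 2 or not sections[0]:
        raise NotationError("not a complete HELM string (polymer and connection sections required)")
    chains: list[list[str]] = []
    index_of: dict[int, int] = {}
    for entry in sections[0].split("|"):
        m = _HELM_POLYMER.match(entry.strip())
        if not m:
            raise NotationError(f"unsupported HELM polymer entry {entry!r}")
        index_of[int(m.group(1))] = len(chains)
        chains.append(_split_helm_monomers(m.group(2)))
    connections: list[Connection] = []
    if sections[1]:
        for entry in sections[1].split("|"):
            m = _HELM_CONN.match(entry.strip())
            if not m:
                raise NotationError(f"malformed HELM connection {entry!r}")
            p1, p2 = int(m.group(1)), int(m.group(2))
            if p1 not in index_of or p2 not in index_of:
                raise NotationError(f"HELM connection {entry!r} cites an undefined polymer")
            connections.append(
                Connection(
                    Site(index_of[p1], int(m.group(3)), m.group(4)),
                    Site(index_of[p2], int(m.group(5)), m.group(6)),
                )
            )
    p = PeptideSequence(chains=chains, connections=connections)
    p.validate(lib)
    return p


def write_helm(p: PeptideSequence) -> str:
    """Emit a canonical HELM v2 string (chains in input order; connections
    sorted lexicographically so the output is bit-stable)."""
    polymers = []
    for chain in p.chains:
        body = ".".join(m if len(m) == 1 else f"[{m}]" for m in chain)
        polymers.append(f"PEPTIDE{len(polymers) + 1}{{{body}}}")
    conns = sorted(
        f"PEPTIDE{c.a.chain + 1},PEPTIDE{c.b.chain + 1},"
        f"{c.a.position}:{c.a.label}-{c.b.position}:{c.b.label}"
        for c in (c.normalized() for c in p.connections)
    )
    return f"{'|'.join(polymers)}${'|'.join(conns)}$$$"


# --------------------------------------------------------------------------
# BILN

_BILN_MONOMER = re.compile(r"^([^().\-]+)((?:\(\d+,R?\d\))*)$")
_BILN_BOND = re.compile(r"\((\d+),R?(\d)\)")


def parse_biln(s: str, lib: MonomerLibrary) -> PeptideSequence:
    """Parse a BILN string: hyphen-separated monomer ids per chain, chains
    separated by ``.``, explicit bonds as paired ``(index,Rn)`` suffixes."""
    s = s.strip()
    if not s:
        raise NotationError("empty BILN string")
    chains: list[list[str]] = []
    bond_sites: dict[int, list[Site]] = {}
    for chain_text in s.split("."):
        chain: list[str] = []
        for tok in chain_text.split("-"):
            m = _BILN_MONOMER.match(tok.strip())
            if not m:
                raise NotationError(f"malformed BILN monomer token {tok!r}")
            chain.append(m.group(1))
            for idx, label in _BILN_BOND.findall(m.group(2)):
                bond_sites.setdefault(int(idx), []).append(
                    Site(len(chains), len(chain), f"R{label}")
                )
        chains.append(chain)
    connections = []
    for idx, sites in sorted(bond_sites.items()):
        if len(sites) != 2:
            raise NotationError(
                f"BILN bond index {idx} appears {len(sites)} time(s); it must pair exactly two sites"
            )
        connections.append(Connection(sites[0], sites[1]))
    p = PeptideSequence(chains=chains, connections=connections)
    p.validate(lib)
    return p


def write_biln(p: PeptideSequence) -> str:
    """Emit a canonical BILN string (bond indices numbered in sorted
    connection order)."""
    suffixes: dict[tuple[int, int], list[str]] = {}
    for i, conn in enumerate(
        sorted((c.normalized() for c in p.connections)), start=1
    ):
        for site in (conn.a, conn.b):
            suffixes.setdefault((site.chain, site.position), []).append(
                f"({i},{site.label[1]})"
            )
    chain_texts = []
    for ci, chain in enumerate(p.chains):
        toks = [
            mid + "".join(suffixes.get((ci, pos), []))
            for pos, mid in enumerate(chain, start=1)
        ]
        chain_texts.append("-".join(toks))
    return ".".join(chain_texts)


# --------------------------------------------------------------------------
# conversion and three-letter codes

_PARSERS = {"fasta": parse_fasta_extended, "helm": parse_helm, "biln": parse_biln}
_WRITERS = {
    "fasta": lambda p, lib: write_fasta_extended(p, lib),
    "helm": lambda p, lib: write_helm(p),
    "biln": lambda p, lib: write_biln(p),
}


def convert(s: str, from_notation: str, to_notation: str, lib: MonomerLibrary) -> str:
    """Convert a peptide string between notations (semantically lossless:
    parsing the output under the target notation reproduces the input's
    :class:`PeptideSequence`)."""
    if from_notation == to_notation:
        raise NotationError("source and target notation must differ")
    try:
        parser = _PARSERS[from_notation]
        writer = _WRITERS[to_notation]
    except KeyError as exc:
        raise NotationError(f"unknown notation {exc.args[0]!r}") from None
    return writer(parser(s, lib), lib)


def three_to_one(s: str) -> str:
    """Convert hyphen- or space-delimited three-letter residue codes to the
    one-letter string (``"Gly-Phe"`` -> ``"GF"``)."""
    from Bio.Data.IUPACData import protein_letters_3to1

    parts = [p for p in re.split(r"[-\s]+", s.strip()) if p]
    if not parts:
        raise NotationError("empty three-letter sequence")
    out = []
    for part in parts:
        code = part.capitalize()
        if code not in protein_letters_3to1:
            raise NotationError(f"unknown three-letter code {part!r}")
        out.append(protein_letters_3to1[code])
    return "".join(out)


# --------------------------------------------------------------------------
# assembly

@dataclass
class MolecularGraph:
    """Assembled peptide: RDKit molecule plus per-atom residue provenance
    ``(chain index, 1-based residue position)``."""

    mol: Chem.Mol
    provenance: list[tuple[int, int]]

    @property
    def formula(self) -> str:
        return rdMolDescriptors.CalcMolFormula(self.mol)


def _find_hydroxyl(mol: Chem.RWMol, acid_atom: int, context: str) -> int:
    """Locate the leaving hydroxyl oxygen on an acid attachment atom."""
    atom = mol.GetAtomWithIdx(acid_atom)
    for nb in atom.GetNeighbors():
        bond = mol.GetBondBetweenAtoms(acid_atom, nb.GetIdx())
        if (
            nb.GetSymbol() == "O"
            and nb.GetDegree() == 1
            and bond.GetBondType() == Chem.BondType.SINGLE
            and nb.GetFormalCharge() == 0
        ):
            return nb.GetIdx()
    raise NotationError(f"{context}: no free hydroxyl left at the acid attachment")


def assemble(p: PeptideSequence, lib: MonomerLibrary) -> MolecularGraph:
    """Condense a peptide into its molecular graph.

    Successive residues within a chain are joined R2 (acid) to R1 (amine)
    of the next residue; explicit connections join the cited attachments.
    Each bond formed removes the acid hydroxyl while the amine-side atom
    loses one (implicit) hydrogen — one water per bond, so the assembled
    formula obeys the water-loss law exactly.
    """
    p.validate(lib)
    combined = Chem.RWMol()
    offset: dict[tuple[int, int], int] = {}
    provenance: list[tuple[int, int]] = []
    for ci, chain in enumerate(p.chains):
        for pos, mid in enumerate(chain, start=1):
            frag = lib.lookup(mid).mol()
            offset[(ci, pos)] = combined.GetNumAtoms()
            combined.InsertMol(frag)
            provenance.extend([(ci, pos)] * frag.GetNumAtoms())

    used: set[tuple[int, int, str]] = set()

    def attachment_atom(ci: int, pos: int, label: str) -> tuple[int, str]:
        mid = p.chains[ci][pos - 1]
        monomer = lib.lookup(mid)
        if label not in monomer.attachments:
            raise NotationError(
                f"monomer {mid!r} (chain {ci + 1}, residue {pos}) lacks attachment {label}"
            )
        key = (ci, pos, label)
        if key in used:
            raise NotationError(
                f"attachment {label} of residue {pos} (chain {ci + 1}) reused"
            )
        used.add(key)
        att = monomer.attachments[label]
        return offset[(ci, pos)] + att.atom, att.leaving

    bonds: list[tuple[int, int]] = []  # (acid atom, amine atom), global indices
    for ci, chain in enumerate(p.chains):
        for pos in range(1, len(chain)):
            acid, leaving_a = attachment_atom(ci, pos, "R2")
            amine, leaving_b = attachment_atom(ci, pos + 1, "R1")
            bonds.append((acid, amine))
    for conn in p.connections:
        site_a, site_b = conn.a, conn.b
        atom_a, leave_a = attachment_atom(site_a.chain, site_a.position, site_a.label)
        atom_b, leave_b = attachment_atom(site_b.chain, site_b.position, site_b.label)
        if {leave_a, leave_b} != {"OH", "H"}:
            raise NotationError(
                "connection must pair an acid (OH-leaving) attachment with an "
                f"amine/hydroxyl (H-leaving) attachment, got {leave_a}/{leave_b}"
            )
        if leave_a == "OH":
            bonds.append((atom_a, atom_b))
        else:
            bonds.append((atom_b, atom_a))

    to_remove = []
    for acid, amine in bonds:
        to_remove.append(_find_hydroxyl(combined, acid, f"bond {acid}-{amine}"))
        combined.AddBond(acid, amine, Chem.BondType.SINGLE)
    for idx in sorted(to_remove, reverse=True):
        combined.RemoveAtom(idx)
        del provenance[idx]

    mol = combined.GetMol()
    Chem.SanitizeMol(mol)
    return MolecularGraph(mol=mol, provenance=provenance)
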