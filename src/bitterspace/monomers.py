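"""Chemical building blocks for peptide assembly.

A :class:`Monomer` is a capped small molecule (free amine, free acid) with
labelled attachment points following the HELM monomer convention:

* ``R1`` — backbone amine side (leaving group: one hydrogen),
* ``R2`` — backbone acid side (leaving group: hydroxyl),
* ``R3`` — side-chain attachment where present (e.g. the side-chain
  carboxyl of Glu/Asp used by gamma-linked peptides).

Condensation at an R2/R3 acid attachment removes the hydroxyl; together
with the amine hydrogen this eliminates one water per amide (or ester)
bond formed, which keeps assembled masses exact.

The package ships a versioned core library (the 20 canonical L-amino
acids plus monomers for the modification classes that occur in bitter
peptide collections: D-amino acids, pyroglutamate, norleucine/norvaline,
ornithine, methionine sulfoxide, phosphoserine, and terminal acyl/ester
caps). User libraries are merged at load time; user entries take
precedence over the shipped core set.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

from rdkit import Chem

__all__ = [
    "Monomer",
    "MonomerLibrary",
    "MonomerError",
    "load_library",
    "core_library",
    "register_monomer",
    "write_library",
]

CANONICAL_ONE_LETTER = set("ACDEFGHIKLMNPQRSTVWY")

_LIBRARY_COLUMNS = ["id", "name", "smiles", "attachments", "natural", "one_letter", "terminal"]


class MonomerError(ValueError):
    """Raised for malformed monomer records, unknown ids, or id conflicts."""


@dataclass(frozen=True)
class Attachment:
    """One labelled attachment point: atom index plus leaving-group kind."""

    atom: int
    leaving: str  # "H" (amine side) or "OH" (acid side)


@dataclass(frozen=True)
class Monomer:
    """A single chemical building block.

    Parameters
    ----------
    id:
        Short unique identifier (case-sensitive), e.g. ``"G"`` or ``"Nle"``.
    name:
        Human-readable name.
    smiles:
        Structure of the capped monomer; must parse to a valid molecule.
    attachments:
        Map of attachment label (``R1``/``R2``/``R3``) to :class:`Attachment`.
    natural:
        True for the 20 canonical L-amino acids.
    one_letter:
        Single-character code, canonical residues only.
    terminal:
        True for chain caps that legitimately expose a single attachment
        point (N-terminal acyl caps expose only R2, C-terminal ester caps
        only R1).
    """

    id: str
    name: str
    smiles: str
    attachments: dict[str, Attachment]
    natural: bool = False
    one_letter: str | None = None
    terminal: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise MonomerError("monomer id must be non-empty")
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise MonomerError(f"monomer {self.id!r}: structure does not parse: {self.smiles!r}")
        n_atoms = mol.GetNumAtoms()
        for label, att in self.attachments.items():
            if label not in ("R1", "R2", "R3"):
                raise MonomerError(f"monomer {self.id!r}: unknown attachment label {label!r}")
            if not 0 <= att.atom < n_atoms:
                raise MonomerError(
                    f"monomer {self.id!r}: attachment {label} atom {att.atom} "
                    f"outside molecule ({n_atoms} atoms)"
                )
        if not self.terminal and not {"R1", "R2"} <= self.attachments.keys():
            raise MonomerError(
                f"monomer {self.id!r}: chain monomers must expose R1 and R2 "
                "(flag terminal caps explicitly)"
            )
        if self.terminal and not self.attachments:
            raise MonomerError(f"monomer {self.id!r}: terminal cap needs at least one attachment")
        if self.one_letter is not None and len(self.one_letter) != 1:
            raise MonomerError(f"monomer {self.id!r}: one_letter must be a single character")

    def mol(self) -> Chem.Mol:
        """Return a fresh RDKit molecule of the capped monomer."""
        return Chem.MolFromSmiles(self.smiles)


@dataclass(frozen=True)
class MonomerLibrary:
    """Immutable id -> :class:`Monomer` map with total, checked lookup."""

    entries: dict[str, Monomer] = field(default_factory=dict)
    version: str = "unversioned"

    def __contains__(self, monomer_id: str) -> bool:
        return monomer_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, monomer_id: str) -> Monomer:
        try:
            return self.entries[monomer_id]
        except KeyError:
            raise MonomerError(f"unknown monomer id {monomer_id!r}") from None

    def by_one_letter(self, code: str) -> Monomer:
        for m in self.entries.values():
            if m.natural and m.one_letter == code:
                return m
        raise MonomerError(f"no natural monomer with one-letter code {code!r}")


def _parse_attachments(text: str, monomer_id: str) -> dict[str, Attachment]:
    atts: dict[str, Attachment] = {}
    for part in filter(None, (p.strip() for p in text.split(";"))):
        try:
            label, atom, leaving = part.split(":")
            atts[label] = Attachment(atom=int(atom), leaving=leaving)
        except ValueError:
            raise MonomerError(
                f"monomer {monomer_id!r}: malformed attachment field {part!r}"
            ) from None
    return atts


def _attachments_str(atts: dict[str, Attachment]) -> str:
    return ";".join(f"{label}:{a.atom}:{a.leaving}" for label, a in sorted(atts.items()))


def _validate_entries(monomers: list[Monomer]) -> dict[str, Monomer]:
    entries: dict[str, Monomer] = {}
    for m in monomers:
        if m.id in entries:
            raise MonomerError(f"duplicate monomer id {m.id!r}")
        entries[m.id] = m
    one_letters = [m.one_letter for m in monomers if m.natural and m.one_letter]
    if len(one_letters) != len(set(one_letters)):
        raise MonomerError("one-letter codes of natural monomers must be unique")
    return entries


def _read_structured_text(lines: list[str], origin: str) -> tuple[list[Monomer], str]:
    version = "unversioned"
    rows = []
    header: list[str] | None = None
    for line in lines:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            comment = line.lstrip("# ").strip()
            if comment:
                version = comment
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            missing = {"id", "smiles", "attachments"} - set(header)
            if missing:
                raise MonomerError(f"{origin}: missing columns {sorted(missing)}")
            continue
        rows.append(dict(zip(header, fields)))
    monomers = []
    for row in rows:
        monomers.append(
            Monomer(
                id=row["id"],
                name=row.get("name", row["id"]),
                smiles=row["smiles"],
                attachments=_parse_attachments(row["attachments"], row["id"]),
                natural=row.get("natural", "0") == "1",
                one_letter=row.get("one_letter") or None,
                terminal=row.get("terminal", "0") == "1",
            )
        )
    return monomers, version


def _read_sdf(path: str) -> tuple[list[Monomer], str]:
    monomers = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise MonomerError(f"{path}: record {i + 1} does not parse as a molecule")
        props = mol.GetPropsAsDict()
        if "id" not in props:
            raise MonomerError(f"{path}: record {i + 1} lacks an 'id' data field")
        mid = str(props["id"])
        if "attachments" not in props:
            raise MonomerError(f"{path}: monomer {mid!r} lacks an 'attachments' data field")
        monomers.append(
            Monomer(
                id=mid,
                name=str(props.get("name", mid)),
                smiles=Chem.MolToSmiles(mol, canonical=False),
                attachments=_parse_attachments(str(props["attachments"]), mid),
                natural=str(props.get("natural", "0")) == "1",
                one_letter=str(props["one_letter"]) if props.get("one_letter") else None,
                terminal=str(props.get("terminal", "0")) == "1",
            )
        )
    return monomers, "sdf-import"


def core_library() -> MonomerLibrary:
    """Load the library shipped with the package (canonical 20 + extensions)."""
    ref = importlib.resources.files("bitterspace").joinpath("data/monomers.tsv")
    monomers, version = _read_structured_text(ref.read_text().splitlines(), "core library")
    lib = MonomerLibrary(entries=_validate_entries(monomers), version=version)
    missing = CANONICAL_ONE_LETTER - {
        m.one_letter for m in lib.entries.values() if m.natural and m.one_letter
    }
    if missing:  # shipped data must always carry the canonical core
        raise MonomerError(f"core library lacks canonical residues: {sorted(missing)}")
    return lib


def load_library(path, format: str = "structured-text", merge_core: bool = True) -> MonomerLibrary:
    """Load a monomer library from ``path``.

    ``format`` is ``"structured-text"`` (tab-separated: id, name, smiles,
    attachments, natural, one_letter, terminal) or ``"sdf"`` (one MolBlock
    per monomer with the same metadata as SDF data fields). With
    ``merge_core`` (default) the shipped canonical set is merged in, file
    entries taking precedence; duplicate ids *within* the file are always
    an error.
    """
    if format == "structured-text":
        with open(path) as fh:
            monomers, version = _read_structured_text(fh.readlines(), str(path))
    elif format == "sdf":
        monomers, version = _read_sdf(path)
    else:
        raise MonomerError(f"unknown library format {format!r}")
    entries = _validate_entries(monomers)  # duplicates in the file are conflicts
    if merge_core:
        merged = dict(core_library().entries)
        merged.update(entries)  # user entries shadow core entries
        entries = _validate_entries(list(merged.values()))
    return MonomerLibrary(entries=entries, version=version)


def register_monomer(lib: MonomerLibrary, monomer: Monomer) -> MonomerLibrary:
    """Return a new library containing ``monomer``; the input is unchanged."""
    if monomer.id in lib.entries:
        raise MonomerError(f"monomer id {monomer.id!r} already registered")
    entries = dict(lib.entries)
    entries[monomer.id] = monomer
    return replace(lib, entries=entries)


def write_library(lib: MonomerLibrary, path) -> None:
    """Serialize a library to the structured-text format read by load_library."""
    with open(path, "w") as fh:
        fh.write(f"# {lib.version}\n")
        fh.write("\t".join(_LIBRARY_COLUMNS) + "\n")
        for m in lib.entries.values():
            fh.write(
                "\t".join(
                    [
                        m.id,
                        m.name,
                        m.smiles,
                        _attachments_str(m.attachments),
                        "1" if m.natural else "0",
                        m.one_letter or "",
                        "1" if m.terminal else "0",
                    ]
                )
                + "\n"
            )
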