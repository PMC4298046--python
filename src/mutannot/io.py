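"""Readers/writers for sequences, structures, alignments and mutation lists.

The in-memory model is deliberately small: a :class:`StructureModel` is an
ordered list of chains, each an ordered list of :class:`Residue`, each holding
:class:`Atom` records with Cartesian coordinates in Angstrom.  Alternate
conformations are resolved at parse time (highest occupancy wins, ties broken
by altloc letter) so every atom appears exactly once, and only the first model
of a multi-model file is kept.

Mutations are expressed in 1-based coordinates of the query (UniProt-style)
protein sequence; structure residues keep their author numbering throughout.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "ProteinSequence",
    "MutationRecord",
    "MutationParseError",
    "MutationValidationError",
    "FormatError",
    "parse_substitution",
    "format_substitution",
    "validate_mutation",
    "read_structure",
    "write_structure",
    "read_fasta",
    "write_fasta",
    "read_msa",
    "read_mutations",
    "chain_sequence",
]

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

WATER_NAMES = {"HOH", "WAT"}


class FormatError(ValueError):
    """A file does not satisfy the named standard (ragged MSA, empty PDB...)."""


class MutationParseError(ValueError):
    """A mutation string cannot be interpreted."""


class MutationValidationError(ValueError):
    """A parsed mutation is internally inconsistent (e.g. silent substitution)."""


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    coords: tuple[float, float, float]
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.serial} {self.name!r} has empty element")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"atom {self.serial} {self.name!r} has non-finite coords")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    number: int
    icode: str
    name: str
    kind: str  # amino-acid | nucleotide | hetero | water
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.name}{self.number}{self.icode.strip()}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        """One-letter code; non-standard residues map to their parent (MSE -> M)."""
        if self.name in AA3_TO_1:
            return AA3_TO_1[self.name]
        info = gemmi.find_tabulated_residue(self.name)
        if info is not None and info.is_amino_acid():
            code = info.one_letter_code.upper()
            return code if code.isalpha() else "X"
        return "X"


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def amino_acids(self) -> list[Residue]:
        return [r for r in self.residues if r.kind == "amino-acid"]


@dataclass
class StructureModel:
    id: str
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id!r}")

    def residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c.residues


@dataclass(frozen=True)
class ProteinSequence:
    """A 1-based protein sequence over the 20 standard residues plus X."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - set(AA1_TO_3) - {"X"}
        if bad:
            raise ValueError(f"sequence {self.id!r} has invalid letters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def at(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise IndexError(f"position {position} outside 1..{len(self.residues)}")
        return self.residues[position - 1]


@dataclass(frozen=True)
class MutationRecord:
    protein_id: str
    wt: str
    position: int
    mut: str
    kind: str  # substitution | deletion | insertion | frameshift
    raw: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise MutationValidationError(f"{self.raw!r}: position must be >= 1")
        if self.kind == "substitution" and self.wt == self.mut:
            raise MutationValidationError(
                f"{self.raw!r}: silent substitution ({self.wt} -> {self.mut})"
            )

    @property
    def short(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"


_RES3 = "|".join(AA3_TO_1)
_SUBST_RE = re.compile(rf"^({_RES3})(\d+)({_RES3})$", re.IGNORECASE)
_FRAMESHIFT_RE = re.compile(rf"^({_RES3})(\d+)({_RES3})fsX?\d*$", re.IGNORECASE)
_DELETION_RE = re.compile(rf"^({_RES3})(\d+)[-–]({_RES3})(\d+)(?:del)?$", re.IGNORECASE)
_INSERTION_RE = re.compile(rf"^({_RES3})(\d+)_({_RES3})(\d+)ins([A-Za-z]+)$", re.IGNORECASE)


def _aa1(code3: str, raw: str) -> str:
    try:
        return AA3_TO_1[code3.capitalize().upper()]
    except KeyError:
        raise MutationParseError(f"{raw!r}: unknown residue code {code3!r}") from None


def parse_substitution(text: str, protein_id: str = "") -> MutationRecord:
    """Parse a protein-level mutation string into a :class:`MutationRecord`.

    Accepted dialects: ``Ala111Val`` (substitution), ``Tyr173SerfsX7``
    (frameshift), ``Val153-Val156`` (range deletion) and
    ``Thr426_Arg427insL`` (insertion).  Three-letter codes are converted to
    one-letter; silent substitutions are rejected.
    """
    raw = text.strip()
    if m := _FRAMESHIFT_RE.match(raw):
        return MutationRecord(protein_id, _aa1(m[1], raw), int(m[2]),
                              _aa1(m[3], raw), "frameshift", raw)
    if m := _INSERTION_RE.match(raw):
        return MutationRecord(protein_id, _aa1(m[1], raw), int(m[2]),
                              m[5].upper(), "insertion", raw)
    if m := _DELETION_RE.match(raw):
        return MutationRecord(protein_id, _aa1(m[1], raw), int(m[2]),
                              "-", "deletion", raw)
    if m := _SUBST_RE.match(raw):
        return MutationRecord(protein_id, _aa1(m[1], raw), int(m[2]),
                              _aa1(m[3], raw), "substitution", raw)
    # three-letter-looking tokens with an unknown code get a clearer error
    if re.match(r"^[A-Za-z]{3}\d+[A-Za-z]{3}$", raw):
        raise MutationParseError(f"{raw!r}: unknown residue code")
    raise MutationParseError(f"cannot parse mutation string {raw!r}")


def format_substitution(m: MutationRecord) -> str:
    """Inverse of :func:`parse_substitution` for substitution records."""
    if m.kind != "substitution":
        return m.raw
    return f"{AA1_TO_3[m.wt].capitalize()}{m.position}{AA1_TO_3[m.mut].capitalize()}"


def validate_mutation(seq: ProteinSequence, m: MutationRecord) -> tuple[bool, str]:
    """Check that the wild-type residue of ``m`` matches ``seq`` at its position."""
    if not 1 <= m.position <= len(seq):
        raise MutationValidationError(
            f"{m.raw!r}: position {m.position} outside sequence "
            f"{seq.id!r} (length {len(seq)})"
        )
    observed = seq.at(m.position)
    if observed == m.wt:
        return True, "ok"
    return False, (
        f"{m.raw!r}: expected {m.wt} at position {m.position} of {seq.id!r}, "
        f"found {observed}"
    )


# ---------------------------------------------------------------------------
# structures


def _residue_kind(name: str) -> str:
    if name in WATER_NAMES:
        return "water"
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.is_amino_acid():
        return "amino-acid"
    if info is not None and info.is_nucleic_acid():
        return "nucleotide"
    return "hetero"


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    # highest occupancy wins; ties go to the alphabetically first altloc
    by_name: dict[str, Atom] = {}
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None:
            by_name[a.name] = a
        elif (a.occupancy, prev.altloc or "~") > (prev.occupancy, a.altloc or "~"):
            by_name[a.name] = a
    return list(by_name.values())


def read_structure(path: str | Path) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel` (first model only)."""
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise FormatError(f"{path}: no models")
    model = st[0]
    out = StructureModel(id=st.name or Path(path).stem)
    n_aa = 0
    for gchain in model:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            atoms = [
                Atom(
                    serial=ga.serial,
                    name=ga.name,
                    element=ga.element.name or "X",
                    coords=(ga.pos.x, ga.pos.y, ga.pos.z),
                    altloc=ga.altloc if ga.altloc != "\0" else "",
                    occupancy=ga.occ,
                )
                for ga in gres
            ]
            kind = _residue_kind(gres.name)
            if kind == "amino-acid":
                n_aa += 1
            chain.residues.append(
                Residue(
                    chain_id=gchain.name,
                    number=gres.seqid.num,
                    icode=(gres.seqid.icode or "").strip(),
                    name=gres.name,
                    kind=kind,
                    atoms=_resolve_altlocs(atoms),
                )
            )
        if chain.residues:
            out.chains.append(chain)
    if n_aa == 0:
        raise FormatError(f"{path}: structure contains no amino-acid residues")
    return out


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a :class:`StructureModel` as a single-model PDB file."""
    st = gemmi.Structure()
    st.name = model.id
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            gres.het_flag = "A" if res.kind == "amino-acid" else "H"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = a.occupancy
                ga.altloc = a.altloc or "\0"
                ga.serial = a.serial
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# sequences and alignments


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return [ProteinSequence(id=r.id, residues=str(r.seq).upper()) for r in records]


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def read_msa(path: str | Path, fmt: str | None = None):
    """Read an aligned FASTA or Clustal file into a :class:`conservation.MSA`."""
    from .conservation import MSA

    path = Path(path)
    formats = [fmt] if fmt else ["fasta", "clustal"]
    last_err: Exception | None = None
    for f in formats:
        try:
            aln = AlignIO.read(str(path), f)
            return MSA(
                ids=[r.id for r in aln],
                rows=[str(r.seq).upper() for r in aln],
            )
        except ValueError as err:
            last_err = err
    # AlignIO refuses ragged alignments; surface that as a format error
    raise FormatError(f"{path}: not a valid alignment ({last_err})")


def read_mutations(path: str | Path) -> list[MutationRecord]:
    """Read a TSV with columns protein_id, mutation[, disease] into records."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("protein_id", "mutation"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return [
        parse_substitution(row.mutation, protein_id=row.protein_id)
        for row in df.itertuples()
    ]


def chain_sequence(
    model: StructureModel, chain_id: str
) -> tuple[ProteinSequence, list[Residue]]:
    """One-letter sequence of the amino-acid residues of a chain.

    Returns the sequence together with the parallel residue list so callers
    can translate sequence indices back to author numbering.
    """
    residues = model.chain(chain_id).amino_acids()
    seq = "".join(r.one_letter for r in residues)
    return ProteinSequence(id=f"{model.id}:{chain_id}", residues=seq), residues
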