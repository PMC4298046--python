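"""Distance-based intermolecular contacts between an enzyme chain and partners.

A target-chain residue is "in contact" with a binding partner (ligand, tRNA
chain, or protein partner chain) when any of its heavy atoms lies within the
cutoff — 4.0 A by default — of any partner heavy atom.  Crystal structures
generally lack hydrogens, so only heavy atoms enter the calculation; waters
are always excluded.  The neighbour search uses a k-d tree and is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io import Residue, StructureModel

__all__ = [
    "LIGAND",
    "TRNA",
    "PARTNER_CHAIN",
    "DEFAULT_LIGAND_NAMES",
    "DEFAULT_DENY_LIST",
    "PartnerSelection",
    "ContactAnnotation",
    "contact_residues",
    "annotate_contacts",
    "trna_chains",
]

LIGAND = "LIGAND"
TRNA = "TRNA"
PARTNER_CHAIN = "PARTNER_CHAIN"

#: contact tags as they appear in annotation tables
TAG_FOR_KIND = {LIGAND: "ATP_AA", TRNA: "TRNA", PARTNER_CHAIN: "DIMER"}

#: nucleotide cofactors plus the 20 free amino acids seen as het groups
DEFAULT_LIGAND_NAMES = frozenset(
    {"ATP", "ADP", "AMP", "ANP", "ACP", "AGS"}
    | {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)

#: ions, cryoprotectants and buffer components never treated as partners
DEFAULT_DENY_LIST = frozenset(
    {"HOH", "WAT", "NA", "K", "CL", "MG", "CA", "ZN", "MN", "FE", "NI", "CU",
     "GOL", "EDO", "PEG", "PG4", "SO4", "PO4", "ACT", "DMS", "MPD", "TRS"}
)


@dataclass(frozen=True)
class PartnerSelection:
    """A labelled set of partner atoms: ligand het-groups or whole chains."""

    kind: str  # LIGAND | TRNA | PARTNER_CHAIN
    chain_ids: frozenset[str] = frozenset()
    het_names: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in TAG_FOR_KIND:
            raise ValueError(f"unknown partner kind {self.kind!r}")

    @property
    def tag(self) -> str:
        return TAG_FOR_KIND[self.kind]


@dataclass
class ContactAnnotation:
    """Per-residue contact tags on the target chain."""

    target_chain: str
    tags: dict[tuple[str, int, str], set[str]] = field(default_factory=dict)

    def tags_for(self, residue: Residue) -> set[str]:
        return self.tags.get(residue.key, set())


def _partner_atoms(
    model: StructureModel,
    target_chain: str,
    sel: PartnerSelection,
    deny: frozenset[str],
) -> np.ndarray:
    coords: list[tuple[float, float, float]] = []
    for chain in model.chains:
        for res in chain.residues:
            if res.kind == "water" or res.name in deny:
                continue
            in_chain_sel = chain.id in sel.chain_ids and chain.id != target_chain
            in_het_sel = res.kind == "hetero" and res.name in sel.het_names
            if not (in_chain_sel or in_het_sel):
                continue
            coords.extend(a.coords for a in res.atoms if a.is_heavy)
    return np.asarray(coords, dtype=float).reshape(-1, 3)


def contact_residues(
    model: StructureModel,
    target_chain: str,
    partner: PartnerSelection,
    cutoff: float = 4.0,
    deny: frozenset[str] = DEFAULT_DENY_LIST,
) -> set[tuple[str, int, str]]:
    """Residue keys of the target chain within ``cutoff`` of the partner.

    A residue is included iff the minimum heavy-atom distance between it and
    any partner atom is <= cutoff.  An empty partner selection yields an
    empty set ("no partner"), not an error.
    """
    chain = model.chain(target_chain)  # raises KeyError for unknown chains
    partner_xyz = _partner_atoms(model, target_chain, partner, deny)
    if partner_xyz.shape[0] == 0:
        return set()
    tree = cKDTree(partner_xyz)
    hits: set[tuple[str, int, str]] = set()
    for res in chain.residues:
        if res.kind == "water":
            continue
        xyz = np.asarray([a.coords for a in res.atoms if a.is_heavy], dtype=float)
        if xyz.size == 0:
            continue
        d, _ = tree.query(xyz, k=1)
        if np.min(d) <= cutoff:
            hits.add(res.key)
    return hits


def annotate_contacts(
    model: StructureModel,
    target_chain: str,
    selections: list[PartnerSelection],
    cutoff: float = 4.0,
    deny: frozenset[str] = DEFAULT_DENY_LIST,
) -> ContactAnnotation:
    """Union of per-selection contact sets, each residue tagged by partner kind.

    A residue touching several partners carries every corresponding tag.
    """
    ann = ContactAnnotation(target_chain=target_chain)
    for sel in selections:
        for key in contact_residues(model, target_chain, sel, cutoff, deny):
            ann.tags.setdefault(key, set()).add(sel.tag)
    return ann


def trna_chains(model: StructureModel, target_chain: str) -> frozenset[str]:
    """Chains whose residues are mostly nucleotides (tRNA partner candidates)."""
    out = set()
    for chain in model.chains:
        if chain.id == target_chain or not chain.residues:
            continue
        n_nt = sum(1 for r in chain.residues if r.kind == "nucleotide")
        n_poly = sum(1 for r in chain.residues if r.kind in ("nucleotide", "amino-acid"))
        if n_poly and n_nt / n_poly > 0.5:
            out.add(chain.id)
    return frozenset(out)
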