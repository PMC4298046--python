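"""Deterministic synthetic structures/MSAs and the packaged curated tables.

The generators build chemically sane poly-alanine backbones from internal
coordinates (bond lengths 1.33/1.46/1.52 A, ideal angles, chosen phi/psi),
which makes the whole pipeline testable without any external structure:
an ideal helix, a beta-hairpin, a translated two-chain dimer at a requested
interface separation, and a chain with a het-group ligand at a requested
pocket distance.  Identical parameters always give byte-identical output.

``load_curated`` returns the packaged annotation tables: the full mutation
census (63 substitutions plus the deletion/insertion/frameshift records),
the per-mutation feature values (homologue residue spread, secondary
structure, RSA with the published buried/bold flag, intermolecular
interaction, domain), and the published category letters.  Residue-spread
columns are historical data from a 2014 sequence-database snapshot and are
shipped verbatim rather than recomputed; transcription discrepancies between
the source tables are carried in ``note`` columns.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import FeatureBundle
from .conservation import MSA
from .io import (
    Atom,
    Chain,
    MutationRecord,
    ProteinSequence,
    Residue,
    StructureModel,
    parse_substitution,
)
from .pairalign import NoCoverage

__all__ = [
    "CuratedTables",
    "IntegrityError",
    "make_helix",
    "make_hairpin",
    "make_dimer",
    "make_ligand_complex",
    "make_msa",
    "load_curated",
    "curated_bundles",
    "load_reference_sequence",
]

# backbone internal coordinates (A, degrees)
_B_CN, _B_NCA, _B_CAC, _B_CO, _B_CACB = 1.33, 1.46, 1.52, 1.23, 1.52
_A_CACN, _A_CNCA, _A_NCAC, _A_CACO, _A_NCACB = 116.6, 121.9, 111.0, 120.5, 110.4

_INTERACTION_TAG = {
    "Dimerization": "DIMER",
    "ATP/amino-acid binding": "ATP_AA",
    "tRNA binding": "TRNA",
    "Anti-codon binding": "",  # domain-style label, not a substrate contact
}


class IntegrityError(RuntimeError):
    """Packaged data files do not match their recorded checksums."""


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, dihedral: float) -> np.ndarray:
    """NeRF atom placement: position D from A-B-C plus internal coordinates."""
    ang, dih = np.radians(angle), np.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [-bond * np.cos(ang),
         bond * np.sin(ang) * np.cos(dih),
         bond * np.sin(ang) * np.sin(dih)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _build_backbone(
    phi_psi: list[tuple[float, float]],
    chain_id: str = "A",
    res_name: str = "ALA",
    start_number: int = 1,
    with_cb: bool = True,
) -> StructureModel:
    """Poly-amino-acid chain from per-residue (phi, psi); omega fixed at 180."""
    n_res = len(phi_psi)
    if n_res < 4:
        raise ValueError("need at least 4 residues")
    coords: list[dict[str, np.ndarray]] = []
    for i, (phi, psi) in enumerate(phi_psi):
        atoms: dict[str, np.ndarray] = {}
        if i == 0:
            atoms["N"] = np.zeros(3)
            atoms["CA"] = np.array([_B_NCA, 0.0, 0.0])
            ang = np.radians(_A_NCAC)
            atoms["C"] = atoms["CA"] + _B_CAC * np.array([-np.cos(ang), np.sin(ang), 0.0])
        else:
            prev = coords[i - 1]
            prev_psi = phi_psi[i - 1][1]
            atoms["N"] = _place(prev["N"], prev["CA"], prev["C"], _B_CN, _A_CACN, prev_psi)
            atoms["CA"] = _place(prev["CA"], prev["C"], atoms["N"], _B_NCA, _A_CNCA, 180.0)
            atoms["C"] = _place(prev["C"], atoms["N"], atoms["CA"], _B_CAC, _A_NCAC, phi)
        coords.append(atoms)
    for i, (phi, psi) in enumerate(phi_psi):
        atoms = coords[i]
        atoms["O"] = _place(atoms["N"], atoms["CA"], atoms["C"], _B_CO, _A_CACO, psi + 180.0)
        if with_cb and res_name != "GLY":
            atoms["CB"] = _place(atoms["C"], atoms["N"], atoms["CA"], _B_CACB, _A_NCACB, 122.6)

    chain = Chain(id=chain_id)
    serial = 1
    order = ["N", "CA", "C", "O"] + (["CB"] if with_cb and res_name != "GLY" else [])
    for i, atoms in enumerate(coords):
        res = Residue(chain_id=chain_id, number=start_number + i, icode="",
                      name=res_name, kind="amino-acid")
        for name in order:
            elem = "N" if name == "N" else ("O" if name == "O" else "C")
            res.atoms.append(Atom(serial=serial, name=name, element=elem,
                                  coords=tuple(np.round(atoms[name], 3))))
            serial += 1
        chain.residues.append(res)
    return StructureModel(id="synthetic", chains=[chain])


def make_helix(n: int = 12, phi: float = -57.0, psi: float = -47.0,
               chain_id: str = "A") -> StructureModel:
    """Ideal alpha-helix (default phi/psi -57/-47) of n alanines."""
    if n < 4:
        raise ValueError("helix needs n >= 4")
    model = _build_backbone([(phi, psi)] * n, chain_id=chain_id)
    model.id = f"helix{n}"
    return model


def make_hairpin(n: int = 12) -> StructureModel:
    """Two-stranded antiparallel beta-hairpin with a two-residue turn."""
    if n < 8:
        raise ValueError("hairpin needs n >= 8")
    arm = (n - 2) // 2
    strand = (-139.0, 135.0)
    turn = [(60.0, -120.0), (-80.0, 0.0)]  # type II' turn
    phi_psi = [strand] * arm + turn + [strand] * (n - 2 - arm)
    model = _build_backbone(phi_psi)
    model.id = f"hairpin{n}"
    return model


def _min_interchain_distance(model: StructureModel) -> float:
    a = np.array([at.coords for r in model.chains[0].residues for at in r.atoms])
    b = np.array([at.coords for r in model.chains[1].residues for at in r.atoms])
    from scipy.spatial import cKDTree

    d, _ = cKDTree(a).query(b, k=1)
    return float(np.min(d))


def make_dimer(separation: float = 3.8, n: int = 12) -> StructureModel:
    """Two parallel ideal helices, chain B translated so that the minimum
    inter-chain heavy-atom distance equals ``separation`` (within 0.01 A)."""
    if separation <= 0:
        raise ValueError("separation must be positive")
    base = make_helix(n)

    def shifted(t: float) -> StructureModel:
        chain_b = Chain(id="B")
        serial = 10000
        for res in base.chains[0].residues:
            rb = Residue(chain_id="B", number=res.number, icode="", name=res.name,
                         kind="amino-acid")
            for a in res.atoms:
                rb.atoms.append(Atom(serial=serial, name=a.name, element=a.element,
                                     coords=(a.coords[0] + t, a.coords[1], a.coords[2])))
                serial += 1
            chain_b.residues.append(rb)
        return StructureModel(id=f"dimer{n}", chains=[base.chains[0], chain_b])

    lo, hi = 0.5, 100.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _min_interchain_distance(shifted(mid)) < separation:
            lo = mid
        else:
            hi = mid
    model = shifted(0.5 * (lo + hi))
    if abs(_min_interchain_distance(model) - separation) > 0.1:
        raise ValueError(f"could not realise separation {separation}")
    return model


def make_ligand_complex(pocket_distance: float = 3.5, n: int = 12) -> StructureModel:
    """Ideal helix plus an ATP het-group whose nearest atom sits exactly
    ``pocket_distance`` from the chain (placed along +x beyond the chain)."""
    if pocket_distance <= 0:
        raise ValueError("pocket_distance must be positive")
    model = make_helix(n)
    chain_atoms = [(a, r) for r in model.chains[0].residues for a in r.atoms]
    ref, _ = max(chain_atoms, key=lambda pair: pair[0].coords[0])
    x0, y0, z0 = ref.coords
    lig = Residue(chain_id="L", number=1, icode="", name="ATP", kind="hetero")
    for k, (name, elem) in enumerate([("PA", "P"), ("O1A", "O"), ("C1'", "C")]):
        lig.atoms.append(Atom(serial=9000 + k, name=name, element=elem,
                              coords=(x0 + pocket_distance + 1.6 * k, y0, z0)))
    model.chains.append(Chain(id="L", residues=[lig]))
    model.id = f"ligand{n}"
    return model


def make_msa(n_rows: int, profile: list[dict[str, float]], seed: int) -> MSA:
    """Sample an MSA column-wise i.i.d. from per-column symbol distributions."""
    rng = np.random.default_rng(seed)
    for i, col in enumerate(profile):
        total = sum(col.values())
        if abs(total - 1.0) > 1e-9 or any(p < 0 for p in col.values()):
            raise ValueError(f"column {i + 1}: probabilities must be >= 0 and sum to 1")
    cols = []
    for col in profile:
        syms = sorted(col)
        probs = np.array([col[s] for s in syms])
        cols.append(rng.choice(syms, size=n_rows, p=probs / probs.sum()))
    rows = ["".join(cols[j][i] for j in range(len(profile))) for i in range(n_rows)]
    return MSA(ids=[f"seq{i + 1:03d}" for i in range(n_rows)], rows=rows)


# ---------------------------------------------------------------------------
# curated tables


@dataclass
class CuratedTables:
    mutations: pd.DataFrame
    features: pd.DataFrame
    categories: pd.DataFrame

    @property
    def records(self) -> list[MutationRecord]:
        return [
            parse_substitution(row.mutation, protein_id=row.protein_id)
            for row in self.mutations.itertuples()
        ]

    @property
    def substitutions(self) -> pd.DataFrame:
        kinds = [r.kind for r in self.records]
        return self.mutations[[k == "substitution" for k in kinds]]


def _data_dir():
    return resources.files("mutannot") / "data"


def _verify_manifest() -> None:
    data = _data_dir()
    manifest = (data / "MANIFEST.sha256").read_text()
    for line in manifest.strip().splitlines():
        digest, name = line.split()
        blob = (data / name).read_bytes()
        if hashlib.sha256(blob).hexdigest() != digest:
            raise IntegrityError(f"checksum mismatch for packaged file {name}")


def load_curated() -> CuratedTables:
    """Load and validate the packaged curated annotation tables."""
    _verify_manifest()
    data = _data_dir()
    read = lambda name: pd.read_csv(  # noqa: E731
        (data / name).open("r"), sep="\t", dtype=str
    ).fillna("")
    tables = CuratedTables(
        mutations=read("mutations.tsv"),
        features=read("features.tsv"),
        categories=read("categories.tsv"),
    )
    subs = tables.substitutions
    if len(subs) != 63:
        raise IntegrityError(f"expected 63 substitution records, found {len(subs)}")
    key = lambda df: set(zip(df.protein_id, df.mutation))  # noqa: E731
    if key(tables.features) != key(subs):
        raise IntegrityError("features rows do not join 1:1 with substitutions")
    if key(tables.categories) != key(subs):
        raise IntegrityError("categories rows do not join 1:1 with substitutions")
    return tables


def curated_bundles(tables: CuratedTables | None = None) -> list[FeatureBundle]:
    """Feature bundles reconstructed from the curated tables, one per
    substitution mutation, ready for classification."""
    tables = tables or load_curated()
    meta = {
        (r.protein_id, r.mutation): r for r in tables.mutations.itertuples()
    }
    bundles = []
    for row in tables.features.itertuples():
        m = parse_substitution(row.mutation, protein_id=row.protein_id)
        info = meta[(row.protein_id, row.mutation)]
        no_coverage = row.ss == "NA" and row.rsa == "NA"
        tag = _INTERACTION_TAG.get(row.interaction, "")
        bundles.append(
            FeatureBundle(
                mutation=m,
                coverage=NoCoverage("not-in-structure") if no_coverage else "mapped",
                contact_tags={tag} if tag else set(),
                ss_code=None if no_coverage else (row.ss if row.ss else None),
                rsa=float(row.rsa) if row.rsa not in ("", "-", "NA") else None,
                natural_variant=row.natural_variant == "1",
                domain=row.domain,
                enzyme=info.enzyme,
                compartment=info.compartment,
            )
        )
    return bundles


def load_reference_sequence(protein_id: str = "P41250") -> ProteinSequence:
    """Packaged stand-in query sequence for the GRS mutation list.

    This is a synthetic sequence (the real database entry is not shipped):
    it has the correct length and the correct wild-type residue at every
    curated mutation position, which is all the validation and mapping
    machinery needs.
    """
    from .io import read_fasta

    data = _data_dir()
    path = data / f"synthetic_{protein_id}.fasta"
    if not path.is_file():
        raise FileNotFoundError(f"no packaged reference sequence for {protein_id}")
    with resources.as_file(path) as p:
        return read_fasta(p)[0]
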