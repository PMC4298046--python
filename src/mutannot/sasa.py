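"""Solvent-accessible surface area (Shrake-Rupley) and relative accessibility.

Per-atom areas are computed by rolling a 1.4 A water probe over van der Waals
spheres: each atom's expanded sphere (r_vdw + probe) is sampled with a
deterministic golden-section spiral point set and the accessible area is the
fraction of points outside every neighbouring expanded sphere times
4*pi*(r+probe)^2.  No random numbers are involved, so results are bit-stable
for a fixed point count.

Relative solvent accessibility (RSA) of a residue is its summed atom area
divided by a residue-type maximum, in percent.  Two maximum-accessibility
normalisations are provided: the empirical Rost & Sander (1994) table
(default) and the theoretical Tien et al. (2013) values; RSA shifts by a few
points between them, so every result carries a provenance label.  A residue
is called solvent accessible when RSA > 20% (strict), else buried.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import Residue, StructureModel

__all__ = [
    "VDW_RADII",
    "MAX_ASA_TABLES",
    "SasaResult",
    "shrake_rupley",
    "residue_rsa",
    "burial_class",
    "ACCESSIBLE",
    "BURIED",
    "sphere_points",
]

ACCESSIBLE = "ACCESSIBLE"
BURIED = "BURIED"

#: heavy-atom van der Waals radii (A), Chothia/NACCESS-style, per element.
#: Hydrogens are ignored entirely.
VDW_RADII: dict[str, float] = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

#: residue-type maximum accessible areas (A^2) for RSA normalisation
MAX_ASA_TABLES: dict[str, dict[str, float]] = {
    # Rost & Sander (1994) empirical maxima
    "rost-sander": {
        "ALA": 106.0, "ARG": 248.0, "ASN": 157.0, "ASP": 163.0, "CYS": 135.0,
        "GLN": 198.0, "GLU": 194.0, "GLY": 84.0, "HIS": 184.0, "ILE": 169.0,
        "LEU": 164.0, "LYS": 205.0, "MET": 188.0, "PHE": 197.0, "PRO": 136.0,
        "SER": 130.0, "THR": 142.0, "TRP": 227.0, "TYR": 222.0, "VAL": 142.0,
    },
    # Tien et al. (2013) theoretical maxima
    "tien-theoretical": {
        "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
        "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
        "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
        "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
    },
}


@dataclass
class SasaResult:
    """Per-atom and per-residue solvent-accessible areas for one model."""

    probe: float
    n_points: int
    atom_area: dict[tuple[tuple[str, int, str], str], float]
    residue_area: dict[tuple[str, int, str], float]

    def residue_sa(self, residue: Residue) -> float:
        return self.residue_area.get(residue.key, 0.0)


def sphere_points(n: int) -> np.ndarray:
    """Deterministic near-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def _radius(element: str, atom_label: str) -> float:
    r = VDW_RADII.get(element.upper())
    if r is None:
        raise ValueError(f"no van der Waals radius for element {element!r} ({atom_label})")
    return r


def shrake_rupley(
    model: StructureModel,
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> SasaResult:
    """Shrake-Rupley accessible surface area for every heavy atom of a model."""
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a usable quadrature")
    radii = radii or VDW_RADII

    keys: list[tuple[tuple[str, int, str], str]] = []
    xyz: list[tuple[float, float, float]] = []
    rads: list[float] = []
    for res in model.residues():
        for a in res.atoms:
            if not a.is_heavy:
                continue
            r = radii.get(a.element.upper())
            if r is None:
                raise ValueError(
                    f"no van der Waals radius for element {a.element!r} "
                    f"(atom {a.name} of {res.label})"
                )
            keys.append((res.key, a.name))
            xyz.append(a.coords)
            rads.append(r)
    if not keys:
        raise ValueError("model has no heavy atoms")

    coords = np.asarray(xyz)
    radii_arr = np.asarray(rads) + probe
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * radii_arr.max()

    atom_area: dict[tuple[tuple[str, int, str], str], float] = {}
    for i, key in enumerate(keys):
        ri = radii_arr[i]
        pts = coords[i] + ri * unit
        neighbours = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            rj = radii_arr[j]
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > rj * rj
        atom_area[key] = 4.0 * np.pi * ri * ri * accessible.sum() / n_points

    residue_area: dict[tuple[str, int, str], float] = {}
    for (res_key, _), area in atom_area.items():
        residue_area[res_key] = residue_area.get(res_key, 0.0) + area
    return SasaResult(probe=probe, n_points=n_points,
                      atom_area=atom_area, residue_area=residue_area)


def residue_rsa(
    sasa: SasaResult,
    model: StructureModel,
    chain_id: str,
    maxasa: str = "rost-sander",
) -> dict[tuple[str, int, str], float]:
    """Per-residue relative solvent accessibility, percent, one decimal.

    RSA = 100 * SA(residue) / maxASA(residue type).  Non-standard residues
    are normalised by their parent amino acid's maximum.  Values above 100
    are possible at termini or unusual geometry and are reported as-is.
    """
    try:
        table = MAX_ASA_TABLES[maxasa]
    except KeyError:
        raise ValueError(
            f"unknown max-ASA table {maxasa!r}; choose from {sorted(MAX_ASA_TABLES)}"
        ) from None
    out: dict[tuple[str, int, str], float] = {}
    for res in model.chain(chain_id).amino_acids():
        name = res.name if res.name in table else _parent_name(res)
        maximum = table.get(name)
        if maximum is None or maximum <= 0:
            raise ValueError(f"no max-ASA value for residue {res.label}")
        out[res.key] = round(100.0 * sasa.residue_sa(res) / maximum, 1)
    return out


def _parent_name(res: Residue) -> str:
    one = res.one_letter
    from .io import AA1_TO_3

    return AA1_TO_3.get(one, "ALA")


def burial_class(rsa: float) -> str:
    """ACCESSIBLE iff RSA strictly exceeds 20%; 20.0 itself is BURIED."""
    if rsa < 0:
        raise ValueError(f"negative RSA {rsa}")
    return ACCESSIBLE if rsa > 20.0 else BURIED
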