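"""Reduced secondary-structure assignment from backbone hydrogen bonds.

This is a compact Kabsch-Sander assigner producing the six-letter alphabet
{H, G, E, T, S, -}: alpha-helix, 3-10 helix, strand, turn, bend, unassigned.
Pi-helix stretches are merged into H and isolated beta-bridges into E, which
is the reduced alphabet used throughout the annotation tables.

Backbone amide hydrogens are reconstructed geometrically (crystal structures
rarely include them): H sits 1.0 A from N along the direction of the
preceding residue's O->C carbonyl vector, so the N-H bond is antiparallel to
that C=O.  Prolines have no amide hydrogen and cannot donate.  A hydrogen
bond between donor NH and acceptor CO is recorded when the Kabsch-Sander
electrostatic energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

falls below -0.5.  Chains are split into segments wherever the peptide bond
C(i)-N(i+1) exceeds 2.5 A; no hydrogen bond is recorded across a break.
"""

from __future__ import annotations

import numpy as np

from .io import Residue, StructureModel

__all__ = [
    "HBOND_ENERGY_CUTOFF",
    "CHAIN_BREAK_DISTANCE",
    "BEND_ANGLE_DEG",
    "place_amide_hydrogens",
    "hbond_energy",
    "assign_secondary_structure",
]

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
CHAIN_BREAK_DISTANCE = 2.5  # A, maximum peptide-bond C-N length
BEND_ANGLE_DEG = 70.0  # kappa(CA_{i-2}, CA_i, CA_{i+2}) threshold for S
_MIN_DIST = 0.5  # clash clamp for the electrostatic formula

BACKBONE = ("N", "CA", "C", "O")


def _xyz(res: Residue, name: str) -> np.ndarray | None:
    a = res.atom(name)
    return None if a is None else np.asarray(a.coords)


def _has_backbone(res: Residue) -> bool:
    return all(res.atom(n) is not None for n in BACKBONE)


def _segment_ids(residues: list[Residue]) -> list[int]:
    """Segment index per residue; increments at missing backbone or long bonds."""
    seg = 0
    ids: list[int] = []
    for i, res in enumerate(residues):
        if i > 0:
            prev = residues[i - 1]
            c = _xyz(prev, "C")
            n = _xyz(res, "N")
            if (
                not _has_backbone(prev)
                or not _has_backbone(res)
                or c is None
                or n is None
                or float(np.linalg.norm(n - c)) > CHAIN_BREAK_DISTANCE
            ):
                seg += 1
        ids.append(seg)
    return ids


def place_amide_hydrogens(residues: list[Residue]) -> dict[int, np.ndarray]:
    """Reconstructed amide-H position per residue index.

    H = N + u where u is the unit vector of the preceding carbonyl's O->C
    direction; segment-initial residues and prolines get no hydrogen.
    """
    segs = _segment_ids(residues)
    out: dict[int, np.ndarray] = {}
    for i, res in enumerate(residues):
        if res.name == "PRO" or i == 0 or segs[i] != segs[i - 1]:
            continue
        n = _xyz(res, "N")
        c_prev = _xyz(residues[i - 1], "C")
        o_prev = _xyz(residues[i - 1], "O")
        if n is None or c_prev is None or o_prev is None:
            continue
        u = c_prev - o_prev
        norm = float(np.linalg.norm(u))
        if norm == 0.0:
            continue
        out[i] = n + u / norm
    return out


def hbond_energy(
    n: np.ndarray, h: np.ndarray, c: np.ndarray, o: np.ndarray
) -> tuple[float, bool]:
    """Kabsch-Sander energy (kcal/mol) for donor N-H against acceptor C=O.

    Returns ``(energy, clash)``; inter-atomic distances below 0.5 A are
    clamped and flagged as a clash.
    """
    clash = False

    def dist(a: np.ndarray, b: np.ndarray) -> float:
        nonlocal clash
        d = float(np.linalg.norm(a - b))
        if d < _MIN_DIST:
            clash = True
            return _MIN_DIST
        return d

    e = 0.084 * 332.0 * (
        1.0 / dist(o, n) + 1.0 / dist(c, h) - 1.0 / dist(o, h) - 1.0 / dist(c, n)
    )
    return e, clash


def _hbond_set(
    residues: list[Residue], segs: list[int], hydrogens: dict[int, np.ndarray]
) -> set[tuple[int, int]]:
    """Pairs (acceptor i, donor j): CO of residue i accepts NH of residue j."""
    bonds: set[tuple[int, int]] = set()
    n_res = len(residues)
    coords = {
        i: {name: _xyz(residues[i], name) for name in ("N", "C", "O")}
        for i in range(n_res)
    }
    for j in range(n_res):  # donor
        h = hydrogens.get(j)
        nj = coords[j]["N"]
        if h is None or nj is None:
            continue
        for i in range(n_res):  # acceptor
            if abs(i - j) < 2 or segs[i] != segs[j]:
                continue
            ci, oi = coords[i]["C"], coords[i]["O"]
            if ci is None or oi is None:
                continue
            # cheap distance gate before the full energy evaluation
            if float(np.linalg.norm(oi - nj)) > 5.2:
                continue
            e, _ = hbond_energy(nj, h, ci, oi)
            if e < HBOND_ENERGY_CUTOFF:
                bonds.add((i, j))
    return bonds


def assign_secondary_structure(model: StructureModel, chain_id: str) -> str:
    """Per-residue reduced DSSP string for the amino acids of one chain.

    Pattern rules: an n-turn at i exists when CO(i) accepts NH(i+n) for
    n in {3,4,5}; two consecutive turns of the same period start a helix
    (period 4 or 5 -> H, period 3 -> G).  Parallel/antiparallel bridge
    patterns mark strand residues E (isolated bridges included).  Remaining
    turn residues get T; a backbone kink above 70 degrees gets S; priority
    is H > E > G > T > S.
    """
    residues = model.chain(chain_id).amino_acids()
    n_res = len(residues)
    if n_res == 0:
        return ""
    segs = _segment_ids(residues)
    hydrogens = place_amide_hydrogens(residues)
    bonds = _hbond_set(residues, segs, hydrogens)

    def hb(acceptor: int, donor: int) -> bool:
        return (acceptor, donor) in bonds

    def adjacent(i: int, j: int) -> bool:
        """True when residues i..j are consecutive within one segment."""
        lo, hi = min(i, j), max(i, j)
        return 0 <= lo and hi < n_res and segs[lo] == segs[hi]

    # n-turns: turn[n][i] means CO(i) accepts NH(i+n)
    turn: dict[int, set[int]] = {3: set(), 4: set(), 5: set()}
    for n in (3, 4, 5):
        for i in range(n_res - n):
            if adjacent(i, i + n) and hb(i, i + n):
                turn[n].add(i)

    is_h = np.zeros(n_res, dtype=bool)  # alpha (incl. pi merged)
    is_g = np.zeros(n_res, dtype=bool)
    for n, mark in ((4, is_h), (5, is_h), (3, is_g)):
        for i in range(1, n_res):
            if i - 1 in turn[n] and i in turn[n]:
                mark[i : i + n] = True

    # beta bridges -> E (isolated bridges merged into strand)
    is_e = np.zeros(n_res, dtype=bool)
    for i in range(n_res):
        for j in range(i + 3, n_res):
            flank_i = i - 1 >= 0 and i + 1 < n_res and adjacent(i - 1, i + 1)
            flank_j = j - 1 >= 0 and j + 1 < n_res and adjacent(j - 1, j + 1)
            para = (flank_i and hb(i - 1, j) and hb(j, i + 1)) or (
                flank_j and hb(j - 1, i) and hb(i, j + 1)
            )
            anti = (hb(i, j) and hb(j, i)) or (
                flank_i and flank_j and hb(i - 1, j + 1) and hb(j - 1, i + 1)
            )
            if para or anti:
                is_e[i] = True
                is_e[j] = True

    # single turns -> T over the bridged span's interior
    is_t = np.zeros(n_res, dtype=bool)
    for n in (3, 4, 5):
        for i in turn[n]:
            is_t[i + 1 : i + n] = True

    # bend: kappa over CA(i-2), CA(i), CA(i+2)
    is_s = np.zeros(n_res, dtype=bool)
    for i in range(2, n_res - 2):
        if segs[i - 2] != segs[i + 2]:
            continue
        a = _xyz(residues[i - 2], "CA")
        b = _xyz(residues[i], "CA")
        c = _xyz(residues[i + 2], "CA")
        if a is None or b is None or c is None:
            continue
        u, v = b - a, c - b
        nu, nv = float(np.linalg.norm(u)), float(np.linalg.norm(v))
        if nu == 0 or nv == 0:
            continue
        cosk = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
        if np.degrees(np.arccos(cosk)) > BEND_ANGLE_DEG:
            is_s[i] = True

    out = []
    for i, res in enumerate(residues):
        if not _has_backbone(res):
            out.append("-")
        elif is_h[i]:
            out.append("H")
        elif is_e[i]:
            out.append("E")
        elif is_g[i]:
            out.append("G")
        elif is_t[i]:
            out.append("T")
        elif is_s[i]:
            out.append("S")
        else:
            out.append("-")
    return "".join(out)
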