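"""Per-column residue distributions and BLOSUM62 conservation from an MSA.

The family alignment (typically the top mammalian BLAST hits for the query,
or a structure-guided class-wide alignment) yields three kinds of evidence
per mutation site:

* a residue-frequency profile of the aligned column, in integer percent
  (gaps counted as ``-``; largest-remainder rounding so percents sum to 100);
* a 0-100 conservation score: the mean BLOSUM62 score over all unordered
  non-gap residue pairs, normalised by the mean self-substitution score of
  the column and clamped at zero, binned into <40 / 40-60 / 60-80 / >80 with
  boundary values joining the interval whose lower limit they equal;
* a natural-variant flag: the disease-associated mutant residue already
  occurs in at least one homologue at that column.

Scores are unweighted over rows; duplicate sequences therefore count twice
(sequence weighting is deliberately out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from Bio.Align import substitution_matrices

from .io import MutationRecord

__all__ = [
    "MSA",
    "ColumnProfile",
    "ConservationBin",
    "BIN_LABELS",
    "column_frequencies",
    "conservation_score",
    "bin_conservation",
    "natural_variant_flag",
    "column_for_position",
]

BIN_LABELS = ("<40", "40-60", "60-80", ">80")
_GAPLIKE = {"-", "."}


@dataclass
class MSA:
    """A rectangular multiple sequence alignment; columns are 1-based."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty MSA")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("ragged MSA: rows differ in length")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def column(self, index: int) -> str:
        """Column as a string of symbols; index is 1-based."""
        if not 1 <= index <= self.width:
            raise IndexError(f"column {index} outside 1..{self.width}")
        return "".join(row[index - 1] for row in self.rows)

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"no sequence {seq_id!r} in MSA") from None


@dataclass(frozen=True)
class ColumnProfile:
    """Integer-percent residue distribution of one MSA column."""

    counts: dict[str, int]
    percents: dict[str, int]

    @property
    def dominant(self) -> str:
        return max(self.percents, key=lambda k: (self.percents[k], k))

    def spread_string(self) -> str:
        """Table-style rendering, descending percent: 'A': 77, 'S': 21, ..."""
        items = sorted(self.percents.items(), key=lambda kv: (-kv[1], kv[0]))
        return ", ".join(f"'{sym}': {pct}" for sym, pct in items)


@dataclass(frozen=True)
class ConservationBin:
    score: float  # 0-100, or NaN when undefined
    bin: str  # one of BIN_LABELS or '-'


def column_frequencies(msa: MSA, column: int) -> ColumnProfile:
    """Residue counts and integer percents for one column (gaps included).

    Percents use largest-remainder rounding so they always sum to exactly
    100; ties in remainder are broken toward the more frequent symbol, then
    alphabetically.
    """
    col = msa.column(column)
    counts: dict[str, int] = {}
    for sym in col:
        sym = "-" if sym in _GAPLIKE else sym.upper()
        counts[sym] = counts.get(sym, 0) + 1
    total = len(col)
    exact = {sym: 100.0 * c / total for sym, c in counts.items()}
    floors = {sym: int(exact[sym]) for sym in counts}
    shortfall = 100 - sum(floors.values())
    by_remainder = sorted(
        counts, key=lambda s: (-(exact[s] - floors[s]), -counts[s], s)
    )
    percents = dict(floors)
    for sym in by_remainder[:shortfall]:
        percents[sym] += 1
    return ColumnProfile(counts=counts, percents=percents)


def conservation_score(msa: MSA, column: int, matrix: str = "BLOSUM62") -> float:
    """Normalised mean sum-of-pairs substitution score for a column, 0-100.

    With B the substitution matrix, S is the mean of B(a_i, a_j) over all
    unordered pairs of non-gap residues and S_id the mean of B(a, a) over the
    column's residues; the score is 100 * max(0, S / S_id).  A fully
    conserved column scores exactly 100.  Raises when fewer than two
    residues are present (the bin is then reported as '-').
    """
    mat = substitution_matrices.load(matrix)
    col = [s.upper() for s in msa.column(column) if s not in _GAPLIKE]
    if len(col) < 2:
        raise ValueError(f"column {column}: fewer than two non-gap residues")
    pair_scores = [float(mat[a, b]) for a, b in combinations(col, 2)]
    s = sum(pair_scores) / len(pair_scores)
    s_id = sum(float(mat[a, a]) for a in col) / len(col)
    return 100.0 * max(0.0, s / s_id)


def bin_conservation(score: float) -> ConservationBin:
    """Four-interval binning with the lower-limit tie rule.

    Intervals are [0,40), [40,60), [60,80), [80,100]: a boundary score joins
    the interval whose lower limit it equals (60 -> 60-80, 80 -> >80).
    """
    if not 0.0 <= score <= 100.0:
        raise ValueError(f"score {score} outside 0..100")
    if score < 40.0:
        label = "<40"
    elif score < 60.0:
        label = "40-60"
    elif score < 80.0:
        label = "60-80"
    else:
        label = ">80"
    return ConservationBin(score=score, bin=label)


def natural_variant_flag(m: MutationRecord, profile: ColumnProfile) -> tuple[bool, str]:
    """Whether the mutant residue already occurs among the homologues.

    The profile must come from the MSA column aligned to the mutation's
    position.  Returns the flag plus a short carrier note.
    """
    count = profile.counts.get(m.mut, 0)
    if count >= 1:
        return True, (
            f"mutant residue {m.mut} occurs {count}x among homologues at this column"
        )
    return False, f"mutant residue {m.mut} absent from homologues at this column"


def column_for_position(msa: MSA, ref_id: str, position: int) -> int:
    """1-based MSA column holding the ref sequence's 1-based residue position."""
    row = msa.row(ref_id)
    seen = 0
    for col0, sym in enumerate(row):
        if sym not in _GAPLIKE:
            seen += 1
            if seen == position:
                return col0 + 1
    raise IndexError(
        f"position {position} beyond ungapped length {seen} of {ref_id!r}"
    )
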