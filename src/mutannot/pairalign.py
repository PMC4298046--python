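"""Global pairwise alignment and mutation-site mapping onto a structure.

The query (full-length protein sequence) is aligned against the sequence
extracted from the structural homologue's chain with a global affine-gap
(Needleman-Wunsch/Gotoh) alignment under BLOSUM62 with EMBOSS-style
penalties (gap open -10, extend -0.5).  Query and homologue are expected to
be close, so the exact gap model matters little; penalties are configurable.

A mutation position maps to the structure residue aligned to it, reported in
the model's author numbering.  Positions aligned to a gap, to a residue
missing from the model (crystallographic disorder), or lying outside the
alignment are reported as NO_COVERAGE with the corresponding reason.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .io import MutationRecord, ProteinSequence, Residue, StructureModel, chain_sequence

__all__ = [
    "PairwiseAlignment",
    "NoCoverage",
    "GAP_IN_SUBJECT",
    "RESIDUE_MISSING_IN_MODEL",
    "BEYOND_STRUCTURE",
    "global_align",
    "map_mutation_to_structure",
    "identity_fraction",
]

GAP_IN_SUBJECT = "gap-in-subject"
RESIDUE_MISSING_IN_MODEL = "residue-missing-in-model"
BEYOND_STRUCTURE = "beyond-structure"

_VALID = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class NoCoverage:
    """A query position with no usable structural counterpart."""

    reason: str  # one of the module-level reason constants


@dataclass
class PairwiseAlignment:
    """A global alignment of query against subject with a per-column map."""

    query_id: str
    subject_id: str
    gapped_query: str
    gapped_subject: str
    score: float
    matrix: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -0.5

    def __post_init__(self) -> None:
        if len(self.gapped_query) != len(self.gapped_subject):
            raise ValueError("gapped strings differ in length")
        if any(q == "-" and s == "-" for q, s in zip(self.gapped_query, self.gapped_subject)):
            raise ValueError("alignment contains a gap-gap column")

    @property
    def columns(self) -> list[tuple[int | None, int | None]]:
        """Per column: (1-based query position | None, subject position | None)."""
        out = []
        qi = si = 0
        for q, s in zip(self.gapped_query, self.gapped_subject):
            qpos = spos = None
            if q != "-":
                qi += 1
                qpos = qi
            if s != "-":
                si += 1
                spos = si
            out.append((qpos, spos))
        return out

    def subject_position(self, query_position: int) -> int | None:
        """1-based subject index aligned to a query position, or None for a gap."""
        for qpos, spos in self.columns:
            if qpos == query_position:
                return spos
        raise IndexError(f"query position {query_position} outside alignment")


def _check_sequence(seq: ProteinSequence) -> None:
    if not seq.residues:
        raise ValueError(f"sequence {seq.id!r} is empty")
    bad = set(seq.residues) - _VALID
    if bad:
        raise ValueError(f"sequence {seq.id!r} has non-amino-acid letters {sorted(bad)}")


def global_align(
    a: ProteinSequence,
    b: ProteinSequence,
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> PairwiseAlignment:
    """Optimal global affine-gap alignment of two protein sequences.

    End gaps are penalised like internal ones (a true global alignment), so
    even sequences with no favourable pairing align full-length.  The first
    optimal traceback reported by the aligner is used, which is
    deterministic for fixed inputs.
    """
    _check_sequence(a)
    _check_sequence(b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    alignments = aligner.align(a.residues, b.residues)
    best = alignments[0]
    gq, gs = str(best[0]), str(best[1])
    return PairwiseAlignment(
        query_id=a.id,
        subject_id=b.id,
        gapped_query=gq,
        gapped_subject=gs,
        score=float(best.score),
        matrix=matrix,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


def identity_fraction(aln: PairwiseAlignment) -> float:
    """Fraction of aligned (non-gap) columns with identical residues."""
    pairs = [
        (q, s)
        for q, s in zip(aln.gapped_query, aln.gapped_subject)
        if q != "-" and s != "-"
    ]
    if not pairs:
        return 0.0
    return sum(q == s for q, s in pairs) / len(pairs)


def map_mutation_to_structure(
    m: MutationRecord,
    aln: PairwiseAlignment,
    model: StructureModel,
    chain_id: str,
    min_identity: float = 0.95,
    subject_full: ProteinSequence | None = None,
) -> Residue | NoCoverage:
    """Resolve a mutation's query position to a structure residue.

    The alignment subject is normally the sequence extracted from the model
    chain itself; when the alignment was computed against a full-length
    homologue sequence instead, pass it as ``subject_full`` so that residues
    present in the sequence but unresolved in the crystal are reported as
    NO_COVERAGE(residue-missing-in-model) rather than matched incorrectly.
    """
    seq, residues = chain_sequence(model, chain_id)
    subject_seq = subject_full.residues if subject_full is not None else seq.residues
    if aln.gapped_subject.replace("-", "") != subject_seq:
        raise ValueError(
            f"alignment subject does not match chain {chain_id} of {model.id}"
        )
    ident = identity_fraction(aln)
    if ident < min_identity:
        raise ValueError(
            f"query/structure identity {ident:.2f} below {min_identity:.2f}: "
            "wrong structure supplied?"
        )
    if not 1 <= m.position <= len(aln.gapped_query.replace("-", "")):
        return NoCoverage(BEYOND_STRUCTURE)
    spos = aln.subject_position(m.position)
    if spos is None:
        return NoCoverage(GAP_IN_SUBJECT)
    if subject_full is not None:
        # second hop: locate the full-sequence position among modelled residues
        inner = global_align(subject_full, seq)
        mpos = inner.subject_position(spos)
        if mpos is None:
            return NoCoverage(RESIDUE_MISSING_IN_MODEL)
        return residues[mpos - 1]
    return residues[spos - 1]
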