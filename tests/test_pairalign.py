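"""Affine-gap alignment against exhaustive enumeration; site mapping."""

import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from mutannot import fixtures, pairalign
from mutannot.io import ProteinSequence, chain_sequence, parse_substitution

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def enumerate_best_score(a, b, gap_open=-10.0, gap_extend=-0.5):
    """Max score over every global alignment, scored with affine gap runs."""
    best = [-np.inf]

    def walk(i, j, score, state):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, score + BLOSUM62[a[i], b[j]], "m")
        if i < len(a):
            cost = gap_extend if state == "ga" else gap_open
            walk(i + 1, j, score + cost, "ga")
        if j < len(b):
            cost = gap_extend if state == "gb" else gap_open
            walk(i, j + 1, score + cost, "gb")

    walk(0, 0, 0.0, "start")
    return best[0]


def test_identity_alignment_has_no_gaps():
    seq = ProteinSequence("q", "MKTAYIAKQR")
    aln = pairalign.global_align(seq, ProteinSequence("s", seq.residues))
    assert "-" not in aln.gapped_query + aln.gapped_subject
    assert aln.score == sum(BLOSUM62[c, c] for c in seq.residues)
    assert pairalign.identity_fraction(aln) == 1.0


def test_score_matches_enumeration_oracle_on_short_pairs():
    rng = np.random.default_rng(62)
    alphabet = "ACDE"
    pairs = []
    for la, lb in itertools.product(range(1, 7), repeat=2):
        if la + lb > 10:  # keep enumeration affordable
            continue
        pairs.append((
            "".join(rng.choice(list(alphabet), la)),
            "".join(rng.choice(list(alphabet), lb)),
        ))
    assert len(pairs) >= 25
    for sa, sb in pairs:
        aln = pairalign.global_align(ProteinSequence("a", sa), ProteinSequence("b", sb))
        assert aln.score == pytest.approx(enumerate_best_score(sa, sb)), (sa, sb)


def test_score_symmetry():
    rng = np.random.default_rng(3)
    for _ in range(10):
        sa = "".join(rng.choice(list("ACDEFGHIKL"), rng.integers(3, 9)))
        sb = "".join(rng.choice(list("ACDEFGHIKL"), rng.integers(3, 9)))
        ab = pairalign.global_align(ProteinSequence("a", sa), ProteinSequence("b", sb))
        ba = pairalign.global_align(ProteinSequence("b", sb), ProteinSequence("a", sa))
        assert ab.score == ba.score


def test_global_contract_on_disjoint_sequences():
    aln = pairalign.global_align(ProteinSequence("a", "AAAA"),
                                 ProteinSequence("b", "WWWW"))
    assert aln.gapped_query.replace("-", "") == "AAAA"
    assert aln.gapped_subject.replace("-", "") == "WWWW"


def test_known_pair_score():
    aln = pairalign.global_align(ProteinSequence("a", "HEAGAWGHEE"),
                                 ProteinSequence("b", "PAWHEAE"))
    assert aln.score == pytest.approx(enumerate_best_score("HEAGAWGHEE", "PAWHEAE"))


def test_mapping_is_order_preserving_and_injective(helix12):
    seq, residues = chain_sequence(helix12, "A")
    query = ProteinSequence("q", seq.residues)
    aln = pairalign.global_align(query, seq)
    mapped = []
    for pos in range(1, len(query) + 1):
        m = parse_substitution(f"Ala{pos}Val")
        res = pairalign.map_mutation_to_structure(m, aln, helix12, "A")
        assert not isinstance(res, pairalign.NoCoverage)
        mapped.append(res.number)
    assert mapped == sorted(set(mapped))


def test_mapping_reports_no_coverage_for_truncated_structure():
    model = fixtures.make_helix(8)
    seq, _ = chain_sequence(model, "A")
    # query has 4 extra N-terminal residues absent from the structure
    query = ProteinSequence("q", "AAAA" + seq.residues)
    aln = pairalign.global_align(query, seq)
    m = parse_substitution("Ala2Val")
    res = pairalign.map_mutation_to_structure(m, aln, model, "A")
    assert isinstance(res, pairalign.NoCoverage)
    assert res.reason == pairalign.GAP_IN_SUBJECT
    beyond = parse_substitution("Ala99Val")
    assert pairalign.map_mutation_to_structure(beyond, aln, model, "A").reason == \
        pairalign.BEYOND_STRUCTURE


def test_low_identity_rejected(helix12):
    seq, _ = chain_sequence(helix12, "A")
    query = ProteinSequence("q", "WY" * 6)
    aln = pairalign.global_align(query, seq)
    with pytest.raises(ValueError, match="identity"):
        pairalign.map_mutation_to_structure(
            parse_substitution("Trp1Ala"), aln, helix12, "A")


def test_gap_gap_columns_rejected():
    with pytest.raises(ValueError):
        pairalign.PairwiseAlignment("q", "s", "A-A", "A-A", 0.0)
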