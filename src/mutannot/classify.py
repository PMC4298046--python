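"""Fuse per-mutation evidence into one of four mechanistic categories.

Categories follow the scheme used throughout the annotation tables:

* **A** — the site contacts a reaction substrate (ATP/amino-acid or tRNA),
  so the change can directly disturb aminoacylation;
* **B** — the site is buried in the structural core, so the change likely
  affects folding or stability;
* **C** — the site sits on a surface that is (or may become) a biomolecular
  interface, including the homodimer interface;
* **D** — no structural annotation is possible (no aligned residue, a
  disordered site, or no assigned secondary structure).

The precedence is deterministic: no structural coverage -> D; substrate or
tRNA contact -> A; dimer contact -> C (contacts dominate burial); unassigned
secondary structure -> D; buried (RSA <= 20%) -> B; otherwise -> C
(potential interface).  Conservation bins and natural-variant flags are
reported as evidence but never change the letter; an optional switch can
demote natural-variant sites to D for exploratory use.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .conservation import ConservationBin
from .io import MutationRecord
from .pairalign import NoCoverage, PairwiseAlignment
from .sasa import BURIED, burial_class

__all__ = [
    "FeatureBundle",
    "Category",
    "SummaryStats",
    "categorize",
    "summarize",
    "render_annotated_alignment",
    "parse_alignment_report",
]


@dataclass
class FeatureBundle:
    """All structural and evolutionary evidence gathered for one mutation."""

    mutation: MutationRecord
    coverage: str | NoCoverage = "mapped"
    contact_tags: set[str] = field(default_factory=set)  # subset of {ATP_AA, TRNA, DIMER}
    ss_code: str | None = None  # {H,G,E,T,S,-} or None without coverage
    rsa: float | None = None  # percent, None without coverage or when unresolved
    conservation: ConservationBin | None = None
    natural_variant: bool = False
    domain: str = ""
    enzyme: str = ""
    compartment: str = ""  # cytoplasmic | mitochondrial

    @property
    def covered(self) -> bool:
        return not isinstance(self.coverage, NoCoverage)

    @property
    def burial(self) -> str | None:
        return None if self.rsa is None else burial_class(self.rsa)


@dataclass(frozen=True)
class Category:
    letter: str  # A | B | C | D
    subtype: str
    rationale: str


def categorize(b: FeatureBundle, natural_variant_to_d: bool = False) -> Category:
    """Assign the mechanistic category for one feature bundle (pure function)."""
    m = b.mutation.short
    if not b.covered:
        reason = b.coverage.reason if isinstance(b.coverage, NoCoverage) else "unmapped"
        return Category("D", "no-structure",
                        f"{m}: no structural coverage ({reason})")
    if natural_variant_to_d and b.natural_variant:
        return Category("D", "no-structure",
                        f"{m}: natural variant in homologues, demoted by configuration")
    if "ATP_AA" in b.contact_tags:
        return Category("A", "ligand-binding",
                        f"{m}: within contact distance of ATP/amino-acid ligand")
    if "TRNA" in b.contact_tags:
        return Category("A", "tRNA-binding",
                        f"{m}: within contact distance of tRNA")
    if "DIMER" in b.contact_tags:
        return Category("C", "dimerization",
                        f"{m}: at the homodimer interface")
    if b.ss_code == "-" or b.ss_code is None or b.rsa is None:
        return Category("D", "disordered-site",
                        f"{m}: site without assigned secondary structure")
    if b.burial == BURIED:
        return Category("B", "structural-core",
                        f"{m}: buried (RSA {b.rsa:.1f}% <= 20%) in the structural core")
    return Category("C", "potential-interface",
                    f"{m}: solvent accessible (RSA {b.rsa:.1f}%) without substrate "
                    "contacts; potential biomolecular interface")


@dataclass
class SummaryStats:
    total: int
    by_letter: dict[str, int]
    by_enzyme: dict[str, int]
    by_compartment: dict[str, int]
    contact_tagged: int
    most_mutated_wt: list[tuple[str, int]]

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "by_letter": dict(self.by_letter),
            "by_enzyme": dict(self.by_enzyme),
            "by_compartment": dict(self.by_compartment),
            "contact_tagged": self.contact_tagged,
            "most_mutated_wt": [list(t) for t in self.most_mutated_wt],
        }


def summarize(categories: list[Category], bundles: list[FeatureBundle]) -> SummaryStats:
    """Census over classified mutations; empty input yields an all-zero summary."""
    if len(categories) != len(bundles):
        raise ValueError("categories and bundles differ in length")
    letters = Counter(c.letter for c in categories)
    enzymes = Counter(b.enzyme for b in bundles if b.enzyme)
    compartments = Counter(b.compartment for b in bundles if b.compartment)
    wt = Counter(b.mutation.wt for b in bundles)
    return SummaryStats(
        total=len(bundles),
        by_letter={k: letters.get(k, 0) for k in "ABCD"},
        by_enzyme=dict(sorted(enzymes.items())),
        by_compartment=dict(sorted(compartments.items())),
        contact_tagged=sum(1 for b in bundles if b.contact_tags),
        most_mutated_wt=wt.most_common(3),
    )


# ---------------------------------------------------------------------------
# annotated-alignment report

_CONTACT_CHAR = {"ATP_AA": "^", "TRNA": "~", "DIMER": "="}
_CHAR_CONTACT = {v: k for k, v in _CONTACT_CHAR.items()}
_BIN_DIGIT = {"<40": "1", "40-60": "2", "60-80": "3", ">80": "4"}
_DIGIT_BIN = {v: k for k, v in _BIN_DIGIT.items()}
_MARGIN = 13  # label (6) + start coordinate (6) + space


def render_annotated_alignment(
    aln: PairwiseAlignment,
    bundles: list[FeatureBundle],
    bins: dict[int, ConservationBin] | None = None,
    contacts: dict[int, set[str]] | None = None,
    width: int = 60,
) -> str:
    """Fixed-width text report of the query/structure alignment with tracks.

    Tracks per block: the two sequences; ``MUT`` marking mutation sites with
    ``*``; ``CNTCT`` underlining contact residues (``^`` ATP/amino-acid,
    ``~`` tRNA, ``=`` dimer); ``CONSV`` giving the conservation bin as a
    digit 1-4.  ``bins`` and ``contacts`` are keyed by 1-based query
    position; contact tags carried by the bundles are merged in at their
    mutation positions.
    """
    bins = bins or {}
    contacts = {k: set(v) for k, v in (contacts or {}).items()}
    qlen = len(aln.gapped_query.replace("-", ""))
    for b in bundles:
        pos = b.mutation.position
        if not 1 <= pos <= qlen:
            raise IndexError(
                f"mutation {b.mutation.short} position outside alignment query"
            )
        if b.contact_tags:
            contacts.setdefault(pos, set()).update(b.contact_tags)
    mut_positions = {b.mutation.position for b in bundles}

    columns = aln.columns
    n = len(columns)
    mut_track = []
    contact_track = []
    consv_track = []
    for qpos, _ in columns:
        mut_track.append("*" if qpos in mut_positions else " ")
        ch = " "
        if qpos is not None and qpos in contacts:
            for tag in ("ATP_AA", "TRNA", "DIMER"):  # fixed display precedence
                if tag in contacts[qpos]:
                    ch = _CONTACT_CHAR[tag]
                    break
        contact_track.append(ch)
        d = " "
        if qpos is not None and qpos in bins:
            d = _BIN_DIGIT[bins[qpos].bin]
        consv_track.append(d)

    header = [
        f"# query:   {aln.query_id}  (mutations bracketed below as [WT pos MUT])",
        f"# subject: {aln.subject_id}",
        f"# matrix {aln.matrix}, gap open {aln.gap_open}, extend {aln.gap_extend}, "
        f"score {aln.score:.1f}",
        "# mutations: "
        + ", ".join(f"[{b.mutation.short}]" for b in sorted(
            bundles, key=lambda x: x.mutation.position)),
        "# tracks: MUT '*' mutation site; CNTCT '^' ATP/aa '~' tRNA '=' dimer; "
        "CONSV 1:<40 2:40-60 3:60-80 4:>80",
        "",
    ]

    lines: list[str] = header
    for start in range(0, n, width):
        stop = min(start + width, n)
        qstart = next((q for q, _ in columns[start:stop] if q is not None), 0)
        sstart = next((s for _, s in columns[start:stop] if s is not None), 0)
        lines.append(f"{'QUERY':<6}{qstart:>6} {aln.gapped_query[start:stop]}")
        lines.append(f"{'SBJCT':<6}{sstart:>6} {aln.gapped_subject[start:stop]}")
        lines.append(f"{'MUT':<6}{'':>6} {''.join(mut_track[start:stop])}".rstrip())
        lines.append(f"{'CNTCT':<6}{'':>6} {''.join(contact_track[start:stop])}".rstrip())
        lines.append(f"{'CONSV':<6}{'':>6} {''.join(consv_track[start:stop])}".rstrip())
        lines.append("")
    return "\n".join(lines)


def parse_alignment_report(text: str) -> dict:
    """Recover per-position annotations from a rendered report (round-trip).

    Returns a dict with ``mutations`` (query positions), ``contacts``
    (position -> tag) and ``bins`` (position -> bin label).
    """
    mutations: set[int] = set()
    contacts: dict[int, str] = {}
    bins: dict[int, str] = {}
    block_query: str = ""
    qstart = 0
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        label = line[:6].strip()
        body = line[_MARGIN:]
        if label == "QUERY":
            qstart = int(line[6:12])
            block_query = body
            continue
        if label not in ("MUT", "CNTCT", "CONSV"):
            continue
        qpos = qstart - 1
        for i, q in enumerate(block_query):
            if q != "-":
                qpos += 1
            ch = body[i] if i < len(body) else " "
            if ch == " " or q == "-":
                continue
            if label == "MUT" and ch == "*":
                mutations.add(qpos)
            elif label == "CNTCT" and ch in _CHAR_CONTACT:
                contacts[qpos] = _CHAR_CONTACT[ch]
            elif label == "CONSV" and ch in _DIGIT_BIN:
                bins[qpos] = _DIGIT_BIN[ch]
    return {"mutations": mutations, "contacts": contacts, "bins": bins}
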