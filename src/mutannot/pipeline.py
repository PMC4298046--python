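"""End-to-end annotation: from sequence + mutations + structure + MSA to
classified mutations and a rendered alignment report.

This is the glue the command-line tool drives; each step lives in its own
module and can be used independently.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import classify, conservation, contacts, pairalign, sasa, secstruct
from .conservation import MSA
from .io import MutationRecord, ProteinSequence, StructureModel, chain_sequence, validate_mutation
from .pairalign import NoCoverage

__all__ = ["AnnotationResult", "annotate_mutations"]


@dataclass
class AnnotationResult:
    bundles: list[classify.FeatureBundle]
    categories: list[classify.Category]
    alignment: pairalign.PairwiseAlignment
    report: str
    summary: classify.SummaryStats


def annotate_mutations(
    query: ProteinSequence,
    mutations: list[MutationRecord],
    model: StructureModel,
    target_chain: str,
    partner_chains: frozenset[str] = frozenset(),
    ligand_names: frozenset[str] = contacts.DEFAULT_LIGAND_NAMES,
    trna_chains: frozenset[str] | None = None,
    msa: MSA | None = None,
    msa_ref_id: str | None = None,
    cutoff: float = 4.0,
    rsa_threshold: float = 20.0,
    maxasa: str = "rost-sander",
    min_identity: float = 0.95,
    strict: bool = True,
) -> AnnotationResult:
    """Run the full annotation pipeline for substitution mutations.

    Non-substitution records (deletions, insertions, frameshifts) are parsed
    upstream but only flagged; they are excluded here.  ``rsa_threshold`` is
    carried for reporting; the burial rule itself is the strict >20% call.
    """
    subs = [m for m in mutations if m.kind == "substitution"]
    for m in subs:
        ok, msg = validate_mutation(query, m)
        if not ok and strict:
            raise ValueError(msg)

    aln = pairalign.global_align(query, chain_sequence(model, target_chain)[0])
    if pairalign.identity_fraction(aln) < min_identity:
        raise ValueError(
            "query/structure identity below threshold: wrong structure supplied?"
        )

    selections = [
        contacts.PartnerSelection(kind=contacts.LIGAND, het_names=ligand_names)
    ]
    if partner_chains:
        selections.append(
            contacts.PartnerSelection(
                kind=contacts.PARTNER_CHAIN, chain_ids=frozenset(partner_chains)
            )
        )
    auto_trna = (
        trna_chains if trna_chains is not None
        else contacts.trna_chains(model, target_chain)
    )
    if auto_trna:
        selections.append(
            contacts.PartnerSelection(kind=contacts.TRNA, chain_ids=frozenset(auto_trna))
        )
    contact_ann = contacts.annotate_contacts(model, target_chain, selections, cutoff)

    ss = secstruct.assign_secondary_structure(model, target_chain)
    sasa_res = sasa.shrake_rupley(model)
    rsa = sasa.residue_rsa(sasa_res, model, target_chain, maxasa=maxasa)
    residues = model.chain(target_chain).amino_acids()
    ss_by_key = {r.key: ss[i] for i, r in enumerate(residues)}

    bundles: list[classify.FeatureBundle] = []
    bins: dict[int, conservation.ConservationBin] = {}
    for m in subs:
        mapped = pairalign.map_mutation_to_structure(
            m, aln, model, target_chain, min_identity=min_identity
        )
        bundle = classify.FeatureBundle(mutation=m, enzyme=m.protein_id)
        if isinstance(mapped, NoCoverage):
            bundle.coverage = mapped
        else:
            bundle.coverage = "mapped"
            bundle.contact_tags = set(contact_ann.tags_for(mapped))
            bundle.ss_code = ss_by_key.get(mapped.key, "-")
            bundle.rsa = rsa.get(mapped.key)
        if msa is not None and msa_ref_id is not None:
            col = conservation.column_for_position(msa, msa_ref_id, m.position)
            profile = conservation.column_frequencies(msa, col)
            bundle.natural_variant = conservation.natural_variant_flag(m, profile)[0]
            try:
                score = conservation.conservation_score(msa, col)
                bundle.conservation = conservation.bin_conservation(score)
                bins[m.position] = bundle.conservation
            except ValueError:
                bundle.conservation = None
        bundles.append(bundle)

    cats = [classify.categorize(b) for b in bundles]
    # contact underline track over all query positions that map to a tagged residue
    key_to_qpos: dict[tuple[str, int, str], int] = {}
    cols = aln.columns
    for qpos, spos in cols:
        if qpos is not None and spos is not None:
            key_to_qpos[residues[spos - 1].key] = qpos
    track = {
        key_to_qpos[key]: tags
        for key, tags in contact_ann.tags.items()
        if key in key_to_qpos
    }
    report = classify.render_annotated_alignment(aln, bundles, bins=bins, contacts=track)
    return AnnotationResult(
        bundles=bundles,
        categories=cats,
        alignment=aln,
        report=report,
        summary=classify.summarize(cats, bundles),
    )
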