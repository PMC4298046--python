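"""Contact sets: brute-force equivalence, monotonicity, symmetry, tagging."""

import numpy as np
import pytest

from mutannot import contacts, fixtures
from mutannot.io import Atom, Chain, Residue, StructureModel


def brute_force_contacts(model, target_chain, partner, cutoff, deny=contacts.DEFAULT_DENY_LIST):
    """O(n^2) oracle over all heavy-atom pairs."""
    hits = set()
    partner_atoms = []
    for chain in model.chains:
        for res in chain.residues:
            if res.kind == "water" or res.name in deny:
                continue
            in_chain = chain.id in partner.chain_ids and chain.id != target_chain
            in_het = res.kind == "hetero" and res.name in partner.het_names
            if in_chain or in_het:
                partner_atoms.extend(a.coords for a in res.atoms if a.is_heavy)
    for res in model.chain(target_chain).residues:
        if res.kind == "water":
            continue
        for a in res.atoms:
            if not a.is_heavy:
                continue
            for p in partner_atoms:
                if np.linalg.norm(np.subtract(a.coords, p)) <= cutoff:
                    hits.add(res.key)
                    break
            if res.key in hits:
                break
    return hits


def random_two_chain_model(rng, with_ligand=False):
    chains = []
    serial = 1
    for cid, offset in (("A", 0.0), ("B", rng.uniform(2.0, 12.0))):
        chain = Chain(id=cid)
        for i in range(rng.integers(3, 7)):
            res = Residue(chain_id=cid, number=i + 1, icode="", name="GLY",
                          kind="amino-acid")
            for j in range(rng.integers(1, 4)):
                xyz = rng.normal(scale=3.0, size=3) + np.array([offset, 0, 0])
                res.atoms.append(Atom(serial=serial, name=f"C{j}", element="C",
                                      coords=tuple(np.round(xyz, 3))))
                serial += 1
            chain.residues.append(res)
        chains.append(chain)
    model = StructureModel(id="rnd", chains=chains)
    if with_ligand:
        lig = Residue(chain_id="L", number=1, icode="", name="ATP", kind="hetero")
        xyz = rng.normal(scale=4.0, size=3)
        lig.atoms.append(Atom(serial=serial, name="PA", element="P",
                              coords=tuple(np.round(xyz, 3))))
        model.chains.append(Chain(id="L", residues=[lig]))
    return model


def test_two_atoms_beyond_cutoff_no_contact():
    a = Chain("A", [Residue("A", 1, "", "GLY", "amino-acid",
                            [Atom(1, "CA", "C", (0.0, 0.0, 0.0))])])
    b = Chain("B", [Residue("B", 1, "", "GLY", "amino-acid",
                            [Atom(2, "CA", "C", (4.5, 0.0, 0.0))])])
    model = StructureModel("pair", [a, b])
    sel = contacts.PartnerSelection(kind=contacts.PARTNER_CHAIN,
                                    chain_ids=frozenset("B"))
    assert contacts.contact_residues(model, "A", sel, 4.0) == set()
    assert contacts.contact_residues(model, "A", sel, 4.5) != set()


def test_matches_brute_force_on_random_structures():
    rng = np.random.default_rng(20140104)
    sel_chain = contacts.PartnerSelection(kind=contacts.PARTNER_CHAIN,
                                          chain_ids=frozenset("B"))
    sel_lig = contacts.PartnerSelection(kind=contacts.LIGAND,
                                        het_names=frozenset({"ATP"}))
    for k in range(100):
        model = random_two_chain_model(rng, with_ligand=(k % 2 == 0))
        for sel in (sel_chain, sel_lig):
            for cutoff in (3.0, 4.0, 6.0):
                assert contacts.contact_residues(model, "A", sel, cutoff) == \
                    brute_force_contacts(model, "A", sel, cutoff), f"structure {k}"


def test_monotone_in_cutoff():
    rng = np.random.default_rng(7)
    sel = contacts.PartnerSelection(kind=contacts.PARTNER_CHAIN,
                                    chain_ids=frozenset("B"))
    for _ in range(20):
        model = random_two_chain_model(rng)
        prev = set()
        for cutoff in (2.0, 3.0, 4.0, 5.0, 8.0):
            cur = contacts.contact_residues(model, "A", sel, cutoff)
            assert prev <= cur
            prev = cur


def test_interface_symmetry_under_chain_swap():
    """Relabelling the chains and swapping target/partner roles must yield
    the same residue-level interface."""
    model = fixtures.make_dimer(3.8)
    swapped = StructureModel(id=model.id, chains=[])
    for chain in model.chains:
        new_id = {"A": "B", "B": "A"}[chain.id]
        new_chain = Chain(id=new_id)
        for res in chain.residues:
            new_chain.residues.append(
                Residue(new_id, res.number, res.icode, res.name, res.kind,
                        list(res.atoms)))
        swapped.chains.append(new_chain)
    sel_b = contacts.PartnerSelection(kind=contacts.PARTNER_CHAIN,
                                      chain_ids=frozenset("B"))
    iface = contacts.contact_residues(model, "A", sel_b, 4.0)
    iface_swapped = contacts.contact_residues(swapped, "B",
                                              contacts.PartnerSelection(
                                                  kind=contacts.PARTNER_CHAIN,
                                                  chain_ids=frozenset("A")), 4.0)
    assert iface
    assert {(n, i) for _, n, i in iface} == {(n, i) for _, n, i in iface_swapped}


def test_empty_partner_selection_yields_empty_set(helix12):
    sel = contacts.PartnerSelection(kind=contacts.LIGAND, het_names=frozenset())
    assert contacts.contact_residues(helix12, "A", sel, 4.0) == set()
    with pytest.raises(KeyError):
        contacts.contact_residues(helix12, "Z", sel, 4.0)


def test_annotate_contacts_tags_by_kind():
    model = fixtures.make_dimer(3.5)
    lig = fixtures.make_ligand_complex(3.5)
    model.chains.append(lig.chains[1])  # borrow the ATP group
    anns = contacts.annotate_contacts(
        model, "A",
        [contacts.PartnerSelection(kind=contacts.PARTNER_CHAIN,
                                   chain_ids=frozenset("B")),
         contacts.PartnerSelection(kind=contacts.LIGAND,
                                   het_names=frozenset({"ATP"}))])
    tags = set().union(*anns.tags.values())
    assert tags == {"DIMER", "ATP_AA"}
    for key in anns.tags:
        assert key[0] == "A"


def test_trna_chain_detection():
    model = fixtures.make_helix(6)
    nt = Chain("T")
    for i, name in enumerate(["A", "U", "G", "C"]):
        nt.residues.append(Residue("T", i + 1, "", name, "nucleotide",
                                   [Atom(800 + i, "P", "P", (50.0, float(i), 0.0))]))
    model.chains.append(nt)
    assert contacts.trna_chains(model, "A") == frozenset({"T"})
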