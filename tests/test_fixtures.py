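"""Generator geometry/determinism and curated-table integrity."""

import hashlib

import numpy as np
import pytest

from mutannot import contacts, fixtures
from mutannot.conservation import column_frequencies


def backbone_bond_lengths(model):
    out = {"N-CA": [], "CA-C": [], "C-N": []}
    residues = model.chains[0].residues
    for i, res in enumerate(residues):
        n = np.array(res.atom("N").coords)
        ca = np.array(res.atom("CA").coords)
        c = np.array(res.atom("C").coords)
        out["N-CA"].append(np.linalg.norm(ca - n))
        out["CA-C"].append(np.linalg.norm(c - ca))
        if i + 1 < len(residues):
            n_next = np.array(residues[i + 1].atom("N").coords)
            out["C-N"].append(np.linalg.norm(n_next - c))
    return out


def test_backbone_geometry_is_chemically_sane(helix12, hairpin12):
    for model in (helix12, hairpin12):
        bonds = backbone_bond_lengths(model)
        assert np.allclose(bonds["N-CA"], 1.46, atol=0.01)
        assert np.allclose(bonds["CA-C"], 1.52, atol=0.01)
        assert np.allclose(bonds["C-N"], 1.33, atol=0.01)


def test_generators_are_deterministic():
    a = fixtures.make_helix(10)
    b = fixtures.make_helix(10)
    for ra, rb in zip(a.residues(), b.residues()):
        for aa, ab in zip(ra.atoms, rb.atoms):
            assert aa.coords == ab.coords
    m1 = fixtures.make_msa(20, [{"A": 0.5, "C": 0.5}], seed=4)
    m2 = fixtures.make_msa(20, [{"A": 0.5, "C": 0.5}], seed=4)
    assert m1.rows == m2.rows


def test_dimer_separation_is_honoured():
    for sep in (3.0, 3.8, 5.0):
        model = fixtures.make_dimer(sep)
        assert fixtures._min_interchain_distance(model) == pytest.approx(sep, abs=0.1)
    sel = contacts.PartnerSelection(kind=contacts.PARTNER_CHAIN,
                                    chain_ids=frozenset("B"))
    near = fixtures.make_dimer(3.8)
    assert contacts.contact_residues(near, "A", sel, 4.0)
    assert not contacts.contact_residues(near, "A", sel, 3.5)


def test_ligand_complex_distance_controls_contacts():
    sel = contacts.PartnerSelection(kind=contacts.LIGAND, het_names=frozenset({"ATP"}))
    far = fixtures.make_ligand_complex(4.5)
    assert not contacts.contact_residues(far, "A", sel, 4.0)
    close = fixtures.make_ligand_complex(3.5)
    assert contacts.contact_residues(close, "A", sel, 4.0)


def test_unphysical_generator_parameters_rejected():
    with pytest.raises(ValueError):
        fixtures.make_helix(3)
    with pytest.raises(ValueError):
        fixtures.make_dimer(-1.0)
    with pytest.raises(ValueError):
        fixtures.make_msa(5, [{"A": 0.7}], seed=1)  # probabilities must sum to 1


def test_msa_sampler_recovers_profile_within_3_sigma():
    profile = [{"A": 0.77, "S": 0.21, "E": 0.01, "-": 0.01}]
    msa = fixtures.make_msa(100, profile, seed=2014)
    freqs = column_frequencies(msa, 1)
    for sym, p in profile[0].items():
        n = 100
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(freqs.counts.get(sym, 0) - n * p) <= 3 * sigma + 1e-9
    # delta distribution is exact
    delta = fixtures.make_msa(100, [{"C": 1.0}], seed=0)
    assert column_frequencies(delta, 1).percents == {"C": 100}
    # different seeds give different samples
    assert fixtures.make_msa(50, profile, seed=1).rows != \
        fixtures.make_msa(50, profile, seed=2).rows


def test_curated_counts(curated):
    assert len(curated.substitutions) == 63
    grs = curated.features[curated.features.protein_id == "P41250"]
    assert len(grs) == 14
    tagged = curated.features[curated.features.interaction != ""]
    assert len(tagged) == 12


def test_curated_spreads_sum_to_100(curated):
    for row in curated.features.itertuples():
        total = sum(int(p.split(":")[1]) for p in row.spread.split(","))
        assert total == 100, row.mutation


def test_curated_burial_flags_consistent_with_rsa_rule(curated):
    for row in curated.features.itertuples():
        if row.rsa in ("", "-", "NA"):
            continue
        assert (row.rsa_bold_buried == "1") == (float(row.rsa) <= 20.0), row.mutation


def test_manifest_integrity_detected(monkeypatch, tmp_path):
    data_dir = tmp_path / "data"
    data_dir.mkdir()
    src = fixtures._data_dir()
    for name in ("mutations.tsv", "features.tsv", "categories.tsv",
                 "synthetic_P41250.fasta", "MANIFEST.sha256"):
        (data_dir / name).write_bytes((src / name).read_bytes())
    with open(data_dir / "features.tsv", "a") as fh:
        fh.write("# tampered\n")
    monkeypatch.setattr(fixtures, "_data_dir", lambda: data_dir)
    digest = hashlib.sha256((data_dir / "features.tsv").read_bytes()).hexdigest()
    manifest = (data_dir / "MANIFEST.sha256").read_text()
    assert digest not in manifest
    with pytest.raises(fixtures.IntegrityError):
        fixtures.load_curated()
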