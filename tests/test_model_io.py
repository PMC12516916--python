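"""Round-trips and consistency checks for the two prediction dialects."""

import json

import numpy as np
import pytest

from dimerqa.errors import ConsistencyError, ParseError
from dimerqa.fixtures import make_confidence, make_dimer, write_fixture
from dimerqa.model import Dialect
from dimerqa.model_io import read_af3, read_colabfold, read_reference
from dimerqa.scores import score_model


@pytest.mark.parametrize("dialect", [Dialect.COLABFOLD, Dialect.AF3])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_fixture_round_trip(tmp_path, dialect, seed):
    """Writer → reader reproduces coordinates to PDB precision and confidence
    values to 1e-4, with the structure and confidence indices aligned."""
    model = make_dimer(seed=seed)
    conf = make_confidence(model, quality=0.7, noise_sd=0.05, seed=seed)
    struct_path, conf_path = write_fixture(model, conf, dialect, tmp_path)
    reader = read_colabfold if dialect == Dialect.COLABFOLD else read_af3
    back, bundle = reader(struct_path, conf_path)

    assert back.n_residues == model.n_residues
    assert back.chain_ids() == model.chain_ids()
    for orig, rt in zip(model.iter_residues(), back.iter_residues()):
        assert orig.name == rt.name and orig.auth_number == rt.auth_number
        np.testing.assert_allclose(rt.atom_coords(), orig.atom_coords(), atol=1.5e-3)
    np.testing.assert_allclose(bundle.plddt, conf.plddt, atol=1e-4)
    np.testing.assert_allclose(bundle.pae, conf.pae, atol=1e-4)
    assert bundle.ptm == pytest.approx(conf.ptm, abs=1e-4)
    assert bundle.iptm == pytest.approx(conf.iptm, abs=1e-4)
    # per-residue plddt channel comes from the record, aligned by seq_index
    for res, v in zip(back.iter_residues(), bundle.plddt):
        assert res.plddt == pytest.approx(v)


def test_dialect_invariance(tmp_path):
    """The same synthetic model written in both dialects scores identically."""
    model = make_dimer(seed=5)
    conf = make_confidence(model, quality=0.9, noise_sd=0.03, seed=5)
    p_cf, c_cf = write_fixture(model, conf, Dialect.COLABFOLD, tmp_path / "cf")
    p_a3, c_a3 = write_fixture(model, conf, Dialect.AF3, tmp_path / "af3")
    s_cf = score_model(*read_colabfold(p_cf, c_cf), voroif=0.5)
    s_a3 = score_model(*read_af3(p_a3, c_a3), voroif=0.5)
    for key in ("plddt", "pae", "iplddt", "ipae", "ptm", "iptm", "model_confidence", "pdockq2"):
        assert s_cf.as_row()[key] == pytest.approx(s_a3.as_row()[key], abs=1e-9)


def test_af3_atom_plddt_aggregation(tmp_path):
    """Atom pLDDTs average to per-residue values: constant, two-value mean,
    and a randomized fixture against an independent per-residue loop."""
    model = make_dimer(n_a=50, n_b=50, interface_width=5, seed=3)
    conf = make_confidence(model, quality=0.5, noise_sd=0.0, seed=3)
    struct_path, conf_path = write_fixture(model, conf, Dialect.AF3, tmp_path)
    record = json.loads(conf_path.read_text())

    rng = np.random.default_rng(11)
    record["atom_plddts"] = [round(float(v), 4) for v in rng.uniform(0, 100, len(record["atom_plddts"]))]
    # overwrite two residues with known patterns
    n0 = len(model.chains[0].residues[0].atoms)
    record["atom_plddts"][:n0] = [70.0] * n0
    n1 = len(model.chains[0].residues[1].atoms)
    record["atom_plddts"][n0 : n0 + n1] = [80.0, 90.0] * (n1 // 2) + [85.0] * (n1 % 2)
    conf_path.write_text(json.dumps(record))

    back, bundle = read_af3(struct_path, conf_path)
    assert bundle.plddt[0] == pytest.approx(70.0)
    assert bundle.plddt[1] == pytest.approx(85.0)
    # brute-force oracle: mean per residue over the flat atom list
    pos, expected = 0, []
    for res in back.iter_residues():
        k = len(res.atoms)
        expected.append(np.mean(record["atom_plddts"][pos : pos + k]))
        pos += k
    np.testing.assert_allclose(bundle.plddt, expected, atol=1e-6)


def test_colabfold_length_mismatch(tmp_path):
    model = make_dimer(seed=0)
    conf = make_confidence(model, quality=0.5, seed=0)
    struct_path, conf_path = write_fixture(model, conf, Dialect.COLABFOLD, tmp_path)
    record = json.loads(conf_path.read_text())
    record["plddt"] = record["plddt"][:-1]
    record["pae"] = [row[:-1] for row in record["pae"][:-1]]
    conf_path.write_text(json.dumps(record))
    with pytest.raises(ConsistencyError, match="119"):
        read_colabfold(struct_path, conf_path)


@pytest.mark.parametrize("field", ["pae", "plddt", "ptm", "iptm"])
def test_colabfold_missing_field(tmp_path, field):
    model = make_dimer(seed=0)
    conf = make_confidence(model, quality=0.5, seed=0)
    struct_path, conf_path = write_fixture(model, conf, Dialect.COLABFOLD, tmp_path)
    record = json.loads(conf_path.read_text())
    del record[field]
    conf_path.write_text(json.dumps(record))
    with pytest.raises(ParseError, match=field):
        read_colabfold(struct_path, conf_path)


def test_af3_token_map_mismatch(tmp_path):
    model = make_dimer(seed=1)
    conf = make_confidence(model, quality=0.5, seed=1)
    struct_path, conf_path = write_fixture(model, conf, Dialect.AF3, tmp_path)
    record = json.loads(conf_path.read_text())
    record["token_res_ids"][0] = 999  # points at no structure residue
    conf_path.write_text(json.dumps(record))
    with pytest.raises(ConsistencyError):
        read_af3(struct_path, conf_path)


def test_reference_bfactor_and_dimer_check(tmp_path):
    """B-factor survives the reference round-trip; single chains are rejected
    for dimer use."""
    from dimerqa.fixtures import write_reference

    model = make_dimer(seed=9)
    path = write_reference(model, tmp_path)
    ref = read_reference(path)
    for orig, rt in zip(model.iter_residues(), ref.iter_residues()):
        assert rt.bfactor == pytest.approx(orig.bfactor, abs=0.01)
        assert rt.plddt is None

    # strip chain B out of the PDB text -> one chain -> dimer-usage error
    lines = [l for l in path.read_text().splitlines() if not (l.startswith(("ATOM", "HETATM")) and l[21] == "B")]
    single = tmp_path / "single.pdb"
    single.write_text("\n".join(lines) + "\n")
    with pytest.raises(ParseError, match="dimer"):
        read_reference(single)
    assert len(read_reference(single, require_dimer=False).chains) == 1


def test_altloc_resolution(tmp_path):
    """Alternate locations collapse to one atom per name: highest occupancy
    wins, ties go to file order; waters are dropped."""
    pdb = tmp_path / "alt.pdb"
    pdb.write_text(
        "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.40 10.00           N  \n"
        "ATOM      2  N  BALA A   1       9.000   0.000   0.000  0.60 10.00           N  \n"
        "ATOM      3  CA AALA A   1       1.000   0.000   0.000  0.50 20.00           C  \n"
        "ATOM      4  CA BALA A   1       8.000   0.000   0.000  0.50 30.00           C  \n"
        "ATOM      5  CA  GLY A   2       2.000   0.000   0.000  1.00 15.00           C  \n"
        "HETATM    6  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O  \n"
        "ATOM      7  CA  ALA B   1       0.000   4.000   0.000  1.00 12.00           C  \n"
        "ATOM      8  CA  GLY B   2       3.800   4.000   0.000  1.00 18.00           C  \n"
        "END\n"
    )
    model = read_reference(pdb)
    res1 = model.chains[0].residues[0]
    names = [n for n, _ in res1.atoms]
    assert names == ["N", "CA"]
    assert res1.atom("N")[0] == pytest.approx(9.0)   # occupancy 0.60 wins
    assert res1.atom("CA")[0] == pytest.approx(1.0)  # tie -> first in file
    assert model.n_residues == 4  # water excluded
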