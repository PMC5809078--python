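"""Structure reading/writing, residue classification and truncation."""

import numpy as np
import pytest

from kinkscan.structure_io import (
    AtomRecord,
    ResidueRecord,
    classify_residue,
    read_structure,
    truncate_sidechain,
    write_structure,
)
from kinkscan.synthetic_data import build_duplex, plant_intercalator
from kinkscan.duplex_builder import build_curated_duplexes

MINIMAL_PDB = (
    "ATOM      1  C1'  DA A   1       1.000   2.000   3.000  1.00 20.00           C  \n"
    "END\n"
)

THREE_MODEL_PDB = "".join(
    f"MODEL     {i + 1:4d}\n"
    f"ATOM      1  C1'  DA A   1       1.000   2.000   {float(i):7.3f}  1.00 20.00           C  \n"
    "ENDMDL\n"
    for i in range(3)
) + "END\n"


def _coords(model):
    return np.array([a.position for r in model.iter_residues() for a in r.atoms])


class TestReadStructure:
    def test_minimal_single_atom_file(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(MINIMAL_PDB)
        with pytest.warns(UserWarning, match="no experiment-method"):
            ens = read_structure(path)
        assert len(ens.models) == 1
        model = ens.models[0]
        assert list(model.chains) == ["A"]
        (res,) = model.iter_residues()
        assert res.name == "DA" and len(res.atoms) == 1
        np.testing.assert_allclose(res.atoms[0].position, [1.0, 2.0, 3.0])

    def test_model_blocks_become_models(self, tmp_path):
        path = tmp_path / "three.pdb"
        path.write_text(THREE_MODEL_PDB)
        with pytest.warns(UserWarning):
            ens = read_structure(path)
        assert len(ens.models) == 3
        zs = [m.chains["A"][0].atoms[0].position[2] for m in ens.models]
        assert zs == [0.0, 1.0, 2.0]

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "nope.pdb")

    def test_trajectory_topology_mismatch_raises(self, tmp_path):
        bad = THREE_MODEL_PDB.replace(" DA A   1 ", " DG A   1 ", 1)
        path = tmp_path / "bad.pdb"
        path.write_text(bad)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="topology mismatch"):
                read_structure(path, trajectory=True)

    def test_experiment_method_read_from_header(self, tmp_path):
        path = tmp_path / "xray.pdb"
        path.write_text("EXPDTA    X-RAY DIFFRACTION\n" + MINIMAL_PDB)
        ens = read_structure(path)
        assert ens.metadata["experiment_method"] == "X-RAY DIFFRACTION"


class TestWriteStructure:
    @pytest.mark.parametrize("fmt,ext", [("pdb", ".pdb"), ("mmcif", ".cif")])
    def test_round_trip_coordinates(self, tmp_path, kinked_model, fmt, ext):
        path = tmp_path / f"dup{ext}"
        write_structure(kinked_model, path, format=fmt)
        with pytest.warns(UserWarning):
            ens = read_structure(path)
        a, b = _coords(kinked_model), _coords(ens.models[0])
        assert a.shape == b.shape
        assert np.max(np.abs(a - b)) <= 1e-3

    def test_pdb_and_mmcif_agree(self, tmp_path, kinked_model):
        p1, p2 = tmp_path / "x.pdb", tmp_path / "x.cif"
        write_structure(kinked_model, p1, format="pdb")
        write_structure(kinked_model, p2, format="mmcif")
        with pytest.warns(UserWarning):
            a = _coords(read_structure(p1).models[0])
            b = _coords(read_structure(p2).models[0])
        assert np.max(np.abs(a - b)) <= 1e-3

    def test_multi_model_emits_model_blocks(self, tmp_path, ideal_model, kinked_model):
        from kinkscan.structure_io import StructureEnsemble

        path = tmp_path / "ens.pdb"
        write_structure(StructureEnsemble(models=[ideal_model, kinked_model, ideal_model]),
                        path)
        text = path.read_text()
        assert text.count("MODEL ") == 3 and text.count("ENDMDL") == 3

    def test_duplex_survives_serialization(self, tmp_path, kinked_model):
        """Full-pipeline round trip: the re-read file yields the same
        base-pair list."""
        path = tmp_path / "dup.pdb"
        write_structure(kinked_model, path)
        with pytest.warns(UserWarning):
            reread = read_structure(path).models[0]
        d0 = build_curated_duplexes(kinked_model)[0]
        d1 = build_curated_duplexes(reread)[0]
        ids0 = [(p.res_I.id, p.res_II.id) for p in d0.pairs]
        ids1 = [(p.res_I.id, p.res_II.id) for p in d1.pairs]
        assert ids0 == ids1 and d0.sequence_I == d1.sequence_I


def _residue(name, atom_names, with_o2prime=False):
    names = list(atom_names) + (["O2'"] if with_o2prime else [])
    atoms = [AtomRecord(name=n, element=n[0], position=np.random.rand(3) * 10)
             for n in names]
    return ResidueRecord(chain_id="A", number=1, name=name, atoms=atoms)


PURINE = ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"]
PYRIMIDINE = ["N1", "C2", "N3", "C4", "C5", "C6"]


class TestClassifyResidue:
    @pytest.mark.parametrize("name,atoms,o2,expected", [
        ("DA", PURINE + ["C1'"], False, "dna_nucleotide"),
        ("A", PURINE + ["C1'"], False, "dna_nucleotide"),   # legacy one-letter
        ("A", PURINE + ["C1'"], True, "rna_nucleotide"),    # ribose marker
        ("U", PYRIMIDINE, False, "rna_nucleotide"),
        ("5CM", PYRIMIDINE, False, "modified_nucleotide"),
        ("LEU", ["N", "CA", "C", "O", "CB"], False, "amino_acid"),
        ("HOH", ["O"], False, "other"),
        ("XYZ", ["C1", "C2"], False, "other"),
    ])
    def test_kinds(self, name, atoms, o2, expected):
        assert classify_residue(_residue(name, atoms, o2)) == expected

    def test_total_on_arbitrary_names(self):
        # never raises, whatever the residue looks like
        for name in ("", "???", "ZN", "1MA", "PSU"):
            assert classify_residue(_residue(name, ["X1"])) in {
                "dna_nucleotide", "rna_nucleotide", "modified_nucleotide",
                "amino_acid", "other",
            }


class TestTruncateSidechain:
    def test_met_to_ala(self, kinked_model):
        model = plant_intercalator(kinked_model, 5, "MET", 2.0)
        out = truncate_sidechain(model, ("P", 1, ""), "ALA")
        res = out.find_residue("P", 1)
        assert res.name == "ALA"
        assert res.atom_names() == {"N", "CA", "C", "O", "CB"}

    def test_phe_to_gly(self, kinked_model):
        model = plant_intercalator(kinked_model, 5, "PHE", 2.0)
        out = truncate_sidechain(model, ("P", 1, ""), "GLY")
        res = out.find_residue("P", 1)
        assert res.name == "GLY"
        assert res.atom_names() == {"N", "CA", "C", "O"}

    def test_retained_atoms_do_not_move(self, kinked_model):
        model = plant_intercalator(kinked_model, 5, "LEU", 2.0)
        before = {a.name: a.position.copy()
                  for a in model.find_residue("P", 1).atoms}
        out = truncate_sidechain(model, ("P", 1, ""), "ALA")
        for a in out.find_residue("P", 1).atoms:
            assert np.max(np.abs(a.position - before[a.name])) == 0.0

    def test_gly_to_ala_unsupported(self, kinked_model):
        model = plant_intercalator(kinked_model, 5, "LEU", 2.0)
        model = truncate_sidechain(model, ("P", 1, ""), "GLY")
        with pytest.raises(ValueError, match="no CB"):
            truncate_sidechain(model, ("P", 1, ""), "ALA")

    def test_non_amino_acid_rejected(self, ideal_model):
        with pytest.raises(TypeError):
            truncate_sidechain(ideal_model, ("A", 1, ""), "ALA")
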