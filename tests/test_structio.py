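import numpy as np
import pytest

from rristack.errors import (
    EmptyFile,
    MalformedProfile,
    MappingFailure,
    NoPolymerResidues,
    UnknownChain,
)
from rristack.structio import (
    Chain,
    Residue,
    align_structure_to_sequence,
    parse_fasta,
    parse_pdb_complex,
    parse_psiblast_profile,
    write_pdb,
)


def atom_line(serial, name, resname, chain, resseq, x, y, z,
              occ=1.00, altloc=" ", element=None, record="ATOM"):
    """Fixed-column PDB coordinate record."""
    element = element or name.strip()[0]
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (f"{record:<6s}{serial:>5d} {name_field}{altloc}{resname:<3s} "
            f"{chain}{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{occ:6.2f}{0.0:6.2f}          {element:>2s}")


def write_lines(tmp_path, lines, name="test.pdb"):
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


class TestParsePdb:
    def test_hydrogens_dropped(self, tmp_path):
        path = write_lines(tmp_path, [
            atom_line(1, "CA", "ALA", "A", 1, 1.0, 2.0, 3.0),
            atom_line(2, "H", "ALA", "A", 1, 1.5, 2.5, 3.5, element="H"),
        ])
        rec = parse_pdb_complex(path, {"A"}, set())
        (chain,) = rec.receptor_chains
        assert len(chain.residues) == 1
        assert len(chain.residues[0].atoms) == 1
        assert chain.residues[0].atoms[0].element == "C"

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        path = write_lines(tmp_path, [
            atom_line(1, "CA", "ALA", "A", 1, 1.0, 0.0, 0.0,
                      occ=0.60, altloc="A"),
            atom_line(2, "CA", "ALA", "A", 1, 9.0, 0.0, 0.0,
                      occ=0.40, altloc="B"),
        ])
        rec = parse_pdb_complex(path, {"A"}, set())
        atom = rec.receptor_chains[0].residues[0].atoms[0]
        assert atom.coords[0] == pytest.approx(1.0)

    def test_altloc_tie_prefers_first_identifier(self, tmp_path):
        path = write_lines(tmp_path, [
            atom_line(1, "CA", "ALA", "A", 1, 9.0, 0.0, 0.0,
                      occ=0.50, altloc="B"),
            atom_line(2, "CA", "ALA", "A", 1, 1.0, 0.0, 0.0,
                      occ=0.50, altloc="A"),
        ])
        rec = parse_pdb_complex(path, {"A"}, set())
        atom = rec.receptor_chains[0].residues[0].atoms[0]
        assert atom.coords[0] == pytest.approx(1.0)

    def test_hetatm_only_raises(self, tmp_path):
        path = write_lines(tmp_path, [
            atom_line(1, "C1", "GLC", "A", 1, 0.0, 0.0, 0.0,
                      record="HETATM"),
        ])
        with pytest.raises(NoPolymerResidues):
            parse_pdb_complex(path, {"A"}, set())

    def test_unknown_chain_raises(self, tmp_path):
        path = write_lines(tmp_path, [
            atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0),
        ])
        with pytest.raises(UnknownChain):
            parse_pdb_complex(path, {"A"}, {"Z"})

    def test_selenomethionine_mapped_to_parent(self, tmp_path):
        path = write_lines(tmp_path, [
            atom_line(1, "CA", "MSE", "A", 1, 0.0, 0.0, 0.0,
                      record="HETATM"),
            atom_line(2, "CA", "ALA", "A", 2, 3.8, 0.0, 0.0),
        ])
        rec = parse_pdb_complex(path, {"A"}, set())
        assert [r.aa for r in rec.receptor_chains[0].residues] == ["M", "A"]

    def test_waters_dropped(self, tmp_path):
        path = write_lines(tmp_path, [
            atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0),
            atom_line(2, "O", "HOH", "A", 100, 5.0, 5.0, 5.0,
                      record="HETATM"),
        ])
        rec = parse_pdb_complex(path, {"A"}, set())
        assert len(rec.receptor_chains[0].residues) == 1

    def test_no_parsed_atom_is_hydrogen(self, small_complex, tmp_path):
        record, _ = small_complex
        path = tmp_path / "rt.pdb"
        write_pdb(record, path)
        parsed = parse_pdb_complex(path, {"A"}, {"B"})
        for chain in parsed.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    assert atom.element not in ("H", "D")
                    assert np.isfinite(atom.coords).all()

    def test_round_trip_preserves_structure(self, small_complex, tmp_path):
        record, _ = small_complex
        path = tmp_path / "rt.pdb"
        write_pdb(record, path)
        parsed = parse_pdb_complex(path, {"A"}, {"B"})
        for orig_chain, new_chain in zip(record.chains, parsed.chains):
            orig_res = orig_chain.resolved_residues
            new_res = new_chain.resolved_residues
            assert len(orig_res) == len(new_res)
            for ro, rn in zip(orig_res, new_res):
                assert ro.aa == rn.aa
                assert len(ro.atoms) == len(rn.atoms)
                np.testing.assert_allclose(
                    ro.coord_matrix(), rn.coord_matrix(), atol=1e-3
                )


class TestParseFasta:
    def test_single_record(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">x\nACD\n")
        assert parse_fasta(path) == {"x": "ACD"}

    def test_multi_record_and_normalization(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">a\nacd\n>b\nWWW*\n>c\nKK\nKK\n")
        seqs = parse_fasta(path)
        assert len(seqs) == 3
        assert seqs["a"] == "ACD"
        assert seqs["b"] == "WWW"
        assert seqs["c"] == "KKKK"

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text("")
        with pytest.raises(EmptyFile):
            parse_fasta(path)


PSSM_HEADER = (
    "\nLast position-specific scoring matrix computed\n"
    "            " + "   ".join("ARNDCQEGHILKMFPSTWYV") + "   "
    + "   ".join("ARNDCQEGHILKMFPSTWYV") + "\n"
)


def pssm_row(idx, aa, scores, pcts, tail="  1.00 0.50"):
    return (f"{idx:>5d} {aa}  " + " ".join(str(s) for s in scores)
            + "  " + " ".join(str(p) for p in pcts) + tail)


class TestPsiblastProfile:
    def make_file(self, tmp_path, rows):
        path = tmp_path / "p.pssm"
        path.write_text(PSSM_HEADER + "\n".join(rows) + "\n\n")
        return path

    def test_scores_and_frequencies(self, tmp_path):
        scores1 = [1] + [0] * 19          # A column = 1
        pcts1 = [100] + [0] * 19
        scores2 = [0] * 19 + [2]          # V column = 2
        pcts2 = [50] * 2 + [0] * 18
        path = self.make_file(tmp_path, [
            pssm_row(1, "A", scores1, pcts1),
            pssm_row(2, "V", scores2, pcts2),
        ])
        prof = parse_psiblast_profile(path)
        assert prof.length == 2
        assert prof.pssm[0, 0] == 1.0       # column A
        assert prof.pssm[1, 19] == 2.0      # column V
        np.testing.assert_allclose(prof.psfm.sum(axis=1), [1.0, 1.0])
        assert prof.psfm[1, 0] == pytest.approx(0.5)
        assert prof.conservation is None

    def test_percentages_renormalized(self, tmp_path):
        pcts = [30, 30] + [0] * 18  # sums to 60, not 100
        path = self.make_file(tmp_path, [pssm_row(1, "A", [0] * 20, pcts)])
        prof = parse_psiblast_profile(path)
        assert prof.psfm[0].sum() == pytest.approx(1.0)
        assert prof.psfm[0, 0] == pytest.approx(0.5)

    def test_truncated_row_raises(self, tmp_path):
        path = self.make_file(tmp_path, [
            pssm_row(1, "A", [0] * 20, [100] + [0] * 13, tail=""),
        ])
        with pytest.raises(MalformedProfile):
            parse_psiblast_profile(path)


def make_chain(letters, full_sequence):
    residues = [
        Residue(chain_id="A", struct_index=i, aa=aa,
                atoms=[__import__("rristack.structio", fromlist=["Atom"])
                       .Atom("CA", "C", np.array([3.8 * i, 0.0, 0.0]))])
        for i, aa in enumerate(letters)
    ]
    return Chain("A", residues, full_sequence=full_sequence)


class TestAlignment:
    def test_identity_mapping(self):
        chain = align_structure_to_sequence(make_chain("ACD", "ACD"))
        assert [r.seq_position for r in chain.residues] == [0, 1, 2]

    def test_internal_missing_residue(self):
        chain = align_structure_to_sequence(make_chain("AD", "ACD"))
        assert [r.seq_position for r in chain.residues] == [0, 2]

    def test_low_identity_raises(self):
        with pytest.raises(MappingFailure):
            align_structure_to_sequence(make_chain("WWW", "AAAA"))

    def test_mapping_strictly_increasing(self):
        chain = align_structure_to_sequence(
            make_chain("ACDKLM", "ACDEFGKLM")
        )
        positions = [r.seq_position for r in chain.resolved_residues]
        assert positions == sorted(positions)
        assert len(set(positions)) == len(positions)
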