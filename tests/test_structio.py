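import numpy as np
import pytest

from oxfoot.structio import (
    RATES_TABLE_SCHEMA,
    ResidueId,
    SiteAssignment,
    StructureParseError,
    TableSchemaError,
    read_structure,
    read_table,
    write_annotated_structure,
)


class TestResidueId:
    def test_parse_roundtrip(self):
        r = ResidueId.parse("A:W17")
        assert (r.chain, r.number, r.code) == ("A", 17, "W")
        assert str(r) == "A:W17"

    @pytest.mark.parametrize("bad", [("A", 0, "W"), ("A", 3, "Z")])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            ResidueId(*bad)


class TestSiteAssignment:
    def test_ambiguous_pair_must_be_adjacent(self):
        a, b = ResidueId("A", 10, "W"), ResidueId("A", 12, "F")
        with pytest.raises(ValueError):
            SiteAssignment((a, b), ambiguous=True)

    def test_parse_ambiguous(self):
        s = SiteAssignment.parse("A:W10|A:F11")
        assert s.ambiguous and len(s.residues) == 2


class TestReadStructure:
    def test_fixture_roundtrip(self, tripeptide_pdb):
        s = read_structure(tripeptide_pdb)
        assert len(s.residues) == 3
        assert len(s.atoms) == 13  # 4 backbone x3 + 1 CB
        assert s.chain_sequence("A") == "GAG"

    def test_model_selection(self, tmp_path):
        text = (
            "MODEL        1\n"
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  CA  GLY A   1       5.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
        )
        p = tmp_path / "multi.pdb"
        p.write_text(text)
        s = read_structure(p, model_index=2)
        assert len(s.atoms) == 1 and s.atoms[0].x == pytest.approx(5.0)

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        text = (
            "ATOM      1  CA AGLY A   1       1.000   0.000   0.000  0.60  0.00           C\n"
            "ATOM      2  CA BGLY A   1       9.000   0.000   0.000  0.40  0.00           C\n"
        )
        p = tmp_path / "alt.pdb"
        p.write_text(text)
        s = read_structure(p)
        assert len(s.atoms) == 1
        assert s.atoms[0].x == pytest.approx(1.0)

    def test_waters_and_hydrogens_skipped(self, tmp_path):
        text = (
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  H   GLY A   1       0.500   0.000   0.000  1.00  0.00           H\n"
            "ATOM      3  O   HOH A  99       9.000   9.000   9.000  1.00  0.00           O\n"
        )
        p = tmp_path / "mix.pdb"
        p.write_text(text)
        assert len(read_structure(p).atoms) == 1

    def test_empty_model_errors(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("REMARK nothing here\n")
        with pytest.raises(StructureParseError):
            read_structure(p)


class TestReadTable:
    HEADER = "peptide_id,site,mod_mass,time_ms,area_unmod,area_mod,replicate"

    def test_two_rows(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(f"{self.HEADER}\npep1,A:W17,16,0,100,0,1\npep1,A:W17,16,5,80,20,1\n")
        df = read_table(p, RATES_TABLE_SCHEMA)
        assert len(df) == 2
        assert df["time_ms"].tolist() == [0.0, 5.0]

    def test_extra_column_ignored(self, tmp_path, caplog):
        p = tmp_path / "t.csv"
        p.write_text(f"{self.HEADER},rt_min\npep1,A:W17,16,0,100,0,1,12.3\n")
        df = read_table(p, RATES_TABLE_SCHEMA)
        assert len(df) == 1

    def test_missing_required_column_named(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("peptide_id,site,mod_mass,area_unmod,area_mod\npep1,A:W17,16,1,1\n")
        with pytest.raises(TableSchemaError, match="time_ms"):
            read_table(p, RATES_TABLE_SCHEMA)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(f"{self.HEADER}\npep1,A:W17,16,oops,100,0,1\n")
        with pytest.raises(TableSchemaError, match="time_ms"):
            read_table(p, RATES_TABLE_SCHEMA)

    def test_tab_and_crlf_dialects(self, tmp_path):
        p = tmp_path / "t.tsv"
        header = self.HEADER.replace(",", "\t")
        p.write_bytes(f"{header}\r\npep1\tA:W17\t16\t0\t100\t0\t1\r\n".encode())
        df = read_table(p, RATES_TABLE_SCHEMA)
        assert df["area_unmod"].iloc[0] == 100.0

    def test_column_order_free(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "time_ms,peptide_id,site,mod_mass,area_mod,area_unmod,replicate\n"
            "5,pep1,A:W17,16,20,80,1\n"
        )
        df = read_table(p, RATES_TABLE_SCHEMA)
        assert df["area_unmod"].iloc[0] == 80.0


class TestWriteAnnotated:
    def test_bfactor_values_and_sentinel(self, tripeptide, tmp_path):
        res2 = tripeptide.residues[1]
        out = tmp_path / "out.pdb"
        write_annotated_structure(tripeptide, {res2: 1.5}, out)
        bvals = {}
        for line in out.read_text().splitlines():
            if line.startswith("ATOM"):
                bvals.setdefault(int(line[22:26]), set()).add(float(line[60:66]))
        assert bvals[1] == {0.0} and bvals[2] == {1.5} and bvals[3] == {0.0}

    def test_clamping_warns(self, tripeptide, tmp_path):
        res1 = tripeptide.residues[0]
        out = tmp_path / "out.pdb"
        with pytest.warns(UserWarning, match="clamped"):
            write_annotated_structure(tripeptide, {res1: 12345.0}, out)
        line = next(l for l in out.read_text().splitlines() if l.startswith("ATOM"))
        assert float(line[60:66]) == pytest.approx(999.99)

    def test_write_read_roundtrip_preserves_atoms(self, tripeptide, tmp_path):
        out = tmp_path / "rt.pdb"
        write_annotated_structure(tripeptide, {}, out)
        back = read_structure(out)
        assert len(back.atoms) == len(tripeptide.atoms)
        for a, b in zip(tripeptide.atoms, back.atoms):
            assert a.name == b.name and a.residue == b.residue
            assert np.allclose([a.x, a.y, a.z], [b.x, b.y, b.z], atol=5e-4)
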