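"""Geometric interaction profiling of docked complexes and report ingest."""

import math

import numpy as np
import pytest

from ahiot.interactions import (InteractionRules, detect_interactions,
                                ingest_plip_report, parse_complex, profile)
from ahiot.synthetic import ComplexGenSpec, gen_complex


def _write(tmp_path, text, name="c.pdb"):
    p = tmp_path / name
    p.write_text(text)
    return p


def _parse(tmp_path, spec):
    text, expected = gen_complex(spec)
    path = _write(tmp_path, text)
    return parse_complex(path, ligand_selector="LIG"), expected


MINIMAL = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.450   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.300   2.400   0.000  1.00  0.00           O
ATOM      5  CB  GLY A   1       2.000  -1.400   0.000  1.00  0.00           C
HETATM    6  C1  LIG L   2      20.000   0.000   0.000  1.00  0.00           C
HETATM    7  C2  LIG L   2      21.500   0.000   0.000  1.00  0.00           C
HETATM    8  O1  LIG L   2      22.100   1.300   0.000  1.00  0.00           O
END
"""

WATER_ONLY = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
HETATM    2  O   HOH W   2       5.000   0.000   0.000  1.00  0.00           O
END
"""

ALTLOC = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
HETATM    2  C1 ALIG L   2       9.000   0.000   0.000  0.50  0.00           C
HETATM    3  C1 BLIG L   2       9.200   0.000   0.000  0.50  0.00           C
END
"""


class TestParseComplex:
    def test_minimal_fixture_counts(self, tmp_path):
        c = parse_complex(_write(tmp_path, MINIMAL), ligand_selector="LIG")
        assert len(c.protein_atoms) == 5
        assert len(c.ligand_atoms) == 3

    def test_water_is_not_a_ligand(self, tmp_path):
        with pytest.raises(ValueError, match="no non-water"):
            parse_complex(_write(tmp_path, WATER_ONLY))

    def test_altloc_keeps_single_atom(self, tmp_path):
        c = parse_complex(_write(tmp_path, ALTLOC), ligand_selector="LIG")
        assert len(c.ligand_atoms) == 1

    def test_wrong_selector_lists_candidates(self, tmp_path):
        with pytest.raises(ValueError, match="LIG"):
            parse_complex(_write(tmp_path, MINIMAL), ligand_selector="XYZ")


class TestDetectInteractions:
    def test_salt_bridge_distance_arithmetic(self, tmp_path):
        c, _ = _parse(tmp_path, ComplexGenSpec(planted=[("salt_bridge", 1)]))
        records = detect_interactions(c)
        assert [r.type for r in records] == ["salt_bridge"]
        # cation sits 4.8 A from the carboxylate-oxygen centroid (<= 5.5)
        assert records[0].distance == pytest.approx(4.8, abs=0.01)
        assert records[0].residue.startswith("ASP")

    def test_hbond_beyond_cutoff_excluded(self, tmp_path):
        text, _ = gen_complex(ComplexGenSpec(planted=[("hbond", 1)]))
        # push the ligand acceptor from 3.0 A to 4.5 A, past the 4.1 A cutoff
        text = text.replace("   3.000", "   4.500")
        c = parse_complex(_write(tmp_path, text), ligand_selector="LIG")
        assert detect_interactions(c) == []

    def test_parallel_pi_stacking_detected(self, tmp_path):
        c, _ = _parse(tmp_path, ComplexGenSpec(planted=[("pi_stacking", 1)]))
        records = detect_interactions(c)
        assert [r.type for r in records] == ["pi_stacking"]
        assert records[0].distance == pytest.approx(4.2, abs=0.01)
        assert records[0].angle == pytest.approx(0.0, abs=5.0)

    def test_mixed_planting_one_record_each(self, tmp_path):
        spec = ComplexGenSpec(planted=[("hbond", 1), ("hydrophobic", 1), ("salt_bridge", 1)])
        c, expected = _parse(tmp_path, spec)
        prof = profile(c)
        assert prof.d_i == 3
        assert prof.count_by_type() == {"hbond": 1, "hydrophobic": 1, "salt_bridge": 1}

    @pytest.mark.parametrize("planted", [
        [("salt_bridge", 3)],
        [],
        [("hbond", 2), ("pi_cation", 1)],
        [("pi_stacking", 1), ("hydrophobic", 2)],
    ])
    def test_planted_recovery_exact(self, tmp_path, planted):
        c, expected = _parse(tmp_path, ComplexGenSpec(planted=planted, decoy_atoms=5))
        prof = profile(c)
        assert prof.d_i == expected.d_i
        assert prof.count_by_type() == expected.count_by_type()

    def test_rigid_transform_invariance(self, tmp_path, rng):
        from scipy.spatial.transform import Rotation

        spec = ComplexGenSpec(planted=[("salt_bridge", 1), ("hbond", 1),
                                       ("pi_stacking", 1)], decoy_atoms=3)
        c, _ = _parse(tmp_path, spec)
        d_before = profile(c).d_i
        R = Rotation.random(rng=12345).as_matrix()
        t = np.array([13.0, -7.0, 42.0])

        def move(atoms):
            return [type(a)(name=a.name, element=a.element, resname=a.resname,
                            resseq=a.resseq, chain=a.chain,
                            pos=tuple(R @ np.array(a.pos) + t), charge=a.charge)
                    for a in atoms]

        moved = type(c)(complex_id=c.complex_id,
                        protein_atoms=move(c.protein_atoms),
                        ligand_atoms=move(c.ligand_atoms))
        assert profile(moved).d_i == d_before

    def test_tightening_cutoffs_never_increases_di(self, tmp_path):
        spec = ComplexGenSpec(planted=[("hbond", 1), ("hydrophobic", 1),
                                       ("salt_bridge", 1), ("pi_cation", 1)])
        c, _ = _parse(tmp_path, spec)
        loose = profile(c, InteractionRules()).d_i
        tight = InteractionRules(hbond_dist_max=2.5, hydrophobic_dist_max=3.0,
                                 salt_bridge_dist_max=4.0, pi_cation_dist_max=4.0)
        assert profile(c, tight).d_i <= loose

    def test_removing_ligand_atom_never_increases_di(self, tmp_path):
        spec = ComplexGenSpec(planted=[("hbond", 1), ("salt_bridge", 1)])
        c, _ = _parse(tmp_path, spec)
        d_full = profile(c).d_i
        reduced = type(c)(complex_id=c.complex_id, protein_atoms=c.protein_atoms,
                          ligand_atoms=c.ligand_atoms[:-1])
        assert profile(reduced).d_i <= d_full


PLIP_XML_9 = """<?xml version="1.0"?>
<report>
  <bindingsite id="1">
    <interactions>
      <hydrogen_bonds>
        {hb}
      </hydrogen_bonds>
      <hydrophobic_interactions>
        {hp}
      </hydrophobic_interactions>
      <salt_bridges>
        <salt_bridge id="1"><restype>ASP</restype><resnr>97</resnr><reschain>A</reschain><dist>4.2</dist></salt_bridge>
      </salt_bridges>
      <pi_stacks>
        <pi_stack id="1"><restype>TRP</restype><resnr>94</resnr><reschain>A</reschain><centdist>4.4</centdist></pi_stack>
      </pi_stacks>
      <water_bridges>
        <water_bridge id="1"><restype>TYR</restype><resnr>116</resnr><reschain>A</reschain><dist>3.4</dist></water_bridge>
      </water_bridges>
    </interactions>
  </bindingsite>
</report>
"""


def _xml_nine():
    hb = "".join(
        f'<hydrogen_bond id="{i}"><restype>SER</restype><resnr>{i}</resnr>'
        f"<reschain>A</reschain><dist_d-a>3.1</dist_d-a></hydrogen_bond>"
        for i in range(1, 4))
    hp = "".join(
        f'<hydrophobic_interaction id="{i}"><restype>VAL</restype><resnr>{i}</resnr>'
        f"<reschain>A</reschain><dist>3.8</dist></hydrophobic_interaction>"
        for i in range(1, 4))
    return PLIP_XML_9.format(hb=hb, hp=hp)


class TestPlipIngest:
    def test_nine_interactions_counted(self, tmp_path):
        # synthetic report in the profiler tool's XML layout
        p = tmp_path / "report.xml"
        p.write_text(_xml_nine())
        prof = ingest_plip_report(p)
        assert prof.d_i == 9
        assert prof.count_by_type() == {
            "hbond": 3, "hydrophobic": 3, "salt_bridge": 1,
            "pi_stacking": 1, "other": 1}

    def test_other_types_toggleable(self, tmp_path):
        p = tmp_path / "report.xml"
        p.write_text(_xml_nine())
        assert ingest_plip_report(p, include_other=False).d_i == 8

    def test_empty_report_zero(self, tmp_path):
        p = tmp_path / "empty.xml"
        p.write_text("<report><bindingsite><interactions></interactions></bindingsite></report>")
        assert ingest_plip_report(p).d_i == 0

    def test_text_report_rows_counted(self, tmp_path):
        text = (
            "**Salt Bridges**\n"
            "+-------+\n"
            "| RESNR | RESTYPE |\n"
            "+-------+\n"
            "| 97 | ASP |\n"
            "| 288 | GLU |\n"
            "+-------+\n"
        )
        p = tmp_path / "report.txt"
        p.write_text(text)
        prof = ingest_plip_report(p)
        assert prof.d_i == 2
        assert prof.count_by_type() == {"salt_bridge": 2}

    def test_unrecognized_schema_errors(self, tmp_path):
        p = tmp_path / "junk.txt"
        p.write_text("nothing to see here\n")
        with pytest.raises(ValueError, match="schema"):
            ingest_plip_report(p)

    def test_profiler_matches_synthetic_report_on_salt_bridges(self, tmp_path):
        # cross-route check: geometric profiler vs report ingest on the
        # planted-salt-bridge fixture
        c, _ = _parse(tmp_path, ComplexGenSpec(planted=[("salt_bridge", 2)]))
        geometric = profile(c).count_by_type()["salt_bridge"]
        xml = ("<report><bindingsite><interactions><salt_bridges>"
               + "".join(f'<salt_bridge id="{i}"><restype>ASP</restype>'
                         f"<resnr>{i}</resnr><reschain>A</reschain>"
                         f"<dist>4.8</dist></salt_bridge>" for i in (1, 2))
               + "</salt_bridges></interactions></bindingsite></report>")
        p = tmp_path / "sb.xml"
        p.write_text(xml)
        assert ingest_plip_report(p).count_by_type()["salt_bridge"] == geometric
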