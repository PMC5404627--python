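import numpy as np
import pytest

from poremap import (
    SelectionSpec,
    SiteMeta,
    read_trajectory,
    select_representatives,
    trim,
    write_heat_structure,
)
from poremap.errors import (
    BoundsError,
    DimensionError,
    FormatError,
    SelectionError,
    UnsupportedGeometryError,
)
from poremap.trajio import FrameSeries, register_reader, write_trajectory_pdb

from conftest import make_frames

PDB_TWO_MODELS = """\
CRYST1   70.000   70.000  120.000  90.00  90.00  90.00 P 1           1
MODEL        1
ATOM      1  P   POP A   1      10.000  20.000  30.000  1.00  0.00           P
ATOM      2  P   POP A   2      15.000  25.000  35.000  1.00  0.00           P
ATOM      3  OW  SOL A   3       1.000   2.000   3.000  1.00  0.00           O
ATOM      4  OW  SOL A   4       4.000   5.000   6.000  1.00  0.00           O
ENDMDL
MODEL        2
ATOM      1  P   POP A   1      11.000  20.000  30.000  1.00  0.00           P
ATOM      2  P   POP A   2      15.000  26.000  35.000  1.00  0.00           P
ATOM      3  OW  SOL A   3       1.000   2.000   4.000  1.00  0.00           O
ATOM      4  OW  SOL A   4       4.500   5.000   6.000  1.00  0.00           O
ENDMDL
END
"""

GRO_ONE_FRAME = """\
test frame t= 0.0
    2
    1POPC     P    1   1.000   2.000   3.000
    2POPC     P    2   4.000   5.000   6.000
   7.00000   7.00000  12.00000
"""


class TestReadPdb:
    def test_two_model_extraction(self, tmp_path):
        path = tmp_path / "two.pdb"
        path.write_text(PDB_TWO_MODELS)
        traj = read_trajectory(path, dt=10.0)
        assert traj.n_frames == 2
        assert traj.n_sites == 4
        np.testing.assert_allclose(traj.box, [[70, 70, 120]] * 2)
        np.testing.assert_allclose(traj.coords[0, 0], [10.0, 20.0, 30.0])
        np.testing.assert_allclose(traj.coords[1, 3], [4.5, 5.0, 6.0])
        np.testing.assert_allclose(traj.times, [0.0, 10.0])
        assert traj.sites[0] == SiteMeta(resid=1, resname="POP", atom="P", chain="A")

    def test_triclinic_rejected(self, tmp_path):
        path = tmp_path / "tri.pdb"
        path.write_text(
            PDB_TWO_MODELS.replace(
                "  90.00  90.00  90.00", "  90.00  90.00  60.00"
            )
        )
        with pytest.raises(UnsupportedGeometryError):
            read_trajectory(path)

    def test_missing_box_rejected(self, tmp_path):
        path = tmp_path / "nobox.pdb"
        path.write_text("\n".join(PDB_TWO_MODELS.splitlines()[1:]) + "\n")
        with pytest.raises(FormatError, match="CRYST1"):
            read_trajectory(path)

    def test_inconsistent_atom_count_rejected(self, tmp_path):
        lines = PDB_TWO_MODELS.splitlines()
        del lines[-3]  # drop one atom of model 2
        path = tmp_path / "bad.pdb"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError, match="atom count"):
            read_trajectory(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="input not found"):
            read_trajectory(tmp_path / "absent.pdb")


class TestReadGro:
    def test_nm_to_angstrom(self, tmp_path):
        path = tmp_path / "one.gro"
        path.write_text(GRO_ONE_FRAME)
        traj = read_trajectory(path)
        np.testing.assert_allclose(traj.box[0], [70.0, 70.0, 120.0])
        np.testing.assert_allclose(traj.coords[0, 0], [10.0, 20.0, 30.0])
        assert traj.sites[1].resname == "POPC"

    def test_times_from_titles(self, tmp_path):
        two = GRO_ONE_FRAME + GRO_ONE_FRAME.replace("t= 0.0", "t= 10.0")
        path = tmp_path / "two.gro"
        path.write_text(two)
        traj = read_trajectory(path)
        np.testing.assert_allclose(traj.times, [0.0, 10.0])

    def test_triclinic_box_rejected(self, tmp_path):
        path = tmp_path / "tri.gro"
        path.write_text(
            GRO_ONE_FRAME.replace(
                "   7.00000   7.00000  12.00000",
                "   7.00000   7.00000  12.00000   0.0   0.0   1.0   0.0   0.0   0.0",
            )
        )
        with pytest.raises(UnsupportedGeometryError):
            read_trajectory(path)

    def test_plugin_reader(self, tmp_path):
        def fake_reader(path):
            coords = np.zeros((1, 1, 3))
            return np.array([0.0]), coords, np.array([[10.0, 10, 10]]), [
                SiteMeta(resid=1, resname="XXX", atom="Q")
            ]

        register_reader("fake", fake_reader)
        path = tmp_path / "anything.bin"
        path.write_text("")
        traj = read_trajectory(path, format="fake")
        assert traj.n_sites == 1 and traj.sites[0].resname == "XXX"


class TestSelect:
    def _multi_atom_traj(self, n_res, resname="POPC", atoms=("N", "P", "C")):
        sites = []
        for r in range(n_res):
            for a in atoms:
                sites.append(SiteMeta(resid=r + 1, resname=resname, atom=a))
        s = len(sites)
        coords = np.arange(2 * s * 3, dtype=float).reshape(2, s, 3)
        return FrameSeries(
            times=np.array([0.0, 1.0]),
            coords=coords,
            box=np.full((2, 3), 100.0),
            sites=sites,
        )

    def test_one_site_per_residue(self):
        traj = self._multi_atom_traj(128)
        out = select_representatives(traj, SelectionSpec([("POPC", "P")]))
        assert out.n_sites == 128
        assert all(s.atom == "P" for s in out.sites)
        assert [s.resid for s in out.sites] == list(range(1, 129))

    def test_empty_rules(self):
        traj = self._multi_atom_traj(4)
        out = select_representatives(traj, SelectionSpec([]))
        assert out.n_sites == 0
        assert out.n_frames == traj.n_frames

    def test_water_oxygen_selection(self):
        traj = self._multi_atom_traj(3, resname="SOL", atoms=("OW", "HW1", "HW2"))
        out = select_representatives(traj, SelectionSpec([("SOL", "OW")]))
        assert out.n_sites == 3
        assert {s.atom for s in out.sites} == {"OW"}

    def test_missing_atom_names_residue(self):
        traj = self._multi_atom_traj(2)
        with pytest.raises(SelectionError, match="POPC"):
            select_representatives(traj, SelectionSpec([("POPC", "MG")]))

    def test_idempotent(self):
        traj = self._multi_atom_traj(5)
        spec = SelectionSpec([("POPC", "P")])
        once = select_representatives(traj, spec)
        twice = select_representatives(once, spec)
        np.testing.assert_array_equal(once.coords, twice.coords)
        assert once.sites == twice.sites

    def test_ambiguous_rules_rejected(self):
        traj = self._multi_atom_traj(2)
        with pytest.raises(SelectionError, match="matched by 2 rules"):
            select_representatives(traj, SelectionSpec([("POPC", "P"), ("POP*", "N")]))


class TestTrim:
    def test_paper_window_count(self):
        traj = make_frames(np.zeros((2300, 1, 3)))
        out = trim(traj, 2001, 2256, 1)
        assert out.n_frames == 256

    def test_degenerate_window(self):
        traj = make_frames(np.zeros((10, 1, 3)))
        out = trim(traj, 4, 4, 7)
        assert out.n_frames == 1
        assert out.times[0] == 4.0  # preserved, not re-zeroed

    def test_stride_sequence(self):
        traj = make_frames(np.zeros((11, 1, 3)))
        out = trim(traj, 0, 9, 3)
        np.testing.assert_allclose(out.times, [0.0, 3.0, 6.0, 9.0])

    def test_out_of_range(self):
        traj = make_frames(np.zeros((10, 1, 3)))
        with pytest.raises(BoundsError):
            trim(traj, 0, 10, 1)
        with pytest.raises(BoundsError):
            trim(traj, 5, 4, 1)


class TestWriteHeat:
    def _traj(self):
        coords = np.array([[[1.0, 2, 3], [4, 5, 6], [7, 8, 9]]])
        return make_frames(coords, box=(50, 50, 50))

    def _bfactors(self, path):
        return [
            float(line[60:66])
            for line in path.read_text().splitlines()
            if line.startswith("ATOM")
        ]

    def test_all_zero_heat(self, tmp_path):
        path = tmp_path / "zero.pdb"
        write_heat_structure(self._traj(), 0, np.zeros(3), path)
        assert self._bfactors(path) == [0.0, 0.0, 0.0]

    def test_linear_rescale(self, tmp_path):
        path = tmp_path / "heat.pdb"
        write_heat_structure(self._traj(), 0, np.array([1.0, 2.0, 4.0]), path)
        np.testing.assert_allclose(self._bfactors(path), [25.0, 50.0, 99.99], atol=0.015)

    def test_frame_out_of_bounds(self, tmp_path):
        with pytest.raises(BoundsError):
            write_heat_structure(self._traj(), 1, np.zeros(3), tmp_path / "x.pdb")

    def test_length_mismatch(self, tmp_path):
        with pytest.raises(DimensionError):
            write_heat_structure(self._traj(), 0, np.zeros(5), tmp_path / "x.pdb")

    def test_roundtrip_precision(self, tmp_path):
        rng = np.random.default_rng(11)
        coords = rng.uniform(0, 60, (3, 7, 3))
        traj = make_frames(coords, box=(60, 60, 60), dt=2.0)
        path = tmp_path / "traj.pdb"
        write_trajectory_pdb(traj, path)
        back = read_trajectory(path, dt=2.0)
        assert back.n_frames == 3 and back.n_sites == 7
        np.testing.assert_allclose(back.coords, traj.coords, atol=1e-3)
        assert [s.resid for s in back.sites] == [s.resid for s in traj.sites]
        assert [s.atom for s in back.sites] == [s.atom for s in traj.sites]


class TestFrameSeriesInvariants:
    def test_nonuniform_times_rejected(self):
        with pytest.raises(FormatError, match="uniform"):
            FrameSeries(
                times=np.array([0.0, 1.0, 3.0]),
                coords=np.zeros((3, 1, 3)),
                box=np.full((3, 3), 10.0),
                sites=[SiteMeta(1, "A", "X")],
            )

    def test_nonpositive_box_rejected(self):
        with pytest.raises(FormatError, match="positive"):
            make_frames(np.zeros((2, 1, 3)), box=(10, 0, 10))
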