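"""SASA engine, PDB I/O, salt bridges, labeling-structure correlation."""

import math

import numpy as np
import pytest

from cysfoot.structure_sasa import (
    StructureModel,
    cys_side_chain_sasa,
    labeling_sasa_correlation,
    read_structure,
    salt_bridge_distance,
    shrake_rupley,
    sphere_points,
    write_structure,
)
from cysfoot.synthetic_data import make_sphere_fixture

S_EXT = 1.8 + 1.4  # sulfur vdW + probe


def _model(coords, element="S"):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[-2]
    radius = {"S": 1.8, "C": 1.7, "O": 1.52, "N": 1.55}[element]
    return StructureModel(
        names=np.array([element] * n),
        residue_names=np.array(["UNK"] * n),
        chains=np.array(["A"] * n),
        residue_numbers=np.arange(1, n + 1),
        elements=np.array([element] * n),
        radii=np.full(n, radius),
        coords=coords,
    )


def _brute_force_pair_sasa(coords, radii_ext, n_points=100_000, seed=0):
    """Independent oracle: random uniform sphere points, direct burial check."""
    rng = np.random.default_rng(seed)
    areas = []
    for i in range(len(coords)):
        dirs = rng.normal(size=(n_points, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = coords[i] + radii_ext[i] * dirs
        exposed = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 >= radii_ext[j] ** 2
        areas.append(4 * math.pi * radii_ext[i] ** 2 * exposed.mean())
    return np.array(areas)


class TestSpherePoints:
    def test_unit_norm_and_count(self):
        pts = sphere_points(960)
        assert pts.shape == (960, 3)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)

    def test_centroid_near_origin(self):
        assert np.linalg.norm(sphere_points(500).mean(axis=0)) < 0.01


class TestShrakeRupley:
    def test_isolated_atom_closed_form(self):
        model = _model([[0.0, 0.0, 0.0]])
        res = shrake_rupley(model, probe_radius=1.4, n_points=960)
        exact = 4 * math.pi * S_EXT**2
        assert res.atom_sasa[0, 0] == pytest.approx(exact, rel=0.01)

    def test_isolated_error_decreases_with_points(self):
        # carbon radius: exact sphere 4*pi*3.1^2
        model = _model([[0.0, 0.0, 0.0]], element="C")
        exact = 4 * math.pi * 3.1**2
        errs = [
            abs(shrake_rupley(model, n_points=n).atom_sasa[0, 0] - exact) / exact
            for n in (60, 960, 4000)
        ]
        assert errs[0] < 0.05 and errs[-1] <= errs[0]
        assert errs[1] < 0.01

    def test_distant_pair_each_isolated(self):
        model = _model([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]])
        res = shrake_rupley(model)
        exact = 4 * math.pi * S_EXT**2
        assert np.allclose(res.atom_sasa[0], exact, rtol=0.01)

    @pytest.mark.parametrize("distance", [2.0, 3.5, 5.0])
    def test_overlapping_pair_vs_brute_force_oracle(self, distance):
        coords = np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]])
        model = _model(coords)
        res = shrake_rupley(model, n_points=960)
        oracle = _brute_force_pair_sasa(coords, np.full(2, S_EXT))
        assert res.atom_sasa[0] == pytest.approx(oracle, rel=0.02)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(scale=2.0, size=(8, 3))
        # random rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = coords @ q.T + np.array([10.0, -5.0, 3.0])
        a = shrake_rupley(_model(coords)).atom_sasa
        b = shrake_rupley(_model(moved)).atom_sasa
        assert a.sum() == pytest.approx(b.sum(), rel=0.005)

    def test_distant_atom_changes_nothing(self):
        base = np.array([[0.0, 0.0, 0.0], [2.5, 0.0, 0.0]])
        far = np.vstack([base, [200.0, 0.0, 0.0]])
        a = shrake_rupley(_model(base)).atom_sasa[0]
        b = shrake_rupley(_model(far)).atom_sasa[0, :2]
        assert np.allclose(a, b)

    def test_caged_atom_fully_buried(self):
        model = make_sphere_fixture("cage")
        res = shrake_rupley(model)
        assert res.atom_sasa[0, 0] == 0.0

    def test_multi_frame_output_shape(self):
        coords = np.stack([np.zeros((2, 3)), np.ones((2, 3))])
        coords[:, 1, 0] += 3.0
        res = shrake_rupley(_model(coords))
        assert res.atom_sasa.shape == (2, 2)


CYS_PDB = """\
ATOM      1  N   CYS A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  CYS A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   CYS A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   CYS A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  CYS A   1       2.009  -0.767  -1.210  1.00  0.00           C
ATOM      6  SG  CYS A   1       1.409  -2.469  -1.363  1.00  0.00           S
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  SG  CYS A   1       0.000   0.000   0.000  1.00  0.00           S
ATOM      2  CB  CYS A   1       1.800   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  SG  CYS A   1       0.000   0.000   5.000  1.00  0.00           S
ATOM      2  CB  CYS A   1       1.800   0.000   5.000  1.00  0.00           C
ENDMDL
END
"""


class TestStructureIO:
    def test_single_model_parse(self, tmp_path):
        f = tmp_path / "cys.pdb"
        f.write_text(CYS_PDB)
        model = read_structure(f)
        assert model.n_atoms == 6 and model.n_frames == 1
        sg = model.atoms[5]
        assert sg.name == "SG" and sg.vdw_radius == pytest.approx(1.8)

    def test_two_models_become_frames(self, tmp_path):
        f = tmp_path / "two.pdb"
        f.write_text(TWO_MODEL_PDB)
        model = read_structure(f)
        assert model.n_atoms == 2 and model.n_frames == 2
        assert model.coords[1, 0, 2] == pytest.approx(5.0)

    def test_unknown_element_default_radius_warns(self, tmp_path):
        f = tmp_path / "odd.pdb"
        f.write_text(
            "ATOM      1 XX   UNK A   1       0.000   0.000   0.000"
            "  1.00  0.00          XX\nEND\n"
        )
        with pytest.warns(UserWarning, match="default radius"):
            model = read_structure(f)
        assert model.radii[0] == pytest.approx(1.70)

    def test_malformed_file_raises(self, tmp_path):
        f = tmp_path / "bad.pdb"
        f.write_text("ATOM    garbage line that is not fixed-column\n")
        with pytest.raises(ValueError):
            read_structure(f)

    def test_write_read_round_trip(self, tmp_path):
        model = make_sphere_fixture("pair", distance=10.0)
        f = tmp_path / "pair.pdb"
        write_structure(model, f)
        back = read_structure(f, strip_hetero=False)
        assert back.n_atoms == 2
        assert np.allclose(back.coords, model.coords, atol=1e-3)


class TestCysSideChain:
    def test_exposed_cys_positive(self, tmp_path):
        f = tmp_path / "cys.pdb"
        f.write_text(CYS_PDB)
        model = read_structure(f)
        areas = cys_side_chain_sasa(model)
        assert areas[("A", 1)][0] > 50.0  # CB+SG nearly fully exposed

    def test_side_chain_excludes_backbone(self, tmp_path):
        f = tmp_path / "cys.pdb"
        f.write_text(CYS_PDB)
        model = read_structure(f)
        sasa = shrake_rupley(model)
        side = cys_side_chain_sasa(model, sasa=sasa)[("A", 1)][0]
        cb = sasa.atom_sasa[0, 4]
        sg = sasa.atom_sasa[0, 5]
        assert side == pytest.approx(cb + sg)

    def test_no_cysteines_warns_empty(self):
        model = make_sphere_fixture("isolated")
        with pytest.warns(UserWarning, match="no cysteine"):
            assert cys_side_chain_sasa(model) == {}

    def test_per_frame_length(self, tmp_path):
        f = tmp_path / "two.pdb"
        f.write_text(TWO_MODEL_PDB)
        model = read_structure(f)
        areas = cys_side_chain_sasa(model)
        assert len(areas[("A", 1)]) == 2


def _salt_bridge_model(nz_z_by_frame):
    """ASP OD1/OD2 fixed at origin region; LYS NZ moving along z."""
    frames = []
    for z in nz_z_by_frame:
        frames.append(
            [
                [0.0, 0.0, 0.0],  # OD1
                [1.0, 0.8, 0.0],  # OD2
                [0.0, 0.0, z],  # NZ
            ]
        )
    coords = np.asarray(frames)
    return StructureModel(
        names=np.array(["OD1", "OD2", "NZ"]),
        residue_names=np.array(["ASP", "ASP", "LYS"]),
        chains=np.array(["A", "A", "A"]),
        residue_numbers=np.array([10, 10, 20]),
        elements=np.array(["O", "O", "N"]),
        radii=np.array([1.52, 1.52, 1.55]),
        coords=coords,
    )


class TestSaltBridge:
    def test_engineered_distance(self):
        model = _salt_bridge_model([3.0])
        series, rupture = salt_bridge_distance(model, ("A", 10), ("A", 20))
        assert series[0] == pytest.approx(3.0)
        assert rupture is None

    def test_rupture_flagged_at_first_long_frame(self):
        model = _salt_bridge_model([3.0, 3.0, 8.0, 8.0])
        series, rupture = salt_bridge_distance(
            model, ("A", 10), ("A", 20), rupture_cutoff=4.5
        )
        assert np.allclose(series, [3.0, 3.0, 8.0, 8.0])
        assert rupture == 2

    def test_dwell_requirement(self):
        model = _salt_bridge_model([3.0, 8.0, 3.0, 8.0, 8.0, 8.0])
        _, rupture = salt_bridge_distance(
            model, ("A", 10), ("A", 20), rupture_cutoff=4.5, rupture_dwell=3
        )
        assert rupture == 3

    def test_symmetric_arguments(self):
        model = _salt_bridge_model([3.0, 6.0])
        s1, _ = salt_bridge_distance(model, ("A", 10), ("A", 20))
        s2, _ = salt_bridge_distance(model, ("A", 20), ("A", 10))
        assert np.allclose(s1, s2)

    def test_non_capable_residue_rejected(self):
        model = _salt_bridge_model([3.0])
        model.residue_names = np.array(["ALA", "ALA", "LYS"])
        with pytest.raises(ValueError, match="not salt-bridge capable"):
            salt_bridge_distance(model, ("A", 10), ("A", 20))

    def test_missing_atoms_named(self):
        model = _salt_bridge_model([3.0])
        model.names = np.array(["OD1", "OD2", "CA"])  # LYS lost its NZ
        with pytest.raises(ValueError, match="NZ"):
            salt_bridge_distance(model, ("A", 10), ("A", 20))


class TestCorrelation:
    def test_perfect_positive(self):
        ratios = {116: 0.1, 228: 0.4, 324: 0.9}
        sasa = {k: v * 100 for k, v in ratios.items()}
        r, rho, n = labeling_sasa_correlation(ratios, sasa)
        assert r == pytest.approx(1.0) and rho == pytest.approx(1.0) and n == 3

    def test_perfect_negative(self):
        ratios = {1: 0.1, 2: 0.5, 3: 0.9}
        sasa = {k: -v for k, v in ratios.items()}
        r, _, _ = labeling_sasa_correlation(ratios, sasa)
        assert r == pytest.approx(-1.0)

    def test_four_point_hand_evaluation(self):
        """Oracle: direct covariance formula on x=(1,2,3,4), y=(2,1,4,3)."""
        ratios = dict(zip((1, 2, 3, 4), (1.0, 2.0, 3.0, 4.0)))
        sasa = dict(zip((1, 2, 3, 4), (2.0, 1.0, 4.0, 3.0)))
        # pearson by hand: centered products sum to 3, both sums of squares 5
        x = np.array([1, 2, 3, 4], float)
        y = np.array([2, 1, 4, 3], float)
        hand = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        r, rho, n = labeling_sasa_correlation(ratios, sasa)
        assert r == pytest.approx(hand) == pytest.approx(0.6)
        # y is already in rank order, so Spearman equals Pearson here
        assert rho == pytest.approx(0.6)

    def test_too_few_sites(self):
        with pytest.raises(ValueError, match=">=3"):
            labeling_sasa_correlation({1: 0.5, 2: 0.6}, {1: 1.0, 2: 2.0})
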