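"""Unit tests for domain types, file I/O and membrane geometry."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lidmap.model_io import (
    Frame,
    Role,
    assign_leaflets,
    build_elastic_bonds,
    generate_start_orientations,
    min_image_distance,
    min_image_distance_matrix,
    read_structure,
    read_trajectory,
    write_structure,
    write_trajectory,
)
from lidmap.synthetic import BilayerSpec, ProteinScheduleSpec, make_bilayer, make_protein_trajectory

from conftest import build_topology, make_trajectory


# ---------------------------------------------------------------------------
# minimum image
# ---------------------------------------------------------------------------

def _naive_27_image(a, b, box):
    best = np.inf
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            for sz in (-1, 0, 1):
                shift = np.array([sx, sy, sz]) * box
                best = min(best, float(np.linalg.norm(a - (b + shift))))
    return best


def test_min_image_wraparound_and_degenerate():
    box = np.array([10.0, 10.0, 10.0])
    assert min_image_distance((0, 0, 0), (9, 0, 0), box) == pytest.approx(1.0)
    assert min_image_distance((3, 4, 5), (3, 4, 5), box) == 0.0
    with pytest.raises(ValueError):
        min_image_distance((0, 0, 0), (1, 1, 1), (10.0, -1.0, 10.0))


def test_min_image_matches_27_image_oracle(rng):
    box = np.array([12.0, 17.0, 9.0])
    A = rng.uniform(0, 1, size=(1000, 3)) * box
    B = rng.uniform(0, 1, size=(1000, 3)) * box
    for a, b in zip(A, B):
        d = min_image_distance(a, b, box)
        assert d == pytest.approx(_naive_27_image(a, b, box), abs=1e-9)
        # symmetry
        assert d == pytest.approx(min_image_distance(b, a, box), abs=1e-12)
    # matrix variant agrees with the scalar one
    D = min_image_distance_matrix(A[:10], B[:10], box)
    for i in range(10):
        for j in range(10):
            assert D[i, j] == pytest.approx(min_image_distance(A[i], B[j], box), abs=1e-12)


# ---------------------------------------------------------------------------
# structure I/O
# ---------------------------------------------------------------------------

def test_structure_roundtrip_preserves_numbering(tmp_path, small_bilayer):
    _, top, frame = small_bilayer
    path = tmp_path / "bilayer.gro"
    write_structure(path, top, frame)
    top2, frame2 = read_structure(path)
    assert top2.n_beads == top.n_beads
    assert np.array_equal(top2.residue_seq, top.residue_seq)
    assert list(top2.bead_names) == list(top.bead_names)
    assert list(top2.roles) == list(top.roles)
    assert list(top2.species) == list(top.species)
    # GRO stores nm at 3 decimals -> 0.01 A precision
    assert np.abs(frame2.coords - frame.coords).max() < 0.006
    # reading twice is bitwise identical on fields
    top3, _ = read_structure(path)
    assert np.array_equal(top3.residue_seq, top2.residue_seq)
    assert list(top3.roles) == list(top2.roles)


def test_protein_chain_backbone_count(tmp_path, small_bilayer):
    """A 66-residue BB chain (residues 235-300) reads back as 66 backbone beads."""
    spec, btop, bframe = small_bilayer
    pspec = ProteinScheduleSpec(
        n_rigid=57, anchor_residues=6, planted_contact_fractions=(1.0, 0.5, 0.0),
        residue_start=235,
    )
    traj, _ = make_protein_trajectory(btop, bframe, pspec, n_frames=2, seed=3,
                                      bilayer_spec=spec)
    path = tmp_path / "sys.gro"
    write_structure(path, traj.topology, next(iter(traj)))
    top2, _ = read_structure(path)
    bb = top2.backbone_mask
    assert bb.sum() == 66
    assert top2.residue_seq[bb].min() == 235
    assert top2.residue_seq[bb].max() == 300


def test_unknown_bead_name_errors(tmp_path):
    top = build_topology(lipid_species=("POPC",))
    top.bead_names[0] = "QQ9"  # replace the head bead's name with an unknown token
    frame = Frame(coords=np.arange(9, dtype=float).reshape(3, 3), box=(50, 50, 50))
    path = tmp_path / "bad.gro"
    write_structure(path, top, frame)
    with pytest.raises(ValueError, match="QQ9"):
        read_structure(path)
    # a role table resolves it
    top2, _ = read_structure(path, role_table={"POPC": {"QQ9": "lipid_head"}})
    assert top2.roles[0] is Role.LIPID_HEAD


def test_trajectory_roundtrip_stride_and_mismatch(tmp_path, bound_protein_traj):
    traj, _ = bound_protein_traj
    sub = make_trajectory(
        traj.topology, [f.coords for f in list(traj)[:10]],
        box=next(iter(traj)).box,
    )
    xtc = tmp_path / "t.xtc"
    write_trajectory(xtc, sub)
    rt = read_trajectory(xtc, traj.topology)
    frames = list(rt.iter_frames())
    assert len(frames) == 10
    # XTC stores at 0.001 nm = 0.01 A precision
    for f_in, f_out in zip(sub, frames):
        assert np.abs(f_in.coords - f_out.coords).max() < 0.006
    assert len(list(read_trajectory(xtc, traj.topology, stride=2))) == 5
    # mismatched bead count errors, naming expected/found
    small_top = build_topology(n_protein_res=2, lipid_species=("POPC",))
    with pytest.raises(ValueError, match=r"expected 5.*found"):
        read_trajectory(xtc, small_top)


# ---------------------------------------------------------------------------
# leaflet assignment
# ---------------------------------------------------------------------------

def test_assign_leaflets_planted_bilayer():
    top = build_topology(lipid_species=("POPC",) * 4)
    coords = np.zeros((12, 3))
    for l, z in enumerate([20.0, 20.0, 60.0, 60.0]):
        coords[3 * l] = [10 * l, 5, z]
        sign = 1 if z < 40 else -1
        coords[3 * l + 1] = [10 * l, 5, z + 4 * sign]
        coords[3 * l + 2] = [10 * l, 5, z + 8 * sign]
    mm = assign_leaflets(Frame(coords=coords, box=(50, 50, 100)), top)
    assert mm.midplane_z == pytest.approx(40.0)
    assert mm.leaflet == {0: "lower", 1: "lower", 2: "upper", 3: "upper"}
    assert mm.lower_head_z == pytest.approx(20.0)


def test_assign_leaflets_single_leaflet_errors():
    top = build_topology(lipid_species=("POPC",) * 3)
    coords = np.zeros((9, 3))
    coords[:, 2] = 20.0
    with pytest.raises(ValueError, match="no bilayer"):
        assign_leaflets(Frame(coords=coords, box=(50, 50, 100)), top)


def test_lower_leaflet_composition_exact(small_bilayer):
    """An 80:10:10 lower-leaflet fixture yields exactly 80:10:10 species counts."""
    _, top, frame = small_bilayer
    mm = assign_leaflets(frame, top)
    lower = mm.molecules("lower")
    assert len(lower) == 100
    counts = {}
    for m in lower:
        sp = str(top.species[np.flatnonzero(top.molecule_id == m)[0]])
        counts[sp] = counts.get(sp, 0) + 1
    assert counts == {"POPC": 80, "POPS": 10, "PIP2": 10}


# ---------------------------------------------------------------------------
# elastic bonds
# ---------------------------------------------------------------------------

def _protein_frame(coords, box=(100.0, 100.0, 100.0)):
    top = build_topology(n_protein_res=len(coords))
    return top, Frame(coords=np.asarray(coords, dtype=float), box=box)


def test_elastic_bonds_collinear_triplet():
    top, frame = _protein_frame([[0, 0, 0], [4, 0, 0], [8, 0, 0]])
    bonds = build_elastic_bonds(frame, top)
    assert bonds.pairs.tolist() == [[0, 2]]
    assert bonds.lengths[0] == pytest.approx(8.0)
    assert bonds.force_constant == 400.0


def test_elastic_bonds_empty_when_all_far():
    top, frame = _protein_frame([[0, 0, 0], [20, 0, 0], [40, 0, 0], [60, 0, 0]])
    assert len(build_elastic_bonds(frame, top).pairs) == 0


def test_elastic_bonds_match_bruteforce_and_rigid_invariance(rng):
    coords = np.cumsum(rng.normal(0, 2.0, size=(20, 3)), axis=0)
    top, frame = _protein_frame(coords)
    bonds = build_elastic_bonds(frame, top)
    expected = []
    for i in range(20):
        for j in range(i + 2, 20):
            d = np.linalg.norm(coords[i] - coords[j])
            if 5.0 <= d <= 9.0:
                expected.append((i, j, d))
    assert bonds.pairs.tolist() == [[i, j] for i, j, _ in expected]
    assert np.allclose(bonds.lengths, [d for _, _, d in expected])
    # rigid rotation + translation leaves the bond list unchanged
    R = Rotation.from_euler("zyx", [31, -47, 112], degrees=True)
    moved = R.apply(coords) + np.array([5.0, -3.0, 8.0])
    bonds2 = build_elastic_bonds(Frame(coords=moved, box=frame.box), top)
    assert bonds2.pairs.tolist() == bonds.pairs.tolist()
    assert np.allclose(bonds2.lengths, bonds.lengths, atol=1e-9)
    # the exported table carries nm lengths
    assert "r0_nm" in bonds.to_table()


def test_elastic_bonds_need_three_beads():
    top, frame = _protein_frame([[0, 0, 0], [4, 0, 0]])
    with pytest.raises(ValueError):
        build_elastic_bonds(frame, top)


# ---------------------------------------------------------------------------
# start orientations
# ---------------------------------------------------------------------------

@pytest.fixture()
def complex_and_membrane(small_bilayer):
    _, btop, bframe = small_bilayer
    mm = assign_leaflets(bframe, btop)
    top = build_topology(n_protein_res=8)
    coords = np.random.default_rng(5).normal(0, 4.0, size=(8, 3)) + [40, 40, 50]
    frame = Frame(coords=coords, box=bframe.box)
    return top, frame, mm


def test_start_orientations_stepping_rule(complex_and_membrane):
    top, frame, mm = complex_and_membrane
    frames = generate_start_orientations(frame, top, mm, n=4, offset=7.0)
    assert len(frames) == 4
    # angles {0, 180} about x (k=0,2) and {90, 270} about y (k=1,3)
    centroid = frame.coords.mean(axis=0)
    for k, (axis, angle) in enumerate([("x", 0), ("y", 90), ("x", 180), ("y", 270)]):
        R = Rotation.from_euler(axis, angle, degrees=True)
        expected = R.apply(frame.coords - centroid) + centroid
        got = frames[k].coords
        # same rotation up to the post-rotation z shift
        shift = got[:, 2].mean() - expected[:, 2].mean()
        assert np.allclose(got[:, :2], expected[:, :2], atol=1e-9)
        assert np.allclose(got[:, 2], expected[:, 2] + shift, atol=1e-9)


def test_start_orientations_gap_and_distinctness(complex_and_membrane):
    top, frame, mm = complex_and_membrane
    frames = generate_start_orientations(frame, top, mm, n=16, offset=7.0)
    assert len(frames) == 16
    for f in frames:
        gap = mm.lower_head_min_z - f.coords[:, 2].max()
        assert gap == pytest.approx(7.0, abs=1e-6)
    # pairwise distinct poses
    for i in range(16):
        for j in range(i + 1, 16):
            assert np.abs(frames[i].coords - frames[j].coords).max() > 1e-6
    with pytest.raises(ValueError):
        generate_start_orientations(frame, top, mm, n=0)
    with pytest.raises(ValueError):
        generate_start_orientations(frame, top, mm, offset=-1.0)
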