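"""Tests for the geographic orientation analysis and state extraction."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lidmap.contacts import BoundSeries, residue_lipid_contact_fractions
from lidmap.model_io import Frame, MembraneModel
from lidmap.orientation import (
    BodyFrame,
    OrientationSeries,
    OrientationState,
    extract_states,
    great_circle_deg,
    orientation_histogram,
    orientation_series,
    representative_frame,
    state_contact_profile,
)

from conftest import build_topology, make_trajectory


def _membrane():
    return MembraneModel(midplane_z=50.0, leaflet={0: "lower", 1: "upper"},
                         lower_head_z=40.0, upper_head_z=60.0, lower_head_min_z=40.0)


@pytest.fixture(scope="module")
def rigid_reference():
    rng = np.random.default_rng(99)
    coords = rng.normal(0, 4.0, size=(12, 3))
    return coords - coords.mean(axis=0)


def _series_for_rotations(rigid_reference, rotations, translations=None):
    top = build_topology(n_protein_res=12)
    frames = []
    for i, R in enumerate(rotations):
        t = translations[i] if translations is not None else np.array([50.0, 50.0, 20.0])
        frames.append(R.apply(rigid_reference) + t)
    traj = make_trajectory(top, frames, box=(100, 100, 100))
    body = BodyFrame.from_reference(rigid_reference)
    return orientation_series(traj, np.arange(12), body, _membrane()), body


def test_identity_rotation_reference_angles(rigid_reference):
    body = BodyFrame.from_reference(rigid_reference)
    series, _ = _series_for_rotations(rigid_reference, [Rotation.identity()] * 3)
    # expected: inward normal (0,0,-1) expressed in body axes
    v = body.axes @ np.array([0.0, 0.0, -1.0])
    exp_lat = 90.0 - np.rad2deg(np.arccos(v[2]))
    exp_lon = np.rad2deg(np.arctan2(v[1], v[0]))
    assert np.allclose(series.latitude, exp_lat, atol=1e-9)
    assert np.allclose(series.longitude, exp_lon, atol=1e-9)
    # repeated calls are identical
    series2, _ = _series_for_rotations(rigid_reference, [Rotation.identity()] * 3)
    assert np.array_equal(series.latitude, series2.latitude)


def test_random_rotations_match_rotation_matrix_oracle(rigid_reference):
    """Angles recovered from coordinates match those computed directly from
    the known rotation matrices, to 1e-6 degrees."""
    rng = np.random.default_rng(123)
    rotations = [Rotation.random(random_state=rng) for _ in range(100)]
    translations = rng.uniform(20, 80, size=(100, 3))
    series, body = _series_for_rotations(rigid_reference, rotations, translations)
    n_hat = np.array([0.0, 0.0, -1.0])
    for k, R in enumerate(rotations):
        v = body.axes @ (R.as_matrix().T @ n_hat)
        lat = 90.0 - np.rad2deg(np.arccos(np.clip(v[2], -1, 1)))
        lon = np.rad2deg(np.arctan2(v[1], v[0]))
        assert series.latitude[k] == pytest.approx(lat, abs=1e-6)
        assert abs((series.longitude[k] - lon + 180) % 360 - 180) < 1e-6


def test_spin_about_world_normal_is_invariant(rigid_reference):
    """Spinning the frames about the membrane normal leaves both angles
    unchanged: the normal's piercing point lies on the rotation axis."""
    base = Rotation.from_euler("xyz", [25, -40, 60], degrees=True)
    spins = [Rotation.from_euler("z", a, degrees=True) * base for a in (0, 30, 90, 200)]
    series, _ = _series_for_rotations(rigid_reference, spins)
    assert np.allclose(series.latitude, series.latitude[0], atol=1e-8)
    assert np.allclose(series.longitude, series.longitude[0], atol=1e-8)


def test_spin_about_body_axis_shifts_longitude(rigid_reference):
    """Rotating the frame about the body polar axis shifts longitude by the
    spin angle and leaves latitude unchanged."""
    body = BodyFrame.from_reference(rigid_reference)
    z_body_world = body.axes[2]
    theta = 30.0
    spin = Rotation.from_rotvec(np.deg2rad(theta) * z_body_world)
    series, _ = _series_for_rotations(rigid_reference, [Rotation.identity(), spin])
    assert series.latitude[1] == pytest.approx(series.latitude[0], abs=1e-8)
    dlon = (series.longitude[1] - series.longitude[0] + 180) % 360 - 180
    assert abs(abs(dlon) - theta) < 1e-6


def test_orientation_selection_mismatch_errors(rigid_reference):
    body = BodyFrame.from_reference(rigid_reference)
    top = build_topology(n_protein_res=12)
    traj = make_trajectory(top, [rigid_reference + 50.0], box=(100, 100, 100))
    with pytest.raises(ValueError, match="match"):
        orientation_series(traj, np.arange(11), body, _membrane())
    with pytest.raises(ValueError, match="degenerate|collinear"):
        BodyFrame.from_reference(np.outer(np.arange(5.0), [1.0, 0, 0]))


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------

def _series(lats, lons, bound=None):
    n = len(lats)
    return OrientationSeries(
        latitude=np.asarray(lats, dtype=float),
        longitude=np.asarray(lons, dtype=float),
        bound=np.ones(n, dtype=bool) if bound is None else np.asarray(bound),
        times=np.arange(n, dtype=float),
    )


def test_histogram_counting_and_normalization():
    s = _series([10] * 6 + [50] * 4, [20] * 6 + [-120] * 4)
    h = orientation_histogram(s, bin_deg=5.0)
    assert h.H.sum() == pytest.approx(1.0)
    assert sorted(h.H[h.H > 0]) == [pytest.approx(0.4), pytest.approx(0.6)]
    single = orientation_histogram(_series([0.0], [0.0]))
    assert single.H.max() == 1.0
    with pytest.raises(ValueError, match="bound"):
        orientation_histogram(_series([0.0], [0.0], bound=[False]))


def test_smoothing_is_periodic_across_the_longitude_seam():
    s = _series([0.0] * 10, [179.0] * 10)
    h = orientation_histogram(s, bin_deg=5.0)
    S = h.smoothed(10.0)
    # mass sits in the last longitude bin (center 177.5); wrap smoothing must
    # leak symmetrically: one bin to the left (172.5) equals one bin across
    # the seam (-177.5)
    j = np.argmax(h.H.sum(axis=0))
    assert S[70, j] == pytest.approx(S[0, j], rel=1e-9)
    assert S.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# state extraction
# ---------------------------------------------------------------------------

def test_single_cluster_single_state():
    rng = np.random.default_rng(4)
    lats = 40 + rng.normal(0, 2, 200)
    lons = -60 + rng.normal(0, 2, 200)
    s = _series(lats, lons)
    h = orientation_histogram(s)
    smap = extract_states(h, s)
    assert len(smap.states) == 1
    st = smap.states[0]
    assert st.population == pytest.approx(1.0)
    assert great_circle_deg(st.center_lat, st.center_lon, 40, -60) < 7.5
    assert smap.unassigned_mass == pytest.approx(0.0)


def test_equal_peaks_within_radius_merge_to_lower_bin():
    s = _series([0.0] * 10 + [0.0] * 10, [2.5] * 10 + [22.5] * 10)
    h = orientation_histogram(s, bin_deg=5.0)
    smap = extract_states(h, s, smooth_sigma_deg=0.0, assign_radius_deg=30.0)
    assert len(smap.states) == 1
    # equal-mass peaks 20 deg apart merge; the lower flat-index bin wins
    assert smap.states[0].center_lon == pytest.approx(2.5)
    assert smap.states[0].population == pytest.approx(1.0)


def test_state_population_and_unassigned_sum_to_one():
    rng = np.random.default_rng(8)
    lats = np.concatenate([40 + rng.normal(0, 2, 120), -30 + rng.normal(0, 2, 60),
                           rng.uniform(-90, 90, 40)])
    lons = np.concatenate([60 + rng.normal(0, 2, 120), -100 + rng.normal(0, 2, 60),
                           rng.uniform(-180, 180, 40)])
    s = _series(lats, lons)
    smap = extract_states(orientation_histogram(s), s)
    total = sum(st.population for st in smap.states) + smap.unassigned_mass
    assert total == pytest.approx(1.0, abs=1e-12)
    # populations are ordered descending
    pops = [st.population for st in smap.states]
    assert pops == sorted(pops, reverse=True)
    # member sets are disjoint
    all_members = np.concatenate([st.member_frames for st in smap.states])
    assert len(all_members) == len(set(all_members.tolist()))


def test_representative_frame_selection_and_ties():
    s = _series([0.0, 1.0, 3.0, -1.0], [0.0, 0.0, 0.0, 0.0])
    st = OrientationState(center_lat=0.0, center_lon=0.0, population=1.0,
                          member_frames=np.array([1, 2]), representative=-1,
                          peak_bin=(0, 0))
    assert representative_frame(st, s) == 1  # 1 deg beats 3 deg
    st_tie = OrientationState(center_lat=0.0, center_lon=0.0, population=1.0,
                              member_frames=np.array([1, 3]), representative=-1,
                              peak_bin=(0, 0))
    assert representative_frame(st_tie, s) == 1  # equidistant -> smaller index
    empty = OrientationState(center_lat=0.0, center_lon=0.0, population=0.0,
                             member_frames=np.array([], dtype=int),
                             representative=-1, peak_bin=(0, 0))
    with pytest.raises(ValueError):
        representative_frame(empty, s)


# ---------------------------------------------------------------------------
# per-state contact profiles
# ---------------------------------------------------------------------------

def test_state_profile_with_all_frames_equals_global(bound_protein_traj):
    traj, _ = bound_protein_traj
    global_profile = residue_lipid_contact_fractions(traj, part="head")
    state_profile = state_contact_profile(np.arange(traj.n_frames), traj, part="head")
    assert np.array_equal(global_profile.fractions, state_profile.fractions)


def test_single_frame_state_matches_direct_oracle(bound_protein_traj):
    traj, _ = bound_protein_traj
    one = state_contact_profile([5], traj, part="head")
    frame = list(traj)[5]
    top = traj.topology
    from lidmap.model_io import Role, min_image_distance

    by_res = top.backbone_indices_by_residue()
    for i, r in enumerate(one.residue_seq):
        for j, sp in enumerate(one.species):
            hit = False
            for b in by_res[int(r)]:
                for k in range(top.n_beads):
                    if top.roles[k] is Role.LIPID_HEAD and str(top.species[k]) == sp:
                        if min_image_distance(frame.coords[b], frame.coords[k],
                                              frame.box) <= 7.0:
                            hit = True
            assert one.fractions[i, j] == float(hit)
    with pytest.raises(ValueError):
        state_contact_profile([], traj)


def test_per_state_profiles_separate_planted_signatures():
    """State-tagged residues contact head groups only in their own state."""
    from lidmap.synthetic import (
        BilayerSpec,
        OrientationStateSpec,
        ProteinScheduleSpec,
        make_bilayer,
        make_protein_trajectory,
    )
    from lidmap.contacts import detect_bound_frames
    from lidmap.model_io import assign_leaflets

    # one-species bilayer so the single species column equals the any-lipid
    # head-contact fraction
    bspec = BilayerSpec(box_xy=(60.0, 60.0), lower_composition={"POPC": 1.0})
    btop, bframe = make_bilayer(bspec, seed=5)
    pspec = ProteinScheduleSpec(
        states=(OrientationStateSpec(40, 60, 0.5), OrientationStateSpec(-30, -120, 0.5)),
        bound_fraction=1.0,
        planted_contact_fractions=(),
        state_tagged_residues=1,
        state_block=10,
    )
    traj, truth = make_protein_trajectory(btop, bframe, pspec, n_frames=400, seed=21,
                                          bilayer_spec=bspec)
    mm = assign_leaflets(next(iter(traj)), traj.topology)
    bs = detect_bound_frames(traj)
    from lidmap.orientation import orientation_histogram as ohist, orientation_series as oser

    series = oser(traj, truth.rigid_indices, truth.body, mm, bs)
    smap = extract_states(ohist(series), series)
    assert len(smap.states) == 2
    # map extracted states onto planted centers
    for st in smap.states:
        dists = [great_circle_deg(st.center_lat, st.center_lon, la, lo)
                 for la, lo in truth.state_centers]
        planted = int(np.argmin(dists))
        profile = state_contact_profile(st.member_frames, traj, part="head")
        own = truth.state_tagged_residue_seqs[planted][0]
        other = truth.state_tagged_residue_seqs[1 - planted][0]
        i_own = list(profile.residue_seq).index(own)
        i_other = list(profile.residue_seq).index(other)
        assert profile.fractions[i_own].max() >= 0.9
        assert profile.fractions[i_other].max() <= 0.1
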