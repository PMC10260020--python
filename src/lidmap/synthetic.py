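"""Synthetic bead-bilayer and protein-trajectory generators with planted
ground truth.

These fixtures replace multi-microsecond coarse-grained simulations for
testing: every quantity the analysis modules estimate (contact fractions,
bound fraction, orientation-state populations, lipid enrichment, NMR
correlations, relaxation rates) is planted with a known value and must be
recoverable within stated tolerances.

Lipids are 3-bead caricatures (one head bead named PO4 plus two acyl beads)
on a jittered lattice at a fixed area per lipid; the protein is a bead chain
with a rigid sub-domain whose pose follows a scheduled orientation-state
sequence, plus tail beads whose head-group contacts are scheduled to hit
planted per-residue contact fractions exactly.  All generators are
bit-reproducible given (spec, seed); randomness is split into per-molecule
sub-streams so adding lipids does not perturb the protein's randomness.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .contacts import ContactProfile
from .experiment import DEFAULT_R2_DELAYS, DecayCurve, PeakTable, TitrationSeries
from .model_io import BeadTopology, Frame, Role, Trajectory
from .orientation import BodyFrame, angles_to_unit, great_circle_deg

__all__ = [
    "BilayerSpec",
    "EnrichmentSpec",
    "ProteinScheduleSpec",
    "OrientationStateSpec",
    "NMRSpec",
    "SyntheticTruth",
    "make_bilayer",
    "make_bilayer_frames",
    "make_protein_trajectory",
    "make_nmr_titration",
    "make_decay",
    "bound_schedule_from_fraction",
]


# ---------------------------------------------------------------------------
# bilayer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentSpec:
    """Radial enrichment of one species around a site.

    ``fold`` is the planted local density relative to the *leaflet-average*
    density, so fold=2 corresponds to +100% on an enrichment map.
    """

    species: str = "PIP2"
    center_xy: tuple[float, float] | None = None  # None -> box center
    radius: float = 15.0
    fold: float = 2.0

    def __post_init__(self) -> None:
        if self.fold < 0:
            raise ValueError("fold must be >= 0")


@dataclass(frozen=True)
class BilayerSpec:
    """Two-leaflet bead bilayer on a jittered lattice.

    Defaults emulate the plasma-membrane-like systems used for receptor
    juxtamembrane studies: 100% POPC in the upper leaflet and an
    80:10:10 POPC:POPS:PIP2 mixture in the lower (intracellular) leaflet,
    ~65 A^2 per lipid.
    """

    box_xy: tuple[float, float] = (100.0, 100.0)
    box_z: float = 200.0
    area_per_lipid: float = 65.0
    lower_composition: dict = field(
        default_factory=lambda: {"POPC": 0.80, "POPS": 0.10, "PIP2": 0.10}
    )
    upper_composition: dict = field(default_factory=lambda: {"POPC": 1.0})
    lower_head_z: float = 80.0
    upper_head_z: float = 118.0
    acyl_spacing: float = 4.0
    jitter_sd: float = 0.8
    enrichment: EnrichmentSpec | None = None

    def __post_init__(self) -> None:
        for comp in (self.lower_composition, self.upper_composition):
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"leaflet composition must sum to 1, got {total}")
        if self.lower_head_z >= self.upper_head_z:
            raise ValueError("lower leaflet must sit below the upper leaflet")


def _largest_remainder_counts(fractions: dict, n: int) -> dict:
    """Integer species counts summing to n, by largest-remainder rounding."""
    species = sorted(fractions)
    quotas = {s: fractions[s] * n for s in species}
    counts = {s: int(np.floor(quotas[s])) for s in species}
    short = n - sum(counts.values())
    remainders = sorted(species, key=lambda s: (-(quotas[s] - counts[s]), s))
    for s in remainders[:short]:
        counts[s] += 1
    return counts


def _lattice_sites(box_xy, area_per_lipid) -> np.ndarray:
    spacing = np.sqrt(area_per_lipid)
    nx = max(2, int(round(box_xy[0] / spacing)))
    ny = max(2, int(round(box_xy[1] / spacing)))
    xs = (np.arange(nx) + 0.5) * box_xy[0] / nx
    ys = (np.arange(ny) + 0.5) * box_xy[1] / ny
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    return np.stack([X.ravel(), Y.ravel()], axis=1)


def _assign_species(
    spec: BilayerSpec, sites: np.ndarray, composition: dict, rng: np.random.Generator,
    enriched_leaflet: bool,
) -> np.ndarray:
    """Assign one species per lattice site.

    Without enrichment the assignment is a seeded site permutation sliced by
    exact largest-remainder counts, with PIP2 occupying a prefix of the
    permutation so that raising the PIP2 fraction at a fixed seed only adds
    PIP2 sites (never removes one) - the concentration-doubling property the
    analysis tests rely on.  With enrichment, the enriched species' in-disc
    count is drawn with an expected value of fold * mean-density * disc sites
    (integer part plus a Bernoulli remainder), which makes the planted disc
    enrichment unbiased at the planted fold.
    """
    n = len(sites)
    counts = _largest_remainder_counts(composition, n)
    species_sorted = sorted(counts)
    out = np.empty(n, dtype=object)
    enr = spec.enrichment
    if not (enriched_leaflet and enr is not None and enr.species in counts and enr.fold != 1.0):
        perm = rng.permutation(n)
        # PIP2 first so its site set is nested across concentrations
        ordered = [s for s in ("PIP2",) if s in counts] + [
            s for s in species_sorted if s != "PIP2"
        ]
        start = 0
        for s in ordered:
            out[perm[start:start + counts[s]]] = s
            start += counts[s]
        return out

    center = np.asarray(
        enr.center_xy if enr.center_xy is not None
        else (spec.box_xy[0] / 2.0, spec.box_xy[1] / 2.0)
    )
    d = sites - center
    d[:, 0] -= spec.box_xy[0] * np.round(d[:, 0] / spec.box_xy[0])
    d[:, 1] -= spec.box_xy[1] * np.round(d[:, 1] / spec.box_xy[1])
    in_disc = np.einsum("ij,ij->i", d, d) <= enr.radius**2
    n_in = int(in_disc.sum())
    n_enr = counts[enr.species]
    # expected enriched count inside the disc is fold x (areal density x disc
    # area): using the disc *area* rather than the in-disc site count keeps
    # the planted density unbiased under lattice discretisation
    area_density = n_enr / (spec.box_xy[0] * spec.box_xy[1])
    mu = enr.fold * area_density * np.pi * enr.radius**2
    mu = min(mu, float(min(n_in, n_enr)))
    k_in = int(np.floor(mu)) + int(rng.random() < (mu - np.floor(mu)))
    k_in = min(k_in, n_in, n_enr)
    idx_in = np.flatnonzero(in_disc)
    idx_out = np.flatnonzero(~in_disc)
    chosen_in = rng.choice(idx_in, size=k_in, replace=False)
    chosen_out = rng.choice(idx_out, size=n_enr - k_in, replace=False)
    enr_sites = np.concatenate([chosen_in, chosen_out])
    out[enr_sites] = enr.species
    rest = np.setdiff1d(np.arange(n), enr_sites)
    rest = rest[rng.permutation(len(rest))]
    start = 0
    for s in species_sorted:
        if s == enr.species:
            continue
        out[rest[start:start + counts[s]]] = s
        start += counts[s]
    return out


def _leaflet_beads(spec: BilayerSpec, leaflet: str) -> tuple[float, np.ndarray]:
    """Head z and the z-offsets of the 3 beads (head, 2 acyl toward midplane)."""
    if leaflet == "lower":
        head_z = spec.lower_head_z
        offsets = np.array([0.0, spec.acyl_spacing, 2 * spec.acyl_spacing])
    else:
        head_z = spec.upper_head_z
        offsets = np.array([0.0, -spec.acyl_spacing, -2 * spec.acyl_spacing])
    return head_z, offsets


def make_bilayer(spec: BilayerSpec, seed: int) -> tuple[BeadTopology, Frame]:
    """Build one bilayer realization: topology plus a single frame."""
    ss = np.random.SeedSequence(seed)
    rng_species, rng_jitter = [np.random.default_rng(c) for c in ss.spawn(2)]

    names, resids, resnames, mids, roles, species = [], [], [], [], [], []
    coords = []
    mol = 0
    resid = 1
    for leaflet, comp in (("lower", spec.lower_composition), ("upper", spec.upper_composition)):
        sites = _lattice_sites(spec.box_xy, spec.area_per_lipid)
        sp = _assign_species(spec, sites, comp, rng_species, leaflet == "lower")
        head_z, offsets = _leaflet_beads(spec, leaflet)
        jitter = rng_jitter.normal(0.0, spec.jitter_sd, size=(len(sites), 2))
        for i in range(len(sites)):
            xy = sites[i] + jitter[i]
            xy[0] %= spec.box_xy[0]
            xy[1] %= spec.box_xy[1]
            for name, dz, role in (
                ("PO4", 0.0, Role.LIPID_HEAD),
                ("C1A", offsets[1], Role.LIPID_ACYL),
                ("C2A", offsets[2], Role.LIPID_ACYL),
            ):
                names.append(name)
                resids.append(resid)
                resnames.append(str(sp[i]))
                mids.append(mol)
                roles.append(role)
                species.append(str(sp[i]))
                coords.append([xy[0], xy[1], head_z + dz])
            mol += 1
            resid += 1
    top = BeadTopology(
        bead_names=np.array(names, dtype=object),
        residue_seq=np.array(resids),
        residue_names=np.array(resnames, dtype=object),
        molecule_id=np.array(mids),
        roles=np.array(roles, dtype=object),
        species=np.array(species, dtype=object),
    )
    frame = Frame(
        coords=np.array(coords),
        box=np.array([spec.box_xy[0], spec.box_xy[1], spec.box_z]),
        time=0.0,
    )
    return top, frame


def make_bilayer_frames(
    topology: BeadTopology,
    base_frame: Frame,
    spec: BilayerSpec,
    n_frames: int,
    seed: int,
    dt: float = 1.0,
) -> Trajectory:
    """Jitter the bilayer around its lattice sites over ``n_frames`` frames.

    Each lipid draws its xy displacements from its own sub-stream, so the
    trajectory of one molecule is independent of how many others exist.
    """
    ss = np.random.SeedSequence(seed)
    lipids = topology.lipid_molecules()
    streams = ss.spawn(len(lipids))
    disp = np.zeros((n_frames, topology.n_beads, 2))
    for k, mid in enumerate(lipids):
        sel = topology.molecule_id == mid
        rng = np.random.default_rng(streams[k])
        d = rng.normal(0.0, spec.jitter_sd, size=(n_frames, 2))
        disp[:, sel, :] = d[:, None, :]
    frames = []
    for f in range(n_frames):
        coords = base_frame.coords.copy()
        coords[:, :2] += disp[f]
        coords[:, 0] %= base_frame.box[0]
        coords[:, 1] %= base_frame.box[1]
        frames.append(Frame(coords=coords, box=base_frame.box.copy(), time=f * dt))
    return Trajectory(topology, frames=frames)


# ---------------------------------------------------------------------------
# protein schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrientationStateSpec:
    """One planted orientation state: center angles and its population as a
    fraction of bound time."""

    latitude: float
    longitude: float
    population: float


@dataclass(frozen=True)
class ProteinScheduleSpec:
    """Scheduled protein chain: rigid sub-domain pose plus tail contacts.

    ``states`` plant orientation states (populations may sum to < 1; the
    remainder is spent in a diffuse background of orientations kept at least
    ``background_exclusion_deg`` away from every planted center).
    ``anchor_residues`` tail residues touch the head groups in every bound
    frame (they operationalise "bound"); ``planted_contact_fractions`` gives
    additional tail residues whose head-contact fraction over bound frames is
    planted via an even (Bresenham) schedule; ``state_tagged_residues`` adds,
    per planted state, tail residues that contact the head groups only while
    that state is occupied (distinct per-state contact signatures).
    """

    n_rigid: int = 20
    residue_start: int = 1
    states: tuple[OrientationStateSpec, ...] = (
        OrientationStateSpec(40.0, 60.0, 1.0),
    )
    bound_schedule: tuple[tuple[bool, int], ...] | None = None
    bound_fraction: float = 1.0
    anchor_residues: int = 6
    planted_contact_fractions: tuple[float, ...] = (1.0, 0.5, 0.0)
    state_tagged_residues: int = 0
    contact_species: str | None = "POPC"
    orientation_jitter_deg: float = 3.0
    xy_step: float = 0.5
    state_block: int = 20
    rigid_size_sd: float = 4.0
    contact_depth: float = 3.5
    unbound_offset: float = 40.0
    background_exclusion_deg: float = 45.0

    def __post_init__(self) -> None:
        if self.n_rigid < 3:
            raise ValueError("rigid domain needs at least 3 beads")
        total = sum(s.population for s in self.states)
        if total > 1.0 + 1e-9:
            raise ValueError("state populations must sum to <= 1")
        for f in self.planted_contact_fractions:
            if not 0.0 <= f <= 1.0:
                raise ValueError("planted contact fractions must lie in [0, 1]")
        if not self.states:
            raise ValueError("need at least one orientation state")


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a synthetic protein trajectory."""

    bound: np.ndarray  # (F,) bool
    state_labels: np.ndarray  # (F,) int, -1 = background/unbound
    state_centers: list[tuple[float, float]]  # (lat, lon) per planted state
    state_populations: list[float]
    contact_fractions: dict[int, float]  # residue_seq -> planted fraction (of bound)
    rigid_indices: np.ndarray  # bead indices of the rigid selection
    body: BodyFrame
    anchor_residue_seqs: list[int]
    planted_residue_seqs: list[int]
    state_tagged_residue_seqs: list[list[int]] = field(default_factory=list)
    contact_species: str | None = "POPC"


def bound_schedule_from_fraction(
    n_frames: int, fraction: float, min_block: int = 15
) -> tuple[tuple[bool, int], ...]:
    """Deterministic bound/unbound segments hitting ``fraction`` exactly
    (to frame resolution), with every segment at least ``min_block`` frames
    so debounced detection recovers the schedule."""
    n_bound = int(round(fraction * n_frames))
    n_un = n_frames - n_bound
    if n_bound == 0:
        return ((False, n_frames),)
    if n_un == 0:
        return ((True, n_frames),)
    n_un_lead = max(min_block, n_un // 2)
    n_un_lead = min(n_un_lead, n_un)
    n_un_tail = n_un - n_un_lead
    sched = [(False, n_un_lead), (True, n_bound)]
    if n_un_tail:
        sched.append((False, n_un_tail))
    return tuple(sched)


def _rotation_for(v_body: np.ndarray, body: BodyFrame, n_hat: np.ndarray) -> Rotation:
    """Minimal rotation R with R^T n_hat = (v expressed in reference coords)."""
    u = body.axes.T @ v_body
    rot, _ = Rotation.align_vectors(n_hat[None, :], u[None, :])
    return rot


def _background_orientation(
    rng: np.random.Generator, centers: list[tuple[float, float]], exclusion_deg: float
) -> tuple[float, float]:
    for _ in range(10000):
        lat = np.rad2deg(np.arcsin(rng.uniform(-1.0, 1.0)))
        lon = rng.uniform(-180.0, 180.0)
        if all(
            great_circle_deg(lat, lon, cl, cn) >= exclusion_deg for cl, cn in centers
        ):
            return float(lat), float(lon)
    raise RuntimeError("could not place a background orientation outside exclusion zones")


def _bresenham_contacts(fraction: float, n: int) -> np.ndarray:
    """Boolean schedule of length n with exactly round(fraction*n) True,
    spread evenly."""
    k = np.arange(n)
    return np.floor((k + 1) * fraction + 1e-12) > np.floor(k * fraction + 1e-12)


def make_protein_trajectory(
    bilayer_top: BeadTopology,
    bilayer_frame: Frame,
    spec: ProteinScheduleSpec,
    n_frames: int,
    seed: int,
    bilayer_spec: BilayerSpec | None = None,
    dt: float = 1.0,
) -> tuple[Trajectory, SyntheticTruth]:
    """Pose a scheduled protein chain over a bilayer.

    Bound segments place the rigid domain below the lower leaflet in its
    scheduled orientation and pin the anchor/planted tail residues to the
    head groups; unbound segments offset the whole chain far below the
    leaflet.  Returns the combined trajectory and the planted truth.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(6)
    rng_ref, rng_sched, rng_jit, rng_bg, rng_walk = (
        np.random.default_rng(c) for c in children[:5]
    )
    bilayer_child = children[5]
    box = bilayer_frame.box
    head_mask = bilayer_top.role_mask(Role.LIPID_HEAD)
    lower_heads = head_mask & (
        bilayer_frame.coords[:, 2] < bilayer_frame.coords[head_mask, 2].mean()
    )
    lower_head_z = float(bilayer_frame.coords[lower_heads, 2].mean())
    # planted contacts pin tail beads under heads of one designated species so
    # that species' per-residue contact column equals the planted fraction;
    # contact_species=None pins to the nearest head of any species, which
    # keeps the protein geometry independent of the leaflet composition
    if spec.contact_species is None:
        contact_heads = lower_heads
    else:
        contact_heads = lower_heads & (bilayer_top.species == spec.contact_species)
    if not contact_heads.any():
        raise ValueError(
            f"contact species {spec.contact_species!r} absent from the lower leaflet"
        )

    # ----- protein topology -------------------------------------------------
    n_tagged = spec.state_tagged_residues * len(spec.states)
    n_tail = spec.anchor_residues + len(spec.planted_contact_fractions) + n_tagged
    n_res = spec.n_rigid + n_tail
    res0 = spec.residue_start
    names = np.array(["BB"] * n_res, dtype=object)
    resids = np.arange(res0, res0 + n_res)
    resnames = np.array(["ALA"] * n_res, dtype=object)
    prot_mol = int(bilayer_top.molecule_id.max()) + 1
    top = BeadTopology(
        bead_names=np.concatenate([bilayer_top.bead_names, names]),
        residue_seq=np.concatenate([bilayer_top.residue_seq, resids]),
        residue_names=np.concatenate([bilayer_top.residue_names, resnames]),
        molecule_id=np.concatenate(
            [bilayer_top.molecule_id, np.full(n_res, prot_mol)]
        ),
        roles=np.concatenate(
            [bilayer_top.roles, np.array([Role.PROTEIN_BACKBONE] * n_res, dtype=object)]
        ),
        species=np.concatenate(
            [bilayer_top.species, np.array(["PROT"] * n_res, dtype=object)]
        ),
    )
    nb = bilayer_top.n_beads
    rigid_idx = nb + np.arange(spec.n_rigid)
    tail_idx = nb + spec.n_rigid + np.arange(n_tail)

    # rigid reference blob (non-degenerate almost surely)
    rigid_ref = rng_ref.normal(0.0, spec.rigid_size_sd, size=(spec.n_rigid, 3))
    rigid_ref -= rigid_ref.mean(axis=0)
    body = BodyFrame.from_reference(rigid_ref)
    n_hat = np.array([0.0, 0.0, -1.0])  # inward normal (toward protein side)

    # tail base xy offsets around the protein center
    ang = 2 * np.pi * np.arange(n_tail) / max(n_tail, 1)
    tail_offsets = 3.0 * np.stack([np.cos(ang), np.sin(ang)], axis=1)

    # ----- schedules --------------------------------------------------------
    schedule = spec.bound_schedule or bound_schedule_from_fraction(
        n_frames, spec.bound_fraction
    )
    if sum(s[1] for s in schedule) != n_frames:
        raise ValueError("bound schedule does not cover n_frames")
    bound = np.concatenate(
        [np.full(length, flag, dtype=bool) for flag, length in schedule]
    )
    bound_positions = np.flatnonzero(bound)
    n_bound = len(bound_positions)

    # per-bound-frame state labels in blocks
    labels = np.full(n_frames, -1, dtype=int)
    centers = [(s.latitude, s.longitude) for s in spec.states]
    if n_bound:
        block = max(1, spec.state_block)
        n_blocks = int(np.ceil(n_bound / block))
        pops = {i: s.population for i, s in enumerate(spec.states)}
        pops[-1] = max(0.0, 1.0 - sum(pops.values()))
        counts = _largest_remainder_counts(pops, n_blocks)
        block_labels = np.concatenate(
            [np.full(counts[i], i) for i in sorted(counts)]
        )
        block_labels = block_labels[rng_sched.permutation(n_blocks)]
        per_frame = np.repeat(block_labels, block)[:n_bound]
        labels[bound_positions] = per_frame

    # per-residue contact schedules over bound frames
    fractions = [1.0] * spec.anchor_residues + list(spec.planted_contact_fractions)
    contact_sched = np.zeros((n_tail, n_frames), dtype=bool)
    for j, f in enumerate(fractions):
        contact_sched[j, bound_positions] = _bresenham_contacts(f, n_bound)
    # state-tagged residues contact only while their state is occupied
    for s in range(len(spec.states)):
        for k in range(spec.state_tagged_residues):
            j = len(fractions) + s * spec.state_tagged_residues + k
            contact_sched[j] = labels == s

    # ----- frames -----------------------------------------------------------
    bilayer_traj = make_bilayer_frames(
        bilayer_top, bilayer_frame,
        bilayer_spec or BilayerSpec(box_xy=(box[0], box[1]), box_z=box[2]),
        n_frames, int(bilayer_child.generate_state(1)[0] % (2**31)), dt=dt,
    )
    center_xy = np.array([box[0] / 2.0, box[1] / 2.0])
    jitter_rad = np.deg2rad(spec.orientation_jitter_deg)
    frames = []
    truth_labels = labels.copy()
    bg_current: tuple[float, float] | None = None
    for f_i, bframe in enumerate(bilayer_traj):
        coords = np.empty((top.n_beads, 3))
        coords[:nb] = bframe.coords
        head_xyz = bframe.coords[contact_heads]
        if bound[f_i]:
            lab = labels[f_i]
            if lab >= 0:
                lat, lon = centers[lab]
                bg_current = None
            else:
                # contiguous background frames share one diffuse orientation
                if bg_current is None or f_i == 0 or labels[f_i - 1] != -1 or not bound[f_i - 1]:
                    bg_current = _background_orientation(
                        rng_bg, centers, spec.background_exclusion_deg
                    )
                lat, lon = bg_current
            v = angles_to_unit(lat, lon)
            R = _rotation_for(v, body, n_hat)
            J = Rotation.from_rotvec(rng_jit.normal(0.0, jitter_rad, 3))
            pose = (R * J).apply(rigid_ref)
            center_xy = (center_xy + rng_walk.normal(0.0, spec.xy_step, 2)) % box[:2]
            rigid_center = np.array([center_xy[0], center_xy[1], lower_head_z - 22.0])
            coords[rigid_idx] = pose + rigid_center
            for j in range(n_tail):
                base = (center_xy + tail_offsets[j]) % box[:2]
                if contact_sched[j, f_i]:
                    d2 = (head_xyz[:, 0] - base[0]) ** 2 + (head_xyz[:, 1] - base[1]) ** 2
                    h = head_xyz[int(np.argmin(d2))]
                    coords[tail_idx[j]] = [h[0], h[1], h[2] - spec.contact_depth]
                else:
                    coords[tail_idx[j]] = [base[0], base[1], lower_head_z - 30.0]
        else:
            # far below the leaflet: no contacts at all
            J = Rotation.from_rotvec(rng_jit.normal(0.0, jitter_rad, 3))
            pose = J.apply(rigid_ref)
            z = lower_head_z - spec.unbound_offset
            coords[rigid_idx] = pose + np.array([center_xy[0], center_xy[1], z - 10.0])
            for j in range(n_tail):
                base = (center_xy + tail_offsets[j]) % box[:2]
                coords[tail_idx[j]] = [base[0], base[1], z]
            bg_current = None
        frames.append(Frame(coords=coords, box=box.copy(), time=f_i * dt))

    planted_res = [int(resids[spec.n_rigid + spec.anchor_residues + j])
                   for j in range(len(spec.planted_contact_fractions))]
    anchors = [int(resids[spec.n_rigid + j]) for j in range(spec.anchor_residues)]
    base = spec.n_rigid + spec.anchor_residues + len(spec.planted_contact_fractions)
    tagged = [
        [int(resids[base + s * spec.state_tagged_residues + k])
         for k in range(spec.state_tagged_residues)]
        for s in range(len(spec.states))
    ] if spec.state_tagged_residues else []
    contact_truth = {r: 1.0 for r in anchors}
    contact_truth.update(
        {r: f for r, f in zip(planted_res, spec.planted_contact_fractions)}
    )
    truth = SyntheticTruth(
        bound=bound,
        state_labels=truth_labels,
        state_centers=centers,
        state_populations=[s.population for s in spec.states],
        contact_fractions=contact_truth,
        rigid_indices=rigid_idx,
        body=body,
        anchor_residue_seqs=anchors,
        planted_residue_seqs=planted_res,
        state_tagged_residue_seqs=tagged,
        contact_species=spec.contact_species,
    )
    return Trajectory(top, frames=frames), truth


# ---------------------------------------------------------------------------
# NMR fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NMRSpec:
    """Titration intensity fixture with a controllable Pearson correlation
    between the intensity ratio I/I0 and the contact fraction.

    With ratios modelled as I/I0 = 1 - slope * fraction + noise, the
    correlation with the contact fraction is negative for positive slope; the
    noise SD is solved so the expected correlation equals ``target_r``.
    """

    target_r: float = -0.55
    slope: float = 0.8
    ratios: tuple[float, ...] = (0.0, 5.0, 10.0, 25.0)
    species: str | None = None
    vanish_threshold: float | None = None
    i0: float = 1.0e5

    def __post_init__(self) -> None:
        if not -1.0 <= self.target_r <= 1.0:
            raise ValueError("|target_r| must be <= 1")


def make_nmr_titration(
    contacts: ContactProfile, spec: NMRSpec, seed: int
) -> TitrationSeries:
    """Peak tables whose final-point intensity ratios correlate with the
    contact profile at the planted Pearson r."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    frac = (
        contacts.column(spec.species) if spec.species is not None
        else contacts.fractions.max(axis=1)
    )
    residues = contacts.residue_seq
    sigma_f = float(np.std(frac))
    if spec.slope == 0.0:
        if spec.target_r != 0.0:
            raise ValueError("target correlation unreachable with slope 0")
        noise_sd = 0.01
    else:
        if sigma_f == 0.0:
            raise ValueError("contact profile has zero variance; cannot plant r")
        if spec.target_r == 0.0:
            raise ValueError("target_r=0 is degenerate; use slope=0 instead")
        if np.sign(spec.target_r) != -np.sign(spec.slope):
            raise ValueError(
                "sign of target_r must oppose the slope (ratios fall as contacts rise)"
            )
        if abs(spec.target_r) == 1.0:
            noise_sd = 0.0
        else:
            noise_sd = abs(spec.slope) * sigma_f * np.sqrt(
                1.0 / spec.target_r**2 - 1.0
            )

    h0 = 8.2 + 0.0005 * (residues - residues.min())
    n0 = 110.0 + 0.05 * (residues - residues.min())
    tables = [
        PeakTable(
            residue_seq=residues,
            h_ppm=h0,
            n_ppm=n0,
            intensity=np.full(len(residues), spec.i0),
            observed=np.ones(len(residues), dtype=bool),
        )
    ]
    max_ratio = max(spec.ratios[1:])
    for ratio in spec.ratios[1:]:
        scale = ratio / max_ratio
        eps = rng.normal(0.0, noise_sd, size=len(residues)) if noise_sd > 0 else 0.0
        ii0 = 1.0 - scale * spec.slope * frac + scale * eps
        intensity = spec.i0 * ii0
        observed = np.ones(len(residues), dtype=bool)
        if spec.vanish_threshold is not None:
            observed = ii0 >= spec.vanish_threshold
        tables.append(
            PeakTable(
                residue_seq=residues,
                h_ppm=np.where(observed, h0 + 0.002 * scale, np.nan),
                n_ppm=np.where(observed, n0 + 0.01 * scale, np.nan),
                intensity=np.where(observed, intensity, np.nan),
                observed=observed,
            )
        )
    return TitrationSeries(ratios=list(spec.ratios), tables=tables)


def make_decay(
    r2_true: float,
    delays: np.ndarray | None = None,
    noise_sd: float = 0.0,
    replicates: int = 3,
    i0: float = 100.0,
    seed: int = 0,
) -> DecayCurve:
    """Single-exponential decay fixture I = I0 exp(-R2 t) (1 + eps) with
    multiplicative Gaussian noise, at the standard delay list by default."""
    if r2_true < 0:
        raise ValueError("R2 must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise SD must be >= 0")
    delays = DEFAULT_R2_DELAYS if delays is None else np.asarray(delays, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    clean = i0 * np.exp(-r2_true * delays)
    reps = []
    for _ in range(replicates):
        eps = rng.normal(0.0, noise_sd, size=len(delays)) if noise_sd > 0 else 0.0
        reps.append(clean * (1.0 + eps))
    return DecayCurve(delays=delays, intensities=np.stack(reps))
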