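"""Protein-lipid contact profiles, residue-residue distance maps, and
membrane-bound-state statistics.

A contact is counted when a protein backbone bead lies within a cutoff
(default 7 A, inclusive, minimum image) of a lipid bead of the requested part
(head-group, acyl-chain, or either).  Contacts are per residue-species-frame:
any lipid of the species counts once per frame.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model_io import Role, Trajectory, min_image_distance_matrix

__all__ = [
    "ContactProfile",
    "ResidueDistanceMap",
    "BoundSeries",
    "residue_lipid_contact_fractions",
    "residue_residue_distance_map",
    "detect_bound_frames",
    "bound_statistics",
]

#: lipid part -> bead roles counted for that part.  "any" is the union of the
#: head-group and acyl-chain roles, so fraction(any) is exactly the per-frame
#: union of head/acyl contact events.
PART_ROLES = {
    "head": (Role.LIPID_HEAD,),
    "acyl": (Role.LIPID_ACYL,),
    "any": (Role.LIPID_HEAD, Role.LIPID_ACYL),
}


@dataclass
class ContactProfile:
    """Per-residue contact fraction per lipid species.

    ``fractions[i, j]`` is the fraction of analysed frames in which residue
    ``residue_seq[i]`` had at least one bead of ``species[j]`` (of the chosen
    lipid part) within the cutoff.
    """

    residue_seq: np.ndarray  # (R,) int
    species: list[str]  # (S,)
    part: str
    fractions: np.ndarray  # (R, S) in [0, 1]
    n_frames: int
    cutoff: float = 7.0

    def column(self, species: str) -> np.ndarray:
        return self.fractions[:, self.species.index(species)]

    def to_table(self) -> str:
        header = [
            f"# part: {self.part}  cutoff_A: {self.cutoff:g}  n_frames: {self.n_frames}",
            "residue\t" + "\t".join(self.species),
        ]
        rows = [
            f"{int(r)}\t" + "\t".join(f"{v:.6f}" for v in row)
            for r, row in zip(self.residue_seq, self.fractions)
        ]
        return "\n".join(header + rows) + "\n"


def _species_bead_indices(
    topology, part: str, species_filter: Sequence[str] | None
) -> dict[str, np.ndarray]:
    try:
        roles = PART_ROLES[part]
    except KeyError:
        raise ValueError(f"unknown lipid part {part!r}; expected head, acyl or any")
    mask = topology.role_mask(roles)
    species_present = sorted(
        {str(s) for s in np.unique(topology.species[mask])}
    )
    if species_filter is not None:
        wanted = [str(s) for s in species_filter]
        missing = [s for s in wanted if s not in species_present]
        if missing:
            raise ValueError(f"species not present with part {part!r}: {missing}")
        species_present = wanted
    if not species_present:
        raise ValueError("empty lipid species selection")
    return {
        s: np.flatnonzero(mask & (topology.species == s)) for s in species_present
    }


def residue_lipid_contact_fractions(
    traj: Trajectory,
    part: str = "head",
    cutoff: float = 7.0,
    species_filter: Sequence[str] | None = None,
    all_protein_beads: bool = False,
    equil_offset: int = 0,
    frame_indices: Sequence[int] | None = None,
) -> ContactProfile:
    """Fraction of frames each protein residue contacts each lipid species.

    The protein side uses backbone beads only by default
    (``all_protein_beads=True`` widens to every protein bead).  The first
    ``equil_offset`` frames are discarded as equilibration.  ``frame_indices``
    restricts the average to the given (post-offset) frame positions, which is
    how per-state profiles are computed.
    """
    top = traj.topology
    by_res = (
        top.protein_indices_by_residue() if all_protein_beads
        else top.backbone_indices_by_residue()
    )
    residues = top.protein_residues()
    if len(residues) == 0:
        raise ValueError("topology has no protein backbone beads")
    species_beads = _species_bead_indices(top, part, species_filter)
    species = list(species_beads)
    lipid_idx = np.concatenate([species_beads[s] for s in species])
    col_of = np.concatenate(
        [np.full(len(species_beads[s]), j) for j, s in enumerate(species)]
    )
    res_rows = []  # row index per protein bead used
    bead_rows = []
    for i, r in enumerate(residues):
        for b in by_res[int(r)]:
            res_rows.append(i)
            bead_rows.append(b)
    res_rows = np.asarray(res_rows)
    bead_rows = np.asarray(bead_rows)

    counts = np.zeros((len(residues), len(species)))
    n_used = 0
    wanted = None if frame_indices is None else set(int(i) for i in frame_indices)
    k = -1
    for f_i, frame in enumerate(traj):
        if f_i < equil_offset:
            continue
        k += 1
        if wanted is not None and k not in wanted:
            continue
        D = min_image_distance_matrix(
            frame.coords[bead_rows], frame.coords[lipid_idx], frame.box
        )
        close = D <= cutoff
        # residue x species contact indicator for this frame
        hit = np.zeros((len(residues), len(species)), dtype=bool)
        rows, cols = np.nonzero(close)
        if len(rows):
            np.logical_or.at(hit, (res_rows[rows], col_of[cols]), True)
        counts += hit
        n_used += 1
    if n_used == 0:
        raise ValueError("zero frames selected for contact analysis")
    return ContactProfile(
        residue_seq=residues,
        species=species,
        part=part,
        fractions=counts / n_used,
        n_frames=n_used,
        cutoff=cutoff,
    )


@dataclass
class ResidueDistanceMap:
    """Time-averaged minimum inter-residue bead distances between two
    selections, with close (<=4 A) and no-contact (>=6 A) masks."""

    residues_a: np.ndarray
    residues_b: np.ndarray
    mean_min_distance: np.ndarray  # (A, B) Angstrom
    close_cutoff: float = 4.0
    far_cutoff: float = 6.0

    @property
    def close_mask(self) -> np.ndarray:
        return self.mean_min_distance <= self.close_cutoff

    @property
    def no_contact_mask(self) -> np.ndarray:
        return self.mean_min_distance >= self.far_cutoff

    def to_table(self) -> str:
        header = [
            f"# close_cutoff_A: {self.close_cutoff:g}  far_cutoff_A: {self.far_cutoff:g}",
            "residue_a\\residue_b\t" + "\t".join(str(int(b)) for b in self.residues_b),
        ]
        rows = [
            f"{int(a)}\t" + "\t".join(f"{v:.4f}" for v in row)
            for a, row in zip(self.residues_a, self.mean_min_distance)
        ]
        return "\n".join(header + rows) + "\n"


def residue_residue_distance_map(
    traj: Trajectory,
    sel_a: Sequence[int],
    sel_b: Sequence[int],
    close_cutoff: float = 4.0,
    far_cutoff: float = 6.0,
) -> ResidueDistanceMap:
    """Average over frames of the minimum bead-bead distance between every
    residue pair of two disjoint protein selections (author residue numbers)."""
    sel_a = [int(r) for r in sel_a]
    sel_b = [int(r) for r in sel_b]
    if not sel_a or not sel_b:
        raise ValueError("selections must be non-empty")
    if set(sel_a) & set(sel_b):
        raise ValueError("selections overlap")
    by_res = traj.topology.protein_indices_by_residue()
    for r in sel_a + sel_b:
        if r not in by_res:
            raise ValueError(f"residue {r} not found among protein residues")
    idx_a = [by_res[r] for r in sel_a]
    idx_b = [by_res[r] for r in sel_b]
    flat_a = np.concatenate(idx_a)
    flat_b = np.concatenate(idx_b)
    # block boundaries for residue-wise min reduction
    bounds_a = np.cumsum([0] + [len(x) for x in idx_a])
    bounds_b = np.cumsum([0] + [len(x) for x in idx_b])

    total = np.zeros((len(sel_a), len(sel_b)))
    n = 0
    for frame in traj:
        D = min_image_distance_matrix(frame.coords[flat_a], frame.coords[flat_b], frame.box)
        for i in range(len(sel_a)):
            block = D[bounds_a[i]:bounds_a[i + 1]]
            for j in range(len(sel_b)):
                total[i, j] += block[:, bounds_b[j]:bounds_b[j + 1]].min()
        n += 1
    if n == 0:
        raise ValueError("trajectory has zero frames")
    return ResidueDistanceMap(
        residues_a=np.asarray(sel_a),
        residues_b=np.asarray(sel_b),
        mean_min_distance=total / n,
        close_cutoff=close_cutoff,
        far_cutoff=far_cutoff,
    )


@dataclass
class BoundSeries:
    """Per-frame membrane-bound flag with the criterion parameters used."""

    bound: np.ndarray  # (F,) bool
    times: np.ndarray  # (F,) ps
    cutoff: float
    min_residues: int
    dwell_frames: int
    raw: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.bound)

    def to_table(self) -> str:
        header = [
            f"# cutoff_A: {self.cutoff:g}  min_residues: {self.min_residues}  "
            f"dwell_frames: {self.dwell_frames}",
            "time_ps\tbound",
        ]
        rows = [f"{t:.6g}\t{int(b)}" for t, b in zip(self.times, self.bound)]
        return "\n".join(header + rows) + "\n"


def _debounce(raw: np.ndarray, dwell: int) -> np.ndarray:
    """Run-length state machine: a run of >= dwell consecutive raw-True frames
    switches the state to bound from the start of that run; a run of >= dwell
    raw-False frames switches back; shorter runs keep the current state."""
    out = np.zeros(len(raw), dtype=bool)
    state = False
    i = 0
    while i < len(raw):
        j = i
        while j < len(raw) and raw[j] == raw[i]:
            j += 1
        run = j - i
        if run >= dwell:
            state = bool(raw[i])
        out[i:j] = state
        i = j
    return out


def detect_bound_frames(
    traj: Trajectory,
    cutoff: float = 7.0,
    min_residues: int = 5,
    dwell_frames: int = 5,
    species_filter: Sequence[str] | None = None,
) -> BoundSeries:
    """Flag frames in which the protein is membrane bound.

    Raw criterion per frame: at least ``min_residues`` protein residues have a
    lipid head-group bead (any species unless filtered) within ``cutoff``.
    The raw flag is then debounced: ``dwell_frames`` consecutive raw-bound
    frames are needed to enter the bound state and the same number of raw-
    unbound frames to leave it, which suppresses single-frame flickers.
    """
    if dwell_frames < 1:
        raise ValueError("dwell_frames must be >= 1")
    top = traj.topology
    by_res = top.backbone_indices_by_residue()
    residues = top.protein_residues()
    species_beads = _species_bead_indices(top, "head", species_filter)
    lipid_idx = np.concatenate(list(species_beads.values()))
    res_rows, bead_rows = [], []
    for i, r in enumerate(residues):
        for b in by_res[int(r)]:
            res_rows.append(i)
            bead_rows.append(b)
    res_rows = np.asarray(res_rows)
    bead_rows = np.asarray(bead_rows)

    raw = []
    times = []
    for frame in traj:
        D = min_image_distance_matrix(
            frame.coords[bead_rows], frame.coords[lipid_idx], frame.box
        )
        close_any = (D <= cutoff).any(axis=1)
        n_contacting = len(np.unique(res_rows[close_any]))
        raw.append(n_contacting >= min_residues)
        times.append(frame.time)
    raw = np.asarray(raw, dtype=bool)
    return BoundSeries(
        bound=_debounce(raw, dwell_frames),
        times=np.asarray(times, dtype=float),
        cutoff=cutoff,
        min_residues=min_residues,
        dwell_frames=dwell_frames,
        raw=raw,
    )


def bound_statistics(series: BoundSeries) -> tuple[float, float | None, int]:
    """(bound_fraction, first_binding_time, n_binding_events).

    The fraction is bound frames over total frames; the first binding time is
    the timestamp of the first bound frame (None if never bound); events count
    unbound -> bound transitions.
    """
    b = series.bound
    if len(b) == 0:
        raise ValueError("empty bound series")
    fraction = float(np.mean(b))
    if not b.any():
        return 0.0, None, 0
    first = float(series.times[int(np.argmax(b))])
    prev = np.concatenate([[False], b[:-1]])
    events = int(np.sum(b & ~prev))
    return fraction, first, events
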