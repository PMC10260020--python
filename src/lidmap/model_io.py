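"""Domain types, structure/trajectory I/O and membrane geometry.

The in-memory model is deliberately small: a :class:`BeadTopology` describing
every bead of a coarse-grained system (protein chain plus lipid bilayer), a
:class:`Frame` of coordinates in Angstrom with an orthorhombic box, and a
:class:`Trajectory` that either holds frames in memory or streams them from an
XTC/DCD file.  File parsing is delegated to MDAnalysis; everything downstream
of the readers works on plain NumPy arrays.

Conventions used throughout the package:

* coordinates and cutoffs are in Angstrom (file-native nm is converted at I/O);
* boxes are orthorhombic; triclinic input is rejected;
* distance cutoffs are inclusive (``<=``);
* the membrane normal is +z toward the upper-leaflet solvent, and the protein
  sits on the intracellular side *below* the lower leaflet.
"""
from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Role",
    "BeadTopology",
    "Frame",
    "Trajectory",
    "MembraneModel",
    "ElasticBondSet",
    "ResidueSeries",
    "TrajectoryTruncated",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "min_image_distance",
    "min_image_distance_matrix",
    "assign_leaflets",
    "build_elastic_bonds",
    "generate_start_orientations",
]


class Role(str, enum.Enum):
    """Chemical role of a bead."""

    PROTEIN_BACKBONE = "protein_backbone"
    PROTEIN_SIDECHAIN = "protein_sidechain"
    LIPID_HEAD = "lipid_head"
    LIPID_ACYL = "lipid_acyl"
    LIPID_LINKER = "lipid_linker"
    SOLVENT = "solvent"
    ION = "ion"


PROTEIN_ROLES = frozenset({Role.PROTEIN_BACKBONE, Role.PROTEIN_SIDECHAIN})
LIPID_ROLES = frozenset({Role.LIPID_HEAD, Role.LIPID_ACYL, Role.LIPID_LINKER})

#: Default Martini-style bead-name -> role resolution.  Head-group beads cover
#: the phosphate/choline/serine beads and, for PI(4,5)P2, the inositol ring and
#: its phosphates; GL1/GL2 are glycerol linkers; C*A/C*B/D*A/D*B are acyl
#: beads; BB/SC* are protein beads.
DEFAULT_HEAD_NAMES = frozenset(
    {"NC3", "NH3", "PO4", "CNO", "CP", "P1", "P2", "C1", "C2", "C3", "INO"}
)
DEFAULT_LINKER_NAMES = frozenset({"GL1", "GL2", "GL3"})
DEFAULT_SOLVENT_NAMES = frozenset({"W", "WN", "WP", "SOL"})
DEFAULT_ION_NAMES = frozenset({"ION", "NA", "CL", "NA+", "CL-", "CA", "MG"})

_AA3 = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: residue-name normalisation for lipid species
_SPECIES_ALIASES = {"POP2": "PIP2", "PI24": "PIP2", "PAP2": "PIP2", "PIP2": "PIP2"}


def _default_role(bead_name: str) -> Role | None:
    name = bead_name.upper()
    if name == "BB":
        return Role.PROTEIN_BACKBONE
    if name.startswith("SC") and len(name) <= 3:
        return Role.PROTEIN_SIDECHAIN
    if name in DEFAULT_HEAD_NAMES:
        return Role.LIPID_HEAD
    if name in DEFAULT_LINKER_NAMES:
        return Role.LIPID_LINKER
    if len(name) == 3 and name[0] in "CD" and name[1].isdigit() and name[2] in "AB":
        return Role.LIPID_ACYL
    if name in DEFAULT_SOLVENT_NAMES:
        return Role.SOLVENT
    if name in DEFAULT_ION_NAMES:
        return Role.ION
    return None


@dataclass(frozen=True)
class Frame:
    """One set of coordinates (Angstrom) with an orthorhombic box and time (ps)."""

    coords: np.ndarray  # (N, 3) float64, Angstrom
    box: np.ndarray  # (3,) float64, Angstrom
    time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        object.__setattr__(self, "box", np.asarray(self.box, dtype=float))
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths (orthorhombic)")


@dataclass
class BeadTopology:
    """Bead-resolution topology with residue mapping and chemical roles.

    ``residue_seq`` preserves author numbering from the input file; internal
    bead indices are 0-based.  ``molecule_id`` groups beads into molecules: a
    contiguous run of protein residues is one molecule, every lipid / solvent /
    ion residue is its own molecule.
    """

    bead_names: np.ndarray  # (N,) str
    residue_seq: np.ndarray  # (N,) int, author numbering
    residue_names: np.ndarray  # (N,) str
    molecule_id: np.ndarray  # (N,) int
    roles: np.ndarray  # (N,) object array of Role
    species: np.ndarray  # (N,) str (POPC, POPS, PIP2, PROT, SOL, ION)

    def __post_init__(self) -> None:
        self.bead_names = np.asarray(self.bead_names, dtype=object)
        self.residue_seq = np.asarray(self.residue_seq, dtype=int)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.molecule_id = np.asarray(self.molecule_id, dtype=int)
        self.roles = np.asarray(self.roles, dtype=object)
        self.species = np.asarray(self.species, dtype=object)
        n = len(self.bead_names)
        for arr_name in ("residue_seq", "residue_names", "molecule_id", "roles", "species"):
            if len(getattr(self, arr_name)) != n:
                raise ValueError(f"{arr_name} length does not match bead count {n}")
        self.validate()

    # -- masks ---------------------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.bead_names)

    def role_mask(self, roles: Role | Iterable[Role]) -> np.ndarray:
        if isinstance(roles, Role):
            roles = (roles,)
        roles = set(roles)
        return np.fromiter((r in roles for r in self.roles), dtype=bool, count=self.n_beads)

    @property
    def protein_mask(self) -> np.ndarray:
        return self.role_mask(PROTEIN_ROLES)

    @property
    def backbone_mask(self) -> np.ndarray:
        return self.role_mask(Role.PROTEIN_BACKBONE)

    @property
    def lipid_mask(self) -> np.ndarray:
        return self.role_mask(LIPID_ROLES)

    # -- residue bookkeeping --------------------------------------------------
    def protein_residues(self) -> np.ndarray:
        """Ordered author residue numbers of the protein chain."""
        seqs = self.residue_seq[self.backbone_mask]
        _, order = np.unique(seqs, return_index=True)
        return seqs[np.sort(order)]

    def backbone_indices_by_residue(self) -> dict[int, np.ndarray]:
        """residue_seq -> bead indices of its backbone beads."""
        idx = np.flatnonzero(self.backbone_mask)
        out: dict[int, np.ndarray] = {}
        for i in idx:
            out.setdefault(int(self.residue_seq[i]), []).append(i)  # type: ignore[arg-type]
        return {r: np.asarray(v, dtype=int) for r, v in out.items()}

    def protein_indices_by_residue(self) -> dict[int, np.ndarray]:
        idx = np.flatnonzero(self.protein_mask)
        out: dict[int, list[int]] = {}
        for i in idx:
            out.setdefault(int(self.residue_seq[i]), []).append(int(i))
        return {r: np.asarray(v, dtype=int) for r, v in out.items()}

    def lipid_molecules(self) -> np.ndarray:
        """Molecule ids of lipid molecules, in order of first appearance."""
        mids = self.molecule_id[self.lipid_mask]
        _, order = np.unique(mids, return_index=True)
        return mids[np.sort(order)]

    def validate(self) -> None:
        """Check the topology invariants (one role per bead, lipid head beads,
        constant residue_seq within a residue)."""
        lipid_ids = set(self.lipid_molecules().tolist())
        head = self.role_mask(Role.LIPID_HEAD)
        for mid in lipid_ids:
            if not np.any(head & (self.molecule_id == mid)):
                raise ValueError(f"lipid molecule {mid} has no head bead")


class TrajectoryTruncated(RuntimeError):
    """Raised after yielding the readable frames of a truncated trajectory."""

    def __init__(self, message: str, frames_read: int):
        super().__init__(message)
        self.frames_read = frames_read


class Trajectory:
    """Ordered frames over a fixed topology.

    Either fully in memory (``frames=[...]``) or backed by an XTC/DCD file, in
    which case frames are streamed from disk on every iteration instead of
    being loaded wholesale.
    """

    def __init__(
        self,
        topology: BeadTopology,
        frames: Sequence[Frame] | None = None,
        path: str | os.PathLike | None = None,
        stride: int = 1,
    ):
        if (frames is None) == (path is None):
            raise ValueError("provide exactly one of frames or path")
        if stride < 1:
            raise ValueError("stride must be >= 1")
        self.topology = topology
        self.stride = int(stride)
        self._frames = list(frames) if frames is not None else None
        self._path = os.fspath(path) if path is not None else None
        if self._frames is not None:
            for f in self._frames:
                if f.coords.shape[0] != topology.n_beads:
                    raise ValueError(
                        f"frame has {f.coords.shape[0]} beads, topology has {topology.n_beads}"
                    )
            times = [f.time for f in self._frames]
            if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
                raise ValueError("frames must be time-ordered")
            self._n_frames = len(self._frames)
        else:
            self._n_frames = None  # determined lazily

    # -- construction ----------------------------------------------------------
    @classmethod
    def from_frames(cls, topology: BeadTopology, frames: Sequence[Frame]) -> "Trajectory":
        return cls(topology, frames=frames)

    # -- iteration -------------------------------------------------------------
    def _open_reader(self):
        import MDAnalysis as mda

        ext = os.path.splitext(self._path)[1].lower()
        if ext == ".xtc":
            return mda.coordinates.XTC.XTCReader(self._path)
        if ext == ".dcd":
            return mda.coordinates.DCD.DCDReader(self._path)
        raise ValueError(f"unsupported trajectory format: {ext!r} (expected .xtc or .dcd)")

    def iter_frames(self, indices: Sequence[int] | None = None) -> Iterator[Frame]:
        """Yield frames in order, honouring the stride; ``indices`` restricts
        to the given post-stride frame positions."""
        wanted = None if indices is None else set(int(i) for i in indices)
        if self._frames is not None:
            for k, fr in enumerate(self._frames[:: self.stride]):
                if wanted is None or k in wanted:
                    yield fr
            return
        reader = self._open_reader()
        n_atoms = reader.n_atoms
        if n_atoms != self.topology.n_beads:
            reader.close()
            raise ValueError(
                f"bead count mismatch: expected {self.topology.n_beads}, found {n_atoms}"
            )
        count = 0
        out_index = 0
        try:
            try:
                for i, ts in enumerate(reader):
                    if i % self.stride:
                        continue
                    frame = _frame_from_timestep(ts)
                    count += 1
                    if wanted is None or out_index in wanted:
                        yield frame
                    out_index += 1
            except (EOFError, OSError, RuntimeError) as exc:  # truncated file
                raise TrajectoryTruncated(
                    f"trajectory {self._path} truncated after {count} readable frames: {exc}",
                    frames_read=count,
                ) from exc
        finally:
            reader.close()

    def __iter__(self) -> Iterator[Frame]:
        return self.iter_frames()

    @property
    def n_frames(self) -> int:
        if self._n_frames is None:
            reader = self._open_reader()
            try:
                total = len(reader)
            finally:
                reader.close()
            self._n_frames = (total + self.stride - 1) // self.stride
        if self._frames is not None:
            return len(self._frames[:: self.stride])
        return self._n_frames

    def load(self) -> "Trajectory":
        """Materialise a file-backed trajectory in memory."""
        if self._frames is not None:
            return self
        return Trajectory(self.topology, frames=list(self.iter_frames()))


def _check_orthorhombic(dimensions: np.ndarray, where: str) -> np.ndarray:
    if dimensions is None:
        raise ValueError(f"{where}: no box information")
    lx, ly, lz, alpha, beta, gamma = [float(x) for x in dimensions]
    if not np.allclose([alpha, beta, gamma], 90.0, atol=1e-3):
        raise ValueError(
            f"{where}: triclinic box (angles {alpha:g}, {beta:g}, {gamma:g}) not supported; "
            "orthorhombic boxes only"
        )
    if min(lx, ly, lz) <= 0:
        raise ValueError(f"{where}: non-positive box dimension")
    return np.array([lx, ly, lz], dtype=float)


def _frame_from_timestep(ts) -> Frame:
    box = _check_orthorhombic(ts.dimensions, "trajectory frame")
    time = float(ts.time) if ts.time is not None else 0.0
    return Frame(coords=np.array(ts.positions, dtype=float), box=box, time=time)


# ---------------------------------------------------------------------------
# structure I/O
# ---------------------------------------------------------------------------

def read_structure(
    path: str | os.PathLike,
    role_table: Mapping[str, Mapping[str, str]] | None = None,
) -> tuple[BeadTopology, Frame]:
    """Read a GRO or PDB bead structure into a topology and one frame.

    ``role_table`` maps species -> {bead name -> role string} and overrides the
    shipped Martini-style defaults.  An unresolvable bead name raises a
    ``ValueError`` naming the offending bead.
    """
    import MDAnalysis as mda
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(os.fspath(path))
    atoms = u.atoms
    names = atoms.names.astype(object)
    resids = atoms.resids.astype(int)
    resnames = atoms.resnames.astype(object)
    box = _check_orthorhombic(u.dimensions, os.fspath(path))

    species = np.empty(len(names), dtype=object)
    roles = np.empty(len(names), dtype=object)
    # species from residue name
    for i, (nm, rn) in enumerate(zip(names, resnames)):
        rn_up = str(rn).upper()
        default = _default_role(str(nm))
        if rn_up in _AA3 or default in PROTEIN_ROLES:
            species[i] = "PROT"
        elif default is Role.SOLVENT:
            species[i] = "SOL"
        elif default is Role.ION:
            species[i] = "ION"
        else:
            species[i] = _SPECIES_ALIASES.get(rn_up, rn_up)

    for i, (nm, sp) in enumerate(zip(names, species)):
        role = None
        if role_table is not None:
            table = role_table.get(str(sp)) or role_table.get("*")
            if table is not None and str(nm) in table:
                role = Role(table[str(nm)])
        if role is None:
            role = _default_role(str(nm))
        if role is None:
            raise ValueError(
                f"cannot resolve role of bead {nm!r} (residue {resnames[i]!r} "
                f"{resids[i]}): unknown name with no role-table entry"
            )
        roles[i] = role

    molecule_id = _assign_molecule_ids(resids, roles)
    top = BeadTopology(
        bead_names=names,
        residue_seq=resids,
        residue_names=resnames,
        molecule_id=molecule_id,
        roles=roles,
        species=species,
    )
    frame = Frame(coords=np.array(atoms.positions, dtype=float), box=box, time=0.0)
    return top, frame


def _assign_molecule_ids(resids: np.ndarray, roles: np.ndarray) -> np.ndarray:
    """Contiguous protein residues share one molecule id; every other residue
    is its own molecule."""
    mid = np.zeros(len(resids), dtype=int)
    current = 0
    prev_resid: int | None = None
    prev_protein = False
    for i in range(len(resids)):
        resid = int(resids[i])
        is_protein = roles[i] in PROTEIN_ROLES
        new_residue = prev_resid is None or resid != prev_resid
        if new_residue and prev_resid is not None:
            if not (is_protein and prev_protein):
                current += 1
        mid[i] = current
        if new_residue:
            prev_protein = is_protein
        prev_resid = resid
    return mid


def _universe_from(topology: BeadTopology, frames: Sequence[Frame]):
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    n = topology.n_beads
    # residues in order of first appearance
    res_keys: list[tuple[int, int]] = []
    resindex = np.zeros(n, dtype=int)
    seen: dict[tuple[int, int], int] = {}
    for i in range(n):
        key = (int(topology.molecule_id[i]), int(topology.residue_seq[i]))
        if key not in seen:
            seen[key] = len(res_keys)
            res_keys.append(key)
        resindex[i] = seen[key]
    n_res = len(res_keys)
    u = mda.Universe.empty(
        n, n_residues=n_res, atom_resindex=resindex,
        residue_segindex=np.zeros(n_res, dtype=int), trajectory=False,
    )
    u.add_TopologyAttr("names", [str(x) for x in topology.bead_names])
    first = {}
    for i in range(n):
        first.setdefault(resindex[i], i)
    u.add_TopologyAttr("resids", [int(topology.residue_seq[first[r]]) for r in range(n_res)])
    u.add_TopologyAttr("resnames", [str(topology.residue_names[first[r]]) for r in range(n_res)])
    coords = np.stack([f.coords for f in frames]).astype(np.float32)
    dims = np.array(
        [[f.box[0], f.box[1], f.box[2], 90.0, 90.0, 90.0] for f in frames], dtype=np.float64
    )
    u.load_new(coords, format=MemoryReader, dimensions=dims)
    return u


def write_structure(path: str | os.PathLike, topology: BeadTopology, frame: Frame) -> None:
    """Write a single-frame GRO (or PDB) structure."""
    u = _universe_from(topology, [frame])
    u.atoms.write(os.fspath(path))


def write_trajectory(path: str | os.PathLike, trajectory: Trajectory) -> None:
    """Write an XTC or DCD trajectory (all frames, stride applied)."""
    import MDAnalysis as mda

    frames = list(trajectory.iter_frames())
    u = _universe_from(trajectory.topology, frames)
    with mda.Writer(os.fspath(path), trajectory.topology.n_beads) as w:
        for i, ts in enumerate(u.trajectory):
            ts.time = frames[i].time
            w.write(u.atoms)


def read_trajectory(
    path: str | os.PathLike, topology: BeadTopology, stride: int = 1
) -> Trajectory:
    """Open an XTC or DCD trajectory for streaming over ``topology``.

    Frames are yielded in file order without loading the whole file; a bead
    count mismatch raises immediately on first iteration.
    """
    traj = Trajectory(topology, path=path, stride=stride)
    # fail fast on count mismatch
    reader = traj._open_reader()
    try:
        if reader.n_atoms != topology.n_beads:
            raise ValueError(
                f"bead count mismatch: expected {topology.n_beads}, found {reader.n_atoms}"
            )
    finally:
        reader.close()
    return traj


# ---------------------------------------------------------------------------
# periodic geometry
# ---------------------------------------------------------------------------

def min_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    """Euclidean distance between two points under the minimum-image
    convention, each axis treated independently (orthorhombic box)."""
    box = np.asarray(box, dtype=float)
    if box.shape != (3,) or np.any(box <= 0):
        raise ValueError("box must be three positive lengths")
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d -= box * np.round(d / box)
    return float(np.sqrt(np.sum(d * d)))


def min_image_distance_matrix(A: np.ndarray, B: np.ndarray, box: np.ndarray) -> np.ndarray:
    """(len(A), len(B)) matrix of minimum-image distances."""
    box = np.asarray(box, dtype=float)
    if box.shape != (3,) or np.any(box <= 0):
        raise ValueError("box must be three positive lengths")
    d = np.asarray(A, dtype=float)[:, None, :] - np.asarray(B, dtype=float)[None, :, :]
    d -= box * np.round(d / box)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


# ---------------------------------------------------------------------------
# membrane model
# ---------------------------------------------------------------------------

@dataclass
class MembraneModel:
    """Leaflet bookkeeping for a bilayer.

    ``leaflet`` maps lipid molecule id -> "upper" / "lower".  The normal
    convention is +z toward the upper-leaflet solvent; the intracellular
    (protein) side is below the lower leaflet, so the inward normal used by
    the orientation analysis is -z.
    """

    midplane_z: float
    leaflet: dict[int, str]
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    lower_head_z: float = float("nan")
    upper_head_z: float = float("nan")
    lower_head_min_z: float = float("nan")

    @property
    def inward_normal(self) -> np.ndarray:
        """Unit vector from the lower leaflet toward the protein side."""
        return -np.asarray(self.normal, dtype=float)

    def molecules(self, side: str) -> np.ndarray:
        return np.array([m for m, s in self.leaflet.items() if s == side], dtype=int)


def assign_leaflets(frame: Frame, topology: BeadTopology) -> MembraneModel:
    """Assign each lipid to a leaflet by the sign of (mean head z - midplane).

    The midplane is the mean z of all lipid head beads; ties go to the lower
    leaflet.  Raises if fewer than two lipids carry head beads or if one
    leaflet ends up empty ("no bilayer detected").
    """
    head = topology.role_mask(Role.LIPID_HEAD)
    if not np.any(head):
        raise ValueError("no lipid head beads in topology")
    z = frame.coords[:, 2]
    midplane = float(np.mean(z[head]))
    leaflet: dict[int, str] = {}
    lower_heads: list[float] = []
    upper_heads: list[float] = []
    for mid in topology.lipid_molecules():
        sel = head & (topology.molecule_id == mid)
        if not np.any(sel):
            continue
        zm = float(np.mean(z[sel]))
        side = "upper" if zm > midplane else "lower"
        leaflet[int(mid)] = side
        (upper_heads if side == "upper" else lower_heads).extend(z[sel].tolist())
    if len(leaflet) < 2:
        raise ValueError("need at least 2 lipids with head beads")
    if not lower_heads or not upper_heads:
        raise ValueError("no bilayer detected: one leaflet is empty")
    return MembraneModel(
        midplane_z=midplane,
        leaflet=leaflet,
        lower_head_z=float(np.mean(lower_heads)),
        upper_head_z=float(np.mean(upper_heads)),
        lower_head_min_z=float(np.min(lower_heads)),
    )


# ---------------------------------------------------------------------------
# elastic network
# ---------------------------------------------------------------------------

@dataclass
class ElasticBondSet:
    """Backbone elastic network: bead-index pairs with equilibrium lengths.

    Force constant in kJ mol^-1 nm^-2; lengths in Angstrom.
    """

    pairs: np.ndarray  # (M, 2) int bead indices
    lengths: np.ndarray  # (M,) float, Angstrom
    force_constant: float
    lower_cutoff: float
    upper_cutoff: float

    def to_table(self) -> str:
        """Delimited text (i, j, r0_nm, k) for inclusion in topology files."""
        lines = [
            f"; elastic bonds: k={self.force_constant:g} kJ/mol/nm^2, "
            f"cutoffs {self.lower_cutoff:g}-{self.upper_cutoff:g} A",
            "i\tj\tr0_nm\tk",
        ]
        for (i, j), r in zip(self.pairs, self.lengths):
            lines.append(f"{int(i)}\t{int(j)}\t{r / 10.0:.4f}\t{self.force_constant:g}")
        return "\n".join(lines) + "\n"


def build_elastic_bonds(
    reference: Frame,
    topology: BeadTopology,
    lower: float = 5.0,
    upper: float = 9.0,
    force_constant: float = 400.0,
) -> ElasticBondSet:
    """Build the elastic network over protein backbone beads.

    One bond per backbone pair (i, j) with backbone-ordinal separation >= 2
    whose reference distance lies in [lower, upper] (inclusive); the
    equilibrium length is the reference distance.  Defaults follow the common
    coarse-grained recipe (400 kJ mol^-1 nm^-2, 5-9 A window).
    """
    bb = np.flatnonzero(topology.backbone_mask)
    if len(bb) < 3:
        raise ValueError("need at least 3 protein backbone beads")
    X = reference.coords[bb]
    diff = X[:, None, :] - X[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    n = len(bb)
    ii, jj = np.triu_indices(n, k=2)
    keep = (dist[ii, jj] >= lower) & (dist[ii, jj] <= upper)
    pairs = np.stack([bb[ii[keep]], bb[jj[keep]]], axis=1)
    lengths = dist[ii[keep], jj[keep]]
    return ElasticBondSet(
        pairs=pairs,
        lengths=lengths,
        force_constant=force_constant,
        lower_cutoff=lower,
        upper_cutoff=upper,
    )


# ---------------------------------------------------------------------------
# start orientations
# ---------------------------------------------------------------------------

def generate_start_orientations(
    complex_frame: Frame,
    topology: BeadTopology,
    membrane: MembraneModel,
    n: int = 16,
    offset: float = 7.0,
) -> list[Frame]:
    """Generate ``n`` rigid start poses of the protein complex below the
    lower leaflet.

    Rotation k uses angle k*(360/n) degrees about the x axis for even k and
    the y axis for odd k (equal angular steps, alternating axes); after each
    rotation the complex is translated along z so its minimum z-gap to the
    lower-leaflet head beads equals ``offset`` (complex below the leaflet,
    matching the intracellular geometry).
    """
    from scipy.spatial.transform import Rotation

    if n < 1:
        raise ValueError("n must be >= 1")
    if offset <= 0:
        raise ValueError("offset must be positive")
    if not np.isfinite(membrane.lower_head_min_z):
        raise ValueError("membrane model lacks lower-leaflet head positions")
    prot = np.flatnonzero(topology.protein_mask)
    if len(prot) == 0:
        raise ValueError("no protein beads in topology")
    X0 = complex_frame.coords[prot]
    centroid = X0.mean(axis=0)
    out: list[Frame] = []
    for k in range(n):
        angle = 360.0 * k / n
        axis = "x" if k % 2 == 0 else "y"
        R = Rotation.from_euler(axis, angle, degrees=True)
        X = R.apply(X0 - centroid) + centroid
        shift = (membrane.lower_head_min_z - offset) - X[:, 2].max()
        X = X + np.array([0.0, 0.0, shift])
        coords = complex_frame.coords.copy()
        coords[prot] = X
        out.append(Frame(coords=coords, box=complex_frame.box, time=float(k)))
    return out


# ---------------------------------------------------------------------------
# generic per-residue series
# ---------------------------------------------------------------------------

@dataclass
class ResidueSeries:
    """A per-residue scalar track (CSP, intensity ratio, SCS, RMSF, ...)."""

    residue_seq: np.ndarray  # (R,) int
    values: np.ndarray  # (R,) float
    kind: str
    flags: np.ndarray | None = None  # optional boolean per residue (e.g. vanished)

    def __post_init__(self) -> None:
        self.residue_seq = np.asarray(self.residue_seq, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.residue_seq) != len(self.values):
            raise ValueError("residue_seq and values must have equal length")
        if len(np.unique(self.residue_seq)) != len(self.residue_seq):
            raise ValueError("residues must be unique")

    def to_table(self) -> str:
        lines = [f"# kind: {self.kind}", "residue\tvalue"]
        for r, v in zip(self.residue_seq, self.values):
            lines.append(f"{int(r)}\t{v:.10g}")
        return "\n".join(lines) + "\n"
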