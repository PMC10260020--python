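"""2D lipid density and enrichment/depletion maps, and backbone RMSF.

Density maps are xy-plane histograms of a chosen lipid bead (default the PO4
phosphate bead) on a ~1 A grid covering the box footprint exactly; the
enrichment map expresses each bin as the percent deviation from the leaflet's
average density, so a value of +100% marks a doubling of the local density.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model_io import MembraneModel, ResidueSeries, Trajectory, assign_leaflets

__all__ = [
    "DensityMap",
    "EnrichmentMap",
    "lipid_density_map",
    "enrichment_map",
    "average_density_maps",
    "backbone_rmsf",
    "kabsch",
]


@dataclass
class DensityMap:
    """Mean bead counts per xy bin, averaged over frames."""

    grid: np.ndarray  # (nx, ny) mean counts per bin
    bin_size: tuple[float, float]  # actual bin widths (A)
    origin: tuple[float, float]
    box_xy: tuple[float, float]
    species: str
    bead_name: str
    n_frames: int
    leaflet: str
    centering: str  # "none" or a description of the centering selection

    def sidecar(self) -> str:
        return json.dumps(
            {
                "bin_size_A": list(self.bin_size),
                "origin_A": list(self.origin),
                "box_xy_A": list(self.box_xy),
                "species": self.species,
                "bead_name": self.bead_name,
                "n_frames": self.n_frames,
                "leaflet": self.leaflet,
                "centering": self.centering,
            },
            indent=2,
        )

    def to_table(self) -> str:
        return "\n".join(
            "\t".join(f"{v:.8g}" for v in row) for row in self.grid
        ) + "\n"


@dataclass
class EnrichmentMap:
    """Percent enrichment/depletion of density relative to the grid mean.

    By construction the mean over all bins is zero (to float precision).
    """

    grid: np.ndarray  # (nx, ny) percent
    source: DensityMap

    def to_table(self) -> str:
        return "\n".join(
            "\t".join(f"{v:.6g}" for v in row) for row in self.grid
        ) + "\n"

    def disc_mean(self, center_xy: Sequence[float], radius: float) -> float:
        """Mean enrichment over bins whose centers lie within ``radius`` of
        ``center_xy`` (minimum image in xy)."""
        nx, ny = self.grid.shape
        bx, by = self.source.bin_size
        cx = (np.arange(nx) + 0.5) * bx + self.source.origin[0]
        cy = (np.arange(ny) + 0.5) * by + self.source.origin[1]
        dx = cx[:, None] - float(center_xy[0])
        dy = cy[None, :] - float(center_xy[1])
        Lx, Ly = self.source.box_xy
        dx -= Lx * np.round(dx / Lx)
        dy -= Ly * np.round(dy / Ly)
        mask = dx**2 + dy**2 <= radius**2
        if not mask.any():
            raise ValueError("no bins inside the requested disc")
        return float(self.grid[mask].mean())


def lipid_density_map(
    traj: Trajectory,
    species: str,
    bead_name: str = "PO4",
    bin_size: float = 1.0,
    leaflet: str = "lower",
    center_on: Sequence[int] | None = None,
    membrane: MembraneModel | None = None,
) -> DensityMap:
    """xy density map of one lipid species' reference bead.

    Bead positions are wrapped into the box and histogrammed per frame on a
    grid of ~``bin_size`` A covering the box footprint exactly; the result is
    divided by the number of frames.  ``center_on`` (bead indices) translates
    each frame so the selection's xy center of geometry sits at the box
    center before binning, with periodic wrapping.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    if leaflet not in ("lower", "upper", "both"):
        raise ValueError("leaflet must be 'lower', 'upper' or 'both'")
    top = traj.topology
    sel = (top.species == species) & (top.bead_names == bead_name)
    if leaflet != "both":
        if membrane is None:
            first = next(iter(traj))
            membrane = assign_leaflets(first, top)
        keep_mols = set(membrane.molecules(leaflet).tolist())
        sel &= np.fromiter(
            (int(m) in keep_mols for m in top.molecule_id), dtype=bool, count=top.n_beads
        )
    idx = np.flatnonzero(sel)
    if len(idx) == 0:
        raise ValueError(
            f"no beads named {bead_name!r} of species {species!r} in leaflet {leaflet!r}"
        )
    center_idx = None if center_on is None else np.asarray(center_on, dtype=int)
    if center_idx is not None and len(center_idx) == 0:
        raise ValueError("empty centering selection")

    grid = None
    n_frames = 0
    box_xy = None
    for frame in traj:
        Lx, Ly = float(frame.box[0]), float(frame.box[1])
        if grid is None:
            nx = max(1, int(round(Lx / bin_size)))
            ny = max(1, int(round(Ly / bin_size)))
            grid = np.zeros((nx, ny))
            box_xy = (Lx, Ly)
            edges_x = np.linspace(0.0, Lx, nx + 1)
            edges_y = np.linspace(0.0, Ly, ny + 1)
        xy = frame.coords[idx, :2].copy()
        if center_idx is not None:
            cog = frame.coords[center_idx, :2].mean(axis=0)
            xy += np.array([Lx / 2.0, Ly / 2.0]) - cog
        xy[:, 0] %= Lx
        xy[:, 1] %= Ly
        H, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=[edges_x, edges_y])
        grid += H
        n_frames += 1
    if n_frames == 0:
        raise ValueError("trajectory has zero frames")
    return DensityMap(
        grid=grid / n_frames,
        bin_size=(box_xy[0] / grid.shape[0], box_xy[1] / grid.shape[1]),
        origin=(0.0, 0.0),
        box_xy=box_xy,
        species=species,
        bead_name=bead_name,
        n_frames=n_frames,
        leaflet=leaflet,
        centering="none" if center_idx is None else f"{len(center_idx)}-bead cog",
    )


def average_density_maps(maps: Sequence[DensityMap]) -> DensityMap:
    """Average compatible density maps (same grid/species), e.g. over
    independent bilayer realizations."""
    if not maps:
        raise ValueError("no maps to average")
    first = maps[0]
    for m in maps[1:]:
        if m.grid.shape != first.grid.shape or m.species != first.species:
            raise ValueError("density maps are not compatible")
    grid = np.mean([m.grid for m in maps], axis=0)
    total_frames = int(sum(m.n_frames for m in maps))
    return DensityMap(
        grid=grid,
        bin_size=first.bin_size,
        origin=first.origin,
        box_xy=first.box_xy,
        species=first.species,
        bead_name=first.bead_name,
        n_frames=total_frames,
        leaflet=first.leaflet,
        centering=first.centering,
    )


def enrichment_map(density: DensityMap, observed_only: bool = False) -> EnrichmentMap:
    """Percent enrichment/depletion relative to the average density.

    E(bin) = 100 * (rho(bin) - rho_mean) / rho_mean, with rho_mean taken over
    the full footprint (or, with ``observed_only``, over bins with at least
    one observation).  The mean of the output over the bins entering rho_mean
    is zero by construction.
    """
    grid = density.grid
    if observed_only:
        mask = grid > 0
        if not mask.any():
            raise ValueError("all-zero density map")
        mean = float(grid[mask].mean())
    else:
        mean = float(grid.mean())
        if mean <= 0:
            raise ValueError("all-zero density map")
    return EnrichmentMap(grid=100.0 * (grid - mean) / mean, source=density)


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t with R @ (P - Pc) + Qc
    superposing P onto Q.  Returns (R, t) such that aligned = P @ R.T + t.

    Raises on degenerate (collinear or fewer than 3 point) inputs.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.shape[0] < 3:
        raise ValueError("need two equal selections of >= 3 beads")
    Pc = P.mean(axis=0)
    Qc = Q.mean(axis=0)
    H = (P - Pc).T @ (Q - Qc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] <= 1e-10 * max(S[0], 1.0):
        raise ValueError("degenerate alignment selection (collinear beads)")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Qc - R @ Pc
    return R, t


def backbone_rmsf(
    traj: Trajectory,
    align_on: Sequence[int] | None = None,
    report_on: Sequence[int] | None = None,
) -> ResidueSeries:
    """Root-mean-square fluctuation of backbone beads after superposition.

    Each frame is superposed onto the mean structure by a least-squares fit on
    ``align_on`` beads (default: all backbone beads); RMSF(r) is the square
    root of the time-mean squared displacement of residue r's backbone bead
    from its time-mean position.  The mean structure is obtained by a first
    alignment pass onto frame 0.
    """
    top = traj.topology
    bb = np.flatnonzero(top.backbone_mask)
    align_idx = bb if align_on is None else np.asarray(align_on, dtype=int)
    report_idx = bb if report_on is None else np.asarray(report_on, dtype=int)
    if len(align_idx) == 0 or len(report_idx) == 0:
        raise ValueError("alignment and report selections must be non-empty")

    frames = [f.coords for f in traj]
    if len(frames) < 2:
        raise ValueError("need at least 2 frames for RMSF")

    # pass 1: align all frames onto frame 0, build the mean structure
    ref_align = frames[0][align_idx]
    aligned_report = []
    aligned_align = []
    for X in frames:
        R, t = kabsch(X[align_idx], ref_align)
        aligned_report.append(X[report_idx] @ R.T + t)
        aligned_align.append(X[align_idx] @ R.T + t)
    mean_align = np.mean(aligned_align, axis=0)

    # pass 2: align original frames onto the mean structure
    aligned = []
    for X in frames:
        R, t = kabsch(X[align_idx], mean_align)
        aligned.append(X[report_idx] @ R.T + t)
    A = np.stack(aligned)  # (F, M, 3)
    mean_pos = A.mean(axis=0)
    msd = np.mean(np.sum((A - mean_pos) ** 2, axis=2), axis=0)
    rmsf_per_bead = np.sqrt(msd)

    # reduce to per-residue (mean over a residue's report beads)
    res_of = top.residue_seq[report_idx]
    residues = []
    values = []
    for r in dict.fromkeys(res_of.tolist()):
        sel = res_of == r
        residues.append(int(r))
        values.append(float(rmsf_per_bead[sel].mean()))
    return ResidueSeries(
        residue_seq=np.asarray(residues), values=np.asarray(values), kind="RMSF"
    )
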