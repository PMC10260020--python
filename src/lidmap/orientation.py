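"""Geographic (latitude/longitude) orientation analysis of a rigid domain
relative to the membrane, and orientation-state extraction.

The orientation of a membrane-bound rigid body is summarised by where the
inward membrane normal (pointing from the lower leaflet toward the protein
side) pierces the body's unit sphere: the normal is expressed in the body
frame of the reference structure, giving a latitude in [-90, 90] degrees and
a longitude in (-180, 180] degrees.  A 2D population histogram over these
angles, restricted to membrane-bound frames, is smoothed and its local maxima
define orientation states whose populations are fractions of the bound time.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .contacts import BoundSeries, ContactProfile, residue_lipid_contact_fractions
from .membrane_maps import kabsch
from .model_io import MembraneModel, Trajectory

__all__ = [
    "BodyFrame",
    "OrientationSeries",
    "OrientationHistogram",
    "OrientationState",
    "OrientationStateMap",
    "orientation_series",
    "orientation_histogram",
    "extract_states",
    "representative_frame",
    "state_contact_profile",
    "angles_to_unit",
    "great_circle_deg",
]


def angles_to_unit(lat_deg, lon_deg) -> np.ndarray:
    """(lat, lon) degrees -> unit vector(s)."""
    lat = np.deg2rad(np.asarray(lat_deg, dtype=float))
    lon = np.deg2rad(np.asarray(lon_deg, dtype=float))
    return np.stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)], axis=-1
    )


def great_circle_deg(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle angle (degrees) between points on the unit sphere."""
    u = angles_to_unit(lat1, lon1)
    v = angles_to_unit(lat2, lon2)
    dot = np.clip(np.sum(u * v, axis=-1), -1.0, 1.0)
    return np.rad2deg(np.arccos(dot))


def _unit_to_angles(v: np.ndarray) -> tuple[float, float]:
    lat = 90.0 - np.rad2deg(np.arccos(np.clip(v[2], -1.0, 1.0)))
    lon = np.rad2deg(np.arctan2(v[1], v[0]))
    if lon <= -180.0:
        lon += 360.0
    return float(lat), float(lon)


@dataclass
class BodyFrame:
    """Reference coordinates of the rigid selection with orthonormal,
    right-handed body axes (rows of ``axes``).

    The default axes are the principal axes of the reference coordinates,
    ordered by descending variance, with a deterministic sign convention: the
    first axis points toward the hemisphere of the highest-index bead, the
    second toward that of the lowest-index bead, and the third completes the
    right-handed triad.
    """

    reference: np.ndarray  # (M, 3) centered reference coordinates
    axes: np.ndarray  # (3, 3), rows are body axes in reference coordinates
    mode: str = "principal-axes"

    @classmethod
    def from_reference(
        cls, coords: np.ndarray, axes: np.ndarray | None = None
    ) -> "BodyFrame":
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[0] < 3:
            raise ValueError("rigid selection needs at least 3 beads")
        centered = coords - coords.mean(axis=0)
        if axes is not None:
            A = np.asarray(axes, dtype=float)
            if A.shape != (3, 3) or not np.allclose(A @ A.T, np.eye(3), atol=1e-8):
                raise ValueError("user axes must be a 3x3 orthonormal matrix")
            if np.linalg.det(A) < 0:
                raise ValueError("user axes must be right-handed")
            return cls(reference=centered, axes=A, mode="user-supplied")
        cov = centered.T @ centered
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        e1, e2 = evecs[:, order[0]], evecs[:, order[1]]
        if evals[order[1]] <= 1e-10 * max(evals[order[0]], 1.0):
            raise ValueError("degenerate (collinear) rigid selection")
        hi = centered[-1]
        lo = centered[0]
        if np.dot(e1, hi) < 0:
            e1 = -e1
        if np.dot(e2, lo) < 0:
            e2 = -e2
        e3 = np.cross(e1, e2)
        return cls(reference=centered, axes=np.stack([e1, e2, e3]), mode="principal-axes")


@dataclass
class OrientationSeries:
    """Per-frame orientation angles with bound flags."""

    latitude: np.ndarray  # (F,) degrees in [-90, 90]
    longitude: np.ndarray  # (F,) degrees in (-180, 180]
    bound: np.ndarray  # (F,) bool
    times: np.ndarray  # (F,) ps

    def __len__(self) -> int:
        return len(self.latitude)

    def to_table(self) -> str:
        header = ["time_ps\tlatitude_deg\tlongitude_deg\tbound"]
        rows = [
            f"{t:.6g}\t{la:.6f}\t{lo:.6f}\t{int(b)}"
            for t, la, lo, b in zip(self.times, self.latitude, self.longitude, self.bound)
        ]
        return "\n".join(header + rows) + "\n"


def orientation_series(
    traj: Trajectory,
    rigid_sel: Sequence[int],
    body: BodyFrame,
    membrane: MembraneModel,
    bound: BoundSeries | None = None,
) -> OrientationSeries:
    """Latitude/longitude of the inward membrane normal in the body frame.

    Per frame, the least-squares rotation R mapping the reference rigid
    selection onto the frame is computed (Kabsch); the inward normal n is
    expressed in body axes as v = B (R^T n), giving latitude
    90 - arccos(v_z) and longitude atan2(v_y, v_x).
    """
    rigid_idx = np.asarray(rigid_sel, dtype=int)
    if len(rigid_idx) != body.reference.shape[0]:
        raise ValueError(
            f"rigid selection ({len(rigid_idx)} beads) does not match the body "
            f"reference ({body.reference.shape[0]} beads)"
        )
    n_hat = membrane.inward_normal
    n_hat = n_hat / np.linalg.norm(n_hat)
    lats, lons, times = [], [], []
    for frame in traj:
        X = frame.coords[rigid_idx]
        R, _ = kabsch(body.reference, X)  # R maps reference -> frame
        v = body.axes @ (R.T @ n_hat)
        lat, lon = _unit_to_angles(v)
        lats.append(lat)
        lons.append(lon)
        times.append(frame.time)
    F = len(lats)
    if bound is not None and len(bound) != F:
        raise ValueError("bound series length does not match trajectory")
    flags = bound.bound.copy() if bound is not None else np.ones(F, dtype=bool)
    return OrientationSeries(
        latitude=np.asarray(lats),
        longitude=np.asarray(lons),
        bound=flags,
        times=np.asarray(times),
    )


@dataclass
class OrientationHistogram:
    """Normalized population histogram over (longitude, latitude)."""

    H: np.ndarray  # (n_lon, n_lat), mass sums to 1
    lon_edges: np.ndarray
    lat_edges: np.ndarray
    bin_deg: float
    bound_only: bool

    @property
    def lon_centers(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    @property
    def lat_centers(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    def smoothed(self, sigma_deg: float) -> np.ndarray:
        """Gaussian smoothing, periodic in longitude, reflected in latitude."""
        if sigma_deg <= 0:
            return self.H.copy()
        sigma_bins = sigma_deg / self.bin_deg
        return ndimage.gaussian_filter(self.H, sigma=sigma_bins, mode=("wrap", "reflect"))

    def to_table(self) -> str:
        header = [
            f"# rows: longitude centers {self.lon_centers[0]:.1f}..{self.lon_centers[-1]:.1f} deg; "
            f"cols: latitude centers {self.lat_centers[0]:.1f}..{self.lat_centers[-1]:.1f} deg"
        ]
        rows = ["\t".join(f"{v:.8g}" for v in row) for row in self.H]
        return "\n".join(header + rows) + "\n"


def orientation_histogram(
    series: OrientationSeries, bin_deg: float = 5.0, bound_only: bool = True
) -> OrientationHistogram:
    """Histogram orientation angles; longitude is periodic.  With
    ``bound_only`` (default) only membrane-bound frames contribute; the mass
    over contributing frames sums to 1."""
    sel = series.bound if bound_only else np.ones(len(series), dtype=bool)
    if not sel.any():
        raise ValueError("no bound frames for orientation histogram")
    n_lon = max(1, int(round(360.0 / bin_deg)))
    n_lat = max(1, int(round(180.0 / bin_deg)))
    lon_edges = np.linspace(-180.0, 180.0, n_lon + 1)
    lat_edges = np.linspace(-90.0, 90.0, n_lat + 1)
    lon = series.longitude[sel]
    lat = series.latitude[sel]
    H, _, _ = np.histogram2d(lon, lat, bins=[lon_edges, lat_edges])
    # points exactly at +180 / +90 belong to the last bin (histogram2d already
    # closes the upper edge)
    H /= H.sum()
    return OrientationHistogram(
        H=H, lon_edges=lon_edges, lat_edges=lat_edges,
        bin_deg=360.0 / n_lon, bound_only=bound_only,
    )


@dataclass
class OrientationState:
    """One orientation state: center angles, population (fraction of bound
    time), members and representative frame."""

    center_lat: float
    center_lon: float
    population: float
    member_frames: np.ndarray  # frame indices into the series
    representative: int
    peak_bin: tuple[int, int]


@dataclass
class OrientationStateMap:
    """Extracted orientation states plus the smoothed histogram they came
    from.  State populations plus the unassigned mass sum to 1 over bound
    frames."""

    states: list[OrientationState]
    unassigned_mass: float
    histogram: OrientationHistogram
    smoothed: np.ndarray
    smooth_sigma_deg: float
    min_peak_mass: float
    assign_radius_deg: float

    def summary(self) -> list[dict]:
        return [
            {
                "state": i + 1,
                "center_lat_deg": s.center_lat,
                "center_lon_deg": s.center_lon,
                "population": s.population,
                "n_members": int(len(s.member_frames)),
                "representative_frame": int(s.representative),
            }
            for i, s in enumerate(self.states)
        ]


def _local_maxima(S: np.ndarray) -> list[tuple[int, int]]:
    footprint = np.ones((3, 3), dtype=bool)
    M = ndimage.maximum_filter(S, footprint=footprint, mode=("wrap", "reflect"))
    peaks = np.argwhere((S >= M) & (S > 0))
    return [tuple(p) for p in peaks]


def extract_states(
    hist: OrientationHistogram,
    series: OrientationSeries,
    smooth_sigma_deg: float = 10.0,
    min_peak_mass: float = 0.02,
    assign_radius_deg: float = 30.0,
) -> OrientationStateMap:
    """Extract orientation states from the population histogram.

    The histogram is Gaussian-smoothed (periodic in longitude, reflected in
    latitude); candidate states are local maxima, merged when closer than the
    assignment radius (the stronger peak wins; exact ties keep the lower flat
    bin index).  Each bound frame is assigned to the nearest surviving peak
    within the assignment radius (great-circle distance); states whose
    population falls below ``min_peak_mass`` are dropped and their frames
    reassigned among the remaining peaks.  States are numbered by descending
    population.  Zero states is a valid result.
    """
    S = hist.smoothed(smooth_sigma_deg)
    peaks = _local_maxima(S)
    n_lat = S.shape[1]
    # order candidates by descending smoothed value, ties by flat index
    peaks.sort(key=lambda p: (-S[p], p[0] * n_lat + p[1]))
    lon_c = hist.lon_centers
    lat_c = hist.lat_centers
    kept: list[tuple[int, int]] = []
    for p in peaks:
        ok = True
        for q in kept:
            d = great_circle_deg(lat_c[p[1]], lon_c[p[0]], lat_c[q[1]], lon_c[q[0]])
            if d < assign_radius_deg:
                ok = False
                break
        if ok:
            kept.append(p)

    bound_idx = np.flatnonzero(series.bound)
    n_bound = len(bound_idx)
    if n_bound == 0:
        raise ValueError("no bound frames")

    def assign(peaks_list):
        if not peaks_list:
            return np.full(n_bound, -1, dtype=int)
        plat = np.array([lat_c[p[1]] for p in peaks_list])
        plon = np.array([lon_c[p[0]] for p in peaks_list])
        flat = series.latitude[bound_idx]
        flon = series.longitude[bound_idx]
        D = np.stack(
            [great_circle_deg(flat, flon, la, lo) for la, lo in zip(plat, plon)],
            axis=1,
        )  # (n_bound, n_peaks)
        nearest = np.argmin(D, axis=1)
        dmin = D[np.arange(n_bound), nearest]
        out = np.where(dmin <= assign_radius_deg, nearest, -1)
        return out

    active = list(kept)
    while True:
        labels = assign(active)
        pops = np.array(
            [np.mean(labels == i) for i in range(len(active))]
        ) if active else np.array([])
        weak = [i for i, p in enumerate(pops) if p < min_peak_mass]
        if not weak:
            break
        # drop the weakest peak and re-assign
        drop = int(np.argmin(pops))
        active.pop(drop)
        if not active:
            labels = np.full(n_bound, -1, dtype=int)
            break

    states: list[OrientationState] = []
    for i, p in enumerate(active):
        members = bound_idx[labels == i]
        if len(members) == 0:
            continue
        center_lat = float(lat_c[p[1]])
        center_lon = float(lon_c[p[0]])
        d = great_circle_deg(
            series.latitude[members], series.longitude[members], center_lat, center_lon
        )
        rep = int(members[np.argmin(d)])  # argmin returns first on ties
        states.append(
            OrientationState(
                center_lat=center_lat,
                center_lon=center_lon,
                population=float(len(members) / n_bound),
                member_frames=members,
                representative=rep,
                peak_bin=(int(p[0]), int(p[1])),
            )
        )
    states.sort(key=lambda s: (-s.population, s.peak_bin[0] * n_lat + s.peak_bin[1]))
    unassigned = 1.0 - sum(s.population for s in states)
    return OrientationStateMap(
        states=states,
        unassigned_mass=float(unassigned),
        histogram=hist,
        smoothed=S,
        smooth_sigma_deg=smooth_sigma_deg,
        min_peak_mass=min_peak_mass,
        assign_radius_deg=assign_radius_deg,
    )


def representative_frame(state: OrientationState, series: OrientationSeries) -> int:
    """Member frame angularly closest to the state center; ties break to the
    smallest frame index."""
    if len(state.member_frames) == 0:
        raise ValueError("state has no member frames")
    d = great_circle_deg(
        series.latitude[state.member_frames],
        series.longitude[state.member_frames],
        state.center_lat,
        state.center_lon,
    )
    return int(state.member_frames[np.argmin(d)])


def state_contact_profile(
    member_frames: Sequence[int],
    traj: Trajectory,
    part: str = "head",
    cutoff: float = 7.0,
    species_filter: Sequence[str] | None = None,
) -> ContactProfile:
    """Contact-fraction profile restricted to a state's member frames,
    normalized by the member-frame count."""
    member_frames = np.asarray(member_frames, dtype=int)
    if len(member_frames) == 0:
        raise ValueError("empty state membership")
    return residue_lipid_contact_fractions(
        traj,
        part=part,
        cutoff=cutoff,
        species_filter=species_filter,
        frame_indices=member_frames,
    )
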