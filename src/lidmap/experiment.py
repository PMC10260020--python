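"""Analysis of solution-NMR, CD and imaging readouts, and their comparison
with simulation contact profiles.

Covers amide chemical-shift perturbations (CSP), titration intensity
profiles, secondary chemical shifts (SCS), single-exponential R2 relaxation
fits, mean-residue-ellipticity conversion and difference CD spectra, the
membrane/intracellular line-scan ratio, and the Pearson correlation between a
per-residue NMR series and a contact profile.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .contacts import ContactProfile
from .model_io import ResidueSeries

__all__ = [
    "PeakTable",
    "TitrationSeries",
    "DecayCurve",
    "CDSpectrum",
    "R2Fit",
    "CorrelationResult",
    "csp",
    "intensity_profile",
    "secondary_chemical_shifts",
    "fit_r2_decay",
    "nmr_contact_correlation",
    "cd_mre",
    "cd_difference",
    "line_scan_membrane_ratio",
]

#: the common delay list (seconds) for transverse-relaxation experiments
DEFAULT_R2_DELAYS = np.array(
    [0.0, 0.03392, 0.06784, 0.13568, 0.1696, 0.20352, 0.27136, 0.3392]
)


@dataclass
class PeakTable:
    """Per-residue amide peak table: 1H/15N shifts (ppm) and intensity.

    Residues not observed (exchange-broadened beyond detection) carry
    ``observed=False`` and NaN shifts/intensity.
    """

    residue_seq: np.ndarray  # (R,) int, unique
    h_ppm: np.ndarray
    n_ppm: np.ndarray
    intensity: np.ndarray
    observed: np.ndarray  # bool

    def __post_init__(self) -> None:
        self.residue_seq = np.asarray(self.residue_seq, dtype=int)
        if len(np.unique(self.residue_seq)) != len(self.residue_seq):
            raise ValueError("residues must be unique")
        for name in ("h_ppm", "n_ppm", "intensity"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.observed = np.asarray(self.observed, dtype=bool)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PeakTable":
        """Build from a DataFrame with columns residue_seq, H_ppm, N_ppm,
        intensity (NaN rows mean unobserved)."""
        obs = df[["H_ppm", "N_ppm", "intensity"]].notna().all(axis=1).to_numpy()
        return cls(
            residue_seq=df["residue_seq"].to_numpy(),
            h_ppm=df["H_ppm"].to_numpy(float),
            n_ppm=df["N_ppm"].to_numpy(float),
            intensity=df["intensity"].to_numpy(float),
            observed=obs,
        )

    @classmethod
    def read(cls, path) -> "PeakTable":
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        return cls.from_frame(df)

    def as_dict(self) -> dict[int, tuple[float, float, float, bool]]:
        return {
            int(r): (h, n, i, bool(o))
            for r, h, n, i, o in zip(
                self.residue_seq, self.h_ppm, self.n_ppm, self.intensity, self.observed
            )
        }


@dataclass
class TitrationSeries:
    """Ordered ligand:protein molar ratios with one peak table per point;
    point 0 is the reference."""

    ratios: Sequence[float]
    tables: Sequence[PeakTable]

    def __post_init__(self) -> None:
        if len(self.ratios) != len(self.tables):
            raise ValueError("one peak table per titration point required")
        if len(self.ratios) < 2:
            raise ValueError("need a reference point and at least one titration point")
        if self.ratios[0] != 0:
            raise ValueError("point 0 must be the reference (ratio 0)")


def csp(
    reference: PeakTable, titrated: PeakTable, alpha: float = 0.154
) -> tuple[ResidueSeries, list[int]]:
    """Amide chemical-shift perturbation per shared observed residue.

    CSP = sqrt(dH^2 + (alpha * dN)^2) with the standard 15N scaling
    alpha = 0.154.  Returns the series and the residues omitted because they
    are unobserved in either table.
    """
    ref = reference.as_dict()
    tit = titrated.as_dict()
    shared, omitted = [], []
    values = []
    for r in sorted(set(ref) | set(tit)):
        a = ref.get(r)
        b = tit.get(r)
        if a is None or b is None or not (a[3] and b[3]):
            omitted.append(r)
            continue
        dh = b[0] - a[0]
        dn = b[1] - a[1]
        shared.append(r)
        values.append(np.sqrt(dh**2 + (alpha * dn) ** 2))
    if not shared:
        raise ValueError("no shared observed residues between the tables")
    series = ResidueSeries(
        residue_seq=np.asarray(shared), values=np.asarray(values), kind="CSP ppm"
    )
    return series, omitted


def intensity_profile(titration: TitrationSeries) -> list[ResidueSeries]:
    """I/I0 per residue for every titration point past the reference.

    Residues whose peak disappears relative to the reference are reported as
    ratio 0 with a vanished flag; residues unobserved in the reference are
    omitted.
    """
    ref = titration.tables[0]
    out: list[ResidueSeries] = []
    ref_map = ref.as_dict()
    for ratio, table in zip(titration.ratios[1:], titration.tables[1:]):
        tit = table.as_dict()
        residues, values, vanished = [], [], []
        for r in sorted(ref_map):
            h0, n0, i0, obs0 = ref_map[r]
            if not obs0:
                continue
            if i0 <= 0:
                raise ValueError(f"non-positive reference intensity for residue {r}")
            entry = tit.get(r)
            if entry is None or not entry[3]:
                residues.append(r)
                values.append(0.0)
                vanished.append(True)
            else:
                residues.append(r)
                values.append(entry[2] / i0)
                vanished.append(False)
        out.append(
            ResidueSeries(
                residue_seq=np.asarray(residues),
                values=np.asarray(values),
                kind=f"intensity-ratio:{ratio:g}x",
                flags=np.asarray(vanished, dtype=bool),
            )
        )
    return out


def secondary_chemical_shifts(
    assigned: Mapping[int, float], random_coil: Mapping[int, float]
) -> ResidueSeries:
    """SCS = observed shift minus random-coil shift, per residue.

    ``random_coil`` must cover every assigned residue (the table is expected
    to be pre-corrected for pH/temperature); missing assignments are simply
    omitted, a residue missing from the random-coil table raises.
    """
    residues, values = [], []
    for r in sorted(assigned):
        obs = assigned[r]
        if obs is None or (isinstance(obs, float) and np.isnan(obs)):
            continue
        if r not in random_coil:
            raise ValueError(f"residue {r} absent from the random-coil table")
        residues.append(int(r))
        values.append(float(obs) - float(random_coil[r]))
    return ResidueSeries(
        residue_seq=np.asarray(residues), values=np.asarray(values), kind="SCS ppm"
    )


@dataclass
class DecayCurve:
    """Relaxation delays (s) with per-replicate intensities."""

    delays: np.ndarray  # (D,) strictly increasing, non-negative
    intensities: np.ndarray  # (replicates, D)

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if len(self.delays) < 3:
            raise ValueError("need at least 3 delay points")
        if np.any(self.delays < 0) or np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be non-negative and strictly increasing")
        if self.intensities.shape[1] != len(self.delays):
            raise ValueError("intensities shape does not match delays")


@dataclass
class R2Fit:
    r2: float  # s^-1
    i0: float
    r2_stderr: float
    i0_stderr: float
    negative_rate: bool
    converged: bool
    message: str = ""


def fit_r2_decay(curve: DecayCurve) -> R2Fit:
    """Least-squares single-exponential fit I(t) = I0 exp(-R2 t), jointly over
    all replicate points.

    Initialised from a log-space linear regression over positive intensities,
    then refined with nonlinear least squares; the standard errors come from
    the fit's curvature.  A negative fitted rate is flagged, not raised.
    """
    t = np.tile(curve.delays, curve.intensities.shape[0])
    y = curve.intensities.ravel()
    if np.any(curve.intensities[:, curve.delays == 0.0] <= 0):
        raise ValueError("intensities at delay 0 must be positive")

    pos = y > 0
    if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        p0 = (float(np.exp(intercept)), float(-slope))
    else:
        p0 = (float(np.max(y)), 1.0)

    def model(tt, i0, r2):
        return i0 * np.exp(-r2 * tt)

    if np.allclose(y, y[0]):
        # constant curve: R2 = 0 exactly
        return R2Fit(r2=0.0, i0=float(y[0]), r2_stderr=0.0, i0_stderr=0.0,
                     negative_rate=False, converged=True)
    try:
        popt, pcov = optimize.curve_fit(
            model, t, y, p0=p0, maxfev=20000, xtol=1e-12, ftol=1e-12
        )
    except RuntimeError as exc:
        return R2Fit(
            r2=float("nan"), i0=float("nan"), r2_stderr=float("nan"),
            i0_stderr=float("nan"), negative_rate=False, converged=False,
            message=f"non-convergence: {exc}",
        )
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else (np.nan, np.nan)
    return R2Fit(
        r2=float(popt[1]),
        i0=float(popt[0]),
        r2_stderr=float(perr[1]),
        i0_stderr=float(perr[0]),
        negative_rate=bool(popt[1] < 0),
        converged=True,
    )


@dataclass
class CorrelationResult:
    r: float
    p: float
    r_squared: float
    n: int
    selector: str = ""


def nmr_contact_correlation(
    series: ResidueSeries,
    contacts: ContactProfile,
    species: str | None = None,
) -> CorrelationResult:
    """Pearson correlation between a per-residue NMR series and a contact
    profile, over the residues shared by both.

    The contact column is a single species, or the per-residue maximum over
    species when none is given.  p is two-sided from the t transform with
    n - 2 degrees of freedom; R^2 = r^2 exactly.
    """
    frac = (
        contacts.column(species) if species is not None
        else contacts.fractions.max(axis=1)
    )
    cmap = {int(r): f for r, f in zip(contacts.residue_seq, frac)}
    xs, ys = [], []
    for r, v in zip(series.residue_seq, series.values):
        if int(r) in cmap and np.isfinite(v):
            xs.append(v)
            ys.append(cmap[int(r)])
    if len(xs) < 3:
        raise ValueError("fewer than 3 paired residues after intersection")
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("zero variance in one of the paired series")
    res = stats.pearsonr(xs, ys)
    r = float(res.statistic)
    return CorrelationResult(
        r=r,
        p=float(res.pvalue),
        r_squared=r * r,
        n=len(xs),
        selector=(
            f"series={series.kind}; species={species or 'max-over-species'}; "
            f"part={contacts.part}"
        ),
    )


@dataclass
class CDSpectrum:
    """Far-UV CD spectrum: wavelength grid (nm) and ellipticity.

    ``units`` is "mdeg" for raw ellipticity or "MRE" for mean residue
    ellipticity (deg cm^2 dmol^-1 res^-1); the metadata needed for the
    conversion travels with the spectrum.
    """

    wavelength_nm: np.ndarray
    values: np.ndarray
    units: str = "mdeg"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.wavelength_nm) != len(self.values):
            raise ValueError("wavelength and value arrays must match")
        if self.units not in ("mdeg", "MRE"):
            raise ValueError("units must be 'mdeg' or 'MRE'")


def cd_mre(
    raw: CDSpectrum,
    concentration_mg_ml: float,
    path_length_cm: float,
    n_residues: int,
    molar_mass: float,
) -> CDSpectrum:
    """Convert raw ellipticity (mdeg) to mean residue ellipticity.

    [theta]_MRW = theta_mdeg * MRW / (10 * l_cm * c_mg/mL) with the mean
    residue weight MRW = molar mass / (n_residues - 1).
    """
    if raw.units != "mdeg":
        raise ValueError("input spectrum must be in mdeg")
    for name, v in (
        ("concentration", concentration_mg_ml),
        ("path length", path_length_cm),
        ("molar mass", molar_mass),
    ):
        if v is None or v <= 0:
            raise ValueError(f"missing or non-positive {name}")
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    mrw = molar_mass / (n_residues - 1)
    factor = mrw / (10.0 * path_length_cm * concentration_mg_ml)
    return CDSpectrum(
        wavelength_nm=raw.wavelength_nm.copy(),
        values=raw.values * factor,
        units="MRE",
        metadata={
            **raw.metadata,
            "concentration_mg_ml": concentration_mg_ml,
            "path_length_cm": path_length_cm,
            "n_residues": n_residues,
            "molar_mass": molar_mass,
            "mrw": mrw,
        },
    )


def cd_difference(
    bound: CDSpectrum, free: CDSpectrum, zero_tol: float = 1e-9
) -> tuple[CDSpectrum, float | None]:
    """Pointwise difference spectrum (bound minus free) and the wavelength of
    its negative ellipticity minimum (None when the difference is flat or
    never negative)."""
    if bound.units != free.units:
        raise ValueError(f"unit mismatch: {bound.units} vs {free.units}")
    if len(bound.wavelength_nm) != len(free.wavelength_nm) or not np.allclose(
        bound.wavelength_nm, free.wavelength_nm
    ):
        raise ValueError("wavelength grids do not match")
    diff = bound.values - free.values
    spectrum = CDSpectrum(
        wavelength_nm=bound.wavelength_nm.copy(), values=diff, units=bound.units
    )
    if np.max(np.abs(diff)) <= zero_tol or np.min(diff) >= 0:
        return spectrum, None
    wl_min = float(bound.wavelength_nm[int(np.argmin(diff))])
    return spectrum, wl_min


def line_scan_membrane_ratio(
    profile: Sequence[float], membrane_mask: Sequence[bool]
) -> float:
    """Mean intensity in the membrane section divided by the mean in the
    intracellular section of a 1D fluorescence line scan."""
    profile = np.asarray(profile, dtype=float)
    mask = np.asarray(membrane_mask, dtype=bool)
    if profile.shape != mask.shape:
        raise ValueError("profile and mask must have equal length")
    if not mask.any() or mask.all():
        raise ValueError("mask must split the scan into non-empty sections")
    intra = float(profile[~mask].mean())
    if intra == 0:
        raise ValueError("zero intracellular mean")
    return float(profile[mask].mean()) / intra
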