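"""Forward models and primary SAXS analysis.

Chemical shifts are back-calculated with a two-state model (static
random-coil reference plus helix offsets gated by the per-conformer DSSP
'H' indicator); scattering curves come from the Debye equation over
point scatterers (per-residue Calpha or all heavy atoms with
element-constant factors).  Primary SAXS analysis covers the Guinier
approximation, the pair-distance distribution p(r), the dimensionless
Kratky transform, mass-fractal (power-law) fits, and reduced-chi-square
model-to-data fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from ._residue_data import (
    ELEMENT_ELECTRONS,
    ELEMENT_MASS,
    HELIX_SHIFT_OFFSETS,
    RANDOM_COIL_SHIFTS,
)
from .analysis import helix_indicator
from .conformers import Conformer, Ensemble

logger = logging.getLogger(__name__)

__all__ = [
    "ShiftTable",
    "SecondaryShifts",
    "SAXSCurve",
    "GuinierResult",
    "PofR",
    "FractalFit",
    "FitResult",
    "coil_shift_table",
    "predict_shifts",
    "secondary_shifts",
    "shift_agreement",
    "debye_curve",
    "guinier_fit",
    "pr_from_coords",
    "dimensionless_kratky",
    "fractal_fit",
    "chi2_fit",
    "ensemble_metrics",
    "radius_of_gyration",
    "classify_shape",
]

SUPPORTED_NUCLEI = ("CA", "CB", "HA")


@dataclass
class ShiftTable:
    """Chemical shifts per (residue, nucleus) in ppm.

    Backed by a DataFrame with columns residue (1-based), nucleus, value
    and optional sigma.
    """

    data: pd.DataFrame

    def __post_init__(self):
        required = {"residue", "nucleus", "value"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"shift table needs columns {sorted(required)}")
        bad = set(self.data["nucleus"]) - set(SUPPORTED_NUCLEI)
        if bad:
            raise ValueError(f"unsupported nuclei: {sorted(bad)}")
        if self.data.duplicated(["residue", "nucleus"]).any():
            raise ValueError("duplicate residue-nucleus entries")
        self.data = self.data.reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "ShiftTable":
        return cls(pd.DataFrame(records, columns=["residue", "nucleus", "value"]))

    def series(self) -> pd.Series:
        return self.data.set_index(["residue", "nucleus"])["value"]

    def __len__(self):
        return len(self.data)


@dataclass
class SecondaryShifts:
    """Observed minus random-coil shifts, per (residue, nucleus)."""

    data: pd.DataFrame  # residue, nucleus, value

    def series(self) -> pd.Series:
        return self.data.set_index(["residue", "nucleus"])["value"]


def coil_shift_table(sequence: str) -> ShiftTable:
    """Static random-coil reference shifts for a sequence."""
    rows = []
    for pos, aa in enumerate(sequence, start=1):
        ca, cb, ha = RANDOM_COIL_SHIFTS[aa]
        rows.append((pos, "CA", ca))
        if cb is not None:
            rows.append((pos, "CB", cb))
        rows.append((pos, "HA", ha))
    return ShiftTable.from_records(rows)


def predict_shifts(ens: Ensemble | Conformer, coil: ShiftTable,
                   helix_offsets: dict | None = None,
                   helix_fraction: np.ndarray | None = None) -> ShiftTable:
    """Two-state ensemble shift prediction.

    Per conformer the shift is coil + h_i * offset(nucleus) with h_i the
    DSSP alpha-helix indicator of residue i; the ensemble prediction is
    the unweighted mean, i.e. coil + f_H(i) * offset with f_H the helix
    frequency.  ``helix_fraction`` short-circuits the DSSP pass when the
    caller has it precomputed.
    """
    offsets = dict(HELIX_SHIFT_OFFSETS)
    if helix_offsets:
        offsets.update(helix_offsets)
    if helix_fraction is None:
        members = ens.members if isinstance(ens, Ensemble) else [ens]
        frac = np.mean([helix_indicator(c) for c in members], axis=0)
    else:
        frac = np.asarray(helix_fraction, dtype=float)
    rows = []
    for _, rec in coil.data.iterrows():
        res = int(rec["residue"])
        if res - 1 >= len(frac):
            logger.warning("no conformer residue for coil entry %d; omitted", res)
            continue
        rows.append((res, rec["nucleus"],
                     rec["value"] + frac[res - 1] * offsets[rec["nucleus"]]))
    return ShiftTable.from_records(rows)


def secondary_shifts(obs: ShiftTable, coil: ShiftTable) -> SecondaryShifts:
    """Delta-delta = observed minus random-coil on the common entries."""
    merged = obs.series().to_frame("obs").join(
        coil.series().to_frame("coil"), how="inner")
    if merged.empty:
        raise ValueError("no overlapping residue-nucleus entries")
    out = (merged["obs"] - merged["coil"]).rename("value").reset_index()
    return SecondaryShifts(out)


def shift_agreement(pred: ShiftTable, obs: ShiftTable, coil: ShiftTable):
    """RMSD over primary shifts and Pearson correlation of secondary shifts.

    The RMSD is identical for primary and secondary shifts because the
    coil reference cancels in the difference; both are computed and
    cross-checked.  Returns (rmsd, pooled secondary correlation,
    per-nucleus correlation dict).
    """
    p = pred.series()
    o = obs.series()
    common = p.index.intersection(o.index)
    if len(common) < 3:
        raise ValueError("need at least 3 common residue-nucleus pairs")
    dp = p.loc[common].to_numpy()
    do = o.loc[common].to_numpy()
    rmsd = float(np.sqrt(np.mean((dp - do) ** 2)))

    sec_p = secondary_shifts(pred, coil).series()
    sec_o = secondary_shifts(obs, coil).series()
    sec_common = sec_p.index.intersection(sec_o.index)
    sp = sec_p.loc[sec_common].to_numpy()
    so = sec_o.loc[sec_common].to_numpy()
    rmsd_secondary = float(np.sqrt(np.mean((sp - so) ** 2)))
    assert abs(rmsd - rmsd_secondary) < 1e-9, \
        "primary and secondary RMSD must agree (coil cancellation)"

    pooled = float(sp_stats.pearsonr(sp, so)[0]) if len(sp) >= 3 else np.nan
    per_nucleus = {}
    nuclei = sec_common.get_level_values("nucleus")
    for nuc in sorted(set(nuclei)):
        mask = nuclei == nuc
        if mask.sum() >= 3 and np.std(sp[mask]) > 0 and np.std(so[mask]) > 0:
            per_nucleus[nuc] = float(sp_stats.pearsonr(sp[mask], so[mask])[0])
    return rmsd, pooled, per_nucleus


# ---------------------------------------------------------------------------
# SAXS
# ---------------------------------------------------------------------------

@dataclass
class SAXSCurve:
    """Scattering profile: momentum transfer s (nm^-1), intensity, sigma."""

    s: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if len(self.sigma) != len(self.s):
                raise ValueError("sigma length mismatch")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive")
        if len(self.s) != len(self.I):
            raise ValueError("s and I must have equal length")
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("s must be strictly increasing")

    def __len__(self):
        return len(self.s)


@dataclass(frozen=True)
class GuinierResult:
    rg: float           # nm
    i0: float
    window: tuple       # (first, last) indices, inclusive
    r_squared: float
    srg_limit: float

    @property
    def n_points(self) -> int:
        return self.window[1] - self.window[0] + 1


@dataclass
class PofR:
    r: np.ndarray       # bin centers, nm
    p: np.ndarray
    dmax: float         # nm

    def __post_init__(self):
        if np.any(self.p < 0):
            raise ValueError("p(r) must be non-negative")
        # bin centers may overhang Dmax by half a bin width
        half = 0.5 * (self.r[1] - self.r[0]) if len(self.r) > 1 else 0.0
        beyond = self.r > self.dmax + half + 1e-12
        if np.any(self.p[beyond] > 0):
            raise ValueError("p(r) must vanish beyond Dmax")


@dataclass(frozen=True)
class FractalFit:
    dm: float
    flory_nu: float
    s_range: tuple
    n_points: int

    def __post_init__(self):
        if self.dm <= 0:
            raise ValueError("mass-fractal dimension must be positive")


@dataclass(frozen=True)
class FitResult:
    scale: float
    background: float
    chi2: float          # reduced
    n_points: int
    n_parameters: int


def _scatterers(obj: Conformer, granularity: str):
    if granularity == "ca":
        coords = obj.ca_coords()
        coords = coords[~np.isnan(coords[:, 0])]
        f = np.ones(len(coords))
    elif granularity == "heavy":
        mask = obj.heavy_mask
        coords = obj.coords[mask]
        f = np.array([ELEMENT_ELECTRONS[e] for e in obj.elements[mask]])
    else:
        raise ValueError("granularity must be 'ca' or 'heavy'")
    return coords, f


def debye_curve(obj: Conformer | Ensemble, s_grid,
                granularity: str = "ca",
                coords: np.ndarray | None = None,
                f: np.ndarray | None = None) -> SAXSCurve:
    """Debye-equation scattering curve.

    I(s) = sum_ij f_i f_j sinc(s r_ij); an ensemble yields the unweighted
    mean of its members' curves.  ``coords``/``f`` allow scattering from
    a bare point set (nm coordinates, per-point factors).
    """
    s = np.asarray(s_grid, dtype=float)
    if np.any(np.diff(s) <= 0) or np.any(s < 0):
        raise ValueError("s grid must be ascending and non-negative")
    if isinstance(obj, Ensemble):
        curves = np.stack([
            debye_curve(m, s, granularity=granularity).I for m in obj.members
        ])
        return SAXSCurve(s, curves.mean(axis=0))
    if coords is None:
        coords, f = _scatterers(obj, granularity)
    coords = np.asarray(coords, dtype=float)
    f = np.ones(len(coords)) if f is None else np.asarray(f, dtype=float)
    n = len(coords)
    if n < 2:
        logger.warning("fewer than 2 scatterers: flat curve")
        return SAXSCurve(s, np.full(len(s), float(np.sum(f ** 2))))
    diff = coords[:, None, :] - coords[None, :, :]
    iu = np.triu_indices(n, k=1)
    r = np.sqrt(np.sum(diff[iu] ** 2, axis=-1))
    w = (f[:, None] * f[None, :])[iu]
    x = np.outer(s, r)
    sinc = np.ones_like(x)
    nz = x > 0
    sinc[nz] = np.sin(x[nz]) / x[nz]
    intensity = np.sum(f ** 2) + 2.0 * sinc @ w
    return SAXSCurve(s, intensity)


def debye_from_distances(s_grid, r, weights=None) -> SAXSCurve:
    """Debye curve from a pairwise-distance sample (or histogram).

    ``r`` are distances (nm) with optional ``weights``; the self term is
    not included (callers add sum f^2 themselves if they need absolute
    scale — for shape analysis only relative intensities matter).
    """
    s = np.asarray(s_grid, dtype=float)
    r = np.asarray(r, dtype=float)
    w = np.ones_like(r) if weights is None else np.asarray(weights, dtype=float)
    x = np.outer(s, r)
    sinc = np.ones_like(x)
    nz = x > 0
    sinc[nz] = np.sin(x[nz]) / x[nz]
    return SAXSCurve(s, sinc @ w)


def guinier_fit(curve: SAXSCurve, srg_limit: float = 1.2,
                max_iter: int = 20) -> GuinierResult:
    """Iterative Guinier fit: ln I vs s^2 restricted to s*Rg below limit.

    Starts from the 10 lowest-s points and re-applies the window until it
    stabilizes.  Rejects curves with no Guinier regime (positive slope).
    """
    s = curve.s
    I = curve.I
    usable = I > 0
    if usable.sum() < 5:
        raise ValueError("need at least 5 positive-intensity points")
    n_window = min(10, usable.sum())
    window = np.where(usable)[0][:n_window]
    prev = None
    rg = None
    for _ in range(max_iter):
        x = s[window] ** 2
        y = np.log(I[window])
        slope, intercept, rvalue, _, _ = sp_stats.linregress(x, y)
        if slope >= 0:
            raise ValueError("no Guinier regime: non-negative low-angle slope")
        rg = float(np.sqrt(-3.0 * slope))
        new_window = np.where(usable & (s * rg < srg_limit))[0]
        if len(new_window) < 5:
            break
        if prev is not None and np.array_equal(new_window, window):
            break
        prev = window
        window = new_window
    return GuinierResult(rg=rg, i0=float(np.exp(intercept)),
                         window=(int(window[0]), int(window[-1])),
                         r_squared=float(rvalue ** 2), srg_limit=srg_limit)


def pr_from_coords(obj: Conformer | Ensemble, bin_width: float = 0.05,
                   granularity: str = "ca",
                   coords: np.ndarray | None = None,
                   f: np.ndarray | None = None) -> PofR:
    """Pair-distance distribution from coordinates.

    Weighted histogram of all pairwise scatterer distances; Dmax is the
    largest pair distance.  Ensembles average member histograms on a
    common grid (Dmax is the maximum over members).
    """
    if isinstance(obj, Ensemble):
        singles = [pr_from_coords(m, bin_width, granularity) for m in obj.members]
        dmax = max(p.dmax for p in singles)
        n_bins = int(np.ceil(dmax / bin_width)) + 1
        grid = (np.arange(n_bins) + 0.5) * bin_width
        acc = np.zeros(n_bins)
        for p in singles:
            acc[:len(p.p)] += p.p
        return PofR(grid, acc / len(singles), dmax)
    if coords is None:
        coords, f = _scatterers(obj, granularity)
    coords = np.asarray(coords, dtype=float)
    f = np.ones(len(coords)) if f is None else np.asarray(f, dtype=float)
    if len(coords) < 2:
        raise ValueError("need at least two scatterers")
    diff = coords[:, None, :] - coords[None, :, :]
    iu = np.triu_indices(len(coords), k=1)
    r = np.sqrt(np.sum(diff[iu] ** 2, axis=-1))
    w = (f[:, None] * f[None, :])[iu]
    dmax = float(r.max())
    n_bins = int(np.ceil(dmax / bin_width)) + 1
    hist, _ = np.histogram(r, bins=n_bins, range=(0.0, n_bins * bin_width),
                           weights=w)
    centers = (np.arange(n_bins) + 0.5) * bin_width
    return PofR(centers, hist.astype(float), dmax)


def dimensionless_kratky(curve: SAXSCurve, g: GuinierResult):
    """(s Rg)^2 I(s)/I(0) versus s Rg."""
    if g.i0 <= 0:
        raise ValueError("non-positive I(0)")
    x = curve.s * g.rg
    y = x ** 2 * curve.I / g.i0
    return x, y


def fractal_fit(curve: SAXSCurve, s_range: tuple = (0.55, 2.0)) -> FractalFit:
    """Mass-fractal dimension from the mid-angle log-log slope.

    Dm is the negative slope of log I versus log s inside ``s_range``
    (default 0.55-2.0 nm^-1); the Flory exponent is nu = 1/Dm.
    """
    lo, hi = s_range
    mask = (curve.s >= lo) & (curve.s <= hi) & (curve.I > 0)
    if mask.sum() < 5:
        raise ValueError("need at least 5 in-range points for the fractal fit")
    slope, _, _, _, _ = sp_stats.linregress(np.log(curve.s[mask]),
                                            np.log(curve.I[mask]))
    dm = float(-slope)
    if dm <= 0:
        raise ValueError("non-decaying intensity in the fractal window")
    return FractalFit(dm=dm, flory_nu=1.0 / dm, s_range=(lo, hi),
                      n_points=int(mask.sum()))


def classify_shape(dm: float) -> str:
    """Mass-fractal shape ladder.

    Rod-like chains give Dm near 1, swollen/disordered chains 1.7-1.8,
    ideal (self-crossing) random walks and thin discs 2, compact globules
    3-4.
    """
    if dm < 1.35:
        return "extended rod-like"
    if dm < 1.9:
        return "swollen chain / disordered"
    if dm < 2.5:
        return "random-walk chain or disc"
    return "compact/globular"


def chi2_fit(model: SAXSCurve, data: SAXSCurve,
             fit_background: bool = False) -> FitResult:
    """Reduced chi-square of a scaled model against data.

    The scale (and optional additive constant) minimizing chi^2 has a
    closed form; the model is interpolated onto the data grid when the
    grids differ.
    """
    if data.sigma is None:
        raise ValueError("data curve needs uncertainties")
    if np.any(data.sigma <= 0):
        raise ValueError("uncertainties must be positive")
    if len(model.s) == len(data.s) and np.allclose(model.s, data.s):
        im = model.I
    else:
        im = np.interp(data.s, model.s, model.I)
    iv = 1.0 / data.sigma ** 2
    if fit_background:
        a11 = np.sum(im * im * iv)
        a12 = np.sum(im * iv)
        a22 = np.sum(iv)
        b1 = np.sum(im * data.I * iv)
        b2 = np.sum(data.I * iv)
        det = a11 * a22 - a12 * a12
        c = (b1 * a22 - b2 * a12) / det
        b = (a11 * b2 - a12 * b1) / det
        k = 2
    else:
        c = np.sum(im * data.I * iv) / np.sum(im * im * iv)
        b = 0.0
        k = 1
    resid = (c * im + b - data.I) / data.sigma
    chi2 = float(np.sum(resid ** 2) / max(len(data.s) - k, 1))
    return FitResult(scale=float(c), background=float(b), chi2=chi2,
                     n_points=len(data.s), n_parameters=k)


def radius_of_gyration(coords: np.ndarray, weights=None) -> float:
    """Weighted RMS distance from the center of mass (nm)."""
    coords = np.asarray(coords, dtype=float)
    w = np.ones(len(coords)) if weights is None else np.asarray(weights, dtype=float)
    com = np.average(coords, axis=0, weights=w)
    return float(np.sqrt(np.average(np.sum((coords - com) ** 2, axis=1), weights=w)))


def ensemble_metrics(ens: Ensemble | Conformer,
                     mass_weighted: bool = True) -> pd.DataFrame:
    """Per-conformer Rg and terminal Calpha end-to-end distance (nm)."""
    members = ens.members if isinstance(ens, Ensemble) else [ens]
    rows = []
    for k, conf in enumerate(members):
        ca = conf.ca_coords()
        if np.isnan(ca[0, 0]) or np.isnan(ca[-1, 0]):
            raise ValueError("terminal Calpha atoms are required")
        mask = conf.heavy_mask
        coords = conf.coords[mask]
        weights = (np.array([ELEMENT_MASS[e] for e in conf.elements[mask]])
                   if mass_weighted else None)
        rows.append({
            "conformer": k,
            "rg": radius_of_gyration(coords, weights),
            "end_to_end": float(np.linalg.norm(ca[-1] - ca[0])),
        })
    return pd.DataFrame(rows)
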