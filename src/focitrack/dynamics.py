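"""Mobility and population-distribution analysis of focus tracks.

Mean squared displacement (MSD) is the workhorse: for free 2D diffusion
``MSD(Δt) = 4·D·Δt``, so a through-origin line ``y = a·t`` fitted to the first
few MSD points gives the apparent diffusion coefficient ``D = a/4``. Confined
motion bends the MSD toward a plateau, which is detected by comparing the
linear fit against a single-exponential saturation model. Population
distributions of per-focus intensity, area and total signal are summarized by
Gaussian kernel density estimates whose area is matched to the source
histogram, with a peak normalization factor anchored at the first time point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .segmentation import Focus
from .tracking import FocusTrack

__all__ = [
    "MSDCurve",
    "DiffusionFit",
    "DensityCurve",
    "MSDShape",
    "compute_msd",
    "compute_track_msd",
    "ensemble_msd",
    "fit_diffusion_coefficient",
    "focus_timeseries",
    "kde_distribution",
    "classify_msd_shape",
]


@dataclass
class MSDCurve:
    """Lag time (min) vs mean squared displacement (µm²).

    The lag-0 point (MSD = 0) is included; ``n_pairs`` counts the displacement
    pairs contributing to each lag and ``sem`` is their standard error (for
    ensemble curves, across tracks).
    """

    lag_times: np.ndarray
    msd: np.ndarray
    sem: np.ndarray
    n_pairs: np.ndarray

    def __len__(self) -> int:
        return len(self.lag_times)

    @property
    def nonzero(self) -> "MSDCurve":
        keep = self.lag_times > 0
        return MSDCurve(self.lag_times[keep], self.msd[keep],
                        self.sem[keep], self.n_pairs[keep])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag_min": self.lag_times,
                "msd_um2": self.msd,
                "sem_um2": self.sem,
                "n_pairs": self.n_pairs,
            }
        )


@dataclass(frozen=True)
class DiffusionFit:
    """Through-origin fit ``MSD = a·t`` with ``D = a/4`` (2D diffusion)."""

    slope: float  # µm²/min
    D: float  # µm²/min, slope / 4
    n_points: int
    residual_norm: float


@dataclass
class DensityCurve:
    """A kernel density curve scaled to its source histogram.

    ``density`` integrates (trapezoid rule) to ``hist_area * norm_factor``;
    ``norm_factor`` is the factor, fixed at the first time point, that makes
    the tallest histogram bar equal 1.
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    hist_area: float
    norm_factor: float

    @property
    def area(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass(frozen=True)
class MSDShape:
    """Model-comparison verdict on MSD curvature."""

    label: str  # 'linear' | 'saturating' | 'indeterminate'
    linear_sse: float
    saturating_sse: float
    ratio: float  # saturating_sse / linear_sse


def compute_msd(positions: np.ndarray, dt: float) -> MSDCurve:
    """Time-averaged MSD of one trajectory over all in-track pairs.

    For lag ``n·dt`` the MSD is the mean squared displacement over every
    ordered pair of positions ``n`` frames apart (overlapping windows).
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 2:
        raise ValueError("positions must have shape (n, 2)")
    n = positions.shape[0]
    if n < 2:
        return MSDCurve(np.empty(0), np.empty(0), np.empty(0), np.empty(0, dtype=int))
    lags = np.arange(n, dtype=float) * dt
    msd = np.zeros(n)
    sem = np.zeros(n)
    npairs = np.zeros(n, dtype=int)
    npairs[0] = n
    for k in range(1, n):
        disp = positions[k:] - positions[:-k]
        sq = np.einsum("ij,ij->i", disp, disp)
        msd[k] = sq.mean()
        sem[k] = sq.std(ddof=1) / math.sqrt(sq.size) if sq.size > 1 else 0.0
        npairs[k] = sq.size
    return MSDCurve(lags, msd, sem, npairs)


def compute_track_msd(track: FocusTrack) -> MSDCurve:
    """MSD of one focus track (single-focus tracks give an empty curve)."""
    return compute_msd(track.positions, track.frame_interval)


def ensemble_msd(
    tracks: Sequence[FocusTrack] | Sequence[np.ndarray],
    dt: float | None = None,
    min_tracks_per_lag: int = 3,
) -> MSDCurve:
    """Per-lag unweighted mean of per-track MSD curves, with SEM across tracks.

    The curve is truncated at the last lag supported by at least
    ``min_tracks_per_lag`` tracks (or by all tracks, when fewer are supplied).
    Accepts ``FocusTrack`` objects or raw ``(n, 2)`` position arrays (then
    ``dt`` is required).
    """
    curves: list[MSDCurve] = []
    for tr in tracks:
        if isinstance(tr, FocusTrack):
            c = compute_track_msd(tr)
        else:
            if dt is None:
                raise ValueError("dt is required for raw position arrays")
            c = compute_msd(np.asarray(tr), dt)
        if len(c) > 0:
            curves.append(c)
    if not curves:
        warnings.warn("ensemble_msd: no usable tracks (need >= 2 positions each)")
        return MSDCurve(np.empty(0), np.empty(0), np.empty(0), np.empty(0, dtype=int))

    max_len = max(len(c) for c in curves)
    step = curves[0].lag_times[1] - curves[0].lag_times[0] if len(curves[0]) > 1 else dt
    support = np.zeros(max_len, dtype=int)
    sums = np.zeros(max_len)
    sumsq = np.zeros(max_len)
    for c in curves:
        m = len(c)
        support[:m] += 1
        sums[:m] += c.msd
        sumsq[:m] += c.msd**2
    need = min(min_tracks_per_lag, len(curves))
    keep = support >= need
    last = int(np.max(np.nonzero(keep)[0])) + 1
    mean = sums[:last] / support[:last]
    var = np.zeros(last)
    ok = support[:last] > 1
    var[ok] = (sumsq[:last][ok] - support[:last][ok] * mean[ok] ** 2) / (
        support[:last][ok] - 1
    )
    sem = np.sqrt(np.clip(var, 0, None) / support[:last])
    lags = np.arange(last, dtype=float) * float(step)
    return MSDCurve(lags, mean, sem, support[:last])


def fit_diffusion_coefficient(curve: MSDCurve, n_points: int = 4) -> DiffusionFit:
    """Least-squares through-origin line on the first ``n_points`` nonzero lags.

    The fit starts at the origin (lag 0, MSD 0, which is excluded as a data
    point); the apparent diffusion coefficient is ``D = slope / 4``.
    """
    nz = curve.nonzero
    if len(nz) < 2:
        raise ValueError("need at least 2 nonzero-lag MSD points to fit")
    x = nz.lag_times[:n_points]
    y = nz.msd[:n_points]
    a = float(np.dot(x, y) / np.dot(x, x))
    resid = y - a * x
    return DiffusionFit(
        slope=a,
        D=a / 4.0,
        n_points=len(x),
        residual_norm=float(np.linalg.norm(resid)),
    )


def focus_timeseries(
    foci_by_frame: Mapping[int, Sequence[Focus]],
    n_frames: int | None = None,
) -> pd.DataFrame:
    """Per-frame mean focus intensity, area and total signal, with SEM.

    ``total`` is mean pixel intensity × area, the per-focus amount of labeled
    protein. Frames without foci report NaN (missing), not zero.
    """
    if n_frames is None:
        n_frames = 1 + max(foci_by_frame, default=-1)
    rows = []
    for t in range(n_frames):
        foci = foci_by_frame.get(t, ())
        if not foci:
            rows.append({"frame": t, "n_foci": 0, "mean_intensity": np.nan,
                         "sem_intensity": np.nan, "mean_area": np.nan,
                         "sem_area": np.nan, "mean_total": np.nan,
                         "sem_total": np.nan})
            continue
        inten = np.array([f.mean_intensity for f in foci])
        area = np.array([f.area for f in foci])
        total = np.array([f.total_intensity for f in foci])

        def _sem(v: np.ndarray) -> float:
            return float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else 0.0

        rows.append(
            {
                "frame": t,
                "n_foci": len(foci),
                "mean_intensity": float(inten.mean()),
                "sem_intensity": _sem(inten),
                "mean_area": float(area.mean()),
                "sem_area": _sem(area),
                "mean_total": float(total.mean()),
                "sem_total": _sem(total),
            }
        )
    return pd.DataFrame(rows).set_index("frame")


def kde_distribution(
    values: Sequence[float],
    bandwidth: float,
    t0_values: Sequence[float] | None = None,
    bins: int | str = 20,
    grid: np.ndarray | None = None,
    n_grid: int = 512,
    target_area: float | None = None,
) -> DensityCurve:
    """Gaussian-kernel density estimate scaled to the histogram of ``values``.

    The bandwidth is the kernel standard deviation in data units. The raw
    density (unit area) is scaled so the area under the curve equals the area
    of the histogram of ``values`` — or ``target_area`` when two conditions
    are compared after equalizing their histogram areas. A peak-normalization
    factor computed on the histogram of ``t0_values`` (default: ``values``
    itself) makes the tallest first-time-point bar equal 1; the same factor is
    meant to be reused for later time points of the same quantity.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 values for a density estimate")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")

    counts, edges = np.histogram(vals, bins=bins)
    widths = np.diff(edges)
    hist_area = float(np.sum(counts * widths))
    if target_area is None:
        target_area = hist_area

    ref = np.asarray(t0_values, dtype=float) if t0_values is not None else vals
    ref_counts, ref_edges = np.histogram(ref, bins=bins)
    # scale the reference histogram to the target area before taking its peak,
    # mirroring the equal-area scaling applied to the curves
    ref_area = float(np.sum(ref_counts * np.diff(ref_edges)))
    peak = ref_counts.max() * (target_area / ref_area) if ref_area > 0 else 1.0
    norm_factor = 1.0 / peak if peak > 0 else 1.0

    if grid is None:
        lo = vals.min() - 5.0 * bandwidth
        hi = vals.max() + 5.0 * bandwidth
        grid = np.linspace(lo, hi, n_grid)
    else:
        grid = np.asarray(grid, dtype=float)

    z = (grid[:, None] - vals[None, :]) / bandwidth
    density = np.exp(-0.5 * z**2).sum(axis=1) / (vals.size * bandwidth * math.sqrt(2 * math.pi))
    density = density * target_area * norm_factor
    return DensityCurve(
        grid=grid,
        density=density,
        bandwidth=bandwidth,
        hist_area=float(target_area),
        norm_factor=float(norm_factor),
    )


def classify_msd_shape(
    curve: MSDCurve,
    ratio_threshold: float = 0.5,
    min_points: int = 6,
) -> MSDShape:
    """Classify an MSD curve as linear (free diffusion) or saturating (confined).

    A through-origin line and a single-exponential plateau
    ``c·(1 − exp(−t/τ))`` are fitted to the nonzero lags; because the plateau
    model nests the line (τ → ∞), it is preferred only when it both reduces
    the sum of squared residuals below ``ratio_threshold`` times the linear
    fit's *and* its fitted timescale τ lies inside the observed lag range —
    otherwise the bend is extrapolation, not evidence of confinement. Curves
    with fewer than ``min_points`` nonzero lags are 'indeterminate'.
    """
    nz = curve.nonzero
    if len(nz) < min_points:
        return MSDShape("indeterminate", math.nan, math.nan, math.nan)
    x, y = nz.lag_times, nz.msd
    a = float(np.dot(x, y) / np.dot(x, x))
    lin_sse = float(np.sum((y - a * x) ** 2))
    scale = float(np.sum(y**2)) + 1e-300

    def plateau(t, c, tau):
        return c * (1.0 - np.exp(-t / tau))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                plateau, x, y,
                p0=[max(float(y.max()), 1e-12), float(x[0])],
                bounds=([0.0, 1e-9], [np.inf, np.inf]),
                maxfev=20000,
            )
        sat_sse = float(np.sum((y - plateau(x, *popt)) ** 2))
        tau = float(popt[1])
    except Exception:
        sat_sse = math.inf
        tau = math.inf

    if lin_sse / scale < 1e-12:  # numerically exact line
        return MSDShape("linear", lin_sse, sat_sse, math.nan)
    ratio = sat_sse / lin_sse
    saturating = ratio < ratio_threshold and tau <= float(x.max())
    return MSDShape("saturating" if saturating else "linear", lin_sse, sat_sse, ratio)
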