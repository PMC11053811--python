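"""Time-series analytics: tracer autocorrelation, MSD, release kinetics.

The tracer autocorrelation

    C(t) = ( <N(t0+t) N(t0)> - <N(t0)>^2 ) / ( <N^2(t0)> - <N(t0)>^2 )

follows the micelle size N experienced by each chain, averaged over every
chain as tracer and every sample as time origin; the relaxation time is the
first 1/e crossing.  Cargo mobility is quantified by the origin-averaged
mean squared displacement and its scaling exponent alpha, and release
curves are summarised with the Korsmeyer-Peppas law M_t/M_inf = k t^n
fitted to the initial 60% of the curve, where 0.45 < n < 1 signals
non-Fickian release (diffusion plus carrier relaxation/erosion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

INV_E = 1.0 / np.e


class DegenerateSeriesError(ValueError):
    """The input series carries no usable signal (zero variance, all zero...)."""


@dataclass
class KineticsSeries:
    """Tidy time-indexed record of the observables tracked during a run."""

    times: np.ndarray
    ec_fraction: np.ndarray | None = None        # fraction of end-caps removed
    b_fraction: np.ndarray | None = None         # fraction of hydrophobic beads freed
    encapsulated_count: np.ndarray | None = None
    released_fraction: np.ndarray | None = None
    msd: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def tracer_autocorrelation(tracer_N: np.ndarray) -> np.ndarray:
    """C(t) for lags 0..T-1 from per-tracer micelle-size series.

    ``tracer_N`` has shape (n_tracers, T); every sample serves as a time
    origin and all tracers are pooled.  Normalisation uses the pooled mean
    and variance, so C(0) = 1 exactly; a constant series is degenerate.
    """
    N = np.atleast_2d(np.asarray(tracer_N, dtype=float))
    n_tracers, T = N.shape
    mean = N.mean()
    var = (N * N).mean() - mean * mean
    if var <= 0:
        raise DegenerateSeriesError("tracer size series has zero variance")
    c = np.empty(T)
    for lag in range(T):
        c[lag] = (N[:, :T - lag] * N[:, lag:]).mean()
    return (c - mean * mean) / var


def relaxation_time(times, C, threshold: float = INV_E) -> float | None:
    """First crossing of C(t) below 1/e, linearly interpolated.

    Returns None when the correlation never relaxes below the threshold
    within the sampled window (the run was too short).
    """
    times = np.asarray(times, dtype=float)
    C = np.asarray(C, dtype=float)
    below = np.flatnonzero(C < threshold)
    if not len(below):
        return None
    k = below[0]
    if k == 0:
        return float(times[0])
    t0, t1 = times[k - 1], times[k]
    c0, c1 = C[k - 1], C[k]
    return float(t0 + (c0 - threshold) / (c0 - c1) * (t1 - t0))


def msd_curve(unwrapped: np.ndarray) -> np.ndarray:
    """Origin- and tracer-averaged MSD for lags 1..T-1.

    ``unwrapped`` has shape (T, n_tracers, 3) in unwrapped coordinates.
    """
    pos = np.asarray(unwrapped, dtype=float)
    if pos.ndim == 2:
        pos = pos[:, None, :]
    T = pos.shape[0]
    if T < 2:
        raise ValueError("need at least two frames for an MSD")
    out = np.empty(T - 1)
    for lag in range(1, T):
        d = pos[lag:] - pos[:-lag]
        out[lag - 1] = np.mean(np.sum(d * d, axis=-1))
    return out


@dataclass(frozen=True)
class MSDFit:
    """Power-law fit MSD ~ prefactor * t^alpha over a time window."""

    alpha: float
    prefactor: float
    window: tuple[float, float]


def fit_msd_exponent(times, msd, window: tuple[float, float] | None = None) -> MSDFit:
    """Least-squares slope of log MSD vs log t.

    Defaults to the last temporal decade of the curve, where the diffusive
    regime of a Langevin bead (alpha -> 1 for t >> 1/gamma) is reached.
    A vanishing MSD (static tracers) is degenerate.
    """
    times = np.asarray(times, dtype=float)
    msd = np.asarray(msd, dtype=float)
    if np.all(msd <= 0):
        raise DegenerateSeriesError("MSD is identically zero; exponent undefined")
    if window is None:
        window = (times[-1] / 10.0, times[-1])
    mask = (times >= window[0]) & (times <= window[1]) & (msd > 0) & (times > 0)
    if mask.sum() < 2:
        raise ValueError("fewer than two usable points in the fit window")
    slope, intercept = np.polyfit(np.log(times[mask]), np.log(msd[mask]), 1)
    return MSDFit(alpha=float(slope), prefactor=float(np.exp(intercept)), window=window)


def cargo_msd(unwrapped: np.ndarray, times,
              window: tuple[float, float] | None = None) -> tuple[np.ndarray, MSDFit]:
    """MSD curve plus its scaling exponent for a set of cargo tracers."""
    times = np.asarray(times, dtype=float)
    msd = msd_curve(unwrapped)
    lags = times[1:] - times[0]
    return msd, fit_msd_exponent(lags, msd, window)


def release_series(times, encapsulated_flags: np.ndarray,
                   initial_mask: np.ndarray | None = None) -> KineticsSeries:
    """Fraction of initially encapsulated cargo currently free, per frame.

    ``encapsulated_flags`` has shape (T, n_cargo); the initially
    encapsulated set defaults to frame 0.  Re-entry of a released molecule
    into any micelle lowers the fraction again (the fraction reports the
    current state, not a cumulative count).
    """
    flags = np.asarray(encapsulated_flags, dtype=bool)
    initial = flags[0] if initial_mask is None else np.asarray(initial_mask, dtype=bool)
    n0 = int(initial.sum())
    if n0 == 0:
        raise DegenerateSeriesError("no cargo is encapsulated at the origin")
    released = (initial & ~flags).sum(axis=1) / n0
    return KineticsSeries(times=np.asarray(times, dtype=float),
                          encapsulated_count=flags.sum(axis=1),
                          released_fraction=released)


@dataclass(frozen=True)
class KPFit:
    """Korsmeyer-Peppas fit of a release curve."""

    k_kinetic: float
    n_exponent: float
    fit_window: float
    residual: float                # rms residual over the fitted points
    n_points: int

    @property
    def regime(self) -> str:
        if self.n_exponent <= 0.45:
            return "Fickian"
        if self.n_exponent < 1.0:
            return "non-Fickian"
        return "case-II"


def kp_fit(times, released_fraction, fit_window: float = 0.60,
           min_points: int = 5) -> KPFit:
    """Nonlinear least-squares fit of M_t/M_inf = k t^n.

    Only the initial part of the curve with M_t/M_inf <= ``fit_window`` (and
    t > 0) enters the fit; the power law is fitted on the untransformed
    curve with a log-log linear fit supplying the starting point.
    """
    t = np.asarray(times, dtype=float)
    m = np.asarray(released_fraction, dtype=float)
    if np.all(m <= 0):
        raise DegenerateSeriesError("release curve is identically zero")
    # truncate at the first exceedance so late-time re-entries cannot re-admit points
    over = np.flatnonzero(m > fit_window)
    last = over[0] if len(over) else len(m)
    mask = (t > 0)
    mask[last:] = False
    if mask.sum() < min_points:
        raise ValueError(f"need at least {min_points} points below the "
                         f"{fit_window:.0%} release threshold, got {int(mask.sum())}")
    tt, mm = t[mask], m[mask]

    pos = mm > 0
    if pos.sum() >= 2:
        n0, logk0 = np.polyfit(np.log(tt[pos]), np.log(mm[pos]), 1)
        p0 = (float(np.exp(logk0)), float(np.clip(n0, 0.05, 3.0)))
    else:
        p0 = (mm.max() / tt.max(), 1.0)
    popt, _ = curve_fit(lambda t_, k, n: k * np.power(t_, n), tt, mm,
                        p0=p0, maxfev=20000)
    k, n = (float(v) for v in popt)
    if k <= 0:
        raise DegenerateSeriesError("fitted kinetic constant is non-positive")
    resid = float(np.sqrt(np.mean((k * tt ** n - mm) ** 2)))
    return KPFit(k_kinetic=k, n_exponent=n, fit_window=fit_window,
                 residual=resid, n_points=int(mask.sum()))
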