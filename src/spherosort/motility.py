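"""Track-level motility statistics and polar-coordinate MSD analysis.

Trajectories are transformed to polar coordinates (r, ϕ) about the spheroid
center, and origin-referenced ensemble mean squared displacements are built
separately in the radial and angular directions:

    ⟨(r − r0)²⟩ = Γ_r · t^α_r          ⟨(ϕ − ϕ0)²⟩ = Γ_ϕ · t^α_ϕ

with (r0, ϕ0) the first polar position of each trajectory.  The curves are
fit to the power law by nonlinear (Levenberg–Marquardt) least squares on the
lag interval [0, 3 h], lag 0 excluded; the exponent classifies motility as
sub-diffusive (α < 1), diffusive (α ≈ 1) or super-diffusive (α > 1), with the
95% CI of α̂ deciding the band.  The time-dependent effective diffusion
coefficient D_eff(t) = (Γ/2)·t^(α−1) satisfies MSD = 2·D_eff(t)·t identically
and lets non-diffusive data sets be compared in diffusion units at matched
time points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats as sps

from .geometry import SpheroidGeometry
from .tracks import Track

__all__ = [
    "PolarTrack",
    "MSDCurve",
    "PowerLawFit",
    "MotilityClass",
    "FitError",
    "instantaneous_speed",
    "persistence",
    "to_polar",
    "compute_msd",
    "fit_power_law",
    "bootstrap_power_law",
    "effective_diffusion",
    "classify_motility",
]

DEFAULT_FIT_RANGE_MIN = (0.0, 180.0)  # [0, 3 h]


class FitError(RuntimeError):
    """Power-law fit failed to converge or had insufficient data."""


# ---------------------------------------------------------------------------
# Per-track metrics
# ---------------------------------------------------------------------------

def instantaneous_speed(track: Track) -> np.ndarray:
    """Speeds |Δposition|/Δt between consecutive spots, in µm/min."""
    if len(track.spots) < 2:
        raise ValueError("instantaneous speed undefined for a single-spot track")
    xy = track.xy
    t = track.times
    disp = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    dt = np.diff(t)
    return disp / dt


def persistence(track: Track) -> float:
    """Net displacement over path length, dimensionless in [0, 1]."""
    xy = track.xy
    if len(xy) < 2:
        raise ValueError("persistence undefined for a single-spot track")
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    path = steps.sum()
    if path == 0:
        raise ValueError("persistence undefined for zero path length")
    net = np.linalg.norm(xy[-1] - xy[0])
    return float(net / path)


# ---------------------------------------------------------------------------
# Polar transform
# ---------------------------------------------------------------------------

@dataclass
class PolarTrack:
    """Polar representation of one trajectory about the spheroid center.

    ``phi`` is unwrapped: successive angular steps larger than π in magnitude
    are shifted by ±2π so the angle is continuous.  A spot exactly at the
    center takes r = 0 and carries the previous spot's angle (the first
    spot's angle defaults to 0 in that case).
    """

    track_id: str
    t: np.ndarray  # min
    r: np.ndarray  # µm
    phi: np.ndarray  # rad, unwrapped
    population: str = ""
    initial_compartment: str | None = None

    @property
    def origin(self) -> tuple[float, float]:
        """(r0, ϕ0): the trajectory's first polar position."""
        return float(self.r[0]), float(self.phi[0])


def to_polar(track: Track, geom: SpheroidGeometry) -> PolarTrack:
    """Transform a Cartesian track to (r, ϕ) about the spheroid center."""
    xy = track.xy - np.asarray(geom.center)
    r = np.hypot(xy[:, 0], xy[:, 1])
    raw_phi = np.arctan2(xy[:, 1], xy[:, 0])
    # carry the previous angle through the center, where phi is undefined
    at_center = r < 1e-12
    if at_center.any():
        for i in np.nonzero(at_center)[0]:
            raw_phi[i] = raw_phi[i - 1] if i > 0 else 0.0
    phi = np.unwrap(raw_phi)
    return PolarTrack(
        track_id=track.track_id,
        t=track.times,
        r=r,
        phi=phi,
        population=track.population,
        initial_compartment=track.initial_compartment,
    )


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------

@dataclass
class MSDCurve:
    """Ensemble mean squared displacement in one polar direction.

    ``msd[k]`` is the average of (value(lag_k) − value(0))² over every track
    that reaches lag_k, in µm² (radial) or rad² (angular).  ``n_contributing``
    counts the averaged tracks per lag and is non-increasing.
    """

    direction: str  # "radial" | "angular"
    lags: np.ndarray  # min, starting at 0
    msd: np.ndarray
    n_contributing: np.ndarray
    grouping: str = "per-condition ensemble"
    time_averaged: bool = False


def _track_values(pt: PolarTrack, direction: str) -> np.ndarray:
    if direction == "radial":
        return pt.r
    if direction == "angular":
        return pt.phi
    raise ValueError(f"unknown direction {direction!r}")


def compute_msd(
    polar_tracks: list[PolarTrack],
    direction: str = "radial",
    max_lag: float | None = None,
    time_averaged: bool = False,
) -> MSDCurve:
    """Ensemble MSD over tracks sharing a common frame interval.

    Origin-referenced by default: at lag t the squared excursion from each
    trajectory's own origin, (value(t) − value(0))², is averaged over all
    tracks long enough (equal-track weighting).  With ``time_averaged=True``
    every pair of spots separated by the lag contributes instead; the flag is
    recorded on the output.

    Lags that no track reaches are omitted.
    """
    if not polar_tracks:
        raise ValueError("no tracks supplied")
    dts = set()
    for pt in polar_tracks:
        if len(pt.t) >= 2:
            dts.update(np.round(np.diff(pt.t), 9))
    if len(dts) > 1:
        raise ValueError(f"tracks do not share a single frame interval: {sorted(dts)}")
    dt = dts.pop() if dts else 1.0

    max_len = max(len(pt.t) for pt in polar_tracks)
    n_lags = max_len
    if max_lag is not None:
        n_lags = min(n_lags, int(np.floor(max_lag / dt)) + 1)

    sums = np.zeros(n_lags)
    counts = np.zeros(n_lags, dtype=int)
    for pt in polar_tracks:
        v = _track_values(pt, direction)
        m = min(len(v), n_lags)
        if time_averaged:
            for k in range(m):
                d = v[k:] - v[: len(v) - k] if k else np.zeros(len(v))
                sums[k] += np.mean(d**2)
                counts[k] += 1
        else:
            d2 = (v[:m] - v[0]) ** 2
            sums[:m] += d2
            counts[:m] += 1
    keep = counts > 0
    return MSDCurve(
        direction=direction,
        lags=np.arange(n_lags)[keep] * dt,
        msd=sums[keep] / counts[keep],
        n_contributing=counts[keep],
        time_averaged=time_averaged,
    )


# ---------------------------------------------------------------------------
# Power-law fit
# ---------------------------------------------------------------------------

@dataclass
class PowerLawFit:
    """MSD = Γ·t^α fit over a lag window.

    ``gamma`` has units µm²·min^(−α) (radial) or rad²·min^(−α) (angular).
    Standard errors come from the nonlinear-fit covariance.
    """

    gamma: float
    alpha: float
    se_gamma: float
    se_alpha: float
    fit_range: tuple[float, float]
    rss: float
    n_points: int
    direction: str = "radial"

    def ci95_alpha(self) -> tuple[float, float]:
        half = 1.959963984540054 * self.se_alpha
        return (self.alpha - half, self.alpha + half)


def fit_power_law(
    curve: MSDCurve,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE_MIN,
    p0: tuple[float, float] | None = None,
) -> PowerLawFit:
    """Fit Γ·t^α to an MSD curve by Levenberg–Marquardt least squares.

    The fit runs on the linear scale within ``fit_range`` (minutes); lag 0 is
    excluded since the model is degenerate there.  Unless ``p0`` is given,
    initialization comes from the log–log linear regression of the positive
    MSD values.

    Raises
    ------
    FitError
        Fewer than 3 positive-lag points in range, or no convergence.
    """
    t0, t1 = fit_range
    sel = (curve.lags > 0) & (curve.lags >= t0) & (curve.lags <= t1)
    t = curve.lags[sel]
    y = curve.msd[sel]
    if t.size < 3:
        raise FitError(
            f"need >= 3 positive-lag points in [{t0}, {t1}] min, got {t.size}"
        )

    if p0 is None:
        pos = y > 0
        if pos.sum() >= 2:
            slope, intercept = np.polyfit(np.log(t[pos]), np.log(y[pos]), 1)
            p0 = (float(np.exp(intercept)), float(slope))
        else:
            p0 = (max(y.max(), 1e-12), 1.0)

    def model(tt, gamma, alpha):
        return gamma * np.power(tt, alpha)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        try:
            popt, pcov = optimize.curve_fit(
                model, t, y, p0=p0, method="lm", maxfev=20000
            )
        except (RuntimeError, ValueError) as exc:
            raise FitError(f"power-law fit did not converge: {exc}") from exc
    gamma, alpha = popt
    if gamma <= 0:
        raise FitError(f"fit returned non-positive amplitude gamma={gamma}")
    resid = y - model(t, *popt)
    rss = float(resid @ resid)
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return PowerLawFit(
        gamma=float(gamma),
        alpha=float(alpha),
        se_gamma=float(se[0]),
        se_alpha=float(se[1]),
        fit_range=(float(t0), float(t1)),
        rss=rss,
        n_points=int(t.size),
        direction=curve.direction,
    )


def bootstrap_power_law(
    polar_tracks: list[PolarTrack],
    direction: str = "radial",
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE_MIN,
    max_lag: float | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> PowerLawFit:
    """Power-law fit with track-resampling (bootstrap) standard errors.

    The point estimate is the plain fit to the full-ensemble MSD.  Standard
    errors, however, come from refitting ``n_boot`` bootstrap resamples of
    whole tracks: squared displacements at different lags of the same track
    are strongly correlated, so the nonlinear-fit covariance understates the
    parameter uncertainty, while resampling tracks (the independent unit)
    does not.  Use this fit for motility classification of noisy ensembles.
    """
    if max_lag is None:
        max_lag = fit_range[1]
    curve = compute_msd(polar_tracks, direction=direction, max_lag=max_lag)
    fit = fit_power_law(curve, fit_range=fit_range)

    # per-track squared displacements on the common lag grid
    n_lags = len(curve.lags)
    vals = [_track_values(pt, direction) for pt in polar_tracks]
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(6,)))
    gammas, alphas = [], []
    n = len(polar_tracks)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sums = np.zeros(n_lags)
        counts = np.zeros(n_lags, dtype=int)
        for i in idx:
            v = vals[i]
            m = min(len(v), n_lags)
            sums[:m] += (v[:m] - v[0]) ** 2
            counts[:m] += 1
        keep = counts > 0
        boot_curve = MSDCurve(
            direction=direction,
            lags=curve.lags[keep],
            msd=sums[keep] / counts[keep],
            n_contributing=counts[keep],
        )
        try:
            bfit = fit_power_law(boot_curve, fit_range=fit_range, p0=(fit.gamma, fit.alpha))
        except FitError:
            continue
        gammas.append(bfit.gamma)
        alphas.append(bfit.alpha)
    if len(alphas) >= 10:
        se_gamma = float(np.std(gammas, ddof=1))
        se_alpha = float(np.std(alphas, ddof=1))
    else:  # resampling failed almost everywhere; keep covariance-based errors
        se_gamma, se_alpha = fit.se_gamma, fit.se_alpha
    return PowerLawFit(
        gamma=fit.gamma,
        alpha=fit.alpha,
        se_gamma=se_gamma,
        se_alpha=se_alpha,
        fit_range=fit.fit_range,
        rss=fit.rss,
        n_points=fit.n_points,
        direction=direction,
    )


def effective_diffusion(fit: PowerLawFit, times: np.ndarray) -> np.ndarray:
    """Time-dependent effective diffusion coefficient D_eff(t) = (Γ/2)·t^(α−1).

    Satisfies 2·D_eff(t)·t = Γ·t^α identically, so MSD = 2·D_eff(t)·t holds at
    every t.  Units: µm²/min for radial fits.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0) or (np.any(t == 0) and fit.alpha < 1):
        raise ValueError("t must be > 0 (t=0 diverges for alpha < 1)")
    return (fit.gamma / 2.0) * np.power(t, fit.alpha - 1.0)


# ---------------------------------------------------------------------------
# Motility classification
# ---------------------------------------------------------------------------

@dataclass
class MotilityClass:
    """Sub-diffusive / diffusive / super-diffusive call for one fit."""

    label: str
    alpha: float
    ci95: tuple[float, float]


def classify_motility(fit: PowerLawFit) -> MotilityClass:
    """Classify by whether the 95% CI of α̂ lies below, across, or above 1."""
    if not np.isfinite(fit.se_alpha):
        raise ValueError("fit has no finite standard error for alpha")
    lo, hi = fit.ci95_alpha()
    if hi < 1.0:
        label = "sub-diffusive"
    elif lo > 1.0:
        label = "super-diffusive"
    else:
        label = "diffusive"
    return MotilityClass(label=label, alpha=fit.alpha, ci95=(lo, hi))
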