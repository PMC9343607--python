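"""Spheroid geometry: fitted ellipses, the Distance Index and compartments.

The spheroid core is modelled as an ellipse fitted to a binary mask (moment
based, matching Fiji's *Fit Ellipse*) or to a point cloud (direct
least-squares conic fit).  Two sorting statistics are computed against that
ellipse:

* the Distance Index ``DI = d / a`` — a cell's distance ``d`` to the spheroid
  center divided by the semi-major axis ``a`` (0 at the center, 1 at the
  spheroid-matrix interface along the major axis), with an alternative
  *elliptical* normalization that is exactly 1 everywhere on the boundary;
* ``ΔDI`` — final minus initial DI of a tracked cell, positive for net
  outward motion.

Cells are assigned to the *edge* compartment when their true Euclidean
distance to the ellipse boundary is at most a ring width (30 µm by default,
about two cell layers), otherwise *core*; points outside the ellipse are
*outside*.  The point-to-ellipse distance is solved numerically on the
parametric normal equation rather than approximated by a shrunken ellipse.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpheroidGeometry",
    "GeometryError",
    "fit_ellipse",
    "distance_index",
    "delta_distance_index",
    "point_to_boundary_distance",
    "classify_compartment",
    "sorting_summary",
]

Normalization = Literal["major-axis", "elliptical"]

DEFAULT_RING_WIDTH_UM = 30.0


class GeometryError(ValueError):
    """Raised for degenerate geometric input (collinear points, empty mask)."""


@dataclass(frozen=True)
class SpheroidGeometry:
    """Fitted ellipse describing the spheroid core.

    Parameters
    ----------
    center : (float, float)
        Ellipse center ``(cx, cy)`` in µm.
    a, b : float
        Semi-major and semi-minor axes in µm, ``a >= b > 0``.
    phi0_axis : float
        Orientation of the major axis in radians, measured from +x.
    frame : int or None
        Frame index when per-frame geometry is used; ``None`` for static.
    """

    center: tuple[float, float]
    a: float
    b: float
    phi0_axis: float = 0.0
    frame: int | None = None

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise GeometryError(
                f"require a >= b > 0, got a={self.a}, b={self.b}"
            )

    @property
    def is_circle(self) -> bool:
        return np.isclose(self.a, self.b)

    def to_local(self, xy: np.ndarray) -> np.ndarray:
        """Rotate/translate points into the ellipse-aligned frame."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        c, s = np.cos(self.phi0_axis), np.sin(self.phi0_axis)
        rot = np.array([[c, s], [-s, c]])
        return (xy - np.asarray(self.center)) @ rot.T

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """True for points inside or on the ellipse."""
        local = self.to_local(xy)
        v = (local[:, 0] / self.a) ** 2 + (local[:, 1] / self.b) ** 2
        return v <= 1.0 + 1e-12

    def to_dict(self) -> dict:
        return {
            "cx": self.center[0],
            "cy": self.center[1],
            "a": self.a,
            "b": self.b,
            "theta": self.phi0_axis,
            "frame": self.frame,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpheroidGeometry":
        return cls(
            center=(float(d["cx"]), float(d["cy"])),
            a=float(d["a"]),
            b=float(d["b"]),
            phi0_axis=float(d.get("theta", 0.0)),
            frame=d.get("frame"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SpheroidGeometry":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Ellipse fitting
# ---------------------------------------------------------------------------

def _fit_ellipse_mask(mask: np.ndarray, pixel_size: float) -> SpheroidGeometry:
    """Moment-based ellipse of the single foreground component of a mask.

    Pixel centers sit at integer (col, row) coordinates, 0-based; ``x`` is the
    column index.  The returned ellipse has the same centroid and second
    central moments as the foreground region, the convention used by Fiji's
    *Fit Ellipse*.
    """
    from scipy import ndimage

    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise GeometryError("empty mask")
    labels, n = ndimage.label(mask)
    if n != 1:
        # keep the largest component; a spheroid mask should be one blob
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
        warnings.warn(
            f"mask has {n} components; using the largest", stacklevel=3
        )
    if mask.sum() < 5:
        raise GeometryError("mask foreground has fewer than 5 pixels")

    rows, cols = np.nonzero(mask)
    x = cols.astype(float)
    y = rows.astype(float)
    cx, cy = x.mean(), y.mean()
    # second central moments with the 1/12 pixel-area correction so a filled
    # disc of radius R yields semi-axes R (not the point-sample moments)
    mxx = ((x - cx) ** 2).mean() + 1.0 / 12.0
    myy = ((y - cy) ** 2).mean() + 1.0 / 12.0
    mxy = ((x - cx) * (y - cy)).mean()
    cov = np.array([[mxx, mxy], [mxy, myy]])
    evals, evecs = np.linalg.eigh(cov)
    # equivalent-ellipse semi-axes: lambda = axis^2 / 4
    axes = 2.0 * np.sqrt(np.maximum(evals, 0.0))
    order = np.argsort(axes)[::-1]
    a_px, b_px = axes[order]
    major = evecs[:, order[0]]
    theta = float(np.arctan2(major[1], major[0]))
    if theta <= -np.pi / 2:
        theta += np.pi
    elif theta > np.pi / 2:
        theta -= np.pi
    return SpheroidGeometry(
        center=(cx * pixel_size, cy * pixel_size),
        a=float(a_px * pixel_size),
        b=float(max(b_px, 1e-12) * pixel_size),
        phi0_axis=theta,
    )


def _fit_ellipse_points(points: np.ndarray) -> SpheroidGeometry:
    """Direct least-squares conic (Fitzgibbon) fit to boundary points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise GeometryError("need at least 5 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    # collinearity check via the rank of centered coordinates
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
        raise GeometryError("points are collinear")

    # scale for conditioning
    mx, my = x.mean(), y.mean()
    sx = x.std() or 1.0
    sy = y.std() or 1.0
    xs, ys = (x - mx) / sx, (y - my) / sy

    D1 = np.column_stack([xs**2, xs * ys, ys**2])
    D2 = np.column_stack([xs, ys, np.ones_like(xs)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    C1 = np.array([[0.0, 0.0, 2.0], [0.0, -1.0, 0.0], [2.0, 0.0, 0.0]])
    try:
        T = -np.linalg.solve(S3, S2.T)
        M = np.linalg.solve(C1, S1 + S2 @ T)
    except np.linalg.LinAlgError as exc:
        raise GeometryError("degenerate point configuration") from exc
    evals, evecs = np.linalg.eig(M)
    cond = 4.0 * evecs[0] * evecs[2] - evecs[1] ** 2
    good = np.where(np.real(cond) > 0)[0]
    if good.size == 0:
        raise GeometryError("no ellipse fits these points")
    a1 = np.real(evecs[:, good[0]])
    coef = np.concatenate([a1, T @ a1])  # A,B,C,D,E,F in scaled coords

    A, B, C, D, E, F = coef
    # undo scaling: substitute xs=(x-mx)/sx, ys=(y-my)/sy
    A2 = A / sx**2
    B2 = B / (sx * sy)
    C2 = C / sy**2
    D2_ = D / sx - 2 * A * mx / sx**2 - B * my / (sx * sy)
    E2 = E / sy - 2 * C * my / sy**2 - B * mx / (sx * sy)
    F2 = (
        F
        + A * mx**2 / sx**2
        + C * my**2 / sy**2
        + B * mx * my / (sx * sy)
        - D * mx / sx
        - E * my / sy
    )
    return _conic_to_geometry(A2, B2, C2, D2_, E2, F2)


def _conic_to_geometry(A, B, C, D, E, F) -> SpheroidGeometry:
    den = 4 * A * C - B**2
    if den <= 0:
        raise GeometryError("conic is not an ellipse")
    cx = (B * E - 2 * C * D) / den
    cy = (B * D - 2 * A * E) / den
    Fc = A * cx**2 + B * cx * cy + C * cy**2 + D * cx + E * cy + F
    M = np.array([[A, B / 2], [B / 2, C]])
    evals, evecs = np.linalg.eigh(M)
    axes2 = -Fc / evals
    if np.any(axes2 <= 0):
        raise GeometryError("conic is not a real ellipse")
    axes = np.sqrt(axes2)
    order = np.argsort(axes)[::-1]
    a_, b_ = axes[order]
    major = evecs[:, order[0]]
    theta = float(np.arctan2(major[1], major[0]))
    if theta <= -np.pi / 2:
        theta += np.pi
    elif theta > np.pi / 2:
        theta -= np.pi
    return SpheroidGeometry(center=(float(cx), float(cy)), a=float(a_), b=float(b_), phi0_axis=theta)


def fit_ellipse(
    core: np.ndarray | Sequence[Sequence[float]],
    *,
    pixel_size: float = 1.0,
) -> SpheroidGeometry:
    """Fit the spheroid-core ellipse from a binary mask or a point set.

    A 2D boolean/integer array is treated as a mask (moment-based equivalent
    ellipse, centroid + second central moments); an (N, 2) float array is
    treated as boundary points (direct least-squares conic fit).

    Parameters
    ----------
    core : ndarray
        Binary mask (rows x cols) or (N, 2) array of ``(x, y)`` points in µm.
    pixel_size : float
        µm per pixel, applied to mask input only.

    Raises
    ------
    GeometryError
        Empty mask, fewer than 5 points, or collinear points.
    """
    arr = np.asarray(core)
    if arr.ndim == 2 and arr.shape[1] == 2 and arr.dtype.kind == "f":
        return _fit_ellipse_points(arr)
    if arr.ndim == 2 and (arr.dtype == bool or arr.dtype.kind in "iu") and arr.shape[1] != 2:
        return _fit_ellipse_mask(arr, pixel_size)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return _fit_ellipse_points(arr.astype(float))
    if arr.ndim == 2:
        return _fit_ellipse_mask(arr, pixel_size)
    raise GeometryError(f"cannot interpret input of shape {arr.shape}")


# ---------------------------------------------------------------------------
# Distance index
# ---------------------------------------------------------------------------

def distance_index(
    position: Sequence[float] | np.ndarray,
    geom: SpheroidGeometry,
    normalization: Normalization = "major-axis",
) -> float | np.ndarray:
    """Distance Index of one or many cell positions.

    ``major-axis`` (the assay's literal definition): ``DI = d / a`` with ``d``
    the Euclidean distance to the spheroid center.  ``elliptical``:
    ``sqrt((x'/a)^2 + (y'/b)^2)`` in the ellipse-aligned frame, which is 1
    everywhere on the boundary rather than only at the major-axis vertices.
    """
    xy = np.asarray(position, dtype=float)
    single = xy.ndim == 1
    local = geom.to_local(xy)
    if normalization == "major-axis":
        di = np.hypot(local[:, 0], local[:, 1]) / geom.a
    elif normalization == "elliptical":
        di = np.sqrt((local[:, 0] / geom.a) ** 2 + (local[:, 1] / geom.b) ** 2)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return float(di[0]) if single else di


def _geom_for_frame(geoms, frame: int) -> SpheroidGeometry:
    if isinstance(geoms, SpheroidGeometry):
        return geoms
    try:
        return geoms[frame]
    except (KeyError, IndexError) as exc:
        raise KeyError(f"no geometry for frame {frame}") from exc


def delta_distance_index(
    track,
    geoms,
    normalization: Normalization = "major-axis",
) -> dict:
    """ΔDI = DI at the last spot minus DI at the first spot of a track.

    ``geoms`` is a single static :class:`SpheroidGeometry` or a mapping from
    frame index to geometry (per-frame refit).  Positive ΔDI means net
    outward motion.

    Returns a dict with ``value``, ``initial_DI`` and ``final_DI``.
    """
    spots = track.spots
    if len(spots) < 2:
        raise ValueError("ΔDI undefined for a track with fewer than 2 spots")
    first, last = spots[0], spots[-1]
    g0 = _geom_for_frame(geoms, first.frame)
    g1 = _geom_for_frame(geoms, last.frame)
    di0 = distance_index((first.x, first.y), g0, normalization)
    di1 = distance_index((last.x, last.y), g1, normalization)
    return {"value": di1 - di0, "initial_DI": di0, "final_DI": di1}


# ---------------------------------------------------------------------------
# Point-to-ellipse distance and compartments
# ---------------------------------------------------------------------------

def _dist_to_ellipse_first_quadrant(px: np.ndarray, py: np.ndarray, a: float, b: float) -> np.ndarray:
    """Distance from first-quadrant points to the ellipse x²/a²+y²/b²=1.

    Bisection on the auxiliary function of the normal equation (Eberly's
    robust formulation); works for interior and exterior points alike.
    """
    px = np.asarray(px, float)
    py = np.asarray(py, float)
    out = np.empty_like(px)

    on_x_axis = py < 1e-14
    on_y_axis = (px < 1e-14) & ~on_x_axis
    general = ~(on_x_axis | on_y_axis)

    if on_y_axis.any():
        out[on_y_axis] = np.abs(b - py[on_y_axis])
    if on_x_axis.any():
        x0 = px[on_x_axis]
        # nearest point may be off-axis when the point is inside the evolute
        crit = (a * a - b * b) / a
        near = np.empty_like(x0)
        inside_evolute = x0 < crit if a > b else np.zeros_like(x0, bool)
        if np.any(inside_evolute):
            xi = x0[inside_evolute]
            xe = a * a * xi / (a * a - b * b)
            ye = b * np.sqrt(np.maximum(1 - (xe / a) ** 2, 0.0))
            near[inside_evolute] = np.hypot(xi - xe, ye)
        near[~inside_evolute] = np.abs(x0[~inside_evolute] - a)
        out[on_x_axis] = near
    if general.any():
        x0 = px[general]
        y0 = py[general]
        # solve for t in F(t) = (a x0/(t+a^2))^2 + (b y0/(t+b^2))^2 - 1 = 0,
        # t in (-b^2, inf); F is decreasing
        t_lo = -(b * b) + b * y0  # F(t_lo) >= 0
        t_hi = np.maximum(a * x0 - a * a, b * y0 - b * b) + np.hypot(x0, y0) * max(a, b)
        for _ in range(200):
            t = 0.5 * (t_lo + t_hi)
            f = (a * x0 / (t + a * a)) ** 2 + (b * y0 / (t + b * b)) ** 2 - 1.0
            pos = f > 0
            t_lo = np.where(pos, t, t_lo)
            t_hi = np.where(pos, t_hi, t)
            if np.max(t_hi - t_lo) < 1e-12 * max(a, b):
                break
        t = 0.5 * (t_lo + t_hi)
        xe = a * a * x0 / (t + a * a)
        ye = b * b * y0 / (t + b * b)
        out[general] = np.hypot(x0 - xe, y0 - ye)
    return out


def point_to_boundary_distance(
    position: Sequence[float] | np.ndarray, geom: SpheroidGeometry
) -> float | np.ndarray:
    """Euclidean distance from point(s) to the ellipse boundary (always ≥ 0)."""
    xy = np.asarray(position, dtype=float)
    single = xy.ndim == 1
    local = geom.to_local(xy)
    d = _dist_to_ellipse_first_quadrant(
        np.abs(local[:, 0]), np.abs(local[:, 1]), geom.a, geom.b
    )
    return float(d[0]) if single else d


def classify_compartment(
    position: Sequence[float] | np.ndarray,
    geom: SpheroidGeometry,
    ring_width: float = DEFAULT_RING_WIDTH_UM,
) -> str | np.ndarray:
    """Assign *edge* / *core* / *outside* for one or many positions.

    Interior points whose distance to the spheroid-matrix interface is at
    most ``ring_width`` µm are *edge*; deeper interior points are *core*;
    points beyond the interface are *outside*.
    """
    xy = np.asarray(position, dtype=float)
    single = xy.ndim == 1
    inside = geom.contains(xy)
    d = point_to_boundary_distance(xy, geom)
    d = np.atleast_1d(d)
    labels = np.where(~inside, "outside", np.where(d <= ring_width, "edge", "core"))
    return str(labels[0]) if single else labels


# ---------------------------------------------------------------------------
# Sorting summary
# ---------------------------------------------------------------------------

def sorting_summary(
    cells: pd.DataFrame,
    geom: SpheroidGeometry,
    normalization: Normalization = "major-axis",
    compare: bool = True,
) -> dict:
    """Per-population Distance Index table with an optional pairwise test.

    Parameters
    ----------
    cells : DataFrame
        Columns ``x_um``, ``y_um``, ``population``.
    geom : SpheroidGeometry
    compare : bool
        When exactly two populations are present, run the two-sample
        decision-tree comparison from :mod:`spherosort.stats`.

    Returns
    -------
    dict with ``table`` (DataFrame indexed by population: n, median DI,
    quartiles) and ``comparison`` (a ComparisonResult or None).
    """
    from .stats import compare_groups

    di = distance_index(cells[["x_um", "y_um"]].to_numpy(float), geom, normalization)
    df = cells.assign(DI=di)
    rows = []
    groups = {}
    for pop, sub in df.groupby("population", sort=True):
        if len(sub) == 0:
            warnings.warn(f"population {pop!r} is empty; omitted")
            continue
        q1, med, q3 = np.percentile(sub["DI"], [25, 50, 75])
        rows.append(
            {"population": pop, "n": len(sub), "median_DI": med, "q1_DI": q1, "q3_DI": q3}
        )
        groups[pop] = sub["DI"].to_numpy()
    table = pd.DataFrame(rows).set_index("population")
    comparison = None
    if compare and len(groups) == 2:
        (ga, gb) = groups.values()
        comparison = compare_groups(ga, gb)
    return {"table": table, "normalization": normalization, "comparison": comparison}
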