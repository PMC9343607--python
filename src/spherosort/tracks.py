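"""Trajectory containers and I/O: TrackMate-dialect XML and tidy CSV.

Curation mirrors the assay pipeline: tracks shorter than 5 raw spots are
discarded, then interior gaps are closed by linear interpolation (interpolated
frames stay flagged), and each track is labelled *edge* or *core* from its
FIRST spot's distance to the spheroid-matrix interface.  The spot-count filter
is applied before interpolation, so interpolated spots never rescue a short
track.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lxml import etree

from .geometry import DEFAULT_RING_WIDTH_UM, SpheroidGeometry, classify_compartment

__all__ = [
    "Spot",
    "Track",
    "TrackValidationError",
    "read_tracks",
    "write_tracks_csv",
    "write_trackmate_xml",
    "tracks_to_dataframe",
    "filter_tracks",
    "close_gaps",
    "assign_initial_compartment",
]

DEFAULT_MIN_SPOTS = 5


class TrackValidationError(ValueError):
    """Raised for malformed or inconsistent track records."""


@dataclass(frozen=True)
class Spot:
    frame: int
    t: float  # min
    x: float  # µm
    y: float  # µm


@dataclass
class Track:
    """One cell's time-ordered positions.

    Frames are strictly increasing; after :func:`close_gaps` they are
    consecutive and every inserted frame index is recorded in
    ``interpolated_frames``.
    """

    track_id: str
    spots: list[Spot]
    population: str = ""
    initial_compartment: str | None = None
    interpolated_frames: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        frames = [s.frame for s in self.spots]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise TrackValidationError(
                f"track {self.track_id!r}: frames not strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.spots)

    @property
    def xy(self) -> np.ndarray:
        return np.array([(s.x, s.y) for s in self.spots], dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.spots], dtype=float)

    @property
    def frames(self) -> np.ndarray:
        return np.array([s.frame for s in self.spots], dtype=int)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _tracks_from_dataframe(df: pd.DataFrame, calibration: float, dt: float) -> list[Track]:
    required = {"track_id", "frame", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise TrackValidationError(f"missing columns: {sorted(missing)}")
    tracks: list[Track] = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy()
        if len(np.unique(frames)) != len(frames):
            dup = int(frames[np.argmax(np.diff(frames) == 0)])
            raise TrackValidationError(
                f"track {tid!r}: duplicate frame {dup}"
            )
        if "t" in sub.columns and sub["t"].notna().all():
            times = sub["t"].to_numpy(float)
            expected = frames * dt
            if not np.allclose(times, expected, rtol=1e-6, atol=1e-6):
                warnings.warn(
                    f"track {tid!r}: supplied times inconsistent with frame*dt; "
                    "overriding with frame*dt"
                )
                times = expected
        else:
            times = frames * dt
        pop = ""
        if "population" in sub.columns:
            vals = sub["population"].dropna().unique()
            pop = str(vals[0]) if len(vals) else ""
        spots = [
            Spot(int(f), float(t), float(x) * calibration, float(y) * calibration)
            for f, t, x, y in zip(frames, times, sub["x"], sub["y"])
        ]
        tracks.append(Track(track_id=str(tid), spots=spots, population=pop))
    return tracks


def _read_trackmate_xml(path, calibration: float, dt: float) -> list[Track]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise TrackValidationError(f"malformed TrackMate XML: {exc}") from exc
    root = tree.getroot()
    model = root.find("Model") if root.tag != "Model" else root
    if model is None:
        raise TrackValidationError("no <Model> element in TrackMate XML")

    spots_by_id: dict[str, tuple[int, float, float, float]] = {}
    allspots = model.find("AllSpots")
    if allspots is None:
        raise TrackValidationError("no <AllSpots> element")
    for spot in allspots.iter("Spot"):
        sid = spot.get("ID")
        try:
            frame = int(float(spot.get("FRAME")))
            x = float(spot.get("POSITION_X"))
            y = float(spot.get("POSITION_Y"))
        except (TypeError, ValueError) as exc:
            raise TrackValidationError(f"bad spot record ID={sid!r}") from exc
        if spot.get("POSITION_Z") not in (None, "0", "0.0"):
            warnings.warn("z coordinates present; dropped (analysis is planar)")
        t_attr = spot.get("POSITION_T")
        t = frame * dt
        if t_attr is not None:
            t_xml = float(t_attr)
            if abs(t_xml - t) > 1e-6 * max(1.0, abs(t)):
                warnings.warn(
                    f"spot {sid}: POSITION_T={t_xml} inconsistent with frame*dt={t}; "
                    "using frame*dt"
                )
            else:
                t = t_xml
        spots_by_id[sid] = (frame, t, x, y)

    alltracks = model.find("AllTracks")
    if alltracks is None:
        raise TrackValidationError("no <AllTracks> element")
    tracks: list[Track] = []
    for trk in alltracks.iter("Track"):
        tid = trk.get("TRACK_ID", trk.get("name", "?"))
        ids: set[str] = set()
        for edge in trk.iter("Edge"):
            for key in ("SPOT_SOURCE_ID", "SPOT_TARGET_ID"):
                sid = edge.get(key)
                if sid is None:
                    raise TrackValidationError(f"track {tid!r}: edge missing {key}")
                ids.add(sid)
        recs = sorted((spots_by_id[sid] for sid in ids if sid in spots_by_id))
        frames_seen: set[int] = set()
        spots = []
        for frame, t, x, y in recs:
            if frame in frames_seen:
                raise TrackValidationError(f"track {tid!r}: duplicate frame {frame}")
            frames_seen.add(frame)
            spots.append(Spot(frame, t, x * calibration, y * calibration))
        tracks.append(
            Track(
                track_id=str(tid),
                spots=spots,
                population=trk.get("POPULATION", ""),
            )
        )
    return tracks


def read_tracks(
    path,
    dialect: str = "csv",
    calibration: float = 1.0,
    dt: float = 10.0,
) -> list[Track]:
    """Read tracks from a TrackMate-dialect XML or a tidy CSV.

    Parameters
    ----------
    path : path-like
    dialect : {"trackmate-xml", "csv"}
    calibration : float
        µm per pixel; stored coordinates are multiplied by this.
    dt : float
        Frame interval in minutes; times become ``frame * dt`` unless the
        file carries consistent explicit times.
    """
    if dialect == "trackmate-xml":
        return _read_trackmate_xml(path, calibration, dt)
    if dialect == "csv":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise TrackValidationError(f"malformed CSV: {exc}") from exc
        rename = {"x_um": "x", "y_um": "y", "t_min": "t"}
        df = df.rename(columns=rename)
        return _tracks_from_dataframe(df, calibration, dt)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    """Canonical tidy representation, one row per spot."""
    rows = []
    for tr in tracks:
        for s in tr.spots:
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": s.frame,
                    "t_min": s.t,
                    "x_um": s.x,
                    "y_um": s.y,
                    "population": tr.population,
                    "initial_compartment": tr.initial_compartment or "",
                    "interpolated": s.frame in tr.interpolated_frames,
                }
            )
    return pd.DataFrame(rows)


def write_tracks_csv(tracks: list[Track], path) -> None:
    tracks_to_dataframe(tracks).to_csv(path, index=False)


def write_trackmate_xml(tracks: list[Track], path, *, drop: dict | None = None) -> None:
    """Write tracks as TrackMate-dialect XML (``<Model><AllSpots>/<AllTracks>``).

    ``drop`` optionally maps ``track_id -> iterable of frame indices`` whose
    spots are omitted, to fabricate gap fixtures.
    """
    drop = {k: set(v) for k, v in (drop or {}).items()}
    root = etree.Element("TrackMate", version="7.0.0")
    model = etree.SubElement(root, "Model", spatialunits="pixel", timeunits="frame")
    allspots = etree.SubElement(model, "AllSpots")
    alltracks = etree.SubElement(model, "AllTracks")

    sid = 0
    frame_elements: dict[int, etree._Element] = {}
    for tr in tracks:
        dropped = drop.get(tr.track_id, set())
        kept = [s for s in tr.spots if s.frame not in dropped]
        ids = []
        for s in kept:
            frame_el = frame_elements.get(s.frame)
            if frame_el is None:
                frame_el = etree.SubElement(
                    allspots, "SpotsInFrame", frame=str(s.frame)
                )
                frame_elements[s.frame] = frame_el
            etree.SubElement(
                frame_el,
                "Spot",
                ID=str(sid),
                name=f"ID{sid}",
                FRAME=str(s.frame),
                POSITION_X=repr(s.x),
                POSITION_Y=repr(s.y),
                POSITION_Z="0",
                POSITION_T=repr(s.t),
                QUALITY="1.0",
            )
            ids.append(sid)
            sid += 1
        attrs = {
            "name": f"Track_{tr.track_id}",
            "TRACK_ID": str(tr.track_id),
            "NUMBER_SPOTS": str(len(kept)),
        }
        if tr.population:
            attrs["POPULATION"] = tr.population  # dialect extension
        trk = etree.SubElement(alltracks, "Track", **attrs)
        for a, b in zip(ids, ids[1:]):
            etree.SubElement(
                trk, "Edge", SPOT_SOURCE_ID=str(a), SPOT_TARGET_ID=str(b)
            )
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def filter_tracks(tracks: list[Track], min_spots: int = DEFAULT_MIN_SPOTS) -> list[Track]:
    """Keep tracks with at least ``min_spots`` raw (pre-interpolation) spots."""
    return [t for t in tracks if len(t.spots) >= min_spots]


def close_gaps(track: Track) -> Track:
    """Fill every missing interior frame by linear interpolation.

    The first and last spots are never altered; inserted frames are flagged
    in ``interpolated_frames``.  Times of inserted spots follow the linear
    parameterization between the bracketing spots.
    """
    spots = track.spots
    if len(spots) < 2:
        return track
    new_spots: list[Spot] = [spots[0]]
    interpolated = set(track.interpolated_frames)
    for a, b in zip(spots, spots[1:]):
        span = b.frame - a.frame
        for k in range(1, span):
            w = k / span
            new_spots.append(
                Spot(
                    frame=a.frame + k,
                    t=a.t + w * (b.t - a.t),
                    x=a.x + w * (b.x - a.x),
                    y=a.y + w * (b.y - a.y),
                )
            )
            interpolated.add(a.frame + k)
        new_spots.append(b)
    return replace(track, spots=new_spots, interpolated_frames=interpolated)


def assign_initial_compartment(
    track: Track,
    geom: SpheroidGeometry,
    ring_width: float = DEFAULT_RING_WIDTH_UM,
) -> Track:
    """Label a track *edge* or *core* from its FIRST spot only.

    A first spot within ``ring_width`` µm of the spheroid-matrix interface
    (including points outside the core ellipse) is *edge*; deeper interior
    points are *core*.  Later compartment switches do not relabel the track.
    """
    first = track.spots[0]
    label = classify_compartment((first.x, first.y), geom, ring_width)
    if label == "outside":
        label = "edge"  # matrix-side cells sit at the interface layer
    return replace(track, initial_compartment=label)
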