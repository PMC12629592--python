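"""Readers, writers and kymograph construction.

Movies are multi-page TIFF stacks with calibration (nm/pixel, s/frame)
and channel roles supplied by configuration rather than embedded in the
file.  Kymographs (time x axial position images) are built by sampling
each frame along a polyline ROI with linear interpolation and averaging
over a perpendicular width.  Event tables round-trip through versioned
CSV.  Internally coordinates are 0-based pixel indices; everything
reported to the user is physical (nm, s).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage

from .kinetics import EventRecord

__all__ = [
    "MovieStack",
    "Kymograph",
    "LineROI",
    "read_movie",
    "write_movie",
    "build_kymograph",
    "write_event_table",
    "read_event_table",
    "load_config",
    "save_config",
    "config_hash",
]

EVENT_SCHEMA = "tiptrack-events v1"
EVENT_COLUMNS = [
    "id",
    "microtubule_id",
    "region",
    "start_time",
    "dwell",
    "mean_intensity",
    "mean_position",
    "flags",
]


@dataclass
class MovieStack:
    """A multi-channel fluorescence movie with calibration.

    ``pixels`` has shape (channel, frame, row, column); ``channels``
    names the role of each channel plane (e.g. "microtubule",
    "molecule").
    """

    pixels: np.ndarray
    channels: tuple[str, ...]
    pixel_size: float  # nm per pixel
    frame_interval: float  # s per frame

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError("pixels must be (channel, frame, row, column)")
        if self.pixels.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.pixels.shape[0]} channel planes but "
                f"{len(self.channels)} channel roles"
            )

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[1]

    def channel(self, role: str) -> np.ndarray:
        """Frames of one channel by role; raises if the role is absent."""
        try:
            return self.pixels[self.channels.index(role)]
        except ValueError:
            raise KeyError(
                f"channel role {role!r} not present; have {self.channels}"
            ) from None


@dataclass
class Kymograph:
    """Time x axial-position intensities sampled along a microtubule."""

    pixels: np.ndarray  # (channel, frame, axial sample)
    channels: tuple[str, ...]
    axial_positions: np.ndarray  # nm from the first ROI vertex
    pixel_size: float
    frame_interval: float

    @property
    def times(self) -> np.ndarray:
        return self.frame_interval * np.arange(self.pixels.shape[1])

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.pixels[self.channels.index(role)]
        except ValueError:
            raise KeyError(
                f"channel role {role!r} not present; have {self.channels}"
            ) from None


@dataclass
class LineROI:
    """Polyline region of interest in 0-based pixel coordinates.

    ``vertices`` is a sequence of (row, col) points; ``width`` is the
    perpendicular averaging width in pixels.
    """

    vertices: np.ndarray
    width: int = 1

    def __post_init__(self) -> None:
        self.vertices = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        if self.vertices.shape[0] < 2 or self.vertices.shape[1] != 2:
            raise ValueError("ROI needs >= 2 (row, col) vertices")
        if self.width < 1:
            raise ValueError("width must be >= 1")


def write_movie(path: str | Path, movie: MovieStack) -> None:
    """Write a movie as a multi-page TIFF (channel-major page order)."""
    pixels = movie.pixels.astype(np.float32, copy=False)
    meta = {
        "channels": list(movie.channels),
        "pixel_size": movie.pixel_size,
        "frame_interval": movie.frame_interval,
        "shape": list(pixels.shape),
    }
    tifffile.imwrite(str(path), pixels, metadata=meta, photometric="minisblack")


def read_movie(path: str | Path, config: dict | None = None) -> MovieStack:
    """Read a multi-page TIFF into a :class:`MovieStack`.

    Calibration and channel roles come from ``config`` (keys
    ``channels``, ``pixel_size``, ``frame_interval``) when given,
    otherwise from the metadata written by :func:`write_movie`.
    """
    with tifffile.TiffFile(str(path)) as tf:
        pixels = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    cfg = dict(meta)
    if config:
        cfg.update(config)
    for key in ("channels", "pixel_size", "frame_interval"):
        if key not in cfg:
            raise ValueError(f"movie config missing {key!r}")
    channels = tuple(cfg["channels"])
    if pixels.ndim == 3:
        pixels = pixels[np.newaxis]
    if pixels.ndim != 4:
        raise ValueError(f"expected a 3D or 4D stack, found shape {pixels.shape}")
    if pixels.shape[0] != len(channels):
        raise ValueError(
            f"channel mismatch: file has {pixels.shape[0]} planes, "
            f"config names {len(channels)} roles {channels}"
        )
    return MovieStack(
        pixels=pixels,
        channels=channels,
        pixel_size=float(cfg["pixel_size"]),
        frame_interval=float(cfg["frame_interval"]),
    )


def _sample_points(roi: LineROI) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Arc-length-ordered sample points (~1 px spacing) and normals."""
    verts = roi.vertices
    pts: list[np.ndarray] = []
    normals: list[np.ndarray] = []
    for a, b in zip(verts[:-1], verts[1:]):
        seg = b - a
        length = float(np.hypot(*seg))
        if length == 0:
            continue
        n_samp = max(int(np.ceil(length)), 1)
        t = np.linspace(0.0, 1.0, n_samp, endpoint=False)
        pts.append(a + t[:, None] * seg)
        normal = np.array([-seg[1], seg[0]]) / length
        normals.append(np.tile(normal, (n_samp, 1)))
    pts.append(verts[-1:])
    last_seg = verts[-1] - verts[-2]
    last_len = float(np.hypot(*last_seg))
    normals.append((np.array([[-last_seg[1], last_seg[0]]]) / last_len))
    points = np.concatenate(pts)
    norms = np.concatenate(normals)
    arclen = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(points, axis=0).T))])
    return points, norms, arclen


def build_kymograph(movie: MovieStack, roi: LineROI) -> Kymograph:
    """Sample each frame along the ROI polyline into a kymograph.

    Intensities are linearly interpolated at ~1 px spacing along the
    line and averaged over ``roi.width`` perpendicular offsets.  The
    axial origin is the first vertex.
    """
    points, normals, arclen = _sample_points(roi)
    h, w = movie.pixels.shape[-2:]
    if (points < -0.5).any() or (points[:, 0] > h - 0.5).any() or (
        points[:, 1] > w - 0.5
    ).any():
        raise ValueError("ROI extends outside the image")
    offsets = np.arange(roi.width) - (roi.width - 1) / 2.0
    # (offset, sample, 2) coordinate grid
    coords = points[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    rows = coords[..., 0].ravel()
    cols = coords[..., 1].ravel()

    n_ch, n_fr = movie.pixels.shape[:2]
    out = np.empty((n_ch, n_fr, points.shape[0]), dtype=float)
    for c in range(n_ch):
        for f in range(n_fr):
            vals = ndimage.map_coordinates(
                movie.pixels[c, f].astype(float),
                np.vstack([rows, cols]),
                order=1,
                mode="nearest",
            ).reshape(offsets.size, points.shape[0])
            out[c, f] = vals.mean(axis=0)
    return Kymograph(
        pixels=out,
        channels=movie.channels,
        axial_positions=arclen * movie.pixel_size,
        pixel_size=movie.pixel_size,
        frame_interval=movie.frame_interval,
    )


def write_event_table(events: list[EventRecord], path: str | Path) -> None:
    """Write events as versioned CSV (first line carries the schema tag)."""
    rows = [
        {
            "id": ev.id,
            "microtubule_id": ev.microtubule_id,
            "region": ev.region if ev.region is not None else "",
            "start_time": ev.start_time,
            "dwell": ev.dwell,
            "mean_intensity": ev.mean_intensity,
            "mean_position": ev.mean_position,
            "flags": ";".join(ev.flags),
        }
        for ev in events
    ]
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"# {EVENT_SCHEMA}\n")
        df.to_csv(fh, index=False)


def read_event_table(path: str | Path) -> list[EventRecord]:
    """Read a versioned event CSV back into :class:`EventRecord` objects."""
    with open(path) as fh:
        header = fh.readline().strip()
        if header != f"# {EVENT_SCHEMA}":
            raise ValueError(
                f"unknown event-table schema {header!r}; expected '# {EVENT_SCHEMA}'"
            )
        df = pd.read_csv(fh, dtype={"region": "string", "flags": "string"})
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns {sorted(missing)}")
    events: list[EventRecord] = []
    for i, row in df.iterrows():
        try:
            region = row["region"] if pd.notna(row["region"]) else None
            flags = (
                tuple(str(row["flags"]).split(";"))
                if pd.notna(row["flags"]) and str(row["flags"])
                else ()
            )
            events.append(
                EventRecord(
                    id=int(row["id"]),
                    microtubule_id=int(row["microtubule_id"]),
                    region=region,
                    start_time=float(row["start_time"]),
                    dwell=float(row["dwell"]),
                    mean_intensity=float(row["mean_intensity"]),
                    mean_position=float(row["mean_position"]),
                    flags=flags,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed event table row {i}: {exc}") from exc
    return events


def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON configuration file into a dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(config: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=True))


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration, for run logs."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
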