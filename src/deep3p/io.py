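"""TIFF + JSON-sidecar image I/O and ROI CSV round-tripping.

Stacks and movies travel as multi-page TIFF (16-bit unsigned counts)
with a JSON sidecar of the same stem carrying the metadata the arrays
cannot: ``{pixel_size_um, z_positions_um, pulses_per_pixel, channel}``
for stacks, ``{frame_rate_hz, pixel_size_um, depth_um}`` for movies.
ROIs travel as CSV rows ``label, slice, kind, coordinates`` with
coordinates encoded ``"r0 c0;r1 c1;..."`` (0-based row, col).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import tifffile

from .sbr import ImageStack, Roi
from .traces import ActivityMovie

__all__ = [
    "write_stack",
    "read_stack",
    "write_movie",
    "read_movie",
    "write_rois_csv",
    "read_rois_csv",
]


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def write_stack(path, stack: ImageStack) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.voxels, dtype=np.uint16))
    meta = {
        "pixel_size_um": stack.pixel_size_um,
        "z_positions_um": list(map(float, stack.z_positions_um)),
        "pulses_per_pixel": stack.pulses_per_pixel,
        "channel": stack.channel,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_stack(path) -> ImageStack:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    return ImageStack(
        voxels=tifffile.imread(path),
        pixel_size_um=meta["pixel_size_um"],
        z_positions_um=np.asarray(meta["z_positions_um"], dtype=float),
        channel=meta.get("channel", ""),
        pulses_per_pixel=meta.get("pulses_per_pixel", 1),
    )


def write_movie(path, movie: ActivityMovie) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(movie.frames, dtype=np.uint16))
    meta = {
        "frame_rate_hz": movie.frame_rate_hz,
        "pixel_size_um": movie.pixel_size_um,
        "depth_um": movie.depth_um,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_movie(path) -> ActivityMovie:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    return ActivityMovie(
        frames=tifffile.imread(path),
        frame_rate_hz=meta["frame_rate_hz"],
        pixel_size_um=meta.get("pixel_size_um", 1.0),
        depth_um=meta.get("depth_um", 0.0),
    )


def _encode_coords(coords: np.ndarray) -> str:
    return ";".join(f"{r:g} {c:g}" for r, c in coords)


def _decode_coords(text: str) -> np.ndarray:
    pairs = [p.split() for p in text.split(";") if p.strip()]
    return np.asarray([[float(r), float(c)] for r, c in pairs])


def write_rois_csv(path, rois: list[Roi]) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "slice", "kind", "coordinates"])
        for roi in rois:
            writer.writerow(
                [roi.label, roi.slice_index, roi.kind, _encode_coords(roi.coordinates)]
            )
    return path


def read_rois_csv(path) -> list[Roi]:
    rois = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rois.append(
                Roi(
                    kind=row["kind"],
                    coordinates=_decode_coords(row["coordinates"]),
                    slice_index=int(row["slice"]),
                    label=row["label"],
                )
            )
    return rois
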