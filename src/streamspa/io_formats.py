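"""Readers and writers for MRC images/stacks, STAR metadata tables and EPU XML.

Conventions used throughout the package:

* Particle coordinates are 0-based pixel indices of the particle box center,
  with the origin at the top-left of the array as stored, i.e. ``image[y, x]``
  (x = column, y = row).
* Defocus is carried in micrometres (underfocus positive) in in-memory types
  and converted to Angstroms only in the STAR writers (RELION convention);
  the conversion is isolated here.
* STAR files use ``data_`` blocks; tabular blocks carry a ``loop_`` with
  underscore-prefixed tags, scalar blocks carry tag/value pairs.
"""

from __future__ import annotations

import re
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import mrcfile
import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when a file does not conform to its declared format."""


class MetadataError(ValueError):
    """Raised when required metadata is missing from a file."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class MovieStack:
    """Ordered frames of a dose-fractionated exposure.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, ny, nx)
        Electron counts per frame.
    pixel_size : float
        Physical pixel size in Angstrom/pixel.
    voltage_kV : float
        Acceleration voltage in kV.
    dose_per_frame : float, optional
        Accumulated exposure per frame in electrons/A^2; required for
        dose weighting, optional otherwise.
    """

    frames: np.ndarray
    pixel_size: float
    voltage_kV: float = 300.0
    dose_per_frame: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3D (n_frames, ny, nx) array")
        if self.frames.shape[0] < 3:
            raise ValueError("a movie needs at least 3 frames")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class BeamShiftRecord:
    """Beam-shift metadata of one movie in an EPU session."""

    movie_id: str
    shift_x: float
    shift_y: float
    location_id: str

    def __post_init__(self) -> None:
        if not self.location_id:
            raise ValueError("location_id must be non-empty")


# ---------------------------------------------------------------------------
# MRC
# ---------------------------------------------------------------------------


def read_movie(path) -> MovieStack:
    """Read an MRC stack as a movie.

    The header pixel size and (when present in extended metadata) voltage
    are propagated; a single-image file is rejected since it cannot be
    motion corrected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with mrcfile.open(path, permissive=False) as mrc:
            data = np.asarray(mrc.data, dtype=np.float64)
            psize = float(mrc.voxel_size.x)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt header / truncated data
        raise FormatError(f"cannot read MRC file {path}: {exc}") from exc
    if data.ndim == 2 or (data.ndim == 3 and data.shape[0] < 3):
        raise FormatError(f"{path} is not a movie (needs >= 3 frames)")
    if data.ndim != 3:
        raise FormatError(f"{path}: unsupported dimensionality {data.ndim}")
    if psize <= 0:
        psize = 1.0
    return MovieStack(frames=data, pixel_size=psize)


def write_movie(stack: MovieStack, path) -> None:
    """Write a MovieStack to an MRC stack (mode 2, float32)."""
    with mrcfile.new(Path(path), overwrite=True) as mrc:
        mrc.set_data(stack.frames.astype(np.float32))
        mrc.voxel_size = stack.pixel_size


def write_micrograph(image: np.ndarray, path, pixel_size: float) -> None:
    """Write a single 2D image as MRC with the given pixel size (A/px)."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("micrograph must be 2D")
    if not np.all(np.isfinite(image)):
        raise ValueError("micrograph contains non-finite values")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    with mrcfile.new(Path(path), overwrite=True) as mrc:
        mrc.set_data(image.astype(np.float32))
        mrc.voxel_size = pixel_size


def read_micrograph(path) -> tuple[np.ndarray, float]:
    """Read a single 2D MRC image; returns (image, pixel_size)."""
    try:
        with mrcfile.open(Path(path), permissive=False) as mrc:
            data = np.asarray(mrc.data, dtype=np.float64)
            psize = float(mrc.voxel_size.x)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot read MRC file {path}: {exc}") from exc
    if data.ndim != 2:
        raise FormatError(f"{path} is not a single 2D image")
    return data, (psize if psize > 0 else 1.0)


# ---------------------------------------------------------------------------
# STAR
# ---------------------------------------------------------------------------

def write_star(blocks: Mapping[str, "pd.DataFrame | Mapping"], path) -> None:
    """Write named blocks to a STAR file.

    DataFrame values become ``loop_`` tables; mappings become scalar
    tag/value blocks. Tags are written with a leading underscore.
    """
    lines: list[str] = []
    for name, block in blocks.items():
        lines.append(f"data_{name}")
        lines.append("")
        if isinstance(block, pd.DataFrame):
            lines.append("loop_")
            for i, col in enumerate(block.columns, start=1):
                lines.append(f"_{col} #{i}")
            for _, row in block.iterrows():
                lines.append(" ".join(_star_fmt(v) for v in row))
        else:
            for tag, value in block.items():
                lines.append(f"_{tag} {_star_fmt(value)}")
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def _star_fmt(value) -> str:
    if isinstance(value, (float, np.floating)):
        return f"{value:.6g}" if value == 0 else f"{value:.12g}"
    return str(value)


def read_star(path) -> dict[str, "pd.DataFrame | dict"]:
    """Parse a STAR file into a dict of DataFrames (loop_) / dicts (scalars)."""
    blocks: dict[str, pd.DataFrame | dict] = {}
    name = None
    mode = None  # None | "scalar" | "loop-tags" | "loop-rows"
    tags: list[str] = []
    rows: list[list[str]] = []
    scalars: dict[str, str] = {}

    def _flush():
        nonlocal tags, rows, scalars
        if name is None:
            return
        if tags:
            df = pd.DataFrame(rows, columns=tags)
            for col in df.columns:
                converted = pd.to_numeric(df[col], errors="coerce")
                if not converted.isna().any():
                    df[col] = converted
            blocks[name] = df
        else:
            out: dict = {}
            for k, v in scalars.items():
                try:
                    out[k] = float(v) if ("." in v or "e" in v.lower()) else int(v)
                except ValueError:
                    out[k] = v
            blocks[name] = out
        tags, rows, scalars = [], [], {}

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("data_"):
            _flush()
            name = line[len("data_"):]
            mode = "scalar"
        elif line == "loop_":
            mode = "loop-tags"
        elif line.startswith("_"):
            if mode == "loop-tags":
                tags.append(line.split()[0][1:])
            else:
                parts = line.split(None, 1)
                scalars[parts[0][1:]] = parts[1] if len(parts) > 1 else ""
        else:
            mode = "loop-rows"
            row = line.split()
            if tags and len(row) == len(tags):
                rows.append(row)
    _flush()
    return blocks


# Motion-model STAR layout: one scalar block of model shape metadata, one
# loop_ of per-frame global shifts, one loop_ of polynomial coefficients in
# the documented order (index = position in the trivariate monomial basis).

def write_motion_star(model, path) -> None:
    """Write a fitted deformation model to a per-micrograph STAR file."""
    if model.coeffs_x is None or model.global_traj is None:
        raise ValueError("deformation model is not fitted")
    n = len(model.global_traj.shifts)
    general = {
        "motionModelVersion": 1,
        "frameCount": n,
        "polynomialOrder": 3,
        "coefficientCount": len(model.coeffs_x),
    }
    shifts = pd.DataFrame(
        {
            "frameIndex": np.arange(n),
            "shiftX": model.global_traj.shifts[:, 0],
            "shiftY": model.global_traj.shifts[:, 1],
            "frameWeight": (model.weights.w if model.weights is not None
                            else np.full(n, 1.0 / n)),
        }
    )
    coeffs = pd.DataFrame(
        {
            "coeffIndex": np.arange(len(model.coeffs_x)),
            "coeffX": model.coeffs_x,
            "coeffY": model.coeffs_y,
        }
    )
    write_star(
        {"general": general, "global_shifts": shifts, "local_motion_model": coeffs},
        path,
    )


def read_motion_star(path) -> dict:
    blocks = read_star(path)
    for key in ("general", "global_shifts", "local_motion_model"):
        if key not in blocks:
            raise FormatError(f"{path}: missing STAR block data_{key}")
    return blocks


def write_particles_star(particles: Sequence, path, ctf_params=None,
                         optics_groups=None, pixel_size: float | None = None) -> None:
    """Write picked particles (plus optional per-particle CTF) to STAR.

    ``ctf_params`` is an optional sequence of CtfParams aligned with
    ``particles``; defocus is converted from um to A here and nowhere else.
    ``optics_groups`` is an optional sequence of integers.
    """
    cols: dict[str, list] = {"rlnCoordinateX": [], "rlnCoordinateY": [],
                             "rlnAutopickFigureOfMerit": []}
    if ctf_params is not None:
        cols.update({"rlnDefocusU": [], "rlnDefocusV": [],
                     "rlnDefocusAngle": [], "rlnPhaseShift": []})
    if optics_groups is not None:
        cols["rlnOpticsGroup"] = []
    if len(particles) == 0:
        warnings.warn("writing header-only particle table (no particles)")
    for i, p in enumerate(particles):
        cols["rlnCoordinateX"].append(float(p.x))
        cols["rlnCoordinateY"].append(float(p.y))
        cols["rlnAutopickFigureOfMerit"].append(float(p.score))
        if ctf_params is not None:
            c = ctf_params[i]
            cols["rlnDefocusU"].append(c.dfx * 1e4)   # um -> A
            cols["rlnDefocusV"].append(c.dfy * 1e4)
            cols["rlnDefocusAngle"].append(c.ang_ast)
            cols["rlnPhaseShift"].append(np.degrees(c.phshift))
        if optics_groups is not None:
            cols["rlnOpticsGroup"].append(int(optics_groups[i]))
    blocks: dict = {}
    if pixel_size is not None:
        blocks["optics"] = {"rlnImagePixelSize": pixel_size}
    blocks["particles"] = pd.DataFrame(cols)
    write_star(blocks, path)


# ---------------------------------------------------------------------------
# EPU metadata
# ---------------------------------------------------------------------------

#: Default EPU movie/xml naming pattern. Groups ``id1``/``id2`` are the
#: template-position identifiers that distinguish shots within a hole.
EPU_FILENAME_RE = re.compile(
    r"FoilHole_(?P<hole>\d+)_Data_(?P<id1>\d+)_(?P<id2>\d+)"
)


def parse_epu_metadata(xml_path, movie_filename: str | None = None,
                       filename_re: re.Pattern = EPU_FILENAME_RE) -> BeamShiftRecord:
    """Extract the beam shift and shot-location identifier of one EPU movie.

    The beam shift is read from the session XML; the location identifier
    (which shot of a multi-shot hole template the movie belongs to) is
    parsed from the EPU filename. An unmatched filename degrades to using
    the whole stem as identifier, with a warning.
    """
    xml_path = Path(xml_path)
    if movie_filename is None:
        movie_filename = xml_path.name
    try:
        root = ET.parse(xml_path).getroot()
    except ET.ParseError as exc:
        raise MetadataError(f"cannot parse EPU XML {xml_path}: {exc}") from exc

    shift = _find_beam_shift(root)
    if shift is None:
        raise MetadataError(f"{xml_path}: no BeamShift element found")

    stem = Path(movie_filename).stem
    m = filename_re.search(stem)
    if m:
        location_id = f"{m.group('id1')}_{m.group('id2')}"
    else:
        warnings.warn(
            f"EPU filename {movie_filename!r} does not match the expected "
            "pattern; using the whole name as location identifier"
        )
        location_id = stem
    return BeamShiftRecord(movie_id=stem, shift_x=shift[0], shift_y=shift[1],
                           location_id=location_id)


def _find_beam_shift(root: ET.Element) -> tuple[float, float] | None:
    # namespace-agnostic search: tag local name "BeamShift" with numeric
    # children whose local names end in "x"/"y"
    for elem in root.iter():
        if elem.tag.split("}")[-1] == "BeamShift":
            x = y = None
            for child in elem:
                local = child.tag.split("}")[-1].lstrip("_").lower()
                if local == "x":
                    x = float(child.text)
                elif local == "y":
                    y = float(child.text)
            if x is not None and y is not None:
                return x, y
    return None
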