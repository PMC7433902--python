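"""Readers and writers for image stacks, polygon ROIs and results tables.

Coordinate convention, used everywhere in the package: 0-based pixels,
``x`` is the column index, ``y`` is the row index, origin at the top-left,
pixel centers at integer coordinates.  Image stacks are indexed
``(channel, z, y, x)``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import LinearRing

log = logging.getLogger("centroasym")

#: xy sampling fallback (um/px) when TIFF metadata carries no pixel size;
#: typical reconstructed 3D-SIM sampling.
DEFAULT_PIXEL_SIZE_XY = 0.041
#: optical section spacing (um) of the acquisition this package targets.
DEFAULT_Z_STEP = 0.125

MITOTIC_STAGES = frozenset(
    {"interphase", "prophase", "prometaphase", "metaphase", "anaphase", "telophase"}
)
CENTROSOME_POSITIONS = frozenset({"apical", "basal", "unknown"})

ROI_COLUMNS = ["cell_id", "centriole_id", "frame", "z_ref", "vertex_index", "x", "y"]


@dataclass
class ImageStack:
    """Multi-channel fluorescence stack in arbitrary intensity units.

    ``pixels`` has shape ``(n_channels, n_z, n_y, n_x)``; all channels share
    the spatial grid.  Intensities must be non-negative.
    """

    pixels: np.ndarray
    channel_names: list[str]
    pixel_size_xy: float = DEFAULT_PIXEL_SIZE_XY
    z_step: float = DEFAULT_Z_STEP
    time_index: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError(f"pixels must be (C, Z, Y, X), got ndim={self.pixels.ndim}")
        if len(self.channel_names) != self.pixels.shape[0]:
            raise ValueError("channel_names length must match the channel axis")
        if self.pixel_size_xy <= 0:
            raise ValueError("pixel_size_xy must be positive")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.pixels.shape

    def channel_index(self, channel: str) -> int:
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(
                f"channel {channel!r} not in stack channels {self.channel_names}"
            ) from None

    def plane(self, channel: str, z_ref: int | str = "max-projection") -> np.ndarray:
        """2D measurement plane: a single z section or the max projection."""
        c = self.channel_index(channel)
        if z_ref == "max-projection":
            return self.pixels[c].max(axis=0)
        z = int(z_ref)
        if not 0 <= z < self.pixels.shape[1]:
            raise IndexError(f"z_ref {z} outside 0..{self.pixels.shape[1] - 1}")
        return self.pixels[c, z]


@dataclass
class PolygonROI:
    """A centriole's measurement contour as ordered XY vertices (pixels)."""

    cell_id: str
    centriole_id: str
    frame: int = 0
    z_ref: int | str = "max-projection"
    vertices: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array of (x, y)")
        if len(self.vertices) < 3:
            raise ValueError(
                f"ROI {self.centriole_id!r}: a polygon needs >= 3 vertices, "
                f"got {len(self.vertices)}"
            )

    @property
    def is_simple(self) -> bool:
        """True when the contour does not self-intersect."""
        return LinearRing(self.vertices).is_simple

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the vertex set."""
        return (
            float(self.vertices[:, 0].min()),
            float(self.vertices[:, 1].min()),
            float(self.vertices[:, 0].max()),
            float(self.vertices[:, 1].max()),
        )


@dataclass
class CellMetadata:
    cell_id: str
    genotype: str = "wild-type"
    stage: str = "interphase"
    centrosome_position: str = "unknown"

    def __post_init__(self) -> None:
        if self.stage not in MITOTIC_STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {sorted(MITOTIC_STAGES)}")
        if self.centrosome_position not in CENTROSOME_POSITIONS:
            raise ValueError(f"unknown centrosome position {self.centrosome_position!r}")


# ---------------------------------------------------------------------------
# image stacks


def write_stack(path, stack: ImageStack) -> None:
    """Write a stack as TIFF with package metadata in the image description."""
    meta = {
        "channel_names": stack.channel_names,
        "pixel_size_xy": stack.pixel_size_xy,
        "z_step": stack.z_step,
        "time_index": stack.time_index,
        "axes": "CZYX",
    }
    tifffile.imwrite(
        str(path), stack.pixels, description=json.dumps(meta), photometric="minisblack"
    )


def read_stack(path, pixel_size_xy: float | None = None) -> ImageStack:
    """Read a TIFF/OME-TIFF stack.

    Falls back to ``ch0..chN`` channel labels (with a logged warning) and the
    configured/default pixel size when the file carries no metadata.
    """
    try:
        with tifffile.TiffFile(str(path)) as tif:
            series = tif.series[0]
            pixels = series.asarray()
            description = tif.pages[0].description or ""
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read image stack {path}: {exc}") from exc

    meta: dict = {}
    if description:
        try:
            parsed = json.loads(description)
            if isinstance(parsed, dict):
                meta = parsed
        except (json.JSONDecodeError, UnicodeDecodeError):
            pass

    if pixels.ndim == 2:
        pixels = pixels[np.newaxis, np.newaxis]
    elif pixels.ndim == 3:
        # foreign 3D TIFF: lead axis is channels unless the file says otherwise
        axes = meta.get("axes") or getattr(series, "axes", "")
        if axes.upper().startswith("Z"):
            pixels = pixels[np.newaxis]
        else:
            pixels = pixels[:, np.newaxis]
    elif pixels.ndim != 4:
        raise OSError(f"cannot read image stack {path}: unsupported dimensionality {pixels.ndim}")

    names = meta.get("channel_names")
    if not names or len(names) != pixels.shape[0]:
        names = [f"ch{i}" for i in range(pixels.shape[0])]
        log.warning("%s: no channel labels in metadata, using %s", path, names)

    return ImageStack(
        pixels=pixels,
        channel_names=list(names),
        pixel_size_xy=float(meta.get("pixel_size_xy") or pixel_size_xy or DEFAULT_PIXEL_SIZE_XY),
        z_step=float(meta.get("z_step") or DEFAULT_Z_STEP),
        time_index=meta.get("time_index"),
    )


# ---------------------------------------------------------------------------
# polygon ROIs


def write_rois(path, rois: list[PolygonROI]) -> None:
    rows = []
    for roi in rois:
        for i, (x, y) in enumerate(roi.vertices):
            rows.append(
                dict(cell_id=roi.cell_id, centriole_id=roi.centriole_id,
                     frame=roi.frame, z_ref=roi.z_ref, vertex_index=i, x=x, y=y)
            )
    pd.DataFrame(rows, columns=ROI_COLUMNS).to_csv(path, index=False)


def read_rois(path) -> list[PolygonROI]:
    """Read contour CSV (one row per vertex; see ``ROI_COLUMNS``)."""
    df = pd.read_csv(path)
    missing = set(ROI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing ROI columns {sorted(missing)}")
    rois = []
    for (cell_id, centriole_id, frame, z_ref), grp in df.groupby(
        ["cell_id", "centriole_id", "frame", "z_ref"], sort=False
    ):
        grp = grp.sort_values("vertex_index")
        idx = grp["vertex_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise ValueError(
                f"centriole {centriole_id!r}: vertex_index must be contiguous from 0, got {idx.tolist()}"
            )
        if len(grp) < 3:
            raise ValueError(f"centriole {centriole_id!r}: fewer than 3 vertices")
        z: int | str = z_ref
        if z != "max-projection":
            z = int(z)
        rois.append(
            PolygonROI(
                cell_id=str(cell_id),
                centriole_id=str(centriole_id),
                frame=int(frame),
                z_ref=z,
                vertices=grp[["x", "y"]].to_numpy(float),
            )
        )
    return rois


def read_metadata(path) -> dict[str, CellMetadata]:
    df = pd.read_csv(path)
    out = {}
    for row in df.itertuples(index=False):
        md = CellMetadata(
            cell_id=str(row.cell_id),
            genotype=getattr(row, "genotype", "wild-type"),
            stage=row.stage,
            centrosome_position=getattr(row, "centrosome_position", "unknown"),
        )
        out[md.cell_id] = md
    return out


# ---------------------------------------------------------------------------
# results tables


def write_results(path, records) -> None:
    """Write a results table (records = dataclasses, dicts or a DataFrame).

    Unbounded ratios are serialized as the literal token ``inf``.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if not records:
            raise ValueError("no records to write")
        rows = [r if isinstance(r, dict) else vars(r) for r in records]
        df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no records to write")
    df.to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df


# ---------------------------------------------------------------------------
# configuration and logging


DEFAULT_CONFIG: dict = {
    "pixel_size_xy": DEFAULT_PIXEL_SIZE_XY,
    "z_step": DEFAULT_Z_STEP,
    "background_method": "annulus",
    "background_value": 0.0,
    "tie_tolerance": 0.05,
    "detection_floor": 0.0,
    "mtoc_activity_threshold": 1.5,
    "line_profile_width": 12,
}


def load_config(path=None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        cfg.update(user)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def setup_logging(level: int = logging.INFO) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)
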