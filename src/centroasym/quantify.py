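"""Contour-based centriolar intensity quantification.

The core measurement: total fluorescence above background inside a
hand-drawn polygon contour, evaluated on pixel centers.  A pixel belongs to
the contour when its center lies strictly inside the polygon (even-odd
rule) or exactly on its boundary.  Background is subtracted per pixel and
clamped at zero before summing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import profile_line
from skimage.morphology import disk

from .io import ImageStack, PolygonROI

_EDGE_TOL = 1e-9


def points_in_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd point-in-polygon test; points on an edge count as inside.

    Parameters
    ----------
    points : (M, 2) array of (x, y)
    vertices : (N, 2) array of (x, y), ordered, implicitly closed

    Returns
    -------
    (M,) boolean array
    """
    points = np.asarray(points, float)
    vertices = np.asarray(vertices, float)
    x, y = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    on_edge = np.zeros(len(points), dtype=bool)
    scale = max(1.0, np.abs(vertices).max())
    tol = _EDGE_TOL * scale

    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        # ray casting toward +x, half-open in y to count shared vertices once
        crosses = (y1 > y) != (y2 > y)
        if crosses.any():
            with np.errstate(divide="ignore", invalid="ignore"):
                x_int = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            inside ^= crosses & (x < x_int)
        # collinearity + bounding box => point lies on the segment
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        seg_len = np.hypot(x2 - x1, y2 - y1)
        if seg_len > 0:
            on_seg = (
                (np.abs(cross) <= tol * seg_len)
                & (x >= min(x1, x2) - tol)
                & (x <= max(x1, x2) + tol)
                & (y >= min(y1, y2) - tol)
                & (y <= max(y1, y2) + tol)
            )
            on_edge |= on_seg
    return inside | on_edge


def rasterize(roi: PolygonROI, shape: tuple[int, int]) -> np.ndarray:
    """Boolean pixel mask of the contour on an image of shape (ny, nx)."""
    ny, nx = shape
    xmin, ymin, xmax, ymax = roi.bounds()
    x0 = max(0, int(np.floor(xmin)))
    y0 = max(0, int(np.floor(ymin)))
    x1 = min(nx - 1, int(np.ceil(xmax)))
    y1 = min(ny - 1, int(np.ceil(ymax)))
    mask = np.zeros(shape, dtype=bool)
    if x1 < x0 or y1 < y0:
        return mask
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    sub = points_in_polygon(pts, roi.vertices).reshape(ys.shape)
    mask[y0 : y1 + 1, x0 : x1 + 1] = sub
    return mask


@dataclass
class CentrioleMeasurement:
    """Background-corrected totals for one centriole contour."""

    centriole_id: str
    cell_id: str = ""
    totals: dict[str, float] = field(default_factory=dict)
    pixel_count: int = 0
    background_per_pixel: dict[str, float] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)

    def total(self, channel: str) -> float:
        return self.totals[channel]

    @property
    def ok(self) -> bool:
        return not ({"overlapping", "out_of_bounds", "ambiguous"} & self.flags)


def measure_total(
    stack: ImageStack,
    roi: PolygonROI,
    channel: str,
    background: float,
    clamp: str = "pixel",
) -> CentrioleMeasurement:
    """Total centriolar intensity above background inside the contour.

    ``total = sum over contour pixels of max(0, I - background)`` with
    per-pixel clamping (``clamp="pixel"``, default) or a single clamp of the
    summed difference (``clamp="total"``).  The plane measured is the ROI's
    ``z_ref`` section or the max projection.
    """
    if background < 0:
        raise ValueError("background must be >= 0")
    if clamp not in ("pixel", "total"):
        raise ValueError("clamp must be 'pixel' or 'total'")
    plane = stack.plane(channel, roi.z_ref)
    ny, nx = plane.shape

    flags: set[str] = set()
    if not roi.is_simple:
        flags.add("ambiguous")
    xmin, ymin, xmax, ymax = roi.bounds()
    if xmin < -0.5 or ymin < -0.5 or xmax > nx - 0.5 or ymax > ny - 0.5:
        flags.add("out_of_bounds")

    mask = rasterize(roi, plane.shape)
    n_px = int(mask.sum())
    if n_px == 0:
        raise ValueError(f"ROI {roi.centriole_id!r}: polygon contains no pixel centers")

    vals = plane[mask].astype(float)
    if clamp == "pixel":
        total = float(np.maximum(0.0, vals - background).sum())
    else:
        total = float(max(0.0, vals.sum() - background * n_px))

    return CentrioleMeasurement(
        centriole_id=roi.centriole_id,
        cell_id=roi.cell_id,
        totals={channel: total},
        pixel_count=n_px,
        background_per_pixel={channel: float(background)},
        flags=flags,
    )


def measure_channels(
    stack: ImageStack,
    roi: PolygonROI,
    channels: list[str] | None = None,
    background: dict[str, float] | float | None = None,
    method: str = "annulus",
    clamp: str = "pixel",
) -> CentrioleMeasurement:
    """Measure several channels on one contour with a shared pixel set."""
    channels = channels or stack.channel_names
    merged = None
    for ch in channels:
        if isinstance(background, dict):
            bg = background[ch]
        elif background is not None:
            bg = float(background)
        else:
            bg = estimate_background(stack, roi, method=method, channel=ch)
        m = measure_total(stack, roi, ch, bg, clamp=clamp)
        if merged is None:
            merged = m
        else:
            merged.totals.update(m.totals)
            merged.background_per_pixel.update(m.background_per_pixel)
            merged.flags |= m.flags
    return merged


def annulus_mask(
    roi: PolygonROI, shape: tuple[int, int], inner_px: int = 2, outer_px: int = 6
) -> np.ndarray:
    """Ring around the contour: dilation by ``outer_px`` minus dilation by ``inner_px``."""
    core = rasterize(roi, shape)
    if not core.any():
        raise ValueError(f"ROI {roi.centriole_id!r}: empty rasterization")
    inner = ndimage.binary_dilation(core, structure=disk(inner_px))
    outer = ndimage.binary_dilation(core, structure=disk(outer_px))
    # the ring must fit inside the image, else the median is not representative
    ys, xs = np.nonzero(outer)
    ny, nx = shape
    if ys.min() == 0 or xs.min() == 0 or ys.max() == ny - 1 or xs.max() == nx - 1:
        xmin, ymin, xmax, ymax = roi.bounds()
        if xmin - outer_px < 0 or ymin - outer_px < 0 or xmax + outer_px > nx - 1 or ymax + outer_px > ny - 1:
            raise ValueError(f"ROI {roi.centriole_id!r}: background annulus falls outside the image")
    return outer & ~inner


def estimate_background(
    stack: ImageStack,
    roi: PolygonROI,
    method: str = "annulus",
    channel: str | None = None,
    fixed_value: float | None = None,
    inner_px: int = 2,
    outer_px: int = 6,
) -> float:
    """Per-pixel background: a fixed experimenter value or the annulus median."""
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("fixed background requires fixed_value")
        return float(fixed_value)
    if method != "annulus":
        raise ValueError(f"unknown background method {method!r}")
    if channel is None:
        channel = stack.channel_names[0]
    plane = stack.plane(channel, roi.z_ref)
    ring = annulus_mask(roi, plane.shape, inner_px=inner_px, outer_px=outer_px)
    return float(np.median(plane[ring]))


def background_sd(
    stack: ImageStack, roi: PolygonROI, channel: str, inner_px: int = 2, outer_px: int = 6
) -> float:
    """Standard deviation of annulus pixels; basis for detection floors."""
    plane = stack.plane(channel, roi.z_ref)
    ring = annulus_mask(roi, plane.shape, inner_px=inner_px, outer_px=outer_px)
    return float(np.std(plane[ring]))


def detection_floor(
    stack: ImageStack, roi: PolygonROI, channel: str, k: float = 3.0
) -> float:
    """Marker-detection floor: ``k * annulus SD * sqrt(pixel_count)``.

    A centriole whose background-corrected total falls below this value is
    scored as marker-negative.
    """
    sd = background_sd(stack, roi, channel)
    n_px = int(rasterize(roi, stack.plane(channel, roi.z_ref).shape).sum())
    return float(k * sd * np.sqrt(n_px))


def line_profile_ratio(
    stack: ImageStack,
    line: tuple[tuple[float, float], tuple[float, float]],
    cytoplasm_roi: PolygonROI,
    channel: str,
    width: int = 12,
    z_ref: int | str = "max-projection",
) -> tuple[float, np.ndarray]:
    """Centrosome band intensity normalized to cytoplasm.

    Mean intensity over a ``width``-pixel wide band along ``line`` divided by
    the mean intensity inside ``cytoplasm_roi``.  Returns ``(ratio, profile)``
    where ``profile`` is the width-averaged intensity at each position along
    the line.
    """
    plane = stack.plane(channel, z_ref)
    (x0, y0), (x1, y1) = line
    ny, nx = plane.shape
    for x, y in ((x0, y0), (x1, y1)):
        if not (0 <= x <= nx - 1 and 0 <= y <= ny - 1):
            raise ValueError("line endpoints must lie inside the image")
    # profile_line expects (row, col) = (y, x)
    profile = profile_line(
        plane.astype(float), (y0, x0), (y1, x1), linewidth=width,
        reduce_func=np.mean, mode="reflect",
    )
    band_mean = float(np.mean(profile))

    cyto_mask = rasterize(cytoplasm_roi, plane.shape)
    if not cyto_mask.any():
        raise ValueError("cytoplasm ROI contains no pixels")
    cyto_mean = float(plane[cyto_mask].mean())
    if cyto_mean <= 0:
        raise ValueError("degenerate normalization: cytoplasm mean <= 0")
    return band_mean / cyto_mean, profile
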