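"""Synthetic microscopy generators with known ground truth.

Every stage of the measurement pipeline can be exercised against these
generators: diffraction-limited centriole pairs rendered as pixel-integrated
2D Gaussians over a constant background with Poisson (optionally plus
Gaussian read) noise; FRAP traces with a bleach event, an immobile fraction
and single-exponential recovery; spindle-pole tracks with a prescribed
rotation schedule; and asymmetry-record populations drawn from per-stage
category profiles.  All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .asymmetry import AsymmetryRecord
from .dynamics import FrapTrace, SpindleTrack
from .io import ImageStack, PolygonROI


@dataclass
class PairGroundTruth:
    """True parameters of one rendered centriole pair."""

    positions: np.ndarray  # (2, 2) of (x, y) in pixels
    true_totals: dict[str, tuple[float, float]]  # channel -> (focus0, focus1) AU
    psf_sigma: float = 1.5  # px
    background: float = 50.0  # AU / pixel
    noise_model: str = "poisson"  # "none" | "poisson" | "poisson+gaussian"
    read_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        if self.positions.shape != (2, 2):
            raise ValueError("positions must be (2, 2)")
        for ch, (t0, t1) in self.true_totals.items():
            if t0 < 0 or t1 < 0:
                raise ValueError(f"negative total for channel {ch!r}")
        if self.noise_model not in ("none", "poisson", "poisson+gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @property
    def separation(self) -> float:
        return float(np.hypot(*(self.positions[1] - self.positions[0])))

    @property
    def overlapping(self) -> bool:
        """Foci closer than 3 sigma are not independently measurable."""
        return self.separation < 3.0 * self.psf_sigma


def gaussian_pixel_mass(
    shape: tuple[int, int], x0: float, y0: float, sigma: float
) -> np.ndarray:
    """Unit-mass 2D Gaussian integrated over each pixel.

    Pixel (row r, col c) covers [c-0.5, c+0.5] x [r-0.5, r+0.5]; the mass in
    a pixel is the product of 1D Gaussian integrals (error functions), so the
    full-plane sum equals 1 up to border truncation.
    """
    ny, nx = shape
    s = sigma * math.sqrt(2.0)
    xe = (np.arange(nx + 1) - 0.5 - x0) / s
    ye = (np.arange(ny + 1) - 0.5 - y0) / s
    fx = 0.5 * np.diff(erf(xe))
    fy = 0.5 * np.diff(erf(ye))
    return np.outer(fy, fx)


def render_pair(
    truth: PairGroundTruth, shape: tuple[int, int] = (64, 64)
) -> ImageStack:
    """Render the pair into a single-z multi-channel stack.

    Noiseless expectation at each pixel is ``background + sum_focus
    total * G(pixel; position, psf_sigma)``; noise is applied per the
    truth's noise model with its seed.
    """
    ny, nx = shape
    for x, y in truth.positions:
        if not (0 <= x <= nx - 1 and 0 <= y <= ny - 1):
            raise ValueError(f"focus ({x}, {y}) outside image of shape {shape}")
    masses = [
        gaussian_pixel_mass(shape, x, y, truth.psf_sigma) for x, y in truth.positions
    ]
    rng = np.random.default_rng(truth.seed)
    channels = []
    names = []
    for ch, totals in truth.true_totals.items():
        expect = np.full(shape, float(truth.background))
        for total, mass in zip(totals, masses):
            expect += total * mass
        if truth.noise_model == "none":
            img = expect
        else:
            img = rng.poisson(expect).astype(float)
            if truth.noise_model == "poisson+gaussian" and truth.read_noise_sd > 0:
                img = img + rng.normal(0.0, truth.read_noise_sd, size=shape)
                img = np.maximum(img, 0.0)
        channels.append(img)
        names.append(ch)
    pixels = np.stack(channels)[:, np.newaxis]  # (C, 1, Y, X)
    return ImageStack(pixels=pixels, channel_names=names)


def roi_for_focus(
    position: tuple[float, float],
    psf_sigma: float,
    cell_id: str = "cell",
    centriole_id: str = "c0",
    radius_sigmas: float = 3.0,
    n_vertices: int = 24,
) -> PolygonROI:
    """Circular measurement contour of radius ``radius_sigmas * psf_sigma``."""
    x0, y0 = position
    r = radius_sigmas * psf_sigma
    ang = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    verts = np.column_stack([x0 + r * np.cos(ang), y0 + r * np.sin(ang)])
    return PolygonROI(cell_id=cell_id, centriole_id=centriole_id, frame=0,
                      z_ref=0, vertices=verts)


# ---------------------------------------------------------------------------
# asymmetry-record populations

#: daughter/mother ratio intervals of the two-centriole categories
CATEGORY_RATIO_RANGES = {
    "transition": (0.1, 2.0),
    "strong": (2.0, 10.0),
    "complete": (10.0, 1000.0),
}


def simulate_population(
    stage_profiles: dict[str, dict[str, float]],
    n_per_stage: int,
    seed: int = 0,
    centrosome_position: str = "apical",
    marker_channel: str = "Cnb",
) -> list[AsymmetryRecord]:
    """Draw asymmetry records from per-stage category probabilities.

    ``stage_profiles`` maps stage -> {category: probability}; probabilities
    must sum to 1 per stage.  Ratios within a two-centriole category are
    drawn log-uniformly over the category's ratio interval; single-centriole
    categories carry no ratio.
    """
    rng = np.random.default_rng(seed)
    records: list[AsymmetryRecord] = []
    for stage, profile in stage_profiles.items():
        cats = list(profile)
        probs = np.array([profile[c] for c in cats], float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"stage {stage!r}: category probabilities must sum to 1")
        draws = rng.choice(len(cats), size=n_per_stage, p=probs)
        for i, k in enumerate(draws):
            cat = cats[k]
            ratio = None
            inverted = False
            if cat in CATEGORY_RATIO_RANGES:
                lo, hi = CATEGORY_RATIO_RANGES[cat]
                ratio = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
                # keep draws off the open upper/lower boundaries
                if cat == "transition":
                    ratio = min(ratio, np.nextafter(2.0, 0.0))
                elif cat == "complete":
                    ratio = max(ratio, np.nextafter(10.0, np.inf))
                inverted = ratio < 1.0
            records.append(
                AsymmetryRecord(
                    cell_id=f"{stage}_{i}",
                    stage=stage,
                    centrosome_position=centrosome_position,
                    marker_channel=marker_channel,
                    ratio=ratio,
                    category=cat,
                    inverted=inverted,
                )
            )
    return records


# ---------------------------------------------------------------------------
# FRAP traces


@dataclass
class FrapGroundTruth:
    """True parameters of a simulated FRAP experiment (S/N units)."""

    pre_level: float = 4.0
    bleach_frame: int = 5
    bleach_depth: float = 0.8  # fraction of signal removed at the bleach
    immobile_fraction: float = 0.3
    recovery_rate: float = 0.01  # 1/s
    frame_interval: float = 30.0  # s; acquisition every 30-60 s
    noise_sd: float = 0.0  # Gaussian noise on the S/N readout
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.bleach_depth <= 1.0:
            raise ValueError("bleach_depth must lie in [0, 1]")
        if not 0.0 <= self.immobile_fraction <= 1.0:
            raise ValueError("immobile_fraction must lie in [0, 1]")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def expected_sn(self, n_frames: int) -> np.ndarray:
        """Noiseless S/N: flat pre-bleach, exponential post-bleach recovery."""
        t = np.arange(n_frames) * self.frame_interval
        sn = np.full(n_frames, self.pre_level)
        post = slice(self.bleach_frame, None)
        dt = t[post] - t[self.bleach_frame]
        mobile = self.pre_level * self.bleach_depth * (1.0 - self.immobile_fraction)
        sn[post] = self.pre_level * (1.0 - self.bleach_depth) + mobile * (
            1.0 - np.exp(-self.recovery_rate * dt)
        )
        return sn


def simulate_frap(
    truth: FrapGroundTruth,
    n_frames: int = 45,
    background_level: float = 50.0,
    cytoplasm_excess: float = 100.0,
) -> FrapTrace:
    """Simulate a FRAP trace with raw photometry channels.

    The S/N ground truth (plus Gaussian noise of ``noise_sd``) is embedded
    into centrosome/cytoplasm/background raw intensities so that
    :func:`centroasym.dynamics.sn_series` recovers it exactly.
    """
    if truth.bleach_frame >= n_frames:
        raise ValueError("bleach_frame must precede the last frame")
    rng = np.random.default_rng(truth.seed)
    sn = truth.expected_sn(n_frames)
    if truth.noise_sd > 0:
        sn = sn + rng.normal(0.0, truth.noise_sd, size=n_frames)
    times = np.arange(n_frames) * truth.frame_interval
    background = np.full(n_frames, background_level)
    cytoplasm = background + cytoplasm_excess
    centrosome = background + sn * cytoplasm_excess
    return FrapTrace(
        times=times,
        centrosome_signal=centrosome,
        cytoplasm_signal=cytoplasm,
        background=background,
        bleach_frame=truth.bleach_frame,
    )


# ---------------------------------------------------------------------------
# spindle tracks


def simulate_spindle(
    initial_axis_angle: float,
    rotation_schedule: np.ndarray,
    pole_distance: float = 6.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
    center: tuple[float, float] = (0.0, 0.0),
    nebd_frame: int = 0,
    anaphase_frame: int | None = None,
) -> SpindleTrack:
    """Spindle-pole track rotating per a per-frame schedule of deltas.

    Frame t has axis angle ``initial + sum(schedule[:t])`` (degrees); poles
    sit at ``center +/- (pole_distance/2) * (cos, sin)`` plus independent
    Gaussian positional jitter on every coordinate.
    """
    schedule = np.asarray(rotation_schedule, float)
    theta = np.radians(initial_axis_angle + np.concatenate([[0.0], np.cumsum(schedule)]))
    n = len(theta)
    rng = np.random.default_rng(seed)
    cx, cy = center
    half = pole_distance / 2.0
    axis = np.column_stack([np.cos(theta), np.sin(theta)])
    pole1 = np.array([cx, cy]) + half * axis
    pole2 = np.array([cx, cy]) - half * axis
    if jitter_sd > 0:
        pole1 = pole1 + rng.normal(0.0, jitter_sd, size=pole1.shape)
        pole2 = pole2 + rng.normal(0.0, jitter_sd, size=pole2.shape)
    return SpindleTrack(
        pole1=pole1,
        pole2=pole2,
        nebd_frame=nebd_frame,
        anaphase_frame=n - 1 if anaphase_frame is None else anaphase_frame,
    )
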