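"""Synthetic fluorescence-microscopy data with known ground truth.

This module generates the two kinds of input the analysis pipeline consumes:

* seeded time-lapse stacks of a single nucleus containing point-spread-blurred
  repair-protein foci that appear, disappear, grow in intensity, bleach and
  move by (optionally confined) Brownian motion, while the whole nucleus may
  drift and rotate;
* fixed-cell two-channel fields (channel A = 53BP1-like, channel B = RPA-like,
  plus an S-phase marker channel) in which a known number of B foci is nested
  inside each A focus.

Every generated dataset carries a :class:`SyntheticGroundTruth` with the true
per-frame focus positions, identities and amplitudes (and, for two-channel
fields, the true nested-focus counts), so each downstream stage can be scored
against truth without any external data.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SimConfig",
    "FocusState",
    "SyntheticGroundTruth",
    "TwoChannelTruth",
    "simulate_brownian_track",
    "simulate_timelapse",
    "simulate_two_channel",
    "write_timelapse",
]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a single-nucleus time-lapse simulation.

    Units: lengths in pixels unless a field name says µm; times in frames or
    minutes as named; intensities in arbitrary detector units on a 0–255 scale.
    """

    image_size: tuple[int, int] = (256, 256)  # (H, W) pixels
    n_frames: int = 51
    frame_interval: float = 20.0  # min between frames
    pixel_size: float = 0.1  # µm / pixel
    nucleus_center: tuple[float, float] = (128.0, 128.0)  # (x, y) px
    nucleus_axes: tuple[float, float] = (90.0, 70.0)  # semi-axes (x, y) px
    nucleus_drift: tuple[float, float] = (0.0, 0.0)  # (dx, dy) px / frame
    nucleus_rotation: float = 0.0  # deg / frame about the nucleus center
    n_initial_foci: int = 10
    birth_rate: float = 0.03  # expected new foci per frame (Poisson)
    death_prob: float = 0.02  # per-focus, per-frame disappearance probability
    diffusion_coefficient: float = 0.005  # µm² / min
    confinement_radius: float | None = None  # µm; None = unconfined
    focus_sigma: float = 2.0  # Gaussian point-spread width, px
    focus_amplitude: float = 120.0  # peak intensity above background
    amplitude_growth: float = 0.01  # fractional amplitude increase per frame
    bleach_rate: float = 0.005  # fractional global signal loss per frame
    noise_poisson_scale: float = 1.0  # photons per intensity unit; 0 disables
    noise_gaussian_sd: float = 2.0  # additive read noise SD; 0 disables
    min_focus_separation: float | None = None  # µm between focus centers at placement
    background_nucleus: float = 40.0  # nucleoplasm intensity (must be > 0)
    background_outside: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ValueError("image_size must be at least 8x8 pixels")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be positive")
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion_coefficient must be >= 0")
        if not (0.0 <= self.death_prob <= 1.0):
            raise ValueError("death_prob must be a probability in [0, 1]")
        if not (0.0 <= self.bleach_rate <= 1.0):
            raise ValueError("bleach_rate must be in [0, 1]")
        if self.birth_rate < 0:
            raise ValueError("birth_rate must be >= 0")
        if self.confinement_radius is not None and self.confinement_radius <= 0:
            raise ValueError("confinement_radius must be positive or None")
        if self.background_nucleus <= 0:
            raise ValueError("background_nucleus must be strictly positive")
        ax, ay = self.nucleus_axes
        cx, cy = self.nucleus_center
        if ax <= 0 or ay <= 0:
            raise ValueError("nucleus_axes must be positive")
        if cx - ax < 0 or cx + ax > w or cy - ay < 0 or cy + ay > h:
            raise ValueError("nucleus does not fit inside the image")


@dataclass(frozen=True)
class FocusState:
    """Ground-truth state of one focus in one frame (positions in µm)."""

    focus_id: int
    x_um: float
    y_um: float
    amplitude: float


@dataclass
class SyntheticGroundTruth:
    """Per-frame truth for a simulated time-lapse.

    ``frames[t]`` lists every focus alive at frame ``t``; a focus id appears in
    every frame between its birth and death frame inclusive (no gaps).
    """

    frames: list[list[FocusState]]
    birth_frame: dict[int, int]
    death_frame: dict[int, int]
    pixel_size: float
    frame_interval: float

    def counts_per_frame(self) -> np.ndarray:
        return np.array([len(f) for f in self.frames], dtype=int)

    def durations(self) -> dict[int, float]:
        """True track duration in min: (death − birth) · frame interval."""
        return {
            fid: (self.death_frame[fid] - self.birth_frame[fid]) * self.frame_interval
            for fid in self.birth_frame
        }

    def positions(self, frame: int) -> dict[int, tuple[float, float]]:
        return {s.focus_id: (s.x_um, s.y_um) for s in self.frames[frame]}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "frame": t,
                "focus_id": s.focus_id,
                "x_um": s.x_um,
                "y_um": s.y_um,
                "amplitude": s.amplitude,
                "birth_frame": self.birth_frame[s.focus_id],
                "death_frame": self.death_frame[s.focus_id],
            }
            for t, states in enumerate(self.frames)
            for s in states
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "frame", "focus_id", "x_um", "y_um", "amplitude",
                "birth_frame", "death_frame",
            ],
        )


def simulate_brownian_track(
    D: float,
    n_steps: int,
    dt: float,
    confinement_radius: float | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    start: Sequence[float] = (0.0, 0.0),
) -> np.ndarray:
    """Simulate one 2D Brownian trajectory, optionally confined to a disc.

    Parameters
    ----------
    D : diffusion coefficient, µm²/min. Per-axis step variance is ``2·D·dt``
        so the expected ensemble MSD is ``4·D·Δt``.
    n_steps : number of displacement steps; the returned array holds
        ``n_steps + 1`` positions including the start point.
    dt : time step in min.
    confinement_radius : if given, steps are reflected at the boundary of a
        disc of this radius (µm) centered on the start point.

    Returns
    -------
    ndarray of shape ``(n_steps + 1, 2)`` with positions in µm.
    """
    if D < 0:
        raise ValueError("diffusion coefficient D must be >= 0")
    if dt <= 0:
        raise ValueError("time step dt must be > 0")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if confinement_radius is not None and confinement_radius <= 0:
        raise ValueError("confinement_radius must be positive or None")
    if rng is None:
        rng = np.random.default_rng(seed)

    start = np.asarray(start, dtype=float)
    sd = math.sqrt(2.0 * D * dt)
    steps = rng.normal(0.0, sd, size=(n_steps, 2))
    positions = np.empty((n_steps + 1, 2))
    positions[0] = start
    pos = start.copy()
    for i in range(n_steps):
        pos = pos + steps[i]
        if confinement_radius is not None:
            pos = _reflect_into_disc(pos, start, confinement_radius)
        positions[i + 1] = pos
    return positions


def _reflect_into_disc(pos: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Radially reflect a point at the boundary of a disc until inside."""
    rel = pos - center
    rho = float(np.hypot(*rel))
    if rho <= radius or rho == 0.0:
        return pos
    unit = rel / rho
    # fold the radial coordinate into [0, radius] (triangle wave)
    period = 2.0 * radius
    r = rho % period
    if r > radius:
        r = period - r
    return center + unit * r


def _inside_ellipse(x: float, y: float, cfg: SimConfig, margin: float = 1.0) -> bool:
    cx, cy = cfg.nucleus_center
    ax, ay = cfg.nucleus_axes
    return ((x - cx) / (ax * margin)) ** 2 + ((y - cy) / (ay * margin)) ** 2 <= 1.0


def _draw_in_ellipse(rng: np.random.Generator, cfg: SimConfig, margin: float = 0.9) -> np.ndarray:
    """Rejection-sample a point uniformly inside the (shrunken) nucleus ellipse."""
    cx, cy = cfg.nucleus_center
    ax, ay = cfg.nucleus_axes
    while True:
        u = rng.uniform(-1.0, 1.0, size=2)
        if u[0] ** 2 + u[1] ** 2 <= 1.0:
            return np.array([cx + u[0] * ax * margin, cy + u[1] * ay * margin])


@dataclass
class _LiveFocus:
    pos: np.ndarray  # world coordinates, px (before drift/rotation)
    birth: int
    origin: np.ndarray  # birth position, anchor of confinement


def _drift_transform(t: int, cfg: SimConfig, pos: np.ndarray) -> np.ndarray:
    """Map world (undrifted) pixel coordinates to image coordinates at frame t."""
    theta = math.radians(cfg.nucleus_rotation * t)
    c = np.array(cfg.nucleus_center)
    shift = np.array(cfg.nucleus_drift) * t
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    return rot @ (pos - c) + c + shift


def _render_gaussian(img: np.ndarray, x: float, y: float, sigma: float, amp: float) -> None:
    """Add an isotropic 2D Gaussian to ``img`` in place (4σ window)."""
    h, w = img.shape
    r = int(math.ceil(4.0 * sigma))
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - x
    ys = np.arange(y0, y1) - y
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sigma**2))
    img[y0:y1, x0:x1] += amp * g


def _ellipse_mask(
    shape: tuple[int, int],
    center: Sequence[float],
    axes: Sequence[float],
    theta_deg: float = 0.0,
) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    u = xx - center[0]
    v = yy - center[1]
    th = math.radians(theta_deg)
    ur = u * math.cos(th) + v * math.sin(th)
    vr = -u * math.sin(th) + v * math.cos(th)
    return (ur / axes[0]) ** 2 + (vr / axes[1]) ** 2 <= 1.0


def _ellipse_window(
    shape: tuple[int, int],
    center: Sequence[float],
    axes: Sequence[float],
) -> tuple[tuple[slice, slice], np.ndarray]:
    """Bounding-box slice and local mask of an axis-aligned ellipse."""
    h, w = shape
    x0 = max(int(center[0] - axes[0]) - 1, 0)
    x1 = min(int(center[0] + axes[0]) + 2, w)
    y0 = max(int(center[1] - axes[1]) - 1, 0)
    y1 = min(int(center[1] + axes[1]) + 2, h)
    sl = (slice(y0, y1), slice(x0, x1))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = ((xx - center[0]) / axes[0]) ** 2 + ((yy - center[1]) / axes[1]) ** 2 <= 1.0
    return sl, mask


def simulate_timelapse(config: SimConfig) -> tuple[np.ndarray, SyntheticGroundTruth]:
    """Render a seeded time-lapse stack of one nucleus with mobile foci.

    Each live focus is rendered as an isotropic Gaussian of width
    ``focus_sigma`` at its true position; amplitudes grow by
    ``amplitude_growth`` per frame alive and the whole frame decays by
    ``bleach_rate`` per frame. Shot (Poisson) and read (Gaussian) noise are
    added last. Identical config (including seed) gives a bit-identical stack.

    Returns
    -------
    (stack, truth) : ``stack`` is float32 of shape (n_frames, H, W) clipped to
    [0, 255]; ``truth`` records positions in µm in *image* coordinates, i.e.
    after any nucleus drift/rotation.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    sep_px = (
        cfg.min_focus_separation / cfg.pixel_size
        if cfg.min_focus_separation is not None
        else None
    )

    def _place(existing: list[np.ndarray]) -> np.ndarray:
        p = _draw_in_ellipse(rng, cfg)
        if sep_px is None:
            return p
        for _ in range(1000):
            if all(np.hypot(*(p - q)) >= sep_px for q in existing):
                break
            p = _draw_in_ellipse(rng, cfg)
        return p

    foci: dict[int, _LiveFocus] = {}
    next_id = 0
    for _ in range(cfg.n_initial_foci):
        p = _place([f.pos for f in foci.values()])
        foci[next_id] = _LiveFocus(pos=p, birth=0, origin=p.copy())
        next_id += 1

    step_sd_px = math.sqrt(2.0 * cfg.diffusion_coefficient * cfg.frame_interval) / cfg.pixel_size
    conf_px = (
        cfg.confinement_radius / cfg.pixel_size
        if cfg.confinement_radius is not None
        else None
    )

    frames_truth: list[list[FocusState]] = []
    birth: dict[int, int] = {i: 0 for i in foci}
    death: dict[int, int] = {}
    stack = np.empty((cfg.n_frames, h, w), dtype=np.float32)

    for t in range(cfg.n_frames):
        if t > 0:
            # move, then kill, then give birth — all from the single rng
            for fid in sorted(foci):
                f = foci[fid]
                if step_sd_px > 0:
                    for _ in range(50):
                        cand = f.pos + rng.normal(0.0, step_sd_px, size=2)
                        if conf_px is not None:
                            cand = _reflect_into_disc(cand, f.origin, conf_px)
                        if _inside_ellipse(cand[0], cand[1], cfg, margin=0.97):
                            f.pos = cand
                            break
            if cfg.death_prob > 0:
                for fid in sorted(foci):
                    if rng.random() < cfg.death_prob:
                        death[fid] = t - 1
                        del foci[fid]
            n_new = rng.poisson(cfg.birth_rate) if cfg.birth_rate > 0 else 0
            for _ in range(n_new):
                p = _place([f.pos for f in foci.values()])
                foci[next_id] = _LiveFocus(pos=p, birth=t, origin=p.copy())
                birth[next_id] = t
                next_id += 1

        theta_t = cfg.nucleus_rotation * t
        shift_t = np.array(cfg.nucleus_drift) * t
        nuc_center_t = np.array(cfg.nucleus_center) + shift_t
        mask = _ellipse_mask((h, w), nuc_center_t, cfg.nucleus_axes, theta_t)
        img = np.full((h, w), cfg.background_outside, dtype=float)
        img[mask] = cfg.background_nucleus

        states: list[FocusState] = []
        bleach = (1.0 - cfg.bleach_rate) ** t
        for fid in sorted(foci):
            f = foci[fid]
            ip = _drift_transform(t, cfg, f.pos)
            amp = cfg.focus_amplitude * (1.0 + cfg.amplitude_growth) ** (t - f.birth)
            _render_gaussian(img, ip[0], ip[1], cfg.focus_sigma, amp)
            states.append(
                FocusState(
                    focus_id=fid,
                    x_um=ip[0] * cfg.pixel_size,
                    y_um=ip[1] * cfg.pixel_size,
                    amplitude=amp * bleach,
                )
            )
        img *= bleach

        if cfg.noise_poisson_scale > 0:
            img = rng.poisson(np.clip(img, 0, None) * cfg.noise_poisson_scale) / cfg.noise_poisson_scale
        if cfg.noise_gaussian_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_gaussian_sd, size=img.shape)
        stack[t] = np.clip(img, 0.0, 255.0).astype(np.float32)
        frames_truth.append(states)

    for fid in foci:
        death[fid] = cfg.n_frames - 1

    truth = SyntheticGroundTruth(
        frames=frames_truth,
        birth_frame=birth,
        death_frame=death,
        pixel_size=cfg.pixel_size,
        frame_interval=cfg.frame_interval,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# fixed-cell two-channel fields


@dataclass
class TwoChannelTruth:
    """Ground truth for a fixed-cell two-channel field.

    ``nested_counts[(cell, a_id)]`` is the number of channel-B foci rendered
    inside that channel-A focus; ``a_positions`` are A-focus centers in µm.
    """

    nested_counts: dict[tuple[int, int], int]
    a_positions: dict[tuple[int, int], tuple[float, float]]
    b_positions: list[tuple[float, float]]
    edu_positive: dict[int, bool]
    nucleus_centers: dict[int, tuple[float, float]]
    pixel_size: float

    def category_fractions(self, edu_only: bool = False) -> dict[str, float]:
        """True fractions of A foci with 0, 1 or >1 nested B foci."""
        counts = [
            c
            for (cell, _a), c in self.nested_counts.items()
            if not edu_only or self.edu_positive[cell]
        ]
        n = len(counts)
        if n == 0:
            return {"0": math.nan, "1": math.nan, ">1": math.nan}
        arr = np.array(counts)
        return {
            "0": float(np.mean(arr == 0)),
            "1": float(np.mean(arr == 1)),
            ">1": float(np.mean(arr > 1)),
        }


def simulate_two_channel(
    n_cells: int,
    foci_per_cell: int,
    nested_counts_distribution: Mapping[int, float],
    edu_positive_fraction: float = 0.7,
    seed: int = 0,
    *,
    tile: int = 160,
    pixel_size: float = 0.04,
    sigma_a: float = 6.0,
    sigma_b: float = 2.0,
    amp_a: float = 150.0,
    amp_b: float = 170.0,
    background_nucleus: float = 40.0,
    background_outside: float = 6.0,
    b_background_nucleus: float = 12.0,
    noise_gaussian_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, TwoChannelTruth]:
    """Render a field of fixed nuclei with nested two-channel foci.

    Nuclei are laid out on a grid of ``tile``-pixel cells. Each nucleus holds
    ``foci_per_cell`` channel-A foci (minimum mutual separation enforced so the
    segmentation task is well posed); every A focus receives a number of
    channel-B foci drawn from ``nested_counts_distribution`` (probabilities for
    0, 1, 2, … nested foci), rendered strictly inside the parent's footprint.
    A third image encodes the S-phase (EdU) status of each nucleus.

    Returns ``(channel_a, channel_b, edu, truth)``; images are float32.
    """
    if n_cells < 1 or foci_per_cell < 1:
        raise ValueError("n_cells and foci_per_cell must be >= 1")
    if not (0.0 <= edu_positive_fraction <= 1.0):
        raise ValueError("edu_positive_fraction must be in [0, 1]")
    if sigma_b >= sigma_a:
        raise ValueError("nested channel-B foci must be smaller than their parent A focus")
    ks = sorted(int(k) for k in nested_counts_distribution)
    if any(k < 0 for k in ks):
        raise ValueError("nested counts must be nonnegative")
    probs = np.array([nested_counts_distribution[k] for k in ks], dtype=float)
    if np.any(probs < 0) or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("nested_counts_distribution must be a probability distribution")

    rng = np.random.default_rng(seed)
    ncols = int(math.ceil(math.sqrt(n_cells)))
    nrows = int(math.ceil(n_cells / ncols))
    H, W = nrows * tile, ncols * tile
    chan_a = np.full((H, W), background_outside, dtype=float)
    chan_b = np.full((H, W), background_outside, dtype=float)
    edu_img = np.full((H, W), background_outside, dtype=float)

    axes = (0.40 * tile, 0.33 * tile)
    nested_counts: dict[tuple[int, int], int] = {}
    a_positions: dict[tuple[int, int], tuple[float, float]] = {}
    b_positions: list[tuple[float, float]] = []
    edu_status: dict[int, bool] = {}
    centers: dict[int, tuple[float, float]] = {}

    min_sep = 4.5 * sigma_a
    for cell in range(n_cells):
        row, col = divmod(cell, ncols)
        cx = col * tile + tile / 2 + rng.uniform(-3, 3)
        cy = row * tile + tile / 2 + rng.uniform(-3, 3)
        centers[cell] = (cx, cy)
        sl, nuc = _ellipse_window((H, W), (cx, cy), axes)
        chan_a[sl][nuc] = background_nucleus
        chan_b[sl][nuc] = b_background_nucleus
        positive = bool(rng.random() < edu_positive_fraction)
        edu_status[cell] = positive
        edu_img[sl][nuc] = 150.0 if positive else 25.0

        placed: list[np.ndarray] = []
        sep = min_sep
        attempts = 0
        while len(placed) < foci_per_cell:
            u = rng.uniform(-1.0, 1.0, size=2)
            attempts += 1
            if u[0] ** 2 + u[1] ** 2 > 1.0:
                continue
            p = np.array([cx + u[0] * axes[0] * 0.80, cy + u[1] * axes[1] * 0.80])
            if all(np.hypot(*(p - q)) >= sep for q in placed):
                placed.append(p)
            elif attempts > 4000:
                sep *= 0.9  # relax separation rather than loop forever
                attempts = 0

        for a_id, p in enumerate(placed):
            _render_gaussian(chan_a, p[0], p[1], sigma_a, amp_a)
            a_positions[(cell, a_id)] = (p[0] * pixel_size, p[1] * pixel_size)
            k = int(rng.choice(ks, p=probs))
            nested_counts[(cell, a_id)] = k
            sub: list[np.ndarray] = []
            # keep nested foci well inside the parent's segmentable footprint
            # (the thresholded A mask extends to roughly 0.8 sigma_a)
            b_radius = 0.6 * sigma_a
            b_sep = 3.2 * sigma_b
            tries = 0
            while len(sub) < k:
                off = rng.uniform(-1.0, 1.0, size=2)
                tries += 1
                if off[0] ** 2 + off[1] ** 2 > 1.0:
                    continue
                bp = p + off * b_radius
                if all(np.hypot(*(bp - q)) >= b_sep for q in sub):
                    sub.append(bp)
                elif tries > 4000:
                    b_sep *= 0.9
                    tries = 0
            for bp in sub:
                _render_gaussian(chan_b, bp[0], bp[1], sigma_b, amp_b)
                b_positions.append((bp[0] * pixel_size, bp[1] * pixel_size))

    if noise_gaussian_sd > 0:
        chan_a = chan_a + rng.normal(0.0, noise_gaussian_sd, size=chan_a.shape)
        chan_b = chan_b + rng.normal(0.0, noise_gaussian_sd, size=chan_b.shape)
        edu_img = edu_img + rng.normal(0.0, noise_gaussian_sd, size=edu_img.shape)

    truth = TwoChannelTruth(
        nested_counts=nested_counts,
        a_positions=a_positions,
        b_positions=b_positions,
        edu_positive=edu_status,
        nucleus_centers=centers,
        pixel_size=pixel_size,
    )
    return (
        np.clip(chan_a, 0, 255).astype(np.float32),
        np.clip(chan_b, 0, 255).astype(np.float32),
        np.clip(edu_img, 0, 255).astype(np.float32),
        truth,
    )


def write_timelapse(
    stack: np.ndarray,
    truth: SyntheticGroundTruth,
    config: SimConfig,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write a simulated run to disk: multi-page TIFF, truth CSV, manifest JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": out / "stack.tif",
        "truth": out / "ground_truth.csv",
        "manifest": out / "manifest.json",
    }
    tifffile.imwrite(paths["stack"], stack, photometric="minisblack")
    truth.to_dataframe().to_csv(paths["truth"], index=False)
    manifest = {"config": dataclasses.asdict(config), "seed": config.seed}
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
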