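"""Synthetic micromass scenes and groove fluorescence series with ground truth.

Two generators stand in for experimental images so that every stage of the
analysis can be verified against exact truth:

* :func:`generate_micromass_scene` renders dark condensation-like objects
  (ellipses, or branched unions of overlapping ellipses) on a bright noisy
  background, emulating brightfield micromass images.
* :func:`generate_groove_series` renders a time series of a rectangular
  groove containing anisotropic 2-D Gaussian condensations whose FWHMs
  follow logistic growth toward a final size (saturating kinetics) and
  whose peak amplitude may ramp over time; the Gaussian model makes the
  FWHM ground truth analytic.

Noise is additive Gaussian by default (Poisson optional for the groove
series).  All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from condensia import morphometrics

#: CSV header for ground-truth tables.
TRUTH_COLUMNS = [
    "object_id",
    "t_h",
    "cx_um",
    "cy_um",
    "length_fwhm_um",
    "width_fwhm_um",
    "area_px",
    "major_px",
    "minor_px",
    "class_label",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class PlacementError(RuntimeError):
    """Raised when objects cannot be packed at the requested minimum gap."""


@dataclass
class MicromassSceneSpec:
    """Parameters of one synthetic brightfield micromass scene.

    Objects are darker than the background, as condensations are in
    brightfield.  ``min_gap`` is the minimum pixel gap between rendered
    objects (0 permits touching); ``axis_ratio_range`` bounds the a/b ratio
    of the generating ellipses.
    """

    image_size: tuple[int, int] = (512, 512)
    n_objects: int = 10
    shape_family: str = "ellipse"  # or "branched"
    area_range: tuple[float, float] = (400.0, 1200.0)
    axis_ratio_range: tuple[float, float] = (1.0, 2.0)
    background_level: float = 0.8
    object_level: float = 0.3
    noise_sd: float = 0.02
    min_gap: int = 5
    seed: int = 0
    class_label: str = ""

    def validate(self) -> None:
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
        if self.object_level >= self.background_level:
            raise ValueError("objects must be darker than the background")
        lo, hi = self.area_range
        if not (0 < lo <= hi):
            raise ValueError("invalid area_range")
        if hi > 0.25 * self.image_size[0] * self.image_size[1]:
            raise ValueError("area_range exceeds image capacity")
        if self.axis_ratio_range[0] < 1.0:
            raise ValueError("axis ratio must be >= 1")


@dataclass
class CondensationParams:
    """Growth schedule of one synthetic condensation in a groove.

    The FWHM follows logistic growth
    ``F(t) = F_final / (1 + exp(-rate * (t - midpoint)))`` so size
    saturates at ``F_final``; the peak amplitude ramps linearly from
    ``amplitude_start`` to ``amplitude_end`` over the series (a proxy for
    cell density increasing over days).
    """

    center_um: float
    final_length_um: float = 80.0
    final_width_um: float = 40.0
    growth_midpoint_h: float = 8.0
    growth_rate: float = 0.5
    amplitude_start: float = 0.5
    amplitude_end: float = 1.0

    def fwhm_at(self, t_h: float) -> tuple[float, float]:
        g = 1.0 / (1.0 + np.exp(-self.growth_rate * (t_h - self.growth_midpoint_h)))
        return self.final_length_um * g, self.final_width_um * g

    def amplitude_at(self, t_h: float, t_final_h: float) -> float:
        frac = t_h / t_final_h if t_final_h > 0 else 1.0
        return self.amplitude_start + (self.amplitude_end - self.amplitude_start) * frac


@dataclass
class GrooveSeriesSpec:
    """Parameters of one synthetic groove fluorescence time series.

    The groove long axis is rendered parallel to the image x-axis
    (columns); frame ``k`` corresponds to time ``k * frame_interval_h``.
    """

    groove_width_um: float = 100.0
    groove_length_um: float = 500.0
    pixel_size_um: float = 1.0
    n_timepoints: int = 72
    frame_interval_h: float = 0.5
    condensations: list[CondensationParams] = field(default_factory=list)
    background_level: float = 0.1
    noise_sd: float = 0.01
    noise_model: str = "gaussian"  # or "poisson"
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive (calibration error)")
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        for c in self.condensations:
            if c.final_length_um <= 0 or c.final_width_um <= 0:
                raise ValueError("condensation FWHMs must be positive")
            if c.final_width_um > self.groove_width_um:
                raise ValueError(
                    "condensation ground-truth width exceeds the groove width"
                )

    @property
    def times_h(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.frame_interval_h

    @property
    def frame_shape(self) -> tuple[int, int]:
        h = int(round(self.groove_width_um / self.pixel_size_um))
        w = int(round(self.groove_length_um / self.pixel_size_um))
        return h, w


# ---------------------------------------------------------------------------
# micromass scenes
# ---------------------------------------------------------------------------

def _ellipse_mask(shape, center, a, b, theta):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = rr - center[0]
    dx = cc - center[1]
    # rotate into ellipse frame; a = semi-axis along theta
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _dilate_gap(mask: np.ndarray, gap: int) -> np.ndarray:
    """Dilate by a Euclidean disk of radius ``gap`` (identity for gap <= 0)."""
    if gap <= 0:
        return mask
    from scipy import ndimage as ndi

    r = int(gap)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    footprint = yy**2 + xx**2 <= r**2
    return ndi.binary_dilation(mask, structure=footprint)


def _render_object(spec: MicromassSceneSpec, rng: np.random.Generator):
    """Draw one object's mask on the full grid plus its analytic truth."""
    area = rng.uniform(*spec.area_range)
    ratio = rng.uniform(*spec.axis_ratio_range)
    # area = pi*a*b with a = ratio*b
    b = np.sqrt(area / (np.pi * ratio))
    a = ratio * b
    theta = rng.uniform(0, np.pi)
    h, w = spec.image_size
    margin = a + 2
    if 2 * margin >= min(h, w):
        raise PlacementError("object too large for the image")
    cy = rng.uniform(margin, h - margin)
    cx = rng.uniform(margin, w - margin)
    mask = _ellipse_mask(spec.image_size, (cy, cx), a, b, theta)
    if spec.shape_family == "branched":
        n_lobes = rng.integers(1, 4)
        for _ in range(n_lobes):
            off = rng.uniform(-a, a, size=2) * 0.6
            lb = b * rng.uniform(0.4, 0.8)
            la = lb * rng.uniform(1.0, ratio)
            lth = rng.uniform(0, np.pi)
            cy2 = np.clip(cy + off[0], margin, h - margin)
            cx2 = np.clip(cx + off[1], margin, w - margin)
            mask |= _ellipse_mask(spec.image_size, (cy2, cx2), la, lb, lth)
    return mask, {"cy": cy, "cx": cx, "a": a, "b": b, "theta": theta}


def generate_micromass_scene(
    spec: MicromassSceneSpec, max_tries: int = 200
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a brightfield-like scene of dark objects on a noisy background.

    Returns the image (float, clipped to [0, 1]) and a ground-truth table
    with one row per object (centroid, rasterized area, generating-ellipse
    axis lengths).  Raises :class:`PlacementError` when ``n_objects``
    cannot be placed pairwise at least ``min_gap`` px apart.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    placed = np.zeros((h, w), dtype=bool)
    forbidden = np.zeros((h, w), dtype=bool)
    masks, infos = [], []
    for _ in range(spec.n_objects):
        for attempt in range(max_tries):
            mask, info = _render_object(spec, rng)
            if not (mask & forbidden).any():
                break
        else:
            raise PlacementError(
                f"could not place {spec.n_objects} objects with min_gap="
                f"{spec.min_gap}px after {max_tries} tries"
            )
        masks.append(mask)
        infos.append(info)
        placed |= mask
        forbidden = _dilate_gap(placed, spec.min_gap)

    image = np.full((h, w), spec.background_level, dtype=float)
    for mask in masks:
        image[mask] = spec.object_level
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    rows = []
    for i, (mask, info) in enumerate(zip(masks, infos)):
        rows.append(
            {
                "object_id": i,
                "t_h": 0.0,
                "cx_um": info["cx"],
                "cy_um": info["cy"],
                "length_fwhm_um": np.nan,
                "width_fwhm_um": np.nan,
                "area_px": int(mask.sum()),
                "major_px": 2.0 * info["a"],
                "minor_px": 2.0 * info["b"],
                "class_label": spec.class_label,
            }
        )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return image, truth


def scene_label_map(spec: MicromassSceneSpec) -> np.ndarray:
    """Noise-free label map of the objects a spec generates (same seed).

    Re-renders the scene's objects and labels them 1..N, giving perfect
    instance masks for descriptor computation without segmentation.
    Overlapping objects (min_gap = 0) keep the later label on contested
    pixels.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    labels = np.zeros((h, w), dtype=np.int32)
    placed = np.zeros((h, w), dtype=bool)
    forbidden = np.zeros((h, w), dtype=bool)
    for i in range(spec.n_objects):
        for _ in range(200):
            mask, _info = _render_object(spec, rng)
            if not (mask & forbidden).any():
                break
        else:
            raise PlacementError("placement failure")
        labels[mask] = i + 1
        placed |= mask
        forbidden = _dilate_gap(placed, spec.min_gap)
    return labels


def generate_two_class_shapes(
    class_a_spec: MicromassSceneSpec,
    class_b_spec: MicromassSceneSpec,
    n_per_class: int,
    seed: int = 0,
    calibration: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two labelled descriptor populations rendered from two scene specs.

    Scenes are generated (several per class, with per-scene seeds derived
    from ``seed``) until at least ``n_per_class`` objects exist per class;
    descriptors are computed from the exact object label maps, so the
    populations reflect the generating distributions, not segmentation
    error.  Identical specs give populations with no systematic shift.
    Per-scene object counts are Poisson-distributed around the spec's
    ``n_objects`` (min 1), as replicate images vary in counts — this also
    keeps the image-level descriptor (number of condensations) from being
    degenerate across the population.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2 (discriminant needs >= 2 per class)")
    rng = np.random.default_rng(seed)
    tables = []
    for cls, spec in (("a", class_a_spec), ("b", class_b_spec)):
        parts, total = [], 0
        while total < n_per_class:
            n_obj = max(1, int(rng.poisson(spec.n_objects)))
            s = MicromassSceneSpec(
                **{
                    **spec.__dict__,
                    "n_objects": n_obj,
                    "seed": int(rng.integers(2**31)),
                }
            )
            labels = scene_label_map(s)
            tab = morphometrics.descriptor_table(labels, calibration=calibration)
            parts.append(tab)
            total += len(tab)
        table = pd.concat(parts, ignore_index=True).iloc[:n_per_class].copy()
        table["class"] = cls
        tables.append(table)
    return tables[0], tables[1]


# ---------------------------------------------------------------------------
# groove series
# ---------------------------------------------------------------------------

def generate_groove_series(
    spec: GrooveSeriesSpec,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a groove time series of growing Gaussian condensations.

    Returns a ``(T, H, W)`` stack and a truth table with one row per
    condensation per timepoint holding the true FWHMs, centre, and
    amplitude at that time.  Frames contain, additively: the background
    level, each condensation as a separable anisotropic 2-D Gaussian
    (length along the groove axis = columns), and noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.frame_shape
    times = spec.times_h
    t_final = times[-1] if len(times) else 0.0
    yy = (np.arange(h) + 0.5) * spec.pixel_size_um
    xx = (np.arange(w) + 0.5) * spec.pixel_size_um
    cy = spec.groove_width_um / 2.0

    stack = np.empty((spec.n_timepoints, h, w), dtype=float)
    rows = []
    for k, t in enumerate(times):
        frame = np.full((h, w), spec.background_level, dtype=float)
        for i, cond in enumerate(spec.condensations):
            length_fwhm, width_fwhm = cond.fwhm_at(t)
            amp = cond.amplitude_at(t, t_final)
            sx = max(length_fwhm / FWHM_PER_SIGMA, 1e-9)
            sy = max(width_fwhm / FWHM_PER_SIGMA, 1e-9)
            gx = np.exp(-0.5 * ((xx - cond.center_um) / sx) ** 2)
            gy = np.exp(-0.5 * ((yy - cy) / sy) ** 2)
            frame += amp * gy[:, None] * gx[None, :]
            rows.append(
                {
                    "object_id": i,
                    "t_h": t,
                    "cx_um": cond.center_um,
                    "cy_um": cy,
                    "length_fwhm_um": length_fwhm,
                    "width_fwhm_um": width_fwhm,
                    "area_px": np.nan,
                    "major_px": np.nan,
                    "minor_px": np.nan,
                    "class_label": "",
                }
            )
        if spec.noise_model == "poisson":
            scale = 1000.0
            frame = rng.poisson(np.clip(frame, 0, None) * scale) / scale
        elif spec.noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.noise_sd, size=frame.shape)
        stack[k] = frame
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return stack, truth
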