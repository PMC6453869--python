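"""High-content quantification of condensations confined in microgrooves.

A groove is a rectangular channel that uniaxially confines a cell mass.
Condensations appear as local maxima of nuclear (Hoechst) fluorescence.
The quantifier works on 1-D intensity profiles:

* the **major-axis profile** averages fluorescence across the groove's
  short axis; condensations are peaks in this profile, their **length** is
  the full width at half maximum (FWHM) of the peak;
* for each peak, the **minor-axis profile** averages fluorescence along
  the groove restricted to that peak's half-max interval; its FWHM is the
  condensation **width**.

Half-maximum is referenced to the peak's prominence base (evaluation
height = peak height − prominence/2), which makes FWHM robust to a
constant background offset.  Peak prominence itself is reported as a proxy
for cell density.  Derived metrics: aspect ratio (length/width in
width-constrained grooves; longest/shortest in unconstrained ones),
condensations per 100 µm, backward tracking from the final frame to each
condensation's establishment, per-timepoint summaries, and plateau times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

#: nominal widths (µm) of grooves whose short axis constrains growth
CONSTRAINED_WIDTHS = (25.0, 50.0, 100.0, 200.0)


@dataclass
class GrooveROI:
    """Rectangular region of one groove in image pixel coordinates.

    Half-open rectangle ``[y0, y1) × [x0, x1)``; ``nominal_width`` is the
    groove's fabricated width in µm (or the string ``"TCP"`` for an
    unconstrained tissue-culture-plate field); ``long_axis`` says which
    image axis runs along the groove.
    """

    x0: int
    y0: int
    x1: int
    y1: int
    nominal_width: float | str = 100.0
    long_axis: str = "horizontal"
    pixel_size: float = 1.0

    def validate(self, image_shape: tuple[int, int] | None = None) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (calibration error)")
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError("empty ROI rectangle")
        if image_shape is not None:
            h, w = image_shape[:2]
            if self.x0 < 0 or self.y0 < 0 or self.x1 > w or self.y1 > h:
                raise ValueError("ROI outside image bounds")

    @property
    def constrained(self) -> bool:
        """Width-constrained grooves use length/width for the aspect ratio;
        300-µm grooves and TCP use longest/shortest."""
        if isinstance(self.nominal_width, str):
            return False
        return float(self.nominal_width) in CONSTRAINED_WIDTHS

    def extract(self, frame: np.ndarray) -> np.ndarray:
        """Crop the ROI and orient it with the groove long axis on columns."""
        self.validate(frame.shape)
        sub = frame[self.y0 : self.y1, self.x0 : self.x1]
        if self.long_axis == "vertical":
            sub = sub.T
        return sub

    @property
    def major_extent_um(self) -> float:
        a = (self.x1 - self.x0) if self.long_axis == "horizontal" else (self.y1 - self.y0)
        return a * self.pixel_size

    @property
    def minor_extent_um(self) -> float:
        a = (self.y1 - self.y0) if self.long_axis == "horizontal" else (self.x1 - self.x0)
        return a * self.pixel_size


@dataclass
class AxialProfile:
    """1-D intensity profile along one groove axis, in µm coordinates."""

    positions: np.ndarray
    intensities: np.ndarray
    axis: str  # "major" or "minor"
    pixel_size: float = 1.0


@dataclass
class CondensationMeasurement:
    """One condensation at one timepoint, measured from axial profiles."""

    position: float  # µm along the groove major axis
    length: float  # µm, FWHM of the major-axis peak
    width: float  # µm, FWHM of the minor-axis peak (NaN if missing)
    prominence: float
    timepoint: float = 0.0  # hours
    aspect_ratio: float = np.nan
    length_interval: tuple[float, float] = (np.nan, np.nan)
    end_clipped: bool = False
    width_missing: bool = False
    width_clipped: bool = False


@dataclass
class CondensationTrack:
    """One condensation followed backwards from the final frame."""

    track_id: int
    measurements: list[CondensationMeasurement] = field(default_factory=list)

    @property
    def establishment_time(self) -> float:
        return self.measurements[0].timepoint

    @property
    def timepoints(self) -> list[float]:
        return [m.timepoint for m in self.measurements]


# ---------------------------------------------------------------------------
# profiles and peaks
# ---------------------------------------------------------------------------

def axial_profile(
    frame: np.ndarray,
    roi: GrooveROI,
    axis: str = "major",
    restrict_box: tuple[float, float] | None = None,
) -> AxialProfile:
    """Mean-intensity profile along one groove axis.

    ``axis="major"`` averages over the groove's short axis and returns a
    profile along the groove; ``axis="minor"`` averages along the groove —
    optionally restricted to ``restrict_box``, a (lo, hi) µm interval along
    the major axis (the extent of one condensation) — and returns the
    cross-groove profile.
    """
    sub = roi.extract(frame).astype(float)
    px = roi.pixel_size
    if axis == "major":
        if restrict_box is not None:
            lo = max(int(np.floor(restrict_box[0] / px)), 0)
            hi = min(int(np.ceil(restrict_box[1] / px)), sub.shape[0])
            if hi <= lo:
                raise ValueError("restrict_box collapses to an empty interval")
            sub = sub[lo:hi, :]
        prof = sub.mean(axis=0)
    elif axis == "minor":
        if restrict_box is not None:
            lo = max(int(np.floor(restrict_box[0] / px)), 0)
            hi = min(int(np.ceil(restrict_box[1] / px)), sub.shape[1])
            if hi <= lo:
                raise ValueError("restrict_box collapses to an empty interval")
            sub = sub[:, lo:hi]
        prof = sub.mean(axis=1)
    else:
        raise ValueError("axis must be 'major' or 'minor'")
    positions = (np.arange(prof.size) + 0.5) * px
    return AxialProfile(positions=positions, intensities=prof, axis=axis, pixel_size=px)


def robust_noise_sd(values: np.ndarray) -> float:
    """Noise scale from the median absolute first difference (MAD·1.4826/√2)."""
    diffs = np.diff(np.asarray(values, dtype=float))
    if diffs.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(diffs - np.median(diffs))) / np.sqrt(2.0))


def default_min_prominence(profile: AxialProfile, factor: float = 5.0) -> float:
    """Prominence floor: ``factor`` × the profile's robust noise estimate.

    The prominence of the largest pure-noise excursion in a profile of a
    few hundred samples reaches ~4σ (peak near +3σ, surrounding valleys
    below the baseline), so the floor sits at 5σ to reject it while staying
    far below condensation peaks, which exceed the noise many-fold.
    """
    return max(factor * robust_noise_sd(profile.intensities), 1e-12)


def detect_condensations(
    profile: AxialProfile,
    min_prominence: float | None = None,
    min_fwhm_um: float = 10.0,
) -> list[dict]:
    """Find peaks with topographic prominence above a floor; measure FWHM.

    Returns one record per peak: ``position`` (µm), ``prominence``,
    ``fwhm`` (µm), ``interval`` (half-max crossing interval in µm, clipped
    at the profile ends, with ``end_clipped`` flagging truncation).  The
    evaluation height for the half-max crossings is
    ``peak height − prominence/2``.  Peaks narrower than ``min_fwhm_um``
    (default: one nuclear diameter) are discarded: a condensation is a
    multicellular aggregate, so a sub-nuclear FWHM can only be a noise
    spike.  With no qualifying peaks the list is empty.
    """
    y = np.asarray(profile.intensities, dtype=float)
    if y.size < 3:
        return []
    if min_prominence is None:
        min_prominence = default_min_prominence(profile)
    peaks, props = signal.find_peaks(y, prominence=min_prominence)
    if peaks.size == 0:
        return []
    widths, _heights, left_ips, right_ips = signal.peak_widths(
        y,
        peaks,
        rel_height=0.5,
        prominence_data=(
            props["prominences"],
            props["left_bases"],
            props["right_bases"],
        ),
    )
    px = profile.pixel_size
    origin = profile.positions[0]
    records = []
    for i, pk in enumerate(peaks):
        if (right_ips[i] - left_ips[i]) * px < min_fwhm_um:
            continue
        lo = origin + left_ips[i] * px
        hi = origin + right_ips[i] * px
        clipped = left_ips[i] <= 0.0 or right_ips[i] >= y.size - 1.0
        records.append(
            {
                "position": float(profile.positions[pk]),
                "prominence": float(props["prominences"][i]),
                "fwhm": float((right_ips[i] - left_ips[i]) * px),
                "interval": (float(lo), float(hi)),
                "end_clipped": bool(clipped),
            }
        )
    return records


def measure_condensation(
    frame: np.ndarray,
    roi: GrooveROI,
    peak: dict,
    min_prominence: float | None = None,
    timepoint: float = 0.0,
) -> CondensationMeasurement:
    """Measure one condensation's width from the minor-axis profile.

    The minor-axis profile is computed with the major-axis restriction set
    to the peak's half-max interval (the condensation's length extent).
    The width is the FWHM of the minor profile's most prominent peak; when
    no peak qualifies the width is missing and the measurement is flagged.
    The width is geometrically bounded by the groove's short-axis extent.
    """
    minor = axial_profile(frame, roi, axis="minor", restrict_box=peak["interval"])
    minor_peaks = detect_condensations(minor, min_prominence=min_prominence)
    if minor_peaks:
        best = max(minor_peaks, key=lambda r: r["prominence"])
        width = best["fwhm"]
        width_missing = False
    else:
        width = np.nan
        width_missing = True
    width_clipped = False
    if np.isfinite(width) and width > roi.minor_extent_um:
        width = roi.minor_extent_um
        width_clipped = True
    return CondensationMeasurement(
        position=peak["position"],
        length=peak["fwhm"],
        width=width,
        prominence=peak["prominence"],
        timepoint=timepoint,
        length_interval=peak["interval"],
        end_clipped=peak["end_clipped"],
        width_missing=width_missing,
        width_clipped=width_clipped,
    )


def measure_frame(
    frame: np.ndarray,
    roi: GrooveROI,
    min_prominence: float | None = None,
    timepoint: float = 0.0,
) -> list[CondensationMeasurement]:
    """Detect and measure every condensation in one frame of one groove."""
    major = axial_profile(frame, roi, axis="major")
    peaks = detect_condensations(major, min_prominence=min_prominence)
    out = []
    for pk in peaks:
        m = measure_condensation(
            frame, roi, pk, min_prominence=min_prominence, timepoint=timepoint
        )
        m.aspect_ratio = aspect_ratio(m.length, m.width, roi)
        out.append(m)
    return out


# ---------------------------------------------------------------------------
# derived metrics
# ---------------------------------------------------------------------------

def aspect_ratio(length: float, width: float, roi: GrooveROI) -> float:
    """Aspect ratio under the groove-width convention.

    Width-constrained grooves (25–200 µm): length/width — may drop below 1
    when a condensation is wider than long.  300-µm grooves and TCP, where
    growth is unconstrained: longest/shortest, always ≥ 1.
    """
    if not np.isfinite(width) or width <= 0 or not np.isfinite(length):
        return np.nan
    if roi.constrained:
        return length / width
    return max(length, width) / min(length, width)


def derive_metrics(
    measurements: list[CondensationMeasurement], roi: GrooveROI
) -> dict:
    """Per-groove summary at one timepoint: ARs and density per 100 µm."""
    ars = [aspect_ratio(m.length, m.width, roi) for m in measurements]
    density = len(measurements) / roi.major_extent_um * 100.0
    return {
        "aspect_ratios": ars,
        "count": len(measurements),
        "per_100um": density,
    }


# ---------------------------------------------------------------------------
# backward tracking
# ---------------------------------------------------------------------------

def track_backwards(
    frames: list[list[CondensationMeasurement]],
    base_gate_um: float = 10.0,
    gate_length_factor: float = 0.5,
) -> list[CondensationTrack]:
    """Track condensations from the final frame back to their establishment.

    Every condensation in the final frame starts a track (tracks are
    conserved: one per final-frame condensation).  Going backwards, each
    track is linked to the nearest unclaimed peak in the previous frame
    within a gate of ``max(base_gate_um, gate_length_factor × length)``;
    assignment is greedy, closest pair first, and no two tracks may claim
    the same peak.  A track with no match ends: that frame is its
    establishment time.  Measurements within each track are returned in
    chronological order.
    """
    if not frames or not frames[-1]:
        return []
    tracks = [
        CondensationTrack(track_id=i, measurements=[m])
        for i, m in enumerate(frames[-1])
    ]
    active = list(range(len(tracks)))
    for t in range(len(frames) - 2, -1, -1):
        candidates = frames[t]
        pairs = []
        for ti in active:
            head = tracks[ti].measurements[0]
            gate = max(base_gate_um, gate_length_factor * head.length)
            for ci, cand in enumerate(candidates):
                d = abs(cand.position - head.position)
                if d <= gate:
                    pairs.append((d, ti, ci))
        pairs.sort(key=lambda p: p[0])
        used_tracks: set[int] = set()
        used_cands: set[int] = set()
        matched = []
        for d, ti, ci in pairs:
            if ti in used_tracks or ci in used_cands:
                continue
            used_tracks.add(ti)
            used_cands.add(ci)
            tracks[ti].measurements.insert(0, candidates[ci])
            matched.append(ti)
        active = matched
        if not active:
            break
    return tracks


# ---------------------------------------------------------------------------
# time-series summaries
# ---------------------------------------------------------------------------

def plateau_time(times: np.ndarray, values: np.ndarray, band: float = 0.10) -> float:
    """Earliest time after which a metric stays within ±band of its final value.

    NaNs are ignored.  A constant series plateaus at its first timepoint;
    an all-missing series returns NaN with a warning.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    if not ok.any():
        warnings.warn("plateau_time: all values missing")
        return np.nan
    times, values = times[ok], values[ok]
    final = values[-1]
    tol = band * abs(final)
    inside = np.abs(values - final) <= tol
    # last index where the series is outside the band
    outside = np.nonzero(~inside)[0]
    if outside.size == 0:
        return float(times[0])
    idx = outside[-1] + 1
    return float(times[idx]) if idx < len(times) else float(times[-1])


def summarize_series(
    frames: list[list[CondensationMeasurement]],
    times: np.ndarray,
    roi: GrooveROI,
    band: float = 0.10,
) -> pd.DataFrame:
    """Per-timepoint means of length/width/AR/prominence plus counts.

    Parameters are averaged over the condensations present at each
    timepoint.  The returned frame carries a ``plateau_time_h`` entry per
    metric in its ``attrs``; plateau detection needs ≥ 2 timepoints.
    """
    rows = []
    for t, ms in zip(times, frames):
        lengths = [m.length for m in ms]
        widths = [m.width for m in ms if np.isfinite(m.width)]
        ars = [m.aspect_ratio for m in ms if np.isfinite(m.aspect_ratio)]
        proms = [m.prominence for m in ms]
        rows.append(
            {
                "t_h": t,
                "count": len(ms),
                "per_100um": len(ms) / roi.major_extent_um * 100.0,
                "mean_length_um": np.mean(lengths) if lengths else np.nan,
                "sd_length_um": np.std(lengths, ddof=1) if len(lengths) > 1 else np.nan,
                "mean_width_um": np.mean(widths) if widths else np.nan,
                "sd_width_um": np.std(widths, ddof=1) if len(widths) > 1 else np.nan,
                "mean_aspect_ratio": np.mean(ars) if ars else np.nan,
                "mean_prominence": np.mean(proms) if proms else np.nan,
            }
        )
    summary = pd.DataFrame(rows)
    if len(summary) >= 2:
        plateaus = {}
        for col in ("count", "mean_length_um", "mean_width_um", "mean_aspect_ratio"):
            plateaus[col] = plateau_time(
                summary["t_h"].to_numpy(), summary[col].to_numpy(), band=band
            )
        summary.attrs["plateau_time_h"] = plateaus
    return summary


# ---------------------------------------------------------------------------
# marker-positive nuclei fraction
# ---------------------------------------------------------------------------

def marker_positive_fraction(
    nuclei_frame: np.ndarray,
    marker_frame: np.ndarray,
    region_mask: np.ndarray,
    marker_threshold: float,
    detect_threshold: float | None = None,
    min_distance: int = 3,
) -> float:
    """Fraction of detected nuclei whose marker intensity is above threshold.

    Nuclei are local maxima of the nuclear channel inside ``region_mask``
    above ``detect_threshold`` (default: Otsu of the in-region nuclear
    intensities).  For each nucleus the marker channel is read at the
    nuclear position; the fraction of marker-positive nuclei is returned
    (in [0, 1]).  Zero detected nuclei gives NaN with a warning.
    """
    from skimage import feature, filters

    nuclei_frame = np.asarray(nuclei_frame, dtype=float)
    marker_frame = np.asarray(marker_frame, dtype=float)
    if nuclei_frame.shape != marker_frame.shape:
        raise ValueError("nuclei and marker channels must be registered (same shape)")
    region_mask = np.asarray(region_mask, dtype=bool)
    if detect_threshold is None:
        vals = nuclei_frame[region_mask]
        if vals.size == 0 or vals.min() == vals.max():
            warnings.warn("no nuclei detected in region")
            return np.nan
        detect_threshold = filters.threshold_otsu(vals)
    coords = feature.peak_local_max(
        np.where(region_mask, nuclei_frame, -np.inf),
        min_distance=min_distance,
        threshold_abs=detect_threshold,
    )
    if len(coords) == 0:
        warnings.warn("no nuclei detected in region")
        return np.nan
    marker_vals = marker_frame[coords[:, 0], coords[:, 1]]
    return float(np.mean(marker_vals >= marker_threshold))


def measurements_to_frame(
    tracks: list[CondensationTrack] | None = None,
    frames: list[list[CondensationMeasurement]] | None = None,
) -> pd.DataFrame:
    """Flatten tracks or per-frame measurement lists into a tidy table."""
    rows = []
    if tracks is not None:
        for tr in tracks:
            for m in tr.measurements:
                rows.append(_measurement_row(m, track_id=tr.track_id))
    elif frames is not None:
        for ms in frames:
            for m in ms:
                rows.append(_measurement_row(m, track_id=-1))
    return pd.DataFrame(
        rows,
        columns=[
            "track_id",
            "t_h",
            "position_um",
            "length_um",
            "width_um",
            "prominence",
            "aspect_ratio",
            "end_clipped",
            "width_clipped",
        ],
    )


def _measurement_row(m: CondensationMeasurement, track_id: int) -> dict:
    return {
        "track_id": track_id,
        "t_h": m.timepoint,
        "position_um": m.position,
        "length_um": m.length,
        "width_um": m.width,
        "prominence": m.prominence,
        "aspect_ratio": m.aspect_ratio,
        "end_clipped": m.end_clipped,
        "width_clipped": m.width_clipped,
    }
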