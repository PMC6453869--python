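"""End-to-end orchestration: configuration, I/O, manifests, and the two runs.

``run_micromass_analysis`` takes one or two classes of brightfield images,
segments each, pools descriptor tables per class, and (with two classes)
ranks descriptors by the standardized linear discriminant.

``run_groove_analysis`` takes a multi-page TIFF time series plus groove ROI
definitions, measures condensations per groove per frame, tracks them
backwards from the final frame, and writes measurement, track, and summary
tables grouped by nominal groove width.  With a single frame it runs in
endpoint mode (no tracking, no plateau times).

Every run writes a manifest (resolved configuration, seed, package
version) so outputs are reproducible byte-for-byte under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from skimage import io as skio

from condensia import condseg, grooveprofile, morphometrics, synthgen
from condensia.condseg import SegmentationConfig
from condensia.grooveprofile import GrooveROI

log = logging.getLogger("condensia")

CSV_KW = dict(index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> np.ndarray:
    """Read a single-frame TIFF/PNG image as a float array."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return np.asarray(tifffile.imread(path))
    return np.asarray(skio.imread(path))


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF as a (T, H, W) stack.

    Pages are read individually so a corrupted page aborts with its frame
    index in the error message.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        frames = []
        for k, page in enumerate(tf.pages):
            try:
                frames.append(page.asarray())
            except Exception as exc:  # pragma: no cover - corrupt-file path
                raise IOError(f"failed to read frame {k} of {path}") from exc
    stack = np.asarray(frames)
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a (T, H, W) float stack as a multi-page 32-bit TIFF."""
    tifffile.imwrite(
        Path(path), np.asarray(stack, dtype=np.float32), photometric="minisblack"
    )


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    """Write a label map as 16-bit TIFF."""
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit TIFF")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def write_overlay(path: str | Path, image: np.ndarray, labels: np.ndarray) -> None:
    """QC overlay: grayscale image with label boundaries burned in red."""
    from skimage import segmentation as seg
    from skimage.util import img_as_ubyte

    gray = condseg.to_grayscale(image)
    rng = gray.max() - gray.min()
    gray = (gray - gray.min()) / rng if rng > 0 else np.zeros_like(gray)
    rgb = np.stack([gray] * 3, axis=-1)
    edges = seg.find_boundaries(labels, mode="outer")
    rgb[edges] = [1.0, 0.0, 0.0]
    skio.imsave(Path(path), img_as_ubyte(rgb), check_contrast=False)


def load_rois(path: str | Path, pixel_size: float) -> list[GrooveROI]:
    """Read groove ROI rectangles from a YAML file.

    Expected layout::

        grooves:
          - {x0: 0, y0: 0, x1: 500, y1: 100, nominal_width: 100}
          - {x0: 0, y0: 120, x1: 500, y1: 170, nominal_width: 50, long_axis: horizontal}
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not data or "grooves" not in data:
        raise ValueError(f"no 'grooves' list found in {path}")
    rois = []
    for entry in data["grooves"]:
        rois.append(
            GrooveROI(
                x0=int(entry["x0"]),
                y0=int(entry["y0"]),
                x1=int(entry["x1"]),
                y1=int(entry["y1"]),
                nominal_width=entry.get("nominal_width", 100.0),
                long_axis=entry.get("long_axis", "horizontal"),
                pixel_size=pixel_size,
            )
        )
    return rois


def write_manifest(outdir: Path, config: dict, seed: int | None) -> None:
    """Record the resolved configuration, seed, and version alongside outputs."""
    from condensia import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "condensia_version": __version__,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# micromass run
# ---------------------------------------------------------------------------

def run_micromass_analysis(
    images: dict[str, list],
    outdir: str | Path,
    seg_config: SegmentationConfig | None = None,
    calibration: float = 1.0,
    seed: int | None = None,
    write_qc: bool = False,
) -> dict:
    """Segment, describe, and (with two classes) rank descriptors.

    Parameters
    ----------
    images : dict
        Class name → list of images (arrays) or image paths.  One class
        gives descriptor tables only; two classes add the discriminant.
    outdir : path
        Output directory; receives one descriptor CSV per class,
        ``lda.json`` when applicable, QC overlays, and a manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seg_config = seg_config or SegmentationConfig()

    tables: dict[str, pd.DataFrame] = {}
    for cls, items in images.items():
        parts = []
        for i, item in enumerate(items):
            img = read_image(item) if isinstance(item, (str, Path)) else item
            labels = condseg.segment_micromass(img, seg_config)
            log.info("class %s image %d: %d condensations", cls, i, labels.max())
            tab = morphometrics.descriptor_table(labels, calibration=calibration)
            tab.insert(0, "image_index", i)
            parts.append(tab)
            if write_qc:
                write_overlay(outdir / f"qc_{cls}_{i}.png", img, labels)
        table = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
        tables[cls] = table
        table.to_csv(outdir / f"descriptors_{cls}.csv", **CSV_KW)

    result: dict = {"tables": tables, "lda": None}
    names = list(tables)
    if len(names) == 2:
        a, b = tables[names[0]], tables[names[1]]
        if len(a) < 2 or len(b) < 2:
            log.warning(
                "LDA skipped: need >= 2 condensations per class (got %d, %d)",
                len(a),
                len(b),
            )
        else:
            lda = morphometrics.fit_discriminant(a, b)
            result["lda"] = lda
            with open(outdir / "lda.json", "w") as fh:
                json.dump(lda.to_dict(), fh, indent=2)

    write_manifest(
        outdir,
        {
            "mode": "micromass",
            "classes": {k: len(v) for k, v in images.items()},
            "segmentation": dataclasses.asdict(seg_config),
            "calibration_um_per_px": calibration,
        },
        seed,
    )
    return result


# ---------------------------------------------------------------------------
# groove run
# ---------------------------------------------------------------------------

def run_groove_analysis(
    stack,
    rois: list[GrooveROI],
    outdir: str | Path,
    frame_interval_h: float = 0.5,
    min_prominence: float | None = None,
    seed: int | None = None,
) -> dict:
    """Profile, measure, track, and summarize every groove in a time series.

    ``stack`` is a (T, H, W) array or a multi-page TIFF path; frame ``k``
    is timestamped ``k × frame_interval_h`` hours.  A single frame runs in
    endpoint mode: measurements only, no tracks or plateau times.  Outputs
    per groove: ``measurements_g<i>.csv``, ``tracks_g<i>.csv``; plus
    ``summary.csv`` over all grooves (grouped by nominal width) and a
    manifest.
    """
    if isinstance(stack, (str, Path)):
        stack = read_stack(stack)
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    times = np.arange(stack.shape[0]) * frame_interval_h
    endpoint_mode = stack.shape[0] == 1

    all_summaries = []
    results = []
    for gi, roi in enumerate(rois):
        frames = [
            grooveprofile.measure_frame(
                stack[k], roi, min_prominence=min_prominence, timepoint=times[k]
            )
            for k in range(stack.shape[0])
        ]
        tracks = [] if endpoint_mode else grooveprofile.track_backwards(frames)
        summary = grooveprofile.summarize_series(frames, times, roi)
        summary.insert(0, "groove", gi)
        summary.insert(1, "nominal_width_um", str(roi.nominal_width))
        all_summaries.append(summary)
        results.append({"roi": roi, "frames": frames, "tracks": tracks, "summary": summary})

        grooveprofile.measurements_to_frame(frames=frames).to_csv(
            outdir / f"measurements_g{gi}.csv", **CSV_KW
        )
        if tracks:
            grooveprofile.measurements_to_frame(tracks=tracks).to_csv(
                outdir / f"tracks_g{gi}.csv", **CSV_KW
            )
        log.info(
            "groove %d (%s µm): %d final condensations, %d tracks",
            gi,
            roi.nominal_width,
            len(frames[-1]),
            len(tracks),
        )

    pd.concat(all_summaries, ignore_index=True).to_csv(outdir / "summary.csv", **CSV_KW)
    write_manifest(
        outdir,
        {
            "mode": "grooves",
            "n_frames": int(stack.shape[0]),
            "frame_interval_h": frame_interval_h,
            "n_grooves": len(rois),
            "min_prominence": min_prominence,
        },
        seed,
    )
    return {"grooves": results, "times": times}


# ---------------------------------------------------------------------------
# synthetic-data run
# ---------------------------------------------------------------------------

def run_synth(config: dict, outdir: str | Path) -> None:
    """Generate synthetic data described by a YAML-style config dict.

    ``mode: micromass`` writes ``scene.tif`` + ``truth.csv``;
    ``mode: grooves`` writes ``series.tif`` + ``truth.csv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mode = config.get("mode", "micromass")
    if mode == "micromass":
        fields = {f.name for f in dataclasses.fields(synthgen.MicromassSceneSpec)}
        spec = synthgen.MicromassSceneSpec(
            **{k: v for k, v in config.items() if k in fields}
        )
        if "image_size" in config:
            spec.image_size = tuple(config["image_size"])
        if "area_range" in config:
            spec.area_range = tuple(config["area_range"])
        image, truth = synthgen.generate_micromass_scene(spec)
        tifffile.imwrite(outdir / "scene.tif", image.astype(np.float32))
        truth.to_csv(outdir / "truth.csv", **CSV_KW)
    elif mode == "grooves":
        conds = [
            synthgen.CondensationParams(**c) for c in config.get("condensations", [])
        ]
        fields = {f.name for f in dataclasses.fields(synthgen.GrooveSeriesSpec)}
        spec = synthgen.GrooveSeriesSpec(
            **{k: v for k, v in config.items() if k in fields and k != "condensations"},
            condensations=conds,
        )
        stack, truth = synthgen.generate_groove_series(spec)
        write_stack(outdir / "series.tif", stack)
        truth.to_csv(outdir / "truth.csv", **CSV_KW)
    else:
        raise ValueError(f"unknown synth mode: {mode}")
    write_manifest(outdir, {"mode": f"synth-{mode}", **config}, config.get("seed"))
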