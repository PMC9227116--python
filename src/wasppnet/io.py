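"""Manifest-driven dataset loading, optical-flow preprocessing, PNG export.

Real micro-expression corpora are license-gated, so ingestion is
manifest-driven only: a CSV names every sample, its subject, its label
and where its pixels live (a PNG/JPEG per sample, or one shared ``.npz``
container holding an ``images`` array in manifest row order).  Expected
columns::

    sample_id, subject_id, label, path [, dataset_tag, scale_factor,
    raw_emotion, frame_strategy]

When a ``raw_emotion`` column is present, raw corpus emotions are mapped
to the three-class taxonomy (happiness -> positive; repression, disgust,
fear, sadness, anger, hatred, contempt -> negative; surprise ->
surprise) and the ``label`` column is overwritten.  Corpora without an
annotated apex frame (e.g. the SMIC situation) should record how the
second frame was chosen in ``frame_strategy``; the loader carries the
column through untouched so the choice stays visible.

``flow_from_frame_pair`` computes a dense optical-flow image from an
onset/apex frame pair with the iterative Lucas-Kanade solver; algorithm
name and parameters are recorded in :data:`FLOW_ALGORITHM` so manifests
can cite them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from skimage import transform
from skimage.registration import optical_flow_ilk

from .synthetic_data import FlowDataset, LABELS

__all__ = ["load_manifest", "flow_from_frame_pair", "export_png",
           "DEFAULT_RELABEL", "FLOW_ALGORITHM", "ManifestError"]

REQUIRED_COLUMNS = ("sample_id", "subject_id", "label", "path")

DEFAULT_RELABEL = {
    "happiness": "positive", "happy": "positive",
    "repression": "negative", "disgust": "negative", "fear": "negative",
    "sadness": "negative", "anger": "negative", "hatred": "negative",
    "contempt": "negative",
    "surprise": "surprise",
}

FLOW_ALGORITHM = {"name": "iterative_lucas_kanade",
                  "implementation": "skimage.registration.optical_flow_ilk",
                  "radius": 7, "num_warp": 10, "gaussian": False}


class ManifestError(ValueError):
    pass


def _read_image(path: Path, channels: int, side: int) -> np.ndarray:
    """Read a quantized PNG/JPEG flow image back to (C, side, side) in
    [-1, 1]."""
    from imageio.v3 import imread
    arr = np.asarray(imread(path), dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    arr = arr / 255.0 * 2.0 - 1.0
    if arr.shape[2] < channels:
        raise ManifestError(
            f"{path}: has {arr.shape[2]} channels, need {channels}")
    arr = arr[:, :, :channels]
    if arr.shape[0] != side or arr.shape[1] != side:
        arr = transform.resize(arr, (side, side), order=1,
                               anti_aliasing=True, preserve_range=True)
    return np.ascontiguousarray(arr.transpose(2, 0, 1).astype(np.float32))


def load_manifest(path: str | Path, channels: int = 3,
                  image_side: int = 75,
                  relabel: dict[str, str] | None = None) -> FlowDataset:
    """Load a manifest CSV and its images into a :class:`FlowDataset`.

    Images are resized bilinearly to ``image_side`` and validated against
    the requested channel count.  Errors name the offending manifest row.
    """
    path = Path(path)
    base = path.parent
    manifest = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in manifest.columns]
    if missing:
        raise ManifestError(f"{path}: missing column(s) {missing}")
    dup = manifest["sample_id"].duplicated()
    if dup.any():
        raise ManifestError(
            f"{path}: duplicate sample_id at row(s) "
            f"{[int(i) for i in manifest.index[dup]]}")
    if "raw_emotion" in manifest.columns:
        mapping = relabel or DEFAULT_RELABEL
        mapped = manifest["raw_emotion"].astype(str).str.lower().map(mapping)
        bad = mapped.isna()
        if bad.any():
            raise ManifestError(
                f"{path}: unmappable raw_emotion at row(s) "
                f"{[int(i) for i in manifest.index[bad]]}")
        manifest = manifest.assign(label=mapped)
    for row_i, label in enumerate(manifest["label"]):
        if label not in LABELS:
            raise ManifestError(
                f"{path}: row {row_i}: unknown label {label!r} "
                f"(expected one of {LABELS})")

    paths = manifest["path"].astype(str)
    n = len(manifest)
    images = np.empty((n, channels, image_side, image_side),
                      dtype=np.float32)
    containers: dict[Path, np.ndarray] = {}
    container_cursor: dict[Path, int] = {}
    for row_i, rel in enumerate(paths):
        full = (base / rel).resolve()
        if not full.exists():
            raise ManifestError(f"{path}: row {row_i}: unreadable image "
                                f"{full}")
        if full.suffix == ".npz":
            if full not in containers:
                with np.load(full) as archive:
                    containers[full] = archive["images"].astype(np.float32)
                container_cursor[full] = 0
            stack = containers[full]
            k = container_cursor[full]
            container_cursor[full] += 1
            img = stack[k]
            if img.shape[0] != channels:
                raise ManifestError(
                    f"{path}: row {row_i}: container has {img.shape[0]} "
                    f"channels, need {channels}")
            if img.shape[1] != image_side:
                img = np.stack([
                    transform.resize(plane, (image_side, image_side),
                                     order=1, preserve_range=True)
                    for plane in img]).astype(np.float32)
            images[row_i] = img
        else:
            images[row_i] = _read_image(full, channels, image_side)
    return FlowDataset(images,
                       manifest["label"].to_numpy(dtype=str),
                       manifest["subject_id"].to_numpy(dtype=str),
                       manifest.reset_index(drop=True))


def export_png(dataset: FlowDataset, directory: str | Path) -> pd.DataFrame:
    """Quantize each flow image to per-channel 8-bit PNG (for visual
    inspection) and return a manifest pointing at the files."""
    from imageio.v3 import imwrite
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = dataset.manifest.copy()
    rel_paths = []
    for i in range(len(dataset)):
        img = dataset.images[i]
        q = np.clip((img + 1.0) / 2.0 * 255.0, 0, 255).astype(np.uint8)
        name = f"{manifest['sample_id'].iloc[i]}.png"
        imwrite(directory / name, q.transpose(1, 2, 0))
        rel_paths.append(name)
    manifest["path"] = rel_paths
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


def flow_from_frame_pair(onset: np.ndarray, apex: np.ndarray,
                         channels: int = 3,
                         image_side: int = 75) -> np.ndarray:
    """Dense optical flow (onset -> apex) as a (channels, side, side)
    image: horizontal u, vertical v, and |flow| when ``channels == 3``.

    Frames may be grayscale or RGB (averaged to grayscale) but must share
    one shape.
    """
    onset = np.asarray(onset, dtype=np.float64)
    apex = np.asarray(apex, dtype=np.float64)
    if onset.shape != apex.shape:
        raise ValueError(
            f"frame shapes differ: {onset.shape} vs {apex.shape}")
    if onset.ndim == 3:
        onset = onset.mean(axis=2)
        apex = apex.mean(axis=2)
    flow = optical_flow_ilk(onset, apex, radius=FLOW_ALGORITHM["radius"],
                            num_warp=FLOW_ALGORITHM["num_warp"],
                            gaussian=FLOW_ALGORITHM["gaussian"])
    v, u = flow  # skimage returns (row, col) displacement
    planes = [u, v]
    if channels == 3:
        planes.append(np.hypot(u, v))
    out = np.stack([
        transform.resize(p, (image_side, image_side), order=1,
                         preserve_range=True)
        for p in planes])
    return out.astype(np.float32)
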