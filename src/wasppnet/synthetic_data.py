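"""Synthetic optical-flow image generator.

Real inputs to these classifiers are dense optical-flow fields computed
between the onset and apex frames of a facial micro-expression: subtle,
localized muscle motion whose locus depends on the emotion and whose
spatial extent and magnitude vary with the subject's facial anatomy.
The generator emulates exactly that structure on a schematic face
layout:

* **positive** — bilateral lower-face (mouth-corner) loci with outward
  displacement vectors (a smile pulling the corners apart);
* **negative** — central brow plus lower-face loci with inward vectors
  (brow lowering, mouth tightening);
* **surprise** — upper-face (brow/forehead) loci with upward vectors
  (brow raise).

Each class has a fixed template of 2-3 Gaussian displacement blobs;
blob radius and peak displacement scale linearly with a per-subject
scale factor, which models the subject-anatomy-driven multi-scale
challenge: the same emotion excites wider or narrower regions on
different faces.  Small random jitter of blob centers and amplitudes
plus per-pixel Gaussian noise keep the task non-trivial while remaining
learnable by construction.

Displacement components live in [-1, 1] before noise.  Channel layout is
(u, v) horizontal/vertical displacement, plus the flow magnitude as a
third channel when ``channels == 3``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LABELS", "GeneratorConfig", "FlowDataset", "render_flow_field",
           "generate_dataset", "emulate_combined_profile",
           "load_dataset", "CLASS_TEMPLATES"]

LABELS = ("positive", "negative", "surprise")

# (center_x, center_y, direction_x, direction_y, radius) in unit-square
# face coordinates; y grows downward.
CLASS_TEMPLATES: dict[str, tuple[tuple[float, ...], ...]] = {
    "positive": (
        (0.30, 0.72, -0.80, 0.30, 0.10),   # left mouth corner, outward
        (0.70, 0.72, 0.80, 0.30, 0.10),    # right mouth corner, outward
    ),
    "negative": (
        (0.50, 0.30, 0.00, 0.70, 0.09),    # brow center, pulled down
        (0.35, 0.70, 0.70, -0.20, 0.09),   # mouth corners, pulled inward
        (0.65, 0.70, -0.70, -0.20, 0.09),
    ),
    "surprise": (
        (0.35, 0.28, 0.00, -0.85, 0.11),   # brow raise, upward
        (0.65, 0.28, 0.00, -0.85, 0.11),
        (0.50, 0.80, 0.00, 0.45, 0.10),    # jaw drop, downward
    ),
}

_PEAK_DISPLACEMENT = 0.8     # peak |vector| before jitter, scale 1
_CENTER_JITTER = 0.03        # std of blob-center jitter (unit square)
_AMPLITUDE_JITTER = 0.10     # relative std of per-blob amplitude jitter


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    n_subjects: int = 10
    samples_per_subject: int = 12
    class_probabilities: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    image_side: int = 75
    channels: int = 3
    subject_scale_range: tuple[float, float] = (0.6, 1.6)
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_probabilities) - 1.0) > 1e-9:
            raise ValueError("class_probabilities must sum to 1")
        low, high = self.subject_scale_range
        if not (0 < low <= high):
            raise ValueError("subject_scale_range must satisfy 0 < low <= high")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.channels not in (2, 3):
            raise ValueError("channels must be 2 (u, v) or 3 (u, v, |flow|)")


@dataclasses.dataclass
class FlowDataset:
    """In-memory labeled optical-flow dataset, the unit of LOSO splitting."""
    images: np.ndarray            # (N, C, side, side) float32
    labels: np.ndarray            # (N,) unicode, values in LABELS
    subjects: np.ndarray          # (N,) unicode subject ids
    manifest: pd.DataFrame        # sample_id, subject_id, label, ...

    def __len__(self) -> int:
        return self.images.shape[0]

    def subset(self, index: np.ndarray) -> "FlowDataset":
        return FlowDataset(self.images[index], self.labels[index],
                           self.subjects[index],
                           self.manifest.iloc[index].reset_index(drop=True))

    def save(self, directory: str | Path) -> tuple[Path, Path]:
        """Write ``flow_images.npz`` (array ``images``, row order matches
        the manifest) and ``manifest.csv``; returns both paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        container = directory / "flow_images.npz"
        np.savez_compressed(container, images=self.images)
        manifest = self.manifest.copy()
        manifest["path"] = container.name
        manifest_path = directory / "manifest.csv"
        manifest.to_csv(manifest_path, index=False)
        return container, manifest_path


def load_dataset(directory: str | Path) -> FlowDataset:
    """Inverse of :meth:`FlowDataset.save`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    with np.load(directory / "flow_images.npz") as archive:
        images = archive["images"].astype(np.float32)
    return FlowDataset(images, manifest["label"].to_numpy(dtype=str),
                       manifest["subject_id"].to_numpy(dtype=str), manifest)


def render_flow_field(class_label: str, scale_factor: float,
                      channels: int = 3, side: int = 75,
                      rng: np.random.Generator | None = None,
                      jitter: bool = True) -> np.ndarray:
    """Render one noiseless flow image for a class at a given subject
    scale.

    Blob standard deviation and peak displacement both scale linearly
    with ``scale_factor``.  With ``jitter`` (default) blob centers and
    amplitudes receive small rng-driven perturbations; pass
    ``jitter=False`` for the pure class template.
    """
    if class_label not in CLASS_TEMPLATES:
        raise ValueError(f"unknown class {class_label!r}")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be > 0")
    rng = rng or np.random.default_rng(0)
    yy, xx = np.mgrid[0:side, 0:side]
    xx = (xx + 0.5) / side
    yy = (yy + 0.5) / side
    u = np.zeros((side, side))
    v = np.zeros((side, side))
    for cx, cy, dx, dy, radius in CLASS_TEMPLATES[class_label]:
        amp = _PEAK_DISPLACEMENT * scale_factor
        if jitter:
            cx = cx + rng.normal(0.0, _CENTER_JITTER)
            cy = cy + rng.normal(0.0, _CENTER_JITTER)
            amp = amp * (1.0 + rng.normal(0.0, _AMPLITUDE_JITTER))
        sigma = radius * scale_factor
        blob = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma ** 2))
        u += amp * dx * blob
        v += amp * dy * blob
    u = np.clip(u, -1.0, 1.0)
    v = np.clip(v, -1.0, 1.0)
    planes = [u, v]
    if channels == 3:
        planes.append(np.hypot(u, v))
    return np.stack(planes).astype(np.float32)


def generate_dataset(cfg: GeneratorConfig) -> FlowDataset:
    """Draw a full labeled dataset under ``cfg``.

    Each subject draws one scale factor, fixed across all its samples
    (per-subject facial-scale identity); labels are i.i.d. from
    ``class_probabilities``; additive Gaussian pixel noise at
    ``noise_sigma`` is applied to every channel.  Identical configs
    (including seed) produce byte-identical datasets.
    """
    rng = np.random.default_rng(cfg.seed)
    low, high = cfg.subject_scale_range
    n = cfg.n_subjects * cfg.samples_per_subject
    images = np.empty((n, cfg.channels, cfg.image_side, cfg.image_side),
                      dtype=np.float32)
    labels = np.empty(n, dtype=object)
    subjects = np.empty(n, dtype=object)
    rows = []
    i = 0
    for s in range(cfg.n_subjects):
        subject_id = f"S{s + 1:03d}"
        scale = float(rng.uniform(low, high))
        for _ in range(cfg.samples_per_subject):
            label = LABELS[rng.choice(3, p=cfg.class_probabilities)]
            img = render_flow_field(label, scale, cfg.channels,
                                    cfg.image_side, rng)
            if cfg.noise_sigma > 0:
                img = img + rng.normal(0.0, cfg.noise_sigma,
                                       img.shape).astype(np.float32)
            images[i] = img
            labels[i] = label
            subjects[i] = subject_id
            rows.append({"sample_id": f"{subject_id}_{i:04d}",
                         "subject_id": subject_id, "label": label,
                         "scale_factor": scale, "path": ""})
            i += 1
    manifest = pd.DataFrame(rows)
    return FlowDataset(images, labels.astype(str), subjects.astype(str),
                       manifest)


def emulate_combined_profile(seed: int = 0,
                             samples_per_subject: int = 6) -> GeneratorConfig:
    """Config mirroring the class imbalance and subject count of the
    combined three-corpus benchmark: 74 subjects (26 + 32 + 16) and an
    expected class mix of (109, 250, 82) / 441 for
    (positive, negative, surprise); the per-corpus surprise counts are
    25 + 14 + 43 and the benchmark total is 441."""
    counts = np.array([109.0, 250.0, 82.0])
    probs = counts / counts.sum()
    return GeneratorConfig(
        n_subjects=74, samples_per_subject=samples_per_subject,
        class_probabilities=tuple(float(p) for p in probs), seed=seed)
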