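"""Synthetic sensor fabrication: rendered micromarker frames and word datasets.

This module generates every input the downstream stack consumes:

* grayscale frames of a dark-circular-marker substrate deformed by a known
  homography (optionally with per-marker local displacements and pixel noise),
* deformation sequences emulating throat-muscle motion, and
* labeled 26-class multichannel strain-sequence datasets with subject and
  attachment-state structure, mimicking spelling-alphabet utterances.

Everything is driven by explicit seeds: the same seed yields bit-identical
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SubstrateSpec",
    "DeformationField",
    "SequenceGenConfig",
    "Sample",
    "LabeledDataset",
    "render_marker_image",
    "generate_motion_sequence",
    "generate_word_dataset",
]

_SUPERSAMPLE = 4  # anti-aliasing factor; makes centroids sub-pixel testable


@dataclass(frozen=True)
class SubstrateSpec:
    """Geometry and photometry of the marker substrate.

    Dark circular markers on a light substrate, laid out on a regular
    ``rows x cols`` grid centered in the frame.  Defaults put 30 markers in a
    320x240 field of view, comfortably more than the 16 markers of interest
    the tracking stage selects.
    """

    rows: int = 5
    cols: int = 6
    pitch_px: float = 24.0
    marker_radius_px: float = 6.0
    image_size: tuple[int, int] = (320, 240)  # (width, height)
    fg_intensity: int = 20
    bg_intensity: int = 235

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if not (0 <= self.fg_intensity < self.bg_intensity <= 255):
            raise ValueError("require 0 <= fg < bg <= 255 (dark markers on light substrate)")
        if not self.marker_radius_px < self.pitch_px / 2:
            raise ValueError("marker_radius_px must be < pitch_px / 2")
        if self.image_size[0] < 1 or self.image_size[1] < 1:
            raise ValueError("image_size must be positive")

    def marker_centers(self) -> np.ndarray:
        """Undeformed marker centers, shape (rows*cols, 2) as (x, y) pixels."""
        w, h = self.image_size
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        xs = (np.arange(self.cols) - (self.cols - 1) / 2.0) * self.pitch_px + cx
        ys = (np.arange(self.rows) - (self.rows - 1) / 2.0) * self.pitch_px + cy
        gx, gy = np.meshgrid(xs, ys)
        return np.stack([gx.ravel(), gy.ravel()], axis=1)


@dataclass
class DeformationField:
    """A projective deformation of substrate coordinates.

    ``H`` maps undeformed (x, y) pixel coordinates to deformed ones in
    homogeneous form, with ``H[2, 2] == 1``.  ``local_displacements`` adds an
    optional per-marker (dx, dy) on top of the global transform.
    """

    H: np.ndarray = field(default_factory=lambda: np.eye(3))
    local_displacements: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        if self.H.shape != (3, 3):
            raise ValueError("H must be 3x3")
        if abs(np.linalg.det(self.H)) < 1e-12:
            raise ValueError("H must be invertible")
        self.H = self.H / self.H[2, 2]

    @classmethod
    def identity(cls) -> "DeformationField":
        return cls(np.eye(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 2) points through H (plus local displacements if set)."""
        pts = np.asarray(points, dtype=float)
        ones = np.ones((pts.shape[0], 1))
        ph = np.hstack([pts, ones]) @ self.H.T
        out = ph[:, :2] / ph[:, 2:3]
        if self.local_displacements is not None:
            disp = np.asarray(self.local_displacements, dtype=float)
            if disp.shape != pts.shape:
                raise ValueError("local_displacements must match marker count")
            out = out + disp
        return out


def render_marker_image(
    spec: SubstrateSpec,
    fld: DeformationField,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render an 8-bit grayscale frame of the deformed substrate.

    Markers are drawn as anti-aliased dark circles (4x supersampled coverage)
    at the deformed marker centers; centers remain recoverable to sub-pixel
    precision by intensity-weighted centroiding.  Gaussian pixel noise of
    standard deviation ``noise_sd`` is added when requested.

    Raises
    ------
    ValueError
        If the field maps every marker outside the frame ("empty field of
        view").
    """
    w, h = spec.image_size
    centers = fld.apply(spec.marker_centers())
    r = spec.marker_radius_px
    in_fov = (
        (centers[:, 0] > -r)
        & (centers[:, 0] < w - 1 + r)
        & (centers[:, 1] > -r)
        & (centers[:, 1] < h - 1 + r)
    )
    if not in_fov.any():
        raise ValueError("empty field of view: deformation maps all markers outside the frame")

    s = _SUPERSAMPLE
    coverage = np.zeros((h * s, w * s), dtype=np.float64)
    for cx, cy in centers[in_fov]:
        # supersampled pixel index range covering the circle
        x0 = max(int(np.floor((cx - r - 1) * s)), 0)
        x1 = min(int(np.ceil((cx + r + 1) * s)) + 1, w * s)
        y0 = max(int(np.floor((cy - r - 1) * s)), 0)
        y1 = min(int(np.ceil((cy + r + 1) * s)) + 1, h * s)
        if x0 >= x1 or y0 >= y1:
            continue
        # center of supersampled pixel j is at full-res coordinate (j + 0.5)/s - 0.5
        xs = (np.arange(x0, x1) + 0.5) / s - 0.5
        ys = (np.arange(y0, y1) + 0.5) / s - 0.5
        dx = xs[None, :] - cx
        dy = ys[:, None] - cy
        inside = (dx * dx + dy * dy) <= r * r
        np.maximum(coverage[y0:y1, x0:x1], inside, out=coverage[y0:y1, x0:x1])

    cov = coverage.reshape(h, s, w, s).mean(axis=(1, 3))
    img = spec.bg_intensity + cov * (spec.fg_intensity - spec.bg_intensity)
    if noise_sd > 0:
        rng = np.random.default_rng(0) if rng is None else rng
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_motion_sequence(
    spec: SubstrateSpec,
    pattern: str,
    n_frames: int,
    seed: int = 0,
    amplitude: float = 0.05,
) -> list[DeformationField]:
    """Deformation-field sequence emulating throat-muscle motion.

    Pattern ``"expand_contract"`` models the expansion/contraction phases of
    phonation: one axis contracts while the orthogonal axis elongates, then
    the motion reverses, all about the frame center.  Frame 0 is the identity.
    ``"translate"`` drifts the whole substrate along a seeded direction.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    w, h = spec.image_size
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    T = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1]], dtype=float)
    Tinv = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1]], dtype=float)
    rng = np.random.default_rng(seed)

    fields: list[DeformationField] = [DeformationField.identity()]
    if pattern == "expand_contract":
        jitter = rng.normal(0.0, 0.05 * amplitude, size=n_frames)
        for t in range(1, n_frames):
            # one full expansion (x contracts, y elongates) then reversal
            env = np.sin(np.pi * t / max(n_frames - 1, 1))
            a = amplitude * np.sin(2.0 * np.pi * t / max(n_frames - 1, 1)) + jitter[t] * env
            S = np.diag([1.0 - a, 1.0 + a, 1.0])
            fields.append(DeformationField(T @ S @ Tinv))
    elif pattern == "translate":
        theta = rng.uniform(0, 2 * np.pi)
        step = rng.uniform(0.05, 0.15) * spec.pitch_px
        for t in range(1, n_frames):
            dx, dy = t * step * np.cos(theta), t * step * np.sin(theta)
            fields.append(DeformationField(np.array([[1, 0, dx], [0, 1, dy], [0, 0, 1]], dtype=float)))
    else:
        raise ValueError(f"unknown motion pattern: {pattern!r}")
    return fields[:n_frames]


# ---------------------------------------------------------------------------
# Labeled word-sequence datasets


@dataclass(frozen=True)
class SequenceGenConfig:
    """Conditions for the synthetic word-utterance dataset.

    Emulates a spelling-alphabet corpus: 26 word classes, several subjects
    with individual channel gains and speaking speeds, and a handful of
    attachment states, each tied to a distinct residual-deviation field of the
    marker layout.  Utterance lengths fall in the 100-220 step validity
    window of the preprocessing stage (about 2-4.4 s at 50 Hz).
    """

    n_classes: int = 26
    samples_per_class: int = 10
    n_subjects: int = 6
    n_channels: int = 8
    length_range: tuple[int, int] = (100, 220)
    template_noise_sd: float = 0.05
    channel_noise_sd: float = 0.05
    attachment_states: int = 3
    n_markers: int = 30
    subject_gain_range: tuple[float, float] = (0.8, 1.2)
    subject_speed_range: tuple[float, float] = (0.85, 1.15)
    state_offset_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (100 <= lo <= hi <= 220):
            raise ValueError("length_range must lie within [100, 220]")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.samples_per_class < 1:
            raise ValueError("samples_per_class must be >= 1")
        if self.n_subjects < 1 or self.n_channels < 1 or self.attachment_states < 1:
            raise ValueError("n_subjects, n_channels, attachment_states must be >= 1")


@dataclass
class Sample:
    """One utterance: a T x C strain sequence plus its provenance."""

    values: np.ndarray  # (T, C)
    label: int
    subject: int
    state: int
    residual_map: np.ndarray  # (n_markers,) per-marker deviation magnitudes (px)


@dataclass
class LabeledDataset:
    samples: list[Sample]
    config: SequenceGenConfig
    class_templates: np.ndarray  # (n_classes, template_len, C)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples])

    @property
    def subjects(self) -> np.ndarray:
        return np.array([s.subject for s in self.samples])

    @property
    def states(self) -> np.ndarray:
        return np.array([s.state for s in self.samples])

    def save(self, directory: str | Path) -> None:
        """Serialize as per-sample CSV tables plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"seed": self.config.seed, "n_samples": len(self.samples), "samples": []}
        for i, s in enumerate(self.samples):
            name = f"sample_{i:05d}.csv"
            np.savetxt(directory / name, s.values, delimiter=",")
            np.savetxt(directory / f"residual_{i:05d}.csv", s.residual_map, delimiter=",")
            manifest["samples"].append(
                {
                    "file": name,
                    "residual_file": f"residual_{i:05d}.csv",
                    "label": int(s.label),
                    "subject": int(s.subject),
                    "state": int(s.state),
                    "length": int(s.values.shape[0]),
                }
            )
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "LabeledDataset":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        samples = []
        for m in manifest["samples"]:
            values = np.loadtxt(directory / m["file"], delimiter=",", ndmin=2)
            residual = np.loadtxt(directory / m["residual_file"], delimiter=",", ndmin=1)
            samples.append(Sample(values, m["label"], m["subject"], m["state"], residual))
        cfg = SequenceGenConfig(seed=manifest["seed"])
        return cls(samples, cfg, np.empty((0, 0, 0)))


def _smooth_random_curves(rng: np.random.Generator, n: int, length: int, n_channels: int) -> np.ndarray:
    """Smooth unit-RMS random templates via low-order random Fourier series."""
    t = np.linspace(0.0, 1.0, length)
    out = np.empty((n, length, n_channels))
    n_harm = 6
    for i in range(n):
        for c in range(n_channels):
            a = rng.normal(0.0, 1.0, size=n_harm)
            b = rng.normal(0.0, 1.0, size=n_harm)
            y = np.zeros(length)
            for k in range(1, n_harm + 1):
                y += a[k - 1] * np.sin(2 * np.pi * k * t) + b[k - 1] * np.cos(2 * np.pi * k * t)
            # taper so utterances start and end near rest
            y *= np.sin(np.pi * t) ** 2
            rms = np.sqrt(np.mean(y**2))
            out[i, :, c] = y / (rms + 1e-12)
    return out


def _resample(template: np.ndarray, new_len: int) -> np.ndarray:
    """Linear time-resampling of a (L, C) template to (new_len, C)."""
    L = template.shape[0]
    x_old = np.linspace(0.0, 1.0, L)
    x_new = np.linspace(0.0, 1.0, new_len)
    return np.stack([np.interp(x_new, x_old, template[:, c]) for c in range(template.shape[1])], axis=1)


def generate_word_dataset(config: SequenceGenConfig) -> LabeledDataset:
    """Generate a balanced labeled dataset of synthetic word utterances.

    Per-class smooth random templates are shared across subjects; each sample
    is the class template time-resampled by the subject's speed factor,
    scaled by per-subject channel gains, offset by its attachment state's
    per-channel baseline, and perturbed by template- and channel-level noise.
    Every sample carries a residual-deviation map drawn from its attachment
    state (state mean field plus jitter).

    The output is fully determined by ``config.seed``; with
    ``template_noise_sd=0`` and a single subject and state, all samples of a
    class are identical.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    template_len = 160
    templates = _smooth_random_curves(rng, cfg.n_classes, template_len, cfg.n_channels)

    lo, hi = cfg.length_range
    class_lengths = rng.integers(lo, hi + 1, size=cfg.n_classes)
    subj_gain = rng.uniform(*cfg.subject_gain_range, size=(cfg.n_subjects, cfg.n_channels))
    subj_speed = rng.uniform(*cfg.subject_speed_range, size=cfg.n_subjects)
    # attachment state -> smooth per-marker mean deviation field (px); the
    # per-channel baseline offset is a linear function of the field strength,
    # so residual maps and strain-pattern shifts share correlation structure
    base_field = rng.uniform(0.5, 1.5, size=(cfg.attachment_states, 1))
    phase = rng.uniform(0, 2 * np.pi, size=(cfg.attachment_states, 1))
    idx = np.arange(cfg.n_markers)[None, :]
    state_fields = base_field * (1.2 + np.sin(2 * np.pi * idx / cfg.n_markers + phase))
    coupling = rng.choice([-1.0, 1.0], size=cfg.n_channels) * rng.uniform(0.5, 1.0, size=cfg.n_channels)
    state_offsets = cfg.state_offset_sd * 2.0 * (base_field - 1.0) * coupling[None, :]

    samples: list[Sample] = []
    for label in range(cfg.n_classes):
        for j in range(cfg.samples_per_class):
            subject = j % cfg.n_subjects
            state = int(rng.integers(cfg.attachment_states))
            jitter = rng.normal() if cfg.template_noise_sd > 0 else 0.0
            T = int(round(class_lengths[label] * subj_speed[subject] * (1.0 + 0.1 * cfg.template_noise_sd * jitter)))
            T = int(np.clip(T, lo, hi))
            vals = _resample(templates[label], T)
            vals = vals * subj_gain[subject][None, :]
            vals = vals + state_offsets[state][None, :]
            if cfg.template_noise_sd > 0:
                # smooth low-frequency distortion of the template
                warp = rng.normal(0.0, cfg.template_noise_sd, size=(1, cfg.n_channels))
                vals = vals * (1.0 + warp)
            if cfg.channel_noise_sd > 0:
                vals = vals + rng.normal(0.0, cfg.channel_noise_sd, size=vals.shape)
            residual = np.abs(state_fields[state] + rng.normal(0.0, 0.05, size=cfg.n_markers) * (cfg.template_noise_sd > 0))
            samples.append(Sample(vals, label, subject, state, residual))
    return LabeledDataset(samples, cfg, templates)
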