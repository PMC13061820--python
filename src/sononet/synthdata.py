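"""Synthetic grayscale speckled "ultrasound" exams.

Each exam consists of 5 protocolised scans; each scan visits a predefined
ordered sequence of (class, duration) segments.  Classes 0-5 are rendered as
bright elliptical phantoms over multiplicative-speckle background; class 6
("Other") segments show a *static* ellipse whose axes are drawn from the same
marginal distribution as the pulsating class-3 ("Heart") ellipse, so a single
frame carries no information about the class, while the 10-frame dynamics
(pulsation) separate the two perfectly.  That temporal-only discriminability
is the property the 2D-versus-3D experiments rely on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

from ._errors import InvalidConfigError
from .datapipe import Exam, ExamManifest, ScanVideo, OTHER_CLASS

__all__ = [
    "PhantomSpec",
    "ProtocolSpec",
    "default_protocol",
    "render_frame",
    "generate_exam",
    "generate_dataset",
]

#: per-class base geometry: (center_y, center_x) as fractions, (ax_y, ax_x) as
#: fractions of the image size, and intensity.  Class 3 pulsates; the rest are
#: static with mild per-video jitter.
CLASS_GEOMETRY = {
    0: ((0.30, 0.30), (0.10, 0.22), 0.85),
    1: ((0.30, 0.70), (0.22, 0.10), 0.80),
    2: ((0.70, 0.30), (0.08, 0.08), 0.95),
    3: ((0.50, 0.50), (0.18, 0.14), 0.90),  # heart: pulsating
    4: ((0.70, 0.70), (0.16, 0.24), 0.75),
    5: ((0.50, 0.20), (0.06, 0.14), 0.70),
}

HEART_CLASS = 3
HEART_PULSE_AMPLITUDE = 0.35
HEART_PULSE_PERIOD = 8


@dataclass(frozen=True)
class PhantomSpec:
    """A parametric ellipse with optional dynamics."""

    class_id: int
    center: tuple[float, float]  # (y, x) in pixels
    axes: tuple[float, float]  # (ay, ax) in pixels
    intensity: float
    dynamics: str = "static"  # static | pulsating | drifting
    period: int = HEART_PULSE_PERIOD
    amplitude: float = 0.0
    velocity: tuple[float, float] = (0.0, 0.0)  # px / frame
    phase: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.intensity <= 1.0:
            raise InvalidConfigError("intensity must lie in (0, 1]")
        if min(self.axes) <= 0:
            raise InvalidConfigError("axes must be positive")
        if self.dynamics == "pulsating" and self.period < 2:
            raise InvalidConfigError("pulsation period must be >= 2 frames")
        if self.dynamics not in ("static", "pulsating", "drifting"):
            raise InvalidConfigError(f"unknown dynamics {self.dynamics!r}")

    def at(self, t: int) -> tuple[tuple[float, float], tuple[float, float]]:
        """Center and axes at frame ``t``."""
        cy, cx = self.center
        ay, ax = self.axes
        if self.dynamics == "pulsating":
            s = 1.0 + self.amplitude * np.sin(2.0 * np.pi * t / self.period + self.phase)
            ay, ax = ay * s, ax * s
        elif self.dynamics == "drifting":
            cy += self.velocity[0] * t
            cx += self.velocity[1] * t
        return (cy, cx), (ay, ax)


@dataclass(frozen=True)
class ProtocolSpec:
    """5 ordered scans, each a sequence of (class_id, duration) segments."""

    scans: tuple[tuple[tuple[int, int], ...], ...]

    def __post_init__(self) -> None:
        if len(self.scans) != 5:
            raise InvalidConfigError("a protocol defines exactly 5 scans")
        for scan in self.scans:
            for class_id, duration in scan:
                if not 0 <= class_id <= OTHER_CLASS:
                    raise InvalidConfigError(f"class id {class_id} out of range")
                if duration < 1:
                    raise InvalidConfigError("segment durations must be >= 1")

    def allowed_classes(self, scan_id: int) -> set[int]:
        """Classes that may appear in 1-based scan ``scan_id`` (always
        including Other)."""
        segs = self.scans[scan_id - 1]
        return {c for c, _ in segs} | {OTHER_CLASS}

    def priors(self) -> dict[int, list[int]]:
        return {sid: sorted(self.allowed_classes(sid)) for sid in range(1, 6)}

    def label_histogram(self) -> np.ndarray:
        hist = np.zeros(OTHER_CLASS + 1, dtype=int)
        for scan in self.scans:
            for class_id, duration in scan:
                hist[class_id] += duration
        return hist


def default_protocol(segment: int = 40) -> ProtocolSpec:
    """Five 200-frame scans of ``segment``-frame segments covering classes
    0-5, with Other interleaved."""
    return ProtocolSpec(
        scans=(
            ((0, segment), (6, segment), (0, segment), (6, segment), (0, segment)),
            ((1, segment), (6, segment), (2, segment), (6, segment), (1, segment)),
            ((3, segment), (6, segment), (3, segment), (6, segment), (3, segment)),
            ((4, segment), (6, segment), (4, segment), (6, segment), (4, segment)),
            ((5, segment), (6, segment), (5, segment), (6, segment), (5, segment)),
        )
    )


def _ellipse_mask(size: int, center, axes) -> np.ndarray:
    """Anti-aliased ellipse: 1 inside, 0 outside, soft one-pixel edge."""
    y, x = np.ogrid[:size, :size]
    cy, cx = center
    ay, ax = axes
    r = np.sqrt(((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2)
    edge = 1.0 / min(ay, ax)  # ~one pixel in normalised radius
    return np.clip((1.0 - r) / edge + 0.5, 0.0, 1.0)


def render_frame(
    phantoms: list[PhantomSpec],
    t: int,
    size: int,
    rng: np.random.Generator,
    base_intensity: float = 0.15,
    speckle_shape: float = 4.0,
) -> np.ndarray:
    """One 8-bit frame: phantom intensity profile times unit-mean gamma
    speckle over a dim background."""
    if size < 32:
        raise InvalidConfigError("frame size must be >= 32")
    field_ = np.full((size, size), base_intensity)
    for ph in phantoms:
        center, axes = ph.at(t)
        mask = _ellipse_mask(size, center, axes)
        field_ = field_ + (ph.intensity - base_intensity) * mask
    speckle = rng.gamma(speckle_shape, 1.0 / speckle_shape, size=(size, size))
    img = np.clip(field_ * speckle, 0.0, 1.0)
    return np.round(img * 255.0).astype(np.uint8)


def _heart_phantom(size: int, rng: np.random.Generator) -> PhantomSpec:
    (cy, cx), (ay, ax), inten = CLASS_GEOMETRY[HEART_CLASS]
    jit = rng.uniform(-0.03, 0.03, size=2)
    return PhantomSpec(
        class_id=HEART_CLASS,
        center=((cy + jit[0]) * size, (cx + jit[1]) * size),
        axes=(ay * size, ax * size),
        intensity=inten,
        dynamics="pulsating",
        period=HEART_PULSE_PERIOD,
        amplitude=HEART_PULSE_AMPLITUDE,
        phase=float(rng.uniform(0.0, 2.0 * np.pi)),
    )


def _matched_static_other(size: int, rng: np.random.Generator) -> PhantomSpec:
    """A static ellipse whose axes are one random draw from the pulsating
    heart's instantaneous-axes distribution: indistinguishable from class 3
    on any single frame, trivially separable from its 10-frame dynamics."""
    heart = _heart_phantom(size, rng)
    s = 1.0 + HEART_PULSE_AMPLITUDE * np.sin(rng.uniform(0.0, 2.0 * np.pi))
    return replace(
        heart,
        class_id=OTHER_CLASS,
        axes=(heart.axes[0] * s, heart.axes[1] * s),
        dynamics="static",
        amplitude=0.0,
        phase=0.0,
    )


def _static_class_phantom(class_id: int, size: int, rng: np.random.Generator) -> PhantomSpec:
    (cy, cx), (ay, ax), inten = CLASS_GEOMETRY[class_id]
    jit = rng.uniform(-0.03, 0.03, size=2)
    scale = rng.uniform(0.9, 1.1)
    return PhantomSpec(
        class_id=class_id,
        center=((cy + jit[0]) * size, (cx + jit[1]) * size),
        axes=(ay * size * scale, ax * size * scale),
        intensity=inten,
        dynamics="drifting",
        velocity=(float(rng.uniform(-0.05, 0.05)), float(rng.uniform(-0.05, 0.05))),
    )


def _segment_phantoms(class_id: int, size: int, rng: np.random.Generator) -> list[PhantomSpec]:
    if class_id == HEART_CLASS:
        return [_heart_phantom(size, rng)]
    if class_id == OTHER_CLASS:
        return [_matched_static_other(size, rng)]
    return [_static_class_phantom(class_id, size, rng)]


def generate_exam(
    patient_id: str,
    protocol: ProtocolSpec,
    seed: int,
    size: int = 64,
    out_dir: str | Path | None = None,
    clip_len: int = 10,
) -> tuple[Exam, dict[str, np.ndarray]]:
    """Render one complete 5-scan exam.

    Returns the Exam record and a dict video_id -> (T, H, W) uint8 frame
    stack.  When ``out_dir`` is given the frames are also written as 8-bit
    grayscale PNGs (paths in the manifest are relative to ``out_dir``).
    """
    rng = np.random.default_rng(seed)
    scans = []
    frames_by_video: dict[str, np.ndarray] = {}
    for scan_id in range(1, 6):
        segments = protocol.scans[scan_id - 1]
        video_id = f"{patient_id}_s{scan_id}"
        labels: list[int] = []
        frames: list[np.ndarray] = []
        for class_id, duration in segments:
            if class_id != OTHER_CLASS and duration < clip_len:
                import warnings

                warnings.warn(
                    f"{video_id}: segment of class {class_id} lasts {duration} < "
                    f"{clip_len} frames; it will yield no clips",
                    stacklevel=2,
                )
            phantoms = _segment_phantoms(class_id, size, rng)
            for t in range(duration):
                frames.append(render_frame(phantoms, t, size, rng))
                labels.append(class_id)
        stack = np.stack(frames)
        frames_by_video[video_id] = stack
        paths = [f"{patient_id}/{video_id}_f{i:04d}.png" for i in range(len(frames))]
        if out_dir is not None:
            vdir = Path(out_dir) / patient_id
            vdir.mkdir(parents=True, exist_ok=True)
            for p, img in zip(paths, stack):
                Image.fromarray(img, mode="L").save(Path(out_dir) / p)
        scans.append(ScanVideo(scan_id=scan_id, video_id=video_id, frames=paths, labels=labels))
    return Exam(exam_id=f"{patient_id}_e0", scans=scans), frames_by_video


def generate_dataset(
    n_patients: int,
    protocol: ProtocolSpec | None = None,
    seed: int = 0,
    size: int = 64,
    out_dir: str | Path | None = None,
    clip_len: int = 10,
) -> tuple[ExamManifest, dict[int, list[int]], dict[str, np.ndarray]]:
    """Generate ``n_patients`` complete exams.

    Returns (manifest, scan priors, frames).  With ``out_dir`` set, writes
    ``manifest.json``, ``priors.json`` and the PNG frame tree there.
    """
    if n_patients < 3:
        raise InvalidConfigError("need at least 3 patients to allow a split")
    protocol = protocol or default_protocol()
    seeds = np.random.SeedSequence(seed).spawn(n_patients)
    patients: dict[str, list[Exam]] = {}
    frames: dict[str, np.ndarray] = {}
    for i, child in enumerate(seeds):
        pid = f"p{i:03d}"
        exam, fv = generate_exam(
            pid, protocol, seed=child, size=size, out_dir=out_dir, clip_len=clip_len
        )
        patients[pid] = [exam]
        frames.update(fv)
    manifest = ExamManifest(patients=patients, root=Path(out_dir) if out_dir else None)
    priors = protocol.priors()
    if out_dir is not None:
        manifest.save(Path(out_dir) / "manifest.json")
        with open(Path(out_dir) / "priors.json", "w") as fh:
            json.dump({str(k): v for k, v in priors.items()}, fh, indent=1, sort_keys=True)
    return manifest, priors, frames
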