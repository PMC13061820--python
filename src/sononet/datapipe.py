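"""Exam manifests, clip extraction, patient-disjoint splits, imbalance-aware
sampling and clip-level augmentation.

A *manifest* is the JSON tree ``patients -> exams -> scans``; each scan is an
ordered list of frame image paths plus a per-frame class label in {0..6}.
Clips are runs of ``N`` consecutive identically-labelled frames; the matched
2D dataset takes the central frame of every clip so the two datasets have the
same cardinality and label multiset.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from ._errors import InvalidConfigError

NUM_CLASSES = 7
OTHER_CLASS = 6

__all__ = [
    "NUM_CLASSES",
    "OTHER_CLASS",
    "ScanVideo",
    "Exam",
    "ExamManifest",
    "ClipRecord",
    "SplitSpec",
    "extract_clips",
    "central_frame",
    "build_clip_index",
    "clip_index_to_frame",
    "make_splits",
    "sampler_weights",
    "class_distribution",
    "normalize",
    "draw_augment_params",
    "apply_augment",
    "augment_clip",
    "ClipDataset",
]


# ---------------------------------------------------------------------------
# manifest

@dataclass
class ScanVideo:
    scan_id: int
    video_id: str
    frames: list[str]
    labels: list[int]

    def validate(self) -> None:
        if len(self.frames) != len(self.labels):
            raise InvalidConfigError(
                f"scan {self.video_id}: {len(self.frames)} frames vs "
                f"{len(self.labels)} labels"
            )
        bad = [l for l in self.labels if not 0 <= l < NUM_CLASSES]
        if bad:
            raise InvalidConfigError(f"scan {self.video_id}: labels out of range: {bad[:5]}")


@dataclass
class Exam:
    exam_id: str
    scans: list[ScanVideo]

    @property
    def complete(self) -> bool:
        return sorted(s.scan_id for s in self.scans) == [1, 2, 3, 4, 5]

    def validate(self) -> None:
        ids = [s.scan_id for s in self.scans]
        if len(ids) != len(set(ids)):
            raise InvalidConfigError(f"exam {self.exam_id}: duplicate scan ids {ids}")
        for s in self.scans:
            s.validate()


@dataclass
class ExamManifest:
    patients: dict[str, list[Exam]] = field(default_factory=dict)
    root: Path | None = None  # base directory frame paths are relative to

    def validate(self) -> None:
        for exams in self.patients.values():
            for exam in exams:
                exam.validate()

    def videos(self):
        """Yield (patient_id, ScanVideo) over all exams."""
        for pid, exams in sorted(self.patients.items()):
            for exam in exams:
                for scan in exam.scans:
                    yield pid, scan

    def complete_patients(self) -> list[str]:
        return sorted(
            pid
            for pid, exams in self.patients.items()
            if any(e.complete for e in exams)
        )

    def to_dict(self) -> dict:
        return {
            "patients": [
                {
                    "patient_id": pid,
                    "exams": [
                        {
                            "exam_id": e.exam_id,
                            "complete": e.complete,
                            "scans": [
                                {
                                    "scan_id": s.scan_id,
                                    "video_id": s.video_id,
                                    "frames": s.frames,
                                    "labels": s.labels,
                                }
                                for s in e.scans
                            ],
                        }
                        for e in exams
                    ],
                }
                for pid, exams in sorted(self.patients.items())
            ]
        }

    def save(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "ExamManifest":
        path = Path(path)
        with open(path) as fh:
            d = json.load(fh)
        patients: dict[str, list[Exam]] = {}
        for p in d["patients"]:
            exams = [
                Exam(
                    exam_id=e["exam_id"],
                    scans=[
                        ScanVideo(s["scan_id"], s["video_id"], list(s["frames"]), list(s["labels"]))
                        for s in e["scans"]
                    ],
                )
                for e in p["exams"]
            ]
            patients[p["patient_id"]] = exams
        m = cls(patients=patients, root=path.parent)
        m.validate()
        return m


# ---------------------------------------------------------------------------
# clips

@dataclass(frozen=True)
class ClipRecord:
    """An N-frame clip with a single label; [start, end) is half-open."""

    patient_id: str
    video_id: str
    start: int
    end: int
    label: int
    scan_id: int = 0

    @property
    def central_index(self) -> int:
        return self.start + (self.end - self.start) // 2


def extract_clips(labels, n: int) -> list[tuple[int, int, int]]:
    """Cut maximal constant-label runs into floor(run/N) non-overlapping
    (start, end, label) clips anchored at each run's first frame; remainder
    frames are dropped and no clip crosses a label change."""
    if n < 1:
        raise InvalidConfigError("clip length must be >= 1")
    labels = list(labels)
    clips: list[tuple[int, int, int]] = []
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        for s in range(i, j - n + 1, n):
            clips.append((s, s + n, labels[i]))
        i = j
    return clips


def central_frame(clip: ClipRecord) -> int:
    return clip.central_index


def build_clip_index(manifest: ExamManifest, clip_len: int) -> list[ClipRecord]:
    records = []
    for pid, scan in manifest.videos():
        for start, end, label in extract_clips(scan.labels, clip_len):
            records.append(
                ClipRecord(pid, scan.video_id, start, end, label, scan_id=scan.scan_id)
            )
    return records


def clip_index_to_frame(records: list[ClipRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "video_id": r.video_id,
                "start": r.start,
                "end": r.end,
                "label": r.label,
                "central_index": r.central_index,
                "scan_id": r.scan_id,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# splits

@dataclass
class SplitSpec:
    seed: int
    train: list[str]
    val: list[str]
    test: list[str]

    def assignment(self) -> dict[str, str]:
        out = {}
        for name, pids in (("train", self.train), ("val", self.val), ("test", self.test)):
            for pid in pids:
                out[pid] = name
        return out

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"seed": self.seed, "train": self.train, "val": self.val, "test": self.test},
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def load(cls, path) -> "SplitSpec":
        with open(path) as fh:
            d = json.load(fh)
        return cls(seed=d["seed"], train=d["train"], val=d["val"], test=d["test"])


def make_splits(
    manifest: ExamManifest,
    test_fraction: float = 0.15,
    val_fraction: float = 0.2,
    seed: int = 0,
    test_seed: int | None = None,
) -> SplitSpec:
    """Patient-disjoint train/val/test assignment.

    The test set is drawn only from patients with at least one complete exam,
    at ``test_fraction`` of those patients (rounded down).  The remaining
    patients are split so the training side gets floor(1 - val_fraction);
    both draws are seeded.  ``test_seed`` pins the test draw independently of
    ``seed`` so hold-out reruns can re-randomise train/val while keeping the
    test set fixed.
    """
    complete = manifest.complete_patients()
    if not complete:
        raise InvalidConfigError("no complete exams to draw a test set from")
    all_patients = sorted(manifest.patients)
    n_test = int(len(complete) * test_fraction)
    rng_test = np.random.default_rng(seed if test_seed is None else test_seed)
    test = sorted(rng_test.permutation(complete)[:n_test].tolist())

    remaining = [p for p in all_patients if p not in set(test)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(remaining).tolist()
    n_train = int(len(remaining) * (1.0 - val_fraction))
    train = sorted(order[:n_train])
    val = sorted(order[n_train:])
    return SplitSpec(seed=seed, train=train, val=val, test=test)


# ---------------------------------------------------------------------------
# sampling & statistics

def sampler_weights(labels) -> np.ndarray:
    """Inverse-class-frequency weight per sample (for sampling with
    replacement so each batch is approximately class-balanced)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise InvalidConfigError("cannot compute sampler weights for an empty dataset")
    counts = Counter(labels.tolist())
    return np.array([1.0 / counts[int(l)] for l in labels])


def class_distribution(
    values, num_classes: int = NUM_CLASSES, from_counts: bool = False
) -> np.ndarray:
    """Per-class percentage shares (summing to 100).

    ``values`` is a list of labels, or a length-``num_classes`` count vector
    when ``from_counts`` is true.
    """
    arr = np.asarray(values)
    if arr.size == 0:
        raise InvalidConfigError("empty input")
    if from_counts:
        counts = arr.astype(float)
    else:
        counts = np.bincount(arr.astype(int), minlength=num_classes).astype(float)
    return 100.0 * counts / counts.sum()


def normalize(frames: np.ndarray) -> np.ndarray:
    """8-bit grayscale -> float32 in [0, 1]."""
    return np.asarray(frames, dtype=np.float32) / 255.0


# ---------------------------------------------------------------------------
# augmentation

@dataclass(frozen=True)
class AugmentParams:
    hflip: bool
    vflip: bool
    gamma: float
    scale: float
    angle: float

    @property
    def is_identity(self) -> bool:
        return (
            not self.hflip
            and not self.vflip
            and self.gamma == 1.0
            and self.scale == 1.0
            and self.angle == 0.0
        )


def draw_augment_params(rng: np.random.Generator) -> AugmentParams:
    """One draw of the training augmentation: 50% flips, gamma in [0.7, 1.4],
    scale in [0.8, 1.2], rotation in [-10, +10] degrees."""
    return AugmentParams(
        hflip=bool(rng.random() < 0.5),
        vflip=bool(rng.random() < 0.5),
        gamma=float(rng.uniform(0.7, 1.4)),
        scale=float(rng.uniform(0.8, 1.2)),
        angle=float(rng.uniform(-10.0, 10.0)),
    )


def _resize_about_center(frame: np.ndarray, scale: float) -> np.ndarray:
    from scipy import ndimage

    h, w = frame.shape
    out = ndimage.zoom(frame, scale, order=1, mode="constant", cval=0.0, grid_mode=True)
    oh, ow = out.shape
    if oh >= h:  # centre-crop back
        top, left = (oh - h) // 2, (ow - w) // 2
        return out[top : top + h, left : left + w]
    pad_t, pad_l = (h - oh) // 2, (w - ow) // 2
    padded = np.zeros_like(frame)
    padded[pad_t : pad_t + oh, pad_l : pad_l + ow] = out
    return padded


def apply_augment(frame: np.ndarray, params: AugmentParams) -> np.ndarray:
    """Apply one parameter draw to a single (H, W) frame in [0, 1]."""
    from scipy import ndimage

    out = frame
    if params.hflip:
        out = out[:, ::-1]
    if params.vflip:
        out = out[::-1, :]
    if params.gamma != 1.0:
        out = np.power(np.clip(out, 0.0, 1.0), params.gamma)
    if params.scale != 1.0:
        out = _resize_about_center(np.ascontiguousarray(out), params.scale)
    if params.angle != 0.0:
        out = ndimage.rotate(
            out, params.angle, reshape=False, order=1, mode="constant", cval=0.0
        )
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def augment_clip(frames: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Augment a (T, H, W) clip with a single parameter draw shared by all
    frames, preserving temporal consistency.  Frames must already be
    normalised to [0, 1]."""
    frames = np.asarray(frames)
    if frames.min() < 0.0 or frames.max() > 1.0:
        raise InvalidConfigError("augment_clip expects frames normalised to [0, 1]")
    params = draw_augment_params(rng)
    if params.is_identity:
        return frames.astype(np.float32, copy=True)
    return np.stack([apply_augment(f, params) for f in frames])


# ---------------------------------------------------------------------------
# datasets

class ClipDataset:
    """In-memory clip dataset over a manifest + clip index.

    ``mode='3d'`` items are (1, N, H, W) clips; ``mode='2d'`` items are the
    matched (1, H, W) central frames.  Pixel values are normalised to [0, 1].
    """

    def __init__(
        self,
        manifest: ExamManifest,
        records: list[ClipRecord],
        mode: str = "3d",
        patients: set[str] | None = None,
        labels_keep: set[int] | None = None,
        frames: dict[str, np.ndarray] | None = None,
    ) -> None:
        if mode not in ("2d", "3d"):
            raise InvalidConfigError(f"mode must be '2d' or '3d', got {mode!r}")
        self.mode = mode
        self.records = [
            r
            for r in records
            if (patients is None or r.patient_id in patients)
            and (labels_keep is None or r.label in labels_keep)
        ]
        self._frames: dict[str, np.ndarray] = {}  # video_id -> (T, H, W) uint8
        root = manifest.root or Path(".")
        needed = {r.video_id for r in self.records}
        if frames is not None:  # in-memory frame stacks, no PNG round-trip
            self._frames = {v: frames[v] for v in needed}
        else:
            for _, scan in manifest.videos():
                if scan.video_id in needed:
                    stack = [
                        np.asarray(Image.open(root / f).convert("L")) for f in scan.frames
                    ]
                    self._frames[scan.video_id] = np.stack(stack)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    @property
    def scan_ids(self) -> np.ndarray:
        return np.array([r.scan_id for r in self.records])

    def clip_pixels(self, i: int) -> np.ndarray:
        r = self.records[i]
        return normalize(self._frames[r.video_id][r.start : r.end])

    def __getitem__(self, i: int):
        r = self.records[i]
        clip = self.clip_pixels(i)
        if self.mode == "2d":
            x = clip[r.central_index - r.start][None]  # (1, H, W)
        else:
            x = clip[None]  # (1, N, H, W)
        return x, r.label

    def batch(self, indices, rng: np.random.Generator | None = None):
        """Stack items into (x, y); if ``rng`` is given, augment each clip
        with its own parameter draw (shared across the clip's frames)."""
        xs, ys = [], []
        for i in indices:
            r = self.records[i]
            clip = self.clip_pixels(i)
            if rng is not None:
                clip = augment_clip(clip, rng)
            if self.mode == "2d":
                xs.append(clip[r.central_index - r.start][None])
            else:
                xs.append(clip[None])
            ys.append(r.label)
        return np.stack(xs), np.array(ys)
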