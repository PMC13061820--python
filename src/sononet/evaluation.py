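"""Clip- and video-level evaluation, confusion matrices with class-wise mean
accuracy, and scan-prior logit masking."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import InvalidConfigError
from .datapipe import NUM_CLASSES, OTHER_CLASS

__all__ = [
    "TRAIN_MASK_VALUE",
    "ScanPrior",
    "EvalReport",
    "mask_logits",
    "mask_logits_batch",
    "predict_video",
    "confusion_and_scores",
    "clip_truth_label",
]

#: additive mask used during training so the loss stays finite; inference
#: masking uses -inf.
TRAIN_MASK_VALUE = -1e9


@dataclass(frozen=True)
class ScanPrior:
    """Map scan id -> set of class ids that may appear in that scan."""

    allowed: dict[int, frozenset[int]]

    def __post_init__(self) -> None:
        for sid, classes in self.allowed.items():
            if not classes:
                raise InvalidConfigError(f"scan {sid}: allowed set is empty")
            if OTHER_CLASS not in classes:
                raise InvalidConfigError(
                    f"scan {sid}: the Other class ({OTHER_CLASS}) must always be allowed"
                )

    def __getitem__(self, scan_id: int) -> frozenset[int]:
        return self.allowed[scan_id]

    @classmethod
    def from_dict(cls, d: dict) -> "ScanPrior":
        return cls({int(k): frozenset(int(c) for c in v) for k, v in d.items()})

    @classmethod
    def load(cls, path) -> "ScanPrior":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def mask_logits(logits: np.ndarray, allowed, fill: float = -np.inf) -> np.ndarray:
    """Replace logits of classes outside ``allowed`` by ``fill`` (-inf by
    default, so the softmax renormalises over the allowed classes only)."""
    logits = np.asarray(logits)
    allowed = set(int(a) for a in allowed)
    if not allowed:
        raise InvalidConfigError("allowed class set is empty")
    k = logits.shape[-1]
    if not allowed <= set(range(k)):
        raise InvalidConfigError(f"allowed set {allowed} not a subset of 0..{k - 1}")
    keep = np.zeros(k, dtype=bool)
    keep[sorted(allowed)] = True
    out = np.array(logits, dtype=np.float64, copy=True)
    out[..., ~keep] = fill
    return out


def mask_logits_batch(
    logits: np.ndarray, allowed: np.ndarray, fill: float = TRAIN_MASK_VALUE
) -> np.ndarray:
    """Per-row masking with a boolean (batch, K) allowed matrix."""
    out = np.array(logits, copy=True)
    out[~allowed] = fill
    return out


def clip_truth_label(labels: np.ndarray, rule: str = "central") -> int:
    """Ground-truth label of a possibly mixed-label clip: the central frame's
    label (default) or the majority label."""
    labels = np.asarray(labels)
    if rule == "central":
        return int(labels[len(labels) // 2])
    if rule == "majority":
        return int(np.bincount(labels).argmax())
    raise InvalidConfigError(f"unknown truth rule {rule!r}")


def predict_video(
    model,
    frames: np.ndarray,
    clip_len: int,
    prior_allowed=None,
    batch_size: int = 16,
) -> pd.DataFrame:
    """Classify a video cut into floor(T/N) consecutive non-overlapping
    clips from frame 0.

    ``frames`` is (T, H, W), already normalised to [0, 1].  2D models
    classify the central frame of each clip so both families consume
    identical clip boundaries.  Returns a frame with columns start, end,
    pred and p0..p{K-1}.
    """
    frames = np.asarray(frames, dtype=np.float32)
    t = frames.shape[0]
    if t < clip_len:
        raise InvalidConfigError(f"video has {t} frames < clip length {clip_len}")
    starts = np.arange(0, (t // clip_len) * clip_len, clip_len)
    if model.spatial_only:
        x = np.stack([frames[s + clip_len // 2][None] for s in starts])
    else:
        x = np.stack([frames[s : s + clip_len][None] for s in starts])
    logit_rows = []
    for lo in range(0, len(x), batch_size):
        logit_rows.append(model.logits(x[lo : lo + batch_size], train=False))
    logits = np.concatenate(logit_rows)
    if prior_allowed is not None:
        logits = mask_logits(logits, prior_allowed)
    from .nn import softmax

    probs = softmax(logits, axis=1)
    preds = logits.argmax(axis=1)
    df = pd.DataFrame({"start": starts, "end": starts + clip_len, "pred": preds})
    for c in range(probs.shape[1]):
        df[f"p{c}"] = probs[:, c]
    return df


@dataclass
class EvalReport:
    """Confusion matrix (rows = truth) plus derived scores.

    ``ma``/``sd`` are the mean and population standard deviation of
    per-class recalls over classes with support > 0; classes without support
    are listed in ``absent_classes``.
    """

    confusion: np.ndarray
    overall_accuracy: float
    per_class_recall: np.ndarray
    ma: float
    sd: float
    absent_classes: list[int]
    per_video_accuracy: dict[str, float] | None = None

    @property
    def per_video_mean(self) -> float:
        accs = list(self.per_video_accuracy.values())
        return float(np.mean(accs))

    @property
    def per_video_std(self) -> float:
        accs = list(self.per_video_accuracy.values())
        return float(np.std(accs))

    def to_dict(self) -> dict:
        d = {
            "confusion": self.confusion.tolist(),
            "overall_accuracy": self.overall_accuracy,
            "per_class_recall": [None if np.isnan(r) else r for r in self.per_class_recall],
            "ma": self.ma,
            "sd": self.sd,
            "absent_classes": self.absent_classes,
        }
        if self.per_video_accuracy is not None:
            d["per_video_accuracy"] = self.per_video_accuracy
            d["per_video_mean"] = self.per_video_mean
            d["per_video_std"] = self.per_video_std
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def confusion_and_scores(
    preds, truths, k: int = NUM_CLASSES, video_ids=None
) -> EvalReport:
    """Confusion matrix, overall accuracy, per-class recalls, MA/SD and
    (when ``video_ids`` is given) per-video accuracies."""
    preds = np.asarray(preds)
    truths = np.asarray(truths)
    if preds.shape != truths.shape:
        raise InvalidConfigError(
            f"length mismatch: {preds.shape} predictions vs {truths.shape} truths"
        )
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (truths, preds), 1)
    support = confusion.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(support > 0, np.diag(confusion) / support, np.nan)
    present = support > 0
    ma = float(np.mean(recall[present]))
    sd = float(np.std(recall[present]))
    report = EvalReport(
        confusion=confusion,
        overall_accuracy=float((preds == truths).mean()),
        per_class_recall=recall,
        ma=ma,
        sd=sd,
        absent_classes=[int(c) for c in np.flatnonzero(~present)],
    )
    if video_ids is not None:
        video_ids = np.asarray(video_ids)
        if video_ids.shape != preds.shape:
            raise InvalidConfigError("video_ids length mismatch")
        per_video = {
            str(v): float((preds[video_ids == v] == truths[video_ids == v]).mean())
            for v in np.unique(video_ids)
        }
        report.per_video_accuracy = per_video
    return report
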