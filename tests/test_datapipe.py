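import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sononet._errors import InvalidConfigError
from sononet.datapipe import (
    ClipDataset,
    ClipRecord,
    Exam,
    ExamManifest,
    ScanVideo,
    augment_clip,
    build_clip_index,
    central_frame,
    class_distribution,
    clip_index_to_frame,
    draw_augment_params,
    apply_augment,
    extract_clips,
    make_splits,
    normalize,
    sampler_weights,
)

# the per-class training-set cardinalities printed in the source publication
PRINTED_COUNTS = [1168, 3362, 768, 3244, 4381, 643, 12428]


class TestExtractClips:
    def test_single_run_with_remainder(self):
        clips = extract_clips([3] * 25, 10)
        assert clips == [(0, 10, 3), (10, 20, 3)]

    def test_runs_not_crossed(self):
        labels = [1] * 10 + [2] * 10
        clips = extract_clips(labels, 10)
        assert clips == [(0, 10, 1), (10, 20, 2)]

    def test_too_short_run(self):
        assert extract_clips([5] * 9, 10) == []

    def test_empty(self):
        assert extract_clips([], 10) == []

    def test_invalid_n(self):
        with pytest.raises(InvalidConfigError):
            extract_clips([1, 2], 0)

    def test_anchored_at_run_start(self):
        labels = [0] * 3 + [1] * 12 + [0] * 3
        assert extract_clips(labels, 5) == [(3, 8, 1), (8, 13, 1)]

    @given(
        labels=st.lists(st.integers(min_value=0, max_value=3), max_size=60),
        n=st.integers(min_value=1, max_value=12),
    )
    @settings(max_examples=200, deadline=None)
    def test_count_equals_sum_of_floor_runs(self, labels, n):
        # brute-force oracle: count maximal runs and sum floor(run / n)
        runs, i = [], 0
        while i < len(labels):
            j = i
            while j < len(labels) and labels[j] == labels[i]:
                j += 1
            runs.append(j - i)
            i = j
        clips = extract_clips(labels, n)
        assert len(clips) == sum(r // n for r in runs)
        for s, e, label in clips:
            assert e - s == n
            assert all(l == label for l in labels[s:e])


class TestCentralFrame:
    @pytest.mark.parametrize(
        "start,end,expected", [(0, 10, 5), (10, 20, 15), (0, 5, 2)]
    )
    def test_examples(self, start, end, expected):
        clip = ClipRecord("p", "v", start, end, 0)
        assert central_frame(clip) == expected


def _manifest_with_patients(n_total, n_complete):
    """Synthetic label-only manifest: first ``n_complete`` patients have all
    5 scans, the rest have 4."""
    patients = {}
    for i in range(n_total):
        pid = f"p{i:04d}"
        n_scans = 5 if i < n_complete else 4
        scans = [
            ScanVideo(sid, f"{pid}_s{sid}", [f"{pid}/{sid}_{t}.png" for t in range(10)], [6] * 10)
            for sid in range(1, n_scans + 1)
        ]
        patients[pid] = [Exam(exam_id=f"{pid}_e0", scans=scans)]
    return ExamManifest(patients=patients)


class TestSplits:
    def test_printed_cohort_counts(self):
        """413 patients with 374 complete exams at a 15% complete-exam test
        fraction gives 56 test and 357 remaining patients; 80/20 on the
        remainder gives 285 train and 72 val."""
        manifest = _manifest_with_patients(413, 374)
        split = make_splits(manifest, 0.15, 0.2, seed=0)
        assert len(split.test) == 56
        assert len(split.train) + len(split.val) == 357
        assert len(split.train) == 285
        assert len(split.val) == 72

    def test_partition_property(self):
        manifest = _manifest_with_patients(20, 12)
        for seed in range(3):
            split = make_splits(manifest, 0.25, 0.2, seed=seed)
            train, val, test = set(split.train), set(split.val), set(split.test)
            assert not (train & val or train & test or val & test)
            assert train | val | test == set(manifest.patients)

    def test_test_only_from_complete(self):
        manifest = _manifest_with_patients(10, 4)
        split = make_splits(manifest, 0.5, 0.2, seed=1)
        complete = set(manifest.complete_patients())
        assert set(split.test) <= complete

    def test_reproducible_and_test_fixed_across_seeds(self):
        manifest = _manifest_with_patients(30, 20)
        s0 = make_splits(manifest, 0.25, 0.2, seed=0, test_seed=9)
        s0b = make_splits(manifest, 0.25, 0.2, seed=0, test_seed=9)
        s1 = make_splits(manifest, 0.25, 0.2, seed=1, test_seed=9)
        assert s0.train == s0b.train and s0.val == s0b.val and s0.test == s0b.test
        assert s0.test == s1.test
        assert s0.train != s1.train

    def test_no_complete_exams(self):
        manifest = _manifest_with_patients(5, 0)
        with pytest.raises(InvalidConfigError):
            make_splits(manifest, 0.15, 0.2, seed=0)

    def test_save_load_roundtrip(self, tmp_path):
        manifest = _manifest_with_patients(12, 8)
        split = make_splits(manifest, 0.25, 0.2, seed=3)
        path = tmp_path / "split.json"
        split.save(path)
        from sononet.datapipe import SplitSpec

        loaded = SplitSpec.load(path)
        assert loaded.train == split.train
        assert loaded.test == split.test


class TestSamplerWeights:
    def test_inverse_frequency_ratio(self):
        w = sampler_weights([0, 1, 1, 1])
        assert w[0] / w[1] == pytest.approx(3.0)

    def test_single_class_uniform(self):
        w = sampler_weights([2, 2, 2])
        assert len(set(w.tolist())) == 1

    def test_printed_counts_ordering(self):
        labels = np.concatenate([[c] * n for c, n in enumerate(PRINTED_COUNTS)])
        w = sampler_weights(labels)
        per_class = {c: w[labels == c][0] for c in range(7)}
        assert max(per_class, key=per_class.get) == 5  # rarest class
        assert min(per_class, key=per_class.get) == 6  # most frequent class

    def test_empty_raises(self):
        with pytest.raises(InvalidConfigError):
            sampler_weights([])

    def test_weighted_draws_near_uniform(self):
        """10k replacement draws from the printed-count distribution land
        within 2 percentage points of uniform per class."""
        labels = np.concatenate([[c] * n for c, n in enumerate(PRINTED_COUNTS)])
        w = sampler_weights(labels)
        rng = np.random.default_rng(0)
        draws = rng.choice(labels, size=10_000, replace=True, p=w / w.sum())
        shares = np.bincount(draws, minlength=7) / 10_000
        assert np.abs(shares - 1 / 7).max() < 0.02


class TestClassDistribution:
    def test_printed_majority_share(self):
        shares = class_distribution(PRINTED_COUNTS, from_counts=True)
        assert round(shares[6], 1) == 47.8

    def test_printed_minority_shares(self):
        shares = class_distribution(PRINTED_COUNTS, from_counts=True)
        assert round(shares[0], 1) == 4.5
        # the source table truncates 2.95 to 2.9; allow either rounding
        assert abs(shares[2] - 2.9) < 0.06
        assert round(shares[5], 1) == 2.5

    def test_sums_to_100(self):
        shares = class_distribution([0, 1, 1, 3, 6, 6, 6])
        assert shares.sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_class(self):
        shares = class_distribution([4, 4, 4])
        assert shares[4] == 100.0

    def test_empty(self):
        with pytest.raises(InvalidConfigError):
            class_distribution([])


class TestNormalize:
    @pytest.mark.parametrize("v,expected", [(255, 1.0), (0, 0.0), (128, 128 / 255)])
    def test_values(self, v, expected):
        out = normalize(np.array([[v]], dtype=np.uint8))
        assert out[0, 0] == pytest.approx(expected)
        assert out.dtype == np.float32


class TestAugment:
    def test_identity_draw(self, rng):
        from sononet.datapipe import AugmentParams

        frames = rng.random((3, 32, 32)).astype(np.float32)
        params = AugmentParams(False, False, 1.0, 1.0, 0.0)
        assert params.is_identity
        out = np.stack([apply_augment(f, params) for f in frames])
        np.testing.assert_array_equal(out, frames)

    def test_bounds_and_shape(self, rng):
        frames = rng.random((5, 40, 40)).astype(np.float32)
        for _ in range(10):
            out = augment_clip(frames, rng)
            assert out.shape == frames.shape
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_temporal_consistency(self, rng):
        """Frame 0 of the augmented clip equals the same transform applied
        to frame 0 alone (parameters are drawn once per clip)."""
        frames = np.random.default_rng(5).random((4, 32, 32)).astype(np.float32)
        params_rng = np.random.default_rng(11)
        params = draw_augment_params(params_rng)
        whole = np.stack([apply_augment(f, params) for f in frames])
        single = apply_augment(frames[0], params)
        np.testing.assert_array_equal(whole[0], single)

    def test_rejects_unnormalised(self, rng):
        frames = np.full((2, 32, 32), 255.0, dtype=np.float32)
        with pytest.raises(InvalidConfigError):
            augment_clip(frames, rng)


class TestManifestAndDatasets:
    def test_manifest_roundtrip(self, small_dataset, tmp_path):
        manifest, _, _ = small_dataset
        path = tmp_path / "m.json"
        manifest.save(path)
        loaded = ExamManifest.load(path)
        assert sorted(loaded.patients) == sorted(manifest.patients)
        assert loaded.patients["p000"][0].complete

    def test_clip_index_frame_columns(self, small_clip_index):
        df = clip_index_to_frame(small_clip_index)
        for col in ("patient_id", "video_id", "start", "end", "label", "central_index"):
            assert col in df.columns
        assert (df["end"] - df["start"] == 10).all()
        assert (df["central_index"] == df["start"] + 5).all()

    def test_central_dataset_matches_clip_dataset(self, small_dataset, small_clip_index):
        """The 2D dataset has one frame per clip and the same label multiset."""
        manifest, _, _ = small_dataset
        ds3 = ClipDataset(manifest, small_clip_index, "3d")
        ds2 = ClipDataset(manifest, small_clip_index, "2d")
        assert len(ds2) == len(ds3)
        assert sorted(ds2.labels.tolist()) == sorted(ds3.labels.tolist())
        x2, y2 = ds2[0]
        x3, y3 = ds3[0]
        assert x2.shape == (1, 64, 64)
        assert x3.shape == (1, 10, 64, 64)
        assert y2 == y3
        np.testing.assert_array_equal(x2[0], x3[0, 5])  # central frame

    def test_dataset_values_normalised(self, small_dataset, small_clip_index):
        manifest, _, _ = small_dataset
        ds = ClipDataset(manifest, small_clip_index, "3d")
        x, _ = ds[0]
        assert 0.0 <= x.min() and x.max() <= 1.0
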