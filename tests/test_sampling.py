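"""Imbalance treatments: weights, under/over-sampling epochs, artifacted
batches, augmentation and pacing."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mammobalance as mb
from mammobalance.sampling import (
    artifacted_epoch,
    augment,
    class_weights,
    max_batch_minority_weight,
    minority_pacing_shuffle,
    oversample_epoch,
    realize_batch,
    undersample,
)
from mammobalance.types import BatchPlan, DatasetIndex, Directive, PlanEntry


def make_index(n_benign, n_malignant, split="train", extra_splits=()):
    rows = []
    i = 0
    for label, n in ((0, n_benign), (1, n_malignant)):
        for _ in range(n):
            rows.append(
                {
                    "path": f"img_{i}.png",
                    "patient_id": f"P{i//2:04d}",
                    "breast_id": f"P{i//2:04d}_{'LR'[i%2]}",
                    "laterality": "LR"[i % 2],
                    "view": "CC",
                    "label": label,
                    "split": split,
                }
            )
            i += 1
    for sp, n_b, n_m in extra_splits:
        for label, n in ((0, n_b), (1, n_m)):
            for _ in range(n):
                rows.append(
                    {
                        "path": f"img_{i}.png",
                        "patient_id": f"P{i//2:04d}",
                        "breast_id": f"P{i//2:04d}_{'LR'[i%2]}",
                        "laterality": "LR"[i % 2],
                        "view": "CC",
                        "label": label,
                        "split": sp,
                    }
                )
                i += 1
    return DatasetIndex(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# class weighting
# ---------------------------------------------------------------------------

class TestClassWeights:
    def test_vindr_training_counts(self):
        idx = make_index(13286, 704)
        w = class_weights(idx, "train")
        assert w.w_minority == Fraction(13286, 704)
        assert float(w.w_minority) == pytest.approx(18.87, abs=0.01)
        assert w.w_majority == 1 and w.minority_label == 1

    def test_balanced_counts_weight_one(self):
        w = class_weights(make_index(50, 50), "train")
        assert w.w_minority == 1

    def test_empty_class_rejected(self):
        with pytest.raises(mb.DegenerateInputError):
            class_weights(make_index(10, 0), "train")

    @given(st.integers(1, 300), st.integers(1, 300))
    @settings(max_examples=40, deadline=None)
    def test_weight_times_minority_equals_majority_exactly(self, n_ben, n_mal):
        idx = make_index(n_ben, n_mal)
        w = class_weights(idx, "train")
        n_min, n_maj = sorted((n_ben, n_mal))
        assert w.w_minority * n_min == n_maj  # exact rational arithmetic
        assert w.w_minority >= 1

    def test_per_batch_weight_bound_at_batch_8(self):
        assert max_batch_minority_weight(8) == 7


# ---------------------------------------------------------------------------
# under-sampling
# ---------------------------------------------------------------------------

class TestUndersample:
    def test_vindr_like_reduction(self):
        idx = make_index(13286, 704)
        out = undersample(idx, "train", seed=0)
        ben, mal = out.counts("train")
        assert (ben, mal) == (704, 704)
        reduction = 1 - len(out) / len(idx)
        assert reduction == pytest.approx(0.90, abs=0.005)

    def test_balanced_input_identity(self):
        idx = make_index(20, 20)
        out = undersample(idx, "train", seed=1)
        assert out.records.equals(idx.records)

    def test_subset_and_deterministic(self):
        idx = make_index(100, 10, extra_splits=[("test", 20, 5)])
        a = undersample(idx, "train", seed=3)
        b = undersample(idx, "train", seed=3)
        assert a.records.equals(b.records)
        kept = set(a.records["path"])
        assert kept <= set(idx.records["path"])
        # other splits untouched
        assert a.counts("test") == idx.counts("test")
        # minority untouched
        assert a.counts("train")[1] == 10


# ---------------------------------------------------------------------------
# over-sampling epochs
# ---------------------------------------------------------------------------

def majority_paths(plans, half):
    out = []
    for p in plans:
        out.extend(e.path for e in p.entries[: min(half, len(p.entries) // 2)])
    return out


class TestOversampleEpoch:
    def test_small_example_enumeration(self):
        idx = make_index(8, 2)
        plans = oversample_epoch(idx, "train", batch_size=8, seed=0)
        assert len(plans) == 2
        maj = [e.path for p in plans for e in p.entries if e.label == 0]
        assert sorted(maj) == sorted(
            idx.records[idx.records["label"] == 0]["path"]
        )
        minority = [e.path for p in plans for e in p.entries if e.label == 1]
        assert len(minority) == 8
        assert set(minority) <= set(idx.records[idx.records["label"] == 1]["path"])

    def test_single_batch_when_majority_fits_half(self):
        idx = make_index(4, 2)
        plans = oversample_epoch(idx, "train", batch_size=8, seed=0)
        assert len(plans) == 1

    def test_majority_seen_exactly_once(self):
        idx = make_index(23, 5)
        plans = oversample_epoch(idx, "train", batch_size=8, seed=7)
        assert len(plans) == int(np.ceil(23 / 4))
        maj = [e.path for p in plans for e in p.entries if e.label == 0]
        assert sorted(maj) == sorted(idx.records[idx.records["label"] == 0]["path"])
        # every batch is half majority, half minority (last possibly short)
        for p in plans:
            labels = [e.label for e in p.entries]
            assert labels.count(0) == labels.count(1)

    def test_odd_batch_size_rejected(self):
        with pytest.raises(mb.ConfigurationError):
            oversample_epoch(make_index(8, 2), "train", batch_size=7, seed=0)

    def test_contracts_on_random_configurations(self, rng):
        for _ in range(50):
            n_maj = int(rng.integers(4, 60))
            n_min = int(rng.integers(1, n_maj + 1))
            bs = int(rng.choice([4, 6, 8]))
            idx = make_index(n_maj, n_min)
            plans = oversample_epoch(idx, "train", bs, seed=int(rng.integers(2**31)))
            maj = [e.path for p in plans for e in p.entries if e.label == 0]
            assert sorted(maj) == sorted(
                idx.records[idx.records["label"] == 0]["path"]
            )
            assert len(plans) == int(np.ceil(n_maj / (bs // 2)))


class TestArtifactedEpoch:
    def test_batch_composition_4_2_2(self):
        idx = make_index(20, 2)
        plans = artifacted_epoch(idx, "train", batch_size=8, seed=0)
        assert len(plans) == 5
        for p in plans:
            as_is_ben = [e for e in p.entries if e.label == 0 and e.directive.kind == "as_is"]
            real_mal = [e for e in p.entries if e.label == 1 and e.directive.kind == "as_is"]
            art = [e for e in p.entries if e.directive.kind == "artifact"]
            assert (len(as_is_ben), len(real_mal), len(art)) == (4, 2, 2)
            # artifact directives reference this batch's own benign records
            ben_paths = {e.path for e in as_is_ben}
            assert all(e.path in ben_paths for e in art)
            assert all(e.directive.k in (1, 2, 3) for e in art)
            # implied labels balance: 4 benign vs 2 real + 2 synthetic malignant
            eff = [e.effective_label for e in p.entries]
            assert eff.count(0) == eff.count(1) == 4

    def test_each_benign_seen_once_as_is(self):
        idx = make_index(20, 2)
        plans = artifacted_epoch(idx, "train", batch_size=8, seed=1)
        as_is = [
            e.path
            for p in plans
            for e in p.entries
            if e.label == 0 and e.directive.kind == "as_is"
        ]
        assert sorted(as_is) == sorted(idx.records[idx.records["label"] == 0]["path"])

    def test_deficient_classes_rejected_by_name(self):
        with pytest.raises(mb.ConfigurationError, match="benign"):
            artifacted_epoch(make_index(2, 5), "train", batch_size=8, seed=0)
        with pytest.raises(mb.ConfigurationError, match="malignant"):
            artifacted_epoch(make_index(10, 1), "train", batch_size=8, seed=0)

    def test_contracts_on_random_configurations(self, rng):
        for _ in range(50):
            n_ben = int(rng.integers(4, 50))
            n_mal = int(rng.integers(2, 20))
            idx = make_index(n_ben, n_mal)
            plans = artifacted_epoch(idx, "train", 8, seed=int(rng.integers(2**31)))
            as_is = [
                e.path
                for p in plans
                for e in p.entries
                if e.label == 0 and e.directive.kind == "as_is"
            ]
            assert sorted(as_is) == sorted(
                idx.records[idx.records["label"] == 0]["path"]
            )
            for p in plans[:-1]:
                arts = [e for e in p.entries if e.directive.kind == "artifact"]
                assert len(arts) == 2

    def test_plans_pure_function_of_seed(self):
        idx = make_index(17, 4)
        a = artifacted_epoch(idx, "train", 8, seed=5)
        b = artifacted_epoch(idx, "train", 8, seed=5)
        assert [p.to_dict() for p in a] == [p.to_dict() for p in b]


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

class TestAugment:
    def test_deterministic(self, rng):
        img = rng.random((128, 128))
        assert np.array_equal(augment(img, seed=3), augment(img, seed=3))

    def test_zero_image_stays_zero(self):
        img = np.zeros((64, 64))
        assert (augment(img, seed=1) == 0).all()

    def test_shape_and_range_preserved(self, rng):
        img = rng.random((100, 80))
        out = augment(img, seed=9)
        assert out.shape == img.shape
        assert out.min() >= 0 and out.max() <= 1

    def test_translation_below_limit_by_cross_correlation(self):
        """Pure-translation augmentations move a centred point target by
        strictly less than the configured limit (phase-correlation oracle)."""
        from skimage.registration import phase_cross_correlation

        img = np.zeros((201, 201))
        img[100, 100] = 1.0  # centre pixel: invariant under vertical flip
        for seed in range(20):
            out = augment(
                img,
                seed=seed,
                max_translate_px=100,
                max_rotate_deg=0.0,
                zoom_range=(1.0, 1.0),
                max_inpaint_patches=0,
            )
            shift, _, _ = phase_cross_correlation(out, img, upsample_factor=1)
            assert np.abs(shift).max() < 100


# ---------------------------------------------------------------------------
# minority pacing
# ---------------------------------------------------------------------------

def _plan_with_count(n_mal, batch_size=8):
    entries = [
        PlanEntry(ref=i, path=f"m{i}", breast_id=f"b{i}", label=1)
        for i in range(n_mal)
    ] + [
        PlanEntry(ref=100 + i, path=f"b{i}", breast_id=f"c{i}", label=0)
        for i in range(batch_size - n_mal)
    ]
    return BatchPlan(entries=entries, batch_size=batch_size)


def window_counts(plans, n_windows=5):
    counts = [
        sum(1 for e in p.entries if e.label == 1 and e.directive.kind == "as_is")
        for p in plans
    ]
    bounds = np.linspace(0, len(plans), n_windows + 1).astype(int)
    return [sum(counts[a:b]) for a, b in zip(bounds[:-1], bounds[1:])]


class TestMinorityPacingShuffle:
    def test_uniform_plans_stay_balanced(self):
        plans = [_plan_with_count(2) for _ in range(10)]
        out = minority_pacing_shuffle(plans, seed=0)
        assert len(out) == 10
        w = window_counts(out)
        assert max(w) - min(w) <= 1

    def test_adversarial_order_rebalanced(self):
        # all the malignant batches piled at the front
        plans = [_plan_with_count(2) for _ in range(5)] + [
            _plan_with_count(0) for _ in range(15)
        ]
        before = window_counts(plans)
        assert max(before) - min(before) > 1
        out = minority_pacing_shuffle(plans, seed=1)
        after = window_counts(out)
        assert max(after) - min(after) <= 1

    def test_empty_plan_list(self):
        assert minority_pacing_shuffle([], seed=0) == []

    def test_batches_preserved_as_multiset(self):
        plans = [_plan_with_count(i % 3) for i in range(12)]
        out = minority_pacing_shuffle(plans, seed=2)
        assert sorted(id(p) for p in plans) == sorted(id(p) for p in out)


# ---------------------------------------------------------------------------
# plan realisation
# ---------------------------------------------------------------------------

class TestRealizeBatch:
    def test_artifact_directives_applied(self, small_preprocessed):
        entries = [
            PlanEntry(ref=0, path="a", breast_id="B0_L", label=0),
            PlanEntry(
                ref=0,
                path="a",
                breast_id="B0_L",
                label=0,
                directive=Directive(kind="artifact", k=1, seed=11),
            ),
        ]
        plan = BatchPlan(entries=entries, batch_size=2)

        def loader(entry):
            m = small_preprocessed.with_pixels(small_preprocessed.pixels)
            m.breast_id = entry.breast_id
            m.label = entry.label
            return m

        out = realize_batch(plan, loader)
        assert out[0].label == 0 and out[1].label == 1
        assert out[1].breast_id == "B0_L+art"
        assert not np.array_equal(out[0].pixels, out[1].pixels)
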