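"""Class-imbalance treatments as dataset transforms and batch plans.

Four treatments are provided for a binary cohort with a majority (usually
benign) and a minority (usually malignant) class:

* **class weighting** — global loss weights ``w_minority =
  n_majority / n_minority`` and ``w_majority = 1``, computed once over the
  training split (per-batch ratios at batch size 8 could never exceed 7,
  which cannot balance a 19:1 cohort);
* **under-sampling** — a fixed random subset of the majority class taken
  once before training so the classes balance;
* **over-sampling** — epochs where every majority record fills the first
  half of some batch exactly once and minority records are drawn with
  replacement into the second halves;
* **artifacting** — batches composed of half as-is benign records, two
  real malignant records, and synthetic-malignant directives pointing at
  two of the batch's own benign records (at batch size 8: 4 + 2 + 2).

Plans are pure functions of ``(index, seed)`` and serialise to JSONL for
replay.  Train-time augmentation (flip / translate / rotate / zoom /
inpaint) and the minority-pacing reshuffle live here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
from skimage.transform import AffineTransform, warp

from .errors import ConfigurationError, DegenerateInputError
from .lesions import artifact_image
from .types import BatchPlan, DatasetIndex, Directive, Mammogram, PlanEntry


# ---------------------------------------------------------------------------
# class weighting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassWeights:
    """Global loss weights; ``w_minority`` is exact (a Fraction)."""

    w_minority: Fraction
    minority_label: int
    w_majority: int = 1


def class_weights(index: DatasetIndex, split: str = "train") -> ClassWeights:
    """Eq.-style global weights from the split's class tallies."""
    n_ben, n_mal = index.counts(split)
    if n_ben == 0 or n_mal == 0:
        raise DegenerateInputError(
            f"split '{split}' lacks a class (benign={n_ben}, malignant={n_mal})"
        )
    if n_mal <= n_ben:
        return ClassWeights(w_minority=Fraction(n_ben, n_mal), minority_label=1)
    return ClassWeights(w_minority=Fraction(n_mal, n_ben), minority_label=0)


def max_batch_minority_weight(batch_size: int = 8) -> int:
    """Largest minority weight any per-batch scheme could produce.

    Enumerates every batch composition with at least one sample of each
    class; the maximum of ``n_majority / n_minority`` is ``batch_size - 1``
    — the reason weights are computed globally rather than per batch.
    """
    if batch_size < 2:
        raise ConfigurationError("batch must hold at least one of each class")
    best = Fraction(0)
    for n_min in range(1, batch_size):
        n_maj = batch_size - n_min
        best = max(best, Fraction(n_maj, n_min))
    return int(best)


# ---------------------------------------------------------------------------
# under-sampling
# ---------------------------------------------------------------------------

def undersample(index: DatasetIndex, split: str, seed: int) -> DatasetIndex:
    """Balance one split by down-sampling its majority class once.

    The majority records of ``split`` are sampled uniformly without
    replacement down to the minority count; other splits and the minority
    class pass through untouched.  The sample is fixed (not per epoch) and
    deterministic in ``seed``.
    """
    n_ben, n_mal = index.counts(split)
    if n_ben == 0 or n_mal == 0:
        raise DegenerateInputError(f"split '{split}' lacks a class")
    maj_label = 0 if n_ben >= n_mal else 1
    n_min = min(n_ben, n_mal)

    df = index.records
    in_split = df["split"] == split
    maj_pos = np.flatnonzero(in_split & (df["label"] == maj_label))
    rng = np.random.default_rng(seed)
    keep_maj = set(rng.choice(maj_pos, size=n_min, replace=False).tolist())
    keep = [
        i
        for i in range(len(df))
        if not (in_split.iloc[i] and df["label"].iloc[i] == maj_label) or i in keep_maj
    ]
    return DatasetIndex(df.iloc[keep])


# ---------------------------------------------------------------------------
# epoch planners
# ---------------------------------------------------------------------------

def _entries(df, positions) -> list[PlanEntry]:
    return [
        PlanEntry(
            ref=int(p),
            path=str(df["path"].iloc[p]),
            breast_id=str(df["breast_id"].iloc[p]),
            label=int(df["label"].iloc[p]),
        )
        for p in positions
    ]


def oversample_epoch(
    index: DatasetIndex, split: str, batch_size: int, seed: int
) -> list[BatchPlan]:
    """One epoch of minority over-sampling.

    Each majority record appears exactly once, in the first half of some
    batch; second halves are uniform draws (with replacement across
    batches) from the minority records.  The final batch may be short, in
    which case its minority half shrinks proportionally so the batch stays
    balanced.
    """
    if batch_size % 2 != 0 or batch_size < 2:
        raise ConfigurationError("batch_size must be even and >= 2")
    n_ben, n_mal = index.counts(split)
    if n_ben == 0 or n_mal == 0:
        raise DegenerateInputError(f"split '{split}' lacks a class")
    maj_label = 0 if n_ben >= n_mal else 1

    df = index.records
    in_split = df["split"] == split
    maj_pos = np.flatnonzero(in_split & (df["label"] == maj_label))
    min_pos = np.flatnonzero(in_split & (df["label"] != maj_label))

    rng = np.random.default_rng(seed)
    order = rng.permutation(maj_pos)
    half = batch_size // 2
    plans = []
    for start in range(0, len(order), half):
        chunk = order[start : start + half]
        minority = rng.choice(min_pos, size=len(chunk), replace=True)
        plans.append(
            BatchPlan(
                entries=_entries(df, list(chunk) + list(minority)),
                batch_size=batch_size,
            )
        )
    return plans


def artifacted_epoch(
    index: DatasetIndex, split: str, batch_size: int = 8, seed: int = 0
) -> list[BatchPlan]:
    """One epoch of the synthetic-lesion batch rule.

    Every batch holds ``batch_size/2`` benign records as-is, 2 real
    malignant records (sampled with replacement — the real minority is
    over-sampled), and ``batch_size/2 - 2`` artifact directives, each
    referencing a benign record already present in the batch with a lesion
    count ``k`` drawn uniformly from {1, 2, 3}.  The epoch ends when every
    benign record has filled an as-is slot once.
    """
    if batch_size % 2 != 0 or batch_size < 6:
        raise ConfigurationError("batch_size must be even and >= 6")
    half = batch_size // 2
    n_art = half - 2
    n_ben, n_mal = index.counts(split)
    if n_ben < half:
        raise ConfigurationError(
            f"need >= {half} benign records in '{split}', found {n_ben}"
        )
    if n_mal < 2:
        raise ConfigurationError(
            f"need >= 2 malignant records in '{split}', found {n_mal}"
        )

    df = index.records
    in_split = df["split"] == split
    ben_pos = np.flatnonzero(in_split & (df["label"] == 0))
    mal_pos = np.flatnonzero(in_split & (df["label"] == 1))

    rng = np.random.default_rng(seed)
    order = rng.permutation(ben_pos)
    plans = []
    for start in range(0, len(order), half):
        chunk = order[start : start + half]
        entries = _entries(df, chunk)
        entries += _entries(df, rng.choice(mal_pos, size=2, replace=True))
        n_here = min(n_art, len(chunk))
        art_refs = rng.choice(chunk, size=n_here, replace=False)
        for p in art_refs:
            entries.append(
                PlanEntry(
                    ref=int(p),
                    path=str(df["path"].iloc[p]),
                    breast_id=str(df["breast_id"].iloc[p]),
                    label=int(df["label"].iloc[p]),
                    directive=Directive(
                        kind="artifact",
                        k=int(rng.integers(1, 4)),
                        seed=int(rng.integers(2**31)),
                    ),
                )
            )
        plans.append(BatchPlan(entries=entries, batch_size=batch_size))
    return plans


def minority_pacing_shuffle(
    plans: Sequence[BatchPlan], window_fraction: float = 0.2, seed: int = 0
) -> list[BatchPlan]:
    """Reorder batches so real-malignant records pace evenly through the epoch.

    Each contiguous ``window_fraction`` stretch of the reordered epoch
    carries the same count of real (as-is, label 1) malignant entries to
    within +-1, provided the per-batch counts make that feasible.  Uses a
    greedy largest-first assignment of batches to windows.
    """
    plans = list(plans)
    if not plans:
        return []
    n_windows = max(1, int(round(1.0 / window_fraction)))
    n = len(plans)
    base, extra = divmod(n, n_windows)
    capacity = [base + (1 if i < extra else 0) for i in range(n_windows)]

    counts = [
        sum(1 for e in p.entries if e.label == 1 and e.directive.kind == "as_is")
        for p in plans
    ]
    order = sorted(range(n), key=lambda i: -counts[i])
    window_sum = [0] * n_windows
    window_members: list[list[int]] = [[] for _ in range(n_windows)]
    for i in order:
        open_windows = [w for w in range(n_windows) if len(window_members[w]) < capacity[w]]
        w = min(open_windows, key=lambda wi: (window_sum[wi], wi))
        window_members[w].append(i)
        window_sum[w] += counts[i]

    rng = np.random.default_rng(seed)
    out = []
    for members in window_members:
        members = list(rng.permutation(members))
        out.extend(plans[int(i)] for i in members)
    return out


# ---------------------------------------------------------------------------
# train-time augmentation
# ---------------------------------------------------------------------------

def augment(
    img: np.ndarray,
    seed: int,
    max_translate_px: int = 100,
    max_rotate_deg: float = 10.0,
    zoom_range: tuple[float, float] = (0.9, 1.1),
    max_inpaint_patches: int = 3,
    max_patch_px: int = 200,
) -> np.ndarray:
    """Randomised train-time augmentation of a normalised image.

    Applies a vertical flip (p = 0.5), an affine with rotation uniform in
    +-``max_rotate_deg``, zoom uniform in ``zoom_range`` and integer
    translation strictly below ``max_translate_px`` per axis, then inpaints
    0-3 rectangular patches (side <= ``max_patch_px``) with their local
    mean.  Output keeps the shape and stays in [0, 1].
    """
    rng = np.random.default_rng(seed)
    img = np.asarray(img, dtype=float)
    out = img
    if rng.random() < 0.5:
        out = np.flipud(out)

    angle = math.radians(rng.uniform(-max_rotate_deg, max_rotate_deg))
    zoom = rng.uniform(*zoom_range)
    t = max(1, max_translate_px)
    tr = int(rng.integers(-(t - 1), t))
    tc = int(rng.integers(-(t - 1), t))

    h, w = out.shape
    center = np.array([w / 2.0, h / 2.0])
    tf = (
        AffineTransform(translation=-center)
        + AffineTransform(rotation=angle, scale=(zoom, zoom))
        + AffineTransform(translation=center + np.array([tc, tr]))
    )
    out = warp(out, tf.inverse, order=1, mode="constant", cval=0.0, preserve_range=True)

    n_patches = int(rng.integers(0, max_inpaint_patches + 1))
    for _ in range(n_patches):
        ph = int(rng.integers(8, min(max_patch_px, h) + 1))
        pw = int(rng.integers(8, min(max_patch_px, w) + 1))
        r0 = int(rng.integers(0, max(1, h - ph + 1)))
        c0 = int(rng.integers(0, max(1, w - pw + 1)))
        region = out[r0 : r0 + ph, c0 : c0 + pw]
        region[...] = region.mean()

    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# plan realisation (the sampler -> trainer contract)
# ---------------------------------------------------------------------------

def realize_batch(
    plan: BatchPlan, loader: Callable[[PlanEntry], Mammogram]
) -> list[Mammogram]:
    """Materialise a batch: load records and apply artifact directives.

    Artifacted records are duplicates of in-batch benign images with
    lesions inserted (the benign original stays in the batch); they get a
    derived breast id so breast-wise evaluation treats them as distinct
    synthetic breasts.
    """
    out = []
    for entry in plan.entries:
        mam = loader(entry)
        if entry.directive.kind == "artifact":
            mam = artifact_image(mam, k=entry.directive.k, seed=entry.directive.seed)
            mam.breast_id = f"{mam.breast_id}+art"
        out.append(mam)
    return out


def plans_to_jsonl(plans: Sequence[BatchPlan], path) -> None:
    import json

    with open(path, "w") as fh:
        for p in plans:
            fh.write(json.dumps(p.to_dict()) + "\n")
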