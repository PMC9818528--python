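"""Breast-wise scoring and the metric suite.

Signs of malignancy may show on only one of the CC/MLO views, so per-image
malignancy scores are averaged into one score per breast before any metric
is computed.  The suite is AUC-ROC (computed as the Mann-Whitney
statistic, so ties count half), sensitivity and specificity at a fixed
operating point,

    Se = TP / (TP + FN),        Sp = TN / (TN + FP),

and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

with the convention MCC = 0 when any denominator factor vanishes.
Standard errors come from bootstrapping breasts (resampling with
replacement, 1000 resamples by default); resamples that lose a class are
redrawn.  The report also carries per-class 20-bin score histograms,
normalised so each class's bars sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import DegenerateInputError
from .types import Mammogram, MetricsReport

N_HIST_BINS = 20


@dataclass(frozen=True)
class PredictionRecord:
    """Per-breast prediction input: one score per view plus the label."""

    breast_id: str
    image_scores: tuple[float, ...]
    label: int

    def __post_init__(self) -> None:
        if len(self.image_scores) == 0:
            raise DegenerateInputError("a breast needs at least one image score")


@dataclass(frozen=True)
class Confusion:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def breast_scores(
    records: Sequence[PredictionRecord],
) -> list[tuple[str, float, int]]:
    """Average each breast's per-view scores into one (id, score, label)."""
    if len(records) == 0:
        raise DegenerateInputError("no prediction records")
    return [
        (r.breast_id, float(np.mean(r.image_scores)), int(r.label)) for r in records
    ]


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC-ROC as the Mann-Whitney statistic.

    Equals ``P(score_mal > score_ben) + 0.5 * P(tie)`` over all
    malignant/benign pairs; computed from midranks in O(n log n).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("AUC needs both classes present")
    ranks = rankdata(scores)  # midranks
    pos_rank_sum = float(ranks[labels == 1].sum())
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def confusion_at(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> Confusion:
    """Confusion table at an operating point; score >= threshold -> malignant."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    return Confusion(
        TP=int((pred & (labels == 1)).sum()),
        TN=int((~pred & (labels == 0)).sum()),
        FP=int((pred & (labels == 0)).sum()),
        FN=int((~pred & (labels == 1)).sum()),
    )


def sens_spec(conf: Confusion) -> tuple[float | None, float | None]:
    """(Se, Sp); a zero denominator yields None (undefined, not an error)."""
    se = conf.TP / (conf.TP + conf.FN) if (conf.TP + conf.FN) > 0 else None
    sp = conf.TN / (conf.TN + conf.FP) if (conf.TN + conf.FP) > 0 else None
    return se, sp


def mcc(conf: Confusion) -> float:
    """Matthews correlation; 0 by convention when a denominator factor is 0."""
    denom = (
        (conf.TP + conf.FP)
        * (conf.TP + conf.FN)
        * (conf.TN + conf.FP)
        * (conf.TN + conf.FN)
    )
    if denom == 0:
        return 0.0
    num = conf.TP * conf.TN - conf.FP * conf.FN
    return float(num) / float(np.sqrt(float(denom)))


def bootstrap_se(
    breast_rows: Sequence[tuple[str, float, int]],
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    n_boot: int = 1000,
    seed: int = 0,
) -> float:
    """Bootstrap standard error of a metric over breast resamples.

    Breasts are resampled with replacement (resample size = original
    size); resamples lacking a class are redrawn, with the total number of
    attempts capped at ``10 * n_boot``.  ``metric_fn(scores, labels)``
    must return a float.
    """
    if len(breast_rows) < 2:
        raise DegenerateInputError("bootstrap needs at least 2 breasts")
    scores = np.array([r[1] for r in breast_rows], dtype=float)
    labels = np.array([r[2] for r in breast_rows], dtype=int)
    if labels.min() == labels.max():
        raise DegenerateInputError("bootstrap needs both classes present")

    rng = np.random.default_rng(seed)
    n = len(breast_rows)
    values = np.empty(n_boot)
    attempts = 0
    got = 0
    cap = 10 * n_boot
    while got < n_boot:
        if attempts >= cap:
            raise DegenerateInputError(
                f"exceeded {cap} bootstrap attempts without both classes"
            )
        idx = rng.integers(0, n, size=n)
        attempts += 1
        lab = labels[idx]
        if lab.min() == lab.max():
            continue
        values[got] = metric_fn(scores[idx], lab)
        got += 1
    return float(values.std(ddof=1))


def score_histograms(
    scores: Sequence[float], labels: Sequence[int], n_bins: int = N_HIST_BINS
) -> dict:
    """Per-class score histograms over [0, 1], each normalised to sum 1."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    out = {}
    for name, lab in (("benign", 0), ("malignant", 1)):
        counts, _ = np.histogram(scores[labels == lab], bins=n_bins, range=(0.0, 1.0))
        total = counts.sum()
        out[name] = (counts / total if total > 0 else counts.astype(float)).tolist()
    return out


# ---------------------------------------------------------------------------
# baseline scorer
# ---------------------------------------------------------------------------

def mean_breast_intensity(mam: Mammogram) -> float:
    """Mean intensity over in-breast pixels.

    After preprocessing the background is exactly zero, so nonzero pixels
    are the breast; on raw images the breast is segmented first with the
    triangle threshold and largest-component rule.
    """
    px = np.asarray(mam.pixels, dtype=float)
    if mam.normalised:
        m = px > 0
    else:
        from .preprocess import (
            breast_mask,
            image_histogram,
            threshold_value,
            triangle_threshold,
        )

        px = np.clip(px, 0.0, 1.0)
        t = triangle_threshold(image_histogram(px))
        _, bm = breast_mask(px, threshold_value(t))
        m = bm.mask
    return float(px[m].mean()) if m.any() else 0.0


def baseline_scores(mams: Sequence[Mammogram]) -> np.ndarray:
    """Cohort-rescaled mean-intensity baseline, in [0, 1].

    Raw per-image mean in-breast intensities are min-max rescaled across
    the evaluated cohort; a cohort of one image (or a constant cohort)
    scores 0.5 by convention.  This trivial scorer stands in for a trained
    classifier in end-to-end smoke tests: lesions add intensity, so it
    separates artifacted from clean images.
    """
    raw = np.array([mean_breast_intensity(m) for m in mams], dtype=float)
    if raw.size == 1 or raw.max() <= raw.min():
        return np.full(raw.shape, 0.5)
    return (raw - raw.min()) / (raw.max() - raw.min())


class MeanIntensityBaseline:
    """Cohort-level scorer object usable with :func:`evaluate`."""

    def cohort_scores(self, mams: Sequence[Mammogram]) -> np.ndarray:
        return baseline_scores(mams)


# ---------------------------------------------------------------------------
# top-level evaluation
# ---------------------------------------------------------------------------

def evaluate(
    mams: Sequence[Mammogram],
    scorer,
    threshold: float = 0.5,
    n_boot: int = 1000,
    seed: int = 0,
) -> MetricsReport:
    """Breast-wise evaluation of a scored cohort.

    ``scorer`` is either a per-image callable mapping a Mammogram to a
    float in [0, 1], or an object with a ``cohort_scores(mams)`` method
    (used by baselines that need cohort-level rescaling).  Images sharing
    a breast id are averaged; a breast is malignant if any of its images
    is.  Pure function of (inputs, scorer, seed).
    """
    if len(mams) == 0:
        raise DegenerateInputError("nothing to evaluate")
    if hasattr(scorer, "cohort_scores"):
        image_scores = np.asarray(scorer.cohort_scores(mams), dtype=float)
    else:
        image_scores = np.array([float(scorer(m)) for m in mams], dtype=float)

    by_breast: dict[str, dict] = {}
    for mam, s in zip(mams, image_scores):
        slot = by_breast.setdefault(mam.breast_id, {"scores": [], "label": 0})
        slot["scores"].append(float(s))
        slot["label"] = max(slot["label"], int(mam.label))
    records = [
        PredictionRecord(bid, tuple(v["scores"]), v["label"])
        for bid, v in by_breast.items()
    ]
    rows = breast_scores(records)
    scores = np.array([r[1] for r in rows])
    labels = np.array([r[2] for r in rows])

    auc = roc_auc(scores, labels)
    conf = confusion_at(scores, labels, threshold)
    se, sp = sens_spec(conf)
    mcc_val = mcc(conf)

    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31, size=4)

    def _se_metric(sc, lb):
        c = confusion_at(sc, lb, threshold)
        v, _ = sens_spec(c)
        return v if v is not None else np.nan

    def _sp_metric(sc, lb):
        c = confusion_at(sc, lb, threshold)
        _, v = sens_spec(c)
        return v if v is not None else np.nan

    auc_se = bootstrap_se(rows, roc_auc, n_boot, int(seeds[0]))
    sens_se = bootstrap_se(rows, _se_metric, n_boot, int(seeds[1]))
    spec_se = bootstrap_se(rows, _sp_metric, n_boot, int(seeds[2]))
    mcc_se = bootstrap_se(
        rows, lambda sc, lb: mcc(confusion_at(sc, lb, threshold)), n_boot, int(seeds[3])
    )

    return MetricsReport(
        auc=auc,
        auc_se=auc_se,
        sensitivity=se,
        sensitivity_se=sens_se,
        specificity=sp,
        specificity_se=spec_se,
        mcc=mcc_val,
        mcc_se=mcc_se,
        score_histogram=score_histograms(scores, labels),
        n_breasts=len(rows),
        threshold=threshold,
        n_boot=n_boot,
    )
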