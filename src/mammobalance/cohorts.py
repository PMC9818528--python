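"""Published compositions of the public FFDM datasets.

These are the class tallies of the mammography cohorts the toolkit is
designed around: a multi-vendor industrial dataset (HMI), VinDr-Mammo,
the Chinese Mammography Database (CMMD), and INBreast (test only).  They
drive the imbalance presets of the phantom generator and the imbalance
arithmetic (class weights, undersampling reduction) without requiring any
dataset download.  Counts are images per split and class as published.
"""

from __future__ import annotations

from fractions import Fraction

REFERENCE_COHORTS: dict[str, dict[str, dict[str, int]]] = {
    "hmi": {
        "train": {"benign": 1952, "malignant": 856},
        "val": {"benign": 402, "malignant": 133},
        "test": {"benign": 257, "malignant": 247},
    },
    "vindr": {
        "train": {"benign": 13286, "malignant": 704},
        "val": {"benign": 1924, "malignant": 86},
        "test": {"benign": 3802, "malignant": 198},
    },
    "cmmd": {
        "train": {"benign": 678, "malignant": 1574},
        "val": {"benign": 216, "malignant": 530},
        "test": {"benign": 218, "malignant": 528},
    },
    "inbreast": {
        "train": {"benign": 0, "malignant": 0},
        "val": {"benign": 0, "malignant": 0},
        "test": {"benign": 310, "malignant": 100},
    },
}


def split_counts(dataset: str, split: str) -> tuple[int, int]:
    """(n_benign, n_malignant) for one split of a reference cohort."""
    c = REFERENCE_COHORTS[dataset][split]
    return c["benign"], c["malignant"]


def dataset_total(dataset: str) -> int:
    return sum(sum(s.values()) for s in REFERENCE_COHORTS[dataset].values())


def class_percentage(dataset: str, split: str, label: str) -> float:
    """Percentage of one class within a split (e.g. benign share of training)."""
    c = REFERENCE_COHORTS[dataset][split]
    total = c["benign"] + c["malignant"]
    return 100.0 * c[label] / total


def malignant_percentage_overall(dataset: str) -> float:
    """Malignant share of the whole dataset, in percent."""
    mal = sum(s["malignant"] for s in REFERENCE_COHORTS[dataset].values())
    return 100.0 * mal / dataset_total(dataset)


def imbalance_ratio(dataset: str, split: str = "train") -> Fraction:
    """Benign:malignant ratio of a split, as an exact fraction."""
    ben, mal = split_counts(dataset, split)
    return Fraction(ben, mal)


# benign:malignant ratios used by the phantom generator's imbalance presets,
# matching the training-set ratios of the reference cohorts (rounded to the
# ratios the datasets are described by: 7:3, 19:1, 3:7).
IMBALANCE_PRESETS: dict[str, tuple[int, int]] = {
    "hmi": (7, 3),
    "vindr": (19, 1),
    "cmmd": (3, 7),
}
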