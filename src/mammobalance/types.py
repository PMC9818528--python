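"""Core data containers shared across the toolkit.

The unit that flows through the pipeline is the :class:`Mammogram`: a 2-D
intensity grid plus the metadata needed for breast-wise evaluation
(laterality, view, patient/breast identity, binary label, pixel spacing).
Cohorts are indexed by a :class:`DatasetIndex`, a thin wrapper around a
pandas DataFrame with the manifest columns
``path,patient_id,breast_id,laterality,view,label,split``.

Batch planners emit :class:`BatchPlan` objects: ordered lists of
``(record, directive)`` pairs, where a directive is either ``as_is`` or
``artifact(k, seed)`` (insert ``k`` synthetic lesions, replayable from the
stored seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

MANIFEST_COLUMNS = [
    "path",
    "patient_id",
    "breast_id",
    "laterality",
    "view",
    "label",
    "split",
]

SPLITS = ("train", "val", "test")


def breast_id_for(patient_id: str, laterality: str) -> str:
    """Breast identity is a pure function of (patient, laterality)."""
    return f"{patient_id}_{laterality}"


@dataclass
class Mammogram:
    """One mammographic image plus its metadata.

    ``pixels`` holds either raw integer data or normalised floats in [0, 1];
    ``normalised`` records whether the full preprocessing chain has run.
    ``annotations`` accumulates ground-truth lesion records when synthetic
    lesions are inserted, and ``extras`` carries non-serialised side
    information such as the phantom generator's ground-truth breast mask.
    """

    pixels: np.ndarray
    laterality: str = "unknown"
    view: str = "unknown"
    patient_id: str = ""
    breast_id: str = ""
    label: int = 0
    pixel_spacing_mm: float = 0.1
    normalised: bool = False
    oriented: bool = False
    annotations: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.breast_id and self.patient_id:
            self.breast_id = breast_id_for(self.patient_id, self.laterality)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray, **changes) -> "Mammogram":
        """Copy of this record with new pixel data (metadata preserved)."""
        out = replace(self, pixels=pixels, **changes)
        out.annotations = list(self.annotations)
        out.extras = dict(self.extras)
        return out


@dataclass(frozen=True)
class BreastMask:
    """Binary support of the breast plus its tight half-open bounding box."""

    mask: np.ndarray
    bbox: tuple[int, int, int, int]  # (row_min, row_max, col_min, col_max)

    @staticmethod
    def from_mask(mask: np.ndarray) -> "BreastMask":
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        if rows.size == 0:
            raise ConfigurationError("empty mask has no bounding box")
        return BreastMask(
            mask=mask.astype(bool),
            bbox=(int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1),
        )

    @property
    def centroid(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.mask)
        return float(rr.mean()), float(cc.mean())


@dataclass
class LesionPatch:
    """A rendered synthetic lesion ready for insertion.

    ``intensity`` is the additive brightness map (zero for distortions,
    which warp rather than add), ``alpha`` the blending support in [0, 1],
    and ``geometry`` the kind-specific ground truth: the radial contour and
    spicule strokes for masses, calcification centres and diameters for
    clusters, and the swirl parameters for distortions.
    """

    intensity: np.ndarray
    alpha: np.ndarray
    kind: str  # {"mass", "calc", "distortion"}
    geometry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.intensity.shape != self.alpha.shape:
            raise ConfigurationError("intensity and alpha shapes differ")

    @property
    def radius_px(self) -> float:
        """Circumscribing radius used for placement and overlap checks."""
        return max(self.intensity.shape) / 2.0


@dataclass(frozen=True)
class Directive:
    """What to do with a record when a batch is realised."""

    kind: str = "as_is"  # {"as_is", "artifact"}
    k: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind}
        if self.kind == "artifact":
            d.update(k=self.k, seed=self.seed)
        return d


@dataclass(frozen=True)
class PlanEntry:
    """One slot of a batch: a manifest record plus its directive."""

    ref: int  # positional index into the manifest
    path: str
    breast_id: str
    label: int
    directive: Directive = Directive()

    @property
    def effective_label(self) -> int:
        """Label the trainer sees: artifacting makes a record malignant."""
        return 1 if self.directive.kind == "artifact" else int(self.label)


@dataclass
class BatchPlan:
    """Ordered batch contents; the sampler-to-trainer contract."""

    entries: list[PlanEntry]
    batch_size: int

    def __len__(self) -> int:
        return len(self.entries)

    def to_dict(self) -> dict:
        return {
            "batch_size": self.batch_size,
            "entries": [
                {
                    "ref": e.ref,
                    "path": e.path,
                    "breast_id": e.breast_id,
                    "label": int(e.label),
                    "directive": e.directive.to_dict(),
                }
                for e in self.entries
            ],
        }


class DatasetIndex:
    """Cohort manifest: one row per image, with split and label.

    Wraps a DataFrame with :data:`MANIFEST_COLUMNS`; samplers consume it and
    the phantom generator produces it.
    """

    def __init__(self, records: pd.DataFrame):
        missing = [c for c in MANIFEST_COLUMNS if c not in records.columns]
        if missing:
            raise ConfigurationError(f"manifest missing columns: {missing}")
        df = records[MANIFEST_COLUMNS].reset_index(drop=True).copy()
        df["label"] = df["label"].astype(int)
        bad = set(df["label"].unique()) - {0, 1}
        if bad:
            raise ConfigurationError(f"labels must be 0/1, found {sorted(bad)}")
        self.records = df

    # -- construction -------------------------------------------------
    @classmethod
    def from_manifest(cls, path: str | Path) -> "DatasetIndex":
        """Read a manifest CSV; relative image paths resolve against it."""
        path = Path(path)
        df = pd.read_csv(path, dtype={"patient_id": str, "breast_id": str})
        root = path.parent
        df["path"] = [
            p if Path(p).is_absolute() else str(root / p) for p in df["path"]
        ]
        return cls(df)

    @classmethod
    def from_rows(cls, rows: Iterable[dict]) -> "DatasetIndex":
        return cls(pd.DataFrame(list(rows), columns=MANIFEST_COLUMNS))

    def to_manifest(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    # -- queries ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def split(self, name: str) -> pd.DataFrame:
        return self.records[self.records["split"] == name]

    def counts(self, split: str | None = None) -> tuple[int, int]:
        """(n_benign, n_malignant) overall or within one split."""
        df = self.records if split is None else self.split(split)
        labels = df["label"].to_numpy()
        return int((labels == 0).sum()), int((labels == 1).sum())

    def subset(self, refs: Sequence[int]) -> "DatasetIndex":
        return DatasetIndex(self.records.iloc[sorted(refs)])


@dataclass
class MetricsReport:
    """Breast-wise metric suite with bootstrap standard errors."""

    auc: float
    auc_se: float
    sensitivity: float | None
    sensitivity_se: float
    specificity: float | None
    specificity_se: float
    mcc: float
    mcc_se: float
    score_histogram: dict  # {"benign": [...], "malignant": [...]} 20 bins each
    n_breasts: int
    threshold: float
    n_boot: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_se": self.auc_se,
            "sensitivity": self.sensitivity,
            "sensitivity_se": self.sensitivity_se,
            "specificity": self.specificity,
            "specificity_se": self.specificity_se,
            "mcc": self.mcc,
            "mcc_se": self.mcc_se,
            "score_histogram": self.score_histogram,
            "n_breasts": self.n_breasts,
            "threshold": self.threshold,
            "n_boot": self.n_boot,
        }
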