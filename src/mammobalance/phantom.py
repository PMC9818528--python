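"""Synthetic FFDM-like phantom mammograms and cohorts.

The generator emulates the geometry a full-field digital mammogram shows:
one bright breast region (a half-ellipse anchored to the chest-wall edge
given by laterality) against a near-black noisy background, a triangular
pectoral wedge on MLO views, and optionally a small burned-in label
marking far from the breast.  Tissue texture is base intensity 0.45 plus
density-scaled band-passed Gaussian noise — the minimal structure the
triangle threshold and the lesion blender need, with no claim of
anatomical realism.

Cohorts pair breasts into patients (one patient = one breast pair,
malignancy assigned breast-wise), write one 16-bit PNG per image plus a
CSV manifest, and keep every patient's images inside a single split.
Malignant phantoms are produced by inserting synthetic lesions into a
clean phantom, so ground-truth annotations are written alongside.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import ConfigurationError
from .lesions import artifact_image
from .types import DatasetIndex, Mammogram, breast_id_for

MIN_DIM_PX = 64


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom mammogram."""

    height_px: int = 512
    width_px: int = 408
    laterality: str = "L"
    view: str = "CC"
    density: float = 0.35  # texture amplitude in [0, 1]
    # 0.2 mm/px makes the default 512 x 408 frame a ~10 x 8 cm field,
    # large enough to host millimetre-scale lesions with realistic sizes
    pixel_spacing_mm: float = 0.2
    add_label_marker: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < MIN_DIM_PX or self.width_px < MIN_DIM_PX:
            raise ConfigurationError(f"phantom dimensions must be >= {MIN_DIM_PX} px")
        if not (0.01 < self.pixel_spacing_mm < 1.0):
            raise ConfigurationError("pixel_spacing_mm must lie in (0.01, 1.0)")
        if not (0.0 <= self.density <= 1.0):
            raise ConfigurationError("density must lie in [0, 1]")
        if self.laterality not in ("L", "R"):
            raise ConfigurationError("laterality must be 'L' or 'R'")
        if self.view not in ("CC", "MLO"):
            raise ConfigurationError("view must be 'CC' or 'MLO'")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a phantom cohort.

    ``n_benign``/``n_malignant`` count breasts; with two views per breast
    each contributes a CC and an MLO image.  Split fractions apply to
    patients (breast pairs), so a patient's images never straddle splits.
    """

    n_benign: int
    n_malignant: int
    views_per_breast: int = 1
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_benign < 0 or self.n_malignant < 0:
            raise ConfigurationError("breast counts must be non-negative")
        if self.views_per_breast not in (1, 2):
            raise ConfigurationError("views_per_breast must be 1 or 2")
        fr = self.split_fractions
        if len(fr) != 3 or any(f < 0 or f > 1 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ConfigurationError("split fractions must lie in [0,1] and sum to 1")


def generate_phantom(spec: PhantomSpec) -> Mammogram:
    """Render one phantom mammogram, deterministic in ``spec.seed``.

    Intensities lie in [0, 1]; the foreground (breast plus pectoral wedge
    on MLO) is a single connected bright region occupying roughly 25-60%
    of the frame, anchored to the chest-wall edge.  The ground-truth
    foreground mask is stored in ``extras['phantom_mask']``.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height_px, spec.width_px

    img = np.clip(rng.normal(0.02, 0.008, size=(H, W)), 0.0, 1.0)

    # half-ellipse breast anchored to the chest-wall edge
    a = (0.40 + 0.06 * rng.random()) * H  # semi-axis along rows
    b = (0.55 + 0.10 * rng.random()) * W  # semi-axis along cols
    cr = H / 2.0 + rng.uniform(-0.04, 0.04) * H
    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    dc = cols if spec.laterality == "L" else (W - 1) - cols
    ellipse = ((rows - cr) / a) ** 2 + (dc / b) ** 2 <= 1.0

    fg = ellipse
    wedge = np.zeros((H, W), dtype=bool)
    if spec.view == "MLO":
        # triangular pectoral wedge hugging the top chest-side corner
        h_p = (0.30 + 0.10 * rng.random()) * H
        w_p = (0.20 + 0.08 * rng.random()) * W
        wedge = (rows / h_p + dc / w_p) <= 1.0
        fg = fg | wedge

    # band-passed Gaussian texture, amplitude scaled by density
    white = rng.standard_normal((H, W))
    band = ndimage.gaussian_filter(white, 4.0) - ndimage.gaussian_filter(white, 16.0)
    std = band.std()
    if std > 0:
        band = band / std
    tissue = 0.45 + 0.3 * spec.density * band
    img = np.where(fg, tissue, img)
    img[wedge] += 0.12

    marker_mask = np.zeros((H, W), dtype=bool)
    if spec.add_label_marker:
        # small bright disc in the background corner away from the chest wall
        radius = max(3, int(round(0.012 * min(H, W))))
        mr = radius + 8
        mc = (W - radius - 8) if spec.laterality == "L" else (radius + 8)
        marker_mask = (rows - mr) ** 2 + (cols - mc) ** 2 <= radius**2
        marker_mask &= ~fg
        img[marker_mask] = 0.9

    img = ndimage.gaussian_filter(img, 0.8)  # soft skin line
    img = np.clip(img, 0.0, 1.0)

    mam = Mammogram(
        pixels=img,
        laterality=spec.laterality,
        view=spec.view,
        pixel_spacing_mm=spec.pixel_spacing_mm,
        label=0,
    )
    mam.extras["phantom_mask"] = fg
    if spec.add_label_marker:
        mam.extras["marker_mask"] = marker_mask
    return mam


def _largest_remainder(n: int, fractions) -> list[int]:
    """Integer allocation of n items over fractions, totals preserved."""
    raw = [n * f for f in fractions]
    base = [int(math.floor(x)) for x in raw]
    short = n - sum(base)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:short]:
        base[i] += 1
    return base


def _assign_splits(patients: list[dict], fractions, rng) -> None:
    """Stratify patients (by having a malignant breast) across splits."""
    groups = {
        True: [p for p in patients if p["malignant"]],
        False: [p for p in patients if not p["malignant"]],
    }
    names = ("train", "val", "test")
    for members in groups.values():
        order = rng.permutation(len(members))
        alloc = _largest_remainder(len(members), fractions)
        bounds = np.cumsum([0] + alloc)
        for si, name in enumerate(names):
            for j in order[bounds[si] : bounds[si + 1]]:
                members[j]["split"] = name


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> DatasetIndex:
    """Write a phantom cohort to disk and return its manifest.

    Layout: ``images/*.png`` (16-bit), ``masks/*.png`` lesion supports,
    ``annotations/*.json`` sidecars for malignant images, ``manifest.csv``.
    Byte-identical across runs with the same spec.
    """
    out_dir = Path(out_dir)
    try:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(exist_ok=True)
        (out_dir / "annotations").mkdir(exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create cohort directory {out_dir}: {exc}") from exc

    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_benign + spec.n_malignant

    # pair breasts into patients; each malignant breast is paired with a
    # benign one while supplies last, so malignancy is breast-wise
    breast_labels = [1] * spec.n_malignant + [0] * spec.n_benign
    patients: list[dict] = []
    mal = [l for l in breast_labels if l == 1]
    ben = [l for l in breast_labels if l == 0]
    while mal or ben:
        pair = []
        if mal:
            pair.append(mal.pop())
            if ben:
                pair.append(ben.pop())
            elif mal:
                pair.append(mal.pop())
        else:
            pair.append(ben.pop())
            if ben:
                pair.append(ben.pop())
        if len(pair) == 2 and rng.random() < 0.5:
            pair.reverse()
        patients.append({"labels": pair, "malignant": any(pair)})

    _assign_splits(patients, spec.split_fractions, rng)

    ss = np.random.SeedSequence(spec.seed)
    image_seeds = iter(ss.spawn(max(1, n_total * spec.views_per_breast * 2)))

    rows = []
    views = ["CC", "MLO"][: spec.views_per_breast]
    for p_idx, patient in enumerate(patients):
        patient_id = f"P{p_idx:04d}"
        for b_idx, label in enumerate(patient["labels"]):
            laterality = "LR"[b_idx]
            breast_id = breast_id_for(patient_id, laterality)
            k = int(rng.integers(1, 4)) if label == 1 else 0
            for view in views:
                child = next(image_seeds)
                img_seed = int(child.generate_state(1)[0] % (2**31))
                pspec = replace(
                    spec.phantom, laterality=laterality, view=view, seed=img_seed
                )
                mam = generate_phantom(pspec)
                mam = replace_meta(mam, patient_id, breast_id, laterality, view)
                if label == 1:
                    art_seed = int(child.generate_state(2)[1] % (2**31))
                    mam = artifact_image(mam, k=k, seed=art_seed)

                stem = f"{patient_id}_{laterality}_{view}"
                img_path = out_dir / "images" / f"{stem}.png"
                _write_png16(img_path, mam.pixels)
                if label == 1:
                    mask_path = out_dir / "masks" / f"{stem}_support.png"
                    support = mam.extras.get(
                        "lesion_support", np.zeros_like(mam.pixels, dtype=bool)
                    )
                    Image.fromarray((support * 255).astype(np.uint8)).save(mask_path)
                    sidecar = {
                        "path": str(img_path.relative_to(out_dir)),
                        "support_mask": str(mask_path.relative_to(out_dir)),
                        "lesions": [
                            {"kind": a["kind"], "center": list(a["center"])}
                            for a in mam.annotations
                        ],
                    }
                    with open(out_dir / "annotations" / f"{stem}.json", "w") as fh:
                        json.dump(sidecar, fh, indent=1)

                rows.append(
                    {
                        "path": str(img_path.relative_to(out_dir)),
                        "patient_id": patient_id,
                        "breast_id": breast_id,
                        "laterality": laterality,
                        "view": view,
                        "label": label,
                        "split": patient["split"],
                    }
                )

    DatasetIndex.from_rows(rows).to_manifest(out_dir / "manifest.csv")
    # cohort-level metadata PNGs cannot carry (notably the pixel spacing)
    with open(out_dir / "cohort.json", "w") as fh:
        json.dump(
            {
                "n_benign": spec.n_benign,
                "n_malignant": spec.n_malignant,
                "views_per_breast": spec.views_per_breast,
                "pixel_spacing_mm": spec.phantom.pixel_spacing_mm,
                "seed": spec.seed,
            },
            fh,
            indent=1,
        )
    # re-read so the returned index carries resolved image paths
    return DatasetIndex.from_manifest(out_dir / "manifest.csv")


def replace_meta(
    mam: Mammogram, patient_id: str, breast_id: str, laterality: str, view: str
) -> Mammogram:
    out = mam.with_pixels(mam.pixels)
    out.patient_id = patient_id
    out.breast_id = breast_id
    out.laterality = laterality
    out.view = view
    return out


def _write_png16(path: Path, img: np.ndarray) -> None:
    arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    Image.fromarray(np.round(arr * 65535).astype(np.uint16)).save(path)
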