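"""Automated mammogram preprocessing.

The chain turns a raw mammogram into the network-ready representation:

1. background removal with the triangle threshold on the 256-bin intensity
   histogram;
2. breast extraction as the largest 4-connected component of the binarised
   image (smaller components — burned-in labels and markings — are zeroed);
3. horizontal orientation so the breast sits on the left edge;
4. crop to the breast's bounding box, rescale so the breast height equals
   the target size (aspect ratio preserved, bilinear), and zero-pad the
   right side to a square target x target frame;
5. histogram equalisation over in-breast pixels only, mapping intensities
   monotonically onto [0, 1] while the background stays exactly 0.

Coordinates are 0-based and row-major; bounding boxes are half-open.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .errors import DegenerateInputError
from .types import BreastMask, Mammogram

N_BINS = 256

# 4-connectivity structuring element for component labelling
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def triangle_threshold(histogram: np.ndarray) -> int:
    """Triangle-method threshold bin for a 256-bin count histogram.

    A straight line is drawn from the histogram peak to the farthest
    non-empty bin on the longer tail; the returned bin maximises the
    perpendicular distance from the histogram curve to that line.  Ties
    break to the smallest bin index; when the two tails are equally long
    the right tail is used.

    Returns an int in [0, len(histogram) - 1].
    """
    h = np.asarray(histogram, dtype=float)
    if h.ndim != 1 or h.size < 1:
        raise DegenerateInputError("histogram must be a 1-D count vector")
    if not np.any(h > 0):
        raise DegenerateInputError("all-zero histogram has no threshold")

    peak = int(np.argmax(h))  # first maximum
    nz = np.flatnonzero(h > 0)
    left_end, right_end = int(nz[0]), int(nz[-1])
    # pick the longer tail (right wins ties)
    if (right_end - peak) >= (peak - left_end):
        end = right_end
    else:
        end = left_end
    if end == peak:
        return peak  # histogram concentrated in a single bin

    lo, hi = (peak, end) if end > peak else (end, peak)
    bins = np.arange(lo, hi + 1)
    # perpendicular distance from (b, h[b]) to the line (peak,h[peak])-(end,h[end])
    dx, dy = end - peak, h[end] - h[peak]
    dist = np.abs(dy * (bins - peak) - dx * (h[lo : hi + 1] - h[peak]))
    dist = dist / float(np.hypot(dx, dy))
    return int(bins[int(np.argmax(dist))])  # argmax -> smallest index on ties


def image_histogram(img: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """256-bin histogram of a float image over [0, 1]."""
    counts, _ = np.histogram(np.asarray(img, dtype=float), bins=n_bins, range=(0.0, 1.0))
    return counts


def threshold_value(bin_index: int, n_bins: int = N_BINS) -> float:
    """Upper edge of the threshold bin: foreground is ``img > value``."""
    return (bin_index + 1) / n_bins


def breast_mask(img: np.ndarray, threshold: float) -> tuple[np.ndarray, BreastMask]:
    """Largest 4-connected component of ``img > threshold``.

    Returns the cleaned image (pixels outside the component zeroed, which
    removes label markings) together with the :class:`BreastMask`.
    """
    img = np.asarray(img, dtype=float)
    binary = img > threshold
    if not binary.any():
        raise DegenerateInputError("no foreground above threshold")
    labels, n = ndimage.label(binary, structure=_CROSS)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1  # ties: smallest label id
    else:
        keep = 1
    mask = labels == keep
    cleaned = np.where(mask, img, 0.0)
    return cleaned, BreastMask.from_mask(mask)


def orient_left(
    img: np.ndarray, mask: BreastMask, laterality: str = "unknown"
) -> tuple[np.ndarray, BreastMask, bool]:
    """Flip horizontally if the breast sits in the right half of the frame.

    The decision uses the mask centroid alone, so it is robust to missing
    or wrong laterality metadata; the flag reports whether a flip happened.
    """
    if not mask.mask.any():
        raise DegenerateInputError("empty mask cannot be oriented")
    _, ccol = mask.centroid
    width = img.shape[1]
    if ccol >= width / 2.0:
        return np.fliplr(img).copy(), BreastMask.from_mask(np.fliplr(mask.mask)), True
    return img, mask, False


def crop_resize_pad(
    img: np.ndarray, mask: BreastMask, target: int = 2048
) -> tuple[np.ndarray, np.ndarray]:
    """Crop to the breast bbox, scale breast height to ``target``, pad right.

    The aspect ratio is preserved; if the scaled width exceeds ``target``
    (very wide breasts) the columns are centre-cropped.  Returns the
    ``target x target`` image and the correspondingly transformed breast
    mask (nearest-neighbour).
    """
    r0, r1, c0, c1 = mask.bbox
    crop = img[r0:r1, c0:c1]
    mcrop = mask.mask[r0:r1, c0:c1]
    crop_h, crop_w = crop.shape
    scale = target / crop_h
    new_w = int(round(crop_w * scale))
    if new_w < 1:
        raise DegenerateInputError("breast too narrow to resize at this target")

    order = 1  # bilinear
    anti = scale < 1.0
    resized = _sk_resize(
        crop, (target, new_w), order=order, mode="edge",
        anti_aliasing=anti, preserve_range=True,
    )
    # bilinear coverage (> 0) rather than nearest: a one-pixel breast tip
    # must survive downsampling, or repeated runs would erode the support
    rmask = _sk_resize(
        mcrop.astype(float), (target, new_w), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    ) > 0.0

    if new_w > target:  # centre-crop overflow
        off = (new_w - target) // 2
        resized = resized[:, off : off + target]
        rmask = rmask[:, off : off + target]
        new_w = target

    out = np.zeros((target, target), dtype=float)
    out[:, :new_w] = resized
    mout = np.zeros((target, target), dtype=bool)
    mout[:, :new_w] = rmask
    return out, mout


def normalise(img: np.ndarray, mask: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """Histogram-equalise in-breast intensities onto [0, 1].

    The cumulative distribution is computed over mask pixels only and
    applied inside the mask; the background stays exactly 0.  The mapping
    is monotone non-decreasing in intensity, sends the in-mask minimum to 0
    and the maximum to 1.  A constant in-mask image maps to 0.5 (documented
    convention for the degenerate case).
    """
    img = np.asarray(img, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    vals = img[mask]
    if vals.size == 0:
        raise DegenerateInputError("empty mask: nothing to normalise")
    mn, mx = float(vals.min()), float(vals.max())
    out = np.zeros_like(img)
    if mx <= mn:
        out[mask] = 0.5
        return out
    # quantise to n_bins levels over the in-mask range
    q = np.clip(((vals - mn) / (mx - mn) * n_bins).astype(int), 0, n_bins - 1)
    counts = np.bincount(q, minlength=n_bins)
    cdf = np.cumsum(counts) / vals.size
    cdf_min = cdf[np.flatnonzero(counts)[0]]
    denom = 1.0 - cdf_min
    if denom <= 0:
        out[mask] = 0.5
        return out
    lut = (cdf - cdf_min) / denom
    # floor at half a bin width: in-mask pixels must stay distinguishable
    # from the exact-zero background, or re-running the chain would erode
    # the breast support (the minimum still maps to 0 within one bin width)
    out[mask] = np.maximum(lut[q], 1.0 / (2 * n_bins))
    return out


def preprocess(raw: Mammogram, target: int = 2048) -> Mammogram:
    """Full chain: threshold -> mask -> orient -> crop/resize/pad -> equalise.

    Accepts integer or float pixel data; integers are scaled by their
    maximum to [0, 1] first.  Stage failures are re-raised with the stage
    name attached.
    """
    img = np.asarray(raw.pixels, dtype=float)
    if np.issubdtype(raw.pixels.dtype, np.integer):
        peak = float(img.max())
        img = img / peak if peak > 0 else img
    else:
        img = np.clip(img, 0.0, 1.0)

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise type(exc)(f"{name}: {exc}") from exc

    if raw.normalised:
        # the chain's own output convention: exact-zero background is the
        # segmentation, so re-running the chain must not re-threshold
        thr = 0.0
    else:
        t_bin = _stage("triangle_threshold", triangle_threshold, image_histogram(img))
        thr = threshold_value(t_bin)
    cleaned, mask = _stage("breast_mask", breast_mask, img, thr)
    oriented, mask, _flipped = _stage("orient_left", orient_left, cleaned, mask, raw.laterality)
    sized, sized_mask = _stage("crop_resize_pad", crop_resize_pad, oriented, mask, target)
    equalised = _stage("normalise", normalise, sized, sized_mask)

    # resizing the breast to `target` rows changes the physical sampling
    crop_h = mask.bbox[1] - mask.bbox[0]
    new_spacing = raw.pixel_spacing_mm * crop_h / target

    out = raw.with_pixels(
        equalised.astype(np.float32),
        normalised=True,
        oriented=True,
        pixel_spacing_mm=new_spacing,
    )
    out.extras["breast_mask"] = sized_mask
    return out
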