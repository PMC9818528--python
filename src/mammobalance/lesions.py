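"""Synthetic malignant lesion rendering and insertion.

Three lesion families are synthesised, matching the radiological findings
most associated with malignancy:

* **Spiculated masses** — a dense core whose outline is drawn from a
  log-normal radial process on the circle: ``r(theta) =
  R * exp(z(theta) - sigma^2 / 2)`` with ``z`` a zero-mean wrapped Gaussian
  process with squared-exponential angular correlation.  The ``-sigma^2/2``
  correction keeps ``E[r] = R``.  Spicules grow outward from the contour
  with an iterative branching walk, tapering in width and intensity.
* **Microcalcification clusters** — small bright elliptical deposits with
  equivalent diameters drawn uniformly between 0.25 and 1 mm, scattered
  inside a convex (elliptical) cluster region.
* **Architectural distortions** — a localised twist of the tissue,
  implemented as an inverse-mapped swirl: the output pixel at polar offset
  ``(rho, phi)`` from the centre samples the input at angle
  ``phi + strength * exp(-rho / r_eff)`` with ``r_eff = radius * ln(2)/5``
  (bilinear interpolation), so the twist decays smoothly to the identity.

Insertion is additive with an alpha support in normalised intensity space
(``out = clip(img + alpha * intensity * gain, 0, 1)``); distortions warp in
place.  Pixels outside the lesion support are bit-identical to the input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, ContractError, PlacementError
from .preprocess import breast_mask, image_histogram, threshold_value, triangle_threshold
from .types import BreastMask, LesionPatch, Mammogram

N_CONTOUR = 360  # radial samples per mass contour (1 degree resolution)
DEFAULT_GAIN = 0.35  # additive blending gain in normalised intensity space
SPICULE_STEP_PX = 2.0
SPICULE_JITTER_DEG = 10.0
PLACEMENT_MARGIN_PX = 20


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MassParams:
    """Spiculated-mass generator parameters.

    ``mean_radius_mm`` sets the expected core radius; ``log_radius_sigma``
    is the log-scale contour roughness and ``angular_corr_deg`` the angular
    smoothness scale of the contour process.  Spicule count/length and the
    branching law control the stellate appearance; ``contrast`` scales the
    peak added intensity (relative to the blending gain).
    """

    mean_radius_mm: float = 3.0
    log_radius_sigma: float = 0.25
    angular_corr_deg: float = 30.0
    n_spicules: int = 12
    spicule_len_mm: float = 2.0
    branch_prob: float = 0.15
    max_branch_depth: int = 2
    contrast: float = 0.8

    def __post_init__(self) -> None:
        if self.mean_radius_mm <= 0:
            raise ConfigurationError("mean_radius_mm must be positive")
        if self.log_radius_sigma < 0:
            raise ConfigurationError("log_radius_sigma must be >= 0")
        if self.angular_corr_deg <= 0:
            raise ConfigurationError("angular_corr_deg must be positive")
        if self.n_spicules < 0 or self.max_branch_depth < 0:
            raise ConfigurationError("spicule counts must be non-negative")
        if not (0.0 <= self.branch_prob <= 1.0):
            raise ConfigurationError("branch_prob must lie in [0, 1]")
        if not (0.0 < self.contrast <= 1.0):
            raise ConfigurationError("contrast must lie in (0, 1]")


@dataclass(frozen=True)
class CalcClusterParams:
    """Microcalcification cluster parameters (diameters in mm)."""

    n_calcs: int = 8
    cluster_radius_mm: float = 4.0
    diam_range_mm: tuple[float, float] = (0.25, 1.0)
    intensity_boost: float = 0.8

    def __post_init__(self) -> None:
        if self.n_calcs < 1:
            raise ConfigurationError("n_calcs must be >= 1")
        lo, hi = self.diam_range_mm
        if not (0 < lo <= hi):
            raise ConfigurationError("diam_range_mm must satisfy 0 < lo <= hi")
        if not (0.0 < self.intensity_boost <= 1.0):
            raise ConfigurationError("intensity_boost must lie in (0, 1]")
        if self.cluster_radius_mm <= 0:
            raise ConfigurationError("cluster_radius_mm must be positive")


@dataclass(frozen=True)
class SwirlParams:
    """Local twist: ``strength`` radians at the centre, decaying over
    ``radius_px`` (effective scale ``radius_px * ln(2) / 5``)."""

    center: tuple[float, float]  # (row, col)
    strength: float = 2.5
    radius_px: float = 60.0

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ConfigurationError("radius_px must be positive")

    @property
    def r_eff(self) -> float:
        return self.radius_px * math.log(2.0) / 5.0


# ---------------------------------------------------------------------------
# mass contour: wrapped-GP log-normal radial process
# ---------------------------------------------------------------------------

@lru_cache(maxsize=16)
def _contour_factor(sigma: float, corr_deg: float, n: int) -> np.ndarray | None:
    """Matrix square root of the wrapped squared-exponential covariance."""
    if sigma == 0.0:
        return None
    theta = np.arange(n) * (360.0 / n)
    delta = np.abs(theta[:, None] - theta[None, :])
    delta = np.minimum(delta, 360.0 - delta)  # wrap around the circle
    cov = sigma**2 * np.exp(-0.5 * (delta / corr_deg) ** 2)
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)  # numerically tiny negatives from smoothness
    return v * np.sqrt(w)


def sample_mass_contour(
    params: MassParams, pixel_spacing_mm: float, seed: int
) -> np.ndarray:
    """Closed radial contour ``r(theta_k)`` in pixels, k = 0..359.

    The contour is star-shaped about its centre by construction
    (single-valued radius), strictly positive, and its expected radius is
    ``mean_radius_mm / pixel_spacing_mm``.
    """
    rng = np.random.default_rng(seed)
    mean_r_px = params.mean_radius_mm / pixel_spacing_mm
    sigma = params.log_radius_sigma
    factor = _contour_factor(sigma, params.angular_corr_deg, N_CONTOUR)
    if factor is None:
        return np.full(N_CONTOUR, mean_r_px)
    z = factor @ rng.standard_normal(N_CONTOUR)
    return mean_r_px * np.exp(z - sigma**2 / 2.0)


# ---------------------------------------------------------------------------
# spicules: iterative branching walk
# ---------------------------------------------------------------------------

@dataclass
class SpiculeStroke:
    """One tapering spicule stroke: points relative to the mass centre."""

    points: np.ndarray  # (n, 2) float, (row, col) offsets
    widths: np.ndarray  # px, tapering to 0 at the tip
    intensities: np.ndarray  # relative brightness, tapering to 0
    depth: int  # 0 = root, >0 = branch generation
    n_steps: int


def grow_spicules(
    contour: np.ndarray, params: MassParams, pixel_spacing_mm: float, seed: int
) -> list[SpiculeStroke]:
    """Grow spicule strokes outward from the mass contour.

    Exactly ``n_spicules`` root strokes start on the contour and step
    outward (radial direction plus Gaussian angular jitter per step).  At
    each step a branch spawns with probability ``branch_prob``, up to
    ``max_branch_depth`` generations; branches inherit a shortened length
    budget.  Width and intensity taper linearly to zero at the tip.
    """
    rng = np.random.default_rng(seed)
    strokes: list[SpiculeStroke] = []
    if params.n_spicules == 0:
        return strokes

    len_px = params.spicule_len_mm / pixel_spacing_mm
    jitter = math.radians(SPICULE_JITTER_DEG)

    def _walk(start: np.ndarray, direction: float, length: float, depth: int) -> None:
        n_steps = max(1, int(round(length / SPICULE_STEP_PX)))
        pts = np.empty((n_steps + 1, 2))
        pts[0] = start
        pos = start.copy()
        ang = direction
        pending: list[tuple[np.ndarray, float, float]] = []
        for s in range(n_steps):
            ang += rng.normal(0.0, jitter)
            pos = pos + SPICULE_STEP_PX * np.array([math.sin(ang), math.cos(ang)])
            pts[s + 1] = pos
            if depth < params.max_branch_depth and rng.random() < params.branch_prob:
                side = 1.0 if rng.random() < 0.5 else -1.0
                bang = ang + side * rng.uniform(math.radians(20), math.radians(40))
                pending.append((pos.copy(), bang, length * 0.6))
        frac = 1.0 - np.arange(n_steps + 1) / n_steps
        strokes.append(
            SpiculeStroke(
                points=pts,
                widths=2.5 * frac,
                intensities=frac,
                depth=depth,
                n_steps=n_steps,
            )
        )
        for start_b, ang_b, len_b in pending:
            _walk(start_b, ang_b, len_b, depth + 1)

    root_angles = rng.uniform(0.0, 2.0 * math.pi, size=params.n_spicules)
    for ang in root_angles:
        deg = (math.degrees(ang)) % 360.0
        r0 = float(np.interp(deg, np.arange(N_CONTOUR), contour, period=360.0))
        start = r0 * np.array([math.sin(ang), math.cos(ang)])
        length = len_px * rng.uniform(0.8, 1.2)
        _walk(start, ang, length, depth=0)
    return strokes


# ---------------------------------------------------------------------------
# renderers
# ---------------------------------------------------------------------------

def _polar_grid(half: int) -> tuple[np.ndarray, np.ndarray]:
    ax = np.arange(-half, half + 1, dtype=float)
    rr, cc = np.meshgrid(ax, ax, indexing="ij")
    rho = np.hypot(rr, cc)
    phi = np.arctan2(rr, cc)  # angle measured from +col axis, row = sin
    return rho, phi


def render_mass(params: MassParams, pixel_spacing_mm: float, seed: int) -> LesionPatch:
    """Render a spiculated mass patch.

    The filled contour gets a half-cosine radial intensity falloff (peak
    ``contrast`` at the centre, zero at the edge); spicule strokes are
    composited on top; alpha is the smoothed support.
    """
    rng = np.random.default_rng(seed)
    contour = sample_mass_contour(params, pixel_spacing_mm, int(rng.integers(2**31)))
    strokes = grow_spicules(contour, params, pixel_spacing_mm, int(rng.integers(2**31)))

    extent = float(contour.max())
    for s in strokes:
        extent = max(extent, float(np.abs(s.points).max()))
    half = int(math.ceil(extent)) + 4
    rho, phi = _polar_grid(half)

    deg = (np.degrees(phi)) % 360.0
    r_edge = np.interp(deg, np.arange(N_CONTOUR), contour, period=360.0)
    inside = rho <= r_edge
    intensity = np.zeros_like(rho)
    with np.errstate(invalid="ignore"):
        falloff = 0.5 * (1.0 + np.cos(np.pi * np.clip(rho / r_edge, 0.0, 1.0)))
    intensity[inside] = params.contrast * falloff[inside]

    # stamp spicule strokes as small Gaussian footprints along each polyline
    layer = np.zeros_like(intensity)
    size = intensity.shape[0]
    yy, xx = np.mgrid[-3:4, -3:4].astype(float)
    for s in strokes:
        for (dr, dc), w, val in zip(s.points, s.widths, s.intensities):
            if w <= 0.05 or val <= 0.01:
                continue
            r_i, c_i = int(round(dr)) + half, int(round(dc)) + half
            if not (3 <= r_i < size - 3 and 3 <= c_i < size - 3):
                continue
            foot = val * params.contrast * 0.6 * np.exp(
                -(yy**2 + xx**2) / (2.0 * max(w / 2.0, 0.5) ** 2)
            )
            region = layer[r_i - 3 : r_i + 4, c_i - 3 : c_i + 4]
            np.maximum(region, foot, out=region)
    intensity = np.maximum(intensity, layer)

    # support is the filled contour plus the spicule strokes; the interior
    # counts in full even where the cosine falloff is near zero
    support = np.where(inside, 1.0, (layer > 0.01).astype(float))
    alpha = np.clip(ndimage.gaussian_filter(support, 1.5), 0.0, 1.0)
    alpha[support > 0] = np.maximum(alpha[support > 0], 0.5)
    alpha[alpha < 1e-3] = 0.0  # keep the support finite (no Gaussian tails)
    alpha[rho <= 0.5] = 1.0  # centre pixel fully blended

    return LesionPatch(
        intensity=intensity,
        alpha=alpha,
        kind="mass",
        geometry={
            "contour_px": contour,
            "strokes": strokes,
            "mean_radius_mm": params.mean_radius_mm,
        },
    )


def render_calc_cluster(
    params: CalcClusterParams, pixel_spacing_mm: float, seed: int
) -> LesionPatch:
    """Render a convex cluster of small bright calcifications.

    Each deposit is an ellipse with equivalent diameter drawn uniformly
    from ``diam_range_mm``; centres are sampled uniformly inside an
    elliptical (convex) cluster region.  The brightness profile is a
    steep super-Gaussian whose half-maximum contour sits at the nominal
    equivalent diameter.
    """
    lo_px = params.diam_range_mm[0] / pixel_spacing_mm
    if lo_px < 1.0:
        raise ConfigurationError(
            f"pixel spacing {pixel_spacing_mm} mm too coarse for "
            f"{params.diam_range_mm[0]} mm calcifications"
        )
    rng = np.random.default_rng(seed)
    cluster_r_px = params.cluster_radius_mm / pixel_spacing_mm
    max_d_px = params.diam_range_mm[1] / pixel_spacing_mm
    half = int(math.ceil(cluster_r_px + max_d_px / 2.0)) + 4
    size = 2 * half + 1

    # convex (elliptical) cluster region, randomly squashed and rotated
    ratio = rng.uniform(0.6, 1.0)
    tilt = rng.uniform(0.0, math.pi)
    a, b = cluster_r_px, cluster_r_px * ratio

    centers = []
    while len(centers) < params.n_calcs:
        u, v = rng.uniform(-1.0, 1.0, size=2)
        if u * u + v * v <= 1.0:
            dr = a * u * math.sin(tilt) + b * v * math.cos(tilt)
            dc = a * u * math.cos(tilt) - b * v * math.sin(tilt)
            centers.append((dr, dc))

    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    rr -= half
    cc -= half
    intensity = np.zeros((size, size))
    deposits = []
    for dr, dc in centers:
        d_mm = rng.uniform(*params.diam_range_mm)
        d_px = d_mm / pixel_spacing_mm
        q = rng.uniform(0.7, 1.0)  # axis ratio; equivalent diameter preserved
        ea, eb = (d_px / 2.0) / math.sqrt(q), (d_px / 2.0) * math.sqrt(q)
        ang = rng.uniform(0.0, math.pi)
        xr = (rr - dr) * math.cos(ang) + (cc - dc) * math.sin(ang)
        yr = -(rr - dr) * math.sin(ang) + (cc - dc) * math.cos(ang)
        m = np.sqrt((xr / ea) ** 2 + (yr / eb) ** 2)  # 1 at the half-max edge
        blob = params.intensity_boost * np.exp(-math.log(2.0) * m**4)
        blob[m > 2.0] = 0.0  # truncate the negligible tail; finite support
        np.maximum(intensity, blob, out=intensity)
        deposits.append(
            {"center": (dr, dc), "diameter_mm": d_mm, "axes_px": (ea, eb), "angle": ang}
        )

    alpha = np.clip(intensity / params.intensity_boost, 0.0, 1.0)
    return LesionPatch(
        intensity=intensity,
        alpha=alpha,
        kind="calc",
        geometry={"deposits": deposits, "cluster_radius_mm": params.cluster_radius_mm},
    )


def measure_blob_diameters(
    patch_intensity: np.ndarray, pixel_spacing_mm: float, level_frac: float = 0.5
) -> list[float]:
    """Equivalent diameters (mm) of the half-maximum supports in a patch.

    Sub-pixel contours are extracted at ``level_frac * max`` with marching
    squares; each closed contour's shoelace area gives the equivalent
    diameter.  Because the polygon is inscribed in the smooth level curve,
    its area understates a small convex blob's; the regular-polygon
    relation ``A = (n/2) R^2 sin(2 pi / n)`` corrects for the vertex count.
    """
    from skimage.measure import find_contours

    peak = float(patch_intensity.max())
    if peak <= 0:
        return []
    out = []
    for contour in find_contours(patch_intensity, level_frac * peak):
        if not np.allclose(contour[0], contour[-1]):
            continue  # open contour clipped by the patch edge
        y, x = contour[:, 0], contour[:, 1]
        area = 0.5 * abs(float(np.dot(y[:-1], x[1:]) - np.dot(y[1:], x[:-1])))
        n_vertices = len(contour) - 1
        if area <= 0 or n_vertices < 3:
            continue
        radius = math.sqrt(2.0 * area / (n_vertices * math.sin(2.0 * math.pi / n_vertices)))
        out.append(2.0 * radius * pixel_spacing_mm)
    return out


# ---------------------------------------------------------------------------
# swirl distortion
# ---------------------------------------------------------------------------

def apply_swirl(img: np.ndarray, params: SwirlParams) -> np.ndarray:
    """Inverse-mapped local twist (bilinear interpolation).

    The output pixel at polar offset ``(rho, phi)`` from the centre samples
    the input at ``phi + strength * exp(-rho / r_eff)``.  ``strength = 0``
    is the identity; pixels far from the centre are numerically unchanged
    because the twist decays exponentially.
    """
    img = np.asarray(img, dtype=float)
    cr, cc = params.center
    if not (0 <= cr < img.shape[0] and 0 <= cc < img.shape[1]):
        raise ConfigurationError("swirl centre must lie inside the image")
    rows, cols = np.mgrid[0 : img.shape[0], 0 : img.shape[1]].astype(float)
    dr, dc = rows - cr, cols - cc
    rho = np.hypot(dr, dc)
    phi = np.arctan2(dr, dc)
    theta = phi + params.strength * np.exp(-rho / params.r_eff)
    src_r = cr + rho * np.sin(theta)
    src_c = cc + rho * np.cos(theta)
    return ndimage.map_coordinates(img, [src_r, src_c], order=1, mode="nearest")


def swirl_support_radius(params: SwirlParams, min_arc_px: float = 0.5) -> float:
    """Outermost radius where the swirl still moves a pixel >= ``min_arc_px``.

    The arc displacement is ``rho * strength * exp(-rho / r_eff)``; the
    outer root is located by a numeric scan (the closed form involves the
    Lambert W function).
    """
    if params.strength == 0:
        return 0.0
    rho = np.linspace(0.0, 30.0 * params.r_eff, 4096)
    arc = rho * abs(params.strength) * np.exp(-rho / params.r_eff)
    moving = np.flatnonzero(arc >= min_arc_px)
    if moving.size == 0:
        return 0.0
    return float(rho[moving[-1]]) + 2.0


# ---------------------------------------------------------------------------
# placement and insertion
# ---------------------------------------------------------------------------

def choose_insertion_site(
    mask: BreastMask | np.ndarray,
    patch_radius_px: float,
    seed: int,
    margin_px: int = PLACEMENT_MARGIN_PX,
) -> tuple[int, int]:
    """Uniform site inside the breast mask eroded by the patch radius.

    The erosion (computed with a Euclidean distance transform) guarantees
    the lesion support lies fully inside breast tissue, ``margin_px`` away
    from the skin line.
    """
    m = mask.mask if isinstance(mask, BreastMask) else np.asarray(mask, dtype=bool)
    radius = patch_radius_px + margin_px
    if radius > 0:
        framed = m.copy()  # the image border counts as outside tissue
        framed[0, :] = framed[-1, :] = framed[:, 0] = framed[:, -1] = False
        eroded = ndimage.distance_transform_edt(framed) > radius
    else:
        eroded = m
    candidates = np.argwhere(eroded)
    if candidates.shape[0] == 0:
        raise PlacementError(
            f"no site can host a lesion of radius {patch_radius_px:.0f} px"
        )
    rng = np.random.default_rng(seed)
    r, c = candidates[int(rng.integers(candidates.shape[0]))]
    return int(r), int(c)


def _support_bbox(site: tuple[int, int], patch: LesionPatch, shape) -> tuple[int, int, int, int]:
    half_r = patch.alpha.shape[0] // 2
    half_c = patch.alpha.shape[1] // 2
    r0, c0 = site[0] - half_r, site[1] - half_c
    r1, c1 = r0 + patch.alpha.shape[0], c0 + patch.alpha.shape[1]
    if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
        raise PlacementError("lesion support exceeds image bounds")
    return r0, r1, c0, c1


def insert_lesion(
    mam: Mammogram,
    patch: LesionPatch,
    site: tuple[int, int],
    gain: float = DEFAULT_GAIN,
) -> Mammogram:
    """Insert one lesion at ``site`` (row, col) and flip the label to 1.

    Mass/calc patches blend additively (``clip(img + alpha * intensity *
    gain, 0, 1)`` over the support); distortions apply the swirl in place.
    Pixels outside the support are bit-identical to the input.  The
    inserted geometry is recorded in ``annotations`` and the union support
    mask in ``extras['lesion_support']``.
    """
    img = np.asarray(mam.pixels, dtype=float)
    out = img.copy()

    if patch.kind == "distortion":
        params: SwirlParams = replace(patch.geometry["swirl"], center=(float(site[0]), float(site[1])))
        support_r = swirl_support_radius(params)
        swirled = apply_swirl(img, params)
        rows, cols = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        support = np.hypot(rows - site[0], cols - site[1]) <= support_r
        out[support] = swirled[support]
        geometry = {"swirl": params}
    else:
        r0, r1, c0, c1 = _support_bbox(site, patch, img.shape)
        region = out[r0:r1, c0:c1]
        add = patch.alpha * patch.intensity * gain
        touched = add > 0
        region[touched] = np.clip(region[touched] + add[touched], 0.0, 1.0)
        support = np.zeros(img.shape, dtype=bool)
        support[r0:r1, c0:c1] = touched
        geometry = dict(patch.geometry)

    result = mam.with_pixels(out, label=1)
    result.annotations.append(
        {
            "kind": patch.kind,
            "center": (int(site[0]), int(site[1])),
            "geometry": geometry,
            "support": support,
        }
    )
    prev = result.extras.get("lesion_support")
    result.extras["lesion_support"] = support if prev is None else (prev | support)
    return result


DEFAULT_KIND_PROBS = {"mass": 0.5, "calc": 0.3, "distortion": 0.2}


def artifact_image(
    mam: Mammogram,
    k: int,
    seed: int,
    kind_probs: dict[str, float] | None = None,
    mass_params: MassParams | None = None,
    calc_params: CalcClusterParams | None = None,
    swirl_strength_range: tuple[float, float] = (1.5, 3.5),
    swirl_radius_range_mm: tuple[float, float] = (4.0, 8.0),
    gain: float = DEFAULT_GAIN,
    max_tries: int = 100,
    margin_mm: float = 2.0,
) -> Mammogram:
    """Insert ``k`` lesions of independently sampled kinds into a benign image.

    The input must be benign (inserting a benign finding into a malignant
    image would not change its class) with float intensities in [0, 1] —
    canonically the output of the preprocessing chain.  Lesion kinds are
    drawn from ``kind_probs`` (default mass 0.5 / calc 0.3 / distortion
    0.2); sites keep a ``margin_mm`` distance from the skin line (2 mm =
    20 px at the 0.1 mm/px reference spacing) and are resampled until the
    lesion supports are pairwise disjoint.  The result is labelled
    malignant.
    """
    if mam.label != 0:
        raise ContractError("artifact_image requires a benign (label 0) input")
    if k not in (1, 2, 3):
        raise ConfigurationError("k must be 1, 2, or 3")
    img = np.asarray(mam.pixels, dtype=float)
    if img.min() < 0 or img.max() > 1:
        raise ContractError("artifact_image requires intensities in [0, 1]")

    probs = dict(DEFAULT_KIND_PROBS if kind_probs is None else kind_probs)
    kinds = list(probs)
    pvec = np.array([probs[kd] for kd in kinds], dtype=float)
    pvec = pvec / pvec.sum()
    mass_params = mass_params or MassParams()
    calc_params = calc_params or CalcClusterParams()
    spacing = mam.pixel_spacing_mm

    # breast support: exact zeros after normalisation, triangle threshold
    # on raw phantoms
    if mam.normalised or (img == 0).mean() > 0.2:
        support_mask = img > 0
        labels, n = ndimage.label(support_mask)
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
            support_mask = labels == (int(np.argmax(sizes)) + 1)
        mask = BreastMask.from_mask(support_mask)
    else:
        t = triangle_threshold(image_histogram(img))
        _, mask = breast_mask(img, threshold_value(t))

    rng = np.random.default_rng(seed)
    margin_px = max(4, int(round(margin_mm / spacing)))

    # render the k patches first, then place them jointly
    patches: list[LesionPatch] = []
    for _ in range(k):
        kind = kinds[int(rng.choice(len(kinds), p=pvec))]
        if kind == "mass":
            patches.append(render_mass(mass_params, spacing, int(rng.integers(2**31))))
        elif kind == "calc":
            patches.append(
                render_calc_cluster(calc_params, spacing, int(rng.integers(2**31)))
            )
        else:
            sw = SwirlParams(
                center=(0.0, 0.0),
                strength=float(rng.uniform(*swirl_strength_range)),
                radius_px=float(rng.uniform(*swirl_radius_range_mm)) / spacing,
            )
            radius = swirl_support_radius(sw)
            n_side = 2 * int(math.ceil(radius)) + 1
            patches.append(
                LesionPatch(
                    intensity=np.zeros((n_side, n_side)),
                    alpha=np.zeros((n_side, n_side)),
                    kind="distortion",
                    geometry={"swirl": sw},
                )
            )

    # largest-first with restarts: greedy sequential placement can paint
    # itself into a corner when lesions are large relative to the breast
    order = sorted(range(k), key=lambda i: -patches[i].radius_px)
    n_restarts = 20
    tries_each = max(1, max_tries // n_restarts) * 5
    sites: list[tuple[int, int] | None] = [None] * k
    for _restart in range(n_restarts):
        occupied = np.zeros(img.shape, dtype=bool)
        sites = [None] * k
        ok = True
        for i in order:
            patch = patches[i]
            found = None
            for _try in range(tries_each):
                cand = choose_insertion_site(
                    mask, patch.radius_px, int(rng.integers(2**31)), margin_px=margin_px
                )
                foot = _footprint(cand, patch, img.shape)
                if foot is not None and not (foot & occupied).any():
                    found = cand
                    # 2 px of clearance between neighbouring supports
                    occupied |= ndimage.binary_dilation(foot, iterations=2)
                    break
            if found is None:
                ok = False
                break
            sites[i] = found
        if ok:
            break
    if not all(s is not None for s in sites):
        raise PlacementError(
            f"could not place {k} non-overlapping lesions after {n_restarts} rounds"
        )

    result = mam
    for patch, site in zip(patches, sites):
        result = insert_lesion(result, patch, site, gain=gain)
    return result


def _footprint(
    site: tuple[int, int], patch: LesionPatch, shape
) -> np.ndarray | None:
    """Bool map of the pixels this lesion would touch, or None if clipped."""
    if patch.kind == "distortion":
        radius = patch.radius_px
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        return np.hypot(rows - site[0], cols - site[1]) <= radius
    try:
        r0, r1, c0, c1 = _support_bbox(site, patch, shape)
    except PlacementError:
        return None
    out = np.zeros(shape, dtype=bool)
    out[r0:r1, c0:c1] = (patch.alpha * patch.intensity) > 0  # touched pixels
    return out
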