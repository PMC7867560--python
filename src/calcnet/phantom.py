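"""Synthetic non-contrast CT phantoms of pelvic calcifications.

Each phantom is a 5 x 5 x 5 cm cube (fifty 1-mm slices, 5 x 5 cm field of
view) holding one high-attenuation calcification near its centre, embedded
in a fat background with sparse soft-tissue structures — the same local
geometry a radiologist sees when a distal ureteral stone or a pelvic
phlebolith is windowed out of an abdominal NECT.

The two classes differ in the canonical local signs:

* stones — more irregular surface, optionally a soft-tissue rim ring
  (the oedematous ureter wall, the "rim sign");
* phleboliths — rounder, optionally a low-attenuation centre (central
  lucency) and a tapering soft-tissue comet tail (the feeding vein).

Peak attenuation and largest diameter are drawn from essentially the same
distributions for both classes, so attenuation and volume alone carry almost
no class signal; morphology does.  Scanner realism is limited to additive
Gaussian noise followed by a Gaussian point-spread blur.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull

from ._random import substream, substream_seed
from .core import (PHLEBOLITH, STONE, CTStack, CalcnetError, SizingError,
                   normalize_label)

DEFAULT_SHAPE = (50, 50, 50)
DEFAULT_SPACING = (1.0, 1.0, 1.0)
SEGMENTATION_HU = 250.0  # calcifications must exceed this to be segmentable


@dataclass
class PhantomParams:
    """Full description of one synthetic calcification.

    ``max_diameter_mm`` is the largest caliper diameter of the calcified
    body; ``peak_hu`` its plateau attenuation before blurring.  Optional
    features: a soft-tissue rim ring (``rim_hu``, nominally 0-60 HU), an
    interior lucency (``lucency_hu``, must stay below 250 HU) and a comet
    tail.  ``surface_irregularity`` is the relative amplitude of the
    low-order spherical-harmonic surface perturbation; ``None`` selects a
    class default (stones rougher than phleboliths).
    """

    class_label: str
    max_diameter_mm: float = 4.5
    peak_hu: float = 700.0
    rim_present: bool = False
    rim_hu: float = 30.0
    lucency_present: bool = False
    lucency_hu: float = 30.0
    comet_present: bool = False
    background_fat_hu: float = -100.0
    noise_sd_hu: float = 15.0
    blur_fwhm_mm: float = 1.2
    surface_irregularity: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_label = normalize_label(self.class_label)
        if self.peak_hu <= SEGMENTATION_HU:
            raise CalcnetError(
                f"peak_hu must exceed {SEGMENTATION_HU} HU to be segmentable, "
                f"got {self.peak_hu}")
        if self.max_diameter_mm <= 0:
            raise CalcnetError("max_diameter_mm must be positive")
        if self.lucency_present and self.lucency_hu >= SEGMENTATION_HU:
            raise CalcnetError(
                f"lucency_hu must be below {SEGMENTATION_HU} HU, got {self.lucency_hu}")
        if self.noise_sd_hu < 0 or self.blur_fwhm_mm < 0:
            raise CalcnetError("noise_sd_hu and blur_fwhm_mm must be >= 0")

    @property
    def irregularity(self) -> float:
        if self.surface_irregularity is not None:
            return float(self.surface_irregularity)
        return 0.12 if self.class_label == STONE else 0.04


@dataclass
class CohortDistributions:
    """Class-conditional sampling distributions for a phantom cohort.

    Diameters follow scaled Beta laws over the study ranges (stones
    2.0-11.8 mm, phleboliths 2.8-9.6 mm) with both class means near 4.5 mm.
    Peak attenuation is drawn from one shared range for both classes so the
    size/attenuation scatter of the two classes overlaps; the class signal
    lives in the morphological features and their presence probabilities.
    """

    stone_diameter_range: tuple[float, float] = (2.0, 11.8)
    stone_diameter_beta: tuple[float, float] = (2.0, 5.8)
    phlebolith_diameter_range: tuple[float, float] = (2.8, 9.6)
    phlebolith_diameter_beta: tuple[float, float] = (2.0, 6.0)
    peak_hu_range: tuple[float, float] = (450.0, 1100.0)
    stone_rim_prob: float = 0.8
    phlebolith_rim_prob: float = 0.05
    stone_lucency_prob: float = 0.0
    phlebolith_lucency_prob: float = 0.5
    stone_comet_prob: float = 0.0
    phlebolith_comet_prob: float = 0.6
    rim_hu_range: tuple[float, float] = (10.0, 60.0)
    lucency_hu_range: tuple[float, float] = (10.0, 60.0)
    stone_irregularity: float = 0.12
    phlebolith_irregularity: float = 0.04
    noise_sd_hu: float = 15.0
    blur_fwhm_mm: float = 1.2

    def sample_params(self, label: str, rng: np.random.Generator) -> PhantomParams:
        """Draw one PhantomParams for the given class."""
        label = normalize_label(label)
        if label == STONE:
            lo, hi = self.stone_diameter_range
            a, b = self.stone_diameter_beta
            rim_p, luc_p, com_p = (self.stone_rim_prob, self.stone_lucency_prob,
                                   self.stone_comet_prob)
            irr = self.stone_irregularity
        else:
            lo, hi = self.phlebolith_diameter_range
            a, b = self.phlebolith_diameter_beta
            rim_p, luc_p, com_p = (self.phlebolith_rim_prob,
                                   self.phlebolith_lucency_prob,
                                   self.phlebolith_comet_prob)
            irr = self.phlebolith_irregularity
        return PhantomParams(
            class_label=label,
            max_diameter_mm=float(lo + (hi - lo) * rng.beta(a, b)),
            peak_hu=float(rng.uniform(*self.peak_hu_range)),
            rim_present=bool(rng.random() < rim_p),
            rim_hu=float(rng.uniform(*self.rim_hu_range)),
            lucency_present=bool(rng.random() < luc_p),
            lucency_hu=float(rng.uniform(*self.lucency_hu_range)),
            comet_present=bool(rng.random() < com_p),
            noise_sd_hu=self.noise_sd_hu,
            blur_fwhm_mm=self.blur_fwhm_mm,
            surface_irregularity=irr,
        )


def _rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation via QR of a Gaussian matrix."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _harmonic_field(dirs: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Low-order angular perturbation, normalised to max |.| = 1.

    Evaluates a random combination of degree-2 and degree-3 polynomial
    harmonics of the unit direction vectors (n, 3).
    """
    x, y, z = dirs[:, 0], dirs[:, 1], dirs[:, 2]
    basis = np.stack([
        x * y, y * z, x * z,
        x * x - y * y, 3 * z * z - 1,
        x * (x * x - 3 * y * y), y * (3 * x * x - y * y),
        z * (5 * z * z - 3), x * (5 * z * z - 1),
    ], axis=1)
    f = basis @ coeffs[: basis.shape[1]]
    m = np.max(np.abs(f))
    return f / m if m > 0 else f


def _inside_fraction(points_mm: np.ndarray, center: np.ndarray, rot: np.ndarray,
                     semi_axes: np.ndarray, amp: float,
                     coeffs: np.ndarray) -> np.ndarray:
    """Normalised radius rho of each point: rho <= 1 means inside the body."""
    u = (points_mm - center) @ rot  # into body frame
    v = u / semi_axes
    rho = np.linalg.norm(v, axis=1)
    nz = rho > 1e-12
    dirs = np.zeros_like(v)
    dirs[nz] = v[nz] / rho[nz, None]
    mod = 1.0 + amp * _harmonic_field(dirs, coeffs)
    return rho / np.maximum(mod, 0.2)


def _caliper_diameter(coords_mm: np.ndarray) -> float:
    """Largest pairwise distance between voxel centres (convex-hull caliper)."""
    if len(coords_mm) == 0:
        return 0.0
    if len(coords_mm) == 1:
        return 0.0
    pts = np.unique(coords_mm, axis=0)
    if len(pts) > 4:
        try:
            pts = pts[ConvexHull(pts, qhull_options="QJ").vertices]
        except Exception:  # degenerate (coplanar) clouds fall back to all points
            pass
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def generate_stack(params: PhantomParams,
                   shape: tuple[int, int, int] = DEFAULT_SHAPE,
                   spacing: tuple[float, float, float] = DEFAULT_SPACING,
                   id: str = "") -> CTStack:
    """Render one synthetic calcification stack.

    Deterministic for a fixed ``params.seed``.  The calcified body is a
    randomly oriented ellipsoid with a low-order spherical-harmonic surface
    perturbation, rescaled so its caliper diameter matches
    ``params.max_diameter_mm`` to about one voxel; Gaussian noise and a
    Gaussian blur of ``blur_fwhm_mm`` are applied last.

    Raises
    ------
    SizingError
        If the calcification (plus rim/comet margins) cannot fit the cube.
    """
    shape = tuple(int(n) for n in shape)
    spacing = tuple(float(s) for s in spacing)
    extent = np.array([n * s for n, s in zip(shape, spacing)])
    # the calcification must sit well inside the cube with room for its
    # rim/comet and background context, as in the curated study cubes
    if params.max_diameter_mm > 0.45 * extent.min():
        raise SizingError(
            f"calcification of {params.max_diameter_mm} mm too large for a "
            f"cube of extent {extent.min()} mm (limit {0.45 * extent.min():.1f} mm)")

    rng = np.random.default_rng(params.seed)
    nx, ny, nz = shape
    sx, sy, sz = spacing

    grid = np.full(shape, params.background_fat_hu, dtype=np.float32)
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    pts = np.stack([ix.ravel() * sx, iy.ravel() * sy, iz.ravel() * sz], axis=1)

    center = np.array([(nx - 1) / 2 * sx, (ny - 1) / 2 * sy, (nz - 1) / 2 * sz])
    center = center + rng.uniform(-0.75, 0.75, size=3)

    # sparse soft-tissue background structures (vessel/bowel cross-sections)
    for _ in range(rng.poisson(3)):
        bc = rng.uniform(0, 1, size=3) * extent
        baxes = rng.uniform(2.0, 6.0, size=3)
        bhu = rng.uniform(20.0, 60.0)
        brot = _rotation_matrix(rng)
        bu = (pts - bc) @ brot / baxes
        binside = (np.linalg.norm(bu, axis=1) <= 1.0).reshape(shape)
        grid[binside] = bhu

    # calcified body: oriented ellipsoid + surface perturbation
    rot = _rotation_matrix(rng)
    a1 = params.max_diameter_mm / 2.0
    if params.class_label == STONE:
        ratios = rng.uniform(0.55, 0.95, size=2)
    else:
        ratios = rng.uniform(0.80, 1.00, size=2)
    semi = a1 * np.array([1.0, ratios[0], ratios[1]])
    amp = params.irregularity
    coeffs = rng.normal(size=9)

    rho = _inside_fraction(pts, center, rot, semi, amp, coeffs)
    inside = rho <= 1.0
    meas = _caliper_diameter(pts[inside])
    if meas > 0:
        semi = semi * (params.max_diameter_mm / meas)
        rho = _inside_fraction(pts, center, rot, semi, amp, coeffs)
        inside = rho <= 1.0
    if not inside.any():  # sub-voxel body: paint the centre voxel
        ci = tuple(int(round(c / s)) for c, s in zip(center, spacing))
        inside = np.zeros(len(pts), dtype=bool)
        inside[np.ravel_multi_index(ci, shape)] = True
        rho = np.where(inside, 0.0, 2.0)

    # comet tail: tapering soft-tissue cone leaving the body (phlebolith vein)
    if params.comet_present:
        v = rng.normal(0, 0.3, size=3)
        v[2] = rng.choice([-1.0, 1.0])
        v /= np.linalg.norm(v)
        t = (pts - center) @ v
        radial = np.linalg.norm((pts - center) - t[:, None] * v, axis=1)
        t0 = 0.35 * params.max_diameter_mm
        length = float(np.clip(rng.uniform(1.0, 2.0) * params.max_diameter_mm,
                               3.0, extent.min() / 2 - 2.0))
        taper = np.clip(1.0 - (t - t0) / length, 0.0, 1.0)
        w0 = max(0.35 * params.max_diameter_mm, 1.2)
        in_tail = (t > t0) & (t <= t0 + length) & (radial <= w0 * taper)
        tail = in_tail.reshape(shape) & ~inside.reshape(shape)
        grid[tail] = 40.0

    # soft-tissue rim ring around a stone (the "rim sign")
    if params.rim_present:
        rim_outer = (a1 + 1.8) / a1
        in_rim = (rho > 1.0) & (rho <= rim_outer)
        grid[in_rim.reshape(shape)] = params.rim_hu

    grid[inside.reshape(shape)] = params.peak_hu

    # central lucency inside a phlebolith
    if params.lucency_present:
        luc_frac = float(np.clip(1.5 / a1, 0.35, 0.6))
        grid[(rho <= luc_frac).reshape(shape)] = params.lucency_hu

    if params.noise_sd_hu > 0:
        grid = grid + rng.normal(0, params.noise_sd_hu, size=shape).astype(np.float32)
    if params.blur_fwhm_mm > 0:
        sigma_mm = params.blur_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        gaussian_filter(grid, sigma=[sigma_mm / s for s in spacing], output=grid)

    return CTStack(grid, spacing, params.class_label, id)


def generate_cohort(n_stones: int, n_phleboliths: int,
                    distributions: CohortDistributions | None = None,
                    seed: int = 0, id_prefix: str = "calc",
                    shape: tuple[int, int, int] = DEFAULT_SHAPE,
                    spacing: tuple[float, float, float] = DEFAULT_SPACING,
                    ) -> tuple[list[CTStack], pd.DataFrame]:
    """Generate a labelled cohort plus its manifest.

    Returns exactly ``n_stones + n_phleboliths`` stacks (stones first) and a
    manifest with one row per stack: id, label, true diameter, peak HU, the
    per-stack render seed and the drawn feature flags.  Each stack draws its
    parameters and rendering noise from a counter-based substream of the
    master seed, so any subset is reproducible regardless of order.
    """
    if n_stones < 0 or n_phleboliths < 0:
        raise CalcnetError("cohort counts must be >= 0")
    dists = distributions or CohortDistributions()
    stacks: list[CTStack] = []
    rows = []
    labels = [STONE] * n_stones + [PHLEBOLITH] * n_phleboliths
    for i, label in enumerate(labels):
        prng = substream(seed, "phantom-params", i)
        params = dists.sample_params(label, prng)
        params = replace(params, seed=substream_seed(seed, "phantom-render", i))
        sid = f"{id_prefix}{i:04d}"
        stacks.append(generate_stack(params, shape=shape, spacing=spacing, id=sid))
        rows.append({
            "id": sid, "label": label,
            "diameter_mm": round(params.max_diameter_mm, 3),
            "peak_hu": round(params.peak_hu, 1),
            "seed": params.seed,
            "rim": int(params.rim_present),
            "lucency": int(params.lucency_present),
            "comet": int(params.comet_present),
        })
    manifest = pd.DataFrame(rows, columns=["id", "label", "diameter_mm",
                                           "peak_hu", "seed", "rim",
                                           "lucency", "comet"])
    return stacks, manifest
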