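"""Synthetic inputs for the whole pipeline.

Real inputs to this pipeline are (a) instance label masks from a nucleus
segmentation network, (b) ROI polygon annotations, and (c) per-case tables
counting the patches a classifier assigned to each category.  None of
these can be redistributed, so this module generates statistically
controlled stand-ins with recoverable ground truth:

* nuclei are radially perturbed ellipses — lognormal area, gamma-shifted
  axis ratio (support >= 1 with exact target mean), a single low-order
  Fourier perturbation of the radius — placed without overlap by rejection
  sampling.  Every shape descriptor the morphometry module measures has an
  analytic or near-analytic target, so parameter-recovery tests are exact
  up to discretization;
* intensities inside each nucleus are drawn equiprobably from
  ``texture_levels`` distinct gray levels, making the target Shannon
  entropy exactly log2(texture_levels);
* patch-count tables are multinomial draws over Dirichlet-sampled
  category compositions, mimicking how a patch classifier's per-case
  predictions concentrate on the true category with small spill-over.

Class profile defaults are ordered so that expected cellularity ranks
glioblastoma tumor cell area > anaplastic astrocytoma > microvascular
proliferation > diffuse astrocytoma > necrosis, the ordering observed in
astrocytic-tumor cohorts, with per-class nuclear size, elongation and
texture levels set to the same cohort-scale magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .categories import CATEGORIES, DIAGNOSES
from .morphometry import DEFAULT_MPP
from .tiling import ROIAnnotation

__all__ = [
    "ClassProfile",
    "MixtureSpec",
    "default_profiles",
    "default_mixture_specs",
    "generate_nucleus_image",
    "generate_patch_count_table",
    "generate_roi",
]

_MAX_PLACEMENT_TRIES = 100  # rejection-sampling cap per nucleus


@dataclass(frozen=True)
class ClassProfile:
    """Generative parameters for one annotation category's tissue.

    nucleus_density is the expected nuclei per 100x100 µm tile; area is
    lognormal (mean/sd in µm²); axis ratio is 1 + Gamma with the stated
    mean/sd; boundary_noise is the relative radial perturbation amplitude;
    texture_levels sets the per-nucleus count of distinct gray levels.
    """

    category: str
    nucleus_density: float
    area_mean: float
    area_sd: float
    axis_ratio_mean: float
    axis_ratio_sd: float
    boundary_noise: float
    texture_levels: int
    rng_seed: int = 0

    def __post_init__(self):
        if self.nucleus_density < 0:
            raise ValueError("nucleus_density must be >= 0")
        if self.area_mean <= 0 or self.area_sd < 0:
            raise ValueError("area_mean must be > 0 and area_sd >= 0")
        if self.axis_ratio_mean < 1 or self.axis_ratio_sd < 0:
            raise ValueError("axis_ratio_mean must be >= 1 and sd >= 0")
        if not 0 <= self.boundary_noise <= 0.5:
            raise ValueError("boundary_noise must lie in [0, 0.5]")
        if self.texture_levels < 1:
            raise ValueError("texture_levels must be >= 1")


def default_profiles(seed: int = 0) -> dict[str, ClassProfile]:
    """Per-category profiles at cohort-scale magnitudes.

    Densities are chosen so that expected cellularity
    (density x mean area / 10^4 µm²) reproduces the published ordering
    tumor cell (~0.195) > anaplastic (~0.18) > MVP (~0.12) > diffuse
    (~0.05) > necrosis (~0.003).
    """
    base = dict(zip(
        CATEGORIES,
        [
            # density, area_mean, area_sd, ar_mean, ar_sd, noise, levels
            (24.0, 21.3, 9.1, 1.44, 0.30, 0.04, 30),
            (69.0, 26.0, 12.8, 1.54, 0.35, 0.06, 27),
            (64.0, 30.5, 15.2, 1.57, 0.35, 0.08, 28),
            (2.2, 13.7, 7.4, 1.50, 0.33, 0.03, 30),
            (48.0, 25.3, 13.6, 1.73, 0.45, 0.10, 26),
        ],
    ))
    return {
        cat: ClassProfile(cat, *vals, rng_seed=seed + i)
        for i, (cat, vals) in enumerate(base.items())
    }


def _sample_axis_ratio(rng: np.random.Generator, mean: float, sd: float) -> float:
    # 1 + Gamma keeps support >= 1 with the target mean exact (no truncation bias)
    if sd == 0 or mean == 1.0:
        return mean
    shape = ((mean - 1.0) / sd) ** 2
    scale = sd**2 / (mean - 1.0)
    return 1.0 + float(rng.gamma(shape, scale))


def _sample_area(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return mean
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


class _NucleusShape:
    """One perturbed ellipse in polar form: r(phi) = s * r_e(phi) * (1 + eps sin(k phi + p0)).

    The polar representation gives an exact pixel-center membership test, so
    rasterized areas are unbiased estimates of the analytic target area.
    """

    def __init__(self, rng: np.random.Generator, area_px: float, q: float, noise: float):
        self.a = np.sqrt(q)  # unit-area ellipse semi-axes up to scale
        self.b = 1.0 / np.sqrt(q)
        self.k = int(rng.integers(3, 7))
        self.phase = rng.uniform(0, 2 * np.pi)
        self.noise = noise
        self.theta = rng.uniform(0, np.pi)
        # continuous area = s^2 * (1/2) int r_e^2 (1 + eps sin)^2 dphi
        phi = np.linspace(0.0, 2 * np.pi, 4096, endpoint=False)
        r = self._unit_radius(phi)
        self.scale = np.sqrt(area_px / (0.5 * np.sum(r**2) * (2 * np.pi / phi.size)))
        self.max_radius = float(self.scale * r.max())

    def _unit_radius(self, phi: np.ndarray) -> np.ndarray:
        r_e = self.a * self.b / np.hypot(self.b * np.cos(phi), self.a * np.sin(phi))
        return r_e * (1.0 + self.noise * np.sin(self.k * phi + self.phase))

    def radius_at(self, alpha: np.ndarray) -> np.ndarray:
        """Boundary radius at world angle(s) alpha (orientation applied)."""
        return self.scale * self._unit_radius(alpha - self.theta)

    def rasterize(self, cy: float, cx: float, shape: tuple[int, int]):
        """Pixel-center rasterization clipped to the image: (rows, cols, clipped)."""
        h, w = shape
        rmax = self.max_radius
        r0, r1 = int(np.floor(cy - rmax)), int(np.ceil(cy + rmax))
        c0, c1 = int(np.floor(cx - rmax)), int(np.ceil(cx + rmax))
        clipped = r0 < 0 or c0 < 0 or r1 > h - 1 or c1 > w - 1
        rr, cc = np.mgrid[max(r0, 0) : min(r1, h - 1) + 1, max(c0, 0) : min(c1, w - 1) + 1]
        dy, dx = rr - cy, cc - cx
        inside = np.hypot(dy, dx) <= self.radius_at(np.arctan2(dy, dx))
        return rr[inside], cc[inside], clipped


def generate_nucleus_image(
    profile: ClassProfile,
    width_px: int = 512,
    height_px: int = 512,
    mpp: float = DEFAULT_MPP,
    n_nuclei: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Simulate one field of non-overlapping nuclei for a class profile.

    Returns ``(label_mask, intensity, truth)``: a uint16 label mask
    (0 = background), a uint8 grayscale image, and a per-nucleus ground
    truth table (sampled area in µm², axis ratio, center, clipping flag).
    Deterministic given ``profile.rng_seed`` (or an explicit ``rng``).
    The nucleus count is Poisson around the density target unless
    ``n_nuclei`` pins it; placement failures after a bounded number of
    rejections yield fewer nuclei, recorded in ``truth.attrs['n_failed']``.
    """
    if width_px < 64 or height_px < 64:
        raise ValueError("image must be at least 64x64 px")
    if mpp <= 0:
        raise ValueError("mpp must be positive")
    rng = np.random.default_rng(profile.rng_seed) if rng is None else rng

    tile_area_um2 = width_px * height_px * mpp**2
    lam = profile.nucleus_density * tile_area_um2 / 1e4
    n_target = int(rng.poisson(lam)) if n_nuclei is None else int(n_nuclei)

    labels = np.zeros((height_px, width_px), dtype=np.uint16)
    intensity = np.full((height_px, width_px), 235, dtype=np.uint8)
    gray_levels = np.unique(
        np.round(np.linspace(30, 220, profile.texture_levels)).astype(np.uint8)
    )

    records = []
    n_failed = 0
    next_label = 1
    for _ in range(n_target):
        area_um2 = _sample_area(rng, profile.area_mean, profile.area_sd)
        q = _sample_axis_ratio(rng, profile.axis_ratio_mean, profile.axis_ratio_sd)
        nucleus = _NucleusShape(rng, area_um2 / mpp**2, q, profile.boundary_noise)
        placed = False
        for _ in range(_MAX_PLACEMENT_TRIES):
            cy = rng.uniform(0, height_px)
            cx = rng.uniform(0, width_px)
            rr, cc, clipped = nucleus.rasterize(cy, cx, labels.shape)
            if rr.size == 0 or np.any(labels[rr, cc]):
                continue
            labels[rr, cc] = next_label
            intensity[rr, cc] = rng.choice(gray_levels, size=rr.size)
            records.append(
                {
                    "instance_id": next_label,
                    "area_um2": area_um2,
                    "axis_ratio": q,
                    "center_row": cy,
                    "center_col": cx,
                    "orientation": nucleus.theta,
                    "harmonic": nucleus.k,
                    "n_pixels": int(rr.size),
                    "clipped": bool(clipped),
                }
            )
            next_label += 1
            placed = True
            break
        if not placed:
            n_failed += 1

    truth = pd.DataFrame(
        records,
        columns=[
            "instance_id", "area_um2", "axis_ratio", "center_row", "center_col",
            "orientation", "harmonic", "n_pixels", "clipped",
        ],
    )
    truth.attrs["n_requested"] = n_target
    truth.attrs["n_failed"] = n_failed
    truth.attrs["category"] = profile.category
    return labels, intensity, truth


@dataclass(frozen=True)
class MixtureSpec:
    """Composition of one simulated case's patch predictions."""

    true_diagnosis: str
    dirichlet_alphas: tuple[float, ...]
    n_patches: int
    case_id: str = ""

    def __post_init__(self):
        if self.true_diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {self.true_diagnosis!r}")
        if len(self.dirichlet_alphas) != len(CATEGORIES):
            raise ValueError(f"need {len(CATEGORIES)} Dirichlet alphas")
        if any(a <= 0 for a in self.dirichlet_alphas):
            raise ValueError("Dirichlet alphas must be positive")
        if self.n_patches < 1:
            raise ValueError("n_patches must be >= 1")


def default_mixture_specs(
    n_per_diagnosis: int = 5,
    n_patches: int = 400,
    concentration: float = 50.0,
    spill_alpha: float = 0.1,
) -> list[MixtureSpec]:
    """Cases whose predictions concentrate on the true diagnosis's categories.

    The off-category Dirichlet weight defaults to 0.1 so the expected
    spill-over ratio per wrong category is spill_alpha / (alpha sum) ~ 0.002,
    the per-mille scale seen in real per-case prediction tables; glioblastoma
    cases spread their concentration over the three hallmark categories.
    """
    own = {
        "diffuse_astrocytoma": [0],
        "anaplastic_astrocytoma": [1],
        "glioblastoma": [2, 3, 4],
    }
    specs = []
    for diag in DIAGNOSES:
        alphas = np.full(len(CATEGORIES), spill_alpha)
        alphas[own[diag]] = concentration / len(own[diag])
        for i in range(n_per_diagnosis):
            specs.append(
                MixtureSpec(diag, tuple(alphas), n_patches, f"{diag}_{i}")
            )
    return specs


def generate_patch_count_table(specs, seed: int = 0) -> pd.DataFrame:
    """Multinomial patch-prediction counts for a list of case mixtures.

    Per case the category composition is Dirichlet-sampled from the spec's
    alphas, then counts are multinomial over ``n_patches``.  Reproducible
    per seed.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("specs must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for i, spec in enumerate(specs):
        p = rng.dirichlet(spec.dirichlet_alphas)
        counts = rng.multinomial(spec.n_patches, p)
        rows.append(
            {
                "case_id": spec.case_id or f"case_{i}",
                "true_diagnosis": spec.true_diagnosis,
                **dict(zip(CATEGORIES, counts.tolist())),
            }
        )
    return pd.DataFrame(rows)


def generate_roi(
    vertices,
    category: str,
    roi_id: str = "roi_0",
    slide_id: str = "slide_0",
) -> ROIAnnotation:
    """Wrap a vertex list as a validated ROI annotation.

    Rejects self-intersecting polygons with a diagnostic naming the defect.
    """
    poly = Polygon(vertices)
    if not poly.is_valid:
        from shapely.validation import explain_validity

        raise ValueError(
            f"ROI {roi_id}: invalid polygon ({explain_validity(poly)})"
        )
    return ROIAnnotation(
        roi_id=roi_id,
        category=category,
        polygon=tuple((float(x), float(y)) for x, y in vertices),
        slide_id=slide_id,
    )
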