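"""Synthetic inputs with known ground truth for the whole pipeline.

Four generators:

* :func:`make_phantom` — a voxelised nested-ellipse abdominal phantom using
  the six-class scheme (body wall of subcutaneous fat around external muscle
  around the abdominal cavity, with visceral-fat blobs and paired psoas
  discs inside).
* :func:`corrupt_segmentation` — imperfect "rater"/"model" segmentations of a
  ground truth: smooth random boundary displacement in mm, per-class
  over-/under-segmentation bias, and stray label flips.
* :func:`simulate_cohort` — paired test-retest tissue-volume cohorts with
  log-normal between-subject volumes and multiplicative (log-normal)
  within-subject error, gender covariates and an optional true day-180
  change.
* :func:`simulate_bias_observations` — per-slice area differences between
  segmentation models and a consensus ground truth, generated from the
  hierarchical linear-bias model (intercept, slope in area, inter-model
  random effect, residual noise).

All generators are bit-reproducible given their spec (a single seed fans out
to per-component substreams via ``numpy.random.SeedSequence``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import LabelVolume

#: female/male default per-tissue log-scale volume parameters (mL).  Chosen to
#: mirror typical adult abdominal-MRI body-composition magnitudes: females
#: carry more subcutaneous fat, males more visceral fat and muscle.
_DEFAULT_LOG_MEAN = {
    "F": {"SF": np.log(7000.0), "VF": np.log(1400.0), "PM": np.log(260.0), "EM": np.log(1800.0)},
    "M": {"SF": np.log(4500.0), "VF": np.log(2600.0), "PM": np.log(380.0), "EM": np.log(2600.0)},
}

#: default within-subject log-SD per tissue; approximately the wCV, set to the
#: repeatability regime this kind of study reports (SF/EM tight, PM loose).
_DEFAULT_SIGMA_W = {"SF": 0.041, "VF": 0.10, "PM": 0.23, "EM": 0.018}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the abdominal phantom; all physical parameters in mm."""

    n_slices: int = 25
    in_plane: tuple[int, int] = (128, 96)
    spacing: tuple[float, float, float] = (1.46, 1.46, 4.0)
    body_radii_mm: tuple[float, float] = (80.0, 55.0)
    sf_thickness_mm: float = 12.0
    em_thickness_mm: float = 10.0
    vf_blob_count: int = 6
    vf_blob_radius_mm: tuple[float, float] = (6.0, 11.0)
    pm_disc_radius_mm: float = 8.0
    pm_disc_offsets_mm: tuple[tuple[float, float], ...] = ((-22.0, -18.0), (22.0, -18.0))

    def __post_init__(self) -> None:
        if self.n_slices < 1 or min(self.in_plane) < 8:
            raise ValueError("phantom grid too small")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be positive")
        rx, ry = self.body_radii_mm
        wall = self.sf_thickness_mm + self.em_thickness_mm
        if not (rx > 0 and ry > 0 and self.sf_thickness_mm > 0 and self.em_thickness_mm > 0):
            raise ValueError("radii and ring thicknesses must be positive")
        if wall >= min(rx, ry):
            raise ValueError("rings not nested: SF+EM wall thicker than the body radius")


def _ellipse_mask(xx: np.ndarray, yy: np.ndarray, cx: float, cy: float, rx: float, ry: float) -> np.ndarray:
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> LabelVolume:
    """Voxelise the nested-ellipse phantom; deterministic given the spec.

    The axial cross-section is an elliptic cylinder: subcutaneous fat (2)
    outermost, external muscle (5) inside it, then the abdominal cavity whose
    base label is cavity-excluded (1), holding visceral-fat blobs (3) placed
    on a deterministic interior ring and two psoas discs (4).
    """
    nx, ny = spec.in_plane
    dx, dy, _ = spec.spacing
    # voxel-centre physical coordinates, origin at the in-plane centre
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    xx, yy = np.meshgrid(x, y, indexing="ij")

    rx, ry = spec.body_radii_mm
    sf_rx, sf_ry = rx - spec.sf_thickness_mm, ry - spec.sf_thickness_mm
    cav_rx, cav_ry = sf_rx - spec.em_thickness_mm, sf_ry - spec.em_thickness_mm

    plane = np.zeros((nx, ny), dtype=np.int16)
    plane[_ellipse_mask(xx, yy, 0, 0, rx, ry)] = 2  # SF
    plane[_ellipse_mask(xx, yy, 0, 0, sf_rx, sf_ry)] = 5  # EM
    cavity = _ellipse_mask(xx, yy, 0, 0, cav_rx, cav_ry)
    plane[cavity] = 1  # cavity-excluded base

    # visceral-fat blobs on a deterministic ring, radii evenly spanning range
    if spec.vf_blob_count > 0:
        r_lo, r_hi = spec.vf_blob_radius_mm
        radii = np.linspace(r_lo, r_hi, spec.vf_blob_count)
        ring_r = 0.55 * min(cav_rx, cav_ry)
        angles = 2 * np.pi * np.arange(spec.vf_blob_count) / spec.vf_blob_count + np.pi / 2
        for ang, rad in zip(angles, radii):
            cx, cy = ring_r * np.cos(ang) * cav_rx / min(cav_rx, cav_ry), ring_r * np.sin(ang)
            blob = _ellipse_mask(xx, yy, cx, cy, rad, rad) & cavity
            plane[blob] = 3

    for cx, cy in spec.pm_disc_offsets_mm:
        disc = _ellipse_mask(xx, yy, cx, cy, spec.pm_disc_radius_mm, spec.pm_disc_radius_mm)
        if not disc.any() or (disc & ~cavity).any():
            raise ValueError("psoas disc extends outside the abdominal cavity")
        plane[disc] = 4

    grid = np.repeat(plane[:, :, None], spec.n_slices, axis=2)
    return LabelVolume(grid, spec.spacing)


def sf_ring_volume_ml(spec: PhantomSpec) -> float:
    """Closed-form volume (mL) of the phantom's subcutaneous-fat ring.

    Elliptic-cylinder shell: ``pi*(rx*ry - (rx-t)(ry-t)) * height / 1000``.
    """
    rx, ry = spec.body_radii_mm
    t = spec.sf_thickness_mm
    height = spec.n_slices * spec.spacing[2]
    return float(np.pi * (rx * ry - (rx - t) * (ry - t)) * height / 1000.0)


@dataclass(frozen=True)
class CorruptionSpec:
    """Imperfection model for one simulated rater/segmentation model.

    ``displacement_mm`` is the RMS amplitude of a smooth random boundary
    displacement field (correlation length ``smoothness_mm``);
    ``class_bias_mm`` maps a label to a signed over(+)/under(-)-segmentation
    margin in mm; ``flip_rate`` is the fraction of voxels replaced by a
    uniformly random label.
    """

    displacement_mm: float = 1.5
    class_bias_mm: dict[int, float] = field(default_factory=dict)
    flip_rate: float = 0.0
    smoothness_mm: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.displacement_mm < 0 or self.smoothness_mm <= 0:
            raise ValueError("displacement must be >= 0 and smoothness > 0")
        if not 0 <= self.flip_rate < 1:
            raise ValueError("flip_rate must lie in [0, 1)")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, ...], sigma_vox: tuple[float, ...]) -> np.ndarray:
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="nearest")
    rms = np.sqrt(np.mean(smooth**2))
    return smooth / rms if rms > 0 else smooth


def corrupt_segmentation(truth: LabelVolume, spec: CorruptionSpec) -> LabelVolume:
    """Produce an imperfect segmentation of *truth* per the corruption spec.

    Order of operations: smooth boundary displacement (label lookup through a
    random deformation field, nearest-neighbour so labels stay in scheme),
    then per-class dilation/erosion by the signed bias margin, then random
    label flips.  All randomness derives from ``spec.seed``.
    """
    ss = np.random.SeedSequence(spec.seed).spawn(3)
    grid = truth.grid
    spacing = np.asarray(truth.spacing)

    if spec.displacement_mm > 0:
        rng = np.random.default_rng(ss[0])
        sigma_vox = tuple(spec.smoothness_mm / s for s in spacing)
        coords = np.meshgrid(*[np.arange(n, dtype=float) for n in grid.shape], indexing="ij")
        warped = []
        for ax in range(3):
            disp_vox = spec.displacement_mm / spacing[ax]
            warped.append(coords[ax] + disp_vox * _smooth_field(rng, grid.shape, sigma_vox))
        grid = ndimage.map_coordinates(grid, warped, order=0, mode="nearest")

    for lab in sorted(spec.class_bias_mm):
        bias = spec.class_bias_mm[lab]
        if bias == 0:
            continue
        mask = grid == lab
        if not mask.any():
            continue
        if bias > 0:
            dist = ndimage.distance_transform_edt(~mask, sampling=truth.spacing)
            grid = np.where(dist <= bias, lab, grid)
        else:
            dist = ndimage.distance_transform_edt(mask, sampling=truth.spacing)
            shrink = mask & (dist <= -bias)
            # ceded voxels inherit the nearest non-class label
            _, idx = ndimage.distance_transform_edt(
                mask, sampling=truth.spacing, return_indices=True
            )
            grid = grid.copy()
            grid[shrink] = grid[tuple(i[shrink] for i in idx)]

    if spec.flip_rate > 0:
        rng = np.random.default_rng(ss[2])
        n_flip = int(round(spec.flip_rate * grid.size))
        flat = grid.ravel().copy()
        pos = rng.choice(grid.size, size=n_flip, replace=False)
        flat[pos] = rng.integers(0, 6, size=n_flip)
        grid = flat.reshape(grid.shape)

    return LabelVolume(np.ascontiguousarray(grid), truth.spacing, truth.orientation)


@dataclass(frozen=True)
class CohortSpec:
    """Statistical structure of a double-baseline + day-180 volume cohort.

    Between-subject true volumes are log-normal per gender and tissue;
    replicate measurements carry multiplicative log-normal within-subject
    error with log-SD ``sigma_w`` (optionally per gender), so the
    within-subject coefficient of variation is ``sqrt(exp(sigma_w^2)-1)``,
    approximately ``sigma_w``.  A per-patient true day-180 fractional change
    is drawn Normal(``change_mean``, ``change_sd``).
    """

    n_patients: int = 49
    female_fraction: float = 0.5
    log_mean: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in _DEFAULT_LOG_MEAN.items()}
    )
    log_sd: float = 0.35
    sigma_w: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_SIGMA_W))
    sigma_w_by_gender: dict[str, dict[str, float]] | None = None
    change_mean: float = 0.0
    change_sd: float = 0.0
    followup_fraction: float = 38.0 / 49.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or not 0 <= self.female_fraction <= 1:
            raise ValueError("invalid cohort size or gender fraction")
        if any(s < 0 for s in self.sigma_w.values()) or self.log_sd < 0:
            raise ValueError("SDs must be non-negative")

    def sigma_for(self, tissue: str, gender: str) -> float:
        if self.sigma_w_by_gender and gender in self.sigma_w_by_gender:
            if tissue in self.sigma_w_by_gender[gender]:
                return self.sigma_w_by_gender[gender][tissue]
        return self.sigma_w[tissue]


def simulate_cohort(spec: CohortSpec = CohortSpec()) -> pd.DataFrame:
    """Simulate a volume table (one row per patient/visit/tissue, mL)."""
    ss = np.random.SeedSequence(spec.seed).spawn(2)
    rng = np.random.default_rng(ss[0])
    rng_err = np.random.default_rng(ss[1])

    n_f = int(round(spec.female_fraction * spec.n_patients))
    genders = ["F"] * n_f + ["M"] * (spec.n_patients - n_f)
    tissues = sorted(spec.sigma_w)
    has_followup = np.zeros(spec.n_patients, dtype=bool)
    n_fu = int(round(spec.followup_fraction * spec.n_patients))
    has_followup[:n_fu] = True
    rng.shuffle(has_followup)

    rows = []
    for i, gender in enumerate(genders):
        pid = f"P{i + 1:03d}"
        change = rng.normal(spec.change_mean, spec.change_sd) if spec.change_sd or spec.change_mean else spec.change_mean
        for tissue in tissues:
            true_v = float(np.exp(rng.normal(spec.log_mean[gender][tissue], spec.log_sd)))
            sw = spec.sigma_for(tissue, gender)
            for visit in ("baseline1", "baseline2"):
                v = true_v * float(np.exp(rng_err.normal(0.0, sw))) if sw > 0 else true_v
                rows.append((pid, visit, gender, tissue, v))
            if has_followup[i]:
                v = true_v * (1.0 + change)
                v *= float(np.exp(rng_err.normal(0.0, sw))) if sw > 0 else 1.0
                rows.append((pid, "day180", gender, tissue, max(v, 1e-9)))
    return pd.DataFrame(rows, columns=["patient", "visit", "gender", "tissue", "volume_ml"])


@dataclass(frozen=True)
class BiasSimSpec:
    """Generating parameters of the hierarchical area-bias model.

    ``delta[n, m] = alpha + beta * (a[n] - mean(a)) + u[m] + eps[n, m]`` with
    ``u ~ N(0, sigma_inter^2)`` (model random effect) and
    ``eps ~ N(0, sigma_intra^2)``.  Areas are uniform on
    ``[area_low, area_high]`` cm².
    """

    n_slices: int = 25
    n_models: int = 15
    area_low: float = 50.0
    area_high: float = 200.0
    alpha: float = -5.0
    beta: float = -0.05
    sigma_inter: float = 1.5
    sigma_intra: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 2 or self.n_models < 2:
            raise ValueError("need at least 2 slices and 2 models")
        if self.sigma_inter < 0 or self.sigma_intra < 0:
            raise ValueError("variance components must be non-negative")
        if not self.area_high > self.area_low > 0:
            raise ValueError("area range must be positive and increasing")


def simulate_bias_observations(spec: BiasSimSpec = BiasSimSpec()) -> pd.DataFrame:
    """Simulate the (slice, model, area, difference) bias-observation table."""
    ss = np.random.SeedSequence(spec.seed).spawn(3)
    rng_a = np.random.default_rng(ss[0])
    rng_u = np.random.default_rng(ss[1])
    rng_e = np.random.default_rng(ss[2])

    a = rng_a.uniform(spec.area_low, spec.area_high, size=spec.n_slices)
    u = rng_u.normal(0.0, spec.sigma_inter, size=spec.n_models) if spec.sigma_inter > 0 else np.zeros(spec.n_models)
    eps = (
        rng_e.normal(0.0, spec.sigma_intra, size=(spec.n_slices, spec.n_models))
        if spec.sigma_intra > 0
        else np.zeros((spec.n_slices, spec.n_models))
    )
    delta = spec.alpha + spec.beta * (a[:, None] - a.mean()) + u[None, :] + eps

    n_idx, m_idx = np.meshgrid(np.arange(spec.n_slices), np.arange(spec.n_models), indexing="ij")
    return pd.DataFrame(
        {
            "slice": n_idx.ravel() + 1,
            "model": m_idx.ravel() + 1,
            "area_cm2": a[n_idx.ravel()],
            "diff_cm2": delta.ravel(),
        }
    )
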