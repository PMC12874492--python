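"""Seeded generator of ultrasound-like phantoms.

Real thyroid ultrasound poses a specific bundle of difficulties: granular
multiplicative speckle, a single hypo-intense (dark) nodule whose size and
eccentricity vary widely, blurred boundaries, occasional dark acoustic-
shadow bands, and labels whose boundaries wobble slightly between
annotators.  The generator emulates each of these with controllable
strength so the segmentation pipeline can be exercised across easy-to-hard
regimes without any external dataset:

* nodule geometry — a rotated ellipse whose radius is modulated by
  low-frequency radial harmonics (irregular, mildly spiculated outlines),
  rescaled so the enclosed area matches a target fraction of the image;
* intensity — two-level image (background vs. darker nodule) smoothed by a
  Gaussian to soften the boundary;
* speckle — a Rayleigh random field, spatially smoothed to the typical
  grain size and applied multiplicatively;
* shadow — a soft-edged vertical band of reduced gain below the nodule;
* label noise — a smooth random displacement of the mask boundary, strictly
  confined to a band around the true contour.

Synthetic "patients" contribute several re-rendered views of the same
nodule so patient-level grouped splitting is meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .errors import ConfigurationError, InvalidParameterError

__all__ = [
    "PhantomConfig", "SegmentationSample",
    "generate_phantom", "jitter_label", "generate_dataset",
    "write_dataset", "read_dataset",
]


@dataclass
class PhantomConfig:
    """Knobs of the phantom generator (lengths in pixels, areas as
    fractions of the image)."""

    image_size: int = 256
    area_range: tuple[float, float] = (0.02, 0.18)
    axis_ratio_range: tuple[float, float] = (0.45, 1.0)
    background_level: float = 0.55
    contrast: float = 0.30
    boundary_blur_sigma: float = 1.5
    speckle_strength: float = 0.40
    speckle_grain: float = 1.0
    shadow_prob: float = 0.30
    shadow_width_range: tuple[float, float] = (0.08, 0.25)
    shadow_gain: float = 0.55
    jitter_magnitude: float = 2.0
    allow_empty: bool = False

    def __post_init__(self):
        lo, hi = self.area_range
        if not (0.0 < lo < hi <= 0.5):
            raise ConfigurationError("area_range must satisfy 0 < lo < hi <= 0.5")
        qlo, qhi = self.axis_ratio_range
        if not (0.0 < qlo < qhi <= 1.0):
            raise ConfigurationError("axis_ratio_range must satisfy 0 < lo < hi <= 1")
        if self.boundary_blur_sigma < 0:
            raise ConfigurationError("boundary blur sigma must be >= 0")
        if self.speckle_strength < 0 or self.contrast < 0:
            raise ConfigurationError("speckle strength and contrast must be >= 0")
        if not (0.0 <= self.shadow_prob <= 1.0):
            raise ConfigurationError("shadow probability must lie in [0, 1]")
        # the largest nodule must fit inside the image at some placement
        r_max = np.sqrt(hi / (np.pi * qlo)) * (1.0 + _HARMONIC_AMP_TOTAL)
        if r_max + 0.02 > 0.48:
            raise ConfigurationError(
                "area/axis-ratio ranges admit nodules too large for the image")


@dataclass
class SegmentationSample:
    """One image with its exact and annotator-jittered masks."""

    image: np.ndarray          # (H, W) float in [0, 1]
    mask: np.ndarray           # (H, W) bool, exact ground truth
    noisy_mask: np.ndarray     # (H, W) bool, boundary-jittered variant
    patient_id: str
    sample_id: str = ""


# amplitude budget of the radial harmonics (modes 2..5)
_HARMONIC_MODES = (2, 3, 4, 5)
_HARMONIC_AMP_TOTAL = 0.20


@dataclass
class _Geometry:
    center: tuple[float, float]     # (row, col) in units of image size
    area_frac: float
    axis_ratio: float
    angle: float
    amps: np.ndarray
    phases: np.ndarray


def _sample_geometry(cfg: PhantomConfig, rng: np.random.Generator) -> _Geometry:
    area_frac = rng.uniform(*cfg.area_range)
    axis_ratio = rng.uniform(*cfg.axis_ratio_range)
    # keep the whole (harmonically inflated) outline inside the frame
    r_max = np.sqrt(area_frac / (np.pi * axis_ratio)) * (1.0 + _HARMONIC_AMP_TOTAL)
    margin = min(0.45, r_max + 0.02)
    return _Geometry(
        center=(rng.uniform(margin, 1.0 - margin),
                rng.uniform(margin, 1.0 - margin)),
        area_frac=area_frac,
        axis_ratio=axis_ratio,
        angle=rng.uniform(0.0, np.pi),
        amps=rng.uniform(0.0, _HARMONIC_AMP_TOTAL / len(_HARMONIC_MODES),
                         size=len(_HARMONIC_MODES)),
        phases=rng.uniform(0.0, 2 * np.pi, size=len(_HARMONIC_MODES)),
    )


def _radius_profile(geom: _Geometry, phi: np.ndarray, size: int) -> np.ndarray:
    """Nodule radius at polar angle phi, normalised to the target area."""
    a = np.sqrt(geom.area_frac / (np.pi * geom.axis_ratio)) * size
    b = geom.axis_ratio * a
    rel = phi - geom.angle
    r_ell = a * b / np.sqrt((b * np.cos(rel)) ** 2 + (a * np.sin(rel)) ** 2)
    mod = np.ones_like(phi)
    for k, amp, ph in zip(_HARMONIC_MODES, geom.amps, geom.phases):
        mod += amp * np.cos(k * phi + ph)
    r = r_ell * mod
    # renormalise so the enclosed area (∫ r²/2 dφ) hits the target exactly
    grid = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    rel_g = grid - geom.angle
    r_g = a * b / np.sqrt((b * np.cos(rel_g)) ** 2 + (a * np.sin(rel_g)) ** 2)
    mod_g = np.ones_like(grid)
    for k, amp, ph in zip(_HARMONIC_MODES, geom.amps, geom.phases):
        mod_g += amp * np.cos(k * grid + ph)
    area_num = 0.5 * np.sum((r_g * mod_g) ** 2) * (2 * np.pi / grid.size)
    r *= np.sqrt(geom.area_frac * size * size / area_num)
    return r


def _render_mask(cfg: PhantomConfig, geom: _Geometry) -> np.ndarray:
    n = cfg.image_size
    rows, cols = np.mgrid[0:n, 0:n].astype(np.float64)
    dy = rows - geom.center[0] * n
    dx = cols - geom.center[1] * n
    rho = np.hypot(dy, dx)
    phi = np.arctan2(dy, dx)
    return rho <= _radius_profile(geom, phi, n)


def _render_image(cfg: PhantomConfig, mask: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    n = cfg.image_size
    img = np.full((n, n), cfg.background_level, dtype=np.float64)
    img[mask] = cfg.background_level - cfg.contrast
    if cfg.boundary_blur_sigma > 0:
        img = ndimage.gaussian_filter(img, cfg.boundary_blur_sigma)
    if mask.any() and rng.uniform() < cfg.shadow_prob:
        width = rng.uniform(*cfg.shadow_width_range) * n
        cols_in = np.where(mask.any(axis=0))[0]
        cx = rng.uniform(cols_in.min(), cols_in.max())
        y0 = np.where(mask.any(axis=1))[0].max()
        col_gain = 1.0 - (1.0 - cfg.shadow_gain) * np.exp(
            -0.5 * ((np.arange(n) - cx) / (width / 2.0)) ** 2)
        depth = 1.0 / (1.0 + np.exp(-(np.arange(n) - y0) / 2.0))
        img *= 1.0 - np.outer(depth, 1.0 - col_gain)
    if cfg.speckle_strength > 0:
        field = ndimage.gaussian_filter(rng.rayleigh(1.0, size=(n, n)),
                                        cfg.speckle_grain)
        field /= field.mean()
        img = img * (1.0 + cfg.speckle_strength * (field - 1.0))
    return np.clip(img, 0.0, 1.0)


def generate_phantom(cfg: PhantomConfig, seed: int,
                     patient_id: str | None = None,
                     geometry: "_Geometry | None" = None) -> SegmentationSample:
    """Render one phantom; bit-identical for identical ``(cfg, seed)``.

    The nodule is darker than the background by ``cfg.contrast``; its mask
    area lies in ``cfg.area_range`` (up to pixel quantisation); speckle is
    multiplicative.  ``geometry`` lets dataset generation reuse one
    nodule across the views of a synthetic patient.
    """
    rng = np.random.default_rng(seed)
    geom = geometry if geometry is not None else _sample_geometry(cfg, rng)
    mask = _render_mask(cfg, geom)
    if not mask.any() and not cfg.allow_empty:
        raise ConfigurationError("generated an empty mask; config infeasible")
    image = _render_image(cfg, mask, rng)
    noisy = jitter_label(mask, cfg.jitter_magnitude,
                         int(rng.integers(0, 2 ** 31)))
    return SegmentationSample(image=image, mask=mask, noisy_mask=noisy,
                              patient_id=patient_id or f"p{seed}")


def jitter_label(mask: np.ndarray, magnitude: float, seed: int) -> np.ndarray:
    """Boundary-jittered mask emulating inter-observer annotation noise.

    The true boundary is displaced by a smooth zero-mean random field whose
    excursion is clipped to ``magnitude`` pixels, so every flipped pixel
    lies within that distance of the original contour (as measured by the
    Euclidean distance transform).  ``magnitude = 0`` returns the mask
    unchanged.
    """
    mask = np.asarray(mask, dtype=bool)
    if magnitude < 0:
        raise InvalidParameterError("jitter magnitude must be >= 0")
    if magnitude == 0 or not mask.any():
        return mask.copy()
    dist_in = ndimage.distance_transform_edt(mask)
    if magnitude > dist_in.max():
        warnings.warn("jitter magnitude exceeds the nodule radius",
                      RuntimeWarning, stacklevel=2)
    dist_out = ndimage.distance_transform_edt(~mask)
    signed = dist_out - dist_in                     # >0 outside, <0 inside
    rng = np.random.default_rng(seed)
    eta = ndimage.gaussian_filter(rng.standard_normal(mask.shape),
                                  max(1.0, magnitude))
    sd = eta.std()
    if sd > 0:
        eta *= (magnitude / 2.0) / sd
    eta = np.clip(eta, -magnitude, magnitude)
    return signed <= eta


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def generate_dataset(cfg: PhantomConfig, n: int,
                     split: tuple[float, float, float] = (0.8, 0.1, 0.1),
                     seed: int = 0,
                     images_per_patient: tuple[int, int] = (5, 15),
                     ) -> tuple[list[SegmentationSample], ...]:
    """Patient-grouped train/val/test phantom sets.

    Synthetic patients contribute ``images_per_patient`` re-rendered views
    of one nodule geometry (fresh speckle/shadow/jitter, slightly moved and
    rotated).  Splitting is at patient level: no patient id ever appears in
    two splits.  Returns (train, val, test).
    """
    if n < 10:
        raise InvalidParameterError("need at least 10 samples to split")
    if abs(sum(split) - 1.0) > 1e-9 or any(s <= 0 for s in split):
        raise ConfigurationError("split ratios must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    patients: list[list[SegmentationSample]] = []
    total = 0
    while total < n:
        pid = f"patient{len(patients):04d}"
        prng = np.random.default_rng(rng.integers(0, 2 ** 31))
        geom = _sample_geometry(cfg, prng)
        # cap so small datasets still hold >= 3 patients for splitting
        n_img = min(int(prng.integers(images_per_patient[0],
                                      images_per_patient[1] + 1)),
                    max(1, n // 3), n - total)
        views = []
        r_max = np.sqrt(geom.area_frac / (np.pi * geom.axis_ratio)) \
            * (1.0 + _HARMONIC_AMP_TOTAL)
        lo = min(0.45, r_max + 0.02)
        for j in range(n_img):
            g = replace(geom,
                        center=(np.clip(geom.center[0] + prng.uniform(-0.04, 0.04),
                                        lo, 1.0 - lo),
                                np.clip(geom.center[1] + prng.uniform(-0.04, 0.04),
                                        lo, 1.0 - lo)),
                        angle=geom.angle + prng.uniform(-0.2, 0.2))
            s = generate_phantom(cfg, int(prng.integers(0, 2 ** 31)),
                                 patient_id=pid, geometry=g)
            s.sample_id = f"{pid}_{j:03d}"
            views.append(s)
        patients.append(views)
        total += n_img
    order = rng.permutation(len(patients))
    targets = [split[0] * n, (split[0] + split[1]) * n]
    splits: list[list[SegmentationSample]] = [[], [], []]
    count = 0
    for k in order:
        views = patients[k]
        if count < targets[0]:
            splits[0].extend(views)
        elif count < targets[1]:
            splits[1].extend(views)
        else:
            splits[2].extend(views)
        count += len(views)
    # every split must hold at least one patient
    for idx in (1, 2):
        if not splits[idx]:
            donor_pid = splits[0][-1].patient_id
            moved = [s for s in splits[0] if s.patient_id == donor_pid]
            splits[0] = [s for s in splits[0] if s.patient_id != donor_pid]
            splits[idx] = moved
    return tuple(splits)


# ---------------------------------------------------------------------------
# disk layout (also the import format for real datasets)
# ---------------------------------------------------------------------------

def _to_png(arr: np.ndarray, path: Path) -> None:
    Image.fromarray((np.clip(arr, 0, 1) * 255).round().astype(np.uint8)).save(path)


def write_dataset(splits: tuple[list[SegmentationSample], ...],
                  root: str | Path) -> pd.DataFrame:
    """Write image/, mask/, noisy_mask/ PNG trees plus manifest.csv."""
    root = Path(root)
    for sub in ("image", "mask", "noisy_mask"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    rows = []
    for split_name, samples in zip(("train", "val", "test"), splits):
        for s in samples:
            fname = f"{s.sample_id or s.patient_id}.png"
            _to_png(s.image, root / "image" / fname)
            _to_png(s.mask.astype(float), root / "mask" / fname)
            _to_png(s.noisy_mask.astype(float), root / "noisy_mask" / fname)
            rows.append({"filename": fname, "patient_id": s.patient_id,
                         "split": split_name})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(root / "manifest.csv", index=False)
    return manifest


def read_dataset(root: str | Path) -> dict[str, list[SegmentationSample]]:
    """Read the layout written by :func:`write_dataset`."""
    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv")
    out: dict[str, list[SegmentationSample]] = {"train": [], "val": [], "test": []}
    for row in manifest.itertuples():
        img = np.asarray(Image.open(root / "image" / row.filename),
                         dtype=np.float64) / 255.0
        mask = np.asarray(Image.open(root / "mask" / row.filename)) > 127
        noisy_path = root / "noisy_mask" / row.filename
        noisy = (np.asarray(Image.open(noisy_path)) > 127
                 if noisy_path.exists() else mask)
        out[row.split].append(SegmentationSample(
            image=img, mask=mask, noisy_mask=noisy,
            patient_id=str(row.patient_id),
            sample_id=Path(row.filename).stem))
    return out
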