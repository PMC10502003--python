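"""Synthetic ground-truth phantoms and simulated ensemble segmentations.

The generator reproduces the statistical structure the robustness
analysis assumes about trained segmentation models:

* a connected ground-truth organ phantom per image (ellipsoid or smooth
  random blob);
* J model outputs per image that are *mostly accurate* — small random
  affine jitter of the truth (rotation, scale, shear, translation, the
  ranges mirroring typical training-time augmentation) plus random
  boundary dilation/erosion — but with small independent per-model,
  per-image probabilities of **catastrophic failure**: a spatially
  distant spurious false-positive component, or the dropout of a
  connected chunk of the organ;
* an iid per-voxel **rater model** with known sensitivity/specificity,
  matching the generative assumptions of STAPLE exactly, for parameter-
  recovery tests.

Every artifact is a pure function of its spec including the master seed:
seeds are derived hierarchically via ``numpy.random.SeedSequence`` keyed
by (master seed, image index, model index), so each mask can be
regenerated in isolation and failures are independent across models.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, ImageRecord, StudyManifest, save_manifest, save_mask

_STRUCT_6 = ndimage.generate_binary_structure(3, 1)

__all__ = [
    "PhantomSpec",
    "ModelProfile",
    "StudySpec",
    "SharedBias",
    "StudyImage",
    "SyntheticStudy",
    "SpuriousPlacementError",
    "make_phantom",
    "simulate_model_output",
    "simulate_rater",
    "simulate_study",
    "write_study",
]

# Default noise amplitudes are calibrated to the *output* disagreement of
# trained ensemble members, not to training-augmentation ranges: on the
# desk-scale 64^3 grid the organ phantom is only ~15 voxels in radius, so
# per-model deviations of ~1 voxel plus a shared (correlated) per-image
# error reproduce the pooled single-model Dice (~0.9), the broad
# threshold plateau and the saturating ensemble gain that real Deep
# Ensembles exhibit.  Catastrophic failures (distant spurious components,
# partial dropouts) ride on top with small independent probabilities.


class SpuriousPlacementError(RuntimeError):
    """Raised when no voxel satisfies the spurious-component distance
    constraint on the given grid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Configuration of one ground-truth phantom.

    ``family="ellipsoid"`` builds an axis-aligned ellipsoid with the given
    semi-axes (voxels); ``family="blob"`` thresholds smoothed Gaussian
    noise at the quantile matching ``volume_fraction`` and keeps the
    largest connected component.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    family: str = "ellipsoid"
    semi_axes: tuple[float, float, float] = (16.0, 14.0, 12.0)
    center: tuple[float, float, float] | None = None
    blob_smooth_voxels: float = 6.0
    volume_fraction: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("ellipsoid", "blob"):
            raise ValueError(f"unknown phantom family {self.family!r}")
        if any(d <= 0 for d in self.grid_shape):
            raise ValueError(f"grid_shape must be positive, got {self.grid_shape}")
        if self.family == "ellipsoid" and any(a < 1 for a in self.semi_axes):
            raise ValueError(f"semi-axes must be >= 1 voxel, got {self.semi_axes}")
        if self.family == "blob" and not 0.0 < self.volume_fraction < 0.5:
            raise ValueError(
                f"volume_fraction must lie in (0, 0.5), got {self.volume_fraction}")


@dataclass(frozen=True)
class ModelProfile:
    """Noise profile of one simulated model.

    Affine jitter ranges are maxima of uniform draws.  Non-affine surface
    disagreement comes from sub-voxel surface roughening (random fraction
    of the one-voxel shells flipped, rate up to
    ``surface_roughen_max_rate``); whole-shell morphological noise
    (0..``boundary_noise_max_iter`` random dilate/erode iterations) is
    available but off by default — one full shell is a very coarse
    perturbation for a desk-scale phantom.  ``p_spurious`` / ``p_dropout``
    are per-image probabilities of the two catastrophic-failure modes.
    """

    rotation_max_deg: float = 1.5
    scale_max: float = 0.015
    shear_max: float = 0.015
    translation_max_voxels: float = 0.75
    boundary_noise_max_iter: int = 0
    surface_roughen_max_rate: float = 0.15
    p_spurious: float = 0.05
    spurious_volume_range: tuple[float, float] = (60.0, 400.0)
    spurious_min_distance_mm: float = 20.0
    p_dropout: float = 0.02
    dropout_fraction_range: tuple[float, float] = (0.25, 0.75)
    seed_offset: int = 0

    def __post_init__(self) -> None:
        for name in ("rotation_max_deg", "scale_max", "shear_max",
                     "translation_max_voxels"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("p_spurious", "p_dropout"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.boundary_noise_max_iter < 0:
            raise ValueError("boundary_noise_max_iter must be non-negative")
        if not 0.0 <= self.surface_roughen_max_rate <= 1.0:
            raise ValueError("surface_roughen_max_rate must lie in [0, 1]")

    @classmethod
    def identity(cls) -> "ModelProfile":
        """A noiseless profile: the simulated output equals the truth."""
        return cls(rotation_max_deg=0.0, scale_max=0.0, shear_max=0.0,
                   translation_max_voxels=0.0, boundary_noise_max_iter=0,
                   surface_roughen_max_rate=0.0, p_spurious=0.0, p_dropout=0.0)


@dataclass(frozen=True)
class SharedBias:
    """Per-image affine error *common to all models* of the ensemble.

    Ensemble members trained on the same data make correlated mistakes;
    averaging cannot remove this component, which is why ensemble gains
    saturate.  The shared bias is drawn once per image and applied to the
    truth before the per-model jitter.  It is volume-preserving by default
    (rotation, shear, translation; no scale): a correlated boundary
    localisation error rather than a correlated volume bias."""

    rotation_max_deg: float = 2.0
    scale_max: float = 0.0
    shear_max: float = 0.02
    translation_max_voxels: float = 1.0

    def as_profile(self) -> "ModelProfile":
        return ModelProfile(rotation_max_deg=self.rotation_max_deg,
                            scale_max=self.scale_max, shear_max=self.shear_max,
                            translation_max_voxels=self.translation_max_voxels,
                            boundary_noise_max_iter=0,
                            surface_roughen_max_rate=0.0,
                            p_spurious=0.0, p_dropout=0.0)


@dataclass(frozen=True)
class StudySpec:
    """A full synthetic study: ``n_images`` phantoms with per-image shape
    variation, each segmented by ``n_models`` simulated models.

    ``profiles`` defaults to ``n_models`` copies of the default
    :class:`ModelProfile` (per-model draws still differ through the seed
    hierarchy).  ``shared_bias`` adds a per-image error common to all
    models.  All randomness derives from ``master_seed``.
    """

    n_images: int = 40
    n_models: int = 16
    organ: str = "phantom"
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    profiles: tuple[ModelProfile, ...] | None = None
    shared_bias: SharedBias | None = field(default_factory=SharedBias)
    semi_axis_jitter: float = 0.25
    center_jitter_voxels: float = 4.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 1 or self.n_models < 1:
            raise ValueError("n_images and n_models must be >= 1")
        if self.profiles is not None and len(self.profiles) != self.n_models:
            raise ValueError(
                f"need {self.n_models} profiles, got {len(self.profiles)}")

    def model_profiles(self) -> tuple[ModelProfile, ...]:
        if self.profiles is not None:
            return tuple(self.profiles)
        return tuple(ModelProfile() for _ in range(self.n_models))


def _rng_for(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, key)]))


# ---------------------------------------------------------------------------
# Phantoms


def make_phantom(spec: PhantomSpec) -> BinaryMask:
    """Build a connected ground-truth phantom, deterministic per seed."""
    shape = spec.grid_shape
    if spec.family == "ellipsoid":
        center = spec.center or tuple((d - 1) / 2.0 for d in shape)
        grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
        r2 = sum(((g - c) / a) ** 2
                 for g, c, a in zip(grids, center, spec.semi_axes))
        voxels = r2 <= 1.0
    else:
        rng = np.random.default_rng(spec.seed)
        noise = ndimage.gaussian_filter(rng.standard_normal(shape),
                                        spec.blob_smooth_voxels)
        thr = np.quantile(noise, 1.0 - spec.volume_fraction)
        voxels = noise >= thr
        labels, n = ndimage.label(voxels)
        if n > 1:
            sizes = ndimage.sum_labels(voxels, labels, index=range(1, n + 1))
            voxels = labels == (int(np.argmax(sizes)) + 1)
    if not voxels.any():
        raise ValueError("degenerate phantom: no foreground voxels")
    return BinaryMask(voxels, spec.spacing, label="ground_truth")


# ---------------------------------------------------------------------------
# Simulated model outputs


def _random_affine(rng: np.random.Generator, profile: ModelProfile) -> tuple[np.ndarray, np.ndarray]:
    """(matrix, translation) of a random small affine transform."""
    ax, ay, az = np.deg2rad(rng.uniform(-profile.rotation_max_deg,
                                        profile.rotation_max_deg, 3))
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    scales = 1.0 + rng.uniform(-profile.scale_max, profile.scale_max, 3)
    shear = np.eye(3)
    for (i, j) in ((0, 1), (0, 2), (1, 2)):
        shear[i, j] = rng.uniform(-profile.shear_max, profile.shear_max)
    M = Rz @ Ry @ Rx @ shear @ np.diag(scales)
    t = rng.uniform(-profile.translation_max_voxels,
                    profile.translation_max_voxels, 3)
    return M, t


def _apply_affine(voxels: np.ndarray, M: np.ndarray, t: np.ndarray) -> np.ndarray:
    center = (np.array(voxels.shape) - 1) / 2.0
    Minv = np.linalg.inv(M)
    # scipy's affine_transform maps output coords to input coords:
    # in = Minv @ out + offset; the transform acts about the grid centre.
    offset = center - Minv @ (center + t)
    out = ndimage.affine_transform(voxels.astype(np.uint8), Minv, offset=offset,
                                   order=0, mode="constant", cval=0)
    return out.astype(bool)


def _boundary_noise(voxels: np.ndarray, rng: np.random.Generator,
                    max_iter: int) -> np.ndarray:
    """Whole-shell morphological noise: 0..max_iter random dilation or
    erosion iterations with a random structuring element.  Coarse (each
    iteration displaces the entire surface by about one voxel)."""
    n = int(rng.integers(0, max_iter + 1)) if max_iter > 0 else 0
    dilate = bool(rng.random() < 0.5)
    conn = int(rng.integers(1, 4))
    if n == 0:
        return voxels
    struct = ndimage.generate_binary_structure(3, conn)
    op = ndimage.binary_dilation if dilate else ndimage.binary_erosion
    return op(voxels, structure=struct, iterations=n)


def _surface_roughen(voxels: np.ndarray, rng: np.random.Generator,
                     max_rate: float) -> np.ndarray:
    """Sub-voxel, non-affine surface noise: each voxel of the one-voxel
    outer (inner) shell is added (removed) independently with a per-model
    random rate drawn from U(0, max_rate).  The expected surface
    displacement is max_rate/2 voxels, so the disagreement stays at the
    scale trained models actually exhibit."""
    add_rate = rng.uniform(0.0, max_rate)
    rem_rate = rng.uniform(0.0, max_rate)
    u_add = rng.random(voxels.shape)
    u_rem = rng.random(voxels.shape)
    if max_rate == 0.0:
        return voxels
    outer = ndimage.binary_dilation(voxels, structure=_STRUCT_6) & ~voxels
    inner = voxels & ~ndimage.binary_erosion(voxels, structure=_STRUCT_6,
                                             border_value=0)
    out = voxels | (outer & (u_add < add_rate))
    return out & ~(inner & (u_rem < rem_rate))


def _apply_dropout(voxels: np.ndarray, rng: np.random.Generator,
                   fraction_range: tuple[float, float]) -> np.ndarray:
    fg = np.argwhere(voxels)
    if len(fg) == 0:
        return voxels
    frac = rng.uniform(*fraction_range)
    seed_vox = fg[int(rng.integers(len(fg)))]
    d2 = ((fg - seed_vox) ** 2).sum(axis=1)
    k = max(1, int(round(frac * len(fg))))
    drop = fg[np.argsort(d2, kind="stable")[:k]]
    out = voxels.copy()
    out[tuple(drop.T)] = False
    return out


def _add_spurious(voxels: np.ndarray, gt: np.ndarray,
                  spacing: Sequence[float], rng: np.random.Generator,
                  volume_range: tuple[float, float],
                  min_distance_mm: float) -> np.ndarray:
    vol = rng.uniform(*volume_range)
    r_vox = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
    r_mm = r_vox * float(max(spacing))
    dist_from_gt = ndimage.distance_transform_edt(~gt, sampling=spacing)
    # candidate centres: far enough from the truth that the whole component
    # keeps the minimum surface distance, and fully inside the grid
    ok = dist_from_gt >= (min_distance_mm + r_mm)
    margin = int(np.ceil(r_vox))
    interior = np.zeros_like(ok)
    if all(d > 2 * margin for d in voxels.shape):
        interior[margin:-margin or None, margin:-margin or None,
                 margin:-margin or None] = True
    candidates = np.argwhere(ok & interior)
    if len(candidates) == 0:
        raise SpuriousPlacementError(
            f"no voxel lies >= {min_distance_mm} mm (+ component radius "
            f"{r_mm:.1f} mm) from the truth on grid {voxels.shape}"
        )
    center = candidates[int(rng.integers(len(candidates)))]
    grids = np.ogrid[: voxels.shape[0], : voxels.shape[1], : voxels.shape[2]]
    ball = sum(((g - c) / r_vox) ** 2 for g, c in zip(grids, center)) <= 1.0
    return voxels | ball


def simulate_model_output(gt: BinaryMask, profile: ModelProfile,
                          rng: np.random.Generator | int,
                          return_info: bool = False):
    """One simulated model segmentation of ``gt``.

    Pipeline: random affine jitter → random boundary dilation/erosion →
    possible dropout of a connected chunk (prob ``p_dropout``) → possible
    distant spurious component (prob ``p_spurious``).  All draws come from
    ``rng``; failure events across models are independent when each model
    gets its own hierarchically derived generator.

    With ``return_info=True`` also returns a dict recording which failure
    modes fired (used by study-level diagnostics and tests).
    """
    if gt.is_empty():
        raise ValueError("ground truth mask is empty")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))

    M, t = _random_affine(rng, profile)
    out = _apply_affine(gt.voxels, M, t)
    out = _boundary_noise(out, rng, profile.boundary_noise_max_iter)
    out = _surface_roughen(out, rng, profile.surface_roughen_max_rate)
    # draw both event uniforms unconditionally so the stream layout is fixed
    u_dropout = rng.random()
    u_spurious = rng.random()
    did_dropout = u_dropout < profile.p_dropout
    did_spurious = u_spurious < profile.p_spurious
    if did_dropout:
        out = _apply_dropout(out, rng, profile.dropout_fraction_range)
    if did_spurious:
        out = _add_spurious(out, gt.voxels, gt.spacing, rng,
                            profile.spurious_volume_range,
                            profile.spurious_min_distance_mm)
    mask = BinaryMask(out, gt.spacing, label="model")
    if return_info:
        return mask, {"dropout": bool(did_dropout), "spurious": bool(did_spurious)}
    return mask


def simulate_rater(gt: BinaryMask, sensitivity: float, specificity: float,
                   rng: np.random.Generator | int) -> BinaryMask:
    """An iid per-voxel rater with the given sensitivity/specificity —
    exactly the generative model STAPLE assumes.  Each true-foreground
    voxel is kept with probability ``sensitivity``; each background voxel
    is flipped on with probability ``1 − specificity``."""
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    u = rng.random(gt.shape)
    fg = gt.voxels
    out = np.where(fg, u < sensitivity, u < (1.0 - specificity))
    return BinaryMask(out, gt.spacing, label="rater")


# ---------------------------------------------------------------------------
# Full studies


@dataclass(frozen=True)
class StudyImage:
    image_id: str
    ground_truth: BinaryMask
    model_masks: tuple[BinaryMask, ...]
    model_ids: tuple[str, ...]
    failures: tuple[dict, ...]  # per-model {"dropout": bool, "spurious": bool}


@dataclass(frozen=True)
class SyntheticStudy:
    spec: StudySpec
    images: tuple[StudyImage, ...]

    @property
    def references(self) -> list[BinaryMask]:
        return [img.ground_truth for img in self.images]

    @property
    def model_masks_per_image(self) -> list[list[BinaryMask]]:
        return [list(img.model_masks) for img in self.images]

    @property
    def image_ids(self) -> list[str]:
        return [img.image_id for img in self.images]


def _vary_phantom(spec: StudySpec, image_idx: int) -> PhantomSpec:
    rng = _rng_for(spec.master_seed, image_idx)
    base = spec.phantom
    if base.family == "ellipsoid":
        axes = np.array(base.semi_axes) * (
            1.0 + rng.uniform(-spec.semi_axis_jitter, spec.semi_axis_jitter, 3))
        axes = np.maximum(axes, 1.0)
        center = np.array(base.center or
                          tuple((d - 1) / 2.0 for d in base.grid_shape))
        center = center + rng.uniform(-spec.center_jitter_voxels,
                                      spec.center_jitter_voxels, 3)
        return dataclasses.replace(base, semi_axes=tuple(axes),
                                   center=tuple(center))
    # blob phantoms vary through their per-image seed
    return dataclasses.replace(
        base, seed=int(rng.integers(np.iinfo(np.int32).max)))


def simulate_study(spec: StudySpec) -> SyntheticStudy:
    """Generate the full study in memory: per-image phantom (with shape
    variation) plus J simulated model outputs each."""
    profiles = spec.model_profiles()
    images = []
    for i in range(spec.n_images):
        gt = make_phantom(_vary_phantom(spec, i))
        if spec.shared_bias is not None:
            # the error component all models share; drawn once per image
            bias_rng = _rng_for(spec.master_seed, i, 0)
            M, t = _random_affine(bias_rng, spec.shared_bias.as_profile())
            common = BinaryMask(_apply_affine(gt.voxels, M, t), gt.spacing,
                                label="shared_bias")
        else:
            common = gt
        masks, infos = [], []
        for j, profile in enumerate(profiles):
            rng = _rng_for(spec.master_seed, i, j + 1, profile.seed_offset)
            mask, info = simulate_model_output(common, profile, rng, return_info=True)
            masks.append(dataclasses.replace(mask, label=f"model_{j:02d}"))
            infos.append(info)
        images.append(StudyImage(
            image_id=f"img_{i:03d}",
            ground_truth=gt,
            model_masks=tuple(masks),
            model_ids=tuple(f"model_{j:02d}" for j in range(spec.n_models)),
            failures=tuple(infos),
        ))
    return SyntheticStudy(spec, tuple(images))


def write_study(study: SyntheticStudy, out_dir: str | Path) -> StudyManifest:
    """Persist a study: NIfTI masks, ``manifest.json`` and a spec echo
    (``study_spec.json``) recording the full configuration and master seed.
    Deterministic given the spec (uncompressed NIfTI payloads)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for img in study.images:
        ref_path = f"{img.image_id}_reference.nii"
        save_mask(img.ground_truth, out_dir / ref_path)
        model_paths = []
        for mid, mask in zip(img.model_ids, img.model_masks):
            path = f"{img.image_id}_{mid}.nii"
            save_mask(mask, out_dir / path)
            model_paths.append((mid, path))
        records.append(ImageRecord(img.image_id, study.spec.organ, ref_path,
                                   tuple(model_paths)))
    manifest = StudyManifest(tuple(records), study.spec.phantom.spacing)
    save_manifest(manifest, out_dir / "manifest.json")
    spec_doc = dataclasses.asdict(study.spec)
    with open(out_dir / "study_spec.json", "w") as fh:
        json.dump(spec_doc, fh, indent=2, sort_keys=True, default=list)
        fh.write("\n")
    return manifest
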