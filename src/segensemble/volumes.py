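"""Domain types and I/O for co-registered 3D segmentation volumes.

The pipeline's universal currency is a binary mask on a regular 3D grid
with a physical voxel spacing in millimetres.  Probability maps (outputs
of ensemble averaging and of the STAPLE E-step) share the same geometry
contract.  Volumes are persisted as NIfTI; a study manifest ties images,
candidate model masks and reference masks together.

All masks of one image are assumed co-registered on a common grid.  No
resampling is performed anywhere: a geometry mismatch (shape, or spacing
differing beyond 1e-6 relative) is an error, never silently fixed.  The
affine is carried through for provenance but spacing alone drives every
millimetre distance downstream.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "BinaryMask",
    "ProbabilityMap",
    "ImageRecord",
    "StudyManifest",
    "GeometryError",
    "check_same_geometry",
    "load_mask",
    "load_probability_map",
    "save_mask",
    "load_manifest",
    "save_manifest",
]

_SPACING_RTOL = 1e-6


class GeometryError(ValueError):
    """Raised when two volumes that must share a grid do not."""


def _validate_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 components, got {len(spacing)}")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing components must be positive and finite, got {spacing}")
    return spacing


def _validate_shape(voxels: np.ndarray) -> None:
    if voxels.ndim != 3:
        raise ValueError(f"volume must be 3-dimensional, got ndim={voxels.ndim}")
    if any(d <= 0 for d in voxels.shape):
        raise ValueError(f"volume must have positive dimensions, got shape={voxels.shape}")


@dataclass(frozen=True)
class BinaryMask:
    """A 3D {0,1} voxel grid with per-axis spacing in mm.

    Parameters
    ----------
    voxels
        3D array; any dtype whose values are exactly 0 or 1.  Stored as bool.
    spacing
        Physical size of a voxel along each axis, in millimetres.
    label
        Free text naming the organ and/or source (model id, fusion scheme).
    affine
        Optional 4x4 orientation matrix, recorded on load and written on
        save but never used in computation.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    label: str = ""
    affine: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels)
        _validate_shape(voxels)
        if voxels.dtype != bool:
            uniques = np.unique(voxels)
            if not np.all(np.isin(uniques, (0, 1))):
                raise ValueError(
                    f"binary mask voxels must be 0 or 1, found values {uniques[:5]}"
                )
            voxels = voxels.astype(bool)
        object.__setattr__(self, "voxels", voxels)
        object.__setattr__(self, "spacing", _validate_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def volume_voxels(self) -> int:
        """Foreground voxel count."""
        return int(self.voxels.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_mm3(self) -> float:
        return self.volume_voxels * self.voxel_volume_mm3

    @property
    def physical_diagonal_mm(self) -> float:
        """Diagonal of the image's physical extent; used as a finite
        worst-case cap for surface distances of degenerate (empty) masks."""
        ext = np.array(self.shape) * np.array(self.spacing)
        return float(np.sqrt((ext**2).sum()))

    def is_empty(self) -> bool:
        return not self.voxels.any()

    def with_voxels(self, voxels: np.ndarray, label: str | None = None) -> "BinaryMask":
        """A new mask on the same grid."""
        return BinaryMask(voxels, self.spacing, self.label if label is None else label,
                          self.affine)


@dataclass(frozen=True)
class ProbabilityMap:
    """A 3D grid of per-voxel foreground probabilities in [0, 1].

    Same geometry contract as :class:`BinaryMask`.  ``provenance`` records
    which sources (model ids, scheme name) produced the map.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    provenance: tuple[str, ...] = ()
    affine: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels, dtype=float)
        _validate_shape(voxels)
        if not np.all(np.isfinite(voxels)):
            raise ValueError("probability map contains non-finite values")
        lo, hi = float(voxels.min()), float(voxels.max())
        if lo < -1e-12 or hi > 1 + 1e-12:
            raise ValueError(f"probability values must lie in [0, 1], found [{lo}, {hi}]")
        object.__setattr__(self, "voxels", np.clip(voxels, 0.0, 1.0))
        object.__setattr__(self, "spacing", _validate_spacing(self.spacing))
        object.__setattr__(self, "provenance", tuple(self.provenance))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


def check_same_geometry(a: BinaryMask | ProbabilityMap,
                        b: BinaryMask | ProbabilityMap) -> None:
    """Raise :class:`GeometryError` unless ``a`` and ``b`` share shape and
    spacing (spacing to 1e-6 relative)."""
    if a.shape != b.shape:
        raise GeometryError(f"shape mismatch: {a.shape} vs {b.shape}")
    sa, sb = np.array(a.spacing), np.array(b.spacing)
    if not np.allclose(sa, sb, rtol=_SPACING_RTOL, atol=0.0):
        raise GeometryError(f"spacing mismatch: {a.spacing} vs {b.spacing}")


# ---------------------------------------------------------------------------
# NIfTI persistence


def _read_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite voxel values")
    spacing = _validate_spacing(img.header.get_zooms()[:3])
    return np.asarray(data, dtype=float), spacing, np.asarray(img.affine)


def load_mask(path: str | Path, binarize_threshold: float = 0.5,
              label: str = "") -> BinaryMask:
    """Load a NIfTI volume as a binary mask.

    Voxels with value ``>= binarize_threshold`` become foreground; spacing
    is read from the header.  The volume is treated as already co-registered
    with the other masks of its image.
    """
    data, spacing, affine = _read_nifti(path)
    return BinaryMask(data >= binarize_threshold, spacing, label, affine)


def load_probability_map(path: str | Path,
                         provenance: Sequence[str] = ()) -> ProbabilityMap:
    """Load a NIfTI volume of values in [0, 1] as a probability map."""
    data, spacing, affine = _read_nifti(path)
    return ProbabilityMap(data, spacing, tuple(provenance), affine)


def save_mask(mask: BinaryMask | ProbabilityMap, path: str | Path) -> None:
    """Write a mask or probability map as NIfTI.

    Binary masks are written as uint8 so a reload is voxel-exact;
    probability maps as float32 (round trip within 1e-6).  Spacing goes
    into the affine (and header zooms) and survives to 1e-6 mm.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(mask, BinaryMask):
        data = mask.voxels.astype(np.uint8)
    else:
        data = mask.voxels.astype(np.float32)
    affine = mask.affine if mask.affine is not None else np.diag((*mask.spacing, 1.0))
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Study manifests


@dataclass(frozen=True)
class ImageRecord:
    """One image of a study: its reference mask and the candidate masks
    produced by each ensemble model, in a fixed model order."""

    image_id: str
    organ: str
    reference_path: str
    model_paths: tuple[tuple[str, str], ...]  # (model_id, path), order preserved

    @property
    def model_ids(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.model_paths)


@dataclass(frozen=True)
class StudyManifest:
    """Images x models x reference masks of one study.

    Invariants: every image has at least one model mask; within one organ
    all images carry the identical ordered model-id list; no duplicate
    model ids within an image.
    """

    images: tuple[ImageRecord, ...]
    spacing: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        per_organ: dict[str, tuple[str, ...]] = {}
        for rec in self.images:
            if not rec.model_paths:
                raise ValueError(f"image {rec.image_id!r}: no model masks listed")
            ids = rec.model_ids
            if len(set(ids)) != len(ids):
                raise ValueError(f"image {rec.image_id!r}: duplicated model id in {ids}")
            if not rec.reference_path:
                raise ValueError(f"image {rec.image_id!r}: missing reference mask entry")
            if rec.organ in per_organ and per_organ[rec.organ] != ids:
                raise ValueError(
                    f"image {rec.image_id!r}: model ids {ids} differ from other "
                    f"images of organ {rec.organ!r} ({per_organ[rec.organ]})"
                )
            per_organ.setdefault(rec.organ, ids)

    def __len__(self) -> int:
        return len(self.images)

    def check_files_exist(self, root: str | Path = ".") -> None:
        root = Path(root)
        for rec in self.images:
            paths = [rec.reference_path] + [p for _, p in rec.model_paths]
            for p in paths:
                if not (root / p).exists() and not Path(p).exists():
                    raise FileNotFoundError(
                        f"image {rec.image_id!r}: referenced file missing: {p}"
                    )


def _manifest_from_rows(rows: Iterable[dict]) -> StudyManifest:
    by_image: dict[str, dict] = {}
    order: list[str] = []
    for row in rows:
        iid = str(row["image_id"])
        if iid not in by_image:
            by_image[iid] = {"organ": str(row["organ"]), "reference": None, "models": []}
            order.append(iid)
        role = str(row["role"])
        if role == "reference":
            by_image[iid]["reference"] = str(row["path"])
        elif role.startswith("model:"):
            by_image[iid]["models"].append((role.split(":", 1)[1], str(row["path"])))
        else:
            raise ValueError(f"image {iid!r}: unknown role {role!r}")
    records = []
    for iid in order:
        entry = by_image[iid]
        if entry["reference"] is None:
            raise ValueError(f"image {iid!r}: missing reference mask entry")
        records.append(ImageRecord(iid, entry["organ"], entry["reference"],
                                   tuple(entry["models"])))
    return StudyManifest(tuple(records))


def load_manifest(path: str | Path, check_files: bool = True) -> StudyManifest:
    """Load a study manifest from JSON or CSV.

    JSON layout: ``{"spacing": [...], "images": [{"image_id", "organ",
    "reference", "models": [{"id", "path"}, ...]}, ...]}``.
    CSV layout: columns ``image_id, organ, role, path`` with role either
    ``reference`` or ``model:<id>``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    if path.suffix.lower() == ".csv":
        with open(path, newline="") as fh:
            manifest = _manifest_from_rows(csv.DictReader(fh))
    else:
        with open(path) as fh:
            doc = json.load(fh)
        records = []
        for entry in doc["images"]:
            models = tuple((str(m["id"]), str(m["path"])) for m in entry.get("models", ()))
            if "reference" not in entry or not entry["reference"]:
                raise ValueError(f"image {entry.get('image_id')!r}: missing reference mask entry")
            records.append(ImageRecord(str(entry["image_id"]), str(entry["organ"]),
                                       str(entry["reference"]), models))
        spacing = doc.get("spacing")
        manifest = StudyManifest(tuple(records),
                                 _validate_spacing(spacing) if spacing else None)
    if check_files:
        manifest.check_files_exist(path.parent)
    return manifest


def save_manifest(manifest: StudyManifest, path: str | Path) -> None:
    """Write a manifest as JSON (model ordering preserved)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "spacing": list(manifest.spacing) if manifest.spacing else None,
        "images": [
            {
                "image_id": rec.image_id,
                "organ": rec.organ,
                "reference": rec.reference_path,
                "models": [{"id": m, "path": p} for m, p in rec.model_paths],
            }
            for rec in manifest.images
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
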