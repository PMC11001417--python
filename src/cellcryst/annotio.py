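"""Image + polygon-annotation I/O.

Reads and writes the Labelme JSON dialect (``shapes[].label``,
``shapes[].points``, ``imageHeight``, ``imageWidth``), converts polygons to
binary instance masks, and applies the resizing pipeline used for bright-field
micrographs (area-filtered image resampling, nearest-neighbor masks).

Reserved class labels: ``crystal_G``, ``crystal_H``, ``cell``.  Unknown labels
pass through untouched.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image as PILImage
from skimage.transform import resize as _sk_resize

from ._geometry import rasterize_polygon, tight_bbox, trace_mask_to_polygon

__all__ = [
    "Instance",
    "AnnotatedImage",
    "ManifestRecord",
    "DatasetManifest",
    "AnnotationFormatError",
    "read_labelme",
    "write_labelme",
    "read_image",
    "write_image",
    "polygons_to_masks",
    "resize_annotated",
    "read_manifest",
    "write_manifest",
    "instances_to_coco",
    "CRYSTAL_G",
    "CRYSTAL_H",
    "CELL",
]

CRYSTAL_G = "crystal_G"
CRYSTAL_H = "crystal_H"
CELL = "cell"


class AnnotationFormatError(ValueError):
    """Raised when an annotation file is missing required keys."""


@dataclass
class Instance:
    """One annotated or predicted object: a class label plus geometry.

    Either ``polygon`` ((n, 2) float (x, y) vertices) or ``mask`` (boolean
    array) must be present; masks are rasterized from polygons on demand.
    """

    label: str
    polygon: np.ndarray | None = None
    mask: np.ndarray | None = None
    score: float | None = None
    group_id: int | None = None

    def get_mask(self, image_shape: tuple[int, int]) -> np.ndarray:
        if self.mask is not None:
            if self.mask.shape != tuple(image_shape):
                raise ValueError(
                    f"instance mask shape {self.mask.shape} != image shape {tuple(image_shape)}"
                )
            return self.mask
        if self.polygon is None:
            raise ValueError("instance has neither polygon nor mask")
        return rasterize_polygon(self.polygon, image_shape)

    def get_polygon(self) -> np.ndarray:
        if self.polygon is not None:
            return self.polygon
        if self.mask is None:
            raise ValueError("instance has neither polygon nor mask")
        return trace_mask_to_polygon(self.mask)


@dataclass
class AnnotatedImage:
    """An image together with its per-instance ground truth.

    ``image`` may be None for annotation-only files; ``shape`` is always the
    (height, width) of the pixel grid the instances live on.
    """

    shape: tuple[int, int]
    instances: list[Instance] = field(default_factory=list)
    image: np.ndarray | None = None
    pixel_pitch_um: float | None = None
    provenance: str | None = None

    def masks(self, labels: set[str] | None = None) -> list[np.ndarray]:
        return [
            inst.get_mask(self.shape)
            for inst in self.instances
            if labels is None or inst.label in labels
        ]

    def labels(self) -> list[str]:
        return [inst.label for inst in self.instances]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for inst in self.instances:
            counts[inst.label] = counts.get(inst.label, 0) + 1
        return counts


@dataclass
class ManifestRecord:
    image_path: str
    annotation_path: str
    class_counts: dict[str, int]
    seed: int | None = None


@dataclass
class DatasetManifest:
    """Index of an on-disk dataset: (image, annotation) path pairs."""

    records: list[ManifestRecord]
    config_fingerprint: str | None = None
    seed: int | None = None
    root: Path | None = None

    def __len__(self) -> int:
        return len(self.records)

    def load(self, index: int) -> AnnotatedImage:
        rec = self.records[index]
        root = self.root or Path(".")
        ann = read_labelme(root / rec.annotation_path)
        img = read_image(root / rec.image_path)
        ann.image = img
        if img.shape[:2] != ann.shape:
            raise ValueError(
                f"image {rec.image_path} shape {img.shape[:2]} != annotation shape {ann.shape}"
            )
        return ann


# ---------------------------------------------------------------------------
# Labelme dialect
# ---------------------------------------------------------------------------

def read_labelme(path: str | Path) -> AnnotatedImage:
    """Read a Labelme-dialect JSON annotation file.

    Accepts both ``version``-bearing and version-less files.  Polygon points
    are (x, y), 0-based, origin top-left.  Self-intersecting polygons warn
    and are later rasterized under the even-odd rule.
    """
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh)
    for key in ("shapes", "imageHeight", "imageWidth"):
        if key not in data:
            raise AnnotationFormatError(f"{path.name}: missing required key {key!r}")
    shape = (int(data["imageHeight"]), int(data["imageWidth"]))
    instances = []
    for i, sh in enumerate(data["shapes"]):
        for key in ("label", "points"):
            if key not in sh:
                raise AnnotationFormatError(
                    f"{path.name}: shape {i} missing required key {key!r}"
                )
        poly = np.asarray(sh["points"], dtype=float)
        if _self_intersects(poly):
            warnings.warn(
                f"{path.name}: shape {i} ({sh['label']}) self-intersects; "
                "even-odd rasterization applies",
                stacklevel=2,
            )
        instances.append(
            Instance(
                label=sh["label"],
                polygon=poly,
                score=sh.get("score"),
                group_id=sh.get("group_id"),
            )
        )
    return AnnotatedImage(shape=shape, instances=instances, provenance=str(path))


def write_labelme(annotated: AnnotatedImage, path: str | Path,
                  image_path: str | None = None) -> None:
    """Write an AnnotatedImage as a Labelme-dialect JSON file.

    Instances that carry only masks are traced to polygons first (error on
    empty masks).  Output is deterministic: identical inputs produce
    byte-identical files.
    """
    shapes = []
    for inst in annotated.instances:
        poly = inst.get_polygon()
        sh = {
            "label": inst.label,
            "points": [[float(x), float(y)] for x, y in poly],
            "group_id": inst.group_id,
            "shape_type": "polygon",
            "flags": {},
        }
        if inst.score is not None:
            sh["score"] = float(inst.score)
        shapes.append(sh)
    h, w = annotated.shape
    doc = {
        "version": "5.2.1",
        "flags": {},
        "shapes": shapes,
        "imagePath": image_path or "",
        "imageData": None,
        "imageHeight": int(h),
        "imageWidth": int(w),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def _self_intersects(poly: np.ndarray) -> bool:
    if len(poly) < 4:
        return False
    try:
        from shapely.geometry import Polygon
        return not Polygon(poly).is_simple
    except Exception:  # pragma: no cover - shapely failure on weird input
        return False


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG/TIFF image as a numpy array (grayscale 2-D or RGB)."""
    with PILImage.open(path) as im:
        if im.mode not in ("L", "RGB"):
            im = im.convert("RGB")
        return np.asarray(im)


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit image; 2-D arrays are expanded to RGB for PNG output."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        raise ValueError("expected an 8-bit image")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    PILImage.fromarray(arr).save(path)


# ---------------------------------------------------------------------------
# Polygons <-> masks, resizing
# ---------------------------------------------------------------------------

def polygons_to_masks(polygons: list[np.ndarray],
                      image_shape: tuple[int, int]) -> list[np.ndarray]:
    """Rasterize polygons to boolean masks (pixel-center even-odd rule)."""
    return [rasterize_polygon(p, image_shape) for p in polygons]


def resize_annotated(annotated: AnnotatedImage, target: int) -> AnnotatedImage:
    """Resize an annotated image to ``target`` x ``target`` pixels.

    The intensity image is resampled with an anti-aliased (area-like) filter;
    masks use nearest-neighbor so they stay binary; polygons are scaled by
    target/original per axis.  Non-square inputs are scaled per axis with a
    warning.  Instance count is always preserved; a warning fires if an
    instance's mask becomes empty (possible only for sub-pixel instances).
    """
    if target < 16:
        raise ValueError("target resolution must be >= 16")
    h, w = annotated.shape
    if h != w:
        warnings.warn("non-square input: axes scaled independently", stacklevel=2)
    sy, sx = target / h, target / w
    image = None
    if annotated.image is not None:
        out_shape = (target, target) if annotated.image.ndim == 2 else (
            target, target, annotated.image.shape[2])
        image = _sk_resize(annotated.image, out_shape, anti_aliasing=True,
                           preserve_range=True).round().astype(np.uint8)
    new_instances = []
    for inst in annotated.instances:
        poly = None if inst.polygon is None else inst.polygon * np.array([sx, sy])
        mask = None
        if inst.mask is not None:
            mask = _sk_resize(inst.mask.astype(np.uint8), (target, target),
                              order=0, preserve_range=True,
                              anti_aliasing=False).astype(bool)
            if not mask.any():
                warnings.warn(
                    f"instance '{inst.label}' vanished during resize "
                    "(sub-pixel at target resolution)",
                    stacklevel=2,
                )
        new_instances.append(replace(inst, polygon=poly, mask=mask))
    pitch = None
    if annotated.pixel_pitch_um is not None:
        pitch = annotated.pixel_pitch_um * (h / target)
    return AnnotatedImage(
        shape=(target, target),
        instances=new_instances,
        image=image,
        pixel_pitch_um=pitch,
        provenance=annotated.provenance,
    )


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

_MANIFEST_CLASSES = (CRYSTAL_G, CRYSTAL_H, CELL)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """Write a dataset manifest as a tab-separated file with a header."""
    lines = []
    if manifest.config_fingerprint is not None:
        lines.append(f"# config_fingerprint\t{manifest.config_fingerprint}")
    if manifest.seed is not None:
        lines.append(f"# seed\t{manifest.seed}")
    cols = ["image_path", "annotation_path"] + [f"n_{c}" for c in _MANIFEST_CLASSES] + ["seed"]
    lines.append("\t".join(cols))
    for rec in manifest.records:
        counts = [str(rec.class_counts.get(c, 0)) for c in _MANIFEST_CLASSES]
        seed = "" if rec.seed is None else str(rec.seed)
        lines.append("\t".join([rec.image_path, rec.annotation_path, *counts, seed]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path: str | Path) -> DatasetManifest:
    path = Path(path)
    fingerprint = None
    seed = None
    records = []
    header: list[str] | None = None
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("\t")
            if key == "config_fingerprint":
                fingerprint = value
            elif key == "seed":
                seed = int(value)
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            continue
        row = dict(zip(header, parts))
        counts = {c: int(row.get(f"n_{c}", 0) or 0) for c in _MANIFEST_CLASSES}
        rec_seed = row.get("seed") or None
        records.append(ManifestRecord(
            image_path=row["image_path"],
            annotation_path=row["annotation_path"],
            class_counts=counts,
            seed=None if rec_seed is None else int(rec_seed),
        ))
    if not records:
        raise AnnotationFormatError(f"{path.name}: manifest contains no records")
    return DatasetManifest(records=records, config_fingerprint=fingerprint,
                           seed=seed, root=path.parent)


def config_fingerprint(config_dict: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# COCO-style export (interoperability with standard detector trainers)
# ---------------------------------------------------------------------------

def instances_to_coco(annotated_list: list[AnnotatedImage],
                      image_paths: list[str] | None = None) -> dict:
    """Export annotations as a COCO-style dict (polygon segmentation records)."""
    categories: dict[str, int] = {}
    images = []
    annotations = []
    ann_id = 1
    for img_id, ann in enumerate(annotated_list, start=1):
        h, w = ann.shape
        images.append({
            "id": img_id,
            "file_name": image_paths[img_id - 1] if image_paths else f"{img_id}.png",
            "height": int(h),
            "width": int(w),
        })
        for inst in ann.instances:
            if inst.label not in categories:
                categories[inst.label] = len(categories) + 1
            poly = inst.get_polygon()
            mask = inst.get_mask(ann.shape)
            if not mask.any():
                continue
            x0, y0, x1, y1 = tight_bbox(mask)
            annotations.append({
                "id": ann_id,
                "image_id": img_id,
                "category_id": categories[inst.label],
                "segmentation": [list(map(float, poly.ravel()))],
                "bbox": [float(x0), float(y0), float(x1 - x0 + 1), float(y1 - y0 + 1)],
                "area": float(mask.sum()),
                "iscrowd": 0,
            })
            ann_id += 1
    return {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": v, "name": k} for k, v in categories.items()],
    }
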