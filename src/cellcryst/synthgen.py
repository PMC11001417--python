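"""Synthetic bright-field culture images with exact instance ground truth.

Emulates micrographs of baculovirus-infected insect-cell cultures grown for
in cellulo protein crystallization: a bright, noisy background, translucent
elliptical cell bodies with darker rims, and two crystal morphologies —

* target **G**: a single large rod-like crystal per bearing cell (long axis up
  to 140 µm, often protruding from the cell body), present in ~95% of cells;
* target **H**: smaller crystals with a hexagonal cross-section, several per
  bearing cell, randomly oriented and clustered, present in >85% of cells.

The default acquisition geometry is a 300 x 300 µm field of view imaged at
2136 x 2136 px and downscaled to 512 x 512 PNG for training.  All intensity
and texture parameters are synthetic inventions exposed on
:class:`GeneratorConfig`; the generator's contract is that a detector can
learn the scenes and the metric suite can score them, with pixel-exact
ground-truth masks for every cell and crystal.

Determinism: one root seed with hierarchical per-image substreams, so image i
of a dataset does not depend on how many images are requested.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely import affinity
from shapely.geometry import Point

from ._geometry import rasterize_polygon
from .annotio import (
    CELL,
    CRYSTAL_G,
    CRYSTAL_H,
    AnnotatedImage,
    DatasetManifest,
    Instance,
    ManifestRecord,
    config_fingerprint,
    resize_annotated,
    write_image,
    write_labelme,
    write_manifest,
)

__all__ = [
    "GeneratorConfig",
    "GeneratorConfigError",
    "CellSpec",
    "CrystalSpec",
    "SceneSpec",
    "sample_scene",
    "render_scene",
    "generate_images",
    "generate_dataset",
    "child_seed",
]

G_MAX_LENGTH_UM = 140.0


class GeneratorConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic field of view.

    Lengths are µm unless suffixed ``_px``; intensity values are 8-bit gray
    levels.  ``crystal_classes`` may contain ``"G"``, ``"H"`` or the alias
    ``"mixed"`` (both classes enabled per cell, as in a co-infected culture).
    """

    field_of_view_um: float = 300.0
    full_resolution_px: int = 2136
    output_resolution_px: int = 512
    cell_density: tuple[int, int] = (10, 40)
    efficiency_G: float = 0.95
    efficiency_H: float = 0.85
    crystal_classes: tuple[str, ...] = ("G",)
    cell_axis_um: tuple[float, float] = (15.0, 25.0)
    g_length_um: tuple[float, float] = (40.0, 140.0)
    g_width_um: tuple[float, float] = (5.0, 12.0)
    h_length_um: tuple[float, float] = (3.0, 15.0)
    h_aspect: tuple[float, float] = (1.0, 2.0)
    h_per_cell: tuple[int, int] = (1, 6)
    background_mean: float = 200.0
    background_sigma: float = 6.0
    blur_sigma_um: float = 0.5
    cell_interior_factor: float = 0.90
    cell_rim_factor: float = 0.75
    g_intensity: float = 70.0
    h_intensity: float = 125.0
    crystal_edge_factor: float = 0.55
    rng_seed: int = 0

    @property
    def pixel_pitch_um(self) -> float:
        return self.field_of_view_um / self.full_resolution_px

    def enabled_classes(self) -> tuple[str, ...]:
        classes = set(self.crystal_classes)
        if "mixed" in classes:
            classes |= {"G", "H"}
            classes.discard("mixed")
        return tuple(sorted(classes))

    def validate(self) -> None:
        if not 0.0 <= self.efficiency_G <= 1.0:
            raise GeneratorConfigError("efficiency_G must lie in [0, 1]")
        if not 0.0 <= self.efficiency_H <= 1.0:
            raise GeneratorConfigError("efficiency_H must lie in [0, 1]")
        if self.full_resolution_px < self.output_resolution_px:
            raise GeneratorConfigError(
                "full_resolution_px must be >= output_resolution_px")
        if self.field_of_view_um <= 0 or self.full_resolution_px <= 0:
            raise GeneratorConfigError(
                "field_of_view_um/full_resolution_px must give a pixel pitch > 0")
        if not set(self.enabled_classes()) <= {"G", "H"}:
            raise GeneratorConfigError(
                f"crystal_classes contains unknown class: {self.crystal_classes}")
        lo, hi = self.cell_density
        if lo < 0 or hi < lo:
            raise GeneratorConfigError("cell_density must be a (lo, hi) range, 0 <= lo <= hi")
        if self.g_length_um[1] > G_MAX_LENGTH_UM:
            raise GeneratorConfigError(
                f"g_length_um upper bound exceeds the {G_MAX_LENGTH_UM} um morphology limit")
        if self.h_per_cell[0] < 1 or self.h_per_cell[1] < self.h_per_cell[0]:
            raise GeneratorConfigError("h_per_cell must be a (lo, hi) range with lo >= 1")

    # -- presets ----------------------------------------------------------

    @classmethod
    def for_target(cls, target: str, scale: str = "paper") -> "GeneratorConfig":
        """Acquisition-matched config for one target ('G', 'H' or 'mixed').

        ``scale='desk'`` shrinks the field of view to 100 µm and the raster
        to 256→128 px so small H crystals remain several pixels wide while
        whole experiments stay CPU-friendly; morphology and efficiencies are
        unchanged apart from clipping G rods to fit the smaller field.
        """
        if target not in ("G", "H", "mixed"):
            raise GeneratorConfigError(f"unknown target: {target!r}")
        base = cls(crystal_classes=(target,))
        if scale == "paper":
            return base
        if scale == "desk":
            return replace(
                base,
                field_of_view_um=100.0,
                full_resolution_px=256,
                output_resolution_px=128,
                cell_density=(3, 7),
                g_length_um=(20.0, 60.0),
                g_width_um=(4.0, 9.0),
            )
        raise GeneratorConfigError(f"unknown scale: {scale!r}")

    @classmethod
    def easy(cls, resolution: int = 128) -> "GeneratorConfig":
        """High-contrast, low-clutter scenes for training sanity checks:
        nearly invisible cell bodies, large dark rod crystals, mild noise."""
        return cls(
            field_of_view_um=100.0,
            full_resolution_px=resolution,
            output_resolution_px=resolution,
            cell_density=(2, 4),
            crystal_classes=("G",),
            efficiency_G=1.0,
            g_length_um=(20.0, 50.0),
            g_width_um=(6.0, 12.0),
            background_sigma=4.0,
            cell_interior_factor=0.99,
            cell_rim_factor=0.96,
            g_intensity=60.0,
        )


@dataclass(frozen=True)
class CellSpec:
    """One elliptical cell body, in full-resolution pixel coordinates."""

    center: tuple[float, float]
    axes: tuple[float, float]  # semi-axes, px
    orientation: float  # radians
    texture_seed: int = 0

    def polygon(self, n_vertices: int = 48) -> np.ndarray:
        t = np.linspace(0.0, 2 * math.pi, n_vertices, endpoint=False)
        a, b = self.axes
        x = a * np.cos(t)
        y = b * np.sin(t)
        co, si = math.cos(self.orientation), math.sin(self.orientation)
        return np.stack([
            self.center[0] + co * x - si * y,
            self.center[1] + si * x + co * y,
        ], axis=1)

    def contains(self, x: float, y: float, shrink: float = 1.0) -> bool:
        dx, dy = x - self.center[0], y - self.center[1]
        co, si = math.cos(self.orientation), math.sin(self.orientation)
        u = (co * dx + si * dy) / (self.axes[0] * shrink)
        v = (-si * dx + co * dy) / (self.axes[1] * shrink)
        return u * u + v * v <= 1.0


@dataclass(frozen=True)
class CrystalSpec:
    """One crystal instance: class, pose, physical size and outline polygon."""

    crystal_class: str  # "G" or "H"
    host_cell: int | None
    polygon: np.ndarray  # (n, 2) px
    length_um: float
    width_um: float
    orientation: float
    cluster_id: int | None = None


@dataclass(frozen=True)
class SceneSpec:
    """A sampled field of view: config plus cell and crystal layout."""

    config: GeneratorConfig
    cells: tuple[CellSpec, ...]
    crystals: tuple[CrystalSpec, ...]
    seed: int
    render_seed: int

    def validate(self) -> None:
        g_per_cell: dict[int, int] = {}
        for c in self.crystals:
            if c.host_cell is not None and not 0 <= c.host_cell < len(self.cells):
                raise ValueError("crystal references a non-existent host cell")
            if c.crystal_class == "G" and c.host_cell is not None:
                g_per_cell[c.host_cell] = g_per_cell.get(c.host_cell, 0) + 1
        if any(v > 1 for v in g_per_cell.values()):
            raise ValueError("a cell may bear at most one G crystal")


def child_seed(root_seed: int, index: int) -> int:
    """Hierarchical per-image substream seed (stable in ``index``)."""
    ss = np.random.SeedSequence([int(root_seed), int(index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# Scene sampling
# ---------------------------------------------------------------------------

def _rect_polygon(cx, cy, length_px, width_px, theta):
    hl, hw = length_px / 2, width_px / 2
    corners = np.array([[-hl, -hw], [hl, -hw], [hl, hw], [-hl, hw]])
    co, si = math.cos(theta), math.sin(theta)
    rot = np.array([[co, -si], [si, co]])
    return corners @ rot.T + np.array([cx, cy])


def _hex_polygon(cx, cy, length_px, width_px, theta):
    # elongated hexagon: the projected outline of a hexagonal prism
    hl, hw = length_px / 2, width_px / 2
    pts = np.array([
        [hl, 0.0], [hl / 2, hw], [-hl / 2, hw],
        [-hl, 0.0], [-hl / 2, -hw], [hl / 2, -hw],
    ])
    co, si = math.cos(theta), math.sin(theta)
    rot = np.array([[co, -si], [si, co]])
    return pts @ rot.T + np.array([cx, cy])


def _ellipse_shape(cell: CellSpec):
    circ = Point(0.0, 0.0).buffer(1.0, quad_segs=16)
    el = affinity.scale(circ, cell.axes[0], cell.axes[1])
    el = affinity.rotate(el, cell.orientation, use_radians=True)
    return affinity.translate(el, cell.center[0], cell.center[1])


_MAX_CELL_OVERLAP = 0.6


def sample_scene(config: GeneratorConfig, seed: int) -> SceneSpec:
    """Sample cell positions and crystal layout for one field of view.

    Cells are placed with rejection sampling against >60% mutual overlap
    (overlap fraction relative to the smaller cell).  Each cell then
    independently bears a single G crystal with probability ``efficiency_G``
    and/or 1–6 H crystals with probability ``efficiency_H``, per enabled
    class; two or more H crystals in a cell share a cluster id and a cluster
    anchor, emulating the observed clustering.  Deterministic for fixed
    (config, seed).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n_px = config.full_resolution_px
    px_per_um = 1.0 / config.pixel_pitch_um

    lo, hi = config.cell_density
    n_cells = int(rng.integers(lo, hi + 1))

    cells: list[CellSpec] = []
    shapes = []
    for _ in range(n_cells):
        placed = None
        for _try in range(30):
            center = (float(rng.uniform(0, n_px)), float(rng.uniform(0, n_px)))
            axes = (
                float(rng.uniform(*config.cell_axis_um)) * 0.5 * px_per_um,
                float(rng.uniform(*config.cell_axis_um)) * 0.5 * px_per_um,
            )
            orientation = float(rng.uniform(0, math.pi))
            cand = CellSpec(center=center, axes=axes, orientation=orientation,
                            texture_seed=int(rng.integers(2**31)))
            cand_shape = _ellipse_shape(cand)
            ok = True
            for sh in shapes:
                inter = cand_shape.intersection(sh).area
                if inter / min(cand_shape.area, sh.area) > _MAX_CELL_OVERLAP:
                    ok = False
                    break
            placed = cand
            if ok:
                break
        cells.append(placed)
        shapes.append(_ellipse_shape(placed))

    crystals: list[CrystalSpec] = []
    classes = config.enabled_classes()
    next_cluster = 0
    for idx, cell in enumerate(cells):
        if "G" in classes and rng.random() < config.efficiency_G:
            length = float(rng.uniform(*config.g_length_um))
            width = float(rng.uniform(*config.g_width_um))
            theta = float(rng.uniform(0, math.pi))
            # rod anchored at the cell, free to protrude beyond its rim
            cx = cell.center[0] + float(rng.normal(0, cell.axes[0] / 4))
            cy = cell.center[1] + float(rng.normal(0, cell.axes[1] / 4))
            crystals.append(CrystalSpec(
                crystal_class="G", host_cell=idx,
                polygon=_rect_polygon(cx, cy, length * px_per_um,
                                      width * px_per_um, theta),
                length_um=length, width_um=width, orientation=theta,
            ))
        if "H" in classes and rng.random() < config.efficiency_H:
            count = int(rng.integers(config.h_per_cell[0], config.h_per_cell[1] + 1))
            cluster_id = None
            if count >= 2:
                cluster_id = next_cluster
                next_cluster += 1
            # cluster anchor well inside the cell body
            for _try in range(20):
                ax = cell.center[0] + float(rng.normal(0, cell.axes[0] / 3))
                ay = cell.center[1] + float(rng.normal(0, cell.axes[1] / 3))
                if cell.contains(ax, ay, shrink=0.6):
                    break
            else:
                ax, ay = cell.center
            spread = max(config.h_length_um) * px_per_um * 0.6
            for _k in range(count):
                for _try in range(20):
                    cx = ax + float(rng.normal(0, spread))
                    cy = ay + float(rng.normal(0, spread))
                    if cell.contains(cx, cy, shrink=0.85):
                        break
                else:
                    cx, cy = ax, ay
                length = float(rng.uniform(*config.h_length_um))
                aspect = float(rng.uniform(*config.h_aspect))
                theta = float(rng.uniform(0, math.pi))
                crystals.append(CrystalSpec(
                    crystal_class="H", host_cell=idx,
                    polygon=_hex_polygon(cx, cy, length * px_per_um,
                                         length / aspect * px_per_um, theta),
                    length_um=length, width_um=length / aspect,
                    orientation=theta, cluster_id=cluster_id,
                ))

    scene = SceneSpec(
        config=config,
        cells=tuple(cells),
        crystals=tuple(crystals),
        seed=int(seed),
        render_seed=int(rng.integers(2**31)),
    )
    scene.validate()
    return scene


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_scene(scene: SceneSpec) -> AnnotatedImage:
    """Render a scene to a grayscale micrograph-like image with ground truth.

    Bright Gaussian background; cells as translucent ellipses with a darker
    rim; crystals filled at a class-specific gray level with a darker,
    higher-contrast edge band; global Gaussian blur.  One instance (polygon +
    full-resolution mask) per cell and per crystal.
    """
    scene.validate()
    cfg = scene.config
    n_px = cfg.full_resolution_px
    rng = np.random.default_rng(scene.render_seed)
    img = rng.normal(cfg.background_mean, cfg.background_sigma, (n_px, n_px))

    instances: list[Instance] = []
    cell_masks = []
    for cell in scene.cells:
        poly = cell.polygon()
        mask = rasterize_polygon(poly, (n_px, n_px))
        cell_masks.append(mask)
        if mask.any():
            interior = ndimage.binary_erosion(mask, iterations=2)
            rim = mask & ~interior
            img[interior] *= cfg.cell_interior_factor
            img[rim] *= cfg.cell_rim_factor
        instances.append(Instance(label=CELL, polygon=poly, mask=mask))

    for crystal in scene.crystals:
        mask = rasterize_polygon(crystal.polygon, (n_px, n_px))
        if not mask.any():
            # fully outside the frame after jitter; keep ground truth honest
            continue
        level = cfg.g_intensity if crystal.crystal_class == "G" else cfg.h_intensity
        interior = ndimage.binary_erosion(mask)
        edge = mask & ~interior
        img[mask] = level + rng.normal(0, 2.0, int(mask.sum()))
        img[edge] = level * cfg.crystal_edge_factor
        label = CRYSTAL_G if crystal.crystal_class == "G" else CRYSTAL_H
        instances.append(Instance(label=label, polygon=crystal.polygon,
                                  mask=mask, group_id=crystal.cluster_id))

    blur_px = cfg.blur_sigma_um / cfg.pixel_pitch_um
    if blur_px > 0:
        img = ndimage.gaussian_filter(img, blur_px)
    img = np.clip(img, 0, 255).round().astype(np.uint8)

    return AnnotatedImage(
        shape=(n_px, n_px),
        instances=instances,
        image=img,
        pixel_pitch_um=cfg.pixel_pitch_um,
        provenance=f"scene(seed={scene.seed})",
    )


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _render_at_output(config: GeneratorConfig, seed: int) -> AnnotatedImage:
    scene = sample_scene(config, seed)
    ann = render_scene(scene)
    if config.output_resolution_px != config.full_resolution_px:
        import warnings as _warnings
        with _warnings.catch_warnings():
            # sub-pixel instances are dropped below rather than kept empty
            _warnings.simplefilter("ignore", UserWarning)
            ann = resize_annotated(ann, config.output_resolution_px)
        # a crystal below one output pixel is not annotatable ground truth
        ann.instances = [i for i in ann.instances
                         if i.get_mask(ann.shape).any()]
    return ann


def generate_images(config: GeneratorConfig, n_images: int,
                    seed: int) -> list[AnnotatedImage]:
    """Generate ``n_images`` annotated images in memory, at output resolution."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    config.validate()
    return [_render_at_output(config, child_seed(seed, i))
            for i in range(n_images)]


def generate_dataset(config: GeneratorConfig, n_images: int, seed: int,
                     out_dir: str | Path) -> DatasetManifest:
    """Generate a dataset on disk: PNG images, Labelme JSON, TSV manifest.

    Images are written as 8-bit RGB PNG at ``output_resolution_px``;
    annotations keep the (rescaled) ground-truth polygons.  Regenerating with
    the same (config, seed) produces byte-identical annotation files.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for i in range(n_images):
        cseed = child_seed(seed, i)
        ann = _render_at_output(config, cseed)
        img_name = f"img_{i:04d}.png"
        ann_name = f"img_{i:04d}.json"
        write_image(ann.image, out_dir / img_name)
        write_labelme(ann, out_dir / ann_name, image_path=img_name)
        records.append(ManifestRecord(
            image_path=img_name,
            annotation_path=ann_name,
            class_counts=ann.class_counts(),
            seed=cseed,
        ))
    manifest = DatasetManifest(
        records=records,
        config_fingerprint=config_fingerprint(asdict(config)),
        seed=int(seed),
        root=out_dir,
    )
    write_manifest(manifest, out_dir / "manifest.tsv")
    return manifest
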