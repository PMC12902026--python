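"""Synthetic blood-smear image generation.

Renders microscopy-like fields of view containing round (normal) erythrocytes
and crescent-shaped (sickle) erythrocytes on a stained background with a
smooth illumination gradient and pixel noise.  Every downstream stage of the
package — quality filtering, embedding training, classification, Grad-CAM —
can therefore be exercised without any external image download.

The generator is fully deterministic given a seed: per-image seeds are derived
from the master seed with :class:`numpy.random.SeedSequence`, so a dataset is
bit-reproducible from ``(parameters, seed)``.

An image is labelled ``sickle`` iff it contains at least one sickle cell;
real thin-film datasets label whole fields of view the same way, and the
classifier operates at image level.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd

NORMAL = "normal"
SICKLE = "sickle"

# Stain palette: pale eosin background, darker purple-blue cells.
_BACKGROUND_RGB = np.array([225.0, 215.0, 222.0])
_NORMAL_RGB = np.array([188.0, 120.0, 148.0])
_SICKLE_RGB = np.array([150.0, 95.0, 150.0])


class PackingError(RuntimeError):
    """Raised when cells cannot be placed without excessive overlap."""


@dataclass(frozen=True)
class CellSpec:
    """Geometry and colour of a single rendered cell.

    ``curvature`` is a dimensionless "sickleness" knob: 0 gives a plain
    elliptical footprint, larger values carve a deeper crescent.  Only sickle
    cells use it.
    """

    shape_kind: str  # "round" | "sickle"
    center: Tuple[float, float]  # (row, col), pixels
    size: float  # radius (round) or half-length (sickle), pixels
    curvature: float = 0.0
    orientation: float = 0.0  # radians
    color: Tuple[float, float, float] = tuple(_NORMAL_RGB)

    def __post_init__(self) -> None:
        if self.shape_kind not in ("round", "sickle"):
            raise ValueError(f"unknown shape_kind {self.shape_kind!r}")
        if self.size <= 0:
            raise ValueError("cell size must be positive")
        if self.curvature < 0:
            raise ValueError("curvature must be non-negative")


@dataclass
class JitterParams:
    """Nuisance-variation knobs emulating acquisition variability.

    illumination_range
        Half-range of the per-image brightness offset (grey levels); the
        offset is drawn uniformly from ``[-r, +r]``.
    gradient_amplitude
        Peak-to-trough amplitude of the smooth illumination gradient.
    color_jitter
        Std-dev of the per-cell RGB stain perturbation.
    noise_sigma
        Std-dev of additive Gaussian pixel noise.
    size_jitter
        Relative std-dev of cell size around its nominal value.
    curvature
        Nominal sickle-cell curvature (0 = ellipse, ~1 = deep crescent).
    """

    illumination_range: float = 12.0
    gradient_amplitude: float = 8.0
    color_jitter: float = 10.0
    noise_sigma: float = 4.0
    size_jitter: float = 0.15
    curvature: float = 1.0
    max_overlap: float = 0.25
    cell_size: float = 6.5

    @classmethod
    def separable(cls) -> "JitterParams":
        """Minimal-nuisance preset: jitter at minimum, curvature high, so the
        two classes are well separated in pixel space."""
        return cls(
            illumination_range=1.0,
            gradient_amplitude=2.0,
            color_jitter=2.0,
            noise_sigma=1.5,
            size_jitter=0.08,
            curvature=1.3,
        )


@dataclass
class SmearImage:
    pixels: np.ndarray  # H x W x 3 uint8
    label: str
    cells: List[CellSpec]
    sickle_mask: np.ndarray  # H x W bool
    seed: int

    def __post_init__(self) -> None:
        has_sickle = bool(self.sickle_mask.any())
        expected = SICKLE if has_sickle else NORMAL
        if self.label != expected:
            raise ValueError(
                f"label {self.label!r} inconsistent with sickle_mask "
                f"({int(self.sickle_mask.sum())} foreground pixels)"
            )


@dataclass
class LabeledDataset:
    """Ordered collection of smear images with per-class counts."""

    images: List[SmearImage] = field(default_factory=list)

    @property
    def class_counts(self) -> Dict[str, int]:
        counts = {NORMAL: 0, SICKLE: 0}
        for im in self.images:
            counts[im.label] += 1
        return counts

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self) -> Iterator[SmearImage]:
        return iter(self.images)

    def __getitem__(self, i: int) -> SmearImage:
        return self.images[i]

    def labels(self) -> np.ndarray:
        """Binary labels, 0 = normal, 1 = sickle."""
        return np.array([1 if im.label == SICKLE else 0 for im in self.images])

    def pixel_stack(self) -> np.ndarray:
        return np.stack([im.pixels for im in self.images])


def generate_cell_mask(spec: CellSpec, canvas_size: Tuple[int, int]) -> np.ndarray:
    """Rasterize one cell footprint onto a boolean canvas.

    Round cells are filled discs of radius ``size``.  Sickle cells start from
    an ellipse with semi-axes ``(size, 0.75*size)`` and have a disc of radius
    ``size`` subtracted; the cutting disc sits at distance
    ``2*size - curvature*size`` from the cell centre along the minor axis, so
    at curvature 0 it does not touch the ellipse (plain elliptical footprint)
    and increasing curvature slides it in continuously, carving a crescent.
    """
    h, w = canvas_size
    r0, c0 = spec.center
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    dr = rows - r0
    dc = cols - c0
    if spec.shape_kind == "round":
        return dr * dr + dc * dc <= spec.size**2

    # Rotate into the cell frame: u along the major axis, v along the minor.
    cos_t, sin_t = np.cos(spec.orientation), np.sin(spec.orientation)
    u = cos_t * dc + sin_t * dr
    v = -sin_t * dc + cos_t * dr
    a = spec.size
    b = 0.75 * spec.size
    ellipse = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if spec.curvature == 0:
        mask = ellipse
    else:
        cut_dist = 2.0 * spec.size - spec.curvature * spec.size
        cut = u**2 + (v - cut_dist) ** 2 <= spec.size**2
        mask = ellipse & ~cut
    if not mask.any():
        # Extreme curvature can erase the footprint; keep a minimal core so
        # the sickle-label invariant stays well defined.
        mask = (u / a) ** 2 + ((v + b / 2) / (b / 2)) ** 2 <= 1.0
    return mask


def _bounding_radius(spec: CellSpec) -> float:
    return spec.size


def _place_cells(
    n_normal: int,
    n_sickle: int,
    size: Tuple[int, int],
    jitter: JitterParams,
    rng: np.random.Generator,
) -> List[CellSpec]:
    h, w = size
    specs: List[CellSpec] = []
    kinds = ["round"] * n_normal + ["sickle"] * n_sickle
    rng.shuffle(kinds)
    for kind in kinds:
        base = _NORMAL_RGB if kind == "round" else _SICKLE_RGB
        placed = False
        for _ in range(100):
            cell_size = float(
                np.clip(
                    jitter.cell_size * (1 + jitter.size_jitter * rng.standard_normal()),
                    2.0,
                    min(h, w) / 4,
                )
            )
            margin = cell_size + 1
            center = (
                float(rng.uniform(margin, h - margin)),
                float(rng.uniform(margin, w - margin)),
            )
            ok = True
            for other in specs:
                min_gap = (1.0 - jitter.max_overlap) * (cell_size + other.size)
                d = np.hypot(center[0] - other.center[0], center[1] - other.center[1])
                if d < min_gap:
                    ok = False
                    break
            if not ok:
                continue
            color = tuple(
                float(np.clip(c + jitter.color_jitter * rng.standard_normal(), 0, 255))
                for c in base
            )
            curvature = 0.0
            if kind == "sickle":
                curvature = float(
                    max(0.2, jitter.curvature * (1 + 0.1 * rng.standard_normal()))
                )
            specs.append(
                CellSpec(
                    shape_kind=kind,
                    center=center,
                    size=cell_size,
                    curvature=curvature,
                    orientation=float(rng.uniform(0, 2 * np.pi)),
                    color=color,
                )
            )
            placed = True
            break
        if not placed:
            raise PackingError(
                f"could not place cell {len(specs) + 1} of {len(kinds)} on a "
                f"{h}x{w} canvas after 100 attempts; reduce counts or overlap "
                "constraint"
            )
    return specs


def generate_smear_image(
    n_normal: int,
    n_sickle: int,
    size: Tuple[int, int] = (64, 64),
    background_level: float = 225.0,
    jitter: JitterParams | None = None,
    seed: int = 0,
) -> SmearImage:
    """Render one labelled smear image.

    Deterministic given ``seed``.  The image label follows the presence rule:
    ``sickle`` iff at least one sickle cell was rendered.
    """
    h, w = size
    if h < 64 or w < 64:
        raise ValueError("canvas must be at least 64x64")
    if n_normal < 0 or n_sickle < 0:
        raise ValueError("cell counts must be non-negative")
    jitter = jitter if jitter is not None else JitterParams()
    rng = np.random.default_rng(seed)

    # Background: tinted base + smooth two-way gradient + per-image offset.
    offset = rng.uniform(-jitter.illumination_range, jitter.illumination_range)
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    phase_r, phase_c = rng.uniform(0, 2 * np.pi, size=2)
    gradient = (jitter.gradient_amplitude / 2.0) * (
        np.sin(2 * np.pi * rows / h + phase_r) + np.sin(2 * np.pi * cols / w + phase_c)
    )
    tint = _BACKGROUND_RGB - _BACKGROUND_RGB.mean() + background_level
    img = tint[None, None, :] + (gradient + offset)[:, :, None]

    specs = _place_cells(n_normal, n_sickle, size, jitter, rng)
    sickle_mask = np.zeros((h, w), dtype=bool)
    for spec in specs:
        mask = generate_cell_mask(spec, size)
        # Slightly darker rim for a stained-cell look.
        img[mask] = np.asarray(spec.color)
        if spec.shape_kind == "sickle":
            sickle_mask |= mask

    img = img + rng.normal(0.0, jitter.noise_sigma, size=img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    label = SICKLE if sickle_mask.any() else NORMAL
    return SmearImage(
        pixels=pixels, label=label, cells=specs, sickle_mask=sickle_mask, seed=seed
    )


def generate_dataset(
    n_per_class: Dict[str, int],
    size: Tuple[int, int] = (64, 64),
    jitter: JitterParams | None = None,
    seed: int = 0,
    cells_per_image: Tuple[int, int] = (4, 8),
    sickle_fraction: float = 0.6,
) -> LabeledDataset:
    """Generate a dataset with exactly the requested per-class counts.

    Normal-class images contain only round cells; sickle-class images mix
    round and sickle cells (a ``sickle_fraction`` share of the total count,
    at least one), mirroring real fields of view where sickled and normal
    erythrocytes co-occur.  Per-image seeds are spawned deterministically
    from the master seed.
    """
    jitter = jitter if jitter is not None else JitterParams()
    for lbl, n in n_per_class.items():
        if lbl not in (NORMAL, SICKLE):
            raise ValueError(f"unknown label {lbl!r}")
        if n < 0:
            raise ValueError("counts must be non-negative")
    n_normal_imgs = n_per_class.get(NORMAL, 0)
    n_sickle_imgs = n_per_class.get(SICKLE, 0)

    master = np.random.SeedSequence(seed)
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in master.spawn(n_normal_imgs + n_sickle_imgs + 1)
    ]
    count_rng = np.random.default_rng(child_seeds[-1])

    images: List[SmearImage] = []
    for i in range(n_normal_imgs):
        n_cells = int(count_rng.integers(cells_per_image[0], cells_per_image[1] + 1))
        images.append(
            generate_smear_image(
                n_cells, 0, size=size, jitter=jitter, seed=child_seeds[i]
            )
        )
    for j in range(n_sickle_imgs):
        n_cells = int(count_rng.integers(cells_per_image[0], cells_per_image[1] + 1))
        n_sick = max(1, int(round(sickle_fraction * n_cells)))
        images.append(
            generate_smear_image(
                n_cells - n_sick,
                n_sick,
                size=size,
                jitter=jitter,
                seed=child_seeds[n_normal_imgs + j],
            )
        )
    return LabeledDataset(images=images)


def write_dataset(dataset: LabeledDataset, out_dir: str, prefix: str = "smear") -> pd.DataFrame:
    """Write PNGs plus a CSV manifest; returns the manifest frame."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, im in enumerate(dataset):
        n_normal = sum(1 for c in im.cells if c.shape_kind == "round")
        n_sickle = sum(1 for c in im.cells if c.shape_kind == "sickle")
        fname = f"{prefix}_{i:05d}_{im.label}.png"
        iio.imwrite(os.path.join(out_dir, fname), im.pixels)
        rows.append(
            {
                "filename": fname,
                "label": im.label,
                "seed": im.seed,
                "n_normal": n_normal,
                "n_sickle": n_sickle,
            }
        )
    manifest = pd.DataFrame(rows, columns=["filename", "label", "seed", "n_normal", "n_sickle"])
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def read_dataset(out_dir: str, manifest: pd.DataFrame | None = None) -> LabeledDataset:
    """Reload a written dataset (pixels and labels only; masks are not stored)."""
    if manifest is None:
        manifest = pd.read_csv(os.path.join(out_dir, "manifest.csv"))
    images = []
    for _, row in manifest.iterrows():
        pixels = np.asarray(iio.imread(os.path.join(out_dir, row["filename"])))
        mask = np.zeros(pixels.shape[:2], dtype=bool)
        if row["label"] == SICKLE:
            # Reloaded images carry no geometry; a sentinel pixel keeps the
            # label/mask invariant without pretending to know cell outlines.
            mask[0, 0] = True
        images.append(
            SmearImage(
                pixels=pixels,
                label=row["label"],
                cells=[],
                sickle_mask=mask,
                seed=int(row["seed"]),
            )
        )
    return LabeledDataset(images=images)
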