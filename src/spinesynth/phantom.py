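"""Paired multi-contrast synthetic spine volumes for testing and desk-scale training.

Real whole-spine cohorts with paired T1w FSE / T2w FSE / STIR / axial Dixon
acquisitions are access-restricted, so this module builds a schematic digital
phantom instead: stacked vertebral bodies separated by discs, a posterior
CSF-filled canal and a muscle block, each voxel carrying a fat fraction ``f``
and a water fraction ``w``.  Every modality is rendered from the same tissue
map by a linear mixing model

    s_modality = base(label) + alpha_modality * f + beta_modality * w + noise

whose coefficient signs encode the textbook contrast behaviour: fat is bright
on T1w/T2w FSE and on the Dixon fat image, suppressed on STIR and the Dixon
water image; free water is dark on T1w, bright on T2w/STIR/Dixon water.
Focal lesions (Modic type 1/2, hemangioma, edema) override ``f``/``w``
locally.  The map (f, w, label) -> five contrasts is deterministic, so it
doubles as a closed-form oracle translator when validating trained models.
No claim of Bloch-equation fidelity is made; the geometry is schematic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .stitching import ChunkSet
from .volume import ImageVolume, save_nifti

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "TissueMap",
    "build_tissue_map",
    "render_contrast",
    "degrade_axial",
    "split_into_chunks",
    "make_dataset",
    "MODALITIES",
    "CONTRAST_COEFFS",
    "BASE_SIGNAL",
]

MODALITIES = ("t1w", "t2w", "stir", "dixon_fat", "dixon_water")

LABELS = {"background": 0, "vertebra": 1, "disc": 2, "canal": 3, "muscle": 4, "lesion": 5}

#: baseline signal per tissue label (arbitrary units)
BASE_SIGNAL = {
    "background": 0.05,
    "vertebra": 0.4,
    "disc": 0.5,
    "canal": 0.2,
    "muscle": 0.3,
    "lesion": 0.4,  # lesions sit in vertebrae; contrast comes from f/w
}

#: (alpha, beta) = fat / water signal coefficients per modality
CONTRAST_COEFFS = {
    "t1w": (0.5, -0.3),
    "t2w": (0.4, 0.5),
    "stir": (-0.35, 0.6),
    "dixon_fat": (0.8, 0.0),
    "dixon_water": (-0.1, 0.8),
}

#: (f, w) of each base tissue
TISSUE_FRACTIONS = {
    "background": (0.0, 0.0),
    "vertebra": (0.5, 0.2),
    "disc": (0.05, 0.8),
    "canal": (0.0, 0.9),
    "muscle": (0.1, 0.6),
}

#: lesion phenotypes: (f, w) defaults
LESION_FRACTIONS = {
    "modic1": (0.1, 0.9),
    "modic2": (0.9, 0.2),
    "hemangioma": (0.8, 0.3),
    "edema": (0.05, 0.95),
}


@dataclass
class LesionSpec:
    """A spherical focal lesion painted into a vertebra."""

    kind: str
    center: tuple
    radius: float
    fat_fraction: float | None = None
    water_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in LESION_FRACTIONS:
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        f0, w0 = LESION_FRACTIONS[self.kind]
        if self.fat_fraction is None:
            self.fat_fraction = f0
        if self.water_fraction is None:
            self.water_fraction = w0


@dataclass
class PhantomSpec:
    """Full description of one synthetic subject; ``seed`` fixes everything."""

    shape: tuple = (32, 96, 96)
    spacing: tuple = (3.0, 1.1, 1.1)
    n_vertebrae: int = 5
    disc_thickness: int = 4
    lesions: list = field(default_factory=list)
    noise_sd: float = 0.02
    seed: int = 0


@dataclass
class TissueMap:
    """Label grid plus per-voxel fat and water fractions."""

    labels: np.ndarray
    f: np.ndarray
    w: np.ndarray
    affine: np.ndarray


def _default_affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def build_tissue_map(spec: PhantomSpec) -> TissueMap:
    """Paint the schematic spine geometry and lesion overrides.

    Axis 0 is right-left, axis 1 runs down the spine (inferior), axis 2
    posterior.  Vertebral bodies are ellipsoids stacked along axis 1 with
    discs between them, a canal column posterior to the bodies, and a muscle
    slab behind that.
    """
    nx, ny, nz = spec.shape
    labels = np.zeros(spec.shape, dtype=np.uint8)
    f = np.zeros(spec.shape)
    w = np.zeros(spec.shape)

    def paint(mask, name):
        labels[mask] = LABELS[name]
        ff, ww = TISSUE_FRACTIONS[name]
        f[mask] = ff
        w[mask] = ww

    # muscle slab across the posterior third
    z_muscle = int(0.68 * nz)
    muscle = np.zeros(spec.shape, bool)
    muscle[:, :, z_muscle:] = True
    paint(muscle, "muscle")

    # vertebral column geometry
    seg = ny / spec.n_vertebrae
    body_h = seg - spec.disc_thickness
    if body_h < 2:
        raise ValueError("shape too small for n_vertebrae stacked bodies")
    cx, cz = nx / 2.0, 0.42 * nz
    rx, rz = max(2.0, nx * 0.3), max(2.0, nz * 0.14)
    ii, jj, kk = np.indices(spec.shape, dtype=float)

    for v in range(spec.n_vertebrae):
        top = v * seg
        cy = top + body_h / 2.0
        ry = body_h / 2.0
        body = ((ii - cx) / rx) ** 2 + ((jj - cy) / ry) ** 2 + ((kk - cz) / rz) ** 2 <= 1.0
        paint(body, "vertebra")
        if v < spec.n_vertebrae - 1:
            disc = (
                (np.abs(jj - (top + body_h + spec.disc_thickness / 2.0)) <= spec.disc_thickness / 2.0)
                & (((ii - cx) / rx) ** 2 + ((kk - cz) / rz) ** 2 <= 0.9)
            )
            paint(disc, "disc")

    # spinal canal: thin column posterior to the bodies
    canal_z = cz + rz + 2
    canal = ((ii - cx) / max(1.5, rx * 0.25)) ** 2 + ((kk - canal_z) / 2.0) ** 2 <= 1.0
    canal &= kk < z_muscle
    paint(canal, "canal")

    # lesions override fractions inside their sphere
    for li, les in enumerate(spec.lesions):
        c = np.asarray(les.center, dtype=float)
        if np.any(c < 0) or np.any(c >= np.asarray(spec.shape)):
            raise ValueError(f"lesion {li} center {les.center} outside volume")
        sphere = ((ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2) <= les.radius**2
        labels[sphere] = LABELS["lesion"]
        f[sphere] = les.fat_fraction
        w[sphere] = les.water_fraction

    return TissueMap(labels, f, w, _default_affine(spec.spacing))


def render_contrast(t: TissueMap, modality: str, noise_sd: float = 0.0, seed: int = 0) -> ImageVolume:
    """Render one MR contrast from the tissue map via the linear mixing model."""
    if modality not in CONTRAST_COEFFS:
        raise ValueError(f"unknown modality {modality!r}; choose from {MODALITIES}")
    alpha, beta = CONTRAST_COEFFS[modality]
    inv = {v: k for k, v in LABELS.items()}
    base = np.zeros(t.labels.shape)
    for code in np.unique(t.labels):
        base[t.labels == code] = BASE_SIGNAL[inv[int(code)]]
    signal = base + alpha * t.f + beta * t.w
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return ImageVolume(np.clip(signal, 0.0, None), t.affine.copy())


def degrade_axial(vol: ImageVolume, slice_thickness: float) -> ImageVolume:
    """Emulate the low through-plane resolution of an axial Dixon stack.

    Gaussian blur with FWHM equal to ``slice_thickness`` along the
    inferior-superior axis (axis 1), decimation to that slice spacing, then
    linear resampling back onto the original grid.  Other axes are untouched.
    """
    spacing = vol.spacing[1]
    if slice_thickness < spacing:
        raise ValueError("slice_thickness must be >= native spacing along axis 1")
    factor = slice_thickness / spacing
    sigma = (slice_thickness / spacing) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    data = ndimage.gaussian_filter1d(np.asarray(vol.data, dtype=float), sigma, axis=1, mode="nearest")
    n = vol.shape[1]
    coarse_pos = np.arange(0, n, factor)
    fine_pos = np.arange(n, dtype=float)
    # sample at coarse slice centers, then linear interpolation back
    coarse = ndimage.map_coordinates(
        data, _axis1_coords(data.shape, coarse_pos), order=1, mode="nearest"
    ).reshape(data.shape[0], len(coarse_pos), data.shape[2])
    idx = np.interp(fine_pos, coarse_pos, np.arange(len(coarse_pos), dtype=float))
    out = ndimage.map_coordinates(
        coarse, _axis1_coords(coarse.shape, idx), order=1, mode="nearest"
    ).reshape(vol.shape)
    return ImageVolume(out, vol.affine.copy())


def _axis1_coords(shape, positions):
    """Coordinate arrays sampling ``positions`` along axis 1 of ``shape``."""
    i, j, k = np.meshgrid(
        np.arange(shape[0], dtype=float),
        np.asarray(positions, dtype=float),
        np.arange(shape[2], dtype=float),
        indexing="ij",
    )
    return np.vstack([i.ravel(), j.ravel(), k.ravel()])


def split_into_chunks(
    vol: ImageVolume, n: int = 2, overlap: int = 8, jitter: float = 0.0, seed: int = 0
) -> ChunkSet:
    """Cut a volume into ``n`` vertically consecutive chunks with voxel overlap.

    Each chunk's affine encodes its true world position; ``jitter`` adds a
    random translation (mm, uniform in [-jitter, jitter] per axis) for
    exercising registration.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ny = vol.shape[1]
    height = int(np.ceil((ny + (n - 1) * overlap) / n))
    if n > 1 and overlap >= height:
        raise ValueError(f"overlap {overlap} too large for chunk height {height}")
    rng = np.random.default_rng(seed)
    chunks = []
    for c in range(n):
        start = min(c * (height - overlap), ny - height) if n > 1 else 0
        stop = min(start + height, ny)
        data = vol.data[:, start:stop, :].copy()
        affine = vol.affine.copy()
        affine[:3, 3] = (vol.affine @ np.array([0.0, start, 0.0, 1.0]))[:3]
        if jitter > 0:
            affine[:3, 3] += rng.uniform(-jitter, jitter, size=3)
        chunks.append(ImageVolume(data, affine))
    return ChunkSet(chunks)


def random_spec(template: PhantomSpec, seed: int) -> PhantomSpec:
    """Randomize lesions (count, site, phenotype) around a template spec."""
    rng = np.random.default_rng(seed)
    nx, ny, nz = template.shape
    seg = ny / template.n_vertebrae
    body_h = seg - template.disc_thickness
    lesions = []
    for _ in range(int(rng.integers(1, 4))):
        kind = str(rng.choice(list(LESION_FRACTIONS)))
        v = int(rng.integers(0, template.n_vertebrae))
        cy = v * seg + body_h / 2.0 + rng.uniform(-body_h / 6, body_h / 6)
        center = (nx / 2.0 + rng.uniform(-2, 2), cy, 0.42 * nz + rng.uniform(-3, 3))
        radius = float(rng.uniform(1.5, min(3.5, body_h / 2.5)))
        lesions.append(LesionSpec(kind, center, radius))
    return dataclasses.replace(template, lesions=lesions, seed=seed)


def render_study(spec: PhantomSpec, dixon_slice_thickness: float = 6.0) -> dict:
    """Render all five modalities for one subject; Dixon pair degraded axially."""
    t = build_tissue_map(spec)
    study = {}
    for m_i, mod in enumerate(MODALITIES):
        vol = render_contrast(t, mod, spec.noise_sd, seed=spec.seed * 7 + m_i)
        if mod.startswith("dixon"):
            vol = degrade_axial(vol, dixon_slice_thickness)
        study[mod] = vol
    return study


def make_dataset(
    template: PhantomSpec,
    n_subjects: int,
    out_dir: str | Path,
    seed: int = 0,
    dixon_slice_thickness: float = 6.0,
) -> pd.DataFrame:
    """Write ``n_subjects`` randomized phantom studies as NIfTI plus a CSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = random_spec(template, sub_seed)
        study = render_study(spec, dixon_slice_thickness)
        sid = f"sub-{s:03d}"
        files = {}
        for mod, vol in study.items():
            path = out / f"{sid}_{mod}.nii.gz"
            save_nifti(vol, path)
            files[mod] = path.name
        rows.append(
            {
                "subject": sid,
                "seed": sub_seed,
                "n_lesions": len(spec.lesions),
                "lesions": ";".join(
                    f"{l.kind}@{tuple(round(float(x), 1) for x in l.center)}r{l.radius:.1f}"
                    for l in spec.lesions
                ),
                **files,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
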