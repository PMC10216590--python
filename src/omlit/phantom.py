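"""Seeded synthetic tissue phantoms: generate, slice, render, damage.

A phantom is a 3-D label volume emulating resin-embedded cortex at light-
microscope scale: neuropil background, non-overlapping somata (each with a
nucleus and 1-3 nucleoli), straight blood vessels crossing the volume, and
random-walk neurite processes emanating from the somata.  Everything is
generated from a single integer seed and a parameter set, and regeneration
is bit-identical.

Phantoms are sliced into serial sections (majority label per pixel across
the slab, with a deeper-structure precedence order on ties), and sections
are rendered into reflected-light images through the multilayer optical
model: each label maps to a section material, the stack reflectance is
computed once per label, and per-pixel intensity is ``gain * R + offset``
plus optional seeded noise.  A defect injector overlays the coating
artifacts seen in practice (scratches, cracks, dirt specks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .contrast_model import OmlitConfig, build_stacks
from .materials import MaterialLibrary
from .tmm import Illumination, stack_reflectance

__all__ = [
    "LABELS",
    "LABEL_NAMES",
    "LABEL_PRECEDENCE",
    "DEFAULT_LABEL_MATERIALS",
    "PhantomParams",
    "TissuePhantom",
    "SectionLabelMap",
    "SectionImage",
    "GenerationError",
    "UnmappedLabelError",
    "generate_phantom",
    "slice_phantom",
    "render_section",
    "add_defects",
]

#: Integer codes of the tissue classes.
LABELS = {"neuropil": 0, "cytoplasm": 1, "nucleus": 2, "nucleolus": 3, "vessel_lumen": 4}
LABEL_NAMES = {v: k for k, v in LABELS.items()}

#: Tie-break order when a slab's majority vote is ambiguous: deeper/denser
#: structures win (nucleolus > nucleus > cytoplasm > vessel lumen > neuropil).
LABEL_PRECEDENCE = (
    LABELS["nucleolus"],
    LABELS["nucleus"],
    LABELS["cytoplasm"],
    LABELS["vessel_lumen"],
    LABELS["neuropil"],
)

#: Default label -> section-material mapping for rendering.
DEFAULT_LABEL_MATERIALS = {
    LABELS["neuropil"]: "stained_tissue",
    LABELS["cytoplasm"]: "stained_cell",
    LABELS["nucleus"]: "stained_cell",
    LABELS["nucleolus"]: "stained_cell",
    LABELS["vessel_lumen"]: "resin",
}


class GenerationError(RuntimeError):
    """Phantom generation failed (e.g. rejection-sampling budget exhausted)."""


class UnmappedLabelError(KeyError):
    """A label present in the section has no material mapping."""


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and content of a synthetic cortex phantom.

    Sizes are physical; the voxel grid may be anisotropic (finer along z to
    support ultrathin sectioning).  Defaults emulate a wide cortical field:
    soma diameters 5-20 um, one nucleus per soma (radius fraction 0.7) with
    1-3 nucleoli, a few crossing vessels, short neurite processes.
    """

    volume_um: tuple[float, float, float] = (350.0, 350.0, 3.0)  # (x, y, z)
    voxel_nm: tuple[float, float, float] = (200.0, 200.0, 60.0)  # (x, y, z)
    soma_count: int = 120
    soma_radius_um: tuple[float, float] = (2.5, 10.0)
    nucleus_radius_fraction: float = 0.7
    nucleolus_radius_fraction: float = 0.15
    nucleoli_per_nucleus: tuple[int, int] = (1, 3)
    vessel_count: int = 4
    vessel_radius_um: tuple[float, float] = (3.0, 6.0)
    processes_per_cell: int = 3
    process_radius_um: float = 0.5
    process_length_um: float = 15.0
    rejection_budget_per_soma: int = 1000

    def grid_shape(self) -> tuple[int, int, int]:
        """(nz, ny, nx) voxel counts."""
        nx = int(round(self.volume_um[0] * 1000.0 / self.voxel_nm[0]))
        ny = int(round(self.volume_um[1] * 1000.0 / self.voxel_nm[1]))
        nz = int(round(self.volume_um[2] * 1000.0 / self.voxel_nm[2]))
        return nz, ny, nx


@dataclass(frozen=True)
class TissuePhantom:
    """Label volume (z, y, x) plus the recipe that produced it."""

    labels: np.ndarray  # uint8, shape (nz, ny, nx)
    voxel_nm: tuple[float, float, float]  # (x, y, z)
    seed: int
    params: PhantomParams
    soma_centers_nm: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    soma_radii_nm: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_sections(self) -> int:
        return self.labels.shape[0]


@dataclass(frozen=True)
class SectionLabelMap:
    """One sectioned slab's 2-D ground-truth labels."""

    labels: np.ndarray  # uint8, (ny, nx)
    section_index: int
    section_thickness_nm: float
    pixel_size_nm: tuple[float, float]  # (x, y)


@dataclass(frozen=True)
class SectionImage:
    """Rendered grayscale section (float intensities) with its recipe."""

    data: np.ndarray  # float64, (ny, nx)
    pixel_size_nm: tuple[float, float]
    metadata: dict
    defect_mask: np.ndarray | None = None

    def to_uint16(self) -> np.ndarray:
        return np.clip(np.round(self.data * 65535.0), 0, 65535).astype(np.uint16)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _paint_ellipsoid(vol, center_nm, radius_nm, voxel_nm, label, only_over=None):
    """Paint a sphere of physical radius into the anisotropic voxel grid."""
    nz, ny, nx = vol.shape
    vx, vy, vz = voxel_nm
    cx, cy, cz = center_nm
    x0 = max(0, int((cx - radius_nm) / vx) - 1)
    x1 = min(nx, int((cx + radius_nm) / vx) + 2)
    y0 = max(0, int((cy - radius_nm) / vy) - 1)
    y1 = min(ny, int((cy + radius_nm) / vy) + 2)
    z0 = max(0, int((cz - radius_nm) / vz) - 1)
    z1 = min(nz, int((cz + radius_nm) / vz) + 2)
    if x0 >= x1 or y0 >= y1 or z0 >= z1:
        return
    zz = (np.arange(z0, z1) + 0.5) * vz - cz
    yy = (np.arange(y0, y1) + 0.5) * vy - cy
    xx = (np.arange(x0, x1) + 0.5) * vx - cx
    d2 = zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
    mask = d2 <= radius_nm * radius_nm
    sub = vol[z0:z1, y0:y1, x0:x1]
    if only_over is not None:
        mask = mask & np.isin(sub, only_over)
    sub[mask] = label


def generate_phantom(params: PhantomParams, seed: int) -> TissuePhantom:
    """Generate a seeded label volume; bit-identical for the same inputs.

    Somata are placed by rejection sampling with no mutual overlap (raises
    :class:`GenerationError` naming the budget when the requested density is
    infeasible); vessels are straight tubes crossing the volume; processes
    are persistent random-walk tubes seeded on soma surfaces, painted over
    neuropil only.
    """
    rng = np.random.default_rng(seed)
    shape = params.grid_shape()
    vol = np.zeros(shape, dtype=np.uint8)
    ext_nm = tuple(v * 1000.0 for v in params.volume_um)
    voxel_nm = params.voxel_nm

    # vessels first (somata may overwrite them)
    for _ in range(params.vessel_count):
        r = rng.uniform(*params.vessel_radius_um) * 1000.0
        axis = rng.integers(0, 2)  # crossing direction in the imaging plane
        a = np.array([rng.uniform(0, ext_nm[0]), rng.uniform(0, ext_nm[1]), rng.uniform(0, ext_nm[2])])
        b = a.copy()
        a[axis], b[axis] = 0.0, ext_nm[axis]
        b[1 - axis] = np.clip(b[1 - axis] + rng.normal(0, 0.2 * ext_nm[1 - axis]), 0, ext_nm[1 - axis])
        length = float(np.linalg.norm(b - a))
        n_steps = max(2, int(length / (r / 2.0)))
        for t in np.linspace(0.0, 1.0, n_steps):
            _paint_ellipsoid(
                vol, a + t * (b - a), r, voxel_nm, LABELS["vessel_lumen"],
                only_over=[LABELS["neuropil"]],
            )

    # somata: rejection sampling without overlap
    centers: list[np.ndarray] = []
    radii: list[float] = []
    budget = params.rejection_budget_per_soma * max(1, params.soma_count)
    attempts = 0
    while len(centers) < params.soma_count:
        if attempts >= budget:
            raise GenerationError(
                f"placed {len(centers)}/{params.soma_count} somata within the "
                f"rejection budget of {budget} attempts; reduce density or radii"
            )
        attempts += 1
        r = rng.uniform(*params.soma_radius_um) * 1000.0
        c = np.array([rng.uniform(0, ext_nm[0]), rng.uniform(0, ext_nm[1]), rng.uniform(0, ext_nm[2])])
        if any(np.linalg.norm(c - c2) < r + r2 for c2, r2 in zip(centers, radii)):
            continue
        centers.append(c)
        radii.append(r)

    nucleolus_counts = [
        int(rng.integers(params.nucleoli_per_nucleus[0], params.nucleoli_per_nucleus[1] + 1))
        for _ in centers
    ]
    process_dirs = []
    for c, r in zip(centers, radii):
        dirs = []
        for _ in range(params.processes_per_cell):
            v = rng.normal(size=3)
            v[2] *= 0.2  # keep processes roughly in-plane, like a thin slab of cortex
            dirs.append(v / np.linalg.norm(v))
        process_dirs.append(dirs)

    for (c, r, n_nucleoli) in zip(centers, radii, nucleolus_counts):
        _paint_ellipsoid(vol, c, r, voxel_nm, LABELS["cytoplasm"])
        r_nuc = r * params.nucleus_radius_fraction
        _paint_ellipsoid(vol, c, r_nuc, voxel_nm, LABELS["nucleus"])
        r_nucl = r * params.nucleolus_radius_fraction
        for _ in range(n_nucleoli):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            off = u * rng.uniform(0, max(0.0, r_nuc - r_nucl))
            _paint_ellipsoid(vol, c + off, r_nucl, voxel_nm, LABELS["nucleolus"])

    # processes: persistent random walks from soma surfaces, over neuropil only
    step_nm = max(params.process_radius_um * 1000.0, min(voxel_nm))
    for (c, r, dirs) in zip(centers, radii, process_dirs):
        for d in dirs:
            pos = c + d * (r + step_nm)
            heading = d.copy()
            n_steps = int(params.process_length_um * 1000.0 / step_nm)
            for _ in range(n_steps):
                _paint_ellipsoid(
                    vol, pos, params.process_radius_um * 1000.0, voxel_nm,
                    LABELS["cytoplasm"], only_over=[LABELS["neuropil"]],
                )
                jitter = rng.normal(scale=0.4, size=3)
                jitter[2] *= 0.2
                heading = heading + jitter
                heading /= np.linalg.norm(heading)
                pos = pos + heading * step_nm
                if not all(0 <= pos[i] <= ext_nm[i] for i in range(3)):
                    break

    return TissuePhantom(
        labels=vol,
        voxel_nm=voxel_nm,
        seed=seed,
        params=params,
        soma_centers_nm=np.array(centers).reshape(-1, 3),
        soma_radii_nm=np.array(radii),
    )


# ---------------------------------------------------------------------------
# Sectioning
# ---------------------------------------------------------------------------

def slice_phantom(
    phantom: TissuePhantom, section_thickness_nm: float, index: int
) -> SectionLabelMap:
    """Ground-truth label map of serial section ``index``.

    The slab spans ``[index * t, (index + 1) * t)`` in depth, quantized to
    voxel layers; each pixel takes the majority label over the slab, ties
    broken by :data:`LABEL_PRECEDENCE` (deeper structure wins).
    """
    vz = phantom.voxel_nm[2]
    nz = phantom.labels.shape[0]
    z0 = int(round(index * section_thickness_nm / vz))
    z1 = int(round((index + 1) * section_thickness_nm / vz))
    z1 = max(z1, z0 + 1)
    if index < 0 or z0 >= nz or z1 > nz:
        raise IndexError(
            f"section {index} (voxel rows [{z0}, {z1})) outside volume of {nz} rows"
        )
    slab = phantom.labels[z0:z1]
    counts = np.stack([(slab == lab).sum(axis=0) for lab in LABEL_PRECEDENCE])
    winner = np.argmax(counts, axis=0)  # first max wins -> precedence order
    out = np.array(LABEL_PRECEDENCE, dtype=np.uint8)[winner]
    return SectionLabelMap(
        labels=out,
        section_index=index,
        section_thickness_nm=section_thickness_nm,
        pixel_size_nm=(phantom.voxel_nm[0], phantom.voxel_nm[1]),
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_section(
    labelmap: SectionLabelMap,
    config: OmlitConfig,
    illum: Illumination,
    lib: MaterialLibrary,
    label_materials: dict[int, str] | None = None,
    gain: float = 1.0,
    offset: float = 0.0,
    noise_sd: float = 0.0,
    poisson_scale: float = 0.0,
    seed: int = 0,
) -> SectionImage:
    """Render a reflected-light image of one section.

    The stack reflectance is computed once per label present (section layer
    thickness taken from the label map, material from ``label_materials``);
    intensity is ``gain * R + offset``, then optional seeded shot noise
    (Poisson with ``poisson_scale`` expected counts at intensity 1) and
    additive Gaussian noise of standard deviation ``noise_sd``.
    """
    if label_materials is None:
        label_materials = DEFAULT_LABEL_MATERIALS
    cfg = replace(config, section_thickness_nm=labelmap.section_thickness_nm)
    present = np.unique(labelmap.labels)
    reflectance = {}
    for lab in present:
        lab = int(lab)
        if lab not in label_materials:
            raise UnmappedLabelError(
                f"label {lab} ({LABEL_NAMES.get(lab, '?')}) has no material mapping"
            )
        stack, _ = build_stacks(replace(cfg, cell_material=label_materials[lab]))
        reflectance[lab] = stack_reflectance(stack, illum, lib).R
    lut = np.zeros(int(present.max()) + 1)
    for lab, r in reflectance.items():
        lut[lab] = r
    img = gain * lut[labelmap.labels] + offset
    rng = np.random.default_rng(seed)
    if poisson_scale > 0:
        img = rng.poisson(np.clip(img, 0, None) * poisson_scale) / poisson_scale
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    meta = {
        "wavelength_nm": illum.wavelength_nm,
        "spectral_fwhm_nm": illum.spectral_fwhm_nm,
        "numerical_aperture": illum.numerical_aperture,
        "section_index": labelmap.section_index,
        "section_thickness_nm": labelmap.section_thickness_nm,
        "gain": gain,
        "offset": offset,
        "noise_sd": noise_sd,
        "poisson_scale": poisson_scale,
        "seed": seed,
        "label_reflectance": {str(k): float(v) for k, v in sorted(reflectance.items())},
    }
    return SectionImage(
        data=img.astype(float),
        pixel_size_nm=labelmap.pixel_size_nm,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# Defects
# ---------------------------------------------------------------------------

def _stamp_line(mask, r0, c0, r1, c1, half_width):
    """Mark a thick line segment on a boolean mask (disk-stamped polyline)."""
    length = math.hypot(r1 - r0, c1 - c0)
    n = max(2, int(length * 2))
    rr = np.linspace(r0, r1, n)
    cc = np.linspace(c0, c1, n)
    h, w = mask.shape
    for r, c in zip(rr, cc):
        rlo, rhi = int(max(0, r - half_width)), int(min(h, r + half_width + 1))
        clo, chi = int(max(0, c - half_width)), int(min(w, c + half_width + 1))
        if rlo >= rhi or clo >= chi:
            continue
        yy, xx = np.ogrid[rlo:rhi, clo:chi]
        mask[rlo:rhi, clo:chi] |= (yy - r) ** 2 + (xx - c) ** 2 <= half_width**2


def add_defects(
    image: SectionImage,
    scratches: int = 0,
    scratch_width_px: int = 3,
    scratch_depth: float = 0.3,
    cracks: int = 0,
    crack_depth: float = 0.4,
    specks: int = 0,
    speck_radius_px: int = 4,
    speck_level: float = 0.05,
    seed: int = 0,
) -> SectionImage:
    """Overlay coating defects: scratches, cracks and dirt specks.

    Scratches are straight dark lines crossing the field (intensity reduced
    by ``scratch_depth``); cracks are jagged bright polylines (exposed
    reflective coating, intensity raised by ``crack_depth``); specks are
    dark disks set to ``speck_level``.  Deterministic per seed; with all
    counts 0 the image is returned unchanged.  The pixels touched are
    recorded in ``defect_mask``.
    """
    if scratches == 0 and cracks == 0 and specks == 0:
        return image
    rng = np.random.default_rng(seed)
    img = image.data.copy()
    h, w = img.shape
    mask = np.zeros((h, w), dtype=bool)

    for _ in range(scratches):
        m = np.zeros_like(mask)
        if rng.random() < 0.5:
            r0, r1 = rng.uniform(0, h - 1), rng.uniform(0, h - 1)
            _stamp_line(m, r0, 0, r1, w - 1, scratch_width_px / 2.0)
        else:
            c0, c1 = rng.uniform(0, w - 1), rng.uniform(0, w - 1)
            _stamp_line(m, 0, c0, h - 1, c1, scratch_width_px / 2.0)
        img[m] = np.clip(img[m] - scratch_depth, 0.0, None)
        mask |= m

    for _ in range(cracks):
        m = np.zeros_like(mask)
        n_seg = int(rng.integers(3, 7))
        pts_r = np.clip(np.cumsum(rng.uniform(-0.4, 0.4, n_seg + 1)) * h + rng.uniform(0, h), 0, h - 1)
        pts_c = np.linspace(rng.uniform(0, w * 0.3), rng.uniform(w * 0.7, w - 1), n_seg + 1)
        for i in range(n_seg):
            _stamp_line(m, pts_r[i], pts_c[i], pts_r[i + 1], pts_c[i + 1], 1.0)
        img[m] = img[m] + crack_depth
        mask |= m

    for _ in range(specks):
        m = np.zeros_like(mask)
        r, c = rng.uniform(0, h - 1), rng.uniform(0, w - 1)
        _stamp_line(m, r, c, r, c, float(speck_radius_px))
        img[m] = speck_level
        mask |= m

    meta = dict(image.metadata)
    meta["defects"] = {
        "scratches": scratches,
        "scratch_width_px": scratch_width_px,
        "scratch_depth": scratch_depth,
        "cracks": cracks,
        "crack_depth": crack_depth,
        "specks": specks,
        "speck_radius_px": speck_radius_px,
        "speck_level": speck_level,
        "seed": seed,
    }
    return SectionImage(
        data=img, pixel_size_nm=image.pixel_size_nm, metadata=meta, defect_mask=mask
    )


def count_somata(phantom: TissuePhantom) -> int:
    """Number of disjoint somata by connected-component labeling of the
    cytoplasm/nucleus/nucleolus voxels (independent of the generator's
    bookkeeping; used as a brute-force check)."""
    cell = np.isin(
        phantom.labels, [LABELS["cytoplasm"], LABELS["nucleus"], LABELS["nucleolus"]]
    )
    _, n = ndimage.label(cell)
    return int(n)
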