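"""ROI-pair contrast measurement on section images.

Mirrors how contrast is quantified on acquired sections: the image is
normalized, pairs of equal-area regions are selected — one inside a cell
body, one in the surrounding neuropil — and each pair's contrast is the
ratio of the brighter to the darker mean intensity.  The estimate is the
per-pair average (with its standard deviation), matching the
"n pairs evaluated, average contrast" protocol; 50 pairs is the reference
pair count.

ROIs are fixed squares sampled reproducibly from a ground-truth label map
(seeded), rather than hand-drawn regions; manually defined ROIs can be
imported from a simple CSV of pixel coordinates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .phantom import LABELS, SectionLabelMap

__all__ = [
    "RoiPair",
    "ContrastEstimate",
    "DegenerateImageError",
    "SamplingError",
    "normalize_image",
    "sample_roi_pairs",
    "measure_contrast",
    "write_roi_csv",
    "read_roi_csv",
]

#: Labels considered "cell" for ROI placement.
CELL_LABELS = (LABELS["cytoplasm"], LABELS["nucleus"], LABELS["nucleolus"])
#: Label considered "surround".
SURROUND_LABEL = LABELS["neuropil"]


class DegenerateImageError(ValueError):
    """Operation undefined on a constant image."""


class SamplingError(RuntimeError):
    """Could not sample the requested number of valid ROI pairs."""


@dataclass(frozen=True)
class RoiPair:
    """Equal-area, disjoint cell/surround pixel sets (``(row, col)`` arrays)."""

    pair_id: int
    cell_pixels: np.ndarray  # (N, 2) int
    surround_pixels: np.ndarray  # (N, 2) int

    def __post_init__(self) -> None:
        cp = np.asarray(self.cell_pixels, dtype=int).reshape(-1, 2)
        sp = np.asarray(self.surround_pixels, dtype=int).reshape(-1, 2)
        if cp.shape[0] == 0 or cp.shape != sp.shape:
            raise ValueError("cell and surround regions must be non-empty and equal-area")
        both = np.vstack([cp, sp])
        if np.unique(both, axis=0).shape[0] != both.shape[0]:
            raise ValueError("cell and surround regions must be disjoint")
        object.__setattr__(self, "cell_pixels", cp)
        object.__setattr__(self, "surround_pixels", sp)

    @classmethod
    def from_squares(
        cls, pair_id: int, cell_center: tuple[int, int], surround_center: tuple[int, int], side: int
    ) -> "RoiPair":
        half = side // 2

        def square(center):
            r, c = center
            rr, cc = np.mgrid[r - half : r - half + side, c - half : c - half + side]
            return np.column_stack([rr.ravel(), cc.ravel()])

        return cls(pair_id, square(cell_center), square(surround_center))


@dataclass(frozen=True)
class ContrastEstimate:
    """Per-pair contrasts with their mean, spread and bookkeeping."""

    per_pair: np.ndarray
    mean: float
    sd: float
    n: int
    n_excluded: int = 0
    formula: str = "ratio"

    @property
    def sem(self) -> float:
        return self.sd / np.sqrt(self.n) if self.n > 0 else float("nan")


def normalize_image(
    image: np.ndarray, mode: str = "percentile", p_low: float = 0.1, p_high: float = 99.9
) -> np.ndarray:
    """Affine intensity normalization to [0, 1].

    ``percentile`` mode maps the 0.1 / 99.9 percentiles to 0 / 1 and clips
    (robust to isolated hot pixels); ``minmax`` maps the extrema.  Constant
    images are rejected (the affine map is undefined).  Invariant under
    positive affine rescaling of the input.
    """
    img = np.asarray(image, dtype=float)
    if mode == "percentile":
        lo, hi = np.percentile(img, [p_low, p_high])
    elif mode == "minmax":
        lo, hi = float(img.min()), float(img.max())
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if hi <= lo:
        raise DegenerateImageError("constant image: affine normalization undefined")
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def _valid_centers(mask: np.ndarray, side: int) -> np.ndarray:
    """Boolean map of centers whose (side x side) square lies fully in mask."""
    # minimum_filter == binary erosion by the square footprint
    return ndimage.minimum_filter(mask.astype(np.uint8), size=side, mode="constant", cval=0) > 0


def sample_roi_pairs(
    labelmap: SectionLabelMap,
    n: int = 50,
    roi_side_px: int = 11,
    min_separation_px: float = 25.0,
    max_pair_distance_px: float = 40.0,
    seed: int = 0,
) -> list[RoiPair]:
    """Seeded sampling of ``n`` cell/surround ROI pairs from a label map.

    Each cell square lies entirely within cytoplasm/nucleus/nucleolus, its
    paired surround square entirely within neuropil and within
    ``max_pair_distance_px`` of the cell square's center (nearest valid
    position, row-major tie-break).  Chosen cell centers are at least
    ``min_separation_px`` apart.  Deterministic per seed; raises
    :class:`SamplingError` reporting the achievable count when the map
    cannot supply ``n`` pairs.
    """
    if n == 0:
        return []
    labels = labelmap.labels
    cell_ok = _valid_centers(np.isin(labels, CELL_LABELS), roi_side_px)
    surr_ok = _valid_centers(labels == SURROUND_LABEL, roi_side_px)
    cell_centers = np.argwhere(cell_ok)
    if cell_centers.shape[0] == 0:
        raise SamplingError(f"requested {n} pairs, achievable 0 (no eligible cell ROI)")

    rng = np.random.default_rng(seed)
    order = rng.permutation(cell_centers.shape[0])
    chosen: list[tuple[int, int]] = []
    pairs: list[RoiPair] = []
    surr_coords = np.argwhere(surr_ok)
    for idx in order:
        if len(pairs) >= n:
            break
        r, c = map(int, cell_centers[idx])
        if any((r - r2) ** 2 + (c - c2) ** 2 < min_separation_px**2 for r2, c2 in chosen):
            continue
        d2 = (surr_coords[:, 0] - r) ** 2 + (surr_coords[:, 1] - c) ** 2
        within = np.nonzero(d2 <= max_pair_distance_px**2)[0]
        if within.size == 0:
            continue
        best = within[np.argmin(d2[within])]  # argmin is row-major-first on ties
        sr, sc = map(int, surr_coords[best])
        pairs.append(RoiPair.from_squares(len(pairs), (r, c), (sr, sc), roi_side_px))
        chosen.append((r, c))
    if len(pairs) < n:
        raise SamplingError(f"requested {n} pairs, achievable {len(pairs)}")
    return pairs


def measure_contrast(
    image: np.ndarray, pairs: list[RoiPair], formula: str = "ratio"
) -> ContrastEstimate:
    """Per-pair contrast of mean region brightnesses, aggregated.

    ``ratio``: brighter mean / darker mean (>= 1); ``michelson``:
    ``(hi - lo) / (hi + lo)``.  Pairs whose darker mean is exactly 0 are
    excluded and counted in ``n_excluded``.  The estimate is the mean and
    standard deviation over pairs (per-pair averaging, not pooled pixels).
    """
    img = np.asarray(image, dtype=float)
    values = []
    n_excluded = 0
    for p in pairs:
        m_cell = float(img[p.cell_pixels[:, 0], p.cell_pixels[:, 1]].mean())
        m_surr = float(img[p.surround_pixels[:, 0], p.surround_pixels[:, 1]].mean())
        hi, lo = max(m_cell, m_surr), min(m_cell, m_surr)
        if formula == "ratio":
            if lo == 0:
                n_excluded += 1
                continue
            values.append(hi / lo)
        elif formula == "michelson":
            if hi + lo == 0:
                n_excluded += 1
                continue
            values.append((hi - lo) / (hi + lo))
        else:
            raise ValueError(f"unknown contrast formula {formula!r}")
    if not values:
        raise SamplingError("no measurable pair (all pairs degenerate or empty input)")
    arr = np.asarray(values)
    return ContrastEstimate(
        per_pair=arr,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        n=int(arr.size),
        n_excluded=n_excluded,
        formula=formula,
    )


# ---------------------------------------------------------------------------
# ROI CSV interchange: pair_id,role,x,y (0-based pixel coordinates, row-major;
# x = column, y = row)
# ---------------------------------------------------------------------------

def write_roi_csv(pairs: list[RoiPair], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pair_id", "role", "x", "y"])
        for p in pairs:
            for r, c in p.cell_pixels:
                writer.writerow([p.pair_id, "cell", c, r])
            for r, c in p.surround_pixels:
                writer.writerow([p.pair_id, "surround", c, r])


def read_roi_csv(path: str | Path) -> list[RoiPair]:
    by_pair: dict[int, dict[str, list[tuple[int, int]]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        expected = {"pair_id", "role", "x", "y"}
        if reader.fieldnames is None or set(reader.fieldnames) != expected:
            raise ValueError(f"ROI CSV must have columns {sorted(expected)}")
        for row in reader:
            pid = int(row["pair_id"])
            by_pair.setdefault(pid, {"cell": [], "surround": []})[row["role"]].append(
                (int(row["y"]), int(row["x"]))
            )
    return [
        RoiPair(pid, np.array(d["cell"]), np.array(d["surround"]))
        for pid, d in sorted(by_pair.items())
    ]
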