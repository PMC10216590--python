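"""Cell/surround contrast of the OMLIT stack and configuration sweeps.

The imaging configuration is a stack of (top to bottom): stained ultrathin
section, optional metal coating, polycarbonate carrier tape, conductive
carbon tape, silicon wafer, illuminated from air.  Two variants of the
stack are evaluated that differ only in the section material — a stained
cell body versus the surrounding stained neuropil — and the contrast is
the ratio of the brighter to the darker reflectance,

    C = max(R_cell, R_surround) / min(R_cell, R_surround)  >= 1.

(Michelson contrast ``(R_hi - R_lo)/(R_hi + R_lo)`` is available as an
alternative formula.)  Sweeping C over section thickness, coating thickness
and LED wavelength maps the design space; the report lists, per coating
material and wavelength, the optimum and the smallest coating thickness
reaching 95% of it.

Because the reflectances of the two stacks are thin-film interference
signals, C oscillates with section thickness with a period of
``lambda / (2 n cos(theta))`` — the reason thicker sections can still show
good contrast at longer wavelengths.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .materials import MaterialLibrary
from .tmm import Illumination, Layer, LayerStack, reflectance_grid, stack_reflectance

__all__ = [
    "Coating",
    "OmlitConfig",
    "ContrastValue",
    "SweepResult",
    "DegenerateContrastError",
    "InsufficientDataError",
    "build_stacks",
    "contrast",
    "contrast_from_reflectances",
    "sweep",
    "optimum_report",
    "format_report_text",
    "estimate_period",
    "PeriodEstimate",
    "DEFAULT_WAVELENGTHS_NM",
    "default_section_grid",
    "default_coating_grid",
]

#: The four LED lines of the reference microscope.
DEFAULT_WAVELENGTHS_NM = (390.0, 470.0, 555.0, 630.0)

#: Default LED spectral width for sweeps.  A real LED line has a finite
#: band; band-averaging also keeps the ratio contrast bounded (a strictly
#: monochromatic model has unbounded ratio wherever a reflectance crosses 0),
#: so sweep optima are well-posed.
DEFAULT_LED_FWHM_NM = 25.0


def default_section_grid(step_nm: float = 5.0) -> np.ndarray:
    """Section thickness grid, 10-300 nm (covers ultrathin and thick sections)."""
    return np.arange(10.0, 300.0 + step_nm / 2, step_nm)


def default_coating_grid(step_nm: float = 5.0) -> np.ndarray:
    """Coating thickness grid, 10-400 nm."""
    return np.arange(10.0, 400.0 + step_nm / 2, step_nm)


class DegenerateContrastError(ZeroDivisionError):
    """Contrast undefined because the darker reflectance is 0."""


class InsufficientDataError(ValueError):
    """Trace does not contain enough oscillations to estimate a period."""


@dataclass(frozen=True)
class Coating:
    material: str
    thickness_nm: float


@dataclass(frozen=True)
class OmlitConfig:
    """One imaging configuration (stack geometry + material roles).

    ``coating=None`` encodes the coating-free scheme.  Tape and carbon tape
    default to incoherent (their thickness exceeds the LED coherence
    length); the section and coating are coherent thin films.
    """

    section_thickness_nm: float = 60.0
    coating: Coating | None = None
    tape_material: str = "polycarbonate_tape"
    tape_thickness_nm: float = 50_000.0
    carbon_tape_material: str = "carbon_tape"
    carbon_tape_thickness_nm: float = 100_000.0
    substrate: str = "silicon"
    incident_medium: str = "air"
    cell_material: str = "stained_cell"
    surround_material: str = "stained_tissue"
    tape_coherence: str = "incoherent"
    carbon_tape_coherence: str = "incoherent"

    def __post_init__(self) -> None:
        for name in ("section_thickness_nm", "tape_thickness_nm", "carbon_tape_thickness_nm"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.coating is not None and self.coating.thickness_nm < 0:
            raise ValueError("coating thickness must be >= 0")


@dataclass(frozen=True)
class ContrastValue:
    """Contrast plus the two reflectances and the snapshots that produced it."""

    contrast: float
    R_cell: float
    R_surround: float
    config: OmlitConfig
    illumination: Illumination
    formula: str = "ratio"


@dataclass
class SweepResult:
    """Dense contrast grid over (wavelength x section x coating thickness)."""

    coating_material: str | None
    wavelengths_nm: np.ndarray
    section_nm: np.ndarray
    coating_nm: np.ndarray
    contrast: np.ndarray  # shape (W, S, C)
    R_cell: np.ndarray
    R_surround: np.ndarray
    fraction: float = 0.95
    argmax: tuple = field(init=False)
    fraction_thickness_nm: float = field(init=False)

    def __post_init__(self) -> None:
        w, s, c = np.unravel_index(int(np.argmax(self.contrast)), self.contrast.shape)
        self.argmax = (
            float(self.wavelengths_nm[w]),
            float(self.section_nm[s]),
            float(self.coating_nm[c]),
            float(self.contrast[w, s, c]),
        )
        best_per_coating = self.contrast.max(axis=(0, 1))
        c_max = self.argmax[3]
        ok = np.nonzero(best_per_coating >= self.fraction * c_max)[0]
        self.fraction_thickness_nm = float(self.coating_nm[ok[0]])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table ``wavelength_nm,section_nm,coating_nm,contrast,R_cell,R_surround``."""
        w, s, c = np.meshgrid(
            self.wavelengths_nm, self.section_nm, self.coating_nm, indexing="ij"
        )
        return pd.DataFrame(
            {
                "wavelength_nm": w.ravel(),
                "section_nm": s.ravel(),
                "coating_nm": c.ravel(),
                "contrast": self.contrast.ravel(),
                "R_cell": self.R_cell.ravel(),
                "R_surround": self.R_surround.ravel(),
            }
        )

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        wl, sec, coat, cmax = self.argmax
        return {
            "coating_material": self.coating_material,
            "best_contrast": cmax,
            "wavelength_nm": wl,
            "section_nm": sec,
            "coating_nm": coat,
            "fraction": self.fraction,
            "fraction_thickness_nm": self.fraction_thickness_nm,
        }

    def save_heatmaps(self, out_dir: str | Path, cmap: str = "viridis") -> list[Path]:
        """One contrast heatmap PNG per wavelength (coating x section axes)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for wi, wl in enumerate(self.wavelengths_nm):
            fig, ax = plt.subplots(figsize=(5, 4))
            im = ax.pcolormesh(
                self.coating_nm, self.section_nm, self.contrast[wi], cmap=cmap, shading="auto"
            )
            si, ci = np.unravel_index(int(np.argmax(self.contrast[wi])), self.contrast[wi].shape)
            ax.plot(self.coating_nm[ci], self.section_nm[si], "r.", ms=10)
            ax.set_xlabel("coating thickness (nm)")
            ax.set_ylabel("section thickness (nm)")
            label = self.coating_material or "no coating"
            ax.set_title(f"{label}, {wl:g} nm, max C = {self.contrast[wi].max():.3f}")
            fig.colorbar(im, ax=ax, label="contrast")
            p = out_dir / f"contrast_{label}_{wl:g}nm.png"
            fig.savefig(p, dpi=120, bbox_inches="tight")
            plt.close(fig)
            paths.append(p)
        return paths


# ---------------------------------------------------------------------------

def build_stacks(config: OmlitConfig) -> tuple[LayerStack, LayerStack]:
    """The (cell, surround) stack pair: identical except the section material."""

    def stack_for(section_material: str) -> LayerStack:
        layers = [Layer(section_material, config.section_thickness_nm, "coherent")]
        if config.coating is not None:
            layers.append(Layer(config.coating.material, config.coating.thickness_nm, "coherent"))
        layers.append(Layer(config.tape_material, config.tape_thickness_nm, config.tape_coherence))
        layers.append(
            Layer(
                config.carbon_tape_material,
                config.carbon_tape_thickness_nm,
                config.carbon_tape_coherence,
            )
        )
        return LayerStack(
            incident_medium=config.incident_medium,
            layers=tuple(layers),
            substrate=config.substrate,
        )

    return stack_for(config.cell_material), stack_for(config.surround_material)


def contrast_from_reflectances(
    R_cell: float, R_surround: float, formula: str = "ratio"
) -> float:
    """Contrast of two reflectances; ``ratio`` (>= 1) or ``michelson`` ([0, 1))."""
    hi, lo = max(R_cell, R_surround), min(R_cell, R_surround)
    if formula == "ratio":
        if lo <= 0:
            raise DegenerateContrastError("darker reflectance is 0: ratio contrast undefined")
        return hi / lo
    if formula == "michelson":
        if hi + lo <= 0:
            raise DegenerateContrastError("both reflectances are 0")
        return (hi - lo) / (hi + lo)
    raise ValueError(f"unknown contrast formula {formula!r}")


def contrast(
    config: OmlitConfig,
    illum: Illumination,
    lib: MaterialLibrary,
    formula: str = "ratio",
) -> ContrastValue:
    """Model contrast between the cell and surround stacks under ``illum``."""
    stack_cell, stack_surround = build_stacks(config)
    R_cell = stack_reflectance(stack_cell, illum, lib).R
    R_surround = stack_reflectance(stack_surround, illum, lib).R
    return ContrastValue(
        contrast=contrast_from_reflectances(R_cell, R_surround, formula),
        R_cell=R_cell,
        R_surround=R_surround,
        config=config,
        illumination=illum,
        formula=formula,
    )


def sweep(
    config_template: OmlitConfig,
    section_grid_nm,
    coating_grid_nm,
    wavelengths_nm,
    illum_template: Illumination | None = None,
    lib: MaterialLibrary | None = None,
    formula: str = "ratio",
    fraction: float = 0.95,
) -> SweepResult:
    """Contrast over the (wavelength x section x coating) grid.

    For the coating-free template the coating axis degenerates to the
    single value 0.  Deterministic; evaluated vectorized through the
    transfer-matrix engine.  When no illumination template is given, each
    wavelength is an LED line with ``DEFAULT_LED_FWHM_NM`` Gaussian band
    (band-averaged reflectances); pass a template with
    ``spectral_fwhm_nm=0`` for a strictly monochromatic sweep.
    """
    if lib is None:
        raise ValueError("a material library is required")
    section_grid_nm = np.asarray(sorted(section_grid_nm), dtype=float)
    wavelengths_nm = np.asarray(sorted(wavelengths_nm), dtype=float)
    if config_template.coating is None:
        coating_grid_nm = np.array([0.0])
    else:
        coating_grid_nm = np.asarray(sorted(coating_grid_nm), dtype=float)
    if section_grid_nm.size == 0 or coating_grid_nm.size == 0 or wavelengths_nm.size == 0:
        raise ValueError("sweep grids must be non-empty")
    if illum_template is None:
        illum_template = Illumination(
            wavelength_nm=float(wavelengths_nm[0]), spectral_fwhm_nm=DEFAULT_LED_FWHM_NM
        )

    # Representative config: coating thickness is overridden per grid point.
    if config_template.coating is not None:
        config0 = replace(
            config_template, coating=replace(config_template.coating, thickness_nm=0.0)
        )
        coating_index = 1
    else:
        config0 = config_template
        coating_index = None
    stack_cell, stack_surround = build_stacks(config0)

    W, S, C = wavelengths_nm.size, section_grid_nm.size, coating_grid_nm.size
    R_cell = np.empty((W, S, C))
    R_surround = np.empty((W, S, C))
    overrides = {0: section_grid_nm[:, None]}
    if coating_index is not None:
        overrides[coating_index] = coating_grid_nm[None, :]
    for wi, wl in enumerate(wavelengths_nm):
        illum = replace(illum_template, wavelength_nm=float(wl))
        rc = reflectance_grid(stack_cell, illum, lib, overrides)
        rs = reflectance_grid(stack_surround, illum, lib, overrides)
        R_cell[wi] = np.broadcast_to(rc, (S, C))
        R_surround[wi] = np.broadcast_to(rs, (S, C))

    hi = np.maximum(R_cell, R_surround)
    lo = np.minimum(R_cell, R_surround)
    if formula == "ratio":
        if np.any(lo <= 0):
            raise DegenerateContrastError("darker reflectance is 0 somewhere on the grid")
        cgrid = hi / lo
    elif formula == "michelson":
        cgrid = (hi - lo) / (hi + lo)
    else:
        raise ValueError(f"unknown contrast formula {formula!r}")

    return SweepResult(
        coating_material=None if config_template.coating is None else config_template.coating.material,
        wavelengths_nm=wavelengths_nm,
        section_nm=section_grid_nm,
        coating_nm=coating_grid_nm,
        contrast=cgrid,
        R_cell=R_cell,
        R_surround=R_surround,
        fraction=fraction,
    )


def optimum_report(sweeps: dict[str, SweepResult], fraction: float = 0.95) -> pd.DataFrame:
    """Per-(coating material, wavelength) optimum table.

    One row per material and wavelength: the best contrast over the
    (section, coating) grid, where it occurs, and the smallest coating
    thickness whose best-over-section contrast reaches ``fraction`` of the
    row optimum (the "95%-of-optimum" coating thickness).  Rows sorted by
    material then wavelength.
    """
    if not sweeps:
        raise ValueError("no sweeps given")
    wavelength_sets = {tuple(s.wavelengths_nm.tolist()) for s in sweeps.values()}
    if len(wavelength_sets) != 1:
        raise ValueError("all sweeps must share the same wavelength set")
    rows = []
    for material in sorted(sweeps):
        res = sweeps[material]
        for wi, wl in enumerate(res.wavelengths_nm):
            grid = res.contrast[wi]  # (S, C)
            si, ci = np.unravel_index(int(np.argmax(grid)), grid.shape)
            row_opt = float(grid[si, ci])
            best_per_coating = grid.max(axis=0)
            ok = np.nonzero(best_per_coating >= fraction * row_opt)[0]
            rows.append(
                {
                    "coating_material": material,
                    "wavelength_nm": float(wl),
                    "best_contrast": row_opt,
                    "tissue_thickness_nm": float(res.section_nm[si]),
                    "coating_thickness_nm": float(res.coating_nm[ci]),
                    "fraction_thickness_nm": float(res.coating_nm[ok[0]]),
                }
            )
    df = pd.DataFrame(rows).sort_values(
        ["coating_material", "wavelength_nm"], kind="stable", ignore_index=True
    )
    return df


def format_report_text(report: pd.DataFrame, fraction: float = 0.95) -> str:
    """Pretty fixed-width report; the coating column shows the
    ``<optimum> (<f%-of-optimum>) *`` parenthetical when the latter is smaller."""
    lines = [
        f"{'Coating Material':<18}{'Best Contrast':>14}  {'Wavelength':>10}  "
        f"{'Tissue Thickness':>17}  {'Coating Thickness':>18}"
    ]
    starred = False
    prev_material = None
    for _, row in report.iterrows():
        coat = f"{row.coating_thickness_nm:g}"
        if row.fraction_thickness_nm < row.coating_thickness_nm:
            coat = f"{coat} ({row.fraction_thickness_nm:g}) *"
            starred = True
        material = row.coating_material if row.coating_material != prev_material else ""
        prev_material = row.coating_material
        lines.append(
            f"{material:<18}{row.best_contrast:>14.4f}  {row.wavelength_nm:>10g}  "
            f"{row.tissue_thickness_nm:>17g}  {coat:>18}"
        )
    if starred:
        lines.append(
            f"* The coating thickness corresponding to the {fraction:.0%} optimum "
            "contrast is shown in parentheses."
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeriodEstimate:
    period_nm: float
    peak_positions_nm: np.ndarray


def estimate_period(
    thickness_nm, values, min_prominence_frac: float = 0.05
) -> PeriodEstimate:
    """Dominant oscillation period of a contrast-vs-thickness trace.

    Local maxima are detected with a prominence threshold of
    ``min_prominence_frac`` of the trace's peak-to-peak amplitude, refined
    by parabolic interpolation, and the period is the mean peak-to-peak
    spacing.  Requires at least two detected peaks (>= 2 oscillations).
    """
    thickness_nm = np.asarray(thickness_nm, dtype=float)
    values = np.asarray(values, dtype=float)
    if thickness_nm.ndim != 1 or thickness_nm.shape != values.shape:
        raise ValueError("thickness and values must be equal-length 1-D arrays")
    amp = float(values.max() - values.min())
    if amp <= 0:
        raise InsufficientDataError("constant trace: no oscillation to measure")
    peaks, _ = find_peaks(values, prominence=min_prominence_frac * amp)
    if peaks.size < 2:
        raise InsufficientDataError(
            f"found {peaks.size} peak(s); need >= 2 oscillations in the trace"
        )
    positions = []
    for p in peaks:
        if 0 < p < values.size - 1:
            y0, y1, y2 = values[p - 1 : p + 2]
            denom = y0 - 2 * y1 + y2
            shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
            shift = float(np.clip(shift, -0.5, 0.5))
            step = thickness_nm[p + 1] - thickness_nm[p] if shift >= 0 else thickness_nm[p] - thickness_nm[p - 1]
            positions.append(thickness_nm[p] + shift * abs(step))
        else:
            positions.append(thickness_nm[p])
    positions = np.asarray(positions)
    period = float(np.mean(np.diff(positions)))
    return PeriodEstimate(period_nm=period, peak_positions_nm=positions)


def save_summary_json(sweeps: dict[str, SweepResult], report: pd.DataFrame, path: str | Path) -> None:
    """JSON summary: per-sweep argmax plus the report rows."""
    doc = {
        "schema": "omlit-sweep-summary/1",
        "sweeps": {m or "none": s.summary() for m, s in sweeps.items()},
        "report": report.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")
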