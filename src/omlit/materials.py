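"""Material optical constants: storage, validation, interpolation and I/O.

A material is described by a dispersion table ``(wavelength_nm, n, k)``
sampled at strictly increasing wavelengths; between samples ``n`` and ``k``
are each linearly interpolated.  The global sign convention is
``ñ = n + i·k`` with ``k > 0`` meaning absorption.  No extrapolation is
ever performed: querying outside a material's sampled range is an error.

The bundled default library covers every medium of the OMLIT stack
(air / stained section / metal coating / polycarbonate tape / carbon tape /
silicon) over at least 380–650 nm.  Metal and silicon values come from
standard published dispersion data; stained tissue, stained cell, resin and
carbon tape are documented synthetic placeholders (see each entry's
provenance note) because measured constants for those media are not
publicly available.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "OpticalConstants",
    "MaterialLibrary",
    "LibraryParseError",
    "LibraryValidationError",
    "CoverageError",
    "UnknownMaterialError",
    "load_library",
    "write_library",
    "default_library",
    "REQUIRED_DEFAULT_MATERIALS",
]

#: Materials the bundled default library must provide.
REQUIRED_DEFAULT_MATERIALS = (
    "air",
    "silicon",
    "polycarbonate_tape",
    "carbon_tape",
    "silver",
    "chromium",
    "copper",
    "stained_tissue",
    "stained_cell",
)

#: Wavelength range (nm) every bundled material must cover.
DEFAULT_COVERAGE_NM = (390.0, 630.0)


class LibraryParseError(ValueError):
    """A material file could not be parsed (malformed row, bad header...)."""


class LibraryValidationError(ValueError):
    """Parsed data violates a library invariant (ordering, duplicates...)."""


class UnknownMaterialError(KeyError):
    """Requested material id is not in the library."""


class CoverageError(ValueError):
    """Wavelength outside a material's sampled range (no extrapolation)."""


@dataclass(frozen=True)
class OpticalConstants:
    """Dispersion table of one material.

    Parameters
    ----------
    material_id : str
        Short identifier, e.g. ``"silver"``.
    wavelengths_nm, n, k : ndarray
        Equal-length 1-D arrays; wavelengths strictly increasing,
        ``n > 0`` and ``k >= 0`` everywhere.
    provenance : str
        Free-text source note.
    """

    material_id: str
    wavelengths_nm: np.ndarray
    n: np.ndarray
    k: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        n = np.asarray(self.n, dtype=float)
        k = np.asarray(self.k, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise LibraryValidationError(
                f"{self.material_id}: need at least one (wavelength, n, k) sample"
            )
        if n.shape != wl.shape or k.shape != wl.shape:
            raise LibraryValidationError(f"{self.material_id}: ragged sample arrays")
        if not np.all(np.diff(wl) > 0):
            raise LibraryValidationError(
                f"{self.material_id}: wavelengths must be strictly increasing"
            )
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(n)) and np.all(np.isfinite(k))):
            raise LibraryValidationError(f"{self.material_id}: non-finite sample")
        if np.any(n <= 0):
            raise LibraryValidationError(f"{self.material_id}: n must be > 0")
        if np.any(k < 0):
            raise LibraryValidationError(f"{self.material_id}: k must be >= 0")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "k", k)

    @property
    def range_nm(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def complex_index(self, wavelength_nm: float) -> complex:
        """ñ = n + i·k at ``wavelength_nm``, linearly interpolated.

        Exact at tabulated wavelengths; raises :class:`CoverageError`
        outside the sampled range.
        """
        lo, hi = self.range_nm
        if not (lo <= wavelength_nm <= hi):
            raise CoverageError(
                f"{self.material_id}: wavelength {wavelength_nm} nm outside "
                f"sampled range [{lo}, {hi}] nm (no extrapolation)"
            )
        n = float(np.interp(wavelength_nm, self.wavelengths_nm, self.n))
        k = float(np.interp(wavelength_nm, self.wavelengths_nm, self.k))
        return complex(n, k)


class MaterialLibrary:
    """Mapping ``material_id -> OpticalConstants`` with validated entries."""

    def __init__(self, entries: dict[str, OpticalConstants] | list[OpticalConstants]):
        if not isinstance(entries, dict):
            entries = {e.material_id: e for e in entries}
        for mid, entry in entries.items():
            if mid != entry.material_id:
                raise LibraryValidationError(
                    f"key {mid!r} does not match entry id {entry.material_id!r}"
                )
        self._entries: dict[str, OpticalConstants] = dict(entries)

    # -- mapping-ish surface -------------------------------------------------
    def __contains__(self, material_id: str) -> bool:
        return material_id in self._entries

    def __getitem__(self, material_id: str) -> OpticalConstants:
        try:
            return self._entries[material_id]
        except KeyError:
            raise UnknownMaterialError(
                f"unknown material {material_id!r}; known: {sorted(self._entries)}"
            ) from None

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def material_ids(self) -> list[str]:
        return sorted(self._entries)

    def complex_index(self, material_id: str, wavelength_nm: float) -> complex:
        """Complex refractive index ñ = n + i·k of ``material_id``."""
        return self[material_id].complex_index(wavelength_nm)

    def with_entry(self, entry: OpticalConstants) -> "MaterialLibrary":
        """New library with ``entry`` added or replaced."""
        entries = dict(self._entries)
        entries[entry.material_id] = entry
        return MaterialLibrary(entries)


# ---------------------------------------------------------------------------
# File I/O.  CSV dialect: header ``material_id,wavelength_nm,n,k``, UTF-8,
# '.' decimal separator, '#' comment lines; a ``# provenance <id>: note``
# comment attaches a source note.  The JSON mirror is
# ``{"materials": [{"material_id", "provenance", "samples": [[wl, n, k], ...]}]}``.
# ---------------------------------------------------------------------------

_CSV_HEADER = ["material_id", "wavelength_nm", "n", "k"]
_PROVENANCE_PREFIX = "# provenance "


def _build_library(
    rows: list[tuple[int, str, float, float, float]],
    provenance: dict[str, str],
) -> MaterialLibrary:
    by_material: dict[str, list[tuple[int, float, float, float]]] = {}
    order: list[str] = []
    for lineno, mid, wl, n, k in rows:
        if mid not in by_material:
            by_material[mid] = []
            order.append(mid)
        by_material[mid].append((lineno, wl, n, k))
    entries = {}
    for mid in order:
        samples = by_material[mid]
        wls = [s[1] for s in samples]
        if len(set(wls)) != len(wls):
            dupes = sorted({w for w in wls if wls.count(w) > 1})
            raise LibraryValidationError(
                f"{mid}: duplicate wavelength rows at {dupes} nm"
            )
        entries[mid] = OpticalConstants(
            material_id=mid,
            wavelengths_nm=np.array(wls),
            n=np.array([s[2] for s in samples]),
            k=np.array([s[3] for s in samples]),
            provenance=provenance.get(mid, ""),
        )
    return MaterialLibrary(entries)


def _parse_csv(text: str, source: str) -> MaterialLibrary:
    provenance: dict[str, str] = {}
    data_lines: list[tuple[int, str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            if stripped.startswith(_PROVENANCE_PREFIX) and ":" in stripped:
                head, _, note = stripped[len(_PROVENANCE_PREFIX):].partition(":")
                provenance[head.strip()] = note.strip()
            continue
        data_lines.append((lineno, line))
    if not data_lines:
        raise LibraryParseError(f"{source}: no data rows")
    header_lineno, header_line = data_lines[0]
    header = next(csv.reader([header_line]))
    if [h.strip() for h in header] != _CSV_HEADER:
        raise LibraryParseError(
            f"{source}:{header_lineno}: expected header {','.join(_CSV_HEADER)!r}, "
            f"got {header_line.strip()!r}"
        )
    rows: list[tuple[int, str, float, float, float]] = []
    for lineno, line in data_lines[1:]:
        fields = next(csv.reader([line]))
        if len(fields) != 4:
            raise LibraryParseError(
                f"{source}:{lineno}: expected 4 fields, got {len(fields)}"
            )
        mid = fields[0].strip()
        if not mid:
            raise LibraryParseError(f"{source}:{lineno}: empty material_id")
        try:
            wl, n, k = (float(fields[i]) for i in (1, 2, 3))
        except ValueError as exc:
            raise LibraryParseError(f"{source}:{lineno}: {exc}") from None
        rows.append((lineno, mid, wl, n, k))
    return _build_library(rows, provenance)


def _parse_json(text: str, source: str) -> MaterialLibrary:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise LibraryParseError(f"{source}: {exc}") from None
    try:
        materials = doc["materials"]
        rows = []
        provenance = {}
        for i, mat in enumerate(materials):
            mid = mat["material_id"]
            provenance[mid] = mat.get("provenance", "")
            for j, (wl, n, k) in enumerate(mat["samples"]):
                rows.append((i, mid, float(wl), float(n), float(k)))
    except (KeyError, TypeError, ValueError) as exc:
        raise LibraryParseError(f"{source}: malformed library JSON ({exc})") from None
    return _build_library(rows, provenance)


def load_library(path: str | Path) -> MaterialLibrary:
    """Load a material library from a ``.csv`` or ``.json`` file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return _parse_json(text, str(path))
    return _parse_csv(text, str(path))


def _format_float(x: float) -> str:
    # repr() is the shortest string that round-trips the double exactly,
    # which is what makes write->load->write a fixed point.
    return repr(float(x))


def write_library(lib: MaterialLibrary, path: str | Path) -> None:
    """Write ``lib`` to ``path`` (dialect chosen from the file extension).

    ``load_library(write_library(lib, p))`` reproduces every sample
    bit-for-bit (floats serialized via shortest round-trip repr).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "materials": [
                {
                    "material_id": mid,
                    "provenance": lib[mid].provenance,
                    "samples": [
                        [float(w), float(n), float(k)]
                        for w, n, k in zip(lib[mid].wavelengths_nm, lib[mid].n, lib[mid].k)
                    ],
                }
                for mid in lib.material_ids
            ]
        }
        path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
        return
    buf = io.StringIO()
    for mid in lib.material_ids:
        if lib[mid].provenance:
            buf.write(f"{_PROVENANCE_PREFIX}{mid}: {lib[mid].provenance}\n")
    buf.write(",".join(_CSV_HEADER) + "\n")
    for mid in lib.material_ids:
        entry = lib[mid]
        for w, n, k in zip(entry.wavelengths_nm, entry.n, entry.k):
            buf.write(f"{mid},{_format_float(w)},{_format_float(n)},{_format_float(k)}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def default_library() -> MaterialLibrary:
    """The bundled default library (see module docstring for provenance)."""
    text = (
        resources.files("omlit").joinpath("data/default_materials.csv").read_text("utf-8")
    )
    lib = _parse_csv(text, "omlit/data/default_materials.csv")
    for mid in REQUIRED_DEFAULT_MATERIALS:
        lo, hi = lib[mid].range_nm
        if lo > DEFAULT_COVERAGE_NM[0] or hi < DEFAULT_COVERAGE_NM[1]:
            raise LibraryValidationError(
                f"bundled {mid} covers [{lo}, {hi}] nm, needs {DEFAULT_COVERAGE_NM}"
            )
    return lib
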