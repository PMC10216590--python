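"""Reflectance of planar multilayers by the characteristic-matrix method.

The optical response of a stack of plane-parallel films between two
semi-infinite media is computed with the standard thin-film formalism:
each coherent layer contributes a 2x2 characteristic matrix

    M = [[cos d,        i sin d / eta],
         [i eta sin d,  cos d       ]],

where ``d = 2*pi*n~*t*cos(theta)/lambda`` is the (complex) phase thickness
and ``eta`` the optical admittance (``n~ cos(theta)`` for s-polarization,
``n~ / cos(theta)`` for p).  With ``(B, C)^T = (prod M_j) . (1, eta_sub)^T``
the amplitude reflectance is ``r = (eta0*B - C) / (eta0*B + C)`` and
``R = |r|^2``; the transmitted intensity is ``T = 4*eta0*Re(eta_sub) /
|eta0*B + C|^2`` and the absorptance ``A = 1 - R - T``.

Layers much thicker than the source coherence length (e.g. the 50 um
polycarbonate tape under an LED) are flagged *incoherent*: their phase is
physically scrambled, so the stack reflectance is the uniform average of
the coherent result over that layer's phase.  The average is evaluated
numerically with a fixed number of equally spaced phase samples over one
period (default 64), which reproduces the textbook incoherent-summation
closed form to better than 1e-6.

An independent oracle, :func:`reflectance_recursive`, computes the same
reflectance by bottom-up recursion of interface Fresnel amplitude
coefficients written in terms of normal wavevector components (a Parratt
recursion) and never touches the matrix formalism; the two routes are
cross-checked in the test suite.

Sign conventions: ``n~ = n + i*k`` with ``k > 0`` meaning absorption;
branch cuts are chosen so waves decay into absorbing media
(``Im(n~ cos(theta)) >= 0``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .materials import MaterialLibrary

__all__ = [
    "Layer",
    "LayerStack",
    "Illumination",
    "ReflectanceResult",
    "DegenerateGeometryError",
    "UnsupportedInputError",
    "IlluminationError",
    "refraction_angle",
    "admittance",
    "characteristic_matrix",
    "stack_reflectance",
    "reflectance_recursive",
    "incoherent_combine",
    "spectral_angular_average",
    "reflectance_grid",
    "gaussian_band_nodes",
    "aperture_nodes",
]

# -- numerical policy (fixed, documented defaults) --------------------------
#: Phase samples per incoherent layer for the uniform phase average.
PHASE_SAMPLES = 64
#: Im(delta) above which a layer is opaque: the back-reflected wave is
#: attenuated by exp(-2*300) ~ 1e-260, so its phase is irrelevant and the
#: transmitted intensity is 0 to double precision.
OPAQUE_IM_DELTA = 300.0
#: Im(delta) above which phase-averaging an incoherent layer is skipped
#: (round-trip attenuation exp(-2*10) < 3e-9: no interference to average).
PHASE_AVERAGE_SKIP_IM_DELTA = 10.0
#: Quadrature nodes for the Gaussian spectral average over +/- 2*FWHM.
SPECTRAL_NODES = 17
#: Gauss-Legendre order for the angular (numerical-aperture) average.
ANGULAR_NODES = 8
#: Tolerance on k of the incident medium ("lossless" model assumption).
INCIDENT_K_TOL = 1e-12


class DegenerateGeometryError(ValueError):
    """Grazing/degenerate geometry (cos(theta) = 0) for a p-admittance."""


class UnsupportedInputError(ValueError):
    """Operation does not support this input (e.g. incoherent layer in oracle)."""


class IlluminationError(ValueError):
    """Invalid illumination parameters (angle, NA, polarization...)."""


@dataclass(frozen=True)
class Layer:
    """One film: material id, thickness in nm, coherence flag."""

    material: str
    thickness_nm: float
    coherence: str = "coherent"  # "coherent" | "incoherent"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.thickness_nm) and self.thickness_nm >= 0):
            raise ValueError(f"layer thickness must be finite and >= 0, got {self.thickness_nm}")
        if self.coherence not in ("coherent", "incoherent"):
            raise ValueError(f"coherence must be 'coherent' or 'incoherent', got {self.coherence!r}")


@dataclass(frozen=True)
class LayerStack:
    """Semi-infinite incident medium / ordered films (top->bottom) / substrate."""

    incident_medium: str
    layers: tuple[Layer, ...]
    substrate: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))


@dataclass(frozen=True)
class Illumination:
    """Monochromatic (or narrow-band) illumination geometry.

    ``spectral_fwhm_nm > 0`` and/or ``numerical_aperture > 0`` request
    band/cone averaging (see :func:`spectral_angular_average`); both at 0
    describe a strictly monochromatic plane wave.
    """

    wavelength_nm: float
    angle_deg: float = 0.0
    polarization: str = "unpolarized"  # "s" | "p" | "unpolarized"
    spectral_fwhm_nm: float = 0.0
    numerical_aperture: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle_deg < 90.0:
            raise IlluminationError(f"angle_deg must be in [0, 90), got {self.angle_deg}")
        if self.polarization not in ("s", "p", "unpolarized"):
            raise IlluminationError(f"bad polarization {self.polarization!r}")
        if self.spectral_fwhm_nm < 0:
            raise IlluminationError("spectral_fwhm_nm must be >= 0")
        if not 0.0 <= self.numerical_aperture < 1.0:
            raise IlluminationError(
                f"numerical_aperture must be in [0, 1), got {self.numerical_aperture}"
            )


@dataclass(frozen=True)
class ReflectanceResult:
    """Reflectance / transmittance / absorptance, total and per polarization."""

    R: float
    T: float
    A: float
    R_s: float
    R_p: float
    T_s: float
    T_p: float

    @property
    def A_s(self) -> float:
        return 1.0 - self.R_s - self.T_s

    @property
    def A_p(self) -> float:
        return 1.0 - self.R_p - self.T_p


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def _branch_cos(n: complex, cos_theta: complex) -> complex:
    """Pick the sqrt branch so the wave decays into an absorbing medium."""
    prod = n * cos_theta
    if prod.imag < 0 or (prod.imag == 0 and prod.real < 0):
        return -cos_theta
    return cos_theta


def _cos_theta_in(n0: complex, sin0: float, n: complex) -> complex:
    s = n0 * sin0 / n
    c = np.sqrt(1.0 - s * s + 0j)
    return _branch_cos(n, complex(c))


def refraction_angle(n0: complex, theta0_deg: float, nj: complex) -> complex:
    """Complex propagation angle (radians) in a medium of index ``nj``.

    Complex Snell's law ``n0 sin(theta0) = nj sin(thetaj)`` with the branch
    chosen so the refracted wave decays into an absorbing medium.  The
    incident medium must be lossless (real ``n0``).
    """
    if abs(complex(n0).imag) > INCIDENT_K_TOL:
        raise IlluminationError("incident medium must be lossless (real index)")
    sin0 = math.sin(math.radians(theta0_deg))
    c = _cos_theta_in(complex(n0).real, sin0, complex(nj))
    return complex(np.arccos(c))


def admittance(n: complex, theta: complex, pol: str) -> complex:
    """Optical admittance (free-space units): ``n cos(theta)`` (s) or ``n / cos(theta)`` (p)."""
    c = np.cos(theta)
    if pol == "s":
        return complex(n * c)
    if pol == "p":
        if abs(c) < 1e-15:
            raise DegenerateGeometryError("cos(theta) = 0: p-admittance undefined")
        return complex(n / c)
    raise IlluminationError(f"polarization must be 's' or 'p', got {pol!r}")


def characteristic_matrix(
    n: complex, thickness_nm: float, wavelength_nm: float, theta: complex, pol: str
) -> np.ndarray:
    """2x2 characteristic matrix of one coherent layer.

    ``[[cos d, i sin d / eta], [i eta sin d, cos d]]`` with phase thickness
    ``d = 2 pi n t cos(theta) / lambda``.  Unimodular (det = 1) for any
    complex ``d``.
    """
    c = np.cos(theta)
    delta = 2.0 * np.pi * n * thickness_nm * c / wavelength_nm
    eta = admittance(n, theta, pol)
    cd, sd = np.cos(delta), np.sin(delta)
    return np.array([[cd, 1j * sd / eta], [1j * eta * sd, cd]], dtype=complex)


# ---------------------------------------------------------------------------
# Stack evaluation core (vectorized over thickness grids and phase samples)
# ---------------------------------------------------------------------------

def _resolve_indices(stack: LayerStack, wavelength_nm: float, lib: MaterialLibrary):
    n0 = lib.complex_index(stack.incident_medium, wavelength_nm)
    if abs(n0.imag) > INCIDENT_K_TOL:
        raise IlluminationError(
            f"incident medium {stack.incident_medium!r} must be lossless at "
            f"{wavelength_nm} nm (k = {n0.imag})"
        )
    ns = [lib.complex_index(layer.material, wavelength_nm) for layer in stack.layers]
    n_sub = lib.complex_index(stack.substrate, wavelength_nm)
    return n0.real, ns, n_sub


def _rt_one_pol(
    n0: float,
    sin0: float,
    ns: list[complex],
    thicknesses,
    coherences: list[str],
    n_sub: complex,
    wavelength_nm: float,
    pol: str,
    phase_samples: int,
):
    """(R, T) broadcast over thickness arrays, averaged over incoherent phases.

    The characteristic matrices are evaluated in the ``n - ik`` (Macleod)
    convention — i.e. on the conjugate of the library indices — which is the
    convention the published matrix form assumes; R and T are convention-
    independent.  Decay into absorbing media then means ``Im(delta) <= 0``.
    """
    cos0 = math.sqrt(max(0.0, 1.0 - sin0 * sin0))
    eta0 = n0 * cos0 if pol == "s" else n0 / cos0

    def cos_conj(n: complex) -> complex:
        # branch with Im(n cos) <= 0: decaying wave in the n - ik convention
        s = n0 * sin0 / n
        c = complex(np.sqrt(1.0 - s * s + 0j))
        prod = n * c
        if prod.imag > 0 or (prod.imag == 0 and prod.real < 0):
            c = -c
        return c

    n_sub = np.conj(n_sub)
    cos_sub = cos_conj(n_sub)
    eta_sub = n_sub * cos_sub if pol == "s" else n_sub / cos_sub

    deltas = []
    etas = []
    for n, d in zip(ns, thicknesses):
        n = np.conj(n)
        c = cos_conj(n)
        d = np.asarray(d, dtype=float)
        deltas.append(2.0 * np.pi * n * d * c / wavelength_nm)
        etas.append(n * c if pol == "s" else n / c)

    # Phase axes for incoherent layers that actually interfere.
    avg_layers = []
    for i, (layer_coh, delta) in enumerate(zip(coherences, deltas)):
        if layer_coh != "incoherent":
            continue
        if np.all(np.asarray(thicknesses[i]) == 0):
            continue  # zero-thickness layer is a no-op regardless of flag
        if np.max(np.asarray(delta).imag) <= -PHASE_AVERAGE_SKIP_IM_DELTA:
            continue  # opaque: back-reflection annihilated, phase irrelevant
        avg_layers.append(i)

    n_phase_axes = len(avg_layers)
    if n_phase_axes:
        base_ndim = int(np.broadcast(*[np.asarray(d) for d in deltas]).ndim) if deltas else 0
        # append one trailing axis per averaged layer
        deltas = [np.asarray(d)[(...,) + (None,) * n_phase_axes] for d in deltas]
        offsets = (np.arange(phase_samples) + 0.5) * (np.pi / phase_samples)
        for axis, i in enumerate(avg_layers):
            shape = [1] * (base_ndim + n_phase_axes)
            shape[base_ndim + axis] = phase_samples
            deltas[i] = deltas[i] + offsets.reshape(shape)

    # Opaque cap: cos/sin of delta with huge |Im| would overflow; beyond
    # |Im(delta)| = 300 the layer transmits nothing, so cap and zero T there.
    opaque = np.zeros((), dtype=bool)
    capped = []
    for delta in deltas:
        delta = np.asarray(delta, dtype=complex)
        mask = delta.imag < -OPAQUE_IM_DELTA
        opaque = opaque | mask
        capped.append(np.where(mask, delta.real - 1j * OPAQUE_IM_DELTA, delta))
    deltas = capped

    # (B, C) recursion, bottom layer first, with per-step rescaling to keep
    # magnitudes O(1) (r is invariant; the scale is tracked for T).
    B = np.ones((), dtype=complex)
    C = np.asarray(eta_sub, dtype=complex)
    log_scale = np.zeros(())
    for eta, delta in zip(reversed(etas), reversed(deltas)):
        cd, sd = np.cos(delta), np.sin(delta)
        B, C = B * cd + C * (1j * sd / eta), B * (1j * eta * sd) + C * cd
        s = np.maximum(np.abs(B), np.abs(C))
        s = np.where(s == 0, 1.0, s)
        B = B / s
        C = C / s
        log_scale = log_scale + np.log(s)

    denom = eta0 * B + C
    r = (eta0 * B - C) / denom
    R = np.abs(r) ** 2
    num = 4.0 * eta0 * max(eta_sub.real, 0.0)
    with np.errstate(divide="ignore", over="ignore", under="ignore"):
        logT = np.where(num > 0, np.log(num), -np.inf) - 2.0 * np.log(np.abs(denom)) - 2.0 * log_scale
        T = np.exp(logT)
    T = np.where(opaque, 0.0, T)

    if n_phase_axes:
        axes = tuple(range(-n_phase_axes, 0))
        R = R.mean(axis=axes)
        T = T.mean(axis=axes)
    R = np.clip(R, 0.0, 1.0)
    T = np.clip(T, 0.0, 1.0)
    return R, T


def _evaluate(
    stack: LayerStack,
    wavelength_nm: float,
    angle_deg: float,
    lib: MaterialLibrary,
    thickness_overrides: dict[int, np.ndarray] | None = None,
    phase_samples: int = PHASE_SAMPLES,
):
    """(R_s, T_s, R_p, T_p) arrays for one wavelength/angle."""
    n0, ns, n_sub = _resolve_indices(stack, wavelength_nm, lib)
    sin0 = math.sin(math.radians(angle_deg))
    thicknesses = [layer.thickness_nm for layer in stack.layers]
    if thickness_overrides:
        for i, arr in thickness_overrides.items():
            thicknesses[i] = np.asarray(arr, dtype=float)
    coherences = [layer.coherence for layer in stack.layers]
    out = []
    for pol in ("s", "p"):
        out.extend(
            _rt_one_pol(
                n0, sin0, ns, thicknesses, coherences, n_sub, wavelength_nm, pol, phase_samples
            )
        )
    return out  # R_s, T_s, R_p, T_p


def _result_from_rt(R_s, T_s, R_p, T_p, polarization: str) -> ReflectanceResult:
    R_s, T_s, R_p, T_p = (float(x) for x in (R_s, T_s, R_p, T_p))
    if polarization == "s":
        R, T = R_s, T_s
    elif polarization == "p":
        R, T = R_p, T_p
    else:
        R, T = 0.5 * (R_s + R_p), 0.5 * (T_s + T_p)
    return ReflectanceResult(
        R=R, T=T, A=1.0 - R - T, R_s=R_s, R_p=R_p, T_s=T_s, T_p=T_p
    )


def stack_reflectance(
    stack: LayerStack,
    illum: Illumination,
    lib: MaterialLibrary,
    phase_samples: int = PHASE_SAMPLES,
) -> ReflectanceResult:
    """Reflectance/transmittance/absorptance of ``stack`` under ``illum``.

    Coherent sub-stacks are evaluated with the characteristic-matrix
    product; incoherent layers are handled by uniform phase averaging
    (:func:`incoherent_combine`); a nonzero spectral FWHM or numerical
    aperture triggers :func:`spectral_angular_average`.
    """
    if illum.spectral_fwhm_nm > 0 or illum.numerical_aperture > 0:
        return spectral_angular_average(stack, illum, lib, phase_samples=phase_samples)
    rt = _evaluate(stack, illum.wavelength_nm, illum.angle_deg, lib, None, phase_samples)
    return _result_from_rt(*rt, illum.polarization)


def incoherent_combine(
    stack: LayerStack,
    illum: Illumination,
    lib: MaterialLibrary,
    phase_samples: int = PHASE_SAMPLES,
) -> ReflectanceResult:
    """Stack response with incoherent layers phase-averaged.

    Equal to the uniform average of the fully coherent result over one
    phase period of every incoherent layer, evaluated with ``phase_samples``
    equally spaced midpoint samples; deterministic for fixed settings.
    A stack without incoherent layers reduces to :func:`stack_reflectance`.
    """
    rt = _evaluate(stack, illum.wavelength_nm, illum.angle_deg, lib, None, phase_samples)
    return _result_from_rt(*rt, illum.polarization)


def reflectance_grid(
    stack: LayerStack,
    illum: Illumination,
    lib: MaterialLibrary,
    thickness_overrides: dict[int, np.ndarray],
    phase_samples: int = PHASE_SAMPLES,
) -> np.ndarray:
    """Reflectance broadcast over per-layer thickness arrays.

    ``thickness_overrides`` maps layer index -> array of thicknesses (nm);
    arrays broadcast against each other (e.g. shape ``(S, 1)`` against
    ``(1, C)`` for a 2-D sweep).  A nonzero spectral FWHM / numerical
    aperture in ``illum`` band- / cone-averages the grid.  Used by the
    configuration sweep; the scalar path of :func:`stack_reflectance` runs
    through the same engine.
    """
    if illum.numerical_aperture > 0 and illum.angle_deg != 0:
        raise IlluminationError("NA-averaging is defined about normal incidence")
    wls, wl_w = gaussian_band_nodes(illum.wavelength_nm, illum.spectral_fwhm_nm)
    thetas_deg, ang_w = aperture_nodes(illum.numerical_aperture)
    if illum.numerical_aperture == 0:
        thetas_deg = np.array([illum.angle_deg])

    acc = None
    for wl, ww in zip(wls, wl_w):
        for th, aw in zip(thetas_deg, ang_w):
            R_s, T_s, R_p, T_p = _evaluate(
                stack, float(wl), float(th), lib, thickness_overrides, phase_samples
            )
            if illum.polarization == "s":
                R = np.asarray(R_s)
            elif illum.polarization == "p":
                R = np.asarray(R_p)
            else:
                R = 0.5 * (np.asarray(R_s) + np.asarray(R_p))
            acc = ww * aw * R if acc is None else acc + ww * aw * R
    return acc


# ---------------------------------------------------------------------------
# Independent oracle: Parratt-style interface recursion in kz form
# ---------------------------------------------------------------------------

def reflectance_recursive(
    stack: LayerStack, illum: Illumination, lib: MaterialLibrary
) -> float:
    """Reflectance by bottom-up Fresnel interface recursion (coherent only).

    Independent of the matrix formalism: works with normal wavevector
    components ``kz_j = (2 pi / lambda) sqrt(n~_j^2 - n0^2 sin^2 theta0)``
    (branch ``Im kz >= 0``), interface Fresnel coefficients and explicit
    round-trip phase factors.  Serves as the cross-implementation oracle
    for :func:`stack_reflectance`.
    """
    for layer in stack.layers:
        if layer.coherence != "coherent" and layer.thickness_nm > 0:
            raise UnsupportedInputError(
                "reflectance_recursive supports fully coherent stacks only"
            )
    lam = illum.wavelength_nm
    n0c, ns, n_sub = _resolve_indices(stack, lam, lib)
    sin0 = math.sin(math.radians(illum.angle_deg))
    kpar2 = (n0c * sin0) ** 2

    def kz(n: complex) -> complex:
        v = complex(np.sqrt(n * n - kpar2 + 0j))
        if v.imag < 0 or (v.imag == 0 and v.real < 0):
            v = -v
        return 2.0 * np.pi * v / lam

    indices = [complex(n0c)] + list(ns) + [n_sub]
    kzs = [kz(n) for n in indices]
    thicknesses = [layer.thickness_nm for layer in stack.layers]

    def rho(a: int, b: int, pol: str) -> complex:
        if pol == "s":
            return (kzs[a] - kzs[b]) / (kzs[a] + kzs[b])
        na2, nb2 = indices[a] ** 2, indices[b] ** 2
        return (nb2 * kzs[a] - na2 * kzs[b]) / (nb2 * kzs[a] + na2 * kzs[b])

    def one_pol(pol: str) -> float:
        r = rho(len(indices) - 2, len(indices) - 1, pol)
        for j in range(len(thicknesses) - 1, -1, -1):
            phase = np.exp(2j * kzs[j + 1] * thicknesses[j])
            rj = rho(j, j + 1, pol)
            r = (rj + r * phase) / (1.0 + rj * r * phase)
        return float(abs(r) ** 2)

    if illum.polarization == "s":
        return one_pol("s")
    if illum.polarization == "p":
        return one_pol("p")
    return 0.5 * (one_pol("s") + one_pol("p"))


# ---------------------------------------------------------------------------
# Band / aperture averaging
# ---------------------------------------------------------------------------

def gaussian_band_nodes(
    center_nm: float, fwhm_nm: float, n_nodes: int = SPECTRAL_NODES
) -> tuple[np.ndarray, np.ndarray]:
    """Wavelength nodes and normalized Gaussian weights for a source band.

    Equally spaced nodes over ``center +/- 2*FWHM``; weights from a Gaussian
    of the stated FWHM.  ``fwhm_nm = 0`` degenerates to the single center
    wavelength with weight 1.
    """
    if fwhm_nm < 0:
        raise IlluminationError("spectral FWHM must be >= 0")
    if fwhm_nm == 0:
        return np.array([center_nm]), np.array([1.0])
    sigma = fwhm_nm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    wls = np.linspace(center_nm - 2 * fwhm_nm, center_nm + 2 * fwhm_nm, n_nodes)
    w = np.exp(-0.5 * ((wls - center_nm) / sigma) ** 2)
    return wls, w / w.sum()


def aperture_nodes(
    na: float, n_nodes: int = ANGULAR_NODES
) -> tuple[np.ndarray, np.ndarray]:
    """Incidence-angle nodes (degrees) and weights for an illumination cone.

    Uniform-irradiance average over the cone up to ``asin(NA)`` about normal
    incidence: solid-angle weight ``sin(theta) cos(theta)`` on Gauss-Legendre
    nodes.  ``na = 0`` degenerates to normal incidence with weight 1.
    """
    if not 0.0 <= na < 1.0:
        raise IlluminationError(f"numerical aperture must be in [0, 1), got {na}")
    if na == 0:
        return np.array([0.0]), np.array([1.0])
    theta_max = math.asin(na)
    x, gl_w = np.polynomial.legendre.leggauss(n_nodes)
    thetas = 0.5 * (x + 1.0) * theta_max
    w = gl_w * np.sin(thetas) * np.cos(thetas)
    return np.degrees(thetas), w / w.sum()


def spectral_angular_average(
    stack: LayerStack,
    illum: Illumination,
    lib: MaterialLibrary,
    phase_samples: int = PHASE_SAMPLES,
) -> ReflectanceResult:
    """Gaussian spectral and aperture-cone angular average of the response.

    Wavelength: Gaussian weights of the stated FWHM, truncated at +/- 2 FWHM,
    on a fixed grid of ``SPECTRAL_NODES`` points.  Angle: uniform-irradiance
    average over the illumination cone up to ``asin(NA)`` (solid-angle weight
    ``sin(theta) cos(theta)``, Gauss-Legendre order ``ANGULAR_NODES``),
    taken about normal incidence.  Collapses to the single-point evaluation
    when FWHM and NA are both 0.
    """
    if illum.numerical_aperture > 0 and illum.angle_deg != 0:
        raise IlluminationError("NA-averaging is defined about normal incidence")
    wls, wl_w = gaussian_band_nodes(illum.wavelength_nm, illum.spectral_fwhm_nm)
    thetas_deg, ang_w = aperture_nodes(illum.numerical_aperture)

    acc = np.zeros(4)
    for wl, ww in zip(wls, wl_w):
        for th, aw in zip(thetas_deg, ang_w):
            rt = _evaluate(stack, float(wl), float(th), lib, None, phase_samples)
            acc += ww * aw * np.array([float(x) for x in rt])
    return _result_from_rt(*acc, illum.polarization)
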