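"""Inverse pipeline: observed delta-S21 -> complex membrane permittivity.

The forward chain is

    membrane eps_par  ->  delta C of the split gap (sensitivity kernel)
                      ->  delta s21 of the calibrated circuit at the
                          measurement frequency
                      ->  x instrument gain.

The sensitivity kernel is the exact first-order derivative of the gap
capacitance with respect to the membrane-layer permittivity, evaluated on the
unperturbed stack (membrane slab carrying the bulk-water permittivity), so the
forward map is near-linear in the complex permittivity contrast and the
two-parameter inversion is a small damped least-squares problem.

A single complex instrument gain per (lipid, frequency) anchor absorbs
un-modelled instrument factors; it is fixed by one printed (permittivity,
delta-|S21|) pair and makes the anchor's forward response real and equal to
the printed magnitude by construction.

The probing field attenuates quickly with height above the electrodes, so a
thin water film between electrode and membrane (hydration / surface liquid)
changes the recovered values; ``invert_with_elevation`` inserts that film into
the layer stack before building the kernel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from .circuit import RingResonatorModel, default_model, delta_s21
from .errors import DegenerateAnchorError, InputError, InversionError
from .field import SensorGeometry, membrane_stack, sensitivity_kernel
from .media import WATER


@dataclass(frozen=True)
class ComplexPermittivity:
    """Relative permittivity ``eps' - j eps''`` with an orientation tag.

    ``orientation`` records which polarization the value describes: the split
    gap probes the in-plane (``parallel``) membrane response.
    """

    eps_real: float
    eps_imag: float = 0.0
    orientation: str = "parallel"

    def __post_init__(self):
        if self.orientation not in ("parallel", "perpendicular", "isotropic"):
            raise InputError(f"unknown orientation {self.orientation!r}")

    def validate(self) -> None:
        if not (np.isfinite(self.eps_real) and np.isfinite(self.eps_imag)):
            raise InputError("permittivity must be finite")
        if self.eps_real < 1.0:
            raise InputError("eps' must be >= 1 for a physical medium")
        if self.eps_imag < 0.0:
            raise InputError("eps'' must be >= 0 (convention eps = eps' - j eps'')")

    @property
    def value(self) -> complex:
        return self.eps_real - 1j * self.eps_imag

    @classmethod
    def from_complex(cls, z: complex, orientation: str = "parallel") -> "ComplexPermittivity":
        return cls(float(np.real(z)), float(-np.imag(z)), orientation)


@dataclass(frozen=True)
class ExtractionConfig:
    """Settings of one extraction: frequency, membrane slab, elevation, gain."""

    frequency_hz: float = 2.7e9
    membrane_thickness: float = 5e-9
    elevation: float = 0.0
    instrument_gain: complex = 1.0 + 0.0j
    resolution: int = 24
    tol_rel: float = 1e-6
    magnitude_only: bool = False

    def validate(self, model: RingResonatorModel | None = None) -> None:
        if self.frequency_hz <= 0 or self.membrane_thickness <= 0:
            raise InputError("frequency and membrane thickness must be positive")
        if self.elevation < 0:
            raise InputError("elevation must be >= 0")
        if model is not None and model.mode_frequencies:
            if not any(abs(self.frequency_hz / f - 1) < 0.05 for f in model.mode_frequencies):
                raise InputError(
                    "extraction frequency must be one of the calibrated mode frequencies"
                )

    def replace(self, **changes) -> "ExtractionConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class ExtractionResult:
    permittivity: ComplexPermittivity
    residual: float
    iterations: int
    success: bool
    diagnostics: dict = dc_field(default_factory=dict)


@lru_cache(maxsize=64)
def _membrane_kernel_weight(
    geometry: SensorGeometry,
    frequency_hz: float,
    membrane_thickness: float,
    elevation: float,
    resolution: int,
) -> complex:
    """Total dC/d(eps_r) of the membrane layer (farads per unit relative
    permittivity) on the unperturbed (all-water) stack."""
    stack = membrane_stack(
        frequency_hz,
        membrane_permittivity=None,
        membrane_thickness=membrane_thickness,
        elevation=elevation,
    )
    weights, _ = sensitivity_kernel(geometry, stack, resolution)
    return complex(weights["membrane"])


def membrane_kernel_weight(geometry: SensorGeometry, config: ExtractionConfig) -> complex:
    config.validate()
    return _membrane_kernel_weight(
        geometry,
        float(config.frequency_hz),
        float(config.membrane_thickness),
        float(config.elevation),
        int(config.resolution),
    )


def forward_delta(
    permittivity: ComplexPermittivity,
    config: ExtractionConfig,
    model: RingResonatorModel | None = None,
    geometry: SensorGeometry | None = None,
) -> complex:
    """Predicted complex delta-S21 when a membrane of the given parallel
    permittivity replaces bulk water in the membrane layer."""
    permittivity.validate()
    model = default_model() if model is None else model
    geometry = SensorGeometry() if geometry is None else geometry
    config.validate(model)
    w = membrane_kernel_weight(geometry, config)
    eps_medium = WATER.permittivity(config.frequency_hz)
    dcap = w * (permittivity.value - eps_medium)
    if dcap == 0:
        return 0.0 + 0.0j
    return complex(config.instrument_gain) * delta_s21(model, dcap, config.frequency_hz)


def calibrate_gain(
    anchor_permittivity: ComplexPermittivity,
    anchor_delta: float,
    config: ExtractionConfig,
    model: RingResonatorModel | None = None,
    geometry: SensorGeometry | None = None,
) -> complex:
    """Complex gain making |forward_delta(anchor)| equal the observed anchor
    delta-|S21| (and the anchor response real-positive)."""
    if not anchor_delta > 0:
        raise InputError("anchor delta must be positive")
    raw = forward_delta(anchor_permittivity, config.replace(instrument_gain=1.0 + 0.0j), model, geometry)
    if raw == 0:
        raise DegenerateAnchorError("anchor permittivity produces zero model response")
    return complex(anchor_delta / raw)


def invert(
    observed: complex,
    config: ExtractionConfig,
    model: RingResonatorModel | None = None,
    geometry: SensorGeometry | None = None,
) -> ExtractionResult:
    """Recover the parallel membrane permittivity from an observed delta-S21.

    Damped least squares on (eps', eps'') with multi-start from the medium
    value and 1.5x the medium value; ties broken by lowest residual, then
    lowest eps''.  In ``magnitude_only`` mode the observation is a real
    delta-|S21| interpreted in the gain-anchored convention (the anchor
    response is real-positive by construction).
    """
    model = default_model() if model is None else model
    geometry = SensorGeometry() if geometry is None else geometry
    config.validate(model)
    obs = complex(observed)
    if config.magnitude_only:
        obs = complex(abs(observed))
    if not np.isfinite(obs.real) or not np.isfinite(obs.imag):
        raise InputError("observed delta-S21 must be finite")

    eps_medium = WATER.permittivity(config.frequency_hz)

    def residuals(x):
        p = ComplexPermittivity(max(x[0], 1.0), max(x[1], 0.0))
        d = forward_delta(p, config, model, geometry)
        return np.array([d.real - obs.real, d.imag - obs.imag])

    starts = [
        np.array([eps_medium.real, -eps_medium.imag]),
        np.array([1.5 * eps_medium.real, -1.5 * eps_medium.imag]),
    ]
    best = None
    nfev = 0
    for x0 in starts:
        sol = least_squares(
            residuals,
            x0,
            bounds=([1.0, 0.0], [np.inf, np.inf]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        nfev += sol.nfev
        cand = (np.linalg.norm(sol.fun), sol.x[1], sol.x)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:  # pragma: no cover
        raise InversionError("no inversion start converged")
    resid, _, x = best
    scale = max(abs(obs), 1e-12)
    success = resid <= config.tol_rel * scale
    # optimum pinned at eps' = 1 or eps'' = 0 with unexplained residual:
    # the observation has no physical solution (constrained-boundary case)
    on_boundary = bool((x[0] <= 1.0 + 1e-6 or x[1] <= 1e-3) and not success)
    diagnostics = {
        "boundary": on_boundary,
        "frequency_hz": config.frequency_hz,
        "elevation_m": config.elevation,
        "medium_permittivity": eps_medium,
        "n_function_evaluations": nfev,
    }
    result = ExtractionResult(
        permittivity=ComplexPermittivity(float(x[0]), float(x[1]), "parallel"),
        residual=float(resid),
        iterations=nfev,
        success=bool(success),
        diagnostics=diagnostics,
    )
    if not success and not on_boundary:
        raise InversionError(
            f"inversion residual {resid:.3e} above tolerance {config.tol_rel * scale:.3e}",
            trace=diagnostics,
        )
    return result


def invert_with_elevation(
    observed: complex,
    elevation: float,
    config: ExtractionConfig,
    model: RingResonatorModel | None = None,
    geometry: SensorGeometry | None = None,
) -> ExtractionResult:
    """As :func:`invert`, with a water film of the given thickness between the
    electrode surface and the membrane; elevation 0 reduces exactly to
    :func:`invert`."""
    if elevation < 0:
        raise InputError("elevation must be >= 0")
    return invert(observed, config.replace(elevation=float(elevation)), model, geometry)
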