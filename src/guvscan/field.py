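"""Quasi-static field solver for the split-gap cross-section.

The split gap (width ``s`` = 500 nm) is over two hundred times narrower than
the guided wavelength at 7.9 GHz, so the gap load is computed electrostatically
on the 2-D cross-section at slot mid-length: a finite-volume Laplace solve of
``div(eps grad phi) = 0`` on a tensor-product grid, with the two electrodes at
+/- V/2 (Dirichlet over the metal, including the slot side-walls across the
metal thickness) and zero normal flux on the truncated outer boundaries.

The grid is uniform (``slot_width / resolution``) near the gap and
geometrically stretched outwards, with extra grid lines forced onto every
dielectric interface so nanometre membrane slabs are resolved exactly.  The
slot length enters only as a multiplier when converting per-unit-length
capacitance to the total gap capacitance.

Complex relative permittivities are supported throughout; "energies" and
capacitances use the non-conjugated bilinear form, so the capacitance is the
complex C = Q/V of a lossy load and reduces to the usual electrostatic energy
for real media.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RegularGridInterpolator

from .errors import InputError, RangeError, SolverError, StateError
from .media import EPS0, WATER

# ---------------------------------------------------------------------------
# geometry and layer stack
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensorGeometry:
    """Printed device dimensions (meters) and passive-layer permittivities.

    ``slot_width`` is the split gap ``s``; ``coupling_gap`` is the microstrip
    coupling dimension ``g`` (metadata for the circuit model, not used by the
    field solve).  ``metal_thickness`` may be zero to recover the ideal
    coplanar limit used by the analytic cross-checks.
    """

    slot_width: float = 500e-9
    slot_length: float = 100e-6
    metal_thickness: float = 0.54e-6
    coupling_gap: float = 3.5e-6
    channel_height: float = 18.8e-6
    channel_width: float = 25e-6
    substrate_thickness: float = 1e-3
    pdms_thickness: float = 3e-3
    substrate_permittivity: float = 4.6
    pdms_permittivity: float = 2.7

    def validate(self) -> None:
        for name in (
            "slot_width",
            "slot_length",
            "coupling_gap",
            "channel_height",
            "channel_width",
            "substrate_thickness",
            "pdms_thickness",
        ):
            if not getattr(self, name) > 0:
                raise InputError(f"{name} must be strictly positive")
        if self.metal_thickness < 0:
            raise InputError("metal_thickness must be >= 0")
        if not self.slot_width < self.channel_width:
            raise InputError("slot must be narrower than the channel")
        if not self.metal_thickness < self.channel_height:
            raise InputError("metal must be thinner than the channel height")


@dataclass(frozen=True)
class Layer:
    """One dielectric layer above the electrode plane (bottom-to-top order)."""

    name: str
    thickness: float  # meters; np.inf only for the topmost (bulk) layer
    permittivity: complex
    analyte: bool = False


@dataclass(frozen=True)
class LayerStack:
    """Dielectric layers above the electrode surface, bottom-to-top.

    Exactly one layer carries the ``analyte`` flag (the membrane slab under
    study; a bulk-only stack flags the bulk).  The topmost layer is treated as
    semi-infinite: it extends up to the channel ceiling, above which the PDMS
    lid from the geometry takes over.  ``slot_fill`` is the permittivity
    inside the slot opening; ``None`` means the bulk (topmost) permittivity.
    """

    layers: tuple
    slot_fill: complex | None = None

    def validate(self) -> None:
        if not self.layers:
            raise InputError("stack needs at least one layer")
        if sum(1 for l in self.layers if l.analyte) != 1:
            raise InputError("exactly one layer must be flagged as the analyte")
        for l in self.layers[:-1]:
            if not (np.isfinite(l.thickness) and l.thickness > 0):
                raise InputError(f"layer {l.name!r} must have finite positive thickness")
        if not (np.isinf(self.layers[-1].thickness) or self.layers[-1].thickness > 0):
            raise InputError("topmost layer thickness must be positive or infinite")

    @property
    def analyte_layer(self) -> Layer:
        return next(l for l in self.layers if l.analyte)

    def interfaces(self):
        """y coordinates of the internal layer boundaries (above y = 0)."""
        ys, y = [], 0.0
        for l in self.layers[:-1]:
            y += l.thickness
            ys.append(y)
        return ys

    @property
    def bulk_permittivity(self) -> complex:
        return self.layers[-1].permittivity


def uniform_stack(permittivity: complex) -> LayerStack:
    """A homogeneous medium above the electrodes (bulk flagged as analyte)."""
    return LayerStack(layers=(Layer("medium", np.inf, complex(permittivity), analyte=True),))


def membrane_stack(
    frequency_hz: float,
    membrane_permittivity: complex | None = None,
    membrane_thickness: float = 5e-9,
    elevation: float = 0.0,
    medium=WATER,
) -> LayerStack:
    """Water / (elevation film) / membrane / bulk-water stack at ``frequency_hz``.

    ``membrane_permittivity=None`` inserts a membrane slab with the bulk
    permittivity — the unperturbed reference used to build sensitivity kernels.
    """
    eps_w = medium.permittivity(frequency_hz)
    eps_m = eps_w if membrane_permittivity is None else complex(membrane_permittivity)
    layers = []
    if elevation > 0:
        layers.append(Layer("film", float(elevation), eps_w))
    layers.append(Layer("membrane", float(membrane_thickness), eps_m, analyte=True))
    layers.append(Layer("medium", np.inf, eps_w))
    return LayerStack(layers=tuple(layers))


# ---------------------------------------------------------------------------
# field map container
# ---------------------------------------------------------------------------


@dataclass
class FieldMap:
    """Solved potential and cell-centred fields on the tensor grid.

    ``x``/``y`` are node coordinates; ``phi`` is indexed [y, x].  ``ex``/``ey``
    and ``eps`` live on cell centres (shape (ny-1, nx-1)); ``labels`` names the
    material region of each cell.  ``cell_weights`` are the per-cell
    d(C/length)/d(eps0*eps_r) factors of the discrete energy functional, so
    C/length = eps0 * sum(eps_r * cell_weights) holds exactly.
    """

    geometry: SensorGeometry
    stack: LayerStack
    x: np.ndarray
    y: np.ndarray
    phi: np.ndarray
    eps: np.ndarray
    labels: np.ndarray
    ex: np.ndarray
    ey: np.ndarray
    cell_weights: np.ndarray
    voltage: float
    residual: float
    solved: bool = True
    metadata: dict = dc_field(default_factory=dict)

    @property
    def xc(self):
        return 0.5 * (self.x[:-1] + self.x[1:])

    @property
    def yc(self):
        return 0.5 * (self.y[:-1] + self.y[1:])

    @property
    def cell_areas(self):
        return np.outer(np.diff(self.y), np.diff(self.x))

    def intensity(self):
        """|E|^2 on cell centres."""
        return np.abs(self.ex) ** 2 + np.abs(self.ey) ** 2

    def region_mask(self, region) -> np.ndarray:
        """Boolean cell mask for a named region or a callable mask(xc, yc)."""
        if callable(region):
            xx, yy = np.meshgrid(self.xc, self.yc)
            return np.asarray(region(xx, yy), bool)
        if region == "analyte" or region == "membrane":
            return self.labels == self.stack.analyte_layer.name
        if region == "slot":
            return self.labels == "slot"
        if region == "measurement":
            # probing-field column: slot interior plus the part of the
            # membrane band that spans the slot opening
            xx, _ = np.meshgrid(self.xc, self.yc)
            over_slot = np.abs(xx) <= self.geometry.slot_width / 2.0
            return (self.labels == "slot") | (
                (self.labels == self.stack.analyte_layer.name) & over_slot
            )
        mask = self.labels == region
        if not mask.any():
            raise InputError(f"unknown or empty region {region!r}")
        return mask


# ---------------------------------------------------------------------------
# grid construction
# ---------------------------------------------------------------------------


def _stretch(start: float, step: float, limit: float, ratio: float = 1.12):
    """Geometrically growing grid points from ``start`` (exclusive) up to ``limit``."""
    pts, pos = [], start
    while pos < limit - 1e-15:
        step *= ratio
        pos = min(pos + step, limit)
        pts.append(pos)
    return np.asarray(pts)


def _build_axes(geometry: SensorGeometry, stack: LayerStack, resolution: int,
                x_extent: float | None, y_top: float | None, y_bottom: float | None,
                electrode_halfwidth: float | None):
    s = geometry.slot_width
    t = geometry.metal_thickness
    res = int(resolution)
    if res < 16:
        raise InputError("resolution must be at least 16 nodes per slot width")
    if res % 2:
        res += 1
    h = s / res
    x_extent = 10.0 * s if x_extent is None else float(x_extent)
    y_top_default = max(10.0 * s, 1.05 * geometry.channel_height)
    y_top = y_top_default if y_top is None else float(y_top)
    y_bottom = (t + 10.0 * s) if y_bottom is None else float(y_bottom)

    x_fine = np.arange(0, int(np.ceil(1.5 * s / h)) + 1) * h
    xs = [x_fine, _stretch(x_fine[-1], h, x_extent)]
    x_half = np.concatenate(xs)
    if electrode_halfwidth is not None:
        x_half = np.append(x_half, float(electrode_halfwidth))
    x = np.unique(np.concatenate([-x_half, x_half]))

    fine_lo, fine_hi = -(t + s), 2.0 * s
    y_parts = [np.arange(int(np.floor(fine_lo / h)), int(np.ceil(fine_hi / h)) + 1) * h]
    y_parts.append(_stretch(y_parts[0][-1], h, y_top))
    y_parts.append(-_stretch(-y_parts[0][0], h, y_bottom))
    # extra refinement of the first half slot-width above the electrode plane,
    # where the analyte band sits and the field varies fastest
    h4 = h / 4.0
    y_parts.append(np.arange(0, int(np.ceil(0.5 * s / h4)) + 1) * h4)
    mandatory = [0.0, -t] + [yy for yy in stack.interfaces() if yy < y_top]
    if geometry.channel_height < y_top:
        mandatory.append(geometry.channel_height)
    y = np.concatenate(y_parts + [np.asarray(mandatory)])
    y = np.unique(y)
    # drop near-duplicates but never a mandatory interface line
    keep = np.ones(y.size, bool)
    keep[1:] = np.diff(y) > 1e-13
    mand = np.asarray(mandatory)
    for m in mand:
        keep[np.argmin(np.abs(y - m))] = True
    y = y[keep]
    return x, y


def _cell_labels_and_eps(geometry: SensorGeometry, stack: LayerStack, x, y,
                         electrode_halfwidth):
    s, t = geometry.slot_width, geometry.metal_thickness
    xc = 0.5 * (x[:-1] + x[1:])
    yc = 0.5 * (y[:-1] + y[1:])
    xx, yy = np.meshgrid(xc, yc)
    labels = np.full(xx.shape, "", dtype=object)
    eps = np.empty(xx.shape, dtype=complex)

    slot_fill = stack.slot_fill if stack.slot_fill is not None else stack.bulk_permittivity
    ew = np.inf if electrode_halfwidth is None else float(electrode_halfwidth)

    below = yy < -t if t > 0 else yy < 0
    labels[below] = "substrate"
    eps[below] = geometry.substrate_permittivity

    if t > 0:
        band = (~below) & (yy < 0)
        in_metal = band & (np.abs(xx) >= s / 2) & (np.abs(xx) <= ew)
        labels[band] = "slot"
        eps[band] = slot_fill
        labels[in_metal] = "metal"
        eps[in_metal] = 1.0

    above = yy >= 0
    lo = 0.0
    for layer in stack.layers:
        hi = lo + layer.thickness
        sel = above & (yy >= lo) & (yy < hi)
        labels[sel] = layer.name
        eps[sel] = layer.permittivity
        lo = hi
    lid = above & (yy >= geometry.channel_height)
    labels[lid] = "pdms"
    eps[lid] = geometry.pdms_permittivity
    return labels, eps


def solve_potential(
    geometry: SensorGeometry,
    stack: LayerStack,
    resolution: int = 24,
    voltage: float = 1.0,
    x_extent: float | None = None,
    y_top: float | None = None,
    y_bottom: float | None = None,
    electrode_halfwidth: float | None = None,
) -> FieldMap:
    """Finite-volume solve of the slot cross-section; returns a :class:`FieldMap`.

    ``resolution`` is the number of grid cells per slot width in the fine
    region.  ``electrode_halfwidth`` truncates the electrodes at a finite
    outer edge (used by the coplanar-strip analytic cross-checks); by default
    they extend to the domain boundary.
    """
    geometry.validate()
    stack.validate()
    x, y = _build_axes(geometry, stack, resolution, x_extent, y_top, y_bottom, electrode_halfwidth)
    labels, eps = _cell_labels_and_eps(geometry, stack, x, y, electrode_halfwidth)
    nx, ny = x.size, y.size
    dx, dy = np.diff(x), np.diff(y)

    s, t = geometry.slot_width, geometry.metal_thickness
    ew = np.inf if electrode_halfwidth is None else float(electrode_halfwidth)
    xx, yy = np.meshgrid(x, y)
    tol = 1e-12
    metal = (yy >= -t - tol) & (yy <= tol) & (np.abs(xx) >= s / 2 - tol) & (np.abs(xx) <= ew + tol)
    v_dirichlet = np.where(xx > 0, voltage / 2.0, -voltage / 2.0)

    # horizontal link conductances g_h[j, i] between nodes (i,j)-(i+1,j)
    g_h = np.zeros((ny, nx - 1), complex)
    g_h[1:, :] += eps * (dy[:, None] / 2.0)
    g_h[:-1, :] += eps * (dy[:, None] / 2.0)
    g_h /= dx[None, :]
    # vertical link conductances g_v[j, i] between nodes (i,j)-(i,j+1)
    g_v = np.zeros((ny - 1, nx), complex)
    g_v[:, 1:] += eps * (dx[None, :] / 2.0)
    g_v[:, :-1] += eps * (dx[None, :] / 2.0)
    g_v /= dy[:, None]

    idx = np.arange(nx * ny).reshape(ny, nx)
    rows, cols, vals = [], [], []

    def add_links(g, ia, ib):
        rows.extend([ia, ib, ia, ib])
        cols.extend([ia, ib, ib, ia])
        vals.extend([g, g, -g, -g])

    ia = idx[:, :-1].ravel()
    ib = idx[:, 1:].ravel()
    add_links(g_h.ravel(), ia, ib)
    ia = idx[:-1, :].ravel()
    ib = idx[1:, :].ravel()
    add_links(g_v.ravel(), ia, ib)

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    a = sp.csr_matrix((vals, (rows, cols)), shape=(nx * ny, nx * ny))

    b = np.zeros(nx * ny, complex)
    fixed = metal.ravel()
    vfix = v_dirichlet.ravel()
    # eliminate Dirichlet nodes symmetrically: move their columns to the rhs
    b -= a @ (np.where(fixed, vfix, 0.0))
    free = ~fixed
    a_ff = a[free][:, free]
    # guard against isolated zero rows (cannot happen on a connected grid)
    try:
        phi_free = spla.spsolve(a_ff.tocsc(), b[free])
    except Exception as exc:  # pragma: no cover
        raise SolverError(f"sparse solve failed: {exc}") from exc
    phi = np.where(fixed, vfix, 0.0).astype(complex)
    phi[free] = phi_free
    res_vec = a_ff @ phi_free - b[free]
    scale = float(np.linalg.norm(b[free])) or 1.0
    residual = float(np.linalg.norm(res_vec)) / scale
    if not np.all(np.isfinite(phi)):
        raise SolverError("non-finite potential", residual=residual)
    phi = phi.reshape(ny, nx)

    # cell-centred fields
    dphix = (phi[:, 1:] - phi[:, :-1]) / dx[None, :]
    ex = -0.5 * (dphix[:-1, :] + dphix[1:, :])
    dphiy = (phi[1:, :] - phi[:-1, :]) / dy[:, None]
    ey = -0.5 * (dphiy[:, :-1] + dphiy[:, 1:])

    # exact per-cell derivative of the discrete energy functional: each cell
    # contributes (dy/2)/dx to its two horizontal edge conductances and
    # (dx/2)/dy to its two vertical ones, so (non-conjugated squares)
    w_h = (phi[:, 1:] - phi[:, :-1]) ** 2 / dx[None, :]
    w_v = (phi[1:, :] - phi[:-1, :]) ** 2 / dy[:, None]
    cell_weights = (
        (w_h[:-1, :] + w_h[1:, :]) * (dy[:, None] / 2.0)
        + (w_v[:, :-1] + w_v[:, 1:]) * (dx[None, :] / 2.0)
    ) / voltage**2

    return FieldMap(
        geometry=geometry,
        stack=stack,
        x=x,
        y=y,
        phi=phi,
        eps=eps,
        labels=labels,
        ex=ex,
        ey=ey,
        cell_weights=cell_weights,
        voltage=voltage,
        residual=residual,
        metadata={"resolution": resolution},
    )


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def _require_solved(fmap: FieldMap) -> None:
    if not getattr(fmap, "solved", False):
        raise StateError("field map has not been solved")


def capacitance(fmap: FieldMap):
    """(C per unit slot length [F/m], total C [F]) from the discrete energy."""
    _require_solved(fmap)
    per_m = EPS0 * complex(np.sum(fmap.eps * fmap.cell_weights))
    return per_m, per_m * fmap.geometry.slot_length


def gap_capacitance(geometry: SensorGeometry, stack: LayerStack, resolution: int = 24, **kw):
    """Solve and return (C per meter, total C) of the split gap."""
    return capacitance(solve_potential(geometry, stack, resolution, **kw))


def field_profile(fmap: FieldMap, y_max: float | None = None):
    """(y, |E|^2) on the slot centreline for y >= 0 (cell centres)."""
    _require_solved(fmap)
    inten = fmap.intensity()
    xc = fmap.xc
    mid = np.argsort(np.abs(xc))[:2]  # the two cells straddling x = 0
    prof = inten[:, mid].mean(axis=1)
    ys = fmap.yc
    sel = ys >= 0
    if y_max is not None:
        sel &= ys <= y_max
    return ys[sel], np.asarray(prof[sel], float)


def _intensity_interpolator(fmap: FieldMap):
    return RegularGridInterpolator(
        (fmap.yc, fmap.xc), fmap.intensity(), bounds_error=False, fill_value=None
    )


def _band_average_intensity(fmap: FieldMap, y_lo: float, y_hi: float) -> float:
    """Exact area-weighted mean of |E|^2 over the horizontal band
    [y_lo, y_hi]: cells are weighted by their overlap with the band."""
    dy = np.diff(fmap.y)
    overlap = np.clip(np.minimum(fmap.y[1:], y_hi) - np.maximum(fmap.y[:-1], y_lo), 0.0, None)
    if not overlap.any():
        # band thinner than the local cells: fall back to interpolation
        interp = _intensity_interpolator(fmap)
        xc, wx = fmap.xc, np.diff(fmap.x)
        ys = np.linspace(y_lo, y_hi, 5)
        acc = sum(
            float(np.sum(interp(np.column_stack([np.full_like(xc, yv), xc])) * wx) / np.sum(wx))
            for yv in ys
        )
        return acc / 5.0
    w = np.outer(overlap, np.diff(fmap.x))
    del dy
    return float(np.sum(fmap.intensity() * w) / np.sum(w))


def elevation_factor(fmap: FieldMap, elevation: float, thickness: float | None = None) -> float:
    """Membrane-band-averaged |E|^2 at ``elevation`` relative to contact.

    The membrane slab (thickness of the analyte layer unless overridden) is
    slid up by ``elevation`` and the layer-averaged field intensity is divided
    by its value at contact (elevation 0).  Equals 1 at zero elevation by
    definition and decreases as the membrane leaves the gap's near field.
    """
    _require_solved(fmap)
    if elevation < 0:
        raise InputError("elevation must be >= 0")
    th = thickness
    if th is None:
        th = fmap.stack.analyte_layer.thickness
        if not np.isfinite(th):
            th = 5e-9
    if elevation + th > fmap.y[-1]:
        raise RangeError("elevation lies outside the simulated domain")
    if elevation == 0:
        return 1.0
    top = _band_average_intensity(fmap, elevation, elevation + th)
    ref = _band_average_intensity(fmap, 0.0, th)
    return float(top / ref)


def parallel_energy_fraction(fmap: FieldMap, region="membrane") -> float:
    """Fraction of the electric energy in ``region`` carried by the in-plane
    (across-slot) field component E_par; the E_par and E_perp fractions sum to
    one exactly."""
    _require_solved(fmap)
    mask = fmap.region_mask(region)
    if not mask.any():
        raise InputError("region selects no cells")
    w = np.real(fmap.eps)[mask] * fmap.cell_areas[mask]
    par = np.sum(w * np.abs(fmap.ex[mask]) ** 2)
    tot = np.sum(w * (np.abs(fmap.ex[mask]) ** 2 + np.abs(fmap.ey[mask]) ** 2))
    if tot == 0:
        raise InputError("region carries no field energy")
    return float(par / tot)


def sensitivity_kernel(
    geometry: SensorGeometry, stack: LayerStack, resolution: int = 24,
    fmap: FieldMap | None = None, per_length: bool = False, **kw
):
    """Per-region dC/d(eps_r) weights in farads (total, unless ``per_length``).

    By the stationarity of the electrostatic energy functional the exact
    first-order sensitivity of the capacitance to a uniform permittivity
    change of one region is the field energy stored there, so
    ``sum_r eps_r * weight_r == C`` holds to machine precision and a uniform
    change of all regions reproduces the global-scaling derivative.
    """
    if fmap is None:
        fmap = solve_potential(geometry, stack, resolution, **kw)
    _require_solved(fmap)
    scale = EPS0 if per_length else EPS0 * geometry.slot_length
    out = {}
    for name in np.unique(fmap.labels.astype(str)):
        if name == "metal":
            continue
        mask = fmap.labels == name
        out[name] = scale * complex(np.sum(fmap.cell_weights[mask]))
    return out, fmap


# ---------------------------------------------------------------------------
# analytic references (coplanar-strip closed forms)
# ---------------------------------------------------------------------------


def coplanar_centerline_intensity(y, slot_width: float):
    """Intensity ratio |E(y)|^2 / |E(0)|^2 on the centreline of an ideal
    zero-thickness slot between coplanar half-planes: 1 / (1 + (2y/s)^2)."""
    y = np.asarray(y, float)
    return 1.0 / (1.0 + (2.0 * y / slot_width) ** 2)


def coplanar_strip_capacitance(slot_width: float, strip_width: float, eps_r: float = 1.0) -> float:
    """Full-space capacitance per unit length of two zero-thickness coplanar
    strips of width ``strip_width`` separated by ``slot_width``, from the
    conformal-map elliptic-integral solution."""
    from scipy.special import ellipk

    a = slot_width / 2.0
    b = a + strip_width
    k = a / b
    kp = np.sqrt(1.0 - k * k)
    # per half-space C = eps K(k')/(2 K(k)); both half-spaces in parallel
    return eps_r * EPS0 * ellipk(kp * kp) / ellipk(k * k)
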