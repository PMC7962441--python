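"""Pennes bio-heat solver on the gelatin-phantom geometry.

The phantom is a cylinder (default 20 mm diameter, 11 mm thick) irradiated
from the top.  Heat transport is conduction plus the Beer-Lambert
volumetric source from :mod:`fracptt.optics`:

    rho*Cp * dT/dt = div(k grad T) + Q,

with a convective (Robin) condition ``-n.(-k grad T) = h (T - T_air)`` on
the irradiated top face and zero-flux (insulated) conditions on all other
faces.  The advection term of the general Pennes form carries velocity
``u = 0`` for a solid phantom and is kept only as a declared constant; no
perfusion term is modelled.

Discretisation is a conservative cell-centred finite-volume scheme on a
uniform grid.  Three grid symmetries are supported: ``full3d`` and
``quarter3d`` Cartesian grids with a voxelised cylinder wall, and an
``axisym_rz`` radial grid valid for rotationally symmetric (flat-beam)
sources.  Time integration is an explicit forward-Euler reference scheme
(monotone under the CFL bound) or an unconditionally stable Douglas-Gunn
alternating-direction-implicit (ADI) scheme for long exposures.

Interface units: mm, s, W, degC; material constants are given in their
conventional SI units and converted internally to the mm system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

from .optics import BeamSpec, HeatSource, heat_source, irradiance_field

__all__ = [
    "MaterialProps",
    "Symmetry",
    "PhantomGeometry",
    "TemperatureHistory",
    "NumericalFailure",
    "stability_limit",
    "PennesSolver",
    "solve",
]


class NumericalFailure(RuntimeError):
    """Raised when the field develops NaN/Inf or runaway oscillations."""


@dataclass(frozen=True)
class MaterialProps:
    """Thermo-optical constants of the absorbing gelatin phantom.

    Defaults are the study's phantom values: a strongly absorbing dye-loaded
    gelatin (mu_a = 1/mm) initially at refrigerator temperature (5 degC)
    under 20 degC ambient air, melting at 35 degC.
    """

    mu_a_mm: float = 1.0  # absorption coefficient, 1/mm
    rho_kg_m3: float = 1060.0
    cp_J_kgK: float = 3600.0
    k_W_mK: float = 0.303
    h_W_m2K: float = 10.0  # top-surface convective coefficient
    T_air_C: float = 20.0
    T_init_C: float = 5.0
    melt_threshold_C: float = 35.0
    advection_velocity_m_s: float = 0.0  # solid phantom: fixed 0

    def __post_init__(self) -> None:
        if min(self.rho_kg_m3, self.cp_J_kgK, self.k_W_mK) <= 0:
            raise ValueError("rho, Cp and k must all be positive")
        if self.h_W_m2K < 0 or self.mu_a_mm < 0:
            raise ValueError("h and mu_a must be >= 0")
        if self.advection_velocity_m_s != 0.0:
            raise ValueError("advection velocity is fixed to 0 for the solid phantom")

    # conversions to the internal mm / s / W / degC system
    @property
    def k_mm(self) -> float:  # W/(mm K)
        return self.k_W_mK * 1e-3

    @property
    def vol_heat_capacity_mm(self) -> float:  # J/(mm^3 K)
        return self.rho_kg_m3 * self.cp_J_kgK * 1e-9

    @property
    def h_mm(self) -> float:  # W/(mm^2 K)
        return self.h_W_m2K * 1e-6

    @property
    def alpha_mm2_s(self) -> float:  # thermal diffusivity, mm^2/s
        return self.k_mm / self.vol_heat_capacity_mm


class Symmetry(str, Enum):
    FULL3D = "full3d"
    QUARTER3D = "quarter3d"
    AXISYM_RZ = "axisym_rz"


@dataclass(frozen=True)
class PhantomGeometry:
    diameter_mm: float = 20.0
    thickness_mm: float = 11.0
    dx_mm: float = 0.1
    symmetry: Symmetry = Symmetry.QUARTER3D

    def __post_init__(self) -> None:
        object.__setattr__(self, "symmetry", Symmetry(self.symmetry))
        if self.diameter_mm <= 0 or self.thickness_mm <= 0 or self.dx_mm <= 0:
            raise ValueError("geometry dimensions must be positive")


def stability_limit(geometry: PhantomGeometry, material: MaterialProps) -> float:
    """Largest explicit time step, ``dx^2 / (6 alpha)`` for the 3-D scheme (s)."""
    if geometry.dx_mm <= 0:
        raise ValueError("dx must be positive")
    return geometry.dx_mm**2 / (6.0 * material.alpha_mm2_s)


# --------------------------------------------------------------------------
# grids


class _CartesianGrid:
    """Cell-centred Cartesian grid over the (possibly quarter) cylinder."""

    def __init__(self, geometry: PhantomGeometry):
        dx = geometry.dx_mm
        R = geometry.diameter_mm / 2.0
        nz = max(1, round(geometry.thickness_mm / dx))
        if geometry.symmetry is Symmetry.QUARTER3D:
            n = max(1, round(R / dx))
            x = (np.arange(n) + 0.5) * dx
            self.sym_factor = 4.0
        else:
            n = 2 * max(1, round(R / dx))
            x = (np.arange(n) + 0.5) * dx - R
            self.sym_factor = 1.0
        self.geometry = geometry
        self.dx = dx
        self.x = x
        self.y = x.copy()
        self.z = (np.arange(nz) + 0.5) * dx
        xc, yc = np.meshgrid(self.x, self.y, indexing="ij")
        inside = (xc**2 + yc**2) <= R**2 + 1e-12
        self.mask = np.repeat(inside[:, :, None], nz, axis=2)
        self.shape = self.mask.shape
        # face transmissivity: 1 between two active cells, else 0
        self.fx = (self.mask[1:, :, :] & self.mask[:-1, :, :]).astype(float)
        self.fy = (self.mask[:, 1:, :] & self.mask[:, :-1, :]).astype(float)
        self.fz = (self.mask[:, :, 1:] & self.mask[:, :, :-1]).astype(float)
        self.cell_volume = dx**3
        self.top_area = dx**2

    def source_array(self, hs: HeatSource) -> np.ndarray:
        """Cell-averaged Q (W/mm^3): 3x3 lateral supersampling, exact z average."""
        dx, mu = self.dx, hs.mu_a_mm
        offs = np.array([-dx / 3.0, 0.0, dx / 3.0])
        surf = np.zeros(self.shape[:2])
        for ox in offs:
            for oy in offs:
                xs, ys = np.meshgrid(self.x + ox, self.y + oy, indexing="ij")
                surf += hs.field.surface(xs, ys)
        surf /= offs.size**2
        z0 = self.z - dx / 2.0
        z1 = self.z + dx / 2.0
        if mu > 0:
            zfac = (np.exp(-mu * z0) - np.exp(-mu * z1)) / (mu * dx)
        else:
            zfac = np.zeros_like(self.z)
        Q = mu * surf[:, :, None] * zfac[None, None, :]
        Q[~self.mask] = 0.0
        return Q


class _AxisymGrid:
    """Cell-centred r-z grid for rotationally symmetric problems."""

    def __init__(self, geometry: PhantomGeometry):
        dx = geometry.dx_mm
        R = geometry.diameter_mm / 2.0
        nr = max(1, round(R / dx))
        nz = max(1, round(geometry.thickness_mm / dx))
        self.geometry = geometry
        self.dx = dx
        self.r = (np.arange(nr) + 0.5) * dx
        self.z = (np.arange(nz) + 0.5) * dx
        rf = np.arange(nr + 1) * dx  # radial faces
        self.ring_area = math.pi * (rf[1:] ** 2 + rf[:-1] ** 2) * 0.0  # placeholder
        self.axial_area = math.pi * (rf[1:] ** 2 - rf[:-1] ** 2)  # per ring, mm^2
        self.radial_face_area = 2.0 * math.pi * rf[1:-1] * dx  # between ring i,i+1 per dz
        self.cell_volume = self.axial_area * dx  # (nr,) mm^3
        self.mask = np.ones((nr, nz), dtype=bool)
        self.shape = self.mask.shape
        self.sym_factor = 1.0

    def source_array(self, hs: HeatSource) -> np.ndarray:
        dx, mu = self.dx, hs.mu_a_mm
        nr = len(self.r)
        # area-weighted radial supersampling (4 sub-annuli per cell)
        surf = np.zeros(nr)
        rf0 = self.r - dx / 2.0
        for s in range(4):
            rs_in = rf0 + s * dx / 4.0
            rs_out = rs_in + dx / 4.0
            rmid = np.sqrt((rs_in**2 + rs_out**2) / 2.0)
            w = (rs_out**2 - rs_in**2) / ((rf0 + dx) ** 2 - rf0**2)
            surf += w * hs.field.surface(rmid, np.zeros_like(rmid))
        z0 = self.z - dx / 2.0
        z1 = self.z + dx / 2.0
        if mu > 0:
            zfac = (np.exp(-mu * z0) - np.exp(-mu * z1)) / (mu * dx)
        else:
            zfac = np.zeros_like(self.z)
        return mu * surf[:, None] * zfac[None, :]


def _make_grid(geometry: PhantomGeometry):
    if geometry.symmetry is Symmetry.AXISYM_RZ:
        return _AxisymGrid(geometry)
    return _CartesianGrid(geometry)


# --------------------------------------------------------------------------
# history container


@dataclass
class TemperatureHistory:
    """Stored temperature fields plus the running per-voxel peak.

    ``frames[i]`` is the field at ``times[i]`` on the solver grid
    (quarter/full Cartesian ``(nx, ny, nz)`` or axisymmetric ``(nr, nz)``).
    """

    times: np.ndarray
    frames: list
    peak_map: np.ndarray
    geometry: PhantomGeometry
    material: MaterialProps
    ledger: pd.DataFrame
    coords: dict = dc_field(default_factory=dict)
    meta: dict = dc_field(default_factory=dict)

    @property
    def symmetry(self) -> Symmetry:
        return self.geometry.symmetry

    @property
    def z_mm(self) -> np.ndarray:
        return self.coords["z"]

    def axis_peak_profile(self):
        """(z, peak T) along the central axis (nearest-to-axis cell column)."""
        if self.symmetry is Symmetry.AXISYM_RZ:
            return self.z_mm, self.peak_map[0, :]
        i = int(np.argmin(np.abs(self.coords["x"])))
        j = int(np.argmin(np.abs(self.coords["y"])))
        return self.z_mm, self.peak_map[i, j, :]

    def _mirror_surface(self, plane: np.ndarray) -> np.ndarray:
        """Expand a quarter-plane surface map to the full plane."""
        top = np.concatenate([plane[::-1, ::-1], plane[::-1, :]], axis=1)
        bot = np.concatenate([plane[:, ::-1], plane], axis=1)
        return np.concatenate([top, bot], axis=0)

    def surface_map(self, index: int = -1):
        """Full-plane surface (z=0 layer) temperature map and its x, y coords."""
        if self.symmetry is Symmetry.AXISYM_RZ:
            raise ValueError("surface_map needs a Cartesian run; use frames[i][:, 0]")
        plane = self.frames[index][:, :, 0]
        if self.symmetry is Symmetry.QUARTER3D:
            full = self._mirror_surface(plane)
            x = np.concatenate([-self.coords["x"][::-1], self.coords["x"]])
            y = np.concatenate([-self.coords["y"][::-1], self.coords["y"]])
        else:
            full, x, y = plane, self.coords["x"], self.coords["y"]
        return full, x, y

    def peak_surface_T(self, index: int = -1) -> float:
        """Maximum surface temperature of the stored frame ``index``."""
        if self.symmetry is Symmetry.AXISYM_RZ:
            return float(self.frames[index][:, 0].max())
        return float(self.frames[index][:, :, 0].max())

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            times=self.times,
            peak_map=self.peak_map,
            frames=np.stack(self.frames),
            symmetry=str(self.symmetry.value),
            **{f"coord_{k}": v for k, v in self.coords.items()},
        )


# --------------------------------------------------------------------------
# solver


class PennesSolver:
    """Conservative finite-volume integrator for one phantom problem.

    Normally built via :func:`solve`; the lower-level constructor accepts a
    raw cell-averaged source array so single steps and scheme properties
    can be exercised directly.
    """

    def __init__(
        self,
        geometry: PhantomGeometry,
        material: MaterialProps,
        Q_W_mm3: Optional[np.ndarray] = None,
        top_robin: bool = True,
    ):
        self.geometry = geometry
        self.material = material
        self.grid = _make_grid(geometry)
        g, m = self.grid, material
        self.Q = np.zeros(g.shape) if Q_W_mm3 is None else np.asarray(Q_W_mm3, float)
        if self.Q.shape != g.shape:
            raise ValueError(f"source shape {self.Q.shape} != grid shape {g.shape}")
        self.C = m.vol_heat_capacity_mm  # J/(mm^3 K)
        self.kappa = m.k_mm  # W/(mm K)
        # series resistance of half-cell conduction + surface convection
        if top_robin and m.h_mm > 0:
            self.U = 1.0 / (1.0 / m.h_mm + (g.dx / 2.0) / self.kappa)
        else:
            self.U = 0.0
        if isinstance(g, _AxisymGrid):
            self._absorbed_power = float(np.sum(self.Q * g.cell_volume[:, None]))
        else:
            self._absorbed_power = float(np.sum(self.Q[g.mask]) * g.cell_volume) * g.sym_factor

    # -- stability ---------------------------------------------------------
    def max_stable_dt(self) -> float:
        g, dx = self.grid, self.grid.dx
        if isinstance(g, _AxisymGrid):
            # per-cell conductance sum (radial + axial + Robin top)
            nr, nz = g.shape
            G = np.zeros(g.shape)
            A_r = g.radial_face_area  # (nr-1,)
            G[:-1, :] += (self.kappa * A_r / dx)[:, None]
            G[1:, :] += (self.kappa * A_r / dx)[:, None]
            G[:, :-1] += (self.kappa * g.axial_area / dx)[:, None]
            G[:, 1:] += (self.kappa * g.axial_area / dx)[:, None]
            G[:, 0] += self.U * g.axial_area
            C_cell = self.C * g.cell_volume[:, None]
            return float((C_cell / G).min())
        # uniform Cartesian: 6 conductive faces + Robin top (worst-case cell)
        return self.C * dx**3 / (6.0 * self.kappa * dx + self.U * dx**2)

    # -- single explicit step ---------------------------------------------
    def step(self, T: np.ndarray, dt: float):
        """One explicit conservative update.  Returns (T_new, convective_loss_J)."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        if dt > self.max_stable_dt() * (1.0 + 1e-9):
            raise ValueError(
                f"explicit step dt={dt:.4g}s exceeds stability limit "
                f"{self.max_stable_dt():.4g}s"
            )
        g, C, k = self.grid, self.C, self.kappa
        dx = g.dx
        if isinstance(g, _AxisymGrid):
            net = np.zeros_like(T)  # W per cell
            Fr = k * (T[1:, :] - T[:-1, :]) / dx * g.radial_face_area[:, None]
            net[:-1, :] += Fr
            net[1:, :] -= Fr
            Fz = k * (T[:, 1:] - T[:, :-1]) / dx * g.axial_area[:, None]
            net[:, :-1] += Fz
            net[:, 1:] -= Fz
            q_top = self.U * (T[:, 0] - self.material.T_air_C) * g.axial_area
            net[:, 0] -= q_top
            V = g.cell_volume[:, None]
            T_new = T + dt * (net / (C * V) + self.Q / C)
            loss = float(q_top.sum()) * dt
            return T_new, loss
        net = np.zeros_like(T)
        d = (T[1:, :, :] - T[:-1, :, :]) * g.fx
        net[:-1, :, :] += d
        net[1:, :, :] -= d
        d = (T[:, 1:, :] - T[:, :-1, :]) * g.fy
        net[:, 1:, :] -= d
        net[:, :-1, :] += d
        d = (T[:, :, 1:] - T[:, :, :-1]) * g.fz
        net[:, :, 1:] -= d
        net[:, :, :-1] += d
        # net currently in K units * (k*dx) flux scale: flux = k*dT/dx*dx^2 = k*dx*dT
        q_top = self.U * (T[:, :, 0] - self.material.T_air_C) * g.mask[:, :, 0]
        T_new = T + dt * ((k / (C * dx * dx)) * net + self.Q / C)
        T_new[:, :, 0] -= dt * q_top / (C * dx)
        T_new[~g.mask] = self.material.T_init_C
        loss = float(q_top.sum()) * g.top_area * dt * g.sym_factor
        return T_new, loss

    # -- ADI (Douglas-Gunn) ------------------------------------------------
    def _adi_ops(self):
        """1-D operator coefficient triplets (lower, diag, upper) per axis, 1/s."""
        g = self.grid
        if isinstance(g, _AxisymGrid):
            raise NotImplementedError("ADI is implemented for Cartesian grids")
        kap = self.kappa / (self.C * g.dx * g.dx)  # 1/s
        ops = []
        for axis, f in ((0, g.fx), (1, g.fy), (2, g.fz)):
            lower = np.zeros(g.shape)
            upper = np.zeros(g.shape)
            sl_lo = [slice(None)] * 3
            sl_lo[axis] = slice(1, None)
            sl_up = [slice(None)] * 3
            sl_up[axis] = slice(None, -1)
            lower[tuple(sl_lo)] = kap * f
            upper[tuple(sl_up)] = kap * f
            diag = -(lower + upper)
            if axis == 2 and self.U > 0:
                diag[:, :, 0] -= self.U / (self.C * g.dx) * g.mask[:, :, 0]
            ops.append((lower, diag, upper))
        return ops

    @staticmethod
    def _apply_tridiag(op, T, axis):
        lower, diag, upper = op
        out = diag * T
        sl_c = [slice(None)] * 3
        sl_n = [slice(None)] * 3
        sl_c[axis], sl_n[axis] = slice(1, None), slice(None, -1)
        out[tuple(sl_c)] += lower[tuple(sl_c)] * T[tuple(sl_n)]
        sl_c[axis], sl_n[axis] = slice(None, -1), slice(1, None)
        out[tuple(sl_c)] += upper[tuple(sl_c)] * T[tuple(sl_n)]
        return out

    @staticmethod
    def _solve_tridiag(lower, diag, upper, rhs, axis):
        """Thomas algorithm along ``axis``, vectorised over the others."""
        a = np.moveaxis(lower, axis, -1).copy()
        b = np.moveaxis(diag, axis, -1).copy()
        c = np.moveaxis(upper, axis, -1).copy()
        d = np.moveaxis(rhs, axis, -1).copy()
        n = d.shape[-1]
        for i in range(1, n):
            w = a[..., i] / b[..., i - 1]
            b[..., i] -= w * c[..., i - 1]
            d[..., i] -= w * d[..., i - 1]
        d[..., -1] /= b[..., -1]
        for i in range(n - 2, -1, -1):
            d[..., i] = (d[..., i] - c[..., i] * d[..., i + 1]) / b[..., i]
        return np.moveaxis(d, -1, axis)

    def step_adi(self, T: np.ndarray, dt: float):
        """One Douglas-Gunn ADI step (unconditionally stable, ~2nd order)."""
        g = self.grid
        ops = self._ops_cache if hasattr(self, "_ops_cache") else self._adi_ops()
        self._ops_cache = ops
        gam = dt / 2.0
        f = self.Q / self.C + np.where(
            g.mask, 0.0, 0.0
        )  # volumetric forcing, K/s
        # constant part of the Robin term
        robin_const = np.zeros(g.shape)
        if self.U > 0:
            robin_const[:, :, 0] = (
                self.U / (self.C * g.dx) * self.material.T_air_C * g.mask[:, :, 0]
            )
        A = [self._apply_tridiag(op, T, ax) for ax, op in enumerate(ops)]
        rhs = T + gam * A[0] + dt * (A[1] + A[2]) + dt * (f + robin_const)
        ident = np.ones(g.shape)
        t1 = self._solve_tridiag(-gam * ops[0][0], ident - gam * ops[0][1], -gam * ops[0][2], rhs, 0)
        t2 = self._solve_tridiag(
            -gam * ops[1][0], ident - gam * ops[1][1], -gam * ops[1][2], t1 - gam * A[1], 1
        )
        t3 = self._solve_tridiag(
            -gam * ops[2][0], ident - gam * ops[2][1], -gam * ops[2][2], t2 - gam * A[2], 2
        )
        t3[~g.mask] = self.material.T_init_C
        q0 = self.U * (T[:, :, 0] - self.material.T_air_C) * g.mask[:, :, 0]
        q1 = self.U * (t3[:, :, 0] - self.material.T_air_C) * g.mask[:, :, 0]
        loss = float((q0 + q1).sum()) * 0.5 * g.top_area * dt * g.sym_factor
        return t3, loss

    @property
    def absorbed_power_W(self) -> float:
        return self._absorbed_power


def _stored_energy(grid, material, T) -> float:
    dT = T - material.T_init_C
    if isinstance(grid, _AxisymGrid):
        return float(np.sum(dT * grid.cell_volume[:, None])) * material.vol_heat_capacity_mm
    return (
        float(np.sum(dT[grid.mask]))
        * grid.cell_volume
        * material.vol_heat_capacity_mm
        * grid.sym_factor
    )


def solve(
    beam: BeamSpec,
    geometry: PhantomGeometry,
    material: MaterialProps,
    duration_s: float = 15.0,
    store_every_s: float = 1.0,
    scheme: str = "explicit",
    dt: Optional[float] = None,
) -> TemperatureHistory:
    """Integrate the phantom problem and return its temperature history.

    Frames are stored every ``store_every_s`` seconds (plus the initial and
    final fields); the running per-voxel peak and a global energy ledger
    (absorbed optical energy vs stored heat + convective losses) are
    maintained throughout.
    """
    if duration_s < 0:
        raise ValueError("duration must be >= 0")
    if geometry.symmetry is Symmetry.AXISYM_RZ and beam.mode.value != "flat":
        raise ValueError("axisymmetric grid supports the flat beam only")
    field = irradiance_field(beam, material.mu_a_mm)
    hs = heat_source(field)
    solver = PennesSolver(geometry, material)
    solver.Q = solver.grid.source_array(hs)
    if isinstance(solver.grid, _AxisymGrid):
        solver._absorbed_power = float(np.sum(solver.Q * solver.grid.cell_volume[:, None]))
    else:
        solver._absorbed_power = (
            float(np.sum(solver.Q[solver.grid.mask])) * solver.grid.cell_volume
        ) * solver.grid.sym_factor
    return _integrate(solver, duration_s, store_every_s, scheme, dt, beam)


def _integrate(
    solver: PennesSolver,
    duration_s: float,
    store_every_s: float,
    scheme: str = "explicit",
    dt: Optional[float] = None,
    beam: Optional[BeamSpec] = None,
) -> TemperatureHistory:
    g, m = solver.grid, solver.material
    T = np.full(g.shape, m.T_init_C, dtype=float)
    if isinstance(g, _CartesianGrid):
        T[~g.mask] = m.T_init_C
    peak = T.copy()
    frames = [T.copy()]
    times = [0.0]
    ledger_rows = [dict(time_s=0.0, absorbed_J=0.0, stored_J=0.0, lost_J=0.0)]
    if scheme == "explicit":
        dt_use = 0.9 * solver.max_stable_dt() if dt is None else dt
        stepper = solver.step
    elif scheme == "adi":
        dt_use = (store_every_s / 10.0 if store_every_s > 0 else 0.1) if dt is None else dt
        stepper = solver.step_adi
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    adiabatic_rate = float(solver.Q.max()) / solver.C  # K/s upper bound on heating
    lost = 0.0
    t = 0.0
    next_store = store_every_s if store_every_s > 0 else duration_s
    nstep = 0
    while t < duration_s - 1e-12:
        dt_step = min(dt_use, duration_s - t)
        if store_every_s > 0:
            dt_step = min(dt_step, next_store - t) if next_store > t else dt_step
        T, dloss = stepper(T, dt_step)
        lost += dloss
        t += dt_step
        nstep += 1
        np.maximum(peak, T, out=peak)
        if nstep % 50 == 0 or t >= duration_s - 1e-12:
            if not np.all(np.isfinite(T)):
                bad = np.argwhere(~np.isfinite(T))[0]
                raise NumericalFailure(
                    f"non-finite temperature at step {nstep}, cell {tuple(bad)}; "
                    f"reduce dt below {solver.max_stable_dt():.4g}s"
                )
            bound = max(m.T_init_C, m.T_air_C) + adiabatic_rate * t + 1e-6
            if T.max() > bound:
                raise NumericalFailure(
                    f"temperature {T.max():.2f} exceeds adiabatic bound {bound:.2f} "
                    f"at t={t:.3f}s (instability); suggested dt <= "
                    f"{0.5 * solver.max_stable_dt():.4g}s"
                )
        store_now = (store_every_s > 0 and t >= next_store - 1e-9) or t >= duration_s - 1e-12
        if store_now:
            frames.append(T.copy())
            times.append(t)
            ledger_rows.append(
                dict(
                    time_s=t,
                    absorbed_J=solver.absorbed_power_W * t,
                    stored_J=_stored_energy(g, m, T),
                    lost_J=lost,
                )
            )
            while store_every_s > 0 and next_store <= t + 1e-9:
                next_store += store_every_s
    ledger = pd.DataFrame(ledger_rows)
    with np.errstate(invalid="ignore", divide="ignore"):
        ledger["closure"] = (ledger.stored_J + ledger.lost_J - ledger.absorbed_J) / ledger[
            "absorbed_J"
        ].where(ledger.absorbed_J > 0)
    coords = (
        dict(r=g.r, z=g.z)
        if isinstance(g, _AxisymGrid)
        else dict(x=g.x, y=g.y, z=g.z)
    )
    meta = dict(
        scheme=scheme,
        dt_s=dt_use,
        n_steps=nstep,
        absorbed_power_W=solver.absorbed_power_W,
        beam=None if beam is None else {
            "mode": beam.mode.value,
            "irradiance_W_cm2": beam.irradiance_W_cm2,
            "total_power_W": beam.power,
            "flat_profile": beam.flat_profile.value,
        },
    )
    return TemperatureHistory(
        times=np.asarray(times),
        frames=frames,
        peak_map=peak,
        geometry=solver.geometry,
        material=m,
        ledger=ledger,
        coords=coords,
        meta=meta,
    )
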