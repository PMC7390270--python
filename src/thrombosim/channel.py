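"""2D channel model of clot growth under pressure-driven flow.

A planar dimension-reduction of the spatial thrombus model: plasma flows
through a channel of height H (the vessel diameter) driven by a pressure
drop chosen to impose a target wall shear rate; a tissue-factor patch on the
bottom wall feeds activated factors (Ba) into the plasma through a
saturating surface-reaction boundary condition; seven clotting factors and
two platelet classes are advected, diffuse and react; fibrin polymer and
clot-bound platelets generate a Brinkman drag -mu/K_f u (Davies drag law for
fibrous media) that throttles and finally arrests the flow.

Numerics: MAC staggered grid; the quasi-steady Stokes-Brinkman system is
solved as one sparse saddle-point problem with Dirichlet pressure at inlet
and outlet (plasma inertia is negligible at these Reynolds numbers, ~2);
transport uses first-order upwind advection, central diffusion and
Patankar-type semi-implicit reactions, so all concentrations stay
nonnegative without clipping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .parameters import ParameterSet, load_parameters

__all__ = [
    "ChannelGeometry",
    "FlowParams",
    "PermeabilityParams",
    "SurfaceReactionParams",
    "FlowState",
    "ChannelModel",
    "ScenarioResult",
    "SingularResistance",
    "permeability_resistance",
    "inlet_pressure",
    "inlet_pressure_cylindrical",
    "platelet_mobility",
    "run_scenario",
]

#: Hydraulic-resistance level (mm^-2) marking a mechanically relevant clot;
#: the isosurface used to visualize and detect clot initiation.
CLOT_RESISTANCE_LEVEL = 10.0


class SingularResistance(ValueError):
    """Clot platelet density reached the packing limit; drag diverges."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Planar channel with a TF patch on the bottom wall."""

    L: float = 8.0            # mm, length
    H: float = 1.0            # mm, height (vessel diameter)
    patch_start: float = 2.0  # mm from inlet
    patch_width: float = 0.2  # mm
    h: float = 0.04           # mm, grid spacing

    def __post_init__(self):
        if min(self.L, self.H, self.patch_width, self.h) <= 0 or self.patch_start <= 0:
            raise ValueError("geometry lengths must be positive")
        if self.patch_start + self.patch_width > self.L:
            raise ValueError("patch extends past the outlet")
        for name, length in (("L", self.L), ("H", self.H)):
            if abs(round(length / self.h) - length / self.h) > 1e-9:
                raise ValueError(f"h must divide {name}")

    @property
    def nx(self) -> int:
        return int(round(self.L / self.h))

    @property
    def ny(self) -> int:
        return int(round(self.H / self.h))

    def patch_mask(self) -> np.ndarray:
        """Bottom-wall faces belonging to the patch, shape (nx,)."""
        xc = (np.arange(self.nx) + 0.5) * self.h
        return (xc >= self.patch_start) & (xc <= self.patch_start + self.patch_width)


@dataclass(frozen=True)
class FlowParams:
    rho: float = 1.06e-6  # kg/mm^3
    nu: float = 1.3       # mm^2/s
    gamma: float = 40.0   # s^-1, target clot-free wall shear rate
    p_out: float = 0.0

    @property
    def mu(self) -> float:
        """Dynamic viscosity, kg/(mm s)."""
        return self.rho * self.nu


@dataclass(frozen=True)
class PermeabilityParams:
    alpha: float = 6e-4     # mm, fibrin fiber radius
    phi_max: float = 400.0  # 1e9/L
    Fp_ref: float = 7000.0  # nM, fibrin-polymer normalization
    Fp_cap: float = 0.7     # cap of the normalized solid fraction


@dataclass(frozen=True)
class SurfaceReactionParams:
    alpha1: float = 7.7e4  # surface reaction amplitude
    beta1: float = 0.225   # nM^-1, saturation


def permeability_resistance(Fp, phi_c, params: PermeabilityParams = PermeabilityParams()):
    """Inverse hydraulic permeability 1/K_f (mm^-2) of the growing clot.

    Davies drag law for fibrous media with a platelet crowding factor:

        1/K_f = (16 / alpha^2) * Fp~^(3/2) * (1 + 56 Fp~^3)
                * (phi_max + phi_c) / (phi_max - phi_c),

    where Fp~ = min(Fp_cap, Fp / Fp_ref) is the normalized fibrin-polymer
    concentration.  Raises :class:`SingularResistance` at phi_c >= phi_max.
    """
    Fp = np.asarray(Fp, dtype=float)
    phi_c = np.asarray(phi_c, dtype=float)
    if np.any(phi_c >= params.phi_max):
        raise SingularResistance("phi_c reached phi_max; hydraulic drag diverges")
    fp = np.minimum(params.Fp_cap, Fp / params.Fp_ref)
    crowd = (params.phi_max + phi_c) / (params.phi_max - phi_c)
    return (16.0 / params.alpha**2) * fp**1.5 * (1.0 + 56.0 * fp**3) * crowd


def inlet_pressure(gamma: float, geom: ChannelGeometry, flow: FlowParams) -> float:
    """Pressure drop imposing clot-free wall shear ``gamma`` in the channel.

    For plane Poiseuille flow the wall shear is dp*H/(2*mu*L), so
    p_in = 2*L*gamma*mu/H (p_out = 0).
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    return 2.0 * geom.L * gamma * flow.mu / geom.H


def inlet_pressure_cylindrical(gamma: float, geom: ChannelGeometry,
                               flow: FlowParams) -> float:
    """Reference form p_in = 4*L*gamma*mu/D for a cylindrical vessel of
    diameter D = H (kept for comparison with the 3D configuration)."""
    return 4.0 * geom.L * gamma * flow.mu / geom.H


def platelet_mobility(phi_total, phi_max: float):
    """Saturating transport factor k = tanh(pi (1 - phi/phi_max)), >= 0."""
    return np.maximum(np.tanh(np.pi * (1.0 - np.asarray(phi_total) / phi_max)), 0.0)


# ---------------------------------------------------------------------------
# Stokes-Brinkman flow solver (MAC grid, coupled sparse solve)
# ---------------------------------------------------------------------------

@dataclass
class FlowState:
    u: np.ndarray       # (nx+1, ny) x-velocity at vertical faces, mm/s
    v: np.ndarray       # (nx, ny+1) y-velocity at horizontal faces (walls = 0)
    p: np.ndarray       # (nx, ny) pressure at cell centers
    flowrate: float     # mm^2/s per unit depth, at the outlet

    def wall_shear_bottom(self, h: float) -> np.ndarray:
        """Wall shear rate du/dy at y=0 per x-face.

        The one-sided estimate 2 u0 / h is exact for the mirror-ghost
        discretization of plane Poiseuille flow (whose discrete solution is
        the continuum parabola plus a h^2/4 offset)."""
        return 2.0 * self.u[:, 0] / h

    def divergence(self, h: float) -> np.ndarray:
        return (np.diff(self.u, axis=0) + np.diff(self.v, axis=1)) / h


class _StokesBrinkman:
    """Assembles/solves the steady Stokes-Brinkman saddle system once per
    resistance field.  Unknowns: interior-free u faces, interior v faces,
    all cell pressures; Dirichlet pressure at inlet/outlet, no-slip walls."""

    def __init__(self, geom: ChannelGeometry, flow: FlowParams):
        self.geom, self.flow = geom, flow
        nx, ny = geom.nx, geom.ny
        self.n_u = (nx + 1) * ny
        self.n_v = nx * (ny - 1)
        self.n_p = nx * ny
        self.Iu = np.arange(self.n_u).reshape(nx + 1, ny)
        self.Iv = self.n_u + np.arange(self.n_v).reshape(nx, ny - 1)
        self.Ip = self.n_u + self.n_v + np.arange(self.n_p).reshape(nx, ny)

    def solve(self, resistance: np.ndarray, p_in: float) -> FlowState:
        geom, flow = self.geom, self.flow
        nx, ny, h = geom.nx, geom.ny, geom.h
        mu = flow.mu
        R = np.asarray(resistance, dtype=float)
        if R.shape != (nx, ny):
            raise ValueError(f"resistance must have shape {(nx, ny)}")

        rows, cols, vals = [], [], []
        rhs = np.zeros(self.n_u + self.n_v + self.n_p)

        def add(r, c, v):
            r = np.ravel(r)
            rows.append(r)
            cols.append(np.ravel(c))
            vals.append(np.broadcast_to(np.ravel(np.asarray(v, dtype=float)), r.shape))

        c2 = mu / h**2
        # --- x momentum ------------------------------------------------
        i_idx, j_idx = np.meshgrid(np.arange(nx + 1), np.arange(ny), indexing="ij")
        diag = np.full((nx + 1, ny), 4.0)
        diag[0, :] -= 1.0    # zero-gradient ghost at inlet
        diag[-1, :] -= 1.0   # and outlet
        diag[:, 0] += 1.0    # no-slip wall ghosts
        diag[:, -1] += 1.0
        Rf = np.empty((nx + 1, ny))
        Rf[1:nx] = 0.5 * (R[:-1] + R[1:])
        Rf[0] = R[0]
        Rf[nx] = R[-1]
        add(self.Iu, self.Iu, c2 * diag + mu * Rf)
        m = i_idx >= 1
        add(self.Iu[m], self.Iu[i_idx[m] - 1, j_idx[m]], -c2)
        m = i_idx <= nx - 1
        add(self.Iu[m], self.Iu[i_idx[m] + 1, j_idx[m]], -c2)
        m = j_idx >= 1
        add(self.Iu[m], self.Iu[i_idx[m], j_idx[m] - 1], -c2)
        m = j_idx <= ny - 2
        add(self.Iu[m], self.Iu[i_idx[m], j_idx[m] + 1], -c2)
        # pressure gradient; the boundary faces sit half a cell from the
        # prescribed inlet/outlet pressures
        m = (i_idx >= 1) & (i_idx <= nx - 1)
        add(self.Iu[m], self.Ip[i_idx[m] - 1, j_idx[m]], -1.0 / h)
        add(self.Iu[m], self.Ip[i_idx[m], j_idx[m]], 1.0 / h)
        add(self.Iu[0, :], self.Ip[0, :], 2.0 / h)
        add(self.Iu[nx, :], self.Ip[nx - 1, :], -2.0 / h)
        rhs[self.Iu[0, :]] += 2.0 * p_in / h          # known inlet pressure
        rhs[self.Iu[nx, :]] -= 2.0 * flow.p_out / h   # known outlet pressure

        # --- y momentum (interior faces j=1..ny-1) ----------------------
        i_idx, j_idx = np.meshgrid(np.arange(nx), np.arange(1, ny), indexing="ij")
        diag = np.full((nx, ny - 1), 4.0)
        diag[0, :] -= 1.0
        diag[-1, :] -= 1.0
        Rf = 0.5 * (R[:, :-1] + R[:, 1:])
        add(self.Iv, self.Iv, c2 * diag + mu * Rf)
        m = i_idx >= 1
        add(self.Iv[m], self.Iv[i_idx[m] - 1, j_idx[m] - 1], -c2)
        m = i_idx <= nx - 2
        add(self.Iv[m], self.Iv[i_idx[m] + 1, j_idx[m] - 1], -c2)
        m = j_idx >= 2
        add(self.Iv[m], self.Iv[i_idx[m], j_idx[m] - 2], -c2)
        m = j_idx <= ny - 2
        add(self.Iv[m], self.Iv[i_idx[m], j_idx[m]], -c2)
        add(self.Iv, self.Ip[i_idx, j_idx], 1.0 / h)
        add(self.Iv, self.Ip[i_idx, j_idx - 1], -1.0 / h)

        # --- continuity --------------------------------------------------
        i_idx, j_idx = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        add(self.Ip, self.Iu[i_idx + 1, j_idx], 1.0 / h)
        add(self.Ip, self.Iu[i_idx, j_idx], -1.0 / h)
        m = j_idx <= ny - 2
        add(self.Ip[m], self.Iv[i_idx[m], j_idx[m]], 1.0 / h)
        m = j_idx >= 1
        add(self.Ip[m], self.Iv[i_idx[m], j_idx[m] - 1], -1.0 / h)

        n = self.n_u + self.n_v + self.n_p
        A = sp.csc_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(n, n))
        sol = spla.spsolve(A, rhs)
        if not np.all(np.isfinite(sol)):
            raise RuntimeError("flow solve produced non-finite values")
        u = sol[:self.n_u].reshape(nx + 1, ny)
        v = np.zeros((nx, ny + 1))
        v[:, 1:-1] = sol[self.n_u:self.n_u + self.n_v].reshape(nx, ny - 1)
        p = sol[self.n_u + self.n_v:].reshape(nx, ny)
        flowrate = float(u[-1, :].sum() * h)
        return FlowState(u=u, v=v, p=p, flowrate=flowrate)


# ---------------------------------------------------------------------------
# Coupled model
# ---------------------------------------------------------------------------

_TRANSPORTED = ("P", "T", "Ba", "A", "Fg", "F")  # Fp is immobile


@dataclass(frozen=True)
class ScenarioResult:
    initiation_time: float | None
    occlusion_time: float | None
    occluded: bool
    timeline: pd.DataFrame  # t_s, maxFp_nM, maxR_inv_mm2, flowrate_mm2_s
    t_end: float

    def __post_init__(self):
        if (self.initiation_time is not None and self.occlusion_time is not None
                and self.initiation_time > self.occlusion_time):
            raise ValueError("initiation must precede occlusion")


class ChannelModel:
    """Coupled flow + transport + surface-reaction integrator.

    Parameters come from a flow-tier :class:`~thrombosim.parameters.ParameterSet`
    (default ``table2``); plasma composition is controlled by ``phif0``
    (0 for normal pooled plasma, 300 for platelet-rich plasma).
    """

    def __init__(self, geom: ChannelGeometry = ChannelGeometry(),
                 params: ParameterSet | str = "table2", *,
                 gamma: float = 40.0, phif0: float | None = None,
                 alpha1: float | None = None, dt_max: float = 0.005,
                 flow_update_dt: float = 0.5):
        ps = params if isinstance(params, ParameterSet) else load_parameters(params)
        if ps.tier != "flow":
            raise ValueError(f"expected a flow-tier set, got {ps.tier!r}")
        self.geom = geom
        self.k = ps.values
        self.flow_params = FlowParams(rho=self.k["rho"], nu=self.k["nu"], gamma=gamma)
        self.perm = PermeabilityParams(alpha=self.k["alpha"], phi_max=self.k["phi_max"],
                                       Fp_ref=7000.0, Fp_cap=0.7)
        self.surface = SurfaceReactionParams(
            alpha1=self.k["alpha1"] if alpha1 is None else alpha1,
            beta1=self.k["beta1"])
        self.phif0 = self.k["phif0"] if phif0 is None else float(phif0)
        self.gamma = float(gamma)
        self.dt_max = dt_max
        self.flow_update_dt = flow_update_dt
        self._solver = _StokesBrinkman(geom, self.flow_params)
        self.p_in = inlet_pressure(gamma, geom, self.flow_params)
        self.reset()

    # -- state ---------------------------------------------------------

    def reset(self) -> None:
        nx, ny = self.geom.nx, self.geom.ny
        z = lambda: np.zeros((nx, ny))
        self.fields = {
            "P": np.full((nx, ny), self.k["P0"]),
            "T": z(), "Ba": z(),
            "A": np.full((nx, ny), self.k["A0"]),
            "Fg": np.full((nx, ny), self.k["Fg0"]),
            "F": z(), "Fp": z(),
        }
        self.phif = np.full((nx, ny), self.phif0)
        self.phic = z()
        self._patch = self.geom.patch_mask()
        self._dirichlet_mask = np.array([n in ("P", "A", "Fg") for n in _TRANSPORTED])
        self.phic[self._patch, 0] = self.k["phic0"]
        self.t = 0.0
        self._R_cache = None
        self.flow = self._solver.solve(self.resistance(), self.p_in)
        self.clot_free_flowrate = self.flow.flowrate
        self._R_at_solve = self.resistance()

    def resistance(self) -> np.ndarray:
        if self._R_cache is None:
            self._R_cache = permeability_resistance(self.fields["Fp"], self.phic,
                                                    self.perm)
        return self._R_cache

    @property
    def inlet_values(self) -> dict[str, float]:
        return {"P": self.k["P0"], "A": self.k["A0"], "Fg": self.k["Fg0"],
                "T": 0.0, "Ba": 0.0, "F": 0.0}

    # -- operators -------------------------------------------------------

    def _advect_diffuse(self, C: np.ndarray, D: float, c_in: np.ndarray,
                        dirichlet_inlet: np.ndarray, u: np.ndarray, v: np.ndarray,
                        face_factor_x: np.ndarray | None = None,
                        face_factor_y: np.ndarray | None = None) -> np.ndarray:
        """Flux divergence (per second) of upwind advection + central diffusion.

        Operates on a stack of species at once: ``C`` has shape
        (nspec, nx, ny), ``c_in`` the inlet concentrations (nspec,) and
        ``dirichlet_inlet`` a boolean mask (nspec,) of species held at their
        plasma level at the inlet.  ``face_factor_x/y`` optionally scale
        every face flux (platelet mobility); walls are impermeable and the
        outlet is upwinded.
        """
        nx, ny, h = self.geom.nx, self.geom.ny, self.geom.h
        ns = C.shape[0]
        cin = c_in.reshape(ns, 1)
        # x faces: advective + diffusive flux
        Fx = np.zeros((ns, nx + 1, ny))
        ui = u[1:-1]
        up = np.where(ui > 0, C[:, :-1], C[:, 1:])
        Fx[:, 1:-1] = ui * up - (D / h) * (C[:, 1:] - C[:, :-1])
        Fx[:, 0] = np.where(u[0] > 0, u[0] * cin, u[0] * C[:, 0])
        Fx[:, 0] -= dirichlet_inlet.reshape(ns, 1) * (2.0 * D / h) * (C[:, 0] - cin)
        Fx[:, -1] = np.where(u[-1] > 0, u[-1] * C[:, -1], 0.0)
        # y faces: interior only (walls impermeable)
        Fy = np.zeros((ns, nx, ny + 1))
        vi = v[:, 1:-1]
        up = np.where(vi > 0, C[:, :, :-1], C[:, :, 1:])
        Fy[:, :, 1:-1] = vi * up - (D / h) * (C[:, :, 1:] - C[:, :, :-1])
        if face_factor_x is not None:
            Fx *= face_factor_x
            Fy *= face_factor_y
        return -((Fx[:, 1:] - Fx[:, :-1]) + (Fy[:, :, 1:] - Fy[:, :, :-1])) / h

    def _apply_patch_bc(self, dt: float) -> None:
        """Saturating surface production of Ba on the patch faces.

        The Robin flux alpha1 (B0-Ba)/(1 + beta1 (B0-Ba)) is applied
        implicitly: the per-cell update solves its quadratic exactly, which
        is unconditionally stable and caps Ba at B0.
        """
        mask = self._patch
        if not mask.any() or self.surface.alpha1 == 0.0:
            return
        Ba = self.fields["Ba"]
        B0, b1 = self.k["B0"], self.surface.beta1
        c = dt * self.surface.alpha1 / self.geom.h
        d = B0 - Ba[mask, 0]
        if b1 == 0.0:
            x = d / (1.0 + c)
        else:
            q = 1.0 + c - d * b1
            x = (-q + np.sqrt(q * q + 4.0 * b1 * d)) / (2.0 * b1)
        Ba[mask, 0] = B0 - np.maximum(x, 0.0)

    def _react(self, dt: float) -> None:
        """Patankar semi-implicit volume kinetics (positivity preserving)."""
        f = self.fields
        k = self.k
        T, Ba, A, Fg = f["T"], f["Ba"], f["A"], f["Fg"]
        act = (k["k1"] * self.phic + k["k2"] * Ba + k["k3"] * T
               + k["k4"] * T**2 + k["k5"] * T**3)
        conv = act * f["P"]
        bprod = k["k7"] * self.phic + k["k8"] * T
        fgconv = k["k10"] * T * Fg / (k["K10"] + Fg)
        pact = k["k12"] * T + k["k13"] * self.phic

        f["P"] = f["P"] / (1.0 + dt * act)
        f["T"] = (T + dt * conv) / (1.0 + dt * k["k6"] * A)
        f["Ba"] = (Ba + dt * bprod * k["B0"]) / (1.0 + dt * (bprod + k["k9"] * A))
        f["A"] = A / (1.0 + dt * (k["k6"] * T + k["k9"] * Ba))
        f["Fg"] = Fg / (1.0 + dt * k["k10"] * T / (k["K10"] + Fg))
        f["F"] = (f["F"] + dt * fgconv) / (1.0 + dt * k["k11"])
        f["Fp"] = f["Fp"] + dt * k["k11"] * f["F"]
        new_phif = self.phif / (1.0 + dt * pact)
        self.phic = self.phic + (self.phif - new_phif)
        self.phif = new_phif

    def _platelet_faces(self):
        """Mobility factor on x and y faces from the total platelet load."""
        tot = self.phic + self.phif
        kx = np.empty((self.geom.nx + 1, self.geom.ny))
        kx[1:-1] = 0.5 * (tot[:-1] + tot[1:])
        kx[0], kx[-1] = tot[0], tot[-1]
        ky = np.zeros((self.geom.nx, self.geom.ny + 1))
        ky[:, 1:-1] = 0.5 * (tot[:, :-1] + tot[:, 1:])
        return (platelet_mobility(kx, self.perm.phi_max),
                platelet_mobility(ky, self.perm.phi_max))

    def step(self, dt: float) -> None:
        f = self.fields
        u, v = self.flow.u, self.flow.v
        inlet = self.inlet_values
        C = np.stack([f[name] for name in _TRANSPORTED])
        c_in = np.array([inlet[name] for name in _TRANSPORTED])
        C = C + dt * self._advect_diffuse(C, self.k["D"], c_in,
                                          self._dirichlet_mask, u, v)
        mx, my = self._platelet_faces()
        Phi = np.stack([self.phif, self.phic])
        Phi = Phi + dt * self._advect_diffuse(
            Phi, self.k["Dp"], np.array([self.phif0, 0.0]),
            np.array([True, False]), u, v, mx, my)
        new_phif, new_phic = Phi
        # bound platelets supplied at the injured wall (patch Dirichlet);
        # phic0 = 0 means no bound-platelet condition at all
        if self.k["phic0"] > 0.0:
            mask = self._patch
            kcell = platelet_mobility(self.phic[mask, 0] + self.phif[mask, 0],
                                      self.perm.phi_max)
            new_phic[mask, 0] += dt * kcell * self.k["Dp"] * (
                self.k["phic0"] - self.phic[mask, 0]) / (0.5 * self.geom.h**2)
        for i, name in enumerate(_TRANSPORTED):
            f[name] = np.maximum(C[i], 0.0)
        self.phif = np.maximum(new_phif, 0.0)
        self.phic = np.maximum(new_phic, 0.0)
        self._apply_patch_bc(dt)
        self._react(dt)
        self._R_cache = None
        self.t += dt

    def update_flow(self, rel_change: float = 0.01) -> None:
        """Re-solve the quasi-steady flow if the drag field moved enough."""
        R = self.resistance()
        scale = max(float(np.max(R)), CLOT_RESISTANCE_LEVEL)
        if np.max(np.abs(R - self._R_at_solve)) > rel_change * scale:
            self.flow = self._solver.solve(R, self.p_in)
            self._R_at_solve = R

    def stable_dt(self) -> float:
        umax = max(np.max(np.abs(self.flow.u)), np.max(np.abs(self.flow.v)), 1e-12)
        adv = 0.8 * self.geom.h / umax
        dif = 0.2 * self.geom.h**2 / max(self.k["D"], self.k["Dp"])
        return min(self.dt_max, adv, dif)

    # -- diagnostics ------------------------------------------------------

    def near_patch_mask(self) -> np.ndarray:
        g = self.geom
        xc = (np.arange(g.nx) + 0.5) * g.h
        margin = 2.0 * g.patch_width
        return (xc >= g.patch_start - margin) & (xc <= g.patch_start + g.patch_width + margin)

    def spanning_clot(self) -> bool:
        """True if some x-column exceeds the clot resistance level at every
        height (an occluding band)."""
        R = self.resistance()
        return bool(np.any(np.all(R >= CLOT_RESISTANCE_LEVEL, axis=1)))


def run_scenario(geom: ChannelGeometry = ChannelGeometry(),
                 params: ParameterSet | str = "table2", *,
                 gamma: float = 40.0, phif0: float | None = None,
                 alpha1: float | None = None, t_end: float = 300.0,
                 record_dt: float = 2.0, dt_max: float = 0.005,
                 flow_update_dt: float = 0.5) -> ScenarioResult:
    """Couple flow, transport and the patch reaction up to ``t_end``.

    Initiation is declared when the hydraulic resistance near the patch
    reaches the clot isosurface level (10 mm^-2); occlusion when a clot band
    spans the channel height and the flow rate drops below 1% of its
    clot-free value.  Returns the event times (None if not reached) and a
    coarse timeline of clot burden and flow rate.
    """
    model = ChannelModel(geom, params, gamma=gamma, phif0=phif0, alpha1=alpha1,
                         dt_max=dt_max, flow_update_dt=flow_update_dt)
    near = model.near_patch_mask()
    initiation = occlusion = None
    rows = []
    next_flow = next_rec = 0.0
    while model.t < t_end - 1e-9:
        if model.t >= next_rec:
            R = model.resistance()
            rows.append({"t_s": model.t,
                         "maxFp_nM": float(model.fields["Fp"][near].max()),
                         "maxR_inv_mm2": float(R[near].max()),
                         "flowrate_mm2_s": model.flow.flowrate})
            next_rec += record_dt
        dt = min(model.stable_dt(), t_end - model.t)
        model.step(dt)
        if model.t >= next_flow:
            model.update_flow()
            next_flow += flow_update_dt
        if initiation is None and model.resistance()[near].max() >= CLOT_RESISTANCE_LEVEL:
            initiation = model.t
        if (occlusion is None
                and model.flow.flowrate <= 0.01 * model.clot_free_flowrate
                and model.spanning_clot()):
            occlusion = model.t
            break
    R = model.resistance()
    rows.append({"t_s": model.t,
                 "maxFp_nM": float(model.fields["Fp"][near].max()),
                 "maxR_inv_mm2": float(R[near].max()),
                 "flowrate_mm2_s": model.flow.flowrate})
    return ScenarioResult(initiation_time=initiation, occlusion_time=occlusion,
                          occluded=occlusion is not None,
                          timeline=pd.DataFrame(rows), t_end=t_end)
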