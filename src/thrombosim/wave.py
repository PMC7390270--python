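"""Reduced one-equation model of thrombin propagation from an injured wall.

The spatial thrombus model collapses, under quasi-stationarity of the fast
factors, to a single reaction-diffusion equation for thrombin T(y, t) on the
coordinate y measured from the injured wall:

    dT/dt = D d2T/dy2 + Phi(T, y)

    Phi(T, y) = (k1*phi0 + k2*Ba(y) + k3*T + k4*T^2 + k5*T^3) * (P0 - T)
                - sigma(y) * T

The production factor lumps platelet-driven initiation (k1*phi0), the
surface-generated FIXa/FXa boundary layer Ba(y) = B0*exp(-Ba_decay*y), and
the thrombin amplification loop; (P0 - T) expresses prothrombin consumption
and sigma = k6*A0 + a*gamma the combined antithrombin sink and removal of
thrombin by a flow of wall shear rate gamma.

Phi is a quartic polynomial in T, so its equilibria, the sign of the wave
propagation integral int_{T0}^{T2} Phi dT, the shear-rate threshold gamma*
at which that sign flips, and the position where a growing clot stalls are
all available in closed form up to scalar root-finding, and are
cross-checked here against direct simulation of the PDE.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .parameters import ParameterSet, load_parameters

__all__ = [
    "WaveParams",
    "EquilibriumSet",
    "WaveField",
    "WaveCriterion",
    "DegenerateEquilibria",
    "CriterionUndefined",
    "ThresholdNotFound",
    "reaction_term",
    "ba_profile",
    "find_equilibria",
    "wave_criterion",
    "shear_threshold",
    "shear_threshold_closed_form",
    "simulate_wave",
    "occluded_fraction",
    "clot_final_size",
    "first_crossing_time",
    "front_positions",
    "front_speed",
]


class DegenerateEquilibria(RuntimeError):
    """Phi has no stable zero in [0, P0]."""


class CriterionUndefined(RuntimeError):
    """The propagation integral needs two distinct stable equilibria."""


class ThresholdNotFound(RuntimeError):
    """No sign change of the propagation integral inside the shear bracket."""


@dataclass(frozen=True)
class WaveParams:
    """Constants of the reduced thrombin-wave model."""

    k1: float        # (1e9/L)^-1 s^-1, platelet-driven production
    k2: float        # nM^-1 s^-1, production by surface FIXa/FXa
    k3: float        # nM^-1 s^-1, amplification, linear
    k4: float        # nM^-2 s^-1, amplification, quadratic
    k5: float        # nM^-3 s^-1, amplification, cubic
    k6: float        # nM^-1 s^-1, antithrombin inhibition
    P0: float        # nM, prothrombin level
    A0: float        # nM, antithrombin level
    B0: float        # nM, FIX+FX level at the wall
    phi0: float      # 1e9/L, platelet count
    a: float         # s/mm, removal-by-flow coefficient
    gamma: float     # s^-1, wall shear rate
    D: float         # mm^2/s, thrombin diffusivity
    Tstar: float = 200.0     # nM, occlusion threshold
    Ba_decay: float = 23.0259  # mm^-1, FIXa/FXa boundary-layer decay

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.P0 <= 0:
            raise ValueError("P0 must be positive")

    @classmethod
    def from_parameters(cls, source: ParameterSet | str = "table2-wave",
                        **overrides: float) -> "WaveParams":
        ps = source if isinstance(source, ParameterSet) else load_parameters(source)
        if ps.tier != "wave":
            raise ValueError(f"expected a wave-tier set, got {ps.tier!r}")
        if overrides:
            ps = ps.with_overrides(**overrides)
        return cls(**ps.values)

    @property
    def sigma(self) -> float:
        """Total thrombin sink k6*A0 + a*gamma (s^-1)."""
        return self.k6 * self.A0 + self.a * self.gamma

    def with_gamma(self, gamma: float) -> "WaveParams":
        return replace(self, gamma=float(gamma))


@dataclass(frozen=True)
class EquilibriumSet:
    """Zeros of Phi(., y) in [0, P0] with their stability."""

    roots: np.ndarray    # ascending
    stable: np.ndarray   # bool, same length

    @property
    def T0(self) -> float:
        """Lowest stable equilibrium (quiescent state)."""
        return float(self.roots[self.stable][0])

    @property
    def T2(self) -> float:
        """Highest stable equilibrium (clotted state)."""
        return float(self.roots[self.stable][-1])

    @property
    def bistable(self) -> bool:
        return int(np.count_nonzero(self.stable)) >= 2


@dataclass(frozen=True)
class WaveCriterion:
    propagates: bool
    integral: float  # nM^2/s, int_{T0}^{T2} Phi dT
    T0: float
    T2: float


@dataclass(frozen=True)
class WaveField:
    """Thrombin profile T(y, t) on a 1D grid from the injured wall."""

    y: np.ndarray      # mm, nodes
    times: np.ndarray  # s
    T: np.ndarray      # nM, shape (len(times), len(y))


# --------------------------------------------------------------------------
# The reaction polynomial
# --------------------------------------------------------------------------

def ba_profile(y, params: WaveParams):
    """Stationary FIXa/FXa boundary layer B0*exp(-Ba_decay*y)."""
    return params.B0 * np.exp(-params.Ba_decay * np.asarray(y, dtype=float))


def phi_coefficients(params: WaveParams, y: float = 0.0) -> np.ndarray:
    """Ascending coefficients of the quartic Phi(T, y) in T.

    With c0 = k1*phi0 + k2*Ba(y) and s = sigma(y):

        Phi = c0*P0 + (k3*P0 - c0 - s)*T + (k4*P0 - k3)*T^2
              + (k5*P0 - k4)*T^3 - k5*T^4
    """
    p = params
    c0 = p.k1 * p.phi0 + p.k2 * float(ba_profile(y, p))
    return np.array([
        c0 * p.P0,
        p.k3 * p.P0 - c0 - p.sigma,
        p.k4 * p.P0 - p.k3,
        p.k5 * p.P0 - p.k4,
        -p.k5,
    ])


def reaction_term(T, y, params: WaveParams):
    """Phi(T, y) in nM/s, vectorized over T and/or y."""
    T = np.asarray(T, dtype=float)
    p = params
    c = p.k1 * p.phi0 + p.k2 * ba_profile(y, p) + p.k3 * T + p.k4 * T**2 + p.k5 * T**3
    return c * (p.P0 - T) - p.sigma * T


def find_equilibria(params: WaveParams, y: float = 0.0,
                    scan_resolution: float = 1e-3) -> EquilibriumSet:
    """All zeros of Phi(., y) in [0, P0], located by sign scan + bisection.

    ``scan_resolution`` is relative to P0.  Stability follows the sign of
    dPhi/dT at the root.  Raises :class:`DegenerateEquilibria` if no stable
    zero exists.
    """
    coeffs = phi_coefficients(params, y)
    poly = np.polynomial.Polynomial(coeffs)
    dpoly = poly.deriv()
    grid = np.linspace(0.0, params.P0, int(np.ceil(1.0 / scan_resolution)) + 1)
    vals = poly(grid)
    roots: list[float] = []
    for g, v in ((grid[0], vals[0]), (grid[-1], vals[-1])):
        if v == 0.0:
            roots.append(float(g))
    sign_change = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    for i in sign_change:
        roots.append(float(brentq(poly, grid[i], grid[i + 1], xtol=1e-12 * params.P0)))
    # exact zeros landing on interior grid nodes
    interior_zero = np.nonzero(vals[1:-1] == 0.0)[0] + 1
    roots.extend(float(grid[i]) for i in interior_zero)
    roots = sorted(set(roots))
    if not roots:
        raise DegenerateEquilibria("Phi has no zero in [0, P0]")
    arr = np.array(roots)
    stable = dpoly(arr) < 0.0
    if not stable.any():
        raise DegenerateEquilibria("Phi has no stable zero in [0, P0]")
    return EquilibriumSet(arr, stable)


def wave_criterion(params: WaveParams, y: float = 0.0) -> WaveCriterion:
    """Sign of the propagation integral between the two stable equilibria.

    The wave connecting the quiescent state T0 to the clotted state T2
    advances (positive speed) exactly when int_{T0}^{T2} Phi dT > 0.  The
    integral is evaluated in closed form from the polynomial antiderivative.
    Raises :class:`CriterionUndefined` when Phi(., y) is not bistable.
    """
    eq = find_equilibria(params, y)
    if not eq.bistable:
        raise CriterionUndefined(
            f"Phi is not bistable at y={y}: stable roots {eq.roots[eq.stable]}"
        )
    integral = _phi_integral(params, y, eq.T0, eq.T2)
    return WaveCriterion(integral > 0.0, integral, eq.T0, eq.T2)


def _phi_integral(params: WaveParams, y: float, lo: float, hi: float) -> float:
    anti = np.polynomial.Polynomial(phi_coefficients(params, y)).integ()
    return float(anti(hi) - anti(lo))


def _propagation_sign(params: WaveParams, y: float) -> float:
    """+1 advance / -1 retreat, tolerating monostable parameter regions.

    When only the clotted (high) state is stable the wave trivially invades;
    when only the quiescent state survives it trivially retreats.
    """
    try:
        eq = find_equilibria(params, y)
    except DegenerateEquilibria:
        return -1.0
    if eq.bistable:
        return float(np.sign(_phi_integral(params, y, eq.T0, eq.T2)))
    return 1.0 if eq.T2 > 0.5 * params.P0 else -1.0


# --------------------------------------------------------------------------
# Shear-rate threshold
# --------------------------------------------------------------------------

def shear_threshold(params: WaveParams, y: float = 0.0, *,
                    gamma_max: float = 1e4, tol: float = 1e-3) -> float:
    """Critical wall shear rate gamma* above which the wave cannot advance.

    gamma* is the root in gamma of the propagation integral (equilibria
    recomputed at every gamma), bracketed on [0, gamma_max] and bisected to
    ``tol`` (s^-1).  Requires propagation at gamma = 0; raises
    :class:`ThresholdNotFound` with a bracket report if the integral never
    changes sign (e.g. a = 0, so sigma does not depend on gamma).
    """
    lo, hi = 0.0, float(gamma_max)
    s_lo = _propagation_sign(params.with_gamma(lo), y)
    if s_lo <= 0:
        raise ThresholdNotFound("no propagation at gamma=0; threshold undefined")
    s_hi = _propagation_sign(params.with_gamma(hi), y)
    if s_hi > 0:
        raise ThresholdNotFound(
            f"propagation persists on the whole bracket [0, {gamma_max}] "
            f"(sign at both ends: +1)"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _propagation_sign(params.with_gamma(mid), y) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def shear_threshold_closed_form(params: WaveParams, y: float = 0.0,
                                T2: float | None = None) -> float:
    """Closed-form gamma* under the approximation T0 ~ 0.

    Setting int_0^{T2} Phi dT = 0 with sigma = k6*A0 + a*gamma and solving
    for gamma gives

        gamma* = [ (k1*phi0 + k2*Ba)(P0*T2 - T2^2/2) + k3(P0*T2^2/2 - T2^3/3)
                   + k4(P0*T2^3/3 - T2^4/4) + k5(P0*T2^4/4 - T2^5/5)
                   - k6*A0*T2^2/2 ] / (a*T2^2/2)

    This is a comparison-only evaluator: it neglects the quiescent
    equilibrium shift (T0 > 0 whenever k1*phi0 + k2*Ba > 0) and holds T2
    fixed while gamma varies.  Use :func:`shear_threshold` for the model's
    own criterion.
    """
    p = params
    if p.a <= 0:
        raise ThresholdNotFound("a = 0: sigma does not depend on gamma")
    if T2 is None:
        T2 = find_equilibria(p.with_gamma(0.0), y).T2
    Ba = float(ba_profile(y, p))
    c0 = p.k1 * p.phi0 + p.k2 * Ba
    num = (c0 * (p.P0 * T2 - T2**2 / 2)
           + p.k3 * (p.P0 * T2**2 / 2 - T2**3 / 3)
           + p.k4 * (p.P0 * T2**3 / 3 - T2**4 / 4)
           + p.k5 * (p.P0 * T2**4 / 4 - T2**5 / 5)
           - p.k6 * p.A0 * T2**2 / 2)
    return num / (p.a * T2**2 / 2)


# --------------------------------------------------------------------------
# Direct simulation
# --------------------------------------------------------------------------

def simulate_wave(params: WaveParams, length: float = 1.0, t_end: float = 800.0,
                  *, h: float = 0.02, output_dt: float = 1.0,
                  T_init: np.ndarray | None = None, method: str = "lsoda",
                  rtol: float = 1e-6, atol: float = 1e-9) -> WaveField:
    """Method-of-lines integration of the reduced model.

    Zero-flux boundaries at both ends; T(y, 0) = 0 unless ``T_init`` is
    given (initiation then emerges from the k2*Ba(y) and k1*phi0 sources).
    The default domain is 1 mm, the vessel diameter, with the reference grid
    step h = 0.02 mm.

    ``method="lsoda"`` uses the adaptive stiff solver; ``method="rk2"`` a
    fixed-step Heun scheme with an automatically chosen stable step --
    preferable on fine grids (many nodes), where front-speed studies need
    h well below the intrinsic front width sqrt(D / reaction rate).
    """
    if length <= 0 or t_end <= 0:
        raise ValueError("length and t_end must be positive")
    n = int(round(length / h)) + 1
    y = np.linspace(0.0, length, n)
    c0 = params.k1 * params.phi0 + params.k2 * ba_profile(y, params)
    sig = params.sigma
    p = params
    D_h2 = params.D / h**2

    def rhs(t, T):
        lap = np.empty_like(T)
        lap[1:-1] = T[:-2] - 2.0 * T[1:-1] + T[2:]
        lap[0] = 2.0 * (T[1] - T[0])        # mirrored ghost: zero flux
        lap[-1] = 2.0 * (T[-2] - T[-1])
        prod = (c0 + p.k3 * T + p.k4 * T * T + p.k5 * T * T * T) * (p.P0 - T)
        return D_h2 * lap + prod - sig * T

    T0 = np.zeros(n) if T_init is None else np.asarray(T_init, dtype=float).copy()
    if T0.shape != (n,):
        raise ValueError(f"T_init must have shape ({n},)")
    times = np.arange(0.0, t_end + 0.5 * output_dt, output_dt)
    times = times[times <= t_end]
    if method == "rk2":
        T = _integrate_rk2(rhs, T0, times, p, h)
    else:
        sol = solve_ivp(rhs, (0.0, float(t_end)), T0, method="LSODA",
                        t_eval=times, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"wave integration failed: {sol.message}")
        T = sol.y.T
    return WaveField(y=y, times=times, T=np.maximum(T, 0.0))


def _integrate_rk2(rhs, T0, times, params: WaveParams, h: float) -> np.ndarray:
    """Fixed-step Heun integration; dt from diffusion and reaction bounds."""
    dpoly = np.polynomial.Polynomial(phi_coefficients(params, 0.0)).deriv()
    grid = np.linspace(0.0, params.P0, 201)
    rate = float(np.max(np.abs(dpoly(grid))))
    dt = 0.4 * min(h * h / (2.0 * params.D), 1.0 / max(rate, 1e-12))
    out = np.empty((times.size, T0.size))
    T = T0.copy()
    t = times[0]
    out[0] = T
    for i in range(1, times.size):
        target = times[i]
        while t < target - 1e-12:
            step = min(dt, target - t)
            k1 = rhs(t, T)
            k2 = rhs(t + step, T + step * k1)
            T = T + 0.5 * step * (k1 + k2)
            t += step
        out[i] = T
    return out


def first_crossing_time(field: WaveField, threshold: float) -> float | None:
    """First time max_y T(y, t) crosses ``threshold`` (linear interpolation)."""
    peak = field.T.max(axis=1)
    above = peak >= threshold
    if not above.any():
        return None
    j = int(np.argmax(above))
    if j == 0:
        return float(field.times[0])
    t0, t1 = field.times[j - 1], field.times[j]
    v0, v1 = peak[j - 1], peak[j]
    return float(t0 + (threshold - v0) / (v1 - v0) * (t1 - t0))


def occluded_fraction(field: WaveField, t: float, Tstar: float | None = None,
                      diameter: float | None = None) -> float:
    """Percent of the vessel diameter where T exceeds the occlusion level.

    The occupied measure is the trapezoid-weighted length of {y: T > T*} at
    the output time nearest ``t``; ``diameter`` defaults to the simulated
    domain length.
    """
    if not (field.times[0] <= t <= field.times[-1]):
        raise ValueError(f"t={t} outside the simulated range")
    Tstar = 200.0 if Tstar is None else Tstar
    i = int(np.argmin(np.abs(field.times - t)))
    profile = field.T[i]
    w = np.full(field.y.size, field.y[1] - field.y[0])
    w[0] *= 0.5
    w[-1] *= 0.5
    measure = float(w[profile > Tstar].sum())
    diameter = float(field.y[-1] - field.y[0]) if diameter is None else diameter
    return min(100.0 * measure / diameter, 100.0)


def clot_final_size(params: WaveParams, domain_length: float = 1.0,
                    tol: float = 1e-4) -> float:
    """Distance from the wall at which a growing clot stalls.

    The propagation integral is positive near the wall (where the Ba
    boundary layer boosts production) and decays with y; the clot stops at
    the smallest y where its sign flips.  If the sign is positive across the
    whole domain the domain length is returned.
    """
    if _propagation_sign(params, 0.0) <= 0:
        raise CriterionUndefined("no propagation at y=0")
    n = 64
    ys = np.linspace(0.0, domain_length, n + 1)
    signs = np.array([_propagation_sign(params, float(yy)) for yy in ys])
    flip = np.nonzero(signs <= 0)[0]
    if flip.size == 0:
        return float(domain_length)
    lo, hi = float(ys[flip[0] - 1]), float(ys[flip[0]])
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _propagation_sign(params, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# Front tracking (shared with the cascade-reduction comparison)
# --------------------------------------------------------------------------

def front_positions(field: WaveField, level: float) -> np.ndarray:
    """Outermost y where T crosses ``level``, per output time (NaN if none)."""
    out = np.full(field.times.size, np.nan)
    for i, profile in enumerate(field.T):
        above = profile >= level
        if not above.any():
            continue
        j = int(np.nonzero(above)[0][-1])
        if j == profile.size - 1:
            out[i] = field.y[-1]
        else:
            f = (profile[j] - level) / (profile[j] - profile[j + 1])
            out[i] = field.y[j] + f * (field.y[j + 1] - field.y[j])
    return out


def front_speed(field: WaveField, level: float,
                window: tuple[float, float] = (0.5, 1.0)) -> float:
    """Front speed (mm/s) from a linear fit of the level-set position.

    The fit uses the fraction of the run given by ``window`` (default: the
    second half).  NaN if the level set exists at fewer than three output
    times in the window.
    """
    pos = front_positions(field, level)
    t = field.times
    lo = t[0] + window[0] * (t[-1] - t[0])
    hi = t[0] + window[1] * (t[-1] - t[0])
    m = (t >= lo) & (t <= hi) & np.isfinite(pos)
    if m.sum() < 3:
        return float("nan")
    slope = np.polyfit(t[m], pos[m], 1)[0]
    return float(slope)
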