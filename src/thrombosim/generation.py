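"""Thrombin generation in motionless plasma.

A four-variable stiff ODE model of the thrombin-generation assay: factor Xa
is produced by the TF:VIIa trigger, by thrombin, and by thrombin-activated
platelets; prothrombin is converted to thrombin by FXa and by the
thrombin-driven amplification loop (linear + quadratic + cubic feedback);
antithrombin inhibits both FXa and thrombin.  State variables (all nM):

    d[Xa]/dt    = a1*TF*[VIIa]*([X]0-[Xa]) + a2*[IIa]*([X]0-[Xa])
                  + a3*phi0*[IIa]*([X]0-[Xa]) - a4*[Xa]*[ATIII]
    d[II]/dt    = -(b1*[Xa] + k3*[IIa] + k4*[IIa]^2 + k5*[IIa]^3)*[II]
    d[IIa]/dt   = +(b1*[Xa] + k3*[IIa] + k4*[IIa]^2 + k5*[IIa]^3)*[II]
                  - b2*[ATIII]*[IIa]
    d[ATIII]/dt = -a4*[Xa]*[ATIII] - b2*[IIa]*[ATIII]

phi0 is the platelet count in units of 1e9/L.  From the thrombin trace the
standard assay metrics are derived: peak, time to peak, endogenous thrombin
potential (ETP, the time integral of the curve) and lag time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .parameters import ParameterSet, load_parameters

__all__ = [
    "GenerationParams",
    "ThrombinCurve",
    "GenerationMetrics",
    "IntegrationFailure",
    "simulate_generation",
    "curve_metrics",
    "platelet_sweep",
]

#: Default lag-time threshold (nM), a common thrombin-generation convention.
DEFAULT_LAG_THRESHOLD = 2.0

_STATE_NAMES = ("Xa", "II", "IIa", "ATIII")


class IntegrationFailure(RuntimeError):
    """The ODE solver failed or produced a non-finite state variable."""


@dataclass(frozen=True)
class GenerationParams:
    """Rate constants and initial concentrations of the generation model."""

    a1: float   # nM^-2 s^-1, FX activation by TF:VIIa
    a2: float   # nM^-1 s^-1, FX activation by thrombin
    a3: float   # nM^-1 (1e9/L)^-1 s^-1, FX activation by platelets
    a4: float   # nM^-1 s^-1, FXa inhibition by antithrombin
    b1: float   # nM^-1 s^-1, prothrombin activation by FXa
    b2: float   # nM^-1 s^-1, thrombin inhibition by antithrombin
    k3: float   # nM^-1 s^-1
    k4: float   # nM^-2 s^-1
    k5: float   # nM^-3 s^-1
    TF: float   # nM
    VIIa: float  # nM
    X0: float   # nM
    II0: float  # nM
    ATIII0: float  # nM
    phi0: float  # 1e9/L platelet count

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    @classmethod
    def from_parameters(cls, source: ParameterSet | str = "table1",
                        **overrides: float) -> "GenerationParams":
        ps = source if isinstance(source, ParameterSet) else load_parameters(source)
        if ps.tier != "generation":
            raise ValueError(f"expected a generation-tier set, got {ps.tier!r}")
        if overrides:
            ps = ps.with_overrides(**overrides)
        return cls(**ps.values)

    def with_phi0(self, phi0: float) -> "GenerationParams":
        return replace(self, phi0=float(phi0))


@dataclass(frozen=True)
class ThrombinCurve:
    """A thrombin concentration trace on a strictly increasing time grid."""

    times: np.ndarray      # s
    IIa_values: np.ndarray  # nM

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.IIa_values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size == 0:
            raise ValueError("times and IIa_values must be equal-length 1D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "IIa_values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.times, "IIa_nM": self.IIa_values})


@dataclass(frozen=True)
class GenerationMetrics:
    peak: float          # nM
    time_to_peak: float  # s
    ETP: float           # nM*s
    lag_time: float | None  # s, None if the threshold is never crossed


def _rhs(t, s, p: GenerationParams):
    Xa, II, IIa, AT = s
    activation = ((p.a1 * p.TF * p.VIIa + (p.a2 + p.a3 * p.phi0) * IIa)
                  * (p.X0 - Xa) - p.a4 * Xa * AT)
    conversion = (p.b1 * Xa + p.k3 * IIa + p.k4 * IIa**2 + p.k5 * IIa**3) * II
    return (activation,
            -conversion,
            conversion - p.b2 * AT * IIa,
            -p.a4 * Xa * AT - p.b2 * IIa * AT)


def simulate_generation(params: GenerationParams, t_end: float = 2000.0,
                        output_grid: float = 1.0, *, rtol: float = 1e-8,
                        atol: float = 1e-12,
                        full_state: bool = False):
    """Integrate the generation model and return the thrombin trace.

    Parameters
    ----------
    params
        Rate constants and initial concentrations.
    t_end
        Integration horizon in seconds (default 2000 s, the assay window).
    output_grid
        Spacing of the output time grid in seconds.
    full_state
        If True also return the full trajectory as a DataFrame with columns
        Xa, II, IIa, ATIII.

    Raises
    ------
    IntegrationFailure
        If the solver fails or a state variable leaves the finite range; the
        message names the offending variable.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    t_eval = np.arange(0.0, t_end + 0.5 * output_grid, output_grid)
    t_eval = t_eval[t_eval <= t_end]
    y0 = (0.0, params.II0, 0.0, params.ATIII0)
    sol = solve_ivp(_rhs, (0.0, float(t_end)), y0, args=(params,),
                    method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise IntegrationFailure(f"ODE solver failed: {sol.message}")
    bad = ~np.isfinite(sol.y).all(axis=1)
    if bad.any():
        raise IntegrationFailure(
            f"non-finite state in variable {_STATE_NAMES[int(np.argmax(bad))]!r}"
        )
    curve = ThrombinCurve(sol.t, np.maximum(sol.y[2], 0.0))
    if full_state:
        frame = pd.DataFrame(sol.y.T, columns=_STATE_NAMES)
        frame.insert(0, "t_s", sol.t)
        return curve, frame
    return curve


def curve_metrics(curve: ThrombinCurve,
                  lag_threshold: float = DEFAULT_LAG_THRESHOLD) -> GenerationMetrics:
    """Assay metrics of a thrombin trace.

    Peak and time-to-peak come from the discrete maximum, ETP from
    trapezoidal integration over the whole curve, and the lag time from the
    first (linearly interpolated) upward crossing of ``lag_threshold``.
    """
    t, v = curve.times, curve.IIa_values
    i = int(np.argmax(v))
    peak = float(v[i])
    etp = float(np.trapezoid(v, t))
    lag = None
    above = v >= lag_threshold
    if above.any() and peak >= lag_threshold > 0:
        j = int(np.argmax(above))
        if j == 0:
            lag = float(t[0])
        else:
            # linear interpolation between the bracketing samples
            f = (lag_threshold - v[j - 1]) / (v[j] - v[j - 1])
            lag = float(t[j - 1] + f * (t[j] - t[j - 1]))
    return GenerationMetrics(peak=peak, time_to_peak=float(t[i]), ETP=etp,
                             lag_time=lag)


def platelet_sweep(params: GenerationParams,
                   phi0_values: Sequence[float] | Iterable[float],
                   t_end: float = 2000.0, output_grid: float = 1.0,
                   lag_threshold: float = DEFAULT_LAG_THRESHOLD) -> pd.DataFrame:
    """Generation metrics across platelet counts, other constants fixed.

    Returns a DataFrame with one row per requested phi0, in input order,
    with columns ``phi0, peak_nM, ttp_s, ETP_nMs, lag_s``.
    """
    phi0_values = list(phi0_values)
    if any(p < 0 for p in phi0_values):
        raise ValueError("platelet counts must be non-negative")
    rows = []
    for phi0 in phi0_values:
        curve = simulate_generation(params.with_phi0(phi0), t_end, output_grid)
        m = curve_metrics(curve, lag_threshold)
        rows.append({"phi0": float(phi0), "peak_nM": m.peak, "ttp_s": m.time_to_peak,
                     "ETP_nMs": m.ETP, "lag_s": np.nan if m.lag_time is None else m.lag_time})
    return pd.DataFrame(rows)
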