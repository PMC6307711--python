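"""One-dimensional effective theory of the chiral colony front.

The colony edge is reduced to two coupled fields on a periodic x-axis: the
front height h(t, x) and the strain-1 fraction f(t, x),

    dh/dt = v0 + (v0/2) (dh/dx)^2 + Dh d2h/dx2 + alpha df/dx + noise
    df/dt = Df d2f/dx2 + beta (f* - f) df/dx + v0 (dh/dx)(df/dx) + noise

i.e. a chiral extension of the KPZ equation coupled to a Burgers-type
equation for the composition.  alpha and beta scale with the *difference*
in strain chiralities, and f* is the composite chirality (1/2 for equal and
opposite handedness).  The h-noise is additive; the f-noise is genetic
drift, multiplicative with amplitude proportional to sqrt(f(1-f)) so that
f = 0 and f = 1 are absorbing.

Closed-form results implemented alongside the integrator: the triangular
bulge profile that grows around an in-flow boundary, the bulge apex
velocity, the drift velocity of boundaries on a flat front, and the
piecewise-linear equilibrium strain fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TheoryParams",
    "FrontFields",
    "CFLError",
    "integrate_front",
    "bulge_profile",
    "equilibrium_fraction",
    "boundary_velocity",
    "apex_velocity",
    "step_fraction_profile",
]


class CFLError(RuntimeError):
    """Requested timestep violates the explicit-scheme stability bound."""


@dataclass(frozen=True)
class TheoryParams:
    """Coefficients of the coupled front equations.

    v0: flat-front speed; Dh: front smoothing; alpha: chiral shape coupling
    (>= 0 by the strain-ordering convention); Df: fraction diffusivity;
    beta: chiral advection scale (>= 0); f_star: composite chirality;
    sigma_h / sigma_f: noise amplitudes (0 = deterministic).
    """

    v0: float
    Dh: float
    alpha: float
    Df: float
    beta: float
    f_star: float
    sigma_h: float = 0.0
    sigma_f: float = 0.0

    def __post_init__(self) -> None:
        if self.v0 <= 0 or self.Dh <= 0 or self.Df <= 0:
            raise ValueError("v0, Dh and Df must be positive")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError(
                "alpha and beta must be >= 0 (order the strains so that "
                "strain 1 is the more left-handed one)"
            )
        if self.sigma_h < 0 or self.sigma_f < 0:
            raise ValueError("noise amplitudes must be >= 0")


@dataclass
class FrontFields:
    """Periodic front profiles: height h(x) and strain-1 fraction f(x)."""

    dx: float
    h: np.ndarray
    f: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.h.shape != self.f.shape or self.h.ndim != 1:
            raise ValueError("h and f must be 1-d arrays of equal length")
        if np.any(self.f < -1e-12) or np.any(self.f > 1 + 1e-12):
            raise ValueError("f must lie in [0, 1]")
        if not np.all(np.isfinite(self.h)):
            raise ValueError("h must be finite")

    @property
    def x(self) -> np.ndarray:
        return self.dx * np.arange(self.h.size)

    def copy(self) -> "FrontFields":
        return FrontFields(self.dx, self.h.copy(), self.f.copy(), self.t)


def step_fraction_profile(x: np.ndarray, edges: list[tuple[float, int]],
                          width: float) -> np.ndarray:
    """Smoothed multi-step fraction profile built from tanh ramps.

    ``edges`` is a list of (position, direction) with direction +1 for a
    rising edge (f: 0 -> 1) and -1 for a falling edge.  A ramp width of two
    grid spacings avoids grid-scale ringing in the integrator.
    """
    x = np.asarray(x, dtype=float)
    edges = sorted(edges)
    base = 1.0 if edges and edges[0][1] < 0 else 0.0
    f = np.full_like(x, base)
    for pos, direction in edges:
        f = f + direction * 0.5 * (1.0 + np.tanh((x - pos) / width))
    return np.clip(f, 0.0, 1.0)


def _check_dt(dt: float, dx: float, params: TheoryParams, c_max: float) -> None:
    diff_limit = 0.25 * dx * dx / max(params.Dh, params.Df)
    if dt > diff_limit * (1 + 1e-12):
        raise CFLError(
            f"dt = {dt:g} exceeds the diffusive stability bound "
            f"0.25 dx^2 / max(Dh, Df) = {diff_limit:g}"
        )
    if c_max > 0 and dt > 0.5 * dx / c_max * (1 + 1e-12):
        raise CFLError(
            f"dt = {dt:g} exceeds the advective stability bound "
            f"0.5 dx / |c|_max = {0.5 * dx / c_max:g}"
        )


def integrate_front(fields: FrontFields, params: TheoryParams, t_end: float,
                    dt: float | None = None,
                    rng: np.random.Generator | None = None,
                    record_every: float = 0.0,
                    freeze_f: bool = False) -> FrontFields | list[FrontFields]:
    """Integrate the coupled front equations from ``fields.t`` to ``t_end``.

    Explicit finite differences: central stencils for the diffusion terms
    and (dh/dx)^2, first-order upwinding (side chosen by the sign of the
    local advection speed) for the Burgers and shape-coupling advection of
    f.  Noise, when enabled, is added Euler-Maruyama style in the Ito
    convention and f is clipped back to [0, 1] after each step.

    If ``dt`` is omitted, a stable step is chosen automatically; an explicit
    ``dt`` violating the stability bounds raises :class:`CFLError`.  With
    ``record_every > 0`` a list of snapshots (including the final state) is
    returned instead of a single state.

    ``freeze_f = True`` holds the composition field fixed and integrates the
    height equation alone.  This is the *sharp-boundary limit* in which the
    closed-form bulge and dip shapes are derived: in the stochastic model
    genetic drift pins strain boundaries to near-zero width, whereas in the
    noiseless continuum a rising (in-flow) composition step is a rarefaction
    wave of the Burgers flow and slowly spreads.
    """
    fields = fields.copy()
    h, f = fields.h, fields.f
    dx = fields.dx
    n = h.size
    stochastic = params.sigma_h > 0 or params.sigma_f > 0
    if stochastic and rng is None:
        raise ValueError("an rng is required when noise amplitudes are nonzero")

    def c_bound() -> float:
        hx = (np.roll(h, -1) - np.roll(h, 1)) / (2 * dx)
        return params.beta * max(abs(params.f_star), abs(params.f_star - 1.0)) \
            + params.v0 * float(np.abs(hx).max())

    if dt is None:
        dt = 0.9 * min(0.25 * dx * dx / max(params.Dh, params.Df),
                       0.5 * dx / max(c_bound(), 1e-12))
    _check_dt(dt, dx, params, c_bound())

    snapshots: list[FrontFields] = []
    next_record = fields.t + record_every
    sqrt_dtdx = np.sqrt(dt / dx)
    while fields.t < t_end - 1e-12:
        step_dt = min(dt, t_end - fields.t)
        hp = np.roll(h, -1)
        hm = np.roll(h, 1)
        hx = (hp - hm) / (2 * dx)
        hxx = (hp - 2 * h + hm) / (dx * dx)
        fx_c = (np.roll(f, -1) - np.roll(f, 1)) / (2 * dx)

        if params.v0 * float(np.abs(hx).max()) * dt > 0.6 * dx:
            raise CFLError("front slopes grew beyond the advective stability bound")

        # Godunov upwinding of the Hamilton-Jacobi term (v0/2)(dh/dx)^2:
        # central differencing stalls slope corners (bulge apexes), which
        # must advance at v0 (1 + slope^2 / 2)
        pm = (h - hm) / dx
        pp = (hp - h) / dx
        nonlin = np.maximum(np.maximum(pm, 0.0) ** 2,
                            np.minimum(pp, 0.0) ** 2)
        dh = params.v0 + 0.5 * params.v0 * nonlin + params.Dh * hxx \
            + params.alpha * fx_c
        h += step_dt * dh
        if stochastic and params.sigma_h > 0:
            h += params.sigma_h * sqrt_dtdx * rng.standard_normal(n)

        if not freeze_f:
            fxx = (np.roll(f, -1) - 2 * f + np.roll(f, 1)) / (dx * dx)
            c = params.beta * (params.f_star - f) + params.v0 * hx
            fx_up = np.where(c > 0,
                             (np.roll(f, -1) - f) / dx,
                             (f - np.roll(f, 1)) / dx)
            df = params.Df * fxx + c * fx_up
            f += step_dt * df
            if stochastic and params.sigma_f > 0:
                amp = np.sqrt(np.clip(f * (1.0 - f), 0.0, None))
                f += params.sigma_f * amp * sqrt_dtdx * rng.standard_normal(n)
            np.clip(f, 0.0, 1.0, out=f)
        fields.t += step_dt

        if record_every > 0 and fields.t >= next_record - 1e-9:
            snapshots.append(fields.copy())
            next_record += record_every
    if record_every > 0:
        if not snapshots or snapshots[-1].t < fields.t - 1e-9:
            snapshots.append(fields.copy())
        return snapshots
    return fields


def bulge_profile(x, t: float, params: TheoryParams, x_b: float = 0.0):
    """Triangular bulge shape ``h - v0 t`` around an in-flow boundary.

    Height v0 alpha^2 t / (8 Dh^2) at the apex, slopes of magnitude
    alpha/(2 Dh), support half-width v0 alpha t / (4 Dh); height and width
    grow linearly in time while the slope stays constant.
    """
    if t <= 0:
        raise ValueError("t must be positive")
    x = np.asarray(x, dtype=float)
    half_width = params.v0 * params.alpha * t / (4.0 * params.Dh)
    apex = params.v0 * params.alpha ** 2 * t / (8.0 * params.Dh ** 2)
    slope = params.alpha / (2.0 * params.Dh)
    out = np.where(np.abs(x - x_b) >= half_width, 0.0,
                   apex - slope * np.abs(x - x_b))
    return out if out.ndim else float(out)


def equilibrium_fraction(f_star, params: TheoryParams):
    """Steady-state global fraction of strain 1 as a function of f*.

    Piecewise linear: exclusion (0 or 1) outside the coexistence window
    ``|f* - 1/2| < alpha v0 / (2 Dh beta)``, and a line of slope
    ``beta Dh / (alpha v0)`` through (1/2, 1/2) inside it.  Continuous and
    monotone non-decreasing in f*.
    """
    f_star_arr = np.asarray(f_star, dtype=float)
    if params.beta == 0.0:
        if params.alpha <= 0.0:
            raise ValueError(
                "beta = 0 with alpha = 0: no chiral coupling, the "
                "equilibrium fraction is degenerate"
            )
        # infinitely wide coexistence window; bulge symmetry pins f at 1/2
        out = np.full_like(f_star_arr, 0.5)
        return out if out.ndim else float(out)
    half_window = params.alpha * params.v0 / (2.0 * params.Dh * params.beta)
    slope = params.beta * params.Dh / (params.alpha * params.v0)
    out = np.clip(0.5 + slope * (f_star_arr - 0.5), 0.0, 1.0)
    out = np.where(f_star_arr <= 0.5 - half_window, 0.0, out)
    out = np.where(f_star_arr >= 0.5 + half_window, 1.0, out)
    return out if out.ndim else float(out)


def boundary_velocity(f_star: float, beta: float) -> float:
    """Drift velocity of strain boundaries on a flat front, beta (1/2 - f*)."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    return beta * (0.5 - f_star)


def apex_velocity(params: TheoryParams) -> float:
    """Growth speed of a bulge apex, v0 (1 + alpha^2 / (8 Dh^2)) >= v0."""
    return params.v0 + params.v0 * params.alpha ** 2 / (8.0 * params.Dh ** 2)
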