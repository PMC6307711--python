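"""Two-strain stochastic lattice model of chiral growth in compact aggregates.

The model is a generalized stepping-stone simulation on a rectangular grid.
Each site holds up to ``N`` cells of two strains.  Every timestep consists of

1. a *deterministic* update: logistic growth plus density-dependent,
   nearest-neighbour migration whose coefficients are assigned relative to
   the migration direction (source, destination, left, back, right), which
   makes the scheme isotropic on the lattice while allowing a chiral bias
   (``ml != mr``); and
2. a *stochastic* update: two rounds of binomial resampling, the first for
   demographic fluctuations of the total occupancy, the second for genetic
   drift between the strains.

Because migration into fully occupied sites is blocked and there is no
death, the pattern behind the expanding front freezes, as in microbial
colonies.  Only a moving window of rows (or a moving annulus for radial
colonies) around the front is updated; frozen regions are never touched.

Axis convention: axis 0 is ``y`` (growth direction, row 0 at the bottom),
axis 1 is ``x`` (periodic).  "Left" of a migration direction is 90 degrees
counterclockwise from it, so a strain with ``ml > mr`` is left-handed and
its sector boundaries twist counterclockwise in radial colonies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StrainParams",
    "LatticeConfig",
    "LatticeState",
    "Simulation",
    "growth_increment",
    "directional_flux",
    "migration_increment",
    "deterministic_update",
    "demographic_sampling",
    "drift_sampling",
    "step",
    "init_linear_front",
    "init_circular_colony",
    "front_row",
]

_MIG_NAMES = ("m0", "ms", "md", "ml", "mb", "mr")


class ClampWarning(UserWarning):
    """Deterministic update produced out-of-range expectations (clamped)."""


@dataclass(frozen=True)
class StrainParams:
    """Per-strain growth rate and the six direction-relative migration
    coefficients.

    ``m0`` is independent of the source density; ``ms, md, ml, mb, mr``
    multiply the occupancy fraction of the source, destination, left, back
    and right sites *relative to the migration direction*.  Chirality is
    ``ml - mr`` (positive = left-handed); motility is ``ml + mr``, so
    chirality can be varied at fixed motility.
    """

    g: float
    m0: float = 0.0
    ms: float = 0.0
    md: float = 0.0
    ml: float = 0.0
    mb: float = 0.0
    mr: float = 0.0

    def __post_init__(self) -> None:
        for name in ("g",) + _MIG_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
        if self.migration_total > 1.0 + 1e-12:
            raise ValueError(
                "sum of migration coefficients exceeds 1 "
                f"({self.migration_total:.4f}); expected per-step emigration "
                "would exceed the site occupancy"
            )

    @property
    def migration_total(self) -> float:
        return self.m0 + self.ms + self.md + self.ml + self.mb + self.mr

    @property
    def chirality(self) -> float:
        """Signed chirality ``ml - mr`` (> 0 for a left-handed strain)."""
        return self.ml - self.mr

    @property
    def motility(self) -> float:
        return self.ml + self.mr

    def mirrored(self) -> "StrainParams":
        """The mirror-image strain (swap left and right coefficients)."""
        return replace(self, ml=self.mr, mr=self.ml)


@dataclass(frozen=True)
class LatticeConfig:
    """Lattice geometry, carrying capacity and moving-window policy.

    The lattice spacings and the timestep are carried symbolically but are
    1 in all standard runs.  ``window_behind``/``window_ahead`` set how many
    rows behind/ahead of the front stay active; the window advances whenever
    the front comes within ``advance_margin`` rows of its leading edge.
    """

    width: int
    height: int
    N: int
    dx: float = 1.0
    dy: float = 1.0
    dt: float = 1.0
    window_behind: int = 30
    window_ahead: int = 30
    advance_margin: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("carrying capacity N must be >= 1")
        if self.width < 3 or self.height < 3:
            raise ValueError("lattice must be at least 3x3")
        if self.dx != self.dy:
            raise ValueError("dx and dy must be equal")
        if self.window_behind < 2 or self.window_ahead < 2:
            raise ValueError("window depths must be >= 2 rows")
        if self.advance_margin >= self.window_ahead:
            raise ValueError("advance_margin must be smaller than window_ahead")


@dataclass
class LatticeState:
    """Integer occupancy fields for the two strains plus the active window.

    ``y_lo:y_hi`` is the half-open row interval currently updated (linear
    geometry).  For radial geometry the active region is an annulus around
    the colony edge and the row window spans the whole lattice.
    """

    n1: np.ndarray
    n2: np.ndarray
    t: float = 0.0
    y_lo: int = 0
    y_hi: int = 0
    geometry: str = "linear"
    center: tuple[float, float] | None = None
    r_front: float = 0.0
    _dist: np.ndarray | None = field(default=None, repr=False)
    _mask: np.ndarray | None = field(default=None, repr=False)
    _mask_r: float = field(default=-1.0, repr=False)

    @property
    def n(self) -> np.ndarray:
        """Total occupancy field."""
        return self.n1 + self.n2

    def copy(self) -> "LatticeState":
        return LatticeState(
            self.n1.copy(), self.n2.copy(), self.t, self.y_lo, self.y_hi,
            self.geometry, self.center, self.r_front,
        )

    def dist_from_center(self) -> np.ndarray:
        if self.center is None:
            raise ValueError("state has no colony center (linear geometry?)")
        if self._dist is None:
            h, w = self.n1.shape
            yy, xx = np.mgrid[0:h, 0:w]
            cx, cy = self.center
            self._dist = np.hypot(xx - cx, yy - cy)
        return self._dist


def _validate_densities(*arrays: np.ndarray, N: int) -> None:
    for a in arrays:
        a = np.asarray(a)
        if np.any(a < 0) or np.any(a > N):
            raise ValueError("densities must lie in [0, N]")


def growth_increment(n_alpha, n_total, params: StrainParams, N: int, dt: float = 1.0):
    """Expected logistic-growth increment ``g * n_alpha * (1 - n/N) * dt``.

    Zero at carrying capacity and for an absent strain.
    """
    n_alpha = np.asarray(n_alpha, dtype=float)
    n_total = np.asarray(n_total, dtype=float)
    if np.any(n_alpha < 0) or np.any(n_total > N) or np.any(n_alpha > n_total):
        raise ValueError("require 0 <= n_alpha <= n_total <= N")
    out = params.g * n_alpha * (1.0 - n_total / N) * dt
    return out if out.ndim else float(out)


def directional_flux(n_alpha_src, n_src, n_dest, n_left, n_back, n_right,
                     params: StrainParams, N: int):
    """Expected migrant count along one direction, per unit time.

    The neighbourhood is supplied in direction-relative order: *left* is 90
    degrees counterclockwise from the migration direction, *right* clockwise,
    *back* opposite.  The flux vanishes when the destination is full.
    """
    _validate_densities(np.asarray(n_alpha_src), np.asarray(n_src),
                        np.asarray(n_dest), np.asarray(n_left),
                        np.asarray(n_back), np.asarray(n_right), N=N)
    u_s = np.asarray(n_src, dtype=float) / N
    u_d = np.asarray(n_dest, dtype=float) / N
    u_l = np.asarray(n_left, dtype=float) / N
    u_b = np.asarray(n_back, dtype=float) / N
    u_r = np.asarray(n_right, dtype=float) / N
    bracket = (params.m0 + params.ms * u_s + params.md * u_d + params.mb * u_b) \
        + (params.ml * u_l + params.mr * u_r)
    out = np.asarray(n_alpha_src, dtype=float) * (1.0 - u_d) * bracket
    return out if out.ndim else float(out)


def _shifted(u: np.ndarray):
    """Neighbour values of ``u``: (x+1, x-1, y+1, y-1); x periodic, y closed
    (out-of-lattice treated as empty)."""
    ux_p = np.roll(u, -1, axis=1)
    ux_m = np.roll(u, 1, axis=1)
    uy_p = np.zeros_like(u)
    uy_p[:-1] = u[1:]
    uy_m = np.zeros_like(u)
    uy_m[1:] = u[:-1]
    return ux_p, ux_m, uy_p, uy_m


def _flux_fields(n_a: np.ndarray, u: np.ndarray, shifts, p: StrainParams):
    """Outgoing flux fields (east, west, north, south) for one strain.

    The left/right coefficient terms are grouped as a two-term sum so that
    mirror reflection (flip x, swap ml/mr) commutes with the update at the
    level of floating-point bit patterns (IEEE addition is commutative).
    """
    ux_p, ux_m, uy_p, uy_m = shifts
    m0, ms, md, ml, mb, mr = p.m0, p.ms, p.md, p.ml, p.mb, p.mr
    fe = n_a * (1.0 - ux_p) * ((m0 + ms * u + md * ux_p + mb * ux_m)
                               + (ml * uy_p + mr * uy_m))
    fw = n_a * (1.0 - ux_m) * ((m0 + ms * u + md * ux_m + mb * ux_p)
                               + (ml * uy_m + mr * uy_p))
    fn = n_a * (1.0 - uy_p) * ((m0 + ms * u + md * uy_p + mb * uy_m)
                               + (ml * ux_m + mr * ux_p))
    fs = n_a * (1.0 - uy_m) * ((m0 + ms * u + md * uy_m + mb * uy_p)
                               + (ml * ux_p + mr * ux_m))
    # no flux across the top/bottom lattice edges
    fn[-1] = 0.0
    fs[0] = 0.0
    return fe, fw, fn, fs


def _net_migration(fe, fw, fn, fs) -> np.ndarray:
    in_e = np.roll(fe, 1, axis=1)
    in_w = np.roll(fw, -1, axis=1)
    in_n = np.zeros_like(fn)
    in_n[1:] = fn[:-1]
    in_s = np.zeros_like(fs)
    in_s[:-1] = fs[1:]
    return ((in_e - fe) + (in_w - fw)) + ((in_n - fn) + (in_s - fs))


def migration_increment(n_alpha, n_total, params: StrainParams, N: int,
                        dt: float = 1.0) -> np.ndarray:
    """Net expected migration change per site (incoming minus outgoing).

    Migration conserves cells, so the returned field sums to zero over the
    lattice (up to floating-point accumulation).
    """
    n_a = np.asarray(n_alpha, dtype=float)
    u = np.asarray(n_total, dtype=float) / N
    _validate_densities(n_a, np.asarray(n_total), N=N)
    fluxes = _flux_fields(n_a, u, _shifted(u), params)
    return _net_migration(*fluxes) * dt


def deterministic_update(n1, n2, params1: StrainParams, params2: StrainParams,
                         N: int, dt: float = 1.0, warn: bool = True):
    """Expected next-step densities ``rho`` for both strains (synchronous).

    ``rho = n + (growth + migration) * dt`` computed from the time-t fields.
    Values are clamped to ``[0, N]`` per strain and the pair rescaled
    proportionally where ``rho1 + rho2 > N``; clamping indicates
    out-of-regime parameters and triggers a warning.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    u = (n1 + n2) / N
    shifts = _shifted(u)
    one_minus_u = 1.0 - u
    rho = []
    for n_a, p in ((n1, params1), (n2, params2)):
        G = p.g * n_a * one_minus_u
        M = _net_migration(*_flux_fields(n_a, u, shifts, p))
        rho.append(n_a + (G + M) * dt)
    rho1, rho2 = rho

    clamped = 0
    for r in (rho1, rho2):
        neg = r < 0.0
        if neg.any():
            clamped += int(neg.sum())
            r[neg] = 0.0
    tot = rho1 + rho2
    over = tot > N
    if over.any():
        clamped += int(over.sum())
        scale = N / tot[over]
        rho1[over] *= scale
        rho2[over] *= scale
    if clamped and warn:
        warnings.warn(
            f"clamped {clamped} out-of-range expected densities; "
            "parameters may be outside the model's stable regime",
            ClampWarning, stacklevel=2,
        )
    return rho1, rho2


def demographic_sampling(rho1, rho2, N: int, rng: np.random.Generator) -> np.ndarray:
    """First stochastic round: total occupancy ``n ~ Binomial(N, (rho1+rho2)/N)``."""
    p = (np.asarray(rho1, dtype=float) + np.asarray(rho2, dtype=float)) / N
    if p.min() < -1e-9 or p.max() > 1.0 + 1e-9:
        raise RuntimeError(
            "success probability outside [0, 1]: deterministic update was "
            "not clamped correctly"
        )
    return rng.binomial(N, np.clip(p, 0.0, 1.0))


def drift_sampling(n_new, rho1, rho2, rng: np.random.Generator):
    """Second stochastic round (genetic drift): split ``n_new`` between strains.

    ``n1 ~ Binomial(n_new, rho1/(rho1+rho2))``; empty expectations give
    empty sites.  ``f = 0`` and ``f = 1`` are absorbing.
    """
    rho1 = np.asarray(rho1, dtype=float)
    tot = rho1 + np.asarray(rho2, dtype=float)
    safe = np.where(tot > 0.0, tot, 1.0)
    p1 = np.clip(rho1 / safe, 0.0, 1.0)
    n1 = rng.binomial(n_new, p1)
    return n1, n_new - n1


def _sample_update(rho1: np.ndarray, rho2: np.ndarray, N: int,
                   rng: np.random.Generator):
    """Both stochastic rounds, drawing only where the outcome is random.

    Statistically identical to ``demographic_sampling`` followed by
    ``drift_sampling``: sites with expected occupancy exactly 0 or N and
    sites where one strain's expectation vanishes are deterministic, so no
    variates are consumed there (this also defines the canonical RNG stream
    of :func:`step`)."""
    shape = rho1.shape
    r1 = rho1.ravel()
    r2 = rho2.ravel()
    tot = r1 + r2
    p = tot / N
    if p.min() < -1e-9 or p.max() > 1.0 + 1e-9:
        raise RuntimeError("success probability outside [0, 1] after clamping")
    n_new = np.where(p >= 1.0, N, 0).astype(np.int64)
    mid = np.flatnonzero((p > 0.0) & (p < 1.0))
    if mid.size:
        n_new[mid] = rng.binomial(N, np.clip(p.take(mid), 0.0, 1.0))
    n1 = np.where(r2 <= 0.0, n_new, 0)
    mixed = np.flatnonzero((r1 > 0.0) & (r2 > 0.0) & (n_new > 0))
    if mixed.size:
        n1[mixed] = rng.binomial(
            n_new.take(mixed),
            np.clip(r1.take(mixed) / tot.take(mixed), 0.0, 1.0))
    return n1.reshape(shape), (n_new - n1).reshape(shape)


def front_row(state: LatticeState) -> int:
    """Highest occupied row inside the active window (-1 if empty)."""
    sub = state.n1[state.y_lo:state.y_hi] + state.n2[state.y_lo:state.y_hi]
    occ = np.flatnonzero(sub.any(axis=1))
    if occ.size == 0:
        return -1
    return state.y_lo + int(occ[-1])


def step(state: LatticeState, params1: StrainParams, params2: StrainParams,
         config: LatticeConfig, rng: np.random.Generator,
         warn: bool = True) -> bool:
    """Advance the state by one timestep inside the active window.

    Returns False when the expansion is complete (the front can no longer
    advance with a full leading window); the state is still updated.
    """
    if state.geometry == "radial":
        return _step_radial(state, params1, params2, config, rng, warn)

    lo, hi = state.y_lo, state.y_hi
    front_pre = front_row(state)
    # rows more than one site beyond the front cannot change this step
    hi_eff = min(front_pre + 2, hi)

    # rows in the contiguous saturated block at the bottom of the window
    # have an exactly trivial deterministic update (no growth, all migration
    # blocked by exclusion), so the expensive kernel starts one row below
    # the first unsaturated row; the stochastic rounds still cover them
    ntot_win = state.n1[lo:hi_eff] + state.n2[lo:hi_eff]
    row_sat = (ntot_win.min(axis=1) == config.N)
    n_sat_rows = int(np.argmin(row_sat)) if not row_sat.all() else row_sat.size
    det_lo = lo + max(n_sat_rows - 1, 0)

    lo_h, hi_h = max(det_lo - 1, 0), min(hi_eff + 1, config.height)
    s1 = state.n1[lo_h:hi_h]
    s2 = state.n2[lo_h:hi_h]
    rho1, rho2 = deterministic_update(s1, s2, params1, params2, config.N,
                                      config.dt, warn=warn)
    a, b = det_lo - lo_h, hi_eff - lo_h
    if det_lo > lo:
        r1 = np.concatenate([state.n1[lo:det_lo].astype(float), rho1[a:b]])
        r2 = np.concatenate([state.n2[lo:det_lo].astype(float), rho2[a:b]])
    else:
        r1, r2 = rho1[a:b], rho2[a:b]
    n1_new, n2_new = _sample_update(r1, r2, config.N, rng)
    state.n1[lo:hi_eff] = n1_new
    state.n2[lo:hi_eff] = n2_new
    state.t += config.dt

    front = front_row(state)
    if front >= hi - 1 - config.advance_margin:
        new_hi = min(front + 1 + config.window_ahead, config.height)
        if new_hi == state.y_hi and front >= config.height - 1 - config.advance_margin:
            return False  # front has reached the top of the lattice
        state.y_hi = new_hi
        state.y_lo = max(front - config.window_behind, 0)
    return True


def _step_radial(state: LatticeState, params1, params2, config, rng,
                 warn: bool) -> bool:
    dist = state.dist_from_center()
    if state._mask is None or state.r_front > state._mask_r:
        state._mask = (dist >= state.r_front - config.window_behind) & \
                      (dist <= state.r_front + config.window_ahead)
        state._mask_r = state.r_front + 1.0
    mask = state._mask
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1_ = max(rows[0] - 1, 0), min(rows[-1] + 2, state.n1.shape[0])
    c0, c1_ = max(cols[0] - 1, 0), min(cols[-1] + 2, state.n1.shape[1])
    box = (slice(r0, r1_), slice(c0, c1_))
    rho1, rho2 = deterministic_update(state.n1[box], state.n2[box],
                                      params1, params2, config.N, config.dt,
                                      warn=warn)
    sub_mask = mask[box]
    m1, m2 = rho1[sub_mask], rho2[sub_mask]
    n1_new, n2_new = _sample_update(m1, m2, config.N, rng)
    n1_box = state.n1[box]
    n2_box = state.n2[box]
    n1_box[sub_mask] = n1_new
    n2_box[sub_mask] = n2_new
    state.t += config.dt

    occ = (state.n1[box] + state.n2[box]) > 0
    if occ.any():
        state.r_front = float(dist[box][occ].max())
    cx, cy = state.center
    r_max = min(cx, cy, state.n1.shape[1] - 1 - cx, state.n1.shape[0] - 1 - cy)
    return state.r_front < r_max - config.window_ahead


def init_linear_front(config: LatticeConfig, f0: float, mode: str = "well_mixed",
                      rows: int = 8, patch_center: float | None = None,
                      patch_width: int | None = None,
                      rng: np.random.Generator | None = None) -> LatticeState:
    """Flat front: the bottom ``rows`` rows filled to carrying capacity.

    Modes: ``well_mixed`` draws each site's strain-1 count binomially at
    fraction ``f0``; ``two_domains`` puts strain 1 in a contiguous x-interval
    of fractional width ``f0`` (one in-flow and one out-flow boundary on the
    periodic ring); ``single_patch`` embeds a strain-1 interval of
    ``patch_width`` columns inside strain 2.
    """
    if not 0.0 <= f0 <= 1.0:
        raise ValueError("f0 must lie in [0, 1]")
    if rows >= config.height - config.window_ahead:
        raise ValueError("initial rows exceed the lattice height")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n1 = np.zeros((config.height, config.width), dtype=np.int64)
    n2 = np.zeros_like(n1)
    filled = slice(0, rows)
    if mode == "well_mixed":
        n1[filled] = rng.binomial(config.N, f0, size=(rows, config.width))
        n2[filled] = config.N - n1[filled]
    elif mode == "two_domains":
        w1 = int(round(f0 * config.width))
        n1[filled, :w1] = config.N
        n2[filled, w1:] = config.N
    elif mode == "single_patch":
        if patch_width is None:
            patch_width = max(int(round(f0 * config.width)), 1)
        if patch_width > config.width:
            raise ValueError("patch wider than the lattice")
        c = config.width // 2 if patch_center is None else int(patch_center)
        xs = (np.arange(patch_width) + c - patch_width // 2) % config.width
        n2[filled] = config.N
        n1[:rows, xs] = config.N
        n2[:rows, xs] = 0
    else:
        raise ValueError(f"unknown initialization mode {mode!r}")
    front = rows - 1
    state = LatticeState(n1, n2, t=0.0,
                         y_lo=max(front - config.window_behind, 0),
                         y_hi=min(front + 1 + config.window_ahead, config.height))
    return state


def init_circular_colony(config: LatticeConfig, radius: float, f0: float,
                         center: tuple[float, float] | None = None,
                         rng: np.random.Generator | None = None) -> LatticeState:
    """Well-mixed disk of the given radius at carrying capacity."""
    if not 0.0 <= f0 <= 1.0:
        raise ValueError("f0 must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if center is None:
        center = ((config.width - 1) / 2.0, (config.height - 1) / 2.0)
    cx, cy = center
    if radius > min(cx, cy, config.width - 1 - cx, config.height - 1 - cy):
        raise ValueError("initial circle does not fit the lattice")
    n1 = np.zeros((config.height, config.width), dtype=np.int64)
    n2 = np.zeros_like(n1)
    state = LatticeState(n1, n2, geometry="radial", center=center,
                         y_lo=0, y_hi=config.height)
    disk = state.dist_from_center() <= radius
    k = int(disk.sum())
    draws = rng.binomial(config.N, f0, size=k)
    n1[disk] = draws
    n2[disk] = config.N - draws
    state.r_front = float(radius)
    return state


class Simulation:
    """Convenience wrapper bundling config, strain parameters, state and RNG.

    All randomness flows through one seeded generator; per-site draws are
    consumed in row-major order, so runs are bit-reproducible for a given
    (config, parameters, seed) triple on one platform.
    """

    def __init__(self, config: LatticeConfig, params1: StrainParams,
                 params2: StrainParams, seed: int | None = None,
                 rng: np.random.Generator | None = None):
        self.config = config
        self.params1 = params1
        self.params2 = params2
        if rng is None:
            rng = np.random.default_rng(config.seed if seed is None else seed)
        self.rng = rng
        self.state: LatticeState | None = None
        self.stop_reason: str | None = None

    def init_linear_front(self, f0: float, mode: str = "well_mixed", **kw) -> LatticeState:
        self.state = init_linear_front(self.config, f0, mode, rng=self.rng, **kw)
        return self.state

    def init_circular_colony(self, radius: float, f0: float, **kw) -> LatticeState:
        self.state = init_circular_colony(self.config, radius, f0, rng=self.rng, **kw)
        return self.state

    def step(self, warn: bool = True) -> bool:
        if self.state is None:
            raise RuntimeError("initialize the state first")
        return step(self.state, self.params1, self.params2, self.config,
                    self.rng, warn=warn)

    def run(self, max_steps: int, callback=None, callback_every: int = 0,
            warn: bool = False) -> str:
        """Run up to ``max_steps`` or until the front exhausts the lattice.

        ``callback(sim)`` is invoked every ``callback_every`` steps (and once
        at the end).  Returns the stop reason.
        """
        reason = "max_steps"
        for i in range(max_steps):
            active = self.step(warn=warn)
            if callback is not None and callback_every and (i + 1) % callback_every == 0:
                callback(self)
            if not active:
                reason = "front_reached_edge"
                break
        if callback is not None:
            callback(self)
        self.stop_reason = reason
        return reason
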