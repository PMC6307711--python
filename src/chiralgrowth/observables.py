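"""Measurements on lattice snapshots: front profiles, strain fractions,
heterozygosity, expansion velocity, sector-boundary tracking, logarithmic
spiral fits, boundary widths and bulge-slope fits.

The front height h(x) is defined per column as the topmost half-occupancy
crossing (n >= N/2) with linear interpolation between the bracketing rows;
the local strain fraction f(x) is averaged over a band of rows just behind
the front.  Sector boundaries are the f = 1/2 crossings of a lightly
smoothed fraction profile; they are classified as in-flow (the chiral
biases of the flanking strains point toward each other, i.e. the more
left-handed strain sits to the right) or out-flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .lattice import LatticeState

__all__ = [
    "FrontProfile",
    "Boundary",
    "BoundaryTrack",
    "SpiralFit",
    "front_profile",
    "global_fraction",
    "heterozygosity",
    "expansion_velocity",
    "extract_boundaries",
    "track_boundaries",
    "fit_log_spiral",
    "radial_boundary_angles",
    "boundary_width",
    "fit_bulge_slopes",
    "window_heterozygosity",
]


@dataclass
class FrontProfile:
    """Per-column front height and strain-1 fraction at one time."""

    h: np.ndarray
    f: np.ndarray
    valid: np.ndarray
    t: float
    band_depth: int

    @property
    def x(self) -> np.ndarray:
        return np.arange(self.h.size, dtype=float)


@dataclass(frozen=True)
class Boundary:
    """One f = 1/2 crossing along the front."""

    x: float
    kind: str  # "in_flow" | "out_flow"


@dataclass
class BoundaryTrack:
    """A sector boundary followed over time (linear fronts)."""

    kind: str
    t: list[float] = field(default_factory=list)
    x: list[float] = field(default_factory=list)
    alive: bool = True

    def velocity(self) -> tuple[float, float]:
        """Least-squares drift velocity of the (unwrapped) track."""
        if len(self.t) < 3:
            raise ValueError("track too short for a velocity fit")
        res = stats.linregress(self.t, self.x)
        return float(res.slope), float(res.stderr)


@dataclass
class SpiralFit:
    """Least-squares fit of the averaged boundary angle to theta = c0 + c1 ln r."""

    c0: float
    c1: float
    c1_se: float
    r_squared: float
    radii: np.ndarray
    theta_mean: np.ndarray
    n_boundaries: int


def front_profile(state: LatticeState, N: int, band_depth: int = 10) -> FrontProfile:
    """Extract h(x) and f(x) from a lattice state.

    h(x) is the interpolated height of the topmost n >= N/2 crossing; a
    saturated front at row k gives h = k + 1/2.  f(x) averages the strain
    densities over ``band_depth`` rows ending at the front row.  Columns
    with no occupied band are flagged invalid (NaN).
    """
    # the front lies inside the active window; ignore rows above it
    top_row = state.y_hi if state.y_hi > 0 else state.n1.shape[0]
    n1, n2 = state.n1[:top_row], state.n2[:top_row]
    ntot = n1 + n2
    H, W = ntot.shape
    occ = ntot >= N / 2.0
    any_occ = occ.any(axis=0)
    # topmost row satisfying the threshold, per column
    top = H - 1 - np.argmax(occ[::-1], axis=0)
    top = np.where(any_occ, top, 0)

    cols = np.arange(W)
    n_at = ntot[top, cols].astype(float)
    above = np.minimum(top + 1, H - 1)
    n_above = np.where(top < H - 1, ntot[above, cols], 0).astype(float)
    denom = n_at - n_above
    frac = np.where(denom > 0, (n_at - N / 2.0) / np.where(denom > 0, denom, 1.0), 0.0)
    h = top + np.clip(frac, 0.0, 1.0)

    depth = np.arange(band_depth)[:, None]
    rows = np.clip(top[None, :] - depth, 0, H - 1)
    s1 = n1[rows, cols[None, :]].sum(axis=0).astype(float)
    stot = ntot[rows, cols[None, :]].sum(axis=0).astype(float)
    valid = any_occ & (stot > 0)
    f = np.where(valid, s1 / np.where(stot > 0, stot, 1.0), np.nan)
    h = np.where(any_occ, h, np.nan)
    return FrontProfile(h=h, f=f, valid=valid, t=state.t, band_depth=band_depth)


def global_fraction(profile: FrontProfile) -> float:
    """Spatially averaged strain-1 fraction over valid columns."""
    if not profile.valid.any():
        raise ValueError("no valid columns in the profile")
    return float(np.nanmean(profile.f))


def heterozygosity(profile: FrontProfile) -> float:
    """Column-averaged H = <2 f (1 - f)>; 0 iff every column is monomorphic."""
    if not profile.valid.any():
        raise ValueError("no valid columns in the profile")
    f = profile.f[profile.valid]
    return float(np.mean(2.0 * f * (1.0 - f)))


def window_heterozygosity(state: LatticeState) -> float:
    """Per-site heterozygosity averaged over occupied sites of the active
    window (the quantity used to detect the intermixing transition)."""
    lo, hi = state.y_lo, state.y_hi
    n1 = state.n1[lo:hi].astype(float)
    ntot = n1 + state.n2[lo:hi]
    occ = ntot > 0
    if not occ.any():
        return 0.0
    f = n1[occ] / ntot[occ]
    return float(np.mean(2.0 * f * (1.0 - f)))


def expansion_velocity(t, h_mean, fit_window: tuple[float, float] | None = None):
    """Least-squares front speed from mean height vs time.

    ``fit_window = (t_min, t_max)`` discards the transient; defaults to the
    trailing 70% of samples.  Returns (velocity, standard error).
    """
    t = np.asarray(t, dtype=float)
    h_mean = np.asarray(h_mean, dtype=float)
    if fit_window is None:
        t_min = t[0] + 0.3 * (t[-1] - t[0])
        fit_window = (t_min, t[-1])
    keep = (t >= fit_window[0]) & (t <= fit_window[1])
    if keep.sum() < 3:
        raise ValueError("fewer than 3 samples in the fit window")
    res = stats.linregress(t[keep], h_mean[keep])
    return float(res.slope), float(res.stderr)


def _smooth_periodic(f: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return f
    kernel = np.ones(window) / window
    pad = window // 2
    ext = np.concatenate([f[-pad:], f, f[:pad]])
    sm = np.convolve(ext, kernel, mode="same")
    return sm[pad:pad + f.size]


def extract_boundaries(profile: FrontProfile, chi1: float, chi2: float,
                       smooth: int = 5) -> list[Boundary]:
    """Locate f = 1/2 crossings of the smoothed fraction profile.

    Crossing positions are interpolated between columns (periodic x).  A
    crossing with the more left-handed strain on its right side is an
    in-flow boundary.  Returns an empty list for monomorphic or uniformly
    mixed fronts; under periodic x, in-flow and out-flow counts are equal.
    """
    f = profile.f.copy()
    if np.isnan(f).any():
        # fill isolated invalid columns by neighbour interpolation
        idx = np.arange(f.size)
        good = ~np.isnan(f)
        if good.sum() < 2:
            return []
        f = np.interp(idx, idx[good], f[good], period=f.size)
    fs = _smooth_periodic(f, smooth)
    d = fs - 0.5
    d_next = np.roll(d, -1)
    crossing = (d * d_next < 0) | ((d == 0) & (d_next != 0))
    out: list[Boundary] = []
    for i in np.flatnonzero(crossing):
        di, dn = d[i], d_next[i]
        xc = (i + di / (di - dn)) % f.size
        rising = dn > di
        right_chi, left_chi = (chi1, chi2) if rising else (chi2, chi1)
        kind = "in_flow" if right_chi > left_chi else "out_flow"
        out.append(Boundary(x=float(xc), kind=kind))
    return out


def track_boundaries(times: list[float], boundary_lists: list[list[Boundary]],
                     width: int, max_displacement: float = 10.0) -> list[BoundaryTrack]:
    """Greedy nearest-neighbour matching of boundaries across snapshots.

    Matching distance is periodic in x and capped at ``max_displacement``
    per step; unmatched boundaries terminate (sector extinction) or start
    new tracks.  Track x-positions are unwrapped across the periodic seam.
    """
    tracks: list[BoundaryTrack] = []
    active: list[BoundaryTrack] = []
    for t, blist in zip(times, boundary_lists):
        unmatched = list(blist)
        still_active = []
        for tr in active:
            if not unmatched:
                tr.alive = False
                continue
            last = tr.x[-1] % width
            dists = [min(abs(b.x - last), width - abs(b.x - last)) for b in unmatched]
            j = int(np.argmin(dists))
            if dists[j] <= max_displacement and unmatched[j].kind == tr.kind:
                b = unmatched.pop(j)
                delta = (b.x - last + width / 2) % width - width / 2
                tr.t.append(t)
                tr.x.append(tr.x[-1] + delta)
                still_active.append(tr)
            else:
                tr.alive = False
        for b in unmatched:
            tr = BoundaryTrack(kind=b.kind, t=[t], x=[b.x])
            tracks.append(tr)
            still_active.append(tr)
        active = still_active
    return tracks


def fit_log_spiral(r, theta) -> SpiralFit:
    """Least-squares Bernoulli-spiral fit ``theta = c0 + c1 ln r`` for one
    generic boundary track.

    Accepts any (r, theta) samples — e.g. a boundary digitized from a
    colony image — with theta already unwrapped by continuity.  ``c1 > 0``
    means counterclockwise twisting with increasing radius.
    """
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if r.size != theta.size or r.size < 3:
        raise ValueError("need at least 3 (r, theta) samples")
    if np.any(r <= 0):
        raise ValueError("radii must be positive")
    res = stats.linregress(np.log(r), theta)
    return SpiralFit(c0=float(res.intercept), c1=float(res.slope),
                     c1_se=float(res.stderr), r_squared=float(res.rvalue ** 2),
                     radii=r, theta_mean=theta, n_boundaries=1)


def radial_boundary_angles(state: LatticeState, r_min: float, r_max: float,
                           dr: float = 1.0, smooth: int = 5,
                           min_boundaries: int = 2,
                           match_tol: float = 0.35) -> SpiralFit:
    """Fit the averaged sector-boundary angle of a radial colony to a
    logarithmic (Bernoulli) spiral theta = c0 + c1 ln r.

    At each sampled radius the frozen pattern is read along a ring, sector
    boundaries are located as f = 1/2 crossings of the smoothed angular
    fraction profile, and boundaries are linked across radii by angular
    continuity.  Only boundaries alive over the full radius range enter the
    average; each boundary's initial angle is subtracted before averaging.
    ``c1 > 0`` means counterclockwise twisting (left-handed strains).
    """
    if state.center is None:
        raise ValueError("state has no colony center")
    cx, cy = state.center
    n1, n2 = state.n1, state.n2
    H, W = n1.shape
    radii = np.arange(r_min, r_max + 1e-9, dr)
    if radii.size < 5:
        raise ValueError("radius range too small for a spiral fit")

    per_radius: list[np.ndarray] = []
    for r in radii:
        m = max(int(2 * math.pi * r), 64)
        theta = np.linspace(0.0, 2 * math.pi, m, endpoint=False)
        xs = np.clip(np.rint(cx + r * np.cos(theta)).astype(int), 0, W - 1)
        ys = np.clip(np.rint(cy + r * np.sin(theta)).astype(int), 0, H - 1)
        a = n1[ys, xs].astype(float)
        tot = a + n2[ys, xs]
        good = tot > 0
        if good.sum() < m // 2:
            raise ValueError(f"ring at r = {r:.1f} is mostly empty")
        f = np.empty(m)
        f[good] = a[good] / tot[good]
        if not good.all():
            idx = np.arange(m)
            f[~good] = np.interp(idx[~good], idx[good], f[good], period=m)
        fs = _smooth_periodic(f, smooth)
        d = fs - 0.5
        dn = np.roll(d, -1)
        cross = np.flatnonzero((d * dn < 0) | ((d == 0) & (dn != 0)))
        th = (cross + d[cross] / (d[cross] - dn[cross])) * (2 * math.pi / m)
        per_radius.append(th)

    # link boundaries across radii by angular continuity
    tracks = [[th] for th in per_radius[0]]
    alive = list(range(len(tracks)))
    for th_list in per_radius[1:]:
        available = list(th_list)
        next_alive = []
        for k in alive:
            prev = tracks[k][-1] % (2 * math.pi)
            if not available:
                continue
            dists = [abs((th - prev + math.pi) % (2 * math.pi) - math.pi)
                     for th in available]
            j = int(np.argmin(dists))
            if dists[j] <= match_tol:
                th = available.pop(j)
                delta = (th - prev + math.pi) % (2 * math.pi) - math.pi
                tracks[k].append(tracks[k][-1] + delta)
                next_alive.append(k)
        alive = next_alive
    full = [np.asarray(tracks[k]) for k in alive
            if len(tracks[k]) == radii.size]
    if len(full) < min_boundaries:
        raise ValueError(
            f"only {len(full)} boundaries survive the full radius range "
            f"(minimum {min_boundaries}); fit refused"
        )
    rel = np.stack([tr - tr[0] for tr in full])
    theta_mean = rel.mean(axis=0)
    fit = fit_log_spiral(radii, theta_mean)
    fit.n_boundaries = len(full)
    return fit


def boundary_width(state: LatticeState, y_window: tuple[int, int]) -> tuple[float, np.ndarray]:
    """Summed local heterozygosity per row, averaged over ``y_window``.

    For each row y in the window the per-site heterozygosity
    2 f (1 - f) with f = n1/(n1+n2) is summed over x; the result has units
    of lattice sites and measures the width of strain boundaries crossing
    that row.  Returns (mean width, per-row widths).
    """
    lo, hi = y_window
    n1 = state.n1[lo:hi].astype(float)
    ntot = n1 + state.n2[lo:hi]
    f = np.where(ntot > 0, n1 / np.where(ntot > 0, ntot, 1.0), 0.0)
    het = np.where(ntot > 0, 2.0 * f * (1.0 - f), 0.0)
    per_row = het.sum(axis=1)
    return float(per_row.mean()), per_row


def fit_bulge_slopes(profile: FrontProfile, x_b: float,
                     fit_window: tuple[float, float] = (8.0, 40.0)):
    """Linear fits of h(x) on each side of a boundary, excluding the apex.

    ``fit_window = (inner, outer)`` is the distance range from ``x_b`` used
    on each side; the inner margin excludes the rounded apex.  Returns
    ((slope_left, se_left), (slope_right, se_right)); for a symmetric bulge
    the magnitudes agree within error and equal alpha/(2 Dh).
    """
    W = profile.h.size
    inner, outer = fit_window
    if not 0 < inner < outer:
        raise ValueError("fit_window must satisfy 0 < inner < outer")
    # center the profile on the boundary to avoid the periodic seam
    shift = int(round(W / 2 - x_b))
    h = np.roll(profile.h, shift)
    xc = (x_b + shift) % W
    x = np.arange(W, dtype=float)
    out = []
    for side in (-1, +1):
        dist = side * (x - xc)
        keep = (dist >= inner) & (dist <= outer) & ~np.isnan(h)
        if keep.sum() < 3:
            raise ValueError("fit window contains fewer than 3 valid columns")
        res = stats.linregress(x[keep], h[keep])
        out.append((float(res.slope), float(res.stderr)))
    return tuple(out)
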