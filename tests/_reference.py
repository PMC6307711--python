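"""Naive per-site reference implementation of the deterministic update.

Independent oracle for the vectorized kernel: plain Python loops over
sites and migration directions, with the direction-relative neighbour
tables written out explicitly (left = 90 degrees counterclockwise from the
migration direction).  Periodic in x, closed in y (missing neighbours count
as empty; no flux leaves the lattice through the top/bottom edges).
"""

import numpy as np

# direction -> (dx, dy) of destination, left, back, right sites
# relative to the migration direction
_DIRS = {
    "east": dict(dest=(1, 0), left=(0, 1), back=(-1, 0), right=(0, -1)),
    "west": dict(dest=(-1, 0), left=(0, -1), back=(1, 0), right=(0, 1)),
    "north": dict(dest=(0, 1), left=(-1, 0), back=(0, -1), right=(1, 0)),
    "south": dict(dest=(0, -1), left=(1, 0), back=(0, 1), right=(-1, 0)),
}


def _density(n, x, y, W, H):
    x = x % W  # periodic in x
    if y < 0 or y >= H:
        return 0.0  # empty beyond the top/bottom edges
    return float(n[y, x])


def naive_flux(n_a, n_tot, x, y, direction, p, N):
    """Expected migrants of one strain out of (x, y) along one direction."""
    H, W = n_tot.shape
    d = _DIRS[direction]
    dest_x, dest_y = x + d["dest"][0], y + d["dest"][1]
    if dest_y < 0 or dest_y >= H:
        return 0.0  # no migration through the y edges
    u_src = _density(n_tot, x, y, W, H) / N
    u_dest = _density(n_tot, dest_x, dest_y, W, H) / N
    u_left = _density(n_tot, x + d["left"][0], y + d["left"][1], W, H) / N
    u_back = _density(n_tot, x + d["back"][0], y + d["back"][1], W, H) / N
    u_right = _density(n_tot, x + d["right"][0], y + d["right"][1], W, H) / N
    bracket = (p.m0 + p.ms * u_src + p.md * u_dest + p.ml * u_left
               + p.mb * u_back + p.mr * u_right)
    return float(n_a[y, x]) * (1.0 - u_dest) * bracket


def naive_deterministic_update(n1, n2, p1, p2, N, dt=1.0):
    """Loop-based synchronous update returning (rho1, rho2), clamped."""
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    n_tot = n1 + n2
    H, W = n_tot.shape
    rhos = []
    for n_a, p in ((n1, p1), (n2, p2)):
        rho = np.empty((H, W))
        for y in range(H):
            for x in range(W):
                growth = p.g * n_a[y, x] * (1.0 - n_tot[y, x] / N)
                mig = 0.0
                for direction, d in _DIRS.items():
                    mig -= naive_flux(n_a, n_tot, x, y, direction, p, N)
                    # incoming: the neighbour opposite to `direction` sends
                    # flux along `direction` into (x, y)
                    sx, sy = x - d["dest"][0], y - d["dest"][1]
                    if 0 <= sy < H:
                        mig += naive_flux(n_a, n_tot, sx % W, sy, direction,
                                          p, N)
                rho[y, x] = n_a[y, x] + (growth + mig) * dt
        rhos.append(rho)
    rho1, rho2 = rhos
    rho1 = np.clip(rho1, 0.0, N)
    rho2 = np.clip(rho2, 0.0, N)
    tot = rho1 + rho2
    over = tot > N
    rho1[over] *= N / tot[over]
    rho2[over] *= N / tot[over]
    return rho1, rho2
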