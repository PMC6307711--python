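"""Map lattice migration coefficients to continuum transport coefficients.

In the deterministic limit the lattice model coarse-grains to a
reaction-diffusion equation whose flux contains a density-dependent
diffusivity D(n), a straight (down-gradient) advection strength S(n), and a
chiral advection strength A(n) that multiplies the gradient rotated by 90
degrees.  A(n) is the only term that changes sign under mirror reflection;
its sign encodes handedness (positive = left-handed here).

The composite parameters of the one-dimensional front theory follow from
the strain chiralities: ``f* = chi1 / (chi1 - chi2)``.  The couplings
``alpha/Dh`` and ``beta/v0`` are estimated empirically from simulated bulge
slopes and boundary velocities rather than derived from the microscopic
coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lattice import StrainParams

__all__ = [
    "ContinuumCoeffs",
    "continuum_coefficients",
    "chirality_measure",
    "effective_f_star",
    "estimate_theory_ratios",
]


@dataclass(frozen=True)
class ContinuumCoeffs:
    """Continuum transport coefficients evaluated at one density.

    D: diffusivity (length^2/time); S: straight advection strength;
    A: chiral advection strength (sign = handedness, positive = left-handed).
    """

    D: float
    S: float
    A: float
    n: float
    N: int


def continuum_coefficients(params: StrainParams, n: float, N: int,
                           dx: float = 1.0, dt: float = 1.0) -> ContinuumCoeffs:
    """Evaluate D, S, A at total density ``n``.

    D and A carry an overall (1 - n/N) exclusion factor and therefore vanish
    at carrying capacity; A is proportional to ``ml - mr`` and D to
    ``ml + mr``, so chirality and motility can be tuned independently.
    """
    if not 0 <= n <= N:
        raise ValueError("n must lie in [0, N]")
    u = n / N
    msum = params.ms + params.md + params.ml + params.mb + params.mr
    scale = dx * dx / dt
    D = (params.m0 + u * msum) * (1.0 - u) * scale
    S = (2.0 * (params.mb - params.md) * (1.0 - u)
         + (params.m0 + msum)) * scale
    A = 2.0 * (params.ml - params.mr) * (1.0 - u) * scale
    return ContinuumCoeffs(D=D, S=S, A=A, n=n, N=N)


def chirality_measure(params: StrainParams) -> float:
    """Signed scalar chirality ``chi = ml - mr`` (> 0 = left-handed)."""
    return params.ml - params.mr


def effective_f_star(chi1: float, chi2: float) -> tuple[float, bool]:
    """Composite chirality ``f* = chi1 / (chi1 - chi2)``.

    The convention that makes the front-theory couplings positive requires
    strain 1 to be the more left-handed strain; if the caller's ordering
    violates this, the strains are swapped internally and the returned flag
    is True (then ``f*`` refers to the swapped labelling).

    ``f* in (0, 1)`` means opposite handedness; 1/2 means equal-and-opposite
    chirality; 0 and 1 are the non-chiral-vs-chiral edge cases.
    """
    if chi1 == chi2:
        raise ValueError(
            "strains have equal chirality: f* is undefined (no composite "
            "boundary dynamics)"
        )
    swapped = chi1 < chi2
    if swapped:
        chi1, chi2 = chi2, chi1
    return chi1 / (chi1 - chi2), swapped


def estimate_theory_ratios(slope_left: float | None = None,
                           slope_right: float | None = None,
                           slope_se: float = 0.0,
                           v_parallel: float | None = None,
                           v_parallel_se: float = 0.0,
                           v0: float | None = None,
                           f_star: float | None = None) -> dict:
    """Empirical estimates of the front-theory ratios alpha/Dh and beta/v0.

    For a symmetric bulge (``f* = 1/2``) the two slope magnitudes equal
    ``alpha/(2 Dh)``, so ``alpha/Dh = 2 |slope|`` (slopes averaged when both
    sides are given).  ``beta/v0`` follows from a measured boundary drift
    velocity via ``v_par = beta (1/2 - f*)``; at ``f* = 1/2`` that estimator
    is degenerate and is refused.

    Returns a dict with the available estimates and propagated standard
    errors.
    """
    out: dict = {}
    slopes = [abs(s) for s in (slope_left, slope_right) if s is not None]
    if slopes:
        out["alpha_over_Dh"] = 2.0 * float(np.mean(slopes))
        out["alpha_over_Dh_se"] = 2.0 * slope_se / math.sqrt(len(slopes))
    if v_parallel is not None:
        if v0 is None or f_star is None:
            raise ValueError("v0 and f_star are required with v_parallel")
        denom = v0 * (0.5 - f_star)
        if denom == 0.0:
            raise ZeroDivisionError(
                "f* = 1/2: boundary velocity carries no information about "
                "beta; use the symmetric bulge-slope estimator instead"
            )
        out["beta_over_v0"] = v_parallel / denom
        out["beta_over_v0_se"] = abs(v_parallel_se / denom)
    if "alpha_over_Dh" in out and "beta_over_v0" in out and out["alpha_over_Dh"]:
        # slope of the equilibrium-fraction line in the coexistence window
        out["coexistence_slope"] = out["beta_over_v0"] / out["alpha_over_Dh"]
    return out
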