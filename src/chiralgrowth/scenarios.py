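"""Named, reproducible competition scenarios and parameter scans.

Each scenario bundles the lattice geometry, strain parameters and initial
condition of one reference experiment (circular sectoring
colony, mutual invasion, growth-penalty competition, bulge formation,
equilibrium-fraction scans, the intermixing transition, velocity checks).
Scenarios carry the reference parameters as defaults and ship a
``scaled`` desk-scale variant (linear dimensions divided by ~3-5) for quick
runs; measured tolerances widen accordingly.

All randomness is derived from one integer seed via ``SeedSequence``
spawning, so any scenario re-run with the same seed is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cg_io
from . import observables as obs
from .lattice import LatticeConfig, Simulation, StrainParams
from .theory import bulge_profile, step_fraction_profile, TheoryParams, FrontFields

__all__ = [
    "Scenario",
    "RunResult",
    "SCENARIOS",
    "get_scenario",
    "opposite_chirality_pair",
    "run_replicate",
    "run_scenario",
    "scan",
    "make_fixture",
]


@dataclass(frozen=True)
class Scenario:
    """A fully specified simulation experiment."""

    name: str
    description: str
    geometry: str  # "linear" | "radial"
    width: int
    height: int
    N: int
    strain1: StrainParams
    strain2: StrainParams
    init_mode: str = "well_mixed"  # linear: well_mixed | two_domains | single_patch
    f0: float = 0.5
    init_rows: int = 8
    patch_width: int | None = None
    patch_strain: int = 1
    radius: float = 30.0
    replicates: int = 4
    max_steps: int = 10_000
    measure_every: int = 50
    band_depth: int = 10
    window_behind: int = 30
    window_ahead: int = 30

    def config(self, seed: int | None = None) -> LatticeConfig:
        return LatticeConfig(width=self.width, height=self.height, N=self.N,
                             window_behind=self.window_behind,
                             window_ahead=self.window_ahead, seed=seed)


def opposite_chirality_pair(f_star: float, delta_chi: float = 0.1,
                            motility: float = 0.1, g: float = 0.1,
                            m0: float = 0.0) -> tuple[StrainParams, StrainParams]:
    """Strain pair with composite chirality ``f*`` at fixed chirality
    difference and fixed motility ``ml + mr``.

    chi1 = f* * delta_chi and chi2 = chi1 - delta_chi, so strain 1 is the
    more left-handed strain and f* = chi1/(chi1 - chi2) exactly.
    """
    chi1 = f_star * delta_chi
    chi2 = chi1 - delta_chi
    def mk(chi):
        return StrainParams(g=g, m0=m0, ml=(motility + chi) / 2,
                            mr=(motility - chi) / 2)
    return mk(chi1), mk(chi2)


def _strains(g, ml1, mr1, ml2, mr2, m0=0.0):
    return (StrainParams(g=g, m0=m0, ml=ml1, mr=mr1),
            StrainParams(g=g, m0=m0, ml=ml2, mr=mr2))


def _registry() -> dict[str, Scenario]:
    s: dict[str, Scenario] = {}
    p1, p2 = _strains(0.03, 0.045, 0.005, 0.045, 0.005)
    s["circular_sectors"] = Scenario(
        name="circular_sectors", geometry="radial", width=700, height=700,
        N=100, strain1=p1, strain2=p2, f0=0.5, radius=30.0, replicates=1,
        max_steps=4000, measure_every=100,
        description="Well-mixed circular colony of two equally left-handed "
                    "strains; sector boundaries twist counterclockwise as "
                    "logarithmic spirals.")
    p1, p2 = _strains(0.1, 0.05, 0.05, 0.01, 0.09)
    s["patch_invasion"] = Scenario(
        name="patch_invasion", geometry="linear", width=600, height=3300,
        N=200, strain1=p1, strain2=p2, init_mode="single_patch",
        patch_width=60, patch_strain=2, replicates=1, max_steps=12_000,
        description="A localized right-handed patch invades and displaces a "
                    "non-chiral resident.")
    p1, p2 = _strains(0.1, 0.09, 0.01, 0.01, 0.09)
    s["opposite_chirality_coexistence"] = Scenario(
        name="opposite_chirality_coexistence", geometry="linear", width=600,
        height=3000, N=200, strain1=p1, strain2=p2, init_mode="well_mixed",
        f0=0.5, replicates=4, max_steps=10_000,
        description="Equal-and-opposite chirality from well-mixed initial "
                    "conditions; the left-handed fraction converges to 1/2.")
    p1 = StrainParams(g=0.01, ml=0.1, mr=0.0)
    p2 = StrainParams(g=0.01, ml=0.05, mr=0.05)
    s["growth_penalty_chiral_vs_nonchiral"] = Scenario(
        name="growth_penalty_chiral_vs_nonchiral", geometry="linear",
        width=1000, height=3600, N=200, strain1=p1, strain2=p2,
        f0=0.5, replicates=1, max_steps=60_000, measure_every=200,
        description="Left-handed strain vs a faster-growing non-chiral "
                    "strain; scan the growth advantage of strain 2.")
    p1, p2 = _strains(0.1, 0.09, 0.01, 0.01, 0.09)
    s["growth_penalty_opposite_chirality"] = Scenario(
        name="growth_penalty_opposite_chirality", geometry="linear",
        width=500, height=3000, N=200, strain1=p1, strain2=p2,
        f0=0.5, replicates=1, max_steps=12_000, measure_every=100,
        description="Equal-and-opposite chirality with a growth-rate "
                    "difference; coexistence persists up to ~7%.")
    p1, p2 = _strains(0.1, 0.009, 0.001, 0.001, 0.009)
    s["bulge_formation"] = Scenario(
        name="bulge_formation", geometry="linear", width=2400, height=2100,
        N=200, strain1=p1, strain2=p2, init_mode="two_domains", f0=0.5,
        replicates=1, max_steps=30_000, measure_every=200,
        description="Two weakly, oppositely chiral domains; a triangular "
                    "bulge grows at the in-flow boundary and a shallow dip "
                    "at the out-flow boundary.")
    p1, p2 = opposite_chirality_pair(0.5, delta_chi=0.1, motility=0.1,
                                     g=0.1)
    s["equilibrium_fraction_scan"] = Scenario(
        name="equilibrium_fraction_scan", geometry="linear", width=300,
        height=3000, N=400, strain1=p1, strain2=p2, f0=0.5, replicates=2,
        max_steps=9000,
        description="Equilibrium fraction vs composite chirality f* at "
                    "fixed chirality difference 0.1 and motility 0.1.")
    p1, p2 = opposite_chirality_pair(0.5, delta_chi=0.1, motility=0.1,
                                     g=0.1, m0=0.01)
    s["equilibrium_fraction_scan_narrow"] = Scenario(
        name="equilibrium_fraction_scan_narrow", geometry="linear",
        width=300, height=3000, N=200, strain1=p1, strain2=p2, f0=0.5,
        replicates=2, max_steps=9000,
        description="As equilibrium_fraction_scan but with a density-"
                    "independent migration floor m0 = 0.01; the coexistence "
                    "window narrows and the f̄_eq slope steepens.")
    p1, p2 = _strains(0.1, 0.075, 0.025, 0.025, 0.075)
    s["mixing_transition_drift"] = Scenario(
        name="mixing_transition_drift", geometry="linear", width=1000,
        height=8000, N=40, strain1=p1, strain2=p2, f0=0.5, replicates=1,
        max_steps=25_000, measure_every=200,
        description="Opposite handedness at fixed chirality 0.05; scan the "
                    "per-site carrying capacity N across the "
                    "segregation/intermixing transition.")
    p1, p2 = opposite_chirality_pair(0.5, delta_chi=0.1, motility=0.1, g=0.1)
    s["mixing_transition_chirality"] = Scenario(
        name="mixing_transition_chirality", geometry="linear", width=1000,
        height=8000, N=200, strain1=p1, strain2=p2, f0=0.5, replicates=1,
        max_steps=25_000, measure_every=200,
        description="Fixed N = 200 and motility 0.1; scan the chirality "
                    "magnitude across the intermixing transition.")
    p = StrainParams(g=0.1, ml=0.05, mr=0.05)
    s["velocity_check"] = Scenario(
        name="velocity_check", geometry="linear", width=200, height=1000,
        N=200, strain1=p, strain2=p, f0=1.0, replicates=4, max_steps=4000,
        measure_every=20,
        description="Isolated-strain expansion velocity at fixed motility "
                    "ml + mr = 0.1; chirality does not change the speed.")
    return s


SCENARIOS = _registry()

# desk-scale presets: linear dimensions divided by ~3-5, small lattices for
# quick qualitative runs; replicates raised so averages stay meaningful
_SCALED: dict[str, dict] = {
    "circular_sectors": dict(width=300, height=300, radius=15.0, max_steps=1500),
    "patch_invasion": dict(width=150, height=1200, patch_width=16, max_steps=4000),
    "opposite_chirality_coexistence": dict(width=200, height=1000, N=100,
                                           max_steps=4000),
    "growth_penalty_chiral_vs_nonchiral": dict(width=128, height=1600,
                                               max_steps=30_000),
    "growth_penalty_opposite_chirality": dict(width=128, height=2400,
                                              max_steps=8000),
    "bulge_formation": dict(width=600, height=700, max_steps=9000),
    "equilibrium_fraction_scan": dict(width=150, height=1500, max_steps=5000),
    "equilibrium_fraction_scan_narrow": dict(width=150, height=1500,
                                             max_steps=5000),
    "mixing_transition_drift": dict(width=200, height=2600, max_steps=7000),
    "mixing_transition_chirality": dict(width=200, height=2600, max_steps=7000),
    "velocity_check": dict(width=128, height=700, max_steps=2200),
}


def get_scenario(name: str, scaled: bool = False) -> Scenario:
    """Look up a named scenario, optionally in its desk-scale variant."""
    try:
        sc = SCENARIOS[name]
    except KeyError:
        known = ", ".join(sorted(SCENARIOS))
        raise KeyError(f"unknown scenario {name!r}; known: {known}") from None
    if scaled:
        over = dict(_SCALED.get(name, {}))
        over["replicates"] = max(sc.replicates, 4)
        sc = replace(sc, **over)
    return sc


def set_parameter(scenario: Scenario, path: str, value) -> Scenario:
    """Return a copy of the scenario with one dotted-path field replaced.

    Examples: ``N``, ``f0``, ``strain2.g``, ``strain1.ml``."""
    parts = path.split(".")
    if len(parts) == 1:
        if not hasattr(scenario, parts[0]):
            raise AttributeError(f"scenario has no field {path!r}")
        return replace(scenario, **{parts[0]: value})
    if len(parts) == 2 and parts[0] in ("strain1", "strain2"):
        strain = getattr(scenario, parts[0])
        if not hasattr(strain, parts[1]):
            raise AttributeError(f"strain has no field {parts[1]!r}")
        return replace(scenario, **{parts[0]: replace(strain, **{parts[1]: value})})
    raise AttributeError(f"cannot resolve parameter path {path!r}")


@dataclass
class RunResult:
    """Time series and final state of one replicate."""

    scenario: str
    seed: int
    times: np.ndarray
    f_bar: np.ndarray
    H_front: np.ndarray
    H_window: np.ndarray
    h_mean: np.ndarray
    state: object
    stop_reason: str

    def final_fraction(self, tail: int = 5) -> float:
        return float(np.mean(self.f_bar[-tail:]))

    def final_heterozygosity(self, tail: int = 5) -> float:
        return float(np.mean(self.H_window[-tail:]))

    def trailing_slope(self, tail_frac: float = 0.2) -> float:
        """Linear-fit slope of f̄ over the trailing fraction of samples."""
        k = max(int(len(self.times) * tail_frac), 3)
        t, f = self.times[-k:], self.f_bar[-k:]
        if len(t) < 3 or t[-1] == t[0]:
            return np.nan
        return float(np.polyfit(t, f, 1)[0])

    def converged(self, tol: float = 1e-5, min_samples: int = 10) -> bool:
        if len(self.times) < min_samples:
            return False
        slope = self.trailing_slope()
        return bool(np.isfinite(slope) and abs(slope) <= tol)

    @property
    def extinct(self) -> bool:
        return self.f_bar[-1] <= 0.0 or self.f_bar[-1] >= 1.0


def run_replicate(scenario: Scenario, seed: int,
                  max_steps: int | None = None) -> RunResult:
    """Run one replicate of a scenario and record its measurement series."""
    if scenario.replicates < 1:
        raise ValueError("replicate count must be >= 1")
    config = scenario.config(seed=seed)
    sim = Simulation(config, scenario.strain1, scenario.strain2, seed=seed)
    if scenario.geometry == "radial":
        sim.init_circular_colony(scenario.radius, scenario.f0)
    else:
        kw = {}
        if scenario.init_mode == "single_patch":
            kw = dict(patch_width=scenario.patch_width)
            if scenario.patch_strain == 2:
                # embed a strain-2 patch by building the mirror-labelled state
                sim_sw = Simulation(config, scenario.strain2, scenario.strain1,
                                    rng=sim.rng)
                st = sim_sw.init_linear_front(scenario.f0, "single_patch", **kw)
                st.n1, st.n2 = st.n2, st.n1
                sim.state = st
            else:
                sim.init_linear_front(scenario.f0, "single_patch", **kw)
        else:
            sim.init_linear_front(scenario.f0, scenario.init_mode,
                                  rows=scenario.init_rows)

    times, f_bar, H_front, H_window, h_mean = [], [], [], [], []

    def measure(s: Simulation):
        st = s.state
        times.append(st.t)
        H_window.append(obs.window_heterozygosity(st))
        if scenario.geometry == "radial":
            n1 = st.n1.sum()
            ntot = n1 + st.n2.sum()
            f_bar.append(n1 / ntot if ntot else np.nan)
            H_front.append(np.nan)
            h_mean.append(st.r_front)
        else:
            prof = obs.front_profile(st, config.N, scenario.band_depth)
            f_bar.append(obs.global_fraction(prof))
            H_front.append(obs.heterozygosity(prof))
            h_mean.append(float(np.nanmean(prof.h)))

    reason = sim.run(max_steps or scenario.max_steps, callback=measure,
                     callback_every=scenario.measure_every)
    return RunResult(scenario=scenario.name, seed=seed,
                     times=np.asarray(times), f_bar=np.asarray(f_bar),
                     H_front=np.asarray(H_front),
                     H_window=np.asarray(H_window),
                     h_mean=np.asarray(h_mean), state=sim.state,
                     stop_reason=reason)


def run_scenario(scenario: Scenario, out_dir, seed: int = 0,
                 replicates: int | None = None, write_png: bool = False) -> Path:
    """Run all replicates of a scenario and write a tidy run directory.

    Contents: ``measurements.tsv`` (one row per replicate and sample time),
    one final snapshot TSV (optionally PNG) per replicate, and
    ``metadata.json`` with the full parameter set, seeds and stop reasons.
    """
    replicates = scenario.replicates if replicates is None else replicates
    if replicates < 1:
        raise ValueError("replicate count must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in np.random.SeedSequence(seed).spawn(replicates)]
    rows = []
    reasons = []
    for rep, s in enumerate(child_seeds):
        res = run_replicate(scenario, s)
        reasons.append(res.stop_reason)
        for i in range(len(res.times)):
            rows.append(dict(replicate=rep, t=res.times[i],
                             f_bar=res.f_bar[i], H_front=res.H_front[i],
                             H_window=res.H_window[i], h_mean=res.h_mean[i]))
        cg_io.write_snapshot_tsv(out_dir / f"snapshot_rep{rep}.tsv", res.state)
        if write_png:
            cg_io.write_snapshot_png(out_dir / f"snapshot_rep{rep}.png",
                                     res.state, scenario.N)
    pd.DataFrame(rows).to_csv(out_dir / "measurements.tsv", sep="\t",
                              index=False)
    cg_io.write_metadata(out_dir / "metadata.json", scenario=scenario,
                         seed=seed, replicate_seeds=child_seeds,
                         stop_reasons=reasons)
    return out_dir


def scan(scenario: Scenario, axis: str, values, replicates: int = 1,
         seed: int = 0, slope_tol: float = 1e-5) -> pd.DataFrame:
    """Run the scenario once per (axis value, replicate) and summarize.

    Returns one row per run with the endpoint fraction and heterozygosity,
    an extinction flag (f̄ pinned at 0 or 1) and a convergence flag from the
    trailing-slope steady-state test.  Results are independent of the order
    of ``values``: each run's seed derives from (seed, value index is not
    used) the value itself and the replicate index.
    """
    values = list(values)
    rows = []
    for value in values:
        sc = set_parameter(scenario, axis, value)
        for rep in range(replicates):
            # seed depends on (seed, value, rep) only => permutation invariant
            value_key = int(np.abs(np.float64(value).view(np.int64))) % (2 ** 31)
            ss = np.random.SeedSequence([seed, value_key, rep])
            child = int(ss.generate_state(1)[0] % (2 ** 31))
            res = run_replicate(sc, child)
            rows.append(dict(value=value, replicate=rep,
                             f_final=res.final_fraction(),
                             H_final=res.final_heterozygosity(),
                             extinct=res.extinct,
                             converged=res.converged(tol=slope_tol),
                             stop_reason=res.stop_reason))
    return pd.DataFrame(rows)


def make_fixture(kind: str, seed: int = 0, **params):
    """Deterministic, self-describing small test inputs.

    Kinds: ``tiny_lattice`` (random occupancy pair), ``step_front`` (sharp
    composition step for the front integrator), ``spiral_track`` (exact
    Bernoulli spiral samples), ``triangle_bulge`` (exact triangular bulge
    profile).
    """
    rng = np.random.default_rng(seed)
    if kind == "tiny_lattice":
        h = params.get("height", 10)
        w = params.get("width", 10)
        N = params.get("N", 20)
        n1 = rng.integers(0, N + 1, size=(h, w))
        n2 = rng.integers(0, N + 1, size=(h, w))
        over = n1 + n2 > N
        n2[over] = N - n1[over]
        return n1.astype(np.int64), n2.astype(np.int64)
    if kind == "step_front":
        L = params.get("length", 256)
        dx = params.get("dx", 1.0)
        edges = params.get("edges", [(L * dx / 4, +1), (3 * L * dx / 4, -1)])
        x = dx * np.arange(L)
        f = step_fraction_profile(x, edges, width=2 * dx)
        return FrontFields(dx=dx, h=np.zeros(L), f=f)
    if kind == "spiral_track":
        c0 = params.get("c0", 0.0)
        c1 = params.get("c1", 0.3)
        r = np.asarray(params.get("radii", np.arange(20.0, 120.0)))
        return r, c0 + c1 * np.log(r)
    if kind == "triangle_bulge":
        tp = TheoryParams(v0=params.get("v0", 0.4), Dh=params.get("Dh", 1.0),
                          alpha=params.get("alpha", 0.08),
                          Df=1.0, beta=0.0, f_star=0.5)
        t = params.get("t", 1000.0)
        L = params.get("length", 512)
        x = np.arange(L, dtype=float)
        return x, bulge_profile(x, t, tp, x_b=params.get("x_b", L / 2)), tp, t
    raise ValueError(f"unknown fixture kind {kind!r}")
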