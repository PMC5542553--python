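"""End-to-end simulation loop, scenario presets and inoculum generation.

Each biological step executes, in order: (1) quasi-steady solve of the
solute fields with the current uptake sinks; (2) explicit-Euler
growth/decay of every agent at its voxel's concentrations; (3) division,
EPS excretion, death and removal; (4) adhesive-link rebuild; (5) DEM
relaxation to mechanical equilibrium, followed — under flow — by a window
of overdamped advection at the imposed shear.  Detachment bookkeeping
(connected components, attached/detached transitions, outflow removal)
closes the step.

Presets encode the study conditions: the full-scale cases (100x40x100 um
box, 30x12x30 grid, 40-cell inoculum, 15 % stop volume, shear rates up to
0.24 1/s, doubled box for detachment tracking) and desk-scale reductions
(40x10x40 um box, 12x4x12 grid, 8-cell inoculum, ~12 um stop height, a
softer contact spring so the overdamped time step stays practical) used by
the trend suite.  Full-scale presets carry ``desk_scale=False``: they
represent days of simulated growth and are not meant for interactive runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinetics, lifecycle
from .agents import AOB, HET, NOB, AgentState
from .analysis import clusters, height_field
from .config import Domain, Parameters, mass_from_radius, params_for_groups
from .mechanics import AdhesiveLinks, build_links, relax
from .solute import shear_flow, solve_quasi_steady

__all__ = ["Scenario", "Frame", "SnapshotSeries", "make_inoculum", "run",
           "preset", "PRESET_NAMES"]


@dataclass
class Scenario:
    """Run protocol: inoculum, feed wall, flow schedule, stop condition."""

    name: str = "growth"
    inoculum: int = 40
    inoculum_mode: str = "grid"          # "grid" | "three_species"
    inoculum_span: float = 1.0           # fraction of L_x seeded (detachment
                                         # cases leave downstream track room)
    feed: str = "top"                    # nutrient Dirichlet wall
    gamma_dot: float = 0.0               # shear during growth (1/s)
    flow_time: float = 2.0               # s of advection per bio step under flow
    relax_max_time: float = 1.0          # s budget for quiescent relaxation
    relax_pressure_tol: float = 1e-3     # relative virial-pressure tolerance
    stop_height: float | None = None     # um
    stop_volume_fraction: float | None = None
    max_bio_steps: int = 500
    snapshot_every: int = 20
    shear_gamma_dot: float | None = None  # post-growth shear phase (1/s)
    shear_duration: float = 0.0           # s of flow time in that phase
    shear_window: float = 5.0             # s per detachment-check window
    solute_tol: float = 1e-5
    max_agents: int = 30000
    replicates: int = 5
    desk_scale: bool = True
    description: str = ""


@dataclass
class Frame:
    time: float        # biological time (s)
    t_flow: float      # accumulated flow/mechanics time in shear phases (s)
    agents: AgentState


@dataclass
class SnapshotSeries:
    """Time-stamped agent states plus event logs and final fields."""

    frames: list
    events: pd.DataFrame
    detach_events: pd.DataFrame
    metrics: pd.DataFrame
    fields: dict
    params: Parameters
    domain: Domain
    scenario_info: dict
    seed: int
    removed_mass: float = 0.0

    @property
    def final(self) -> AgentState:
        return self.frames[-1].agents

    def tstar(self, mu_m_per_h: float | None = None) -> np.ndarray:
        """Non-dimensional growth time T* = t * mu_m for each frame."""
        mu = (self.params.mu_m if mu_m_per_h is None else mu_m_per_h) / 3600.0
        return np.array([f.time for f in self.frames]) * mu

    def save(self, path) -> None:
        from .io import save_series
        save_series(self, path)


def make_inoculum(scenario: Scenario, domain: Domain, p,
                  rng: np.random.Generator) -> AgentState:
    """Seed bacteria of 1 um diameter resting on the substratum (z = r).

    "grid" spreads the requested count evenly over the substratum with a
    small jitter (stochastic symmetry breaking); "three_species" places one
    HET, one AOB and one NOB near the domain centre.
    """
    r0 = 0.5
    m0 = mass_from_radius(r0, p.rho_X)
    if scenario.inoculum_mode == "three_species":
        cx, cy = domain.L_x / 2.0, domain.L_y / 2.0
        pos = np.array([[cx - 1.0, cy, r0], [cx + 1.0, cy, r0], [cx, cy + 1.0, r0]])
        agents = AgentState.empty()
        agents.append(np.array([HET, AOB, NOB], np.int8), pos, m0)
        return agents
    count = scenario.inoculum
    if count < 1:
        raise ValueError("inoculum count must be >= 1")
    span = scenario.inoculum_span * domain.L_x
    nx = max(1, int(round(np.sqrt(count * span / domain.L_y))))
    ny = int(np.ceil(count / nx))
    if nx * ny < count:
        nx += 1
    sx, sy = span / nx, domain.L_y / ny
    if min(sx, sy) < 2.0 * r0:
        raise ValueError(
            f"inoculum of {count} cells exceeds substratum packing "
            f"({nx}x{ny} grid, spacing {min(sx, sy):.2f} um < 1 um)")
    jitter = 0.2
    xs, ys = [], []
    for k in range(count):
        i, j = k % nx, k // nx
        xs.append((i + 0.5) * sx)
        ys.append((j + 0.5) * sy)
    pos = np.column_stack([
        (np.array(xs) + rng.uniform(-jitter, jitter, count) * sx) % span,
        (np.array(ys) + rng.uniform(-jitter, jitter, count) * sy) % domain.L_y,
        np.full(count, r0)])
    agents = AgentState.empty()
    agents.append(np.full(count, HET, np.int8), pos, m0)
    return agents


# ---------------------------------------------------------------------------
# detachment bookkeeping

class _DetachTracker:
    """Tracks attached/detached transitions between successive states.

    An agent contributes to at most one detachment event: clusters that
    transiently re-agglomerate with the film and break off again are not
    re-counted (the ledger entries are merged).
    """

    def __init__(self):
        self.attached_ids: set = set()
        self.ever_detached: set = set()
        self.events: list[dict] = []

    def update(self, agents: AgentState, links, domain, p,
               time: float, t_flow: float) -> None:
        if agents.n == 0:
            self.attached_ids = set()
            return
        cs = clusters(agents, links, domain, p)
        vol = agents.volume(p)
        attached_vol = float(vol[cs.attached[cs.labels]].sum())
        now_attached: set = set()
        for c in range(cs.n):
            ids = agents.id[cs.members[c]]
            if cs.attached[c]:
                now_attached.update(int(i) for i in ids)
            else:
                newly = [int(i) for i in ids
                         if int(i) in self.attached_ids
                         and int(i) not in self.ever_detached]
                if newly:
                    self.events.append({
                        "time": time, "t_flow": t_flow,
                        "n_agents": int(ids.size),
                        "volume": float(cs.volumes[c]),
                        # normalized by the remaining (attached) volume;
                        # undefined once the film is gone
                        "norm_volume": (float(cs.volumes[c]) / attached_vol
                                        if attached_vol > 0 else np.nan),
                    })
                self.ever_detached.update(int(i) for i in ids)
        self.attached_ids = now_attached


def _outflow_removal(agents: AgentState, domain: Domain) -> float:
    """Remove agents whose centres crossed the open x boundaries; returns
    the removed biomass (fg)."""
    if domain.bc_x == "periodic" or agents.n == 0:
        return 0.0
    gone = (agents.position[:, 0] < 0.0) | (agents.position[:, 0] > domain.L_x)
    if not gone.any():
        return 0.0
    mass = float(agents.mass[gone].sum() + agents.eps_shell[gone].sum())
    agents.remove(gone)
    return mass


# ---------------------------------------------------------------------------
# main loop

def run(params: Parameters, domain: Domain, scenario: Scenario, seed: int,
        network=None, initial: AgentState | None = None) -> SnapshotSeries:
    """Run one replicate of a scenario; fully deterministic for a seed.

    ``initial`` replaces the generated inoculum (e.g. a pre-grown biofilm
    for a pure shear/detachment phase with ``max_bio_steps = 0``).
    """
    rng = np.random.default_rng(seed)
    params = params.resolved(domain)
    p = params.internal()
    if network is not None:
        net = network
    elif scenario.inoculum_mode == "three_species":
        net = kinetics.three_species_network(p)
    else:
        net = kinetics.single_species_network(p)
    agents = (initial.copy() if initial is not None
              else make_inoculum(scenario, domain, p, rng))

    fields = {s: np.full(domain.shape, p.S_b) for s in net.solutes}
    U = shear_flow(domain, scenario.gamma_dot) if scenario.gamma_dot else None
    frames: list[Frame] = []
    events: list[dict] = []
    metrics: list[dict] = []
    tracker = _DetachTracker()
    removed_mass = 0.0
    links = AdhesiveLinks.none()
    time = 0.0
    t_flow = 0.0

    last_relax = {"pressure": 0.0, "steps": 0}

    def record(force=False):
        step_idx = len(metrics)
        h = height_field(agents, domain, p)
        metrics.append({
            "time": time, "t_flow": t_flow, "tstar": time * p.mu_m,
            "tss": t_flow * (scenario.shear_gamma_dot or scenario.gamma_dot or 0.0),
            "n_agents": agents.n, "total_mass": agents.total_mass(),
            "max_height": float(h.max()), "mean_height": float(h.mean()),
            "n_links": links.n_active,
            "relax_pressure": last_relax["pressure"],
            "relax_steps": last_relax["steps"],
        })
        if force or step_idx % scenario.snapshot_every == 0:
            frames.append(Frame(time, t_flow, agents.copy()))

    def stamp(evts):
        for e in evts:
            e["time"] = time
        events.extend(evts)

    record(force=True)
    for step in range(scenario.max_bio_steps):
        # 1. quasi-steady solute fields (warm-started from the last solve)
        fields, _ = solve_quasi_steady(
            fields, U, {s: p.D_S for s in net.solutes},
            lambda f: kinetics.uptake_field(agents, domain, net, f),
            domain, feed=scenario.feed, S_b=p.S_b, tol=scenario.solute_tol)
        # 2. growth / decay at the agent's voxel
        ix, iy, iz = domain.voxel_of(agents.position)
        S_local = {s: fields[s][ix, iy, iz] for s in net.solutes}
        r_net, r_shell = kinetics.agent_rates(agents, S_local, net)
        kinetics.step_biomass(agents, r_net, r_shell, params.dt_bio)
        # 3. discrete events
        stamp(lifecycle.divide(agents, p, rng))
        stamp(lifecycle.secrete_eps(agents, p, rng))
        ev, removed = lifecycle.death_and_removal(agents, p)
        stamp(ev)
        removed_mass += removed
        # 4. adhesive links
        links = build_links(agents, p, domain)
        # 5. mechanical relaxation (+ advection under flow)
        res = relax(agents, links, domain, p, gamma_dot=0.0,
                    pressure_tol=scenario.relax_pressure_tol,
                    max_time=scenario.relax_max_time)
        last_relax = {"pressure": float(res.pressures[-1])
                      if res.pressures.size else 0.0,
                      "steps": res.steps}
        if scenario.gamma_dot:
            relax(agents, links, domain, p, gamma_dot=scenario.gamma_dot,
                  pressure_tol=None, max_time=scenario.flow_time)
            t_flow += scenario.flow_time
        # cluster bookkeeping every step under flow; sparser when quiescent
        # (must precede outflow removal: links index the current arrays)
        if scenario.gamma_dot or step % 10 == 0:
            tracker.update(agents, links, domain, p, time, t_flow)
        removed_mass += _outflow_removal(agents, domain)
        time += params.dt_bio
        record()
        if agents.n > scenario.max_agents:
            raise RuntimeError(
                f"agent count {agents.n} exceeded the cap at t={time:g}s")
        h_max = metrics[-1]["max_height"]
        if scenario.stop_height is not None and h_max >= scenario.stop_height:
            break
        if scenario.stop_volume_fraction is not None:
            vfrac = float(agents.volume(p).sum()) / domain.volume
            if vfrac >= scenario.stop_volume_fraction:
                break

    # post-growth shear phase (deformation / detachment of the mature film)
    if scenario.shear_gamma_dot is not None and scenario.shear_duration > 0:
        links = build_links(agents, p, domain)
        tracker.update(agents, links, domain, p, time, t_flow)  # register state
        n_windows = int(np.ceil(scenario.shear_duration / scenario.shear_window))
        for w in range(n_windows):
            links = build_links(agents, p, domain)
            relax(agents, links, domain, p, gamma_dot=scenario.shear_gamma_dot,
                  pressure_tol=None, max_time=scenario.shear_window)
            t_flow += scenario.shear_window
            tracker.update(agents, links, domain, p, time, t_flow)
            removed_mass += _outflow_removal(agents, domain)
            record()
            if agents.n == 0:
                break
    record(force=True)

    return SnapshotSeries(
        frames=frames,
        events=pd.DataFrame(events),
        detach_events=pd.DataFrame(tracker.events),
        metrics=pd.DataFrame(metrics),
        fields=fields,
        params=params, domain=domain,
        scenario_info=dataclasses.asdict(scenario),
        seed=seed, removed_mass=removed_mass)


# ---------------------------------------------------------------------------
# presets

PRESET_NAMES = ("growth_grid", "three_species_demo", "shear_growth",
                "detachment", "growth_grid_scaled", "shear_growth_scaled",
                "detachment_scaled")

# Desk-scale study grids used by the trend suite (see docs/methods.md for
# how these map onto the full-scale conditions).
TREND_DELTA_KAPPA = ((3.0e-3, 0.35), (7.0e-3, 0.70), (1.6e-2, 1.40))
TREND_SHEAR_RATES = (0.0, 0.1, 0.7)          # 1/s, growth under shear
DETACH_SHEAR_RATES = (0.04, 0.12, 0.24)      # 1/s, pre-grown-film erosion

_SCALED_KN = 1e-6   # N/m; softer spring => practical overdamped dt_mech


def _scaled_params(**overrides) -> Parameters:
    """Desk-scale mechanics: contact spring softened so the overdamped
    spring time-scale permits dt_mech ~ 1e-3 s; densities pinned at the
    full-scale values (keeps agent masses and hence the drag/adhesion
    balance at study scale); substratum coupling in the stiff (no-slip)
    tangential limit; dt_bio doubled (growth is transport-limited)."""
    anchor = Parameters().resolved(Domain())
    kw = dict(k_n=_SCALED_KN, dt_bio=2000.0, wall_friction="no_slip",
              rho_X=anchor.rho_X, rho_EPS=anchor.rho_EPS)
    kw.update(overrides)
    return Parameters(**kw)


def preset(name: str, *, delta: float | None = None, kappa: float | None = None,
           gamma_dot: float | None = None, feed: str = "top",
           ) -> tuple[Parameters, Domain, Scenario]:
    """Build (Parameters, Domain, Scenario) for a named study case.

    delta/kappa select the nutrient condition (defaults: the baseline
    1.52e-2 / 0.35); gamma_dot the shear rate where the case uses one.
    """
    if name == "growth_grid":
        domain = Domain()
        params = Parameters().resolved(domain)
        scen = Scenario(name=name, inoculum=40, feed=feed,
                        stop_volume_fraction=0.15, max_bio_steps=1500,
                        desk_scale=False,
                        description="biofilm growth to 15% box volume, "
                                    "quiescent medium, Table-scale domain")
    elif name == "three_species_demo":
        domain = Domain()
        params = Parameters().resolved(domain)
        scen = Scenario(name=name, inoculum=3, inoculum_mode="three_species",
                        max_bio_steps=60, desk_scale=True,
                        description="HET/AOB/NOB competition demo")
    elif name == "shear_growth":
        domain = Domain()
        params = Parameters(gamma_dot=gamma_dot or 0.04).resolved(domain)
        scen = Scenario(name=name, inoculum=40, gamma_dot=gamma_dot or 0.04,
                        max_bio_steps=504, desk_scale=False,
                        description="growth under simple shear to T* = 140")
    elif name == "detachment":
        domain = Domain(L_x=200.0, N_x=60, bc_x="outflow")
        params = Parameters().resolved(domain)
        gd = gamma_dot or 0.2
        scen = Scenario(name=name, inoculum=4, inoculum_span=0.5,
                        stop_height=48.0,
                        max_bio_steps=1500, shear_gamma_dot=gd,
                        shear_duration=1.3e5 / gd, shear_window=50.0,
                        desk_scale=False,
                        description="pre-grown 48 um film sheared to "
                                    "T** = 1.3e5; doubled box, open x")
    elif name in ("growth_grid_scaled", "shear_growth_scaled",
                  "detachment_scaled"):
        if name == "detachment_scaled":
            domain = Domain(L_x=48.0, L_y=4.0, L_z=24.0,
                            N_x=36, N_y=3, N_z=18, bc_x="outflow")
            d0, k0 = 7.0e-3, 0.35
        else:
            domain = Domain(L_x=40.0, L_y=4.0, L_z=40.0,
                            N_x=30, N_y=3, N_z=30)
            d0, k0 = TREND_DELTA_KAPPA[0]
        params = _scaled_params().resolved(domain)
        params = params_for_groups(params, domain,
                                   delta if delta is not None else d0,
                                   kappa if kappa is not None else k0)
        if name == "growth_grid_scaled":
            scen = Scenario(name=name, inoculum=10, feed=feed,
                            stop_volume_fraction=0.15, max_bio_steps=900,
                            relax_pressure_tol=3e-3, snapshot_every=300,
                            description="desk-scale quiescent growth to "
                                        "15% box volume")
        elif name == "shear_growth_scaled":
            gd = gamma_dot if gamma_dot is not None else TREND_SHEAR_RATES[-1]
            scen = Scenario(name=name, inoculum=10, gamma_dot=gd,
                            stop_volume_fraction=0.15, max_bio_steps=900,
                            relax_pressure_tol=3e-3, flow_time=2.0,
                            snapshot_every=300,
                            description="desk-scale growth under shear")
        else:
            gd = gamma_dot if gamma_dot is not None else 0.12
            scen = Scenario(name=name, inoculum=8, inoculum_span=0.5,
                            stop_volume_fraction=0.12, max_bio_steps=900,
                            relax_pressure_tol=3e-3, shear_gamma_dot=gd,
                            shear_duration=90.0, shear_window=1.0,
                            snapshot_every=300,
                            description="desk-scale film growth plus "
                                        "shear-driven erosion, open x")
    else:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return params, domain, scen
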