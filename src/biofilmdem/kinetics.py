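"""Growth/decay kinetics and the configurable reaction network.

Every particulate process is a product of a maximum specific rate,
Monod saturation terms S/(K+S) and optional inhibition terms K/(K+S),
multiplied by the local concentration of the *acting* particulate group.
A stoichiometric table maps each process onto the particulate phases
(HET, AOB, NOB, EPS, INERT) and the soluble components
(S_S, S_NH4, S_NO2, S_NO3, S_O2).

Agent masses evolve by dm/dt = r * m with r the summed specific rate of
the agent's group, integrated with an explicit Euler step at the
biological time step.  A coefficient on the EPS column of a process whose
acting group is a bacterium is interpreted as EPS-*shell* production by
that bacterium; the EPS column of an EPS-acting process applies to free
EPS particles.

Two presets ship: the fully specified single-species set used for the
morphology studies (one generic heterotroph limited by the carbonaceous
substrate, with EPS and inert decay set to zero), and a representative —
explicitly non-canonical — three-species HET/AOB/NOB nitrification network
with ASM-style rate forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agents import EPS, GROUP_CODES, GROUP_NAMES, AgentState
from .config import Domain

__all__ = [
    "monod", "Process", "ReactionNetwork",
    "single_species_network", "three_species_network",
    "specific_rate", "agent_rates", "step_biomass",
    "biomass_concentrations", "uptake_field",
    "network_to_dict", "network_from_dict",
]

SOLUTES = ("S_S", "S_NH4", "S_NO2", "S_NO3", "S_O2")


def monod(S, K):
    """Saturation factor S/(K+S) in [0, 1); monotone increasing in S."""
    S = np.asarray(S, dtype=float)
    if K <= 0:
        raise ValueError("half-saturation constant K must be positive")
    if np.any(S < 0):
        raise ValueError("negative substrate concentration")
    out = S / (K + S)
    return float(out) if out.ndim == 0 else out


def inhibition(S, K):
    """Inhibition factor K/(K+S) in (0, 1]; monotone decreasing in S."""
    S = np.asarray(S, dtype=float)
    if K <= 0:
        raise ValueError("inhibition constant K must be positive")
    if np.any(S < 0):
        raise ValueError("negative substrate concentration")
    out = K / (K + S)
    return float(out) if out.ndim == 0 else out


@dataclass
class Process:
    """One kinetic process: rate = rate_max * prod Monod * prod inhibition,
    per unit concentration of the acting group.  rate_max in 1/s."""

    name: str
    group: str                        # acting particulate group ("HET", ...)
    rate_max: float                   # 1/s
    monod_terms: list = field(default_factory=list)       # [(solute, K), ...]
    inhibition_terms: list = field(default_factory=list)  # [(solute, K), ...]
    stoich: dict = field(default_factory=dict)            # component -> coeff

    def rate(self, S: dict) -> np.ndarray | float:
        """Specific rate (1/s) at local solute concentrations."""
        r = self.rate_max
        for solute, K in self.monod_terms:
            r = r * monod(S[solute], K)
        for solute, K in self.inhibition_terms:
            r = r * inhibition(S[solute], K)
        return r


@dataclass
class ReactionNetwork:
    solutes: tuple
    processes: list

    def __post_init__(self) -> None:
        known = set(GROUP_CODES) | set(self.solutes)
        for p in self.processes:
            if p.group not in GROUP_CODES:
                raise ValueError(f"process {p.name!r}: unknown acting group {p.group!r}")
            for solute, _ in list(p.monod_terms) + list(p.inhibition_terms):
                if solute not in self.solutes:
                    raise ValueError(f"process {p.name!r}: undeclared solute {solute!r}")
            for comp in p.stoich:
                if comp not in known:
                    raise ValueError(f"process {p.name!r}: unknown component {comp!r}")

    def for_group(self, code: int) -> list:
        name = GROUP_NAMES[code]
        return [p for p in self.processes if p.group == name]


# ---------------------------------------------------------------------------
# presets

def single_species_network(p, b_eps: float = 0.0, b_inert: float = 0.0) -> ReactionNetwork:
    """Generic single-heterotroph preset for the morphology studies.

    Growth is Monod-limited by the carbonaceous substrate only; EPS shell
    is produced at Y_EPS/Y per unit new biomass; decay of EPS and inert
    agents defaults to zero (negligible against growth) but feeds back to
    substrate when enabled.  ``p`` is the internal parameter namespace.
    """
    procs = [
        Process("het_growth", "HET", p.mu_m, monod_terms=[("S_S", p.K_S)],
                stoich={"HET": 1.0, "EPS": p.Y_EPS / p.Y,
                        "S_S": -(1.0 / p.Y)}),
        Process("het_decay", "HET", p.b, stoich={"HET": -1.0}),
        Process("eps_decay", "EPS", b_eps, stoich={"EPS": -1.0, "S_S": 1.0}),
        Process("inert_decay", "INERT", b_inert, stoich={"INERT": -1.0, "S_S": 1.0}),
    ]
    return ReactionNetwork(solutes=("S_S",), processes=procs)


def three_species_network(p) -> ReactionNetwork:
    """Representative HET/AOB/NOB nitrification network (ASM-style forms).

    Rate constants and affinities are typical activated-sludge literature
    values, NOT a canonical reproduction of any particular table: the
    schema is the contract, the numbers are drop-in replaceable.
    Yields in gCOD/gCOD (N species in gN, O2 as negative COD).
    """
    h = 1.0 / 3600.0
    Y_H, Y_A, Y_N = p.Y, 0.15, 0.04
    procs = [
        Process("het_growth", "HET", p.mu_m,
                monod_terms=[("S_S", p.K_S), ("S_O2", 2.0e-4)],
                stoich={"HET": 1.0, "EPS": p.Y_EPS / p.Y, "S_S": -1.0 / Y_H,
                        "S_O2": -(1.0 - Y_H) / Y_H}),
        Process("aob_growth", "AOB", 0.76 * h,
                monod_terms=[("S_NH4", 1.0e-3), ("S_O2", 5.0e-4)],
                stoich={"AOB": 1.0, "S_NH4": -1.0 / Y_A, "S_NO2": 1.0 / Y_A,
                        "S_O2": -(3.42 - Y_A) / Y_A}),
        Process("nob_growth", "NOB", 0.81 * h,
                monod_terms=[("S_NO2", 1.3e-3), ("S_O2", 6.8e-4)],
                stoich={"NOB": 1.0, "S_NO2": -1.0 / Y_N, "S_NO3": 1.0 / Y_N,
                        "S_O2": -(1.15 - Y_N) / Y_N}),
        Process("het_decay", "HET", p.b, stoich={"HET": -1.0}),
        Process("aob_decay", "AOB", 0.11 * h, stoich={"AOB": -1.0}),
        Process("nob_decay", "NOB", 0.11 * h, stoich={"NOB": -1.0}),
        Process("eps_decay", "EPS", 0.0, stoich={"EPS": -1.0, "S_S": 1.0}),
        Process("inert_decay", "INERT", 0.0, stoich={"INERT": -1.0, "S_S": 1.0}),
    ]
    return ReactionNetwork(solutes=SOLUTES, processes=procs)


# ---------------------------------------------------------------------------
# agent-level rates

def specific_rate(group_code: int, local_S: dict, net: ReactionNetwork) -> float:
    """Net specific growth/decay rate (1/s) of one agent of the given group
    at the solute concentrations of its voxel.  Negative means shrinkage."""
    procs = net.for_group(group_code)
    if not procs and GROUP_NAMES[group_code] not in {q.group for q in net.processes}:
        raise KeyError(f"group {GROUP_NAMES[group_code]} absent from network")
    gname = GROUP_NAMES[group_code]
    return float(sum(p.stoich.get(gname, 0.0) * p.rate(local_S) for p in procs))


def agent_rates(agents: AgentState, S_at_agents: dict,
                net: ReactionNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-agent (net core rate, EPS-shell production rate), 1/s.

    ``S_at_agents`` maps solute name -> per-agent local concentration.
    Shell production applies only to bacterial groups (EPS column of a
    process acting on a bacterium).
    """
    r_net = np.zeros(agents.n)
    r_shell = np.zeros(agents.n)
    for p in net.processes:
        code = GROUP_CODES[p.group]
        mask = agents.group == code
        if not mask.any():
            continue
        local = {s: arr[mask] for s, arr in S_at_agents.items()}
        rate = p.rate(local)
        r_net[mask] += p.stoich.get(p.group, 0.0) * rate
        if code != EPS:
            r_shell[mask] += p.stoich.get("EPS", 0.0) * rate
    return r_net, r_shell


def step_biomass(agents: AgentState, r_net: np.ndarray, r_shell: np.ndarray,
                 dt_bio: float) -> np.ndarray:
    """Explicit Euler biomass update: m <- m (1 + r dt).

    Shell mass accrues at r_shell * m_core; when the net core rate is
    negative the shell shrinks by the same relative factor (core and shell
    decay proportionally).  Returns a mask of agents whose mass would have
    become non-positive (flagged for the death/removal pathway; their mass
    is clamped just above zero rather than erroring).
    """
    if dt_bio <= 0:
        raise ValueError("dt_bio must be positive")
    factor = 1.0 + r_net * dt_bio
    flagged = factor <= 0.0
    m_old = agents.mass.copy()
    agents.mass = np.where(flagged, m_old * 1e-6, m_old * factor)
    agents.eps_shell = agents.eps_shell + np.maximum(r_shell, 0.0) * m_old * dt_bio
    shrink = (r_net < 0) & ~flagged
    agents.eps_shell[shrink] *= factor[shrink]
    agents.eps_shell[flagged] *= 1e-6
    return flagged


# ---------------------------------------------------------------------------
# voxel fields

def biomass_concentrations(agents: AgentState, domain: Domain) -> dict:
    """Per-group biomass concentration fields (fg um^-3 == kg m^-3).

    Core mass is binned to the voxel containing the agent centre; HET shell
    mass counts towards the EPS phase.
    """
    fields = {name: np.zeros(domain.shape) for name in GROUP_NAMES.values()}
    if agents.n == 0:
        return fields
    ix, iy, iz = domain.voxel_of(agents.position)
    vv = domain.voxel_volume
    for code, name in GROUP_NAMES.items():
        mask = agents.group == code
        if mask.any():
            np.add.at(fields[name], (ix[mask], iy[mask], iz[mask]),
                      agents.mass[mask] / vv)
    shelled = agents.eps_shell > 0
    if shelled.any():
        np.add.at(fields["EPS"], (ix[shelled], iy[shelled], iz[shelled]),
                  agents.eps_shell[shelled] / vv)
    return fields


def uptake_field(agents: AgentState, domain: Domain, net: ReactionNetwork,
                 S_fields: dict) -> dict:
    """Per-solute volumetric reaction rates R (kg m^-3 s^-1) on the grid.

    R(voxel, solute) = sum over processes of stoichiometry x specific rate
    at the voxel's concentrations x local concentration of the acting
    group.  Consumption is negative; empty voxels give zero.
    """
    X = biomass_concentrations(agents, domain)
    R = {s: np.zeros(domain.shape) for s in net.solutes}
    for p in net.processes:
        Xg = X[p.group]
        if p.rate_max == 0.0 or not np.any(Xg):
            continue
        rate = p.rate(S_fields) * Xg
        for solute in net.solutes:
            c = p.stoich.get(solute, 0.0)
            if c:
                R[solute] += c * rate
    return R


# ---------------------------------------------------------------------------
# serialisation (round-trippable through the YAML config)

def network_to_dict(net: ReactionNetwork) -> dict:
    return {
        "solutes": list(net.solutes),
        "processes": [
            {"name": p.name, "group": p.group, "rate_max": p.rate_max,
             "monod": [[s, K] for s, K in p.monod_terms],
             "inhibition": [[s, K] for s, K in p.inhibition_terms],
             "stoich": dict(p.stoich)}
            for p in net.processes
        ],
    }


def network_from_dict(d: dict) -> ReactionNetwork:
    procs = [
        Process(q["name"], q["group"], float(q["rate_max"]),
                monod_terms=[(s, float(K)) for s, K in q.get("monod", [])],
                inhibition_terms=[(s, float(K)) for s, K in q.get("inhibition", [])],
                stoich={k: float(v) for k, v in q.get("stoich", {}).items()})
        for q in d["processes"]
    ]
    return ReactionNetwork(solutes=tuple(d["solutes"]), processes=procs)
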