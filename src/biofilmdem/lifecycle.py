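"""Discrete stochastic agent events: division, EPS excretion, death and
removal.

Division: when a bacterium's core diameter reaches the threshold
(default 1.25 um) it splits into two daughters.  Daughter 1 keeps the
mother's position and draws a mass fraction uniformly from
[0.5 - band, 0.5 + band] (band 10%); daughter 2 takes the exact remainder
and is displaced along a uniformly random 3D direction.  The EPS shell
splits in proportion to the daughter masses.  Total mass is conserved
exactly.

EPS excretion: the shell grows with the cell; once the composite
(core + shell) diameter reaches ``eps_excrete_ratio`` times the core
diameter, the whole shell becomes a free EPS particle placed adjacent in
a random direction, and the shell resets to zero.

Death and removal: active agents whose core diameter shrinks to the death
threshold (0.8 um) become inert; any residual shell is released as a
co-located free EPS particle (inert agents carry no shell).  Agents of any
group at or below the removal diameter (0.1 um) are deleted and their mass
is added to the removed-mass ledger.

Event order within a biological step is division, then EPS excretion, then
death/removal, with agents visited in index order under a single RNG
stream — runs are bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np

from .agents import ACTIVE_GROUPS, EPS, INERT, AgentState

__all__ = ["divide", "secrete_eps", "death_and_removal", "random_directions"]


def random_directions(rng: np.random.Generator, k: int) -> np.ndarray:
    """k unit vectors uniform on the sphere (Gaussian normalisation)."""
    v = rng.normal(size=(k, 3))
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    # a zero draw has probability 0; guard anyway
    bad = norm[:, 0] < 1e-12
    if bad.any():
        v[bad] = np.array([0.0, 0.0, 1.0])
        norm[bad] = 1.0
    return v / norm


def divide(agents: AgentState, p, rng: np.random.Generator) -> list[dict]:
    """Divide every bacterium at or above the division diameter (in place).

    Returns event records (time left to the caller to stamp).  Daughter 1
    replaces the mother in place; daughter 2 is appended with a fresh id.
    """
    diam = 2.0 * agents.radius(p)
    eligible = np.isin(agents.group, ACTIVE_GROUPS) & (diam >= p.d_div)
    idx = np.flatnonzero(eligible)
    events: list[dict] = []
    if idx.size == 0:
        return events
    band = p.daughter_fraction_band
    frac = rng.uniform(0.5 - band, 0.5 + band, size=idx.size)
    dirs = random_directions(rng, idx.size)
    m = agents.mass[idx]
    shell = agents.eps_shell[idx]
    m1 = frac * m
    m2 = m - m1                    # exact remainder: total conserved
    s1 = frac * shell
    s2 = shell - s1
    rho = agents.density(p)[idx]
    r1 = np.cbrt(3.0 * m1 / (4.0 * np.pi * rho))
    r2 = np.cbrt(3.0 * m2 / (4.0 * np.pi * rho))
    sep = (r1 + r2) if p.division_separation == "radii" else 2.0 * (r1 + r2)
    mother_pos = agents.position[idx].copy()
    mother_ids = agents.id[idx].copy()
    # daughter 1 in place
    agents.mass[idx] = m1
    agents.eps_shell[idx] = s1
    # daughter 2 appended (periodic wrap deferred to the mechanics stage)
    new_ids = agents.append(
        agents.group[idx], mother_pos + dirs * sep[:, None], m2, s2,
        velocity=agents.velocity[idx])
    for q in range(idx.size):
        events.append({
            "event": "division", "parent": int(mother_ids[q]),
            "daughter": int(new_ids[q]), "mass": float(m[q]),
            "fraction": float(frac[q]),
        })
    return events


def secrete_eps(agents: AgentState, p, rng: np.random.Generator) -> list[dict]:
    """Excrete over-threshold EPS shells as free EPS particles (in place)."""
    has_shell = agents.eps_shell > 0.0
    if not has_shell.any():
        return []
    r_core = agents.radius(p)
    r_comp = agents.contact_radius(p)
    ready = has_shell & (r_comp >= p.eps_excrete_ratio * r_core)
    idx = np.flatnonzero(ready)
    events: list[dict] = []
    if idx.size == 0:
        return events
    shell = agents.eps_shell[idx].copy()
    r_eps = np.cbrt(3.0 * shell / (4.0 * np.pi * p.rho_EPS))
    dirs = random_directions(rng, idx.size)
    sep = r_core[idx] + r_eps
    pos = agents.position[idx] + dirs * sep[:, None]
    host_ids = agents.id[idx].copy()
    agents.eps_shell[idx] = 0.0
    new_ids = agents.append(np.full(idx.size, EPS, np.int8), pos, shell,
                            velocity=agents.velocity[idx])
    for q in range(idx.size):
        events.append({"event": "eps_excretion", "parent": int(host_ids[q]),
                       "daughter": int(new_ids[q]), "mass": float(shell[q])})
    return events


def death_and_removal(agents: AgentState, p) -> tuple[list[dict], float]:
    """Apply the death and removal diameter thresholds (in place).

    Returns (events, removed_mass): active agents at or below the death
    diameter become INERT (their shell is released as a co-located EPS
    particle); agents at or below the removal diameter are deleted with
    their total mass returned in the ledger.
    """
    events: list[dict] = []
    removed_mass = 0.0
    if agents.n == 0:
        return events, removed_mass
    diam = 2.0 * agents.radius(p)
    dying = np.isin(agents.group, ACTIVE_GROUPS) & (diam <= p.d_dead)
    idx = np.flatnonzero(dying)
    if idx.size:
        shells = agents.eps_shell[idx].copy()
        pos = agents.position[idx].copy()
        vel = agents.velocity[idx].copy()
        for q, a in enumerate(idx):
            events.append({"event": "death", "parent": int(agents.id[a]),
                           "mass": float(agents.mass[a])})
        agents.group[idx] = INERT
        agents.eps_shell[idx] = 0.0
        release = shells > 0.0
        if release.any():
            agents.append(np.full(int(release.sum()), EPS, np.int8),
                          pos[release], shells[release], velocity=vel[release])
    diam = 2.0 * agents.radius(p)
    gone = diam <= p.d_remove
    if gone.any():
        removed_mass = float(agents.mass[gone].sum() + agents.eps_shell[gone].sum())
        for a in np.flatnonzero(gone):
            events.append({"event": "removal", "parent": int(agents.id[a]),
                           "mass": float(agents.mass[a] + agents.eps_shell[a])})
        agents.remove(gone)
    return events, removed_mass
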