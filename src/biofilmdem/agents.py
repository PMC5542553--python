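"""Structure-of-arrays container for the agent population.

Each agent is a rigid sphere with a functional-group label, a core biomass
(femtograms of COD), and — for heterotrophs — an attached EPS shell mass.
The *core radius* follows from core mass and the group's density; the
*contact radius* additionally includes the shell volume (shell material at
EPS density) and is what the mechanics sees.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["AgentState", "HET", "AOB", "NOB", "EPS", "INERT", "GROUP_NAMES", "GROUP_CODES"]

HET, AOB, NOB, EPS, INERT = 0, 1, 2, 3, 4
GROUP_NAMES = {HET: "HET", AOB: "AOB", NOB: "NOB", EPS: "EPS", INERT: "INERT"}
GROUP_CODES = {v: k for k, v in GROUP_NAMES.items()}
ACTIVE_GROUPS = (HET, AOB, NOB)

_FOUR_THIRDS_PI = 4.0 / 3.0 * math.pi


class AgentState:
    """Arrays: id (int64), group (int8), position (n,3), velocity (n,3),
    mass (core, fg), eps_shell (fg).  EPS and INERT agents carry no shell."""

    __slots__ = ("id", "group", "position", "velocity", "mass", "eps_shell", "_next_id")

    def __init__(self, id, group, position, mass, eps_shell=None, velocity=None,
                 next_id=None):
        self.id = np.asarray(id, dtype=np.int64)
        self.group = np.asarray(group, dtype=np.int8)
        self.position = np.asarray(position, dtype=np.float64).reshape(-1, 3)
        self.mass = np.asarray(mass, dtype=np.float64)
        n = self.id.size
        self.eps_shell = (np.zeros(n) if eps_shell is None
                          else np.asarray(eps_shell, dtype=np.float64))
        self.velocity = (np.zeros((n, 3)) if velocity is None
                         else np.asarray(velocity, dtype=np.float64).reshape(-1, 3))
        self._next_id = int(next_id) if next_id is not None else (
            int(self.id.max()) + 1 if n else 0)
        self.check()

    # -- construction -------------------------------------------------------
    @classmethod
    def empty(cls) -> "AgentState":
        return cls(np.empty(0, np.int64), np.empty(0, np.int8),
                   np.empty((0, 3)), np.empty(0))

    def copy(self) -> "AgentState":
        return AgentState(self.id.copy(), self.group.copy(), self.position.copy(),
                          self.mass.copy(), self.eps_shell.copy(),
                          self.velocity.copy(), next_id=self._next_id)

    def append(self, group, position, mass, eps_shell=0.0, velocity=None) -> np.ndarray:
        """Append agents, assigning fresh ids; returns the new ids."""
        group = np.atleast_1d(np.asarray(group, dtype=np.int8))
        k = group.size
        new_ids = np.arange(self._next_id, self._next_id + k, dtype=np.int64)
        self._next_id += k
        self.id = np.concatenate([self.id, new_ids])
        self.group = np.concatenate([self.group, group])
        self.position = np.vstack([self.position, np.asarray(position, float).reshape(k, 3)])
        self.mass = np.concatenate([self.mass, np.broadcast_to(np.asarray(mass, float), (k,))])
        self.eps_shell = np.concatenate(
            [self.eps_shell, np.broadcast_to(np.asarray(eps_shell, float), (k,))])
        vel = np.zeros((k, 3)) if velocity is None else np.asarray(velocity, float).reshape(k, 3)
        self.velocity = np.vstack([self.velocity, vel])
        return new_ids

    def remove(self, mask: np.ndarray) -> None:
        keep = ~np.asarray(mask, bool)
        self.id = self.id[keep]
        self.group = self.group[keep]
        self.position = self.position[keep]
        self.mass = self.mass[keep]
        self.eps_shell = self.eps_shell[keep]
        self.velocity = self.velocity[keep]

    # -- derived geometry ----------------------------------------------------
    @property
    def n(self) -> int:
        return self.id.size

    def density(self, p) -> np.ndarray:
        """Per-agent core density (fg um^-3) from the group label."""
        rho = np.full(self.n, p.rho_X)
        rho[self.group == EPS] = p.rho_EPS
        return rho

    def radius(self, p) -> np.ndarray:
        """Core radius (um): from core mass and the group density."""
        return np.cbrt(self.mass / (_FOUR_THIRDS_PI * self.density(p)))

    def contact_radius(self, p) -> np.ndarray:
        """Radius of the composite sphere core + EPS shell (shell at rho_EPS)."""
        vol = self.mass / self.density(p) + self.eps_shell / p.rho_EPS
        return np.cbrt(vol / _FOUR_THIRDS_PI)

    def volume(self, p) -> np.ndarray:
        """Composite agent volume (um^3), shell included."""
        return self.mass / self.density(p) + self.eps_shell / p.rho_EPS

    def total_mass(self) -> float:
        """Total COD (fg), core plus shells."""
        return float(self.mass.sum() + self.eps_shell.sum())

    # -- invariants ----------------------------------------------------------
    def check(self) -> None:
        n = self.n
        if not (self.group.size == n and self.mass.size == n
                and self.eps_shell.size == n and self.position.shape == (n, 3)
                and self.velocity.shape == (n, 3)):
            raise ValueError("inconsistent agent array lengths")
        if n and np.unique(self.id).size != n:
            raise ValueError("duplicate agent ids")
        if np.any(self.mass <= 0):
            raise ValueError("agent core mass must be strictly positive")
        if np.any(self.eps_shell < 0):
            raise ValueError("EPS shell mass must be non-negative")
        shelled = (self.group == EPS) | (self.group == INERT)
        if np.any(self.eps_shell[shelled] != 0.0):
            raise ValueError("EPS and INERT agents must carry no EPS shell")

    def __repr__(self) -> str:
        counts = {GROUP_NAMES[g]: int((self.group == g).sum())
                  for g in np.unique(self.group)}
        return f"AgentState(n={self.n}, {counts})"
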