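"""Biofilm morphometrics, composition and detachment statistics.

Morphology: on the analysis grid, the height field h(x, y) is the top of
the highest sphere in each column; mean height, RMS surface roughness and
overall porosity are

    h_bar     = mean(h)
    roughness = sqrt(mean((h - h_bar)^2))
    porosity  = 1 - sum F(i,j,k) / (N_x N_y h_max)

with F the voxel biomass-occupancy indicator and h_max the height-field
maximum in voxel units.  A voxel counts as filled if any agent sphere
intersects it (a centre-only rule is available).

Clusters: connected components of the contact-or-adhesion graph; a
component is *attached* if any member touches the substratum, otherwise
it is a (potentially detaching) free cluster.

Detachment statistics: event counts per time window, lognormal ML fit of
cluster volumes, and the detachment rate = total detached volume / time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .agents import EPS, INERT, AgentState
from .config import Domain
from .mechanics import AdhesiveLinks, build_pairs, min_image

__all__ = [
    "height_field", "occupancy", "morphology", "Morphology",
    "volume_fractions", "active_layer_thickness",
    "clusters", "ClusterSet", "detachment_statistics",
]


def height_field(agents: AgentState, domain: Domain, p,
                 grid: tuple[int, int] | None = None) -> np.ndarray:
    """Per-column biofilm height max(z + r); zero where the column is empty.

    ``grid`` overrides the (N_x, N_y) column counts — finer columns than
    the solute voxels resolve finger-scale roughness better.
    """
    nx, ny = grid if grid is not None else (domain.N_x, domain.N_y)
    h = np.zeros((nx, ny))
    if agents.n == 0:
        return h
    ix = np.clip((agents.position[:, 0] / domain.L_x * nx).astype(int), 0, nx - 1)
    iy = np.clip((agents.position[:, 1] / domain.L_y * ny).astype(int), 0, ny - 1)
    tops = agents.position[:, 2] + agents.contact_radius(p)
    np.maximum.at(h, (ix, iy), tops)
    return h


def occupancy(agents: AgentState, domain: Domain, p,
              rule: str = "sphere") -> np.ndarray:
    """Voxel biomass indicator F(i,j,k).

    rule="sphere": filled iff any agent sphere intersects the voxel
    (exact sphere/box test); rule="centre": filled iff it contains a centre.
    """
    F = np.zeros(domain.shape, dtype=bool)
    if agents.n == 0:
        return F
    if rule == "centre":
        ix, iy, iz = domain.voxel_of(agents.position)
        F[ix, iy, iz] = True
        return F
    if rule != "sphere":
        raise ValueError(f"unknown occupancy rule {rule!r}")
    h = domain.voxel
    rc = agents.contact_radius(p)
    lo = np.floor((agents.position - rc[:, None]) / h).astype(int)
    hi = np.floor((agents.position + rc[:, None]) / h).astype(int)
    lo = np.clip(lo, 0, np.array(domain.shape) - 1)
    hi = np.clip(hi, 0, np.array(domain.shape) - 1)
    for a in range(agents.n):
        c = agents.position[a]
        r2 = rc[a] ** 2
        for i in range(lo[a, 0], hi[a, 0] + 1):
            for j in range(lo[a, 1], hi[a, 1] + 1):
                for k in range(lo[a, 2], hi[a, 2] + 1):
                    if F[i, j, k]:
                        continue
                    # distance from centre to nearest point of the voxel box
                    box_lo = np.array([i, j, k]) * h
                    box_hi = box_lo + h
                    nearest = np.minimum(np.maximum(c, box_lo), box_hi)
                    if np.sum((c - nearest) ** 2) <= r2:
                        F[i, j, k] = True
    return F


@dataclass(frozen=True)
class Morphology:
    mean_height: float
    roughness: float
    porosity: float
    max_height: float
    degenerate: bool = False   # zero-height biofilm: porosity undefined -> 0


def morphology(h: np.ndarray, F: np.ndarray, domain: Domain) -> Morphology:
    """Mean height, RMS roughness and porosity from the height field and
    the occupancy indicator."""
    h_bar = float(h.mean())
    rough = float(np.sqrt(np.mean((h - h_bar) ** 2)))
    h_max = float(h.max())
    hz = domain.voxel[2]
    h_max_vox = h_max / hz
    if h_max_vox <= 0.0:
        return Morphology(h_bar, rough, 0.0, h_max, degenerate=True)
    filled = float(F.sum())
    porosity = 1.0 - filled / (F.shape[0] * F.shape[1] * h_max_vox)
    return Morphology(h_bar, rough, float(np.clip(porosity, 0.0, 1.0)), h_max)


def volume_fractions(agents: AgentState, p) -> dict:
    """Fractions of total agent volume: bacteria / EPS (free + shells) /
    inert.  All zero for an empty population."""
    out = {"bacteria": 0.0, "EPS": 0.0, "inert": 0.0}
    if agents.n == 0:
        return out
    core = agents.mass / agents.density(p)
    shell = agents.eps_shell / p.rho_EPS
    bac = ~np.isin(agents.group, (EPS, INERT))
    v_bac = float(core[bac].sum())
    v_eps = float(core[agents.group == EPS].sum() + shell.sum())
    v_in = float(core[agents.group == INERT].sum())
    total = v_bac + v_eps + v_in
    return {"bacteria": v_bac / total, "EPS": v_eps / total, "inert": v_in / total}


def active_layer_thickness(agents: AgentState, rates: np.ndarray,
                           domain: Domain, p,
                           frac_threshold: float = 0.5) -> float:
    """Mean thickness of the actively growing surface layer (um).

    A cell is active if its growth rate is at least ``frac_threshold``
    times the population maximum; per column the layer spans from the
    local height down to the lowest active cell.  Columns without agents
    are skipped; 0 if no cell is active.
    """
    if agents.n == 0:
        return 0.0
    rates = np.asarray(rates, dtype=float)
    r_max = rates.max()
    if r_max <= 0.0:
        return 0.0
    active = rates >= frac_threshold * r_max
    if not active.any():
        return 0.0
    h = height_field(agents, domain, p)
    ix, iy, _ = domain.voxel_of(agents.position)
    zmin = np.full((domain.N_x, domain.N_y), np.inf)
    np.minimum.at(zmin, (ix[active], iy[active]), agents.position[active, 2])
    has = np.isfinite(zmin)
    if not has.any():
        return 0.0
    return float(np.mean(np.maximum(h[has] - zmin[has], 0.0)))


@dataclass
class ClusterSet:
    labels: np.ndarray        # component label per agent
    attached: np.ndarray      # per component: touches the substratum?
    volumes: np.ndarray       # per component: total agent volume (um^3)
    members: list             # per component: agent index arrays

    @property
    def n(self) -> int:
        return self.attached.size

    def detached_components(self) -> np.ndarray:
        return np.flatnonzero(~self.attached)


def clusters(agents: AgentState, links: AdhesiveLinks | None, domain: Domain,
             p, contact_tol: float = 1e-6, wall_tol: float = 0.05) -> ClusterSet:
    """Connected components under contact-overlap OR active-adhesive-link
    adjacency; components touching the substratum are flagged attached.

    ``contact_tol`` is the relative slack on r_i + r_j for "touching";
    ``wall_tol`` the relative slack on z <= r for substratum contact.
    """
    n = agents.n
    if n == 0:
        return ClusterSet(np.empty(0, int), np.empty(0, bool), np.empty(0), [])
    rc = agents.contact_radius(p)
    perx = domain.bc_x == "periodic"
    pery = domain.bc_y == "periodic"
    cutoff = 2.0 * float(rc.max()) * (1.0 + contact_tol)
    pi, pj = build_pairs(agents.position, cutoff, domain.L_x, domain.L_y, perx, pery)
    if pi.size:
        dx = min_image(agents.position[pi] - agents.position[pj],
                       (domain.L_x, domain.L_y), (perx, pery))
        d = np.linalg.norm(dx, axis=1)
        touch = d <= (rc[pi] + rc[pj]) * (1.0 + contact_tol)
        pi, pj = pi[touch], pj[touch]
    if links is not None and links.i.size:
        act = links.active.astype(bool)
        pi = np.concatenate([pi, links.i[act]])
        pj = np.concatenate([pj, links.j[act]])
    adj = coo_matrix((np.ones(pi.size), (pi, pj)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    touches_wall = agents.position[:, 2] <= rc * (1.0 + wall_tol)
    attached = np.zeros(n_comp, dtype=bool)
    np.logical_or.at(attached, labels, touches_wall)
    vol = agents.volume(p)
    volumes = np.zeros(n_comp)
    np.add.at(volumes, labels, vol)
    members = [np.flatnonzero(labels == c) for c in range(n_comp)]
    return ClusterSet(labels, attached, volumes, members)


def detachment_statistics(events: pd.DataFrame, initial_volume: float,
                          duration: float, n_bins: int = 20) -> dict:
    """Summarise a detachment-event log.

    ``events`` needs columns ``time`` (s) and ``volume`` (um^3); a
    ``norm_volume`` column (volume / remaining biofilm volume) is used when
    present.  Returns binned event counts, the lognormal ML fit of cluster
    volumes (mu, sigma of log volume), the detachment rate
    total volume / duration, and summary fractions.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if events is None or len(events) == 0:
        return {"n_events": 0, "rate": 0.0, "counts": np.zeros(n_bins, int),
                "bin_edges": np.linspace(0.0, duration, n_bins + 1),
                "lognormal_mu": np.nan, "lognormal_sigma": np.nan,
                "max_norm_volume": 0.0, "mean_norm_volume": 0.0,
                "total_detached_fraction": 0.0}
    t = np.asarray(events["time"], dtype=float)
    v = np.asarray(events["volume"], dtype=float)
    norm = (np.asarray(events["norm_volume"], dtype=float)
            if "norm_volume" in events else v / max(initial_volume, 1e-300))
    edges = np.linspace(0.0, duration, n_bins + 1)
    counts, _ = np.histogram(t, bins=edges)
    if v.size >= 2 and np.all(v > 0):
        sigma, _, scale = stats.lognorm.fit(v, floc=0)
        mu = float(np.log(scale))
    else:
        mu, sigma = (float(np.log(v[0])) if v.size and v[0] > 0 else np.nan), np.nan
    return {
        "n_events": int(v.size),
        "rate": float(v.sum() / duration),
        "counts": counts,
        "bin_edges": edges,
        "lognormal_mu": mu,
        "lognormal_sigma": float(sigma) if sigma is not None else np.nan,
        "max_norm_volume": float(np.nanmax(norm)),
        "mean_norm_volume": float(np.nanmean(norm)),
        "total_detached_fraction": float(v.sum() / max(initial_volume, 1e-300)),
    }
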