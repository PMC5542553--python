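"""DEM mechanics: spring–dashpot contact, EPS-spring adhesion, Stokes drag,
and relaxation to mechanical equilibrium.

Forces
------
Contact (normal + tangential spring–dashpot, Hookean by default):

    F_n = f(delta) (k_n delta n - gamma_n m_eff v_n)
    F_t = f(delta) (-k_t delta_t - gamma_t m_eff v_t)

with f = 1 (Hookean) or f = sqrt(delta * d), d = r_i r_j / (r_i + r_j)
(Hertzian).  Walls are treated as particles of infinite radius
(m_eff = m_i).  EPS adhesion is a central spring of stiffness
k_eps * m_ij_eps anchored at rest length d0 = r_i + r_j; the link breaks
permanently (within a relaxation phase) at separation 2 d0.  Drag is
Stokes flow past a sphere, F = 6 pi mu r (U - v), with the imposed shear
U_x = gamma_dot * z.

Integration
-----------
Motion is integrated in the overdamped limit of the equation of motion:
each step sets v_i = U(z_i) + (F_contact + F_adhesion)_i / zeta_i with
zeta_i = 6 pi mu r_i, then advances positions explicitly.  Stability
requires dt below the spring relaxation time zeta/k; the step is chosen
automatically as a fraction of that bound.  Relaxation runs until the
internal virial pressure

    P = (1 / 3V) sum_pairs F_ij . d_ij

falls below tolerance (growth-induced pressure release) or a pseudo-time
budget is exhausted.  Tangential spring history accumulates while a
contact persists and resets on contact loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .agents import EPS, AgentState
from .config import Domain

__all__ = [
    "MechanicsError", "AdhesiveLinks", "build_links", "build_pairs",
    "contact_force", "wall_contact", "adhesive_force", "drag_force",
    "relax", "RelaxResult", "min_image",
]


class MechanicsError(RuntimeError):
    pass


def min_image(dx: np.ndarray, box, periodic=(True, True)) -> np.ndarray:
    """Minimum-image displacement for x/y-periodic boxes (z never wraps)."""
    dx = np.array(dx, dtype=float)
    for ax in (0, 1):
        if periodic[ax] and box is not None:
            L = box[ax]
            dx[..., ax] -= L * np.round(dx[..., ax] / L)
    return dx


# ---------------------------------------------------------------------------
# single-pair force laws (reference implementations; the relaxation loop
# uses the compiled kernel below)

def _f_factor(delta: float, r_i: float, r_j: float, hertzian: bool) -> float:
    if not hertzian:
        return 1.0
    d_eff = r_i * r_j / (r_i + r_j)   # 0.5 d_i d_j / (d_i + d_j)
    return np.sqrt(delta * d_eff)


def contact_force(pos_i, pos_j, vel_i, vel_j, r_i, r_j, m_i, m_j, p,
                  model: str | None = None, box=None, periodic=(True, True),
                  delta_t=None):
    """Spring–dashpot contact force pair (F_i, F_j); zero unless overlapping.

    ``delta_t`` is the accumulated tangential spring displacement (3-vector);
    omit for an instantaneous (no tangential-spring) evaluation.
    """
    hertzian = (model or p.contact_model) == "hertzian"
    dx = min_image(np.asarray(pos_i, float) - np.asarray(pos_j, float), box, periodic)
    d = float(np.linalg.norm(dx))
    delta = r_i + r_j - d
    if delta <= 0.0:
        return np.zeros(3), np.zeros(3)
    if d < 1e-12:
        warnings.warn("coincident agent centres; using +z fallback normal")
        n = np.array([0.0, 0.0, 1.0])
    else:
        n = dx / d
    m_eff = m_i * m_j / (m_i + m_j)
    f = _f_factor(delta, r_i, r_j, hertzian)
    v_rel = np.asarray(vel_i, float) - np.asarray(vel_j, float)
    v_n = np.dot(v_rel, n) * n
    v_t = v_rel - v_n
    F = f * (p.k_n * delta * n - p.gamma_n * m_eff * v_n)
    dt_vec = np.zeros(3) if delta_t is None else np.asarray(delta_t, float)
    F = F + f * (-p.k_t * dt_vec - p.gamma_t * m_eff * v_t)
    return F, -F


def wall_contact(pos, vel, r, m, p, L_z=None, model: str | None = None):
    """Contact force from the substratum (z=0) and, if L_z given, top wall."""
    hertzian = (model or p.contact_model) == "hertzian"
    pos = np.asarray(pos, float)
    vel = np.asarray(vel, float)
    F = np.zeros(3)
    delta = r - pos[2]
    if delta > 0.0:   # substratum; wall as infinite-radius particle, m_eff = m
        f = np.sqrt(delta * r) if hertzian else 1.0
        F[2] += f * (p.k_n * delta - p.gamma_n * m * vel[2])
    if L_z is not None:
        delta = r - (L_z - pos[2])
        if delta > 0.0:
            f = np.sqrt(delta * r) if hertzian else 1.0
            F[2] -= f * (p.k_n * delta + p.gamma_n * m * vel[2])
    return F


def adhesive_force(d0, m_eps, pos_i, pos_j, k_eps, box=None, periodic=(True, True)):
    """EPS spring force pair and surviving-link flag.

    F on i = k_eps m_eps (d - d0) towards j (attractive when stretched);
    at d >= 2 d0 the link breaks: (0, 0, False).
    """
    dx = min_image(np.asarray(pos_i, float) - np.asarray(pos_j, float), box, periodic)
    d = float(np.linalg.norm(dx))
    if d >= 2.0 * d0 or m_eps <= 0.0 or d < 1e-12:
        return np.zeros(3), np.zeros(3), False
    n = dx / d
    F = -k_eps * m_eps * (d - d0) * n
    return F, -F, True


def drag_force(r, vel, U_local, mu):
    """Stokes drag 6 pi mu r (U - v) on a sphere (internal units)."""
    return 6.0 * np.pi * mu * r * (np.asarray(U_local, float) - np.asarray(vel, float))


# ---------------------------------------------------------------------------
# adhesive links

@dataclass
class AdhesiveLinks:
    """Index pairs with rest length d0 = r_i + r_j and combined EPS mass."""

    i: np.ndarray
    j: np.ndarray
    d0: np.ndarray
    m_eps: np.ndarray
    active: np.ndarray

    @classmethod
    def none(cls) -> "AdhesiveLinks":
        z = np.empty(0)
        return cls(np.empty(0, np.int64), np.empty(0, np.int64), z, z,
                   np.empty(0, np.uint8))

    @property
    def n_active(self) -> int:
        return int(self.active.sum())


def _pair_eps_mass(agents: AgentState) -> np.ndarray:
    """EPS material each agent contributes to a link: shell mass, plus own
    mass for free EPS particles."""
    m = agents.eps_shell.copy()
    m[agents.group == EPS] += agents.mass[agents.group == EPS]
    return m


def build_links(agents: AgentState, p, domain: Domain,
                factor: float | None = None) -> AdhesiveLinks:
    """Form links between pairs within factor*(r_i+r_j) that share EPS mass."""
    if agents.n < 2:
        return AdhesiveLinks.none()
    factor = p.link_formation_factor if factor is None else factor
    rc = agents.contact_radius(p)
    cutoff = factor * 2.0 * float(rc.max())
    pi, pj = build_pairs(agents.position, cutoff, domain.L_x, domain.L_y,
                         domain.bc_x == "periodic", domain.bc_y == "periodic")
    if pi.size == 0:
        return AdhesiveLinks.none()
    contrib = _pair_eps_mass(agents)
    m_eps = contrib[pi] + contrib[pj]
    dx = min_image(agents.position[pi] - agents.position[pj],
                   (domain.L_x, domain.L_y),
                   (domain.bc_x == "periodic", domain.bc_y == "periodic"))
    d = np.linalg.norm(dx, axis=1)
    d0 = rc[pi] + rc[pj]
    keep = (m_eps > 0.0) & (d <= factor * d0)
    return AdhesiveLinks(pi[keep], pj[keep], d0[keep], m_eps[keep],
                         np.ones(int(keep.sum()), np.uint8))


@njit(cache=False)
def _build_pairs_nb(pos, cutoff, Lx, Ly, perx, pery):  # pragma: no cover
    """Cell-list pair search; each pair within cutoff reported exactly once.

    Periodic dimensions collapse to a single cell when fewer than four
    cells fit (avoids double-visiting wrapped neighbours).
    """
    n = pos.shape[0]
    cut2 = cutoff * cutoff
    ncx = int(Lx / cutoff)
    if ncx < 4:
        ncx = 1
    ncy = int(Ly / cutoff)
    if ncy < 4:
        ncy = 1
    zmin = pos[0, 2]
    zmax = pos[0, 2]
    for i in range(1, n):
        if pos[i, 2] < zmin:
            zmin = pos[i, 2]
        if pos[i, 2] > zmax:
            zmax = pos[i, 2]
    ncz = int((zmax - zmin) / cutoff) + 1
    if ncz < 1:
        ncz = 1
    ncells = ncx * ncy * ncz
    cell_of = np.empty(n, np.int64)
    count = np.zeros(ncells + 1, np.int64)
    for i in range(n):
        x = pos[i, 0]
        if perx:
            x -= Lx * np.floor(x / Lx)
        cx = int(x / Lx * ncx)
        if cx < 0:
            cx = 0
        elif cx >= ncx:
            cx = ncx - 1
        y = pos[i, 1]
        if pery:
            y -= Ly * np.floor(y / Ly)
        cy = int(y / Ly * ncy)
        if cy < 0:
            cy = 0
        elif cy >= ncy:
            cy = ncy - 1
        cz = int((pos[i, 2] - zmin) / cutoff)
        if cz >= ncz:
            cz = ncz - 1
        c = (cx * ncy + cy) * ncz + cz
        cell_of[i] = c
        count[c + 1] += 1
    for c in range(ncells):
        count[c + 1] += count[c]
    order = np.empty(n, np.int64)
    fill = count.copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1
    cap = max(16, n * 24)
    out_i = np.empty(cap, np.int64)
    out_j = np.empty(cap, np.int64)
    m = 0
    # half stencil: self cell (i<j) plus 13 forward neighbours
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                for off in range(14):
                    # explicit half-stencil: self + 13 forward neighbours
                    if off == 0:
                        ox, oy, oz = 0, 0, 0
                    elif off == 1:
                        ox, oy, oz = 0, 0, 1
                    elif off == 2:
                        ox, oy, oz = 0, 1, -1
                    elif off == 3:
                        ox, oy, oz = 0, 1, 0
                    elif off == 4:
                        ox, oy, oz = 0, 1, 1
                    elif off == 5:
                        ox, oy, oz = 1, -1, -1
                    elif off == 6:
                        ox, oy, oz = 1, -1, 0
                    elif off == 7:
                        ox, oy, oz = 1, -1, 1
                    elif off == 8:
                        ox, oy, oz = 1, 0, -1
                    elif off == 9:
                        ox, oy, oz = 1, 0, 0
                    elif off == 10:
                        ox, oy, oz = 1, 0, 1
                    elif off == 11:
                        ox, oy, oz = 1, 1, -1
                    elif off == 12:
                        ox, oy, oz = 1, 1, 0
                    else:
                        ox, oy, oz = 1, 1, 1
                    nx = cx + ox
                    if ncx == 1:
                        if ox != 0:
                            continue
                        nx = 0
                    elif perx:
                        nx = nx % ncx
                    elif nx < 0 or nx >= ncx:
                        continue
                    ny = cy + oy
                    if ncy == 1:
                        if oy != 0:
                            continue
                        ny = 0
                    elif pery:
                        ny = ny % ncy
                    elif ny < 0 or ny >= ncy:
                        continue
                    nz = cz + oz
                    if nz < 0 or nz >= ncz:
                        continue
                    c2 = (nx * ncy + ny) * ncz + nz
                    same = c2 == c
                    for a in range(count[c], count[c + 1]):
                        i = order[a]
                        b0 = a + 1 if same else count[c2]
                        for b in range(b0, count[c2 + 1]):
                            j = order[b]
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            if perx:
                                dx -= Lx * np.floor(dx / Lx + 0.5)
                            if pery:
                                dy -= Ly * np.floor(dy / Ly + 0.5)
                            if dx * dx + dy * dy + dz * dz <= cut2:
                                if m >= cap:
                                    cap *= 2
                                    gi = np.empty(cap, np.int64)
                                    gj = np.empty(cap, np.int64)
                                    gi[:m] = out_i[:m]
                                    gj[:m] = out_j[:m]
                                    out_i, out_j = gi, gj
                                if i < j:
                                    out_i[m] = i
                                    out_j[m] = j
                                else:
                                    out_i[m] = j
                                    out_j[m] = i
                                m += 1
    return out_i[:m], out_j[:m]


def build_pairs(pos: np.ndarray, cutoff: float, Lx: float, Ly: float,
                perx: bool = True, pery: bool = True):
    """All unique pairs within ``cutoff`` (minimum-image in periodic x/y)."""
    pos = np.ascontiguousarray(pos, dtype=np.float64)
    if pos.shape[0] < 2:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    return _build_pairs_nb(pos, float(cutoff), float(Lx), float(Ly),
                           bool(perx), bool(pery))


# ---------------------------------------------------------------------------
# relaxation kernel

@njit(cache=False)
def _relax_kernel(pos, vel, rc, mass, zeta, pi, pj, tang, wall_t,
                  li, lj, ld0, lmeps, lactive,
                  k_n, k_t, g_n, g_t, hertzian, k_eps,
                  Lx, Ly, Lz, perx, pery, wrapx, wrapy, top_wall,
                  wall_no_slip, gamma_dot, dt, nsteps, p_tol, Vdom,
                  skin_half, trace, cumdisp):  # pragma: no cover
    """Integrate up to nsteps; returns (steps_done, pressure, code).

    code: 0 converged (pressure < p_tol), 1 budget exhausted,
          2 pair list stale (displacement exceeded half-skin),
          3 instability (velocity blow-up).
    """
    n = pos.shape[0]
    npair = pi.shape[0]
    nlink = li.shape[0]
    F = np.zeros((n, 3))
    vmax_allow = 0.5 * rc.min() if n else 1.0
    pressure = 0.0
    for step in range(nsteps):
        for a in range(n):
            F[a, 0] = 0.0
            F[a, 1] = 0.0
            F[a, 2] = 0.0
        virial = 0.0
        # contacts
        for q in range(npair):
            i = pi[q]
            j = pj[q]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if perx:
                dx -= Lx * np.floor(dx / Lx + 0.5)
            if pery:
                dy -= Ly * np.floor(dy / Ly + 0.5)
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            delta = rc[i] + rc[j] - d
            if delta <= 0.0:
                tang[q, 0] = 0.0
                tang[q, 1] = 0.0
                tang[q, 2] = 0.0
                continue
            if d < 1e-12:
                nx, ny, nz = 0.0, 0.0, 1.0
                d = 1e-12
            else:
                nx, ny, nz = dx / d, dy / d, dz / d
            m_eff = mass[i] * mass[j] / (mass[i] + mass[j])
            f = 1.0
            if hertzian:
                f = np.sqrt(delta * rc[i] * rc[j] / (rc[i] + rc[j]))
            vrx = vel[i, 0] - vel[j, 0]
            vry = vel[i, 1] - vel[j, 1]
            vrz = vel[i, 2] - vel[j, 2]
            vn = vrx * nx + vry * ny + vrz * nz
            fnx = f * (k_n * delta * nx - g_n * m_eff * vn * nx)
            fny = f * (k_n * delta * ny - g_n * m_eff * vn * ny)
            fnz = f * (k_n * delta * nz - g_n * m_eff * vn * nz)
            # tangential spring + dashpot
            vtx = vrx - vn * nx
            vty = vry - vn * ny
            vtz = vrz - vn * nz
            tx = tang[q, 0] + vtx * dt
            ty = tang[q, 1] + vty * dt
            tz = tang[q, 2] + vtz * dt
            tn = tx * nx + ty * ny + tz * nz
            tx -= tn * nx
            ty -= tn * ny
            tz -= tn * nz
            tang[q, 0] = tx
            tang[q, 1] = ty
            tang[q, 2] = tz
            ftx = f * (-k_t * tx - g_t * m_eff * vtx)
            fty = f * (-k_t * ty - g_t * m_eff * vty)
            ftz = f * (-k_t * tz - g_t * m_eff * vtz)
            fx = fnx + ftx
            fy = fny + fty
            fz = fnz + ftz
            F[i, 0] += fx
            F[i, 1] += fy
            F[i, 2] += fz
            F[j, 0] -= fx
            F[j, 1] -= fy
            F[j, 2] -= fz
            virial += fx * dx + fy * dy + fz * dz
        # adhesive links
        for q in range(nlink):
            if lactive[q] == 0:
                continue
            i = li[q]
            j = lj[q]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if perx:
                dx -= Lx * np.floor(dx / Lx + 0.5)
            if pery:
                dy -= Ly * np.floor(dy / Ly + 0.5)
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d >= 2.0 * ld0[q]:
                lactive[q] = 0   # permanent within this phase
                continue
            if d < 1e-12:
                continue
            coeff = -k_eps * lmeps[q] * (d - ld0[q]) / d
            fx = coeff * dx
            fy = coeff * dy
            fz = coeff * dz
            F[i, 0] += fx
            F[i, 1] += fy
            F[i, 2] += fz
            F[j, 0] -= fx
            F[j, 1] -= fy
            F[j, 2] -= fz
            virial += fx * dx + fy * dy + fz * dz
        # walls (excluded from the internal virial)
        for a in range(n):
            delta = rc[a] - pos[a, 2]
            if delta > 0.0:
                f = np.sqrt(delta * rc[a]) if hertzian else 1.0
                F[a, 2] += f * (k_n * delta - g_n * mass[a] * vel[a, 2])
                wtx = wall_t[a, 0] + vel[a, 0] * dt
                wty = wall_t[a, 1] + vel[a, 1] * dt
                wall_t[a, 0] = wtx
                wall_t[a, 1] = wty
                F[a, 0] += f * (-k_t * wtx - g_t * mass[a] * vel[a, 0])
                F[a, 1] += f * (-k_t * wty - g_t * mass[a] * vel[a, 1])
            else:
                wall_t[a, 0] = 0.0
                wall_t[a, 1] = 0.0
            if top_wall:
                delta = rc[a] - (Lz - pos[a, 2])
                if delta > 0.0:
                    f = np.sqrt(delta * rc[a]) if hertzian else 1.0
                    F[a, 2] -= f * (k_n * delta + g_n * mass[a] * vel[a, 2])
        pressure = virial / (3.0 * Vdom)
        trace[step] = pressure
        if abs(pressure) < p_tol:
            return step, pressure, 0
        # overdamped update with imposed shear flow
        vmax = 0.0
        maxcum = 0.0
        for a in range(n):
            ux = gamma_dot * pos[a, 2]
            vx = ux + F[a, 0] / zeta[a]
            vy = F[a, 1] / zeta[a]
            vz = F[a, 2] / zeta[a]
            if wall_no_slip and pos[a, 2] < rc[a]:
                # substratum adhesion in the stiff tangential limit
                vx = 0.0
                vy = 0.0
            vel[a, 0] = vx
            vel[a, 1] = vy
            vel[a, 2] = vz
            sp = np.sqrt(vx * vx + vy * vy + vz * vz)
            if sp > vmax:
                vmax = sp
            pos[a, 0] += vx * dt
            pos[a, 1] += vy * dt
            pos[a, 2] += vz * dt
            cumdisp[a] += sp * dt
            if cumdisp[a] > maxcum:
                maxcum = cumdisp[a]
            if wrapx:
                pos[a, 0] -= Lx * np.floor(pos[a, 0] / Lx)
            if wrapy:
                pos[a, 1] -= Ly * np.floor(pos[a, 1] / Ly)
        if vmax * dt > vmax_allow:
            return step + 1, pressure, 3
        if maxcum > skin_half:
            return step + 1, pressure, 2
    return nsteps, pressure, 1


@dataclass
class RelaxResult:
    times: np.ndarray       # pseudo-time at each recorded step (s)
    pressures: np.ndarray   # internal virial pressure trace
    steps: int
    dt: float
    converged: bool


def relax(agents: AgentState, links: AdhesiveLinks, domain: Domain, p,
          gamma_dot: float = 0.0, pressure_tol: float | None = 1e-5,
          max_time: float = 2.0, dt: float | None = None,
          top_wall: bool = True, chunk: int = 1000) -> RelaxResult:
    """Relax the population to mechanical equilibrium (in place).

    ``pressure_tol`` is relative to the initial virial pressure magnitude;
    pass ``None`` to integrate the full ``max_time`` (flow advection).
    Raises :class:`MechanicsError` on kinetic blow-up.
    """
    n = agents.n
    if n == 0:
        return RelaxResult(np.empty(0), np.empty(0), 0, 0.0, True)
    rc = agents.contact_radius(p)
    zeta = 6.0 * np.pi * p.mu_fluid * rc
    k_max = max(p.k_n, p.k_t)
    if links.n_active:
        k_max = max(k_max, p.k_eps * float(links.m_eps.max()))
    tau = float(zeta.min()) / k_max
    if dt is None:
        dt = 0.1 * tau
        if p.dt_mech is not None:
            dt = min(dt, p.dt_mech)
    elif dt > 0.5 * tau:
        raise MechanicsError(
            f"dt_mech={dt:g} exceeds the overdamped stability bound {0.5 * tau:g}")
    dt_floor = dt * 2.0 ** -8
    perx = domain.bc_x == "periodic"
    pery = domain.bc_y == "periodic"
    skin = 1.0 * float(rc.max())
    cutoff = 2.0 * float(rc.max()) + skin
    pos = agents.position
    vel = agents.velocity
    mass = agents.mass + agents.eps_shell   # inertia irrelevant; dashpot scale
    traces, times = [], []
    t = 0.0
    steps_total = 0
    p_thresh = -1.0   # set after first chunk from initial pressure
    converged = pressure_tol is None
    finished = False
    wall_t = np.zeros((n, 2))
    while not finished and t < max_time - 1e-12:
        pi, pj = build_pairs(pos, cutoff, domain.L_x, domain.L_y, perx, pery)
        tang = np.zeros((pi.size, 3))
        cumdisp = np.zeros(n)
        stale = False
        while not stale and t < max_time - 1e-12:
            nsteps = min(chunk, max(1, int(np.ceil((max_time - t) / dt))))
            trace = np.empty(nsteps)
            done, pressure, code = _relax_kernel(
                pos, vel, rc, mass, zeta, pi, pj, tang, wall_t,
                links.i, links.j, links.d0, links.m_eps, links.active,
                p.k_n, p.k_t, p.gamma_n, p.gamma_t, p.hertzian, p.k_eps,
                domain.L_x, domain.L_y, domain.L_z, perx, pery, perx, pery,
                top_wall, getattr(p, "wall_no_slip", False),
                gamma_dot, dt, nsteps,
                max(p_thresh, 0.0) if pressure_tol is not None else -1.0,
                domain.volume, 0.5 * skin, trace, cumdisp)
            if done:
                traces.append(trace[:done].copy())
                times.append(t + dt * np.arange(1, done + 1))
                t += dt * done
                steps_total += done
            if p_thresh < 0.0 and pressure_tol is not None and traces:
                p_thresh = pressure_tol * max(abs(traces[0][0]), 1e-300)
                if abs(traces[0][0]) == 0.0:
                    code = 0   # nothing to relax
            if code == 0:
                converged = True
                finished = True
                stale = True
            elif code == 2:
                stale = True              # rebuild pair list
            elif code == 3:
                # crowded contacts stiffen the effective spring; retry with
                # a finer step rather than giving up immediately
                dt *= 0.5
                stale = True
                if dt < dt_floor:
                    raise MechanicsError(
                        f"mechanical relaxation unstable at t={t:.4g}s "
                        f"(virial pressure {pressure:.3g}) despite dt "
                        f"refinement to {dt:.3g}s")
    return RelaxResult(
        np.concatenate(times) if times else np.empty(0),
        np.concatenate(traces) if traces else np.empty(0),
        steps_total, dt, converged)
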