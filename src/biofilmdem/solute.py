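"""Quasi-steady advection–diffusion–reaction solver on the voxel grid.

The mass balance dS/dt + U.grad(S) = div(D_e grad S) + R is discretised
with forward Euler in pseudo-time, central differences for diffusion
(conservative flux form, face diffusivities by arithmetic averaging) and
first-order upwinding for advection.  Because nutrient transport is fast
against growth, each biological step solves the field to steady state:
pseudo-time is iterated until the per-step change drops below tolerance.

Boundary conditions: periodic in x and y; in z one wall is a Dirichlet
feed at the bulk concentration (imposed on the wall *face* through a ghost
value, second order) and the other is zero-flux.  ``feed="top"`` is the
standard biofilm setting (substratum at z=0 impermeable), ``feed="bottom"``
models growth on a nutrient-supplying substratum, ``feed="none"`` closes
the box (used for conservation checks).

Reaction rates are refreshed from the current concentrations every
``picard_block`` pseudo-steps (chunked Picard iteration); the converged
fixed point does not depend on the block size.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .config import Domain

__all__ = [
    "shear_flow", "velocity_at", "effective_diffusivity", "stable_dt",
    "step_solute", "solve_quasi_steady", "SoluteError", "ConvergenceError",
]

_FEED_CODE = {"none": 0, "top": 1, "bottom": 2}


class SoluteError(RuntimeError):
    pass


class ConvergenceError(SoluteError):
    def __init__(self, msg, residual=None, iterations=None):
        super().__init__(msg)
        self.residual = residual
        self.iterations = iterations


# ---------------------------------------------------------------------------
# imposed flow

def shear_flow(domain: Domain, gamma_dot: float) -> np.ndarray:
    """Voxel-centre velocities (um/s) of a simple shear U_x = gamma_dot * z."""
    U = np.zeros(domain.shape + (3,))
    U[..., 0] = gamma_dot * domain.centres(2)[None, None, :]
    return U


def velocity_at(positions: np.ndarray, gamma_dot: float) -> np.ndarray:
    """Exact shear-flow velocity at arbitrary points."""
    pos = np.atleast_2d(positions)
    U = np.zeros_like(pos)
    U[:, 0] = gamma_dot * pos[:, 2]
    return U


def effective_diffusivity(X_total: np.ndarray, p, closure=None) -> np.ndarray:
    """Per-voxel effective diffusivity D_e = D_S * f(X) (um^2/s).

    ``closure`` maps local biomass concentration (kg m^-3) to a relative
    diffusivity in (0, 1]; the default is no hindrance (f = 1).
    """
    X = np.asarray(X_total, dtype=float)
    if closure is None:
        return np.full(X.shape, p.D_S)
    f = np.asarray(closure(X), dtype=float)
    if np.any(f <= 0) or np.any(f > 1.0 + 1e-12):
        raise SoluteError("relative diffusivity closure must map into (0, 1]")
    return p.D_S * f


def stable_dt(D_e, U, domain: Domain, safety: float = 0.4) -> float:
    """Forward-Euler stability bound for diffusion + upwind advection.

    The Dirichlet ghost doubles the boundary-cell z coefficient, hence the
    2/hz^2 term.
    """
    hx, hy, hz = domain.voxel
    Dmax = float(np.max(D_e))
    diff = 2.0 * Dmax * (1.0 / hx**2 + 1.0 / hy**2 + 2.0 / hz**2)
    umax = float(np.max(np.abs(U))) if U is not None else 0.0
    adv = umax * (1.0 / hx + 1.0 / hy + 1.0 / hz)
    denom = diff + adv
    if denom == 0:
        return np.inf
    return safety / denom


@njit(cache=False)
def _fe_steps(S, De, R, C, U, dt, hx, hy, hz, nsteps, feed, S_b):  # pragma: no cover
    """nsteps forward-Euler updates in place; returns max |dS| of last step.

    ``R`` holds explicit (non-negative) sources, ``C`` linearised sink
    coefficients (1/s): the update is semi-implicit in the sink,
    S <- (S + dt*(flux + R)) / (1 + dt*C), which is positivity-preserving
    for stiff Monod-type consumption and shares the explicit fixed point.
    """
    nx, ny, nz = S.shape
    Snew = np.empty_like(S)
    maxd = 0.0
    for _ in range(nsteps):
        maxd = 0.0
        for i in range(nx):
            im = i - 1 if i > 0 else nx - 1
            ip = i + 1 if i < nx - 1 else 0
            for j in range(ny):
                jm = j - 1 if j > 0 else ny - 1
                jp = j + 1 if j < ny - 1 else 0
                for k in range(nz):
                    s = S[i, j, k]
                    d = De[i, j, k]
                    # diffusive fluxes, arithmetic face diffusivity
                    fx = (0.5 * (d + De[ip, j, k]) * (S[ip, j, k] - s)
                          - 0.5 * (d + De[im, j, k]) * (s - S[im, j, k])) / hx**2
                    fy = (0.5 * (d + De[i, jp, k]) * (S[i, jp, k] - s)
                          - 0.5 * (d + De[i, jm, k]) * (s - S[i, jm, k])) / hy**2
                    # z: walls
                    if k < nz - 1:
                        up = 0.5 * (d + De[i, j, k + 1]) * (S[i, j, k + 1] - s)
                    else:
                        up = 2.0 * d * (S_b - s) if feed == 1 else 0.0
                    if k > 0:
                        dn = 0.5 * (d + De[i, j, k - 1]) * (s - S[i, j, k - 1])
                    else:
                        dn = -2.0 * d * (S_b - s) if feed == 2 else 0.0
                    fz = (up - dn) / hz**2
                    # first-order upwind advection (periodic x/y, no z flow
                    # through walls beyond what U supplies)
                    adv = 0.0
                    ux = U[i, j, k, 0]
                    if ux > 0.0:
                        adv += ux * (s - S[im, j, k]) / hx
                    elif ux < 0.0:
                        adv += ux * (S[ip, j, k] - s) / hx
                    uy = U[i, j, k, 1]
                    if uy > 0.0:
                        adv += uy * (s - S[i, jm, k]) / hy
                    elif uy < 0.0:
                        adv += uy * (S[i, jp, k] - s) / hy
                    uz = U[i, j, k, 2]
                    if uz > 0.0 and k > 0:
                        adv += uz * (s - S[i, j, k - 1]) / hz
                    elif uz < 0.0 and k < nz - 1:
                        adv += uz * (S[i, j, k + 1] - s) / hz
                    snew = (s + dt * (fx + fy + fz - adv + R[i, j, k])) \
                        / (1.0 + dt * C[i, j, k])
                    Snew[i, j, k] = snew
                    if abs(snew - s) > maxd:
                        maxd = abs(snew - s)
        S[:, :, :] = Snew
    return maxd


def _as_field_dict(S):
    if isinstance(S, dict):
        return S, False
    return {"S_S": S}, True


def step_solute(S, U, D_e, R, dt, domain: Domain, feed: str = "top",
                S_b: float = 0.0, check_stability: bool = True):
    """One forward-Euler update of a single solute field (returns a new array).

    Raises :class:`SoluteError` on stability violation or NaN.
    """
    S = np.array(S, dtype=float)
    D_e = np.broadcast_to(np.asarray(D_e, float), S.shape).copy()
    R = np.broadcast_to(np.asarray(R, float), S.shape).copy()
    U = np.zeros(S.shape + (3,)) if U is None else np.asarray(U, float)
    if check_stability and dt > stable_dt(D_e, U, domain, safety=1.0):
        raise SoluteError(
            f"dt={dt:g} violates the explicit stability bound "
            f"{stable_dt(D_e, U, domain, safety=1.0):g}")
    _fe_steps(S, D_e, R, np.zeros_like(S), U, dt, *domain.voxel, 1,
              _FEED_CODE[feed], S_b)
    if not np.all(np.isfinite(S)):
        raise SoluteError("NaN/Inf in solute field after update")
    return S


def solve_quasi_steady(S, U, D_e, R_closure, domain: Domain, feed: str = "top",
                       S_b: float = 0.0, tol: float = 1e-6,
                       max_iters: int = 400_000, dt: float | None = None,
                       picard_block: int = 50):
    """Iterate pseudo-time until the per-step relative change < tol.

    Parameters
    ----------
    S : array or dict of arrays (solute name -> field); updated copies are
        returned together with the iteration count.
    R_closure : callable(fields dict) -> dict of volumetric rates, or None.
        Re-evaluated every ``picard_block`` steps (Picard iteration for
        Monod-type sinks).
    tol : relative tolerance on max |dS| per pseudo-step, scaled by the
        larger of S_b and the field maximum.

    Concentrations are clipped at zero between blocks.  Raises
    :class:`ConvergenceError` at max_iters, reporting the residual.
    """
    fields, single = _as_field_dict(S)
    fields = {k: np.array(v, dtype=float) for k, v in fields.items()}
    shape = next(iter(fields.values())).shape
    U = np.zeros(shape + (3,)) if U is None else np.ascontiguousarray(U, dtype=float)
    if not isinstance(D_e, dict):
        D_e = {k: D_e for k in fields}
    D_e = {k: np.ascontiguousarray(np.broadcast_to(np.asarray(v, float), shape))
           for k, v in D_e.items()}
    if dt is None:
        dt = min(stable_dt(D_e[k], U, domain) for k in fields)
    hx, hy, hz = domain.voxel
    feed_c = _FEED_CODE[feed]
    iters = 0
    scale = {k: max(S_b, float(np.max(np.abs(v))), 1e-300) for k, v in fields.items()}
    worst = np.inf
    while iters < max_iters:
        if R_closure is not None:
            R = R_closure(fields)
        else:
            R = {k: np.zeros(shape) for k in fields}
        block = min(picard_block, max_iters - iters)
        worst = 0.0
        for name, arr in fields.items():
            # split signed R into explicit sources and a linearised sink
            # coefficient (semi-implicit, positivity-preserving)
            Rn = np.asarray(R[name], dtype=float)
            Rp = np.where(Rn > 0.0, Rn, 0.0)
            floor = 1e-12 * scale[name]
            C = np.where(Rn < 0.0, -Rn / np.maximum(arr, floor), 0.0)
            md = _fe_steps(arr, D_e[name], np.ascontiguousarray(Rp),
                           np.ascontiguousarray(C), U, dt, hx, hy, hz,
                           block, feed_c, S_b)
            np.clip(arr, 0.0, None, out=arr)
            worst = max(worst, md / scale[name])
        iters += block
        if not all(np.all(np.isfinite(a)) for a in fields.values()):
            raise SoluteError(f"NaN in solute field at iteration {iters}")
        if worst < tol:
            break
    else:
        raise ConvergenceError(
            f"quasi-steady solve did not converge in {max_iters} steps "
            f"(residual {worst:.3e})", residual=worst, iterations=iters)
    out = fields["S_S"] if single else fields
    return out, iters
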