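"""Run configuration: kinetic, stoichiometric and mechanical parameters,
the computational domain, and the dimensionless groups that organise the
morphology experiments.

Parameters are stored in the units they are conventionally reported in
(rates in h^-1, concentrations in kg m^-3, spring constants in N m^-1, ...)
and converted once, via :meth:`Parameters.internal`, to the internal
micrometre / femtogram / second system used by the simulation engine.
Conveniently, 1 kg m^-3 == 1 fg um^-3, so densities and concentrations
carry over unchanged.

The three dimensionless groups controlling nutrient-limited morphology are

    delta = S_b * D_S / (Y * mu_m * rho_X * L_z^2)   (transport/consumption)
    kappa = K_S / S_b                                (Monod saturation)
    beta  = b / mu_m                                 (relative decay)

The biomass density ``rho_X`` is, by default, derived by inverting the
expression for delta so that the baseline parameter set realises
``delta_target`` (default 1.52e-2) in the run's own domain.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from types import SimpleNamespace
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "Parameters",
    "Domain",
    "DimensionlessGroups",
    "ConfigError",
    "load_config",
    "save_config",
    "dimensionless_groups",
    "params_for_groups",
    "radius_from_mass",
    "mass_from_radius",
    "HOUR",
]

HOUR = 3600.0  # seconds

# unit conversion factors into the internal um / fg / s system
_N_PER_M_TO_INTERNAL = 1e18      # N m^-1  -> fg s^-2
_PA_S_TO_INTERNAL = 1e12         # Pa s    -> fg um^-1 s^-1
_M2_S_TO_INTERNAL = 1e12         # m^2 s^-1 -> um^2 s^-1
# kg m^-3 -> fg um^-3 is exactly 1.0


class ConfigError(ValueError):
    """Raised for missing mandatory fields or violated invariants."""


@dataclass
class Parameters:
    """Kinetic, stoichiometric, mass-transfer and mechanical constants.

    Defaults are the baseline single-species parameter set. ``rho_X`` and
    ``rho_EPS`` default to ``None`` meaning *derive at load time*: rho_X
    from the delta_target inversion, rho_EPS as rho_X / 2.
    """

    # kinetics and stoichiometry
    mu_m: float = 1.0            # maximum specific growth rate, 1/h
    b: float = 1.33e-2           # first-order decay coefficient, 1/h
    K_S: float = 3.50e-5         # substrate affinity, kg m^-3
    Y: float = 0.61              # growth yield, gCOD/gCOD
    Y_EPS: float = 0.18          # EPS formation coefficient, gCOD/gCOD
    # mass transfer
    D_S: float = 1.6e-9          # substrate diffusivity, m^2 s^-1
    S_b: float = 1.0e-4          # bulk substrate concentration, kg m^-3
    # mechanics
    k_n: float = 1.0e-4          # normal contact spring coefficient, N m^-1
    gamma_n: float = 1.0e-5      # normal contact damping coefficient, s^-1
    k_t: Optional[float] = None      # tangential spring; default 2/7 * k_n
    gamma_t: Optional[float] = None  # tangential damping; default gamma_n / 2
    k_eps: float = 5.0e9         # EPS stiffness per unit EPS mass, s^-2
    mu_fluid: float = 1.0e-3     # dynamic viscosity, Pa s
    contact_model: str = "hookean"   # "hookean" | "hertzian"
    link_formation_factor: float = 1.1  # links form within this * (r_i + r_j)
    wall_friction: str = "spring"    # "spring" | "no_slip" (stiff-k_t limit)
    # densities (COD-equivalent); None -> derived
    rho_X: Optional[float] = None    # biomass density, kg m^-3
    rho_EPS: Optional[float] = None  # EPS density, kg m^-3
    delta_target: float = 1.52e-2    # delta realised by the derived rho_X
    # lifecycle thresholds (diameters, um)
    d_div: float = 1.25
    d_dead: float = 0.8
    d_remove: float = 0.1
    eps_excrete_ratio: float = 1.25   # shell/core diameter ratio at excretion
    daughter_fraction_band: float = 0.10   # daughter-1 in [0.5-band, 0.5+band]*m
    division_separation: str = "radii"     # "radii" | "diameters"
    # time stepping (s); None -> chosen automatically from stability bounds
    dt_bio: float = 1000.0
    dt_mech: Optional[float] = None
    dt_diff: Optional[float] = None
    # imposed flow
    gamma_dot: float = 0.0       # shear rate, 1/s

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        positive = [
            "mu_m", "K_S", "Y", "Y_EPS", "D_S", "S_b", "k_n", "k_eps",
            "mu_fluid", "d_div", "d_dead", "d_remove", "dt_bio",
        ]
        for name in positive:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ConfigError(f"parameter {name!r} must be strictly positive, got {v!r}")
        for name in ("b", "gamma_n", "gamma_dot"):
            if getattr(self, name) < 0:
                raise ConfigError(f"parameter {name!r} must be non-negative")
        if not (self.d_remove < self.d_dead < self.d_div):
            raise ConfigError(
                "diameter thresholds must satisfy d_remove < d_dead < d_div, got "
                f"{self.d_remove} / {self.d_dead} / {self.d_div}"
            )
        if not self.eps_excrete_ratio > 1.0:
            raise ConfigError("eps_excrete_ratio must exceed 1")
        if self.contact_model not in ("hookean", "hertzian"):
            raise ConfigError(f"unknown contact model {self.contact_model!r}")
        if self.division_separation not in ("radii", "diameters"):
            raise ConfigError(f"unknown division_separation {self.division_separation!r}")
        if self.wall_friction not in ("spring", "no_slip"):
            raise ConfigError(f"unknown wall_friction {self.wall_friction!r}")
        if not 0.0 < self.daughter_fraction_band < 0.5:
            raise ConfigError("daughter_fraction_band must lie in (0, 0.5)")
        for small, big in (("dt_diff", "dt_mech"), ("dt_mech", "dt_bio")):
            a, c = getattr(self, small), getattr(self, big)
            if a is not None and c is not None and a > c:
                raise ConfigError(f"time steps must satisfy {small} <= {big}")
        if self.rho_X is not None and self.rho_X <= 0:
            raise ConfigError("rho_X must be strictly positive")
        if self.rho_EPS is not None and self.rho_EPS <= 0:
            raise ConfigError("rho_EPS must be strictly positive")

    # -- derived fields -----------------------------------------------------
    def resolved(self, domain: "Domain") -> "Parameters":
        """Return a copy with rho_X / rho_EPS / tangential constants filled in.

        rho_X is obtained by inverting the delta expression at the domain's
        L_z so that the configured (S_b, D_S, Y, mu_m) realise delta_target.
        """
        p = dataclasses.replace(self)
        if p.rho_X is None:
            L_z_m = domain.L_z * 1e-6
            mu_m_s = p.mu_m / HOUR
            p.rho_X = p.S_b * p.D_S / (p.Y * mu_m_s * p.delta_target * L_z_m**2)
        if p.rho_EPS is None:
            p.rho_EPS = p.rho_X / 2.0
        if p.k_t is None:
            p.k_t = 2.0 / 7.0 * p.k_n
        if p.gamma_t is None:
            p.gamma_t = p.gamma_n / 2.0
        return p

    def internal(self) -> SimpleNamespace:
        """Convert to the internal um / fg / s unit system.

        Requires densities and tangential constants to be resolved first
        (see :meth:`resolved`).
        """
        if self.rho_X is None or self.rho_EPS is None:
            raise ConfigError("densities unresolved; call Parameters.resolved(domain) first")
        k_t = self.k_t if self.k_t is not None else 2.0 / 7.0 * self.k_n
        gamma_t = self.gamma_t if self.gamma_t is not None else self.gamma_n / 2.0
        return SimpleNamespace(
            mu_m=self.mu_m / HOUR,
            b=self.b / HOUR,
            K_S=self.K_S,                 # fg um^-3 == kg m^-3
            Y=self.Y,
            Y_EPS=self.Y_EPS,
            D_S=self.D_S * _M2_S_TO_INTERNAL,
            S_b=self.S_b,
            k_n=self.k_n * _N_PER_M_TO_INTERNAL,
            k_t=k_t * _N_PER_M_TO_INTERNAL,
            gamma_n=self.gamma_n,
            gamma_t=gamma_t,
            k_eps=self.k_eps,             # s^-2, mass in fg
            mu_fluid=self.mu_fluid * _PA_S_TO_INTERNAL,
            contact_model=self.contact_model,
            hertzian=self.contact_model == "hertzian",
            wall_no_slip=self.wall_friction == "no_slip",
            link_formation_factor=self.link_formation_factor,
            rho_X=self.rho_X,
            rho_EPS=self.rho_EPS,
            d_div=self.d_div,
            d_dead=self.d_dead,
            d_remove=self.d_remove,
            eps_excrete_ratio=self.eps_excrete_ratio,
            daughter_fraction_band=self.daughter_fraction_band,
            division_separation=self.division_separation,
            dt_bio=self.dt_bio,
            dt_mech=self.dt_mech,
            dt_diff=self.dt_diff,
            gamma_dot=self.gamma_dot,
        )


@dataclass
class Domain:
    """Rectangular computational box [0,L_x]x[0,L_y]x[0,L_z] with a uniform
    voxel grid for the solute solver.  z = 0 is the substratum."""

    L_x: float = 100.0
    L_y: float = 40.0
    L_z: float = 100.0
    N_x: int = 30
    N_y: int = 12
    N_z: int = 30
    bc_x: str = "periodic"       # "periodic" | "outflow"
    bc_y: str = "periodic"
    nutrient_feed: str = "top"   # "top" | "bottom" | "none"

    def __post_init__(self) -> None:
        for name in ("L_x", "L_y", "L_z"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"domain length {name} must be positive")
        for name in ("N_x", "N_y", "N_z"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ConfigError(f"voxel count {name} must be a positive integer")
        for name in ("bc_x", "bc_y"):
            if getattr(self, name) not in ("periodic", "outflow"):
                raise ConfigError(f"{name} must be 'periodic' or 'outflow'")
        if self.nutrient_feed not in ("top", "bottom", "none"):
            raise ConfigError("nutrient_feed must be 'top', 'bottom' or 'none'")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.L_x, self.L_y, self.L_z])

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.N_x, self.N_y, self.N_z)

    @property
    def voxel(self) -> np.ndarray:
        """Voxel edge lengths (um)."""
        return np.array([self.L_x / self.N_x, self.L_y / self.N_y, self.L_z / self.N_z])

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel))

    @property
    def volume(self) -> float:
        return float(self.L_x * self.L_y * self.L_z)

    def voxel_of(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel indices containing each position (positions clipped to box)."""
        pos = np.atleast_2d(positions)
        h = self.voxel
        idx = []
        for ax, n in zip(range(3), self.shape):
            i = np.floor(pos[:, ax] / h[ax]).astype(np.int64)
            idx.append(np.clip(i, 0, n - 1))
        return idx[0], idx[1], idx[2]

    def centres(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along one axis."""
        n = self.shape[axis]
        h = self.voxel[axis]
        return (np.arange(n) + 0.5) * h


@dataclass(frozen=True)
class DimensionlessGroups:
    delta: float
    kappa: float
    beta: float


def dimensionless_groups(p: Parameters, d: Domain) -> DimensionlessGroups:
    """delta, kappa, beta from the parameter set and the domain height.

    Computed in SI; all inputs are converted internally (mu_m, b from h^-1).
    """
    if p.rho_X is None:
        p = p.resolved(d)
    mu_m_s = p.mu_m / HOUR
    b_s = p.b / HOUR
    L_z_m = d.L_z * 1e-6
    denom = p.Y * mu_m_s * p.rho_X * L_z_m**2
    if denom == 0 or p.S_b == 0 or mu_m_s == 0:
        raise ConfigError("zero denominator in dimensionless groups")
    return DimensionlessGroups(
        delta=p.S_b * p.D_S / denom,
        kappa=p.K_S / p.S_b,
        beta=b_s / mu_m_s,
    )


def params_for_groups(base: Parameters, domain: Domain,
                      delta: float, kappa: float) -> Parameters:
    """Parameter set realising given (delta, kappa) at fixed rho_X.

    Follows the morphology-experiment protocol: delta is varied through the
    bulk concentration S_b, kappa independently through K_S.
    """
    base = base.resolved(domain)
    g0 = dimensionless_groups(base, domain)
    S_b = base.S_b * (delta / g0.delta)
    return dataclasses.replace(base, S_b=S_b, K_S=kappa * S_b)


def radius_from_mass(mass: float | np.ndarray, density: float) -> float | np.ndarray:
    """Sphere radius (um) from mass (fg) and density (kg m^-3 == fg um^-3)."""
    m = np.asarray(mass, dtype=float)
    if np.any(m <= 0) or density <= 0:
        raise ValueError("mass and density must be strictly positive")
    r = np.cbrt(3.0 * m / (4.0 * math.pi * density))
    return float(r) if np.isscalar(mass) else r


def mass_from_radius(radius: float | np.ndarray, density: float) -> float | np.ndarray:
    """Sphere mass (fg) from radius (um) and density (kg m^-3)."""
    r = np.asarray(radius, dtype=float)
    if np.any(r <= 0) or density <= 0:
        raise ValueError("radius and density must be strictly positive")
    m = 4.0 / 3.0 * math.pi * density * r**3
    return float(m) if np.isscalar(radius) else m


# ---------------------------------------------------------------------------
# config file I/O (flat YAML keys mirroring the conventional symbols)

_PARAM_FIELDS = {f.name for f in dataclasses.fields(Parameters)}
_DOMAIN_FIELDS = {f.name for f in dataclasses.fields(Domain)}


def load_config(path) -> tuple[Parameters, Domain, dict]:
    """Load a YAML run configuration.

    Returns the validated ``(Parameters, Domain, scenario)`` triple;
    densities and tangential constants are resolved against the domain.
    Unknown top-level keys raise; scenario options live under ``scenario:``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    scenario = raw.pop("scenario", {}) or {}
    network = raw.pop("reaction_network", None)
    if network is not None:
        # parsed lazily by kinetics.network_from_dict; carried alongside
        # the scenario options
        scenario["reaction_network"] = network
    pkw, dkw = {}, {}
    for key, val in raw.items():
        if key in _PARAM_FIELDS:
            pkw[key] = val
        elif key in _DOMAIN_FIELDS:
            dkw[key] = val
        else:
            raise ConfigError(f"unknown configuration key {key!r}")
    try:
        domain = Domain(**dkw)
        params = Parameters(**pkw).resolved(domain)
    except TypeError as exc:   # wrong types for dataclass fields
        raise ConfigError(str(exc)) from exc
    return params, domain, scenario


def save_config(path, params: Parameters, domain: Domain,
                scenario: dict | None = None, network: dict | None = None) -> None:
    """Write a configuration that :func:`load_config` reads back losslessly.

    ``network`` is a reaction-network dictionary as produced by
    :func:`biofilmdem.kinetics.network_to_dict`.
    """
    out = {**dataclasses.asdict(params), **dataclasses.asdict(domain)}
    if scenario:
        out["scenario"] = scenario
    if network is not None:
        out["reaction_network"] = network
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=True)
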