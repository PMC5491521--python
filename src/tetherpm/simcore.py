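"""Brownian dynamics of a sphere bound to a planar surface by reversible tethers.

The model: a spherical particle (a non-motile coccal bacterium, or an abiotic
bead) carries ``n_tethers_total`` anchor points quasi-uniformly distributed over
its surface.  Each tether is a pull-only Hookean spring of rest length ``L0``
and stiffness ``k`` connecting its anchor to a fixed attachment point on the
substratum plane ``z = 0``.  The particle obeys overdamped Langevin dynamics:
Stokes drag, thermal white noise, and the elastic tether forces; gravity and
buoyancy are neglected.  A bound tether detaches once its elastic force exceeds
the tether adhesion force (a strict threshold), and an unbound tether whose
anchor tip comes within one rest length of the surface re-attaches at the
perpendicular projection of its tip.  Detachment with successive re-attachment
lets the particle creep laterally while remaining adherent — the mechanism this
package exists to study.

Coordinates: substratum at ``z = 0``, fluid at ``z > 0``; SI units internally.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from numba import njit
from numba.typed import List as NumbaList

from .errors import (
    ConfigurationError,
    ContractViolationError,
    DataError,
    InvalidArgumentError,
)

BOLTZMANN = 1.380649e-23  # J/K

#: Default tether adhesion force sweep (N).  Spans the weak-force regime where
#: tethers detach many times per second (large vibration amplitudes) through
#: the detachment transition up to forces that effectively pin the particle;
#: the sweep midpoint (3.8e-13 N = 0.38 pN) is the shipped default adhesion
#: force for dynamic-tether runs.
DEFAULT_FORCE_SWEEP = (1.0e-13, 2.0e-13, 3.8e-13, 8.0e-13, 2.0e-12)


# ---------------------------------------------------------------------------
# Configuration and state containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """All physical and numerical parameters of the tethered-particle model.

    Defaults describe a density-matched 1 µm sphere in a viscous near-surface
    medium at room temperature, bound by 12 of 256 tethers with the spring
    constant measured for adhering bacteria (1.2e-5 N/m).  ``fluid_viscosity``
    is an *effective* viscosity: it folds unresolved near-wall and
    tether-internal friction into a single Stokes drag coefficient, and its
    default is calibrated so the simulated tracks relax on the tenth-of-second
    timescales observed for adhering bacteria (see docs/methods.md).
    """

    particle_diameter: float = 1.0e-6  # m
    particle_mass: float | None = None  # kg; None = density-matched sphere
    temperature: float = 298.0  # K
    fluid_viscosity: float = 0.45  # Pa s (effective, near-surface)
    fluid_density: float = 1.0e3  # kg/m^3
    n_tethers_total: int = 256
    n_tethers_initial_bound: int = 12
    tether_rest_length: float = 150.0e-9  # m
    tether_spring_constant: float = 1.2e-5  # N/m
    tether_adhesion_force: float = 3.8e-13  # N; may be +inf (non-detachable)
    timestep: float = 2.0e-4  # s
    duration: float = 33.0  # s
    frame_rate: float = 60.0  # Hz
    seed: int = 0
    integrator: str = "overdamped"  # or "inertial"
    allow_compression: bool = False  # two-sided spring (off: pull-only)
    attach_probability: float = 1.0  # per-step probability of re-attachment

    def __post_init__(self) -> None:
        positive = {
            "particle_diameter": self.particle_diameter,
            "temperature": self.temperature,
            "fluid_viscosity": self.fluid_viscosity,
            "fluid_density": self.fluid_density,
            "tether_rest_length": self.tether_rest_length,
            "tether_spring_constant": self.tether_spring_constant,
            "timestep": self.timestep,
            "duration": self.duration,
            "frame_rate": self.frame_rate,
        }
        for name, value in positive.items():
            if not (value > 0) or not math.isfinite(value):
                raise ConfigurationError(f"{name} must be strictly positive, got {value!r}")
        if self.particle_mass is not None and not self.particle_mass > 0:
            raise ConfigurationError("particle_mass must be strictly positive")
        if not self.tether_adhesion_force > 0:  # +inf allowed
            raise ConfigurationError("tether_adhesion_force must be positive (may be +inf)")
        if self.n_tethers_total < 0:
            raise ConfigurationError("n_tethers_total must be >= 0")
        if not 0 <= self.n_tethers_initial_bound <= self.n_tethers_total:
            raise ConfigurationError(
                "n_tethers_initial_bound must lie in [0, n_tethers_total]"
            )
        if self.timestep >= 1.0 / self.frame_rate:
            raise ConfigurationError("timestep must be smaller than the frame interval")
        if self.duration * self.frame_rate < 2:
            raise ConfigurationError("duration x frame_rate must cover at least 2 frames")
        if self.integrator not in ("overdamped", "inertial"):
            raise ConfigurationError(f"unknown integrator {self.integrator!r}")
        if not 0.0 <= self.attach_probability <= 1.0:
            raise ConfigurationError("attach_probability must lie in [0, 1]")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("seed must be an integer")

    @property
    def radius(self) -> float:
        return 0.5 * self.particle_diameter

    @property
    def mass(self) -> float:
        """Particle mass; density-matched sphere when not set explicitly."""
        if self.particle_mass is not None:
            return self.particle_mass
        return self.fluid_density * (4.0 / 3.0) * math.pi * self.radius**3

    @property
    def drag_coefficient(self) -> float:
        """Stokes drag 6*pi*eta*a on the sphere (N s/m)."""
        return 6.0 * math.pi * self.fluid_viscosity * self.radius

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration * self.frame_rate + 1e-9))

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in self.__dataclass_fields__  # noqa: SLF001 - dataclass introspection
        }
        if d["tether_adhesion_force"] == math.inf:
            d["tether_adhesion_force"] = "inf"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if d.get("tether_adhesion_force") in ("inf", "Infinity", "+inf"):
            d["tether_adhesion_force"] = math.inf
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class TetherState:
    """One tether: a body-frame anchor direction plus binding bookkeeping."""

    anchor_direction: np.ndarray  # unit vector, particle body frame
    bound: bool = False
    attachment_point: np.ndarray | None = None  # (x, y) on z=0, only when bound
    bind_time: float | None = None

    def __post_init__(self) -> None:
        self.anchor_direction = np.asarray(self.anchor_direction, dtype=float)
        if abs(np.linalg.norm(self.anchor_direction) - 1.0) > 1e-12:
            raise InvalidArgumentError("anchor_direction must be a unit vector")
        if self.attachment_point is not None:
            self.attachment_point = np.asarray(self.attachment_point, dtype=float)


@dataclass
class ParticleState:
    """Sphere-center position (and velocity, for the inertial integrator)."""

    position: np.ndarray  # (3,) m
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))
    time: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)


@dataclass
class TetherEventLog:
    """Time-ordered attach/detach events plus the bound-count time series."""

    events: list[tuple[float, int, str]] = field(default_factory=list)
    bound_count_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    bound_count_series: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def events_for(self, tether_index: int) -> list[tuple[float, str]]:
        return [(t, ev) for t, i, ev in self.events if i == tether_index]


@dataclass
class Trajectory:
    """Frame-sampled output of one simulation run."""

    times: np.ndarray  # (n_frames,) s, exact multiples of 1/frame_rate
    positions: np.ndarray  # (n_frames, 3) m
    config: SimulationConfig
    config_hash: str
    log: TetherEventLog

    @property
    def frames(self) -> np.ndarray:
        """(n_frames, 4) array of (time, x, y, z)."""
        return np.column_stack([self.times, self.positions])


@dataclass
class ResidenceTimes:
    """Completed attach->detach residence times, censored intervals separate."""

    completed: list[float]
    censored: list[float]


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def place_anchors(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the sphere (Fibonacci spiral lattice).

    Deterministic for a given ``n``; the lattice keeps the minimum pairwise
    angle above ~1.5x the ideal equal-area angle asymptotically, which is as
    close to "equally distributed" as a constructive lattice gets.
    """
    if n < 1:
        raise InvalidArgumentError(f"need at least one anchor, got n={n}")
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    golden_angle = math.pi * (3.0 - math.sqrt(5.0))
    theta = golden_angle * i
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    vec = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    return vec / np.linalg.norm(vec, axis=1, keepdims=True)


def initialize(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ParticleState, list[TetherState]]:
    """Set up the particle resting on the surface with the initial bound set.

    The particle center starts at ``z = a`` (sphere touching the substratum).
    The ``n_tethers_initial_bound`` anchors closest to the surface (ties broken
    by anchor index) are bound, each attached at the perpendicular projection
    of its anchor tip onto ``z = 0``.  Raises :class:`ConfigurationError` when
    the rest length cannot reach that many anchors.
    """
    del rng  # placement is deterministic
    particle = ParticleState(position=np.array([0.0, 0.0, config.radius]))
    if config.n_tethers_total == 0:
        if config.n_tethers_initial_bound:
            raise ConfigurationError("cannot bind tethers when n_tethers_total = 0")
        return particle, []
    directions = place_anchors(config.n_tethers_total)
    tethers = [TetherState(anchor_direction=u) for u in directions]
    n_bind = config.n_tethers_initial_bound
    if n_bind == 0:
        return particle, tethers
    tip_heights = particle.position[2] + config.radius * directions[:, 2]
    order = np.argsort(tip_heights, kind="stable")
    if tip_heights[order[n_bind - 1]] > config.tether_rest_length:
        raise ConfigurationError(
            f"tether rest length {config.tether_rest_length:.3g} m cannot reach "
            f"{n_bind} anchors (closest {n_bind} tip heights extend to "
            f"{tip_heights[order[n_bind - 1]]:.3g} m)"
        )
    for idx in order[:n_bind]:
        tip = particle.position + config.radius * directions[idx]
        tethers[idx].bound = True
        tethers[idx].attachment_point = tip[:2].copy()
        tethers[idx].bind_time = 0.0
    return particle, tethers


# ---------------------------------------------------------------------------
# Forces and single-step dynamics (reference NumPy path)
# ---------------------------------------------------------------------------


def tether_force(
    tether: TetherState, particle: ParticleState, config: SimulationConfig
) -> np.ndarray:
    """Hookean restoring force (N) a bound tether exerts on the particle.

    Pull-only by default: magnitude ``k * max(0, d - L0)`` directed from the
    anchor tip toward the attachment point; slack tethers exert nothing.  With
    ``allow_compression`` the spring is two-sided.
    """
    if not tether.bound:
        raise ContractViolationError("tether_force requires a bound tether")
    tip = particle.position + config.radius * tether.anchor_direction
    att = np.array([tether.attachment_point[0], tether.attachment_point[1], 0.0])
    delta = att - tip
    d = float(np.linalg.norm(delta))
    if d <= 0.0:
        return np.zeros(3)
    ext = d - config.tether_rest_length
    if ext <= 0.0 and not config.allow_compression:
        return np.zeros(3)
    return config.tether_spring_constant * ext * delta / d


def total_tether_force(
    particle: ParticleState, tethers: Sequence[TetherState], config: SimulationConfig
) -> np.ndarray:
    force = np.zeros(3)
    for tether in tethers:
        if tether.bound:
            force += tether_force(tether, particle, config)
    return force


def tether_potential(
    position: np.ndarray, tethers: Sequence[TetherState], config: SimulationConfig
) -> float:
    """Total elastic energy (J) of the bound tethers at a given center position.

    Used by the equipartition oracle: its finite-difference Hessian at the
    mechanical equilibrium yields the effective lateral stiffness.
    """
    k, l0 = config.tether_spring_constant, config.tether_rest_length
    energy = 0.0
    for tether in tethers:
        if not tether.bound:
            continue
        tip = position + config.radius * tether.anchor_direction
        delta = np.array(
            [tether.attachment_point[0] - tip[0], tether.attachment_point[1] - tip[1], -tip[2]]
        )
        ext = float(np.linalg.norm(delta)) - l0
        if ext > 0.0 or config.allow_compression:
            energy += 0.5 * k * ext * ext
    return energy


def step(
    particle: ParticleState,
    tethers: Sequence[TetherState],
    config: SimulationConfig,
    rng: np.random.Generator,
    dt: float | None = None,
) -> ParticleState:
    """Advance the particle one timestep (reference implementation).

    Overdamped Euler–Maruyama by default: ``dr = (F/gamma) dt + xi`` with
    isotropic Gaussian noise of per-axis variance ``2 (kT/gamma) dt``; the
    sphere is reflected at ``z = a`` (non-penetration).  The inertial
    integrator is a BBK-discretized Langevin velocity-Verlet using the
    particle mass.
    """
    dt = config.timestep if dt is None else dt
    if dt <= 0:
        raise InvalidArgumentError("timestep must be positive")
    gamma = config.drag_coefficient
    kT = BOLTZMANN * config.temperature
    force = total_tether_force(particle, tethers, config)
    if config.integrator == "overdamped":
        noise = rng.standard_normal(3) * math.sqrt(2.0 * kT * dt / gamma) if kT > 0 else 0.0
        new_pos = particle.position + force / gamma * dt + noise
        new_vel = particle.velocity
    else:
        # Gronbech-Jensen/Farago discretization: exact free diffusion and
        # Boltzmann configurational statistics at finite dt
        m = config.mass
        beta = (
            rng.standard_normal(3) * math.sqrt(2.0 * gamma * kT * dt)
            if kT > 0
            else np.zeros(3)
        )
        b = 1.0 / (1.0 + 0.5 * gamma * dt / m)
        a = (1.0 - 0.5 * gamma * dt / m) * b
        new_pos = (
            particle.position
            + b * dt * particle.velocity
            + 0.5 * b * dt * dt / m * force
            + 0.5 * b * dt / m * beta
        )
        trial = ParticleState(position=new_pos, velocity=particle.velocity)
        force_new = total_tether_force(trial, tethers, config)
        new_vel = (
            a * particle.velocity
            + 0.5 * dt / m * (a * force + force_new)
            + b / m * beta
        )
    if new_pos[2] < config.radius:
        new_pos = new_pos.copy()
        new_pos[2] = 2.0 * config.radius - new_pos[2]
        if config.integrator == "inertial":
            new_vel = new_vel.copy()
            new_vel[2] = -new_vel[2]
    return ParticleState(position=new_pos, velocity=new_vel, time=particle.time + dt)


def update_tethers(
    particle: ParticleState,
    tethers: Sequence[TetherState],
    config: SimulationConfig,
    rng: np.random.Generator,
    time: float,
) -> list[tuple[float, int, str]]:
    """Detach over-threshold tethers, then re-attach tethers within reach.

    Mutates ``tethers`` in place and returns the logged events.  Detachment
    uses a strict inequality (a tether at exactly its adhesion force stays
    bound); attachment is deterministic at the perpendicular projection of the
    anchor tip unless ``attach_probability`` < 1.
    """
    events: list[tuple[float, int, str]] = []
    for idx, tether in enumerate(tethers):  # detachments first
        if tether.bound:
            f = float(np.linalg.norm(tether_force(tether, particle, config)))
            if f > config.tether_adhesion_force:
                tether.bound = False
                tether.attachment_point = None
                tether.bind_time = None
                events.append((time, idx, "detach"))
    for idx, tether in enumerate(tethers):  # then attachments, index ascending
        if tether.bound:
            continue
        tip = particle.position + config.radius * tether.anchor_direction
        if tip[2] <= config.tether_rest_length:
            if config.attach_probability >= 1.0 or rng.random() < config.attach_probability:
                tether.bound = True
                tether.attachment_point = tip[:2].copy()
                tether.bind_time = time
                events.append((time, idx, "attach"))
    return events


# ---------------------------------------------------------------------------
# Fused simulation kernel (numba)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _run_kernel(
    offsets,  # (n, 3) anchor offsets a*u in m
    bound,  # (n,) uint8, mutated
    attach,  # (n, 2) attachment points, mutated
    pos,  # (3,) mutated
    vel,  # (3,) mutated (inertial only)
    k,
    l0,
    f_adh,
    gamma,
    kT,
    mass,
    dt,
    radius,
    allow_comp,
    attach_prob,
    inertial,
    n_steps,
    frame_steps,  # (n_frames,) int64, strictly increasing, last == n_steps
    seed,
    ev_step,
    ev_tether,
    ev_kind,  # numba typed lists (int64)
):
    np.random.seed(seed)
    n = offsets.shape[0]
    n_frames = frame_steps.shape[0]
    frames = np.empty((n_frames, 3))
    counts = np.empty(n_frames, np.int64)
    noise_over = math.sqrt(2.0 * kT * dt / gamma) if kT > 0 else 0.0
    sigma_in = math.sqrt(2.0 * gamma * kT * dt) if kT > 0 else 0.0
    fi = 0
    for s in range(n_steps + 1):
        while fi < n_frames and frame_steps[fi] == s:
            frames[fi, 0] = pos[0]
            frames[fi, 1] = pos[1]
            frames[fi, 2] = pos[2]
            c = 0
            for t in range(n):
                if bound[t]:
                    c += 1
            counts[fi] = c
            fi += 1
        if s == n_steps:
            break
        # total elastic force at the current position
        fx = 0.0
        fy = 0.0
        fz = 0.0
        for t in range(n):
            if bound[t]:
                tx = pos[0] + offsets[t, 0]
                ty = pos[1] + offsets[t, 1]
                tz = pos[2] + offsets[t, 2]
                dx = attach[t, 0] - tx
                dy = attach[t, 1] - ty
                dz = -tz
                d = math.sqrt(dx * dx + dy * dy + dz * dz)
                if d > 0.0:
                    ext = d - l0
                    if ext > 0.0 or allow_comp:
                        c = k * ext / d
                        fx += c * dx
                        fy += c * dy
                        fz += c * dz
        if inertial:
            # Gronbech-Jensen/Farago step (exact free diffusion at finite dt)
            if kT > 0:
                bx = sigma_in * np.random.standard_normal()
                by = sigma_in * np.random.standard_normal()
                bz = sigma_in * np.random.standard_normal()
            else:
                bx = by = bz = 0.0
            bfac = 1.0 / (1.0 + 0.5 * gamma * dt / mass)
            afac = (1.0 - 0.5 * gamma * dt / mass) * bfac
            pos[0] += bfac * dt * vel[0] + 0.5 * bfac * dt * dt / mass * fx + 0.5 * bfac * dt / mass * bx
            pos[1] += bfac * dt * vel[1] + 0.5 * bfac * dt * dt / mass * fy + 0.5 * bfac * dt / mass * by
            pos[2] += bfac * dt * vel[2] + 0.5 * bfac * dt * dt / mass * fz + 0.5 * bfac * dt / mass * bz
            # re-evaluate the force at the new position for the velocity kick
            fx2 = 0.0
            fy2 = 0.0
            fz2 = 0.0
            for t in range(n):
                if bound[t]:
                    tx = pos[0] + offsets[t, 0]
                    ty = pos[1] + offsets[t, 1]
                    tz = pos[2] + offsets[t, 2]
                    dx = attach[t, 0] - tx
                    dy = attach[t, 1] - ty
                    dz = -tz
                    d = math.sqrt(dx * dx + dy * dy + dz * dz)
                    if d > 0.0:
                        ext = d - l0
                        if ext > 0.0 or allow_comp:
                            c = k * ext / d
                            fx2 += c * dx
                            fy2 += c * dy
                            fz2 += c * dz
            vel[0] = afac * vel[0] + 0.5 * dt / mass * (afac * fx + fx2) + bfac / mass * bx
            vel[1] = afac * vel[1] + 0.5 * dt / mass * (afac * fy + fy2) + bfac / mass * by
            vel[2] = afac * vel[2] + 0.5 * dt / mass * (afac * fz + fz2) + bfac / mass * bz
        else:
            pos[0] += fx / gamma * dt
            pos[1] += fy / gamma * dt
            pos[2] += fz / gamma * dt
            if kT > 0:
                pos[0] += noise_over * np.random.standard_normal()
                pos[1] += noise_over * np.random.standard_normal()
                pos[2] += noise_over * np.random.standard_normal()
        if pos[2] < radius:  # reflecting wall: non-penetration of the substratum
            pos[2] = 2.0 * radius - pos[2]
            if inertial:
                vel[2] = -vel[2]
        # tether update: detachments first, then attachments, index ascending
        for t in range(n):
            if bound[t]:
                tx = pos[0] + offsets[t, 0]
                ty = pos[1] + offsets[t, 1]
                tz = pos[2] + offsets[t, 2]
                dx = attach[t, 0] - tx
                dy = attach[t, 1] - ty
                dz = -tz
                d = math.sqrt(dx * dx + dy * dy + dz * dz)
                ext = d - l0
                fmag = 0.0
                if ext > 0.0 or allow_comp:
                    fmag = abs(k * ext)
                if fmag > f_adh:
                    bound[t] = 0
                    ev_step.append(s + 1)
                    ev_tether.append(t)
                    ev_kind.append(0)
        for t in range(n):
            if not bound[t]:
                tz = pos[2] + offsets[t, 2]
                if tz <= l0:
                    if attach_prob >= 1.0 or np.random.random() < attach_prob:
                        bound[t] = 1
                        attach[t, 0] = pos[0] + offsets[t, 0]
                        attach[t, 1] = pos[1] + offsets[t, 1]
                        ev_step.append(s + 1)
                        ev_tether.append(t)
                        ev_kind.append(1)
    return frames, counts


def simulate(
    config: SimulationConfig,
    particle: ParticleState | None = None,
    tethers: Sequence[TetherState] | None = None,
) -> Trajectory:
    """Run a full tethered-particle simulation and return the sampled track.

    Frames are recorded at the integration step nearest each multiple of the
    frame interval (``floor(duration * frame_rate)`` frames in total, so the
    default 33 s at 60 Hz yields 1980 frames).  Bit-reproducible for a fixed
    ``(config, seed)``.  ``particle``/``tethers`` override the standard
    resting initial condition (both must be given together), e.g. to start
    from a pre-tensioned tether arrangement.
    """
    if (particle is None) != (tethers is None):
        raise InvalidArgumentError("provide both particle and tethers, or neither")
    if particle is None:
        particle, tethers = initialize(config)
    if len(tethers) != config.n_tethers_total:
        raise ConfigurationError("tether list length must equal n_tethers_total")
    n = config.n_tethers_total
    offsets = (
        config.radius * np.array([t.anchor_direction for t in tethers]).reshape(n, 3)
        if n
        else np.zeros((0, 3))
    )
    bound = np.array([1 if t.bound else 0 for t in tethers], dtype=np.uint8)
    attach = np.zeros((n, 2))
    for i, t in enumerate(tethers):
        if t.bound:
            attach[i] = t.attachment_point
    dt = config.timestep
    n_frames = config.n_frames
    frame_steps = np.rint(np.arange(n_frames) / (config.frame_rate * dt)).astype(np.int64)
    frame_steps = np.maximum.accumulate(frame_steps)  # monotone despite rounding
    n_steps = int(frame_steps[-1])
    # numba typed lists holding the event stream
    from numba import int64 as _nb_i64

    ev_step = NumbaList.empty_list(_nb_i64)
    ev_tether = NumbaList.empty_list(_nb_i64)
    ev_kind = NumbaList.empty_list(_nb_i64)
    pos = particle.position.copy()
    vel = np.zeros(3)
    frames, counts = _run_kernel(
        offsets,
        bound,
        attach,
        pos,
        vel,
        config.tether_spring_constant,
        config.tether_rest_length,
        config.tether_adhesion_force,
        config.drag_coefficient,
        BOLTZMANN * config.temperature,
        config.mass,
        dt,
        config.radius,
        config.allow_compression,
        config.attach_probability,
        config.integrator == "inertial",
        n_steps,
        frame_steps,
        int(config.seed) & 0x7FFFFFFF,
        ev_step,
        ev_tether,
        ev_kind,
    )
    # initial bound set (logged at t=0) precedes the in-run event stream
    events: list[tuple[float, int, str]] = [
        (0.0, int(i), "attach")
        for i in np.nonzero(np.array([t.bound for t in tethers], dtype=bool))[0]
    ]
    kinds = ("detach", "attach")
    for s, t, kcode in zip(ev_step, ev_tether, ev_kind):
        events.append((s * dt, int(t), kinds[kcode]))
    times = np.arange(n_frames) / config.frame_rate
    # bound counts are stamped with the actual integration-step times of the
    # sampled frames so replaying the event stream reproduces them exactly
    log = TetherEventLog(
        events=events, bound_count_times=frame_steps * dt, bound_count_series=counts
    )
    return Trajectory(
        times=times,
        positions=frames,
        config=config,
        config_hash=config.content_hash(),
        log=log,
    )


def pretensioned_state(
    config: SimulationConfig, n_bound: int, radial_stretch: float = 0.5
) -> tuple[ParticleState, list[TetherState]]:
    """Initial condition with every bound tether under tension.

    The ``n_bound`` lowest anchors are attached at their tip's perpendicular
    projection pushed radially outward by a factor ``1 + radial_stretch`` (in
    the surface plane, about the particle axis), so each tether is stretched
    and the particle sits in a laterally harmonic trap at the substratum.
    This is the reference configuration for the equipartition oracle: the
    lateral positional variance must equal kT divided by the lateral Hessian
    of the total tether potential.
    """
    particle, tethers = initialize(replace(config, n_tethers_initial_bound=0))
    directions = np.array([t.anchor_direction for t in tethers])
    order = np.argsort(directions[:, 2], kind="stable")
    for idx in order[:n_bound]:
        tip = particle.position + config.radius * directions[idx]
        tethers[idx].bound = True
        tethers[idx].attachment_point = tip[:2] * (1.0 + radial_stretch)
        tethers[idx].bind_time = 0.0
    return particle, tethers


# ---------------------------------------------------------------------------
# Event-log analysis
# ---------------------------------------------------------------------------


def residence_times(log: TetherEventLog, duration: float) -> ResidenceTimes:
    """Per-tether bound intervals from the event log.

    One duration per completed attach->detach pair; tethers still bound at the
    end of the run contribute right-censored intervals (``duration - t_attach``)
    reported separately.  Raises :class:`DataError` on malformed alternation.
    """
    per_tether: dict[int, list[tuple[float, str]]] = {}
    last_time = -math.inf
    for t, idx, kind in log.events:
        if t < last_time:
            raise DataError("event log is not time-ordered")
        last_time = t
        per_tether.setdefault(idx, []).append((t, kind))
    completed: list[float] = []
    censored: list[float] = []
    for idx, evs in per_tether.items():
        open_since: float | None = None
        for t, kind in evs:
            if kind == "attach":
                if open_since is not None:
                    raise DataError(f"tether {idx}: attach while already bound")
                open_since = t
            elif kind == "detach":
                if open_since is None:
                    raise DataError(f"tether {idx}: detach while not bound")
                completed.append(t - open_since)
                open_since = None
            else:
                raise DataError(f"unknown event kind {kind!r}")
        if open_since is not None:
            censored.append(duration - open_since)
    return ResidenceTimes(completed=completed, censored=censored)


# ---------------------------------------------------------------------------
# Oracles used by the validation suite
# ---------------------------------------------------------------------------


def equilibrium_position(
    start: np.ndarray, tethers: Sequence[TetherState], config: SimulationConfig
) -> np.ndarray:
    """Numerically minimize the total tether potential (z constrained >= a)."""
    from scipy.optimize import minimize

    res = minimize(
        lambda r: tether_potential(r, tethers, config) * 1e18,  # aJ for conditioning
        np.asarray(start, dtype=float),
        method="L-BFGS-B",
        bounds=[(None, None), (None, None), (config.radius, None)],
        options={"ftol": 1e-15, "gtol": 1e-12},
    )
    return res.x


def lateral_stiffness(
    position: np.ndarray, tethers: Sequence[TetherState], config: SimulationConfig,
    h: float = 1e-11,
) -> tuple[float, float]:
    """Finite-difference lateral Hessian (k_xx, k_yy) of the tether potential."""

    def v(dx: float, dy: float) -> float:
        return tether_potential(position + np.array([dx, dy, 0.0]), tethers, config)

    v0 = v(0.0, 0.0)
    kxx = (v(h, 0.0) - 2 * v0 + v(-h, 0.0)) / h**2
    kyy = (v(0.0, h) - 2 * v0 + v(0.0, -h)) / h**2
    return kxx, kyy


def stokes_einstein_diffusivity(config: SimulationConfig) -> float:
    """kT / (6 pi eta a) in m^2/s."""
    return BOLTZMANN * config.temperature / config.drag_coefficient


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """Deterministic independent child seeds (< 2**31) from one base seed."""
    ss = np.random.SeedSequence(int(base_seed))
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n, dtype=np.uint32)]


def replicate_configs(
    config: SimulationConfig, seeds: Iterable[int]
) -> list[SimulationConfig]:
    return [replace(config, seed=int(s)) for s in seeds]
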