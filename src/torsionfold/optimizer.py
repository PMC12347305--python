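"""Hybrid global optimizer: golden-ratio simulated annealing whose move
generator is a jumping-spider population metaheuristic.

The annealer partitions the cooling range at temperatures scaled by the
golden-section constant Phi = 0.618: each section boundary is 0.618 times
the previous one, and the cooling factor alpha increases by 0.05 per
section (0.75 ... 0.95 by default, five sections), so cold sections are
searched more intensively than hot ones.  Within a temperature, each
Metropolis step draws its candidate from a short run of a spider-hunting
population search (persecution, jump, local/global search, pheromone-based
replacement of weak agents) seeded at the current solution, and accepts it
by the Boltzmann criterion.  A least-squares stop criterion on the trailing
best-energy series terminates the final section once the slope is flat.

All solution vectors are torsion angles in degrees, wrapped into the
per-variable bounds (default [-180, 180)) after every update.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError, NumericError
from .geometry import TorsionState

__all__ = [
    "CoolingSchedule",
    "JSOAConfig",
    "OptimizerConfig",
    "SpiderPopulation",
    "OptimizeResult",
    "iterations_for_alpha",
    "build_cooling_schedule",
    "regression_slope",
    "metropolis_accept",
    "jsoa_strategy_update",
    "pheromone_rates",
    "low_pheromone_update",
    "bioperturbation",
    "calibrate_initial_temperature",
    "minimize",
]

GOLDEN_SECTION = 0.618


def iterations_for_alpha(t0: float, tf: float, alpha: float) -> int:
    """Number of multiplicative decrements by ``alpha`` taking t0 down to tf.

    ceil(ln(tf/t0) / ln(alpha)); 0 when tf == t0.  Non-decreasing in alpha,
    so later (larger-alpha) sections of the schedule iterate more per unit
    of temperature ratio.
    """
    if not (0.0 < alpha < 1.0):
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")
    if t0 <= 0 or tf <= 0 or tf > t0:
        raise DomainError(f"need t0 >= tf > 0, got t0={t0}, tf={tf}")
    if tf == t0:
        return 0
    return math.ceil(math.log(tf / t0) / math.log(alpha))


@dataclass(frozen=True)
class CoolingSchedule:
    """Golden-section cooling plan.

    ``sections`` is a list of (T_start, T_end, alpha); consecutive section
    boundaries satisfy T_{s+1} = 0.618 * T_s except the last, which is cut
    at the final temperature.
    """

    t0: float
    tf: float
    phi: float
    sections: tuple[tuple[float, float, float], ...]

    @property
    def c(self) -> float:
        """ln Tf - ln T0 of the classical iteration-count formula."""
        return math.log(self.tf) - math.log(self.t0)

    def temperature_ladder(self) -> list[tuple[float, int]]:
        """Every temperature visited, with its section index."""
        ladder = []
        for s, (t_start, t_end, alpha) in enumerate(self.sections):
            t = t_start
            while t > t_end * (1.0 + 1e-12):
                ladder.append((t, s))
                t *= alpha
        return ladder


def build_cooling_schedule(t0: float, tf: float, alpha0: float = 0.75,
                           alpha_step: float = 0.05, alpha_max: float = 0.95,
                           phi: float = GOLDEN_SECTION,
                           max_sections: int = 5) -> CoolingSchedule:
    """Partition [tf, t0] into golden-section cooling sections.

    Section s spans [phi^(s+1) * t0, phi^s * t0] and cools with
    alpha0 + s * alpha_step capped at alpha_max; sectioning stops at
    ``max_sections`` or when a boundary would fall below tf, and the last
    section always ends at tf.
    """
    if t0 <= tf or tf <= 0:
        raise DomainError(f"need t0 > tf > 0, got t0={t0}, tf={tf}")
    sections = []
    t_start = t0
    for s in range(max_sections):
        alpha = min(alpha0 + s * alpha_step, alpha_max)
        boundary = t0 * phi ** (s + 1)
        last = s == max_sections - 1 or boundary <= tf
        t_end = tf if last else boundary
        sections.append((t_start, t_end, alpha))
        if last:
            break
        t_start = t_end
    return CoolingSchedule(t0=t0, tf=tf, phi=phi, sections=tuple(sections))


def regression_slope(energies, mode: str = "corrected") -> float:
    """Slope of the trailing Metropolis-cycle energy series.

    ``corrected``: ordinary least-squares slope of E_i against i = 1..k.
    ``as_printed``: the literal simplified formula
    m = (12 sum_{i=2..k} i E_i - 6 (k-1) sum_{i=2..k} E_i) / (k^3 - k),
    which drops the i = 1 point and is biased for constant series; kept for
    fidelity with the formulation it was transcribed from.
    """
    e = np.asarray(energies, dtype=float)
    k = len(e)
    if k < 2:
        raise DomainError(f"slope needs at least 2 energies, got {k}")
    if mode == "corrected":
        i = np.arange(1, k + 1, dtype=float)
        return float(np.polyfit(i, e, 1)[0])
    if mode == "as_printed":
        i = np.arange(2, k + 1, dtype=float)
        tail = e[1:]
        return float((12.0 * np.sum(i * tail) - 6.0 * (k - 1) * np.sum(tail))
                     / (k**3 - k))
    raise DomainError(f"unknown slope mode {mode!r}")


def metropolis_accept(d_e: float, t: float, rng: np.random.Generator,
                      mode: str = "standard") -> bool:
    """Boltzmann acceptance of an energy change d_e at temperature t.

    d_e <= 0 is always accepted.  ``standard`` accepts uphill moves with
    probability exp(-d_e/t); ``as_printed`` accepts when exp(-d_e/t) < u
    with u ~ U(0,1) (probability 1 - exp(-d_e/t)), mirroring a transcription
    that inverts the comparison.
    """
    if t <= 0:
        raise DomainError(f"temperature must be positive, got {t}")
    if d_e <= 0:
        return True
    p = math.exp(max(-d_e / t, -745.0))
    u = rng.random()
    if mode == "standard":
        return u < p
    if mode == "as_printed":
        return p < u
    raise DomainError(f"unknown acceptance mode {mode!r}")


# ---------------------------------------------------------------------------
# spider population strategies
# ---------------------------------------------------------------------------

@dataclass
class JSOAConfig:
    """Spider-search constants.

    ``v0`` (initial jump speed, printed numeral 100) and ``g_grav``
    (9.80665) parameterize the projectile-motion jump update; the jump
    angle comes from a uniform (0, 1) draw interpreted through
    alpha = phi * pi / 180 radians, as printed.  ``epsilon_dist`` selects
    the local-search epsilon distribution: standard normal by default,
    uniform (0, 1) optionally.
    """

    n_agents: int = 10
    max_iter: int = 20
    v0: float = 100.0
    g_grav: float = 9.80665
    pheromone_threshold: float = 0.3
    walk_range: tuple[float, float] = (-2.0, 2.0)
    epsilon_dist: str = "normal"
    init_jitter_deg: float = 10.0

    def __post_init__(self):
        if self.n_agents < 2:
            raise DomainError("population needs at least 2 agents")
        if self.max_iter < 1:
            raise DomainError("max_iter must be >= 1")
        if not (0.0 < self.pheromone_threshold < 1.0):
            raise DomainError("pheromone threshold must lie in (0, 1)")


@dataclass
class SpiderPopulation:
    """Agents (rows of torsion vectors) with their fitness (minimization)."""

    agents: np.ndarray
    fitness: np.ndarray

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.fitness))

    @property
    def worst_index(self) -> int:
        return int(np.argmax(self.fitness))

    @property
    def best(self) -> np.ndarray:
        return self.agents[self.best_index]

    @property
    def worst(self) -> np.ndarray:
        return self.agents[self.worst_index]


def _wrap_bounds(x: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    lo, hi = bounds
    return (x - lo) % (hi - lo) + lo


def _jump(x, phi_draw, v0, g_grav):
    alpha = np.asarray(phi_draw) * math.pi / 180.0
    return x * np.tan(alpha) - x**2 * g_grav / (2.0 * v0**2 * np.cos(alpha)**2)


def pheromone_rates(population: SpiderPopulation) -> np.ndarray:
    """Min-max normalized fitness in [0, 1]: 1 at the best agent, 0 at the
    worst; all ones when every fitness is equal (nothing to rank)."""
    f = np.asarray(population.fitness, dtype=float)
    worst, best = f.max(), f.min()
    if worst == best:
        return np.ones_like(f)
    return (worst - f) / (worst - best)


def jsoa_strategy_update(mode: str, agent_index: int,
                         population: SpiderPopulation, config: JSOAConfig,
                         rng: np.random.Generator,
                         bounds: tuple[float, float] = (-180.0, 180.0),
                         **draws) -> np.ndarray:
    """One strategy move for one agent; returns the wrapped new vector.

    ``draws`` lets callers pin the stochastic inputs (r, phi, walk, eps,
    lam) for exact verification; by default they are drawn from the
    distributions the update rules specify.
    """
    x = np.asarray(population.agents[agent_index], dtype=float)
    n = len(population.agents)
    if mode == "persecution":
        r = draws.get("r")
        if r is None:
            r = rng.integers(n - 1)
            r = r + 1 if r >= agent_index else r
        new = 0.5 * (x - population.agents[r])
    elif mode == "jump":
        phi_draw = draws.get("phi", rng.random())
        new = _jump(x, phi_draw, config.v0, config.g_grav)
    elif mode == "local":
        walk = draws.get("walk", rng.uniform(*config.walk_range))
        eps = draws.get("eps")
        if eps is None:
            eps = (rng.standard_normal() if config.epsilon_dist == "normal"
                   else rng.random())
        new = population.best + walk * (0.5 - eps)
    elif mode == "global":
        lam = draws.get("lam", rng.standard_cauchy())
        new = population.best + (population.best - population.worst) * lam
    else:
        raise DomainError(f"unknown strategy {mode!r}")
    return _wrap_bounds(new, bounds)


def low_pheromone_update(population: SpiderPopulation, config: JSOAConfig,
                         rng: np.random.Generator,
                         bounds: tuple[float, float] = (-180.0, 180.0)):
    """Replace weak agents (pheromone rate <= threshold) near the best one.

    Each replaced agent becomes x_best + (x_r1 - (-1)^sigma * x_r2) / 2 with
    sigma in {0, 1} and distinct random indices r1 != r2.  Returns the new
    agent matrix and the boolean mask of replaced rows (their fitness must
    be re-evaluated by the caller).
    """
    n = len(population.agents)
    if n < 3:
        raise DomainError("pheromone replacement needs at least 3 agents")
    rates = pheromone_rates(population)
    agents = population.agents.copy()
    replaced = rates <= config.pheromone_threshold
    best = population.best
    for i in np.flatnonzero(replaced):
        r1, r2 = rng.choice(n, size=2, replace=False)
        sigma = int(rng.integers(2))
        agents[i] = _wrap_bounds(
            best + 0.5 * (agents[r1] - (-1.0) ** sigma * agents[r2]), bounds)
    return agents, replaced


def _evaluate_rows(objective, x: np.ndarray) -> np.ndarray:
    if getattr(objective, "supports_batch", False):
        return np.asarray(objective(x), dtype=float)
    return np.array([objective(row) for row in x], dtype=float)


def bioperturbation(state, objective, config: JSOAConfig,
                    rng: np.random.Generator,
                    bounds: tuple[float, float] = (-180.0, 180.0)):
    """Generate a candidate solution by a short spider-population search.

    The population is re-initialized on every call from the incoming
    solution (the solution itself plus Gaussian-jittered copies).  Each
    iteration gives every agent a coin-flip between attack (persecution or
    jump) and search (local or global), then applies the pheromone
    replacement to weak agents.  Returns (best-ever vector, best-ever
    fitness); the best-ever fitness never exceeds the best fitness of the
    initial population.

    Accepts a :class:`~torsionfold.geometry.TorsionState` or a flat vector
    and returns the matching type (plus the fitness).
    """
    is_state = isinstance(state, TorsionState)
    x0 = state.flatten() if is_state else np.asarray(state, dtype=float)
    d = len(x0)
    n = config.n_agents
    agents = np.tile(x0, (n, 1))
    agents[1:] += rng.normal(0.0, config.init_jitter_deg, (n - 1, d))
    agents = _wrap_bounds(agents, bounds)
    fitness = _evaluate_rows(objective, agents)
    if not np.all(np.isfinite(fitness)):
        raise NumericError("objective returned a non-finite value")
    k = int(np.argmin(fitness))
    best_x, best_f = agents[k].copy(), float(fitness[k])

    half_pi_scale = math.pi / 180.0
    for _ in range(config.max_iter):
        best = agents[int(np.argmin(fitness))]
        worst = agents[int(np.argmax(fitness))]
        attack = rng.random(n) < 0.5
        sub = rng.random(n) < 0.5
        new = np.empty_like(agents)

        m = attack & sub  # persecution
        if m.any():
            idx = np.flatnonzero(m)
            r = rng.integers(n - 1, size=len(idx))
            r = np.where(r >= idx, r + 1, r)
            new[idx] = 0.5 * (agents[idx] - agents[r])
        m = attack & ~sub  # jump
        if m.any():
            phi_draw = rng.random(m.sum())
            alpha = phi_draw * half_pi_scale
            xi = agents[m]
            new[m] = (xi * np.tan(alpha)[:, None]
                      - xi**2 * (config.g_grav
                                 / (2.0 * config.v0**2 * np.cos(alpha)**2))[:, None])
        m = ~attack & sub  # local search around the best agent
        if m.any():
            walk = rng.uniform(*config.walk_range, m.sum())
            eps = (rng.standard_normal(m.sum()) if config.epsilon_dist == "normal"
                   else rng.random(m.sum()))
            new[m] = best + (walk * (0.5 - eps))[:, None]
        m = ~attack & ~sub  # global search along the best-worst axis
        if m.any():
            lam = rng.standard_cauchy(m.sum())
            new[m] = best + (best - worst) * lam[:, None]

        agents = _wrap_bounds(new, bounds)
        fitness = _evaluate_rows(objective, agents)
        pop = SpiderPopulation(agents, fitness)
        if n >= 3:
            agents, replaced = low_pheromone_update(pop, config, rng, bounds)
            if replaced.any():
                fitness = fitness.copy()
                fitness[replaced] = _evaluate_rows(objective, agents[replaced])
        if not np.all(np.isfinite(fitness)):
            raise NumericError("objective returned a non-finite value")
        k = int(np.argmin(fitness))
        if fitness[k] < best_f:
            best_x, best_f = agents[k].copy(), float(fitness[k])

    if is_state:
        return TorsionState.from_flat(state.sequence, best_x,
                                      omega_free=state.omega_free), best_f
    return best_x, best_f


# ---------------------------------------------------------------------------
# full annealer
# ---------------------------------------------------------------------------

@dataclass
class OptimizerConfig:
    """All annealing and spider-search settings.

    ``t0``/``tf`` default to automatic calibration: t0 is chosen so ~90% of
    uphill perturbations from the initial solution would be accepted, and
    tf = 1e-3 * t0.  ``metropolis_length`` defaults to max(50, 2 * dim).
    """

    t0: float | None = None
    tf: float | None = None
    tf_ratio: float = 1e-3
    alpha0: float = 0.75
    alpha_step: float = 0.05
    alpha_max: float = 0.95
    max_sections: int = 5
    phi: float = GOLDEN_SECTION
    metropolis_length: int | None = None
    acceptance_mode: str = "standard"
    slope_mode: str = "corrected"
    slope_tol: float = 1e-3
    k_max: int = 5
    spider: JSOAConfig = field(default_factory=JSOAConfig)
    bounds: tuple[float, float] = (-180.0, 180.0)
    seed: int | None = None


@dataclass
class OptimizeResult:
    best_state: object
    best_energy: float
    trace: list[tuple[int, float, float]]  # (cycle, temperature, best energy)
    initial_energy: float
    n_cycles: int
    early_stop: bool
    t0: float
    tf: float


def calibrate_initial_temperature(objective, x0: np.ndarray,
                                  config: JSOAConfig, rng: np.random.Generator,
                                  bounds=(-180.0, 180.0),
                                  target_acceptance: float = 0.9,
                                  n_samples: int = 100) -> float:
    """Pick T0 so that about ``target_acceptance`` of random perturbation
    moves away from the start would be accepted: T0 = <dE+> / ln(1/chi0).
    Falls back to 1.0 when no sampled move is uphill."""
    f0 = float(objective(np.asarray(x0, dtype=float)))
    n = config.n_agents
    agents = np.tile(x0, (n, 1))
    agents[1:] += rng.normal(0.0, config.init_jitter_deg, (n - 1, len(x0)))
    agents = _wrap_bounds(agents, bounds)
    fitness = _evaluate_rows(objective, agents)
    pop = SpiderPopulation(agents, fitness)
    modes = ("persecution", "jump", "local", "global")
    uphill = []
    for _ in range(n_samples):
        mode = modes[rng.integers(4)]
        i = int(rng.integers(n))
        cand = jsoa_strategy_update(mode, i, pop, config, rng, bounds)
        d_e = float(objective(cand)) - f0
        if d_e > 0:
            uphill.append(d_e)
    if not uphill:
        return 1.0
    return float(np.mean(uphill) / math.log(1.0 / target_acceptance))


def minimize(objective, initial, config: OptimizerConfig | None = None,
             rng: np.random.Generator | None = None) -> OptimizeResult:
    """Refine a solution by annealing with spider-search perturbations.

    ``objective`` maps a flat torsion vector (degrees) to an energy;
    ``initial`` is a :class:`~torsionfold.geometry.TorsionState` or flat
    vector.  The best-so-far energy recorded in the trace is non-increasing
    by construction; the stop criterion runs only in the final (coldest)
    section and terminates once the trailing slope magnitude drops below
    ``slope_tol``.
    """
    config = config or OptimizerConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    is_state = isinstance(initial, TorsionState)
    x = initial.flatten() if is_state else np.asarray(initial, dtype=float)
    f = f0 = float(objective(x))
    if not math.isfinite(f):
        raise NumericError("objective is non-finite at the initial solution")

    t0 = config.t0
    if t0 is None:
        t0 = calibrate_initial_temperature(objective, x, config.spider, rng,
                                           config.bounds)
    tf = config.tf if config.tf is not None else config.tf_ratio * t0
    schedule = build_cooling_schedule(t0, tf, config.alpha0, config.alpha_step,
                                      config.alpha_max, config.phi,
                                      config.max_sections)
    ladder = schedule.temperature_ladder()
    last_section = len(schedule.sections) - 1
    l_k = config.metropolis_length or max(50, 2 * len(x))

    best_x, best_f = x.copy(), f
    trace = []
    window: deque = deque(maxlen=config.k_max)
    early = False
    for cycle, (t, section) in enumerate(ladder):
        for _ in range(l_k):
            cand, cand_f = bioperturbation(x, objective, config.spider, rng,
                                           config.bounds)
            if metropolis_accept(cand_f - f, t, rng, config.acceptance_mode):
                x, f = cand, cand_f
                if f < best_f:
                    best_x, best_f = x.copy(), f
        trace.append((cycle, t, best_f))
        if section == last_section:
            window.append(best_f)
            if len(window) == config.k_max:
                m = regression_slope(list(window), config.slope_mode)
                if abs(m) < config.slope_tol:
                    early = True
                    break

    if is_state:
        best_state = TorsionState.from_flat(initial.sequence, best_x,
                                            omega_free=initial.omega_free)
    else:
        best_state = best_x
    return OptimizeResult(best_state=best_state, best_energy=best_f,
                          trace=trace, initial_energy=f0,
                          n_cycles=len(trace), early_stop=early, t0=t0, tf=tf)
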