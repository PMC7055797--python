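"""Serial-transfer evolution protocol with Monte Carlo mutant seeding.

A run starts from a wild-type inoculum in fresh medium, grows each batch
cycle to resource exhaustion (:mod:`snapsim.growth_dynamics`), seeds
mutant cells along the five transition arrows of the strain model, dilutes
the culture through a bottleneck into fresh medium, and repeats until the
population has grown a target number of cumulative generations (default
1000).  Under the default protocol (capacity 1e10, 100-fold dilution) each
cycle contributes ~6.7 generations, so a run spans ~151 passages.

Mutant seeding interprets the per-cell appearance probability
``p = min(1, g_i * mu_ij)`` (``g_i`` = generations the parent strain grew
during the cycle just completed) in one of three modes:

* ``"scaled"`` (default) -- the number of parent cells converting to the
  child strain is Poisson with mean ``n_i * p``, applied to end-of-cycle
  counts before the bottleneck.  This is the population-level reading of
  the per-cell probability: mutant supply scales with the size of the
  parent population, which is what lets duplications arise within the
  1000-generation horizon and gives the neutral WT<->DUP system its
  mutation-segregation balance ``mu_f / (mu_f + mu_b)``.
* ``"single"`` -- one uniform draw per arrow per passage; if it falls
  below ``p`` exactly one cell converts, joining the culture after the
  bottleneck (so a seeded single cell grows a full cycle before first
  facing dilution).  This literal single-cell Monte Carlo is kept for
  sensitivity analysis; with realistic rates its mutant supply is
  independent of population size and far too small to recapitulate
  duplication dynamics on the 1000-generation horizon.
* ``"poisson"`` -- like ``"single"`` but the number of seeded cells is
  Poisson with mean ``p`` instead of Bernoulli.

In all modes conversion moves cells: the parent strain is decremented by
the number of cells seeded (capped at its current count).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from .growth_dynamics import GrowthParams, integrate_cycle
from .strain_model import (
    ARROWS,
    Arrow,
    FitnessScheme,
    PopulationState,
    StrainType,
    TransitionRates,
    default_rates,
    validate_scheme,
)

__all__ = [
    "PassageProtocol",
    "RngStream",
    "Trajectory",
    "Scenario",
    "ReplicateSummary",
    "mutation_probability",
    "sample_mutation_events",
    "sample_scaled_events",
    "apply_bottleneck",
    "run_serial_passages",
    "average_replicates",
    "mean_of_trajectories",
    "classify_outcome",
    "scenario_preset",
]

logger = logging.getLogger("snapsim.passage")

SEEDING_MODES = ("scaled", "single", "poisson")
BOTTLENECK_MODES = ("continuous", "stochastic")


@dataclass(frozen=True)
class PassageProtocol:
    """Serial-passage protocol parameters.

    Defaults mirror the standard setup: a starting population of 1e6
    wild-type cells, batches saturating at 1e10 cells, 100-fold dilution
    transferring 1e8 cells per bottleneck, until 1000 cumulative
    generations of growth.
    """

    dilution_factor: float = 100.0
    bottleneck_size: float = 1e8
    initial_population: float = 1e6
    target_generations: float = 1000.0
    bottleneck_mode: str = "continuous"
    seeding_mode: str = "scaled"
    fixation_threshold: float = 0.99

    def __post_init__(self) -> None:
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must exceed 1")
        if self.target_generations <= 0:
            raise ValueError("target_generations must be positive")
        if self.bottleneck_mode not in BOTTLENECK_MODES:
            raise ValueError(f"bottleneck_mode must be one of {BOTTLENECK_MODES}")
        if self.seeding_mode not in SEEDING_MODES:
            raise ValueError(f"seeding_mode must be one of {SEEDING_MODES}")
        if not 0 < self.fixation_threshold <= 1:
            raise ValueError("fixation_threshold must lie in (0, 1]")


class RngStream:
    """Seeded random stream; identical seed => identical draw sequence."""

    def __init__(self, seed: int):
        self.seed = int(seed)
        self._rng = np.random.default_rng(self.seed)

    def draw(self) -> float:
        """One uniform variate x with 0 < x < 1."""
        x = self._rng.random()
        while x == 0.0:  # pragma: no cover - probability ~2^-53
            x = self._rng.random()
        return x

    def poisson(self, lam: float) -> int:
        return int(self._rng.poisson(lam))

    def binomial(self, n: int, p: float) -> int:
        return int(self._rng.binomial(n, p))


@dataclass
class Trajectory:
    """Per-passage record of a serial-passage run.

    Counts are the end-of-cycle (pre-bottleneck) census of each strain;
    ``generations`` is the cumulative log2 fold-expansion of the total
    population.
    """

    passages: np.ndarray
    generations: np.ndarray
    counts: np.ndarray  # shape (n_passages, 4), strain order WT/DUP/D1/D2
    outcome: Optional[str] = None
    fixation_generation: Optional[float] = None
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.passages)

    def fractions(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(totals > 0, self.counts / totals, 0.0)
        return f


@dataclass
class Scenario:
    """A complete, validated simulation setup."""

    scheme: FitnessScheme = field(default_factory=FitnessScheme)
    rates: TransitionRates = field(default_factory=default_rates)
    growth: GrowthParams = field(default_factory=GrowthParams)
    protocol: PassageProtocol = field(default_factory=PassageProtocol)
    replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        validate_scheme(self.scheme, self.rates)
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def mutation_probability(g: float, mu: float) -> float:
    """Per-cell probability ``min(1, g * mu)`` of generating the child strain.

    ``g`` is the parent strain's generations of growth over the most
    recent completed cycle; the product is capped at 1 because it is a
    probability.
    """
    if g < 0:
        raise ValueError("generations of growth must be non-negative")
    if not 0 <= mu <= 1:
        raise ValueError("transition rate must lie in [0, 1]")
    return min(1.0, g * mu)


def sample_mutation_events(
    rng: RngStream,
    g: np.ndarray,
    counts: np.ndarray,
    rates: TransitionRates,
) -> Dict[Arrow, int]:
    """Literal single-cell Monte Carlo: one uniform draw per arrow.

    Arrows are evaluated in the fixed order WT->DUP, DUP->WT, DUP->D1,
    D1->WT, D1->D2 so that seeded runs are reproducible; an arrow only
    fires when its parent strain is present.  Returns the arrows that
    fired, each seeding exactly one cell.
    """
    events: Dict[Arrow, int] = {}
    for arrow in ARROWS:
        parent, _child = arrow
        if counts[parent] <= 0:
            continue
        p = mutation_probability(float(g[parent]), rates.rate(*arrow))
        x = rng.draw()
        if x < p:
            events[arrow] = 1
    return events


def sample_poisson_events(
    rng: RngStream,
    g: np.ndarray,
    counts: np.ndarray,
    rates: TransitionRates,
) -> Dict[Arrow, int]:
    """Poisson-number variant of the single-cell rule (mean = per-cell p)."""
    events: Dict[Arrow, int] = {}
    for arrow in ARROWS:
        parent, _child = arrow
        if counts[parent] <= 0:
            continue
        p = mutation_probability(float(g[parent]), rates.rate(*arrow))
        if p > 0:
            c = rng.poisson(p)
            if c > 0:
                events[arrow] = c
    return events


def sample_scaled_events(
    rng: RngStream,
    g: np.ndarray,
    counts: np.ndarray,
    rates: TransitionRates,
) -> Dict[Arrow, int]:
    """Population-scaled seeding: Poisson(n_parent * per-cell p) per arrow."""
    events: Dict[Arrow, int] = {}
    for arrow in ARROWS:
        parent, _child = arrow
        n_parent = float(counts[parent])
        if n_parent <= 0:
            continue
        p = mutation_probability(float(g[parent]), rates.rate(*arrow))
        if p > 0:
            c = rng.poisson(n_parent * p)
            if c > 0:
                events[arrow] = c
    return events


def _apply_events(n: np.ndarray, events: Dict[Arrow, int], passage: int) -> None:
    """Convert cells along each fired arrow, capped at the parent count."""
    for (parent, child), cells in events.items():
        moved = min(float(cells), float(n[parent]))
        n[parent] -= moved
        n[child] += moved
        if moved > 0:
            logger.debug(
                "event passage=%d arrow=%s>%s cells=%g",
                passage,
                parent.name,
                child.name,
                moved,
            )


def apply_bottleneck(
    state: PopulationState,
    protocol: PassageProtocol,
    rng: RngStream,
    growth: GrowthParams,
) -> PopulationState:
    """Dilute the end-of-cycle culture into fresh medium.

    Continuous mode divides every strain count by the dilution factor
    (fractional cells permitted, matching a deterministic ODE treatment);
    stochastic mode draws the transferred counts by binomial thinning with
    probability ``1/dilution_factor`` per cell.  Resource is reset to a
    full batch and per-cycle generation counters to zero.
    """
    d = protocol.dilution_factor
    if protocol.bottleneck_mode == "continuous":
        n_new = state.n / d
    else:
        whole = np.round(state.n).astype(np.int64)
        n_new = np.array(
            [rng.binomial(int(c), 1.0 / d) if c > 0 else 0 for c in whole], dtype=float
        )
    return PopulationState(n=n_new, resource=growth.r0, time=0.0)


def run_serial_passages(scenario: Scenario, seed: Optional[int] = None) -> Trajectory:
    """Run one serial-passage trajectory to the generation target.

    Loop per passage: grow the batch to resource exhaustion, accumulate
    cumulative generations (log2 of the total-population fold-expansion
    that cycle), seed mutants according to the protocol's seeding mode,
    record the end-of-cycle census, and bottleneck into fresh medium.
    Stops once cumulative generations reach the target.  Identical
    scenario + seed give a bit-identical trajectory.
    """
    if seed is None:
        seed = scenario.seed
    rng = RngStream(seed)
    protocol = scenario.protocol
    state = PopulationState.founding(protocol.initial_population, scenario.growth.r0)

    passages: List[int] = []
    generations: List[float] = []
    counts: List[np.ndarray] = []
    cum_g = 0.0
    passage = 0

    while cum_g < protocol.target_generations:
        passage += 1
        start_total = state.total
        try:
            state = integrate_cycle(state, scenario.scheme, scenario.growth)
        except Exception as err:
            raise RuntimeError(f"growth cycle failed at passage {passage}: {err}") from err
        cycle_g = math.log2(state.total / start_total)
        if cycle_g <= 0:
            raise RuntimeError(f"no growth at passage {passage}; protocol cannot progress")
        cum_g += cycle_g

        if protocol.seeding_mode == "scaled":
            # Mutants arise during growth: seed on the end-of-cycle
            # population, before dilution.
            events = sample_scaled_events(rng, state.g, state.n, scenario.rates)
            _apply_events(state.n, events, passage)
            passages.append(passage)
            generations.append(cum_g)
            counts.append(state.n.copy())
            state = apply_bottleneck(state, protocol, rng, scenario.growth)
        else:
            # Single-cell modes: a seeded cell joins after the bottleneck
            # so it grows a full cycle before first facing dilution.
            end_g = state.g.copy()
            end_counts = state.n.copy()
            passages.append(passage)
            generations.append(cum_g)
            counts.append(end_counts)
            state = apply_bottleneck(state, protocol, rng, scenario.growth)
            if protocol.seeding_mode == "single":
                events = sample_mutation_events(rng, end_g, end_counts, scenario.rates)
            else:
                events = sample_poisson_events(rng, end_g, end_counts, scenario.rates)
            _apply_events(state.n, events, passage)

    traj = Trajectory(
        passages=np.array(passages, dtype=int),
        generations=np.array(generations, dtype=float),
        counts=np.array(counts, dtype=float),
        seed=seed,
    )
    traj.outcome, traj.fixation_generation = classify_outcome(
        traj, threshold=protocol.fixation_threshold
    )
    return traj


def classify_outcome(trajectory: Trajectory, threshold: float = 0.99):
    """Label a trajectory's evolutionary outcome.

    ``fixed_d2`` -- the double-inactivation class reached the fixation
    threshold (first crossing reported as the fixation generation);
    ``segregated`` -- duplication-bearing classes were present but are
    gone at the end; ``steady_state`` -- every strain fraction changed by
    < 1e-3 over the last 10% of records; otherwise ``incomplete``.
    """
    if len(trajectory) == 0:
        raise ValueError("trajectory is empty")
    frac = trajectory.fractions()
    d2 = frac[:, StrainType.D2]
    crossed = np.nonzero(d2 >= threshold)[0]
    if crossed.size:
        return "fixed_d2", float(trajectory.generations[crossed[0]])

    dup_classes = trajectory.counts[:, 1:].sum(axis=1)
    if np.any(dup_classes > 0) and dup_classes[-1] == 0:
        return "segregated", None

    tail = max(2, int(np.ceil(len(trajectory) * 0.10)))
    window = frac[-tail:]
    if np.all(window.max(axis=0) - window.min(axis=0) < 1e-3):
        return "steady_state", None
    return "incomplete", None


def mean_of_trajectories(trajectories: Sequence[Trajectory]) -> Trajectory:
    """Pointwise arithmetic mean of counts (truncated to the shortest run)."""
    if not trajectories:
        raise ValueError("no trajectories to average")
    npass = min(len(t) for t in trajectories)
    counts = np.mean([t.counts[:npass] for t in trajectories], axis=0)
    gens = np.mean([t.generations[:npass] for t in trajectories], axis=0)
    return Trajectory(
        passages=trajectories[0].passages[:npass].copy(),
        generations=gens,
        counts=counts,
    )


@dataclass
class ReplicateSummary:
    """Mean trajectory and outcome statistics over independent replicates."""

    mean: Trajectory
    outcome_fractions: Dict[str, float]
    fixation_generations: List[float]
    replicates: int
    seeds: List[int]


def average_replicates(scenario: Scenario) -> ReplicateSummary:
    """Run ``scenario.replicates`` independent seeds and average them.

    Replicate i runs with seed ``scenario.seed + i`` on an independent
    stream; returns the pointwise mean of counts per passage plus the
    fraction of replicates in each outcome class and the fixation
    generations of the replicates that fixed.
    """
    seeds = [scenario.seed + i for i in range(scenario.replicates)]
    runs = [run_serial_passages(scenario, seed=s) for s in seeds]
    outcomes: Dict[str, float] = {}
    for t in runs:
        outcomes[t.outcome] = outcomes.get(t.outcome, 0) + 1
    outcome_fractions = {k: v / len(runs) for k, v in outcomes.items()}
    fixations = [t.fixation_generation for t in runs if t.fixation_generation is not None]
    return ReplicateSummary(
        mean=mean_of_trajectories(runs),
        outcome_fractions=outcome_fractions,
        fixation_generations=fixations,
        replicates=scenario.replicates,
        seeds=seeds,
    )


#: Fitness presets for the six standard selection scenarios: the
#: duplication confers no advantage (A), a 5% (B) or 25% (C) advantage;
#: D-F add, on top of the 25% duplication advantage, a further 2/5/10%
#: advantage for deleting the unnecessary duplicate genes (D2), composed
#: multiplicatively.  The single-inactivation class D1 is assigned the
#: duplication fitness (its own fitness is not separately constrained).
PANEL_PRESETS = {
    "A": FitnessScheme(wt=1.0, dup=1.0, d1=1.0, d2=1.0),
    "B": FitnessScheme(wt=1.0, dup=1.05, d1=1.05, d2=1.05),
    "C": FitnessScheme(wt=1.0, dup=1.25, d1=1.25, d2=1.25),
    "D": FitnessScheme(wt=1.0, dup=1.25, d1=1.25, d2=1.25 * 1.02),
    "E": FitnessScheme(wt=1.0, dup=1.25, d1=1.25, d2=1.25 * 1.05),
    "F": FitnessScheme(wt=1.0, dup=1.25, d1=1.25, d2=1.25 * 1.10),
}


def scenario_preset(panel: str, replicates: int = 100, seed: int = 0, **overrides) -> Scenario:
    """Standard selection scenario for panel label A-F.

    All presets use the default transition rates, growth parameters and
    passage protocol; keyword overrides replace whole Scenario fields.
    """
    key = panel.upper()
    if key not in PANEL_PRESETS:
        raise ValueError(f"unknown panel {panel!r}; expected one of {sorted(PANEL_PRESETS)}")
    scenario = Scenario(
        scheme=PANEL_PRESETS[key],
        replicates=replicates,
        seed=seed,
    )
    if overrides:
        scenario = replace(scenario, **overrides)
    return scenario
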