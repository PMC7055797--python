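"""Domain types for the four-strain duplication/divergence model.

The model follows a bacterial population adapting to a new niche through a
tandem duplication of a chromosomal segment that carries (at least) two
essential genes.  Four strain classes exist:

* ``WT``  -- wild type, single-copy chromosome.
* ``DUP`` -- carries the duplication; unstable, can segregate back to WT.
* ``D1``  -- duplication with one essential gene inactivated in one copy;
  can still segregate, but only to the arrangement retaining the intact
  copy.
* ``D2``  -- duplication with a *different* essential gene inactivated in
  each copy.  Segregation of either copy would now remove an essential
  gene, so the duplication -- and with it the rearranged gene order -- is
  locked in place.  ``D2`` is absorbing: no outgoing transitions.

Transitions are parameterized per generation of growth of the parent
strain.  The five arrows of the model, in the fixed evaluation order used
throughout the package, are::

    WT  -> DUP   duplication formation
    DUP -> WT    segregation (collapse to single copy)
    DUP -> D1    first essential-gene inactivation
    D1  -> WT    segregation retaining the intact copy
    D1  -> D2    second essential-gene inactivation
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Tuple

import numpy as np

__all__ = [
    "StrainType",
    "ARROWS",
    "ValidationError",
    "FitnessScheme",
    "TransitionRates",
    "PopulationState",
    "default_rates",
    "validate_scheme",
]


class StrainType(enum.IntEnum):
    """The four strain classes; integer values index count arrays."""

    WT = 0
    DUP = 1
    D1 = 2
    D2 = 3


Arrow = Tuple[StrainType, StrainType]

#: The five permitted transitions, in fixed evaluation order.  D2 is
#: terminal; any arrow out of D2 is a validation error.
ARROWS: Tuple[Arrow, ...] = (
    (StrainType.WT, StrainType.DUP),
    (StrainType.DUP, StrainType.WT),
    (StrainType.DUP, StrainType.D1),
    (StrainType.D1, StrainType.WT),
    (StrainType.D1, StrainType.D2),
)

#: Short names for the five arrows as used in scenario configuration files.
ARROW_NAMES: Mapping[str, Arrow] = {
    "dup": (StrainType.WT, StrainType.DUP),
    "seg": (StrainType.DUP, StrainType.WT),
    "inact1": (StrainType.DUP, StrainType.D1),
    "d1_seg": (StrainType.D1, StrainType.WT),
    "inact2": (StrainType.D1, StrainType.D2),
}


class ValidationError(ValueError):
    """A fitness scheme or rate set violates a model invariant."""


@dataclass(frozen=True)
class FitnessScheme:
    """Relative fitness per strain, wild type = 1 by convention.

    Fitness multiplies the Monod growth rate, so a strain with ``v = 1.25``
    grows 25% faster than wild type at every resource concentration.
    """

    wt: float = 1.0
    dup: float = 1.0
    d1: float = 1.0
    d2: float = 1.0

    def __getitem__(self, strain: StrainType) -> float:
        return self.as_array()[int(strain)]

    def as_array(self) -> np.ndarray:
        return np.array([self.wt, self.dup, self.d1, self.d2], dtype=float)


@dataclass(frozen=True)
class TransitionRates:
    """Per-generation transition rates keyed by (parent, child) arrow.

    Rates are dimensionless probabilities per generation of growth of the
    parent strain; only the five arrows in :data:`ARROWS` may be nonzero.
    """

    mu: Mapping[Arrow, float] = field(default_factory=dict)

    def rate(self, parent: StrainType, child: StrainType) -> float:
        return float(self.mu.get((parent, child), 0.0))

    def items(self) -> Iterator[Tuple[Arrow, float]]:
        for arrow in ARROWS:
            yield arrow, self.rate(*arrow)

    @classmethod
    def from_named(
        cls,
        dup: float = 0.0,
        seg: float = 0.0,
        inact1: float = 0.0,
        d1_seg: float = 0.0,
        inact2: float = 0.0,
    ) -> "TransitionRates":
        named = {"dup": dup, "seg": seg, "inact1": inact1, "d1_seg": d1_seg, "inact2": inact2}
        return cls(mu={ARROW_NAMES[k]: float(v) for k, v in named.items()})

    def to_named(self) -> dict:
        return {name: self.rate(*arrow) for name, arrow in ARROW_NAMES.items()}


def default_rates() -> TransitionRates:
    """Package default transition rates.

    Duplication formation and segregation sit inside the experimentally
    observed spontaneous range (1e-2 down to 1e-5 per cell per generation,
    segregation being the faster process); gene inactivation uses the
    canonical spontaneous loss-of-function rate of ~1e-5 per gene per
    generation.  Segregation of a D1 strain is half the DUP segregation
    rate: only the recombinant retaining the intact essential-gene copy is
    viable.
    """
    return TransitionRates.from_named(
        dup=1e-4,
        seg=1e-2,
        inact1=1e-5,
        d1_seg=5e-3,
        inact2=1e-5,
    )


@dataclass
class PopulationState:
    """Absolute cell counts per strain within one batch-growth cycle.

    ``n`` holds absolute cell numbers (fractional values are permitted in
    continuous-dilution mode), ``resource`` the remaining limiting
    resource, ``time`` the elapsed within-cycle time and ``g`` the
    generations (log2 fold-expansion) each strain has grown this cycle.
    """

    n: np.ndarray
    resource: float
    time: float = 0.0
    g: np.ndarray = field(default_factory=lambda: np.zeros(len(StrainType)))

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.n.shape != (len(StrainType),):
            raise ValidationError(f"n must have shape ({len(StrainType)},), got {self.n.shape}")
        if np.any(self.n < 0):
            raise ValidationError("cell counts must be non-negative")
        if self.resource < 0:
            raise ValidationError("resource must be non-negative")

    @classmethod
    def founding(cls, n_wt: float, resource: float) -> "PopulationState":
        n = np.zeros(len(StrainType))
        n[StrainType.WT] = n_wt
        return cls(n=n, resource=resource)

    @property
    def total(self) -> float:
        return float(self.n.sum())

    def fractions(self) -> np.ndarray:
        tot = self.total
        return self.n / tot if tot > 0 else np.zeros_like(self.n)

    def copy(self) -> "PopulationState":
        return PopulationState(
            n=self.n.copy(), resource=self.resource, time=self.time, g=self.g.copy()
        )


def validate_scheme(
    scheme: FitnessScheme, rates: TransitionRates
) -> Tuple[FitnessScheme, TransitionRates]:
    """Validate a fitness scheme / rate set pair, returning them unchanged.

    Raises :class:`ValidationError` naming the offending field when a
    fitness value is non-positive, a rate lies outside [0, 1], or any arrow
    out of the terminal D2 class is nonzero.
    """
    for strain in StrainType:
        v = scheme[strain]
        if not np.isfinite(v) or v <= 0:
            raise ValidationError(f"fitness v[{strain.name}] = {v}: must be finite and > 0")
    for arrow, mu in rates.mu.items():
        parent, child = arrow
        label = f"mu[{parent.name}->{child.name}]"
        if not np.isfinite(mu) or mu < 0 or mu > 1:
            raise ValidationError(f"{label} = {mu}: rates must lie in [0, 1]")
        if parent is StrainType.D2 and mu != 0:
            raise ValidationError(f"{label} = {mu}: D2 is terminal, no outgoing transitions")
        if mu != 0 and arrow not in ARROWS:
            raise ValidationError(f"{label} = {mu}: not a permitted transition")
    return scheme, rates
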