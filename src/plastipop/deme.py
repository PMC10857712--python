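"""Single-subpopulation dynamics: resource bookkeeping, starvation
switching, type-II intraguild predation and the per-deme update.

A deme holds the expected stage composition of both strains (a 2 x 10
nonnegative array: plastic strain first), a resource amount ``R`` and a diet
label. Within one step the deme is projected with the matrices of its
current effective resource state, the resource is decremented linearly by
the consumer count, and predatory adults of each strain remove juveniles
and dauer larvae of the other via a Holling type-II functional response.

This module is the scalar reference implementation of the update; the
lattice engine in :mod:`plastipop.metapop` vectorises the same arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .lifecycle import (
    CONSUMER_STAGES,
    D,
    DIETS,
    J,
    N_STAGES,
    PREDATOR_STAGES,
    PREY_STAGES,
    ResourceState,
    StrainParams,
    build_fertility_matrix,
    build_transition_matrix,
)

__all__ = [
    "PredationParams",
    "GlobalParams",
    "Deme",
    "consumer_count",
    "update_resource",
    "effective_state",
    "predator_count",
    "holling_kills",
    "apply_predation",
    "step_deme",
]

PLASTIC, NONPLASTIC = 0, 1


@dataclass(frozen=True)
class PredationParams:
    """Type-II functional-response parameters: attack rate ``a`` (per prey
    per step) and handling time ``h`` (steps per prey)."""

    attack_rate: float = 0.2
    handling_time: float = 0.15

    def __post_init__(self) -> None:
        if self.attack_rate < 0 or self.handling_time < 0:
            raise ValueError("attack rate and handling time must be >= 0")


@dataclass(frozen=True)
class GlobalParams:
    """Strain-independent model parameters.

    ``beta`` — per-capita resource consumption per step; ``psi`` — intensity
    of density-dependent mortality; ``dispersal`` — fraction ``r`` of dauers
    exported to EACH von Neumann neighbour per step (so ``4 r <= 1``);
    ``extinction_threshold`` — expected counts below this are zeroed so that
    competitive exclusion is a reachable state.
    """

    beta: float = 0.002
    psi: float = 6e-5
    predation: PredationParams = field(default_factory=PredationParams)
    dispersal: float = 0.01
    extinction_threshold: float = 1e-6

    def __post_init__(self) -> None:
        if min(self.beta, self.psi, self.dispersal, self.extinction_threshold) < 0:
            raise ValueError("all global parameters must be >= 0")
        if 4.0 * self.dispersal > 1.0 + 1e-12:
            raise ValueError(
                f"dispersal r={self.dispersal} invalid: a deme cannot export "
                "more than its dauers (requires 4r <= 1)"
            )


@dataclass
class Deme:
    """One subpopulation: stage counts, resource amount and diet label."""

    counts: np.ndarray  # shape (2, 10); [PLASTIC], [NONPLASTIC]
    resource: float
    diet: ResourceState

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (2, N_STAGES):
            raise ValueError(f"counts must have shape (2, {N_STAGES})")
        if np.any(self.counts < 0) or self.resource < 0:
            raise ValueError("counts and resource must be nonnegative")
        if self.diet not in DIETS:
            raise ValueError("diet label must be OP50 or L76, never STARVED")

    @classmethod
    def empty(cls, diet: ResourceState = ResourceState.OP50, resource: float = 500.0) -> "Deme":
        return cls(np.zeros((2, N_STAGES)), resource, diet)

    def copy(self) -> "Deme":
        return Deme(self.counts.copy(), self.resource, self.diet)

    def flat(self) -> np.ndarray:
        """The 20-entry population vector (plastic stages 1-10, then
        non-plastic), matching the block projection layout."""
        return self.counts.reshape(-1)


def consumer_count(counts: np.ndarray) -> float:
    """Total feeding individuals ``N_c`` over both strains — every stage
    except the eggs and the non-feeding dauer larvae."""
    counts = np.asarray(counts, dtype=float)
    return float(counts[..., list(CONSUMER_STAGES)].sum())


def update_resource(resource: float, beta: float, n_consumers: float) -> float:
    """Linear consumption ``R' = R - beta * N_c``, clamped at zero."""
    return max(resource - beta * n_consumers, 0.0)


def effective_state(
    resource: float, beta: float, n_consumers: float, diet: ResourceState
) -> ResourceState:
    """Resource state experienced this step: ``STARVED`` iff the available
    resource is strictly below the per-step demand ``R_min = beta * N_c``,
    else the deme's diet label."""
    if resource < beta * n_consumers:
        return ResourceState.STARVED
    return diet


def predator_count(strain_counts: np.ndarray, lam: float) -> float:
    """Expected predatory-mouth-form individuals among the young and
    breeding adults (YA + RA1..RA5; old adults excluded) of one strain."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    strain_counts = np.asarray(strain_counts, dtype=float)
    return float(lam * strain_counts[list(PREDATOR_STAGES)].sum())


def holling_kills(n_prey: float, n_predators: float, a: float, h: float) -> float:
    """Expected prey killed in one step under a Holling type-II response.

    Per predator, the kill rate ``a n / (1 + a h n)`` saturates at ``1/h``;
    the total is clamped at the prey available.
    """
    if min(n_prey, n_predators, a, h) < 0:
        raise ValueError("all predation inputs must be >= 0")
    if n_prey == 0.0:
        return 0.0
    kills = a * n_prey / (1.0 + a * h * n_prey) * n_predators
    return min(kills, n_prey)


def apply_predation(
    deme: Deme, strains: tuple[StrainParams, StrainParams], params: GlobalParams
) -> Deme:
    """Remove juveniles and dauer larvae of each strain eaten by the other.

    Both predation directions are evaluated from the same pre-predation
    state (simultaneous, order-independent). Predator numbers use the lambda
    of the deme's current effective resource state.
    """
    a, h = params.predation.attack_rate, params.predation.handling_time
    n_c = consumer_count(deme.counts)
    state = effective_state(deme.resource, params.beta, n_c, deme.diet)
    pre = deme.counts.copy()
    post = deme.counts.copy()
    for prey_strain, pred_strain in ((PLASTIC, NONPLASTIC), (NONPLASTIC, PLASTIC)):
        lam = strains[pred_strain].mouthform.for_state(state, deme.diet)
        n_pred = predator_count(pre[pred_strain], lam)
        for stage in PREY_STAGES:
            post[prey_strain, stage] -= holling_kills(pre[prey_strain, stage], n_pred, a, h)
    post[post < params.extinction_threshold] = 0.0
    return Deme(post, deme.resource, deme.diet)


def step_deme(
    deme: Deme,
    strains: tuple[StrainParams, StrainParams],
    params: GlobalParams,
    resource_limitation: bool = True,
) -> Deme:
    """One projection step for a single deme (no predation, no dispersal).

    The effective state and the consumer count are evaluated on the pre-step
    composition; the population is projected with the block matrix
    ``A(epsilon)`` (survival ``sigma(N_c)`` baked into ``U``), and the
    resource is decremented with the same ``N_c``. Entries below the
    extinction threshold are zeroed. With ``resource_limitation=False`` the
    resource is treated as unlimited (state is always the diet label, no
    decrement).
    """
    n_c = consumer_count(deme.counts)
    if resource_limitation:
        state = effective_state(deme.resource, params.beta, n_c, deme.diet)
        new_resource = update_resource(deme.resource, params.beta, n_c)
    else:
        state = deme.diet
        new_resource = deme.resource
    new_counts = np.empty_like(deme.counts)
    for s, strain in enumerate(strains):
        A = build_transition_matrix(strain, state, n_c, params.psi) + build_fertility_matrix(
            strain, state
        )
        new_counts[s] = A @ deme.counts[s]
    new_counts[new_counts < params.extinction_threshold] = 0.0
    return Deme(new_counts, new_resource, deme.diet)
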